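"""Morphological descriptors of individual marine snow vignettes.

A vignette is the cut-out greyscale image of one particle as exported by
in situ imaging systems such as the Underwater Vision Profiler (UVP).
This module turns a vignette into a record of 24 morphological
descriptors spanning four groups: size, grey intensity, shape, and
structure. These records are the raw material of the PCA morphospace.

Conventions (all oracle-checkable):

* grey polarity: 0 = black, 255 = white; particles are dark on a light
  background.
* perimeter: number of foreground pixel edges adjacent to background
  (exact edge count, not a Crofton/Crofton-like estimate).
* second-order moments include the +1/12 pixel-extent correction, so a
  1 x n bar has elongation exactly n and a single pixel elongation 1.
* grey statistics are computed over foreground pixels only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.morphology import convex_hull_image

__all__ = [
    "Vignette",
    "ObjectMask",
    "EmptyObjectError",
    "FEATURE_NAMES",
    "FEATURE_GROUPS",
    "binarize",
    "extract_features",
    "feature_table",
]

#: descriptor names, grouped: size / grey intensity / shape / structure
FEATURE_GROUPS: dict[str, tuple[str, ...]] = {
    "size": (
        "area",
        "perimeter",
        "esd",
        "major_axis",
        "minor_axis",
        "convex_area",
    ),
    "grey": (
        "mean_grey",
        "median_grey",
        "min_grey",
        "max_grey",
        "integrated_grey",
        "darkness",
    ),
    "shape": (
        "elongation",
        "circularity",
        "eccentricity",
        "symmetry_major",
        "symmetry_minor",
        "solidity",
    ),
    "structure": (
        "grey_std",
        "grey_skewness",
        "grey_kurtosis",
        "grey_range",
        "perimeter_area_ratio",
        "boundary_index",
    ),
}

FEATURE_NAMES: tuple[str, ...] = tuple(
    name for group in FEATURE_GROUPS.values() for name in group
)

# 8-connectivity for foreground components
_STRUCT8 = np.ones((3, 3), dtype=bool)


class EmptyObjectError(ValueError):
    """Raised when binarization finds no foreground pixel."""

    def __init__(self, object_id: str):
        self.object_id = object_id
        super().__init__(f"empty object: no pixel below threshold for {object_id!r}")


@dataclass(frozen=True)
class Vignette:
    """A single-particle greyscale image plus acquisition metadata.

    Parameters
    ----------
    pixels
        2-D uint8-compatible array of grey values in [0, 255], 0 = black.
    pixel_size_mm
        Edge length of one pixel in millimetres (> 0).
    object_id
        Opaque identifier, unique within a dataset.
    """

    pixels: np.ndarray
    pixel_size_mm: float
    object_id: str

    def __post_init__(self):
        px = np.asarray(self.pixels)
        if px.ndim != 2 or px.size == 0:
            raise ValueError(f"{self.object_id!r}: pixel grid must be non-empty 2-D")
        if px.min() < 0 or px.max() > 255:
            raise ValueError(f"{self.object_id!r}: grey values outside [0, 255]")
        if not self.pixel_size_mm > 0:
            raise ValueError(f"{self.object_id!r}: pixel_size_mm must be > 0")
        object.__setattr__(self, "pixels", px)


@dataclass(frozen=True)
class ObjectMask:
    """Binary foreground mask congruent with a vignette.

    Exactly one 8-connected component; at least one foreground pixel.
    """

    mask: np.ndarray

    def __post_init__(self):
        m = np.asarray(self.mask, dtype=bool)
        if not m.any():
            raise ValueError("mask has no foreground pixel")
        _, n = ndimage.label(m, structure=_STRUCT8)
        if n != 1:
            raise ValueError(f"mask has {n} connected components, expected 1")
        object.__setattr__(self, "mask", m)


def binarize(vignette: Vignette, threshold: float) -> ObjectMask:
    """Segment a vignette into its single largest dark object.

    Foreground are pixels strictly darker than ``threshold`` (grey value
    < threshold) against the light background. When several 8-connected
    components exist only the largest is kept (ties broken by label
    order, i.e. scan order).

    Raises
    ------
    EmptyObjectError
        If no pixel is darker than the threshold.
    """
    if not 0 < threshold < 255:
        raise ValueError(f"threshold must be in (0, 255), got {threshold}")
    fg = vignette.pixels < threshold
    if not fg.any():
        raise EmptyObjectError(vignette.object_id)
    labels, n = ndimage.label(fg, structure=_STRUCT8)
    if n > 1:
        sizes = ndimage.sum_labels(fg, labels, index=np.arange(1, n + 1))
        fg = labels == (int(np.argmax(sizes)) + 1)
    return ObjectMask(fg)


def _edge_perimeter(mask: np.ndarray) -> int:
    """Count foreground pixel edges adjacent to background (or the frame)."""
    padded = np.pad(mask, 1, constant_values=False)
    p = 0
    for axis, shift in ((0, 1), (0, -1), (1, 1), (1, -1)):
        p += int((padded & ~np.roll(padded, shift, axis=axis)).sum())
    return p


def _central_moments(mask: np.ndarray) -> tuple[float, float, float, float, float]:
    """Centroid and second central moments with the +1/12 pixel-extent term."""
    rows, cols = np.nonzero(mask)
    n = rows.size
    cr, cc = rows.mean(), cols.mean()
    mu_rr = ((rows - cr) ** 2).mean() + 1.0 / 12.0
    mu_cc = ((cols - cc) ** 2).mean() + 1.0 / 12.0
    mu_rc = ((rows - cr) * (cols - cc)).mean()
    return cr, cc, mu_rr, mu_cc, mu_rc


def _axis_symmetry(mask: np.ndarray, cr: float, cc: float, theta: float) -> float:
    """Fraction of foreground pixels whose mirror image about the axis
    through the centroid at angle ``theta`` is also foreground."""
    rows, cols = np.nonzero(mask)
    y = rows - cr
    x = cols - cc
    # reflect across the line through origin with direction (cos t, sin t)
    c2, s2 = math.cos(2 * theta), math.sin(2 * theta)
    xr = c2 * x + s2 * y
    yr = s2 * x - c2 * y
    rr = np.rint(yr + cr).astype(int)
    cc_r = np.rint(xr + cc).astype(int)
    inside = (
        (rr >= 0) & (rr < mask.shape[0]) & (cc_r >= 0) & (cc_r < mask.shape[1])
    )
    hits = np.zeros(rows.size, dtype=bool)
    hits[inside] = mask[rr[inside], cc_r[inside]]
    return float(hits.mean())


def extract_features(vignette: Vignette, mask: ObjectMask) -> dict[str, float]:
    """Compute the 24 morphological descriptors of one object.

    Grey statistics are computed over foreground pixels only; pixels
    outside the mask never contribute. Degenerate cases: a single-pixel
    object has elongation 1 (the +1/12 moment term makes both axes
    equal) and perimeter 4; zero grey variance yields skewness and
    kurtosis of 0 by convention.
    """
    m = mask.mask
    if m.shape != vignette.pixels.shape:
        raise ValueError(
            f"{vignette.object_id!r}: mask shape {m.shape} does not match "
            f"vignette shape {vignette.pixels.shape}"
        )

    area = float(m.sum())
    perimeter = float(_edge_perimeter(m))
    esd = 2.0 * math.sqrt(area / math.pi)
    cr, cc, mu_rr, mu_cc, mu_rc = _central_moments(m)
    # principal axes of the inertia ellipse
    common = (mu_rr + mu_cc) / 2.0
    diff = math.hypot((mu_rr - mu_cc) / 2.0, mu_rc)
    lam1, lam2 = common + diff, common - diff
    major = 4.0 * math.sqrt(max(lam1, 0.0))
    minor = 4.0 * math.sqrt(max(lam2, 0.0))
    elongation = major / minor if minor > 0 else 1.0
    eccentricity = math.sqrt(max(1.0 - lam2 / lam1, 0.0)) if lam1 > 0 else 0.0
    # orientation of the major axis (image x = cols, y = rows)
    theta = 0.5 * math.atan2(2.0 * mu_rc, mu_cc - mu_rr)

    hull = convex_hull_image(m) if area > 1 else m
    convex_area = float(hull.sum())

    grey = vignette.pixels[m].astype(float)
    mean_grey = float(grey.mean())
    gstd = float(grey.std())  # population std
    if gstd > 0:
        z = (grey - mean_grey) / gstd
        skewness = float((z**3).mean())
        kurtosis = float((z**4).mean() - 3.0)  # excess
    else:
        skewness = 0.0
        kurtosis = 0.0

    return {
        "area": area,
        "perimeter": perimeter,
        "esd": esd,
        "major_axis": major,
        "minor_axis": minor,
        "convex_area": convex_area,
        "mean_grey": mean_grey,
        "median_grey": float(np.median(grey)),
        "min_grey": float(grey.min()),
        "max_grey": float(grey.max()),
        "integrated_grey": float(grey.sum()),
        "darkness": 255.0 - mean_grey,
        "elongation": elongation,
        "circularity": 4.0 * math.pi * area / perimeter**2,
        "eccentricity": eccentricity,
        "symmetry_major": _axis_symmetry(m, cr, cc, theta),
        "symmetry_minor": _axis_symmetry(m, cr, cc, theta + math.pi / 2.0),
        "solidity": area / convex_area,
        "grey_std": gstd,
        "grey_skewness": skewness,
        "grey_kurtosis": kurtosis,
        "grey_range": float(grey.max() - grey.min()),
        "perimeter_area_ratio": perimeter / area,
        # boundary complexity; ln(1+.) keeps it finite for 1-px objects
        "boundary_index": math.log1p(perimeter) / math.log1p(area),
    }


@dataclass
class FeatureTableResult:
    """Feature table plus the ids of vignettes that failed segmentation."""

    table: pd.DataFrame
    failed_ids: list[str] = field(default_factory=list)


def feature_table(
    vignettes,
    threshold: float = 230.0,
    on_empty: str = "skip",
) -> FeatureTableResult:
    """Extract features for a collection of vignettes.

    One row per object, indexed by ``object_id``. Vignettes whose
    binarization finds no foreground are skipped and their ids recorded
    (``on_empty="skip"``) or re-raised (``on_empty="raise"``).

    Raises
    ------
    ValueError
        On duplicate object ids, or an empty input collection.
    """
    rows: dict[str, dict[str, float]] = {}
    failed: list[str] = []
    n_in = 0
    for v in vignettes:
        n_in += 1
        if v.object_id in rows:
            raise ValueError(f"duplicate object_id: {v.object_id!r}")
        try:
            mask = binarize(v, threshold)
        except EmptyObjectError:
            if on_empty == "raise":
                raise
            failed.append(v.object_id)
            continue
        rows[v.object_id] = extract_features(v, mask)
    if n_in == 0:
        raise ValueError("no vignettes supplied")
    table = pd.DataFrame.from_dict(rows, orient="index", columns=list(FEATURE_NAMES))
    table.index.name = "object_id"
    return FeatureTableResult(table=table, failed_ids=failed)
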