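"""Configuration, file readers and writers.

Tabular inputs follow the EcoTaxa object-export convention: a
tab-separated file with one header row, or two header rows where the
second row carries type tags such as ``[f]``/``[t]`` and is skipped.
Column aliases commonly seen in UVP/EcoTaxa exports are normalized to
the canonical names ``object_id``, ``depth_m``, ``cast``, ``time_d``,
``annotation`` and ``esd_mm``; unknown columns are preserved.

The annotation category separates the non-living stream (marine snow)
from living forms (zooplankton); the split is done upstream by
EcoTaxa's classifiers, this reader only routes on the stored category.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from PIL import Image

from .features import Vignette
from .ecology import ObservationSet

logger = logging.getLogger("snowmorph")

__all__ = [
    "PipelineConfig",
    "read_objects",
    "read_vignette_png",
    "write_vignette_png",
    "write_table",
    "read_table",
]

#: annotation keywords routed to the marine snow (non-living) stream
SNOW_KEYWORDS = ("detritus", "marine snow", "aggregate", "fiber", "artefact")

#: canonical name <- accepted aliases (lowercased)
COLUMN_ALIASES: dict[str, tuple[str, ...]] = {
    "object_id": ("object_id", "objid", "id"),
    "depth_m": ("depth_m", "object_depth_min", "depth", "object_depth"),
    "cast": ("cast", "sample_id", "station", "profile"),
    "time_d": ("time_d", "owd", "open_water_days", "time_days"),
    "annotation": ("annotation", "object_annotation_category", "category"),
    "esd_mm": ("esd_mm", "object_esd", "esd"),
    "volume_L": ("volume_L", "sample_volume", "acq_volimage"),
}


@dataclass
class PipelineConfig:
    """Instrument constants and pipeline parameters.

    ``pixel_size_mm`` has no default: it is an instrument calibration
    constant that must be supplied.
    """

    pixel_size_mm: float
    image_volume_L: float = 1.0  # illuminated volume per image
    min_object_pixels: int = 80  # vignettes stored for objects above this
    depth_bin_m: float = 5.0
    k: int = 5
    n_components: int = 4
    trim_fraction: float = 0.001
    seed: int = 0
    n_restarts: int = 10
    binarize_threshold: float = 245.0
    log_set: tuple[str, ...] = (
        "area",
        "perimeter",
        "esd",
        "convex_area",
        "integrated_grey",
        "perimeter_area_ratio",
    )
    size_bins_per_octave: int = 5
    snow_keywords: tuple[str, ...] = SNOW_KEYWORDS

    def __post_init__(self):
        for name in ("pixel_size_mm", "image_volume_L", "min_object_pixels",
                     "depth_bin_m", "k", "n_components"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        if self.k < 2:
            raise ValueError("k must be >= 2 for named morphotypes")

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        """Load from a YAML or JSON mapping."""
        text = Path(path).read_text()
        data = yaml.safe_load(text)
        for key in ("log_set", "snow_keywords"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["log_set"] = list(d["log_set"])
        d["snow_keywords"] = list(d["snow_keywords"])
        return d


def _normalize_columns(df: pd.DataFrame) -> pd.DataFrame:
    lower = {c.lower(): c for c in df.columns}
    rename = {}
    for canonical, aliases in COLUMN_ALIASES.items():
        for alias in aliases:
            if alias in lower:
                rename[lower[alias]] = canonical
                break
    return df.rename(columns=rename)


def read_table(path) -> pd.DataFrame:
    """Read a tab-separated table, tolerating a two-row EcoTaxa header."""
    df = pd.read_csv(path, sep="\t", dtype={})
    if len(df) and df.iloc[0].astype(str).str.startswith("[").all():
        df = df.iloc[1:].reset_index(drop=True)
        for col in df.columns:
            try:
                df[col] = pd.to_numeric(df[col])
            except (ValueError, TypeError):
                pass
    return _normalize_columns(df)


def read_objects(
    path, config: PipelineConfig
) -> tuple[ObservationSet, pd.DataFrame, pd.DataFrame | None]:
    """Read an object export; route snow vs living; normalize units.

    Returns ``(snow_observations, living_table, feature_table)``.
    ``feature_table`` is the subset of recognised morphological
    descriptor columns indexed by object id, or None when absent.
    Volumes per (cast, depth bin) are taken from a ``volume_L`` column
    when present, else from ``image_volume_L`` summed over images
    (approximated as one image per object — suitable only for toy
    files, and logged).

    Raises
    ------
    ValueError
        If a required column (object_id, depth_m, cast) is missing.
    """
    df = read_table(path)
    for col in ("object_id", "depth_m", "cast"):
        if col not in df.columns:
            raise ValueError(f"missing required column: {col!r}")
    n0 = len(df)
    df = df.dropna(subset=["object_id", "depth_m"])
    if len(df) < n0:
        logger.warning("dropped %d unparseable rows", n0 - len(df))
    df["depth_m"] = df["depth_m"].astype(float)

    if "annotation" in df.columns:
        ann = df["annotation"].astype(str).str.lower()
        is_snow = ann.apply(
            lambda a: any(k in a for k in config.snow_keywords)
        )
    else:
        is_snow = pd.Series(True, index=df.index)
    living = df[~is_snow].copy()
    snow = df[is_snow].copy()
    logger.info("read %d objects: %d snow, %d living", len(df), len(snow),
                len(living))

    if "time_d" not in snow.columns:
        snow["time_d"] = 0.0
    if "morphotype" not in snow.columns:
        snow["morphotype"] = "unclassified"

    h = config.depth_bin_m
    snow["depth_bin"] = np.floor(snow["depth_m"] / h) * h
    if "volume_L" in snow.columns:
        volumes = (
            snow.groupby(["cast", "depth_bin"])["volume_L"].first().reset_index()
        )
    else:
        logger.warning(
            "no volume column; approximating bin volumes as "
            "image_volume_L per object"
        )
        volumes = (
            snow.groupby(["cast", "depth_bin"])
            .size()
            .mul(config.image_volume_L)
            .rename("volume_L")
            .reset_index()
        )
    objects = snow.drop(columns=["depth_bin"]).set_index("object_id")

    from .features import FEATURE_NAMES

    feat_cols = [c for c in FEATURE_NAMES if c in df.columns]
    features = objects[feat_cols].astype(float) if feat_cols else None
    obs = ObservationSet(
        objects=objects, volumes=volumes, bin_height_m=config.depth_bin_m
    )
    return obs, living, features


def read_vignette_png(path, pixel_size_mm: float) -> Vignette:
    """Load an 8-bit greyscale PNG named <object_id>.png."""
    p = Path(path)
    img = Image.open(p).convert("L")
    return Vignette(np.asarray(img), pixel_size_mm, p.stem)


def write_vignette_png(vignette: Vignette, directory) -> Path:
    out = Path(directory) / f"{vignette.object_id}.png"
    Image.fromarray(vignette.pixels.astype(np.uint8), mode="L").save(out)
    return out


def write_table(df: pd.DataFrame, path, index: bool = True) -> None:
    """Write a tab-separated table with a fixed float format (stable bytes)."""
    df.to_csv(path, sep="\t", index=index, float_format="%.10g",
              lineterminator="\n")
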