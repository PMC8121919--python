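"""Synthetic marine snow: vignettes and depth-time fields with known truth.

Every downstream module is testable without field data through two
generators:

* **Vignettes** emulating the five visually distinct morphotype
  archetypes — dark (small, very dark, compact disc), elongated
  (high-aspect ellipse), flake (small bright smooth disc), fluffy
  (medium bright blob with rough boundary and strong grey texture) and
  agglomerated (large union of several overlapping blobs of different
  shades). Default parameters are frozen so that the archetype medians
  reproduce the qualitative ordering observed in the field: dark is
  darkest, elongated has the highest aspect ratio, agglomerated the
  largest perimeter, flake is small/bright/smooth, fluffy
  medium/bright/heterogeneous, and the median perimeters order as
  flake < dark < fluffy ~ elongated << agglomerated.

* **Fields**: per-morphotype depth-time concentration grids built from
  a Gaussian peak sinking at a known speed v (its centre at
  z = v (t - t0)) superposed on a Martin-type (z/100)^b background,
  observed either exactly (expected concentrations) or through Poisson
  counts at a configurable sampled volume per 5-m bin.

All generators are deterministic given a seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter, label as nd_label

from .features import Vignette
from .ecology import ObservationSet, DEPTH_BIN_M

__all__ = [
    "ArchetypeSpec",
    "DEFAULT_ARCHETYPES",
    "MorphotypeField",
    "FieldSpec",
    "generate_vignette",
    "generate_population",
    "generate_field",
    "expected_concentration",
    "sample_powerlaw_esd",
]

#: grey values: background white, foreground clipped below the
#: segmentation threshold so objects never merge into the background
BACKGROUND_GREY = 255
MAX_FOREGROUND_GREY = 235
DEFAULT_THRESHOLD = 245.0


@dataclass(frozen=True)
class ArchetypeSpec:
    """Parameters of one synthetic morphotype archetype.

    ``scale_px`` is a lognormal size scale (disc radius or semi-major
    axis); ``grey_mean``/``grey_std`` set the foreground grey texture;
    ``aspect_range`` applies to the elongated type, ``n_blobs_range``
    to the agglomerated type and ``roughness`` (smoothing sigma of the
    random field, px) to the fluffy type.
    """

    name: str
    scale_log_mu: float
    scale_log_sigma: float
    grey_mean: float
    grey_std: float
    aspect_range: tuple[float, float] = (1.0, 1.0)
    n_blobs_range: tuple[int, int] = (1, 1)
    roughness: float = 3.5

    def __post_init__(self):
        if self.name not in (
            "dark",
            "elongated",
            "flake",
            "fluffy",
            "agglomerated",
        ):
            raise ValueError(f"unknown archetype {self.name!r}")


#: frozen default archetype parameters (pixel units)
DEFAULT_ARCHETYPES: dict[str, ArchetypeSpec] = {
    "dark": ArchetypeSpec("dark", math.log(6.3), 0.12, 45.0, 8.0),
    "elongated": ArchetypeSpec(
        "elongated", math.log(14.0), 0.12, 140.0, 18.0, aspect_range=(4.0, 6.5)
    ),
    "flake": ArchetypeSpec("flake", math.log(5.6), 0.12, 205.0, 6.0),
    "fluffy": ArchetypeSpec("fluffy", math.log(7.5), 0.12, 185.0, 30.0),
    "agglomerated": ArchetypeSpec(
        "agglomerated", math.log(6.5), 0.15, 175.0, 12.0, n_blobs_range=(4, 8)
    ),
}


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def _paint(mask: np.ndarray, grey_mean: float, grey_std: float,
           rng: np.random.Generator, texture: np.ndarray | None = None) -> np.ndarray:
    """White canvas with the mask filled by noisy grey values."""
    canvas = np.full(mask.shape, BACKGROUND_GREY, dtype=float)
    n = int(mask.sum())
    if texture is not None:
        t = texture[mask]
        t_std = t.std()
        t = t / t_std if t_std > 0 else t
        # structured texture plus mild pixel noise
        vals = grey_mean + grey_std * t + 0.25 * grey_std * rng.standard_normal(n)
    else:
        vals = grey_mean + grey_std * rng.standard_normal(n)
    canvas[mask] = np.clip(vals, 0, MAX_FOREGROUND_GREY)
    return canvas.astype(np.uint8)


def _disc_mask(shape, cy, cx, r) -> np.ndarray:
    yy, xx = np.ogrid[: shape[0], : shape[1]]
    return (yy - cy) ** 2 + (xx - cx) ** 2 <= r**2


def _largest_component(mask: np.ndarray) -> np.ndarray:
    labels, n = nd_label(mask, structure=np.ones((3, 3), dtype=bool))
    if n <= 1:
        return mask
    sizes = np.bincount(labels.ravel())[1:]
    return labels == (int(np.argmax(sizes)) + 1)


def _archetype_mask(spec: ArchetypeSpec, rng: np.random.Generator):
    """Binary shape mask for one archetype; returns (mask, texture|None)."""
    scale = float(rng.lognormal(spec.scale_log_mu, spec.scale_log_sigma))
    if spec.name in ("dark", "flake"):
        r = scale
        m = int(math.ceil(r)) + 4
        side = 2 * m + 1
        return _disc_mask((side, side), m, m, r), None
    if spec.name == "elongated":
        a = scale
        aspect = float(rng.uniform(*spec.aspect_range))
        b = max(a / aspect, 1.2)
        theta = float(rng.uniform(0, math.pi))
        m = int(math.ceil(a)) + 4
        side = 2 * m + 1
        yy, xx = np.ogrid[:side, :side]
        y, x = yy - m, xx - m
        u = x * math.cos(theta) + y * math.sin(theta)
        v = -x * math.sin(theta) + y * math.cos(theta)
        return (u / a) ** 2 + (v / b) ** 2 <= 1.0, None
    if spec.name == "fluffy":
        target_area = math.pi * scale**2
        side = int(6 * scale) + 9
        f = gaussian_filter(rng.standard_normal((side, side)), spec.roughness)
        f /= f.std()
        yy, xx = np.ogrid[:side, :side]
        r2 = ((yy - side // 2) ** 2 + (xx - side // 2) ** 2) / (1.6 * scale) ** 2
        score = f - r2  # favour the centre so the blob is compact-ish
        thr = np.quantile(score, 1.0 - target_area / score.size)
        mask = _largest_component(score > thr)
        return mask, (f - f[mask].mean())
    # agglomerated: chain of overlapping discs -> always one component
    n_blobs = int(rng.integers(spec.n_blobs_range[0], spec.n_blobs_range[1] + 1))
    radii = [float(rng.lognormal(spec.scale_log_mu, spec.scale_log_sigma))
             for _ in range(n_blobs)]
    side = int(2 * (sum(radii[: max(3, n_blobs)]) + 6))
    centres = [(side / 2.0, side / 2.0)]
    for i in range(1, n_blobs):
        base = centres[int(rng.integers(len(centres)))]
        ang = float(rng.uniform(0, 2 * math.pi))
        d = 0.95 * (radii[i - 1] + radii[i])
        centres.append((base[0] + d * math.sin(ang), base[1] + d * math.cos(ang)))
    mask = np.zeros((side, side), dtype=bool)
    shade = np.zeros((side, side))
    for (cy, cx), r in zip(centres, radii):
        dm = _disc_mask((side, side), cy, cx, r)
        mask |= dm
        shade[dm] = rng.uniform(-1.5, 1.5)  # per-blob shade: multielement look
    return mask, shade - (shade[mask].mean() if mask.any() else 0.0)


def _crop(mask: np.ndarray, pad: int = 3):
    rows = np.nonzero(mask.any(axis=1))[0]
    cols = np.nonzero(mask.any(axis=0))[0]
    r0, r1 = max(rows[0] - pad, 0), min(rows[-1] + pad + 1, mask.shape[0])
    c0, c1 = max(cols[0] - pad, 0), min(cols[-1] + pad + 1, mask.shape[1])
    return slice(r0, r1), slice(c0, c1)


def generate_vignette(
    spec: ArchetypeSpec,
    seed,
    object_id: str | None = None,
    pixel_size_mm: float = 0.088,
) -> tuple[Vignette, str]:
    """Render one synthetic vignette; returns (vignette, truth label)."""
    rng = _rng(seed)
    mask, texture = _archetype_mask(spec, rng)
    sl = _crop(mask)
    mask = mask[sl]
    texture = texture[sl] if texture is not None else None
    canvas = _paint(mask, spec.grey_mean, spec.grey_std, rng, texture)
    oid = object_id or f"{spec.name}_{rng.integers(1 << 31)}"
    return Vignette(canvas, pixel_size_mm, oid), spec.name


def generate_population(
    weights,
    n: int,
    seed,
    archetypes: dict[str, ArchetypeSpec] | None = None,
    pixel_size_mm: float = 0.088,
) -> tuple[list[Vignette], list[str]]:
    """Draw a mixed population of n vignettes with truth labels.

    ``weights`` are the mixture weights over the archetype names in
    their canonical order (dark, elongated, flake, fluffy,
    agglomerated); they must sum to 1.
    """
    archetypes = archetypes or DEFAULT_ARCHETYPES
    names = list(archetypes)
    w = np.asarray(weights, dtype=float)
    if w.size != len(names) or (w < 0).any() or not math.isclose(w.sum(), 1.0,
                                                                 abs_tol=1e-9):
        raise ValueError(f"weights must be {len(names)} non-negatives summing to 1")
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = _rng(seed)
    draws = rng.choice(len(names), size=n, p=w)
    vignettes, labels = [], []
    for i, j in enumerate(draws):
        v, lab = generate_vignette(
            archetypes[names[j]], rng, object_id=f"obj_{i:06d}",
            pixel_size_mm=pixel_size_mm,
        )
        vignettes.append(v)
        labels.append(lab)
    return vignettes, labels


# ---------------------------------------------------------------------------
# depth-time concentration fields


@dataclass(frozen=True)
class MorphotypeField:
    """Truth parameters of one morphotype's depth-time field.

    A Gaussian concentration peak of amplitude ``peak_amplitude_per_L``
    and width ``peak_width_m`` sinks at ``v_m_per_d`` (its centre at
    z = v (t - t0)); beneath it sits a Martin background
    ``n100_per_L`` x (z/100)^b.
    """

    v_m_per_d: float
    b: float
    n100_per_L: float = 0.0
    peak_amplitude_per_L: float = 1.0
    peak_width_m: float = 20.0
    t0_d: float = 0.0

    def __post_init__(self):
        if self.v_m_per_d < 0:
            raise ValueError("sinking speed must be >= 0")


@dataclass(frozen=True)
class FieldSpec:
    """Sampling design for a synthetic field campaign.

    One cast per time point; every 5-m bin down to ``z_max_m`` is
    sampled with ``bin_volume_L`` litres (the study-scale average is
    112 L per bin).
    """

    morphotypes: dict[str, MorphotypeField]
    times_d: tuple[float, ...]
    z_max_m: float = 520.0
    bin_volume_L: float = 112.0
    bin_height_m: float = DEPTH_BIN_M

    def __post_init__(self):
        if self.bin_volume_L <= 0:
            raise ValueError("bin volume must be > 0")


def _grid(spec: FieldSpec) -> np.ndarray:
    return np.arange(0.0, spec.z_max_m, spec.bin_height_m)


def _true_concentration(f: MorphotypeField, z_centre, t: float) -> np.ndarray:
    z = np.asarray(z_centre, dtype=float)
    zp = f.v_m_per_d * (t - f.t0_d)
    peak = f.peak_amplitude_per_L * np.exp(
        -((z - zp) ** 2) / (2.0 * f.peak_width_m**2)
    )
    bg = f.n100_per_L * (np.maximum(z, 2.5) / 100.0) ** f.b
    return peak + bg


def expected_concentration(spec: FieldSpec) -> pd.DataFrame:
    """Noiseless field: exact expected concentrations at bin centres.

    Returns the same long-table schema as
    :func:`snowmorph.ecology.bin_concentrations` (count is the expected
    count, possibly fractional), so it feeds the ecology operations
    directly.
    """
    edges = _grid(spec)
    centres = edges + spec.bin_height_m / 2.0
    rows = []
    for t in spec.times_d:
        cast = f"cast_t{t:g}"
        for name, f in spec.morphotypes.items():
            conc = _true_concentration(f, centres, t)
            for e, c in zip(edges, conc):
                rows.append((cast, t, e, name, c * spec.bin_volume_L,
                             spec.bin_volume_L, c))
    return pd.DataFrame(
        rows,
        columns=["cast", "time_d", "depth_bin", "morphotype", "count",
                 "volume_L", "conc_per_L"],
    )


def generate_field(spec: FieldSpec, seed) -> tuple[ObservationSet, dict]:
    """Poisson-sampled field: per-object observations plus the truth.

    Counts per (bin, time, morphotype) are Poisson with mean
    volume x n(z, t); each counted particle becomes one object record at
    the bin-centre depth. Returns ``(observations, truth)`` with truth
    holding the (v, b) parameters per morphotype.
    """
    rng = _rng(seed)
    edges = _grid(spec)
    centres = edges + spec.bin_height_m / 2.0
    obj_rows = []
    vol_rows = []
    for t in spec.times_d:
        cast = f"cast_t{t:g}"
        for e in edges:
            vol_rows.append((cast, e, spec.bin_volume_L))
        for name, f in spec.morphotypes.items():
            mean = spec.bin_volume_L * _true_concentration(f, centres, t)
            counts = rng.poisson(mean)
            for z, k in zip(centres, counts):
                obj_rows.extend([(z, cast, t, name)] * int(k))
    objects = pd.DataFrame(
        obj_rows, columns=["depth_m", "cast", "time_d", "morphotype"]
    )
    volumes = pd.DataFrame(vol_rows, columns=["cast", "depth_bin", "volume_L"])
    truth = {
        name: {"v_m_per_d": f.v_m_per_d, "b": f.b}
        for name, f in spec.morphotypes.items()
    }
    obs = ObservationSet(objects=objects, volumes=volumes,
                         bin_height_m=spec.bin_height_m)
    return obs, truth


def sample_powerlaw_esd(
    n: int, exponent: float, d_min: float, d_max: float, seed
) -> np.ndarray:
    """Draw n diameters from a power-law pdf proportional to d^exponent.

    Inverse-CDF sampling on [d_min, d_max]; used to exercise the size
    spectrum estimator against a known slope.
    """
    if exponent == -1.0:
        raise ValueError("exponent -1 not supported")
    rng = _rng(seed)
    u = rng.uniform(size=n)
    a1 = exponent + 1.0
    return (d_min**a1 + u * (d_max**a1 - d_min**a1)) ** (1.0 / a1)
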