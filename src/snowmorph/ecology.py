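"""Particle-ecology metrics derived from morphotyped observations.

Concentrations are binned over 5-m depth intervals as count / sampled
volume (ind L^-1). From the binned profiles the module derives the
classical export diagnostics:

* size-spectrum slope: OLS fit of ln n on ln d over log-spaced ESD
  bins, with n the normalized abundance count / (volume x bin width);
* vertical attenuation: Martin-type power law
  n_z = n_100 * (z / 100)^b fitted in log-log space over 0-500 m;
* Shannon-Wiener diversity H = -sum p_i ln p_i over morphotype
  concentrations treated as species;
* bulk sinking rates from the deepening of the concentration peak
  through time, via a type-I (ordinary least squares) regression of
  time (dependent) on peak depth (independent) — the speed is the
  inverse of the fitted slope;
* an upper-bound speed from a depth travelled over an elapsed time.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .clustering import fit_kmeans, assign

__all__ = [
    "ObservationSet",
    "bin_concentrations",
    "make_size_bins",
    "size_spectrum_slope",
    "attenuation_exponent",
    "shannon_diversity",
    "diversity_sensitivity",
    "peak_depth_series",
    "sinking_rate_regression",
    "SinkingRate",
    "max_sinking_speed",
]

DEPTH_BIN_M = 5.0


@dataclass
class ObservationSet:
    """Per-object records plus per-cast sampled volumes.

    ``objects``: one row per particle with columns ``depth_m``, ``cast``,
    ``time_d`` (days; open-water days or calendar), ``morphotype`` and
    optionally ``esd_mm``. ``volumes``: one row per (cast, depth_bin)
    with the sampled volume in litres; ``depth_bin`` is the lower edge
    of a half-open [z, z + bin) interval.
    """

    objects: pd.DataFrame
    volumes: pd.DataFrame
    bin_height_m: float = DEPTH_BIN_M

    def __post_init__(self):
        if (self.objects["depth_m"] < 0).any():
            raise ValueError("negative depths in observations")
        if (self.volumes["volume_L"] <= 0).any():
            raise ValueError("non-positive sampled volumes")


def bin_concentrations(obs: ObservationSet) -> pd.DataFrame:
    """Depth-bin counts into concentrations per morphotype and cast.

    Returns a long table (cast, time_d, depth_bin, morphotype, count,
    volume_L, conc_per_L) covering every sampled (cast, depth_bin)
    crossed with every morphotype: bins with sampled volume but no
    particles get concentration 0; bins never sampled are absent.

    Raises
    ------
    ValueError
        If any object falls in a bin without sampled volume for its
        cast (ids listed).
    """
    h = obs.bin_height_m
    df = obs.objects.copy()
    df["depth_bin"] = np.floor(df["depth_m"] / h) * h
    sampled = set(map(tuple, obs.volumes[["cast", "depth_bin"]].to_numpy()))
    key = list(map(tuple, df[["cast", "depth_bin"]].to_numpy()))
    bad = [k not in sampled for k in key]
    if any(bad):
        ids = df.index[bad].tolist()[:10]
        raise ValueError(f"objects outside sampled depth bins: ids {ids}")

    counts = (
        df.groupby(["cast", "time_d", "depth_bin", "morphotype"], observed=True)
        .size()
        .rename("count")
        .reset_index()
    )
    cast_time = df[["cast", "time_d"]].drop_duplicates()
    morphos = sorted(df["morphotype"].unique().tolist())
    grid = (
        obs.volumes.merge(cast_time, on="cast")
        .merge(pd.DataFrame({"morphotype": morphos}), how="cross")
    )
    out = grid.merge(
        counts, on=["cast", "time_d", "depth_bin", "morphotype"], how="left"
    )
    out["count"] = out["count"].fillna(0.0)
    out["conc_per_L"] = out["count"] / out["volume_L"]
    return out.sort_values(
        ["cast", "time_d", "depth_bin", "morphotype"]
    ).reset_index(drop=True)


def make_size_bins(
    d_min: float, d_max: float, per_octave: int = 5
) -> np.ndarray:
    """Log-spaced ESD bin edges with ``per_octave`` bins per doubling."""
    if not 0 < d_min < d_max:
        raise ValueError("need 0 < d_min < d_max")
    n = int(np.ceil(np.log2(d_max / d_min) * per_octave))
    return d_min * 2.0 ** (np.arange(n + 1) / per_octave)


def size_spectrum_slope(
    diameters, volume_L: float, bin_edges=None
) -> tuple[float, float]:
    """Slope of the normalized particle size spectrum.

    Particles are counted in (log-spaced by default) ESD bins; the
    normalized abundance n = count / (volume x bin width) is regressed
    as ln n = ln a + b ln d over the non-empty bins, with d the
    geometric centre of each bin. Returns ``(slope, ln_intercept)``.

    Raises
    ------
    ValueError
        "spectrum undefined" with fewer than 3 non-empty bins.
    """
    d = np.asarray(diameters, dtype=float)
    if bin_edges is None:
        bin_edges = make_size_bins(d.min(), d.max() * (1 + 1e-12))
    edges = np.asarray(bin_edges, dtype=float)
    counts, _ = np.histogram(d, bins=edges)
    widths = np.diff(edges)
    centres = np.sqrt(edges[:-1] * edges[1:])
    nonempty = counts > 0
    if nonempty.sum() < 3:
        raise ValueError(
            f"spectrum undefined: only {int(nonempty.sum())} non-empty size bins"
        )
    n_norm = counts[nonempty] / (volume_L * widths[nonempty])
    slope, intercept = np.polyfit(np.log(centres[nonempty]), np.log(n_norm), 1)
    return float(slope), float(intercept)


def attenuation_exponent(
    profile: pd.DataFrame,
    z_ref: float = 100.0,
    z_max: float = 500.0,
    bin_height_m: float = DEPTH_BIN_M,
) -> tuple[float, float]:
    """Martin-type attenuation n_z = n_100 (z/z_ref)^b for one profile.

    ``profile`` holds ``depth_bin`` (lower edges) and ``conc_per_L`` for
    one morphotype at one time. Bins with positive concentration whose
    centre lies in (0, z_max] enter an OLS fit of ln n on ln(z/z_ref);
    b is the slope (negative means concentration decreases with depth)
    and n_100 = exp(intercept). Returns ``(n_100, b)``.

    Raises
    ------
    ValueError
        "attenuation undefined" with fewer than 3 usable bins.
    """
    z = profile["depth_bin"].to_numpy(dtype=float) + bin_height_m / 2.0
    n = profile["conc_per_L"].to_numpy(dtype=float)
    use = (n > 0) & (z > 0) & (z <= z_max)
    if use.sum() < 3:
        raise ValueError(
            f"attenuation undefined: only {int(use.sum())} positive bins in "
            f"(0, {z_max}] m"
        )
    b, ln_n100 = np.polyfit(np.log(z[use] / z_ref), np.log(n[use]), 1)
    return float(np.exp(ln_n100)), float(b)


def shannon_diversity(concentrations) -> float:
    """Shannon-Wiener index H = -sum p_i ln p_i over morphotype concentrations.

    Morphotypes are treated as species; zero concentrations contribute
    nothing. Natural logarithm, so the maximum is ln k for k types.

    Raises
    ------
    ValueError
        If all concentrations are zero or any is negative.
    """
    n = np.asarray(concentrations, dtype=float)
    if (n < 0).any():
        raise ValueError("negative concentrations")
    total = n.sum()
    if total == 0:
        raise ValueError("diversity undefined: all concentrations zero")
    p = n[n > 0] / total
    return float(-(p * np.log(p)).sum())


def diversity_sensitivity(
    coordinates,
    strata,
    ks=(25, 50, 100),
    seed: int = 0,
    baseline_k: int = 5,
    n_restarts: int = 10,
) -> tuple[pd.DataFrame, dict[int, float]]:
    """Diversity of strata recomputed at alternative cluster numbers.

    Refits k-means on the morphospace coordinates at each k in ``ks``
    (plus the k = 5 baseline), recomputes the Shannon index per stratum
    from cluster occupancies, and reports the Spearman rank correlation
    of each stratum ordering with the baseline ordering. Used to check
    that conclusions about which phase is more diverse do not depend on
    the choice of k.

    Returns ``(H_table, rank_correlations)`` with H_table indexed by
    stratum, one column per k.
    """
    strata = np.asarray(strata)
    X = np.asarray(coordinates, dtype=float)
    all_ks = [baseline_k] + [k for k in ks if k != baseline_k]
    H = {}
    for k in all_ks:
        model = fit_kmeans(X, k=k, seed=seed, n_restarts=n_restarts)
        labels = assign(model, X)
        h_per = {}
        for s in np.unique(strata):
            counts = np.bincount(labels[strata == s], minlength=k)
            h_per[s] = shannon_diversity(counts)
        H[k] = h_per
    table = pd.DataFrame(H)
    base = table[baseline_k]
    rho = {
        k: float(spearmanr(base, table[k]).statistic)
        for k in all_ks
        if k != baseline_k
    }
    return table, rho


def peak_depth_series(
    profiles: pd.DataFrame,
    morphotype: str,
    smooth: bool = False,
    bin_height_m: float = DEPTH_BIN_M,
) -> pd.DataFrame:
    """Depth of the concentration maximum through time for one morphotype.

    ``profiles`` is the long table from :func:`bin_concentrations`. For
    each time point the bin-centre depth of the maximum concentration is
    reported (ties broken toward the shallowest bin); all-zero profiles
    are omitted. With ``smooth=True`` a centred 3-bin moving average is
    applied before locating the maximum.
    """
    sub = profiles[profiles["morphotype"] == morphotype]
    rows = []
    for t, grp in sub.groupby("time_d"):
        prof = (
            grp.groupby("depth_bin")["conc_per_L"].mean().sort_index()
        )
        vals = prof.to_numpy()
        if smooth and len(vals) >= 3:
            vals = np.convolve(vals, np.ones(3) / 3.0, mode="same")
        if np.all(vals == 0):
            continue
        i = int(np.argmax(vals))  # lowest index = shallowest on ties
        rows.append((t, float(prof.index[i] + bin_height_m / 2.0)))
    return pd.DataFrame(rows, columns=["time_d", "peak_depth_m"])


@dataclass
class SinkingRate:
    """Bulk sinking speed from peak deepening, or a non-sinking flag."""

    speed_m_per_d: float | None
    slope_d_per_m: float
    non_sinking: bool = False


def sinking_rate_regression(times, depths) -> SinkingRate:
    """Type-I regression of peak time on peak depth; speed = 1/slope.

    Time is the dependent variable and depth the independent one, so
    the fitted slope is in d m^-1 and its inverse is the bulk sinking
    speed in m d^-1. A non-positive slope (peak not deepening) returns
    the ``non_sinking`` flag instead of a speed.

    Raises
    ------
    ValueError
        With fewer than 3 points or zero depth spread.
    """
    t = np.asarray(times, dtype=float)
    z = np.asarray(depths, dtype=float)
    if t.size < 3:
        raise ValueError(f"need >= 3 points, got {t.size}")
    if np.ptp(z) == 0:
        raise ValueError("zero depth spread")
    slope, _ = np.polyfit(z, t, 1)
    if slope <= 0:
        return SinkingRate(None, float(slope), non_sinking=True)
    return SinkingRate(float(1.0 / slope), float(slope))


def max_sinking_speed(depth_travelled_m: float, elapsed_d: float) -> float:
    """Upper-bound sinking speed: depth travelled over elapsed time (m d^-1).

    E.g. particles produced at the surface and observed at 900 m ten
    days later imply a maximum speed of 90 m d^-1.
    """
    if elapsed_d <= 0:
        raise ValueError(f"elapsed time must be > 0, got {elapsed_d}")
    if depth_travelled_m < 0:
        raise ValueError(f"depth must be >= 0, got {depth_travelled_m}")
    return depth_travelled_m / elapsed_d
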