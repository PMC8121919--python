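"""PCA morphospace: outlier trimming, transformation, fitting, projection.

The morphospace summarises the 24 morphological descriptors into a few
principal components. The pipeline mirrors the field procedure: trim the
most extreme values of each measurement (0.1% by default) to eliminate
outliers, log-transform the right-skewed variables, standardize, and
run a PCA on the correlation structure. Objects are then defined by
their coordinates (4 by default) in this space, and objects from a new
campaign can be projected through a morphospace fitted on another.

Determinism: component signs are fixed so that each component's
largest-magnitude loading is positive, making fits reproducible across
runs and platforms.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "DEFAULT_LOG_SET",
    "PreprocessSpec",
    "Morphospace",
    "trim_extremes",
    "transform",
    "fit_pca",
    "fit_morphospace",
    "project",
]

#: right-skewed size/structure descriptors mapped through log10(1 + x)
DEFAULT_LOG_SET: tuple[str, ...] = (
    "area",
    "perimeter",
    "esd",
    "convex_area",
    "integrated_grey",
    "perimeter_area_ratio",
)


@dataclass
class PreprocessSpec:
    """Fitted preprocessing: trim bounds, log set, standardization constants."""

    trim_fraction: float = 0.001
    log_set: tuple[str, ...] = DEFAULT_LOG_SET
    bounds: dict[str, tuple[float, float]] = field(default_factory=dict)
    means: dict[str, float] = field(default_factory=dict)
    stds: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if not 0.0 <= self.trim_fraction <= 0.05:
            raise ValueError(
                f"trim_fraction must be in [0, 0.05], got {self.trim_fraction}"
            )


@dataclass
class Morphospace:
    """Fitted preprocessing plus PCA loadings and explained variances.

    ``loadings`` has shape (n_variables, n_components) with orthonormal
    columns; ``explained_variance_ratio`` is non-increasing and sums to
    at most 1.
    """

    preprocess: PreprocessSpec
    variables: tuple[str, ...]
    loadings: np.ndarray
    explained_variance: np.ndarray
    explained_variance_ratio: np.ndarray
    training_set_id: str = ""

    def save(self, path) -> None:
        """Serialize to a portable JSON file."""
        payload = {
            "preprocess": {
                "trim_fraction": self.preprocess.trim_fraction,
                "log_set": list(self.preprocess.log_set),
                "bounds": {k: list(v) for k, v in self.preprocess.bounds.items()},
                "means": self.preprocess.means,
                "stds": self.preprocess.stds,
            },
            "variables": list(self.variables),
            "loadings": self.loadings.tolist(),
            "explained_variance": self.explained_variance.tolist(),
            "explained_variance_ratio": self.explained_variance_ratio.tolist(),
            "training_set_id": self.training_set_id,
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def load(cls, path) -> "Morphospace":
        d = json.loads(Path(path).read_text())
        pp = d["preprocess"]
        spec = PreprocessSpec(
            trim_fraction=pp["trim_fraction"],
            log_set=tuple(pp["log_set"]),
            bounds={k: tuple(v) for k, v in pp["bounds"].items()},
            means=pp["means"],
            stds=pp["stds"],
        )
        return cls(
            preprocess=spec,
            variables=tuple(d["variables"]),
            loadings=np.asarray(d["loadings"], dtype=float),
            explained_variance=np.asarray(d["explained_variance"], dtype=float),
            explained_variance_ratio=np.asarray(
                d["explained_variance_ratio"], dtype=float
            ),
            training_set_id=d["training_set_id"],
        )


def trim_extremes(
    table: pd.DataFrame,
    trim_fraction: float = 0.001,
    max_dropped: float = 0.20,
) -> tuple[pd.DataFrame, dict[str, tuple[float, float]]]:
    """Drop rows with extreme values in any variable.

    For each column, rows outside the empirical
    [f/2, 1 - f/2] quantile interval are marked; the union of marked
    rows over all columns is dropped. A constant column never marks a
    row. The per-variable bounds are returned for reuse when projecting
    new data.

    Raises
    ------
    ValueError
        If more than ``max_dropped`` of the rows would be dropped
        (a pathological table) or the trim fraction is invalid.
    """
    if not 0.0 <= trim_fraction <= 0.05:
        raise ValueError(f"trim_fraction must be in [0, 0.05], got {trim_fraction}")
    bounds: dict[str, tuple[float, float]] = {}
    keep = pd.Series(True, index=table.index)
    for col in table.columns:
        x = table[col].to_numpy(dtype=float)
        # order-statistic quantiles: bounds are attainable data values, so
        # a fraction too small to single out any row drops nothing
        lo = np.quantile(x, trim_fraction / 2.0, method="lower")
        hi = np.quantile(x, 1.0 - trim_fraction / 2.0, method="higher")
        bounds[col] = (float(lo), float(hi))
        keep &= (table[col] >= lo) & (table[col] <= hi)
    n_drop = int((~keep).sum())
    if len(table) and n_drop > max_dropped * len(table):
        raise ValueError(
            f"trimming would drop {n_drop}/{len(table)} rows "
            f"(> {max_dropped:.0%}); table looks pathological"
        )
    return table.loc[keep], bounds


def transform(
    table: pd.DataFrame, spec: PreprocessSpec, fit: bool = False
) -> pd.DataFrame:
    """Log-transform the skewed variables, then centre and scale.

    Log-set variables are mapped x -> log10(1 + x) (so x = 0 maps to 0);
    every variable is then standardized. With ``fit=True`` the means and
    standard deviations are learned from the table and stored on
    ``spec``; otherwise the stored constants are reused unchanged, which
    makes projection of new data consistent with the fit.

    Raises
    ------
    ValueError
        On a negative value in a log-set variable (named, with the
        offending object id), or a zero-variance variable at fit time.
    """
    out = table.astype(float).copy()
    for col in spec.log_set:
        if col not in out.columns:
            continue
        neg = out.index[out[col] < 0]
        if len(neg):
            raise ValueError(
                f"negative value in log-set variable {col!r} "
                f"(object_id {neg[0]!r})"
            )
        out[col] = np.log10(1.0 + out[col])
    if fit:
        spec.means = {c: float(out[c].mean()) for c in out.columns}
        # population std: standardized table has exact unit variance
        spec.stds = {c: float(out[c].std(ddof=0)) for c in out.columns}
        zero = [c for c, s in spec.stds.items() if s == 0.0]
        if zero:
            raise ValueError(f"zero-variance variables at fit time: {zero}")
    for col in out.columns:
        out[col] = (out[col] - spec.means[col]) / spec.stds[col]
    return out


def fit_pca(
    transformed: pd.DataFrame, n_components: int = 4, rank_tol: float = 1e-10
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Principal components of the correlation structure.

    The input is the standardized table, so its (population) covariance
    equals the correlation matrix of the original variables. Components
    are its eigenvectors ordered by decreasing eigenvalue; the sign of
    each is fixed so that its largest-magnitude loading is positive.

    Returns ``(loadings, eigenvalues, explained_variance_ratio)`` where
    loadings has shape (n_variables, n_components).

    Raises
    ------
    ValueError
        If the table has fewer rows than variables, ``n_components``
        exceeds the number of variables, or the requested number of
        components exceeds the numerical rank (listing the collinear
        variables involved).
    """
    X = transformed.to_numpy(dtype=float)
    n, p = X.shape
    if n <= p:
        raise ValueError(f"need more rows ({n}) than variables ({p})")
    if not 1 <= n_components <= p:
        raise ValueError(f"n_components must be in [1, {p}], got {n_components}")
    corr = (X.T @ X) / n
    eigval, eigvec = np.linalg.eigh(corr)
    order = np.argsort(eigval)[::-1]
    eigval = np.clip(eigval[order], 0.0, None)
    eigvec = eigvec[:, order]
    rank = int((eigval > rank_tol * eigval[0]).sum())
    if n_components > rank:
        null = eigvec[:, rank:]
        involved = sorted(
            transformed.columns[np.unique(np.nonzero(np.abs(null) > 0.1)[0])]
        )
        raise ValueError(
            f"table is rank-deficient (rank {rank} < n_components "
            f"{n_components}); collinear variables: {involved}"
        )
    loadings = eigvec[:, :n_components]
    # sign convention: largest-|loading| entry of each component positive
    for j in range(n_components):
        i = int(np.argmax(np.abs(loadings[:, j])))
        if loadings[i, j] < 0:
            loadings[:, j] = -loadings[:, j]
    ratio = eigval[:n_components] / eigval.sum()
    return loadings, eigval[:n_components], ratio


def fit_morphospace(
    table: pd.DataFrame,
    n_components: int = 4,
    trim_fraction: float = 0.001,
    log_set: tuple[str, ...] = DEFAULT_LOG_SET,
    training_set_id: str = "",
) -> Morphospace:
    """Trim, transform and fit the PCA morphospace in one call."""
    trimmed, bounds = trim_extremes(table, trim_fraction)
    spec = PreprocessSpec(trim_fraction=trim_fraction, log_set=log_set, bounds=bounds)
    transformed = transform(trimmed, spec, fit=True)
    loadings, eigval, ratio = fit_pca(transformed, n_components)
    return Morphospace(
        preprocess=spec,
        variables=tuple(table.columns),
        loadings=loadings,
        explained_variance=eigval,
        explained_variance_ratio=ratio,
        training_set_id=training_set_id,
    )


def project(
    morphospace: Morphospace, table: pd.DataFrame
) -> tuple[pd.DataFrame, pd.Series]:
    """Project objects into a fitted morphospace.

    Objects outside the stored trim bounds are still projected but
    flagged. Returns ``(coordinates, outside_bounds)``: coordinates is a
    (rows x n_components) frame with columns PC1..PCn, the flag a
    boolean series aligned with it.

    Raises
    ------
    ValueError
        If a fitted variable is missing from the table.
    """
    missing = [v for v in morphospace.variables if v not in table.columns]
    if missing:
        raise ValueError(f"missing variables: {missing}")
    table = table[list(morphospace.variables)]
    transformed = transform(table, morphospace.preprocess, fit=False)
    coords = transformed.to_numpy(dtype=float) @ morphospace.loadings
    n_comp = morphospace.loadings.shape[1]
    coords = pd.DataFrame(
        coords, index=table.index, columns=[f"PC{i + 1}" for i in range(n_comp)]
    )
    outside = pd.Series(False, index=table.index, name="outside_trim_bounds")
    for col, (lo, hi) in morphospace.preprocess.bounds.items():
        outside |= (table[col] < lo) | (table[col] > hi)
    return coords, outside
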