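"""Morphotype clustering, naming, and inter-rater agreement.

Objects positioned in the PCA morphospace are partitioned with k-means
(k = 5 in the standard configuration) into functional morphotypes. When
k = 5, clusters are named by deterministic rules codifying the medians
that characterise the five field morphotypes: dark (small, dark,
compact), elongated, flake (small, bright, smooth), fluffy (medium,
bright, heterogeneous) and agglomerated (large, multielement).

Agreement between two alternative classifications of the same objects
(e.g. morphospaces trained on different campaigns) is quantified with
percent agreement and Cohen's kappa after aligning arbitrary cluster
indices by optimal assignment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import cdist
from sklearn.cluster import KMeans

__all__ = [
    "MorphotypeModel",
    "AgreementReport",
    "MORPHOTYPE_NAMES",
    "fit_kmeans",
    "assign",
    "align_labels",
    "agreement_kappa",
    "name_morphotypes",
]

#: the five canonical morphotype names (ordering fixed by the naming rules)
MORPHOTYPE_NAMES: tuple[str, ...] = (
    "dark",
    "elongated",
    "flake",
    "fluffy",
    "agglomerated",
)


@dataclass
class MorphotypeModel:
    """k cluster centroids in PC space plus semantic names and provenance."""

    centroids: np.ndarray
    names: tuple[str, ...]
    seed: int
    n_restarts: int
    training_set_id: str = ""
    inertia: float = float("nan")

    @property
    def k(self) -> int:
        return self.centroids.shape[0]

    def to_dict(self) -> dict:
        return {
            "centroids": self.centroids.tolist(),
            "names": list(self.names),
            "seed": self.seed,
            "n_restarts": self.n_restarts,
            "training_set_id": self.training_set_id,
            "inertia": self.inertia,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MorphotypeModel":
        return cls(
            centroids=np.asarray(d["centroids"], dtype=float),
            names=tuple(d["names"]),
            seed=d["seed"],
            n_restarts=d["n_restarts"],
            training_set_id=d.get("training_set_id", ""),
            inertia=d.get("inertia", float("nan")),
        )


@dataclass
class AgreementReport:
    """Aligned confusion matrix with percent agreement and Cohen's kappa."""

    confusion: pd.DataFrame
    percent_agreement: float
    kappa: float
    mapping: dict
    degenerate: bool = False  # both labelings constant and equal (p_e = 1)


def fit_kmeans(
    coordinates, k: int, seed: int, n_restarts: int = 10
) -> MorphotypeModel:
    """Best-of-restarts k-means on morphospace coordinates.

    Minimises within-cluster sum of squares over ``n_restarts``
    k-means++ initialisations; deterministic given ``seed``.

    Raises
    ------
    ValueError
        If there are fewer distinct points than clusters.
    """
    X = np.asarray(coordinates, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    n_distinct = np.unique(X, axis=0).shape[0]
    if n_distinct < k:
        raise ValueError(f"only {n_distinct} distinct points for k={k}")
    km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed)
    km.fit(X)
    return MorphotypeModel(
        centroids=km.cluster_centers_.astype(float),
        names=tuple(f"type_{i + 1}" for i in range(k)),
        seed=seed,
        n_restarts=n_restarts,
        inertia=float(km.inertia_),
    )


def assign(model: MorphotypeModel, coordinates) -> np.ndarray:
    """Label each row by its nearest centroid (Euclidean).

    Exact ties are broken toward the lowest centroid index.
    """
    X = np.asarray(coordinates, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if X.shape[1] != model.centroids.shape[1]:
        raise ValueError(
            f"coordinate dimension {X.shape[1]} does not match model "
            f"dimension {model.centroids.shape[1]}"
        )
    d = cdist(X, model.centroids)
    return np.argmin(d, axis=1)  # argmin takes the lowest index on ties


def align_labels(labels_a, labels_b) -> dict:
    """Map b-labels onto a-labels maximizing the confusion diagonal.

    Cluster indices are arbitrary; before comparing two labelings the
    correspondence is established by optimal assignment
    (Hungarian algorithm) on the confusion matrix. Returns a bijective
    ``{b_label: a_label}`` mapping over the union of observed labels.
    """
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    if a.shape != b.shape:
        raise ValueError(f"label vectors differ in length: {a.shape} vs {b.shape}")
    cats = sorted(set(a.tolist()) | set(b.tolist()))
    conf = pd.crosstab(
        pd.Categorical(a, categories=cats), pd.Categorical(b, categories=cats),
        dropna=False,
    ).reindex(index=cats, columns=cats, fill_value=0)
    rows, cols = linear_sum_assignment(conf.to_numpy(), maximize=True)
    return {cats[c]: cats[r] for r, c in zip(rows, cols)}


def agreement_kappa(labels_a, labels_b, align: bool = True) -> AgreementReport:
    """Percent agreement and Cohen's kappa between two labelings.

    Labels are aligned first (``align_labels``) unless ``align=False``.
    Agreement is 100 x diagonal / n; kappa = (p_o - p_e) / (1 - p_e)
    with chance agreement p_e from the marginal products (unweighted,
    categorical). If both labelings are constant and identical, p_e = 1
    and kappa is reported as 1 with the ``degenerate`` flag set.
    """
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    if a.size == 0:
        raise ValueError("empty label vectors")
    if a.shape != b.shape:
        raise ValueError(f"label vectors differ in length: {a.shape} vs {b.shape}")
    mapping = align_labels(a, b) if align else {v: v for v in set(b.tolist())}
    b_aligned = np.asarray([mapping[v] for v in b.tolist()])
    cats = sorted(set(a.tolist()) | set(b_aligned.tolist()))
    conf = pd.crosstab(
        pd.Categorical(a, categories=cats),
        pd.Categorical(b_aligned, categories=cats),
        dropna=False,
    ).reindex(index=cats, columns=cats, fill_value=0)
    n = a.size
    M = conf.to_numpy(dtype=float)
    p_o = np.trace(M) / n
    p_e = float((M.sum(axis=1) / n) @ (M.sum(axis=0) / n))
    if p_e >= 1.0:
        return AgreementReport(conf, 100.0 * p_o, 1.0, mapping, degenerate=True)
    kappa = (p_o - p_e) / (1.0 - p_e)
    return AgreementReport(conf, 100.0 * p_o, float(kappa), mapping)


def name_morphotypes(
    model: MorphotypeModel, feature_table: pd.DataFrame, labels
) -> MorphotypeModel:
    """Assign semantic names to the k = 5 clusters.

    Ordered rules on cluster medians, each consuming its cluster:

    1. largest median perimeter  -> agglomerated
    2. highest median darkness   -> dark
    3. highest median elongation -> elongated
    4. of the remaining two, higher median grey st.dev. -> fluffy,
       the other -> flake

    With k != 5 the generic ``type_1..k`` names are kept and a warning
    is issued.
    """
    labels = np.asarray(labels)
    if len(labels) != len(feature_table):
        raise ValueError("labels and feature table length mismatch")
    if model.k != 5:
        warnings.warn(
            f"naming rules are defined for k=5, got k={model.k}; "
            "keeping generic type names"
        )
        return model
    med = feature_table.groupby(labels).median()
    remaining = list(med.index)
    names: dict[int, str] = {}
    for stat, name in (
        ("perimeter", "agglomerated"),
        ("darkness", "dark"),
        ("elongation", "elongated"),
    ):
        winner = med.loc[remaining, stat].idxmax()
        names[winner] = name
        remaining.remove(winner)
    fluffy = med.loc[remaining, "grey_std"].idxmax()
    names[fluffy] = "fluffy"
    remaining.remove(fluffy)
    names[remaining[0]] = "flake"
    return MorphotypeModel(
        centroids=model.centroids,
        names=tuple(names[i] for i in range(5)),
        seed=model.seed,
        n_restarts=model.n_restarts,
        training_set_id=model.training_set_id,
        inertia=model.inertia,
    )
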