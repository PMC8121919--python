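"""End-to-end pipeline: vignettes to morphotyped profiles and metrics.

Stages, in the order the method runs: feature extraction (when raw
vignettes are supplied) -> outlier trimming -> log/standardize
transform -> PCA morphospace -> k-means clustering -> morphotype naming
-> depth binning -> export metrics. Every run writes a manifest (config,
seed, package version, content hash) and stamps it into the output
files so results are auditable and reruns byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .io import PipelineConfig, write_table
from .features import feature_table
from .morphospace import Morphospace, fit_morphospace, project
from .clustering import (
    MorphotypeModel,
    fit_kmeans,
    assign,
    name_morphotypes,
    agreement_kappa,
    AgreementReport,
)
from .ecology import (
    ObservationSet,
    bin_concentrations,
    attenuation_exponent,
    shannon_diversity,
)

logger = logging.getLogger("snowmorph")

__all__ = ["PipelineResult", "run_pipeline", "crossval", "save_model",
           "load_model"]


@dataclass
class PipelineResult:
    """Artifact bundle of one pipeline run."""

    features: pd.DataFrame
    morphospace: Morphospace
    model: MorphotypeModel
    labels: pd.Series  # morphotype name per object_id
    profiles: pd.DataFrame | None
    metrics: pd.DataFrame | None
    manifest: dict


def save_model(morphospace: Morphospace, model: MorphotypeModel, path) -> None:
    """Serialize morphospace + cluster model into one portable JSON file."""
    morphospace.save(path)
    d = json.loads(Path(path).read_text())
    d["kmeans"] = model.to_dict()
    Path(path).write_text(json.dumps(d, indent=1))


def load_model(path) -> tuple[Morphospace, MorphotypeModel]:
    d = json.loads(Path(path).read_text())
    return Morphospace.load(path), MorphotypeModel.from_dict(d["kmeans"])


def _manifest(config: PipelineConfig, n_objects: int) -> dict:
    payload = {"config": config.to_dict(), "version": __version__,
               "n_objects": n_objects}
    digest = hashlib.sha256(
        json.dumps(payload, sort_keys=True).encode()
    ).hexdigest()[:16]
    payload["hash"] = digest
    return payload


def run_pipeline(
    config: PipelineConfig,
    vignettes=None,
    features: pd.DataFrame | None = None,
    observations: ObservationSet | None = None,
    outdir=None,
    training_set_id: str = "run",
) -> PipelineResult:
    """Execute the full classification pipeline.

    Inputs are raw ``vignettes`` or a precomputed ``features`` table
    (one of the two is required). When ``observations`` (depths, casts,
    times, volumes) are supplied, objects are morphotyped and the
    profile and metric tables are produced as well. With ``outdir`` the
    morphospace/model file, labelled table, profile table, metrics
    table and manifest are written.
    """
    if features is None:
        if vignettes is None:
            raise ValueError("need vignettes or a feature table")
        logger.info("stage features: extracting descriptors")
        res = feature_table(vignettes, threshold=config.binarize_threshold)
        features = res.table
        if res.failed_ids:
            logger.warning("stage features: %d empty objects skipped",
                           len(res.failed_ids))
    logger.info("stage morphospace: %d objects", len(features))
    space = fit_morphospace(
        features,
        n_components=config.n_components,
        trim_fraction=config.trim_fraction,
        log_set=config.log_set,
        training_set_id=training_set_id,
    )
    coords, outside = project(space, features)
    logger.info("stage clustering: k=%d on %d coordinates", config.k,
                len(coords))
    model = fit_kmeans(coords.to_numpy(), k=config.k, seed=config.seed,
                       n_restarts=config.n_restarts)
    model.training_set_id = training_set_id
    idx = assign(model, coords.to_numpy())
    model = name_morphotypes(model, features, idx)
    labels = pd.Series(
        [model.names[i] for i in idx], index=features.index, name="morphotype"
    )

    profiles = None
    metrics = None
    if observations is not None:
        obj = observations.objects.copy()
        common = obj.index.intersection(labels.index)
        obj.loc[common, "morphotype"] = labels.loc[common]
        obs = ObservationSet(objects=obj, volumes=observations.volumes,
                             bin_height_m=observations.bin_height_m)
        logger.info("stage profiles: binning %d objects", len(obj))
        profiles = bin_concentrations(obs)
        metrics = _metric_table(profiles, bin_height_m=obs.bin_height_m)

    manifest = _manifest(config, len(features))
    result = PipelineResult(features, space, model, labels, profiles,
                            metrics, manifest)
    if outdir is not None:
        _write_bundle(result, Path(outdir))
    return result


def _metric_table(profiles: pd.DataFrame, bin_height_m: float) -> pd.DataFrame:
    """Per (morphotype, time) attenuation; per time diversity and peaks."""
    rows = []
    for (name, t), grp in profiles.groupby(["morphotype", "time_d"]):
        prof = grp.groupby("depth_bin", as_index=False)["conc_per_L"].mean()
        try:
            n100, b = attenuation_exponent(prof, bin_height_m=bin_height_m)
        except ValueError:
            n100, b = np.nan, np.nan
        rows.append({"morphotype": name, "time_d": t, "n_100": n100, "b": b})
    out = pd.DataFrame(rows)
    div = (
        profiles.groupby(["time_d", "morphotype"])["conc_per_L"]
        .sum()
        .groupby("time_d")
        .apply(lambda s: shannon_diversity(s.to_numpy()) if s.sum() > 0 else np.nan)
        .rename("shannon_H")
        .reset_index()
    )
    return out.merge(div, on="time_d", how="left")


def _write_bundle(result: PipelineResult, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    save_model(result.morphospace, result.model, outdir / "morphospace.json")
    stamp = result.manifest["hash"]
    labelled = result.labels.to_frame()
    labelled["manifest_hash"] = stamp
    write_table(labelled, outdir / "labels.tsv")
    if result.profiles is not None:
        p = result.profiles.copy()
        p["manifest_hash"] = stamp
        write_table(p, outdir / "profiles.tsv", index=False)
    if result.metrics is not None:
        m = result.metrics.copy()
        m["manifest_hash"] = stamp
        write_table(m, outdir / "metrics.tsv", index=False)
    (outdir / "manifest.json").write_text(
        json.dumps(result.manifest, indent=1, sort_keys=True)
    )
    logger.info("wrote artifact bundle to %s (hash %s)", outdir, stamp)


def crossval(
    config: PipelineConfig,
    features_a: pd.DataFrame,
    features_b: pd.DataFrame,
) -> AgreementReport:
    """Train-on-A / train-on-B cross-classification agreement.

    Fits a morphospace + cluster model on each campaign, classifies the
    pooled objects under both models, and reports percent agreement and
    Cohen's kappa after aligning cluster labels — the reproducibility
    check used across the two field campaigns.
    """
    pooled = pd.concat([features_a, features_b])
    labels = {}
    for name, feats in (("a", features_a), ("b", features_b)):
        space = fit_morphospace(
            feats, n_components=config.n_components,
            trim_fraction=config.trim_fraction, log_set=config.log_set,
            training_set_id=name,
        )
        coords, _ = project(space, pooled)
        model = fit_kmeans(
            project(space, feats)[0].to_numpy(), k=config.k,
            seed=config.seed, n_restarts=config.n_restarts,
        )
        labels[name] = assign(model, coords.to_numpy())
    return agreement_kappa(labels["a"], labels["b"])
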