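"""High-level orchestration: encode → fit → classify → validate → embed.

These functions are the programmatic equivalent of a pipeline driver: each
takes plain inputs (paths or in-memory objects) plus a ``RunConfig``,
continues past per-site failures while collecting a failure manifest, and —
when given an output directory — writes its artifacts together with the
resolved configuration and package version, so any run can be reproduced
from its own metadata.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .core import CDPAVector, cdpa_matrix, vecd, write_cdpa_table
from .exceptions import CDPAError, OverfitRiskError
from .group_models import (
    ConfusionMatrix,
    GroupModel,
    evaluate,
    fit_group_models,
    mahalanobis_profile,
    nearest_mean_classify,
    save_models,
)
from .logit import LogisticModel, fit_logistic, predict_probabilities
from .robustness import MDSEmbedding, NoiseConfig, NoiseExperiment, classical_mds, run_noise_validation
from .structure_io import BindingSite, LigandSelector, extract_binding_site, parse_structure

__all__ = [
    "RunConfig",
    "encode_structures",
    "encode_dataset",
    "fit",
    "classify",
    "validate",
    "mds_embed",
]

# a logistic fit with params >= n/1.25 is memorisation, not modelling
_OVERFIT_RATIO = 1.25


@dataclass(frozen=True)
class RunConfig:
    """Resolved parameters of a pipeline run (written beside every output)."""

    cutoff: float = 5.3
    divisor: str = "n-1"
    ridge: "str | float | None" = "auto"
    l2: float = 1e-6
    tau_grid: tuple[float, ...] = tuple(np.round(np.arange(0.1, 1.01, 0.1), 2))
    replications: int = 100
    seed: int = 0
    classifier: str = "nearest-mean"
    merge_map: Optional[dict] = None
    force_logistic: bool = False

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["package_version"] = __version__
        return d


def _write_metadata(out_dir: Optional[Path], config: RunConfig, command: str) -> None:
    if out_dir is None:
        return
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    meta = {"command": command, **config.to_dict()}
    (out_dir / f"{command}_config.json").write_text(json.dumps(meta, indent=1, default=str))


def encode_structures(
    inputs: Sequence[tuple[str, str, LigandSelector]],
    config: RunConfig = RunConfig(),
    out_dir: Optional[Path] = None,
) -> tuple[list[BindingSite], list[CDPAVector], list[dict]]:
    """Extract and encode sites from (structure_id, pdb_text, selector) triples.

    Per-site failures are recorded in the returned manifest and the batch
    continues; an empty input list is a usage error.
    """
    if not inputs:
        raise ValueError("no structures supplied")
    sites: list[BindingSite] = []
    vectors: list[CDPAVector] = []
    failures: list[dict] = []
    for structure_id, pdb_text, selector in inputs:
        try:
            atoms = parse_structure(pdb_text, name=structure_id)
            site = extract_binding_site(
                atoms, selector, cutoff=config.cutoff, structure_id=structure_id
            )
            vectors.append(vecd(cdpa_matrix(site, divisor=config.divisor)))
            sites.append(site)
        except (CDPAError, ValueError) as err:
            failures.append({"structure_id": structure_id, "error": str(err)})
    _write_metadata(out_dir, config, "encode")
    if out_dir is not None and sites:
        mats = [cdpa_matrix(s, divisor=config.divisor) for s in sites]
        write_cdpa_table(Path(out_dir) / "cdpa_table.tsv", mats, [s.ligand_label for s in sites])
        (Path(out_dir) / "encode_failures.json").write_text(json.dumps(failures, indent=1))
    return sites, vectors, failures


def encode_dataset(
    sites: Sequence[BindingSite], config: RunConfig = RunConfig()
) -> list[CDPAVector]:
    """Encode already-extracted sites under the run's divisor convention."""
    return [vecd(cdpa_matrix(s, divisor=config.divisor)) for s in sites]


def fit(
    vectors: Sequence[CDPAVector],
    labels: Sequence[str],
    config: RunConfig = RunConfig(),
    out_dir: Optional[Path] = None,
) -> tuple[dict[str, GroupModel], Optional[LogisticModel]]:
    """Fit group models and, when requested, the logistic classifier.

    The logistic fit is refused when its parameter count reaches n/1.25 —
    at that ratio a zero training error certifies overfitting, not signal —
    unless ``force_logistic`` is set.
    """
    models = fit_group_models(vectors, labels, ridge=config.ridge)
    logistic = None
    if config.classifier == "logistic":
        n_obs = len(vectors)
        j, p = len(models), len(models)
        n_params = (j - 1) * (p + 1)
        if n_params >= n_obs / _OVERFIT_RATIO and not config.force_logistic:
            raise OverfitRiskError(
                f"logistic model has {n_params} parameters for {n_obs} observations "
                f"(>= n/{_OVERFIT_RATIO}); training error would reflect overfitting. "
                "Set force_logistic=True to proceed anyway."
            )
        profiles = [mahalanobis_profile(v, models) for v in vectors]
        logistic = fit_logistic(profiles, list(labels), l2=config.l2)
    _write_metadata(out_dir, config, "fit")
    if out_dir is not None:
        save_models(models, Path(out_dir) / "group_models.json")
    return models, logistic


def classify(
    vectors: Sequence[CDPAVector],
    models: Mapping[str, GroupModel],
    config: RunConfig = RunConfig(),
    logistic_model: Optional[LogisticModel] = None,
    labels_true: Optional[Sequence[str]] = None,
    out_dir: Optional[Path] = None,
) -> tuple[pd.DataFrame, Optional[ConfusionMatrix]]:
    """Classify vectors; emit profiles, predictions, probabilities and a
    confusion matrix when truth is supplied."""
    if config.classifier == "logistic" and logistic_model is None:
        raise ValueError("classifier 'logistic' requires a fitted logistic model")
    rows = []
    preds = []
    for v in vectors:
        profile = mahalanobis_profile(v, models)
        row = {"site_id": v.site_id, **{f"D_{k}": d for k, d in profile.distances.items()}}
        if config.classifier == "logistic":
            pp = predict_probabilities(logistic_model, profile)
            row.update({f"P_{k}": p for k, p in pp.probabilities.items()})
            pred = pp.assigned_label
        else:
            pred = nearest_mean_classify(profile).label
        row["predicted"] = pred
        preds.append(pred)
        rows.append(row)
    df = pd.DataFrame(rows)
    confusion = None
    if labels_true is not None:
        confusion = evaluate(list(labels_true), preds, merge_map=config.merge_map)
        df["true"] = list(labels_true)
    _write_metadata(out_dir, config, "classify")
    if out_dir is not None:
        df.to_csv(Path(out_dir) / "classify.tsv", sep="\t", index=False)
        if confusion is not None:
            confusion.to_frame().to_csv(Path(out_dir) / "confusion.tsv", sep="\t")
    return df, confusion


def validate(
    sites: Sequence[BindingSite],
    models: Mapping[str, GroupModel],
    config: RunConfig = RunConfig(),
    logistic_model: Optional[LogisticModel] = None,
    out_dir: Optional[Path] = None,
) -> NoiseExperiment:
    """Run the Gaussian-noise validation with the run's τ grid and seed."""
    noise_config = NoiseConfig(
        tau_grid=tuple(config.tau_grid),
        replications=config.replications,
        seed=config.seed,
        classifier=config.classifier,
    )
    experiment = run_noise_validation(
        sites,
        models,
        noise_config,
        logistic_model=logistic_model,
        divisor=config.divisor,
        merge_map=config.merge_map,
    )
    _write_metadata(out_dir, config, "validate")
    if out_dir is not None:
        experiment.to_long_frame().to_csv(
            Path(out_dir) / "noise_errors.tsv", sep="\t", index=False
        )
    return experiment


def mds_embed(
    vectors: Sequence[CDPAVector],
    k: int = 2,
    config: RunConfig = RunConfig(),
    out_dir: Optional[Path] = None,
) -> MDSEmbedding:
    """Classical MDS of the descriptor vectors for visual diagnostics."""
    embedding = classical_mds(vectors, k=k)
    _write_metadata(out_dir, config, "mds")
    if out_dir is not None:
        df = pd.DataFrame(
            embedding.coordinates, columns=[f"mds{i + 1}" for i in range(k)]
        )
        df.insert(0, "site_id", list(embedding.site_ids))
        df.to_csv(Path(out_dir) / "mds.tsv", sep="\t", index=False)
    return embedding
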