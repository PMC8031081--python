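"""Per-ligand group models in descriptor space and nearest-mean classification.

Each ligand group is modelled by the sample mean and 6x6 sample covariance
of its members' descriptor 6-vectors.  A site is compared to a group by the
squared Mahalanobis form D = (v − μ)' Σ⁻¹ (v − μ) (no square root — the
quadratic itself is the distance used throughout, both for nearest-mean
assignment and as the predictors of the logistic classifier).

Small groups cannot support a full-rank 6x6 covariance (fewer than 7
members), so a ridge Σ + εI is applied with a warning; the ridge actually
used is recorded on the model.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve

from .core import CDPAVector
from .exceptions import SingularModelError, SmallGroupWarning

__all__ = [
    "CANONICAL_GROUPS",
    "GroupModel",
    "DistanceProfile",
    "Assignment",
    "ConfusionMatrix",
    "fit_group_model",
    "fit_group_models",
    "mahalanobis_profile",
    "nearest_mean_classify",
    "evaluate",
    "save_models",
    "load_models",
]

# fixed group ordering used for deterministic tie-breaks and table layout
CANONICAL_GROUPS = (
    "AMP",
    "ATP",
    "FAD",
    "FMN",
    "GLC",
    "HEM",
    "NAD",
    "PO4",
    "Steroid",
)

_COND_LIMIT = 1e12
_MIN_FULL_RANK = 7  # members needed for an invertible 6x6 sample covariance


def canonical_sort(labels: Iterable[str]) -> list[str]:
    """Sort labels by the canonical group ordering, unknown labels last (alphabetical)."""
    order = {lab: i for i, lab in enumerate(CANONICAL_GROUPS)}
    return sorted(set(labels), key=lambda l: (order.get(l, len(order)), l))


@dataclass
class GroupModel:
    """Mean and covariance of one ligand group's descriptor vectors."""

    label: str
    mean: np.ndarray
    covariance: np.ndarray
    n_members: int
    singular: bool = False
    ridge: float = 0.0

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=float)
        self.covariance = np.asarray(self.covariance, dtype=float)
        if not np.allclose(self.covariance, self.covariance.T, atol=1e-10):
            raise ValueError("covariance must be symmetric to 1e-10")
        self._cho = None

    def _factor(self):
        if self._cho is None:
            C = self.covariance + self.ridge * np.eye(len(self.mean))
            try:
                self._cho = cho_factor(0.5 * (C + C.T))
            except np.linalg.LinAlgError as err:  # pragma: no cover - defensive
                raise SingularModelError(
                    f"group {self.label!r}: covariance not positive definite"
                ) from err
        return self._cho

    def mahalanobis(self, v: np.ndarray) -> float:
        """Squared Mahalanobis form of a 6-vector under this group's model."""
        if self.singular and self.ridge == 0.0:
            raise SingularModelError(
                f"group {self.label!r}: singular covariance; refit with ridge"
            )
        dev = np.asarray(v, dtype=float) - self.mean
        return float(dev @ cho_solve(self._factor(), dev))


def _vectors_to_array(vectors: Sequence["CDPAVector | np.ndarray"]) -> np.ndarray:
    rows = [v.v if isinstance(v, CDPAVector) else np.asarray(v, dtype=float) for v in vectors]
    return np.vstack(rows)


def fit_group_model(
    vectors: Sequence["CDPAVector | np.ndarray"],
    label: str,
    ridge: "str | float | None" = "auto",
) -> GroupModel:
    """Fit a group's sample mean and covariance (divisor n−1).

    ``ridge="auto"`` applies ε = 1e-6 × mean(diag Σ) when the covariance is
    singular or ill-conditioned (condition number > 1e12) or the group has
    fewer than 7 members; a float fixes ε explicitly; ``None`` disables the
    ridge, in which case a singular model raises on first use.
    """
    X = _vectors_to_array(vectors)
    n = X.shape[0]
    if n < 2:
        raise ValueError(f"group {label!r}: need at least 2 members, got {n}")
    mean = X.mean(axis=0)
    dev = X - mean
    cov = dev.T @ dev / (n - 1)
    cov = 0.5 * (cov + cov.T)
    p = X.shape[1]
    evals = np.linalg.eigvalsh(cov)
    singular = (
        n <= p
        or evals.min() <= 0
        or (evals.max() / max(evals.min(), 1e-300)) > _COND_LIMIT
    )
    eps = 0.0
    if ridge == "auto":
        if singular or n < _MIN_FULL_RANK:
            eps = 1e-6 * float(np.mean(np.diag(cov)))
            if eps <= 0:
                eps = 1e-12
            warnings.warn(
                f"group {label!r}: n={n} members; covariance ridge ε={eps:.3g} applied",
                SmallGroupWarning,
                stacklevel=2,
            )
    elif ridge is None:
        if singular:
            # model is constructed but flagged; Mahalanobis use will raise
            pass
    else:
        eps = float(ridge)
    return GroupModel(
        label=label, mean=mean, covariance=cov, n_members=n, singular=singular, ridge=eps
    )


def fit_group_models(
    vectors: Sequence["CDPAVector | np.ndarray"],
    labels: Sequence[str],
    ridge: "str | float | None" = "auto",
) -> dict[str, GroupModel]:
    """Fit one model per label, in canonical label order."""
    if len(vectors) != len(labels):
        raise ValueError("vectors and labels must have equal length")
    labels = list(labels)
    models: dict[str, GroupModel] = {}
    for lab in canonical_sort(labels):
        members = [v for v, l in zip(vectors, labels) if l == lab]
        models[lab] = fit_group_model(members, lab, ridge=ridge)
    return models


@dataclass(frozen=True)
class DistanceProfile:
    """Squared Mahalanobis distances of one site to every fitted group mean."""

    site_id: str
    distances: dict[str, float]

    def as_array(self, order: Optional[Sequence[str]] = None) -> np.ndarray:
        keys = list(order) if order is not None else list(self.distances)
        return np.array([self.distances[k] for k in keys])


def mahalanobis_profile(
    v: "CDPAVector | np.ndarray", models: Mapping[str, GroupModel]
) -> DistanceProfile:
    """Distance profile of a descriptor vector against a fitted model set."""
    site_id = v.site_id if isinstance(v, CDPAVector) else ""
    vec = v.v if isinstance(v, CDPAVector) else np.asarray(v, dtype=float)
    distances = {lab: m.mahalanobis(vec) for lab, m in models.items()}
    return DistanceProfile(site_id=site_id, distances=distances)


@dataclass(frozen=True)
class Assignment:
    label: str
    tie: bool = False


def nearest_mean_classify(profile: DistanceProfile) -> Assignment:
    """Assign to the group with minimal distance; ties go to the first label
    in canonical ordering and are flagged."""
    if not profile.distances:
        raise ValueError("empty distance profile")
    dmin = min(profile.distances.values())
    winners = [lab for lab, d in profile.distances.items() if d == dmin]
    if len(winners) == 1:
        return Assignment(label=winners[0], tie=False)
    return Assignment(label=canonical_sort(winners)[0], tie=True)


@dataclass(frozen=True)
class ConfusionMatrix:
    """Row = true group, column = predicted group; error_rate = 1 − trace/total."""

    labels: tuple[str, ...]
    counts: np.ndarray
    error_rate: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=list(self.labels), columns=list(self.labels))


def evaluate(
    labels_true: Sequence[str],
    labels_pred: Sequence["str | Assignment"],
    merge_map: Optional[Mapping[str, str]] = None,
) -> ConfusionMatrix:
    """Tally a confusion matrix, optionally merging sublabels first.

    ``merge_map`` maps sublabels back to their parent group (e.g. both HEM
    subgroups to HEM) and is applied to truth and prediction alike, so a
    split used only for model building never changes the evaluation unit.
    """
    preds = [p.label if isinstance(p, Assignment) else p for p in labels_pred]
    if len(labels_true) != len(preds):
        raise ValueError("labels_true and labels_pred must have equal length")
    mm = dict(merge_map or {})
    t = [mm.get(l, l) for l in labels_true]
    p = [mm.get(l, l) for l in preds]
    labs = canonical_sort(set(t) | set(p))
    idx = {lab: i for i, lab in enumerate(labs)}
    counts = np.zeros((len(labs), len(labs)), dtype=int)
    for ti, pi in zip(t, p):
        counts[idx[ti], idx[pi]] += 1
    total = counts.sum()
    error = 1.0 - np.trace(counts) / total if total else 0.0
    return ConfusionMatrix(labels=tuple(labs), counts=counts, error_rate=float(error))


def save_models(models: Mapping[str, GroupModel], path) -> None:
    """Serialise a fitted model set as plain keyed text (JSON)."""
    payload = {
        lab: {
            "label": m.label,
            "mean": m.mean.tolist(),
            "covariance": m.covariance.tolist(),
            "n_members": m.n_members,
            "singular": bool(m.singular),
            "ridge": m.ridge,
        }
        for lab, m in models.items()
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


def load_models(path) -> dict[str, GroupModel]:
    with open(path) as fh:
        payload = json.load(fh)
    return {
        lab: GroupModel(
            label=d["label"],
            mean=np.array(d["mean"]),
            covariance=np.array(d["covariance"]),
            n_members=int(d["n_members"]),
            singular=bool(d["singular"]),
            ridge=float(d["ridge"]),
        )
        for lab, d in payload.items()
    }
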