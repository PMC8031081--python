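"""Polytomous (multinomial) logistic regression on group-distance profiles.

The predictors are the squared Mahalanobis distances of a site to every
fitted group mean, so class probabilities depend not just on the nearest
group but on the whole distance profile.  The model is parameterised with a
reference category (default AMP): that class's coefficient row is fixed at
zero and the remaining (J−1) rows of intercept + slopes are estimated by
(optionally L2-penalised) maximum likelihood with L-BFGS-B on the exact
negative log-likelihood and gradient.

Quasi-separation — e.g. a group whose distances perfectly identify it —
drives unpenalised coefficients to extreme magnitudes.  Rather than report
such unstable numbers silently, the fit flags non-convergence/separation and
suggests a small positive penalty.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import logsumexp, softmax

from .group_models import Assignment, DistanceProfile, canonical_sort

__all__ = [
    "LogisticModel",
    "ProbabilityProfile",
    "fit_logistic",
    "predict_probabilities",
    "certainty_summary",
    "coefficient_table",
]

_SEPARATION_COEF_LIMIT = 50.0


@dataclass
class LogisticModel:
    """Fitted multinomial-logit coefficients in reference-category form.

    ``coefficients`` is (J−1) × (P+1): one row per non-reference class (in
    ``class_labels`` order after the reference), columns = intercept then one
    slope per predictor in ``predictor_labels`` order.
    """

    reference_label: str
    class_labels: tuple[str, ...]  # reference first
    predictor_labels: tuple[str, ...]
    coefficients: np.ndarray
    fit_meta: dict = field(default_factory=dict)

    def scores(self, x: np.ndarray) -> np.ndarray:
        """Linear scores per class (reference fixed at 0)."""
        x1 = np.concatenate([[1.0], np.asarray(x, dtype=float)])
        return np.concatenate([[0.0], self.coefficients @ x1])


@dataclass(frozen=True)
class ProbabilityProfile:
    """Per-class membership probabilities for one site, plus the argmax label."""

    site_id: str
    probabilities: dict[str, float]
    assigned_label: str


def _design(
    profiles: Sequence[DistanceProfile], predictor_order: Sequence[str]
) -> np.ndarray:
    rows = []
    for p in profiles:
        missing = set(predictor_order) - set(p.distances)
        if missing:
            raise ValueError(
                f"profile {p.site_id!r} missing predictors: {sorted(missing)}"
            )
        rows.append([p.distances[k] for k in predictor_order])
    return np.asarray(rows, dtype=float)


def _nll_and_grad(
    B_flat: np.ndarray, X1: np.ndarray, Y: np.ndarray, l2: float, shape: tuple[int, int]
):
    """Penalised negative log-likelihood and gradient; reference row fixed at 0."""
    B = B_flat.reshape(shape)  # (J-1, P+1)
    scores = np.hstack([np.zeros((X1.shape[0], 1)), X1 @ B.T])  # (n, J)
    nll = -(np.sum(scores[Y.astype(bool)]) - np.sum(logsumexp(scores, axis=1)))
    P = softmax(scores, axis=1)
    resid = P - Y  # (n, J)
    grad = resid[:, 1:].T @ X1  # (J-1, P+1)
    # penalise slopes only, not intercepts
    pen = l2 * B.copy()
    pen[:, 0] = 0.0
    nll += 0.5 * l2 * float(np.sum(B[:, 1:] ** 2))
    return nll, (grad + pen).ravel()


def fit_logistic(
    profiles: Sequence[DistanceProfile],
    labels: Sequence[str],
    reference: str = "AMP",
    l2: float = 1e-6,
    max_iter: int = 1000,
    tol: float = 1e-10,
) -> LogisticModel:
    """Fit the multinomial-logit classifier on distance profiles.

    ``l2`` is the ridge weight on the slope coefficients (intercepts are
    unpenalised); the default 1e-6 is near-MLE but keeps quasi-separated fits
    finite.  At ``l2=0`` a separated fit is flagged (``fit_meta["converged"]
    is False``) with guidance to set ``l2 > 0``.
    """
    if len(profiles) != len(labels):
        raise ValueError("profiles and labels must have equal length")
    if l2 < 0:
        raise ValueError("l2 must be >= 0")
    class_labels = canonical_sort(labels)
    if len(class_labels) < 2:
        raise ValueError("need at least 2 classes")
    counts = {lab: labels.count(lab) if isinstance(labels, list) else int(np.sum(np.asarray(labels) == lab)) for lab in class_labels}
    empty = [lab for lab, c in counts.items() if c == 0]
    if empty:
        raise ValueError(f"classes with zero members: {empty}")
    if reference not in class_labels:
        reference = class_labels[0]
    class_labels = [reference] + [l for l in class_labels if l != reference]
    predictor_order = tuple(profiles[0].distances.keys())
    X = _design(profiles, predictor_order)
    # distances to tight groups can span many orders of magnitude; optimise on
    # standardised columns and map the coefficients back afterwards (the model
    # is reparameterisation-invariant; the tiny slope penalty applies on the
    # standardised scale)
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    Xs = (X - mu) / sd
    X1 = np.hstack([np.ones((Xs.shape[0], 1)), Xs])
    lab_idx = {lab: j for j, lab in enumerate(class_labels)}
    Y = np.zeros((X.shape[0], len(class_labels)))
    for i, lab in enumerate(labels):
        Y[i, lab_idx[lab]] = 1.0
    shape = (len(class_labels) - 1, X1.shape[1])
    trace: list[float] = []

    def cb(xk):
        trace.append(_nll_and_grad(xk, X1, Y, l2, shape)[0])

    res = minimize(
        _nll_and_grad,
        np.zeros(shape).ravel(),
        args=(X1, Y, l2, shape),
        method="L-BFGS-B",
        jac=True,
        callback=cb,
        options={"maxiter": max_iter, "ftol": tol, "gtol": 1e-9},
    )
    Bs = res.x.reshape(shape)
    B = np.empty_like(Bs)
    B[:, 1:] = Bs[:, 1:] / sd
    B[:, 0] = Bs[:, 0] - Bs[:, 1:] @ (mu / sd)
    # at l2=0 a (quasi-)separated fit has no finite MLE: the optimizer either
    # blows up the coefficients or stalls at an essentially zero deviance
    separated = l2 == 0.0 and (
        bool(np.abs(Bs).max() > _SEPARATION_COEF_LIMIT)
        or res.fun / X1.shape[0] < 1e-6
    )
    converged = bool(res.success) and not separated
    if not converged:
        warnings.warn(
            "logistic fit did not converge cleanly"
            + (" (quasi-separation suspected; set l2 > 0)" if separated or l2 == 0 else ""),
            UserWarning,
            stacklevel=2,
        )
    return LogisticModel(
        reference_label=reference,
        class_labels=tuple(class_labels),
        predictor_labels=predictor_order,
        coefficients=B,
        fit_meta={
            "converged": converged,
            "separated": separated,
            "iterations": int(res.nit),
            "l2": l2,
            "nll": float(res.fun),
            "trace": trace,
        },
    )


def predict_probabilities(
    model: LogisticModel, profile: DistanceProfile
) -> ProbabilityProfile:
    """Softmax class probabilities for one profile; argmax assignment.

    Exact probability ties (rare outside degenerate models) resolve to the
    first label in canonical ordering, matching the nearest-mean tie rule.
    """
    missing = set(model.predictor_labels) - set(profile.distances)
    if missing:
        raise ValueError(f"profile missing predictors: {sorted(missing)}")
    x = np.array([profile.distances[k] for k in model.predictor_labels])
    p = softmax(model.scores(x))
    probs = {lab: float(pi) for lab, pi in zip(model.class_labels, p)}
    pmax = max(probs.values())
    winners = [lab for lab, pi in probs.items() if pi == pmax]
    assigned = winners[0] if len(winners) == 1 else canonical_sort(winners)[0]
    return ProbabilityProfile(
        site_id=profile.site_id, probabilities=probs, assigned_label=assigned
    )


def classify_profiles(
    model: LogisticModel, profiles: Sequence[DistanceProfile]
) -> list[Assignment]:
    return [
        Assignment(label=predict_probabilities(model, p).assigned_label)
        for p in profiles
    ]


def certainty_summary(
    results: Sequence[ProbabilityProfile], labels_true: Sequence[str]
) -> pd.DataFrame:
    """Quartiles of the assigned-class probability, split by outcome and group.

    Returns a tidy frame with one row per (group, outcome) plus overall rows
    (group = "ALL"), columns q25/q50/q75/n — the numbers behind the usual
    certainty box plots: confident correct classifications should concentrate
    near 1, misclassifications lower.
    """
    if len(results) != len(labels_true):
        raise ValueError("results and labels_true must have equal length")
    if not results:
        raise ValueError("no results to summarise")
    rows = []
    recs = [
        (t, "correct" if r.assigned_label == t else "incorrect", r.probabilities[r.assigned_label])
        for r, t in zip(results, labels_true)
    ]
    groups = ["ALL"] + canonical_sort(labels_true)
    for g in groups:
        for outcome in ("correct", "incorrect"):
            vals = [p for t, o, p in recs if o == outcome and (g == "ALL" or t == g)]
            if not vals:
                continue
            q25, med, q75 = np.percentile(vals, [25, 50, 75])
            rows.append(
                {"group": g, "outcome": outcome, "q25": q25, "q50": med, "q75": q75, "n": len(vals)}
            )
    return pd.DataFrame(rows)


def coefficient_table(model: LogisticModel) -> pd.DataFrame:
    """Coefficients as responses × [Intercept + predictors] (reference row omitted)."""
    cols = ["Intercept"] + list(model.predictor_labels)
    return pd.DataFrame(
        model.coefficients, index=list(model.class_labels[1:]), columns=cols
    )
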