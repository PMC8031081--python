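"""Core CDPA encoding: principal frames, axis distances, and the 3x3 descriptor.

A binding site is an n x 3 cloud of atom coordinates (Å).  Its shape is
summarised by the covariance matrix of the per-atom Euclidean distances to
the three principal axes of the cloud — the eigenvector directions of the
coordinate covariance through the centroid, ordered by decreasing variance.
Because distances to the axes do not depend on the coordinate frame the
structure was deposited in, the descriptor is invariant to rigid motion
(and to reflections) without any alignment step.

The 3x3 symmetric descriptor is vectorised to a 6-vector with the three
off-diagonals scaled by sqrt(2), so the vector's Euclidean norm equals the
matrix's Frobenius norm and downstream Euclidean/Mahalanobis geometry is
preserved.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .exceptions import DegenerateFrameWarning, DegenerateSiteError
from .structure_io import BindingSite

__all__ = [
    "PrincipalFrame",
    "CDPAMatrix",
    "CDPAVector",
    "coordinate_covariance",
    "principal_frame",
    "distances_to_axes",
    "cdpa_matrix",
    "distance_covariance",
    "vecd",
    "radius_of_gyration",
    "encode_sites",
    "write_cdpa_table",
    "read_cdpa_table",
]

_EIG_DEGENERACY_RTOL = 1e-8


@dataclass(frozen=True)
class PrincipalFrame:
    """Centroid plus orthonormal principal axes of an atom cloud.

    ``axes`` has the unit eigenvectors of the coordinate covariance as rows,
    sorted by decreasing eigenvalue; ``variances`` holds the matching
    eigenvalues (Å², divisor-n convention).
    """

    centroid: np.ndarray
    axes: np.ndarray
    variances: np.ndarray

    def __post_init__(self) -> None:
        gram = self.axes @ self.axes.T
        if not np.allclose(gram, np.eye(3), atol=1e-10):
            raise ValueError("axes must be orthonormal to 1e-10")
        if np.any(np.diff(self.variances) > 1e-12):
            raise ValueError("variances must be sorted non-increasing")


@dataclass(frozen=True)
class CDPAMatrix:
    """The 3x3 covariance of atom distances to the three principal axes (Å²)."""

    S: np.ndarray
    site_id: str = ""
    n_atoms: int = 0

    def __post_init__(self) -> None:
        S = np.asarray(self.S, dtype=float)
        if S.shape != (3, 3) or not np.allclose(S, S.T, atol=1e-10):
            raise ValueError("S must be 3x3 symmetric to 1e-10")
        if np.linalg.eigvalsh(0.5 * (S + S.T)).min() < -1e-10:
            raise ValueError("S must be positive semi-definite")
        object.__setattr__(self, "S", S)


@dataclass(frozen=True)
class CDPAVector:
    """Norm-preserving 6-vector form of a CDPAMatrix.

    Layout: (Var d1, Var d2, Var d3, √2·Cov(d1,d2), √2·Cov(d1,d3), √2·Cov(d2,d3)).
    """

    v: np.ndarray
    site_id: str = ""

    def __post_init__(self) -> None:
        v = np.asarray(self.v, dtype=float)
        if v.shape != (6,):
            raise ValueError("v must be a 6-vector")
        object.__setattr__(self, "v", v)


def _as_coords(coords: "np.ndarray | BindingSite") -> np.ndarray:
    if isinstance(coords, BindingSite):
        coords = coords.coords
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 2 or coords.shape[1] != 3:
        raise ValueError("coordinates must be an n x 3 array")
    if not np.all(np.isfinite(coords)):
        raise ValueError("coordinates must be finite")
    return coords


def coordinate_covariance(coords: np.ndarray) -> np.ndarray:
    """Population covariance (divisor n) of an n x 3 coordinate array.

    This is the convention used for the principal-axis decomposition; the
    divisor does not affect the axes themselves, only the variances.
    """
    X = _as_coords(coords)
    n = X.shape[0]
    if n < 2:
        raise DegenerateSiteError(f"need at least 2 points for a covariance, got {n}")
    dev = X - X.mean(axis=0)
    S = dev.T @ dev / n
    return 0.5 * (S + S.T)


def principal_frame(coords: np.ndarray) -> PrincipalFrame:
    """Principal axes of an atom cloud, with a deterministic sign convention.

    Eigenvectors of the (symmetrised) coordinate covariance, sorted by
    decreasing eigenvalue.  Each axis is oriented so its largest-magnitude
    component is positive (ties broken by earliest index); distances to an
    axis are sign-blind, so this only pins down the frame for reproducibility.
    Near-equal eigenvalues (relative gap < 1e-8) trigger a degeneracy
    warning: the axes, and hence the descriptor, are then convention-dependent.
    """
    X = _as_coords(coords)
    if X.shape[0] < 4:
        raise DegenerateSiteError(
            f"need at least 4 atoms for a principal frame, got {X.shape[0]}"
        )
    S = coordinate_covariance(X)
    if np.allclose(S, 0.0, atol=1e-14):
        raise DegenerateSiteError("coincident points: coordinate covariance is zero")
    evals, evecs = np.linalg.eigh(S)  # ascending
    order = np.argsort(evals)[::-1]
    evals = evals[order]
    axes = evecs[:, order].T
    scale = max(evals[0], 1e-300)
    gaps = np.abs(np.diff(evals)) / scale
    if np.any(gaps < _EIG_DEGENERACY_RTOL):
        warnings.warn(
            "near-equal eigenvalues: principal axes are not unique and the "
            "descriptor is convention-dependent",
            DegenerateFrameWarning,
            stacklevel=2,
        )
    for j in range(3):
        k = int(np.argmax(np.abs(axes[j])))
        if axes[j][k] < 0:
            axes[j] = -axes[j]
    return PrincipalFrame(centroid=X.mean(axis=0), axes=axes, variances=np.clip(evals, 0.0, None))


def distances_to_axes(coords: np.ndarray, frame: PrincipalFrame) -> np.ndarray:
    """n x 3 matrix of Euclidean distances of each atom to each principal axis.

    d[k, j] = ||(x_k − x̄) − ((x_k − x̄)·u_j) u_j|| for unit axis u_j through
    the centroid x̄.
    """
    X = _as_coords(coords)
    dev = X - frame.centroid
    proj = dev @ frame.axes.T  # (n, 3) signed components along each axis
    sq = np.sum(dev**2, axis=1)[:, None] - proj**2
    return np.sqrt(np.clip(sq, 0.0, None))


def _column_covariance(M: np.ndarray, divisor: str) -> np.ndarray:
    n = M.shape[0]
    dev = M - M.mean(axis=0)
    if divisor == "n":
        S = dev.T @ dev / n
    elif divisor == "n-1":
        S = dev.T @ dev / (n - 1)
    else:
        raise ValueError(f"divisor must be 'n' or 'n-1', got {divisor!r}")
    return 0.5 * (S + S.T)


def distance_covariance(d: np.ndarray, divisor: str = "n-1") -> np.ndarray:
    """Covariance step of the encoder, applied to a precomputed n x 3 matrix
    of atom-to-axis distances.

    Useful when only the distance matrix is known (e.g. checking a worked
    example); ``cdpa_matrix`` composes ``principal_frame`` →
    ``distances_to_axes`` → this step.
    """
    d = np.asarray(d, dtype=float)
    if d.ndim != 2 or d.shape[1] != 3:
        raise ValueError("distance matrix must be n x 3")
    if d.shape[0] < 2:
        raise DegenerateSiteError("need at least 2 atoms")
    if np.any(d < 0):
        raise ValueError("distances must be non-negative")
    return _column_covariance(d, divisor)


def cdpa_matrix(site: "BindingSite | np.ndarray", divisor: str = "n-1") -> CDPAMatrix:
    """Encode a binding site as the covariance of its atom-to-axis distances.

    ``divisor`` selects the sample (``"n-1"``, default) or population
    (``"n"``) convention for the distance covariance; the two differ by a
    factor n/(n−1) and are otherwise interchangeable downstream as long as
    one convention is used throughout.
    """
    site_id = site.site_id if isinstance(site, BindingSite) else ""
    X = _as_coords(site)
    if X.shape[0] < 4:
        raise DegenerateSiteError(
            f"site {site_id or '<anonymous>'} has {X.shape[0]} atoms; need >= 4"
        )
    frame = principal_frame(X)
    d = distances_to_axes(X, frame)
    S = _column_covariance(d, divisor)
    # clip tiny negative eigenvalues from roundoff
    w = np.linalg.eigvalsh(S)
    if w.min() < 0 and w.min() > -1e-10:
        S = S - np.eye(3) * w.min()
    return CDPAMatrix(S=S, site_id=site_id, n_atoms=X.shape[0])


_SQRT2 = np.sqrt(2.0)


def vecd(S: "CDPAMatrix | np.ndarray") -> CDPAVector:
    """Vectorise a symmetric 3x3 matrix with √2-weighted off-diagonals.

    The weighting makes the map an isometry: ||vecd(S)||² = ||S||_F².
    """
    site_id = S.site_id if isinstance(S, CDPAMatrix) else ""
    M = S.S if isinstance(S, CDPAMatrix) else np.asarray(S, dtype=float)
    if M.shape != (3, 3):
        raise ValueError("expected a 3x3 matrix")
    if np.abs(M - M.T).max() > 1e-8:
        raise ValueError("matrix is asymmetric beyond 1e-8")
    v = np.array(
        [M[0, 0], M[1, 1], M[2, 2], _SQRT2 * M[0, 1], _SQRT2 * M[0, 2], _SQRT2 * M[1, 2]]
    )
    return CDPAVector(v=v, site_id=site_id)


def radius_of_gyration(site: "BindingSite | np.ndarray", definition: str = "rms") -> float:
    """Radius of gyration of the atom cloud.

    ``"rms"`` (default) is the root-mean-square distance of atoms to the
    centroid — the standard definition.  ``"sd"`` gives the literal standard
    deviation of the centroid distances, occasionally seen in prose
    descriptions; it differs whenever the mean distance is nonzero.
    """
    X = _as_coords(site)
    r = np.linalg.norm(X - X.mean(axis=0), axis=1)
    if definition == "rms":
        return float(np.sqrt(np.mean(r**2)))
    if definition == "sd":
        return float(np.std(r))
    raise ValueError(f"definition must be 'rms' or 'sd', got {definition!r}")


def encode_sites(
    sites: Iterable[BindingSite], divisor: str = "n-1"
) -> list[CDPAVector]:
    """Encode each site to its 6-vector descriptor (cdpa_matrix then vecd)."""
    return [vecd(cdpa_matrix(s, divisor=divisor)) for s in sites]


_TABLE_COLUMNS = [
    "site_id",
    "ligand_label",
    "S11",
    "S22",
    "S33",
    "S12",
    "S13",
    "S23",
    "v1",
    "v2",
    "v3",
    "v4",
    "v5",
    "v6",
]


def write_cdpa_table(
    path,
    matrices: Sequence[CDPAMatrix],
    labels: Sequence[str],
) -> pd.DataFrame:
    """Write descriptors as a TSV round-trippable at 12 significant digits."""
    rows = []
    for m, lab in zip(matrices, labels, strict=True):
        v = vecd(m).v
        rows.append(
            [m.site_id, lab, m.S[0, 0], m.S[1, 1], m.S[2, 2], m.S[0, 1], m.S[0, 2], m.S[1, 2], *v]
        )
    df = pd.DataFrame(rows, columns=_TABLE_COLUMNS)
    df.to_csv(path, sep="\t", index=False, float_format="%.12g")
    return df


def read_cdpa_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(_TABLE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"CDPA table missing columns: {sorted(missing)}")
    return df
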