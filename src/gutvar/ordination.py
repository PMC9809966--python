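"""Bray-Curtis dissimilarity, principal coordinates, environmental vectors.

PCoA is classical scaling: double-centre the squared dissimilarities,
eigendecompose, and scale eigenvectors by the square roots of the positive
eigenvalues.  No correction is applied for negative eigenvalues; they are
reported and their axes dropped.

``envfit`` regresses an external variable (e.g. a metabolite concentration)
on the sample scores of the retained axes; the arrow direction is the
normalised coefficient vector, the statistic is the squared multiple
correlation R², and significance comes from permuting the variable across
samples.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .io import SampleTable

__all__ = [
    "DistanceMatrix",
    "OrdinationResult",
    "FittedVector",
    "bray_curtis",
    "pcoa",
    "envfit",
]


@dataclass
class DistanceMatrix:
    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("distance matrix must be square")
        if v.shape[0] != len(self.labels):
            raise ValueError("label count does not match matrix size")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric")
        if np.abs(np.diag(v)).max(initial=0.0) > 1e-12:
            raise ValueError("distance matrix diagonal must be zero")
        if v.min(initial=0.0) < 0:
            raise ValueError("distances must be non-negative")
        self.values = v


@dataclass
class OrdinationResult:
    coordinates: pd.DataFrame  # samples x retained axes
    eigenvalues: np.ndarray  # all eigenvalues, descending
    proportion_explained: np.ndarray  # over positive eigenvalues


@dataclass
class FittedVector:
    variable: str
    direction: np.ndarray  # unit vector in ordination space
    r2: float
    p_perm: float


def bray_curtis(abund: SampleTable | pd.DataFrame) -> DistanceMatrix:
    """Pairwise Bray-Curtis dissimilarity between sample rows.

    d(i, j) = sum_k |x_ik - x_jk| / sum_k (x_ik + x_jk); a pair of all-zero
    samples has an undefined dissimilarity, set to 0 with a warning.
    """
    df = abund.data if isinstance(abund, SampleTable) else abund
    x = df.to_numpy(dtype=float)
    if x.min(initial=0.0) < 0:
        raise ValueError("abundances must be non-negative")
    with np.errstate(invalid="ignore"):
        d = squareform(pdist(x, metric="braycurtis"))
    if np.isnan(d).any():
        warnings.warn("all-zero sample pair; setting its dissimilarity to 0")
        d = np.nan_to_num(d, nan=0.0)
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2.0  # exact symmetry
    return DistanceMatrix(list(df.index), d)


def pcoa(d: DistanceMatrix, n_axes: int = 2) -> OrdinationResult:
    """Classical scaling of a dissimilarity matrix.

    Gower centring: B = -1/2 * J D^2 J with J = I - 11'/n.  Coordinates are
    eigenvectors scaled by sqrt(eigenvalue) for positive eigenvalues only.
    """
    D = d.values
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D**2) @ J
    eigval, eigvec = np.linalg.eigh((B + B.T) / 2.0)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    tol = max(1e-12, 1e-10 * abs(eigval[0])) if n else 1e-12
    positive = eigval > tol
    n_pos = int(positive.sum())
    if n_axes > n_pos:
        warnings.warn(
            f"only {n_pos} positive eigenvalues; truncating to {n_pos} axes"
        )
        n_axes = n_pos
    coords = eigvec[:, :n_axes] * np.sqrt(eigval[:n_axes])
    coordinates = pd.DataFrame(
        coords,
        index=d.labels,
        columns=[f"PCo{i + 1}" for i in range(n_axes)],
    )
    pos_sum = eigval[positive].sum()
    proportion = eigval[:n_pos] / pos_sum if pos_sum > 0 else np.zeros(0)
    return OrdinationResult(coordinates, eigval, proportion)


def _r2(y: np.ndarray, Q: np.ndarray) -> float:
    """Squared multiple correlation of centred y on the orthonormal basis Q."""
    ssy = float(y @ y)
    if ssy == 0:
        return 0.0
    proj = Q.T @ y
    return float(proj @ proj / ssy)


def envfit(
    ord_result: OrdinationResult,
    env: SampleTable | pd.DataFrame,
    n_perm: int = 999,
    seed: int | None = None,
) -> list[FittedVector]:
    """Fit environmental variables as vectors into an ordination.

    For each variable, least-squares regression of the (centred) values on
    the sample scores gives R² and the arrow direction; the permutation p is
    (1 + #{permuted R² >= observed}) / (1 + n_perm), permuting the variable
    across samples.
    """
    if n_perm < 99:
        raise ValueError(f"n_perm must be >= 99, got {n_perm}")
    df = env.data if isinstance(env, SampleTable) else env
    if list(df.index) != list(ord_result.coordinates.index):
        try:
            df = df.loc[ord_result.coordinates.index]
        except KeyError as exc:
            raise ValueError(
                "environmental rows do not align with ordination samples"
            ) from exc
    X = ord_result.coordinates.to_numpy(dtype=float)
    Xc = X - X.mean(axis=0)
    Q, _ = np.linalg.qr(Xc)
    rng = np.random.default_rng(seed)
    n = X.shape[0]
    out = []
    for var in df.columns:
        y = df[var].to_numpy(dtype=float)
        if np.ptp(y) == 0:
            warnings.warn(f"constant environmental variable {var!r}")
            out.append(FittedVector(var, np.zeros(X.shape[1]), 0.0, 1.0))
            continue
        yc = y - y.mean()
        r2_obs = _r2(yc, Q)
        beta, *_ = np.linalg.lstsq(Xc, yc, rcond=None)
        direction = beta / np.linalg.norm(beta)
        # vectorised permutation null: rows of P are permuted copies of yc
        perms = np.argsort(rng.random((n_perm, n)), axis=1)
        P = yc[perms]
        proj = P @ Q  # n_perm x n_axes
        r2_perm = (proj**2).sum(axis=1) / float(yc @ yc)
        p = (1.0 + np.count_nonzero(r2_perm >= r2_obs - 1e-12)) / (1.0 + n_perm)
        out.append(FittedVector(var, direction, r2_obs, float(p)))
    return out
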