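"""Classic fuzzy C-means clustering.

Fuzzy C-means (FCM) partitions ``n`` points into ``C`` overlapping clusters
by minimising the membership-weighted within-cluster scatter

    J(U, c) = sum_x sum_y  p_xy^w  ||point_y - c_x||^2,

subject to every membership column summing to one.  The fuzzifier ``w > 1``
controls how soft the partition is: as ``w -> 1`` the memberships approach a
hard k-means assignment, large ``w`` blurs every point across all clusters.

The alternating-optimisation driver :func:`fcm_fit` interleaves the closed
form membership update with the weighted-mean centre update and stops when no
membership entry moves by more than ``tol``.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

__all__ = [
    "FCMConfig",
    "FCMResult",
    "fcm_objective",
    "fcm_update_memberships",
    "fcm_update_centers",
    "fcm_fit",
    "validate_partition",
]

#: distances at or below this are treated as an exact coincidence
_ZERO_DIST = 1e-12


@dataclass(frozen=True)
class FCMConfig:
    """Settings for an FCM fit.

    Parameters
    ----------
    n_clusters:
        Number of clusters ``C`` (>= 1).
    fuzzifier:
        Weighting exponent ``w``; must be strictly greater than 1 (at
        ``w = 1`` the membership update degenerates).
    tol:
        Convergence threshold on the maximum absolute membership change.
    max_iter:
        Iteration cap.
    seed:
        Seed for the centre initialisation (distinct samples drawn without
        replacement).
    """

    n_clusters: int
    fuzzifier: float = 2.0
    tol: float = 1e-4
    max_iter: int = 300
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_clusters < 1:
            raise ValueError("n_clusters must be >= 1")
        if not self.fuzzifier > 1.0:
            raise ValueError("fuzzifier must be strictly greater than 1")
        if not (0.0 < self.tol < 1.0):
            raise ValueError("tol must lie in (0, 1)")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")


@dataclass
class FCMResult:
    """Outcome of :func:`fcm_fit`.

    ``partition`` is the ``C x n`` membership matrix (columns sum to 1),
    ``centers`` the ``C x d`` cluster centres and ``history`` the objective
    value after every full update sweep.
    """

    partition: np.ndarray
    centers: np.ndarray
    history: np.ndarray
    n_iter: int
    converged: bool


def _as_matrix(X, name: str = "X") -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError(f"{name} must be a 2-D array, got ndim={X.ndim}")
    if not np.all(np.isfinite(X)):
        raise ValueError(f"{name} contains non-finite entries")
    return X


def validate_partition(U, n_samples: int | None = None, atol: float = 1e-6) -> np.ndarray:
    """Check that ``U`` is a valid fuzzy partition (entries in [0,1], columns
    summing to one) and return it as a float array."""
    U = _as_matrix(U, "partition")
    if n_samples is not None and U.shape[1] != n_samples:
        raise ValueError(
            f"partition has {U.shape[1]} columns, expected {n_samples} samples"
        )
    if np.any(U < -atol) or np.any(U > 1 + atol):
        raise ValueError("partition entries must lie in [0, 1]")
    col = U.sum(axis=0)
    if np.any(np.abs(col - 1.0) > atol):
        raise ValueError("partition columns must sum to 1")
    return U


def memberships_from_sqdist(
    D: np.ndarray, fuzzifier: float, lam: float | None = None
) -> np.ndarray:
    """Membership matrix from a ``C x n`` squared-distance matrix.

    Implements the inverse-distance update: with squared distances ``D`` the
    membership of sample ``y`` in cluster ``x`` is proportional to
    ``D[x, y] ** (-1 / (w - 1))``, normalised over clusters.  A sample at
    zero distance from one or more centres gets its full membership split
    equally among the coinciding centres.

    When ``lam`` is given, any sample whose largest normalised membership
    reaches ``lam`` is snapped hard to the arg-max cluster (the crispification
    threshold used by the kernelised variant).
    """
    D = np.asarray(D, dtype=float)
    C, n = D.shape
    expo = -1.0 / (fuzzifier - 1.0)
    zero = D <= _ZERO_DIST
    any_zero = zero.any(axis=0)

    U = np.empty_like(D)
    with np.errstate(divide="ignore", over="ignore"):
        inv = np.where(zero, np.nan, D) ** expo
    # soft columns
    soft_cols = ~any_zero
    if soft_cols.any():
        block = inv[:, soft_cols]
        U[:, soft_cols] = block / block.sum(axis=0, keepdims=True)
    # coinciding samples: split among the zero-distance clusters
    if any_zero.any():
        zblock = zero[:, any_zero].astype(float)
        U[:, any_zero] = zblock / zblock.sum(axis=0, keepdims=True)
    if lam is not None and soft_cols.any():
        top = U.max(axis=0)
        snap = soft_cols & (top >= lam)
        if snap.any():
            arg = U[:, snap].argmax(axis=0)
            hard = np.zeros((C, int(snap.sum())))
            hard[arg, np.arange(hard.shape[1])] = 1.0
            U[:, snap] = hard
    return U


def fcm_objective(X, U, centers, fuzzifier: float = 2.0) -> float:
    """Membership-weighted within-cluster sum of squared distances.

    Reduces to the k-means objective for a hard (one-hot) partition.
    """
    X = _as_matrix(X)
    centers = _as_matrix(centers, "centers")
    U = validate_partition(U, n_samples=X.shape[0])
    if centers.shape[0] != U.shape[0]:
        raise ValueError("centers and partition disagree on the cluster count")
    if centers.shape[1] != X.shape[1]:
        raise ValueError("centers and X disagree on dimensionality")
    D = cdist(centers, X, metric="sqeuclidean")
    return float(np.sum(U**fuzzifier * D))


def fcm_update_memberships(X, centers, fuzzifier: float = 2.0) -> np.ndarray:
    """One membership update given fixed centres.

    Returns the ``C x n`` partition with columns summing to one.  Samples
    coinciding with a centre receive membership 1 there (split equally if
    several centres coincide).
    """
    X = _as_matrix(X)
    centers = _as_matrix(centers, "centers")
    if centers.shape[1] != X.shape[1]:
        raise ValueError("centers and X disagree on dimensionality")
    D = cdist(centers, X, metric="sqeuclidean")
    return memberships_from_sqdist(D, fuzzifier)


def fcm_update_centers(X, U, fuzzifier: float = 2.0) -> np.ndarray:
    """One centre update given a fixed partition: each centre is the
    ``p^w``-weighted mean of all samples."""
    X = _as_matrix(X)
    U = validate_partition(U, n_samples=X.shape[0])
    W = U**fuzzifier
    mass = W.sum(axis=1)
    if np.any(mass <= 0.0):
        bad = int(np.flatnonzero(mass <= 0.0)[0])
        raise ValueError(f"cluster {bad} has zero total membership (degenerate)")
    return (W @ X) / mass[:, None]


def init_center_indices(rng: np.random.Generator, n: int, C: int) -> np.ndarray:
    """Indices of ``C`` distinct samples drawn without replacement."""
    return rng.choice(n, size=C, replace=False)


def fcm_fit(X, cfg: FCMConfig) -> FCMResult:
    """Alternate membership and centre updates until convergence.

    Centres are initialised as ``C`` distinct samples drawn under
    ``cfg.seed``; the run is deterministic for a fixed seed.  The recorded
    objective history is non-increasing (each half-update minimises the
    objective in its own block of variables).
    """
    X = _as_matrix(X)
    n = X.shape[0]
    C = cfg.n_clusters
    if n < C:
        raise ValueError(f"need at least n_clusters={C} samples, got {n}")
    rng = np.random.default_rng(cfg.seed)
    centers = X[init_center_indices(rng, n, C)].copy()

    history: list[float] = []
    U_prev: np.ndarray | None = None
    converged = False
    it = 0
    for it in range(1, cfg.max_iter + 1):
        U = fcm_update_memberships(X, centers, cfg.fuzzifier)
        centers = fcm_update_centers(X, U, cfg.fuzzifier)
        history.append(fcm_objective(X, U, centers, cfg.fuzzifier))
        if U_prev is not None and np.max(np.abs(U - U_prev)) < cfg.tol:
            converged = True
            break
        U_prev = U
    return FCMResult(
        partition=U,
        centers=centers,
        history=np.asarray(history),
        n_iter=it,
        converged=converged,
    )


def config_with(cfg: FCMConfig, **kwargs) -> FCMConfig:
    """Return a copy of ``cfg`` with the given fields replaced."""
    return dataclasses.replace(cfg, **kwargs)
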