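"""Kernelised fuzzy C-means.

The samples are mapped implicitly into a reproducing-kernel feature space
through a kernel function ``Z``; squared distances there follow from the
kernel alone,

    d(x, y) = Z(x, x) - 2 Z(x, y) + Z(y, y),

so clustering can run on the Gram matrix without ever materialising the
feature map.  Cluster centres are kept as convex weight vectors over the
training samples: if centre ``q`` has weights ``v`` then
``Z(x, q) = sum_s v_s Z(x, i_s)`` and ``Z(q, q) = v' K v``.

Two behaviours distinguish this variant from the classic Euclidean FCM:

* with a linear kernel the induced distance is exactly the squared Euclidean
  distance, and the fit coincides with :func:`cofsvm.fcm.fcm_fit`;
* an optional crispification threshold ``lam``: once a sample's dominant
  normalised membership reaches ``lam`` (default 0.65) the sample is snapped
  hard to that cluster, accelerating the separation of core points from
  boundary points.  Set ``lam=None`` to keep the update purely soft.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics.pairwise import pairwise_kernels

from .fcm import (
    _as_matrix,
    init_center_indices,
    memberships_from_sqdist,
)

__all__ = [
    "KernelSpec",
    "KFCMConfig",
    "KFCMResult",
    "gram_matrix",
    "kernel_distance",
    "center_sqdist",
    "kfcm_fit",
]

_KERNEL_NAMES = ("linear", "rbf", "polynomial")


@dataclass(frozen=True)
class KernelSpec:
    """A kernel function ``Z(x, y)``.

    ``name`` is one of ``linear``, ``rbf`` or ``polynomial``.  For the rbf
    kernel ``gamma=None`` resolves at fit time to ``1 / (d * var(X))`` (the
    usual data-driven scale).  ``degree`` and ``coef0`` apply to the
    polynomial kernel ``(gamma * x.y + coef0) ** degree``.
    """

    name: str = "rbf"
    gamma: float | None = None
    degree: int = 3
    coef0: float = 0.0

    def __post_init__(self) -> None:
        if self.name not in _KERNEL_NAMES:
            raise ValueError(f"unknown kernel {self.name!r}; expected one of {_KERNEL_NAMES}")
        if self.gamma is not None and self.gamma <= 0:
            raise ValueError("gamma must be positive")
        if self.degree < 1:
            raise ValueError("degree must be >= 1")

    def resolve(self, X) -> "KernelSpec":
        """Return a copy with a concrete gamma for the given training data."""
        if self.name == "linear" or self.gamma is not None:
            return self
        X = np.asarray(X, dtype=float)
        var = float(X.var())
        gamma = 1.0 / (X.shape[1] * var) if var > 0 else 1.0
        return dataclasses.replace(self, gamma=gamma)

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "gamma": self.gamma,
            "degree": self.degree,
            "coef0": self.coef0,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "KernelSpec":
        return cls(**d)


def _pairwise(X, Y, spec: KernelSpec) -> np.ndarray:
    if spec.name == "linear":
        return pairwise_kernels(X, Y, metric="linear")
    if spec.name == "rbf":
        if spec.gamma is None:
            raise ValueError("rbf kernel needs a resolved gamma")
        return pairwise_kernels(X, Y, metric="rbf", gamma=spec.gamma)
    gamma = 1.0 if spec.gamma is None else spec.gamma
    return pairwise_kernels(
        X, Y, metric="polynomial", gamma=gamma, degree=spec.degree, coef0=spec.coef0
    )


def gram_matrix(X, spec: KernelSpec) -> np.ndarray:
    """The ``n x n`` symmetric PSD matrix of ``Z(i_x, i_y)`` values."""
    X = _as_matrix(X)
    K = _pairwise(X, X, spec)
    return 0.5 * (K + K.T)  # enforce exact symmetry against fp noise


def cross_gram(X, Y, spec: KernelSpec) -> np.ndarray:
    """Kernel values between the rows of two sample matrices."""
    return _pairwise(_as_matrix(X), _as_matrix(Y, "Y"), spec)


def self_kernel_diag(X, spec: KernelSpec) -> np.ndarray:
    """``Z(x, x)`` for every row of ``X`` without forming a full Gram matrix."""
    X = _as_matrix(X)
    if spec.name == "rbf":
        return np.ones(X.shape[0])
    sq = np.einsum("ij,ij->i", X, X)
    if spec.name == "linear":
        return sq
    gamma = 1.0 if spec.gamma is None else spec.gamma
    return (gamma * sq + spec.coef0) ** spec.degree


def kernel_distance(x, y, spec: KernelSpec) -> float:
    """Kernel-induced squared distance ``Z(x,x) - 2 Z(x,y) + Z(y,y)``.

    For the linear kernel this is exactly the squared Euclidean distance; for
    any stationary kernel (rbf) it vanishes at ``x == y``.
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    y = np.atleast_2d(np.asarray(y, dtype=float))
    if x.shape != y.shape:
        raise ValueError("x and y must have equal dimension")
    kxx = float(self_kernel_diag(x, spec)[0])
    kyy = float(self_kernel_diag(y, spec)[0])
    kxy = float(_pairwise(x, y, spec)[0, 0])
    return max(0.0, kxx - 2.0 * kxy + kyy)


@dataclass(frozen=True)
class KFCMConfig:
    """Settings for a kernel-FCM fit.

    ``lam`` is the crispification threshold: a sample whose dominant
    normalised membership reaches ``lam`` is assigned hard.  The default
    0.65 is the operating point at which the clustering becomes decisive
    without hardening genuinely ambiguous boundary samples; ``None``
    disables the branch entirely.
    """

    n_clusters: int
    fuzzifier: float = 2.0
    lam: float | None = 0.65
    tol: float = 1e-4
    max_iter: int = 300
    seed: int = 0
    kernel: KernelSpec = field(default_factory=KernelSpec)

    def __post_init__(self) -> None:
        if self.n_clusters < 1:
            raise ValueError("n_clusters must be >= 1")
        if not self.fuzzifier > 1.0:
            raise ValueError("fuzzifier must be strictly greater than 1")
        if self.lam is not None and not (0.0 < self.lam <= 1.0):
            raise ValueError("lam must lie in (0, 1] or be None")
        if not (0.0 < self.tol < 1.0):
            raise ValueError("tol must lie in (0, 1)")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")


@dataclass
class KFCMResult:
    """Outcome of :func:`kfcm_fit`.

    ``weights`` holds the centres as a ``C x n`` row-stochastic matrix over
    the training samples; ``kernel`` is the resolved kernel spec (concrete
    gamma).  Use :func:`center_sqdist` with ``weights`` and the training
    matrix to measure kernel distances from new points to the centres.
    """

    partition: np.ndarray
    weights: np.ndarray
    history: np.ndarray
    n_iter: int
    converged: bool
    kernel: KernelSpec


def _center_sqdist_from_gram(K: np.ndarray, V: np.ndarray) -> np.ndarray:
    """``C x n`` squared kernel distances given Gram ``K`` and centre weights ``V``."""
    cross = V @ K
    ss = np.einsum("cn,cn->c", V, cross)
    D = np.diag(K)[None, :] - 2.0 * cross + ss[:, None]
    np.maximum(D, 0.0, out=D)
    return D


def center_sqdist(X_query, X_fit, weights, spec: KernelSpec) -> np.ndarray:
    """Squared kernel distances from query points to fitted centres.

    Returns an ``n_query x C`` matrix; row ``i`` holds the distance of query
    point ``i`` to each centre represented by ``weights`` over ``X_fit``.
    """
    Xq = _as_matrix(X_query, "X_query")
    Xf = _as_matrix(X_fit, "X_fit")
    V = np.asarray(weights, dtype=float)
    diag = self_kernel_diag(Xq, spec)
    Kqf = cross_gram(Xq, Xf, spec)
    Kff = gram_matrix(Xf, spec)
    cross = Kqf @ V.T  # n_q x C
    ss = np.einsum("cn,nm,cm->c", V, Kff, V)
    D = diag[:, None] - 2.0 * cross + ss[None, :]
    np.maximum(D, 0.0, out=D)
    return D


def kfcm_fit(X, cfg: KFCMConfig) -> KFCMResult:
    """Kernel fuzzy C-means on the Gram matrix.

    The loop mirrors the classic fit: distances to the current centres,
    membership update (with the optional ``lam`` hard-assignment branch),
    centre-weight update ``v = mu^w / sum mu^w``, until the largest
    membership change drops below ``tol``.  With a linear kernel and
    ``lam=None`` the iterates coincide with :func:`cofsvm.fcm.fcm_fit`
    for the same seed.
    """
    X = _as_matrix(X)
    n = X.shape[0]
    C = cfg.n_clusters
    if n < C:
        raise ValueError(f"need at least n_clusters={C} samples, got {n}")
    kernel = cfg.kernel.resolve(X)
    K = gram_matrix(X, kernel)
    rng = np.random.default_rng(cfg.seed)
    idx = init_center_indices(rng, n, C)
    V = np.zeros((C, n))
    V[np.arange(C), idx] = 1.0

    history: list[float] = []
    U_prev: np.ndarray | None = None
    converged = False
    it = 0
    for it in range(1, cfg.max_iter + 1):
        D = _center_sqdist_from_gram(K, V)
        U = memberships_from_sqdist(D, cfg.fuzzifier, cfg.lam)
        W = U**cfg.fuzzifier
        mass = W.sum(axis=1)
        # a cluster emptied by hard snapping keeps its previous centre
        alive = mass > 0.0
        V_new = V.copy()
        V_new[alive] = W[alive] / mass[alive, None]
        V = V_new
        history.append(float(np.sum(W * _center_sqdist_from_gram(K, V))))
        if U_prev is not None and np.max(np.abs(U - U_prev)) < cfg.tol:
            converged = True
            break
        U_prev = U
    return KFCMResult(
        partition=U,
        weights=V,
        history=np.asarray(history),
        n_iter=it,
        converged=converged,
        kernel=kernel,
    )
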