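"""Binary fuzzy support vector machine.

A fuzzy SVM attaches a membership degree ``mu_x`` in (0, 1] to every
training point and scales that point's slack penalty by it, so the primal
reads

    min  1/2 ||m||^2 + C sum_x mu_x xi_x
    s.t. j_x (m . i_x + h) >= 1 - xi_x,  xi_x >= 0.

In the dual this caps each coefficient at ``mu_x * C`` instead of ``C``:
points believed to be noise (low membership) simply cannot pull hard on the
separating hyperplane.  With all memberships equal to one the machine is the
ordinary soft-margin C-SVM.

Membership assignment strategies:

``constant-one``
    every point counts fully (classical SVM);
``class-center-linear``
    membership decays linearly with distance from the class mean, from 1 at
    the centre down to a floor ``delta`` at the class's farthest point — a
    cheap geometric heuristic that demotes points sitting far inside enemy
    territory (typical label noise);
``kfcm-partition``
    membership is the sample's dominant-cluster membership from a per-class
    kernel fuzzy C-means run, tying the machine to the clustering stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._qp import DualSolution, solve_svm_dual
from .fcm import _as_matrix
from .kernel_fcm import KFCMConfig, KernelSpec, cross_gram, gram_matrix, kfcm_fit

__all__ = [
    "FuzzyTrainingSet",
    "MembershipStrategy",
    "FSVMModel",
    "assign_memberships",
    "fsvm_fit",
    "fsvm_decision",
    "fsvm_predict",
]

_STRATEGIES = ("constant-one", "class-center-linear", "kfcm-partition")


@dataclass
class FuzzyTrainingSet:
    """Triples (sample, role, membership).

    Roles live in {-1, 0, +1}; plain binary training restricts them to
    {-1, +1} (role 0 marks the mixed samples of the multilabel machinery).
    """

    samples: np.ndarray
    roles: np.ndarray
    memberships: np.ndarray

    def __post_init__(self) -> None:
        self.samples = _as_matrix(self.samples, "samples")
        self.roles = np.asarray(self.roles, dtype=int).ravel()
        self.memberships = np.asarray(self.memberships, dtype=float).ravel()
        n = self.samples.shape[0]
        if self.roles.shape != (n,) or self.memberships.shape != (n,):
            raise ValueError("samples, roles and memberships must align")
        if not np.isin(self.roles, (-1, 0, 1)).all():
            raise ValueError("roles must lie in {-1, 0, +1}")
        if np.any(self.memberships < 0) or np.any(self.memberships > 1):
            raise ValueError("memberships must lie in [0, 1]")

    def __len__(self) -> int:
        return self.samples.shape[0]


@dataclass(frozen=True)
class MembershipStrategy:
    """How to turn raw training data into membership degrees.

    ``delta`` is the floor of the class-centre-linear decay (the farthest
    member of a class keeps membership ``delta`` rather than 0, so no point
    is erased outright).  ``kfcm`` configures the per-class clustering for
    the ``kfcm-partition`` strategy; ``n_clusters`` there is a per-class
    count.
    """

    kind: str = "class-center-linear"
    delta: float = 0.1
    kfcm: KFCMConfig | None = None

    def __post_init__(self) -> None:
        if self.kind not in _STRATEGIES:
            raise ValueError(f"unknown strategy {self.kind!r}; expected one of {_STRATEGIES}")
        if not (0.0 < self.delta < 1.0):
            raise ValueError("delta must lie in (0, 1)")


def assign_memberships(X, y, strategy: MembershipStrategy) -> np.ndarray:
    """Membership degree for every sample, computed class by class.

    ``y`` may be any integer class labelling (binary roles or multiclass);
    each distinct value is treated as one class.  Outputs lie in (0, 1];
    a single-sample class degenerates to membership 1.
    """
    X = _as_matrix(X)
    y = np.asarray(y).ravel()
    if y.shape[0] != X.shape[0]:
        raise ValueError("X and y must align")
    mu = np.ones(X.shape[0])
    if strategy.kind == "constant-one":
        return mu
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        if idx.size <= 1:
            continue
        Xc = X[idx]
        if strategy.kind == "class-center-linear":
            r = np.linalg.norm(Xc - Xc.mean(axis=0), axis=1)
            rmax = r.max()
            if rmax > 0:
                mu[idx] = 1.0 - (1.0 - strategy.delta) * r / rmax
        else:  # kfcm-partition
            cfg = strategy.kfcm or KFCMConfig(n_clusters=2)
            if idx.size < cfg.n_clusters:
                continue
            res = kfcm_fit(Xc, cfg)
            mu[idx] = np.maximum(res.partition.max(axis=0), 1e-6)
    return mu


@dataclass
class FSVMModel:
    """A trained fuzzy SVM.

    Only the retained (support) samples are stored for evaluation;
    ``alpha_full`` keeps every dual coefficient of the training run for
    KKT diagnostics.  ``dual_coefs`` are the signed products
    ``alpha_x * j_x`` that enter the decision function
    ``f(i) = sum alpha_y j_y Z(i, i_y) + h``.
    """

    support_samples: np.ndarray
    dual_coefs: np.ndarray
    support_roles: np.ndarray
    offset: float
    kernel: KernelSpec
    penalty: float
    alpha_full: np.ndarray = field(repr=False, default=None)
    solver_gap: float = 0.0

    @property
    def alpha(self) -> np.ndarray:
        """Dual coefficients of the retained support samples."""
        return self.dual_coefs * self.support_roles

    def to_dict(self) -> dict:
        return {
            "support_samples": self.support_samples.tolist(),
            "dual_coefs": self.dual_coefs.tolist(),
            "support_roles": self.support_roles.tolist(),
            "offset": self.offset,
            "kernel": self.kernel.to_dict(),
            "penalty": self.penalty,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FSVMModel":
        return cls(
            support_samples=np.asarray(d["support_samples"], dtype=float),
            dual_coefs=np.asarray(d["dual_coefs"], dtype=float),
            support_roles=np.asarray(d["support_roles"], dtype=int),
            offset=float(d["offset"]),
            kernel=KernelSpec.from_dict(d["kernel"]),
            penalty=float(d["penalty"]),
        )


def fsvm_fit(
    train: FuzzyTrainingSet,
    C: float = 1.0,
    kernel: KernelSpec | None = None,
    tol: float = 1e-8,
) -> FSVMModel:
    """Train a binary fuzzy SVM by solving the membership-capped dual.

    The dual is  max sum a_x - 1/2 sum a_x a_y j_x j_y Z(i_x, i_y)  under
    ``0 <= a_x <= mu_x C`` and ``sum a_x j_x = 0``; the offset is recovered
    from the margin support vectors (averaged) or, failing any, the midpoint
    of the KKT-feasible interval.
    """
    if C <= 0:
        raise ValueError("penalty C must be positive")
    roles = train.roles
    if not np.isin(roles, (-1, 1)).all():
        raise ValueError("binary training requires roles in {-1, +1}")
    if len(np.unique(roles)) < 2:
        raise ValueError("both classes must be present")
    kernel = (kernel or KernelSpec()).resolve(train.samples)
    K = gram_matrix(train.samples, kernel)
    y = roles.astype(float)
    caps = train.memberships * C
    sol: DualSolution = solve_svm_dual(K, y, np.ones(len(y)), caps, tol=tol)
    if not sol.converged:  # pragma: no cover - guarded by generous max_iter
        raise RuntimeError(f"dual solver did not converge (gap={sol.gap:.3e})")
    sv = sol.alpha > 1e-10
    if not sv.any():
        sv = np.ones(len(y), dtype=bool)  # degenerate: keep everything
    return FSVMModel(
        support_samples=train.samples[sv].copy(),
        dual_coefs=sol.alpha[sv] * y[sv],
        support_roles=roles[sv].copy(),
        offset=sol.offset,
        kernel=kernel,
        penalty=C,
        alpha_full=sol.alpha,
        solver_gap=sol.gap,
    )


def fsvm_decision(model: FSVMModel, x) -> np.ndarray | float:
    """Pre-sign decision value(s) ``sum alpha_y j_y Z(x, i_y) + h``."""
    x = np.asarray(x, dtype=float)
    single = x.ndim == 1
    X = np.atleast_2d(x)
    if X.shape[1] != model.support_samples.shape[1]:
        raise ValueError(
            f"feature dimension {X.shape[1]} does not match model "
            f"({model.support_samples.shape[1]})"
        )
    vals = cross_gram(X, model.support_samples, model.kernel) @ model.dual_coefs
    vals = vals + model.offset
    return float(vals[0]) if single else vals


def fsvm_predict(model: FSVMModel, x) -> np.ndarray | int:
    """Sign of the decision value; an exact 0 maps to +1."""
    vals = fsvm_decision(model, x)
    if np.isscalar(vals):
        return 1 if vals >= 0 else -1
    return np.where(np.asarray(vals) >= 0, 1, -1)
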