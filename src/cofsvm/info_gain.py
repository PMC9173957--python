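"""Mutual information ("information gain") between discrete label variables.

For two discrete variables ``I`` and ``J`` with joint probabilities
``u(i, j)`` the gain is

    IG(I, J) = sum_ij u(i, j) log2( u(i, j) / (u(i) u(j)) )
             = H(I) + H(J) - H(I, J),

in bits.  Both routes are evaluated and must agree; the result is clipped at
zero from below against floating-point noise.  Applied to the indicator
columns of a multilabel target this yields a symmetric label-correlation
matrix whose diagonal holds the per-label entropies — large off-diagonal
entries flag label pairs that co-occur far from independence.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "entropy",
    "DiscreteJoint",
    "information_gain",
    "label_correlation_matrix",
]


def entropy(p) -> float:
    """Shannon entropy in bits of a probability vector, with 0*log(0) = 0."""
    p = np.asarray(p, dtype=float).ravel()
    if np.any(p < -1e-12):
        raise ValueError("probabilities must be nonnegative")
    if abs(p.sum() - 1.0) > 1e-9:
        raise ValueError(f"probabilities must sum to 1, got {p.sum()!r}")
    pos = p[p > 0]
    return float(-(pos * np.log2(pos)).sum())


@dataclass(frozen=True)
class DiscreteJoint:
    """Empirical joint distribution of two discrete variables.

    Wraps a nonnegative contingency table of counts; joint and marginal
    probabilities are the plug-in (unsmoothed) estimates.
    """

    counts: np.ndarray

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=float)
        if counts.ndim != 2:
            raise ValueError("counts must be a 2-D contingency table")
        if np.any(counts < 0) or not np.all(np.isfinite(counts)):
            raise ValueError("counts must be finite and nonnegative")
        if counts.sum() <= 0:
            raise ValueError("contingency table is empty")
        object.__setattr__(self, "counts", counts)

    @property
    def joint(self) -> np.ndarray:
        return self.counts / self.counts.sum()

    @property
    def marginal_rows(self) -> np.ndarray:
        return self.joint.sum(axis=1)

    @property
    def marginal_cols(self) -> np.ndarray:
        return self.joint.sum(axis=0)

    @classmethod
    def from_indicators(cls, a, b) -> "DiscreteJoint":
        """2x2 table of two binary indicator vectors."""
        a = np.asarray(a).astype(int).ravel()
        b = np.asarray(b).astype(int).ravel()
        if a.shape != b.shape:
            raise ValueError("indicator vectors must have equal length")
        table = np.zeros((2, 2))
        np.add.at(table, (a, b), 1.0)
        return cls(table)


def information_gain(joint: DiscreteJoint) -> float:
    """Mutual information of a joint distribution, in bits.

    Computed both as the double sum over the joint table and through the
    entropy identity H(I) + H(J) - H(I, J); an internal consistency check
    requires the two to agree to 1e-9.
    """
    u = joint.joint
    ui = joint.marginal_rows
    uj = joint.marginal_cols

    mask = u > 0
    outer = np.outer(ui, uj)
    direct = float(np.sum(u[mask] * np.log2(u[mask] / outer[mask])))

    via_entropy = entropy(ui) + entropy(uj) - entropy(u.ravel())
    if abs(direct - via_entropy) > 1e-9:  # pragma: no cover - internal guard
        raise AssertionError(
            f"mutual-information routes disagree: {direct} vs {via_entropy}"
        )
    return max(0.0, direct)


def label_correlation_matrix(Y) -> np.ndarray:
    """Pairwise information gain between the indicator columns of ``Y``.

    ``Y`` is an ``n x L`` binary matrix.  Entry ``(a, b)`` is the gain
    between columns ``a`` and ``b``; the diagonal holds each label's own
    entropy.  A constant (all-zero or all-one) column carries no information
    and produces zero entries, with a warning.
    """
    Y = np.asarray(Y)
    if Y.ndim != 2:
        raise ValueError("Y must be a 2-D indicator matrix")
    if not np.isin(Y, (0, 1)).all():
        raise ValueError("Y must be binary")
    Y = Y.astype(int)
    n, L = Y.shape
    const = [a for a in range(L) if Y[:, a].min() == Y[:, a].max()]
    if const:
        warnings.warn(
            f"label columns {const} are constant; their correlation entries are 0",
            stacklevel=2,
        )
    M = np.zeros((L, L))
    for a in range(L):
        pa = Y[:, a].mean()
        M[a, a] = entropy([pa, 1.0 - pa])
        for b in range(a + 1, L):
            M[a, b] = M[b, a] = information_gain(
                DiscreteJoint.from_indicators(Y[:, a], Y[:, b])
            )
    return M
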