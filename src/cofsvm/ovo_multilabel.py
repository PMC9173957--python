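"""One-vs-one multilabel decomposition with mixed-class machines.

A ``z``-label problem is decomposed into the ``z (z - 1) / 2`` ordered label
pairs ``(w, t)``.  Within a pair, every training sample takes one of three
roles: +1 (carries label ``w`` only), -1 (carries ``t`` only), 0 (carries
both — a *mixed* sample) or it is excluded (carries neither).  Mixed samples
are constrained to the margin band: the machine seeks

    f(i) = m . i + h     with
    m . i+ + h >= 1,  m . i- + h <= -1,  -1 <= m . i0 + h <= 1,

each constraint softened by a membership-weighted slack.  At evaluation time
the decision value is read three ways: ``f > 1`` positive, ``f < -1``
negative, and the closed band ``[-1, +1]`` mixed — a sample in the band is
claimed by both labels of the pair.

Votes are aggregated per label (a mixed outcome contributes half a vote to
each side); labels reaching ``theta * (z - 1)`` votes enter the predicted
set, with the top-voted label always emitted so predictions are never empty.

:class:`ClusteredFuzzyOvoClassifier` chains the full pipeline: per-label
membership assignment, optional cluster-based pruning, one mixed-class
fuzzy SVM per label pair, three-way voting.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._qp import solve_svm_dual
from .fcm import _as_matrix
from .fsvm import MembershipStrategy, assign_memberships
from .info_gain import label_correlation_matrix
from .kernel_fcm import KernelSpec, cross_gram, gram_matrix
from .pruning import PruningConfig, prune_multiclass

__all__ = [
    "SubproblemSpec",
    "MixedFSVMModel",
    "decompose",
    "fit_mixed_subproblem",
    "three_way_decision",
    "aggregate",
    "ClusteredFuzzyOvoClassifier",
    "validate_multilabel",
]

POSITIVE = "positive"
MIXED = "mixed"
NEGATIVE = "negative"


def validate_multilabel(Y) -> np.ndarray:
    """Check an ``n x z`` indicator matrix: binary entries, every sample
    carrying at least one label."""
    Y = np.asarray(Y)
    if Y.ndim != 2:
        raise ValueError("Y must be a 2-D indicator matrix")
    if not np.isin(Y, (0, 1)).all():
        raise ValueError("Y must be binary")
    Y = Y.astype(int)
    if np.any(Y.sum(axis=1) < 1):
        raise ValueError("every sample must carry at least one label")
    return Y


@dataclass
class SubproblemSpec:
    """One label pair and the role of every participating sample.

    ``sample_indices`` are indices into the full training set;
    ``roles`` aligns with them (+1 label ``w`` only, -1 label ``t`` only,
    0 both).  Samples with neither label are excluded and do not appear.
    """

    pair: tuple[int, int]
    sample_indices: np.ndarray
    roles: np.ndarray

    def __post_init__(self) -> None:
        w, t = self.pair
        if not w < t:
            raise ValueError("pair must be ordered (w < t)")
        self.sample_indices = np.asarray(self.sample_indices, dtype=int).ravel()
        self.roles = np.asarray(self.roles, dtype=int).ravel()
        if self.sample_indices.shape != self.roles.shape:
            raise ValueError("sample_indices and roles must align")


def decompose(Y, correlation: np.ndarray | None = None) -> list[SubproblemSpec]:
    """All ``z (z - 1) / 2`` pairwise subproblems, lexicographic by pair.

    If ``correlation`` (a symmetric label-correlation matrix) is given, the
    list is reordered by descending pairwise correlation so the most
    entangled label pairs are handled first.
    """
    Y = validate_multilabel(Y)
    z = Y.shape[1]
    if z < 2:
        raise ValueError("need at least 2 labels")
    specs = []
    for w in range(z):
        for t in range(w + 1, z):
            has_w = Y[:, w] == 1
            has_t = Y[:, t] == 1
            included = has_w | has_t
            idx = np.flatnonzero(included)
            roles = np.where(
                has_w[idx] & has_t[idx], 0, np.where(has_w[idx], 1, -1)
            )
            specs.append(SubproblemSpec(pair=(w, t), sample_indices=idx, roles=roles))
    if correlation is not None:
        corr = np.asarray(correlation, dtype=float)
        specs.sort(key=lambda s: -corr[s.pair[0], s.pair[1]])
    return specs


@dataclass
class MixedFSVMModel:
    """A trained mixed-class fuzzy SVM for one label pair.

    The decision function is ``f(i) = sum_x beta_x Z(i, i_x) + h`` over the
    training samples of the subproblem; mixed samples contribute through two
    band constraints whose dual coefficients are folded into ``beta``.
    """

    pair: tuple[int, int]
    samples: np.ndarray
    beta: np.ndarray
    offset: float
    kernel: KernelSpec
    penalty: float
    roles: np.ndarray
    memberships: np.ndarray
    # per-constraint dual detail, kept for KKT / objective diagnostics
    constraint_alpha: np.ndarray = field(repr=False, default=None)
    constraint_signs: np.ndarray = field(repr=False, default=None)
    constraint_targets: np.ndarray = field(repr=False, default=None)
    constraint_caps: np.ndarray = field(repr=False, default=None)
    constraint_sample: np.ndarray = field(repr=False, default=None)

    def decision(self, x) -> np.ndarray | float:
        x = np.asarray(x, dtype=float)
        single = x.ndim == 1
        X = np.atleast_2d(x)
        vals = cross_gram(X, self.samples, self.kernel) @ self.beta + self.offset
        return float(vals[0]) if single else vals

    def primal_objective(self) -> float:
        """``1/2 ||m||^2`` plus the membership-weighted slack total, with the
        slacks read off the training decision values."""
        K = gram_matrix(self.samples, self.kernel)
        reg = 0.5 * float(self.beta @ K @ self.beta)
        f = K @ self.beta + self.offset
        mu = self.memberships
        slack = np.zeros_like(f)
        pos = self.roles == 1
        neg = self.roles == -1
        mix = self.roles == 0
        slack[pos] = np.maximum(0.0, 1.0 - f[pos])
        slack[neg] = np.maximum(0.0, f[neg] + 1.0)
        slack[mix] = np.maximum(0.0, f[mix] - 1.0) + np.maximum(0.0, -1.0 - f[mix])
        return reg + self.penalty * float(np.sum(mu * slack))

    def to_dict(self) -> dict:
        return {
            "pair": list(self.pair),
            "samples": self.samples.tolist(),
            "beta": self.beta.tolist(),
            "offset": self.offset,
            "kernel": self.kernel.to_dict(),
            "penalty": self.penalty,
            "roles": self.roles.tolist(),
            "memberships": self.memberships.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MixedFSVMModel":
        return cls(
            pair=tuple(d["pair"]),
            samples=np.asarray(d["samples"], dtype=float),
            beta=np.asarray(d["beta"], dtype=float),
            offset=float(d["offset"]),
            kernel=KernelSpec.from_dict(d["kernel"]),
            penalty=float(d["penalty"]),
            roles=np.asarray(d["roles"], dtype=int),
            memberships=np.asarray(d["memberships"], dtype=float),
        )


def fit_mixed_subproblem(
    X,
    spec: SubproblemSpec,
    memberships,
    penalty: float = 1.0,
    kernel: KernelSpec | None = None,
    tol: float = 1e-8,
) -> MixedFSVMModel:
    """Train the mixed-class machine of one label pair.

    ``memberships`` aligns with the full sample matrix ``X``.  Each positive
    or negative sample contributes one margin constraint with target 1; each
    mixed sample contributes the two band constraints (targets -1, signs
    +1 and -1).  The resulting dual is the standard template of
    :mod:`cofsvm._qp` with per-constraint caps ``mu * penalty``; with no
    mixed samples the problem is exactly the binary fuzzy SVM.
    """
    X = _as_matrix(X)
    memberships = np.asarray(memberships, dtype=float).ravel()
    if memberships.shape[0] != X.shape[0]:
        raise ValueError("memberships must align with X")
    if penalty <= 0:
        raise ValueError("penalty must be positive")
    roles = spec.roles
    if not (roles == 1).any() or not (roles == -1).any():
        raise ValueError("subproblem needs at least one positive and one negative sample")

    Xs = X[spec.sample_indices]
    mus = memberships[spec.sample_indices]
    kernel = (kernel or KernelSpec()).resolve(Xs)

    # constraint expansion: sample index, sign, target
    samp, signs, targets = [], [], []
    for local, role in enumerate(roles):
        if role == 1:
            samp.append(local); signs.append(1.0); targets.append(1.0)
        elif role == -1:
            samp.append(local); signs.append(-1.0); targets.append(1.0)
        else:
            samp.append(local); signs.append(1.0); targets.append(-1.0)
            samp.append(local); signs.append(-1.0); targets.append(-1.0)
    samp = np.asarray(samp, dtype=int)
    signs = np.asarray(signs)
    targets = np.asarray(targets)
    caps = mus[samp] * penalty

    K = gram_matrix(Xs, kernel)
    Kexp = K[np.ix_(samp, samp)]
    sol = solve_svm_dual(Kexp, signs, targets, caps, tol=tol)
    if not sol.converged:  # pragma: no cover
        raise RuntimeError(f"dual solver did not converge (gap={sol.gap:.3e})")
    beta = np.bincount(samp, weights=sol.alpha * signs, minlength=len(Xs))

    return MixedFSVMModel(
        pair=spec.pair,
        samples=Xs.copy(),
        beta=beta,
        offset=sol.offset,
        kernel=kernel,
        penalty=penalty,
        roles=roles.copy(),
        memberships=mus.copy(),
        constraint_alpha=sol.alpha,
        constraint_signs=signs,
        constraint_targets=targets,
        constraint_caps=caps,
        constraint_sample=samp,
    )


def three_way_decision(f):
    """Map a decision value to 'positive' (f > 1), 'mixed' (-1 <= f <= 1,
    boundaries inclusive) or 'negative' (f < -1)."""
    f = np.asarray(f, dtype=float)
    out = np.where(f > 1.0, POSITIVE, np.where(f < -1.0, NEGATIVE, MIXED))
    return str(out[()]) if out.ndim == 0 else out


def aggregate(outcomes, z: int, theta: float = 0.5) -> np.ndarray:
    """Combine per-pair outcomes for one sample into a predicted label set.

    ``outcomes`` maps each ordered pair ``(w, t)`` to one of the three-way
    outcomes; all ``z (z - 1) / 2`` pairs must be present.  Each pair adds a
    full vote to its winning label, or half a vote to each label on a mixed
    outcome.  Labels with at least ``theta * (z - 1)`` votes are predicted;
    the top-voted label is always included (ties break to the lowest index).
    Returns a length-``z`` indicator vector.
    """
    outcomes = dict(outcomes)
    expected = {(w, t) for w in range(z) for t in range(w + 1, z)}
    if set(outcomes) != expected:
        missing = expected - set(outcomes)
        raise ValueError(f"incomplete outcome set; missing pairs {sorted(missing)[:3]}")
    votes = np.zeros(z)
    for (w, t), o in outcomes.items():
        if o == POSITIVE:
            votes[w] += 1.0
        elif o == NEGATIVE:
            votes[t] += 1.0
        elif o == MIXED:
            votes[w] += 0.5
            votes[t] += 0.5
        else:
            raise ValueError(f"unknown outcome {o!r}")
    pred = (votes >= theta * (z - 1)).astype(int)
    pred[int(votes.argmax())] = 1
    return pred


class ClusteredFuzzyOvoClassifier:
    """End-to-end multilabel classifier: memberships, pruning, pairwise
    mixed-class fuzzy SVMs, three-way voting.

    Parameters
    ----------
    penalty:
        Slack penalty of every pairwise machine.
    kernel:
        Kernel shared by the machines.  The default is linear: the
        three-way band reads decision values as distances from the
        separator, which a linear kernel provides globally; strongly local
        kernels (rbf) saturate toward the offset far from the training data
        and would misread deep-interior points as mixed.
    membership:
        Strategy used to grade training points per label class.  Mixed
        samples of a pair are graded within their own group (they form
        their own cluster between the two classes; grading them against
        either single-label class centre would spuriously mark them as
        outliers).
    prune:
        Whether to run the cluster-based reduction on single-label samples
        before training (mixed samples are never pruned).
    pruning:
        Pruning configuration (ignored when ``prune`` is False).
    theta:
        Vote-fraction threshold of :func:`aggregate`.  Votes are quantised
        in half-vote steps, so thresholds between quantisation points pick
        the next step up.  The default 0.75 demands clear majorities: at
        1/2 the threshold collides with the vote total an uninvolved label
        collects from all-mixed outcomes (half a vote per pair), admitting
        spurious third labels on dual-labelled points, and at exactly 2/3
        (for four labels) a label scraping together one full vote plus two
        halves still enters the set.
    order_by_correlation:
        Order the subproblem list by descending label correlation.
    seed:
        Seed forwarded to the clustering stages.
    """

    def __init__(
        self,
        penalty: float = 1.0,
        kernel: KernelSpec | None = None,
        membership: MembershipStrategy | None = None,
        prune: bool = True,
        pruning: PruningConfig | None = None,
        theta: float = 0.75,
        order_by_correlation: bool = False,
        seed: int = 0,
    ) -> None:
        self.penalty = penalty
        self.kernel = kernel or KernelSpec("linear")
        self.membership = membership or MembershipStrategy()
        self.prune = prune
        if pruning is None:
            from .kernel_fcm import KFCMConfig

            pruning = PruningConfig(kfcm=KFCMConfig(n_clusters=2, kernel=self.kernel))
        self.pruning = pruning
        self.theta = theta
        self.order_by_correlation = order_by_correlation
        self.seed = seed
        self.models_: list[MixedFSVMModel] | None = None
        self.label_correlation_: np.ndarray | None = None
        self.pruning_audit_ = None
        self.n_labels_: int | None = None

    def fit(self, X, Y) -> "ClusteredFuzzyOvoClassifier":
        X = _as_matrix(X)
        Y = validate_multilabel(Y)
        z = Y.shape[1]
        if z < 2:
            raise ValueError("need at least 2 labels")
        self.n_labels_ = z
        self.label_correlation_ = label_correlation_matrix(Y)

        # per-label memberships: each label class graded independently
        mu_label = np.ones((z, X.shape[0]))
        for c in range(z):
            members = np.flatnonzero(Y[:, c] == 1)
            if members.size:
                marks = np.zeros(members.size, dtype=int)
                mu_label[c, members] = assign_memberships(
                    X[members], marks, self.membership
                )

        dropped = np.zeros(X.shape[0], dtype=bool)
        self.pruning_audit_ = None
        if self.prune:
            single = Y.sum(axis=1) == 1
            if single.any():
                import dataclasses as _dc

                cfg = _dc.replace(
                    self.pruning,
                    kfcm=_dc.replace(self.pruning.kfcm, seed=self.seed),
                )
                sidx = np.flatnonzero(single)
                keep, mu_p, audit = prune_multiclass(
                    X[sidx], Y[sidx].argmax(axis=1), cfg
                )
                dropped[sidx[~keep]] = True
                self.pruning_audit_ = audit
                if self.membership.kind == "kfcm-partition":
                    lbl = Y[sidx].argmax(axis=1)
                    for c in range(z):
                        m = lbl == c
                        mu_label[c, sidx[m]] = np.maximum(mu_p[m], 1e-6)

        corr = self.label_correlation_ if self.order_by_correlation else None
        specs = decompose(Y, correlation=corr)
        models = []
        for spec in specs:
            w, t = spec.pair
            live = ~dropped[spec.sample_indices] | (spec.roles == 0)
            sub = SubproblemSpec(
                pair=spec.pair,
                sample_indices=spec.sample_indices[live],
                roles=spec.roles[live],
            )
            mu = np.ones(X.shape[0])
            idx, roles = sub.sample_indices, sub.roles
            mu[idx[roles == 1]] = mu_label[w, idx[roles == 1]]
            mu[idx[roles == -1]] = mu_label[t, idx[roles == -1]]
            both = idx[roles == 0]
            if both.size > 1:
                mu[both] = assign_memberships(
                    X[both], np.zeros(both.size, dtype=int), self.membership
                )
            else:
                mu[both] = 0.5 * (mu_label[w, both] + mu_label[t, both])
            models.append(
                fit_mixed_subproblem(X, sub, mu, self.penalty, self.kernel)
            )
        self.models_ = models
        return self

    def _check_fitted(self) -> None:
        if self.models_ is None:
            raise RuntimeError("classifier is not fitted")

    def decision_matrix(self, X) -> np.ndarray:
        """``n x n_pairs`` raw decision values, pair order as fitted."""
        self._check_fitted()
        X = _as_matrix(X)
        return np.column_stack([m.decision(X) for m in self.models_])

    @property
    def pairs_(self) -> list[tuple[int, int]]:
        self._check_fitted()
        return [m.pair for m in self.models_]

    def predict(self, X) -> np.ndarray:
        """Predicted ``n x z`` indicator matrix."""
        self._check_fitted()
        F = self.decision_matrix(X)
        z = self.n_labels_
        preds = np.zeros((F.shape[0], z), dtype=int)
        pairs = self.pairs_
        for i in range(F.shape[0]):
            outcomes = {
                pair: three_way_decision(F[i, k]) for k, pair in enumerate(pairs)
            }
            preds[i] = aggregate(outcomes, z, self.theta)
        return preds
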