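"""Cluster-based training-set reduction.

Support vectors live on the boundary of the class-conditional feature
distributions; samples deep inside a well-separated class cannot become
support vectors and only inflate the QP.  This module runs kernel fuzzy
C-means within each class, flags samples whose dominant cluster membership
reaches a core threshold ``tau`` as *interior*, and drops an interior sample
only if it is also clearly outside the margin region: its kernel distance to
the nearest other-class centre must exceed both the class's own radius
(protects overlapping classes) and the class's closest approach to that
enemy plus one class spread (protects the margin-facing rim, where the
support vectors of well-separated classes live).  Survivors carry their
dominant-cluster membership onward, ready to feed the fuzzy SVM's
``kfcm-partition`` membership strategy.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field

import numpy as np

from .fcm import _as_matrix
from .fsvm import FuzzyTrainingSet
from .kernel_fcm import KFCMConfig, center_sqdist, kfcm_fit

__all__ = [
    "PruningConfig",
    "PruningAudit",
    "classify_samples",
    "prune_multiclass",
    "prune_training_set",
]


@dataclass(frozen=True)
class PruningConfig:
    """Settings for the pruning pass.

    ``core_threshold`` (tau) is the dominant-membership level above which a
    sample counts as interior; soft partitions never reach exactly 1, so a
    value below 1 is required for any pruning to happen at all.  ``kfcm``
    configures the per-class clustering (``n_clusters`` per class);
    ``keep_min_per_class`` is a hard floor on survivors per class.
    """

    core_threshold: float = 0.95
    kfcm: KFCMConfig = field(default_factory=lambda: KFCMConfig(n_clusters=2))
    keep_min_per_class: int = 3

    def __post_init__(self) -> None:
        if not (0.0 < self.core_threshold <= 1.0):
            raise ValueError("core_threshold must lie in (0, 1]")
        if self.keep_min_per_class < 1:
            raise ValueError("keep_min_per_class must be >= 1")


@dataclass
class PruningAudit:
    """Reproducibility record of a pruning pass."""

    kept_indices: np.ndarray
    dropped_indices: np.ndarray
    memberships: np.ndarray  # dominant-cluster membership, every sample
    interior: np.ndarray  # boolean flag, every sample
    class_radius: dict
    core_threshold: float

    @property
    def drop_fraction(self) -> float:
        n = len(self.kept_indices) + len(self.dropped_indices)
        return len(self.dropped_indices) / n if n else 0.0

    def to_dict(self) -> dict:
        return {
            "kept_indices": self.kept_indices.tolist(),
            "dropped_indices": self.dropped_indices.tolist(),
            "memberships": self.memberships.tolist(),
            "interior": self.interior.astype(bool).tolist(),
            "class_radius": {str(k): v for k, v in self.class_radius.items()},
            "core_threshold": self.core_threshold,
            "drop_fraction": self.drop_fraction,
        }


def classify_samples(U, core_threshold: float) -> np.ndarray:
    """Boolean flag per sample: True = interior (dominant membership >= tau),
    False = boundary."""
    U = np.asarray(U, dtype=float)
    return U.max(axis=0) >= core_threshold


def prune_multiclass(X, labels, cfg: PruningConfig):
    """Pruning decision for an arbitrarily labelled sample set.

    Returns ``(keep_mask, memberships, audit)`` where ``keep_mask`` is a
    boolean array over samples and ``memberships`` the dominant-cluster
    membership of every sample from its own class's clustering.  Classes
    smaller than ``keep_min_per_class`` (or than the cluster count) are kept
    whole with a warning.
    """
    X = _as_matrix(X)
    labels = np.asarray(labels).ravel()
    if labels.shape[0] != X.shape[0]:
        raise ValueError("X and labels must align")
    n = X.shape[0]
    classes = np.unique(labels)
    keep = np.ones(n, dtype=bool)
    mu = np.ones(n)
    interior = np.zeros(n, dtype=bool)
    fits = {}
    radius = {}
    spread = {}

    for ci, cls in enumerate(classes):
        idx = np.flatnonzero(labels == cls)
        if idx.size < max(cfg.keep_min_per_class, cfg.kfcm.n_clusters, 2):
            warnings.warn(
                f"class {cls!r} has only {idx.size} samples; kept whole",
                stacklevel=2,
            )
            continue
        sub_cfg = dataclasses.replace(cfg.kfcm, seed=cfg.kfcm.seed + ci)
        res = kfcm_fit(X[idx], sub_cfg)
        fits[cls] = (idx, res)
        mu[idx] = res.partition.max(axis=0)
        interior[idx] = classify_samples(res.partition, cfg.core_threshold)
        own_d = np.sqrt(center_sqdist(X[idx], X[idx], res.weights, res.kernel).min(axis=1))
        radius[cls] = float(own_d.max())
        spread[cls] = float(own_d.mean())

    for cls, (idx, res) in fits.items():
        flags = interior[idx]
        if not flags.any():
            continue
        # nearest other-class centre, kernel distance
        other_d = np.full(idx.size, np.inf)
        for ocls, (oidx, ores) in fits.items():
            if ocls == cls:
                continue
            d = center_sqdist(X[idx], X[oidx], ores.weights, ores.kernel).min(axis=1)
            other_d = np.minimum(other_d, d)
        other_d = np.sqrt(other_d)
        # margin guard: a dropped sample must sit beyond the class radius
        # AND beyond the class's closest approach to the enemy by more than
        # one class spread (support vectors live on that approach rim)
        guard = max(radius[cls], float(other_d.min()) + spread[cls])
        drop = flags & (other_d > guard)
        kept_count = idx.size - int(drop.sum())
        if kept_count < cfg.keep_min_per_class:
            # restore the most boundary-like dropped samples first
            restore_order = np.argsort(mu[idx])
            for r in restore_order:
                if kept_count >= cfg.keep_min_per_class:
                    break
                if drop[r]:
                    drop[r] = False
                    kept_count += 1
        keep[idx[drop]] = False

    audit = PruningAudit(
        kept_indices=np.flatnonzero(keep),
        dropped_indices=np.flatnonzero(~keep),
        memberships=mu,
        interior=interior,
        class_radius=radius,
        core_threshold=cfg.core_threshold,
    )
    return keep, mu, audit


def prune_training_set(X, y, cfg: PruningConfig):
    """Reduce a binary training set before fuzzy-SVM training.

    ``y`` holds roles in {-1, +1}.  Returns the reduced
    :class:`~cofsvm.fsvm.FuzzyTrainingSet` (survivors with their
    dominant-cluster memberships) and the :class:`PruningAudit`.
    """
    X = _as_matrix(X)
    y = np.asarray(y, dtype=int).ravel()
    if not np.isin(y, (-1, 1)).all():
        raise ValueError("roles must lie in {-1, +1}")
    keep, mu, audit = prune_multiclass(X, y, cfg)
    reduced = FuzzyTrainingSet(
        samples=X[keep].copy(),
        roles=y[keep].copy(),
        memberships=mu[keep].copy(),
    )
    return reduced, audit
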