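"""Synthetic multilabel benchmark generator and evaluation harness.

Motion-feature datasets of the kind the classifier targets are tables of
real-valued feature vectors (one row per frame or clip) with one or more of
``z`` action labels per row.  The generator emulates exactly the structure
the method's stages assume, with ground truth recorded for every nuisance:

* ``z`` Gaussian modes in ``d`` dimensions, placed as a regular simplex with
  mutual distance ``class_separation`` (in units of the within-mode sigma);
* a fraction of *dual-labelled* samples drawn at the midpoint between a
  random mode pair and marked with both labels — these populate the
  three-way decision band;
* a fraction of *noise points*: clean single-label draws whose label is
  flipped to a random other label, emulating annotation noise.

The evaluation harness mirrors confusion-matrix reporting: a per-class
confusion matrix whose rows sum to the per-class truth counts, subset
accuracy (exact label-set match) and per-label accuracy.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .fcm import _as_matrix

__all__ = ["GeneratorSpec", "SyntheticDataset", "MetricsRecord", "generate", "evaluate"]

#: feature-vector lengths typical of frame-descriptor sweeps
FEATURE_LENGTH_PROFILE = (16, 64, 144, 256, 400, 576, 784, 1024)


@dataclass(frozen=True)
class GeneratorSpec:
    """Generator settings.

    Defaults describe the standard study condition used throughout the test
    suite: 800 samples, 16 features, 4 labels, mode separation 6 sigma,
    10% dual-labelled samples, 5% flipped-label noise.
    """

    n_samples: int = 800
    n_features: int = 16
    n_labels: int = 4
    class_separation: float = 6.0
    dual_label_fraction: float = 0.10
    noise_fraction: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        if self.n_labels < 2:
            raise ValueError("n_labels must be >= 2")
        if self.n_features < self.n_labels:
            raise ValueError("n_features must be >= n_labels (simplex placement)")
        if not (0.0 <= self.dual_label_fraction < 1.0):
            raise ValueError("dual_label_fraction must lie in [0, 1)")
        if not (0.0 <= self.noise_fraction < 0.5):
            raise ValueError("noise_fraction must lie in [0, 0.5)")
        if self.class_separation <= 0:
            raise ValueError("class_separation must be positive")


@dataclass
class SyntheticDataset:
    """Features, observed labels and the full truth record."""

    X: np.ndarray
    Y: np.ndarray  # observed indicators (after label flips)
    true_labels: np.ndarray  # pre-flip indicators
    modes: np.ndarray  # per-sample primary mode (dual: first of the pair)
    noise_mask: np.ndarray
    dual_mask: np.ndarray
    mode_means: np.ndarray

    def truth_dict(self) -> dict:
        return {
            "true_labels": self.true_labels.tolist(),
            "modes": self.modes.tolist(),
            "noise_mask": self.noise_mask.astype(bool).tolist(),
            "dual_mask": self.dual_mask.astype(bool).tolist(),
            "mode_means": self.mode_means.tolist(),
        }


def _simplex_means(z: int, d: int, separation: float) -> np.ndarray:
    """z mode means, mutually ``separation`` apart: scaled standard basis
    vectors (||a e_i - a e_j|| = a sqrt(2))."""
    means = np.zeros((z, d))
    means[np.arange(z), np.arange(z)] = separation / np.sqrt(2.0)
    return means


def generate(spec: GeneratorSpec) -> SyntheticDataset:
    """Draw a dataset under the spec; deterministic for a fixed seed.

    Exactly ``floor(dual_label_fraction * n)`` rows carry two labels and
    exactly ``floor(noise_fraction * n)`` single-label rows have a flipped
    label.  Within-mode covariance is the identity (sigma = 1), so
    ``class_separation`` is directly in sigma units.
    """
    rng = np.random.default_rng(spec.seed)
    n, d, z = spec.n_samples, spec.n_features, spec.n_labels
    means = _simplex_means(z, d, spec.class_separation)

    n_dual = int(np.floor(spec.dual_label_fraction * n))
    n_single = n - n_dual
    n_noise = int(np.floor(spec.noise_fraction * n))
    if n_noise > n_single:
        raise ValueError("noise_fraction leaves too few single-label samples")

    X = np.empty((n, d))
    Y = np.zeros((n, z), dtype=int)
    modes = np.empty(n, dtype=int)
    dual_mask = np.zeros(n, dtype=bool)

    # dual-labelled rows: midpoint of a random mode pair
    pairs = [(a, b) for a in range(z) for b in range(a + 1, z)]
    for i in range(n_dual):
        a, b = pairs[rng.integers(len(pairs))]
        X[i] = 0.5 * (means[a] + means[b]) + rng.standard_normal(d)
        Y[i, a] = Y[i, b] = 1
        modes[i] = a
        dual_mask[i] = True
    # single-label rows
    single_modes = rng.integers(z, size=n_single)
    X[n_dual:] = means[single_modes] + rng.standard_normal((n_single, d))
    Y[np.arange(n_dual, n), single_modes] = 1
    modes[n_dual:] = single_modes

    true_labels = Y.copy()
    # flip labels on a random subset of the single-label rows
    noise_mask = np.zeros(n, dtype=bool)
    flip_rows = rng.choice(np.arange(n_dual, n), size=n_noise, replace=False)
    for i in flip_rows:
        old = int(Y[i].argmax())
        new = int(rng.choice([c for c in range(z) if c != old]))
        Y[i, old] = 0
        Y[i, new] = 1
        noise_mask[i] = True

    perm = rng.permutation(n)
    return SyntheticDataset(
        X=X[perm],
        Y=Y[perm],
        true_labels=true_labels[perm],
        modes=modes[perm],
        noise_mask=noise_mask[perm],
        dual_mask=dual_mask[perm],
        mode_means=means,
    )


@dataclass
class MetricsRecord:
    """Evaluation summary of a multilabel prediction."""

    confusion: np.ndarray
    subset_accuracy: float
    per_label_accuracy: np.ndarray
    class_counts: np.ndarray

    def to_dict(self) -> dict:
        return {
            "confusion": self.confusion.tolist(),
            "subset_accuracy": self.subset_accuracy,
            "per_label_accuracy": self.per_label_accuracy.tolist(),
            "class_counts": self.class_counts.tolist(),
        }


def evaluate(predictions, truth) -> MetricsRecord:
    """Score predicted indicators against reference indicators.

    The confusion matrix is per reference label: for each sample and each
    label it truly carries, a correct prediction (label present in the
    predicted set) lands on the diagonal, otherwise the count goes to the
    sample's top-voted predicted label.  Rows therefore sum to the per-class
    truth counts.  Subset accuracy requires the exact label set.
    """
    P = _as_matrix(np.asarray(predictions, dtype=float), "predictions").astype(int)
    T = _as_matrix(np.asarray(truth, dtype=float), "truth").astype(int)
    if P.shape != T.shape:
        raise ValueError(f"shape mismatch: predictions {P.shape} vs truth {T.shape}")
    n, z = T.shape
    confusion = np.zeros((z, z), dtype=int)
    for i in range(n):
        top_pred = int(P[i].argmax()) if P[i].any() else 0
        for c in np.flatnonzero(T[i]):
            confusion[c, c if P[i, c] == 1 else top_pred] += 1
    subset = float(np.mean((P == T).all(axis=1)))
    per_label = (P == T).mean(axis=0)
    return MetricsRecord(
        confusion=confusion,
        subset_accuracy=subset,
        per_label_accuracy=per_label,
        class_counts=T.sum(axis=0),
    )
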