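"""Permutation feature importance over the ten EMG features, and top-k selection.

Importance of a feature is the drop in held-out accuracy when that feature's
values are shuffled across trials, relative to the unpermuted baseline. The
permutation unit is the whole-trial block of that feature (all windows and all
channels together), so the within-trial temporal structure the sequence
classifier relies on is preserved — only the association between the feature
and the label is destroyed. Each feature is permuted ``n_repeats`` times and
the permuted accuracies averaged; a feature that carries no label information
has importance near zero, a load-bearing feature has a large positive one.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import train_test_split

from .classifier import SequenceSample

__all__ = ["ImportanceReport", "permutation_importance", "select_features"]


@dataclass
class ImportanceReport:
    """Baseline accuracy plus per-feature permuted accuracy and importance."""

    feature_names: tuple[str, ...]
    baseline_accuracy: float
    permuted_accuracy: dict[str, float]
    permuted_accuracy_sd: dict[str, float]
    n_repeats: int
    seed: int

    @property
    def importance(self) -> dict[str, float]:
        # Exactly baseline - permuted, by construction.
        return {f: self.baseline_accuracy - self.permuted_accuracy[f] for f in self.feature_names}

    def standard_error(self, feature: str) -> float:
        return self.permuted_accuracy_sd[feature] / np.sqrt(max(self.n_repeats, 1))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "feature": list(self.feature_names),
                "permuted_accuracy": [self.permuted_accuracy[f] for f in self.feature_names],
                "importance": [self.importance[f] for f in self.feature_names],
            }
        )


def _to_sequences(values: np.ndarray, labels: np.ndarray) -> list[SequenceSample]:
    return [
        SequenceSample(v.reshape(v.shape[0], -1), int(y)) for v, y in zip(values, labels)
    ]


def permutation_importance(
    classifier_factory: Callable[[], object],
    features: np.ndarray,
    labels: Sequence[int],
    feature_names: Sequence[str],
    n_repeats: int = 10,
    seed: int = 0,
    test_fraction: float = 0.2,
) -> ImportanceReport:
    """Permutation importance with an 80/20 stratified split.

    Parameters
    ----------
    classifier_factory : zero-argument callable returning an unfitted
        classifier with ``fit``/``predict`` over sequence samples
    features : array (n_trials, n_windows, n_channels, n_features)
    labels : per-trial class labels (at least two classes)
    feature_names : names aligned with the last axis of ``features``
    n_repeats : permutations per feature, averaged
    seed : drives the split and every permutation; results are reproducible
        bit-for-bit under a fixed seed
    """
    features = np.asarray(features, dtype=float)
    if features.ndim != 4:
        raise ValueError("features must be (n_trials, n_windows, n_channels, n_features)")
    if features.shape[3] != len(feature_names):
        raise ValueError("feature_names must align with the last axis")
    labels = np.asarray(labels, dtype=int)
    if np.unique(labels).size < 2:
        raise ValueError("need at least 2 classes")
    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")

    rng = np.random.default_rng(seed)
    idx_train, idx_test = train_test_split(
        np.arange(len(labels)),
        test_size=test_fraction,
        stratify=labels,
        random_state=int(rng.integers(0, 2**31 - 1)),
    )
    clf = classifier_factory()
    clf.fit(_to_sequences(features[idx_train], labels[idx_train]))
    test_values = features[idx_test]
    test_labels = labels[idx_test]
    baseline = float(
        np.mean(clf.predict(_to_sequences(test_values, test_labels)) == test_labels)
    )

    permuted_mean: dict[str, float] = {}
    permuted_sd: dict[str, float] = {}
    for k, name in enumerate(feature_names):
        accs = []
        for _ in range(n_repeats):
            perm = rng.permutation(len(test_labels))
            shuffled = test_values.copy()
            shuffled[:, :, :, k] = test_values[perm][:, :, :, k]
            pred = clf.predict(_to_sequences(shuffled, test_labels))
            accs.append(float(np.mean(pred == test_labels)))
        permuted_mean[name] = float(np.mean(accs))
        permuted_sd[name] = float(np.std(accs, ddof=1)) if n_repeats > 1 else 0.0
    return ImportanceReport(
        feature_names=tuple(feature_names),
        baseline_accuracy=baseline,
        permuted_accuracy=permuted_mean,
        permuted_accuracy_sd=permuted_sd,
        n_repeats=n_repeats,
        seed=seed,
    )


def select_features(report: ImportanceReport, k: int) -> tuple[str, ...]:
    """Top-k features by importance, descending; ties break by registry order."""
    if k <= 0:
        raise ValueError("k must be positive")
    if k > len(report.feature_names):
        raise ValueError(f"k={k} exceeds the {len(report.feature_names)} available features")
    order = {name: i for i, name in enumerate(report.feature_names)}
    imp = report.importance
    ranked = sorted(report.feature_names, key=lambda f: (-imp[f], order[f]))
    return tuple(ranked[:k])
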