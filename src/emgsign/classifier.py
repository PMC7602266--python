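"""Sequence classifiers and cross-user evaluation.

Two classifiers share one interface (``fit`` / ``predict`` / ``predict_proba``):

* :class:`LstmClassifier` — a single-layer long short-term memory network with
  a final-step softmax readout, trained full-batch with Adam and
  backpropagation through time. It is implemented directly in numpy, which
  keeps training bit-deterministic under a fixed seed.
* :class:`CentroidClassifier` — nearest class centroid on time-averaged
  sequences. Deterministic and training-free; it serves as the fast fallback
  so that cross-user comparisons do not depend on neural-network training
  variance.

Evaluation produces confusion matrices and per-motion / per-subject / overall
accuracies, and :func:`loso_cross_validate` runs the leave-one-subject-out
protocol: for each fold one subject is held out entirely, a bilinear model is
optionally fitted on the remaining subjects' stacked features, the held-out
subject is folded in through the closed-form adaptation from a designated
calibration motion, and the classifier is tested on the held-out subject's
remaining trials.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from . import bilinear as bl

__all__ = [
    "SequenceSample",
    "TrainConfig",
    "EvalResult",
    "LstmClassifier",
    "CentroidClassifier",
    "build_sequences",
    "make_classifier",
    "train",
    "predict",
    "evaluate",
    "loso_cross_validate",
    "LosoFold",
    "LosoResult",
]


@dataclass(frozen=True)
class SequenceSample:
    """One classifier input: an (n_steps x n_dims) sequence with its label."""

    sequence: np.ndarray
    label: int
    subject_id: str = ""

    def __post_init__(self) -> None:
        seq = np.atleast_2d(np.asarray(self.sequence, dtype=float))
        if seq.shape[0] < 1:
            raise ValueError("sequence needs at least one step")
        if not np.isfinite(seq).all():
            raise ValueError("sequence values must be finite")
        object.__setattr__(self, "sequence", seq)


@dataclass(frozen=True)
class TrainConfig:
    """LSTM training hyperparameters.

    The defaults mirror the operating point the pipeline was designed at: a
    learning rate of 1e-4 and 500 full-batch epochs (enough for the validation
    loss to level off), one LSTM layer with 64 hidden units.
    """

    learning_rate: float = 1e-4
    iterations: int = 500
    hidden_size: int = 64
    n_layers: int = 1
    batch_size: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")
        if self.hidden_size < 1:
            raise ValueError("hidden_size must be >= 1")
        if self.n_layers != 1:
            raise ValueError("only a single LSTM layer is supported")


def build_sequences(
    series_list: Sequence, vocabulary, selected_features: Sequence[str] | None = None
) -> list[SequenceSample]:
    """Turn per-trial feature series into classifier sequences (raw mode).

    The time axis is the sliding-window axis; dimensions are the flattened
    (channel, feature) pairs, optionally restricted to ``selected_features``.
    """
    samples = []
    dims = None
    for fs in series_list:
        values = fs.values
        if selected_features is not None:
            idx = [fs.feature_names.index(f) for f in selected_features]
            values = values[:, :, idx]
        seq = values.reshape(values.shape[0], -1)
        if dims is None:
            dims = seq.shape[1]
        elif seq.shape[1] != dims:
            raise ValueError("trials have inconsistent feature dimensions")
        samples.append(
            SequenceSample(seq, vocabulary.index(fs.motion_label), fs.subject_id)
        )
    return samples


def _stack(samples: Sequence[SequenceSample]) -> tuple[np.ndarray, np.ndarray]:
    lengths = {s.sequence.shape for s in samples}
    if len({shape for shape in lengths}) != 1:
        raise ValueError(f"sequences must share one shape, got {sorted(lengths)}")
    x = np.stack([s.sequence for s in samples])
    y = np.asarray([s.label for s in samples], dtype=int)
    return x, y


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class LstmClassifier:
    """Single-layer LSTM with final-step softmax readout (numpy, full batch).

    Gate order is (input, forget, cell, output); the forget-gate bias is
    initialized to +1, the standard trick that keeps early gradients flowing.
    Training aborts with a diagnostic if the loss turns non-finite.
    """

    def __init__(self, config: TrainConfig | None = None):
        self.config = config or TrainConfig()
        self.loss_history: list[float] = []
        self.n_classes: int | None = None
        self._params: dict[str, np.ndarray] | None = None

    # -- forward / backward -------------------------------------------------
    def _forward(self, x: np.ndarray):
        p = self._params
        b_sz, t_len, _ = x.shape
        h_dim = self.config.hidden_size
        h = np.zeros((b_sz, h_dim))
        c = np.zeros((b_sz, h_dim))
        cache = []
        for t in range(t_len):
            a = x[:, t] @ p["Wx"] + h @ p["Wh"] + p["b"]
            ai, af, ag, ao = np.split(a, 4, axis=1)
            i = 1 / (1 + np.exp(-ai))
            f = 1 / (1 + np.exp(-af))
            g = np.tanh(ag)
            o = 1 / (1 + np.exp(-ao))
            c_new = f * c + i * g
            h_new = o * np.tanh(c_new)
            cache.append((x[:, t], h, c, i, f, g, o, c_new))
            h, c = h_new, c_new
        logits = h @ p["Wy"] + p["by"]
        return logits, h, cache

    def _backward(self, x, y_onehot, logits, cache):
        p = self._params
        grads = {k: np.zeros_like(v) for k, v in p.items()}
        b_sz = x.shape[0]
        probs = _softmax(logits)
        dlogits = (probs - y_onehot) / b_sz
        h_last = cache[-1][6] * np.tanh(cache[-1][7])
        grads["Wy"] = h_last.T @ dlogits
        grads["by"] = dlogits.sum(axis=0)
        dh = dlogits @ p["Wy"].T
        dc = np.zeros_like(dh)
        for x_t, h_prev, c_prev, i, f, g, o, c_new in reversed(cache):
            tc = np.tanh(c_new)
            do = dh * tc
            dc = dc + dh * o * (1 - tc**2)
            di, dg, df = dc * g, dc * i, dc * c_prev
            da = np.concatenate(
                [di * i * (1 - i), df * f * (1 - f), dg * (1 - g**2), do * o * (1 - o)],
                axis=1,
            )
            grads["Wx"] += x_t.T @ da
            grads["Wh"] += h_prev.T @ da
            grads["b"] += da.sum(axis=0)
            dh = da @ p["Wh"].T
            dc = dc * f
        return grads

    # -- public API ---------------------------------------------------------
    def fit(self, samples: Sequence[SequenceSample]) -> "LstmClassifier":
        x, y = _stack(samples)
        classes = np.unique(y)
        if classes.size < 2:
            raise ValueError("training needs at least 2 classes")
        self.n_classes = int(classes.max()) + 1
        n_dims = x.shape[2]
        h = self.config.hidden_size
        rng = np.random.default_rng(self.config.seed)
        self._params = {
            "Wx": rng.standard_normal((n_dims, 4 * h)) / np.sqrt(n_dims),
            "Wh": rng.standard_normal((h, 4 * h)) / np.sqrt(h),
            "b": np.zeros(4 * h),
            "Wy": rng.standard_normal((h, self.n_classes)) / np.sqrt(h),
            "by": np.zeros(self.n_classes),
        }
        self._params["b"][h : 2 * h] = 1.0  # forget-gate bias
        onehot = np.eye(self.n_classes)[y]
        m = {k: np.zeros_like(v) for k, v in self._params.items()}
        v = {k: np.zeros_like(v_) for k, v_ in self._params.items()}
        beta1, beta2, eps = 0.9, 0.999, 1e-8
        lr = self.config.learning_rate
        batch = self.config.batch_size or x.shape[0]
        self.loss_history = []
        order = np.arange(x.shape[0])
        step = 0
        for epoch in range(self.config.iterations):
            if batch < x.shape[0]:
                rng.shuffle(order)
            epoch_loss = 0.0
            for start in range(0, x.shape[0], batch):
                idx = order[start : start + batch]
                logits, _, cache = self._forward(x[idx])
                probs = _softmax(logits)
                loss = -np.mean(
                    np.log(np.maximum(probs[np.arange(idx.size), y[idx]], 1e-300))
                )
                if not np.isfinite(loss):
                    raise FloatingPointError(
                        f"training diverged (non-finite loss at epoch {epoch}); "
                        "lower the learning rate"
                    )
                epoch_loss += loss * idx.size
                grads = self._backward(x[idx], onehot[idx], logits, cache)
                step += 1
                for k in self._params:
                    m[k] = beta1 * m[k] + (1 - beta1) * grads[k]
                    v[k] = beta2 * v[k] + (1 - beta2) * grads[k] ** 2
                    m_hat = m[k] / (1 - beta1**step)
                    v_hat = v[k] / (1 - beta2**step)
                    self._params[k] -= lr * m_hat / (np.sqrt(v_hat) + eps)
            self.loss_history.append(epoch_loss / x.shape[0])
        return self

    def predict_proba(self, samples: Sequence[SequenceSample]) -> np.ndarray:
        if self._params is None:
            raise RuntimeError("classifier is not fitted")
        x, _ = _stack(samples)
        logits, _, _ = self._forward(x)
        return _softmax(logits)

    def predict(self, samples: Sequence[SequenceSample]) -> np.ndarray:
        return np.argmax(self.predict_proba(samples), axis=1)


class CentroidClassifier:
    """Nearest class centroid on time-averaged sequences (deterministic)."""

    def __init__(self):
        self.centroids_: np.ndarray | None = None
        self.classes_: np.ndarray | None = None
        self.n_classes: int | None = None

    @staticmethod
    def _collapse(samples: Sequence[SequenceSample]) -> np.ndarray:
        return np.stack([s.sequence.mean(axis=0) for s in samples])

    def fit(self, samples: Sequence[SequenceSample]) -> "CentroidClassifier":
        x = self._collapse(samples)
        y = np.asarray([s.label for s in samples])
        self.classes_ = np.unique(y)
        if self.classes_.size < 2:
            raise ValueError("training needs at least 2 classes")
        self.n_classes = int(self.classes_.max()) + 1
        self.centroids_ = np.stack([x[y == k].mean(axis=0) for k in self.classes_])
        return self

    def predict_proba(self, samples: Sequence[SequenceSample]) -> np.ndarray:
        if self.centroids_ is None:
            raise RuntimeError("classifier is not fitted")
        x = self._collapse(samples)
        d2 = ((x[:, None, :] - self.centroids_[None, :, :]) ** 2).sum(axis=2)
        # Softmin over distances: a proper probability vector, argmax-consistent
        # with nearest centroid.
        logits = -d2
        logits -= logits.max(axis=1, keepdims=True)
        e = np.exp(logits)
        probs_compact = e / e.sum(axis=1, keepdims=True)
        probs = np.zeros((x.shape[0], self.n_classes))
        probs[:, self.classes_] = probs_compact
        return probs

    def predict(self, samples: Sequence[SequenceSample]) -> np.ndarray:
        if self.centroids_ is None:
            raise RuntimeError("classifier is not fitted")
        x = self._collapse(samples)
        d2 = ((x[:, None, :] - self.centroids_[None, :, :]) ** 2).sum(axis=2)
        return self.classes_[np.argmin(d2, axis=1)]


def make_classifier(kind: str = "lstm", train_config: TrainConfig | None = None):
    if kind == "lstm":
        return LstmClassifier(train_config)
    if kind == "centroid":
        return CentroidClassifier()
    raise ValueError(f"unknown classifier kind {kind!r}; use 'lstm' or 'centroid'")


def train(samples: Sequence[SequenceSample], config: TrainConfig | None = None) -> LstmClassifier:
    """Train the LSTM classifier; deterministic given the config seed."""
    return LstmClassifier(config).fit(samples)


def predict(classifier, samples: Sequence[SequenceSample]) -> tuple[np.ndarray, np.ndarray]:
    """Labels and class-probability scores (rows sum to 1)."""
    scores = classifier.predict_proba(samples)
    return classifier.predict(samples), scores


@dataclass
class EvalResult:
    """Confusion matrix plus per-motion, per-subject and overall accuracy."""

    confusion: np.ndarray
    label_names: tuple[str, ...]
    per_motion_accuracy: np.ndarray
    per_subject_accuracy: dict[str, float]
    overall_accuracy: float
    n_samples: int

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.confusion, index=self.label_names, columns=self.label_names)


def evaluate(
    classifier,
    samples: Sequence[SequenceSample],
    n_classes: int | None = None,
    label_names: Sequence[str] | None = None,
) -> EvalResult:
    """Evaluate predictions into a confusion matrix and accuracy breakdowns."""
    if not samples:
        raise ValueError("no samples to evaluate")
    y_true = np.asarray([s.label for s in samples])
    y_pred = classifier.predict(samples)
    return summarize_predictions(
        y_true, y_pred, [s.subject_id for s in samples], n_classes, label_names
    )


def summarize_predictions(
    y_true: np.ndarray,
    y_pred: np.ndarray,
    subjects: Sequence[str],
    n_classes: int | None = None,
    label_names: Sequence[str] | None = None,
) -> EvalResult:
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    k = n_classes or int(max(y_true.max(), y_pred.max())) + 1
    conf = np.zeros((k, k), dtype=int)
    np.add.at(conf, (y_true, y_pred), 1)
    row_sums = conf.sum(axis=1)
    with np.errstate(invalid="ignore"):
        per_motion = np.where(row_sums > 0, np.diag(conf) / np.maximum(row_sums, 1), np.nan)
    subjects = np.asarray(subjects)
    per_subject = {
        str(s): float(np.mean(y_true[subjects == s] == y_pred[subjects == s]))
        for s in dict.fromkeys(subjects.tolist())
    }
    names = tuple(label_names) if label_names is not None else tuple(f"M{i+1}" for i in range(k))
    return EvalResult(
        confusion=conf,
        label_names=names,
        per_motion_accuracy=per_motion,
        per_subject_accuracy=per_subject,
        overall_accuracy=float(np.mean(y_true == y_pred)),
        n_samples=int(y_true.size),
    )


# ---------------------------------------------------------------------------
# Leave-one-subject-out cross-validation
# ---------------------------------------------------------------------------


@dataclass
class LosoFold:
    subject: str
    result: EvalResult
    model: "bl.BilinearModel | None" = None
    adaptation: "bl.AdaptationResult | None" = None


@dataclass
class LosoResult:
    folds: list[LosoFold]
    aggregate: EvalResult

    @property
    def per_fold_accuracy(self) -> dict[str, float]:
        return {f.subject: f.result.overall_accuracy for f in self.folds}


@dataclass(frozen=True)
class _Trial:
    subject: str
    motion: int
    index: int
    seq: np.ndarray  # (T, C_blocks)


def _organize(
    sequences: Sequence[np.ndarray], labels: Sequence[int], subjects: Sequence[str]
) -> list[_Trial]:
    trials = [
        _Trial(str(s), int(m), i, np.atleast_2d(np.asarray(q, dtype=float)))
        for i, (q, m, s) in enumerate(zip(sequences, labels, subjects))
    ]
    shapes = {t.seq.shape for t in trials}
    if len({sh for sh in shapes}) != 1:
        raise ValueError(f"all trials must share one (T, C) shape, got {sorted(shapes)}")
    return trials


def _build_training_stack(
    trials: list[_Trial], train_subjects: list[str], n_motions: int
) -> tuple[bl.StackedMatrix, int, int]:
    """Stack training trials into the (C*U x M*N_eff) bilinear data matrix.

    Requires a balanced design: every training subject contributes the same
    number of trials of every motion. Columns are motion-major, then trial,
    then window; rows are channel-block-major, user-minor.
    """
    t_len, c_blocks = trials[0].seq.shape
    by_key: dict[tuple[str, int], list[_Trial]] = {}
    for t in trials:
        if t.subject in train_subjects:
            by_key.setdefault((t.subject, t.motion), []).append(t)
    counts = {len(v) for v in by_key.values()}
    if len(by_key) != len(train_subjects) * n_motions or len(counts) != 1:
        raise ValueError(
            "bilinear mode needs a balanced design: every training subject must "
            "have the same number of trials of every motion"
        )
    n_rep = counts.pop()
    n_eff = n_rep * t_len
    u = len(train_subjects)
    data = np.empty((c_blocks * u, n_motions * n_eff))
    for ui, subj in enumerate(train_subjects):
        for m in range(n_motions):
            reps = sorted(by_key[(subj, m)], key=lambda t: t.index)
            for n, trial in enumerate(reps):
                cols = slice(m * n_eff + n * t_len, m * n_eff + (n + 1) * t_len)
                for c in range(c_blocks):
                    data[c * u + ui, cols] = trial.seq[:, c]
    return bl.StackedMatrix(data, c_blocks), n_rep, n_eff


def _trial_columns(trial: _Trial) -> bl.StackedMatrix:
    """A single trial as a (C x T) one-user stacked matrix."""
    return bl.StackedMatrix(trial.seq.T.copy(), trial.seq.shape[1])


def loso_cross_validate(
    sequences: Sequence[np.ndarray],
    labels: Sequence[int],
    subjects: Sequence[str],
    *,
    n_motions: int,
    bilinear_enabled: bool = True,
    i_dim: int = 6,
    j_dim: int = 120,
    tol: float = 1e-6,
    max_iter: int = 50,
    calibration_motion: int = 0,
    n_calibration_trials: int | None = None,
    classifier: str = "centroid",
    train_config: TrainConfig | None = None,
    label_names: Sequence[str] | None = None,
    block_scale_groups: Sequence[int] | None = None,
    seed: int = 0,
) -> LosoResult:
    """Leave-one-subject-out cross-validation, with or without the bilinear stage.

    Each fold trains on all other subjects and tests on the held-out subject.
    In bilinear mode the fold fits (Z, W, X) on the training subjects' stacked
    features (latent dimensions clamped to the fold's feasible ranges), adapts
    to the held-out subject using their first ``n_calibration_trials`` trials
    of the designated calibration motion (default: half of that motion's
    trials), projects the remaining trials to motion factors, and classifies
    those; the calibration trials are excluded from testing in BOTH modes so
    the two arms see identical test sets. In raw mode the classifier consumes
    the feature sequences directly.

    ``block_scale_groups`` optionally assigns each feature block (column of the
    per-trial sequences) to a scale group (typically one group per feature
    name); each fold then divides every block by the standard deviation of its
    group over the training subjects, so features measured in different units
    become comparable without using held-out data.
    """
    trials = _organize(sequences, labels, subjects)
    subject_order = list(dict.fromkeys(t.subject for t in trials))
    if len(subject_order) < 2:
        raise ValueError("leave-one-subject-out needs at least 2 subjects")
    t_len = trials[0].seq.shape[0]  # windows per trial

    # Designate calibration trials once so both arms exclude the same ones.
    cal_ids: set[int] = set()
    for subj in subject_order:
        cal_trials = sorted(
            (t for t in trials if t.subject == subj and t.motion == calibration_motion),
            key=lambda t: t.index,
        )
        if not cal_trials:
            raise ValueError(
                f"subject {subj} has no trials of calibration motion {calibration_motion}"
            )
        n_cal = n_calibration_trials or max(1, len(cal_trials) // 2)
        cal_ids.update(t.index for t in cal_trials[:n_cal])

    folds: list[LosoFold] = []
    all_true, all_pred, all_subj = [], [], []
    for fold_i, held_out in enumerate(subject_order):
        train_subjects = [s for s in subject_order if s != held_out]
        fold_trials = trials
        if block_scale_groups is not None:
            groups = np.asarray(block_scale_groups)
            if groups.size != trials[0].seq.shape[1]:
                raise ValueError("block_scale_groups must have one entry per block")
            train_vals = np.concatenate(
                [t.seq for t in trials if t.subject != held_out], axis=0
            )
            scales = np.ones(groups.size)
            for g in np.unique(groups):
                sd = float(train_vals[:, groups == g].std())
                scales[groups == g] = sd if sd > 0 else 1.0
            fold_trials = [
                _Trial(t.subject, t.motion, t.index, t.seq / scales) for t in trials
            ]
        test_trials = [
            t for t in fold_trials if t.subject == held_out and t.index not in cal_ids
        ]
        if not test_trials:
            raise ValueError(f"subject {held_out} has no test trials left")
        model = adaptation = None
        if bilinear_enabled:
            y_train, _, n_eff = _build_training_stack(fold_trials, train_subjects, n_motions)
            i_eff = max(1, min(i_dim, len(train_subjects)))
            j_eff = max(1, min(j_dim, n_motions * n_eff))
            model = bl.fit(
                y_train,
                (i_eff, j_eff, y_train.block_count, len(train_subjects), n_motions, n_eff),
                tol=tol,
                max_iter=max_iter,
            )
            cal = sorted(
                (
                    t
                    for t in fold_trials
                    if t.subject == held_out
                    and t.motion == calibration_motion
                    and t.index in cal_ids
                ),
                key=lambda t: t.index,
            )
            y_cal = bl.StackedMatrix(
                np.hstack([_trial_columns(t).data for t in cal]), y_train.block_count
            )
            adaptation = bl.adapt_new_user(model, y_cal, calibration_motion)
            # Training samples: the shared motion factors, one sequence per
            # (motion, repetition); test samples: projected held-out trials.
            train_samples = []
            for m in range(n_motions):
                xm = model.motion_columns(m)  # (J, n_eff)
                for n in range(xm.shape[1] // t_len):
                    train_samples.append(
                        SequenceSample(xm[:, n * t_len : (n + 1) * t_len].T, m, "train")
                    )
            test_samples = [
                SequenceSample(
                    bl.project_motions(adaptation, _trial_columns(t)).T, t.motion, held_out
                )
                for t in test_trials
            ]
        else:
            train_samples = [
                SequenceSample(t.seq, t.motion, t.subject)
                for t in fold_trials
                if t.subject in train_subjects
            ]
            test_samples = [
                SequenceSample(t.seq, t.motion, held_out) for t in test_trials
            ]
        cfg = train_config or TrainConfig()
        if classifier == "lstm":
            cfg = TrainConfig(
                learning_rate=cfg.learning_rate,
                iterations=cfg.iterations,
                hidden_size=cfg.hidden_size,
                n_layers=cfg.n_layers,
                batch_size=cfg.batch_size,
                seed=cfg.seed + fold_i + 1000 * seed,
            )
        clf = make_classifier(classifier, cfg)
        clf.fit(train_samples)
        y_true = np.asarray([s.label for s in test_samples])
        y_pred = clf.predict(test_samples)
        result = summarize_predictions(
            y_true, y_pred, [held_out] * len(test_samples), n_motions, label_names
        )
        folds.append(LosoFold(held_out, result, model, adaptation))
        all_true.append(y_true)
        all_pred.append(y_pred)
        all_subj.extend([held_out] * len(test_samples))
    aggregate = summarize_predictions(
        np.concatenate(all_true), np.concatenate(all_pred), all_subj, n_motions, label_names
    )
    return LosoResult(folds=folds, aggregate=aggregate)
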