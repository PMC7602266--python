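"""End-to-end orchestration: features -> selection -> bilinear -> classifier.

Every run is driven by a :class:`PipelineConfig` (loadable from YAML), flows
through the same prepared feature tensors, and emits machine-readable result
tables plus a human-readable log with the config hash, so reruns with an
identical config and seed are bit-identical.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml
from sklearn.model_selection import train_test_split

from . import classifier as clf_mod
from .bilinear import grid_search_ij
from .classifier import EvalResult, LosoResult, SequenceSample, TrainConfig
from .features import FeatureConfig, FeatureSeries, extract_features
from .io import DatasetManifest, EmgTrial, LabelVocabulary, load_dataset

__all__ = [
    "PipelineConfig",
    "compute_features",
    "feature_tensor",
    "features_to_frame",
    "run_single_subject",
    "run_loso",
    "run_grid",
]

#: The default six-feature subset used after selection.
DEFAULT_SELECTED_FEATURES = ("RMS", "LOG", "AAC", "PSR", "MNP", "MDF")


@dataclass(frozen=True)
class PipelineConfig:
    """All knobs of one pipeline run."""

    manifest: str | None = None
    out_dir: str | None = None
    window_samples: int = 600
    stride_samples: int | None = None
    selected_features: tuple[str, ...] = DEFAULT_SELECTED_FEATURES
    selection_k: int = 6
    selection_repeats: int = 10
    bilinear_enabled: bool = True
    i_dim: int = 6
    j_dim: int = 120
    bilinear_tol: float = 1e-6
    bilinear_max_iter: int = 50
    calibration_motion: int = 0
    n_calibration_trials: int | None = None
    classifier: str = "lstm"
    learning_rate: float = 1e-4
    iterations: int = 500
    hidden_size: int = 64
    normalize: bool = True
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        if "selected_features" in doc:
            doc["selected_features"] = tuple(doc["selected_features"])
        return cls(**doc)

    def feature_config(self) -> FeatureConfig:
        return FeatureConfig(
            window_samples=self.window_samples,
            stride_samples=self.stride_samples,
            feature_set=tuple(self.selected_features),
        )

    def train_config(self, seed_offset: int = 0) -> TrainConfig:
        return TrainConfig(
            learning_rate=self.learning_rate,
            iterations=self.iterations,
            hidden_size=self.hidden_size,
            seed=self.seed + seed_offset,
        )

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def compute_features(
    trials: Sequence[EmgTrial], config: FeatureConfig | None = None
) -> list[FeatureSeries]:
    config = config or FeatureConfig()
    return [extract_features(t, config) for t in trials]


def feature_tensor(
    series_list: Sequence[FeatureSeries], vocabulary: LabelVocabulary
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Stack per-trial series into (n_trials, T, C, F) + labels + subjects."""
    values = np.stack([fs.values for fs in series_list])
    labels = np.asarray([vocabulary.index(fs.motion_label) for fs in series_list])
    subjects = [fs.subject_id for fs in series_list]
    return values, labels, subjects


def features_to_frame(series_list: Sequence[FeatureSeries]) -> pd.DataFrame:
    """Tidy long-format table: subject, motion, trial, window, channel, feature, value."""
    rows = []
    for fs in series_list:
        nw, nc, nf = fs.values.shape
        for w in range(nw):
            for ch in range(nc):
                for k, name in enumerate(fs.feature_names):
                    rows.append(
                        (fs.subject_id, fs.motion_label, fs.trial_index, w, ch, name,
                         fs.values[w, ch, k])
                    )
    return pd.DataFrame(
        rows, columns=["subject", "motion", "trial", "window", "channel", "feature", "value"]
    )


def _sequences_and_groups(values: np.ndarray) -> tuple[list[np.ndarray], np.ndarray]:
    """Flatten (T, C, F) per trial to (T, C*F) and tag each block's feature group."""
    n, t, c, f = values.shape
    seqs = [values[i].reshape(t, c * f) for i in range(n)]
    groups = np.tile(np.arange(f), c)
    return seqs, groups


def _normalize_global(values: np.ndarray) -> np.ndarray:
    """Divide each feature by its global standard deviation (single-subject runs)."""
    out = values.copy()
    for k in range(values.shape[3]):
        sd = float(values[:, :, :, k].std())
        if sd > 0:
            out[:, :, :, k] /= sd
    return out


@dataclass
class RunArtifacts:
    result: EvalResult
    summary: dict
    out_dir: Path | None = None


def _write_eval(result: EvalResult, out_dir: Path, prefix: str = "") -> None:
    result.to_frame().to_csv(out_dir / f"{prefix}confusion.csv")
    pd.DataFrame(
        {"motion": result.label_names, "accuracy": result.per_motion_accuracy}
    ).to_csv(out_dir / f"{prefix}per_motion.csv", index=False)
    pd.DataFrame(
        {"subject": list(result.per_subject_accuracy), "accuracy": list(result.per_subject_accuracy.values())}
    ).to_csv(out_dir / f"{prefix}per_subject.csv", index=False)


def _finish(summary: dict, config: PipelineConfig, log_lines: list[str]) -> Path | None:
    out = None
    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=2, default=float)
        with open(out / "run.log", "w") as fh:
            fh.write("\n".join(log_lines) + "\n")
    return out


def _prepare(config: PipelineConfig, trials=None, manifest=None):
    if trials is None:
        if config.manifest is None:
            raise ValueError("config needs a manifest path or explicit trials")
        trials, manifest = load_dataset(config.manifest)
    series = compute_features(trials, config.feature_config())
    vocab = manifest.vocabulary if manifest is not None else _infer_vocab(series)
    values, labels, subjects = feature_tensor(series, vocab)
    return values, labels, subjects, vocab


def _infer_vocab(series) -> LabelVocabulary:
    from .io import default_vocabulary

    labels = {fs.motion_label for fs in series}
    default = default_vocabulary()
    if labels <= set(default.labels):
        used = tuple(l for l in default.labels if l in labels)
        return LabelVocabulary(used, {l: default.phrases.get(l, l) for l in used})
    return LabelVocabulary(tuple(sorted(labels)))


def run_single_subject(
    config: PipelineConfig,
    trials: Sequence[EmgTrial] | None = None,
    manifest: DatasetManifest | None = None,
) -> RunArtifacts:
    """Within-subject evaluation: stratified 80/20 split per motion.

    Trains the configured classifier on the training split of a (typically
    single-subject) dataset and evaluates on the held-out 20%, writing the
    confusion matrix and accuracy tables when an output directory is set.
    """
    t0 = time.time()
    values, labels, subjects, vocab = _prepare(config, trials, manifest)
    if config.normalize:
        values = _normalize_global(values)
    idx_train, idx_test = train_test_split(
        np.arange(len(labels)), test_size=0.2, stratify=labels, random_state=config.seed
    )
    seqs, _ = _sequences_and_groups(values)
    mk = lambda idx: [
        SequenceSample(seqs[i], int(labels[i]), subjects[i]) for i in idx
    ]
    clf = clf_mod.make_classifier(config.classifier, config.train_config())
    clf.fit(mk(idx_train))
    result = clf_mod.evaluate(clf, mk(idx_test), len(vocab), tuple(vocab))
    if config.out_dir and config.classifier == "lstm":
        from .io import save_classifier

        Path(config.out_dir).mkdir(parents=True, exist_ok=True)
        save_classifier(clf, Path(config.out_dir) / "classifier.npz")
    summary = {
        "mode": "single_subject",
        "overall_accuracy": result.overall_accuracy,
        "n_train": len(idx_train),
        "n_test": len(idx_test),
        "config_hash": config.digest(),
        "seed": config.seed,
        "elapsed_s": time.time() - t0,
    }
    log = [
        f"single-subject run, config {config.digest()}",
        f"trials={len(labels)} features={config.selected_features}",
        f"classifier={config.classifier} accuracy={result.overall_accuracy:.4f}",
    ]
    out = _finish(summary, config, log)
    if out:
        _write_eval(result, out)
    return RunArtifacts(result=result, summary=summary, out_dir=out)


@dataclass
class LosoArtifacts:
    bilinear: LosoResult | None
    raw: LosoResult | None
    summary: dict
    out_dir: Path | None = None


def run_loso(
    config: PipelineConfig,
    trials: Sequence[EmgTrial] | None = None,
    manifest: DatasetManifest | None = None,
    compare: bool = False,
) -> LosoArtifacts:
    """Leave-one-subject-out evaluation, optionally both with and without the
    bilinear stage.

    When ``compare`` is true, both arms share the fold structure, the feature
    tensors, the calibration-trial exclusions and the seed, so the difference
    between them isolates the bilinear factorization. A paired per-fold
    accuracy table is part of the summary.
    """
    t0 = time.time()
    values, labels, subjects, vocab = _prepare(config, trials, manifest)
    seqs, groups = _sequences_and_groups(values)
    common = dict(
        n_motions=len(vocab),
        i_dim=config.i_dim,
        j_dim=config.j_dim,
        tol=config.bilinear_tol,
        max_iter=config.bilinear_max_iter,
        calibration_motion=config.calibration_motion,
        n_calibration_trials=config.n_calibration_trials,
        classifier=config.classifier,
        train_config=config.train_config() if config.classifier == "lstm" else None,
        label_names=tuple(vocab),
        block_scale_groups=groups if config.normalize else None,
        seed=config.seed,
    )
    arms: dict[str, LosoResult | None] = {"bilinear": None, "raw": None}
    if config.bilinear_enabled or compare:
        arms["bilinear"] = clf_mod.loso_cross_validate(
            seqs, labels, subjects, bilinear_enabled=True, **common
        )
    if not config.bilinear_enabled or compare:
        arms["raw"] = clf_mod.loso_cross_validate(
            seqs, labels, subjects, bilinear_enabled=False, **common
        )
    summary: dict = {
        "mode": "loso",
        "config_hash": config.digest(),
        "seed": config.seed,
        "i_dim": config.i_dim,
        "j_dim": config.j_dim,
        "elapsed_s": time.time() - t0,
    }
    paired = {}
    for name, res in arms.items():
        if res is not None:
            summary[f"{name}_accuracy"] = res.aggregate.overall_accuracy
            paired[name] = res.per_fold_accuracy
    if paired:
        summary["per_fold_accuracy"] = paired
    log = [f"loso run, config {config.digest()}"]
    for name, res in arms.items():
        if res is not None:
            log.append(f"{name}: accuracy={res.aggregate.overall_accuracy:.4f}")
    out = _finish(summary, config, log)
    if out:
        for name, res in arms.items():
            if res is not None:
                _write_eval(res.aggregate, out, prefix=f"{name}_")
        if arms["bilinear"] and arms["raw"]:
            pd.DataFrame(
                {
                    "subject": list(arms["bilinear"].per_fold_accuracy),
                    "bilinear": list(arms["bilinear"].per_fold_accuracy.values()),
                    "raw": list(arms["raw"].per_fold_accuracy.values()),
                }
            ).to_csv(out / "paired_folds.csv", index=False)
    return LosoArtifacts(
        bilinear=arms["bilinear"], raw=arms["raw"], summary=summary, out_dir=out
    )


def run_grid(
    config: PipelineConfig,
    i_candidates: Sequence[int],
    j_candidates: Sequence[int],
    trials: Sequence[EmgTrial] | None = None,
    manifest: DatasetManifest | None = None,
) -> tuple[pd.DataFrame, tuple[int, int]]:
    """Accuracy surface over (I, J) via bilinear-mode LOSO at each grid point."""
    values, labels, subjects, vocab = _prepare(config, trials, manifest)
    seqs, groups = _sequences_and_groups(values)

    def evaluate(i: int, j: int) -> float:
        res = clf_mod.loso_cross_validate(
            seqs,
            labels,
            subjects,
            n_motions=len(vocab),
            bilinear_enabled=True,
            i_dim=i,
            j_dim=j,
            tol=config.bilinear_tol,
            max_iter=config.bilinear_max_iter,
            calibration_motion=config.calibration_motion,
            n_calibration_trials=config.n_calibration_trials,
            classifier=config.classifier,
            train_config=config.train_config() if config.classifier == "lstm" else None,
            label_names=tuple(vocab),
            block_scale_groups=groups if config.normalize else None,
            seed=config.seed,
        )
        return res.aggregate.overall_accuracy

    surface, best = grid_search_ij(i_candidates, j_candidates, evaluate)
    df = pd.DataFrame(surface, columns=["I", "J", "accuracy"])
    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        df.to_csv(out / "grid_surface.csv", index=False)
    return df, best
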