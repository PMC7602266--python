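"""File I/O: delimited EMG trial files, dataset manifests, model containers.

Trial files are plain delimited text (comma or whitespace, auto-detected), one
row per sample and one column per channel, no header. Manifests are either a
CSV with columns ``path,subject,motion,trial`` or a YAML mapping that also
carries the vocabulary, channel count and sampling rate explicitly. Fitted
models are stored as a single ``.npz`` container holding the named matrices
plus a JSON metadata blob (format version, dimensions, vocabulary, config), so
a round trip is bit-identical on the factor matrices.

Signal units are unscaled arbitrary units; no calibration is applied.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .bilinear import BilinearModel, StackedMatrix

__all__ = [
    "ASL20_VOCABULARY",
    "default_vocabulary",
    "EmgTrial",
    "ManifestEntry",
    "DatasetManifest",
    "LabelVocabulary",
    "TrialParseError",
    "read_trial",
    "write_trial",
    "load_manifest",
    "load_dataset",
    "write_dataset",
    "save_model",
    "load_model",
    "save_classifier",
    "load_classifier",
    "ModelIOError",
]

MODEL_FORMAT_VERSION = 1

#: The 20-phrase ASL vocabulary, M1..M20.
ASL20_VOCABULARY: tuple[tuple[str, str], ...] = (
    ("M1", "How are you?"),
    ("M2", "Nice to meet you."),
    ("M3", "See you later."),
    ("M4", "That's what I mean."),
    ("M5", "I don't understand."),
    ("M6", "What is your name?"),
    ("M7", "Where are you from?"),
    ("M8", "What happens?"),
    ("M9", "What is wrong?"),
    ("M10", "Please call 911."),
    ("M11", "Where is the store?"),
    ("M12", "How can I get food?"),
    ("M13", "How much does it cost?"),
    ("M14", "Yes, thank you."),
    ("M15", "I am sorry."),
    ("M16", "Where is the hospital?"),
    ("M17", "I don't feel good."),
    ("M18", "Please help me."),
    ("M19", "Please write it."),
    ("M20", "I love you."),
)


@dataclass(frozen=True)
class LabelVocabulary:
    """An ordered motion-label vocabulary with optional phrase meanings."""

    labels: tuple[str, ...]
    phrases: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("vocabulary labels must be unique")
        if not self.labels:
            raise ValueError("vocabulary must be non-empty")

    def index(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise KeyError(f"motion label {label!r} not in vocabulary") from None

    def __len__(self) -> int:
        return len(self.labels)

    def __iter__(self):
        return iter(self.labels)


def default_vocabulary() -> LabelVocabulary:
    """The 20-motion ASL phrase vocabulary (M1..M20)."""
    return LabelVocabulary(
        labels=tuple(code for code, _ in ASL20_VOCABULARY),
        phrases=dict(ASL20_VOCABULARY),
    )


@dataclass(frozen=True)
class EmgTrial:
    """One recorded trial: a (T_samples x C_channels) raw signal plus metadata."""

    subject_id: str
    motion_label: str
    trial_index: int
    samples: np.ndarray
    sampling_rate_hz: float = 200.0

    def __post_init__(self) -> None:
        s = np.atleast_2d(np.asarray(self.samples, dtype=float))
        if s.shape[0] < 2:
            raise ValueError("a trial needs at least 2 samples")
        if s.shape[1] < 1:
            raise ValueError("a trial needs at least 1 channel")
        if not np.isfinite(s).all():
            raise ValueError(
                f"trial ({self.subject_id}, {self.motion_label}, {self.trial_index}) "
                "contains non-finite samples"
            )
        if self.sampling_rate_hz <= 0:
            raise ValueError("sampling_rate_hz must be positive")
        if self.trial_index < 0:
            raise ValueError("trial_index must be >= 0")
        object.__setattr__(self, "samples", s)

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def n_channels(self) -> int:
        return self.samples.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sampling_rate_hz


@dataclass(frozen=True)
class ManifestEntry:
    file_path: str
    subject_id: str
    motion_label: str
    trial_index: int


@dataclass(frozen=True)
class DatasetManifest:
    """The index of a dataset: one entry per trial file plus shared metadata."""

    entries: tuple[ManifestEntry, ...]
    vocabulary: LabelVocabulary
    channel_count: int | None = None
    sampling_rate_hz: float = 200.0
    root: Path | None = None

    def __post_init__(self) -> None:
        keys = [(e.subject_id, e.motion_label, e.trial_index) for e in self.entries]
        if len(set(keys)) != len(keys):
            dupes = sorted({k for k in keys if keys.count(k) > 1})
            raise ValueError(f"duplicate (subject, motion, trial) entries: {dupes[:3]}")
        bad = sorted({e.motion_label for e in self.entries} - set(self.vocabulary.labels))
        if bad:
            raise ValueError(f"motion labels not in vocabulary: {bad}")


class TrialParseError(ValueError):
    """A trial file could not be parsed; carries the offending line number."""

    def __init__(self, path, line_number: int, message: str):
        self.path = str(path)
        self.line_number = line_number
        super().__init__(f"{path}, line {line_number}: {message}")


def _parse_numeric_table(path: Path) -> np.ndarray:
    rows: list[list[float]] = []
    n_cols: int | None = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            parts = line.split(",") if "," in line else line.split()
            if n_cols is None:
                n_cols = len(parts)
            elif len(parts) != n_cols:
                raise TrialParseError(
                    path, lineno, f"expected {n_cols} columns, found {len(parts)}"
                )
            try:
                rows.append([float(p) for p in parts])
            except ValueError:
                bad = next(p for p in parts if not _is_number(p))
                raise TrialParseError(path, lineno, f"non-numeric value {bad!r}") from None
    if not rows:
        raise TrialParseError(path, 0, "file contains no data rows")
    return np.asarray(rows, dtype=float)


def _is_number(token: str) -> bool:
    try:
        float(token)
        return True
    except ValueError:
        return False


def read_trial(
    path,
    entry: ManifestEntry,
    sampling_rate_hz: float = 200.0,
    expected_channels: int | None = None,
) -> EmgTrial:
    """Read one delimited trial file with metadata from its manifest entry."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"trial file not found: {path} (entry {entry})")
    samples = _parse_numeric_table(path)
    if not np.isfinite(samples).all():
        raise ValueError(f"{path}: trial contains NaN or infinite values")
    if expected_channels is not None and samples.shape[1] != expected_channels:
        raise ValueError(
            f"{path}: has {samples.shape[1]} channels, dataset expects {expected_channels}"
        )
    return EmgTrial(
        subject_id=entry.subject_id,
        motion_label=entry.motion_label,
        trial_index=entry.trial_index,
        samples=samples,
        sampling_rate_hz=sampling_rate_hz,
    )


def write_trial(trial: EmgTrial, path) -> None:
    """Write a trial as comma-delimited text at full float precision."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savetxt(path, trial.samples, fmt="%.17g", delimiter=",")


def load_manifest(path) -> DatasetManifest:
    """Load a CSV (path,subject,motion,trial) or YAML dataset manifest."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"manifest not found: {path}")
    if path.suffix.lower() in {".yaml", ".yml"}:
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        vocab_labels = doc.get("vocabulary")
        vocab = (
            LabelVocabulary(tuple(vocab_labels)) if vocab_labels else default_vocabulary()
        )
        entries = tuple(
            ManifestEntry(
                file_path=str(t["path"]),
                subject_id=str(t["subject"]),
                motion_label=str(t["motion"]),
                trial_index=int(t["trial"]),
            )
            for t in doc.get("trials", [])
        )
        return DatasetManifest(
            entries=entries,
            vocabulary=vocab,
            channel_count=doc.get("channel_count"),
            sampling_rate_hz=float(doc.get("sampling_rate_hz", 200.0)),
            root=path.parent,
        )
    df = pd.read_csv(path, dtype={"subject": str, "motion": str})
    required = {"path", "subject", "motion", "trial"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"manifest {path} missing columns: {sorted(missing)}")
    entries = tuple(
        ManifestEntry(
            file_path=str(r.path),
            subject_id=str(r.subject),
            motion_label=str(r.motion),
            trial_index=int(r.trial),
        )
        for r in df.itertuples()
    )
    labels = {e.motion_label for e in entries}
    default = default_vocabulary()
    if not entries or labels <= set(default.labels):
        used = tuple(l for l in default.labels if l in labels) or default.labels
        vocab = LabelVocabulary(used, {l: default.phrases[l] for l in used})
    else:
        vocab = LabelVocabulary(tuple(sorted(labels)))
    return DatasetManifest(entries=entries, vocabulary=vocab, root=path.parent)


def load_dataset(manifest_path) -> tuple[list[EmgTrial], DatasetManifest]:
    """Load every trial named in a manifest, in manifest order.

    Channel count and sampling rate must be consistent across the dataset; a
    file whose channel count disagrees raises a validation error naming it.
    """
    manifest = load_manifest(manifest_path)
    root = manifest.root or Path(".")
    trials: list[EmgTrial] = []
    channels = manifest.channel_count
    for entry in manifest.entries:
        fpath = Path(entry.file_path)
        if not fpath.is_absolute():
            fpath = root / fpath
        trial = read_trial(
            fpath, entry, sampling_rate_hz=manifest.sampling_rate_hz,
            expected_channels=channels,
        )
        if channels is None:
            channels = trial.n_channels
        trials.append(trial)
    return trials, manifest


def write_dataset(trials: Sequence[EmgTrial], out_dir, manifest_name: str = "manifest.csv") -> Path:
    """Write trials as delimited files plus a CSV manifest; returns manifest path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for trial in trials:
        fname = f"{trial.subject_id}_{trial.motion_label}_{trial.trial_index}.csv"
        write_trial(trial, out_dir / fname)
        rows.append(
            {
                "path": fname,
                "subject": trial.subject_id,
                "motion": trial.motion_label,
                "trial": trial.trial_index,
            }
        )
    manifest_path = out_dir / manifest_name
    pd.DataFrame(rows).to_csv(manifest_path, index=False)
    return manifest_path


class ModelIOError(RuntimeError):
    """A model container could not be read (corrupt file or version mismatch)."""


def save_model(model: BilinearModel, path) -> None:
    """Serialize a fitted bilinear model to a single .npz container."""
    if model.Z.size == 0 or model.X.size == 0:
        raise ValueError("refusing to save an unfitted/empty model")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    meta = {
        "format_version": MODEL_FORMAT_VERSION,
        "kind": "bilinear",
        "dims": model.dims,
        "objective_history": model.objective_history,
        "converged": model.converged,
        "n_iterations": model.n_iterations,
        "config": model.config,
    }
    np.savez(
        path,
        Z=model.Z,
        W=model.W.data,
        X=model.X,
        W_block_count=np.array([model.W.block_count]),
        metadata=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
    )


def load_model(path) -> BilinearModel:
    """Load a bilinear model container; bit-identical factors on round trip."""
    path = Path(path)
    try:
        with np.load(path) as npz:
            meta = json.loads(bytes(npz["metadata"]).decode())
            if meta.get("format_version") != MODEL_FORMAT_VERSION:
                raise ModelIOError(
                    f"{path}: unsupported model format version {meta.get('format_version')!r}"
                )
            return BilinearModel(
                Z=npz["Z"],
                W=StackedMatrix(npz["W"], int(npz["W_block_count"][0])),
                X=npz["X"],
                dims=meta["dims"],
                objective_history=list(meta["objective_history"]),
                converged=bool(meta["converged"]),
                n_iterations=int(meta["n_iterations"]),
                config=meta.get("config", {}),
            )
    except ModelIOError:
        raise
    except Exception as exc:
        raise ModelIOError(f"could not load model container {path}: {exc}") from exc


def save_classifier(classifier, path) -> None:
    """Serialize a trained LSTM classifier (weights + config) to .npz."""
    if getattr(classifier, "_params", None) is None:
        raise ValueError("refusing to save an unfitted classifier")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    cfg = classifier.config
    meta = {
        "format_version": MODEL_FORMAT_VERSION,
        "kind": "lstm",
        "n_classes": classifier.n_classes,
        "loss_history": classifier.loss_history,
        "config": {
            "learning_rate": cfg.learning_rate,
            "iterations": cfg.iterations,
            "hidden_size": cfg.hidden_size,
            "n_layers": cfg.n_layers,
            "batch_size": cfg.batch_size,
            "seed": cfg.seed,
        },
    }
    np.savez(
        path,
        metadata=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
        **classifier._params,
    )


def load_classifier(path):
    """Load a trained LSTM classifier; weights round-trip within float tolerance."""
    from .classifier import LstmClassifier, TrainConfig

    path = Path(path)
    try:
        with np.load(path) as npz:
            meta = json.loads(bytes(npz["metadata"]).decode())
            if meta.get("format_version") != MODEL_FORMAT_VERSION:
                raise ModelIOError(
                    f"{path}: unsupported model format version {meta.get('format_version')!r}"
                )
            if meta.get("kind") != "lstm":
                raise ModelIOError(f"{path}: not an LSTM classifier container")
            clf = LstmClassifier(TrainConfig(**meta["config"]))
            clf.n_classes = int(meta["n_classes"])
            clf.loss_history = list(meta["loss_history"])
            clf._params = {k: npz[k] for k in ("Wx", "Wh", "b", "Wy", "by")}
            return clf
    except ModelIOError:
        raise
    except Exception as exc:
        raise ModelIOError(f"could not load classifier container {path}: {exc}") from exc
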