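"""Recordings, framing, spectral features and patient-grouped folds.

A recording is one patient session of single-channel PPG.  Sessions are cut
into fixed-length frames (default 5 s, 50 % overlap), and classifiers
consume the log one-sided power spectrum of each frame: at a sampling rate
``fs`` an integer-second frame yields exactly ``fs // 2`` bins at 1 Hz
resolution (DC dropped).

Cross-validation is always grouped by patient: frames from one patient
never appear in both the train and test split of a fold.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.signal import periodogram

__all__ = [
    "PPGRecording",
    "FrameSet",
    "FeatureSet",
    "FormatError",
    "load_recordings",
    "save_recordings",
    "frame_signal",
    "frame_recordings",
    "log_power_spectrum",
    "patient_folds",
    "subsample_balance",
    "save_frameset",
    "load_frameset",
]


class FormatError(ValueError):
    """Raised when an on-disk recording or sidecar is malformed."""


@dataclass
class PPGRecording:
    """One patient session: waveform, sampling rate, patient id, class.

    ``severity_class`` is a 1-based integer label (1..C); re-indexing from
    arbitrary on-disk labels happens in :func:`load_recordings`.
    """

    patient_id: str
    signal: np.ndarray
    fs: float
    severity_class: int

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        if self.signal.ndim != 1 or self.signal.size < 1:
            raise ValueError("signal must be a non-empty 1-D array")
        if not self.fs > 0:
            raise ValueError(f"fs must be positive, got {self.fs}")
        if int(self.severity_class) < 1:
            raise ValueError("severity_class must be a positive integer")
        self.severity_class = int(self.severity_class)

    @property
    def duration(self) -> float:
        """Session length in seconds."""
        return self.signal.size / self.fs


@dataclass
class FrameSet:
    """Fixed-length frames with aligned class labels and patient ids."""

    frames: np.ndarray  # (n, L)
    labels: np.ndarray  # (n,) ints in 1..C
    patient_ids: np.ndarray  # (n,) strings
    fs: float
    frame_seconds: float
    provenance: np.ndarray | None = None  # (n,) strings, e.g. real/synthetic

    def __post_init__(self) -> None:
        self.frames = np.atleast_2d(np.asarray(self.frames, dtype=float))
        self.labels = np.asarray(self.labels, dtype=int)
        self.patient_ids = np.asarray(self.patient_ids, dtype=str)
        n = self.frames.shape[0]
        if not (self.labels.shape == (n,) and self.patient_ids.shape == (n,)):
            raise ValueError("labels and patient_ids must align with frames rows")
        if self.provenance is not None:
            self.provenance = np.asarray(self.provenance, dtype=str)
            if self.provenance.shape != (n,):
                raise ValueError("provenance must align with frames rows")

    def __len__(self) -> int:
        return self.frames.shape[0]

    @property
    def frame_length(self) -> int:
        return self.frames.shape[1]

    @property
    def classes(self) -> np.ndarray:
        return np.unique(self.labels)

    def class_counts(self) -> dict[int, int]:
        vals, counts = np.unique(self.labels, return_counts=True)
        return dict(zip(vals.tolist(), counts.tolist()))

    def subset(self, idx: np.ndarray) -> "FrameSet":
        idx = np.asarray(idx)
        return FrameSet(
            self.frames[idx],
            self.labels[idx],
            self.patient_ids[idx],
            self.fs,
            self.frame_seconds,
            None if self.provenance is None else self.provenance[idx],
        )


@dataclass
class FeatureSet:
    """Per-frame log-power features (dimensionless) with aligned metadata."""

    features: np.ndarray  # (n, D)
    labels: np.ndarray
    patient_ids: np.ndarray

    def __post_init__(self) -> None:
        self.features = np.atleast_2d(np.asarray(self.features, dtype=float))
        self.labels = np.asarray(self.labels, dtype=int)
        self.patient_ids = np.asarray(self.patient_ids, dtype=str)
        if not np.all(np.isfinite(self.features)):
            raise ValueError("features must be finite")

    def __len__(self) -> int:
        return self.features.shape[0]


# ---------------------------------------------------------------------------
# I/O: one CSV per session (one sample per row) plus a key=value sidecar
# ---------------------------------------------------------------------------

_REQUIRED_META = ("patient_id", "class", "fs")


def _read_sidecar(path: Path) -> dict[str, str]:
    meta: dict[str, str] = {}
    for line in path.read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise FormatError(f"{path}: expected key=value lines, got {line!r}")
        key, value = line.split("=", 1)
        meta[key.strip()] = value.strip()
    for key in _REQUIRED_META:
        if key not in meta:
            raise FormatError(f"{path}: missing metadata field {key!r}")
    return meta


def load_recordings(path: str | Path, format: str = "csv") -> list[PPGRecording]:
    """Read a directory of PPG sessions.

    CSV dialect: for every session there is ``<name>.csv`` holding one
    amplitude sample per row and ``<name>.meta`` holding ``key=value``
    lines with at least ``patient_id``, ``class`` and ``fs``.

    Classes found on disk are re-indexed to consecutive integers 1..C in
    sorted order of the original values.
    """
    if format != "csv":
        raise ValueError(f"unsupported format {format!r}; only 'csv' is available")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    csv_files = sorted(path.glob("*.csv"))
    if not csv_files:
        raise FormatError(f"no .csv session files under {path}")

    raw: list[tuple[str, np.ndarray, float, int]] = []
    for csv_file in csv_files:
        meta = _read_sidecar(csv_file.with_suffix(".meta"))
        samples = []
        for i, line in enumerate(csv_file.read_text().splitlines()):
            line = line.strip()
            if not line:
                continue
            try:
                samples.append(float(line))
            except ValueError:
                raise FormatError(
                    f"{csv_file}: non-numeric sample at row {i}: {line!r}"
                ) from None
        raw.append(
            (meta["patient_id"], np.asarray(samples), float(meta["fs"]), int(meta["class"]))
        )

    original_classes = sorted({cls for *_, cls in raw})
    remap = {cls: i + 1 for i, cls in enumerate(original_classes)}
    return [
        PPGRecording(pid, sig, fs, remap[cls]) for pid, sig, fs, cls in raw
    ]


def save_recordings(recordings: list[PPGRecording], path: str | Path) -> None:
    """Write recordings in the CSV + sidecar dialect read by ``load_recordings``."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    for i, rec in enumerate(recordings):
        stem = path / f"session_{i:04d}"
        np.savetxt(stem.with_suffix(".csv"), rec.signal, fmt="%.17g")
        stem.with_suffix(".meta").write_text(
            f"patient_id={rec.patient_id}\nclass={rec.severity_class}\nfs={rec.fs:g}\n"
        )


def save_frameset(fr: FrameSet, path: str | Path) -> None:
    """Persist a FrameSet as an .npz container with a JSON header."""
    header = json.dumps({"fs": fr.fs, "frame_seconds": fr.frame_seconds})
    extra = {} if fr.provenance is None else {"provenance": fr.provenance}
    np.savez(
        path,
        frames=fr.frames,
        labels=fr.labels,
        patient_ids=fr.patient_ids,
        header=np.array(header),
        **extra,
    )


def load_frameset(path: str | Path) -> FrameSet:
    with np.load(path, allow_pickle=False) as z:
        header = json.loads(str(z["header"]))
        prov = z["provenance"] if "provenance" in z.files else None
        return FrameSet(
            z["frames"], z["labels"], z["patient_ids"],
            header["fs"], header["frame_seconds"], prov,
        )


# ---------------------------------------------------------------------------
# Framing and spectral features
# ---------------------------------------------------------------------------


def frame_signal(
    rec: PPGRecording, frame_seconds: float = 5.0, overlap_frac: float = 0.5
) -> FrameSet:
    """Cut one recording into fixed-length frames.

    Frames are consecutive half-open windows ``[start, start + L)`` of
    length ``L = round(fs * frame_seconds)`` with hop
    ``round(L * (1 - overlap_frac))``; a trailing partial window is
    discarded.
    """
    if not 0 <= overlap_frac < 1:
        raise ValueError("overlap_frac must lie in [0, 1)")
    L = int(round(rec.fs * frame_seconds))
    if rec.signal.size < L:
        raise ValueError(
            f"signal of {rec.signal.size} samples is shorter than one "
            f"{L}-sample frame"
        )
    hop = int(round(L * (1 - overlap_frac)))
    if hop < 1:
        raise ValueError("overlap_frac too close to 1: hop would be zero")
    n_frames = (rec.signal.size - L) // hop + 1
    starts = np.arange(n_frames) * hop
    frames = np.stack([rec.signal[s : s + L] for s in starts])
    return FrameSet(
        frames,
        np.full(n_frames, rec.severity_class),
        np.full(n_frames, rec.patient_id),
        rec.fs,
        frame_seconds,
    )


def frame_recordings(
    recordings: list[PPGRecording],
    frame_seconds: float = 5.0,
    overlap_frac: float = 0.5,
) -> FrameSet:
    """Frame every recording and concatenate into one FrameSet."""
    if not recordings:
        raise ValueError("no recordings given")
    fs = recordings[0].fs
    if any(r.fs != fs for r in recordings):
        raise ValueError("all recordings must share one sampling rate")
    parts = [frame_signal(r, frame_seconds, overlap_frac) for r in recordings]
    return FrameSet(
        np.concatenate([p.frames for p in parts]),
        np.concatenate([p.labels for p in parts]),
        np.concatenate([p.patient_ids for p in parts]),
        fs,
        frame_seconds,
    )


def log_power_spectrum(fr: FrameSet, eps_floor: float = 1e-12) -> FeatureSet:
    """Log one-sided power spectrum of each frame, ``fs // 2`` bins.

    Each frame is split into non-overlapping 1-second sub-segments whose
    untapered periodograms are averaged (Welch with a boxcar window and no
    overlap); the DC bin is dropped and bins 1..fs/2 Hz kept, so a 500-sample
    frame at 100 Hz yields a 50-dimensional feature at 1 Hz resolution.
    ``eps_floor`` keeps the log finite on zero-power bins.
    """
    fs = int(round(fr.fs))
    if fr.fs != fs or fr.frame_length % fs != 0:
        raise ValueError("frame length must be an integer number of seconds")
    n_seg = fr.frame_length // fs
    segs = fr.frames.reshape(len(fr), n_seg, fs)
    _, power = periodogram(segs, fs=fs, window="boxcar", axis=-1)
    mean_power = power.mean(axis=1)[:, 1:]  # drop DC, keep 1..fs/2 Hz
    return FeatureSet(np.log(mean_power + eps_floor), fr.labels, fr.patient_ids)


# ---------------------------------------------------------------------------
# Patient-grouped cross-validation and balancing
# ---------------------------------------------------------------------------


def patient_folds(
    fr: FrameSet, patients_per_class: int = 1, seed: int = 0
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Leave-N-patients-out folds: each test fold holds exactly
    ``patients_per_class`` patients from every class; the number of folds is
    the floor of the smallest per-class patient count divided by
    ``patients_per_class``.  Patients beyond the fold budget stay in every
    training split.  Assignment is deterministic under ``seed``.
    """
    rng = np.random.default_rng(seed)
    classes = fr.classes
    per_class_patients: dict[int, np.ndarray] = {}
    for cls in classes:
        pats = np.unique(fr.patient_ids[fr.labels == cls])
        if pats.size == 0:
            raise ValueError(f"class {cls} has zero patients")
        per_class_patients[cls] = rng.permutation(pats)
    n_folds = min(p.size for p in per_class_patients.values()) // patients_per_class
    if n_folds < 1:
        raise ValueError(
            f"need at least {patients_per_class} patients per class for one fold"
        )
    folds = []
    for k in range(n_folds):
        test_patients: set[str] = set()
        for cls in classes:
            sel = per_class_patients[cls][
                k * patients_per_class : (k + 1) * patients_per_class
            ]
            test_patients.update(sel.tolist())
        test_mask = np.isin(fr.patient_ids, sorted(test_patients))
        folds.append((np.flatnonzero(~test_mask), np.flatnonzero(test_mask)))
    return folds


def subsample_balance(fr: FrameSet, seed: int = 0) -> FrameSet:
    """Balance classes by removing extra frames from overpopulated classes.

    Every class is reduced to the minimum per-class frame count; removed
    frames are chosen uniformly at random under ``seed`` and retained rows
    keep their original order.
    """
    counts = fr.class_counts()
    if not counts:
        raise ValueError("empty FrameSet")
    target = min(counts.values())
    rng = np.random.default_rng(seed)
    keep: list[np.ndarray] = []
    for cls in fr.classes:
        idx = np.flatnonzero(fr.labels == cls)
        keep.append(np.sort(rng.choice(idx, size=target, replace=False)))
    order = np.sort(np.concatenate(keep))
    return fr.subset(order)


def check_no_patient_leakage(
    fr: FrameSet, folds: list[tuple[np.ndarray, np.ndarray]]
) -> bool:
    """True iff no patient appears in both splits of any fold and no patient
    is tested twice across folds."""
    seen: set[str] = set()
    for train_idx, test_idx in folds:
        train_p = set(fr.patient_ids[train_idx])
        test_p = set(fr.patient_ids[test_idx])
        if train_p & test_p:
            return False
        if seen & test_p:
            return False
        seen |= test_p
    return True
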