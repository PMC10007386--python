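"""Common in-memory containers shared by every pipeline stage.

A single-lead ECG recording is held as an :class:`ECGRecord`: the raw
amplitude samples in millivolts, the sampling rate, and a list of
rhythm-labeled intervals (half-open, in samples).  Fixed-length heartbeat
templates clipped around R-peaks are stacked row-wise in a
:class:`BeatMatrix` together with their per-beat metadata.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: closed label vocabulary — atrial flutter, AV-junctional rhythm and noisy
#: acquisitions all map to OTHER and are excluded from the binary task
NSR = "NSR"
AFIB = "AFib"
OTHER = "other"

LABELS = (NSR, AFIB, OTHER)


@dataclass
class ECGRecord:
    """One single-channel ECG recording with rhythm-labeled intervals.

    Parameters
    ----------
    record_id : str
        Identifier of the recording.
    patient_id : str
        Identifier of the patient the recording belongs to; several
        recordings may share a patient.
    signal : ndarray of float, shape (n_samples,)
        Amplitudes in millivolts.
    fs : float
        Sampling rate in Hz.
    intervals : list of (int, int, str)
        Rhythm intervals ``(start, end, label)`` with 0-based half-open
        sample bounds and label in :data:`LABELS`.  Non-overlapping and
        within the signal.
    provenance : str
        One of ``"afdb-like"``, ``"cinc-like"``, ``"synthetic"``.
    rpeak_times : ndarray of float or None
        Candidate or ground-truth R-peak times in seconds (synthetic
        records carry ground truth; AFDB records carry the provided QRS
        annotations to be refined).
    beat_labels : list of str or None
        Per-R-peak labels aligned with ``rpeak_times`` (synthetic only).
    """

    record_id: str
    patient_id: str
    signal: np.ndarray
    fs: float
    intervals: list = field(default_factory=list)
    provenance: str = "synthetic"
    rpeak_times: np.ndarray | None = None
    beat_labels: list | None = None

    def __post_init__(self):
        self.signal = np.asarray(self.signal, dtype=float)
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        n = self.signal.size
        prev_end = None
        for start, end, label in self.intervals:
            if not (0 <= start < end <= n):
                raise ValueError(
                    f"interval [{start}, {end}) outside signal of length {n}"
                )
            if label not in LABELS:
                raise ValueError(f"unknown rhythm label {label!r}")
            if prev_end is not None and start < prev_end:
                raise ValueError("rhythm intervals overlap")
            prev_end = end

    @property
    def duration(self) -> float:
        """Record length in seconds."""
        return self.signal.size / self.fs

    def label_at(self, sample: int) -> str | None:
        """Rhythm label covering ``sample``, or None if unlabeled."""
        for start, end, label in self.intervals:
            if start <= sample < end:
                return label
        return None


@dataclass
class BeatMatrix:
    """Stack of fixed-length beat templates with row-aligned metadata.

    ``samples`` has one row per beat of length pre+post (see
    :mod:`beatae.preprocess`); ``lcsd`` is NaN where the statistic is
    undefined (first/last beat of a recording) or not yet attached.
    """

    samples: np.ndarray                 # (n_beats, L) millivolts
    labels: np.ndarray                  # (n_beats,) strings from LABELS
    record_ids: np.ndarray              # (n_beats,) str
    patient_ids: np.ndarray             # (n_beats,) str
    r_times: np.ndarray                 # (n_beats,) seconds
    fs: float
    padded: np.ndarray | None = None    # (n_beats,) bool
    lcsd: np.ndarray | None = None      # (n_beats,) float, NaN = undefined

    def __post_init__(self):
        self.samples = np.atleast_2d(np.asarray(self.samples, dtype=float))
        n = self.samples.shape[0]
        self.labels = np.asarray(self.labels)
        self.record_ids = np.asarray(self.record_ids)
        self.patient_ids = np.asarray(self.patient_ids)
        self.r_times = np.asarray(self.r_times, dtype=float)
        if self.padded is None:
            self.padded = np.zeros(n, dtype=bool)
        self.padded = np.asarray(self.padded, dtype=bool)
        if self.lcsd is not None:
            self.lcsd = np.asarray(self.lcsd, dtype=float)
        for name in ("labels", "record_ids", "patient_ids", "r_times", "padded"):
            if getattr(self, name).shape[0] != n:
                raise ValueError(f"metadata column {name!r} length mismatch")
        if self.lcsd is not None and self.lcsd.shape[0] != n:
            raise ValueError("lcsd column length mismatch")

    def __len__(self) -> int:
        return self.samples.shape[0]

    @property
    def template_length(self) -> int:
        return self.samples.shape[1]

    def take(self, idx) -> "BeatMatrix":
        """Row subset (keeps metadata aligned)."""
        idx = np.asarray(idx)
        return BeatMatrix(
            samples=self.samples[idx],
            labels=self.labels[idx],
            record_ids=self.record_ids[idx],
            patient_ids=self.patient_ids[idx],
            r_times=self.r_times[idx],
            fs=self.fs,
            padded=self.padded[idx],
            lcsd=None if self.lcsd is None else self.lcsd[idx],
        )

    @staticmethod
    def concatenate(matrices: list["BeatMatrix"]) -> "BeatMatrix":
        """Stack several matrices sharing one fs and template length."""
        if not matrices:
            raise ValueError("nothing to concatenate")
        fs = matrices[0].fs
        if any(m.fs != fs for m in matrices):
            raise ValueError("all matrices must share one sampling rate")
        has_lcsd = all(m.lcsd is not None for m in matrices)
        return BeatMatrix(
            samples=np.vstack([m.samples for m in matrices]),
            labels=np.concatenate([m.labels for m in matrices]),
            record_ids=np.concatenate([m.record_ids for m in matrices]),
            patient_ids=np.concatenate([m.patient_ids for m in matrices]),
            r_times=np.concatenate([m.r_times for m in matrices]),
            fs=fs,
            padded=np.concatenate([m.padded for m in matrices]),
            lcsd=np.concatenate([m.lcsd for m in matrices]) if has_lcsd else None,
        )

    def save_npz(self, path) -> None:
        """Persist to a single NPZ container."""
        np.savez(
            path,
            samples=self.samples,
            labels=self.labels.astype(str),
            record_ids=self.record_ids.astype(str),
            patient_ids=self.patient_ids.astype(str),
            r_times=self.r_times,
            fs=np.array([self.fs]),
            padded=self.padded,
            lcsd=self.lcsd if self.lcsd is not None else np.full(len(self), np.nan),
        )

    @staticmethod
    def load_npz(path) -> "BeatMatrix":
        with np.load(path, allow_pickle=False) as z:
            return BeatMatrix(
                samples=z["samples"],
                labels=z["labels"],
                record_ids=z["record_ids"],
                patient_ids=z["patient_ids"],
                r_times=z["r_times"],
                fs=float(z["fs"][0]),
                padded=z["padded"],
                lcsd=z["lcsd"],
            )
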