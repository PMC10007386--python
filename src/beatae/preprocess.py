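"""From raw ECG to a matrix of fixed-length, outlier-free beat templates.

The chain is: 0.5 Hz FIR high-pass (zero-phase), QRS detection with an
envelope-and-adaptive-threshold scheme in the Hamilton family, local-max
R-peak refinement, clipping of 200 ms-before / 400 ms-after templates,
zero-padding of intruding second R-peaks (70 ms before the next R to also
blank its Q-wave), and cosine-distance outlier rejection against each
recording's average waveform (DMEAN).
"""

from __future__ import annotations

import logging
import math

import numpy as np
from scipy import signal as sps

from .records import AFIB, NSR, BeatMatrix, ECGRecord

__all__ = [
    "PRE_SECONDS",
    "POST_SECONDS",
    "template_window",
    "highpass_filter",
    "detect_rpeaks",
    "refine_rpeaks",
    "segment_beats",
    "pad_second_rpeak",
    "dmean_filter",
    "preprocess_record",
]

log = logging.getLogger(__name__)

PRE_SECONDS = 0.2     # template window before the R-peak
POST_SECONDS = 0.4    # template window after the R-peak
PAD_LEAD_SECONDS = 0.07   # zero-padding starts this much before a second R
HIGHPASS_CUTOFF = 0.5     # Hz


def _round_half_away(x: float) -> int:
    """Round half away from zero (used for window sample counts)."""
    return int(math.floor(x + 0.5)) if x >= 0 else int(math.ceil(x - 0.5))


def template_window(fs: float) -> tuple[int, int]:
    """(pre, post) sample counts; template length is pre + post with the
    R-peak at index pre."""
    return _round_half_away(PRE_SECONDS * fs), _round_half_away(POST_SECONDS * fs)


def highpass_taps(fs: float, cutoff: float = HIGHPASS_CUTOFF) -> np.ndarray:
    """Windowed-sinc high-pass FIR: delta minus a unit-DC-gain Hamming
    low-pass, so DC is rejected to machine precision.  Order ~= 3*fs
    (odd) keeps the transition narrow enough to attenuate 0.2 Hz by more
    than 20 dB while leaving 10 Hz untouched."""
    numtaps = int(3 * fs) | 1
    lp = sps.firwin(numtaps, cutoff, window="hamming", fs=fs)
    lp /= lp.sum()
    hp = -lp
    hp[numtaps // 2] += 1.0
    return hp


def highpass_filter(signal: np.ndarray, fs: float) -> np.ndarray:
    """Apply the 0.5 Hz high-pass with group-delay compensation.

    The FIR is linear-phase and applied centered (``mode='same'``), so
    R-peak positions are preserved exactly.  Raises if the signal is
    shorter than the filter.
    """
    if fs <= 1:
        raise ValueError("sampling rate must exceed 1 Hz")
    signal = np.asarray(signal, dtype=float)
    taps = highpass_taps(fs)
    if signal.size < taps.size:
        raise ValueError(
            f"signal ({signal.size} samples) shorter than filter ({taps.size} taps)"
        )
    return sps.fftconvolve(signal, taps, mode="same")


def detect_rpeaks(signal: np.ndarray, fs: float) -> np.ndarray:
    """QRS detection: band-pass -> differentiate -> rectify -> moving
    average -> adaptive threshold with a 200 ms refractory period.

    Envelope peaks accepted by the running signal/noise threshold are
    mapped back to the R-peak by taking the local absolute maximum of the
    input within +/-100 ms.  Returns strictly increasing sample indices;
    empty for flat signals.
    """
    signal = np.asarray(signal, dtype=float)
    if signal.size == 0 or np.ptp(signal) == 0:
        return np.array([], dtype=int)

    # QRS energy lives around 8-16 Hz
    numtaps = int(0.3 * fs) | 1
    bp = sps.firwin(numtaps, [8.0, 16.0], pass_zero=False, fs=fs)
    filtered = sps.fftconvolve(signal, bp, mode="same")
    envelope = np.abs(np.diff(filtered, prepend=filtered[0]))
    win = max(1, int(round(0.08 * fs)))
    envelope = np.convolve(envelope, np.ones(win) / win, mode="same")

    refractory = int(round(0.2 * fs))
    cand, _ = sps.find_peaks(envelope, distance=refractory)
    if cand.size == 0:
        return np.array([], dtype=int)

    # Hamilton-style running estimates of QRS and noise peak heights
    spk = float(np.max(envelope[: int(2 * fs)])) if signal.size >= 2 * fs else float(
        np.max(envelope)
    )
    npk = float(np.mean(envelope))
    accepted = []
    for idx in cand:
        height = envelope[idx]
        threshold = npk + 0.3125 * (spk - npk)
        if height > threshold:
            accepted.append(idx)
            spk = 0.125 * height + 0.875 * spk
        else:
            npk = 0.125 * height + 0.875 * npk
    if not accepted:
        return np.array([], dtype=int)

    refined = refine_rpeaks(signal, np.array(accepted), fs, radius=0.1)
    # enforce refractory after refinement
    out = [refined[0]]
    for idx in refined[1:]:
        if idx - out[-1] >= refractory:
            out.append(idx)
    return np.array(out, dtype=int)


def refine_rpeaks(
    signal: np.ndarray,
    candidates: np.ndarray,
    fs: float,
    radius: float = 0.05,
) -> np.ndarray:
    """Move each candidate to the local absolute maximum within
    ``+/-radius`` seconds; preserves order and merges duplicates."""
    signal = np.asarray(signal, dtype=float)
    candidates = np.asarray(candidates, dtype=int)
    r = max(1, int(round(radius * fs)))
    refined = []
    for idx in candidates:
        lo = max(0, idx - r)
        hi = min(signal.size, idx + r + 1)
        refined.append(lo + int(np.argmax(np.abs(signal[lo:hi]))))
    return np.unique(np.array(refined, dtype=int))


def segment_beats(
    signal: np.ndarray,
    rpeaks: np.ndarray,
    fs: float,
    intervals: list,
    record_id: str = "",
    patient_id: str = "",
) -> BeatMatrix:
    """Clip one template per R-peak: ``pre`` samples before to ``post``
    samples after, keeping only beats whose full window lies inside the
    signal and inside a single NSR or AFib interval.  Beats in ``other``
    intervals or straddling interval boundaries are dropped (count
    logged).  The template label is the interval label.
    """
    signal = np.asarray(signal, dtype=float)
    rpeaks = np.asarray(rpeaks, dtype=int)
    pre, post = template_window(fs)
    rows, labels, r_times = [], [], []
    dropped = 0
    for rp in rpeaks:
        lo, hi = rp - pre, rp + post
        if lo < 0 or hi > signal.size:
            dropped += 1
            continue
        label = None
        for start, end, lab in intervals:
            if start <= lo and hi <= end:
                label = lab
                break
        if label not in (NSR, AFIB):
            dropped += 1
            continue
        rows.append(signal[lo:hi])
        labels.append(label)
        r_times.append(rp / fs)
    if dropped:
        log.debug("segment_beats: dropped %d boundary/other beats", dropped)
    n = len(rows)
    return BeatMatrix(
        samples=np.array(rows).reshape(n, pre + post),
        labels=np.array(labels, dtype=object) if n else np.empty(0, dtype=object),
        record_ids=np.full(n, record_id, dtype=object),
        patient_ids=np.full(n, patient_id, dtype=object),
        r_times=np.array(r_times),
        fs=fs,
    )


def pad_second_rpeak(
    template: np.ndarray, next_rr: float, fs: float
) -> tuple[np.ndarray, bool]:
    """Blank an intruding second R-peak with trailing zeros.

    If the next RR-interval is shorter than the 400 ms post-window, the
    second beat's QRS intrudes into this template; every sample from
    ``pre + rint((next_rr - 0.07) * fs)`` to the end is zeroed so the
    padding also covers the intruder's Q-wave.  Returns the (possibly
    copied) template and a flag saying whether padding was applied.
    Idempotent: re-padding an already padded template changes nothing.
    """
    template = np.asarray(template, dtype=float)
    if next_rr >= POST_SECONDS:
        return template, False
    pre, _ = template_window(fs)
    start = pre + int(np.rint((next_rr - PAD_LEAD_SECONDS) * fs))
    if start < pre:
        log.warning("pad_second_rpeak: start before R-peak; zeroing whole tail")
        start = pre
    out = template.copy()
    out[start:] = 0.0
    return out, True


def dmean_filter(
    matrix: BeatMatrix,
    threshold: float = 0.2,
    max_fraction: float = 0.3,
) -> tuple[BeatMatrix, np.ndarray]:
    """Cosine-distance outlier rejection against the average waveform.

    Operates per recording: the mean template is computed over all of a
    recording's beats, and beat i is flagged when
    ``d_i = 1 - x_i.m / (|x_i||m|) > threshold``.  Zero-norm beats are
    flagged unconditionally.  At most ``max_fraction`` of a recording's
    beats are removed; beyond that the lowest-distance beats are kept and
    a warning logged.  Returns the kept matrix and the removed row
    indices (into the input matrix).
    """
    outliers: list[int] = []
    for rec in np.unique(matrix.record_ids):
        rows = np.flatnonzero(matrix.record_ids == rec)
        if rows.size < 2:
            continue
        x = matrix.samples[rows]
        m = x.mean(axis=0)
        m_norm = np.linalg.norm(m)
        x_norms = np.linalg.norm(x, axis=1)
        d = np.full(rows.size, 2.0)  # zero-norm beats get the maximum distance
        ok = (x_norms > 0) & (m_norm > 0)
        if m_norm > 0:
            d[ok] = 1.0 - (x[ok] @ m) / (x_norms[ok] * m_norm)
        flagged = np.flatnonzero((d > threshold) | (x_norms == 0))
        cap = int(math.floor(max_fraction * rows.size))
        if flagged.size > cap:
            log.warning(
                "dmean_filter: %d/%d beats of %s over threshold; keeping the "
                "lowest-distance ones (cap %d)",
                flagged.size, rows.size, rec, cap,
            )
            flagged = flagged[np.argsort(d[flagged], kind="stable")[-cap:]] if cap else \
                np.array([], dtype=int)
        outliers.extend(rows[flagged])
    outliers_arr = np.array(sorted(outliers), dtype=int)
    keep = np.setdiff1d(np.arange(len(matrix)), outliers_arr)
    return matrix.take(keep), outliers_arr


def preprocess_record(
    record: ECGRecord,
    dmean_threshold: float = 0.2,
    use_provided_rpeaks: bool = False,
) -> tuple[BeatMatrix, np.ndarray]:
    """Full per-record chain: high-pass, R-peak detection (or refinement
    of provided candidates), segmentation, second-R-peak padding, DMEAN.

    Returns the kept beat matrix and the detected R-peak sample indices
    (the series used downstream for the LCSD denominator).
    """
    filtered = highpass_filter(record.signal, record.fs)
    if use_provided_rpeaks and record.rpeak_times is not None:
        cand = np.round(np.asarray(record.rpeak_times) * record.fs).astype(int)
        cand = cand[(cand >= 0) & (cand < filtered.size)]
        rpeaks = refine_rpeaks(filtered, cand, record.fs)
    else:
        rpeaks = detect_rpeaks(filtered, record.fs)
    matrix = segment_beats(
        filtered, rpeaks, record.fs, record.intervals,
        record_id=record.record_id, patient_id=record.patient_id,
    )
    # pad templates whose successor R-peak intrudes into the post-window
    rp_times = rpeaks / record.fs
    next_rr = {rp_times[i]: rp_times[i + 1] - rp_times[i] for i in range(len(rp_times) - 1)}
    for i in range(len(matrix)):
        rr = next_rr.get(matrix.r_times[i])
        if rr is not None:
            matrix.samples[i], matrix.padded[i] = pad_second_rpeak(
                matrix.samples[i], rr, record.fs
            )
    kept, _ = dmean_filter(matrix, threshold=dmean_threshold)
    return kept, rpeaks
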