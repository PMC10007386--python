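"""Rhythm feature (LCSD) and feature standardization.

The Local Change of Successive Differences (LCSD) is a per-beat,
dimensionless measure of local RR-interval irregularity.  For R-peaks at
times R_1 .. R_N, the statistic at interior beat i (1 < i < N) is

    LCSD(R_i) = |(R_{i+1} - R_i) - (R_i - R_{i-1})| / mean-RR,

where mean-RR is the average RR-interval of the recording (all N-1
intervals of the detected R series, including beats later discarded as
morphological outliers).  AFib's irregular ventricular response drives
the numerator up, while the normalization makes the statistic invariant
to uniform time scaling, so slow and fast hearts are comparable.  The
first and last beats have no two adjacent RR-intervals and are marked
undefined (NaN), never 0.
"""

from __future__ import annotations

import json
import logging

import numpy as np

from .records import BeatMatrix

__all__ = ["compute_lcsd", "attach_lcsd", "Standardizer"]

log = logging.getLogger(__name__)


def compute_lcsd(r_times: np.ndarray) -> np.ndarray:
    """Per-beat LCSD for a strictly increasing R-time series (seconds).

    Returns an array aligned with ``r_times``; boundary beats (and every
    beat when N < 3) are NaN.  Raises on non-monotone input.
    """
    r = np.asarray(r_times, dtype=float)
    n = r.size
    out = np.full(n, np.nan)
    if n < 3:
        return out
    rr = np.diff(r)
    if np.any(rr <= 0):
        raise ValueError("R-peak times must be strictly increasing")
    mean_rr = rr.mean()
    out[1:-1] = np.abs(rr[1:] - rr[:-1]) / mean_rr
    return out


def attach_lcsd(
    matrix: BeatMatrix,
    rpeak_series: dict[str, np.ndarray],
    drop_undefined: bool = True,
) -> BeatMatrix:
    """Attach an LCSD column to a beat matrix.

    ``rpeak_series`` maps each record id to the full detected R-time
    series (seconds) of that recording — not merely the surviving beats,
    since the statistic is defined on the R series itself.  Each beat is
    matched to its R-peak by nearest time (within half a sample).  Beats
    with undefined LCSD (recording endpoints) are dropped when
    ``drop_undefined`` (count logged), kept as NaN otherwise.
    """
    lcsd = np.full(len(matrix), np.nan)
    half_sample = 0.5 / matrix.fs
    for rec in np.unique(matrix.record_ids):
        if rec not in rpeak_series:
            raise KeyError(f"no R-peak series for recording {rec!r}")
        r = np.asarray(rpeak_series[rec], dtype=float)
        values = compute_lcsd(r)
        rows = np.flatnonzero(matrix.record_ids == rec)
        for i in rows:
            j = int(np.argmin(np.abs(r - matrix.r_times[i])))
            if abs(r[j] - matrix.r_times[i]) <= half_sample + 1e-12:
                lcsd[i] = values[j]
    out = BeatMatrix(
        samples=matrix.samples,
        labels=matrix.labels,
        record_ids=matrix.record_ids,
        patient_ids=matrix.patient_ids,
        r_times=matrix.r_times,
        fs=matrix.fs,
        padded=matrix.padded,
        lcsd=lcsd,
    )
    if drop_undefined:
        keep = np.flatnonzero(~np.isnan(lcsd))
        n_drop = len(out) - keep.size
        if n_drop:
            log.debug("attach_lcsd: dropped %d beats with undefined LCSD", n_drop)
        out = out.take(keep)
    return out


class Standardizer:
    """Per-feature zero-mean/unit-sd transform learned from training data.

    Fit on training rows only; validation and test are transformed with
    the training statistics.  Constant features get sd replaced by 1
    (logged) so they map to zero rather than dividing by zero.
    """

    def __init__(self):
        self.means_: np.ndarray | None = None
        self.sds_: np.ndarray | None = None

    def fit(self, x: np.ndarray) -> "Standardizer":
        x = np.asarray(x, dtype=float)
        self.means_ = x.mean(axis=0)
        sds = x.std(axis=0)
        n_const = int(np.sum(sds == 0))
        if n_const:
            log.warning("Standardizer: %d constant feature(s); sd set to 1", n_const)
        sds = np.where(sds == 0, 1.0, sds)
        self.sds_ = sds
        return self

    def transform(self, x: np.ndarray) -> np.ndarray:
        if self.means_ is None:
            raise RuntimeError("Standardizer.transform called before fit")
        return (np.asarray(x, dtype=float) - self.means_) / self.sds_

    def fit_transform(self, x: np.ndarray) -> np.ndarray:
        return self.fit(x).transform(x)

    def save_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {"means": self.means_.tolist(), "sds": self.sds_.tolist()}, fh
            )

    @staticmethod
    def load_json(path) -> "Standardizer":
        with open(path) as fh:
            blob = json.load(fh)
        s = Standardizer()
        s.means_ = np.array(blob["means"])
        s.sds_ = np.array(blob["sds"])
        return s


def export_lcsd_csv(matrix: BeatMatrix, path) -> None:
    """Write `recording,beat_index,R_time_s,lcsd` rows."""
    if matrix.lcsd is None:
        raise ValueError("matrix has no LCSD column")
    with open(path, "w") as fh:
        fh.write("recording,beat_index,R_time_s,lcsd\n")
        for i in range(len(matrix)):
            fh.write(
                f"{matrix.record_ids[i]},{i},{matrix.r_times[i]:.6f},"
                f"{matrix.lcsd[i]:.9g}\n"
            )
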