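"""Run the preprocessing chain on a short-RR AFib recording.

High-pass filtering, QRS detection, 200/400 ms template clipping,
zero-padding of intruding second R-peaks, and DMEAN outlier rejection.
The short-RR preset guarantees some templates contain a second R-peak,
so the padding path is visible.
"""

import numpy as np

from beatae import AFIB_SHORT_RR_RHYTHM, NoiseParams, generate_record, template_window
from beatae.preprocess import (
    detect_rpeaks,
    dmean_filter,
    highpass_filter,
    preprocess_record,
    segment_beats,
)

rec = generate_record(
    AFIB_SHORT_RR_RHYTHM,
    noise=NoiseParams(white_sd=0.03, wander_amplitude=0.1, seed=7),
    duration=60.0,
    fs=250.0,
)
pre, post = template_window(rec.fs)
print(f"template window: {pre} samples before R, {post} after "
      f"(length {pre + post} at {rec.fs:.0f} Hz)")

filtered = highpass_filter(rec.signal, rec.fs)
rpeaks = detect_rpeaks(filtered, rec.fs)
true = np.round(rec.rpeak_times * rec.fs).astype(int)
hits = sum(np.min(np.abs(rpeaks - t)) <= 2 for t in true)
print(f"QRS detection: {rpeaks.size} detections, "
      f"{hits}/{true.size} within 2 samples of ground truth")

raw = segment_beats(filtered, rpeaks, rec.fs, rec.intervals,
                    record_id=rec.record_id, patient_id=rec.patient_id)
matrix, _ = preprocess_record(rec)
kept, outliers = dmean_filter(raw, threshold=0.2)
print(f"segmented {len(raw)} beats; DMEAN removed {outliers.size}; "
      f"{int(matrix.padded.sum())} templates zero-padded "
      f"(second R-peak within the 400 ms post-window)")
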