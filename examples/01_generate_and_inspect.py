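"""Generate synthetic NSR and AFib recordings and inspect their rhythm.

Builds one recording per class with the default presets and prints the
RR-interval statistics and the median per-beat LCSD.  AFib should show a
similar mean RR but a far larger RR spread and LCSD — the rhythm
signature the classifier exploits.
"""

import numpy as np

from beatae import (
    AFIB_RHYTHM,
    NSR_RHYTHM,
    NoiseParams,
    compute_lcsd,
    generate_record,
)

for rhythm in (NSR_RHYTHM, AFIB_RHYTHM):
    rec = generate_record(
        rhythm,
        noise=NoiseParams(white_sd=0.02, wander_amplitude=0.1, seed=1),
        duration=120.0,
        fs=250.0,
    )
    rr = np.diff(rec.rpeak_times)
    lcsd = compute_lcsd(rec.rpeak_times)
    print(
        f"{rhythm.label:5s}: {len(rec.rpeak_times)} beats, "
        f"RR {rr.mean():.3f} +/- {rr.std():.3f} s, "
        f"median LCSD {np.nanmedian(lcsd):.4f}"
    )

print(
    "\nThe mean heart rates overlap, but AFib's successive-difference "
    "statistic (LCSD) is an order of magnitude larger."
)
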