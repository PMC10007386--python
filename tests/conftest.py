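import numpy as np
import pytest

from beatae import (
    AFIB_SHORT_RR_RHYTHM,
    NoiseParams,
    RhythmParams,
    generate_record,
)
from beatae.records import NSR

NOISELESS = NoiseParams(white_sd=0.0, wander_amplitude=0.0)


@pytest.fixture(scope="session")
def clean_nsr_record():
    """Perfectly regular noiseless NSR: RR exactly 0.8 s, fs 250 Hz."""
    return generate_record(
        RhythmParams(label=NSR, mean_rr=0.8, sd_rr=0.0),
        noise=NOISELESS,
        duration=10.0,
        fs=250.0,
    )


@pytest.fixture(scope="session")
def short_rr_afib_record():
    """Noiseless AFib with the short-RR preset, guaranteeing templates
    that contain a second R-peak."""
    return generate_record(
        AFIB_SHORT_RR_RHYTHM,
        noise=NoiseParams(white_sd=0.0, wander_amplitude=0.0, seed=7),
        duration=60.0,
        fs=250.0,
    )


@pytest.fixture(scope="session")
def standardized_beats():
    """Small standardized beat matrix (both classes) for network tests."""
    from beatae.experiment import _resolve_config, build_beat_matrix
    from beatae.features import Standardizer

    cfg = _resolve_config(
        {"data": {"n_records_per_class": 5, "duration": 40.0, "seed": 5}}
    )
    matrix, _ = build_beat_matrix(cfg)
    x = Standardizer().fit_transform(matrix.samples)
    y = (matrix.labels == "AFib").astype(float)
    return x, y
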