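import numpy as np
import pytest

import caficu as cf
from caficu.prd import compute_prd, dt_angles, locate_t_waves, t_vector_series, to_orthogonal


def prd_pipeline(rec):
    """Record -> PRD value + dT series + intermediates, shared across tests."""
    beats = cf.detect_r_peaks(rec)
    rr = cf.build_rr_series(beats)
    vcg = to_orthogonal(rec)
    windows = locate_t_waves(vcg, beats, rr=rr)
    tv = t_vector_series(vcg, windows, beats)
    dts = dt_angles(tv)
    return compute_prd(dts), dts, tv, beats


@pytest.fixture(scope="session")
def sinus_rr():
    series, truth = cf.simulate_rr(cf.RrSimConfig(seed=0))
    return series, truth


@pytest.fixture(scope="session")
def clean_ecg():
    """Noise-free 3-lead record with constant T-wave axis."""
    return cf.simulate_ecg(cf.EcgSimConfig(duration_s=120.0, seed=1))


@pytest.fixture(scope="session")
def band_response():
    """PRD of metronomic-beat records with T-axis rotation at several
    amplitudes/frequencies.

    Metronomic beats isolate the analyzer's band selectivity: with beat-interval
    variability the generator itself demodulates fast rotation into genuine
    low-frequency angle power.
    """
    out = {}
    for key, amp, freq in [
        ("amp0", 0.0, 0.08),
        ("amp5", 5.0, 0.08),
        ("amp10", 10.0, 0.08),
        ("out_of_band", 10.0, 0.40),
    ]:
        rec, _ = cf.simulate_ecg(
            cf.EcgSimConfig(
                duration_s=300.0,
                mean_rr_ms=750.0,
                rr_resp_amp_ms=0.0,
                rr_noise_ms=0.0,
                t_axis_amp_deg=amp,
                t_axis_freq_hz=freq,
                seed=3,
            )
        )
        value, _, _, _ = prd_pipeline(rec)
        out[key] = value.prd_deg2
    return out
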