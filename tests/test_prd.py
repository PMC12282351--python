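"""Vectorcardiogram conversion, T-vector averaging, dT angles, and the
low-frequency wavelet quantification."""

import numpy as np
import pytest

import caficu as cf
from caficu.errors import InsufficientDataError, InsufficientLeadsError
from caficu.prd import (
    KORS_LEADS,
    KORS_MATRIX,
    DTSeries,
    TVectorSeries,
    TWaveWindow,
    Vcg,
    compute_prd,
    dt_angles,
    locate_t_waves,
    morlet_cwt,
    t_vector,
    to_orthogonal,
)
from caficu.signal_io import EcgRecord
from tests.conftest import prd_pipeline


class TestToOrthogonal:
    def test_identity_transform_passes_leads_through(self, clean_ecg):
        rec, _ = clean_ecg
        vcg = to_orthogonal(rec, "identity")
        assert np.array_equal(vcg.x, rec.samples[0])
        assert np.array_equal(vcg.y, rec.samples[1])
        assert np.array_equal(vcg.z, rec.samples[2])

    def test_axis_sample_angles(self):
        vcg = Vcg(np.array([1.0]), np.array([0.0]), np.array([0.0]), fs=250.0)
        assert vcg.amplitude[0] == pytest.approx(1.0)
        assert vcg.azimuth[0] == pytest.approx(0.0)
        assert vcg.elevation[0] == pytest.approx(0.0)

    def test_y_axis_gives_90_elevation(self):
        vcg = Vcg(np.array([0.0]), np.array([2.0]), np.array([0.0]), fs=250.0)
        assert vcg.elevation[0] == pytest.approx(90.0)
        assert vcg.amplitude[0] == pytest.approx(2.0)

    def test_kors_matches_hand_matrix_product(self):
        rng = np.random.default_rng(2)
        leads = rng.normal(0, 0.5, (8, 1000))
        rec = EcgRecord(leads, 250.0, KORS_LEADS)
        vcg = to_orthogonal(rec, "kors")
        expected = KORS_MATRIX @ leads
        assert np.allclose([vcg.x, vcg.y, vcg.z], expected, atol=1e-12)

    def test_two_leads_signal_prd_unavailable(self):
        rec = EcgRecord(np.zeros((2, 1000)), 250.0, ["I", "II"])
        with pytest.raises(InsufficientLeadsError):
            to_orthogonal(rec)

    def test_amplitude_is_vector_norm_everywhere(self, clean_ecg):
        rec, _ = clean_ecg
        vcg = to_orthogonal(rec)
        assert np.allclose(vcg.amplitude, np.sqrt(vcg.x**2 + vcg.y**2 + vcg.z**2))


class TestLocateTWaves:
    def test_windows_cover_true_support(self, clean_ecg):
        rec, truth = clean_ecg
        beats = cf.detect_r_peaks(rec)
        rr = cf.build_rr_series(beats)
        vcg = to_orthogonal(rec)
        windows = locate_t_waves(vcg, beats, rr=rr)
        assert len(windows) >= len(beats.r_samples) - 3
        lo_ms, hi_ms = truth.t_support_ms
        fs = rec.fs
        for win in windows[:20]:
            r = beats.r_samples[win.beat_index]
            support = np.arange(r + int(lo_ms / 1000 * fs), r + int(hi_ms / 1000 * fs))
            covered = np.intersect1d(support, np.arange(win.start, win.end))
            assert len(covered) >= 0.9 * len(support)

    def test_ectopic_beats_skipped(self, clean_ecg):
        rec, _ = clean_ecg
        beats = cf.detect_r_peaks(rec)
        beats.labels[5] = "ectopic"
        vcg = to_orthogonal(rec)
        windows = locate_t_waves(vcg, beats)
        assert all(w.beat_index != 5 for w in windows)

    def test_empty_beats_give_empty_windows(self, clean_ecg):
        rec, _ = clean_ecg
        vcg = to_orthogonal(rec)
        beats = cf.BeatSeries(np.array([100]), np.array(["normal"], dtype=object), rec.fs)
        assert locate_t_waves(vcg, beats) == []


class TestTVector:
    def test_constant_direction_recovered_exactly(self):
        n = 50
        amp = np.linspace(0.1, 1.0, n)
        az, el = 35.0, 20.0
        u = np.array([
            np.cos(np.radians(el)) * np.cos(np.radians(az)),
            np.sin(np.radians(el)),
            np.cos(np.radians(el)) * np.sin(np.radians(az)),
        ])
        vcg = Vcg(amp * u[0], amp * u[1], amp * u[2], fs=250.0)
        res = t_vector(vcg, TWaveWindow(0, 0, n))
        assert res[0] == pytest.approx(az, abs=1e-9)
        assert res[1] == pytest.approx(el, abs=1e-9)

    def test_two_sample_weighted_mean(self):
        # amplitudes (1, 3) at azimuths (0, 40) -> weighted azimuth 30
        az = np.radians([0.0, 40.0])
        x = np.array([1.0, 3.0]) * np.cos(az)
        z = np.array([1.0, 3.0]) * np.sin(az)
        vcg = Vcg(x, np.zeros(2), z, fs=250.0)
        res = t_vector(vcg, TWaveWindow(0, 0, 2))
        assert res[0] == pytest.approx(30.0, abs=1e-9)

    def test_matches_loop_oracle(self):
        rng = np.random.default_rng(3)
        vcg = Vcg(*rng.normal(0, 1, (3, 40)), fs=250.0)
        res = t_vector(vcg, TWaveWindow(0, 5, 35))
        w = vcg.amplitude[5:35]
        az_o = sum(wi * ai for wi, ai in zip(w, vcg.azimuth[5:35])) / w.sum()
        el_o = sum(wi * ei for wi, ei in zip(w, vcg.elevation[5:35])) / w.sum()
        assert res[0] == pytest.approx(az_o, abs=1e-9)
        assert res[1] == pytest.approx(el_o, abs=1e-9)
        assert np.linalg.norm(res[2]) == pytest.approx(1.0)

    def test_zero_amplitude_window_drops_beat(self):
        vcg = Vcg(np.zeros(10), np.zeros(10), np.zeros(10), fs=250.0)
        assert t_vector(vcg, TWaveWindow(0, 0, 10)) is None


def _tv(units, times=None):
    units = np.asarray(units, float)
    units = units / np.linalg.norm(units, axis=1, keepdims=True)
    n = len(units)
    return TVectorSeries(np.zeros(n), np.zeros(n), times if times is not None else np.arange(n, dtype=float), units)


class TestDtAngles:
    @pytest.mark.parametrize(
        "u1,u2,expected",
        [
            ((1, 0, 0), (1, 0, 0), 0.0),
            ((1, 0, 0), (0, 1, 0), 90.0),
            ((1, 0, 0), (0.5, 0.5, np.sqrt(0.5)), 60.0),
        ],
    )
    def test_closed_form_pairs(self, u1, u2, expected):
        dts = dt_angles(_tv([u1, u2]))
        assert dts.dtheta_deg[0] == pytest.approx(expected, abs=1e-9)

    def test_rotation_invariance(self):
        rng = np.random.default_rng(4)
        units = rng.normal(0, 1, (30, 3))
        from scipy.spatial.transform import Rotation

        rot = Rotation.random(random_state=7).as_matrix()
        a = dt_angles(_tv(units))
        b = dt_angles(_tv(units @ rot.T))
        assert np.allclose(a.dtheta_deg, b.dtheta_deg, atol=1e-9)

    def test_single_vector_raises(self):
        with pytest.raises(InsufficientDataError):
            dt_angles(_tv([(1, 0, 0)]))


def _dts(x, t):
    return DTSeries(np.asarray(x, float), np.asarray(t, float))


class TestComputePrd:
    def test_constant_series_zero(self):
        t = np.arange(0, 300, 0.8)
        v = compute_prd(_dts(np.full(len(t), 7.0), t))
        assert v.prd_deg2 == pytest.approx(0.0, abs=1e-20)

    def test_band_selectivity_on_raw_series(self):
        t = np.arange(0, 300, 0.8)
        in_band = compute_prd(_dts(5 + 2 * np.sin(2 * np.pi * 0.08 * t), t))
        out_band = compute_prd(_dts(5 + 2 * np.sin(2 * np.pi * 0.3 * t), t))
        assert in_band.prd_deg2 > 10 * out_band.prd_deg2

    def test_quadratic_amplitude_scaling(self):
        t = np.arange(0, 300, 0.8)
        x = np.sin(2 * np.pi * 0.05 * t)
        p1 = compute_prd(_dts(5 + x, t)).prd_deg2
        p2 = compute_prd(_dts(5 + 2 * x, t)).prd_deg2
        assert p2 == pytest.approx(4.0 * p1, rel=1e-9)

    def test_time_shift_and_offset_invariance(self):
        t = np.arange(0, 300, 0.8)
        x = 2 * np.sin(2 * np.pi * 0.05 * t)
        a = compute_prd(_dts(5 + x, t)).prd_deg2
        b = compute_prd(_dts(12 + x, t + 7200.0)).prd_deg2
        assert b == pytest.approx(a, rel=1e-9)

    def test_short_series_flagged(self):
        t = np.arange(0, 20, 0.8)
        v = compute_prd(_dts(np.sin(t), t))
        assert v.prd_deg2 is None
        assert "short_series" in v.flags

    def test_agrees_with_pywt_cwt_in_passband(self):
        """Independent cross-check: pywt's conv-based CWT and the FFT filter
        bank must agree on relative passband response (quadratic in amplitude,
        same in-band/out-of-band ordering)."""
        pywt = pytest.importorskip("pywt")
        t = np.arange(0, 300, 0.25)
        freqs = np.geomspace(0.01, 0.1, 12)
        scales = pywt.frequency2scale("cmor0.5-1.0", freqs * 0.25)

        def pywt_power(x):
            c, _ = pywt.cwt(x - x.mean(), scales, "cmor0.5-1.0", sampling_period=0.25)
            return np.mean(np.abs(c) ** 2)

        def ours(x):
            c = morlet_cwt(x - x.mean(), freqs, 4.0)
            return np.mean(np.abs(c) ** 2)

        x1 = np.sin(2 * np.pi * 0.05 * t)
        x2 = 2 * np.sin(2 * np.pi * 0.05 * t)
        assert pywt_power(x2) / pywt_power(x1) == pytest.approx(4.0, rel=1e-3)
        assert ours(x2) / ours(x1) == pytest.approx(4.0, rel=1e-6)
        xo = 2 * np.sin(2 * np.pi * 0.3 * t)
        assert pywt_power(x2) > pywt_power(xo)
        assert ours(x2) > ours(xo)


class TestPipeline:
    def test_no_modulation_gives_near_zero_dt(self, clean_ecg):
        rec, _ = clean_ecg
        _, dts, _, _ = prd_pipeline(rec)
        assert dts.dtheta_deg.max() <= 1.0

    def test_dt_matches_generator_truth(self):
        rec, truth = cf.simulate_ecg(
            cf.EcgSimConfig(duration_s=120.0, t_axis_amp_deg=10.0, seed=6)
        )
        _, dts, tv, beats = prd_pipeline(rec)
        match = np.abs(
            beats.r_samples[tv.beat_indices][:, None] - truth.r_samples[None, :]
        ).argmin(axis=1)
        dirs = truth.t_directions[match]
        true_angles = np.degrees(
            np.arccos(np.clip(np.sum(dirs[:-1] * dirs[1:], axis=1), -1, 1))
        )
        assert np.abs(dts.dtheta_deg - true_angles).max() < 1e-6

    def test_monotone_in_modulation_amplitude(self, band_response):
        assert band_response["amp10"] > band_response["amp5"] > band_response["amp0"]
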