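"""Synthetic data with known ground truth.

Three generators, each a pure function of its config and seed:

* :func:`simulate_rr` — RR series as a sum of respiratory (HF) and
  low-frequency sinusoidal modulation, transient deceleration bursts, and
  Gaussian noise, evaluated at the actual cumulative beat times.
* :func:`simulate_ecg` — a 3-lead orthogonal-lead ECG built from a
  sum-of-Gaussians P-QRS-T dipole whose T-wave direction is rigidly rotated
  about a fixed axis by ``amp_deg * sin(2*pi*f*t)``; the true per-beat
  repolarization direction and the true angle series between successive beats
  (exactly ``|delta theta|``) are exported.
* :func:`simulate_cohort` — marker distributions shaped like the published
  ICU cohort, 30-day exponential survival with hazard proportional to
  ``exp(beta_prd*PRD + beta_dc*DC)`` on the capped markers, administrative
  censoring at day 30 (discharged-alive patients are censored at day 30,
  matching the endpoint construction).

The ground-truth exports are sufficient to score every downstream operation
without re-deriving truth.
"""

from __future__ import annotations

import datetime
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .rhythm import RRSeries
from .score import ScoreCoefficients, cap_markers, compute_caf, reference_coefficients
from .signal_io import EcgRecord

FOLLOW_UP = 30.0  # days; administrative censoring horizon


# ------------------------------------------------------------------ RR series

@dataclass
class RrSimConfig:
    mean_rr_ms: float = 800.0
    resp_freq_hz: float = 0.25
    resp_amp_ms: float = 20.0
    lf_freq_hz: float = 0.1
    lf_amp_ms: float = 10.0
    burst_rate_per_min: float = 2.0
    burst_magnitude_ms: float = 30.0
    noise_sd_ms: float = 5.0
    n_beats: int = 1800
    seed: int = 0

    def __post_init__(self) -> None:
        if not 300.0 <= self.mean_rr_ms <= 2000.0:
            raise ValueError("mean_rr_ms must lie in [300, 2000]")
        for f in ("resp_amp_ms", "lf_amp_ms", "burst_magnitude_ms", "noise_sd_ms"):
            if getattr(self, f) < 0:
                raise ValueError(f"{f} must be non-negative")


@dataclass
class RrGroundTruth:
    resp_amp_ms: float
    lf_amp_ms: float
    burst_indices: np.ndarray
    burst_magnitude_ms: float


_BURST_SHAPE = np.array([0.5, 1.0, 0.5])


def simulate_rr(cfg: RrSimConfig) -> tuple[RRSeries, RrGroundTruth]:
    rng = np.random.default_rng(cfg.seed)
    rr = np.empty(cfg.n_beats)
    t = 0.0
    for i in range(cfg.n_beats):
        base = (
            cfg.mean_rr_ms
            + cfg.resp_amp_ms * np.sin(2 * np.pi * cfg.resp_freq_hz * t)
            + cfg.lf_amp_ms * np.sin(2 * np.pi * cfg.lf_freq_hz * t)
        )
        rr[i] = base + (rng.normal(0.0, cfg.noise_sd_ms) if cfg.noise_sd_ms > 0 else 0.0)
        t += rr[i] / 1000.0
    total_min = rr.sum() / 60000.0
    n_bursts = rng.poisson(cfg.burst_rate_per_min * total_min) if cfg.burst_rate_per_min > 0 else 0
    burst_idx = np.sort(rng.integers(1, cfg.n_beats - 2, size=n_bursts)) if n_bursts else np.array([], dtype=int)
    for b in burst_idx:
        rr[b - 1 : b + 2] += cfg.burst_magnitude_ms * _BURST_SHAPE[: len(rr[b - 1 : b + 2])]
    beat_time_s = np.cumsum(rr) / 1000.0
    series = RRSeries(rr, beat_time_s, np.ones(cfg.n_beats, dtype=bool))
    return series, RrGroundTruth(cfg.resp_amp_ms, cfg.lf_amp_ms, burst_idx, cfg.burst_magnitude_ms)


# ----------------------------------------------------------------- ECG record

@dataclass
class EcgSimConfig:
    fs: float = 250.0
    duration_s: float = 300.0
    mean_rr_ms: float = 800.0
    qrs_amp_mv: float = 1.2
    qrs_sigma_ms: float = 12.0
    t_amp_mv: float = 0.35
    t_offset_ms: float = 300.0
    t_sigma_ms: float = 40.0
    p_amp_mv: float = 0.12
    rr_resp_amp_ms: float = 25.0  # respiratory sinus arrhythmia at 0.25 Hz
    rr_noise_ms: float = 10.0
    t_axis_freq_hz: float = 0.08
    t_axis_amp_deg: float = 0.0
    baseline_wander_mv: float = 0.0
    noise_sd_mv: float = 0.0
    af_like: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.t_axis_freq_hz < 0:
            raise ValueError("t_axis_freq_hz must be non-negative")
        if not 0 <= self.t_axis_amp_deg < 90:
            raise ValueError("t_axis_amp_deg must lie in [0, 90)")


@dataclass
class EcgGroundTruth:
    r_samples: np.ndarray
    t_directions: np.ndarray  # (n_beats, 3) unit vectors
    theta_deg: np.ndarray  # signed rotation angle per beat
    true_dt_deg: np.ndarray  # |diff(theta)|; angle between successive T vectors
    t_support_ms: tuple[float, float]  # true T-wave support (>= 25% of peak), rel. to R


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


_D_QRS = _unit(np.array([0.9, 0.35, 0.25]))
_D_T0 = _unit(np.array([0.8, 0.45, 0.3]))


def _rotate(v: np.ndarray, axis: np.ndarray, theta_rad: float) -> np.ndarray:
    """Rodrigues rotation of ``v`` about unit ``axis``."""
    return (
        v * np.cos(theta_rad)
        + np.cross(axis, v) * np.sin(theta_rad)
        + axis * np.dot(axis, v) * (1 - np.cos(theta_rad))
    )


def simulate_ecg(cfg: EcgSimConfig) -> tuple[EcgRecord, EcgGroundTruth]:
    rng = np.random.default_rng(cfg.seed)
    n = int(round(cfg.duration_s * cfg.fs))
    tgrid = np.arange(n) / cfg.fs
    sig = np.zeros((3, n))

    # beat times
    r_times = []
    t = 0.5
    while t < cfg.duration_s - 0.7:
        r_times.append(t)
        if cfg.af_like:
            t += rng.uniform(0.4, 1.2)
        else:
            rr_s = (
                cfg.mean_rr_ms
                + cfg.rr_resp_amp_ms * np.sin(2 * np.pi * 0.25 * t)
                + (rng.normal(0.0, cfg.rr_noise_ms) if cfg.rr_noise_ms > 0 else 0.0)
            ) / 1000.0
            t += max(0.35, rr_s)
    r_times = np.array(r_times)

    axis = _unit(np.cross(_D_T0, np.array([0.0, 0.0, 1.0])))  # perpendicular to T axis
    theta = np.radians(cfg.t_axis_amp_deg) * np.sin(2 * np.pi * cfg.t_axis_freq_hz * r_times)

    t_dirs = np.empty((len(r_times), 3))
    qs = cfg.qrs_sigma_ms / 1000.0
    ts = cfg.t_sigma_ms / 1000.0
    toff = cfg.t_offset_ms / 1000.0
    for i, (rt, th) in enumerate(zip(r_times, theta)):
        d_t = _rotate(_D_T0, axis, th)
        t_dirs[i] = d_t
        for centre, sigma, amp, direction in (
            (rt - 0.16, 0.025, cfg.p_amp_mv, _D_QRS),
            (rt, qs, cfg.qrs_amp_mv, _D_QRS),
            (rt + toff, ts, cfg.t_amp_mv, d_t),
        ):
            lo = max(0, int((centre - 4 * sigma) * cfg.fs))
            hi = min(n, int((centre + 4 * sigma) * cfg.fs) + 1)
            if hi <= lo:
                continue
            g = amp * np.exp(-((tgrid[lo:hi] - centre) ** 2) / (2 * sigma**2))
            sig[:, lo:hi] += direction[:, None] * g[None, :]

    if cfg.baseline_wander_mv > 0:
        sig += cfg.baseline_wander_mv * np.sin(2 * np.pi * 0.2 * tgrid)[None, :]
    if cfg.noise_sd_mv > 0:
        sig += rng.normal(0.0, cfg.noise_sd_mv, size=sig.shape)

    rec = EcgRecord(
        sig, cfg.fs, ["X", "Y", "Z"], t0=datetime.time(2, 0, 0), record_id="sim-ecg"
    )
    # true support: where the T Gaussian is >= 25% of its peak
    half_support = cfg.t_sigma_ms * np.sqrt(2 * np.log(4))
    truth = EcgGroundTruth(
        r_samples=np.round(r_times * cfg.fs).astype(int),
        t_directions=t_dirs,
        theta_deg=np.degrees(theta),
        true_dt_deg=np.abs(np.diff(np.degrees(theta))),
        t_support_ms=(cfg.t_offset_ms - half_support, cfg.t_offset_ms + half_support),
    )
    return rec, truth


# -------------------------------------------------------------------- cohorts

@dataclass
class CohortSimConfig:
    n: int = 1000
    beta_prd: float = field(default_factory=lambda: reference_coefficients().beta_prd)
    beta_dc: float = field(default_factory=lambda: reference_coefficients().beta_dc)
    prd_log_mu: float = float(np.log(7.7))  # lognormal median 7.7 deg^2
    prd_log_sigma: float = 0.79  # matches the published IQR of 8.6
    dc_mean_ms: float = 4.0
    dc_sd_ms: float = 3.8
    baseline_hazard_per_day: float = 0.004
    saps3_mean: float = 52.0
    saps3_sd: float = 12.0
    saps3_coupling: float = 8.0  # SAPS3 shift per SD of the linear predictor
    cap_dc_normal: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be at least 1")
        if self.baseline_hazard_per_day <= 0:
            raise ValueError("baseline hazard must be positive")


def simulate_cohort(cfg: CohortSimConfig) -> tuple[pd.DataFrame, dict]:
    """Cohort table with 30-day survival generated from the known hazard model."""
    rng = np.random.default_rng(cfg.seed)
    prd_raw = rng.lognormal(cfg.prd_log_mu, cfg.prd_log_sigma, cfg.n)
    dc_raw = rng.normal(cfg.dc_mean_ms, cfg.dc_sd_ms, cfg.n)
    capped = [cap_markers(p, d, cap_dc_normal=cfg.cap_dc_normal) for p, d in zip(prd_raw, dc_raw)]
    prd_c = np.array([c[0] for c in capped])
    dc_c = np.array([c[1] for c in capped])
    lp = cfg.beta_prd * prd_c + cfg.beta_dc * dc_c
    hazard = cfg.baseline_hazard_per_day * np.exp(lp)
    raw_t = rng.exponential(1.0 / hazard)
    event = raw_t <= FOLLOW_UP
    time_days = np.where(event, raw_t, FOLLOW_UP)
    lp_std = (lp - lp.mean()) / (lp.std() if lp.std() > 0 else 1.0)
    saps3 = np.clip(
        np.round(cfg.saps3_mean + cfg.saps3_coupling * lp_std + rng.normal(0, 10, cfg.n)),
        10,
        150,
    )
    coef = ScoreCoefficients(cfg.beta_prd, cfg.beta_dc, cfg.beta_dc, source="generator")
    caf = np.array(
        [
            compute_caf(p, d, coef, cap_dc_normal=cfg.cap_dc_normal).score
            for p, d in zip(prd_raw, dc_raw)
        ]
    )
    df = pd.DataFrame(
        {
            "id": np.arange(cfg.n),
            "time_days": time_days,
            "event": event.astype(int),
            "prd": prd_raw,
            "dc": dc_raw,
            "prd_capped": prd_c,
            "dc_capped": dc_c,
            "caf": caf,
            "saps3": saps3,
        }
    )
    truth = {
        "beta_prd": cfg.beta_prd,
        "beta_dc": cfg.beta_dc,
        "linear_predictor": lp,
        "baseline_hazard_per_day": cfg.baseline_hazard_per_day,
    }
    return df, truth
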