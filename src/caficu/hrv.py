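"""Task-Force time- and frequency-domain heart-rate-variability metrics.

Time domain: SDNN (population SD of valid NN intervals), RMSSD (root mean
square of successive differences between adjacent valid intervals), and the
HRV triangular index (N / max histogram bin count, 1/128 s bins, requiring at
least 5 min of data).

Frequency domain: Welch periodogram of the cubic-spline resampled (4 Hz),
linearly detrended NN tachogram, integrated over VLF 0.0033-0.04 Hz,
LF 0.04-0.15 Hz, HF 0.15-0.40 Hz.  A Lomb-Scargle estimator is available as a
configuration alternative for heavily gapped series.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps
from scipy.interpolate import CubicSpline

from .errors import InsufficientDataError
from .rhythm import RRSeries

VLF_BAND = (0.0033, 0.04)
LF_BAND = (0.04, 0.15)
HF_BAND = (0.15, 0.40)

HRVI_BIN_MS = 1000.0 / 128.0  # Task-Force convention


@dataclass
class HrvMetrics:
    sdnn_ms: float
    rmssd_ms: float
    hrvi: float | None
    vlf_ms2: float | None = None
    lf_ms2: float | None = None
    hf_ms2: float | None = None
    lf_hf_ratio: float | None = None


def time_domain(rr: RRSeries, hrvi_min_span_s: float = 300.0) -> tuple[float, float, float | None]:
    """(sdnn_ms, rmssd_ms, hrvi). hrvi is None below ``hrvi_min_span_s`` of data."""
    v = rr.rr_ms[rr.valid]
    if len(v) < 2:
        raise InsufficientDataError("need at least 2 valid intervals")
    sdnn = float(np.std(v))
    # successive differences only between adjacent valid intervals
    adj = rr.valid[:-1] & rr.valid[1:]
    diffs = np.diff(rr.rr_ms)[adj]
    if len(diffs) == 0:
        raise InsufficientDataError("no adjacent valid interval pairs for RMSSD")
    rmssd = float(np.sqrt(np.mean(diffs**2)))
    span = rr.beat_time_s[rr.valid][-1] - rr.beat_time_s[rr.valid][0]
    hrvi = None
    if span >= hrvi_min_span_s:
        bins = np.floor(v / HRVI_BIN_MS).astype(int)
        counts = np.bincount(bins - bins.min())
        hrvi = float(len(v) / counts.max())
    return sdnn, rmssd, hrvi


def _band_power(f: np.ndarray, p: np.ndarray, band: tuple[float, float]) -> float:
    mask = (f >= band[0]) & (f < band[1])
    if mask.sum() < 2:
        return 0.0
    return float(np.trapezoid(p[mask], f[mask]))


def frequency_domain(
    rr: RRSeries,
    resample_hz: float = 4.0,
    method: str = "welch",
) -> tuple[float, float, float, float | None]:
    """(vlf, lf, hf, lf_hf_ratio) in ms^2, from the valid NN tachogram."""
    t = rr.beat_time_s[rr.valid]
    v = rr.rr_ms[rr.valid]
    if len(v) < 4 or t[-1] - t[0] < 120.0:
        raise InsufficientDataError("need at least 120 s of valid data")
    if method == "welch":
        grid = np.arange(t[0], t[-1], 1.0 / resample_hz)
        x = CubicSpline(t, v)(grid)
        x = sps.detrend(x, type="linear")
        nperseg = min(len(x), 1024)
        f, p = sps.welch(x, fs=resample_hz, nperseg=nperseg, noverlap=nperseg // 2)
    elif method == "lomb":
        # gap-tolerant alternative; scaled so a pure sinusoid integrates to
        # roughly its variance (relative band comparisons are the use case)
        x = v - np.polyval(np.polyfit(t, v, 1), t)
        f = np.linspace(VLF_BAND[0], HF_BAND[1] + 0.05, 800)
        pw = sps.lombscargle(t, x - x.mean(), 2 * np.pi * f)
        p = 4.0 * pw / len(t) * (t[-1] - t[0])
    else:
        raise ValueError(f"unknown method {method!r}")
    vlf = _band_power(f, p, VLF_BAND)
    lf = _band_power(f, p, LF_BAND)
    hf = _band_power(f, p, HF_BAND)
    ratio = lf / hf if hf > 0 else None
    return vlf, lf, hf, ratio


def hrv_metrics(rr: RRSeries, method: str = "welch") -> HrvMetrics:
    """Full HRV battery; frequency metrics omitted when the series is too short."""
    sdnn, rmssd, hrvi = time_domain(rr)
    try:
        vlf, lf, hf, ratio = frequency_domain(rr, method=method)
    except InsufficientDataError:
        return HrvMetrics(sdnn, rmssd, hrvi)
    return HrvMetrics(sdnn, rmssd, hrvi, vlf, lf, hf, ratio)
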