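"""Periodic repolarization dynamics (PRD).

Low-frequency (<= 0.1 Hz) oscillations of the T wave's spatial direction are a
marker of sympathetic activity on the ventricular myocardium.  The chain is:

1. convert the multichannel ECG to an orthogonal X/Y/Z vectorcardiogram,
2. delineate a T-wave window per accepted beat,
3. compute each beat's weight-averaged repolarization direction T deg
   (amplitude-weighted mean azimuth/elevation over the window),
4. take the angle dT deg between successive T deg unit vectors,
5. quantify the <= 0.1 Hz content of the dT deg series with a continuous
   wavelet transform, reporting the mean squared coefficient in deg^2.

Angle frame (fixed by convention): azimuth = atan2(z, x), elevation = angle
from the x-z plane toward y; both in degrees.

Fewer than three leads make the vectorcardiogram — and hence PRD —
unavailable; :class:`~caficu.errors.InsufficientLeadsError` signals scoring to
take the DC-only path.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InsufficientDataError, InsufficientLeadsError
from .rhythm import NORMAL, BeatSeries, RRSeries
from .signal_io import EcgRecord

# Kors regression matrix: (X, Y, Z) from the 8 independent leads
# (I, II, V1..V6) of the standard 12-lead ECG.
KORS_LEADS = ["I", "II", "V1", "V2", "V3", "V4", "V5", "V6"]
KORS_MATRIX = np.array(
    [
        [0.38, -0.07, -0.13, 0.05, -0.01, 0.14, 0.06, 0.54],
        [-0.07, 0.93, 0.06, -0.02, -0.05, 0.06, -0.17, 0.13],
        [0.11, -0.23, -0.43, -0.06, -0.14, -0.20, -0.11, 0.31],
    ]
)


@dataclass
class Vcg:
    """Orthogonal-lead vectorcardiogram with per-sample angles (degrees)."""

    x: np.ndarray
    y: np.ndarray
    z: np.ndarray
    fs: float
    azimuth: np.ndarray = field(init=False)
    elevation: np.ndarray = field(init=False)
    amplitude: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, float)
        self.y = np.asarray(self.y, float)
        self.z = np.asarray(self.z, float)
        if not (len(self.x) == len(self.y) == len(self.z)):
            raise ValueError("x, y, z must have equal length")
        self.amplitude = np.sqrt(self.x**2 + self.y**2 + self.z**2)
        self.azimuth = np.degrees(np.arctan2(self.z, self.x))
        with np.errstate(invalid="ignore", divide="ignore"):
            ratio = np.where(self.amplitude > 0, self.y / np.where(self.amplitude > 0, self.amplitude, 1.0), 0.0)
        self.elevation = np.degrees(np.arcsin(np.clip(ratio, -1.0, 1.0)))

    def __len__(self) -> int:
        return len(self.x)


@dataclass
class TWaveWindow:
    beat_index: int
    start: int
    end: int  # half-open [start, end)


@dataclass
class TVectorSeries:
    """Per-beat weight-averaged repolarization direction."""

    azimuth_w: np.ndarray
    elevation_w: np.ndarray
    beat_time_s: np.ndarray
    unit_vectors: np.ndarray  # (n, 3), |u| = 1
    beat_indices: np.ndarray | None = None  # indices into the BeatSeries

    def __len__(self) -> int:
        return len(self.azimuth_w)


@dataclass
class DTSeries:
    """Angle (degrees) between successive T-degree vectors; time of the later beat."""

    dtheta_deg: np.ndarray
    time_s: np.ndarray

    def __len__(self) -> int:
        return len(self.dtheta_deg)


@dataclass
class PrdValue:
    prd_deg2: float | None
    n_beats: int
    flags: tuple[str, ...] = ()


def to_orthogonal(
    rec: EcgRecord,
    transform: str | np.ndarray = "identity",
    polarity: tuple[float, float, float] = (1.0, 1.0, 1.0),
) -> Vcg:
    """Convert the record's leads to an orthogonal X/Y/Z vectorcardiogram.

    ``transform`` is ``"identity"`` (first three leads, with per-lead polarity,
    for quasi-orthogonal monitor leads), ``"kors"`` (regression matrix for
    12-lead records carrying I, II, V1..V6), or an explicit (3, n_leads) matrix.
    """
    if rec.n_leads < 3:
        raise InsufficientLeadsError(
            f"{rec.n_leads} lead(s): vectorcardiogram requires at least 3 leads"
        )
    if isinstance(transform, str) and transform == "identity":
        x = polarity[0] * rec.samples[0]
        y = polarity[1] * rec.samples[1]
        z = polarity[2] * rec.samples[2]
        return Vcg(x, y, z, rec.fs)
    if isinstance(transform, str) and transform == "kors":
        names = {n.upper(): i for i, n in enumerate(rec.lead_names)}
        missing = [n for n in KORS_LEADS if n not in names]
        if missing:
            raise InsufficientLeadsError(f"Kors transform needs leads {missing}")
        leads = np.stack([rec.samples[names[n]] for n in KORS_LEADS])
        xyz = KORS_MATRIX @ leads
        return Vcg(xyz[0], xyz[1], xyz[2], rec.fs)
    matrix = np.asarray(transform, dtype=float)
    if matrix.ndim != 2 or matrix.shape != (3, rec.n_leads):
        raise ValueError(f"transform matrix must have shape (3, {rec.n_leads})")
    xyz = matrix @ rec.samples
    return Vcg(xyz[0], xyz[1], xyz[2], rec.fs)


def locate_t_waves(
    vcg: Vcg,
    beats: BeatSeries,
    rr: RRSeries | None = None,
    k1: float = 0.25,
    k2: float = 0.55,
    rel_threshold: float = 0.25,
) -> list[TWaveWindow]:
    """Delineate one T-wave window per accepted beat.

    The search window is [R + k1*1000*sqrt(RR_s), R + k2*1000*sqrt(RR_s)] ms
    (square-root rate adaptation), clipped before the next R peak, then
    refined to the contiguous region around the in-window amplitude maximum
    where the vector amplitude stays above ``rel_threshold`` of that maximum.
    Beats labelled non-normal, or whose preceding interval is invalid, are
    skipped.  May legitimately return an empty list.
    """
    fs = vcg.fs
    r = beats.r_samples
    windows: list[TWaveWindow] = []
    for j in range(1, len(r)):
        if beats.labels[j] != NORMAL or beats.labels[j - 1] != NORMAL:
            continue
        if rr is not None and not rr.valid[j - 1]:
            continue
        rr_s = (r[j] - r[j - 1]) / fs
        s0 = r[j] + int(round(k1 * 1000.0 * np.sqrt(rr_s) * fs / 1000.0))
        s1 = r[j] + int(round(k2 * 1000.0 * np.sqrt(rr_s) * fs / 1000.0))
        if j + 1 < len(r):
            s1 = min(s1, r[j + 1] - int(0.02 * fs))
        s1 = min(s1, len(vcg))
        if s1 - s0 < 3:
            continue
        amp = vcg.amplitude[s0:s1]
        m = int(np.argmax(amp))
        peak = amp[m]
        if peak <= 0:
            continue
        above = amp >= rel_threshold * peak
        lo = m
        while lo > 0 and above[lo - 1]:
            lo -= 1
        hi = m + 1
        while hi < len(amp) and above[hi]:
            hi += 1
        windows.append(TWaveWindow(j, s0 + lo, s0 + hi))
    return windows


def _unit_from_angles(az_deg: float, el_deg: float) -> np.ndarray:
    az, el = np.radians(az_deg), np.radians(el_deg)
    return np.array([np.cos(el) * np.cos(az), np.sin(el), np.cos(el) * np.sin(az)])


def t_vector(vcg: Vcg, window: TWaveWindow) -> tuple[float, float, np.ndarray] | None:
    """Weight-averaged (azimuth, elevation, unit_vector) over one T-wave window.

    Weights are the per-sample vector amplitudes; an all-zero window yields
    None (beat dropped).
    """
    sl = slice(window.start, window.end)
    w = vcg.amplitude[sl]
    total = w.sum()
    if total <= 0:
        return None
    az_w = float(np.sum(w * vcg.azimuth[sl]) / total)
    el_w = float(np.sum(w * vcg.elevation[sl]) / total)
    return az_w, el_w, _unit_from_angles(az_w, el_w)


def t_vector_series(vcg: Vcg, windows: list[TWaveWindow], beats: BeatSeries) -> TVectorSeries:
    az, el, times, units, idx = [], [], [], [], []
    for win in windows:
        res = t_vector(vcg, win)
        if res is None:
            continue
        az.append(res[0])
        el.append(res[1])
        units.append(res[2])
        times.append(beats.r_samples[win.beat_index] / beats.fs)
        idx.append(win.beat_index)
    return TVectorSeries(
        np.array(az), np.array(el), np.array(times),
        np.array(units).reshape(-1, 3), np.array(idx, dtype=int),
    )


def dt_angles(tv: TVectorSeries) -> DTSeries:
    """Angle between successive repolarization unit vectors, in degrees."""
    if len(tv) < 2:
        raise InsufficientDataError("need at least 2 T vectors for dT angles")
    dots = np.sum(tv.unit_vectors[:-1] * tv.unit_vectors[1:], axis=1)
    ang = np.degrees(np.arccos(np.clip(dots, -1.0, 1.0)))
    return DTSeries(ang, tv.beat_time_s[1:])


#: Morlet bandwidth parameter B: the mother wavelet is
#: psi(t) = (pi*B)^(-1/2) * exp(2*pi*i*t) * exp(-t^2 / B), whose Fourier
#: transform is the Gaussian exp(-pi^2 * B * (f - 1)^2).  The modest
#: bandwidth gives the <= 0.1 Hz passband tolerant edges on the short
#: (5-30 min) series this score is computed from.
PRD_MORLET_B = 0.5
PRD_FMIN_HZ = 0.01
PRD_FMAX_HZ = 0.1
PRD_N_SCALES = 12
#: resampling grid for the angle series.  Must sit well above the beat rate:
#: linear interpolation leaves images of beat-frequency content just below
#: twice the beat rate, and a grid near 2 Hz folds those images into the
#: <= 0.1 Hz band.  4 Hz keeps them out of band for any plausible heart rate.
PRD_GRID_HZ = 4.0


def morlet_cwt(
    x: np.ndarray,
    freqs_hz: np.ndarray,
    fs: float,
    bandwidth: float = PRD_MORLET_B,
) -> np.ndarray:
    """Analytic Morlet CWT as an FFT-domain Gaussian filter bank.

    Row i holds the complex band-pass coefficients for centre frequency
    ``freqs_hz[i]``; each filter has unit peak gain (and gain 2 on the
    analytic side), so a sinusoid of amplitude A at a centre frequency
    yields coefficients of magnitude A there.  The Gaussian frequency
    response makes the stopband exact to machine precision, which the
    <= 0.1 Hz band contract of this method depends on.
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    nfft = 1 << max(3, int(np.ceil(np.log2(2 * n))))  # pad against wrap-around
    X = np.fft.fft(x, nfft)
    f = np.fft.fftfreq(nfft, d=1.0 / fs)
    out = np.empty((len(freqs_hz), n), dtype=complex)
    for i, fc in enumerate(freqs_hz):
        h = 2.0 * np.exp(-np.pi**2 * bandwidth * ((f / fc) - 1.0) ** 2)
        h[f < 0] = 0.0
        out[i] = np.fft.ifft(X * h)[:n]
    return out


def compute_prd(
    dts: DTSeries,
    min_span_s: float = 60.0,
    min_angles: int = 30,
    grid_hz: float = PRD_GRID_HZ,
    fmin_hz: float = PRD_FMIN_HZ,
    fmax_hz: float = PRD_FMAX_HZ,
    n_scales: int = PRD_N_SCALES,
    bandwidth: float = PRD_MORLET_B,
) -> PrdValue:
    """Quantify <= 0.1 Hz power of the dT-degree series (deg^2).

    The unevenly sampled series is linearly interpolated onto a ``grid_hz``
    grid, mean-detrended, and passed through the analytic Morlet filter bank
    whose centre frequencies tile [``fmin_hz``, ``fmax_hz``] log-uniformly;
    PRD is the mean squared coefficient magnitude over time and scales,
    excluding each scale's cone of influence (two e-folding times of the
    wavelet envelope at the series edges).  Scales whose cone covers the
    whole series contribute nothing; a series too short for any scale is
    flagged rather than scored.
    """
    n = len(dts)
    span = dts.time_s[-1] - dts.time_s[0] if n >= 2 else 0.0
    if n < min_angles or span < min_span_s:
        return PrdValue(None, n, flags=("short_series",))
    dt = 1.0 / grid_hz
    grid = np.arange(dts.time_s[0], dts.time_s[-1], dt)
    x = np.interp(grid, dts.time_s, dts.dtheta_deg)
    x = x - x.mean()
    freqs = np.geomspace(fmin_hz, fmax_hz, n_scales)
    coefs = morlet_cwt(x, freqs, grid_hz, bandwidth)
    power_sum = 0.0
    count = 0
    for i, fc in enumerate(freqs):
        # envelope e-folding time of the scaled wavelet, in samples
        sigma = np.sqrt(bandwidth / 2.0) / (fc * dt)
        k = int(np.ceil(2.0 * sigma))
        if 2 * k >= len(x):
            continue
        seg = np.abs(coefs[i, k : len(x) - k]) ** 2
        power_sum += seg.sum()
        count += seg.size
    if count == 0:
        return PrdValue(None, n, flags=("short_series",))
    return PrdValue(float(power_sum / count), n)


def prd_from_record(
    rec: EcgRecord,
    beats: BeatSeries,
    rr: RRSeries | None = None,
    transform: str | np.ndarray = "identity",
    is_af: bool = False,
) -> tuple[PrdValue, DTSeries]:
    """Full PRD chain for one record. AF recordings are allowed but flagged."""
    vcg = to_orthogonal(rec, transform=transform)
    windows = locate_t_waves(vcg, beats, rr=rr)
    tv = t_vector_series(vcg, windows, beats)
    if len(tv) < 2:
        return PrdValue(None, len(tv), flags=("short_series",)), DTSeries(np.array([]), np.array([]))
    dts = dt_angles(tv)
    value = compute_prd(dts)
    if is_af and value.prd_deg2 is not None:
        value = PrdValue(value.prd_deg2, value.n_beats, flags=value.flags + ("af",))
    return value, dts
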