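"""Beat detection, RR-interval series construction, and AF screening.

The R-peak detector is a deterministic bandpass-energy detector (8-25 Hz
Butterworth, squared, 120 ms moving average, adaptive threshold, 200 ms
refractory) with a per-lead quality gate and lead fallback.

RR validity follows standard Holter practice: intervals outside
[300, 2000] ms, or differing by more than 20% from the preceding valid
interval, or adjacent to a non-normal beat, are flagged invalid.  Ectopy is
labelled by a morphology-free prematurity rule (short interval followed by a
compensatory pause).

AF screening is an RR-irregularity surrogate: over sliding 60-beat windows it
combines the normalized RMSSD of the median-filtered series with the fraction
of successive differences above 50 ms; the record is flagged AF when more than
half of the windows exceed both thresholds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal as sps

from .errors import InsufficientDataError, NoBeatsError
from .signal_io import EcgRecord

NORMAL, ECTOPIC, ARTIFACT = "normal", "ectopic", "artifact"


@dataclass
class BeatSeries:
    """R-peak sample indices with per-beat labels."""

    r_samples: np.ndarray
    labels: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        self.r_samples = np.asarray(self.r_samples, dtype=int)
        self.labels = np.asarray(self.labels, dtype=object)
        if len(self.r_samples) != len(self.labels):
            raise ValueError("labels must match r_samples in length")
        if np.any(np.diff(self.r_samples) <= 0):
            raise ValueError("r_samples must be strictly increasing")

    @property
    def times_s(self) -> np.ndarray:
        return self.r_samples / self.fs


@dataclass
class RRSeries:
    """Successive RR intervals (ms) with validity flags.

    ``beat_time_s[i]`` is the time of the beat *terminating* interval i.
    """

    rr_ms: np.ndarray
    beat_time_s: np.ndarray
    valid: np.ndarray

    def __post_init__(self) -> None:
        self.rr_ms = np.asarray(self.rr_ms, dtype=float)
        self.beat_time_s = np.asarray(self.beat_time_s, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        if not (len(self.rr_ms) == len(self.beat_time_s) == len(self.valid)):
            raise ValueError("rr_ms, beat_time_s and valid must have equal length")
        if np.any(self.rr_ms <= 0):
            raise ValueError("RR intervals must be positive")
        if np.any(np.diff(self.beat_time_s) <= 0):
            raise ValueError("beat times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.rr_ms)

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            {"beat_time_s": self.beat_time_s, "rr_ms": self.rr_ms, "valid": self.valid.astype(int)}
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "RRSeries":
        df = pd.read_csv(path)
        return cls(df["rr_ms"].to_numpy(), df["beat_time_s"].to_numpy(), df["valid"].to_numpy(bool))


@dataclass
class AfAssessment:
    """Outcome of RR-irregularity AF screening.

    ``is_af`` is None when too few intervals were available (indeterminate).
    """

    is_af: bool | None
    irregularity_score: float
    fraction_irregular: float
    n_windows: int = 0


def _detect_single_lead(x: np.ndarray, fs: float) -> np.ndarray:
    nyq = fs / 2.0
    hi = min(25.0, 0.9 * nyq)
    b, a = sps.butter(3, [8.0 / nyq, hi / nyq], btype="band")
    filt = sps.filtfilt(b, a, x)
    env = sps.convolve(filt**2, np.ones(max(1, int(0.12 * fs))) / max(1, int(0.12 * fs)), mode="same")
    thr = 0.25 * np.percentile(env, 99.5)
    if thr <= 0:
        return np.array([], dtype=int)
    peaks, _ = sps.find_peaks(env, height=thr, distance=max(1, int(0.2 * fs)))
    if len(peaks) == 0:
        return peaks
    # quality gate: QRS energy must dominate the between-beat baseline
    med_env = np.median(env)
    if med_env <= 0 or np.median(env[peaks]) < 8.0 * med_env:
        return np.array([], dtype=int)
    # refine to the raw-amplitude extremum near each energy peak
    half = max(1, int(0.05 * fs))
    centred = np.abs(x - np.median(x))
    refined = []
    for p in peaks:
        lo, hi_ = max(0, p - half), min(len(x), p + half + 1)
        refined.append(lo + int(np.argmax(centred[lo:hi_])))
    refined = np.unique(refined)
    return refined[np.r_[True, np.diff(refined) > int(0.2 * fs)]]


def detect_r_peaks(rec: EcgRecord, lead_strategy: str | int = "first_good") -> BeatSeries:
    """Detect R peaks, falling back across leads when one is flat or noisy.

    ``lead_strategy`` may be ``"first_good"`` (default), a lead index, or a
    lead name.  Raises :class:`NoBeatsError` when no lead yields at least 10
    plausible beats.
    """
    if rec.duration_s < 10.0:
        raise InsufficientDataError("need at least 10 s of signal for beat detection")
    if lead_strategy == "first_good":
        order = list(range(rec.n_leads))
    elif isinstance(lead_strategy, int):
        order = [lead_strategy]
    else:
        order = [rec.lead_names.index(lead_strategy)]
    for li in order:
        x = rec.samples[li]
        if np.ptp(x) < 1e-9:  # flat line
            continue
        peaks = _detect_single_lead(x, rec.fs)
        if len(peaks) >= 10:
            return BeatSeries(peaks, np.array([NORMAL] * len(peaks), dtype=object), rec.fs)
    raise NoBeatsError("no lead produced at least 10 plausible beats")


def _local_median(rr: np.ndarray, i: int, half: int = 4) -> float:
    lo, hi = max(0, i - half), min(len(rr), i + half + 1)
    return float(np.median(rr[lo:hi]))


def label_ectopic(beats: BeatSeries, rr_ms: np.ndarray, prematurity: float = 0.8) -> None:
    """Label beats ectopic by prematurity + compensatory-pause rule (in place).

    The beat terminating a premature interval (interval < ``prematurity`` x
    local median, followed by an interval above the local median) is labelled.
    """
    for i in range(len(rr_ms) - 1):
        med = _local_median(rr_ms, i)
        if rr_ms[i] < prematurity * med and rr_ms[i + 1] > med:
            beats.labels[i + 1] = ECTOPIC


def apply_validity_filters(
    rr_ms: np.ndarray,
    labels: np.ndarray,
    rr_min_ms: float = 300.0,
    rr_max_ms: float = 2000.0,
    max_rel_delta: float = 0.2,
) -> np.ndarray:
    """Per-interval validity flags. Deterministic and idempotent given (rr, labels)."""
    n = len(rr_ms)
    valid = np.ones(n, dtype=bool)
    valid &= (rr_ms >= rr_min_ms) & (rr_ms <= rr_max_ms)
    for i in range(n):  # interval i spans beats i..i+1
        if labels[i] != NORMAL or labels[i + 1] != NORMAL:
            valid[i] = False
    prev = None
    for i in range(n):
        if not valid[i]:
            continue
        if prev is not None and abs(rr_ms[i] - prev) > max_rel_delta * prev:
            valid[i] = False
        else:
            prev = rr_ms[i]
    return valid


def build_rr_series(
    beats: BeatSeries,
    rr_min_ms: float = 300.0,
    rr_max_ms: float = 2000.0,
    max_rel_delta: float = 0.2,
) -> RRSeries:
    """Build the RR series from detected beats, labelling ectopy and flagging
    implausible intervals invalid."""
    if len(beats.r_samples) < 2:
        raise InsufficientDataError("need at least 2 beats to form RR intervals")
    rr_ms = np.diff(beats.r_samples) * (1000.0 / beats.fs)
    label_ectopic(beats, rr_ms)
    valid = apply_validity_filters(rr_ms, beats.labels, rr_min_ms, rr_max_ms, max_rel_delta)
    beat_time_s = beats.r_samples[1:] / beats.fs
    return RRSeries(rr_ms, beat_time_s, valid)


def assess_af(
    rr: RRSeries,
    window_beats: int = 60,
    step_beats: int = 30,
    nrmssd_threshold: float = 0.10,
    irregular_fraction_threshold: float = 0.25,
    af_window_fraction: float = 0.5,
) -> AfAssessment:
    """Screen the raw RR series for AF-like irregularity.

    Runs on all intervals (validity filtering would mask AF itself).  With
    fewer than ``window_beats`` intervals the result is indeterminate
    (``is_af=None``), never an exception.
    """
    x = rr.rr_ms
    if len(x) < window_beats:
        return AfAssessment(None, float("nan"), float("nan"), 0)
    med = sps.medfilt(x, kernel_size=3)
    flagged = 0
    scores = []
    n_win = 0
    for start in range(0, len(x) - window_beats + 1, step_beats):
        w_med = med[start : start + window_beats]
        w_raw = x[start : start + window_beats]
        d_med = np.diff(w_med)
        nrmssd = float(np.sqrt(np.mean(d_med**2)) / np.mean(w_med))
        frac_gt50 = float(np.mean(np.abs(np.diff(w_raw)) > 50.0))
        scores.append(nrmssd)
        n_win += 1
        if nrmssd > nrmssd_threshold and frac_gt50 > irregular_fraction_threshold:
            flagged += 1
    frac = flagged / n_win
    return AfAssessment(frac > af_window_fraction, float(np.median(scores)), frac, n_win)
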