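"""Read/write MIT-format (PhysioNet/WFDB) ECG records and extract analysis windows.

Only the subset of the format the package produces and consumes is supported:
single-.dat records in format 16 (16-bit little-endian, sample-interleaved)
with explicit per-lead gain and units.  Amplitudes are always held in mV
internally; records without unit metadata are rejected rather than guessed.

The analysis window defaults to 02:00:00-02:30:00 local record clock — the
standardized first-night window the score was developed on — but is fully
configurable.  Partial overlap of at least 20 min is accepted with a warning
(DC and PRD are validated for recordings of 20 min or more); shorter overlap
is rejected.
"""

from __future__ import annotations

import datetime
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import EmptyWindowError, RecordFormatError, WindowTooShortError

_UNIT_TO_MV = {"mV": 1.0, "mv": 1.0, "uV": 1e-3, "uv": 1e-3, "V": 1e3}

#: default digital gain (ADC units per mV) used when writing
WRITE_GAIN = 1000.0


@dataclass
class EcgRecord:
    """A multichannel ECG waveform in physical units (mV).

    ``samples`` has shape (n_leads, n_samples); ``t0`` is the wall-clock time
    of the first sample and is required for window extraction (never inferred).
    """

    samples: np.ndarray
    fs: float
    lead_names: list[str]
    t0: datetime.time | None = None
    record_id: str = "record"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.atleast_2d(np.asarray(self.samples, dtype=float))
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if self.samples.shape[0] != len(self.lead_names):
            raise ValueError("lead_names length must match number of leads")

    @property
    def n_leads(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs


@dataclass
class AnalysisWindow:
    """Time-of-day window, default 02:00 for 1800 s."""

    start_clock: datetime.time = datetime.time(2, 0, 0)
    duration_s: float = 1800.0

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ValueError("window duration must be positive")


def _seconds_of_day(t: datetime.time) -> float:
    return t.hour * 3600 + t.minute * 60 + t.second + t.microsecond / 1e6


def _time_from_seconds(s: float) -> datetime.time:
    s = s % 86400
    h, rem = divmod(int(round(s * 1e6)), 3600_000_000)
    m, rem = divmod(rem, 60_000_000)
    sec, us = divmod(rem, 1_000_000)
    return datetime.time(h % 24, m, sec, us)


def write_record(rec: EcgRecord, path: str | Path) -> tuple[Path, Path]:
    """Write ``rec`` as a ``.hea``/``.dat`` pair (format 16, gain 1000 adu/mV).

    ``path`` is the record base path (extensions are added). Returns the two
    paths written.
    """
    base = Path(path)
    base.parent.mkdir(parents=True, exist_ok=True)
    name = base.name
    digital = np.clip(np.round(rec.samples * WRITE_GAIN), -32767, 32767).astype("<i2")
    interleaved = np.ascontiguousarray(digital.T)  # (n_samples, n_leads)

    hea = base.with_suffix(".hea")
    dat = base.with_suffix(".dat")
    lines = []
    t0_str = ""
    if rec.t0 is not None:
        t0_str = f" {rec.t0.strftime('%H:%M:%S')}"
    fs_str = f"{rec.fs:g}"
    lines.append(f"{name} {rec.n_leads} {fs_str} {rec.n_samples}{t0_str}")
    for i, lead in enumerate(rec.lead_names):
        first = int(digital[i, 0]) if rec.n_samples else 0
        checksum = int(np.int16(digital[i].astype(np.int64).sum() & 0xFFFF))
        lines.append(
            f"{name}.dat 16 {WRITE_GAIN:g}(0)/mV 16 0 {first} {checksum} 0 {lead}"
        )
    hea.write_text("\n".join(lines) + "\n")
    interleaved.tofile(dat)
    return hea, dat


def read_record(path: str | Path) -> EcgRecord:
    """Read a single-file MIT-format record (format 16) into physical mV."""
    base = Path(path)
    if base.suffix == ".hea":
        base = base.with_suffix("")
    hea = base.with_suffix(".hea")
    if not hea.exists():
        raise RecordFormatError(f"header file not found: {hea}")
    raw_lines = [
        ln.strip()
        for ln in hea.read_text().splitlines()
        if ln.strip() and not ln.startswith("#")
    ]
    head = raw_lines[0].split()
    if len(head) < 4:
        raise RecordFormatError(f"malformed header record line: {raw_lines[0]!r}")
    record_id = head[0].split("/")[0]
    n_sig = int(head[1])
    fs = float(head[2].split("/")[0])
    n_samples = int(head[3])
    t0 = None
    if len(head) >= 5:
        token = head[4]
        for fmt in ("%H:%M:%S.%f", "%H:%M:%S"):
            try:
                t0 = datetime.datetime.strptime(token, fmt).time()
                break
            except ValueError:
                continue

    lead_names: list[str] = []
    gains: list[float] = []
    baselines: list[float] = []
    unit_scales: list[float] = []
    dat_names: set[str] = set()
    for i, line in enumerate(raw_lines[1 : 1 + n_sig]):
        tok = line.split()
        if len(tok) < 3:
            raise RecordFormatError(f"malformed signal line: {line!r}")
        dat_names.add(tok[0])
        if tok[1].split("x")[0] != "16":
            raise RecordFormatError(
                f"unsupported signal format {tok[1]!r}; only format 16 is supported"
            )
        gain_tok = tok[2]
        if "/" not in gain_tok:
            raise RecordFormatError(
                f"signal {i} has no unit metadata ({gain_tok!r}); units are required"
            )
        gain_part, unit = gain_tok.split("/", 1)
        if unit not in _UNIT_TO_MV:
            raise RecordFormatError(f"cannot convert unit {unit!r} to mV")
        unit_scales.append(_UNIT_TO_MV[unit])
        if "(" in gain_part:
            g, b = gain_part.split("(")
            baselines.append(float(b.rstrip(")")))
        else:
            g = gain_part
            baselines.append(0.0)
        gain = float(g) if float(g) != 0 else 200.0
        gains.append(gain)
        lead_names.append(tok[-1] if len(tok) >= 9 else f"sig{i}")
    if len(lead_names) != n_sig:
        raise RecordFormatError("header lists fewer signal lines than n_sig")
    if len(dat_names) != 1:
        raise RecordFormatError("multi-file records are not supported")

    dat = base.parent / dat_names.pop()
    if not dat.exists():
        raise RecordFormatError(f"signal file not found: {dat}")
    raw = np.fromfile(dat, dtype="<i2")
    if raw.size < n_sig * n_samples:
        raise RecordFormatError(
            f"signal file truncated: expected {n_sig * n_samples} samples, got {raw.size}"
        )
    digital = raw[: n_sig * n_samples].reshape(n_samples, n_sig).T.astype(float)
    physical = np.empty_like(digital)
    for i in range(n_sig):
        physical[i] = (digital[i] - baselines[i]) / gains[i] * unit_scales[i]
    return EcgRecord(physical, fs, lead_names, t0=t0, record_id=record_id)


def extract_window(
    rec: EcgRecord,
    win: AnalysisWindow | None = None,
    min_overlap_s: float = 1200.0,
) -> EcgRecord:
    """Extract the standardized analysis window from ``rec``.

    The overlap between the record's clock span and the window is returned as a
    new record (``t0`` updated).  No overlap raises :class:`EmptyWindowError`;
    partial overlap below ``min_overlap_s`` raises :class:`WindowTooShortError`;
    partial overlap at or above it is returned with ``meta['window_complete']``
    set to False and a warning.
    """
    if win is None:
        win = AnalysisWindow()
    if rec.t0 is None:
        raise ValueError("record has no clock start time (t0); cannot window")
    rec_sod = _seconds_of_day(rec.t0)
    win_sod = _seconds_of_day(win.start_clock)
    # window offset relative to record start, wrapped to (-12 h, +12 h]
    offset = ((win_sod - rec_sod + 43200.0) % 86400.0) - 43200.0
    lo = max(0.0, offset)
    hi = min(rec.duration_s, offset + win.duration_s)
    if hi <= lo:
        raise EmptyWindowError(
            f"record span [{rec.t0}, +{rec.duration_s:.0f}s] does not overlap "
            f"window [{win.start_clock}, +{win.duration_s:.0f}s]"
        )
    overlap = hi - lo
    complete = overlap >= win.duration_s - 0.5 / rec.fs
    if not complete and overlap < min_overlap_s:
        raise WindowTooShortError(
            f"window overlap {overlap:.0f}s is below the minimum {min_overlap_s:.0f}s"
        )
    if not complete:
        warnings.warn(
            f"incomplete analysis window: {overlap:.0f}s of {win.duration_s:.0f}s",
            stacklevel=2,
        )
    i0 = int(round(lo * rec.fs))
    i1 = int(round(hi * rec.fs))
    out = EcgRecord(
        rec.samples[:, i0:i1].copy(),
        rec.fs,
        list(rec.lead_names),
        t0=_time_from_seconds(rec_sod + lo),
        record_id=rec.record_id,
        meta={**rec.meta, "window_complete": complete},
    )
    return out
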