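"""End-to-end runs: record -> markers -> score -> machine-readable report.

``run_patient`` executes the full chain for one record and produces a
:class:`RunReport` in which every value is traceable to a module output;
absent values are explicit ``None`` with a reason flag.  AF-positive records
yield markers flagged AF but no score (normal-to-normal interval metrics are
undefined in AF) unless ``force`` is set.  Records with fewer than three
leads follow the DC-only scoring path.

``run_cohort`` runs the validation-style statistics battery on a cohort
table: Kaplan-Meier by score stratum with log-rank, ROC/Youden, the
reclassification metrics against a SAPS3-only Cox model, and the risk-tier
table.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .errors import InsufficientDataError, InsufficientLeadsError
from .hrv import HrvMetrics, hrv_metrics
from .prd import prd_from_record
from .prsa import deceleration_capacity
from .rhythm import assess_af, build_rr_series, detect_r_peaks
from .score import DEFAULT_CUTOFF, CafResult, ScoreCoefficients, compute_caf
from .signal_io import AnalysisWindow, EcgRecord, extract_window, read_record
from .stats import classify_risk_tier, fit_cox, km_curve, reclassification, roc_youden


@dataclass
class RunConfig:
    window_start: str = "02:00:00"
    window_duration_s: float = 1800.0
    min_window_s: float = 1200.0
    apply_window: bool = True
    transform: str = "identity"
    prsa_T: int = 4
    prsa_L: int = 20
    cutoff: int = DEFAULT_CUTOFF
    fallback: str = "exponential"
    cap_dc_normal: bool = True
    force: bool = False

    def hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


@dataclass
class RunReport:
    record_id: str
    window: dict
    flags: dict
    dc_ms: float | None
    prd_deg2: float | None
    hrv: dict | None
    caf: dict | None
    reasons: dict = field(default_factory=dict)
    version: str = __version__
    config_hash: str = ""

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.to_dict(), indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text


def _parse_clock(s: str):
    import datetime

    parts = [int(p) for p in s.split(":")]
    while len(parts) < 3:
        parts.append(0)
    return datetime.time(*parts)


def run_patient(
    record: str | Path | EcgRecord,
    coef: ScoreCoefficients,
    config: RunConfig | None = None,
) -> RunReport:
    """Full single-patient analysis. See module docstring for the data flow."""
    cfg = config or RunConfig()
    rec = record if isinstance(record, EcgRecord) else read_record(record)
    window_info = {"start": None, "duration_s": None, "complete": None}
    if cfg.apply_window:
        win = AnalysisWindow(_parse_clock(cfg.window_start), cfg.window_duration_s)
        rec = extract_window(rec, win, min_overlap_s=cfg.min_window_s)
        window_info = {
            "start": cfg.window_start,
            "duration_s": rec.duration_s,
            "complete": rec.meta.get("window_complete"),
        }

    reasons: dict[str, str] = {}
    beats = detect_r_peaks(rec)
    rr = build_rr_series(beats)
    af = assess_af(rr)
    flags = {
        "is_af": af.is_af,
        "n_leads": rec.n_leads,
        "n_beats": len(beats.r_samples),
        "n_valid_intervals": int(rr.valid.sum()),
    }

    dcv = deceleration_capacity(rr, T=cfg.prsa_T, L=cfg.prsa_L)
    flags["n_anchors"] = dcv.n_anchors
    flags["dc_quality"] = dcv.quality

    prd_value = None
    try:
        prd_res, _ = prd_from_record(
            rec, beats, rr=rr, transform=cfg.transform, is_af=bool(af.is_af)
        )
        prd_value = prd_res.prd_deg2
        flags["prd_available"] = prd_value is not None
        if prd_value is None:
            reasons["prd"] = ",".join(prd_res.flags) or "unavailable"
    except InsufficientLeadsError:
        flags["prd_available"] = False
        reasons["prd"] = "insufficient_leads"

    hrv_dict = None
    caf_dict = None
    if af.is_af and not cfg.force:
        reasons["hrv"] = "atrial_fibrillation"
        reasons["caf"] = "atrial_fibrillation"
    else:
        try:
            m: HrvMetrics = hrv_metrics(rr)
            hrv_dict = dataclasses.asdict(m)
        except InsufficientDataError as exc:
            reasons["hrv"] = str(exc)
        if dcv.dc_ms is None:
            reasons["caf"] = "dc_undefined"
        else:
            result: CafResult = compute_caf(
                prd_value,
                dcv.dc_ms,
                coef,
                cutoff=cfg.cutoff,
                fallback=cfg.fallback,
                cap_dc_normal=cfg.cap_dc_normal,
            )
            caf_dict = dataclasses.asdict(result)

    return RunReport(
        record_id=rec.record_id,
        window=window_info,
        flags=flags,
        dc_ms=dcv.dc_ms,
        prd_deg2=prd_value,
        hrv=hrv_dict,
        caf=caf_dict,
        reasons=reasons,
        config_hash=cfg.hash(),
    )


REQUIRED_COHORT_COLUMNS = ["id", "time_days", "event", "caf", "saps3"]


def run_cohort(
    cohort: pd.DataFrame,
    cutoff: int = DEFAULT_CUTOFF,
    n_boot: int = 200,
    seed: int = 0,
) -> dict:
    """Validation-style statistics battery on a cohort table."""
    missing = [c for c in REQUIRED_COHORT_COLUMNS if c not in cohort.columns]
    if missing:
        raise ValueError(f"cohort table is missing columns: {missing}")
    df = cohort.dropna(subset=["time_days", "event", "caf", "saps3"]).copy()
    df["high_caf"] = (df["caf"] >= cutoff).astype(int)
    times = df["time_days"].to_numpy(float)
    events = df["event"].to_numpy(int)

    curves, logrank_p = km_curve(times, events, group=df["high_caf"].to_numpy())
    km_out = {
        str(g): {"mortality_30d": c.mortality_at(30.0), "n": c.n, "events": c.n_events}
        for g, c in curves.items()
    }

    roc = roc_youden(df["caf"].to_numpy(float), events.astype(bool))

    base_fit = fit_cox(df, ["saps3"])
    aug_fit = fit_cox(df, ["saps3", "high_caf"])
    base_lp = base_fit.coef["saps3"] * df["saps3"].to_numpy(float)
    aug_lp = (
        aug_fit.coef["saps3"] * df["saps3"].to_numpy(float)
        + aug_fit.coef["high_caf"] * df["high_caf"].to_numpy(float)
    )
    reclass = reclassification(base_lp, aug_lp, times, events, n_boot=n_boot, seed=seed)

    tiers = [classify_risk_tier(s, c, caf_cutoff=cutoff) for s, c in zip(df["saps3"], df["caf"])]
    tier_table = pd.Series([t.value for t in tiers]).value_counts().to_dict()

    return {
        "n": int(len(df)),
        "n_events": int(events.sum()),
        "high_caf_prevalence": float(df["high_caf"].mean()),
        "km_by_stratum": km_out,
        "logrank_p": logrank_p,
        "roc": {"auc": roc.auc, "youden_j": roc.youden_j, "threshold": roc.threshold},
        "cox": {
            "saps3_only": {"coef": base_fit.coef, "hr": base_fit.hr, "p": base_fit.p},
            "saps3_plus_caf": {"coef": aug_fit.coef, "hr": aug_fit.hr, "p": aug_fit.p},
        },
        "reclassification": {
            "idi": reclass.idi,
            "nri_continuous": reclass.nri_continuous,
            "median_improvement": reclass.median_improvement,
            "ci": reclass.ci,
        },
        "tier_table": tier_table,
    }
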