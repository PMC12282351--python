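"""Survival-statistics layer: Cox coefficient estimation, Kaplan-Meier with
Greenwood confidence intervals, log-rank, ROC/Youden, survival reclassification
metrics (IDI / continuous NRI / median improvement), fixed-threshold risk
tiers, and the events-per-variable sample-size rule.

Cox models are fitted with lifelines (Efron tie handling).  The Kaplan-Meier
product-limit estimator and the Greenwood variance are implemented here so the
standard error is exposed directly; confidence intervals are computed on the
log(-log) scale and clipped to [0, 1].

The endpoint convention is 30-day intrahospital mortality: deaths carry their
day, everyone else (including patients discharged alive before day 30) is
censored at day 30 — so every subject has known 30-day status and the
reclassification metrics are complete-case at the horizon.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats as scistats
from sklearn.metrics import roc_auc_score

from .errors import InsufficientDataError
from .score import ScoreCoefficients

FOLLOW_UP_DAYS = 30.0


# ---------------------------------------------------------------- Cox fitting

@dataclass
class CoxFit:
    """Per-covariate partial-likelihood estimates."""

    coef: dict[str, float]
    se: dict[str, float]
    hr: dict[str, float]
    ci_low: dict[str, float]
    ci_high: dict[str, float]
    p: dict[str, float]
    n: int
    n_events: int


def fit_cox(
    cohort: pd.DataFrame,
    covariates: list[str],
    duration_col: str = "time_days",
    event_col: str = "event",
) -> CoxFit:
    """Fit a Cox proportional-hazards model (Efron ties) on ``covariates``."""
    df = cohort[[duration_col, event_col, *covariates]].dropna()
    if df[event_col].sum() < 1:
        raise InsufficientDataError("no events in cohort")
    for c in covariates:
        if df[c].nunique() < 2:
            raise InsufficientDataError(f"covariate {c!r} is constant")
    cph = CoxPHFitter()
    cph.fit(df, duration_col=duration_col, event_col=event_col)
    s = cph.summary
    return CoxFit(
        coef=s["coef"].to_dict(),
        se=s["se(coef)"].to_dict(),
        hr=s["exp(coef)"].to_dict(),
        ci_low=s["exp(coef) lower 95%"].to_dict(),
        ci_high=s["exp(coef) upper 95%"].to_dict(),
        p=s["p"].to_dict(),
        n=len(df),
        n_events=int(df[event_col].sum()),
    )


def derive_score_coefficients(
    cohort: pd.DataFrame,
    prd_col: str = "prd",
    dc_col: str = "dc",
) -> ScoreCoefficients:
    """Training-cohort coefficient derivation: multivariable {PRD, DC} plus the
    univariable DC-only model for the PRD-unavailable scoring path."""
    multi = fit_cox(cohort, [prd_col, dc_col])
    uni = fit_cox(cohort, [dc_col])
    return ScoreCoefficients(
        beta_prd=multi.coef[prd_col],
        beta_dc=multi.coef[dc_col],
        beta_dc_uni=uni.coef[dc_col],
        source="cox-fit",
    )


# -------------------------------------------------------------- Kaplan-Meier

@dataclass
class KmEstimate:
    """Product-limit survival estimate with Greenwood standard errors."""

    times: np.ndarray
    survival: np.ndarray
    greenwood_se: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    n: int = 0
    n_events: int = 0

    def survival_at(self, t: float) -> float:
        """Step-function lookup S(t)."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])

    def mortality_at(self, t: float) -> float:
        return 1.0 - self.survival_at(t)


def _km_single(times: np.ndarray, events: np.ndarray, alpha: float = 0.05) -> KmEstimate:
    order = np.argsort(times, kind="stable")
    t, e = times[order], events[order].astype(bool)
    event_times = np.unique(t[e])
    n_risk = np.array([(t >= et).sum() for et in event_times], dtype=float)
    d = np.array([((t == et) & e).sum() for et in event_times], dtype=float)
    surv = np.cumprod(1.0 - d / n_risk)
    # Greenwood: Var[S] = S^2 * sum d / (n (n - d))
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(n_risk > d, d / (n_risk * (n_risk - d)), np.inf)
    cum = np.cumsum(terms)
    se = surv * np.sqrt(np.where(np.isfinite(cum), cum, 0.0))
    se = np.where(surv > 0, se, 0.0)
    z = scistats.norm.ppf(1 - alpha / 2)
    ci_low = np.empty_like(surv)
    ci_high = np.empty_like(surv)
    for i, (s, c) in enumerate(zip(surv, cum)):
        if s <= 0.0 or s >= 1.0 or not np.isfinite(c):
            ci_low[i] = ci_high[i] = s
            continue
        # log(-log) scale then back-transform
        se_theta = math.sqrt(c) / abs(math.log(s))
        ci_low[i] = s ** math.exp(z * se_theta)
        ci_high[i] = s ** math.exp(-z * se_theta)
    return KmEstimate(
        event_times,
        surv,
        se,
        np.clip(ci_low, 0.0, 1.0),
        np.clip(ci_high, 0.0, 1.0),
        n=len(t),
        n_events=int(e.sum()),
    )


def km_curve(
    times,
    events,
    group=None,
    alpha: float = 0.05,
):
    """Kaplan-Meier estimate; with ``group`` given, per-group estimates plus
    the log-rank p-value across groups.

    Subjects censored at the same time as an event are counted at risk for it
    (the standard events-before-censoring convention).
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events).astype(bool)
    if len(times) == 0:
        raise InsufficientDataError("empty cohort")
    if group is None:
        if events.sum() == 0:
            return KmEstimate(
                np.array([]), np.array([]), np.array([]), np.array([]), np.array([]),
                n=len(times), n_events=0,
            )
        return _km_single(times, events, alpha)
    group = np.asarray(group)
    curves = {}
    for g in np.unique(group):
        mask = group == g
        if mask.sum() == 0:
            raise InsufficientDataError(f"empty group {g!r}")
        curves[g] = km_curve(times[mask], events[mask], alpha=alpha)
    res = multivariate_logrank_test(times, group, events)
    return curves, float(res.p_value)


# ---------------------------------------------------------------- ROC/Youden

@dataclass
class RocResult:
    auc: float
    youden_j: float
    threshold: float
    sensitivity: float
    specificity: float


def roc_youden(scores, outcomes) -> RocResult:
    """Trapezoidal AUC and Youden's J = max(sens + spec - 1).

    The optimal threshold is the midpoint between the adjacent score values
    the cut separates ("score >= threshold" classifies positive).
    """
    scores = np.asarray(scores, dtype=float)
    outcomes = np.asarray(outcomes).astype(bool)
    if outcomes.all() or not outcomes.any():
        raise InsufficientDataError("both outcome classes must be present")
    auc = float(roc_auc_score(outcomes, scores))
    uniq = np.unique(scores)
    cand = np.concatenate([[uniq[0] - 1.0], (uniq[:-1] + uniq[1:]) / 2.0, [uniq[-1] + 1.0]])
    n_pos, n_neg = outcomes.sum(), (~outcomes).sum()
    best = (-np.inf, cand[0], 0.0, 0.0)
    for thr in cand:
        pred = scores >= thr
        sens = (pred & outcomes).sum() / n_pos
        spec = (~pred & ~outcomes).sum() / n_neg
        j = sens + spec - 1.0
        if j > best[0]:
            best = (j, thr, sens, spec)
    return RocResult(auc, float(best[0]), float(best[1]), float(best[2]), float(best[3]))


# ------------------------------------------------------------ reclassification

@dataclass
class ReclassificationResult:
    idi: float
    nri_continuous: float
    median_improvement: float
    ci: dict[str, tuple[float, float]] = field(default_factory=dict)


def _risks_from_lp(lp: np.ndarray, times: np.ndarray, events: np.ndarray, t0: float) -> np.ndarray:
    """Predicted t0-risk per subject: the cohort KM survival anchored at t0,
    raised to exp(centred linear predictor)."""
    km = km_curve(times, events)
    s0 = km.survival_at(t0) if km.n_events else 1.0
    s0 = min(max(s0, 1e-12), 1.0 - 1e-12)
    return 1.0 - s0 ** np.exp(lp - lp.mean())


def _reclass_point(
    r_base: np.ndarray, r_aug: np.ndarray, d: np.ndarray
) -> tuple[float, float, float]:
    ev, nev = d, ~d
    idi = (r_aug[ev].mean() - r_base[ev].mean()) - (r_aug[nev].mean() - r_base[nev].mean())
    up, down = r_aug > r_base, r_aug < r_base
    nri = (up[ev].mean() - down[ev].mean()) - (up[nev].mean() - down[nev].mean())
    med = (np.median(r_aug[ev]) - np.median(r_aug[nev])) - (
        np.median(r_base[ev]) - np.median(r_base[nev])
    )
    return float(idi), float(nri), float(med)


def reclassification(
    base_scores,
    augmented_scores,
    times,
    events,
    t0: float = FOLLOW_UP_DAYS,
    scores_are_risks: bool = False,
    n_boot: int = 1000,
    seed: int = 0,
) -> ReclassificationResult:
    """Survival-adapted IDI, continuous NRI, and median improvement at ``t0``.

    ``base_scores``/``augmented_scores`` are per-subject linear predictors
    (converted internally to KM-anchored t0-risks) or, with
    ``scores_are_risks=True``, predicted risks directly.  Percentile bootstrap
    CIs with ``n_boot`` replicates (0 disables them).
    """
    base = np.asarray(base_scores, dtype=float)
    aug = np.asarray(augmented_scores, dtype=float)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events).astype(bool)
    if t0 > times.max() and events.sum() == 0:
        raise InsufficientDataError("t0 beyond available follow-up")
    d = events & (times <= t0)
    if not d.any() or d.all():
        raise InsufficientDataError("need both events and non-events at t0")

    def point(b, a, tt, ee, dd):
        if scores_are_risks:
            rb, ra = b, a
        else:
            rb = _risks_from_lp(b, tt, ee, t0)
            ra = _risks_from_lp(a, tt, ee, t0)
        return _reclass_point(rb, ra, dd)

    idi, nri, med = point(base, aug, times, events, d)
    ci: dict[str, tuple[float, float]] = {}
    if n_boot > 0:
        rng = np.random.default_rng(seed)
        reps = np.empty((n_boot, 3))
        n = len(base)
        for b in range(n_boot):
            idx = rng.integers(0, n, n)
            db = d[idx]
            if not db.any() or db.all():
                reps[b] = (np.nan, np.nan, np.nan)
                continue
            reps[b] = point(base[idx], aug[idx], times[idx], events[idx], db)
        lo, hi = np.nanpercentile(reps, [2.5, 97.5], axis=0)
        ci = {
            "idi": (float(lo[0]), float(hi[0])),
            "nri_continuous": (float(lo[1]), float(hi[1])),
            "median_improvement": (float(lo[2]), float(hi[2])),
        }
    return ReclassificationResult(idi, nri, med, ci)


# ------------------------------------------------------------------ risk tiers

class RiskTier(enum.Enum):
    """Fixed-threshold SAPS3 x CAF risk groups (published decision-tree cuts).

    Naming follows the figure legend; the results-text names are aliases.
    """

    LOW = "low"
    INCREASED = "increased"
    HIGH = "high"
    VERY_HIGH = "very_high"

    @property
    def alias(self) -> str:
        return {
            RiskTier.LOW: "very_low",
            RiskTier.INCREASED: "low",
            RiskTier.HIGH: "intermediate",
            RiskTier.VERY_HIGH: "high",
        }[self]

    @property
    def ordinal(self) -> int:
        return list(RiskTier).index(self)


SAPS3_CUT_LOW = 56.0
SAPS3_CUT_MID = 69.0
SAPS3_CUT_HIGH = 89.0


def classify_risk_tier(saps3: float, caf: float, caf_cutoff: float = 11.0) -> RiskTier:
    """Deterministic tier from the published partition.

    low: SAPS3 < 56; increased: 56 <= SAPS3 < 69, or SAPS3 >= 69 with
    CAF < cutoff; high: 69 <= SAPS3 < 89 with CAF >= cutoff; very high:
    SAPS3 >= 89 with CAF >= cutoff.  Exactly one tier fires for every
    (saps3, caf) pair.
    """
    if saps3 < SAPS3_CUT_LOW:
        return RiskTier.LOW
    if saps3 < SAPS3_CUT_MID or caf < caf_cutoff:
        return RiskTier.INCREASED
    if saps3 < SAPS3_CUT_HIGH:
        return RiskTier.HIGH
    return RiskTier.VERY_HIGH


# ------------------------------------------------------------------ EPV rule

def sample_size_epv(n_params: int, event_rate: float, epv: int = 10) -> tuple[int, int]:
    """Events-per-variable minimum: (min_events, min_patients)."""
    if n_params < 1:
        raise ValueError("n_params must be at least 1")
    if not 0 < event_rate <= 1:
        raise ValueError("event_rate must be in (0, 1]")
    min_events = n_params * epv
    return min_events, math.ceil(min_events / event_rate)
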