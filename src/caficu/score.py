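"""The CAF-ICU cardiac autonomic function score.

The score combines sympathetic overactivity (rising PRD) and vagal impairment
(falling DC) into a single integer risk unit:

    CAF = round[ 10 * exp(beta_PRD * PRD + beta_DC * DC) ],  clamped to [0, 100]

with PRD capped at 30 deg^2, DC floored at 0 ms (and, in the default
normal-value mode, additionally capped at 4.5 ms — DC values at or above
4.5 ms are considered normal, so the benefit saturates).  When PRD is
unavailable (fewer than three ECG leads) the DC-only variant applies the
univariable DC coefficient in the same exponential template; the published
figure-caption formula ``round[10*(C*beta_DC + beta_DC*DC)]`` with C = 4.5 is
available verbatim behind ``fallback="caption-literal"`` for reproduction
studies (it conflicts with the methods text, which is why it is not the
default).

The cohort cutoff is the training-cohort median; the published constant is 11
units.  Rounding is half-away-from-zero; the even-n median is the lower
median, so the cutoff is always an attained integer score.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np

PRD_CAP_DEG2 = 30.0
DC_FLOOR_MS = 0.0
DC_NORMAL_MS = 4.5
SCORE_MIN = 0
SCORE_MAX = 100
DEFAULT_CUTOFF = 11

VARIANT_FULL = "full"
VARIANT_DC_ONLY = "dc_only"


@dataclass
class ScoreCoefficients:
    """Log-hazard coefficients feeding the score.

    ``beta_prd`` (per deg^2) and ``beta_dc`` (per ms) come from the
    multivariable model; ``beta_dc_uni`` from the univariable DC-only model
    used when PRD is unavailable.
    """

    beta_prd: float
    beta_dc: float
    beta_dc_uni: float
    source: str = "user"

    def __post_init__(self) -> None:
        for name in ("beta_prd", "beta_dc", "beta_dc_uni"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")
        if self.beta_prd <= 0 or self.beta_dc >= 0:
            warnings.warn(
                "unexpected coefficient signs (expected beta_prd > 0 > beta_dc); "
                "the score loses its monotone risk interpretation",
                stacklevel=2,
            )

    def to_json(self, path: str | Path, cutoff: int = DEFAULT_CUTOFF) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "beta_prd": self.beta_prd,
                    "beta_dc": self.beta_dc,
                    "beta_dc_uni": self.beta_dc_uni,
                    "cutoff": cutoff,
                    "source": self.source,
                },
                indent=2,
            )
        )

    @classmethod
    def from_json(cls, path: str | Path) -> tuple["ScoreCoefficients", int]:
        d = json.loads(Path(path).read_text())
        coef = cls(d["beta_prd"], d["beta_dc"], d["beta_dc_uni"], d.get("source", "file"))
        return coef, int(d.get("cutoff", DEFAULT_CUTOFF))


def reference_coefficients() -> ScoreCoefficients:
    """Reference coefficients calibrated to the published cohort summaries.

    The originally fitted values are not public; these are the unique pair for
    which the published marker medians (survivors PRD 7.2 deg^2 / DC 4.1 ms,
    non-survivors PRD 12.9 / DC 1.6) map onto the published score medians
    (11 and 14 units) under the score formula.  They are suitable for
    simulation and end-to-end exercises, not for clinical use.
    """
    return ScoreCoefficients(
        beta_prd=0.029660, beta_dc=-0.028839, beta_dc_uni=-0.10, source="table-calibrated"
    )


@dataclass
class CafResult:
    score: int
    variant: str
    high_risk: bool
    cutoff: int = DEFAULT_CUTOFF


def cap_markers(
    prd_deg2: float | None,
    dc_ms: float,
    cap_dc_normal: bool = True,
) -> tuple[float | None, float]:
    """Apply the marker caps: PRD <= 30 deg^2, DC >= 0 ms (and <= 4.5 ms when
    the normal-value cap mode is on)."""
    prd_c = None if prd_deg2 is None else min(float(prd_deg2), PRD_CAP_DEG2)
    dc_c = max(float(dc_ms), DC_FLOOR_MS)
    if cap_dc_normal:
        dc_c = min(dc_c, DC_NORMAL_MS)
    return prd_c, dc_c


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def compute_caf(
    prd_deg2: float | None,
    dc_ms: float,
    coef: ScoreCoefficients,
    cutoff: int = DEFAULT_CUTOFF,
    fallback: str = "exponential",
    cap_dc_normal: bool = True,
) -> CafResult:
    """Compute the integer score (0-100) and dichotomized risk flag.

    Capping is applied internally (idempotent, so pre-capped inputs are fine).
    With PRD None the DC-only variant is used and PRD is never read.
    """
    prd_c, dc_c = cap_markers(prd_deg2, dc_ms, cap_dc_normal=cap_dc_normal)
    if prd_c is not None:
        raw = 10.0 * math.exp(coef.beta_prd * prd_c + coef.beta_dc * dc_c)
        variant = VARIANT_FULL
    elif fallback == "exponential":
        raw = 10.0 * math.exp(coef.beta_dc_uni * dc_c)
        variant = VARIANT_DC_ONLY
    elif fallback == "caption-literal":
        raw = 10.0 * (DC_NORMAL_MS * coef.beta_dc_uni + coef.beta_dc_uni * dc_c)
        variant = VARIANT_DC_ONLY
    else:
        raise ValueError(f"unknown fallback mode {fallback!r}")
    score = min(SCORE_MAX, max(SCORE_MIN, _round_half_away(raw)))
    return CafResult(score, variant, score >= cutoff, cutoff)


def dichotomize_cohort(scores) -> int:
    """Training-cohort cutoff: the sample median (lower median on even n)."""
    arr = np.sort(np.asarray(list(scores)))
    if len(arr) == 0:
        raise ValueError("cannot take the median of an empty cohort")
    return int(arr[(len(arr) - 1) // 2])
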