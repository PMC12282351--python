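# caficu

Cardiac autonomic risk stratification for the intensive care unit, computed
automatically from routine monitor ECGs.

Established ICU scores such as SAPS3 summarise admission physiology but ignore
the state of the autonomic nervous system, which ECG monitoring measures for
free. `caficu` implements the full chain from a raw MIT-format ECG record to a
cardiac autonomic function score (CAF) and the survival statistics used to
derive and validate such a score:

- **DC — deceleration capacity of heart rate** (ms), an integral measure of
  deceleration-related heart-rate oscillations and an indirect quantifier of
  vagal activity. Computed by phase-rectified signal averaging (PRSA) of the
  RR-interval series with anchor smoothing T = 4 (recommended for noisy
  monitor signals) and Haar-wavelet quantification of the central averaged
  curve.
- **PRD — periodic repolarization dynamics** (deg²), low-frequency
  (≤ 0.1 Hz) oscillation of the T wave's spatial direction and a marker of
  sympathetic activity. Computed from the vectorcardiogram: per-beat
  amplitude-weighted repolarization direction T°, the angle dT° between
  successive T° vectors, and a Morlet continuous-wavelet quantification of
  the ≤ 0.1 Hz band of the dT° series.
- **The score**, combining both markers into integer risk units:

  ```
  CAF = round[ 10 · exp(β_PRD · PRD + β_DC · DC) ],   clamped to [0, 100]
  ```

  with PRD capped at 30 deg², DC capped into [0, 4.5] ms (values ≥ 4.5 ms are
  considered normal), a DC-only fallback when fewer than three ECG leads are
  available, and dichotomization at the training-cohort median (published
  constant: 11 units).
- **Survival statistics**: Cox coefficient estimation (lifelines, Efron
  ties), Kaplan–Meier with Greenwood standard errors and log(−log) confidence
  intervals, log-rank, ROC/Youden, survival-adapted IDI / continuous NRI /
  median improvement with bootstrap CIs, the fixed-threshold SAPS3 × CAF risk
  tiers (cuts at 56 / 69 / 89 with CAF 11), and events-per-variable sample
  size arithmetic.
- **Synthetic data** with exported ground truth: RR series with tunable
  oscillatory structure, 3-lead ECGs whose T-wave axis rotates at a chosen
  frequency and amplitude, and cohorts drawn from a known proportional-hazards
  model — so the entire chain is testable without patient data.

Also included: a Task-Force HRV battery (SDNN, RMSSD, triangular index,
VLF/LF/HF band powers), an RR-irregularity AF screen, and a minimal
MIT-format (.hea/.dat) reader/writer.

## Worked example

```python
import datetime
import caficu as cf

# a 30-minute 3-lead record on the standardized 02:00-02:30 analysis window
rec, _ = cf.simulate_ecg(cf.EcgSimConfig(duration_s=1800, t_axis_amp_deg=8.0, seed=11))
rec.t0 = datetime.time(2, 0, 0)

report = cf.run_patient(rec, cf.reference_coefficients())
print(f"DC      = {report.dc_ms:.2f} ms")
print(f"PRD     = {report.prd_deg2:.3f} deg^2")
print(f"SDNN    = {report.hrv['sdnn_ms']:.1f} ms   RMSSD = {report.hrv['rmssd_ms']:.1f} ms")
print(f"CAF     = {report.caf['score']} units ({report.caf['variant']})")
```

prints

```
DC      = 9.61 ms
PRD     = 0.004 deg^2
SDNN    = 20.4 ms   RMSSD = 25.4 ms
CAF     = 9 units (full)
```

A high DC (strong vagal deceleration structure — this record's RR series
carries deceleration bursts) and a tiny PRD (only an 8° slow T-axis wobble on
a noise-free record) give a score of 9 units, below the 11-unit high-risk
cutoff. Combined with a SAPS3 of 72 this patient would fall in the second
("increased") of the four published risk tiers:

```python
from caficu.stats import classify_risk_tier
classify_risk_tier(72, 9)   # -> RiskTier.INCREASED
```

The same chain is available from the shell:

```sh
caf simulate ecg --seed 11 --out rec          # writes rec.hea/rec.dat
caf run --record rec --no-window              # JSON report
caf score --prd 12.9 --dc 1.6                 # -> {"score": 14, ...}
```

The published coefficients were never printed; `reference_coefficients()`
ships values calibrated so the published marker medians map onto the published
score medians (see `docs/methods.md`). For real use, derive coefficients from
a training cohort with `derive_score_coefficients()`.

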