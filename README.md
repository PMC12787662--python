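# tricadence

Movement-cadence analysis for triathlon from a single trunk-worn inertial
measurement unit (IMU): detect swimming strokes, cycling pedal strokes and
running strides from 100 Hz accelerometer/gyroscope traces, assemble
per-race cadences into a longitudinal dataset, and model how cadence
changes over a racing season with linear and penalized-smooth mixed
models.

It is written for sports scientists and biomechanists who monitor
athletes with wearable sensors and want a tested, reproducible pipeline
from raw signals to a statistical verdict — including a synthetic-data
module with exact ground truth, so every stage can be validated without
any proprietary recordings.

## The method

**Detection.** Each discipline is counted from the axis carrying its
movement signature: swim strokes as peaks *and* troughs of the
medio-lateral acceleration, pedal strokes as yaw-gyroscope extrema
confirmed against the antero-posterior accelerometer, and strides as
vertical-acceleration peaks. Channels are filtered with a zero-phase
4th-order Butterworth low-pass, extrema are screened by robust prominence
and thinned with a 0.25–0.5 s minimum detection (refractory) interval;
average cadence is 60 × count / duration.

**Modelling.** For cadence C of athlete i at week W, with season as a
categorical fixed effect and per-athlete random intercepts and slopes,

    linear:      C_it = β0 + β1·W_it + β2·season_it + b0_i + b1_i·W_it + ε_it
    non-linear:  C_it = β0 + f(W_it) + β2·season_it + b0_i + b1_i·W_it + ε_it

where b0_i ~ N(0, σ²_b0), b1_i ~ N(0, σ²_b1), ε_it ~ N(0, σ²) and f is a
thin-plate regression spline. Both are penalized least-squares problems
estimated by restricted maximum likelihood (REML); the fit reports
variance components, effective degrees of freedom (eDF), AIC/BIC/adjusted
r², population prediction curves with pointwise 95% CIs, individual
trajectories pooled toward the population mean, weekly percentage change,
and a likelihood-ratio comparison of the two models. See
`docs/methods.md` for the full account.

## Worked example

```python
import numpy as np
from tricadence import *

# 1. a noisy 5-minute swim recording with known stroke times
cfg = SignalGenConfig("swim", duration_s=300.0, cadence_events_per_min=64.0,
                      jitter_cv=0.05, noise_snr_db=10.0,
                      spike_rate_per_min=2.0, seed=42)
rec, truth = gen_imu_recording(cfg)
events = detect(rec, "swim")
print(truth.count, events.count, average_cadence(events, rec.duration_s))
# -> 321 321 64.2    (all 321 true strokes recovered; 64.20 strokes/min)

# 2. a simulated season with a mid-season dip in cadence, and both models
season = SeasonGenConfig(n_participants=12, weeks=tuple(range(15)),
                         trend_shape="u_shape", beta0=60.0, beta2=2.0,
                         trend_amp=5.0, sd_b0=4.0, sd_b1=0.2, sd_eps=2.0,
                         two_season_fraction=0.5, seed=3)
data, _ = gen_season_dataset(season)
fit_lin = fit_model(data, DesignSpec("linear"))
fit_nl = fit_model(data, DesignSpec("nonlinear"))
cmp = compare_models(fit_lin, fit_nl)
```

The comparison prints AIC 892.81 (linear) vs 790.46 (non-linear), BIC
944.51 vs 864.77, adjusted r² 0.846 vs 0.915, and a likelihood-ratio
statistic D = 116.52 on 8.38 effective df (p ≈ 3e−21): the smooth model
decisively wins because the simulated truth really dips mid-season, and
its eDF of 4.62 quantifies that curvature. The fitted population curve
falls from 60.4 strokes/min at week 0 to 55.9 at week 7 and recovers to
61.0 by week 14 — a mean change of +1.25% per week over weeks 7–14:

```python
curve = predict_curve(fit_nl, np.arange(15.0), season=1)
pct, mean_pct = weekly_percent_change(curve, window=(7, 14))
```

On linear-truth data the same comparison correctly stays null (the
smooth's eDF collapses toward ~1 and p is large) — that calibration is
exercised by the test suite.

A command-line interface wraps the same library:

```sh
tricadence simulate --kind imu --discipline swim --output rec.csv
tricadence detect --input rec.csv --discipline swim --output events.csv
tricadence run-all --seed 1 --outdir out/   # simulate -> detect -> assemble -> model
```

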