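# Methods

`tricadence` implements a complete analysis chain for movement cadence in
triathlon measured by a single trunk-worn IMU (tri-axial accelerometer,
m/s², and gyroscope, deg/s, both at 100 Hz): event detection from the raw
signals, assembly of a longitudinal race table, and season-level modelling
of cadence with linear and penalized-smooth mixed models. Because raw
competition recordings are not redistributable, the package ships a
first-class synthetic-data module whose generators carry exact ground
truth; every quantitative claim in the test suite is computed against that
truth at run time.

## Event detection

Each discipline uses the axis that carries the cleanest movement
signature: swimming strokes are peaks *and* troughs of the medio-lateral
acceleration (trunk roll with each arm stroke); cycling pedal strokes are
peaks and troughs of the yaw angular velocity, each candidate confirmed by
an extremum of the antero-posterior acceleration within ±0.15 s; running
strides are peaks of the vertical acceleration (one impact per stride).

The channel is low-pass filtered with a zero-phase (forward–backward)
4th-order Butterworth filter, so the effective magnitude response is the
squared single-pass response and no phase delay is introduced. Default
corner frequencies are 3 Hz (swim), 6 Hz (cycle) and 8 Hz (run): each
passes the discipline's fundamental event frequency (≈0.4–1.7 Hz for the
oscillatory disciplines, impact content to a few Hz for running) with wide
margin while rejecting broadband noise and one-sample artifacts.

Candidate extrema are screened by prominence. The threshold is
`max(prominence_frac × robust_amplitude, min_prominence_abs)` where the
robust amplitude is 1.4826 × MAD of the filtered channel (equal to the
amplitude for a pure sinusoid) and `prominence_frac` defaults to 0.2. The
absolute floor (`min_prominence_abs`, defaults 0.5 m/s² swim, 10 deg/s
cycle, 2 m/s² run) exists because a purely channel-relative threshold is
scale-free: a channel carrying only sensor noise would still present
extrema at a fixed fraction of its own robust amplitude, and a detector
that reports events from a noise-only channel is useless in practice. The
floors sit several-fold below genuine movement amplitudes.

Surviving candidates are thinned with a refractory (minimum detection)
interval between 0.25 and 0.5 s: greedy acceptance in order of descending
prominence (earlier wins ties), rejecting any candidate closer than the
interval to an accepted event of either kind. Defaults are 0.5 s for swim
and run and 0.25 s for cycling, staying below the inter-event interval at
each discipline's maximum plausible cadence (80 strokes/min → 0.75 s;
200 pedal strokes/min → 0.30 s; 95 strides/min → 0.63 s).

**Record boundaries.** A genuine extremum shortly before the record end
has near-zero textbook prominence — the record stops before the signal
descends past the extremum's base. Prominence is therefore assessed on a
slope-continued linear extension of the filtered signal (single-increment
slope, clamped to the signal's range, one refractory interval long);
candidates outside the original sample range are discarded. Even so,
an event within roughly half the filter's response width of either
boundary (~0.1 s at a 3 Hz corner) is unrecoverable by *any* zero-phase
filter: the turn never materialises in the filtered record. This is why
count accuracy on clean finite records saturates just below 100% when
event times fall arbitrarily relative to the window, and why the
noise-free oracle sweep uses integer cadences, which place events at
quarter-period offsets from the record ends.

Average cadence is `60 × count / duration` (events/min).

## Synthetic recordings

The oscillatory disciplines use a sinusoid with per-cycle period jitter:
cycle boundary times come from intervals Normal(T, (cv·T)²) truncated at
0.1 T (one standard-normal draw per interval, so the interval stream is
reproducible independently of the noise settings), and the phase is
piecewise-linear between boundaries. Ground-truth events are the exact
quarter- and three-quarter-phase times. Running uses Gaussian impact
pulses of 60 ms FWHM centred in each stride interval. Primary-channel
amplitudes are physiologically plausible (3 m/s² swim ML, 60 deg/s cycle
yaw with a 1.5 m/s² phase-locked AP companion, 8 m/s² run vertical);
off-axis channels carry only 0.15-unit white noise so axis selection is
testable. Degradations: additive white Gaussian noise calibrated to an
SNR in dB against the clean signal RMS, a 0.1 Hz baseline-wander
sinusoid, and one-sample spikes of 5× signal amplitude with random sign
at a Poisson rate. What this emulates — quasi-periodic propulsion,
broadband noise, attachment artifacts — and what it does not: real stroke
asymmetry, turns, coasting, multi-path harmonics, or device saturation.
Passing tests therefore demonstrate algorithmic correctness and noise
robustness, not field validity on real recordings.

Default cadence ranges are 50–80 strokes/min (swim), 150–200 pedal
strokes/min (cycle) and 75–95 strides/min (run).

## Race-table assembly

Races carrying any exclusion flag (`unwell`, `injured_during_race`,
`imu_attachment_fault`, `gps_fail`) are dropped as units; multiple races
by one participant on one day in one discipline are averaged into a
single observation (the target is longitudinal, not acute, change); then
discipline chaining removes a cycle leg without its same-day swim and a
run leg without both predecessors, since each leg's performance carries
into the next. Assembly order is flag removal → same-day merge →
chaining, so a flagged race never contaminates a same-day average.
A missing race distance can be imputed as the mean of the distances
recorded by other participants' working GPS units in the same race;
average race velocity (distance/duration) is carried descriptively and
never modelled.

## Longitudinal models

For cadence C of athlete i at week W (week 0 = first race week of the
season calendar; season entered as a categorical fixed effect with season
1 as reference):

    linear:     C_it = β0 + β1 W_it + β2 season_it + b0_i + b1_i W_it + ε_it
    non-linear: C_it = β0 + f(W_it) + β2 season_it + b0_i + b1_i W_it + ε_it

with b0_i ~ N(0, σ²_b0), b1_i ~ N(0, σ²_b1), ε_it ~ N(0, σ²), all
mutually independent, and f a thin-plate regression spline of the week
number.

**TPRS construction.** From the full 1-D thin-plate system (radial basis
|r|³, null space {1, W}) on the distinct observed weeks, the wiggly
subspace is projected onto the k leading eigenvectors of the radial
kernel (k = 10 by default, capped at the number of distinct weeks), the
thin-plate side constraint is absorbed, and columns are centred
(sum-to-zero over observations) for identifiability against the
intercept. The penalty is PSD and exactly zero on constant and linear
functions.

**Estimation.** Random effects are ridge-penalized coefficient blocks
(random-effect smooths), so both models are penalized least squares with
penalty parameters chosen by exact Gaussian REML: the criterion
−l_R = ½(n−M_p)(log 2πσ̂²+1) − ½log|S_λ|₊ + ½log|B′B+S_λ| with σ²
profiled out, optimized over log-parameters by Nelder–Mead from three
fixed starts (0, ±4), convergence at 1e−8 on the criterion,
log-parameters clipped to [−18, 22]. The smooth carries a *double*
penalty — its curvature penalty plus a separate shrinkage ridge on its
linear null space — so the smooth's effective degrees of freedom can fall
below 1 when the data carry no week trend at all. Variance components are
recovered as σ̂²/λ̂ for the ridge blocks. This implementation reproduces
lme4's REML optimum to six significant digits on a frozen linear-model
fixture and mgcv's population curve to <0.2 events/min on a frozen
smooth-model fixture (see `tests/test_crosscheck.py`).

**Effective df, criteria, comparison.** Per-coefficient edf is the
diagonal of (B′B+S_λ)⁻¹B′B; `edf_total` its trace; `edf_smooth` the sum
over the smooth's columns. The conditional log-likelihood at the fitted
values uses the profiled ML variance RSS/n (the convention mgcv's
`logLik.gam` uses for Gaussian fits); AIC = −2ℓ + 2·edf_total,
BIC = −2ℓ + log(n)·edf_total, adjusted r² = 1 − (RSS/(n−edf_total)) /
(TSS/(n−1)), reported unclipped. The likelihood-ratio statistic is
D = 2(ℓ_nl − ℓ_lin) clipped at zero, referred to χ² with
df = max(Δedf_test, 0.5) where edf_test = 2 tr(F) − tr(FF) is the
smoothing-corrected effective df. The plain Δtr(F) reference is
measurably anti-conservative (≈0.13–0.17 type-I at α = 0.05 in
200-replicate linear-truth simulations; mgcv's own `anova` rejects at
≈0.47 on the same data), while the corrected df brings the test to ≈0.06
— the corrected form is the package's deliberate choice. All p-values
near the variance boundary are approximate (the null distribution is a
χ² mixture); comparisons carry a `boundary_warning` flag.

**Prediction.** Population curves set random effects to zero; pointwise
95% CIs are ±1.96 × SE from the Bayesian posterior covariance
σ̂²(B′B+S_λ)⁻¹ restricted to fixed + smooth coefficients. Individual
trajectories add each athlete's b̂0 + b̂1·W; penalization pools them
toward the population mean, so they need not pass through the raw data.
Grid points outside the observed week range are flagged, not refused.
Weekly percentage change is 100·(m[w+1]−m[w])/m[w] on a unit-step grid,
with its arithmetic mean over a window.

**Normality check.** A one-sample Kolmogorov–Smirnov statistic against a
normal with sample-estimated mean/SD, with the p-value calibrated by
seeded Monte Carlo (2000 replicates re-estimating the parameters,
Lilliefors-style) rather than the naive KS distribution.

## Simulation study sizes

The test suite's simulation studies use sizes on the scale of a junior
squad followed for one season, chosen once: variance-component recovery
uses 40 participants × 15 weeks (30 seeds); likelihood-ratio calibration
and power and CI coverage use 10 participants × 12 weeks (200, 100 and
200 replicates), with σ_b0 = 3, σ_b1 = 0.1, σ = 2 events/min and a
mid-season dip of 5× (power) or 3× (coverage) the residual SD. Detection
benchmarks use 60 recordings of 300 s per discipline at 10 dB SNR, 5%
interval jitter and 2 spikes/min.

## Known limitations

* Events within ~half a filter response width of a record boundary are
  undetectable in principle; counts on finite windows can differ from
  ground truth by ±1 per boundary.
* The LRT's χ² reference remains approximate near the smoothing boundary
  even with the corrected df.
* The double-penalty smooth deliberately shrinks the linear null space;
  its edf is therefore not directly comparable to a default (unshrunk)
  mgcv smooth when the trend is near-linear.
* The cycling confirmation window (±0.15 s) loses selectivity at very
  high cadences where antero-posterior extrema are dense.
* Synthetic signals are morphologically minimal (see above); duathlon
  race formats are out of scope and must be pre-segmented upstream.
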