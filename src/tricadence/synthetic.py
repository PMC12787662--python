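"""Synthetic IMU recordings and season-long cadence datasets with known truth.

Two generators back the whole pipeline:

* :func:`gen_imu_recording` builds a quasi-periodic six-channel inertial
  recording for one triathlon discipline together with the exact ground-truth
  propulsive-event times (swim strokes, pedal strokes or run strides).
* :func:`gen_season_dataset` builds a longitudinal race-cadence table from the
  additive mixed model

      C_it = beta0 + f(W_it) + beta2 * season_it + b0_i + b1_i * W_it + eps_it

  with Gaussian random intercepts ``b0_i``, random slopes ``b1_i`` and
  residuals ``eps_it``, returning every realised latent quantity so parameter
  recovery is testable.

Signal morphology is deliberately minimal: a sinusoid with per-cycle period
jitter for the oscillatory disciplines (swim medio-lateral acceleration,
cycling yaw angular velocity plus a phase-locked antero-posterior companion)
and a train of Gaussian impact pulses for running.  Peaks and troughs of the
oscillation (or impact apices for running) are the ground truth, so every
downstream detector has an exact oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd

__all__ = [
    "SignalGenConfig",
    "SeasonGenConfig",
    "ImuRecording",
    "EventSeries",
    "gen_imu_recording",
    "gen_season_dataset",
    "trend_function",
    "DEFAULT_CADENCE_RANGES",
]

#: Physiologically plausible cadence ranges, events/min.
DEFAULT_CADENCE_RANGES = {
    "swim": (50.0, 80.0),
    "cycle": (150.0, 200.0),
    "run": (75.0, 95.0),
}

#: Peak amplitude of the primary oscillation / impact per discipline, in the
#: channel's native units (m/s^2 for accelerometer axes, deg/s for gyroscope).
_PRIMARY_AMPLITUDE = {"swim": 3.0, "cycle": 60.0, "run": 8.0}

#: Amplitude of the cycling antero-posterior accelerometer companion (m/s^2).
_CYCLE_AP_AMPLITUDE = 1.5

#: Standard deviation of the pure-noise off-axis channels.
_OFFAXIS_NOISE_SD = 0.15

#: FWHM of the running impact pulse, seconds.
_RUN_PULSE_FWHM_S = 0.060

_CHANNELS = ("acc_ml", "acc_ap", "acc_v", "gyr_yaw", "gyr_roll", "gyr_pitch")


class InvalidConfigError(ValueError):
    """Raised when a generator configuration violates its invariants."""


@dataclass(frozen=True)
class SignalGenConfig:
    """Configuration for one synthetic IMU recording.

    Parameters
    ----------
    discipline
        ``"swim"``, ``"cycle"`` or ``"run"``.
    duration_s
        Recording length in seconds (> 0).
    cadence_events_per_min
        Target propulsive-event rate (events/min), or a callable of time in
        seconds returning an instantaneous rate (week-invariant profile).
    sample_rate_hz
        Sampling rate, default 100 Hz.
    jitter_cv
        Coefficient of variation of the inter-cycle intervals (>= 0).
    noise_snr_db
        SNR of additive white Gaussian noise relative to the clean primary
        channel's RMS; ``None`` disables noise.
    drift_amp
        Amplitude of a 0.1 Hz baseline-wander sinusoid added to the primary
        channel (native units).
    spike_rate_per_min
        Expected rate of one-sample artifact spikes (5x signal amplitude,
        random sign) on the primary channels.
    seed
        RNG seed; identical configs produce identical recordings.
    """

    discipline: str
    duration_s: float
    cadence_events_per_min: float | Callable[[float], float]
    sample_rate_hz: float = 100.0
    jitter_cv: float = 0.0
    noise_snr_db: float | None = None
    drift_amp: float = 0.0
    spike_rate_per_min: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.discipline not in ("swim", "cycle", "run"):
            raise InvalidConfigError(f"unknown discipline {self.discipline!r}")
        if not self.duration_s > 0:
            raise InvalidConfigError("duration_s must be > 0")
        if not self.sample_rate_hz > 0:
            raise InvalidConfigError("sample_rate_hz must be > 0")
        if self.jitter_cv < 0:
            raise InvalidConfigError("jitter_cv must be >= 0")
        if self.spike_rate_per_min < 0:
            raise InvalidConfigError("spike_rate_per_min must be >= 0")


@dataclass
class ImuRecording:
    """Synchronised six-channel IMU traces at a fixed sampling rate.

    Accelerometer channels are in m/s^2 (medio-lateral, antero-posterior,
    vertical); gyroscope channels in deg/s (yaw, roll, pitch).
    """

    time_s: np.ndarray
    acc_ml: np.ndarray
    acc_ap: np.ndarray
    acc_v: np.ndarray
    gyr_yaw: np.ndarray
    gyr_roll: np.ndarray
    gyr_pitch: np.ndarray
    sample_rate_hz: float
    discipline: str | None = None

    def __post_init__(self) -> None:
        n = len(self.time_s)
        for name in _CHANNELS:
            if len(getattr(self, name)) != n:
                raise ValueError(f"channel {name} length mismatch")
        if self.sample_rate_hz <= 0:
            raise ValueError("sample_rate_hz must be > 0")

    @property
    def n_samples(self) -> int:
        return len(self.time_s)

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sample_rate_hz

    def channel(self, name: str) -> np.ndarray:
        if name not in _CHANNELS:
            raise KeyError(name)
        return getattr(self, name)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_s": self.time_s, **{c: getattr(self, c) for c in _CHANNELS}})


@dataclass
class EventSeries:
    """Strictly increasing propulsive-event timestamps for one discipline."""

    event_times_s: np.ndarray
    discipline: str | None = None

    def __post_init__(self) -> None:
        self.event_times_s = np.asarray(self.event_times_s, dtype=float)
        if self.event_times_s.size > 1 and np.any(np.diff(self.event_times_s) <= 0):
            raise ValueError("event times must be strictly increasing")

    @property
    def count(self) -> int:
        return int(self.event_times_s.size)

    def __len__(self) -> int:
        return self.count


def _interval_stream(
    rng: np.random.Generator,
    rate_per_s: float | Callable[[float], float],
    duration_s: float,
    jitter_cv: float,
) -> np.ndarray:
    """Boundary times of successive cycles covering [0, duration_s].

    Interval k is Normal(T_k, (jitter_cv * T_k)^2) truncated below at
    0.1 * T_k, where T_k is the nominal period at the current time.  One
    standard-normal draw is consumed per interval regardless of jitter_cv,
    which keeps the interval stream reproducible across noise settings.
    """
    times = [0.0]
    t = 0.0
    while t <= duration_s:
        rate = rate_per_s(t) if callable(rate_per_s) else rate_per_s
        if rate <= 0:
            raise InvalidConfigError("cadence profile must stay positive")
        period = 1.0 / rate
        z = rng.standard_normal()
        interval = max(period * (1.0 + jitter_cv * z), 0.1 * period)
        t += interval
        times.append(t)
    return np.asarray(times)


def _phase_from_boundaries(t: np.ndarray, boundaries: np.ndarray) -> np.ndarray:
    """Piecewise-linear cycle phase: 2*pi*k at boundary k."""
    idx = np.searchsorted(boundaries, t, side="right") - 1
    idx = np.clip(idx, 0, len(boundaries) - 2)
    left = boundaries[idx]
    width = boundaries[idx + 1] - boundaries[idx]
    return 2.0 * np.pi * (idx + (t - left) / width)


def _add_noise_drift_spikes(
    rng: np.random.Generator,
    signal: np.ndarray,
    t: np.ndarray,
    cfg: SignalGenConfig,
    amplitude: float,
) -> np.ndarray:
    out = signal.copy()
    if cfg.noise_snr_db is not None:
        signal_rms = float(np.sqrt(np.mean(signal**2)))
        noise_rms = signal_rms / (10.0 ** (cfg.noise_snr_db / 20.0))
        out = out + noise_rms * rng.standard_normal(len(t))
    if cfg.drift_amp != 0.0:
        out = out + cfg.drift_amp * np.sin(2.0 * np.pi * 0.1 * t)
    if cfg.spike_rate_per_min > 0:
        n_spikes = rng.poisson(cfg.spike_rate_per_min * cfg.duration_s / 60.0)
        if n_spikes > 0:
            pos = rng.integers(0, len(t), size=n_spikes)
            sign = rng.choice([-1.0, 1.0], size=n_spikes)
            out[pos] = out[pos] + sign * 5.0 * amplitude
    return out


def gen_imu_recording(config: SignalGenConfig) -> tuple[ImuRecording, EventSeries]:
    """Generate one synthetic recording plus its ground-truth event series.

    Swim: the medio-lateral accelerometer carries the oscillation and each
    peak *and* each trough is one stroke.  Cycle: the yaw gyroscope carries
    the oscillation (peaks + troughs = pedal strokes) and the
    antero-posterior accelerometer a phase-locked companion.  Run: the
    vertical accelerometer carries one Gaussian impact per stride (peaks
    only).  Off-axis channels are pure low-level noise so axis selection is
    testable.
    """
    rng = np.random.default_rng(config.seed)
    n = int(round(config.duration_s * config.sample_rate_hz))
    t = np.arange(n) / config.sample_rate_hz
    amp = _PRIMARY_AMPLITUDE[config.discipline]

    rate_fn = config.cadence_events_per_min
    events_per_s: float | Callable[[float], float]
    if callable(rate_fn):
        events_per_s = lambda s: rate_fn(s) / 60.0  # noqa: E731
    else:
        events_per_s = rate_fn / 60.0

    if config.discipline in ("swim", "cycle"):
        # One oscillation cycle yields two events (peak + trough).
        cycles_per_s = (
            (lambda s: events_per_s(s) / 2.0) if callable(events_per_s) else events_per_s / 2.0
        )
        bounds = _interval_stream(rng, cycles_per_s, config.duration_s, config.jitter_cv)
        phase = _phase_from_boundaries(t, bounds)
        clean = amp * np.sin(phase)
        widths = np.diff(bounds)
        peaks = bounds[:-1] + 0.25 * widths
        troughs = bounds[:-1] + 0.75 * widths
        truth = np.sort(np.concatenate([peaks, troughs]))
        truth = truth[truth < config.duration_s]
    else:  # run
        bounds = _interval_stream(rng, events_per_s, config.duration_s, config.jitter_cv)
        impacts = bounds[:-1] + 0.5 * np.diff(bounds)  # one impact per stride cycle
        truth = impacts[impacts < config.duration_s]
        sigma = _RUN_PULSE_FWHM_S / (2.0 * np.sqrt(2.0 * np.log(2.0)))
        clean = np.zeros(n)
        half = 4.0 * sigma
        for ti in truth:
            lo = max(0, int((ti - half) * config.sample_rate_hz))
            hi = min(n, int((ti + half) * config.sample_rate_hz) + 1)
            clean[lo:hi] += amp * np.exp(-0.5 * ((t[lo:hi] - ti) / sigma) ** 2)

    primary = _add_noise_drift_spikes(rng, clean, t, config, amp)

    channels = {c: _OFFAXIS_NOISE_SD * rng.standard_normal(n) for c in _CHANNELS}
    if config.discipline == "swim":
        channels["acc_ml"] = primary
    elif config.discipline == "run":
        channels["acc_v"] = primary
    else:
        channels["gyr_yaw"] = primary
        companion = _CYCLE_AP_AMPLITUDE * np.sin(phase)
        channels["acc_ap"] = _add_noise_drift_spikes(
            rng, companion, t, config, _CYCLE_AP_AMPLITUDE
        )

    rec = ImuRecording(
        time_s=t, sample_rate_hz=config.sample_rate_hz, discipline=config.discipline, **channels
    )
    return rec, EventSeries(truth, discipline=config.discipline)


# ---------------------------------------------------------------------------
# Season-long longitudinal cadence datasets
# ---------------------------------------------------------------------------

#: Sprint-distance segment scale (distance m, duration s) per discipline.
_RACE_SCALE = {"swim": (750.0, 660.0), "cycle": (20000.0, 2100.0), "run": (5000.0, 1250.0)}


@dataclass(frozen=True)
class SeasonGenConfig:
    """Configuration for a season-long longitudinal cadence dataset.

    ``trend_shape`` selects the population smooth f(W): ``flat`` (zero),
    ``linear`` (beta1 * W), ``u_shape`` (negative Gaussian dip centred
    mid-season, depth ``trend_amp``) or ``rise_plateau`` (logistic rise of
    height ``trend_amp``).  ``two_season_fraction`` of participants have all
    their observations labelled season 2 (receiving the ``beta2`` offset).
    """

    n_participants: int
    weeks: tuple[float, ...] = tuple(range(15))
    trend_shape: str = "flat"
    beta0: float = 60.0
    beta1: float = 0.0
    beta2: float = 0.0
    trend_amp: float = 5.0
    sd_b0: float = 0.0
    sd_b1: float = 0.0
    sd_eps: float = 0.0
    discipline: str = "swim"
    two_season_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_participants < 2:
            raise InvalidConfigError("n_participants must be >= 2")
        if len(self.weeks) < 1:
            raise InvalidConfigError("every participant needs >= 1 week")
        if min(self.sd_b0, self.sd_b1, self.sd_eps) < 0:
            raise InvalidConfigError("all SDs must be >= 0")
        if self.trend_shape not in ("flat", "linear", "u_shape", "rise_plateau"):
            raise InvalidConfigError(f"unknown trend_shape {self.trend_shape!r}")
        if not 0.0 <= self.two_season_fraction <= 1.0:
            raise InvalidConfigError("two_season_fraction must lie in [0, 1]")


def trend_function(config: SeasonGenConfig) -> Callable[[np.ndarray], np.ndarray]:
    """Population smooth f(W) selected by ``config.trend_shape``."""
    w = np.asarray(config.weeks, dtype=float)
    lo, hi = float(w.min()), float(w.max())
    mid = 0.5 * (lo + hi)
    rng_w = max(hi - lo, 1.0)

    shape = config.trend_shape
    if shape == "flat":
        return lambda x: np.zeros_like(np.asarray(x, dtype=float))
    if shape == "linear":
        return lambda x: config.beta1 * np.asarray(x, dtype=float)
    if shape == "u_shape":
        s = rng_w / 6.0
        return lambda x: -config.trend_amp * np.exp(
            -0.5 * ((np.asarray(x, dtype=float) - mid) / s) ** 2
        )
    # rise_plateau: saturating logistic increase
    s = rng_w / 8.0
    return lambda x: config.trend_amp / (1.0 + np.exp(-(np.asarray(x, dtype=float) - mid) / s))


def gen_season_dataset(config: SeasonGenConfig) -> tuple[pd.DataFrame, dict]:
    """Simulate a longitudinal race-cadence table and return the latent truth.

    Returns
    -------
    data : pandas.DataFrame
        Columns ``participant_id, week, season, discipline, cadence,
        distance_m, duration_s, flags`` (the longitudinal CSV dialect).
    truth : dict
        ``beta0, beta1, beta2, sd_b0, sd_b1, sd_eps, b0 (per participant),
        b1 (per participant), f (per observation), eps (per observation),
        trend`` — enough to reconstruct every cadence exactly.
    """
    rng = np.random.default_rng(config.seed)
    m = config.n_participants
    b0 = rng.normal(0.0, config.sd_b0, size=m) if config.sd_b0 > 0 else np.zeros(m)
    b1 = rng.normal(0.0, config.sd_b1, size=m) if config.sd_b1 > 0 else np.zeros(m)
    n_s2 = int(round(config.two_season_fraction * m))
    season_of = np.array([2] * n_s2 + [1] * (m - n_s2))

    f = trend_function(config)
    rows = []
    f_vals, eps_vals = [], []
    weeks = np.asarray(config.weeks, dtype=float)
    for i in range(m):
        pid = f"P{i + 1:02d}"
        for wk in weeks:
            fw = float(f(wk))
            eps = rng.normal(0.0, config.sd_eps) if config.sd_eps > 0 else 0.0
            season = int(season_of[i])
            cad = (
                config.beta0
                + fw
                + config.beta2 * (season == 2)
                + b0[i]
                + b1[i] * wk
                + eps
            )
            # Descriptive race covariates; carried but never modelled.
            dist, dur = _RACE_SCALE[config.discipline]
            rows.append(
                {
                    "participant_id": pid,
                    "week": wk,
                    "season": season,
                    "discipline": config.discipline,
                    "cadence": cad,
                    "distance_m": dist,
                    "duration_s": dur,
                    "flags": "",
                }
            )
            f_vals.append(fw)
            eps_vals.append(eps)

    data = pd.DataFrame(rows)
    truth = {
        "beta0": config.beta0,
        "beta1": config.beta1,
        "beta2": config.beta2,
        "sd_b0": config.sd_b0,
        "sd_b1": config.sd_b1,
        "sd_eps": config.sd_eps,
        "b0": dict(zip([f"P{i + 1:02d}" for i in range(m)], b0)),
        "b1": dict(zip([f"P{i + 1:02d}" for i in range(m)], b1)),
        "f": np.asarray(f_vals),
        "eps": np.asarray(eps_vals),
        "trend": f,
    }
    return data, truth
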