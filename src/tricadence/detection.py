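"""Automatic cadence detection from a single trunk-worn IMU.

The detector counts propulsive events per discipline from the axis that
carries the cleanest movement signature:

* swimming strokes — peaks *and* troughs of the medio-lateral accelerometer;
* cycling pedal strokes — peaks and troughs of the yaw gyroscope, each
  candidate confirmed against an extremum of the synchronised
  antero-posterior accelerometer;
* running strides — peaks of the vertical accelerometer.

Each channel is low-pass filtered with a zero-phase (forward–backward)
Butterworth filter, candidate extrema are screened by prominence, and the
surviving events are thinned with a refractory ("minimum detection")
interval between 0.25 and 0.5 s so artifact extrema are never counted twice.
Average cadence is simply 60 x count / duration.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import signal as sps

from .synthetic import EventSeries, ImuRecording

__all__ = [
    "DetectionParams",
    "DEFAULT_PARAMS",
    "butterworth_lowpass",
    "find_extrema",
    "detect_swim_strokes",
    "detect_cycle_pedal_strokes",
    "detect_run_strides",
    "detect",
    "average_cadence",
]


class InvalidParameterError(ValueError):
    """Raised for out-of-range filter or detection parameters."""


class DegenerateInputError(ValueError):
    """Raised when a signal is empty or too short to process."""


class MissingChannelError(KeyError):
    """Raised when a recording lacks the channel a detector needs."""


@dataclass(frozen=True)
class DetectionParams:
    """Tunable knobs of the peak-counting detector.

    ``min_interval_s`` is the refractory interval and must lie in
    [0.25, 0.5] s.  ``prominence_frac`` scales a robust (MAD-based) amplitude
    of the filtered channel into a relative prominence threshold;
    ``min_prominence_abs`` is an absolute floor in the channel's physical
    units so that a channel carrying only low-level noise yields no events.
    ``confirm_window_s`` is used by the cycling detector only.
    """

    cutoff_hz: float
    filter_order: int = 4
    min_interval_s: float = 0.5
    prominence_frac: float = 0.2
    min_prominence_abs: float = 0.0
    confirm_window_s: float = 0.15

    def __post_init__(self) -> None:
        if not 0.25 <= self.min_interval_s <= 0.5:
            raise InvalidParameterError("min_interval_s must lie in [0.25, 0.5] s")
        if self.cutoff_hz <= 0:
            raise InvalidParameterError("cutoff_hz must be > 0")
        if self.filter_order < 2 or self.filter_order % 2:
            raise InvalidParameterError("filter_order must be an even integer >= 2")
        if self.prominence_frac < 0 or self.confirm_window_s < 0:
            raise InvalidParameterError("fractions and windows must be >= 0")


#: Per-discipline defaults.  Cutoffs pass the fundamental event frequency
#: with margin; refractory intervals stay below the inter-event interval at
#: each discipline's maximum plausible cadence; absolute prominence floors
#: are well below genuine movement amplitudes.
DEFAULT_PARAMS: dict[str, DetectionParams] = {
    "swim": DetectionParams(cutoff_hz=3.0, min_interval_s=0.5, min_prominence_abs=0.5),
    "cycle": DetectionParams(cutoff_hz=6.0, min_interval_s=0.25, min_prominence_abs=10.0),
    "run": DetectionParams(cutoff_hz=8.0, min_interval_s=0.5, min_prominence_abs=2.0),
}


def butterworth_lowpass(
    x: np.ndarray, sample_rate_hz: float, cutoff_hz: float, order: int = 4
) -> np.ndarray:
    """Zero-phase Butterworth low-pass filter (filtfilt, squared response)."""
    x = np.asarray(x, dtype=float)
    nyq = sample_rate_hz / 2.0
    if not 0 < cutoff_hz < nyq:
        raise InvalidParameterError(f"cutoff {cutoff_hz} Hz outside (0, Nyquist={nyq}) Hz")
    if order < 2:
        raise InvalidParameterError("order must be >= 2")
    if x.size <= 3 * order:
        raise DegenerateInputError("signal too short for the requested filter order")
    sos = sps.butter(order, cutoff_hz, btype="low", fs=sample_rate_hz, output="sos")
    return sps.sosfiltfilt(sos, x)


def _robust_amplitude(x: np.ndarray) -> float:
    """MAD-based amplitude scale (equals the amplitude for a pure sinusoid)."""
    med = np.median(x)
    return 1.4826 * float(np.median(np.abs(x - med)))


def _candidates(x: np.ndarray, mode: str, threshold: float):
    """(index, prominence, is_peak) triples above the prominence threshold."""
    prom = max(threshold, 1e-12)  # always request prominences
    idx_p, props_p = sps.find_peaks(x, prominence=prom)
    out = [(int(i), float(p), True) for i, p in zip(idx_p, props_p["prominences"])]
    if mode == "peaks_and_troughs":
        idx_t, props_t = sps.find_peaks(-x, prominence=prom)
        out += [(int(i), float(p), False) for i, p in zip(idx_t, props_t["prominences"])]
    return out


def _refractory_thin(cands, sample_rate_hz: float, min_interval_s: float) -> np.ndarray:
    """Greedy thinning: accept by descending prominence (earlier wins ties);
    reject any candidate within ``min_interval_s`` of an accepted event."""
    if not cands:
        return np.asarray([], dtype=int)
    order = sorted(cands, key=lambda c: (-c[1], c[0]))
    min_gap = min_interval_s * sample_rate_hz
    accepted: list[int] = []
    for i, _, _ in order:
        if all(abs(i - j) >= min_gap for j in accepted):
            accepted.append(i)
    return np.asarray(sorted(accepted), dtype=int)


def _edge_extended(x: np.ndarray, n_pad: int) -> np.ndarray:
    """Extend both ends with linear ramps continuing the boundary slope.

    An extremum just inside the record boundary otherwise loses its
    prominence because the signal ends before descending past its base;
    continuing the local trend restores the prominence a longer record
    would have shown without inventing new extrema.
    """
    if n_pad <= 0 or x.size < 8:
        return np.concatenate([np.full(n_pad, x[0]), x, np.full(n_pad, x[-1])])
    # single-increment slopes: the signal is low-pass filtered, and a wider
    # fit window could straddle an extremum sitting right at the boundary
    slope_l = x[1] - x[0]
    slope_r = x[-1] - x[-2]
    lo, hi = float(x.min()), float(x.max())
    left = np.clip(x[0] - slope_l * np.arange(n_pad, 0, -1), lo, hi)
    right = np.clip(x[-1] + slope_r * np.arange(1, n_pad + 1), lo, hi)
    return np.concatenate([left, x, right])


def find_extrema(
    x: np.ndarray,
    sample_rate_hz: float,
    min_interval_s: float,
    prominence_frac: float,
    mode: str = "peaks_and_troughs",
    min_prominence_abs: float = 0.0,
) -> np.ndarray:
    """Indices of prominent extrema after refractory thinning.

    The prominence threshold is ``max(prominence_frac * robust_amplitude,
    min_prominence_abs)``; no two retained events of any kind are closer than
    ``min_interval_s``.  Extrema near the record boundaries are assessed on
    a slope-continued extension so they are retained when prominent.
    """
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise DegenerateInputError("empty signal")
    if mode not in ("peaks", "peaks_and_troughs"):
        raise InvalidParameterError(f"unknown mode {mode!r}")
    threshold = max(prominence_frac * _robust_amplitude(x), min_prominence_abs)
    n_pad = int(round(min_interval_s * sample_rate_hz))
    cands = _edge_candidates(x, mode, threshold, n_pad)
    return _refractory_thin(cands, sample_rate_hz, min_interval_s)


def _edge_candidates(x: np.ndarray, mode: str, threshold: float, n_pad: int):
    """Prominence-screened candidates, assessed on the edge-extended signal
    but reported on (and restricted to) the original sample range."""
    xe = _edge_extended(x, n_pad)
    return [
        (i - n_pad, p, k)
        for i, p, k in _candidates(xe, mode, threshold)
        if 0 <= i - n_pad < x.size
    ]


def _filtered_channel(rec: ImuRecording, name: str, params: DetectionParams) -> np.ndarray:
    try:
        x = rec.channel(name)
    except KeyError as exc:  # pragma: no cover - channel names are fixed
        raise MissingChannelError(name) from exc
    if x is None or len(x) == 0:
        raise DegenerateInputError(f"channel {name} is empty")
    return butterworth_lowpass(x, rec.sample_rate_hz, params.cutoff_hz, params.filter_order)


def _events_from_indices(rec: ImuRecording, idx: np.ndarray, discipline: str) -> EventSeries:
    return EventSeries(rec.time_s[idx], discipline=discipline)


def detect_swim_strokes(rec: ImuRecording, params: DetectionParams | None = None) -> EventSeries:
    """Count swim strokes: peaks and troughs of the medio-lateral axis."""
    params = params or DEFAULT_PARAMS["swim"]
    xf = _filtered_channel(rec, "acc_ml", params)
    idx = find_extrema(
        xf,
        rec.sample_rate_hz,
        params.min_interval_s,
        params.prominence_frac,
        "peaks_and_troughs",
        params.min_prominence_abs,
    )
    return _events_from_indices(rec, idx, "swim")


def detect_cycle_pedal_strokes(
    rec: ImuRecording, params: DetectionParams | None = None
) -> EventSeries:
    """Count pedal strokes: yaw-gyroscope extrema confirmed by the
    antero-posterior accelerometer within ``confirm_window_s``."""
    params = params or DEFAULT_PARAMS["cycle"]
    yaw = _filtered_channel(rec, "gyr_yaw", params)
    ap_params = replace(params, min_prominence_abs=params.min_prominence_abs / 40.0)
    ap = _filtered_channel(rec, "acc_ap", ap_params)

    n_pad = int(round(params.min_interval_s * rec.sample_rate_hz))
    threshold = max(params.prominence_frac * _robust_amplitude(yaw), params.min_prominence_abs)
    cands = _edge_candidates(yaw, "peaks_and_troughs", threshold, n_pad)

    ap_threshold = max(
        ap_params.prominence_frac * _robust_amplitude(ap), ap_params.min_prominence_abs
    )
    ap_idx = np.asarray(
        sorted(i for i, _, _ in _edge_candidates(ap, "peaks_and_troughs", ap_threshold, n_pad))
    )

    window = params.confirm_window_s * rec.sample_rate_hz
    confirmed = []
    for i, prom, is_peak in cands:
        if ap_idx.size:
            pos = np.searchsorted(ap_idx, i)
            near = min(
                abs(i - ap_idx[max(pos - 1, 0)]),
                abs(i - ap_idx[min(pos, ap_idx.size - 1)]),
            )
            if near <= window:
                confirmed.append((i, prom, is_peak))
    idx = _refractory_thin(confirmed, rec.sample_rate_hz, params.min_interval_s)
    return _events_from_indices(rec, idx, "cycle")


def detect_run_strides(rec: ImuRecording, params: DetectionParams | None = None) -> EventSeries:
    """Count running strides: peaks only of the vertical axis."""
    params = params or DEFAULT_PARAMS["run"]
    xf = _filtered_channel(rec, "acc_v", params)
    idx = find_extrema(
        xf,
        rec.sample_rate_hz,
        params.min_interval_s,
        params.prominence_frac,
        "peaks",
        params.min_prominence_abs,
    )
    return _events_from_indices(rec, idx, "run")


_DETECTORS = {
    "swim": detect_swim_strokes,
    "cycle": detect_cycle_pedal_strokes,
    "run": detect_run_strides,
}


def detect(rec: ImuRecording, discipline: str, params: DetectionParams | None = None) -> EventSeries:
    """Dispatch to the discipline-specific detector."""
    try:
        fn = _DETECTORS[discipline]
    except KeyError as exc:
        raise InvalidParameterError(f"unknown discipline {discipline!r}") from exc
    return fn(rec, params)


def average_cadence(events: EventSeries, duration_s: float) -> float:
    """Average cadence in events per minute: 60 x count / duration."""
    if duration_s <= 0:
        raise InvalidParameterError("duration_s must be > 0")
    return 60.0 * events.count / duration_s
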