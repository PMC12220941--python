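"""Sweep filtering and trial averaging.

Raw recordings are per-trial voltage sweeps sampled at 2 kHz with a 20 ms
pre-stimulus segment; stimulus onset defines t = 0.  Analysis-ready traces are
obtained by averaging trials and band-pass filtering (0.125–300 Hz for flash
ERG, 3–100 Hz for VEP, plus a 50 Hz notch for light-adapted VEP).  All filters
are applied forward-backward (zero phase) so that implicit times — latencies
from stimulus onset to a component's extremum — are not biased by group delay.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Sequence

import numpy as np
from scipy import signal

from .errors import DomainError
from .photometry import StimulusSpec

DEFAULT_SAMPLE_RATE_HZ = 2000.0
DEFAULT_PRE_STIMULUS_MS = 20.0

#: Butterworth sections per band edge; forward-backward application doubles
#: the effective magnitude order.
DEFAULT_FILTER_ORDER = 4
DEFAULT_NOTCH_Q = 10.0


class Channel(str, Enum):
    ERG = "ERG"
    VEP = "VEP"


@dataclass(frozen=True)
class Trace:
    """A single analysis-ready voltage trace (µV).

    The time axis is ``t_ms = index / sample_rate * 1000 - pre_stimulus_ms``;
    stimulus onset is at t = 0.  ``filter_log`` records every transformation
    applied, in order.
    """

    values: np.ndarray
    sample_rate: float = DEFAULT_SAMPLE_RATE_HZ
    pre_stimulus_ms: float = DEFAULT_PRE_STIMULUS_MS
    filter_log: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if self.sample_rate <= 0:
            raise DomainError("sample_rate must be > 0")
        if values.ndim != 1:
            raise DomainError("a Trace holds a 1-D voltage array")
        if not np.all(np.isfinite(values)):
            raise DomainError("trace values must be finite")

    def time_ms(self) -> np.ndarray:
        return np.arange(self.values.size) / self.sample_rate * 1000.0 - self.pre_stimulus_ms

    @property
    def post_stimulus_ms(self) -> float:
        return (self.values.size - 1) / self.sample_rate * 1000.0 - self.pre_stimulus_ms

    def with_values(self, values: np.ndarray, log_entry: str) -> "Trace":
        return replace(self, values=np.asarray(values, float),
                       filter_log=self.filter_log + (log_entry,))


@dataclass(frozen=True)
class SweepSet:
    """Raw per-trial sweeps plus acquisition metadata; the unit of recording."""

    sweeps: np.ndarray  # (n_trials, n_samples), µV
    stimulus: StimulusSpec
    channel: Channel = Channel.ERG
    sample_rate: float = DEFAULT_SAMPLE_RATE_HZ
    pre_stimulus_ms: float = DEFAULT_PRE_STIMULUS_MS
    trial_onset_times_s: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        sweeps = np.asarray(self.sweeps, dtype=float)
        if sweeps.ndim != 2:
            raise DomainError("sweeps must be a (n_trials, n_samples) array")
        if sweeps.shape[0] < 1:
            raise DomainError("a recording needs at least one sweep")
        object.__setattr__(self, "sweeps", sweeps)
        object.__setattr__(self, "channel", Channel(self.channel))
        if self.sample_rate <= 0:
            raise DomainError("sample_rate must be > 0")
        if self.trial_onset_times_s and len(self.trial_onset_times_s) != sweeps.shape[0]:
            raise DomainError("one trial onset time per sweep required")

    @property
    def n_trials(self) -> int:
        return int(self.sweeps.shape[0])


def _sos_filtfilt(sos: np.ndarray, x: np.ndarray) -> np.ndarray:
    # reflect padding; traces are short relative to the slowest filter
    # transients but start and end near rest, so edge artifacts stay small
    return signal.sosfiltfilt(sos, x, padtype="even")


def bandpass(
    trace: Trace,
    low_hz: float,
    high_hz: float,
    order: int = DEFAULT_FILTER_ORDER,
) -> Trace:
    """Zero-phase Butterworth band-pass (or low-pass when ``low_hz == 0``).

    The filter is applied forward and backward, so a symmetric pulse keeps its
    peak position to within one sample.
    """
    nyquist = trace.sample_rate / 2.0
    if not (0 <= low_hz < high_hz < nyquist):
        raise DomainError(
            f"invalid band ({low_hz}, {high_hz}) Hz for fs={trace.sample_rate} Hz"
        )
    if low_hz == 0:
        sos = signal.butter(order, high_hz, btype="low", fs=trace.sample_rate, output="sos")
        entry = f"lowpass({high_hz:g} Hz, order {order}, zero-phase)"
    else:
        sos = signal.butter(
            order, [low_hz, high_hz], btype="band", fs=trace.sample_rate, output="sos"
        )
        entry = f"bandpass({low_hz:g}-{high_hz:g} Hz, order {order}, zero-phase)"
    return trace.with_values(_sos_filtfilt(sos, trace.values), entry)


def notch50(trace: Trace, freq_hz: float = 50.0, q: float = DEFAULT_NOTCH_Q) -> Trace:
    """Zero-phase 50 Hz notch (IIR, quality factor ``q``) for mains rejection."""
    if trace.sample_rate <= 2 * freq_hz:
        raise DomainError("sample rate too low for a 50 Hz notch")
    b, a = signal.iirnotch(freq_hz, q, fs=trace.sample_rate)
    filtered = signal.filtfilt(b, a, trace.values, padtype="even")
    return trace.with_values(filtered, f"notch({freq_hz:g} Hz, Q={q:g}, zero-phase)")


def average_trials(sweeps: SweepSet) -> Trace:
    """Point-wise arithmetic mean across trials.

    With intertrial intervals that are not multiples of the 20 ms mains
    period, the 50 Hz phases rotate between trials and largely cancel in the
    mean; no artifact rejection is applied.
    """
    if sweeps.n_trials < 1:
        raise DomainError("cannot average an empty sweep set")
    mean = sweeps.sweeps.mean(axis=0)
    return Trace(
        values=mean,
        sample_rate=sweeps.sample_rate,
        pre_stimulus_ms=sweeps.pre_stimulus_ms,
        filter_log=(f"average_trials(n={sweeps.n_trials})",),
    )


def baseline_stats(trace: Trace) -> dict[str, float]:
    """Mean and sample standard deviation of the pre-stimulus segment (µV)."""
    n_pre = int(math.floor(trace.pre_stimulus_ms / 1000.0 * trace.sample_rate))
    if n_pre < 10:
        raise DomainError(
            f"pre-stimulus segment spans {n_pre} samples; need at least 10"
        )
    segment = trace.values[:n_pre]
    sd = float(np.std(segment, ddof=1)) if segment.size > 1 else 0.0
    return {"mean": float(np.mean(segment)), "sd": sd}
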