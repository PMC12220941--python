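"""ERG and VEP wave-marker placement.

Markers are extrema searched in fixed post-stimulus windows on filtered,
trial-averaged traces:

===========  ==============  ===========================================
marker       window (ms)     polarity / reference
===========  ==============  ===========================================
a_o          (0.5, 12]       trough, from baseline (optogenetic)
a            (12, 30]        trough, from baseline
b            (20, 120]       peak; dark-adapted from the a-wave trough,
                             light-adapted from baseline
N1_o         (15, 40]        trough, from baseline (optogenetic, VEP)
P1           (30, 50]        peak, from baseline (VEP)
N1           (40, 90]        trough after P1, from the P1 peak level (VEP)
===========  ==============  ===========================================

Amplitudes are reported as positive magnitudes with their reference recorded.
A marker is *present* when its amplitude reaches ``max(3 x baseline sd,
min_deflection_uv)``; the additive floor keeps the criterion meaningful on
noise-free synthetic traces.  The a_o trough must additionally be interior to
its window (a monotone deflection ending at the window edge is the leading
flank of a native a-wave, not a distinct optogenetic component).  When an a_o
is present, the a-wave is still measured but flagged low-confidence: the
oscillations following the optogenetic deflection superimpose the native
a-wave and preclude accurate quantification.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np

from .errors import DomainError
from .photometry import Adaptation, StimulusSpec
from .preprocessing import Trace, baseline_stats

#: Additive presence floor (µV) combined with the 3 sigma criterion.
DEFAULT_MIN_DEFLECTION_UV = 2.0

A_O, A, B, P1, N1, N1_O = "a_o", "a", "b", "P1", "N1", "N1_o"


class Confidence(str, Enum):
    CLEAR = "clear"
    LOW = "low"
    ABSENT = "absent"


@dataclass(frozen=True)
class MarkerWindows:
    """Search windows in ms post-stimulus, half-open (low, high]."""

    a_o: tuple[float, float] = (0.5, 12.0)
    a: tuple[float, float] = (12.0, 30.0)
    b: tuple[float, float] = (20.0, 120.0)
    n1_o: tuple[float, float] = (15.0, 40.0)
    p1: tuple[float, float] = (30.0, 50.0)
    n1: tuple[float, float] = (40.0, 90.0)


DEFAULT_WINDOWS = MarkerWindows()


@dataclass(frozen=True)
class Marker:
    name: str
    present: bool
    implicit_time_ms: float | None = None
    amplitude_uv: float | None = None
    reference: str = "baseline"
    confidence: Confidence = Confidence.ABSENT

    def __post_init__(self) -> None:
        if not self.present and (
            self.implicit_time_ms is not None or self.amplitude_uv is not None
        ):
            raise DomainError("absent markers carry no time or amplitude")
        if self.present:
            if self.implicit_time_ms is None or self.amplitude_uv is None:
                raise DomainError("present markers need a time and an amplitude")
            if self.implicit_time_ms < 0 or self.amplitude_uv < 0:
                raise DomainError("implicit time and amplitude must be >= 0")


@dataclass(frozen=True)
class MarkerSet:
    markers: dict[str, Marker]
    conventions: dict[str, str]
    noise_sd_uv: float

    def __getitem__(self, name: str) -> Marker:
        return self.markers[name]


def _absent(name: str) -> Marker:
    return Marker(name=name, present=False, confidence=Confidence.ABSENT)


def _window_extremum(
    trace: Trace, window: tuple[float, float], mode: str
) -> tuple[float, float, bool, bool]:
    """Extremum over the half-open window (low, high] ms.

    Returns ``(time_ms, value_uv, is_first, is_last)`` where the flags mark
    an extremum sitting on the first or last sample of the window — i.e. a
    deflection truncated by the window rather than a distinct peak.  Plateau
    ties resolve to the earliest sample (implicit time is
    time-to-first-attainment).
    """
    low, high = window
    if trace.post_stimulus_ms < high:
        raise DomainError(
            f"trace ends {trace.post_stimulus_ms:.1f} ms post-stimulus; "
            f"marker window reaches {high:g} ms"
        )
    t = trace.time_ms()
    idx = np.nonzero((t > low) & (t <= high))[0]
    if idx.size == 0:
        raise DomainError(f"no samples in window ({low}, {high}] ms")
    seg = trace.values[idx]
    j = int(np.argmin(seg)) if mode == "min" else int(np.argmax(seg))
    return float(t[idx[j]]), float(seg[j]), j == 0, j == seg.size - 1


def _threshold(noise_sd: float, min_deflection: float, k: float = 3.0) -> float:
    return max(k * noise_sd, min_deflection)


def detect_ao(
    trace: Trace,
    noise_sd: float,
    *,
    windows: MarkerWindows = DEFAULT_WINDOWS,
    min_deflection_uv: float = DEFAULT_MIN_DEFLECTION_UV,
    baseline_mean: float | None = None,
) -> Marker:
    """Detect the early optogenetic trough (a_o) in the (0.5, 12] ms window.

    Present iff the trough magnitude from baseline reaches the presence
    threshold and the trough is interior to the window.
    """
    if baseline_mean is None:
        baseline_mean = baseline_stats(trace)["mean"]
    t_trough, v_trough, _, is_last = _window_extremum(trace, windows.a_o, "min")
    amplitude = baseline_mean - v_trough
    if amplitude >= _threshold(noise_sd, min_deflection_uv) and not is_last:
        return Marker(A_O, True, t_trough, amplitude, "baseline", Confidence.CLEAR)
    return _absent(A_O)


def place_erg_markers(
    trace: Trace,
    stim: StimulusSpec,
    *,
    windows: MarkerWindows = DEFAULT_WINDOWS,
    min_deflection_uv: float = DEFAULT_MIN_DEFLECTION_UV,
) -> MarkerSet:
    """Place a_o, a and b markers on a filtered, averaged ERG trace.

    The b-wave amplitude is referenced to the a-wave trough level under dark
    adaptation (standard clinical convention) and to the pre-stimulus baseline
    under light adaptation, where optogenetic deflections superimpose the true
    a-wave.  If no a-wave is present on a dark-adapted trace (dim scotopic
    flashes), the b-wave falls back to the baseline reference.
    """
    stats = baseline_stats(trace)
    base, noise_sd = stats["mean"], stats["sd"]
    thr = _threshold(noise_sd, min_deflection_uv)

    ao = detect_ao(
        trace, noise_sd, windows=windows,
        min_deflection_uv=min_deflection_uv, baseline_mean=base,
    )

    # The a trough must be interior to its window: a minimum on the first
    # sample is the decaying flank of an a_o, one on the last sample the
    # onset of a slow negative drift — neither is a distinct a-wave.
    t_a, v_a, a_first, a_last = _window_extremum(trace, windows.a, "min")
    a_amp = base - v_a
    if a_amp >= thr and not (a_first or a_last):
        a_conf = Confidence.LOW if ao.present else Confidence.CLEAR
        a = Marker(A, True, t_a, a_amp, "baseline", a_conf)
    else:
        a = _absent(A)

    t_b, v_b, _, _ = _window_extremum(trace, windows.b, "max")
    dark = stim.adaptation is Adaptation.DARK
    if dark and a.present:
        b_ref_level, b_reference = v_a, "a_peak"
    else:
        b_ref_level, b_reference = base, "baseline"
    b_amp = v_b - b_ref_level
    if b_amp >= thr:
        b = Marker(B, True, t_b, b_amp, b_reference, Confidence.CLEAR)
    else:
        b = _absent(B)

    conventions = {
        "adaptation": stim.adaptation.value,
        "b_reference": b_reference if b.present else "n/a",
        "a_reference": "baseline",
        "presence_threshold_uv": f"{thr:.3f}",
    }
    return MarkerSet({A_O: ao, A: a, B: b}, conventions, noise_sd)


def place_vep_markers(
    trace: Trace,
    *,
    windows: MarkerWindows = DEFAULT_WINDOWS,
    min_deflection_uv: float = DEFAULT_MIN_DEFLECTION_UV,
) -> MarkerSet:
    """Place N1_o, P1 and N1 markers on a filtered, averaged VEP trace.

    N1 is the most negative sample after the P1 peak and its amplitude is the
    P1-to-N1 level difference.  N1_o — the early optogenetic cortical trough —
    is accepted down to 2 sigma but flagged low-confidence below 3 sigma, as
    it often sits just above noise level.  Unsatisfiable windows (no samples
    after P1) yield absent markers, not exceptions.
    """
    stats = baseline_stats(trace)
    base, noise_sd = stats["mean"], stats["sd"]
    thr3 = _threshold(noise_sd, min_deflection_uv)
    thr2 = _threshold(noise_sd, min_deflection_uv, k=2.0)

    t_no, v_no, _, _ = _window_extremum(trace, windows.n1_o, "min")
    no_amp = base - v_no
    if no_amp >= thr3:
        n1_o = Marker(N1_O, True, t_no, no_amp, "baseline", Confidence.CLEAR)
    elif no_amp >= thr2:
        n1_o = Marker(N1_O, True, t_no, no_amp, "baseline", Confidence.LOW)
    else:
        n1_o = _absent(N1_O)

    t_p1, v_p1, _, _ = _window_extremum(trace, windows.p1, "max")
    p1_amp = v_p1 - base
    p1 = (
        Marker(P1, True, t_p1, p1_amp, "baseline", Confidence.CLEAR)
        if p1_amp >= thr3
        else _absent(P1)
    )

    n1_low = max(windows.n1[0], t_p1) if p1.present else windows.n1[0]
    if n1_low >= windows.n1[1]:
        n1 = _absent(N1)
    else:
        t_n1, v_n1, _, _ = _window_extremum(trace, (n1_low, windows.n1[1]), "min")
        if p1.present:
            n1_amp, n1_reference = v_p1 - v_n1, "P1_peak"
        else:
            n1_amp, n1_reference = base - v_n1, "baseline"
        n1 = (
            Marker(N1, True, t_n1, n1_amp, n1_reference, Confidence.CLEAR)
            if n1_amp >= thr3
            else _absent(N1)
        )

    conventions = {
        "adaptation": "light",
        "n1_reference": n1.reference if n1.present else "n/a",
        "presence_threshold_uv": f"{thr3:.3f}",
    }
    return MarkerSet({N1_O: n1_o, P1: p1, N1: n1}, conventions, noise_sd)


def amplitude(markerset: MarkerSet, name: str) -> float | None:
    """Amplitude (µV, positive magnitude) of a marker, or None when absent."""
    marker = markerset[name]
    return marker.amplitude_uv if marker.present else None


def implicit_time(markerset: MarkerSet, name: str) -> float | None:
    """Implicit time (ms from stimulus onset) of a marker, or None when absent."""
    marker = markerset[name]
    return marker.implicit_time_ms if marker.present else None
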