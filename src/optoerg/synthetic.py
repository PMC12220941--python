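"""Synthetic ERG/VEP waveform and cohort simulator.

The study's raw recordings are not publicly deposited, so every analysis
stage is exercised against simulated data whose structure mirrors the real
recordings: per-trial sweeps at 2 kHz with a 20 ms pre-stimulus baseline,
additive white noise, and 50 Hz mains interference whose per-trial phase
follows the protocol's intertrial spacing.

Waveforms are sums of parametric components.  Pulse-like waves (a, b, P1, N1,
N1_o, the degenerate retina's slow positive deflection) are two-sided
Gaussians — independent rise and decay widths around a signed peak.  The
optogenetic a_o deflection rises as a saturating exponential from exactly
t = 0 (its onset is faster than the 2 kHz sampling can resolve, so the first
post-stimulus sample is already well off baseline) and decays as a Gaussian.
Oscillatory components (the OP burst, the post-a_o oscillations) are
exponentially damped sinusoids.  No waveform equations exist to copy; these
are the simplest shapes matching the published morphology.

Three genotype templates drive the simulator, their timing and amplitude
defaults pinned to the published group medians:

* ``WT`` — native rod/cone responses only (a, b, OPs; VEP P1/N1).
* ``WT_ReaChR`` — native responses plus the optogenetic a_o (33.76 µV,
  8.0 ms at 100 cd·s/m²) and cortical N1_o (27.12 ms); the native b-wave is
  dampened (×0.556 on the standard background, ×0.538 under the
  pre-activating amber background) and delayed (+16.13 ms) for
  ReaChR-activating flashes.
* ``RD1_ReaChR`` — no native components; a smaller a_o (6.36 µV) plus a slow
  positive deflection, for ReaChR-activating flashes only.

Component amplitudes scale with flash energy through a Hill saturation
``E^n / (E^n + E50^n)`` normalized at the reference energy where the paper
median is defined; the a_o is additionally hard-gated by the ReaChR
activation threshold so it appears at 100 cd·s/m² and above but never below.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import DomainError
from .photometry import (
    Adaptation,
    BackgroundClass,
    DriveClass,
    PhotometryCalibration,
    StimulusSpec,
    classify_stimulus,
)
from .preprocessing import (
    Channel,
    DEFAULT_PRE_STIMULUS_MS,
    DEFAULT_SAMPLE_RATE_HZ,
    SweepSet,
)

# ---------------------------------------------------------------------------
# Published medians used as template anchors
# ---------------------------------------------------------------------------
AO_TIME_MS = 8.0
A_TIME_LIGHT_MS = 17.4
B_TIME_DARK_MS = 35.75
B_TIME_LIGHT_WT_MS = 51.62
B_TIME_LIGHT_WTR_MS = 67.75
B_DELAY_MS = round(B_TIME_LIGHT_WTR_MS - B_TIME_LIGHT_WT_MS, 2)  # +16.13 ms
AO_AMP_WTR_UV = 33.76
AO_AMP_RD1_UV = 6.36
B_AMP_WT_10_UV = 61.92
B_DAMPENING = 0.556
B_DAMPENING_PREACTIVATED = 0.538
B_AMP_WT_BLUE_UV = 107.86
N1_TIME_MS = 55.25
N1O_TIME_MS = 27.12

WT, WT_REACHR, RD1_REACHR = "WT", "WT_ReaChR", "RD1_ReaChR"
GENOTYPES = (WT, WT_REACHR, RD1_REACHR)

PULSE_KINDS = frozenset({"a", "b", "slow_positive", "P1", "N1", "N1_o"})
OSC_KINDS = frozenset({"post_ao_oscillation", "op_burst"})
MAINS_FREQ_HZ = 50.0

#: a_o rise model: fraction of the deflection carried by the effectively
#: instantaneous channel-opening jump, and its time constant (ms).
AO_FAST_FRACTION = 0.35
AO_FAST_TAU_MS = 0.2


# ---------------------------------------------------------------------------
# Components
# ---------------------------------------------------------------------------
@dataclass(frozen=True)
class ComponentTemplate:
    """One parametric waveform component.

    ``peak_amplitude_uv`` is signed (negative for troughs).  For pulse kinds
    ``rise_sigma_ms``/``decay_sigma_ms`` are the Gaussian widths before and
    after the peak; for the a_o kind ``rise_sigma_ms`` is the saturating-rise
    time constant.  Oscillatory kinds interpret ``peak_time_ms`` as burst
    onset and need ``frequency_hz`` (within the 75–300 Hz OP band) and
    ``decay_tau_ms``.
    """

    kind: str
    peak_time_ms: float
    peak_amplitude_uv: float
    rise_sigma_ms: float | None = None
    decay_sigma_ms: float | None = None
    frequency_hz: float | None = None
    decay_tau_ms: float | None = None

    def __post_init__(self) -> None:
        if self.kind in PULSE_KINDS or self.kind == "a_o":
            if not (self.rise_sigma_ms and self.rise_sigma_ms > 0):
                raise DomainError(f"{self.kind}: rise_sigma_ms must be > 0")
            if not (self.decay_sigma_ms and self.decay_sigma_ms > 0):
                raise DomainError(f"{self.kind}: decay_sigma_ms must be > 0")
        elif self.kind in OSC_KINDS:
            if not (self.decay_tau_ms and self.decay_tau_ms > 0):
                raise DomainError(f"{self.kind}: decay_tau_ms must be > 0")
            if self.frequency_hz is None or not 75.0 <= self.frequency_hz <= 300.0:
                raise DomainError(f"{self.kind}: frequency_hz must lie in [75, 300]")
        elif self.kind == "mains":
            if not (self.frequency_hz and self.frequency_hz > 0):
                raise DomainError("mains: frequency_hz must be > 0")
        elif self.kind != "white_noise":
            raise DomainError(f"unknown component kind {self.kind!r}")


def component_wave(
    tpl: ComponentTemplate, t_ms: np.ndarray, phase_rad: float = 0.0
) -> np.ndarray:
    """Evaluate a component on a time grid (ms relative to stimulus onset).

    Deterministic pure function; ``phase_rad`` applies to the mains kind only.
    """
    t = np.asarray(t_ms, dtype=float)
    kind = tpl.kind
    if kind in PULSE_KINDS:
        tp = tpl.peak_time_ms
        y = np.where(
            t < tp,
            np.exp(-((t - tp) ** 2) / (2.0 * tpl.rise_sigma_ms**2)),
            np.exp(-((t - tp) ** 2) / (2.0 * tpl.decay_sigma_ms**2)),
        )
        return tpl.peak_amplitude_uv * y
    if kind == "a_o":
        # Two-timescale rise: an effectively instantaneous jump (already well
        # off baseline at the first 0.5 ms sample) blended with a slower
        # approach so the trough at peak_time_ms stays distinct; Gaussian
        # return toward baseline afterwards.
        tp, tau_slow, sd = tpl.peak_time_ms, tpl.rise_sigma_ms, tpl.decay_sigma_ms
        y = np.zeros_like(t)
        rising = (t >= 0) & (t <= tp)

        def _rise(x):
            return AO_FAST_FRACTION * (1.0 - np.exp(-x / AO_FAST_TAU_MS)) + (
                1.0 - AO_FAST_FRACTION
            ) * (1.0 - np.exp(-x / tau_slow))

        y[rising] = _rise(t[rising]) / _rise(np.array(tp))
        decaying = t > tp
        y[decaying] = np.exp(-((t[decaying] - tp) ** 2) / (2.0 * sd**2))
        return tpl.peak_amplitude_uv * y
    if kind in OSC_KINDS:
        t0 = tpl.peak_time_ms
        y = np.zeros_like(t)
        m = t >= t0
        dt = t[m] - t0
        y[m] = np.exp(-dt / tpl.decay_tau_ms) * np.sin(
            2.0 * np.pi * tpl.frequency_hz * dt / 1000.0
        )
        return tpl.peak_amplitude_uv * y
    if kind == "mains":
        return tpl.peak_amplitude_uv * np.sin(
            2.0 * np.pi * tpl.frequency_hz * t / 1000.0 + phase_rad
        )
    raise DomainError(
        "white_noise is drawn per sweep by the simulator, not a deterministic wave"
    )


@dataclass(frozen=True)
class IntensityResponse:
    """Hill saturation of a component amplitude with flash energy.

    ``scale(E) = h(E) / h(reference_energy)`` with ``h(E) = E^n/(E^n+E50^n)``,
    so the template amplitude is exact at its reference energy.
    """

    e50: float
    hill_n: float = 1.0
    reference_energy: float = 1.0

    def __post_init__(self) -> None:
        if self.e50 <= 0 or self.hill_n <= 0 or self.reference_energy <= 0:
            raise DomainError("IntensityResponse parameters must be > 0")

    def _hill(self, energy: float) -> float:
        if energy <= 0:
            return 0.0
        en = energy**self.hill_n
        return en / (en + self.e50**self.hill_n)

    def scale(self, energy: float) -> float:
        return self._hill(energy) / self._hill(self.reference_energy)


@dataclass(frozen=True)
class GenotypeComponent:
    template: ComponentTemplate
    intensity: IntensityResponse | None = None
    reachr_gated: bool = False


@dataclass(frozen=True)
class AnimalEffects:
    """Per-animal deviations: amplitude multipliers and time shifts by kind."""

    amplitude: Mapping[str, float] = field(default_factory=dict)
    time_shift_ms: Mapping[str, float] = field(default_factory=dict)


@dataclass(frozen=True)
class ExpectedMarker:
    present: bool
    implicit_time_ms: float | None = None
    amplitude_uv: float | None = None
    confidence: str = "absent"


#: Detection floor mirrored from the markers module; the truth table uses the
#: same criterion the detector applies to noise-free traces.
_PRESENCE_FLOOR_UV = 2.0


@dataclass(frozen=True)
class GenotypeTemplate:
    """Per-genotype component bundles, keyed by stimulus class and channel.

    ERG stimulus classes: ``dark`` (scotopic/mesopic flashes), ``light``
    (photopic flashes on the standard 30 cd/m² background) and
    ``preactivated`` (flashes on a ReaChR-preactivating background, the
    blue-on-amber paradigm).  VEP components form a single bundle.
    """

    genotype: str
    erg: Mapping[str, tuple[GenotypeComponent, ...]]
    vep: tuple[GenotypeComponent, ...] = ()
    b_dampening_factor: float = 1.0
    b_dampening_preactivated: float = 1.0
    b_delay_ms: float = 0.0

    @staticmethod
    def stimulus_class(
        stim: StimulusSpec, cal: PhotometryCalibration | None = None
    ) -> str:
        if stim.adaptation is Adaptation.DARK:
            return "dark"
        _, background = classify_stimulus(stim, cal)
        return (
            "preactivated"
            if background is BackgroundClass.PREACTIVATING_BACKGROUND
            else "light"
        )

    def concrete_components(
        self,
        stim: StimulusSpec,
        channel: Channel | str = Channel.ERG,
        cal: PhotometryCalibration | None = None,
        effects: AnimalEffects | None = None,
    ) -> list[ComponentTemplate]:
        """Resolve the stimulus-scaled, gate-filtered component list."""
        channel = Channel(channel)
        cls = self.stimulus_class(stim, cal)
        bundle = self.vep if channel is Channel.VEP else self.erg.get(cls, ())
        activating = classify_stimulus(stim, cal)[0] is DriveClass.REACHR_ACTIVATING
        out: list[ComponentTemplate] = []
        for gc in bundle:
            if gc.reachr_gated and not activating:
                continue
            tpl = gc.template
            amp = tpl.peak_amplitude_uv
            time = tpl.peak_time_ms
            if gc.intensity is not None:
                amp *= gc.intensity.scale(stim.flash_energy)
            if tpl.kind == "b" and channel is Channel.ERG:
                if cls == "light":
                    amp *= self.b_dampening_factor
                elif cls == "preactivated":
                    amp *= self.b_dampening_preactivated
                if activating:
                    time += self.b_delay_ms
            if effects is not None:
                amp *= effects.amplitude.get(tpl.kind, 1.0)
                time += effects.time_shift_ms.get(tpl.kind, 0.0)
            out.append(replace(tpl, peak_amplitude_uv=amp, peak_time_ms=time))
        return out

    def clean_trace(
        self,
        stim: StimulusSpec,
        t_ms: np.ndarray,
        channel: Channel | str = Channel.ERG,
        cal: PhotometryCalibration | None = None,
        effects: AnimalEffects | None = None,
    ) -> np.ndarray:
        """Noise-free superposition of all active components."""
        total = np.zeros_like(np.asarray(t_ms, dtype=float))
        for tpl in self.concrete_components(stim, channel, cal, effects):
            total = total + component_wave(tpl, t_ms)
        return total

    def expected_markers(
        self,
        stim: StimulusSpec,
        channel: Channel | str = Channel.ERG,
        cal: PhotometryCalibration | None = None,
    ) -> dict[str, ExpectedMarker]:
        """Ground-truth marker table the detector should recover.

        Applies the same measurement conventions the markers module uses
        (dark-adapted b from the a trough; VEP N1 from the P1 peak) to the
        generating parameters, gated at the detection floor.
        """
        channel = Channel(channel)
        comps = {
            tpl.kind: tpl for tpl in self.concrete_components(stim, channel, cal)
        }
        out: dict[str, ExpectedMarker] = {}

        def pulse(kind: str) -> ComponentTemplate | None:
            return comps.get(kind)

        if channel is Channel.ERG:
            ao = pulse("a_o")
            ao_present = ao is not None and abs(ao.peak_amplitude_uv) >= _PRESENCE_FLOOR_UV
            out["a_o"] = (
                ExpectedMarker(True, ao.peak_time_ms, abs(ao.peak_amplitude_uv), "clear")
                if ao_present
                else ExpectedMarker(False)
            )
            a = pulse("a")
            a_present = a is not None and abs(a.peak_amplitude_uv) >= _PRESENCE_FLOOR_UV
            out["a"] = (
                ExpectedMarker(
                    True, a.peak_time_ms, abs(a.peak_amplitude_uv),
                    "low" if ao_present else "clear",
                )
                if a_present
                else ExpectedMarker(False)
            )
            b = pulse("b")
            if b is not None:
                if stim.adaptation is Adaptation.DARK and a_present:
                    b_amp = b.peak_amplitude_uv + abs(a.peak_amplitude_uv)
                else:
                    b_amp = b.peak_amplitude_uv
                out["b"] = (
                    ExpectedMarker(True, b.peak_time_ms, b_amp, "clear")
                    if b_amp >= _PRESENCE_FLOOR_UV
                    else ExpectedMarker(False)
                )
            else:
                out["b"] = ExpectedMarker(False)
        else:
            n1_o = pulse("N1_o")
            out["N1_o"] = (
                ExpectedMarker(True, n1_o.peak_time_ms, abs(n1_o.peak_amplitude_uv), "clear")
                if n1_o is not None and abs(n1_o.peak_amplitude_uv) >= _PRESENCE_FLOOR_UV
                else ExpectedMarker(False)
            )
            p1 = pulse("P1")
            p1_present = p1 is not None and p1.peak_amplitude_uv >= _PRESENCE_FLOOR_UV
            out["P1"] = (
                ExpectedMarker(True, p1.peak_time_ms, p1.peak_amplitude_uv, "clear")
                if p1_present
                else ExpectedMarker(False)
            )
            n1 = pulse("N1")
            if n1 is not None:
                n1_amp = abs(n1.peak_amplitude_uv) + (
                    p1.peak_amplitude_uv if p1_present else 0.0
                )
                out["N1"] = (
                    ExpectedMarker(True, n1.peak_time_ms, n1_amp, "clear")
                    if n1_amp >= _PRESENCE_FLOOR_UV
                    else ExpectedMarker(False)
                )
            else:
                out["N1"] = ExpectedMarker(False)
        return out


# ---------------------------------------------------------------------------
# Default genotype templates
# ---------------------------------------------------------------------------
def _wt_bundles() -> dict[str, tuple[GenotypeComponent, ...]]:
    dark = (
        GenotypeComponent(
            ComponentTemplate("a", 16.0, -150.0, rise_sigma_ms=3.0, decay_sigma_ms=6.0),
            IntensityResponse(e50=2.0, reference_energy=3.0),
        ),
        GenotypeComponent(
            ComponentTemplate(
                "b", B_TIME_DARK_MS, 300.0, rise_sigma_ms=5.0, decay_sigma_ms=15.0
            ),
            IntensityResponse(e50=0.05, reference_energy=3.0),
        ),
    )
    light = (
        GenotypeComponent(
            ComponentTemplate(
                "a", A_TIME_LIGHT_MS, -15.0, rise_sigma_ms=2.5, decay_sigma_ms=4.0
            ),
            IntensityResponse(e50=30.0, reference_energy=100.0),
        ),
        GenotypeComponent(
            ComponentTemplate(
                "b", B_TIME_LIGHT_WT_MS, B_AMP_WT_10_UV,
                rise_sigma_ms=8.0, decay_sigma_ms=12.0,
            ),
            IntensityResponse(e50=5.0, reference_energy=10.0),
        ),
        GenotypeComponent(
            ComponentTemplate(
                "op_burst", 25.0, 0.7, frequency_hz=110.0, decay_tau_ms=15.0
            ),
            IntensityResponse(e50=5.0, reference_energy=10.0),
        ),
    )
    preactivated = (
        GenotypeComponent(
            ComponentTemplate("a", 17.0, -8.0, rise_sigma_ms=2.5, decay_sigma_ms=4.0),
            IntensityResponse(e50=3.0, reference_energy=5.0),
        ),
        GenotypeComponent(
            ComponentTemplate(
                "b", 45.0, B_AMP_WT_BLUE_UV, rise_sigma_ms=6.0, decay_sigma_ms=12.0
            ),
            IntensityResponse(e50=2.0, reference_energy=5.0),
        ),
    )
    return {"dark": dark, "light": light, "preactivated": preactivated}


def _wt_vep() -> tuple[GenotypeComponent, ...]:
    scaling = IntensityResponse(e50=30.0, reference_energy=100.0)
    return (
        GenotypeComponent(
            ComponentTemplate("P1", 40.0, 10.0, rise_sigma_ms=3.0, decay_sigma_ms=4.0),
            scaling,
        ),
        GenotypeComponent(
            ComponentTemplate(
                "N1", N1_TIME_MS, -20.0, rise_sigma_ms=7.0, decay_sigma_ms=6.0
            ),
            scaling,
        ),
    )


def _ao_component(amplitude_uv: float) -> GenotypeComponent:
    return GenotypeComponent(
        ComponentTemplate(
            "a_o", AO_TIME_MS, -amplitude_uv, rise_sigma_ms=3.0, decay_sigma_ms=2.5
        ),
        IntensityResponse(e50=150.0, hill_n=2.0, reference_energy=100.0),
        reachr_gated=True,
    )


def default_template(genotype: str) -> GenotypeTemplate:
    """The built-in genotype templates anchored at the published medians."""
    if genotype == WT:
        return GenotypeTemplate(WT, erg=_wt_bundles(), vep=_wt_vep())
    if genotype == WT_REACHR:
        bundles = _wt_bundles()
        optogenetic = (
            _ao_component(AO_AMP_WTR_UV),
            GenotypeComponent(
                ComponentTemplate(
                    "post_ao_oscillation", 10.0, 3.0,
                    frequency_hz=140.0, decay_tau_ms=8.0,
                ),
                IntensityResponse(e50=150.0, hill_n=2.0, reference_energy=100.0),
                reachr_gated=True,
            ),
        )
        bundles["light"] = bundles["light"] + optogenetic
        bundles["preactivated"] = bundles["preactivated"] + optogenetic
        vep = _wt_vep() + (
            GenotypeComponent(
                ComponentTemplate(
                    "N1_o", N1O_TIME_MS, -8.0, rise_sigma_ms=4.0, decay_sigma_ms=5.0
                ),
                IntensityResponse(e50=150.0, hill_n=2.0, reference_energy=100.0),
                reachr_gated=True,
            ),
        )
        return GenotypeTemplate(
            WT_REACHR,
            erg=bundles,
            vep=vep,
            b_dampening_factor=B_DAMPENING,
            b_dampening_preactivated=B_DAMPENING_PREACTIVATED,
            b_delay_ms=B_DELAY_MS,
        )
    if genotype == RD1_REACHR:
        # The degenerate retina responds to ReaChR-activating flashes only:
        # a small a_o and a slow positive deflection reminiscent of b-wave
        # kinetics, the latter kept below the detection floor so no b-wave is
        # attributed to a photoreceptor-free retina.
        optogenetic = (
            _ao_component(AO_AMP_RD1_UV),
            GenotypeComponent(
                ComponentTemplate(
                    "slow_positive", 60.0, 1.8, rise_sigma_ms=15.0, decay_sigma_ms=25.0
                ),
                reachr_gated=True,
            ),
        )
        vep = (
            GenotypeComponent(
                ComponentTemplate(
                    "N1_o", N1O_TIME_MS, -5.0, rise_sigma_ms=4.0, decay_sigma_ms=5.0
                ),
                IntensityResponse(e50=150.0, hill_n=2.0, reference_energy=100.0),
                reachr_gated=True,
            ),
        )
        return GenotypeTemplate(
            RD1_REACHR,
            erg={"dark": (), "light": optogenetic, "preactivated": optogenetic},
            vep=vep,
        )
    raise DomainError(f"unknown genotype {genotype!r}; known: {GENOTYPES}")


# ---------------------------------------------------------------------------
# Protocol
# ---------------------------------------------------------------------------
@dataclass(frozen=True)
class ProtocolEntry:
    stimulus: StimulusSpec
    channel: Channel = Channel.ERG
    n_trials: int = 20
    iti_s: float = 0.987

    def __post_init__(self) -> None:
        object.__setattr__(self, "channel", Channel(self.channel))
        if self.n_trials < 1:
            raise DomainError("n_trials must be >= 1")
        if self.iti_s <= 0:
            raise DomainError("iti_s must be > 0")


def default_trial_count(stim: StimulusSpec) -> int:
    if stim.adaptation is Adaptation.DARK:
        return 3
    return 5 if stim.flash_energy == 150.0 else 20


def default_iti_s(stim: StimulusSpec) -> float:
    if stim.adaptation is Adaptation.DARK:
        return 5.0 if stim.flash_energy <= 0.011 else 10.0
    return 0.987 if stim.flash_energy <= 150.0 else 1.987


def _entry(stim: StimulusSpec, channel: Channel = Channel.ERG) -> ProtocolEntry:
    return ProtocolEntry(stim, channel, default_trial_count(stim), default_iti_s(stim))


def default_protocol() -> tuple[ProtocolEntry, ...]:
    """The full stimulus protocol: dark-adapted, photopic series, blue-on-amber, VEP."""
    dark = [
        StimulusSpec(e, adaptation=Adaptation.DARK) for e in (0.01, 3.0)
    ]
    light = [
        StimulusSpec(e, background_luminance=30.0) for e in (10.0, 30.0, 100.0, 150.0, 900.0)
    ]
    blue_on_amber = StimulusSpec(
        5.0,
        background_luminance=3500.0,
        flash_color="blue",
        background_color="amber",
    )
    vep_stim = StimulusSpec(100.0, background_luminance=30.0)
    return tuple(
        [_entry(s) for s in dark]
        + [_entry(s) for s in light]
        + [_entry(blue_on_amber)]
        + [_entry(vep_stim, Channel.VEP)]
    )


def validate_protocol(entries: Iterable[ProtocolEntry]) -> list[str]:
    """Warn about intertrial intervals that are multiples of the 20 ms mains period."""
    messages = []
    for entry in entries:
        iti_ms = entry.iti_s * 1000.0
        if abs(iti_ms / 20.0 - round(iti_ms / 20.0)) < 1e-9:
            msg = (
                f"ITI {entry.iti_s:g} s for {entry.stimulus.label} is a multiple of "
                "20 ms; trial averaging will not cancel 50 Hz mains noise"
            )
            warnings.warn(msg, UserWarning, stacklevel=2)
            messages.append(msg)
    return messages


# ---------------------------------------------------------------------------
# Sweep and cohort simulation
# ---------------------------------------------------------------------------
def simulate_sweepset(
    genotype: str | GenotypeTemplate,
    stim: StimulusSpec,
    channel: Channel | str = Channel.ERG,
    *,
    n_sweeps: int | None = None,
    iti_s: float | None = None,
    noise_sd_uv: float = 3.0,
    mains_amplitude_uv: float = 2.0,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    sample_rate: float = DEFAULT_SAMPLE_RATE_HZ,
    pre_stimulus_ms: float = DEFAULT_PRE_STIMULUS_MS,
    duration_ms: float = 500.0,
    cal: PhotometryCalibration | None = None,
    effects: AnimalEffects | None = None,
) -> SweepSet:
    """Simulate one recording: per-trial sweeps for a genotype and stimulus.

    Each sweep is the genotype's noise-free waveform plus white noise and a
    50 Hz mains sinusoid whose phase advances with the trial onset times
    (``k * iti_s``), reproducing the cancellation — or lack of it — that the
    protocol's intertrial intervals produce under trial averaging.
    """
    template = genotype if isinstance(genotype, GenotypeTemplate) else default_template(genotype)
    channel = Channel(channel)
    if n_sweeps is None:
        n_sweeps = default_trial_count(stim)
    if iti_s is None:
        iti_s = default_iti_s(stim)
    if n_sweeps < 1:
        raise DomainError("n_sweeps must be >= 1")
    if rng is None:
        rng = np.random.default_rng(seed)

    n_samples = int(round(duration_ms / 1000.0 * sample_rate))
    t_ms = np.arange(n_samples) / sample_rate * 1000.0 - pre_stimulus_ms
    clean = template.clean_trace(stim, t_ms, channel, cal, effects)

    onsets = np.arange(n_sweeps) * iti_s
    sweeps = np.empty((n_sweeps, n_samples))
    for k in range(n_sweeps):
        sweep = clean.copy()
        if mains_amplitude_uv:
            sweep += mains_amplitude_uv * np.sin(
                2.0 * np.pi * MAINS_FREQ_HZ * (onsets[k] + t_ms / 1000.0)
            )
        if noise_sd_uv:
            sweep += rng.normal(0.0, noise_sd_uv, n_samples)
        sweeps[k] = sweep
    return SweepSet(
        sweeps=sweeps,
        stimulus=stim,
        channel=channel,
        sample_rate=sample_rate,
        pre_stimulus_ms=pre_stimulus_ms,
        trial_onset_times_s=tuple(float(o) for o in onsets),
    )


@dataclass(frozen=True)
class CohortSpec:
    """A simulated study cohort: group sizes, noise model, protocol, seed.

    Group sizes default to the study's (WT 6, WT+ReaChR 11, rd1+ReaChR 6).
    Between-animal variability is lognormal on component amplitudes
    (coefficient of variation ``between_animal_cv``, median-unbiased) and
    additive normal on component peak times (``time_jitter_sd_ms``).
    """

    n_per_group: Mapping[str, int] = field(
        default_factory=lambda: {WT: 6, WT_REACHR: 11, RD1_REACHR: 6}
    )
    seed: int = 0
    noise_sd_uv: float = 3.0
    mains_amplitude_uv: float = 2.0
    between_animal_cv: float = 0.2
    time_jitter_sd_ms: float = 1.0
    protocol: tuple[ProtocolEntry, ...] | None = None

    def __post_init__(self) -> None:
        for genotype, count in self.n_per_group.items():
            if genotype not in GENOTYPES:
                raise DomainError(f"unknown genotype {genotype!r}")
            if count < 1:
                raise DomainError("group counts must be >= 1")
        if self.between_animal_cv < 0:
            raise DomainError("between_animal_cv must be >= 0")
        if self.time_jitter_sd_ms < 0:
            raise DomainError("time_jitter_sd_ms must be >= 0")


@dataclass(frozen=True)
class Recording:
    animal_id: str
    genotype: str
    entry: ProtocolEntry
    sweepset: SweepSet


def draw_animal_effects(
    rng: np.random.Generator,
    kinds: Sequence[str],
    cv: float,
    time_sd_ms: float,
) -> AnimalEffects:
    """One animal's component deviations: lognormal amplitudes, normal times."""
    amplitude = {k: float(np.exp(rng.normal(0.0, cv))) if cv else 1.0 for k in kinds}
    shift = {k: float(rng.normal(0.0, time_sd_ms)) if time_sd_ms else 0.0 for k in kinds}
    return AnimalEffects(amplitude=amplitude, time_shift_ms=shift)


def _template_kinds(template: GenotypeTemplate) -> list[str]:
    kinds: list[str] = []
    for bundle in list(template.erg.values()) + [template.vep]:
        for gc in bundle:
            if gc.template.kind not in kinds:
                kinds.append(gc.template.kind)
    return kinds


def simulate_cohort(
    spec: CohortSpec,
    cal: PhotometryCalibration | None = None,
) -> tuple[list[Recording], pd.DataFrame]:
    """Simulate a full cohort; returns recordings plus the generating truth.

    Reproducible: the same spec (including seed) yields a bitwise-identical
    cohort.  The truth table holds each animal's realized amplitude
    multipliers and time shifts for recovery testing.
    """
    protocol = spec.protocol if spec.protocol is not None else default_protocol()
    root = np.random.SeedSequence(spec.seed)
    recordings: list[Recording] = []
    truth_rows: list[dict] = []
    groups = sorted(spec.n_per_group.items())
    animal_seeds = root.spawn(sum(count for _, count in groups))
    cursor = 0
    for genotype, count in groups:
        template = default_template(genotype)
        kinds = _template_kinds(template)
        for i in range(count):
            animal_id = f"{genotype}_{i + 1:02d}"
            rng = np.random.default_rng(animal_seeds[cursor])
            cursor += 1
            effects = draw_animal_effects(
                rng, kinds, spec.between_animal_cv, spec.time_jitter_sd_ms
            )
            for kind in kinds:
                truth_rows.append(
                    {
                        "animal_id": animal_id,
                        "genotype": genotype,
                        "component": kind,
                        "amplitude_multiplier": effects.amplitude[kind],
                        "time_shift_ms": effects.time_shift_ms[kind],
                    }
                )
            for entry in protocol:
                sweepset = simulate_sweepset(
                    template,
                    entry.stimulus,
                    entry.channel,
                    n_sweeps=entry.n_trials,
                    iti_s=entry.iti_s,
                    noise_sd_uv=spec.noise_sd_uv,
                    mains_amplitude_uv=spec.mains_amplitude_uv,
                    rng=rng,
                    cal=cal,
                    effects=effects,
                )
                recordings.append(Recording(animal_id, genotype, entry, sweepset))
    return recordings, pd.DataFrame(truth_rows)
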