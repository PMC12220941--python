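"""Photometric calibration for full-field (ganzfeld) flash stimulation.

Rodent ERG stimulators describe flashes photometrically (flash energy in
cd·s/m², steady backgrounds in cd/m²), while channelrhodopsin actuators such
as ReaChR are characterized radiometrically by the photon flux reaching the
retina.  For a fixed stimulator geometry and dilated pupil the two scales are
linearly related, so a single calibration constant ``k_flash`` (photons·cm⁻²·s⁻¹
per cd·s/m²) converts between them.  The default constant is anchored at the
published ReaChR activation threshold: a flux of 8×10¹⁴ photons·cm⁻²·s⁻¹
corresponds to a 68 cd·s/m² flash, i.e. ``k_flash = 8e14 / 68``.

The module also classifies stimuli against that threshold — whether a flash is
bright enough to drive ReaChR directly, and whether a steady background is
bright enough to pre-activate it — which downstream code uses to decide when
the optogenetic ERG/VEP components (a_o, N1_o) are expected.

Spectral sensitivity is handled with a single dimensionless weight per LED
primary (ReaChR is red-shifted, λmax ≈ 590 nm, so blue light is a weak driver);
no full action-spectrum model is attempted.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from types import MappingProxyType
from typing import Mapping

from .errors import ConfigurationError, DomainError

#: photons·cm⁻²·s⁻¹ per cd·s/m², anchored at 8e14 photons/cm²/s == 68 cd·s/m².
DEFAULT_K_FLASH = 8e14 / 68.0

#: Relative ReaChR drive per LED primary (λmax ≈ 590 nm ⇒ blue is weak).
#: "amber" is the red+green mixture used for pre-adapting backgrounds.
DEFAULT_PRIMARY_WEIGHTS: Mapping[str, float] = MappingProxyType(
    {"red": 1.0, "green": 0.8, "blue": 0.2, "white": 1.0, "amber": 0.9}
)


class Adaptation(str, Enum):
    DARK = "dark"
    LIGHT = "light"


class DriveClass(str, Enum):
    SUB_THRESHOLD = "sub_threshold"
    REACHR_ACTIVATING = "reachr_activating"


class BackgroundClass(str, Enum):
    NO_PREACTIVATION = "no_preactivation"
    PREACTIVATING_BACKGROUND = "preactivating_background"


@dataclass(frozen=True)
class PhotometryCalibration:
    """Constants linking photometric stimulus units to retinal photon flux.

    Parameters
    ----------
    k_flash
        photons·cm⁻²·s⁻¹ of retinal flux per cd·s/m² of flash energy.
    reachr_threshold_flux
        Minimum flux (photons·cm⁻²·s⁻¹) for direct ReaChR-mediated changes in
        neuronal firing; comparison is inclusive (≥).
    primary_weights
        Dimensionless ReaChR drive per LED color key, each in [0, 1].
    background_integration_s
        Window (s) used to place a steady background luminance on the
        flash-energy scale when computing its ReaChR drive.
    preactivation_flux
        Background flux (photons·cm⁻²·s⁻¹) above which steady ReaChR
        pre-activation is assumed.
    """

    k_flash: float = DEFAULT_K_FLASH
    reachr_threshold_flux: float = 8e14
    primary_weights: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PRIMARY_WEIGHTS)
    )
    background_integration_s: float = 1.0
    preactivation_flux: float = 1e16

    def __post_init__(self) -> None:
        if self.k_flash <= 0:
            raise ConfigurationError("k_flash must be > 0")
        if self.reachr_threshold_flux <= 0:
            raise ConfigurationError("reachr_threshold_flux must be > 0")
        if self.background_integration_s <= 0:
            raise ConfigurationError("background_integration_s must be > 0")
        if self.preactivation_flux <= 0:
            raise ConfigurationError("preactivation_flux must be > 0")
        for color, w in self.primary_weights.items():
            if not 0.0 <= w <= 1.0:
                raise ConfigurationError(
                    f"primary weight for {color!r} must be in [0, 1], got {w}"
                )

    def weight(self, color: str) -> float:
        try:
            return self.primary_weights[color]
        except KeyError:
            raise ConfigurationError(
                f"unknown color key {color!r}; known: {sorted(self.primary_weights)}"
            ) from None


@dataclass(frozen=True)
class StimulusSpec:
    """A single flash stimulus and its adaptation context.

    ``flash_energy`` is in cd·s/m² (≥ 0), ``background_luminance`` in cd/m²
    (≥ 0, and 0 under dark adaptation).  Flash duration is at most 4 ms, the
    stimulator's maximum.
    """

    flash_energy: float
    flash_duration_ms: float = 4.0
    background_luminance: float = 0.0
    flash_color: str = "white"
    background_color: str = "white"
    adaptation: Adaptation = Adaptation.LIGHT

    def __post_init__(self) -> None:
        object.__setattr__(self, "adaptation", Adaptation(self.adaptation))
        if self.flash_energy < 0:
            raise DomainError("flash_energy must be >= 0")
        if not 0.0 < self.flash_duration_ms <= 4.0:
            raise DomainError("flash_duration_ms must be in (0, 4] ms")
        if self.background_luminance < 0:
            raise DomainError("background_luminance must be >= 0")
        if self.adaptation is Adaptation.DARK and self.background_luminance != 0:
            raise DomainError("dark adaptation implies background_luminance == 0")

    @property
    def label(self) -> str:
        bg = (
            f" on {self.background_luminance:g} cd/m2 {self.background_color}"
            if self.background_luminance
            else ""
        )
        return (
            f"{self.adaptation.value} {self.flash_energy:g} cd.s/m2 "
            f"{self.flash_color}{bg}"
        )


def retinal_flux(energy: float, cal: PhotometryCalibration | None = None) -> float:
    """Retinal photon flux (photons·cm⁻²·s⁻¹) of a flash of ``energy`` cd·s/m².

    Strictly linear through the origin: ``k_flash * energy``.
    """
    if energy < 0:
        raise DomainError("flash energy must be >= 0")
    cal = cal or PhotometryCalibration()
    return cal.k_flash * energy


def energy_for_flux(flux: float, cal: PhotometryCalibration | None = None) -> float:
    """Flash energy (cd·s/m²) producing the given retinal photon flux."""
    if flux < 0:
        raise DomainError("flux must be >= 0")
    cal = cal or PhotometryCalibration()
    return flux / cal.k_flash


def reachr_drive(
    stim: StimulusSpec, cal: PhotometryCalibration | None = None
) -> dict[str, float]:
    """ReaChR-weighted photon flux of the flash and of the steady background.

    The background luminance (cd/m²) is integrated over
    ``background_integration_s`` to place it on the flash-energy scale before
    conversion.  Returns ``{"flash_flux": ..., "background_flux": ...}``.
    """
    cal = cal or PhotometryCalibration()
    flash_flux = cal.k_flash * stim.flash_energy * cal.weight(stim.flash_color)
    background_flux = (
        cal.k_flash
        * stim.background_luminance
        * cal.background_integration_s
        * cal.weight(stim.background_color)
    )
    return {"flash_flux": flash_flux, "background_flux": background_flux}


def classify_stimulus(
    stim: StimulusSpec, cal: PhotometryCalibration | None = None
) -> tuple[DriveClass, BackgroundClass]:
    """Classify a stimulus against the ReaChR flash and background thresholds.

    The flash is ``REACHR_ACTIVATING`` iff its weighted flux reaches
    ``reachr_threshold_flux`` (inclusive); the background is
    ``PREACTIVATING_BACKGROUND`` iff its weighted flux reaches
    ``preactivation_flux``.
    """
    cal = cal or PhotometryCalibration()
    drive = reachr_drive(stim, cal)
    flash = (
        DriveClass.REACHR_ACTIVATING
        if drive["flash_flux"] >= cal.reachr_threshold_flux
        else DriveClass.SUB_THRESHOLD
    )
    background = (
        BackgroundClass.PREACTIVATING_BACKGROUND
        if drive["background_flux"] >= cal.preactivation_flux
        else BackgroundClass.NO_PREACTIVATION
    )
    return flash, background
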