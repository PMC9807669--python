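"""Ocular photometry: corneal irradiance to retinal photon flux and dose.

Stimulus intensities in this kind of experiment are set at the light
source (laser or LED power, neutral-density filters, pulse duration) but
the quantity that matters physiologically is the photon flux density
reaching the retina.  The conversion model used here collects the corneal
irradiance over the fully dilated mouse pupil and spreads the collected
power uniformly over the whole retinal surface:

    flux = irradiance * driver_fraction * 10**(-nd_od)
           * (pupil_area / retina_area) / E_photon

with ``E_photon = h * c / wavelength`` and unit conversions such that the
result is in photons per square micrometre per second.  The default
geometry is the C57BL/6 mouse eye: 3.2 mm^2 pupil collecting area and
17.8 mm^2 retinal surface.

All internal computation is double precision; when comparing against
published photometric values, round to 2 significant figures (the
precision at which such quantities are customarily reported).
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = [
    "PLANCK_CONSTANT_J_S",
    "SPEED_OF_LIGHT_M_S",
    "StimulusSpec",
    "OcularGeometry",
    "PhotonDose",
    "photon_energy",
    "retinal_photon_flux",
    "delivered_photons",
    "photon_dose",
]

#: Planck constant, J*s (CODATA 2018 exact value).
PLANCK_CONSTANT_J_S = 6.62607015e-34
#: Speed of light in vacuum, m/s (CODATA 2018 exact value).
SPEED_OF_LIGHT_M_S = 2.99792458e8


@dataclass(frozen=True)
class StimulusSpec:
    """One light stimulus as delivered at the cornea.

    Parameters
    ----------
    wavelength_nm
        Light wavelength in nanometres (> 0).
    corneal_irradiance_mw_per_cm2
        Unattenuated power density measured at the eye, mW/cm^2.
    duration_s
        Stimulus duration in seconds.
    nd_od
        Total optical density of neutral-density filters in the light
        path (0 means no attenuation; OD 1 attenuates tenfold).
    driver_fraction
        Source power setting in [0, 1], modelled as linear in optical
        power (e.g. an LED driver at 40% -> 0.4).
    source_label
        Free-text identifier, e.g. ``"520nm laser"``.
    """

    wavelength_nm: float
    corneal_irradiance_mw_per_cm2: float
    duration_s: float
    nd_od: float = 0.0
    driver_fraction: float = 1.0
    source_label: str = ""

    def __post_init__(self) -> None:
        if self.wavelength_nm <= 0:
            raise ValueError(f"wavelength_nm must be > 0, got {self.wavelength_nm}")
        if self.corneal_irradiance_mw_per_cm2 < 0:
            raise ValueError("corneal_irradiance_mw_per_cm2 must be >= 0")
        if self.duration_s < 0:
            raise ValueError("duration_s must be >= 0")
        if self.nd_od < 0:
            raise ValueError("nd_od must be >= 0")
        if not 0.0 <= self.driver_fraction <= 1.0:
            raise ValueError(f"driver_fraction must lie in [0, 1], got {self.driver_fraction}")


@dataclass(frozen=True)
class OcularGeometry:
    """Collecting-pupil and retinal areas used to spread corneal power.

    Defaults are for a fully dilated C57BL/6-strain mouse eye.
    """

    pupil_area_mm2: float = 3.2
    retina_area_mm2: float = 17.8

    def __post_init__(self) -> None:
        if self.pupil_area_mm2 <= 0 or self.retina_area_mm2 <= 0:
            raise ValueError("pupil_area_mm2 and retina_area_mm2 must be > 0")


@dataclass(frozen=True)
class PhotonDose:
    """Retinal photon flux density and the total delivered dose."""

    flux_photons_per_um2_s: float
    total_photons_per_um2: float

    def __post_init__(self) -> None:
        if self.flux_photons_per_um2_s < 0 or self.total_photons_per_um2 < 0:
            raise ValueError("photon quantities must be >= 0")


def photon_energy(wavelength_nm: float) -> float:
    """Energy of a single photon in joules, ``h * c / lambda``.

    Strictly decreasing in wavelength.
    """
    if wavelength_nm <= 0:
        raise ValueError(f"wavelength_nm must be > 0, got {wavelength_nm}")
    return PLANCK_CONSTANT_J_S * SPEED_OF_LIGHT_M_S / (wavelength_nm * 1e-9)


def retinal_photon_flux(stim: StimulusSpec, geom: OcularGeometry = OcularGeometry()) -> float:
    """Retinal photon flux density in photons * um^-2 * s^-1.

    Corneal irradiance (after ND attenuation and driver scaling) is
    collected over the pupil area and spread uniformly over the retina.
    Linear in irradiance and in driver_fraction; ND 1.0 attenuates
    exactly tenfold.
    """
    irradiance_w_cm2 = (
        stim.corneal_irradiance_mw_per_cm2
        * 1e-3
        * stim.driver_fraction
        * 10.0 ** (-stim.nd_od)
    )
    # pupil area mm^2 -> cm^2 (1 mm^2 = 1e-2 cm^2)
    collected_power_w = irradiance_w_cm2 * geom.pupil_area_mm2 * 1e-2
    retina_area_um2 = geom.retina_area_mm2 * 1e6
    return collected_power_w / retina_area_um2 / photon_energy(stim.wavelength_nm)


def delivered_photons(stim: StimulusSpec, geom: OcularGeometry = OcularGeometry()) -> float:
    """Total delivered dose in photons * um^-2 (flux x duration)."""
    return retinal_photon_flux(stim, geom) * stim.duration_s


def photon_dose(stim: StimulusSpec, geom: OcularGeometry = OcularGeometry()) -> PhotonDose:
    """Flux and total dose for a stimulus, as a :class:`PhotonDose`."""
    flux = retinal_photon_flux(stim, geom)
    return PhotonDose(
        flux_photons_per_um2_s=flux,
        total_photons_per_um2=flux * stim.duration_s,
    )
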