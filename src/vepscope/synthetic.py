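"""Seeded synthetic VEP and ERG sweep generator with genotype presets.

No raw recordings are distributed with this package, so every downstream
stage is exercised on simulated data with known ground truth.  The
generator emulates:

* triphasic cortical VEP waveforms (P1 positive, N1 negative, P2
  positive, in that order) built from Gaussian lobes;
* a saturating Naka-Rushton amplitude law
  ``f(I) = I**s / (I**s + I50**s)`` linking the P1N1 amplitude to the
  delivered photon dose;
* a latency law in which the P1 latency relaxes from
  ``base_latency + latency_delay`` near threshold down to
  ``base_latency`` at saturation (delay proportional to ``1 - f(I)``);
* photopic ERGs with an a-wave, b-wave and damped oscillatory
  potentials (control) or noise-only traces (rod/cone-transducin
  double-knockout, DKO);
* additive white Gaussian recording noise (optional first-order
  autoregressive colouring) and a decaying stimulus artifact at onset.

The two genotype presets carry the pooled dynamic-range parameters of
light-adapted control vs. Gnat1/Gnat2 double-knockout mice (control
I50 = 3e3 photons/um^2, slope 0.156; DKO I50 = 7.87e5, slope 0.817) with
the DKO latency delayed relative to control at every dose.  All
randomness is driven by a single seed: identical (seed, config, preset,
dose) produce bit-identical sweep sets.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from functools import lru_cache

import numpy as np

from .preprocess import SweepSet

__all__ = [
    "ComponentShape",
    "GenotypePreset",
    "SyntheticConfig",
    "CONTROL",
    "DKO",
    "PRESETS",
    "saturation_fraction",
    "vep_template",
    "template_p1n1_amplitude",
    "template_p1_time",
    "expected_latency",
    "expected_p1n1_amplitude",
    "simulate_vep_sweeps",
    "simulate_erg_sweeps",
    "simulate_stacked_sweeps",
]


@dataclass(frozen=True)
class ComponentShape:
    """Lobe layout of the noiseless triphasic VEP template.

    ``lobes`` is a tuple of ``(center_s, width_s, amplitude)`` Gaussian
    lobes in time order; the default encodes P1 (+), N1 (-), P2 (+).
    Amplitudes are relative: the template is rescaled at simulation time
    so that its P1N1 amplitude matches the amplitude law exactly.
    """

    lobes: tuple[tuple[float, float, float], ...] = (
        (0.045, 0.008, 1.0),   # P1
        (0.075, 0.012, -1.4),  # N1
        (0.120, 0.020, 0.7),   # P2
    )

    def __post_init__(self) -> None:
        if len(self.lobes) < 2:
            raise ValueError("shape needs at least P1 and N1 lobes")
        centers = [c for c, _, _ in self.lobes]
        if any(np.diff(centers) <= 0):
            raise ValueError("lobe centers must be strictly increasing in time")
        if not (self.lobes[0][2] > 0 > self.lobes[1][2]):
            raise ValueError("first lobe must be positive (P1) and second negative (N1)")

    @property
    def p1_center_s(self) -> float:
        return self.lobes[0][0]

    @property
    def span_s(self) -> float:
        """Time past onset after which the template is negligible."""
        c, w, _ = self.lobes[-1]
        return c + 6.0 * w


@dataclass(frozen=True)
class GenotypePreset:
    """Amplitude/latency laws and waveform shape for one genotype.

    ``i50_photons_um2`` and ``slope`` parameterize the Naka-Rushton
    amplitude law; ``max_p1n1_uv`` is the saturating P1N1 amplitude;
    latency relaxes from ``base_latency_s + latency_delay_s`` near
    threshold to ``base_latency_s`` at saturation.  ``erg_present``
    controls whether photopic ERG features are generated, and
    ``stacked_recovery`` scales the second (laser) response of a stacked
    LED+laser protocol (fraction of the unconditioned amplitude that
    survives an ongoing saturating stimulus).
    """

    i50_photons_um2: float
    slope: float
    max_p1n1_uv: float
    base_latency_s: float
    latency_delay_s: float
    shape: ComponentShape = ComponentShape()
    erg_present: bool = True
    stacked_recovery: float = 0.8

    def __post_init__(self) -> None:
        if self.i50_photons_um2 <= 0 or self.slope <= 0:
            raise ValueError("i50 and slope must be > 0")
        if self.max_p1n1_uv <= 0 or self.base_latency_s <= 0:
            raise ValueError("max_p1n1_uv and base_latency_s must be > 0")
        if self.latency_delay_s < 0:
            raise ValueError("latency_delay_s must be >= 0")
        if not 0.0 <= self.stacked_recovery <= 1.0:
            raise ValueError("stacked_recovery must lie in [0, 1]")


#: Light-adapted wildtype preset (pooled dynamic-range fit parameters).
CONTROL = GenotypePreset(
    i50_photons_um2=3e3,
    slope=0.156,
    max_p1n1_uv=400.0,
    base_latency_s=0.045,
    latency_delay_s=0.040,
    erg_present=True,
    stacked_recovery=0.8,
)

#: Gnat1/Gnat2 double-knockout preset: right-shifted, steeper dynamic
#: range; latency delayed at all doses; no photopic ERG; laser response
#: abolished during a saturating LED stimulus.
DKO = GenotypePreset(
    i50_photons_um2=7.87e5,
    slope=0.817,
    max_p1n1_uv=400.0,
    base_latency_s=0.090,
    latency_delay_s=0.060,
    erg_present=False,
    stacked_recovery=0.0,
)

PRESETS: dict[str, GenotypePreset] = {"control": CONTROL, "dko": DKO}


@dataclass(frozen=True)
class SyntheticConfig:
    """Acquisition-side simulation parameters.

    Defaults emulate the recording protocol being modelled: 50 kHz
    digitization, 20 presentations per stimulus condition, 0.2 s of
    pre-stimulus baseline and 0.6 s post-onset.  ``noise_ar`` applies
    optional first-order autoregressive colouring to the additive noise
    (0 = white, the default).
    """

    seed: int = 0
    sample_rate_hz: float = 50_000.0
    n_sweeps: int = 20
    pre_s: float = 0.2
    post_s: float = 0.6
    noise_sd_uv: float = 15.0
    artifact_amp_uv: float = 200.0
    artifact_tau_s: float = 0.0003
    noise_ar: float = 0.0
    genotype: str = "control"

    def __post_init__(self) -> None:
        if self.sample_rate_hz <= 0:
            raise ValueError("sample_rate_hz must be > 0")
        if self.n_sweeps < 1:
            raise ValueError("n_sweeps must be >= 1")
        if self.pre_s <= 0 or self.post_s <= 0:
            raise ValueError("pre_s and post_s must be > 0")
        if self.noise_sd_uv < 0:
            raise ValueError("noise_sd_uv must be >= 0")
        if not 0.0 <= self.noise_ar < 1.0:
            raise ValueError("noise_ar must lie in [0, 1)")

    @property
    def n_samples(self) -> int:
        return int(round((self.pre_s + self.post_s) * self.sample_rate_hz))

    def times(self) -> np.ndarray:
        """Sample times relative to stimulus onset."""
        return np.arange(self.n_samples) / self.sample_rate_hz - self.pre_s


def saturation_fraction(dose_photons_um2: float, preset: GenotypePreset) -> float:
    """Naka-Rushton saturation fraction ``I**s / (I**s + I50**s)``.

    Evaluated in log space for numerical stability; 0 at zero dose,
    exactly 0.5 at ``I = I50``, -> 1 as the dose saturates.
    """
    if dose_photons_um2 < 0:
        raise ValueError("dose must be >= 0")
    if dose_photons_um2 == 0:
        return 0.0
    ratio = (preset.i50_photons_um2 / dose_photons_um2) ** preset.slope
    return 1.0 / (1.0 + ratio)


def vep_template(
    times_s: np.ndarray,
    shape: ComponentShape = ComponentShape(),
    scale: float = 1.0,
    latency_shift_s: float = 0.0,
) -> np.ndarray:
    """Noiseless triphasic template evaluated at ``times_s`` (rel. onset).

    Sum of Gaussian lobes, rigidly shifted by ``latency_shift_s`` and
    multiplied by ``scale``; identically zero before onset (t < 0).
    """
    if scale < 0:
        raise ValueError(f"scale must be >= 0, got {scale}")
    t = np.asarray(times_s, dtype=float)
    if t.ndim != 1 or (t.size > 1 and np.any(np.diff(t) <= 0)):
        raise ValueError("times_s must be a strictly increasing 1-D array")
    out = np.zeros_like(t)
    if scale == 0.0:
        return out
    for center, width, amp in shape.lobes:
        out += amp * np.exp(-0.5 * ((t - center - latency_shift_s) / width) ** 2)
    out *= scale
    out[t < 0] = 0.0
    return out


_DENSE_DT_S = 1e-6


@lru_cache(maxsize=32)
def _template_extrema(shape: ComponentShape) -> tuple[float, float, float]:
    """(p1_time, p1_value, n1_value) of the unit, unshifted template on a dense grid."""
    t = np.arange(0.0, shape.span_s, _DENSE_DT_S)
    y = vep_template(t, shape=shape, scale=1.0, latency_shift_s=0.0)
    i_p1 = int(np.argmax(y))
    i_n1 = i_p1 + int(np.argmin(y[i_p1:]))
    return float(t[i_p1]), float(y[i_p1]), float(y[i_n1])


def template_p1n1_amplitude(shape: ComponentShape = ComponentShape()) -> float:
    """P1N1 amplitude (P1 peak minus N1 trough) of the unit template."""
    _, p1, n1 = _template_extrema(shape)
    return p1 - n1


def template_p1_time(shape: ComponentShape = ComponentShape()) -> float:
    """Time of the unit template's P1 peak (unshifted), seconds."""
    return _template_extrema(shape)[0]


def _latency_shift(preset: GenotypePreset, frac: float) -> float:
    """Rigid template shift placing P1 per the preset latency law."""
    target = preset.base_latency_s + preset.latency_delay_s * (1.0 - frac)
    return target - preset.shape.p1_center_s


def expected_latency(preset: GenotypePreset, dose_photons_um2: float) -> float:
    """Ground-truth P1 latency of the noiseless simulated waveform.

    This is the actual peak time of the (overlapping-lobe) template
    under the preset latency law, located on a dense grid -- the
    reference against which component detection is validated.
    """
    frac = saturation_fraction(dose_photons_um2, preset)
    return template_p1_time(preset.shape) + _latency_shift(preset, frac)


def expected_p1n1_amplitude(preset: GenotypePreset, dose_photons_um2: float) -> float:
    """Ground-truth noiseless P1N1 amplitude in uV at the given dose."""
    return preset.max_p1n1_uv * saturation_fraction(dose_photons_um2, preset)


def _artifact(times_s: np.ndarray, amp_uv: float, tau_s: float) -> np.ndarray:
    """Decaying stimulus-artifact transient starting at onset."""
    if amp_uv == 0.0:
        return np.zeros_like(times_s)
    out = np.zeros_like(times_s)
    mask = times_s >= 0
    out[mask] = amp_uv * np.exp(-times_s[mask] / tau_s)
    return out


def _noise(
    rng: np.random.Generator, n_sweeps: int, n_samples: int, sd_uv: float, ar: float
) -> np.ndarray:
    if sd_uv == 0.0:
        return np.zeros((n_sweeps, n_samples))
    white = rng.normal(0.0, sd_uv, size=(n_sweeps, n_samples))
    if ar == 0.0:
        return white
    # AR(1) colouring with marginal sd preserved
    from scipy.signal import lfilter

    innov = white * np.sqrt(1.0 - ar**2)
    return lfilter([1.0], [1.0, -ar], innov, axis=1)


def simulate_vep_sweeps(
    config: SyntheticConfig,
    preset: GenotypePreset,
    dose_photons_um2: float,
    rng: np.random.Generator | None = None,
    gain: float = 1.0,
) -> SweepSet:
    """Simulate one stimulus condition: ``n_sweeps`` noisy VEP traces.

    Each sweep is the noiseless template scaled so its P1N1 amplitude is
    ``gain * max_p1n1_uv * f(dose)`` and latency-shifted per the preset
    law, plus the onset artifact and additive noise.  ``gain`` models
    animal-to-animal amplitude variability (1.0 = preset value).  With
    ``rng=None`` the generator is seeded from ``config.seed`` so the
    same seed always yields bit-identical output.
    """
    if gain < 0:
        raise ValueError("gain must be >= 0")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    t = config.times()
    frac = saturation_fraction(dose_photons_um2, preset)
    amp = gain * preset.max_p1n1_uv * frac
    scale = amp / template_p1n1_amplitude(preset.shape)
    clean = vep_template(t, preset.shape, scale=scale, latency_shift_s=_latency_shift(preset, frac))
    clean = clean + _artifact(t, config.artifact_amp_uv, config.artifact_tau_s)
    traces = clean[None, :] + _noise(
        rng, config.n_sweeps, config.n_samples, config.noise_sd_uv, config.noise_ar
    )
    return SweepSet(
        traces=traces,
        sample_rate_hz=config.sample_rate_hz,
        onset_s=config.pre_s,
        meta={
            "kind": "vep",
            "genotype": config.genotype,
            "dose_photons_um2": dose_photons_um2,
            "seed": config.seed,
        },
    )


@dataclass(frozen=True)
class _ErgShape:
    """Internal photopic-ERG lobe layout (times s, amplitudes uV)."""

    a_center_s: float = 0.018
    a_width_s: float = 0.005
    a_amp_uv: float = -30.0
    b_center_s: float = 0.048
    b_width_s: float = 0.015
    b_amp_uv: float = 120.0
    op_freq_hz: float = 130.0
    op_center_s: float = 0.034
    op_width_s: float = 0.009
    op_amp_uv: float = 15.0


def _erg_clean(times_s: np.ndarray, shape: _ErgShape, gain: float) -> np.ndarray:
    t = times_s
    y = shape.a_amp_uv * np.exp(-0.5 * ((t - shape.a_center_s) / shape.a_width_s) ** 2)
    y += shape.b_amp_uv * np.exp(-0.5 * ((t - shape.b_center_s) / shape.b_width_s) ** 2)
    # oscillatory potentials ride the b-wave rising phase
    envelope = np.exp(-0.5 * ((t - shape.op_center_s) / shape.op_width_s) ** 2)
    y += shape.op_amp_uv * envelope * np.sin(2.0 * np.pi * shape.op_freq_hz * (t - shape.op_center_s))
    y *= gain
    y[t < 0] = 0.0
    return y


def simulate_erg_sweeps(
    config: SyntheticConfig,
    preset: GenotypePreset,
    rng: np.random.Generator | None = None,
    gain: float = 1.0,
    erg_shape: _ErgShape = _ErgShape(),
) -> SweepSet:
    """Simulate photopic ERG sweeps for one animal.

    If the preset has ``erg_present`` the clean trace carries a fast
    negative a-wave, a slower larger positive b-wave and ~130 Hz damped
    oscillatory potentials on the b-wave rising phase; otherwise the
    traces contain only the onset artifact and noise.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    t = config.times()
    clean = _erg_clean(t, erg_shape, gain) if preset.erg_present else np.zeros_like(t)
    clean = clean + _artifact(t, config.artifact_amp_uv, config.artifact_tau_s)
    traces = clean[None, :] + _noise(
        rng, config.n_sweeps, config.n_samples, config.noise_sd_uv, config.noise_ar
    )
    return SweepSet(
        traces=traces,
        sample_rate_hz=config.sample_rate_hz,
        onset_s=config.pre_s,
        meta={"kind": "erg", "genotype": config.genotype, "seed": config.seed},
    )


def simulate_stacked_sweeps(
    config: SyntheticConfig,
    preset: GenotypePreset,
    laser_dose_photons_um2: float,
    led_dose_photons_um2: float,
    led_duration_s: float = 1.0,
    laser_delay_s: float = 0.5,
    rng: np.random.Generator | None = None,
    gain: float = 1.0,
) -> SweepSet:
    """Stacked-stimulus protocol: laser pulse during a saturating LED step.

    The record contains an LED-ON response at onset, a laser response at
    ``laser_delay_s`` scaled by the preset's ``stacked_recovery`` factor
    (0 = fully abolished by the ongoing saturating stimulus), and for
    ERG-competent presets an LED-OFF response at the end of the LED
    step.  The laser-response onset is stored in
    ``meta["laser_onset_s"]`` (relative to LED onset).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    t = config.times()
    if config.post_s < led_duration_s + 0.4:
        raise ValueError("post_s too short for the stacked protocol (need LED duration + 0.4 s)")
    unit = template_p1n1_amplitude(preset.shape)

    def _resp(dose: float, t0: float, factor: float = 1.0) -> np.ndarray:
        frac = saturation_fraction(dose, preset)
        scale = factor * gain * preset.max_p1n1_uv * frac / unit
        return vep_template(t - t0, preset.shape, scale=scale, latency_shift_s=_latency_shift(preset, frac))

    clean = _resp(led_dose_photons_um2, 0.0)
    clean += _resp(laser_dose_photons_um2, laser_delay_s, factor=preset.stacked_recovery)
    if preset.erg_present:
        # OFF response at LED offset, smaller than the ON response
        clean += _resp(led_dose_photons_um2, led_duration_s, factor=0.6)
    clean = clean + _artifact(t, config.artifact_amp_uv, config.artifact_tau_s)
    clean = clean + _artifact(t - laser_delay_s, config.artifact_amp_uv, config.artifact_tau_s)
    traces = clean[None, :] + _noise(
        rng, config.n_sweeps, config.n_samples, config.noise_sd_uv, config.noise_ar
    )
    return SweepSet(
        traces=traces,
        sample_rate_hz=config.sample_rate_hz,
        onset_s=config.pre_s,
        meta={
            "kind": "stacked",
            "genotype": config.genotype,
            "laser_dose_photons_um2": laser_dose_photons_um2,
            "led_dose_photons_um2": led_dose_photons_um2,
            "laser_onset_s": laser_delay_s,
            "seed": config.seed,
        },
    )
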