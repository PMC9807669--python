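# vepscope

Analysis pipeline for flash-evoked cortical potentials (VEPs) and
electroretinograms (ERGs), built for dynamic-range studies that compare
light-adapted wildtype mice against Gnat1⁻/⁻; Gnat2^cpfl3/cpfl3
double-knockout (DKO) mice, in which rod and cone phototransduction is
abolished and residual photosensitivity is carried by melanopsin-expressing
intrinsically photosensitive retinal ganglion cells (ipRGCs).

The package covers the full chain from stimulus to statistics:

- **Photometry** — corneal irradiance (mW/cm²), wavelength, neutral-density
  attenuation and pulse duration are converted to retinal photon flux
  (photons·μm⁻²·s⁻¹) and delivered dose (photons·μm⁻²), collecting over a
  3.2 mm² dilated mouse pupil and spreading over a 17.8 mm² retina.
- **Preprocessing** — per-sweep signal-to-noise ratio (response-window RMS /
  pre-stimulus RMS, baseline-subtracted), SNR-gated sweep averaging, and
  zero-phase Butterworth filtering.
- **Component metrics** — detection of the triphasic VEP waveform (first
  positive deflection P1, first negative N1, second positive P2); latency =
  onset→P1 time, amplitude = |P1 − N1|; ERG a-wave/b-wave/oscillatory-potential
  features.
- **Dynamic range** — the response statistic is the averaged trace squared and
  integrated over 0–400 ms after onset (V²·s), normalized per animal to its
  maximum, and fit to the Naka-Rushton equation

  R = I^s / (I^s + I₅₀^s)

  where I₅₀ is the half-saturating flash intensity and the dimensionless
  exponent *s* ("slope") measures response heterogeneity. Fits are pooled or
  per animal, via multistart nonlinear least squares on (log₁₀ I₅₀, log s).
- **Group comparisons** — unpaired t-tests (Student pooled-variance by
  default, Welch optional) on maximal amplitude, saturation amplitude ratio,
  I₅₀ and slope.
- **Synthetic cohorts** — no raw recordings are distributed, so a seeded
  generator produces sweep sets with known ground truth: Gaussian-lobe
  triphasic templates whose amplitude follows a Naka-Rushton law of dose and
  whose latency lengthens near threshold, genotype presets (control
  I₅₀ = 3·10³ photons/μm², s = 0.156; DKO I₅₀ = 7.87·10⁵, s = 0.817, delayed
  latency, no photopic ERG), recording noise and an onset stimulus artifact.

## Worked example

```python
import numpy as np
from vepscope.pipeline import run_pipeline

result = run_pipeline({"seed": 1})
pooled = result["fits"].query("scope == 'pooled'").set_index("genotype")
print(np.log10(pooled.loc["dko", "i50"] / pooled.loc["control", "i50"]))
```

With the default configuration (two genotypes × 4 animals × 9 doses spanning
10³–10⁷ photons/μm², 20 sweeps per condition at 50 kHz) this prints:

```
control  pooled fit: I50 = 9.09e+03 photons/um^2, slope = 0.350
dko      pooled fit: I50 = 1.39e+06 photons/um^2, slope = 1.358
dynamic-range separation: 2.18 log units
amplitude ratio (laser+LED / laser): control 0.77 vs dko 0.00, p = 2.8e-11
maximal P1N1 amplitude: control 293 uV vs dko 372 uV, p = 0.10
photopic ERG present: {'control': 1.0, 'dko': 0.0}
```

Read: the DKO intensity–response curve is right-shifted by about two log
units and steeper than control (reduced sensitivity, increased response
homogeneity); a bright laser pulse delivered during a saturating LED step
still evokes ~77% of the unconditioned response in controls but nothing in
DKO animals (saturability); maximal response amplitudes do not differ
significantly; photopic ERG features exist only in controls. Note that the
pooled power-curve parameters sit above the generating amplitude-law presets
because power scales as the square of amplitude.

The same stages are exposed on the command line:

```sh
vepscope calibrate --wavelength-nm 520 --irradiance-mw-cm2 2960 --duration-ms 0.1
# retinal photon flux: 1.39e+10 photons/um^2/s
# delivered dose:      1.39e+06 photons/um^2
vepscope simulate --genotype dko --doses 1e5,1e7 --seed 1 --out sweeps/
vepscope components sweeps/dko_dose1e+07.tsv
vepscope run --seed 1 --out results/
```

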