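# Methods

## Photometric model

Stimulus intensity is specified at the cornea (irradiance in mW/cm²,
wavelength in nm, neutral-density optical density, driver fraction,
duration). The retinal photon flux density is

    flux = irradiance · driver · 10^(−OD) · (A_pupil / A_retina) / (h·c/λ)

with the collected power spread uniformly over the whole retina. Defaults
are the fully dilated C57BL/6 mouse eye: pupil collecting area 3.2 mm²,
retinal surface 17.8 mm². h and c are the CODATA 2018 exact values, fixed
as named constants. The driver fraction is modelled as linear in optical
power — the simplest assumption for an LED driver in the absence of a
calibration curve. Dose = flux × duration. Photometric values are computed
at full double precision; comparisons against published values are made at
2 significant figures, the customary reporting precision. Out of scope:
pupillometry, Stiles–Crawford effects, preretinal media absorption, and
photoisomerization-rate conversion.

## Synthetic waveform generator

The generator defines the study conditions for every downstream test; it is
not a tuning knob.

**VEP template.** A sum of three Gaussian lobes (P1 +, N1 −, P2 +) with
strictly increasing centres. Gaussians were chosen over asymmetric kernels
because the downstream contracts concern only ordering, polarity and
extremum values, and Gaussian extrema are analytically transparent. The
default shape places P1/N1/P2 at 45/75/120 ms with widths 8/12/20 ms and
relative amplitudes +1.0/−1.4/+0.7. The template is identically zero before
stimulus onset and is rescaled at simulation time so its P1N1 amplitude
(located numerically on a 1 μs grid, cached per shape) matches the amplitude
law exactly.

**Amplitude law.** P1N1 amplitude = gain · A_max · f(I) with
f(I) = I^s/(I^s + I₅₀^s). Genotype presets carry the pooled dynamic-range
parameters: control I₅₀ = 3·10³ photons/μm², s = 0.156; DKO I₅₀ = 7.87·10⁵,
s = 0.817. A_max = 400 μV for both genotypes (maximal responses are of
similar magnitude). The per-animal gain is log-normal with σ = 0.25, a
typical between-animal amplitude variability for cortical field potentials;
without it, between-animal variance would be unrealistically dominated by
residual averaging noise and any group difference would reach significance.

**Latency law.** P1 latency = base + delay · (1 − f(I)): latency relaxes to
an asymptote at saturating intensities and lengthens toward threshold. The
functional form is a modelling choice — published evidence for this
preparation is that DKO latency exceeds control at every tested intensity,
with no numeric values printed — so the presets are illustrative: control
45 ms base + 40 ms delay span the few-tens-of-ms range typical of such
recordings, DKO 90 ms base + 60 ms delay. Because the control maximum
(85 ms) stays below the DKO minimum (90 ms), the genotype ordering holds at
every dose by construction. Ground truth for tests is
`expected_latency`, the actual dense-grid peak time of the overlapping-lobe
template under this law (lobe overlap shifts the analytic lobe centre by a
fraction of a millisecond). Per-animal latency jitter is Gaussian with
σ = 5 ms.

**ERG.** Control (photopic, light-adapted): a-wave Gaussian at 18 ms
(−30 μV), b-wave at 48 ms (+120 μV), and 130 Hz oscillatory potentials under
a Gaussian envelope on the b-wave rising phase (15 μV) — amplitudes and
timing in the photopic mouse range. DKO traces contain no ERG component at
all, only artifact and noise.

**Stacked protocol.** The saturating-stimulus experiment (laser pulse
halfway through a 1 s saturating LED step) is emulated by summing two
dose-scheduled template responses; the second (laser) response is scaled by
a recovery factor — control 0.8, DKO 0.0 — expressing how much of the
unconditioned response survives the ongoing saturating stimulus. Controls
additionally get an LED-OFF response (0.6 × the ON scaling) at LED offset.
Adaptation beyond this single factor is out of scope.

**Noise and artifact.** Additive white Gaussian noise, default σ = 15 μV
per sample at 50 kHz (realistic for a gain-1000 differential recording; an
AR(1) colouring knob exists but defaults off, as no noise spectrum is
specified for the emulated rig). The stimulus artifact is a 200 μV
exponential transient (τ = 0.3 ms) at onset. Acquisition defaults: 50 kHz
sampling, 20 sweeps per condition, 0.2 s pre-stimulus and 0.6 s
post-stimulus record. All randomness flows from one integer seed through
`numpy.random.Generator`; identical inputs give bit-identical sweep sets.

What the generator does **not** emulate: biophysical phototransduction
kinetics, cortical network dynamics, line noise, electrode drift,
inter-sweep adaptation, or non-stationary noise. Passing tests therefore
demonstrate correctness of the analysis chain under controlled conditions,
not performance on real recordings.

## Preprocessing conventions

- **SNR.** Response-window RMS divided by pre-stimulus-window RMS, both
  after subtracting the pre-stimulus mean. The exclusion threshold of 1 is
  meaningful exactly under this convention: stationary noise scores ≈ 1.
  Noiseless input (zero pre-stimulus RMS) returns an `inf` sentinel rather
  than raising. Window defaults: baseline 100 ms ending at onset, response
  400 ms from onset (mirroring the power-integration window).
- **Averaging.** Sweeps with SNR ≥ threshold (default 1) are averaged. An
  all-excluded condition yields an explicit empty average
  (`n_included = 0`) that detection refuses; it is not an exception.
- **Filtering.** All filters are Butterworth, applied zero-phase
  (forward–backward, SOS form) so filtering cannot bias latency estimates —
  a deliberate departure from the causal single-pole hardware filters of a
  typical rig, whose phase lag would shift peaks. The ERG "cleaning" filter
  is the 4-pole 200 Hz lowpass; the VEP hardware band is 10 Hz–3 kHz
  single-pole.
- **Time convention.** t = 0 at stimulus onset in all outputs; records
  store the onset position so absolute indices are recoverable.

## Component detection

Detection runs on the 200 Hz low-passed, baseline-subtracted average so
local extrema reflect waveform lobes, not single samples; the noise SD is
estimated from the pre-stimulus window of the same filtered trace, so the
prominence threshold automatically tightens with sweep averaging. The
search window is 10–400 ms post onset (the 10 ms blanking period skips the
stimulus artifact; 400 ms accommodates the long near-threshold DKO
latencies). P1 is the earliest qualifying local maximum, N1 the earliest
subsequent qualifying minimum, P2 (optional) the earliest subsequent
qualifying maximum; plateaus resolve to their first sample; peak times are
then refined on the unfiltered trace within ±2 ms.

A candidate qualifies when it (a) exceeds k·σ of the filtered pre-stimulus
noise, with k = 3 by default, and (b) reaches at least half the largest
same-polarity excursion in the search window. Both criteria are deliberate:
with ~10² effectively independent samples in a 200 Hz-band search window,
a 2σ criterion would false-alarm on a large fraction of pure-noise averages,
and an absolute threshold alone lets early noise bumps pre-empt the dominant
deflection under the earliest-extremum rule at low SNR. k = 3 with relative
prominence 0.5 keeps the noise-only false-positive rate at the few-percent
level while recovering noiseless template peaks exactly (within one sample
period) and tolerating noise up to ~20% of the P1 amplitude.

ERG features use global extrema instead (a-wave = minimum within 50 ms of
onset, b-wave = subsequent maximum within 400 ms, same k·σ criterion);
oscillatory-potential RMS is measured on the 75–300 Hz band-passed trace
(standard ERG convention) over the a-to-b interval. Feature absence is
encoded in `response_present`, never raised.

## Power statistic and Naka-Rushton fitting

Power is the trapezoidal integral of the squared averaged trace (in volts)
over 0–400 ms post onset; at 50 kHz the quadrature error is negligible
relative to any other uncertainty. All power values — including
noise-driven values from sub-threshold stimuli — enter per-animal
normalization and fitting; no response-status filtering is applied (the
statistic is defined over all recorded intensities, and discarding
"no-response" points would bias the foot of the curve upward).

The fit minimizes Σ(R_obs − R_model)² over (log₁₀ I₅₀, log s), enforcing
positivity by parameterization, with no free amplitude (normalization pins
the saturating response at 1). Multistart: 5 initial log₁₀ I₅₀ values
spanning the data's intensity range × initial slopes {0.1, 0.3, 1, 3};
termination at relative RSS change < 10⁻¹²; best-RSS solution kept.
Degenerate data (all R equal) return a non-converged flag; fits on fewer
than 3 points or less than one decade of intensity span are flagged
unreliable; per-animal fits additionally require ≥ 4 distinct intensities
to enter group summaries. Confidence intervals on (I₅₀, s) are out of
scope.

Because power scales as the square of amplitude, the pooled power-curve
parameters do not equal the generating amplitude-law presets: the squared,
re-normalized law has a higher effective half-saturation intensity and a
steeper effective slope, and the shift is larger for the shallow control
curve than for the steep DKO curve. Numerically, the control/DKO
separation contracts from 2.42 log units (amplitude law) to ≈ 2.1 log
units (fitted power curves) under the default doses. The pipeline fits
power, as the analysis it implements prescribes.

## Group comparisons

Unpaired two-sample t-tests at α = 0.05; Student pooled-variance by default
("simple unpaired"), Welch by flag — the equal-variance assumption of the
emulated analysis is not documented, so both are offered. I₅₀ is compared
on log₁₀ scale (its between-animal distribution is multiplicative); slope
and amplitudes on natural scale. Repeated-measures ANOVA across
intensities is deliberately not implemented: the pipeline exports a tidy
long-format table (animal × intensity × metric) shaped for any external
statistics package, and re-implementing RM ANOVA would invite silent
divergence from standard tools.

## Pipeline, formats, determinism

Sweep archives are tab-delimited trace matrices (μV) with a YAML sidecar
(sample rate, onset, metadata); tidy metrics are long-format CSV keyed by
(animal, dose, metric); units are fixed package-wide (μV, s, nm, mW/cm²,
photons/μm²) and conversions happen only in the photometry module. The
default cohort is 4 animals per genotype × 9 half-log-spaced doses
(10³–10⁷ photons/μm²) × 20 sweeps, plus 5 ERG animals per genotype and the
stacked protocol (laser 1.4·10⁶ photons/μm² on a 10⁷ photons/μm² LED
step) — sizes chosen so a full run completes in a few seconds on one core
while keeping ≥ 2 animals per cell for inference. Per-animal RNG streams
are derived as `default_rng([seed, stage, genotype_index, animal_index])`,
so outputs are byte-identical for a fixed config and seed (the manifest
records the config hash, seed and package version, and deliberately no
timestamps). Unknown configuration keys are rejected before any
computation.

## Known limitations

- The latency law and all latency constants are illustrative modelling
  choices, not reproductions of measured values.
- The stacked-stimulus recovery factor collapses photoreceptor and ipRGC
  adaptation dynamics into a single scalar.
- The detector is built for averaged waveforms; single-sweep component
  estimation, later components (N2/P3), and template-matching approaches
  are out of scope.
- Group inference is limited to two-group t-tests; intensity-resolved
  inference is exported, not computed.
- The conversion from threshold dose to the threshold *flux* of a 50 ms
  flash depends on a convention (dose/duration vs. nominal source flux)
  that is not uniquely determined by the stated geometry; this package
  reports flux = dose/duration and does not attempt to reproduce
  convention-dependent threshold-flux figures.
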