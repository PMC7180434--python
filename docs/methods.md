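# Methods

## Optical model

The package treats the needle-tip probe as a two-wavelength continuous-wave
near-infrared spectroscopy instrument. Light attenuation in tissue is
modelled by the modified Beer–Lambert law with hemoglobin as the only
chromophore:

ΔOD(λ) = −log₁₀(I_o/I_i) = [ε_HbO₂(λ)·[HbO₂] + ε_Hb(λ)·[Hb]]·L·B(λ)

Assumptions: scattering losses are constant over a trial (they cancel in
the *change* of optical density), water/lipid/melanin absorption is
negligible at 690 and 850 nm relative to hemoglobin, and the medium is
homogeneous over the probed volume. Concentrations are therefore
*relative*: with nominal L and B they are reported on an arbitrary molar
scale, and only ratios (StO₂) and orderings between tissues are
interpretable.

The base of the logarithm is 10, the standard optical-density convention,
matching the units of the shipped extinction table.

### Extinction spectra

`data/hemoglobin_extinction.csv` carries a standard compiled HbO₂/Hb molar
extinction dataset, resampled to a 10 nm grid over 650–1000 nm and rounded
to 1 cm⁻¹ M⁻¹. Lookups interpolate linearly and are exact at grid points.
The spectra cross at 796.8 nm (the isosbestic point, "about 800 nm"),
which is why the probe wavelengths 690/850 nm straddle it: Hb dominates
absorption at 690 nm, HbO₂ at 850 nm. `find_isosbestic` locates the
crossing of the interpolated difference spectrum by bisection (Brent) to
better than 0.1 nm and refuses intervals without a sign change.

### Inversion and conditioning

The dual-wavelength inversion solves the 2×2 system by Cramer's rule. The
system is rejected as ill-conditioned when |det(A)| < 1e-9·‖A‖∞², a
relative guard that triggers exactly where it should physically: as both
wavelengths approach the isosbestic point the rows of A become
proportional and oxygenation becomes unobservable. Negative recovered
concentrations are *not* clipped — they are physically impossible, so they
are passed through with a `mismatch` flag to signal that the
two-chromophore model does not explain the measurement.

Incident intensity I_i is not separately measured by the device; when
ingesting raw intensity recordings it is taken as the mean of the first
100 samples (1 s) of a per-channel baseline recording
(`calibrate_incident`), configurable.

### Parameters

| parameter | default | units | rationale |
|---|---|---|---|
| L (path length) | 1.0 | cm | nominal needle-tip source–detector spacing; only scales the relative concentrations |
| B(λ) (DPF) | 1.0 | – | no established DPF for a needle-tip geometry; overridable per wavelength |
| det guard | 1e-9·‖A‖∞² | – | relative, scale-free singularity threshold |
| baseline window | 100 samples | – | 1 s at the 100 Hz sampling rate |

## Classifier

Features per trial are the pair ([HbO₂], [Hb]) from the time-averaged ΔOD
of a trial; StO₂ adds no information (it is a ratio of the two) and is not
an input. Inputs are z-scored with training-set statistics stored in the
model.

The RBF network has K Gaussian hidden units and a linear output with bias.
Training is two-stage:

1. **Centers** — k-means (k-means++ seeding, Lloyd iterations, at most
   300) on the standardized features. The within-cluster sum of squares is
   recorded after every assignment step and asserted non-increasing; an
   empty cluster is re-seeded at the point farthest from its current
   center. **Widths** — σ_j is the mean Euclidean distance from center j
   to its 2 nearest centers (a single center gets σ = 1; zero widths from
   duplicated centers fall back to the mean positive width).
2. **Weights** — normalized LMS, w ← w + μ·e·φ/(ε + ‖φ‖²), with the bias
   trained as a weight on a constant activation of 1. Defaults μ = 0.5,
   ε = 1e-6, 100 epochs with per-epoch shuffling under the run seed. The
   hidden activations are fixed during this stage, so they are computed
   once. For μ ∈ (0, 1] each update contracts the per-sample error.

Targets are 1 for the vessel group (artery, vein) and 0 otherwise. The
decision threshold is chosen from the grid {0.1, …, 0.9} (step 0.1) by
maximizing training F-measure; ties break toward 0.5 and then toward the
lower value, and a score exactly equal to the threshold classifies as
"other" (the vessel call requires a strictly higher score). Grid points
with an undefined F-measure (no true and no predicted positives) are
skipped; if all are undefined, selection fails loudly.

Models serialize to JSON (centers, widths, weights, bias, threshold,
normalization, feature names, seed, config); serialization is
deterministic, so identical seeds and configs give bit-identical files.

## Metrics

Confusion counts follow the vessel-positive convention. PPV = TP/(TP+FP),
sensitivity = TP/(TP+FN), accuracy = (TP+TN)/n, and the F-measure is their
harmonic mean. Metrics with zero denominators are reported as explicitly
undefined (`None`/NaN), never coerced to 0 or 1, so degenerate sweep rows
cannot win a threshold selection. `invert_f_measure` solves the harmonic
mean for the missing partner, known·F/(2·known − F), and rejects
infeasible pairs (2·known ≤ F). The CLI prints percentages to 2 decimal
places; full precision is kept internally.

## Synthetic tissue simulator

The simulator emulates the data-collection protocol: per trial, ~10 s of
dual-wavelength ΔOD at 100 Hz in one of seven tissue layers (skin, fat,
muscle, artery, vein, lung, pleural cavity), reduced to one feature
vector. Per class it draws a trial mean from Normal(m, trial_sd·m) per
channel, adds white noise Normal(0, noise_sd·m) per sample and a 0.2 Hz
sinusoidal drift of amplitude drift_amp·m with random phase.

The class means shipped in `data/tissue_profiles.json` were derived by
forward-mapping plausible relative concentrations (µM) — artery (65, 12),
vein (45, 30), muscle (11, 9), fat (5.5, 4.5), skin (4, 3.3), lung
(1.5, 1.3), pleural cavity (85, 60) — through the MBLL with L = 1, B = 1.
They were chosen once so that every reported ordinal relation between
tissue layers holds: vein above artery at 690 nm but below it at 850 nm;
muscle above fat above skin at both wavelengths; lung minimal and pleural
cavity maximal at both; vessels richer than muscle/fat/skin/lung in both
chromophores; StO₂ of artery (84.4%) above vein (60%) above the
non-vessel tissues. The pleural-cavity profile models the *measurement*
(few returned photons read as a large ΔOD), not true tissue hemoglobin.
Noise defaults — noise_sd 0.25, trial_sd 0.10, drift_amp 0.05, all as
fractions of the class mean — put the nearest inter-class gaps at roughly
4–6 between-trial standard deviations, i.e. largely but not perfectly
separable classes.

What the simulator does **not** model: photon-transport physics (no
Monte-Carlo simulation), hematoma or motion artifacts, probe-angle and
contact variability, between-animal physiological variation, or temporal
correlation beyond the single drift sinusoid. Passing tests therefore
demonstrate that the pipeline is correct and behaves sensibly under the
assumed feature geometry — not that the classifier would reach the same
performance on live recordings.

## Problem sizes and determinism

The standard experiment is 300 training and 100 blind-test trials,
stratified near-uniformly over the 7 classes (counts differ by at most 1),
with K = 64 hidden neurons — the reference operating point. One full
simulate/train/evaluate cycle takes well under a second; the 20-seed
stability check in the acceptance tests runs in a few seconds. All
randomness flows from a single integer seed per run through
`numpy.random.default_rng`; trial seeds are spawned from the master
generator and recorded in the dataset manifest, and every CLI command
writes a JSON log of its configuration and library versions. File writes
are write-then-rename, so interrupted runs cannot leave truncated models.

## Known limitations

- Concentrations are relative; no absolute calibration is attempted, and
  L/B defaults are nominal rather than measured.
- Only two chromophores are unmixed; a third absorber biases both
  estimates (flagged only when it drives a concentration negative).
- The classifier is binary (vessel vs. other); per-tissue multiclass
  output and artery/vein discrimination are out of scope.
- The simulator's class geometry is idealized; its noise parameters are
  design choices, not fitted to recordings.
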