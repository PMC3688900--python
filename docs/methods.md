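# Methods

This note documents the models and procedures implemented in `specseg`, the
parameter choices that matter, what the synthetic data emulate (and what
they do not), and the numerical decisions taken where the design was open.

## Acquisition design and the SPT reference

The design model is a sparse-sampling block paradigm: `n_runs` runs of
`volumes_per_run` single acquisitions every `acq_interval` seconds (defaults
9 × 34 × 8 s = 306 volumes, 2448 s), stimulus on for `on_duration` = 32 s and
off for a per-cycle duration drawn uniformly from {30, 32, 34, 36} s,
4 cycles per run, with the first onset of each run delayed by 0, 4 or 6 s
(cycling across runs).  The uniform jitter grid is an approximation: the
original sessions report off-durations in the 30–36 s range with mean
34.4 s, but only the range and mean are known, so a symmetric grid over the
range is used and documented as approximate (sample mean 33 s).

The stimulus presentation timing (SPT) reference is built per run: the
on/off boxcar on a 0.1 s grid (≪ the 8 s acquisition interval, so
discretisation error is negligible) is convolved with a canonical
double-gamma HRF (gamma shapes 6 and 16 at unit scale, undershoot ratio
1/6, unit peak — the convention of standard SPM-style analyses; the
original toolchain implies but does not name its HRF), sampled at the
acquisition times, z-scored within the run, and concatenated.  Per-run
construction and whole-session construction put the spectral peak on the
same bin; per-run was chosen because the runs are independently jittered.

Spectral anchors: the stimulus fundamental is the session FFT-grid bin
nearest 4 cycles / 272 s — bin 36 of the 306-point grid, 36/2448 =
0.01471 Hz at the 5-decimal reporting precision used throughout — and the
second harmonic is bin 72 (0.02941 Hz).

**Phase convention.** All phases are FFT phases in the cosine convention
`x(t) = A cos(2πft + φ)`, degrees in (−180, 180].  The generated SPT
measures ≈ −106° at the fundamental: the boxcar's on-block centre (16 s
into a 68 s mean cycle) contributes −85°, and the causal HRF delay and
onset jitter the rest.  Published component tables in this field sometimes
use other sign/reference conventions for absolute phase; what is
convention-independent is the *phase difference* between a component and
the SPT, which is what the package reports (wrapped into [0, 360), so
in-phase ≈ 0° and anti-phase ≈ 180°).  The bundled emulation therefore
plants component phases relative to the measured SPT phase using published
phase differences, never absolute phases.

`phase_to_seconds` converts a phase difference at the fundamental into
seconds of a stimulus cycle (12.8° of a 68 s cycle ≈ 2.4 s).

## Frequency-domain measurement

* **High-pass filter**: Butterworth order 5 at 0.0074 Hz = 1/(2 × 68 s),
  applied forward-backward (`filtfilt`) for zero phase; the filter order is
  a package choice (unstated in the source analyses); passband gain is
  within 1% above twice the cutoff, so planted amplitudes at the
  fundamental (2× cutoff) survive essentially unchanged.
* **Spectrum**: one-sided FFT of the (subject-averaged) 306-point series;
  amplitudes in unit-amplitude convention (a cosine of amplitude a measures
  a; DC and Nyquist scaled by half).  The spectral peak is the maximal
  amplitude strictly above the cutoff; peak matching against the
  fundamental/second harmonic is exact on the grid (the grid spacing,
  0.000409 Hz, is coarse enough that planted and stimulus bins coincide by
  construction; higher harmonics are not matched).
* **Periodicity test**: a robust detector of a periodic component at a
  given bin.  The series is rank-transformed (robustness to heavy tails),
  and the statistic is a Fisher-g-type ratio — power at the tested bin over
  total power in the tested band (cutoff to Nyquist).  The null is formed
  by random permutations of the ranks, which hold the marginal distribution
  fixed while destroying serial structure; the p-value is
  (1 + #{g_perm ≥ g_obs})/(n_perm + 1), exact at finite samples, with
  minimum attainable p of 1/(n_perm + 1).  A circular-shift null is *not*
  usable here: circular shifts leave periodogram magnitudes invariant, so
  the statistic would be degenerate under that null.  Downstream, p-values
  are Bonferroni-corrected by (number of components × number of tested
  bins); for the reference conditions that factor is 16 × 135, where 135 =
  round((0.0625 − 0.0074) Hz × 306 / 0.125 Hz).
* **Correlation**: Spearman rank correlation between the run-averaged
  (34-point) component time course and the run-averaged SPT, with the
  t-approximation p-value; Benjamini–Hochberg FDR across the tested
  component set at q < 0.05.  Filtering precedes averaging (the order is a
  package choice; the filter is transparent in the passband so the choice
  is immaterial to the statistics).

## Classification

The three-step rule, with the grey-matter flag as an input: GM components
peaking at the fundamental or second harmonic are stimulus-related, split
into activated (significant positive r), deactivated (significant
negative r) and neutral (non-significant); GM components peaking elsewhere
are stimulus-unrelated; non-GM components peaking at a stimulus bin are
stimulus-related non-GM, all others noise.  The Bonferroni-corrected
periodicity p is reported in the component table but does not gate the
label — the label logic follows the correlation and peak-matching rules
exactly.  Sign symmetry holds by construction: negating a time course swaps
activated and deactivated and shifts the phase difference by 180° (mod 360).

## Group ICA

Temporal-concatenation group spatial ICA: each subject's (time × voxel)
matrix is reduced to k₁ temporal principal components (default 40), the
reduced matrices are stacked, reduced again to the model order (default 40,
with 50/60 available), whitened, and unmixed by Infomax — natural-gradient
ascent with the logistic nonlinearity, learning rate 0.001 annealed by
0.98 per sweep (halved on overshoot), block updates (block ≈ √(V/3),
minimum 32), at most 512 sweeps; these hyperparameters follow common
Infomax practice and are all configurable.  Non-convergence yields a
partial result with a warning rather than an error.  Per-subject maps and
time courses are recovered by projecting the aggregate mixing matrix back
through the stored per-subject reduction operators; subject time courses
are z-scored per component (every individual time course has SD 1), map
signs are fixed so each group map's skewness is non-negative, and maps are
z-scored at reporting time.  Group statistical maps are voxel-wise
one-sample t-tests across subject maps with BH-FDR thresholding at
q < 0.01 within each component map.

## Artifact selection and removal

For each of the six realignment parameters the four components with the
largest |Pearson r| between IC time course and trace are selected; for CSF,
the four components whose |z| maps correlate most with the binary CSF mask
(Pearson is the toolchain default where the procedure says only
"correlated").  The union is deduplicated in first-seen order and the
selected IC time courses are regressed out of every voxel by OLS (intercept
included, fitted contribution subtracted, whole session at once).  An empty
selection is the identity.  Exactly four per parameter are returned
regardless of magnitude — the contract of the two-pass scheme.

## GLM arm

Per subject, OLS of every voxel on the z-scored SPT regressor (the same
waveform as the frequency analysis uses) plus per-run baseline, linear and
parabolic drift nuisances (per-run rather than per-session, mirroring their
role as low-frequency drift filters); rank deficiency raises an error
naming the collinear columns.  The stimulus betas enter a group one-sample
t-test thresholded either by BH-FDR (q < 0.05) or uncorrected p (the map
comparison convention is p < 0.001 uncorrected applied to both ICA and GLM
maps).  Overlap reports give Dice, GLM-only and ICA-only voxel counts per
class, comparing activation-like classes with the positive mask and
deactivation-like with the negative.

## Synthetic data

`synthesize` builds per-subject 4-D volumes as Σ map ⊗ time course +
voxelwise Gaussian noise, on a 16×16×10 default grid (mirroring the
10-slice partial-coverage geometry at desk scale).  Spatial maps are
z-scored Gaussian blobs thresholded at 1 (matching ICA's z-scored map
convention).  Motion traces mix a slow random-walk baseline with the
motion-coupled component time courses; the coupled components load on
*every* trace (own trace strongest), reflecting the strong
inter-correlation of real realignment parameters — this also ensures each
artifact parameter has several genuinely coupled components so the top-4
rankings fill with true artifacts and planted grey-matter sources survive
the removal pass.  CSF artifacts are confined to the CSF mask.  The default
pipeline source set places blob supports on a near-disjoint grid
(spatially independent maps are what spatial ICA assumes), keeps the two
stimulus-locked sources 120° apart in phase — far enough from exact
anti-phase that their time courses are not collinear, which would make the
pair unseparable in principle — and gives every planted time course
independent Gaussian noise (SD 0.6) for the same reason.

What the generator does **not** emulate: MR physics and k-space artifacts,
physiological (cardiac/respiratory) waveforms beyond aliased periodic
artifacts, registration/smoothing residuals, inter-subject spatial
variability (all subjects share the planted maps), and scanner drift beyond
polynomial trends.  Passing tests therefore demonstrate the correctness of
the analysis pipeline under its own model assumptions, not robustness to
real-data violations of them.

## The reference grey-matter emulation

The original recordings are not deposited, so group-level maps are not
recoverable; what is recoverable is the classifier's behaviour under the
study conditions.  `specseg.study` plants the 16 grey-matter components
with their published stimulus-bin frequency, spectral amplitude and phase
difference; the two unrelated components (no published amplitude/phase)
are planted at their off-stimulus bins with amplitude 0.08 — mid-range of
the published amplitudes, consistent with their averaged-time-course SDs
being typical of the set — and random phase.

Each component's background is run-periodic multi-tone noise: random-phase
unit tones on the in-band run-harmonic bins (multiples of 9 on the
306-point grid, excluding the stimulus bins, the component's own bin, and
Nyquist), built as one 34-point run template and tiled.  Run-periodic
background is the model the published evidence supports: averaged
time-course SDs (0.235–0.381) far exceed what independent noise averaged
over 19 subjects × 9 runs would leave, and the unrelated components'
behaviour "repeats from run to run" (they sit on run-harmonic bins
themselves: 0.03309 = 81/2448 and 0.04044 = 99/2448 are 9 and 11 cycles
per run).  White or 1/f Gaussian noise cannot jointly satisfy the
published near-zero correlations of the neutral components and their
published spectral peaks — the required variance buries the peak.

The background is orthogonalised against the SPT run average within its
own frequency subspace (exactly zero linear correlation with the reference
without touching the stimulus bins), and its scale is solved by bisection
so the measured run-averaged Spearman r reproduces the published value.
The scale is capped so the largest background bin stays ≤ 0.8× the planted
amplitude: the published spectral-peak location is a categorical study
condition and takes priority over matching |r| exactly (the cap binds only
for one neutral component, whose measured |r| then lands near 0.1 instead
of 0.08 — still far from significance).

Under these conditions the classifier recovers 3 activated / 9 deactivated
/ 2 neutral / 2 unrelated; the test suite requires the 3/9 split in ≥ 90%
of 50 seeds and `scripts/acceptance.py` reports the modal counts over 50
seeds.  Problem sizes used by the tests: the emulation runs at full
reference scale (306 points × 16 components × 50 seeds); the volumetric
pipeline tests run 3 subjects on a 16×16×10 grid at ICA orders 24
(subject pass) and 8 (group pass), sizes at which the planted sources are
reliably separable.

## Numerical choices and degenerate inputs

* Frequencies are reported rounded to 5 decimals (the reporting precision
  of the component tables); grid membership checks accept that precision.
* Constant series: Spearman correlation is undefined → (nan, p=1) with a
  warning; classification treats nan r as non-significant.
* FDR on an empty p-list returns empty; single p is returned unchanged.
* Phase differences wrap into [0, 360); the float-modulo edge case
  ((−ε) % 360 = 360.0) maps to 0.
* Ties in rank-based statistics: scipy's average-rank and tie-corrected
  p-values are used throughout; periodically sampled cosines have repeated
  values whose float-level near-ties make "exact ±1" rank correlations
  hold only to ~10⁻³.
* Infomax sign/permutation indeterminacy: maps are skew-positive, ordered
  by aggregate mixing variance; tests match components by maximal |r|.
* One global seed fans out to per-stage seeds through SHA-256 (stable
  across platforms, all below 2³¹).

## Known limitations

* The grey-matter flag is an input (or a mask heuristic on synthetic
  data); the expert visual-inspection step of the original procedure is
  out of scope, as is anatomical labelling of map maxima.
* The robust periodicity procedure cited by the original analysis is
  under-specified there; the implemented rank/permutation variant is
  documented above and is not asserted to be numerically identical.
* Absolute spectral phases depend on the HRF and sign conventions (see
  above); only phase differences are comparable across implementations.
* ICASSO-style stability resampling and alternative ICA objectives are not
  implemented (the unmixing step is pluggable in principle but only
  Infomax is provided).
* GLM is plain OLS — no AR(1) prewhitening or global scaling.
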