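# Methods

This note documents the models, algorithms, numerical choices and known
limitations of `vepmap`. It is the companion to the API documentation: the
*why* behind the defaults.

## Problem setting

Motion-onset visual evoked potentials (VEPs) are scalp EEG deflections
time-locked to the onset of visual motion. The classical motion VEP contains
a sequence of named components — an early striate C1 peaking near 100 ms
that inverts polarity between upper- and lower-field stimulation, a P120
over the motion-sensitive MT+ complex, an N160/N170–N180 complex over
posterior parietal and lateral occipital cortex, a broad P250 over the
intraparietal sulcus, and an offset response (oC1) about 100 ms after the
motion stops that shares the striate generator. The package implements the
combined analysis that localizes these components: equivalent-current-dipole
(ECD) fitting of the averaged VEP under a spherical head model, constrained
(*seeded*) by fMRI activations from a block-design motion experiment, with
phase-encoded retinotopy available to delineate visual areas.

Because no public recordings exist for this paradigm, every analysis stage
is validated by parameter recovery on synthetic data whose generators are
first-class, tested library code.

## Forward model

The head is a concentric three-shell sphere (brain+CSF, skull, scalp) of
outer radius 82 mm (a group-average head), boundary radii at fractions
0.87/0.92/1.00, conductivities 0.33/0.0042/0.33 S/m (skull ≈ 80× more
resistive than soft tissue). These shell parameters are conventional
defaults, exposed in the `HeadModel` configuration; only the 82 mm radius is
a measured group value.

For each spherical-harmonic degree *n* the radial potential in every layer
is `A r^n + B r^-(n+1)`. Continuity of potential and radial current at the
two internal interfaces plus zero current at the scalp gives a 5×5 linear
system per degree whose surface solution defines a gain factor `g_n`
(normalized so a homogeneous sphere gives `g_n = (2n+1)/n`). Gains depend
only on the head model and are cached, which keeps a lead-field evaluation
near 0.5 ms — the inner loop of dipole fitting. The per-electrode angular
sums use stable upward Legendre recurrences.

Numerical choices:

* **Series truncation** defaults to 100 degrees. The tail of the expansion
  decays like `(b/R)^n` with `b` the source depth; 100 degrees keeps the
  relative truncation error below 1e-8 for eccentricities up to 0.9 of the
  brain radius (verified by order doubling). A built-in check compares the
  last ten retained degrees against the total and raises rather than return
  an unconverged field.
* **Validation** is against the closed-form homogeneous-sphere dipole
  potential (the Legendre series summed analytically via generating-function
  identities), implemented independently in
  `forward_model.homogeneous_sphere_potential`; with equal conductivities
  the shell series matches it to ~1e-15 relative.
* **Units**: positions mm, moments nA·m, potentials µV. A 30 nA·m source
  produces a few µV at the scalp, the realistic VEP scale.

The montage is the standard 10-10 64-channel layout (including the mastoids
M1/M2), taken from the published electrode table shipped with MNE, projected
radially onto the best-fit sphere and exactly mirror-symmetrized across the
sagittal plane. Sphere fitting is algebraic least squares refined by
Gauss-Newton on the true radial residuals.

**Coordinate frame.** The head frame is RAS mm with the origin at the
fitted electrode-sphere center. Published stereotaxic (Talairach/MNI-style)
coordinates of occipital cortex extend beyond an 82 mm sphere centered
there, so synthetic scenarios place sources through a fixed similarity map
(translate the origin to (0, −25, 10), scale by 0.85) that brings all
default sources below 0.85 of the brain radius. Nearest-ROI matching and
displacement comparisons are invariant under any such common similarity
transform. For real data the map is a user-replaceable affine hook.

## VEP preprocessing

Epochs span −100…+1000 ms around motion onset (275 samples at 250 Hz), with
the pre-stimulus 100 ms as voltage baseline. Artifact rejection flags (never
deletes) trials by peak-to-peak ceiling (150 µV on EEG, 100 µV on the
designated ocular channels) or flatline floor (0.5 µV); the thresholds are
conventional VEP practice and configurable, since no standard numeric values
exist. Averaging is the per-channel mean over unflagged trials of one
condition. The 35 Hz low-pass is a Hamming-window FIR applied
forward-backward (zero phase: peak latencies are untouched; the squared
magnitude response gives > 40 dB attenuation at twice the cutoff).
Re-referencing subtracts the averaged mastoids. The acquisition-side
0.1–100 Hz band-pass and the mains notch are treated as properties of the
simulated raw data, not re-applied offline.

Peak measurement returns the extremum of declared polarity in a latency
window, breaking amplitude ties toward the earliest latency and flagging
boundary extrema. Scalp topography uses surface spherical splines (order
m = 4, 50 Legendre terms), exact at the electrodes when unregularized.

## Dipole fitting

A source model is a small ordered set of fixed-position, fixed-orientation
dipoles. Fitting a window minimizes a compound cost

```
cost = 0.8 · RV + 0.2 · energy
```

* **RV** (residual variance, %) is the unexplained fraction of scalp power
  over channels × window samples. Both data and lead fields are projected to
  the average reference before comparison, making the fit independent of
  the recording reference.
* **energy** is a source-interaction penalty: the summed individual scalp
  power of the dipoles in excess of the power the model actually radiates,
  normalized by the data power and clipped at zero. Non-interacting
  configurations score zero; mutually cancelling moments (large individual
  fields summing to a small scalp field — the classic instability of
  multi-dipole fits) inflate it quadratically. The original analysis
  software's energy constraint is proprietary and unpublished; this is the
  package's own documented surrogate, kept behind the single
  `energy_term` operation so it can be swapped. A plain normalized
  source-power term was evaluated and rejected: its optimum systematically
  merges temporally overlapping sources (verified by exhaustive grid
  search), defeating parameter recovery.

Given a candidate position, the optimal orientation is closed-form: after
projecting out the frozen dipoles' fields, the unit moment direction
maximizing explained variance solves a 3×3 generalized eigenvalue problem.
The nonlinear search therefore runs over position only: 8 deterministic
starts on a posterior-brain lattice plus 4 seeded random starts, each a
bounded Nelder-Mead polish, winner refined at tight tolerance (ties broken
by lower cost, then lower eccentricity). Positions are constrained to 0.9 of
the brain radius. Orientation sign is normalized so each dipole's window
moment peaks positive.

**Sequential fitting** walks the component windows in latency order — slow
motion: C1 70–110, P120 100–140, N160 140–170, N180 170–200, P250 200–300 ms,
then an oC1 window (340–360 ms) that re-reports the C1 dipole rather than
adding one; fast motion prepends N70 (60–80 ms). Earlier dipoles keep their
geometry while their waveforms are co-estimated. A window whose residual
power after the frozen dipoles is below 1e-8 of the epoch power is skipped:
fitting a dipole to numerical residue only splits moment power across
near-collinear lead fields. Dipole optimization is restricted to the
40–350 ms range; the oC1 reuse window may extend to 360 ms since no dipole
is optimized there.

**Seeding** snaps each dipole to its nearest fMRI ROI centroid and refits
orientation only, cycling over dipoles until the coupled orientations
stabilize; per-window RV is reported before and after seeding, the
convention of seeded source analyses.

**Residual orthogonality tests** (ROT) correlate each source waveform with
the residual projected onto that dipole's scalp pattern; |r| significant at
two-sided p < 0.05 flags misassigned variance. Under independent residuals
the pass rate calibrates to 95%. Note the test is a *statistical* check:
with near-zero but structured residuals (e.g. window-edge cross-talk) it
flags correlations that are physically negligible.

Source waveforms are least-squares moment series from the stacked oriented
lead fields, with a rank guard that names the most collinear dipole pair.

### What recovery can and cannot achieve

The component windows adjoin so that each window ends 10 ms before the next
component's peak. Any finite-width waveform therefore leaks into the
neighboring window, and a single dipole fit per window absorbs a small
compromise: on the default scenario the intrinsic position offset is 1–4 mm
(confirmed as the cost's true global optimum by exhaustive grid search, i.e.
it is not an optimizer artifact). This mirrors the real method's behavior —
unseeded fits land several mm from the fMRI activation, which is exactly why
the seeding step exists. Latency recovery through the seeded model is
accurate to about one sample (4 ms at 250 Hz); the low-pass filter shifts
the peak of asymmetric deflections slightly toward their heavier tail.

## fMRI statistics

**Phase-encoded (retinotopy).** Per voxel, the F ratio divides signal power
at the stimulus DFT bin (8 cycles/scan) by the mean power of all other bins
excluding DC, the Nyquist bin and the second/third harmonics (bins 16, 24);
df = (2, 2·n_noise_bins) is recorded. The noise-free voxel gets a +inf
sentinel. Response phase maps linearly to the coordinate swept by the
stimulus cycle after subtracting a hemodynamic delay (default 5 s,
configurable; the sweep direction flag negates the mapping). The visual
field sign is the sign of the z-component of the cross product of the
polar-angle and eccentricity gradients (central differences) on the 2D
lattice standing in for the flattened cortical surface, zeroed where F is
below threshold or a gradient degenerates; mirror-image areas and their
non-mirror neighbors get opposite signs, delineating area borders.

A note on the F statistic's degrees of freedom: descriptions of this
analysis sometimes state df "equal to the number of time points"; with
2 real degrees of freedom in the signal bin and 2 per noise bin, the
calibrated choice is (2, 2·n_noise) and the null rate verifies against it.

**Block design.** OLS per voxel on [boxcar ⊗ canonical HRF, constant,
linear drift], t statistic for the task regressor with df = T − 3. The
canonical HRF is the double-gamma (peak 6 s, undershoot 16 s, ratio 1/6)
sampled at the TR. Cluster inference: voxels one-sided-thresholded at
p ≤ 0.001, 6-connected components, and a max-cluster-size null built by
sign-flipping the confound-model residuals (≥ 1000 permutations by default;
at least 100 enforced). Permutation inference replaces parametric
Gaussian-random-field cluster correction: it is exact under the sign-flip
symmetry assumption and desk-scale. Family-wise error control verifies on
pure-noise volumes.

## Coregistration

Thresholded clusters become ROIs with voxel-count-weighted centroids in mm
(peak-voxel representation available behind a flag; centroids are more
stable under noise). Each dipole is matched to the Euclidean-nearest ROI
centroid, ties broken by larger cluster then lexicographic label, with the
runner-up logged. Matching is per condition by default (pooling available).
`compare_models` reports per-label displacement between two dipole sets,
invariant to row order.

On the published slow-motion/upper-field coordinate tables the matching
assigns every unseeded dipole to its same-named activation, one-to-one. (In
the reverse, ROI-to-dipole direction, the lateral-occipital activation is
marginally nearer the striate dipole — 20.7 vs 21.3 mm — so the strictly
bidirectional mutual-nearest-neighbor property does not hold on the printed
values; the workflow only ever matches dipole → ROI.)

## Synthetic data

All generators are pure functions of (specification, seed) and reproduce
bit-identically.

**VEP sessions.** Five dipoles (six for fast motion, adding a dorsal
parieto-occipital source) at the group-average activation coordinates,
mapped into the head frame. Orientations are fixed unit vectors chosen once
so the sources project distinct scalp topographies (pairwise pattern
correlation ≤ ~0.42, weighted by waveform overlap) — the spatial
distinctness that makes named components separable in real recordings.
Component waveforms are asymmetric Gaussian deflections (rise SD 0.45× the
nominal SD, fall 1.55×): a brisk onset with slower decay, the typical
evoked morphology, which also keeps the windowed sequential fit well posed.
Latencies follow the motion-VEP template (slow: C1 100, P120 120, N160 160,
N180 180, P250 250, oC1 350 ms; fast adds N70 at 70 ms and shifts the
posterior N2 to 170 ms); amplitudes (12–30 nA·m) give scalp components of a
few µV. Trials arrive with 650–1000 ms uniform-jitter onset asynchrony, 525
trials per condition by default. Noise is an equal-power 1/f + white
mixture scaled so RMS signal / RMS noise at the peak channel equals the
scenario SNR (default 10). Artifacts (frontal-dominant blink transients and
single-channel excursions) are injected into a seeded 8% of trials,
confined to each trial's exclusive time range so truth flags map one-to-one
onto epochs despite overlapping epochs.

**BOLD.** Block-design series are spherical blobs following boxcar ⊗ HRF
plus AR(1) (ρ = 0.3) + white noise at unit marginal variance, on a 3 mm
grid whose affine is built around the requested centers (16 s ON/OFF, 8
cycles, TR 2 s, 128 volumes). The retinotopy phantom is a 2D lattice of
sinusoids at bin 8 whose phase encodes each voxel's polar angle or
eccentricity plus the hemodynamic delay, divided into horizontal strips of
alternating mirror/non-mirror progression (64 s/cycle, 8 cycles, 256
volumes); SNR is response RMS over noise RMS.

**What the generators do not emulate:** realistic skull geometry and
conductivity inhomogeneity, slow waveform rises (real C1 onsets ~40 ms
before peak; the generator's sharper rise keeps window cross-talk small, so
recovery figures are optimistic relative to real data), inter-subject
variability, correlated sensor noise and channel drift, scanner motion and
distortion, and real cortical surface geometry (the retinotopy lattice is an
idealized flat map). Passing recovery tests therefore demonstrates the
estimators are correct and calibrated under the stated noise models, not
that real-data localization reaches millimeter accuracy.

## Problem sizes in tests and the acceptance script

The test suite uses 50 noisy replicates for single-dipole recovery, 20 full
pipeline replicates for the seeded model, 200 null runs (500 permutations
each) for family-wise control, and 10,000 voxels for the voxelwise null
calibrations. The standalone acceptance script reruns the same computations
at 20 / 8 / 100 replicates respectively, its own choice of report scale.
The demonstration pipeline uses 200 trials per condition.

## Known limitations

* The energy term is a surrogate for an unpublished constraint; its exact
  numerical values are package-specific (its qualitative role — suppressing
  interacting dipoles — is preserved and tested).
* Sequential single-dipole fits are biased by window-edge component overlap
  (millimeters here; more with slower real waveform rises). The seeded model
  is the intended end product.
* The spherical head model misplaces sources relative to a realistic BEM/FEM
  by up to ~1 cm in real heads; all synthetic truth lives in the same
  spherical world, so this error is invisible to the tests by construction.
* Cluster inference assumes sign-symmetric noise for the flip permutations.
* ROT significance scales with residual length; it flags structured residual
  regardless of its absolute size.
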