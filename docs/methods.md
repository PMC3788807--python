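# Methods

## Signal models

The difference signal of pulsed ASL is modelled as the convolution
`dM(t) = 2 M0b f (c ⊛ (r·m))(t)`, `f = CBF/6000` in ml/g/s.  The
delivery function is a plug-flow boxcar with arterial T1 decay,
`c(t) = α e^(−t/T1b)` on `[BAT, BAT + τ)`.  Dispersion of the bolus
front is not modelled.

**Single-stage model** (instantaneous exchange): residue
`r(u) = e^(−f u/λ)`, relaxation `m(u) = e^(−u/T1t)` for time-since-
arrival `u`.  The convolution is evaluated in closed form in three
regimes (before arrival, during bolus passage, after bolus end); the
degenerate rate difference `1/T1b = f/λ + 1/T1t` is handled by an
`expm1`-based limit, so the expression is continuous in all parameters.

**Two-stage model**: a weighted sum of two kinetically independent
components sharing CBF, τ and α.

* Pre-capillary (weight `f_pc`): the label transits non-exchanging
  vessels, so the residue is a unit boxcar of duration `pcTT` and the
  relaxation stays at the blood T1.  The product `c·m` then collapses
  to `α e^(−t/T1b)` times the overlap of the delivery window with the
  residue window — a fully closed form.
* Capillary (weight `1 − f_pc`): single-stage kinetics with delivery
  arriving at `BAT_c` and tissue relaxation T1t.

`BAT_c` is a free parameter, deliberately *not* tied to `BAT + pcTT`:
pre-capillary vessels in a voxel may feed capillary beds outside it, so
the stages are treated as independent signal sources.  The two-stage
family contains the single-stage model at `f_pc = 0` (up to the
`BAT ↔ BAT_c` relabelling), which is why the two-stage RSS can never be
meaningfully worse.

Both closed forms are cross-checked in the test-suite against an
independent trapezoidal numerical convolution (1 ms grid, integrated
piecewise over the smooth support so the quadrature is second-order);
agreement is required to a relative error below 1e-3 and is in practice
~1e-9.

## Constants and parameters

| quantity | meaning | unit | default | note |
|---|---|---|---|---|
| α | inversion efficiency | — | 1.0 | assumed perfect tagging |
| λ | blood/tissue water partition coefficient | ml/g | 0.9 | whole-brain value |
| T1b | arterial blood T1 | s | 1.3 | 1.5 T |
| τ | bolus duration | s | 0.7 | sequence property, fixed in all fits |
| TI grid | inflow times | s | 0.2–2.4, step 0.2 | 12 points |
| T1t, M0t | tissue T1 and equilibrium signal | s, a.u. | fitted | per-voxel inversion-recovery calibration |
| M0b | blood equilibrium signal | a.u. | M0t/λ | voxelwise, absorbs B1 inhomogeneity |
| CBF | perfusion | ml/100 g/min | fitted | /6000 inside kinetics |
| BAT, BAT_c | arrival times | s | fitted | ≥ 0 |
| pcTT | pre-capillary transit time | s | fitted | ≥ 0 |
| f_pc | pre-capillary signal fraction | — | fitted | ∈ [0, 1] |

Simulation work uses `M0b = 1`; only relative amplitudes matter for
fitting.

## Calibration

T1t and M0t are fitted per voxel to the magnitude inversion-recovery
signal `M0t |1 − 2 e^(−TI/T1t)|` at TIs {0.2, 0.6, 1.4, 2.4} s, by
Nelder–Mead from T1 starts {0.3, 0.8, 1.3, 2.0, 3.0} s.  The magnitude
form is the default because magnitude reconstructions are the norm for
this readout; a signed-recovery option (`magnitude=False`) is exposed.
An all-zero voxel is flagged non-converged and excluded downstream.

## Optimization

All model fits use derivative-free Nelder–Mead least squares.  Because
the simplex is unconstrained, positive parameters (BAT, CBF, pcTT,
BAT_c, T1t, M0t) are optimized through a softplus transform and `f_pc`
through a logistic transform; estimates are reported on the natural
scale.  Initialization uses a fixed, deterministic start grid —
single-stage: BAT ∈ {0.2, 0.6, 1.0} s; two-stage: BAT ∈ {0.2, 0.6,
1.0} × BAT_c ∈ {0.6, 1.0, 1.4} × pcTT ∈ {0.5, 1.0} × f_pc ∈ {0.2, 0.5,
0.8} (54 starts) — with the CBF start solved from the peak-signal
amplitude.  Each start runs a capped exploration (150 iterations); the
best start (ties broken by enumeration order) is polished until the
relative RSS change falls below 1e-8, with at most 2000 iterations and
one simplex restart.  Non-convergence is flagged on the results object,
never fatal.  Identical inputs always produce identical fits.

## Model comparison

`BIC = N ln(RSS/N) + k ln N` with N the number of TIs and k = 2 / 5;
the lower BIC wins and exact ties go to the single-stage model.  An RSS
of zero would make the criterion singular, and on noiseless synthetic
curves both models can interpolate the data so that the comparison
would be decided by floating-point noise; any RSS at or below
`(1e-8)² · Σ dM²` (the square of the optimizer's relative convergence
tolerance) is therefore treated as a numerically perfect fit with
BIC = −∞.  Two perfect fits tie, and the tie-break prefers the more
parsimonious model.  Known consequence of honest optimization: on the
noiseless simulated curve composed purely of the fast source
(`f_pc = 1`, generated with a 0.4 s bolus but fitted with the fixed
0.7 s τ) the five-parameter model genuinely halves the residual and is
BIC-preferred; a less thorough optimizer lands in a worse local minimum
there and reports the opposite preference.

## Simulated biphasic curves

The generator mixes two *single-stage* sources on the 12-point TI
grid: stage 1 (pre-capillary surrogate) BAT = 0.1 s, τ = 0.4 s,
CBF = 50 ml/100 g/min; stage 2 (capillary) BAT = 0.9 s, τ = 0.7 s,
CBF = 50; T1t = 1.1 s, T1b = 1.3 s;
`dM_tot = f_pc dM₁ + (1 − f_pc) dM₂` for `f_pc` = 0.0 … 1.0 in steps of
0.1 (summary statistics use the nine interior values).  Both sources
deliberately relax with the *tissue* T1 even though the two-stage
fitting model relaxes its pre-capillary stage with the blood T1 — the
generator and the fitted model are intentionally mismatched, which is
why the two-stage fitted CBF settles near 58–59 rather than 50
ml/100 g/min while the single-stage fit collapses to ~33 on average.
Optional noise is additive zero-mean Gaussian on dM (difference images
are approximately Gaussian; Rician magnitude statistics are out of
scope), reproducible under a fixed seed.

## Digital phantom

A 16×16×4 grid (12×12×1 in the fast test fixture) containing a
pure-tissue block (single-stage, BAT 0.7 s, CBF 60), a pure-artery
block (single-stage, BAT 0.2 s, CBF 80), a mixed block (the two-source
sum at `f_pc = 0.5`) and background voxels holding noise only.  dM
amplitudes are scaled by `M0b = M0t/λ` with M0t = 1000; matching
inversion-recovery volumes are generated from the forward model.  The
default noise (SD 0.25 on dM, 5 on IR) puts the peak-dM SNR of the
weakest (mixed) region near 10.  The phantom emulates region geometry,
calibration and noise levels but none of the acquisition physics (no
motion, background-suppression, readout or partial-volume effects), so
phantom recovery demonstrates the estimator and pipeline, not
robustness to real-scanner artifacts.  In the mixed region the
generating CBF is not exactly identifiable under the intentional
generator/model mismatch; recovery there is judged against the value
the two-stage fit converges to on the noiseless mixed curve, while the
pure regions are judged against their generating parameters through
the BIC-preferred (single-stage) estimates.

## Noise filter

Voxels are excluded when their peak dM over TIs is below 3× the noise
level measured outside the brain mask.  The noise level is the mean
over noise voxels of the per-voxel peak |dM| — the same statistic the
filter thresholds.  Comparing a 12-sample maximum against 3× the mean
of single samples instead (statistic `"sample_abs"`, also available)
places the threshold near 2.4 noise SDs, which a 12-sample Gaussian
maximum exceeds about 10% of the time, so pure-noise voxels would leak
through at that rate; the per-voxel-peak statistic puts the threshold
near 6 SDs and rejects essentially all of them.

## ROI analysis

The tumour ROI is the set of lesion voxels with pcCBV strictly above
the lesion's 90th-percentile value, the percentile computed with
linear interpolation between order statistics (all-equal lesions yield
an empty ROI and a warning).  pcCBV is always computed voxelwise
*before* averaging — the ROI mean of CBF·pcTT/60 is not the product of
the ROI means.  Summaries report mean, SD and median per parameter
(means and medians both, since either may be wanted) plus the
percentage of voxels preferring the two-stage model.  Group contrasts
use a two-tailed paired t test on per-subject means; a zero-variance
nonzero difference is flagged degenerate with NaN results rather than
guessed.

## Problem sizes and runtime

The shipped study sizes — 9–11 simulated curves, a 32-point recovery
grid, 100 noisy replicates, and the 16×16×4 phantom (~160 fitted
voxels) — run in a few minutes on a single core and are large enough
for every summary statistic asserted; larger grids change none of the
conclusions, only the runtime.

## Known limitations

* Two-compartment permeability (PS) models, continuous/pseudo-continuous
  labeling, bolus dispersion, and probabilistic model averaging are out
  of scope.
* The two-stage parameters are weakly identified in monophasic voxels
  under noise (a mixture can mimic a single component); per the
  post-hoc-selection design, two-stage maps are carried everywhere and
  should be masked by the model-choice map before interpretation.
* Masks (brain, lesion, healthy reference) are inputs; no segmentation,
  registration or partial-volume correction is performed.
* Uncertainty intervals on the per-voxel estimates are not computed.
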