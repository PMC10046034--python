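# Methods

## Problem and overall design

The pipeline tests which blood-pressure index — systolic, diastolic, or
mean arterial pressure (MAP) — best reflects hypertensive cerebrovascular
remodeling. Subjects are labeled normotensive/hypertensive under each
rule, vascular morphology is summarized in a 17-value feature vector, and
classifiers are scored on how well morphology predicts each rule's label.
Everything runs against synthetic phantoms, so every stage has exact
ground truth and the whole analysis is reproducible from a seed.

## Blood-pressure rules

Resting pressure is the arithmetic mean of four repeated (SBP, DBP)
readings. MAP = ⅓·SBP + ⅔·DBP, rounded to two decimals. The six MAP bands
are printed to two decimals (… 99.00 | 99.01 …), so rounding before
comparison makes the partition exhaustive over positive pressures; the
monotonicity and exhaustiveness of the categorizer are property-tested.
The systolic rule uses a strict cut (SBP > 130); subjects in the
120–130 mmHg band satisfy neither the hypertensive nor the normal
definition and are excluded from that sub-experiment rather than forced
into a class. The cuts and strictness live in `BPCategoryRules`.

## Phantom generator

**Vessel trees.** Branches are unit-speed polylines: a straight base
direction plus sinusoidal lateral displacement in two orthogonal
directions with random phase; `tortuosity_amplitude` (voxels) scales the
displacement. Each tip spawns two children with radii decayed by a factor
in (0, 1]; root radii are lognormal around `root_mean` with log-SD
`root_sigma`. Trees are kept inside the volume with a margin of at least
the maximum radius (directions reflect off the safe box), and a spec whose
radii cannot fit raises. The rasterizer marks a voxel as vessel iff its
center lies within the local radius of the centerline (exact Euclidean
criterion), which makes the truth mask a capsule union whose voxel count
matches πr²L + 4/3·πr³ per branch to ~1%. Intensities are two Gaussians
(vessels 200, tissue 100 by default), optionally multiplied by a smooth
bias field 1 + a·∏cos(·) whose max/min ratio is bounded by (1+a)/(1−a).

**Cohorts.** Class-conditional resting pressures are normal:
normotensive 114.6 ± 5.7 / 78.4 ± 6.0 mmHg, hypertensive 136.6 ± 7.2 /
85.4 ± 6.4 mmHg (the systolic-rule cohort demographics). Four readings
are simulated as the true value plus N(0, 3 mmHg) repeats to exercise the
averaging rule. Defaults for the cohort experiments: 64³ volumes, two
root branches, three levels, root radius 4 voxels.

**MAP coupling.** Vascular remodeling is modeled as driven by chronic
pressure load with onset above the normal MAP band:

    severity = effect_size · clip((MAP − 99.00) / (119.00 − 99.00), 0, 1)

i.e. zero through the normal band, rising linearly and saturating at the
grade-2 boundary. Severity shrinks radii by up to 30% and raises
tortuosity amplitude by up to 100% (at effect_size = 1). The onset-form
response is the package's own design choice: a response that varies below
the normal band would make the systolic groups trivially separable
(their normal class is capped at MAP < 93.33 by definition), which
contradicts the premise that MAP is the physiologically proximate driver.
Under this model the MAP-labeled task is the sharpest read-out of
morphology, and systolic/diastolic labels act as noisy proxies — the
qualitative ordering the experiments probe. Idiosyncratic anatomical
variation beyond the pressure-coupled component is deliberately small
(`root_sigma` = 0.01): the generator emulates a cohort in which pressure
load dominates morphology. Real cohorts have far larger unexplained
variance, acquisition artifacts and anatomy the phantom does not model
(circle-of-Willis topology, flow effects, partial volume), so passing
tests demonstrate the pipeline's correctness and the internal consistency
of the design, not clinical effect sizes.

## Preprocessing

Bias correction fits a polynomial (default order 2) to log-intensities by
least squares and divides out its spatial variation, rescaling to
preserve the mean. Smoothing is MAP estimation under a generalized
Gaussian Markov random field prior — gradient descent on
(x−y)²/2σ² + λ·Σ|x_i−x_j|^β over the 6-neighborhood, with β = 1.5,
λ = 0.2, step 0.1, 10 iterations; intensities are rescaled by their SD so
the defaults are intensity-scale-free. At β = 2 one step reduces to a
linear smoother (tested against an independent convolution
implementation); a constant volume is a fixed point. On a noisy cylinder
scene the defaults cut tissue noise SD by ~60% while retaining ~90% of
the truth-edge gradient. Brain masking thresholds at the median
intensity, closes and hole-fills, and keeps the largest 26-connected
component; on phantoms this separates the tissue block from any empty
halo while containing the vasculature entirely.

## Segmentation

The intensity model is a two-component 1-D Gaussian mixture fitted by a
hand-rolled EM (initialized at the 10th/90th percentiles, or at the
mid-range split when those coincide for very sparse vessels); the mean
log-likelihood history is recorded and non-decreasing, and the fit is
cross-checked against an independent mixture implementation in the tests.
The brighter component is always reported as vessels. Initial
segmentation takes the vessel-posterior decision; for equal variances and
weights the boundary is exactly (μ_b + μ_o)/2. Adaptive refinement visits
every 8-connected component of every axial slice, dilates its bounding
box by `window_growth` × the component's equivalent diameter (default
1.0), recomputes local μ_b (in-mask window voxels) and μ_o (out-of-mask),
and adds window voxels above T = (μ_b + μ_o)/2; windows with no
out-of-mask voxels are skipped and logged. Seeds are all refined voxels
plus out-of-mask voxels above their window's threshold. Region growing
accepts voxels strictly above the *global* T (the per-window alternative
is noted but not used) over 26-neighborhoods; it is implemented as
connected-component labeling of accept-or-seed voxels keeping seeded
components — proven voxel-identical to a queue-based flood fill in the
tests — with a minimum component size of 5 voxels. The chain is monotone
(initial ⊆ refined ⊆ grown-before-filter), fully deterministic, exact on
noiseless phantoms, and reaches Dice ≥ 90% (measured ≈ 99.9%) on the
standard 128³ phantom with separation 100, noise SD 15 and 20% bias.

## Features

Radii are the Euclidean distance transform sampled at skeleton voxels
(skeletonization keeps thick vessels from over-weighting the
distribution). The digital distance transform measures to the nearest
background voxel *center*, so it overestimates the continuous radius by a
sub-voxel amount (e.g. 4.12 for a radius-4 tube); the cylinder-recovery
oracle tolerance max(0.5, 0.15·r) absorbs this. The CDF is evaluated at
integer thresholds 1..11 with overflow accumulated in the last bin, and
stored with the zero-after-saturation convention (entries after the first
exact 1 are written as 0), which keeps the saturation position
informative. Curvatures come from the implicit surface of the Gaussian
pre-smoothed mask (SD 1 voxel): mean curvature from
(∇φᵀH∇φ − |∇φ|²·trH)/(2|∇φ|³) and Gaussian curvature from the explicit
adjugate form ∇φᵀ adj(H) ∇φ/|∇φ|⁴, evaluated at boundary voxels, skipping
vanishing gradients; the sign convention makes convex bright shapes
positively curved, and sphere/cylinder/slab oracles bound the error
(median within 15%/30% of the analytic values). The vector layout is
fixed as: 11 padded CDF bins, median radius, mean radius, then
average/median mean curvature and average/median Gaussian curvature.

For cohort-scale experiments a volume-free route computes the same radius
statistics directly from the tree's per-point radii and the curvature
statistics from the analytic tube surface (k₁ = 1/r,
k₂ = κcosθ/(1 − rκcosθ) sampled over the circumference, with κ the
centerline curvature); on a straight tube this gives mean curvature
1/(2r) and Gaussian ≈ 0, consistent with the imaging route, and the two
routes agree on median radius within a voxel in the tests. The
acceptance-scale cohort comparison (2 × 150 subjects × 20 replicates)
uses this route; the imaging chain itself is validated separately on the
standard phantom and the oracle fixtures. A full imaging run at that
scale is available (`cohort_feature_table(..., mode="volumes")`) but is
three orders of magnitude slower.

## Balancing and classification

Standard SMOTE interpolates x + λ(x_nn − x), λ ~ U[0,1], among the k = 5
nearest minority neighbors; the weighted-accumulation variant blends a
point and its k neighbors with random weights normalized to sum to one
(weights are per-neighbor; a per-feature reading of the same idea is
possible but not implemented). Features are balanced unscaled. By default
the harness is leakage-safe: SMOTE runs inside training folds only and
held-out samples are always original; `balance_before_split=True` reproduces the
historically common balance-then-split ordering, which leaks synthetic
neighbors of test points into training and inflates accuracy — use it
only for fidelity comparisons. Classifier hyperparameters beyond
kernel/metric/layer sizes are library defaults; KNN's Minkowski order is
3 so it is distinct from the Euclidean entry. RUSBoost is a compact SAMME
loop with per-round weight-proportional undersampling of each class to
the minority size. Leave-one-out is deterministic given data order;
k-fold and hold-out are stratified and seeded, and a degenerate
single-class training fold is re-split with a new seed (logged).
Quadratic discriminant uses a small regularization (1e-3) for stability
on near-collinear features.

## Problem sizes and numerical choices

Tests run phantoms at 64³ (128³ for the standard segmentation property),
cohorts at 2 × 150 subjects with 20 replicate seeds for the ordering
property, and 50 permutation seeds per classifier family for the null
check; these sizes were chosen so the full suite completes in a few
minutes while keeping every statistical margin wide. Ties at thresholds
are excluded by strict inequalities (measure-zero under continuous
noise); all randomness flows from explicit integer seeds through
`numpy.random.default_rng`; axial slicing is axis 0; 26-connectivity in
3-D and 8-connectivity in 2-D throughout.

## Known limitations

The phantom's anatomy is schematic (binary trees, sinusoidal tortuosity,
two-Gaussian intensities); skull stripping reduces to brain-mask
extraction; the bias-correction and MRF smoothing are documented
simplified equivalents of the richer models used on real MRA, not
re-implementations. Accuracy values on synthetic cohorts echo the
qualitative behavior of real-data experiments (MAP best, systolic next,
diastolic last) but are not comparable to any real cohort's numbers. The
17-value descriptor's curvature rows depend on the pre-smoothing SD;
changing it rescales curvature statistics and invalidates comparisons
across settings.
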