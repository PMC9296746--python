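# Methods

This note documents the models, parameter choices and numerical decisions
behind `spectsynth`, and what the synthetic-data pipeline does and does not
emulate.

## Geometry and presets

All stages share a cubic lattice holding a cylindrical water phantom
(Jaszczak-type, diameter 21.6 cm, length 18.6 cm at full scale) whose
diameter covers a fixed fraction (~35%) of the lattice extent.

| preset | lattice | voxel | projections | matrix | u-net input |
|--------|---------|-------|-------------|--------|-------------|
| `full` | 256³ | 2.4 mm | 120 × 3° | 128² (2×2 binning) | 64×128×128 |
| `desk` | 32³ | 4.8 mm | 60 × 6° | 32² | 32×32×32 |

The desk preset is deliberately a **half-scale phantom on a coarse
lattice**: it preserves every structural element of the full protocol
(heterogeneous phantoms, attenuation, distance-dependent blur, Poisson
noise, angular interpolation by half the sampling step, OS-EM) while the
complete study — dataset build, simulation, training of three networks,
evaluation, reconstructions — runs in roughly a quarter of an hour on a
single CPU core.  Quantities tied to absolute physical scale (collimator
blur in voxels, sphere diameters in voxels) are correspondingly coarser, so
desk-scale metric *values* are not comparable to full-scale ones; the
pipeline's directional findings are.

## Phantom generation

**Random shapes.** Three generator families produce connected voxel blobs of
8–64 voxels: spheres perturbed by random real spherical harmonics up to
degree 4 (amplitudes ~ N(0, (0.3/l)²)); star-convex bodies whose radius is
the spherical product of two 2D superformula profiles (m ∈ {0..8},
n1,n2,n3 ∈ [0.5, 4]); and the largest 26-connected component of thresholded
multi-octave smoothed Gaussian noise.  The literature the shape generators
follow gives constructions, not parameter values; the randomized ranges here
are package defaults chosen to give visually diverse blobs, and are
configurable.  Volume control selects the global scale (or noise threshold)
through the order statistic of the voxel radius-to-profile ratio, which hits
the target count exactly before the connectivity filter; a bounded rejection
loop (50 draws) guarantees the final volume stays in range or fails loudly
with the seed.  10–25 shapes per mask are placed at uniform random rotations
(quaternion method) and positions, wholly inside the cylinder; overlaps are
allowed.  A shape too elongated for the coarse desk cylinder is redrawn
(bounded), which slightly biases the accepted shape population at desk scale
only.

**Patterns.** Six special categories (hot cylinder with cold shapes,
chessboard, rods, cross, seven stripes of 2.4–16.8 mm, six NEMA-style
spheres of 10–37 mm diameter on a 57.2 mm-radius circle) are generated at
full-scale physical dimensions and scaled with the lattice; every pattern
except the sphere arrangement receives a uniform random 3D rotation, the
spheres an in-plane rotation.  On the 32³ desk lattice, stripe thicknesses
and the smallest spheres round to ~1 voxel and neighbouring components can
merge; the geometric assertions (exactly 7 slabs, exactly 6 disjoint
spheres) therefore hold on the full lattice and are tested there.

**Heterogeneity.** Binary masks are multiplied by a random periodic field,
a truncated 3D Fourier series with power-law-damped amplitudes
(β = 0.9, cutoff M = 8, period p = 50 voxels at full scale — 120 mm, kept at
the same physical length, 25 voxels, at desk scale).  The (0,0,0) term of
the series divides by zero and is excluded; it only shifts the DC level,
which the subsequent rescale removes.  Because voxel coordinates are
integers, the series is evaluated exactly as one inverse DFT on a p³ period
(frequencies beyond the period alias exactly), then sampled by index
wrapping — this matches the brute-force triple sum to ~1e-13 and is orders
of magnitude faster.  The masked field is rescaled affinely so the active
minimum maps to 1 (configurable floor; 0 would erase activity) and the
maximum to 100, rounded to integers; a degenerate constant field maps all
active voxels to 100.

**Manifest.** The dataset composition follows the reference proportions
75/20/1/1/1/1/1% with largest-remainder rounding at any total size.  Maximum
activity concentrations are sampled log-uniformly over 0.2–14 MBq/mL: the
clinical distribution this emulates is concentrated at low concentrations
with a long tail, and a log-uniform law covers the stated range with that
qualitative shape without asserting fidelity to the unpublished histogram.
Splits are stratified per category.  Every entry carries its own seed; the
manifest and everything derived from it are bit-reproducible.

## Acquisition simulation

The projector is a **rotation-based attenuated parallel-beam model**, not a
Monte Carlo photon transport.  Per gantry angle the volume is rotated about
the cylinder axis, attenuated voxel-wise by exp(−μ·water path to the
detector), blurred slab-by-slab with a Gaussian PSF of width
σ(d) = σ₀ + slope·d (defaults σ₀ = 2 mm, slope = 0.03 — a
Gaussian-diffusion stand-in for a medium-energy parallel-hole collimator),
and summed along rays.  μ defaults to 0.136 cm⁻¹, the narrow-beam value for
water at 208 keV.  What is *not* modelled: photon scatter, septal
penetration, energy windows, detector dead time — the documented fidelity
gap versus a full simulation.  What is preserved is the statistical contract
the downstream study needs: deterministic noise-free projections, linear
count scaling (concentration × voxel volume × sensitivity × time per view;
sensitivity defaults to 10 cps/MBq, a typical magnitude that puts desk peak
pixels at ~10¹–10³ counts across the concentration range), and named,
seeded Poisson realizations (A, B) that are bit-reproducible and
independent.

In-plane rotation is implemented as a **bilinear splat with precomputed
scatter tables** (cached per angle): each voxel distributes its value over
the four rotated neighbours, which conserves activity exactly for in-bounds
voxels — sampling-based rotation (`scipy.ndimage.rotate`) does not conserve
counts (up to tens of percent for a point source) and was rejected for this
reason.  The backprojector gathers with the same tables and is therefore the
*exact* transpose of the projector: a matched pair for OS-EM.

The default base orbit is a synthetic ellipse (the non-circular orbit of the
physical measurement this emulates is not published as a table); any
per-angle radius table can be loaded from CSV.  Radial expansion adds a
constant offset to all radii and fails if the detector would touch the
phantom.

## Network and training

The 3D u-net treats the projection stack (angle, row, column) as a volume;
cyclic wrap-padding of the angle axis (60 → 64 as [59, 60, 1…60, 1, 2])
makes pooling across the angular wrap-around safe and the length divisible
by 2^depth.  Blocks follow the standard design: two 3×3×3 convolutions with
instance normalization (no learned affine — unstated in the design this
follows, configurable) and leaky ReLU (slope 0.01, likewise configurable),
channel doubling per encoder block, 2× max-pooling, stride-2 2×2×2
transposed convolutions, skip connections, and two final 1×1×1 convolutions
with ReLU (output therefore non-negative).  Full preset: depth 4, base 32
channels; desk preset: depth 3, base 4 — sized so a training run is minutes,
not hours, on one CPU.

The implementation is **pure NumPy** (float32, channel-last layout so every
convolution contraction is a GEMM; manual backpropagation verified against
finite differences).  Two numerical choices matter: the final ReLU head gets
a small positive bias at initialization (0.1), since a zero-initialized
double-ReLU head can start saturated at exactly zero output, where the L1
subgradient vanishes and training never escapes; and instance-norm epsilon
is 1e-5.

Training follows the reference protocol: Adam (reference defaults), L1 loss
on stacks normalized to [0,1] by the maximum of the *input* projections
(targets divided by the same factor; synthetic outputs rescaled by it), mini
batch 5, validation after every epoch, weights of the lowest validation loss
kept (ties: earliest epoch).  Schedules are step-halving (full-scale
reference: 7e-5 halved every 20 of 60 epochs) or linear (the small-dataset
variant: 1.2e-5 → 0.8e-5 over 200 epochs).  Desk-scale analogs scale the
learning rates up by ~10–20× and epochs down, since the desk network is four
orders of magnitude smaller and sees ~200× fewer optimizer steps; the
training-set-size contrast keeps the reference's ~1/20 data ratio and
longer, lower-rate schedule.  Everything is reproducible under one seed
(weight init, batch shuffling).

The u-net label semantics mirror the reference table: interpolation networks
(θ ≠ 0) are trained noisy→noisy (the target is the *same* noise realization
at shifted angles — the denoising effect is emergent, since the network
cannot predict independent noise), while the pure-denoising configuration
(θ = 0) is trained noisy→noise-free, as specified for that network.

## Evaluation

SSIM uses the Gaussian-window form (11×11, σ = 1.5, stabilizers
C1 = (0.01 L)², C2 = (0.03 L)², population covariances, window-valid
interior mean), computed per 2D projection with the data range L set to the
maximum of the ground-truth stack of the comparison; implemented in-package
and cross-checked against `skimage.metrics.structural_similarity` to 1e-6.
NRMSE is RMSE divided by the same ground-truth stack maximum, in percent
(mean- and range-normalizations selectable); the normalizer is a package
choice, as the quantity's definition leaves it open.  Per-dataset means over
the synthetic angles are aggregated as a mean of means.

Paired comparisons: NRMSE differences are tested with Shapiro–Wilk at
α = 0.05 — on the paired *differences*, the statistically relevant quantity,
a deliberate sharpening of the protocol this follows, which applied it to
the values — gating between the paired two-sided t test and the Wilcoxon
signed-rank test; SSIM always uses Wilcoxon (exact distribution up to
n = 25, normal approximation with continuity correction above, zero
differences dropped).  All-zero differences are flagged degenerate with
p = 1.  No multiple-comparison correction is applied (raw p-values are
reported).  Bland–Altman limits are mean ± 1.96 SD of the paired
differences.

## Reconstruction

OS-EM with the matched projector/backprojector (attenuation compensation
only — scatter compensation is out of scope along with scatter simulation;
no resolution recovery), round-robin angle subsets, uniform positive initial
estimate, multiplicative updates with voxels of zero subset sensitivity left
untouched.  Full-scale protocol: 6 iterations × 8 subsets of 120
projections; desk runs use 6 × 6 of 60.  The EM fixed-point and
monotone-likelihood properties hold by construction and are tested.  Image
calibration divides total reconstructed counts by known activity ×
acquisition time (cps/MBq); on a uniform desk phantom the round trip
recovers the simulated sensitivity within ~1% and the filled concentration
within ~5% in a central VOI.  At 6 iterations the EM estimate of a uniform
attenuated cylinder still carries a radial convergence profile of a few
percent; VOI-independence checks use ≥12 iterations.  SNR is VOI mean over
voxel SD; recovery is mask-integrated activity over true activity with
nearest-neighbour regridding when lattices differ.

## The study harness

`run_study` executes manifest → phantoms → noise-free projections → Poisson
realizations → training → evaluation → paired tests → orbit table → mixed
reconstructions, all derived from one seed, with optional content-hash-keyed
caching of the simulation stage.  The default desk study uses 150 masks
(105 train / 10 val / 35 test, stratified), three networks (U1: θ = +6°,
realization A; U2: same but realization B; U3: same as U1 but a ~1/20
stratified training subset with the long low-rate schedule), orbit
expansions of +2 and +16 cm evaluated with U1, and a uniform-cylinder SNR
comparison between an all-measured noisy reconstruction and a
half-measured/half-synthetic one.

## What the synthetic data does and does not show

The generator emulates the *structure* of the validation study: random
heterogeneous activity in a cylindrical water phantom, count statistics in a
clinically plausible range, paired noise realizations, orbit perturbations.
It does not emulate scatter physics, real collimators, anatomical activity
distributions, patient orbits, or detector effects, and the desk lattice is
far below clinical resolution.  Passing tests therefore demonstrate the
internal consistency and directional findings of the methodology (denoising
toward the noise-free ground truth, degradation with training-set reduction
and orbit expansion, SNR behaviour of mixed reconstructions) — not clinical
performance numbers.

## Known limitations

- The projector's fidelity gap (no scatter/penetration) means absolute
  SSIM/NRMSE/SNR/recovery values are not comparable to measurements.
- Desk-scale networks are small and trained briefly; residual structure
  error is larger relative to noise than for the full-scale reference, which
  compresses the margins of the directional effects.
- Pattern geometry degenerates near one voxel on the desk lattice (stripes
  and small spheres merge).
- The non-circular base orbit is synthetic; only its qualitative
  non-circularity matters to the pipeline.
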