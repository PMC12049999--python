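# Methods

This note records the scientific and numerical choices behind
`cardiotag`: what is modelled, what is deliberately simplified, which
parameters matter, and what the verification experiments do and do not
demonstrate.

## Anatomy model

The left ventricle is a truncated thick-walled prolate ellipsoid of
revolution about the image z axis. Parameters, with defaults sampled
uniformly per case:

| parameter | range | units | meaning |
|---|---|---|---|
| `endo_radius_eq` | 15–30 | mm | equatorial endocardial radius |
| `wall_thickness` | 6–14 | mm | uniform ED wall thickness |
| `long_axis_length` | 65–95 | mm | epicardial apex to basal plane |
| `base_truncation_fraction` | 0.45–0.7 | – | basal plane height / epicardial long semi-axis |

The ranges were chosen so that any sampled ventricle fits a 128 mm
field of view with margin, spanning roughly the adult range from small
to dilated hearts. Voxelization is by voxel-center inclusion (0-based
indices, world = origin + index·spacing); the myocardial voxel count
agrees with the exact truncated-shell volume to < 2 % at 1 mm. A
triangulated endo+epi surface mesh (open at the base) accompanies every
label volume. Background structures — one liver ellipsoid below the
apex and one partial chest ring — are placed with a 2-voxel safety
margin and scale with the field of view; image realism around the LV is
their only role. No right ventricle, papillary muscles or torso atlas
is attempted.

## Motion model

Cardiac deformation is a closed-form, axisymmetric, exactly
incompressible mapping (see the README for the equations) with three
amplitudes: endocardial contraction `c`, apex-to-base twist `τ`, and
longitudinal shortening `s`, driven by a raised-cosine activation that
is 0 at ED, 1 at the systolic peak (default at 37.5 % of the cycle,
around the normal end-systolic time), and relaxes to ~0 at the cycle
end. The construction provides exact ground truth everywhere:
analytic displacement, deformation gradient (det F = 1 to machine
precision; verified against finite differences to < 1e-4 relative),
closed-form inverse (round-trip < 1e-6 mm), and analytic strain.

A biomechanical simulation would produce richer motion — regional
heterogeneity, wall-thickening gradients, valve-plane descent, a
realistic electromechanical activation sequence. The kinematic family
trades that realism for exactness: the pipeline's contract (train on
images with known dense motion, score against ground truth) is
preserved, but passing results say nothing about pathology-specific
motion patterns the family cannot express. Biophysical parameters
(shear-modulus scale 0.25–10 log-uniform, peak active stress
0.1–1.0 MPa, filling pressure 4–25 mmHg) are sampled and mapped
monotonically (higher stress and preload increase, stiffer tissue
decreases, a common drive in [0, 1], plus small per-component jitter)
onto amplitude ranges c ∈ [0.05, 0.35], τ ∈ [5°, 20°], s ∈
[0.05, 0.25]; the biophysical values travel in the manifests so cohort
bookkeeping matches protocols stated in those terms.

Label warping uses the closed-form inverse map with nearest-neighbour
lookup (no holes by construction); warped wall volume is conserved to
< 3 % across all phases, the discretization residual of an exactly
volume-preserving map.

## Tag signal model

The CSPAMM signal is the idealized closed form: a 1-1 SPAMM
preparation imposes `ρ·cos(2π e·X/d)` per direction with the material
ED coordinate X (tags advect exactly), and the complementary
subtraction removes DC exactly. The stated acquisition assumptions
(t_aq < T2*, t_RR > T1, swept flip angle) make tag fading negligible,
which is why no relaxation times appear anywhere. Not modelled:
k-space/EPI readout, B0/B1 inhomogeneity, breathing or slice
misalignment.

Noise convention (the literature rarely states one): per-channel
zero-mean Gaussian on real and imaginary parts with σ = A_myo/SNR,
where A_myo is the mean noise-free myocardial magnitude of that
direction's volume, applied independently per tag direction *before*
complex multiplication — each direction is a separate acquisition.
The realized σ matches prescription to < 2 % at 128³; the product of
three noisy complex volumes produces the heavy-tailed magnitude noise
visible in real combined CSPAMM data. Anisotropic acquisition grids
(porcine 2×2×5 mm) are synthesized on the acquisition lattice and
trilinearly resampled to 1 mm before combination; magnitudes are
min-max normalized to [0, 1] per volume.

The tag-period probe measures the dominant spatial frequency of the
real-valued modulation (zero-padded FFT with parabolic peak
refinement, well below 0.1 mm resolution). It is defined on the
single-direction complex volume, not on the combined magnitude, whose
rectified pattern has intensity nulls every d/2.

## Strain measures

Three routes, mirroring how tagged-MR studies report them:

* **Radial (tensor route).** F = I + ∇u by central differences on the
  ED grid (one-sided at the mask boundary; voxels without any in-mask
  neighbour pair along an axis are excluded), E = ½(FᵀF − I) projected
  on the in-plane outward radial direction, averaged over the wall.
  Agrees with the analytic tensor to ~1e-3 (mean absolute, interior
  voxels at 1 mm).
* **Circumferential (mask route).** Per SAX slice in the middle 50 %
  of the wall's long-axis extent (apical and basal slices are the
  error-prone ones), the wall annulus is skeletonized; the mid-wall
  diameter is twice the mean distance of skeleton pixels from the
  annulus centroid; e_c is the engineering strain of the slice-averaged
  diameter. Slices with an open annulus at any phase are dropped.
* **Longitudinal (mask route).** In two orthogonal LAX planes through
  the axis, the wall mask is skeletonized and the length of the longest
  endpoint-to-endpoint geodesic measured. Two numerical refinements
  matter: the mask is extruded past the basal cut before
  skeletonization (the medial axis of a flat-cut strip forks toward the
  corners, a half-width artifact that would otherwise grow with wall
  thickening), and the pixel chain is smoothed with a short moving
  average before summation (an 8-connected chain overestimates oblique
  curve length by up to ~8 %).

Note the deliberate convention mix: e_r is Green–Lagrange while e_c and
e_l are engineering (length-ratio) strains; at peak deformation the two
conventions differ substantially, so the three components are not
mutually comparable magnitudes.

**What the longitudinal mask route measures.** Under the motion
model's pure longitudinal scaling z' = z(1 − s·a), the base-to-apex
distance contracts by exactly s·a, but the LAX mid-wall contour does
not: its apex arc runs transverse to the long axis and is invariant
under z-scaling. The skeleton-length strain is therefore systematically
smaller in magnitude than s·a — about 70–85 % of it depending on the
LV aspect ratio. The package provides the exact closed-form length
ratio of the forward-mapped mid-wall contour
(`motion.midline_length_ratio`) as the oracle for what the route
actually measures; the skeleton implementation agrees with it to
< 0.01 under pure shortening. The same geometric fact applies to real
skeleton-based longitudinal strain measurements whenever apical
curvature contributes to the measured curve. (The mid-line oracle
follows material midpoints; under wall-thickening contraction the
geometric mid-line of the deformed wall deviates from it by a few
percent, so oracle comparisons are made under pure shortening.)

## Networks and training

The 3D UNet pair follows the standard encoder–decoder layout: two
3×3×3 conv + ReLU per resolution level, channel count N doubling at
each of `depth` max-pool downsamplings, nearest-neighbour upsampling
with a channel-halving convolution and skip concatenation, 1×1×1
output head (2 channels for SAXNet: x, y; 1 for LAXNet: z). Full-scale
configuration: N = 64, depth 4, 64³ patches. The layer stack is
implemented in numpy (im2col + BLAS) with numba-jitted direct stencil
kernels used when numba imports; both paths are algebraically
identical and cross-checked in the tests, and all gradients are exact
(adjoint and directional-derivative tests).

Training: Adam, masked MSE over myocardial voxels only, batch 32,
initial lr 1e-4 halved (≤ 3 times) whenever validation loss exceeds
the best epoch so far, 25 epochs, best-validation weights retained,
case-level 80/10/10 splits, fully seeded. Patch extraction pairs the
ED image with every later phase, lattice stride 16, ≥ 10 % myocardium
per retained patch, with provenance sufficient to reconstruct the
source block bit-exactly. Inference stitches overlapping patches
(default stride = half patch) with a strictly positive separable
raised-cosine window normalized by the accumulated weight — an exact
partition of unity, so a constant prediction stitches to a constant.
Checkpoints embed the architecture and the tag distance they were
trained for and refuse mismatched inference unless overridden.

## The desk-scale verification experiment

`experiments.run_scaled_learning` executes the entire pipeline at a
size chosen to finish in minutes on one CPU core: 48³ grid at 2 mm
(96 mm FOV), proportionally smaller ventricles (endo radius 10–16 mm,
wall 5–8 mm, length 50–66 mm), 4 cardiac phases (three ED-pairs, one
of which is a zero-motion anchor), per-case SNR uniform in 5–35, 7 mm
tags, N = 8 depth-2 networks on 12³ patches (stride 12), 20 training /
3 validation / 5 test cases, 25 epochs, batch 16, lr 1e-3. Batch size
and learning rate are the scaled-preset adaptations: a 400× smaller
network trains stably at the higher rate, and 16 patches fill a batch
from far fewer cases.

At seed 1 this yields held-out median absolute displacement errors of
0.09 / 0.10 / 0.23 mm (x / y / z) and pooled predicted-vs-truth Pearson
correlations of 0.91 / 0.91 / 0.96 — subvoxel recovery with the z
component hardest, as expected: longitudinal displacements near the
apex exceed half a tag period, so their recovery leans on anatomical
context that a 24 mm patch only partly provides. These numbers
demonstrate that the simulator, the training loop and the inference
stitching compose correctly; they do not demonstrate in-vivo accuracy,
robustness to tag fading, breathing artifacts, or anatomy outside the
ellipsoidal family.

The SNR sensitivity sweep re-synthesizes identical cases (same
geometry, motion and background; fresh noise only) per SNR level and
re-runs inference and the full strain pipeline, with the ED anatomy
carried to each phase by the *inferred* fields (forward splatting with
morphological closing), as an in-vivo analysis must do.

## Numerical conventions

* Quartiles: linear interpolation (recorded in every summary object).
* Signed errors are predicted − reference; displacement errors pool
  myocardial voxels over all non-reference phases.
* Grids: axis-aligned only; NIfTI affines are diagonal and oblique
  affines are rejected on read. Displacement NIfTIs are 4D float32,
  (x, y, z) component order, mm.
* Degenerate inputs fail loudly: empty myocardium, non-orthonormal tag
  directions, open annuli on all slices, constant input to the period
  probe or to Pearson correlation.
* Determinism: every stochastic stage takes an explicit seed;
  identical seeds give bitwise-identical volumes, and training curves
  reproduce exactly on one machine.

## Known limitations

* The anatomy/motion family is idealized; no regional dysfunction, no
  valve-plane dynamics, no RV.
* The signal model omits readout physics and tag fading.
* e_c/e_l mask routes inherit skeletonization discretization (~0.005
  strain at 1 mm; larger on coarse grids).
* The scaled learning check trains small networks on small volumes;
  full-protocol training (N = 64, 260 cases, 64³ patches) is supported
  by the same code but takes GPU-scale resources.
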