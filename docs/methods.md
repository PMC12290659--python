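# Methods

`plicl` learns texture representations of nerve-fiber architecture from 3D
polarized light imaging (3D-PLI) parameter maps by self-supervised
contrastive learning, and ships everything needed to exercise the method
without external data: the physical signal model, an analytic phantom
generator, the PLI-specific augmentation algebra, classical texture
baselines, and a downstream evaluation suite.

## Signal model and parameter retrieval

A birefringent section between a rotating polarizer and a circular analyzer
transmits, at polarizer angle ρ,

    I(ρ) = I_T/2 · (1 + sin(2ρ − 2φ) · sin δ),       δ ≈ 2π t Δn / λ · cos²α,

with transmittance `I_T = I_0 e^{−tμ}` (Bouguer–Lambert), in-plane direction
φ (mod π), retardation |sin δ|, cumulative birefringent thickness t (µm),
birefringence Δn, wavelength λ (550 nm by default) and inclination α.
Nine equidistant angles over 180° make the order-2 discrete Fourier
coefficients exact, so retrieval is closed-form:

    I_T = 2·mean(I),   a = (2/9)Σ I_k cos 2ρ_k,   b = (2/9)Σ I_k sin 2ρ_k,
    |sin δ| = √(a²+b²)/mean(I),   φ = ½·atan2(−a, b)  (mod π).

These formulas are validated by a round-trip identity test (< 1e−9 on 10⁴
random pixels).  The sign of δ is unobservable; retardation is stored as a
magnitude.  An all-zero profile leaves direction/retardation undefined; both
are returned as 0 together with a flag.

Inclination estimation is a deliberately simplified two-step inversion:
`t̂ = −ln(I_T/I_0)/μ_ref` with a single reference attenuation coefficient,
then `cos²α = arcsin(r)·λ/(2π t̂ Δn)` clipped to [0, 1].  It resolves only
the principal branch of |sin δ| and assumes uniform attenuation; it is
accurate to a few degrees on simulator output when μ_ref matches the true
attenuation, and is not intended as a calibrated physical retrieval.

## Augmentations

All augmentations act jointly on (I_T, φ, r), because the three maps derive
from one underlying sinusoid:

* **Attenuation scaling** `I_T′ = I_0 (I_T/I_0)^{γ_a}`, and **thickness
  scaling** `r′ = |sin(γ_t arcsin r)|` with the matching transmittance
  exponent.  The magnitude in the thickness rule keeps r in [0, 1] when the
  scaled phase passes π/2, consistent with retardation being |sin δ|.
  Exponents are drawn as 2^u, u ~ U[−1, 1].
* **Resampling** (affine warps, blur) averages transmittance linearly and
  (r, φ) as the transmittance-weighted complex field `r·I_T·e^{i2φ}`,
  decomposed back into magnitude and half-phase.  Stencils whose weights sum
  to one leave constant fields exactly fixed.
* **Direction correction**: unit direction vectors are pushed through the
  transform Jacobian (for affine maps, the matrix itself), re-expressed
  mod π, *before* the pixel grid is warped.  Rotation reduces to φ′ = φ + θ
  and flips to φ′ = −φ (mod π); both are covered by the general path.

Randomized policy (training defaults): affine with per-axis scale
[0.9, 1.3], rotation ±180°, per-axis shear ±20°, bilinear resampling with
zero padding; center crop (discarding padding); random flips (p = 0.5 per
axis); thickness and attenuation scaling; Gaussian blur with p = 0.5 and
σ ∈ [0, 2] (reflect boundary, truncated at 4σ).  Interpolation order and the
blur truncation radius are implementation choices documented here; nonlinear
(displacement-field) warps are out of scope.

## Context sampling and the contrastive objective

Positive pairs are patches assumed to share fiber-architecture content.
Anchors are drawn uniformly over tissue (GM/WM mask) centers; the positive
location is drawn in the undistorted reference frame:

* **SAME** — the anchor itself; **CL-2D** — uniform on an in-plane circle of
  radius r µm; **CL-3D** — uniform on the *surface* of a sphere of radius
  r µm, with the z component divided by the 60 µm section spacing and
  snapped to the nearest section other than the anchor's (ties random,
  out-of-stack draws redrawn); **NN** — a random adjacent section at the
  same in-plane reference coordinates.  Voxels are strongly anisotropic, so
  all geometry is computed in micrometers before snapping.
* Patches are always cut from the **original, unwarped** section maps; the
  per-section frames supply natural orientation variation.  Positive
  locations are not foreground-checked (only anchors are); a strict mode is
  not provided because the phantom's background is physically valid signal.

The encoder is a 50-layer bottleneck residual network with every block's
channel width scaled by 1/8 (pooled output 256; full width would give 2048),
followed by a 2-layer projection head (hidden 90, output 32).  Inputs are
the cyclic-safe channels (I_T, r cos 2φ, r sin 2φ), standardized by running
per-channel statistics accumulated over the first `standardization_batches`
batches and then frozen — freezing makes inference deterministic.  The
InfoNCE loss contrasts each sample's positive against all other 2N−2 batch
members under cosine similarity at temperature τ = 0.5; projections are
L2-normalized before the similarity.  Reference optimization settings:
Adam, lr 1e−3, weight decay 1e−6, 512 pairs per batch.

The network and its training loop are implemented in a compact NumPy
reverse-mode autodiff module (`plicl.nn`): im2col convolution, batch
normalization with running statistics, max/average pooling, linear layers, a
fused normalized-temperature cross entropy, and Adam.  Gradients are
verified against central finite differences and the loss against an explicit
double-loop oracle.  Batch-norm statistics are per (single-device) batch.

**Desk-scale profile** (`desk_config()`): 64 pairs per batch,
standardization frozen after 16 batches, lr 3e−3, anchor patch 48 px with a
32 px crop, 450 steps.  The elevated learning rate compensates for the
small batch; patch and crop sizes preserve the physical extent of the
reference protocol at the phantom's 4 µm pixels (see below).  These sizes
were fixed once as the package's single-CPU profile.

Inference tiles sections (128 px tiles, 50 % overlap by default) and
extracts one pooled 256-d vector per tile without augmentation; tiles can be
labeled by the modal mask value of their footprint.

## Synthetic phantom

The phantom is an analytic 3D structure in a common reference frame: an
annular "cortex" band (GM) around a "white matter" core, outside it
background.  Angular sectors carry regionally distinct fiber recipes —
defaults: radial cortical fibers (strong columnar texture), tangential
cortical fibers (smooth laminae), a coherent parallel bundle, and an
incoherent crossing simulated by averaging the intensity profiles of two
populations ~80° apart before retrieval, which reproduces the
characteristic retardation drop of crossings.  Regions differ in thickness,
attenuation, inclination and texture heterogeneity (a per-recipe gain on a
band-limited 3D noise field with mild cross-section correlation).

Sections are serial slices: radii and center drift smoothly with z, each
section is evaluated in an independently jittered affine frame (rotation
±3°, translation ±2 px; the section→reference transform is stored), a 10 %
fraction of sections receives a 1.5× attenuation-outlier scaling, and
Gaussian noise (σ = 0.01 on unit-scale intensities) is added to the raw
9-angle profiles before harmonic retrieval.  Masks (BG/GM/WM), region
identities and morphology are emitted analytically: cortical depth as the
normalized band coordinate (0 pial, 1 GM/WM), curvature as the inverse
level-set radius, obliqueness from the z-slope of the band surface.

The default pixel size is 4 µm: at 256 px the phantom spans ~1 mm, so the
118 µm context radius is small relative to anatomical regions and a 48 px
anchor covers ~192 µm — the same physical geometry as the full-resolution
protocol (192 px at 1.3 µm).  This choice matters: at 1.3 µm/px a 256 px
phantom is only ~0.3 mm wide, positives frequently fall in unrelated
regions, and the contrastive task carries almost no signal.

**What the phantom does not emulate:** real vervet anatomy, blood vessels,
tears/folds beyond affine jitter, partial-volume mixtures at region borders
beyond pixel sampling, scanner shading, or the registration errors of a real
3D reconstruction.  Passing tests therefore demonstrate the correctness and
internal consistency of the machinery at a realistic desk scale, not
performance on real tissue.

## Classical baselines

Direction maps are reduced to an orientation-gradient magnitude before
feature extraction: φ is doubled into the unit complex field
`z = cos 2φ + i sin 2φ`, filtered with both 3×3 Sobel kernels, and
aggregated as φ̂ = |G_x + G_y| / 12, the tight normalizer Σ|K_x + K_y|
bounding φ̂ to [0, 1].  On each tile and each of (I_T/I_0, r, φ̂):
128-bin histogram statistics (mean, population variance, skewness, excess
kurtosis, Shannon entropy in nats) → 15 features; rotation-invariant uniform
LBP, 8 points, radii {1, 2, 3}, 10-bin histograms over the valid interior →
90 features; symmetric normalized GLCMs over 32 levels at distances
{1, 2, 4} and four angles (angle-averaged contrast, correlation, energy,
homogeneity; correlation of a single-level tile defined as 0) → 36 features;
concatenation → 141.  Entropy base, bin ranges and the statistic
conventions are package choices documented here, since several are not
uniquely determined by common usage.

## Downstream evaluation

* **PCA** fitted on a seeded random voxel subset, applied everywhere.
* **Two-step clustering**: k-means (128 centroids by default) on a seeded
  100 000-sample subset, nearest-centroid assignment of all voxels, Ward/
  Euclidean agglomeration of the centroids; cuts at any K; silhouettes are
  computed on the k-means subsample (full-volume silhouettes are quadratic).
* **Cross-section IoU**: per adjacent pair and per cluster in their union,
  on foreground voxels; averaged over clusters first, then pairs.
* **Linear probe**: one-vs-rest logistic regression on z-scored features,
  class-balanced training subsets, macro F1 mean ± SE over repeated fits,
  evaluated on held-out *sections* (section-level splits avoid leakage
  through cross-section continuity).
* **Morphology regression**: ridge (α = 1e4 by default) from z-scored
  features to cortical depth, WM depth, curvature and obliqueness, scored by
  R² on a disjoint seeded test set.  Targets come from the phantom's
  analytic ground truth.
* **RBF retrieval**: affinity `exp(−‖h − q‖²/(2σ²))` (σ = 3.5) of every
  voxel to the mean feature of user-chosen query voxels, typically on
  PCA-reduced, σ = 2-smoothed feature maps.

## Numerical and design notes

* All direction arithmetic is mod π; outputs are canonicalized to [0, π).
* Resampling with zero transmittance emits r = 0, φ = 0 (flagged cases).
* Bilinear warps zero-pad; the training pipeline center-crops to discard
  padding.  Blur uses reflect boundaries so constant fields are fixed
  points.
* CL-2D radii are measured in the reference frame when jitter exists.
* Checkpoints, stacks and feature maps are stored in HDF5; parameter maps
  and raw series also round-trip through multi-page TIFF.
* Problem sizes in the shipped tests (256² phantoms, 450-step training,
  64-pair batches) are the package's desk-scale study conditions; the
  reference protocol values (512-pair batches, 192/128 px patches at
  1.3 µm) remain the documented defaults of the corresponding data types.

## Known limitations

Single-device training only (no synchronized batch norm across devices);
the inclination model is a labeled approximation; nonlinear section
transforms and displacement-field augmentation are extension points; the
phantom's morphology spans a narrow obliqueness range (a few degrees), so
obliqueness regression on the phantom is close to degenerate; NumPy training
throughput (~0.5 s per 64-pair batch of 32² crops on one CPU) is appropriate
for desk-scale experiments, not full-scale runs.
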