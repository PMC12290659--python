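# plicl

Self-supervised texture representations for **3D polarized light imaging
(3D-PLI)** — a microscopy technique that images brain sections between
rotating polarizers and yields, per pixel, three co-registered parameter
maps: transmittance *I_T*, in-plane fiber direction *φ* (mod 180°), and
retardation *|sin δ|*.  Characterizing nerve-fiber architecture in these
maps (cortical layers, fiber bundles, crossings, U-fibers) normally demands
expert reading; `plicl` instead learns compact texture embeddings from
unlabeled section stacks and provides the surrounding machinery to simulate,
train, and evaluate them.  It is aimed at researchers working with serial
polarimetric or histological section data who need observer-independent
texture descriptors.

## Method

Positive pairs for contrastive learning are sampled by **3D spatial
context**: an anchor patch at a random tissue location and a positive patch
displaced by a vector drawn uniformly on a sphere of radius *r* (µm) in the
undistorted 3D reference frame, snapped to a neighboring section (CL-3D;
in-plane circle → CL-2D, r = 0 across sections → NN, r = 0 in-plane → Same).
Both patches receive PLI-aware augmentations that act jointly on
(*I_T*, φ, *r*): physically derived attenuation/thickness scalings
(*I_T′ = I_0 (I_T/I_0)^γ*, *r′ = |sin(γ arcsin r)|*), geometric transforms
with direction correction through the Jacobian (φ′ = φ + θ under rotation),
and resampling on the complex field *r·I_T·e^{i2φ}*.  A width-reduced
(1/8) 50-layer residual encoder maps the cyclic-safe channels
(*I_T*, *r* cos 2φ, *r* sin 2φ) to 256-d features *h*; a projection head
(90 → 32) feeds the InfoNCE objective

    ℓ_{i,j} = −log [ exp(s(z_i, z_j)/τ) / Σ_{k≠i} exp(s(z_i, z_k)/τ) ],  τ = 0.5,

with cosine similarity *s* over 2N in-batch samples.  After training the
head is discarded and whole sections are tiled (128 px, 50 % overlap) into
feature maps used for clustering, linear probing, morphology regression and
query-based retrieval.  Classical baselines (histogram / LBP / GLCM features
on *I_T*, *|sin δ|* and a circular-Sobel direction gradient φ̂) share the
same tiling grid.

Everything runs on plain NumPy — including the encoder, which is built on a
small in-repo reverse-mode autodiff module — so the full pipeline works on a
single CPU at desk scale.  A four-region analytic phantom (radial/tangential
cortex, parallel/crossing white matter) generated from the physical signal
model supplies realistic multi-section stacks with ground-truth masks,
region labels, transforms and morphology.

## Worked example

Train a CL-3D encoder on the default synthetic stack and probe the learned
features with 10–100 labels per fiber-configuration region on held-out
sections:

```python
import numpy as np
from plicl.synthdata import PhantomSpec, make_phantom, labeled_patch_dataset
from plicl.contrastive import train, desk_config
from plicl.downstream import linear_probe

stack = make_phantom(PhantomSpec(), seed=1)
print(f"phantom: {stack.n_sections} sections of {stack.shape[0]}x{stack.shape[1]} px "
      f"({stack.pixel_size_um} um/px), regions: {', '.join(stack.region_names)}")

model = train(stack, mode="cl3d", radius_um=118.0, cfg=desk_config(),
              seed=0, steps=450, patch_px=48, train_sections=[0, 1, 2, 3, 4, 5])
print(f"contrastive loss: {model.loss_curve[0]:.3f} (first step) -> "
      f"{np.mean(model.loss_curve[-20:]):.3f} (last 20 steps)")

tr = labeled_patch_dataset(stack, 32, 16, label_source="region", sections=[0, 1, 2, 3, 4, 5])
te = labeled_patch_dataset(stack, 32, 16, label_source="region", sections=[6, 7])
trk = [(p, l) for p, l, *_ in tr if l > 0]; tek = [(p, l) for p, l, *_ in te if l > 0]
xtr, ytr = model.encode([p for p, _ in trk]), np.array([l for _, l in trk])
xte, yte = model.encode([p for p, _ in tek]), np.array([l for _, l in tek])
res = linear_probe(xtr, ytr, xte, yte, n_per_class=[10, 30, 100], repeats=10, seed=0)
for n, f1, se in zip(res.n_per_class, res.f1_mean, res.f1_se):
    print(f"linear probe, {n:4d} labels/region: macro F1 = {f1:.3f} +- {se:.3f}")
```

Output of this exact script (one CPU, ~4 minutes):

```
phantom: 8 sections of 256x256 px (4.0 um/px), regions: gm_radial, gm_tangential, wm_parallel, wm_crossing
contrastive loss: 4.861 (first step) -> 4.521 (last 20 steps)
linear probe,   10 labels/region: macro F1 = 0.901 +- 0.009
linear probe,   30 labels/region: macro F1 = 0.924 +- 0.006
linear probe,  100 labels/region: macro F1 = 0.946 +- 0.003
```

The contrastive loss falls from the uninformative level (log 126 ≈ 4.84 for
64-pair batches) as the encoder discovers cross-section structure, and a
linear classifier on the frozen 256-d features separates the four fiber
configurations with only tens of labels — the minimal-annotation regime the
method is designed for.  The same stack, model and features feed the other
evaluations (`two_step_cluster`, `cross_section_iou`,
`morphology_regression`, `rbf_retrieval`) and the `plicl` command-line tool
(`plicl phantom / sample-pairs / train / infer / cluster`).

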