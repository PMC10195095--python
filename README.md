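# myoconduct

Estimation of anisotropic **intracellular electrical conductivity tensors**
of myocardium from 3D labeled voxel reconstructions.

Cardiac conduction models (monodomain/bidomain) need the effective
conductivity of the intracellular (myocyte) domain along three
microstructural axes: along the myocyte long axis (longitudinal,
σ<sub>myo,l</sub>), across it within a laminar sheet (transverse,
σ<sub>myo,t</sub>), and normal to the interlaminar cleft planes (normal,
σ<sub>myo,n</sub>). Direct measurements are sparse, disagree by an order of
magnitude, and barely exist for diseased tissue such as the infarct border
zone. This package implements an image-based alternative: given a myocyte
instance segmentation, co-registered tissue-class masks, and a connexin43
(Cx43) immunofluorescence channel — at isotropic ~200 nm voxels, the scale
of confocal reconstructions — it builds a voxel conductivity model of the
intracellular space and intercellular coupling, solves the stationary
current problem under electrode boundary conditions, and reads off the
directional conductivities. It is aimed at cardiac modelers and
microscopists who want tissue-specific bidomain parameters and
microstructure–conductivity relationships.

## Method

1. **Gap-junction detection.** The Cx43 channel is thresholded at
   `mode + 4.5 SD` of the stack histogram. Myocytes are dilated (3×,
   26-neighborhood), isolated with a one-voxel separating membrane layer,
   and each thresholded Cx43 voxel within 1 µm of that layer is projected
   to its nearest membrane voxel. Membrane voxels that receive signal and
   are shared by ≥ 2 myocytes are *gap-junction-containing voxels*; each is
   attributed to one myocyte pair.
2. **Conductivity calibration.** The mean number of coupled voxels per
   myocyte pair in control tissue, N<sub>gj,control</sub>, is anchored to a
   measured whole-pair conductance of 1.24 µS:
   σ<sub>gj</sub> = 1.24 µS / N<sub>gj,control</sub> · l/A for voxel edge
   length l and face area A = l².
3. **Conductivity model and Poisson solve.** Myocyte voxels get the
   cytoplasmic conductivity σ<sub>cyto</sub> = 0.86 S/m, gap-junction
   voxels σ<sub>gj</sub>, everything else (extracellular space, vessels,
   fibroblasts, myofibroblasts, clefts, uncoupled membrane) 0. For each
   axis, ∇·σ∇φ = 0 is solved with +1 V / −1 V Dirichlet planes on the
   domain ends (flux-conservative 7-point scheme, harmonic-mean face
   conductances, conjugate gradients to a 1e-10 relative residual).
   Conducting voxels unreachable from the electrodes are excluded first.
4. **Directional conductivity.** σ<sub>dir</sub> = mean(J<sub>dir</sub>) /
   E<sub>dir</sub>, the cross-section-averaged axial current density over
   the applied field (E = 2 V / domain length); non-conducting area counts
   as zero current, so σ<sub>dir</sub> is a tissue-scale effective value.
5. **Tissue features and statistics.** Volume fractions
   (V<sub>myo</sub>, V<sub>vessels</sub>, V<sub>fibro</sub>,
   V<sub>myofibro</sub>, V<sub>e</sub> = 100% − their sum, V<sub>gj</sub>),
   fibrosis V<sub>fibrosis</sub> = (V<sub>e</sub> + V<sub>fibro</sub> +
   V<sub>myofibro</sub>) − control mean of the same sum, orientation QC
   (Δl ≤ 10°, Δn ≤ 30°), OLS feature–conductivity regressions with R²
   effect sizes, and pooled-variance t-tests between groups.

Because real confocal stacks are not bundled, the package ships a
synthetic **brick-myocyte tissue generator** with ground truth and a
closed-form conductivity oracle for periodic lattices; the solver is
validated against it to < 1e-10 S/m (see `docs/methods.md`).

## Worked example

```python
import numpy as np
from myoconduct import (
    GridSpec, generate_brick_tissue, threshold_cx43, build_boundary,
    project_cx43, calibrate_sigma_gj, build_model, estimate_tensor,
    volume_fractions, myocyte_orientation, cleft_normal, qc_exclude,
)
from myoconduct.synthetic_tissue import control_spec

# one control-like stack: 63 x 100 x 63 voxels at 1 um
grid = GridSpec((63, 100, 63), spacing=1e-6)
tissue = generate_brick_tissue(control_spec(grid, seed=5))

# gap-junction detection from the Cx43 channel
cx_mask = threshold_cx43(tissue.cx43)                      # mode + 4.5 SD
isolated, boundary = build_boundary(tissue.segments)       # one-voxel membrane layer
gj = project_cx43(cx_mask, boundary, isolated)             # shared-membrane voxels
cal = calibrate_sigma_gj(gj.pair_counts, grid)             # 1.24 uS per pair

# tissue features
feats = volume_fractions(tissue.segments, tissue.labels, gj)
feats.delta_l = myocyte_orientation(tissue.segments)
feats.delta_n, feats.no_cleft = cleft_normal(tissue.labels)
feats = qc_exclude(feats)

# conductivity tensor
model = build_model(isolated, gj, sigma_cyto=0.86, sigma_gj=cal.sigma_gj)
tensor = estimate_tensor(model, tol=1e-10)
```

This prints (via the obvious `print` lines):

```
Vmyo = 86.99%   Ve = 10.00%   Vgj = 0.0847%
delta_l = 0.11 deg   excluded = False
Ngj,control = 11.6   sigma_gj = 0.107 S/m
sigma_myo,l = 0.314 S/m
sigma_myo,t = 0.015 S/m
sigma_myo,n = 0.000 S/m
```

Reading: the synthetic stack is densely packed (V<sub>myo</sub> 87%), its
gap-junction voxel fraction (0.08%) is in the range seen in normal
myocardium, and the tensor shows the expected strong anisotropy —
longitudinal conduction through end-to-end junctions is ~20× the
transverse value, and the normal direction is fully blocked by an
interlaminar cleft plane (σ<sub>myo,n</sub> = 0), as observed in many real
stacks.

The same steps are available from a shell via the `myoconduct` CLI
(`synth`, `gj`, `features`, `solve`, `substacks`, `stats` subcommands).

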