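# Methods

## Model overview

The package estimates the effective electrical conductivity of the
intracellular domain of myocardium along the three microstructural axes
(x = normal to interlaminar cleft planes, y = myocyte long axis,
z = transverse within the laminar sheet). Input is a co-registered set of
3D volumes on one isotropic voxel grid: a myocyte instance segmentation, a
Cx43 fluorescence channel, and boolean masks for vessels, fibroblasts,
myofibroblasts, and clefts. Anisotropic grids are rejected at read time —
the gap-junction calibration and the discretization both assume a single
voxel edge length l and face area A = l².

Conduction is modeled as a stationary current problem on a
piecewise-constant scalar conductivity field σ(x): cytoplasm σ_cyto,
gap-junction voxels σ_gj, everything else 0. The intracellular space of
adjacent myocytes is connected *only* through gap-junction voxels in the
one-voxel membrane layer; there is no myocyte–non-myocyte coupling, no
time dependence, and no extracellular return path (the extracellular
domain is treated in its own right by extracellular-conductivity methods
and is out of scope here).

## Parameters

| parameter | default | units | rationale |
|---|---|---|---|
| σ_cyto | 0.86 | S/m | cytoplasmic conductivity of atrial myocytes from converging experimental methods. A value of 0.89 S/m also circulates for the same measurements; the default follows the lower figure and the parameter is exposed everywhere it is used. |
| pair conductance | 1.24e-6 | S | whole-cell measured conductance of a normal ventricular myocyte pair; anchor of the gap-junction calibration. |
| k_sd (Cx43 threshold) | 4.5 | — | threshold = histogram mode + 4.5 SD of the whole stack. Mode uses unit bins for integer data and 256 equal bins (bin center reported) for float data, ties toward the lowest bin. |
| max_dist (projection) | 1e-6 | m | Cx43 signal farther than 1 µm from the membrane layer is discarded. |
| Δl / Δn QC limits | 10 / 30 | degrees | stacks with weak microstructural alignment are excluded; strict inequalities. |
| solver tol | 1e-10 | — | relative residual ‖b − Ax‖/‖b‖ of the voxel-normalized linear system. |
| substack extent | 100e-6 | m | tiling extent in x and y; anchored at index 0, trailing voxels dropped. |

Gap-junction conductivity is σ_gj = pair_conductance / N_gj,control · l/A,
with N_gj,control the mean coupled-voxel count over *coupled* pairs
(count ≥ 1) pooled across control stacks. Whether uncoupled pairs belong
in that average is ambiguous; an `n_uncoupled_pairs` argument exposes the
alternative.

## Gap-junction localization

Membrane construction mirrors how shared sarcolemma is recovered from an
instance segmentation: three 26-neighborhood dilations grow each myocyte
(fronts of different myocytes freeze on contact, so no voxel is claimed
twice), then one parallel isolation pass clears any myocyte voxel whose
26-neighborhood holds a *smaller* foreign ID. The asymmetric rule is
deliberate: a symmetric "any foreign ID" rule clears both sides of a
touching interface and leaves a two-voxel gap in which no background voxel
is adjacent to two myocytes — the shared-membrane criterion for gap
junctions could then never fire exactly where two cells abut. The
asymmetric pass leaves the one-voxel separating layer by construction. Its
cost is that the receding side depends on the ID ordering; for tissue
whose myocytes are already separated (every watershed-style segmentation,
and the synthetic generator) the rule never fires asymmetrically and the
result is invariant under relabeling.

Projection assigns each thresholded Cx43 voxel within `max_dist` of the
membrane layer to its nearest membrane voxel (Euclidean distance; ties go
to the smallest linear voxel index, x fastest). A membrane voxel that
receives signal and is 26-adjacent to ≥ 2 myocytes becomes one
gap-junction voxel, attributed to the lexicographically smallest adjacent
ID pair.

## Discretization and solver

The PDE ∇·σ∇φ = 0 is discretized with the flux-conservative 7-point
finite-volume scheme; the face conductance between adjacent voxels is the
harmonic mean of their conductivities times A/l. Harmonic averaging is
exact for series compositions across axis-aligned interfaces, which is
what makes layered lattices solvable to closed form (below). Electrode
planes are Dirichlet values (+1 V low index, −1 V high index) imposed on
the ghost faces of the first and last voxel layer, giving those voxels a
conductance 2σA/l to the electrode; all other domain faces are zero-flux.
The applied field is E = 2 V / (n·l).

Before each solve, conducting voxels are partitioned by face-connected
(6-neighborhood) components. Components reachable from neither electrode
are excluded (set to σ = 0 and counted); components touching exactly one
electrode are assigned that electrode's potential directly — their exact
solution carries zero current — and only electrode-bridging components
enter the linear system. The system is symmetric positive definite and is
solved by conjugate gradients with an additive two-level preconditioner: a
Jacobi smoother plus a direct coarse solve over aggregates formed from
connected components of the strongly conducting voxels (σ ≥ 0.5·σ_max,
i.e. cytoplasm) and of the weak remainder (junction clusters), each sliced
into 4-voxel slabs along the field axis. The coarse space spans the slow
modes of junction-dominated conduction (near-constant potential per cell
stretch, jumps across discs); typical solves converge in ~60–200
iterations where plain Jacobi needs thousands.

The directional conductivity evaluates axial current density on voxel
faces: J = h·Δφ/l per face (h the harmonic face conductivity, 2σ at
electrode faces), averaged over the *full* cross-section of each of the
n+1 face planes (non-conducting faces contribute 0), then averaged over
planes and divided by E. For a converged solution the per-plane totals
agree to solver tolerance (charge conservation), which the tests assert
plane by plane. Potentials on non-conducting voxels are stored as NaN and
never enter any reduction.

## Synthetic tissue generator

The generator tiles the grid with axis-aligned brick myocytes (defaults
100 × 20 × 20 µm) separated by one-voxel extracellular walls, with
running-bond stagger between columns, an optional global longitudinal
phase, and optional per-column phase jitter (`phase_jitter`). Real
myocardium shows no long-range lateral registration of intercalated-disc
positions, so the tissue presets use fully independent column phases;
rigid lattices (jitter 0) are reserved for the analytic validation, where
exact periodicity is the point. Gap-junction voxels are sampled uniformly
without replacement from each realized junction face (end-to-end and
lateral), by default eroded one voxel in-plane so that every sampled voxel
is 26-adjacent to exactly the two intended myocytes — image-based
detection then recovers the generator's pair counts exactly, which the
tests assert. Cleft slabs normal to x snap to the nearest inter-myocyte
wall plane: a slab through the middle of one cell would be re-sealed by
the dilation step (same ID on both sides), which cannot happen to real
interlaminar clefts separating distinct cells. Vessel (elongated along y),
fibroblast, and myofibroblast blocks are carved at random non-overlapping
positions until target volume fractions are met within one percentage
point.

Presets: `control_spec` (junction counts sized to put V_gj near the
~0.07–0.1% seen in normal tissue, thin clefts every 50 µm, ~3% inclusions)
and `mi_spec` (junction counts scaled by 0.4, expanded clefts, ~7%
inclusions — lower V_myo and V_gj, higher fibrosis). The generator
emulates topology and composition, *not* realistic myocyte shapes,
membrane texture, the t-system, or imaging noise; passing tests therefore
validate the conductivity pipeline and feature definitions, not
segmentation of real images.

### Closed-form conductivity and its limits

For an unstaggered, unrotated, uncarved lattice whose grid tiles exactly
(field axis terminated by bricks on both electrodes), every conducting
column along the field axis is a series chain of cytoplasm spans and
one-voxel junction layers, in parallel across the cross-section.
`analytic_conductivity` evaluates that reduction. Two caveats are made
explicit in the API rather than glossed over:

* the reduction assumes equipotential cross-sections, so for junction
  patches smaller than the full brick-shadow face it *neglects the
  constriction resistance* where current funnels into the patch and is an
  upper bound. It is exact — to machine precision — when the patch covers
  the face, because each column is then literally one-dimensional. Partial
  patches are instead verified against an independent dense node-per-voxel
  Kirchhoff solve in the tests (agreement ~1e-14 S/m; the layered bound
  exceeds the dense value by a few percent on the small fixtures).
* junction layers of the *other* families lie parallel to the field; when
  such walls exist, their patches are extra conducting bridges outside the
  layered form, and the function raises rather than returning a wrong
  number. The validation therefore uses one lattice per junction family.

### Validation problem sizes

The analytic agreement run uses three full-shadow lattices of 15 × 31 × 15
voxel bricks: 63 × 127 × 63 (end junctions; all three directions
compared), 63 × 127 × 15 (lateral-x junctions; normal and longitudinal),
and 15 × 127 × 63 (lateral-z; longitudinal and transverse), at
σ_cyto = 0.86, σ_gj = 0.1 S/m. Observed worst-case
|numerical − analytic| is ~2e-13 S/m.

The stack-length study asks how far the longitudinal conductivity of a
short stack, whose borders truncate myocytes or are bridged by them,
strays from the value of a long stack. Design: 100 × 20 × 20 µm bricks at
1 µm voxels, stagger 0.5 with full phase jitter, 63 × 63 voxel
cross-section (3 × 3 myocyte columns), stack lengths 100/200/300/400 µm,
three random phases per length, preset clefts and inclusions, and
conductivity models from the same validation family as the lattices:
full-shadow junction faces at fixed σ_gj = 0.1 S/m built from the
generator's ground-truth junction map. Reported is the largest relative
deviation of any stack from the 400 µm mean; observed values are ~1–6%
across seeds.

The model family matters here, and the reason is itself a finding. With
image-calibrated sparse junction patches (V_gj-realistic counts run
through the 1.24 µS calibration), a single end-to-end disc carries roughly
60% of a 100 µm column's axial resistance. Whenever a stack border falls
exactly on a disc — a myocyte bridging the whole window, or a disc in the
border voxel layer — that column trades one disc for direct electrode
contact and the stack's σ_myo,l jumps by 15–20%. With ~100 µm myocytes and
100 µm windows such coincidences are common, so under sparse-patch
conditions the "short stacks within 10% of long stacks" property is not
robust; it becomes robust exactly when discs are electrically cheap, as
they are for full-face junction layers (~8% of column resistance).
Microstructure-calibrated conductivity models should therefore expect
genuinely heavier stack-to-stack variability at the 100 µm scale than
idealized-junction models suggest.

## Statistics

Feature–conductivity relationships use ordinary least squares with the
F-test against the intercept-only model; effect sizes are weak
(R² < 0.3), moderate (0.3 ≤ R² ≤ 0.5, boundaries inclusive), strong
(R² > 0.5). Control and infarct groups are reported separately when
significance (p < 0.05) holds in exactly one group but not pooled, or when
the groups' R² differ by more than 0.1. Group comparisons use the
two-sided pooled-variance Student t-test; values are reported as
mean ± sample SD. No multiple-testing correction is applied — reported
p-values are per test.

A simulated-null calibration test (y independent of x, n = 20, 1000
replicates) checks that the rejection rate at p < 0.05 stays within
Monte-Carlo error of the nominal level.

## Degenerate inputs and tie-breaks

* Constant Cx43 image: SD = 0, empty mask, warning.
* Fewer than 10 myocytes for orientation: all are used, warning.
* Degenerate moment tensors (spheres): numpy's deterministic `eigh`
  ordering; axes are sign-aligned to +y (first nonzero component decides
  when the y component is 0) before averaging as unit vectors.
* Empty cleft mask: Δn = 0 with a `no_cleft` flag.
* No conducting voxel touches an electrode: all components excluded,
  σ_dir = 0, warning.
* Zero-variance predictors and sub-minimal group sizes raise named errors
  rather than fitting.

## Known limitations

* The generator's packing is denser than real myocardium (V_myo ~85% vs
  ~64%); composition-sensitive absolute conductivities are accordingly
  higher than literature control values, while orderings and relationships
  are preserved.
* Rotated lattices support geometry only (for the orientation oracle);
  junction placement requires axis alignment.
* Myocyte–fibroblast/macrophage coupling, Cx43 plaque substructure, and
  extracellular conduction are out of scope.
* The closed-form oracle covers layered lattices only; staggered or
  carved geometries are validated against the dense Kirchhoff solve at
  small size and against internal invariants (conservation, maximum
  principle, monotonicity, scale invariance) at scale.
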