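# Methods

`spinefe` implements a complete quantitative-CT-to-finite-element pipeline for
the whole lumbar spine (L1–L5): phantom-calibrated densitometry, image-driven
heterogeneous material mapping, conforming tetrahedral meshing of vertebrae,
intervertebral discs and ligament cables, a linear C3D4 solver with
quasi-brittle element damage, and the two clinical load cases — axial
compression to failure (failure load, FL) and pure-moment range of motion
(ROM).  This note records the model, its assumptions, the numerical choices,
and what the synthetic data generator does and does not emulate.

## Densitometry

Trabecular HU is converted to bone mineral density through a two-point
phantom calibration measured in the same scan,

    BMD_MDCT = [HAb / (HUb − HUw)] · (HU − HUw),      HAb = 200, HAw = 0 mg/mL,

followed by the linear cross-calibration to standard QCT,

    BMD_QCT = 0.69 · BMD_MDCT − 11 mg/mL.

`HUb` and `HUw` are eroded-interior means of the bone- and water-equivalent
phantom inserts (erosion 1.5 mm, so partial-volume rims never bias the
calibration).  Each vertebra is sampled with an automatically placed
cylindrical ROI: mid-height, displaced anteriorly by 40 % of the anterior
half-depth, radius 40 % of the trabecular semi-axis, restricted to voxels more
than 2 mm inside the segmentation border.  The rule is algorithmic because a
reproducible pipeline cannot depend on manual ROI placement; the geometric
fractions mimic the clinical convention of sampling the anterior trabecular
compartment away from both endplates.  The subject score `BMD_QCT-L1-3` is
the arithmetic mean over L1–L3, and the cohort label is *healthy* at
≥ 80 mg/mL, *osteoporotic* below; the exactly-80 boundary (unclassified by
the clinical rule) is assigned to healthy with a logged warning so the
function is total and deterministic.  Descriptive statistics use the
population SD convention (divisor *n*), which is the convention under which
the reference healthy cohort reproduces 100.77 ± 9.25 mg/mL.

## Material model

Bone follows the densitometric power-law chain (HU clamped at 0 to guard
against partial-volume voxels):

    ρ_app = 47 + 1.122·HU  [kg/m³],     ρ_ash = 0.6·ρ_app,
    Ez = 4730·ρ_app^1.56  [MPa],        Ex = Ey = 0.333·Ez,
    Gxy = 0.121·Ez,  Gxz = Gyz = 0.157·Ez,  ν_xy = 0.381,  ν_xz = ν_yz = 0.104,
    σ_max = 137·ρ_ash^1.88 (ρ_ash < 0.317) | 114·ρ_ash^1.72 (above)  [MPa],
    ε_AB = −0.00315 + 0.0728·ρ_ash  (clamped ≥ 10⁻⁶),
    σ_min = 65.1·ρ_ash^1.93  [MPa].

Densities are stored in kg/m³ but every power law evaluates the density in
g/cm³ — that is the unit system in which the literature coefficients yield
megapascals; evaluating them with kg/m³ produces non-physical moduli.  The
transversely isotropic symmetry axis is the global spine axial direction for
all elements.  Because all moduli are fixed ratios of `Ez`, the compliance
matrix of every bone element is `1/Ez` times one constant matrix, which the
solver exploits.  Discs are linear elastic and isotropic (annulus E = 25 MPa,
nucleus E = 1 MPa, both ν = 0.49); poroelastic or hyperelastic disc behaviour
is out of scope.

Element HU is sampled by trilinear interpolation at the element centroid
(a volume-averaged 5-point variant is available via `hu_sampling="volume"`).
When the segmentation mask is available, sampling is *mask-guided*: voxels
outside the vertebral labels are replaced by their nearest bone voxel before
interpolation.  Without this, the 3 mm slice spacing mixes trabecular bone
with disc and soft-tissue HU at every endplate and maps a spuriously weak
layer there that then controls the failure load.

## Geometry and meshing

The synthetic anatomy is five elliptical vertebral bodies with a thin
cortical shell, four tapering discs whose nucleus outline is the outer
outline scaled by √0.30 (so the nucleus/disc area ratio is exactly 30 %), and
posterior-element landmark points that anchor the seven ligaments (ALL, PLL,
LF, ISL, SSL, ITL, FCL) with the tabulated constants (e.g. ALL: E =
55.77 MPa, A = 32.4 mm², 3 cables per segment; FCL: 6 per segment).  The
posterior elements are not meshed as solids: the load cases exercised here
need the attachment topology and moment arms, not cosmetic anatomy, so
ligament cables snap to the nearest vertebral surface node.  A consequence is
that the interspinous/supraspinous moment arms are shorter than anatomical,
which stiffens flexion less than a full posterior arch would.

The disc cross-section tapers linearly between the adjacent endplate
outlines (rather than inheriting a single endplate outline) so that the
extruded mesh is conforming at both interfaces; all tie constraints
(annulus–nucleus, disc–vertebra, ligament–vertebra) are realized by shared
nodes.

Meshing is a structured extrusion: one triangulated elliptical cross-section
(concentric rings, Delaunay-connected, with one ring snapped exactly onto the
nucleus outline) is swept axially and scaled to the local outline; each
triangular prism is split into three tetrahedra by cutting every quad face
through its smallest global node index, which makes neighbouring prisms
agree.  The ring count comes from the nominal anthropometry, so all subjects
of a cohort share one template and differ only in node positions.  Default
edge lengths are 3.0 mm (vertebrae) / 1.5 mm (discs); the finer 1.5/0.75 mm
setting used for mesh-independence work is available through the same API,
and `convergence_study` runs the descending-ladder sensitivity analysis with
a 5 % default tolerance on FL.

## FE solver and load cases

Standard linear-tetrahedron elasticity, assembled sparsely with a
precomputed scatter so that damage re-assembly is cheap, factorized with
SuperLU (symmetric-mode minimum-degree ordering).  The superior endplate is
rigidly coupled to a virtual master point (linear multipoint constraints,
small rotations); compression prescribes all six master dofs (axial push,
platen-like), ROM applies a pure moment about the motion axis with the master
otherwise free.  The inferior surface is fixed in all translations.
Ligaments are tension-only cables (EA/L along the chord), resolved by
fixed-point iteration on the active set; because the model is linear and the
loading proportional, cable strain signs are invariant along the load path,
so the active set found at the peak moment holds on the whole ramp and the
moment–angle curve is exactly linear through the origin.

**Failure load.**  A displacement ramp (default 4 % of model height over 40
steps — 2 % did not always bracket the peak because axial compliance is
dominated by the soft discs) is applied; at each step elements whose maximum
principal stress exceeds σ_max or whose minimum principal stress exceeds
σ_min in magnitude lose their stiffness (knock-down factor 0.01), and the
step iterates until no new element fails.  For a fixed damage state the
solution scales linearly with the imposed displacement, so the driver only
refactorizes when the damage state or cable set changes.  FL is the peak of
the recorded load–displacement curve, and the ramp terminates at the first
structural collapse (force below 70 % of the running peak): with a
quasi-brittle knock-down under displacement control, continuing the ramp
merely crushes the already-failed section and, through the compliant discs,
produces spurious secondary peaks.  `stop_fraction=0` restores the
unconditional ramp.  ε_AB is retained on the material card for the post-yield
modulus option but does not enter the default quasi-brittle model.

**ROM.**  Pure moments ramp to 7.5 N·m for flexion (+My), extension (−My),
lateral bending (Mx) and twisting (Mz); the reported angle is the master
rotation about the loading axis in degrees.  Damage is disabled (kinematics
only).

## Synthetic CT generator

The generator emulates a clinical-routine acquisition: 1 mm in-plane voxels,
3 mm axial slices, air background at −1000 HU, a paraspinal soft-tissue
envelope (40 HU, 5 mm) around the anatomy — a real abdominal scan never has
bone bordering air — and a two-insert calibration phantom (bone-equivalent
400 HU ↦ 200 mg/mL, water-equivalent 0 HU ↦ 0 mg/mL) lying beneath the
subject.  The trabecular mean HU is obtained by *inverting* the densitometry
chain for the requested `BMD_QCT-L1-3` target through the same phantom that
is placed in the volume, so noiseless synthesis followed by densitometry is
an identity to better than 1 mg/mL.  Gaussian HU noise (default SD 30 HU,
seeded) is added to trabecular and insert voxels; the cortical shell is a
homogeneous 1200 HU ring.  Not emulated: scanner blur/PSF, beam hardening,
contrast-agent enhancement gradients, micro-architecture, cortical thickness
variation, posterior-element bone.  Passing tests therefore demonstrate the
correctness and internal consistency of the pipeline on idealized anatomy,
not segmentation robustness or accuracy on real patient scans.

## Study conditions and calibration

The reference cohort fixes the densitometric targets to the twelve
subject-level QCT scores of the cohort the package models (six healthy:
108.04 … 95.54; six osteoporotic: 67.67 … 62.69 mg/mL), with geometry seeds
1–6 shared between cohorts so bone density is the only systematic difference.
The anthropometric defaults are *desk-scale* — chosen once so that the
healthy-cohort failure loads at the coarse 3.0/1.5 mm mesh fall inside the
experimental plausibility band for whole-lumbar compressive failure
(967–4387 N) — and then frozen: body semi-axes 13.9 (AP) × 17.8 (ML) mm,
body height 18 mm, disc height 6 mm, shell 0.4 mm, 2 % caudal growth per
level, 3 % seeded jitter.  At these conditions a twelve-subject cohort
simulates in a few minutes on one CPU; the mesh-converged 1.5/0.75 mm
configuration is available but is cluster-scale work.

Known limitations: the 0.4 mm shell is thinner than the 1 mm in-plane voxel,
so cortical load-bearing is only partially resolved; failure is quasi-brittle
rather than elastoplastic, making the post-peak branch non-physical (hence
the first-collapse convention); linear kinematics overestimates nothing at
small angles but ROM angles beyond ~15° stretch the small-rotation
assumption; facet articulation is represented only by the facet capsular
cables, so twisting stiffness is on the compliant side.

## Statistics

Cohort comparisons use the exact Mann–Whitney U test: all C(n₁+n₂, n₁)
labelings of the pooled mid-ranks are enumerated (n ≤ 8 per group), and the
two-sided p counts labelings at least as extreme on either tail; this is
invariant under monotone transformations and, at n = 6 + 6 with complete
separation, gives p = 2/924 ≈ 0.0022.  Spearman ρ uses average ranks; its
p-value is exact (all permutations) for n ≤ 7, a seeded Monte Carlo
permutation test (20 000 draws, add-one corrected) for 8 ≤ n ≤ 12, and the
t-approximation above.  Pearson r (and R²) is reported alongside Spearman
for the FL–BMD association.  The comparison table marks significance at
p < 0.01.
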