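# Methods

## Problem

An intraluminal self-expanding spring applies a sustained axial force to
a plicated segment of small intestine (distraction enterogenesis). The
quantity the package predicts is the axial force `F` required to double
the length of the distracted segment *elastically* — i.e. the force the
expanded spring must deliver — as a function of the patient's lumen
radius `R` and wall thickness `t`, together with the Hooke's-law spring
constant `k = F / Δx` for a chosen working displacement `Δx`.

Doubling is interpreted as an end-to-end axial stretch `λ_z = 2` of the
distracted segment. Only the elastic response is modelled: the growth
tensor in the multiplicative decomposition `F = F* · G` is kept at
`G = I` (tissue proliferation under sustained load is a separate,
slower process and out of scope), and viscous effects are neglected
(pseudo-elastic tissue).

## Constitutive model

Each wall layer is a compressible neo-Hookean solid:

    W(F) = C (Ī₁ − 3) + (1/D) [ (J² − 1)/2 − ln J ],
    Ī₁ = J^(−2/3) tr(FᵀF),  J = det F,

with the Cauchy stress obtained by pushing forward `∂W/∂E`:

    σ = (2C/J) dev(B̄) + (1/D)(J − 1/J) I,   B̄ = J^(−2/3) F Fᵀ.

`C` is half the shear modulus and `D` twice the inverse bulk modulus,
so small-strain elasticity gives `C = E/(4(1+ν))` and `D = 6(1−2ν)/E`.
All layers share `ν = 0.49` (nearly incompressible soft tissue);
`ν = 0.5` yields `D = 0`, the exactly incompressible limit, in which the
volumetric term is dropped and `J = 1` is required. The closed-form
stress is cross-checked in the test suite against a central
finite-difference of `W` with respect to the Lagrangian strain — an
oracle that shares no code path with the closed form.

## Layer moduli

Uniaxial tensile tests provide three porcine means (intact wall
1.56 MPa; submucosa + muscularis, mucosa scraped off, 1.01 MPa; isolated
submucosa 1.35 MPa) and one human mean (intact, 2.63 MPa; paediatric
donors). Per-layer moduli are obtained from the porcine triple by a
thickness-weighted **parallel (iso-strain) rule of mixtures** — in the
device configuration the layers are bonded and stretch together axially,
which makes iso-strain the physically consistent mixing rule:

    E_sm+mp = (f_sm E_sm + f_mp E_mp) / (f_sm + f_mp)
    E_intact = f_mu E_mu + f_sm E_sm + f_mp E_mp

with `(f_mu, f_sm, f_mp) = (0.75, 0.05, 0.20)` (histology-derived
thickness fractions). Solving gives `E_mp = 0.925`, `E_mu = 1.7433` MPa.
Human layers are these values scaled by `2.63/1.56 ≈ 1.686`, so the
scaled composite reproduces the human intact modulus exactly. The
mesentery has no measurement of its own and defaults to the submucosa's
constants (configurable).

Note an internal tension in the source data that the package inherits:
the calibration necessarily makes the (inner) mucosa the stiffest layer,
so the axial Cauchy stress *decreases* from inner to outer wall across
layer interfaces in any model built from these moduli (see
"Known limitations").

## Tensile characterization

Records are trimmed before fitting: leading samples with force at or
below the 2 N preload are removed, and if the record contains a
post-peak drop exceeding 5 % of the peak force, everything from the
global peak onward is removed (failure). The Young's modulus uses the
least-squares slope of the best linear window — every contiguous window
of at least 40 % of the trimmed samples is scored by R² (prefix-sum
evaluation), ties resolved toward the longer window. This window rule is
deterministic and robust to residual toe curvature. Strain is
engineering strain (displacement / gauge length); gauge dimensions are
required inputs since they are specimen-specific. Group summaries report
both specimen-pooled and per-subject means (subjects contribute unequal
specimen counts), with sample standard deviations.

## Semi-analytic layered solver (the oracle)

Treating each layer as a laterally traction-free bar sharing the axial
stretch (`F = diag(λ_r, λ_r, λ_z)`, `σ_lateral = 0` solved by a
bracketed Brent iteration on λ_r ∈ (0.3, 1.5)), the doubling force is

    F = Σ_layers P_zz(λ_z = 2) × A_layer,

where `P_zz = J σ_zz / λ_z` is the nominal (first Piola) axial stress
and `A_layer` the undeformed annular area. Radial interlayer pressure is
neglected; at ν = 0.49 with a common ν across layers the lateral
contractions nearly coincide, and the FEM (which resolves the coupling)
agrees with this reduction to ~1 % at its default mesh. In the
incompressible limit the solver reduces to the closed form
`P_zz = 2C(λ − λ⁻²)`, which the tests use as the convergence target.

## Finite-element model

* **Geometry/mesh.** Structured 8-node hexahedra on the three-layer
  cylinder. Axial symmetry of the two-ended loading is exploited: the
  mesh covers half the segment, with the symmetry plane (`u_z = 0`) at
  the true mid-length and the prescribed displacement at the loaded end.
  Default segment length 1.5 cm (the ink-marked distracted segment);
  for a homogeneous response the force is length-independent, so this
  choice mainly sets mesh proportions.
* **Mesentery.** Optional rectangular sheet hanging radially off the
  outer-wall generatrix at θ = 270°, spanning the segment length; top
  edge tied node-to-node to the wall, base edge fully fixed (the
  mesenteric root barely moves in vivo). Defaults — height equal to the
  lumen radius, thickness 0.5 mm, submucosa material — are assumptions,
  configurable and recorded in output metadata.
* **Boundary conditions.** The spring's contact with the mucosa
  prevents twist: inner-surface nodes are rotated to a cylindrical
  basis and `u_θ = 0` is imposed exactly (radial and axial motion stay
  free). Toggleable; without it (and without a mesentery) three
  tangential single-node pins suppress the in-plane rigid modes.
* **Element technology.** Total-Lagrangian formulation. The volumetric
  energy is evaluated at the element-mean dilatation `J̄` (mean-dilatation
  / B-bar split) while the isochoric term uses full 2×2×2 Gauss
  quadrature — this avoids the volumetric locking of trilinear hexes at
  ν = 0.49 (verified: the ν = 0.45 → 0.49 force change is ~5 %, not the
  orders-of-magnitude stiffening of a locking element). The internal
  force is the exact analytic gradient of this energy (checked against a
  complex-step energy gradient); element tangents are complex-step
  derivatives of the internal force, consistent to machine precision.
* **Solution.** Constraints (fixes, prescribed displacements, nodal
  basis rotations, ties) are eliminated exactly through a sparse
  transformation `u = T q + λ g`. Load is applied in increments with
  full Newton (sparse LU), automatic step halving (≤ 4 consecutive) with
  regrowth after easy increments, backtracking on transient element
  inversion, and a homogeneous-extension-plus-isochoric-contraction
  predictor that typically leaves only a handful of Newton iterations
  per increment.
* **Verification.** Patch test on a distorted brick mesh passes to
  1e-10; tangent–residual directional finite-difference agreement to
  1e-5; free-cylinder reaction at λ_z = 2 within 3 % of the
  semi-analytic oracle across the modelled (t, R) ranges; uniform mesh
  halving from the default resolution (1 element per layer radially,
  24 circumferential, 10 axial on the half model) changes the reaction
  by ~0.9 % (< 1 %). The dominant discretization error is circumferential
  faceting, O(Δθ²).

## Force map and spring design

The default sweep covers wall thickness 0.5–3 mm (6 points) × lumen
radius 0.25–3 cm (12 points); the exact grid spacing is a package
choice. Entries are solved semi-analytically by default (the FEM is
available per entry); failures are recorded per entry rather than
dropped. Force increases strictly in both t and R, and per-axis ordinary
least squares yields R² ≥ 0.98 throughout — F is exactly linear in R at
fixed t (annulus area = π(2Rt + t²)) and affine-plus-small-quadratic in
t at fixed R. The reported force is the total axial reaction transmitted
through the segment (the force the spring must deliver; the two ends
carry equal and opposite reactions). Spring constants default to a 60 mm
working displacement (a 7.5 cm relaxed spring compressed into the 1.5 cm
segment) but the displacement is an explicit argument.

## Synthetic data

No public intestinal tensile or geometry dataset exists, so the
generators emulate the measurement conditions the analysis assumes:

* **Tensile curves** — exponential-approach toe rising exactly to the
  2 N preload at the toe strain (default 0.05), a linear region of slope
  `E·A/L0` up to the failure strain (default 0.5), then a linear force
  drop to zero over 5 % additional strain; additive i.i.d. Gaussian
  force noise (simplest load-cell model); seeded and bit-reproducible.
  The toe shape and drop-off width are conventions — only their
  existence matters, since they exercise the trimming logic.
* **Geometry cohorts** — default 61 subjects, ages 2 months–69 years
  (log-uniform), wall thickness 1–4 mm and lumen radius 1–2 cm following
  linear-in-log-age trends (growth slows with age but does not reverse)
  plus clipped Gaussian noise; flattened width `d = πR`. Per-subject
  scatter is configurable, not calibrated — no scatter statistics exist
  to calibrate against.

What passing tests show: the analysis recovers known moduli from curves
with the assumed morphology and noise model, and the mechanical chain is
internally consistent. What they do not show: robustness to real-world
artefacts absent from the generator (grip slip, preconditioning drift,
rate effects, digitization error), or validity of the neo-Hookean form
itself for a given specimen.

## Numerical choices

* Uniaxial lateral-stretch root: Brent on (0.3, 1.5), residual lateral
  stress below 1e-10 MPa.
* Newton: relative residual 1e-9 (absolute floor 1e-9 N), ≤ 30
  iterations, ≤ 4 consecutive halvings; complex-step size 1e-30.
* Linear-window fit: window ≥ max(5, 40 % of samples); R² rounded to
  1e-10 before the argmax so numerically tied windows resolve to the
  longest.
* Sliver avoidance: wall fractions must sum to 1 within 1e-9; layer
  partitions conserve total thickness exactly (last layer takes the
  rounding residue).
* Units: mm, N, MPa internally; radii and segment lengths accepted in
  cm (the clinical convention) at the interfaces.
* Problem sizes: verification sweeps run at 16 circumferential × 4
  axial elements (1 per layer radially) and the refinement check at the
  default-to-doubled pair; the profile model uses 1 radial
  element per layer × 16 circumferential × 6 axial with the mesentery. These sizes sit on the flat part
  of the convergence curve established by the halving check.

## Known limitations

* The calibrated layer moduli make the mucosa the stiffest layer, so
  through-thickness axial/hoop stress *decreases* inner→outer across
  layer interfaces under the doubling stretch; at mid-length the strain
  state is nearly homogeneous (the thin default mesentery perturbs it by
  well under 1 %). Reports of the opposite through-thickness stress
  gradient in this configuration cannot be reproduced from these moduli.
* Forces from the tissue moduli at λ_z = 2 are in the
  10²-N range for centimetre-scale segments — two orders of magnitude
  above the ~0.2–11 N loads that nitinol springs of this size deliver.
  Within this model that simply means a spring delivering ~10 N cannot
  come close to doubling the segment elastically; elastic doubling as a
  design target and the printed spring forces are mutually consistent
  only if most of the observed lengthening is growth (G ≠ I), which is
  out of scope here.
* No anisotropy (muscle fiber directions), no viscoelasticity, no
  contact between spring coils and tissue, no intestinal curvature.
* The mesentery's geometry and material are unmeasured assumptions.
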