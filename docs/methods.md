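# Methods

`beltsas` models small-angle X-ray scattering (SAXS) from
membrane-protein–detergent complexes with an explicit Monte-Carlo
detergent corona, analyses lamellar diffraction of membrane stacks,
and performs SEC-MALS protein-conjugate arithmetic. This note records
the model, its assumptions, the defaults and the numerical choices.

## The corona model

A detergent-solubilised membrane protein is treated as a rigid atomic
model wearing a torus-like belt of detergent around its hydrophobic
circumference. The frame convention is fixed throughout: the
transmembrane axis is z and the hydrophobic midplane is z = 0
(`orient_membrane_frame` puts the principal axis of a user-supplied
transmembrane residue selection along z and its centroid at the
origin).

The belt is built geometrically, not atomistically:

1. **Excluded volume.** Atoms occupy grid cells within their van der
   Waals radius (C 1.70, N 1.55, O 1.52, S 1.80 Å) on a cubic grid,
   default spacing 2.0 Å. The volume estimate is occupied-cell count ×
   spacing³; it converges within ~2 % under grid refinement for
   smooth solids.
2. **Midplane curve.** The boundary cells of the z = 0 occupancy layer,
   ordered by polar angle about the layer centroid (ties broken by
   radius), form a closed loop around the protein circumference. For a
   two-fold symmetric dimer the loop is computed once around the
   combined excluded volume, because the belt wraps the whole complex.
3. **Point selection.** Points drawn uniformly in a box enclosing the
   complex (density is a free parameter; the planted benchmarks use
   0.04–0.27 points/Å³ depending on box size) are classified by an
   anisotropic distance to the curve: offsets are scaled by 1/R_xy in
   the membrane plane and 1/R_z along the normal, so the hydrocarbon
   core is an elliptical tube of half-axes (R_xy, R_z) around the
   curve. Headgroup-shell points lie between that tube and the
   enlarged tube (R_xy + D_xy, R_z + D_z). Both classes exclude points
   within 3.0 Å of any protein atom.
4. **Head–tail connectivity.** A shell point must lie within the
   anisotropic shell thickness (D_xy, D_z) of the hydrocarbon core.
   This is checked against the sampled tail points *and* against the
   continuum core surface along the ray to the nearest curve point.
   The second check matters: with discrete tail samples alone, the
   outer ~1 interpoint spacing of the shell is systematically thinned
   (a ~6 % head-volume deficit at 0.17 points/Å³), which measurably
   shifts the core–shell form-factor minimum. The ray distance is
   exact for spherical micelles and an upper bound in general, so it
   only ever *adds* heads that the continuum rule would accept.
5. **Composition bookkeeping.** The hydrocarbon core is assumed
   water-free, so V_tail = (tail-point count)/(box density) and the
   number of detergent molecules is N_DM = ⌊V_tail / 294 Å³⌋ (the
   volume of one decyl chain). Rounding down is a choice; at the point
   counts used the ±1 ambiguity is far below the Monte-Carlo counting
   noise.
6. **Contrasts.** Per DM molecule, the tail carries 81 e in 294 Å³ and
   the dry maltoside head 181 e in 350 Å³; in buffer of 0.340 e/Å³
   the per-molecule excesses are −18.96 e (core) and +62.0 e (shell).
   The totals N_DM × excess are spread uniformly over the points of
   each class. The shell's geometric volume may exceed N_DM × 350 Å³;
   the surplus is implicitly hydration water and carries no net
   scattering because only the fixed total excess is distributed.
   Curvature "dilution" of the headgroup shell is not modelled; shell
   thickness anisotropy (D_xy ≠ D_z) absorbs that effect instead.
7. **Protein and hydration.** Protein atoms scatter with
   b = Z − ρ_buffer × V_displaced using Fraser-style displaced volumes
   (C 16.44, N 2.49, O 9.13, S 19.86 Å³). Hydrogens present in a file
   are folded into their bonded heavy atom; no implicit hydrogens are
   added to heavy-atom-only models, keeping the bookkeeping uniform
   across predicted structures. A hydration layer of box points
   between 3.0 and 6.0 Å from the nearest atom (outside the corona)
   carries +0.03 e/Å³ by default; both numbers are configurable.

The shell thicknesses are restricted to D < 10 Å — a physically
reasonable bound for a maltoside headgroup layer — and the proposal
validator additionally keeps the belt inside the Monte-Carlo box.

## Forward scattering

Intensities are Debye sums I(q) = Σᵢⱼ bᵢbⱼ sinc(q·rᵢⱼ), evaluated
exactly for small bodies and through a weighted pair-distance
histogram (bin width 0.5 Å by default, 0.2 Å in fidelity tests) for
large ones; a numba kernel streams the pair loop. Before the sum the
point cloud is coarsened on a cubic grid (default cell 3.0 Å,
benchmark runs 4–5 Å): each cell contributes one scatterer with the
cell's total b at the b-weighted centre. Cells where positive and
negative b nearly cancel fall back to the plain mean — the weighted
"centroid" of mixed-sign weights is unbounded and a single such cell
can corrupt the whole curve. Coarsening both the simulated data and
the fitted model at the same cell size makes the residual smearing
cancel in parameter recovery.

Model-to-data comparison is a reduced χ² with an analytically fitted
scale factor (optionally also a constant background; both modes are
available because published fits rarely state which was used), with
points below a configurable q_min (default 0.02 Å⁻¹) excluded — the
standard guard against low-q aggregation upturns. Curve statistics
follow the usual conventions: self-consistent Guinier window
q·Rg < 1.3; Porod volume 2π²I(0)/Q̃ with a constant background from a
Porod-law fit to the top third of the q range and Guinier
extrapolation of the invariant to q = 0; b-weighted pair-distance
histogram for p(r) and Dmax. Internal q is Å⁻¹; curves whose maximum
q exceeds 2 are assumed to be nm⁻¹ on read.

## Refinement

The dimer is P2-symmetric: the mate protomer is generated by a 180°
rotation about z and never carries its own parameters. The objective
is χ²ᵣ plus two penalties: a steric term w·Σ(3.0 − d)² over
inter-protomer (and inter-body) atom pairs closer than 3.0 Å, and
harmonic junction restraints k·Σ(d_CαCα − 3.8 Å)² between consecutive
rigid bodies of a partition. Default weights w = k = 10 per Å², large
enough that a 1 Å violation outweighs typical χ² differences.

Optimisation is a keep-best random search: every proposal perturbs
all active parameters with Gaussian steps (4 Å radii/offsets, 2 Å
shell thicknesses, 5° body rotations, 2 Å body translations), accepts
only improvements, and shrinks all steps geometrically per stage.
Degenerate proposals (non-positive radii, D ≥ 10 Å, belt outside the
box) are re-drawn without being evaluated. The corona is rebuilt at
every evaluation from one fixed box point set, so the objective is a
deterministic function of the parameters and Monte-Carlo noise cannot
alias the search. Runs with the same seed are bit-identical and the
kept-best trace is non-increasing by construction.

## Lamellar analysis

Bragg peaks are detected on the background-relative residual
(I − bg)/bg of a power-law-plus-constant background (exponent scanned
on a grid, amplitudes by weighted least squares, peak regions masked
iteratively). Relative residuals keep detection uniform when the
noise scales with the signal. The default prominence threshold is 8 ×
the robust σ of the relative baseline — planted Bragg peaks sit two
orders of magnitude above it — with a minimum width of 2 samples and
a minimum separation of 8 samples so noise cannot split one
reflection in two. Peak centres are refined by a local quadratic fit
(±6 samples), which localises well below one grid spacing at
signal-to-noise ≥ 10. Orders are assigned from the smallest-s peak
with a 2.5 % harmonic tolerance; repeat distances are d = 2π/s, in
the inverse unit of s, printed at 0.01 nm.

## Conjugate analysis

Two-component conjugate arithmetic is exact closed-form:
MW_modifier = MW_total − MW_protein, weight fraction
MW_modifier/MW_total, bound monomers = round(MW_modifier/monomer
mass), mixture dn/dc = w_p·0.1850 + (1 − w_p)·0.1473 ml/g. The
synthetic three-detector model (LS ∝ c·MW·(dn/dc)², RI ∝ c·dn/dc,
UV ∝ c·w_p·ε with unit instrument constants) is exactly invertible
when noiseless; inversion refuses a zero UV signal or signals
implying negative masses. Dividing 42.4 kDa of DM by 482.6 g/mol
gives 87.9 → 88 monomers under nearest-integer rounding; counts one
lower arise only under truncation, which we do not use.

## Synthetic data and what passing tests show

Every generator is a pure function of its parameters and seed and
ships a planted-truth sidecar sufficient to regenerate the dataset
bit-identically. Noise is multiplicative Gaussian (σ = fraction × I),
the conventional SAS error model, with a Poisson option for
diffraction counts. Default grids: SAXS 0.005–0.5 Å⁻¹ (200
log-spaced points), diffraction 0.1–2.5 nm⁻¹ (1000 linear points).

The toy protein is an ideal poly-Ala helix bundle (backbone N, CA, C,
O; 1.5 Å rise, 100°/residue, consecutive Cα at 3.8 ± 0.05 Å) along z.
It emulates the size and topology of a tetraspan membrane protein but
none of a real structure's side chains, loops or sequence-dependent
contrast, so passing recovery tests demonstrates the estimator's
behaviour under the stated model, not performance on experimental
data — experimental fits additionally contend with structure-model
error, smearing and inter-particle effects.

The planted-complex benchmark (`beltsas.benchmark`) decorates a
104-residue 4-helix bundle dimer (protomer offset 12 Å from the
two-fold axis) with a belt of R_xy = 28, R_z = 10, D_xy = 6,
D_z = 5 Å (~280 DM molecules), simulates 1 %-noise curves on
q = 0.01–0.35 Å⁻¹, and refits from a start 15–20 % away (shell
thicknesses start at 5 Å, the midpoint of the physical range). The
box discretisation (50k points, fixed seed) is shared between
simulation and fit so that recovery error isolates measurement noise
and the search; per-seed data noise and search streams differ. Each
fit runs up to three independent searches of 600 evaluations
(6 stages, decay 0.55), stopping early once χ²ᵣ ≤ 1.4. Across ten
seeds the median relative error of the four rim parameters is ≤ 3 %
and the median |N_DM error| ≤ 5 of ~280.

## Numerical choices and degenerate inputs

* Pair-histogram bins introduce phase errors O((qΔr)²); at the default
  widths they are below 0.5 % over the fitted q ranges.
* The Debye sum of a point cloud has an intrinsic sampling floor:
  near deep form-factor minima the relative deviation from the
  continuum form factor diverges (the analytic value crosses zero).
  Fidelity checks therefore compare away from the zero (homogeneous
  sphere) or above 1 % of the maximum (core–shell); quasi-random
  (Sobol) clouds push the error elsewhere below 0.5 %.
* `select_rim` with an empty curve, zero-radius tubes, or a box too
  sparse to populate the belt raises or returns empty sets rather
  than guessing.
* Selection is bit-identical between the NumPy path (small inputs)
  and the numba kernel (large inputs): same operation order, no
  fastmath.
* The midplane curve requires occupied cells on both sides of z = 0;
  models not crossing the midplane are rejected ("no midplane").

## Known limitations

* No spherical-harmonic acceleration (CRYSOL-style), no resolution
  smearing, no SANS contrast variation, no ab initio bead modelling.
* Rigid-body refinement moves bodies of one protomer; the P2 mate is
  always the rotated copy. Flexibility/ensembles are out of scope.
* The corona has uniform contrast per class; headgroup hydration
  gradients and curvature dilution are not modelled.
* Peak detection assumes a smooth monotone background plus isolated
  reflections; overlapping reflections from coexisting phases are
  assigned to whichever harmonic series starts at the smallest s.
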