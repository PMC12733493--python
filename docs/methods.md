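# Methods

## Scope and model

rismhydra computes the equilibrium solvation structure of a rigid,
fully parameterized solute in an infinite-dilution aqueous bath at ambient
conditions (298.15 K, 0.997 g/cm³, i.e. 0.03332 water molecules/Å³), and
derives hydration observables from it. The solute is fixed; solute
flexibility, solvation free energies, electrolytes and temperature scans
are out of scope.

Two coupled stages:

1. **Bulk solvent (1D XRISM).** The neat-water site–site correlations are
   solved on a radial grid from the XRISM equation
   H(k) = [I − W(k)C(k)ρ]⁻¹ W(k)C(k)W(k) with a KH or HNC closure. All
   three sites of the rigid water are carried explicitly (a 3×3 problem);
   the intramolecular correlation is ω_αγ(k) = sinc(k·l_αγ) with the k→0
   limit taken analytically. The output is the susceptibility
   χ_αβ(k) = ω_αβ(k) + ρ h_αβ(k), the solvent-side input of the 3D stage.
   Plain XRISM is used — no dielectric-consistency correction — so the
   model's bulk dielectric constant is not imposed; this matters for
   quantitative dielectric response but not for the short-range structure
   the analysis consumes.

2. **3D solver.** On a Cartesian box around the solute, the 3D-RISM OZ
   equation h_β(k) = Σ_α c_α(k)χ_αβ(k) is iterated against the KH closure.
   The two equivalent hydrogens are collapsed into one unknown field via a
   reduced kernel (the sum of χ over equivalent members), so water is a
   two-field problem.

## Water model

The catalogue ships `spce` (standard SPC/E: q_O = −0.8476 e,
σ_O = 3.166 Å, ε_O = 0.1553 kcal/mol, bare hydrogens, l_OH = 1.0 Å,
109.47°) and `mspce`, the modified SPC/E conventionally used with
integral-equation theories: small hydrogen Lennard-Jones terms
(σ_H = 1.1657 Å, ε_H = 0.01553 kcal/mol, the values distributed with
standard RISM toolchains) regularize the site equations, which are
singular for a bare Coulomb hydrogen. `mspce` is the default everywhere.

## Numerics

* **Radial transforms** use the type-I discrete sine transform on the
  abscissae r_j = j·dr, k_n = n·π/((N+1)dr), making forward and inverse
  transforms exact inverses on the grid. Default radial grid 2¹³ points at
  dr = 0.01 Å (k_max ≈ 314 Å⁻¹, ample for any 3D box here); the test suite
  uses 2048 × 0.02 Å, which leaves the water structure unchanged at the
  resolution tested (first-peak position stable under dr halving).
* **Long-range electrostatics** are Ng-split, u = u_s + u_l with
  u_l = q q' erf(ηr)/r. The short range (erfc) is tabulated with the LJ
  term; the long range lives analytically in reciprocal space
  (4π e^(−k²/4η²)/k² times the charge structure factor). Iteration runs on
  the short-range part of c, so every transformed field is short-ranged.
  In 3D, η = max(0.25, 4/(L_min/2)) so the erfc tail is negligible at half
  the box. The k = 0 Coulomb mode is dropped: net-charged solutes are
  implicitly neutralized by a uniform background (the standard choice; it
  leaves short-range structure unaffected for adequately buffered boxes).
* **Closure and capping.** The reduced short-range potential is capped at
  +40 kT inside hard cores before exponentiation: e⁻⁴⁰ underflows
  gracefully and no inf−inf can arise. The KH branches meet at d = 0 with
  matching value and slope (tested).
* **Iteration.** Both stages share one MDIIS accelerator (residual-
  subspace extrapolation with a sum-to-one constraint): 20 vectors /
  damping 0.5 in 1D, 5 vectors / damping 0.7 in 3D, restart when the
  residual exceeds 10× the best seen. Residuals are max-norm changes of
  the iterated field; tolerances are 10⁻⁸ (1D, tighter so susceptibility
  error never dominates) and 10⁻⁶ (3D). The charged water state point is
  reached by a charge ramp (0 → 0.5 → 0.75 → 1), each rung warm-started;
  ambient `mspce` water converges in ≈ 170 iterations. `method="picard"`
  gives the plain damped reference iteration used in cross-checks.
* **Grids.** Boxes cover the solute extents plus a buffer (default 12 Å)
  with shapes rounded up to even 7-smooth integers for FFT efficiency;
  a configurable memory ceiling raises an explicit error with the byte
  count instead of thrashing. Default spacing 0.25 Å; the toy-scale runs
  in tests and the acceptance script use 0.5–0.6 Å, recorded in each run's
  provenance so coarse runs are never silent.

## Analysis definitions

* **Distance to the solute** is nearest-atom-centre distance by default
  (a vdW-surface variant, d minus the atom radius clamped at zero, is
  selectable); the choice is recorded per run. Centre-based distances make
  one-layer shell thicknesses come out around 0.3–0.5 nm.
* **Shell profile.** The cumulative count n(r_cut) = ρ Σ_{d≤r_cut} g·ΔV is
  binned at the grid spacing; n′ is the per-bin increment over the bin
  width, and the shell density divides n′ by ρ times the *measured* shell
  volume per unit thickness (bin voxel count × ΔV / bin width). Dividing
  by the measured rather than an idealized 4πr² volume cancels box-shape
  and topology artefacts, so the profile tends to exactly 1 in bulk for
  any solute shape. Optional 5-point smoothing is off by default.
* **Shell boundary** r_cut* is the first local minimum of the shell
  density after its first above-bulk peak, refined by a parabolic fit
  through the bracketing bins; a minimum that never dips below bulk is
  flagged as a weak shell, and featureless profiles raise a no-boundary
  error rather than returning a number.
* **H-bonded fraction.** Geometric criterion: water-hydrogen density
  integrated within 2.6 Å of solute N/O acceptors (solvent donates) plus
  water-oxygen density within 3.5 Å of solute donor heavy atoms (N/O with
  a covalent H within 1.25 Å), restricted to the first shell, divided by
  the shell population; ρ_Hw = 2ρ with the hydrogen count halved to count
  molecules. The radii are conventional H-bond geometry and configurable;
  the fraction is clamped to [0, 1] with a warning if the sphere integrals
  double-count.
* **Pockets** are Voronoi-style nearest-residue assignments of first-shell
  voxels: parameter-free and exactly partitioning, so counts over a full
  residue partition sum to the total hydration number to machine
  precision. The residue lists of serum albumin's Sudlow sites I and II
  ship as constants (`pockets: "sudlow"` in the pipeline config).
* **SASA** is Shrake–Rupley with a deterministic golden-spiral quadrature
  (960 points/atom by default; doubling changes totals by < 0.3% on the
  fixture suite), probe 1.4 Å, all atoms included, radii taken from the
  input (PQR radius column or parameter table).

## Synthetic fixtures: what they do and do not show

The generator supplies every test input without downloads: LJ spheres,
monovalent ions, a rigid water-as-solute, seeded random zero-net-charge
polyatomics, radial fields painted through the same distance transform the
analysis uses (so grid integrals have 1D quadrature oracles), and
two-Gaussian shell profiles with an enhanced first shell and a depleted
trough — the statistical structure the boundary criterion assumes. All
fixtures are byte-reproducible from (recipe, seed).

Passing on these fixtures validates the numerics (transform pairs,
convolution theorems, closure algebra, integration, partitioning) and the
solver's physics on spherically symmetric and small polyatomic solutes.
It does not validate protein-scale behaviour: a full protein run at 0.25 Å
(hours, tens of GB) exercises no new code paths but much larger condition
numbers, and crystal-structure preparation (protonation, disulfides,
missing atoms) is delegated to the user's PQR. The parameter-assignment
machinery is tested on toy tables; no force field ships with the package.

## Known limitations

* KH linearizes density enhancement, which underestimates sharp first-peak
  heights relative to HNC or simulation (neat-water g_OwOw first peak
  ≈ 2.35 here); this is the closure's known trade-off for unconditional
  convergence and non-negativity.
* No solvation free energies, pressure corrections or partial molar
  volumes; no solvent dynamics (residence times are not equilibrium
  observables of this theory).
* The hydrogen-bond count is a density-integral proxy with geometric
  radii, not an orientational criterion; its absolute value shifts with
  the chosen radii (documented defaults), while trends across solutes are
  stable.
* Net-charged solutes rely on the uniform-background convention; ionic
  activity effects and counterions are not modelled.
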