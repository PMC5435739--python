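# Methods

This note records the models implemented in `hygroelast`, their
assumptions, the parameter defaults and why they were chosen, what the
synthetic generators do and do not emulate, and the numerical choices
that matter when interpreting results.

## Scope and system model

All analyses operate on a single static configuration: atoms restricted
to C, H and O, an explicit covalent bond set, optional ring annotations,
and an orthorhombic periodic box.  Orthorhombic cells are a deliberate
restriction — every distance in the package is a minimum-image distance,
and the simple component-wise wrap is only valid for rectangular cells;
triclinic inputs are rejected at parse time rather than silently
mishandled.  There is no trajectory handling and no force field: the
package analyses geometry and topology, plus whatever energy function the
caller supplies for strain sweeps.

Atom roles are purely topological.  A water is an oxygen bonded to
exactly two hydrogens and nothing else; everything outside water is
polymer; a polymer oxygen bonded to one hydrogen and one carbon is a
hydroxyl oxygen.  Donors are oxygens carrying at least one hydrogen and
acceptors are *all* oxygens — adequate because the systems of interest
contain no nitrogen, and deliberately not generalized further.

File I/O: PDB (ATOM/HETATM + CONECT + CRYST1, via MDAnalysis) and
extended XYZ with the box on a `Lattice="..."` comment line.  PDB
coordinates round-trip at the format's three-decimal precision; extended
XYZ at ten decimals but without connectivity.  Bond perception, for
inputs without connectivity, bonds atoms within `scale` × (sum of
covalent radii C 0.76, H 0.31, O 0.66 Å); `scale` defaults to 1.2, the
usual tolerance between equilibrium bond lengths (O–H 0.96 Å vs cutoff
1.16 Å) and nonbonded contacts (> 1.4 Å in the generated systems).

## Hydrogen bonds

Detection is the standard two-criterion geometric test: the
hydrogen-to-acceptor minimum-image distance must not exceed `d_max`
(default 2.5 Å) and the donor–hydrogen–acceptor interior angle must be at
least `theta_min` (default 120°; 180° is linear).  Bifurcated bonds are
allowed — one hydrogen may satisfy the criteria with several acceptors
and each pairing counts separately — because no exclusion rule is part of
the criteria.  Pairs where the hydrogen is covalently bonded to the
acceptor are excluded; other intramolecular pairs (e.g. two hydroxyls of
one chain) are retained.

Each detected bond is scored with the 12-10 potential gated by the fourth
power of the angle cosine (see README).  Note the deliberate asymmetry,
which follows the two conventions' own definitions: the *detection*
cutoff applies to the H···A distance, while the *energy* is evaluated on
the donor–acceptor distance r_DA.  Both distances are stored on every
bond.  The well parameters D_hb = 4.0 kcal/mol and r_hb = 2.75 Å are
typical O–H···O literature values; they are plain overridable defaults,
and every reported energy scales linearly with D_hb.

Partitioning assigns each bond to water–water (ww), polymer–polymer (pp)
or polymer–water (pw, either donor orientation) from the role labels of
donor and acceptor.  The decomposition is exact by construction:
`all = pp + ww + pw` for both energies and counts, and the test suite
asserts it on every configuration class.

## Radial distribution functions

Single-frame estimator: g(r_k) = (pair count in shell k) / (n_A ρ_B
V_shell), with ρ_B = n_B/V_box, spherical shells of width `dr` (default
0.05 Å) and r_max capped at half the smallest box length, where
minimum-image distances stop being unambiguous.  Self-pairs are excluded
when selections overlap.  No trajectory averaging exists because inputs
are single snapshots; on one frame the estimator is exact bookkeeping
(the shell-count integral inverts the normalization identically, which
is how coordination numbers are computed) but statistically noisy, so
peak *heights* from a single configuration should be read qualitatively.
The estimator was cross-checked bin-for-bin against MDAnalysis InterRDF.

The water–hydroxyl convenience wrapper defaults to water hydrogens vs
hydroxyl oxygens, the pairing for which a first peak near 1.75 Å is an
H···O hydrogen-bond distance; both group selections are explicit
arguments because hydration RDFs are reported under several conventions.

## Free volume

Two independent routes to the van der Waals volume:

* **Group contributions (VABC)** from composition counts alone.  The
  six-term form with the explicit bond count is the canonical path
  (`vabc_eq8`); the bond count is validated against the per-molecule
  cyclomatic identity N_Bonds = N − 1 + N_AR + N_NAR, applied per
  connected component and summed for multi-molecule systems.  The
  collapsed bond-free form in circulation (`vabc_eq10`) is also provided
  verbatim, constant term applied once per molecule.  Its printed carbon
  coefficient (14.93 Å³) is *not* what exact elimination of the bond
  count yields (20.58 − 5.92 = 14.66 Å³); the discrepancy has no
  published derivation, so both forms are kept as printed and neither is
  "corrected".  `eq10_implied_coefficients()` exposes the exact
  substitution (in rational arithmetic) for comparison: O 8.79, H 1.32,
  aromatic −20.62, nonaromatic −9.72, constant +5.92 all match the
  printed collapsed form; only carbon differs.
* **Voxel geometry**: the union of hard spheres at van der Waals radii
  (C 1.7, H 1.2, O 1.55 Å) integrated on a grid, spheres wrapping across
  the periodic faces.  Probe radius 0 gives the van der Waals volume —
  with these radii a single carbon sphere is 20.58 Å³ and a hydrogen
  sphere 7.24 Å³, exactly the VABC atomic contributions, a coincidence
  the test suite pins.  (The oxygen contribution 14.71 Å³ is *not* the
  bare sphere volume 15.60 Å³ at r_O = 1.55 Å; no adjustment is made.)
  A positive probe yields a solvent-excluded volume morphologically:
  grow each sphere by the probe, take the largest periodic connected
  component of the complement as the probe-accessible exterior (smaller
  cavities count as excluded volume), and keep every voxel farther than
  the probe radius from it (a periodic Euclidean distance transform).

Default grid spacing is 0.2 Å; tests needing ~1 % accuracy use 0.1 Å
(and 0.05 Å for the oxygen sphere, whose boundary falls exactly on voxel
centres at 0.1 Å — a measure-zero alignment that the acceptance script
avoids by jittering the sphere centre sub-voxel).  Spacing must be finer
than the smallest sphere radius or the computation is refused.

Occupied volume is Bondi's packing estimate v_OC = 1.3 v_W on either
route, total volume is the periodic box volume, and
FFV = 1 − v_OC/v_T.  Over-packed inputs (v_OC > v_T) return a negative
FFV with a warning rather than an exception, since they arise
legitimately from careless box choices and should be visible, not fatal.

## Elasticity

With the entropic contribution neglected (valid at moderate temperature
and small strain), the modulus is the strain curvature of the
potential-energy density.  `strain_sweep` applies affine uniaxial strain
— coordinates and box length along one axis scaled by (1+ε), no internal
relaxation between steps (a documented simplification; relaxation would
require forces, which are out of scope) — and records U(ε)/V₀ with V₀
the *unstrained* box volume.  Reference-volume normalization is the
zero-stress convention: dividing by the strained volume would leak the
first-order volume change of the cohesive energy into the curvature
(≈ −3 % for a 12-6 chain at rest).

The default protocol expands from 0 to 0.01 in 10 steps (11 points).
`modulus_from_series` fits u(ε) = u₀ + bε + aε² by least squares and
returns E = 2a; the fit (rather than an endpoint finite difference)
suppresses evaluation noise and makes E invariant to constant energy
offsets.  One caveat measured and worth knowing: on a one-sided sweep of
an anharmonic potential the cubic term biases the fitted curvature (for a
12-6 chain at 1 % amplitude, by about −10 %).  The `symmetric=True`
option sweeps −ε_max…+ε_max instead, cancelling the cubic term by parity;
curvature-sensitive work should use it (the end-to-end chain test
recovers K r_m²/v to 0.3 % that way).

The pair stiffness K = [n(n−1) − 2m(m−1)] ε/r_m² is implemented as
printed.  It equals the true curvature of ε[(r_m/r)ⁿ − 2(r_m/r)ᵐ] at r_m
only when n = 2m, because the −2 normalization places the minimum at r_m
only then (otherwise U′(r_m) = ε(2m−n)/r_m ≠ 0 and the curvature at r_m
is [n(n+1) − 2m(m+1)] ε/r_m²).  The 12-6 and 2-1 cases both satisfy
n = 2m; the tests check the identity on that family and assert the exact
deviation off it.  Moduli in kcal/mol/Å³ convert to GPa by ×6.9477.

## Synthetic configurations

The generators replace equilibrated atomistic models of lignin,
hemicellulose and their complex with small deterministic toys that have
the features the analyses key on, and nothing more:

* **Water**: rigid gas-phase geometry (O–H 0.9572 Å, H–O–H 104.52°),
  uniform random position and orientation, rejection-sampled so all
  intermolecular atom pairs stay ≥ `min_dist` (default 2.0 Å) apart,
  capped at 10,000 trials per molecule.
* **Lignin-like unit** (20 atoms, C₉H₁₀O): an aromatic ring with three
  ring hydrogens and a three-carbon side chain rising out of the ring
  plane, terminated by a hydroxymethyl group — the hydroxyl is extended
  away from the backbone, the feature that makes lignin hydroxyls
  water-accessible.  One hydroxyl per unit.
* **Xylan-like unit** (15 atoms, C₅H₇O₃): a puckered nonaromatic
  six-ring (5 C + ring O) carrying exactly two ring-attached hydroxyls —
  the backbone-localized hydroxyl pattern of xylose units.
* Chains join `n_units` copies with one covalent bond each, routed
  through positions chosen so consecutive units cannot overlap; a small
  Gaussian jitter (0.1 Å) breaks perfect periodicity without touching
  topology.  Idealized bond lengths throughout (C–C 1.54, C–O 1.43,
  O–H 0.96, aromatic C–C 1.39 Å); element masses C 12.011, H 1.008,
  O 15.999, water 18.015 amu.
* **Hydration** to a dry-basis moisture target inserts
  k = round(MC/100 × dry mass / 18.015) waters into void space
  (≥ `min_dist` from every atom), leaving the dry subsystem bit-exact.
  The achieved MC is therefore within one water-mass of the target.  MC
  is dry-basis percent — the wood-science convention — everywhere in the
  package.  With `expansion_volume` set, the box is first rescaled
  isotropically by that many Å³ per inserted water, modelling a matrix
  that swells to admit water; 30 Å³ corresponds to bulk liquid water, and
  values above ~22.6 Å³ (the Bondi-occupied volume of one water) make
  FFV grow on hydration while smaller or zero expansion makes it fall.
  That threshold is exactly the void-filling-vs-swelling dichotomy that
  separates lignin-like from hemicellulose-like FFV response at low MC,
  and the mechanism tests build fixtures on either side of it.

What the toys do *not* emulate: realistic conformational statistics,
force-field-valid geometry, chain entanglement, crosslinking, realistic
densities, or equilibrated hydrogen-bond networks.  Consequently passing
tests demonstrate that the *analysis machinery* is correct (detection,
normalization, partitioning, volume accounting, curvature fits) and that
mechanism signs follow from geometry; they do not reproduce — and the
package does not claim — the absolute FFV levels, RDF peak heights,
H-bond energy curves or GPa-scale moduli of equilibrated cell-wall
models.  The published summary numbers live in `trends` as data, not as
predictions.

## Packaged trend series

`trends.load_paper_dataset` carries only sentence-printed summary values
(no digitized figure markers): longitudinal moduli (0.5 %, 19.1 GPa),
(3 %, 19.4 GPa), (14.5 %, 14.6 GPa); transverse endpoints (0 %, 7.9 GPa),
(15 %, 2.6 GPa), whose two-point rate pins the quoted 0.35 GPa per % MC;
lignin FFV (0 %, 0.14), (2.5 %, 0.13), (30 %, 0.20) with hemicellulose
(0 %, 0.10), (30 %, 0.17) as a separate series; and the simulated modulus
peak locations 2.5 % MC (LCC) and 10 % MC (lignin), stored with NaN
moduli because peak values were not printed.  Each series carries a
provenance string restating its source numbers.  `linear_rate` is an
inclusive-window least-squares fit (equal to the endpoint slope for two
points); `find_peak` is an argmax with smallest-MC tie-breaking.

## Determinism and problem sizes

Every stochastic routine takes an explicit seed and is bit-reproducible
given (seed, parameters).  The test suite and the acceptance script run
on small systems chosen to make their checks sharp rather than big:
15–20-water boxes (where exhaustive O(n³) hydrogen-bond scans and
Monte-Carlo volume oracles are exact-enough references), 4–8-unit chains
(where template arithmetic gives closed-form expected counts), 10–12 Å
voxel grids at 0.1–0.15 Å, and 500-atom ideal gases for RDF statistics.
The moisture-trend test aggregates 12 hydration seeds per MC level in a
snug box; roomy boxes were rejected at design time because randomly
placed waters almost never sit within hydrogen-bonding range of the
chain, leaving the statistic powerless.

## Known limitations

* Orthorhombic boxes only; no triclinic support.
* Affine strain without internal relaxation underestimates softening from
  internal rearrangement; virial-stress routes are out of scope.
* The voxel solvent-excluded path treats probe-sized interior cavities as
  excluded volume (flood-fill from the largest periodic component); for
  the intended probe-0 use this path is inactive.
* Classification assumes chemically sane valences and raises on H with
  two bonds, O with more than two, C with more than four.
* RDF peak heights from one snapshot carry full single-frame noise.
* Bifurcated hydrogen bonds are counted once per acceptor; comparisons
  with counting conventions that keep only the best acceptor per
  hydrogen will differ at dense hydrogen-bond networks.
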