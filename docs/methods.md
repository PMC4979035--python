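# Methods

This note records the models implemented in `polarbind`, their
assumptions, the numerical choices that matter, what the synthetic
fixtures do and do not emulate, and the known limitations.

## Scope and units

All computations are implicit-solvent post-processing of coordinate
frames; no dynamics is propagated.  Internal units are Å, kcal/mol,
elementary charges, amu, Kelvin; the Coulomb constant is
332.0636 kcal·Å/(mol·e²).  Waters and monatomic ions parsed from PDB
input are kept but assigned segment `other` and excluded from all energy
terms.  Residue numbering is taken verbatim from input; no renumbering.

## Trajectory metrics

RMSD uses least-squares rigid superposition (Kabsch, via
`scipy.spatial.transform.Rotation.align_vectors`) with optional weights;
the reported value is `sqrt(Σ wᵢ‖xᵢ−yᵢ‖²/Σ wᵢ)` after the transform.
RMSF is measured about the **iterated mean structure**: frames are
superposed onto a running mean that is refined for two passes, on the
same selection being measured (equal weights by default, masses by
flag).  The trajectory mean — not a crystal reference — was chosen
because it makes RMSF a pure fluctuation measure, independent of any
systematic drift from the starting structure; the alternative convention
(crystal reference) mixes drift into the fluctuation.  Cα values can be
aggregated per residue; a Pearson-correlation utility supports profile
comparisons.

## Hydrogen bonds

A candidate is a donor N–H with an acceptor O (and its antecedent C)
taken from topology connectivity; the backbone scope restricts to amide
N–H / carbonyl C=O pairs at least two residues apart.  Detection uses
the donor–acceptor heavy-atom distance (≤ 3.5 Å) together with the
donor–H–acceptor angle (≥ 120°), both cutoffs **inclusive** and applied
uniformly.  The per-bond energy statistic is the vacuum Coulomb energy
over the four (C,O)×(N,H) pairs with dielectric 1 and no cutoff, and its
trajectory mean averages over *all* frames, bound or not — a bond that
breaks therefore raises (weakens) its mean energy, which is the
behavior the statistic is meant to expose.  Occupancy is the fraction of
frames passing the criteria; native-bond fractions are block averages of
(native bonds present)/(native total).

## Molecular-mechanics energies

Group–group Coulomb and Lennard-Jones sums with AMBER-style (rmin/2, ε)
parameters and Lorentz–Berthelot combining (`rmin = 2^{1/6} σ`), no
cutoff and no periodicity.  Binding energies contain only intergroup
terms: in the single-trajectory protocol complex, receptor, and ligand
share conformations, so every intramolecular term cancels identically in
the difference and is never computed.  The per-residue interaction
spectrum is exactly additive by construction.  A toy harmonic bonded
potential (bonds + angles, with analytic gradient verified against
central differences) supports minimization and Hessians; fixture
equilibrium values are measured from the native geometry so the native
frame is a stationary point of the bonded terms.

## Poisson–Boltzmann solvation

The linear PB equation at zero ionic strength, `∇·(ε∇φ) = −4πkρ`, is
discretized on a regular grid with a 7-point stencil:

* charges spread to nodes by trilinear (cloud-in-cell) weights;
* the dielectric boundary is the solvent-excluded region built by
  inflating atom spheres by the probe radius (1.4 Å) and eroding by the
  probe via a Euclidean distance transform — a DelPhi-style voxel
  molecular surface without analytic re-entrant patches;
* **edge dielectrics are harmonic means** of the endpoint values.  The
  harmonic mean respects flux continuity across the jump: with it the
  Born-ion error falls from 7.7 to 0.9 kcal/mol as the grid is refined
  from 2 to 4 grids/Å, whereas the arithmetic mean does not converge to
  the analytic value;
* Dirichlet boundary values are atom-centered monopoles screened by the
  solvent dielectric;
* the symmetric positive-definite system is solved by
  Jacobi-preconditioned conjugate gradients (relative residual 10⁻⁸ by
  default), with `max_iterations` guarding non-convergence.

The reaction-field energy is the two-solve difference against a uniform
interior-dielectric reference on the *identical* grid, so the divergent
grid self-energy cancels exactly; binding ΔG_pol additionally solves
receptor and ligand inside the complex's grid geometry to cancel
grid-placement artifacts.  Induced surface charges are recovered from
Gauss's law applied to the converged potential (total node charge minus
free charge); for the Born ion their sum reproduces −q(1 − 1/80) to
better than 0.1 %.

Default grid density is 4 grids/Å with 10 Å padding.  Pipeline and
self-consistency runs on the synthetic complex use 1.2–1.5 grids/Å with
5–6 Å padding — the package's desk-scale problem size, chosen because
the validated Born convergence transfers and binding differences at
those settings are stable to the tolerances asserted in the tests.

The nonpolar term is γ·SASA + β (γ = 0.00542 kcal/(mol·Å²),
β = 0.92 kcal/mol) with Shrake–Rupley sphere-point areas (960
deterministic golden-spiral points per atom).  β is applied once per
species and cancels in the complex − receptor − ligand difference, so
binding nonpolar energy is exactly γ·ΔSASA.

## Normal-mode entropy

Each species is minimized on the toy force field (L-BFGS with analytic
gradients, RMS-gradient tolerance 10⁻⁴ kcal/mol/Å), the Hessian is built
by central differences of the analytic gradient (step 10⁻⁴ Å),
mass-weighted, and projected against the six rigid-body vectors.
Entropies are Sackur–Tetrode translation at 1 atm, classical rigid rotor
(symmetry number 1), and quantum harmonic oscillator vibrations at
300 K.  The binding entry is `TΔS_term = −TΔS_bind`, **positive when
binding loses entropy**, so the total binding free energy is the plain
sum of all five components.  (Reference decompositions in circulation
sometimes print the two single-structure rows of this term with a
flipped sign although their totals require the positive convention; the
package uses the positive convention throughout, and its worked example
takes those entries as magnitudes.)  Per-condition entropy averages over
20 evenly spaced snapshots by default (2 in the desk-scale runs), with
standard deviations reported.

## MM/PBSA assembly

Snapshots are taken at even stride over a window:
`stride = floor((W−1)/(n−1))` for n ≥ 2, which reduces to the identity
at n = W and to the window endpoints at n = 2.  The default window is
the full trajectory; production practice would restrict to the
equilibrated portion.  Component means carry sample standard deviations
(not standard errors).  A condition fails if more than 5 % of its
snapshots fail.  Per-residue decomposition attributes ele/vdW by the
exact pairwise split, ΔG_pol by the linear attribution
`½ Σ_{i∈res} qᵢ Δφ_rf(rᵢ)` of the complex-versus-separated
reaction-field difference (exactly additive over residues plus the
ligand), and nonpolar by γ·ΔSASA over the residue's atoms.

## Self-consistent polarized charges

Fragmentation: one fragment per residue plus one for the ligand; caps
duplicate C,O of the preceding and N,H,CA of the following residue.
Cap atoms are fitted but discarded on reassembly, and they are *excluded
from the background* seen by their fragment — the caps stand in for
those atoms, so counting their point charges too would double the
near-field.

The electronic step is a declared linear-response surrogate:
`qᵢ = q_ref,i − αᵢ(φᵢ − φ̄)` with the α-weighted mean φ̄ subtracted so
the fragment's total charge is conserved exactly, and zero external
potential returns the reference charges.  Default response coefficients
are α = 10⁻³ e²·Å/kcal for N and O, 5·10⁻⁴ for H, 2·10⁻⁴ for C — sized
so typical interfacial potentials (tens of kcal/(mol·e)) shift polar
charges by a few hundredths of an e and the loop contracts in a handful
of iterations, the regime a fragment quantum calculation would show.  A
quantum backend could replace the surrogate behind the same interface.

Each cycle: external potential at fragment atoms from all other
fragments' current charges plus the PB induced surface charges →
surrogate response → restrained ESP refit on 1.4–2.0× van-der-Waals
shells with a hard integer net-charge constraint → reassembly → PB solve
for new surface charges.  The refit is restrained (harmonic, λ = 5·10⁻⁴)
**toward the responded charges**: the ESP fit is near-singular for
buried atoms, and restraining toward the unpolarized reference lets
those directions drift and scramble the response; anchoring at the
responded target keeps the refit faithful where the data are
uninformative.  Canonical hyperbolic RESP restraints are not
implemented.  Convergence is max |Δq| < 10⁻³ e (typically 3–5
iterations); three consecutive increases engage 0.5 mixing.

On the toy complex, the fitted charges strengthen the designed
hydrogen-bond Coulomb energies in aggregate (mean over the three bonds,
≈ 0.3 kcal/mol).  One of the three individually weakens slightly: its
donor H is buried at the interface while its N is solvent-exposed, so
Born-type reaction-field self-amplification of the N and O charges
outweighs the mutual-polarization gain — a real feature of coupling a
charge response to a continuum reaction field on this geometry, not a
fitting artifact.  The generator's factor-scaled "polarized" charge set,
by contrast, strengthens all three bonds by construction.

## Synthetic fixtures

The generators are pure functions of their spec (fixed seed ⇒
byte-identical output).

* `born_ion` — q = +1 e, PB radius 2 Å: the analytic solvation case.
* `dimer` — one harmonic bond, no LJ: closed-form frequency
  `ν = (1/2πc)√(k′/μ)` with k′ = 2k for E = k(r−r₀)².
* `mini_helix` — an ideal helical backbone (rise 1.5 Å, 100°/residue)
  with carbonyl O along the axis toward the C-terminus and amide H
  opposite, guaranteeing the i→i+4 hydrogen bonds (n−4 of them) while
  i→i+2/i+3 pairs fail the angle test.
* `toy_complex` — a 10-residue extended "pocket" peptide (5 backbone
  atoms per residue, alternating pleat) plus a 12-atom ligand placed so
  that exactly three receptor–ligand hydrogen bonds satisfy the
  criteria in the native frame: the glycine-like residue's amide
  donates to the ligand carbonyl, and two ligand N–H donors reach the
  glycine- and serine-like carbonyls — the classic serine-protease
  S1-pocket motif.  Charges are integers per fragment; the "polarized"
  partner scales the designed-bond atoms' charges by 1.15 and
  redistributes the surplus within each fragment.

Trajectories are native + iid Gaussian jitter (σ = 0.1 Å default, the
scale that keeps designed bonds intact while producing realistic
RMSD/RMSF statistics); a rupture schedule displaces the ligand-side atom
pair of a designed bond 3 Å along the donor–acceptor axis from the
scheduled frame on, clearing the 3.5 Å cutoff from the 2.9 Å native
separation with margin.

What the fixtures do **not** emulate: real protein folds or sequences,
side chains, anharmonic and correlated dynamics, conformational
transitions, explicit water, or the actual chemistry of any inhibitor.
Passing tests therefore demonstrate that the analysis machinery is
correct (oracle-validated numerics, exact bookkeeping, correct
qualitative response to polarization), not that the pipeline reproduces
any particular experimental binding constant; headline statistics of
real systems (RMSD plateaus, occupancies, absolute ΔG values) require
real MD input.

## Degenerate inputs and tie-breaks

Superposition rejects < 3 or collinear points.  Clash errors fire below
0.1 Å separation in any pairwise energy.  ESP evaluation excludes points
within 0.5 Å of a charge (with a warning).  Zero-response surrogates
converge on iteration 1 by construction.  Single-frame ("X-ray")
conditions report zero standard deviations.  Monatomic species have zero
rotational and vibrational entropy; near-linear moment ratios below
10⁻⁸ switch to the linear-rotor formula.  Up to six weakly imaginary
modes after projection are dropped with a warning; more raise a
saddle-point error.

## Known limitations

* Linear PB only, zero salt; no nonlinear PB, no Debye–Hückel screening,
  no multigrid/focusing.
* The voxel solvent-excluded surface has O(h) boundary placement error;
  quantitative ΔG_pol at coarse desk-scale grids carries a few tenths of
  a kcal/mol of grid noise (the identical-grid differencing removes most
  but not all of it).
* The electronic response is a linear surrogate; no charge transfer
  between fragments, no geometry dependence of the response, no actual
  quantum chemistry.
* No mmCIF or force-field topology (PSF/prmtop) parsing; no automatic
  protonation — fixtures carry their hydrogens, and applying the
  pipeline to a real PDB entry requires an external protonation step
  whose choices (e.g. histidine tautomers) must be documented by the
  user.
* No FEP/TI, no three-trajectory MM/PBSA, no quasi-harmonic or
  interaction-entropy alternatives.
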