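# polarbind

Implicit-solvent energetics of protein–ligand binding: single-trajectory
MM/PBSA with per-residue decomposition, hydrogen-bond occupancy and Coulomb
energetics, trajectory stability metrics, and a self-consistent
polarized-charge (PPC-style) fitting loop — all exercisable at desk scale on
synthetic protein–ligand fixtures.

## Who this is for

Computational chemists and structural bioinformaticians who post-process
molecular-dynamics snapshots of a receptor–ligand complex into binding free
energies, and who want to study how **electronic polarization of partial
charges** — absent from standard fixed-charge force fields — changes
hydrogen-bond stability and the electrostatic component of binding.  The
package re-implements the full analysis chain (including the
finite-difference Poisson–Boltzmann solver) so every term is inspectable,
and ships deterministic synthetic fixtures so the machinery can be validated
without hundreds of nanoseconds of MD.

## The model

The binding free energy of each condition (charge set × trajectory) is the
snapshot average of

```
ΔG_bind = ΔE_ele + ΔE_vdW + ΔG_pol + ΔG_nonpol + TΔS_term
```

* **ΔE_ele, ΔE_vdW** — receptor–ligand Coulomb and Lennard-Jones group
  interactions (`k q_i q_j / r_ij`, AMBER-style rmin/ε with
  Lorentz–Berthelot combining).  In the single-trajectory protocol the
  intramolecular terms cancel exactly, so only intergroup terms are computed.
* **ΔG_pol** — reaction-field energy `½ Σ q_i [φ_solv(r_i) − φ_ref(r_i)]`
  from a finite-difference linear Poisson–Boltzmann solver (ε_in = 1,
  ε_out = 80, probe 1.4 Å, 4 grids/Å by default); complex, receptor and
  ligand are solved on the identical grid so grid self-energies cancel.
* **ΔG_nonpol** — `γ·ΔSASA` with γ = 0.00542 kcal/(mol·Å²) and offset
  β = 0.92 kcal/mol (β cancels in the binding difference); SASA by
  Shrake–Rupley sphere-point counting.
* **TΔS_term** — normal-mode entropies (Sackur–Tetrode translation, rigid
  rotor, quantum harmonic oscillator) of minimized complex/receptor/ligand;
  positive when entropy opposes binding.

Hydrogen bonds use donor–acceptor distance ≤ 3.5 Å and donor–H–acceptor
angle ≥ 120° (both inclusive); the per-bond energy statistic is the vacuum
Coulomb energy over the four C,O × N,H pairs.

Polarized charges are derived self-consistently: the solute is cut into
residue fragments with conjugate caps, a linear-response surrogate (standing
in for the fragment quantum-chemistry step) shifts fragment charges under
the potential of all other fragments plus the PB induced surface charges,
the shifted charges are refit on Connolly-style shells with a restrained
least-squares ESP fit under a hard integer net-charge constraint, and the
loop iterates until max |Δq| < 10⁻³ e (typically 3–5 iterations).

## Worked example

Generate the synthetic receptor–ligand complex (a 10-residue pocket whose
serine/glycine-like residues form three designed hydrogen bonds with a
12-atom ligand), then run the trajectory and charge-fitting analyses:

```bash
polarbind synth --kind toy_complex --seed 7 --frames 20 --out demo
polarbind rmsd  --traj demo/trajectory.pdb --ref demo/native.pdb \
                --select backbone --out demo/rmsd.csv
polarbind hbonds --traj demo/trajectory.pdb --native demo/native.pdb \
                 --topology demo/topology.json --scope protein_ligand \
                 --block 5 --out demo/hb.csv
polarbind ppc-fit --structure demo/native.pdb --topology demo/topology.json \
                  --grid-density 1.5 --padding 6 --out demo/ppc.csv
```

which prints

```
wrote toy_complex fixture to demo
mean RMSD 0.166 A over 20 frames -> demo/rmsd.csv
4 blocks -> demo/hb.csv
iteration 1: max |dq| = 2.12e-02 e
iteration 2: max |dq| = 1.79e-02 e
iteration 3: max |dq| = 2.34e-03 e
iteration 4: max |dq| = 3.93e-04 e
converged in 4 iterations -> demo/ppc.csv
```

The mean backbone RMSD of ≈ 0.17 Å is the thermal jitter of the fixture
(σ = 0.1 Å per coordinate gives √3·σ ≈ 0.17 Å); every 5-frame block of
`demo/hb.csv` reports fraction 1.0 because all three designed
receptor–ligand hydrogen bonds persist under that jitter; and the charge
fit contracts below the 10⁻³ e tolerance in four cycles, writing the
polarized per-atom charges to `demo/ppc.csv`.  A condition matrix
(`polarbind mmpbsa --config run.yaml --out results/`) then evaluates any
charge-set × trajectory combination into a binding-energy table with
standard deviations.

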