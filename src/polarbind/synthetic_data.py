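"""Deterministic, seeded generators for every fixture the pipeline needs.

Fixture kinds
-------------
``born_ion``
    A single +1 e ion of PB radius 2.0 A — the analytic reference case for
    the Poisson-Boltzmann solver (Born formula) and the Gauss-law check on
    induced surface charge.
``dimer``
    A harmonic diatomic (one bond, no LJ) — closed-form normal-mode and
    minimization oracle.
``mini_helix``
    An ideal helical backbone (5 atoms N,H,CA,C,O per residue) whose
    geometry guarantees the i -> i+4 amide hydrogen bonds, giving a
    backbone H-bond network of known size.
``toy_complex``
    A receptor-ligand complex: an extended 10-residue (default) peptide
    "pocket" plus a 12-atom ligand forming exactly three receptor-ligand
    hydrogen bonds (a receptor amide donating to a ligand carbonyl, and
    two ligand N-H donors to receptor carbonyls — the motif of a serine /
    glycine pocket binding a macrocyclic inhibitor).

Each fixture carries a "base" charge set (integer charge per residue and
per ligand) and a "polarized" partner differing only at the designed
hydrogen-bond atoms: their charges are scaled by the polarization factor
and the surplus is redistributed within the fragment so fragment net
charges are conserved.  By construction the polarized set strictly
strengthens (lowers) the Coulomb energy of every designed bond.

Trajectories are native + iid Gaussian jitter; a rupture schedule
displaces the ligand-side pair of a designed bond 3 A along the
donor-acceptor axis from the scheduled frame on, guaranteeing the bond
fails the 3.5 A criterion thereafter.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .hbond import HBond, PROTEIN_LIGAND
from .model_io import (LIGAND, OTHER, PROTEIN, AtomRecord, ChargeSet,
                       Topology, Trajectory)

__all__ = ["FixtureSpec", "Fixture", "make_fixture", "make_trajectory"]

# backbone template: name -> (element, charge, rmin_half, epsilon, mass, pb_radius)
_BB = {
    "N":  ("N", -0.45, 1.824, 0.1700, 14.007, 1.55),
    "H":  ("H", +0.30, 0.600, 0.0157, 1.008, 1.20),
    "CA": ("C", +0.10, 1.908, 0.0860, 12.011, 1.70),
    "C":  ("C", +0.50, 1.908, 0.0860, 12.011, 1.70),
    "O":  ("O", -0.45, 1.661, 0.2100, 15.999, 1.52),
}
_BOND_K = 300.0     # kcal/mol/A^2
_ANGLE_K = 50.0     # kcal/mol/rad^2


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of a synthetic fixture; equal specs give identical output."""

    kind: str = "toy_complex"
    n_residues: int = 10
    ligand_atoms: int = 12
    seed: int = 0
    noise_sigma: float = 0.1          # A, thermal jitter per atom coordinate
    rupture: tuple = ()               # ((designed-bond id, rupture frame), ...)
    polarization_factor: float = 1.15

    def __post_init__(self):
        if self.kind not in ("born_ion", "dimer", "mini_helix", "toy_complex"):
            raise ValueError(f"unknown fixture kind {self.kind!r}")
        if self.kind == "toy_complex" and self.n_residues < 7:
            raise ValueError("toy_complex needs at least 7 residues")
        if self.kind == "mini_helix" and self.n_residues < 5:
            raise ValueError("mini_helix needs at least 5 residues")
        if self.kind == "toy_complex" and self.ligand_atoms < 12:
            raise ValueError("toy_complex ligand has at least 12 atoms")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")


@dataclass
class Fixture:
    """A generated system: topology, native frame, paired charge sets."""

    spec: FixtureSpec
    topology: Topology
    native: np.ndarray
    base: ChargeSet
    polarized: ChargeSet
    designed_hbonds: list = field(default_factory=list)

    @property
    def receptor_indices(self):
        return np.nonzero(self.topology.segments == PROTEIN)[0]

    @property
    def ligand_indices(self):
        return np.nonzero(self.topology.segments == LIGAND)[0]


def _backbone_atom(serial, name, resname, resid, pos, segment=PROTEIN):
    el, q, rmh, eps, m, pbr = _BB[name]
    return AtomRecord(serial=serial, name=name, element=el,
                      residue_name=resname, residue_index=resid,
                      segment=segment, position=np.asarray(pos, float),
                      charge=q, lj_rmin_half=rmh, lj_epsilon=eps,
                      mass=m, pb_radius=pbr)


def _measure_bonded(atoms, bond_pairs, angle_triples):
    """Harmonic terms with equilibria measured from the native geometry."""
    pos = np.array([a.position for a in atoms])
    bonds = []
    for i, j in bond_pairs:
        bonds.append((i, j, _BOND_K, float(np.linalg.norm(pos[i] - pos[j]))))
    angles = []
    for i, j, k in angle_triples:
        v1 = pos[i] - pos[j]
        v2 = pos[k] - pos[j]
        c = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
        angles.append((i, j, k, _ANGLE_K, float(np.arccos(np.clip(c, -1, 1)))))
    return bonds, angles


def _peptide_connectivity(n_res, offset=0):
    """Bond/angle index lists for a chain of 5-atom (N,H,CA,C,O) residues."""
    def a(i, name):  # atom index of residue i (0-based)
        return offset + 5 * i + ("N", "H", "CA", "C", "O").index(name)
    bonds, angles = [], []
    for i in range(n_res):
        bonds += [(a(i, "N"), a(i, "H")), (a(i, "N"), a(i, "CA")),
                  (a(i, "CA"), a(i, "C")), (a(i, "C"), a(i, "O"))]
        angles += [(a(i, "H"), a(i, "N"), a(i, "CA")),
                   (a(i, "N"), a(i, "CA"), a(i, "C")),
                   (a(i, "CA"), a(i, "C"), a(i, "O"))]
        if i + 1 < n_res:
            bonds.append((a(i, "C"), a(i + 1, "N")))
            angles += [(a(i, "CA"), a(i, "C"), a(i + 1, "N")),
                       (a(i, "O"), a(i, "C"), a(i + 1, "N")),
                       (a(i, "C"), a(i + 1, "N"), a(i + 1, "CA"))]
    return bonds, angles


# ---------------------------------------------------------------------------
# geometry builders
# ---------------------------------------------------------------------------

def _helix_positions(n_res):
    """Ideal alpha-helical backbone: O along +axis, amide H along -axis.

    Parameters (rise 1.5 A, 100 deg/residue, CA radius 2.3 A) give
    i -> i+4 N-H...O=C hydrogen bonds comfortably inside the 3.5 A /
    120 deg criteria while i -> i+2, i -> i+3 pairs fail the angle test.
    """
    out = {}
    for i in range(n_res):
        th = np.radians(100.0 * i)
        z = 1.5 * i
        def cyl(radius, dphi, dz):
            return np.array([radius * np.cos(th + np.radians(dphi)),
                             radius * np.sin(th + np.radians(dphi)), z + dz])
        N = cyl(1.6, -28.0, -0.9)
        CA = cyl(2.3, 0.0, 0.0)
        C = cyl(1.6, +26.0, +0.55)
        O = C + np.array([0.0, 0.0, 1.23])
        H = N + np.array([0.0, 0.0, -1.01])
        out[i] = {"N": N, "H": H, "CA": CA, "C": C, "O": O}
    return out


def _strand_positions(n_res):
    """Extended receptor chain along x; amide H and carbonyl O of residue i
    point to +y when i (1-based) is even, -y when odd."""
    out = {}
    for i in range(n_res):
        resid = i + 1
        side = 1.0 if resid % 2 == 0 else -1.0
        x = 3.8 * resid
        zig = 0.3 * side          # pleat so Calpha atoms are not collinear
        N = np.array([x - 1.35, 0.0, 0.0])
        H = N + np.array([0.0, 1.01 * side, 0.0])
        CA = np.array([x, 0.0, zig])
        C = np.array([x + 1.35, 0.0, 0.0])
        O = C + np.array([0.0, 1.23 * side, 0.0])
        out[i] = {"N": N, "H": H, "CA": CA, "C": C, "O": O}
    return out


# ligand template: name -> (element, base charge, rmin_half, eps, mass, pb_r,
#                           position)
_LIGAND_TEMPLATE = [
    # designed acceptor carbonyl (receives receptor residue-6 N-H)
    ("O1", "O", -0.45, 1.661, 0.210, 15.999, 1.52, (21.45, 2.90, 0.0)),
    ("C7", "C", +0.45, 1.908, 0.086, 12.011, 1.70, (20.60, 3.80, 0.0)),
    # designed donor 1 (donates to receptor residue-6 carbonyl)
    ("N1", "N", -0.40, 1.824, 0.170, 14.007, 1.55, (24.15, 4.13, 0.0)),
    ("H9", "H", +0.30, 0.600, 0.0157, 1.008, 1.20, (24.15, 3.12, 0.0)),
    # designed donor 2 (donates to receptor residue-4 carbonyl)
    ("N4", "N", -0.40, 1.824, 0.170, 14.007, 1.55, (16.55, 4.13, 0.0)),
    ("H13", "H", +0.30, 0.600, 0.0157, 1.008, 1.20, (16.55, 3.12, 0.0)),
    # skeleton
    ("C2", "C", +0.10, 1.908, 0.086, 12.011, 1.70, (18.00, 3.90, 0.0)),
    ("C3", "C", +0.05, 1.908, 0.086, 12.011, 1.70, (19.30, 4.40, 0.0)),
    ("C8", "C", +0.05, 1.908, 0.086, 12.011, 1.70, (21.90, 4.25, 0.0)),
    ("C9", "C", 0.00, 1.908, 0.086, 12.011, 1.70, (23.10, 4.60, 0.0)),
    ("H21", "H", 0.00, 1.487, 0.0157, 1.008, 1.20, (21.90, 4.90, 0.90)),
    ("H22", "H", 0.00, 1.487, 0.0157, 1.008, 1.20, (19.35, 5.45, 0.55)),
]
_LIGAND_BONDS = [("O1", "C7"), ("C7", "C3"), ("C3", "C2"), ("C2", "N4"),
                 ("N4", "H13"), ("C7", "C8"), ("C8", "C9"), ("C9", "N1"),
                 ("N1", "H9"), ("C8", "H21"), ("C3", "H22")]
_LIGAND_ANGLES = [("O1", "C7", "C3"), ("O1", "C7", "C8"), ("C7", "C8", "C9"),
                  ("C8", "C9", "N1"), ("C9", "N1", "H9"), ("C3", "C2", "N4"),
                  ("C2", "N4", "H13"), ("C7", "C3", "C2")]

# designed-bond atom names: (receptor resid, receptor atoms, ligand atoms)
_GLY_RES = 6     # donates its amide N-H to ligand O1; its C=O accepts H9
_SER_RES = 4     # its C=O accepts ligand H13


def _build_peptide(kind, n_res):
    geo = _helix_positions(n_res) if kind == "helix" else _strand_positions(n_res)
    resname = {_SER_RES: "SER", _GLY_RES: "GLY"} if kind == "strand" else {}
    atoms = []
    for i in range(n_res):
        rn = resname.get(i + 1, "ALA")
        for name in ("N", "H", "CA", "C", "O"):
            atoms.append(_backbone_atom(len(atoms) + 1, name, rn, i + 1,
                                        geo[i][name]))
    bond_pairs, angle_triples = _peptide_connectivity(n_res)
    return atoms, bond_pairs, angle_triples


def _polarize(topology, base, designed_atoms, factor):
    """Scale charges at designed H-bond atoms, conserving fragment charge.

    The surplus created within each fragment (residue or ligand) is spread
    uniformly over the fragment's non-designed atoms.
    """
    q = base.charges.copy()
    designed = sorted(set(designed_atoms))
    for idx in designed:
        q[idx] = factor * base.charges[idx]
    for _, res in topology.residues.iterrows():
        span = list(range(res["start"], res["stop"]))
        in_frag = [i for i in span if i in designed]
        if not in_frag:
            continue
        rest = [i for i in span if i not in designed]
        excess = q[span].sum() - base.charges[span].sum()
        if rest:
            q[rest] -= excess / len(rest)
        else:  # whole fragment designed: rescale to conserve exactly
            q[span] -= excess / len(span)
    return ChargeSet("polarized", q)


def make_fixture(spec: FixtureSpec) -> Fixture:
    """Build a fixture system from its spec (pure function of the spec)."""
    if spec.kind == "born_ion":
        atom = AtomRecord(serial=1, name="ION", element="NA",
                          residue_name="ION", residue_index=1, segment=OTHER,
                          position=np.zeros(3), charge=1.0, lj_rmin_half=1.8,
                          lj_epsilon=0.1, mass=22.99, pb_radius=2.0)
        top = Topology([atom])
        cs = ChargeSet("base", [1.0])
        return Fixture(spec, top, top.positions.copy(), cs,
                       ChargeSet("polarized", [1.0]), [])

    if spec.kind == "dimer":
        a1 = AtomRecord(serial=1, name="N", element="N", residue_name="DIM",
                        residue_index=1, segment=OTHER,
                        position=np.zeros(3), charge=0.3, lj_rmin_half=1.824,
                        lj_epsilon=0.0, mass=14.007, pb_radius=1.55)
        a2 = AtomRecord(serial=2, name="O", element="O", residue_name="DIM",
                        residue_index=1, segment=OTHER,
                        position=np.array([1.2, 0.0, 0.0]), charge=-0.3,
                        lj_rmin_half=1.661, lj_epsilon=0.0, mass=15.999,
                        pb_radius=1.52)
        top = Topology([a1, a2], bonds=[(0, 1, _BOND_K, 1.2)])
        cs = ChargeSet("base", [0.3, -0.3])
        return Fixture(spec, top, top.positions.copy(), cs,
                       ChargeSet("polarized", [0.3, -0.3]), [])

    if spec.kind == "mini_helix":
        atoms, bond_pairs, angle_triples = _build_peptide("helix",
                                                          spec.n_residues)
        bonds, angles = _measure_bonded(atoms, bond_pairs, angle_triples)
        top = Topology(atoms, bonds, angles)
        base = ChargeSet("base", top.charges)
        return Fixture(spec, top, top.positions.copy(), base,
                       ChargeSet("polarized", top.charges.copy()), [])

    # toy_complex
    atoms, bond_pairs, angle_triples = _build_peptide("strand",
                                                      spec.n_residues)
    n_rec = len(atoms)
    name_to_idx = {}
    for name, el, q, rmh, eps, m, pbr, pos in _LIGAND_TEMPLATE:
        name_to_idx[name] = len(atoms)
        atoms.append(AtomRecord(serial=len(atoms) + 1, name=name, element=el,
                                residue_name="LIG", residue_index=1,
                                segment=LIGAND, position=np.asarray(pos),
                                charge=q, lj_rmin_half=rmh, lj_epsilon=eps,
                                mass=m, pb_radius=pbr))
    # optional extra nonpolar tail to reach the requested ligand size
    prev = name_to_idx["C9"]
    for extra in range(spec.ligand_atoms - len(_LIGAND_TEMPLATE)):
        pos = atoms[prev].position + np.array([0.2, 1.3, 0.45])
        name = f"CX{extra + 1}"
        name_to_idx[name] = len(atoms)
        atoms.append(AtomRecord(serial=len(atoms) + 1, name=name, element="C",
                                residue_name="LIG", residue_index=1,
                                segment=LIGAND, position=pos, charge=0.0,
                                lj_rmin_half=1.908, lj_epsilon=0.086,
                                mass=12.011, pb_radius=1.70))
        bond_pairs.append((prev, name_to_idx[name]))
        prev = name_to_idx[name]
    for a, b in _LIGAND_BONDS:
        bond_pairs.append((name_to_idx[a], name_to_idx[b]))
    for a, b, c in _LIGAND_ANGLES:
        angle_triples.append((name_to_idx[a], name_to_idx[b], name_to_idx[c]))
    bonds, angles = _measure_bonded(atoms, bond_pairs, angle_triples)
    top = Topology(atoms, bonds, angles)

    def rec(resid, name):
        return 5 * (resid - 1) + ("N", "H", "CA", "C", "O").index(name)

    designed = [
        # receptor GLY amide donates to ligand carbonyl O1=C7
        HBond(rec(_GLY_RES, "N"), rec(_GLY_RES, "H"),
              name_to_idx["O1"], name_to_idx["C7"], PROTEIN_LIGAND),
        # ligand N1-H9 donates to receptor GLY carbonyl
        HBond(name_to_idx["N1"], name_to_idx["H9"],
              rec(_GLY_RES, "O"), rec(_GLY_RES, "C"), PROTEIN_LIGAND),
        # ligand N4-H13 donates to receptor SER carbonyl
        HBond(name_to_idx["N4"], name_to_idx["H13"],
              rec(_SER_RES, "O"), rec(_SER_RES, "C"), PROTEIN_LIGAND),
    ]
    base = ChargeSet("base", top.charges)
    designed_atoms = [i for hb in designed
                      for i in (hb.donor, hb.hydrogen, hb.acceptor,
                                hb.antecedent)]
    polarized = _polarize(top, base, designed_atoms,
                          spec.polarization_factor)
    return Fixture(spec, top, top.positions.copy(), base, polarized, designed)


def make_trajectory(fixture: Fixture, n_frames: int, sigma=None,
                    schedule=None, seed=None) -> Trajectory:
    """Native structure + Gaussian jitter, with scripted bond ruptures.

    ``schedule`` is a sequence of ``(designed_bond_id, rupture_frame)``;
    from ``rupture_frame`` (0-based) onward the ligand-side heavy atom and
    its partner (H or antecedent) of that bond are displaced 3 A along the
    donor-acceptor axis, clearing the 3.5 A cutoff from the 2.9 A native
    separation.
    """
    spec = fixture.spec
    sigma = spec.noise_sigma if sigma is None else float(sigma)
    schedule = spec.rupture if schedule is None else tuple(schedule)
    seed = spec.seed if seed is None else int(seed)
    top = fixture.topology
    rng = np.random.default_rng(seed)

    displacements = []  # (frame, atom indices, vector)
    for bond_id, frame in schedule:
        try:
            hb = fixture.designed_hbonds[bond_id]
        except IndexError:
            raise ValueError(f"rupture schedule references unknown bond "
                             f"{bond_id}") from None
        if not (0 <= frame < n_frames):
            raise ValueError(f"rupture frame {frame} outside trajectory")
        seg = top.segments
        if seg[hb.donor] == LIGAND:
            moved = (hb.donor, hb.hydrogen)
            axis = fixture.native[hb.donor] - fixture.native[hb.acceptor]
        else:
            moved = (hb.acceptor, hb.antecedent)
            axis = fixture.native[hb.acceptor] - fixture.native[hb.donor]
        axis = axis / np.linalg.norm(axis)
        displacements.append((int(frame), moved, 3.0 * axis))

    coords = np.empty((n_frames, top.n_atoms, 3))
    for f in range(n_frames):
        frame = fixture.native.copy()
        if sigma > 0:
            frame += rng.normal(0.0, sigma, size=frame.shape)
        for rupture_frame, moved, vec in displacements:
            if f >= rupture_frame:
                for idx in moved:
                    frame[idx] += vec
        coords[f] = frame
    return Trajectory(top, coords)
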