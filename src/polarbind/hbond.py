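"""Hydrogen-bond detection, occupancy statistics, and Coulomb energetics.

A hydrogen bond is a donor-heavy-atom / donor-hydrogen / acceptor /
acceptor-antecedent quadruple (N-H ... O=C for backbone amides).  The
geometric criterion is the donor-acceptor heavy-atom distance together
with the donor-H-acceptor angle, both cutoffs inclusive (defaults 3.5 A
and 120 degrees).  The per-bond energy statistic is the vacuum Coulomb
energy over the four C,O x N,H pairs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .constants import COULOMB_KCAL
from .mm_energy import ClashError
from .model_io import LIGAND, PROTEIN, Topology, Trajectory

__all__ = ["HBondCriteria", "HBond", "HBondSeries", "enumerate_candidates",
           "detect", "native_fraction_series", "hbond_coulomb_energy",
           "occupancy", "hbond_series"]

BACKBONE_BACKBONE = "backbone-backbone"
PROTEIN_LIGAND = "protein-ligand"
OTHER_CLASS = "other"


@dataclass(frozen=True)
class HBondCriteria:
    """Geometric hydrogen-bond criteria (cutoffs inclusive)."""

    distance_cutoff: float = 3.5   # donor-acceptor heavy-atom distance, A
    angle_cutoff: float = 120.0    # donor-H-acceptor angle, degrees

    def __post_init__(self):
        if self.distance_cutoff <= 0:
            raise ValueError("distance_cutoff must be > 0")
        if not (0 < self.angle_cutoff <= 180):
            raise ValueError("angle_cutoff must be in (0, 180]")


@dataclass(frozen=True)
class HBond:
    """Donor(N), hydrogen(H), acceptor(O), antecedent(C) atom indices."""

    donor: int
    hydrogen: int
    acceptor: int
    antecedent: int
    kind: str = OTHER_CLASS

    def __post_init__(self):
        ids = (self.donor, self.hydrogen, self.acceptor, self.antecedent)
        if len(set(ids)) != 4:
            raise ValueError(f"hbond atom indices must be distinct: {ids}")


@dataclass
class HBondSeries:
    """Per-frame presence, donor-acceptor distance, and optional energy."""

    hbond: HBond
    frame_index: np.ndarray
    present: np.ndarray
    distance: np.ndarray
    energy: np.ndarray | None = None

    @property
    def occupancy(self) -> float:
        return occupancy(self.present)


def _donor_pairs(topology: Topology):
    """(N, H) pairs: a nitrogen bonded to a hydrogen."""
    adj = topology.bonded_neighbors()
    el = topology.elements
    pairs = []
    for i in range(topology.n_atoms):
        if el[i] != "N":
            continue
        hs = sorted(j for j in adj[i] if el[j] == "H")
        if not hs and topology.names[i] in ("N",):
            warnings.warn(f"polar donor atom {i} has no bonded hydrogen; "
                          "donor skipped", stacklevel=2)
        pairs.extend((i, h) for h in hs)
    return pairs


def _acceptor_pairs(topology: Topology):
    """(O, C) pairs: an oxygen bonded to a carbon antecedent."""
    adj = topology.bonded_neighbors()
    el = topology.elements
    pairs = []
    for i in range(topology.n_atoms):
        if el[i] != "O":
            continue
        cs = sorted(j for j in adj[i] if el[j] == "C")
        if cs:
            pairs.append((i, cs[0]))
    return pairs


def _classify(topology, donor, acceptor):
    seg = topology.segments
    names = topology.names
    sd, sa = seg[donor], seg[acceptor]
    if {sd, sa} == {PROTEIN, LIGAND}:
        return PROTEIN_LIGAND
    if (sd == sa == PROTEIN and names[donor] == "N" and names[acceptor] == "O"):
        return BACKBONE_BACKBONE
    return OTHER_CLASS


def enumerate_candidates(topology: Topology, scope: str = "all"):
    """Deterministic, duplicate-free hydrogen-bond candidate list.

    ``scope='backbone'`` restricts to amide N-H donors and carbonyl C=O
    acceptors within the protein, at least 2 residues apart;
    ``'protein_ligand'`` to donor/acceptor pairs straddling the
    protein-ligand boundary; ``'all'`` imposes no restriction beyond
    donor != acceptor atoms.
    """
    if scope not in ("backbone", "protein_ligand", "all"):
        raise ValueError(f"unknown scope {scope!r}")
    donors = _donor_pairs(topology)
    acceptors = _acceptor_pairs(topology)
    seg = topology.segments
    names = topology.names
    rid = topology.residue_indices
    out = []
    for (n, h) in donors:
        for (o, c) in acceptors:
            if len({n, h, o, c}) != 4:
                continue
            kind = _classify(topology, n, o)
            if scope == "backbone":
                if not (seg[n] == seg[o] == PROTEIN
                        and names[n] == "N" and names[o] == "O"
                        and abs(int(rid[n]) - int(rid[o])) >= 2):
                    continue
                kind = BACKBONE_BACKBONE
            elif scope == "protein_ligand":
                if kind != PROTEIN_LIGAND:
                    continue
            out.append(HBond(n, h, o, c, kind))
    return out


def detect(coords, candidates, criteria: HBondCriteria = HBondCriteria()):
    """Presence flags for candidate bonds in one frame (inclusive cutoffs).

    Present iff donor-acceptor distance <= distance_cutoff and
    donor-H-acceptor angle >= angle_cutoff.
    """
    coords = np.asarray(coords, float)
    if not candidates:
        return np.zeros(0, dtype=bool)
    don = np.array([hb.donor for hb in candidates])
    hyd = np.array([hb.hydrogen for hb in candidates])
    acc = np.array([hb.acceptor for hb in candidates])
    d_da = np.linalg.norm(coords[don] - coords[acc], axis=1)
    v1 = coords[don] - coords[hyd]
    v2 = coords[acc] - coords[hyd]
    cosang = (v1 * v2).sum(1) / (np.linalg.norm(v1, axis=1)
                                 * np.linalg.norm(v2, axis=1))
    ang = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
    return (d_da <= criteria.distance_cutoff) & (ang >= criteria.angle_cutoff)


def native_fraction_series(traj: Trajectory, native_coords, criteria=None,
                           block: int = 100, scope: str = "backbone",
                           candidates=None) -> pd.DataFrame:
    """Block-averaged fraction of native hydrogen bonds along a trajectory.

    The native list is the set of candidates present in ``native_coords``;
    each block's fraction is the mean over its frames of (native bonds
    present) / (native total).  Returns a DataFrame (block, frame_start,
    frame_stop, fraction).
    """
    criteria = criteria or HBondCriteria()
    if block <= 0:
        raise ValueError("block must be a positive frame count")
    if candidates is None:
        candidates = enumerate_candidates(traj.topology, scope=scope)
    native_flags = detect(native_coords, candidates, criteria)
    native = [hb for hb, f in zip(candidates, native_flags) if f]
    if not native:
        raise ValueError("no native hydrogen bonds under the criteria")
    rows = []
    for b0 in range(0, traj.n_frames, block):
        b1 = min(b0 + block, traj.n_frames)
        fracs = [detect(traj.coords[f], native, criteria).mean()
                 for f in range(b0, b1)]
        rows.append((len(rows), int(traj.frame_index[b0]),
                     int(traj.frame_index[b1 - 1]), float(np.mean(fracs))))
    return pd.DataFrame(rows, columns=["block", "frame_start", "frame_stop",
                                       "fraction"])


def hbond_coulomb_energy(coords, hbond: HBond, charges) -> float:
    """Vacuum Coulomb energy over the four (C,O) x (N,H) pairs, kcal/mol.

    ``E = k sum_{i in {C,O}} sum_{j in {N,H}} q_i q_j / r_ij`` with
    ``k = 332.0636`` kcal*A/(mol*e^2) and dielectric 1.
    """
    coords = np.asarray(coords, float)
    q = np.asarray(charges, float)
    e = 0.0
    for i in (hbond.antecedent, hbond.acceptor):
        for j in (hbond.donor, hbond.hydrogen):
            r = float(np.linalg.norm(coords[i] - coords[j]))
            if r < 0.1:
                raise ClashError(f"hbond atoms {i},{j} at {r:.3f} A")
            e += q[i] * q[j] / r
    return COULOMB_KCAL * e


def occupancy(present) -> float:
    """Fraction of frames in which the bond is present."""
    present = np.asarray(present)
    if present.size == 0:
        raise ValueError("occupancy needs at least one frame")
    return float(np.asarray(present, float).mean())


def hbond_series(traj: Trajectory, hbond: HBond,
                 criteria: HBondCriteria = HBondCriteria(),
                 charges=None) -> HBondSeries:
    """Per-frame presence/distance (and energy, if charges given) series.

    The energy statistic is evaluated in every frame, whether or not the
    bond is geometrically present (full-trajectory mean convention).
    """
    present = np.zeros(traj.n_frames, bool)
    dist = np.zeros(traj.n_frames)
    energy = np.zeros(traj.n_frames) if charges is not None else None
    for f in range(traj.n_frames):
        c = traj.coords[f]
        present[f] = bool(detect(c, [hbond], criteria)[0])
        dist[f] = np.linalg.norm(c[hbond.donor] - c[hbond.acceptor])
        if charges is not None:
            energy[f] = hbond_coulomb_energy(c, hbond, charges)
    return HBondSeries(hbond, traj.frame_index.copy(), present, dist, energy)
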