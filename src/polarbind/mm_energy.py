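"""Gas-phase molecular-mechanics energies.

Pairwise Coulomb and Lennard-Jones interactions between disjoint atom
groups (the intermolecular part of the binding energy — in the
single-trajectory protocol the intramolecular terms cancel exactly, so
only group-group terms are ever assembled into binding energies), a
per-residue interaction spectrum, and the toy harmonic bonded potential
(with analytic gradient) that supports minimization and normal modes.

Lennard-Jones parameters are AMBER-style (rmin/2, epsilon) combined with
Lorentz-Berthelot rules: ``rmin_ij = rmin_half_i + rmin_half_j``,
``eps_ij = sqrt(eps_i * eps_j)``; the relation to sigma/epsilon form is
``rmin = 2^(1/6) sigma``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .constants import COULOMB_KCAL
from .model_io import Selection, SelectionError, Topology

__all__ = ["MMParams", "PairEnergy", "ClashError", "group_interaction",
           "per_residue_spectrum", "toy_bonded_energy", "toy_total_energy"]

CLASH_DISTANCE = 0.1  # A


class ClashError(ValueError):
    """Two interacting atoms closer than the clash distance."""


@dataclass(frozen=True)
class MMParams:
    """Nonbonded parameters.  No cutoff by default (MM/PBSA use)."""

    coulomb_constant: float = COULOMB_KCAL
    combining_rule: str = "lorentz_berthelot"
    cutoff: float | None = None


@dataclass(frozen=True)
class PairEnergy:
    """Electrostatic + van der Waals interaction energy (kcal/mol)."""

    ele: float
    vdw: float

    def __add__(self, other):
        return PairEnergy(self.ele + other.ele, self.vdw + other.vdw)

    def __sub__(self, other):
        return PairEnergy(self.ele - other.ele, self.vdw - other.vdw)


def _pair_arrays(coords, topology, charges, ia, ib):
    xa, xb = coords[ia], coords[ib]
    diff = xa[:, None, :] - xb[None, :, :]
    r = np.sqrt((diff ** 2).sum(-1))
    if r.size and r.min() < CLASH_DISTANCE:
        i, j = np.unravel_index(int(r.argmin()), r.shape)
        raise ClashError(
            f"atoms {ia[i]} and {ib[j]} at {r[i, j]:.3f} A (< {CLASH_DISTANCE} A)")
    qa, qb = charges[ia], charges[ib]
    return r, qa, qb


def group_interaction(coords, topology: Topology, charges,
                      group_a: Selection, group_b: Selection,
                      params: MMParams = MMParams()) -> PairEnergy:
    """Coulomb + LJ interaction energy between two disjoint atom groups.

    ``charges`` is a per-atom vector (e); pass ``topology.charges`` or a
    swapped-in charge set.  Energies in kcal/mol.
    """
    ia, ib = group_a.index_array, group_b.index_array
    if np.intersect1d(ia, ib).size:
        raise SelectionError("group_interaction: groups overlap")
    coords = np.asarray(coords, float)
    charges = np.asarray(charges, float)
    r, qa, qb = _pair_arrays(coords, topology, charges, ia, ib)

    inv_r = 1.0 / r
    if params.cutoff is not None:
        inv_r = np.where(r <= params.cutoff, inv_r, 0.0)
    ele = params.coulomb_constant * float((qa[:, None] * qb[None, :] * inv_r).sum())

    rmh = topology.lj_rmin_half
    eps = topology.lj_epsilon
    rmin = rmh[ia][:, None] + rmh[ib][None, :]
    eps_ij = np.sqrt(eps[ia][:, None] * eps[ib][None, :])
    x6 = (rmin * inv_r) ** 6
    vdw = float((eps_ij * (x6 ** 2 - 2.0 * x6)).sum())
    return PairEnergy(ele, vdw)


def per_residue_spectrum(coords, topology: Topology, charges,
                         ligand: Selection,
                         params: MMParams = MMParams()) -> pd.DataFrame:
    """Ligand-residue interaction spectrum over protein residues.

    One row per protein residue with its Coulomb and LJ interaction with
    the ligand.  Component sums over residues reproduce the whole-protein
    group interaction exactly (additivity of pairwise sums).
    """
    lig = set(ligand.indices)
    rows = []
    for _, res in topology.residues.iterrows():
        if res["segment"] != "protein":
            continue
        res_idx = [i for i in range(res["start"], res["stop"]) if i not in lig]
        if not res_idx:
            continue
        pe = group_interaction(coords, topology, charges,
                               Selection(tuple(res_idx)), ligand, params)
        rows.append((res["name"], res["index"], pe.ele, pe.vdw))
    return pd.DataFrame(rows, columns=["residue_name", "residue_index",
                                       "ele", "vdw"])


def toy_bonded_energy(coords, topology: Topology):
    """Harmonic bonded energy and its analytic gradient.

    ``E = sum_b k_b (r - r0)^2 + sum_a k_theta (theta - theta0)^2``.
    Returns ``(energy, gradient)`` with gradient shape (N, 3) in
    kcal/mol/A.
    """
    coords = np.asarray(coords, float)
    energy = 0.0
    grad = np.zeros_like(coords)
    for b in topology.bonds:
        d = coords[b.i] - coords[b.j]
        r = np.linalg.norm(d)
        if r < 1e-10:
            raise ClashError(f"bond ({b.i},{b.j}) atoms coincide")
        dr = r - b.r0
        energy += b.k * dr * dr
        g = (2.0 * b.k * dr / r) * d
        grad[b.i] += g
        grad[b.j] -= g
    for a in topology.angles:
        rij = coords[a.i] - coords[a.j]
        rkj = coords[a.k] - coords[a.j]
        nij = np.linalg.norm(rij)
        nkj = np.linalg.norm(rkj)
        cosg = np.dot(rij, rkj) / (nij * nkj)
        cosg = np.clip(cosg, -1.0, 1.0)
        theta = np.arccos(cosg)
        dth = theta - a.theta0
        energy += a.force_k * dth * dth
        sing = np.sqrt(max(1.0 - cosg * cosg, 1e-12))
        # d(theta)/d(r_i) etc. (standard angle derivative)
        di = (cosg * rij / nij - rkj / nkj) / (nij * sing)
        dk = (cosg * rkj / nkj - rij / nij) / (nkj * sing)
        coeff = 2.0 * a.force_k * dth
        grad[a.i] += coeff * di
        grad[a.k] += coeff * dk
        grad[a.j] -= coeff * (di + dk)
    return float(energy), grad


def toy_total_energy(coords, topology: Topology, charges=None,
                     include: Selection | None = None):
    """Bonded + intra-group nonbonded toy energy with analytic gradient.

    The nonbonded part runs over all atom pairs of ``include`` (default:
    all atoms) except 1-2 and 1-3 bonded exclusions.  Supports
    minimization and numerical Hessians for normal-mode entropy.
    """
    coords = np.asarray(coords, float)
    q = topology.charges if charges is None else np.asarray(charges, float)
    energy, grad = toy_bonded_energy(coords, topology)

    idx = np.arange(topology.n_atoms) if include is None else include.index_array
    pair_key = ("nbpairs", tuple(int(i) for i in idx))
    if pair_key not in topology._cache:
        excl = topology.exclusion_pairs()
        ii, jj = [], []
        for a_pos in range(len(idx)):
            for b_pos in range(a_pos + 1, len(idx)):
                i, j = int(idx[a_pos]), int(idx[b_pos])
                if (min(i, j), max(i, j)) not in excl:
                    ii.append(i)
                    jj.append(j)
        topology._cache[pair_key] = (np.array(ii, int), np.array(jj, int))
    ii, jj = topology._cache[pair_key]
    if len(ii):
        d = coords[ii] - coords[jj]
        r2 = (d ** 2).sum(1)
        r = np.sqrt(r2)
        if r.min() < CLASH_DISTANCE:
            raise ClashError("nonbonded clash between included atoms")
        inv_r = 1.0 / r
        qq = COULOMB_KCAL * q[ii] * q[jj]
        rmin = topology.lj_rmin_half[ii] + topology.lj_rmin_half[jj]
        eij = np.sqrt(topology.lj_epsilon[ii] * topology.lj_epsilon[jj])
        x6 = (rmin * inv_r) ** 6
        energy += float((qq * inv_r).sum())
        energy += float((eij * (x6 ** 2 - 2.0 * x6)).sum())
        dEdr = -qq / r2 + 12.0 * eij * (x6 - x6 ** 2) / r
        gvec = (dEdr * inv_r)[:, None] * d
        np.add.at(grad, ii, gvec)
        np.add.at(grad, jj, -gvec)
    return float(energy), grad
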