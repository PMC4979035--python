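"""Single-trajectory MM/PBSA: per-snapshot binding-energy components,
condition matrices (charge set x trajectory), and per-residue decomposition.

The binding free energy of each condition is assembled as

    dG_bind = dE_ele + dE_vdw + dG_pol + dG_nonpol + TdS_term

where the gas-phase terms are receptor-ligand group interactions (the
intramolecular terms cancel exactly in the single-trajectory protocol),
dG_pol is the reaction-field difference complex - receptor - ligand with
all three species solved on the complex's grid (identical grid placement
cancels grid artifacts), dG_nonpol = gamma * dSASA (the beta offset
cancels in the difference), and the TdS_term is positive when binding
loses entropy.  Means carry sample standard deviations over snapshots.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import entropy_nma, hbond, mm_energy, solvation
from .model_io import Selection, Topology, Trajectory

__all__ = ["Condition", "EnergyComponents", "PipelineConfig",
           "extract_snapshots", "snapshot_components", "run_condition",
           "assemble_total", "per_residue_decomposition",
           "condition_difference"]

COMPONENTS = ("ele", "vdw", "pol", "nonpol")


@dataclass(frozen=True)
class Condition:
    """One Table row: which charge set on which trajectory."""

    charge_label: str
    trajectory_label: str


@dataclass
class EnergyComponents:
    """The binding-energy record: four components + entropy + totals.

    All in kcal/mol; ``std`` holds sample standard deviations where the
    value is a snapshot average (empty/zero for single-frame conditions).
    ``sub_total = ele + vdw + pol + nonpol`` and
    ``total = sub_total + tds`` by construction.
    """

    ele: float
    vdw: float
    pol: float
    nonpol: float
    tds: float = 0.0
    std: dict = field(default_factory=dict)
    n_snapshots: int = 1

    @property
    def sub_total(self) -> float:
        return self.ele + self.vdw + self.pol + self.nonpol

    @property
    def total(self) -> float:
        return self.sub_total + self.tds

    def as_dict(self):
        return {"ele": self.ele, "vdw": self.vdw, "pol": self.pol,
                "nonpol": self.nonpol, "sub_total": self.sub_total,
                "tds": self.tds, "total": self.total}


@dataclass
class PipelineConfig:
    """End-to-end MM/PBSA settings."""

    snapshot_count: int = 200
    entropy_snapshot_count: int = 20
    pb: solvation.PBParams = field(default_factory=solvation.PBParams)
    nonpolar: solvation.NonpolarParams = field(
        default_factory=solvation.NonpolarParams)
    entropy: entropy_nma.EntropyParams = field(
        default_factory=entropy_nma.EntropyParams)
    criteria: hbond.HBondCriteria = field(default_factory=hbond.HBondCriteria)
    mm: mm_energy.MMParams = field(default_factory=mm_energy.MMParams)
    seed: int = 0
    compute_entropy: bool = True
    max_failure_fraction: float = 0.05

    def __post_init__(self):
        if self.entropy_snapshot_count > self.snapshot_count:
            raise ValueError("entropy snapshots cannot exceed snapshots")


def extract_snapshots(traj: Trajectory, n: int, window=None) -> Trajectory:
    """n frames at even stride over a frame window (0-based, inclusive).

    Stride rule: for n >= 2, ``stride = floor((W - 1) / (n - 1))`` over a
    window of W frames starting at its first frame — n = W gives the
    identity, n = 2 the window endpoints.  Deterministic.
    """
    if window is None:
        window = (0, traj.n_frames - 1)
    w0, w1 = int(window[0]), int(window[1])
    if not (0 <= w0 <= w1 < traj.n_frames):
        raise ValueError(f"bad window {window}")
    length = w1 - w0 + 1
    if n > length:
        raise ValueError(f"cannot extract {n} snapshots from a "
                         f"{length}-frame window")
    if n < 1:
        raise ValueError("need n >= 1")
    if n == 1:
        idx = [w0]
    else:
        stride = (length - 1) // (n - 1)
        idx = [w0 + stride * k for k in range(n)]
    return traj.subset(idx)


def snapshot_components(coords, topology: Topology, charges,
                        receptor: Selection, ligand: Selection,
                        config: PipelineConfig) -> EnergyComponents:
    """Binding-energy components (no entropy) for one snapshot.

    The receptor and ligand PB solves reuse the complex's grid geometry.
    """
    ir = receptor.index_array
    il = ligand.index_array
    if np.intersect1d(ir, il).size:
        raise ValueError("receptor and ligand selections overlap")
    coords = np.asarray(coords, float)
    charges = np.asarray(charges, float)

    pe = mm_energy.group_interaction(coords, topology, charges, receptor,
                                     ligand, config.mm)

    solute = np.concatenate([ir, il])
    radii = topology.pb_radii
    origin, h, shape = solvation.make_grid(coords[solute], radii[solute],
                                           config.pb)
    pol = {}
    for key, idx in (("complex", solute), ("receptor", ir), ("ligand", il)):
        e, _ = solvation.polar_solvation_energy(
            coords[idx], radii[idx], charges[idx], config.pb,
            origin=origin, shape=shape)
        pol[key] = e
    dpol = pol["complex"] - pol["receptor"] - pol["ligand"]

    area = {}
    for key, idx in (("complex", solute), ("receptor", ir), ("ligand", il)):
        total, _ = solvation.sasa(coords[idx], radii[idx], config.nonpolar,
                                  probe=config.pb.probe_radius)
        area[key] = total
    dnp = config.nonpolar.gamma * (area["complex"] - area["receptor"]
                                   - area["ligand"])
    return EnergyComponents(ele=pe.ele, vdw=pe.vdw, pol=dpol, nonpol=dnp)


def _entropy_term(coords, topology, charges, receptor, ligand, config):
    ep = config.entropy
    results = {}
    for key, sel in (("complex", None), ("receptor", receptor),
                     ("ligand", ligand)):
        if sel is None:
            idx = np.concatenate([receptor.index_array, ligand.index_array])
            idx = np.sort(idx)
            sel = Selection(tuple(int(i) for i in idx))
        sub_top, sub_coords, sub_q = _subsystem(topology, coords, charges, sel)
        xmin = entropy_nma.minimize(sub_coords, sub_top, sub_q, ep)
        spec = (None if sub_top.n_atoms == 1
                else entropy_nma.normal_modes(xmin, sub_top, sub_q, ep))
        results[key] = entropy_nma.entropy(xmin, spec, sub_top, ep)
    return entropy_nma.binding_entropy_term(results["complex"],
                                            results["receptor"],
                                            results["ligand"])


def _subsystem(topology, coords, charges, sel: Selection):
    """Extract a sub-topology (renumbered) for one species."""
    import dataclasses as dc
    idx = sel.index_array
    remap = {int(a): k for k, a in enumerate(idx)}
    atoms = [dc.replace(topology.atoms[a], serial=k + 1,
                        charge=float(charges[a]))
             for k, a in enumerate(idx)]
    bonds = [(remap[b.i], remap[b.j], b.k, b.r0) for b in topology.bonds
             if b.i in remap and b.j in remap]
    angles = [(remap[a.i], remap[a.j], remap[a.k], a.force_k, a.theta0)
              for a in topology.angles
              if a.i in remap and a.j in remap and a.k in remap]
    sub = Topology(atoms, bonds, angles)
    return sub, np.asarray(coords, float)[idx], np.asarray(charges)[idx]


def run_condition(condition: Condition, registry: dict,
                  topology: Topology, receptor: Selection, ligand: Selection,
                  config: PipelineConfig, window=None):
    """Snapshot-averaged components +- std for one (charge, trajectory) cell.

    ``registry`` maps ``charge_sets`` (label -> ChargeSet) and
    ``trajectories`` (label -> Trajectory).  Entropy runs on the
    ``entropy_snapshot_count`` evenly spaced members of the snapshot set.
    Returns ``(EnergyComponents, per-snapshot DataFrame)``.
    """
    cs = registry["charge_sets"][condition.charge_label]
    traj = registry["trajectories"][condition.trajectory_label]
    charges = cs.charges
    n = min(config.snapshot_count, traj.n_frames)
    snaps = extract_snapshots(traj, n, window)

    rows, failures = [], 0
    for f in range(snaps.n_frames):
        try:
            comp = snapshot_components(snaps.coords[f], topology, charges,
                                       receptor, ligand, config)
            rows.append({"frame": int(snaps.frame_index[f]),
                         **{k: getattr(comp, k) for k in COMPONENTS}})
        except Exception as exc:  # noqa: BLE001 - snapshot failures recorded
            failures += 1
            warnings.warn(f"snapshot {f} failed: {exc}", stacklevel=2)
    if failures > config.max_failure_fraction * snaps.n_frames:
        raise RuntimeError(
            f"condition {condition}: {failures}/{snaps.n_frames} "
            "snapshots failed")
    table = pd.DataFrame(rows)

    tds_vals = []
    if config.compute_entropy:
        n_ent = min(config.entropy_snapshot_count, snaps.n_frames)
        esnaps = extract_snapshots(snaps, n_ent)
        for f in range(esnaps.n_frames):
            tds_vals.append(_entropy_term(esnaps.coords[f], topology, charges,
                                          receptor, ligand, config))
    tds = float(np.mean(tds_vals)) if tds_vals else 0.0

    means = {k: float(table[k].mean()) for k in COMPONENTS}
    std = {k: (float(table[k].std(ddof=1)) if len(table) > 1 else 0.0)
           for k in COMPONENTS}
    if len(tds_vals) > 1:
        std["tds"] = float(np.std(tds_vals, ddof=1))
    comp = EnergyComponents(**means, tds=tds, std=std,
                            n_snapshots=len(table))
    return comp, table


def assemble_total(components) -> float:
    """dG_bind = ele + vdw + pol + nonpol + TdS_term (all five required).

    Accepts an :class:`EnergyComponents` or a mapping with keys
    ele/vdw/pol/nonpol/tds; the entropy entry is positive when entropy
    opposes binding.
    """
    if isinstance(components, EnergyComponents):
        return components.total
    missing = [k for k in (*COMPONENTS, "tds") if k not in components]
    if missing:
        raise KeyError(f"missing energy terms: {missing}")
    return float(sum(components[k] for k in (*COMPONENTS, "tds")))


def per_residue_decomposition(snapshots, topology: Topology, charges,
                              ligand: Selection,
                              config: PipelineConfig) -> pd.DataFrame:
    """Per-residue binding-energy decomposition, snapshot-averaged.

    ele/vdw come from the residue-ligand interaction spectrum; pol is the
    linear attribution ``1/2 sum_{i in res} q_i [dphi_rf_complex(r_i) -
    dphi_rf_species(r_i)]`` (residue rows sum to the total exactly, the
    ligand's share reported as residue index 0); nonpol is
    ``gamma * dSASA`` over the residue's atoms.
    """
    if isinstance(snapshots, Trajectory):
        frames = snapshots.coords
    else:
        frames = np.atleast_2d(np.asarray(snapshots, float))
        if frames.ndim == 2:
            frames = frames[None]
    charges = np.asarray(charges, float)
    il = ligand.index_array
    protein_idx = np.array([i for i in range(topology.n_atoms)
                            if topology.segments[i] == "protein"
                            and i not in set(il.tolist())], int)
    receptor = Selection(tuple(int(i) for i in protein_idx))
    radii = topology.pb_radii
    solute = np.sort(np.concatenate([receptor.index_array, il]))

    acc = None
    for coords in frames:
        spec = mm_energy.per_residue_spectrum(coords, topology, charges,
                                              ligand, config.mm)
        origin, h, shape = solvation.make_grid(coords[solute], radii[solute],
                                               config.pb)

        def rf_potential(idx):
            p = config.pb
            solv = solvation.solve_pb(coords[idx], radii[idx], charges[idx],
                                      p, origin=origin, shape=shape)
            ref = solvation.solve_pb(coords[idx], radii[idx], charges[idx],
                                     p, origin=solv.origin, shape=solv.shape,
                                     uniform_eps=p.eps_in, x0=solv.phi)
            return (solvation.potential_at(solv, coords[idx])
                    - solvation.potential_at(ref, coords[idx]))

        dphi_cplx = rf_potential(solute)
        dphi_rec = rf_potential(receptor.index_array)
        dphi_lig = rf_potential(il)
        dphi_species = np.zeros(topology.n_atoms)
        dphi_species[receptor.index_array] = dphi_rec
        dphi_species[il] = dphi_lig
        dphi_c = np.zeros(topology.n_atoms)
        dphi_c[solute] = dphi_cplx
        pol_atom = 0.5 * charges * (dphi_c - dphi_species)

        _, sasa_cplx = solvation.sasa(coords[solute], radii[solute],
                                      config.nonpolar,
                                      probe=config.pb.probe_radius)
        _, sasa_rec = solvation.sasa(coords[receptor.index_array],
                                     radii[receptor.index_array],
                                     config.nonpolar,
                                     probe=config.pb.probe_radius)
        _, sasa_lig = solvation.sasa(coords[il], radii[il], config.nonpolar,
                                     probe=config.pb.probe_radius)
        dsasa_atom = np.zeros(topology.n_atoms)
        dsasa_atom[solute] = sasa_cplx
        dsasa_atom[receptor.index_array] -= sasa_rec
        dsasa_atom[il] -= sasa_lig

        rows = []
        for _, res in topology.residues.iterrows():
            span = [i for i in range(res["start"], res["stop"])
                    if i in set(receptor.indices)]
            if not span:
                continue
            m = spec[(spec["residue_index"] == res["index"])
                     & (spec["residue_name"] == res["name"])]
            ele = float(m["ele"].iloc[0]) if len(m) else 0.0
            vdw = float(m["vdw"].iloc[0]) if len(m) else 0.0
            rows.append({
                "residue_name": res["name"], "residue_index": res["index"],
                "ele": ele, "vdw": vdw,
                "pol": float(pol_atom[span].sum()),
                "nonpol": config.nonpolar.gamma * float(dsasa_atom[span].sum()),
            })
        rows.append({
            "residue_name": "LIG", "residue_index": 0,
            "ele": 0.0, "vdw": 0.0,
            "pol": float(pol_atom[il].sum()),
            "nonpol": config.nonpolar.gamma * float(dsasa_atom[il].sum()),
        })
        df = pd.DataFrame(rows)
        acc = df if acc is None else acc.set_index(
            ["residue_name", "residue_index"]).add(
            df.set_index(["residue_name", "residue_index"])).reset_index()
    for c in COMPONENTS:
        acc[c] = acc[c] / len(frames)
    acc["total"] = acc[list(COMPONENTS)].sum(axis=1)
    return acc


def condition_difference(table_a: pd.DataFrame,
                         table_b: pd.DataFrame) -> pd.DataFrame:
    """Element-wise per-snapshot component differences a - b."""
    if len(table_a) != len(table_b):
        raise ValueError("snapshot tables have different lengths")
    out = {"frame": table_a["frame"].to_numpy()}
    for k in COMPONENTS:
        out[k] = table_a[k].to_numpy() - table_b[k].to_numpy()
    return pd.DataFrame(out)
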