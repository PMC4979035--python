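"""Snapshot extraction, component assembly, condition structure,
per-residue decomposition."""

import numpy as np
import pandas as pd
import pytest

import polarbind as pb
from polarbind.mmpbsa import (Condition, EnergyComponents, PipelineConfig,
                              assemble_total, condition_difference,
                              extract_snapshots, per_residue_decomposition,
                              run_condition, snapshot_components)
from polarbind.mm_energy import group_interaction
from polarbind.model_io import Selection
from polarbind.synthetic_data import FixtureSpec, make_fixture, make_trajectory


@pytest.fixture(scope="module")
def fast_cfg(fast_pb):
    return PipelineConfig(snapshot_count=3, entropy_snapshot_count=1,
                          pb=fast_pb, compute_entropy=False)


def _selections(fx):
    rec = Selection(tuple(int(i) for i in fx.receptor_indices))
    lig = Selection(tuple(int(i) for i in fx.ligand_indices))
    return rec, lig


class TestExtractSnapshots:
    def test_identity_when_n_equals_window(self, toy):
        traj = make_trajectory(toy, 10, sigma=0.0)
        out = extract_snapshots(traj, 10)
        assert np.array_equal(out.coords, traj.coords)

    def test_two_snapshots_are_window_endpoints(self, toy):
        traj = make_trajectory(toy, 100, sigma=0.01, seed=4)
        out = extract_snapshots(traj, 2)
        assert np.array_equal(out.coords[0], traj.coords[0])
        assert np.array_equal(out.coords[1], traj.coords[99])

    def test_stride_arithmetic_200_of_1000(self, toy):
        traj = pb.Trajectory(toy.topology,
                             np.broadcast_to(toy.native,
                                             (1000, *toy.native.shape)))
        out = extract_snapshots(traj, 200)
        assert list(out.frame_index) == list(range(1, 1000 + 1, 5))[:200]
        assert out.frame_index[-1] == 996  # 0-based frame 995

    def test_window_and_errors(self, toy):
        traj = make_trajectory(toy, 20, sigma=0.0)
        with pytest.raises(ValueError):
            extract_snapshots(traj, 30)
        with pytest.raises(ValueError):
            extract_snapshots(traj, 2, window=(5, 25))
        out = extract_snapshots(traj, 2, window=(10, 19))
        assert list(out.frame_index) == [11, 20]


class TestAssembleTotal:
    def test_all_zeros(self):
        comp = EnergyComponents(0.0, 0.0, 0.0, 0.0, 0.0)
        assert assemble_total(comp) == 0.0

    def test_mapping_input_and_missing_term(self):
        vals = {"ele": -27.76, "vdw": -52.42, "pol": 47.90,
                "nonpol": -4.95, "tds": 24.19}
        assert assemble_total(vals) == pytest.approx(-13.04, abs=0.02)
        with pytest.raises(KeyError):
            assemble_total({k: v for k, v in vals.items() if k != "tds"})

    def test_component_identities(self):
        comp = EnergyComponents(-1.5, -2.5, 3.0, -0.25, 1.25)
        assert comp.sub_total == pytest.approx(-1.25, abs=1e-12)
        assert comp.total == pytest.approx(comp.sub_total + comp.tds,
                                           abs=1e-12)


class TestSnapshotComponents:
    def test_inert_ligand_all_zero(self, toy, fast_cfg):
        """Zero charges and no LJ on the ligand: every component ~ 0."""
        import dataclasses
        top = toy.topology
        atoms = [dataclasses.replace(a, charge=0.0, lj_epsilon=0.0)
                 if a.segment == "ligand" else dataclasses.replace(a)
                 for a in top.atoms]
        # keep receptor charges but zero them too so pol difference is clean
        atoms = [dataclasses.replace(a, charge=0.0) for a in atoms]
        top0 = pb.Topology(atoms, top.bonds, top.angles)
        rec, lig = _selections(toy)
        comp = snapshot_components(toy.native, top0, top0.charges, rec, lig,
                                   fast_cfg)
        assert comp.ele == 0.0
        assert comp.vdw == pytest.approx(0.0, abs=1e-12)
        assert comp.pol == pytest.approx(0.0, abs=1e-6)
        # nonpol measures buried surface only; it is nonzero by geometry

    def test_ele_matches_brute_force(self, toy, fast_cfg):
        rec, lig = _selections(toy)
        comp = snapshot_components(toy.native, toy.topology,
                                   toy.base.charges, rec, lig, fast_cfg)
        from polarbind.constants import COULOMB_KCAL
        ele = 0.0
        for i in rec.indices:
            for j in lig.indices:
                r = np.linalg.norm(toy.native[i] - toy.native[j])
                ele += (COULOMB_KCAL * toy.base.charges[i]
                        * toy.base.charges[j] / r)
        assert comp.ele == pytest.approx(ele, abs=1e-8)

    def test_distant_ligand_separability(self, fast_pb):
        """Complex = receptor + far ligand: pol and nonpol differences
        vanish within grid tolerance."""
        fx = make_fixture(FixtureSpec(kind="toy_complex"))
        coords = fx.native.copy()
        coords[fx.ligand_indices] += np.array([0.0, 40.0, 0.0])
        rec, lig = _selections(fx)
        cfg = PipelineConfig(snapshot_count=1, entropy_snapshot_count=1,
                             pb=fast_pb, compute_entropy=False)
        comp = snapshot_components(coords, fx.topology, fx.base.charges,
                                   rec, lig, cfg)
        assert comp.nonpol == pytest.approx(0.0, abs=1e-9)
        assert abs(comp.pol) < 0.4          # grid tolerance at coarse spacing
        assert abs(comp.ele) < 1.0          # residual long-range Coulomb


class TestRunCondition:
    def test_constant_trajectory_zero_std(self, toy, fast_cfg):
        traj = make_trajectory(toy, 3, sigma=0.0)
        registry = {"charge_sets": {"base": toy.base},
                    "trajectories": {"static": traj}}
        rec, lig = _selections(toy)
        comp, table = run_condition(Condition("base", "static"), registry,
                                    toy.topology, rec, lig, fast_cfg)
        assert comp.n_snapshots == 3
        for k in ("ele", "vdw", "pol", "nonpol"):
            assert comp.std[k] == pytest.approx(0.0, abs=1e-9)

    def test_single_frame_xray_condition(self, toy, fast_cfg):
        xray = pb.Trajectory(toy.topology, toy.native[None])
        registry = {"charge_sets": {"base": toy.base},
                    "trajectories": {"xray": xray}}
        rec, lig = _selections(toy)
        comp, table = run_condition(Condition("base", "xray"), registry,
                                    toy.topology, rec, lig, fast_cfg)
        assert comp.n_snapshots == 1
        assert all(v == 0.0 for k, v in comp.std.items())

    def test_charge_swap_structure(self, toy, fast_cfg):
        """Swapping the charge set changes ele/pol but leaves vdw and
        nonpol bit-identical on the same trajectory."""
        traj = make_trajectory(toy, 3, sigma=0.08, seed=9)
        registry = {"charge_sets": {"base": toy.base,
                                    "polarized": toy.polarized},
                    "trajectories": {"t": traj}}
        rec, lig = _selections(toy)
        a, ta = run_condition(Condition("base", "t"), registry,
                              toy.topology, rec, lig, fast_cfg)
        b, tb = run_condition(Condition("polarized", "t"), registry,
                              toy.topology, rec, lig, fast_cfg)
        assert np.array_equal(ta["vdw"].to_numpy(), tb["vdw"].to_numpy())
        assert np.array_equal(ta["nonpol"].to_numpy(),
                              tb["nonpol"].to_numpy())
        assert not np.allclose(ta["ele"], tb["ele"])
        assert not np.allclose(ta["pol"], tb["pol"])


class TestConditionDifference:
    def test_identical_tables_zero(self):
        t = pd.DataFrame({"frame": [1, 2], "ele": [1.0, 2.0],
                          "vdw": [0.5, 0.5], "pol": [3.0, 2.0],
                          "nonpol": [-0.1, -0.2]})
        d = condition_difference(t, t)
        for k in ("ele", "vdw", "pol", "nonpol"):
            assert np.allclose(d[k], 0.0)

    def test_mean_linearity(self, rng):
        n = 50
        ta = pd.DataFrame({"frame": np.arange(n),
                           **{k: rng.normal(size=n)
                              for k in ("ele", "vdw", "pol", "nonpol")}})
        tb = pd.DataFrame({"frame": np.arange(n),
                           **{k: rng.normal(size=n)
                              for k in ("ele", "vdw", "pol", "nonpol")}})
        d = condition_difference(ta, tb)
        assert d["ele"].mean() == pytest.approx(
            ta["ele"].mean() - tb["ele"].mean(), abs=1e-9)

    def test_mismatched_lengths(self):
        t = pd.DataFrame({"frame": [1], "ele": [0.0], "vdw": [0.0],
                          "pol": [0.0], "nonpol": [0.0]})
        with pytest.raises(ValueError):
            condition_difference(t, t.iloc[:0])

    def test_polarized_vs_base_ele_dominates(self, toy, fast_cfg):
        """The charge-set swap shows up almost entirely in the
        electrostatic component."""
        traj = make_trajectory(toy, 2, sigma=0.05, seed=6)
        registry = {"charge_sets": {"base": toy.base,
                                    "polarized": toy.polarized},
                    "trajectories": {"t": traj}}
        rec, lig = _selections(toy)
        _, ta = run_condition(Condition("polarized", "t"), registry,
                              toy.topology, rec, lig, fast_cfg)
        _, tb = run_condition(Condition("base", "t"), registry,
                              toy.topology, rec, lig, fast_cfg)
        d = condition_difference(ta, tb)
        assert d["vdw"].abs().max() == 0.0
        assert d["nonpol"].abs().max() == 0.0
        assert d["ele"].abs().mean() > d["pol"].abs().mean()


@pytest.fixture(scope="module")
def decomposition(toy, fast_pb):
    cfg = PipelineConfig(snapshot_count=1, entropy_snapshot_count=1,
                         pb=fast_pb, compute_entropy=False)
    rec, lig = _selections(toy)
    table = per_residue_decomposition(toy.native, toy.topology,
                                      toy.base.charges, lig, cfg)
    comp = snapshot_components(toy.native, toy.topology,
                               toy.base.charges, rec, lig, cfg)
    return table, comp


class TestPerResidueDecomposition:
    def test_ele_additivity_exact(self, decomposition):
        table, comp = decomposition
        assert table["ele"].sum() == pytest.approx(comp.ele, abs=1e-6)
        assert table["vdw"].sum() == pytest.approx(comp.vdw, abs=1e-6)

    def test_pol_and_nonpol_sums_within_attribution_tolerance(
            self, decomposition):
        table, comp = decomposition
        assert table["pol"].sum() == pytest.approx(comp.pol, rel=0.02,
                                                   abs=0.02)
        assert table["nonpol"].sum() == pytest.approx(comp.nonpol, rel=0.02,
                                                      abs=1e-6)

    def test_designed_hbond_residues_lead_spectrum(self, decomposition):
        table, _ = decomposition
        prot = table[table["residue_index"] > 0]
        order = prot.iloc[np.argsort(-prot["total"].abs())]
        assert set(order["residue_index"].iloc[:2]) == {4, 6}

    def test_distant_uncharged_residue_negligible(self, decomposition, toy):
        table, _ = decomposition
        row = table[table["residue_index"] == 1].iloc[0]
        assert abs(row["ele"]) < 0.5
        assert abs(row["total"]) < 0.75
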