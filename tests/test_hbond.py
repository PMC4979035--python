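"""Hydrogen-bond enumeration, detection, occupancy, Coulomb energetics."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.spatial.transform import Rotation

import polarbind as pb
from polarbind.constants import COULOMB_KCAL
from polarbind.hbond import (HBond, HBondCriteria, detect,
                             enumerate_candidates, hbond_coulomb_energy,
                             hbond_series, native_fraction_series, occupancy)
from polarbind.mm_energy import ClashError
from polarbind.synthetic_data import FixtureSpec, make_fixture, make_trajectory


def _linear_nho(d_no, angle_deg):
    """Coordinates C,O,N,H with given N-O distance and N-H-O angle.

    H sits on the N-O axis 1.0 A from N; the acceptor O is rotated off
    axis around H to set the angle; C extends past O.
    """
    N = np.zeros(3)
    H = np.array([1.0, 0.0, 0.0])
    # place O so that angle N-H-O = angle_deg and |N-O| = d_no
    # solve in the xy-plane: O = H + r*(cos(theta), sin(theta), 0) where
    # theta measured from the H->N direction (-x)
    theta = np.radians(angle_deg)
    # find r so |N - O| = d_no
    # N-O^2 = |H - N|^2 + r^2 - 2 r |H-N| cos(theta)
    hn = 1.0
    a, b, c = 1.0, -2 * hn * np.cos(theta), hn ** 2 - d_no ** 2
    r = (-b + np.sqrt(b * b - 4 * a * c)) / (2 * a)
    direction = np.array([-np.cos(theta), np.sin(theta), 0.0])
    O = H - direction * r * np.array([1.0, -1.0, 1.0])  # rotate away from N
    O = H + r * np.array([np.cos(np.pi - theta), np.sin(np.pi - theta), 0.0])
    C = O + 1.23 * (O - H) / np.linalg.norm(O - H)
    return np.array([C, O, N, H])


def _quad_topology():
    names = ["C", "O", "N", "H"]
    atoms = [pb.AtomRecord(serial=i + 1, name=n, element=n, residue_name="X",
                           residue_index=1 + (i // 2), position=np.zeros(3))
             for i, n in enumerate(names)]
    return pb.Topology(atoms, bonds=[(0, 1, 300, 1.23), (2, 3, 300, 1.0)])


class TestDetect:
    CRIT = HBondCriteria()
    HB = HBond(donor=2, hydrogen=3, acceptor=1, antecedent=0)

    def check(self, d, ang):
        coords = _linear_nho(d, ang)
        # verify construction before using it
        assert np.linalg.norm(coords[2] - coords[1]) == pytest.approx(d)
        v1 = coords[2] - coords[3]
        v2 = coords[1] - coords[3]
        got = np.degrees(np.arccos(np.dot(v1, v2)
                                   / np.linalg.norm(v1) / np.linalg.norm(v2)))
        assert got == pytest.approx(ang, abs=1e-6)
        return bool(detect(coords, [self.HB], self.CRIT)[0])

    def test_well_inside_cutoffs(self):
        assert self.check(2.9, 180.0)

    def test_distance_filter(self):
        assert not self.check(3.6, 180.0)

    def test_angle_filter_near_cutoff(self):
        assert not self.check(2.9, 119.0)
        assert self.check(2.9, 121.0)

    def test_angle_boundary_inclusive_exact_geometry(self):
        """cos(angle) is exactly 0 for orthogonal vectors, so a 90-degree
        cutoff probes the inclusive rule without rounding."""
        N = np.array([1.0, 0.0, 0.0])
        H = np.zeros(3)
        O = np.array([0.0, 2.9, 0.0])
        C = O + np.array([0.0, 1.23, 0.0])
        coords = np.array([C, O, N, H])
        hb = HBond(2, 3, 1, 0)
        assert detect(coords, [hb], HBondCriteria(3.5, 90.0))[0]
        assert not detect(coords, [hb], HBondCriteria(3.5, 90.0001))[0]

    def test_distance_boundary_inclusive(self):
        # |N - O| is exactly 3.5 in floating point
        N = np.zeros(3)
        H = np.array([0.0, 1.0, 0.0])
        O = np.array([0.0, 3.5, 0.0])
        C = O + np.array([0.0, 1.23, 0.0])
        coords = np.array([C, O, N, H])
        hb = HBond(2, 3, 1, 0)
        assert np.linalg.norm(N - O) == 3.5
        assert detect(coords, [hb], HBondCriteria(3.5, 120.0))[0]
        assert not detect(coords, [hb], HBondCriteria(3.4999, 120.0))[0]

    def test_empty_candidates(self):
        flags = detect(np.zeros((4, 3)), [], self.CRIT)
        assert flags.shape == (0,)

    def test_criteria_validation(self):
        with pytest.raises(ValueError):
            HBondCriteria(distance_cutoff=-1.0)
        with pytest.raises(ValueError):
            HBondCriteria(angle_cutoff=181.0)


class TestEnumerate:
    def test_two_residue_peptide_no_backbone_candidates(self):
        fx = make_fixture(FixtureSpec(kind="mini_helix", n_residues=5))
        # restrict to first two residues
        import dataclasses
        atoms = [dataclasses.replace(a) for a in fx.topology.atoms[:10]]
        bonds = [b for b in fx.topology.bonds if b.i < 10 and b.j < 10]
        two = pb.Topology(atoms, bonds)
        assert enumerate_candidates(two, scope="backbone") == []

    def test_helix_contains_all_i_to_i_plus_4(self, helix):
        n = helix.spec.n_residues
        cands = enumerate_candidates(helix.topology, scope="backbone")
        pairs = {(hb.donor // 5 + 1, hb.acceptor // 5 + 1) for hb in cands}
        for i in range(1, n - 3):
            assert (i + 4, i) in pairs
        flags = detect(helix.native, cands)
        detected = {(hb.donor // 5 + 1, hb.acceptor // 5 + 1)
                    for hb, f in zip(cands, flags) if f}
        assert detected == {(i + 4, i) for i in range(1, n - 3)}

    def test_toy_complex_exactly_designed_triples(self, toy):
        cands = enumerate_candidates(toy.topology, scope="protein_ligand")
        flags = detect(toy.native, cands)
        found = {(hb.donor, hb.hydrogen, hb.acceptor, hb.antecedent)
                 for hb, f in zip(cands, flags) if f}
        designed = {(hb.donor, hb.hydrogen, hb.acceptor, hb.antecedent)
                    for hb in toy.designed_hbonds}
        assert found == designed
        assert len(found) == 3

    def test_duplicate_free_and_deterministic(self, toy):
        a = enumerate_candidates(toy.topology, scope="all")
        b = enumerate_candidates(toy.topology, scope="all")
        assert a == b
        keys = [(hb.donor, hb.hydrogen, hb.acceptor) for hb in a]
        assert len(keys) == len(set(keys))


class TestNativeFraction:
    def test_native_copies_give_unity(self, helix):
        traj = make_trajectory(helix, 12, sigma=0.0)
        table = native_fraction_series(traj, helix.native, block=4)
        assert np.allclose(table["fraction"], 1.0)

    def test_half_broken_gives_half(self, helix):
        cands = enumerate_candidates(helix.topology, scope="backbone")
        flags = detect(helix.native, cands)
        native = [hb for hb, f in zip(cands, flags) if f]
        # break half the native bonds in every frame by moving acceptors
        coords = helix.native.copy()
        for hb in native[: len(native) // 2]:
            coords[hb.acceptor] += 50.0
        traj = pb.Trajectory(helix.topology, np.stack([coords] * 6))
        table = native_fraction_series(traj, helix.native, block=3)
        assert np.allclose(table["fraction"],
                           1.0 - (len(native) // 2) / len(native))

    def test_scripted_rupture_blocks_follow_schedule(self, toy):
        traj = make_trajectory(toy, 100, sigma=0.0, schedule=[(0, 50), (1, 50)])
        table = native_fraction_series(traj, toy.native, block=25,
                                       scope="protein_ligand")
        assert np.allclose(table["fraction"], [1.0, 1.0, 1.0 / 3.0, 1.0 / 3.0])

    def test_zero_native_bonds_is_error(self, toy):
        far = toy.native + np.where(
            (toy.topology.segments == "ligand")[:, None], 100.0, 0.0)
        traj = make_trajectory(toy, 4, sigma=0.0)
        with pytest.raises(ValueError):
            native_fraction_series(traj, far, scope="protein_ligand")


class TestCoulombEnergy:
    def test_zero_charges(self):
        coords = _linear_nho(2.9, 180.0)
        hb = HBond(2, 3, 1, 0)
        assert hbond_coulomb_energy(coords, hb, np.zeros(4)) == 0.0

    def test_hand_summed_oracle(self):
        coords = _linear_nho(3.0, 150.0)
        hb = HBond(2, 3, 1, 0)
        q = np.array([0.5, -0.5, -0.3, 0.3])  # C, O, N, H
        expected = 0.0
        for i in (0, 1):
            for j in (2, 3):
                r = np.linalg.norm(coords[i] - coords[j])
                expected += COULOMB_KCAL * q[i] * q[j] / r
        got = hbond_coulomb_energy(coords, hb, q)
        assert got == pytest.approx(expected, abs=1e-6)

    def test_bilinearity_doubling_charges(self):
        coords = _linear_nho(2.9, 170.0)
        hb = HBond(2, 3, 1, 0)
        q = np.array([0.5, -0.5, -0.3, 0.3])
        assert hbond_coulomb_energy(coords, hb, 2 * q) == pytest.approx(
            4 * hbond_coulomb_energy(coords, hb, q), rel=1e-12)

    def test_even_under_global_sign_flip(self):
        coords = _linear_nho(2.9, 170.0)
        hb = HBond(2, 3, 1, 0)
        q = np.array([0.5, -0.5, -0.3, 0.3])
        assert hbond_coulomb_energy(coords, hb, -q) == pytest.approx(
            hbond_coulomb_energy(coords, hb, q), rel=1e-12)

    def test_rigid_motion_invariance(self, rng):
        coords = _linear_nho(2.9, 160.0)
        hb = HBond(2, 3, 1, 0)
        q = np.array([0.5, -0.5, -0.3, 0.3])
        base = hbond_coulomb_energy(coords, hb, q)
        R = Rotation.random(random_state=7).as_matrix()
        moved = coords @ R.T + np.array([5.0, -3.0, 2.0])
        assert hbond_coulomb_energy(moved, hb, q) == pytest.approx(
            base, rel=1e-12)

    def test_clash_error(self):
        coords = _linear_nho(2.9, 180.0)
        coords[1] = coords[3] + 1e-3  # O on top of H
        hb = HBond(2, 3, 1, 0)
        with pytest.raises(ClashError):
            hbond_coulomb_energy(coords, hb, np.ones(4))

    def test_distinct_indices_required(self):
        with pytest.raises(ValueError):
            HBond(1, 1, 2, 3)


class TestOccupancy:
    def test_always_present(self):
        assert occupancy(np.ones(50, bool)) == 1.0

    def test_definition(self):
        flags = np.zeros(100, bool)
        flags[:34] = True
        assert occupancy(flags) == pytest.approx(0.34)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            occupancy(np.zeros(0, bool))

    def test_scripted_rupture_occupancy(self, toy):
        traj = make_trajectory(toy, 100, sigma=0.0, schedule=[(2, 40)])
        s = hbond_series(traj, toy.designed_hbonds[2])
        assert s.occupancy == pytest.approx(0.40)
        untouched = hbond_series(traj, toy.designed_hbonds[0])
        assert untouched.occupancy == 1.0

    def test_series_carries_energies(self, toy):
        traj = make_trajectory(toy, 10, sigma=0.0)
        s = hbond_series(traj, toy.designed_hbonds[0],
                         charges=toy.base.charges)
        assert s.energy.shape == (10,)
        assert np.all(s.energy < 0)


@given(st.lists(st.booleans(), min_size=1, max_size=200))
def test_occupancy_always_in_unit_interval(flags):
    assert 0.0 <= occupancy(np.array(flags)) <= 1.0
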