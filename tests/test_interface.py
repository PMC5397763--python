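"""Interface residues, hydrogen bonds, occupancy, pseudoenergies, hotspots."""

import numpy as np
import pytest

from interlock.interface import (
    EnergyParams,
    HBondCriteria,
    detect_hbonds,
    energy_time_series,
    hbond_occupancy,
    hotspots,
    interface_energies,
    interface_residues,
    min_distance_series,
)
from interlock.structio import Ensemble, Residue, Snapshot, make_atom
from interlock.synthetic_data import generate_ensemble
from conftest import point_snapshot, single_atom_residue


def two_chain_points(d):
    """Two single-atom residues on different chains, d Å apart."""
    return Snapshot(
        [
            single_atom_residue("A", 1, [0.0, 0.0, 0.0]),
            single_atom_residue("B", 1, [d, 0.0, 0.0]),
        ]
    )


def nh_residue(chain, number, pos):
    """Residue exposing a backbone-N donor."""
    return Residue(chain, number, "GLY", [make_atom("N", "N", pos)])


def o_residue(chain, number, pos):
    """Residue exposing a backbone-O acceptor."""
    return Residue(chain, number, "GLY", [make_atom("O", "O", pos)])


class TestInterfaceResidues:
    def test_boundary_distance_included(self):
        snap = two_chain_points(4.9)
        assert interface_residues(snap, "A", "B", cutoff=5.0) == [
            ("A", 1, ""),
            ("B", 1, ""),
        ]

    def test_separated_chains_give_empty_interface(self):
        assert interface_residues(two_chain_points(50.0), "A", "B") == []

    def test_symmetric_in_chain_arguments(self, toy_complex):
        assert interface_residues(toy_complex, "A", "B") == interface_residues(
            toy_complex, "B", "A"
        )

    def test_matches_brute_force_scan(self, toy_complex):
        cutoff = 5.0
        expected = set()
        for ra in toy_complex.chain("A"):
            for rb in toy_complex.chain("B"):
                xa, xb = ra.heavy_coords(), rb.heavy_coords()
                if np.sqrt(((xa[:, None] - xb[None]) ** 2).sum(-1).min()) <= cutoff:
                    expected |= {ra.key, rb.key}
        assert set(interface_residues(toy_complex, "A", "B", cutoff)) == expected

    def test_missing_chain_rejected(self, toy_complex):
        with pytest.raises(KeyError):
            interface_residues(toy_complex, "A", "Z")


class TestDetectHbonds:
    def test_distance_criterion(self):
        near = Snapshot([nh_residue("A", 1, [0, 0, 0]), o_residue("B", 1, [3.2, 0, 0])])
        far = Snapshot([nh_residue("A", 1, [0, 0, 0]), o_residue("B", 1, [3.8, 0, 0])])
        assert len(detect_hbonds(near)) == 1
        assert detect_hbonds(far) == []

    def test_planted_hbond_detected(self, toy_complex, toy_spec):
        bonds = detect_hbonds(toy_complex)
        found = {(b.donor_residue[1], b.acceptor_residue[1]) for b in bonds}
        assert found == set(map(tuple, toy_spec.hbond_pairs))

    def test_angle_criterion_applies_only_with_hydrogens(self):
        donor_pos, acceptor_pos = np.zeros(3), np.array([3.0, 0.0, 0.0])
        good_h = make_atom("H", "H", [1.0, 0.0, 0.0])  # points at the acceptor
        bad_h = make_atom("H", "H", [-1.0, 0.0, 0.0])  # points away
        for h, expected in ((good_h, 1), (bad_h, 0)):
            snap = Snapshot(
                [
                    Residue("A", 1, "GLY", [make_atom("N", "N", donor_pos), h]),
                    o_residue("B", 1, acceptor_pos),
                ]
            )
            assert len(detect_hbonds(snap)) == expected

    def test_matches_brute_force_donor_acceptor_scan(self, toy_complex):
        from interlock.interface import _donor_acceptor_atoms

        criteria = HBondCriteria()
        expected = set()
        for rd in toy_complex:
            donors, _ = _donor_acceptor_atoms(rd)
            for ra in toy_complex:
                if ra.chain_id == rd.chain_id:
                    continue
                _, acceptors = _donor_acceptor_atoms(ra)
                for d in donors:
                    for a in acceptors:
                        if np.linalg.norm(d.position - a.position) <= criteria.da_cutoff:
                            expected.add((rd.key, ra.key, d.name, a.name))
        got = {
            (b.donor_residue, b.acceptor_residue, b.donor_atom, b.acceptor_atom)
            for b in detect_hbonds(toy_complex, criteria)
        }
        assert got == expected

    def test_proline_does_not_donate(self):
        snap = Snapshot(
            [
                Residue("A", 1, "PRO", [make_atom("N", "N", [0, 0, 0])]),
                o_residue("B", 1, [3.0, 0, 0]),
            ]
        )
        assert detect_hbonds(snap) == []


class TestOccupancy:
    def test_seven_of_ten_frames_is_stable(self, toy_complex, toy_spec):
        ens = generate_ensemble(toy_complex, 10, noise_sd=0.0, broken_fraction=0.3, seed=0)
        records = hbond_occupancy(ens)
        assert len(records) == len(toy_spec.hbond_pairs)
        assert records[0].occupancy == pytest.approx(0.70)
        assert records[0].stable

    def test_five_of_ten_frames_is_not_stable(self, toy_complex):
        ens = generate_ensemble(toy_complex, 10, noise_sd=0.0, broken_fraction=0.5, seed=0)
        records = hbond_occupancy(ens)
        assert records[0].occupancy == pytest.approx(0.50)
        assert not records[0].stable  # strictly > 50% required

    def test_never_formed_pairs_not_reported(self, toy_complex):
        ens = generate_ensemble(toy_complex, 5, noise_sd=0.0, broken_fraction=1.0, seed=0)
        assert hbond_occupancy(ens) == []

    def test_single_frame_occupancy_is_zero_or_one(self, toy_complex):
        ens = generate_ensemble(toy_complex, 1, noise_sd=0.0, seed=0)
        for rec in hbond_occupancy(ens):
            assert rec.occupancy in (0.0, 1.0)


class TestMinDistanceSeries:
    def test_identical_frames_give_constant_series(self, toy_complex, toy_spec):
        ens = generate_ensemble(toy_complex, 4, noise_sd=0.0, seed=0)
        a, b = toy_spec.contact_pairs[0]
        series = min_distance_series(ens, (("A", a, ""), ("B", b, "")))
        assert np.allclose(series, series[0])

    def test_single_atom_pair_distance(self):
        ens = Ensemble([two_chain_points(6.0)])
        series = min_distance_series(ens, (("A", 1, ""), ("B", 1, "")))
        assert series[0] == pytest.approx(6.0)

    def test_matches_per_frame_brute_force(self, toy_ensemble, toy_spec):
        a, b = toy_spec.contact_pairs[1]
        series = min_distance_series(toy_ensemble, (("A", a, ""), ("B", b, "")))
        for k, snap in enumerate(toy_ensemble):
            xa = snap.residue(("A", a, "")).heavy_coords()
            xb = snap.residue(("B", b, "")).heavy_coords()
            expected = np.sqrt(((xa[:, None] - xb[None]) ** 2).sum(-1).min())
            assert series[k] == pytest.approx(expected)

    def test_unknown_residue_rejected(self, toy_ensemble):
        with pytest.raises(KeyError):
            min_distance_series(toy_ensemble, (("A", 999, ""), ("B", 1, "")))


def random_interface_snapshot(seed):
    """Two chains of mixed residue types scattered around a loose interface."""
    rng = np.random.default_rng(seed)
    names = ["ALA", "ASP", "LYS", "GLN", "SER", "ARG", "GLU"]
    atoms_for = {
        "ALA": ["CB"], "ASP": ["CB", "OD1", "OD2"], "LYS": ["CB", "NZ"],
        "GLN": ["CB", "OE1", "NE2"], "SER": ["CB", "OG"],
        "ARG": ["CB", "NE", "NH1", "NH2"], "GLU": ["CB", "OE1", "OE2"],
    }
    residues = []
    for chain, z0 in (("A", 0.0), ("B", 4.5)):
        for k in range(6):
            name = names[int(rng.integers(len(names)))]
            centre = np.array([k * 5.0, rng.normal(0, 1.0), z0 + rng.normal(0, 0.5)])
            atoms = [make_atom("CA", "C", centre), make_atom("N", "N", centre + rng.normal(0, 0.8, 3)),
                     make_atom("O", "O", centre + rng.normal(0, 0.8, 3))]
            for nm in atoms_for[name]:
                el = nm[0] if nm[0] in "NOC" else "C"
                atoms.append(make_atom(nm, el, centre + rng.normal(0, 1.0, 3)))
            residues.append(Residue(chain, k + 1, name, atoms))
    return Snapshot(residues)


class TestEnergies:
    def test_separated_chains_score_zero(self):
        snap = two_chain_points(50.0)
        e = interface_energies(snap, "A", "B")
        assert e.hbond_energy == e.electrostatic_energy == e.vdw_energy == 0.0
        assert e.n_interface_residues == 0
        assert np.isnan(e.normalized_per_residue)

    def test_single_hbond_counts_once(self):
        snap = Snapshot(
            [nh_residue("A", 1, [0, 0, 0]), o_residue("B", 1, [3.2, 0, 0])]
        )
        e = interface_energies(snap, "A", "B")
        assert e.hbond_energy == pytest.approx(-1.5)

    def test_electrostatic_signs(self):
        asp = Residue("A", 1, "ASP", [make_atom("OD1", "O", [0, 0, 0]),
                                      make_atom("OD2", "O", [0.5, 0, 0])])
        lys = Residue("B", 1, "LYS", [make_atom("NZ", "N", [4.0, 0, 0])])
        arg = Residue("B", 1, "ARG", [make_atom("NH1", "N", [4.0, 0, 0]),
                                      make_atom("NH2", "N", [4.5, 0, 0]),
                                      make_atom("NE", "N", [4.25, 1.0, 0])])
        lys_a = Residue("A", 1, "LYS", [make_atom("NZ", "N", [0, 0, 0])])
        attract = interface_energies(Snapshot([asp, lys]), "A", "B")
        repulse = interface_energies(Snapshot([lys_a, arg]), "A", "B")
        assert attract.electrostatic_energy == pytest.approx(-1.0)
        assert repulse.electrostatic_energy == pytest.approx(+1.0)

    def test_total_is_sum_of_terms_and_attribution_conserves(self):
        for seed in range(20):
            snap = random_interface_snapshot(seed)
            e = interface_energies(snap, "A", "B")
            assert e.total_stabilizing == pytest.approx(
                e.hbond_energy + e.electrostatic_energy + e.vdw_energy, abs=1e-9
            )
            assert sum(e.per_residue.values()) == pytest.approx(
                e.total_stabilizing, abs=1e-6
            )

    def test_vdw_window(self):
        inside = two_chain_points(4.0)
        below = two_chain_points(2.5)
        beyond = two_chain_points(5.5)
        assert interface_energies(inside, "A", "B").vdw_energy == pytest.approx(-0.2)
        assert interface_energies(below, "A", "B").vdw_energy == 0.0
        assert interface_energies(beyond, "A", "B").vdw_energy == 0.0


class TestEnergyTimeSeries:
    def test_broken_frames_score_zero(self, toy_complex):
        ens = generate_ensemble(toy_complex, 10, noise_sd=0.0, broken_fraction=0.3, seed=0)
        series = energy_time_series(ens, "A", "B")
        totals = [e.total_stabilizing for _, e in series]
        assert all(t < 0 for t in totals[:7])
        assert all(t == 0 for t in totals[7:])

    def test_stride(self, toy_ensemble):
        assert len(energy_time_series(toy_ensemble, "A", "B", stride=1)) == 10
        assert len(energy_time_series(toy_ensemble, "A", "B", stride=10)) == 1
        frames = [k for k, _ in energy_time_series(toy_ensemble, "A", "B", stride=3)]
        assert frames == [0, 3, 6, 9]


class TestHotspots:
    def strong_pair_snapshot(self):
        # residue A1 engaged in many vdW contacts: large attributed energy
        atoms_a = [make_atom(f"C{k}", "C", [0.2 * k, 0, 0]) for k in range(12)]
        atoms_b = [make_atom(f"C{k}", "C", [0.2 * k, 0, 4.0]) for k in range(12)]
        return Snapshot(
            [Residue("A", 1, "ALA", atoms_a), Residue("B", 1, "ALA", atoms_b)]
        )

    def test_strongly_bonded_residue_flagged(self):
        snap = self.strong_pair_snapshot()
        e = interface_energies(snap, "A", "B")
        assert e.per_residue[("A", 1, "")] <= -2.0
        assert hotspots(snap, "A", "B") == [("A", 1, ""), ("B", 1, "")]

    def test_no_interface_no_hotspots(self):
        assert hotspots(two_chain_points(50.0), "A", "B") == []

    def test_threshold_monotonicity(self):
        snap = self.strong_pair_snapshot()
        loose = set(hotspots(snap, "A", "B", params=EnergyParams(hotspot_threshold=-1.0)))
        strict = set(hotspots(snap, "A", "B", params=EnergyParams(hotspot_threshold=-3.0)))
        assert strict <= loose
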