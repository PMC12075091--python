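"""RDF, H-bond detection, residence intervals and interaction scores."""

import numpy as np
import pytest

from aquaredox import hydration as hyd
from aquaredox import synthetic_trajectory as straj
from aquaredox.hydration import HBondCriteria, RDFProfile

from oracles import brute_force_score, direct_shell_count


def _two_atom_traj(d, box=20.0):
    topo = straj.Topology(["S", "O"], ["sulfur", "water_oxygen"], [0, 1], {})
    frames = np.zeros((1, 2, 3))
    frames[0, 1, 0] = d
    return straj.Trajectory(box=np.full(3, box), frames=frames, topology=topo)


def _hbond_frame(dist, angle_deg):
    """S at origin; water O at ``dist`` on x; O-H tilted so the O-H...S
    angle at H equals ``angle_deg``."""
    topo = straj.Topology(
        ["S", "O", "H", "H"],
        ["sulfur", "water_oxygen", "water_hydrogen", "water_hydrogen"],
        [0, 1, 1, 1], {2: 1, 3: 1},
    )
    o = np.array([dist, 0.0, 0.0])
    s = np.zeros(3)
    # place H on the segment O->S, then rotate by (180 - angle) about z
    alpha = np.deg2rad(180.0 - angle_deg)
    to_s = (s - o) / np.linalg.norm(s - o)
    rot = np.array([
        [np.cos(alpha), -np.sin(alpha), 0],
        [np.sin(alpha), np.cos(alpha), 0],
        [0, 0, 1],
    ])
    # direction from H to O must make the requested angle with H to S;
    # simplest: put H at o + 0.96 * R(alpha) @ to_s
    h1 = o + 0.9572 * (rot @ to_s)
    h2 = o + np.array([0.0, 0.0, 0.9572])
    frame = np.stack([s, o, h1, h2])
    return frame + 10.0, topo   # shift into a 20 A box interior


class TestRDF:
    def test_ideal_gas_limit(self):
        traj = straj.ideal_gas_frames(500, n_frames=2000, seed=2)
        rdf = hyd.compute_rdf(traj, "sulfur", "water_oxygen", bin_width=0.1)
        sel = rdf.bin_centers >= 3.0
        assert np.mean(np.abs(rdf.g[sel] - 1.0)) <= 0.03

    def test_two_fixed_atoms_single_occupied_bin(self):
        traj = _two_atom_traj(4.25)
        rdf = hyd.compute_rdf(traj, "sulfur", "water_oxygen", bin_width=0.5,
                              r_max=10.0)
        occupied = np.nonzero(rdf.g)[0]
        assert occupied.tolist() == [8]        # bin [4.0, 4.5)

    def test_minimum_image_distance_used(self):
        """Atoms straddling the boundary register at 3 A, not box - 3."""
        topo = straj.Topology(["S", "O"], ["sulfur", "water_oxygen"],
                              [0, 1], {})
        frames = np.zeros((1, 2, 3))
        frames[0, 0, 0] = 0.5
        frames[0, 1, 0] = 17.5                 # 3 A across the 20 A boundary
        traj = straj.Trajectory(box=np.full(3, 20.0), frames=frames,
                                topology=topo)
        rdf = hyd.compute_rdf(traj, "sulfur", "water_oxygen", bin_width=0.5)
        assert rdf.g[np.nonzero(rdf.g)[0][0]] > 0
        assert rdf.bin_centers[np.nonzero(rdf.g)[0][0]] == pytest.approx(3.25)

    def test_r_max_beyond_half_box_rejected(self):
        traj = _two_atom_traj(4.0)
        with pytest.raises(ValueError, match="r_max"):
            hyd.compute_rdf(traj, "sulfur", "water_oxygen", r_max=15.0)

    def test_missing_role_rejected(self):
        traj = _two_atom_traj(4.0)
        with pytest.raises(ValueError, match="role"):
            hyd.compute_rdf(traj, "sulfur", "sulfur_hydrogen")


class TestFirstPeakAndCoordination:
    def test_constructed_gaussian_peak_located(self):
        r = np.arange(0.05, 10.0, 0.1)
        g = np.exp(-0.5 * ((r - 3.8) / 0.3) ** 2)
        prof = RDFProfile(r, g, 0.1, "sulfur", "water_oxygen", 1, 0.01)
        r_peak, g_peak = hyd.first_peak(prof)
        assert abs(r_peak - 3.8) <= 0.1
        assert g_peak == pytest.approx(1.0, abs=0.1)

    def test_monotone_profile_is_error(self):
        r = np.arange(0.05, 10.0, 0.1)
        prof = RDFProfile(r, np.exp(-r), 0.1, "s", "o", 1, 0.01)
        with pytest.raises(ValueError, match="maximum"):
            hyd.first_peak(prof)

    def test_scheduled_shell_gives_first_peak_in_design_range(self,
                                                              small_thiol_traj):
        traj, _ = small_thiol_traj
        rdf = hyd.compute_rdf(traj, "sulfur", "water_oxygen", bin_width=0.2,
                              r_max=10.0)
        r_peak, _ = hyd.first_peak(rdf)
        assert 3.0 <= r_peak <= 3.8

    def test_ideal_gas_coordination_matches_analytic(self):
        traj = straj.ideal_gas_frames(400, n_frames=300, seed=3)
        rdf = hyd.compute_rdf(traj, "sulfur", "water_oxygen", bin_width=0.1)
        rho = 400 / 30.0**3
        for r_cut in (5.0, 8.0):
            expected = rho * 4 / 3 * np.pi * r_cut**3
            assert hyd.coordination_number(rdf, r_cut) == pytest.approx(
                expected, rel=0.05)

    def test_integral_matches_direct_count(self, small_thiol_traj):
        traj, _ = small_thiol_traj
        rdf = hyd.compute_rdf(traj, "sulfur", "water_oxygen", bin_width=0.1,
                              r_max=10.0)
        r_cut = 4.95          # bin edge, so integral and count cut agree
        integral = hyd.coordination_number(rdf, r_cut)
        direct = direct_shell_count(traj, r_cut)
        assert integral == pytest.approx(direct, rel=0.02, abs=0.02)


class TestDetectHbonds:
    def test_inside_defaults_one_bond(self):
        frame, topo = _hbond_frame(3.2, 178.0)
        bonds = hyd.detect_hbonds(frame, topo, box=np.full(3, 20.0))
        ohs = [b for b in bonds if b[2] == "OH-S"]
        assert len(ohs) == 1
        assert ohs[0][3] == pytest.approx(3.2, abs=1e-6)
        assert 170.0 <= ohs[0][4] <= 180.0

    def test_bent_geometry_rejected(self):
        frame, topo = _hbond_frame(3.2, 120.0)
        bonds = hyd.detect_hbonds(frame, topo, box=np.full(3, 20.0))
        assert [b for b in bonds if b[2] == "OH-S"] == []

    def test_beyond_cutoff_rejected(self):
        frame, topo = _hbond_frame(4.3, 178.0)
        bonds = hyd.detect_hbonds(frame, topo, box=np.full(3, 20.0))
        assert [b for b in bonds if b[2] == "OH-S"] == []

    def test_disulfide_never_yields_sh_o(self, small_disulfide_traj):
        traj, _ = small_disulfide_traj
        for f in range(0, traj.n_frames, 25):
            bonds = hyd.detect_hbonds(traj.frames[f], traj.topology, traj.box)
            assert all(b[2] != "SH-O" for b in bonds)

    def test_raising_cutoff_never_loses_bonds(self, small_thiol_traj):
        traj, _ = small_thiol_traj
        loose = HBondCriteria(max_distance={("O", "O"): 3.5, ("O", "S"): 4.5})
        for f in (0, 50, 100):
            tight_set = {b[:3] for b in hyd.detect_hbonds(
                traj.frames[f], traj.topology, traj.box)}
            loose_set = {b[:3] for b in hyd.detect_hbonds(
                traj.frames[f], traj.topology, traj.box, loose)}
            assert tight_set <= loose_set

    def test_criteria_validation(self):
        with pytest.raises(ValueError):
            HBondCriteria(max_distance={("O", "S"): -1.0})
        with pytest.raises(ValueError):
            HBondCriteria(max_angle_deviation_deg=95.0)


class TestIntervalsAndScores:
    def test_hand_built_interval_decomposition(self):
        """Bonded frames {3,4,5,9} decompose into runs [3-5] and [9]."""
        sched = straj.BondSchedule(intervals=[(3, 0, 3, 5), (3, 0, 9, 9)])
        traj, _ = straj.generate_solvation_trajectory(
            "thiol", n_waters=6, n_frames=12, schedule=sched, seed=5,
        )
        ivs = hyd.bond_intervals(traj)
        key = (3, 0, "OH-S")
        assert ivs.intervals[key] == [(3, 5), (9, 9)]
        assert sorted(ivs.lengths("OH-S")) == [1, 3]

    def test_score_weighting_and_persistence(self):
        ivs = hyd.BondIntervalSet(
            intervals={(3, 0, "OH-S"): [(0, 2), (10, 14)]}, window=(0, 19)
        )
        assert hyd.interaction_score(ivs, "OH-S").value == 8.0
        assert hyd.interaction_score(ivs, "OH-S", min_persistence=4).value == 5.0
        assert hyd.interaction_score(
            ivs, "OH-S", weight_exponent=1.0).value == 34.0

    def test_raising_persistence_never_raises_score(self, small_thiol_traj):
        traj, _ = small_thiol_traj
        ivs = hyd.bond_intervals(traj)
        values = [hyd.interaction_score(ivs, "OH-S", min_persistence=m).value
                  for m in (1, 2, 4, 8)]
        assert values == sorted(values, reverse=True)

    def test_matches_brute_force_oracle_small(self, small_thiol_traj):
        traj, _ = small_thiol_traj
        ivs = hyd.bond_intervals(traj)
        for direction in ("OH-S", "SH-O"):
            ours = hyd.interaction_score(ivs, direction).value
            assert ours == brute_force_score(traj, direction)

    def test_window_restricts_counting(self, small_thiol_traj):
        traj, sched = small_thiol_traj
        full = hyd.bond_intervals(traj)
        half = hyd.bond_intervals(traj, window=(75, 149))
        assert (hyd.interaction_score(half, "OH-S").value
                <= hyd.interaction_score(full, "OH-S").value)
        with pytest.raises(ValueError):
            hyd.bond_intervals(traj, window=(100, 99))

    def test_atom_relabeling_invariance(self, small_thiol_traj):
        """Scores are invariant under a role-preserving atom reindexing."""
        traj, _ = small_thiol_traj
        n = traj.topology.n_atoms
        perm = np.concatenate([[0, 1], 2 + np.roll(np.arange(n - 2), 3)])
        inv = np.argsort(perm)
        topo = traj.topology
        new_topo = straj.Topology(
            elements=[topo.elements[i] for i in perm],
            roles=[topo.roles[i] for i in perm],
            molecule_ids=[topo.molecule_ids[i] for i in perm],
            bonds={int(inv[h]): int(inv[a]) for h, a in topo.bonds.items()},
        )
        new_traj = straj.Trajectory(
            box=traj.box, frames=traj.frames[:, perm], topology=new_topo
        )
        for direction in ("OH-S", "SH-O"):
            a = hyd.interaction_score(hyd.bond_intervals(traj), direction)
            b = hyd.interaction_score(hyd.bond_intervals(new_traj), direction)
            assert a.value == b.value


class TestPerSulfurSummary:
    def test_simple_normalization(self):
        out = hyd.per_sulfur_summary({"OH-S": 10.0, "SH-O": 0.0}, n_sulfur=2)
        assert out["per_sulfur"]["OH-S"] == 5.0
        assert out["total_per_sulfur"] == 5.0

    def test_zero_bonds_and_invalid_n(self):
        out = hyd.per_sulfur_summary({}, n_sulfur=1)
        assert out["total"] == 0.0
        with pytest.raises(ValueError):
            hyd.per_sulfur_summary({}, n_sulfur=0)

    def test_thiol_to_disulfide_ratio_is_two(self):
        """Equal per-direction occupancy per sulfur: the thiol's combined
        per-sulfur score (donor + acceptor) is twice the disulfide's
        (acceptor only)."""
        thiol, _ = straj.generate_solvation_trajectory(
            "thiol", n_waters=60, n_frames=400, occupancy=0.5, seed=31)
        disu, _ = straj.generate_solvation_trajectory(
            "disulfide", n_waters=60, n_frames=400, occupancy=0.5, seed=32)
        def combined(traj):
            ivs = hyd.bond_intervals(traj)
            scores = {d: hyd.interaction_score(ivs, d) for d in ("OH-S", "SH-O")}
            n_s = traj.topology.atoms_with_role("sulfur").size
            return hyd.per_sulfur_summary(scores, n_s)["total_per_sulfur"]
        ratio = combined(thiol) / combined(disu)
        assert ratio == pytest.approx(2.0, rel=0.15)
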