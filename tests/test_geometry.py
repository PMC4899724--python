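"""Filter geometry, superposition and steered-pull mechanics."""

import numpy as np
import pytest
from dataclasses import replace

from kvgating import (
    Frame,
    PullSchedule,
    align_to_reference,
    ca_distance_series,
    carbonyl_displacement_stats,
    com_pair_distance,
    detect_collapse,
    filter_diameter,
    filter_diameter_series,
    ion_occupancy,
    pull_force,
    read_trajectory,
    write_trajectory,
)
from kvgating.geometry import DiameterSeries, _alignment_selection
from kvgating.synthetic import gen_filter_trajectory

RNG = np.random.default_rng(42)


def quaternion_superpose(x, y):
    """Independent superposition oracle (Horn's quaternion eigenvector method).

    Returns the RMSD after optimally superposing x onto y.
    """
    xc = x - x.mean(axis=0)
    yc = y - y.mean(axis=0)
    sxx, sxy, sxz = (xc[:, 0] * yc.T).sum(1)
    syx, syy, syz = (xc[:, 1] * yc.T).sum(1)
    szx, szy, szz = (xc[:, 2] * yc.T).sum(1)
    k = np.array(
        [
            [sxx + syy + szz, szy - syz, sxz - szx, syx - sxy],
            [szy - syz, sxx - syy - szz, sxy + syx, szx + sxz],
            [sxz - szx, sxy + syx, -sxx + syy - szz, syz + szy],
            [syx - sxy, szx + sxz, syz + szy, -sxx - syy + szz],
        ]
    )
    lam_max = np.linalg.eigvalsh(k)[-1]
    e = (xc**2).sum() + (yc**2).sum() - 2.0 * lam_max
    return np.sqrt(max(e, 0.0) / len(x))


def single_atom_frame(positions, residue=445, atom="O"):
    """Four chains with one atom each at the given xyz positions."""
    chains = ["A", "B", "C", "D"]
    return Frame(
        chain_id=np.array(chains),
        res_id=np.full(4, residue),
        res_name=np.array(["GLY"] * 4),
        atom_name=np.array([atom] * 4),
        element=np.array([atom[0]] * 4),
        coords=np.asarray(positions, dtype=float),
    )


def rigid_motion(frame, angle_deg=90.0, translation=(1.0, -2.0, 0.5)):
    th = np.deg2rad(angle_deg)
    rot = np.array([[np.cos(th), -np.sin(th), 0], [np.sin(th), np.cos(th), 0], [0, 0, 1]])
    return replace(frame, coords=frame.coords @ rot.T + np.asarray(translation))


class TestComPairDistance:
    def test_single_atom_square(self):
        fr = single_atom_frame([[1, 0, 0], [0, 1, 0], [-1, 0, 0], [0, -1, 0]])
        d = com_pair_distance(fr, 445)
        assert d == pytest.approx((2.0, 2.0))

    def test_translation_invariance(self):
        fr = single_atom_frame(RNG.normal(size=(4, 3)))
        assert com_pair_distance(rigid_motion(fr), 445) == pytest.approx(
            com_pair_distance(fr, 445)
        )

    def test_equal_mass_two_atom_com(self):
        """COM of two equal-mass atoms is their midpoint."""
        coords = []
        for center in ([1, 0, 0], [0, 1, 0], [-1, 0, 0], [0, -1, 0]):
            c = np.asarray(center, dtype=float)
            coords += [c + [0, 0, 0.2], c - [0, 0, 0.2]]
        fr = Frame(
            chain_id=np.repeat(["A", "B", "C", "D"], 2),
            res_id=np.full(8, 416),
            res_name=np.array(["PHE"] * 8),
            atom_name=np.array(["CB", "CG"] * 4),
            element=np.array(["C"] * 8),
            coords=np.array(coords),
        )
        assert com_pair_distance(fr, 416) == pytest.approx((2.0, 2.0))

    def test_missing_residue_named(self):
        fr = single_atom_frame(np.eye(4, 3))
        with pytest.raises(ValueError, match="999"):
            com_pair_distance(fr, 999)


class TestPullForce:
    def test_printed_reference_point(self):
        """k = 2000 kJ/mol/nm^2 gives 200 kJ/mol/nm at 0.1 nm displacement."""
        sched = PullSchedule(force_constant=2000.0, rate=0.002, reference_0=1.0)
        force, ref = pull_force(sched, time=0.0, current_distance=0.9)
        assert force == pytest.approx(200.0)
        assert ref == pytest.approx(1.0)

    def test_zero_displacement_zero_force(self):
        sched = PullSchedule(2000.0, 0.002, 1.0)
        assert pull_force(sched, 10.0, 1.0 + 0.002 * 10.0)[0] == pytest.approx(0.0)

    def test_per_residue_speed_is_half_rate(self):
        assert PullSchedule(2000.0, 0.002, 1.0).per_residue_speed == pytest.approx(0.001)

    def test_linearity(self):
        s1 = PullSchedule(1000.0, 0.0, 1.0)
        s2 = PullSchedule(2000.0, 0.0, 1.0)
        f1 = pull_force(s1, 0.0, 0.8)[0]
        assert pull_force(s2, 0.0, 0.8)[0] == pytest.approx(2 * f1)
        assert pull_force(s1, 0.0, 0.6)[0] == pytest.approx(2 * f1)


class TestAlignment:
    @pytest.fixture(scope="class")
    @staticmethod
    def base_frame():
        return gen_filter_trajectory(n_frames=2, jitter_sigma=0.0).frames[0]

    def test_identity(self, base_frame):
        aligned, rmsd = align_to_reference(base_frame, base_frame)
        assert rmsd < 1e-12
        assert np.allclose(aligned.coords, base_frame.coords)

    def test_rigid_motion_recovered(self, base_frame):
        moved = rigid_motion(base_frame)
        aligned, rmsd = align_to_reference(moved, base_frame)
        assert rmsd < 1e-9
        assert np.allclose(aligned.coords, base_frame.coords, atol=1e-9)

    def test_noisy_rmsd_matches_quaternion_oracle(self, base_frame):
        """Kabsch RMSD equals the independent quaternion-method RMSD."""
        rng = np.random.default_rng(7)
        noisy = replace(
            base_frame, coords=base_frame.coords + rng.normal(0, 0.02, base_frame.coords.shape)
        )
        moved = rigid_motion(noisy, angle_deg=37.0, translation=(0.3, 0.1, -0.2))
        aligned, rmsd = align_to_reference(moved, base_frame)
        sel_m = _alignment_selection(moved, range(441, 447), ("N", "CA", "C", "O"))
        sel_r = _alignment_selection(base_frame, range(441, 447), ("N", "CA", "C", "O"))
        oracle = quaternion_superpose(moved.coords[sel_m], base_frame.coords[sel_r])
        assert rmsd == pytest.approx(oracle, rel=1e-9)
        # least-squares optimality: no rigid motion does better than the oracle
        assert rmsd <= oracle + 1e-12

    def test_missing_selection_atom_reported(self, base_frame):
        mask = ~(
            (base_frame.chain_id == "B")
            & (base_frame.res_id == 444)
            & (base_frame.atom_name == "CA")
        )
        broken = Frame(
            chain_id=base_frame.chain_id[mask],
            res_id=base_frame.res_id[mask],
            res_name=base_frame.res_name[mask],
            atom_name=base_frame.atom_name[mask],
            element=base_frame.element[mask],
            coords=base_frame.coords[mask],
        )
        with pytest.raises(ValueError, match="444"):
            align_to_reference(broken, base_frame)


class TestFilterDiameter:
    def test_square_ring(self):
        fr = single_atom_frame(
            [[0.25, 0, 1.2], [0, 0.25, 1.2], [-0.25, 0, 1.2], [0, -0.25, 1.2]]
        )
        assert filter_diameter(fr, 445) == pytest.approx(0.5)

    def test_distorted_square_mean(self):
        fr = single_atom_frame(
            [[0.25, 0, 0], [0, 0.35, 0], [-0.25, 0, 0], [0, -0.35, 0]]
        )
        assert filter_diameter(fr, 445) == pytest.approx(0.6)

    def test_programmed_widening_recovered(self):
        traj = gen_filter_trajectory(n_frames=11, widening_schedule={445: 0.01})
        series = filter_diameter_series(list(traj.frames), 445)
        assert series.diameters[-1] - series.diameters[0] == pytest.approx(0.1, abs=1e-9)

    def test_agrees_with_bruteforce_pairwise(self):
        """Opposing-pair mean equals a direct pairwise-distance computation."""
        traj = gen_filter_trajectory(n_frames=3, jitter_sigma=0.02, seed=5)
        fr = traj.frames[1]
        for pos in (443, 445):
            pts = {
                ch: fr.coords[fr.select(chain=ch, res_id=pos, atom_name="O")][0]
                for ch in "ABCD"
            }
            brute = 0.5 * (
                np.linalg.norm(pts["A"] - pts["C"]) + np.linalg.norm(pts["B"] - pts["D"])
            )
            assert filter_diameter(fr, pos) == pytest.approx(brute, rel=1e-12)


class TestCaSeries:
    def test_static_trajectory_constant(self):
        traj = gen_filter_trajectory(n_frames=5)
        series = ca_distance_series(list(traj.frames))
        for s in series.values():
            assert np.allclose(s.diameters, s.diameters[0])

    def test_localized_change_stays_local(self):
        traj = gen_filter_trajectory(n_frames=11, widening_schedule={443: 0.01})
        series = ca_distance_series(list(traj.frames), positions=(443, 445))
        assert series[443].diameters[-1] > series[443].diameters[0] + 0.05
        assert np.allclose(series[445].diameters, series[445].diameters[0])

    def test_per_frame_rotation_removed_by_alignment(self):
        traj = gen_filter_trajectory(n_frames=6)
        frames = [rigid_motion(f, angle_deg=15.0 * i) for i, f in enumerate(traj.frames)]
        ref = traj.frames[0]
        aligned = [align_to_reference(f, ref)[0] for f in frames]
        series = ca_distance_series(aligned, positions=(445,))
        assert np.allclose(series[445].diameters, series[445].diameters[0], atol=1e-9)


class TestDisplacementStats:
    def test_identical_frames_zero(self):
        traj = gen_filter_trajectory(n_frames=4)
        mean, se = carbonyl_displacement_stats(list(traj.frames))
        assert mean == pytest.approx(0.0, abs=1e-12)
        assert se == pytest.approx(0.0, abs=1e-12)

    def test_programmed_uniform_widening(self):
        traj = gen_filter_trajectory(n_frames=2)
        ref = traj.frames[0]
        widened = gen_filter_trajectory(
            n_frames=2, widening_schedule={443: 0.05, 444: 0.05, 445: 0.05}
        ).frames[1]
        mean, _ = carbonyl_displacement_stats([ref, widened], reference=ref)
        assert mean == pytest.approx(0.025, abs=1e-9)  # frame 0 contributes 0

    def test_control_jitter_below_criterion(self):
        """A jitter-only control stays under the 0.02 nm displacement criterion."""
        traj = gen_filter_trajectory(n_frames=40, jitter_sigma=0.01, seed=11)
        mean, se = carbonyl_displacement_stats(list(traj.frames))
        assert mean < 0.02

    def test_too_few_frames_rejected(self):
        traj = gen_filter_trajectory(n_frames=2)
        with pytest.raises(ValueError):
            carbonyl_displacement_stats([traj.frames[0]])


class TestDetectCollapse:
    def test_programmed_step_at_229(self):
        """A programmed abrupt widening at frame 229 is located exactly."""
        traj = gen_filter_trajectory(
            n_frames=260, collapse_frame=229, jitter_sigma=0.005, seed=2
        )
        series = filter_diameter_series(list(traj.frames), 445)
        assert detect_collapse(series, threshold=0.05, window=10) == 229

    def test_flat_noisy_series_none(self):
        rng = np.random.default_rng(0)
        series = DiameterSeries(
            445, np.arange(100.0), 0.5 + rng.normal(0, 0.005, 100)
        )
        assert detect_collapse(series, threshold=0.05, window=10) is None

    def test_step_at_first_eligible_frame(self):
        d = np.concatenate([np.full(10, 0.5), np.full(30, 0.7)])
        series = DiameterSeries(445, np.arange(40.0), d)
        assert detect_collapse(series, threshold=0.05, window=10) == 10

    def test_short_series_rejected(self):
        series = DiameterSeries(445, np.arange(5.0), np.full(5, 0.5))
        with pytest.raises(ValueError):
            detect_collapse(series, window=10)


class TestIonOccupancy:
    def test_resting_counts_and_no_departure(self):
        traj = gen_filter_trajectory(n_frames=12)
        occ = ion_occupancy(list(traj.frames))
        assert np.all(occ.counts == 2)
        assert occ.departure_frame is None

    def test_programmed_exit_detected(self):
        traj = gen_filter_trajectory(n_frames=30, ion_exit_frame=17)
        occ = ion_occupancy(list(traj.frames), window=5)
        assert occ.departure_frame == 17

    def test_sodium_outside_filter(self):
        traj = gen_filter_trajectory(n_frames=3)
        occ = ion_occupancy(list(traj.frames), ion="NA")
        assert np.all(occ.counts == 0)

    def test_no_ions_rejected(self):
        fr = single_atom_frame(np.eye(4, 3) * 0.2)
        with pytest.raises(ValueError):
            ion_occupancy([fr], ion="K")


class TestPdbRoundTrip:
    def test_write_read_preserves_geometry(self, tmp_path):
        traj = gen_filter_trajectory(n_frames=4, jitter_sigma=0.01, seed=9)
        path = tmp_path / "traj.pdb"
        write_trajectory(list(traj.frames), path)
        back = read_trajectory(path)
        assert len(back) == 4
        for orig, re_read in zip(traj.frames, back):
            # PDB stores 3 decimals in Angstrom -> 5e-5 nm rounding
            assert np.abs(orig.coords - re_read.coords).max() < 1e-4
        assert filter_diameter(back[0], 445) == pytest.approx(
            filter_diameter(traj.frames[0], 445), abs=2e-4
        )
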