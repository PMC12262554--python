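"""Water-structure classification: hydrogen bonds, 3BA, shells, residence."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from lovhydra import synthdata as sd
from lovhydra import watershell as ws
from lovhydra.frames import Frame, Trajectory

from conftest import make_bead_frame, make_water_frame

TETRA = float(np.degrees(np.arccos(-1.0 / 3.0)))
ICO = float(np.degrees(np.arccos(1.0 / np.sqrt(5.0))))


def _two_waters(d_oo, donor_on_axis=True):
    h = [np.array([[0.9572, 0.0, 0.0], [-0.24, 0.927, 0.0]]),
         np.array([[0.0, 0.9572, 0.0], [0.91, -0.29, 0.0]])]
    if donor_on_axis:
        h[0] = np.array([[0.9572, 0.0, 0.0], [-0.24, 0.927, 0.0]])
    else:
        h[0] = np.array([[0.0, 0.0, 0.9572], [0.0, 0.916, -0.277]])
        h[1] = np.array([[0.0, 0.0, 0.9572], [0.0, 0.916, -0.277]])
    return make_water_frame([[0, 0, 0], [d_oo, 0, 0]], h)


class TestHbondNeighbors:
    def test_on_axis_donor_within_cutoff_bonds(self):
        frame = _two_waters(2.8)
        nb = ws.find_hbond_neighbors(frame)
        assert nb[0] == [3] and nb[3] == [0]

    def test_beyond_oo_cutoff_never_bonds(self):
        frame = _two_waters(4.0)
        nb = ws.find_hbond_neighbors(frame)
        assert nb[0] == [] and nb[3] == []

    def test_off_axis_hydrogens_do_not_bond(self):
        frame = _two_waters(2.8, donor_on_axis=False)
        nb = ws.find_hbond_neighbors(frame)
        assert nb[0] == [] and nb[3] == []

    def test_matches_brute_force_all_pairs_oracle(self, rng):
        # random waters, hydrogens in random orientations
        n = 100
        pos = rng.uniform(0, 18, size=(n, 3))
        hoff = []
        for _ in range(n):
            d1 = rng.normal(size=3)
            d1 /= np.linalg.norm(d1)
            perp = np.cross(d1, [0, 0, 1.0])
            if np.linalg.norm(perp) < 1e-6:
                perp = np.cross(d1, [0, 1.0, 0])
            perp /= np.linalg.norm(perp)
            ang = np.radians(104.52)
            d2 = np.cos(ang) * d1 + np.sin(ang) * perp
            hoff.append(0.9572 * np.stack([d1, d2]))
        frame = make_water_frame(pos, hoff)
        crit = ws.HBondCriterion()
        nb = ws.find_hbond_neighbors(frame, crit)

        cos_tol = np.cos(np.radians(crit.max_angle_dev))
        oracle = {3 * i: set() for i in range(n)}
        for i in range(n):
            for j in range(i + 1, n):
                oo = pos[j] - pos[i]
                d = np.linalg.norm(oo)
                if d > crit.max_oo:
                    continue
                bonded = False
                for donor, acceptor, axis in ((i, j, oo / d),
                                              (j, i, -oo / d)):
                    for h in hoff[donor]:
                        if (h / np.linalg.norm(h)) @ axis >= cos_tol:
                            bonded = True
                if bonded:
                    oracle[3 * i].add(3 * j)
                    oracle[3 * j].add(3 * i)
        assert {k: set(v) for k, v in nb.items()} == oracle

    def test_symmetric_and_irreflexive(self):
        frame = sd.gen_water_geometry(
            sd.GeometrySpec("mixed", 120, jitter_deg=5.0, seed=3))
        nb = ws.find_hbond_neighbors(frame)
        for center, lst in nb.items():
            assert center not in lst
            for other in lst:
                assert center in nb[other]


class TestThreeBodyAngles:
    def test_perpendicular_neighbors_give_90(self):
        frame = make_water_frame([[0, 0, 0], [2.8, 0, 0], [0, 2.8, 0]])
        nb = {0: [3, 6], 3: [0], 6: [0]}
        angles = ws.three_body_angles(frame, nb)
        assert angles == [(0, pytest.approx(90.0))]

    def test_ideal_tetrahedron_gives_109_47(self):
        frame = sd.gen_water_geometry(
            sd.GeometrySpec("tetrahedral", 5, jitter_deg=0.0, seed=0))
        angles = ws.three_body_angles(frame, ws.find_hbond_neighbors(frame))
        assert len(angles) == 6
        assert all(abs(a - TETRA) < 1e-9 for _, a in angles)

    def test_icosahedral_adjacent_vertices_give_63_43(self):
        # independent oracle: adjacent-vertex angle of a regular icosahedron
        # is arccos(1/sqrt(5))
        frame = sd.gen_water_geometry(
            sd.GeometrySpec("icosahedral", 13, jitter_deg=0.0, seed=0))
        angles = ws.three_body_angles(frame, ws.find_hbond_neighbors(frame))
        assert len(angles) == 3
        assert all(abs(a - ICO) < 1e-9 for _, a in angles)

    def test_waters_with_fewer_than_two_neighbors_contribute_nothing(self):
        frame = make_water_frame([[0, 0, 0], [2.8, 0, 0]])
        assert ws.three_body_angles(frame, {0: [3], 3: [0]}) == []


class TestClassifyAngles:
    @pytest.mark.parametrize("angle,klass", [
        (109.5, "wrap"), (60.0, "icosahedral"), (160.0, "bound"),
        (85.0, "unclassified"), (100.0, "wrap"), (120.0, "wrap"),
    ])
    def test_window_assignment(self, angle, klass):
        out = ws.classify_angles([angle])
        assert out[f"n_{klass}"] == 1

    def test_counts_partition_total(self, rng):
        angles = rng.uniform(0, 180, size=500)
        out = ws.classify_angles(angles)
        total = sum(out[f"n_{k}"] for k in
                    ("wrap", "icosahedral", "bound", "unclassified"))
        assert total == out["n_total"] == 500

    def test_overlapping_windows_rejected(self):
        with pytest.raises(ValueError):
            ws.ClassWindows(wrap=(100, 160), bound=(150, 170))


class TestShellAssign:
    def test_within_cutoff_assigned_beyond_not(self):
        frame = make_water_frame(
            [[3.0, 0, 0], [0, 0, 100.0]],
            extra_atoms=[([0.0, 0.0, 0.0], 410, "LEU", "C", "CB")])
        shells = ws.shell_assign(frame, cutoff=4.5)
        assert shells[410] == {0}

    def test_water_can_sit_in_two_shells(self):
        frame = make_water_frame(
            [[2.0, 0, 0]],
            extra_atoms=[([0.0, 0, 0], 410, "LEU", "C", "CB"),
                         ([4.0, 0, 0], 411, "ALA", "C", "CB")])
        shells = ws.shell_assign(frame, cutoff=4.5)
        assert shells[410] == {0} and shells[411] == {0}

    def test_matches_brute_force_distance_oracle(self, rng):
        n_wat, n_bead = 40, 6
        wpos = rng.uniform(0, 25, size=(n_wat, 3))
        bpos = rng.uniform(0, 25, size=(n_bead, 3))
        frame = make_water_frame(
            wpos, extra_atoms=[(bpos[i], 500 + i, "ALA", "C", "CA")
                               for i in range(n_bead)])
        shells = ws.shell_assign(frame, cutoff=4.5)
        for i in range(n_bead):
            expect = {3 * j for j in range(n_wat)
                      if np.linalg.norm(wpos[j] - bpos[i]) <= 4.5}
            assert shells[500 + i] == expect

    def test_shell_counts_monotone_in_cutoff(self, rng):
        frame = make_water_frame(
            rng.uniform(0, 15, size=(30, 3)),
            extra_atoms=[([7.5, 7.5, 7.5], 500, "ALA", "C", "CA")])
        sizes = [len(ws.shell_assign(frame, c)[500])
                 for c in (3.0, 4.5, 6.0, 8.0)]
        assert sizes == sorted(sizes)


class TestHydrationProfile:
    def test_pure_tetrahedral_shell_is_all_wrap(self):
        frame = sd.gen_water_geometry(
            sd.GeometrySpec("tetrahedral", 5, jitter_deg=0.0, seed=0))
        frame = _add_bead(frame)
        prof = ws.hydration_profile([frame])
        assert prof.loc[403, "frac_wrap"] == 1.0
        assert prof.loc[403, "frac_icosahedral"] == 0.0
        assert prof.loc[403, "frac_bound"] == 0.0

    @pytest.mark.parametrize("klass,col", [
        ("icosahedral", "frac_icosahedral"), ("planar", "frac_bound")])
    def test_jitter_free_classes_are_pure(self, klass, col):
        n = 13 if klass == "icosahedral" else 3
        frame = _add_bead(sd.gen_water_geometry(
            sd.GeometrySpec(klass, n, jitter_deg=0.0, seed=0)))
        prof = ws.hydration_profile([frame])
        assert prof.loc[403, col] == 1.0

    def test_mixed_generator_round_trip_within_tolerance(self):
        frame = sd.gen_water_geometry(
            sd.GeometrySpec("mixed", 200, jitter_deg=0.0, seed=1))
        angles = ws.three_body_angles(frame, ws.find_hbond_neighbors(frame))
        out = ws.classify_angles(angles)
        truth = frame.truth["angle_fractions"]
        for klass in ("wrap", "icosahedral"):
            assert abs(out[f"frac_{klass}"] - truth.get(klass, 0.0)) <= 0.05

    def test_empty_shell_reported_as_zero_with_flag(self):
        frame = make_water_frame(
            [[0, 0, 50.0]],
            extra_atoms=[([0, 0, 0], 403, "ALA", "C", "CA")])
        prof = ws.hydration_profile([frame])
        assert bool(prof.loc[403, "empty_shell"])
        assert prof.loc[403, "frac_wrap"] == 0.0


def _add_bead(frame):
    origins = frame.truth["unit_origins"]
    extra = [(np.asarray(o) + [0, 0, 1.0], 403 + i, "ALA", "C", "CA")
             for i, o in enumerate(origins)]
    coords = np.vstack([frame.coords] + [e[0][None, :] for e in extra])
    out = Frame(coords,
                np.concatenate([frame.resid, [e[1] for e in extra]]),
                np.concatenate([frame.resname,
                                np.array([e[2] for e in extra], object)]),
                np.concatenate([frame.element,
                                np.array([e[3] for e in extra], object)]),
                np.concatenate([frame.atom_name,
                                np.array([e[4] for e in extra], object)]))
    out.truth = frame.truth
    return out


def _shuttle_trajectory(pattern, dt=1.0):
    """Water visits the bead's shell on frames where pattern is 1."""
    frames = []
    n = len(pattern)
    coords = np.empty((n, 4, 3))
    for i, p in enumerate(pattern):
        w = [0.0, 3.0, 0.0] if p else [0.0, 60.0, 0.0]
        coords[i] = np.array([[0.0, 0.0, 0.0], w,
                              np.add(w, [0.9572, 0, 0]),
                              np.add(w, [-0.24, 0.927, 0])])
    topo = Frame(coords[0],
                 np.array([403, 1001, 1001, 1001]),
                 np.array(["ALA", "HOH", "HOH", "HOH"], object),
                 np.array(["C", "O", "H", "H"], object),
                 np.array(["CA", "OW", "HW1", "HW2"], object))
    return Trajectory(topo, coords, np.arange(n) * dt)


class TestResidenceTimes:
    def test_first_passage_duration_counts_occupied_frames(self):
        traj = _shuttle_trajectory([1] * 10 + [0] * 5)
        table = ws.residence_times(traj)
        assert table.loc[403, "mean_residence_ps"] == 10.0
        assert table.loc[403, "n_visits"] == 1

    def test_re_entries_are_excluded(self):
        traj = _shuttle_trajectory([1] * 10 + [0] * 3 + [1] * 50 + [0] * 2)
        table = ws.residence_times(traj)
        assert table.loc[403, "mean_residence_ps"] == 10.0
        assert table.loc[403, "n_visits"] == 1

    def test_visit_open_at_trajectory_end_is_discarded(self):
        traj = _shuttle_trajectory([0] * 5 + [1] * 10)
        table = ws.residence_times(traj)
        assert table.loc[403, "n_visits"] == 0

    def test_single_frame_trajectory_rejected(self):
        traj = _shuttle_trajectory([1])
        with pytest.raises(ValueError):
            ws.residence_times(traj)

    def test_telegraph_round_trip_recovers_mean_dwell(self):
        spec = sd.ShellDynamicsSpec(n_residues=50, n_frames=5000, dt=1.0,
                                    mean_dwell=50.0, occupancy=2.0, seed=7)
        traj = sd.gen_toy_trajectory(spec)
        table = ws.residence_times(traj)
        mean = np.nanmean(table["mean_residence_ps"])
        assert abs(mean / 50.0 - 1.0) < 0.10


class TestWrapChangeFlags:
    def test_no_change_no_flags(self):
        frame = _add_bead(sd.gen_water_geometry(
            sd.GeometrySpec("mixed", 150, jitter_deg=0.0, seed=5)))
        prof = ws.hydration_profile([frame])
        flags = ws.wrap_change_flags(prof, prof)
        assert not flags["flagged"].any()

    def test_hand_computed_single_drop(self):
        # wrap_ref mean 0.2; residue dropping 0.4 -> 0.0 exceeds 0.5*0.2
        import pandas as pd
        ref = pd.DataFrame({"frac_wrap": [0.4, 0.2, 0.0, 0.2]},
                           index=[1, 2, 3, 4])
        cur = ref.copy()
        cur.loc[1, "frac_wrap"] = 0.0
        flags = ws.wrap_change_flags(ref, cur)
        assert flags["flagged"].tolist() == [True, False, False, False]

    def test_uniform_small_drop_not_flagged(self):
        import pandas as pd
        ref = pd.DataFrame({"frac_wrap": [0.2] * 5}, index=range(5))
        cur = ref * 0.9  # 10% relative drop: delta 0.02 < 0.5*0.2
        flags = ws.wrap_change_flags(ref, cur)
        assert not flags["flagged"].any()


class TestRigidBodyInvariance:
    def test_angles_shells_unchanged_under_rigid_transform(self, rng):
        frame = _add_bead(sd.gen_water_geometry(
            sd.GeometrySpec("mixed", 150, jitter_deg=4.0, seed=9)))
        R = Rotation.random(random_state=4).as_matrix()
        moved = frame.transformed(R, np.array([11.0, -4.0, 7.0]))
        moved.truth = frame.truth

        a0 = sorted(a for _, a in ws.three_body_angles(
            frame, ws.find_hbond_neighbors(frame)))
        a1 = sorted(a for _, a in ws.three_body_angles(
            moved, ws.find_hbond_neighbors(moved)))
        assert np.allclose(a0, a1, atol=1e-9)

        s0 = ws.shell_assign(frame)
        s1 = ws.shell_assign(moved)
        assert s0 == s1
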