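import numpy as np
import pytest

from ethmig import trajectory as tr
from ethmig.units import ethanol_geometry


def scripted_ho_distance_trajectory(d_ho, dt_fs=0.1, h_index=6):
    """Ethanol-based trajectory where one beta hydrogen follows a given
    H–O distance schedule (radially toward O); everything else is static."""
    geo = ethanol_geometry()
    n = len(d_ho)
    frames = np.broadcast_to(geo.coordinates, (n, 9, 3)).copy()
    u = geo.coordinates[h_index] - geo.coordinates[0]
    u = u / np.linalg.norm(u)
    frames[:, h_index] = geo.coordinates[0] + np.asarray(d_ho)[:, None] * u
    return tr.Trajectory(
        elements=list(geo.elements), frames=frames, dt_fs=dt_fs
    )


def scripted_co_distance_trajectory(d_co, dt_fs=0.1):
    geo = ethanol_geometry()
    n = len(d_co)
    frames = np.broadcast_to(geo.coordinates, (n, 9, 3)).copy()
    u = geo.coordinates[0] - geo.coordinates[1]  # C_alpha -> O
    u = u / np.linalg.norm(u)
    frames[:, 0] = geo.coordinates[1] + np.asarray(d_co)[:, None] * u
    frames[:, 3] = frames[:, 0] + (geo.coordinates[3] - geo.coordinates[0])
    return tr.Trajectory(
        elements=list(geo.elements), frames=frames, dt_fs=dt_fs
    )


class TestMigrationTimes:
    def test_first_crossing_frame_exact(self):
        # beta-H crosses 1.0 Å between frames 1233 and 1234 at dt = 0.1 fs
        i = np.arange(2000)
        d = np.clip(1.0 + 0.005 * (1233.5 - i), 0.95, 2.6)
        traj = scripted_ho_distance_trajectory(d, dt_fs=0.1)
        assert (d[1233] >= 1.0) and (d[1234] < 1.0)
        rec = tr.migration_times(traj)
        assert rec.first_migration_fs == pytest.approx(123.4, abs=1e-9)
        assert rec.first_origin == "beta"
        assert rec.second_migration_fs is None

    def test_no_crossing_gives_absent_times(self):
        d = np.full(100, 2.6)
        traj = scripted_ho_distance_trajectory(d)
        rec = tr.migration_times(traj)
        assert rec.first_migration_fs is None
        assert rec.second_migration_fs is None

    def test_recrossing_uses_first_crossing_only(self):
        d = np.full(300, 2.6)
        d[100:120] = 0.98  # first visit
        d[120:200] = 1.5   # leaves again
        d[200:] = 0.97     # returns
        traj = scripted_ho_distance_trajectory(d, dt_fs=0.1)
        rec = tr.migration_times(traj)
        assert rec.first_migration_fs == pytest.approx(10.0, abs=1e-9)

    def test_hydroxyl_hydrogen_excluded(self):
        geo = ethanol_geometry()
        frames = np.broadcast_to(geo.coordinates, (50, 9, 3)).copy()
        traj = tr.Trajectory(list(geo.elements), frames, dt_fs=1.0)
        rec = tr.migration_times(traj)
        # hydroxyl H sits below 1 Å the whole time yet is not a migration
        assert rec.first_migration_fs is None

    def test_rotation_translation_invariant(self):
        from ethmig.explosion import random_rotation

        d = np.full(200, 2.6)
        d[50:] = 0.96
        traj = scripted_ho_distance_trajectory(d, dt_fs=0.5)
        rot = random_rotation(np.random.default_rng(1))
        moved = tr.Trajectory(
            elements=traj.elements,
            frames=traj.frames @ rot.T + np.array([5.0, -3.0, 2.0]),
            dt_fs=traj.dt_fs,
        )
        a = tr.migration_times(traj)
        b = tr.migration_times(moved)
        assert a.first_migration_fs == b.first_migration_fs
        assert a.first_origin == b.first_origin


class TestCoBreak:
    def test_crossing_frame_exact(self):
        # d(C,O) crosses 3.0 Å between frames 4999 and 5000 at dt = 0.1 fs
        n = 6000
        d = 1.43 + np.maximum(0, np.arange(n) - 4500) * (1.57 / 499.0)
        assert d[4999] <= 3.0 < d[5000]
        traj = scripted_co_distance_trajectory(d, dt_fs=0.1)
        assert tr.co_break_time(traj) == pytest.approx(500.0, abs=1e-9)

    def test_bound_oscillation_never_breaks(self):
        t = np.arange(500)
        d = 1.45 + 0.15 * np.sin(t / 10)
        traj = scripted_co_distance_trajectory(d, dt_fs=0.1)
        assert tr.co_break_time(traj) is None


class TestFinalFragments:
    def test_intact_geometry_unfragmented(self):
        geo = ethanol_geometry()
        traj = tr.Trajectory(
            list(geo.elements), geo.coordinates[None, :, :], dt_fs=1.0
        )
        assert tr.final_fragments(traj) == "unfragmented"

    def test_separated_h3o_and_c2h3_is_dhm(self):
        geo = ethanol_geometry()
        coords = geo.coordinates.copy()
        # move O, hydroxyl H, one alpha H and one beta H far away as H3O
        shift = np.array([-10.0, 0.0, 0.0])
        o = coords[0]
        coords[0] += shift
        coords[3] += shift
        coords[4] = coords[0] + np.array([0.0, 0.95, 0.0])
        coords[6] = coords[0] + np.array([0.0, 0.0, 0.95])
        traj = tr.Trajectory(list(geo.elements), coords[None], dt_fs=1.0)
        assert tr.final_fragments(traj) == "DHM"

    def test_component_compositions_sum_to_parent(self):
        geo = ethanol_geometry()
        coords = geo.coordinates.copy()
        coords[:3] += 8.0
        traj = tr.Trajectory(list(geo.elements), coords[None], dt_fs=1.0)
        comps = tr._bond_components(traj.elements, coords, tr.BOND_SCALE)
        all_atoms = sorted(i for c in comps for i in c)
        assert all_atoms == list(range(9))


class TestXyzIO:
    def test_round_trip(self, tmp_path):
        d = np.linspace(2.6, 0.95, 100)
        traj = scripted_ho_distance_trajectory(d, dt_fs=0.5)
        p = tmp_path / "traj.xyz"
        tr.write_xyz_trajectory(traj, p)
        back = tr.read_xyz_trajectory(p, dt_fs=0.5)
        assert back.n_frames == 100
        assert back.times_fs[-1] == pytest.approx(49.5)
        np.testing.assert_allclose(back.frames, traj.frames, atol=1e-4)
        assert back.elements == traj.elements

    def test_single_frame_valid_and_analyses_absent(self, tmp_path):
        geo = ethanol_geometry()
        p = tmp_path / "single.xyz"
        p.write_text(geo.to_xyz())
        traj = tr.read_xyz_trajectory(p, dt_fs=0.1)
        assert traj.n_frames == 1
        assert tr.migration_times(traj).first_migration_fs is None
        assert tr.co_break_time(traj) is None

    def test_inconsistent_atom_counts_rejected_with_frame_index(self, tmp_path):
        p = tmp_path / "bad.xyz"
        p.write_text(
            "3\nc\nH 0 0 0\nH 1 0 0\nO 2 0 0\n"
            "2\nc\nH 0 0 0\nO 1 0 0\n"
        )
        with pytest.raises(tr.XYZFormatError, match="frame 1"):
            tr.read_xyz_trajectory(p, dt_fs=1.0)

    def test_unknown_element_rejected(self, tmp_path):
        p = tmp_path / "xe.xyz"
        p.write_text("1\nc\nXe 0 0 0\n")
        with pytest.raises(tr.XYZFormatError, match="Xe"):
            tr.read_xyz_trajectory(p, dt_fs=1.0)


class TestYieldCurves:
    def test_cumulative_counting(self):
        recs = [
            tr.MigrationRecord(
                final_channel="DHM", second_migration_fs=t,
                first_migration_fs=t / 2,
            )
            for t in (100.0, 200.0, 300.0)
        ]
        grid = np.arange(0, 500, 50.0)
        curve = tr.cumulative_yield(recs, "DHM", grid)
        assert curve.value_at(150) == 1
        assert curve.value_at(250) == 2
        assert curve.value_at(450) == 3
        assert (np.diff(curve.values) >= 0).all()

    def test_empty_channel_all_zero(self):
        grid = np.arange(0, 100, 10.0)
        curve = tr.cumulative_yield([], "DHM", grid)
        assert (curve.values == 0).all()

    def test_scale_to_experiment(self):
        grid = np.arange(0, 1500, 100.0)
        theory = tr.YieldCurve(grid, np.full_like(grid, 50.0))
        experiment = tr.YieldCurve(grid, np.full_like(grid, 0.02))
        scaled = tr.scale_to_experiment(theory, experiment, t_ref_fs=1000)
        assert scaled.scale_factor == pytest.approx(4e-4)
        assert scaled.value_at(1000) == pytest.approx(
            experiment.value_at(1000)
        )
        twice = tr.scale_to_experiment(scaled, experiment, t_ref_fs=1000)
        np.testing.assert_allclose(twice.values, scaled.values)

    def test_scale_zero_theory_rejected(self):
        grid = np.arange(0, 1500, 100.0)
        theory = tr.YieldCurve(grid, np.zeros_like(grid))
        with pytest.raises(ValueError):
            tr.scale_to_experiment(theory, theory)


class TestCorrelations:
    def test_concerted_break_recovered(self):
        rng = np.random.default_rng(0)
        recs = []
        for _ in range(200):
            t1 = rng.exponential(150)
            t2 = 400 + rng.exponential(600)
            recs.append(
                tr.MigrationRecord(
                    final_channel="DHM",
                    first_migration_fs=t1,
                    second_migration_fs=t2,
                    co_break_fs=t2 + 40 + rng.normal(0, 5),
                    second_origin="alpha",
                )
            )
        corr = tr.migration_correlations(recs)
        assert corr["t_co_vs_t2"]["slope"] == pytest.approx(1.0, abs=0.05)
        assert corr["t_co_vs_t2"]["r"] > 0.98

    def test_independent_migrations_uncorrelated(self):
        rng = np.random.default_rng(1)
        recs = [
            tr.MigrationRecord(
                final_channel="DHM",
                first_migration_fs=rng.exponential(150),
                second_migration_fs=400 + rng.exponential(600),
            )
            for _ in range(200)
        ]
        corr = tr.migration_correlations(recs)
        assert abs(corr["t2_vs_t1"]["r"]) < 0.15

    def test_degenerate_zero_variance_reported_absent(self):
        recs = [
            tr.MigrationRecord(
                first_migration_fs=100.0,
                second_migration_fs=100.0,
                co_break_fs=140.0,
            )
            for _ in range(5)
        ]
        corr = tr.migration_correlations(recs)
        assert corr["t2_vs_t1"] is None
        assert corr["t_co_vs_t2"] is None

    def test_fewer_than_three_pairs_absent(self):
        recs = [
            tr.MigrationRecord(
                first_migration_fs=1.0, second_migration_fs=2.0
            )
        ]
        assert tr.migration_correlations(recs)["t2_vs_t1"] is None
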