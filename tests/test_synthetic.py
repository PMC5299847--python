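"""Synthetic trajectory generator: archetype curves, noise model, rendering."""

import numpy as np
import pytest

from osmotrace import (
    ARCHETYPE_LABELS,
    DEFAULT_ARCHETYPES,
    ArchetypeClass,
    ChamberCohort,
    RenderGeometry,
    SimulationConfig,
    archetype_profile,
    make_default_panel,
    measure_cell,
    render_images,
    simulate_trajectories,
)
from osmotrace.synthetic import ConfigurationError, PlacementError

from conftest import make_traj


class TestArchetypeProfile:
    @pytest.mark.parametrize("label", ARCHETYPE_LABELS)
    def test_pre_stimulus_baseline_is_unity(self, label):
        arch = DEFAULT_ARCHETYPES[label]
        t = np.array([-30.0, -5.0, -0.001])
        assert np.all(archetype_profile(arch, t) == 1.0)

    def test_down_regulated_asymptote_equals_steady_fold(self):
        arch = ArchetypeClass("down_regulated", 10.0, 0.01, 0.5, 0.0, 0.5)
        assert archetype_profile(arch, 1e6) == pytest.approx(0.5)

    @pytest.mark.parametrize("label", ARCHETYPE_LABELS)
    def test_dense_grid_extreme_equals_peak_fold(self, label):
        # oracle: evaluate the curve densely; its extreme deviation from 1
        # must occur exactly at the analytic peak time with value peak_fold
        arch = DEFAULT_ARCHETYPES[label]
        t = np.linspace(-30, 2000, 200001)
        f = np.asarray(archetype_profile(arch, t))
        extreme = f.max() if arch.peak_fold >= 1 else f.min()
        # grid spacing ~0.01 min bounds how closely samples bracket the peak
        assert extreme == pytest.approx(arch.peak_fold, abs=1e-3)
        assert archetype_profile(arch, arch.time_to_peak_min) == pytest.approx(
            arch.peak_fold
        )

    @pytest.mark.parametrize("label", ARCHETYPE_LABELS)
    def test_continuity(self, label):
        arch = DEFAULT_ARCHETYPES[label]
        t = np.linspace(-40, 600, 64001)
        f = np.asarray(archetype_profile(arch, t))
        assert np.max(np.abs(np.diff(f))) < 0.01  # no jumps at piece boundaries

    def test_invariant_violations_rejected(self):
        with pytest.raises(ConfigurationError):
            ArchetypeClass("rapid_up_adapt", 5, 0.08, 3.0, 0.0, 1.5)  # needs adaptation
        with pytest.raises(ConfigurationError):
            ArchetypeClass("late_up_no_adapt", 150, 0.015, 2.5, 0.01, 2.5)
        with pytest.raises(ConfigurationError):
            ArchetypeClass("down_regulated", 10, 0.01, 1.2, 0.0, 1.2)  # peak >= 1
        with pytest.raises(ConfigurationError):
            ArchetypeClass("no_such_shape", 5, 0.08, 3.0, 0.02, 1.5)


class TestSimulateTrajectories:
    def test_noiseless_series_equals_baseline_times_curve(
        self, small_panel, small_cohort, noiseless_config
    ):
        trajs, truth = simulate_trajectories(
            small_panel, small_cohort, noiseless_config, seed=3
        )
        for traj in trajs:
            arch = truth.archetypes[traj.strain]
            expected = noiseless_config.baseline_level * np.asarray(
                archetype_profile(arch, traj.times)
            )
            rec = truth.cell_record(traj.strain, traj.cell_id)
            if rec["n_bursts"] == 0:
                np.testing.assert_allclose(
                    traj.values[traj.valid], expected[traj.valid], rtol=1e-12
                )

    def test_same_seed_is_bit_identical(self, small_panel, small_cohort):
        a, ta = simulate_trajectories(small_panel, small_cohort, seed=11)
        b, tb = simulate_trajectories(small_panel, small_cohort, seed=11)
        assert len(a) == len(b)
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x.values, y.values)
            np.testing.assert_array_equal(x.valid, y.valid)
        assert ta.cells.equals(tb.cells)

    def test_monte_carlo_mean_matches_noise_model(self, grid):
        # 1000 cells, noise sd 5: per-time sample mean within 3*(5/sqrt(1000))
        # of the noiseless curve
        panel = make_default_panel(n_per_archetype=1)
        panel.table = panel.table.iloc[:1]
        cohort = ChamberCohort(
            times=grid, initial_cells=1000, division_rate=0.0, truncation_hazard=0.0
        )
        config = SimulationConfig(
            noise_sd=5.0,
            background_level=0.0,
            bleach_rate=0.0,
            baseline_cv=0.0,
            delay_jitter_sd_min=0.0,
            rate_cv=0.0,
            steady_cv=0.0,
        )
        trajs, truth = simulate_trajectories(panel, cohort, config, seed=5)
        S = np.stack([t.values for t in trajs])
        arch = truth.archetypes[panel.table["strain"].iloc[0]]
        expected = config.baseline_level * np.asarray(archetype_profile(arch, grid))
        tol = 3 * 5.0 / np.sqrt(1000)
        assert np.max(np.abs(S.mean(axis=0) - expected)) < tol

    def test_truncation_bookkeeping(self, small_panel, small_cohort):
        trajs, truth = simulate_trajectories(small_panel, small_cohort, seed=2)
        n_full = sum(t.is_full_length for t in trajs)
        n_trunc = sum(not t.is_full_length for t in trajs)
        assert n_full + n_trunc == len(trajs) == len(truth.cells)
        assert n_full == int(truth.cells["full_length"].sum())
        # every trajectory traceable to exactly one truth record
        keys = set(zip(truth.cells["strain"], truth.cells["cell_id"]))
        assert len(keys) == len(truth.cells)
        for t in trajs:
            assert (t.strain, t.cell_id) in keys

    def test_live_cells_at_every_timepoint(self, small_panel, small_cohort):
        trajs, _ = simulate_trajectories(small_panel, small_cohort, seed=8)
        by_strain = {}
        for t in trajs:
            by_strain.setdefault(t.strain, []).append(t.valid)
        for strain, valids in by_strain.items():
            assert np.stack(valids).sum(axis=0).min() >= 1

    def test_invalid_config_rejected(self):
        with pytest.raises(ConfigurationError):
            SimulationConfig(baseline_level=0.0)
        with pytest.raises(ConfigurationError):
            SimulationConfig(noise_sd=-1.0)


class TestRenderImages:
    def test_uniform_cell_round_trip(self):
        traj = make_traj([100.0] * 3, cell_id=0)
        geom = RenderGeometry(shape=(64, 64), background_level=0.0)
        frames, masks = render_images([traj], geom, seed=0)
        assert measure_cell(frames[0], masks[0], 1, "uniform") == pytest.approx(100.0)

    def test_nuclear_cell_top10_vs_whole_mean(self):
        # arithmetic oracle on constructed pixels: 10% at 200, rest at 50
        frame = np.full(100, 50.0)
        frame[:10] = 200.0
        mask = np.ones(100, dtype=int)
        assert measure_cell(frame, mask, 1, "nuclear") == pytest.approx(200.0)
        assert measure_cell(frame, mask, 1, "uniform") == pytest.approx(65.0)

    def test_nuclear_render_reproduces_trajectory_under_top10_readout(self):
        traj = make_traj([120.0, 140.0], cell_id=0)
        geom = RenderGeometry(shape=(64, 64), localization="nuclear")
        frames, masks = render_images([traj], geom, seed=1)
        for t in range(2):
            assert measure_cell(frames[t], masks[t], 1, "nuclear") == pytest.approx(
                traj.values[t]
            )
            assert measure_cell(frames[t], masks[t], 1, "uniform") < traj.values[t]

    def test_background_pixels_at_background_level(self):
        traj = make_traj([80.0], cell_id=0)
        geom = RenderGeometry(shape=(48, 48), background_level=7.0)
        frames, masks = render_images([traj], geom, seed=0)
        assert np.median(frames[0][masks[0] == 0]) == pytest.approx(7.0)

    def test_truncated_cell_absent_from_mask(self):
        traj = make_traj([90.0, 90.0, np.nan], valid=[True, True, False])
        frames, masks = render_images([traj], RenderGeometry(shape=(48, 48)), seed=0)
        assert (masks[0] == 1).sum() > 0
        assert (masks[2] == 1).sum() == 0

    def test_overfull_frame_raises_placement_error(self):
        trajs = [make_traj([1.0], cell_id=i) for i in range(50)]
        with pytest.raises(PlacementError):
            render_images(trajs, RenderGeometry(shape=(24, 24), cell_radius_px=6), seed=0)

    def test_render_determinism(self):
        trajs = [make_traj([10.0, 20.0], cell_id=i) for i in range(5)]
        geom = RenderGeometry(shape=(96, 96), noise_sd=2.0)
        f1, m1 = render_images(trajs, geom, seed=4)
        f2, m2 = render_images(trajs, geom, seed=4)
        np.testing.assert_array_equal(f1, f2)
        np.testing.assert_array_equal(m1, m2)
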