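"""Synthetic cohort generator: calibration, determinism, substreams."""

import dataclasses
import math

import numpy as np
import pytest

from rbctweezers import (
    CohortDesign,
    NoiseModel,
    cell_length,
    convert_units,
    draw_cohort,
    estimate_elasticity,
    estimate_zeta,
    leukodepleted_schedule,
    simulate_elongation_sweep,
    simulate_ros,
    simulate_zeta_sweep,
    standard_schedule,
)
from rbctweezers.cohort_stats import ros_percent_positive
from rbctweezers.errors import InvalidParameterError, ScheduleError


class TestDrawCohort:
    def test_day1_mean_within_sampling_error(self, schedule):
        """CLT: n=40 sample mean of true zeta within 3 SE of -14.5 mV."""
        design = CohortDesign(days=(1,), seed=11)
        records = [r for r in draw_cohort(design, schedule) if r.kind == "zeta"]
        zetas = [convert_units(r.true_zeta, "V", "mV") for r in records]
        assert len(zetas) == 40
        assert np.mean(zetas) == pytest.approx(-14.5, abs=3 * 0.7)

    def test_deterministic_given_seed(self, schedule):
        design = CohortDesign(seed=5)
        assert draw_cohort(design, schedule) == draw_cohort(design, schedule)

    def test_seed_changes_cohort(self, schedule):
        a = draw_cohort(CohortDesign(seed=1), schedule)
        b = draw_cohort(CohortDesign(seed=2), schedule)
        assert a != b

    def test_minimal_cohort(self, schedule):
        records = draw_cohort(
            CohortDesign(days=(1,), n_cells_zeta=2, n_cells_elastic=0, seed=0), schedule
        )
        assert len(records) == 2
        assert all(r.true_zeta < 0 and r.rest_length > 0 for r in records)

    def test_unknown_day_raises_schedule_error(self, schedule):
        with pytest.raises(ScheduleError):
            draw_cohort(CohortDesign(days=(1, 50), seed=0), schedule)

    def test_elasticity_only_on_assayed_days(self, schedule):
        """Day 1 has no elasticity assay; elastic cells start on day 8."""
        records = draw_cohort(CohortDesign(seed=0), schedule)
        days_elastic = {r.day for r in records if r.kind == "elastic"}
        assert days_elastic == {8, 15, 22, 29, 36}
        assert all(r.true_mu > 0 for r in records if r.kind == "elastic")

    def test_leukodepleted_arm_covers_15_days(self):
        design = CohortDesign(days=(1, 8, 15), n_cells_zeta=20, n_cells_elastic=0,
                              arm="leukodepleted", seed=3)
        records = draw_cohort(design, leukodepleted_schedule())
        assert len(records) == 60
        day1 = [convert_units(r.true_zeta, "V", "mV") for r in records if r.day == 1]
        # sample-mean SE at n=20 equals the published SE (0.5 mV)
        assert np.mean(day1) == pytest.approx(-14.0, abs=3 * 0.5)


class TestZetaSweepSimulation:
    def test_noiseless_velocities_proportional_to_voltage(self, schedule, medium, chamber, noiseless):
        cell = draw_cohort(CohortDesign(days=(1,), seed=0), schedule)[0]
        sweep = simulate_zeta_sweep(cell, chamber, medium, noiseless)
        ratio = sweep.velocities / sweep.voltages
        assert np.ptp(ratio) == pytest.approx(0.0, abs=1e-18)

    def test_known_zeta_gives_466_um_s_at_50V(self, medium, chamber, noiseless, schedule):
        from rbctweezers.synthetic import CellRecord

        cell = CellRecord(cell_id="x", day=1, arm="standard", kind="zeta",
                          rest_length=8e-6, true_zeta=-0.0145)
        sweep = simulate_zeta_sweep(cell, chamber, medium, noiseless)
        v50 = sweep.velocities[list(sweep.voltages).index(50.0)]
        assert abs(v50) == pytest.approx(46.6e-6, rel=5e-3)

    def test_substream_independence(self, schedule, medium, chamber, noise):
        cells = draw_cohort(CohortDesign(days=(1,), seed=7), schedule)[:2]
        s0 = simulate_zeta_sweep(cells[0], chamber, medium, noise, root_seed=7)
        s1 = simulate_zeta_sweep(cells[1], chamber, medium, noise, root_seed=7)
        assert not np.allclose(s0.velocities / s0.velocities[0],
                               s1.velocities / s1.velocities[0])

    def test_reproducible_given_root_seed(self, schedule, medium, chamber, noise):
        cell = draw_cohort(CohortDesign(days=(1,), seed=7), schedule)[0]
        a = simulate_zeta_sweep(cell, chamber, medium, noise, root_seed=7)
        b = simulate_zeta_sweep(cell, chamber, medium, noise, root_seed=7)
        np.testing.assert_array_equal(a.velocities, b.velocities)

    def test_track_mode_consistent_with_velocity(self, schedule, medium, chamber, noiseless):
        from rbctweezers import terminal_velocity

        cell = draw_cohort(CohortDesign(days=(1,), seed=7), schedule)[0]
        sweep, tracks = simulate_zeta_sweep(
            cell, chamber, medium, noiseless, root_seed=7, tracks=True
        )
        for volt, vel in zip(sweep.voltages, sweep.velocities):
            fit = terminal_velocity(tracks[float(volt)], transient_fraction=0.0)
            assert fit.velocity == pytest.approx(vel, rel=1e-9)


class TestElongationSweepSimulation:
    def test_noiseless_elongation_strictly_increasing(self, schedule, medium, chamber, noiseless):
        cell = next(r for r in draw_cohort(CohortDesign(seed=0), schedule) if r.kind == "elastic")
        sweep = simulate_elongation_sweep(cell, chamber, medium, noiseless)
        assert np.all(np.diff(sweep.lengths) > 0)
        assert sweep.lengths[0] > sweep.rest_length

    def test_stiffness_ratio_scales_elongation(self, medium, chamber, noiseless):
        from rbctweezers.synthetic import CellRecord

        soft = CellRecord(cell_id="s", day=8, arm="standard", kind="elastic",
                          rest_length=8e-6, true_mu=convert_units(4.1e-4, "dyne/cm", "N/m"))
        stiff = dataclasses.replace(soft, cell_id="t",
                                    true_mu=convert_units(9.6e-4, "dyne/cm", "N/m"))
        dl_soft = simulate_elongation_sweep(soft, chamber, medium, noiseless).lengths[-1] - 8e-6
        dl_stiff = simulate_elongation_sweep(stiff, chamber, medium, noiseless).lengths[-1] - 8e-6
        assert dl_stiff / dl_soft == pytest.approx(4.1 / 9.6, rel=1e-9)

    def test_rendered_stack_round_trip_within_pixel(self, schedule, medium, chamber, noiseless):
        """Renderer -> segmentation loop recovers each step length to 1 px."""
        cell = next(r for r in draw_cohort(CohortDesign(seed=1), schedule) if r.kind == "elastic")
        sweep, stack = simulate_elongation_sweep(
            cell, chamber, medium, noiseless, frames=True, pixel_size=0.2e-6
        )
        measured = cell_length(stack)
        assert np.all(np.abs(measured - sweep.lengths) < 0.2e-6)


class TestFullLoopRecovery:
    def test_day_means_recovered_within_sampling_error(self, schedule, medium, chamber, noise):
        """Cohort -> sweeps -> estimators recovers the day-8 schedule means
        for both zeta (n=40) and elasticity (n=20) within 2 SE."""
        records = draw_cohort(CohortDesign(days=(8,), seed=42), schedule)
        zetas, mus = [], []
        for cell in records:
            if cell.kind == "zeta":
                zetas.append(estimate_zeta(
                    simulate_zeta_sweep(cell, chamber, medium, noise, root_seed=42)).zeta_mV)
            else:
                mus.append(estimate_elasticity(
                    simulate_elongation_sweep(cell, chamber, medium, noise, root_seed=42)).mu_dyne_cm)
        assert np.mean(zetas) == pytest.approx(-9.7, abs=2 * 0.3)
        assert np.mean(mus) == pytest.approx(4.1e-4, abs=2 * 0.6e-4)

    def test_noise_scaling_inflates_day_mean_se(self, schedule, medium, chamber):
        """Quadrupling the velocity noise widens the spread of recovered
        day means (Monte-Carlo over independent small cohorts)."""
        def day_mean(seed, rel_sd):
            nm = NoiseModel(velocity_rel_sd=rel_sd)
            cells = draw_cohort(
                CohortDesign(days=(1,), n_cells_zeta=6, n_cells_elastic=0, seed=seed),
                standard_schedule(),
            )
            # single shared true zeta so only measurement noise varies
            est = [
                estimate_zeta(simulate_zeta_sweep(c, chamber, medium, nm, root_seed=seed)).zeta_mV
                for c in cells
            ]
            return float(np.mean(est))

        lo = np.std([day_mean(s, 0.02) for s in range(60)], ddof=1)
        hi = np.std([day_mean(s, 0.08) for s in range(60)], ddof=1)
        assert hi > lo


class TestRos:
    def test_zero_fraction_only_false_positives(self, schedule):
        import dataclasses as dc

        sched = dc.replace(schedule, ros_positive_fraction={1: 0.0})
        pct = ros_percent_positive(simulate_ros(1, sched, seed=3))
        assert pct < 0.2

    def test_saturated_fraction(self, schedule):
        import dataclasses as dc

        sched = dc.replace(schedule, ros_positive_fraction={1: 1.0})
        pct = ros_percent_positive(simulate_ros(1, sched, seed=3))
        assert pct > 99.8

    def test_week1_ratio_calibration(self, schedule):
        ratios = []
        for seed in range(20):
            p1 = ros_percent_positive(simulate_ros(1, schedule, seed=seed))
            p8 = ros_percent_positive(simulate_ros(8, schedule, seed=seed))
            ratios.append(p8 / p1)
        assert np.mean(ratios) == pytest.approx(1.60, abs=0.05)

    def test_invalid_fraction_raises(self, schedule):
        import dataclasses as dc

        sched = dc.replace(schedule, ros_positive_fraction={1: 1.5})
        with pytest.raises(ScheduleError):
            simulate_ros(1, sched)

    def test_missing_day_raises(self, schedule):
        with pytest.raises(ScheduleError):
            simulate_ros(99, schedule)

    def test_event_count_and_positivity(self, schedule):
        events = simulate_ros(8, schedule, n_events=5000, seed=0)
        assert events.intensities.size == 5000
        assert np.all(events.intensities > 0)

    def test_too_few_events_rejected(self, schedule):
        with pytest.raises(InvalidParameterError):
            simulate_ros(1, schedule, n_events=50)
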