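"""The worked competitive-release model: constants, dynamics, experiment."""

import math

import numpy as np
import pytest

from hybridgrid.competitive_release import (ARM_NAMES, RESISTANT, SENSITIVE,
                                            Cell, CompetitiveReleaseModel,
                                            CompetitiveReleaseParams,
                                            build_arms, run_experiment)
from hybridgrid.rng import RandomSource
from hybridgrid.raster import Raster
from hybridgrid.toolkit import prob_scale


@pytest.fixture
def params_small():
    return CompetitiveReleaseParams(xDim=24, yDim=24, steps=100, seed=0)


class TestParams:
    def test_probability_scaling(self):
        p = CompetitiveReleaseParams()
        ts = 2.0 / 24
        assert p.div_prob_sen == prob_scale(0.5, ts)
        assert p.div_prob_res == prob_scale(0.2, ts)
        assert p.death_prob == prob_scale(0.02, ts)
        assert p.drug_death == prob_scale(0.8, ts)

    def test_treatment_schedule_constants(self):
        p = CompetitiveReleaseParams()
        assert p.drug_start == 240.0     # day 20
        assert p.drug_period == 180.0    # 15 days
        assert p.drug_duration == 24.0   # 2 days (pulsed default)

    def test_drug_constants(self):
        p = CompetitiveReleaseParams()
        assert p.drug_uptake == pytest.approx(-0.0025)
        # 0.02 um^2/s to lattice units: dimensionless 0.36
        assert p.drug_diff_rate == pytest.approx(0.36)
        assert p.drug_boundary_val == 1.0

    def test_physical_bookkeeping(self):
        p = CompetitiveReleaseParams()
        assert p.domain_area_mm2 == pytest.approx(4.0)
        assert round(p.simulated_years, 1) == 2.3

    def test_arm_durations(self):
        p = CompetitiveReleaseParams()
        assert p.arm_duration("no_drug") == 0.0
        assert p.arm_duration("constant") == 200.0
        assert p.arm_duration("pulsed") == 24.0
        with pytest.raises(ValueError):
            p.arm_duration("bogus")

    def test_cell_type_colors(self):
        assert RESISTANT == 0x00FF00 and SENSITIVE == 0x0000FF


class TestInitTumor:
    def test_radius_ten_seeds_317_cells(self):
        m = CompetitiveReleaseModel(CompetitiveReleaseParams(), RandomSource(0))
        assert m.init_tumor() == 317
        assert m.population() == 317

    @pytest.mark.parametrize("prob,expected", [(0.0, SENSITIVE), (1.0, RESISTANT)])
    def test_extreme_resistant_probability(self, prob, expected, params_small):
        m = CompetitiveReleaseModel(params_small, RandomSource(0))
        m.init_tumor(radius=5, resistantProb=prob)
        assert all(c.type == expected for c in m.grid)

    def test_radius_larger_than_grid_clips(self, params_small):
        m = CompetitiveReleaseModel(params_small, RandomSource(0))
        n = m.init_tumor(radius=100)
        assert n == 24 * 24  # every position, nothing out of bounds


class TestDrugSchedule:
    def test_off_before_and_at_start(self):
        m = CompetitiveReleaseModel(CompetitiveReleaseParams(), RandomSource(0))
        assert not m.drug_on(0)
        assert not m.drug_on(239)
        assert not m.drug_on(240)  # remainder 0: strict inequality

    def test_on_just_after_start_for_window_length(self):
        m = CompetitiveReleaseModel(CompetitiveReleaseParams(), RandomSource(0))
        assert m.drug_on(241)
        assert m.drug_on(263)      # remainder 23 < 24
        assert not m.drug_on(264)  # remainder 24: window closed

    def test_pulse_repeats_each_period(self):
        m = CompetitiveReleaseModel(CompetitiveReleaseParams(), RandomSource(0))
        assert not m.drug_on(420)  # exact period multiple
        assert m.drug_on(421)

    def test_no_drug_arm_never_doses(self):
        p = CompetitiveReleaseParams()
        m = CompetitiveReleaseModel(p, RandomSource(0), drug_duration=0.0)
        assert not any(m.drug_on(t) for t in range(0, 2000))

    def test_constant_arm_doses_every_tick_except_period_multiples(self):
        p = CompetitiveReleaseParams()
        m = CompetitiveReleaseModel(p, RandomSource(0),
                                    drug_duration=p.arm_duration("constant"))
        for t in range(241, 1000):
            expected = math.fmod(t - 240, 180) != 0
            assert m.drug_on(t) == expected


class TestCellStep:
    def test_fully_surrounded_cell_never_divides(self):
        p = CompetitiveReleaseParams(xDim=8, yDim=8, death_rate=0.0)
        m = CompetitiveReleaseModel(p, RandomSource(1))
        for dx in (-1, 0, 1):
            for dy in (-1, 0, 1):
                m.grid.new_agent_sq(4 + dx, 4 + dy)
        center = m.grid.get_agent(4, 4)
        for _ in range(500):
            m.cell_step(center)
        assert m.population() == 9

    def test_single_cell_event_rates_match_analytic(self):
        """Monte-Carlo death/division frequencies of a lone drug-free
        sensitive cell match the per-tick probabilities (4-sigma)."""
        p = CompetitiveReleaseParams(xDim=8, yDim=8)
        m = CompetitiveReleaseModel(p, RandomSource(2))
        trials, deaths, divisions = 10**5, 0, 0
        cell = m.grid.new_agent_sq(4, 4)
        cell.type = SENSITIVE
        for _ in range(trials):
            pop_before = m.population()
            m.cell_step(cell)
            if not cell.alive:
                deaths += 1
                cell = m.grid.new_agent_sq(4, 4)
                cell.type = SENSITIVE
            elif m.population() > pop_before:
                divisions += 1
                for other in list(m.grid):
                    if other is not cell:
                        m.grid.dispose(other)
        for observed, prob in ((deaths, p.death_prob),
                               (divisions, (1 - p.death_prob) * p.div_prob_sen)):
            sd = math.sqrt(trials * prob * (1 - prob))
            assert abs(observed - trials * prob) < 4 * sd

    def test_drug_raises_sensitive_death_only(self):
        p = CompetitiveReleaseParams(xDim=8, yDim=8)
        m = CompetitiveReleaseModel(p, RandomSource(3))
        m.drug.set_all(1.0)
        trials = 4 * 10**4
        deaths = {SENSITIVE: 0, RESISTANT: 0}
        for t in (SENSITIVE, RESISTANT):
            cell = m.grid.new_agent_sq(4, 4)
            cell.type = t
            for _ in range(trials):
                m.cell_step(cell)
                if not cell.alive:
                    deaths[t] += 1
                    cell = m.grid.new_agent_sq(4, 4)
                    cell.type = t
                else:
                    for other in list(m.grid):
                        if other is not cell:
                            m.grid.dispose(other)
            m.grid.dispose(cell)
            m.drug.set_all(1.0)  # uptake has been nibbling at it
        p_sen = p.death_prob + 1.0 * p.drug_death
        sd = math.sqrt(trials * p_sen * (1 - p_sen))
        assert abs(deaths[SENSITIVE] - trials * p_sen) < 5 * sd
        sd_res = math.sqrt(trials * p.death_prob * (1 - p.death_prob))
        assert abs(deaths[RESISTANT] - trials * p.death_prob) < 5 * sd_res

    def test_daughters_inherit_type(self, params_small):
        m = CompetitiveReleaseModel(params_small, RandomSource(4))
        m.init_tumor(radius=3, resistantProb=1.0)
        for tick in range(60):
            m.model_step(tick)
        assert m.population() > 0
        assert all(c.type == RESISTANT for c in m.grid)


class TestModelStep:
    def test_fast_sweep_matches_reference_cell_step_loop(self):
        """The inlined sweep in model_step and an explicit shuffle +
        cell_step loop produce identical trajectories from one seed."""
        p = CompetitiveReleaseParams(xDim=20, yDim=20)
        fast = CompetitiveReleaseModel(p, RandomSource(7))
        ref = CompetitiveReleaseModel(p, RandomSource(7))
        fast.init_tumor(radius=4)
        ref.init_tumor(radius=4)
        for tick in range(60):
            fast.model_step(tick)
            # reference path: public single-cell operation
            ref.grid.shuffle_agents(ref.rng)
            for cell in ref.grid:
                ref.cell_step(cell)
            if ref.drug_on(tick):
                ref.drug.diffusion_adi(p.drug_diff_rate, p.drug_boundary_val)
            else:
                ref.drug.diffusion_adi(p.drug_diff_rate)
            ref.drug.update()
            ref.grid.increment_tick()
        assert fast.population() == ref.population()
        occ_fast = {c.i: c.type for c in fast.grid}
        occ_ref = {c.i: c.type for c in ref.grid}
        assert occ_fast == occ_ref
        assert np.array_equal(fast.drug.values, ref.drug.values)

    def test_no_drug_arm_field_stays_zero(self, params_small):
        m = CompetitiveReleaseModel(params_small, RandomSource(0), drug_duration=0.0)
        m.init_tumor(radius=4)
        for tick in range(300):
            m.model_step(tick)
        assert (m.drug.values == 0.0).all()

    def test_drug_field_bounded_by_maximum_principle(self):
        p = CompetitiveReleaseParams(xDim=20, yDim=20)
        m = CompetitiveReleaseModel(p, RandomSource(5))
        m.init_tumor(radius=4)
        for tick in range(500):
            m.model_step(tick)
            assert m.drug.values.min() >= 0.0
            assert m.drug.values.max() <= p.drug_boundary_val + 1e-12

    def test_population_bounded_by_lattice(self, params_small):
        m = CompetitiveReleaseModel(params_small, RandomSource(6), drug_duration=0.0)
        m.init_tumor(radius=4)
        for tick in range(600):
            m.model_step(tick)
        assert m.population() <= 24 * 24


class TestDrawModel:
    def test_empty_model_zero_drug_is_black(self, params_small):
        m = CompetitiveReleaseModel(params_small, RandomSource(0))
        r = Raster(24, 24)
        m.draw_model(r, 0)
        assert all(r.get_pix(x, y) == 0 for x in range(24) for y in range(24))

    def test_cells_draw_type_color_with_slot_offset(self, params_small):
        m = CompetitiveReleaseModel(params_small, RandomSource(0))
        c = m.grid.new_agent_sq(3, 7)
        c.type = RESISTANT
        r = Raster(24 * 3, 24)
        m.draw_model(r, 2)
        assert r.get_pix(2 * 24 + 3, 7) == RESISTANT
        assert r.get_pix(3, 7) == 0  # slot 0 untouched

    def test_drug_draws_heatmap_color(self, params_small):
        from hybridgrid.toolkit import heat_map_rgb
        m = CompetitiveReleaseModel(params_small, RandomSource(0))
        m.drug.set_all(0.5)
        r = Raster(24, 24)
        m.draw_model(r, 0)
        assert r.get_pix(5, 5) == heat_map_rgb(0.5)

    def test_raster_too_narrow_raises(self, params_small):
        m = CompetitiveReleaseModel(params_small, RandomSource(0))
        with pytest.raises(IndexError):
            m.draw_model(Raster(24, 24), 1)


class TestExperiment:
    def test_arms_identical_before_treatment(self):
        """Same seed, no drug yet: all three arms march in lockstep."""
        p = CompetitiveReleaseParams(xDim=40, yDim=40)
        models = build_arms(p)
        for tick in range(241):
            pops = []
            for m in models:
                m.model_step(tick)
                pops.append(m.population())
            assert pops[0] == pops[1] == pops[2]
        occ = [{c.i: c.type for c in m.grid} for m in models]
        assert occ[0] == occ[1] == occ[2]

    def test_csv_shape_and_snapshots(self, tmp_path, params_small):
        out = run_experiment(params_small, tmp_path, snapshot_days=5, visScale=1)
        rows = (tmp_path / "populations.csv").read_text().splitlines()
        assert len(rows) == params_small.steps
        assert all(len(r.split(",")) == 3 for r in rows)
        # 100 ticks of 2h = 8.33 days -> snapshots at day 0 and 5
        names = sorted(x.name for x in tmp_path.glob("*.png"))
        assert names == ["ModelsDay0.png", "ModelsDay5.png"]

    def test_seeded_run_byte_identical(self, tmp_path, params_small):
        run_experiment(params_small, tmp_path / "a", visScale=1)
        run_experiment(params_small, tmp_path / "b", visScale=1)
        assert (tmp_path / "a/populations.csv").read_bytes() == \
               (tmp_path / "b/populations.csv").read_bytes()
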