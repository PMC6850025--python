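"""Simulator: temperature scenarios, thermal growth model, sampling."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from warmgrowth.config import ConfigError, GrowthParams, SelectivityParams, SimulationConfig
from warmgrowth import growthsim


def _config(**kw):
    base = dict(
        recruits_per_year_per_area=5,
        reference_temp_sd=0.0,
        temp_obs_sd=0.0,
        reference_temp_trend=0.0,
        individual_growth_cv=0.0,
        annual_growth_cv=0.0,
        measurement_sd=0.0,
        rng_seed=0,
    )
    base.update(kw)
    return SimulationConfig(**base).validate()


class TestTemperature:
    def test_no_warming_areas_identical(self):
        heated, ref = growthsim.generate_temperature_series(
            _config(warming_form="none", warming_magnitude=0.0)
        )
        pd.testing.assert_series_equal(heated.temps, ref.temps)

    def test_step_offset_exact(self):
        cfg = _config(warming_form="step", warming_magnitude=7.0)
        heated, ref = growthsim.generate_temperature_series(cfg)
        diff = heated.temps - ref.temps
        assert (diff[diff.index < 1980] == 0.0).all()
        assert np.allclose(diff[diff.index >= 1980], 7.0)

    def test_linear_ramp_midpoint(self):
        # magnitude 7 over 24 years: halfway (impact+12) the offset is 3.5
        cfg = _config(
            warming_form="linear",
            warming_magnitude=7.0,
            warming_form_params={"ramp_years": 24.0},
        )
        offset = growthsim.warming_offset([1980 + 12], cfg)
        assert offset[0] == pytest.approx(3.5, abs=1e-12)

    def test_saturating_forms_bounded(self):
        years = np.arange(1969, 2005)
        for form in ("asymptotic", "sigmoid"):
            cfg = _config(warming_form=form, warming_magnitude=7.0)
            dt = growthsim.warming_offset(years, cfg)
            assert (dt[years < 1980] == 0).all()
            assert (dt >= 0).all() and (dt <= 7.0).all()
            assert dt[-1] > dt[years >= 1980][0]  # increases toward magnitude

    def test_unknown_form_rejected(self):
        with pytest.raises(ConfigError, match="warming_form"):
            _config(warming_form="quadratic")

    def test_shared_trend_by_construction(self):
        cfg = _config(reference_temp_trend=0.05, warming_form="step")
        heated, ref = growthsim.generate_temperature_series(cfg)
        post = heated.temps.index >= 1981
        d = (heated.temps - ref.temps)[post]
        assert np.allclose(np.diff(d), 0.0)  # offset constant => same trend


class TestGrowthIncrement:
    def test_maximum_at_optimum(self):
        p = GrowthParams()
        length = 80.0
        t_opt = growthsim.thermal_optimum(length, p)
        expected_gmax = p.k * (p.l_inf_mm - length)
        assert growthsim.growth_increment(length, t_opt, p) == pytest.approx(
            expected_gmax, rel=1e-12
        )

    def test_zero_at_asymptotic_length(self):
        p = GrowthParams()
        assert growthsim.growth_increment(p.l_inf_mm, 25.0, p) == 0.0

    def test_optimum_declines_logarithmically(self):
        # theta0=30, theta1=5, l_ref=70: at L = 70*e the optimum is 25 degC
        p = GrowthParams(theta0_c=30.0, theta1_c=5.0, l_ref_mm=70.0)
        assert growthsim.thermal_optimum(70.0 * np.e, p) == pytest.approx(25.0, abs=1e-12)
        # clamped at theta0 for fish below the reference length
        assert growthsim.thermal_optimum(10.0, p) == pytest.approx(30.0)

    def test_nonpositive_length_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            growthsim.growth_increment(0.0, 20.0, GrowthParams())

    def test_increment_nonnegative_everywhere(self):
        p = GrowthParams()
        lengths = np.linspace(1.0, p.l_inf_mm + 50, 200)
        inc = growthsim.growth_increment(lengths, 35.0, p)
        assert (inc >= 0).all()


class TestPopulation:
    def test_deterministic_and_identical_across_areas(self):
        pop = growthsim.simulate_population(_config(warming_form="none"))
        # zero noise + no warming: every same-cohort fish in both areas has
        # the same trajectory
        traj = pop.trajectories
        per_cohort_age = traj.groupby(["birth_year", "age"])["length_mm"].nunique()
        assert (per_cohort_age == 1).all()

    def test_trajectories_strictly_increasing(self, small_config):
        pop = growthsim.simulate_population(small_config)
        diffs = (
            pop.trajectories.sort_values(["fish_id", "age"])
            .groupby("fish_id")["length_mm"]
            .diff()
            .dropna()
        )
        assert (diffs > 0).all()

    def test_same_seed_bit_identical(self, small_config):
        a = growthsim.simulate_population(small_config)
        b = growthsim.simulate_population(small_config)
        pd.testing.assert_frame_equal(a.fish, b.fish)
        pd.testing.assert_frame_equal(a.trajectories, b.trajectories)

    def test_heated_age1_exceeds_reference_after_warming(self):
        pop = growthsim.simulate_population(_config(warming_form="step"))
        age1 = pop.trajectories[pop.trajectories["age"] == 1]
        means = age1.groupby(["area", "birth_year"])["length_mm"].mean().unstack(0)
        post = means.index >= 1980
        assert (means.loc[post, "heated"] > means.loc[post, "reference"]).all()
        pre = means.index < 1980
        assert np.allclose(means.loc[pre, "heated"], means.loc[pre, "reference"])

    def test_warming_magnitude_monotone_below_optimum(self):
        # while the heated area stays below the small-fish optimum, more
        # warming means weakly larger age-1 differences
        diffs = []
        for mag in (0.0, 2.0, 4.0, 5.0):
            pop = growthsim.simulate_population(
                _config(warming_form="step", warming_magnitude=mag)
            )
            age1 = pop.trajectories[
                (pop.trajectories["age"] == 1) & (pop.trajectories["birth_year"] >= 1980)
            ]
            m = age1.groupby("area")["length_mm"].mean()
            diffs.append(m["heated"] - m["reference"])
        assert all(b >= a - 1e-12 for a, b in zip(diffs, diffs[1:]))

    def test_capture_consistency(self, small_config):
        pop = growthsim.simulate_population(small_config)
        fish = pop.fish
        assert (fish["capture_year"] == fish["birth_year"] + fish["capture_age"]).all()
        assert (fish["capture_year"] <= small_config.year_end).all()
        assert (fish["capture_length_mm"] > 0).all()

    def test_individuals_view_matches_tables(self, quiet_config):
        pop = growthsim.simulate_population(quiet_config)
        ind = next(pop.individuals())
        row = pop.fish.iloc[0]
        assert ind.fish_id == row.fish_id
        assert len(ind.true_length_at_age) == row.capture_age + 1
        assert ind.true_length_at_age[0] == quiet_config.growth_params.hatch_mm


class TestSampleCatch:
    def test_identity_filter_returns_all_females(self, quiet_config):
        pop = growthsim.simulate_population(quiet_config)
        sampled, meta = growthsim.sample_catch(
            pop, apply_selectivity=False, stratify=False
        )
        assert (sampled["sex"] == "F").all()
        assert len(sampled) == (pop.fish["sex"] == "F").sum()
        assert meta["n_sampled"] == meta["n_female"]

    def test_l50_is_half_retention(self):
        p = SelectivityParams(l50_mm=100.0, slope_mm=20.0)
        assert growthsim.logistic_selectivity(100.0, p) == pytest.approx(0.5)

    def test_stratified_cap(self, rng):
        # one bin with 10 fish, cap of 2 -> exactly 2 retained
        cfg = SimulationConfig(
            stratified_subsample_n=2, stratification_start_year=1990
        )
        fish = pd.DataFrame(
            {
                "fish_id": range(10),
                "area": "heated",
                "birth_year": 1990,
                "sex": "F",
                "capture_age": 5,
                "capture_year": 1995,
                "capture_length_mm": np.linspace(150, 160, 10),
            }
        )
        pop = growthsim.Population(
            fish=fish,
            trajectories=pd.DataFrame(),
            temperature_heated=None,
            temperature_reference=None,
            config=cfg,
        )
        sampled, _ = growthsim.sample_catch(pop, cfg, rng, apply_selectivity=False)
        assert len(sampled) == 2

    def test_empty_result_warns_not_raises(self, quiet_config):
        pop = growthsim.simulate_population(quiet_config)
        pop = dataclasses.replace(pop, fish=pop.fish.assign(sex="M"))
        with pytest.warns(UserWarning, match="no fish"):
            sampled, _ = growthsim.sample_catch(pop)
        assert len(sampled) == 0


class TestCommunityRecords:
    def test_schema_and_effort(self, small_null_config):
        rec = growthsim.simulate_catch_records(small_null_config)
        assert set(rec.columns) >= {
            "area", "year", "month", "station", "night", "species", "count", "nets",
        }
        assert rec["count"].ge(0).all()
        assert set(rec.loc[rec["area"] == "heated", "month"]) == {10}
        assert set(rec.loc[rec["area"] == "reference", "month"]) == {8}

    def test_drift_only_after_impact_in_heated(self, small_config):
        cfg = small_config
        rec = growthsim.simulate_catch_records(cfg)
        smelt = rec[rec["species"] == "smelt"].groupby(["area", "year"])["count"].mean()
        pre = smelt["heated"][smelt["heated"].index < cfg.impact_year].mean()
        post = smelt["heated"][smelt["heated"].index >= cfg.impact_year + 12].mean()
        assert post < pre  # cold-water species declines in the heated area
        ref_pre = smelt["reference"][smelt["reference"].index < cfg.impact_year].mean()
        ref_post = smelt["reference"][smelt["reference"].index >= cfg.impact_year + 12].mean()
        assert abs(ref_post - ref_pre) < 0.5 * abs(post - pre) + 1.0
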