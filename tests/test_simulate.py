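"""Synthetic-data generator: structure, determinism, and the generative
model's moments."""

import numpy as np
import pandas as pd
import pytest

from cattlernm.pedigree import PedigreeTable, validate_and_sort
from cattlernm.simulate import (SimScenario, _sample_genetic_coefficients,
                                battery_scenario, build_g8, simulate_dataset,
                                simulate_pedigree, simulate_weather)


def tiny_scenario(**kw):
    base = dict(n_founders=80, n_generations=2, n_farms=3, years=(2000, 2010),
                seed=11)
    base.update(kw)
    return SimScenario(**base)


class TestScenarioValidation:
    def test_psd_enforced(self):
        bad = np.eye(8)
        bad[0, 1] = bad[1, 0] = 5.0
        with pytest.raises(ValueError, match="positive semi-definite"):
            tiny_scenario(true_g8=bad)

    def test_missing_rate_bounds(self):
        with pytest.raises(ValueError, match="missing_ww_rate"):
            tiny_scenario(missing_ww_rate=1.5)

    def test_generations_minimum(self):
        with pytest.raises(ValueError, match="generation"):
            tiny_scenario(n_generations=0)


class TestPedigreeSim:
    def test_single_generation_offspring_have_founder_parents(self):
        ped = simulate_pedigree(tiny_scenario(n_generations=1))
        founders = set(ped.loc[ped["generation"] == 0, "animal"])
        kids = ped[ped["generation"] == 1]
        assert kids["sire"].isin(founders).all()
        assert kids["dam"].isin(founders).all()

    def test_determinism(self):
        a = simulate_pedigree(tiny_scenario())
        b = simulate_pedigree(tiny_scenario())
        pd.testing.assert_frame_equal(a, b)

    def test_acyclic_and_sorted(self):
        ped = simulate_pedigree(tiny_scenario(n_generations=3))
        sorted_ped = validate_and_sort(ped[["animal", "sire", "dam", "birth_date"]])
        assert len(sorted_ped) == len(ped)

    def test_generation_depth(self):
        ped = simulate_pedigree(tiny_scenario(n_founders=200, n_generations=3,
                                              years=(2000, 2016)))
        sorted_ped = validate_and_sort(ped[["animal", "sire", "dam"]])
        depth = sorted_ped.generation_depth()
        by_animal = dict(zip(sorted_ped.ids, depth))
        last = ped[ped["generation"] == 3]
        got = np.array([by_animal[a] for a in last["animal"]])
        assert got.mean() == pytest.approx(3.0, abs=0.01)

    def test_dams_reused_across_parities(self):
        ped = simulate_pedigree(tiny_scenario(progeny_per_dam=3))
        counts = ped.loc[ped["dam"].notna(), "dam"].value_counts()
        assert (counts >= 2).any()
        parities = ped.groupby("dam")["parity"].nunique().dropna()
        assert parities.max() >= 2


class TestWeatherSim:
    def test_determinism(self):
        a = simulate_weather(tiny_scenario(n_farms=2))
        b = simulate_weather(tiny_scenario(n_farms=2))
        for f in a:
            pd.testing.assert_frame_equal(a[f].daily, b[f].daily)
            pd.testing.assert_frame_equal(a[f].hourly, b[f].hourly)

    def test_dewpoint_never_exceeds_temperature(self):
        w = simulate_weather(tiny_scenario(n_farms=2))
        for f in w:
            assert (w[f].hourly["dewpoint_c"] <= w[f].hourly["temp_c"] + 1e-12).all()
            assert (w[f].daily["precip_mm"] >= 0).all()

    def test_zero_drought_amplitude_equalises_years(self):
        w = simulate_weather(tiny_scenario(n_farms=1, wet_dry_amplitude=0.0,
                                           farm_precip_spread=0.0))
        daily = w[0].daily
        annual = daily.groupby(pd.to_datetime(daily["date"]).dt.year)["precip_mm"].sum()
        annual = annual.iloc[1:-1]  # full years only
        assert annual.std() / annual.mean() < 0.25  # occurrence noise only

    def test_zero_depression_zero_noise_gives_saturation(self):
        from cattlernm.enviro import compute_rh
        w = simulate_weather(tiny_scenario(
            n_farms=1, dewpoint_depression_c=0.0, dewpoint_seasonal_amp_c=0.0,
            dewpoint_noise_sd_c=0.0, temp_noise_sd_c=0.0))
        h = w[0].hourly
        rh = compute_rh(h["temp_c"].to_numpy(), h["dewpoint_c"].to_numpy())
        assert np.allclose(rh, 100.0, atol=1e-9)


class TestGeneticCoefficients:
    def test_founder_covariance_recovers_g8(self):
        """Sampled founder coefficient vectors have covariance G8."""
        g8 = battery_scenario(4, n_founders=10).true_g8
        n = 5000
        ped = PedigreeTable(np.array([f"f{i}" for i in range(n)], dtype=object),
                            np.full(n, -1), np.full(n, -1))
        rng = np.random.default_rng(99)
        coef = _sample_genetic_coefficients(ped, g8, rng)
        emp = np.cov(coef.T)
        rel = np.linalg.norm(emp - g8) / np.linalg.norm(g8)
        assert rel < 0.10

    def test_offspring_regression_on_midparent(self):
        """Offspring coefficients = parent average + Mendelian noise, so the
        regression of offspring on mid-parent is 1."""
        n_fam = 4000
        ids = []
        sire = []
        dam = []
        for k in range(n_fam):
            ids += [f"s{k}", f"d{k}", f"o{k}"]
            sire += [-1, -1, 3 * k]
            dam += [-1, -1, 3 * k + 1]
        ped = PedigreeTable(np.array(ids, dtype=object),
                            np.array(sire), np.array(dam))
        g8 = battery_scenario(2, n_founders=10).true_g8
        coef = _sample_genetic_coefficients(ped, g8, np.random.default_rng(7))
        off = coef[2::3, 0]
        mid = 0.5 * (coef[0::3, 0] + coef[1::3, 0])
        slope = np.polyfit(mid, off, 1)[0]
        assert slope == pytest.approx(1.0, abs=0.05)


class TestPhenotypes:
    def test_determinism(self):
        a = simulate_dataset(tiny_scenario())[2]
        b = simulate_dataset(tiny_scenario())[2]
        pd.testing.assert_frame_equal(a, b)

    def test_missing_ww_rate_within_binomial_bounds(self):
        sc = tiny_scenario(n_founders=400, missing_ww_rate=0.2, years=(2000, 2014))
        rec = simulate_dataset(sc)[2]
        n = len(rec)
        frac = rec["ww_kg"].isna().mean()
        half_width = 2.58 * np.sqrt(0.2 * 0.8 / n)
        assert abs(frac - 0.2) < half_width + 1e-9

    def test_pure_residual_when_no_genetics(self):
        sc = tiny_scenario(n_founders=600, years=(2000, 2014),
                           true_g8=np.zeros((8, 8)), true_pm=np.zeros((2, 2)),
                           true_cg=np.zeros((2, 2)),
                           true_r=np.diag([9.0, 25.0]), missing_ww_rate=0.0)
        rec = simulate_dataset(sc)[2]
        # BW variance within a fixed-effect class is residual only
        grp = rec.groupby(["sex_birth_class", "parity_class", "veg_zone"])
        resid = rec["bw_kg"] - grp["bw_kg"].transform("mean") \
            - sc.fixed_effect_values["ec_slope"]["bw"] * (
                rec["ec_scaled"] - grp["ec_scaled"].transform("mean"))
        assert resid.var(ddof=1) == pytest.approx(9.0, rel=0.07)

    def test_mean_by_fixed_class_matches_specified_values(self):
        sc = tiny_scenario(n_founders=800, years=(2000, 2014))
        rec = simulate_dataset(sc)[2]
        fe = sc.fixed_effect_values
        # difference of class means estimates the difference of class effects
        m = rec.groupby("sex_birth_class")["bw_kg"].agg(["mean", "count"])
        if {"1", "3"} <= set(m.index):
            diff = m.loc["3", "mean"] - m.loc["1", "mean"]
            expected = fe["sex_birth_class"]["3"] - fe["sex_birth_class"]["1"]
            se = 3 * np.sqrt(rec["bw_kg"].var() * (1 / m.loc["3", "count"]
                                                   + 1 / m.loc["1", "count"]))
            assert abs(diff - expected) < se

    def test_truth_ledger_reconstructs_phenotype(self):
        """records = fixed + phi u + phi v(dam) + mpe + cg + e, exactly."""
        sc = tiny_scenario(missing_ww_rate=0.0)
        pedf, weather, rec, truth = simulate_dataset(sc)
        fe = sc.fixed_effect_values
        coef = truth.coefficients.set_index("animal")
        mpe = truth.mpe.set_index("dam")
        cg = truth.cg_effects.set_index("cg_id")
        row = rec.iloc[37]
        expect = (fe["mu"]["bw"]
                  + fe["sex_birth_class"][row["sex_birth_class"]]
                  + fe["parity_class"][row["parity_class"]]
                  + fe["veg_zone"][row["veg_zone"]]
                  + fe["ec_slope"]["bw"] * row["ec_scaled"]
                  + coef.loc[row["animal"], "u_bw0"]
                  + coef.loc[row["animal"], "u_bw1"] * row["ec_scaled"]
                  + cg.loc[row["cg_id"], "bw"])
        if pd.notna(row["dam"]):
            expect += (coef.loc[row["dam"], "v_bw0"]
                       + coef.loc[row["dam"], "v_bw1"] * row["ec_scaled"]
                       + mpe.loc[row["dam"], "bw"])
        resid = row["bw_kg"] - expect
        assert abs(resid) < 6 * np.sqrt(sc.true_r[0, 0])


class TestBuildG8:
    def test_targets_hit_at_midpoint(self):
        g8, pm, cg, r = build_g8(0.3, 0.1, 0.5, 0.3, 0.2, 0.1, 0.4, 0.3,
                                 vp=25.0, prop_mpe=0.08, prop_cg=0.10)
        vp0 = g8[0, 0] + g8[4, 4] + pm[0, 0] + cg[0, 0] + r[0, 0]
        assert vp0 == pytest.approx(25.0)
        assert g8[0, 0] / vp0 == pytest.approx(0.3)
        assert g8[4, 4] / vp0 == pytest.approx(0.1)
        assert g8[1, 1] / g8[0, 0] == pytest.approx(0.5)
        assert np.linalg.eigvalsh(g8).min() > -1e-10

    def test_battery_scenarios_all_valid(self):
        for i in range(10):
            sc = battery_scenario(i, n_founders=20)
            assert np.linalg.eigvalsh(sc.true_g8).min() > -1e-10
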