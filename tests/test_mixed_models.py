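import numpy as np
import pandas as pd
import pytest

import stablegrid as sg
from stablegrid.mixed_models import (AICcUndefinedError, build_design,
                                     lsm_rows, stepwise_select)

from .helpers import oracle_gls


def balanced_usage(n_days=3, noise_sd=0.0, seed=0):
    """2 breeds x 2 animals x n_days, fully balanced, known cell structure."""
    rng = np.random.default_rng(seed)
    rows = []
    base = {"warmblood": 50.0, "pony": 60.0}
    day_eff = {d: 2.0 * d for d in range(1, n_days + 1)}
    metas = []
    hid = 0
    for breed in ("warmblood", "pony"):
        for _ in range(2):
            hid += 1
            metas.append({"horse_id": hid, "breed_class": breed,
                          "sex": "mare", "age": 10.0, "entry_day": 1})
            for d in range(1, n_days + 1):
                rows.append({
                    "horse_id": hid, "day": d, "variant": "with_pasture",
                    "hours_covered": 24, "n_fixes": 8640, "included": True,
                    "squares_per_hour": base[breed] + day_eff[d]
                    + rng.normal(0, noise_sd),
                })
    return pd.DataFrame(rows), pd.DataFrame(metas)


def simulated_lmm_frame(n_horses=12, n_days=10, sigma_a=4.0, sigma_e=3.0,
                        age_slope=0.0, seed=1):
    """Usage data drawn directly from the mixed model (not the simulator)."""
    rng = np.random.default_rng(seed)
    ages = rng.integers(2, 30, n_horses).astype(float)
    breeds = rng.choice(["warmblood", "pony", "other"], n_horses)
    sexes = rng.choice(["gelding", "mare"], n_horses)
    effects = rng.normal(0, sigma_a, n_horses)
    day_eff = rng.normal(0, 2.0, n_days)
    rows, metas = [], []
    for h in range(n_horses):
        metas.append({"horse_id": h + 1, "breed_class": breeds[h],
                      "sex": sexes[h], "age": ages[h], "entry_day": 1})
        for d in range(n_days):
            rows.append({
                "horse_id": h + 1, "day": d + 1, "included": True,
                "squares_per_hour": 50.0 + day_eff[d] + effects[h]
                + age_slope * (ages[h] - 12.0) + rng.normal(0, sigma_e),
            })
    return pd.DataFrame(rows), pd.DataFrame(metas), effects


class TestModel1:
    def test_balanced_lsms_equal_cell_means(self):
        usage, metas = balanced_usage(noise_sd=1.0, seed=3)
        fit = sg.fit_model1(usage, metas, terms=("breed_class", "day"))
        lsm = fit.lsm("breed_class").set_index("level")["lsm"]
        merged = usage.merge(metas, on="horse_id")
        cell = merged.groupby("breed_class")["squares_per_hour"].mean()
        for breed in ("warmblood", "pony"):
            assert lsm[breed] == pytest.approx(cell[breed], abs=1e-8)
        day_lsm = fit.lsm("day").set_index("level")["lsm"]
        day_mean = merged.groupby(merged["day"].astype(str).str.zfill(3))[
            "squares_per_hour"].mean()
        for d in day_mean.index:
            assert day_lsm[d] == pytest.approx(day_mean[d], abs=1e-8)

    def test_fixed_effects_match_gls_oracle(self):
        usage, metas, _ = simulated_lmm_frame(n_horses=6, n_days=5, seed=5)
        fit = sg.fit_model1(usage, metas, terms=("breed_class", "age"))
        df = sg.prepare_model1_frame(usage, metas)
        X, info = build_design(df, ["breed_class", "age"])
        beta = oracle_gls(df["squares_per_hour"], X, df["horse_id"],
                          fit.sigma_a2, fit.sigma_e2)
        np.testing.assert_allclose(fit.params.to_numpy(), beta, rtol=1e-5)

    def test_null_effects_recovered(self):
        usage, metas, _ = simulated_lmm_frame(
            n_horses=14, n_days=12, sigma_a=0.0, age_slope=0.0, seed=11)
        fit = sg.fit_model1(usage, metas)
        assert fit.sigma_a2 < 0.5
        est, se, _ = fit.coef("age")
        assert est - 1.96 * se <= 0.0 <= est + 1.96 * se

    def test_variance_components_nonnegative(self):
        usage, metas, _ = simulated_lmm_frame(seed=2)
        fit = sg.fit_model1(usage, metas)
        assert fit.sigma_a2 >= 0.0
        assert fit.sigma_e2 > 0.0
        assert fit.aicc >= fit.aic

    def test_blups_track_true_animal_effects(self):
        usage, metas, effects = simulated_lmm_frame(
            n_horses=15, n_days=15, sigma_a=5.0, sigma_e=3.0, seed=8)
        fit = sg.fit_model1(usage, metas)
        from scipy.stats import spearmanr
        blups = np.array([fit.blups[h + 1] for h in range(15)])
        assert spearmanr(blups, effects).statistic > 0.8

    def test_single_sex_design_names_aliased_term(self):
        usage, metas = balanced_usage(noise_sd=1.0)
        with pytest.raises(sg.RankDeficiencyError, match="sex"):
            sg.fit_model1(usage, metas, terms=("breed_class", "sex", "day"))


class TestStepwise:
    def test_intercept_only_truth_mostly_stops_at_intercept(self):
        hits = 0
        for rep in range(10):
            usage, metas, _ = simulated_lmm_frame(
                n_horses=8, n_days=6, sigma_a=3.0, sigma_e=3.0,
                age_slope=0.0, seed=100 + rep)
            # rebuild response with no day effect either
            rng = np.random.default_rng(200 + rep)
            df = sg.prepare_model1_frame(usage, metas)
            effects = rng.normal(0, 3.0, 8)
            df["squares_per_hour"] = (50.0 + effects[df["horse_id"] - 1]
                                      + rng.normal(0, 3.0, len(df)))
            chosen, _, trace = stepwise_select(
                df, "squares_per_hour",
                ["breed_class", "sex", "age"], groups="horse_id")
            hits += (chosen == [])
        assert hits >= 9

    def test_strong_day_effect_selected_first(self):
        rng = np.random.default_rng(7)
        usage, metas, _ = simulated_lmm_frame(n_horses=8, n_days=6, seed=7)
        df = sg.prepare_model1_frame(usage, metas)
        day_eff = {d: 15.0 * i for i, d in enumerate(sorted(df["day"].unique()))}
        df["squares_per_hour"] = (50.0 + df["day"].map(day_eff)
                                  + rng.normal(0, 2.0, len(df)))
        chosen, _, trace = stepwise_select(
            df, "squares_per_hour", ["breed_class", "sex", "day", "age"],
            groups="horse_id")
        assert chosen[0] == "day"
        first_round = trace[(trace["round"] == 1) & (trace["status"] == "chosen")]
        assert first_round["candidate"].tolist() == ["day"]

    def test_single_improving_candidate_one_round(self):
        usage, metas, _ = simulated_lmm_frame(
            n_horses=10, n_days=8, age_slope=-1.5, sigma_a=1.0, seed=13)
        df = sg.prepare_model1_frame(usage, metas)
        chosen, fit, trace = stepwise_select(df, "squares_per_hour", ["age"],
                                             groups="horse_id")
        assert chosen == ["age"]
        assert trace["round"].max() == 1

    def test_aicc_refused_when_undefined(self):
        usage, metas = balanced_usage(n_days=3)
        df = sg.prepare_model1_frame(usage, metas)
        df = df.iloc[:5]  # n=5: day (3 levels) + intercept + 2 var = 6 params
        chosen, _, trace = stepwise_select(df, "squares_per_hour", ["day"],
                                           groups="horse_id")
        assert any(trace["status"].str.startswith("refused")), trace
        assert chosen == []

    def test_empty_candidates_rejected(self):
        usage, metas = balanced_usage()
        df = sg.prepare_model1_frame(usage, metas)
        with pytest.raises(ValueError):
            stepwise_select(df, "squares_per_hour", [], groups="horse_id")


class TestLsmBonferroni:
    def test_two_level_factor_multiplier_is_one(self):
        usage, metas, _ = simulated_lmm_frame(seed=4)
        fit = sg.fit_model1(usage, metas)
        _, comp = sg.lsm_with_bonferroni(fit, "sex")
        assert len(comp) == 1
        assert comp["p_adj"].iloc[0] == pytest.approx(comp["p_raw"].iloc[0])

    def test_day_factor_combinatorics(self):
        assert sg.n_pairwise(227) == 25_651

    def test_adjusted_significance_is_subset(self):
        usage, metas, _ = simulated_lmm_frame(n_horses=12, n_days=8, seed=6)
        fit = sg.fit_model1(usage, metas)
        _, comp = sg.lsm_with_bonferroni(fit, "day")
        assert sg.n_pairwise(8) == len(comp)
        assert (comp["p_adj"] >= comp["p_raw"] - 1e-15).all()
        adj_sig = set(comp.index[comp["significant"]])
        raw_sig = set(comp.index[comp["p_raw"] < 0.05])
        assert adj_sig <= raw_sig

    def test_balanced_one_way_lsms_are_group_means(self):
        rng = np.random.default_rng(1)
        freq = pd.DataFrame({
            "day": np.repeat([1, 2, 3, 4], 2),
            "row": 0, "col": np.tile([0, 1], 4),
            "location": np.tile(["LH_1", "FS_1"], 4),
            "frequency": rng.uniform(0, 10, 8),
        })
        fit = sg.fit_model2(freq, terms=("location",))
        lsm = fit.lsm("location").set_index("level")["lsm"]
        means = freq.groupby("location")["frequency"].mean()
        for loc in means.index:
            assert lsm[loc] == pytest.approx(means[loc], abs=1e-10)

    def test_one_level_factor_empty_comparisons(self):
        freq = pd.DataFrame({"day": [1, 2, 3], "row": 0, "col": 0,
                             "location": "LH_1",
                             "frequency": [1.0, 2.0, 3.0]})
        fit = sg.fit_model2(freq, terms=("location",))
        _, comp = sg.lsm_with_bonferroni(fit, "location")
        assert len(comp) == 0


class TestModel2:
    def test_constant_location_frequencies_recovered_exactly(self):
        days = range(1, 6)
        rows = []
        for d in days:
            rows.append({"day": d, "row": 1, "col": 1, "location": "LH_1",
                         "frequency": 7.0})
            rows.append({"day": d, "row": 2, "col": 2, "location": "FS_1",
                         "frequency": 3.0})
        fit = sg.fit_model2(pd.DataFrame(rows))
        lsm = fit.lsm("location").set_index("level")["lsm"]
        assert lsm["LH_1"] == pytest.approx(7.0, abs=1e-10)
        assert lsm["FS_1"] == pytest.approx(3.0, abs=1e-10)

    def test_additive_truth_recovered(self):
        rng = np.random.default_rng(9)
        day_eff = {d: 0.5 * d for d in range(1, 9)}
        loc_eff = {"LH_1": 4.0, "FS_1": 1.0, "PADDOCK": 0.2}
        rows = []
        for d in day_eff:
            for i, (loc, e) in enumerate(loc_eff.items()):
                rows.append({"day": d, "row": i, "col": i, "location": loc,
                             "frequency": 2.0 + day_eff[d] + e
                             + rng.normal(0, 0.05)})
        fit = sg.fit_model2(pd.DataFrame(rows))
        lsm = fit.lsm("location").set_index("level")["lsm"]
        # differences of location LSMs recover generating differences
        assert (lsm["LH_1"] - lsm["FS_1"]) == pytest.approx(3.0, abs=0.1)
        assert (lsm["FS_1"] - lsm["PADDOCK"]) == pytest.approx(0.8, abs=0.1)

    def test_residual_kurtosis_reported(self):
        rng = np.random.default_rng(10)
        rows = [{"day": d, "row": i, "col": i,
                 "location": ["LH_1", "FS_1"][i % 2],
                 "frequency": float(rng.standard_t(3))}
                for d in range(1, 30) for i in range(6)]
        fit = sg.fit_model2(pd.DataFrame(rows))
        assert np.isfinite(fit.excess_kurtosis())


class TestDesignMachinery:
    def test_lsm_rows_weighting(self):
        df = pd.DataFrame({
            "b": ["x", "x", "y", "y"], "d": ["1", "2", "1", "2"],
            "age": [4.0, 6.0, 8.0, 10.0],
        })
        X, info = build_design(df, ["b", "d", "age"])
        levels, L = lsm_rows(info, "b")
        assert levels == ["x", "y"]
        # intercept 1, equal weight 1/2 on the other factor, age at mean 7
        np.testing.assert_allclose(L[0], [1.0, 0.0, 0.5, 7.0])
        np.testing.assert_allclose(L[1], [1.0, 1.0, 0.5, 7.0])
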