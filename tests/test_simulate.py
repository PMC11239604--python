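"""Trial simulator: moments, determinism, and the aligned-test reduction."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import hierpower as hp
from hierpower import DegenerateDataError, EffectSpec, HierarchicalDesign


@pytest.fixture
def null_effect():
    return EffectSpec.single_outcome(0.0, 0, 8)


class TestSimulateTrial:
    def test_row_count_and_columns(self, design, vm, null_effect):
        df = hp.simulate_trial(design, vm, null_effect, seed=1)
        assert len(df) == 5760
        assert {"hospital", "clinic", "provider", "participant", "arm",
                "subgroup"}.issubset(df.columns)
        assert sum(c.startswith("y") for c in df.columns) == 8

    def test_seed_determinism(self, design, vm, null_effect):
        a = hp.simulate_trial(design, vm, null_effect, seed=42)
        b = hp.simulate_trial(design, vm, null_effect, seed=42)
        pd.testing.assert_frame_equal(a, b)
        c = hp.simulate_trial(design, vm, null_effect, seed=43)
        assert not a.equals(c)

    def test_arm_assignment_respects_randomization_level(self, vm,
                                                         null_effect):
        for level, group in [("hospital", "hospital"),
                             ("clinic", ["hospital", "clinic"]),
                             ("provider", ["hospital", "clinic", "provider"])]:
            d = hp.default_design(level)
            df = hp.simulate_trial(d, vm, null_effect, seed=5)
            per_unit = df.groupby(group)["arm"].nunique()
            assert (per_unit == 1).all()
            assert (df["arm"] == "intervention").mean() == 0.5

    def test_effect_shifts_only_affected_outcome(self, design, vm):
        eff = EffectSpec.single_outcome(5.0, 2, 8)
        df0 = hp.simulate_trial(design, vm,
                                EffectSpec.single_outcome(0.0, 2, 8), seed=9)
        df1 = hp.simulate_trial(design, vm, eff, seed=9)
        treated = df1["arm"] == "intervention"
        np.testing.assert_allclose(df1.loc[treated, "y3"],
                                   df0.loc[treated, "y3"] + 5.0)
        np.testing.assert_allclose(df1["y1"], df0["y1"])
        np.testing.assert_allclose(df1.loc[~treated, "y3"],
                                   df0.loc[~treated, "y3"])

    def test_no_clustering_zeroes_cluster_components(self, null_effect):
        vm = hp.VarianceModel(rho_provider=0.0, rho_clinic=0.0,
                              rho_hospital=0.0)
        # with all ICCs zero only the residual component remains, so a
        # same-provider pair is uncorrelated
        d = HierarchicalDesign(400, 1, 3, 2)
        df = hp.simulate_trial(d, vm, null_effect, seed=3)
        wide = df.pivot_table(index=["hospital", "provider"],
                              columns="participant", values="y1")
        r = np.corrcoef(wide[0], wide[1])[0, 1]
        assert abs(r) < 0.1

    def test_same_provider_pair_correlation_near_007(self, vm, null_effect):
        # many independent same-provider pairs; expected correlation
        # 0.05 + 0.01 + 0.01 = 0.07
        d = HierarchicalDesign(500, 2, 3, 2)
        pairs = []
        for seed in range(30):
            df = hp.simulate_trial(d, vm, null_effect, seed=seed)
            wide = df.pivot_table(index=["hospital", "clinic", "provider"],
                                  columns="participant", values="y1")
            pairs.append(wide.to_numpy())
        xy = np.vstack(pairs)
        r = np.corrcoef(xy[:, 0], xy[:, 1])[0, 1]
        assert r == pytest.approx(0.07, abs=0.01)

    def test_moment_recovery_of_isu_composite_mean(self, design, vm):
        # across >= 5000 simulated hospitals the variance of the hospital
        # composite mean must match vbar * w'Sigma w = 0.00194010
        means = hp.simulate_isu_means(design, vm, reps=750, seed=12)
        x = means @ vm.composite_weights
        var = x.reshape(-1).var(ddof=1)
        assert var == pytest.approx(0.0019401041666, rel=0.05)


class TestAnalyzeTrial:
    def test_hospital_level_reduction_equals_two_sample_t(self, design, vm):
        # hand-set ISU means: the aligned test must equal the closed-form
        # two-sample t on those 20 numbers
        sc = hp.default_scenarios()["composite-hospital"]
        df = hp.simulate_trial(design, vm,
                               EffectSpec.single_outcome(0.0, 0, 8), seed=21)
        rng = np.random.default_rng(0)
        isu_vals = np.where(design.hospital_arms() == 1, 1.0, 0.0) \
            + rng.normal(size=20)
        for j in range(8):
            df[f"y{j + 1}"] = isu_vals[df["hospital"].to_numpy()]
        res = hp.analyze_trial(df, sc)
        t, _ = stats.ttest_ind(isu_vals[:10], isu_vals[10:])
        assert res.statistic == pytest.approx(t ** 2, rel=1e-10)
        assert (res.ndf, res.ddf) == (1, 18)

    def test_within_level_reduction_equals_paired_t(self, vm):
        sc = hp.default_scenarios()["composite-participant"]
        df = hp.simulate_trial(sc.design, vm,
                               EffectSpec.single_outcome(0.3, 0, 8), seed=4)
        res = hp.analyze_trial(df, sc)
        # independent recomputation with pandas
        ycols = [f"y{j + 1}" for j in range(8)]
        comp = df[ycols].mean(axis=1)
        per = df.assign(comp=comp).groupby(["hospital", "arm"])["comp"].mean()
        d = (per.xs("intervention", level="arm")
             - per.xs("control", level="arm")).to_numpy()
        t, _ = stats.ttest_1samp(d, 0.0)
        assert res.statistic == pytest.approx(t ** 2, rel=1e-10)
        assert (res.ndf, res.ddf) == (1, 19)

    def test_multivariate_reduction_matches_manual_hotelling(self, vm):
        sc = hp.default_scenarios()["multivariate-hospital"]
        df = hp.simulate_trial(sc.design, vm,
                               EffectSpec.single_outcome(0.5, 0, 8), seed=8)
        res = hp.analyze_trial(df, sc)
        ycols = [f"y{j + 1}" for j in range(8)]
        isu = df.groupby("hospital")[ycols].mean().to_numpy()
        arms = sc.design.hospital_arms() == 1
        Yt, Yc = isu[arms], isu[~arms]
        S = (np.cov(Yt.T) * 9 + np.cov(Yc.T) * 9) / 18
        d = Yt.mean(0) - Yc.mean(0)
        t2 = 5.0 * d @ np.linalg.solve(S, d)
        f = t2 * (18 - 8 + 1) / (18 * 8)
        assert res.statistic == pytest.approx(f, rel=1e-10)
        assert (res.ndf, res.ddf) == (8, 11)

    def test_pooled_contrast_df(self, vm):
        sc = hp.default_scenarios()["subgroup-pooled"]
        df = hp.simulate_trial(sc.design, vm,
                               EffectSpec.single_outcome(0.2, 0, 8), seed=13)
        res = hp.analyze_trial(df, sc)
        assert (res.ndf, res.ddf) == (1, 16)

    def test_stratified_df(self, vm):
        sc = hp.default_scenarios()["subgroup-stratified"]
        df = hp.simulate_trial(sc.design, vm,
                               EffectSpec.single_outcome(0.2, 0, 8), seed=14)
        res = hp.analyze_trial(df, sc)
        assert (res.ndf, res.ddf) == (1, 8)

    def test_constant_outcomes_raise_degenerate_error(self, design, vm):
        sc = hp.default_scenarios()["composite-hospital"]
        df = hp.simulate_trial(design, vm,
                               EffectSpec.single_outcome(0.0, 0, 8), seed=2)
        for j in range(8):
            df[f"y{j + 1}"] = 1.0
        with pytest.raises(DegenerateDataError):
            hp.analyze_trial(df, sc)


class TestEmpiricalPower:
    def test_reproducible_and_se_formula(self):
        sc = hp.default_scenarios()["composite-hospital"]
        a = hp.empirical_power(sc, 0.5, reps=400, seed=77)
        b = hp.empirical_power(sc, 0.5, reps=400, seed=77)
        assert a == b
        assert a.se == pytest.approx(
            np.sqrt(a.power * (1 - a.power) / 400))

    def test_requires_minimum_replicates(self):
        sc = hp.default_scenarios()["composite-hospital"]
        with pytest.raises(hp.InvalidDesignError):
            hp.empirical_power(sc, 0.5, reps=10, seed=1)

    def test_full_trial_path_agrees_with_analytic(self):
        # per-replicate full simulation + analyze_trial, the slow oracle
        sc = hp.default_scenarios()["composite-hospital"]
        analytic = sc.power(0.5).power
        sim = hp.empirical_power(sc, 0.5, reps=250, seed=31,
                                 use_full_trials=True)
        band = 3 * np.sqrt(analytic * (1 - analytic) / 250)
        assert abs(sim.power - analytic) <= band

    def test_fast_and_full_paths_agree(self):
        sc = hp.default_scenarios()["composite-participant"]
        fast = hp.empirical_power(sc, 0.3, reps=2000, seed=5)
        full = hp.empirical_power(sc, 0.3, reps=250, seed=6,
                                  use_full_trials=True)
        band = 3 * np.sqrt(0.25 / 250) + 3 * np.sqrt(0.25 / 2000)
        assert abs(fast.power - full.power) <= band
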