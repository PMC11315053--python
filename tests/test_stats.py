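import numpy as np
import pandas as pd
import pytest

from trotsym.simulate import simulate_normalized_diffs, simulate_study
from trotsym.stats import (
    apply_pooling_thresholds,
    fit_mixed_model,
    lilliefors_normal,
    pooling_check,
    run_full_analysis,
)
from trotsym.datasets import pooling_centers
from trotsym.normalize import build_normalized_dataset
from trotsym.types import (
    DIFF_COLUMNS,
    NoiseModel,
    StudyDesign,
    VariableEffect,
    zero_effect_table,
)


def _effect(sigma_horse=1.5, sigma_limb=1.0, sigma_res=2.0, **cells):
    base = {
        ("hard", "straight"): -2.0,
        ("soft", "straight"): 0.5,
        ("soft", "inside"): 1.0,
        ("soft", "outside"): -1.0,
        ("hard", "inside"): 0.0,
        ("hard", "outside"): 0.0,
    }
    base.update(cells)
    return VariableEffect(base, sigma_horse, sigma_limb, sigma_res)


def _oracle_dataset():
    return simulate_normalized_diffs(
        StudyDesign(), _effect(), np.random.default_rng(42)
    )


class TestLilliefors:
    def test_statistic_matches_statsmodels(self):
        from statsmodels.stats.diagnostic import lilliefors as sm_lilliefors

        rng = np.random.default_rng(3)
        for x in (rng.standard_normal(40), rng.exponential(1.0, 40)):
            stat, _ = lilliefors_normal(x, n_sim=2000, seed=0)
            sm_stat, _ = sm_lilliefors(x, dist="norm")
            assert stat == pytest.approx(sm_stat, abs=1e-12)

    def test_decisions_agree_with_statsmodels(self):
        from statsmodels.stats.diagnostic import lilliefors as sm_lilliefors

        rng = np.random.default_rng(4)
        normal = rng.standard_normal(50)
        skewed = rng.exponential(1.0, 50)
        _, p_norm = lilliefors_normal(normal, seed=1)
        _, p_skew = lilliefors_normal(skewed, seed=1)
        assert p_norm > 0.05 and sm_lilliefors(normal, "norm")[1] > 0.05
        assert p_skew < 0.05 and sm_lilliefors(skewed, "norm")[1] < 0.05

    def test_degenerate_input(self):
        assert lilliefors_normal(np.full(10, 2.0))[1] == 1.0
        with pytest.raises(ValueError):
            lilliefors_normal(np.array([1.0, 2.0]))


class TestPoolingCheck:
    def test_published_centers_all_pass(self):
        res = apply_pooling_thresholds(pooling_centers())
        assert len(res.table) == 12
        assert res.table["passed"].all()
        assert res.pooling_permitted

    def test_center_above_threshold_fails(self):
        res = apply_pooling_thresholds({"DHDmin": 7.0, "DWDmin": 0.5})
        tab = res.table.set_index("variable")
        assert not tab.loc["DHDmin", "passed"]
        assert tab.loc["DWDmin", "passed"]
        assert not res.pooling_permitted

    def test_all_zero_differences_pass(self):
        res = apply_pooling_thresholds({v: 0.0 for v in DIFF_COLUMNS})
        assert res.pooling_permitted

    def test_simulated_null_study_pools(self):
        study = simulate_study(
            StudyDesign(),
            zero_effect_table(sigma_res=1.0),
            noise=NoiseModel(seed=13),
            with_signals=False,
        )
        diffs = build_normalized_dataset(study.truth_summaries)
        res = pooling_check(diffs, n_sim=2000, seed=0)
        assert res.pooling_permitted
        assert set(res.table["variable"]) == set(DIFF_COLUMNS)

    def test_large_side_difference_blocks_pooling(self):
        study = simulate_study(
            StudyDesign(),
            zero_effect_table(sigma_res=1.0),
            noise=NoiseModel(seed=13),
            with_signals=False,
        )
        diffs = build_normalized_dataset(study.truth_summaries)
        diffs.loc[diffs["reshod_limb"] == "left", "DHDmin"] += 10.0
        res = pooling_check(diffs, n_sim=2000, seed=0)
        tab = res.table.set_index("variable")
        assert not tab.loc["DHDmin", "passed"]
        assert not res.pooling_permitted


class TestMixedModelOracle:
    """Cross-checks of the REML/Satterthwaite machinery.

    The frozen expected values were computed on the identical dataset with
    independent mixed-model software (REML, Satterthwaite degrees of
    freedom, equal-weight marginal means, Bonferroni-adjusted pairwise
    contrasts)."""

    EXPECTED_EMM = {
        "inside": (-0.52028794, -1.68817585, 0.64759998),
        "outside": (-2.77791231, -3.94580022, -1.61002439),
        "straight": (-0.47822724, -1.42248403, 0.46602955),
        "hard": (-2.20545043, -3.40941412, -1.00148673),
        "soft": (-0.31216789, -1.22356646, 0.59923067),
    }
    EXPECTED_VC = {
        "horse": 0.80610867,
        "limb_within_horse": 0.84616216,
        "residual": 2.7567682,
    }

    def test_emms_cis_and_pvalues(self):
        res = fit_mixed_model(_oracle_dataset(), "value")
        assert res.p_surface == pytest.approx(0.00065531, abs=2e-5)
        assert res.p_direction == pytest.approx(0.00003025, abs=2e-5)
        for level, (est, lo, hi) in self.EXPECTED_EMM.items():
            got = res.emm[level]
            assert got[0] == pytest.approx(est, abs=1e-4)
            assert got[1] == pytest.approx(lo, abs=5e-3)
            assert got[2] == pytest.approx(hi, abs=5e-3)
        for name, v in self.EXPECTED_VC.items():
            assert res.varcomp[name] == pytest.approx(v, abs=1e-3)

    def test_pairwise_contrasts(self):
        res = fit_mixed_model(_oracle_dataset(), "value")
        pw = res.pairwise_direction.set_index("contrast")
        assert pw.loc["inside - outside", "estimate"] == pytest.approx(
            2.25762437, abs=1e-4
        )
        assert pw.loc["inside - outside", "p_bonferroni"] == pytest.approx(
            0.00020285, abs=5e-5
        )
        assert pw.loc["outside - straight", "estimate"] == pytest.approx(
            -2.29968506, abs=1e-4
        )
        assert pw.loc["inside - straight", "p_bonferroni"] == 1.0
        assert pw.loc["inside - outside", "ddf"] == pytest.approx(57.0, abs=0.5)

    def test_matches_statsmodels_mixedlm(self):
        import statsmodels.formula.api as smf

        df = _oracle_dataset()
        df["limb"] = df["horse_id"] + ":" + df["reshod_limb"]
        sm_fit = smf.mixedlm(
            "value ~ surface + direction",
            df,
            groups="horse_id",
            re_formula="1",
            vc_formula={"limb": "0 + C(limb)"},
        ).fit(reml=True)
        res = fit_mixed_model(df, "value")
        ours = res.fixed_effects.set_index("term")["estimate"]
        assert ours["intercept"] == pytest.approx(sm_fit.params["Intercept"], abs=1e-4)
        assert ours["surface[soft]"] == pytest.approx(
            sm_fit.params["surface[T.soft]"], abs=1e-4
        )
        assert ours["direction[outside]"] == pytest.approx(
            sm_fit.params["direction[T.outside]"], abs=1e-4
        )
        assert res.varcomp["residual"] == pytest.approx(sm_fit.scale, rel=1e-3)


class TestMixedModelProperties:
    def test_noiseless_additive_case_recovers_construction(self):
        surf = {"hard": -2.0, "soft": 1.0}
        direc = {"inside": 0.5, "outside": -1.5, "straight": 0.0}
        cells = {(s, d): surf[s] + direc[d] for s in surf for d in direc}
        eff = VariableEffect(cells)
        df = simulate_normalized_diffs(
            StudyDesign(), eff, np.random.default_rng(0)
        )
        res = fit_mixed_model(df, "value")
        for d, g in direc.items():
            want = (surf["hard"] + surf["soft"]) / 2 + g
            assert res.emm[d][0] == pytest.approx(want, abs=1e-6)
        for s, f in surf.items():
            want = f + np.mean(list(direc.values()))
            assert res.emm[s][0] == pytest.approx(want, abs=1e-6)

    def test_bonferroni_monotonicity(self):
        res = fit_mixed_model(_oracle_dataset(), "value")
        pw = res.pairwise_direction
        assert (pw["p_bonferroni"] >= pw["p_raw"] - 1e-15).all()
        assert (pw["p_bonferroni"] <= 1.0).all()

    def test_negative_shift_gives_negative_emms(self):
        cells = {
            (s, d): -3.0
            for s in ("hard", "soft")
            for d in ("inside", "outside", "straight")
        }
        eff = VariableEffect(cells, 0.5, 0.3, 0.8)
        df = simulate_normalized_diffs(
            StudyDesign(), eff, np.random.default_rng(5)
        )
        res = fit_mixed_model(df, "value")
        assert all(res.emm[lev][0] < 0 for lev in res.emm)

    def test_boundary_variance_triggers_fallback(self):
        df = simulate_normalized_diffs(
            StudyDesign(), _effect(sigma_res=3.0), np.random.default_rng(1)
        )
        res = fit_mixed_model(df, "value")
        assert res.varcomp["limb_within_horse"] == 0.0
        assert res.warnings

    def test_too_few_horses_rejected(self):
        df = _oracle_dataset()
        with pytest.raises(ValueError):
            fit_mixed_model(df[df.horse_id == "H01"], "value")


class TestRunFullAnalysis:
    def test_null_study_rarely_significant(self):
        study = simulate_study(
            StudyDesign(),
            zero_effect_table(sigma_horse=1.0, sigma_limb=0.8, sigma_res=2.0),
            noise=NoiseModel(seed=17),
            with_signals=False,
        )
        diffs = build_normalized_dataset(study.truth_summaries)
        analysis = run_full_analysis(diffs, pooling_seed=0)
        assert analysis.pooling is not None and analysis.pooling.pooling_permitted
        n_sig = int(
            (analysis.report[["p_direction", "p_surface"]] < 0.05).to_numpy().sum()
        )
        assert n_sig <= 5  # expectation ~1.2 of 24 tests under the null
        assert len(analysis.report) == 12
        assert "emm_inside" in analysis.report.columns
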