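"""Before/after evaluation: regression recovery, tables, small-cell rule."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from vppflow import evaluation, synth
from vppflow.config import GeneratorConfig
from vppflow.evaluation import (
    fit_log_los_model,
    fit_return_models,
    reconstruct_denominators,
    robustness_suite,
    summarize_table1,
    vpp_routing_table2,
)


@pytest.fixture(scope="module")
def study():
    cfg = GeneratorConfig(seed=42, n_encounters=13_700)
    return synth.generate_encounters(cfg)


class TestLogLosModel:
    def test_recovers_planted_effect(self, study):
        est = fit_log_los_model(study, ["patient", "operational", "saturation"])
        truth = np.log(0.9585)
        assert est.ci_low <= truth <= est.ci_high
        assert est.pct_change == pytest.approx(100 * (np.exp(est.coef) - 1))
        assert est.minutes_change == pytest.approx(
            est.pre_mean_minutes * (np.exp(est.coef) - 1))

    def test_null_effect_not_significant(self):
        cfg = GeneratorConfig(seed=17, n_encounters=13_700, intervention_effect=1.0)
        enc = synth.generate_encounters(cfg)
        est = fit_log_los_model(enc, ["patient"])
        assert est.pvalue > 0.05

    def test_adjustment_reduces_confounding_bias(self):
        cfg = GeneratorConfig(seed=23, n_encounters=13_700)
        enc = synth.generate_encounters(cfg, post_acuity_shift=0.25)
        truth = np.log(0.9585)
        raw = fit_log_los_model(enc, [])
        adj = fit_log_los_model(enc, ["patient", "operational"])
        assert abs(adj.coef - truth) < abs(raw.coef - truth)

    def test_education_period_excluded_by_default(self, study):
        est = fit_log_los_model(study, [])
        n_pre_post = (study["period"].isin(["pre", "post"])).sum()
        assert est.n_obs == n_pre_post

    def test_missing_post_rows_rejected(self, study):
        pre_only = study[study["period"] == "pre"]
        with pytest.raises(ValueError):
            fit_log_los_model(pre_only, [])


class TestReturnModels:
    def test_null_returns_not_significant(self, study):
        out = fit_return_models(study, [])
        for est in out.values():
            assert est.pvalue > 0.05

    def test_planted_return_surge_detected(self, study):
        enc = study.copy()
        rng = np.random.default_rng(0)
        post = enc["period"] == "post"
        extra = post & (rng.random(len(enc)) < enc["returned_72h"].mean())
        enc.loc[extra, "returned_72h"] = True
        est = fit_return_models(enc, [])["returned_72h"]
        assert est.coef > 0 and est.pvalue < 0.05

    def test_empty_covariates_match_raw_odds_ratio(self, study):
        est = fit_return_models(study, [])["returned_72h"]
        pre = study[study["period"] == "pre"]["returned_72h"]
        post = study[study["period"] == "post"]["returned_72h"]
        odds = lambda p: p / (1 - p)
        raw_log_or = np.log(odds(post.mean()) / odds(pre.mean()))
        assert est.coef == pytest.approx(raw_log_or, abs=1e-6)

    def test_zero_variance_outcome_named(self, study):
        silent = study.copy()
        silent["returned_72h_admit"] = False
        with pytest.raises(ValueError, match="returned_72h_admit"):
            fit_return_models(silent, [])


class TestTable1:
    def test_los_difference_identity(self, study):
        pre = study[study["period"] == "pre"]
        post = study[study["period"] == "post"]
        table = summarize_table1(pre, post).set_index("variable")
        row = table.loc["ED length of stay (min)"]
        assert row["difference_minutes"] == pytest.approx(row["pre"] - row["post"])
        assert row["difference_pct_of_pre"] == pytest.approx(
            100 * (row["pre"] - row["post"]) / row["pre"])

    def test_identical_tables_show_no_differences(self, study):
        pre = study[study["period"] == "pre"]
        table = summarize_table1(pre, pre.copy())
        assert (table["pvalue"].dropna() > 0.05).all()
        los = table.set_index("variable").loc["ED length of stay (min)"]
        assert los["difference_minutes"] == 0.0

    def test_single_row_inputs_flag_undefined_sd(self, study):
        one = study.iloc[[0]]
        table = summarize_table1(one, one.copy()).set_index("variable")
        row = table.loc["ED length of stay (min)"]
        assert np.isnan(row["pre_sd"]) and np.isnan(row["pvalue"])

    def test_empty_input_rejected(self, study):
        with pytest.raises(ValueError):
            summarize_table1(study.iloc[:0], study)


class TestTable2SmallCellRule:
    def test_selection_is_pure_function_of_cell_minimum(self):
        assert evaluation._select_test(np.array([[9, 100], [50, 100]])) == "fisher"
        assert evaluation._select_test(np.array([[10, 100], [50, 100]])) == "chi2"
        assert evaluation._select_test(np.array([[100, 9], [50, 100]])) == "fisher"

    def test_published_esi5_counts_give_tiny_fisher_p(self):
        # 7/35 routed pre vs 19/23 post, reconstructed from the printed table
        table = np.array([[7, 28], [19, 4]])
        # independent oracle: two-sided Fisher by hypergeometric enumeration
        n1, n2 = table[0].sum(), table[1].sum()
        k = table[:, 0].sum()
        rv = stats.hypergeom(n1 + n2, k, n1)
        p_obs = rv.pmf(table[0, 0])
        oracle = sum(rv.pmf(x) for x in range(max(0, k - n2), min(k, n1) + 1)
                     if rv.pmf(x) <= p_obs * (1 + 1e-9))
        p = stats.fisher_exact(table)[1]
        assert p == pytest.approx(oracle, rel=1e-6)
        assert p < 0.001

    def test_symmetric_table_fisher_p_one(self):
        pre = pd.DataFrame({"esi": [5] * 8, "complaint": ["other"] * 8,
                            "seen_in_vpp": [True] * 4 + [False] * 4})
        post = pre.copy()
        out = vpp_routing_table2(pre, post).set_index("esi_stratum")
        row = out.loc["5"]
        assert row["test"] == "fisher" and row["pvalue"] == pytest.approx(1.0)

    def test_full_table_structure(self, study):
        pre = study[study["period"] == "pre"]
        post = study[study["period"] == "post"]
        out = vpp_routing_table2(pre, post)
        assert list(out["esi_stratum"]) == [
            "1", "2", "3 - other", "3 - skin/urinary/eye", "4", "5"]
        assert ((out["pre_pct"].dropna() >= 0) & (out["pre_pct"].dropna() <= 100)).all()
        for _, row in out.iterrows():
            if row["test"] is None:
                continue
            cells = np.array([[row["pre_vpp"], row["pre_total"] - row["pre_vpp"]],
                              [row["post_vpp"], row["post_total"] - row["post_vpp"]]])
            assert row["test"] == ("fisher" if cells.min() < 10 else "chi2")


class TestDenominatorReconstruction:
    @pytest.mark.parametrize("count,pct,expected", [
        (7, 20.0, 35),       # 7/35 = 20.00%
        (19, 82.61, 23),     # 19/23 = 82.6087%
        (139, 18.08, 769),   # 139/769 = 18.0754%
    ])
    def test_published_percentages_invert_exactly(self, count, pct, expected):
        out = reconstruct_denominators(count, pct)
        assert out["denominator"] == expected

    def test_unmatchable_percentage_rejected(self):
        with pytest.raises(ValueError):
            reconstruct_denominators(7, 33.33, search_max=20)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            reconstruct_denominators(-1, 20.0)
        with pytest.raises(ValueError):
            reconstruct_denominators(5, 0.0)


class TestRobustness:
    def test_specs_recover_effect_within_band(self, study):
        table = robustness_suite(study)
        assert len(table) == 5
        assert ((table["pct_change"] > -6.0) & (table["pct_change"] < -3.0)).all()
        lo, hi = table.attrs["minutes_change_range"]
        assert lo <= table["minutes_change"].min() <= hi

    def test_esi_coding_invariance(self, study):
        cat = fit_log_los_model(study, ["patient"])
        cont = fit_log_los_model(study, ["patient"], continuous_esi=True)
        assert abs(cat.coef - cont.coef) < cat.se

    def test_single_spec_table(self, study):
        table = robustness_suite(study, specs=[{"covariate_groups": [],
                                                "spec_id": "only"}])
        assert len(table) == 1 and table["spec_id"].iloc[0] == "only"
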