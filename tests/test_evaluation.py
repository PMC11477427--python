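import numpy as np
import pandas as pd
import pytest

from cnarisk import (
    MODEL_IDS,
    PipelineConfig,
    km_curve,
    logrank_statistic,
    model_report,
    multigroup_logrank,
    multivariate_cox,
    rank_models,
    run_pipeline,
    simulate_cohort,
    stratified_analysis,
)
from cnarisk.evaluation import ModelReport
from cnarisk.io_gistic import SurvivalTable
from cnarisk.synthetic_data import PlantedGene, SimulationConfig, draw_survival_times

from conftest import make_survival


def _surv(time, event, **cof) -> SurvivalTable:
    df = pd.DataFrame({"time": time, "event": event, **cof},
                      index=pd.Index([f"s{i}" for i in range(len(time))], name="sample"))
    return SurvivalTable(df)


class TestKMCurve:
    def test_uncensored_closed_form(self):
        out = km_curve(np.array([1.0, 2.0, 3.0]), np.array([1, 1, 1]),
                       np.array(["g"] * 3))["g"]
        steps = dict(zip(out["time"], out["survival"]))
        assert steps[1.0] == pytest.approx(2 / 3)
        assert steps[2.0] == pytest.approx(1 / 3)
        assert steps[3.0] == pytest.approx(0.0)

    def test_all_censored_flat_at_one(self):
        out = km_curve(np.array([5.0, 8.0]), np.array([0, 0]), np.array(["g"] * 2))["g"]
        assert (out["survival"] == 1.0).all()

    def test_hand_computed_censored_fixture(self):
        # 8 subjects, events at 1,2,3,5,6, censored at 2,4,7:
        # S = 7/8, 0.75, 0.6, 0.4, 0.2 at the five event times
        time = np.array([1.0, 2.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0])
        event = np.array([1, 1, 0, 1, 0, 1, 1, 0])
        out = km_curve(time, event, np.array(["g"] * 8))["g"]
        steps = dict(zip(out["time"], out["survival"]))
        for t, s in [(1.0, 7 / 8), (2.0, 0.75), (3.0, 0.6), (5.0, 0.4), (6.0, 0.2)]:
            assert steps[t] == pytest.approx(s, rel=1e-12)

    def test_non_increasing_from_one(self, default_pipeline):
        for rep in default_pipeline.reports.values():
            for df in rep.km.values():
                s = df["survival"].to_numpy()
                assert s[0] <= 1.0 + 1e-12
                assert (np.diff(s) <= 1e-12).all()


class TestMultigroupLogrank:
    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_two_groups_equal_screening_statistic(self, seed):
        time, event = make_survival(50, seed=seed)
        rng = np.random.default_rng(seed + 100)
        group = (rng.random(50) < 0.3).astype(int)
        group[:2] = [0, 1]
        stat2, _ = logrank_statistic(time, event, group)
        statk, df, _ = multigroup_logrank(time, event,
                                          np.where(group == 1, "A", "B"))
        assert df == 1
        assert abs(statk - stat2) < 1e-9

    @pytest.mark.parametrize("seed", [4, 5])
    def test_matches_lifelines_k_groups(self, seed):
        from lifelines.statistics import multivariate_logrank_test

        time, event = make_survival(80, seed=seed)
        rng = np.random.default_rng(seed)
        labels = rng.choice(["A", "B", "C", "D"], 80)
        stat, df, p = multigroup_logrank(time, event, labels)
        ref = multivariate_logrank_test(time, labels, event)
        assert stat == pytest.approx(ref.test_statistic, rel=1e-9)
        assert p == pytest.approx(ref.p_value, rel=1e-6)

    def test_undefined_cases_return_none(self):
        time, event = make_survival(10, seed=0)
        assert multigroup_logrank(time, event, np.array(["A"] * 10)) is None
        assert multigroup_logrank(time, np.zeros(10, int), np.array(["A", "B"] * 5)) is None

    def test_null_pvalues_uniform(self):
        # label-permuted null: p-values should be uniform on [0, 1]
        from scipy import stats as sps

        rng = np.random.default_rng(77)
        time, event = make_survival(60, seed=77, event_frac=0.8)
        base = np.array(["A"] * 20 + ["B"] * 20 + ["C"] * 20)
        ps = []
        for _ in range(1000):
            labels = rng.permutation(base)
            ps.append(multigroup_logrank(time, event, labels)[2])
        assert sps.kstest(ps, "uniform").pvalue > 0.01

    def test_three_arm_power(self):
        # planted hazard ratios (2.0, 1.0, 0.5): p < 0.001 nearly always
        rng = np.random.default_rng(88)
        n = 300
        hits = 0
        for _ in range(100):
            labels = rng.choice(["hi", "mid", "lo"], n)
            lp = np.select([labels == "hi", labels == "lo"],
                           [np.log(2.0), np.log(0.5)], 0.0)
            t_event = rng.exponential(1.0, n) / np.exp(lp)
            cens = rng.exponential(2.0, n)
            time = np.minimum(t_event, cens)
            event = (t_event <= cens).astype(int)
            if multigroup_logrank(time, event, labels)[2] < 1e-3:
                hits += 1
        assert hits >= 95


def _mock_report(model_id, p, groups, events_per_group=5, n_per_group=30,
                 pairwise_p=1e-4):
    sizes = {g: n_per_group for g in groups}
    events = {g: events_per_group + i for i, g in enumerate(groups)}
    pw = {}
    gs = sorted(groups)
    for i, a in enumerate(gs):
        for b in gs[i + 1:]:
            pw[f"{a}|{b}"] = pairwise_p
    return ModelReport(model_id, n_per_group * len(groups), sizes, events,
                       {}, 1.0 if p is not None else None,
                       len(groups) - 1 if p is not None else None, p, pw)


class TestRankModels:
    def test_selects_smallest_p(self):
        reports = {m: _mock_report(m, p, ["H", "L", "NA"])
                   for m, p in zip(MODEL_IDS, [0.3, 0.2, 0.1, 0.4, 0.05, 1e-6, 0.2, 0.9])}
        res = rank_models(reports)
        assert res.selected == "maxsum_deep"
        assert res.order[0] == "maxsum_deep"

    def test_tie_broken_by_fewer_groups_then_model_order(self):
        reports = {m: _mock_report(m, 0.01, ["H", "L", "NA"]) for m in MODEL_IDS}
        reports["combinations_deep"] = _mock_report("combinations_deep", 0.01, ["H/H", "NA/NA"])
        res = rank_models(reports)
        # two-group model ranks first on the group count tie-break;
        # remaining ties follow the fixed model-id order
        assert res.order[0] == "combinations_deep"
        assert res.order[1:] == [m for m in MODEL_IDS if m != "combinations_deep"]

    def test_small_group_penalized(self):
        reports = {m: _mock_report(m, 0.5, ["H", "NA"]) for m in MODEL_IDS}
        tiny = _mock_report("maxsum_deep", 1e-8, ["H", "L", "NA"])
        tiny.group_sizes["L"] = 1  # < 2% of cohort
        reports["maxsum_deep"] = tiny
        res = rank_models(reports, min_group_frac=0.02)
        row = res.table.set_index("model_id").loc["maxsum_deep"]
        assert row["penalized"] and "small_group" in row["reasons"]
        assert res.selected != "maxsum_deep"

    def test_indistinguishable_extremes_penalized(self):
        reports = {m: _mock_report(m, 0.5, ["H", "NA"]) for m in MODEL_IDS}
        weak = _mock_report("maxsum_soft", 1e-8, ["H", "L", "NA"], pairwise_p=0.8)
        reports["maxsum_soft"] = weak
        res = rank_models(reports)
        assert res.table.set_index("model_id").loc["maxsum_soft", "penalized"]

    def test_all_degenerate_yields_no_selection(self):
        reports = {m: _mock_report(m, None, ["NA"]) for m in MODEL_IDS}
        res = rank_models(reports)
        assert res.selected is None
        assert len(res.table) == 8

    def test_deterministic_total_order(self, default_pipeline):
        a = rank_models(default_pipeline.reports)
        b = rank_models(default_pipeline.reports)
        assert a.order == b.order and a.selected == b.selected

    def test_deep_model_selected_on_planted_deep_scenario(self, default_pipeline):
        assert "deep" in default_pipeline.ranking.selected

    def test_soft_model_selected_when_no_deep_alterations(self):
        # cohorts without deep alterations must fall back to a soft model
        cfg = SimulationConfig(
            n_samples=150, n_genes=60,
            planted=tuple(PlantedGene("soft_amp", 1.3, 0.15) for _ in range(4)),
            deep_fraction=0.0, soft_deep_admixture=0.0, seed=3)
        result = run_pipeline(simulate_cohort(cfg).cohort(),
                              PipelineConfig(engine="asymptotic"))
        assert "soft" in result.ranking.selected
        assert result.reports["maxsum_deep"].overall_p is None


class TestModelReport:
    def test_group_sizes_sum_to_cohort(self, default_pipeline, default_cohort):
        for rep in default_pipeline.reports.values():
            assert sum(rep.group_sizes.values()) == default_cohort.n_samples

    def test_degenerate_single_group_flagged(self):
        time, event = make_survival(20, seed=1)
        surv = _surv(time, event)
        labels = pd.Series(["NA"] * 20, index=surv.sample_ids)
        rep = model_report("single_deep_amp", labels, surv)
        assert rep.overall_p is None and "degenerate" in rep.flags


class TestStratifiedAnalysis:
    def _risk_cohort(self, seed=0, n=400, risk_beta=1.0, cof_beta=0.0):
        rng = np.random.default_rng(seed)
        labels = pd.Series(rng.choice(["H", "NA"], n, p=[0.4, 0.6]))
        cof = rng.choice(["x0", "x1"], n)
        lp = risk_beta * (labels == "H").to_numpy() + cof_beta * (cof == "x1")
        cfg = SimulationConfig()
        time, event = draw_survival_times(rng, lp, cfg)
        surv = _surv(time, event, grp=cof)
        labels.index = surv.sample_ids
        return labels, surv

    def test_risk_effect_significant_in_both_strata(self):
        labels, surv = self._risk_cohort(seed=10, risk_beta=1.0)
        rep = stratified_analysis(labels, surv, "grp")
        h_rows = rep.table[rep.table["group"] == "H"]
        assert len(h_rows) == 2
        assert h_rows["estimable"].all()
        assert h_rows["significant"].all()
        # stratified betas agree with the unstratified truth within CI
        assert ((h_rows["ci_low"] < 1.0) & (1.0 < h_rows["ci_high"])).all()

    def test_zero_event_group_non_estimable(self):
        time = np.array([10.0, 20.0, 30.0, 40.0, 5.0, 6.0, 7.0, 8.0])
        event = np.array([0, 0, 0, 0, 1, 1, 1, 1])
        surv = _surv(time, event, grp=["a"] * 8)
        labels = pd.Series(["L", "L", "L", "L", "NA", "NA", "NA", "NA"],
                           index=surv.sample_ids)
        rep = stratified_analysis(labels, surv, "grp", min_stratum_n=2)
        row = rep.table[rep.table["group"] == "L"].iloc[0]
        assert not row["estimable"] and np.isnan(row["beta"])

    def test_numeric_cofactor_dichotomized_at_cut(self):
        labels, surv = self._risk_cohort(seed=11)
        age = np.random.default_rng(1).normal(65, 10, len(labels))
        surv = SurvivalTable(surv.data.assign(age=age))
        rep = stratified_analysis(labels, surv, "age", age_cut=60)
        assert set(rep.table["stratum"]) == {"<60", ">=60"}

    def test_assignments_not_mutated(self):
        labels, surv = self._risk_cohort(seed=12)
        before = labels.copy()
        stratified_analysis(labels, surv, "grp")
        multivariate_cox(labels, surv, ["grp"])
        pd.testing.assert_series_equal(labels, before)


class TestMultivariateCox:
    def test_joint_recovery_of_risk_and_stage_effects(self):
        rng = np.random.default_rng(20)
        n = 1000
        labels = pd.Series(rng.choice(["H", "NA"], n))
        stage = rng.choice(["i", "ii"], n)
        lp = 1.0 * (labels == "H").to_numpy() + 0.5 * (stage == "ii")
        time, event = draw_survival_times(rng, lp, SimulationConfig())
        surv = _surv(time, event, stage=stage)
        labels.index = surv.sample_ids
        tab = multivariate_cox(labels, surv).set_index("term")
        for term, truth in [("risk_H", 1.0), ("stage_ii", 0.5)]:
            assert abs(tab.loc[term, "beta"] - truth) <= 3 * tab.loc[term, "se"]

    def test_duplicated_cofactor_dropped(self):
        rng = np.random.default_rng(21)
        n = 200
        labels = pd.Series(rng.choice(["H", "NA"], n))
        age = rng.normal(65, 10, n)
        time, event = draw_survival_times(rng, np.zeros(n), SimulationConfig())
        surv = _surv(time, event, age=age, age_copy=age)
        labels.index = surv.sample_ids
        tab = multivariate_cox(labels, surv)
        assert "age_copy" in tab.attrs["dropped"]
        assert "age_copy" not in set(tab["term"])

    def test_shuffled_labels_mostly_non_significant(self):
        rng = np.random.default_rng(22)
        n = 250
        time, event = draw_survival_times(rng, np.zeros(n), SimulationConfig())
        surv = _surv(time, event)
        nonsig = 0
        for _ in range(100):
            labels = pd.Series(rng.permutation(["H"] * 80 + ["NA"] * (n - 80)),
                               index=surv.sample_ids)
            tab = multivariate_cox(labels, surv, cofactors=[]).set_index("term")
            if tab.loc["risk_H", "p"] > 0.05:
                nonsig += 1
        assert nonsig >= 90


class TestPlots:
    def test_km_and_forest_plots_render(self, default_pipeline, default_cohort, tmp_path):
        from cnarisk.evaluation import plot_forest, plot_km

        rep = default_pipeline.reports["maxsum_deep"]
        plot_km(rep, tmp_path / "km.png")
        labels = default_pipeline.assignments["maxsum_deep"]
        strat = stratified_analysis(labels, default_cohort.surv, "sex")
        plot_forest(strat, tmp_path / "forest.svg")
        assert (tmp_path / "km.png").stat().st_size > 0
        assert (tmp_path / "forest.svg").stat().st_size > 0
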