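"""Design construction, adjusted group tests, BH-FDR, partial correlations."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pingouin as pg
import pytest
from scipy import stats as sps

from dcctree.core_io import Cohort
from dcctree.stats import (
    DesignMatrix,
    RankDeficientDesignError,
    adjusted_group_test,
    build_design,
    fdr_bh,
    partial_correlation_ados,
    run_full_analysis,
)
from .conftest import make_record


def bh_oracle(p):
    """Hand implementation of the step-up rule for cross-checking."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p)
    adj = np.empty(m)
    running_min = 1.0
    for rank in range(m, 0, -1):
        idx = order[rank - 1]
        running_min = min(running_min, p[idx] * m / rank)
        adj[idx] = running_min
    return adj


class TestBuildDesign:
    def test_reference_coding_columns(self, toy_cohort):
        design = build_design(toy_cohort)
        cols = design.frame.columns
        assert "intercept" in cols and "group" in cols
        assert sum(c.startswith("site_") for c in cols) == 1  # 2 sites -> 1 column
        assert sum(c.startswith("sex_") for c in cols) == 0  # all male here
        assert design.frame["group"].isin([0.0, 1.0]).all()

    def test_missing_covariate_drops_subject(self, toy_cohort):
        records = list(toy_cohort.records)
        records[0] = make_record("s01", group="ASD", site="S1", iq=float("nan"))
        design = build_design(Cohort(records=records))
        assert design.dropped_subjects == ["s01"]
        assert len(design.frame) == len(records) - 1

    def test_collinear_site_and_group_detected(self):
        # group perfectly aligned with site -> indicator columns collinear
        records = ([make_record(f"a{i}", "ASD", site="P") for i in range(5)]
                   + [make_record(f"t{i}", "TD", site="Q") for i in range(5)])
        with pytest.raises(RankDeficientDesignError):
            build_design(Cohort(records=records))


def _gaussian_summaries(ids, rng, shift=None):
    vals = rng.standard_normal(len(ids))
    if shift is not None:
        vals = vals + shift
    return pd.DataFrame({"mean_global_efficiency": vals,
                         "var_global_efficiency": np.abs(vals)},
                        index=pd.Index(ids, name="subject_id"))


class TestAdjustedGroupTest:
    def test_reduces_to_pooled_t_test_without_covariates(self, rng):
        ids = [f"s{i}" for i in range(20)]
        groups = np.array([1.0] * 10 + [0.0] * 10)
        design = DesignMatrix(frame=pd.DataFrame(
            {"intercept": 1.0, "group": groups}, index=ids))
        y = rng.standard_normal(20)
        y[:10] += 0.8
        summaries = pd.DataFrame({"mean_global_efficiency": y}, index=ids)
        res = adjusted_group_test(summaries, design, "global_efficiency", "mean")
        t_ref, p_ref = sps.ttest_ind(y[:10], y[10:], equal_var=True)
        assert res.t_value == pytest.approx(t_ref, abs=1e-10)
        assert res.p_value == pytest.approx(p_ref, abs=1e-10)

    def test_covariate_rescaling_invariance(self, toy_cohort, rng):
        design = build_design(toy_cohort)
        summaries = _gaussian_summaries(toy_cohort.subject_ids, rng)
        t1 = adjusted_group_test(summaries, design, "global_efficiency", "mean").t_value
        scaled = DesignMatrix(frame=design.frame.copy())
        scaled.frame["age"] = scaled.frame["age"] * 1000.0 + 77.0
        t2 = adjusted_group_test(summaries, scaled, "global_efficiency", "mean").t_value
        assert t1 == pytest.approx(t2, abs=1e-8)

    def test_degenerate_outcome_reported_missing(self, toy_cohort):
        summaries = pd.DataFrame(
            {"mean_global_efficiency": 0.5, "var_global_efficiency": 0.1},
            index=toy_cohort.subject_ids)
        res = adjusted_group_test(summaries, build_design(toy_cohort),
                                  "global_efficiency", "mean")
        assert np.isnan(res.t_value)
        assert res.reason is not None


class TestFdrBh:
    def test_hand_worked_example(self):
        np.testing.assert_allclose(fdr_bh([0.01, 0.02, 0.03, 0.04]),
                                   [0.04, 0.04, 0.04, 0.04])

    def test_identities(self):
        np.testing.assert_allclose(fdr_bh([1.0, 1.0, 1.0]), 1.0)
        np.testing.assert_allclose(fdr_bh([0.037]), [0.037])

    def test_matches_step_up_oracle_and_bounds(self, rng):
        for _ in range(20):
            p = rng.random(int(rng.integers(2, 40)))
            adj = fdr_bh(p)
            np.testing.assert_allclose(adj, bh_oracle(p), atol=1e-12)
            assert np.all(adj >= p - 1e-15)
            assert np.all(adj <= 1.0)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            fdr_bh([0.5, 1.5])


class TestPartialCorrelation:
    def _cohort_with_ados(self, n, rng, conn=None, ados=None):
        records = []
        for i in range(n):
            records.append(make_record(
                f"p{i:02d}", group="ASD", site="S1" if i % 2 else "S2",
                age=10 + rng.random() * 10, iq=90 + rng.random() * 30,
                func_mean_fd=0.05 + rng.random() * 0.1,
                func_perc_fd=rng.random() * 10,
                ados_total=float(ados[i]) if ados is not None else 10.0 + i,
            ))
        return Cohort(records=records)

    def test_without_covariates_equals_plain_pearson(self, rng):
        n = 30
        ados = rng.normal(12, 3, n)
        cohort = self._cohort_with_ados(n, rng, ados=ados)
        ids = cohort.subject_ids
        y = rng.standard_normal(n) + 0.5 * ados
        summaries = pd.DataFrame({"mean_degree_1": y}, index=ids)
        design = DesignMatrix(frame=pd.DataFrame({"intercept": 1.0}, index=ids))
        res = partial_correlation_ados(summaries, design, cohort,
                                       "degree_1", "mean", "TOTAL")
        r_ref = sps.pearsonr(y, ados)
        assert res.r_partial == pytest.approx(r_ref.statistic, abs=1e-12)
        assert res.df == n - 2

    def test_matches_pingouin_with_covariates(self, rng):
        n = 40
        ados = rng.normal(12, 3, n)
        cohort = self._cohort_with_ados(n, rng, ados=ados)
        design = build_design(cohort, include_group=False)
        ids = design.subject_ids
        y = rng.standard_normal(n)
        summaries = pd.DataFrame({"mean_degree_1": y}, index=cohort.subject_ids)
        res = partial_correlation_ados(summaries, design, cohort,
                                       "degree_1", "mean", "TOTAL")
        df = design.frame.loc[ids].drop(columns=["intercept"]).copy()
        df["y"] = summaries.loc[ids, "mean_degree_1"]
        df["ados"] = [r.ados("TOTAL") for r in cohort.records]
        covars = [c for c in df.columns if c not in ("y", "ados")]
        ref = pg.partial_corr(data=df, x="y", y="ados", covar=covars)
        assert res.r_partial == pytest.approx(float(ref["r"].iloc[0]), abs=1e-9)
        assert res.p_value == pytest.approx(float(ref["p_val"].iloc[0]), abs=1e-9)

    def test_residualization_order_symmetric(self, rng):
        # swapping which variable is 'the summary' leaves r unchanged
        n = 30
        ados = rng.normal(12, 3, n)
        cohort = self._cohort_with_ados(n, rng, ados=ados)
        design = build_design(cohort, include_group=False)
        y = rng.standard_normal(n)
        s1 = pd.DataFrame({"mean_degree_1": y}, index=cohort.subject_ids)
        r1 = partial_correlation_ados(s1, design, cohort, "degree_1", "mean", "TOTAL")
        # feed the ADOS values as the 'summary' and y as the 'ADOS'
        cohort2 = self._cohort_with_ados(n, rng, ados=y * 10 + 50)
        s2 = pd.DataFrame({"mean_degree_1": ados}, index=cohort2.subject_ids)
        r2 = partial_correlation_ados(s2, design, cohort2, "degree_1", "mean", "TOTAL")
        assert r1.r_partial == pytest.approx(r2.r_partial, abs=1e-9)

    def test_null_coupling_calibrated(self, rng):
        # independent ADOS: rejection rate ~ alpha, mean r ~ 0
        n = 40
        rejections, rs = [], []
        for _ in range(50):
            ados = rng.normal(12, 3, n)
            cohort = self._cohort_with_ados(n, rng, ados=ados)
            design = build_design(cohort, include_group=False)
            summaries = pd.DataFrame({"mean_degree_1": rng.standard_normal(n)},
                                     index=cohort.subject_ids)
            res = partial_correlation_ados(summaries, design, cohort,
                                           "degree_1", "mean", "TOTAL")
            rejections.append(res.p_value < 0.05)
            rs.append(res.r_partial)
        assert abs(np.mean(rs)) < 0.08
        lo, hi = sps.binom.interval(0.99, 50, 0.05)
        assert lo <= sum(rejections) <= hi

    def test_known_coupling_recovered(self, rng):
        # construct ados = -conn + noise with population partial r = -0.3
        n = 60
        target = -0.3
        estimates = []
        for _ in range(50):
            conn = rng.standard_normal(n)
            noise_sd = np.sqrt(1.0 / target**2 - 1.0)
            ados = 20.0 - conn + rng.normal(0, noise_sd, n)
            cohort = self._cohort_with_ados(n, rng, ados=ados)
            design = build_design(cohort, include_group=False)
            summaries = pd.DataFrame({"mean_degree_1": conn},
                                     index=cohort.subject_ids)
            res = partial_correlation_ados(summaries, design, cohort,
                                           "degree_1", "mean", "TOTAL")
            estimates.append(res.r_partial)
        assert abs(np.median(estimates) - target) < 0.15


class TestFullAnalysis:
    def test_table_schema(self, toy_cohort, rng):
        summaries = _gaussian_summaries(toy_cohort.subject_ids, rng)
        bundle = run_full_analysis(toy_cohort, summaries)
        for table in (bundle.group_mean, bundle.group_variance):
            assert list(table.columns) == ["metric", "summary_kind",
                                           "mean_sd_group1", "mean_sd_group2",
                                           "t", "p", "p_fdr"]
        assert set(bundle.ados_mean["ados_scale"]) == {
            "TOTAL", "COMM", "SOCIAL", "STEREO_BEHAV"}

    def test_node_family_fdr_leaves_network_level_unadjusted(self, toy_cohort, rng):
        ids = toy_cohort.subject_ids
        cols = {}
        for m in ("global_efficiency", "degree_1", "degree_2", "degree_3"):
            cols[f"mean_{m}"] = rng.standard_normal(len(ids))
            cols[f"var_{m}"] = np.abs(rng.standard_normal(len(ids)))
        summaries = pd.DataFrame(cols, index=ids)
        bundle = run_full_analysis(toy_cohort, summaries, fdr_family="node")
        table = bundle.group_mean.set_index("metric")
        assert np.isnan(table.loc["global_efficiency", "p_fdr"])
        degree_rows = table.loc[["degree_1", "degree_2", "degree_3"]]
        np.testing.assert_allclose(degree_rows["p_fdr"],
                                   bh_oracle(degree_rows["p"].to_numpy()))
        bundle_g = run_full_analysis(toy_cohort, summaries, fdr_family="global")
        assert bundle_g.group_mean["p_fdr"].notna().all()
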