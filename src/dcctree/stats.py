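"""Confound-adjusted group comparisons and symptom-severity correlations.

Group differences: for each parameter summary, a linear model
``summary ~ intercept + group + age + iq + func_mean_fd + func_perc_fd +
sex + site`` is fitted and the group coefficient's two-sided t-test
reported; node-level parameter families (one parameter type x one summary
kind across the N nodes) are Benjamini-Hochberg adjusted.

Symptom correlations: within the patient group, each summary and each ADOS
scale are residualized on the same covariates (without the group term) and
the Pearson correlation of the residuals is reported, with significance
from t = r * sqrt(df / (1 - r^2)), df = n - 2 - k for k covariate columns.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .core_io import Cohort
from .metrics import NETWORK_METRICS, NODE_METRIC_PREFIXES

logger = logging.getLogger(__name__)

COVARIATES = ["age", "iq", "func_mean_fd", "func_perc_fd"]
ADOS_SCALES = ["TOTAL", "COMM", "SOCIAL", "STEREO_BEHAV"]


class RankDeficientDesignError(ValueError):
    """The design matrix has linearly dependent columns."""


@dataclass
class DesignMatrix:
    """Subjects x regressors, reference-coded, aligned to the summary table."""

    frame: pd.DataFrame  # includes 'intercept' and possibly 'group'
    dropped_subjects: list[str] = field(default_factory=list)

    @property
    def subject_ids(self) -> list[str]:
        return list(self.frame.index)

    def without_group(self) -> "DesignMatrix":
        return DesignMatrix(frame=self.frame.drop(columns=["group"], errors="ignore"),
                            dropped_subjects=list(self.dropped_subjects))

    @property
    def n_covariate_columns(self) -> int:
        return sum(c not in ("intercept", "group") for c in self.frame.columns)


@dataclass
class GroupTestResult:
    metric: str
    summary_kind: str  # "mean" | "variance"
    t_value: float
    p_value: float
    direction: int  # sign of adjusted ASD - TD difference
    n_used: int
    p_fdr: float | None = None
    reason: str | None = None


@dataclass
class AdosCorrelationResult:
    metric: str
    summary_kind: str
    ados_scale: str
    r_partial: float
    t_value: float
    p_value: float
    n_used: int
    df: int
    reason: str | None = None


def build_design(cohort: Cohort, include_group: bool = True) -> DesignMatrix:
    """Design matrix with intercept, group indicator (ASD=1) and covariates.

    Sex and site are reference-coded indicators (reference = largest site);
    a single-site cohort simply gets no site columns.  Subjects missing any
    required covariate are dropped and logged.  Rank deficiency is an error
    naming the offending columns.
    """
    df = cohort.to_frame()
    required = COVARIATES + ["sex", "site", "group"]
    complete = df[required].notna().all(axis=1)
    dropped = list(df.index[~complete])
    if dropped:
        logger.info("build_design: dropping %d subject(s) with missing covariates: %s",
                    len(dropped), dropped)
    df = df[complete]
    X = pd.DataFrame(index=df.index)
    X["intercept"] = 1.0
    if include_group:
        X["group"] = (df["group"] == "ASD").astype(float)
    for c in COVARIATES:
        X[c] = df[c].astype(float)
    sex_levels = sorted(df["sex"].unique())
    for level in sex_levels[1:]:
        X[f"sex_{level}"] = (df["sex"] == level).astype(float)
    site_counts = df["site"].value_counts()
    if len(site_counts) > 1:
        reference = site_counts.index[0]
        for level in sorted(s for s in site_counts.index if s != reference):
            X[f"site_{level}"] = (df["site"] == level).astype(float)
    else:
        logger.warning("build_design: single-site cohort; no site columns added")
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        collinear = [
            col for col in X.columns
            if np.linalg.matrix_rank(X.drop(columns=[col]).to_numpy()) == rank
        ]
        raise RankDeficientDesignError(
            f"design matrix rank {rank} < {X.shape[1]} columns; "
            f"collinearity involves: {collinear}"
        )
    return DesignMatrix(frame=X, dropped_subjects=dropped)


def adjusted_group_test(
    summaries: pd.DataFrame, design: DesignMatrix, metric: str, summary_kind: str
) -> GroupTestResult:
    """t-test of the group term in ``summary ~ group + covariates``."""
    col = f"{'mean' if summary_kind == 'mean' else 'var'}_{metric}"
    if "group" not in design.frame.columns:
        raise ValueError("design matrix lacks a group column")
    common = design.frame.index.intersection(summaries.index)
    y = summaries.loc[common, col]
    X = design.frame.loc[common]
    keep = y.notna()
    y, X = y[keep], X[keep]
    n_used = len(y)
    n_per_group = X["group"].value_counts()
    if n_used < X.shape[1] + 1 or len(n_per_group) < 2 or n_per_group.min() < 2:
        return GroupTestResult(metric=metric, summary_kind=summary_kind,
                               t_value=np.nan, p_value=np.nan, direction=0,
                               n_used=n_used, reason="insufficient subjects")
    if float(np.var(y)) < 1e-30:
        return GroupTestResult(metric=metric, summary_kind=summary_kind,
                               t_value=np.nan, p_value=np.nan, direction=0,
                               n_used=n_used, reason="degenerate outcome variance")
    fit = sm.OLS(y.to_numpy(), X.to_numpy()).fit()
    gi = list(X.columns).index("group")
    t_val = float(fit.tvalues[gi])
    return GroupTestResult(
        metric=metric, summary_kind=summary_kind, t_value=t_val,
        p_value=float(fit.pvalues[gi]),
        direction=int(np.sign(fit.params[gi])), n_used=n_used,
    )


def fdr_bh(p_values: np.ndarray | list[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.nanmin(p) < 0 or np.nanmax(p) > 1:
        raise ValueError("p-values must lie in [0, 1]")
    out = np.full_like(p, np.nan)
    valid = ~np.isnan(p)
    if valid.any():
        out[valid] = multipletests(p[valid], method="fdr_bh")[1]
    return out


def partial_correlation_ados(
    summaries: pd.DataFrame,
    design: DesignMatrix,
    cohort: Cohort,
    metric: str,
    summary_kind: str,
    ados_scale: str,
) -> AdosCorrelationResult:
    """Covariate-adjusted Pearson correlation of a summary with an ADOS scale.

    Patient-group subjects with a valid score and complete covariates only;
    ``design`` must not contain the group column.
    """
    if ados_scale not in ADOS_SCALES:
        raise ValueError(f"unknown ADOS scale {ados_scale!r}")
    if "group" in design.frame.columns:
        design = design.without_group()
    col = f"{'mean' if summary_kind == 'mean' else 'var'}_{metric}"
    ados = {
        r.subject_id: r.ados(ados_scale)
        for r in cohort.records if r.group == "ASD"
    }
    ids = [s for s in design.frame.index
           if s in ados and ados[s] is not None and s in summaries.index
           and not np.isnan(summaries.loc[s, col])]
    k = design.n_covariate_columns
    n_used = len(ids)
    if n_used < k + 4:
        return AdosCorrelationResult(metric=metric, summary_kind=summary_kind,
                                     ados_scale=ados_scale, r_partial=np.nan,
                                     t_value=np.nan, p_value=np.nan, n_used=n_used,
                                     df=max(n_used - 2 - k, 0),
                                     reason="insufficient subjects")
    X = design.frame.loc[ids].to_numpy()
    y1 = summaries.loc[ids, col].to_numpy(dtype=float)
    y2 = np.array([ados[s] for s in ids], dtype=float)
    # residualize both variables on the covariates (order irrelevant)
    beta1, *_ = np.linalg.lstsq(X, y1, rcond=None)
    beta2, *_ = np.linalg.lstsq(X, y2, rcond=None)
    r1, r2 = y1 - X @ beta1, y2 - X @ beta2
    denom = np.sqrt((r1 @ r1) * (r2 @ r2))
    if denom < 1e-30:
        return AdosCorrelationResult(metric=metric, summary_kind=summary_kind,
                                     ados_scale=ados_scale, r_partial=np.nan,
                                     t_value=np.nan, p_value=np.nan, n_used=n_used,
                                     df=n_used - 2 - k, reason="degenerate residuals")
    r = float((r1 @ r2) / denom)
    df = n_used - 2 - k
    t_val = r * np.sqrt(df / max(1.0 - r * r, 1e-15))
    p_val = 2.0 * sps.t.sf(abs(t_val), df)
    return AdosCorrelationResult(metric=metric, summary_kind=summary_kind,
                                 ados_scale=ados_scale, r_partial=r,
                                 t_value=float(t_val), p_value=float(p_val),
                                 n_used=n_used, df=df)


def _metric_names_from_summaries(summaries: pd.DataFrame) -> list[str]:
    names = [c[len("mean_"):] for c in summaries.columns if c.startswith("mean_")]
    return names


def _fdr_family(metric: str) -> str | None:
    """Node-level family key 'prefix' for degree_i etc., None for network-level."""
    for prefix in NODE_METRIC_PREFIXES:
        if metric.startswith(prefix + "_"):
            return prefix
    return None


def _group_stats_string(values: pd.Series) -> str:
    return f"{values.mean():.4f} ± {values.std(ddof=1):.4f}"


@dataclass
class AnalysisBundle:
    """The four results tables: group tests and ADOS correlations, mean & variance."""

    group_mean: pd.DataFrame
    group_variance: pd.DataFrame
    ados_mean: pd.DataFrame
    ados_variance: pd.DataFrame
    audit: dict = field(default_factory=dict)


def run_full_analysis(
    cohort: Cohort,
    summaries: pd.DataFrame,
    alpha: float = 0.05,
    fdr_family: str = "node",
) -> AnalysisBundle:
    """Group comparisons (with FDR over node-level families) plus ADOS correlations.

    ``fdr_family='node'`` adjusts each node-level parameter type x summary
    kind across nodes, leaving network-level parameters unadjusted;
    ``'global'`` pools all parameters of one summary kind into a single
    family.
    """
    if fdr_family not in ("node", "global"):
        raise ValueError("fdr_family must be 'node' or 'global'")
    design = build_design(cohort, include_group=True)
    design_nogroup = build_design(cohort, include_group=False)
    metric_names = _metric_names_from_summaries(summaries)
    pheno = cohort.to_frame()

    group_tables = {}
    for kind in ("mean", "variance"):
        results = [adjusted_group_test(summaries, design, m, kind) for m in metric_names]
        rows = []
        prefix = "mean" if kind == "mean" else "var"
        for res in results:
            col = f"{prefix}_{res.metric}"
            vals = summaries[col].dropna()
            by_group = {
                g: vals[vals.index.isin(pheno.index[pheno["group"] == g])]
                for g in ("ASD", "TD")
            }
            rows.append({
                "metric": res.metric, "summary_kind": kind,
                "mean_sd_group1": _group_stats_string(by_group["ASD"]),
                "mean_sd_group2": _group_stats_string(by_group["TD"]),
                "t": res.t_value, "p": res.p_value, "p_fdr": np.nan,
            })
        table = pd.DataFrame(rows)
        if fdr_family == "global":
            table["p_fdr"] = fdr_bh(table["p"].to_numpy())
        else:
            families = [_fdr_family(m) for m in table["metric"]]
            for fam in NODE_METRIC_PREFIXES:
                mask = np.array([f == fam for f in families])
                if mask.any():
                    table.loc[mask, "p_fdr"] = fdr_bh(table.loc[mask, "p"].to_numpy())
        group_tables[kind] = table

    ados_tables = {}
    for kind in ("mean", "variance"):
        rows = []
        for m in metric_names:
            for scale in ADOS_SCALES:
                res = partial_correlation_ados(
                    summaries, design_nogroup, cohort, m, kind, scale)
                rows.append({
                    "metric": m, "summary_kind": kind, "ados_scale": scale,
                    "r_partial": res.r_partial, "t": res.t_value, "p": res.p_value,
                    "n_used": res.n_used, "df": res.df,
                })
        ados_tables[kind] = pd.DataFrame(rows)

    audit = {
        "alpha": alpha,
        "fdr_family": fdr_family,
        "n_subjects": len(cohort),
        "dropped_subjects": design.dropped_subjects,
        "design_columns": list(design.frame.columns),
        "n_significant_group_mean": int((group_tables["mean"]["p"] < alpha).sum()),
        "n_significant_group_variance": int((group_tables["variance"]["p"] < alpha).sum()),
    }
    return AnalysisBundle(
        group_mean=group_tables["mean"], group_variance=group_tables["variance"],
        ados_mean=ados_tables["mean"], ados_variance=ados_tables["variance"],
        audit=audit,
    )
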