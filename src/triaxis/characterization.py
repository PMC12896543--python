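"""Preliminary biomarker characterization statistics.

Differential expression between responders and non-responders
(Mann-Whitney U with Benjamini-Hochberg FDR), Kaplan-Meier / log-rank
survival comparison, Cox proportional-hazards fits, inverse-variance
fixed-effect meta-analysis across cohorts, and marker-gene correlation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "DEResult",
    "SurvivalFit",
    "MetaAnalysisResult",
    "differential_expression",
    "km_logrank",
    "cox_fit",
    "fixed_effect_meta",
    "correlate_with_markers",
]


@dataclass
class DEResult:
    """Per-gene differential-expression table (responder vs non-responder)."""

    table: pd.DataFrame  # columns: log2fc, u_stat, p, q, direction

    def top(self, n: int = 10) -> pd.DataFrame:
        return self.table.sort_values("p").head(n)

    def significant(self, alpha: float = 0.05) -> pd.DataFrame:
        return self.table[self.table["q"] < alpha]


def differential_expression(
    expr: pd.DataFrame,
    labels,
    method: str = "auto",
    covariates: pd.DataFrame | None = None,
) -> DEResult:
    """Gene-wise responder vs non-responder comparison on log-scale data.

    The primary mode is an unadjusted Mann-Whitney U test per gene
    (``method`` forwarded to :func:`scipy.stats.mannwhitneyu`: the
    ``"asymptotic"`` normal approximation is tie-corrected; ``"auto"``
    switches to the exact distribution for small untied samples).
    Genes that are constant across all samples get p = 1 by convention.
    If ``covariates`` is given, an ordinary linear model of log
    expression on group + covariates replaces the rank test (the
    adjusted mode); U statistics are then not reported.

    log2fc is the difference of group means on the log2 scale
    (responder minus non-responder).  Benjamini-Hochberg adjustment is
    applied over all tested genes.
    """
    y = np.asarray(labels).astype(int)
    if len(np.unique(y)) < 2:
        raise ValueError("both response classes must be present")
    x = expr.to_numpy(dtype=float)
    r, nr = x[:, y == 1], x[:, y == 0]
    log2fc = r.mean(axis=1) - nr.mean(axis=1)
    constant = x.std(axis=1) == 0

    if covariates is not None:
        import statsmodels.api as sm

        design = sm.add_constant(
            np.column_stack([y, covariates.to_numpy(dtype=float)])
        )
        pvals = np.ones(x.shape[0])
        ustat = np.full(x.shape[0], np.nan)
        for i in range(x.shape[0]):
            if constant[i]:
                continue
            fit = sm.OLS(x[i], design).fit()
            pvals[i] = fit.pvalues[1]
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = stats.mannwhitneyu(
                r, nr, axis=1, alternative="two-sided", method=method
            )
        ustat = np.asarray(res.statistic, dtype=float)
        pvals = np.asarray(res.pvalue, dtype=float)
        pvals[constant] = 1.0
        ustat[constant] = r.shape[1] * nr.shape[1] / 2.0

    _, qvals, _, _ = multipletests(pvals, method="fdr_bh")
    table = pd.DataFrame(
        {
            "log2fc": log2fc,
            "u_stat": ustat,
            "p": pvals,
            "q": qvals,
            "direction": np.sign(log2fc).astype(int),
        },
        index=expr.index,
    )
    return DEResult(table=table)


@dataclass
class SurvivalFit:
    """Survival comparison: KM curves, log-rank, and/or a Cox fit."""

    km_curves: dict = field(default_factory=dict)
    logrank_stat: float | None = None
    logrank_p: float | None = None
    log_hr: float | None = None
    se: float | None = None
    hr: float | None = None
    ci: tuple[float, float] | None = None
    p: float | None = None
    converged: bool = True
    warnings: tuple[str, ...] = ()


def km_logrank(time, event, group) -> SurvivalFit:
    """Two-group Kaplan-Meier curves and the standard log-rank test."""
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    group = np.asarray(group)
    if len(np.unique(group)) != 2:
        raise ValueError("exactly two groups required")
    if event.sum() < 1:
        raise ValueError("at least one event required")
    curves = {}
    for g in np.unique(group):
        kmf = KaplanMeierFitter()
        kmf.fit(time[group == g], event[group == g], label=str(g))
        curves[g] = kmf.survival_function_
    res = multivariate_logrank_test(time, group, event)
    return SurvivalFit(
        km_curves=curves,
        logrank_stat=float(res.test_statistic),
        logrank_p=float(res.p_value),
    )


def cox_fit(time, event, covariates, ties: str = "breslow") -> SurvivalFit:
    """Cox proportional-hazards fit (Breslow ties by default).

    Reports the log-HR, SE, HR and Wald 95% CI of the *first* covariate
    column (the focal one); further covariates act as adjusters.
    Non-convergence or separation is reported in the result rather than
    raised, with the warning text attached.
    """
    cov = pd.DataFrame(covariates)
    if (cov.nunique() <= 1).any():
        raise ValueError("constant covariate")
    if np.asarray(event).sum() < cov.shape[1]:
        raise ValueError("fewer events than covariates")
    df = cov.copy()
    df["_time"] = np.asarray(time, dtype=float)
    df["_event"] = np.asarray(event, dtype=int)
    cph = CoxPHFitter()
    notes: list[str] = []
    try:
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            cph.fit(df, duration_col="_time", event_col="_event")
        notes = [str(w.message) for w in caught]
    except Exception as exc:  # noqa: BLE001 - surfaced as diagnostics
        return SurvivalFit(converged=False, warnings=(str(exc),))
    name = cov.columns[0]
    log_hr = float(cph.params_[name])
    se = float(cph.standard_errors_[name])
    return SurvivalFit(
        log_hr=log_hr,
        se=se,
        hr=float(np.exp(log_hr)),
        ci=(float(np.exp(log_hr - 1.96 * se)), float(np.exp(log_hr + 1.96 * se))),
        p=float(cph.summary.loc[name, "p"]),
        converged=True,
        warnings=tuple(notes),
    )


@dataclass
class MetaAnalysisResult:
    pooled_log_hr: float
    se: float
    hr: float
    ci: tuple[float, float]
    p: float
    q_stat: float
    i2: float  # percent

    def __post_init__(self) -> None:
        if not 0.0 <= self.i2 <= 100.0:
            raise ValueError("I2 must be in [0, 100]")


def fixed_effect_meta(log_hrs, ses) -> MetaAnalysisResult:
    """Inverse-variance fixed-effect pooling with Cochran Q and I2.

    pooled = sum(w_i * theta_i) / sum(w_i) with w_i = 1/se_i^2;
    Q = sum(w_i * (theta_i - pooled)^2); I2 = max(0, (Q - df)/Q) * 100.
    """
    theta = np.asarray(log_hrs, dtype=float)
    se = np.asarray(ses, dtype=float)
    if len(theta) < 2:
        raise ValueError("need >= 2 studies")
    if (se <= 0).any():
        raise ValueError("standard errors must be positive")
    w = 1.0 / se**2
    pooled = float(np.sum(w * theta) / np.sum(w))
    pooled_se = float(np.sqrt(1.0 / np.sum(w)))
    q = float(np.sum(w * (theta - pooled) ** 2))
    df = len(theta) - 1
    i2 = max(0.0, (q - df) / q) * 100.0 if q > 0 else 0.0
    z = pooled / pooled_se
    p = 2.0 * stats.norm.sf(abs(z))
    return MetaAnalysisResult(
        pooled_log_hr=pooled,
        se=pooled_se,
        hr=float(np.exp(pooled)),
        ci=(float(np.exp(pooled - 1.96 * pooled_se)), float(np.exp(pooled + 1.96 * pooled_se))),
        p=float(p),
        q_stat=q,
        i2=float(i2),
    )


def correlate_with_markers(
    expr: pd.DataFrame,
    focal_gene: str,
    marker_genes,
    stratify_labels=None,
) -> pd.DataFrame:
    """Pearson correlation of the focal gene with each marker gene.

    Returns one row per (marker, stratum) with r, p and n; stratum
    ``"all"`` is always present.  Zero-variance genes give a missing r
    with the reason recorded.
    """
    for g in [focal_gene, *marker_genes]:
        if g not in expr.index:
            raise ValueError(f"gene {g!r} not present")
    strata: dict[str, np.ndarray] = {"all": np.ones(expr.shape[1], dtype=bool)}
    if stratify_labels is not None:
        lab = np.asarray(stratify_labels)
        for v in np.unique(lab):
            strata[str(v)] = lab == v
    rows = []
    for stratum, mask in strata.items():
        x = expr.loc[focal_gene].to_numpy(dtype=float)[mask]
        for g in marker_genes:
            yv = expr.loc[g].to_numpy(dtype=float)[mask]
            if np.std(x) == 0 or np.std(yv) == 0:
                rows.append(
                    {"marker": g, "stratum": stratum, "r": np.nan, "p": np.nan,
                     "n": int(mask.sum()), "note": "zero variance"}
                )
                continue
            r, p = stats.pearsonr(x, yv)
            rows.append(
                {"marker": g, "stratum": stratum, "r": float(r), "p": float(p),
                 "n": int(mask.sum()), "note": ""}
            )
    return pd.DataFrame(rows)
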