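"""Leave-one-cohort-out external validation of locked models.

Each external cohort is scored by the locked model with no refitting;
cohorts are equally weighted validation units, so the headline number is
the *macro*-AUC (unweighted mean of per-cohort AUCs) with a bootstrap
CI.  Clinical-utility layers: intercept-only recalibration, decision
curves over the 15-50% risk-threshold band, net reclassification (NRI)
and integrated discrimination (IDI) against a baseline marker, and
benchmark comparison of competing signatures with paired DeLong tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .discovery import (
    LockedModel,
    _logit,
    delong_ci,
    delong_test,
    evaluate_binary,
    build_features,
)
from .signatures import SignatureDefinition
from .synthetic import CohortBundle

__all__ = [
    "LOCOReport",
    "DecisionCurve",
    "ReclassificationReport",
    "loco_validate",
    "recalibrate_intercept",
    "decision_curve",
    "nri_idi",
    "benchmark_compare",
]

_EPS = 1e-7


def _threshold_metrics(probs, labels, threshold: float) -> dict:
    pred = np.asarray(probs) >= threshold
    y = np.asarray(labels, dtype=int)
    tp = int((pred & (y == 1)).sum())
    fp = int((pred & (y == 0)).sum())
    fn = int((~pred & (y == 1)).sum())
    tn = int((~pred & (y == 0)).sum())

    def _safe(num, den):
        return num / den if den > 0 else np.nan

    return {
        "sensitivity": _safe(tp, tp + fn),
        "specificity": _safe(tn, tn + fp),
        "ppv": _safe(tp, tp + fp),
        "npv": _safe(tn, tn + fn),
        "tp": tp, "fp": fp, "fn": fn, "tn": tn,
    }


def _bootstrap_auc_ci(probs, labels, n_boot: int, rng) -> tuple[float, float]:
    from sklearn.metrics import roc_auc_score

    y = np.asarray(labels, dtype=int)
    p = np.asarray(probs, dtype=float)
    stats_ = []
    n = len(y)
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        if len(np.unique(y[idx])) < 2:
            continue
        stats_.append(roc_auc_score(y[idx], p[idx]))
    if not stats_:
        return (np.nan, np.nan)
    lo, hi = np.percentile(stats_, [2.5, 97.5])
    return float(lo), float(hi)


@dataclass
class LOCOReport:
    """Per-cohort and macro-averaged external validation metrics."""

    per_cohort: pd.DataFrame
    macro_auc: float
    macro_auc_ci: tuple[float, float]
    heterogeneity_q: float
    i2: float
    excluded_cohorts: tuple[str, ...] = field(default_factory=tuple)
    predictions: dict = field(default_factory=dict)

    def summary(self) -> str:
        lines = [
            "Leave-one-cohort-out validation (locked model, no refitting)",
            "=" * 64,
        ]
        for cid, row in self.per_cohort.iterrows():
            lines.append(
                f"{cid:<10} n={int(row['n']):>3}  AUC={row['auc']:.3f} "
                f"({row['auc_lo']:.3f}-{row['auc_hi']:.3f})  "
                f"Brier={row['brier']:.3f}"
            )
        lines.append("-" * 64)
        lo, hi = self.macro_auc_ci
        lines.append(
            f"macro-AUC = {self.macro_auc:.3f} (95% CI {lo:.3f}-{hi:.3f}); "
            f"I2 = {self.i2:.0f}%"
        )
        return "\n".join(lines)


def loco_validate(
    model: LockedModel,
    cohorts: list[CohortBundle],
    signature: SignatureDefinition | None = None,
    n_boot: int = 2000,
    seed: int = 0,
    clinical: bool = False,
) -> LOCOReport:
    """Apply a locked model unchanged to each external cohort.

    Per cohort: AUC with percentile-bootstrap 95% CI, PR-AUC, Brier,
    and confusion-matrix rates at the locked threshold.  Cohorts with a
    single response class are excluded from AUC averaging (reported
    with threshold metrics only, with a warning).  The macro-AUC is the
    unweighted mean of per-cohort AUCs; its CI comes from within-cohort
    bootstrap resampling of the macro average.  Heterogeneity of the
    cohort AUCs is summarized by Cochran's Q on logit-AUCs with
    bootstrap SEs, converted to I2.
    """
    rng = np.random.default_rng(seed)
    rows, preds, excluded = [], {}, []
    feature_set = model.feature_names
    gene_features = tuple(f for f in feature_set if f not in ("line_bin", "stage_bin"))
    boot_aucs_per_cohort = []
    for bundle in cohorts:
        feats = build_features(bundle, signature, gene_features, clinical=clinical)
        probs = model.predict_proba(feats)
        y = bundle.response.to_numpy()
        preds[bundle.cohort_id] = pd.Series(probs, index=feats.index)
        row = {"cohort": bundle.cohort_id, "n": len(y),
               "prevalence": float(y.mean())}
        row.update(_threshold_metrics(probs, y, model.threshold))
        if len(np.unique(y)) < 2:
            warnings.warn(
                f"cohort {bundle.cohort_id} has a single class; "
                "excluded from AUC averaging"
            )
            excluded.append(bundle.cohort_id)
            row.update({"auc": np.nan, "auc_lo": np.nan, "auc_hi": np.nan,
                        "pr_auc": np.nan, "brier": float(np.mean((probs - y) ** 2))})
        else:
            m = evaluate_binary(probs, y)
            lo, hi = _bootstrap_auc_ci(probs, y, n_boot, rng)
            row.update({"auc": m["auc"], "auc_lo": lo, "auc_hi": hi,
                        "pr_auc": m["pr_auc"], "brier": m["brier"]})
            from sklearn.metrics import roc_auc_score

            boots = []
            n = len(y)
            for _ in range(min(n_boot, 500)):
                idx = rng.integers(0, n, size=n)
                if len(np.unique(y[idx])) == 2:
                    boots.append(roc_auc_score(y[idx], probs[idx]))
            boot_aucs_per_cohort.append(np.asarray(boots))
        rows.append(row)
    table = pd.DataFrame(rows).set_index("cohort")
    valid = table["auc"].dropna()
    macro = float(valid.mean())
    # macro CI: average of per-cohort bootstrap AUC draws
    if boot_aucs_per_cohort:
        n_draw = min(len(b) for b in boot_aucs_per_cohort)
        draws = np.mean([b[:n_draw] for b in boot_aucs_per_cohort], axis=0)
        macro_ci = (float(np.percentile(draws, 2.5)),
                    float(np.percentile(draws, 97.5)))
    else:
        macro_ci = (np.nan, np.nan)
    q, i2 = _auc_heterogeneity(valid.to_numpy(), boot_aucs_per_cohort)
    return LOCOReport(
        per_cohort=table,
        macro_auc=macro,
        macro_auc_ci=macro_ci,
        heterogeneity_q=q,
        i2=i2,
        excluded_cohorts=tuple(excluded),
        predictions=preds,
    )


def _auc_heterogeneity(aucs, boot_draws) -> tuple[float, float]:
    """Cochran Q / I2 over logit-AUCs with bootstrap SEs."""
    if len(aucs) < 2 or len(boot_draws) != len(aucs):
        return np.nan, np.nan
    eps = 1e-4
    theta = _logit(np.clip(aucs, eps, 1 - eps))
    ses = np.array([
        np.std(_logit(np.clip(b, eps, 1 - eps)), ddof=1) if len(b) > 1 else np.nan
        for b in boot_draws
    ])
    if np.isnan(ses).any() or (ses <= 0).any():
        return np.nan, np.nan
    w = 1.0 / ses**2
    pooled = np.sum(w * theta) / np.sum(w)
    q = float(np.sum(w * (theta - pooled) ** 2))
    df = len(theta) - 1
    i2 = max(0.0, (q - df) / q) * 100.0 if q > 0 else 0.0
    return q, float(i2)


def recalibrate_intercept(probs, labels) -> tuple[np.ndarray, float]:
    """Intercept-only logistic recalibration.

    Fits ``y ~ offset(logit(p))`` with an intercept only and returns
    ``(adjusted_probs, delta)`` where adjusted = inv-logit(logit(p) +
    delta).  At convergence the mean adjusted probability equals the
    event rate (calibration-in-the-large = 0).  Separation falls back
    to a bounded moment-matching step with a warning.
    """
    import statsmodels.api as sm

    p = np.clip(np.asarray(probs, dtype=float), _EPS, 1 - _EPS)
    y = np.asarray(labels, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes required")
    lp = _logit(p)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = sm.GLM(
                y, np.ones((len(y), 1)), offset=lp, family=sm.families.Binomial()
            ).fit()
        delta = float(fit.params[0])
        if not np.isfinite(delta):
            raise ValueError("non-finite recalibration")
    except Exception:
        warnings.warn("recalibration separation; using bounded moment step")
        delta = float(np.clip(_logit(np.clip(y.mean(), _EPS, 1 - _EPS))
                              - _logit(np.clip(p.mean(), _EPS, 1 - _EPS)),
                              -10, 10))
    adjusted = 1.0 / (1.0 + np.exp(-(lp + delta)))
    return adjusted, delta


@dataclass
class DecisionCurve:
    """Net benefit of the model vs treat-all / treat-none per threshold."""

    table: pd.DataFrame  # columns: threshold, nb_model, nb_all, nb_none

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def decision_curve(probs, labels, thresholds=None) -> DecisionCurve:
    """Decision-curve analysis: NB(t) = TP/n - FP/n * t/(1-t).

    A sample is treated when its predicted probability is >= t.
    Treat-none has net benefit 0; treat-all has
    prevalence - (1 - prevalence) * t/(1-t).
    """
    if thresholds is None:
        thresholds = np.round(np.arange(0.15, 0.501, 0.01), 4)
    t_arr = np.asarray(thresholds, dtype=float)
    if ((t_arr <= 0) | (t_arr >= 1)).any():
        raise ValueError("thresholds must be in (0, 1)")
    p = np.asarray(probs, dtype=float)
    y = np.asarray(labels, dtype=int)
    n = len(y)
    prev = y.mean()
    rows = []
    for t in t_arr:
        treated = p >= t
        tp = (treated & (y == 1)).sum()
        fp = (treated & (y == 0)).sum()
        odds = t / (1.0 - t)
        rows.append({
            "threshold": t,
            "nb_model": tp / n - fp / n * odds,
            "nb_all": prev - (1.0 - prev) * odds,
            "nb_none": 0.0,
        })
    return DecisionCurve(table=pd.DataFrame(rows))


@dataclass
class ReclassificationReport:
    nri: float
    nri_events: float
    nri_nonevents: float
    idi: float
    threshold: float

    def __post_init__(self) -> None:
        if not -2.0 <= self.nri <= 2.0:
            raise ValueError("NRI out of range")


def nri_idi(probs_new, probs_old, labels, threshold: float) -> ReclassificationReport:
    """Two-category NRI at a threshold, and IDI.

    NRI = [P(up|event) - P(down|event)] + [P(down|non-event) -
    P(up|non-event)] where up/down are reclassifications of the new
    model across the threshold relative to the old.  IDI is the
    difference in discrimination slopes (mean p in events minus mean p
    in non-events, new minus old).
    """
    pn = np.asarray(probs_new, dtype=float)
    po = np.asarray(probs_old, dtype=float)
    y = np.asarray(labels, dtype=int)
    if pn.shape != po.shape or len(pn) != len(y):
        raise ValueError("predictions must be paired")
    up = (pn >= threshold) & (po < threshold)
    down = (pn < threshold) & (po >= threshold)
    ev, ne = y == 1, y == 0
    nri_ev = (up[ev].mean() - down[ev].mean()) if ev.any() else 0.0
    nri_ne = (down[ne].mean() - up[ne].mean()) if ne.any() else 0.0
    idi = (pn[ev].mean() - pn[ne].mean()) - (po[ev].mean() - po[ne].mean())
    return ReclassificationReport(
        nri=float(nri_ev + nri_ne),
        nri_events=float(nri_ev),
        nri_nonevents=float(nri_ne),
        idi=float(idi),
        threshold=float(threshold),
    )


def benchmark_compare(
    models: dict[str, dict[str, np.ndarray]],
    labels: dict[str, np.ndarray],
    primary: str,
) -> pd.DataFrame:
    """Macro-AUC ranking of scoring models plus DeLong tests vs primary.

    ``models`` maps model name -> {cohort_id -> per-sample scores};
    ``labels`` maps cohort_id -> binary outcomes.  All models must
    score the same samples within each cohort.  Output: one row per
    model with macro-AUC and, for non-primary models, per-cohort paired
    DeLong p-values vs the primary model.
    """
    from sklearn.metrics import roc_auc_score

    if primary not in models:
        raise ValueError(f"primary model {primary!r} not in models")
    cohort_ids = sorted(labels)
    rows = []
    for name, scores in models.items():
        missing = [c for c in cohort_ids if c not in scores]
        if missing:
            raise ValueError(f"model {name!r} missing scores for {missing}")
        aucs, pvals = [], {}
        for cid in cohort_ids:
            y = np.asarray(labels[cid], dtype=int)
            if len(np.unique(y)) < 2:
                continue
            aucs.append(roc_auc_score(y, scores[cid]))
            if name != primary:
                res = delong_test(models[primary][cid], scores[cid], y)
                pvals[f"delong_p_{cid}"] = res["p"]
        rows.append({"model": name, "macro_auc": float(np.mean(aucs)), **pvals})
    table = pd.DataFrame(rows).set_index("model")
    return table.sort_values("macro_auc", ascending=False)
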