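"""Discovery-phase modelling of immunotherapy response.

The core object is :class:`TriAxisModel`: an L1-penalized logistic
regression over three transcriptomic axes — focal-marker expression
(BCL2A1), CD274 expression, and the hot-score of a multi-gene immune
activation program — fitted with nested cross-validation (10 outer / 5
inner stratified folds) so the out-of-fold probabilities are honest.
``fit()`` returns :class:`DiscoveryResults` carrying the out-of-fold
predictions, discrimination/calibration metrics, the locked final model
and a ``summary()`` table; the locked model (coefficients, intercept,
penalty, Youden threshold) is then applied *unchanged* to external
cohorts by the validation module.

Feature scaling is re-fit inside every training split, never on held-out
samples; the locked model folds its scaler into raw-scale coefficients
so external application is a single affine-plus-sigmoid map.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import average_precision_score, roc_auc_score
from sklearn.model_selection import StratifiedKFold

from .signatures import SignatureDefinition, default_hot_signature, score_signature
from .synthetic import CD274_GENE, FOCAL_GENE, CohortBundle

__all__ = [
    "preprocess",
    "build_features",
    "CVReport",
    "LockedModel",
    "TriAxisModel",
    "DiscoveryResults",
    "nested_cv_fit",
    "evaluate_binary",
    "youden_threshold",
    "delong_test",
    "delong_ci",
    "lock_model",
    "DEFAULT_PENALTY_GRID",
]

DEFAULT_PENALTY_GRID = tuple(np.logspace(-2, 2, 7))
_EPS = 1e-7


def preprocess(
    expr: pd.DataFrame,
    counts: bool = False,
    abundance_floor: float = 1.0,
    filter_low: bool = True,
) -> pd.DataFrame:
    """Filter low-abundance genes and robust-normalize per gene.

    Counts are log2(x+1)-transformed first.  Genes whose mean log2
    value falls below ``abundance_floor`` are removed (the floor is a
    configuration default; set ``filter_low=False`` to disable).  Each
    remaining gene is robust z-scored: (x - median) / (1.4826 * MAD);
    genes with MAD = 0 are dropped with a warning.
    """
    if counts:
        if (expr.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        expr = np.log2(expr + 1.0)
    if filter_low:
        expr = expr[expr.mean(axis=1) >= abundance_floor]
    med = expr.median(axis=1)
    mad = (expr.sub(med, axis=0)).abs().median(axis=1)
    keep = mad > 0
    if not keep.all():
        warnings.warn(f"dropping {(~keep).sum()} genes with zero MAD")
    expr = expr[keep]
    if expr.empty:
        raise ValueError("no genes left after filtering")
    med, mad = med[keep], mad[keep]
    return expr.sub(med, axis=0).div(1.4826 * mad, axis=0)


TRI_AXIS = (FOCAL_GENE, CD274_GENE, "HOT")


def build_features(
    bundle: CohortBundle,
    signature: SignatureDefinition | None = None,
    features: tuple[str, ...] = TRI_AXIS,
    clinical: bool = False,
) -> pd.DataFrame:
    """Assemble the per-sample feature table for a cohort.

    Gene features are taken from the cohort's log2 expression; ``"HOT"``
    maps to the mean-z hot score of ``signature`` (default the bundled
    27-gene program).  All features are computed within the cohort, so
    cohort-level batch offsets cancel.  ``clinical=True`` appends the
    binary stage/line covariates.
    """
    if signature is None:
        signature = default_hot_signature()
    cols = {}
    for f in features:
        if f == "HOT":
            cols["HOT"] = score_signature(bundle.expression, signature).scores
        else:
            if f not in bundle.expression.index:
                raise ValueError(f"feature gene {f!r} missing from cohort "
                                 f"{bundle.cohort_id!r}")
            cols[f] = bundle.expression.loc[f]
    table = pd.DataFrame(cols)
    if clinical:
        table = table.join(bundle.covariates[["line_bin", "stage_bin"]])
    if table.isna().any().any():
        raise ValueError("missing values in feature table")
    return table


# ---------------------------------------------------------------------------
# metrics


def evaluate_binary(probs, labels) -> dict:
    """Discrimination and calibration metrics for binary predictions.

    ROC-AUC (rank-based, tie-corrected), PR-AUC as average precision
    (step integral), Brier score, and calibration slope/intercept from
    a logistic regression of the outcome on logit(p).
    """
    p = np.asarray(probs, dtype=float)
    y = np.asarray(labels, dtype=int)
    if p.min() < 0 or p.max() > 1:
        raise ValueError("probabilities must be in [0, 1]")
    if len(np.unique(y)) < 2:
        raise ValueError("both classes required")
    auc = float(roc_auc_score(y, p))
    pr_auc = float(average_precision_score(y, p))
    brier = float(np.mean((p - y) ** 2))
    slope, intercept = _calibration_fit(p, y)
    return {
        "auc": auc,
        "pr_auc": pr_auc,
        "brier": brier,
        "calibration_slope": slope,
        "calibration_intercept": intercept,
    }


def _calibration_fit(p, y) -> tuple[float, float]:
    import statsmodels.api as sm

    lp = _logit(np.clip(p, _EPS, 1 - _EPS))
    if np.std(lp) == 0:
        return np.nan, np.nan
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = sm.GLM(y, sm.add_constant(lp), family=sm.families.Binomial()).fit()
        return float(fit.params[1]), float(fit.params[0])
    except Exception:  # separation / non-convergence
        return np.nan, np.nan


def _logit(p):
    return np.log(p / (1.0 - p))


def youden_threshold(probs, labels) -> tuple[float, float]:
    """Locked classification threshold maximizing Youden's J.

    Candidates are the observed probabilities (classification rule:
    p >= t is positive).  Ties in J are broken toward higher specificity
    (the larger threshold); the returned cutoff is the midpoint of the
    half-open threshold interval that realizes the chosen confusion
    matrix, clipped into (0, 1).  Returns ``(threshold, J)``; an
    anti-predictive input (J <= 0) triggers a warning.
    """
    p = np.asarray(probs, dtype=float)
    y = np.asarray(labels, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes required")
    cand = np.unique(p)
    n_pos, n_neg = (y == 1).sum(), (y == 0).sum()
    best_j, best_t = -np.inf, cand[0]
    for i, t in enumerate(cand):
        pred = p >= t
        sens = (pred & (y == 1)).sum() / n_pos
        spec = (~pred & (y == 0)).sum() / n_neg
        j = sens + spec - 1.0
        if j > best_j + 1e-12 or (abs(j - best_j) <= 1e-12 and t > best_t):
            best_j, best_t, best_i = j, t, i
    lower = cand[best_i - 1] if best_i > 0 else 0.0
    thr = float(np.clip((lower + best_t) / 2.0, _EPS, 1 - _EPS))
    if best_j <= 0:
        warnings.warn(f"anti-predictive probabilities: max Youden J = {best_j:.3f}")
    return thr, float(best_j)


def _placements(probs, labels):
    y = np.asarray(labels, dtype=int)
    p = np.asarray(probs, dtype=float)
    pos, neg = p[y == 1], p[y == 0]
    m, n = len(pos), len(neg)
    # midrank placements (handles ties)
    v10 = np.empty(m)
    v01 = np.empty(n)
    for i, xi in enumerate(pos):
        v10[i] = ((xi > neg).sum() + 0.5 * (xi == neg).sum()) / n
    for j, xj in enumerate(neg):
        v01[j] = ((pos > xj).sum() + 0.5 * (pos == xj).sum()) / m
    return v10, v01


def delong_test(probs_a, probs_b, labels) -> dict:
    """Paired DeLong comparison of two correlated ROC-AUCs.

    Placement-value covariance estimator; two-sided normal p-value.
    Identical predictions give difference 0, p = 1.
    """
    pa, pb = np.asarray(probs_a, float), np.asarray(probs_b, float)
    if pa.shape != pb.shape or len(pa) != len(labels):
        raise ValueError("predictions must be paired on identical samples")
    va10, va01 = _placements(pa, labels)
    vb10, vb01 = _placements(pb, labels)
    auc_a, auc_b = va10.mean(), vb10.mean()
    m, n = len(va10), len(va01)
    s10 = np.cov(np.vstack([va10, vb10]), ddof=1) if m > 1 else np.zeros((2, 2))
    s01 = np.cov(np.vstack([va01, vb01]), ddof=1) if n > 1 else np.zeros((2, 2))
    var = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m + (
        s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]
    ) / n
    diff = auc_a - auc_b
    if var <= 0:
        z, p = 0.0, 1.0
    else:
        z = diff / np.sqrt(var)
        p = 2.0 * stats.norm.sf(abs(z))
    return {"auc_a": float(auc_a), "auc_b": float(auc_b),
            "difference": float(diff), "z": float(z), "p": float(p)}


def delong_ci(probs, labels, alpha: float = 0.05) -> tuple[float, float, float]:
    """DeLong variance-based CI for a single AUC: (auc, lo, hi)."""
    v10, v01 = _placements(probs, labels)
    auc = v10.mean()
    var = np.var(v10, ddof=1) / len(v10) + np.var(v01, ddof=1) / len(v01)
    half = stats.norm.ppf(1 - alpha / 2) * np.sqrt(max(var, 0.0))
    return float(auc), float(max(0.0, auc - half)), float(min(1.0, auc + half))


# ---------------------------------------------------------------------------
# nested CV and locking


@dataclass
class CVReport:
    """Out-of-fold predictions and per-fold choices from nested CV."""

    oof_probs: pd.Series
    fold_assignments: pd.Series
    fold_penalties: list[float]
    metrics: dict
    outer_folds: int
    inner_folds: int


def _fit_l1(x, y, c: float) -> LogisticRegression:
    clf = LogisticRegression(
        l1_ratio=1.0, C=c, solver="liblinear", max_iter=2000, random_state=0
    )
    clf.fit(x, y)
    return clf


def _scale_fit(x):
    mu = x.mean(axis=0)
    sd = x.std(axis=0, ddof=0)
    sd = np.where(sd > 0, sd, 1.0)
    return mu, sd


def _inner_select(x, y, grid, inner, rng_seed) -> float:
    """Pick the penalty with best mean inner-fold AUC (tie: stronger)."""
    k = min(inner, np.bincount(y).min())
    if k < 2:
        return float(sorted(grid)[len(grid) // 2])
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=rng_seed)
    best_c, best_auc = None, -np.inf
    for c in sorted(grid):  # ascending C: ties keep the stronger penalty
        aucs = []
        for tr, te in skf.split(x, y):
            mu, sd = _scale_fit(x[tr])
            clf = _fit_l1((x[tr] - mu) / sd, y[tr], c)
            p = clf.predict_proba((x[te] - mu) / sd)[:, 1]
            if len(np.unique(y[te])) == 2:
                aucs.append(roc_auc_score(y[te], p))
        mean_auc = np.mean(aucs) if aucs else -np.inf
        if mean_auc > best_auc + 1e-12:
            best_auc, best_c = mean_auc, c
    return float(best_c)


def nested_cv_fit(
    features: pd.DataFrame,
    labels,
    outer: int = 10,
    inner: int = 5,
    penalty_grid=DEFAULT_PENALTY_GRID,
    seed: int = 0,
) -> CVReport:
    """Nested stratified cross-validation of the L1 logistic model.

    The inner loop selects the penalty by mean inner-fold AUC for each
    outer training split; the outer model then predicts its held-out
    samples, and the per-sample out-of-fold probabilities are assembled
    (each sample predicted exactly once).  Scaling is re-fit on each
    training split.  If a class is too small for the requested outer
    fold count, the fold count is reduced with a warning.
    """
    x = features.to_numpy(dtype=float)
    y = np.asarray(labels, dtype=int)
    min_class = np.bincount(y).min()
    if min_class < 2:
        raise ValueError("each class needs >= 2 samples")
    k = min(outer, min_class)
    if k < outer:
        warnings.warn(f"outer folds reduced from {outer} to {k} (small class)")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    oof = np.full(len(y), np.nan)
    assign = np.full(len(y), -1)
    penalties = []
    for fold, (tr, te) in enumerate(skf.split(x, y)):
        c = _inner_select(x[tr], y[tr], penalty_grid, inner, seed + 1000 + fold)
        mu, sd = _scale_fit(x[tr])
        clf = _fit_l1((x[tr] - mu) / sd, y[tr], c)
        oof[te] = clf.predict_proba((x[te] - mu) / sd)[:, 1]
        assign[te] = fold
        penalties.append(c)
    oof = np.clip(oof, _EPS, 1 - _EPS)
    metrics = evaluate_binary(oof, y)
    metrics["auc_ci"] = delong_ci(oof, y)[1:]
    return CVReport(
        oof_probs=pd.Series(oof, index=features.index, name="oof_prob"),
        fold_assignments=pd.Series(assign, index=features.index, name="fold"),
        fold_penalties=penalties,
        metrics=metrics,
        outer_folds=k,
        inner_folds=inner,
    )


@dataclass(frozen=True)
class LockedModel:
    """A frozen classifier: raw-scale coefficients + Youden threshold.

    Immutable after locking; applied unchanged to external cohorts.
    Coefficients are on the raw feature scale (the training scaler is
    folded in), so prediction is inv-logit(intercept + x @ coef).
    """

    feature_names: tuple[str, ...]
    coefficients: tuple[float, ...]
    intercept: float
    penalty: float
    threshold: float
    schema_version: int = 1

    def __post_init__(self) -> None:
        if not 0.0 < self.threshold < 1.0:
            raise ValueError("threshold must be in (0, 1)")

    def linear_predictor(self, features: pd.DataFrame) -> np.ndarray:
        missing = [f for f in self.feature_names if f not in features.columns]
        if missing:
            raise ValueError(f"missing features: {missing}")
        x = features[list(self.feature_names)].to_numpy(dtype=float)
        return self.intercept + x @ np.asarray(self.coefficients)

    def predict_proba(self, features: pd.DataFrame) -> np.ndarray:
        return 1.0 / (1.0 + np.exp(-self.linear_predictor(features)))

    def predict(self, features: pd.DataFrame) -> np.ndarray:
        return (self.predict_proba(features) >= self.threshold).astype(int)

    def to_json(self, path=None) -> str:
        payload = json.dumps(
            {
                "schema_version": self.schema_version,
                "feature_names": list(self.feature_names),
                "coefficients": list(self.coefficients),
                "intercept": self.intercept,
                "penalty": self.penalty,
                "threshold": self.threshold,
            },
            indent=2,
        )
        if path is not None:
            with open(path, "w") as fh:
                fh.write(payload)
        return payload

    @classmethod
    def from_json(cls, source) -> "LockedModel":
        if isinstance(source, str) and source.lstrip().startswith("{"):
            obj = json.loads(source)
        else:
            with open(source) as fh:
                obj = json.load(fh)
        return cls(
            feature_names=tuple(obj["feature_names"]),
            coefficients=tuple(obj["coefficients"]),
            intercept=float(obj["intercept"]),
            penalty=float(obj["penalty"]),
            threshold=float(obj["threshold"]),
            schema_version=int(obj.get("schema_version", 1)),
        )


def lock_model(
    features: pd.DataFrame,
    labels,
    penalty_grid=DEFAULT_PENALTY_GRID,
    cv_report: CVReport | None = None,
    seed: int = 0,
    threshold: float | None = None,
) -> LockedModel:
    """Final full-data L1 fit at a 5-fold-CV-chosen penalty.

    The penalty is re-selected by 5-fold CV on the full discovery data
    (mirroring the inner loop); the threshold is the Youden cutoff on
    the nested-CV out-of-fold predictions when a ``cv_report`` is given,
    otherwise an explicit ``threshold`` must be supplied.  A model with
    all coefficients shrunk to zero is rejected.
    """
    x = features.to_numpy(dtype=float)
    y = np.asarray(labels, dtype=int)
    c = _inner_select(x, y, penalty_grid, 5, seed)
    mu, sd = _scale_fit(x)
    clf = _fit_l1((x - mu) / sd, y, c)
    coef_std = clf.coef_[0]
    if np.allclose(coef_std, 0.0):
        raise ValueError("penalty shrank every coefficient to zero; "
                         "refusing to lock an empty model")
    coef_raw = coef_std / sd
    intercept = float(clf.intercept_[0] - np.sum(coef_std * mu / sd))
    if threshold is None:
        if cv_report is None:
            raise ValueError("need cv_report (or explicit threshold) to lock")
        threshold, _ = youden_threshold(cv_report.oof_probs.to_numpy(), y)
    return LockedModel(
        feature_names=tuple(features.columns),
        coefficients=tuple(float(b) for b in coef_raw),
        intercept=intercept,
        penalty=float(c),
        threshold=float(threshold),
    )


# ---------------------------------------------------------------------------
# model / results objects


class TriAxisModel:
    """L1-logistic response model over the tri-axis feature table.

    Parameters
    ----------
    features : DataFrame
        Per-sample feature table (rows = samples).
    labels : array-like
        Binary response (1 = responder).

    Use :meth:`from_cohort` to build the canonical tri-axis features
    (focal marker, CD274, hot score) from a :class:`CohortBundle`.
    """

    def __init__(self, features: pd.DataFrame, labels, cohort_id: str | None = None):
        self.features = features
        self.labels = pd.Series(np.asarray(labels, dtype=int), index=features.index)
        self.cohort_id = cohort_id

    @classmethod
    def from_cohort(
        cls,
        bundle: CohortBundle,
        signature: SignatureDefinition | None = None,
        features: tuple[str, ...] = TRI_AXIS,
        clinical: bool = False,
    ) -> "TriAxisModel":
        table = build_features(bundle, signature, features, clinical)
        return cls(table, bundle.response, cohort_id=bundle.cohort_id)

    def fit(
        self,
        outer: int = 10,
        inner: int = 5,
        penalty_grid=DEFAULT_PENALTY_GRID,
        seed: int = 0,
    ) -> "DiscoveryResults":
        report = nested_cv_fit(self.features, self.labels, outer, inner,
                               penalty_grid, seed)
        locked = lock_model(self.features, self.labels, penalty_grid,
                            cv_report=report, seed=seed)
        return DiscoveryResults(model=self, cv_report=report, locked=locked)


@dataclass
class DiscoveryResults:
    """Fit results: out-of-fold report plus the locked final model."""

    model: TriAxisModel
    cv_report: CVReport
    locked: LockedModel

    @property
    def metrics(self) -> dict:
        return self.cv_report.metrics

    def summary(self) -> str:
        m = self.metrics
        lo, hi = m["auc_ci"]
        lines = [
            "Tri-axis discovery model (L1 logistic, nested CV "
            f"{self.cv_report.outer_folds}x{self.cv_report.inner_folds})",
            "=" * 64,
            f"{'feature':<18}{'coef (raw scale)':>18}",
            "-" * 64,
        ]
        for name, b in zip(self.locked.feature_names, self.locked.coefficients):
            lines.append(f"{name:<18}{b:>18.4f}")
        lines += [
            f"{'intercept':<18}{self.locked.intercept:>18.4f}",
            "-" * 64,
            f"penalty C = {self.locked.penalty:g}   "
            f"locked threshold = {self.locked.threshold:.3f}",
            f"OOF ROC-AUC = {m['auc']:.3f} (95% CI {lo:.3f}-{hi:.3f})   "
            f"PR-AUC = {m['pr_auc']:.3f}",
            f"Brier = {m['brier']:.3f}   calibration slope = "
            f"{m['calibration_slope']:.3f}, intercept = "
            f"{m['calibration_intercept']:.3f}",
        ]
        return "\n".join(lines)
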