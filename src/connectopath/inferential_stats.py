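"""Univariate inference and classifier accuracy statistics.

Group comparisons use the pooled-variance (Student) two-sample t test so
that df = n_A + n_B - 2. Covariate-adjusted comparisons and regressions are
ordinary least squares. Multiple testing is controlled with the
Benjamini-Hochberg step-up procedure at a configurable family size.
Classifier accuracy is benchmarked against the no-information rate with an
exact one-sided binomial test and summarized with a Clopper-Pearson CI.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .connectome_io import ValidationError


@dataclass
class StatResult:
    """One univariate test: estimate, t statistic, df, p and (optional) q."""

    name: str
    estimate: float
    test_stat: float
    df: int
    p: float
    q: float = field(default=np.nan)

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "estimate": self.estimate,
            "test_stat": self.test_stat,
            "df": self.df,
            "p": self.p,
            "q": self.q,
        }


@dataclass
class AccuracyStats:
    """Cross-validated classification summary in the layout of an accuracy table."""

    n_correct: int
    n_total: int
    accuracy_pct: float
    ci95_pct: tuple[float, float]
    nir_pct: float
    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    p_vs_nir: float

    def to_dict(self) -> dict:
        return {
            "n_correct": self.n_correct,
            "n_total": self.n_total,
            "accuracy_pct": self.accuracy_pct,
            "ci95_pct": list(self.ci95_pct),
            "nir_pct": self.nir_pct,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "ppv": self.ppv,
            "npv": self.npv,
            "p_vs_nir": self.p_vs_nir,
        }


# ---------------------------------------------------------------------------
# Group comparisons and associations
# ---------------------------------------------------------------------------


def two_sample_t(x: Sequence[float], y: Sequence[float], name: str = "") -> StatResult:
    """Pooled-variance two-sample t test (two-sided)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValidationError("each group needs at least 2 observations")
    diff = float(np.mean(x) - np.mean(y))
    if np.var(x, ddof=1) == 0 and np.var(y, ddof=1) == 0:
        # degenerate features (e.g. a metric constant in both groups)
        t, p = (0.0, 1.0) if diff == 0 else (np.sign(diff) * np.inf, 0.0)
        return StatResult(
            name=name, estimate=diff, test_stat=t, df=len(x) + len(y) - 2, p=p
        )
    t, p = stats.ttest_ind(x, y, equal_var=True)
    return StatResult(
        name=name,
        estimate=float(np.mean(x) - np.mean(y)),
        test_stat=float(t),
        df=len(x) + len(y) - 2,
        p=float(p),
    )


def _design_matrix(covariates: Optional[pd.DataFrame]) -> Optional[pd.DataFrame]:
    """Numeric design columns; categoricals/booleans are treatment-coded."""
    if covariates is None or covariates.shape[1] == 0:
        return None
    out = {}
    for col in covariates.columns:
        s = covariates[col]
        if s.dtype == bool:
            out[col] = s.astype(float)
        elif s.dtype == object or isinstance(s.dtype, pd.CategoricalDtype):
            dummies = pd.get_dummies(s, prefix=col, drop_first=True, dtype=float)
            for c in dummies.columns:
                out[c] = dummies[c]
        else:
            out[col] = s.astype(float)
    return pd.DataFrame(out, index=covariates.index)


def ancova_group_effect(
    outcome: Sequence[float],
    group: Sequence[str],
    covariates: Optional[pd.DataFrame] = None,
    name: str = "",
) -> StatResult:
    """OLS of outcome ~ group (+ covariates); returns the group coefficient.

    The group factor is coded 1 for the first label encountered, 0 for the
    other, so with no covariates the estimate equals the two-sample mean
    difference and the test reduces to the pooled t test.
    """
    y = np.asarray(outcome, dtype=float)
    group = list(group)
    labels = sorted(set(group))
    if len(labels) != 2:
        raise ValidationError("group must have exactly two levels")
    g = np.asarray([1.0 if v == labels[0] else 0.0 for v in group])
    X = pd.DataFrame({"group": g})
    cov = _design_matrix(covariates)
    if cov is not None:
        X = pd.concat([X, cov.reset_index(drop=True)], axis=1)
    X = sm.add_constant(X, has_constant="add")
    if len(y) <= X.shape[1]:
        raise ValidationError("not enough observations for the design")
    fit = sm.OLS(y, X.to_numpy(dtype=float)).fit()
    if fit.df_resid < 1 or np.linalg.matrix_rank(X.to_numpy(dtype=float)) < X.shape[1]:
        raise ValidationError("rank-deficient design")
    idx = list(X.columns).index("group")
    return StatResult(
        name=name,
        estimate=float(fit.params[idx]),
        test_stat=float(fit.tvalues[idx]),
        df=int(fit.df_resid),
        p=float(fit.pvalues[idx]),
    )


def linear_regression(
    y: Sequence[float],
    x: Sequence[float],
    covariates: Optional[pd.DataFrame] = None,
    name: str = "",
) -> StatResult:
    """OLS slope of y on x (plus optional covariates), two-sided p."""
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    if np.ptp(x) == 0:
        raise ValidationError("predictor x is constant")
    X = pd.DataFrame({"x": x})
    cov = _design_matrix(covariates)
    if cov is not None:
        X = pd.concat([X, cov.reset_index(drop=True)], axis=1)
    X = sm.add_constant(X, has_constant="add")
    if len(y) < X.shape[1] + 1:
        raise ValidationError("not enough observations for the design")
    fit = sm.OLS(y, X.to_numpy(dtype=float)).fit()
    idx = list(X.columns).index("x")
    return StatResult(
        name=name,
        estimate=float(fit.params[idx]),
        test_stat=float(fit.tvalues[idx]),
        df=int(fit.df_resid),
        p=float(fit.pvalues[idx]),
    )


def pearson_correlation(
    x: Sequence[float], y: Sequence[float], name: str = "", method: str = "pearson"
) -> StatResult:
    """Correlation with t = r sqrt((n-2)/(1-r^2)); Spearman optional."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n < 3:
        raise ValidationError("correlation requires n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValidationError("zero variance input")
    if method == "pearson":
        r, p = stats.pearsonr(x, y)
    elif method == "spearman":
        r, p = stats.spearmanr(x, y)
    else:
        raise ValidationError(f"unknown correlation method: {method!r}")
    r = float(r)
    with np.errstate(divide="ignore"):
        t = r * np.sqrt((n - 2) / max(1.0 - r * r, np.finfo(float).tiny))
    return StatResult(name=name, estimate=r, test_stat=float(t), df=n - 2, p=float(p))


# ---------------------------------------------------------------------------
# Multiple testing
# ---------------------------------------------------------------------------


def bh_fdr(pvals: Sequence[float], m: Optional[int] = None) -> np.ndarray:
    """Benjamini-Hochberg step-up q values at family size ``m``.

    q_(i) = min_{j >= i} p_(j) * m / j over the sorted p values, capped at 1,
    returned in input order. ``m`` defaults to len(pvals) and may be larger
    (fixed family convention).
    """
    p = np.asarray(pvals, dtype=float)
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValidationError("p values must lie in [0, 1]")
    k = len(p)
    if k == 0:
        return np.array([])
    if m is None:
        m = k
    if m < k:
        raise ValidationError("family size m must be >= number of p values")
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, k + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(k)
    q[order] = q_sorted
    return q


# ---------------------------------------------------------------------------
# Classifier accuracy statistics
# ---------------------------------------------------------------------------


def nir(group_counts: Sequence[int]) -> float:
    """No-information rate: percentage of the majority class."""
    counts = np.asarray(group_counts, dtype=float)
    if len(counts) < 2 or np.any(counts < 0):
        raise ValidationError("need >= 2 non-negative group counts")
    total = counts.sum()
    if total <= 0:
        raise ValidationError("all group counts are zero")
    return float(100.0 * counts.max() / total)


def clopper_pearson_ci(
    successes: int, n: int, level: float = 0.95
) -> tuple[float, float]:
    """Exact binomial CI via beta quantiles, returned in percent."""
    if not 0 <= successes <= n or n <= 0:
        raise ValidationError("invalid success/trial counts")
    alpha = 1.0 - level
    lower = 0.0 if successes == 0 else stats.beta.ppf(alpha / 2, successes, n - successes + 1)
    upper = 1.0 if successes == n else stats.beta.ppf(1 - alpha / 2, successes + 1, n - successes)
    return float(100.0 * lower), float(100.0 * upper)


def binomial_test_vs_nir(successes: int, n: int, p0: float) -> float:
    """One-sided exact binomial tail P(X >= successes | n, p0)."""
    if not 0 <= successes <= n or n <= 0:
        raise ValidationError("invalid success/trial counts")
    if not 0 < p0 < 1:
        raise ValidationError("null proportion must lie in (0, 1)")
    return float(stats.binom.sf(successes - 1, n, p0))


def confusion_stats(
    predicted: Sequence, actual: Sequence, positive
) -> AccuracyStats:
    """Accuracy, CI, NIR, sensitivity/specificity/PPV/NPV from a 2x2 table."""
    predicted = list(predicted)
    actual = list(actual)
    if len(predicted) != len(actual):
        raise ValidationError("predicted/actual length mismatch")
    classes = set(actual) | set(predicted)
    if len(classes) > 2:
        raise ValidationError("confusion_stats supports exactly two classes")
    tp = sum(1 for p, a in zip(predicted, actual) if p == positive and a == positive)
    fn = sum(1 for p, a in zip(predicted, actual) if p != positive and a == positive)
    tn = sum(1 for p, a in zip(predicted, actual) if p != positive and a != positive)
    fp = sum(1 for p, a in zip(predicted, actual) if p == positive and a != positive)
    n = tp + fn + tn + fp
    n_correct = tp + tn
    pos_total = tp + fn
    neg_total = tn + fp
    nir_pct = nir([pos_total, neg_total])
    return AccuracyStats(
        n_correct=n_correct,
        n_total=n,
        accuracy_pct=100.0 * n_correct / n,
        ci95_pct=clopper_pearson_ci(n_correct, n),
        nir_pct=nir_pct,
        sensitivity=tp / pos_total if pos_total else np.nan,
        specificity=tn / neg_total if neg_total else np.nan,
        ppv=tp / (tp + fp) if (tp + fp) else np.nan,
        npv=tn / (tn + fn) if (tn + fn) else np.nan,
        p_vs_nir=binomial_test_vs_nir(n_correct, n, nir_pct / 100.0),
    )


# ---------------------------------------------------------------------------
# Treatment-response bookkeeping
# ---------------------------------------------------------------------------


def percent_change(w0: float, w6: float) -> float:
    """100 * (w6 - w0) / w0; negative values mean improvement."""
    if w0 <= 0:
        raise ValidationError("baseline score must be positive for percent change")
    return float(100.0 * (w6 - w0) / w0)


def responder_flag(pct_change: float) -> bool:
    """True iff symptoms dropped strictly more than 25% (pct_change < -25)."""
    if not np.isfinite(pct_change):
        raise ValidationError("percent change must be finite")
    return pct_change < -25.0
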