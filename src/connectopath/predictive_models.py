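"""Multivariate models over the 82 local-efficiency AUC features.

Linear soft-margin SVMs (classification) and linear epsilon-insensitive
SVRs (regression) are evaluated with leave-one-out cross-validation.
Feature standardization and model fitting happen strictly inside each
training fold. The cost parameter C is tuned on the same LOOCV loop
(single-loop procedure); significance comes from label permutation, and
variable importance from per-feature ROC AUC (classification) or a loess
r^2 against the intercept-only model (regression).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from sklearn.svm import SVC, SVR

from .connectome_io import CohortTable, ParcellationAtlas, ValidationError
from .inferential_stats import (
    AccuracyStats,
    confusion_stats,
    pearson_correlation,
    percent_change,
)
from .network_metrics import GraphMetricsResult

#: default cost grid: powers of two plus the two literature pin values
DEFAULT_C_GRID: tuple[float, ...] = tuple(
    sorted([2.0**k for k in range(-10, 6)] + [0.218, 10.9])
)

#: reduced grid for permutation loops and scaled CI runs
SMALL_C_GRID: tuple[float, ...] = (0.01, 0.1, 1.0, 10.0)

SVM_TOL = 1e-6
POSITIVE_CLASS = "ADHD"


@dataclass
class FeatureTable:
    """Subjects x features matrix plus an outcome vector."""

    subject_ids: tuple[str, ...]
    feature_names: tuple[str, ...]
    values: np.ndarray
    outcome: np.ndarray
    task: str  # "classification" | "regression"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.subject_ids), len(self.feature_names)):
            raise ValidationError("feature matrix shape mismatch")
        if np.any(~np.isfinite(self.values)):
            raise ValidationError("missing values in feature matrix")
        if len(self.outcome) != len(self.subject_ids):
            raise ValidationError("outcome length mismatch")
        if self.task not in ("classification", "regression"):
            raise ValidationError(f"unknown task: {self.task!r}")

    @property
    def n(self) -> int:
        return len(self.subject_ids)


@dataclass
class ModelEvaluation:
    """LOOCV evaluation of one tuned model."""

    task: str
    tuned_cost: float
    tuned_sigma: Optional[float]
    loocv_predictions: dict[str, object]
    accuracy_stats: Optional[AccuracyStats]
    obs_pred_r: Optional[float]
    obs_pred_p: Optional[float]
    permutation_p: Optional[float]
    importance: list[dict] = field(default_factory=list)
    tuning_trace: dict[float, float] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "task": self.task,
            "tuned_cost": self.tuned_cost,
            "tuned_sigma": self.tuned_sigma,
            "loocv_predictions": self.loocv_predictions,
            "accuracy_stats": self.accuracy_stats.to_dict() if self.accuracy_stats else None,
            "obs_pred_r": self.obs_pred_r,
            "obs_pred_p": self.obs_pred_p,
            "permutation_p": self.permutation_p,
            "importance": self.importance,
            "tuning_trace": {str(k): v for k, v in self.tuning_trace.items()},
        }


# ---------------------------------------------------------------------------
# Feature assembly
# ---------------------------------------------------------------------------

_GENDER_CODE = {"male": 1.0, "m": 1.0, "female": 0.0, "f": 0.0}


def _code_gender(g: str) -> float:
    try:
        return _GENDER_CODE[str(g).strip().lower()]
    except KeyError:
        raise ValidationError(f"cannot code gender value {g!r}") from None


def assemble_features(
    metrics: dict[str, GraphMetricsResult],
    cohort: CohortTable,
    task: str = "diagnosis",
    include_covariates: bool = False,
) -> FeatureTable:
    """Build the subjects x features table for one modelling task.

    ``task`` selects subjects and outcome:

    * ``diagnosis`` — all subjects, class label ADHD/TDC;
    * ``response`` — ADHD subjects with week-6 scores, outcome = signed
      percent change of the total symptom score;
    * ``severity`` — ADHD subjects, outcome = baseline total score.

    Covariates, when flagged, are age + gender for TDC-containing tasks
    (dose and medication-history variables do not exist for controls) and
    the full six-covariate set for ADHD-only tasks.
    """
    if task == "diagnosis":
        subjects = list(cohort.subjects)
    elif task == "response":
        subjects = cohort.treatment_subjects()
    elif task == "severity":
        subjects = cohort.group("ADHD")
    else:
        raise ValidationError(f"unknown task: {task!r}")
    if not subjects:
        raise ValidationError(f"no eligible subjects for task {task!r}")

    first = next(iter(metrics.values()))
    regions = first.regions
    feat_names = [f"leff_{r}_auc" for r in regions]
    rows, outcome, ids = [], [], []
    for s in subjects:
        if s.subject_id not in metrics:
            raise ValidationError(f"missing graph metrics for subject {s.subject_id}")
        res = metrics[s.subject_id]
        row = [res.local_efficiency[r].auc for r in regions]
        if include_covariates:
            row.extend(_covariate_row(s, task))
        rows.append(row)
        ids.append(s.subject_id)
        if task == "diagnosis":
            outcome.append(s.group)
        elif task == "response":
            outcome.append(percent_change(s.adhdrs_total_w0, s.adhdrs_total_w6))
        else:
            outcome.append(float(s.adhdrs_total_w0))
    if include_covariates:
        feat_names = feat_names + _covariate_names(task)
    return FeatureTable(
        subject_ids=tuple(ids),
        feature_names=tuple(feat_names),
        values=np.asarray(rows, dtype=float),
        outcome=np.asarray(outcome),
        task="classification" if task == "diagnosis" else "regression",
    )


_SUBTYPE_CODE = {"inattentive": 0.0, "hyperactive": 1.0, "combined": 2.0}


def _covariate_names(task: str) -> list[str]:
    if task == "diagnosis":
        return ["age", "gender"]
    return [
        "age",
        "gender",
        "mph_dose_mg_per_kg",
        "adhd_subtype",
        "prior_stimulant_6mo",
        "prior_stimulant_duration",
    ]


def _covariate_row(s, task: str) -> list[float]:
    base = [float(s.age), _code_gender(s.gender)]
    if task == "diagnosis":
        return base
    for name in (
        "mph_dose_mg_per_kg",
        "adhd_subtype",
        "prior_stimulant_6mo",
        "prior_stimulant_duration",
    ):
        v = getattr(s, name)
        if v is None:
            raise ValidationError(
                f"covariate {name} undefined for subject {s.subject_id}"
            )
        if name == "adhd_subtype":
            if v not in _SUBTYPE_CODE:
                raise ValidationError(f"unknown subtype {v!r}")
            base.append(_SUBTYPE_CODE[v])
        else:
            base.append(float(v))
    return base


# ---------------------------------------------------------------------------
# SVM training and LOOCV
# ---------------------------------------------------------------------------


def train_linear_svm(
    X: np.ndarray,
    y: np.ndarray,
    C: float,
    task: str,
    epsilon: float = 0.1,
    sigma: Optional[float] = None,
):
    """Fit a linear SVM/SVR; non-linear kernels are intentionally unsupported."""
    if sigma is not None:
        raise NotImplementedError(
            "non-linear (RBF/sigma) kernels are not implemented; all models are linear"
        )
    if C <= 0:
        raise ValidationError("C must be positive")
    if task == "classification":
        if len(set(map(str, y))) < 2:
            raise ValidationError("training set has a single class")
        model = SVC(kernel="linear", C=C, tol=SVM_TOL)
    elif task == "regression":
        if len(y) < 3:
            raise ValidationError("regression requires at least 3 subjects")
        model = SVR(kernel="linear", C=C, epsilon=epsilon, tol=SVM_TOL)
    else:
        raise ValidationError(f"unknown task: {task!r}")
    model.fit(X, y)
    return model


def _fold_standardize(Xtr: np.ndarray, Xte: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mu = Xtr.mean(axis=0)
    sd = Xtr.std(axis=0)
    sd = np.where(sd == 0, 1.0, sd)
    return (Xtr - mu) / sd, (Xte - mu) / sd


def _loocv_predictions(X: np.ndarray, y: np.ndarray, C: float, task: str) -> np.ndarray:
    n = X.shape[0]
    preds = np.empty(n, dtype=object if task == "classification" else float)
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        Ztr, Zte = _fold_standardize(X[mask], X[i : i + 1])
        model = train_linear_svm(Ztr, y[mask], C, task)
        preds[i] = model.predict(Zte)[0]
    return preds


def _score(preds: np.ndarray, y: np.ndarray, task: str, tuning_metric: str) -> float:
    """Higher is better. RMSE-based metrics are negated."""
    if task == "classification":
        if tuning_metric == "rmse":
            # literal RMSE mimic: labels coded 1 (positive) / 0
            yc = (y == POSITIVE_CLASS).astype(float)
            pc = (preds == POSITIVE_CLASS).astype(float)
            return -float(np.sqrt(np.mean((yc - pc) ** 2)))
        return float(np.mean(preds == y))
    rmse = float(np.sqrt(np.mean((preds.astype(float) - y.astype(float)) ** 2)))
    return -rmse


def _tune_and_predict(
    X: np.ndarray,
    y: np.ndarray,
    task: str,
    C_grid: Sequence[float],
    tuning_metric: str,
) -> tuple[float, np.ndarray, dict[float, float]]:
    """Single-loop tuning: pick C maximizing the LOOCV score, return its preds."""
    best = None
    trace: dict[float, float] = {}
    for C in sorted(C_grid):
        preds = _loocv_predictions(X, y, C, task)
        score = _score(preds, y, task, tuning_metric)
        trace[float(C)] = score
        if best is None or score > best[0]:
            best = (score, float(C), preds)
    return best[1], best[2], trace


def loocv_evaluate(
    table: FeatureTable,
    C_grid: Sequence[float] = DEFAULT_C_GRID,
    tuning_metric: str = "auto",
    permutations: int = 0,
    seed: int = 0,
    permutation_C_grid: Optional[Sequence[float]] = None,
) -> ModelEvaluation:
    """Tune C and evaluate with LOOCV; optionally add a permutation p."""
    if table.n < 5:
        raise ValidationError("LOOCV evaluation requires n >= 5")
    task = table.task
    if tuning_metric == "auto":
        tuning_metric = "accuracy" if task == "classification" else "rmse"
    X, y = table.values, table.outcome
    C, preds, trace = _tune_and_predict(X, y, task, C_grid, tuning_metric)

    acc_stats = None
    r = p = None
    if task == "classification":
        acc_stats = confusion_stats(list(preds), list(y), POSITIVE_CLASS)
        observed_stat = acc_stats.n_correct / acc_stats.n_total
        importance = importance_classification(table)
    else:
        res = pearson_correlation(y.astype(float), preds.astype(float))
        r, p = res.estimate, res.p
        observed_stat = r
        importance = importance_regression(table)

    perm_p = None
    if permutations > 0:
        perm_grid = permutation_C_grid if permutation_C_grid is not None else C_grid
        # when the permutation loop uses a reduced grid, recompute the observed
        # statistic on that same grid so the comparison is like-with-like
        same_grid = tuple(sorted(perm_grid)) == tuple(sorted(C_grid))
        perm_p = permutation_test(
            table,
            C_grid=perm_grid,
            B=permutations,
            seed=seed,
            tuning_metric=tuning_metric,
            observed_stat=observed_stat if same_grid else None,
        )
    return ModelEvaluation(
        task=task,
        tuned_cost=C,
        tuned_sigma=None,
        loocv_predictions={
            sid: (pred if task == "classification" else float(pred))
            for sid, pred in zip(table.subject_ids, preds)
        },
        accuracy_stats=acc_stats,
        obs_pred_r=r,
        obs_pred_p=p,
        permutation_p=perm_p,
        importance=importance,
        tuning_trace=trace,
    )


def _pipeline_statistic(
    X: np.ndarray,
    y: np.ndarray,
    task: str,
    C_grid: Sequence[float],
    tuning_metric: str,
) -> float:
    _, preds, _ = _tune_and_predict(X, y, task, C_grid, tuning_metric)
    if task == "classification":
        return float(np.mean(preds == y))
    p = preds.astype(float)
    if np.std(p) == 0 or np.std(y.astype(float)) == 0:
        return 0.0
    return float(np.corrcoef(y.astype(float), p)[0, 1])


def permutation_test(
    table: FeatureTable,
    C_grid: Sequence[float] = DEFAULT_C_GRID,
    B: int = 1000,
    seed: int = 0,
    tuning_metric: str = "auto",
    observed_stat: Optional[float] = None,
) -> float:
    """Permutation p for the full tuning+LOOCV pipeline.

    p = (1 + #{permuted statistic >= observed}) / (B + 1); the statistic is
    LOOCV accuracy (classification) or the observed-vs-predicted r
    (regression). The permutation stream depends only on ``seed``.
    """
    if B < 1:
        raise ValidationError("B must be >= 1")
    task = table.task
    if tuning_metric == "auto":
        tuning_metric = "accuracy" if task == "classification" else "rmse"
    X, y = table.values, table.outcome
    if observed_stat is None:
        observed_stat = _pipeline_statistic(X, y, task, C_grid, tuning_metric)
    rng = np.random.default_rng(seed)
    n_ge = 0
    for _ in range(B):
        perm = rng.permutation(len(y))
        stat = _pipeline_statistic(X, y[perm], task, C_grid, tuning_metric)
        if stat >= observed_stat - 1e-12:
            n_ge += 1
    return (1 + n_ge) / (B + 1)


# ---------------------------------------------------------------------------
# Variable importance
# ---------------------------------------------------------------------------


def _rank_auc(scores: np.ndarray, positives: np.ndarray) -> float:
    """ROC AUC of a score against a binary label via the Mann-Whitney identity."""
    pos = scores[positives]
    neg = scores[~positives]
    if len(pos) == 0 or len(neg) == 0:
        raise ValidationError("ROC AUC needs both classes")
    order = np.argsort(scores, kind="stable")
    ranks = np.empty(len(scores))
    ranks[order] = np.arange(1, len(scores) + 1)
    # midranks for ties
    sorted_scores = scores[order]
    i = 0
    while i < len(scores):
        j = i
        while j + 1 < len(scores) and sorted_scores[j + 1] == sorted_scores[i]:
            j += 1
        if j > i:
            ranks[order[i : j + 1]] = (i + 1 + j + 1) / 2.0
        i = j + 1
    u = ranks[positives].sum() - len(pos) * (len(pos) + 1) / 2.0
    return float(u / (len(pos) * len(neg)))


def importance_classification(table: FeatureTable) -> list[dict]:
    """Per-feature ROC AUC importance, folded to max(AUC, 1-AUC) + direction."""
    if table.task != "classification":
        raise ValidationError("classification importance needs class labels")
    positives = table.outcome == POSITIVE_CLASS
    if positives.all() or not positives.any():
        raise ValidationError("importance needs both classes present")
    entries = []
    for j, name in enumerate(table.feature_names):
        auc = _rank_auc(table.values[:, j], positives)
        entries.append(
            {
                "feature": name,
                "score": max(auc, 1.0 - auc),
                "direction": (
                    f"{POSITIVE_CLASS}_higher" if auc >= 0.5 else f"{POSITIVE_CLASS}_lower"
                ),
            }
        )
    entries.sort(key=lambda e: (-e["score"], e["feature"]))
    return entries


def loess_fit(
    x: np.ndarray, y: np.ndarray, span: float = 0.75, degree: int = 2
) -> np.ndarray:
    """Fitted values of a tricube-weighted local polynomial smoother."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n < 3:
        raise ValidationError("loess requires n >= 3")
    q = max(degree + 1, int(math.ceil(span * n)))
    fitted = np.empty(n)
    for i in range(n):
        d = np.abs(x - x[i])
        idx = np.argsort(d, kind="stable")[:q]
        h = d[idx].max()
        if h == 0:
            fitted[i] = y[idx].mean()
            continue
        w = (1 - (d[idx] / h) ** 3) ** 3
        w = np.clip(w, 0, None)
        active = w > 1e-12
        deg = min(degree, len(np.unique(x[idx][active])) - 1)
        if deg < 1 or active.sum() <= deg:
            tot = w.sum()
            fitted[i] = float(np.average(y[idx], weights=w)) if tot > 0 else y[idx].mean()
            continue
        try:
            coeffs = np.polyfit(x[idx], y[idx], deg, w=np.sqrt(w))
            fitted[i] = np.polyval(coeffs, x[i])
        except np.linalg.LinAlgError:  # ill-conditioned local design
            fitted[i] = float(np.average(y[idx], weights=w))
    return fitted


def importance_regression(
    table: FeatureTable, span: float = 0.75, degree: int = 2
) -> list[dict]:
    """Loess r^2 vs the intercept-only model, per feature, sorted descending."""
    if table.task != "regression":
        raise ValidationError("regression importance needs a numeric outcome")
    y = table.outcome.astype(float)
    tss = float(np.sum((y - y.mean()) ** 2))
    entries = []
    for j, name in enumerate(table.feature_names):
        x = table.values[:, j]
        if np.ptp(x) == 0 or tss == 0:
            entries.append({"feature": name, "score": 0.0, "direction": "flat", "flagged": True})
            continue
        fitted = loess_fit(x, y, span=span, degree=degree)
        rss = float(np.sum((y - fitted) ** 2))
        score = max(0.0, 1.0 - rss / tss)
        slope = np.polyfit(x, y, 1)[0]
        entries.append(
            {
                "feature": name,
                "score": score,
                "direction": "outcome_increases" if slope >= 0 else "outcome_decreases",
            }
        )
    entries.sort(key=lambda e: (-e["score"], e["feature"]))
    return entries


def summarize_top_regions(
    importance: list[dict], atlas: ParcellationAtlas, k: int = 10
) -> dict:
    """Top-k features with region metadata and a network census."""
    if k <= 0:
        raise ValidationError("k must be positive")
    region_entries = [e for e in importance if e["feature"].startswith("leff_")]
    if k > len(importance):
        raise ValidationError(f"k={k} exceeds number of features ({len(importance)})")
    top = []
    census: dict[str, int] = {}
    for e in region_entries[:k]:
        region = e["feature"][len("leff_") : -len("_auc")]
        net = atlas.network_of(region)
        census[net] = census.get(net, 0) + 1
        top.append(
            {
                "feature": e["feature"],
                "region": region,
                "hemisphere": atlas.hemisphere_of(region),
                "network": net,
                "score": e["score"],
                "direction": e["direction"],
            }
        )
    n_top = len(top)
    return {
        "top_regions": top,
        "network_census": census,
        "fraction_subcortical": census.get("subcortical", 0) / n_top if n_top else 0.0,
    }
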