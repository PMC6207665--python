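"""Leave-one-out evaluation, staging dichotomies, ROC and model comparison.

Staging performance is reported on the four standard Metavir dichotomies —
F0 vs F1-4 (any fibrosis), F0-1 vs F2-4 (significant), F0-2 vs F3-4
(advanced), F0-3 vs F4 (cirrhosis).  Each sample is scored by a model
trained on all remaining samples (leave-one-out, standardization refit per
fold); the pooled out-of-fold scores give one ROC curve per model and
dichotomy.  The continuous score for cutpoint k is the summed class score
over stages >= k.  AUROC uses the rank (Mann-Whitney) convention so ties
contribute 1/2.

Model comparison follows the usual nonparametric recipe: a Kruskal-Wallis
test across the per-model performance samples, then all pairwise
Wilcoxon-Mann-Whitney tests with a Bonferroni-adjusted critical p-value
(0.05 / number of pairs; 0.005 for five models).  The performance samples
default to seeded bootstrap-resampled AUROCs (B = 200).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score, roc_curve

from .models import ClassifierSpec, ScoreMatrix, predict_scores, train

__all__ = [
    "Dichotomy",
    "DICHOTOMIES",
    "ROCResult",
    "ConfusionMetrics",
    "ComparisonResult",
    "loo_cv",
    "loo_scores",
    "dichotomize",
    "score_for",
    "auroc",
    "roc_points",
    "confusion_metrics",
    "bootstrap_auroc_samples",
    "compare_models",
    "evaluation_report",
]


@dataclass(frozen=True)
class Dichotomy:
    """Binarization of the ordinal stages: positive iff stage >= cutpoint."""

    cutpoint: int

    def __post_init__(self) -> None:
        if self.cutpoint not in (1, 2, 3, 4):
            raise ValueError("cutpoint must be in {1, 2, 3, 4}")

    @property
    def name(self) -> str:
        k = self.cutpoint
        neg = "F0" if k == 1 else f"F0-{k - 1}"
        pos = "F4" if k == 4 else f"F{k}-4"
        return f"{neg} vs {pos}"


DICHOTOMIES = tuple(Dichotomy(k) for k in (1, 2, 3, 4))


def dichotomize(labels: np.ndarray, d: Dichotomy) -> np.ndarray:
    labels = np.asarray(labels)
    if labels.min() < 0 or labels.max() > 4:
        raise ValueError("stage labels must be in 0..4")
    return (labels >= d.cutpoint).astype(int)


def score_for(scores: ScoreMatrix | np.ndarray, d: Dichotomy) -> np.ndarray:
    """Continuous positive-class score: summed class scores over stages >=
    cutpoint (for a probabilistic row with k=1 this is 1 - P(F0))."""
    s = scores.scores if isinstance(scores, ScoreMatrix) else np.asarray(scores)
    return s[:, d.cutpoint:].sum(axis=1)


# ---------------------------------------------------------------------------
# Cross-validation
# ---------------------------------------------------------------------------


def loo_cv(X: np.ndarray, y: np.ndarray, fit_score) -> np.ndarray:
    """Generic leave-one-out: ``fit_score(X_train, y_train, x_test)`` must
    return the held-out sample's score row.  Returns the pooled (n, k)
    matrix, one row per sample in input order."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    n = len(y)
    if n < 2:
        raise ValueError("leave-one-out needs n >= 2")
    rows = []
    classes = np.unique(y)
    for i in range(n):
        tr = np.ones(n, dtype=bool)
        tr[i] = False
        if len(np.unique(y[tr])) < len(classes):
            warnings.warn(f"fold {i}: training split is missing a class")
        rows.append(fit_score(X[tr], y[tr], X[i]))
    return np.vstack(rows)


def loo_scores(X: np.ndarray, y: np.ndarray, spec: ClassifierSpec,
               ) -> ScoreMatrix:
    """Pooled leave-one-out score matrix for one classifier family.

    Each fold retrains from scratch (including standardization statistics)
    on the remaining n-1 samples.
    """
    def fit_score(Xtr, ytr, xte):
        model = train(Xtr, ytr, spec)
        return predict_scores(model, xte[None, :]).scores[0]

    with warnings.catch_warnings():
        # per-fold MLR convergence warnings would repeat n times
        warnings.simplefilter("ignore")
        pooled = loo_cv(X, y, fit_score)
    return ScoreMatrix(scores=pooled, is_probabilistic=True)


# ---------------------------------------------------------------------------
# ROC / confusion metrics
# ---------------------------------------------------------------------------


@dataclass
class ROCResult:
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auroc: float


def auroc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Area under the empirical ROC (Mann-Whitney/midrank convention)."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("AUROC needs both classes present")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


def roc_points(scores: np.ndarray, labels: np.ndarray) -> ROCResult:
    fpr, tpr, thr = roc_curve(np.asarray(labels),
                              np.asarray(scores, dtype=float))
    return ROCResult(fpr=fpr, tpr=tpr, thresholds=thr,
                     auroc=auroc(scores, labels))


@dataclass
class ConfusionMetrics:
    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    undefined: tuple[str, ...] = ()  # metrics that hit the 0/0 convention

    def as_dict(self) -> dict[str, float]:
        return {"sensitivity": self.sensitivity,
                "specificity": self.specificity,
                "ppv": self.ppv, "npv": self.npv}


def _safe_div(num: int, den: int, name: str, flags: list[str]) -> float:
    if den == 0:
        flags.append(name)
        return 0.0
    return num / den


def confusion_metrics(predicted: np.ndarray, truth: np.ndarray,
                      d: Dichotomy) -> ConfusionMetrics:
    """Sensitivity/specificity/PPV/NPV at the argmax-label operating point.

    ``predicted`` and ``truth`` are stage labels (0..4); both are
    dichotomized at the cutpoint.  0/0 gives 0 and the metric name is
    recorded in ``undefined``.
    """
    p = dichotomize(predicted, d)
    t = dichotomize(truth, d)
    tp = int(np.sum((p == 1) & (t == 1)))
    fn = int(np.sum((p == 0) & (t == 1)))
    fp = int(np.sum((p == 1) & (t == 0)))
    tn = int(np.sum((p == 0) & (t == 0)))
    flags: list[str] = []
    return ConfusionMetrics(
        sensitivity=_safe_div(tp, tp + fn, "sensitivity", flags),
        specificity=_safe_div(tn, tn + fp, "specificity", flags),
        ppv=_safe_div(tp, tp + fp, "ppv", flags),
        npv=_safe_div(tn, tn + fn, "npv", flags),
        undefined=tuple(flags),
    )


# ---------------------------------------------------------------------------
# Model comparison (KW + pairwise WMW, Bonferroni)
# ---------------------------------------------------------------------------


def bootstrap_auroc_samples(scores: ScoreMatrix | np.ndarray,
                            labels: np.ndarray, d: Dichotomy,
                            n_boot: int = 200, seed: int = 0) -> np.ndarray:
    """Bootstrap-resampled AUROCs of pooled out-of-fold scores — the
    per-model performance sample fed to the KW/WMW comparison."""
    s = score_for(scores, d)
    t = dichotomize(np.asarray(labels), d)
    rng = np.random.default_rng(seed)
    n = len(t)
    out = np.empty(n_boot)
    for b in range(n_boot):
        while True:
            idx = rng.integers(0, n, n)
            if len(np.unique(t[idx])) == 2:
                break
        out[b] = auroc(s[idx], t[idx])
    return out


@dataclass
class ComparisonResult:
    kw_statistic: float
    kw_p: float
    pairwise_p: dict[tuple[str, str], float]
    critical_p: float
    significant: dict[tuple[str, str], bool] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.significant:
            self.significant = {k: p < self.critical_p
                                for k, p in self.pairwise_p.items()}


def compare_models(samples: dict[str, np.ndarray]) -> ComparisonResult:
    """Kruskal-Wallis across models, then all pairwise two-sided
    Wilcoxon-Mann-Whitney tests at the Bonferroni-adjusted critical
    p-value 0.05 / C(m, 2) (0.005 for 5 models)."""
    names = list(samples)
    if len(names) < 2:
        raise ValueError("need at least two models to compare")
    lengths = {len(v) for v in samples.values()}
    if len(lengths) > 1:
        raise ValueError("performance samples must have equal length "
                         f"(got {sorted(lengths)})")
    arrays = [np.asarray(samples[n], dtype=float) for n in names]
    if all(np.allclose(a, arrays[0]) for a in arrays):
        kw_stat, kw_p = 0.0, 1.0  # identical samples: no evidence at all
    else:
        kw_stat, kw_p = stats.kruskal(*arrays)
    pairs = list(itertools.combinations(names, 2))
    critical = 0.05 / len(pairs)
    pairwise = {}
    for a, b in pairs:
        xa, xb = np.asarray(samples[a]), np.asarray(samples[b])
        if np.allclose(xa, xa[0]) and np.allclose(xb, xb[0]) \
                and np.isclose(xa[0], xb[0]):
            pairwise[(a, b)] = 1.0
            continue
        pairwise[(a, b)] = float(stats.mannwhitneyu(
            xa, xb, alternative="two-sided").pvalue)
    return ComparisonResult(kw_statistic=float(kw_stat), kw_p=float(kw_p),
                            pairwise_p=pairwise, critical_p=critical)


# ---------------------------------------------------------------------------
# Report assembly
# ---------------------------------------------------------------------------


FEATURE_SETS = {"morph": slice(0, 21), "texture": slice(21, 130),
                "all": slice(0, 130)}


def evaluation_report(features: np.ndarray, labels: np.ndarray,
                      specs: dict[str, ClassifierSpec],
                      feature_sets: tuple[str, ...] = ("morph",),
                      n_boot: int = 200, seed: int = 0,
                      ) -> tuple[pd.DataFrame, dict]:
    """Per feature-set x model x dichotomy AUROC + confusion metrics, plus
    the KW/WMW model-comparison block on bootstrap AUROC samples.

    Returns ``(table, comparisons)`` where ``table`` has one row per
    (feature_set, model, dichotomy) and ``comparisons`` maps
    ``(feature_set, dichotomy_name)`` to a :class:`ComparisonResult`.
    """
    features = np.asarray(features, dtype=float)
    labels = np.asarray(labels)
    rows = []
    comparisons: dict[tuple[str, str], ComparisonResult] = {}
    for fset in feature_sets:
        cols = FEATURE_SETS[fset]
        Xf = features[:, cols]
        pooled: dict[str, ScoreMatrix] = {}
        for name, spec in specs.items():
            pooled[name] = loo_scores(Xf, labels, spec)
        for d in DICHOTOMIES:
            samples = {}
            for name, sm in pooled.items():
                cm = confusion_metrics(sm.argmax_labels(np.arange(5)),
                                       labels, d)
                a = auroc(score_for(sm, d), dichotomize(labels, d))
                rows.append({"feature_set": fset, "model": name,
                             "dichotomy": d.name, "auroc": a,
                             **cm.as_dict()})
                samples[name] = bootstrap_auroc_samples(
                    sm, labels, d, n_boot=n_boot, seed=seed)
            if len(specs) >= 2:
                comparisons[(fset, d.name)] = compare_models(samples)
    return pd.DataFrame(rows), comparisons
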