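"""Non-deep classifier families for 5-stage fibrosis scoring.

Four families operate on feature vectors (21 morphological, 109 textural,
or all 130) and emit an n x 5 per-stage score matrix:

* ANN — a small feed-forward network with softmax output, trained by
  full-batch gradient descent on the cross-entropy loss.  Implemented
  in-package (the analytic gradient is exposed for verification against
  finite differences).  The three stock architectures are one hidden layer
  of 10, one of 20, and two of 20 nodes.
* MLR — multinomial logistic regression by maximum likelihood, optionally
  ridge-penalized.  With many features and few samples the unpenalized MLE
  does not exist (quasi-complete separation) and the optimizer fails to
  converge; this is surfaced as a ``converged=False`` flag rather than
  hidden, since it is a diagnostic outcome in its own right.
* SVM — soft-margin RBF-kernel machines, K(x1, x2) = exp(-|x1-x2|^2 /
  (2 sigma^2)), one binary machine per stage (one-vs-rest); decision
  values are squashed through a logistic and L1-normalized per row to give
  comparable per-class scores.
* RF — bagged forest of 100 information-gain (entropy) trees with
  bootstrap resampling and sqrt(p) feature subsampling; per-class score is
  the fraction of trees voting for the class.

Features are standardized with training-set statistics only; every family
is deterministic under a fixed seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.exceptions import ConvergenceWarning
from sklearn.inspection import permutation_importance
from sklearn.linear_model import LogisticRegression
from sklearn.ensemble import RandomForestClassifier
from sklearn.multiclass import OneVsRestClassifier
from sklearn.svm import SVC

__all__ = [
    "ClassifierSpec",
    "TrainedModel",
    "ScoreMatrix",
    "standardize",
    "train",
    "train_ann",
    "train_mlr",
    "train_svm",
    "train_rf",
    "predict_scores",
    "feature_importance",
    "AnnNet",
]

FAMILIES = ("ann", "mlr", "svm", "rf")
ANN_ARCHITECTURES = {"small": (10,), "medium": (20,), "deep": (20, 20)}


@dataclass(frozen=True)
class ClassifierSpec:
    """Family plus hyperparameters; exactly one family per spec."""

    family: str
    # ANN
    hidden_layers: tuple[int, ...] = (20,)
    learning_rate: float = 0.05
    epochs: int = 2000
    # MLR
    ridge_lambda: float = 0.0
    max_iter: int = 500
    # standardized-scale coefficient magnitude beyond which the MLE is
    # treated as drifting to infinity (separation): |beta| = 15 means an
    # odds ratio of e^15 per standard deviation, far outside anything a
    # finite MLE produces on real data
    mlr_coef_cap: float = 15.0
    # SVM
    sigma: float | None = None  # None -> sqrt(p/2), i.e. gamma = 1/p
    C: float = 1.0
    # RF
    n_trees: int = 100
    max_depth: int | None = None
    # shared
    seed: int = 0

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"family must be one of {FAMILIES}, "
                             f"got {self.family!r}")
        if self.ridge_lambda < 0:
            raise ValueError("ridge_lambda must be >= 0")
        if self.sigma is not None and self.sigma <= 0:
            raise ValueError("sigma must be > 0")
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")


@dataclass
class ScoreMatrix:
    """n x n_classes scores; probabilistic rows sum to 1."""

    scores: np.ndarray
    is_probabilistic: bool = True

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.ndim != 2:
            raise ValueError("scores must be 2-D")

    @property
    def n_classes(self) -> int:
        return self.scores.shape[1]

    def argmax_labels(self, classes: np.ndarray | None = None) -> np.ndarray:
        idx = np.argmax(self.scores, axis=1)
        return idx if classes is None else np.asarray(classes)[idx]


@dataclass
class TrainedModel:
    family: str
    spec: ClassifierSpec
    estimator: object  # sklearn estimator or AnnNet
    mean: np.ndarray
    scale: np.ndarray
    classes: np.ndarray
    converged: bool = True

    @property
    def n_features(self) -> int:
        return len(self.mean)

    def transform(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        if X.shape[1] != self.n_features:
            raise ValueError(
                f"model expects {self.n_features} features, "
                f"got {X.shape[1]}")
        return (X - self.mean) / self.scale


def standardize(X_train: np.ndarray, X_other: np.ndarray | None = None):
    """Per-feature (x - mean) / std using training statistics only.

    Constant features get scale 1 so they pass through centered, never NaN.
    Returns ``(Z_train, Z_other, (mean, scale))``; ``Z_other`` is None when
    no second matrix is given.
    """
    X_train = np.asarray(X_train, dtype=float)
    mean = X_train.mean(axis=0)
    scale = X_train.std(axis=0)
    scale = np.where(scale == 0, 1.0, scale)
    Z_train = (X_train - mean) / scale
    Z_other = None
    if X_other is not None:
        Z_other = (np.asarray(X_other, dtype=float) - mean) / scale
    return Z_train, Z_other, (mean, scale)


# ---------------------------------------------------------------------------
# ANN
# ---------------------------------------------------------------------------


class AnnNet:
    """Feed-forward net: tanh hidden layers, softmax output,
    cross-entropy loss, full-batch gradient descent."""

    def __init__(self, layer_sizes: tuple[int, ...], seed: int = 0):
        self.layer_sizes = tuple(int(s) for s in layer_sizes)
        rng = np.random.default_rng(seed)
        self.W = []
        self.b = []
        for n_in, n_out in zip(self.layer_sizes[:-1], self.layer_sizes[1:]):
            # Xavier-style init, seeded
            self.W.append(rng.normal(0.0, np.sqrt(1.0 / n_in),
                                     (n_in, n_out)))
            self.b.append(np.zeros(n_out))

    def forward(self, X: np.ndarray) -> np.ndarray:
        """Class probabilities (softmax output)."""
        a = X
        for W, b in zip(self.W[:-1], self.b[:-1]):
            a = np.tanh(a @ W + b)
        logits = a @ self.W[-1] + self.b[-1]
        logits = logits - logits.max(axis=1, keepdims=True)
        e = np.exp(logits)
        return e / e.sum(axis=1, keepdims=True)

    def loss_and_grads(self, X: np.ndarray, Y: np.ndarray):
        """Mean cross-entropy and its gradients w.r.t. all W and b.

        ``Y`` is one-hot (n, k).  The analytic gradients returned here are
        the ones used by training, so they can be verified against central
        finite differences.
        """
        n = X.shape[0]
        acts = [X]
        a = X
        for W, b in zip(self.W[:-1], self.b[:-1]):
            a = np.tanh(a @ W + b)
            acts.append(a)
        logits = a @ self.W[-1] + self.b[-1]
        logits = logits - logits.max(axis=1, keepdims=True)
        e = np.exp(logits)
        probs = e / e.sum(axis=1, keepdims=True)
        eps = 1e-12
        loss = float(-np.sum(Y * np.log(probs + eps)) / n)
        dlogits = (probs - Y) / n
        gW = [None] * len(self.W)
        gb = [None] * len(self.b)
        delta = dlogits
        for li in range(len(self.W) - 1, -1, -1):
            gW[li] = acts[li].T @ delta
            gb[li] = delta.sum(axis=0)
            if li > 0:
                delta = (delta @ self.W[li].T) * (1.0 - acts[li] ** 2)
        return loss, gW, gb

    def fit(self, X: np.ndarray, Y: np.ndarray, learning_rate: float,
            epochs: int) -> list[float]:
        losses = []
        for epoch in range(epochs):
            loss, gW, gb = self.loss_and_grads(X, Y)
            if not np.isfinite(loss) or \
                    not all(np.all(np.isfinite(W)) for W in self.W):
                raise RuntimeError(
                    f"ANN training diverged (non-finite loss or weights) "
                    f"at epoch {epoch} with learning rate {learning_rate}")
            losses.append(loss)
            for li in range(len(self.W)):
                self.W[li] -= learning_rate * gW[li]
                self.b[li] -= learning_rate * gb[li]
        return losses


def _one_hot(y: np.ndarray, classes: np.ndarray) -> np.ndarray:
    idx = np.searchsorted(classes, y)
    Y = np.zeros((len(y), len(classes)))
    Y[np.arange(len(y)), idx] = 1.0
    return Y


def train_ann(X: np.ndarray, y: np.ndarray,
              spec: ClassifierSpec) -> TrainedModel:
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes = np.unique(y)
    Z, _, (mean, scale) = standardize(X)
    net = AnnNet((X.shape[1], *spec.hidden_layers, len(classes)),
                 seed=spec.seed)
    net.fit(Z, _one_hot(y, classes), spec.learning_rate, spec.epochs)
    return TrainedModel("ann", spec, net, mean, scale, classes)


# ---------------------------------------------------------------------------
# MLR / SVM / RF
# ---------------------------------------------------------------------------


def train_mlr(X: np.ndarray, y: np.ndarray,
              spec: ClassifierSpec) -> TrainedModel:
    """Multinomial logit by maximum likelihood (optional ridge penalty).

    Non-convergence (typical under separation with lambda = 0) is reported
    on the returned model, mirroring the failure mode seen when all 130
    features are fed to an unpenalized MLR on a small sample.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    Z, _, (mean, scale) = standardize(X)
    if spec.ridge_lambda > 0:
        est = LogisticRegression(penalty="l2", C=1.0 / spec.ridge_lambda,
                                 solver="lbfgs", max_iter=spec.max_iter,
                                 tol=1e-10)
    else:
        est = LogisticRegression(penalty=None, solver="lbfgs",
                                 max_iter=spec.max_iter, tol=1e-10)
    converged = True
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always", ConvergenceWarning)
        est.fit(Z, y)
        if any(issubclass(w.category, ConvergenceWarning) for w in caught):
            converged = False
    if np.max(est.n_iter_) >= spec.max_iter:
        converged = False
    if spec.ridge_lambda == 0:
        # an MLE drifting to infinity under separation can still satisfy
        # the gradient tolerance at enormous coefficients
        if np.abs(est.coef_).max() > spec.mlr_coef_cap:
            converged = False
        # with a rank-deficient design (e.g. more features than samples)
        # the unpenalized likelihood has flat directions and no unique
        # maximum: the ML fit cannot be said to have converged
        design = np.column_stack([np.ones(len(Z)), Z])
        if np.linalg.matrix_rank(design) < design.shape[1]:
            converged = False
    if not converged:
        warnings.warn("MLR maximum-likelihood fit did not converge "
                      f"(separation or iteration cap {spec.max_iter}; "
                      "consider ridge_lambda > 0)")
    return TrainedModel("mlr", spec, est, mean, scale, est.classes_,
                        converged=converged)


def train_svm(X: np.ndarray, y: np.ndarray,
              spec: ClassifierSpec) -> TrainedModel:
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    Z, _, (mean, scale) = standardize(X)
    sigma = spec.sigma if spec.sigma is not None else np.sqrt(X.shape[1] / 2)
    gamma = 1.0 / (2.0 * sigma**2)
    est = OneVsRestClassifier(
        SVC(kernel="rbf", gamma=gamma, C=spec.C, tol=1e-6))
    est.fit(Z, y)
    return TrainedModel("svm", spec, est, mean, scale, est.classes_)


def train_rf(X: np.ndarray, y: np.ndarray,
             spec: ClassifierSpec) -> TrainedModel:
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    Z, _, (mean, scale) = standardize(X)
    est = RandomForestClassifier(
        n_estimators=spec.n_trees, criterion="entropy",
        max_features="sqrt", bootstrap=True, max_depth=spec.max_depth,
        random_state=spec.seed)
    est.fit(Z, y)
    return TrainedModel("rf", spec, est, mean, scale, est.classes_)


_TRAINERS = {"ann": train_ann, "mlr": train_mlr, "svm": train_svm,
             "rf": train_rf}


def train(X: np.ndarray, y: np.ndarray,
          spec: ClassifierSpec) -> TrainedModel:
    """Dispatch to the family's trainer."""
    return _TRAINERS[spec.family](X, y, spec)


def predict_scores(model: TrainedModel, X: np.ndarray) -> ScoreMatrix:
    """Per-class scores for each row of ``X``.

    Probabilistic families (ANN, MLR, RF) return posteriors / vote
    fractions; the SVM's one-vs-rest decision values are squashed through
    a logistic and normalized per row so rows sum to 1.
    """
    Z = model.transform(X)
    if model.family == "ann":
        s = model.estimator.forward(Z)
    elif model.family == "svm":
        d = model.estimator.decision_function(Z)
        if d.ndim == 1:  # binary problem
            d = np.column_stack([-d, d])
        s = 1.0 / (1.0 + np.exp(-d))
        s = s / s.sum(axis=1, keepdims=True)
    else:
        s = model.estimator.predict_proba(Z)
    return ScoreMatrix(scores=s, is_probabilistic=True)


def feature_importance(model: TrainedModel, X: np.ndarray, y: np.ndarray,
                       n_repeats: int = 10, seed: int = 0):
    """Permutation importance (mean accuracy drop), RF only.

    Returns ``(order, importances)`` where ``order`` ranks features by
    decreasing importance with ties broken by feature index.
    """
    if model.family != "rf":
        raise ValueError("feature importance is implemented for the RF "
                         "family only")
    Z = model.transform(X)
    res = permutation_importance(model.estimator, Z, np.asarray(y),
                                 n_repeats=n_repeats, random_state=seed,
                                 scoring="accuracy")
    imp = res.importances_mean
    order = np.lexsort((np.arange(len(imp)), -imp))
    return order, imp
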