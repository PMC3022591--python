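"""Linear-margin classification, MCC evaluation, influence and permutation controls.

The classifier is a maximum-margin linear model (hinge loss, libsvm linear
kernel via scikit-learn). Classes are encoded +1 = control, -1 = cancer so
that a positive decision value d(x) = w·x + b argues for control; the
per-feature influence sign convention then reads minus = pushes toward
cancer, plus = toward control.

Evaluation reports use cancer as the positive class for the confusion
counts; the headline summary statistic is the Matthews correlation
coefficient, which stays meaningful for the unbalanced validation pools
this design produces.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import kendalltau
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .containers import CLASS_CANCER, CLASS_CONTROL

__all__ = [
    "LinearMarginModel",
    "EvaluationReport",
    "PeptidomeClassifier",
    "PeptidomeClassifierResults",
    "train",
    "evaluate",
    "mcc",
    "cross_validate",
    "feature_influence",
    "permutation_control",
    "PermutationControlResult",
    "marker_concordance",
]


def encode_labels(labels) -> np.ndarray:
    """Class labels → ±1 (+1 control, −1 cancer)."""
    arr = np.asarray(labels)
    bad = set(arr) - {CLASS_CONTROL, CLASS_CANCER}
    if bad:
        raise ValueError(f"unknown class labels: {sorted(bad)}")
    return np.where(arr == CLASS_CONTROL, 1, -1)


@dataclass
class LinearMarginModel:
    """A fitted linear decision function d(x) = w·x + b.

    ``sign(d) >= 0`` predicts control (+1), negative predicts cancer (−1).
    """

    weights: pd.Series
    intercept: float
    C: float = 1.0

    @property
    def features(self) -> list:
        return list(self.weights.index)

    def decision_value(self, X: pd.DataFrame) -> np.ndarray:
        return X[self.features].to_numpy() @ self.weights.to_numpy() + self.intercept

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        d = self.decision_value(X)
        return np.where(d >= 0, CLASS_CONTROL, CLASS_CANCER)


#: solver iteration bound — far beyond what any well-posed fit needs, but it
#: keeps degenerate inputs (signal-free, unscaled intensities) from making
#: the margin solver grind; such fits are near-random classifiers either way
_MAX_ITER = 200_000


def train(X: pd.DataFrame, labels, C: float = 1.0) -> LinearMarginModel:
    """Fit the maximum-margin linear classifier.

    Deterministic for fixed input and C. Requires both classes present.
    """
    import warnings as _warnings

    from sklearn.exceptions import ConvergenceWarning

    y = encode_labels(labels)
    if len(set(y)) < 2:
        raise ValueError("training data contains a single class")
    clf = SVC(kernel="linear", C=C, max_iter=_MAX_ITER)
    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore", ConvergenceWarning)
        clf.fit(X.to_numpy(), y)
    # libsvm's coef_ is expressed for classes_ = [-1, 1]; its decision
    # function is positive for the second class (+1 = control) already.
    w = pd.Series(clf.coef_.ravel(), index=X.columns)
    return LinearMarginModel(w, float(clf.intercept_[0]), C)


def mcc(tp: int, fp: int, tn: int, fn: int) -> float:
    """Matthews correlation coefficient from confusion counts.

    (TP·TN − FP·FN)/√((TP+FP)(TP+FN)(TN+FP)(TN+FN)); by convention 0 when
    any marginal factor is 0 (the correlation is undefined there).
    """
    counts = (tp, fp, tn, fn)
    if any(c < 0 for c in counts):
        raise ValueError("confusion counts must be nonnegative")
    if sum(counts) == 0:
        raise ValueError("empty confusion table")
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        return 0.0
    return (tp * tn - fp * fn) / math.sqrt(denom)


@dataclass
class EvaluationReport:
    """Confusion counts (cancer = positive class) with accuracy and MCC."""

    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def accuracy(self) -> float:
        return (self.tp + self.tn) / self.total

    @property
    def mcc(self) -> float:
        return mcc(self.tp, self.fp, self.tn, self.fn)

    def __add__(self, other: "EvaluationReport") -> "EvaluationReport":
        return EvaluationReport(
            self.tp + other.tp, self.fp + other.fp, self.tn + other.tn, self.fn + other.fn
        )

    def summary(self) -> str:
        return (
            f"TP={self.tp} FP={self.fp} TN={self.tn} FN={self.fn} | "
            f"accuracy={self.accuracy:.3f} MCC={self.mcc:.2f}"
        )

    @classmethod
    def from_predictions(cls, truth, predicted) -> "EvaluationReport":
        t = np.asarray(truth)
        p = np.asarray(predicted)
        is_cancer = t == CLASS_CANCER
        pred_cancer = p == CLASS_CANCER
        return cls(
            tp=int((is_cancer & pred_cancer).sum()),
            fp=int((~is_cancer & pred_cancer).sum()),
            tn=int((~is_cancer & ~pred_cancer).sum()),
            fn=int((is_cancer & ~pred_cancer).sum()),
        )


def evaluate(model: LinearMarginModel, X: pd.DataFrame, labels) -> EvaluationReport:
    return EvaluationReport.from_predictions(np.asarray(labels), model.predict(X))


def cross_validate(X: pd.DataFrame, labels, k: int = 10, seed: int = 0, C: float = 1.0) -> float:
    """Mean fold accuracy of stratified k-fold cross-validation.

    ``k == n`` degenerates to leave-one-out. Folds are shuffled with the
    given seed, so the result is deterministic per (data, k, seed).
    """
    y = np.asarray(labels)
    n = len(y)
    if k > n:
        raise ValueError(f"k={k} exceeds n={n}")
    if k == n:
        splits = [(np.delete(np.arange(n), i), np.array([i])) for i in range(n)]
    else:
        skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        splits = list(skf.split(np.zeros(n), y))
    accs = []
    for tr, te in splits:
        model = train(X.iloc[tr], y[tr], C=C)
        accs.append(float((model.predict(X.iloc[te]) == y[te]).mean()))
    return float(np.mean(accs))


def feature_influence(model: LinearMarginModel, feature_maxima: pd.Series) -> pd.Series:
    """Signed model influence per feature.

    influence(j) = d(M_j·e_j) − d(0) = w_j·M_j where M_j is the maximum
    observed value of feature j. With the +1=control encoding, a negative
    influence pushes toward cancer and a positive one toward control.
    Features absent from the model have influence 0.
    """
    infl = pd.Series(0.0, index=feature_maxima.index, name="influence")
    common = [f for f in model.features if f in infl.index]
    infl[common] = model.weights[common] * feature_maxima[common]
    return infl


# ---------------------------------------------------------------------------
# statsmodels-style model/results wrapper
# ---------------------------------------------------------------------------

class PeptidomeClassifier:
    """Linear-margin model over a sample-level feature matrix.

    Parameters
    ----------
    X : DataFrame
        Samples × features (typically the selected signature columns).
    labels : sequence
        ``control`` / ``cancer`` per sample.
    C : float
        Margin regularization constant.
    """

    def __init__(self, X: pd.DataFrame, labels, C: float = 1.0):
        self.X = X
        self.labels = np.asarray(labels)
        self.C = C

    def fit(self) -> "PeptidomeClassifierResults":
        model = train(self.X, self.labels, C=self.C)
        return PeptidomeClassifierResults(self, model)


@dataclass
class PeptidomeClassifierResults:
    """Fitted classifier with its training diagnostics."""

    model_spec: PeptidomeClassifier
    linear_model: LinearMarginModel

    @property
    def params(self) -> pd.Series:
        return self.linear_model.weights

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        return self.linear_model.predict(X)

    def training_report(self) -> EvaluationReport:
        return evaluate(self.linear_model, self.model_spec.X, self.model_spec.labels)

    def influence(self) -> pd.Series:
        return feature_influence(self.linear_model, self.model_spec.X.max(axis=0))

    def cv_accuracy(self, k: int = 10, seed: int = 0) -> float:
        return cross_validate(self.model_spec.X, self.model_spec.labels, k=k, seed=seed, C=self.C)

    def summary(self) -> str:
        rep = self.training_report()
        infl = self.influence().sort_values()
        lines = [
            "Linear-margin peptidome classifier",
            f"  features: {len(self.params)}   C={self.model_spec.C:g}",
            f"  training: {rep.summary()}",
            "  influence (minus: cancer; plus: control):",
        ]
        lines += [f"    {f:>10}  {v:+.3f}" for f, v in infl.items()]
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# Permutation control
# ---------------------------------------------------------------------------

@dataclass
class PermutationControlResult:
    """Label-shuffling control for the select-then-cross-validate pipeline."""

    unshuffled_accuracy: float
    unshuffled_median_p: float
    shuffled_accuracies: np.ndarray
    shuffled_median_p: np.ndarray

    def summary(self) -> str:
        return (
            f"unshuffled CV accuracy {self.unshuffled_accuracy:.3f} "
            f"(median feature p {self.unshuffled_median_p:.3g}); "
            f"shuffled median accuracy {np.median(self.shuffled_accuracies):.3f} "
            f"(median feature p {np.median(self.shuffled_median_p):.3g}, "
            f"n={len(self.shuffled_accuracies)})"
        )


def permutation_control(
    m,
    labels=None,
    params=None,
    p_grid=None,
    i_grid=None,
    n_shuffles: int = 20,
    cv_folds: int = 10,
    seed: int = 0,
    C: float = 1.0,
) -> PermutationControlResult:
    """Re-run the full select + train + CV pipeline under label shuffling.

    Either fixed :class:`FilterParams` (``params``) or search grids may be
    given; with grids, the cutoff optimization itself is repeated for every
    shuffle, so any selection-bias optimism is reproduced faithfully under
    the null.
    """
    from .selection import intensity_filter, mannwhitney_pvalues, optimize_filters

    if n_shuffles < 1:
        raise ValueError("n_shuffles must be >= 1")
    labels = m.labels.to_numpy() if labels is None else np.asarray(labels)
    rng = np.random.default_rng(seed)

    def run(lab):
        lab = pd.Series(lab, index=m.data.index)
        if params is not None:
            pv = mannwhitney_pvalues(m, lab)
            kept = intensity_filter(m, params.intensity_cutoff)
            feats = [f for f in kept if pv[f] <= params.p_cutoff]
            acc = (
                cross_validate(m.data[feats], lab, k=cv_folds, seed=seed, C=C)
                if feats
                else 0.0
            )
            return acc, float(pv.median())
        res = optimize_filters(
            m, lab, p_grid=p_grid, i_grid=i_grid, cv_folds=cv_folds, seed=seed, C=C
        )
        return res.cv_accuracy, float(res.p_values.median())

    acc0, p0 = run(labels)
    accs, med_ps = [], []
    for _ in range(n_shuffles):
        accs_i, p_i = run(rng.permutation(labels))
        accs.append(accs_i)
        med_ps.append(p_i)
    return PermutationControlResult(acc0, p0, np.array(accs), np.array(med_ps))


def marker_concordance(x, y) -> tuple[float, float]:
    """Tie-corrected Kendall tau-b and two-sided p between paired measurements.

    Used to check that an orthogonal immunoassay follows the trend of the
    corresponding mass-spectrometry feature on the same samples.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must be paired (equal length)")
    if x.size < 3:
        raise ValueError("need at least 3 paired observations")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("tau undefined for a constant vector")
    res = kendalltau(x, y)
    return float(res.statistic), float(res.pvalue)
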