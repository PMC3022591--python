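"""Clinical decision-rule panel on apoB-100-normalized apolipoproteins, CRP, CA19-9.

From each clinical record the four derived features are

    apoC-I/apoB-100,  apoC-III/apoB-100,  CRP (µg/ml),  CA19-9 (U/ml),

apoB-100 serving as the normalizing denominator because its serum level
shows no class trend. A small CART-style binary decision tree (Gini
impurity, greedy best split over midpoint thresholds) is trained on one
source and validated cross-source, reporting accuracy, sensitivity
(correct cancers / cancers) and specificity (correct controls / controls).

The tree inducer is implemented here rather than taken from a library so
that tie-breaking is fully specified (equal-gain splits resolve to the
lowest feature index, then the lowest threshold) and training is invariant
to record order.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu

from .containers import CLASS_CANCER, CLASS_CONTROL

__all__ = [
    "MARKERS",
    "DERIVED_FEATURES",
    "derive_features",
    "ClinicalRuleModel",
    "ClinicalRuleResults",
    "ClinicalEvaluation",
    "train_rules",
    "evaluate_rules",
    "group_compare",
    "read_clinical_records",
    "write_clinical_records",
]

MARKERS = ("apoC_I", "apoC_III", "apoB_100", "CRP", "CA19_9")
DERIVED_FEATURES = ("apoC_I_over_apoB_100", "apoC_III_over_apoB_100", "CRP", "CA19_9")


def derive_features(records: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Derive the 4-feature panel from raw marker columns.

    Records with a missing, non-positive or non-finite apoB-100 (or any
    missing marker) are excluded; the exclusion log says why. Returns
    (derived table with sample_id/source/class + 4 features, exclusion log).
    """
    missing_cols = set(MARKERS) - set(records.columns)
    if missing_cols:
        raise ValueError(f"records missing marker columns: {sorted(missing_cols)}")
    reasons = []
    ok = np.ones(len(records), dtype=bool)
    for i, (_, r) in enumerate(records.iterrows()):
        bad = [m for m in MARKERS if not np.isfinite(r[m]) or r[m] <= 0]
        if "apoB_100" in bad or bad:
            ok[i] = False
            reasons.append(
                {"sample_id": r.get("sample_id", i), "reason": f"invalid marker(s): {bad}"}
            )
    kept = records.loc[ok].reset_index(drop=True)
    out = kept[[c for c in ("sample_id", "source", "class") if c in kept.columns]].copy()
    out["apoC_I_over_apoB_100"] = kept["apoC_I"] / kept["apoB_100"]
    out["apoC_III_over_apoB_100"] = kept["apoC_III"] / kept["apoB_100"]
    out["CRP"] = kept["CRP"]
    out["CA19_9"] = kept["CA19_9"]
    return out, pd.DataFrame(reasons, columns=["sample_id", "reason"])


# ---------------------------------------------------------------------------
# CART-style tree
# ---------------------------------------------------------------------------

@dataclass
class _Leaf:
    label: str
    n_control: int
    n_cancer: int


@dataclass
class _Node:
    feature: str
    threshold: float
    left: object   # branch for value <= threshold
    right: object  # branch for value > threshold


def _gini(n_ctrl: int, n_can: int) -> float:
    n = n_ctrl + n_can
    if n == 0:
        return 0.0
    p = n_ctrl / n
    return 2.0 * p * (1.0 - p)


def _majority(y: np.ndarray) -> str:
    n_ctrl = int((y == CLASS_CONTROL).sum())
    n_can = len(y) - n_ctrl
    # deterministic tie rule: prefer control (the cautious call)
    return CLASS_CONTROL if n_ctrl >= n_can else CLASS_CANCER


def _grow(X: np.ndarray, y: np.ndarray, feats: list, depth: int, max_depth: int, min_leaf: int):
    n = len(y)
    n_ctrl = int((y == CLASS_CONTROL).sum())
    n_can = n - n_ctrl
    leaf = _Leaf(_majority(y), n_ctrl, n_can)
    if depth >= max_depth or n_ctrl == 0 or n_can == 0 or n < 2 * min_leaf:
        return leaf

    parent = _gini(n_ctrl, n_can)
    best = None  # (neg_gain, feat_idx, threshold)
    for j in range(X.shape[1]):
        vals = X[:, j]
        order = np.argsort(vals, kind="stable")
        sv, sy = vals[order], y[order]
        uniq = np.unique(sv)
        if uniq.size < 2:
            continue
        cut_points = (uniq[:-1] + uniq[1:]) / 2.0
        is_ctrl = (sy == CLASS_CONTROL).astype(int)
        cum_ctrl = np.cumsum(is_ctrl)
        for thr in cut_points:
            n_left = int(np.searchsorted(sv, thr, side="right"))
            n_right = n - n_left
            if n_left < min_leaf or n_right < min_leaf:
                continue
            lc = int(cum_ctrl[n_left - 1])
            rc = n_ctrl - lc
            gain = parent - (
                n_left / n * _gini(lc, n_left - lc) + n_right / n * _gini(rc, n_right - rc)
            )
            key = (-gain, j, thr)
            if gain > 1e-12 and (best is None or key < best):
                best = key
    if best is None:
        return leaf
    _, j, thr = best
    mask = X[:, j] <= thr
    return _Node(
        feats[j],
        float(thr),
        _grow(X[mask], y[mask], feats, depth + 1, max_depth, min_leaf),
        _grow(X[~mask], y[~mask], feats, depth + 1, max_depth, min_leaf),
    )


def _predict_one(node, row: pd.Series) -> str:
    while isinstance(node, _Node):
        node = node.left if row[node.feature] <= node.threshold else node.right
    return node.label


def _to_dict(node) -> dict:
    if isinstance(node, _Leaf):
        return {"leaf": node.label, "n_control": node.n_control, "n_cancer": node.n_cancer}
    return {
        "feature": node.feature,
        "threshold": node.threshold,
        "le": _to_dict(node.left),
        "gt": _to_dict(node.right),
    }


def _to_text(node, indent: int = 0) -> list:
    pad = "  " * indent
    if isinstance(node, _Leaf):
        return [f"{pad}-> {node.label} (control={node.n_control}, cancer={node.n_cancer})"]
    out = [f"{pad}if {node.feature} <= {node.threshold:.6g}:"]
    out += _to_text(node.left, indent + 1)
    out.append(f"{pad}else:")
    out += _to_text(node.right, indent + 1)
    return out


@dataclass
class ClinicalEvaluation:
    """Confusion counts plus the three clinical rates."""

    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def n_cancer(self) -> int:
        return self.tp + self.fn

    @property
    def n_control(self) -> int:
        return self.tn + self.fp

    @property
    def accuracy(self) -> float:
        return (self.tp + self.tn) / (self.n_cancer + self.n_control)

    @property
    def sensitivity(self) -> float:
        return self.tp / self.n_cancer if self.n_cancer else float("nan")

    @property
    def specificity(self) -> float:
        return self.tn / self.n_control if self.n_control else float("nan")

    def summary(self) -> str:
        return (
            f"accuracy={self.accuracy:.3f} sensitivity={self.sensitivity:.3f} "
            f"({self.tp}/{self.n_cancer}) specificity={self.specificity:.3f} "
            f"({self.tn}/{self.n_control})"
        )


class ClinicalRuleModel:
    """Decision-rule model on the 4-feature clinical panel.

    Parameters
    ----------
    records : DataFrame
        Raw clinical records (marker columns plus class/source).
    max_depth, min_leaf : int
        Tree capacity controls; the shallow defaults keep the rules
        human-readable as a clinical score.
    """

    def __init__(self, records: pd.DataFrame, max_depth: int = 4, min_leaf: int = 5,
                 features: tuple = DERIVED_FEATURES):
        self.records = records
        self.max_depth = max_depth
        self.min_leaf = min_leaf
        self.features = tuple(features)

    def fit(self) -> "ClinicalRuleResults":
        derived, excluded = derive_features(self.records)
        y = derived["class"].to_numpy()
        if len(set(y)) < 2:
            import warnings

            warnings.warn("single-class training data: returning a single-leaf tree", stacklevel=2)
        X = derived[list(self.features)].to_numpy(dtype=float)
        root = _grow(X, y, list(self.features), 0, self.max_depth, self.min_leaf)
        return ClinicalRuleResults(self, root, derived, excluded)


@dataclass
class ClinicalRuleResults:
    """Fitted rule set with training diagnostics."""

    model_spec: ClinicalRuleModel
    root: object
    training_data: pd.DataFrame = field(repr=False, default=None)
    excluded_log: pd.DataFrame = field(repr=False, default=None)

    def predict(self, derived: pd.DataFrame) -> np.ndarray:
        return np.array([_predict_one(self.root, row) for _, row in derived.iterrows()])

    def evaluate(self, records: pd.DataFrame) -> ClinicalEvaluation:
        """Evaluate on raw records (features derived internally)."""
        if len(records) == 0:
            raise ValueError("empty validation set")
        derived, _ = derive_features(records)
        if len(derived) == 0:
            raise ValueError("no valid records after exclusions")
        pred = self.predict(derived)
        truth = derived["class"].to_numpy()
        is_can = truth == CLASS_CANCER
        pred_can = pred == CLASS_CANCER
        return ClinicalEvaluation(
            tp=int((is_can & pred_can).sum()),
            fp=int((~is_can & pred_can).sum()),
            tn=int((~is_can & ~pred_can).sum()),
            fn=int((is_can & ~pred_can).sum()),
        )

    def training_evaluation(self) -> ClinicalEvaluation:
        pred = self.predict(self.training_data)
        truth = self.training_data["class"].to_numpy()
        is_can = truth == CLASS_CANCER
        pred_can = pred == CLASS_CANCER
        return ClinicalEvaluation(
            tp=int((is_can & pred_can).sum()),
            fp=int((~is_can & pred_can).sum()),
            tn=int((~is_can & ~pred_can).sum()),
            fn=int((is_can & ~pred_can).sum()),
        )

    def to_text(self) -> str:
        return "\n".join(_to_text(self.root))

    def to_json(self) -> str:
        return json.dumps(_to_dict(self.root), indent=2)

    def summary(self) -> str:
        ev = self.training_evaluation()
        return "\n".join(
            [
                "Clinical decision rules "
                f"(max_depth={self.model_spec.max_depth}, min_leaf={self.model_spec.min_leaf})",
                f"  training: {ev.summary()}",
                f"  excluded records: {len(self.excluded_log)}",
                self.to_text(),
            ]
        )


def train_rules(records: pd.DataFrame, max_depth: int = 4, min_leaf: int = 5,
                features: tuple = DERIVED_FEATURES) -> ClinicalRuleResults:
    return ClinicalRuleModel(records, max_depth, min_leaf, features).fit()


def evaluate_rules(results: ClinicalRuleResults, records: pd.DataFrame) -> ClinicalEvaluation:
    return results.evaluate(records)


def group_compare(x, y, alternative: str = "greater") -> float:
    """One-sided rank-sum p-value that group ``x`` is shifted above ``y``.

    Exact when both groups are small (<= 8) and tie-free, else the normal
    approximation with continuity correction. Constant pooled data carry
    no ordering information: p = 0.5 is returned (flagged via a warning).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        import warnings

        warnings.warn("constant pooled data: rank test uninformative, p=0.5", stacklevel=2)
        return 0.5
    tie_free = np.unique(pooled).size == pooled.size
    method = "exact" if (x.size <= 8 and y.size <= 8 and tie_free) else "asymptotic"
    return float(mannwhitneyu(x, y, alternative=alternative, method=method).pvalue)


def read_clinical_records(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = ({"sample_id", "source", "class"} | set(MARKERS)) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return df


def write_clinical_records(records: pd.DataFrame, path) -> None:
    records.to_csv(path, sep="\t", index=False, float_format="%.6g", lineterminator="\n")
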