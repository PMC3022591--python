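"""Rank-test feature selection with CV-optimized cutoffs.

Features are filtered by a per-feature two-sided Mann-Whitney U p-value
cutoff and (optionally) a maximum-intensity cutoff. The two cutoffs are
optimized by exhaustive grid search: every (p, intensity) combination is
scored by the stratified ten-fold cross-validated accuracy of a
linear-margin classifier trained on the selected features, and among the
top-scoring combinations the one selecting the fewest features wins
(remaining ties: smaller p cutoff, then larger intensity cutoff).

No multiple-testing correction is applied: the selection filter operates
on raw rank-test p-values by design, and the permutation control in
:mod:`peptisig.classify` is the guard against selection-bias optimism.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu

from .containers import CLASS_CONTROL, SampleMatrix

__all__ = [
    "FilterParams",
    "SelectionResult",
    "mannwhitney_pvalues",
    "rank_test_pvalue",
    "intensity_filter",
    "optimize_filters",
    "DEFAULT_P_GRID",
    "DEFAULT_INTENSITY_GRID",
]

#: default search grids: 15 log-spaced p cutoffs in [0.001, 0.1] and
#: intensity cutoffs 0..500 in steps of 50 (None = filter disabled)
DEFAULT_P_GRID: tuple = tuple(np.geomspace(0.001, 0.1, 15))
DEFAULT_INTENSITY_GRID: tuple = tuple(float(c) for c in range(0, 501, 50))
DISABLED_INTENSITY_GRID: tuple = (None,)


@dataclass(frozen=True)
class FilterParams:
    """A (p-value cutoff, intensity cutoff) pair; ``None`` disables the
    intensity filter (quantile-normalized runs have no meaningful raw
    intensity scale)."""

    p_cutoff: float
    intensity_cutoff: float | None = None

    def __post_init__(self) -> None:
        if not (0 < self.p_cutoff <= 1):
            raise ValueError("p_cutoff must lie in (0, 1]")
        if self.intensity_cutoff is not None and self.intensity_cutoff < 0:
            raise ValueError("intensity_cutoff must be >= 0 or None")


def rank_test_pvalue(x: np.ndarray, y: np.ndarray, alternative: str = "two-sided") -> float:
    """Mann-Whitney U p-value between two groups.

    Exact enumeration when both groups have <= 8 observations and the
    pooled data are tie-free; otherwise the tie-corrected normal
    approximation with continuity correction. A feature constant across
    all samples is maximally uninformative: p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return 1.0
    tie_free = np.unique(pooled).size == pooled.size
    method = "exact" if (x.size <= 8 and y.size <= 8 and tie_free) else "asymptotic"
    return float(mannwhitneyu(x, y, alternative=alternative, method=method).pvalue)


def mannwhitney_pvalues(
    m: SampleMatrix, labels=None, alternative: str = "two-sided"
) -> pd.Series:
    """Per-feature Mann-Whitney p-values between the two clinical groups."""
    labels = m.labels if labels is None else pd.Series(np.asarray(labels), index=m.data.index)
    is_control = (labels == CLASS_CONTROL).to_numpy()
    if is_control.all() or not is_control.any():
        raise ValueError("both classes must be non-empty")
    X = m.data.to_numpy()
    pv = np.array(
        [
            rank_test_pvalue(X[is_control, j], X[~is_control, j], alternative)
            for j in range(X.shape[1])
        ]
    )
    return pd.Series(pv, index=m.features, name="p_value")


def intensity_filter(m: SampleMatrix, cutoff: float | None) -> list[str]:
    """Features whose maximum averaged intensity over samples exceeds ``cutoff``.

    The filter removes features, never samples: a feature survives if at
    least one sample's averaged reading lies above the cutoff. ``None``
    (or 0) keeps everything.
    """
    if cutoff is None:
        return list(m.features)
    maxima = m.data.max(axis=0)
    return [f for f in m.features if maxima[f] > cutoff]


@dataclass
class SelectionResult:
    """Outcome of the cutoff grid search."""

    params: FilterParams
    features: list
    p_values: pd.Series
    cv_accuracy: float
    grid: pd.DataFrame = field(repr=False, default=None)

    def summary(self) -> str:
        icut = "NA" if self.params.intensity_cutoff is None else f"{self.params.intensity_cutoff:g}"
        lines = [
            "Feature selection (Mann-Whitney + intensity cutoffs, CV grid search)",
            f"  p-value cutoff:       {self.params.p_cutoff:.4g}",
            f"  intensity cutoff:     {icut}",
            f"  features selected:    {len(self.features)}",
            f"  ten-fold CV accuracy: {self.cv_accuracy:.3f}",
        ]
        return "\n".join(lines)


def _select(p_values: pd.Series, kept_by_intensity: dict, params: FilterParams) -> list:
    base = kept_by_intensity[params.intensity_cutoff]
    return [f for f in base if p_values[f] <= params.p_cutoff]


def optimize_filters(
    m: SampleMatrix,
    labels=None,
    p_grid=DEFAULT_P_GRID,
    i_grid=DEFAULT_INTENSITY_GRID,
    cv_folds: int = 10,
    seed: int = 0,
    C: float = 1.0,
    alternative: str = "two-sided",
) -> SelectionResult:
    """Exhaustive (p, intensity) grid search scored by cross-validated accuracy.

    Step 1 evaluates every combination; step 2 returns, among combinations
    within 1e-12 of the maximum accuracy, the one with fewest selected
    features (ties: smaller p cutoff, then larger intensity cutoff). A
    combination selecting zero features scores accuracy 0 — there is no
    majority-class fallback. Deterministic given (data, grids, seed).
    """
    from .classify import cross_validate  # deferred: avoids a module cycle

    if not len(p_grid) or not len(i_grid):
        raise ValueError("grids must be non-empty")
    labels = m.labels if labels is None else pd.Series(np.asarray(labels), index=m.data.index)
    pv = mannwhitney_pvalues(m, labels, alternative)
    kept_by_intensity = {c: intensity_filter(m, c) for c in i_grid}

    acc_cache: dict[frozenset, float] = {}
    rows = []
    for p_cut in p_grid:
        for i_cut in i_grid:
            params = FilterParams(float(p_cut), i_cut)
            feats = _select(pv, kept_by_intensity, params)
            key = frozenset(feats)
            if not feats:
                acc = 0.0
            elif key in acc_cache:
                acc = acc_cache[key]
            else:
                acc = cross_validate(
                    m.data[feats], labels, k=cv_folds, seed=seed, C=C
                )
                acc_cache[key] = acc
            rows.append(
                {
                    "p_cutoff": float(p_cut),
                    "intensity_cutoff": np.nan if i_cut is None else float(i_cut),
                    "n_features": len(feats),
                    "cv_accuracy": acc,
                }
            )
    grid = pd.DataFrame(rows)
    best_acc = grid["cv_accuracy"].max()
    cand = grid[grid["cv_accuracy"] >= best_acc - 1e-12].copy()
    # fewest features, then smaller p cutoff, then larger intensity cutoff
    cand["_icut"] = cand["intensity_cutoff"].fillna(np.inf)
    cand = cand.sort_values(
        ["n_features", "p_cutoff", "_icut"], ascending=[True, True, False]
    )
    row = cand.iloc[0]
    icut = None if np.isnan(row["intensity_cutoff"]) else float(row["intensity_cutoff"])
    params = FilterParams(float(row["p_cutoff"]), icut)
    feats = _select(pv, kept_by_intensity, params)
    return SelectionResult(params, feats, pv, float(row["cv_accuracy"]), grid)
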