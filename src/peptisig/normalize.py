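"""Control-decile quantile normalization, fitted per source.

Cross-repository intensity bias is removed by mapping each source's raw
intensities onto decile bins defined by that source's *control* class: per
(source, feature), nine thresholds X1..X9 divide the control-class nonzero
readings into ten quantile bins, and every reading x is replaced by

    bin(x) = 1 + #{i : X_i < x}  in {1..10},

with zeros (missing readings) left at 0. The map is scale-invariant within
a (source, feature): multiplying a source's intensities by any positive
constant leaves its normalized values unchanged, which is exactly how a
multiplicative source bias is removed. A trend that is *opposite* between
sources is not — and cannot be — repaired by this step.

Thresholds use linear interpolation of order statistics (quantile position
h = (n-1)p + 1, the R type-7 / numpy default convention). Normalization
operates at replicate level, before averaging, so averaged bins may be
fractional in {0} ∪ [1, 10].
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import CLASS_CONTROL, ReplicateMatrix

__all__ = ["QuantileMap", "fit_quantile_map", "fit_quantile_maps", "apply_quantile_map"]

_PROBS = np.arange(1, 10) / 10.0
_COLS = [f"X{i}" for i in range(1, 10)]


@dataclass
class QuantileMap:
    """Per (source, feature) decile thresholds fitted on control readings.

    ``thresholds`` is indexed by (source, feature) with ascending columns
    X1..X9. ``flagged`` holds (source, feature) pairs with fewer than two
    nonzero control readings, whose values pass through unnormalized.
    """

    thresholds: pd.DataFrame
    flagged: set = field(default_factory=set)

    def sources(self) -> set:
        return set(self.thresholds.index.get_level_values(0)) | {s for s, _ in self.flagged}

    def merge(self, other: "QuantileMap") -> "QuantileMap":
        return QuantileMap(
            pd.concat([self.thresholds, other.thresholds]),
            self.flagged | other.flagged,
        )


def fit_quantile_map(m: ReplicateMatrix, source: str) -> QuantileMap:
    """Fit decile thresholds for one source from its control-class nonzero readings."""
    meta = m.row_meta()
    sel = (meta["source"] == source) & (meta["class"] == CLASS_CONTROL).to_numpy()
    block = m.data.loc[sel.to_numpy()]
    if block.shape[0] == 0:
        raise ValueError(f"source {source!r} has no control readings to fit on")
    rows, idx, flagged = [], [], set()
    for f in m.features:
        vals = block[f].to_numpy()
        vals = vals[vals > 0]
        if vals.size < 2:
            flagged.add((source, f))
            continue
        rows.append(np.quantile(vals, _PROBS, method="linear"))
        idx.append((source, f))
    if flagged:
        warnings.warn(
            f"source {source!r}: {len(flagged)} feature(s) with <2 nonzero control "
            "readings pass through unnormalized",
            stacklevel=2,
        )
    thr = pd.DataFrame(
        rows,
        index=pd.MultiIndex.from_tuples(idx, names=["source", "feature"])
        if idx
        else pd.MultiIndex.from_arrays([[], []], names=["source", "feature"]),
        columns=_COLS,
    )
    return QuantileMap(thr, flagged)


def fit_quantile_maps(m: ReplicateMatrix, sources=None) -> QuantileMap:
    """Fit one control-decile map per source (each independent of the others)."""
    if sources is None:
        sources = list(dict.fromkeys(m.samples["source"]))
    merged: QuantileMap | None = None
    for s in sources:
        qm = fit_quantile_map(m, s)
        merged = qm if merged is None else merged.merge(qm)
    return merged


def apply_quantile_map(m: ReplicateMatrix, q: QuantileMap) -> ReplicateMatrix:
    """Replace nonzero readings by their control-decile bin, per source.

    bin(x) = 1 + #{i : X_i < x}; a value equal to a threshold falls in the
    lower bin; zeros stay 0. Every source present in the matrix must have a
    fitted (or flagged) map.
    """
    present = set(m.samples["source"])
    missing = present - q.sources()
    if missing:
        raise ValueError(f"no quantile map fitted for source(s): {sorted(missing)}")
    meta = m.row_meta()
    out = m.data.copy()
    src_arr = meta["source"].to_numpy()
    for source in sorted(present):
        rows = src_arr == source
        for f in m.features:
            if (source, f) in q.flagged:
                continue  # passthrough, warned at fit time
            try:
                thr = q.thresholds.loc[(source, f)].to_numpy()
            except KeyError:
                raise ValueError(
                    f"quantile map missing feature {f!r} for source {source!r}"
                ) from None
            x = out.loc[rows, f].to_numpy()
            nz = x > 0
            binned = x.copy()
            binned[nz] = 1.0 + np.searchsorted(thr, x[nz], side="left")
            out.loc[rows, f] = binned
    return ReplicateMatrix(out, m.samples.copy())
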