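"""Replicate summarization with zeros treated as missing readings.

Replicate readings of a sample are averaged ignoring zeros (a zero may be
a missing reading rather than a true zero intensity); features that still
contain a zero in any sample after averaging are dropped, since a
margin classifier could otherwise learn from the missingness pattern
itself. The removal log records per-class zero counts so the absence of a
class preference among removed features can be checked (a two-sided Fisher
exact test is reported but never used to filter).
"""

from __future__ import annotations

import pandas as pd
from scipy.stats import fisher_exact

from .containers import CLASS_CONTROL, ReplicateMatrix, SampleMatrix

__all__ = ["average_replicates", "filter_zero_features"]


def average_replicates(m: ReplicateMatrix) -> SampleMatrix:
    """Per (sample, feature): mean of the nonzero replicate readings.

    A cell is 0 only when every replicate reading was 0. The mean is
    unweighted over nonzero readings even when replicate counts differ
    between samples. Replicate order is irrelevant.
    """
    counts = m.data.index.get_level_values(0).value_counts()
    missing = set(m.samples.index) - set(counts.index)
    if missing:
        raise ValueError(f"samples with zero replicates: {sorted(missing)[:5]}")
    masked = m.data.mask(m.data == 0)
    avg = masked.groupby(level="sample_id", sort=False).mean().fillna(0.0)
    avg = avg.loc[list(m.samples.index)]  # preserve sample-table order
    avg.index.name = "sample_id"
    return SampleMatrix(avg, m.samples.copy())


def filter_zero_features(m: SampleMatrix) -> tuple[SampleMatrix, pd.DataFrame]:
    """Drop features with a zero averaged intensity in at least one sample.

    Returns the strictly positive sub-matrix and a removal log with, per
    removed feature, the per-class zero counts and a two-sided Fisher
    exact p-value for class association of the zeros (diagnostic only).
    """
    zero = m.data.to_numpy() == 0
    removed_mask = zero.any(axis=0)
    kept = [f for f, r in zip(m.features, removed_mask) if not r]
    if not kept:
        raise ValueError(
            "all features removed by the zero filter "
            f"(n={len(m.features)}; check dropout level or replicate count)"
        )
    is_control = (m.labels == CLASS_CONTROL).to_numpy()
    n_ctrl, n_can = int(is_control.sum()), int((~is_control).sum())
    log_rows = []
    for j, f in enumerate(m.features):
        if not removed_mask[j]:
            continue
        z_ctrl = int(zero[is_control, j].sum())
        z_can = int(zero[~is_control, j].sum())
        table = [[z_ctrl, n_ctrl - z_ctrl], [z_can, n_can - z_can]]
        p = float(fisher_exact(table, alternative="two-sided")[1])
        log_rows.append(
            {
                "feature": f,
                "n_zero_control": z_ctrl,
                "n_zero_cancer": z_can,
                "n_control": n_ctrl,
                "n_cancer": n_can,
                "fisher_p": p,
            }
        )
    log = pd.DataFrame(
        log_rows,
        columns=["feature", "n_zero_control", "n_zero_cancer", "n_control", "n_cancer", "fisher_p"],
    )
    return m.subset_features(kept), log
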