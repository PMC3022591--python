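"""Minimal boxplot export for per-feature class/source comparisons."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .containers import SampleMatrix


def feature_boxplot(m: SampleMatrix, feature: str, ax=None):
    """Boxplot of one feature's intensities, grouped by source × class.

    The side-by-side panels make source bias visible: a concordant feature
    keeps the same control-vs-cancer ordering in every source even when
    the absolute intensities differ.
    """
    if feature not in m.features:
        raise ValueError(f"unknown feature {feature!r}")
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    groups, labels = [], []
    for source in dict.fromkeys(m.samples["source"]):
        for cls in ("control", "cancer"):
            sel = (m.samples["source"] == source) & (m.samples["class"] == cls)
            vals = m.data.loc[sel.to_numpy(), feature]
            if len(vals):
                groups.append(vals.to_numpy())
                labels.append(f"{source}\n{cls}")
    ax.boxplot(groups, tick_labels=labels)
    ax.set_ylabel("intensity")
    ax.set_title(f"feature m/z {feature}")
    return ax
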