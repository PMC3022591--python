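"""In-memory containers and TSV readers/writers for intensity matrices.

Two matrix granularities flow through the pipeline:

* :class:`ReplicateMatrix` — one row per (sample, replicate) reading; the
  value 0 is the missing-reading sentinel, deliberately conflating "absent"
  and "not measured".
* :class:`SampleMatrix` — one row per sample after replicate averaging.

Both carry a per-sample metadata table (source, class, optional stage).
All writers are deterministic: stable column order, 6-significant-digit
floats, UTF-8, LF line endings.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

CLASS_CONTROL = "control"
CLASS_CANCER = "cancer"

#: metadata columns that precede feature columns in matrix TSV files
_REPLICATE_META = ["sample_id", "replicate_id", "source", "class"]
_SAMPLE_META = ["sample_id", "source", "class"]

_FLOAT_FMT = "%.6g"


class SchemaError(ValueError):
    """A matrix file violates the expected column schema or value domain."""


def _check_samples_table(samples: pd.DataFrame) -> None:
    missing = {"source", "class"} - set(samples.columns)
    if missing:
        raise SchemaError(f"sample table missing columns: {sorted(missing)}")
    bad = set(samples["class"]) - {CLASS_CONTROL, CLASS_CANCER}
    if bad:
        raise SchemaError(f"unknown class labels: {sorted(bad)}")


@dataclass
class ReplicateMatrix:
    """Replicate-level feature intensities.

    Parameters
    ----------
    data : DataFrame
        Index is a MultiIndex (sample_id, replicate_id); columns are
        feature labels (strings, integer-rounded m/z); values are
        nonnegative intensities with 0 meaning "missing reading".
    samples : DataFrame
        Indexed by sample_id with at least columns ``source`` and
        ``class`` (values ``control``/``cancer``).
    """

    data: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        if self.data.index.nlevels != 2:
            raise SchemaError("ReplicateMatrix.data needs a (sample_id, replicate_id) index")
        _check_samples_table(self.samples)
        if (self.data.to_numpy() < 0).any():
            raise SchemaError("negative intensity in ReplicateMatrix")
        dup = self.data.index.duplicated()
        if dup.any():
            raise SchemaError(
                f"duplicate (sample_id, replicate_id) rows: {list(self.data.index[dup][:5])}"
            )

    @property
    def features(self) -> list[str]:
        return list(self.data.columns)

    def sample_ids(self) -> list[str]:
        return list(self.samples.index)

    def row_meta(self) -> pd.DataFrame:
        """Per-row (source, class) metadata aligned with ``data``."""
        sid = self.data.index.get_level_values(0)
        meta = self.samples.loc[sid, ["source", "class"]].reset_index(drop=True)
        meta.index = self.data.index
        return meta

    def subset_samples(self, sample_ids) -> "ReplicateMatrix":
        keep = self.data.index.get_level_values(0).isin(set(sample_ids))
        return ReplicateMatrix(self.data.loc[keep].copy(), self.samples.loc[list(sample_ids)].copy())


@dataclass
class SampleMatrix:
    """Sample-level (replicate-averaged) feature intensities."""

    data: pd.DataFrame          # index sample_id, columns feature labels
    samples: pd.DataFrame       # index sample_id; source, class

    def __post_init__(self) -> None:
        _check_samples_table(self.samples)
        if not self.data.index.equals(self.samples.index):
            self.samples = self.samples.loc[self.data.index]

    @property
    def features(self) -> list[str]:
        return list(self.data.columns)

    @property
    def labels(self) -> pd.Series:
        return self.samples["class"]

    def subset_samples(self, sample_ids) -> "SampleMatrix":
        ids = list(sample_ids)
        return SampleMatrix(self.data.loc[ids].copy(), self.samples.loc[ids].copy())

    def subset_features(self, features) -> "SampleMatrix":
        return SampleMatrix(self.data[list(features)].copy(), self.samples.copy())


# ---------------------------------------------------------------------------
# TSV round trips
# ---------------------------------------------------------------------------

def write_replicate_matrix(m: ReplicateMatrix, path) -> None:
    meta = m.row_meta()
    flat = m.data.reset_index()
    flat.columns = ["sample_id", "replicate_id"] + list(m.data.columns)
    flat.insert(2, "source", meta["source"].to_numpy())
    flat.insert(3, "class", meta["class"].to_numpy())
    flat.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT, lineterminator="\n")


def read_replicate_matrix(path) -> ReplicateMatrix:
    df = pd.read_csv(path, sep="\t")
    missing = set(_REPLICATE_META) - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: missing columns {sorted(missing)}")
    feats = [c for c in df.columns if c not in _REPLICATE_META]
    vals = df[feats].to_numpy(dtype=float)
    neg = np.argwhere(vals < 0)
    if neg.size:
        r, c = neg[0]
        raise SchemaError(
            f"{path}: negative intensity at sample_id={df['sample_id'].iloc[r]!r}, "
            f"replicate_id={df['replicate_id'].iloc[r]!r}, feature={feats[c]!r}"
        )
    data = df[feats].copy()
    data.index = pd.MultiIndex.from_arrays(
        [df["sample_id"].astype(str), df["replicate_id"].astype(str)],
        names=["sample_id", "replicate_id"],
    )
    samples = (
        df[["sample_id", "source", "class"]]
        .astype(str)
        .drop_duplicates("sample_id")
        .set_index("sample_id")
    )
    return ReplicateMatrix(data, samples)


def write_sample_matrix(m: SampleMatrix, path) -> None:
    flat = m.data.reset_index()
    flat.columns = ["sample_id"] + list(m.data.columns)
    flat.insert(1, "source", m.samples["source"].to_numpy())
    flat.insert(2, "class", m.samples["class"].to_numpy())
    flat.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT, lineterminator="\n")


def read_sample_matrix(path) -> SampleMatrix:
    df = pd.read_csv(path, sep="\t")
    missing = set(_SAMPLE_META) - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: missing columns {sorted(missing)}")
    feats = [c for c in df.columns if c not in _SAMPLE_META]
    data = df[feats].astype(float)
    data.index = pd.Index(df["sample_id"].astype(str), name="sample_id")
    samples = df[["sample_id", "source", "class"]].astype(str).set_index("sample_id")
    return SampleMatrix(data, samples)


def dedupe_feature_labels(labels) -> list[str]:
    """Disambiguate duplicate integer m/z labels by appending ``.1``, ``.2``…"""
    seen: dict[str, int] = {}
    out = []
    for lab in labels:
        lab = str(lab)
        if lab in seen:
            seen[lab] += 1
            out.append(f"{lab}.{seen[lab]}")
        else:
            seen[lab] = 0
            out.append(lab)
    return out
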