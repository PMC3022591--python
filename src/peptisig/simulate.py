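"""Synthetic two-source serum-peptidome and clinical-marker generators.

The generator emulates the statistical structure of a two-biorepository
peptidome study with a third, control-only repository:

* per-feature multiplicative *source bias* (log-normal, drawn once per
  feature × source) — the "trend persists, intensity differs" regime;
* *concordant* features whose cancer-vs-control shift has the same sign in
  both case/control sources, *discordant* features with opposite signs, and
  *null* features with no class effect;
* per-sample biological variation and multiplicative log-normal replicate
  noise (mass-spectrometry intensity noise is scale-dependent);
* intensity-dependent zero dropout: a reading is recorded as 0 with
  probability ``1/(1+exp(steepness*(log I - log midpoint)))``, so missing
  readings concentrate at low intensity.

Ground truth (feature class, per-source effect signs and bias factors) is
returned alongside the data for parameter-recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import CLASS_CANCER, CLASS_CONTROL, ReplicateMatrix
from .preprocess import Spectrum

__all__ = [
    "GeneratorConfig",
    "FeatureTruth",
    "generate_dataset",
    "render_spectra",
    "generate_clinical_cohort",
    "DEFAULT_MARKER_PARAMS",
]

CONCORDANT_UP_CONTROL = "concordant_up_in_control"
CONCORDANT_UP_CANCER = "concordant_up_in_cancer"
DISCORDANT = "discordant"
NULL = "null"


class ConfigurationError(ValueError):
    pass


@dataclass(frozen=True)
class GeneratorConfig:
    """Study design and noise model for the synthetic peptidome generator.

    Defaults mirror the two-repository design the pipeline targets: 637
    features; sources A (21 control / 22 cancer), B (20 control / 40
    cancer) and a control-only source C (12 / 0); two replicates per
    sample. Effects and biases are on the natural-log intensity scale.
    """

    seed: int = 0
    n_features: int = 637
    sources: tuple = (("A", 21, 22), ("B", 20, 40), ("C", 12, 0))
    n_replicates: int = 2
    frac_concordant: float = 0.05
    frac_discordant: float = 0.02
    frac_null: float = 0.93
    effect_size: float = 1.2          # log-scale class shift of discriminative features
    source_bias_sd: float = 1.0       # s.d. of per-(feature, source) log bias
    sample_sd: float = 0.6            # per-sample biological log s.d.
    replicate_cv: float = 0.35        # coefficient of variation of replicate noise
    dropout_midpoint: float = 25.0    # intensity at which p(zero) = 1/2
    dropout_steepness: float = 2.5
    base_intensity_range: tuple = (50.0, 5000.0)
    mz_range: tuple = (900.0, 12000.0)
    min_mz_gap: float = 8.0

    def validate(self) -> None:
        fr = (self.frac_concordant, self.frac_discordant, self.frac_null)
        if any(f < 0 or f > 1 for f in fr):
            raise ConfigurationError("feature-class proportions must lie in [0, 1]")
        if abs(sum(fr) - 1.0) > 1e-9:
            raise ConfigurationError(f"feature-class proportions sum to {sum(fr)}, not 1")
        if self.n_features <= 0 or self.n_replicates <= 0:
            raise ConfigurationError("counts must be positive")
        for name, n_ctrl, n_can in self.sources:
            if n_ctrl < 0 or n_can < 0 or n_ctrl + n_can == 0:
                raise ConfigurationError(f"source {name!r} has no samples")
        if self.replicate_cv < 0 or self.sample_sd < 0 or self.source_bias_sd < 0:
            raise ConfigurationError("noise scales must be nonnegative")
        if self.dropout_midpoint <= 0:
            raise ConfigurationError("dropout_midpoint must be positive")

    def case_control_sources(self) -> list[str]:
        return [name for name, n_ctrl, n_can in self.sources if n_ctrl > 0 and n_can > 0]


@dataclass
class FeatureTruth:
    """Ground truth for one synthetic feature."""

    feature_id: str
    kind: str                          # one of the four feature classes
    effect: dict = field(default_factory=dict)   # source -> signed log effect
    bias: dict = field(default_factory=dict)     # source -> log bias factor


def _sample_mz_labels(rng: np.random.Generator, cfg: GeneratorConfig) -> np.ndarray:
    """Sorted feature m/z values with a minimum gap (keeps peaks resolvable)."""
    lo, hi = cfg.mz_range
    n, g = cfg.n_features, cfg.min_mz_gap
    span = hi - lo
    if span <= n * g:
        raise ConfigurationError("mz_range too narrow for n_features at min_mz_gap")
    gaps = rng.exponential(scale=(span - n * g) / (n + 1), size=n + 1)
    gaps *= (span - n * g) / gaps.sum()
    pos = lo + np.cumsum(gaps[:-1]) + g * np.arange(n)
    return pos


def _dropout_prob(intensity: np.ndarray, cfg: GeneratorConfig) -> np.ndarray:
    z = cfg.dropout_steepness * (np.log(intensity) - np.log(cfg.dropout_midpoint))
    return 1.0 / (1.0 + np.exp(z))


def generate_dataset(config: GeneratorConfig):
    """Generate a replicate-level dataset with known ground truth.

    Returns ``(ReplicateMatrix, samples table, list[FeatureTruth])``; the
    samples table is the matrix's own ``samples`` attribute, returned
    separately for convenience.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    nf = config.n_features

    mz = _sample_mz_labels(rng, config)
    from .containers import dedupe_feature_labels

    labels = dedupe_feature_labels([str(int(round(m))) for m in mz])

    # feature classes
    n_conc = int(round(config.frac_concordant * nf))
    n_disc = int(round(config.frac_discordant * nf))
    kinds = np.array([NULL] * nf, dtype=object)
    perm = rng.permutation(nf)
    conc_idx, disc_idx = perm[:n_conc], perm[n_conc : n_conc + n_disc]
    up_in_control = rng.random(n_conc) < 0.5
    kinds[conc_idx[up_in_control]] = CONCORDANT_UP_CONTROL
    kinds[conc_idx[~up_in_control]] = CONCORDANT_UP_CANCER
    kinds[disc_idx] = DISCORDANT

    src_names = [s[0] for s in config.sources]
    cc_sources = config.case_control_sources()

    # signed log effects per (feature, source); positive = up in control
    effect = {s: np.zeros(nf) for s in src_names}
    sign = np.zeros(nf)
    sign[kinds == CONCORDANT_UP_CONTROL] = 1.0
    sign[kinds == CONCORDANT_UP_CANCER] = -1.0
    for s in cc_sources:
        effect[s][conc_idx] = sign[conc_idx] * config.effect_size
    if len(cc_sources) >= 2 and n_disc:
        disc_sign = np.where(rng.random(n_disc) < 0.5, 1.0, -1.0)
        effect[cc_sources[0]][disc_idx] = disc_sign * config.effect_size
        effect[cc_sources[1]][disc_idx] = -disc_sign * config.effect_size

    bias = {s: rng.normal(0.0, config.source_bias_sd, size=nf) for s in src_names}
    log_lo, log_hi = np.log(config.base_intensity_range)
    base = rng.uniform(log_lo, log_hi, size=nf)

    sigma_rep = np.sqrt(np.log1p(config.replicate_cv**2))

    rows, index, meta = [], [], []
    for s_name, n_ctrl, n_can in config.sources:
        for cls, n in ((CLASS_CONTROL, n_ctrl), (CLASS_CANCER, n_can)):
            half = 0.5 if cls == CLASS_CONTROL else -0.5
            for i in range(n):
                sid = f"{s_name}_{'ctl' if cls == CLASS_CONTROL else 'can'}_{i:03d}"
                meta.append((sid, s_name, cls))
                sample_log = (
                    base
                    + bias[s_name]
                    + half * effect[s_name]
                    + rng.normal(0.0, config.sample_sd, size=nf)
                )
                for r in range(config.n_replicates):
                    val = np.exp(sample_log + rng.normal(0.0, sigma_rep, size=nf))
                    zero = rng.random(nf) < _dropout_prob(val, config)
                    val = np.where(zero, 0.0, val)
                    rows.append(val)
                    index.append((sid, f"r{r + 1}"))

    data = pd.DataFrame(
        np.array(rows),
        index=pd.MultiIndex.from_tuples(index, names=["sample_id", "replicate_id"]),
        columns=labels,
    )
    samples = (
        pd.DataFrame(meta, columns=["sample_id", "source", "class"]).set_index("sample_id")
    )
    truth = [
        FeatureTruth(
            labels[j],
            str(kinds[j]),
            effect={s: float(effect[s][j]) for s in src_names},
            bias={s: float(bias[s][j]) for s in src_names},
        )
        for j in range(nf)
    ]
    return ReplicateMatrix(data, samples), samples, truth


def truth_table(truth) -> pd.DataFrame:
    """FeatureTruth list as a flat DataFrame (for TSV export)."""
    rows = []
    for t in truth:
        row = {"feature_id": t.feature_id, "kind": t.kind}
        row.update({f"effect_{s}": v for s, v in t.effect.items()})
        row.update({f"bias_{s}": v for s, v in t.bias.items()})
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Continuous-spectrum rendering
# ---------------------------------------------------------------------------

def render_spectra(
    matrix: ReplicateMatrix,
    peak_width: float = 2.0,
    mz_range: tuple = (900.0, 12000.0),
    grid_step: float = 0.5,
    baseline_amplitude: float = 30.0,
    baseline_decay: float = 3000.0,
    noise_sd: float = 2.0,
    seed: int = 0,
) -> list[Spectrum]:
    """Render each replicate row as a continuous spectrum.

    Sum of Gaussian peaks (s.d. ``peak_width`` Da) centered at each
    feature's m/z with the row's intensities as apex amplitudes, plus an
    exponentially decaying baseline and additive Gaussian noise (clipped at
    zero). Zero-intensity entries produce no peak.
    """
    if peak_width <= 0:
        raise ValueError("peak_width must be positive")
    centers = np.array([float(str(c).split(".")[0]) for c in matrix.data.columns])
    lo, hi = mz_range
    if centers.min() < lo or centers.max() > hi:
        raise ValueError("feature m/z labels fall outside mz_range")
    rng = np.random.default_rng(seed)
    grid = np.arange(lo, hi + grid_step / 2, grid_step)
    baseline = baseline_amplitude * np.exp(-(grid - lo) / baseline_decay)
    meta = matrix.row_meta()

    reach = 5.0 * peak_width
    lo_idx = np.searchsorted(grid, centers - reach, side="left")
    hi_idx = np.searchsorted(grid, centers + reach, side="right")

    spectra = []
    for (sid, rid), row in matrix.data.iterrows():
        signal = baseline.copy()
        amps = row.to_numpy()
        for j in np.nonzero(amps)[0]:
            sl = slice(lo_idx[j], hi_idx[j])
            signal[sl] += amps[j] * np.exp(
                -((grid[sl] - centers[j]) ** 2) / (2.0 * peak_width**2)
            )
        if noise_sd > 0:
            signal = signal + rng.normal(0.0, noise_sd, size=grid.size)
        spectra.append(
            Spectrum(
                grid,
                np.clip(signal, 0.0, None),
                sample_id=str(sid),
                replicate_id=str(rid),
                source=str(meta.loc[(sid, rid), "source"]),
                label=str(meta.loc[(sid, rid), "class"]),
            )
        )
    return spectra


# ---------------------------------------------------------------------------
# Clinical-marker cohorts
# ---------------------------------------------------------------------------

#: per-marker per-class (log-location, log-scale) of log-normal serum levels.
#: Units: apoC_I µg/ml, apoC_III mg/dl, apoB_100 mg/dl, CRP µg/ml, CA19_9 U/ml.
#: apoC-I and apoC-III are higher in controls, CRP and CA19-9 elevated in
#: cancer, apoB-100 identical across classes (usable as a normalizer).
DEFAULT_MARKER_PARAMS: dict = {
    "apoC_I": {"control": (np.log(80.0), 0.40), "cancer": (np.log(50.0), 0.40)},
    "apoC_III": {"control": (np.log(12.0), 0.40), "cancer": (np.log(8.0), 0.40)},
    "apoB_100": {"control": (np.log(100.0), 0.30), "cancer": (np.log(100.0), 0.30)},
    "CRP": {"control": (np.log(3.0), 0.80), "cancer": (np.log(15.0), 0.80)},
    "CA19_9": {"control": (np.log(10.0), 1.00), "cancer": (np.log(40.0), 1.00)},
}

#: clinical-cohort sizes (source, n_control, n_cancer) mirroring the
#: clinical arm of the study design
DEFAULT_CLINICAL_SIZES = (("A", 33, 70), ("B", 19, 20))


def generate_clinical_cohort(
    seed: int = 0,
    sizes=DEFAULT_CLINICAL_SIZES,
    marker_params: dict | None = None,
) -> pd.DataFrame:
    """Generate a per-source clinical cohort of five serum markers.

    Returns a DataFrame with columns sample_id, source, class and the five
    marker columns; all values are positive (log-normal draws).
    """
    params = DEFAULT_MARKER_PARAMS if marker_params is None else marker_params
    for marker, by_class in params.items():
        for cls, (_, scale) in by_class.items():
            if scale <= 0:
                raise ConfigurationError(
                    f"non-positive log-scale for {marker}/{cls}"
                )
    rng = np.random.default_rng(seed)
    rows = []
    for s_name, n_ctrl, n_can in sizes:
        for cls, n in ((CLASS_CONTROL, n_ctrl), (CLASS_CANCER, n_can)):
            for i in range(n):
                rec = {
                    "sample_id": f"{s_name}_{'ctl' if cls == CLASS_CONTROL else 'can'}_{i:03d}",
                    "source": s_name,
                    "class": cls,
                }
                for marker, by_class in params.items():
                    mu, sigma = by_class[cls]
                    rec[marker] = float(np.exp(rng.normal(mu, sigma)))
                rows.append(rec)
    return pd.DataFrame(rows)
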