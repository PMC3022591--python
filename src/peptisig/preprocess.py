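"""Raw-spectrum preprocessing: resampling, alignment, peak detection, matrix build.

Converts collections of single MALDI-TOF spectra (two-column m/z vs
intensity text files) into the replicate-level intensity matrix the rest
of the pipeline consumes. The dialect implemented here is standard
linear-TOF peptidome practice:

* linear-interpolation resampling onto a uniform m/z grid (default 0.5 Da),
* global cross-correlation alignment against a reference spectrum,
* rolling-median baseline (default 50 Da window) with MAD-scaled noise,
* SNR-thresholded local-maximum peak picking with a minimum-separation
  exclusion rule,
* peak quantification as the windowed apex height above baseline, with
  sub-noise-floor readings stored as 0 (the missing-reading sentinel).

Every constant is a keyword argument so alternative dialects can be tested.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.ndimage import median_filter
from scipy.signal import find_peaks

from .containers import ReplicateMatrix, SchemaError, dedupe_feature_labels

__all__ = [
    "Spectrum",
    "PeakList",
    "resample_spectrum",
    "align_spectra",
    "mean_spectrum",
    "detect_peaks",
    "build_matrix",
    "read_spectrum",
    "write_spectrum",
    "read_spectra_manifest",
    "write_spectra_collection",
    "preprocess_spectra",
]


@dataclass
class Spectrum:
    """A single mass spectrum with its sample bookkeeping."""

    mz: np.ndarray
    intensity: np.ndarray
    sample_id: str = ""
    replicate_id: str = ""
    source: str = ""
    label: str = ""          # clinical class, "control"/"cancer"; may be empty

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.shape != self.intensity.shape:
            raise ValueError("mz and intensity must have equal length")
        if self.mz.size and not np.all(np.diff(self.mz) > 0):
            raise ValueError("mz must be strictly increasing")
        if (self.intensity < 0).any():
            raise ValueError("negative intensity in spectrum")

    @property
    def step(self) -> float:
        return float(self.mz[1] - self.mz[0]) if self.mz.size > 1 else float("nan")


@dataclass
class PeakList:
    """Detected peak apexes with a shared per-peak window half-width (Da)."""

    apex_mz: np.ndarray
    half_width: float

    def __post_init__(self) -> None:
        self.apex_mz = np.asarray(self.apex_mz, dtype=float)
        if self.apex_mz.size and not np.all(np.diff(self.apex_mz) > 0):
            raise ValueError("peak apexes must be strictly increasing")
        if self.half_width <= 0:
            raise ValueError("half_width must be positive")

    def __len__(self) -> int:
        return int(self.apex_mz.size)


def resample_spectrum(s: Spectrum, grid: np.ndarray) -> Spectrum:
    """Linearly interpolate a spectrum onto ``grid`` (must lie within its span)."""
    grid = np.asarray(grid, dtype=float)
    if grid[0] < s.mz[0] or grid[-1] > s.mz[-1]:
        raise ValueError(
            f"grid [{grid[0]}, {grid[-1]}] outside spectrum span [{s.mz[0]}, {s.mz[-1]}]"
        )
    return replace(s, mz=grid, intensity=np.interp(grid, s.mz, s.intensity))


def _best_lag(x: np.ndarray, ref: np.ndarray, max_lag: int) -> int:
    """Integer lag in [-max_lag, max_lag] maximizing cross-correlation of
    ``x`` shifted by the lag against ``ref``; ties go to the smallest |lag|."""
    lags = np.arange(-max_lag, max_lag + 1)
    scores = np.empty(lags.size)
    n = x.size
    for i, lag in enumerate(lags):
        if lag >= 0:
            scores[i] = float(np.dot(x[: n - lag], ref[lag:])) if lag < n else -np.inf
        else:
            scores[i] = float(np.dot(x[-lag:], ref[: n + lag]))
    order = np.lexsort((np.abs(lags), -scores))
    return int(lags[order[0]])


def _shift(x: np.ndarray, lag: int) -> np.ndarray:
    """Shift by ``lag`` bins (positive = toward higher m/z), zero-filling edges."""
    out = np.zeros_like(x)
    if lag == 0:
        out[:] = x
    elif lag > 0:
        out[lag:] = x[: x.size - lag]
    else:
        out[:lag] = x[-lag:]
    return out


def align_spectra(spectra, reference: Spectrum, max_shift: float) -> tuple[list[Spectrum], list[int]]:
    """Shift each spectrum onto the reference by its best integer-bin lag.

    All spectra must already share the reference's grid. ``max_shift`` is in
    Da and is refused above 10% of the grid span (a guard against
    pathological alignments). Returns the shifted spectra and the applied
    lags (in bins).
    """
    step = reference.step
    span = reference.mz[-1] - reference.mz[0]
    if max_shift > 0.1 * span:
        raise ValueError(f"max_shift {max_shift} exceeds 10% of grid span {span}")
    max_lag = max(1, int(round(max_shift / step)))
    out, lags = [], []
    for s in spectra:
        if s.mz.shape != reference.mz.shape or not np.allclose(s.mz, reference.mz):
            raise ValueError("spectra must be resampled to the reference grid before alignment")
        # the lag that best overlays s onto the reference
        lag = _best_lag(s.intensity, reference.intensity, max_lag)
        out.append(replace(s, intensity=_shift(s.intensity, lag)))
        lags.append(lag)
    return out, lags


def mean_spectrum(spectra) -> Spectrum:
    ref = spectra[0]
    stack = np.stack([s.intensity for s in spectra])
    return Spectrum(ref.mz, stack.mean(axis=0), sample_id="<mean>")


def _baseline_and_noise(intensity: np.ndarray, step: float, baseline_window: float):
    win = max(3, int(round(baseline_window / step)) | 1)  # odd window
    baseline = median_filter(intensity, size=win, mode="nearest")
    resid = intensity - baseline
    noise = 1.4826 * float(np.median(np.abs(resid - np.median(resid))))
    return baseline, resid, max(noise, 1e-12)


def detect_peaks(
    spectrum: Spectrum,
    snr_threshold: float = 5.0,
    min_separation: float = 4.0,
    baseline_window: float = 50.0,
) -> PeakList:
    """Pick peaks from a (mean) spectrum.

    Local maxima of the baseline-subtracted signal whose height exceeds
    ``snr_threshold`` times the MAD-scaled noise, accepted greedily in
    decreasing height with a ``min_separation`` (Da) exclusion zone.
    """
    if spectrum.mz.size == 0:
        raise ValueError("empty spectrum")
    step = spectrum.step
    _, resid, noise = _baseline_and_noise(spectrum.intensity, step, baseline_window)
    distance = max(1, int(round(min_separation / step)))
    idx, _ = find_peaks(resid, height=snr_threshold * noise, distance=distance)
    return PeakList(spectrum.mz[idx], half_width=min_separation / 2.0)


def build_matrix(
    spectra,
    peaks: PeakList,
    baseline_window: float = 50.0,
    noise_floor_snr: float = 3.0,
) -> ReplicateMatrix:
    """Quantify each peak in each spectrum as the windowed apex height.

    Entry = maximum baseline-subtracted intensity within ±half_width of the
    apex; values below ``noise_floor_snr`` × the spectrum's noise scale (or
    negative) are stored as 0, the missing-reading sentinel. Columns are
    labeled by integer-rounded apex m/z, duplicates suffixed ``.1``, ``.2``…
    """
    if len(peaks) == 0:
        raise ValueError("empty PeakList")
    labels = dedupe_feature_labels([str(int(round(a))) for a in peaks.apex_mz])
    rows, index, meta = [], [], []
    for s in spectra:
        _, resid, noise = _baseline_and_noise(s.intensity, s.step, baseline_window)
        lo = np.searchsorted(s.mz, peaks.apex_mz - peaks.half_width, side="left")
        hi = np.searchsorted(s.mz, peaks.apex_mz + peaks.half_width, side="right")
        vals = np.array(
            [resid[a:b].max() if b > a else 0.0 for a, b in zip(lo, hi)]
        )
        vals[vals < noise_floor_snr * noise] = 0.0
        rows.append(vals)
        index.append((s.sample_id, s.replicate_id))
        meta.append((s.sample_id, s.source, s.label))
    data = pd.DataFrame(
        np.array(rows),
        index=pd.MultiIndex.from_tuples(index, names=["sample_id", "replicate_id"]),
        columns=labels,
    )
    samples = (
        pd.DataFrame(meta, columns=["sample_id", "source", "class"])
        .drop_duplicates("sample_id")
        .set_index("sample_id")
    )
    return ReplicateMatrix(data, samples)


def preprocess_spectra(
    spectra,
    grid_step: float = 0.5,
    max_shift: float = 2.0,
    snr_threshold: float = 5.0,
    min_separation: float = 4.0,
    baseline_window: float = 50.0,
    noise_floor_snr: float = 3.0,
) -> tuple[ReplicateMatrix, PeakList]:
    """Full preprocessing chain: resample → align → detect → quantify."""
    lo = max(s.mz[0] for s in spectra)
    hi = min(s.mz[-1] for s in spectra)
    grid = np.arange(lo, hi + grid_step / 2, grid_step)
    resampled = [resample_spectrum(s, grid) for s in spectra]
    aligned, _ = align_spectra(resampled, resampled[0], max_shift)
    peaks = detect_peaks(
        mean_spectrum(aligned), snr_threshold, min_separation, baseline_window
    )
    matrix = build_matrix(aligned, peaks, baseline_window, noise_floor_snr)
    return matrix, peaks


# ---------------------------------------------------------------------------
# Spectrum files: two-column text + manifest TSV
# ---------------------------------------------------------------------------

def write_spectrum(s: Spectrum, path) -> None:
    np.savetxt(path, np.column_stack([s.mz, s.intensity]), fmt="%.6g", delimiter="\t")


def read_spectrum(path, **meta) -> Spectrum:
    arr = np.loadtxt(path, delimiter="\t", ndmin=2)
    return Spectrum(arr[:, 0], arr[:, 1], **meta)


def write_spectra_collection(spectra, out_dir) -> str:
    """Write spectra as two-column text plus a manifest TSV; returns manifest path."""
    os.makedirs(out_dir, exist_ok=True)
    rows = []
    for s in spectra:
        name = f"{s.sample_id}_{s.replicate_id}.txt"
        write_spectrum(s, os.path.join(out_dir, name))
        rows.append((name, s.sample_id, s.replicate_id, s.source, s.label))
    manifest = pd.DataFrame(
        rows, columns=["path", "sample_id", "replicate_id", "source", "class"]
    )
    mpath = os.path.join(out_dir, "manifest.tsv")
    manifest.to_csv(mpath, sep="\t", index=False, lineterminator="\n")
    return mpath


def read_spectra_manifest(manifest_path) -> list[Spectrum]:
    manifest = pd.read_csv(manifest_path, sep="\t")
    required = {"path", "sample_id", "replicate_id", "source", "class"}
    missing = required - set(manifest.columns)
    if missing:
        raise SchemaError(f"{manifest_path}: manifest missing columns {sorted(missing)}")
    base = os.path.dirname(os.fspath(manifest_path))
    out = []
    for _, r in manifest.iterrows():
        p = r["path"] if os.path.isabs(str(r["path"])) else os.path.join(base, str(r["path"]))
        out.append(
            read_spectrum(
                p,
                sample_id=str(r["sample_id"]),
                replicate_id=str(r["replicate_id"]),
                source=str(r["source"]),
                label=str(r["class"]),
            )
        )
    return out


def read_mzml(path) -> list[Spectrum]:
    """Optional mzML reader (requires pyteomics)."""
    from pyteomics import mzml as _mzml

    out = []
    with _mzml.MzML(os.fspath(path)) as reader:
        for i, scan in enumerate(reader):
            out.append(
                Spectrum(scan["m/z array"], scan["intensity array"], sample_id=str(i))
            )
    return out
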