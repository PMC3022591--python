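"""Synthetic-data generator: determinism, ground-truth structure, dropout, cohorts."""

import numpy as np
import pandas as pd
import pytest

from peptisig import GeneratorConfig, generate_clinical_cohort, generate_dataset, render_spectra
from peptisig.clinical import group_compare
from peptisig.containers import CLASS_CANCER, CLASS_CONTROL
from peptisig.selection import rank_test_pvalue
from peptisig.simulate import (
    CONCORDANT_UP_CANCER,
    CONCORDANT_UP_CONTROL,
    DISCORDANT,
    ConfigurationError,
    _dropout_prob,
)

from conftest import SMALL_CONFIG


def class_means(rm, source, feature):
    meta = rm.row_meta()
    out = {}
    for cls in (CLASS_CONTROL, CLASS_CANCER):
        sel = ((meta["source"] == source) & (meta["class"] == cls)).to_numpy()
        vals = rm.data.loc[sel, feature]
        vals = vals[vals > 0]
        out[cls] = float(np.log(vals).mean())
    return out


def test_same_seed_gives_byte_identical_output(tmp_path):
    from peptisig import write_replicate_matrix

    for i in (1, 2):
        rm, _, _ = generate_dataset(SMALL_CONFIG)
        write_replicate_matrix(rm, tmp_path / f"m{i}.tsv")
    assert (tmp_path / "m1.tsv").read_bytes() == (tmp_path / "m2.tsv").read_bytes()


@pytest.mark.parametrize(
    "kwargs",
    [
        {"frac_concordant": 0.5, "frac_discordant": 0.5, "frac_null": 0.5},
        {"frac_concordant": -0.1, "frac_discordant": 0.2, "frac_null": 0.9},
        {"n_features": 0},
        {"n_replicates": 0},
        {"sources": (("A", 0, 0),)},
        {"dropout_midpoint": 0.0},
    ],
)
def test_invalid_configuration_rejected(kwargs):
    cfg = GeneratorConfig(**kwargs)
    with pytest.raises(ConfigurationError):
        cfg.validate()


def test_all_intensities_nonnegative(small_dataset):
    rm, _, _ = small_dataset
    assert (rm.data.to_numpy() >= 0).all()


def test_third_source_contains_only_controls(small_dataset):
    rm, samples, _ = small_dataset
    c = samples[samples["source"] == "C"]
    assert set(c["class"]) == {CLASS_CONTROL}


def test_discordant_features_have_opposite_class_trends(small_dataset):
    """A discordant feature's control-minus-cancer sign flips between sources,
    both in the declared truth and in the realized data."""
    rm, _, truth = small_dataset
    disc = [t for t in truth if t.kind == DISCORDANT]
    assert disc, "small config should plant discordant features"
    for t in disc:
        assert t.effect["A"] == -t.effect["B"] != 0
        dA = class_means(rm, "A", t.feature_id)
        dB = class_means(rm, "B", t.feature_id)
        gapA = dA[CLASS_CONTROL] - dA[CLASS_CANCER]
        gapB = dB[CLASS_CONTROL] - dB[CLASS_CANCER]
        assert np.sign(t.effect["A"]) == np.sign(gapA)
        assert np.sign(gapA) == -np.sign(gapB)


def test_concordant_features_share_trend_across_sources(small_dataset):
    rm, _, truth = small_dataset
    for t in truth:
        if t.kind in (CONCORDANT_UP_CONTROL, CONCORDANT_UP_CANCER):
            assert t.effect["A"] == t.effect["B"] != 0


def test_dropout_rate_decreases_with_intensity(default_dataset):
    """Empirical zero-rate per feature-intensity decile is non-increasing."""
    rm, _, _ = default_dataset
    X = rm.data.to_numpy()
    nz_mean = np.where(X > 0, X, np.nan)
    feat_mean = np.nanmean(nz_mean, axis=0)
    zero_rate = (X == 0).mean(axis=0)
    deciles = pd.qcut(feat_mean, 10, labels=False, duplicates="drop")
    rates = [zero_rate[deciles == d].mean() for d in range(int(deciles.max()) + 1)]
    diffs = np.diff(rates)
    assert (diffs <= 0.02).all(), rates  # small sampling-noise allowance


def test_dropout_curve_is_monotone_logistic():
    cfg = GeneratorConfig()
    x = np.geomspace(1, 1e5, 200)
    p = _dropout_prob(x, cfg)
    assert (np.diff(p) < 0).all()
    assert _dropout_prob(np.array([cfg.dropout_midpoint]), cfg) == pytest.approx(0.5)


def test_null_config_gives_uniform_pvalue_fraction():
    """With zero effect size, ~5% of features reach p<0.05 by chance."""
    from peptisig import average_replicates, filter_zero_features, mannwhitney_pvalues

    fracs = []
    for seed in range(3):
        cfg = GeneratorConfig(
            seed=seed, n_features=150, effect_size=0.0,
            sources=(("A", 15, 15), ("B", 15, 15)),
        )
        rm, _, _ = generate_dataset(cfg)
        sm, _ = filter_zero_features(average_replicates(rm))
        pv = mannwhitney_pvalues(sm)
        fracs.append(float((pv < 0.05).mean()))
    assert 0.0 <= np.median(fracs) < 0.12


# ---------------------------------------------------------------------------
# spectrum rendering
# ---------------------------------------------------------------------------

def one_feature_matrix(amplitudes, mz_label="5000"):
    from conftest import toy_replicate_matrix

    vals = np.asarray(amplitudes, dtype=float).reshape(-1, 1)
    return toy_replicate_matrix(vals, classes=[CLASS_CONTROL] * vals.shape[0],
                                features=[mz_label])


def test_rendered_peak_apex_at_feature_mz():
    rm = one_feature_matrix([100.0])
    spectra = render_spectra(rm, peak_width=2.0, mz_range=(4000.0, 6000.0), noise_sd=0.0)
    s = spectra[0]
    apex = s.mz[np.argmax(s.intensity)]
    assert abs(apex - 5000.0) <= 2.0


def test_all_zero_intensities_render_baseline_only():
    rm = one_feature_matrix([0.0])
    spectra = render_spectra(
        rm, mz_range=(4000.0, 6000.0), noise_sd=0.0,
        baseline_amplitude=30.0, baseline_decay=3000.0,
    )
    s = spectra[0]
    expected = 30.0 * np.exp(-(s.mz - 4000.0) / 3000.0)
    np.testing.assert_allclose(s.intensity, expected)


def test_apex_heights_match_amplitudes_within_5pct():
    """Well-separated peaks of amplitude 50 and 100 rise above baseline by
    their planted amplitudes (evaluated against the generative formula)."""
    from conftest import toy_replicate_matrix

    rm = toy_replicate_matrix(
        np.array([[50.0, 100.0]]), classes=[CLASS_CONTROL], features=["3000", "5000"]
    )
    spectra = render_spectra(rm, peak_width=2.0, mz_range=(2000.0, 6000.0),
                             noise_sd=0.0, baseline_amplitude=20.0, baseline_decay=3000.0)
    s = spectra[0]
    baseline = 20.0 * np.exp(-(s.mz - 2000.0) / 3000.0)
    for center, amp in ((3000.0, 50.0), (5000.0, 100.0)):
        window = np.abs(s.mz - center) <= 4.0
        height = (s.intensity - baseline)[window].max()
        assert abs(height - amp) / amp < 0.05


def test_render_rejects_nonpositive_peak_width():
    rm = one_feature_matrix([1.0])
    with pytest.raises(ValueError):
        render_spectra(rm, peak_width=0.0, mz_range=(4000.0, 6000.0))


def test_render_rejects_features_outside_range():
    rm = one_feature_matrix([1.0], mz_label="5000")
    with pytest.raises(ValueError):
        render_spectra(rm, mz_range=(6000.0, 9000.0))


# ---------------------------------------------------------------------------
# clinical cohorts
# ---------------------------------------------------------------------------

def test_clinical_cohort_reproducible_and_positive():
    a = generate_clinical_cohort(seed=5)
    b = generate_clinical_cohort(seed=5)
    pd.testing.assert_frame_equal(a, b)
    for m in ("apoC_I", "apoC_III", "apoB_100", "CRP", "CA19_9"):
        assert (a[m] > 0).all()


def test_apoc3_higher_in_controls_at_default_effect():
    cohort = generate_clinical_cohort(seed=2, sizes=(("A", 200, 200),))
    ctrl = cohort.loc[cohort["class"] == CLASS_CONTROL, "apoC_III"]
    can = cohort.loc[cohort["class"] == CLASS_CANCER, "apoC_III"]
    assert group_compare(ctrl, can, "greater") < 0.01


def test_apob100_has_no_class_trend():
    """The normalizing denominator is null by design: two-sided rank-test
    p-values look uniform across seeds."""
    ps = []
    for seed in range(10):
        cohort = generate_clinical_cohort(seed=seed, sizes=(("A", 60, 60),))
        ctrl = cohort.loc[cohort["class"] == CLASS_CONTROL, "apoB_100"]
        can = cohort.loc[cohort["class"] == CLASS_CANCER, "apoB_100"]
        ps.append(rank_test_pvalue(ctrl.to_numpy(), can.to_numpy()))
    assert 0.2 < np.mean(ps) < 0.8
    assert max(ps) > 0.2  # not systematically significant


def test_nonpositive_marker_scale_rejected():
    bad = {
        "apoC_I": {"control": (1.0, 0.0), "cancer": (1.0, 0.4)},
        "apoC_III": {"control": (1.0, 0.4), "cancer": (1.0, 0.4)},
        "apoB_100": {"control": (1.0, 0.4), "cancer": (1.0, 0.4)},
        "CRP": {"control": (1.0, 0.4), "cancer": (1.0, 0.4)},
        "CA19_9": {"control": (1.0, 0.4), "cancer": (1.0, 0.4)},
    }
    with pytest.raises(ConfigurationError):
        generate_clinical_cohort(seed=0, marker_params=bad)
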