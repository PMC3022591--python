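"""Linear-margin training, MCC, cross-validation, influence, permutation, tau."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import pearsonr

from peptisig import (
    EvaluationReport,
    FilterParams,
    LinearMarginModel,
    PeptidomeClassifier,
    cross_validate,
    evaluate,
    feature_influence,
    marker_concordance,
    mcc,
    permutation_control,
    train,
)
from peptisig.containers import CLASS_CANCER, CLASS_CONTROL

from conftest import toy_sample_matrix


def separable_frame(n=10, margin=5.0, seed=0):
    rng = np.random.default_rng(seed)
    X = pd.DataFrame(rng.normal(size=(2 * n, 3)) * 0.1, columns=["a", "b", "c"])
    X.iloc[:n, 0] += margin
    X.iloc[n:, 0] -= margin
    labels = np.array([CLASS_CONTROL] * n + [CLASS_CANCER] * n)
    return X, labels


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

def test_separable_data_trains_to_perfect_accuracy():
    X, labels = separable_frame()
    model = train(X, labels)
    rep = evaluate(model, X, labels)
    assert rep.accuracy == 1.0


def test_inverted_labels_negate_the_decision_function():
    X, labels = separable_frame()
    inverted = np.where(labels == CLASS_CONTROL, CLASS_CANCER, CLASS_CONTROL)
    m1, m2 = train(X, labels), train(X, inverted)
    np.testing.assert_allclose(m1.weights.to_numpy(), -m2.weights.to_numpy(), atol=1e-6)
    assert m1.intercept == pytest.approx(-m2.intercept, abs=1e-6)


def test_duplicating_every_sample_keeps_the_boundary():
    X, labels = separable_frame()
    m1 = train(X, labels)
    m2 = train(pd.concat([X, X], ignore_index=True), np.concatenate([labels, labels]))
    np.testing.assert_allclose(m1.weights.to_numpy(), m2.weights.to_numpy(), atol=1e-6)


def test_single_class_input_is_an_error():
    X, _ = separable_frame()
    with pytest.raises(ValueError):
        train(X, np.array([CLASS_CONTROL] * len(X)))


def test_positive_decision_value_means_control():
    X, labels = separable_frame()
    model = train(X, labels)
    d = model.decision_value(X)
    assert (d[:10] > 0).all() and (d[10:] < 0).all()
    assert list(model.predict(X)) == list(labels)


# ---------------------------------------------------------------------------
# MCC
# ---------------------------------------------------------------------------

def test_perfect_and_random_confusion_tables():
    assert mcc(10, 0, 10, 0) == 1.0
    assert mcc(1, 1, 1, 1) == 0.0


def test_zero_marginal_convention():
    assert mcc(0, 0, 5, 5) == 0.0


def test_negative_counts_rejected():
    with pytest.raises(ValueError):
        mcc(-1, 0, 1, 0)


def test_mcc_equals_pearson_correlation_of_binary_vectors():
    """Oracle check on 200 random confusion tables: the MCC formula equals
    the Pearson correlation of the truth/prediction indicator vectors."""
    rng = np.random.default_rng(9)
    for _ in range(200):
        tp, fp, tn, fn = rng.integers(1, 30, size=4)
        truth = np.array([1] * tp + [0] * fp + [0] * tn + [1] * fn)
        pred = np.array([1] * tp + [1] * fp + [0] * tn + [0] * fn)
        r = pearsonr(truth, pred).statistic
        assert mcc(tp, fp, tn, fn) == pytest.approx(r, abs=1e-12)


@settings(deadline=None, max_examples=50, derandomize=True)
@given(st.integers(0, 50), st.integers(0, 50), st.integers(0, 50), st.integers(0, 50))
def test_mcc_invariant_under_class_swap(tp, fp, tn, fn):
    if tp + fp + tn + fn == 0:
        return
    assert mcc(tp, fp, tn, fn) == pytest.approx(mcc(tn, fn, tp, fp))


def test_report_rates_agree_with_recomputation():
    X, labels = separable_frame(seed=4)
    model = train(X, labels)
    rep = evaluate(model, X, labels)
    pred = model.predict(X)
    manual = EvaluationReport.from_predictions(labels, pred)
    assert (rep.tp, rep.fp, rep.tn, rep.fn) == (manual.tp, manual.fp, manual.tn, manual.fn)
    assert rep.accuracy == pytest.approx((pred == labels).mean())
    assert rep.mcc == pytest.approx(mcc(rep.tp, rep.fp, rep.tn, rep.fn))


# ---------------------------------------------------------------------------
# cross-validation
# ---------------------------------------------------------------------------

def test_separable_data_cross_validates_perfectly():
    X, labels = separable_frame(n=15)
    assert cross_validate(X, labels, k=5, seed=0) == 1.0


def test_null_features_cross_validate_near_chance():
    rng = np.random.default_rng(10)
    accs = []
    for seed in range(25):
        X = pd.DataFrame(rng.normal(size=(40, 3)))
        labels = np.array([CLASS_CONTROL] * 20 + [CLASS_CANCER] * 20)
        accs.append(cross_validate(X, labels, k=5, seed=seed))
    assert abs(np.mean(accs) - 0.5) < 0.1


def test_leave_one_out_matches_manual_enumeration():
    """k = n on 4 samples: fold-by-fold accuracy recomputed by hand with the
    same margin solver."""
    X = pd.DataFrame({"a": [2.0, 1.5, -1.5, -2.0], "b": [0.1, -0.1, 0.1, -0.1]})
    labels = np.array([CLASS_CONTROL, CLASS_CONTROL, CLASS_CANCER, CLASS_CANCER])
    got = cross_validate(X, labels, k=4, seed=0)
    manual = []
    for i in range(4):
        tr = [j for j in range(4) if j != i]
        m = train(X.iloc[tr], labels[tr])
        manual.append(float(m.predict(X.iloc[[i]])[0] == labels[i]))
    assert got == pytest.approx(np.mean(manual))


def test_k_larger_than_n_rejected():
    X, labels = separable_frame(n=3)
    with pytest.raises(ValueError):
        cross_validate(X, labels, k=7)


# ---------------------------------------------------------------------------
# influence
# ---------------------------------------------------------------------------

def test_influence_closed_form_and_sign_convention():
    model = LinearMarginModel(pd.Series({"x": 2.0, "y": 0.0, "z": -1.5}), intercept=0.3)
    maxima = pd.Series({"x": 5.0, "y": 100.0, "z": 2.0, "unused": 50.0})
    infl = feature_influence(model, maxima)
    assert infl["x"] == pytest.approx(10.0)    # weight 2 × maximum 5
    assert infl["y"] == 0.0                    # zero weight
    assert infl["z"] == pytest.approx(-3.0)    # negative pushes toward cancer
    assert infl["unused"] == 0.0               # absent from the model


def test_model_results_object_reports_influence_and_summary():
    X, labels = separable_frame()
    res = PeptidomeClassifier(X, labels).fit()
    infl = res.influence()
    assert infl["a"] > 0  # feature elevated in controls pushes toward control
    assert "influence" in res.summary()


# ---------------------------------------------------------------------------
# permutation control
# ---------------------------------------------------------------------------

def test_shuffling_destroys_a_real_signal():
    rng = np.random.default_rng(11)
    X = rng.lognormal(3, 0.4, size=(30, 12))
    X[:15, :4] *= 3.0
    sm = toy_sample_matrix(X, classes=[CLASS_CONTROL] * 15 + [CLASS_CANCER] * 15)
    res = permutation_control(sm, params=FilterParams(0.05, None),
                              n_shuffles=10, cv_folds=5, seed=0)
    assert np.median(res.shuffled_accuracies) < res.unshuffled_accuracy - 0.2
    assert res.unshuffled_median_p < np.median(res.shuffled_median_p)


def test_permutation_control_requires_at_least_one_shuffle():
    sm = toy_sample_matrix(np.ones((4, 2)) + np.arange(4)[:, None],
                           classes=[CLASS_CONTROL] * 2 + [CLASS_CANCER] * 2)
    with pytest.raises(ValueError):
        permutation_control(sm, params=FilterParams(0.5, None), n_shuffles=0)


# ---------------------------------------------------------------------------
# concordance
# ---------------------------------------------------------------------------

def test_kendall_tau_worked_examples():
    assert marker_concordance([1, 2, 3, 4], [2, 4, 6, 8])[0] == pytest.approx(1.0)
    assert marker_concordance([1, 2, 3, 4], [-1, -2, -3, -4])[0] == pytest.approx(-1.0)
    tau, _ = marker_concordance([1, 2, 3], [1, 3, 2])
    assert tau == pytest.approx(1 / 3)  # 2 concordant − 1 discordant over 3 pairs


def test_constant_vector_is_an_error_state():
    with pytest.raises(ValueError):
        marker_concordance([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
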