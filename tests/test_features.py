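"""Feature extraction, permutation importance, and BP regressors."""

import numpy as np
import pandas as pd
import pytest

from scalebp.features import (
    ALL_FEATURES,
    FEATURE_SETS,
    RegressorConfig,
    aggregate_fold_metrics,
    cross_validate,
    extract_features,
    fit_bp_regressor,
    permutation_importance,
)


def _beats(ptt1, ptt2, hr):
    return pd.DataFrame({"ptt1_ms": ptt1, "ptt2_ms": ptt2, "hr_bpm": hr})


def test_feature_arithmetic():
    beats = _beats([298.0, 302.0], [378.0, 382.0], [72.0, 78.0])
    f = extract_features(beats, sbp_rest=120.0, dbp_rest=80.0)
    assert f["mPTT1"] == pytest.approx(300.0)
    assert f["PTT1_SYS"] == pytest.approx(2.5)
    assert f["PTT1_DIA"] == pytest.approx(3.75)
    assert f["mPTT2"] == pytest.approx(380.0)
    assert f["Ratio"] == pytest.approx(300.0 / 380.0)
    assert f["mHR"] == pytest.approx(75.0)


def test_ratio_unity_when_ptts_equal():
    beats = _beats([300.0, 300.0], [300.0, 300.0], [70.0, 70.0])
    f = extract_features(beats, 120.0, 80.0)
    assert f["Ratio"] == pytest.approx(1.0)


def test_feature_extraction_requires_two_beats_and_rest_bp():
    one = _beats([300.0], [380.0], [70.0])
    with pytest.raises(ValueError):
        extract_features(one, 120.0, 80.0)
    two = _beats([300.0, 300.0], [380.0, 380.0], [70.0, 70.0])
    with pytest.raises(ValueError):
        extract_features(two, 0.0, 80.0)


def test_feature_extraction_order_invariant():
    beats = _beats([290.0, 310.0, 300.0], [370.0, 390.0, 380.0], [60.0, 80.0, 70.0])
    f1 = extract_features(beats, 120.0, 80.0)
    f2 = extract_features(beats.iloc[::-1], 120.0, 80.0)
    assert f1 == f2


def test_permutation_importance_constant_feature_zero():
    rng = np.random.default_rng(0)
    X = np.column_stack([rng.normal(size=200), np.full(200, 3.0)])
    y = 2.0 * X[:, 0]
    cfg = RegressorConfig(model="xgb", seed=0)
    from scalebp.features import _make_estimator

    est = _make_estimator(cfg).fit(X, y)
    imp = permutation_importance(est, X, y, n_repeats=5, seed=0)
    assert imp[1] == pytest.approx(0.0, abs=1e-12)
    assert imp[0] > 0.5


def test_permutation_importance_finds_dominant_feature():
    rng = np.random.default_rng(1)
    X = rng.normal(size=(400, 4))
    y = 3.0 * X[:, 2] + 0.05 * rng.normal(size=400)
    from scalebp.features import _make_estimator

    est = _make_estimator(RegressorConfig(model="rf", seed=1)).fit(X, y)
    imp = permutation_importance(est, X, y, n_repeats=5, seed=1)
    assert imp[2] > 10 * max(imp[0], imp[1], imp[3])


def test_permutation_importance_matches_sklearn():
    from sklearn.inspection import permutation_importance as sk_imp
    from scalebp.features import _make_estimator

    rng = np.random.default_rng(2)
    X = rng.normal(size=(500, 3))
    y = X[:, 0] + 0.5 * X[:, 1] + 0.1 * rng.normal(size=500)
    est = _make_estimator(RegressorConfig(model="rf", seed=2)).fit(X, y)
    ours = permutation_importance(est, X, y, n_repeats=20, seed=2)
    ref = sk_imp(est, X, y, n_repeats=20, random_state=2, scoring="r2")
    np.testing.assert_allclose(ours, ref.importances_mean, atol=0.05)


def test_ratio_importance_negligible_on_cohort(cohort_features):
    """Ratio carries no BP information next to the other seven parameters."""
    from scalebp.features import _make_estimator

    tab = cohort_features
    X = tab[list(ALL_FEATURES)].to_numpy(float)
    y = tab["sbp_mmHg"].to_numpy()
    est = _make_estimator(RegressorConfig(model="xgb", seed=0)).fit(X, y)
    imp = permutation_importance(est, X, y, n_repeats=5, seed=0)
    scores = dict(zip(ALL_FEATURES, imp))
    assert scores["Ratio"] < 0.1 * max(scores.values())


def test_regressor_fits_constant_target(cohort_features):
    tab = cohort_features.head(200)
    for model in ("rf", "xgb"):
        cfg = RegressorConfig(model=model, seed=0)
        est = fit_bp_regressor(tab, np.full(len(tab), 100.0), cfg)
        pred = est.predict(tab[list(cfg.features)].to_numpy(float))
        np.testing.assert_allclose(pred, 100.0, atol=1e-3)


def test_regressor_input_validation(cohort_features):
    cfg = RegressorConfig(model="rf")
    with pytest.raises(ValueError):
        fit_bp_regressor(cohort_features.head(5), np.ones(5), cfg)
    bad = cohort_features.head(20).copy()
    bad.loc[bad.index[0], "mPTT2"] = np.nan
    with pytest.raises(ValueError):
        fit_bp_regressor(bad, np.ones(20), cfg)


def test_feature_sets():
    assert set(FEATURE_SETS["all7"]) == set(ALL_FEATURES) - {"Ratio"}
    assert "Ratio" not in FEATURE_SETS["calibration_free"]
    with pytest.raises(ValueError):
        RegressorConfig(feature_set="all8")


def test_fold_aggregation_convention():
    mean, sd = aggregate_fold_metrics([0.9381, 0.9392, 0.9386, 0.9592, 0.9591])
    assert round(mean, 3) == 0.947
    assert round(sd, 3) == 0.010
    mean, sd = aggregate_fold_metrics([3.0, 3.0, 3.0])
    assert (mean, sd) == (3.0, 0.0)


def test_cross_validation_structure(cohort_features):
    tab = cohort_features.head(600)
    cfg = RegressorConfig(model="xgb", seed=0)
    out = cross_validate(tab, tab["sbp_mmHg"], cfg, k=5, seed=0)
    assert len(out["fold_pcc"]) == 5
    m, s = aggregate_fold_metrics(out["fold_pcc"])
    assert out["pcc_mean"] == pytest.approx(m)
    assert out["pcc_sd"] == pytest.approx(s)
    with pytest.raises(ValueError):
        cross_validate(tab.head(3), tab["sbp_mmHg"].head(3), cfg, k=5)


def test_noisier_coupling_degrades_pcc():
    """More beat-timing noise in the PTT-BP relation lowers held-out PCC."""
    from scalebp.evaluation import pearson
    from scalebp.segmentation import split_dataset
    from scalebp.simulate import simulate_cohort_features

    pccs = []
    for noise in (1.0, 30.0):
        tab = simulate_cohort_features(1200, seed=5, interval_noise_ms=noise)
        tr, te = split_dataset(len(tab), (0.8, 0.2), seed=5)
        cfg = RegressorConfig(model="xgb", seed=5)
        est = fit_bp_regressor(tab.iloc[tr], tab["sbp_mmHg"].iloc[tr], cfg)
        yhat = est.predict(tab.iloc[te][list(cfg.features)].to_numpy(float))
        pccs.append(pearson(tab["sbp_mmHg"].iloc[te], yhat))
    assert pccs[1] < pccs[0]
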