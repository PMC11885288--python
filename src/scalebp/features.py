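"""PTT feature extraction, permutation importance, and ensemble BP regression.

Each good-quality segment yields eight parameters: the calibration-free
mPTT1, mPTT2, Ratio (= mPTT1/mPTT2) and mHR, and the calibration-based
PTT1_SYS, PTT1_DIA, PTT2_SYS, PTT2_DIA -- the mean transit times divided by
the subject's resting SBP/DBP.  Ratio carries no importance for BP and is
dropped from the working seven-feature set.  SBP and DBP are estimated by
two independent regressors, random forest (300 trees, min leaf 4, min
split 2) or XGBoost (300 trees, depth 3, learning rate 0.1), assessed with
5-fold cross-validation reporting per-fold Pearson correlation and mean
absolute difference.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor
from sklearn.model_selection import KFold
from xgboost import XGBRegressor

from .evaluation import mad, pearson

__all__ = [
    "FEATURE_SETS",
    "RegressorConfig",
    "extract_features",
    "extract_feature_table",
    "permutation_importance",
    "fit_bp_regressor",
    "cross_validate",
    "aggregate_fold_metrics",
]

ALL_FEATURES = (
    "mPTT1", "mPTT2", "Ratio", "PTT1_SYS", "PTT1_DIA", "PTT2_SYS", "PTT2_DIA", "mHR",
)
FEATURE_SETS: dict[str, tuple[str, ...]] = {
    "calibration_based": ("PTT1_SYS", "PTT1_DIA", "PTT2_SYS", "PTT2_DIA"),
    "calibration_free": ("mPTT1", "mPTT2", "mHR"),
    "all7": ("mPTT1", "mPTT2", "mHR", "PTT1_SYS", "PTT1_DIA", "PTT2_SYS", "PTT2_DIA"),
}


@dataclass(frozen=True)
class RegressorConfig:
    """Hyper-parameters for the two ensemble regressors."""

    model: str = "xgb"  # "rf" or "xgb"
    rf_min_leaf: int = 4
    rf_min_split: int = 2
    rf_n_trees: int = 300
    xgb_learning_rate: float = 0.1
    xgb_max_depth: int = 3
    xgb_n_trees: int = 300
    feature_set: str = "all7"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.model not in ("rf", "xgb"):
            raise ValueError(f"unknown model {self.model!r}")
        if self.rf_n_trees <= 0 or self.xgb_n_trees <= 0:
            raise ValueError("tree counts must be positive")
        if not 0.0 < self.xgb_learning_rate <= 1.0:
            raise ValueError("learning rate must be in (0, 1]")
        if self.feature_set not in FEATURE_SETS:
            raise ValueError(f"unknown feature set {self.feature_set!r}")

    @property
    def features(self) -> tuple[str, ...]:
        return FEATURE_SETS[self.feature_set]


def extract_features(
    beats: pd.DataFrame, sbp_rest: float, dbp_rest: float
) -> dict[str, float]:
    """The eight segment parameters from its member-beat annotations.

    ``beats`` must carry ptt1_ms, ptt2_ms and hr_bpm for at least two good
    beats; means over beats are divided by the resting pressures for the
    calibration-based ratios.
    """
    if len(beats) < 2:
        raise ValueError("a segment needs at least two beats for PTT parameters")
    if not np.isfinite(sbp_rest) or not np.isfinite(dbp_rest) or sbp_rest <= 0 or dbp_rest <= 0:
        raise ValueError("resting BP must be positive and finite")
    mptt1 = float(beats["ptt1_ms"].mean())
    mptt2 = float(beats["ptt2_ms"].mean())
    return {
        "mPTT1": mptt1,
        "mPTT2": mptt2,
        "Ratio": mptt1 / mptt2,
        "PTT1_SYS": mptt1 / sbp_rest,
        "PTT1_DIA": mptt1 / dbp_rest,
        "PTT2_SYS": mptt2 / sbp_rest,
        "PTT2_DIA": mptt2 / dbp_rest,
        "mHR": float(beats["hr_bpm"].mean()),
    }


def extract_feature_table(
    segments,
    annotations: pd.DataFrame,
    sbp_rest: float,
    dbp_rest: float,
) -> pd.DataFrame:
    """Feature vectors + BP targets for every good-quality segment."""
    rows = []
    for i, seg in enumerate(segments):
        if seg.quality != 1:
            continue
        beats = annotations.iloc[seg.beat_indices]
        feats = extract_features(beats, sbp_rest, dbp_rest)
        feats["sbp_mmHg"] = seg.sbp_mmHg
        feats["dbp_mmHg"] = seg.dbp_mmHg
        feats["segment"] = i
        rows.append(feats)
    if not rows:
        raise ValueError("no good-quality segments")
    return pd.DataFrame(rows)


def permutation_importance(
    model, X: np.ndarray, y: np.ndarray, n_repeats: int = 10, seed: int = 0
) -> np.ndarray:
    """Mean drop in R^2 when each feature column is shuffled independently.

    Shuffling breaks the feature-target relation, so the drop measures how
    much the fitted model relies on that feature; a constant column scores
    exactly zero.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")
    if X.shape[0] != len(y):
        raise ValueError("X and y lengths differ")
    rng = np.random.default_rng(seed)
    base = _r2(y, model.predict(X))
    scores = np.zeros(X.shape[1])
    for jcol in range(X.shape[1]):
        drops = []
        for _ in range(n_repeats):
            Xp = X.copy()
            Xp[:, jcol] = Xp[rng.permutation(len(y)), jcol]
            drops.append(base - _r2(y, model.predict(Xp)))
        scores[jcol] = np.mean(drops)
    return scores


def _r2(y: np.ndarray, yhat: np.ndarray) -> float:
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    return 1.0 - ss_res / ss_tot


def _make_estimator(config: RegressorConfig):
    if config.model == "rf":
        return RandomForestRegressor(
            n_estimators=config.rf_n_trees,
            min_samples_leaf=config.rf_min_leaf,
            min_samples_split=config.rf_min_split,
            random_state=config.seed,
            n_jobs=1,
        )
    return XGBRegressor(
        n_estimators=config.xgb_n_trees,
        max_depth=config.xgb_max_depth,
        learning_rate=config.xgb_learning_rate,
        random_state=config.seed,
        n_jobs=1,
        verbosity=0,
    )


def fit_bp_regressor(
    features: pd.DataFrame,
    targets: np.ndarray | pd.Series,
    config: RegressorConfig,
):
    """Fit one single-output BP regressor on the configured feature set."""
    cols = list(config.features)
    X = features[cols].to_numpy(dtype=float)
    y = np.asarray(targets, dtype=float)
    if len(y) < 10:
        raise ValueError("need at least 10 samples to fit a BP regressor")
    if not np.all(np.isfinite(X)) or not np.all(np.isfinite(y)):
        raise ValueError("features/targets contain non-finite values")
    est = _make_estimator(config)
    est.fit(X, y)
    return est


def aggregate_fold_metrics(folds) -> tuple[float, float]:
    """Aggregate per-fold metrics as mean +/- population SD over the folds."""
    v = np.asarray(folds, dtype=float)
    if v.size == 0:
        raise ValueError("no fold metrics to aggregate")
    return float(v.mean()), float(v.std())


def cross_validate(
    features: pd.DataFrame,
    targets: np.ndarray | pd.Series,
    config: RegressorConfig,
    k: int = 5,
    seed: int = 0,
) -> dict:
    """k-fold cross-validation; per-fold PCC and MAD plus mean +/- SD.

    Folds are disjoint and shuffled with the seed; the aggregate spread is
    the population standard deviation over the fold metrics.
    """
    y = np.asarray(targets, dtype=float)
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > len(y):
        raise ValueError("more folds than samples")
    cols = list(config.features)
    X = features[cols].to_numpy(dtype=float)
    kf = KFold(n_splits=k, shuffle=True, random_state=seed)
    pccs, mads = [], []
    for train_idx, test_idx in kf.split(X):
        est = _make_estimator(config)
        est.fit(X[train_idx], y[train_idx])
        yhat = est.predict(X[test_idx])
        pccs.append(pearson(y[test_idx], yhat))
        mads.append(mad(yhat - y[test_idx]))
    pcc_mean, pcc_sd = aggregate_fold_metrics(pccs)
    mad_mean, mad_sd = aggregate_fold_metrics(mads)
    return {
        "fold_pcc": pccs,
        "fold_mad": mads,
        "pcc_mean": pcc_mean,
        "pcc_sd": pcc_sd,
        "mad_mean": mad_mean,
        "mad_sd": mad_sd,
    }
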