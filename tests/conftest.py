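"""Shared fixtures: simulated sessions and trained models, built once per run."""

from __future__ import annotations

import numpy as np
import pytest

from scalebp.quality_model import QualityNet, QualityNetConfig
from scalebp.segmentation import split_dataset
from scalebp.simulate import SimulationConfig, simulate_cohort_features, simulate_session
from scalebp.workflow import build_quality_dataset, session_pipeline

# the clean study condition: low sensor noise, no artifacts
CLEAN_CONFIG = SimulationConfig(duration_s=300.0, noise_sd=0.005, seed=11)
# post-exercise session with Bernoulli IPG-foot artifacts
ARTIFACT_CONFIG = SimulationConfig(
    duration_s=300.0, noise_sd=0.005, artifact_rate=0.25, artifact_shift_ms=120.0,
    seed=13,
)


def align_to_truth(annotations, gt, tol_s: float = 0.05) -> np.ndarray:
    """For each annotated beat, the matching ground-truth index (-1 if none)."""
    r = annotations["r_time_s"].to_numpy(float)
    idx = np.clip(np.searchsorted(gt.beat_times, r) - 1, 0, gt.n_beats - 1)
    out = np.full(len(r), -1, dtype=int)
    for cand in (idx, np.clip(idx + 1, 0, gt.n_beats - 1)):
        ok = np.abs(gt.beat_times[cand] - r) <= tol_s
        out[ok] = cand[ok]
    return out


@pytest.fixture(scope="session")
def clean_run():
    return session_pipeline(CLEAN_CONFIG)


@pytest.fixture(scope="session")
def artifact_run():
    return session_pipeline(ARTIFACT_CONFIG)


@pytest.fixture(scope="session")
def clean_session():
    return simulate_session(CLEAN_CONFIG)


@pytest.fixture(scope="session")
def quality_dataset():
    """2,000 balanced clean/corrupted segments for classifier experiments."""
    return build_quality_dataset(2000, seed=17)


@pytest.fixture(scope="session")
def trained_quality(quality_dataset):
    """Desk-scale CNN+GRU trained at most 10 epochs on the balanced set."""
    X, y = quality_dataset
    train_idx, val_idx = split_dataset(len(y), (0.8, 0.2), seed=17, stratify_by=y)
    net = QualityNet(QualityNetConfig.desk_scale(seed=17))
    history = net.fit(X[train_idx], y[train_idx], X[val_idx], y[val_idx], epochs=10)
    return {
        "net": net,
        "history": history,
        "X_val": X[val_idx],
        "y_val": y[val_idx],
    }


@pytest.fixture(scope="session")
def cohort_features():
    """Segment-level feature table with BP affine in PTT2 plus noise."""
    return simulate_cohort_features(2000, seed=19)
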