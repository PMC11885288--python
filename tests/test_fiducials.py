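"""Landmark detection: R waves, J waves, pulse feet, upstroke peaks."""

import numpy as np
import pytest

from conftest import align_to_truth
from scalebp.fiducials import (
    NoPeaksError,
    detect_derivative_peak,
    detect_foot,
    detect_j_wave,
    detect_r_peaks,
    extract_fiducials,
)
from scalebp.preprocess import differentiate, preprocess_record
from scalebp.simulate import (
    SimulationConfig,
    _ecg_channel,
    _pulse_channel,
    inject_artifact,
    simulate_session,
)

FS = 500.0


def test_r_peaks_at_known_instants():
    r_true = np.array([1.0, 1.8, 2.6])
    ecg = _ecg_channel(int(4 * FS), FS, r_true)
    detected = detect_r_peaks(ecg, FS)
    assert len(detected) == 3
    np.testing.assert_allclose(detected, r_true, atol=0.004)


def test_r_peaks_flat_signal_raises():
    with pytest.raises(NoPeaksError):
        detect_r_peaks(np.zeros(int(10 * FS)), FS)


def test_r_peak_count_matches_simulated_beats(clean_run):
    gt = clean_run["ground_truth"]
    n_detected = len(clean_run["annotations"])
    assert abs(n_detected - gt.n_beats) <= 1


def test_j_wave_lag_recovered(clean_session):
    rec, _, gt = clean_session
    proc = preprocess_record(rec)
    r = gt.beat_times
    j = detect_j_wave(proc.channels["bcg"], r, rec.fs)
    lags_ms = (j - r) * 1000.0
    # simulator J lag is 150 ms; allow one sample of detection slack
    assert np.nanmean(np.abs(lags_ms - 150.0) <= 2.0) >= 0.99


def test_j_wave_first_of_two_peaks():
    fs = 500.0
    t = np.arange(int(1.0 * fs)) / fs
    bcg = np.exp(-0.5 * ((t - 0.35) / 0.02) ** 2) + 0.9 * np.exp(
        -0.5 * ((t - 0.55) / 0.02) ** 2
    )
    j = detect_j_wave(bcg, np.array([0.2]), fs)
    assert j[0] == pytest.approx(0.35, abs=0.004)


def test_j_wave_missing_when_monotone():
    t = np.arange(int(1.0 * FS)) / FS
    j = detect_j_wave(t.copy(), np.array([0.2]), FS)  # strictly increasing
    assert np.isnan(j[0])


def test_foot_at_pulse_onset_unfiltered():
    """Foot = derivative upward zero crossing at the constructed pulse minimum."""
    feet = np.array([0.8, 1.6, 2.4])
    pulse = _pulse_channel(int(3.2 * FS), FS, feet, rise_s=0.16)
    d = differentiate(pulse, FS)
    r = feet - 0.3  # R precedes each foot by 300 ms
    detected = detect_foot(d, r, FS)
    np.testing.assert_allclose(detected, feet, atol=2.0 / FS)


def test_foot_missing_when_derivative_never_negative():
    x = np.linspace(0, 1, int(2 * FS)) ** 2
    d = differentiate(x, FS)
    assert np.isnan(detect_foot(d, np.array([0.5]), FS)[0])


def test_derivative_peak_lag_recovered_unfiltered():
    """Upstroke derivative peaks exactly rise/2 = 80 ms after the foot."""
    feet = np.array([0.8, 1.6, 2.4])
    pulse = _pulse_channel(int(3.2 * FS), FS, feet, rise_s=0.16)
    d = differentiate(pulse, FS)
    r = feet - 0.3
    foot_times = detect_foot(d, r, FS)
    peaks = detect_derivative_peak(d, foot_times, r, FS)
    np.testing.assert_allclose(peaks - foot_times, 0.08, atol=2.0 / FS)


def test_derivative_peak_propagates_missing_foot():
    d = np.sin(np.arange(int(2 * FS)) / FS * 2 * np.pi)
    peaks = detect_derivative_peak(d, np.array([np.nan]), np.array([0.1]), FS)
    assert np.isnan(peaks[0])


def test_artifact_shifts_detected_foot_and_peak():
    """A warped IPG onset displaces that beat's foot/peak by about the shift."""
    cfg = SimulationConfig(duration_s=60, noise_sd=0.0, seed=2)
    rec, _, gt = simulate_session(cfg)
    shifted = inject_artifact(rec.copy(), gt, 12, 100.0)
    base = extract_fiducials(preprocess_record(rec))
    warped = extract_fiducials(preprocess_record(shifted))
    d_foot = (warped["ipg_foot_time_s"] - base["ipg_foot_time_s"]) * 1000.0
    d_peak = (warped["dipg_peak_time_s"] - base["dipg_peak_time_s"]) * 1000.0
    assert d_foot.iloc[12] == pytest.approx(100.0, abs=20.0)
    assert d_peak.iloc[12] == pytest.approx(100.0, abs=2.0)
    # locality: other beats keep their timing (zero-phase filtering leaks a
    # couple of ms into the immediate neighbors, nothing more)
    others = np.delete(np.arange(len(base)), 12)
    assert np.nanmax(np.abs(d_foot.iloc[others])) < 3.0
    assert np.nanmax(np.abs(d_peak.iloc[others])) < 0.5


def test_fiducial_ordering_invariant(clean_run):
    fid = clean_run["annotations"]
    ok = fid["complete"]
    assert (fid.loc[ok, "r_time_s"] < fid.loc[ok, "j_time_s"]).all()
    assert (fid.loc[ok, "r_time_s"] < fid.loc[ok, "ppg_foot_time_s"]).all()
    assert (fid.loc[ok, "ppg_foot_time_s"] < fid.loc[ok, "dppg_peak_time_s"]).all()
    assert (fid.loc[ok, "ipg_foot_time_s"] < fid.loc[ok, "dipg_peak_time_s"]).all()
    # non-decreasing across beats
    assert fid["r_time_s"].is_monotonic_increasing


def test_clean_session_interval_recovery(clean_run):
    """>= 99% of clean beats: complete fiducials, PAT2/PTT2 within 2 ms."""
    ann, gt = clean_run["annotations"], clean_run["ground_truth"]
    match = align_to_truth(ann, gt)
    assert (match >= 0).all()
    ok = ann["complete"].to_numpy()
    ptt2_err = np.abs(ann["ptt2_ms"].to_numpy() - gt.true_ptt2[match])
    pat2_err = np.abs(ann["pat2_ms"].to_numpy() - gt.true_pat2[match])
    good = ok & (ptt2_err <= 2.0) & (pat2_err <= 2.0)
    assert good.mean() >= 0.99
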