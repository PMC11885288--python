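"""Per-beat landmark detection.

The timing chain needs six landmarks per beat: the ECG R wave (Pan-Tompkins),
the BCG J wave (first qualifying peak after R), the PPG and IPG feet (first
negative-to-positive zero crossing of the derivative channel after R), and
the DPPG / DIPG upstroke peaks (first qualifying local maximum after the
foot).  Landmarks that cannot be found inside their search window are
recorded as missing, never raised.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import signal as sps

from .records import WaveformRecord

__all__ = [
    "detect_r_peaks",
    "detect_j_wave",
    "detect_foot",
    "detect_derivative_peak",
    "extract_fiducials",
    "NoPeaksError",
]

# Pan-Tompkins constants: the method's integration window and refractory
# period, fixed here because only the method itself is standard.
PT_INTEGRATION_S = 0.150
PT_REFRACTORY_S = 0.250
J_SEARCH_WINDOW_S = 0.400
# relative-amplitude guard: a candidate local maximum must reach this
# fraction of the search-window maximum to qualify (noise-ripple rejection)
J_MIN_REL_AMPLITUDE = 0.30
DPEAK_MIN_REL_AMPLITUDE = 0.50


class NoPeaksError(ValueError):
    """Raised when no R waves can be located in an ECG channel."""


def detect_r_peaks(ecg: np.ndarray, fs: float) -> np.ndarray:
    """Locate R-wave times (s) with the Pan-Tompkins method.

    Differentiate, square, and integrate over a 150 ms moving window, pick
    peaks of the integrated signal with an adaptive amplitude threshold and
    a 250 ms refractory period, then refine each detection to the ECG
    maximum inside +/-60 ms.
    """
    ecg = np.asarray(ecg, dtype=float)
    if fs < 200:
        raise ValueError(f"fs {fs} Hz too low for QRS detection")
    if len(ecg) < int(fs):
        raise ValueError("ECG shorter than one second")

    deriv = np.gradient(ecg) * fs
    squared = deriv**2
    win = max(int(round(PT_INTEGRATION_S * fs)), 1)
    mwi = np.convolve(squared, np.ones(win) / win, mode="same")

    refractory = int(round(PT_REFRACTORY_S * fs))
    # adaptive threshold seeded from the integrated signal's upper range
    seed_thresh = 0.2 * np.percentile(mwi, 99)
    locs, _ = sps.find_peaks(mwi, height=seed_thresh, distance=refractory)
    if len(locs) == 0:
        raise NoPeaksError("no QRS complexes found")

    # adaptive re-screen: running signal/noise estimates (classic PT rule)
    spki = float(np.median(mwi[locs]))
    npki = float(np.median(mwi)) if np.median(mwi) < spki else 0.0
    kept = []
    for i in locs:
        thresh = npki + 0.25 * (spki - npki)
        if mwi[i] >= thresh:
            kept.append(i)
            spki = 0.125 * mwi[i] + 0.875 * spki
        else:
            npki = 0.125 * mwi[i] + 0.875 * npki
    if not kept:
        raise NoPeaksError("no QRS complexes passed the adaptive threshold")

    # refine to the ECG maximum near each integrated-signal peak
    half = int(round(0.060 * fs))
    r_idx = []
    for i in kept:
        lo, hi = max(i - half, 0), min(i + half + 1, len(ecg))
        r_idx.append(lo + int(np.argmax(ecg[lo:hi])))
    r_idx = np.unique(r_idx)
    # enforce refractory after refinement
    final = [r_idx[0]]
    for i in r_idx[1:]:
        if i - final[-1] >= refractory:
            final.append(i)
    return np.asarray(final) / fs


def _local_maxima(x: np.ndarray) -> np.ndarray:
    """Indices of samples strictly greater than both neighbors."""
    if len(x) < 3:
        return np.empty(0, dtype=int)
    return np.flatnonzero((x[1:-1] > x[:-2]) & (x[1:-1] > x[2:])) + 1


def _parabolic_refine(x: np.ndarray, i: int) -> float:
    """Sub-sample peak position by a parabola through (i-1, i, i+1)."""
    if i <= 0 or i >= len(x) - 1:
        return float(i)
    denom = x[i - 1] - 2.0 * x[i] + x[i + 1]
    if denom >= 0:  # not a strict maximum of the fitted parabola
        return float(i)
    delta = 0.5 * (x[i - 1] - x[i + 1]) / denom
    return i + float(np.clip(delta, -0.5, 0.5))


def detect_j_wave(
    bcg: np.ndarray,
    r_times: np.ndarray,
    fs: float,
    window_s: float = J_SEARCH_WINDOW_S,
    min_rel_amplitude: float = J_MIN_REL_AMPLITUDE,
) -> np.ndarray:
    """First qualifying BCG peak after each R wave (the J wave).

    Searches ``(r, r + window_s]``; the earliest strict local maximum whose
    amplitude reaches ``min_rel_amplitude`` of the window maximum is the J
    wave.  NaN where no candidate exists.
    """
    bcg = np.asarray(bcg, dtype=float)
    out = np.full(len(r_times), np.nan)
    for k, r in enumerate(np.asarray(r_times, dtype=float)):
        i0 = int(np.floor(r * fs)) + 1
        i1 = min(int(np.floor((r + window_s) * fs)) + 1, len(bcg))
        if i1 - i0 < 3:
            continue
        seg = bcg[i0:i1]
        cand = _local_maxima(seg)
        if len(cand) == 0:
            continue
        floor_amp = min_rel_amplitude * seg.max()
        cand = cand[seg[cand] >= floor_amp]
        if len(cand):
            out[k] = (i0 + _parabolic_refine(seg, int(cand[0]))) / fs
    return out


def detect_foot(
    derivative: np.ndarray,
    r_times: np.ndarray,
    fs: float,
) -> np.ndarray:
    """Pulse-foot times: first negative-to-positive zero crossing of the
    derivative channel after each R wave (before the next R).

    The crossing position is refined to sub-sample precision by linear
    interpolation between the bracketing samples.  NaN where the derivative
    never crosses upward inside the beat.
    """
    d = np.asarray(derivative, dtype=float)
    r = np.asarray(r_times, dtype=float)
    out = np.full(len(r), np.nan)
    n = len(d)
    for k in range(len(r)):
        i0 = int(np.floor(r[k] * fs)) + 1
        i1 = int(np.floor(r[k + 1] * fs)) if k + 1 < len(r) else n - 1
        i1 = min(i1, n - 1)
        if i1 <= i0:
            continue
        seg0, seg1 = d[i0:i1], d[i0 + 1 : i1 + 1]
        hits = np.flatnonzero((seg0 < 0) & (seg1 >= 0))
        if len(hits) == 0:
            continue
        i = i0 + hits[0]
        frac = -d[i] / (d[i + 1] - d[i])
        out[k] = (i + frac) / fs
    return out


def detect_derivative_peak(
    derivative: np.ndarray,
    foot_times: np.ndarray,
    r_times: np.ndarray,
    fs: float,
    min_rel_amplitude: float = DPEAK_MIN_REL_AMPLITUDE,
) -> np.ndarray:
    """Upstroke-peak times: first qualifying local maximum of the derivative
    after each foot and before the next R wave.

    A missing foot propagates to a missing peak.  The relative-amplitude
    guard rejects noise ripples on the early upstroke.
    """
    d = np.asarray(derivative, dtype=float)
    r = np.asarray(r_times, dtype=float)
    feet = np.asarray(foot_times, dtype=float)
    out = np.full(len(feet), np.nan)
    n = len(d)
    for k, f in enumerate(feet):
        if not np.isfinite(f):
            continue
        i0 = int(np.floor(f * fs)) + 1
        i1 = int(np.floor(r[k + 1] * fs)) if k + 1 < len(r) else n
        i1 = min(i1, n)
        if i1 - i0 < 3:
            continue
        seg = d[i0:i1]
        cand = _local_maxima(seg)
        cand = cand[seg[cand] > 0]
        if len(cand) == 0:
            continue
        cand = cand[seg[cand] >= min_rel_amplitude * seg.max()]
        if len(cand):
            out[k] = (i0 + _parabolic_refine(seg, int(cand[0]))) / fs
    return out


def extract_fiducials(record: WaveformRecord) -> pd.DataFrame:
    """Run the full landmark chain on a preprocessed record.

    Expects channels ``ecg, bcg, dppg, dipg`` (see
    :func:`scalebp.preprocess.preprocess_record`).  Returns one row per
    detected beat with columns ``r_time_s, j_time_s, ppg_foot_time_s,
    dppg_peak_time_s, ipg_foot_time_s, dipg_peak_time_s, complete, status``.
    """
    fs = record.fs
    r = detect_r_peaks(record.channels["ecg"], fs)
    j = detect_j_wave(record.channels["bcg"], r, fs)
    ppg_foot = detect_foot(record.channels["dppg"], r, fs)
    dppg_peak = detect_derivative_peak(record.channels["dppg"], ppg_foot, r, fs)
    ipg_foot = detect_foot(record.channels["dipg"], r, fs)
    dipg_peak = detect_derivative_peak(record.channels["dipg"], ipg_foot, r, fs)

    df = pd.DataFrame(
        {
            "beat_index": np.arange(len(r)),
            "r_time_s": r,
            "j_time_s": j,
            "ppg_foot_time_s": ppg_foot,
            "dppg_peak_time_s": dppg_peak,
            "ipg_foot_time_s": ipg_foot,
            "dipg_peak_time_s": dipg_peak,
        }
    )
    landmark_cols = [
        "j_time_s", "ppg_foot_time_s", "dppg_peak_time_s",
        "ipg_foot_time_s", "dipg_peak_time_s",
    ]
    df["complete"] = df[landmark_cols].notna().all(axis=1)

    def _status(row: pd.Series) -> str:
        missing = [c.split("_time")[0] for c in landmark_cols if pd.isna(row[c])]
        return "ok" if not missing else "missing:" + ",".join(missing)

    df["status"] = df.apply(_status, axis=1)
    return df
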