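"""Beat intervals, rest-phase bias calibration, quality labeling, per-beat BP.

Per beat the timing chain yields two arrival times referenced to the ECG R
wave (PAT1 to the PPG foot, PAT2 to the DPPG peak) and two transit times
referenced to the BCG J wave (PTT1 to the IPG foot, PTT2 to the DIPG peak).
The weight-scale channels carry a constant device delay relative to the
ECG/PPG chain, so a per-session bias -- the mean PTT2-PAT2 delay over the
first few rest beats -- recenters the percentage error

    E = (PAT2 - PTT2 + bias) / PAT2 * 100

at zero for well-timed beats.  Beats with |E| above a threshold (30% by
default) are labeled poor quality.  Reference BP for each beat comes from
linear interpolation of the per-minute cuff readings.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .records import BPReference

__all__ = [
    "BiasEstimate",
    "compute_intervals",
    "estimate_bias",
    "percentage_error",
    "label_beat",
    "interpolate_bp",
    "annotate_beats",
]

QUALITY_THRESHOLD_PCT = 30.0
N_BIAS_BEATS = 5


@dataclass(frozen=True)
class BiasEstimate:
    """Rest-phase PTT2-PAT2 offset used to recenter the percentage error."""

    bias_ms: float
    n_beats_used: int
    rest_window: tuple[float, float]

    def __post_init__(self) -> None:
        if self.n_beats_used < 1:
            raise ValueError("bias estimate needs at least one beat")


def compute_intervals(fiducials: pd.DataFrame) -> pd.DataFrame:
    """Per-beat intervals (ms) and heart rate from a fiducial table.

    pat1 = PPG foot - R, pat2 = DPPG peak - R, ptt1 = IPG foot - J,
    ptt2 = DIPG peak - J; HR is 60/RR assigned to the beat that starts the
    interval (the last beat has no RR and gets NaN).  Beats with incomplete
    fiducial sets keep NaN intervals and ``complete == False``.
    """
    df = fiducials.copy()
    r = df["r_time_s"].to_numpy(float)
    df["pat1_ms"] = (df["ppg_foot_time_s"] - r) * 1000.0
    df["pat2_ms"] = (df["dppg_peak_time_s"] - r) * 1000.0
    df["ptt1_ms"] = (df["ipg_foot_time_s"] - df["j_time_s"]) * 1000.0
    df["ptt2_ms"] = (df["dipg_peak_time_s"] - df["j_time_s"]) * 1000.0
    rr = np.diff(r)
    hr = np.full(len(r), np.nan)
    if len(rr):
        with np.errstate(divide="ignore"):
            hr[:-1] = np.where(rr > 0, 60.0 / rr, np.nan)
    df["hr_bpm"] = hr
    interval_ok = (
        df[["pat1_ms", "pat2_ms", "ptt1_ms", "ptt2_ms"]].gt(0).all(axis=1)
        & df["hr_bpm"].notna()
    )
    df["complete"] = df["complete"] & interval_ok
    return df


def estimate_bias(
    annotations: pd.DataFrame,
    rest_window: tuple[float, float],
    n: int = N_BIAS_BEATS,
) -> BiasEstimate:
    """Mean PTT2-PAT2 delay over the first ``n`` complete rest-phase beats.

    The sign convention (bias = mean(ptt2 - pat2)) makes E vanish for rest
    beats, since the scale channels lag the ECG/PPG chain (PTT2 > PAT2).
    """
    lo, hi = rest_window
    rest = annotations[
        annotations["complete"]
        & (annotations["r_time_s"] >= lo)
        & (annotations["r_time_s"] < hi)
    ]
    if len(rest) < n:
        raise ValueError(
            f"need {n} complete rest beats in [{lo}, {hi}) s, found {len(rest)}"
        )
    head = rest.iloc[:n]
    delay = (head["ptt2_ms"] - head["pat2_ms"]).to_numpy(float)
    return BiasEstimate(bias_ms=float(delay.mean()), n_beats_used=n, rest_window=(lo, hi))


def percentage_error(pat2_ms, ptt2_ms, bias_ms) -> np.ndarray | float:
    """E = (PAT2 - PTT2 + bias) / PAT2 * 100, elementwise."""
    pat2 = np.asarray(pat2_ms, dtype=float)
    if np.any(pat2 <= 0):
        raise ValueError("pat2 must be positive")
    e = (pat2 - np.asarray(ptt2_ms, dtype=float) + bias_ms) / pat2 * 100.0
    return float(e) if np.isscalar(pat2_ms) else e


def label_beat(e_percent, threshold: float = QUALITY_THRESHOLD_PCT):
    """Quality label: poor (0) iff |E| exceeds the threshold, else good (1).

    The threshold comparison is strict ("larger than"), so |E| equal to the
    threshold is still good.  The magnitude is used because a mistimed pulse
    foot can push E far in either direction.
    """
    e = np.asarray(e_percent, dtype=float)
    label = (np.abs(e) <= threshold).astype(int)
    return int(label) if np.isscalar(e_percent) else label


def interpolate_bp(ref: BPReference, beat_times) -> tuple[np.ndarray, np.ndarray]:
    """Per-beat SBP/DBP by piecewise-linear interpolation of the cuff readings.

    Beats outside the reference span clamp to the nearest reading;
    extrapolating beyond the cuff measurements is unjustified.
    """
    t = np.asarray(beat_times, dtype=float)
    sbp = np.interp(t, ref.time_s, ref.sbp_mmHg)
    dbp = np.interp(t, ref.time_s, ref.dbp_mmHg)
    return sbp, dbp


def annotate_beats(
    fiducials: pd.DataFrame,
    bp_ref: BPReference,
    rest_window: tuple[float, float],
    threshold: float = QUALITY_THRESHOLD_PCT,
    n_bias_beats: int = N_BIAS_BEATS,
) -> tuple[pd.DataFrame, BiasEstimate]:
    """Full per-beat annotation: intervals, bias, E, quality label, BP.

    Returns the annotated beat table (``quality`` is NaN for beats whose
    fiducial set is incomplete) and the bias estimate used.
    """
    ann = compute_intervals(fiducials)
    bias = estimate_bias(ann, rest_window, n=n_bias_beats)
    e = np.full(len(ann), np.nan)
    ok = ann["complete"].to_numpy(bool)
    e[ok] = percentage_error(
        ann.loc[ok, "pat2_ms"].to_numpy(), ann.loc[ok, "ptt2_ms"].to_numpy(), bias.bias_ms
    )
    ann["e_percent"] = e
    quality = np.full(len(ann), np.nan)
    quality[ok] = label_beat(e[ok], threshold)
    ann["quality"] = quality
    sbp, dbp = interpolate_bp(bp_ref, ann["r_time_s"].to_numpy())
    ann["sbp_mmHg"], ann["dbp_mmHg"] = sbp, dbp
    return ann, bias
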