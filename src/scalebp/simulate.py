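"""Synthetic session generator for the weight-scale cuffless-BP pipeline.

The study's raw recordings are not publicly available, so every downstream
stage is exercised against simulated sessions with exact per-beat ground
truth.  A session emulates the experimental protocol: a standing rest phase
at baseline blood pressure followed by a post-exercise phase in which SBP
and DBP decay exponentially back toward rest (e.g. SBP 139 -> 113 mmHg over
~6 min).  Pulse transit time is inversely coupled to instantaneous SBP, and
pulse arrival time trails PTT by a fixed device offset (~62 ms).

Channel morphologies are deliberately simple analytic stand-ins that place
the pipeline's fiducial landmarks at known instants:

* ECG   — narrow Gaussian R spike plus small P/T bumps,
* BCG   — windowed damped sinusoid whose first positive extremum (the
          J wave) lags R by a fixed, configurable lag,
* PPG / IPG — raised-cosine upstroke from the pulse foot to the pulse
          peak, half-cosine decay to the next foot.  The upstroke's
          derivative peaks exactly halfway up, so the derivative-peak lag
          after the foot is ``rise/2`` by construction.

They reproduce landmark geometry, not hemodynamics; see docs/methods.md.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable

import numpy as np
import pandas as pd

from .records import BPReference, GroundTruth, WaveformRecord

__all__ = [
    "SimulationConfig",
    "simulate_session",
    "inject_artifact",
    "simulate_cohort_features",
]

# fixed morphology constants (seconds) -- see docs/methods.md
_BCG_FREQ_HZ = 4.5      # dominant I-J-K oscillation frequency
_BCG_DECAY_S = 0.15     # damping time constant of the BCG complex
_ECG_R_SD = 0.010       # R-spike Gaussian width
_ECG_P_SD, _ECG_P_AMP, _ECG_P_LAG = 0.020, 0.15, -0.16
_ECG_T_SD, _ECG_T_AMP, _ECG_T_LAG = 0.040, 0.25, 0.25


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one synthetic session.

    Defaults follow the protocol: one minute of standing rest at baseline BP,
    then six minutes of post-exercise recovery during which SBP decays from
    ``sbp_peak`` toward ``sbp_rest`` with time constant ``decay_tau_s``.
    ``ptt_coupling`` is the linear map PTT2 = a - b * SBP (ms); the default
    solves the two printed operating points (SBP 139 -> PTT2 292 ms and
    SBP 113 -> 330 ms).  PAT2 = PTT2 - ``pat_offset_ms`` for every beat.
    """

    duration_s: float = 420.0
    fs: float = 500.0
    rest_duration_s: float = 60.0
    sbp_rest: float = 113.0
    dbp_rest: float = 69.0
    sbp_peak: float = 139.0
    dbp_peak: float = 74.0
    decay_tau_s: float = 120.0
    hr_rest_bpm: float = 70.0
    hr_peak_bpm: float = 100.0
    hr_trajectory: Callable[[np.ndarray], np.ndarray] | None = None
    ptt_coupling: tuple[float, float] = (495.23, 1.4615)  # PTT2 = a - b*SBP, ms
    pat_offset_ms: float = 62.0
    j_lag_ms: float = 150.0
    foot_to_peak_ms: float = 80.0
    noise_sd: float = 0.02
    artifact_rate: float = 0.0
    artifact_shift_ms: float = 120.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "duration_s", "fs", "sbp_rest", "dbp_rest", "sbp_peak", "dbp_peak",
            "decay_tau_s", "hr_rest_bpm", "hr_peak_bpm", "pat_offset_ms",
            "j_lag_ms", "foot_to_peak_ms",
        ):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"{name} must be positive and finite, got {v}")
        if not np.isfinite(self.rest_duration_s) or self.rest_duration_s < 0:
            raise ValueError("rest_duration_s must be non-negative")
        if not 0.0 <= self.artifact_rate <= 1.0:
            raise ValueError("artifact_rate must be in [0, 1]")
        if self.noise_sd < 0 or not np.isfinite(self.noise_sd):
            raise ValueError("noise_sd must be non-negative")
        a, b = self.ptt_coupling
        if not (np.isfinite(a) and np.isfinite(b)):
            raise ValueError("ptt_coupling must be finite")
        if self.sbp_rest <= self.dbp_rest or self.sbp_peak <= self.dbp_peak:
            raise ValueError("SBP must exceed DBP")

    # --- trajectories -------------------------------------------------

    def sbp_at(self, t: np.ndarray) -> np.ndarray:
        return self._bp(t, self.sbp_rest, self.sbp_peak)

    def dbp_at(self, t: np.ndarray) -> np.ndarray:
        return self._bp(t, self.dbp_rest, self.dbp_peak)

    def _bp(self, t: np.ndarray, rest: float, peak: float) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        rec = t - self.rest_duration_s
        out = np.where(
            rec < 0, rest, rest + (peak - rest) * np.exp(-np.maximum(rec, 0.0) / self.decay_tau_s)
        )
        return out

    def hr_at(self, t: np.ndarray) -> np.ndarray:
        if self.hr_trajectory is not None:
            return np.asarray(self.hr_trajectory(np.asarray(t, dtype=float)), dtype=float)
        t = np.asarray(t, dtype=float)
        rec = t - self.rest_duration_s
        return np.where(
            rec < 0,
            self.hr_rest_bpm,
            self.hr_rest_bpm
            + (self.hr_peak_bpm - self.hr_rest_bpm) * np.exp(-np.maximum(rec, 0.0) / self.decay_tau_s),
        )

    def ptt2_at(self, sbp: np.ndarray) -> np.ndarray:
        a, b = self.ptt_coupling
        return a - b * np.asarray(sbp, dtype=float)


# ---------------------------------------------------------------------------
# event-time layer


def _beat_times(cfg: SimulationConfig) -> np.ndarray:
    """Integrate the heart-rate trajectory into R-wave instants."""
    times = []
    t = 0.5  # first beat well inside the record
    # keep the full fiducial chain (through the DIPG peak) inside the record
    margin = (cfg.j_lag_ms + 450.0) / 1000.0
    while t < cfg.duration_s - margin:
        times.append(t)
        hr = float(cfg.hr_at(t))
        if hr <= 0:
            raise ValueError("heart-rate trajectory must stay positive")
        t += 60.0 / hr
    if len(times) < 2:
        raise ValueError("duration too short to hold two beats")
    return np.asarray(times)


def _beat_events(cfg: SimulationConfig, beat_times: np.ndarray) -> dict[str, np.ndarray]:
    """Per-beat truth: intervals (ms) and absolute fiducial times (s)."""
    sbp = cfg.sbp_at(beat_times)
    dbp = cfg.dbp_at(beat_times)
    ptt2 = cfg.ptt2_at(sbp)
    pat2 = ptt2 - cfg.pat_offset_ms
    ptt1 = ptt2 - cfg.foot_to_peak_ms
    pat1 = pat2 - cfg.foot_to_peak_ms
    if np.any(pat1 <= 0) or np.any(ptt1 <= 0):
        raise ValueError("ptt_coupling / offsets produce non-positive intervals")
    rr = np.diff(beat_times)
    hr = 60.0 / np.concatenate([rr, rr[-1:]])  # last beat inherits final RR
    return {
        "r": beat_times,
        "j": beat_times + cfg.j_lag_ms / 1000.0,
        "ppg_foot": beat_times + pat1 / 1000.0,
        "ipg_foot": beat_times + cfg.j_lag_ms / 1000.0 + ptt1 / 1000.0,
        "pat1": pat1, "pat2": pat2, "ptt1": ptt1, "ptt2": ptt2,
        "sbp": sbp, "dbp": dbp, "hr": hr,
    }


# ---------------------------------------------------------------------------
# waveform synthesis


def _add_gaussians(out: np.ndarray, fs: float, centers: np.ndarray,
                   amp: float, sd: float) -> None:
    n = len(out)
    half = int(round(4 * sd * fs))
    for c in centers:
        i0 = max(int(round((c - 4 * sd) * fs)), 0)
        i1 = min(i0 + 2 * half + 1, n)
        if i0 >= n or i1 <= 0:
            continue
        t = np.arange(i0, i1) / fs
        out[i0:i1] += amp * np.exp(-0.5 * ((t - c) / sd) ** 2)


def _ecg_channel(n: int, fs: float, r_times: np.ndarray) -> np.ndarray:
    out = np.zeros(n)
    _add_gaussians(out, fs, r_times, 1.0, _ECG_R_SD)
    _add_gaussians(out, fs, r_times + _ECG_P_LAG, _ECG_P_AMP, _ECG_P_SD)
    _add_gaussians(out, fs, r_times + _ECG_T_LAG, _ECG_T_AMP, _ECG_T_SD)
    return out


def _bcg_complex(t: np.ndarray) -> np.ndarray:
    """I-J-K complex shape: amplitude-ramped damped sinusoid, zero for t < 0.

    The oscillation starts with the negative I lobe so the J wave (first
    positive extremum) rides on a smooth, band-limited waveform rather than
    an abrupt onset.
    """
    w = 2 * math.pi * _BCG_FREQ_HZ
    ramp_len = 0.5 / _BCG_FREQ_HZ  # ramp over the first half period
    env = np.where(t < ramp_len, np.sin(0.5 * math.pi * np.clip(t, 0, None) / ramp_len) ** 2, 1.0)
    out = -env * np.exp(-t / _BCG_DECAY_S) * np.sin(w * t)
    out[t < 0] = 0.0
    return out


def _bcg_j_peak_offset() -> float:
    """Time from complex onset to the J wave, located numerically."""
    t = np.arange(0.0, 0.4, 1e-5)
    return float(t[np.argmax(_bcg_complex(t))])


_BCG_J_OFFSET = None


def _bcg_channel(n: int, fs: float, j_times: np.ndarray) -> np.ndarray:
    global _BCG_J_OFFSET
    if _BCG_J_OFFSET is None:
        _BCG_J_OFFSET = _bcg_j_peak_offset()
    out = np.zeros(n)
    onset = j_times - _BCG_J_OFFSET
    span = int(round(0.6 * fs))
    for t0 in onset:
        i0 = max(int(math.ceil(t0 * fs)), 0)
        i1 = min(i0 + span, n)
        if i0 >= n:
            continue
        out[i0:i1] += _bcg_complex(np.arange(i0, i1) / fs - t0)
    return out


def _pulse_channel(n: int, fs: float, foot_times: np.ndarray, rise_s: float) -> np.ndarray:
    """Pulse wave: raised-cosine upstroke (foot -> peak over ``rise_s``),
    half-cosine decay from each peak to the next foot.  The foot is a smooth
    local minimum and the upstroke derivative peaks at ``foot + rise_s/2``.

    Virtual feet one median beat before the first and after the last keep the
    edges periodic so edge beats still carry a well-defined foot.
    """
    rr = np.median(np.diff(foot_times)) if len(foot_times) > 1 else 0.8
    feet = np.concatenate([[foot_times[0] - rr], foot_times, [foot_times[-1] + rr]])
    out = np.zeros(n)
    t = np.arange(n) / fs
    for k in range(len(feet) - 1):
        f0, f1 = feet[k], feet[k + 1]
        peak = f0 + rise_s
        if peak >= f1:  # degenerate short beat: pure rise
            peak = 0.5 * (f0 + f1)
        i0 = max(int(math.ceil(f0 * fs)), 0)
        ip = min(max(int(math.ceil(peak * fs)), 0), n)
        i1 = min(int(math.ceil(f1 * fs)), n)
        if i0 < ip:
            u = (t[i0:ip] - f0) / (peak - f0)
            out[i0:ip] = 0.5 * (1 - np.cos(math.pi * u))
        if ip < i1:
            u = (t[ip:i1] - peak) / (f1 - peak)
            out[ip:i1] = 0.5 * (1 + np.cos(math.pi * u))
    return out


# ---------------------------------------------------------------------------
# public operations


def simulate_session(
    cfg: SimulationConfig,
) -> tuple[WaveformRecord, BPReference, GroundTruth]:
    """Generate one synthetic session.

    Returns the four-channel waveform record, the per-minute cuff BP
    reference sampled exactly from the internal trajectory, and the per-beat
    ground truth.  Identical configs (including seed) give identical output.
    """
    rng = np.random.default_rng(cfg.seed)
    n = int(round(cfg.duration_s * cfg.fs))
    beats = _beat_times(cfg)
    ev = _beat_events(cfg, beats)

    rise_s = 2 * cfg.foot_to_peak_ms / 1000.0
    channels = {
        "ecg": _ecg_channel(n, cfg.fs, ev["r"]),
        "ppg": _pulse_channel(n, cfg.fs, ev["ppg_foot"], rise_s),
        "bcg": _bcg_channel(n, cfg.fs, ev["j"]),
        "ipg": _pulse_channel(n, cfg.fs, ev["ipg_foot"], rise_s),
    }
    for name in ("ecg", "ppg", "bcg", "ipg"):
        if cfg.noise_sd > 0:
            channels[name] = channels[name] + rng.normal(0.0, cfg.noise_sd, n)
    record = WaveformRecord(fs=cfg.fs, channels=channels)

    gt = GroundTruth(
        beat_times=ev["r"],
        true_pat1=ev["pat1"], true_pat2=ev["pat2"],
        true_ptt1=ev["ptt1"], true_ptt2=ev["ptt2"],
        true_sbp=ev["sbp"], true_dbp=ev["dbp"], true_hr=ev["hr"],
    )

    # motion artifacts occur while standing after exercise; the rest phase
    # stays clean so the offset calibration is well defined
    if cfg.artifact_rate > 0:
        candidates = np.flatnonzero(beats >= cfg.rest_duration_s)
        hit = candidates[rng.random(len(candidates)) < cfg.artifact_rate]
        for b in hit:
            record = inject_artifact(record, gt, int(b), cfg.artifact_shift_ms)

    ref_t = np.arange(0.0, cfg.duration_s + 1e-9, 60.0)
    bpref = BPReference(
        time_s=ref_t, sbp_mmHg=cfg.sbp_at(ref_t), dbp_mmHg=cfg.dbp_at(ref_t)
    )
    return record, bpref, gt


def inject_artifact(
    record: WaveformRecord,
    gt: GroundTruth,
    beat_index: int,
    shift_ms: float,
    foot_to_peak_ms: float = 80.0,
    j_lag_ms: float = 150.0,
) -> WaveformRecord:
    """Displace one beat's IPG pulse onset by ``shift_ms``.

    The IPG samples around the beat are resampled through a piecewise-linear
    time warp that translates the whole upstroke (foot and peak) by the
    shift while staying continuous at the window edges, emulating a
    mistimed pulse foot.  Other beats are untouched; ``gt.artifact_flags``
    is updated in place.  A zero shift returns an identical copy.
    """
    if not 0 <= beat_index < gt.n_beats:
        raise IndexError(f"beat_index {beat_index} out of range (n={gt.n_beats})")
    out = record.copy()
    if shift_ms == 0:
        return out

    shift = shift_ms / 1000.0
    foot = gt.beat_times[beat_index] + (j_lag_ms + gt.true_ptt1[beat_index]) / 1000.0
    rise = 2 * foot_to_peak_ms / 1000.0
    peak = foot + rise
    w0, w1 = foot - 0.15, peak + 0.25
    if not (w0 < foot + shift < peak + shift < w1):
        raise ValueError(f"shift_ms {shift_ms} too large for the warp window")

    fs = record.fs
    i0 = max(int(math.ceil(w0 * fs)), 0)
    i1 = min(int(math.floor(w1 * fs)) + 1, record.n_samples)
    t = np.arange(i0, i1) / fs
    # warp anchors: window edges fixed, [foot, peak] translated by shift
    src = np.interp(t, [w0, foot + shift, peak + shift, w1], [w0, foot, peak, w1])
    ipg = out.channels["ipg"]
    ipg[i0:i1] = np.interp(src, np.arange(record.n_samples) / fs, ipg)
    gt.artifact_flags[beat_index] = True
    return out


# ---------------------------------------------------------------------------
# cohort-level feature simulator (no waveform synthesis)


def simulate_cohort_features(
    n_segments: int,
    n_sessions: int = 8,
    seed: int = 0,
    beats_per_segment: int = 3,
    interval_noise_ms: float = 2.0,
    bp_noise_mmHg: float = 2.0,
    coupling: tuple[float, float] = (495.23, 1.4615),
    subject_offset_sd_ms: float = 10.0,
) -> pd.DataFrame:
    """Generate a segment-level feature table directly from BP trajectories.

    Sessions draw subject-level resting/peak pressures, then segments sample
    the post-exercise recovery; PTT2 follows the same linear inverse coupling
    to SBP used by the waveform simulator, with millisecond-scale beat noise
    averaged over ``beats_per_segment`` beats.  Targets carry
    ``bp_noise_mmHg`` of cuff-measurement noise, emulating the accuracy of
    the oscillometric reference readings, and each subject's coupling
    intercept is perturbed by ``subject_offset_sd_ms`` (anatomy and sensor
    placement shift absolute transit times between subjects, which is what
    makes resting-BP calibration informative).  This exercises the feature /
    regression layer at cohort scale without paying for waveform synthesis.

    Returns a DataFrame with the eight features (mPTT1, mPTT2, Ratio,
    PTT1_SYS, PTT1_DIA, PTT2_SYS, PTT2_DIA, mHR), the targets sbp_mmHg /
    dbp_mmHg, and a session id column.
    """
    rng = np.random.default_rng(seed)
    a, b = coupling
    per = [n_segments // n_sessions] * n_sessions
    per[-1] += n_segments - sum(per)
    rows = []
    for s, m in enumerate(per):
        a_s = a + rng.normal(0.0, subject_offset_sd_ms)
        sbp_rest = rng.normal(113.0, 8.0)
        dbp_rest = rng.normal(69.0, 5.0)
        sbp_peak = sbp_rest + rng.normal(26.0, 6.0)
        dbp_peak = dbp_rest + rng.normal(5.0, 2.0)
        tau = rng.uniform(90.0, 150.0)
        hr_rest = rng.normal(70.0, 6.0)
        hr_peak = hr_rest + rng.normal(30.0, 6.0)
        t = rng.uniform(0.0, 360.0, size=m)  # seconds into recovery
        decay = np.exp(-t / tau)
        sbp = sbp_rest + (sbp_peak - sbp_rest) * decay
        dbp = dbp_rest + (dbp_peak - dbp_rest) * decay
        hr = hr_rest + (hr_peak - hr_rest) * decay
        k = beats_per_segment
        beat_noise = rng.normal(0.0, interval_noise_ms, size=(m, k)).mean(axis=1)
        mptt2 = a_s - b * sbp + beat_noise
        mptt1 = mptt2 - 80.0 + rng.normal(0.0, interval_noise_ms / math.sqrt(k), size=m)
        mhr = hr + rng.normal(0.0, 1.0, size=m)
        rows.append(
            pd.DataFrame(
                {
                    "session": s,
                    "mPTT1": mptt1,
                    "mPTT2": mptt2,
                    "Ratio": mptt1 / mptt2,
                    "PTT1_SYS": mptt1 / sbp_rest,
                    "PTT1_DIA": mptt1 / dbp_rest,
                    "PTT2_SYS": mptt2 / sbp_rest,
                    "PTT2_DIA": mptt2 / dbp_rest,
                    "mHR": mhr,
                    "sbp_mmHg": sbp + rng.normal(0.0, bp_noise_mmHg, size=m),
                    "dbp_mmHg": dbp + rng.normal(0.0, bp_noise_mmHg, size=m),
                }
            )
        )
    return pd.concat(rows, ignore_index=True)
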