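"""Core data containers shared across the pipeline.

A session is a set of synchronized waveform channels sampled at a common
rate (``WaveformRecord``), a sparse cuff-reference blood-pressure table
(``BPReference``), and — for simulated sessions — the per-beat ground
truth used as the oracle in recovery tests (``GroundTruth``).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["WaveformRecord", "BPReference", "GroundTruth"]


@dataclass
class WaveformRecord:
    """Synchronized multichannel biosignal session.

    Channels are named real-valued arrays of equal length; time for sample
    ``i`` is ``t0 + i / fs`` seconds.
    """

    fs: float
    channels: dict[str, np.ndarray]
    t0: float = 0.0

    def __post_init__(self) -> None:
        if not np.isfinite(self.fs) or self.fs <= 0:
            raise ValueError(f"fs must be positive and finite, got {self.fs}")
        lengths = {name: len(x) for name, x in self.channels.items()}
        if len(set(lengths.values())) > 1:
            raise ValueError(f"channel lengths differ: {lengths}")

    @property
    def n_samples(self) -> int:
        return len(next(iter(self.channels.values())))

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n_samples) / self.fs

    def copy(self) -> "WaveformRecord":
        return WaveformRecord(
            fs=self.fs,
            channels={k: v.copy() for k, v in self.channels.items()},
            t0=self.t0,
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"time_s": self.times})
        for name, x in self.channels.items():
            df[name] = x
        return df

    def save(self, csv_path: str | Path) -> None:
        """Write the channels as CSV plus a JSON metadata sidecar."""
        csv_path = Path(csv_path)
        self.to_frame().to_csv(csv_path, index=False, float_format="%.6g")
        meta = {"fs": self.fs, "duration_s": self.duration_s, "t0": self.t0}
        csv_path.with_suffix(".json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def load(cls, csv_path: str | Path) -> "WaveformRecord":
        csv_path = Path(csv_path)
        df = pd.read_csv(csv_path)
        meta_path = csv_path.with_suffix(".json")
        if meta_path.exists():
            meta = json.loads(meta_path.read_text())
            fs, t0 = float(meta["fs"]), float(meta.get("t0", 0.0))
        else:
            # fall back to the time column spacing
            dt = np.median(np.diff(df["time_s"].to_numpy()))
            fs, t0 = 1.0 / dt, float(df["time_s"].iloc[0])
        channels = {
            c: df[c].to_numpy(dtype=float) for c in df.columns if c != "time_s"
        }
        return cls(fs=fs, channels=channels, t0=t0)


@dataclass
class BPReference:
    """Per-minute cuff blood-pressure readings (time_s, sbp_mmHg, dbp_mmHg)."""

    time_s: np.ndarray
    sbp_mmHg: np.ndarray
    dbp_mmHg: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.time_s, dtype=float)
        if len(t) == 0:
            raise ValueError("BP reference must contain at least one reading")
        if np.any(np.diff(t) <= 0):
            raise ValueError("BP reference times must be strictly increasing")
        sbp = np.asarray(self.sbp_mmHg, dtype=float)
        dbp = np.asarray(self.dbp_mmHg, dtype=float)
        if np.any(sbp <= 0) or np.any(dbp <= 0):
            raise ValueError("pressures must be positive")
        if np.any(sbp <= dbp):
            raise ValueError("SBP must exceed DBP in every reading")
        self.time_s, self.sbp_mmHg, self.dbp_mmHg = t, sbp, dbp

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"time_s": self.time_s, "sbp_mmHg": self.sbp_mmHg, "dbp_mmHg": self.dbp_mmHg}
        )

    def save(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def load(cls, path: str | Path) -> "BPReference":
        df = pd.read_csv(path)
        return cls(
            time_s=df["time_s"].to_numpy(float),
            sbp_mmHg=df["sbp_mmHg"].to_numpy(float),
            dbp_mmHg=df["dbp_mmHg"].to_numpy(float),
        )


@dataclass
class GroundTruth:
    """Per-beat simulator truth: event times, intervals (ms), BP, artifact flags."""

    beat_times: np.ndarray  # R-wave instants, s
    true_pat1: np.ndarray  # ms
    true_pat2: np.ndarray
    true_ptt1: np.ndarray
    true_ptt2: np.ndarray
    true_sbp: np.ndarray  # mmHg
    true_dbp: np.ndarray
    true_hr: np.ndarray  # beats/min
    artifact_flags: np.ndarray = field(default=None)  # bool per beat

    def __post_init__(self) -> None:
        n = len(self.beat_times)
        if self.artifact_flags is None:
            self.artifact_flags = np.zeros(n, dtype=bool)
        arrays = [
            self.true_pat1, self.true_pat2, self.true_ptt1, self.true_ptt2,
            self.true_sbp, self.true_dbp, self.true_hr, self.artifact_flags,
        ]
        if any(len(a) != n for a in arrays):
            raise ValueError("all GroundTruth arrays must share one length")
        for name in ("true_pat1", "true_pat2", "true_ptt1", "true_ptt2"):
            if np.any(getattr(self, name) <= 0):
                raise ValueError(f"{name} must be positive for every beat")

    @property
    def n_beats(self) -> int:
        return len(self.beat_times)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "beat_time_s": self.beat_times,
                "true_pat1_ms": self.true_pat1,
                "true_pat2_ms": self.true_pat2,
                "true_ptt1_ms": self.true_ptt1,
                "true_ptt2_ms": self.true_ptt2,
                "true_sbp_mmHg": self.true_sbp,
                "true_dbp_mmHg": self.true_dbp,
                "true_hr_bpm": self.true_hr,
                "artifact": self.artifact_flags,
            }
        )

    def save(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)
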