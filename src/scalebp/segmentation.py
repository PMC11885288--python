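"""Fixed-length windowing of labeled sessions into classifier/regression samples.

Sessions are cut into 1024-sample windows (about 2 s at 500 Hz) with a
512-sample hop, so adjacent windows overlap by half.  A beat belongs to a
window iff its R wave falls inside it.  A window is kept only when it holds
at least two beats whose quality labels agree; mixed windows are deleted.
Kept windows carry the three scale-side channels (BCG, IPG, DIPG), each
z-normalized independently, plus the mean BP of the member beats.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .preprocess import DegenerateSegmentError, znormalize
from .records import WaveformRecord

__all__ = [
    "Segment",
    "make_segments",
    "segments_to_arrays",
    "categorize_bp",
    "split_dataset",
    "WINDOW_SAMPLES",
    "HOP_SAMPLES",
]

WINDOW_SAMPLES = 1024
HOP_SAMPLES = 512
SEGMENT_CHANNELS = ("bcg", "ipg", "dipg")
BP_CATEGORIES = ("normal", "pre_htn", "stage1", "stage2")


@dataclass
class Segment:
    """One 1024-sample, 3-channel classifier/regression sample."""

    start_index: int
    data: np.ndarray  # (1024, 3) z-normalized (bcg, ipg, dipg)
    quality: int  # 1 good, 0 poor (unanimous over member beats)
    sbp_mmHg: float
    dbp_mmHg: float
    beat_indices: list[int]


def make_segments(
    record: WaveformRecord,
    annotations: pd.DataFrame,
    window: int = WINDOW_SAMPLES,
    hop: int = HOP_SAMPLES,
    min_beats: int = 2,
) -> list[Segment]:
    """Cut an annotated session into quality-labeled segments.

    Windows start at 0, hop, 2*hop, ...; a trailing partial window is
    dropped.  Windows are kept when they contain at least ``min_beats``
    member beats, every member beat has a quality label, and the labels are
    unanimous.  Each kept window's channels are z-normalized independently.
    """
    n = record.n_samples
    if n < window:
        raise ValueError(f"record ({n} samples) shorter than one window ({window})")
    fs = record.fs
    r_times = annotations["r_time_s"].to_numpy(float)
    quality = annotations["quality"].to_numpy(float)
    sbp = annotations["sbp_mmHg"].to_numpy(float)
    dbp = annotations["dbp_mmHg"].to_numpy(float)

    segments: list[Segment] = []
    for start in range(0, n - window + 1, hop):
        t_lo, t_hi = start / fs, (start + window) / fs
        members = np.flatnonzero((r_times >= t_lo) & (r_times < t_hi))
        if len(members) < min_beats:
            continue
        q = quality[members]
        if np.any(np.isnan(q)):  # unlabeable beat: window quality undefined
            continue
        if len(set(q.astype(int))) != 1:  # mixed quality: deleted
            continue
        try:
            data = np.column_stack(
                [
                    znormalize(record.channels[c][start : start + window])
                    for c in SEGMENT_CHANNELS
                ]
            )
        except DegenerateSegmentError:
            continue
        segments.append(
            Segment(
                start_index=start,
                data=data,
                quality=int(q[0]),
                sbp_mmHg=float(sbp[members].mean()),
                dbp_mmHg=float(dbp[members].mean()),
                beat_indices=[int(m) for m in members],
            )
        )
    return segments


def segments_to_arrays(
    segments: list[Segment],
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Stack segments into (X, quality, sbp, dbp) arrays for model code."""
    if not segments:
        raise ValueError("no segments to stack")
    X = np.stack([s.data for s in segments]).astype(np.float32)
    y = np.array([s.quality for s in segments], dtype=np.int64)
    sbp = np.array([s.sbp_mmHg for s in segments])
    dbp = np.array([s.dbp_mmHg for s in segments])
    return X, y, sbp, dbp


def categorize_bp(sbp_mmHg: float, dbp_mmHg: float) -> str:
    """IEEE cuffless-BP category; the higher category of the two pressures wins.

    normal: SBP < 120 and DBP < 80; pre-hypertension: 120 <= SBP < 140 or
    80 <= DBP < 90; stage-1: 140 <= SBP < 160 or 90 <= DBP < 100;
    stage-2: SBP >= 160 or DBP >= 100.
    """
    if sbp_mmHg <= 0 or dbp_mmHg <= 0:
        raise ValueError("pressures must be positive")
    if sbp_mmHg >= 160 or dbp_mmHg >= 100:
        return "stage2"
    if sbp_mmHg >= 140 or dbp_mmHg >= 90:
        return "stage1"
    if sbp_mmHg >= 120 or dbp_mmHg >= 80:
        return "pre_htn"
    return "normal"


def split_dataset(
    n_or_items,
    ratios: tuple[float, ...],
    seed: int = 0,
    stratify_by: np.ndarray | None = None,
) -> list[np.ndarray]:
    """Random disjoint partitions with deterministic, floor-based sizes.

    ``n_or_items`` is either a sample count or a sequence (only its length
    is used); returned partitions are index arrays.  Every partition except
    the last gets the floor of its share; the last absorbs the remainder
    (22,620 at 70:30 gives 15,834/6,786; 2,262 at 80:20 gives 1,809/453).
    With ``stratify_by`` the same rule applies within each stratum.
    """
    n = n_or_items if isinstance(n_or_items, (int, np.integer)) else len(n_or_items)
    if n == 0:
        raise ValueError("cannot split an empty dataset")
    ratios = tuple(float(r) for r in ratios)
    if abs(sum(ratios) - 1.0) > 1e-9:
        raise ValueError(f"ratios must sum to 1, got {sum(ratios)}")
    rng = np.random.default_rng(seed)

    def _split_indices(idx: np.ndarray) -> list[np.ndarray]:
        idx = rng.permutation(idx)
        # epsilon guards exact products (0.7 * 22620) against FP round-down
        sizes = [int(np.floor(r * len(idx) + 1e-9)) for r in ratios[:-1]]
        sizes.append(len(idx) - sum(sizes))
        parts, at = [], 0
        for s in sizes:
            parts.append(np.sort(idx[at : at + s]))
            at += s
        return parts

    if stratify_by is None:
        return _split_indices(np.arange(n))
    strata = np.asarray(stratify_by)
    if len(strata) != n:
        raise ValueError("stratify_by length mismatch")
    parts = [list() for _ in ratios]
    for value in pd.unique(strata):
        for i, p in enumerate(_split_indices(np.flatnonzero(strata == value))):
            parts[i].append(p)
    return [np.sort(np.concatenate(p)) if p else np.empty(0, int) for p in parts]
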