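"""End-to-end orchestration: simulate -> preprocess -> fiducials -> label ->
segment -> quality model -> features -> BP regression -> report.

``run_pipeline`` executes the whole chain on a simulated cohort and writes
every artifact (beat tables, feature table, report JSON, manifest) to a run
directory.  ``session_pipeline`` runs the signal chain on one session and is
the building block the dataset helpers share.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import features as feat
from .evaluation import (
    ConfusionCounts,
    bland_altman,
    classification_metrics,
    error_distribution,
    mad,
    pearson,
)
from .quality_model import QualityNet, QualityNetConfig
from .fiducials import extract_fiducials
from .preprocess import preprocess_record
from .segmentation import make_segments, segments_to_arrays, split_dataset
from .simulate import SimulationConfig, simulate_session
from .timing import annotate_beats

logger = logging.getLogger("scalebp")

__all__ = [
    "PipelineConfig",
    "session_pipeline",
    "build_quality_dataset",
    "run_pipeline",
    "draw_subject_config",
]


@dataclass(frozen=True)
class PipelineConfig:
    """One reproducible full run: per-stage sections, one global seed."""

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    n_sessions: int = 4
    quality_threshold_pct: float = 30.0
    n_bias_beats: int = 5
    split_ratios: tuple[float, float] = (0.7, 0.3)
    val_fraction: float = 0.2
    quality_epochs: int = 6
    quality_config: QualityNetConfig | None = None  # None -> desk-scale
    cv_folds: int = 5
    seed: int = 0

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        d["simulation"].pop("hr_trajectory", None)
        if self.quality_config is not None:
            d["quality_config"] = dataclasses.asdict(self.quality_config)
        return json.dumps(d, indent=2, default=str)

    @classmethod
    def from_json(cls, text: str) -> "PipelineConfig":
        d = json.loads(text)
        if "simulation" in d:
            sim = d["simulation"]
            if "ptt_coupling" in sim:
                sim["ptt_coupling"] = tuple(sim["ptt_coupling"])
            d["simulation"] = SimulationConfig(**sim)
        if d.get("quality_config"):
            qc = d["quality_config"]
            for key in ("kernel_sizes", "dense_units"):
                if key in qc:
                    qc[key] = tuple(qc[key])
            d["quality_config"] = QualityNetConfig(**qc)
        if "split_ratios" in d:
            d["split_ratios"] = tuple(d["split_ratios"])
        return cls(**d)


def draw_subject_config(
    base: SimulationConfig, rng: np.random.Generator, seed: int
) -> SimulationConfig:
    """Subject-level variation around the base protocol conditions."""
    sbp_rest = float(rng.normal(base.sbp_rest, 8.0))
    dbp_rest = float(rng.normal(base.dbp_rest, 5.0))
    return replace(
        base,
        sbp_rest=sbp_rest,
        dbp_rest=dbp_rest,
        sbp_peak=sbp_rest + float(rng.normal(base.sbp_peak - base.sbp_rest, 5.0)),
        dbp_peak=dbp_rest + float(rng.normal(base.dbp_peak - base.dbp_rest, 2.0)),
        hr_rest_bpm=float(rng.normal(base.hr_rest_bpm, 5.0)),
        decay_tau_s=float(rng.uniform(0.8, 1.2) * base.decay_tau_s),
        seed=seed,
    )


def session_pipeline(cfg: SimulationConfig) -> dict:
    """Signal chain for one session; returns every intermediate artifact."""
    record, bp_ref, gt = simulate_session(cfg)
    processed = preprocess_record(record)
    fiducials = extract_fiducials(processed)
    annotations, bias = annotate_beats(
        fiducials, bp_ref, rest_window=(0.0, cfg.rest_duration_s)
    )
    segments = make_segments(processed, annotations)
    return {
        "config": cfg,
        "record": record,
        "processed": processed,
        "bp_ref": bp_ref,
        "ground_truth": gt,
        "annotations": annotations,
        "bias": bias,
        "segments": segments,
    }


def build_quality_dataset(
    n_segments: int,
    seed: int = 0,
    base: SimulationConfig | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Balanced clean/corrupted segment set for classifier experiments.

    Sessions are simulated with a 0.5 per-beat artifact rate in the
    post-exercise phase; windows whose member beats are unanimously good or
    unanimously poor survive segmentation, giving roughly balanced classes
    that are trimmed to exact balance.  Returns (X, y) with X of shape
    (n, 1024, 3).
    """
    base = base or SimulationConfig(
        duration_s=420.0, rest_duration_s=30.0, artifact_rate=0.5
    )
    rng = np.random.default_rng(seed)
    xs, ys = [], []
    n_good = n_poor = 0
    session = 0
    target = n_segments // 2
    while (n_good < target or n_poor < target) and session < 12 * max(
        1, n_segments // 200
    ):
        cfg = draw_subject_config(base, rng, seed=seed + 1000 + session)
        out = session_pipeline(cfg)
        if out["segments"]:
            X, y, _, _ = segments_to_arrays(out["segments"])
            xs.append(X)
            ys.append(y)
            n_good += int((y == 1).sum())
            n_poor += int((y == 0).sum())
        session += 1
    if n_good < target or n_poor < target:
        raise RuntimeError(
            f"could not assemble {n_segments} balanced segments "
            f"(good={n_good}, poor={n_poor})"
        )
    X = np.concatenate(xs)
    y = np.concatenate(ys)
    good = np.flatnonzero(y == 1)[:target]
    poor = np.flatnonzero(y == 0)[:target]
    keep = rng.permutation(np.concatenate([good, poor]))
    return X[keep], y[keep]


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> dict:
    """Execute the full pipeline and write artifacts + report to ``out_dir``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    log_path = out_dir / "run.log"
    handler = logging.FileHandler(log_path)
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    t_start = time.time()
    rng = np.random.default_rng(config.seed)
    report: dict = {"stages": {}}

    try:
        # ---- simulate + signal chain, per session ---------------------
        sessions = []
        all_segments: list = []
        seg_session: list[int] = []
        counts = {"beats": 0, "complete": 0, "good": 0, "poor": 0}
        for s in range(config.n_sessions):
            cfg = draw_subject_config(config.simulation, rng, seed=config.seed * 1000 + s)
            out = session_pipeline(cfg)
            sessions.append(out)
            ann = out["annotations"]
            counts["beats"] += len(ann)
            counts["complete"] += int(ann["complete"].sum())
            counts["good"] += int((ann["quality"] == 1).sum())
            counts["poor"] += int((ann["quality"] == 0).sum())
            seg_session.extend([s] * len(out["segments"]))
            all_segments.extend(out["segments"])
            ann.to_csv(out_dir / f"beats_session{s}.csv", index=False)
            logger.info(
                "session %d: %d beats, %d segments, bias %.1f ms",
                s, len(ann), len(out["segments"]), out["bias"].bias_ms,
            )
        if not all_segments:
            raise RuntimeError("stage segmentation: no segments produced")
        X, y, seg_sbp, seg_dbp = segments_to_arrays(all_segments)
        n_poor = int((y == 0).sum())
        report["stages"]["labeling"] = dict(counts, segments=len(y),
                                            poor_segments=n_poor,
                                            poor_segment_fraction=n_poor / len(y))

        # ---- quality classifier --------------------------------------
        train_idx, test_idx = split_dataset(
            len(y), config.split_ratios, seed=config.seed, stratify_by=y
        )
        inner_tr, inner_val = split_dataset(
            len(train_idx), (1 - config.val_fraction, config.val_fraction),
            seed=config.seed + 1, stratify_by=y[train_idx],
        )
        qcfg = config.quality_config or QualityNetConfig.desk_scale(seed=config.seed)
        clf_report: dict = {"enabled": False}
        tr, va = train_idx[inner_tr], train_idx[inner_val]
        if config.quality_epochs > 0 and len(np.unique(y[tr])) == 2:
            model = QualityNet(qcfg)
            history = model.fit(
                X[tr], y[tr], X[va], y[va], epochs=config.quality_epochs
            )
            labels, _ = model.predict(X[test_idx])
            cm = ConfusionCounts.from_labels(y[test_idx], labels)
            clf_report = {
                "enabled": True,
                "history": history,
                "confusion": dataclasses.asdict(cm),
                "metrics": classification_metrics(cm),
            }
            logger.info("quality model test metrics: %s", clf_report["metrics"])
        report["stages"]["quality_model"] = clf_report

        # ---- features + regression ----------------------------------
        tables = []
        for s, out in enumerate(sessions):
            segs = out["segments"]
            if not segs:
                continue
            cfg = out["config"]
            try:
                tab = feat.extract_feature_table(
                    segs, out["annotations"], cfg.sbp_rest, cfg.dbp_rest
                )
            except ValueError:
                continue
            tab["session"] = s
            tables.append(tab)
        if not tables:
            raise RuntimeError("stage features: no good-quality segments")
        table = pd.concat(tables, ignore_index=True)
        table.to_csv(out_dir / "features.csv", index=False)

        reg_report = {}
        for model_name in ("rf", "xgb"):
            for target in ("sbp_mmHg", "dbp_mmHg"):
                rcfg = feat.RegressorConfig(model=model_name, seed=config.seed)
                cv = feat.cross_validate(
                    table, table[target], rcfg, k=min(config.cv_folds, len(table)),
                    seed=config.seed,
                )
                tr_i, te_i = split_dataset(len(table), config.split_ratios,
                                           seed=config.seed + 2)
                est = feat.fit_bp_regressor(table.iloc[tr_i], table[target].iloc[tr_i], rcfg)
                yhat = est.predict(table.iloc[te_i][list(rcfg.features)].to_numpy(float))
                ref = table[target].iloc[te_i].to_numpy(float)
                ba = bland_altman(ref, yhat)
                reg_report[f"{model_name}_{target[:3]}"] = {
                    "cv": cv,
                    "holdout_pcc": pearson(ref, yhat),
                    "holdout_mad": mad(yhat - ref),
                    "bland_altman": dataclasses.asdict(ba),
                    "error_bins_pct": error_distribution(yhat - ref),
                }
        report["stages"]["regression"] = reg_report

        # ---- report ---------------------------------------------------
        report["elapsed_s"] = time.time() - t_start
        cfg_json = config.to_json()
        (out_dir / "config.json").write_text(cfg_json)
        report["manifest"] = {
            "seed": config.seed,
            "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
        }
        (out_dir / "report.json").write_text(json.dumps(report, indent=2))
        logger.info("pipeline finished in %.1f s", report["elapsed_s"])
        return report
    except Exception as exc:  # stage failures abort with cause
        logger.error("pipeline aborted: %s", exc)
        raise
    finally:
        logger.removeHandler(handler)
        handler.close()
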