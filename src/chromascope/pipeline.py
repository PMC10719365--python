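"""End-to-end orchestration: extraction (segment -> features -> foci ->
typing) and analysis (prune -> balance -> LOPO-CV -> baselines -> screens),
driven by a YAML config with resumable per-sample outputs.

Extraction is fail-soft per sample: a corrupt input is logged and skipped
while the remaining samples complete. Every output directory carries a
``config_hash.txt`` so a results bundle is reproducible from manifest +
config + seed alone.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import analysis as an
from . import cell_typing as ct
from .features import assemble_profile, feature_catalog
from .foci import FociParams, detect_foci
from .io import read_manifest, read_stack
from .segmentation import SegmentationParams, qc_table, segment_stack

log = logging.getLogger("chromascope")

__all__ = ["PipelineConfig", "run_extraction", "run_analysis", "load_config"]


@dataclass
class PipelineConfig:
    manifest: str = ""
    out_dir: str = "chromascope_out"
    dx_um: float = 0.09
    dy_um: float = 0.09
    dz_um: float = 0.5
    segmentation: SegmentationParams = field(default_factory=SegmentationParams)
    foci: FociParams = field(default_factory=FociParams)
    gate_min_cells: int = 20
    # analysis settings
    label_col: str = "condition"
    cells_per_patient: int = 0  # 0 = use all cells
    r_thresh: float = 0.8
    n_perm: int = 10
    n_estimators: int = 500
    ablation_k_grid: tuple = ()
    ablation_p_grid: tuple = ()
    ablation_reps: int = 10
    embedding: str = "tsne"
    seed: int = 0

    def validate(self) -> None:
        if self.dx_um <= 0 or self.dy_um <= 0 or self.dz_um <= 0:
            raise ValueError("voxel sizes must be positive")
        if self.n_perm < 1:
            raise ValueError("n_perm must be >= 1")
        if self.n_estimators < 1:
            raise ValueError("n_estimators must be >= 1")
        if not (0 < self.r_thresh <= 1):
            raise ValueError("r_thresh must be in (0, 1]")

    def hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def load_config(path: str | Path) -> PipelineConfig:
    """Load and validate a YAML pipeline configuration."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    seg = SegmentationParams(**raw.pop("segmentation", {}))
    foci = FociParams(**raw.pop("foci", {}))
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    for key in ("ablation_k_grid", "ablation_p_grid"):
        if key in raw and raw[key] is not None:
            raw[key] = tuple(raw[key])
    cfg = PipelineConfig(segmentation=seg, foci=foci, **raw)
    cfg.validate()
    return cfg


def _write_hash(out_dir: Path, cfg: PipelineConfig) -> None:
    (out_dir / "config_hash.txt").write_text(cfg.hash() + "\n")


def run_extraction(cfg: PipelineConfig) -> pd.DataFrame:
    """Segment every manifest sample, extract profiles, count foci and call
    cell types; write per-stage CSVs under ``cfg.out_dir``.

    Idempotent: samples whose per-sample feature CSV already exists are
    skipped. Per-sample failures are logged and do not stop the run.
    Returns the combined feature table (features.csv).
    """
    cfg.validate()
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    _write_hash(out_dir, cfg)
    per_sample = out_dir / "per_sample"
    per_sample.mkdir(exist_ok=True)
    manifest = read_manifest(cfg.manifest)

    all_qc = []
    for _, row in manifest.iterrows():
        sample_csv = per_sample / f"{row['sample_id']}.csv"
        if sample_csv.exists():
            log.info(json.dumps({"event": "skip_completed", "sample_id": row["sample_id"]}))
            continue
        try:
            stack = read_stack(row["path"], row, cfg.dx_um, cfg.dy_um, cfg.dz_um)
            records = segment_stack(stack, cfg.segmentation)
            all_qc.append(qc_table(records))
            profiles = []
            for rec in records:
                if not rec.qc_pass:
                    continue
                try:
                    prof = assemble_profile(rec)
                    ch = rec.spec.channel_map.get("gH2AX")
                    if ch is not None:
                        prof["foci_count"] = detect_foci(rec.crop[ch], rec.mask3d, cfg.foci, rec.nucleus_id).count
                    profiles.append(prof)
                except Exception as err:  # fail-soft per nucleus
                    log.warning(json.dumps({"event": "nucleus_failed", "nucleus_id": rec.nucleus_id, "error": str(err)}))
            pd.DataFrame(profiles).to_csv(sample_csv, index=False)
        except Exception as err:  # fail-soft per sample
            log.error(json.dumps({"event": "sample_failed", "sample_id": str(row["sample_id"]), "error": str(err)}))

    frames = [pd.read_csv(p) for p in sorted(per_sample.glob("*.csv")) if p.stat().st_size > 1]
    frames = [f for f in frames if not f.empty]
    table = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()
    table.to_csv(out_dir / "features.csv", index=False)
    if all_qc:
        pd.concat(all_qc, ignore_index=True).to_csv(out_dir / "qc.csv", index=False)

    if not table.empty:
        _run_typing(cfg, table, out_dir)
    return table


def _run_typing(cfg: PipelineConfig, table: pd.DataFrame, out_dir: Path) -> None:
    """Per-sample GMM gating on the area-normalized marker intensities."""
    markers = [c.removeprefix("marker_").removesuffix("_area_norm")
               for c in table.columns if c.startswith("marker_") and c.endswith("_area_norm")]
    markers = [m for m in markers if m in ("CD3", "CD4", "CD8")]
    gate_rows, calls = [], []
    for sample_id, sub in table.groupby("sample_id"):
        gates = {}
        for m in markers:
            try:
                gates[m] = ct.fit_marker_gate(
                    sub[f"marker_{m}_area_norm"].to_numpy(), str(sample_id), m,
                    min_cells=cfg.gate_min_cells, seed=cfg.seed,
                )
                g = gates[m]
                gate_rows.append({"sample_id": sample_id, "marker": m, "threshold": g.threshold,
                                  "separation": g.separation, "converged": g.converged})
            except ct.GateError as err:
                log.warning(json.dumps({"event": "gate_unreliable", "sample_id": str(sample_id),
                                        "marker": m, "error": str(err)}))
        quants = sub[["nucleus_id"]].copy()
        for m in markers:
            quants[m] = sub[f"marker_{m}_area_norm"].to_numpy()
        calls.append(ct.calls_table(ct.call_cell_types(gates, quants)).assign(sample_id=sample_id))
    if gate_rows:
        pd.DataFrame(gate_rows).to_csv(out_dir / "gates.csv", index=False)
    if calls:
        pd.concat(calls, ignore_index=True).to_csv(out_dir / "cell_types.csv", index=False)


def run_analysis(cfg: PipelineConfig, table: pd.DataFrame | None = None) -> dict:
    """Run the full analysis layer on a feature table and write the bundle.

    Stages: correlation pruning -> patient-balanced sampling -> LOPO-CV ->
    patient majority vote -> permutation baseline -> optional ablations ->
    Gini ranking + Welch/BH screen -> QC embedding. All randomness derives
    from ``cfg.seed``. Returns the results dict (also written as
    results.json, with tidy CSVs next to it).
    """
    cfg.validate()
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    _write_hash(out_dir, cfg)
    if table is None:
        table = pd.read_csv(out_dir / "features.csv")
    table = table.dropna(axis=1, how="any")

    rng = np.random.default_rng(cfg.seed)
    rf = an.RFConfig(n_estimators=cfg.n_estimators)
    pruned, removed = an.prune_correlated(table, cfg.r_thresh)
    if cfg.cells_per_patient:
        pruned = an.balance_sample(pruned, cfg.cells_per_patient, by="patient_id",
                                   within=("timepoint",), seed=int(rng.integers(2**31)))
    cv = an.lopo_cv_rfc(pruned, cfg.label_col, rf=rf, seed=int(rng.integers(2**31)))
    vote = an.patient_majority_vote(cv)
    baseline = an.permutation_baseline(pruned, cfg.label_col, n_perm=cfg.n_perm, rf=rf,
                                       seed=int(rng.integers(2**31)), real_cv=cv)
    ranking = an.gini_ranking(cv, categories=feature_catalog())
    screen = an.welch_screen_bh(pruned, cfg.label_col)

    results = {
        "config_hash": cfg.hash(),
        "n_cells": int(len(pruned)),
        "n_patients": int(pruned["patient_id"].nunique()),
        "removed_features": removed,
        "classes": cv.classes,
        "fold_scores": cv.fold_scores.tolist(),
        "balanced_accuracy_mean": cv.mean_score,
        "balanced_accuracy_sd": cv.sd_score,
        "sensitivity": cv.sensitivity,
        "specificity": cv.specificity,
        "confusion": cv.confusion.tolist(),
        "patient_accuracy": float(vote["correct"].mean()),
        "permutation_null_mean": baseline.null_mean,
        "permutation_null_means": baseline.null_means.tolist(),
        "wilcoxon_p_vs_null": baseline.p_value,
        "n_significant_features": int(len(screen.significant_features)),
    }
    for key, grid, fn in (("ablation_patients", cfg.ablation_k_grid, an.ablation_patients),
                          ("ablation_cells", cfg.ablation_p_grid, an.ablation_cells)):
        if grid:
            ab = fn(pruned, cfg.label_col, grid, reps=cfg.ablation_reps, rf=rf,
                    seed=int(rng.integers(2**31)))
            results[key] = {"grid": ab.grid, "mean": ab.scores.mean(axis=1).tolist()}
            ab.summary.to_csv(out_dir / f"{key}.csv", index=False)

    (out_dir / "results.json").write_text(json.dumps(results, indent=2))
    vote.to_csv(out_dir / "patient_votes.csv", index=False)
    ranking.to_csv(out_dir / "gini_ranking.csv", index=False)
    screen.table.to_csv(out_dir / "welch_screen.csv", index=False)
    try:
        emb = an.qc_embedding(pruned, method=cfg.embedding, seed=cfg.seed)
        emb.to_csv(out_dir / "embedding.csv", index=False)
    except ValueError as err:
        log.warning(json.dumps({"event": "embedding_skipped", "error": str(err)}))
    return results
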