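"""End-to-end orchestration: simulate -> segment -> stats.

All randomness flows from a single global seed: the cohort is sampled
with it directly and each subject's phantom is rendered from the derived
seed sequence ``(seed, subject_index)``, so a full run is reproducible
from ``(config, seed)`` alone.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .cohort import (
    CohortConfig,
    SubjectRecord,
    default_config,
    make_label_volume,
    render_subject,
    sample_cohort,
    write_cohort,
)
from .errors import ConfigurationError
from .masking import extract_brain, segment_tissues, supraventricular_roi, volumetrics
from .vesselness import (
    VesselnessParams,
    multiscale_vesselness,
    quantify,
    segment_vrs,
)
from .volume import ImageVolume, save_labels

__all__ = [
    "RunConfig",
    "process_subject",
    "run_simulate",
    "run_segment",
    "run_stats",
]

logger = logging.getLogger("vrsquant")

METRICS_COLUMNS = [
    "subject_id",
    "vrs_count",
    "vrs_volume_mm3",
    "wm_volume_mm3",
    "brain_volume_mm3",
]


@dataclass
class RunConfig:
    """Resolved configuration of a full pipeline run."""

    cohort: CohortConfig = field(default_factory=default_config)
    vesselness: VesselnessParams = field(default_factory=VesselnessParams)
    seg_threshold: float = 0.25
    seg_min_size: int = 2
    seg_max_size: int = 200
    alpha: float = 0.05
    n_comparisons: int = 3
    seed: int = 0

    def validate(self) -> None:
        self.cohort.validate()
        if not 0.0 < self.seg_threshold < 1.0:
            raise ConfigurationError("seg_threshold must be in (0, 1)")
        if self.seg_min_size < 1 or self.seg_max_size < self.seg_min_size:
            raise ConfigurationError("need 1 <= seg_min_size <= seg_max_size")
        if not 0.0 < self.alpha < 1.0:
            raise ConfigurationError("alpha must be in (0, 1)")
        if self.n_comparisons < 1:
            raise ConfigurationError("n_comparisons must be >= 1")

    def to_dict(self) -> dict:
        return {
            "cohort": self.cohort.to_dict(),
            "vesselness": asdict(self.vesselness),
            "seg_threshold": self.seg_threshold,
            "seg_min_size": self.seg_min_size,
            "seg_max_size": self.seg_max_size,
            "alpha": self.alpha,
            "n_comparisons": self.n_comparisons,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "cohort" in d:
            d["cohort"] = CohortConfig.from_dict(d["cohort"])
        if "vesselness" in d:
            v = dict(d["vesselness"])
            if "scales_mm" in v:
                v["scales_mm"] = tuple(v["scales_mm"])
            d["vesselness"] = VesselnessParams(**v)
        cfg = cls(**d)
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        try:
            return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})
        except (TypeError, ValueError, KeyError) as exc:
            raise ConfigurationError(f"invalid run config {path}: {exc}") from exc


def subject_render_seed(seed: int, index: int) -> np.random.SeedSequence:
    """Documented per-subject seed derivation: (global seed, subject index)."""
    return np.random.SeedSequence((seed, index))


def process_subject(
    volume: ImageVolume, config: RunConfig
) -> dict:
    """Run the full measurement chain on one T2 volume.

    brain extraction -> tissue clustering -> supraventricular WM ROI ->
    multiscale 2-D vesselness -> thresholding + 3-D component filtering ->
    count / volume quantification. Returns a metrics row (dict).
    """
    brain = extract_brain(volume)
    masks = segment_tissues(volume, brain)
    roi = supraventricular_roi(masks, volume.spacing, config.cohort.roi_min_area_mm2)
    vess = multiscale_vesselness(volume, roi, config.vesselness)
    seg = segment_vrs(
        vess, roi, config.seg_threshold, config.seg_min_size, config.seg_max_size
    )
    metrics = quantify(seg, volume.spacing)
    bv, wmv = volumetrics(masks, volume.spacing)
    return {
        "vrs_count": metrics.count,
        "vrs_volume_mm3": metrics.volume_mm3,
        "wm_volume_mm3": wmv,
        "brain_volume_mm3": bv,
        "_segmentation": seg,
    }


def measure_cohort(
    records: Sequence[SubjectRecord], config: RunConfig
) -> pd.DataFrame:
    """Render and measure every subject in memory (no disk I/O).

    Returns the merged covariate + metrics table used by the statistics
    layer. Phantoms are rendered one at a time from the per-subject seed
    derivation, so memory stays flat for large cohorts.
    """
    from .cohort import records_to_frame

    rows = []
    for i, rec in enumerate(records):
        vol, _masks, _tub = render_subject(
            rec, config.cohort, subject_render_seed(config.seed, i)
        )
        row = process_subject(vol, config)
        row.pop("_segmentation")
        row["subject_id"] = rec.subject_id
        rows.append(row)
    metrics = pd.DataFrame(rows)
    return records_to_frame(records).merge(metrics, on="subject_id", validate="1:1")


def run_simulate(config: RunConfig, out_dir: str | Path) -> Path:
    """Sample and render the configured cohort; write it with a manifest."""
    config.validate()
    records = sample_cohort(config.cohort, config.seed)
    logger.info("simulating %d subjects -> %s", len(records), out_dir)

    def image_stream():
        for i, rec in enumerate(records):
            vol, masks, tubules = render_subject(
                rec, config.cohort, subject_render_seed(config.seed, i)
            )
            yield vol, make_label_volume(masks, tubules)

    manifest = write_cohort(
        records, image_stream(), out_dir, config=config.cohort, seed=config.seed
    )
    logger.info("wrote manifest %s", manifest)
    return manifest


def run_segment(
    config: RunConfig,
    cohort_dir: str | Path,
    out_dir: str | Path,
    save_label_maps: bool = True,
) -> Path:
    """Measure every subject of a cohort on disk; write metrics.csv.

    Missing or unreadable volumes are skipped with a warning; the run
    fails only if no subject could be processed.
    """
    config.validate()
    cohort_dir = Path(cohort_dir)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = json.loads((cohort_dir / "manifest.json").read_text())
    logger.info(
        "segmentation parameters: threshold=%s min_size=%s max_size=%s scales=%s",
        config.seg_threshold,
        config.seg_min_size,
        config.seg_max_size,
        config.vesselness.scales_mm,
    )

    rows = []
    failures = []
    for sub in manifest["subjects"]:
        path = cohort_dir / sub["image"]
        try:
            vol = ImageVolume.load(path)
            row = process_subject(vol, config)
        except Exception as exc:  # noqa: BLE001 - skip-and-log per subject
            logger.warning("skipping %s: %s", sub["subject_id"], exc)
            failures.append(sub["subject_id"])
            continue
        seg = row.pop("_segmentation")
        if save_label_maps:
            save_labels_path = out_dir / f"sub-{sub['subject_id']}_vrs.nii.gz"
            save_labels(seg.label_map, vol.spacing, save_labels_path, dtype=np.int32)
        row["subject_id"] = sub["subject_id"]
        rows.append(row)

    if not rows:
        raise RuntimeError(f"all {len(failures)} subjects failed; no metrics written")
    metrics_path = out_dir / "metrics.csv"
    pd.DataFrame(rows)[METRICS_COLUMNS].to_csv(metrics_path, index=False)
    logger.info("wrote %s (%d rows, %d skipped)", metrics_path, len(rows), len(failures))
    return metrics_path


def run_stats(
    config: RunConfig,
    metrics_csv: str | Path,
    covariates_csv: str | Path,
    out_dir: str | Path,
):
    """Join metrics with covariates and write the statistical reports."""
    from .stats import build_report

    config.validate()
    out_dir = Path(out_dir)
    metrics = pd.read_csv(metrics_csv)
    if metrics.empty:
        raise ValueError(f"metrics table {metrics_csv} is empty")
    cov = pd.read_csv(covariates_csv)
    orphans_m = sorted(set(metrics["subject_id"]) - set(cov["subject_id"]))
    orphans_c = sorted(set(cov["subject_id"]) - set(metrics["subject_id"]))
    if orphans_m or orphans_c:
        raise ValueError(
            f"subject mismatch between tables: metrics-only={orphans_m}, "
            f"covariates-only={orphans_c}"
        )
    df = cov.drop(columns=["planted_count", "planted_volume_mm3"], errors="ignore")
    df = df.drop(columns=["brain_volume_target_mm3", "wm_volume_target_mm3"], errors="ignore")
    df = df.merge(metrics, on="subject_id", validate="1:1")

    report = build_report(df, alpha=config.alpha, n_comparisons=config.n_comparisons)
    out_dir.mkdir(parents=True, exist_ok=True)
    report.comparison_table().to_csv(out_dir / "group_comparisons.csv", index=False)
    report.correlation_table().to_csv(out_dir / "correlations.csv", index=False)
    report.to_json(out_dir / "stat_report.json")
    (out_dir / "run_config.json").write_text(json.dumps(config.to_dict(), indent=2))
    for comp in report.comparisons:
        logger.info(
            "%s: %s", comp.metric,
            "; ".join(f"{a} vs {b}: p={p:.3g}" for (a, b), p in comp.pairwise_p.items()),
        )
    return report
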