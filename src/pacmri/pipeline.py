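"""End-to-end orchestration: reconstruction through model comparison.

``run_pipeline`` processes a cohort of subjects (in-memory objects or HDF5
paths) with one fixed :class:`~pacmri.config.PipelineConfig`: reconstruct
the 1D+t velocity map, refine and screen the ECG cycles, segment the aorta,
measure per-cycle end-systole, split train/holdout, fit the patient-adapted
model, and apply the residual-SD quality gate.  Any stage failure downgrades
the subject's status without aborting the cohort; per-cycle counts always
reconcile (processed = accepted + each rejection reason).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Union

import numpy as np
import pandas as pd

from . import ecg as ecg_mod
from . import evaluate, io, models, recon, segment, systole
from .config import PipelineConfig
from .errors import SegmentationError
from .simulate import Subject

log = logging.getLogger(__name__)

SUBJECT_STATUSES = ("analyzed", "excluded_quality", "segmentation_failed", "failed")


@dataclass
class SubjectResult:
    """Everything the pipeline measured for one subject."""

    subject_id: str
    sex: str
    status: str
    cycle_table: Optional[ecg_mod.CycleTable] = None
    samples: List[systole.SystoleSample] = field(default_factory=list)
    train: List[systole.SystoleSample] = field(default_factory=list)
    holdout: List[systole.SystoleSample] = field(default_factory=list)
    pacm: Optional[models.CardiacModel] = None
    roi_pixels: Optional[np.ndarray] = None
    pixel0: int = 0
    error: str = ""

    @property
    def n_valid(self) -> int:
        return sum(1 for s in self.samples if s.valid)


@dataclass
class RunManifest:
    """Cohort-level bookkeeping, serialisable to JSON."""

    config_hash: str
    seeds: List[int]
    subject_status: Dict[str, str]
    cycle_counts: Dict[str, int]
    output_paths: List[str] = field(default_factory=list)
    excluded_residual_sd: Dict[str, float] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @property
    def n_analyzed(self) -> int:
        return sum(1 for v in self.subject_status.values() if v == "analyzed")


def _config_hash(cfg: PipelineConfig) -> str:
    payload = json.dumps(cfg.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


def process_subject(subject: Subject, cfg: Optional[PipelineConfig] = None) -> SubjectResult:
    """Run the full measurement chain on one subject."""
    cfg = cfg or PipelineConfig()
    sid = subject.config.subject_id
    result = SubjectResult(subject_id=sid, sex=subject.config.sex, status="failed")
    try:
        vmap = recon.reconstruct(subject.echoes, fov_fraction=cfg.fov_fraction)
        result.pixel0 = vmap.pixel0

        cycles = ecg_mod.refine_and_screen(
            subject.ecg,
            window_s=cfg.qrs_window_s,
            search_s=cfg.qrs_search_s,
            hr_min_bpm=cfg.hr_min_bpm,
            hr_max_bpm=cfg.hr_max_bpm,
            ectopic_frac=cfg.ectopic_frac,
        )
        if not cycles.accepted.any():
            result.status = "failed"
            result.error = "no accepted cycles"
            result.cycle_table = cycles
            return result
        mean_hr = float(np.mean(cycles.hr[cycles.accepted]))

        try:
            seg = segment.segment_aorta(
                vmap,
                mean_hr,
                k=cfg.svd_rank,
                tau=cfg.svd_threshold,
                halfwidth_hz=cfg.band_halfwidth_hz,
                power_fraction=cfg.power_fraction,
            )
        except SegmentationError as exc:
            result.status = "segmentation_failed"
            result.error = str(exc)
            result.cycle_table = cycles
            return result
        result.roi_pixels = seg.chosen.pixels + vmap.pixel0

        samples, cycles, _ = systole.measure_systole(
            seg.chosen.course,
            vmap.times,
            cycles,
            n_iter=cfg.baseline_iterations,
            f_lp=cfg.baseline_lowpass_hz,
            n_bins=cfg.baseline_bins,
            min_s=cfg.systole_min_s,
            max_s=cfg.systole_max_s,
            subject_id=sid,
        )
        result.cycle_table = cycles
        result.samples = samples

        split = models.split_train_holdout(samples, frac=cfg.train_fraction)
        result.train = split.train
        result.holdout = split.holdout
        if split.flagged_subjects:
            result.status = "failed"
            result.error = "too few valid cycles"
            return result

        pacm = models.fit_pacm(
            split.train,
            method=cfg.regression,
            quality_threshold_s=cfg.quality_threshold_s,
            sex=subject.config.sex,
            subject_id=sid,
        )
        result.pacm = pacm
        result.status = "analyzed" if pacm.quality_ok else "excluded_quality"
    except Exception as exc:  # noqa: BLE001 - cohort runs must not abort
        log.exception("subject %s failed", sid)
        result.status = "failed"
        result.error = str(exc)
    return result


def run_pipeline(
    subjects: Sequence[Union[Subject, str]],
    cfg: Optional[PipelineConfig] = None,
) -> tuple:
    """Process a cohort; returns ``(manifest, results)``.

    ``subjects`` may mix in-memory :class:`Subject` objects and HDF5 paths.
    """
    cfg = cfg or PipelineConfig()
    results: List[SubjectResult] = []
    seeds: List[int] = []
    for item in subjects:
        subject = io.load_subject(item) if isinstance(item, str) else item
        seeds.append(int(subject.config.seed))
        results.append(process_subject(subject, cfg))

    counts: Dict[str, int] = {r: 0 for r in ecg_mod.REASONS}
    status: Dict[str, str] = {}
    excluded_sd: Dict[str, float] = {}
    for res in results:
        status[res.subject_id] = res.status
        if res.cycle_table is not None:
            for reason, c in res.cycle_table.reason_counts().items():
                counts[reason] += c
        if res.status == "excluded_quality" and res.pacm is not None:
            excluded_sd[res.subject_id] = res.pacm.residual_sd
    manifest = RunManifest(
        config_hash=_config_hash(cfg),
        seeds=seeds,
        subject_status=status,
        cycle_counts=counts,
        excluded_residual_sd=excluded_sd,
    )
    return manifest, results


def cohort_report(
    results: Sequence[SubjectResult], cfg: Optional[PipelineConfig] = None
) -> Dict[str, pd.DataFrame]:
    """Summary tables: per-subject models, pooled per-sex rows, Bland-Altman.

    The pooled rows report the regression coefficients with 95% confidence
    intervals (+/-1.96 SE), the residual SD, and both determination
    coefficients (per-cycle and on subject-mean points).  Excluded subjects
    are marked and keep their residual SD.
    """
    cfg = cfg or PipelineConfig()
    analyzed = [r for r in results if r.status == "analyzed"]
    if not analyzed:
        raise ValueError("no analyzed subject to report on")

    subject_rows = []
    for r in results:
        row = {
            "subject_id": r.subject_id,
            "sex": r.sex,
            "status": r.status,
            "excluded": "x" if r.status != "analyzed" else "",
            "slope_s_per_bpm": np.nan,
            "intercept_s": np.nan,
            "residual_sd_s": np.nan,
            "r_squared": np.nan,
            "n_train": 0,
        }
        if r.pacm is not None:
            row.update(
                slope_s_per_bpm=r.pacm.slope,
                intercept_s=r.pacm.intercept,
                residual_sd_s=r.pacm.residual_sd,
                r_squared=np.nan if r.pacm.r_squared is None else r.pacm.r_squared,
                n_train=r.pacm.n_train,
            )
        subject_rows.append(row)
    subjects_df = pd.DataFrame(subject_rows)

    pooled_rows = []
    for sex in ("M", "F"):
        pool = [s for r in analyzed if r.sex == sex for s in r.train]
        if len({s.subject_id for s in pool}) < 1 or len(pool) < 5:
            continue
        pm = models.fit_population_model(pool, sex=sex, method=cfg.regression)
        pooled_rows.append(
            {
                "model": "pacm_averaged",
                "sex": sex,
                "slope_s_per_bpm": pm.slope,
                "slope_ci95": 1.96 * pm.slope_se,
                "intercept_s": pm.intercept,
                "intercept_ci95": 1.96 * pm.intercept_se,
                "residual_sd_s": pm.residual_sd,
                "r_squared_cycles": np.nan if pm.r_squared is None else pm.r_squared,
                "r_squared_subject_means": (
                    np.nan
                    if pm.r_squared_subject_means is None
                    else pm.r_squared_subject_means
                ),
                "n_train": pm.n_train,
            }
        )
    pooled_df = pd.DataFrame(pooled_rows)

    pacm_by_subject = {r.subject_id: r.pacm for r in analyzed}
    sex_by_subject = {r.subject_id: r.sex for r in analyzed}
    holdout = [s for r in analyzed for s in r.holdout]
    ba_df = pd.DataFrame()
    if holdout:
        global_rows = {
            "weissler": {s: models.weissler_model(s) for s in ("M", "F")},
            "pacm_averaged": {
                s: models.global_model("pacm_averaged", s) for s in ("M", "F")
            },
        }
        ba_df = evaluate.compare_models(
            holdout,
            pacm_by_subject,
            global_rows,
            sex_by_subject=sex_by_subject,
            outlier_k=cfg.outlier_k,
        )
    return {"subjects": subjects_df, "pooled": pooled_df, "bland_altman": ba_df}
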