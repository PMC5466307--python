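"""Configuration objects for the simulator and the processing pipeline.

Two small dataclasses describe a synthetic acquisition: :class:`SubjectConfig`
holds the physiology of one subject (heart-rate statistics, the generating
linear systole/heart-rate model, artifact levels) and
:class:`AcquisitionConfig` holds the scanner-side parameters of the real-time
phase-contrast (RTPC) sequence (central k-space line only, interleaved
velocity encoding).  :class:`PipelineConfig` collects every tunable of the
processing chain so that a whole cohort is processed with one fixed set of
parameters.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Tuple


def _is_power_of_two(n: int) -> bool:
    return n > 0 and (n & (n - 1)) == 0


@dataclass
class AcquisitionConfig:
    """RTPC sequence parameters (defaults follow the real-time protocol).

    The sequence repeats a single central k-space line every ``tr_s`` seconds
    with the velocity-encoding gradient toggled between consecutive echoes,
    so the effective temporal resolution after shared velocity encoding is
    one TR.
    """

    fov_mm: float = 350.0
    matrix_freq: int = 256
    tr_s: float = 0.0066
    te_s: float = 0.0034
    venc_cm_s: float = 150.0
    n_channels: int = 2
    slice_thickness_mm: float = 8.0

    def __post_init__(self) -> None:
        if not _is_power_of_two(self.matrix_freq):
            raise ValueError(f"matrix_freq must be a power of two, got {self.matrix_freq}")
        if self.tr_s <= 0:
            raise ValueError("tr_s must be positive")
        if self.venc_cm_s <= 0:
            raise ValueError("venc_cm_s must be positive")
        if self.n_channels < 1:
            raise ValueError("n_channels must be >= 1")

    @property
    def pixel_mm(self) -> float:
        return self.fov_mm / self.matrix_freq

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "AcquisitionConfig":
        return cls(**d)


@dataclass
class SubjectConfig:
    """Physiology and artifact model of one synthetic subject.

    The generating model of end-systole duration is linear in heart rate,
    ``S = true_intercept + true_slope * HR + N(0, residual_sd)``, the same
    form the patient-adapted cardiac model later fits.  Instantaneous heart
    rate is drawn per beat from a truncated normal in bpm.

    All randomness derives from ``seed`` through an explicit
    generator-splitting scheme (see :mod:`pacmri.simulate`), so an identical
    config yields bit-identical output.
    """

    subject_id: str = "subject-000"
    sex: str = "M"
    n_beats: int = 128
    mean_hr: float = 67.0
    sd_hr: float = 9.5
    hr_bounds: Tuple[float, float] = (44.0, 114.0)
    hr_autocorr: float = 0.95   # lag-1 autocorrelation of the beat-to-beat HR
    true_slope: float = -0.0018     # s/bpm
    true_intercept: float = 0.456   # s
    residual_sd: float = 0.005      # s, cycle-to-cycle scatter around the line
    n_confounders: int = 1
    ectopic_rate: float = 0.02      # probability per beat
    r_jitter_sd: float = 0.010      # s, online R-wave detection jitter
    mhd_amplitude: float = 0.25     # mV, magneto-hydrodynamic bump on the ECG
    noise_sd: float = 3.0           # cm/s, velocity noise at unit magnitude
    seed: int = 0
    # Waveform conventions (the shapes are synthetic by construction; only the
    # timing of the end of forward systolic flow matters downstream).
    peak_velocity_cm_s: float = 100.0
    ejection_delay_s: float = 0.030
    undershoot_frac: float = 0.12   # end-systolic backflow depth, fraction of peak
    ecg_fs: float = 1000.0          # Hz

    def __post_init__(self) -> None:
        if self.n_beats < 3:
            raise ValueError("n_beats must be >= 3")
        if self.sd_hr < 0:
            raise ValueError("sd_hr must be >= 0")
        if self.residual_sd < 0:
            raise ValueError("residual_sd must be >= 0")
        lo, hi = self.hr_bounds
        if not lo < hi:
            raise ValueError(f"hr_bounds must be increasing, got {self.hr_bounds}")
        if self.sex not in ("M", "F"):
            raise ValueError(f"sex must be 'M' or 'F', got {self.sex!r}")
        if not 0.0 <= self.ectopic_rate <= 1.0:
            raise ValueError("ectopic_rate must be a probability")
        if not 0.0 <= self.hr_autocorr < 1.0:
            raise ValueError("hr_autocorr must be in [0, 1)")
        if self.ecg_fs < 200.0:
            raise ValueError("ecg_fs must be >= 200 Hz")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["hr_bounds"] = list(self.hr_bounds)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SubjectConfig":
        d = dict(d)
        if "hr_bounds" in d:
            d["hr_bounds"] = tuple(d["hr_bounds"])
        return cls(**d)

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True)

    @classmethod
    def from_json(cls, s: str) -> "SubjectConfig":
        return cls.from_dict(json.loads(s))


@dataclass
class PipelineConfig:
    """Every tunable of the processing chain, fixed once per cohort.

    The pipeline is parameter-free per subject: the same values are applied
    to every record.
    """

    fov_fraction: float = 0.5          # central FOV kept after the 1D FFT
    svd_rank: int = 3                  # singular components used for segmentation
    svd_threshold: float = 0.25        # loading threshold, fraction of the max
    band_halfwidth_hz: float = 0.03    # cardiac spectral band half-width
    power_fraction: float = 0.40       # ROI candidate rule: > fraction of max band power
    qrs_window_s: float = 0.12         # QRS template width
    qrs_search_s: float = 0.05         # repositioning search radius
    hr_min_bpm: float = 30.0           # cycle screening bounds
    hr_max_bpm: float = 120.0
    ectopic_frac: float = 0.20         # RR deviation for ectopic rule
    baseline_iterations: int = 10
    baseline_lowpass_hz: float = 0.5
    baseline_bins: int = 64
    systole_min_s: float = 0.100       # physiological bounds on measured systole
    systole_max_s: float = 0.500
    train_fraction: float = 0.8
    regression: str = "huber"          # 'huber' or 'ols'
    quality_threshold_s: float = 0.010  # residual-SD gate on the fitted model
    outlier_k: float = 4.0             # holdout exclusion, multiples of robust SD
    cine_frames: int = 64
    early_diastole_frac: float = 1 / 3  # E-wave search window after mean systole

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        return cls(**d)


def load_config(path: str) -> dict:
    """Read a YAML or JSON key-value config file."""
    import yaml

    with open(path) as fh:
        return yaml.safe_load(fh) or {}


def save_config(cfg, path: str) -> None:
    import yaml

    d = cfg.to_dict() if hasattr(cfg, "to_dict") else dict(cfg)
    with open(path, "w") as fh:
        yaml.safe_dump(d, fh, sort_keys=True)
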