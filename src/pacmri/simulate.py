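"""Synthetic real-time phase-contrast (RTPC) acquisition generator.

Generates everything a downstream analysis needs, with ground truth: an RR
sequence with optional ectopic beats, per-beat end-systole durations from a
linear heart-rate model, a 1D+t velocity/magnitude scene of the aorta and
confounding vessels, the corresponding central-k-space-line echo stream per
coil channel with interleaved velocity encoding, and a multi-lead ECG with
a magneto-hydrodynamic (MHD) artifact and jittered online R-wave detections.

The aortic waveform is synthetic by construction: an asymmetric ejection
lobe followed by a brief end-systolic flow reversal (the dicrotic-notch
backflow of ascending-aorta flow), so the end of forward flow is a steep,
well-defined zero crossing at exactly ``R + S_i``.  Only that timing matters
to the measurement chain; the lobe shape itself is conventional.

All randomness flows from ``SubjectConfig.seed`` through a fixed
``numpy.random.SeedSequence`` splitting scheme, so identical configs yield
bit-identical subjects.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .config import AcquisitionConfig, SubjectConfig
from .errors import SimulationError

# Fixed stream names for the generator-splitting scheme (order matters).
_STREAMS = ("rr", "ectopic", "systole", "scene", "ecg", "jitter", "tissue")


def _child_rngs(seed: int) -> dict:
    children = np.random.SeedSequence(seed).spawn(len(_STREAMS))
    return {name: np.random.default_rng(ss) for name, ss in zip(_STREAMS, children)}


# ---------------------------------------------------------------------------
# Domain containers
# ---------------------------------------------------------------------------

@dataclass
class GroundTruth:
    """Per-beat ground truth the real acquisition lacks."""

    r_times: np.ndarray          # s, start of each beat (strictly increasing)
    rr_durations: np.ndarray     # s
    end_systole_s: np.ndarray    # s, true end of forward systolic flow after R
    aorta_pixels: np.ndarray     # full-FOV pixel indices (contiguous)
    confounder_pixels: List[np.ndarray]
    is_ectopic: np.ndarray       # bool per beat

    def __post_init__(self) -> None:
        if not np.all(np.diff(self.r_times) > 0):
            raise ValueError("r_times must be strictly increasing")
        if np.any(self.end_systole_s >= self.rr_durations):
            raise ValueError("end-systole must end within its cycle")
        if len(self.aorta_pixels) == 0:
            raise ValueError("aorta_pixels must be non-empty")


@dataclass
class VelocityScene:
    """Noisy 1D+t velocity/magnitude movie sampled at the echo times."""

    velocity: np.ndarray   # cm/s, [pixel, time]
    magnitude: np.ndarray  # a.u., [pixel, time]
    times: np.ndarray      # s, one per frame
    dt: float              # s


@dataclass
class EchoStream:
    """Per-channel complex central-k-space-line echoes."""

    samples: np.ndarray     # complex, [channel, echo, frequency-sample]
    echo_times: np.ndarray  # s
    venc_toggle: np.ndarray  # +1/-1 per echo, alternating
    config: AcquisitionConfig

    def __post_init__(self) -> None:
        spacing = np.diff(self.echo_times)
        if len(spacing) and not np.allclose(spacing, self.config.tr_s, rtol=1e-9):
            raise ValueError("echo spacing must equal TR")
        if len(self.venc_toggle) > 1 and np.any(
            self.venc_toggle[1:] == self.venc_toggle[:-1]
        ):
            raise ValueError("venc_toggle must alternate")


@dataclass
class ECGTrace:
    """Multi-lead ECG with online R-wave detections."""

    samples: np.ndarray           # mV, [lead, time]
    fs: float                     # Hz
    online_detections: np.ndarray  # s

    def __post_init__(self) -> None:
        if self.fs < 200.0:
            raise ValueError("ECG sampling rate must be >= 200 Hz")
        duration = self.samples.shape[1] / self.fs
        if np.any(self.online_detections < 0) or np.any(self.online_detections > duration):
            raise ValueError("online detections must lie within the record")

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.samples.shape[1]) / self.fs


@dataclass
class Subject:
    """One complete synthetic acquisition."""

    echoes: EchoStream
    ecg: ECGTrace
    truth: GroundTruth
    config: SubjectConfig
    acq: AcquisitionConfig
    scene: Optional[VelocityScene] = None  # kept only when requested


# ---------------------------------------------------------------------------
# RR sequence and end-systole truth
# ---------------------------------------------------------------------------

def simulate_rr_sequence(
    config: SubjectConfig,
    rng: Optional[np.random.Generator] = None,
    ectopic_rng: Optional[np.random.Generator] = None,
) -> Tuple[np.ndarray, np.ndarray]:
    """Draw per-beat RR durations (s) and the ectopic-beat mask.

    Instantaneous heart rate (60/RR, bpm) follows a stationary Gaussian
    AR(1) process with the configured marginal mean/SD, rejection-sampled
    into ``hr_bounds`` beat by beat, so each beat's HR is (truncated) normal
    while consecutive beats stay close - the slow drift and respiratory
    modulation of a resting heart rate.  Ectopic beats replace an RR by
    ``0.6 * min(previous RR, median RR)``, which guarantees a deviation of
    more than 20% from both the record median and the preceding cycle.
    """
    if rng is None or ectopic_rng is None:
        rngs = _child_rngs(config.seed)
        rng = rng or rngs["rr"]
        ectopic_rng = ectopic_rng or rngs["ectopic"]

    lo, hi = config.hr_bounds
    n = config.n_beats
    if config.sd_hr == 0.0:
        if not (lo <= config.mean_hr <= hi):
            raise SimulationError("mean_hr outside hr_bounds with zero variance")
        hr = np.full(n, config.mean_hr, dtype=float)
    else:
        phi = config.hr_autocorr
        step_sd = config.sd_hr * np.sqrt(1.0 - phi * phi)
        innov = rng.normal(size=n)
        hr = np.empty(n)

        def _draw(centre: float, sd: float, first: float) -> float:
            cand = centre + sd * first
            for _ in range(1000):
                if lo <= cand <= hi:
                    return cand
                cand = centre + sd * rng.normal()
            raise SimulationError(
                "rejection sampling failed: hr_bounds capture almost no mass"
            )

        hr[0] = _draw(config.mean_hr, config.sd_hr, innov[0])
        for i in range(1, n):
            centre = config.mean_hr + phi * (hr[i - 1] - config.mean_hr)
            hr[i] = _draw(centre, step_sd, innov[i])
    rr = 60.0 / hr

    is_ectopic = np.zeros(n, dtype=bool)
    if config.ectopic_rate > 0:
        # The first beat has no predecessor, hence cannot satisfy the rule.
        flags = ectopic_rng.random(n) < config.ectopic_rate
        flags[0] = False
        med = float(np.median(rr))
        for i in np.flatnonzero(flags):
            rr[i] = 0.6 * min(rr[i - 1], med)
            is_ectopic[i] = True
    return rr, is_ectopic


def true_end_systole(
    config: SubjectConfig,
    rr: np.ndarray,
    rng: Optional[np.random.Generator] = None,
) -> np.ndarray:
    """Per-beat end-systole durations from the generating linear model.

    ``S_i = intercept + slope * HR_i + N(0, residual_sd)``, clipped to stay
    inside the open interval (0, RR_i).  A deterministic part at or beyond
    RR_i indicates an inconsistent config and raises.
    """
    rr = np.asarray(rr, dtype=float)
    if np.any(rr <= 0):
        raise ValueError("RR durations must be positive")
    if rng is None:
        rng = _child_rngs(config.seed)["systole"]
    hr = 60.0 / rr
    s = config.true_intercept + config.true_slope * hr
    if config.residual_sd > 0:
        s = s + rng.normal(0.0, config.residual_sd, size=len(rr))
    s = np.clip(s, 1e-3, None)
    if np.any(s >= rr):
        raise SimulationError(
            "end-systole >= RR after clipping; generating model inconsistent "
            "with the heart-rate range"
        )
    return s


# ---------------------------------------------------------------------------
# Flow waveform and the 1D+t scene
# ---------------------------------------------------------------------------

def _flow_pulse(t_rel: np.ndarray, ejection_s: float, undershoot_frac: float) -> np.ndarray:
    """Unit-peak ejection waveform as a function of time after flow onset.

    Quarter-sine upstroke over the first 30% of ejection, cosine decay back
    to zero at exactly ``ejection_s``, then a short backflow lobe (depth
    ``undershoot_frac``, duration 25% of ejection) before diastasis at zero.
    The downward zero crossing at ``ejection_s`` is steep because the decay
    slope and the backflow onset slope add.
    """
    t = np.asarray(t_rel, dtype=float)
    v = np.zeros_like(t)
    rise = 0.30 * ejection_s
    m = (t >= 0) & (t < rise)
    v[m] = np.sin(0.5 * np.pi * t[m] / rise)
    m = (t >= rise) & (t < ejection_s)
    v[m] = np.cos(0.5 * np.pi * (t[m] - rise) / (ejection_s - rise))
    under = 0.25 * ejection_s
    m = (t >= ejection_s) & (t < ejection_s + under)
    v[m] = -undershoot_frac * np.sin(np.pi * (t[m] - ejection_s) / under)
    return v


def _vessel_profile(width: int) -> np.ndarray:
    # Parabolic cross-vessel amplitude profile, 1.0 at the centre.
    x = np.linspace(-1.0, 1.0, width)
    return 1.0 - 0.3 * x * x


@dataclass(frozen=True)
class _Vessel:
    pixels: np.ndarray
    sign: float
    peak_scale: float
    delay_extra_s: float
    duration_scale: float


def _vessel_layout(n_pixels: int, n_confounders: int) -> Tuple[_Vessel, List[_Vessel]]:
    """Fixed vessel geometry within the central half of the FOV."""
    c = n_pixels // 2
    aorta = _Vessel(np.arange(c - 10, c - 4), +1.0, 1.0, 0.0, 1.0)
    pool = [
        # Descending aorta: antiparallel flow, slightly delayed pulse.
        _Vessel(np.arange(c + 16, c + 20), -1.0, 0.8, 0.040, 1.0),
        # Pulmonary-artery-like vessel: forward but delayed and slower.
        _Vessel(np.arange(c - 34, c - 31), +1.0, 0.6, 0.080, 0.9),
        # Small vein: antiparallel, late, weak.
        _Vessel(np.arange(c + 30, c + 32), -1.0, 0.4, 0.120, 0.8),
    ]
    if n_confounders > len(pool):
        raise SimulationError(f"at most {len(pool)} confounding vessels supported")
    return aorta, pool[:n_confounders]


def simulate_velocity_scene(
    config: SubjectConfig,
    acq: AcquisitionConfig,
    rr: np.ndarray,
    end_systole: np.ndarray,
    rng: Optional[np.random.Generator] = None,
    lead_in_s: float = 0.5,
    tail_s: float = 0.5,
) -> Tuple[VelocityScene, GroundTruth]:
    """Build the full-FOV 1D+t velocity/magnitude movie plus ground truth.

    The aorta carries the forward systolic wave from ``R + delay`` to
    ``R + S_i`` per beat; confounding vessels carry waves with distinct
    timing and/or sign.  Magnitude is high inside vessels, intermediate in
    the static-tissue band, low in air.  Velocity noise scales inversely
    with magnitude, as phase noise does.
    """
    if rng is None:
        rng = _child_rngs(config.seed)["scene"]
    rr = np.asarray(rr, float)
    end_systole = np.asarray(end_systole, float)
    n_pix = acq.matrix_freq

    r_times = lead_in_s + np.concatenate([[0.0], np.cumsum(rr[:-1])])
    duration = r_times[-1] + rr[-1] + tail_s
    n_frames = int(np.ceil(duration / acq.tr_s))
    times = np.arange(n_frames) * acq.tr_s

    aorta, confounders = _vessel_layout(n_pix, config.n_confounders)

    velocity = np.zeros((n_pix, n_frames))
    magnitude = np.full((n_pix, n_frames), 0.05)
    # Static tissue band spanning the central FOV.
    tissue = slice(n_pix // 2 - 48, n_pix // 2 + 58)
    magnitude[tissue, :] = 0.6

    def paint(vessel: _Vessel) -> None:
        course = np.zeros(n_frames)
        for r, s in zip(r_times, end_systole):
            onset = r + config.ejection_delay_s + vessel.delay_extra_s
            ejection = (s - config.ejection_delay_s) * vessel.duration_scale
            # Waveform support ends at onset + 1.25*ejection (backflow lobe).
            i0 = np.searchsorted(times, onset)
            i1 = np.searchsorted(times, onset + 1.25 * ejection)
            course[i0:i1] += _flow_pulse(times[i0:i1] - onset, ejection, config.undershoot_frac)
        profile = _vessel_profile(len(vessel.pixels))
        amp = vessel.sign * vessel.peak_scale * config.peak_velocity_cm_s
        velocity[vessel.pixels, :] += amp * profile[:, None] * course[None, :]
        magnitude[vessel.pixels, :] = 1.0

    paint(aorta)
    for vessel in confounders:
        paint(vessel)

    if config.noise_sd > 0:
        sigma = config.noise_sd / np.clip(magnitude, 0.2, None)
        velocity = velocity + rng.normal(size=velocity.shape) * sigma
        magnitude = np.clip(magnitude + rng.normal(0.0, 0.02, size=magnitude.shape), 0.01, None)

    truth = GroundTruth(
        r_times=r_times,
        rr_durations=rr,
        end_systole_s=end_systole,
        aorta_pixels=aorta.pixels,
        confounder_pixels=[v.pixels for v in confounders],
        is_ectopic=np.zeros(len(rr), dtype=bool),  # filled by simulate_subject
    )
    return VelocityScene(velocity, magnitude, times, acq.tr_s), truth


# ---------------------------------------------------------------------------
# k-space rendering
# ---------------------------------------------------------------------------

def channel_sensitivities(n_pixels: int, n_channels: int) -> np.ndarray:
    """Smooth, strictly positive coil sensitivity profiles, [channel, pixel].

    Two broad Gaussian lobes weighted toward either half of the FOV, mimicking
    the two anterior elements closest to the ascending aorta.
    """
    x = np.linspace(0.0, 1.0, n_pixels)
    centres = np.linspace(0.35, 0.65, n_channels)
    sens = np.stack([0.15 + np.exp(-((x - c) ** 2) / (2 * 0.18**2)) for c in centres])
    return sens


def render_kspace_lines(scene: VelocityScene, acq: AcquisitionConfig) -> EchoStream:
    """Inverse of the 1D reconstruction: scene -> central-line echoes.

    Per frame and channel, the echo is the unitary inverse FFT along the
    frequency-encoding axis of ``sensitivity * magnitude * exp(i*phase)``,
    with phase = toggle * (pi / (2*venc)) * velocity, the toggle alternating
    between consecutive echoes so that a pair difference spans
    (pi/venc) * velocity.
    """
    n_pix, n_frames = scene.velocity.shape
    if n_frames < 2:
        raise SimulationError("scene must have at least 2 frames")
    if n_pix != acq.matrix_freq:
        raise SimulationError("scene pixel count must match the acquisition matrix")
    toggles = np.empty(n_frames, dtype=np.int8)
    toggles[0::2] = 1
    toggles[1::2] = -1
    phase = (np.pi / (2.0 * acq.venc_cm_s)) * scene.velocity * toggles[None, :]
    sens = channel_sensitivities(n_pix, acq.n_channels)
    image = sens[:, :, None] * (scene.magnitude * np.exp(1j * phase))[None, :, :]
    # [channel, echo, k]
    kspace = np.fft.ifft(np.transpose(image, (0, 2, 1)), axis=-1, norm="ortho")
    return EchoStream(
        samples=kspace,
        echo_times=scene.times.copy(),
        venc_toggle=toggles,
        config=acq,
    )


# ---------------------------------------------------------------------------
# ECG
# ---------------------------------------------------------------------------

def _qrs_shape(t: np.ndarray) -> np.ndarray:
    """Unit QRS complex (mV) as a function of time from the R wave (s)."""
    r = np.exp(-0.5 * (t / 0.007) ** 2)
    q = -0.15 * np.exp(-0.5 * ((t + 0.025) / 0.005) ** 2)
    s = -0.20 * np.exp(-0.5 * ((t - 0.025) / 0.005) ** 2)
    return r + q + s


_LEAD_QRS_GAIN = np.array([1.0, 0.7])
_LEAD_MHD_GAIN = np.array([1.0, 1.3])


def simulate_ecg(
    config: SubjectConfig,
    rr: np.ndarray,
    end_systole: np.ndarray,
    r_times: np.ndarray,
    duration: float,
    rng: Optional[np.random.Generator] = None,
    jitter_rng: Optional[np.random.Generator] = None,
) -> ECGTrace:
    """Two-lead ECG: QRS train + MHD bump synchronous with systolic ejection.

    A final R wave is emitted at the end of the last beat (it begins no
    cycle but closes the last one).  Online detections are the true R times
    plus Gaussian jitter of SD ``r_jitter_sd``.
    """
    if rng is None or jitter_rng is None:
        rngs = _child_rngs(config.seed)
        rng = rng or rngs["ecg"]
        jitter_rng = jitter_rng or rngs["jitter"]
    fs = config.ecg_fs
    n_samp = int(np.ceil(duration * fs))
    t = np.arange(n_samp) / fs
    qrs_sum = np.zeros(n_samp)
    mhd_sum = np.zeros(n_samp)

    r_all = np.concatenate([r_times, [r_times[-1] + rr[-1]]])
    for r in r_all:
        i0 = max(0, int((r - 0.08) * fs))
        i1 = min(n_samp, int((r + 0.08) * fs) + 1)
        qrs_sum[i0:i1] += _qrs_shape(t[i0:i1] - r)
    if config.mhd_amplitude > 0:
        for r, s in zip(r_times, end_systole):
            onset = r + config.ejection_delay_s
            width = s - config.ejection_delay_s
            i0 = int(onset * fs)
            i1 = min(n_samp, int((onset + width) * fs) + 1)
            u = (t[i0:i1] - onset) / width
            mhd_sum[i0:i1] += config.mhd_amplitude * np.sin(np.pi * np.clip(u, 0, 1))

    samples = (
        _LEAD_QRS_GAIN[:, None] * qrs_sum[None, :]
        + _LEAD_MHD_GAIN[:, None] * mhd_sum[None, :]
    )
    if config.noise_sd > 0:
        samples = samples + rng.normal(0.0, 0.02, size=samples.shape)

    detections = r_all.copy()
    if config.r_jitter_sd > 0:
        detections = detections + jitter_rng.normal(0.0, config.r_jitter_sd, size=len(r_all))
    detections = np.clip(detections, 0.0, duration - 1.0 / fs)
    return ECGTrace(samples=samples, fs=fs, online_detections=detections)


# ---------------------------------------------------------------------------
# Subject orchestration
# ---------------------------------------------------------------------------

def simulate_subject(
    config: SubjectConfig,
    acq: Optional[AcquisitionConfig] = None,
    keep_scene: bool = False,
) -> Subject:
    """Generate one complete synthetic RTPC acquisition from a single seed."""
    acq = acq or AcquisitionConfig()
    rngs = _child_rngs(config.seed)
    rr, is_ectopic = simulate_rr_sequence(config, rngs["rr"], rngs["ectopic"])
    systole = true_end_systole(config, rr, rngs["systole"])
    scene, truth = simulate_velocity_scene(config, acq, rr, systole, rngs["scene"])
    truth.is_ectopic = is_ectopic
    echoes = render_kspace_lines(scene, acq)
    duration = scene.times[-1] + scene.dt
    ecg = simulate_ecg(
        config, rr, systole, truth.r_times, duration, rngs["ecg"], rngs["jitter"]
    )
    return Subject(
        echoes=echoes,
        ecg=ecg,
        truth=truth,
        config=config,
        acq=acq,
        scene=scene if keep_scene else None,
    )


def simulate_cohort(
    n_subjects: int,
    seed: int,
    base_config: Optional[SubjectConfig] = None,
    acq: Optional[AcquisitionConfig] = None,
    **overrides,
) -> List[Subject]:
    """Generate a cohort; each subject gets an independent child seed."""
    base = base_config or SubjectConfig()
    seeds = np.random.SeedSequence(seed).generate_state(n_subjects) % (2**31)
    subjects = []
    for i, s in enumerate(seeds):
        cfg = dataclasses.replace(
            base, subject_id=f"subject-{i:03d}", seed=int(s), **overrides
        )
        subjects.append(simulate_subject(cfg, acq))
    return subjects


def simulate_regression_cohort(
    n_cycles: int,
    slope: float,
    intercept: float,
    residual_sd: float,
    seed: int,
    subject_id: str = "pooled",
):
    """(HR, end-systole) pairs from a generating line, as systole samples.

    Emulates a pool of accepted cycles drawn across subjects: heart rates
    are independent truncated-normal draws (the cross-subject marginal,
    67 +/- 9.5 bpm within [44, 114]), and each cycle's end-systole follows
    ``intercept + slope * HR + N(0, residual_sd)``.  Used for calibration
    and parameter-recovery studies of the regression stage in isolation.
    """
    from .systole import SystoleSample

    cfg = SubjectConfig(
        seed=seed,
        n_beats=n_cycles,
        true_slope=slope,
        true_intercept=intercept,
        residual_sd=residual_sd,
        ectopic_rate=0.0,
        hr_autocorr=0.0,
    )
    rngs = _child_rngs(cfg.seed)
    rr, _ = simulate_rr_sequence(cfg, rngs["rr"], rngs["ectopic"])
    systole = true_end_systole(cfg, rr, rngs["systole"])
    return [
        SystoleSample(i, float(60.0 / rr[i]), float(systole[i]), 0.0, True, subject_id)
        for i in range(n_cycles)
    ]


# ---------------------------------------------------------------------------
# Tissue-velocity stream for the cine illustration
# ---------------------------------------------------------------------------

def simulate_tissue_course(
    config: SubjectConfig,
    rr: np.ndarray,
    end_systole: np.ndarray,
    r_times: np.ndarray,
    dt: float = 0.0066,
    e_amplitude: float = 8.0,
    s_amplitude: float = 6.0,
    noise_sd: float = 0.3,
    rng: Optional[np.random.Generator] = None,
) -> Tuple[np.ndarray, np.ndarray]:
    """Myocardial-velocity-like sample stream (times, values in cm/s).

    Each beat carries a systolic S lobe spanning the ejection phase and an
    early-diastolic E lobe at a fixed FRACTION of diastole (starting 10% in,
    lasting 18% of the diastolic duration).  Phase-locking the lobes to the
    two cycle phases makes the stream exactly consistent with the bi-phasic
    cycle decomposition: binning with the true per-beat end-systole aligns
    every beat, and any error in the end-systole source de-aligns the narrow
    E lobe, attenuating its binned peak.
    """
    if rng is None:
        rng = _child_rngs(config.seed)["tissue"]
    duration = r_times[-1] + rr[-1]
    times = np.arange(0.0, duration, dt)
    values = np.zeros_like(times)
    for r, rr_i, s in zip(r_times, rr, end_systole):
        # S lobe over the systolic phase.
        u = (times - r) / s
        m = (u >= 0) & (u < 1)
        values[m] += s_amplitude * np.sin(np.pi * u[m])
        # E lobe at a fixed fraction of diastole.
        dia = rr_i - s
        e_start = r + s + 0.10 * dia
        e_width = 0.18 * dia
        u = (times - e_start) / e_width
        m = (u >= 0) & (u < 1)
        values[m] += -e_amplitude * np.sin(np.pi * u[m])
    if noise_sd > 0:
        values = values + rng.normal(0.0, noise_sd, size=len(values))
    return times, values
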