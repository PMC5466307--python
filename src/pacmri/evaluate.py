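"""Model comparison (Bland-Altman) and the bi-phasic cine time projection.

Bland-Altman agreement between predicted and reference end-systole times is
summarised as bias, +/-1.96 SD limits of agreement, and the bias standard
error, with a one-sample t test of the bias.  The bi-phasic projection maps
every acquired sample's intra-cycle time into a mean cycle by two linear
stretches (one for systole, one for diastole); temporal misalignment caused
by a biased end-systole source smears sharp mid-cycle features, which is
quantified here by the early-diastolic (E-wave) peak of the binned cine
course.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .models import CardiacModel, predict_end_systole
from .systole import SystoleSample

log = logging.getLogger(__name__)


@dataclass
class BlandAltman:
    """Agreement summary of paired measurements (all quantities in seconds)."""

    bias: float
    bias_se: float
    loa_low: float
    loa_high: float
    sd: float
    n: int
    t_stat: float
    p_value: float
    excluded: int = 0
    exclusion_reasons: List[str] = field(default_factory=list)


def bland_altman(pred, ref) -> BlandAltman:
    """Bland-Altman analysis of reference minus prediction."""
    pred = np.asarray(pred, float)
    ref = np.asarray(ref, float)
    if pred.shape != ref.shape:
        raise ValueError("pred and ref must have equal length")
    if len(pred) < 2:
        raise ValueError("need at least 2 pairs")
    diff = ref - pred
    bias = float(diff.mean())
    sd = float(diff.std(ddof=1))
    n = len(diff)
    se = sd / np.sqrt(n)
    if sd > 0:
        t_stat, p = stats.ttest_1samp(diff, 0.0)
    else:
        t_stat, p = (np.inf if bias != 0 else 0.0), (0.0 if bias != 0 else 1.0)
    return BlandAltman(
        bias=bias,
        bias_se=float(se),
        loa_low=bias - 1.96 * sd,
        loa_high=bias + 1.96 * sd,
        sd=sd,
        n=n,
        t_stat=float(t_stat),
        p_value=float(p),
    )


def flag_outlier_cycles(
    samples: Sequence[SystoleSample],
    pacm_by_subject: Dict[str, CardiacModel],
    k: float = 4.0,
    sd_floor: float = 0.004,
) -> np.ndarray:
    """Physiological outliers among holdout cycles (bool mask, True=exclude).

    A cycle is excluded when its measured systole deviates from its own
    subject's patient-adapted prediction by more than ``k`` times the
    subject's residual SD (floored).  This removes cycles where the RR and
    the systole are physiologically decoupled - e.g. an abnormally long RR
    with an unchanged systole (non-conducted P wave) or a systole far longer
    than any RR-based prediction (extrasystole).
    """
    mask = np.zeros(len(samples), dtype=bool)
    for i, s in enumerate(samples):
        model = pacm_by_subject.get(s.subject_id)
        if model is None:
            continue
        pred = float(predict_end_systole(model, s.hr))
        tol = k * max(model.residual_sd, sd_floor)
        if abs(s.systole_s - pred) > tol:
            mask[i] = True
    return mask


def compare_models(
    holdout: Sequence[SystoleSample],
    pacm_by_subject: Dict[str, CardiacModel],
    global_models: Dict[str, CardiacModel],
    sex_by_subject: Optional[Dict[str, str]] = None,
    outlier_k: float = 4.0,
) -> pd.DataFrame:
    """Bland-Altman of each model against the measured holdout systole times.

    ``global_models`` maps a row label to either one model or a dict keyed
    by sex.  The same outlier-cycle exclusion (see
    :func:`flag_outlier_cycles`) applies to every row; paired t tests
    between the per-cycle errors of consecutive rows are reported.
    """
    if not holdout:
        raise ValueError("empty holdout set")
    samples = [s for s in holdout if s.valid]
    excl = flag_outlier_cycles(samples, pacm_by_subject, k=outlier_k)
    kept = [s for s, e in zip(samples, excl) if not e]
    n_excluded = int(excl.sum())
    if n_excluded:
        log.info("excluded %d outlier holdout cycles", n_excluded)
    ref = np.array([s.systole_s for s in kept])

    def predict_with(model_or_dict) -> np.ndarray:
        out = np.empty(len(kept))
        for i, s in enumerate(kept):
            m = model_or_dict
            if isinstance(m, dict):
                sex = (sex_by_subject or {}).get(s.subject_id, "M")
                m = m[sex]
            out[i] = float(predict_end_systole(m, s.hr))
        return out

    rows = []
    errors = {}
    pred_pacm = np.array(
        [float(predict_end_systole(pacm_by_subject[s.subject_id], s.hr)) for s in kept]
    )
    for name, pred in [("pacm", pred_pacm)] + [
        (name, predict_with(m)) for name, m in global_models.items()
    ]:
        ba = bland_altman(pred, ref)
        ba.excluded = n_excluded
        errors[name] = ref - pred
        rows.append(
            {
                "model": name,
                "bias_ms": ba.bias * 1e3,
                "bias_se_ms": ba.bias_se * 1e3,
                "loa_low_ms": ba.loa_low * 1e3,
                "loa_high_ms": ba.loa_high * 1e3,
                "sd_ms": ba.sd * 1e3,
                "n": ba.n,
                "excluded": n_excluded,
                "p_bias": ba.p_value,
            }
        )
    df = pd.DataFrame(rows)
    # Paired t test of |error| of each global model against the PACM row.
    p_vs_pacm = [np.nan]
    for name in list(errors)[1:]:
        d = np.abs(errors[name]) - np.abs(errors["pacm"])
        if np.ptp(d) > 0:
            p_vs_pacm.append(float(stats.ttest_1samp(d, 0.0).pvalue))
        else:
            p_vs_pacm.append(1.0 if np.allclose(d, 0) else 0.0)
    df["p_vs_pacm"] = p_vs_pacm
    return df


# ---------------------------------------------------------------------------
# Bi-phasic cine time projection
# ---------------------------------------------------------------------------

@dataclass
class BiphasicMap:
    """Mean-cycle geometry of the bi-phasic projection."""

    mean_systole: float  # s
    mean_rr: float       # s

    def __post_init__(self) -> None:
        if not 0.0 < self.mean_systole < self.mean_rr:
            raise ValueError("need 0 < mean_systole < mean_rr")


def biphasic_map_from_cycles(rr, systole) -> BiphasicMap:
    """Mean cycle (S-bar, RR-bar) from accepted cycles."""
    return BiphasicMap(
        mean_systole=float(np.mean(systole)), mean_rr=float(np.mean(rr))
    )


def biphasic_project(t, systole_i: float, rr_i: float, bmap: BiphasicMap):
    """Project an intra-cycle time into the mean cycle.

    Systole maps linearly onto [0, S-bar], diastole onto [S-bar, RR-bar];
    the map is continuous, strictly increasing and bijective
    [0, rr_i] -> [0, RR-bar].
    """
    t = np.asarray(t, dtype=float)
    if not 0.0 < systole_i < rr_i:
        raise ValueError("need 0 < systole_i < rr_i")
    if np.any(t < 0) or np.any(t > rr_i):
        raise ValueError("t must lie within [0, rr_i]")
    sbar, rrbar = bmap.mean_systole, bmap.mean_rr
    out = np.where(
        t <= systole_i,
        t * sbar / systole_i,
        sbar + (t - systole_i) * (rrbar - sbar) / (rr_i - systole_i),
    )
    return out if out.ndim else float(out)


@dataclass
class CineCourse:
    """Mean-cycle course after bi-phasic binning of a multi-beat stream."""

    frame_times: np.ndarray  # s, bin centres within [0, RR-bar]
    course: np.ndarray       # binned mean sample value
    n_empty: int
    bmap: BiphasicMap


def reconstruct_cine(
    sample_times: np.ndarray,
    sample_values: np.ndarray,
    r_times: np.ndarray,
    rr: np.ndarray,
    end_systole: np.ndarray,
    bmap: BiphasicMap,
    n_frames: int = 64,
    accepted: Optional[np.ndarray] = None,
) -> CineCourse:
    """Bin a multi-beat sample stream into a mean cardiac cycle.

    Each sample's time within its cycle is projected via the bi-phasic map
    using the per-cycle end-systole from the chosen source (measured or
    model-predicted), then averaged into ``n_frames`` uniform bins of the
    mean cycle.  Empty bins are filled by linear interpolation (and
    counted).
    """
    sample_times = np.asarray(sample_times, float)
    sample_values = np.asarray(sample_values, float)
    r_times = np.asarray(r_times, float)
    rr = np.asarray(rr, float)
    end_systole = np.asarray(end_systole, float)
    if accepted is None:
        accepted = np.ones(len(rr), dtype=bool)

    sums = np.zeros(n_frames)
    counts = np.zeros(n_frames, dtype=int)
    cyc = np.searchsorted(r_times, sample_times, side="right") - 1
    for k, (t, v) in enumerate(zip(sample_times, sample_values)):
        i = cyc[k]
        if i < 0 or i >= len(rr) or not accepted[i]:
            continue
        t_in = t - r_times[i]
        if t_in >= rr[i]:
            continue
        s_i = min(end_systole[i], 0.95 * rr[i])  # guard degenerate diastole
        if s_i <= 0:
            continue
        tp = biphasic_project(t_in, s_i, rr[i], bmap)
        b = min(int(tp / bmap.mean_rr * n_frames), n_frames - 1)
        sums[b] += v
        counts[b] += 1

    course = np.full(n_frames, np.nan)
    filled = counts > 0
    course[filled] = sums[filled] / counts[filled]
    n_empty = int((~filled).sum())
    if n_empty and filled.any():
        idx = np.arange(n_frames)
        course[~filled] = np.interp(idx[~filled], idx[filled], course[filled])
        log.info("interpolated %d empty cine bins", n_empty)
    frame_times = (np.arange(n_frames) + 0.5) / n_frames * bmap.mean_rr
    return CineCourse(frame_times=frame_times, course=course, n_empty=n_empty, bmap=bmap)


def e_wave_peak(cine: CineCourse, early_frac: float = 1 / 3) -> float:
    """Magnitude of the early-diastolic velocity peak of a cine course.

    The E wave is searched in the first ``early_frac`` of diastole after the
    mean end-systole; the peak is the maximum absolute course value there.
    """
    sbar, rrbar = cine.bmap.mean_systole, cine.bmap.mean_rr
    lo = sbar
    hi = sbar + (rrbar - sbar) * early_frac
    m = (cine.frame_times >= lo) & (cine.frame_times <= hi)
    if not m.any():
        raise ValueError("early-diastole window contains no cine frame")
    return float(np.max(np.abs(cine.course[m])))


def wilcoxon_paired_onesided(greater, lesser) -> float:
    """One-sided paired Wilcoxon signed-rank p value (H1: greater > lesser).

    Uses the exact null distribution for n <= 10 pairs, the normal
    approximation otherwise.
    """
    greater = np.asarray(greater, float)
    lesser = np.asarray(lesser, float)
    d = greater - lesser
    d = d[d != 0]
    if len(d) == 0:
        return 1.0
    mode = "exact" if len(d) <= 10 else "approx"
    return float(stats.wilcoxon(d, alternative="greater", mode=mode).pvalue)
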