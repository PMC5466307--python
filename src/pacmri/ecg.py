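"""R-wave refinement by template correlation and cardiac-cycle screening.

Online R-wave detections from the patient monitor are jittery in the magnet
(magneto-hydrodynamic voltage, gradient interference).  A per-subject QRS
template is averaged around the online detections and each detection is
repositioned at the maximum of the template/trace cross-correlation summed
over all leads.  Cycles are then screened: implausible instantaneous heart
rate rejects the cycle; an ectopic beat (RR differing by more than 20% from
both the record median RR and the previous RR) rejects the cycle and both
neighbours.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
import pandas as pd

from .simulate import ECGTrace

log = logging.getLogger(__name__)

REASONS = (
    "ok",
    "hr_out_of_range",
    "ectopic",
    "ectopic_neighbor",
    "systole_out_of_bounds",
    "unmeasured",
)


@dataclass
class QRSPattern:
    """Per-subject mean QRS waveform used for repositioning."""

    template: np.ndarray   # mV, [lead, window]
    window_s: float
    origin_offset: float   # s from template start to the R point
    n_used: int
    n_skipped: int


@dataclass
class CycleTable:
    """Per-cycle bookkeeping: timing, instantaneous heart rate, status.

    Cycle ``i`` runs from ``r_time[i]`` to ``r_time[i] + rr[i]``; the final
    R wave begins no cycle.  ``reason`` values are exhaustive and mutually
    exclusive; ``accepted`` is equivalent to ``reason == 'ok'``.
    """

    r_time: np.ndarray
    rr: np.ndarray
    hr: np.ndarray
    accepted: np.ndarray
    reason: np.ndarray
    median_rr: float

    def __post_init__(self) -> None:
        if not np.all(np.diff(self.r_time) > 0):
            raise ValueError("r_time must be strictly increasing")
        if not np.allclose(self.hr, 60.0 / self.rr):
            raise ValueError("hr must equal 60/rr")
        if not set(np.unique(self.reason)) <= set(REASONS):
            raise ValueError("unknown rejection reason")

    def __len__(self) -> int:
        return len(self.r_time)

    @property
    def accepted_indices(self) -> np.ndarray:
        return np.flatnonzero(self.accepted)

    def reason_counts(self) -> dict:
        counts = {r: 0 for r in REASONS}
        for r in self.reason:
            counts[str(r)] += 1
        return counts

    def with_reason(self, indices, reason: str) -> "CycleTable":
        """Copy with the given accepted cycles downgraded to ``reason``."""
        if reason not in REASONS:
            raise ValueError(f"unknown reason {reason!r}")
        new_reason = self.reason.copy()
        new_accept = self.accepted.copy()
        for i in np.atleast_1d(indices):
            new_reason[i] = reason
            new_accept[i] = reason == "ok"
        return replace(self, accepted=new_accept, reason=new_reason)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "r_time": self.r_time,
                "rr": self.rr,
                "hr": self.hr,
                "accepted": self.accepted,
                "reason": self.reason,
            }
        )


def build_qrs_pattern(ecg: ECGTrace, window_s: float = 0.12) -> QRSPattern:
    """Per-lead mean of windows centred on the online detections.

    Detections whose window exits the record are skipped (and counted);
    fewer than 3 usable detections raises.
    """
    half = int(round(window_s / 2.0 * ecg.fs))
    n_samp = ecg.samples.shape[1]
    windows = []
    n_skipped = 0
    for t in ecg.online_detections:
        c = int(round(t * ecg.fs))
        if c - half < 0 or c + half + 1 > n_samp:
            n_skipped += 1
            continue
        windows.append(ecg.samples[:, c - half : c + half + 1])
    if len(windows) < 3:
        raise ValueError(f"only {len(windows)} usable detections (need >= 3)")
    if n_skipped:
        log.info("QRS pattern: skipped %d detections with truncated windows", n_skipped)
    template = np.mean(windows, axis=0)
    return QRSPattern(
        template=template,
        window_s=window_s,
        origin_offset=half / ecg.fs,
        n_used=len(windows),
        n_skipped=n_skipped,
    )


def reposition_detections(
    ecg: ECGTrace, pattern: QRSPattern, search_s: float = 0.05
) -> np.ndarray:
    """Refined R times at the maximum template correlation near each detection.

    The correlation is the dot product of the template with the trace,
    summed over all leads, evaluated at every shift within ``+/- search_s``;
    ties break toward the earliest shift.  A flat correlation keeps the
    online detection.
    """
    half = pattern.template.shape[1] // 2
    radius = int(round(search_s * ecg.fs))
    n_samp = ecg.samples.shape[1]
    refined = []
    for t in ecg.online_detections:
        c = int(round(t * ecg.fs))
        lo = c - radius
        hi = c + radius
        shifts = np.arange(lo, hi + 1)
        valid = (shifts - half >= 0) & (shifts + half + 1 <= n_samp)
        shifts = shifts[valid]
        if shifts.size == 0:
            refined.append(t)
            continue
        # Sliding dot product, summed across leads.
        scores = np.empty(len(shifts))
        for j, cc in enumerate(shifts):
            seg = ecg.samples[:, cc - half : cc + half + 1]
            scores[j] = float(np.sum(seg * pattern.template))
        if np.ptp(scores) == 0:
            log.info("flat correlation at t=%.3f s; keeping online detection", t)
            refined.append(t)
            continue
        best = shifts[int(np.argmax(scores))]
        refined.append(best / ecg.fs)
    return np.asarray(refined)


def screen_cycles(
    r_times: np.ndarray,
    hr_min_bpm: float = 30.0,
    hr_max_bpm: float = 120.0,
    ectopic_frac: float = 0.20,
    median_rr: Optional[float] = None,
) -> CycleTable:
    """Screen cardiac cycles for QRS-detection errors and ectopic beats.

    The heart-rate rule flags the offending cycle alone; the ectopic rule
    (RR differing by more than ``ectopic_frac`` from BOTH the record median
    RR and the previous RR) flags the cycle and both neighbours.  The median
    is computed once over the whole record before any rejection (pass
    ``median_rr`` to re-screen a subset against the original median).
    """
    r = np.asarray(r_times, float)
    if len(r) < 3:
        raise ValueError("need at least 3 R times")
    rr = np.diff(r)
    hr = 60.0 / rr
    n = len(rr)
    reason = np.array(["ok"] * n, dtype=object)

    out = (hr < hr_min_bpm) | (hr > hr_max_bpm)
    reason[out] = "hr_out_of_range"

    med = float(np.median(rr)) if median_rr is None else float(median_rr)
    ectopic = np.zeros(n, dtype=bool)
    for i in range(1, n):
        # Cycles already rejected as detection errors are not ectopic beats.
        if reason[i] != "ok":
            continue
        if (
            abs(rr[i] - med) > ectopic_frac * med
            and abs(rr[i] - rr[i - 1]) > ectopic_frac * rr[i - 1]
        ):
            ectopic[i] = True
    for i in np.flatnonzero(ectopic):
        if reason[i] == "ok":
            reason[i] = "ectopic"
        for j in (i - 1, i + 1):
            if 0 <= j < n and reason[j] == "ok":
                reason[j] = "ectopic_neighbor"

    accepted = reason == "ok"
    return CycleTable(
        r_time=r[:-1].copy(),
        rr=rr,
        hr=hr,
        accepted=accepted,
        reason=reason,
        median_rr=med,
    )


def refine_and_screen(
    ecg: ECGTrace,
    window_s: float = 0.12,
    search_s: float = 0.05,
    hr_min_bpm: float = 30.0,
    hr_max_bpm: float = 120.0,
    ectopic_frac: float = 0.20,
) -> CycleTable:
    """Template refinement followed by cycle screening."""
    pattern = build_qrs_pattern(ecg, window_s=window_s)
    refined = reposition_detections(ecg, pattern, search_s=search_s)
    return screen_cycles(refined, hr_min_bpm, hr_max_bpm, ectopic_frac)
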