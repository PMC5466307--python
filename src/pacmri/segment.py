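"""Automatic spatial segmentation of the ascending aorta in the 1D+t map.

The velocity map is decomposed by SVD; the spatial loadings of the first
few components are thresholded and OR-combined into a pixel mask; mask
pixels are grouped into contiguous regions of interest (ROIs); the ROI is
selected by spectral power in the cardiac band (subject mean heart
frequency +/- 0.03 Hz), a positive mean velocity, and, among remaining
candidates, the largest pixel count.

The procedure is parameter-free per subject: the same defaults apply to
every record.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import List, Optional

import numpy as np

from .errors import SegmentationError
from .recon import VelocityMap

log = logging.getLogger(__name__)


@dataclass(eq=False)
class ROI:
    """A contiguous run of pixels and its mean-velocity time course."""

    pixels: np.ndarray          # contiguous indices on the cropped spatial axis
    course: np.ndarray          # cm/s per frame (unweighted pixel mean)
    mean_velocity: float        # cm/s, time average of the course
    band_power: float = np.nan  # (cm/s)^2, filled during selection

    def __post_init__(self) -> None:
        p = np.asarray(self.pixels)
        if p.size == 0:
            raise ValueError("ROI must be non-empty")
        if p.size > 1 and not np.all(np.diff(p) == 1):
            raise ValueError("ROI pixels must be contiguous")

    @property
    def size(self) -> int:
        return len(self.pixels)


@dataclass
class SVDComponents:
    u: np.ndarray   # [pixel, k] spatial singular vectors
    s: np.ndarray   # [k] singular values, descending
    vt: np.ndarray  # [k, frame] temporal singular vectors

    def component_image(self, i: int) -> np.ndarray:
        return self.s[i] * np.outer(self.u[:, i], self.vt[i, :])


@dataclass
class SegmentationResult:
    chosen: ROI
    candidates: List[ROI]
    rois: List[ROI]
    singular_values: np.ndarray
    mask: np.ndarray

    def __post_init__(self) -> None:
        if not any(self.chosen is r for r in self.candidates):
            raise ValueError("chosen ROI must be one of the candidates")


def svd_components(vmap: VelocityMap, k: int = 3) -> SVDComponents:
    """First ``k`` rank-1 spatial x temporal components of the velocity map."""
    v = vmap.velocity
    if not np.all(np.isfinite(v)):
        raise ValueError("velocity map must be finite")
    if k > min(v.shape):
        raise ValueError("k exceeds the map rank bound")
    if not np.any(v):
        raise SegmentationError("all-zero velocity map")
    u, s, vt = np.linalg.svd(v, full_matrices=False)
    return SVDComponents(u=u[:, :k], s=s[:k], vt=vt[:k, :])


def threshold_components(components: SVDComponents, tau: float = 0.25) -> np.ndarray:
    """Binary spatial mask from thresholded component loadings.

    Pixel loading of component i is ``s_i * |u_i|`` (the temporal-energy
    weight of that pixel in the rank-1 term); each component keeps pixels at
    or above ``tau`` times its own maximum, and the per-component masks are
    OR-combined.
    """
    if components.s.size < 1:
        raise ValueError("need at least one component")
    weights = components.s[None, :] * np.abs(components.u)  # [pixel, k]
    mask = np.zeros(weights.shape[0], dtype=bool)
    for i in range(weights.shape[1]):
        w = weights[:, i]
        if w.max() > 0:
            # Small relative slack so tau=1 keeps exactly-maximal loadings.
            mask |= w >= tau * w.max() * (1.0 - 1e-9)
    if not mask.any():
        raise SegmentationError("thresholding produced an empty mask")
    return mask


def group_rois(mask: np.ndarray, vmap: VelocityMap) -> List[ROI]:
    """Group kept pixels into maximal runs of consecutive indices."""
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        raise SegmentationError("empty mask")
    splits = np.flatnonzero(np.diff(idx) > 1) + 1
    rois = []
    for run in np.split(idx, splits):
        course = vmap.velocity[run, :].mean(axis=0)
        rois.append(ROI(pixels=run, course=course, mean_velocity=float(course.mean())))
    return rois


def cardiac_band_power(
    course: np.ndarray,
    dt: float,
    mean_hr_bpm: float,
    halfwidth_hz: float = 0.03,
) -> float:
    """Periodogram power of the mean-removed course in the cardiac band.

    The band is ``mean_hr/60 +/- halfwidth`` Hz on a plain (untapered) FFT
    periodogram.  If the record is too short to resolve the band, it is
    widened to the single nearest frequency bin and a warning is logged.
    """
    x = np.asarray(course, float)
    x = x - x.mean()
    n = len(x)
    if n < 2:
        raise ValueError("course too short")
    spec = np.abs(np.fft.rfft(x)) ** 2 / n
    freqs = np.fft.rfftfreq(n, d=dt)
    f0 = mean_hr_bpm / 60.0
    band = (freqs >= f0 - halfwidth_hz) & (freqs <= f0 + halfwidth_hz)
    if not band.any():
        log.warning(
            "cardiac band below spectral resolution (df=%.4f Hz); using nearest bin",
            freqs[1] if n > 1 else np.nan,
        )
        band[np.argmin(np.abs(freqs - f0))] = True
    return float(spec[band].sum())


def select_aorta(
    rois: List[ROI],
    dt: float,
    mean_hr_bpm: float,
    halfwidth_hz: float = 0.03,
    power_fraction: float = 0.40,
) -> List[ROI]:
    """Candidate ROIs: band power above ``power_fraction`` of the maximum and
    positive mean velocity; the largest candidate (lowest index on ties) is
    placed first.  Raises if no candidate survives."""
    if not rois:
        raise SegmentationError("no ROIs to select from")
    for roi in rois:
        roi.band_power = cardiac_band_power(roi.course, dt, mean_hr_bpm, halfwidth_hz)
    p_max = max(r.band_power for r in rois)
    candidates = [
        r for r in rois if r.band_power > power_fraction * p_max and r.mean_velocity > 0
    ]
    if not candidates:
        raise SegmentationError(
            "no pulsatile positive-flow ROI found (segmentation failure)"
        )
    # Largest pixel count wins; ties break toward the lowest pixel index.
    candidates.sort(key=lambda r: (-r.size, int(r.pixels[0])))
    return candidates


def segment_aorta(
    vmap: VelocityMap,
    mean_hr_bpm: float,
    k: int = 3,
    tau: float = 0.25,
    halfwidth_hz: float = 0.03,
    power_fraction: float = 0.40,
) -> SegmentationResult:
    """Full segmentation chain on a reconstructed velocity map."""
    comp = svd_components(vmap, k=k)
    mask = threshold_components(comp, tau=tau)
    rois = group_rois(mask, vmap)
    candidates = select_aorta(rois, vmap.dt, mean_hr_bpm, halfwidth_hz, power_fraction)
    return SegmentationResult(
        chosen=candidates[0],
        candidates=candidates,
        rois=rois,
        singular_values=comp.s.copy(),
        mask=mask,
    )
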