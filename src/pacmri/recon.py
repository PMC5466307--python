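"""Reconstruction of the 1D+t velocity map from central-k-space-line echoes.

The chain is: unitary 1D Fourier transform along the frequency-encoding
axis, central-FOV crop, sliding shared velocity encoding (velocity from
every pair of adjacent interleaved echoes, so frame spacing is one TR), and
magnitude-weighted combination of the coil channels.

No image-based velocity-offset correction is applied anywhere: a constant
phase offset in the echo stream propagates linearly into velocity.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Tuple

import numpy as np

from .config import AcquisitionConfig
from .errors import ReconstructionError
from .simulate import EchoStream


@dataclass
class VelocityMap:
    """Real-valued space x time projected-velocity image plus magnitude.

    ``velocity[pixel, frame]`` is the through-slice velocity (cm/s) projected
    along the phase-encoding axis; positive values follow the ascending
    aorta's flow direction.  Frames are spaced one TR apart and time-stamped
    at the midpoint of the two echoes they combine.
    """

    velocity: np.ndarray   # [pixel, frame], cm/s
    magnitude: np.ndarray  # [pixel, frame]
    dt: float              # s (= TR)
    pixel_extent_mm: float
    t0: float              # s, time of frame 0
    pixel0: int = 0        # index of pixel 0 in the full FOV

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.velocity.shape != self.magnitude.shape:
            raise ValueError("velocity and magnitude must have congruent shapes")

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.velocity.shape[1]) * self.dt

    @property
    def n_pixels(self) -> int:
        return self.velocity.shape[0]


def fourier_1d(echoes: EchoStream) -> np.ndarray:
    """Unitary FFT of every echo into 1D+t image space, [channel, echo, pixel].

    Pixel 0 is the FOV edge (natural array ordering of the transform).
    """
    if echoes.samples.shape[1] < 2:
        raise ReconstructionError("need at least 2 echoes")
    spacing = np.diff(echoes.echo_times)
    if not np.allclose(spacing, spacing[0], rtol=1e-9, atol=1e-12):
        raise ReconstructionError("non-uniform echo spacing")
    return np.fft.fft(echoes.samples, axis=-1, norm="ortho")


def crop_fov(image: np.ndarray, fraction: float = 0.5) -> Tuple[np.ndarray, int]:
    """Keep a centred window of ``round(fraction * N)`` pixels (last axis).

    Returns the cropped array and the start index of the window, using the
    half-open convention (N=256, fraction=0.5 keeps pixels 64..191).
    """
    if not 0.0 < fraction <= 1.0:
        raise ReconstructionError("fraction must be in (0, 1]")
    n = image.shape[-1]
    width = int(round(fraction * n))
    start = (n - width) // 2
    return image[..., start : start + width], start


def shared_velocity_encoding(
    image: np.ndarray, venc_toggle: np.ndarray, acq: AcquisitionConfig
) -> Tuple[np.ndarray, np.ndarray]:
    """Per-channel velocity and magnitude from adjacent interleaved echoes.

    Frame ``j`` combines echoes ``j`` and ``j+1`` (sliding difference), so the
    frame spacing equals one TR.  Velocity is the phase difference of the
    pair scaled by venc/pi, signed by the toggle of the later echo so that a
    constant true velocity is returned unchanged; magnitude is the mean of
    the two echo magnitudes.

    Returns ``(velocity, magnitude)`` with shape [channel, frame, pixel].
    """
    if image.shape[1] < 2:
        raise ReconstructionError("need at least 2 echoes")
    toggles = np.asarray(venc_toggle)
    if np.any(toggles[1:] == toggles[:-1]):
        raise ReconstructionError("venc toggles must alternate")
    pair = image[:, 1:, :] * np.conj(image[:, :-1, :])
    sign = toggles[1:].astype(float)
    velocity = sign[None, :, None] * (acq.venc_cm_s / np.pi) * np.angle(pair)
    magnitude = 0.5 * (np.abs(image[:, 1:, :]) + np.abs(image[:, :-1, :]))
    return velocity, magnitude


def combine_channels(velocity: np.ndarray, magnitude: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Magnitude-weighted sum of per-channel velocity maps.

    ``v = sum_c m_c v_c / sum_c m_c`` elementwise; pixels with zero total
    magnitude get velocity 0.  Returns ``(velocity, total_magnitude)`` with
    the channel axis removed.
    """
    wsum = magnitude.sum(axis=0)
    num = (magnitude * velocity).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        v = np.where(wsum > 0, num / np.where(wsum > 0, wsum, 1.0), 0.0)
    return v, wsum


def reconstruct(echoes: EchoStream, fov_fraction: float = 0.5) -> VelocityMap:
    """Full reconstruction: FFT, central-FOV crop, shared velocity encoding,
    magnitude-weighted channel combination."""
    acq = echoes.config
    image = fourier_1d(echoes)
    image, start = crop_fov(image, fov_fraction)
    vel_c, mag_c = shared_velocity_encoding(image, echoes.venc_toggle, acq)
    velocity, magnitude = combine_channels(vel_c, mag_c)
    # [frame, pixel] -> [pixel, frame]
    return VelocityMap(
        velocity=velocity.T.copy(),
        magnitude=magnitude.T.copy(),
        dt=acq.tr_s,
        pixel_extent_mm=acq.pixel_mm,
        t0=float(echoes.echo_times[0]) + acq.tr_s / 2.0,
        pixel0=start,
    )
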