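"""Eulerian video magnification.

Each frame is decomposed into a Laplacian pyramid; every spatial band is
temporally band-passed, the filtered signal B is amplified and added back
(L' = L + alpha * B), and the pyramid is collapsed to reconstruct the frame.
Sub-pixel motions of amplitude delta are, to first order, amplified to
(1 + alpha) * delta displacements.

The temporal filter is an ideal band-pass applied with the FFT along the
time axis of each pyramid level, so pass/stop-band gains are exactly 1 / 0
at the DFT bin frequencies.  The pyramid uses the classic 5-tap binomial
kernel; detail levels are defined as ``G_k - up(down(G_k))`` which makes
``collapse(build(x)) == x`` to machine precision by construction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List

import numpy as np
from scipy.ndimage import correlate1d

from .errors import DataError

#: 5-tap binomial low-pass kernel used for pyramid down/up sampling.
_KERNEL = np.array([1.0, 4.0, 6.0, 4.0, 1.0]) / 16.0


@dataclass
class EvmConfig:
    """Magnification settings.

    alpha
        Amplification factor applied to the band-passed signal (unitless).
    levels
        Laplacian pyramid depth; frame height and width must be divisible
        by ``2 ** (levels - 1)``.
    f_low, f_high
        Temporal pass-band edges in Hz, with 0 <= f_low < f_high <= fps/2.
    fps
        Frame rate of the sequence being magnified.
    """

    alpha: float = 20.0
    levels: int = 3
    f_low: float = 0.4
    f_high: float = 3.0
    fps: float = 30.0

    def validate(self) -> None:
        if self.alpha < 0:
            raise ValueError("alpha must be >= 0")
        if self.levels < 1:
            raise ValueError("levels must be >= 1")
        if not (0 <= self.f_low < self.f_high <= self.fps / 2):
            raise ValueError(
                f"pass-band [{self.f_low}, {self.f_high}] Hz must satisfy "
                f"0 <= f_low < f_high <= fps/2 = {self.fps / 2}")


def _blur(img: np.ndarray) -> np.ndarray:
    out = correlate1d(img, _KERNEL, axis=0, mode="reflect")
    return correlate1d(out, _KERNEL, axis=1, mode="reflect")


def _down(img: np.ndarray) -> np.ndarray:
    return _blur(img)[::2, ::2]


_UP_WEIGHTS: dict = {}


def _up(img: np.ndarray, shape) -> np.ndarray:
    out = np.zeros(shape, dtype=np.float64)
    out[::2, ::2] = img
    # normalising by the blurred sample comb gives exactly unit DC gain
    # everywhere, including at borders
    if shape not in _UP_WEIGHTS:
        comb = np.zeros(shape)
        comb[::2, ::2] = 1.0
        _UP_WEIGHTS[shape] = _blur(comb)
    return _blur(out) / _UP_WEIGHTS[shape]


def _check_divisible(shape, levels: int) -> None:
    div = 2 ** (levels - 1)
    h, w = shape
    if h % div or w % div:
        raise DataError(
            f"frame shape {h}x{w} must be divisible by 2**(levels-1) = {div} "
            f"for a {levels}-level pyramid")


def build_pyramid(img: np.ndarray, levels: int) -> List[np.ndarray]:
    """Decompose ``img`` into ``levels`` bands, finest detail first.

    The last entry is the low-pass residual.  ``levels=1`` returns the image
    itself as the single band.
    """
    img = np.asarray(img, dtype=np.float64)
    if img.ndim != 2 or img.size == 0:
        raise DataError("build_pyramid expects a non-empty 2-D image")
    if levels < 1:
        raise ValueError("levels must be >= 1")
    _check_divisible(img.shape, levels)
    bands = []
    current = img
    for _ in range(levels - 1):
        low = _down(current)
        bands.append(current - _up(low, current.shape))
        current = low
    bands.append(current)
    return bands


def collapse_pyramid(pyramid: List[np.ndarray]) -> np.ndarray:
    """Invert :func:`build_pyramid` exactly."""
    if not pyramid:
        raise DataError("cannot collapse an empty pyramid")
    img = pyramid[-1]
    for band in reversed(pyramid[:-1]):
        if band.shape != tuple(2 * s for s in img.shape):
            raise DataError(
                f"inconsistent pyramid level shapes {band.shape} vs {img.shape}")
        img = band + _up(img, band.shape)
    return img


def temporal_bandpass(series: np.ndarray, f_low: float, f_high: float,
                      fps: float) -> np.ndarray:
    """Ideal band-pass along axis 0 of a per-pixel time series.

    Frequency components within [f_low, f_high] Hz are kept with unit gain,
    everything else (including DC) is removed.
    """
    series = np.asarray(series, dtype=np.float64)
    if series.shape[0] < 2:
        raise DataError("temporal_bandpass needs at least 2 frames")
    if not (0 <= f_low < f_high <= fps / 2):
        raise ValueError(
            f"band [{f_low}, {f_high}] outside (0, fps/2] for fps={fps}")
    t = series.shape[0]
    freqs = np.fft.rfftfreq(t, d=1.0 / fps)
    spectrum = np.fft.rfft(series, axis=0)
    mask = (freqs >= f_low) & (freqs <= f_high) & (freqs > 0)
    spectrum[~mask] = 0.0
    return np.fft.irfft(spectrum, n=t, axis=0)


def magnify_sequence(frames: np.ndarray, config: EvmConfig) -> np.ndarray:
    """Motion-magnify a ``(T, H, W)`` stack; output clipped to [0, 1].

    Every pyramid level, including the low-pass residual, receives
    L' = L + alpha * B where B is its band-passed time series.
    """
    config.validate()
    frames = np.asarray(frames, dtype=np.float64)
    if frames.ndim != 3:
        raise DataError("magnify_sequence expects a (T, H, W) stack")
    t = frames.shape[0]
    _check_divisible(frames.shape[1:], config.levels)

    pyramids = [build_pyramid(frames[i], config.levels) for i in range(t)]
    out_pyramids = [[None] * config.levels for _ in range(t)]
    for level in range(config.levels):
        stack = np.stack([pyramids[i][level] for i in range(t)])
        band = temporal_bandpass(stack, config.f_low, config.f_high, config.fps)
        amplified = stack + config.alpha * band
        for i in range(t):
            out_pyramids[i][level] = amplified[i]
    result = np.stack([collapse_pyramid(p) for p in out_pyramids])
    return np.clip(result, 0.0, 1.0)
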