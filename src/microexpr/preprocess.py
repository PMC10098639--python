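"""Apex-centred frame-window selection and stream-input construction.

A clip is reduced to exactly 18 frames enclosing the apex (the frame of
peak motion intensity).  The selected frames are resized to the two
network resolutions — 64x64 for the video stream, 144x120 (height x width)
for the optical-flow stream — and both resized sequences are motion
magnified as whole 18-frame sequences (temporal filtering needs the
sequence, not single frames).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional

import numpy as np
from skimage.transform import resize as _skimage_resize

from .datasets_io import Sample, load_frames
from .errors import DataError
from .evm import EvmConfig, magnify_sequence

WINDOW_LENGTH = 18
#: Frames kept strictly before the apex in the centred case.
APEX_BEFORE = 9
#: Frames kept strictly after the apex in the centred case.
APEX_AFTER = 8

VIDEO_SIZE = (64, 64)      # (height, width) of the video-stream input
FLOW_SIZE = (144, 120)     # (height, width) of the flow-stream input


@dataclass
class FrameWindow:
    """The 18-frame window feeding both streams.

    ``indices`` are source-frame indices (non-decreasing; the last index
    repeats when the clip is shorter than 18 frames).  ``frames_small`` and
    ``frames_flowres`` are (64, 64, 18) and (144, 120, 18) volumes in
    height x width x time order.
    """

    indices: List[int]
    frames_small: np.ndarray
    frames_flowres: np.ndarray


def select_frame_window(n_frames: int, apex_index: Optional[int]) -> List[int]:
    """Choose the 18 source-frame indices enclosing the apex.

    Rule precedence:

    a. apex known with >= 9 frames before and >= 8 after: the centred
       window ``[apex-9, apex+8]`` (apex at position 9);
    b. apex known but fewer than 9 frames before it: the first 18 frames;
    c. apex known but fewer than 8 frames after it: the last 18 frames;
    d. apex unknown: the first 18 frames;
    e. clip shorter than 18 frames: every frame, then the offset (last)
       frame duplicated until the window holds 18 entries.
    """
    if n_frames < 1:
        raise DataError("cannot select a frame window from an empty clip")
    if apex_index is not None and not (0 <= apex_index < n_frames):
        raise DataError(
            f"apex index {apex_index} outside clip of {n_frames} frames")

    if n_frames < WINDOW_LENGTH:
        indices = list(range(n_frames))
        indices += [n_frames - 1] * (WINDOW_LENGTH - n_frames)
        return indices
    if apex_index is None:
        return list(range(WINDOW_LENGTH))
    if apex_index < APEX_BEFORE:
        return list(range(WINDOW_LENGTH))
    if n_frames - 1 - apex_index < APEX_AFTER:
        return list(range(n_frames - WINDOW_LENGTH, n_frames))
    return list(range(apex_index - APEX_BEFORE, apex_index + APEX_AFTER + 1))


def resize_frame(img: np.ndarray, height: int, width: int) -> np.ndarray:
    """Bilinear resize of one 2-D intensity image to (height, width)."""
    img = np.asarray(img, dtype=np.float64)
    if img.ndim != 2 or img.size == 0:
        raise DataError("resize_frame expects a non-empty 2-D image")
    if height < 1 or width < 1:
        raise ValueError("target size must be positive")
    if img.shape == (height, width):
        return img.copy()
    return _skimage_resize(img, (height, width), order=1, mode="reflect",
                           anti_aliasing=None, preserve_range=True)


def _resize_stack(frames: np.ndarray, size) -> np.ndarray:
    return np.stack([resize_frame(f, *size) for f in frames])


def build_window(sample: Sample, evm_config: EvmConfig) -> FrameWindow:
    """Select, resize and magnify a sample into the two stream inputs."""
    frames = load_frames(sample)
    indices = select_frame_window(frames.shape[0], sample.apex_index)
    window = frames[indices]

    cfg = EvmConfig(alpha=evm_config.alpha, levels=evm_config.levels,
                    f_low=evm_config.f_low, f_high=evm_config.f_high,
                    fps=sample.fps if sample.fps else evm_config.fps)
    small = magnify_sequence(_resize_stack(window, VIDEO_SIZE), cfg)
    flowres = magnify_sequence(_resize_stack(window, FLOW_SIZE), cfg)

    return FrameWindow(
        indices=indices,
        frames_small=np.transpose(small, (1, 2, 0)),
        frames_flowres=np.transpose(flowres, (1, 2, 0)),
    )
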