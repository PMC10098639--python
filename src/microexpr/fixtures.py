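"""Synthetic expression-clip generator.

Real micro-expression corpora are license-gated, so every stage of the
pipeline is exercised on synthetic clips that reproduce the properties the
method depends on: a subject-specific static "face" (smooth random
texture), a localised Gaussian patch whose centre translates along a
class-specific direction with an amplitude that ramps up to a mid-clip
apex and back (micro domain) or monotonically to the final frame (macro
domain, emulating onset-to-apex macro-expression sequences), sub-pixel to
few-pixel peak displacements, and additive sensor noise.

Class-to-motion mapping: class 0 moves the patch downward, class 1 upward,
class 2 splits into two patches moving horizontally outward.  Sub-pixel
motion is obtained by shifting the analytic Gaussian centre before
rasterisation, so there are no interpolation artifacts and the first-order
motion-magnification prediction holds on these clips.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import imageio.v3 as iio
import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .datasets_io import (DOMAIN_MACRO, DOMAIN_MICRO, Catalog, Sample,
                          scan_dataset)

#: raw label names per unified class, written into samm-like label tables
RAW_LABELS = {0: "other", 1: "happiness", 2: "surprise"}
#: CK-style raw labels used when writing macro-domain trees
RAW_LABELS_MACRO = {0: "anger", 1: "happiness", 2: "surprise"}


@dataclass
class SynthConfig:
    """Generator settings.

    Peak patch displacements are in native pixels: the micro domain moves
    sub-pixel to a couple of pixels, the macro domain several times more,
    mirroring the intensity gap between micro- and macro-expressions.
    """

    n_subjects: int = 12
    clips_per_subject: int = 3
    frames_per_clip: int = 24
    fps: float = 24.0
    # native (height, width); divisible by 4 so clips can be magnified
    # at native resolution as well as after resizing
    frame_shape: tuple = (180, 148)
    micro_amplitude: float = 1.0          # peak displacement, pixels
    macro_amplitude: float = 6.0
    patch_sigma: float = 9.0              # Gaussian patch width, pixels
    patch_contrast: float = 0.35
    noise_std: float = 0.01
    seed: int = 0

    def validate(self) -> None:
        if self.micro_amplitude <= 0 or self.macro_amplitude <= 0:
            raise ValueError("motion amplitudes must be positive")
        if self.macro_amplitude <= self.micro_amplitude:
            raise ValueError("macro amplitude must exceed micro amplitude")
        if self.n_subjects < 1 or self.clips_per_subject < 1:
            raise ValueError("need at least one subject and clip")


def _subject_rng(cfg: SynthConfig, subject_id: str) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence([cfg.seed, zlib.crc32(subject_id.encode())]))


def _clip_rng(cfg: SynthConfig, clip_id: str, class_id: int,
              domain: int) -> np.random.Generator:
    key = zlib.crc32(f"{clip_id}/{class_id}/{domain}".encode())
    return np.random.default_rng(np.random.SeedSequence([cfg.seed, key, 1]))


def _base_face(cfg: SynthConfig, subject_id: str) -> np.ndarray:
    """Subject-specific smooth random texture in [0.2, 0.8]."""
    rng = _subject_rng(cfg, subject_id)
    tex = gaussian_filter(rng.random(cfg.frame_shape), sigma=6.0)
    lo, hi = tex.min(), tex.max()
    return 0.2 + 0.6 * (tex - lo) / (hi - lo if hi > lo else 1.0)


def _gaussian_patch(shape, center, sigma) -> np.ndarray:
    rows = np.arange(shape[0])[:, None]
    cols = np.arange(shape[1])[None, :]
    return np.exp(-((rows - center[0]) ** 2 + (cols - center[1]) ** 2)
                  / (2.0 * sigma ** 2))


def _displacement_profile(t: int, n: int, apex: int, domain: int) -> float:
    """Unit-peak displacement at frame t: ramp to the apex and back for
    micro clips, monotonic onset-to-apex ramp for macro clips."""
    if domain == DOMAIN_MACRO:
        return t / max(n - 1, 1)
    tau = n / 6.0
    return float(np.exp(-((t - apex) / tau) ** 2))


def synth_sample(class_id: int, subject_id: str, domain: int,
                 cfg: SynthConfig, clip_id: Optional[str] = None) -> Sample:
    """Generate one labelled clip deterministically from (class, subject,
    domain, seed)."""
    cfg.validate()
    if class_id not in (0, 1, 2):
        raise ValueError("class_id must be 0, 1 or 2")
    clip_id = clip_id or f"{subject_id}_c{class_id}_d{domain}"
    rng = _clip_rng(cfg, clip_id, class_id, domain)
    n = cfg.frames_per_clip
    h, w = cfg.frame_shape
    base = _base_face(cfg, subject_id)

    amplitude = (cfg.macro_amplitude if domain == DOMAIN_MACRO
                 else cfg.micro_amplitude)
    if domain == DOMAIN_MACRO:
        apex = n - 1
    else:
        apex = (n - 1) // 2 + int(rng.integers(-2, 3))
        apex = int(np.clip(apex, 1, n - 2))

    # class-specific motion: list of (rest_center, unit_direction)
    jitter = rng.uniform(-5, 5, size=2)
    center = np.array([h / 2, w / 2]) + jitter
    if class_id == 0:
        patches = [(center, np.array([1.0, 0.0]))]     # downward
    elif class_id == 1:
        patches = [(center, np.array([-1.0, 0.0]))]    # upward
    else:
        offset = np.array([0.0, w / 6])
        patches = [(center - offset, np.array([0.0, -1.0])),
                   (center + offset, np.array([0.0, 1.0]))]  # outward

    frames = np.empty((n, h, w))
    noise = rng.normal(0.0, cfg.noise_std, size=(n, h, w))
    for t in range(n):
        disp = amplitude * _displacement_profile(t, n, apex, domain)
        frame = base.copy()
        for rest, direction in patches:
            frame += cfg.patch_contrast * _gaussian_patch(
                (h, w), rest + disp * direction, cfg.patch_sigma)
        frames[t] = frame
    frames = np.clip(frames + noise, 0.0, 1.0)

    return Sample(
        clip_id=clip_id,
        subject_id=subject_id,
        dataset="synthetic",
        emotion=class_id,
        domain=domain,
        fps=cfg.fps,
        apex_index=None if domain == DOMAIN_MACRO else apex,
        frames=frames,
    )


def synth_catalog(cfg: SynthConfig, domain: int = DOMAIN_MICRO,
                  out_dir=None) -> Catalog:
    """Balanced catalog: each subject contributes clips cycling the 3
    classes.  With ``out_dir`` set, also writes a samm-like image-sequence
    tree plus ``labels.csv`` that :func:`scan_dataset` can re-read."""
    cfg.validate()
    samples = []
    for si in range(cfg.n_subjects):
        subject = f"s{si:03d}"
        for ci in range(cfg.clips_per_subject):
            class_id = ci % 3
            clip_id = f"{subject}_clip{ci:02d}"
            samples.append(synth_sample(class_id, subject, domain, cfg,
                                        clip_id=clip_id))
    catalog = Catalog(samples=samples)
    if out_dir is not None:
        write_fixture_tree(catalog, out_dir)
    return catalog


def write_fixture_tree(catalog: Catalog, out_dir) -> None:
    """Materialise a catalog as PNG frame folders plus a labels.csv.

    Micro catalogs get a samm-like table (apex column included); macro
    catalogs get a ck-like table (CK-style emotion names, no apex), so
    each tree round-trips through :func:`scan_dataset` with the matching
    layout.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    macro = all(s.domain == DOMAIN_MACRO for s in catalog.samples)
    rows = []
    for sample in catalog.samples:
        clip_dir = out_dir / sample.clip_id
        clip_dir.mkdir(exist_ok=True)
        frames = sample.frames
        for t in range(frames.shape[0]):
            img = (np.clip(frames[t], 0, 1) * 255).round().astype(np.uint8)
            iio.imwrite(clip_dir / f"frame_{t:04d}.png", img)
        row = {
            "clip_id": sample.clip_id,
            "subject_id": sample.subject_id,
            "label": (RAW_LABELS_MACRO if macro
                      else RAW_LABELS)[sample.emotion],
        }
        if not macro:
            row["apex_index"] = ("" if sample.apex_index is None
                                 else sample.apex_index)
        rows.append(row)
    pd.DataFrame(rows).to_csv(out_dir / "labels.csv", index=False)


def load_fixture_tree(root, fps: float = 24.0) -> Catalog:
    """Re-read a tree written by :func:`write_fixture_tree`."""
    return scan_dataset(root, "samm-like", fps=fps)
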