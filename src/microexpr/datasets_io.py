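"""Clip discovery, labelling and frame loading.

Clips live on disk as folders of lexicographically ordered PNG/JPEG frames
next to a ``labels.csv`` table, mirroring how SAMM-, SMIC- and CK+-style
corpora are usually organised:

    root/
      labels.csv          # columns: clip_id, subject_id, label[, apex_index]
      <clip_id>/          # one folder per clip
        frame_0000.png
        frame_0001.png
        ...

Three layouts are understood.  ``samm-like`` provides an apex-frame column;
``smic-like`` does not (the apex frame is not annotated in SMIC-style data);
``ck-like`` holds macro-expressions (domain 1) labelled with classic
seven-emotion names.  All labels are mapped into a unified 3-class space:

    0  other / negative   (anger, contempt, disgust, fear, sadness, ...)
    1  happiness / positive
    2  surprise

Frames are loaded as single-channel float stacks in [0, 1]; colour images
are converted with the BT.601 luma weights.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .errors import ConfigError, DataError, LabelError

logger = logging.getLogger(__name__)

DOMAIN_MICRO = 0
DOMAIN_MACRO = 1

CLASS_NAMES = ["negative", "positive", "surprise"]

IMAGE_EXTENSIONS = {".png", ".jpg", ".jpeg", ".bmp", ".tif", ".tiff"}

#: Per-layout raw-label vocabularies mapped onto the unified 3-class space.
LABEL_MAPS = {
    "samm-like": {
        "other": 0, "anger": 0, "contempt": 0, "disgust": 0, "fear": 0,
        "sadness": 0, "happiness": 1, "surprise": 2,
    },
    "smic-like": {
        "negative": 0, "positive": 1, "surprise": 2,
    },
    "ck-like": {
        "anger": 0, "contempt": 0, "disgust": 0, "fear": 0, "sadness": 0,
        "happiness": 1, "happy": 1, "surprise": 2,
    },
}

LAYOUTS = tuple(LABEL_MAPS)


@dataclass
class Sample:
    """One labelled clip.

    Frames may be backed by image files (``frame_paths``) or held in memory
    (``frames``); :func:`load_frames` resolves either into a ``(T, H, W)``
    float stack in [0, 1].
    """

    clip_id: str
    subject_id: str
    dataset: str
    emotion: int
    domain: int
    fps: float
    apex_index: Optional[int] = None
    frame_paths: Optional[list] = None
    frames: Optional[np.ndarray] = None

    @property
    def n_frames(self) -> int:
        if self.frames is not None:
            return int(self.frames.shape[0])
        return len(self.frame_paths)

    def with_apex(self, apex_index: int) -> "Sample":
        return replace(self, apex_index=apex_index)


@dataclass
class Catalog:
    """Ordered collection of samples plus the unified class names."""

    samples: list = field(default_factory=list)
    class_names: Sequence[str] = tuple(CLASS_NAMES)

    def __len__(self) -> int:
        return len(self.samples)

    def __iter__(self):
        return iter(self.samples)

    def subjects(self) -> list:
        seen = {}
        for s in self.samples:
            seen.setdefault(s.subject_id, None)
        return list(seen)


def map_label(raw: str, dataset: str) -> int:
    """Map a raw emotion label onto the unified 3-class index.

    ``dataset`` names the layout vocabulary (``samm-like``, ``smic-like`` or
    ``ck-like``).  Unknown labels raise :class:`LabelError` naming the value.
    """
    if dataset not in LABEL_MAPS:
        raise ConfigError(
            f"unknown dataset layout {dataset!r}; expected one of {LAYOUTS}")
    key = str(raw).strip().lower()
    table = LABEL_MAPS[dataset]
    if key not in table:
        raise LabelError(
            f"unknown label {raw!r} for layout {dataset!r}; "
            f"known labels: {sorted(table)}")
    return table[key]


def _list_frame_files(clip_dir: Path) -> list:
    return sorted(
        p for p in clip_dir.iterdir()
        if p.is_file() and p.suffix.lower() in IMAGE_EXTENSIONS
    )


def to_grayscale(img: np.ndarray) -> np.ndarray:
    """Convert an image array to float64 grayscale in [0, 1].

    Integer inputs are rescaled by their dtype maximum; RGB(A) channels are
    combined with BT.601 luma weights (0.299, 0.587, 0.114).
    """
    arr = np.asarray(img)
    if np.issubdtype(arr.dtype, np.integer):
        arr = arr.astype(np.float64) / np.iinfo(arr.dtype).max
    else:
        arr = arr.astype(np.float64)
    if arr.ndim == 3:
        if arr.shape[2] >= 3:
            arr = arr[..., 0] * 0.299 + arr[..., 1] * 0.587 + arr[..., 2] * 0.114
        else:
            arr = arr[..., 0]
    return np.clip(arr, 0.0, 1.0)


def load_frames(sample: Sample) -> np.ndarray:
    """Return the sample's frames as a ``(T, H, W)`` float stack in [0, 1]."""
    if sample.frames is not None:
        stack = np.asarray(sample.frames, dtype=np.float64)
        if stack.ndim != 3 or stack.shape[0] == 0:
            raise DataError(f"clip {sample.clip_id}: malformed in-memory stack")
        return stack
    if not sample.frame_paths:
        raise DataError(f"clip {sample.clip_id}: no frames")
    frames = []
    shape = None
    for path in sample.frame_paths:
        try:
            img = iio.imread(path)
        except Exception as exc:  # noqa: BLE001 - re-raise with path context
            raise DataError(f"cannot read frame {path}: {exc}") from exc
        gray = to_grayscale(img)
        if shape is None:
            shape = gray.shape
        elif gray.shape != shape:
            raise DataError(
                f"clip {sample.clip_id}: frame {path} has shape {gray.shape}, "
                f"expected {shape}")
        frames.append(gray)
    return np.stack(frames)


def scan_dataset(root, layout: str, fps: float) -> Catalog:
    """Discover all clips under ``root`` for the given layout.

    Reads ``labels.csv`` (columns ``clip_id, subject_id, label`` and, for
    samm-like trees, an optional ``apex_index``), locates each clip folder
    and returns a :class:`Catalog` with lazily loaded samples.  Clip folders
    containing zero images are skipped with a warning; a missing label table
    is a configuration error.
    """
    root = Path(root)
    if layout not in LABEL_MAPS:
        raise ConfigError(
            f"unknown layout {layout!r}; expected one of {LAYOUTS}")
    if not root.is_dir():
        raise DataError(f"dataset root {root} does not exist")
    table_path = root / "labels.csv"
    if not table_path.is_file():
        raise ConfigError(f"label table {table_path} not found")
    table = pd.read_csv(table_path, dtype={"clip_id": str, "subject_id": str})
    for col in ("clip_id", "subject_id", "label"):
        if col not in table.columns:
            raise ConfigError(f"label table {table_path} lacks column {col!r}")

    domain = DOMAIN_MACRO if layout == "ck-like" else DOMAIN_MICRO
    use_apex = layout == "samm-like" and "apex_index" in table.columns
    samples = []
    for row in table.itertuples(index=False):
        clip_dir = root / str(row.clip_id)
        if not clip_dir.is_dir():
            raise DataError(f"clip folder {clip_dir} not found")
        paths = _list_frame_files(clip_dir)
        if not paths:
            logger.warning("skipping clip %s: no image files", clip_dir)
            continue
        apex = None
        if use_apex:
            raw_apex = getattr(row, "apex_index")
            if raw_apex is not None and not pd.isna(raw_apex):
                apex = int(raw_apex)
        samples.append(Sample(
            clip_id=str(row.clip_id),
            subject_id=str(row.subject_id),
            dataset=layout,
            emotion=map_label(row.label, layout),
            domain=domain,
            fps=float(fps),
            apex_index=apex,
            frame_paths=paths,
        ))
    return Catalog(samples=samples)


def write_manifest(catalog: Catalog, path) -> None:
    """Write the catalog metadata (not pixel data) as a CSV manifest."""
    rows = []
    for s in catalog.samples:
        rows.append({
            "clip_id": s.clip_id,
            "subject_id": s.subject_id,
            "dataset": s.dataset,
            "emotion": s.emotion,
            "domain": s.domain,
            "fps": s.fps,
            "apex_index": "" if s.apex_index is None else s.apex_index,
            "n_frames": s.n_frames,
        })
    pd.DataFrame(rows).to_csv(path, index=False)


def read_manifest(path) -> pd.DataFrame:
    """Read a catalog manifest back as a DataFrame (metadata only)."""
    df = pd.read_csv(path, dtype={"clip_id": str, "subject_id": str})
    return df
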