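"""Dataset directory scanning and orientation-image caching.

A dataset is a directory with one subdirectory per species containing
PNG/JPEG photographs.  Scanning is deterministic (codepoint-ordered, locale
independent), and preprocessing results are cached on disk as 1-bit PNGs
keyed by a hash of the preprocessing configuration, so re-runs with an
unchanged configuration cost nothing and a changed configuration invalidates
the cache automatically.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from PIL import Image

from .exceptions import InvalidInputError
from .preprocessing import BinaryOrientationImage, PreprocessConfig, preprocess_image

__all__ = ["DatasetManifest", "OrientationCache", "scan_dataset", "preprocess_dataset",
           "orientation_matrix", "config_hash"]

log = logging.getLogger(__name__)

IMAGE_EXTS = {".png", ".jpg", ".jpeg"}


@dataclass(frozen=True)
class DatasetManifest:
    """Deterministic listing of a directory-per-class image dataset."""

    samples: tuple  # of (sample_id, path, class label)
    root: Path

    @property
    def classes(self) -> list:
        return sorted({lab for _, _, lab in self.samples})

    @property
    def C(self) -> int:
        return len(self.classes)

    @property
    def class_counts(self) -> dict:
        out: dict = {}
        for _, _, lab in self.samples:
            out[lab] = out.get(lab, 0) + 1
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.samples, columns=["sample_id", "path", "class"])


def scan_dataset(root) -> DatasetManifest:
    """Scan ``root`` for class subdirectories of images.

    Non-image files are skipped with a warning; empty class directories are
    skipped with a warning; fewer than two usable classes is an error.
    Class labels are the directory names verbatim.
    """
    root = Path(root)
    if not root.is_dir():
        raise InvalidInputError(f"dataset root {root} is not a directory")
    samples = []
    usable = 0
    for cls_dir in sorted((d for d in root.iterdir() if d.is_dir()), key=lambda d: d.name):
        files = sorted((f for f in cls_dir.iterdir() if f.is_file()), key=lambda f: f.name)
        imgs = []
        for f in files:
            if f.suffix.lower() in IMAGE_EXTS:
                imgs.append(f)
            else:
                warnings.warn(f"skipping non-image file {f}", stacklevel=2)
        if not imgs:
            warnings.warn(f"skipping empty class directory {cls_dir}", stacklevel=2)
            continue
        usable += 1
        for f in imgs:
            samples.append((f"{cls_dir.name}/{f.stem}", str(f), cls_dir.name))
    if usable < 2:
        raise InvalidInputError(f"need at least 2 usable class directories under {root}")
    return DatasetManifest(samples=tuple(samples), root=root)


def config_hash(cfg: PreprocessConfig) -> str:
    """Stable short hash of a preprocessing configuration."""
    payload = json.dumps(
        {k: getattr(cfg, k) for k in sorted(cfg.__dataclass_fields__)},
        sort_keys=True, default=str,
    )
    return hashlib.sha1(payload.encode()).hexdigest()[:12]


@dataclass
class OrientationCache:
    """Mapping sample_id -> 32x16 binary orientation image, tied to one config hash."""

    entries: dict
    cfg_hash: str
    cache_dir: Optional[Path] = None
    n_recomputed: int = 0
    failures: dict = field(default_factory=dict)

    def __getitem__(self, sample_id: str) -> BinaryOrientationImage:
        return self.entries[sample_id]

    def __len__(self) -> int:
        return len(self.entries)


def _cache_path(cache_dir: Path, cfg_hash: str, sample_id: str) -> Path:
    return cache_dir / cfg_hash / (sample_id + ".png")


def preprocess_dataset(
    manifest: DatasetManifest,
    cfg: PreprocessConfig | None = None,
    cache_dir=None,
) -> OrientationCache:
    """Preprocess every sample once, reusing on-disk results where valid.

    Cached orientation images are stored as 1-bit PNGs under
    ``cache_dir/<config-hash>/<sample_id>.png``; a changed configuration
    changes the hash and forces full recomputation.  Per-sample failures are
    collected (not fatal) unless every sample fails.
    """
    cfg = cfg or PreprocessConfig()
    h = config_hash(cfg)
    cache_dir = Path(cache_dir) if cache_dir is not None else None
    entries: dict = {}
    failures: dict = {}
    recomputed = 0
    for sample_id, path, _ in manifest.samples:
        if cache_dir is not None:
            p = _cache_path(cache_dir, h, sample_id)
            if p.exists():
                px = (np.asarray(Image.open(p).convert("1"), dtype=np.uint8) > 0).astype(np.uint8)
                entries[sample_id] = BinaryOrientationImage(pixels=px, source_id=sample_id)
                continue
        try:
            img = np.asarray(Image.open(path).convert("RGB"))
            boi = preprocess_image(img, cfg, source_id=sample_id)
        except Exception as exc:  # collected, reported, not fatal
            log.warning("preprocessing failed for %s: %s", sample_id, exc)
            failures[sample_id] = str(exc)
            continue
        recomputed += 1
        entries[sample_id] = boi
        if cache_dir is not None:
            p = _cache_path(cache_dir, h, sample_id)
            p.parent.mkdir(parents=True, exist_ok=True)
            Image.fromarray((boi.pixels * 255).astype(np.uint8)).convert("1").save(p)
    if not entries:
        raise InvalidInputError("preprocessing failed for every sample in the dataset")
    return OrientationCache(entries=entries, cfg_hash=h, cache_dir=cache_dir,
                            n_recomputed=recomputed, failures=failures)


def orientation_matrix(cache: OrientationCache, manifest: DatasetManifest):
    """Stack cached orientation images into an (n, 512) matrix plus labels."""
    X, y = [], []
    for sample_id, _, lab in manifest.samples:
        if sample_id in cache.entries:
            X.append(cache.entries[sample_id].pixels.ravel())
            y.append(lab)
    return np.stack(X), np.asarray(y, dtype=object)
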