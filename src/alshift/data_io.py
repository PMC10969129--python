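"""Directory-of-images datasets and deterministic preprocessing.

The on-disk layout is ``<root>/{train,test}/<class_name>/<sample_id>.png``
with exactly two class subdirectories per split.  Images are stored as 8-bit
PNG; in memory every sample carries float pixels in ``[0, 1]``.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
from PIL import Image, UnidentifiedImageError

from .errors import StructureError

logger = logging.getLogger(__name__)

#: Label values.  ``CLASS1`` is the positive ("ASD") class by convention.
CLASS0 = 0
CLASS1 = 1
UNLABELED = -1

_SPLITS = ("train", "test")
_CLASS_NAMES_FILE = "class_names.json"


@dataclass
class ImageSample:
    """One image with its label, provenance and split assignment.

    ``label`` is ``CLASS0``/``CLASS1``, or ``UNLABELED`` which is only legal
    inside an active-learning pool (never in a test set).
    """

    sample_id: str
    pixels: np.ndarray  # (H, W, C) float32 in [0, 1]
    label: int
    domain_id: str
    split: str

    def __post_init__(self) -> None:
        if self.label not in (CLASS0, CLASS1, UNLABELED):
            raise ValueError(f"invalid label {self.label!r}")
        if self.split not in _SPLITS:
            raise ValueError(f"invalid split {self.split!r}")
        if self.label == UNLABELED and self.split == "test":
            raise ValueError("test samples must be labeled")

    def with_label(self, label: int) -> "ImageSample":
        return replace(self, label=label)


@dataclass
class DomainDataset:
    """Train/test splits of one domain, two classes.

    ``class_names`` maps label index to display name: ``class_names[0]`` is
    the negative class (e.g. ``"NC"``), ``class_names[1]`` the positive one
    (e.g. ``"ASD"``).
    """

    domain_id: str
    train: list[ImageSample] = field(default_factory=list)
    test: list[ImageSample] = field(default_factory=list)
    class_names: tuple[str, str] = ("NC", "ASD")

    def __post_init__(self) -> None:
        ids = [s.sample_id for s in self.train] + [s.sample_id for s in self.test]
        if len(ids) != len(set(ids)):
            raise ValueError("sample_ids must be unique across train and test")
        for s in self.test:
            if s.label == UNLABELED:
                raise ValueError(f"test sample {s.sample_id} is unlabeled")

    @property
    def n_train(self) -> int:
        return len(self.train)

    @property
    def n_test(self) -> int:
        return len(self.test)

    def split(self, name: str) -> list[ImageSample]:
        if name not in _SPLITS:
            raise ValueError(f"unknown split {name!r}")
        return self.train if name == "train" else self.test

    def counts(self) -> dict[str, dict[str, int]]:
        """Per-split, per-class sample counts (plus unlabeled)."""
        out: dict[str, dict[str, int]] = {}
        for split in _SPLITS:
            c: dict[str, int] = {self.class_names[0]: 0, self.class_names[1]: 0, "unlabeled": 0}
            for s in self.split(split):
                key = "unlabeled" if s.label == UNLABELED else self.class_names[s.label]
                c[key] += 1
            out[split] = c
        return out


def preprocess(pixels: np.ndarray, target_size: tuple[int, int]) -> np.ndarray:
    """Resize to ``target_size`` (H, W), force 3 channels, scale to [0, 1].

    Bilinear resampling, pinned for reproducibility.  Idempotent: an input
    already of the target shape with values in [0, 1] is returned unchanged
    (bitwise), apart from dtype promotion to float32.
    """
    arr = np.asarray(pixels)
    if arr.ndim == 2:
        arr = arr[:, :, None]
    if arr.ndim != 3:
        raise ValueError(f"expected a 2-D or 3-D image array, got ndim={arr.ndim}")
    if arr.shape[0] == 0 or arr.shape[1] == 0:
        raise ValueError("zero-area input image")
    if arr.shape[2] == 1:
        arr = np.repeat(arr, 3, axis=2)
    elif arr.shape[2] == 4:  # drop alpha
        arr = arr[:, :, :3]
    elif arr.shape[2] != 3:
        raise ValueError(f"unsupported channel count {arr.shape[2]}")

    arr = arr.astype(np.float32, copy=False)
    if arr.size and float(arr.max()) > 1.0:  # assume 8-bit input
        arr = arr / 255.0

    h, w = target_size
    if arr.shape[:2] != (h, w):
        planes = [
            np.asarray(
                Image.fromarray(arr[:, :, c], mode="F").resize((w, h), Image.BILINEAR),
                dtype=np.float32,
            )
            for c in range(3)
        ]
        arr = np.stack(planes, axis=2)
    return np.clip(arr, 0.0, 1.0)


def read_image_directory(
    root_path: str | Path,
    domain_id: str,
    target_size: tuple[int, int] = (64, 64),
    class_names: tuple[str, str] | None = None,
) -> DomainDataset:
    """Load a ``<root>/{train,test}/<class>/*`` tree into a :class:`DomainDataset`.

    Class index assignment: an explicit ``class_names`` argument wins, then a
    ``class_names.json`` sidecar written by :func:`write_image_directory`,
    then lexicographic order of the subdirectory names.  File ordering is an
    explicit lexicographic sort, never filesystem order.  Undecodable files
    are skipped with a logged warning.
    """
    root = Path(root_path)
    for split in _SPLITS:
        if not (root / split).is_dir():
            raise StructureError(f"missing split directory {root / split}")

    if class_names is None:
        sidecar = root / _CLASS_NAMES_FILE
        if sidecar.is_file():
            loaded = json.loads(sidecar.read_text())
            class_names = (str(loaded[0]), str(loaded[1]))

    train_classes = sorted(p.name for p in (root / "train").iterdir() if p.is_dir())
    if len(train_classes) != 2:
        raise StructureError(
            f"expected exactly 2 class subdirectories under {root / 'train'}, "
            f"found {len(train_classes)}: {train_classes}"
        )
    if class_names is None:
        class_names = (train_classes[0], train_classes[1])
    if sorted(class_names) != train_classes:
        raise StructureError(
            f"class subdirectories {train_classes} do not match class names {class_names}"
        )

    samples: dict[str, list[ImageSample]] = {"train": [], "test": []}
    n_skipped = 0
    for split in _SPLITS:
        split_classes = sorted(p.name for p in (root / split).iterdir() if p.is_dir())
        if len(split_classes) != 2:
            raise StructureError(
                f"expected exactly 2 class subdirectories under {root / split}, "
                f"found {len(split_classes)}"
            )
        for cls_dir in split_classes:
            label = class_names.index(cls_dir)
            files = sorted((root / split / cls_dir).iterdir())
            if not any(f.is_file() for f in files):
                logger.warning("empty class directory %s", root / split / cls_dir)
            for f in files:
                if not f.is_file():
                    continue
                try:
                    with Image.open(f) as im:
                        arr = np.asarray(im.convert("RGB"), dtype=np.float32)
                except (UnidentifiedImageError, OSError):
                    logger.warning("skipping undecodable file %s", f)
                    n_skipped += 1
                    continue
                samples[split].append(
                    ImageSample(
                        sample_id=f.stem,
                        pixels=preprocess(arr, target_size),
                        label=label,
                        domain_id=domain_id,
                        split=split,
                    )
                )
    if n_skipped:
        logger.warning("skipped %d undecodable files under %s", n_skipped, root)
    return DomainDataset(
        domain_id=domain_id,
        train=samples["train"],
        test=samples["test"],
        class_names=class_names,
    )


def write_image_directory(dataset: DomainDataset, root_path: str | Path) -> Path:
    """Write a dataset as 8-bit PNGs in the standard layout.

    Every sample must be labeled (unlabeled pools have no class folder).
    A ``class_names.json`` sidecar records the label ordering so a round-trip
    read restores the same label indices.
    """
    root = Path(root_path)
    for split in _SPLITS:
        for name in dataset.class_names:
            (root / split / name).mkdir(parents=True, exist_ok=True)
        for s in dataset.split(split):
            if s.label == UNLABELED:
                raise ValueError(f"cannot write unlabeled sample {s.sample_id}")
            arr = np.clip(np.rint(np.asarray(s.pixels) * 255.0), 0, 255).astype(np.uint8)
            path = root / split / dataset.class_names[s.label] / f"{s.sample_id}.png"
            Image.fromarray(arr).save(path)
    (root / _CLASS_NAMES_FILE).write_text(json.dumps(list(dataset.class_names)))
    return root


def stack_pixels(samples: Sequence[ImageSample]) -> np.ndarray:
    """Stack sample pixels into an (N, H, W, C) float32 batch."""
    if not samples:
        raise ValueError("empty sample sequence")
    return np.stack([np.asarray(s.pixels, dtype=np.float32) for s in samples])


def labels_of(samples: Sequence[ImageSample]) -> np.ndarray:
    return np.array([s.label for s in samples], dtype=np.int64)
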