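"""Image dataset I/O in a class-per-subfolder layout.

A dataset on disk is ``root/<class_name>/<image>.{png,jpg,jpeg}``; in memory it
is a :class:`LabeledDataset` of :class:`ImageSample` objects with intensities
normalised to ``[0, 1]``.  Class names are ordered lexicographically so the
label-to-index mapping is reproducible across platforms.
"""

from __future__ import annotations

import dataclasses
import datetime
import hashlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import yaml
from PIL import Image

IMAGE_EXTENSIONS = (".png", ".jpg", ".jpeg")


class DatasetError(ValueError):
    """Raised for malformed or empty datasets."""


@dataclass
class ImageSample:
    """A single labelled image.

    pixels
        ``(height, width, channels)`` float array with values in ``[0, 1]``;
        ``channels`` is 1 (grayscale) or 3 (RGB).
    label
        Class name.
    id
        Unique identifier within a dataset.
    source_path
        Optional provenance path.
    meta
        Free-form generation/processing log (e.g. synthetic blob centres).
    """

    pixels: np.ndarray
    label: str
    id: str
    source_path: str | None = None
    meta: dict | None = None

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=np.float32)
        if px.ndim == 2:
            px = px[:, :, None]
        if px.ndim != 3 or px.shape[2] not in (1, 3):
            raise DatasetError(
                f"sample {self.id!r}: expected HxWxC with C in {{1,3}}, got {px.shape}"
            )
        if px.shape[0] < 3 or px.shape[1] < 3:
            raise DatasetError(f"sample {self.id!r}: image smaller than 3x3")
        if not np.all(np.isfinite(px)):
            raise DatasetError(f"sample {self.id!r}: non-finite pixel values")
        if px.min() < 0.0 or px.max() > 1.0:
            raise DatasetError(f"sample {self.id!r}: pixel values outside [0, 1]")
        if not self.id:
            raise DatasetError("sample id must be nonempty")
        self.pixels = px

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def channels(self) -> int:
        return self.pixels.shape[2]


@dataclass
class LabeledDataset:
    """An ordered collection of samples plus the ordered class vocabulary."""

    samples: list[ImageSample]
    class_names: list[str]

    def __post_init__(self) -> None:
        if not self.class_names:
            raise DatasetError("class_names must be nonempty")
        if len(set(self.class_names)) != len(self.class_names):
            raise DatasetError("duplicate class names")
        ids = [s.id for s in self.samples]
        if len(set(ids)) != len(ids):
            raise DatasetError("duplicate sample ids")
        allowed = set(self.class_names)
        for s in self.samples:
            if s.label not in allowed:
                raise DatasetError(f"sample {s.id!r} has unknown label {s.label!r}")

    def __len__(self) -> int:
        return len(self.samples)

    def __iter__(self) -> Iterator[ImageSample]:
        return iter(self.samples)

    def label_index(self, label: str) -> int:
        return self.class_names.index(label)

    def labels(self) -> list[str]:
        return [s.label for s in self.samples]

    def subset(self, ids: Sequence[str]) -> "LabeledDataset":
        keep = set(ids)
        return LabeledDataset(
            [s for s in self.samples if s.id in keep], list(self.class_names)
        )


@dataclass
class RunManifest:
    """Echo of one run's effective configuration plus artifact checksums."""

    config: dict
    seed: int | None = None
    input_path: str | None = None
    output_path: str | None = None
    artifacts: dict = field(default_factory=dict)  # relative path -> sha256
    timestamp: str = ""

    def __post_init__(self) -> None:
        if not self.timestamp:
            self.timestamp = datetime.datetime.now(datetime.timezone.utc).isoformat()

    def to_yaml(self) -> str:
        return yaml.safe_dump(dataclasses.asdict(self), sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "RunManifest":
        return cls(**yaml.safe_load(text))

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_yaml())

    @classmethod
    def load(cls, path: str | Path) -> "RunManifest":
        return cls.from_yaml(Path(path).read_text())


def _decode_image(path: Path) -> np.ndarray:
    try:
        with Image.open(path) as im:
            if im.mode == "L":
                arr = np.asarray(im, dtype=np.float32) / 255.0
                return arr[:, :, None]
            if im.mode == "I;16":
                arr = np.asarray(im, dtype=np.float32) / 65535.0
                return arr[:, :, None]
            arr = np.asarray(im.convert("RGB"), dtype=np.float32) / 255.0
            return arr
    except Exception as exc:  # noqa: BLE001 - rewrap with the file name
        raise DatasetError(f"cannot decode image file {path}: {exc}") from exc


def load_dataset(root: str | Path) -> LabeledDataset:
    """Load ``root/<class>/<image>`` into a :class:`LabeledDataset`.

    Class names are the subdirectory names, sorted lexicographically; sample
    ids are ``<class>/<filename>``.  Intensities are scaled by the source
    dtype's maximum so all pixels land in ``[0, 1]``.
    """
    root = Path(root)
    if not root.is_dir():
        raise DatasetError(f"empty dataset: {root} is not a directory")
    class_dirs = sorted(p for p in root.iterdir() if p.is_dir())
    if not class_dirs:
        raise DatasetError(f"empty dataset: no class subdirectories under {root}")
    samples: list[ImageSample] = []
    class_names: list[str] = []
    for cdir in class_dirs:
        files = sorted(
            p for p in cdir.iterdir() if p.suffix.lower() in IMAGE_EXTENSIONS
        )
        if not files:
            raise DatasetError(f"empty dataset: class folder {cdir} has no images")
        class_names.append(cdir.name)
        for f in files:
            samples.append(
                ImageSample(
                    pixels=_decode_image(f),
                    label=cdir.name,
                    id=f"{cdir.name}/{f.name}",
                    source_path=str(f),
                )
            )
    return LabeledDataset(samples, class_names)


def to_rgb(image: ImageSample) -> ImageSample:
    """Replicate a grayscale channel to 3 channels; RGB passes through."""
    if image.channels == 3:
        return ImageSample(image.pixels.copy(), image.label, image.id,
                           image.source_path, image.meta)
    px = np.repeat(image.pixels, 3, axis=2)
    return ImageSample(px, image.label, image.id, image.source_path, image.meta)


def _safe_filename(sample_id: str) -> str:
    stem = sample_id.replace("/", "_").replace("\\", "_")
    if not stem.lower().endswith(IMAGE_EXTENSIONS):
        stem += ".png"
    return stem


def save_dataset(dataset: LabeledDataset, root: str | Path,
                 config: dict | None = None, seed: int | None = None) -> RunManifest:
    """Write a dataset as 8-bit PNGs in the class-per-subfolder layout.

    Returns a :class:`RunManifest` listing every written file with its sha256.
    Pixels survive the round trip up to 8-bit quantisation (error <= 1/255).
    """
    if len(dataset) == 0:
        raise DatasetError("refusing to save an empty dataset")
    root = Path(root)
    root.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, str] = {}
    for sample in dataset:
        cdir = root / sample.label
        cdir.mkdir(exist_ok=True)
        fname = _safe_filename(sample.id.split("/", 1)[-1] if "/" in sample.id
                               else sample.id)
        path = cdir / fname
        arr = np.clip(np.rint(sample.pixels * 255.0), 0, 255).astype(np.uint8)
        if arr.shape[2] == 1:
            Image.fromarray(arr[:, :, 0], mode="L").save(path)
        else:
            Image.fromarray(arr, mode="RGB").save(path)
        artifacts[f"{sample.label}/{fname}"] = hashlib.sha256(
            path.read_bytes()).hexdigest()
    manifest = RunManifest(config=dict(config or {}), seed=seed,
                           output_path=str(root), artifacts=artifacts)
    manifest.save(root / "manifest.yaml")
    return manifest
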