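"""Dataset and feature-matrix I/O.

Datasets live on disk as one subdirectory per class containing 8-bit
grayscale images (PNG/PGM/TIFF); labels are the directory names and file
ordering is lexicographic so leave-one-out fold identity is reproducible.
Feature matrices are tab-separated text with a self-describing ``# key:
value`` header recording the descriptor and its configuration.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from .evaluate import EvalResult, LabeledFeatures
from .synthetic import LabeledDataset

__all__ = [
    "IMAGE_EXTENSIONS",
    "DatasetLayout",
    "load_image",
    "save_image",
    "load_dataset",
    "save_dataset",
    "save_features",
    "load_features",
    "write_eval_report",
]

IMAGE_EXTENSIONS = (".png", ".pgm", ".tif", ".tiff")


@dataclass(frozen=True)
class DatasetLayout:
    """Where and how to read a class-per-directory image tree.

    ``center_crop`` keeps the central fraction of each side (a generic
    stand-in for a face-region cropping template) before the optional
    ``resize`` to a square working resolution.
    """

    root: Path
    extensions: tuple = IMAGE_EXTENSIONS
    center_crop: float | None = None
    resize: int | None = None

    def __post_init__(self):
        object.__setattr__(self, "root", Path(self.root))
        if self.center_crop is not None and not 0.0 < self.center_crop <= 1.0:
            raise ValueError("center_crop must be a fraction in (0, 1]")


def load_image(path) -> np.ndarray:
    """Read an image as a 2-D uint8 grayscale array."""
    try:
        with Image.open(path) as im:
            return np.asarray(im.convert("L"), dtype=np.uint8)
    except Exception as exc:  # noqa: BLE001 - re-raise with the offending path
        raise OSError(f"could not read image {path}: {exc}") from exc


def save_image(path, array) -> None:
    arr = np.asarray(array)
    if arr.dtype != np.uint8:
        arr = np.clip(np.rint(arr), 0, 255).astype(np.uint8)
    Image.fromarray(arr, mode="L").save(path)


def _preprocess(arr: np.ndarray, layout: DatasetLayout) -> np.ndarray:
    if layout.center_crop is not None and layout.center_crop < 1.0:
        h, w = arr.shape
        ch, cw = max(1, round(h * layout.center_crop)), max(1, round(w * layout.center_crop))
        top, left = (h - ch) // 2, (w - cw) // 2
        arr = arr[top : top + ch, left : left + cw]
    if layout.resize is not None and arr.shape != (layout.resize, layout.resize):
        im = Image.fromarray(arr, mode="L").resize(
            (layout.resize, layout.resize), Image.BILINEAR
        )
        arr = np.asarray(im, dtype=np.uint8)
    return arr


def load_dataset(layout: DatasetLayout | str | Path) -> LabeledDataset:
    """Load a class-per-directory tree into a labeled dataset.

    Class directories and files within them are traversed in lexicographic
    order. A tree with fewer than two class directories, or an empty class
    directory, is a protocol error.
    """
    if not isinstance(layout, DatasetLayout):
        layout = DatasetLayout(root=layout)
    root = layout.root
    if not root.is_dir():
        raise FileNotFoundError(f"dataset root {root} does not exist")
    class_dirs = sorted(d for d in root.iterdir() if d.is_dir())
    if len(class_dirs) < 2:
        raise ValueError(f"need at least 2 class directories under {root}, found {len(class_dirs)}")

    images, labels, ids = [], [], []
    for cdir in class_dirs:
        files = sorted(
            f for f in cdir.iterdir() if f.suffix.lower() in layout.extensions
        )
        if not files:
            raise ValueError(f"class directory {cdir} contains no images")
        for f in files:
            images.append(_preprocess(load_image(f), layout))
            labels.append(cdir.name)
            ids.append(str(f.relative_to(root)))

    manifest_path = root / "manifest.json"
    manifest = {}
    if manifest_path.exists():
        manifest = json.loads(manifest_path.read_text())
    manifest.setdefault("source", str(root))
    manifest["ids"] = ids
    return LabeledDataset(images=images, labels=labels, manifest=manifest)


def save_dataset(dataset: LabeledDataset, root) -> Path:
    """Write a dataset as a class-per-directory PNG tree plus manifest."""
    root = Path(root)
    root.mkdir(parents=True, exist_ok=True)
    counters: dict = {}
    for img, label in zip(dataset.images, dataset.labels):
        cdir = root / f"class_{label}"
        cdir.mkdir(exist_ok=True)
        idx = counters.get(label, 0)
        counters[label] = idx + 1
        save_image(cdir / f"img_{idx:04d}.png", img)
    (root / "manifest.json").write_text(json.dumps(dataset.manifest, indent=1))
    return root


def save_features(path, data: LabeledFeatures, manifest: dict | None = None) -> Path:
    """Write a labeled feature matrix as self-describing TSV."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    header = [f"# {k}: {v}" for k, v in (manifest or {}).items()]
    frame = pd.DataFrame(
        data.features, columns=[f"f{j:05d}" for j in range(data.features.shape[1])]
    )
    frame.insert(0, "label", data.labels)
    frame.insert(0, "id", data.ids)
    with open(path, "w") as fh:
        for line in header:
            fh.write(line + "\n")
        frame.to_csv(fh, sep="\t", index=False)
    return path


def load_features(path) -> tuple[LabeledFeatures, dict]:
    """Read a feature TSV back into a labeled matrix plus its manifest."""
    path = Path(path)
    manifest = {}
    with open(path) as fh:
        pos = fh.tell()
        line = fh.readline()
        while line.startswith("#"):
            key, _, value = line[1:].strip().partition(":")
            manifest[key.strip()] = value.strip()
            pos = fh.tell()
            line = fh.readline()
        fh.seek(pos)
        frame = pd.read_csv(fh, sep="\t")
    data = LabeledFeatures(
        features=frame.iloc[:, 2:].to_numpy(dtype=np.float64),
        labels=frame["label"].to_numpy(),
        ids=frame["id"].astype(str).tolist(),
    )
    return data, manifest


def write_eval_report(result: EvalResult, path) -> Path:
    """Plain-text summary plus machine-readable confusion/prediction tables."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(result.summary() + "\n")
    result.confusion.to_csv(path.with_suffix(path.suffix + ".confusion.tsv"), sep="\t")
    result.predictions.to_csv(
        path.with_suffix(path.suffix + ".predictions.tsv"), sep="\t", index=False
    )
    return path
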