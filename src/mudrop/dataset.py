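"""Dataset formats and the train/validation split protocol.

Supports the pipeline used to build droplet-state datasets: extract frames
from control videos, import LabelMe polygon annotations into 5-class masks,
export scenes to the PASCAL VOC segmentation layout (PNG images, indexed-PNG
masks with a palette, ImageSets lists), and split the index into train and
validation sets by a seeded permutation.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
from matplotlib.path import Path as MplPath
from PIL import Image

from .simulator import SceneFrame
from .states import MASK_PALETTE, STATE_NAMES

TRAIN, VAL = "TRAIN", "VAL"


@dataclass
class DatasetIndex:
    """Paired image/mask paths plus an optional train/val assignment."""

    items: list[tuple[Path, Path]]
    split: dict[int, str] = field(default_factory=dict)

    def subset(self, which: str) -> list[tuple[Path, Path]]:
        return [it for i, it in enumerate(self.items)
                if self.split.get(i) == which]

    def load_arrays(self, which: str | None = None
                    ) -> tuple[np.ndarray, np.ndarray]:
        items = self.items if which is None else self.subset(which)
        images = np.stack([np.asarray(Image.open(p).convert("RGB"))
                           for p, _ in items])
        masks = np.stack([load_mask(m) for _, m in items])
        return images, masks


# ---------------------------------------------------------------------------
# video frames
# ---------------------------------------------------------------------------

def video_to_frames(video: str | Path, out_dir: str | Path,
                    stride: int = 1) -> int:
    """Extract every ``stride``-th frame of a video container to sequentially
    numbered PNGs (zero-padded 6 digits).  Returns the frame count written."""
    video, out_dir = Path(video), Path(out_dir)
    if stride < 1:
        raise ValueError("stride must be >= 1")
    if not video.exists():
        raise FileNotFoundError(f"cannot read video {video}")
    out_dir.mkdir(parents=True, exist_ok=True)
    written = 0
    try:
        it = iio.imiter(video)
    except Exception as exc:  # unreadable container
        raise OSError(f"cannot read video {video}: {exc}") from exc
    for i, frame in enumerate(it):
        if i % stride:
            continue
        arr = np.asarray(frame)
        if arr.ndim == 2:
            arr = np.stack([arr] * 3, axis=-1)
        Image.fromarray(arr[..., :3]).save(out_dir / f"{written:06d}.png")
        written += 1
    return written


# ---------------------------------------------------------------------------
# LabelMe import
# ---------------------------------------------------------------------------

def import_labelme(annotation: dict | str | Path) -> np.ndarray:
    """Rasterize a LabelMe polygon annotation to the fixed class encoding.

    A pixel ``(row, col)`` belongs to a polygon when its center
    ``(x, y) = (col + 0.5, row + 0.5)`` lies inside it; later polygons
    overwrite earlier ones on overlap.  Labels must be one of the four state
    names.
    """
    if not isinstance(annotation, dict):
        annotation = json.loads(Path(annotation).read_text())
    h = int(annotation["imageHeight"])
    w = int(annotation["imageWidth"])
    mask = np.zeros((h, w), dtype=np.uint8)
    cols, rows = np.meshgrid(np.arange(w) + 0.5, np.arange(h) + 0.5)
    centers = np.column_stack([cols.ravel(), rows.ravel()])
    for shape in annotation.get("shapes", []):
        label = shape["label"]
        if label not in STATE_NAMES:
            raise ValueError(
                f"unknown label {label!r}; accepted names: "
                f"{sorted(STATE_NAMES)}")
        pts = np.asarray(shape["points"], dtype=np.float64)
        inside = MplPath(pts).contains_points(centers).reshape(h, w)
        mask[inside] = int(STATE_NAMES[label])
    return mask


# ---------------------------------------------------------------------------
# PASCAL VOC segmentation layout
# ---------------------------------------------------------------------------

def _palette() -> list[int]:
    flat = [0] * 768
    for idx, rgb in MASK_PALETTE.items():
        flat[3 * idx:3 * idx + 3] = rgb
    return flat


def save_mask(mask: np.ndarray, path: str | Path) -> None:
    """Write a label mask as an indexed (palette) PNG."""
    img = Image.fromarray(np.asarray(mask, dtype=np.uint8), mode="P")
    img.putpalette(_palette())
    img.save(path)


def load_mask(path: str | Path) -> np.ndarray:
    img = Image.open(path)
    if img.mode != "P":
        img = img.convert("P")
    return np.asarray(img, dtype=np.uint8)


def export_voc(frames: list[SceneFrame], out_dir: str | Path) -> DatasetIndex:
    """Write frames in the VOC segmentation layout; masks round-trip
    bit-identically."""
    out = Path(out_dir)
    img_dir = out / "JPEGImages"
    seg_dir = out / "SegmentationClass"
    set_dir = out / "ImageSets" / "Segmentation"
    for d in (img_dir, seg_dir, set_dir):
        d.mkdir(parents=True, exist_ok=True)
    items = []
    names = []
    for i, f in enumerate(frames):
        name = f"{i:06d}"
        ip = img_dir / f"{name}.png"
        mp = seg_dir / f"{name}.png"
        Image.fromarray(f.image).save(ip)
        save_mask(f.mask, mp)
        items.append((ip, mp))
        names.append(name)
    (set_dir / "all.txt").write_text("".join(n + "\n" for n in names))
    return DatasetIndex(items=items)


def load_voc(root: str | Path) -> DatasetIndex:
    root = Path(root)
    names = (root / "ImageSets" / "Segmentation" / "all.txt").read_text().split()
    items = [(root / "JPEGImages" / f"{n}.png",
              root / "SegmentationClass" / f"{n}.png") for n in names]
    return DatasetIndex(items=items)


# ---------------------------------------------------------------------------
# split protocol
# ---------------------------------------------------------------------------

def split_dataset(index: DatasetIndex, train_fraction: float = 0.8,
                  seed: int = 0) -> DatasetIndex:
    """Assign items to TRAIN/VAL by a seeded permutation.

    The train count rounds half up (e.g. 4379 items at 0.8 give the
    3503 / 876 partition); the assignment is deterministic per seed.
    """
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must lie in (0, 1)")
    n = len(index.items)
    if n == 0:
        raise ValueError("cannot split an empty index")
    n_train = int(np.floor(train_fraction * n + 0.5))
    perm = np.random.default_rng(seed).permutation(n)
    split = {int(i): (TRAIN if k < n_train else VAL)
             for k, i in enumerate(perm)}
    return DatasetIndex(items=list(index.items), split=split)


def write_split_lists(index: DatasetIndex, out_dir: str | Path) -> None:
    set_dir = Path(out_dir) / "ImageSets" / "Segmentation"
    set_dir.mkdir(parents=True, exist_ok=True)
    for which, fname in ((TRAIN, "train.txt"), (VAL, "val.txt")):
        names = [p.stem for p, _ in index.subset(which)]
        (set_dir / fname).write_text("".join(n + "\n" for n in names))
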