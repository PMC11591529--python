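"""I/O and preprocessing for Doppler echocardiographic frames.

Images are H x W x 3 uint8 RGB arrays; masks are H x W integer label maps
with 0=background, 1=MR jet, 2=left atrium. Masks round-trip losslessly as
paletted PNG with palette index equal to the class label. Polygon
annotations follow the Labelme JSON layout (``shapes[].label``,
``shapes[].points`` with points as (x, y) = (column, row)).

Rasterization uses the even-odd rule evaluated at pixel centers
((col + 0.5, row + 0.5)); points lying exactly on a polygon edge count as
inside. Where MR and LA polygons overlap, the MR label wins — the jet lies
inside the atrium.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image

__all__ = [
    "SEG_CLASS_NAMES",
    "MASK_PALETTE",
    "DatasetSplit",
    "load_image",
    "save_image",
    "load_mask",
    "save_mask",
    "rasterize_labelme",
    "preprocess",
    "stratified_split",
    "save_split",
    "load_split",
]

SEG_CLASS_NAMES = ("background", "MR", "LA")
LABEL_BY_NAME = {"MR": 1, "LA": 2}
# background black, MR red, LA green (annotation convention of the masks)
MASK_PALETTE = [0, 0, 0, 255, 0, 0, 0, 200, 0]
TARGET_SIZE = (800, 600)  # (width, height) after sector crop


# ---------------------------------------------------------------------------
# image / mask files


def load_image(path) -> np.ndarray:
    with Image.open(path) as im:
        return np.asarray(im.convert("RGB"))


def save_image(path, pixels: np.ndarray) -> None:
    Image.fromarray(np.asarray(pixels, dtype=np.uint8), "RGB").save(path)


def save_mask(path, mask: np.ndarray) -> None:
    mask = np.asarray(mask)
    if not np.isin(mask, (0, 1, 2)).all():
        raise ValueError("mask labels must be in {0, 1, 2}")
    im = Image.fromarray(mask.astype(np.uint8), "P")
    im.putpalette(MASK_PALETTE + [0, 0, 0] * 253)
    im.save(path)


def load_mask(path) -> np.ndarray:
    with Image.open(path) as im:
        if im.mode != "P":
            raise ValueError(f"{path}: expected a paletted PNG mask")
        return np.asarray(im).astype(np.int64)


# ---------------------------------------------------------------------------
# polygon rasterization


def _points_in_polygon(px: np.ndarray, py: np.ndarray, poly: np.ndarray) -> np.ndarray:
    """Even-odd containment of points (px, py) in ``poly`` (N x 2, (x, y));
    points exactly on an edge are inside."""
    inside = np.zeros(px.shape, dtype=bool)
    on_edge = np.zeros(px.shape, dtype=bool)
    n = len(poly)
    for i in range(n):
        x1, y1 = poly[i]
        x2, y2 = poly[(i + 1) % n]
        # crossing-number toggle for the horizontal ray towards +x
        cond = (y1 > py) != (y2 > py)
        with np.errstate(divide="ignore", invalid="ignore"):
            xint = x1 + (py - y1) * (x2 - x1) / (y2 - y1)
        inside ^= cond & (px < xint)
        # on-segment test: collinear and within the bounding box
        cross = (x2 - x1) * (py - y1) - (y2 - y1) * (px - x1)
        within = (
            (px >= min(x1, x2) - 1e-9)
            & (px <= max(x1, x2) + 1e-9)
            & (py >= min(y1, y2) - 1e-9)
            & (py <= max(y1, y2) + 1e-9)
        )
        on_edge |= (np.abs(cross) < 1e-9) & within
    return inside | on_edge


def rasterize_labelme(annotation_doc: dict, height: int, width: int) -> np.ndarray:
    """Rasterize a Labelme-style polygon document to a label mask.

    LA polygons paint label 2, MR polygons label 1; MR overrides LA on
    overlap. Unknown labels and degenerate (<3 vertex) polygons are errors.
    """
    shapes = annotation_doc.get("shapes", [])
    mask = np.zeros((height, width), dtype=np.int64)
    cols, rows = np.meshgrid(np.arange(width), np.arange(height))
    px = cols + 0.5
    py = rows + 0.5
    for pass_label in (2, 1):  # LA first, MR on top
        for shape in shapes:
            label = shape["label"]
            if label not in LABEL_BY_NAME:
                raise ValueError(f"unknown annotation label {label!r}")
            if LABEL_BY_NAME[label] != pass_label:
                continue
            poly = np.asarray(shape["points"], dtype=np.float64)
            if poly.ndim != 2 or len(poly) < 3:
                raise ValueError(f"polygon for {label!r} needs at least 3 vertices")
            mask[_points_in_polygon(px, py, poly)] = pass_label
    return mask


# ---------------------------------------------------------------------------
# preprocessing


def preprocess(
    image: np.ndarray,
    roi: tuple[int, int, int, int],
    mask: np.ndarray | None = None,
    out_size: tuple[int, int] = TARGET_SIZE,
):
    """Crop ``roi`` = (row0, col0, height, width) and resample to ``out_size``
    (width, height; default 800 x 600). The paired mask is resampled with
    nearest-neighbour interpolation so no new labels appear."""
    image = np.asarray(image)
    r0, c0, h, w = roi
    H, W = image.shape[:2]
    if r0 < 0 or c0 < 0 or h <= 0 or w <= 0 or r0 + h > H or c0 + w > W:
        raise ValueError(f"roi {roi} outside image bounds {(H, W)}")
    crop = image[r0 : r0 + h, c0 : c0 + w]
    out = np.asarray(
        Image.fromarray(crop.astype(np.uint8)).resize(out_size, Image.BILINEAR)
    )
    if mask is None:
        return out
    if mask.shape[:2] != image.shape[:2]:
        raise ValueError("mask shape must match image shape")
    mcrop = mask[r0 : r0 + h, c0 : c0 + w]
    mout = np.asarray(
        Image.fromarray(mcrop.astype(np.uint8)).resize(out_size, Image.NEAREST)
    ).astype(np.int64)
    return out, mout


# ---------------------------------------------------------------------------
# dataset split


@dataclass
class DatasetSplit:
    train_items: list[str]
    test_items: list[str]
    per_class_counts: dict[str, tuple[int, int]]
    seed: int
    train_fraction: float = 0.8
    by_class: dict[str, tuple[list[str], list[str]]] = field(default_factory=dict)


def stratified_split(
    counts_per_class: dict[str, int],
    train_fraction: float = 0.8,
    seed: int = 0,
    items_per_class: dict[str, list[str]] | None = None,
) -> DatasetSplit:
    """Per-class split with ``n_train = floor(train_fraction * n)``; the
    remainder goes to test. Case assignment is shuffled by ``seed`` and is
    reproducible. Classes may be given as bare counts (ids are synthesized as
    ``<grade>_<index>``) or as explicit id lists via ``items_per_class``."""
    if not (0 < train_fraction < 1):
        raise ValueError("train_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    train: list[str] = []
    test: list[str] = []
    per_class_counts: dict[str, tuple[int, int]] = {}
    by_class: dict[str, tuple[list[str], list[str]]] = {}
    for cls in sorted(counts_per_class):
        n = counts_per_class[cls]
        if n <= 0:
            raise ValueError(f"class {cls!r} has no cases")
        if items_per_class is not None:
            ids = list(items_per_class[cls])
            if len(ids) != n:
                raise ValueError(f"class {cls!r}: {len(ids)} ids for count {n}")
        else:
            ids = [f"{cls}_{i:04d}" for i in range(n)]
        order = rng.permutation(n)
        n_train = int(np.floor(train_fraction * n))
        cls_train = [ids[i] for i in order[:n_train]]
        cls_test = [ids[i] for i in order[n_train:]]
        train.extend(cls_train)
        test.extend(cls_test)
        per_class_counts[cls] = (n_train, n - n_train)
        by_class[cls] = (cls_train, cls_test)
    return DatasetSplit(train, test, per_class_counts, seed, train_fraction, by_class)


def save_split(path, split: DatasetSplit) -> None:
    doc = {
        "train": split.train_items,
        "test": split.test_items,
        "seed": split.seed,
        "train_fraction": split.train_fraction,
        "per_class_counts": {k: list(v) for k, v in split.per_class_counts.items()},
    }
    Path(path).write_text(json.dumps(doc, indent=2))


def load_split(path) -> dict:
    return json.loads(Path(path).read_text())
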