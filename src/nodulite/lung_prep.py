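"""CT preprocessing: MetaImage IO, lung-parenchyma segmentation, and export.

The pipeline mirrors standard LUNA16-style preparation of a slice-based
detector:

1. read a MetaImage (.mhd header + .raw voxels) volume in Hounsfield units;
2. segment the lung parenchyma slice by slice (denoise, window, binarize at
   an air/tissue threshold, drop border-touching background, keep the two
   largest interior low-density components, close and fill);
3. convert world-mm nodule annotations to per-slice pixel boxes;
4. export 8-bit windowed PNG slices and YOLO-format label files, split by
   series at 8:2.

Axis convention: voxel arrays are (z, y, x); ``spacing``/``origin`` follow
the same order.  World mm = origin + index * spacing per axis.  Boxes use
continuous pixel coordinates with the origin at the slice's top-left.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import SimpleITK as sitk
from PIL import Image
from scipy import ndimage
from skimage import measure, morphology

from .boxes_and_losses import BBox

__all__ = [
    "CTVolume", "NoduleAnnotation", "LungMask", "SegmentationConfig",
    "FormatError", "read_mhd", "write_mhd", "read_annotations",
    "segment_parenchyma", "apply_mask", "annotation_to_boxes",
    "export_slices", "read_label_file", "split_series", "prepare_dataset",
    "DEFAULT_WINDOW",
]

logger = logging.getLogger(__name__)

#: HU display window used when exporting slices
DEFAULT_WINDOW = (-1000.0, 400.0)


class FormatError(RuntimeError):
    """Raised for unreadable or unsupported MetaImage input."""


@dataclass
class CTVolume:
    """A CT volume: HU voxels (z, y, x), mm spacing/origin, series id."""

    voxels: np.ndarray
    spacing: tuple[float, float, float]  # (sz, sy, sx)
    origin: tuple[float, float, float]   # (oz, oy, ox) world mm
    series_id: str = ""

    def __post_init__(self):
        if self.voxels.ndim != 3 or min(self.voxels.shape) < 1:
            raise ValueError("voxels must be a non-empty 3-D (z, y, x) array")
        if min(self.spacing) <= 0:
            raise ValueError("spacing entries must be positive")

    def world_to_voxel(self, world_zyx) -> np.ndarray:
        return (np.asarray(world_zyx, float) - np.asarray(self.origin)) \
            / np.asarray(self.spacing)

    def voxel_to_world(self, idx_zyx) -> np.ndarray:
        return np.asarray(self.origin) + np.asarray(idx_zyx, float) \
            * np.asarray(self.spacing)


@dataclass(frozen=True)
class NoduleAnnotation:
    """One nodule: world-mm center and diameter (LUNA16 dialect)."""

    series_id: str
    world_x: float
    world_y: float
    world_z: float
    diameter: float

    def __post_init__(self):
        if not self.diameter > 0:
            raise ValueError("diameter must be positive")


@dataclass
class LungMask:
    """Binary mask aligned with a :class:`CTVolume` (values 0/1)."""

    mask: np.ndarray

    def __post_init__(self):
        self.mask = np.ascontiguousarray(self.mask).astype(np.uint8)
        vals = np.unique(self.mask)
        if not np.all(np.isin(vals, (0, 1))):
            raise ValueError("mask values must be 0/1")


# ---------------------------------------------------------------------------
# MetaImage IO
# ---------------------------------------------------------------------------

_SUPPORTED = {sitk.sitkInt16, sitk.sitkUInt16, sitk.sitkFloat32, sitk.sitkFloat64,
              sitk.sitkUInt8, sitk.sitkInt8, sitk.sitkInt32}


def read_mhd(path) -> CTVolume:
    """Read a .mhd/.raw volume; voxels come back (z, y, x) in HU."""
    path = Path(path)
    try:
        img = sitk.ReadImage(str(path))
    except Exception as exc:  # missing raw file, malformed header
        raise FormatError(f"cannot read MetaImage {path}: {exc}") from exc
    if img.GetPixelID() not in _SUPPORTED:
        raise FormatError(f"unsupported element type {img.GetPixelIDTypeAsString()}")
    vox = sitk.GetArrayFromImage(img).astype(np.float32)
    sx, sy, sz = img.GetSpacing()
    ox, oy, oz = img.GetOrigin()
    return CTVolume(vox, (sz, sy, sx), (oz, oy, ox), series_id=path.stem)


def write_mhd(vol: CTVolume, path) -> None:
    """Write a volume as uncompressed .mhd + .raw (float32)."""
    img = sitk.GetImageFromArray(vol.voxels.astype(np.float32))
    sz, sy, sx = vol.spacing
    oz, oy, ox = vol.origin
    img.SetSpacing((float(sx), float(sy), float(sz)))
    img.SetOrigin((float(ox), float(oy), float(oz)))
    sitk.WriteImage(img, str(path), useCompression=False)


def read_annotations(csv_path) -> list[NoduleAnnotation]:
    """Parse a LUNA16-dialect annotations.csv."""
    import pandas as pd

    df = pd.read_csv(csv_path)
    return [
        NoduleAnnotation(series_id=str(r.seriesuid), world_x=float(r.coordX),
                         world_y=float(r.coordY), world_z=float(r.coordZ),
                         diameter=float(r.diameter_mm))
        for r in df.itertuples()
    ]


# ---------------------------------------------------------------------------
# parenchyma segmentation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SegmentationConfig:
    """Thresholds of the slice-wise parenchyma extraction.

    The -320 HU binarization separates aerated lung from soft tissue; the
    window clips extreme values first.  All values are configurable because
    scanner calibrations differ.
    """

    hu_lo: float = -1000.0
    hu_hi: float = 400.0
    threshold: float = -320.0
    median_size: int = 3
    closing_radius: int = 2
    max_components: int = 2


def segment_parenchyma(vol: CTVolume, cfg: SegmentationConfig | None = None) -> LungMask:
    """Slice-wise lung-field segmentation.

    Per slice: median denoise -> HU clip -> binarize below ``threshold`` ->
    drop low-density components touching the border (outside-body air) ->
    keep the largest <= ``max_components`` interior components -> binary
    closing -> hole filling.  Returns an empty mask (with a warning) when no
    interior component exists on any slice.
    """
    cfg = cfg or SegmentationConfig()
    out = np.zeros(vol.voxels.shape, np.uint8)
    footprint = morphology.disk(cfg.closing_radius)
    any_found = False
    for z in range(vol.voxels.shape[0]):
        sl = vol.voxels[z]
        if cfg.median_size > 1:
            sl = ndimage.median_filter(sl, size=cfg.median_size)
        sl = np.clip(sl, cfg.hu_lo, cfg.hu_hi)
        low = sl < cfg.threshold
        labels = measure.label(low, connectivity=1)
        border = np.unique(np.concatenate([
            labels[0], labels[-1], labels[:, 0], labels[:, -1]]))
        interior = [(lab, cnt) for lab, cnt in
                    zip(*np.unique(labels, return_counts=True))
                    if lab != 0 and lab not in border]
        if not interior:
            continue
        any_found = True
        interior.sort(key=lambda t: -t[1])
        keep = np.isin(labels, [lab for lab, _ in interior[: cfg.max_components]])
        keep = ndimage.binary_closing(keep, structure=footprint)
        keep = ndimage.binary_fill_holes(keep)
        out[z] = keep
    if not any_found:
        warnings.warn("no interior lung component found; returning empty mask",
                      stacklevel=2)
    return LungMask(out)


def apply_mask(vol: CTVolume, mask: LungMask, fill_value: float = -1000.0) -> CTVolume:
    """Zero out (to ``fill_value`` HU) everything outside the mask."""
    if mask.mask.shape != vol.voxels.shape:
        raise ValueError("mask/volume shape mismatch")
    vox = np.where(mask.mask.astype(bool), vol.voxels, np.float32(fill_value))
    return CTVolume(vox.astype(np.float32), vol.spacing, vol.origin, vol.series_id)


# ---------------------------------------------------------------------------
# annotations -> per-slice boxes
# ---------------------------------------------------------------------------


def annotation_to_boxes(ann: NoduleAnnotation, vol: CTVolume) -> list[tuple[int, BBox]]:
    """Expand a world-mm nodule to (slice_index, pixel BBox) pairs.

    The voxel center is (world - origin) / spacing per axis; the nodule
    spans integer slices within ``z_c +- diameter / (2 * sz)``; on each
    spanned slice the box is a ``diameter/sx`` by ``diameter/sy`` rectangle
    centered at the in-plane voxel center (no per-slice chord shrink).
    """
    sz, sy, sx = vol.spacing
    cz, cy, cx = vol.world_to_voxel((ann.world_z, ann.world_y, ann.world_x))
    nz, ny, nx = vol.voxels.shape
    if not (0 <= cz < nz and 0 <= cy < ny and 0 <= cx < nx):
        logger.info("annotation %s at voxel (%.1f, %.1f, %.1f) outside volume "
                    "%s; skipped", ann, cz, cy, cx, vol.series_id)
        return []
    half_z = ann.diameter / (2.0 * sz)
    z_lo = math.ceil(cz - half_z)
    z_hi = math.floor(cz + half_z)
    w, h = ann.diameter / sx, ann.diameter / sy
    return [(z, BBox(cx, cy, w, h)) for z in range(max(z_lo, 0), min(z_hi, nz - 1) + 1)]


# ---------------------------------------------------------------------------
# export
# ---------------------------------------------------------------------------


def hu_window_to_uint8(sl: np.ndarray, window=DEFAULT_WINDOW) -> np.ndarray:
    lo, hi = window
    arr = np.clip((sl - lo) / (hi - lo), 0.0, 1.0)
    return np.round(arr * 255.0).astype(np.uint8)


def export_slices(vol: CTVolume, boxes_by_slice: dict[int, list[BBox]],
                  out_dir, window=DEFAULT_WINDOW,
                  negatives: str = "neighbors") -> list[tuple[Path, Path]]:
    """Write per-slice PNGs + YOLO label files.

    ``boxes_by_slice`` maps slice index -> pixel boxes.  ``negatives``
    selects which box-free slices are exported: ``"none"``, ``"neighbors"``
    (default: one slice either side of a nodule-bearing one) or ``"all"``.
    Labels are ``class cx cy w h`` normalized to [0, 1]; file stems are
    ``{series}_{zindex:04d}``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    nz, ny, nx = vol.voxels.shape
    positive = {z for z, bl in boxes_by_slice.items() if bl}
    if negatives == "all":
        selected = set(range(nz))
    elif negatives == "neighbors":
        selected = set(positive)
        for z in positive:
            selected |= {max(z - 1, 0), min(z + 1, nz - 1)}
    elif negatives == "none":
        selected = set(positive)
    else:
        raise ValueError(f"unknown negatives policy {negatives!r}")

    written = []
    for z in sorted(selected):
        stem = f"{vol.series_id}_{z:04d}"
        img_path = out_dir / f"{stem}.png"
        lbl_path = out_dir / f"{stem}.txt"
        Image.fromarray(hu_window_to_uint8(vol.voxels[z], window)).save(img_path)
        lines = []
        for b in boxes_by_slice.get(z, []):
            lines.append(f"0 {b.cx / nx:.6f} {b.cy / ny:.6f} "
                         f"{b.w / nx:.6f} {b.h / ny:.6f}")
        lbl_path.write_text("\n".join(lines) + ("\n" if lines else ""))
        written.append((img_path, lbl_path))
    return written


def read_label_file(path, img_w: int, img_h: int) -> list[BBox]:
    """Parse a YOLO label file back to pixel boxes."""
    boxes = []
    for line in Path(path).read_text().split("\n"):
        line = line.strip()
        if not line:
            continue
        _cls, cx, cy, w, h = line.split()
        boxes.append(BBox(float(cx) * img_w, float(cy) * img_h,
                          float(w) * img_w, float(h) * img_h))
    return boxes


def split_series(series_ids, ratio: float = 0.8, seed: int = 0):
    """Deterministic series-disjoint train/test split (default 8:2)."""
    ids = sorted(set(series_ids))
    rng = np.random.default_rng(seed)
    rng.shuffle(ids)
    n_train = int(round(ratio * len(ids)))
    return ids[:n_train], ids[n_train:]


def prepare_dataset(volume_dir, annotations_csv, out_dir, seed: int = 0,
                    seg_cfg: SegmentationConfig | None = None,
                    negatives: str = "neighbors", ratio: float = 0.8):
    """Full preprocessing of a directory of .mhd volumes.

    Segments each volume, masks it to the parenchyma, expands annotations to
    per-slice boxes, exports train/ and test/ slice sets split by series.
    Returns ``{"train": [...], "test": [...]}`` of written file pairs.
    """
    volume_dir, out_dir = Path(volume_dir), Path(out_dir)
    anns = read_annotations(annotations_csv)
    by_series: dict[str, list[NoduleAnnotation]] = {}
    for a in anns:
        by_series.setdefault(a.series_id, []).append(a)
    mhds = sorted(volume_dir.glob("*.mhd"))
    train_ids, test_ids = split_series([p.stem for p in mhds], ratio, seed)
    out = {"train": [], "test": []}
    for p in mhds:
        vol = read_mhd(p)
        mask = segment_parenchyma(vol, seg_cfg)
        masked = apply_mask(vol, mask)
        boxes: dict[int, list[BBox]] = {}
        for a in by_series.get(vol.series_id, []):
            for z, b in annotation_to_boxes(a, vol):
                boxes.setdefault(z, []).append(b)
        subset = "train" if vol.series_id in train_ids else "test"
        out[subset] += export_slices(masked, boxes, out_dir / subset,
                                     negatives=negatives)
    return out
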