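"""Voxel-stack construction, normalization, annotation rasterization and split
bookkeeping for multichannel autofluorescence (DOCI) imagery.

A specimen is represented as a voxel tensor ``X ∈ R^{H×W×C}`` obtained by
stacking the co-registered spectral channel images, together with binary
tissue/tumor masks ``Y ∈ {0,1}^{H×W}``.  Pathologist annotations arrive as
polygon vertex rings (an XML dialect documented in :func:`read_annotation_xml`)
and are rasterized with an even-odd interior rule evaluated at pixel centers.

Coordinate conventions: 0-based ``(row, col)`` array indexing; polygon
vertices are ``(x=col, y=row)`` with pixel centers at integer coordinates.
"""

from __future__ import annotations

import warnings
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile
from skimage.transform import resize as _sk_resize


@dataclass
class VoxelStack:
    """H×W×C nonnegative image tensor with channel labels."""

    data: np.ndarray
    channel_ids: list[str]
    specimen_id: str = ""

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError(f"voxel stack must be H×W×C, got shape {self.data.shape}")
        if self.data.shape[2] != len(self.channel_ids):
            raise ValueError(
                f"{self.data.shape[2]} channels but {len(self.channel_ids)} channel_ids"
            )
        if len(set(self.channel_ids)) != len(self.channel_ids):
            raise ValueError("channel_ids must be unique")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("voxel stack contains NaN/Inf")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def n_channels(self) -> int:
        return self.data.shape[2]


@dataclass
class BinaryMask:
    """H×W {0,1} map; ``role`` is 'tissue' or 'tumor'."""

    data: np.ndarray
    role: str = "tissue"

    def __post_init__(self):
        arr = np.asarray(self.data)
        vals = np.unique(arr)
        if not np.all(np.isin(vals, (0, 1))):
            raise ValueError(f"mask values must be in {{0,1}}, found {vals[:5]}")
        self.data = arr.astype(np.uint8)
        if self.role not in ("tissue", "tumor"):
            raise ValueError(f"unknown mask role {self.role!r}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape


@dataclass
class AnnotationSet:
    """Closed polygon rings in image coordinates with one label per ring.

    Each ring is an (n, 2) array of (x=col, y=row) vertices, n >= 3.
    """

    polygons: list[np.ndarray] = field(default_factory=list)
    labels: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.polygons = [np.asarray(p, dtype=float) for p in self.polygons]
        for p in self.polygons:
            if p.ndim != 2 or p.shape[1] != 2 or p.shape[0] < 3:
                raise ValueError("each polygon needs >= 3 (x, y) vertices")
        if not self.labels:
            self.labels = ["tumor"] * len(self.polygons)
        if len(self.labels) != len(self.polygons):
            raise ValueError("one label per polygon required")


def build_voxel_stack(
    channel_images: Sequence[np.ndarray],
    channel_ids: Sequence[str],
    specimen_id: str = "",
) -> VoxelStack:
    """Stack co-registered single-channel images into an H×W×C voxel tensor.

    All images must share the same H×W; channel order follows ``channel_ids``.
    """
    if len(channel_images) != len(channel_ids):
        raise ValueError(
            f"{len(channel_images)} images but {len(channel_ids)} channel ids"
        )
    if len(channel_images) == 0:
        raise ValueError("at least one channel image required")
    ref_shape = np.asarray(channel_images[0]).shape
    for img, cid in zip(channel_images, channel_ids):
        shp = np.asarray(img).shape
        if shp != ref_shape:
            raise ValueError(
                f"channel {cid!r} has shape {shp}, expected {ref_shape}"
            )
    data = np.stack([np.asarray(im, dtype=np.float64) for im in channel_images], axis=-1)
    return VoxelStack(data=data, channel_ids=list(channel_ids), specimen_id=specimen_id)


def minmax_normalize(stack: VoxelStack) -> VoxelStack:
    """Scale the whole tensor to [0, 1] by a single global min-max transform.

    Scaling is joint over all channels so relative spectral contrast between
    channels is preserved.  A constant tensor maps to all zeros.
    """
    x = stack.data
    lo, hi = float(x.min()), float(x.max())
    if hi == lo:
        out = np.zeros_like(x)
    else:
        out = (x - lo) / (hi - lo)
    return VoxelStack(out, list(stack.channel_ids), stack.specimen_id)


def _points_in_polygon(points_xy: np.ndarray, poly: np.ndarray) -> np.ndarray:
    """Vectorized even-odd (ray casting) point-in-polygon test.

    A point on a horizontal ray through an edge is counted by the usual
    half-open rule (y1 <= y < y2), which partitions the plane consistently.
    """
    x, y = points_xy[:, 0], points_xy[:, 1]
    inside = np.zeros(len(points_xy), dtype=bool)
    n = len(poly)
    for i in range(n):
        x1, y1 = poly[i]
        x2, y2 = poly[(i + 1) % n]
        crosses = (y1 <= y) != (y2 <= y)
        if not np.any(crosses):
            continue
        with np.errstate(divide="ignore", invalid="ignore"):
            xint = x1 + (y - y1) * (x2 - x1) / (y2 - y1)
        inside ^= crosses & (x < xint)
    return inside


def rasterize_annotations(ann: AnnotationSet, height: int, width: int) -> BinaryMask:
    """Rasterize polygon annotations to a binary mask.

    A pixel is set iff its center (integer (col, row)) lies inside any polygon
    under the even-odd rule; multiple polygons combine by union.  An empty
    annotation set yields an all-zero mask.
    """
    mask = np.zeros((height, width), dtype=np.uint8)
    if not ann.polygons:
        return BinaryMask(mask, role="tumor")
    cols, rows = np.meshgrid(np.arange(width), np.arange(height))
    pts = np.column_stack([cols.ravel(), rows.ravel()]).astype(float)
    for poly in ann.polygons:
        mask.ravel()[_points_in_polygon(pts, poly)] = 1
    return BinaryMask(mask, role="tumor")


def resize_pair(
    stack: VoxelStack,
    masks: Sequence[BinaryMask],
    target: tuple[int, int] = (256, 256),
) -> tuple[VoxelStack, list[BinaryMask]]:
    """Resize a voxel stack (bilinear) and its masks (nearest-neighbor) jointly.

    Nearest-neighbor keeps masks exactly binary and prevents label bleed at
    tumor edges; applying one geometric target to both preserves pixelwise
    correspondence.
    """
    th, tw = int(target[0]), int(target[1])
    if th < 2 or tw < 2:
        raise ValueError(f"resize target must be at least 2×2, got {target}")
    img = _sk_resize(
        stack.data, (th, tw, stack.n_channels), order=1, mode="edge",
        anti_aliasing=False, preserve_range=True,
    )
    out_masks = []
    for m in masks:
        rm = _sk_resize(
            m.data.astype(float), (th, tw), order=0, mode="edge",
            anti_aliasing=False, preserve_range=True,
        )
        out_masks.append(BinaryMask(rm.astype(np.uint8), role=m.role))
    return VoxelStack(img, list(stack.channel_ids), stack.specimen_id), out_masks


def assign_splits(
    metadata: pd.DataFrame,
    fractions: tuple[float, float, float] = (0.6, 0.2, 0.2),
    seed: int = 0,
) -> pd.Series:
    """Assign train/val/test splits grouped by (patient_id, class).

    All specimens sharing a (patient_id, class) pair receive the same split, so
    no tissue of one diagnostic class from one individual can leak across
    splits; a patient may still appear in two splits with *different*
    pathologies.  Fractions are approximated per class; deterministic given
    the seed.
    """
    required = {"patient_id", "class"}
    if not required.issubset(metadata.columns):
        raise ValueError(f"metadata needs columns {sorted(required)}")
    fr = np.asarray(fractions, dtype=float)
    if fr.min() < 0 or not np.isclose(fr.sum(), 1.0):
        raise ValueError("fractions must be nonnegative and sum to 1")
    split_names = np.array(["train", "val", "test"])
    rng = np.random.default_rng(seed)
    out = pd.Series(index=metadata.index, dtype=object)
    for cls, sub in metadata.groupby("class", sort=True):
        groups = sorted(sub["patient_id"].unique())
        n = len(groups)
        if n < 3:
            warnings.warn(
                f"class {cls!r} has only {n} patient group(s); "
                "collapsing to the available splits"
            )
        perm = rng.permutation(n)
        # largest-remainder apportionment of n groups to the three splits
        raw = fr * n
        counts = np.floor(raw).astype(int)
        rem = raw - counts
        for i in np.argsort(-rem)[: n - counts.sum()]:
            counts[i] += 1
        labels = np.repeat(split_names, counts)
        group_split = {groups[perm[i]]: labels[i] for i in range(n)}
        for idx, row in sub.iterrows():
            out.loc[idx] = group_split[row["patient_id"]]
    out.name = "split"
    return out


# ---------------------------------------------------------------------------
# File I/O: TIFF stacks/masks, annotation XML, metadata tables


def write_stack_tiff(path: str | Path, stack: VoxelStack) -> None:
    """Write a voxel stack as a multi-page float32 TIFF (one page per channel)."""
    arr = np.moveaxis(stack.data.astype(np.float32), -1, 0)  # C,H,W pages
    tifffile.imwrite(
        str(path), arr, photometric="minisblack",
        metadata={"channel_ids": stack.channel_ids},
    )


def read_stack_tiff(
    path: str | Path, channel_ids: Sequence[str] | None = None, specimen_id: str = ""
) -> VoxelStack:
    """Read a multi-page/multi-channel TIFF as a voxel stack.

    16-bit integer data is read losslessly and cast to float.
    """
    arr = tifffile.imread(str(path))
    if arr.ndim == 2:
        arr = arr[None]
    data = np.moveaxis(arr.astype(np.float64), 0, -1)
    if channel_ids is None:
        channel_ids = [f"DOCI-{i + 1}" for i in range(data.shape[2])]
    return VoxelStack(data, list(channel_ids), specimen_id)


def write_mask_tiff(path: str | Path, mask: BinaryMask) -> None:
    tifffile.imwrite(str(path), mask.data.astype(np.uint8))


def read_mask_tiff(path: str | Path, role: str = "tumor") -> BinaryMask:
    arr = tifffile.imread(str(path))
    return BinaryMask((np.asarray(arr) > 0).astype(np.uint8), role=role)


def read_annotation_xml(path: str | Path) -> AnnotationSet:
    """Read polygon annotations from a minimal XML dialect.

    Schema::

        <Annotations>
          <Annotation Label="tumor">
            <Region>
              <Vertex X="12.0" Y="30.5"/>
              ...
            </Region>
          </Annotation>
        </Annotations>

    The reader is permissive: any element containing >= 3 ``Vertex`` children
    with ``X``/``Y`` (case-insensitive) attributes is accepted as a ring.
    """
    tree = ET.parse(str(path))
    polys: list[np.ndarray] = []
    labels: list[str] = []

    def label_of(elem, default="tumor"):
        for key in ("Label", "label", "Name", "name"):
            if key in elem.attrib:
                return elem.attrib[key]
        return default

    for region in tree.iter():
        verts = []
        for child in region:
            tag = child.tag.lower().rsplit("}", 1)[-1]
            if tag == "vertex":
                attrs = {k.lower(): v for k, v in child.attrib.items()}
                if "x" in attrs and "y" in attrs:
                    verts.append((float(attrs["x"]), float(attrs["y"])))
        if len(verts) >= 3:
            polys.append(np.asarray(verts))
            parent_label = label_of(region)
            labels.append(parent_label)
    return AnnotationSet(polygons=polys, labels=labels)


def write_annotation_xml(path: str | Path, ann: AnnotationSet) -> None:
    root = ET.Element("Annotations")
    for poly, label in zip(ann.polygons, ann.labels):
        a = ET.SubElement(root, "Annotation", Label=label)
        r = ET.SubElement(a, "Region")
        for x, y in poly:
            ET.SubElement(r, "Vertex", X=str(float(x)), Y=str(float(y)))
    ET.ElementTree(root).write(str(path), xml_declaration=True)


def write_metadata(path: str | Path, metadata: pd.DataFrame) -> None:
    metadata.to_csv(str(path), index=False)


def read_metadata(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(str(path))
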