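"""Overlapping sliding-window slicing for high-resolution inference.

Tiny insects occupy a vanishing fraction of a 4080x3072 leaf photograph, so
the detector never sees them well at full-frame resolution.  The remedy used
here is sliced inference: decompose the image into fixed-size ``S x S``
windows with overlap ratio ``alpha`` (so adjacent windows share a band of
``S - round(S*(1-alpha))`` pixels), run detection on every window, remap the
per-window boxes to global coordinates and fuse duplicates with class-wise
non-maximum suppression.  Training-time dataset slicing (with empty-tile
discard) uses the same geometry.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .geometry import BBox, Detection

DEFAULT_WINDOW = 640
DEFAULT_OVERLAP = 0.2
DEFAULT_MIN_VISIBILITY = 0.25
DEFAULT_CONF_THRESHOLD = 0.3
DEFAULT_NMS_IOU = 0.5


@dataclass(frozen=True)
class TileSpec:
    """Window size S and overlap ratio alpha; stride = round(S * (1 - alpha))."""

    window_size: int = DEFAULT_WINDOW
    overlap_ratio: float = DEFAULT_OVERLAP

    def __post_init__(self) -> None:
        if self.window_size <= 0:
            raise ValueError("window_size must be positive")
        if not (0.0 <= self.overlap_ratio < 1.0):
            raise ValueError("overlap_ratio must lie in [0, 1)")
        if self.stride < 1:
            raise ValueError("stride must be >= 1 (overlap too close to 1)")

    @property
    def stride(self) -> int:
        return int(round(self.window_size * (1.0 - self.overlap_ratio)))


@dataclass(frozen=True)
class TileGrid:
    """Row-major ordered window origins covering an image."""

    image_width: int
    image_height: int
    origins: tuple[tuple[int, int], ...]
    spec: TileSpec = field(default_factory=TileSpec)

    def __len__(self) -> int:
        return len(self.origins)

    def tile_extent(self, index: int) -> tuple[int, int, int, int]:
        """(x0, y0, x1, y1) of tile ``index``, clipped to the image."""
        x0, y0 = self.origins[index]
        s = self.spec.window_size
        return x0, y0, min(x0 + s, self.image_width), min(y0 + s, self.image_height)


def _axis_origins(dim: int, window: int, stride: int) -> list[int]:
    if dim <= window:
        return [0]
    xs: list[int] = []
    x = 0
    while x + window < dim:
        xs.append(x)
        x += stride
    last = dim - window
    if xs and xs[-1] == last:
        return xs
    xs.append(last)
    return xs


def compute_tiles(image_width: int, image_height: int, spec: TileSpec | None = None) -> TileGrid:
    """Lay out overlapping windows over a ``W x H`` image.

    Interior adjacent windows overlap by exactly ``S - stride`` pixels; the
    final window per axis is clamped so it ends at the image edge (it may
    then overlap its neighbour by more than ``alpha * S``).  An axis shorter
    than ``S`` yields a single origin 0 in that axis.
    """
    spec = spec or TileSpec()
    if image_width <= 0 or image_height <= 0:
        raise ValueError("image dimensions must be positive")
    s, stride = spec.window_size, spec.stride
    cols = _axis_origins(image_width, s, stride)
    rows = _axis_origins(image_height, s, stride)
    origins = tuple((x, y) for y in rows for x in cols)
    return TileGrid(image_width, image_height, origins, spec)


def slice_image(image: np.ndarray, grid: TileGrid) -> list[np.ndarray]:
    """Crop every tile of ``grid`` out of ``image`` (H x W [x C] array)."""
    h, w = image.shape[:2]
    if (w, h) != (grid.image_width, grid.image_height):
        raise ValueError(
            f"image is {w}x{h} but grid was computed for "
            f"{grid.image_width}x{grid.image_height}"
        )
    tiles = []
    for k in range(len(grid)):
        x0, y0, x1, y1 = grid.tile_extent(k)
        tiles.append(image[y0:y1, x0:x1].copy())
    return tiles


def slice_annotations(
    gt: list[Detection],
    grid: TileGrid,
    min_visibility: float = DEFAULT_MIN_VISIBILITY,
    discard_empty: bool = True,
) -> dict[int, list[Detection]]:
    """Distribute ground-truth boxes onto tiles.

    A box enters a tile iff the visible fraction (intersection area over box
    area) is at least ``min_visibility``; entered boxes are clipped to the
    tile and translated to tile-local coordinates.  With ``discard_empty``,
    tiles that receive no box are absent from the mapping — the training-set
    convention that drops targetless sub-images as uninformative.
    """
    if not (0.0 <= min_visibility <= 1.0):
        raise ValueError("min_visibility must lie in [0, 1]")
    out: dict[int, list[Detection]] = {}
    for k in range(len(grid)):
        x0, y0, x1, y1 = grid.tile_extent(k)
        tile_box = BBox(x0, y0, x1, y1)
        kept: list[Detection] = []
        for det in gt:
            inter = det.box.intersection_area(tile_box)
            if det.box.area <= 0 or inter / det.box.area < max(min_visibility, 1e-12):
                continue
            clipped = BBox(
                max(det.box.x_min, x0),
                max(det.box.y_min, y0),
                min(det.box.x_max, x1),
                min(det.box.y_max, y1),
            ).translate(-x0, -y0)
            kept.append(replace(det, box=clipped))
        if kept or not discard_empty:
            out[k] = kept
    return out


def remap_to_global(
    per_tile_detections: dict[int, list[Detection]], grid: TileGrid
) -> list[Detection]:
    """Translate tile-local detections back to image coordinates.

    Confidence and label are untouched; boxes are clipped to image bounds.
    Output order follows tile index then within-tile order, which makes the
    merge step deterministic.
    """
    out: list[Detection] = []
    for k in sorted(per_tile_detections):
        if not (0 <= k < len(grid)):
            raise ValueError(f"tile index {k} out of range for grid of {len(grid)} tiles")
        x0, y0 = grid.origins[k]
        for det in per_tile_detections[k]:
            moved = det.translate(x0, y0)
            clipped = moved.box.clip(grid.image_width, grid.image_height)
            out.append(replace(det, box=clipped))
    return out


def merge_detections(
    dets: list[Detection],
    iou_threshold: float = DEFAULT_NMS_IOU,
    conf_threshold: float = DEFAULT_CONF_THRESHOLD,
) -> list[Detection]:
    """Class-wise greedy NMS over remapped detections.

    Detections below ``conf_threshold`` are dropped first.  Then, per class,
    boxes are taken in order of decreasing confidence (ties broken by lower
    input index) and every not-yet-suppressed same-class box with
    IoU > ``iou_threshold`` against a kept box is removed.  The survivors are
    returned sorted by confidence descending (ties again by input index).
    """
    for name, value in (("iou_threshold", iou_threshold), ("conf_threshold", conf_threshold)):
        if not (0.0 <= value <= 1.0):
            raise ValueError(f"{name} must lie in [0, 1]")
    cand = [(i, d) for i, d in enumerate(dets) if d.confidence >= conf_threshold]
    if not cand:
        return []
    order = sorted(cand, key=lambda t: (-t[1].confidence, t[0]))
    boxes = np.array(
        [[d.box.x_min, d.box.y_min, d.box.x_max, d.box.y_max] for _, d in order]
    )
    areas = (boxes[:, 2] - boxes[:, 0]) * (boxes[:, 3] - boxes[:, 1])
    labels = np.array([d.label for _, d in order])
    alive = np.ones(len(order), dtype=bool)
    kept_idx: list[int] = []
    for i in range(len(order)):
        if not alive[i]:
            continue
        kept_idx.append(i)
        rest = alive.copy()
        rest[: i + 1] = False
        rest &= labels == labels[i]
        if not rest.any():
            continue
        j = np.flatnonzero(rest)
        iw = np.minimum(boxes[j, 2], boxes[i, 2]) - np.maximum(boxes[j, 0], boxes[i, 0])
        ih = np.minimum(boxes[j, 3], boxes[i, 3]) - np.maximum(boxes[j, 1], boxes[i, 1])
        inter = np.clip(iw, 0, None) * np.clip(ih, 0, None)
        iou = inter / (areas[j] + areas[i] - inter)
        alive[j[iou > iou_threshold]] = False
    return [order[i][1] for i in kept_idx]
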