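"""Three-stage refinement of the primary-leaf foreground mask.

A semantic segmenter's raw leaf mask typically carries small spurious
components (noise, fragments of other leaves), a ragged boundary, and small
interior holes.  The optimizer applied here runs, in order:

1. connected-component filtering — drop 8-connected components below an
   area threshold (optionally keep only the largest), retaining the main
   leaf body;
2. morphological opening with a fixed structuring element to smooth the
   contour, followed by an explicit hole fill (opening alone cannot fill
   holes; the fill is a separate step for background regions not connected
   to the image border);
3. bilateral filtering of the mask as a continuous field, re-binarized,
   which smooths the boundary while preserving the leaf/background edge.

The refined mask then gates detections: a detection is counted only if at
least ``min_inside_fraction`` of its box area lies on mask foreground, which
is what excludes insects sitting on non-primary leaves.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import measure, morphology
from skimage.restoration import denoise_bilateral

from .geometry import Detection

DEFAULT_MIN_INSIDE_FRACTION = 0.5


@dataclass
class RefineConfig:
    """Knobs of the three-stage mask optimizer.

    area_threshold < 1 is read as a fraction of the image area (default 1%),
    >= 1 as absolute pixels.  ``opening_radius`` of None scales a reference
    radius of 5 px at 2048-px image width linearly with the actual width.
    """

    area_threshold: float = 0.01
    keep_largest_only: bool = True
    opening_shape: str = "disk"  # or "square"
    opening_radius: int | None = None
    fill_holes: bool = True
    bilateral_spatial_sigma: float = 3.0
    bilateral_range_sigma: float = 0.3
    rebinarize_level: float = 0.5

    def __post_init__(self) -> None:
        if self.area_threshold < 0:
            raise ValueError("area_threshold must be >= 0")
        if self.opening_radius is not None and self.opening_radius < 1:
            raise ValueError("opening_radius must be >= 1")
        if not (0.0 < self.rebinarize_level < 1.0):
            raise ValueError("rebinarize_level must lie in (0, 1)")

    def resolved_radius(self, width: int) -> int:
        if self.opening_radius is not None:
            return self.opening_radius
        return max(1, round(5 * width / 2048))

    def resolved_area_threshold(self, shape: tuple[int, int]) -> float:
        if self.area_threshold < 1.0:
            return self.area_threshold * shape[0] * shape[1]
        return self.area_threshold


def _as_bool(mask: np.ndarray) -> np.ndarray:
    mask = np.asarray(mask)
    if mask.ndim != 2:
        raise ValueError("mask must be 2-D")
    return mask.astype(bool)


def filter_components(mask: np.ndarray, cfg: RefineConfig | None = None) -> np.ndarray:
    """Remove small 8-connected components; optionally keep only the largest.

    Ties for the largest area are broken by the lowest label index, which is
    deterministic for a given mask.  Never adds foreground pixels; an empty
    mask passes through unchanged.
    """
    cfg = cfg or RefineConfig()
    mask = _as_bool(mask)
    labels, n = measure.label(mask, connectivity=2, return_num=True)
    if n == 0:
        return mask.copy()
    areas = np.bincount(labels.ravel())[1:]  # skip background label 0
    thr = cfg.resolved_area_threshold(mask.shape)
    keep = np.flatnonzero(areas >= thr) + 1
    if cfg.keep_largest_only:
        keep = np.array([int(np.argmax(areas)) + 1])
    out = np.isin(labels, keep)
    return out


def smooth_morphology(mask: np.ndarray, cfg: RefineConfig | None = None) -> np.ndarray:
    """Binary opening with the configured element, then optional hole fill."""
    cfg = cfg or RefineConfig()
    mask = _as_bool(mask)
    r = cfg.resolved_radius(mask.shape[1])
    if cfg.opening_shape == "disk":
        footprint = morphology.disk(r)
    elif cfg.opening_shape == "square":
        footprint = morphology.footprint_rectangle((2 * r + 1, 2 * r + 1))
    else:
        raise ValueError(f"unknown opening_shape {cfg.opening_shape!r}")
    if footprint.shape[0] > mask.shape[0] or footprint.shape[1] > mask.shape[1]:
        raise ValueError("structuring element larger than the mask")
    out = morphology.opening(mask, footprint)
    if cfg.fill_holes:
        out = ndimage.binary_fill_holes(out)
    return out


def edge_refine(mask: np.ndarray, cfg: RefineConfig | None = None) -> np.ndarray:
    """Bilateral-filter the mask as a continuous field and re-binarize.

    The spatial sigma controls the smoothing support, the range sigma how
    strongly the leaf/background step edge is preserved.  The output cannot
    extend beyond the dilation of the input by the filter's support radius
    (pixels whose window sees no foreground stay background).
    """
    cfg = cfg or RefineConfig()
    if cfg.bilateral_spatial_sigma <= 0 or cfg.bilateral_range_sigma <= 0:
        raise ValueError("bilateral sigmas must be positive")
    mask = _as_bool(mask)
    field = mask.astype(np.float64)
    smoothed = denoise_bilateral(
        field,
        sigma_color=cfg.bilateral_range_sigma,
        sigma_spatial=cfg.bilateral_spatial_sigma,
        mode="constant",
        cval=0,
    )
    return smoothed > cfg.rebinarize_level


def refine_mask(mask: np.ndarray, cfg: RefineConfig | None = None) -> np.ndarray:
    """Full optimizer: component filtering → opening/fill → edge refinement."""
    cfg = cfg or RefineConfig()
    out = filter_components(mask, cfg)
    out = smooth_morphology(out, cfg)
    out = edge_refine(out, cfg)
    return out


def gate_detections(
    dets: list[Detection],
    mask: np.ndarray,
    min_inside_fraction: float = DEFAULT_MIN_INSIDE_FRACTION,
) -> list[Detection]:
    """Keep detections whose box overlaps the mask foreground sufficiently.

    The kept set contains every detection for which (foreground pixels inside
    the box) / (box area) >= ``min_inside_fraction``.  A fraction of 0 keeps
    everything.  Box coordinates are rounded to the pixel grid.
    """
    if not (0.0 <= min_inside_fraction <= 1.0):
        raise ValueError("min_inside_fraction must lie in [0, 1]")
    mask = _as_bool(mask)
    h, w = mask.shape
    # summed-area table for O(1) box sums
    integral = np.zeros((h + 1, w + 1), dtype=np.int64)
    np.cumsum(np.cumsum(mask, axis=0), axis=1, out=integral[1:, 1:])
    kept = []
    for det in dets:
        b = det.box
        if b.x_max > w or b.y_max > h:
            raise ValueError(f"box {b} exceeds mask extent {w}x{h}")
        x0, y0 = int(round(b.x_min)), int(round(b.y_min))
        x1, y1 = int(round(b.x_max)), int(round(b.y_max))
        x1, y1 = max(x1, x0 + 1), max(y1, y0 + 1)
        inside = integral[y1, x1] - integral[y0, x1] - integral[y1, x0] + integral[y0, x0]
        frac = inside / ((x1 - x0) * (y1 - y0))
        if frac >= min_inside_fraction:
            kept.append(det)
    return kept
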