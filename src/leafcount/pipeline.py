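"""The end-to-end counting pipeline and the evaluation harness.

One image flows through: segment the primary leaf -> refine the mask ->
slice into overlapping windows -> detect per window -> remap to global
coordinates -> fuse duplicates with NMS -> gate by the refined mask ->
count per class.  Gating (rather than blanking image pixels before
detection) is the default mechanism for restricting counts to the primary
leaf: the detector never sees artificial borders, and every raw detection
stays available for inspection.  Blanking is offered as an alternative.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import formats
from .detector import Detector, infer_tiles
from .geometry import Detection
from .mask_refine import (
    DEFAULT_MIN_INSIDE_FRACTION,
    RefineConfig,
    gate_detections,
    refine_mask,
)
from .metrics import (
    CountReport,
    MetricsReport,
    count_rmse,
    detection_report,
    match_detections,
)
from .segmenter import PrecomputedSegmenter, Segmenter
from .synthetic import Scene
from .tiling import (
    DEFAULT_CONF_THRESHOLD,
    DEFAULT_MIN_VISIBILITY,
    DEFAULT_NMS_IOU,
    TileSpec,
    compute_tiles,
    merge_detections,
    remap_to_global,
    slice_annotations,
    slice_image,
)


@dataclass
class PipelineConfig:
    tile_spec: TileSpec = field(default_factory=TileSpec)
    refine: RefineConfig = field(default_factory=RefineConfig)
    refine_enabled: bool = True
    conf_threshold: float = DEFAULT_CONF_THRESHOLD
    nms_iou: float = DEFAULT_NMS_IOU
    gating_fraction: float = DEFAULT_MIN_INSIDE_FRACTION
    gating_enabled: bool = True
    blank_outside: bool = False  # alternative: zero pixels outside the mask
    checkpoint: str | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("conf_threshold", "nms_iou", "gating_fraction"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1]")


@dataclass
class ImageResult:
    mask: np.ndarray
    detections: list[Detection]  # merged, pre-gating
    gated: list[Detection]
    counts: dict[str, int]


def _run_detector(detector, tiles: list[np.ndarray]) -> list[list[Detection]]:
    """Accept a real detector or any callable stub tiles -> detection lists."""
    if isinstance(detector, Detector):
        return infer_tiles(detector, tiles)
    return detector(tiles)


def count_image(
    image: np.ndarray,
    cfg: PipelineConfig,
    segmenter: Segmenter,
    detector,
    class_names: tuple[str, ...] = ("adult", "nymph"),
) -> ImageResult:
    """Segment, slice, detect, merge, gate and count one image."""
    h, w = image.shape[:2]
    try:
        mask = segmenter.predict(image)
    except Exception as exc:
        raise RuntimeError(f"segmentation stage failed: {exc}") from exc
    if cfg.refine_enabled:
        mask = refine_mask(mask, cfg.refine)
    work = image
    if cfg.blank_outside:
        work = image.copy()
        work[~mask] = 0
    grid = compute_tiles(w, h, cfg.tile_spec)
    tiles = slice_image(work, grid)
    # tiles at the image edge can be smaller than S; pad to the window size
    s = cfg.tile_spec.window_size
    padded = []
    for t in tiles:
        if t.shape[0] != s or t.shape[1] != s:
            canvas = np.zeros((s, s) + t.shape[2:], dtype=t.dtype)
            canvas[: t.shape[0], : t.shape[1]] = t
            t = canvas
        padded.append(t)
    try:
        per_tile = _run_detector(detector, padded)
    except Exception as exc:
        raise RuntimeError(f"detection stage failed: {exc}") from exc
    merged = merge_detections(
        remap_to_global(dict(enumerate(per_tile)), grid),
        iou_threshold=cfg.nms_iou,
        conf_threshold=cfg.conf_threshold,
    )
    gated = (
        gate_detections(merged, mask, cfg.gating_fraction) if cfg.gating_enabled else merged
    )
    counts = {c: sum(1 for d in gated if d.label == c) for c in class_names}
    return ImageResult(mask=mask, detections=merged, gated=gated, counts=counts)


# -------------------------------------------------------- dataset assembly


def build_tile_dataset(
    scenes: list[Scene],
    spec: TileSpec | None = None,
    min_visibility: float = DEFAULT_MIN_VISIBILITY,
    discard_empty: bool = True,
) -> list[tuple[np.ndarray, list[Detection]]]:
    """Slice rendered scenes into (tile, local ground truth) training pairs.

    Decoy insects are part of the pixels but not of the ground truth — on
    tiles showing non-primary leaves the detector is explicitly trained to
    fire on decoys' appearance (they look identical to targets), which is
    precisely why mask gating is needed downstream.  Here decoy boxes *are*
    included as targets so the detector learns appearance, not leaf
    membership; membership is the mask's job.
    """
    spec = spec or TileSpec()
    out = []
    for scene in scenes:
        if scene.image is None:
            raise ValueError("build_tile_dataset needs rendered scenes")
        h, w = scene.image.shape[:2]
        grid = compute_tiles(w, h, spec)
        tiles = slice_image(scene.image, grid)
        gt = scene.gt + scene.decoy_gt
        per_tile = slice_annotations(gt, grid, min_visibility, discard_empty)
        s = spec.window_size
        for k, anns in per_tile.items():
            t = tiles[k]
            if t.shape[0] != s or t.shape[1] != s:
                canvas = np.zeros((s, s, 3), dtype=t.dtype)
                canvas[: t.shape[0], : t.shape[1]] = t
                t = canvas
            out.append((t, anns))
    return out


# -------------------------------------------------------------- evaluation


def evaluate_scenes(
    scenes: list[Scene],
    cfg: PipelineConfig,
    detector,
    segmenter: Segmenter | None = None,
    class_names: tuple[str, ...] = ("adult", "nymph"),
) -> tuple[MetricsReport, list[CountReport]]:
    """Full pipeline over synthetic scenes with ground truth.

    When no segmenter is given, the scenes' true masks serve as precomputed
    segmentation (the detector and the counting logic are then evaluated in
    isolation from segmentation quality).
    """
    if segmenter is None:
        segmenter = PrecomputedSegmenter(
            {str(i): s.primary_mask for i, s in enumerate(scenes)}
        )
        keyed = True
    else:
        keyed = isinstance(segmenter, PrecomputedSegmenter)
    matches, counts = [], []
    for i, scene in enumerate(scenes):
        if keyed:
            segmenter.set_key(str(i))
        res = count_image(scene.image, cfg, segmenter, detector, class_names)
        matches.append(match_detections(res.gated, scene.gt, iou_threshold=0.5))
        truth = {c: sum(1 for d in scene.gt if d.label == c) for c in class_names}
        counts.append(CountReport(predicted=res.counts, truth=truth))
    present = [c for c in class_names if any(m.n_gt.get(c, 0) for m in matches)]
    report = detection_report(matches, present, rmse=count_rmse(counts))
    return report, counts


def run_evaluation(
    dataset_dir: str | Path,
    cfg: PipelineConfig,
    detector,
    segmenter: Segmenter | None = None,
    split: str | None = "test",
    class_names: tuple[str, ...] = ("adult", "nymph"),
) -> tuple[MetricsReport, list[CountReport]]:
    """Evaluate a generated on-disk corpus (see synthetic.gen_corpus).

    Reads images, VOC ground truth and (absent an explicit segmenter) the
    stored masks; detection metrics at IoU 0.5 plus counting RMSE.
    """
    root = Path(dataset_dir)
    manifest_path = root / "manifest.json"
    if not manifest_path.exists():
        raise FileNotFoundError(f"no manifest.json under {root} (ground truth required)")
    import json

    manifest = json.loads(manifest_path.read_text())
    records = [
        r for r in manifest["scenes"] if split is None or r["split"] == split
    ]
    if not records:
        raise ValueError(f"no scenes in split {split!r}")
    from PIL import Image

    matches, counts = [], []
    own_segmenter = segmenter is None
    for rec in records:
        image = np.array(Image.open(root / rec["image"]))
        gt = formats.read_voc(root / rec["voc"]).objects
        seg = segmenter
        if own_segmenter:
            seg = PrecomputedSegmenter({rec["stem"]: formats.read_mask_png(root / rec["mask"])})
            seg.set_key(rec["stem"])
        elif isinstance(seg, PrecomputedSegmenter):
            seg.set_key(rec["stem"])
        res = count_image(image, cfg, seg, detector, class_names)
        matches.append(match_detections(res.gated, gt, iou_threshold=0.5))
        truth = {c: sum(1 for d in gt if d.label == c) for c in class_names}
        counts.append(CountReport(predicted=res.counts, truth=truth))
    present = [c for c in class_names if any(m.n_gt.get(c, 0) for m in matches)]
    report = detection_report(matches, present, rmse=count_rmse(counts))
    return report, counts
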