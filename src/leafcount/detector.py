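"""A minimal trainable multi-scale anchor-free detector.

This scaffold exists to *host* the novel blocks (DyCM-C3K2 in the backbone,
MCRFPN as the neck) behind config toggles, not to reproduce a production
detector: the backbone is a plain strided conv stack with three output
levels at strides 8/16/32, the head is anchor-free with center-sampling
assignment, and the losses are binary cross-entropy for objectness/class
plus an IoU loss for boxes.  Ground-truth boxes are routed to pyramid
levels by size using the COCO scale boundaries (sqrt(area) < 32 -> stride 8,
< 96 -> stride 16, else stride 32), matching how small survey targets
concentrate on the finest level.

Everything is seeded: two builds from the same config and seed have
bitwise-identical parameters, and training is deterministic on one thread.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .blocks import DyCMConfig, build_block, build_neck
from .geometry import BBox, CLASSES, Detection
from .nn import SGD, Conv2d, InstanceNorm, Module, Tensor
from .tiling import merge_detections

STRIDES = (8, 16, 32)


@dataclass
class DetectorConfig:
    input_size: int = 640
    backbone_widths: tuple[int, int, int] = (16, 32, 64)
    use_dycm: bool = False
    neck: str = "fpn"  # or "mcrfpn"
    num_classes: int = 2
    class_names: tuple[str, ...] = CLASSES
    conf_threshold: float = 0.3
    nms_iou: float = 0.5
    score_threshold: float = 0.05  # internal decode floor (PR-curve tail)
    max_detections: int = 300  # per-tile cap before NMS
    dycm: DyCMConfig = field(default_factory=lambda: DyCMConfig(groups=4, region_grid=4))
    # training schedule (full-scale defaults; tests use tiny profiles)
    epochs: int = 200
    batch_size: int = 16
    learning_rate: float = 0.01
    momentum: float = 0.937
    weight_decay: float = 0.0005
    max_tiles_per_epoch: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.input_size % 32:
            raise ValueError("input_size must be divisible by 32")
        if self.num_classes < 1:
            raise ValueError("num_classes must be >= 1")
        if len(self.class_names) != self.num_classes:
            raise ValueError("class_names must match num_classes")
        if self.neck not in ("fpn", "mcrfpn"):
            raise ValueError(f"unknown neck {self.neck!r}")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["backbone_widths"] = list(self.backbone_widths)
        d["class_names"] = list(self.class_names)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "DetectorConfig":
        d = dict(d)
        d["backbone_widths"] = tuple(d["backbone_widths"])
        d["class_names"] = tuple(d["class_names"])
        if isinstance(d.get("dycm"), dict):
            d["dycm"] = DyCMConfig(**d["dycm"])
        return cls(**d)


@dataclass
class TrainReport:
    epoch_losses: list[float]
    val_map50: float | None
    seed: int
    config: dict


class _Stage(Module):
    def __init__(self, cin, cout, block_name, dycm_cfg, rng, dtype):
        self.down = Conv2d(cin, cout, 3, stride=2, rng=rng, dtype=dtype)
        self.norm = InstanceNorm(cout, dtype=dtype)
        kw = {"dycm_cfg": dycm_cfg} if block_name == "dycm_c3k2" else {}
        self.block = build_block(block_name, cout, cout, rng, dtype=dtype, **kw)
        self.post = InstanceNorm(cout, dtype=dtype)

    def forward(self, x):
        return self.post(self.block(self.norm(self.down(x)).relu()))


class _Head(Module):
    """Per-level prediction head: objectness + class logits + ltrb offsets."""

    def __init__(self, cin, num_classes, rng, dtype):
        hidden = max(16, cin)
        self.conv = Conv2d(cin, hidden, 3, rng=rng, dtype=dtype)
        self.norm = InstanceNorm(hidden, dtype=dtype)
        self.out = Conv2d(hidden, 1 + num_classes + 4, 3, rng=rng, dtype=dtype)

    def forward(self, x):
        return self.out(self.norm(self.conv(x)).relu())


class Detector(Module):
    def __init__(self, cfg: DetectorConfig, dtype=np.float32):
        rng = np.random.default_rng(cfg.seed)
        self.cfg = cfg
        w3, w4, w5 = cfg.backbone_widths
        block = "dycm_c3k2" if cfg.use_dycm else "c3k2"
        self.stem1 = Conv2d(3, 8, 3, stride=2, rng=rng, dtype=dtype)
        self.stem2 = Conv2d(8, 16, 3, stride=2, rng=rng, dtype=dtype)
        self.stem_norm = InstanceNorm(16, dtype=dtype)
        self.stage3 = _Stage(16, w3, block, cfg.dycm, rng, dtype)
        self.stage4 = _Stage(w3, w4, block, cfg.dycm, rng, dtype)
        self.stage5 = _Stage(w4, w5, block, cfg.dycm, rng, dtype)
        self.neck = build_neck(cfg.neck, (w3, w4, w5), rng,
                               out_channels=(w3, w3, w3) if cfg.neck == "fpn" else None,
                               dtype=dtype)
        neck_out = (w3, w3, w3) if cfg.neck == "fpn" else (w3, w4, w5)
        self.heads = [_Head(c, cfg.num_classes, rng, dtype) for c in neck_out]

    @property
    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def forward(self, x: Tensor) -> list[Tensor]:
        """Raw per-level prediction maps [N, 1+K+4, H_l, W_l]."""
        y = self.stem_norm(self.stem2(self.stem1(x).relu())).relu()
        c3 = self.stage3(y)
        c4 = self.stage4(c3)
        c5 = self.stage5(c4)
        feats = self.neck([c3, c4, c5])
        return [head(f) for head, f in zip(self.heads, feats)]


def build_detector(cfg: DetectorConfig) -> Detector:
    return Detector(cfg)


# ----------------------------------------------------------- preprocessing


def _to_input(tiles: list[np.ndarray], size: int) -> np.ndarray:
    batch = np.empty((len(tiles), 3, size, size), dtype=np.float32)
    for i, t in enumerate(tiles):
        if t.shape[0] != size or t.shape[1] != size:
            raise ValueError(f"tile {i} is {t.shape[1]}x{t.shape[0]}, expected {size}x{size}")
        batch[i] = np.moveaxis(t.astype(np.float32) / 255.0 - 0.5, -1, 0)
    return batch


# -------------------------------------------------------------- assignment


def _level_for(box: BBox) -> int:
    s = np.sqrt(box.area)
    if s < 32:
        return 0
    if s < 96:
        return 1
    return 2


def assign_targets(
    gts: list[Detection], cfg: DetectorConfig
) -> list[dict[str, np.ndarray]]:
    """Center-sampling assignment of ground truth to pyramid cells.

    Per level, a cell is positive for a box routed to that level when the
    cell center lies inside the box and within 1.5 strides of the box
    center; a box that captures no cell claims the cell containing its
    center.  Cells contested by several boxes go to the smallest box.
    Returns, per level: obj [H,W], cls [K,H,W], ltrb [4,H,W] targets.
    """
    size = cfg.input_size
    out = []
    for stride in STRIDES:
        g = size // stride
        out.append(
            {
                "obj": np.zeros((g, g), dtype=np.float32),
                "cls": np.zeros((cfg.num_classes, g, g), dtype=np.float32),
                "ltrb": np.zeros((4, g, g), dtype=np.float32),
                "owner_area": np.full((g, g), np.inf, dtype=np.float32),
            }
        )
    name_to_idx = {n: i for i, n in enumerate(cfg.class_names)}
    for det in gts:
        lvl = _level_for(det.box)
        stride = STRIDES[lvl]
        tgt = out[lvl]
        g = size // stride
        b = det.box
        cx, cy = (b.x_min + b.x_max) / 2.0, (b.y_min + b.y_max) / 2.0
        radius = 1.5 * stride
        j0 = max(0, int(b.x_min // stride))
        j1 = min(g - 1, int((b.x_max - 1e-6) // stride))
        i0 = max(0, int(b.y_min // stride))
        i1 = min(g - 1, int((b.y_max - 1e-6) // stride))
        cells = []
        for i in range(i0, i1 + 1):
            for j in range(j0, j1 + 1):
                px, py = (j + 0.5) * stride, (i + 0.5) * stride
                if not (b.x_min <= px < b.x_max and b.y_min <= py < b.y_max):
                    continue
                if abs(px - cx) <= radius and abs(py - cy) <= radius:
                    cells.append((i, j))
        if not cells:
            j = min(g - 1, max(0, int(cx // stride)))
            i = min(g - 1, max(0, int(cy // stride)))
            cells = [(i, j)]
        for i, j in cells:
            if det.box.area >= tgt["owner_area"][i, j]:
                continue
            tgt["owner_area"][i, j] = det.box.area
            px, py = (j + 0.5) * stride, (i + 0.5) * stride
            tgt["obj"][i, j] = 1.0
            tgt["cls"][:, i, j] = 0.0
            tgt["cls"][name_to_idx[det.label], i, j] = 1.0
            tgt["ltrb"][:, i, j] = (
                max(px - b.x_min, 1.0),
                max(py - b.y_min, 1.0),
                max(b.x_max - px, 1.0),
                max(b.y_max - py, 1.0),
            )
    return out


# -------------------------------------------------------------------- loss


def _tmin(a: Tensor, b: np.ndarray) -> Tensor:
    # min(a, b) = a - relu(a - b), differentiable through a
    return a - (a - b).relu()


def detection_loss(preds: list[Tensor], targets: list[list[dict]], cfg: DetectorConfig) -> Tensor:
    """Balanced BCE on objectness, BCE on class scores, IoU loss on boxes.

    Objectness BCE is weighted so positives and negatives contribute
    equally in aggregate (tiny targets leave cells overwhelmingly
    negative); class and box terms average over positive cells only.
    """
    k = cfg.num_classes
    total = None
    n_pos_total = 0.0
    terms = []
    for lvl, pred in enumerate(preds):
        n = pred.shape[0]
        stride = STRIDES[lvl]
        obj_t = np.stack([targets[b][lvl]["obj"] for b in range(n)])
        cls_t = np.stack([targets[b][lvl]["cls"] for b in range(n)])
        ltrb_t = np.stack([targets[b][lvl]["ltrb"] for b in range(n)])
        pos = obj_t > 0.5
        n_pos = float(pos.sum())
        n_neg = float(pos.size - n_pos)
        obj_logits = pred[:, 0]
        w = np.where(pos, (n_neg / max(n_pos, 1.0)), 1.0).astype(pred.data.dtype)
        w /= w.sum()
        obj_loss = (obj_logits.bce_with_logits(obj_t) * w).sum()
        terms.append(obj_loss)
        if n_pos == 0:
            continue
        n_pos_total += n_pos
        posw = (pos.astype(pred.data.dtype) / n_pos)[:, None]
        cls_logits = pred[:, 1 : 1 + k]
        cls_loss = (cls_logits.bce_with_logits(cls_t) * posw).sum()
        ltrb_pred = pred[:, 1 + k :].softplus() * float(stride)
        # IoU of two boxes sharing the anchor point, from ltrb distances
        inter_w = _tmin(ltrb_pred[:, 0], ltrb_t[:, 0]) + _tmin(ltrb_pred[:, 2], ltrb_t[:, 2])
        inter_h = _tmin(ltrb_pred[:, 1], ltrb_t[:, 1]) + _tmin(ltrb_pred[:, 3], ltrb_t[:, 3])
        inter = inter_w * inter_h
        area_p = (ltrb_pred[:, 0] + ltrb_pred[:, 2]) * (ltrb_pred[:, 1] + ltrb_pred[:, 3])
        area_t = (ltrb_t[:, 0] + ltrb_t[:, 2]) * (ltrb_t[:, 1] + ltrb_t[:, 3])
        iou = inter / (area_p + area_t - inter + 1e-9)
        box_loss = ((1.0 - iou) * posw[:, 0]).sum()
        terms.append(cls_loss + 2.0 * box_loss)
    for t in terms:
        total = t if total is None else total + t
    return total


# ---------------------------------------------------------------- training


def train(
    detector: Detector,
    dataset: list[tuple[np.ndarray, list[Detection]]],
    cfg: DetectorConfig | None = None,
    val_dataset: list[tuple[np.ndarray, list[Detection]]] | None = None,
) -> TrainReport:
    """SGD training on sliced tiles; returns the loss trajectory.

    ``dataset`` pairs each fixed-size tile image with its tile-local ground
    truth.  The epoch schedule, batch size, optimizer constants and the
    shuffling are all taken from the config and seeded; when
    ``max_tiles_per_epoch`` is set, each epoch visits a fresh seeded
    subsample (a desk-scale schedule for large corpora).
    """
    cfg = cfg or detector.cfg
    if not dataset:
        raise ValueError("training dataset is empty")
    rng = np.random.default_rng(cfg.seed + 1)
    opt = SGD(detector.parameters(), cfg.learning_rate, cfg.momentum, cfg.weight_decay)
    targets_cache = [assign_targets(gt, cfg) for _, gt in dataset]
    losses = []
    for _epoch in range(cfg.epochs):
        order = rng.permutation(len(dataset))
        if cfg.max_tiles_per_epoch is not None:
            order = order[: cfg.max_tiles_per_epoch]
        epoch_loss, n_batches = 0.0, 0
        for start in range(0, len(order), cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            batch = _to_input([dataset[i][0] for i in idx], cfg.input_size)
            tgts = [targets_cache[i] for i in idx]
            preds = detector(Tensor(batch))
            loss = detection_loss(preds, tgts, cfg)
            opt.zero_grad()
            loss.backward()
            opt.step()
            epoch_loss += float(loss.data)
            n_batches += 1
        losses.append(epoch_loss / max(n_batches, 1))
    val_map = None
    if val_dataset is not None:
        from .metrics import ZeroGroundTruthError, match_detections, mean_average_precision

        matches = []
        for tile, gt in val_dataset:
            dets = infer_tiles(detector, [tile])[0]
            matches.append(match_detections(dets, gt, iou_threshold=0.5))
        present = [
            lab for lab in cfg.class_names if any(m.n_gt.get(lab, 0) for m in matches)
        ]
        try:
            val_map = mean_average_precision(matches, present) if present else None
        except ZeroGroundTruthError:  # pragma: no cover - guarded by `present`
            val_map = None
    return TrainReport(
        epoch_losses=losses, val_map50=val_map, seed=cfg.seed, config=cfg.to_dict()
    )


# --------------------------------------------------------------- inference


def decode_predictions(
    preds: list[Tensor], cfg: DetectorConfig, score_threshold: float | None = None
) -> list[list[Detection]]:
    """Turn raw prediction maps into per-image detection lists (with NMS)."""
    thr = cfg.score_threshold if score_threshold is None else score_threshold
    k = cfg.num_classes
    n = preds[0].shape[0]
    size = cfg.input_size
    per_image: list[list[Detection]] = [[] for _ in range(n)]
    for lvl, pred in enumerate(preds):
        stride = STRIDES[lvl]
        p = pred.data
        g = p.shape[2]
        obj = 1.0 / (1.0 + np.exp(-p[:, 0]))
        cls = 1.0 / (1.0 + np.exp(-p[:, 1 : 1 + k]))
        ltrb = np.log1p(np.exp(-np.abs(p[:, 1 + k :]))) + np.maximum(p[:, 1 + k :], 0.0)
        ltrb *= stride
        scores = obj[:, None] * cls  # [N, K, g, g]
        best_k = scores.argmax(axis=1)
        best_s = scores.max(axis=1)
        ii, jj = np.meshgrid(np.arange(g), np.arange(g), indexing="ij")
        px = (jj + 0.5) * stride
        py = (ii + 0.5) * stride
        for b in range(n):
            sel = np.argwhere(best_s[b] >= thr)
            if len(sel) > cfg.max_detections:
                vals = best_s[b][sel[:, 0], sel[:, 1]]
                sel = sel[np.argsort(-vals, kind="stable")[: cfg.max_detections]]
            for i, j in sel:
                l, t, r, bo = ltrb[b, :, i, j]
                x0 = float(np.clip(px[i, j] - l, 0, size - 1))
                y0 = float(np.clip(py[i, j] - t, 0, size - 1))
                x1 = float(np.clip(px[i, j] + r, x0 + 1e-3, size))
                y1 = float(np.clip(py[i, j] + bo, y0 + 1e-3, size))
                per_image[b].append(
                    Detection(
                        BBox(x0, y0, x1, y1),
                        cfg.class_names[int(best_k[b, i, j])],
                        float(min(best_s[b, i, j], 1.0)),
                    )
                )
    return [
        merge_detections(dets, iou_threshold=cfg.nms_iou, conf_threshold=thr)
        for dets in per_image
    ]


def infer_tiles(
    detector: Detector,
    tiles: list[np.ndarray],
    score_threshold: float | None = None,
    batch_size: int = 8,
) -> list[list[Detection]]:
    """Run the detector on fixed-size tiles; deterministic, order-invariant."""
    cfg = detector.cfg
    out: list[list[Detection]] = []
    for start in range(0, len(tiles), batch_size):
        chunk = tiles[start : start + batch_size]
        preds = detector(Tensor(_to_input(chunk, cfg.input_size)))
        out.extend(decode_predictions(preds, cfg, score_threshold))
    return out


# ------------------------------------------------------------- checkpoints


def save_checkpoint(detector: Detector, path: str | Path) -> None:
    """Write parameters plus a JSON config snapshot into one .npz container."""
    state = detector.state_dict()
    state["__config__"] = np.frombuffer(
        json.dumps(detector.cfg.to_dict()).encode(), dtype=np.uint8
    )
    np.savez(str(path), **state)


def load_checkpoint(path: str | Path) -> Detector:
    with np.load(str(path)) as npz:
        cfg = DetectorConfig.from_dict(
            json.loads(bytes(npz["__config__"].tobytes()).decode())
        )
        det = Detector(cfg)
        det.load_state_dict({k: npz[k] for k in npz.files if k != "__config__"})
    return det
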