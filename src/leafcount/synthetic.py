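"""Seeded synthetic leaf scenes for training and testing without field data.

The generator emulates the *statistical* structure of single-leaf whitefly
survey photographs, not their photometric appearance: one primary leaf
(a smooth harmonically-perturbed ellipse with mild texture) fills most of
the frame; adult and late-instar-nymph targets are shaded ellipses whose
per-image counts follow heavily overdispersed negative binomials (defaults:
adult mean 15.50 / SD 29.15, nymph mean 5.46 / SD 24.31) and whose median
sizes match the survey targets (adults 24x25 px, nymphs 19x19 px); dark
dead-insect-like distractors sit on the leaf but are not ground truth; and
decoy leaves at the image border carry their own insects, recorded
separately, to exercise the segmentation-then-detection rationale (only
insects on the primary leaf should be counted).

Everything is driven by one integer seed and is bitwise reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .geometry import ADULT, NYMPH, BBox, Detection


class PlacementError(RuntimeError):
    """Raised when target placement fails after bounded retries."""


@dataclass
class SceneConfig:
    image_size: tuple[int, int] = (1280, 960)  # (W, H)
    adult_count_mean: float = 15.50
    adult_count_sd: float = 29.15
    nymph_count_mean: float = 5.46
    nymph_count_sd: float = 24.31
    adult_size: tuple[int, int] = (24, 25)  # median (w, h) px
    nymph_size: tuple[int, int] = (19, 19)
    size_jitter: float = 0.2
    n_decoy_leaves: int = 2
    decoy_count_fraction: float = 0.2
    n_distractors: int = 6
    leaf_texture_noise: float = 0.08
    max_overlap_iou: float = 0.3
    placement_retries: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("adult_count_mean", "nymph_count_mean"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("adult_count_sd", "nymph_count_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if min(*self.adult_size, *self.nymph_size) < 3:
            raise ValueError("target sizes must be >= 3 px")

    @classmethod
    def full_scale(cls, **kw) -> "SceneConfig":
        """Preset at the acquisition resolution of the survey imagery."""
        return cls(image_size=(4080, 3072), **kw)


@dataclass
class Scene:
    image: np.ndarray | None  # H x W x 3 uint8, None when rendering skipped
    primary_mask: np.ndarray  # H x W bool
    gt: list[Detection]
    decoy_gt: list[Detection]
    distractors: list[BBox]
    config: SceneConfig = field(repr=False, default=None)


def _nb_count(rng: np.random.Generator, mean: float, sd: float) -> int:
    """Draw one count: negative binomial matched to (mean, SD).

    Falls back to Poisson when the variance is not overdispersed and to the
    rounded mean when SD is 0.  Mean 0 always yields 0.
    """
    if mean <= 0:
        return 0
    var = sd * sd
    if sd == 0:
        return int(round(mean))
    if var <= mean:
        return int(rng.poisson(mean))
    r = mean * mean / (var - mean)
    p = r / (r + mean)
    return int(rng.negative_binomial(r, p))


def _blob_mask(
    shape_hw: tuple[int, int],
    center: tuple[float, float],
    radii: tuple[float, float],
    rng: np.random.Generator,
    wobble: float = 0.06,
) -> np.ndarray:
    """Harmonically perturbed ellipse: smooth irregular leaf-like blob."""
    h, w = shape_hw
    cy, cx = center
    ry, rx = radii
    yy, xx = np.mgrid[0:h, 0:w]
    dx = (xx - cx) / rx
    dy = (yy - cy) / ry
    rho = np.sqrt(dx * dx + dy * dy)
    theta = np.arctan2(dy, dx)
    bound = np.ones_like(rho)
    for k in range(2, 6):
        a = rng.normal(0.0, wobble)
        phi = rng.uniform(0, 2 * math.pi)
        bound += a * np.cos(k * theta + phi)
    return rho < bound


def _smooth_noise(shape_hw: tuple[int, int], rng: np.random.Generator, cell: int = 24) -> np.ndarray:
    """Cheap smooth random field in [-1, 1] for leaf texture."""
    h, w = shape_hw
    ch, cw = max(2, h // cell), max(2, w // cell)
    coarse = rng.normal(0.0, 1.0, (ch, cw))
    up = np.repeat(np.repeat(coarse, cell, axis=0), cell, axis=1)[:h, :w]
    if up.shape[0] < h or up.shape[1] < w:
        up = np.pad(up, ((0, h - up.shape[0]), (0, w - up.shape[1])), mode="edge")
    up = ndimage.uniform_filter(up, size=cell)
    m = np.abs(up).max()
    return up / m if m > 0 else up


def _sample_size(rng: np.random.Generator, median: tuple[int, int], jitter: float) -> tuple[int, int]:
    w = max(3, int(round(median[0] * (1.0 + rng.uniform(-jitter, jitter)))))
    h = max(3, int(round(median[1] * (1.0 + rng.uniform(-jitter, jitter)))))
    return w, h


def _place_boxes(
    rng: np.random.Generator,
    region: np.ndarray,
    counts: dict[str, int],
    sizes: dict[str, tuple[int, int]],
    jitter: float,
    img_wh: tuple[int, int],
    max_iou: float,
    retries: int,
    existing: list[BBox] | None = None,
    forbidden: np.ndarray | None = None,
    param_name: str = "count",
) -> list[Detection]:
    """Rejection-place boxes with centers inside ``region``.

    Overlap between placed boxes is capped at ``max_iou`` (relaxed if the
    scene is too dense for the cap, which overdispersed counts make common);
    a ``forbidden`` mask, when given, must have zero pixels inside any
    placed box (used to keep decoy targets strictly off the primary leaf).
    """
    w_img, h_img = img_wh
    coords = np.argwhere(region)
    if coords.size == 0 and sum(counts.values()) > 0:
        raise PlacementError(f"no room to place targets ({param_name}: empty region)")
    placed: list[BBox] = list(existing or [])
    out: list[Detection] = []
    for label, n in counts.items():
        for _ in range(n):
            bw, bh = _sample_size(rng, sizes[label], jitter)
            box = None
            for attempt in range(2 * retries):
                cy, cx = coords[rng.integers(len(coords))]
                x0, y0 = cx - bw // 2, cy - bh // 2
                if x0 < 0 or y0 < 0 or x0 + bw > w_img or y0 + bh > h_img:
                    continue
                cand = BBox(float(x0), float(y0), float(x0 + bw), float(y0 + bh))
                if forbidden is not None and forbidden[y0 : y0 + bh, x0 : x0 + bw].any():
                    continue
                # first `retries` attempts respect the overlap cap, then it
                # is dropped so that very dense (high-count) scenes remain
                # generable
                if attempt < retries and any(cand.iou(b) > max_iou for b in placed):
                    continue
                box = cand
                break
            if box is None:
                raise PlacementError(
                    f"could not place a {label!r} target after {2 * retries} tries "
                    f"(offending parameter: {param_name})"
                )
            placed.append(box)
            out.append(Detection(box=box, label=label, confidence=1.0))
    return out


def _draw_ellipse(img: np.ndarray, box: BBox, color: tuple[float, float, float], rng) -> None:
    x0, y0 = int(box.x_min), int(box.y_min)
    x1, y1 = int(box.x_max), int(box.y_max)
    h, w = y1 - y0, x1 - x0
    yy, xx = np.mgrid[0:h, 0:w]
    cx, cy = (w - 1) / 2.0, (h - 1) / 2.0
    rho = ((xx - cx) / max(w / 2.0, 1e-6)) ** 2 + ((yy - cy) / max(h / 2.0, 1e-6)) ** 2
    inside = rho < 1.0
    shade = 1.0 - 0.35 * rho  # simple radial shading
    patch = img[y0:y1, x0:x1]
    for c in range(3):
        chan = patch[:, :, c]
        chan[inside] = color[c] * shade[inside]


def gen_scene(cfg: SceneConfig, render: bool = True) -> Scene:
    """Generate one scene; ``render=False`` skips pixel rendering (stats only)."""
    w, h = cfg.image_size
    rng = np.random.default_rng(cfg.seed)

    # --- primary leaf mask
    center = (h * rng.uniform(0.45, 0.55), w * rng.uniform(0.45, 0.55))
    radii = (h * rng.uniform(0.33, 0.40), w * rng.uniform(0.30, 0.38))
    primary = _blob_mask((h, w), center, radii, rng)

    # --- decoy leaves: blobs near the border, clipped away from the primary
    decoy_masks: list[np.ndarray] = []
    for _ in range(cfg.n_decoy_leaves):
        side = rng.integers(4)
        if side == 0:
            c = (rng.uniform(0, 0.12) * h, rng.uniform(0.1, 0.9) * w)
        elif side == 1:
            c = (rng.uniform(0.88, 1.0) * h, rng.uniform(0.1, 0.9) * w)
        elif side == 2:
            c = (rng.uniform(0.1, 0.9) * h, rng.uniform(0, 0.12) * w)
        else:
            c = (rng.uniform(0.1, 0.9) * h, rng.uniform(0.88, 1.0) * w)
        dm = _blob_mask((h, w), c, (h * rng.uniform(0.12, 0.2), w * rng.uniform(0.12, 0.2)), rng)
        dm &= ~primary
        decoy_masks.append(dm)

    # --- primary-leaf targets
    n_adult = _nb_count(rng, cfg.adult_count_mean, cfg.adult_count_sd)
    n_nymph = _nb_count(rng, cfg.nymph_count_mean, cfg.nymph_count_sd)
    sizes = {ADULT: cfg.adult_size, NYMPH: cfg.nymph_size}
    # keep boxes off the outermost mask fringe so centers are robustly inside
    interior = ndimage.binary_erosion(primary, iterations=3) if primary.any() else primary
    if not interior.any():
        interior = primary
    gt = (
        _place_boxes(
            rng,
            interior,
            {ADULT: n_adult, NYMPH: n_nymph},
            sizes,
            cfg.size_jitter,
            (w, h),
            cfg.max_overlap_iou,
            cfg.placement_retries,
            param_name="adult_count_mean/nymph_count_mean",
        )
        if (n_adult + n_nymph) > 0
        else []
    )

    # --- decoy targets on non-primary leaves (zero overlap with primary mask)
    decoy_gt: list[Detection] = []
    if decoy_masks and cfg.decoy_count_fraction > 0:
        n_da = int(rng.poisson(cfg.decoy_count_fraction * n_adult))
        n_dn = int(rng.poisson(cfg.decoy_count_fraction * n_nymph))
        decoy_region = np.zeros_like(primary)
        for dm in decoy_masks:
            decoy_region |= ndimage.binary_erosion(dm, iterations=3)
        # stay clear of the primary leaf by a couple of pixels
        forbidden = ndimage.binary_dilation(primary, iterations=2)
        decoy_region &= ~forbidden
        if decoy_region.any() and (n_da + n_dn) > 0:
            decoy_gt = _place_boxes(
                rng,
                decoy_region,
                {ADULT: n_da, NYMPH: n_dn},
                sizes,
                cfg.size_jitter,
                (w, h),
                cfg.max_overlap_iou,
                cfg.placement_retries,
                existing=[d.box for d in gt],
                forbidden=forbidden,
                param_name="decoy_count_fraction",
            )

    # --- distractors: dark dead-insect-like spots on the leaf, not annotated
    distractors: list[BBox] = []
    if cfg.n_distractors > 0 and interior.any():
        spots = _place_boxes(
            rng,
            interior,
            {ADULT: cfg.n_distractors},
            {ADULT: cfg.adult_size},
            cfg.size_jitter,
            (w, h),
            cfg.max_overlap_iou,
            cfg.placement_retries,
            existing=[d.box for d in gt],
            param_name="n_distractors",
        )
        distractors = [s.box for s in spots]

    image = None
    if render:
        img = np.empty((h, w, 3), dtype=np.float32)
        img[:, :, 0] = 92.0
        img[:, :, 1] = 74.0
        img[:, :, 2] = 52.0  # soil-brown background
        img += 10.0 * _smooth_noise((h, w), rng)[:, :, None]
        for dm in decoy_masks:
            img[dm] = (46.0, 96.0, 50.0)  # darker non-primary leaf
        tex = 1.0 + cfg.leaf_texture_noise * _smooth_noise((h, w), rng)
        leaf_color = np.array([74.0, 152.0, 78.0], dtype=np.float32)
        img[primary] = leaf_color[None, :] * tex[primary, None]
        for box in distractors:
            _draw_ellipse(img, box, (58.0, 44.0, 30.0), rng)
        for det in gt + decoy_gt:
            color = (236.0, 240.0, 228.0) if det.label == ADULT else (214.0, 222.0, 150.0)
            _draw_ellipse(img, det.box, color, rng)
        img += rng.normal(0.0, 2.0, img.shape).astype(np.float32)  # sensor noise
        image = np.clip(img, 0, 255).astype(np.uint8)

    return Scene(
        image=image,
        primary_mask=primary,
        gt=gt,
        decoy_gt=decoy_gt,
        distractors=distractors,
        config=cfg,
    )


def scene_seeds(master_seed: int, n: int) -> list[int]:
    """Derive ``n`` independent per-scene seeds (all below 2**31)."""
    rng = np.random.default_rng(master_seed)
    return [int(s) for s in rng.integers(0, 2**31 - 1, size=n)]


def split_counts(n: int, ratios: tuple[float, ...]) -> list[int]:
    """Largest-remainder apportionment of ``n`` items over split ratios."""
    if any(r <= 0 for r in ratios) or abs(sum(ratios) - 1.0) > 1e-9:
        raise ValueError("ratios must be positive and sum to 1")
    if n < len(ratios):
        raise ValueError("need at least one scene per split")
    exact = [n * r for r in ratios]
    base = [int(math.floor(e)) for e in exact]
    rem = n - sum(base)
    order = sorted(range(len(ratios)), key=lambda i: (-(exact[i] - base[i]), i))
    for i in order[:rem]:
        base[i] += 1
    return base


def gen_split(
    n_scenes: int, ratios: tuple[float, float, float] = (0.8, 0.1, 0.1), seed: int = 0
) -> dict[str, list[int]]:
    """Deterministic train/val/test assignment of scene indices."""
    counts = split_counts(n_scenes, ratios)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n_scenes)
    names = ("train", "val", "test")
    out, i = {}, 0
    for name, c in zip(names, counts):
        out[name] = sorted(int(x) for x in perm[i : i + c])
        i += c
    return out


def gen_mask_fixture(
    kind: str, seed: int = 0, shape: tuple[int, int] = (256, 256)
) -> tuple[np.ndarray, np.ndarray]:
    """(dirty, clean) mask pair with a named corruption for refinement tests.

    kinds: "specks" adds up to 30 off-blob components of <= 10 px;
    "ragged_edge" jitters the boundary by ~1 px of signed-distance noise;
    "holes" punches interior holes of <= 25 px; "multi_component" adds a few
    mid-sized extra blobs.
    """
    rng = np.random.default_rng(seed)
    h, w = shape
    clean = _blob_mask((h, w), (h * 0.5, w * 0.5), (h * 0.36, w * 0.36), rng, wobble=0.04)
    dirty = clean.copy()
    if kind == "specks":
        halo = ndimage.binary_dilation(clean, iterations=4)
        occupied = halo.copy()  # keep specks off the blob and off each other
        bg = np.argwhere(~halo)
        for _ in range(30):
            cy, cx = bg[rng.integers(len(bg))]
            r = int(rng.integers(0, 2))  # 1-px dots or 5-px plus signs
            y0, y1 = max(0, cy - r), min(h, cy + r + 1)
            x0, x1 = max(0, cx - r), min(w, cx + r + 1)
            g0, g1 = max(0, cy - r - 1), min(h, cy + r + 2)
            f0, f1 = max(0, cx - r - 1), min(w, cx + r + 2)
            if occupied[g0:g1, f0:f1].any():
                continue
            yy, xx = np.mgrid[y0:y1, x0:x1]
            speck = (yy - cy) ** 2 + (xx - cx) ** 2 <= r * r
            dirty[y0:y1, x0:x1] |= speck
            occupied[g0:g1, f0:f1] = True
    elif kind == "ragged_edge":
        inside = ndimage.distance_transform_edt(clean)
        outside = ndimage.distance_transform_edt(~clean)
        signed = inside - outside  # > 0 inside the clean blob
        noise = ndimage.gaussian_filter(rng.normal(0, 1, (h, w)), 1.5)
        noise *= 1.0 / max(noise.std(), 1e-9)
        dirty = signed > noise
    elif kind == "holes":
        core = ndimage.binary_erosion(clean, iterations=5)
        inner = np.argwhere(core)
        for _ in range(10):
            cy, cx = inner[rng.integers(len(inner))]
            r = int(rng.integers(1, 3))  # holes of up to ~25 px (r=2 disk: 13 px)
            yy, xx = np.mgrid[max(0, cy - r) : cy + r + 1, max(0, cx - r) : cx + r + 1]
            hole = (yy - cy) ** 2 + (xx - cx) ** 2 <= r * r
            dirty[max(0, cy - r) : cy + r + 1, max(0, cx - r) : cx + r + 1] &= ~hole
    elif kind == "multi_component":
        for _ in range(int(rng.integers(2, 5))):
            cy = h * rng.uniform(0.1, 0.9)
            cx = w * rng.uniform(0.1, 0.9)
            extra = _blob_mask((h, w), (cy, cx), (h * 0.06, w * 0.06), rng, wobble=0.05)
            dirty |= extra & ~ndimage.binary_dilation(clean, iterations=2)
    else:
        raise ValueError(f"unknown fixture kind {kind!r}")
    return dirty, clean


def gen_corpus(
    cfg: SceneConfig,
    n_scenes: int,
    out_dir,
    split_ratios: tuple[float, float, float] = (0.8, 0.1, 0.1),
    render: bool = True,
) -> dict:
    """Write a seeded on-disk dataset: images, masks, VOC XML, Labelme JSON.

    The split into train/val/test follows ``split_ratios`` (largest-remainder
    apportionment of scene counts, seeded shuffle), and a manifest JSON
    records per-scene paths, seeds and split membership.  Returns the
    manifest as a dict.
    """
    import json as _json
    from pathlib import Path as _Path

    from . import formats

    out = _Path(out_dir)
    for sub in ("images", "masks", "voc", "labelme"):
        (out / sub).mkdir(parents=True, exist_ok=True)
    seeds = scene_seeds(cfg.seed, n_scenes)
    split = gen_split(n_scenes, split_ratios, seed=cfg.seed)
    member = {i: name for name, idxs in split.items() for i in idxs}
    w, h = cfg.image_size
    entries = []
    for i, s in enumerate(seeds):
        scene = gen_scene(replace(cfg, seed=s), render=render)
        stem = f"scene_{i:04d}"
        rec = {"index": i, "seed": s, "split": member[i], "stem": stem}
        if render:
            from PIL import Image as _Image

            _Image.fromarray(scene.image).save(out / "images" / f"{stem}.png")
            rec["image"] = f"images/{stem}.png"
        formats.write_mask_png(scene.primary_mask, out / "masks" / f"{stem}.png")
        ann = formats.ImageAnnotation(
            filename=f"{stem}.png", width=w, height=h, objects=scene.gt
        )
        formats.write_voc(ann, out / "voc" / f"{stem}.xml")
        poly = formats.mask_to_polygon(scene.primary_mask)
        shapes = [formats.polygon_shape(formats.PRIMARY_LEAF_LABEL, poly)] if poly else []
        formats.write_labelme(
            out / "labelme" / f"{stem}.json", shapes, (w, h), f"../images/{stem}.png"
        )
        rec.update(
            mask=f"masks/{stem}.png",
            voc=f"voc/{stem}.xml",
            labelme=f"labelme/{stem}.json",
            n_adult=sum(1 for d in scene.gt if d.label == ADULT),
            n_nymph=sum(1 for d in scene.gt if d.label == NYMPH),
            n_decoy=len(scene.decoy_gt),
        )
        entries.append(rec)
    manifest = {
        "seed": cfg.seed,
        "n_scenes": n_scenes,
        "image_size": [w, h],
        "split_ratios": list(split_ratios),
        "splits": split,
        "scenes": entries,
    }
    (out / "manifest.json").write_text(_json.dumps(manifest, indent=2) + "\n")
    return manifest
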