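"""Primary-leaf segmenters behind one pluggable interface.

The counting pipeline only needs *some* source of a foreground-leaf mask.
Production systems use a heavyweight transformer segmenter; that is out of
scope here, so two interchangeable providers are shipped:

* :class:`PrecomputedSegmenter` — serves masks from memory or mask-PNG
  files (e.g. oracle masks of synthetic scenes, or masks exported by an
  external model);
* :class:`TinySegmenter` — a small trainable encoder-decoder operating on a
  4x-downscaled image, sufficient to segment the high-contrast synthetic
  leaf scenes and to exercise the train-seg path end to end.

Both return a full-resolution boolean mask for an H x W x 3 image.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .formats import read_mask_png
from .nn import SGD, Conv2d, Module, Tensor


class Segmenter:
    """Interface: predict(image) -> boolean mask of the same H x W."""

    def predict(self, image: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class PrecomputedSegmenter(Segmenter):
    """Mask provider backed by a dict of arrays or a directory of mask PNGs."""

    def __init__(self, masks: dict[str, np.ndarray] | None = None,
                 mask_dir: str | Path | None = None):
        self.masks = masks or {}
        self.mask_dir = Path(mask_dir) if mask_dir else None
        self._key: str | None = None

    def set_key(self, key: str) -> None:
        self._key = key

    def predict(self, image: np.ndarray) -> np.ndarray:
        if self._key is None:
            raise ValueError("PrecomputedSegmenter needs set_key(<image id>) before predict")
        if self._key in self.masks:
            mask = self.masks[self._key]
        elif self.mask_dir is not None:
            mask = read_mask_png(self.mask_dir / f"{self._key}.png")
        else:
            raise KeyError(f"no mask registered for {self._key!r}")
        if mask.shape != image.shape[:2]:
            raise ValueError(f"mask {mask.shape} does not match image {image.shape[:2]}")
        return mask


def _downscale(image: np.ndarray, factor: int) -> np.ndarray:
    h, w = image.shape[:2]
    hh, ww = h - h % factor, w - w % factor
    x = image[:hh, :ww].astype(np.float32) / 255.0 - 0.5
    x = x.reshape(hh // factor, factor, ww // factor, factor, 3).mean(axis=(1, 3))
    return np.moveaxis(x, -1, 0)  # [3, h', w']


class TinySegmenter(Segmenter, Module):
    """Four-layer fully-convolutional leaf/background classifier.

    Works on a ``downscale``-reduced image; two stride-2 stages bring the
    logit grid to 1/4 of that, and the predicted mask is nearest-upsampled
    back to full resolution.
    """

    def __init__(self, seed: int = 0, downscale: int = 2):
        rng = np.random.default_rng(seed)
        self.downscale = downscale
        self.enc1 = Conv2d(3, 8, 3, stride=2, rng=rng)
        self.enc2 = Conv2d(8, 16, 3, stride=2, rng=rng)
        self.mid = Conv2d(16, 8, 3, rng=rng)
        self.out = Conv2d(8, 1, 3, rng=rng)

    def logits(self, x: Tensor) -> Tensor:
        y = self.enc1(x).relu()
        y = self.enc2(y).relu()
        return self.out(self.mid(y).relu())

    def predict(self, image: np.ndarray) -> np.ndarray:
        x = _downscale(image, self.downscale)[None]
        logit = self.logits(Tensor(x)).data[0, 0]
        coarse = logit > 0.0
        up = self.downscale * 4
        full = np.repeat(np.repeat(coarse, up, axis=0), up, axis=1)
        h, w = image.shape[:2]
        out = np.zeros((h, w), dtype=bool)
        out[: min(h, full.shape[0]), : min(w, full.shape[1])] = full[:h, :w]
        return out

    def fit(
        self,
        images: list[np.ndarray],
        masks: list[np.ndarray],
        epochs: int = 10,
        lr: float = 0.05,
        seed: int = 0,
    ) -> list[float]:
        """BCE training against 8x-downsampled target masks; returns losses."""
        rng = np.random.default_rng(seed)
        opt = SGD(self.parameters(), lr=lr, momentum=0.9)
        f = self.downscale * 4
        losses = []
        for _ in range(epochs):
            order = rng.permutation(len(images))
            total = 0.0
            for i in order:
                x = _downscale(images[i], self.downscale)[None]
                m = masks[i]
                hh, ww = m.shape[0] - m.shape[0] % f, m.shape[1] - m.shape[1] % f
                tgt = (
                    m[:hh, :ww]
                    .reshape(hh // f, f, ww // f, f)
                    .mean(axis=(1, 3))
                    .astype(np.float32)
                )
                logit = self.logits(Tensor(x))[0, 0]
                loss = logit.bce_with_logits(tgt).mean()
                opt.zero_grad()
                loss.backward()
                opt.step()
                total += float(loss.data)
            losses.append(total / len(images))
        return losses
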