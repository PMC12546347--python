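"""Detection network building blocks.

These are the model components this package exists for:

* **CRW** (channel re-weighting): each channel is gated by a learned
  function of its global max- and average-pooled statistics,
  ``X_out = X_in * sigmoid(W2 . relu(W1 . concat(GMP(X), GAP(X))))`` with
  ``W1: 2c -> c/4`` and ``W2: c/4 -> c`` (bias-free, as in the defining
  squeeze-style formulation).
* **SCRF / ACRF**: fusion blocks at the backbone-neck junctions and deep in
  the neck.  SCRF fuses a shallower backbone level (downsampled), the same
  level, and a deeper neck level (upsampled); ACRF additionally folds in a
  shallower level from the end of the neck.  Fusion = channel concat
  followed by CRW and a 1x1 projection.
* **MCRFPN**: the three-level neck assembling SCRF (top-down half) and ACRF
  (bottom-up half).
* **DyCM-Conv** (dynamic context-mixed convolution): per-position kernels
  are generated from a relevance matrix ``R_g = Q_g^T K_g`` between every
  pixel (query) and a pooled ``S_r x S_r`` grid of global region centers
  (keys), linearly projected to one large and one small kernel per group and
  softmax-normalized; the two dynamic branches plus a static depthwise
  branch are merged by elementwise sum.
* **DyCM-C3K2**: a split/bottleneck/concat block whose bottleneck
  convolution is DyCM-Conv, with the cross-stage residual retained.

Resampling conventions (the formulations name ``Up``/``Down`` without
defining them): Down = stride-2 3x3 convolution, Up = 2x nearest-neighbour
interpolation, with a 1x1 projection to a common width on every branch.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import Conv2d, Linear, Module, Tensor, concat, dynamic_mix, unfold

# ------------------------------------------------------------------- CRW


class CRW(Module):
    """Channel re-weighting gate: w = sigmoid(W2 relu(W1 [GMP; GAP]))."""

    def __init__(self, channels: int, rng: np.random.Generator, dtype=np.float32):
        if channels % 4:
            raise ValueError("CRW requires the channel count to be divisible by 4")
        self.channels = channels
        self.fc1 = Linear(2 * channels, channels // 4, bias=False, rng=rng, dtype=dtype)
        self.fc2 = Linear(channels // 4, channels, bias=False, rng=rng, dtype=dtype)

    def gate(self, x: Tensor) -> Tensor:
        if x.shape[1] != self.channels:
            raise ValueError(f"expected {self.channels} channels, got {x.shape[1]}")
        gmp = x.max_spatial()  # [N, C]
        gap = x.mean(axis=(2, 3))  # [N, C]
        z = concat([gmp, gap], axis=1)  # [N, 2C]
        return self.fc2(self.fc1(z).relu()).sigmoid()  # [N, C]

    def forward(self, x: Tensor) -> Tensor:
        n, c = x.shape[0], x.shape[1]
        return x * self.gate(x).reshape(n, c, 1, 1)


# ------------------------------------------------------------ SCRF / ACRF


def _check_ratio(name: str, fine_hw, coarse_hw, factor: int) -> None:
    if fine_hw[0] != coarse_hw[0] * factor or fine_hw[1] != coarse_hw[1] * factor:
        raise ValueError(
            f"{name}: spatial sizes {fine_hw} and {coarse_hw} are not in a "
            f"{factor}x dyadic ratio"
        )


class SCRF(Module):
    """Superficial re-weighted fusion: CRW(concat(Down(P_prev), P_same, Up(P_deep)))."""

    def __init__(
        self,
        c_prev: int,
        c_same: int,
        c_deep: int,
        out_channels: int,
        width: int | None = None,
        rng: np.random.Generator | None = None,
        dtype=np.float32,
    ):
        rng = rng or np.random.default_rng(0)
        w = width or out_channels
        self.down = Conv2d(c_prev, w, 3, stride=2, rng=rng, dtype=dtype)
        self.same = Conv2d(c_same, w, 1, rng=rng, dtype=dtype)
        self.deep = Conv2d(c_deep, w, 1, rng=rng, dtype=dtype)
        self.crw = CRW(3 * w, rng=rng, dtype=dtype)
        self.proj = Conv2d(3 * w, out_channels, 1, rng=rng, dtype=dtype)

    def forward(self, p_prev: Tensor, p_same: Tensor, p_deep: Tensor) -> Tensor:
        _check_ratio("SCRF prev/same", p_prev.shape[2:], p_same.shape[2:], 2)
        _check_ratio("SCRF same/deep", p_same.shape[2:], p_deep.shape[2:], 2)
        parts = [
            self.down(p_prev),
            self.same(p_same),
            self.deep(p_deep).upsample_nearest2(),
        ]
        return self.proj(self.crw(concat(parts, axis=1)))


class ACRF(Module):
    """Advanced re-weighted fusion with a fourth, end-of-neck input.

    CRW(concat(Down(P_prev'), P_same', Up(P_deep'), Down(P_prev''))); the
    deep input may be absent at the coarsest pyramid level (``c_deep=None``),
    where the fusion degrades to three branches.
    """

    def __init__(
        self,
        c_prev: int,
        c_same: int,
        c_deep: int | None,
        c_prev2: int,
        out_channels: int,
        width: int | None = None,
        rng: np.random.Generator | None = None,
        dtype=np.float32,
    ):
        rng = rng or np.random.default_rng(0)
        w = width or out_channels
        self.down1 = Conv2d(c_prev, w, 3, stride=2, rng=rng, dtype=dtype)
        self.same = Conv2d(c_same, w, 1, rng=rng, dtype=dtype)
        self.deep = Conv2d(c_deep, w, 1, rng=rng, dtype=dtype) if c_deep else None
        self.down2 = Conv2d(c_prev2, w, 3, stride=2, rng=rng, dtype=dtype)
        n_branches = 4 if c_deep else 3
        self.crw = CRW(n_branches * w, rng=rng, dtype=dtype)
        self.proj = Conv2d(n_branches * w, out_channels, 1, rng=rng, dtype=dtype)

    def forward(
        self, p_prev: Tensor, p_same: Tensor, p_deep: Tensor | None, p_prev2: Tensor
    ) -> Tensor:
        _check_ratio("ACRF prev/same", p_prev.shape[2:], p_same.shape[2:], 2)
        _check_ratio("ACRF prev2/same", p_prev2.shape[2:], p_same.shape[2:], 2)
        parts = [self.down1(p_prev), self.same(p_same)]
        if self.deep is not None:
            if p_deep is None:
                raise ValueError("ACRF built with a deep branch but p_deep is None")
            _check_ratio("ACRF same/deep", p_same.shape[2:], p_deep.shape[2:], 2)
            parts.append(self.deep(p_deep).upsample_nearest2())
        elif p_deep is not None:
            raise ValueError("ACRF built without a deep branch but p_deep was given")
        parts.append(self.down2(p_prev2))
        return self.proj(self.crw(concat(parts, axis=1)))


class _ReducedSCRF(Module):
    """Two-branch fusion for the finest level (no shallower backbone map)."""

    def __init__(self, c_same, c_deep, out_channels, rng, dtype=np.float32):
        w = out_channels
        self.same = Conv2d(c_same, w, 1, rng=rng, dtype=dtype)
        self.deep = Conv2d(c_deep, w, 1, rng=rng, dtype=dtype)
        self.crw = CRW(2 * w, rng=rng, dtype=dtype)
        self.proj = Conv2d(2 * w, out_channels, 1, rng=rng, dtype=dtype)

    def forward(self, p_same: Tensor, p_deep: Tensor) -> Tensor:
        _check_ratio("SCRF same/deep", p_same.shape[2:], p_deep.shape[2:], 2)
        parts = [self.same(p_same), self.deep(p_deep).upsample_nearest2()]
        return self.proj(self.crw(concat(parts, axis=1)))


class MCRFPN(Module):
    """Three-level neck: SCRF top-down half, then ACRF bottom-up half.

    Inputs are backbone levels (C3, C4, C5) at strides 8/16/32.  Boundary
    levels fuse with reduced variants since they lack a shallower or deeper
    neighbour.  Top-down: P5' = proj(C5); P4' = SCRF(C3, C4, P5');
    P3' = reduced-SCRF(C3, P4').  Bottom-up: P3'' = proj(P3');
    P4'' = ACRF(P3', P4', P5', P3''); P5'' = ACRF(P4', P5', -, P4'')
    (its deep branch is absent at the top of the pyramid).
    """

    def __init__(
        self,
        widths: tuple[int, int, int],
        out_channels: tuple[int, int, int] | None = None,
        rng: np.random.Generator | None = None,
        dtype=np.float32,
    ):
        rng = rng or np.random.default_rng(0)
        c3, c4, c5 = widths
        o3, o4, o5 = out_channels or widths
        self.p5_lateral = Conv2d(c5, o5, 1, rng=rng, dtype=dtype)
        self.scrf4 = SCRF(c3, c4, o5, o4, rng=rng, dtype=dtype)
        self.scrf3 = _ReducedSCRF(c3, o4, o3, rng=rng, dtype=dtype)
        self.p3_out = Conv2d(o3, o3, 1, rng=rng, dtype=dtype)
        self.acrf4 = ACRF(o3, o4, o5, o3, o4, rng=rng, dtype=dtype)
        self.acrf5 = ACRF(o4, o5, None, o4, o5, rng=rng, dtype=dtype)

    def forward(self, feats: list[Tensor]) -> list[Tensor]:
        if len(feats) != 3:
            raise ValueError("MCRFPN expects the three levels [C3, C4, C5]")
        c3, c4, c5 = feats
        p5 = self.p5_lateral(c5)
        p4 = self.scrf4(c3, c4, p5)
        p3 = self.scrf3(c3, p4)
        q3 = self.p3_out(p3)
        q4 = self.acrf4(p3, p4, p5, q3)
        q5 = self.acrf5(p4, p5, None, q4)
        return [q3, q4, q5]


class PlainFPN(Module):
    """Baseline top-down feature pyramid (lateral 1x1 + upsample-add)."""

    def __init__(
        self,
        widths: tuple[int, int, int],
        out_channels: tuple[int, int, int] | None = None,
        rng: np.random.Generator | None = None,
        dtype=np.float32,
    ):
        rng = rng or np.random.default_rng(0)
        c3, c4, c5 = widths
        o3, o4, o5 = out_channels or widths
        if not (o3 == o4 == o5):
            raise ValueError("PlainFPN uses one common output width")
        self.lat3 = Conv2d(c3, o3, 1, rng=rng, dtype=dtype)
        self.lat4 = Conv2d(c4, o4, 1, rng=rng, dtype=dtype)
        self.lat5 = Conv2d(c5, o5, 1, rng=rng, dtype=dtype)
        self.smooth3 = Conv2d(o3, o3, 3, rng=rng, dtype=dtype)
        self.smooth4 = Conv2d(o4, o4, 3, rng=rng, dtype=dtype)

    def forward(self, feats: list[Tensor]) -> list[Tensor]:
        if len(feats) != 3:
            raise ValueError("PlainFPN expects the three levels [C3, C4, C5]")
        c3, c4, c5 = feats
        p5 = self.lat5(c5)
        p4 = self.smooth4(self.lat4(c4) + p5.upsample_nearest2())
        p3 = self.smooth3(self.lat3(c3) + p4.upsample_nearest2())
        return [p3, p4, p5]


# -------------------------------------------------------------- DyCM-Conv


@dataclass(frozen=True)
class DyCMConfig:
    """Hyper-parameters of dynamic context-mixed convolution.

    ``region_grid`` is the pooled key resolution S_r (S_r^2 region centers)
    — distinct from the slicing window size.  ``qk_channels`` of None means
    half the input channels.
    """

    groups: int = 4
    region_grid: int = 4
    k_large: int = 5
    k_small: int = 3
    qk_channels: int | None = None

    def __post_init__(self) -> None:
        if self.k_large % 2 == 0 or self.k_small % 2 == 0:
            raise ValueError("kernel sizes must be odd")
        if not (self.k_large > self.k_small >= 1):
            raise ValueError("need k_large > k_small >= 1")
        if self.region_grid < 1:
            raise ValueError("region_grid must be >= 1")

    def resolve_qk(self, channels: int) -> int:
        qk = self.qk_channels if self.qk_channels is not None else max(self.groups, channels // 2)
        if qk % self.groups:
            raise ValueError(f"qk_channels {qk} not divisible by groups {self.groups}")
        return qk


class DyCMConv(Module):
    """Dynamic context-mixed convolution (shape-preserving, depthwise mixing).

    Per spatial position and channel group, a large and a small kernel are
    generated from that position's relevance to the pooled region centers;
    the two dynamic branches and a static 3x3 depthwise branch are summed.
    """

    def __init__(
        self,
        channels: int,
        cfg: DyCMConfig | None = None,
        rng: np.random.Generator | None = None,
        dtype=np.float32,
    ):
        rng = rng or np.random.default_rng(0)
        cfg = cfg or DyCMConfig()
        if channels % cfg.groups:
            raise ValueError(
                f"channels {channels} not divisible by groups {cfg.groups}"
            )
        self.cfg = cfg
        self.channels = channels
        qk = cfg.resolve_qk(channels)
        # Q/K projections carry no bias so that zero input gives zero relevance
        self.q_proj = Conv2d(channels, qk, 1, bias=False, rng=rng, dtype=dtype)
        self.k_proj = Conv2d(channels, qk, 1, bias=False, rng=rng, dtype=dtype)
        s2 = cfg.region_grid**2
        self.kernel_gen = Linear(s2, cfg.k_large**2 + cfg.k_small**2, rng=rng, dtype=dtype)
        self.dw = Conv2d(channels, channels, 3, groups=channels, rng=rng, dtype=dtype)

    # -- stage 1: relevance between pixels and region centers
    def relevance(self, x: Tensor) -> Tensor:
        """R[n, g, i, j] = <Q-group-g at pixel i, K-group-g at center j>.

        Returns [N, G, HW, S_r^2].
        """
        if x.shape[1] != self.channels:
            raise ValueError(f"expected {self.channels} channels, got {x.shape[1]}")
        cfg = self.cfg
        n, _, h, w = x.shape
        q = self.q_proj(x)  # [N, qk, H, W]
        pooled = x.adaptive_avg_pool((cfg.region_grid, cfg.region_grid))
        k = self.k_proj(pooled)  # [N, qk, S, S]
        qk = q.shape[1]
        gd = qk // cfg.groups
        qg = q.reshape(n, cfg.groups, gd, h * w).transpose(0, 1, 3, 2)  # [N,G,HW,gd]
        kg = k.reshape(n, cfg.groups, gd, cfg.region_grid**2)  # [N,G,gd,S2]
        return qg @ kg  # [N, G, HW, S2]

    # -- stage 2: per-position kernels from relevance rows
    def kernels(self, rel: Tensor) -> tuple[Tensor, Tensor]:
        """Map relevance rows to simplex-valued large/small kernels.

        Each row passes one learnable linear layer whose output is split
        into the k_large^2 and k_small^2 logits; each slice is softmax
        normalized independently.  Returns ([N,G,HW,kl^2], [N,G,HW,ks^2]).
        """
        cfg = self.cfg
        kl2, ks2 = cfg.k_large**2, cfg.k_small**2
        if rel.shape[-1] != cfg.region_grid**2:
            raise ValueError(
                f"relevance rows have length {rel.shape[-1]}, expected {cfg.region_grid ** 2}"
            )
        logits = self.kernel_gen(rel)  # [N, G, HW, kl2+ks2]
        large = logits[:, :, :, :kl2].softmax(axis=-1)
        small = logits[:, :, :, kl2:].softmax(axis=-1)
        return large, small

    def forward(self, x: Tensor) -> Tensor:
        cfg = self.cfg
        n, c, h, w = x.shape
        rel = self.relevance(x)
        k_large, k_small = self.kernels(rel)
        # dynamic branches: unfold once per kernel size, mix per position
        out = None
        for k, ker in ((cfg.k_large, k_large), (cfg.k_small, k_small)):
            cols = unfold(x, k, stride=1, padding=k // 2)  # [N, C, k2, HW]
            kmat = ker.transpose(0, 1, 3, 2)  # [N, G, k2, HW]
            branch = dynamic_mix(cols, kmat, cfg.groups).reshape(n, c, h, w)
            out = branch if out is None else out + branch
        return out + self.dw(x)


class DyCMBottleneck(Module):
    """C3K2-style bottleneck with DyCM-Conv as its convolution + residual."""

    def __init__(self, channels: int, cfg: DyCMConfig, rng, dtype=np.float32):
        self.dycm = DyCMConv(channels, cfg, rng=rng, dtype=dtype)
        self.proj = Conv2d(channels, channels, 1, rng=rng, dtype=dtype)

    def forward(self, x: Tensor) -> Tensor:
        return x + self.proj(self.dycm(x).relu())


class ConvBottleneck(Module):
    """Plain 3x3 bottleneck used by the baseline C3K2 block."""

    def __init__(self, channels: int, rng, dtype=np.float32):
        self.conv1 = Conv2d(channels, channels, 3, rng=rng, dtype=dtype)
        self.conv2 = Conv2d(channels, channels, 3, rng=rng, dtype=dtype)

    def forward(self, x: Tensor) -> Tensor:
        return x + self.conv2(self.conv1(x).relu())


class C3K2(Module):
    """Split -> bottleneck stack -> concat -> 1x1 fuse, optionally DyCM inside."""

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        n_bottlenecks: int = 1,
        use_dycm: bool = False,
        dycm_cfg: DyCMConfig | None = None,
        rng: np.random.Generator | None = None,
        dtype=np.float32,
    ):
        rng = rng or np.random.default_rng(0)
        if out_channels % 2:
            raise ValueError("out_channels must be even (split in half)")
        half = out_channels // 2
        self.pre = Conv2d(in_channels, out_channels, 1, rng=rng, dtype=dtype)
        cfg = dycm_cfg or DyCMConfig()
        if use_dycm:
            self.bottlenecks = [
                DyCMBottleneck(half, cfg, rng=rng, dtype=dtype) for _ in range(n_bottlenecks)
            ]
        else:
            self.bottlenecks = [ConvBottleneck(half, rng=rng, dtype=dtype) for _ in range(n_bottlenecks)]
        self.fuse = Conv2d(out_channels, out_channels, 1, rng=rng, dtype=dtype)
        self.half = half

    def forward(self, x: Tensor) -> Tensor:
        y = self.pre(x)
        a = y[:, : self.half]
        b = y[:, self.half :]
        for bn in self.bottlenecks:
            b = bn(b)
        return self.fuse(concat([a, b], axis=1))


# --------------------------------------------------------------- registry

BLOCK_REGISTRY = {
    "c3k2": lambda cin, cout, rng, **kw: C3K2(cin, cout, use_dycm=False, rng=rng, **kw),
    "dycm_c3k2": lambda cin, cout, rng, **kw: C3K2(cin, cout, use_dycm=True, rng=rng, **kw),
}

NECK_REGISTRY = {
    "fpn": PlainFPN,
    "mcrfpn": MCRFPN,
}


def build_block(name: str, cin: int, cout: int, rng, **kw) -> Module:
    try:
        return BLOCK_REGISTRY[name](cin, cout, rng, **kw)
    except KeyError:
        raise ValueError(f"unknown block {name!r}; known: {sorted(BLOCK_REGISTRY)}") from None


def build_neck(name: str, widths, rng, **kw) -> Module:
    try:
        return NECK_REGISTRY[name](widths, rng=rng, **kw)
    except KeyError:
        raise ValueError(f"unknown neck {name!r}; known: {sorted(NECK_REGISTRY)}") from None
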