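"""Multi-resolution segmentation network for LUAD growth patterns.

The model reads one H&E patch at three magnifications (x10, x5, x2.5,
obtained by area-average downsampling of the x20 patch), encodes each with
a reduced-width residual (bottleneck) encoder, couples the streams with
first-order (squeeze-gate) attention at the first stage and second-order
(Gram-matrix) attention at the last stage, pools global context with a
pyramid pooling module, and decodes to per-pixel probabilities over the
seven classes (non-tumor + six growth patterns).

Ablation variants are reachable through :class:`~anorak.config.NetworkConfig`:
single-stream, multi-stream with plain addition, first-order only, and
second-order only.
"""

from __future__ import annotations

import numpy as np

from . import nn
from .nn import functional as F
from .config import NetworkConfig

__all__ = [
    "build_network", "count_parameters", "make_stream_inputs",
    "first_order_attention", "second_order_attention", "predict_patch",
    "Network",
]


# ---------------------------------------------------------------------------
# stream inputs
# ---------------------------------------------------------------------------

def _area_downsample(img: np.ndarray, factor: int) -> np.ndarray:
    """Block-mean downsampling of an HxW or HxWxC raster."""
    h, w = img.shape[:2]
    if h % factor or w % factor:
        raise ValueError(f"raster {h}x{w} not divisible by factor {factor}")
    x = img.reshape(h // factor, factor, w // factor, factor, -1).astype(np.float64)
    out = x.mean(axis=(1, 3))
    return out.reshape(h // factor, w // factor, *img.shape[2:])


def make_stream_inputs(patch: np.ndarray):
    """Split a x20 patch into the x10 / x5 / x2.5 stream rasters.

    Returns (fine, intermediate, coarse) float arrays whose edges are the
    patch edge divided by 2, 4 and 8; values are per-block means of the
    input, so a 768 patch yields 384/192/96 rasters.
    """
    h, w = patch.shape[:2]
    if h != w:
        raise ValueError(f"patch must be square, got {h}x{w}")
    if h % 8:
        raise ValueError(f"patch size {h} not divisible by 8")
    return tuple(_area_downsample(patch, f) for f in (2, 4, 8))


# ---------------------------------------------------------------------------
# attention operators (functional forms, used by the modules and by tests)
# ---------------------------------------------------------------------------

def first_order_attention(coarse_feats, fine_feats, w1, b1, w2, b2):
    """Channel gating of ``fine_feats`` by globally pooled ``coarse_feats``.

    The coarse features are average-pooled to a vector, passed through a
    two-layer bottleneck (``w1``/``w2``) with a sigmoid output, and the
    resulting per-channel gate in (0,1) rescales the fine features.  Spatial
    size is unchanged.
    """
    coarse_feats = nn.as_tensor(coarse_feats)
    fine_feats = nn.as_tensor(fine_feats)
    w1, w2 = nn.as_tensor(w1), nn.as_tensor(w2)
    if w2.shape[1] != fine_feats.shape[1]:
        raise ValueError(
            f"gate width {w2.shape[1]} does not match fine channels "
            f"{fine_feats.shape[1]}")
    if w1.shape[0] != coarse_feats.shape[1]:
        raise ValueError(
            f"gate input width {w1.shape[0]} does not match coarse channels "
            f"{coarse_feats.shape[1]}")
    z = coarse_feats.mean(axis=(2, 3))                 # (N, C)
    h = F.relu(F.add(F.matmul(z, w1), b1))
    gate = F.sigmoid(F.add(F.matmul(h, w2), b2))       # (N, C_fine)
    n, c = gate.shape
    return F.mul(fine_feats, F.reshape(gate, (n, c, 1, 1)))


def second_order_attention(stream_feats):
    """Gram-matrix channel reweighting across streams.

    For every ordered pair of distinct streams (i, j), the CxC interaction
    of their flattened features, scaled by 1/sqrt(HW) and row-softmaxed,
    reweights the channels of stream j; the fused map is the sum over all
    pairs.  A single stream passes through unchanged.
    """
    feats = [nn.as_tensor(f) for f in stream_feats]
    if len(feats) == 1:
        return feats[0]
    n, c, h, w = feats[0].shape
    for f in feats:
        if f.shape != (n, c, h, w):
            raise ValueError("stream feature maps must share shape after resampling")
    flat = [F.reshape(f, (n, c, h * w)) for f in feats]
    scale = 1.0 / np.sqrt(h * w)
    fused = None
    for i, fi in enumerate(flat):
        for j, fj in enumerate(flat):
            if i == j:
                continue
            gram = F.mul(F.matmul(fi, F.transpose(fj, (0, 2, 1))), scale)
            contrib = F.matmul(F.softmax(gram, axis=-1), fj)
            fused = contrib if fused is None else F.add(fused, contrib)
    return F.reshape(fused, (n, c, h, w))


# ---------------------------------------------------------------------------
# building blocks
# ---------------------------------------------------------------------------

class _Bottleneck(nn.Module):
    """1x1 reduce -> 3x3 -> 1x1 expand residual block."""

    def __init__(self, in_ch, out_ch, stride, rng):
        super().__init__()
        mid = max(1, out_ch // 4)
        self.c1 = nn.Conv2d(in_ch, mid, 1, bias=False, rng=rng)
        self.b1 = nn.BatchNorm2d(mid)
        self.c2 = nn.Conv2d(mid, mid, 3, stride=stride, padding=1, bias=False, rng=rng)
        self.b2 = nn.BatchNorm2d(mid)
        self.c3 = nn.Conv2d(mid, out_ch, 1, bias=False, rng=rng)
        self.b3 = nn.BatchNorm2d(out_ch)
        if stride != 1 or in_ch != out_ch:
            self.proj = nn.Conv2d(in_ch, out_ch, 1, stride=stride, bias=False, rng=rng)
            self.bproj = nn.BatchNorm2d(out_ch)
        else:
            self.proj = None

    def forward(self, x):
        y = F.relu(self.b1(self.c1(x)))
        y = F.relu(self.b2(self.c2(y)))
        y = self.b3(self.c3(y))
        sc = self.bproj(self.proj(x)) if self.proj is not None else x
        return F.relu(F.add(y, sc))


class _Stage(nn.Module):
    def __init__(self, in_ch, out_ch, blocks, rng):
        super().__init__()
        mods = [_Bottleneck(in_ch, out_ch, 2, rng)]
        mods += [_Bottleneck(out_ch, out_ch, 1, rng) for _ in range(blocks - 1)]
        self.body = nn.Sequential(*mods)

    def forward(self, x):
        return self.body(x)


class _StreamEncoder(nn.Module):
    """Reduced-width residual encoder: stem + three stride-2 stages."""

    def __init__(self, widths, rng):
        super().__init__()
        c1, c2, c3 = widths
        self.stem = nn.Sequential(nn.Conv2d(3, c1, 3, padding=1, bias=False, rng=rng),
                                  nn.BatchNorm2d(c1))
        self.stage1 = _Stage(c1, c1, 2, rng)
        self.stage2 = _Stage(c1, c2, 2, rng)
        self.stage3 = _Stage(c2, c3, 2, rng)

    def forward_stage1(self, x):
        return self.stage1(F.relu(self.stem(x)))

    def forward_rest(self, f1):
        return self.stage3(self.stage2(f1))


class _FOGate(nn.Module):
    """Squeeze-gate module: pooled coarse features -> sigmoid channel gate."""

    def __init__(self, c_coarse, c_fine, rng):
        super().__init__()
        hidden = max(1, c_coarse // 4)
        self.fc1 = nn.Linear(c_coarse, hidden, rng=rng)
        self.fc2 = nn.Linear(hidden, c_fine, rng=rng)

    def forward(self, coarse_feats, fine_feats):
        return first_order_attention(coarse_feats, fine_feats,
                                     self.fc1.weight, self.fc1.bias,
                                     self.fc2.weight, self.fc2.bias)


class PyramidPool(nn.Module):
    """Pyramid pooling: multi-bin global context concatenated and re-fused.

    Each bin b: adaptive b x b average pool, 1x1 reduction to C/len(bins)
    channels, ReLU, bilinear upsample back to the feature grid; branches are
    concatenated with the input and fused by a 3x3 convolution back to C.
    """

    def __init__(self, channels, bins, rng):
        super().__init__()
        self.bins = tuple(bins)
        if not self.bins:
            raise ValueError("ppm bins must be non-empty")
        red = max(1, channels // len(self.bins))
        for i in range(len(self.bins)):
            setattr(self, f"red{i}", nn.Conv2d(channels, red, 1, rng=rng))
        self.fuse = nn.Conv2d(channels + red * len(self.bins), channels, 3,
                              padding=1, rng=rng)

    def forward(self, x):
        h, w = x.shape[2], x.shape[3]
        branches = [x]
        for i, b in enumerate(self.bins):
            if b > h or b > w:
                raise ValueError(f"ppm bin {b} larger than feature grid {h}x{w}")
            pooled = F.adaptive_avg_pool2d(x, (b, b))
            reduced = F.relu(getattr(self, f"red{i}")(pooled))
            branches.append(F.upsample_bilinear(reduced, (h, w)))
        return F.relu(self.fuse(F.concat(branches, axis=1)))


class _SOFusion(nn.Module):
    """Per-stream 1x1 projections followed by the Gram-attention core."""

    def __init__(self, channels, n_streams, rng):
        super().__init__()
        for i in range(n_streams):
            setattr(self, f"proj{i}", nn.Conv2d(channels, channels, 1, rng=rng))
        self.n_streams = n_streams

    def forward(self, feats):
        projected = [getattr(self, f"proj{i}")(f) for i, f in enumerate(feats)]
        return second_order_attention(projected)


# ---------------------------------------------------------------------------
# full network
# ---------------------------------------------------------------------------

def _widths(wm: float):
    return tuple(max(1, round(b * wm)) for b in (48, 96, 192))


class Network(nn.Module):
    """Three-stream (or single-stream) attention segmentation network."""

    def __init__(self, config: NetworkConfig, seed: int = 0):
        super().__init__()
        self.config = config
        rng = np.random.default_rng(seed)
        c1, c2, c3 = _widths(config.width_multiplier)
        self.widths = (c1, c2, c3)
        ns = config.n_streams
        for i in range(ns):
            setattr(self, f"enc{i}", _StreamEncoder((c1, c2, c3), rng))
        if config.use_fo:
            # coarse stream gates the fine and intermediate streams
            self.fo_fine = _FOGate(c1, c1, rng)
            self.fo_inter = _FOGate(c1, c1, rng)
        if ns > 1:
            # depth-alignment convolutions for the coarse/intermediate outputs
            self.align_inter = nn.Conv2d(c3, c3, 1, rng=rng)
            self.align_coarse = nn.Conv2d(c3, c3, 1, rng=rng)
        self.ppm = PyramidPool(c3, config.ppm_bins, rng)
        if config.use_so:
            self.so = _SOFusion(c3, ns, rng)
        d1, d2 = c2, c1
        self.dec1 = nn.Sequential(nn.Conv2d(c3, d1, 3, padding=1, bias=False, rng=rng),
                                  nn.BatchNorm2d(d1))
        self.dec2 = nn.Sequential(nn.Conv2d(d1, d2, 3, padding=1, bias=False, rng=rng),
                                  nn.BatchNorm2d(d2))
        self.head = nn.Conv2d(d2, config.n_classes, 1, rng=rng)
        # instrumentation: number of forward invocations per operator
        self.op_calls = {"fo": 0, "so": 0, "ppm": 0}

    # -- helpers -------------------------------------------------------
    @staticmethod
    def _prep(raster: np.ndarray) -> nn.Tensor:
        """HxWx3 (or NxHxWx3) 0-255 raster -> standardized NCHW tensor."""
        x = np.asarray(raster, dtype=np.float32)
        if x.ndim == 3:
            x = x[None]
        x = x.transpose(0, 3, 1, 2) / 255.0
        return nn.Tensor((x - 0.5) / 0.25)

    def forward(self, patches: np.ndarray) -> nn.Tensor:
        """x20 patch batch (N,H,W,3 uint8) -> logits tensor (N,K,H,W)."""
        patches = np.asarray(patches)
        if patches.ndim == 3:
            patches = patches[None]
        n, h, w, _ = patches.shape
        if h % 64:
            raise ValueError(f"patch size {h} must be divisible by 64")
        streams = [np.stack([make_stream_inputs(p)[i] for p in patches])
                   for i in range(3)]                # fine, inter, coarse
        ns = self.config.n_streams
        used = streams[:1] if ns == 1 else streams
        xs = [self._prep(s) for s in used]

        f1 = [getattr(self, f"enc{i}").forward_stage1(x) for i, x in enumerate(xs)]
        if self.config.use_fo:
            self.op_calls["fo"] += 1
            f1[0] = self.fo_fine(f1[2], f1[0])
            f1[1] = self.fo_inter(f1[2], f1[1])
        feats = [getattr(self, f"enc{i}").forward_rest(f) for i, f in enumerate(f1)]

        fine_grid = feats[0].shape[2:]
        if ns > 1:
            feats[1] = F.upsample_bilinear(self.align_inter(feats[1]), fine_grid)
            feats[2] = F.upsample_bilinear(self.align_coarse(feats[2]), fine_grid)
        self.op_calls["ppm"] += 1
        feats[0] = self.ppm(feats[0])

        if self.config.use_so:
            self.op_calls["so"] += 1
            fused = self.so(feats)
        elif ns > 1:
            fused = F.add(F.add(feats[0], feats[1]), feats[2])
        else:
            fused = feats[0]

        y = F.relu(self.dec1(fused))
        y = F.upsample_bilinear(y, (fine_grid[0] * 2, fine_grid[1] * 2))
        y = F.relu(self.dec2(y))
        y = F.upsample_bilinear(y, (fine_grid[0] * 4, fine_grid[1] * 4))
        logits = self.head(y)
        return F.upsample_bilinear(logits, (h, w))


def build_network(config: NetworkConfig, seed: int = 0) -> Network:
    """Construct a network; ablation switches wire or bypass FO/SO/PPM."""
    return Network(config, seed=seed)


def count_parameters(network: nn.Module) -> int:
    """Exact number of trainable scalar parameters."""
    return int(sum(p.data.size for p in network.parameters()))


def predict_patch(network: Network, patch: np.ndarray):
    """Predict one patch: returns (HxWxK probability map, HxW label map).

    Probabilities are a softmax over the class axis (each pixel sums to 1);
    labels are the per-pixel argmax with ties broken toward the lowest class
    index.
    """
    network.eval()
    logits = network.forward(patch)
    probs = F.softmax(logits, axis=1).data[0].transpose(1, 2, 0)
    labels = np.argmax(probs, axis=2).astype(np.uint8)
    return probs, labels
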