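"""The Richardson-Lucy network: an RL-iteration-structured 3D convnet.

The network unrolls the four-step RL update (forward projection, division,
back projection, multiplicative update) into three stages:

* H1 (down-scale estimation): 2x average-pool the normalized input I to
  I_ap; a densely connected 3-layer conv block plus a residual connection
  to I_ap forms FP1 (channel-averaged); DV1 = I_ap / (FP1 + alpha); a
  densely connected 3-layer conv block forms BP1; a 2x transpose-conv
  upsample and channel average give the correction, and E1 = I x correction.
* H2 (original-scale estimation): the same pattern at full resolution with
  2-layer conv blocks and no up/down-sampling; the correction multiplies E1
  to give E2.
* H3 (merge): a densely connected 3-layer conv block on concat(E1, E2),
  channel-averaged, gives the output O.

Every convolution is 3x3x3, stride 1, followed by batch normalization and
softplus. Forward-projector conv layers are initialized with Gaussian
kernels (sd cycling 0.5, 1, 1.5, 2 across output channels), mirroring a
bank of plausible PSFs; all other weights start from a unit Gaussian.

RLN-a is the ablation used to probe the value of the RL structure: identical
layer inventory, but the parameter-free division and multiplicative-update
nodes are removed, so each stage's BP-block output (channel-averaged,
upsampled in H1) is itself the stage estimate.
"""

from __future__ import annotations

import io
import json
import zipfile
from dataclasses import dataclass, asdict, field
from itertools import product
from pathlib import Path
from typing import Optional

import numpy as np

from . import nn
from .nn import Tensor

__all__ = ["RlnConfig", "RlnStageOutputs", "NetworkModel", "build_network",
           "build_rln_a", "init_fp_gaussian", "count_parameters"]

FP_SIGMAS = (0.5, 1.0, 1.5, 2.0)  # per-output-channel Gaussian init sds


@dataclass
class RlnConfig:
    variant: str = "rln"  # rln | rln-a
    n_inputs: int = 1
    fp_channels: int = 4
    bp_channels: int = 8
    h3_channels: int = 8
    alpha: float = 0.001
    bn_momentum: float = 0.9
    bn_eps: float = 1e-3
    fan_in_scaled_init: bool = False  # default: unit-sd Gaussian as designed

    def validate(self) -> None:
        if self.variant not in ("rln", "rln-a"):
            raise ValueError(f"unknown variant {self.variant!r}")
        if self.n_inputs not in (1, 2):
            raise ValueError("n_inputs must be 1 or 2")
        if min(self.fp_channels, self.bp_channels, self.h3_channels) < 1:
            raise ValueError("channel counts must be >= 1")
        if self.alpha <= 0:
            raise ValueError("alpha must be > 0")


@dataclass
class RlnStageOutputs:
    """All named intermediates of one forward pass (numpy arrays, [N,1/C,...])."""

    I_ap: np.ndarray = None
    FP1: np.ndarray = None
    DV1: np.ndarray = None
    BP1: np.ndarray = None
    BP1up: np.ndarray = None
    E1: np.ndarray = None
    FP2: np.ndarray = None
    DV2: np.ndarray = None
    BP2: np.ndarray = None
    E2: np.ndarray = None
    O: np.ndarray = None


def init_fp_gaussian(shape: tuple[int, ...], seed) -> np.ndarray:
    """Gaussian-kernel initialization for forward-projector conv layers.

    Each output channel o of the (O, C, 3, 3, 3) weight gets a 3D Gaussian
    a * exp(-(di^2+dj^2+dk^2)/(2 sigma_o^2)) centered on the kernel, with
    sigma cycling through 0.5, 1, 1.5, 2 across output channels and amplitude
    a drawn uniformly from [0.5, 1] per kernel.
    """
    O, C, kd, kh, kw = shape
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    ci, cj, ck = kd // 2, kh // 2, kw // 2
    w = np.empty(shape, np.float32)
    for o in range(O):
        sigma = FP_SIGMAS[o % len(FP_SIGMAS)]
        for c in range(C):
            a = rng.uniform(0.5, 1.0)
            for i, j, k in product(range(kd), range(kh), range(kw)):
                r2 = (i - ci) ** 2 + (j - cj) ** 2 + (k - ck) ** 2
                w[o, c, i, j, k] = a * np.exp(-r2 / (2.0 * sigma ** 2))
    return w


class _ConvBlock:
    """conv -> batch norm -> softplus."""

    def __init__(self, cin, cout, rng, cfg: RlnConfig, gaussian_init=False):
        if gaussian_init:
            w = init_fp_gaussian((cout, cin, 3, 3, 3), rng)
        else:
            w = rng.standard_normal((cout, cin, 3, 3, 3)).astype(np.float32)
            if cfg.fan_in_scaled_init:
                w /= np.sqrt(cin * 27)
        self.conv = nn.Conv3d(cin, cout, weight=w)
        self.bn = nn.BatchNorm3d(cout, momentum=cfg.bn_momentum, eps=cfg.bn_eps)

    def __call__(self, x: Tensor, training: bool) -> Tensor:
        return nn.softplus(self.bn(self.conv(x), training))

    def parameters(self):
        return self.conv.parameters() + self.bn.parameters()


class _UpBlock:
    """transpose conv (2x2x2, stride 2) -> batch norm -> softplus."""

    def __init__(self, cin, cout, rng, cfg: RlnConfig):
        w = rng.standard_normal((cout, cin, 2, 2, 2)).astype(np.float32)
        if cfg.fan_in_scaled_init:
            w /= np.sqrt(cin * 8)
        self.conv = nn.ConvTranspose3d2x(cin, cout, weight=w)
        self.bn = nn.BatchNorm3d(cout, momentum=cfg.bn_momentum, eps=cfg.bn_eps)

    def __call__(self, x: Tensor, training: bool) -> Tensor:
        return nn.softplus(self.bn(self.conv(x), training))

    def parameters(self):
        return self.conv.parameters() + self.bn.parameters()


class NetworkModel:
    """An instantiated RLN (or RLN-a): layers, parameters, forward pass."""

    def __init__(self, config: RlnConfig, seed: int = 0):
        config.validate()
        self.config = config
        self.seed = seed
        rng = np.random.default_rng(seed)
        fc, bc, hc = config.fp_channels, config.bp_channels, config.h3_channels
        # H1: 3-layer dense FP block, 3-layer dense BP block, 2x upsample
        self.h1_fp = [_ConvBlock(1, fc, rng, config, gaussian_init=True),
                      _ConvBlock(fc, fc, rng, config, gaussian_init=True),
                      _ConvBlock(2 * fc, fc, rng, config, gaussian_init=True)]
        self.h1_bp = [_ConvBlock(1, bc, rng, config),
                      _ConvBlock(bc, bc, rng, config),
                      _ConvBlock(2 * bc, bc, rng, config)]
        self.h1_up = _UpBlock(bc, bc, rng, config)
        # H2: 2-layer blocks, no dense connections, original scale
        self.h2_fp = [_ConvBlock(1, fc, rng, config, gaussian_init=True),
                      _ConvBlock(fc, fc, rng, config, gaussian_init=True)]
        self.h2_bp = [_ConvBlock(1, bc, rng, config),
                      _ConvBlock(bc, bc, rng, config)]
        # H3: 3-layer dense merge block on concat(E1, E2)
        self.h3 = [_ConvBlock(2, hc, rng, config),
                   _ConvBlock(hc, hc, rng, config),
                   _ConvBlock(2 * hc, hc, rng, config)]

    # -- plumbing ----------------------------------------------------------

    def _blocks(self):
        return (self.h1_fp + self.h1_bp + [self.h1_up]
                + self.h2_fp + self.h2_bp + self.h3)

    def parameters(self) -> list[nn.Parameter]:
        out = []
        for blk in self._blocks():
            out.extend(blk.parameters())
        return out

    # -- forward -----------------------------------------------------------

    @staticmethod
    def _dense3(blocks, x: Tensor, training: bool) -> Tensor:
        """3-layer block with a dense connection: layer3 sees concat(out1, out2)."""
        y1 = blocks[0](x, training)
        y2 = blocks[1](y1, training)
        return blocks[2](nn.concat([y1, y2]), training)

    def forward(self, *inputs, training: bool = False, want_stages: bool = False):
        """Run the network on one or two normalized volumes.

        Inputs may be [D,H,W], [N,1,D,H,W] arrays or Tensors; two inputs
        (registered views of the same scene) are merged by averaging. Returns
        the output Tensor, or (output, RlnStageOutputs) with ``want_stages``.
        Odd spatial dims are zero-padded to even internally and the output
        cropped back.
        """
        if len(inputs) != self.config.n_inputs:
            raise ValueError(f"model expects {self.config.n_inputs} input(s), got {len(inputs)}")
        xs = [self._as_tensor(v) for v in inputs]
        if len(xs) == 2:
            x = nn.mul_const(nn.add(xs[0], xs[1]), 0.5)
        else:
            x = xs[0]

        orig = x.shape[2:]
        pads = [(0, s % 2) for s in orig]
        if any(p[1] for p in pads):
            x = _pad_even(x, pads)

        cfg = self.config
        st = RlnStageOutputs()
        # ---- H1
        i_ap = nn.avg_pool2(x)
        fp_feat = self._dense3(self.h1_fp, i_ap, training)
        fp1 = nn.channel_mean(nn.add(fp_feat, i_ap))  # residual then C_AVE
        if cfg.variant == "rln-a":
            dv1, bp_in = None, fp1
        else:
            dv1 = nn.div(i_ap, nn.add_const(fp1, cfg.alpha))
            bp_in = dv1
        bp1 = self._dense3(self.h1_bp, bp_in, training)
        bp1up = self.h1_up(bp1, training)
        corr1 = nn.channel_mean(bp1up)
        e1 = corr1 if cfg.variant == "rln-a" else nn.mul(x, corr1)
        # ---- H2
        g = self.h2_fp[1](self.h2_fp[0](x, training), training)
        fp2 = nn.channel_mean(nn.add(g, x))
        if cfg.variant == "rln-a":
            dv2, bp_in2 = None, fp2
        else:
            dv2 = nn.div(x, nn.add_const(fp2, cfg.alpha))
            bp_in2 = dv2
        bp2 = self.h2_bp[1](self.h2_bp[0](bp_in2, training), training)
        corr2 = nn.channel_mean(bp2)
        e2 = corr2 if cfg.variant == "rln-a" else nn.mul(e1, corr2)
        # ---- H3
        o = nn.channel_mean(self._dense3(self.h3, nn.concat([e1, e2]), training))

        if any(p[1] for p in pads):
            e1, e2, o = (_crop(t, orig) for t in (e1, e2, o))
        self._last_e1 = e1  # live tensor for the auxiliary loss during training
        if want_stages:
            st.I_ap, st.FP1, st.BP1 = i_ap.data, fp1.data, bp1.data
            st.DV1 = dv1.data if dv1 is not None else None
            st.DV2 = dv2.data if dv2 is not None else None
            st.BP1up, st.E1, st.FP2 = bp1up.data, e1.data, fp2.data
            st.BP2, st.E2, st.O = bp2.data, e2.data, o.data
            return o, st
        return o

    def __call__(self, *inputs, **kw):
        return self.forward(*inputs, **kw)

    def predict(self, *volumes) -> np.ndarray:
        """Inference on raw [D,H,W] arrays; returns a [D,H,W] array."""
        with nn.no_grad():
            out = self.forward(*volumes, training=False)
        return out.data[0, 0]

    @staticmethod
    def _as_tensor(v) -> Tensor:
        if isinstance(v, Tensor):
            return v
        arr = np.asarray(getattr(v, "data", v), dtype=np.float32)
        if arr.ndim == 3:
            arr = arr[None, None]
        elif arr.ndim != 5:
            raise ValueError(f"expected [D,H,W] or [N,1,D,H,W], got shape {arr.shape}")
        return Tensor(arr)

    # -- checkpointing -------------------------------------------------------

    def save(self, path) -> Path:
        """Single-archive checkpoint: config + seed + all arrays, versioned."""
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        arrays = {}
        for li, blk in enumerate(self._blocks()):
            for pi, p in enumerate(blk.parameters()):
                arrays[f"p{li}_{pi}"] = p.data
            bn = getattr(blk, "bn", None)
            if bn is not None:
                arrays[f"rm{li}"] = bn.running_mean
                arrays[f"rv{li}"] = bn.running_var
        buf = io.BytesIO()
        np.savez(buf, **arrays)
        meta = {"format": 1, "config": asdict(self.config), "seed": self.seed}
        with zipfile.ZipFile(path, "w") as zf:
            zf.writestr("meta.json", json.dumps(meta))
            zf.writestr("arrays.npz", buf.getvalue())
        return path

    @staticmethod
    def load(path) -> "NetworkModel":
        with zipfile.ZipFile(path) as zf:
            meta = json.loads(zf.read("meta.json"))
            npz = np.load(io.BytesIO(zf.read("arrays.npz")))
        model = NetworkModel(RlnConfig(**meta["config"]), seed=meta["seed"])
        for li, blk in enumerate(model._blocks()):
            for pi, p in enumerate(blk.parameters()):
                p.data[...] = npz[f"p{li}_{pi}"]
            bn = getattr(blk, "bn", None)
            if bn is not None:
                bn.running_mean[...] = npz[f"rm{li}"]
                bn.running_var[...] = npz[f"rv{li}"]
        return model


def _pad_even(x: Tensor, pads) -> Tensor:
    pw = [(0, 0), (0, 0)] + list(pads)
    out_data = np.pad(x.data, pw)

    def bw(g):
        sl = (slice(None), slice(None)) + tuple(slice(0, s) for s in x.shape[2:])
        x._accum(g[sl])
    return nn._wrap(out_data, (x,), bw)


def _crop(x: Tensor, dims) -> Tensor:
    sl = (slice(None), slice(None)) + tuple(slice(0, s) for s in dims)

    def bw(g):
        gx = np.zeros(x.shape, np.float32)
        gx[sl] = g
        x._accum(gx)
    return nn._wrap(x.data[sl], (x,), bw)


def build_network(config: Optional[RlnConfig] = None, seed: int = 0) -> NetworkModel:
    """Instantiate an RLN from its configuration with seeded initialization."""
    config = config or RlnConfig()
    if config.variant != "rln":
        raise ValueError("use build_rln_a for the ablated variant")
    return NetworkModel(config, seed=seed)


def build_rln_a(config: Optional[RlnConfig] = None, seed: int = 0) -> NetworkModel:
    """Instantiate the RLN-a ablation (division and update nodes removed)."""
    if config is None:
        config = RlnConfig(variant="rln-a")
    if config.variant != "rln-a":
        raise ValueError("config.variant must be 'rln-a'")
    return NetworkModel(config, seed=seed)


def count_parameters(model: NetworkModel) -> int:
    """Total trainable scalars: conv weights + biases + batch-norm scale/shift."""
    return int(sum(p.data.size for p in model.parameters()))
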