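"""Training pipeline for the RL network.

The loss is a sum of two terms: an auxiliary mean-square error steering the
down-scale stage's estimate E1 toward an intermediate target
ITM = w*GT + (1-w)*I (default w = 0.8; E1 should be sharper than the input
but blurrier than the ground truth), and a main term

    L_main = mse(O, GT) - ln((1 + SSIM(O, GT)) / 2)

where SSIM here is the single global structural-similarity value computed
from whole-volume means, variances and covariance (C1 = 1e-4, C2 = 9e-4 on
the normalized intensity scale). Both terms are nonnegative and vanish only
for a perfect prediction.

Optimization uses Adam with an exponentially decayed learning rate
r = r0 * dr^(global_step/decay_step), percentile-based input normalization,
and stochastic block selection: each training sample is a random aligned
sub-block cut from a randomly chosen (input, ground truth) pair.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from . import nn
from .network import NetworkModel
from .volume import Volume3D

__all__ = [
    "NormalizationSpec", "TrainConfig", "LossBreakdown",
    "percentile_normalize", "make_itm", "loss_aux", "ssim_global",
    "loss_main", "lr_schedule", "sample_training_block", "train",
]

SSIM_C1 = 1e-4
SSIM_C2 = 9e-4


@dataclass
class NormalizationSpec:
    """Percentile normalization N(u) = (u - P_low) / (P_high - P_low).

    Real acquisitions use p_low in (0, 1) and p_high in (99, 100) to ignore
    hot pixels; simulated data uses the exact (0, 100) min-max form. Values
    below P_low map to negatives and values above P_high map above one; no
    clipping is applied.
    """

    p_low: float = 0.0
    p_high: float = 100.0

    def validate(self) -> None:
        if not 0 <= self.p_low < self.p_high <= 100:
            raise ValueError(f"need 0 <= p_low < p_high <= 100, got ({self.p_low}, {self.p_high})")


def percentile_normalize(vol, spec: NormalizationSpec = NormalizationSpec()):
    """Normalize a volume (Volume3D or array) by its own intensity percentiles."""
    spec.validate()
    arr = np.asarray(getattr(vol, "data", vol), dtype=np.float32)
    lo = np.percentile(arr, spec.p_low)
    hi = np.percentile(arr, spec.p_high)
    if hi <= lo:
        raise ValueError(
            f"degenerate volume: percentile {spec.p_high:g} == percentile "
            f"{spec.p_low:g} = {lo:g}; cannot normalize"
        )
    out = (arr - lo) / (hi - lo)
    if isinstance(vol, Volume3D):
        return Volume3D(out, vol.voxel_size)
    return out


def make_itm(gt, inp, w: float = 0.8):
    """Intermediate target ITM = w*GT + (1-w)*I guiding the H1 estimate."""
    if not 0 <= w <= 1:
        raise ValueError("itm weight must lie in [0, 1]")
    g = np.asarray(getattr(gt, "data", gt), dtype=np.float32)
    i = np.asarray(getattr(inp, "data", inp), dtype=np.float32)
    if g.shape != i.shape:
        raise ValueError(f"dim mismatch {g.shape} vs {i.shape}")
    return w * g + (1.0 - w) * i


def loss_aux(e1, itm) -> float:
    """Mean square error between the H1 estimate and the intermediate target."""
    a = np.asarray(getattr(e1, "data", e1), dtype=np.float64)
    b = np.asarray(getattr(itm, "data", itm), dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError(f"dim mismatch {a.shape} vs {b.shape}")
    return float(np.mean((a - b) ** 2))


def ssim_global(o, gt, c1: float = SSIM_C1, c2: float = SSIM_C2) -> float:
    """Single global SSIM from whole-volume moments (the loss-side variant)."""
    a = np.asarray(getattr(o, "data", o), dtype=np.float64)
    b = np.asarray(getattr(gt, "data", gt), dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError(f"dim mismatch {a.shape} vs {b.shape}")
    mu_a, mu_b = a.mean(), b.mean()
    var_a, var_b = a.var(), b.var()
    cov = ((a - mu_a) * (b - mu_b)).mean()
    return float(((2 * mu_a * mu_b + c1) * (2 * cov + c2))
                 / ((mu_a ** 2 + mu_b ** 2 + c1) * (var_a + var_b + c2)))


LN_GUARD = 1e-7  # floor for (1+SSIM)/2 inside the log


def loss_main(o, gt):
    """Main loss mse(O,GT) - ln((1+SSIM)/2); returns (value, mse, ssim_term)."""
    mse = loss_aux(o, gt)
    s = ssim_global(o, gt)
    ssim_term = -float(np.log(max((1.0 + s) / 2.0, LN_GUARD)))
    return mse + ssim_term, mse, ssim_term


@dataclass
class LossBreakdown:
    l_aux: float
    l_mse: float
    l_ssim_term: float

    @property
    def l_main(self) -> float:
        return self.l_mse + self.l_ssim_term

    @property
    def l_total(self) -> float:
        return self.l_aux + self.l_main


def lr_schedule(r0: float, dr: float, global_step: int, decay_step: int) -> float:
    """Exponentially decayed learning rate r0 * dr^(global_step/decay_step)."""
    if decay_step <= 0:
        raise ValueError("decay_step must be > 0")
    return float(r0 * dr ** (global_step / decay_step))


def sample_training_block(input_vol, gt_vol, block_dims, rng) -> tuple[np.ndarray, np.ndarray]:
    """Cut the same uniformly random sub-block from input and ground truth."""
    i = np.asarray(getattr(input_vol, "data", input_vol))
    g = np.asarray(getattr(gt_vol, "data", gt_vol))
    if i.shape != g.shape:
        raise ValueError("input and ground truth dims differ")
    if any(b > s for b, s in zip(block_dims, i.shape)):
        raise ValueError(f"block {tuple(block_dims)} larger than volume {i.shape}")
    off = [int(rng.integers(0, s - b + 1)) for b, s in zip(block_dims, i.shape)]
    sl = tuple(slice(o, o + b) for o, b in zip(off, block_dims))
    return i[sl], g[sl]


@dataclass
class TrainConfig:
    batch_size: int = 4
    block_dims: tuple[int, int, int] = (64, 64, 64)
    epochs: int = 200
    iters_per_epoch: int = 100
    r0: float = 1e-3
    dr: float = 0.95
    decay_step: int = 1000
    seed: int = 0
    itm_weight: float = 0.8
    normalization: NormalizationSpec = field(default_factory=NormalizationSpec)
    checkpoint_every: int = 0  # epochs; 0 disables
    checkpoint_dir: Optional[str] = None

    def validate(self) -> None:
        if self.batch_size < 1:
            raise ValueError("batch size must be >= 1")
        if not 0 < self.dr <= 1:
            raise ValueError("decay rate must lie in (0, 1]")
        if not 0 < self.itm_weight <= 1:
            raise ValueError("itm weight must lie in (0, 1]")
        if self.epochs < 1 or self.iters_per_epoch < 1:
            raise ValueError("epochs and iterations must be >= 1")


# -- differentiable loss graph ----------------------------------------------

def _mse_t(a: nn.Tensor, b: nn.Tensor) -> nn.Tensor:
    return nn.mean(nn.square(nn.sub(a, b)))


def _ssim_global_t(o: nn.Tensor, gt: nn.Tensor) -> nn.Tensor:
    mu_o = nn.mean(o)
    mu_g = nn.mean(gt)
    var_o = nn.sub(nn.mean(nn.square(o)), nn.square(mu_o))
    var_g = nn.sub(nn.mean(nn.square(gt)), nn.square(mu_g))
    cov = nn.sub(nn.mean(nn.mul(o, gt)), nn.mul(mu_o, mu_g))
    num = nn.mul(nn.add_const(nn.mul_const(nn.mul(mu_o, mu_g), 2.0), SSIM_C1),
                 nn.add_const(nn.mul_const(cov, 2.0), SSIM_C2))
    den = nn.mul(nn.add_const(nn.add(nn.square(mu_o), nn.square(mu_g)), SSIM_C1),
                 nn.add_const(nn.add(var_o, var_g), SSIM_C2))
    return nn.div(num, den)


def loss_total_graph(e1: nn.Tensor, o: nn.Tensor, itm: np.ndarray, gt: np.ndarray):
    """Build the differentiable L_total = L_aux + L_main graph for one batch."""
    itm_t, gt_t = nn.Tensor(itm), nn.Tensor(gt)
    l_aux = _mse_t(e1, itm_t)
    l_mse = _mse_t(o, gt_t)
    s = _ssim_global_t(o, gt_t)
    half = nn.clamp_min(nn.mul_const(nn.add_const(s, 1.0), 0.5), LN_GUARD)
    l_ssim = nn.mul_const(nn.log(half), -1.0)
    total = nn.add(l_aux, nn.add(l_mse, l_ssim))
    parts = LossBreakdown(l_aux=l_aux.item(), l_mse=l_mse.item(),
                          l_ssim_term=l_ssim.item())
    return total, parts


# -- training loop -----------------------------------------------------------

def train(model: NetworkModel, pairs: Sequence, config: TrainConfig,
          progress: bool = False):
    """Train ``model`` on (gt, input) pairs; returns (model, loss log).

    ``pairs`` is a sequence of SimulatedPair objects or (gt, input) tuples of
    Volume3D/arrays, in raw counts; both members are percentile-normalized
    here per ``config.normalization``. The loss log holds one record per
    step: step, lr, l_aux, l_mse, l_ssim_term, l_total.
    """
    config.validate()
    if len(pairs) == 0:
        raise ValueError("training set is empty")
    norm = []
    for p in pairs:
        gt, inp = (p.gt, p.input) if hasattr(p, "gt") else (p[0], p[1])
        norm.append((percentile_normalize(np.asarray(getattr(gt, "data", gt)),
                                          config.normalization),
                     percentile_normalize(np.asarray(getattr(inp, "data", inp)),
                                          config.normalization)))

    rng = np.random.default_rng(config.seed)
    opt = nn.Adam(model.parameters())
    log: list[dict] = []
    total_steps = config.epochs * config.iters_per_epoch
    iterator = range(total_steps)
    if progress:
        from tqdm import tqdm
        iterator = tqdm(iterator, desc="train")

    for step in iterator:
        xb = np.empty((config.batch_size, 1, *config.block_dims), np.float32)
        gb = np.empty_like(xb)
        for n in range(config.batch_size):
            gt, inp = norm[int(rng.integers(0, len(norm)))]
            ib, gtb = sample_training_block(inp, gt, config.block_dims, rng)
            xb[n, 0], gb[n, 0] = ib, gtb
        itm = config.itm_weight * gb + (1.0 - config.itm_weight) * xb

        inputs = (xb, xb) if model.config.n_inputs == 2 else (xb,)
        o = model.forward(*inputs, training=True)
        e1_t = model._last_e1  # live E1 tensor from this forward pass
        total, parts = loss_total_graph(e1_t, o, itm, gb)
        if not np.isfinite(total.item()):
            raise FloatingPointError(f"non-finite loss at step {step}: {parts}")
        opt.zero_grad()
        total.backward()
        lr = lr_schedule(config.r0, config.dr, step, config.decay_step)
        opt.step(lr)
        log.append({"step": step, "lr": lr, "l_aux": parts.l_aux,
                    "l_mse": parts.l_mse, "l_ssim_term": parts.l_ssim_term,
                    "l_total": parts.l_total})

        if (config.checkpoint_every and config.checkpoint_dir
                and (step + 1) % (config.checkpoint_every * config.iters_per_epoch) == 0):
            epoch = (step + 1) // config.iters_per_epoch
            model.save(f"{config.checkpoint_dir}/checkpoint_ep{epoch:04d}.rln")
    return model, log
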