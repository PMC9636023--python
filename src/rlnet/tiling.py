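"""Tile-and-stitch inference for volumes larger than one forward pass.

Subvolume sizing follows a fixed memory budget for 32-bit data: the tile
depth is d = min(D, 1600) planes and the lateral tile size is
w = h = floor(sqrt((budget_mb / 4) * 1024 * 1024 / d)) voxels, where the 4
is bytes per voxel of 32-bit storage and budget_mb defaults to 320 (MB).
Neighboring tiles share a 24-voxel overlap and are blended with linear
ramps; blend weights are renormalized per voxel so they always sum to one,
which makes stitching a constant field exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .volume import Volume3D
from . import nn

__all__ = ["TilePlan", "plan_tiles", "stitch", "predict_tiled"]

DEFAULT_OVERLAP = 24
DEFAULT_BUDGET_MB = 320.0
MAX_DEPTH = 1600


@dataclass
class TilePlan:
    source_dims: tuple[int, int, int]           # (D, H, W)
    tile_dims: tuple[int, int, int]             # (d, h, w)
    overlap: int
    budget_mb: float
    origins: list[tuple[int, int, int]] = field(default_factory=list)

    @property
    def n_tiles(self) -> int:
        return len(self.origins)


def _axis_origins(size: int, tile: int, overlap: int) -> list[int]:
    if tile >= size:
        return [0]
    stride = tile - overlap
    origins = list(range(0, size - tile, stride))
    origins.append(size - tile)  # clamp the final tile to the edge
    return sorted(set(origins))


def plan_tiles(dims, overlap: int = DEFAULT_OVERLAP,
               budget_mb: float = DEFAULT_BUDGET_MB,
               tile_dims=None) -> TilePlan:
    """Deterministic tile layout for a (D, H, W) volume.

    ``tile_dims`` overrides the budget-derived sizing (useful for testing).
    If the formula tile covers the whole volume, a single tile is returned.
    """
    D, H, W = (int(x) for x in dims)
    if min(D, H, W) < 1:
        raise ValueError("dims must be positive")
    if tile_dims is None:
        d = min(D, MAX_DEPTH)
        lat = int(np.floor(np.sqrt((budget_mb / 4.0) * 1024 * 1024 / d)))
        tile_dims = (d, min(lat, H), min(lat, W))
    td = tuple(min(int(t), s) for t, s in zip(tile_dims, (D, H, W)))
    for t, s in zip(td, (D, H, W)):
        if t < s and overlap >= t:
            raise ValueError(f"overlap {overlap} >= tile dim {t}")
    origins = [(z, y, x)
               for z in _axis_origins(D, td[0], overlap)
               for y in _axis_origins(H, td[1], overlap)
               for x in _axis_origins(W, td[2], overlap)]
    return TilePlan(source_dims=(D, H, W), tile_dims=td, overlap=overlap,
                    budget_mb=budget_mb, origins=origins)


def _ramp_profile(length: int, overlap: int, at_start: bool, at_end: bool) -> np.ndarray:
    """Per-axis blend weights: linear 0->1 ramps over interior overlaps."""
    w = np.ones(length, np.float64)
    ramp = (np.arange(1, overlap + 1)) / (overlap + 1.0)
    if at_start:
        n = min(overlap, length)
        w[:n] = ramp[:n]
    if at_end:
        n = min(overlap, length)
        w[-n:] = np.minimum(w[-n:], ramp[:n][::-1])
    return w


def tile_weight(plan: TilePlan, origin) -> np.ndarray:
    """Separable blend-weight block for the tile at ``origin``."""
    profs = []
    for ax in range(3):
        start = origin[ax] > 0
        end = origin[ax] + plan.tile_dims[ax] < plan.source_dims[ax]
        profs.append(_ramp_profile(plan.tile_dims[ax], plan.overlap, start, end))
    return profs[0][:, None, None] * profs[1][None, :, None] * profs[2][None, None, :]


def stitch(tiles, plan: TilePlan) -> Volume3D:
    """Blend predicted tile blocks back into one volume per the plan."""
    if len(tiles) != plan.n_tiles:
        raise ValueError(f"expected {plan.n_tiles} tiles, got {len(tiles)}")
    acc = np.zeros(plan.source_dims, np.float64)
    wsum = np.zeros(plan.source_dims, np.float64)
    for tile, origin in zip(tiles, plan.origins):
        block = np.asarray(getattr(tile, "data", tile), dtype=np.float64)
        if block.shape != plan.tile_dims:
            raise ValueError(f"tile shape {block.shape} != plan {plan.tile_dims}")
        w = tile_weight(plan, origin)
        sl = tuple(slice(o, o + t) for o, t in zip(origin, plan.tile_dims))
        acc[sl] += w * block
        wsum[sl] += w
    if wsum.min() <= 0:
        raise ValueError("tile plan does not cover the volume")
    return Volume3D((acc / wsum).astype(np.float32))


def predict_tiled(model, vol: Volume3D, plan: TilePlan | None = None,
                  overlap: int = DEFAULT_OVERLAP,
                  budget_mb: float = DEFAULT_BUDGET_MB) -> Volume3D:
    """Run the network tile by tile over a (normalized) volume and stitch.

    A volume no larger than one tile is processed in a single forward pass.
    """
    if plan is None:
        plan = plan_tiles(vol.dims, overlap=overlap, budget_mb=budget_mb)
    preds = []
    for origin in plan.origins:
        sl = tuple(slice(o, o + t) for o, t in zip(origin, plan.tile_dims))
        preds.append(model.predict(vol.data[sl]))
    return stitch(preds, plan)
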