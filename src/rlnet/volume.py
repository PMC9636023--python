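"""Volumes and TIFF I/O.

A microscope stack is represented as a :class:`Volume3D`: a (z, y, x) array of
nonnegative intensities ("counts") plus optional physical voxel size in µm.
TIFF pages map to z; within a page rows map to y. All internal computation is
done on a continuous (float) scale; quantization happens only when a volume is
written in 16-bit mode.
"""

from __future__ import annotations

import dataclasses
import datetime
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import tifffile

__all__ = ["Volume3D", "read_volume", "write_volume", "RunManifest"]


@dataclass
class Volume3D:
    """A 3D grayscale intensity volume with fixed (z, y, x) axis order."""

    data: np.ndarray
    voxel_size: Optional[tuple[float, float, float]] = None  # µm per axis (z, y, x)

    def __post_init__(self) -> None:
        arr = np.asarray(self.data)
        if arr.ndim == 2:  # single plane -> degenerate depth
            arr = arr[None, :, :]
        if arr.ndim != 3:
            raise ValueError(f"Volume3D expects 3D data, got shape {arr.shape}")
        if arr.size == 0:
            raise ValueError("Volume3D must have at least one voxel per axis")
        if not np.issubdtype(arr.dtype, np.floating):
            arr = arr.astype(np.float32)
        if not np.all(np.isfinite(arr)):
            raise ValueError("Volume3D intensities must be finite")
        self.data = arr

    @property
    def dims(self) -> tuple[int, int, int]:
        """(D, H, W) voxel counts per (z, y, x) axis."""
        return tuple(self.data.shape)  # type: ignore[return-value]

    def astype(self, dtype) -> "Volume3D":
        return Volume3D(self.data.astype(dtype), self.voxel_size)

    def copy(self) -> "Volume3D":
        return Volume3D(self.data.copy(), self.voxel_size)


def read_volume(path) -> Volume3D:
    """Read a single- or multi-page grayscale TIFF as a Volume3D.

    Integer pixel values are converted to continuous intensities without
    rescaling (a 16-bit count of 30 reads back as 30.0).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such volume: {path}")
    try:
        arr = tifffile.imread(path)
    except Exception as exc:  # non-TIFF payload
        raise ValueError(f"{path} is not a readable TIFF stack: {exc}") from exc
    arr = np.asarray(arr)
    if arr.size == 0:
        raise ValueError(f"{path} contains a zero-page stack")
    if arr.ndim == 2:
        arr = arr[None]
    if arr.ndim != 3:
        raise ValueError(f"{path} is not a grayscale z-stack (shape {arr.shape})")
    return Volume3D(arr.astype(np.float32))


def write_volume(vol: Volume3D, path, bit_depth: str = "float32"):
    """Write a volume as a multi-page TIFF.

    bit_depth "float32" is lossless for float32 data; "uint16" rounds to the
    nearest integer and raises if any rounded value falls outside [0, 65535]
    rather than clipping silently.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if bit_depth in ("float32", "32"):
        tifffile.imwrite(path, vol.data.astype(np.float32), photometric="minisblack")
    elif bit_depth in ("uint16", "16"):
        rounded = np.rint(vol.data)
        if rounded.min() < 0 or rounded.max() > 65535:
            raise ValueError(
                "16-bit output requires rounded values in [0, 65535]; "
                f"got range [{rounded.min():g}, {rounded.max():g}]"
            )
        tifffile.imwrite(path, rounded.astype(np.uint16), photometric="minisblack")
    else:
        raise ValueError(f"unknown bit depth {bit_depth!r} (use 'uint16' or 'float32')")
    return path


@dataclass
class RunManifest:
    """Record of one CLI run: seed, config snapshot, stage logs and artifacts.

    Rerunning a stochastic command with the seed recorded here reproduces its
    outputs bit-for-bit on one device.
    """

    command: str
    seed: Optional[int] = None
    config: dict = field(default_factory=dict)
    started: str = field(default_factory=lambda: datetime.datetime.now().isoformat())
    stages: list = field(default_factory=list)
    outputs: list = field(default_factory=list)

    def log_stage(self, stage: str, t0: float, **info) -> None:
        self.stages.append({"stage": stage, "duration_s": round(time.time() - t0, 3), **info})

    def add_output(self, path) -> None:
        self.outputs.append(str(path))

    def write(self, path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        path.write_text(json.dumps(dataclasses.asdict(self), indent=2))
        return path

    @staticmethod
    def read(path) -> "RunManifest":
        d = json.loads(Path(path).read_text())
        return RunManifest(**d)
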