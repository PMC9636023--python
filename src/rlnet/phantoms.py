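"""Synthetic phantom generation: ground truth objects, PSFs, blur and noise.

This is the data factory used to train and validate the deconvolution models
without any microscope data. A "mixed structure" phantom scatters solid
spheres, hollow ellipsoid shells and small box-shaped dots on a constant
background; a bead phantom scatters Gaussian-smoothed spheres. Inputs are
produced by convolving the ground truth with a parametric point-spread
function and (optionally) degrading it with Poisson + Gaussian noise tuned to
a target SNR (variance-ratio definition, in dB).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np
from scipy.signal import fftconvolve
from scipy.ndimage import gaussian_filter

from .volume import Volume3D, write_volume

__all__ = [
    "PhantomSpec", "BeadSpec", "PsfSpec", "NoiseSpec", "SimulatedPair",
    "make_mixed_phantom", "make_bead_phantom", "make_psf", "blur",
    "add_noise", "snr_db", "make_dataset",
]


# ---------------------------------------------------------------------------
# Specs


@dataclass
class PhantomSpec:
    """Mixed-structure phantom: spheres + ellipsoid shells + dots.

    Defaults describe a 128^3 volume with 100 solid spheres (diameter 4-8
    voxels), 100 ellipsoidal surfaces (axis diameters 4-8, thickness 1-2) and
    400 dots (extent 1-3 voxels per axis), all at random intensities between
    50 and 850 counts over a constant 30-count background.
    """

    dims: tuple[int, int, int] = (128, 128, 128)
    n_spheres: int = 100
    n_shells: int = 100
    n_dots: int = 400
    intensity_range: tuple[float, float] = (50.0, 850.0)
    sphere_diameter_range: tuple[float, float] = (4.0, 8.0)
    shell_diameter_range: tuple[float, float] = (4.0, 8.0)
    shell_thickness_range: tuple[float, float] = (1.0, 2.0)
    dot_extent_range: tuple[int, int] = (1, 3)
    background: float = 30.0

    def validate(self) -> None:
        for lo, hi in (self.intensity_range, self.sphere_diameter_range,
                       self.shell_diameter_range, self.shell_thickness_range,
                       self.dot_extent_range):
            if lo > hi:
                raise ValueError(f"empty range ({lo}, {hi})")
        if min(self.n_spheres, self.n_shells, self.n_dots) < 0 or self.background < 0:
            raise ValueError("counts and background must be >= 0")
        if min(self.dims) < 1:
            raise ValueError("dims must be positive")
        want = max(self.sphere_diameter_range[0], self.shell_diameter_range[0], 1)
        if min(self.dims) < want and (self.n_spheres or self.n_shells):
            raise ValueError("volume too small for the smallest requested object")


@dataclass
class BeadSpec:
    """Bead phantom: random spheres, then a global isotropic Gaussian blur."""

    dims: tuple[int, int, int] = (128, 128, 128)
    n_beads: int = 50
    max_radius: float = 7.0
    intensity_range: tuple[float, float] = (80.0, 255.0)
    preblur_sd: float = 2.0

    def validate(self) -> None:
        if self.max_radius < 1:
            raise ValueError("max radius must be >= 1 voxel")
        if self.preblur_sd <= 0:
            raise ValueError("pre-blur sd must be > 0")
        if self.intensity_range[0] > self.intensity_range[1]:
            raise ValueError("empty intensity range")
        if min(self.dims) < 1:
            raise ValueError("dims must be positive")


@dataclass
class PsfSpec:
    """Parametric 3D PSF.

    ``dispim-like`` is an anisotropic Gaussian whose axial (z) extent is
    ``axial_ratio`` times the lateral extent, mimicking the elongated
    light-sheet PSF. ``isim-like`` and ``widefield-like`` are configurable
    Gaussian stand-ins with milder/stronger axial elongation. The rendered
    kernel is nonnegative, sums to one, and is centered (odd dims per axis).
    """

    kind: str = "dispim-like"  # dispim-like | isim-like | widefield-like | isotropic-gaussian | delta | user-kernel
    lateral_sd: float = 1.0
    axial_ratio: float = 3.0
    kernel_dims: Optional[tuple[int, int, int]] = None
    kernel: Optional[np.ndarray] = None  # for kind="user-kernel"

    _DEFAULT_RATIOS = {
        "dispim-like": 3.0, "isim-like": 1.5,
        "widefield-like": 4.0, "isotropic-gaussian": 1.0,
    }


def make_psf(spec: PsfSpec) -> Volume3D:
    """Render the PSF kernel described by ``spec`` (unit sum, odd dims)."""
    if spec.kind == "user-kernel":
        if spec.kernel is None:
            raise ValueError("user-kernel PsfSpec requires a kernel array")
        k = np.asarray(spec.kernel, dtype=np.float64)
        if any(s % 2 == 0 for s in k.shape):
            raise ValueError("kernel dims must be odd per axis")
        if k.min() < 0:
            raise ValueError("kernel must be nonnegative")
        return Volume3D(k / k.sum())

    if spec.kind == "delta":
        dims = spec.kernel_dims or (3, 3, 3)
        _check_odd(dims)
        k = np.zeros(dims, dtype=np.float64)
        k[dims[0] // 2, dims[1] // 2, dims[2] // 2] = 1.0
        return Volume3D(k)

    if spec.kind not in PsfSpec._DEFAULT_RATIOS:
        raise ValueError(f"unknown PSF kind {spec.kind!r}")
    if spec.lateral_sd <= 0:
        raise ValueError("lateral sd must be positive")
    ratio = spec.axial_ratio if spec.kind == "dispim-like" else \
        PsfSpec._DEFAULT_RATIOS[spec.kind] if spec.axial_ratio == 3.0 else spec.axial_ratio
    sd = (ratio * spec.lateral_sd, spec.lateral_sd, spec.lateral_sd)  # (z, y, x)
    dims = spec.kernel_dims or tuple(2 * int(np.ceil(4 * s)) + 1 for s in sd)
    _check_odd(dims)
    zz, yy, xx = np.meshgrid(*[np.arange(n) - n // 2 for n in dims], indexing="ij")
    k = np.exp(-(zz ** 2 / (2 * sd[0] ** 2) + yy ** 2 / (2 * sd[1] ** 2)
                 + xx ** 2 / (2 * sd[2] ** 2)))
    return Volume3D(k / k.sum())


def _check_odd(dims) -> None:
    if any(int(s) % 2 == 0 or int(s) < 1 for s in dims):
        raise ValueError(f"kernel dims must be odd and positive, got {tuple(dims)}")


@dataclass
class NoiseSpec:
    """Noise model tuned to a target variance-ratio SNR in dB.

    For ``mix="both"`` the signal is Poisson-resampled at ``photons_per_count``
    photons per digital count (shot noise), then zero-mean Gaussian read noise
    is added with a standard deviation solved so the realized SNR
    10*log10(Var(S)/Var(noise)) matches ``target_snr_db``.
    """

    target_snr_db: Optional[float] = 10.0
    mix: str = "both"  # gaussian | poisson | both
    gaussian_sd: Optional[float] = None  # solved from target when None
    photons_per_count: float = 1.0

    def validate(self) -> None:
        if self.mix not in ("gaussian", "poisson", "both"):
            raise ValueError(f"unknown noise mix {self.mix!r}")
        if self.photons_per_count <= 0:
            raise ValueError("photons per count must be > 0")
        if self.target_snr_db is not None and not np.isfinite(self.target_snr_db):
            raise ValueError("target SNR must be finite")
        if self.target_snr_db is None and self.gaussian_sd is None and self.mix != "poisson":
            raise ValueError("need either a target SNR or an explicit Gaussian sd")


@dataclass
class SimulatedPair:
    """One (ground truth, degraded input) training/testing pair."""

    gt: Volume3D
    input: Volume3D
    psf: Optional[PsfSpec] = None
    noise: Optional[NoiseSpec] = None
    object_log: list = field(default_factory=list)
    seed: Optional[int] = None


# ---------------------------------------------------------------------------
# Phantom rasterization


def make_mixed_phantom(spec: PhantomSpec, seed: int):
    """Rasterize a mixed-structure phantom; returns (Volume3D, object log).

    Objects are drawn in order spheres, shells, dots; where objects overlap
    the later-drawn intensity overwrites, so every voxel is either background
    or an intensity sampled within the spec's range.
    """
    spec.validate()
    rng = np.random.default_rng(seed)
    D, H, W = spec.dims
    vol = np.full(spec.dims, spec.background, dtype=np.float32)
    log: list[dict] = []

    ilo, ihi = spec.intensity_range
    for _ in range(spec.n_spheres):
        d = rng.uniform(*spec.sphere_diameter_range)
        c = [rng.uniform(0, n - 1) for n in (D, H, W)]
        inten = rng.uniform(ilo, ihi)
        _draw_ellipsoid(vol, c, (d / 2, d / 2, d / 2), inten)
        log.append({"type": "sphere", "center": c, "diameter": d, "intensity": inten})
    for _ in range(spec.n_shells):
        radii = [rng.uniform(*spec.shell_diameter_range) / 2 for _ in range(3)]
        th = rng.uniform(*spec.shell_thickness_range)
        c = [rng.uniform(0, n - 1) for n in (D, H, W)]
        inten = rng.uniform(ilo, ihi)
        _draw_ellipsoid(vol, c, radii, inten, shell_thickness=th)
        log.append({"type": "shell", "center": c, "radii": radii,
                    "thickness": th, "intensity": inten})
    for _ in range(spec.n_dots):
        ext = [int(rng.integers(spec.dot_extent_range[0], spec.dot_extent_range[1] + 1))
               for _ in range(3)]
        c = [int(rng.integers(0, n)) for n in (D, H, W)]
        inten = rng.uniform(ilo, ihi)
        sl = tuple(slice(max(ci - e // 2, 0), min(ci - e // 2 + e, n))
                   for ci, e, n in zip(c, ext, (D, H, W)))
        vol[sl] = inten
        log.append({"type": "dot", "center": c, "extent": ext, "intensity": inten})
    return Volume3D(vol), log


def _draw_ellipsoid(vol, center, radii, intensity, shell_thickness=None):
    """Fill an ellipsoid (or its surface shell) into ``vol`` in place.

    A shell keeps voxels whose normalized ellipsoid radius r lies in
    [1 - thickness / (2*min radius), 1]; a solid keeps r <= 1.
    """
    bounds = []
    for c, r, n in zip(center, radii, vol.shape):
        lo = max(int(np.floor(c - r - 1)), 0)
        hi = min(int(np.ceil(c + r + 1)) + 1, n)
        if lo >= hi:
            return
        bounds.append((lo, hi))
    grids = np.meshgrid(*[np.arange(lo, hi) for lo, hi in bounds], indexing="ij")
    rsq = sum(((g - c) / r) ** 2 for g, c, r in zip(grids, center, radii))
    rnorm = np.sqrt(rsq)
    if shell_thickness is None:
        mask = rnorm <= 1.0
    else:
        inner = max(1.0 - shell_thickness / (2 * min(radii)), 0.0)
        mask = (rnorm <= 1.0) & (rnorm >= inner)
    sub = vol[tuple(slice(lo, hi) for lo, hi in bounds)]
    sub[mask] = intensity


def make_bead_phantom(spec: BeadSpec, seed: int) -> Volume3D:
    """Random solid spheres smoothed with an isotropic Gaussian (ground truth)."""
    spec.validate()
    rng = np.random.default_rng(seed)
    D, H, W = spec.dims
    vol = np.zeros(spec.dims, dtype=np.float32)
    for _ in range(spec.n_beads):
        r = rng.uniform(1.0, spec.max_radius)
        c = [rng.uniform(0, n - 1) for n in (D, H, W)]
        inten = rng.uniform(*spec.intensity_range)
        _draw_ellipsoid(vol, c, (r, r, r), inten)
    return Volume3D(gaussian_filter(vol, spec.preblur_sd, mode="constant"))


# ---------------------------------------------------------------------------
# Degradation


def blur(vol: Volume3D, psf: Volume3D) -> Volume3D:
    """Zero-padded 'same' linear convolution of a volume with a PSF kernel."""
    if any(k > v for k, v in zip(psf.dims, vol.dims)):
        raise ValueError(f"kernel {psf.dims} larger than volume {vol.dims}")
    out = fftconvolve(vol.data.astype(np.float64), psf.data, mode="same")
    # FFT roundoff can leave tiny negatives on a nonnegative input
    if vol.data.min() >= 0:
        np.maximum(out, 0.0, out=out)
    return Volume3D(out.astype(np.float32), vol.voxel_size)


def snr_db(signal: np.ndarray, noise: np.ndarray) -> float:
    """Variance-ratio SNR in dB: 10*log10(Var(S)/Var(N))."""
    vn = float(np.var(noise))
    if vn == 0:
        raise ValueError("noise has zero variance")
    return float(10.0 * np.log10(np.var(signal) / vn))


def add_noise(vol: Volume3D, noise: NoiseSpec, seed: int) -> Volume3D:
    """Degrade a noiseless volume with Poisson and/or Gaussian noise.

    With a target SNR, the Gaussian sd is solved so the realized
    variance-ratio SNR matches the target; for mix="both" the expected
    Poisson variance (mean signal / photons-per-count) is subtracted first,
    and an error is raised if shot noise alone already exceeds the target.
    """
    noise.validate()
    rng = np.random.default_rng(seed)
    s = vol.data.astype(np.float64)
    var_s = float(np.var(s))

    def target_var():
        return var_s / 10 ** (noise.target_snr_db / 10.0)

    out = s
    var_poisson = 0.0
    if noise.mix in ("poisson", "both"):
        if s.min() < 0:
            raise ValueError("Poisson noise requires a nonnegative volume")
        scale = noise.photons_per_count
        out = rng.poisson(s * scale).astype(np.float64) / scale
        var_poisson = float(np.mean(s)) / scale  # expected shot-noise variance

    if noise.mix in ("gaussian", "both"):
        sd = noise.gaussian_sd
        if sd is None:
            resid = target_var() - (var_poisson if noise.mix == "both" else 0.0)
            if resid <= 0:
                raise ValueError(
                    f"target SNR {noise.target_snr_db} dB unreachable: Poisson noise "
                    f"alone contributes variance {var_poisson:.3g} > target {target_var():.3g}"
                )
            sd = float(np.sqrt(resid))
        if sd > 0:
            out = out + rng.normal(0.0, sd, size=s.shape)

    return Volume3D(out.astype(np.float32), vol.voxel_size)


# ---------------------------------------------------------------------------
# Dataset factory


def make_dataset(n_pairs: int, phantom_spec: PhantomSpec, psf_spec: PsfSpec,
                 noise_spec: Optional[NoiseSpec], seed: int, out_dir,
                 kind: str = "mixed", bead_spec: Optional[BeadSpec] = None) -> Path:
    """Write ``n_pairs`` (gt, input) TIFF pairs plus a JSON manifest.

    Layout: ``<dir>/gt/NNN.tif``, ``<dir>/input/NNN.tif``, ``<dir>/manifest.json``.
    The manifest records the per-pair seeds so the set can be regenerated
    byte-for-byte.
    """
    out_dir = Path(out_dir)
    (out_dir / "gt").mkdir(parents=True, exist_ok=True)
    (out_dir / "input").mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    pair_seeds = [int(x) for x in rng.integers(0, 2 ** 31 - 1, size=2 * n_pairs)]

    psf = make_psf(psf_spec)
    entries = []
    for i in range(n_pairs):
        pair = simulate_pair(phantom_spec, psf_spec, noise_spec,
                             gen_seed=pair_seeds[2 * i], noise_seed=pair_seeds[2 * i + 1],
                             kind=kind, bead_spec=bead_spec, psf=psf)
        gt_path = out_dir / "gt" / f"{i:03d}.tif"
        in_path = out_dir / "input" / f"{i:03d}.tif"
        write_volume(pair.gt, gt_path)
        write_volume(pair.input, in_path)
        entries.append({
            "index": i, "gt": gt_path.name, "input": in_path.name,
            "gen_seed": pair_seeds[2 * i], "noise_seed": pair_seeds[2 * i + 1],
            "n_objects": len(pair.object_log), "object_log": pair.object_log,
        })
    manifest = {
        "seed": seed, "n_pairs": n_pairs, "kind": kind,
        "phantom_spec": asdict(phantom_spec),
        "bead_spec": asdict(bead_spec) if bead_spec else None,
        "psf_spec": {k: v for k, v in asdict(psf_spec).items() if k != "kernel"},
        "noise_spec": asdict(noise_spec) if noise_spec else None,
        "pairs": entries,
    }
    mpath = out_dir / "manifest.json"
    mpath.write_text(json.dumps(manifest, indent=2))
    return mpath


def simulate_pair(phantom_spec, psf_spec, noise_spec, gen_seed, noise_seed,
                  kind="mixed", bead_spec=None, psf=None) -> SimulatedPair:
    """Generate a single (gt, input) pair from specs and explicit seeds."""
    if psf is None:
        psf = make_psf(psf_spec)
    if kind == "mixed":
        gt, log = make_mixed_phantom(phantom_spec, gen_seed)
    elif kind == "bead":
        gt = make_bead_phantom(bead_spec or BeadSpec(dims=phantom_spec.dims), gen_seed)
        log = []
    else:
        raise ValueError(f"unknown phantom kind {kind!r}")
    inp = blur(gt, psf)
    if noise_spec is not None:
        inp = add_noise(inp, noise_spec, noise_seed)
    return SimulatedPair(gt=gt, input=inp, psf=psf_spec, noise=noise_spec,
                         object_log=log, seed=gen_seed)
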