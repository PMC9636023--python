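import numpy as np
import pytest

from rlnet import PhantomSpec, PsfSpec, make_mixed_phantom, make_psf, blur


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def dispim_psf():
    """Anisotropic light-sheet-like PSF (axial extent 3x lateral)."""
    return make_psf(PsfSpec(kind="dispim-like", lateral_sd=1.0, axial_ratio=3.0))


@pytest.fixture(scope="session")
def small_phantom_pair(dispim_psf):
    """A 48^3 mixed phantom and its noiseless blurred version."""
    spec = PhantomSpec(dims=(48, 48, 48), n_spheres=6, n_shells=6, n_dots=20)
    gt, log = make_mixed_phantom(spec, seed=7)
    return gt, blur(gt, dispim_psf), log


def brute_force_conv3d(vol: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """Triple-loop zero-padded 'same' convolution; the independent oracle."""
    D, H, W = vol.shape
    kd, kh, kw = kernel.shape
    rz, ry, rx = kd // 2, kh // 2, kw // 2
    out = np.zeros_like(vol, dtype=np.float64)
    for z in range(D):
        for y in range(H):
            for x in range(W):
                acc = 0.0
                for i in range(kd):
                    for j in range(kh):
                        for k in range(kw):
                            zz, yy, xx = z - (i - rz), y - (j - ry), x - (k - rx)
                            if 0 <= zz < D and 0 <= yy < H and 0 <= xx < W:
                                acc += vol[zz, yy, xx] * kernel[i, j, k]
                out[z, y, x] = acc
    return out
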