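import json

import numpy as np
import pytest
from scipy.optimize import curve_fit

from rlnet import (BeadSpec, NoiseSpec, PhantomSpec, PsfSpec, add_noise, blur,
                   make_bead_phantom, make_dataset, make_mixed_phantom,
                   make_psf, read_volume)
from rlnet.phantoms import snr_db

from conftest import brute_force_conv3d


class TestMixedPhantom:
    def test_default_object_counts_and_background(self):
        spec = PhantomSpec()  # 128^3, 100 spheres, 100 shells, 400 dots
        vol, log = make_mixed_phantom(spec, seed=1)
        assert vol.dims == (128, 128, 128)
        counts = {t: sum(1 for o in log if o["type"] == t)
                  for t in ("sphere", "shell", "dot")}
        assert counts == {"sphere": 100, "shell": 100, "dot": 400}
        # every voxel is background or a sampled object intensity
        vals = vol.data
        is_bg = vals == spec.background
        assert is_bg.any()
        obj = vals[~is_bg]
        assert obj.min() >= 50.0 and obj.max() <= 850.0

    def test_zero_counts_gives_constant_background(self):
        spec = PhantomSpec(dims=(16, 16, 16), n_spheres=0, n_shells=0, n_dots=0)
        vol, log = make_mixed_phantom(spec, seed=3)
        assert log == []
        assert np.all(vol.data == 30.0)

    def test_same_seed_is_deterministic(self):
        spec = PhantomSpec(dims=(32, 32, 32), n_spheres=5, n_shells=5, n_dots=10)
        a, _ = make_mixed_phantom(spec, seed=9)
        b, _ = make_mixed_phantom(spec, seed=9)
        np.testing.assert_array_equal(a.data, b.data)

    def test_shells_are_hollow(self):
        # a single large shell should contain background voxels inside it
        spec = PhantomSpec(dims=(32, 32, 32), n_spheres=0, n_dots=0, n_shells=1,
                           shell_diameter_range=(16, 16), shell_thickness_range=(1, 1))
        vol, log = make_mixed_phantom(spec, seed=2)
        c = [int(round(x)) for x in log[0]["center"]]
        if all(0 <= ci < 32 for ci in c):
            assert vol.data[tuple(c)] == spec.background

    def test_too_small_volume_raises(self):
        with pytest.raises(ValueError):
            make_mixed_phantom(PhantomSpec(dims=(2, 2, 2)), seed=0)


class TestBeadPhantom:
    def test_blur_respects_max_principle(self):
        spec = BeadSpec(dims=(48, 48, 48), n_beads=10)
        vol = make_bead_phantom(spec, seed=5)
        assert vol.data.max() <= 255.0 + 1e-3
        assert vol.data.min() >= 0.0

    def test_zero_beads_gives_empty_volume(self):
        assert np.all(make_bead_phantom(BeadSpec(dims=(16, 16, 16), n_beads=0), 0).data == 0)

    def test_centered_bead_conserves_flux(self):
        # one bead far from all edges: Gaussian smoothing preserves total flux
        spec = BeadSpec(dims=(32, 32, 32), n_beads=1, max_radius=3, preblur_sd=2.0)
        rng_probe = np.random.default_rng(0)
        for seed in range(20):
            vol = make_bead_phantom(spec, seed=seed)
            com = np.array(np.unravel_index(np.argmax(vol.data), vol.dims))
            if np.all(com > 10) and np.all(com < 22):
                break
        spec_raw = BeadSpec(dims=(32, 32, 32), n_beads=1, max_radius=3, preblur_sd=1e-6)
        raw = make_bead_phantom(spec_raw, seed=seed)
        assert abs(vol.data.sum() - raw.data.sum()) / raw.data.sum() < 0.01


class TestPsf:
    def test_delta_kernel_is_single_center_voxel(self):
        k = make_psf(PsfSpec(kind="delta", kernel_dims=(5, 5, 5)))
        assert k.data[2, 2, 2] == 1.0 and k.data.sum() == 1.0

    @pytest.mark.parametrize("kind", ["dispim-like", "isim-like", "widefield-like",
                                      "isotropic-gaussian"])
    def test_unit_sum(self, kind):
        k = make_psf(PsfSpec(kind=kind, lateral_sd=1.2))
        assert abs(k.data.sum() - 1.0) < 1e-6
        assert k.data.min() >= 0

    def test_dispim_axial_lateral_fwhm_ratio(self):
        k = make_psf(PsfSpec(kind="dispim-like", lateral_sd=1.0, axial_ratio=3.0))
        def gauss(x, a, s):
            return a * np.exp(-x ** 2 / (2 * s ** 2))
        prof_z = k.data[:, k.dims[1] // 2, k.dims[2] // 2]
        prof_x = k.data[k.dims[0] // 2, k.dims[1] // 2, :]
        sz = curve_fit(gauss, np.arange(len(prof_z)) - len(prof_z) // 2, prof_z,
                       p0=(prof_z.max(), 2))[0][1]
        sx = curve_fit(gauss, np.arange(len(prof_x)) - len(prof_x) // 2, prof_x,
                       p0=(prof_x.max(), 1))[0][1]
        assert abs(abs(sz / sx) - 3.0) < 0.06  # FWHM ratio within 2%

    def test_even_dims_rejected(self):
        with pytest.raises(ValueError, match="odd"):
            make_psf(PsfSpec(kind="delta", kernel_dims=(4, 5, 5)))

    def test_nonpositive_sd_rejected(self):
        with pytest.raises(ValueError):
            make_psf(PsfSpec(kind="isotropic-gaussian", lateral_sd=0.0))


class TestBlur:
    def test_delta_kernel_is_identity(self, rng):
        from rlnet import Volume3D
        v = Volume3D(rng.random((12, 12, 12), dtype=np.float32))
        out = blur(v, make_psf(PsfSpec(kind="delta")))
        np.testing.assert_allclose(out.data, v.data, atol=1e-5)

    def test_constant_volume_stays_constant_interior(self):
        from rlnet import Volume3D
        v = Volume3D(np.full((16, 16, 16), 30.0))
        k = make_psf(PsfSpec(kind="isotropic-gaussian", lateral_sd=0.8,
                             kernel_dims=(5, 5, 5)))
        out = blur(v, k)
        np.testing.assert_allclose(out.data[4:-4, 4:-4, 4:-4], 30.0, rtol=1e-4)

    def test_matches_brute_force_convolution(self, rng):
        from rlnet import Volume3D
        v = rng.random((16, 16, 16))
        k = rng.random((5, 5, 5))
        k /= k.sum()
        got = blur(Volume3D(v), Volume3D(k)).data
        want = brute_force_conv3d(v, k)
        np.testing.assert_allclose(got, want, rtol=2e-4, atol=1e-5)

    def test_kernel_larger_than_volume_raises(self, rng):
        from rlnet import Volume3D
        with pytest.raises(ValueError):
            blur(Volume3D(np.ones((4, 4, 4))),
                 Volume3D(np.ones((5, 5, 5)) / 125))


class TestNoise:
    @pytest.fixture(scope="class")
    def signal(self):
        spec = PhantomSpec(dims=(48, 48, 48), n_spheres=8, n_shells=8, n_dots=30)
        vol, _ = make_mixed_phantom(spec, seed=11)
        return vol

    def test_realized_snr_matches_target(self, signal):
        target = 10.0
        spec = NoiseSpec(target_snr_db=target, mix="both")
        realized = []
        for seed in range(10):
            noisy = add_noise(signal, spec, seed=seed)
            realized.append(snr_db(signal.data, noisy.data - signal.data))
        assert abs(np.mean(realized) - target) < 0.5

    def test_gaussian_sd_zero_is_identity(self, signal):
        spec = NoiseSpec(target_snr_db=None, mix="gaussian", gaussian_sd=0.0)
        out = add_noise(signal, spec, seed=0)
        np.testing.assert_array_equal(out.data, signal.data)

    def test_same_seed_same_noise(self, signal):
        spec = NoiseSpec(target_snr_db=5.0, mix="both")
        a = add_noise(signal, spec, seed=3)
        b = add_noise(signal, spec, seed=3)
        np.testing.assert_array_equal(a.data, b.data)

    def test_unreachable_target_raises(self, signal):
        # huge target SNR: shot noise alone exceeds the allowed noise budget
        spec = NoiseSpec(target_snr_db=80.0, mix="both")
        with pytest.raises(ValueError, match="unreachable"):
            add_noise(signal, spec, seed=0)


class TestDataset:
    def test_layout_and_manifest(self, tmp_path):
        pspec = PhantomSpec(dims=(24, 24, 24), n_spheres=2, n_shells=2, n_dots=4)
        mpath = make_dataset(3, pspec, PsfSpec(kind="isotropic-gaussian"),
                             None, seed=5, out_dir=tmp_path / "ds")
        man = json.loads(mpath.read_text())
        assert man["n_pairs"] == 3 and len(man["pairs"]) == 3
        gts = sorted((tmp_path / "ds" / "gt").glob("*.tif"))
        inps = sorted((tmp_path / "ds" / "input").glob("*.tif"))
        assert len(gts) == 3 and len(inps) == 3

    def test_noiseless_input_is_exact_blur(self, tmp_path):
        pspec = PhantomSpec(dims=(24, 24, 24), n_spheres=2, n_shells=0, n_dots=2)
        psf_spec = PsfSpec(kind="isotropic-gaussian")
        mpath = make_dataset(1, pspec, psf_spec, None, seed=2, out_dir=tmp_path / "ds")
        man = json.loads(mpath.read_text())
        gt = read_volume(tmp_path / "ds" / "gt" / "000.tif")
        inp = read_volume(tmp_path / "ds" / "input" / "000.tif")
        np.testing.assert_array_equal(inp.data, blur(gt, make_psf(psf_spec)).data)

    def test_regeneration_from_manifest_seeds_is_identical(self, tmp_path):
        from rlnet.phantoms import simulate_pair
        pspec = PhantomSpec(dims=(24, 24, 24), n_spheres=2, n_shells=1, n_dots=3)
        psf_spec = PsfSpec(kind="isotropic-gaussian")
        nspec = NoiseSpec(target_snr_db=8.0, mix="both")
        mpath = make_dataset(2, pspec, psf_spec, nspec, seed=17, out_dir=tmp_path / "ds")
        man = json.loads(mpath.read_text())
        for entry in man["pairs"]:
            pair = simulate_pair(pspec, psf_spec, nspec,
                                 gen_seed=entry["gen_seed"],
                                 noise_seed=entry["noise_seed"])
            stored = read_volume(tmp_path / "ds" / "input" / entry["input"])
            np.testing.assert_array_equal(pair.input.data, stored.data)
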