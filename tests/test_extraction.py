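"""Flipping, smoothing, reference normalization, label-wise averaging."""

import numpy as np
import pytest
from scipy import ndimage

import metacov as mc
from metacov.extraction import (
    SubjectImage,
    extract_uptake,
    flip_lr,
    normalize_to_reference,
    smooth,
)
from metacov.synthetic import PhantomSpec


def _img(data, affine="iso", subject_id="s1", focus_side="none"):
    if affine == "iso":
        affine = np.diag([2.0, 2.0, 2.0, 1.0])
    return SubjectImage(np.asarray(data, dtype=float), affine, subject_id, focus_side)


class TestFlip:
    def test_involution_is_bit_identical(self, rng):
        data = rng.random((6, 5, 4))
        once = flip_lr(_img(data, focus_side="right"))
        twice = flip_lr(SubjectImage(once.data, once.affine, "s1", "right"))
        assert np.array_equal(twice.data, data)

    def test_left_focus_is_noop(self, rng):
        data = rng.random((4, 4, 4))
        img = _img(data, focus_side="left")
        assert flip_lr(img) is img

    def test_flip_moves_right_block_to_left(self):
        """Phantom with value 2 on the right half, 1 on the left: after the
        flip the left half reads 2."""
        data = np.ones((8, 4, 4))
        data[4:, :, :] = 2.0
        out = flip_lr(_img(data, focus_side="right"))
        assert out.data[:4].mean() == pytest.approx(2.0)
        assert out.data[4:].mean() == pytest.approx(1.0)

    def test_missing_affine_raises(self):
        img = SubjectImage(np.zeros((3, 3, 3)), None, "s1", "right")
        with pytest.raises(ValueError, match="orientation"):
            flip_lr(img)

    def test_non_lr_first_axis_raises(self):
        # first voxel axis maps to anatomical anterior-posterior
        affine = np.array(
            [[0.0, 2.0, 0.0, 0.0],
             [2.0, 0.0, 0.0, 0.0],
             [0.0, 0.0, 2.0, 0.0],
             [0.0, 0.0, 0.0, 1.0]]
        )
        img = SubjectImage(np.zeros((3, 3, 3)), affine, "s1", "right")
        with pytest.raises(ValueError, match="left-right"):
            flip_lr(img)


class TestSmooth:
    def test_constant_volume_unchanged(self):
        img = _img(np.full((8, 8, 8), 3.3))
        out = smooth(img, 5.0)
        assert np.allclose(out.data, 3.3, atol=1e-10)

    def test_interior_blob_mass_preserved(self):
        data = np.zeros((24, 24, 24))
        data[10:14, 10:14, 10:14] = 1.0
        out = smooth(_img(data), 5.0)
        assert out.data.sum() == pytest.approx(data.sum(), rel=1e-3)

    def test_peak_matches_direct_convolution(self):
        """Single interior unit voxel vs. a brute-force discrete Gaussian kernel."""
        data = np.zeros((21, 21, 21))
        data[10, 10, 10] = 1.0
        fwhm_vox = 2.0
        voxel_mm = 2.0
        out = smooth(_img(data), fwhm_mm=fwhm_vox * voxel_mm)
        sigma = fwhm_vox / (2 * np.sqrt(2 * np.log(2)))
        # scipy.ndimage truncates at 4 sigma by default; build the same kernel
        radius = int(4 * sigma + 0.5)
        x = np.arange(-radius, radius + 1)
        k1 = np.exp(-0.5 * (x / sigma) ** 2)
        k1 /= k1.sum()
        kernel = k1[:, None, None] * k1[None, :, None] * k1[None, None, :]
        assert out.data[10, 10, 10] == pytest.approx(kernel[radius, radius, radius], abs=1e-12)

    def test_requires_voxel_metadata(self):
        img = SubjectImage(np.zeros((4, 4, 4)), None)
        with pytest.raises(ValueError, match="metadata"):
            smooth(img, 5.0)

    def test_nonpositive_fwhm_rejected(self):
        with pytest.raises(ValueError):
            smooth(_img(np.zeros((4, 4, 4))), 0.0)


class TestNormalize:
    def _setup(self, rng):
        data = rng.random((6, 6, 6)) + 0.5
        labels = np.zeros((6, 6, 6), dtype=int)
        labels[:2] = 1
        labels[4:] = 9
        return data, labels

    def test_reference_mean_becomes_one(self, rng):
        data, labels = self._setup(rng)
        out = normalize_to_reference(_img(data), labels, 9)
        assert out.data[labels == 9].mean() == pytest.approx(1.0, abs=1e-12)

    def test_global_scaling_invariance(self, rng):
        data, labels = self._setup(rng)
        a = normalize_to_reference(_img(data), labels, 9)
        b = normalize_to_reference(_img(data * 3.7), labels, 9)
        assert np.allclose(a.data, b.data, atol=1e-12)

    def test_zero_reference_mean_raises(self):
        labels = np.zeros((4, 4, 4), dtype=int)
        labels[0] = 7
        data = np.zeros((4, 4, 4))
        with pytest.raises(ValueError, match="positive"):
            normalize_to_reference(_img(data), labels, 7)

    def test_empty_reference_raises(self, rng):
        data, labels = self._setup(rng)
        with pytest.raises(ValueError, match="no voxels"):
            normalize_to_reference(_img(data), labels, 42)


class TestExtract:
    def test_noiseless_round_trip(self):
        t = mc.make_region_table(3, 1, 1)
        spec = PhantomSpec(grid_shape=(8, 8, 8), block_shape=(2, 2, 2))
        row = np.array([0.7, 0.9, 1.1, 1.3, 1.5])
        img, lab = mc.simulate_phantom(t, row, spec)
        labels = np.asarray(lab.get_fdata()).astype(int)
        si = _img(np.asarray(img.get_fdata()), subject_id="p1")
        up = extract_uptake([si], labels, t)
        assert np.allclose(up.loc["p1"].to_numpy(), row)

    def test_noisy_recovery_within_standard_error(self):
        t = mc.make_region_table(1, 1, 1)
        spec = PhantomSpec(
            grid_shape=(10, 10, 30), block_shape=(10, 10, 10), voxel_noise_sd=0.1, seed=8
        )
        row = np.array([1.0, 1.2, 0.8])
        img, lab = mc.simulate_phantom(t, row, spec)
        up = extract_uptake(
            [_img(np.asarray(img.get_fdata()))],
            np.asarray(lab.get_fdata()).astype(int),
            t,
        )
        assert np.allclose(up.iloc[0].to_numpy(), row, atol=0.02)

    def test_missing_region_raises(self, rng):
        t = mc.make_region_table(2, 1, 1)
        labels = np.zeros((4, 4, 4), dtype=int)
        labels[0] = 1  # only region 1 present
        with pytest.raises(ValueError, match="no voxels"):
            extract_uptake([_img(rng.random((4, 4, 4)))], labels, t)

    def test_column_order_follows_table(self):
        t = mc.make_region_table(3, 1, 1)
        spec = PhantomSpec(grid_shape=(8, 8, 8), block_shape=(2, 2, 2))
        img, lab = mc.simulate_phantom(t, np.ones(5), spec)
        up = extract_uptake(
            [_img(np.asarray(img.get_fdata()))],
            np.asarray(lab.get_fdata()).astype(int),
            t,
        )
        assert list(up.columns) == t.node_names

    def test_flip_extraction_equivariance(self):
        """Extracting a mirrored phantom equals extracting the original with
        left/right region columns swapped."""
        t = mc.make_region_table(2, 1, 1)
        # blocks placed mirror-symmetrically about the first-axis midline
        spec = PhantomSpec(
            grid_shape=(8, 4, 4),
            block_shape=(2, 2, 2),
            block_origins={1: (0, 0, 0), 2: (6, 0, 0), 3: (0, 2, 2), 4: (6, 2, 2)},
        )
        row = np.array([1.0, 2.0, 3.0, 4.0])
        img, lab = mc.simulate_phantom(t, row, spec)
        labels = np.asarray(lab.get_fdata()).astype(int)
        data = np.asarray(img.get_fdata())
        plain = extract_uptake([_img(data)], labels, t)
        flipped = flip_lr(_img(data, focus_side="right"))
        mirrored = extract_uptake([flipped], labels, t)
        # regions (1,2) and (3,4) are mirror pairs
        assert mirrored.iloc[0, 0] == pytest.approx(plain.iloc[0, 1])
        assert mirrored.iloc[0, 1] == pytest.approx(plain.iloc[0, 0])
        assert mirrored.iloc[0, 2] == pytest.approx(plain.iloc[0, 3])
        assert mirrored.iloc[0, 3] == pytest.approx(plain.iloc[0, 2])

    def test_shape_mismatch_raises(self, rng):
        t = mc.make_region_table(1, 1, 1)
        labels = np.ones((4, 4, 4), dtype=int)
        labels[1] = 2
        labels[2] = 3
        with pytest.raises(ValueError, match="shape"):
            extract_uptake([_img(rng.random((5, 4, 4)))], labels, t)
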