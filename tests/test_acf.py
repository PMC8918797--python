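"""Autocorrelation: FFT vs direct-sum oracle, normalisation, radial averaging."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import nucquant as nq
from nucquant.acf import AcfError, acf_curves_by_nucleus

from _oracle import direct_masked_acf


def _random_instance(rng, masked=True):
    ny, nx = rng.integers(8, 17, size=2)
    plane = rng.random((ny, nx))
    if masked:
        mask = rng.random((ny, nx)) > 0.3
        if mask.sum() < 16:
            mask[:] = True
    else:
        mask = np.ones((ny, nx), dtype=bool)
    return plane, mask


@pytest.mark.parametrize("masked", [True, False])
def test_fft_matches_direct_sum_oracle(rng, masked):
    """FFT path reproduces the direct double sum on random small instances."""
    for _ in range(15):
        plane, mask = _random_instance(rng, masked)
        corr, counts = nq.acf_2d(plane, mask, min_pair_count=1)
        ref, ref_counts = direct_masked_acf(plane, mask)
        assert np.array_equal(counts, ref_counts)
        both = np.isfinite(ref) & (ref_counts > 0)
        assert np.array_equal(np.isfinite(corr), both)
        rel = np.max(np.abs(corr[both] - ref[both])) / np.max(np.abs(ref[both]))
        assert rel < 1e-10


def test_single_bright_voxel_matches_oracle(rng):
    """The 4x4 single-bright-voxel field, full mask, matches the direct sum."""
    plane = np.zeros((4, 4))
    plane[1, 2] = 1.0
    corr, counts = nq.acf_2d(plane, min_pair_count=1, min_mask_voxels=1)
    ref, _ = direct_masked_acf(plane, np.ones((4, 4), bool))
    ok = np.isfinite(ref)
    assert np.allclose(corr[ok], ref[ok], rtol=1e-10, atol=1e-12)


def test_zero_shift_is_exactly_one_and_bounded(rng):
    """C(0) = 1 exactly; |C| stays within 1 at adequately sampled shifts."""
    for _ in range(10):
        plane = rng.normal(2.0, 0.5, size=(48, 48))
        mask = np.hypot(*np.ogrid[-24:24, -24:24]) < 20
        corr, counts = nq.acf_2d(plane, mask, min_pair_count=32)
        assert corr[47, 47] == 1.0
        finite = np.isfinite(corr)
        assert np.nanmax(np.abs(corr[finite])) <= 1.0 + 1e-9


@given(a=st.floats(0.1, 50.0), b=st.floats(-10.0, 10.0))
def test_affine_intensity_invariance(a, b):
    """ACF of a*I + b equals ACF of I for a > 0 (scale/offset free)."""
    rng = np.random.default_rng(7)
    plane = rng.random((16, 16))
    mask = rng.random((16, 16)) > 0.25
    c1, _ = nq.acf_2d(plane, mask, min_pair_count=1)
    c2, _ = nq.acf_2d(a * plane + b, mask, min_pair_count=1)
    ok = np.isfinite(c1)
    assert np.allclose(c1[ok], c2[ok], atol=1e-9)


def test_constant_image_raises():
    with pytest.raises(AcfError, match="zero variance"):
        nq.acf_2d(np.full((16, 16), 3.0))


def test_small_mask_raises():
    plane = np.random.default_rng(0).random((16, 16))
    mask = np.zeros((16, 16), bool)
    mask[0, :4] = True
    with pytest.raises(AcfError, match="mask too small"):
        nq.acf_2d(plane, mask)


def test_iid_noise_decorrelates(rng):
    """i.i.d. noise: |C(d)| < 4/sqrt(N(d)) at a spread of nonzero shifts."""
    plane = rng.standard_normal((256, 256))
    corr, counts = nq.acf_2d(plane, min_pair_count=100)
    ctr = 255
    shifts = [(0, 1), (1, 0), (1, 1), (3, 3), (5, 0), (0, 7), (10, 10),
              (20, 1), (50, 3), (0, 100), (128, 128), (200, 0)]
    for dy, dx in shifts:
        n = counts[ctr + dy, ctr + dx]
        assert abs(corr[ctr + dy, ctr + dx]) < 4.0 / np.sqrt(n)


class TestRadialAverage:
    def test_hand_computed_three_by_three(self):
        """3x3 field with distinct centre/edge/corner values: centre bin is the
        centre value, 1-px bin the mean of 4 edges, sqrt(2)-px bin the mean of
        4 corners, with the bin radii landing exactly at 0, 1 and sqrt(2) px."""
        f = np.array([[1.0, 5.0, 2.0], [6.0, 9.0, 7.0], [3.0, 8.0, 4.0]])
        curve = nq.radial_average(f, pixel_size=1.0, bin_width=0.4)
        assert np.allclose(curve.radii, [0.0, 1.0, np.sqrt(2.0)])
        assert np.allclose(curve.values, [9.0, (5 + 6 + 7 + 8) / 4, (1 + 2 + 3 + 4) / 4])
        assert np.array_equal(curve.counts, [1, 4, 4])

    def test_rotationally_symmetric_field(self):
        """A radially symmetric input reproduces its radial section."""
        # bins narrow enough that each distinct lattice distance gets its own bin
        y, x = np.ogrid[-4:5, -4:5]
        r = np.hypot(y, x)
        field = np.exp(-(r**2) / 50.0)
        curve = nq.radial_average(field, pixel_size=1.0, bin_width=0.05)
        assert np.allclose(curve.values, np.exp(-(curve.radii**2) / 50.0), atol=1e-12)

    def test_zero_radius_bin_is_origin_value(self, rng):
        field = rng.random((9, 9))
        curve = nq.radial_average(field, pixel_size=1.0, bin_width=1.0)
        assert curve.values[0] == field[4, 4]
        assert curve.radii[0] == 0.0

    def test_weighting_by_counts(self):
        """Bin values are pair-count-weighted means, not plain means."""
        field = np.array([[np.nan, 2.0, np.nan], [4.0, 1.0, 8.0], [np.nan, 6.0, np.nan]])
        counts = np.array([[0, 1, 0], [3, 1, 1], [0, 1, 0]])
        curve = nq.radial_average(field, 1.0, 1.0, counts=counts)
        assert curve.values[1] == pytest.approx((2 + 4 * 3 + 8 + 6) / 6)


class TestStackCurves:
    def test_single_nucleus_reduction(self):
        """With one nucleus the stack curve equals radial_average(acf_2d(...))."""
        rng = np.random.default_rng(3)
        plane = rng.random((64, 64))
        mask = np.hypot(*np.ogrid[-32:32, -32:32]) < 25
        data = np.zeros((2, 1, 64, 64))
        data[0, 0] = mask
        data[1, 0] = plane
        stack = nq.ImageStack(data, (190.0, 42.5, 42.5), ["nuclei", "mark"])
        labels = nq.NucleusLabelMap(mask[None].astype(np.int32), (190.0, 42.5, 42.5))
        curve = nq.acf_curve_for_stack(stack, "mark", labels, max_radius=800.0)
        corr, cnt = nq.acf_2d(plane, mask, min_pair_count=16)
        direct = nq.radial_average(corr, 42.5, counts=cnt, max_radius=800.0)
        assert np.allclose(curve.values, direct.values)
        assert curve.n_regions == 1

    def test_grf_correlation_length_recovered(self):
        """GRF scene with known kernel width: fitted ell within 10%."""
        params = nq.SceneParams(field_shape=(1, 512, 512), voxel_size=(190.0, 42.5, 42.5),
                                n_nuclei=1, nucleus_radius=30000.0, nucleus_radius_sd=1.0,
                                mark_mode="grf", grf_kernel_sigma=300.0, seed=5)
        stack, truth = nq.generate_scene(params)
        corr, cnt = nq.acf_2d(stack.channel("mark")[0], min_pair_count=1000)
        curve = nq.radial_average(corr, 42.5, counts=cnt, max_radius=1500.0)
        ell = nq.fit_correlation_length(curve)
        assert abs(ell - truth.true_correlation_length) / 300.0 < 0.10

    def test_heterogeneous_above_uniform(self, stage_scene_pair):
        """GRF (300 nm kernel) scenes sit strictly above uniform scenes at
        every radius in [100, 600] nm — the heterogeneity ordering."""
        (stack_u, truth_u), (stack_g, truth_g) = stage_scene_pair
        cu = nq.acf_curve_for_stack(stack_u, "mark", truth_u.label_map, max_radius=900.0)
        cg = nq.acf_curve_for_stack(stack_g, "mark", truth_g.label_map, max_radius=900.0)
        sel = (cu.radii >= 100) & (cu.radii <= 600)
        assert np.all(cg.values[sel] > cu.values[sel])

    def test_all_nuclei_rejected_raises(self):
        data = np.zeros((2, 1, 32, 32))
        data[1, 0] = np.random.default_rng(0).random((32, 32))
        stack = nq.ImageStack(data, (190.0, 42.5, 42.5), ["nuclei", "mark"])
        labels = nq.NucleusLabelMap(np.zeros((1, 32, 32), np.int32), (190.0, 42.5, 42.5))
        with pytest.raises(AcfError, match="no nucleus"):
            nq.acf_curve_for_stack(stack, "mark", labels)


def test_heterogeneity_monotone_in_blob_load():
    """ACF at 200 nm is non-decreasing in blob density x blob size (3-point
    sweep, 3-s.e. margin across nuclei)."""
    means, ses = [], []
    for dens, sig in [(0.1, 150.0), (0.3, 250.0), (1.0, 350.0)]:
        stack, truth = nq.generate_scene(nq.SceneParams(
            field_shape=(5, 512, 512), voxel_size=(300.0, 85.0, 85.0),
            n_nuclei=10, nucleus_radius=2500.0, nucleus_radius_sd=100.0,
            mark_mode="blobs", blob_density=dens, blob_sigma=sig, blob_amplitude=1.5,
            photon_scale=200.0, seed=31))
        per = acf_curves_by_nucleus(stack, "mark", truth.label_map, max_radius=600.0)
        v = np.array([c.value_at(200.0) for c in per.values()])
        means.append(v.mean())
        ses.append(v.std(ddof=1) / np.sqrt(len(v)))
    assert means[1] > means[0] - 3 * np.hypot(ses[0], ses[1])
    assert means[2] > means[1] - 3 * np.hypot(ses[1], ses[2])
    assert means[2] > means[0] + 3 * np.hypot(ses[0], ses[2])
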