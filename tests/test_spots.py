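"""Site detection and max-normalised radial profiles."""

import numpy as np
import pytest

import nucquant as nq
from nucquant.spots import (SiteNearBorderError, SpotError, aggregate_profiles,
                            profiles_for_sites, radial_profile_at_site)

VS = (300.0, 85.0, 85.0)


def _flat_mark_stack(shape=(5, 96, 96), mark_value=3.0, spots=None):
    """Stack with a uniform mark and optional Gaussian spots [(z,y,x nm, amp, sigma)]."""
    data = np.zeros((3,) + shape)
    data[0] = 1.0
    data[1] = mark_value
    vs = np.asarray(VS)
    grids = np.meshgrid(*(np.arange(s) * v for s, v in zip(shape, vs)), indexing="ij")
    for (c, amp, sig) in spots or []:
        d2 = sum((g - cc) ** 2 for g, cc in zip(grids, c))
        data[2] += amp * np.exp(-d2 / (2 * sig**2))
    return nq.ImageStack(data, VS, ["nuclei", "mark", "spots"])


def _full_labels(shape=(5, 96, 96)):
    return nq.NucleusLabelMap(np.ones(shape, np.int32), VS)


def _site(z=600.0, y=4000.0, x=4000.0):
    return nq.TranscriptionSite(nucleus_id=1, centroid_nm=(z, y, x), peak_intensity=5.0, site_id=1)


class TestDetect:
    def test_blank_channel_empty_list(self):
        stack = _flat_mark_stack()
        assert nq.detect_sites(stack, "spots", _full_labels()) == []

    def test_recall_precision_on_synthetic_scene(self):
        """spot_fraction 0.5, moderate noise: recall and precision >= 0.95,
        centroid error < 1 lateral voxel equivalent."""
        params = nq.SceneParams(field_shape=(7, 512, 512), voxel_size=VS, n_nuclei=30,
                                nucleus_radius=2000.0, nucleus_radius_sd=120.0,
                                spot_fraction=0.5, spot_intensity_mean=5.0,
                                photon_scale=100.0, read_noise_sd=0.02, seed=17)
        stack, truth = nq.generate_scene(params)
        sites = nq.detect_sites(stack, "spots", truth.label_map, log_sigma=120.0)
        gt = truth.site_positions_nm()
        det = np.array([s.centroid_nm for s in sites]).reshape(-1, 3)
        d = np.linalg.norm(det[:, None, :] - gt[None, :, :], axis=2)
        matched_det = (d.min(axis=1) < 3 * 85.0)
        matched_gt = (d.min(axis=0) < 3 * 85.0)
        assert matched_gt.mean() >= 0.95   # recall
        assert matched_det.mean() >= 0.95  # precision
        lateral_err = np.linalg.norm((det[:, 1:][:, None, :] - gt[None, :, 1:]), axis=2).min(axis=1)
        assert np.median(lateral_err) < 85.0

    def test_one_site_per_nucleus_brighter_wins(self):
        """Two planted maxima (2:1) in one nucleus: only the brighter reported."""
        bright = np.array([600.0, 3000.0, 3000.0])
        dim = np.array([600.0, 5000.0, 5000.0])
        stack = _flat_mark_stack(spots=[(bright, 10.0, 150.0), (dim, 5.0, 150.0)])
        sites = nq.detect_sites(stack, "spots", _full_labels(), log_sigma=150.0, threshold=3.0)
        assert len(sites) == 1
        assert np.allclose(sites[0].centroid_nm, bright, atol=150.0)

    def test_empty_labels_raise(self):
        stack = _flat_mark_stack()
        empty = nq.NucleusLabelMap(np.zeros((5, 96, 96), np.int32), VS)
        with pytest.raises(SpotError, match="no nuclei"):
            nq.detect_sites(stack, "spots", empty)


class TestRadialProfile:
    def test_flat_field_gives_all_ones(self):
        prof = radial_profile_at_site(_site(), _flat_mark_stack(), "mark",
                                      max_radius=600.0, bin_width=100.0)
        assert np.all(prof.values == 1.0)

    def test_planted_gaussian_recovered_within_two_percent(self):
        """mark = 1 + exp(-r^2/(2 sigma^2)) planted in the site's plane, noise
        off: normalized profile matches the planted form per bin within 2%."""
        shape = (5, 256, 256)
        vs = (300.0, 42.5, 42.5)
        sigma = 200.0
        site = nq.TranscriptionSite(1, (600.0, 128 * 42.5, 128 * 42.5), 5.0, site_id=1)
        data = np.zeros((2,) + shape)
        data[0] = 1.0
        grids = np.meshgrid(*(np.arange(s) * v for s, v in zip(shape, vs)), indexing="ij")
        d2 = sum((g - c) ** 2 for g, c in zip(grids, site.centroid_nm))
        data[1] = 1.0 + np.exp(-d2 / (2 * sigma**2))
        stack = nq.ImageStack(data, vs, ["nuclei", "mark"])
        prof = radial_profile_at_site(site, stack, "mark", max_radius=800.0, bin_width=42.5)
        planted = 1.0 + np.exp(-prof.radii**2 / (2 * sigma**2))
        planted /= planted.max()
        assert np.all(np.abs(prof.values - planted) / planted < 0.02)

    def test_central_depletion_peak_off_origin(self):
        """Planted dip: the profile maximum is 1 at r > 0 and the value at the
        origin stays below 1."""
        shape = (5, 256, 256)
        vs = (300.0, 42.5, 42.5)
        site = nq.TranscriptionSite(1, (600.0, 128 * 42.5, 128 * 42.5), 5.0, site_id=1)
        data = np.ones((2,) + shape)
        grids = np.meshgrid(*(np.arange(s) * v for s, v in zip(shape, vs)), indexing="ij")
        d2 = sum((g - c) ** 2 for g, c in zip(grids, site.centroid_nm))
        data[1] = 1.0 - 0.5 * np.exp(-d2 / (2 * 200.0**2))
        stack = nq.ImageStack(data, vs, ["nuclei", "mark"])
        prof = radial_profile_at_site(site, stack, "mark", max_radius=800.0, bin_width=42.5)
        assert prof.values.max() == 1.0
        assert prof.radii[prof.values.argmax()] > 0
        assert prof.values[0] < 1.0

    def test_max_is_exactly_one(self):
        rng = np.random.default_rng(2)
        stack = _flat_mark_stack()
        stack.data[1] += rng.random(stack.data[1].shape)
        prof = radial_profile_at_site(_site(), stack, "mark", max_radius=600.0, bin_width=85.0)
        assert prof.values.max() == 1.0

    def test_pure_rescaling_leaves_profile_unchanged(self):
        """Multiplying the mark by a positive constant does not change the
        max-normalised profile (additive offsets do, by design)."""
        rng = np.random.default_rng(3)
        stack = _flat_mark_stack()
        stack.data[1] += rng.random(stack.data[1].shape)
        scaled = nq.ImageStack(stack.data * np.array([1, 7.3, 1])[:, None, None, None],
                               VS, stack.channel_names)
        p1 = radial_profile_at_site(_site(), stack, "mark", 600.0, 85.0)
        p2 = radial_profile_at_site(_site(), scaled, "mark", 600.0, 85.0)
        assert np.allclose(p1.values, p2.values, atol=1e-9)

    def test_border_site_excluded_with_reason(self):
        stack = _flat_mark_stack()
        near_border = nq.TranscriptionSite(1, (600.0, 200.0, 4000.0), 5.0, site_id=9)
        with pytest.raises(SiteNearBorderError, match="site 9"):
            radial_profile_at_site(near_border, stack, "mark", 600.0, 85.0)
        profiles, excluded = profiles_for_sites([near_border, _site()], stack, "mark",
                                                600.0, 85.0)
        assert len(profiles) == 1
        assert excluded[0]["site_id"] == 9


class TestAggregate:
    def test_single_profile_identity(self):
        p = nq.radial_profile_at_site(_site(), _flat_mark_stack(), "mark", 600.0, 100.0)
        agg = aggregate_profiles([p])
        assert np.array_equal(agg.mean, p.values)
        assert np.all(agg.variance == 0.0)
        assert agg.n_sites == 1

    def test_two_profile_arithmetic(self):
        from nucquant.spots import SiteProfile

        r = np.array([50.0, 150.0])
        a = SiteProfile(1, r, np.array([0.5, 1.0]))
        b = SiteProfile(2, r, np.array([1.0, 1.0]))
        agg = aggregate_profiles([a, b])
        assert np.allclose(agg.mean, [0.75, 1.0])
        assert np.allclose(agg.variance, [0.0625, 0.0])  # population variance

    def test_inconsistent_binning_rejected(self):
        from nucquant.spots import SiteProfile

        a = SiteProfile(1, np.array([50.0, 150.0]), np.array([1.0, 0.5]))
        b = SiteProfile(2, np.array([42.5, 127.5]), np.array([1.0, 0.5]))
        with pytest.raises(SpotError, match="binning"):
            aggregate_profiles([a, b])


class TestSiteIntensity:
    def test_uniform_field_returns_value(self):
        v = nq.site_mark_intensity(_site(), _flat_mark_stack(mark_value=3.25), "mark",
                                   aperture_radius=300.0)
        assert v == pytest.approx(3.25)

    def test_planted_enrichment_read_through_small_aperture(self):
        """2x enrichment, aperture much smaller than the enrichment width:
        reads ~2x background within 5%."""
        shape = (5, 128, 128)
        site = _site(600.0, 64 * 85.0, 64 * 85.0)
        stack = _flat_mark_stack(shape, mark_value=1.0)
        grids = np.meshgrid(*(np.arange(s) * v for s, v in zip(shape, VS)), indexing="ij")
        d2 = sum((g - c) ** 2 for g, c in zip(grids, site.centroid_nm))
        stack.data[1] = 1.0 + 1.0 * np.exp(-d2 / (2 * 600.0**2))
        v = nq.site_mark_intensity(site, stack, "mark", aperture_radius=120.0)
        assert v == pytest.approx(2.0, rel=0.05)

    def test_clipped_aperture_excluded(self):
        site = nq.TranscriptionSite(1, (600.0, 100.0, 4000.0), 5.0, site_id=3)
        with pytest.raises(SiteNearBorderError, match="aperture"):
            nq.site_mark_intensity(site, _flat_mark_stack(), "mark", aperture_radius=300.0)


def test_stage_contrast_recovered(enrichment_scene_pair):
    """Two-condition experiment: amplitude 1.2 vs 1.8 enrichment of the mark;
    the aggregate profiles at r=0 separate in the planted direction with
    non-overlapping 3-s.e.m. bands."""
    noisy18, _, truth = enrichment_scene_pair
    params12 = nq.SceneParams(
        field_shape=(7, 768, 768), voxel_size=(300.0, 85.0, 85.0),
        n_nuclei=110, nucleus_radius=1800.0, nucleus_radius_sd=100.0, min_gap=250.0,
        mark_mode="uniform", spot_fraction=1.0, enrichment_amplitude=1.2,
        enrichment_sigma=200.0, spot_intensity_mean=5.0, photon_scale=500.0, seed=12)
    noisy12, truth12 = nq.generate_scene(params12)

    def aggregate(stack, labmap):
        sites = nq.detect_sites(stack, "spots", labmap, log_sigma=120.0)
        profs, _ = profiles_for_sites(sites, stack, "mark", max_radius=600.0, bin_width=100.0)
        return aggregate_profiles(profs)

    hi = aggregate(noisy18, truth.label_map)
    lo = aggregate(noisy12, truth12.label_map)
    assert hi.n_sites >= 100 and lo.n_sites >= 100
    # normalized central value: strong enrichment concentrates the profile at r=0,
    # weak enrichment has relatively more weight at large radii
    k = len(hi.radii) - 1
    hi_tail, lo_tail = hi.mean[k], lo.mean[k]
    assert hi_tail + 3 * hi.sem()[k] < lo_tail - 3 * lo.sem()[k]
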