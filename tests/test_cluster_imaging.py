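"""Cluster segmentation/quantification tests against constructed and
generated ground truth."""

import numpy as np
import pandas as pd
import pytest
from scipy import ndimage as ndi
from scipy.stats import norm

from carscope.cluster_imaging import (
    ClusterTable,
    MembraneImage,
    SyntheticMembraneConfig,
    cluster_metrics,
    exclude_outlier_cells,
    generate_membrane_image,
    read_membrane_tiff,
    segment_clusters,
    write_membrane_tiff,
)


class TestOutlierExclusion:
    def test_identical_intensities_all_kept(self):
        keep = exclude_outlier_cells(np.full(12, 37.0))
        assert keep.all()

    def test_extreme_cell_excluded(self, rng):
        vals = np.exp(rng.normal(3.0, 0.4, size=20))
        vals = np.append(vals, np.median(vals) * 100)
        keep = exclude_outlier_cells(vals, k=2.5)
        assert not keep[-1]
        assert keep[:-1].sum() >= 18  # the bulk survives

    def test_expected_exclusion_fraction_matches_normal_tail(self, rng):
        """Lognormal sample: P(excluded) ~ 2 Phi(-2.5) ~ 1.24%."""
        vals = np.exp(rng.normal(2.0, 0.5, size=20000))
        keep = exclude_outlier_cells(vals, k=2.5)
        frac = 1 - keep.mean()
        assert frac == pytest.approx(2 * norm.cdf(-2.5), abs=0.005)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            exclude_outlier_cells([1.0, 2.0, 0.0, 3.0, 4.0])

    def test_too_few_cells_rejected(self):
        with pytest.raises(ValueError):
            exclude_outlier_cells([1.0, 2.0, 3.0])


def disc_image(centers, radius=6, value=100.0, shape=(120, 120), background=0.0):
    img = np.full(shape, background)
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    for cy, cx in centers:
        img[(yy - cy) ** 2 + (xx - cx) ** 2 <= radius**2] = value
    return img


class TestSegmentation:
    def test_five_separated_discs_give_five_labels(self):
        centers = [(20, 20), (20, 90), (60, 55), (100, 20), (100, 90)]
        image = MembraneImage(disc_image(centers), pixel_size=0.04)
        labels = segment_clusters(image, threshold_spec=50.0)
        assert labels.max() == 5

    def test_touching_spots_split_by_watershed(self):
        """Two Gaussian peaks with an above-threshold saddle: plain
        connected components would give one object, watershed two."""
        yy, xx = np.mgrid[0:80, 0:80]
        g1 = 100 * np.exp(-(((yy - 40) ** 2 + (xx - 34) ** 2) / (2 * 4.0**2)))
        g2 = 100 * np.exp(-(((yy - 40) ** 2 + (xx - 46) ** 2) / (2 * 4.0**2)))
        img = MembraneImage(g1 + g2, pixel_size=0.04)
        thr = 20.0
        n_connected = ndi.label(img.image > thr)[0].max()
        labels = segment_clusters(img, threshold_spec=thr, smooth_sigma=1.0)
        assert n_connected == 1
        assert labels.max() == 2

    def test_empty_foreground_gives_zero_map(self):
        image = MembraneImage(np.zeros((50, 50)), pixel_size=0.04)
        labels = segment_clusters(image, threshold_spec=10.0)
        assert labels.shape == (50, 50)
        assert labels.max() == 0

    def test_scale_invariance_with_relative_threshold(self):
        img, _ = generate_membrane_image(SyntheticMembraneConfig(n_clusters=20, seed=4))
        l1 = segment_clusters(img, threshold_spec="rise:0.5")
        scaled = MembraneImage(img.image * 3.7, pixel_size=img.pixel_size)
        l2 = segment_clusters(scaled, threshold_spec="rise:0.5")
        np.testing.assert_array_equal(l1 > 0, l2 > 0)

    def test_min_size_discards_specks(self):
        img = np.zeros((60, 60))
        img[10, 10] = 500.0  # single bright pixel
        img[40:48, 40:48] = 100.0
        image = MembraneImage(img, pixel_size=0.04)
        labels = segment_clusters(image, threshold_spec=50.0, min_size=4, smooth_sigma=0.5)
        areas = np.bincount(labels.ravel())[1:]
        assert (areas >= 4).all()


class TestClusterMetrics:
    def test_count_per_10um2_arithmetic(self):
        """12 clusters on a 30 um^2 mask -> 4.0 per 10 um^2."""
        pixel_size = 0.1  # 0.01 um^2/px
        n_px = 3000  # 30 um^2
        side = 100
        mask = np.zeros((side, side), dtype=bool)
        mask.ravel()[:n_px] = True
        labels = np.zeros((side, side), dtype=np.int32)
        for i in range(12):  # 12 disjoint 2x2 clusters inside the mask
            r, c = divmod(i, 6)
            labels[r * 4 : r * 4 + 2, c * 4 : c * 4 + 2] = i + 1
        image = MembraneImage(np.ones((side, side)), pixel_size=pixel_size, mask=mask)
        table = cluster_metrics(labels, image)
        assert table.n_clusters == 12
        assert table.count_per_10um2 == pytest.approx(4.0)

    def test_area_and_integrated_intensity_arithmetic(self):
        """10 px at value 7, pixel area 0.0016 um^2 -> area 0.016, integral 70."""
        img = np.zeros((20, 20))
        labels = np.zeros((20, 20), dtype=np.int32)
        img[5, 5:15] = 7.0
        labels[5, 5:15] = 1
        image = MembraneImage(img, pixel_size=0.04)
        table = cluster_metrics(labels, image)
        row = table.clusters.iloc[0]
        assert row["area_um2"] == pytest.approx(0.016)
        assert row["integrated_intensity"] == pytest.approx(70.0)

    def test_uniform_image_normalized_means_are_unity(self):
        img = np.full((40, 40), 11.0)
        labels = np.zeros((40, 40), dtype=np.int32)
        labels[5:15, 5:15] = 1  # arbitrary segmentation
        table = cluster_metrics(labels, MembraneImage(img, pixel_size=0.04))
        assert table.norm_mean_inside == pytest.approx(1.0)
        assert table.norm_mean_outside == pytest.approx(1.0)

    def test_intensity_conservation(self, rng):
        img, _ = generate_membrane_image(SyntheticMembraneConfig(n_clusters=30, seed=7))
        labels = segment_clusters(img, threshold_spec="rise:0.5")
        table = cluster_metrics(labels, img)
        inside_sum = table.clusters["integrated_intensity"].sum()
        outside_sum = img.image[(labels == 0) & img.mask].sum()
        assert inside_sum + outside_sum == pytest.approx(table.total_intensity)

    def test_inside_mean_not_below_outside_for_thresholded_segmentation(self):
        img, _ = generate_membrane_image(SyntheticMembraneConfig(n_clusters=30, seed=2))
        labels = segment_clusters(img, threshold_spec="rise:0.5")
        table = cluster_metrics(labels, img)
        assert table.norm_mean_inside >= table.norm_mean_outside

    def test_empty_mask_rejected(self):
        image = MembraneImage(
            np.ones((10, 10)), pixel_size=0.04, mask=np.zeros((10, 10), dtype=bool)
        )
        with pytest.raises(ValueError):
            cluster_metrics(np.zeros((10, 10), dtype=np.int32), image)


class TestGenerator:
    def test_zero_clusters_flat_background(self):
        cfg = SyntheticMembraneConfig(n_clusters=0, poisson_noise=False, seed=1)
        img, truth = generate_membrane_image(cfg)
        assert truth.empty
        expected = cfg.background + cfg.density_outside * cfg.pixel_size**2 * cfg.brightness
        np.testing.assert_allclose(img.image, expected, rtol=1e-6)

    def test_same_seed_identical_image(self):
        cfg = SyntheticMembraneConfig(n_clusters=15, seed=9)
        a, _ = generate_membrane_image(cfg)
        b, _ = generate_membrane_image(cfg)
        np.testing.assert_array_equal(a.image, b.image)

    def test_inside_footprint_brighter_matching_density_ratio(self):
        """Mean intensity deep inside cluster footprints matches the
        unblurred expectation within 15% (PSF bleeds only at edges)."""
        cfg = SyntheticMembraneConfig(n_clusters=25, seed=3)
        img, truth = generate_membrane_image(cfg)
        n = img.image.shape[0]
        yy, xx = np.mgrid[0:n, 0:n]
        xs, ys = (xx + 0.5) * cfg.pixel_size, (yy + 0.5) * cfg.pixel_size
        interior = np.zeros((n, n), dtype=bool)
        for _, row in truth.iterrows():
            shrunk = max(row.radius_um - 3 * cfg.psf_sigma, 0)
            if shrunk > 0:
                interior |= (
                    (xs - row.center_x_um) ** 2 + (ys - row.center_y_um) ** 2
                ) <= shrunk**2
        expected = cfg.background + cfg.density_inside * cfg.pixel_size**2 * cfg.brightness
        assert img.image[interior].mean() == pytest.approx(expected, rel=0.15)

    def test_overlap_rejection_gives_separated_clusters(self):
        cfg = SyntheticMembraneConfig(n_clusters=40, seed=5)
        _, truth = generate_membrane_image(cfg)
        xy = truth[["center_x_um", "center_y_um"]].to_numpy()
        r = truth["radius_um"].to_numpy()
        d = np.sqrt(((xy[:, None] - xy[None, :]) ** 2).sum(-1))
        sep = r[:, None] + r[None, :] + cfg.min_separation
        off_diag = ~np.eye(len(r), dtype=bool)
        assert (d[off_diag] >= sep[off_diag] - 1e-9).all()

    def test_infeasible_packing_raises(self):
        cfg = SyntheticMembraneConfig(
            field_size=2.0, n_clusters=200, radius_median=0.3, seed=0
        )
        with pytest.raises(RuntimeError, match="non-overlapping"):
            generate_membrane_image(cfg)

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            SyntheticMembraneConfig(density_inside=10.0, density_outside=20.0)


class TestPipelineRecovery:
    def test_count_recovery_within_ten_percent(self):
        cfg = SyntheticMembraneConfig(n_clusters=40, seed=1)
        img, truth = generate_membrane_image(cfg)
        labels = segment_clusters(img, threshold_spec="rise:0.5")
        table = cluster_metrics(labels, img)
        assert table.n_clusters == pytest.approx(len(truth), rel=0.10)

    def test_recovered_count_monotone_in_truth(self):
        recovered = []
        for n_true in (10, 40, 80):
            img, _ = generate_membrane_image(
                SyntheticMembraneConfig(n_clusters=n_true, seed=6)
            )
            labels = segment_clusters(img, threshold_spec="rise:0.5")
            recovered.append(cluster_metrics(labels, img).n_clusters)
        assert recovered[0] < recovered[1] < recovered[2]


class TestImageIO:
    def test_tiff_roundtrip(self, tmp_path):
        img, _ = generate_membrane_image(SyntheticMembraneConfig(n_clusters=5, seed=0))
        path = tmp_path / "membrane.tif"
        write_membrane_tiff(img, path)
        back = read_membrane_tiff(path, pixel_size=img.pixel_size)
        np.testing.assert_allclose(back.image, img.image, rtol=1e-6)
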