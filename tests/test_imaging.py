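"""Synthetic spheroid generation and the quantification pipeline."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.spatial import cKDTree

from pkchip.imaging import (
    SpheroidImage,
    count_positive,
    detect_nuclei,
    feret_diameters,
    generate_synthetic_spheroid,
    measure_spheroid,
    quantify_spheroid,
    segment_spheroid,
    spheroid_volume,
)


def disc_mask(radius_px: int, pad: int = 10) -> np.ndarray:
    n = 2 * (radius_px + pad) + 1
    yy, xx = np.mgrid[:n, :n] - (radius_px + pad)
    return yy**2 + xx**2 <= radius_px**2


def ellipse_mask(a_px: float, b_px: float, rotation_deg: float = 0.0, pad: int = 10):
    n = 2 * int(max(a_px, b_px) + pad) + 1
    c = n // 2
    yy, xx = (np.mgrid[:n, :n] - c).astype(float)
    th = math.radians(rotation_deg)
    u = yy * math.sin(th) + xx * math.cos(th)
    v = yy * math.cos(th) - xx * math.sin(th)
    return (u / a_px) ** 2 + (v / b_px) ** 2 <= 1.0


def match_stats(detected, truth, radius):
    tree = cKDTree(truth)
    d, idx = tree.query(detected)
    used, tp = set(), 0
    for di, ii in sorted(zip(d, idx)):
        if di <= radius and ii not in used:
            used.add(ii)
            tp += 1
    return tp / len(truth), tp / len(detected)


class TestGenerator:
    def test_fixed_seed_is_bitwise_reproducible(self):
        a = generate_synthetic_spheroid(seed=5, n_cells=50, radius_um=80.0)
        b = generate_synthetic_spheroid(seed=5, n_cells=50, radius_um=80.0)
        for name in a.channels:
            np.testing.assert_array_equal(a.channels[name], b.channels[name])
        np.testing.assert_array_equal(
            a.ground_truth["centroids"], b.ground_truth["centroids"]
        )

    def test_mask_area_close_to_analytic_disc(self):
        img = generate_synthetic_spheroid(radius_um=150.0, n_cells=20, seed=0)
        area = img.ground_truth["mask"].sum() * img.pixel_size**2
        assert area == pytest.approx(math.pi * 150.0**2, rel=0.02)

    def test_zero_fractions_leave_marker_channels_at_background(self):
        img = generate_synthetic_spheroid(
            n_cells=50, radius_um=80.0, noise_sd=2.0, seed=3
        )
        for marker in ("gammaH2AX", "CC3", "Ki67"):
            assert img.channels[marker].max() < 2.0 + 6 * 2.0
        assert img.channels["nuclei"].max() > 50.0

    def test_infeasible_packing_is_rejected(self):
        with pytest.raises(ValueError, match="infeasible"):
            generate_synthetic_spheroid(radius_um=30.0, n_cells=500, seed=0)

    def test_tiff_round_trip(self, tmp_path, synthetic_image):
        path = tmp_path / "spheroid.tif"
        synthetic_image.save(path)
        back = SpheroidImage.load(path)
        assert back.pixel_size == synthetic_image.pixel_size
        np.testing.assert_allclose(
            back.channels["nuclei"],
            synthetic_image.channels["nuclei"].astype(np.float32),
        )
        np.testing.assert_allclose(
            back.ground_truth["centroids"], synthetic_image.ground_truth["centroids"]
        )


class TestSegmentation:
    def test_high_overlap_with_ground_truth(self, synthetic_image):
        mask = segment_spheroid(synthetic_image.channels["brightfield"])
        gt = synthetic_image.ground_truth["mask"]
        iou = np.logical_and(mask, gt).sum() / np.logical_or(mask, gt).sum()
        assert iou >= 0.97

    def test_uniform_image_has_no_spheroid(self):
        with pytest.raises(ValueError, match="no spheroid detected"):
            segment_spheroid(np.full((64, 64), 7.0))

    def test_area_stable_under_added_noise(self, synthetic_image):
        bf = synthetic_image.channels["brightfield"]
        base_area = segment_spheroid(bf).sum()
        rng = np.random.default_rng(9)
        noisy = bf + rng.normal(0.0, 0.05 * np.ptp(bf), bf.shape)
        noisy_area = segment_spheroid(np.clip(noisy, 0, None)).sum()
        assert noisy_area == pytest.approx(base_area, rel=0.01)


class TestFeretAndVolume:
    def test_disc_diameters(self):
        fmin, fmax = feret_diameters(disc_mask(100), pixel_size=1.0)
        assert fmin == pytest.approx(200.0, rel=0.02)
        assert fmax == pytest.approx(200.0, rel=0.02)

    @pytest.mark.parametrize("rotation", [0.0, 37.0])
    def test_ellipse_extents_and_rotation_invariance(self, rotation):
        fmin, fmax = feret_diameters(ellipse_mask(100.0, 50.0, rotation))
        assert fmax == pytest.approx(200.0, rel=0.02)
        assert fmin == pytest.approx(100.0, rel=0.02)

    @given(
        seed=st.integers(0, 200),
        n_blobs=st.integers(1, 4),
    )
    def test_feret_min_never_exceeds_feret_max(self, seed, n_blobs):
        rng = np.random.default_rng(seed)
        mask = np.zeros((80, 80), dtype=bool)
        for _ in range(n_blobs):
            r, c = rng.integers(15, 65, 2)
            rad = rng.integers(3, 12)
            yy, xx = np.mgrid[:80, :80]
            mask |= (yy - r) ** 2 + (xx - c) ** 2 <= rad**2
        fmin, fmax = feret_diameters(mask)
        assert fmin <= fmax

    def test_single_pixel_mask_rejected(self):
        mask = np.zeros((10, 10), dtype=bool)
        mask[5, 5] = True
        with pytest.raises(ValueError):
            feret_diameters(mask)

    def test_sphere_volume_from_equal_ferets(self):
        assert spheroid_volume(200.0, 200.0) == pytest.approx(
            4.0 / 3.0 * math.pi * 100.0**3
        )

    def test_volume_scaling_law(self):
        assert spheroid_volume(400.0, 500.0) == pytest.approx(
            8.0 * spheroid_volume(200.0, 250.0)
        )

    def test_ellipse_average_radius_volume(self):
        assert spheroid_volume(100.0, 200.0) == pytest.approx(
            4.0 / 3.0 * math.pi * 75.0**3
        )

    @pytest.mark.parametrize("radius", [50.0, 100.0, 150.0, 200.0])
    def test_pipeline_recovers_analytic_sphere_volume(self, radius):
        m = measure_spheroid(disc_mask(int(radius)), pixel_size=1.0)
        assert m.volume == pytest.approx(4.0 / 3.0 * math.pi * radius**3, rel=0.05)

    def test_measurement_rotation_invariant(self):
        a = measure_spheroid(ellipse_mask(90.0, 60.0, 0.0), 1.0)
        b = measure_spheroid(ellipse_mask(90.0, 60.0, 55.0), 1.0)
        assert b.volume == pytest.approx(a.volume, rel=0.02)


class TestNucleiDetection:
    def test_recall_and_precision_against_ground_truth(self, synthetic_image):
        gt = synthetic_image.ground_truth
        mask = segment_spheroid(synthetic_image.channels["brightfield"])
        detected = detect_nuclei(synthetic_image.channels["nuclei"], mask)
        recall, precision = match_stats(
            detected, gt["centroids"], gt["nucleus_radius_um"]
        )
        assert recall >= 0.9
        assert precision >= 0.9

    def test_zero_signal_channel_yields_no_centroids(self, synthetic_image):
        mask = synthetic_image.ground_truth["mask"]
        flat = np.zeros(mask.shape)
        assert detect_nuclei(flat, mask).shape[0] == 0

    def test_counts_stable_across_seeds(self):
        counts = []
        for seed in (21, 22):
            img = generate_synthetic_spheroid(n_cells=200, seed=seed)
            mask = segment_spheroid(img.channels["brightfield"])
            counts.append(detect_nuclei(img.channels["nuclei"], mask).shape[0])
        assert abs(counts[0] - counts[1]) <= 0.05 * max(counts)


class TestPositiveCounting:
    def test_background_channel_scores_zero(self, synthetic_image):
        gt = synthetic_image.ground_truth
        rng = np.random.default_rng(2)
        flat = np.clip(rng.normal(0.0, 2.0, gt["mask"].shape), 0, None)
        counts = count_positive(
            gt["centroids"], {"gammaH2AX": flat, "Ki67": flat}, gt["mask"]
        )
        assert counts.positives["gammaH2AX"] == 0
        assert counts.density("gammaH2AX") == 0.0
        assert counts.ki67_fraction == 0.0

    def test_empty_centroid_list_gives_defined_zeros(self, synthetic_image):
        gt = synthetic_image.ground_truth
        counts = count_positive(
            np.empty((0, 2)), {"Ki67": synthetic_image.channels["Ki67"]}, gt["mask"]
        )
        assert counts.n_nuclei == 0
        assert counts.ki67_fraction == 0.0

    def test_ki67_fraction_recovered_within_five_points(self, synthetic_image):
        _, counts = quantify_spheroid(synthetic_image)
        assert counts.ki67_fraction == pytest.approx(0.3, abs=0.05)
        assert all(p <= counts.n_nuclei for p in counts.positives.values())

    def test_density_ratio_recovered_as_percent_change(self):
        """Two populations with true density ratio 5:1 read out as a ~400%
        increase."""
        densities = []
        for frac, seed in ((0.25, 31), (0.05, 32)):
            img = generate_synthetic_spheroid(
                n_cells=400, positive_fractions={"gammaH2AX": frac}, seed=seed
            )
            _, counts = quantify_spheroid(img)
            densities.append(counts.density("gammaH2AX"))
        change = 100.0 * (densities[0] - densities[1]) / densities[1]
        assert change == pytest.approx(400.0, abs=60.0)

    def test_density_scales_inversely_with_area(self):
        from pkchip.imaging import BiomarkerCounts

        small = BiomarkerCounts(100, {"CC3": 20}, spheroid_area=5e4)
        large = BiomarkerCounts(100, {"CC3": 20}, spheroid_area=1e5)
        assert small.density("CC3") == pytest.approx(2.0 * large.density("CC3"))
        with pytest.raises(ValueError):
            BiomarkerCounts(10, {"CC3": 11}, spheroid_area=1e4)
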