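"""Droplet detection, line profiles, partitioning, calibration, size fits."""

import numpy as np
import pytest

from condsurf.droplet_imaging import (
    DYNAMIC_RANGE,
    LineProfile,
    PartitionTriplet,
    detect_droplets,
    equilibrium_dilute_concentration,
    fit_standard_curve,
    interface_reduction,
    line_profile,
    partition_triplet,
    size_model,
    size_summary,
)
from condsurf.synthetic_data import GeneratorConfig, gen_droplet_image, gen_size_series


@pytest.fixture(scope="module")
def cfg():
    return GeneratorConfig(seed=1)


def test_blank_image_yields_no_detections(cfg):
    blank = np.zeros((200, 200), dtype=np.uint16)
    det = detect_droplets(blank, cfg.pixel_size, (0.5, 3.0))
    assert len(det) == 0


def test_single_disk_detected_within_one_pixel(cfg):
    """A plain bright disk of radius 20 px is found with radius error <= 1 px."""
    img = np.zeros((160, 160), dtype=float)
    yy, xx = np.mgrid[:160, :160]
    img[np.hypot(yy - 80, xx - 80) <= 20] = 0.6
    img16 = (img * DYNAMIC_RANGE).astype(np.uint16)
    det = detect_droplets(img16, 0.1, (1.0, 3.0))
    assert len(det) == 1
    assert det.radii_px[0] == pytest.approx(20.0, abs=1.0)
    assert np.hypot(*(det.centers[0] - 80.0)) < 2.0


def test_detection_translation_invariance(cfg):
    img, _ = gen_droplet_image(
        cfg.with_(radius_median=2.0, radius_sigma_log=0.1),
        n_droplets=3, shape=(320, 320), seed=8,
    )
    det = detect_droplets(img, cfg.pixel_size, (1.0, 3.5))
    shifted = np.roll(img, (7, -5), axis=(0, 1))
    det_s = detect_droplets(shifted, cfg.pixel_size, (1.0, 3.5))
    assert len(det) == len(det_s) == 3
    order = np.lexsort((det.centers[:, 1], det.centers[:, 0]))
    order_s = np.lexsort((det_s.centers[:, 1], det_s.centers[:, 0]))
    np.testing.assert_allclose(
        det_s.centers[order_s] - det.centers[order], [[7.0, -5.0]] * 3, atol=1.01
    )
    np.testing.assert_allclose(det_s.radii[order_s], det.radii[order], rtol=0.02)


def test_detection_population_median_and_match_rate(cfg):
    """>= 200 lognormal core-shell droplets: median radius within 10% of
    the generating median; >= 90% recovered within 15% radius error."""
    img, truth = gen_droplet_image(cfg, n_droplets=220, shape=(1200, 1200), seed=13)
    det = detect_droplets(img, cfg.pixel_size, (0.4, 3.6))
    assert len(det) >= 200
    assert np.median(det.radii) == pytest.approx(1.2, rel=0.10)
    centers = truth[["row", "col"]].to_numpy()
    radii = truth["radius_um"].to_numpy()
    matched = 0
    for (r, c), rad in zip(det.centers, det.radii):
        d = np.hypot(centers[:, 0] - r, centers[:, 1] - c)
        j = d.argmin()
        if d[j] < 0.5 * radii[j] / cfg.pixel_size and abs(rad - radii[j]) / radii[j] <= 0.15:
            matched += 1
    assert matched >= 0.90 * len(truth)


def test_line_profile_flat_images(cfg):
    half = np.full((100, 100), 32767, dtype=np.uint16)
    prof = line_profile(half, (50, 50), 20.0)
    np.testing.assert_allclose(prof.intensities, 32767 / DYNAMIC_RANGE)
    assert prof.positions[0] == -1.25 and prof.positions[-1] == 1.25
    np.testing.assert_allclose(prof.positions, -prof.positions[::-1])
    zero = np.zeros((100, 100), dtype=np.uint16)
    np.testing.assert_allclose(
        line_profile(zero, (50, 50), 20.0).intensities, 0.0
    )


def test_line_profile_window_must_fit(cfg):
    img = np.zeros((64, 64), dtype=np.uint16)
    with pytest.raises(ValueError, match="window exits"):
        line_profile(img, (10, 32), 20.0)


@pytest.mark.parametrize(
    "amps",
    [(0.26, 0.70, 0.11), (0.10, 0.58, 0.24)],  # MBP-like; GST+DTT-like
)
def test_core_shell_triplet_recovery(cfg, amps):
    """Rendered core-shell droplets reproduce their partition triplet
    (dilute, interface, condensed) within 0.03 per component."""
    c = cfg.with_(
        amp_dilute=amps[0], amp_interface=amps[1], amp_condensed=amps[2],
        radius_median=2.5, radius_sigma_log=0.1,
    )
    img, truth = gen_droplet_image(c, n_droplets=5, shape=(500, 500), seed=11)
    trips = []
    for _, row in truth.iterrows():
        prof = line_profile(img, (row.row, row.col), row.radius_um / c.pixel_size)
        trips.append(partition_triplet(prof).as_tuple())
    mean_trip = np.mean(trips, axis=0)
    np.testing.assert_allclose(mean_trip, amps, atol=0.03)


def test_triplet_orientation_independence(cfg):
    """Symmetric droplet: single-diameter triplets agree with the
    orientation-averaged one to 2%."""
    img, truth = gen_droplet_image(
        cfg.with_(radius_median=2.5, radius_sigma_log=0.01),
        n_droplets=1, shape=(160, 160), seed=4,
    )
    center = (truth.row[0], truth.col[0])
    r_px = truth.radius_um[0] / cfg.pixel_size
    ref = partition_triplet(line_profile(img, center, r_px, n_orientations=8))
    single = partition_triplet(line_profile(img, center, r_px, n_orientations=1))
    for a, b in zip(ref.as_tuple(), single.as_tuple()):
        assert b == pytest.approx(a, rel=0.02, abs=0.01)


def test_flat_profile_gives_constant_triplet():
    x = np.linspace(-1.25, 1.25, 101)
    trip = partition_triplet(LineProfile(x, np.full_like(x, 0.42)))
    assert trip.as_tuple() == pytest.approx((0.42, 0.42, 0.42))


def test_interface_reduction_arithmetic():
    t9 = PartitionTriplet(0.09, 0.90, 0.16)
    t58 = PartitionTriplet(0.10, 0.58, 0.24)
    assert interface_reduction(t9, t58) == pytest.approx(35.56, abs=0.01)
    assert interface_reduction(t9, t9) == 0.0
    assert interface_reduction(
        PartitionTriplet(0.1, 0.8, 0.1), PartitionTriplet(0.1, 0.4, 0.1)
    ) == pytest.approx(50.0)
    with pytest.raises(ValueError):
        interface_reduction(PartitionTriplet(0.1, 0.0, 0.1), t58)


def test_standard_curve_exact_inverse_and_noisy_recovery():
    c = np.array([0.0, 0.5, 1.0, 2.0, 4.0])
    curve = fit_standard_curve(c, 100.0 * c + 50.0)
    assert curve.slope == pytest.approx(100.0)
    assert curve.intercept == pytest.approx(50.0)
    assert curve.concentration(250.0) == pytest.approx(2.0)
    assert curve.concentration(50.0) == pytest.approx(0.0, abs=1e-9)
    assert curve.concentration(10.0) == 0.0  # below intercept clips to zero

    rng = np.random.default_rng(6)
    slopes = [
        fit_standard_curve(c, 100.0 * c + 50.0 + rng.normal(0, 5.0, c.size)).slope
        for _ in range(20)
    ]
    assert np.median(np.abs(np.array(slopes) - 100.0)) / 100.0 < 0.05
    with pytest.raises(ValueError):
        fit_standard_curve(np.array([1.0, 1.0, 1.0]), np.array([1.0, 2.0, 3.0]))


def test_equilibrium_dilute_concentration_round_trip():
    curve = fit_standard_curve(
        np.array([0.0, 0.5, 1.0, 2.0]), np.array([20.0, 70.0, 120.0, 220.0])
    )
    assert equilibrium_dilute_concentration(70.0, curve) == pytest.approx(0.5)


def test_size_model_limits_and_midpoint():
    r0, rinf, c50, n = 1.2, 0.55, 0.75, 2.0
    assert size_model(0.0, r0, rinf, c50, n) == r0
    assert size_model(1e9, r0, rinf, c50, n) == pytest.approx(rinf, rel=1e-6)
    assert size_model(c50, r0, rinf, c50, n) == pytest.approx((r0 + rinf) / 2)


def test_size_summary_recovers_c50(cfg):
    """Lognormal radius samples whose means follow the sigmoid: C50
    recovered within 35% (median over 20 seeds)."""
    c50s = []
    for s in range(20):
        series = gen_size_series(
            cfg, np.array([0.1, 0.25, 0.5, 1.0, 2.5, 5.0]), seed=4000 + s
        )
        table, fit = size_summary(series)
        assert set(table.columns) >= {"mean_radius_um", "median_radius_um"}
        c50s.append(fit.c50)
    assert np.median(c50s) == pytest.approx(0.75, rel=0.35)


def test_size_summary_without_enough_groups_returns_table_only(cfg):
    series = gen_size_series(cfg, np.array([0.1, 1.0]), seed=2)
    table, fit = size_summary(series)
    assert fit is None and len(table) == 2
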