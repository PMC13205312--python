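import numpy as np
import pytest

from bowelperf.border_geometry import (
    LineProfile,
    border_distances,
    calibrate_scale,
    inflection_geometric,
    sample_profile,
)
from bowelperf.errors import DegenerateProfileError, RangeError, ValidationError
from bowelperf.synthetic import BorderScenario, simulate_border_image

import oracles

LINES = [((10.0, 30.0), (150.0, 30.0)), ((10.0, 60.0), (150.0, 60.0)), ((10.0, 90.0), (150.0, 90.0))]


class TestCalibration:
    @pytest.mark.parametrize(
        "p0,p1,cm,expected",
        [((0.0, 0.0), (100.0, 0.0), 1.0, 0.01), ((0.0, 0.0), (3.0, 4.0), 1.0, 0.2)],
    )
    def test_known_scales(self, p0, p1, cm, expected):
        assert calibrate_scale(p0, p1, cm) == pytest.approx(expected)

    def test_coincident_points(self):
        with pytest.raises(ValidationError):
            calibrate_scale((5.0, 5.0), (5.0, 5.0), 1.0)


class TestProfileSampling:
    def test_constant_image(self):
        profile = sample_profile(np.full((50, 50), 3.0), (5.0, 25.0), (45.0, 25.0))
        assert np.allclose(profile.values, 3.0)

    def test_gradient_image_linear_profile(self):
        image = np.tile(np.arange(60.0), (40, 1))
        profile = sample_profile(image, (5.0, 20.0), (55.0, 20.0), step_px=0.5)
        assert np.allclose(np.diff(profile.values), 0.5, atol=1e-12)

    def test_matches_brute_force_bilinear(self, rng):
        image = rng.uniform(0, 1, (40, 60))
        p0, p1 = (3.2, 5.1), (50.7, 33.3)
        profile = sample_profile(image, p0, p1, step_px=0.5)
        length = np.hypot(p1[0] - p0[0], p1[1] - p0[1])
        dx, dy = (p1[0] - p0[0]) / length, (p1[1] - p0[1]) / length
        brute = [
            oracles.bilinear_brute(image, p0[0] + dx * s, p0[1] + dy * s)
            for s in profile.positions_px
        ]
        assert np.allclose(profile.values, brute, atol=1e-12)

    def test_segment_exits_image(self):
        with pytest.raises(RangeError):
            sample_profile(np.zeros((20, 20)), (5.0, 5.0), (25.0, 5.0))


class TestInflection:
    def test_noiseless_logistic_within_one_sample(self):
        image, x0 = simulate_border_image(BorderScenario(seed=0, noise_sd=0.0, x0_px=83.7))
        profile = sample_profile(image, (10.0, 60.0), (150.0, 60.0))
        est = 10.0 + inflection_geometric(profile)
        assert abs(est - x0) <= profile.step_px

    def test_step_edge_within_one_sample(self):
        image, x0 = simulate_border_image(BorderScenario(seed=0, noise_sd=0.0, x0_px=80.0, width_px=0.0))
        profile = sample_profile(image, (10.0, 60.0), (150.0, 60.0))
        assert abs(10.0 + inflection_geometric(profile) - x0) <= profile.step_px

    def test_linear_profile_degenerate(self):
        positions = np.arange(0.0, 50.0, 0.5)
        profile = LineProfile(positions, 2.0 + 0.1 * positions, (1.0, 0.0), (0.0, 0.0))
        with pytest.raises(DegenerateProfileError):
            inflection_geometric(profile)

    def test_flat_noisy_profile_degenerate(self, rng):
        positions = np.arange(0.0, 50.0, 0.5)
        profile = LineProfile(positions, 5.0 + rng.normal(0, 0.5, len(positions)), (1.0, 0.0), (0.0, 0.0))
        with pytest.raises(DegenerateProfileError):
            inflection_geometric(profile)

    def test_noisy_logistic_median_error_below_two_samples(self):
        errors = []
        for seed in range(100):
            image, x0 = simulate_border_image(BorderScenario(seed=seed, noise_sd=0.05, x0_px=80.0))
            profile = sample_profile(image, (10.0, 60.0), (150.0, 60.0))
            est = 10.0 + inflection_geometric(profile)
            errors.append(abs(est - x0) / profile.step_px)
        assert np.median(errors) <= 2.0

    def test_affine_intensity_invariance_is_exact(self):
        image, _ = simulate_border_image(BorderScenario(seed=5, noise_sd=0.05))
        profile = sample_profile(image, (10.0, 60.0), (150.0, 60.0))
        ref = inflection_geometric(profile)
        for a, b in ((2.0, 0.0), (7.0, 3.0), (0.25, -1.5)):
            mapped = LineProfile(profile.positions_px, a * profile.values + b,
                                 profile.direction, profile.origin_xy)
            assert inflection_geometric(mapped) == ref


class TestBorderDistances:
    def _images(self, offsets, seed=42, noise=0.05):
        return {
            name: simulate_border_image(BorderScenario(seed=seed + i, noise_sd=noise, x0_px=80.0 + off))[0]
            for i, (name, off) in enumerate(offsets.items())
        }

    def test_border_at_marker_gives_zero(self):
        images = self._images({"icg": 0.0}, noise=0.0)
        est = border_distances(images, LINES, (80.0, 60.0), 0.01)
        assert abs(est["icg"].signed_distance_cm) <= 0.01

    def test_known_shift_in_centimetres(self):
        images = self._images({"icg": 50.0}, noise=0.0)
        est = border_distances(images, LINES, (80.0, 60.0), 0.01)
        assert est["icg"].signed_distance_cm == pytest.approx(0.5, abs=0.01)

    def test_three_modality_offsets_recovered(self):
        images = self._images({"icg": -10.0, "recicg": -15.0, "sto2": 24.0})
        est = border_distances(images, LINES, (80.0, 60.0), 0.01)
        assert est["icg"].signed_distance_cm == pytest.approx(-0.10, abs=0.03)
        assert est["recicg"].signed_distance_cm == pytest.approx(-0.15, abs=0.03)
        assert est["sto2"].signed_distance_cm == pytest.approx(0.24, abs=0.03)

    def test_translation_equivariance(self):
        images = self._images({"icg": 0.0})
        est = border_distances(images, LINES, (80.0, 60.0), 0.01)
        shifted_lines = [((p0[0], p0[1] + 10.0), (p1[0], p1[1] + 10.0)) for p0, p1 in LINES]
        # vertical shift: the image columns are identical in every row
        est_shift = border_distances(images, shifted_lines, (80.0, 70.0), 0.01)
        assert est_shift["icg"].signed_distance_cm == pytest.approx(est["icg"].signed_distance_cm, abs=1e-9)

    def test_orientation_flip_negates_distance(self):
        images = self._images({"icg": -10.0, "sto2": 24.0})
        est = border_distances(images, LINES, (80.0, 60.0), 0.01)
        flipped = [(p1, p0) for p0, p1 in LINES]
        est_flip = border_distances(images, flipped, (80.0, 60.0), 0.01)
        for name in images:
            assert est_flip[name].signed_distance_cm == -est[name].signed_distance_cm

    def test_degenerate_profile_dropped_with_warning(self, caplog):
        image, _ = simulate_border_image(BorderScenario(seed=1, noise_sd=0.0))
        image[25:36] = 0.5  # flatten the first profile's row band
        est = border_distances({"icg": image}, LINES, (80.0, 60.0), 0.01)
        assert np.isnan(est["icg"].inflections_px[0])
        assert np.isfinite(est["icg"].signed_distance_cm)

    def test_all_degenerate_raises(self):
        flat = np.full((120, 160), 1.0)
        with pytest.raises(DegenerateProfileError):
            border_distances({"icg": flat}, LINES, (80.0, 60.0), 0.01)
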