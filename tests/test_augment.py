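"""Joint (IT, phi, r) augmentation algebra."""

import numpy as np
import pytest

from plicl.augment import (
    AugmentationPolicy,
    affine_augment,
    affine_matrix,
    center_crop,
    correct_direction,
    flip_augment,
    gaussian_blur,
    random_policy_apply,
    resample,
    rotate_direction,
    scale_attenuation,
    scale_thickness,
)
from plicl.physics import ParameterMaps, channel_encode

from conftest import random_maps


def _const_maps(it=1.0, phi=0.0, r=0.5, shape=(8, 8)):
    return ParameterMaps(np.full(shape, it), np.full(shape, phi), np.full(shape, r))


class TestPhotometric:
    def test_attenuation_scaling_closed_form(self):
        out = scale_attenuation(_const_maps(it=0.25), gamma_a=2.0)
        np.testing.assert_allclose(out.transmittance, 0.0625)
        np.testing.assert_allclose(out.retardation, 0.5)

    def test_attenuation_identity_and_inverse_composition(self):
        maps = _const_maps(it=0.37, r=0.8)
        np.testing.assert_allclose(scale_attenuation(maps, 1.0).transmittance, 0.37)
        round_trip = scale_attenuation(scale_attenuation(maps, 2.0), 0.5)
        np.testing.assert_allclose(round_trip.transmittance, 0.37, rtol=1e-12)

    def test_thickness_scaling_closed_form(self):
        out = scale_thickness(_const_maps(r=np.sin(np.pi / 4)), gamma_t=2.0)
        np.testing.assert_allclose(out.retardation, 1.0, atol=1e-12)

    def test_thickness_scaling_wraps_past_quarter_wave(self):
        # r = 1 means delta = pi/2; doubling the thickness gives |sin(pi)| = 0
        out = scale_thickness(_const_maps(r=1.0), gamma_t=2.0)
        np.testing.assert_allclose(out.retardation, 0.0, atol=1e-12)

    def test_thickness_identity(self):
        maps = _const_maps(it=0.6, r=0.3)
        out = scale_thickness(maps, 1.0)
        np.testing.assert_allclose(out.retardation, 0.3)
        np.testing.assert_allclose(out.transmittance, 0.6)

    @pytest.mark.parametrize("fn", [scale_attenuation, scale_thickness])
    def test_rejects_non_positive_gamma(self, fn):
        with pytest.raises(ValueError):
            fn(_const_maps(), 0.0)


class TestResample:
    def test_destructive_orthogonal_directions(self):
        maps = ParameterMaps(np.ones(2), np.array([0.0, np.pi / 2]), np.ones(2))
        out = resample(maps, np.array([[0.5, 0.5]]))
        np.testing.assert_allclose(out.retardation, 0.0, atol=1e-12)
        np.testing.assert_allclose(out.transmittance, 1.0)

    def test_constant_field_fixed_point(self):
        maps = ParameterMaps(np.full(4, 0.7), np.full(4, 0.4), np.full(4, 0.6))
        out = resample(maps, np.full((3, 4), 0.25))
        np.testing.assert_allclose(out.transmittance, 0.7, rtol=1e-12)
        np.testing.assert_allclose(out.retardation, 0.6, rtol=1e-12)
        np.testing.assert_allclose(out.direction, 0.4, rtol=1e-9)

    def test_delta_stencil_selects_source_pixel(self):
        maps = ParameterMaps(np.array([0.3, 0.9]), np.array([0.2, 1.1]), np.array([0.4, 0.8]))
        out = resample(maps, np.array([[1.0, 0.0]]))
        assert np.isclose(out.transmittance[0], 0.3)
        assert np.isclose(out.retardation[0], 0.4)
        assert np.isclose(out.direction[0], 0.2)

    def test_retardation_bounded_by_max_input(self):
        rng = np.random.default_rng(0)
        maps = ParameterMaps(rng.uniform(0.1, 1, 16), rng.uniform(0, np.pi, 16), rng.uniform(0, 1, 16))
        w = rng.uniform(0, 1, (8, 16))
        w /= w.sum(axis=1, keepdims=True)
        out = resample(maps, w)
        assert out.retardation.max() <= maps.retardation.max() + 1e-12

    def test_rejects_bad_weights(self):
        maps = _const_maps(shape=(2, 2))
        with pytest.raises(ValueError):
            resample(maps, np.array([[0.5, 0.5, 0.5, 0.5]]))


class TestDirectionCorrection:
    def test_rotation_closed_form(self):
        phi = np.deg2rad(30.0)
        theta = np.deg2rad(45.0)
        rot = affine_matrix(rotation=theta)
        assert np.isclose(np.rad2deg(correct_direction(phi, rot)), 75.0)
        assert np.isclose(np.rad2deg(rotate_direction(phi, theta)), 75.0)

    def test_horizontal_flip(self):
        phi = np.deg2rad(30.0)
        out = correct_direction(phi, np.diag([-1.0, 1.0]))
        assert np.isclose(np.rad2deg(out), 150.0)

    def test_identity(self):
        phi = np.linspace(0, np.pi, 20, endpoint=False)
        np.testing.assert_allclose(correct_direction(phi, np.eye(2)), phi, atol=1e-12)

    def test_jacobian_path_matches_rotation_closed_form(self):
        rng = np.random.default_rng(1)
        phi = rng.uniform(0, np.pi, 1000)
        for theta in rng.uniform(-np.pi, np.pi, 25):
            a = correct_direction(phi, affine_matrix(rotation=theta))
            b = rotate_direction(phi, theta)
            d = np.abs(a - b)
            assert np.minimum(d, np.pi - d).max() < 1e-9

    def test_rejects_singular_jacobian(self):
        with pytest.raises(ValueError):
            correct_direction(0.3, np.array([[1.0, 1.0], [1.0, 1.0]]))


class TestGeometric:
    def test_quarter_rotation_rotates_grid_and_directions(self):
        rng = np.random.default_rng(2)
        it = rng.uniform(0.2, 1.0, (9, 9))
        maps = ParameterMaps(it, np.zeros((9, 9)), np.full((9, 9), 0.8))
        out = affine_augment(maps, affine_matrix(rotation=np.pi / 2))
        # direction phi = 0 everywhere becomes phi = 90 deg
        np.testing.assert_allclose(np.rad2deg(out.direction), 90.0, atol=1e-6)
        # the pixel grid is permuted: with y down and a CCW rotation in (x, y),
        # the warped image equals rot90 applied in index space
        np.testing.assert_allclose(out.transmittance, np.rot90(it, k=-1), atol=1e-7)

    def test_flip_is_exact_permutation(self):
        maps = random_maps(np.random.default_rng(3), shape=(6, 7))
        out = flip_augment(maps, axis=1)
        np.testing.assert_allclose(out.transmittance, maps.transmittance[:, ::-1])
        np.testing.assert_allclose(out.retardation, maps.retardation[:, ::-1])
        expected = np.mod(-maps.direction[:, ::-1], np.pi)
        d = np.abs(out.direction - expected)
        assert np.minimum(d, np.pi - d).max() < 1e-12

    def test_double_flip_is_identity(self):
        maps = random_maps(np.random.default_rng(4))
        out = flip_augment(flip_augment(maps, 0), 0)
        np.testing.assert_allclose(out.transmittance, maps.transmittance)
        d = np.abs(out.direction - maps.direction)
        assert np.minimum(d, np.pi - d).max() < 1e-12

    def test_zero_sigma_blur_is_identity(self):
        maps = random_maps(np.random.default_rng(5))
        out = gaussian_blur(maps, 0.0)
        np.testing.assert_allclose(out.transmittance, maps.transmittance)

    def test_blur_of_constant_maps_is_identity(self):
        maps = _const_maps(it=0.5, phi=0.7, r=0.4, shape=(16, 16))
        out = gaussian_blur(maps, 2.0)
        np.testing.assert_allclose(out.transmittance, 0.5, rtol=1e-9)
        np.testing.assert_allclose(out.retardation, 0.4, rtol=1e-9)
        np.testing.assert_allclose(out.direction, 0.7, rtol=1e-9)

    def test_blur_reduces_orientation_coherence(self):
        rng = np.random.default_rng(6)
        maps = ParameterMaps(np.ones((32, 32)), rng.uniform(0, np.pi, (32, 32)), np.ones((32, 32)))
        out = gaussian_blur(maps, 2.0)
        assert out.retardation.mean() < 0.8  # incoherent directions cancel

    def test_rotation_equivariance_of_channel_encoding(self):
        # rotating the maps then encoding equals warping the encoded channels
        # and mixing them with the doubled-angle phase
        from scipy import ndimage

        rng = np.random.default_rng(7)
        maps = ParameterMaps(np.ones((16, 16)), rng.uniform(0, np.pi, (16, 16)), rng.uniform(0.2, 1, (16, 16)))
        theta = np.deg2rad(30.0)
        rotated = affine_augment(maps, affine_matrix(rotation=theta))
        got = channel_encode(rotated)
        got_complex = got[1] + 1j * got[2]

        # independent path: warp the encoded channels as plain scalars with
        # the same bilinear grid rotation, then apply the doubled-angle phase
        enc = channel_encode(maps)
        center = np.array([(16 - 1) / 2.0, (16 - 1) / 2.0])
        inv = affine_matrix(rotation=-theta)
        # re-express the (x, y) matrix in (row, col) ordering for scipy
        m_rc = np.array([[inv[1, 1], inv[1, 0]], [inv[0, 1], inv[0, 0]]])
        offset = (center - inv @ center)[::-1]
        warp = lambda a: ndimage.affine_transform(a, m_rc, offset=offset, order=1)
        expected = (warp(enc[1]) + 1j * warp(enc[2])) * np.exp(2j * theta)
        interior = np.zeros((16, 16), dtype=bool)
        interior[4:-4, 4:-4] = True
        np.testing.assert_allclose(got_complex[interior], expected[interior], atol=1e-6)


class TestPolicy:
    def test_identity_policy_is_center_crop(self):
        maps = random_maps(np.random.default_rng(8), shape=(48, 48))
        policy = AugmentationPolicy.identity(crop_px=32)
        out = random_policy_apply(maps, policy, np.random.default_rng(0))
        ref = center_crop(maps, 32)
        np.testing.assert_allclose(out.transmittance, ref.transmittance, atol=1e-7)
        np.testing.assert_allclose(out.retardation, ref.retardation, atol=1e-7)

    def test_reference_patch_and_crop_sizes(self):
        maps = random_maps(np.random.default_rng(9), shape=(192, 192))
        out = random_policy_apply(maps, AugmentationPolicy(), np.random.default_rng(1))
        assert out.shape == (128, 128)

    def test_fixed_seed_is_bit_reproducible(self):
        maps = random_maps(np.random.default_rng(10), shape=(48, 48))
        policy = AugmentationPolicy(crop_px=32)
        a = random_policy_apply(maps, policy, np.random.default_rng(42))
        b = random_policy_apply(maps, policy, np.random.default_rng(42))
        np.testing.assert_array_equal(a.transmittance, b.transmittance)
        np.testing.assert_array_equal(a.direction, b.direction)

    def test_outputs_preserve_map_invariants(self):
        rng = np.random.default_rng(11)
        policy = AugmentationPolicy(crop_px=32)
        for _ in range(10):
            out = random_policy_apply(random_maps(rng, shape=(48, 48)), policy, rng)
            assert out.retardation.min() >= 0 and out.retardation.max() <= 1
            assert out.direction.min() >= 0 and out.direction.max() < np.pi

    def test_yaml_round_trip(self, tmp_path):
        policy = AugmentationPolicy(crop_px=64, blur_prob=0.25)
        path = tmp_path / "policy.yaml"
        policy.to_yaml(path)
        assert AugmentationPolicy.from_yaml(path) == policy

    def test_rejects_invalid_ranges(self):
        with pytest.raises(ValueError):
            AugmentationPolicy(scale_range=(1.3, 0.9))
        with pytest.raises(ValueError):
            AugmentationPolicy(flip_prob=1.5)
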