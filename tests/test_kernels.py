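import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from shapecortex.kernels import (
    GaussianSpec,
    Kernel2D,
    convolve2d,
    default_support_radius,
    dog_kernel,
    filter_bank_apply,
    rectify,
    rotated_gaussian,
    simple_cell_kernel,
)


class TestRotatedGaussian:
    def test_isotropic_invariant_under_quarter_turn(self):
        k = rotated_gaussian(GaussianSpec(sigma1=1.0), support_radius=4)
        assert np.allclose(k.weights, np.rot90(k.weights), atol=1e-12)

    def test_second_moment_follows_elongation_axis(self):
        # elongated along theta=pi/2 (vertical): vertical spread dominates
        k = rotated_gaussian(GaussianSpec(np.pi / 2, 3.0, 1.0), support_radius=9)
        coords = np.arange(-9, 10, dtype=float)
        dy, dx = np.meshgrid(coords, coords, indexing="ij")
        w = k.weights / k.weights.sum()
        assert (w * dy**2).sum() > 2.0 * (w * dx**2).sum()

    def test_axis_symmetry_theta_plus_pi(self):
        a = rotated_gaussian(GaussianSpec(0.7, 3.0, 1.0), 9)
        b = rotated_gaussian(GaussianSpec(0.7 + np.pi, 3.0, 1.0), 9)
        assert np.allclose(a.weights, b.weights, atol=1e-12)

    @pytest.mark.parametrize("mu", [(0.0, 0.0), (2.0, -1.0), (-3.0, 2.0)])
    def test_argmax_at_grid_point_nearest_mu(self, mu):
        k = rotated_gaussian(GaussianSpec(0.3, 2.0, 1.5, mu), support_radius=8)
        iy, ix = np.unravel_index(np.argmax(k.weights), k.weights.shape)
        assert (ix - 8, iy - 8) == (round(mu[0]), round(mu[1]))

    def test_nonpositive_sigma_rejected(self):
        with pytest.raises(ValueError):
            GaussianSpec(sigma1=-1.0)
        with pytest.raises(ValueError):
            GaussianSpec(sigma1=1.0, sigma2=0.0)

    def test_default_sigma2_follows_sigma1(self):
        spec = GaussianSpec(sigma1=2.5)
        assert spec.sigma2 == 2.5


class TestDogKernel:
    def test_balanced_zero_sum(self):
        k = dog_kernel(1.0, 1.5)
        assert abs(k.weights.sum()) < 1e-9

    def test_center_positive_surround_negative(self):
        k = dog_kernel(1.0, 1.5, support_radius=5)
        r = k.support_radius
        assert k.weights[r, r] > 0
        assert k.weights[r, r + 3] < 0  # at radius 3*sigma

    def test_constant_image_gives_no_response(self):
        img = np.full((32, 32), 0.7)
        out = convolve2d(img, dog_kernel(1.0, 1.5))
        assert np.abs(out[5:-5, 5:-5]).max() < 1e-6

    def test_surround_must_be_wider(self):
        with pytest.raises(ValueError):
            dog_kernel(1.0, kappa=1.0)
        with pytest.raises(ValueError):
            dog_kernel(-1.0)


class TestSimpleCellKernel:
    def test_polarity_pair_sums_to_zero(self):
        plus = simple_cell_kernel(0.5, 3.0, 1.5, 3.0, +1)
        minus = simple_cell_kernel(0.5, 3.0, 1.5, 3.0, -1)
        assert np.allclose(plus.weights + minus.weights, 0.0, atol=1e-12)

    def test_balanced(self):
        k = simple_cell_kernel(np.pi / 4, 3.0, 1.5, 3.0)
        assert abs(k.weights.sum()) < 1e-9

    def test_vertical_edge_drives_vertical_channel_most(self, vertical_edge):
        responses = []
        for i in range(8):
            k = simple_cell_kernel(i * np.pi / 8, 3.0, 1.56, 3.0)
            r = convolve2d(vertical_edge, k)
            responses.append(abs(r[32, 32]))
        assert int(np.argmax(responses)) == 4  # theta = pi/2

    def test_bad_parameters(self):
        with pytest.raises(ValueError):
            simple_cell_kernel(0.0, 3.0, 1.5, omega1=0.0)
        with pytest.raises(ValueError):
            simple_cell_kernel(0.0, 3.0, 1.5, 3.0, polarity=2)


class TestConvolve2d:
    def test_delta_kernel_is_identity(self, rng):
        img = rng.random((20, 20))
        delta = np.zeros((3, 3))
        delta[1, 1] = 1.0
        out = convolve2d(img, Kernel2D(delta, 1))
        assert np.allclose(out, img, atol=1e-12)

    def test_zero_field_stays_zero(self):
        out = convolve2d(np.zeros((16, 16)), dog_kernel(1.0, 1.5))
        assert np.all(out == 0)

    def test_translation_equivariance_interior(self, rng):
        k = dog_kernel(1.0, 1.5, support_radius=3)
        img = np.zeros((24, 24))
        img[10, 10] = 1.0
        shifted = np.roll(img, (2, 3), axis=(0, 1))
        a = convolve2d(img, k, "zero")
        b = convolve2d(shifted, k, "zero")
        assert np.allclose(np.roll(a, (2, 3), axis=(0, 1))[6:-6, 6:-6],
                           b[6:-6, 6:-6], atol=1e-12)

    def test_matches_direct_double_loop_oracle(self, rng):
        """Library convolution agrees with the O(n^2 k^2) reference sum."""
        img = rng.random((16, 16))
        kern = Kernel2D(rng.standard_normal((5, 5)), 2)
        out = convolve2d(img, kern, "zero")
        expected = np.zeros_like(img)
        r = 2
        for y in range(16):
            for x in range(16):
                acc = 0.0
                for u in range(-r, r + 1):
                    for v in range(-r, r + 1):
                        yy, xx = y - u, x - v
                        if 0 <= yy < 16 and 0 <= xx < 16:
                            acc += kern.weights[u + r, v + r] * img[yy, xx]
                expected[y, x] = acc
        assert np.abs(out - expected).max() < 1e-10

    def test_fft_path_matches_direct_path(self, rng):
        img = rng.random((32, 32))
        k = dog_kernel(1.5, 1.5)
        for mode in ("reflect", "zero"):
            assert np.allclose(
                filter_bank_apply(img, k, mode), convolve2d(img, k, mode), atol=1e-9
            )

    def test_kernel_larger_than_field_rejected(self):
        with pytest.raises(ValueError):
            convolve2d(np.zeros((4, 4)), dog_kernel(2.0, 1.5))

    def test_unknown_border_mode_rejected(self):
        with pytest.raises(ValueError):
            convolve2d(np.zeros((16, 16)), dog_kernel(1.0, 1.5), "wrap")

    def test_nonfinite_field_rejected(self):
        img = np.zeros((16, 16))
        img[3, 3] = np.nan
        with pytest.raises(ValueError):
            convolve2d(img, dog_kernel(1.0, 1.5))


class TestRectify:
    @pytest.mark.parametrize("value,expected", [(-5.0, 0.0), (3.0, 3.0), (0.0, 0.0)])
    def test_scalar_values(self, value, expected):
        assert rectify(np.array([value]))[0] == expected

    def test_all_negative_field_becomes_zero(self):
        assert np.all(rectify(-np.ones((4, 4))) == 0)


@settings(max_examples=25, deadline=None)
@given(
    sigma=st.floats(0.5, 2.0),
    kappa=st.floats(1.1, 2.0),
    level=st.floats(0.0, 1.0),
)
def test_balanced_kernels_silent_on_constant_images(sigma, kappa, level):
    """Any center-surround or odd-symmetric kernel gives ~zero interior
    response on a constant image."""
    img = np.full((40, 40), level)
    r = default_support_radius(kappa * sigma)
    out = convolve2d(img, dog_kernel(sigma, kappa))
    assert np.abs(out[r:-r, r:-r]).max() < 1e-6
    k = simple_cell_kernel(0.9, 2.0 * sigma, sigma, 3.0)
    out2 = convolve2d(img, k)
    rr = k.support_radius
    assert np.abs(out2[rr:-rr, rr:-rr]).max() < 1e-6
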