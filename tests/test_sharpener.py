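import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from greysharp import (
    FixtureSpec,
    InvalidInputError,
    InvalidParameterError,
    SharpenParams,
    additive_magnitude,
    local_mean,
    local_mean_map,
    make_fixture,
    sharpen_image,
    sharpen_pixel,
)
from .oracles import naive_local_mean, naive_sharpen

small_images = hnp.arrays(
    dtype=np.uint8,
    shape=st.tuples(st.integers(1, 8), st.integers(1, 8)),
    elements=st.integers(0, 255),
)


class TestLocalMean:
    def test_interior_and_corner(self):
        patch = np.array([[10, 10, 10], [10, 100, 10], [10, 10, 10]])
        assert local_mean(patch, 1, 1) == pytest.approx(20.0)
        tiny = np.array([[0, 0], [0, 90]])
        assert local_mean(tiny, 0, 0) == pytest.approx(22.5)

    def test_constant(self):
        assert local_mean(np.full((5, 5), 80), 2, 2) == 80.0

    def test_out_of_bounds(self):
        with pytest.raises(InvalidInputError):
            local_mean(np.zeros((3, 3)), 3, 0)

    @given(small_images)
    def test_map_matches_pointwise_oracle(self, img):
        lm = local_mean_map(img)
        h, w = img.shape
        for r in range(h):
            for c in range(w):
                assert lm[r, c] == pytest.approx(naive_local_mean(img, r, c))


class TestAdditiveMagnitude:
    @pytest.mark.parametrize(
        "x, lm, s, delta, expected",
        [
            (120, 100, 1.0, 40, 40 * 100 / 120),  # above local mean
            (50, 100, 0.5, 40, 10.0),             # below local mean
            (0, 0, 1.0, 40, 0.0),                 # defined degenerate case
            (100, 100, 1.0, 40, 40.0),            # x == LocalMean -> full delta
        ],
    )
    def test_examples(self, x, lm, s, delta, expected):
        assert additive_magnitude(x, lm, s, delta) == pytest.approx(expected)

    @given(
        lm=st.floats(min_value=1.0, max_value=254.0),
        s=st.floats(min_value=0.0, max_value=1.0),
        delta=st.floats(min_value=0.0, max_value=100.0),
        x1=st.integers(0, 255),
        x2=st.integers(0, 255),
    )
    def test_bounded_and_monotone_toward_local_mean(self, lm, s, delta, x1, x2):
        """delta_x stays in [0, s*delta] and grows as x approaches LocalMean:
        smaller discontinuities get the larger boost."""
        d1 = additive_magnitude(x1, lm, s, delta)
        assert -1e-9 <= d1 <= s * delta + 1e-9
        if abs(x1 - lm) <= abs(x2 - lm) and (x1 - lm) * (x2 - lm) >= 0:
            assert d1 >= additive_magnitude(x2, lm, s, delta) - 1e-9


class TestSharpenPixel:
    @pytest.mark.parametrize(
        "x, lm, dx, expected",
        [
            (120, 100, 40 * 100 / 120, 153),  # 153.33 rounds down
            (50, 100, 10, 40),
            (250, 100, 40, 255),              # clamp high
            (5, 100, 10, 0),                  # -5 clamps low
            (100, 100, 40, 140),              # ties go to the additive branch
        ],
    )
    def test_examples(self, x, lm, dx, expected):
        assert sharpen_pixel(x, lm, dx) == expected

    def test_rounds_half_away_from_zero(self):
        assert sharpen_pixel(100, 50, 2.5) == 103  # 102.5 -> 103


class TestSharpenImage:
    def test_identity_at_zero_scale(self, fixture_image):
        res = sharpen_image(fixture_image, SharpenParams(s=0.0, lpf_enabled=False))
        np.testing.assert_array_equal(res.image, fixture_image)

    def test_constant_image_unchanged(self):
        img = np.full((16, 16), 123, dtype=np.uint8)
        res = sharpen_image(img)
        np.testing.assert_array_equal(res.image, img)
        assert res.delta == 0.0
        assert res.edge_map.sum() == 0
        assert res.changed_pixel_count == 0

    def test_nonedge_pixels_bit_exact(self, fixture_image):
        res = sharpen_image(
            fixture_image, SharpenParams(theta_eth=14, lpf_enabled=False, s=1.0)
        )
        mask = res.edge_map == 0
        np.testing.assert_array_equal(res.image[mask], fixture_image[mask])

    def test_bounded_change(self, fixture_image):
        params = SharpenParams(theta_eth=10, lpf_enabled=False, s=0.8)
        res = sharpen_image(fixture_image, params)
        diff = np.abs(res.image.astype(int) - fixture_image.astype(int))
        assert diff.max() <= math.ceil(params.s * res.delta)

    def test_contrast_expands_away_from_local_mean(self, fixture_image):
        res = sharpen_image(
            fixture_image, SharpenParams(theta_eth=10, lpf_enabled=False, s=1.0)
        )
        lm = local_mean_map(fixture_image)
        x = fixture_image.astype(float)
        xhat = res.image.astype(float)
        on = res.edge_map == 1
        below = on & (x < lm)
        assert np.all(xhat[below] <= x[below])
        assert np.all(xhat[on & ~below] >= x[on & ~below])

    def test_step_fixture_hand_evaluated(self):
        """On a 50|150 step with the line-preserving filter setting, each
        surviving edge pixel moves by round(s*Delta*min(x,LM)/max(x,LM))."""
        img = make_fixture(FixtureSpec("vstep", (8, 8), (50, 150), split=4))
        params = SharpenParams(
            theta_eth=18, lpf_enabled=True, theta_lpf=2, s=1.0, delta_override=40.0
        )
        res = sharpen_image(img, params)
        expected = img.astype(int).copy()
        lm = local_mean_map(img)
        for r in range(1, 7):  # interior of the flagged column survives the LPF
            x = 150.0
            dx = 40.0 * lm[r, 4] / x  # x > LocalMean on the high side
            expected[r, 4] = min(255, int(math.floor(x + dx + 0.5)))
        np.testing.assert_array_equal(res.image, expected)
        # literal theta_lpf=3 erases the 1-px line: the whole pass is a no-op
        res3 = sharpen_image(img, params.with_(theta_lpf=3))
        np.testing.assert_array_equal(res3.image, img)
        assert res3.edge_map.sum() == 0

    def test_deterministic(self, fixture_image):
        p = SharpenParams(theta_eth=12, s=0.8, lpf_enabled=True)
        a = sharpen_image(fixture_image, p)
        b = sharpen_image(fixture_image, p)
        np.testing.assert_array_equal(a.image, b.image)
        np.testing.assert_array_equal(a.edge_map, b.edge_map)
        assert a.delta == b.delta

    @given(
        small_images,
        st.integers(1, 60),
        st.integers(1, 8),
        st.booleans(),
        st.sampled_from([0.0, 0.5, 0.8, 1.0]),
        st.floats(min_value=0.0, max_value=80.0),
    )
    def test_matches_straightline_oracle(self, img, theta, tlpf, lpf, s, delta):
        params = SharpenParams(
            theta_eth=theta, theta_lpf=tlpf, lpf_enabled=lpf, s=s,
            delta_override=delta,
        )
        res = sharpen_image(img, params)
        np.testing.assert_array_equal(
            res.image, naive_sharpen(img, theta, tlpf, lpf, s, delta)
        )

    def test_invalid_inputs(self):
        with pytest.raises(InvalidInputError):
            sharpen_image(np.empty((0, 0)))
        with pytest.raises(InvalidParameterError):
            SharpenParams(s=1.5)
        with pytest.raises(InvalidParameterError):
            SharpenParams(theta_eth=-1)
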