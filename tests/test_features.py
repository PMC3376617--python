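import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pestpipe.errors import FeatureError
from pestpipe.features import (
    FEATURE_NAMES,
    color_moments,
    eccentricity,
    extract_features,
    hu_features,
    moments,
    read_features_csv,
    sphericity,
    write_features_csv,
)

from conftest import disc_mask, ellipse_mask, triple_loop_moments


class TestColorMoments:
    def test_constant_channel(self):
        ch = np.full((6, 6), 0.42)
        mask = np.ones((6, 6), dtype=np.uint8)
        assert color_moments(ch, mask) == (pytest.approx(0.42), 0.0, 0.0)

    def test_two_point_distribution(self):
        ch = np.array([[0.0, 1.0]])
        mask = np.ones((1, 2), dtype=np.uint8)
        e, sigma, s = color_moments(ch, mask)
        assert e == pytest.approx(0.5)
        assert sigma == pytest.approx(0.5)
        assert s == pytest.approx(0.0, abs=1e-12)

    def test_skewed_three_point_distribution(self):
        # values {0, 0, 1}: E=1/3, sigma=sqrt(2)/3,
        # s = cbrt(((-1/3)^3 * 2 + (2/3)^3) / 3)
        ch = np.array([[0.0, 0.0, 1.0]])
        mask = np.ones((1, 3), dtype=np.uint8)
        e, sigma, s = color_moments(ch, mask)
        assert e == pytest.approx(1 / 3)
        assert sigma == pytest.approx(np.sqrt(2) / 3)
        expected_s = (((-1 / 3) ** 3 * 2 + (2 / 3) ** 3) / 3) ** (1 / 3)
        assert s == pytest.approx(expected_s)

    def test_negative_skew_keeps_sign(self):
        ch = np.array([[1.0, 1.0, 0.0]])
        mask = np.ones((1, 3), dtype=np.uint8)
        _, _, s = color_moments(ch, mask)
        assert s < 0

    @settings(max_examples=50, deadline=None)
    @given(st.integers(min_value=0, max_value=2**32 - 1))
    def test_permutation_invariance(self, seed):
        rng = np.random.default_rng(seed)
        vals = rng.random(20)
        ch = vals.reshape(4, 5)
        perm = rng.permutation(20).reshape(4, 5)
        mask = np.ones((4, 5), dtype=np.uint8)
        a = color_moments(ch, mask)
        b = color_moments(vals[perm], mask)
        np.testing.assert_allclose(a, b, rtol=1e-10, atol=1e-12)

    def test_empty_mask_rejected(self):
        with pytest.raises(FeatureError):
            color_moments(np.ones((3, 3)), np.zeros((3, 3), dtype=np.uint8))


class TestMoments:
    def test_single_pixel(self):
        m = np.zeros((5, 5), dtype=np.uint8)
        m[2, 3] = 1
        ms = moments(m)
        assert ms.area == 1
        for (p, q), v in ms.mu.items():
            if p + q >= 1:
                assert v == pytest.approx(0.0)

    def test_2x2_block_by_hand(self):
        m = np.zeros((4, 4), dtype=np.uint8)
        m[1:3, 1:3] = 1
        ms = moments(m)
        assert ms.area == 4
        assert ms.mu[(2, 0)] == pytest.approx(1.0)
        assert ms.mu[(0, 2)] == pytest.approx(1.0)
        assert ms.eta[(2, 0)] == pytest.approx(1 / 16)

    def test_matches_triple_loop_oracle(self, rng):
        for _ in range(30):
            m = (rng.random((16, 16)) < 0.4).astype(np.uint8)
            if not m.any():
                continue
            raw_o, mu_o, eta_o = triple_loop_moments(m)
            ms = moments(m)
            for k in raw_o:
                assert ms.raw[k] == pytest.approx(raw_o[k], rel=1e-12, abs=1e-9)
                assert ms.mu[k] == pytest.approx(mu_o[k], rel=1e-9, abs=1e-7)
            for k in eta_o:
                assert ms.eta[k] == pytest.approx(eta_o[k], rel=1e-9, abs=1e-12)

    def test_disc_eta20_approaches_continuous_limit(self):
        # continuous disc: eta20 = 1/(4*pi)
        ms = moments(disc_mask(50))
        assert ms.eta[(2, 0)] == pytest.approx(1 / (4 * np.pi), rel=0.01)


class TestHuFeatures:
    def test_disc_closed_form(self):
        phi1, phi2 = hu_features(moments(disc_mask(50)))
        assert phi1 == pytest.approx(1 / (2 * np.pi), rel=0.01)
        assert phi2 == pytest.approx(0.0, abs=1e-3)

    def test_rotation_invariance_quarter_turns(self, rng):
        m = (rng.random((12, 17)) < 0.5).astype(np.uint8)
        base = hu_features(moments(m))
        for k in (1, 2, 3):
            rot = hu_features(moments(np.rot90(m, k)))
            np.testing.assert_allclose(rot, base, rtol=1e-9, atol=1e-15)

    def test_translation_invariance_exact(self, rng):
        m = np.zeros((30, 30), dtype=np.uint8)
        m[4:12, 5:15] = (rng.random((8, 10)) < 0.6).astype(np.uint8)
        shifted = np.roll(np.roll(m, 9, axis=0), 7, axis=1)
        np.testing.assert_allclose(
            hu_features(moments(shifted)), hu_features(moments(m)), rtol=1e-9
        )

    def test_scale_invariance_within_raster_error(self):
        m = ellipse_mask(20, 10)
        up = np.kron(m, np.ones((2, 2), dtype=np.uint8))
        a = np.array(hu_features(moments(m)))
        b = np.array(hu_features(moments(up)))
        assert abs(b[0] - a[0]) / a[0] < 0.02

    @settings(max_examples=100, deadline=None)
    @given(st.integers(min_value=0, max_value=2**32 - 1))
    def test_phi2_bounded_by_phi1_squared(self, seed):
        rng = np.random.default_rng(seed)
        m = (rng.random((10, 10)) < 0.5).astype(np.uint8)
        if not m.any():
            return
        phi1, phi2 = hu_features(moments(m))
        assert phi2 <= phi1**2 + 1e-12


class TestEccentricity:
    def test_disc_is_round(self):
        assert eccentricity(disc_mask(40)) == pytest.approx(1.0, rel=0.02)

    def test_two_to_one_ellipse(self):
        m = ellipse_mask(40, 20)
        assert eccentricity(m) == pytest.approx(2.0, rel=0.03)
        # brute-force covariance of member pixel coordinates as oracle
        ys, xs = np.nonzero(m)
        cov = np.cov(np.vstack([xs, ys]), bias=True)
        lam = np.linalg.eigvalsh(cov)
        assert eccentricity(m) == pytest.approx(np.sqrt(lam[1] / lam[0]), rel=1e-9)

    def test_rotation_invariance(self):
        e0 = eccentricity(ellipse_mask(40, 20))
        e30 = eccentricity(ellipse_mask(40, 20, theta=np.pi / 6))
        assert e30 == pytest.approx(e0, rel=0.03)

    def test_degenerate_line_hits_cap(self):
        m = np.zeros((5, 20), dtype=np.uint8)
        m[2, 2:18] = 1
        assert eccentricity(m) == np.inf
        assert eccentricity(m, degenerate_cap=99.0) == 99.0

    def test_single_pixel_convention(self):
        m = np.zeros((3, 3), dtype=np.uint8)
        m[1, 1] = 1
        assert eccentricity(m) == 1.0


class TestSphericity:
    def test_disc(self):
        assert sphericity(disc_mask(40)) == pytest.approx(1.0, rel=0.03)

    def test_square_analytic(self):
        m = np.zeros((90, 90), dtype=np.uint8)
        m[5:85, 5:85] = 1
        assert sphericity(m) == pytest.approx(1 / np.sqrt(2), rel=0.03)

    def test_rectangle_analytic(self):
        m = np.zeros((30, 50), dtype=np.uint8)
        m[5:25, 5:45] = 1  # 40 x 20
        assert sphericity(m) == pytest.approx(10 / np.sqrt(500), rel=0.03)

    def test_bounds(self, rng):
        for _ in range(10):
            m = (rng.random((20, 20)) < 0.5).astype(np.uint8)
            if not m.any():
                continue
            from pestpipe.segmentation import keep_largest_region

            m = keep_largest_region(m)
            sp = sphericity(m)
            assert 0.0 < sp <= 1.0

    def test_empty_mask_rejected(self):
        with pytest.raises(FeatureError):
            sphericity(np.zeros((4, 4), dtype=np.uint8))


class TestExtractFeatures:
    def _constant_disc_image(self):
        mask = disc_mask(30)
        img = np.zeros((*mask.shape, 3), dtype=np.uint8)
        img[..., 2] = 40
        img[mask.astype(bool)] = (180, 90, 30)
        return img, mask

    def test_length_and_order(self):
        img, mask = self._constant_disc_image()
        vec = extract_features(img, mask)
        assert vec.shape == (13,)
        assert len(FEATURE_NAMES) == 13

    def test_constant_color_disc(self):
        img, mask = self._constant_disc_image()
        vec = extract_features(img, mask)
        named = dict(zip(FEATURE_NAMES, vec))
        for ch in "hsv":
            assert named[f"{ch}_std"] == pytest.approx(0.0, abs=1e-9)
            assert named[f"{ch}_skew"] == pytest.approx(0.0, abs=1e-9)
        assert named["eccentricity"] == pytest.approx(1.0, rel=0.02)
        assert named["sphericity"] == pytest.approx(1.0, rel=0.03)

    def test_degenerate_region_stays_finite(self):
        img = np.full((5, 20, 3), 100, dtype=np.uint8)
        mask = np.zeros((5, 20), dtype=np.uint8)
        mask[2, 2:18] = 1
        vec = extract_features(img, mask)
        assert np.all(np.isfinite(vec))
        assert vec[FEATURE_NAMES.index("eccentricity")] == 100.0


class TestFeatureCsv:
    def test_round_trip_with_labels(self, tmp_path, rng):
        X = rng.random((5, 13))
        ids = [f"img{i}" for i in range(5)]
        labels = ["a", "b", "a", "c", "b"]
        path = tmp_path / "f.csv"
        write_features_csv(path, ids, X, labels)
        ids2, X2, labels2 = read_features_csv(path)
        assert ids2 == ids and labels2 == labels
        np.testing.assert_array_equal(X2, X)

    def test_round_trip_without_labels(self, tmp_path, rng):
        X = rng.random((3, 13))
        path = tmp_path / "f.csv"
        write_features_csv(path, ["a", "b", "c"], X)
        _, X2, labels2 = read_features_csv(path)
        assert labels2 is None
        np.testing.assert_array_equal(X2, X)

    def test_wrong_header_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("id,foo,bar\nx,1,2\n")
        with pytest.raises(ValueError):
            read_features_csv(path)
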