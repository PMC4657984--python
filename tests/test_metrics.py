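"""Shadow filtering, spectral metrics, object-level GLCM, feature-table assembly."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from phenocrown import (
    MetricConfig,
    build_feature_table,
    feature_columns,
    glcm_metrics,
    relative_intensity,
    spectral_metrics,
    sunlit_mask,
)
from phenocrown.metrics import DEFAULT_OFFSETS

from _oracles import glcm_oracle
from conftest import make_layer


def _full_mask(shape):
    rr, cc = np.meshgrid(np.arange(shape[0]), np.arange(shape[1]), indexing="ij")
    return np.column_stack([rr.ravel(), cc.ravel()])


class TestRelativeIntensity:
    def test_endpoints_map_to_0_and_100(self):
        bands = np.zeros((3, 1, 3), dtype=np.uint8)
        bands[:, 0, 0] = 10  # intensity 30
        bands[:, 0, 1] = 30  # intensity 90
        bands[:, 0, 2] = 20  # intensity 60
        ri = relative_intensity(make_layer(bands))
        assert ri[0, 0] == 0.0
        assert ri[0, 1] == 100.0
        assert ri[0, 2] == pytest.approx(50.0)

    def test_constant_mosaic_maps_to_100_everywhere(self):
        ri = relative_intensity(make_layer(np.full((3, 4, 4), 7, dtype=np.uint8)))
        assert (ri == 100.0).all()

    def test_all_nodata_layer_rejected(self):
        layer = make_layer(np.zeros((3, 4, 4), dtype=np.uint8), nodata=0)
        with pytest.raises(ValueError, match="nodata"):
            relative_intensity(layer)


class TestSunlitMask:
    def test_threshold_boundary_keeps_exact_hits(self):
        ri = np.array([[5.0, 19.9, 20.0, 80.0]])
        mask = np.array([[0, 0], [0, 1], [0, 2], [0, 3]])
        kept = sunlit_mask(mask, ri, 20.0)
        assert kept.tolist() == [[0, 2], [0, 3]]

    def test_zero_threshold_is_identity(self):
        ri = np.array([[5.0, 19.9, 20.0, 80.0]])
        mask = np.array([[0, 0], [0, 1], [0, 2], [0, 3]])
        assert np.array_equal(sunlit_mask(mask, ri, 0.0), mask)

    def test_generated_crowns_lose_the_shadowed_fraction(self, planted_world):
        """Shadow fraction 0.3 at attenuation 0.1 leaves ~70% of crown pixels."""
        from phenocrown.geodata import narrow_crown, pixels_in_polygon

        phenology, _, crowns, layers = planted_world
        assert phenology.shadow_fraction == 0.3
        layer = layers[0]
        ri = relative_intensity(layer)
        fractions = []
        for crown in crowns:
            mask = pixels_in_polygon(
                narrow_crown(crown.geometry, 0.5), layer.transform, layer.shape
            )
            if len(mask) == 0:
                continue
            fractions.append(len(sunlit_mask(mask, ri, 20.0)) / len(mask))
        assert np.mean(fractions) == pytest.approx(0.7, abs=0.05)

    def test_raising_threshold_never_recovers_pixels(self):
        rng = np.random.default_rng(0)
        ri = rng.uniform(0, 100, size=(20, 20))
        mask = _full_mask((20, 20))
        sizes = [len(sunlit_mask(mask, ri, t)) for t in (0, 10, 20, 50, 90, 100)]
        assert sizes == sorted(sizes, reverse=True)


class TestSpectralMetrics:
    def test_equal_green_red_zeroes_ngrvi(self):
        values = np.tile([40.0, 90.0, 90.0], (20, 1))  # B, G, R
        out = spectral_metrics(values, "RGB")
        assert out["ngrvi"] == 0.0

    def test_nir_three_times_red_gives_ndvi_half(self):
        values = np.tile([150.0, 50.0, 80.0], (15, 1))  # NIR, R, G
        out = spectral_metrics(values, "CIR")
        assert out["ndvi"] == pytest.approx(0.5)
        assert out["gndvi"] == pytest.approx((150 - 80) / (150 + 80))

    @pytest.mark.parametrize("camera", ["RGB", "CIR"])
    def test_normalized_bands_sum_to_one(self, camera):
        rng = np.random.default_rng(3)
        values = rng.uniform(1, 255, size=(50, 3))
        out = spectral_metrics(values, camera)
        assert out["norm_1"] + out["norm_2"] + out["norm_3"] == pytest.approx(1.0)
        for name in ("ndvi", "gndvi", "ngrvi", "ngbi", "nrbi"):
            if name in out:
                assert -1.0 <= out[name] <= 1.0

    def test_population_sd_and_unordered_ratios(self):
        values = np.array([[10.0, 20.0, 40.0], [30.0, 20.0, 40.0]])
        out = spectral_metrics(values, "RGB")
        assert out["mean_1"] == 20.0
        assert out["sd_1"] == 10.0  # population form, n divisor
        assert out["ratio_12"] == pytest.approx(20.0 / 20.0)
        assert out["ratio_13"] == pytest.approx(20.0 / 40.0)
        assert out["ratio_23"] == pytest.approx(20.0 / 40.0)

    def test_constant_band_shift_moves_indices_as_their_formulas_predict(self):
        rng = np.random.default_rng(5)
        values = rng.uniform(20, 120, size=(40, 3))
        shift = 30.0
        base = spectral_metrics(values, "RGB")
        shifted = spectral_metrics(values + shift, "RGB")
        m = values.mean(axis=0)
        assert shifted["ratio_12"] == pytest.approx((m[0] + shift) / (m[1] + shift))
        assert shifted["ngrvi"] == pytest.approx(
            (m[1] - m[2]) / (m[1] + m[2] + 2 * shift)
        )
        # a positive-difference index shrinks in magnitude under common shift
        if base["ngrvi"] != 0:
            assert abs(shifted["ngrvi"]) < abs(base["ngrvi"])


class TestGLCM:
    def test_constant_mask_collapses_to_single_cell(self):
        band = np.full((5, 5), 100, dtype=np.uint8)
        out = glcm_metrics(band, _full_mask((5, 5)))
        assert out["contrast"] == 0.0
        assert out["dissimilarity"] == 0.0
        assert out["homogeneity"] == 1.0
        assert out["entropy"] == 0.0
        assert out["second_moment"] == 1.0
        assert out["variance"] == 0.0
        assert out["correlation"] == 0.0

    def test_checkerboard_of_adjacent_levels(self):
        # values 0 and 8 land in adjacent 8-DN-wide bins at 32 levels
        band = np.array([[0, 8], [8, 0]], dtype=np.uint8)
        out = glcm_metrics(band, _full_mask((2, 2)), levels=32, offsets=((0, 1),))
        assert out["contrast"] == pytest.approx(1.0)
        assert out["dissimilarity"] == pytest.approx(1.0)
        assert out["homogeneity"] == pytest.approx(0.5)
        assert out["correlation"] == pytest.approx(-1.0)
        assert out["entropy"] == pytest.approx(np.log(2))
        assert out["second_moment"] == pytest.approx(0.5)

    def test_isolated_pixels_have_no_pairs(self):
        band = np.zeros((5, 5), dtype=np.uint8)
        mask = np.array([[0, 0], [4, 4]])
        assert glcm_metrics(band, mask) is None

    def test_levels_below_two_rejected(self):
        with pytest.raises(ValueError):
            glcm_metrics(np.zeros((3, 3)), _full_mask((3, 3)), levels=1)

    def test_quantization_shift_invariance(self):
        rng = np.random.default_rng(8)
        band = rng.integers(0, 200, size=(10, 10))
        mask = _full_mask((10, 10))
        base = glcm_metrics(band, mask, levels=32)
        shifted = glcm_metrics(band + 8, mask, levels=32)  # one full bin width
        for key in base:
            assert shifted[key] == pytest.approx(base[key], abs=1e-12)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(data=st.data())
    def test_matches_bruteforce_oracle_on_random_grids(self, data):
        h = data.draw(st.integers(2, 8))
        w = data.draw(st.integers(2, 8))
        band = np.array(
            data.draw(
                st.lists(
                    st.lists(st.integers(0, 255), min_size=w, max_size=w),
                    min_size=h,
                    max_size=h,
                )
            )
        )
        flat = data.draw(
            st.lists(st.booleans(), min_size=h * w, max_size=h * w)
        )
        mask = _full_mask((h, w))[np.array(flat, dtype=bool)]
        levels = data.draw(st.sampled_from([4, 8, 32]))
        offsets = data.draw(
            st.sampled_from([DEFAULT_OFFSETS, ((0, 1),), ((1, -1), (1, 1))])
        )
        ours = glcm_metrics(band, mask, levels=levels, offsets=offsets)
        oracle = glcm_oracle(band, mask, levels=levels, offsets=offsets)
        if oracle is None:
            assert ours is None
        else:
            for key, val in oracle.items():
                assert ours[key] == pytest.approx(val, abs=1e-10)


class TestFeatureTable:
    N_METRICS = 36  # 6 mean/sd + 3 ratios + 3 norms + 3 indices + 21 GLCM

    def test_column_accounting_and_no_absent_cells(self, planted_table):
        data = planted_table.data
        n_layers = 8  # 4 dates x 2 cameras
        assert data.shape[1] == 1 + n_layers * (self.N_METRICS + 1)
        assert not data.drop(columns="species").isna().any().any()
        assert set(feature_columns(data, surveys=["s01"])) == {
            c
            for c in data.columns
            if c.startswith("s01.") and not c.endswith("n_sunlit")
        }
        assert len(feature_columns(data, surveys=["s01"], cameras=["RGB"])) == 36

    def test_crown_order_does_not_change_content(self, planted_world):
        _, _, crowns, layers = planted_world
        subset = layers[:2]
        forward = build_feature_table(subset, crowns)
        backward = build_feature_table(subset, list(reversed(crowns)))
        assert forward.data.equals(backward.data)

    def test_fully_shadowed_crown_is_dropped_with_reason(self):
        from shapely.geometry import Point
        from phenocrown import CrownRecord

        bands = np.full((3, 40, 40), 10, dtype=np.uint8)
        bands[:, 2:18, 2:18] = 200  # bright crown
        bands[:, 22:38, 22:38] = 12  # dark crown, below the shadow threshold
        layer = make_layer(bands)
        y0 = layer.transform.y_origin
        bright = CrownRecord("bright", "oak", Point(2.0, y0 - 2.0).buffer(1.4))
        dark = CrownRecord("dark", "ash", Point(6.0, y0 - 6.0).buffer(1.4))
        table = build_feature_table([layer], [bright, dark], MetricConfig())
        assert list(table.data.index) == ["bright"]
        assert table.dropped[0][0] == "dark"
        assert "sunlit" in table.dropped[0][1]

    def test_zero_retained_crowns_is_an_error(self):
        from shapely.geometry import Point
        from phenocrown import CrownRecord

        layer = make_layer(np.full((3, 20, 20), 50, dtype=np.uint8))
        tiny = CrownRecord("tiny", "oak", Point(2, 2).buffer(0.3))
        with pytest.raises(ValueError, match="zero crowns"):
            build_feature_table([layer], [tiny], MetricConfig())

    def test_csv_roundtrip_preserves_table(self, tmp_path, planted_table):
        from phenocrown import FeatureTable

        path = planted_table.to_csv(tmp_path / "features.csv")
        back = FeatureTable.read_csv(path)
        assert back.data.shape == planted_table.data.shape
        np.testing.assert_allclose(
            back.data.drop(columns="species").to_numpy(),
            planted_table.data.drop(columns="species").to_numpy(),
        )
        assert back.dropped == planted_table.dropped
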