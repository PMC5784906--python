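"""QA filtering: edge drops, pixel exclusion, despiking, loess, median."""

import numpy as np
import pytest
import yaml

from rarelulc.classes import BANDS, NOMINAL_DOY
from rarelulc.modis_preprocess import (
    DEFAULT_USEFULNESS_WEIGHTS,
    CleanSeries,
    FilterConfig,
    QaSeries,
    UnusablePixelError,
    close_gaps,
    despike,
    drop_edge_composites,
    feature_names,
    flag_contaminated_pixels,
    from_feature_vector,
    low_quality_mask,
    median_replace,
    preprocess_series,
    smooth_and_resample,
    summer_mask,
    to_feature_vector,
    usefulness_weights,
    weighted_loess,
)

DATES23 = np.asarray(NOMINAL_DOY, dtype=float)


def make_series(values=None, quality=None, usefulness=None, n=23):
    dates = DATES23[:n]
    if values is None:
        values = 0.2 + 0.1 * np.sin(dates / 60.0)
    bands = {b: np.array(values, dtype=float).copy() for b in BANDS}
    return QaSeries(
        dates=dates,
        bands=bands,
        vi_quality=np.zeros(n, dtype=int) if quality is None else np.asarray(quality),
        vi_usefulness=np.zeros(n, dtype=int) if usefulness is None else np.asarray(usefulness),
    )


class TestEdgeDrop:
    def test_23_composites_reduce_to_18(self):
        out = drop_edge_composites(make_series())
        assert len(out) == 18
        assert np.array_equal(out.dates, DATES23[4:22])

    def test_boundary_six_composites_leave_one(self):
        out = drop_edge_composites(make_series(n=6))
        assert len(out) == 1
        assert out.dates[0] == DATES23[4]

    def test_too_short_raises(self):
        with pytest.raises(ValueError):
            drop_edge_composites(make_series(n=5))


class TestPixelExclusion:
    def _series_with_cloudy(self, cloudy_idx18):
        s = make_series()
        # mark composites cloudy on the 18-composite frame (offset 4)
        q = np.zeros(23, dtype=int)
        for i in cloudy_idx18:
            q[i + 4] = 3
        s.vi_quality = q
        return s

    def test_three_consecutive_cloudy_removed(self):
        s = self._series_with_cloudy([0, 1, 2])
        assert not flag_contaminated_pixels([s])[0]

    def test_three_nonconsecutive_summer_cloudy_kept(self):
        # summer composites on the 18-frame are indices 4..11
        s = self._series_with_cloudy([4, 6, 8])
        assert flag_contaminated_pixels([s])[0]

    def test_four_summer_cloudy_removed(self):
        s = self._series_with_cloudy([4, 6, 8, 10])
        assert not flag_contaminated_pixels([s])[0]

    def test_matches_brute_force_enumeration(self, rng):
        cfg = FilterConfig()

        def brute_force_keep(cloudy, in_summer):
            for i in range(len(cloudy) - 2):
                if cloudy[i] and cloudy[i + 1] and cloudy[i + 2]:
                    return False
            return sum(c and s for c, s in zip(cloudy, in_summer)) < 4

        series = []
        expected = []
        for _ in range(200):
            q = (rng.random(23) < 0.25).astype(int) * 3
            s = make_series(quality=q)
            series.append(s)
            trimmed = drop_edge_composites(s, cfg)
            expected.append(
                brute_force_keep(
                    list(low_quality_mask(trimmed, cfg)),
                    list(summer_mask(trimmed.dates)),
                )
            )
        assert np.array_equal(flag_contaminated_pixels(series, cfg), expected)


class TestDespike:
    def test_value_above_summer_q75_removed(self):
        values = np.arange(10, dtype=float)
        values[5:] = [1, 2, 3, 4, 100]
        summer = np.zeros(10, dtype=bool)
        summer[5:] = True
        out = despike(values, summer, "B1")
        # Q75 of [1,2,3,4,100] is 4 (linear interpolation); only 100 exceeds it
        assert np.isnan(out[9])
        assert np.isfinite(out[5:9]).all()
        assert np.array_equal(out[:5], values[:5])

    def test_constant_summer_series_untouched(self):
        values = np.full(8, 0.3)
        summer = np.ones(8, dtype=bool)
        out = despike(values, summer, "B7")
        assert np.isfinite(out).all()

    def test_b2_exempt_even_with_huge_spike(self):
        values = np.array([0.1, 0.1, 0.9, 0.1])
        summer = np.ones(4, dtype=bool)
        out = despike(values, summer, "B2")
        assert np.array_equal(out, values)

    def test_quantile_matches_numpy_oracle(self, rng):
        for _ in range(20):
            values = rng.random(18)
            summer = np.zeros(18, dtype=bool)
            summer[6:12] = True
            out = despike(values, summer, "B3")
            q = np.quantile(values[6:12], 0.75)
            expected_nan = summer & (values > q)
            assert np.array_equal(np.isnan(out), expected_nan)

    def test_empty_summer_raises(self):
        with pytest.raises(ValueError):
            despike(np.ones(5), np.zeros(5, dtype=bool), "B1")


class TestUsefulnessWeights:
    def test_best_flag_maps_to_one_and_bad_flags_small(self):
        w = usefulness_weights(np.array([0, 1, 2, 3, 4, 5, 9]))
        assert w[0] == 1.0
        assert np.all(np.diff(w) <= 0)
        assert np.all(w[5:] <= 0.1)

    def test_negative_flags_rejected(self):
        with pytest.raises(ValueError):
            usefulness_weights(np.array([-1]))

    def test_default_map_roundtrips_through_yaml(self):
        dumped = yaml.safe_load(yaml.safe_dump(DEFAULT_USEFULNESS_WEIGHTS))
        assert dumped == DEFAULT_USEFULNESS_WEIGHTS


class TestWeightedLoess:
    def test_reproduces_exact_quadratic(self):
        x = np.linspace(0, 10, 15)
        y = 2.0 - 0.5 * x + 0.25 * x**2
        fit = weighted_loess(x, y, np.ones(15), x, degree=2, span=1.0)
        assert np.allclose(fit, y, atol=1e-8)

    def test_zero_weight_point_is_ignored(self, rng):
        x = np.linspace(0, 10, 20)
        y = np.sin(x / 3) + rng.normal(0, 0.01, 20)
        y_out = y.copy()
        y_out[10] = 5.0  # gross outlier
        w = np.ones(20)
        w[10] = 0.0
        with_out = weighted_loess(x, y_out, w, x)
        without = weighted_loess(np.delete(x, 10), np.delete(y, 10),
                                 np.delete(w, 10), x)
        assert np.allclose(with_out, without, atol=1e-8)

    def test_single_query_matches_normal_equations_oracle(self, rng):
        x = np.sort(rng.random(25)) * 100
        y = rng.random(25)
        prior = rng.random(25) + 0.1
        span, degree = 0.5, 2
        x0 = 37.0
        fit = weighted_loess(x, y, prior, np.array([x0]), degree, span)[0]
        # independent oracle: explicit tricube x prior weighted normal equations
        q = int(np.ceil(span * len(x)))
        d = np.abs(x - x0)
        idx = np.argsort(d, kind="stable")[:q]
        u = d[idx] / d[idx].max()
        w = (1 - u**3) ** 3 * prior[idx]
        design = np.vander(x[idx] - x0, degree + 1, increasing=True)
        beta = np.linalg.solve(design.T @ (w[:, None] * design), design.T @ (w * y[idx]))
        assert fit == pytest.approx(beta[0], abs=1e-10)

    def test_too_few_valid_points_raises(self):
        with pytest.raises(UnusablePixelError):
            weighted_loess(np.arange(5.0), np.full(5, np.nan), np.ones(5), [2.0])


class TestCloseGaps:
    def test_no_gaps_is_identity(self):
        s = make_series()
        out = close_gaps(s)
        for b in BANDS:
            assert np.array_equal(out.bands[b], s.bands[b])

    def test_interior_gap_filled_near_loess_prediction(self):
        s = make_series()
        truth = s.bands["B1"][10]
        s.bands["B1"][10] = np.nan
        out = close_gaps(s)
        # oracle: weighted least squares at the gap date over the valid points
        cfg = FilterConfig()
        valid = np.isfinite(s.bands["B1"])
        expected = weighted_loess(
            s.dates[valid], s.bands["B1"][valid], np.ones(valid.sum()),
            [s.dates[10]], cfg.loess_degree, cfg.loess_span,
        )[0]
        assert out.bands["B1"][10] == pytest.approx(expected, abs=1e-12)
        assert abs(out.bands["B1"][10] - truth) < 0.02
        # observed values are untouched
        assert np.array_equal(out.bands["B1"][valid], s.bands["B1"][valid])

    def test_too_few_valid_points_flags_pixel(self):
        s = make_series()
        s.bands["B2"][:] = np.nan
        s.bands["B2"][:3] = 0.2
        with pytest.raises(UnusablePixelError):
            close_gaps(s)


class TestMedianReplace:
    def test_low_quality_point_replaced_by_window_median(self):
        s = make_series(values=[1, 1, 9, 1, 1] + [1] * 18)
        s.vi_quality[2] = 3
        out = median_replace(s)
        assert out.bands["B1"][2] == 1.0

    def test_all_good_flags_identity(self):
        s = make_series()
        out = median_replace(s)
        for b in BANDS:
            assert np.array_equal(out.bands[b], s.bands[b])

    def test_only_low_quality_points_change(self):
        s = make_series(values=list(np.arange(23, dtype=float)))
        s.vi_usefulness[7] = 6
        out = median_replace(s)
        changed = out.bands["B1"] != s.bands["B1"]
        assert set(np.where(changed)[0]) <= {7}

    def test_edge_point_uses_shrunken_window(self):
        values = np.array([9.0, 1.0, 1.0, 2.0, 3.0] + [1.0] * 18)
        s = make_series(values=values)
        s.vi_quality[0] = 3
        out = median_replace(s)
        # window at index 0 shrinks to [0, 1, 2]: median of 9,1,1 = 1
        assert out.bands["B1"][0] == np.median(values[:3])


class TestSmoothResample:
    def test_eighteen_evenly_spaced_common_dates(self):
        s = drop_edge_composites(make_series())
        clean = smooth_and_resample(s)
        assert clean.dates.size == 18
        steps = np.diff(clean.dates)
        assert np.allclose(steps, steps[0], atol=1e-9)
        assert clean.dates[0] == s.dates.min() and clean.dates[-1] == s.dates.max()

    def test_constant_series_stays_constant(self):
        s = drop_edge_composites(make_series(values=[0.3] * 23))
        clean = smooth_and_resample(s)
        assert np.allclose(clean.values, 0.3, atol=1e-9)


class TestFeatureVector:
    def test_length_and_band_major_order(self):
        dates = np.linspace(65, 337, 18)
        values = np.arange(72, dtype=float).reshape(4, 18)
        clean = CleanSeries(dates=dates, values=values)
        vec = to_feature_vector(clean)
        assert vec.size == 72
        # element 19 (index 18) is B2 at the first common date
        assert vec[18] == values[1, 0]
        assert feature_names()[18] == "B2_d01"

    def test_roundtrip_is_identity(self):
        dates = np.linspace(65, 337, 18)
        vec = np.linspace(0, 1, 72)
        back = to_feature_vector(from_feature_vector(vec, dates))
        assert np.array_equal(back, vec)

    def test_missing_values_rejected(self):
        dates = np.linspace(65, 337, 18)
        values = np.full((4, 18), np.nan)
        with pytest.raises(ValueError):
            CleanSeries(dates=dates, values=values)


class TestPipelineProperties:
    def test_output_gap_free_and_deterministic(self, tiny_scene):
        s = tiny_scene.qa_series(5)
        c1 = preprocess_series(s)
        c2 = preprocess_series(s)
        assert np.isfinite(c1.values).all()
        assert np.array_equal(c1.values, c2.values)

    def test_near_idempotent_on_clean_smooth_series(self):
        s = make_series()
        clean = preprocess_series(s)
        # re-evaluate the original smooth curve at the common dates
        truth = 0.2 + 0.1 * np.sin(clean.dates / 60.0)
        for bi in range(4):
            assert np.max(np.abs(clean.values[bi] - truth)) < 5e-3
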