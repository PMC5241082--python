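"""ROI histogram metrics, exact rank-sum test, Pearson correlation."""

import math

import numpy as np
import pytest
from scipy import stats as sps

import gnlcorr as g
from gnlcorr.roi import histogram_stats


class TestHistogramStats:
    def test_constant_sample_degenerate_floor(self):
        st = histogram_stats(np.full(500, 2.0))
        assert st.median == 2.0
        assert st.fwhm == pytest.approx(0.02)  # one bin width floor
        assert st.nonuniformity == pytest.approx(0.01)

    def test_gaussian_fwhm_matches_2355_sigma(self):
        rng = np.random.default_rng(8)
        x = rng.normal(1.8, 0.05, 200_000)
        st = histogram_stats(x)
        assert st.fwhm == pytest.approx(2.355 * 0.05, rel=0.10)
        assert st.median == pytest.approx(1.8, abs=0.001)

    def test_bimodal_fwhm_spans_outermost_crossings(self):
        rng = np.random.default_rng(3)
        x = np.concatenate(
            [rng.normal(1.6, 0.02, 50_000), rng.normal(1.9, 0.02, 50_000)]
        )
        st = histogram_stats(x)
        assert st.fwhm > 0.3  # spans both modes, not just one peak

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_median_is_raw_sample_median(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.uniform(1.0, 2.5, 1234)
        st = histogram_stats(x)
        assert st.median == np.median(x)


class TestROI:
    def make_adc(self, value=2.0, shape=(20, 20, 10)):
        geom = g.ImageGeometry.from_origin_spacing(
            (-47.5, -47.5, -22.5), (5.0, 5.0, 5.0), shape
        )
        vals = np.full(shape, value)
        return g.ADCMap(vals, np.ones(shape, bool), geom)

    def test_roi_histogram_constant_map(self):
        adc = self.make_adc(2.0)
        roi = g.ROISpec(((-20.0, 20.0), (-20.0, 20.0), (-10.0, 10.0)))
        st = g.roi_histogram(adc, roi)
        assert st.median == 2.0
        assert st.fwhm == pytest.approx(0.02)

    def test_roi_too_few_valid_voxels(self):
        adc = self.make_adc()
        roi = g.ROISpec(((-4.0, 4.0), (-4.0, 4.0), (-4.0, 4.0)))
        with pytest.raises(ValueError, match="valid voxels"):
            g.roi_histogram(adc, roi)

    def test_roi_outside_volume(self):
        adc = self.make_adc()
        roi = g.ROISpec(((200.0, 240.0), (-20.0, 20.0), (-10.0, 10.0)))
        with pytest.raises(ValueError, match="intersect"):
            g.roi_histogram(adc, roi)

    def test_reference_measure_uniform_phantom(self):
        adc = self.make_adc(2.0)
        ref = g.reference_roi_measure(adc)
        assert ref["mean"] == pytest.approx(2.0)
        assert ref["sd"] == 0.0
        assert ref["ci"] == 0.0
        assert ref["volume_cm3"] == pytest.approx(27.0)

    def test_cube_roi_volume_30mm(self):
        roi = g.ROISpec.cube((0.0, 0.0, 0.0), 30.0)
        assert roi.volume_cm3 == pytest.approx(27.0)
        assert roi.kind == "cubic"


class TestPercentBias:
    def test_zero_when_equal(self):
        assert g.percent_bias(1.93, 1.93) == 0.0

    def test_published_style_values(self):
        assert g.percent_bias(1.65, 1.93) == pytest.approx(-14.5, abs=0.01)
        assert g.percent_bias(1.96, 1.95) == pytest.approx(0.5, abs=0.02)

    def test_rejects_nonpositive_reference(self):
        with pytest.raises(ValueError):
            g.percent_bias(1.5, 0.0)


class TestCrossSystem:
    def test_reference_medians(self):
        out = g.cross_system_summary([1.93, 1.95, 1.83, 1.86, 2.11, 1.95])
        assert out["range"] == pytest.approx(0.28)
        assert out["median"] == pytest.approx(1.94)

    def test_position2_pre_range(self):
        out = g.cross_system_summary([1.65, 1.67, 1.72, 1.55, 1.88, 1.80])
        assert out["range"] == pytest.approx(0.33)

    def test_identical_systems(self):
        out = g.cross_system_summary([1.9, 1.9, 1.9])
        assert out["range"] == 0.0
        assert out["range_to_median"] == 0.0


class TestRankSumExact:
    def test_identical_samples_p_one(self):
        x = [1.0, 2.0, 3.0]
        assert g.rank_sum_exact(x, x) == 1.0

    def test_complete_separation_6v6(self):
        p = g.rank_sum_exact([1, 2, 3, 4, 5, 6], [7, 8, 9, 10, 11, 12])
        assert p == pytest.approx(2.0 / 924.0, abs=1e-15)

    def test_hand_enumerated_2v2(self):
        assert g.rank_sum_exact([5.0, 6.0], [1.0, 2.0]) == pytest.approx(2.0 / 6.0)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_exact_mann_whitney_oracle(self, seed):
        """Tie-free random instances with n+m <= 10 vs scipy's exact MWU."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 6))
        m = int(rng.integers(2, 11 - n))
        x = rng.normal(size=n)
        y = rng.normal(size=m)
        expected = sps.mannwhitneyu(x, y, method="exact").pvalue
        assert g.rank_sum_exact(x, y) == pytest.approx(expected, abs=1e-12)

    def test_tied_instance_matches_permutation_oracle(self):
        x = np.array([32.0, 33.0, 27.0, 27.0, 32.0, 34.0])
        y = np.array([41.0, 54.0, 34.0, 42.0, 37.0, 49.0])

        def statistic(a, b):
            return sps.rankdata(np.concatenate([a, b]))[: len(a)].sum()

        ref = sps.permutation_test(
            (x, y), statistic, permutation_type="independent", n_resamples=np.inf,
            alternative="two-sided",
        )
        # two-sided doubling convention differs at most by the cap; here the
        # tail is one-sided-dominated so the values coincide
        assert g.rank_sum_exact(x, y) == pytest.approx(ref.pvalue, abs=1e-9)

    def test_enumeration_limit_refusal_and_fallback(self):
        x = np.arange(13.0)
        y = np.arange(13.0) + 0.5
        with pytest.raises(ValueError, match="enumeration limit"):
            g.rank_sum_exact(x, y)
        p = g.rank_sum_exact(x, y, fallback_normal=True)
        assert 0.0 < p <= 1.0

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            g.rank_sum_exact([], [1.0])


class TestPearson:
    def test_perfect_linear(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        r, p = g.pearson(x, 2 * x + 1)
        assert r == pytest.approx(1.0)
        assert p < 1e-6

    def test_matches_closed_form(self):
        rng = np.random.default_rng(17)
        x = rng.normal(size=10)
        y = rng.normal(size=10)
        r, p = g.pearson(x, y)
        rr = np.corrcoef(x, y)[0, 1]
        assert r == pytest.approx(rr, abs=1e-12)
        t = rr * math.sqrt(8 / (1 - rr**2))
        assert p == pytest.approx(2 * sps.t.sf(abs(t), 8), abs=1e-12)

    def test_independent_samples_mean_r_near_zero(self):
        rng = np.random.default_rng(21)
        rs = []
        for _ in range(300):
            x = rng.normal(size=12)
            y = rng.permutation(x)
            rs.append(g.pearson(x, y)[0])
        assert abs(np.mean(rs)) < 0.05

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            g.pearson([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
        with pytest.raises(ValueError):
            g.pearson([1.0, 2.0], [1.0, 2.0])
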