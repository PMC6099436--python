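"""Calibration, replicate statistics, control ratios, provenance calls."""

import pytest
from hypothesis import given, settings, strategies as st

from phytoscreen.quant import (classify_provenance, control_ratio,
                               fit_calibration, quantify, replicate_stats,
                               rsd_percent, translocation_factor)


class TestCalibration:
    def test_exact_two_point_line(self):
        curve = fit_calibration([(0, 0), (10, 1000)])
        assert curve.slope == pytest.approx(100.0)
        assert curve.intercept == pytest.approx(0.0)

    def test_collinear_points_r2_one(self):
        curve = fit_calibration([(0, 5), (5, 505), (10, 1005)])
        assert curve.slope == pytest.approx(100.0)
        assert curve.intercept == pytest.approx(5.0)
        assert curve.r_squared == pytest.approx(1.0)

    @pytest.mark.parametrize("points", [[(5.0, 100.0)], [(5, 10), (5, 12)]])
    def test_insufficient_levels_rejected(self, points):
        with pytest.raises(ValueError):
            fit_calibration(points)

    def test_quantify_example(self):
        curve = fit_calibration([(0, 0), (1000, 100000)])  # slope 100
        conc, clipped = quantify(21450, curve, sample_mass_g=1.0,
                                 extract_volume_l=0.002)
        assert conc == pytest.approx(0.429)
        assert not clipped

    def test_area_at_intercept_is_zero(self):
        curve = fit_calibration([(0, 50), (100, 10050)])
        conc, clipped = quantify(50, curve)
        assert conc == 0.0 and not clipped
        conc, clipped = quantify(10, curve)
        assert conc == 0.0 and clipped

    def test_zero_mass_rejected(self):
        curve = fit_calibration([(0, 0), (10, 1000)])
        with pytest.raises(ValueError):
            quantify(100, curve, sample_mass_g=0.0)

    @given(st.floats(min_value=1, max_value=5000))
    @settings(derandomize=True)
    def test_round_trip_recovers_concentration(self, conc_ug_l):
        """quantify(area(conc)) must invert the calibration to 1e-9 rel."""
        slope, intercept = 137.5, 42.0
        curve = fit_calibration([(0, intercept), (1000, intercept + 1000 * slope),
                                 (2000, intercept + 2000 * slope)])
        area = intercept + slope * conc_ug_l
        got, _ = quantify(area, curve, sample_mass_g=1.0, extract_volume_l=0.002)
        assert got == pytest.approx(conc_ug_l * 0.002, rel=1e-9)


class TestReplicateStats:
    def test_mean_sd_rsd(self):
        s = replicate_stats([1.0, 2.0, 3.0])
        assert s.mean == pytest.approx(2.0)
        assert s.sd == pytest.approx(1.0)     # sample SD, n-1 denominator
        assert s.rsd_percent == pytest.approx(50.0)

    def test_identical_values_zero_spread(self):
        s = replicate_stats([2.5, 2.5, 2.5])
        assert s.sd == 0.0 and s.rsd_percent == 0.0

    def test_single_value_rejected(self):
        with pytest.raises(ValueError):
            replicate_stats([1.0])

    @given(st.lists(st.floats(min_value=0.5, max_value=100), min_size=2, max_size=8),
           st.floats(min_value=0.1, max_value=50))
    @settings(derandomize=True)
    def test_rsd_scale_invariant(self, values, c):
        base = replicate_stats(values)
        scaled = replicate_stats([v * c for v in values])
        assert scaled.rsd_percent == pytest.approx(base.rsd_percent, rel=1e-9)

    def test_rsd_from_published_style_mean_sd(self):
        assert round(rsd_percent(1.83, 0.50)) == 27
        assert round(rsd_percent(2.63, 0.37)) == 14


class TestControlRatio:
    @pytest.mark.parametrize("root, gm, expected",
                             [(184, 100, 1.84), (51000, 1000, 51.0), (7.5, 7.5, 1.0)])
    def test_examples(self, root, gm, expected):
        assert control_ratio(root, gm) == pytest.approx(expected)

    def test_zero_gm_signals_not_detected(self):
        with pytest.raises(ZeroDivisionError, match="not detected"):
            control_ratio(100.0, 0.0)


class TestClassifyProvenance:
    def test_gm_absent_is_true_metabolite(self):
        call = classify_provenance("OH-DM-CLP", True, False, False, False)
        assert call.call == "true_metabolite"
        assert call.ratio is None

    @pytest.mark.parametrize("ratio, expected", [
        (378.0, "metabolite_dominant"),
        (491.0, "metabolite_dominant"),
        (51.0, "mixed"),
        (25.0, "mixed"),
        (1.84, "mixed"),
        (0.5, "transformation_leaning"),
    ])
    def test_ratio_bands(self, ratio, expected):
        call = classify_provenance("x", True, True, True, False, ratio=ratio)
        assert call.call == expected
        assert call.ratio == ratio

    def test_negative_control_trumps_everything(self):
        call = classify_provenance("x", True, True, True, True, ratio=500.0)
        assert call.call == "contamination_suspect"

    def test_parent_compound(self):
        call = classify_provenance("STR", True, True, True, False, ratio=0.2,
                                   is_parent=True)
        assert call.call == "parent"

    def test_gm_without_ratio_rejected(self):
        with pytest.raises(ValueError):
            classify_provenance("x", True, False, True, False, ratio=None)

    def test_ratio_without_gm_rejected(self):
        with pytest.raises(ValueError):
            classify_provenance("x", True, False, False, False, ratio=2.0)

    def test_totality_over_input_lattice(self):
        """Every consistent flag/ratio combination yields exactly one call."""
        for root in (True, False):
            for leaf in (True, False):
                for gm in (True, False):
                    for neg in (True, False):
                        for is_parent in (True, False):
                            ratio = 10.0 if gm else None
                            call = classify_provenance("x", root, leaf, gm, neg,
                                                       ratio=ratio,
                                                       is_parent=is_parent)
                            assert call.call  # one and only one call


class TestTranslocation:
    def test_leaf_accumulating_and_root_retained(self):
        assert translocation_factor(2.63, 0.91) == pytest.approx(2.89, abs=0.01)
        assert translocation_factor(0.52, 4.29) == pytest.approx(0.12, abs=0.005)
        assert translocation_factor(1.5, 1.5) == 1.0

    def test_zero_root_flagged(self):
        with pytest.raises(ValueError):
            translocation_factor(1.0, 0.0)
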