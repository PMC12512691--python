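import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from leafgas import (
    ConfigurationError,
    GsmaxParams,
    anatomical_gsmax,
    compare_groups,
    density_size_correlation,
    operational_opening,
    size_summary,
    stomatal_density,
)

PARAMS = GsmaxParams(
    amax_model=("affine_product", {"alpha": 0.06}),
    pore_depth_model=("fraction_of_width", {"c": 0.45}),
)


class TestDensity:
    def test_three_standard_fields(self):
        counts = pd.DataFrame(
            {"individual": ["a"] * 3, "n_stomata": [20, 20, 20], "field_area": [0.198] * 3}
        )
        out = stomatal_density(counts)
        assert out["density_mm2"].iloc[0] == pytest.approx(60 / 0.594, rel=1e-12)
        assert out["density_mm2"].iloc[0] == pytest.approx(101.0, abs=0.02)

    def test_zero_count_field(self):
        counts = pd.DataFrame({"individual": ["a"], "n_stomata": [0], "field_area": [0.198]})
        assert stomatal_density(counts)["density_mm2"].iloc[0] == 0.0

    def test_invalid_area_rejected(self):
        counts = pd.DataFrame({"individual": ["a"], "n_stomata": [5], "field_area": [0.0]})
        with pytest.raises(ValueError):
            stomatal_density(counts)

    @settings(deadline=None, max_examples=40)
    @given(n=st.integers(1, 200), parts=st.integers(2, 6))
    def test_invariant_to_splitting_fields(self, n, parts):
        """Σn/Σarea is unchanged when a field is split into subfields."""
        whole = pd.DataFrame({"individual": ["a"], "n_stomata": [n], "field_area": [0.6]})
        split = pd.DataFrame(
            {"individual": ["a"] * parts,
             "n_stomata": [n // parts] * (parts - 1) + [n - (n // parts) * (parts - 1)],
             "field_area": [0.6 / parts] * parts}
        )
        d1 = stomatal_density(whole)["density_mm2"].iloc[0]
        d2 = stomatal_density(split)["density_mm2"].iloc[0]
        assert d1 == pytest.approx(d2, rel=1e-9)


class TestSizes:
    def test_group_mean_ratio_one_decimal(self):
        # ratio of published means: 24.1/6.4 -> 3.8 at 1 d.p.
        meas = pd.DataFrame({"individual": ["a"] * 2, "length": [24.1] * 2, "width": [6.4] * 2})
        out = size_summary(meas)
        assert round(out["ratio_of_means"].iloc[0], 1) == 3.8

    def test_identical_stomata_sd_zero(self):
        meas = pd.DataFrame({"individual": ["a"] * 5, "length": [24.0] * 5, "width": [6.0] * 5})
        out = size_summary(meas)
        assert out["length_sd"].iloc[0] == 0.0
        assert out["ratio_sd"].iloc[0] == 0.0

    def test_mean_of_ratios_differs_from_ratio_of_means_on_skewed_sample(self):
        rng = np.random.default_rng(5)
        length = np.exp(rng.normal(3.2, 0.3, 400))
        width = np.exp(rng.normal(1.8, 0.3, 400))
        width = np.minimum(width, length)
        meas = pd.DataFrame({"individual": ["a"] * 400, "length": length, "width": width})
        out = size_summary(meas)
        # by Jensen's inequality the mean of per-stoma ratios exceeds the
        # ratio of means here; both are reported
        assert out["ratio_mean"].iloc[0] > out["ratio_of_means"].iloc[0]


class TestGsmax:
    def test_hand_computed_case(self):
        # spreadsheet-style evaluation with a fixed pore geometry
        params = GsmaxParams(
            amax_model=("affine_product", {"alpha": 0.0, "beta": 10.0}),  # µm²
            pore_depth_model=("constant", {"value": 3.0}),  # µm
            d_w=2.49e-5,
            v=0.0224,
        )
        d, amax, depth = 1e8, 10e-12, 3e-6
        expected = (d * 2.49e-5 * amax) / (
            0.0224 * (depth + (math.pi / 2) * math.sqrt(amax / math.pi))
        )
        got = anatomical_gsmax(100.0, 20.0, 6.0, params)
        assert got == pytest.approx(expected, rel=1e-12)
        assert got == pytest.approx(0.1916, abs=2e-4)

    def test_linear_in_density(self):
        g1 = anatomical_gsmax(100.0, 24.0, 6.4, PARAMS)
        g2 = anatomical_gsmax(200.0, 24.0, 6.4, PARAMS)
        assert g2 == pytest.approx(2 * g1, rel=1e-12)

    def test_monotonicity_in_pore_area_and_depth(self):
        base = anatomical_gsmax(100.0, 24.0, 6.4, PARAMS)
        bigger_pore = GsmaxParams(
            amax_model=("affine_product", {"alpha": 0.09}),
            pore_depth_model=("fraction_of_width", {"c": 0.45}),
        )
        deeper = GsmaxParams(
            amax_model=("affine_product", {"alpha": 0.06}),
            pore_depth_model=("fraction_of_width", {"c": 0.9}),
        )
        assert anatomical_gsmax(100.0, 24.0, 6.4, bigger_pore) > base
        assert anatomical_gsmax(100.0, 24.0, 6.4, deeper) < base

    def test_missing_coefficients_is_configuration_error(self):
        with pytest.raises(ConfigurationError):
            GsmaxParams(amax_model=("affine_product", {"alpha": 0.06}),
                        pore_depth_model=("unknown_model", {}))
        with pytest.raises(ConfigurationError):
            GsmaxParams(amax_model=None, pore_depth_model=("constant", {"value": 3.0}))

    def test_calibrated_gsmax_reproduces_operational_opening_row(self):
        """Calibrating the pore-area coefficient so g_smax matches a known
        species mean makes the downstream opening ratio come out right."""
        from scipy.optimize import brentq

        density, SL, WA = 100.3, 24.1, 6.4
        target = 0.378

        def mismatch(alpha):
            p = GsmaxParams(amax_model=("affine_product", {"alpha": alpha}),
                            pore_depth_model=("fraction_of_width", {"c": 0.45}))
            return anatomical_gsmax(density, SL, WA, p) - target

        alpha = brentq(mismatch, 1e-4, 1.0)
        p = GsmaxParams(amax_model=("affine_product", {"alpha": alpha}),
                        pore_depth_model=("fraction_of_width", {"c": 0.45}))
        gsmax = anatomical_gsmax(density, SL, WA, p)
        _, pct = operational_opening(0.252, gsmax)
        assert pct == 67


class TestOperationalOpening:
    @pytest.mark.parametrize(
        "gsw,gsmax,expected",
        [(0.252, 0.378, 67), (0.163, 0.422, 39), (0.261, 0.333, 78)],
    )
    def test_printed_row(self, gsw, gsmax, expected):
        _, pct = operational_opening(gsw, gsmax)
        assert pct == expected

    def test_equal_values_give_100(self):
        _, pct = operational_opening(0.3, 0.3)
        assert pct == 100

    def test_scale_invariance(self):
        p1, _ = operational_opening(0.2, 0.4)
        p2, _ = operational_opening(0.2 * 7.3, 0.4 * 7.3)
        assert p1 == pytest.approx(p2, rel=1e-12)

    def test_nonpositive_gsmax_rejected(self):
        with pytest.raises(ValueError):
            operational_opening(0.2, 0.0)


class TestCorrelation:
    def test_perfect_anticorrelation(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        res = density_size_correlation(x, -2 * x + 10)
        assert res.r == pytest.approx(-1.0)
        assert res.sign == -1

    def test_zero_variance_flagged_undefined(self):
        res = density_size_correlation([1.0, 1.0, 1.0], [2.0, 3.0, 4.0])
        assert not res.defined and math.isnan(res.r)

    def test_null_distribution_small_r_uniformish_p(self):
        rng = np.random.default_rng(7)
        ps = []
        for _ in range(200):
            x, y = rng.normal(size=(2, 100))
            res = density_size_correlation(x, y)
            ps.append(res.p)
        ps = np.array(ps)
        # under independence p is ~Uniform(0,1): mean near 0.5, tails populated
        assert abs(ps.mean() - 0.5) < 0.08
        assert 0.05 < np.mean(ps < 0.5) < 0.95

    def test_published_species_means_anticorrelated(self):
        from leafgas.reference import SPECIES, STOMATAL_DENSITY, STOMATAL_LENGTH

        dens = [STOMATAL_DENSITY[s] for s in SPECIES]
        length = [STOMATAL_LENGTH[s] for s in SPECIES]
        assert density_size_correlation(dens, length).sign == -1


class TestCompareGroups:
    def test_identical_groups_share_letter(self):
        vals = [1.0, 2.0, 3.0] * 3
        groups = ["a"] * 3 + ["b"] * 3 + ["c"] * 3
        res = compare_groups(vals, groups)
        assert res.p == pytest.approx(1.0)
        assert len(set(res.letters.values())) == 1

    def test_widely_separated_groups_get_distinct_letters(self):
        rng = np.random.default_rng(1)
        a = rng.normal(0.0, 1.0, 10)
        b = rng.normal(10.0, 1.0, 10)
        res = compare_groups(np.r_[a, b], ["a"] * 10 + ["b"] * 10)
        assert res.letters["a"] != res.letters["b"]
        assert res.p < 1e-6

    def test_f_statistic_matches_textbook_formula(self):
        # groups [0,1,2],[2,3,4],[4,5,6]: SSB=24 (df 2), SSW=6 (df 6) -> F=12
        vals = [0, 1, 2, 2, 3, 4, 4, 5, 6]
        groups = ["a"] * 3 + ["b"] * 3 + ["c"] * 3
        res = compare_groups(vals, groups)
        assert res.f == pytest.approx(12.0, rel=1e-12)

    def test_degenerate_groups_rejected(self):
        with pytest.raises(ValueError):
            compare_groups([1.0, 2.0, 3.0], ["a", "a", "b"])
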