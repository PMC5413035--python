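"""Resistance-curve families, surface construction and candidate enumeration."""

import numpy as np
import pytest

from resispread.core import AlignmentError, ConfigurationError, RasterGrid
from resispread.resistance import (
    CandidateLadder,
    ResistanceCurve,
    VariableSpec,
    build_surface,
    combine_surfaces,
    enumerate_multivariate_candidates,
    enumerate_univariate_candidates,
    evaluate_curve,
    offset_surface,
    rescale_curve,
)


class TestEvaluateCurve:
    @pytest.mark.parametrize(
        "curve,x,x_range,expected",
        [
            # Gaussian resistance is minimal (1) at the optimal slope
            (ResistanceCurve("gaussian", r_max=100, x_opt=50, x_sd=20), 50.0, (0, 1), 1.0),
            # hand evaluation: 10 - 9 exp(-(70-50)^2 / (2*20^2)) = 10 - 9 e^{-1/2}
            (
                ResistanceCurve("gaussian", r_max=10, x_opt=50, x_sd=20),
                70.0,
                (0, 1),
                10 - 9 * np.exp(-0.5),
            ),
            # binary barrier cell carries the full ratio
            (ResistanceCurve("binary_ratio", ratio=1000), 1.0, (0, 1), 1000.0),
            (ResistanceCurve("binary_ratio", ratio=1000), 0.0, (0, 1), 1.0),
            # monotonic endpoints on normalised units
            (ResistanceCurve("monotonic_positive", r_max=50, r_exp=4), 1.0, (0, 1), 50.0),
            (ResistanceCurve("monotonic_positive", r_max=50, r_exp=4), 0.0, (0, 1), 1.0),
            (ResistanceCurve("monotonic_negative", r_max=50, r_exp=4), 0.0, (0, 1), 50.0),
            # breakpoint: resistance 1 inside the favourable interval
            (
                ResistanceCurve("breakpoint", break_lo=20, break_hi=60, outside_value=100),
                40.0,
                (0, 1),
                1.0,
            ),
            (
                ResistanceCurve("breakpoint", break_lo=20, break_hi=60, outside_value=100),
                70.0,
                (0, 1),
                100.0,
            ),
            (ResistanceCurve("null_ibd"), 123.0, (0, 1), 1.0),
        ],
    )
    def test_closed_forms(self, curve, x, x_range, expected):
        assert evaluate_curve(curve, x, x_range) == pytest.approx(expected, abs=1e-12)

    def test_monotonic_normalisation_uses_raster_range(self):
        curve = ResistanceCurve("monotonic_positive", r_max=50, r_exp=2)
        # x = 30 over range (10, 50) normalises to 0.5
        assert evaluate_curve(curve, 30.0, (10, 50)) == pytest.approx(1 + 49 * 0.25)

    @pytest.mark.parametrize(
        "family",
        ["monotonic_positive", "monotonic_negative", "gaussian", "breakpoint", "binary_ratio"],
    )
    def test_curve_minimum_is_one_over_observed_range(self, family):
        """Every family attains resistance 1 somewhere in the variable range."""
        if family in ("monotonic_positive", "monotonic_negative"):
            curve = ResistanceCurve(family, r_max=100, r_exp=2)
        elif family == "gaussian":
            curve = ResistanceCurve(family, r_max=100, x_opt=50, x_sd=20)
        elif family == "breakpoint":
            curve = ResistanceCurve(family, break_lo=20, break_hi=60, outside_value=500)
        else:
            curve = ResistanceCurve(family, ratio=500)
        # step 0.1 keeps the gaussian optimum (x_opt = 50) exactly on-grid
        x = np.linspace(0, 90, 901) if family != "binary_ratio" else np.array([0.0, 1.0])
        vals = evaluate_curve(curve, x, (0, 90))
        assert vals.min() == pytest.approx(1.0, abs=1e-9)
        cap = 500 if family in ("breakpoint", "binary_ratio") else 100
        assert vals.max() <= cap + 1e-9

    def test_monotonic_families_are_monotone_and_gaussian_unimodal(self):
        x = np.linspace(0, 1, 200)
        up = evaluate_curve(ResistanceCurve("monotonic_positive", r_max=10, r_exp=0.5), x)
        down = evaluate_curve(ResistanceCurve("monotonic_negative", r_max=10, r_exp=0.5), x)
        assert np.all(np.diff(up) >= 0)
        assert np.all(np.diff(down) <= 0)
        xs = np.linspace(0, 90, 901)
        g = evaluate_curve(ResistanceCurve("gaussian", r_max=10, x_opt=50, x_sd=20), xs)
        k = np.argmin(g)
        assert xs[k] == pytest.approx(50, abs=0.1)
        assert np.all(np.diff(g[: k + 1]) <= 1e-12) and np.all(np.diff(g[k:]) >= -1e-12)

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(family="nonsense"),
            dict(family="monotonic_positive", r_max=0.5, r_exp=1),
            dict(family="monotonic_positive", r_max=10, r_exp=0),
            dict(family="gaussian", r_max=10, x_opt=50, x_sd=0),
            dict(family="breakpoint", break_lo=60, break_hi=20, outside_value=10),
            dict(family="binary_ratio", ratio=0.5),
        ],
    )
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(ConfigurationError):
            ResistanceCurve(**kwargs)


class TestSurfaces:
    def test_null_curve_gives_all_ones(self):
        raster = RasterGrid(np.random.default_rng(0).uniform(0, 90, (8, 8)), 100.0)
        s = build_surface(raster, ResistanceCurve("null_ibd"))
        assert np.all(s.raster.values == 1.0)

    def test_binary_ratio_surface_has_two_levels(self):
        raster = RasterGrid(np.array([[0.0, 1.0], [1.0, 0.0]]), 100.0)
        s = build_surface(raster, ResistanceCurve("binary_ratio", ratio=5000))
        assert set(np.unique(s.raster.values)) == {1.0, 5000.0}

    def test_constant_raster_with_gaussian_gives_constant_surface(self):
        raster = RasterGrid(np.full((5, 5), 30.0), 100.0)
        s = build_surface(raster, ResistanceCurve("gaussian", r_max=100, x_opt=50, x_sd=20))
        assert np.ptp(s.raster.values) == 0.0

    def test_nodata_inside_extent_rejected(self):
        values = np.full((5, 5), 10.0)
        values[2, 2] = -9999.0
        raster = RasterGrid(values, 100.0)
        with pytest.raises(ConfigurationError):
            build_surface(raster, ResistanceCurve("null_ibd"))

    def test_combine_sums_cellwise_and_is_permutation_invariant(self, rng):
        rasters = [
            RasterGrid(rng.uniform(1, 5, (6, 6)), 100.0) for _ in range(3)
        ]
        surfaces = [
            build_surface(r, ResistanceCurve("monotonic_positive", r_max=9, r_exp=1))
            for r in rasters
        ]
        total = combine_surfaces(surfaces)
        expected = sum(s.raster.values for s in surfaces)
        np.testing.assert_allclose(total.raster.values, expected)
        shuffled = combine_surfaces([surfaces[2], surfaces[0], surfaces[1]])
        np.testing.assert_allclose(shuffled.raster.values, total.raster.values)

    def test_combined_minimum_at_least_number_of_addends(self):
        # barrier ratio + gaussian slope + positive water distance, each min 1
        rng = np.random.default_rng(3)
        slope = RasterGrid(rng.uniform(0, 90, (10, 10)), 100.0)
        barrier = RasterGrid((rng.random((10, 10)) < 0.1).astype(float), 100.0)
        water = RasterGrid(rng.uniform(0, 5000, (10, 10)), 100.0)
        combo = combine_surfaces(
            [
                build_surface(barrier, ResistanceCurve("binary_ratio", ratio=1000)),
                build_surface(slope, ResistanceCurve("gaussian", r_max=10, x_opt=50, x_sd=20)),
                build_surface(water, ResistanceCurve("monotonic_positive", r_max=50, r_exp=1)),
            ]
        )
        assert combo.raster.values.min() >= 3.0 - 1e-9

    def test_combine_rejects_mismatched_templates(self):
        a = build_surface(RasterGrid(np.ones((4, 4)), 100.0), ResistanceCurve("null_ibd"))
        b = build_surface(RasterGrid(np.ones((5, 4)), 100.0), ResistanceCurve("null_ibd"))
        with pytest.raises(AlignmentError):
            combine_surfaces([a, b])

    def test_offset_adds_constant_and_records_it(self):
        raster = RasterGrid(np.random.default_rng(1).uniform(0, 90, (6, 6)), 100.0)
        s = build_surface(raster, ResistanceCurve("gaussian", r_max=100, x_opt=50, x_sd=20))
        shifted = offset_surface(s, 2.0)
        np.testing.assert_allclose(shifted.raster.values, s.raster.values + 2.0)
        assert shifted.offset == 2.0
        same = offset_surface(s, 0.0)
        np.testing.assert_allclose(same.raster.values, s.raster.values)
        with pytest.raises(ConfigurationError):
            offset_surface(s, -1.0)


class TestEnumeration:
    def binary_ladder(self, ratios=(10, 100, 1000, 5000)):
        return CandidateLadder(
            variables={
                "roads": VariableSpec(
                    name="roads", kind="binary", families=("binary_ratio",), ratio=ratios
                )
            }
        )

    def test_binary_ratio_ladder_count(self):
        curves = enumerate_univariate_candidates("roads", self.binary_ladder())
        assert len(curves) == 4
        assert {c.ratio for c in curves} == {10, 100, 1000, 5000}

    def test_continuous_cross_product_count(self):
        ladder = CandidateLadder(
            variables={
                "ndvi": VariableSpec(
                    name="ndvi",
                    kind="continuous",
                    families=("monotonic_positive", "monotonic_negative"),
                    r_max=(10, 50, 100),
                    r_exp=(0.5, 1, 2),
                )
            }
        )
        assert len(enumerate_univariate_candidates("ndvi", ladder)) == 18

    def test_empty_ladder_rejected(self):
        with pytest.raises(ConfigurationError):
            enumerate_univariate_candidates("roads", self.binary_ladder(ratios=()))

    def test_multivariate_count_three_variables(self):
        """3 supported variables x 3 scale options each: 3*3^2 + 3^3 = 54."""
        ladder = CandidateLadder(
            variables={
                v: VariableSpec(
                    name=v,
                    kind="continuous",
                    families=("monotonic_positive",),
                    r_max=(10, 50, 100),
                    r_exp=(1,),
                )
                for v in ("a", "b", "c")
            }
        )
        best = {
            v: ResistanceCurve("monotonic_positive", r_max=50, r_exp=1) for v in ("a", "b", "c")
        }
        combos = enumerate_multivariate_candidates(best, ladder)
        assert len(combos) == 54

    def test_single_or_no_supported_variable_gives_empty_set(self):
        ladder = CandidateLadder(
            variables={
                "slope": VariableSpec(
                    name="slope",
                    kind="continuous",
                    families=("gaussian",),
                    r_max=(10, 100),
                    x_opt=(50,),
                    x_sd=(20,),
                )
            }
        )
        one = {"slope": ResistanceCurve("gaussian", r_max=100, x_opt=50, x_sd=20)}
        assert enumerate_multivariate_candidates(one, ladder) == []
        assert enumerate_multivariate_candidates({}, ladder) == []

    def test_rescale_preserves_shape_parameters(self):
        g = ResistanceCurve("gaussian", r_max=100, x_opt=50, x_sd=20)
        g10 = rescale_curve(g, 10)
        assert (g10.r_max, g10.x_opt, g10.x_sd) == (10, 50, 20)
        b = rescale_curve(ResistanceCurve("binary_ratio", ratio=1000), 5000)
        assert b.ratio == 5000
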