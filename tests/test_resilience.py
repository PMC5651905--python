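"""Attractors, tipping-point placement, resilience geometry and landscapes."""

import numpy as np
import pytest

from ira.core_io import PairedSeries
from ira.resilience import (
    Attractor,
    ResilienceEstimate,
    TippingPoint,
    assess_resilience,
    basin_borders,
    build_attractors,
    build_landscape,
    compute_resilience,
    place_tipping_points,
)
from ira.threshold_gam import fit_tgam


def _line_attractor(regime_id, span, intercept, slope=0.0, direction=1, x_dom=(-1.0, 1.0)):
    return Attractor(
        regime_id=regime_id,
        year_span=span,
        x_domain=x_dom,
        predict=lambda x, a=intercept, b=slope: a + b * np.asarray(x, float),
        shift_direction=direction,
    )


def _pairs_on_line(years, xs, intercept=0.0, slope=0.0, dy=0.0):
    xs = np.asarray(xs, float)
    return PairedSeries(np.asarray(years), xs, intercept + slope * xs + dy, lag=0)


class TestBuildAttractors:
    def test_single_threshold_gives_two_regimes(self, rng):
        years = np.arange(1985, 2014)
        x = rng.normal(0, 0.5, 29)
        y = np.where(years <= 1996, 1.0, -1.0) + 0.01 * rng.normal(size=29)
        pairs = PairedSeries(years, x, y)
        fit = fit_tgam(pairs)
        atts = build_attractors([fit], pairs)
        assert [a.year_span for a in atts] == [
            (1985, fit.threshold_year_), (fit.threshold_year_ + 1, 2013)
        ]
        assert atts[0].shift_direction in (-1, 1)
        assert atts[1].shift_direction == 0

    def test_on_domain_prediction_matches_branch(self, rng):
        years = np.arange(1985, 2014)
        x = rng.normal(0, 0.5, 29)
        y = np.where(years <= 1996, 1.0, -1.0) + 0.1 * x
        pairs = PairedSeries(years, x, y)
        fit = fit_tgam(pairs)
        atts = build_attractors([fit], pairs)
        grid = np.linspace(x.min(), x.max(), 7)
        np.testing.assert_allclose(atts[0].predict(grid), fit.lower_.predict(grid))

    def test_extrapolation_is_linear_beyond_domain(self, rng):
        years = np.arange(1985, 2014)
        x = np.linspace(-1, 1, 29)
        y = np.where(years <= 1999, 0.5 * x, 0.5 * x - 2.0)
        pairs = PairedSeries(years, x, y)
        fit = fit_tgam(pairs)
        att = build_attractors([fit], pairs)[0]
        hi = att.x_domain[1]
        f = att.predict(np.array([hi, hi + 0.5, hi + 1.0]))
        # equally spaced points beyond the domain fall on a straight line
        assert f[2] - f[1] == pytest.approx(f[1] - f[0], abs=1e-9)


class TestTippingPlacement:
    def test_exit_tip_one_quantum_below_anchor(self):
        # regime years on the attractor, next year's stressor at 0.40
        years = np.arange(2000, 2011)
        xs = np.array([0.0, 0.05, -0.05, 0.1, 0.0, -0.1, 0.05, 0.0, -0.05, 0.40, 0.45])
        pairs = _pairs_on_line(years, xs, intercept=1.0)
        atts = [
            _line_attractor(1, (2000, 2008), 1.0, direction=1),
            _line_attractor(2, (2009, 2010), -1.0),
        ]
        tips = place_tipping_points(atts, pairs, q=0.05)
        exit_tip = [t for t in tips if t.side == "exit"][0]
        assert exit_tip.x == pytest.approx(0.35)
        assert exit_tip.regime_id == 1

    def test_entry_tip_on_attractor_states(self):
        # states exactly on the attractor entered from below, min x = 0.10
        years = np.arange(2000, 2010)
        xs = np.concatenate([[0.0, 0.2], 0.1 + 0.05 * np.arange(8)])
        pairs = PairedSeries(
            years, xs, np.where(years <= 2001, 1.0, -1.0), lag=0
        )
        atts = [
            _line_attractor(1, (2000, 2001), 1.0, direction=1),
            _line_attractor(2, (2002, 2009), -1.0),
        ]
        tips = place_tipping_points(atts, pairs, q=0.05)
        entry = [t for t in tips if t.side == "entry"][0]
        assert entry.x == pytest.approx(0.10)

    def test_entry_tip_respects_vertical_deviation(self):
        # 5 states 0.12 below the attractor, min x = 0.50 -> tip at 0.35
        years = np.arange(2000, 2007)
        xs = np.array([0.0, 0.1, 0.50, 0.55, 0.6, 0.65, 0.7])
        y = np.where(years <= 2001, 1.0, -1.0 - 0.12)
        pairs = PairedSeries(years, xs, y, lag=0)
        atts = [
            _line_attractor(1, (2000, 2001), 1.0, direction=1),
            _line_attractor(2, (2002, 2006), -1.0),
        ]
        tips = place_tipping_points(atts, pairs, q=0.05)
        entry = [t for t in tips if t.side == "entry"][0]
        # brute-force oracle over the q-grid
        vabs = 0.12
        feasible = [
            m * 0.05 for m in range(-100, 100)
            if all(xx - vabs >= m * 0.05 for xx in xs[2:])
        ]
        assert entry.x == pytest.approx(max(feasible))
        assert entry.x == pytest.approx(0.35)

    def test_tip_x_is_quantum_multiple(self, rng):
        years = np.arange(2000, 2012)
        xs = np.concatenate([rng.normal(0, 0.07, 8), [0.43], rng.normal(0.45, 0.05, 3)])
        y = np.where(years <= 2008, 1.0, -1.0) + rng.normal(0, 0.05, 12)
        pairs = PairedSeries(years, xs, y, lag=0)
        atts = [
            _line_attractor(1, (2000, 2008), 1.0, direction=1),
            _line_attractor(2, (2009, 2011), -1.0),
        ]
        for q in (0.05, 0.1):
            for tp in place_tipping_points(atts, pairs, q=q):
                assert abs(tp.x / q - round(tp.x / q)) < 1e-9


class TestComputeResilience:
    def _setup(self):
        atts = [
            _line_attractor(1, (2000, 2004), 0.0, direction=1),
            _line_attractor(2, (2005, 2009), -2.0),
        ]
        tips = [
            TippingPoint("F1", 0.5, 0.0, 1, "exit", direction=1),
            TippingPoint("F2", -0.5, -2.0, 2, "entry", direction=-1),
        ]
        return atts, tips

    def test_state_at_tipping_point_zero(self):
        atts, tips = self._setup()
        pairs = _pairs_on_line([2000], [0.5])
        (e,) = compute_resilience(pairs, atts, tips)
        assert e.hcomp == pytest.approx(0.0)
        assert e.vcomp == pytest.approx(0.0)
        assert e.res == pytest.approx(0.0)

    def test_distance_arithmetic(self):
        atts, tips = self._setup()
        pairs = PairedSeries([2000, 2001], [0.2, 0.2], [0.0, -0.1], lag=0)
        e1, e2 = compute_resilience(pairs, atts, tips)
        assert e1.res == pytest.approx(0.3)   # on attractor, 0.3 from the tip
        assert e2.hcomp == pytest.approx(0.3)
        assert e2.vcomp == pytest.approx(-0.1)
        assert e2.res == pytest.approx(0.2)
        assert e2.rres == pytest.approx(0.2 / 0.3)

    def test_transitional_years_are_zero(self):
        atts, tips = self._setup()
        pairs = PairedSeries([2000, 2001], [0.0, 0.45], [0.0, -1.0], lag=0)
        ests = compute_resilience(pairs, atts, tips, transitional_years=[2001])
        assert ests[1].transitional
        assert ests[1].res == 0.0 and ests[1].rres == 0.0

    def test_res_decreases_towards_tipping_point(self):
        # states on the attractor moving towards the tip: Res strictly decreases
        atts, tips = self._setup()
        xs = np.linspace(-0.4, 0.5, 10)
        vals = [
            compute_resilience(_pairs_on_line([2000], [x]), atts, tips)[0].res
            for x in xs
        ]
        assert all(a > b for a, b in zip(vals, vals[1:]))

    def test_year_outside_all_regimes_rejected(self):
        atts, tips = self._setup()
        pairs = _pairs_on_line([2020], [0.0])
        with pytest.raises(ValueError, match="2020"):
            compute_resilience(pairs, atts, tips)


class TestAssessResilience:
    def _three_regime_case(self, rng):
        years = np.arange(1985, 2014)
        x = np.concatenate([
            rng.normal(0.0, 0.05, 10), [0.5], rng.normal(0.1, 0.05, 7),
            [0.8], rng.normal(0.25, 0.05, 10),
        ])
        level = np.concatenate([np.full(11, 2.0), np.full(8, 0.0), np.full(10, -2.0)])
        y = level + rng.normal(0, 0.05, 29)
        pairs = PairedSeries(years, x, y, lag=0)
        atts = [
            _line_attractor(1, (1985, 1995), 2.0, direction=1),
            _line_attractor(2, (1996, 2003), 0.0, direction=1),
            _line_attractor(3, (2004, 2013), -2.0),
        ]
        return pairs, atts

    def test_geometry_invariants(self, rng):
        pairs, atts = self._three_regime_case(rng)
        estimates, tips, trans = assess_resilience(pairs, atts, q=0.05)
        in_regime = [e for e in estimates if not e.transitional]
        assert all(e.hcomp >= 0 for e in in_regime)
        assert all(e.vcomp <= 0 for e in in_regime)
        assert all(e.res >= 0 for e in in_regime)
        assert max(e.rres for e in estimates) == pytest.approx(1.0)
        assert all(0.0 <= e.rres <= 1.0 for e in estimates)
        for tp in tips:
            assert abs(tp.x / 0.05 - round(tp.x / 0.05)) < 1e-9
        # middle regime has both tips, outer regimes one each
        sides = {(tp.regime_id, tp.side) for tp in tips}
        assert sides == {(1, "exit"), (2, "entry"), (2, "exit"), (3, "entry")}

    def test_explicit_transitional_years_respected(self, rng):
        pairs, atts = self._three_regime_case(rng)
        estimates, tips, trans = assess_resilience(
            pairs, atts, q=0.05, transitional_years=[1995, 2003]
        )
        assert trans == [1995, 2003]
        by_year = {e.year: e for e in estimates}
        assert by_year[1995].transitional and by_year[2003].transitional
        assert all(e.res >= 0 for e in estimates if not e.transitional)


class TestLandscape:
    def _estimates(self, nodes):
        return [
            ResilienceEstimate(2000 + i, 1, x, y, 0.0, 0.0, r, r)
            for i, (x, y, r) in enumerate(nodes)
        ]

    def test_nodes_are_reproduced(self):
        # grid_n=101 puts every node exactly on a grid point
        nodes = [(0, 0, 0.2), (1, 0, 0.8), (0, 1, 0.4), (1, 1, 1.0), (0.5, 0.5, 0.6)]
        ls = build_landscape(self._estimates(nodes), [], grid_n=101)
        for x, y, r in nodes:
            ix = np.argmin(np.abs(ls.grid_x - x))
            iy = np.argmin(np.abs(ls.grid_y - y))
            assert ls.rres_grid[iy, ix] == pytest.approx(r, abs=1e-9)

    def test_constant_field(self):
        nodes = [(0, 0, 0.5), (1, 0, 0.5), (0, 1, 0.5), (1, 1, 0.5)]
        ls = build_landscape(self._estimates(nodes), [])
        defined = np.isfinite(ls.rres_grid)
        np.testing.assert_allclose(ls.rres_grid[defined], 0.5, atol=1e-9)

    def test_unit_square_center_interpolation(self):
        nodes = [(0, 0, 0.0), (1, 0, 0.0), (0, 1, 1.0), (1, 1, 1.0)]
        ls = build_landscape(self._estimates(nodes), [], grid_n=101)
        assert ls.rres_grid[50, 50] == pytest.approx(0.5, abs=1e-9)

    def test_grid_shape_and_outside_hull_nan(self):
        nodes = [(0, 0, 0.1), (1, 0, 0.2), (0.5, 1, 0.3)]  # triangle
        ls = build_landscape(self._estimates(nodes), [], grid_n=100)
        assert ls.rres_grid.shape == (100, 100)
        assert np.isnan(ls.rres_grid[-1, 0])  # top-left corner outside triangle

    def test_collinear_nodes_rejected(self):
        nodes = [(0, 0, 0.1), (0.5, 0.5, 0.2), (1, 1, 0.3)]
        with pytest.raises(ValueError, match="collinear"):
            build_landscape(self._estimates(nodes), [])

    def test_tipping_points_enter_as_zero_nodes(self):
        nodes = [(0, 0, 0.5), (1, 0, 0.5), (0, 1, 0.5), (1, 1, 0.5)]
        tips = [TippingPoint("F1", 0.5, 0.5, 1, "exit")]
        ls = build_landscape(self._estimates(nodes), tips)
        assert ls.rres_grid[50, 50] == pytest.approx(0.0, abs=0.05)


class TestBasinBorders:
    def test_single_zero_node_is_encircled(self):
        nodes = [(x, y, 0.5) for x in (0, 0.5, 1) for y in (0, 0.5, 1) if (x, y) != (0.5, 0.5)]
        nodes.append((0.5, 0.5, 0.0))
        ls = build_landscape(
            [ResilienceEstimate(2000 + i, 1, x, y, 0, 0, r, r) for i, (x, y, r) in enumerate(nodes)],
            [],
            grid_n=101,
        )
        contours = basin_borders(ls)
        assert len(contours) >= 1
        c = max(contours, key=len)
        # closed loop around the centre
        assert np.allclose(c[0], c[-1], atol=1e-9)
        assert c[:, 0].min() < 0.5 < c[:, 0].max()
        assert c[:, 1].min() < 0.5 < c[:, 1].max()

    def test_all_zero_field_has_no_contour(self):
        nodes = [(0, 0, 0.0), (1, 0, 0.0), (0, 1, 0.0), (1, 1, 0.0)]
        ls = build_landscape(
            [ResilienceEstimate(2000 + i, 1, x, y, 0, 0, r, r) for i, (x, y, r) in enumerate(nodes)],
            [],
        )
        assert basin_borders(ls) == []

    def test_two_zero_wells_give_separate_contours(self):
        nodes = []
        for x in np.linspace(0, 1, 6):
            for y in np.linspace(0, 1, 6):
                nodes.append((x, y, 0.5))
        nodes.append((0.2, 0.5, 0.0))
        nodes.append((0.8, 0.5, 0.0))
        ls = build_landscape(
            [ResilienceEstimate(2000 + i, 1, x, y, 0, 0, r, r) for i, (x, y, r) in enumerate(nodes)],
            [],
            grid_n=101,
        )
        contours = basin_borders(ls)
        assert len(contours) >= 2
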