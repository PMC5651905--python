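"""Step 3 — quantitative resilience assessment and folded stability landscapes.

Each regime's fitted TGAM branch is its attractor.  A system state (year) has
a vertical resilience component ``vComp = -|y - attractor(x)|`` (distance to
its attractor, always <= 0) and a horizontal component ``hComp = |x_F - x|``
(distance to the regime's tipping point, always >= 0; regimes with both an
entry- and an exit-side tipping point use the minimum of the two distances).
Resilience is ``Res = hComp + vComp`` and ``rRes = Res / max Res``.  Tipping
points carry zero resilience and lie on the (possibly linearly extrapolated)
attractor at an exact multiple of the rounding quantum q.  Linear
interpolation of all (x, y, rRes) nodes onto a 100 x 100 grid yields the
folded stability landscape; the zero-level contours of that surface are the
basin borders.

Both axes must share a scale, so the stressor is mean-standardised before
this stage (indicator PC-scores are mean-centred by construction).
"""

from __future__ import annotations

import itertools
from collections.abc import Callable, Sequence
from dataclasses import dataclass

import numpy as np
from scipy.interpolate import LinearNDInterpolator
from scipy.spatial import QhullError
from skimage.measure import find_contours

from .core_io import PairedSeries
from .threshold_gam import ThresholdGAM

__all__ = [
    "Attractor",
    "TippingPoint",
    "ResilienceEstimate",
    "StabilityLandscape",
    "build_attractors",
    "place_tipping_points",
    "compute_resilience",
    "assess_resilience",
    "build_landscape",
    "basin_borders",
]


@dataclass(frozen=True)
class Attractor:
    """One regime's fitted response curve and bookkeeping.

    ``shift_direction`` is the sign of the stressor change at the regime's
    exit transition (+1 for a shift triggered by a rising stressor), or 0 for
    the final regime which has no exit.
    """

    regime_id: int
    year_span: tuple[int, int]
    x_domain: tuple[float, float]
    predict: Callable[[np.ndarray], np.ndarray]
    shift_direction: int = 0

    def contains_year(self, year: int) -> bool:
        return self.year_span[0] <= year <= self.year_span[1]


@dataclass(frozen=True)
class TippingPoint:
    """End of an attractor branch; x is an exact multiple of the quantum q.

    ``direction`` is +1 when the basin lies at stressor values below the
    tipping point and -1 when it lies above, so the signed in-basin distance
    of a state at x is ``direction * (x_tip - x)`` (negative once the state
    has moved past the tipping point).
    """

    label: str
    x: float
    y: float
    regime_id: int
    side: str  # "entry" | "exit"
    direction: int = 1

    def distance(self, x: float) -> float:
        return self.direction * (self.x - x)


@dataclass(frozen=True)
class ResilienceEstimate:
    year: int
    regime_id: int | None  # None marks a transitional year
    x: float
    y: float
    hcomp: float
    vcomp: float
    res: float
    rres: float

    @property
    def transitional(self) -> bool:
        return self.regime_id is None


@dataclass(frozen=True)
class StabilityLandscape:
    """rRes interpolated on a grid spanning the node bounding box.

    ``rres_grid[i, j]`` is the value at ``(grid_x[j], grid_y[i])``; cells
    outside the convex hull of the nodes are NaN (undefined, not zero).
    ``nodes`` is the (m, 3) array of interpolated (x, y, rRes) points.
    """

    grid_x: np.ndarray
    grid_y: np.ndarray
    rres_grid: np.ndarray
    nodes: np.ndarray


# ---------------------------------------------------------------------------
# Attractors
# ---------------------------------------------------------------------------

def build_attractors(
    fits: Sequence[ThresholdGAM],
    pairs: PairedSeries,
    n_direction_years: int = 3,
) -> list[Attractor]:
    """Turn a chain of TGAM fits into one attractor per regime.

    Each fit contributes two branch smoothers with known year spans (its
    training years split at its threshold).  Regimes are obtained by tiling
    the full analysis period with branch spans, later fits in the chain
    overriding earlier ones where both offer a branch starting at the same
    year (a sub-period refit supersedes the coarser full-period branch).
    Shift direction is the sign of the largest stressor excursion from the
    regime's median stressor within ``n_direction_years`` of the exit
    boundary — robust to spike-and-relax transitions, where the stressor
    crosses the tipping point transiently and then settles back.
    """
    if not fits:
        raise ValueError("need at least one fitted TGAM")
    first, last = int(pairs.years[0]), int(pairs.years[-1])
    by_start: dict[int, tuple[tuple[int, int], object]] = {}
    for f in fits:  # later fits override earlier ones at the same start year
        yrs = f.years_
        tau = f.threshold_year_
        by_start[int(yrs.min())] = ((int(yrs.min()), tau), f.lower_)
        by_start[tau + 1] = ((tau + 1, int(yrs.max())), f.upper_)
    spans: list[tuple[int, int]] = []
    branches = []
    pos = first
    while pos <= last:
        if pos not in by_start:
            raise ValueError(
                f"threshold chain does not tile the analysis period: no regime "
                f"branch starts at year {pos}"
            )
        span, branch = by_start[pos]
        spans.append(span)
        branches.append(branch)
        pos = span[1] + 1
    for (a0, a1), (b0, b1) in itertools.combinations(spans, 2):
        if a1 >= b0 and b1 >= a0:
            raise ValueError(f"overlapping regime year-spans {(a0, a1)} and {(b0, b1)}")

    attractors: list[Attractor] = []
    for rid, (span, branch) in enumerate(zip(spans, branches), start=1):
        if rid <= len(spans) - 1:  # every regime but the last has an exit
            tau = span[1]
            in_regime = (pairs.years >= span[0]) & (pairs.years <= tau)
            med = float(np.median(pairs.x[in_regime]))
            window = (pairs.years > tau - n_direction_years) & (
                pairs.years <= tau + n_direction_years
            )
            exc = pairs.x[window] - med
            direction = int(np.sign(exc[np.argmax(np.abs(exc))])) or 1
        else:
            direction = 0
        attractors.append(
            Attractor(
                regime_id=rid,
                year_span=span,
                x_domain=(float(branch.x_.min()), float(branch.x_.max())),
                predict=branch.predict,
                shift_direction=direction,
            )
        )
    return attractors


# ---------------------------------------------------------------------------
# Tipping points and resilience estimates
# ---------------------------------------------------------------------------

def _round_q(x: float, q: float) -> float:
    return float(np.floor(x / q + 0.5) * q)


def _regime_states(
    pairs: PairedSeries,
    attractor: Attractor,
    transitional_years: set[int],
) -> tuple[np.ndarray, np.ndarray]:
    mask = np.array(
        [attractor.contains_year(int(t)) and int(t) not in transitional_years
         for t in pairs.years]
    )
    return pairs.x[mask], pairs.y[mask]


def place_tipping_points(
    attractors: Sequence[Attractor],
    pairs: PairedSeries,
    q: float = 0.05,
    transitional_years: Sequence[int] | None = None,
    push: bool = True,
    max_steps: int = 100,
) -> list[TippingPoint]:
    """Place entry- and exit-side tipping points on each attractor.

    Exit side (all but the last regime): the initial x is the first
    transitional year's stressor value (or, absent transitional years, the
    first year of the next regime), rounded to the q-grid and backed off one
    quantum against the shift direction; if ``push`` is set it is then pushed
    outward in q-steps until every in-regime ``Res = hComp + vComp`` is
    non-negative.  Entry side (all but the first regime): the extremal
    q-multiple nearest the year cluster such that ``|x_y - x_F| >= |vComp_y|``
    for every regime year — i.e. the largest q-multiple at or below
    ``min(x_y - |vComp_y|)`` when the regime was entered from below, and the
    mirror image when entered from above.
    """
    if q <= 0:
        raise ValueError("rounding quantum q must be positive")
    transitional = set(int(t) for t in (transitional_years or ()))
    tips: list[TippingPoint] = []
    counter = itertools.count(1)
    for i, att in enumerate(attractors):
        xs, ys = _regime_states(pairs, att, transitional)
        if xs.size == 0:
            raise ValueError(f"regime {att.regime_id} has no non-transitional years")
        vabs = np.abs(ys - att.predict(xs))
        if i > 0:  # entry-side tipping point
            s_prev = attractors[i - 1].shift_direction or 1
            if s_prev > 0:  # entered from below: tip at the low-x edge
                bound = float(np.min(xs - vabs))
                x_f = float(np.floor(bound / q + 1e-9) * q)
            else:
                bound = float(np.max(xs + vabs))
                x_f = float(np.ceil(bound / q - 1e-9) * q)
            tips.append(
                TippingPoint(
                    label=f"F{next(counter)}",
                    x=x_f,
                    y=float(att.predict(np.array([x_f]))[0]),
                    regime_id=att.regime_id,
                    side="entry",
                    direction=-s_prev,
                )
            )
        if i < len(attractors) - 1:  # exit-side tipping point
            s = att.shift_direction or 1
            in_regime = [
                int(t) for t in pairs.years
                if att.contains_year(int(t)) and int(t) not in transitional
            ]
            eff_end = max(in_regime)
            after_years = [int(t) for t in pairs.years if int(t) > eff_end]
            if not after_years:
                raise ValueError(f"regime {att.regime_id} has no years after its exit")
            # the first year after the regime's last resident state: the first
            # transitional year if any, else the next regime's first year
            anchor_year = after_years[0]
            x_anchor = float(pairs.x[pairs.years == anchor_year][0])
            x_f = _round_q(x_anchor, q) - q * s
            steps = 0
            while np.any(s * (x_f - xs) < vabs - 1e-12):
                if not push:
                    break
                x_f += q * s
                steps += 1
                if steps > max_steps:
                    raise ValueError(
                        f"no feasible exit tipping point within {max_steps} steps of "
                        f"size q={q}; consider a larger q"
                    )
            tips.append(
                TippingPoint(
                    label=f"F{next(counter)}",
                    x=float(_round_q(x_f, q)),
                    y=float(att.predict(np.array([_round_q(x_f, q)]))[0]),
                    regime_id=att.regime_id,
                    side="exit",
                    direction=s,
                )
            )
    return tips


def compute_resilience(
    pairs: PairedSeries,
    attractors: Sequence[Attractor],
    tipping_points: Sequence[TippingPoint],
    transitional_years: Sequence[int] | None = None,
) -> list[ResilienceEstimate]:
    """Per-year resilience components, Res and rRes.

    Transitional years carry ``Res = rRes = 0``; every other year must fall in
    exactly one regime's year span.  ``rRes`` divides by the maximum Res over
    all years of the system.
    """
    transitional = set(int(t) for t in (transitional_years or ()))
    tips_by_regime: dict[int, list[TippingPoint]] = {}
    for tp in tipping_points:
        tips_by_regime.setdefault(tp.regime_id, []).append(tp)

    raw: list[ResilienceEstimate] = []
    for t, x, y in zip(pairs.years, pairs.x, pairs.y):
        t = int(t)
        if t in transitional:
            raw.append(ResilienceEstimate(t, None, float(x), float(y), 0.0, 0.0, 0.0, 0.0))
            continue
        matches = [a for a in attractors if a.contains_year(t)]
        if len(matches) != 1:
            raise ValueError(f"year {t} belongs to {len(matches)} regimes (expected 1)")
        att = matches[0]
        vcomp = -abs(float(y) - float(att.predict(np.array([x]))[0]))
        tips = tips_by_regime.get(att.regime_id, [])
        if not tips:
            raise ValueError(f"regime {att.regime_id} has no tipping point")
        # signed basin distance: negative once a state lies beyond a tipping
        # point, which marks it for transitional reclassification
        hcomp = min(tp.distance(float(x)) for tp in tips)
        res = hcomp + vcomp
        raw.append(ResilienceEstimate(t, att.regime_id, float(x), float(y),
                                      hcomp, vcomp, res, 0.0))
    max_res = max((e.res for e in raw), default=0.0)
    out = []
    for e in raw:
        rres = e.res / max_res if max_res > 0 and e.regime_id is not None else 0.0
        out.append(ResilienceEstimate(e.year, e.regime_id, e.x, e.y,
                                      e.hcomp, e.vcomp, e.res, rres))
    return out


def assess_resilience(
    pairs: PairedSeries,
    attractors: Sequence[Attractor],
    q: float = 0.05,
    transitional_years: Sequence[int] | None = None,
    max_iter: int = 10,
) -> tuple[list[ResilienceEstimate], list[TippingPoint], list[int]]:
    """Orchestrate tipping placement and resilience estimation.

    With an explicit transitional-year list, the exit tipping points are
    pushed outward until all in-regime Res are non-negative.  Without one,
    the default rule applies: years at the trailing edge of a regime whose
    Res would be negative under the current tipping placement are peeled off
    as transitional (the transition occupies the boundary years, so the exit
    anchor steps back to the stressor excursion that drove the shift);
    residual interior negativity is then absorbed by pushing the exit tipping
    points outward in q-steps.
    """
    if transitional_years is not None:
        trans_list = sorted(int(t) for t in transitional_years)
        tips = place_tipping_points(attractors, pairs, q, trans_list, push=True)
        estimates = compute_resilience(pairs, attractors, tips, trans_list)
        return estimates, tips, trans_list

    trans: set[int] = set()
    n_boundary_iter = len(pairs) * max_iter
    for _ in range(n_boundary_iter):
        tips = place_tipping_points(attractors, pairs, q, sorted(trans), push=False)
        estimates = compute_resilience(pairs, attractors, tips, sorted(trans))
        peeled = False
        for att in attractors[:-1]:
            in_regime = [
                e for e in estimates
                if e.regime_id == att.regime_id and not e.transitional
            ]
            if len(in_regime) <= 1:
                continue
            tail = max(in_regime, key=lambda e: e.year)
            if tail.res < 0:
                trans.add(tail.year)
                peeled = True
        if not peeled:
            break
    else:
        raise RuntimeError("transitional-year reclassification did not converge")
    tips = place_tipping_points(attractors, pairs, q, sorted(trans), push=True)
    estimates = compute_resilience(pairs, attractors, tips, sorted(trans))
    return estimates, tips, sorted(trans)


# ---------------------------------------------------------------------------
# Stability landscape
# ---------------------------------------------------------------------------

def build_landscape(
    estimates: Sequence[ResilienceEstimate],
    tipping_points: Sequence[TippingPoint],
    auxiliary_zeros: Sequence[tuple[float, float]] | None = None,
    grid_n: int = 100,
) -> StabilityLandscape:
    """Linearly interpolate all rRes nodes onto a ``grid_n x grid_n`` grid.

    Nodes are the yearly states (x, y, rRes), the tipping points (rRes 0) and
    any auxiliary zero points (e.g. a theoretical zero anchoring a basin
    border).  Interpolation is piecewise-linear on the Delaunay triangulation;
    grid cells outside the convex hull are NaN.
    """
    nodes = [(e.x, e.y, e.rres) for e in estimates]
    nodes += [(tp.x, tp.y, 0.0) for tp in tipping_points]
    nodes += [(float(x), float(y), 0.0) for x, y in (auxiliary_zeros or ())]
    node_arr = np.array(nodes, dtype=float)
    if len(node_arr) < 3:
        raise ValueError("need at least 3 nodes to interpolate a landscape")
    try:
        interp = LinearNDInterpolator(node_arr[:, :2], node_arr[:, 2])
    except QhullError as exc:
        raise ValueError("landscape nodes are collinear; cannot triangulate") from exc
    gx = np.linspace(node_arr[:, 0].min(), node_arr[:, 0].max(), grid_n)
    gy = np.linspace(node_arr[:, 1].min(), node_arr[:, 1].max(), grid_n)
    GX, GY = np.meshgrid(gx, gy)
    grid = interp(GX, GY)
    return StabilityLandscape(grid_x=gx, grid_y=gy, rres_grid=grid, nodes=node_arr)


def basin_borders(
    landscape: StabilityLandscape, level: float | None = None
) -> list[np.ndarray]:
    """Zero-level contour polylines of the landscape (basin borders).

    The rRes surface is non-negative, so its exact zero set (the valleys
    through the tipping points) has measure zero and cannot be crossed by a
    finite grid; borders are therefore extracted by marching squares at a
    small resolvable level, by default 2% of the maximum rRes.  Isolated
    zero nodes of an otherwise positive surface yield closed borders around
    them; an all-zero surface yields no interior contour (degenerate case).
    Each polyline is an ordered (m, 2) array of (x, y) points.
    """
    grid = landscape.rres_grid
    defined = np.isfinite(grid)
    if not defined.any():
        return []
    if level is None:
        level = 0.02 * float(np.nanmax(grid))
    contours = find_contours(np.where(defined, grid, np.nan), level)
    out = []
    dx = landscape.grid_x[1] - landscape.grid_x[0]
    dy = landscape.grid_y[1] - landscape.grid_y[0]
    for c in contours:
        xy = np.column_stack(
            [landscape.grid_x[0] + c[:, 1] * dx, landscape.grid_y[0] + c[:, 0] * dy]
        )
        out.append(xy)
    return out
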