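"""Self-contained validation experiments for the whole pipeline.

Each function generates its own inputs (bundled scenarios or simple noise
processes), runs the relevant pipeline stage from scratch, and measures a
summary quantity: oracle deviations for the PCA and the genuine
cross-validation loop, threshold/lag recovery rates on the fold-bifurcation
scenarios, false-positive behaviour of STARS and the effective-df corrected
correlation test, and the geometric invariants of the resilience assessment.
The independent oracles coded here (brute-force covariance eigendecomposition
and a naive refit-everything leave-one-out double loop) deliberately avoid
the implementation shortcuts of the main code paths.
"""

from __future__ import annotations

import numpy as np

from .core_io import PairedSeries, lag_align, log_transform
from ._spline import CubicSplineBasis
from .reduction import cross_correlation, run_pca, stars
from .resilience import (
    Attractor,
    assess_resilience,
    build_attractors,
    build_landscape,
    place_tipping_points,
)
from .synthetic import make_scenario
from .threshold_gam import build_threshold_chain, compare_models, genuine_cv

__all__ = [
    "pca_oracle_deviation",
    "gcv_oracle_deviation",
    "scenario_recovery",
    "stars_behaviour",
    "chelton_behaviour",
    "resilience_geometry",
    "west_hysteresis",
]


# ---------------------------------------------------------------------------
# Criterion experiments
# ---------------------------------------------------------------------------

def pca_oracle_deviation(n_matrices: int = 50, seed: int = 0) -> float:
    """Max |score difference| between run_pca and a brute-force
    eigendecomposition of the covariance matrix, over random small matrices
    (signs aligned per component)."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_matrices):
        n_rows = int(rng.integers(5, 9))
        n_cols = int(rng.integers(3, 6))
        X = rng.normal(0.0, 1.0, (n_rows, n_cols))
        from .core_io import SystemMatrix

        m = SystemMatrix(
            years=np.arange(2000, 2000 + n_rows),
            taxa=tuple(f"t{j}" for j in range(n_cols)),
            values=X,
            scale="log",
        )
        r = run_pca(m)
        # oracle: eigendecomposition of the sample covariance matrix
        Xc = X - X.mean(axis=0)
        evals, evecs = np.linalg.eigh(Xc.T @ Xc / (n_rows - 1))
        order = np.argsort(evals)[::-1]
        scores = Xc @ evecs[:, order]
        flips = np.sign(np.sum(scores * r.scores, axis=0))
        flips[flips == 0] = 1.0
        worst = max(worst, float(np.max(np.abs(scores * flips - r.scores))))
    return worst


def _naive_spline_fit(x, y, k, lam_grid, gamma):
    basis = CubicSplineBasis(x, k)
    B, S = basis.design(x), basis.penalty()
    fits = []
    for lam in lam_grid:
        A = B.T @ B + lam * S
        coef = np.linalg.solve(A, B.T @ y)
        rss = float(np.sum((y - B @ coef) ** 2))
        edf = float(np.trace(B @ np.linalg.solve(A, B.T)))
        crit = len(y) * rss / (len(y) - gamma * edf) ** 2
        fits.append((crit, lam, coef, basis, rss, edf))
    best = min(f[0] for f in fits)
    return next(f for f in fits if f[0] <= best * (1 + 1e-4))


def _naive_predict(fit, x0):
    _, _, coef, basis, _, _ = fit
    if x0 < basis.lo or x0 > basis.hi:
        bound = basis.lo if x0 < basis.lo else basis.hi
        f = (basis.design(np.array([bound])) @ coef).item()
        d = (basis.design_d1(np.array([bound])) @ coef).item()
        return f + d * (x0 - bound)
    return (basis.design(np.array([x0])) @ coef).item()


def gcv_oracle_deviation(seed: int = 42) -> dict[str, float]:
    """|gCV - oracle| for GAM and TGAM on a fixed 20-point stepped dataset.

    The oracle is an explicit refit-from-scratch leave-one-out double loop:
    naive per-lambda solves for every smoother and a naive threshold-year
    search inside every fold.
    """
    rng = np.random.default_rng(seed)
    years = np.arange(1991, 2011)
    x = np.round(rng.normal(0.0, 0.3, 20) + np.where(years >= 2001, 0.25, 0.0), 6)
    y = np.round(
        np.where(years <= 2000, 1.0, -1.0) - 0.8 * x + rng.normal(0, 0.25, 20), 6
    )
    pairs = PairedSeries(years, x, y)
    k, gamma, min_branch = 4, 1.4, 5
    lam_grid = np.logspace(-6, 6, 25)
    n = len(pairs)

    errs_gam, errs_tgam = [], []
    for i in range(n):
        keep = np.arange(n) != i
        fit = _naive_spline_fit(pairs.x[keep], pairs.y[keep], k, lam_grid, gamma)
        errs_gam.append((pairs.y[i] - _naive_predict(fit, pairs.x[i])) ** 2)

        yrs, xs, ys = pairs.years[keep], pairs.x[keep], pairs.y[keep]
        m = len(yrs)
        best = None
        for r, tau in enumerate(yrs, start=1):
            if not (0.1 * m + 1 <= r <= 0.9 * m):
                continue
            lo = yrs <= tau
            if lo.sum() < min_branch or (~lo).sum() < min_branch:
                continue
            try:
                f_lo = _naive_spline_fit(xs[lo], ys[lo], k, lam_grid, gamma)
                f_up = _naive_spline_fit(xs[~lo], ys[~lo], k, lam_grid, gamma)
            except np.linalg.LinAlgError:
                continue
            gcv_whole = m * (f_lo[4] + f_up[4]) / (m - f_lo[5] - f_up[5]) ** 2
            if best is None or gcv_whole < best[0]:
                best = (gcv_whole, tau, f_lo, f_up)
        _, tau, f_lo, f_up = best
        fold_fit = f_lo if pairs.years[i] <= tau else f_up
        errs_tgam.append((pairs.y[i] - _naive_predict(fold_fit, pairs.x[i])) ** 2)

    return {
        "gam": abs(genuine_cv(pairs, "GAM", k=k) - float(np.mean(errs_gam))),
        "tgam": abs(genuine_cv(pairs, "TGAM", k=k) - float(np.mean(errs_tgam))),
        "n": n,
    }


def _run_comparison(truth):
    pca = run_pca(log_transform(truth.system))
    indicator = pca.score_series(0)
    std = truth.stressor.mean_standardise()
    comparison = compare_models(indicator, std)
    opt = comparison.optimum
    response = {
        y: (-v if comparison.flipped else v) for y, v in indicator.items()
    }
    pairs = lag_align(std, response, opt.lag)
    return comparison, opt, pairs


def scenario_recovery(n_seeds: int = 50, base_seed: int = 0) -> dict[str, float]:
    """Threshold/lag recovery on east-like scenarios and model-class selection
    on the smooth-null control."""
    joint = model_ok = 0
    for s in range(n_seeds):
        truth = make_scenario("east_like", base_seed + s)
        _, opt, _ = _run_comparison(truth)
        is_tgam_lag = opt.model_class == "TGAM" and opt.lag == truth.lag
        model_ok += is_tgam_lag
        if is_tgam_lag and truth.thresholds:
            joint += abs(opt.fit.threshold_year_ - truth.thresholds[0]) <= 1
    gam = 0
    for s in range(n_seeds):
        truth = make_scenario("smooth_null", base_seed + s)
        _, opt, _ = _run_comparison(truth)
        gam += opt.model_class == "GAM"
    return {
        "joint_recovery_rate": joint / n_seeds,
        "model_lag_rate": model_ok / n_seeds,
        "smooth_null_gam_rate": gam / n_seeds,
        "n": n_seeds,
    }


def stars_behaviour(n_reps: int = 200, seed: int = 0) -> dict[str, float]:
    """Noiseless step detection plus red-noise false-positive ordering."""
    v = np.concatenate([np.zeros(15), np.full(14, 5.0)])
    noiseless = stars(v, L=10, p=0.05)
    rng = np.random.default_rng(seed)
    fp_raw = fp_corr = 0
    a = 0.5
    for _ in range(n_reps):
        e = np.zeros(29)
        e[0] = rng.normal()
        for t in range(1, 29):
            e[t] = a * e[t - 1] + rng.normal(0.0, np.sqrt(1 - a * a))
        fp_raw += bool(stars(e, L=10, p=0.05).shift_years)
        fp_corr += bool(stars(e, L=10, p=0.05, ar1_correct=True).shift_years)
    return {
        "noiseless_shift_year": float(noiseless.shift_years[0]),
        "fp_uncorrected": fp_raw / n_reps,
        "fp_corrected": fp_corr / n_reps,
        "n": n_reps,
    }


def chelton_behaviour(n_reps: int = 500, seed: int = 0) -> dict[str, float]:
    """J=0 equivalence with the classical Pearson test, and rejection-rate
    ordering under mutual AR(1) autocorrelation."""
    from scipy import stats as sps

    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(50):
        x = rng.normal(0, 1, 25)
        y = 0.4 * x + rng.normal(0, 1, 25)
        ours = cross_correlation(x, y, J=0)
        _, p_ref = sps.pearsonr(x, y)
        worst = max(worst, abs(ours.p_acf - p_ref))

    a = 0.8
    rej_raw = rej_corr = 0
    for _ in range(n_reps):
        def ar(n):
            e = np.zeros(n)
            e[0] = rng.normal()
            for t in range(1, n):
                e[t] = a * e[t - 1] + rng.normal(0.0, np.sqrt(1 - a * a))
            return e

        res = cross_correlation(ar(29), ar(29))
        rej_raw += res.p < 0.05
        rej_corr += res.p_acf < 0.05
    return {
        "classical_p_deviation": worst,
        "rejection_uncorrected": rej_raw / n_reps,
        "rejection_corrected": rej_corr / n_reps,
        "n": n_reps,
    }


def _analyse_scenario(truth, q: float = 0.05):
    comparison, opt, pairs = _run_comparison(truth)
    if opt.model_class != "TGAM":
        return None
    chain = build_threshold_chain(pairs, fit=opt.fit)
    attractors = build_attractors(chain, pairs)
    estimates, tips, trans = assess_resilience(pairs, attractors, q=q)
    return pairs, chain, attractors, estimates, tips, trans


def resilience_geometry(seed: int = 1, q: float = 0.05) -> dict[str, float]:
    """Geometric invariants of a full east-like resilience assessment, plus
    the hand-computable entry tipping-point fixture."""
    truth = make_scenario("east_like", seed)
    out = _analyse_scenario(truth, q=q)
    if out is None:
        raise RuntimeError("east-like scenario did not select a TGAM")
    pairs, chain, attractors, estimates, tips, trans = out
    in_regime = [e for e in estimates if not e.transitional]
    landscape = build_landscape(estimates, tips)
    node_ok = _landscape_reproduces_nodes(landscape)
    return {
        "min_hcomp": min(e.hcomp for e in in_regime),
        "max_vcomp": max(e.vcomp for e in in_regime),
        "min_res": min(e.res for e in in_regime),
        "max_rres": max(e.rres for e in estimates),
        "min_rres": min(e.rres for e in estimates),
        "tip_quantum_error": max(
            abs(tp.x / q - round(tp.x / q)) for tp in tips
        ),
        "n_tipping_points": float(len(tips)),
        "landscape_node_error": node_ok,
        "entry_tip_fixture": entry_tip_fixture(),
    }


def _landscape_reproduces_nodes(landscape) -> float:
    """Max |surface - node| over nodes coinciding with grid points."""
    worst = 0.0
    gx, gy = landscape.grid_x, landscape.grid_y
    for x, y, r in landscape.nodes:
        ix = int(np.argmin(np.abs(gx - x)))
        iy = int(np.argmin(np.abs(gy - y)))
        if abs(gx[ix] - x) < 1e-12 and abs(gy[iy] - y) < 1e-12:
            val = landscape.rres_grid[iy, ix]
            if np.isfinite(val):
                worst = max(worst, abs(val - r))
    return worst


def entry_tip_fixture() -> float:
    """Five states 0.12 below their attractor, min x = 0.50: the entry tipping
    point must land on the q-grid at 0.35 (brute-force verifiable)."""
    years = np.arange(2000, 2007)
    xs = np.array([0.0, 0.1, 0.50, 0.55, 0.6, 0.65, 0.7])
    y = np.where(years <= 2001, 1.0, -1.0 - 0.12)
    pairs = PairedSeries(years, xs, y)
    atts = [
        Attractor(1, (2000, 2001), (-1.0, 1.0), lambda x: np.ones_like(np.asarray(x, float)), 1),
        Attractor(2, (2002, 2006), (-1.0, 1.0), lambda x: -np.ones_like(np.asarray(x, float)), 0),
    ]
    tips = place_tipping_points(atts, pairs, q=0.05)
    return float([t for t in tips if t.side == "entry"][0].x)


def west_hysteresis(n_seeds: int = 25, base_seed: int = 0, q: float = 0.05) -> dict[str, float]:
    """Three-regime recovery on west-like scenarios: hysteresis (y-separation
    of overlapping-x year clusters) and the shallow middle basin."""
    hyst = shallow = three = 0
    for s in range(n_seeds):
        truth = make_scenario("west_like", base_seed + s)
        try:
            out = _analyse_scenario(truth, q=q)
        except (ValueError, RuntimeError):
            continue
        if out is None:
            continue
        pairs, chain, attractors, estimates, tips, trans = out
        if len(attractors) != 3:
            continue
        three += 1
        by_r: dict[int, list[tuple[float, float]]] = {}
        for e in estimates:
            if e.regime_id is not None:
                by_r.setdefault(e.regime_id, []).append((e.x, e.y))
        ok_h = False
        for r1, r2 in ((1, 2), (2, 3)):
            if r1 not in by_r or r2 not in by_r:
                continue
            x1, y1 = np.array(by_r[r1]).T
            x2, y2 = np.array(by_r[r2]).T
            lo, hi = max(x1.min(), x2.min()), min(x1.max(), x2.max())
            m1 = (x1 >= lo) & (x1 <= hi)
            m2 = (x2 >= lo) & (x2 <= hi)
            if m1.sum() < 2 or m2.sum() < 2:
                continue
            ya, yb = y1[m1], y2[m2]
            sep = abs(ya.mean() - yb.mean())
            wsd = np.sqrt((np.var(ya, ddof=1) + np.var(yb, ddof=1)) / 2)
            if wsd > 0 and sep > 3 * wsd:
                ok_h = True
        max_rres = {
            r: max(e.rres for e in estimates if e.regime_id == r) for r in by_r
        }
        ok_s = (
            len(max_rres) == 3
            and max_rres[2] < max_rres[1]
            and max_rres[2] < max_rres[3]
        )
        hyst += ok_h
        shallow += ok_s
    return {
        "hysteresis_rate": hyst / n_seeds,
        "shallow_middle_rate": shallow / n_seeds,
        "three_regime_rate": three / n_seeds,
        "n": n_seeds,
    }
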