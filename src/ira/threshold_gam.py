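"""Step 2 — continuous (GAM) vs discontinuous (threshold-GAM) response models.

A GAM here is a single penalized cubic regression spline of the indicator on
the (lagged) stressor.  A threshold GAM (TGAM) splits the series at a
threshold *year* tau (the last year of the older regime) and fits separate
smoothers to the two branches; tau is chosen by minimising the whole-model
GCV ``n * (rss_1 + rss_2) / (n - edf_1 - edf_2)^2`` over candidate years in a
rank-quantile window.  Model classes are compared by the genuine
cross-validatory squared prediction error (gCV): a leave-one-out loop in which
*everything* — the smoothing parameter of every smoother and, for the TGAM,
the threshold-year search itself — is re-estimated on each fold.
"""

from __future__ import annotations

import logging
import warnings
from collections.abc import Mapping, Sequence
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin

from ._spline import PenalizedSplineFit
from .core_io import PairedSeries, StressorSeries, lag_align
from .reduction import stars

logger = logging.getLogger(__name__)

__all__ = [
    "SplineGAM",
    "ThresholdGAM",
    "ModelComparison",
    "ComparisonRow",
    "fit_gam",
    "fit_tgam",
    "genuine_cv",
    "build_threshold_chain",
    "compare_models",
    "detect_second_threshold",
    "threshold_parsimony_test",
]

DEFAULT_LAM_GRID = np.logspace(-6, 6, 25)


class SplineGAM(RegressorMixin, BaseEstimator):
    """Penalized cubic regression spline with GCV-selected smoothing.

    Parameters
    ----------
    k : basis dimension (default 4 — the small-sample setting of ~30 annual
        observations).
    lam : fixed smoothing penalty; ``None`` selects lam by minimising the
        internal GCV ``n * rss / (n - edf)^2`` over ``lam_grid`` (25 log-spaced
        values in 1e-6..1e6 by default; ties break to the smallest lam).

    Fitted attributes: ``coef_``, ``lam_``, ``edf_`` (trace of the smoother
    matrix), ``fitted_``, ``rss_``, ``gcv_`` and ``deviance_explained_``.
    Prediction outside the training x-range uses linear extrapolation with the
    boundary slope of the spline.
    """

    def __init__(self, k: int = 4, lam: float | None = None, lam_grid=None,
                 gamma: float = 1.4):
        self.k = k
        self.lam = lam
        self.lam_grid = lam_grid
        self.gamma = gamma

    @staticmethod
    def _as_x(X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim == 2:
            X = X[:, 0]
        return X

    def fit(self, X, y):
        x = self._as_x(X)
        y = np.asarray(y, dtype=float)
        if len(x) != len(y):
            raise ValueError("X and y must have equal length")
        if len(x) < self.k + 1:
            raise ValueError(f"need at least k + 1 = {self.k + 1} points, got {len(x)}")
        if np.unique(x).size < 2:
            raise ValueError("degenerate covariate: all x values equal")
        grid = None if self.lam_grid is None else np.asarray(self.lam_grid, dtype=float)
        fit = PenalizedSplineFit(x, y, k=self.k, lam=self.lam, lam_grid=grid,
                                 gamma=self.gamma)
        self._fit = fit
        self.x_ = fit.x
        self.y_ = fit.y
        self.coef_ = fit.coef
        self.lam_ = fit.lam
        self.edf_ = fit.edf
        self.fitted_ = fit.fitted
        self.rss_ = fit.rss
        self.gcv_ = fit.gcv
        self.deviance_explained_ = fit.deviance_explained
        return self

    def predict(self, X):
        return self._fit.predict(self._as_x(X))


class ThresholdGAM(RegressorMixin, BaseEstimator):
    """Time-threshold GAM: separate spline smoothers before and after tau.

    ``fit`` takes X with two columns ``(stressor, year)``; the threshold is on
    the year.  Candidate threshold years are those whose (1-based) rank r in
    the series satisfies ``q_lo * n + 1 <= r <= q_hi * n`` and leaves at least
    ``min_branch`` observations in each branch; tau minimises the whole-model
    GCV, ties resolving to the earliest year.

    Fitted attributes: ``threshold_year_``, ``lower_`` / ``upper_`` branch
    :class:`SplineGAM` fits, ``gcv_whole_``, ``candidate_grid_`` (list of
    (year, whole-model GCV)), ``rss_``, ``edf_total_``,
    ``deviance_explained_``.
    """

    def __init__(
        self,
        k: int = 4,
        window: tuple[float, float] = (0.1, 0.9),
        min_branch: int = 5,
        lam_grid=None,
        gamma: float = 1.4,
        memo: dict | None = None,
    ):
        self.k = k
        self.window = window
        self.min_branch = min_branch
        self.lam_grid = lam_grid
        self.gamma = gamma
        self.memo = memo

    def _branch_fit(self, x: np.ndarray, y: np.ndarray) -> SplineGAM:
        if self.memo is None:
            return SplineGAM(self.k, lam_grid=self.lam_grid, gamma=self.gamma).fit(x, y)
        key = (x.tobytes(), y.tobytes())
        hit = self.memo.get(key)
        if hit is None:
            hit = SplineGAM(self.k, lam_grid=self.lam_grid, gamma=self.gamma).fit(x, y)
            self.memo[key] = hit
        return hit

    def _candidates(self, years: np.ndarray) -> np.ndarray:
        n = len(years)
        q_lo, q_hi = self.window
        ranks = np.arange(1, n + 1)
        in_window = (ranks >= q_lo * n + 1) & (ranks <= q_hi * n)
        feasible = (ranks >= self.min_branch) & (n - ranks >= self.min_branch)
        return years[in_window & feasible]

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != 2:
            raise ValueError("ThresholdGAM expects X with columns (stressor, year)")
        y = np.asarray(y, dtype=float)
        order = np.argsort(X[:, 1], kind="stable")
        x, years, y = X[order, 0], X[order, 1].astype(int), y[order]
        n = len(y)
        candidates = self._candidates(years)
        best = None
        grid: list[tuple[int, float]] = []
        for tau in candidates:
            mask = years <= tau
            try:
                lower = self._branch_fit(x[mask], y[mask])
                upper = self._branch_fit(x[~mask], y[~mask])
            except (ValueError, np.linalg.LinAlgError):
                continue  # infeasible branch (too few or degenerate x)
            rss = lower.rss_ + upper.rss_
            edf = lower.edf_ + upper.edf_
            gcv_whole = n * rss / (n - edf) ** 2
            grid.append((int(tau), float(gcv_whole)))
            if best is None or gcv_whole < best[1]:
                best = (int(tau), float(gcv_whole), lower, upper, rss, edf)
        if best is None:
            raise ValueError("no feasible threshold-year candidate")
        tau, gcv_whole, lower, upper, rss, edf = best
        self.years_ = years
        self.x_ = x
        self.y_ = y
        self.threshold_year_ = tau
        self.lower_ = lower
        self.upper_ = upper
        self.gcv_whole_ = gcv_whole
        self.candidate_grid_ = grid
        self.rss_ = float(rss)
        self.edf_total_ = float(edf)
        tss = float(np.sum((y - y.mean()) ** 2))
        self.deviance_explained_ = 1.0 - self.rss_ / tss if tss > 0 else 1.0
        return self

    def refit_at(self, tau: int) -> "ThresholdGAM":
        """Refit with the threshold fixed at a given year (for parsimony tests)."""
        mask = self.years_ <= tau
        if mask.sum() < self.min_branch or (~mask).sum() < self.min_branch:
            raise ValueError(f"threshold year {tau} leaves an infeasible branch")
        clone = ThresholdGAM(self.k, self.window, self.min_branch, self.lam_grid,
                             self.gamma)
        clone.years_, clone.x_, clone.y_ = self.years_, self.x_, self.y_
        lower = SplineGAM(self.k, lam_grid=self.lam_grid,
                          gamma=self.gamma).fit(self.x_[mask], self.y_[mask])
        upper = SplineGAM(self.k, lam_grid=self.lam_grid,
                          gamma=self.gamma).fit(self.x_[~mask], self.y_[~mask])
        n = len(self.y_)
        clone.threshold_year_ = int(tau)
        clone.lower_, clone.upper_ = lower, upper
        clone.rss_ = lower.rss_ + upper.rss_
        clone.edf_total_ = lower.edf_ + upper.edf_
        clone.gcv_whole_ = n * clone.rss_ / (n - clone.edf_total_) ** 2
        clone.candidate_grid_ = [(int(tau), float(clone.gcv_whole_))]
        tss = float(np.sum((self.y_ - self.y_.mean()) ** 2))
        clone.deviance_explained_ = 1.0 - clone.rss_ / tss if tss > 0 else 1.0
        return clone

    def predict(self, X):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != 2:
            raise ValueError("ThresholdGAM expects X with columns (stressor, year)")
        out = np.empty(len(X))
        mask = X[:, 1] <= self.threshold_year_
        if mask.any():
            out[mask] = self.lower_.predict(X[mask, 0])
        if (~mask).any():
            out[~mask] = self.upper_.predict(X[~mask, 0])
        return out


# ---------------------------------------------------------------------------
# Module-level operation wrappers
# ---------------------------------------------------------------------------

def fit_gam(pairs: PairedSeries, k: int = 4, lam_grid=None) -> SplineGAM:
    """Fit the continuous model to lag-aligned pairs."""
    if len(pairs) < k + 2:
        raise ValueError(f"need at least k + 2 = {k + 2} points, got {len(pairs)}")
    return SplineGAM(k=k, lam_grid=lam_grid).fit(pairs.x, pairs.y)


def fit_tgam(
    pairs: PairedSeries,
    k: int = 4,
    window: tuple[float, float] = (0.1, 0.9),
    min_branch: int = 5,
    lam_grid=None,
) -> ThresholdGAM:
    """Fit the discontinuous model, selecting the threshold year by GCV."""
    X = np.column_stack([pairs.x, pairs.years])
    return ThresholdGAM(k=k, window=window, min_branch=min_branch, lam_grid=lam_grid).fit(
        X, pairs.y
    )


def genuine_cv(
    pairs: PairedSeries,
    model_class: str,
    k: int = 4,
    window: tuple[float, float] = (0.1, 0.9),
    min_branch: int = 5,
    lam_grid=None,
) -> float:
    """Genuine leave-one-out squared prediction error.

    Every fold re-runs the complete estimation — smoothing-parameter selection
    for each smoother and, for the TGAM, the threshold-year search — on the
    remaining n-1 points; the held-out year is predicted by the branch its
    year falls into under the fold's own threshold.
    """
    if model_class not in ("GAM", "TGAM"):
        raise ValueError("model_class must be 'GAM' or 'TGAM'")
    memo: dict = {}  # identical branch fits recur across folds
    n = len(pairs)
    sq_errs = np.empty(n)
    idx = np.arange(n)
    for i in range(n):
        keep = idx != i
        if model_class == "GAM":
            m = SplineGAM(k=k, lam_grid=lam_grid).fit(pairs.x[keep], pairs.y[keep])
            pred = float(m.predict(np.array([pairs.x[i]]))[0])
        else:
            X = np.column_stack([pairs.x[keep], pairs.years[keep]])
            m = ThresholdGAM(k=k, window=window, min_branch=min_branch,
                             lam_grid=lam_grid, memo=memo).fit(X, pairs.y[keep])
            pred = float(m.predict(np.array([[pairs.x[i], pairs.years[i]]]))[0])
        sq_errs[i] = (pairs.y[i] - pred) ** 2
    return float(sq_errs.mean())


@dataclass(frozen=True)
class ComparisonRow:
    model_class: str
    lag: int
    gcv: float
    deviance_explained: float
    fit: object = field(repr=False, compare=False)


@dataclass(frozen=True)
class ModelComparison:
    """All evaluated (model class, lag) fits; the optimum has minimal gCV."""

    rows: tuple[ComparisonRow, ...]
    flipped: bool

    @property
    def optimum(self) -> ComparisonRow:
        return min(self.rows, key=lambda r: (r.gcv, r.lag, r.model_class))


def _apply_flip(values: np.ndarray, flip) -> tuple[np.ndarray, bool]:
    """Resolve the response orientation.

    ``flip='auto'`` negates the indicator iff the mean of the first ceil(n/3)
    values is below the mean of the last ceil(n/3) (so chronologically older
    states sit higher on the y-axis, the customary fold orientation).
    """
    if flip == "auto":
        third = int(np.ceil(len(values) / 3))
        do_flip = bool(values[:third].mean() < values[-third:].mean())
    else:
        do_flip = bool(flip)
    return (-values if do_flip else values), do_flip


def compare_models(
    indicator: Mapping[int, float],
    stressor: StressorSeries,
    lags: Sequence[int] = (0, 1, 2),
    flip="auto",
    k: int = 4,
    window: tuple[float, float] = (0.1, 0.9),
    min_branch: int = 5,
    lam_grid=None,
) -> ModelComparison:
    """Evaluate GAM and TGAM gCV at each stressor lag and locate the optimum."""
    years = np.array(sorted(indicator), dtype=int)
    raw = np.array([float(indicator[int(t)]) for t in years])
    response, flipped = _apply_flip(raw, flip)
    resp_map = dict(zip((int(t) for t in years), response))
    rows: list[ComparisonRow] = []
    for lag in lags:
        pairs = lag_align(stressor, resp_map, lag)
        for model_class in ("GAM", "TGAM"):
            gcv = genuine_cv(pairs, model_class, k=k, window=window,
                             min_branch=min_branch, lam_grid=lam_grid)
            if model_class == "GAM":
                fit = fit_gam(pairs, k=k, lam_grid=lam_grid)
            else:
                fit = fit_tgam(pairs, k=k, window=window, min_branch=min_branch,
                               lam_grid=lam_grid)
            rows.append(ComparisonRow(model_class, int(lag), gcv,
                                      float(fit.deviance_explained_), fit))
    return ModelComparison(rows=tuple(rows), flipped=flipped)


def detect_second_threshold(
    fit: ThresholdGAM,
    pairs: PairedSeries,
    branch: str = "upper",
    k: int = 4,
    window: tuple[float, float] = (0.1, 0.9),
    min_branch: int = 5,
    stars_L: int | None = None,
    stars_p: float = 0.05,
    lam_grid=None,
) -> ThresholdGAM | None:
    """Diagnose and fit an additional threshold within one branch.

    A single TGAM can only represent one threshold.  STARS is run on the
    chosen branch's residuals against year; if a significant step exists, the
    GAM/TGAM comparison is re-run on the branch's years alone and the
    sub-period TGAM is returned iff its gCV beats the sub-period GAM.
    Returns ``None`` (with a logged warning if the branch is too short)
    otherwise.
    """
    if branch not in ("upper", "lower"):
        raise ValueError("branch must be 'upper' or 'lower'")
    tau = fit.threshold_year_
    mask = pairs.years <= tau if branch == "lower" else pairs.years > tau
    sub = PairedSeries(pairs.years[mask], pairs.x[mask], pairs.y[mask], pairs.lag)
    if len(sub) < 2 * min_branch:
        logger.warning(
            "branch %s (%d years) too short for a nested threshold search", branch, len(sub)
        )
        return None
    model = fit.lower_ if branch == "lower" else fit.upper_
    residuals = sub.y - model.predict(sub.x)
    # STARS here is only a cheap screen for two distinct year-clusters within
    # the branch; it is run on the smoother residuals and on the raw branch
    # level (a steep smoother can absorb a step into the x-effect, leaving no
    # residual signature).  Short cut-off L keeps late steps confirmable; the
    # gCV comparison below is the actual arbiter.
    L = stars_L if stars_L is not None else 3
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        yrs = [int(t) for t in sub.years]
        steps = stars(dict(zip(yrs, residuals)), L=L, p=stars_p)
        level_steps = stars(dict(zip(yrs, sub.y)), L=L, p=stars_p)
    if not steps.shift_years and not level_steps.shift_years:
        return None
    gcv_gam = genuine_cv(sub, "GAM", k=k, window=window, min_branch=min_branch,
                         lam_grid=lam_grid)
    try:
        gcv_tgam = genuine_cv(sub, "TGAM", k=k, window=window, min_branch=min_branch,
                              lam_grid=lam_grid)
    except ValueError:
        return None
    if gcv_tgam >= gcv_gam:
        return None
    return fit_tgam(sub, k=k, window=window, min_branch=min_branch, lam_grid=lam_grid)


def build_threshold_chain(
    pairs: PairedSeries,
    fit: ThresholdGAM | None = None,
    k: int = 4,
    window: tuple[float, float] = (0.1, 0.9),
    min_branch: int = 5,
    stars_p: float = 0.05,
    lam_grid=None,
) -> list[ThresholdGAM]:
    """Resolve the full threshold chain (up to two thresholds / three regimes).

    Starting from the full-period TGAM, both branches are screened for an
    additional step (:func:`detect_second_threshold`).  A sub-threshold on the
    *upper* branch simply appends a sub-period fit.  A sub-threshold on the
    *lower* branch means the full-period threshold fell inside a middle
    regime; the years after the earlier threshold are then re-modelled, and
    the re-fitted TGAM replaces the original partition when its gCV beats the
    sub-period GAM.
    """
    kw = dict(k=k, window=window, min_branch=min_branch, lam_grid=lam_grid)
    if fit is None:
        fit = fit_tgam(pairs, **kw)
    sub_lower = detect_second_threshold(fit, pairs, branch="lower",
                                        stars_p=stars_p, **kw)
    if sub_lower is not None:
        tau0 = sub_lower.threshold_year_
        after = PairedSeries(
            pairs.years[pairs.years > tau0], pairs.x[pairs.years > tau0],
            pairs.y[pairs.years > tau0], pairs.lag,
        )
        try:
            gcv_gam = genuine_cv(after, "GAM", **kw)
            gcv_tgam = genuine_cv(after, "TGAM", **kw)
        except ValueError:
            return [fit]
        if gcv_tgam < gcv_gam:
            return [sub_lower, fit_tgam(after, **kw)]
        return [fit]
    sub_upper = detect_second_threshold(fit, pairs, branch="upper",
                                        stars_p=stars_p, **kw)
    if sub_upper is not None:
        return [fit, sub_upper]
    return [fit]


def threshold_parsimony_test(
    fit_a: ThresholdGAM, fit_b: ThresholdGAM, alpha: float = 0.05
) -> tuple[float, ThresholdGAM]:
    """Chi-square parsimony rule between two near-tied threshold fits.

    The residual-deviance difference (Gaussian family, so deviance = RSS) is
    referred to a chi-square with ``df = max(|delta total edf|, 1)``.  A
    non-significant difference (p > alpha) selects the fit with the smaller
    total edf (tie -> earlier threshold year); otherwise the lower-deviance
    fit wins.
    """
    d_dev = abs(fit_a.rss_ - fit_b.rss_)
    d_edf = abs(fit_a.edf_total_ - fit_b.edf_total_)
    if d_dev == 0 and d_edf == 0:
        chosen = fit_a if fit_a.threshold_year_ <= fit_b.threshold_year_ else fit_b
        return 1.0, chosen
    df = max(d_edf, 1.0)
    p = float(stats.chi2.sf(d_dev, df))
    if p > alpha:
        key = lambda f: (f.edf_total_, f.threshold_year_)  # noqa: E731
        chosen = fit_a if key(fit_a) <= key(fit_b) else fit_b
    else:
        chosen = fit_a if fit_a.rss_ <= fit_b.rss_ else fit_b
    return p, chosen
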