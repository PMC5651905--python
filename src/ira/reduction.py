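"""Step 1 — complexity reduction and exploratory change-point diagnostics.

A covariance-matrix PCA of the log-scale system matrix yields holistic
indicator variables (principal-component scores).  Supporting diagnostics:
traffic-light quintile summaries per taxon, STARS sequential t-test step
detection with an optional red-noise (AR(1)) correction of the degrees of
freedom, and Pearson cross-correlation between indicator and stressor with an
effective-sample-size penalty for autocorrelation.
"""

from __future__ import annotations

import warnings
from collections.abc import Mapping, Sequence
from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.decomposition import PCA
from statsmodels.tsa.stattools import acf as _acf

from .core_io import SystemMatrix

__all__ = [
    "PCAResult",
    "TrafficLight",
    "RegimeShiftResult",
    "CrossCorrResult",
    "CovariancePCA",
    "run_pca",
    "traffic_light",
    "stars",
    "cross_correlation",
]


# ---------------------------------------------------------------------------
# PCA on the covariance matrix
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PCAResult:
    """Loadings (taxa x components, unit-norm columns), year scores and
    explained-variance fractions of a covariance-matrix PCA."""

    taxa: tuple[str, ...]
    years: np.ndarray
    loadings: np.ndarray
    scores: np.ndarray
    explained_fraction: np.ndarray

    def score_series(self, component: int = 0) -> dict[int, float]:
        """Year -> score mapping for one component (0-based)."""
        return {int(y): float(s) for y, s in zip(self.years, self.scores[:, component])}


class CovariancePCA(TransformerMixin, BaseEstimator):
    """PCA on the covariance matrix (centred, not variance-scaled).

    Thin scikit-learn transformer around :class:`sklearn.decomposition.PCA`
    with a deterministic sign convention: each component is oriented so that
    its largest-magnitude loading is positive.

    Attributes (after fit)
    ----------------------
    loadings_ : (n_features, n_components) orthonormal columns.
    explained_fraction_ : fraction of total variance per component.
    scores_ : (n_samples, n_components) training scores (column-centred).
    """

    def __init__(self, n_components: int | None = None):
        self.n_components = n_components

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[0] < 2 or X.shape[1] < 2:
            raise ValueError("CovariancePCA needs a 2-D matrix with >= 2 rows and columns")
        if np.allclose(X, X[0], atol=1e-300, rtol=0.0) or np.allclose(
            X - X.mean(axis=0), 0.0
        ):
            raise ValueError("matrix has zero total variance (all rows identical)")
        self._pca = PCA(n_components=self.n_components, svd_solver="full")
        scores = self._pca.fit_transform(X)
        loadings = self._pca.components_.T.copy()
        # sign convention: largest-|loading| entry of each component positive
        flip = np.sign(loadings[np.argmax(np.abs(loadings), axis=0), np.arange(loadings.shape[1])])
        flip[flip == 0] = 1.0
        self.loadings_ = loadings * flip
        self.scores_ = scores * flip
        self.explained_fraction_ = self._pca.explained_variance_ratio_.copy()
        self.mean_ = self._pca.mean_.copy()
        return self

    def transform(self, X):
        X = np.asarray(X, dtype=float)
        return (X - self.mean_) @ self.loadings_

    def fit_transform(self, X, y=None):
        self.fit(X)
        return self.scores_


def run_pca(m: SystemMatrix) -> PCAResult:
    """Covariance-matrix PCA of a log-scale system matrix.

    Components are ordered by decreasing eigenvalue; scores are the centred
    data projected on the loadings, so ``scores = (X - mean) @ loadings``.
    """
    if m.scale != "log":
        raise ValueError("run_pca expects a log-scale matrix (apply log_transform first)")
    est = CovariancePCA().fit(m.values)
    return PCAResult(
        taxa=m.taxa,
        years=m.years.copy(),
        loadings=est.loadings_,
        scores=est.scores_,
        explained_fraction=est.explained_fraction_,
    )


# ---------------------------------------------------------------------------
# Traffic-light quintile summary
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TrafficLight:
    """Per-taxon quintile categories (1..5) over years, taxa ordered by
    descending first-component loading."""

    order: tuple[str, ...]
    years: np.ndarray
    categories: np.ndarray  # (n_years, n_taxa) ints, columns follow `order`


def traffic_light(m: SystemMatrix, pca: PCAResult) -> TrafficLight:
    """Quintile-categorise each logged taxon series, sorted by PC1 loading.

    Categories use average ranks with fixed boundaries at ranks n/5, 2n/5, ...
    (category = ceil(5 * rank / n)), which is deterministic under ties; a
    constant series lands entirely in the middle category.
    """
    if m.taxa != pca.taxa:
        raise ValueError("system matrix and PCA result have inconsistent taxa")
    order_idx = np.argsort(-pca.loadings[:, 0], kind="stable")
    n = m.n_years
    cats = np.empty((n, m.n_taxa), dtype=int)
    for j_out, j in enumerate(order_idx):
        ranks = stats.rankdata(m.values[:, j], method="average")
        cats[:, j_out] = np.ceil(5.0 * ranks / n).astype(int)
    return TrafficLight(
        order=tuple(m.taxa[j] for j in order_idx),
        years=m.years.copy(),
        categories=cats,
    )


# ---------------------------------------------------------------------------
# STARS sequential t-test with red-noise correction
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RegimeShiftResult:
    """Confirmed step changes in a series mean.

    ``shift_years`` are the first years of each new regime; ``rsi`` maps each
    shift year to its (positive) regime shift index.
    """

    shift_years: tuple[int, ...]
    rsi: dict[int, float]
    cutoff: int
    p: float
    huber: float
    alpha: float


def _ar1_ols(v: np.ndarray) -> float:
    """Lag-1 OLS autoregression coefficient of a (demeaned) series."""
    v = v - v.mean()
    denom = float(v[:-1] @ v[:-1])
    if denom <= 0:
        return 0.0
    return float(v[1:] @ v[:-1]) / denom


def _ar1_mpk(v: np.ndarray, L: int) -> float:
    """Subsampled AR(1) estimate with a first-order (MPK-style) bias correction.

    OLS estimates on all consecutive windows of length ``m = min(L, n // 3)``
    are averaged, then corrected by ``alpha + (1 + 3 alpha) / m``.
    """
    n = len(v)
    m = max(4, min(L, n // 3))
    ests = [_ar1_ols(v[i : i + m]) for i in range(0, n - m + 1)]
    a = float(np.mean(ests))
    return a + (1.0 + 3.0 * a) / m


def estimate_ar1(v: np.ndarray, L: int = 10, method: str = "ols") -> float:
    """AR(1) coefficient for the red-noise correction, clamped to (-0.99, 0.99)."""
    v = np.asarray(v, dtype=float)
    if method == "ols":
        a = _ar1_ols(v)
    elif method == "mpk":
        a = _ar1_mpk(v, L)
    else:
        raise ValueError(f"unknown AR(1) estimator {method!r}")
    return float(np.clip(a, -0.99, 0.99))


def stars(
    v: Mapping[int, float] | Sequence[float],
    L: int = 10,
    p: float = 0.05,
    h: float = 1.0,
    ar1_correct: bool = False,
    ar1_method: str = "ols",
) -> RegimeShiftResult:
    """Sequential t-test analysis of regime shifts (STARS).

    A candidate shift opens when a value departs from the current regime's
    baseline mean by more than
    ``diff = t_crit(p, 2*L_eff - 2) * sqrt(2 * sigma2_L / L_eff)``
    where ``sigma2_L`` is the average variance of consecutive L-year windows.
    The regime shift index accumulates Huber-weighted anomalies (weight
    ``min(1, h/|z|)``) measured from the critical level over the next L years;
    the shift is confirmed iff the running RSI stays positive throughout the
    full L-year window (so a shift cannot be confirmed within the last L - 1
    years).  This is a retrospective variant: each regime's baseline mean is
    estimated from its first L years, the same convention as for the initial
    regime.  With ``ar1_correct`` the cut-off length is deflated to
    ``L_eff = L * (1 - alpha) / (1 + alpha)`` in both the degrees of freedom
    and the threshold, which makes the test conservative under red noise.
    """
    if isinstance(v, Mapping):
        years = np.array(sorted(v), dtype=int)
        values = np.array([float(v[int(y)]) for y in years], dtype=float)
    else:
        values = np.asarray(v, dtype=float)
        years = np.arange(len(values), dtype=int)
    n = len(values)
    if L < 2:
        raise ValueError("cut-off length L must be >= 2")
    if L > n:
        raise ValueError(f"cut-off length L={L} exceeds series length {n}")
    if n < 2 * L:
        warnings.warn(
            f"series length {n} < 2L={2 * L}; STARS results may be unstable",
            stacklevel=2,
        )

    alpha = estimate_ar1(values, L, ar1_method) if ar1_correct else 0.0
    L_eff = L * (1.0 - alpha) / (1.0 + alpha) if ar1_correct else float(L)
    L_eff = max(L_eff, 2.0)
    sigma2_L = float(
        np.mean([np.var(values[i : i + L], ddof=1) for i in range(n - L + 1)])
    )
    df = 2.0 * L_eff - 2.0
    t_crit = float(stats.t.ppf(1.0 - p / 2.0, df))
    diff = t_crit * np.sqrt(2.0 * sigma2_L / L_eff)
    sigma_L = np.sqrt(sigma2_L)

    shift_years: list[int] = []
    rsi: dict[int, float] = {}
    regime_start = 0
    # the first L points establish the initial regime; testing starts after
    i = min(L, n - 1)
    while i < n:
        baseline = values[regime_start : regime_start + L]
        mean_cur = float(baseline.mean())
        dev = values[i] - mean_cur
        if abs(dev) > diff and sigma_L > 0 and i + L <= n:
            sign = 1.0 if dev > 0 else -1.0
            level = mean_cur + sign * diff
            cum = 0.0
            ok = True
            for j in range(i, i + L):
                z = sign * (values[j] - level) / sigma_L
                w = 1.0 if abs(z) <= h else h / abs(z)
                cum += w * z / L
                if cum < 0:
                    ok = False
                    break
            if ok and cum > 0:
                shift_years.append(int(years[i]))
                rsi[int(years[i])] = cum
                regime_start = i
        i += 1
    return RegimeShiftResult(
        shift_years=tuple(shift_years),
        rsi=rsi,
        cutoff=L,
        p=p,
        huber=h,
        alpha=float(alpha),
    )


# ---------------------------------------------------------------------------
# Autocorrelation-corrected cross-correlation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CrossCorrResult:
    """Pearson r with an effective sample size penalised for autocorrelation."""

    lag: int
    r: float
    n: int
    n_eff: float
    p: float
    p_acf: float


def cross_correlation(
    x: Sequence[float], y: Sequence[float], lag: int = 0, J: int = 5
) -> CrossCorrResult:
    """Pearson correlation of ``y[t]`` with ``x[t - lag]``, with an
    effective-degrees-of-freedom correction for autocorrelation.

    The effective sample size follows the Pyper–Peterman/Chelton form
    ``1/n_eff = 1/n + (2/n) * sum_{j=1..J} rho_x(j) * rho_y(j)`` (clamped to
    [3, n]); the two-sided p-value uses Student's t with ``n_eff - 2`` df.
    With ``J=0`` this reduces to the classical Pearson test.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if lag < 0:
        raise ValueError("lag must be non-negative")
    if lag > 0:
        xa, ya = x[:-lag], y[lag:]
    else:
        xa, ya = x, y
    n = len(xa)
    if len(ya) != n:
        raise ValueError("x and y must have equal length after lag alignment")
    if n < J + 3:
        raise ValueError(f"need at least J + 3 = {J + 3} aligned pairs, got {n}")
    if np.std(xa) == 0 or np.std(ya) == 0:
        raise ValueError("zero-variance input")

    r = float(np.corrcoef(xa, ya)[0, 1])
    if J > 0:
        rho_x = _acf(xa, nlags=J, fft=False)[1:]
        rho_y = _acf(ya, nlags=J, fft=False)[1:]
        inv_neff = 1.0 / n + (2.0 / n) * float(np.sum(rho_x * rho_y))
        n_eff = 1.0 / inv_neff if inv_neff > 0 else float(n)
    else:
        n_eff = float(n)
    n_eff = float(np.clip(n_eff, 3.0, n))

    def _pvalue(r_: float, df_n: float) -> float:
        df = df_n - 2.0
        denom = 1.0 - r_ * r_
        if denom <= 0:
            return 0.0
        t = abs(r_) * np.sqrt(df / denom)
        return float(2.0 * stats.t.sf(t, df))

    return CrossCorrResult(
        lag=lag,
        r=r,
        n=n,
        n_eff=n_eff,
        p=_pvalue(r, float(n)),
        p_acf=_pvalue(r, n_eff),
    )
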