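"""Fold-bifurcation scenario generator with known ground truth.

Emulates the structure of the study system: ~29 years x ~30 taxa of strictly
positive abundance proxies whose log-scale dynamics are driven by one latent
indicator with contrasting positive/negative loadings, a stressor with AR(1)
noise and step jumps of ~0.5 units, a 0-2 year lagged effect, and hysteretic
regime shifts between affine branch attractors.  All randomness flows through
seeded generators, so identical seeds give bit-identical scenarios.
"""

from __future__ import annotations

import json
from collections.abc import Callable, Sequence
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .core_io import StressorSeries, SystemMatrix, write_stressor_series, write_system_matrix

__all__ = [
    "FoldSpec",
    "SyntheticTruth",
    "simulate_stressor",
    "simulate_fold_system",
    "simulate_taxa",
    "make_scenario",
    "write_scenario",
    "SCENARIO_NAMES",
]

SCENARIO_NAMES = ("east_like", "west_like", "smooth_null")


@dataclass(frozen=True)
class FoldSpec:
    """A ladder of regimes with hysteretic tipping rules.

    ``branch_curves[i]`` maps the lagged stressor to the latent state in
    regime i; the system moves from regime i to i+1 when the lagged stressor
    exceeds ``forward_tips[i]`` and back when it drops below
    ``backward_tips[i]`` (< forward_tips[i], producing hysteresis).
    """

    branch_curves: tuple[Callable[[float], float], ...]
    forward_tips: tuple[float, ...]
    backward_tips: tuple[float, ...]
    lag: int
    noise_sd_state: float
    n_years: int
    seed: int
    start_year: int = 1985
    switch_delay: int = 0

    def __post_init__(self) -> None:
        if len(self.branch_curves) != len(self.forward_tips) + 1:
            raise ValueError("need exactly one more branch curve than forward tips")
        if len(self.forward_tips) != len(self.backward_tips):
            raise ValueError("forward and backward tip lists must have equal length")
        for b, f in zip(self.backward_tips, self.forward_tips):
            if not b < f:
                raise ValueError(f"hysteresis requires backward tip {b} < forward tip {f}")
        if self.lag < 0:
            raise ValueError("lag must be non-negative")
        if self.switch_delay < 0:
            raise ValueError("switch_delay must be non-negative")


@dataclass(frozen=True)
class SyntheticTruth:
    """A generated scenario plus everything needed to verify recovery."""

    name: str
    seed: int
    stressor: StressorSeries
    latent_state: dict[int, float]
    regime_label: dict[int, int]
    taxa_loadings: np.ndarray
    system: SystemMatrix
    lag: int
    thresholds: tuple[int, ...]  # last years of the older regimes
    fold: FoldSpec


def simulate_stressor(
    n_years: int,
    base: float,
    jumps: Sequence[tuple[int, float]] = (),
    ar1: float = 0.0,
    sd: float = 0.0,
    seed: int | None = None,
    start_year: int = 1982,
    rng: np.random.Generator | None = None,
) -> StressorSeries:
    """Annual stressor: base level + cumulative step jumps + stationary AR(1)
    noise with marginal standard deviation ``sd`` and lag-1 autocorrelation
    ``ar1``."""
    if not 0.0 <= ar1 < 1.0:
        raise ValueError("ar1 must be in [0, 1)")
    years = np.arange(start_year, start_year + n_years)
    for jy, _ in jumps:
        if not (start_year <= jy < start_year + n_years):
            raise ValueError(f"jump year {jy} outside simulated range")
    rng = rng if rng is not None else np.random.default_rng(seed)
    noise = np.zeros(n_years)
    if sd > 0:
        innov_sd = sd * np.sqrt(1.0 - ar1 * ar1)
        noise[0] = rng.normal(0.0, sd)
        for t in range(1, n_years):
            noise[t] = ar1 * noise[t - 1] + rng.normal(0.0, innov_sd)
    steps = np.zeros(n_years)
    for jy, delta in jumps:
        steps[years >= jy] += delta
    return StressorSeries(years=years, values=base + steps + noise)


def simulate_fold_system(
    spec: FoldSpec, stressor: StressorSeries
) -> tuple[dict[int, float], dict[int, int]]:
    """Drive the latent state over the fold ladder with hysteresis.

    The tipping rule is evaluated on the lagged stressor: the driver regime
    moves forward when it crosses the next forward tip, backward when it
    retreats below the previous backward tip, and persists otherwise.  The
    *expressed* regime follows the driver after ``switch_delay`` years
    (community reorganization takes time), so the year of a crossing shows
    the old configuration under the new stressor level — the transitional
    state characteristic of observed shifts.  The latent state is the
    expressed regime's branch curve at the lagged stressor plus Gaussian
    state noise.  Regime labels are 1-based.
    """
    years = np.arange(spec.start_year, spec.start_year + spec.n_years)
    first_needed = int(years[0]) - spec.lag
    if first_needed not in stressor:
        raise ValueError(
            f"stressor must cover lagged year {first_needed} for lag {spec.lag}"
        )
    rng = np.random.default_rng(spec.seed)
    n_regimes = len(spec.branch_curves)
    driver: list[int] = []
    r = 0
    for t in years:
        x_lag = stressor[int(t) - spec.lag]
        while r < n_regimes - 1 and x_lag > spec.forward_tips[r]:
            r += 1
        while r > 0 and x_lag < spec.backward_tips[r - 1]:
            r -= 1
        driver.append(r)
    latent: dict[int, float] = {}
    regime: dict[int, int] = {}
    for idx, t in enumerate(years):
        d_idx = idx - spec.switch_delay
        r_expr = driver[d_idx] if d_idx >= 0 else 0
        x_lag = stressor[int(t) - spec.lag]
        value = float(spec.branch_curves[r_expr](x_lag))
        if spec.noise_sd_state > 0:
            value += rng.normal(0.0, spec.noise_sd_state)
        latent[int(t)] = value
        regime[int(t)] = r_expr + 1
    return latent, regime


def simulate_taxa(
    latent_state: dict[int, float],
    n_taxa: int = 30,
    loading_range: tuple[float, float] = (0.3, 1.0),
    base_log_abundance: tuple[float, float] = (np.log(50.0), np.log(5000.0)),
    noise_sd: float = 0.4,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[SystemMatrix, np.ndarray]:
    """Project the latent state onto strictly positive taxon series.

    ``value[t, i] = exp(mu_i + w_i * latent[t] + eps)`` with loadings w_i of
    magnitude in ``loading_range`` and contrasting signs (half positive, half
    negative, shuffled), mimicking warm- vs cold-affiliated taxa.  Returns the
    raw-scale matrix and the loading vector.
    """
    if n_taxa < 2:
        raise ValueError("need at least 2 taxa")
    lo, hi = loading_range
    if not (0 <= lo <= hi):
        raise ValueError("loading_range must satisfy 0 <= lo <= hi")
    rng = rng if rng is not None else np.random.default_rng(seed)
    years = np.array(sorted(latent_state), dtype=int)
    latent = np.array([latent_state[int(t)] for t in years])
    mags = rng.uniform(lo, hi, size=n_taxa)
    signs = np.ones(n_taxa)
    signs[: n_taxa // 2] = -1.0
    rng.shuffle(signs)
    w = mags * signs
    mu = rng.uniform(base_log_abundance[0], base_log_abundance[1], size=n_taxa)
    eps = rng.normal(0.0, noise_sd, size=(len(years), n_taxa))
    log_values = mu[None, :] + np.outer(latent, w) + eps
    taxa = tuple(f"taxon_{i + 1:02d}" for i in range(n_taxa))
    return SystemMatrix(years, taxa, np.exp(log_values), scale="raw"), w


def _thresholds_from_labels(regime: dict[int, int]) -> tuple[int, ...]:
    years = sorted(regime)
    return tuple(
        int(a) for a, b in zip(years[:-1], years[1:]) if regime[b] != regime[a]
    )


def make_scenario(name: str, seed: int) -> SyntheticTruth:
    """Generate one of the bundled study-condition scenarios.

    east_like : 29 years (1985-2013), 30 taxa, one hysteretic shift driven by
        a 0.5-unit stressor jump in 1995, 1-year lag.
    west_like : as above but two shifts (jumps of 0.5 and 0.7 units), 2-year
        lag, a narrow middle regime with a shallow basin.
    smooth_null : continuous (linear) response to a gradually trending
        stressor, no threshold — the GAM-favouring control.
    """
    if name not in SCENARIO_NAMES:
        raise ValueError(f"unknown scenario {name!r}; choose from {SCENARIO_NAMES}")
    ss = np.random.SeedSequence(seed)
    s_stress, s_state, s_taxa = (int(s) % (2**31) for s in ss.generate_state(3))

    # Shift geometry: the stressor spikes by ~0.5 units, crosses the forward
    # tip, then relaxes back towards its old level while the system stays on
    # the new branch (hysteresis), so regime year-clusters overlap in x.
    # Branch curves are affine in latent units with a within-regime slope
    # strong enough for the lag to be identifiable from year-to-year
    # fluctuations; vertical branch separation is many times the state noise.
    if name == "east_like":
        lag = 1
        stressor = simulate_stressor(
            32, base=20.0, jumps=[(1995, 0.5), (1996, -0.5)], ar1=0.4, sd=0.10,
            seed=s_stress, start_year=1982,
        )
        fold = FoldSpec(
            branch_curves=(
                lambda x: 0.30 - 1.0 * (x - 20.1),
                lambda x: -0.30 - 1.0 * (x - 20.1),
            ),
            forward_tips=(20.30,),
            backward_tips=(19.70,),
            lag=lag,
            noise_sd_state=0.04,
            n_years=29,
            seed=s_state,
            start_year=1985,
        )
    elif name == "west_like":
        lag = 2
        stressor = simulate_stressor(
            32, base=19.85,
            jumps=[(1989, 0.15), (1994, 0.5), (1995, -0.45), (2000, 0.9),
                   (2001, -0.5), (2002, -0.35)],
            ar1=0.4, sd=0.10, seed=s_stress, start_year=1982,
        )
        fold = FoldSpec(
            branch_curves=(
                lambda x: 0.7 - 1.0 * (x - 20.2),
                lambda x: 0.0 - 1.0 * (x - 20.2),
                lambda x: -0.7 - 1.0 * (x - 20.2),
            ),
            forward_tips=(20.30, 20.70),
            backward_tips=(19.70, 19.75),
            lag=lag,
            noise_sd_state=0.04,
            n_years=29,
            seed=s_state,
            start_year=1985,
        )
    else:  # smooth_null
        lag = 0
        ramp = [(y, 0.04) for y in range(1990, 2010)]
        stressor = simulate_stressor(
            32, base=20.0, jumps=ramp, ar1=0.4, sd=0.10,
            seed=s_stress, start_year=1982,
        )
        fold = FoldSpec(
            branch_curves=(lambda x: -0.8 * (x - 20.4),),
            forward_tips=(),
            backward_tips=(),
            lag=lag,
            noise_sd_state=0.04,
            n_years=29,
            seed=s_state,
            start_year=1985,
        )

    latent, regime = simulate_fold_system(fold, stressor)
    # observation noise sized so the leading component explains roughly half
    # of the total log-scale variance, the realistic regime for landings data
    system, w = simulate_taxa(latent, n_taxa=30, noise_sd=0.25, seed=s_taxa)
    return SyntheticTruth(
        name=name,
        seed=seed,
        stressor=stressor,
        latent_state=latent,
        regime_label=regime,
        taxa_loadings=w,
        system=system,
        lag=lag,
        thresholds=_thresholds_from_labels(regime),
        fold=fold,
    )


def write_scenario(truth: SyntheticTruth, outdir: str | Path) -> dict[str, Path]:
    """Write system.csv, stressor.csv and truth.json for a scenario."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "system": outdir / "system.csv",
        "stressor": outdir / "stressor.csv",
        "truth": outdir / "truth.json",
    }
    write_system_matrix(truth.system, paths["system"])
    write_stressor_series(truth.stressor, paths["stressor"], name="stressor")
    payload = {
        "scenario": truth.name,
        "seed": truth.seed,
        "lag": truth.lag,
        "thresholds": list(truth.thresholds),
        "forward_tips": list(truth.fold.forward_tips),
        "backward_tips": list(truth.fold.backward_tips),
        "taxa_loadings": [float(v) for v in truth.taxa_loadings],
        "regime_label": {str(k): int(v) for k, v in sorted(truth.regime_label.items())},
        "latent_state": {str(k): float(v) for k, v in sorted(truth.latent_state.items())},
    }
    paths["truth"].write_text(json.dumps(payload, indent=2) + "\n", encoding="utf-8")
    return paths
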