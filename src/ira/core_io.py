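"""Data model, file I/O and alignment utilities shared by all analysis stages.

The framework operates on complete annual series: a year x taxon matrix of
strictly positive abundance proxies (e.g. fisheries landings in tonnes) and a
single stressor series (e.g. annual mean SST in deg C) that must extend far
enough back in time to cover every lag under study.  Missing values are
rejected rather than imputed.
"""

from __future__ import annotations

from collections.abc import Mapping, Sequence
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "SystemMatrix",
    "StressorSeries",
    "PairedSeries",
    "read_system_matrix",
    "write_system_matrix",
    "read_stressor_series",
    "write_stressor_series",
    "log_transform",
    "lag_align",
    "mean_standardise",
]

YEAR_COLUMN = "year"


def _check_years(years: np.ndarray) -> None:
    """Years must be integers, strictly increasing, with no gaps."""
    if years.ndim != 1 or len(years) == 0:
        raise ValueError("years must be a non-empty 1-D sequence")
    diffs = np.diff(years)
    dup = years[:-1][diffs == 0]
    if dup.size:
        raise ValueError(f"duplicate year {int(dup[0])}")
    if np.any(diffs < 0):
        raise ValueError("years must be strictly increasing")
    if np.any(diffs > 1):
        gap_year = int(years[:-1][diffs > 1][0]) + 1
        raise ValueError(f"gap at {gap_year}")


@dataclass(frozen=True)
class SystemMatrix:
    """Year-indexed matrix of per-taxon values (raw tonnes or log-units).

    Attributes
    ----------
    years : (n_years,) int array, strictly increasing, gap-free.
    taxa : taxon labels, one per column.
    values : (n_years, n_taxa) float array with no missing cells.
    scale : ``"raw"`` or ``"log"``.
    """

    years: np.ndarray
    taxa: tuple[str, ...]
    values: np.ndarray
    scale: str = "raw"

    def __post_init__(self) -> None:
        years = np.asarray(self.years, dtype=int)
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "years", years)
        object.__setattr__(self, "taxa", tuple(str(t) for t in self.taxa))
        object.__setattr__(self, "values", values)
        _check_years(years)
        if self.scale not in ("raw", "log"):
            raise ValueError(f"scale must be 'raw' or 'log', got {self.scale!r}")
        if values.shape != (len(years), len(self.taxa)):
            raise ValueError(
                f"values shape {values.shape} does not match "
                f"{len(years)} years x {len(self.taxa)} taxa"
            )
        if not np.all(np.isfinite(values)):
            bad = np.argwhere(~np.isfinite(values))
            y, t = bad[0]
            raise ValueError(
                f"missing or non-finite cell at year {int(years[y])}, "
                f"taxon {self.taxa[t]!r}"
            )

    @property
    def n_years(self) -> int:
        return len(self.years)

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=pd.Index(self.years, name=YEAR_COLUMN), columns=list(self.taxa)
        )


@dataclass(frozen=True)
class StressorSeries:
    """Annual stressor values (deg C, or offset units once standardised)."""

    years: np.ndarray
    values: np.ndarray
    standardized: bool = False

    def __post_init__(self) -> None:
        years = np.asarray(self.years, dtype=int)
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "years", years)
        object.__setattr__(self, "values", values)
        _check_years(years)
        if values.shape != years.shape:
            raise ValueError("stressor years and values must have equal length")
        if not np.all(np.isfinite(values)):
            bad_year = int(years[~np.isfinite(values)][0])
            raise ValueError(f"missing or non-finite stressor value at year {bad_year}")

    def __getitem__(self, year: int) -> float:
        idx = year - int(self.years[0])
        if idx < 0 or idx >= len(self.years):
            raise KeyError(year)
        return float(self.values[idx])

    def __contains__(self, year: int) -> bool:
        return int(self.years[0]) <= year <= int(self.years[-1])

    def mean_standardise(self) -> "StressorSeries":
        """Subtract the series mean; marks the result as standardised."""
        return replace(self, values=mean_standardise(self.values), standardized=True)

    def to_frame(self, name: str = "stressor") -> pd.DataFrame:
        return pd.DataFrame({YEAR_COLUMN: self.years, name: self.values})


@dataclass(frozen=True)
class PairedSeries:
    """Lag-aligned (stressor, indicator) pairs: ``x[t] = stressor[t - lag]``."""

    years: np.ndarray
    x: np.ndarray
    y: np.ndarray
    lag: int = 0

    def __post_init__(self) -> None:
        years = np.asarray(self.years, dtype=int)
        x = np.asarray(self.x, dtype=float)
        y = np.asarray(self.y, dtype=float)
        for name, arr in (("years", years), ("x", x), ("y", y)):
            object.__setattr__(self, name, arr)
        _check_years(years)
        if not (len(years) == len(x) == len(y)):
            raise ValueError("years, x and y must have equal length")
        if self.lag < 0:
            raise ValueError("lag must be non-negative")
        if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
            raise ValueError("paired series contains missing values")

    def __len__(self) -> int:
        return len(self.years)

    def subset_years(self, years: Sequence[int]) -> "PairedSeries":
        mask = np.isin(self.years, np.asarray(list(years), dtype=int))
        return PairedSeries(self.years[mask], self.x[mask], self.y[mask], self.lag)


def _infer_delimiter(path: Path, dialect: str | None) -> str:
    if dialect is not None:
        return dialect
    return "\t" if path.suffix.lower() in (".tsv", ".tab") else ","


def _read_table(path: str | Path, dialect: str | None) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"input file not found: {path}")
    df = pd.read_csv(path, sep=_infer_delimiter(path, dialect), comment="#")
    df.columns = [str(c).strip() for c in df.columns]
    if YEAR_COLUMN not in df.columns:
        raise ValueError(f"{path}: first column must be named '{YEAR_COLUMN}'")
    for col in df.columns:
        if col == YEAR_COLUMN:
            continue
        values = pd.to_numeric(df[col], errors="coerce")
        bad = df[col][values.isna() & df[col].notna()]
        if not bad.empty:
            raise ValueError(f"{path}: non-numeric cell {bad.iloc[0]!r} in column {col!r}")
        df[col] = values
    return df.sort_values(YEAR_COLUMN).reset_index(drop=True)


def read_system_matrix(path: str | Path, dialect: str | None = None) -> SystemMatrix:
    """Read a year x taxon table (CSV/TSV, header row, 'year' first column)."""
    df = _read_table(path, dialect)
    taxa = [c for c in df.columns if c != YEAR_COLUMN]
    if not taxa:
        raise ValueError(f"{path}: no taxon columns found")
    return SystemMatrix(
        years=df[YEAR_COLUMN].to_numpy(dtype=int),
        taxa=tuple(taxa),
        values=df[taxa].to_numpy(dtype=float),
        scale="raw",
    )


def write_system_matrix(
    m: SystemMatrix, path: str | Path, dialect: str | None = None, header: str | None = None
) -> None:
    path = Path(path)
    sep = _infer_delimiter(path, dialect)
    with open(path, "w", encoding="utf-8") as fh:
        if header:
            fh.write(f"# {header}\n")
        m.to_frame().reset_index().to_csv(fh, sep=sep, index=False, lineterminator="\n")


def read_stressor_series(path: str | Path, dialect: str | None = None) -> StressorSeries:
    """Read a two-column (year, value) stressor table."""
    df = _read_table(path, dialect)
    value_cols = [c for c in df.columns if c != YEAR_COLUMN]
    if not value_cols:
        raise ValueError(f"{path}: no stressor value column found")
    return StressorSeries(
        years=df[YEAR_COLUMN].to_numpy(dtype=int),
        values=df[value_cols[0]].to_numpy(dtype=float),
    )


def write_stressor_series(
    s: StressorSeries,
    path: str | Path,
    dialect: str | None = None,
    name: str = "stressor",
    header: str | None = None,
) -> None:
    path = Path(path)
    sep = _infer_delimiter(path, dialect)
    with open(path, "w", encoding="utf-8") as fh:
        if header:
            fh.write(f"# {header}\n")
        s.to_frame(name).to_csv(fh, sep=sep, index=False, lineterminator="\n")


def log_transform(m: SystemMatrix, offset: float = 0.0) -> SystemMatrix:
    """Natural-log transform ``ln(value + offset)`` of a raw matrix.

    The offset is exposed (default 0) because zero-handling ahead of the log
    is a data-preparation decision; any cell with ``value + offset <= 0`` is an
    error listing the offending cells.
    """
    if m.scale != "raw":
        raise ValueError("log_transform expects a raw-scale matrix")
    if offset < 0:
        raise ValueError("offset must be non-negative")
    shifted = m.values + offset
    if np.any(shifted <= 0):
        bad = np.argwhere(shifted <= 0)
        cells = ", ".join(
            f"(year {int(m.years[i])}, {m.taxa[j]!r})" for i, j in bad[:10]
        )
        more = "" if len(bad) <= 10 else f" and {len(bad) - 10} more"
        raise ValueError(
            f"non-positive values after offset {offset}: {cells}{more}; "
            "supply a positive --log-offset"
        )
    return SystemMatrix(m.years, m.taxa, np.log(shifted), scale="log")


def lag_align(
    stressor: StressorSeries, indicator: Mapping[int, float], lag: int
) -> PairedSeries:
    """Pair each indicator year t with the stressor at year ``t - lag``.

    "Lag l" means the stressor leads the response by l years, i.e. the
    stressor of year t-l is the explanatory value for the year-t indicator.
    """
    if lag < 0:
        raise ValueError("lag must be non-negative")
    years = np.array(sorted(indicator), dtype=int)
    needed = years - lag
    missing = [int(y) for y in needed if y not in stressor]
    if missing:
        raise ValueError(
            f"stressor series does not cover lagged year {missing[0]} "
            f"(lag {lag}); earliest stressor year is {int(stressor.years[0])}"
        )
    x = np.array([stressor[int(y)] for y in needed], dtype=float)
    y = np.array([float(indicator[int(t)]) for t in years], dtype=float)
    return PairedSeries(years=years, x=x, y=y, lag=lag)


def mean_standardise(v: Sequence[float]) -> np.ndarray:
    """Subtract the mean (no variance scaling); idempotent."""
    arr = np.asarray(v, dtype=float)
    if arr.ndim != 1 or len(arr) < 2:
        raise ValueError("mean_standardise needs a 1-D sequence of length >= 2")
    return arr - arr.mean()
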