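"""Core domain containers and partition arithmetic.

The model distinguishes, within every country, a *native* population ``P``
(people living in their country of birth) from *migrant* stocks
``D[residence, origin]`` (people born elsewhere).  Migration flows are drawn
from probability distributions fitted separately within partitions of three
covariates:

* origin population size ``P`` — four order-of-magnitude bins P1..P4,
* origin/destination per-capita-GDP ratio ``g`` — four bins g1..g4,
* relative diaspora size ``d`` — five bins d1..d5.

This module holds the partition definitions, the 5-year ↔ 1-year rate
conversion used when calibrating on quinquennial flow data, and the tabular /
matrix containers shared by the calibration and simulation layers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PartitionScheme",
    "CountryPanel",
    "WorldState",
    "FlowMatrices",
    "FlowHistory",
    "population_label",
    "gdp_ratio_label",
    "diaspora_label",
    "rescale_five_year_rate",
    "compound_yearly_rate",
]


# ---------------------------------------------------------------------------
# Partition scheme
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PartitionScheme:
    """Bin edges for the three covariate partitions.

    Population bins are right-closed: P1=[0, 1e6], P2=(1e6, 1e7],
    P3=(1e7, 1e8], P4=(1e8, inf).  GDP-ratio and diaspora bins are
    left-closed: g2=[0.1, 1), d5=[0.1, inf), etc.  The default edges are the
    published partition; alternative edges may be supplied but the closure
    conventions are fixed.
    """

    population_edges: tuple[float, ...] = (1e6, 1e7, 1e8)
    gdp_ratio_edges: tuple[float, ...] = (1e-1, 1.0, 1e1)
    diaspora_edges: tuple[float, ...] = (1e-7, 1e-5, 1e-3, 0.1)
    population_closed: str = "right"
    ratio_closed: str = "left"

    def __post_init__(self) -> None:
        for name in ("population_edges", "gdp_ratio_edges", "diaspora_edges"):
            edges = np.asarray(getattr(self, name), dtype=float)
            if edges.ndim != 1 or len(edges) == 0:
                raise ValueError(f"{name} must be a non-empty 1-D sequence")
            if not np.all(np.diff(edges) > 0):
                raise ValueError(f"{name} must be strictly increasing")
            object.__setattr__(self, name, tuple(edges))
        if self.population_closed != "right" or self.ratio_closed != "left":
            raise ValueError(
                "only right-closed population bins and left-closed "
                "ratio/diaspora bins are supported"
            )

    # -- labels -------------------------------------------------------------

    @property
    def population_labels(self) -> tuple[str, ...]:
        return tuple(f"P{i + 1}" for i in range(len(self.population_edges) + 1))

    @property
    def gdp_ratio_labels(self) -> tuple[str, ...]:
        return tuple(f"g{i + 1}" for i in range(len(self.gdp_ratio_edges) + 1))

    @property
    def diaspora_labels(self) -> tuple[str, ...]:
        return tuple(f"d{i + 1}" for i in range(len(self.diaspora_edges) + 1))

    # -- vectorized bin indices ---------------------------------------------

    def population_bin(self, P) -> np.ndarray:
        """0-based bin index for population size(s); right-closed intervals."""
        arr = np.asarray(P, dtype=float)
        if np.any(arr < 0) or np.any(~np.isfinite(arr)):
            raise ValueError("population size must be finite and >= 0")
        return np.searchsorted(self.population_edges, arr, side="left")

    def gdp_ratio_bin(self, g) -> np.ndarray:
        """0-based bin index for GDPc ratio(s); left-closed intervals."""
        arr = np.asarray(g, dtype=float)
        if np.any(arr <= 0) or np.any(~np.isfinite(arr)):
            raise ValueError("GDPc ratio must be finite and > 0")
        return np.searchsorted(self.gdp_ratio_edges, arr, side="right")

    def diaspora_bin(self, d) -> np.ndarray:
        """0-based bin index for relative diaspora size(s); left-closed."""
        arr = np.asarray(d, dtype=float)
        if np.any(arr < 0) or np.any(~np.isfinite(arr)):
            raise ValueError("diaspora covariate must be finite and >= 0")
        return np.searchsorted(self.diaspora_edges, arr, side="right")

    # -- (de)serialization ----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "population_edges": list(self.population_edges),
            "gdp_ratio_edges": list(self.gdp_ratio_edges),
            "diaspora_edges": list(self.diaspora_edges),
            "population_closed": self.population_closed,
            "ratio_closed": self.ratio_closed,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "PartitionScheme":
        return cls(
            population_edges=tuple(d.get("population_edges", (1e6, 1e7, 1e8))),
            gdp_ratio_edges=tuple(d.get("gdp_ratio_edges", (1e-1, 1.0, 1e1))),
            diaspora_edges=tuple(d.get("diaspora_edges", (1e-7, 1e-5, 1e-3, 0.1))),
            population_closed=d.get("population_closed", "right"),
            ratio_closed=d.get("ratio_closed", "left"),
        )


DEFAULT_SCHEME = PartitionScheme()


def population_label(P: float, scheme: PartitionScheme = DEFAULT_SCHEME) -> str:
    """Label of the population-size bin containing ``P`` (e.g. ``"P1"``)."""
    return scheme.population_labels[int(scheme.population_bin(P))]


def gdp_ratio_label(g: float, scheme: PartitionScheme = DEFAULT_SCHEME) -> str:
    """Label of the GDPc-ratio bin containing ``g`` (e.g. ``"g3"``)."""
    return scheme.gdp_ratio_labels[int(scheme.gdp_ratio_bin(g))]


def diaspora_label(d: float, scheme: PartitionScheme = DEFAULT_SCHEME) -> str:
    """Label of the diaspora bin containing ``d`` (e.g. ``"d5"``)."""
    return scheme.diaspora_labels[int(scheme.diaspora_bin(d))]


# ---------------------------------------------------------------------------
# Rate conversion between 5-year and yearly rates
# ---------------------------------------------------------------------------

def rescale_five_year_rate(m5):
    """Convert a 5-year migration rate to a yearly rate.

    ``m1 = 1 - (1 - m5)**(1/5)``, assuming a homogeneous rate within the
    quinquennium.  Accepts scalars or arrays in [0, 1].
    """
    arr = np.asarray(m5, dtype=float)
    if np.any(arr < 0) or np.any(arr > 1) or np.any(~np.isfinite(arr)):
        raise ValueError("5-year rate must lie in [0, 1]")
    out = 1.0 - (1.0 - arr) ** 0.2
    return float(out) if np.isscalar(m5) else out


def compound_yearly_rate(m1):
    """Inverse of :func:`rescale_five_year_rate`: ``m5 = 1 - (1 - m1)**5``."""
    arr = np.asarray(m1, dtype=float)
    if np.any(arr < 0) or np.any(arr > 1) or np.any(~np.isfinite(arr)):
        raise ValueError("yearly rate must lie in [0, 1]")
    out = 1.0 - (1.0 - arr) ** 5
    return float(out) if np.isscalar(m1) else out


# ---------------------------------------------------------------------------
# Country panel
# ---------------------------------------------------------------------------

PANEL_COLUMNS = (
    "country_id",
    "year",
    "population",
    "natural_change_rate",
    "birth_rate",
    "death_rate",
    "gdpc",
    "region",
    "income_group",
)


class CountryPanel:
    """Per-country, per-year demographic and economic covariates.

    Wraps a tidy DataFrame with columns ``country_id, year, population,
    natural_change_rate, birth_rate, death_rate, gdpc, region, income_group``
    and exposes year-aligned vectors over a fixed country ordering.
    """

    def __init__(self, df: pd.DataFrame):
        missing = [c for c in PANEL_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"panel is missing columns: {missing}")
        df = df.loc[:, list(df.columns)].copy()
        if df.duplicated(subset=["country_id", "year"]).any():
            dups = df[df.duplicated(subset=["country_id", "year"], keep=False)]
            raise ValueError(
                "duplicate (country_id, year) pairs: "
                f"{sorted(set(map(tuple, dups[['country_id', 'year']].values)))[:5]}"
            )
        if (df["population"] < 0).any():
            raise ValueError("population must be >= 0")
        if (df["gdpc"] <= 0).any():
            raise ValueError("gdpc must be > 0")
        if (df["birth_rate"] < 0).any() or (df["death_rate"] < 0).any():
            raise ValueError("birth_rate and death_rate must be >= 0")
        self.df = df.sort_values(["country_id", "year"]).reset_index(drop=True)
        self.countries: tuple[str, ...] = tuple(sorted(df["country_id"].unique()))
        self.years: np.ndarray = np.sort(df["year"].unique()).astype(int)
        self._index = {c: i for i, c in enumerate(self.countries)}
        self._grids = {}
        for col in ("population", "natural_change_rate", "birth_rate",
                    "death_rate", "gdpc"):
            pivot = self.df.pivot(index="year", columns="country_id", values=col)
            pivot = pivot.reindex(index=self.years, columns=self.countries)
            self._grids[col] = pivot.to_numpy(dtype=float)
        self._year_pos = {int(y): i for i, y in enumerate(self.years)}
        first = self.df.drop_duplicates("country_id").set_index("country_id")
        self.region: dict[str, str] = first["region"].to_dict()
        self.income_group: dict[str, str] = first["income_group"].to_dict()

    def _row(self, col: str, year: int, allow_missing: bool = False) -> np.ndarray:
        try:
            pos = self._year_pos[int(year)]
        except KeyError:
            raise KeyError(f"panel does not cover year {year}") from None
        row = self._grids[col][pos]
        if not allow_missing and np.any(np.isnan(row)):
            bad = [c for c, v in zip(self.countries, row) if np.isnan(v)]
            raise ValueError(f"panel column {col!r} missing for {bad} in {year}")
        return row

    def population(self, year: int) -> np.ndarray:
        return self._row("population", year)

    def natural_change(self, year: int) -> np.ndarray:
        return self._row("natural_change_rate", year)

    def birth_rate(self, year: int) -> np.ndarray:
        return self._row("birth_rate", year)

    def death_rate(self, year: int) -> np.ndarray:
        return self._row("death_rate", year)

    def gdpc(self, year: int) -> np.ndarray:
        return self._row("gdpc", year)

    def covers(self, years: Iterable[int]) -> bool:
        return all(int(y) in self._year_pos for y in years)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (f"CountryPanel({len(self.countries)} countries, "
                f"years {self.years.min()}-{self.years.max()})")


# ---------------------------------------------------------------------------
# World state and flow matrices
# ---------------------------------------------------------------------------

def _check_matrix(name: str, A: np.ndarray, n: int) -> np.ndarray:
    A = np.asarray(A, dtype=float)
    if A.shape != (n, n):
        raise ValueError(f"{name} must be {n}x{n}, got {A.shape}")
    if np.any(A < 0):
        raise ValueError(f"{name} has negative entries")
    if np.any(np.diag(A) != 0):
        raise ValueError(f"{name} must have a zero diagonal")
    return A


@dataclass
class WorldState:
    """Native population vector and migrant-stock matrix at one year.

    ``D[i, k]`` is the stock of people born in country ``k`` residing in
    country ``i``; arrival times are aggregated out (return and birth flows
    do not depend on them).
    """

    year: int
    countries: tuple[str, ...]
    P: np.ndarray
    D: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.countries)
        self.countries = tuple(self.countries)
        self.P = np.asarray(self.P, dtype=float)
        if self.P.shape != (n,):
            raise ValueError(f"P must have shape ({n},), got {self.P.shape}")
        if np.any(self.P < 0):
            raise ValueError("P has negative entries")
        self.D = _check_matrix("D", self.D, n)

    @property
    def total_population(self) -> float:
        return float(self.P.sum())

    @property
    def total_migrant_stock(self) -> float:
        return float(self.D.sum())

    def stock_by_origin(self) -> np.ndarray:
        """Total stock of emigrants per origin country (column sums of D)."""
        return self.D.sum(axis=0)

    def stock_by_destination(self) -> np.ndarray:
        """Total immigrant stock per residence country (row sums of D)."""
        return self.D.sum(axis=1)

    def copy(self) -> "WorldState":
        return WorldState(self.year, self.countries, self.P.copy(), self.D.copy())


@dataclass
class FlowMatrices:
    """One year's flows: emigration ``M[origin, dest]``, returns
    ``R[residence, origin]``, and migrant births ``B[residence, origin]``."""

    M: np.ndarray
    R: np.ndarray
    B: np.ndarray

    def __post_init__(self) -> None:
        n = np.asarray(self.M).shape[0]
        self.M = _check_matrix("M", self.M, n)
        self.R = _check_matrix("R", self.R, n)
        self.B = _check_matrix("B", self.B, n)


@dataclass
class FlowHistory:
    """Bilateral flow totals aggregated to multi-year periods.

    ``M[p, i, j]`` is the emigration flow from ``i`` to ``j`` summed over
    period ``p``; ``R[p, i, k]`` the return flow from residence ``i`` back to
    origin ``k``.  ``periods`` holds (start_year, end_year) pairs where the
    end year is exclusive; the canonical source data uses 5-year periods.
    """

    countries: tuple[str, ...]
    periods: tuple[tuple[int, int], ...]
    M: np.ndarray
    R: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.countries)
        p = len(self.periods)
        self.countries = tuple(self.countries)
        self.periods = tuple((int(a), int(b)) for a, b in self.periods)
        for name in ("M", "R"):
            A = np.asarray(getattr(self, name), dtype=float)
            if A.shape != (p, n, n):
                raise ValueError(f"{name} must be ({p},{n},{n}), got {A.shape}")
            if np.any(A < 0):
                raise ValueError(f"{name} has negative entries")
            if np.any(A[:, np.arange(n), np.arange(n)] != 0):
                raise ValueError(f"{name} must have zero diagonals")
            setattr(self, name, A)
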