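"""Readers, writers, aggregation, and model-vs-reference comparison.

All tabular interfaces are tidy CSV:

* country panel: ``country_id,year,population,natural_change_rate,
  birth_rate,death_rate,gdpc,region,income_group`` (per-capita GDP may
  instead be given as ``gdpc_ppp``/``gdpc_mer``/``gdpc_usd`` columns, merged
  by that precedence and then filled from the closest available year);
* emigration flows: ``origin,destination,period_start,period_end,flow``;
* return flows: ``residence,origin,period_start,period_end,flow``;
* stocks: ``residence,origin,year,stock``;
* ensemble summaries: ``series,year,stat,value`` with stat in
  {median,q25,q75,q2.5,q97.5};
* region/income mapping: ``country_id,region,income_group``.
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .calibration import FlowDistributionSet  # noqa: F401  (re-export surface)
from .domain import CountryPanel, FlowHistory, PANEL_COLUMNS, WorldState
from .evolution import EnsembleSummary, QUANTILE_STATS, Trajectory

logger = logging.getLogger(__name__)

__all__ = [
    "read_country_panel",
    "write_country_panel",
    "read_flows",
    "read_return_flows",
    "write_flow_history",
    "flows_to_history",
    "read_stocks",
    "write_stocks",
    "read_summary",
    "write_summary",
    "read_mapping",
    "aggregate_series",
    "compare_to_reference",
]


# ---------------------------------------------------------------------------
# Country panel
# ---------------------------------------------------------------------------

def _merge_gdpc(df: pd.DataFrame) -> tuple[pd.Series, pd.Series]:
    """Apply the PPP -> MER -> USD precedence chain, then fill what is still
    missing from the closest available year (ties resolved to the earlier
    year).  Returns the merged column and a per-row source flag."""
    if "gdpc" in df.columns:
        gdpc = df["gdpc"].astype(float).copy()
        source = pd.Series(
            np.where(gdpc.notna(), "original", None), index=df.index,
            dtype=object,
        )
    else:
        gdpc = pd.Series(np.nan, index=df.index, dtype=float)
        source = pd.Series(None, index=df.index, dtype=object)
        for col, tag in (("gdpc_ppp", "ppp"), ("gdpc_mer", "mer"),
                         ("gdpc_usd", "usd")):
            if col in df.columns:
                take = gdpc.isna() & df[col].notna()
                gdpc[take] = df.loc[take, col].astype(float)
                source[take] = tag
    # closest-year fill within each country
    for cid, grp in df.groupby("country_id", sort=False):
        vals = gdpc.loc[grp.index]
        known = vals.notna()
        if known.all() or not known.any():
            continue
        years = grp["year"].to_numpy()
        kyears = years[known.to_numpy()]
        kvals = vals[known].to_numpy()
        for ridx, year in zip(grp.index[~known.to_numpy()],
                              years[~known.to_numpy()]):
            dist = np.abs(kyears - year)
            best = np.lexsort((kyears, dist))[0]  # closest, ties -> earlier
            gdpc[ridx] = kvals[best]
            source[ridx] = f"closest:{int(kyears[best])}"
    return gdpc, source


def read_country_panel(source, interpolate: bool = True) -> CountryPanel:
    """Read and preprocess a country panel from CSV (or a DataFrame).

    Gaps in ``population`` are filled by linear interpolation strictly
    within each country's observed year span (never extrapolated); countries
    with no population data at all are excluded with a warning.  Per-capita
    GDP is assembled by the precedence chain described in the module
    docstring.  Each filled cell is flagged in ``panel.fill_flags``
    (columns ``population_filled`` and ``gdpc_source``).
    """
    df = source.copy() if isinstance(source, pd.DataFrame) else pd.read_csv(source)
    required = {"country_id", "year"}
    if not required.issubset(df.columns):
        raise ValueError(f"panel needs at least columns {sorted(required)}")
    df = df.sort_values(["country_id", "year"]).reset_index(drop=True)

    no_pop = df.groupby("country_id")["population"].apply(
        lambda s: s.isna().all()
    )
    dropped = no_pop[no_pop].index.tolist()
    if dropped:
        logger.warning("excluding countries with no population data: %s",
                       dropped)
        df = df[~df["country_id"].isin(dropped)].reset_index(drop=True)
    if df.empty:
        raise ValueError("panel has no usable rows")

    pop_filled = pd.Series(False, index=df.index)
    if interpolate:
        for _cid, grp in df.groupby("country_id", sort=False):
            vals = grp["population"]
            if vals.notna().all():
                continue
            interp = vals.copy()
            interp.index = grp["year"].to_numpy()
            filled = interp.interpolate(
                method="index", limit_area="inside"
            )
            newly = vals.isna().to_numpy() & filled.notna().to_numpy()
            df.loc[grp.index, "population"] = filled.to_numpy()
            pop_filled.loc[grp.index[newly]] = True

    gdpc, gdpc_source = _merge_gdpc(df)
    df["gdpc"] = gdpc
    keep = [c for c in PANEL_COLUMNS if c in df.columns]
    still = df["population"].isna() | df["gdpc"].isna()
    if still.any():
        bad = df.loc[still, ["country_id", "year"]]
        logger.warning("dropping %d rows with unfillable population/gdpc: %s",
                       len(bad), bad.head().to_dict("records"))
        df = df[~still]
        pop_filled = pop_filled[~still]
        gdpc_source = gdpc_source[~still]
    panel = CountryPanel(df[keep].reset_index(drop=True))
    panel.fill_flags = pd.DataFrame({
        "country_id": df["country_id"].to_numpy(),
        "year": df["year"].to_numpy(),
        "population_filled": pop_filled.to_numpy(),
        "gdpc_source": gdpc_source.to_numpy(),
    })
    return panel


def write_country_panel(panel: CountryPanel, path) -> None:
    panel.df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Flows and stocks
# ---------------------------------------------------------------------------

def _read_bilateral(path, a: str, b: str, value: str,
                    keys: Sequence[str]) -> pd.DataFrame:
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        return pd.DataFrame(columns=[a, b, *keys, value])
    missing = [c for c in (a, b, *keys, value) if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    if df.empty:
        return df
    if (df[value] < 0).any():
        raise ValueError(f"{path}: negative {value} entries")
    dup = df.duplicated(subset=[a, b, *keys])
    if dup.any():
        raise ValueError(
            f"{path}: duplicate ({a},{b},{','.join(keys)}) rows: "
            f"{df[dup].head().to_dict('records')}"
        )
    diag = (df[a] == df[b]) & (df[value] > 0)
    if diag.any():
        raise ValueError(
            f"{path}: nonzero diagonal rows: {df[diag].head().to_dict('records')}"
        )
    return df


def read_flows(path) -> pd.DataFrame:
    """Emigration flow table ``origin,destination,period_start,period_end,flow``."""
    return _read_bilateral(path, "origin", "destination", "flow",
                           ["period_start", "period_end"])


def read_return_flows(path) -> pd.DataFrame:
    """Return flow table ``residence,origin,period_start,period_end,flow``."""
    return _read_bilateral(path, "residence", "origin", "flow",
                           ["period_start", "period_end"])


def flows_to_history(
    flows: pd.DataFrame,
    return_flows: pd.DataFrame,
    countries: Sequence[str] | None = None,
) -> FlowHistory:
    """Assemble validated period-aggregated matrices from flow tables."""
    if countries is None:
        pool = set()
        for df, cols in ((flows, ("origin", "destination")),
                         (return_flows, ("residence", "origin"))):
            for c in cols:
                if len(df):
                    pool |= set(df[c])
        countries = sorted(pool)
    countries = tuple(countries)
    index = {c: i for i, c in enumerate(countries)}
    periods = sorted(
        {(int(r.period_start), int(r.period_end))
         for df in (flows, return_flows) if len(df)
         for r in df[["period_start", "period_end"]].drop_duplicates().itertuples()}
    )
    n, p = len(countries), len(periods)
    pindex = {pp: i for i, pp in enumerate(periods)}
    M = np.zeros((p, n, n))
    R = np.zeros((p, n, n))
    for df, target, a, b in ((flows, M, "origin", "destination"),
                             (return_flows, R, "residence", "origin")):
        unknown = set()
        for row in df.itertuples():
            ai, bi = getattr(row, a), getattr(row, b)
            if ai not in index or bi not in index:
                unknown |= {x for x in (ai, bi) if x not in index}
                continue
            if ai == bi:
                continue
            target[pindex[(int(row.period_start), int(row.period_end))],
                   index[ai], index[bi]] += row.flow
        if unknown:
            logger.warning("ignoring flows for unknown countries: %s",
                           sorted(unknown))
    return FlowHistory(countries, tuple(periods), M, R)


def write_flow_history(history: FlowHistory, flows_path, returns_path,
                       include_zeros: bool = True) -> None:
    """Write a FlowHistory back to the two flow-table dialects."""
    n = len(history.countries)
    rows_m, rows_r = [], []
    for p, (start, end) in enumerate(history.periods):
        for i in range(n):
            for j in range(n):
                if i == j:
                    continue
                if include_zeros or history.M[p, i, j] > 0:
                    rows_m.append((history.countries[i], history.countries[j],
                                   start, end, history.M[p, i, j]))
                if include_zeros or history.R[p, i, j] > 0:
                    rows_r.append((history.countries[i], history.countries[j],
                                   start, end, history.R[p, i, j]))
    pd.DataFrame(rows_m, columns=[
        "origin", "destination", "period_start", "period_end", "flow",
    ]).to_csv(flows_path, index=False)
    pd.DataFrame(rows_r, columns=[
        "residence", "origin", "period_start", "period_end", "flow",
    ]).to_csv(returns_path, index=False)


def read_stocks(
    path,
    panel: CountryPanel | None = None,
    countries: Sequence[str] | None = None,
) -> dict[int, WorldState]:
    """Stock snapshots ``residence,origin,year,stock`` as WorldStates.

    Native populations are taken from the panel when given (zeros
    otherwise, which is sufficient for calibration-only use).
    """
    df = _read_bilateral(path, "residence", "origin", "stock", ["year"])
    if countries is None:
        countries = (panel.countries if panel is not None
                     else tuple(sorted(set(df["residence"]) | set(df["origin"]))))
    countries = tuple(countries)
    index = {c: i for i, c in enumerate(countries)}
    unknown = (set(df["residence"]) | set(df["origin"])) - set(countries)
    if unknown:
        logger.warning("ignoring stocks for unknown countries: %s",
                       sorted(unknown))
    out: dict[int, WorldState] = {}
    n = len(countries)
    for year, grp in df.groupby("year"):
        D = np.zeros((n, n))
        for row in grp.itertuples():
            if row.residence in index and row.origin in index:
                D[index[row.residence], index[row.origin]] = row.stock
        P = (panel.population(int(year)) if panel is not None
             else np.zeros(n))
        out[int(year)] = WorldState(int(year), countries, P, D)
    return out


def write_stocks(stocks: Mapping[int, WorldState], path,
                 include_zeros: bool = False) -> None:
    rows = []
    for year in sorted(stocks):
        s = stocks[year]
        n = len(s.countries)
        for i in range(n):
            for j in range(n):
                if i != j and (include_zeros or s.D[i, j] > 0):
                    rows.append((s.countries[i], s.countries[j], year,
                                 s.D[i, j]))
    pd.DataFrame(rows, columns=["residence", "origin", "year", "stock"]).to_csv(
        path, index=False
    )


# ---------------------------------------------------------------------------
# Summaries, aggregation, comparison
# ---------------------------------------------------------------------------

def write_summary(summary, path, names: Sequence[str] | None = None) -> None:
    """Write an EnsembleSummary (or a tidy stats frame) as tidy CSV."""
    df = summary.to_frame(names) if isinstance(summary, EnsembleSummary) else summary
    df.to_csv(path, index=False)


def read_summary(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in ("series", "year", "stat", "value")
               if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    return df


def read_mapping(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if "country_id" not in df.columns:
        raise ValueError(f"{path}: missing country_id column")
    return df


def aggregate_series(
    summary: EnsembleSummary | Trajectory,
    mapping,
    axis: str = "origin",
    grouping: str = "region",
):
    """Group per-country stock series by region or income group.

    ``axis="origin"`` groups emigrant stocks by where people were born,
    ``axis="destination"`` groups immigrant stocks by where they live.  For
    an :class:`EnsembleSummary` the sums are taken per ensemble sample and a
    new summary of scalar series (one per group) is returned, so quantile
    bands are bands of group totals, not sums of country bands.  For a
    :class:`Trajectory` a tidy frame ``series,year,value`` is returned.
    """
    if axis not in ("origin", "destination"):
        raise ValueError("axis must be 'origin' or 'destination'")
    if isinstance(mapping, pd.DataFrame):
        if grouping not in mapping.columns:
            raise ValueError(f"mapping has no column {grouping!r}")
        mapping = dict(zip(mapping["country_id"], mapping[grouping]))

    countries = (summary.countries if isinstance(summary, EnsembleSummary)
                 else summary.states[0].countries)
    unmapped = [c for c in countries if c not in mapping]
    if unmapped:
        raise ValueError(f"unmapped countries: {unmapped}")
    groups = sorted({mapping[c] for c in countries})
    masks = {
        g: np.array([mapping[c] == g for c in countries]) for g in groups
    }

    if isinstance(summary, Trajectory):
        rows = []
        for s in summary.states:
            vec = (s.stock_by_origin() if axis == "origin"
                   else s.stock_by_destination())
            for g in groups:
                rows.append((f"stock_{axis}_{g}", s.year,
                             float(vec[masks[g]].sum())))
        return pd.DataFrame(rows, columns=["series", "year", "value"])

    name = f"stock_by_{axis}"
    if name not in summary.samples:
        raise ValueError(
            f"summary lacks the per-country series {name!r}; rerun the "
            "ensemble with it enabled"
        )
    arr = summary.samples[name]  # (n_samples, n_years, n_countries)
    samples = {
        f"stock_{axis}_{g}": arr[:, :, masks[g]].sum(axis=2) for g in groups
    }
    return EnsembleSummary(summary.years, countries, samples, summary.seed)


def compare_to_reference(summary, reference: pd.DataFrame) -> pd.DataFrame:
    """Model-vs-observation table over overlapping series and years.

    ``reference`` holds columns ``series,year,observed``.  The result adds
    the model median and interval bounds, the absolute error (median minus
    observed), the relative error (absolute over observed; NaN where the
    observation is zero), indicators for the 50% and 95% bands, and a rank
    by absolute error magnitude at each series' final compared year.
    """
    stats = (summary.to_frame() if isinstance(summary, EnsembleSummary)
             else summary)
    missing = [c for c in ("series", "year", "observed")
               if c not in reference.columns]
    if missing:
        raise ValueError(f"reference is missing columns {missing}")
    wide = stats.pivot_table(index=["series", "year"], columns="stat",
                             values="value").reset_index()
    merged = reference.merge(wide, on=["series", "year"], how="inner")
    if merged.empty:
        raise ValueError("no overlapping (series, year) pairs to compare")
    merged["abs_error"] = merged["median"] - merged["observed"]
    with np.errstate(divide="ignore", invalid="ignore"):
        rel = merged["abs_error"] / merged["observed"]
    merged["rel_error"] = np.where(merged["observed"] != 0, rel, np.nan)
    merged["in_50"] = (merged["observed"] >= merged["q25"]) & (
        merged["observed"] <= merged["q75"]
    )
    merged["in_95"] = (merged["observed"] >= merged["q2.5"]) & (
        merged["observed"] <= merged["q97.5"]
    )
    final = merged.loc[
        merged.groupby("series")["year"].transform("max") == merged["year"],
        ["series", "abs_error"],
    ].copy()
    final["rank_final_abs_error"] = (
        final["abs_error"].abs().rank(ascending=False, method="first")
    )
    merged = merged.merge(final[["series", "rank_final_abs_error"]],
                          on="series", how="left")
    cols = ["series", "year", "observed", "median", "q25", "q75",
            "q2.5", "q97.5", "abs_error", "rel_error", "in_50", "in_95",
            "rank_final_abs_error"]
    return merged[cols].sort_values(["series", "year"]).reset_index(drop=True)
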