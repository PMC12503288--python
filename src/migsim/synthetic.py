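"""Synthetic worlds with known ground-truth flow distributions.

Stands in for the external inputs (bilateral flow estimates, population
prospects, migrant-stock matrices, GDP panels) so calibration, sampling and
evolution are testable offline and closed-loop: generate a world from a
known :class:`FlowDistributionSet`, simulate a flow history, export it in
the same tabular dialects the calibration layer reads, recalibrate, and
compare against the generating truth.

The default truth mirrors the qualitative structure of real-data
calibrations: Jones-Faddy skew-t emigration rates whose medians fall from
0.006 (P1) to 0.001 (P4) and narrow with population size, Weibull-maximum
destination shares increasing strongly with the diaspora bin and weakly
with the GDP-ratio bin, and a tight symmetric Student-t return rate.  The
default emigration shapes are symmetric (see :func:`default_truth`);
:func:`right_skewed_truth` provides the strongly right-skewed variant.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats as st

from .calibration import FittedDistribution, FlowDistributionSet
from .domain import CountryPanel, FlowHistory, PartitionScheme, WorldState
from .evolution import Trajectory, simulate_trajectory
from .sampling import SamplerContext

__all__ = [
    "SyntheticConfig",
    "default_truth",
    "right_skewed_truth",
    "zero_rate_truth",
    "generate_world",
    "generate_flow_history",
    "SyntheticHistory",
]

REGIONS = ("Africa", "Asia", "Europe", "Americas", "Oceania")
INCOME_GROUPS = ("low", "lower_middle", "upper_middle", "high")

EMIGRATION_MEDIANS = {"P1": 0.006, "P2": 0.004, "P3": 0.002, "P4": 0.001}
# medians span orders of magnitude across diaspora bins, the dominant
# destination gradient (roughly proportional to the bin's d so corridors
# grow at comparable relative speed); GDP-ratio factors modulate weakly
SHARE_MEDIANS_BY_D = {"d1": 1e-6, "d2": 1e-5, "d3": 1e-3, "d4": 0.1, "d5": 0.4}
SHARE_G_FACTORS = {"g1": 0.85, "g2": 0.95, "g3": 1.05, "g4": 1.15}


def skew_t_with_median(
    median: float, scale: float, a: float, b: float
) -> FittedDistribution:
    """Jones-Faddy skew-t with its (untruncated) median placed at `median`."""
    m0 = float(st.jf_skew_t.ppf(0.5, a, b))
    return FittedDistribution(
        "jones_faddy_skew_t",
        {"a": a, "b": b, "loc": median - scale * m0, "scale": scale},
    )


def weibull_max_with_median(
    median: float, shape: float = 2.0, rel_scale: float = 0.5
) -> FittedDistribution:
    """Weibull-maximum with median `median`; scale set relative to it."""
    scale = rel_scale * median
    loc = median + scale * float(np.log(2) ** (1.0 / shape))
    return FittedDistribution(
        "weibull_max", {"c": shape, "loc": loc, "scale": scale}
    )


def default_truth(
    scheme: PartitionScheme = PartitionScheme(),
    emigration_shapes: tuple[float, float] = (5.0, 5.0),
    emigration_rel_scale: float = 0.45,
) -> FlowDistributionSet:
    """The standard ground-truth distribution set.

    The default emigration shapes are the symmetric member of the skew-t
    family: medians then survive the 5-year aggregation of the exported
    history unshifted, which is what makes closed-loop median recovery a
    sharp test.  Skew-dependent behaviour is exercised separately via
    :func:`right_skewed_truth`.
    """
    a, b = emigration_shapes
    emigration = {
        label: skew_t_with_median(
            EMIGRATION_MEDIANS[label],
            emigration_rel_scale * EMIGRATION_MEDIANS[label],
            a, b,
        )
        for label in scheme.population_labels
    }
    shares = {
        (g, d): weibull_max_with_median(
            SHARE_MEDIANS_BY_D[d] * SHARE_G_FACTORS[g]
        )
        for g in scheme.gdp_ratio_labels
        for d in scheme.diaspora_labels
    }
    return_rate = FittedDistribution(
        "student_t", {"df": 6.0, "loc": 0.004, "scale": 0.0012}
    )
    return FlowDistributionSet(
        scheme=scheme,
        emigration=emigration,
        shares=shares,
        return_rate=return_rate,
        provenance={"source": "synthetic ground truth"},
    )


def right_skewed_truth(
    scheme: PartitionScheme = PartitionScheme(),
) -> FlowDistributionSet:
    """A strongly right-skewed emigration truth (heavy upper tail), used to
    study the deterministic-vs-stochastic gap."""
    return default_truth(
        scheme, emigration_shapes=(10.0, 2.0), emigration_rel_scale=0.6
    )


def zero_rate_truth(
    scheme: PartitionScheme = PartitionScheme(),
) -> FlowDistributionSet:
    """Truth whose emigration and return rates are exactly zero.

    The rate distributions carry all their mass below zero, so truncation to
    [0, 1] clamps every draw to the boundary and all flows vanish.
    """
    zero = FittedDistribution("normal", {"loc": -0.5, "scale": 0.01})
    truth = default_truth(scheme)
    return FlowDistributionSet(
        scheme=scheme,
        emigration={l: zero for l in scheme.population_labels},
        shares=truth.shares,
        return_rate=zero,
        provenance={"source": "synthetic zero-rate truth"},
    )


# ---------------------------------------------------------------------------
# World generation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for the synthetic world.

    Populations are stratified round-robin across the population bins and
    drawn log-uniformly within each bin (clipped to ``population_range`` and
    kept ``bin_margin`` away from interior edges), so every bin is covered
    whenever ``n_countries`` is at least the number of bins.  Initial stocks
    combine a few major corridors per origin (diaspora covariate drawn from
    ``major_diaspora_range``, destinations chosen preferentially by size)
    with a sparse background of minor corridors
    (``minor_diaspora_range``); together they span all diaspora bins.
    """

    n_countries: int = 40
    start_year: int = 1990
    end_year: int = 2020
    population_range: tuple[float, float] = (1e5, 1e9)
    gdpc_range: tuple[float, float] = (5e2, 1e5)
    birth_rate_range: tuple[float, float] = (0.010, 0.028)
    death_rate_range: tuple[float, float] = (0.006, 0.014)
    stock_sparsity: float = 0.5
    n_major_corridors: int = 3
    extra_majors_per_decade: float = 2.0
    major_diaspora_range: tuple[float, float] = (2e-4, 0.02)
    minor_diaspora_range: tuple[float, float] = (1e-8, 1e-3)
    minor_presence_exponent: float = 0.25
    bin_margin: float = 2.5
    max_immigrant_share: float = 0.2
    pair_stock_cap: float = 0.05
    seed: int = 0
    scheme: PartitionScheme = field(default_factory=PartitionScheme)


def _log_uniform(rng: np.random.Generator, lo: float, hi: float, size) -> np.ndarray:
    return np.exp(rng.uniform(np.log(lo), np.log(hi), size=size))


def generate_world(cfg: SyntheticConfig) -> tuple[CountryPanel, WorldState]:
    """Generate a country panel and an initial world state.

    The panel's populations are a pure natural-change projection of the
    start-year populations; :func:`generate_flow_history` replaces them with
    the realized simulated populations so that calibration sees covariates
    consistent with the flows.
    """
    scheme = cfg.scheme
    n = cfg.n_countries
    n_bins = len(scheme.population_labels)
    if n < n_bins:
        uncovered = scheme.population_labels[n:]
        raise ValueError(
            f"n_countries={n} cannot cover population bins {list(uncovered)}"
        )
    rng = np.random.default_rng(cfg.seed)
    countries = tuple(f"C{i:03d}" for i in range(n))

    lo, hi = cfg.population_range
    edges = (0.0,) + tuple(scheme.population_edges) + (np.inf,)
    P0 = np.empty(n)
    for i in range(n):
        b = i % n_bins
        # stay clear of interior bin edges so natural change and migration
        # cannot move a country out of its assigned bin over the horizon
        blo = max(edges[b], lo) if edges[b] > 0 else lo
        bhi = min(edges[b + 1], hi)
        if np.isfinite(edges[b + 1]):
            bhi = edges[b + 1] / cfg.bin_margin
        if edges[b] > 0:
            blo = edges[b] * cfg.bin_margin
        if not blo < bhi:
            raise ValueError(
                f"population_range {cfg.population_range} cannot cover bin "
                f"{scheme.population_labels[b]}"
            )
        P0[i] = _log_uniform(rng, blo, bhi, None)

    gdpc = _log_uniform(rng, *cfg.gdpc_range, n)
    cb = rng.uniform(*cfg.birth_rate_range, size=n)
    cd = rng.uniform(*cfg.death_rate_range, size=n)
    c = cb - cd

    years = np.arange(cfg.start_year, cfg.end_year + 1)
    rows = []
    for i, cid in enumerate(countries):
        for t, year in enumerate(years):
            rows.append((
                cid, int(year), P0[i] * (1.0 + c[i]) ** t, c[i], cb[i], cd[i],
                gdpc[i], REGIONS[i % len(REGIONS)],
                INCOME_GROUPS[i % len(INCOME_GROUPS)],
            ))
    panel = CountryPanel(pd.DataFrame(rows, columns=[
        "country_id", "year", "population", "natural_change_rate",
        "birth_rate", "death_rate", "gdpc", "region", "income_group",
    ]))

    # Initial stocks D[j, i] = d_ij * P_i: each origin holds a few dominant
    # corridors toward preferentially large destinations (real diasporas
    # concentrate where earlier migrants settled, mostly populous countries)
    # plus a sparse background of small corridors.  d_ij spans all bins.
    d_matrix = np.zeros((n, n))  # [origin, destination]
    for i in range(n):
        others = np.delete(np.arange(n), i)
        weights = P0[others] / P0[others].sum()
        # larger origins maintain more substantial corridors: their diasporas
        # are absolutely larger and spread over more destinations, which also
        # keeps raw share sums near 1 across origin sizes
        k = cfg.n_major_corridors + cfg.extra_majors_per_decade * max(
            np.log10(P0[i] / cfg.population_range[0]), 0.0
        )
        k = min(int(round(k)), n - 1)
        majors = rng.choice(others, size=k, replace=False, p=weights)
        d_matrix[i, majors] = _log_uniform(rng, *cfg.major_diaspora_range, k)
        # minor corridors exist preferentially toward larger destinations;
        # most corridors into tiny countries carry no stock at all
        presence = cfg.stock_sparsity * (P0 / P0.max()) ** cfg.minor_presence_exponent
        minor = rng.random(n) < presence
        minor[i] = False
        minor[majors] = False
        d_matrix[i, minor] = _log_uniform(
            rng, *cfg.minor_diaspora_range, int(minor.sum())
        )
    D = (d_matrix * P0[:, None]).T
    # bound stocks by destination size — per corridor and in total — as in
    # real stock data (a small country cannot host a huge diaspora); drop
    # sub-person remnants, which integer-valued stock data records as zero
    D = np.minimum(D, cfg.pair_stock_cap * P0[:, None])
    totals = D.sum(axis=1)
    cap = cfg.max_immigrant_share * P0
    over = totals > cap
    D[over] *= (cap[over] / totals[over])[:, None]
    D[D < 1.0] = 0.0
    initial = WorldState(cfg.start_year, countries, P0, D)

    covered = set(scheme.population_bin(P0).tolist())
    missing = [scheme.population_labels[b] for b in range(n_bins)
               if b not in covered]
    if missing:
        raise ValueError(f"generated world does not cover bins {missing}")
    return panel, initial


# ---------------------------------------------------------------------------
# Flow-history generation (closed-loop oracle)
# ---------------------------------------------------------------------------

@dataclass
class SyntheticHistory:
    """A simulated world together with its exported calibration inputs."""

    panel: CountryPanel          # populations replaced by realized values
    initial: WorldState
    truth: FlowDistributionSet
    trajectory: Trajectory
    history: FlowHistory         # 5-year aggregated M and R
    stocks: dict[int, WorldState]  # snapshots at period boundaries


def generate_flow_history(
    panel: CountryPanel,
    initial: WorldState,
    truth: FlowDistributionSet,
    periods: Sequence[tuple[int, int]] | None = None,
    seed: int = 0,
    period_length: int = 5,
    burn_in_years: int = 100,
) -> SyntheticHistory:
    """Forward-simulate with the truth set and export calibration inputs.

    Yearly flows are summed within each period (the granularity of the
    canonical source data); stock snapshots are taken at period boundaries;
    the returned panel carries the realized native populations so that
    emigration rates recomputed from the export refer to the same
    denominators that produced the flows.

    Before the recorded window the stock matrix is burned in for
    ``burn_in_years`` under the truth dynamics (with native populations
    rescaled back to their designed values afterwards), so that corridors
    enter the window with the long accumulation history real stock data
    embodies rather than ramping up from a cold start.
    """
    if burn_in_years > 0:
        base = panel.df[panel.df["year"] == initial.year]
        frames = []
        for k in range(burn_in_years + 1):
            f = base.copy()
            f["year"] = initial.year - burn_in_years + k
            frames.append(f)
        burn_panel = CountryPanel(pd.concat(frames, ignore_index=True))
        burn_seed = int(np.random.SeedSequence([seed, 7]).generate_state(1)[0]
                        % (2 ** 31))
        burn_start = WorldState(
            initial.year - burn_in_years, initial.countries,
            initial.P, initial.D,
        )
        btraj = simulate_trajectory(
            burn_start, burn_panel, truth, burn_in_years,
            SamplerContext.from_seed(burn_seed),
        )
        final = btraj.states[-1]
        # keep the designed native populations; rescale each origin's
        # stocks so the diaspora covariates carry over
        scale = np.where(final.P > 0, initial.P / final.P, 1.0)
        initial = WorldState(
            initial.year, initial.countries, initial.P,
            final.D * scale[None, :],
        )
    if periods is None:
        starts = range(initial.year, int(panel.years.max()), period_length)
        periods = [(s, min(s + period_length, int(panel.years.max())))
                   for s in starts]
    periods = [(int(a), int(b)) for a, b in periods]
    horizon = periods[-1][1] - initial.year
    ctx = SamplerContext.from_seed(seed)
    traj = simulate_trajectory(initial, panel, truth, horizon, ctx, seed=seed)

    n = len(initial.countries)
    M5 = np.zeros((len(periods), n, n))
    R5 = np.zeros((len(periods), n, n))
    year0 = initial.year
    for p, (start, end) in enumerate(periods):
        for y in range(start, end):
            f = traj.flows[y - year0]
            M5[p] += f.M
            R5[p] += f.R
    history = FlowHistory(initial.countries, tuple(periods), M5, R5)

    boundaries = sorted({p[0] for p in periods} | {periods[-1][1]})
    # exported stock snapshots are integer-valued, as real stock data is:
    # sub-person corridor remnants are recorded as zero
    stocks = {}
    for y in boundaries:
        s = traj.states[y - year0]
        stocks[int(y)] = WorldState(
            s.year, s.countries, s.P, np.rint(s.D)
        )

    realized = panel.df.copy()
    pop = {
        (c, s.year): s.P[i]
        for s in traj.states
        for i, c in enumerate(initial.countries)
    }
    key = list(zip(realized["country_id"], realized["year"]))
    realized["population"] = [
        pop.get(k, p) for k, p in zip(key, realized["population"])
    ]
    return SyntheticHistory(
        panel=CountryPanel(realized),
        initial=initial,
        truth=truth,
        trajectory=traj,
        history=history,
        stocks=stocks,
    )
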