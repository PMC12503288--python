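"""Demographic accounting dynamics and Monte-Carlo ensembles.

One yearly step draws all flows from the state at time t and applies them
simultaneously:

    P_i(t+1) = (P_i - sum_l M_il) * (1 + c_i) + sum_l R_li + sum_l B_il
    D_ik(t+1) = D_ik * (1 - c_death_k) - R_ik + M_ki

where M is emigration [origin, destination], R return flows
[residence, origin], and B births from migrant stocks into the residence
country's native population.  Migration inflows are not rescaled by births
or deaths within the step.  With all natural rates zero the step conserves
total persons exactly.

Ensembles run ``n_samples`` independent stochastic trajectories from
per-sample seeds spawned from one master seed, then summarize each output
series by its yearly median and central 50% / 95% prediction intervals.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .calibration import FlowDistributionSet
from .domain import CountryPanel, FlowMatrices, WorldState
from .sampling import (
    SamplerContext,
    birth_flows,
    sample_emigration_rates,
    sample_return_flows,
    sample_share_matrix,
)

logger = logging.getLogger(__name__)

__all__ = [
    "step",
    "apply_flows",
    "Trajectory",
    "simulate_trajectory",
    "deterministic_run",
    "EnsembleSummary",
    "run_ensemble",
    "convergence_diagnostic",
    "DEFAULT_SERIES",
]

QUANTILE_STATS = {
    "median": 0.5,
    "q25": 0.25,
    "q75": 0.75,
    "q2.5": 0.025,
    "q97.5": 0.975,
}


def apply_flows(
    state: WorldState,
    flows: FlowMatrices,
    c: np.ndarray,
    c_death: np.ndarray,
) -> tuple[WorldState, int]:
    """Advance one year given already-drawn flows; returns the new state and
    the number of entries clamped at zero."""
    P, D = state.P, state.D
    M, R, B = flows.M, flows.R, flows.B
    newP = (P - M.sum(axis=1)) * (1.0 + c) + R.sum(axis=0) + B.sum(axis=1)
    newD = D * (1.0 - c_death[None, :]) - R + M.T
    np.fill_diagonal(newD, 0.0)
    clamped = int((newP < 0).sum() + (newD < 0).sum())
    if clamped:
        logger.warning("clamped %d negative entries at year %d",
                       clamped, state.year)
        newP = np.maximum(newP, 0.0)
        newD = np.maximum(newD, 0.0)
    return WorldState(state.year + 1, state.countries, newP, newD), clamped


def step(
    state: WorldState,
    panel: CountryPanel,
    dists: FlowDistributionSet,
    ctx: SamplerContext,
) -> tuple[WorldState, FlowMatrices]:
    """Draw all flows from the state at t and apply them simultaneously."""
    if tuple(panel.countries) != tuple(state.countries):
        raise ValueError("panel countries differ from state countries")
    year = state.year
    c = panel.natural_change(year)
    cd = panel.death_rate(year)
    gdpc = panel.gdpc(year)

    rates = sample_emigration_rates(state.P, dists, ctx)
    shares = sample_share_matrix(state, gdpc, dists, ctx)
    M = state.P[:, None] * rates[:, None] * shares
    np.fill_diagonal(M, 0.0)
    R = sample_return_flows(state, dists, ctx)
    B = birth_flows(state, panel)
    flows = FlowMatrices(M, R, B)
    new_state, _ = apply_flows(state, flows, c, cd)
    return new_state, flows


@dataclass
class Trajectory:
    """One simulated path: states per year plus the flows that produced
    each transition (``len(states) == len(flows) + 1``)."""

    states: list[WorldState]
    flows: list[FlowMatrices]
    mode: str
    seed: int | None = None

    @property
    def years(self) -> np.ndarray:
        return np.array([s.year for s in self.states])

    def series(self, fn: Callable[[WorldState], float]) -> np.ndarray:
        return np.array([fn(s) for s in self.states])

    def replay(self, panel: CountryPanel) -> list[WorldState]:
        """Recompute the states from the recorded flows (consistency check)."""
        out = [self.states[0]]
        for flows in self.flows:
            s = out[-1]
            new, _ = apply_flows(
                s, flows, panel.natural_change(s.year), panel.death_rate(s.year)
            )
            out.append(new)
        return out


def simulate_trajectory(
    initial: WorldState,
    panel: CountryPanel,
    dists: FlowDistributionSet,
    horizon: int,
    ctx: SamplerContext,
    seed: int | None = None,
) -> Trajectory:
    """Repeated application of :func:`step` over ``horizon`` years."""
    if horizon < 0:
        raise ValueError("horizon must be >= 0")
    needed = range(initial.year, initial.year + horizon)
    if not panel.covers(needed):
        raise KeyError(
            f"panel does not cover years {initial.year}.."
            f"{initial.year + horizon - 1}"
        )
    states = [initial.copy()]
    flows: list[FlowMatrices] = []
    for _ in range(horizon):
        new_state, f = step(states[-1], panel, dists, ctx)
        states.append(new_state)
        flows.append(f)
    return Trajectory(states, flows, mode=ctx.mode, seed=seed)


def deterministic_run(
    initial: WorldState,
    panel: CountryPanel,
    dists: FlowDistributionSet,
    horizon: int,
) -> Trajectory:
    """Median-substitution variant: every draw replaced by its distribution's
    truncated median; reproducible without a seed."""
    ctx = SamplerContext(mode="deterministic")
    return simulate_trajectory(initial, panel, dists, horizon, ctx)


# ---------------------------------------------------------------------------
# Ensembles
# ---------------------------------------------------------------------------

DEFAULT_SERIES: dict[str, Callable[[WorldState], np.ndarray | float]] = {
    "total_population": lambda s: s.total_population,
    "total_migrant_stock": lambda s: s.total_migrant_stock,
    "stock_by_origin": lambda s: s.stock_by_origin(),
    "stock_by_destination": lambda s: s.stock_by_destination(),
}


@dataclass
class EnsembleSummary:
    """Per-series Monte-Carlo samples and their quantile bands.

    ``samples[name]`` has shape (n_samples, n_years) for scalar series or
    (n_samples, n_years, n_countries) for per-country series.  Quantiles are
    computed on demand so aggregated series can be summarized the same way.
    """

    years: np.ndarray
    countries: tuple[str, ...]
    samples: dict[str, np.ndarray]
    seed: int | None = None

    @property
    def n_samples(self) -> int:
        return next(iter(self.samples.values())).shape[0]

    def subset(self, n: int) -> "EnsembleSummary":
        """Summary over the first ``n`` samples (nested-prefix diagnostics)."""
        if not 1 <= n <= self.n_samples:
            raise ValueError(f"n must be in [1, {self.n_samples}]")
        return EnsembleSummary(
            self.years, self.countries,
            {k: v[:n] for k, v in self.samples.items()}, self.seed,
        )

    def quantiles(self, name: str) -> pd.DataFrame:
        """Tidy frame ``series, year, stat, value`` for a scalar series."""
        arr = self.samples[name]
        if arr.ndim != 2:
            raise ValueError(
                f"{name!r} is a per-country series; aggregate it first"
            )
        rows = []
        for stat, q in QUANTILE_STATS.items():
            vals = np.quantile(arr, q, axis=0)
            for year, v in zip(self.years, vals):
                rows.append((name, int(year), stat, float(v)))
        return pd.DataFrame(rows, columns=["series", "year", "stat", "value"])

    def band(self, name: str) -> dict[str, np.ndarray]:
        """Quantile arrays (one value per year) for a scalar series."""
        arr = self.samples[name]
        return {
            stat: np.quantile(arr, q, axis=0)
            for stat, q in QUANTILE_STATS.items()
        }

    def to_frame(self, names: Sequence[str] | None = None) -> pd.DataFrame:
        names = names or [
            k for k, v in self.samples.items() if v.ndim == 2
        ]
        return pd.concat(
            [self.quantiles(n) for n in names], ignore_index=True
        )


def run_ensemble(
    initial: WorldState,
    panel: CountryPanel,
    dists: FlowDistributionSet,
    horizon: int,
    n_samples: int,
    seed: int,
    series: Mapping[str, Callable[[WorldState], np.ndarray | float]] | None = None,
) -> EnsembleSummary:
    """Monte-Carlo ensemble of independent stochastic trajectories.

    Sample ``k`` uses a child seed spawned deterministically from the master
    seed, so results are reproducible and independent of evaluation order.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    series = dict(series) if series is not None else dict(DEFAULT_SERIES)
    child_seeds = np.random.SeedSequence(seed).spawn(n_samples)
    collected: dict[str, list[np.ndarray]] = {k: [] for k in series}
    for k in range(n_samples):
        ctx = SamplerContext(rng=np.random.default_rng(child_seeds[k]))
        traj = simulate_trajectory(initial, panel, dists, horizon, ctx)
        for name, fn in series.items():
            collected[name].append(
                np.array([fn(s) for s in traj.states], dtype=float)
            )
    samples = {k: np.stack(v) for k, v in collected.items()}
    years = np.arange(initial.year, initial.year + horizon + 1)
    return EnsembleSummary(years, initial.countries, samples, seed=seed)


def convergence_diagnostic(
    summaries: Sequence[EnsembleSummary],
    series: str = "total_migrant_stock",
) -> pd.DataFrame:
    """Horizon-year median of a series at increasing sample sizes.

    Takes summaries ordered by ascending ``n_samples`` (typically nested
    prefixes of one large ensemble, see :meth:`EnsembleSummary.subset`) and
    reports successive absolute differences of the medians.
    """
    if len(summaries) < 2:
        raise ValueError("need at least two sample sizes")
    ns = [s.n_samples for s in summaries]
    if ns != sorted(ns):
        raise ValueError("summaries must be ordered by ascending n_samples")
    medians = [
        float(np.quantile(s.samples[series][:, -1], 0.5)) for s in summaries
    ]
    diffs = [np.nan] + [
        abs(m2 - m1) for m1, m2 in zip(medians[:-1], medians[1:])
    ]
    return pd.DataFrame(
        {"n_samples": ns, "median": medians, "abs_diff": diffs}
    )
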