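"""Drawing migration flows from calibrated distributions.

Every stochastic quantity (emigration rate per origin, destination share per
ordered pair, return rate per residence-origin pair) is drawn independently
once per simulated year from the fitted distribution of its partition cell,
truncated to [0, 1] by rejection sampling (falling back to clamping after a
bounded number of rounds, so heavy tails keep their shape on the valid
support).  In deterministic mode every draw is replaced by the median of the
truncated distribution.  Birth flows are deterministic in both modes: the
stock times the origin country's birth rate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .calibration import FittedDistribution, FlowDistributionSet, bilateral_diaspora
from .domain import CountryPanel, PartitionScheme, WorldState

logger = logging.getLogger(__name__)

__all__ = [
    "SamplerContext",
    "sample_emigration_rate",
    "sample_emigration_rates",
    "sample_destination_shares",
    "sample_share_matrix",
    "bilateral_flows",
    "sample_return_flows",
    "birth_flows",
]

MODES = ("stochastic", "deterministic")


@dataclass
class SamplerContext:
    """Random state, mode, and truncation policy for one simulation run.

    Identical seed + inputs + mode give bit-identical draws; deterministic
    mode needs no seed at all.
    """

    rng: np.random.Generator = field(
        default_factory=lambda: np.random.default_rng(0)
    )
    mode: str = "stochastic"
    max_rejection_rounds: int = 1000

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}, got {self.mode!r}")

    @classmethod
    def from_seed(cls, seed, mode: str = "stochastic") -> "SamplerContext":
        return cls(rng=np.random.default_rng(seed), mode=mode)

    @property
    def deterministic(self) -> bool:
        return self.mode == "deterministic"


def _draw_truncated(
    dist: FittedDistribution,
    size: int,
    ctx: SamplerContext,
    lo: float = 0.0,
    hi: float = 1.0,
) -> np.ndarray:
    """Rejection-sample `size` values from `dist` restricted to [lo, hi]."""
    frozen = dist.frozen()
    out = np.asarray(frozen.rvs(size=size, random_state=ctx.rng), dtype=float)
    bad = (out < lo) | (out > hi)
    rounds = 0
    while bad.any() and rounds < ctx.max_rejection_rounds:
        out[bad] = frozen.rvs(size=int(bad.sum()), random_state=ctx.rng)
        bad = (out < lo) | (out > hi)
        rounds += 1
    if bad.any():
        logger.warning(
            "clamping %d draws from %s after %d rejection rounds",
            int(bad.sum()), dist.family, rounds,
        )
        np.clip(out, lo, hi, out=out)
    return out


# ---------------------------------------------------------------------------
# Emigration rates
# ---------------------------------------------------------------------------

def sample_emigration_rates(
    P: np.ndarray,
    dists: FlowDistributionSet,
    ctx: SamplerContext,
) -> np.ndarray:
    """One yearly emigration rate per country, grouped by population bin."""
    P = np.asarray(P, dtype=float)
    scheme = dists.scheme
    bins = scheme.population_bin(P)
    rates = np.empty_like(P)
    for b, label in enumerate(scheme.population_labels):
        mask = bins == b
        if not mask.any():
            continue
        dist = dists.emigration[label]
        if ctx.deterministic:
            rates[mask] = dist.truncated_median()
        else:
            rates[mask] = _draw_truncated(dist, int(mask.sum()), ctx)
    return rates


def sample_emigration_rate(
    P: float, dists: FlowDistributionSet, ctx: SamplerContext
) -> float:
    """Single-country convenience wrapper around the vectorized sampler."""
    return float(sample_emigration_rates(np.array([P]), dists, ctx)[0])


# ---------------------------------------------------------------------------
# Destination shares
# ---------------------------------------------------------------------------

def _raw_share_matrix(
    state: WorldState,
    gdpc: np.ndarray,
    dists: FlowDistributionSet,
    ctx: SamplerContext,
) -> np.ndarray:
    """Raw (un-normalized) share draws for every ordered pair."""
    scheme = dists.scheme
    n = len(state.countries)
    with np.errstate(divide="ignore", invalid="ignore"):
        g = gdpc[:, None] / gdpc[None, :]
    d = bilateral_diaspora(state.D, state.P, dists.diaspora_mode)
    off = ~np.eye(n, dtype=bool)
    gbin = np.zeros((n, n), dtype=int)
    dbin = np.zeros((n, n), dtype=int)
    gbin[off] = scheme.gdp_ratio_bin(g[off])
    dbin[off] = scheme.diaspora_bin(d[off])
    raw = np.zeros((n, n))
    for gi, gl in enumerate(scheme.gdp_ratio_labels):
        for di, dl in enumerate(scheme.diaspora_labels):
            mask = off & (gbin == gi) & (dbin == di)
            cnt = int(mask.sum())
            if not cnt:
                continue
            dist = dists.share_for(gl, dl)
            if ctx.deterministic:
                raw[mask] = dist.truncated_median()
            else:
                raw[mask] = _draw_truncated(dist, cnt, ctx)
    return raw


def _renormalize_rows(raw: np.ndarray) -> np.ndarray:
    """Uniformly renormalize each row to sum to 1; degenerate all-zero rows
    become uniform over off-diagonal entries (logged)."""
    n = raw.shape[0]
    off = ~np.eye(n, dtype=bool)
    raw = np.where(off, raw, 0.0)
    sums = raw.sum(axis=1, keepdims=True)
    zero_rows = sums[:, 0] <= 0
    if zero_rows.any():
        logger.warning(
            "uniform shares for %d origins with all-zero raw draws",
            int(zero_rows.sum()),
        )
        raw[zero_rows] = off[zero_rows] / max(n - 1, 1)
        sums = raw.sum(axis=1, keepdims=True)
    return raw / sums


def sample_share_matrix(
    state: WorldState,
    gdpc: np.ndarray,
    dists: FlowDistributionSet,
    ctx: SamplerContext,
) -> np.ndarray:
    """Matrix of destination shares; each row sums to 1, zero diagonal."""
    return _renormalize_rows(_raw_share_matrix(state, gdpc, dists, ctx))


def sample_destination_shares(
    origin: int | str,
    state: WorldState,
    panel: CountryPanel,
    dists: FlowDistributionSet,
    ctx: SamplerContext,
    scheme: PartitionScheme | None = None,
) -> np.ndarray:
    """Normalized share vector over destinations for one origin country."""
    if scheme is not None and scheme != dists.scheme:
        raise ValueError("scheme differs from the calibrated scheme")
    i = (state.countries.index(origin) if isinstance(origin, str) else origin)
    if len(state.countries) < 2:
        raise ValueError("need at least one destination country")
    gdpc = panel.gdpc(state.year)
    shares = sample_share_matrix(state, gdpc, dists, ctx)[i]
    return shares


# ---------------------------------------------------------------------------
# Flow computation
# ---------------------------------------------------------------------------

def bilateral_flows(
    P_i: float, rate: float, shares: np.ndarray
) -> np.ndarray:
    """Bilateral outflows ``M_ij = P_i * rate * share_j`` (persons)."""
    shares = np.asarray(shares, dtype=float)
    if not 0 <= rate <= 1:
        raise ValueError("rate must lie in [0, 1]")
    if shares.size and abs(shares.sum() - 1.0) > 1e-9:
        raise ValueError("shares must sum to 1")
    return P_i * rate * shares


def sample_return_flows(
    state: WorldState,
    dists: FlowDistributionSet,
    ctx: SamplerContext,
) -> np.ndarray:
    """Return flows ``R = D * r`` with one rate draw per occupied pair.

    Deterministic mode uses the return distribution's truncated median for
    every pair, so ``R / D`` is constant across occupied pairs.
    """
    D = state.D
    R = np.zeros_like(D)
    occupied = D > 0
    if ctx.deterministic:
        R[occupied] = D[occupied] * dists.return_rate.truncated_median()
    elif occupied.any():
        r = _draw_truncated(dists.return_rate, int(occupied.sum()), ctx)
        R[occupied] = D[occupied] * r
    return R


def birth_flows(state: WorldState, panel: CountryPanel) -> np.ndarray:
    """Births from migrant stocks into the residence country's natives:
    ``B[i, l] = D[i, l] * c_birth_l`` — no random component."""
    cb = panel.birth_rate(state.year)
    return state.D * cb[None, :]
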