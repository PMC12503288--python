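"""Calibration of partitioned flow-probability distributions.

Bilateral 5-year flow tables are turned into labeled samples of yearly rates
and shares:

* total emigration rates per origin-period, labeled by the origin's
  population bin (P1..P4);
* destination shares ``m_ij = M_ij / M_i`` per ordered country pair, labeled
  by the GDPc-ratio bin and the diaspora bin of the pair;
* return rates ``R_ik / D_ik`` pooled into a single unpartitioned sample
  (they are tightly concentrated, so no partition is needed); 5-year return
  rates above 100% are discarded as data artifacts.

Each labeled sample is fitted by maximum likelihood to a location-scale
family — Jones-Faddy skew-t for emigration rates, Weibull-maximum for
destination shares, Student's t for return rates — and candidate families can
be ranked by the sum of squared errors between the fitted density and the
sample histogram.  Share cells with too few observations fall back to the
distribution pooled over GDP-ratio bins at the same diaspora bin (diaspora
dominates destination choice), then to the global pool.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import scipy.stats as st

from .domain import (
    CountryPanel,
    FlowHistory,
    PartitionScheme,
    WorldState,
    rescale_five_year_rate,
)

logger = logging.getLogger(__name__)

__all__ = [
    "Family",
    "FAMILIES",
    "LabeledSamples",
    "FittedDistribution",
    "FlowDistributionSet",
    "CalibrationConfig",
    "build_emigration_rate_samples",
    "build_share_samples",
    "build_return_rate_samples",
    "fit_distribution",
    "rank_families",
    "calibrate_model",
]


# ---------------------------------------------------------------------------
# Candidate distribution families
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Family:
    """A scipy location-scale family plus multi-start MLE settings."""

    name: str
    dist: st.rv_continuous
    shape_names: tuple[str, ...]
    shape_starts: tuple[tuple[float, ...], ...]

    @property
    def n_params(self) -> int:
        return 2 + len(self.shape_names)


FAMILIES: dict[str, Family] = {
    f.name: f
    for f in (
        Family("jones_faddy_skew_t", st.jf_skew_t, ("a", "b"),
               ((1.0, 1.0), (2.0, 2.0), (4.0, 4.0), (8.0, 4.0), (4.0, 8.0))),
        Family("weibull_max", st.weibull_max, ("c",),
               ((1.5,), (2.5,), (4.0,))),
        Family("student_t", st.t, ("df",), ((2.0,), (5.0,), (20.0,))),
        Family("normal", st.norm, (), ((),)),
    )
}


# ---------------------------------------------------------------------------
# Samples and fitted distributions
# ---------------------------------------------------------------------------

@dataclass
class LabeledSamples:
    """Observations (rates or shares in [0, 1]) belonging to one partition
    cell, plus the count of records discarded while building them."""

    values: np.ndarray
    label: str
    n_discarded: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.size and (
            np.any(self.values < 0) or np.any(self.values > 1)
        ):
            raise ValueError(f"samples for {self.label!r} outside [0, 1]")

    @property
    def n(self) -> int:
        return int(self.values.size)


@dataclass
class FittedDistribution:
    """A fitted location-scale distribution with its goodness score."""

    family: str
    params: dict[str, float]
    sse: float = math.nan
    n_fit: int = 0
    _cache: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")
        fam = FAMILIES[self.family]
        expected = set(fam.shape_names) | {"loc", "scale"}
        if set(self.params) != expected:
            raise ValueError(
                f"{self.family} expects parameters {sorted(expected)}, "
                f"got {sorted(self.params)}"
            )
        if not all(np.isfinite(v) for v in self.params.values()):
            raise ValueError("non-finite parameters")
        if self.params["scale"] <= 0:
            raise ValueError("scale must be > 0")

    def frozen(self):
        """The frozen scipy distribution (cached)."""
        if "frozen" not in self._cache:
            fam = FAMILIES[self.family]
            shapes = [self.params[s] for s in fam.shape_names]
            self._cache["frozen"] = fam.dist(
                *shapes, loc=self.params["loc"], scale=self.params["scale"]
            )
        return self._cache["frozen"]

    def median(self) -> float:
        return float(self.frozen().median())

    def truncated_median(self, lo: float = 0.0, hi: float = 1.0) -> float:
        """Median of the distribution truncated to [lo, hi] (cached)."""
        key = ("tmed", lo, hi)
        if key not in self._cache:
            fr = self.frozen()
            f0, f1 = fr.cdf(lo), fr.cdf(hi)
            if f1 <= f0:  # no mass on [lo, hi]: nearest endpoint
                med = lo if fr.cdf(lo) >= 0.5 else hi
            else:
                med = fr.ppf(0.5 * (f0 + f1))
            self._cache[key] = float(np.clip(med, lo, hi))
        return self._cache[key]

    def density_integral(self) -> float:
        """Numerical integral of the pdf over its support (should be 1)."""
        from scipy.integrate import quad

        fr = self.frozen()
        lo, hi = fr.support()
        val, _ = quad(fr.pdf, lo, hi, limit=200)
        return float(val)

    def to_dict(self) -> dict:
        return {
            "family": self.family,
            "params": {k: float(v) for k, v in self.params.items()},
            "sse": None if math.isnan(self.sse) else float(self.sse),
            "n_fit": int(self.n_fit),
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "FittedDistribution":
        sse = d.get("sse")
        return cls(
            family=d["family"],
            params=dict(d["params"]),
            sse=math.nan if sse is None else float(sse),
            n_fit=int(d.get("n_fit", 0)),
        )


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

def _histogram_sse(values: np.ndarray, fitted, bins: int) -> float:
    """SSE between the sample histogram density and the fitted density,
    evaluated at bin centers of `bins` equal-width bins."""
    hist, edges = np.histogram(values, bins=bins, density=True)
    centers = 0.5 * (edges[:-1] + edges[1:])
    pdf = fitted.pdf(centers)
    pdf = np.where(np.isfinite(pdf), pdf, 0.0)
    return float(np.sum((hist - pdf) ** 2))


def fit_distribution(
    samples: LabeledSamples,
    family: str,
    min_n: int = 30,
    bins: int = 100,
) -> FittedDistribution | None:
    """Maximum-likelihood fit of one family to one labeled sample.

    Returns ``None`` when there are fewer than ``min_n`` observations (the
    caller then applies its fallback policy).  The optimizer is started from
    a small grid of shape values with location/scale initialized from the
    sample median and standard deviation; the start with the best likelihood
    wins.  Raises ``ValueError`` on degenerate (zero-variance) samples or if
    no start converges.
    """
    fam = FAMILIES[family]
    x = np.asarray(samples.values, dtype=float)
    if x.size < min_n:
        return None
    if np.ptp(x) == 0:
        raise ValueError(
            f"degenerate sample for {samples.label!r}: all values equal {x[0]}"
        )

    loc0 = float(np.median(x))
    scale0 = float(np.std(x))
    if fam.dist is st.weibull_max:
        # support is (-inf, loc]; the location start must sit above the data
        loc0 = float(x.max()) + 0.1 * scale0

    candidates: list[tuple[float, tuple[float, ...]]] = []
    failures: list[str] = []
    starts: list[tuple] = [
        shapes + (loc0, scale0) for shapes in fam.shape_starts
    ]
    starts.append(None)  # scipy's internal default start
    for start in starts:
        try:
            # extreme shape trials can overflow inside the pdf; they are
            # rejected below by the finite-likelihood check
            with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
                if start is None:
                    params = fam.dist.fit(x)
                else:
                    shapes = start[:-2]
                    params = fam.dist.fit(
                        x, *shapes, loc=start[-2], scale=start[-1]
                    )
                nll = fam.dist.nnlf(params, x)
            if not np.isfinite(nll) or params[-1] <= 0:
                raise RuntimeError(f"non-finite likelihood at start {start}")
            candidates.append((float(nll), tuple(map(float, params))))
        except Exception as exc:  # noqa: BLE001 - collect fit diagnostics
            failures.append(f"start {start}: {exc}")
    if not candidates:
        raise ValueError(
            f"{family} fit failed for {samples.label!r}: " + "; ".join(failures)
        )
    if failures:
        logger.debug("fit %s/%s: %d starts failed (%s)",
                     family, samples.label, len(failures), failures[0])
    _, best = min(candidates, key=lambda c: c[0])
    names = fam.shape_names + ("loc", "scale")
    fitted = FittedDistribution(
        family=family,
        params=dict(zip(names, best)),
        n_fit=x.size,
    )
    fitted.sse = _histogram_sse(x, fitted.frozen(), bins)
    return fitted


def rank_families(
    samples: LabeledSamples,
    families: Sequence[str] | None = None,
    bins: int = 100,
    min_n: int = 30,
) -> list[FittedDistribution]:
    """Fit every candidate family and sort by ascending histogram SSE.

    Ties are broken by fewer parameters, then lexical family name.  Raises if
    every candidate fails, naming each family's failure.
    """
    families = list(families) if families is not None else list(FAMILIES)
    fits: list[FittedDistribution] = []
    failures: list[str] = []
    for name in families:
        try:
            fit = fit_distribution(samples, name, min_n=min_n, bins=bins)
        except ValueError as exc:
            failures.append(str(exc))
            continue
        if fit is None:
            failures.append(f"{name}: fewer than {min_n} samples")
        else:
            fits.append(fit)
    if not fits:
        raise ValueError(
            "all candidate fits failed for "
            f"{samples.label!r}: " + "; ".join(failures)
        )
    fits.sort(key=lambda f: (f.sse, FAMILIES[f.family].n_params, f.family))
    return fits


# ---------------------------------------------------------------------------
# Sample builders
# ---------------------------------------------------------------------------

def _aligned_indices(panel: CountryPanel, countries: Sequence[str]) -> np.ndarray:
    try:
        return np.array([panel._index[c] for c in countries])
    except KeyError as exc:
        raise ValueError(f"country {exc.args[0]!r} missing from panel") from None


def build_emigration_rate_samples(
    history: FlowHistory,
    panel: CountryPanel,
    scheme: PartitionScheme = PartitionScheme(),
) -> dict[str, LabeledSamples]:
    """Yearly total-emigration-rate samples keyed by population bin.

    Per origin and period, the 5-year rate is the period's total outflow over
    the origin's native population at the period start; it is rescaled to a
    yearly rate and labeled by the period-start population bin.  Origins with
    zero population are skipped with a warning; rates above 1 are discarded.
    """
    idx = _aligned_indices(panel, history.countries)
    buckets: dict[str, list[float]] = {l: [] for l in scheme.population_labels}
    discarded = {l: 0 for l in scheme.population_labels}
    for p, (start, _end) in enumerate(history.periods):
        P = panel.population(start)[idx]
        totals = history.M[p].sum(axis=1)
        for i, c in enumerate(history.countries):
            if P[i] <= 0:
                logger.warning(
                    "skipping %s in %d: zero origin population", c, start
                )
                continue
            rate5 = totals[i] / P[i]
            label = scheme.population_labels[int(scheme.population_bin(P[i]))]
            if rate5 > 1:
                logger.warning(
                    "discarding %s in %d: 5-year emigration rate %.3f > 1",
                    c, start, rate5,
                )
                discarded[label] += 1
                continue
            buckets[label].append(rescale_five_year_rate(rate5))
    return {
        l: LabeledSamples(np.array(v), l, n_discarded=discarded[l])
        for l, v in buckets.items()
    }


def bilateral_diaspora(
    D: np.ndarray, P: np.ndarray, mode: str = "bilateral"
) -> np.ndarray:
    """Diaspora covariate matrix ``d[i, j]`` for origin i, destination j.

    ``bilateral`` (default): stock of i-born people in j over the origin
    population, ``D[j, i] / P_i`` — distinguishes destinations.
    ``origin_total``: the origin's total emigrant stock over its population,
    constant across destinations.
    """
    with np.errstate(divide="ignore", invalid="ignore"):
        if mode == "bilateral":
            d = D.T / P[:, None]
        elif mode == "origin_total":
            d = np.repeat((D.sum(axis=0) / P)[:, None], len(P), axis=1)
        else:
            raise ValueError(f"unknown diaspora_mode {mode!r}")
    return np.where(np.isfinite(d), d, 0.0)


def build_share_samples(
    history: FlowHistory,
    stocks: Mapping[int, WorldState],
    panel: CountryPanel,
    scheme: PartitionScheme = PartitionScheme(),
    diaspora_mode: str = "bilateral",
) -> dict[tuple[str, str], LabeledSamples]:
    """Destination-share samples keyed by (GDPc-ratio bin, diaspora bin).

    For each origin-period with positive total outflow, each destination's
    share ``M_ij / M_i`` is labeled by the GDPc ratio ``g_i / g_j`` and the
    diaspora covariate at the period start.  Pairs with missing GDPc are
    skipped with a warning.
    """
    idx = _aligned_indices(panel, history.countries)
    n = len(history.countries)
    glabels, dlabels = scheme.gdp_ratio_labels, scheme.diaspora_labels
    buckets: dict[tuple[str, str], list[np.ndarray]] = {
        (g, d): [] for g in glabels for d in dlabels
    }
    for p, (start, _end) in enumerate(history.periods):
        if start not in stocks:
            raise ValueError(f"no stock snapshot for period start {start}")
        state = stocks[start]
        if tuple(state.countries) != tuple(history.countries):
            raise ValueError("stock snapshot countries differ from flow table")
        P = panel.population(start)[idx]
        gdpc = panel._row("gdpc", start, allow_missing=True)[idx]
        Mp = history.M[p]
        totals = Mp.sum(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            g = gdpc[:, None] / gdpc[None, :]
        d = bilateral_diaspora(state.D, P, diaspora_mode)
        valid = (totals[:, None] > 0) & ~np.eye(n, dtype=bool)
        gdp_ok = np.isfinite(g) & (g > 0)
        n_missing = int((valid & ~gdp_ok).sum())
        if n_missing:
            logger.warning(
                "skipping %d pairs in %d: missing GDPc", n_missing, start
            )
        valid &= gdp_ok
        if not valid.any():
            continue
        shares = np.where(valid, Mp / np.where(totals[:, None] > 0,
                                               totals[:, None], 1.0), 0.0)
        gbin = np.zeros_like(g, dtype=int)
        dbin = np.zeros_like(g, dtype=int)
        gbin[valid] = scheme.gdp_ratio_bin(g[valid])
        dbin[valid] = scheme.diaspora_bin(d[valid])
        for gi, gl in enumerate(glabels):
            for di, dl in enumerate(dlabels):
                mask = valid & (gbin == gi) & (dbin == di)
                if mask.any():
                    buckets[(gl, dl)].append(shares[mask])
    return {
        key: LabeledSamples(
            np.concatenate(v) if v else np.empty(0), f"{key[0]}|{key[1]}"
        )
        for key, v in buckets.items()
    }


def build_return_rate_samples(
    history: FlowHistory,
    stocks: Mapping[int, WorldState],
) -> LabeledSamples:
    """One pooled sample of yearly return rates ``R_ik / D_ik``.

    5-year rates above 1 (an artifact of the source estimates) are discarded
    and counted, as are pairs with return flow but no stock.  Pairs with
    positive stock and zero flow contribute a rate of 0.
    """
    values: list[np.ndarray] = []
    n_discarded = 0
    for p, (start, _end) in enumerate(history.periods):
        if start not in stocks:
            raise ValueError(f"no stock snapshot for period start {start}")
        D0 = stocks[start].D
        R5 = history.R[p]
        has_stock = D0 > 0
        orphan = (~has_stock) & (R5 > 0)
        if orphan.any():
            logger.warning(
                "discarding %d return flows with zero stock in %d",
                int(orphan.sum()), start,
            )
            n_discarded += int(orphan.sum())
        rate5 = R5[has_stock] / D0[has_stock]
        over = rate5 > 1
        if over.any():
            logger.warning(
                "discarding %d return rates > 100%% in %d",
                int(over.sum()), start,
            )
            n_discarded += int(over.sum())
        values.append(rescale_five_year_rate(rate5[~over]))
    pooled = np.concatenate(values) if values else np.empty(0)
    return LabeledSamples(pooled, "return", n_discarded=n_discarded)


# ---------------------------------------------------------------------------
# Full calibration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CalibrationConfig:
    """Tunable calibration settings.

    ``exploratory=True`` ranks all candidate families per sample and keeps
    the best; otherwise the canonical families are used (skew-t emigration,
    Weibull-max shares, Student-t returns).
    """

    min_fit: int = 30
    sse_bins: int = 100
    emigration_family: str = "jones_faddy_skew_t"
    share_family: str = "weibull_max"
    return_family: str = "student_t"
    diaspora_mode: str = "bilateral"
    exploratory: bool = False
    candidates: tuple[str, ...] = tuple(FAMILIES)

    def to_dict(self) -> dict:
        return {
            "min_fit": self.min_fit,
            "sse_bins": self.sse_bins,
            "emigration_family": self.emigration_family,
            "share_family": self.share_family,
            "return_family": self.return_family,
            "diaspora_mode": self.diaspora_mode,
            "exploratory": self.exploratory,
            "candidates": list(self.candidates),
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "CalibrationConfig":
        d = dict(d)
        if "candidates" in d:
            d["candidates"] = tuple(d["candidates"])
        return cls(**d)


@dataclass
class FlowDistributionSet:
    """Fitted distributions for every flow type, plus fallback pointers.

    ``emigration`` maps each population bin to its rate distribution;
    ``shares`` maps (g-bin, d-bin) cells to share distributions, with
    ``None`` marking cells that had too little data — ``share_fallbacks``
    then points at an entry of ``pooled_shares`` (``"d:<bin>"`` pools over
    GDP-ratio bins at that diaspora bin, ``"all"`` pools everything).
    """

    scheme: PartitionScheme
    emigration: dict[str, FittedDistribution]
    shares: dict[tuple[str, str], FittedDistribution | None]
    return_rate: FittedDistribution
    pooled_shares: dict[str, FittedDistribution] = field(default_factory=dict)
    share_fallbacks: dict[tuple[str, str], str] = field(default_factory=dict)
    diaspora_mode: str = "bilateral"
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [
            l for l in self.scheme.population_labels if l not in self.emigration
        ]
        if missing:
            raise ValueError(f"emigration distributions missing for {missing}")
        for cell, dist in self.shares.items():
            if dist is None and cell not in self.share_fallbacks:
                raise ValueError(f"empty share cell {cell} has no fallback")
        for cell, key in self.share_fallbacks.items():
            if key not in self.pooled_shares:
                raise ValueError(
                    f"fallback {key!r} for cell {cell} not in pooled_shares"
                )

    def share_for(self, g_label: str, d_label: str) -> FittedDistribution:
        """The share distribution for a cell, resolving fallbacks."""
        cell = (g_label, d_label)
        dist = self.shares.get(cell)
        if dist is not None:
            return dist
        if cell in self.share_fallbacks:
            return self.pooled_shares[self.share_fallbacks[cell]]
        raise KeyError(f"no share distribution for cell {cell}")

    # -- serialization -------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "scheme": self.scheme.to_dict(),
            "diaspora_mode": self.diaspora_mode,
            "emigration": {k: v.to_dict() for k, v in self.emigration.items()},
            "shares": {
                f"{g}|{d}": (v.to_dict() if v is not None else None)
                for (g, d), v in self.shares.items()
            },
            "pooled_shares": {
                k: v.to_dict() for k, v in self.pooled_shares.items()
            },
            "share_fallbacks": {
                f"{g}|{d}": v for (g, d), v in self.share_fallbacks.items()
            },
            "return_rate": self.return_rate.to_dict(),
            "provenance": self.provenance,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "FlowDistributionSet":
        def cell(key: str) -> tuple[str, str]:
            g, _, dd = key.partition("|")
            return (g, dd)

        return cls(
            scheme=PartitionScheme.from_dict(d["scheme"]),
            diaspora_mode=d.get("diaspora_mode", "bilateral"),
            emigration={
                k: FittedDistribution.from_dict(v)
                for k, v in d["emigration"].items()
            },
            shares={
                cell(k): (FittedDistribution.from_dict(v) if v else None)
                for k, v in d["shares"].items()
            },
            pooled_shares={
                k: FittedDistribution.from_dict(v)
                for k, v in d.get("pooled_shares", {}).items()
            },
            share_fallbacks={
                cell(k): v for k, v in d.get("share_fallbacks", {}).items()
            },
            return_rate=FittedDistribution.from_dict(d["return_rate"]),
            provenance=dict(d.get("provenance", {})),
        )

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "FlowDistributionSet":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def _provenance(history: FlowHistory, panel: CountryPanel,
                scheme: PartitionScheme, config: CalibrationConfig) -> dict:
    h = hashlib.sha256()
    h.update(np.ascontiguousarray(history.M).tobytes())
    h.update(np.ascontiguousarray(history.R).tobytes())
    ph = hashlib.sha256(
        panel.df.to_csv(index=False).encode()
    ).hexdigest()
    return {
        "flows_sha256": h.hexdigest(),
        "panel_sha256": ph,
        "scheme": scheme.to_dict(),
        "config": config.to_dict(),
        "periods": [list(p) for p in history.periods],
        "n_countries": len(history.countries),
    }


def calibrate_model(
    history: FlowHistory,
    stocks: Mapping[int, WorldState],
    panel: CountryPanel,
    scheme: PartitionScheme = PartitionScheme(),
    config: CalibrationConfig | None = None,
) -> FlowDistributionSet:
    """Full calibration: build all labeled samples and fit every cell.

    Every population bin must carry at least ``config.min_fit`` emigration
    samples (otherwise the model cannot sample emigration and this is a hard
    error).  Share cells below the threshold are marked empty and wired to
    their fallback distribution.
    """
    config = config or CalibrationConfig()

    def _fit(samples: LabeledSamples, family: str) -> FittedDistribution | None:
        if config.exploratory:
            if samples.n < config.min_fit:
                return None
            return rank_families(
                samples, config.candidates, bins=config.sse_bins,
                min_n=config.min_fit,
            )[0]
        return fit_distribution(
            samples, family, min_n=config.min_fit, bins=config.sse_bins
        )

    # emigration rates, one fit per population bin (all bins mandatory)
    rate_samples = build_emigration_rate_samples(history, panel, scheme)
    emigration: dict[str, FittedDistribution] = {}
    for label, samples in rate_samples.items():
        fit = _fit(samples, config.emigration_family)
        if fit is None:
            raise ValueError(
                f"population bin {label} has {samples.n} emigration samples, "
                f"fewer than min_fit={config.min_fit}; cannot calibrate"
            )
        emigration[label] = fit

    # destination shares per (g, d) cell with pooled fallbacks
    share_samples = build_share_samples(
        history, stocks, panel, scheme, config.diaspora_mode
    )
    shares: dict[tuple[str, str], FittedDistribution | None] = {}
    for cell, samples in share_samples.items():
        shares[cell] = _fit(samples, config.share_family) if samples.n else None

    pooled: dict[str, FittedDistribution] = {}
    for d_label in scheme.diaspora_labels:
        vals = np.concatenate(
            [share_samples[(g, d_label)].values
             for g in scheme.gdp_ratio_labels]
        )
        fit = _fit(LabeledSamples(vals, f"pooled|{d_label}"),
                   config.share_family) if vals.size else None
        if fit is not None:
            pooled[f"d:{d_label}"] = fit
    all_vals = np.concatenate([s.values for s in share_samples.values()])
    if all_vals.size:
        fit = _fit(LabeledSamples(all_vals, "pooled|all"), config.share_family)
        if fit is not None:
            pooled["all"] = fit

    fallbacks: dict[tuple[str, str], str] = {}
    for cell, dist in shares.items():
        if dist is None:
            key = f"d:{cell[1]}"
            if key in pooled:
                fallbacks[cell] = key
            elif "all" in pooled:
                fallbacks[cell] = "all"
            else:
                raise ValueError(
                    f"share cell {cell} is empty and no pooled fallback "
                    "could be fitted"
                )

    # return rates, single unpartitioned fit (mandatory)
    return_samples = build_return_rate_samples(history, stocks)
    return_fit = _fit(return_samples, config.return_family)
    if return_fit is None:
        raise ValueError(
            f"only {return_samples.n} return-rate samples, fewer than "
            f"min_fit={config.min_fit}; cannot calibrate"
        )

    prov = _provenance(history, panel, scheme, config)
    prov["n_return_discarded"] = return_samples.n_discarded
    prov["emigration_n"] = {l: s.n for l, s in rate_samples.items()}
    return FlowDistributionSet(
        scheme=scheme,
        emigration=emigration,
        shares=shares,
        pooled_shares=pooled,
        share_fallbacks=fallbacks,
        return_rate=return_fit,
        diaspora_mode=config.diaspora_mode,
        provenance=prov,
    )
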