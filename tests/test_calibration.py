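"""Sample building, distribution fitting, ranking, and full calibration."""

import numpy as np
import pytest
import scipy.stats as st

import migsim as m
from migsim.calibration import (
    LabeledSamples,
    _histogram_sse,
    build_emigration_rate_samples,
    build_return_rate_samples,
    build_share_samples,
    fit_distribution,
    rank_families,
)
from migsim.domain import FlowHistory, PartitionScheme, WorldState

from conftest import make_panel

SCHEME = PartitionScheme()


def history_of(countries, periods, M, R=None):
    M = np.asarray(M, dtype=float)
    R = np.zeros_like(M) if R is None else np.asarray(R, dtype=float)
    return FlowHistory(countries, periods, M, R)


class TestEmigrationRateSamples:
    def test_single_origin_rate_and_label(self):
        countries = ("AAA", "BBB")
        panel = make_panel(countries, [1990], [1e6, 5e7])
        M = [[[0.0, 50_000.0], [0.0, 0.0]]]
        samples = build_emigration_rate_samples(
            history_of(countries, [(1990, 1995)], M), panel, SCHEME
        )
        # 5-year rate 0.05 converts to ~0.0102 yearly, in the P1 bucket
        assert samples["P1"].values == pytest.approx([0.0102062], abs=1e-7)
        # zero outflow is retained as a zero rate in the origin's bin
        assert samples["P3"].values == pytest.approx([0.0])

    def test_period_population_decides_the_bin(self):
        countries = ("AAA",)
        import pandas as pd
        rows = [("AAA", 1990, 5e6, 0.0, 0.0, 0.0, 1e4, "R", "high"),
                ("AAA", 1995, 5e7, 0.0, 0.0, 0.0, 1e4, "R", "high")]
        panel = m.CountryPanel(pd.DataFrame(rows, columns=[
            "country_id", "year", "population", "natural_change_rate",
            "birth_rate", "death_rate", "gdpc", "region", "income_group"]))
        M = np.zeros((2, 1, 1))
        samples = build_emigration_rate_samples(
            history_of(countries, [(1990, 1995), (1995, 2000)], M),
            panel, SCHEME,
        )
        assert samples["P2"].n == 1 and samples["P3"].n == 1

    def test_zero_population_skipped(self, caplog):
        countries = ("AAA", "BBB")
        panel = make_panel(countries, [1990], [0.0, 1e6])
        M = [[[0.0, 10.0], [0.0, 0.0]]]
        with caplog.at_level("WARNING"):
            samples = build_emigration_rate_samples(
                history_of(countries, [(1990, 1995)], M), panel, SCHEME
            )
        assert sum(s.n for s in samples.values()) == 1
        assert "zero origin population" in caplog.text


class TestShareSamples:
    def test_share_values_and_labels(self):
        countries = ("AAA", "BBB", "CCC")
        panel = make_panel(countries, [1990], [1e6, 1e7, 1e7],
                           gdpc=[1000.0, 20000.0, 1000.0])
        M = [[[0.0, 25.0, 75.0], [0.0, 0.0, 0.0], [0.0, 0.0, 0.0]]]
        D = np.zeros((3, 3))
        D[1, 0] = 2e5  # diaspora of AAA in BBB: d = 0.2 -> d5
        stocks = {1990: WorldState(1990, countries, np.array([1e6, 1e7, 1e7]), D)}
        samples = build_share_samples(
            history_of(countries, [(1990, 1995)], M), stocks, panel, SCHEME
        )
        # AAA->BBB: share 0.25, g = 1000/20000 = 0.05 -> g1, d5
        assert samples[("g1", "d5")].values == pytest.approx([0.25])
        # AAA->CCC: share 0.75, g = 1 -> g3, no stock -> d1
        assert samples[("g3", "d1")].values == pytest.approx([0.75])
        # origins with zero outflow contribute nothing
        assert sum(s.n for s in samples.values()) == 2


class TestReturnRateSamples:
    def test_rates_and_discard_rule(self):
        countries = ("AAA", "BBB")
        D = np.array([[0.0, 1000.0], [500.0, 0.0]])
        stocks = {1990: WorldState(1990, countries, np.zeros(2), D)}
        R = [[[0.0, 10.0], [600.0, 0.0]]]  # 600/500 > 1 -> discarded
        samples = build_return_rate_samples(
            history_of(countries, [(1990, 1995)], np.zeros((1, 2, 2)), R),
            stocks,
        )
        assert samples.values == pytest.approx([0.0020080], abs=1e-7)
        assert samples.n_discarded == 1

    def test_all_zero_returns_kept(self):
        countries = ("AAA", "BBB")
        D = np.array([[0.0, 1000.0], [500.0, 0.0]])
        stocks = {1990: WorldState(1990, countries, np.zeros(2), D)}
        samples = build_return_rate_samples(
            history_of(countries, [(1990, 1995)], np.zeros((1, 2, 2))),
            stocks,
        )
        assert samples.n == 2 and np.all(samples.values == 0.0)
        assert samples.n_discarded == 0

    def test_discard_removes_exactly_the_over_one_rates(self):
        rng = np.random.default_rng(4)
        countries = tuple(f"C{i}" for i in range(6))
        D = rng.uniform(10, 1000, (6, 6))
        np.fill_diagonal(D, 0.0)
        rate5 = rng.uniform(0, 1.4, (6, 6))  # some > 1
        np.fill_diagonal(rate5, 0.0)
        R = D * rate5
        stocks = {1990: WorldState(1990, countries, np.zeros(6), D)}
        samples = build_return_rate_samples(
            history_of(countries, [(1990, 1995)], np.zeros((1, 6, 6)), [R]),
            stocks,
        )
        off = ~np.eye(6, dtype=bool)
        n_over = int((rate5[off] > 1).sum())
        assert samples.n_discarded == n_over
        assert samples.n == off.sum() - n_over


class TestFitting:
    def test_weibull_max_parameter_recovery(self):
        true = dict(c=2.5, loc=0.08, scale=0.03)
        x = st.weibull_max.rvs(**true, size=10_000,
                               random_state=np.random.default_rng(9))
        x = np.clip(x, 0, 1)
        fit = fit_distribution(LabeledSamples(x, "w"), "weibull_max")
        assert fit.params["loc"] == pytest.approx(true["loc"], rel=0.05)
        assert fit.params["scale"] == pytest.approx(true["scale"], rel=0.05)

    def test_student_t_recovery_and_density_integral(self):
        x = st.t.rvs(6, loc=0.5, scale=0.05, size=20_000,
                     random_state=np.random.default_rng(2))
        x = np.clip(x, 0, 1)
        fit = fit_distribution(LabeledSamples(x, "t"), "student_t")
        assert fit.params["loc"] == pytest.approx(0.5, rel=0.02)
        assert fit.density_integral() == pytest.approx(1.0, abs=1e-6)

    def test_too_few_samples_gives_empty(self):
        fit = fit_distribution(LabeledSamples(np.full(5, 0.4), "x"), "normal",
                               min_n=30)
        assert fit is None

    def test_degenerate_sample_is_an_error(self):
        with pytest.raises(ValueError, match="degenerate"):
            fit_distribution(LabeledSamples(np.full(100, 0.25), "x"), "normal")

    def test_sse_prefers_the_better_density(self):
        x = st.norm.rvs(0.5, 0.05, size=5000,
                        random_state=np.random.default_rng(3))
        good = st.norm(0.5, 0.05)
        bad = st.norm(0.7, 0.05)
        assert _histogram_sse(x, good, 100) < _histogram_sse(x, bad, 100)


class TestRanking:
    def test_generating_family_ranks_first(self):
        x = st.t.rvs(3, loc=0.5, scale=0.04, size=10_000,
                     random_state=np.random.default_rng(7))
        x = np.clip(x, 0, 1)
        ranked = rank_families(LabeledSamples(x, "t"),
                               ["student_t", "normal"])
        assert ranked[0].family == "student_t"

    def test_single_candidate(self):
        x = st.norm.rvs(0.5, 0.05, size=1000,
                        random_state=np.random.default_rng(1))
        ranked = rank_families(LabeledSamples(np.clip(x, 0, 1), "n"),
                               ["normal"])
        assert [f.family for f in ranked] == ["normal"]

    def test_duplicate_candidates_keep_stable_order(self):
        x = st.norm.rvs(0.5, 0.05, size=1000,
                        random_state=np.random.default_rng(1))
        ranked = rank_families(LabeledSamples(np.clip(x, 0, 1), "n"),
                               ["normal", "normal"])
        assert [f.family for f in ranked] == ["normal", "normal"]

    def test_all_failures_reported(self):
        samples = LabeledSamples(np.full(100, 0.3), "const")
        with pytest.raises(ValueError, match="degenerate"):
            rank_families(samples, ["normal", "student_t"])


class TestCalibrateModel:
    def test_full_calibration_structure(self, calibrated):
        cfg, truth, res, dists = calibrated
        assert set(dists.emigration) == set(SCHEME.population_labels)
        assert dists.return_rate.family == "student_t"
        for label in SCHEME.population_labels:
            assert dists.emigration[label].family == "jones_faddy_skew_t"
            assert dists.emigration[label].n_fit >= 30
        for cell, dist in dists.shares.items():
            if dist is None:
                # every empty cell resolves through its fallback pointer
                assert dists.share_for(*cell) is not None
            else:
                assert dist.family == "weibull_max"
        assert dists.provenance["flows_sha256"]

    def test_closed_loop_median_recovery(self, calibrated):
        """Calibrating on a synthetic history recovers the generating
        emigration-rate medians per population bin."""
        cfg, truth, res, dists = calibrated
        for label in SCHEME.population_labels:
            t = truth.emigration[label].truncated_median()
            f = dists.emigration[label].truncated_median()
            assert f == pytest.approx(t, rel=0.10), label

    def test_calibration_is_deterministic(self, synthetic_history):
        cfg, truth, res = synthetic_history
        d1 = m.calibrate_model(res.history, res.stocks, res.panel)
        d2 = m.calibrate_model(res.history, res.stocks, res.panel)
        for label in SCHEME.population_labels:
            assert d1.emigration[label].params == d2.emigration[label].params

    def test_empty_population_bin_is_hard_error(self):
        countries = ("AAA", "BBB", "CCC")
        panel = make_panel(countries, [1990], [5e5, 5e6, 5e7])
        M = np.zeros((1, 3, 3))
        stocks = {1990: WorldState(1990, countries, np.zeros(3),
                                   np.zeros((3, 3)))}
        with pytest.raises(ValueError, match="P"):
            m.calibrate_model(history_of(countries, [(1990, 1995)], M),
                              stocks, panel)

    def test_serialization_roundtrip(self, calibrated, tmp_path):
        _cfg, _truth, _res, dists = calibrated
        path = tmp_path / "dists.json"
        dists.to_json(path)
        back = m.FlowDistributionSet.from_json(path)
        assert back.scheme == dists.scheme
        for label, dist in dists.emigration.items():
            assert back.emigration[label].params == pytest.approx(dist.params)
        assert back.share_fallbacks == dists.share_fallbacks
        assert back.return_rate.params == pytest.approx(dists.return_rate.params)
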