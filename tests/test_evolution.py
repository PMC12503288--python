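"""Accounting step, trajectories, ensembles, and their invariants."""

import numpy as np
import pytest

import migsim as m
from migsim.domain import FlowMatrices, WorldState
from migsim.evolution import apply_flows, convergence_diagnostic, run_ensemble
from migsim.sampling import SamplerContext

from conftest import make_panel


class TestStep:
    def test_native_population_hand_example(self):
        """P' = (1000 - 10) * 1.01 + 2 + 1 = 1002.9."""
        state = WorldState(2000, ("A", "B"),
                           [1000.0, 5000.0], [[0.0, 100.0], [50.0, 0.0]])
        flows = FlowMatrices(
            M=[[0.0, 10.0], [0.0, 0.0]],
            R=[[0.0, 0.0], [2.0, 0.0]],   # 2 returnees arrive back in A
            B=[[0.0, 1.0], [0.0, 0.0]],   # 1 migrant birth in A
        )
        new, clamped = apply_flows(state, flows, c=np.array([0.01, 0.0]),
                                   c_death=np.zeros(2))
        assert new.P[0] == pytest.approx(1002.9)
        assert clamped == 0

    def test_migrant_stock_hand_example(self):
        """D' = 100 * 0.99 - 5 + 7 = 101 under the survival convention."""
        state = WorldState(2000, ("A", "B"),
                           [1000.0, 5000.0], [[0.0, 100.0], [0.0, 0.0]])
        flows = FlowMatrices(
            M=[[0.0, 0.0], [7.0, 0.0]],   # 7 people move B -> A
            R=[[0.0, 5.0], [0.0, 0.0]],
            B=np.zeros((2, 2)),
        )
        new, _ = apply_flows(state, flows, c=np.zeros(2),
                             c_death=np.array([0.0, 0.01]))
        assert new.D[0, 1] == pytest.approx(101.0)

    def test_zero_rates_are_a_fixed_point(self):
        countries = tuple(f"C{i}" for i in range(5))
        panel = make_panel(countries, [2000, 2001], np.full(5, 1e6))
        truth = m.zero_rate_truth()
        state = WorldState(2000, countries, np.full(5, 1e6),
                           np.diag(np.zeros(5)))
        ctx = SamplerContext.from_seed(1)
        ctx.max_rejection_rounds = 3
        new, flows = m.step(state, panel, truth, ctx)
        assert np.array_equal(new.P, state.P)
        assert np.array_equal(new.D, state.D)
        assert flows.M.sum() == 0 and flows.R.sum() == 0

    def test_missing_panel_year_is_an_error(self, small_world, truth):
        _cfg, panel, initial = small_world
        late = WorldState(2050, initial.countries, initial.P, initial.D)
        with pytest.raises(KeyError):
            m.step(late, panel, truth, SamplerContext.from_seed(0))


class TestConservation:
    def test_total_persons_invariant_without_natural_change(self):
        cfg = m.SyntheticConfig(n_countries=10, seed=3, end_year=2000,
                                birth_rate_range=(0.0, 0.0),
                                death_rate_range=(0.0, 0.0))
        panel, initial = m.generate_world(cfg)
        truth = m.default_truth()
        traj = m.simulate_trajectory(initial, panel, truth, 10,
                                     SamplerContext.from_seed(7))
        totals = [s.total_population + s.total_migrant_stock
                  for s in traj.states]
        assert np.allclose(totals, totals[0], rtol=1e-12)


class TestTrajectory:
    def test_horizon_zero(self, small_world, truth):
        _cfg, panel, initial = small_world
        traj = m.simulate_trajectory(initial, panel, truth, 0,
                                     SamplerContext.from_seed(0))
        assert len(traj.states) == 1 and traj.flows == []

    def test_seed_contract(self, small_world, truth):
        _cfg, panel, initial = small_world
        t1 = m.simulate_trajectory(initial, panel, truth, 5,
                                   SamplerContext.from_seed(9))
        t2 = m.simulate_trajectory(initial, panel, truth, 5,
                                   SamplerContext.from_seed(9))
        for a, b in zip(t1.states, t2.states):
            assert np.array_equal(a.P, b.P) and np.array_equal(a.D, b.D)

    def test_deterministic_is_reproducible_without_seed(self, small_world,
                                                        truth):
        _cfg, panel, initial = small_world
        t1 = m.deterministic_run(initial, panel, truth, 5)
        t2 = m.deterministic_run(initial, panel, truth, 5)
        for a, b in zip(t1.states, t2.states):
            assert np.array_equal(a.P, b.P) and np.array_equal(a.D, b.D)

    def test_replay_reproduces_states_bit_exactly(self, small_world, truth):
        _cfg, panel, initial = small_world
        traj = m.simulate_trajectory(initial, panel, truth, 8,
                                     SamplerContext.from_seed(13))
        replayed = traj.replay(panel)
        for a, b in zip(traj.states, replayed):
            assert np.array_equal(a.P, b.P) and np.array_equal(a.D, b.D)

    def test_states_stay_nonnegative(self, small_world, truth):
        _cfg, panel, initial = small_world
        traj = m.simulate_trajectory(initial, panel, truth, 15,
                                     SamplerContext.from_seed(21))
        for s in traj.states:
            assert np.all(s.P >= 0) and np.all(s.D >= 0)


class TestEnsemble:
    def test_single_sample_degenerates_to_its_trajectory(self, small_world,
                                                         truth):
        _cfg, panel, initial = small_world
        summary = run_ensemble(initial, panel, truth, 5, 1, seed=3)
        band = summary.band("total_migrant_stock")
        assert np.array_equal(band["median"], band["q2.5"])
        assert np.array_equal(band["median"], band["q97.5"])

    def test_interval_nesting(self, small_world, truth):
        _cfg, panel, initial = small_world
        summary = run_ensemble(initial, panel, truth, 10, 60, seed=5)
        for name in ("total_population", "total_migrant_stock"):
            b = summary.band(name)
            assert np.all(b["q2.5"] <= b["q25"] + 1e-9)
            assert np.all(b["q25"] <= b["median"] + 1e-9)
            assert np.all(b["median"] <= b["q75"] + 1e-9)
            assert np.all(b["q75"] <= b["q97.5"] + 1e-9)

    def test_summary_invariant_under_sample_permutation(self, small_world,
                                                        truth):
        _cfg, panel, initial = small_world
        summary = run_ensemble(initial, panel, truth, 5, 40, seed=8)
        perm = np.random.default_rng(0).permutation(40)
        shuffled = m.EnsembleSummary(
            summary.years, summary.countries,
            {k: v[perm] for k, v in summary.samples.items()},
        )
        for name in ("total_population", "total_migrant_stock"):
            assert np.array_equal(summary.band(name)["median"],
                                  shuffled.band(name)["median"])

    def test_master_seed_reproducibility(self, small_world, truth):
        _cfg, panel, initial = small_world
        a = run_ensemble(initial, panel, truth, 4, 10, seed=12)
        b = run_ensemble(initial, panel, truth, 4, 10, seed=12)
        assert np.array_equal(a.samples["total_migrant_stock"],
                              b.samples["total_migrant_stock"])


class TestConvergence:
    def test_nested_subsets_and_table_shape(self, small_world, truth):
        _cfg, panel, initial = small_world
        summary = run_ensemble(initial, panel, truth, 5, 80, seed=2)
        table = convergence_diagnostic(
            [summary.subset(20), summary.subset(40), summary]
        )
        assert list(table["n_samples"]) == [20, 40, 80]
        assert np.isnan(table["abs_diff"].iloc[0])
        assert (table["abs_diff"].iloc[1:] >= 0).all()

    def test_identical_ensembles_have_zero_difference(self, small_world,
                                                      truth):
        _cfg, panel, initial = small_world
        s1 = run_ensemble(initial, panel, truth, 4, 20, seed=6)
        s2 = run_ensemble(initial, panel, truth, 4, 20, seed=6)
        # same seed at equal n: identical medians, so the diff vanishes
        table = convergence_diagnostic([s1.subset(10), s2.subset(10)])
        assert table["abs_diff"].iloc[1] == 0.0

    def test_degenerate_dynamics_have_zero_differences(self):
        countries = tuple(f"C{i}" for i in range(4))
        panel = make_panel(countries, range(2000, 2005), np.full(4, 1e6))
        truth = m.zero_rate_truth()
        D = np.zeros((4, 4))
        D[0, 1] = 1e4
        initial = WorldState(2000, countries, np.full(4, 1e6), D)
        summary = run_ensemble(initial, panel, truth, 3, 30, seed=1)
        table = convergence_diagnostic([summary.subset(10), summary])
        assert table["abs_diff"].iloc[1] == 0.0

    def test_requires_ascending_sample_sizes(self, small_world, truth):
        _cfg, panel, initial = small_world
        s = run_ensemble(initial, panel, truth, 3, 20, seed=4)
        with pytest.raises(ValueError, match="ascending"):
            convergence_diagnostic([s, s.subset(10)])
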