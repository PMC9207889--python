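import numpy as np
import pytest
from scipy import stats

from dwellclust import (
    ValidationError,
    aggregate,
    fixture_scheme,
    idealize,
    scheme_from_dict,
    simulate_dwell_series,
    simulate_path,
    synthesize_trace,
)


class TestSimulatePath:
    def test_two_state_dwell_means_within_3se(self, two_state_scheme):
        path = simulate_path(two_state_scheme, 10**4, seed=1)
        o = np.array([d for s, d in path if s == "O"])
        c = np.array([d for s, d in path if s == "C"])
        # exponential dwell: sd == mean, SE = mean/sqrt(n)
        assert abs(o.mean() - 1.0) <= 3.0 * 1.0 / np.sqrt(o.size)
        assert abs(c.mean() - 3.0) <= 3.0 * 3.0 / np.sqrt(c.size)

    def test_deterministic_routing_alternates(self):
        sch = scheme_from_dict(
            {
                "initial_state": "O",
                "substates": {"O": "O", "C": "C"},
                "rates": {"O": {"C": 2.0}, "C": {"O": 0.5}},
            }
        )
        path = simulate_path(sch, 50, seed=0)
        states = [s for s, _ in path]
        assert states == ["O", "C"] * 25

    def test_same_seed_identical(self, two_state_scheme):
        a = simulate_path(two_state_scheme, 500, seed=9)
        b = simulate_path(two_state_scheme, 500, seed=9)
        assert a == b

    def test_per_substate_dwell_distribution_ks(self):
        sch = fixture_scheme("fig1")
        path = simulate_path(sch, 10**4, seed=3)
        for sid in ("O3", "O4", "C7"):
            dwells = [d for s, d in path if s == sid]
            p = stats.kstest(dwells, "expon", args=(0, sch.mean_dwell(sid))).pvalue
            assert p > 0.01


class TestAggregate:
    def test_composite_closed_dwell_of_three_and_nine_is_twelve(self):
        sch = fixture_scheme("fig1")
        path = [("O3", 1.0), ("C6", 3.0), ("C7", 9.0), ("O4", 2.0)]
        series = aggregate(path, sch)
        assert series.events == [("O", 1.0), ("C", 12.0), ("O", 2.0)]

    def test_alternating_path_is_identity(self, two_state_scheme):
        path = [("O", 1.5), ("C", 2.5), ("O", 0.5)]
        series = aggregate(path, two_state_scheme)
        assert series.events == [("O", 1.5), ("C", 2.5), ("O", 0.5)]

    def test_all_closed_path_single_event(self):
        sch = fixture_scheme("fig1")
        series = aggregate([("C6", 1.0), ("C7", 2.0), ("C6", 3.0)], sch)
        assert series.events == [("C", 6.0)]

    def test_total_time_conserved(self, two_state_scheme):
        path = simulate_path(two_state_scheme, 2000, seed=5)
        series = aggregate(path, two_state_scheme)
        assert series.total_duration == pytest.approx(sum(d for _, d in path))

    def test_hypoexponential_mean_additivity(self):
        # forced route O -> Ca -> Cb -> O: closed dwell is a 2-stage sum
        sch = scheme_from_dict(
            {
                "initial_state": "O",
                "substates": {"O": "O", "Ca": "C", "Cb": "C"},
                "rates": {"O": {"Ca": 1.0}, "Ca": {"Cb": 0.5}, "Cb": {"O": 0.2}},
            }
        )
        series = simulate_dwell_series(sch, 3 * 10**4, seed=2)
        closed = series.durations[series.states == "C"]
        expected = 1.0 / 0.5 + 1.0 / 0.2  # 7 ms
        se = np.sqrt(2.0**2 + 5.0**2) / np.sqrt(closed.size)
        assert abs(closed.mean() - expected) <= 3.0 * se


class TestSynthesizeTrace:
    def test_noiseless_rendering_exact(self):
        from dwellclust import DwellSeries

        series = DwellSeries.from_events([("C", 3.0), ("O", 9.0)])
        trace, truth = synthesize_trace(series, 0.0, 10.0, noise_sd=0.0, dt=0.1)
        assert np.array_equal(trace.samples[:30], np.zeros(30))
        assert np.array_equal(trace.samples[30:], np.full(90, 10.0))
        assert np.array_equal(truth.states, series.states)
        assert np.allclose(truth.durations, series.durations)

    def test_noisy_round_trip_recovers_events(self, two_state_scheme):
        series = simulate_dwell_series(two_state_scheme, 400, seed=8)
        trace, truth = synthesize_trace(series, 0.0, 10.0, noise_sd=2.0, dt=0.1,
                                        seed=9)
        ideal = idealize(trace, 5.0, min_duration=0.2)
        # total duration conserved through synthesis + idealization
        assert ideal.total_duration == pytest.approx(truth.total_duration)

    def test_same_seed_identical(self, two_state_scheme):
        series = simulate_dwell_series(two_state_scheme, 100, seed=0)
        a, _ = synthesize_trace(series, noise_sd=1.0, seed=4)
        b, _ = synthesize_trace(series, noise_sd=1.0, seed=4)
        assert np.array_equal(a.samples, b.samples)

    def test_subsample_event_warns(self):
        from dwellclust import DwellSeries

        series = DwellSeries.from_events([("C", 3.0), ("O", 0.01), ("C", 2.0)])
        with pytest.warns(UserWarning, match="shorter than one sample"):
            trace, truth = synthesize_trace(series, dt=0.1)
        assert truth.durations[1] == pytest.approx(0.1)


class TestFixtureSchemes:
    def test_fig1_mean_dwells(self):
        sch = fixture_scheme("fig1")
        expected = {"C5": 5.0, "O3": 1.0, "O4": 3.0, "C6": 3.0, "C7": 9.0}
        for sid, mean in expected.items():
            assert sch.mean_dwell(sid) == pytest.approx(mean, rel=1e-9)

    def test_fig1_dominant_routes(self):
        sch = fixture_scheme("fig1")
        rates_o3 = dict(sch.successors("O3"))
        assert rates_o3["O4"] / sum(rates_o3.values()) > 0.8
        rates_c6 = dict(sch.successors("C6"))
        assert rates_c6["C7"] / sum(rates_c6.values()) > 0.8

    def test_two_pathway_mean_triples(self):
        sch = fixture_scheme("two_pathway")
        open_a = sum(sch.mean_dwell(f"Oa{i}") for i in (1, 2, 3))
        closed_a = sum(sch.mean_dwell(f"Ca{i}") for i in (1, 2, 3))
        open_b = sum(sch.mean_dwell(f"Ob{i}") for i in (1, 2, 3))
        closed_b = sum(sch.mean_dwell(f"Cb{i}") for i in range(1, 7))
        assert [open_a, closed_a] == pytest.approx([1.0, 20.0])
        assert [open_b, closed_b] == pytest.approx([8.0, 2.0])

    def test_bk_like_topology(self):
        sch = fixture_scheme("bk_like")
        classes = [c for _, c in sch.substates]
        assert classes.count("O") == 3 and classes.count("C") == 5

    def test_unknown_name(self):
        with pytest.raises(ValidationError, match="unknown fixture"):
            fixture_scheme("nope")
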