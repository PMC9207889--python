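import json

import numpy as np
import pytest

from dwellclust import (
    Cluster,
    CurrentTrace,
    DwellSeries,
    KineticScheme,
    ParseError,
    ValidationError,
    fixture_scheme,
    read_cluster_report,
    read_dwell_series,
    read_scheme,
    read_trace,
    simulate_dwell_series,
    write_cluster_report,
    write_dwell_series,
    write_scheme,
    write_trace,
)
from conftest import make_sequences


class TestDwellSeriesValidation:
    def test_alternation_enforced(self):
        with pytest.raises(ValidationError, match="alternate at row 2"):
            DwellSeries.from_events([("O", 2.0), ("O", 3.0)])

    def test_positive_durations_enforced(self):
        with pytest.raises(ValidationError, match="> 0"):
            DwellSeries.from_events([("O", 2.0), ("C", 0.0)])

    def test_unknown_state_rejected(self):
        with pytest.raises(ValidationError):
            DwellSeries(states=np.array(["O", "X"]), durations=np.array([1.0, 2.0]))

    def test_three_events(self):
        s = DwellSeries.from_events([("O", 2.0), ("C", 3.0), ("O", 5.0)])
        assert len(s) == 3
        assert s.total_duration == 10.0


class TestTraceValidation:
    def test_minimum_samples(self):
        with pytest.raises(ValidationError):
            CurrentTrace(samples=[1.0])

    def test_nonfinite_rejected(self):
        with pytest.raises(ValidationError):
            CurrentTrace(samples=[1.0, np.nan, 2.0])

    def test_duration(self):
        t = CurrentTrace(samples=np.zeros(50), dt=0.1)
        assert t.duration == pytest.approx(5.0)


class TestTraceIO:
    def test_two_column_infers_dt(self, tmp_path):
        p = tmp_path / "trace.csv"
        p.write_text("0.0,1.5\n0.2,2.5\n0.4,3.5\n")
        tr = read_trace(p)
        assert tr.dt == pytest.approx(0.2)
        assert np.allclose(tr.samples, [1.5, 2.5, 3.5])

    def test_single_column_with_dt(self, tmp_path):
        p = tmp_path / "trace.csv"
        p.write_text("1.0\n2.0\n3.0\n")
        tr = read_trace(p, dt=0.1)
        assert tr.dt == 0.1
        assert np.allclose(tr.samples, [1, 2, 3])

    def test_header_and_comments_skipped(self, tmp_path):
        p = tmp_path / "trace.csv"
        p.write_text("# recorded at 20 mV\ntime\tcurrent\n0.0\t1.0\n0.1\t2.0\n")
        tr = read_trace(p)
        assert np.allclose(tr.samples, [1.0, 2.0])

    def test_non_numeric_row_names_line(self, tmp_path):
        p = tmp_path / "trace.csv"
        p.write_text("0.0,1.0\n0.1,oops\n0.2,3.0\n")
        with pytest.raises(ParseError, match="line 2"):
            read_trace(p)

    def test_missing_file(self, tmp_path):
        with pytest.raises(ParseError, match="not found"):
            read_trace(tmp_path / "nope.csv")

    def test_empty_file(self, tmp_path):
        p = tmp_path / "empty.csv"
        p.write_text("")
        with pytest.raises(ParseError, match="empty"):
            read_trace(p)

    def test_write_read_round_trip(self, tmp_path):
        tr = CurrentTrace(samples=np.array([0.12345678901234567, 9.87, -1.5]), dt=0.1)
        p = tmp_path / "t.csv"
        write_trace(tr, p)
        back = read_trace(p)
        assert np.array_equal(back.samples, tr.samples)


class TestDwellSeriesIO:
    def test_round_trip_small(self, tmp_path):
        s = DwellSeries.from_events([("O", 2.0), ("C", 3.0), ("O", 5.0)])
        p = tmp_path / "d.csv"
        write_dwell_series(s, p)
        assert read_dwell_series(p) == s

    def test_round_trip_large_simulated(self, tmp_path):
        series = simulate_dwell_series(fixture_scheme("fig1"), 3 * 10**4, seed=1)
        assert len(series) >= 10**4
        p = tmp_path / "d.csv"
        write_dwell_series(series, p)
        back = read_dwell_series(p)
        assert np.array_equal(back.durations, series.durations)
        assert np.array_equal(back.states, series.states)

    def test_non_alternating_file_rejected(self, tmp_path):
        p = tmp_path / "d.csv"
        p.write_text("state,duration\nO,2\nO,3\n")
        with pytest.raises(ValidationError, match="row 2"):
            read_dwell_series(p)

    def test_nonpositive_duration_rejected(self, tmp_path):
        p = tmp_path / "d.csv"
        p.write_text("O,2\nC,-1\n")
        with pytest.raises(ValidationError):
            read_dwell_series(p)


class TestSchemeIO:
    def test_round_trip(self, tmp_path):
        sch = fixture_scheme("fig1")
        p = tmp_path / "s.yaml"
        write_scheme(sch, p)
        back = read_scheme(p)
        assert back.substates == sch.substates
        assert back.rates == sch.rates
        assert back.initial_state == sch.initial_state

    def test_absorbing_substate_rejected(self):
        with pytest.raises(ValidationError, match="absorbing"):
            KineticScheme(
                substates=[("O", "O"), ("C", "C")],
                rates={("O", "C"): 1.0},
                initial_state="O",
            )

    def test_undeclared_substate_rejected(self):
        with pytest.raises(ValidationError):
            KineticScheme(
                substates=[("O", "O"), ("C", "C")],
                rates={("O", "C"): 1.0, ("C", "X"): 1.0},
                initial_state="O",
            )

    def test_mean_dwell(self):
        sch = fixture_scheme("fig1")
        assert sch.mean_dwell("C7") == pytest.approx(9.0)


class TestClusterReport:
    def _clusters(self):
        seqs = make_sequences([(10, 2, 10), (20, 4, 20), (1, 5, 1)])
        return (
            [
                Cluster(template=np.array([15.0, 3.0, 15.0]), members=[0, 1],
                        start_state="O"),
                Cluster(template=np.array([1.0, 5.0, 1.0]), members=[2],
                        start_state="O"),
            ],
            seqs,
        )

    def test_report_contains_records(self, tmp_path):
        clusters, seqs = self._clusters()
        p = tmp_path / "r.json"
        write_cluster_report(clusters, p, r0=0.9, sequences=seqs)
        doc = json.loads(p.read_text())
        assert doc["r0"] == 0.9
        assert len(doc["clusters"]) == 2
        assert doc["clusters"][0]["cardinality"] == 2
        assert "dispersion" in doc["clusters"][0]

    def test_empty_cluster_list(self, tmp_path):
        p = tmp_path / "r.json"
        write_cluster_report([], p)
        assert json.loads(p.read_text())["clusters"] == []

    def test_templates_round_trip_exactly(self, tmp_path):
        clusters, seqs = self._clusters()
        clusters[0].template[0] = 15.000000000000123
        p = tmp_path / "r.json"
        write_cluster_report(clusters, p, sequences=seqs)
        back = read_cluster_report(p)
        assert np.array_equal(back["clusters"][0].template, clusters[0].template)
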