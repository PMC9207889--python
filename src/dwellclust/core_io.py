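"""Domain types and file I/O for dwell-time analysis.

The package works with four kinds of objects: raw single-channel current
traces (:class:`CurrentTrace`), idealized open/closed dwell-time series
(:class:`DwellSeries`), short N-element windows cut from such a series
(:class:`DwellSequence`), and the clusters of cross-correlated windows
(:class:`Cluster`).  Kinetic schemes for the gating simulator are described
by :class:`KineticScheme`.

Traces and dwell series travel as comma- or tab-separated text with
``#`` comment lines; cluster and scan reports are JSON; kinetic schemes are
YAML.  All writers emit full-precision floats so read(write(x)) == x.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import yaml

OPEN = "O"
CLOSED = "C"
STATES = (OPEN, CLOSED)

#: default sampling interval, ms (10 kHz acquisition)
DEFAULT_DT = 0.1


class DwellClustError(Exception):
    """Base class for all package errors."""


class ParseError(DwellClustError):
    """A file could not be parsed; the message names the offending line."""


class ValidationError(DwellClustError):
    """A domain invariant was violated."""


def other_state(state: str) -> str:
    return CLOSED if state == OPEN else OPEN


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class CurrentTrace:
    """A sampled single-channel current recording.

    Parameters
    ----------
    samples : array-like
        Current samples in pA.
    dt : float
        Sampling interval in ms (default 0.1 ms, i.e. 10 kHz).
    meta : dict
        Free-form metadata, e.g. membrane potential in mV or the
        instrument's current resolution.
    """

    samples: np.ndarray
    dt: float = DEFAULT_DT
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1 or self.samples.size < 2:
            raise ValidationError("trace needs at least 2 samples")
        if not np.all(np.isfinite(self.samples)):
            raise ValidationError("trace samples must be finite")
        if not (self.dt > 0):
            raise ValidationError("dt must be positive")

    @property
    def duration(self) -> float:
        """Total trace duration in ms."""
        return self.samples.size * self.dt

    def __len__(self) -> int:
        return self.samples.size


@dataclass
class DwellSeries:
    """Alternating open/closed sojourn record.

    ``states`` and ``durations`` are parallel arrays; states strictly
    alternate and every duration is positive (ms).  The first and last
    events of an idealized trace are only partially observed; the
    ``censored_first``/``censored_last`` flags record that.
    """

    states: np.ndarray
    durations: np.ndarray
    censored_first: bool = False
    censored_last: bool = False

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states, dtype="U1")
        self.durations = np.asarray(self.durations, dtype=float)
        if self.states.shape != self.durations.shape or self.states.ndim != 1:
            raise ValidationError("states and durations must be parallel 1-d arrays")
        if self.states.size == 0:
            raise ValidationError("empty dwell series")
        bad = ~np.isin(self.states, STATES)
        if bad.any():
            raise ValidationError(
                f"unknown state {self.states[bad][0]!r} at row {int(np.nonzero(bad)[0][0]) + 1}"
            )
        nonpos = self.durations <= 0
        if nonpos.any():
            raise ValidationError(
                f"duration must be > 0 at row {int(np.nonzero(nonpos)[0][0]) + 1}"
            )
        same = self.states[1:] == self.states[:-1]
        if same.any():
            raise ValidationError(
                f"states must alternate at row {int(np.nonzero(same)[0][0]) + 2}"
            )

    @classmethod
    def from_events(cls, events: Iterable[tuple[str, float]], **kw) -> "DwellSeries":
        ev = list(events)
        return cls(
            states=np.array([s for s, _ in ev], dtype="U1"),
            durations=np.array([d for _, d in ev], dtype=float),
            **kw,
        )

    @property
    def events(self) -> list[tuple[str, float]]:
        return [(str(s), float(d)) for s, d in zip(self.states, self.durations)]

    @property
    def total_duration(self) -> float:
        return float(self.durations.sum())

    def __len__(self) -> int:
        return self.states.size

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, DwellSeries):
            return NotImplemented
        return (
            np.array_equal(self.states, other.states)
            and np.array_equal(self.durations, other.durations)
            and self.censored_first == other.censored_first
            and self.censored_last == other.censored_last
        )


@dataclass(frozen=True)
class DwellSequence:
    """One N-element O-C-O-... or C-O-C-... window of dwell-times.

    ``origin_index`` is the index, in the source :class:`DwellSeries`, of the
    window's first event; the bookkeeping of the clustering pass excludes
    sequences by this index.  ``product`` (the literal product of the
    durations) drives the longest-sequences-first sort.
    """

    values: np.ndarray
    start_state: str
    origin_index: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if self.values.ndim != 1 or self.values.size < 2:
            raise ValidationError("sequence needs N >= 2 durations")
        if not np.all(self.values > 0):
            raise ValidationError("sequence durations must be > 0")
        if self.start_state not in STATES:
            raise ValidationError(f"bad start_state {self.start_state!r}")

    @property
    def product(self) -> float:
        return float(np.prod(self.values))

    def __len__(self) -> int:
        return self.values.size


@dataclass
class Cluster:
    """A set of cross-correlated dwell-time sequences.

    ``template`` is the weighted mean of the member sequences (which, with
    unit member weights, equals their plain arithmetic mean).  ``members``
    lists the origin indices of the aggregated sequences.
    """

    template: np.ndarray
    members: list[int]
    start_state: str

    def __post_init__(self) -> None:
        self.template = np.asarray(self.template, dtype=float)
        if len(self.members) < 1:
            raise ValidationError("cluster needs at least one member")
        if self.start_state not in STATES:
            raise ValidationError(f"bad start_state {self.start_state!r}")

    @property
    def weight(self) -> int:
        return len(self.members)

    @property
    def cardinality(self) -> int:
        return len(self.members)


@dataclass
class KineticScheme:
    """An aggregated-Markov gating scheme.

    Substates carry a functional class (``O`` conducting / ``C`` shut);
    ``rates[(i, j)]`` is the transition rate constant k_ij in 1/ms.  The
    mean dwell of substate i is 1 / sum_j k_ij.
    """

    substates: list[tuple[str, str]]
    rates: dict[tuple[str, str], float]
    initial_state: str

    def __post_init__(self) -> None:
        ids = [s for s, _ in self.substates]
        if len(set(ids)) != len(ids):
            raise ValidationError("duplicate substate ids")
        classes = dict(self.substates)
        for c in classes.values():
            if c not in STATES:
                raise ValidationError(f"substate class must be O or C, got {c!r}")
        for (i, j), k in self.rates.items():
            if i not in classes or j not in classes:
                raise ValidationError(f"rate ({i},{j}) references undeclared substate")
            if i == j:
                raise ValidationError(f"self-transition ({i},{i}) not allowed")
            if k < 0:
                raise ValidationError(f"negative rate for ({i},{j})")
        if self.initial_state not in classes:
            raise ValidationError(f"initial_state {self.initial_state!r} not declared")
        for sid in classes:
            if self.exit_rate(sid) <= 0:
                raise ValidationError(f"substate {sid!r} is absorbing (exit rate 0)")

    @property
    def ids(self) -> list[str]:
        return [s for s, _ in self.substates]

    def state_class(self, sid: str) -> str:
        return dict(self.substates)[sid]

    def exit_rate(self, sid: str) -> float:
        return float(sum(k for (i, _), k in self.rates.items() if i == sid))

    def mean_dwell(self, sid: str) -> float:
        """Expected sojourn time of a substate, ms."""
        return 1.0 / self.exit_rate(sid)

    def successors(self, sid: str) -> list[tuple[str, float]]:
        return [(j, k) for (i, j), k in self.rates.items() if i == sid and k > 0]


@dataclass
class ExpFitResult:
    """Outcome of a k-component exponential mixture fit."""

    n_components: int
    amplitudes: np.ndarray
    time_constants: np.ndarray
    log_likelihood: float
    gof_statistic: float
    gof_pvalue: float
    accepted: bool
    degenerate: bool = False
    n_samples: int = 0


@dataclass
class R0ScanRow:
    """Bookkeeping for one candidate correlation threshold."""

    r0: float
    n_clusters: int
    n_large_clusters: int
    n_single_ok: int
    n_double_needed: int
    ratio: float  # NaN when undefined (no single-ok cluster)

    @property
    def ratio_defined(self) -> bool:
        return np.isfinite(self.ratio)


@dataclass
class R0ScanResult:
    """Grid of threshold candidates and the selected optimum."""

    grid: list[R0ScanRow]
    optimum: float
    small_data_rule_applied: bool = False

    def row(self, r0: float) -> R0ScanRow:
        for r in self.grid:
            if abs(r.r0 - r0) < 1e-9:
                return r
        raise KeyError(f"R0={r0} not in grid")


# ---------------------------------------------------------------------------
# tabular text reading (comma/tab tolerant, '#' comments, header skip)
# ---------------------------------------------------------------------------

_SPLIT = re.compile(r"[,\t;]|\s+")


def _read_rows(path: str | Path) -> list[tuple[int, list[str]]]:
    """Read non-comment rows of a delimited text file as (lineno, fields)."""
    p = Path(path)
    if not p.exists():
        raise ParseError(f"file not found: {p}")
    rows: list[tuple[int, list[str]]] = []
    with open(p) as fh:
        for lineno, line in enumerate(fh, start=1):
            s = line.strip()
            if not s or s.startswith("#"):
                continue
            rows.append((lineno, [f for f in _SPLIT.split(s) if f]))
    if not rows:
        raise ParseError(f"empty file: {p}")
    return rows


def _is_number(tok: str) -> bool:
    try:
        float(tok)
        return True
    except ValueError:
        return False


def read_trace(
    path: str | Path,
    dt: float | None = None,
    column: int | None = None,
) -> CurrentTrace:
    """Read a current trace from 1- or 2-column delimited text.

    Two numeric columns are interpreted as (time, current) and ``dt`` is
    inferred from the first two timestamps unless given explicitly.  With a
    single column, ``dt`` defaults to 0.1 ms.  A leading non-numeric row is
    treated as a header and skipped; any other non-numeric row raises a
    :class:`ParseError` naming the line.
    """
    rows = _read_rows(path)
    if all(not _is_number(t) for t in rows[0][1]):  # header row
        rows = rows[1:]
        if not rows:
            raise ParseError(f"no data rows in {path}")
    ncol = len(rows[0][1])
    data = np.empty((len(rows), ncol), dtype=float)
    for r, (lineno, fields) in enumerate(rows):
        if len(fields) != ncol:
            raise ParseError(f"line {lineno}: expected {ncol} fields, got {len(fields)}")
        for c, tok in enumerate(fields):
            if not _is_number(tok):
                raise ParseError(f"line {lineno}: non-numeric value {tok!r}")
            data[r, c] = float(tok)
    if column is None:
        column = 1 if ncol >= 2 else 0
    if column >= ncol:
        raise ParseError(f"column {column} not present ({ncol} columns)")
    if dt is None:
        if ncol >= 2 and column != 0:
            dt = float(data[1, 0] - data[0, 0])
        else:
            dt = DEFAULT_DT
    return CurrentTrace(samples=data[:, column], dt=dt)


def read_dwell_series(path: str | Path) -> DwellSeries:
    """Read a (state, duration) table; validates alternation and positivity."""
    rows = _read_rows(path)
    if rows and rows[0][1][0].lower() in ("state", "states"):
        rows = rows[1:]
    states, durations = [], []
    for row_no, (lineno, fields) in enumerate(rows, start=1):
        if len(fields) < 2:
            raise ParseError(f"line {lineno}: expected (state, duration)")
        st = fields[0].upper()
        if st not in STATES:
            raise ValidationError(f"line {lineno}: state must be O or C, got {fields[0]!r}")
        if not _is_number(fields[1]):
            raise ParseError(f"line {lineno}: non-numeric duration {fields[1]!r}")
        states.append(st)
        durations.append(float(fields[1]))
    return DwellSeries(states=np.array(states), durations=np.array(durations))


def write_dwell_series(series: DwellSeries, path: str | Path) -> None:
    """Write a dwell series as CSV at round-trip float precision."""
    with open(path, "w") as fh:
        fh.write("state,duration\n")
        for s, d in zip(series.states, series.durations):
            fh.write(f"{s},{d:.17g}\n")


def write_trace(trace: CurrentTrace, path: str | Path) -> None:
    """Write a trace as (time, current) CSV."""
    t = np.arange(len(trace)) * trace.dt
    with open(path, "w") as fh:
        fh.write("time,current\n")
        for ti, ii in zip(t, trace.samples):
            fh.write(f"{ti:.17g},{ii:.17g}\n")


# ---------------------------------------------------------------------------
# kinetic scheme config (YAML)
# ---------------------------------------------------------------------------


def read_scheme(path: str | Path) -> KineticScheme:
    """Load a kinetic scheme from YAML with ``substates:``/``rates:`` blocks."""
    p = Path(path)
    if not p.exists():
        raise ParseError(f"file not found: {p}")
    with open(p) as fh:
        doc = yaml.safe_load(fh)
    return scheme_from_dict(doc)


def scheme_from_dict(doc: Mapping) -> KineticScheme:
    try:
        substates = [(str(k), str(v)) for k, v in doc["substates"].items()]
        rates = {
            (str(i), str(j)): float(k)
            for i, targets in doc["rates"].items()
            for j, k in targets.items()
        }
        initial = str(doc["initial_state"])
    except (KeyError, TypeError, AttributeError) as exc:
        raise ParseError(f"malformed scheme config: {exc}") from exc
    return KineticScheme(substates=substates, rates=rates, initial_state=initial)


def write_scheme(scheme: KineticScheme, path: str | Path) -> None:
    doc: dict = {
        "initial_state": scheme.initial_state,
        "substates": {i: c for i, c in scheme.substates},
        "rates": {},
    }
    for (i, j), k in scheme.rates.items():
        doc["rates"].setdefault(i, {})[j] = float(k)
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


# ---------------------------------------------------------------------------
# cluster / scan reports (JSON)
# ---------------------------------------------------------------------------


def write_cluster_report(
    clusters: Sequence[Cluster],
    path: str | Path,
    r0: float | None = None,
    sequences: Sequence[DwellSequence] | None = None,
    scan: R0ScanResult | None = None,
    config: Mapping | None = None,
) -> None:
    """Serialize clusters (and optionally the threshold scan) to JSON.

    Per-dimension dispersion (member standard deviation) is included when
    the sequence pool is supplied.
    """
    by_origin = {}
    if sequences is not None:
        by_origin = {s.origin_index: s.values for s in sequences}
    records = []
    for c in clusters:
        rec: dict = {
            "start_state": c.start_state,
            "template": [float(x) for x in c.template],
            "cardinality": c.cardinality,
            "members": list(map(int, c.members)),
        }
        if by_origin:
            vals = np.array([by_origin[m] for m in c.members])
            rec["dispersion"] = [float(x) for x in vals.std(axis=0)]
        records.append(rec)
    doc: dict = {"r0": r0, "clusters": records}
    if scan is not None:
        doc["scan"] = {
            "optimum": scan.optimum,
            "small_data_rule_applied": scan.small_data_rule_applied,
            "grid": [
                {
                    "r0": g.r0,
                    "n_clusters": g.n_clusters,
                    "n_large_clusters": g.n_large_clusters,
                    "n_single_ok": g.n_single_ok,
                    "n_double_needed": g.n_double_needed,
                    "ratio": g.ratio if np.isfinite(g.ratio) else None,
                }
                for g in scan.grid
            ],
        }
    if config is not None:
        doc["config"] = dict(config)
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)


def read_cluster_report(path: str | Path) -> dict:
    """Read back a cluster report; templates come back numerically identical."""
    with open(path) as fh:
        doc = json.load(fh)
    clusters = [
        Cluster(
            template=np.array(rec["template"], dtype=float),
            members=list(rec["members"]),
            start_state=rec["start_state"],
        )
        for rec in doc["clusters"]
    ]
    doc["clusters"] = clusters
    return doc
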