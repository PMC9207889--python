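"""Aggregated-Markov gating simulator.

Channel gating is modelled as a continuous-time Markov chain over
conformational substates, each labelled open (O) or closed (C).  The
recording only reveals the functional class, so consecutive same-class
sojourns aggregate into one observed dwell — e.g. a closed substate
lasting 3 time units followed by one lasting 9 is seen as a single
12-unit closure.  This module samples substate paths, aggregates them to
observable dwell series, and synthesizes noisy current traces at a given
sampling interval, providing ground truth for every downstream test.
"""

from __future__ import annotations

import logging
import warnings
from importlib import resources

import numpy as np

from .core_io import (
    OPEN,
    CurrentTrace,
    DwellSeries,
    KineticScheme,
    ValidationError,
    read_scheme,
)

log = logging.getLogger(__name__)

__all__ = [
    "simulate_path",
    "aggregate",
    "synthesize_trace",
    "fixture_scheme",
    "simulate_dwell_series",
]

FIXTURES = ("fig1", "two_pathway", "bk_like")


def simulate_path(
    scheme: KineticScheme, n_sojourns: int, seed: int | np.random.Generator
) -> list[tuple[str, float]]:
    """Sample a substate path from the scheme's continuous-time Markov chain.

    From substate i the sojourn is Exponential with mean 1/sum_j k_ij and
    the successor is j with probability k_ij / sum_j k_ij.  Reproducible
    for a fixed seed.
    """
    if n_sojourns < 1:
        raise ValidationError("n_sojourns must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    ids = scheme.ids
    index = {s: i for i, s in enumerate(ids)}
    exit_rates = np.array([scheme.exit_rate(s) for s in ids])
    succ_ids: list[list[str]] = []
    succ_cum: list[np.ndarray] = []
    for s in ids:
        succ = scheme.successors(s)
        if not succ:
            succ_ids.append([])
            succ_cum.append(np.array([]))
            continue
        js, ks = zip(*succ)
        p = np.array(ks) / sum(ks)
        succ_ids.append(list(js))
        succ_cum.append(np.cumsum(p))
    # sample the embedded state chain first, then all sojourn times at once
    states = np.empty(n_sojourns, dtype=int)
    cur = index[scheme.initial_state]
    u = rng.random(n_sojourns)
    for t in range(n_sojourns):
        states[t] = cur
        if not succ_ids[cur]:
            raise ValidationError(f"absorbing substate reached: {ids[cur]!r}")
        nxt = int(np.searchsorted(succ_cum[cur], u[t], side="right"))
        nxt = min(nxt, len(succ_ids[cur]) - 1)
        cur = index[succ_ids[cur][nxt]]
    dwells = rng.exponential(scale=1.0 / exit_rates[states])
    return [(ids[s], float(d)) for s, d in zip(states, dwells)]


def aggregate(path: list[tuple[str, float]], scheme: KineticScheme) -> DwellSeries:
    """Merge consecutive same-class sojourns into observed dwell events.

    The result alternates O/C and conserves total time: a route through
    closed substates dwelling 3 and 9 units is observed as one 12-unit
    closed event.
    """
    if not path:
        raise ValidationError("empty path")
    states: list[str] = []
    durations: list[float] = []
    for sid, dwell in path:
        cls = scheme.state_class(sid)
        if states and states[-1] == cls:
            durations[-1] += dwell
        else:
            states.append(cls)
            durations.append(dwell)
    return DwellSeries(states=np.array(states), durations=np.array(durations))


def synthesize_trace(
    series: DwellSeries,
    level_closed: float = 0.0,
    level_open: float = 10.0,
    noise_sd: float = 0.0,
    dt: float = 0.1,
    seed: int | np.random.Generator = 0,
) -> tuple[CurrentTrace, DwellSeries]:
    """Render a dwell series as a sampled current trace with Gaussian noise.

    Each event becomes round(duration/dt) samples at its conductance
    level (pA); events shorter than half a sample are still rendered as
    one sample, with a warning.  Returns the trace together with the
    ground-truth event list *as rendered* (durations quantized to whole
    samples), for recovery tests.
    """
    if dt <= 0:
        raise ValidationError("dt must be positive")
    if noise_sd < 0:
        raise ValidationError("noise_sd must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    counts = np.rint(series.durations / dt).astype(int)
    if np.any(counts < 1):
        warnings.warn("events shorter than one sample rendered as a single sample")
        counts = np.maximum(counts, 1)
    levels = np.where(series.states == OPEN, level_open, level_closed)
    samples = np.repeat(levels, counts).astype(float)
    if noise_sd > 0:
        samples = samples + rng.normal(0.0, noise_sd, size=samples.size)
    truth = DwellSeries(
        states=series.states.copy(),
        durations=counts * dt,
        censored_first=True,
        censored_last=True,
    )
    return CurrentTrace(samples=samples, dt=dt), truth


def fixture_scheme(name: str) -> KineticScheme:
    """Load one of the shipped example schemes.

    ``fig1``
        Five-substate toy (C5, O3, O4, C6, C7 with mean dwells 5, 1, 3,
        3, 9 time units) in which the closed composite C6->C7 (observed
        dwell 12) and the open route O3->O4 (observed dwell 4) dominate.
    ``two_pathway``
        Two weakly coupled open/closed loops whose mean dwell triples
        differ in shape, not just scale — (1, 20, 1) ms and (8, 2, 8) ms
        for O-C-O windows — used for parameter-recovery experiments.
    ``bk_like``
        Three open and five closed substates with plausible rates,
        mimicking the topology used for large-conductance K+ channels.
    """
    if name not in FIXTURES:
        raise ValidationError(f"unknown fixture scheme {name!r}; choose from {FIXTURES}")
    ref = resources.files("dwellclust") / "schemes" / f"{name}.yaml"
    with resources.as_file(ref) as p:
        return read_scheme(p)


def simulate_dwell_series(
    scheme: KineticScheme, n_sojourns: int, seed: int | np.random.Generator
) -> DwellSeries:
    """Convenience: simulate a path and aggregate it in one call."""
    return aggregate(simulate_path(scheme, n_sojourns, seed), scheme)
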