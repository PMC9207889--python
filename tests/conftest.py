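import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from dwellclust import (  # noqa: E402
    DwellSeries,
    DwellSequence,
    scheme_from_dict,
)


@pytest.fixture
def two_state_scheme():
    """Minimal O<->C scheme with mean open dwell 1 ms, mean closed 3 ms."""
    return scheme_from_dict(
        {
            "initial_state": "O",
            "substates": {"O": "O", "C": "C"},
            "rates": {"O": {"C": 1.0}, "C": {"O": 1.0 / 3.0}},
        }
    )


@pytest.fixture
def erlang_recovery_scheme():
    """3-stage (Erlang) open/closed dwells, means 10/30 ms.

    The narrow dwell distribution leaves essentially no events shorter
    than the idealization dead time, so transition recovery can be
    measured cleanly.
    """
    return scheme_from_dict(
        {
            "initial_state": "O1",
            "substates": {
                "O1": "O", "O2": "O", "O3": "O",
                "C1": "C", "C2": "C", "C3": "C",
            },
            "rates": {
                "O1": {"O2": 0.3}, "O2": {"O3": 0.3}, "O3": {"C1": 0.3},
                "C1": {"C2": 0.1}, "C2": {"C3": 0.1}, "C3": {"O1": 0.1},
            },
        }
    )


@pytest.fixture
def five_event_series():
    return DwellSeries.from_events(
        [("O", 2.0), ("C", 3.0), ("O", 5.0), ("C", 1.0), ("O", 4.0)]
    )


def make_sequences(value_rows, start_state="O"):
    """Build a DwellSequence pool from raw rows, origin = row index."""
    return [
        DwellSequence(values=np.asarray(v, dtype=float), start_state=start_state,
                      origin_index=i)
        for i, v in enumerate(value_rows)
    ]


@pytest.fixture
def drift_pool():
    """Six sequences whose shapes rotate gradually in the centered plane.

    The greedy pass absorbs all six into one cluster, but the template
    drifts far enough that the first member ends below R0 = 0.9 against
    the final template — the situation the refinement sweep exists for.
    """
    e1 = np.array([1.0, 0.0, -1.0]) / np.sqrt(2)
    e2 = np.array([1.0, -2.0, 1.0]) / np.sqrt(6)

    def shape(theta_deg, scale):
        th = np.radians(theta_deg)
        return scale * (10.0 + 5.0 * (np.cos(th) * e1 + np.sin(th) * e2))

    angles = [0, 25, 37, 45, 52, 56]
    rows = [shape(t, 1.5 - 0.05 * i) for i, t in enumerate(angles)]
    return make_sequences(rows)


@pytest.fixture
def random_pool():
    """200 positive random sequences (lognormal dwells), product-sorted."""
    rng = np.random.default_rng(42)
    rows = np.exp(rng.normal(0.5, 1.0, size=(200, 3)))
    from dwellclust import sort_by_product

    return sort_by_product(make_sequences(rows))
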