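"""Trace idealization: amplitude-threshold conversion of a current trace
into an alternating open/closed dwell-time series.

The channel current fluctuates around two conductance levels; a threshold
between them labels every sample O or C, and runs of same-label samples
become dwell events.  The threshold is estimated from the amplitude
histogram by a two-component Gaussian mixture whose equal-posterior
crossing separates the levels.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
from scipy.optimize import brentq
from sklearn.mixture import GaussianMixture

from .core_io import CLOSED, OPEN, CurrentTrace, DwellSeries, ValidationError

log = logging.getLogger(__name__)


def estimate_threshold(trace: CurrentTrace) -> float:
    """Estimate the current threshold separating O and C levels, in pA.

    Fits a two-component Gaussian mixture to the sample amplitudes and
    returns the equal-posterior crossing between the two means (falling
    back to the midpoint when the posteriors do not cross between them).

    Raises
    ------
    ValidationError
        If the trace is too short or the amplitude histogram is not
        bimodal, in which case a manual threshold must be supplied.
    """
    x = trace.samples
    if x.size < 100:
        raise ValidationError("need at least 100 samples to estimate a threshold")
    gm = GaussianMixture(
        n_components=2,
        covariance_type="full",
        means_init=np.percentile(x, [25, 75]).reshape(-1, 1),
        weights_init=[0.5, 0.5],
        n_init=1,
        max_iter=500,
        random_state=0,
        reg_covar=1e-10,
    ).fit(x.reshape(-1, 1))
    mu = gm.means_.ravel()
    sd = np.sqrt(gm.covariances_.ravel())
    w = gm.weights_.ravel()
    order = np.argsort(mu)
    mu, sd, w = mu[order], sd[order], w[order]
    # bimodality check: well separated modes, neither vanishing
    sep = (mu[1] - mu[0]) / np.sqrt((sd[0] ** 2 + sd[1] ** 2) / 2.0)
    if sep < 2.0 or w.min() < 0.02:
        raise ValidationError(
            "cannot separate O/C levels: amplitude histogram is not bimodal; "
            "supply a manual threshold"
        )

    def log_posterior_ratio(v: float) -> float:
        a = np.log(w[0]) - np.log(sd[0]) - 0.5 * ((v - mu[0]) / sd[0]) ** 2
        b = np.log(w[1]) - np.log(sd[1]) - 0.5 * ((v - mu[1]) / sd[1]) ** 2
        return a - b

    lo, hi = mu[0], mu[1]
    try:
        if log_posterior_ratio(lo) > 0 > log_posterior_ratio(hi):
            thr = float(brentq(log_posterior_ratio, lo, hi, xtol=1e-12))
        else:
            thr = float(0.5 * (lo + hi))
    except ValueError:
        thr = float(0.5 * (lo + hi))
    log.debug("threshold estimate: modes %.3g/%.3g pA -> %.3g pA", lo, hi, thr)
    return thr


def idealize(
    trace: CurrentTrace,
    threshold: float,
    min_duration: float = 0.0,
    open_is_above: bool = True,
) -> DwellSeries:
    """Threshold a trace into an alternating O/C dwell series.

    Runs of consecutive samples on the same side of ``threshold`` merge
    into one event of duration count x dt.  Events shorter than
    ``min_duration`` (ms) are folded into the preceding event (the leading
    event, which has no predecessor, is folded forward instead); adjacent
    same-state events are then re-merged.  The first and last events are
    retained but flagged censored, since their true durations are cut by
    the recording window.  The summed durations equal the trace duration.
    """
    if not np.isfinite(threshold):
        raise ValidationError("threshold must be finite")
    if min_duration < 0:
        raise ValidationError("min_duration must be >= 0")
    above = trace.samples > threshold
    if above.all() or (~above).all():
        side = "above" if above.all() else "below"
        warnings.warn(f"all samples {side} threshold: single-event series")
    is_open = above if open_is_above else ~above
    # run-length encode
    change = np.nonzero(is_open[1:] != is_open[:-1])[0] + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [is_open.size]))
    states = np.where(is_open[starts], OPEN, CLOSED)
    durations = (ends - starts) * trace.dt

    if min_duration > 0:
        states, durations = _apply_min_duration(states, durations, min_duration)

    return DwellSeries(
        states=states, durations=durations, censored_first=True, censored_last=True
    )


def _apply_min_duration(
    states: np.ndarray, durations: np.ndarray, min_duration: float
) -> tuple[np.ndarray, np.ndarray]:
    """Fold sub-``min_duration`` events into the preceding event, then
    re-merge same-state neighbours.  Leading short events (no predecessor)
    are carried into the first long enough event."""
    out_states: list[str] = []
    out_durs: list[float] = []
    pending = 0.0
    for s, d in zip(states, durations):
        d = d + pending
        pending = 0.0
        if d < min_duration:
            if out_durs:
                out_durs[-1] += d  # absorbed by predecessor, state kept
            else:
                pending = d  # no predecessor yet: carry forward
            continue
        if out_states and out_states[-1] == s:
            out_durs[-1] += d
        else:
            out_states.append(s)
            out_durs.append(d)
    if pending:
        if out_durs:
            out_durs[0] += pending
        else:  # everything was short: one event of the majority... keep first state
            out_states.append(states[0])
            out_durs.append(pending)
    return np.array(out_states), np.array(out_durs)


def open_probability(series: DwellSeries) -> float:
    """Fraction of total time spent in the open state (p_op)."""
    total = series.durations.sum()
    open_time = series.durations[series.states == OPEN].sum()
    return float(open_time / total)
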