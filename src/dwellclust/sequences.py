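"""N-element dwell-time sequences and their cross-correlation.

An O-C-O-... (or C-O-C-...) sequence is a sliding window of N consecutive
dwell-times starting from an open (closed) event.  Sequences starting from
different states are never compared.  Similarity between two sequences X
and Y is the cross-correlation

    R = sum_i (X_i - mean X)(Y_i - mean Y)
        / sqrt( sum_i (X_i - mean X)^2 * sum_i (Y_i - mean Y)^2 )

i.e. the ratio of covariance to root-mean variance.  R is invariant under
positive affine rescaling of either argument, so sequences that are
"similar in shape but rescaled in amplitude" — the hallmark of the broad
exponential dwell-time distributions — count as matches.
"""

from __future__ import annotations

import warnings

import numpy as np

from .core_io import DwellSequence, DwellSeries, ValidationError

__all__ = [
    "extract_sequences",
    "sort_by_product",
    "cross_correlation",
    "is_constant",
]


def extract_sequences(
    series: DwellSeries,
    n: int,
    start_state: str,
    skip_censored: bool = True,
) -> list[DwellSequence]:
    """Enumerate all overlapping N-element windows starting from ``start_state``.

    One sequence is produced per event of class ``start_state`` that has at
    least N-1 successors; its ``origin_index`` is the event's position in
    the series.  Windows touching a censored first/last event are dropped
    by default (their durations are truncated by the recording window).
    Returns an empty list when the series is shorter than N.
    """
    if n < 2:
        raise ValidationError("sequence length N must be >= 2")
    if n == 2:
        warnings.warn(
            "N=2 sequences have correlation exactly +/-1; clustering degenerates "
            "to rising/falling pairs (practical minimum is N=3)"
        )
    m = len(series)
    out: list[DwellSequence] = []
    for i in range(m - n + 1):
        if series.states[i] != start_state:
            continue
        if skip_censored and series.censored_first and i == 0:
            continue
        if skip_censored and series.censored_last and i + n == m:
            continue
        out.append(
            DwellSequence(
                values=series.durations[i : i + n].copy(),
                start_state=start_state,
                origin_index=i,
            )
        )
    return out


def sort_by_product(sequences: list[DwellSequence]) -> list[DwellSequence]:
    """Sort by decreasing product of dwell-times (longest sequences first).

    Ties keep ascending origin order, so the search is deterministic.
    """
    return sorted(sequences, key=lambda s: (-s.product, s.origin_index))


def is_constant(values: np.ndarray, rtol: float = 1e-12) -> bool:
    """True when a sequence has (numerically) zero variance, making its
    cross-correlation undefined."""
    v = np.asarray(values, dtype=float)
    return bool(np.ptp(v) <= rtol * max(1.0, float(np.abs(v).max())))


def cross_correlation(x, y) -> float:
    """Cross-correlation R in [-1, 1] between two equal-length sequences.

    Accepts :class:`DwellSequence` objects or plain arrays (e.g. a cluster
    template).  When both arguments are sequences their start states must
    agree.  Raises :class:`ValidationError` for length mismatch or a
    zero-variance argument, for which R is undefined.
    """
    if isinstance(x, DwellSequence) and isinstance(y, DwellSequence):
        if x.start_state != y.start_state:
            raise ValidationError("sequences start from different states")
    xv = x.values if isinstance(x, DwellSequence) else np.asarray(x, dtype=float)
    yv = y.values if isinstance(y, DwellSequence) else np.asarray(y, dtype=float)
    if xv.shape != yv.shape:
        raise ValidationError(f"length mismatch: {xv.shape} vs {yv.shape}")
    xc = xv - xv.mean()
    yc = yv - yv.mean()
    sx = float(np.sqrt(np.dot(xc, xc)))
    sy = float(np.sqrt(np.dot(yc, yc)))
    if sx == 0.0 or sy == 0.0:
        raise ValidationError("cross-correlation undefined for a constant sequence")
    r = float(np.dot(xc, yc) / (sx * sy))
    # guard against rounding excursions outside [-1, 1]
    return min(1.0, max(-1.0, r))
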