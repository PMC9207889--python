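"""Selection of the correlation threshold R0 by exponential-mixture scoring.

A cluster produced by a single transition route should have dwell-times
that are mono-exponential in every one of its N coordinate dimensions; a
cluster that mixes routes needs a double exponential.  Screening R0 over a
grid and taking the value that minimizes the ratio of double- to
single-exponential verdicts therefore balances over-splitting (high R0,
clusters too small to test) against over-merging (low R0, multi-route
clusters).

Mixture fits are maximum-likelihood (EM with deterministic moment-based
initialization); goodness of fit is a Pearson chi-square on log-spaced
histogram bins pooled to at least five expected counts, accepted at
p >= 0.05 — the operational reading of "the curve agrees with the data
within its uncertainty".
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
from scipy import stats

from .core_io import (
    Cluster,
    DwellSequence,
    ExpFitResult,
    R0ScanResult,
    R0ScanRow,
    ValidationError,
)
from .clustering import cluster_pass, refine_clusters
from .sequences import sort_by_product

log = logging.getLogger(__name__)

__all__ = ["fit_exponential_mixture", "score_threshold", "scan_R0"]

COARSE_GRID = (0.80, 0.85, 0.90, 0.95, 0.97)
GOF_LEVEL = 0.05
MIN_SAMPLES = 20
EM_TOL = 1e-8
EM_MAX_ITER = 500


# ---------------------------------------------------------------------------
# exponential mixture fitting
# ---------------------------------------------------------------------------


def _em_exponential(x: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray, float]:
    """EM for a k-component exponential mixture; deterministic init.

    Time constants start from a geometric spread around the sample mean
    (for k=2: mean/2 and 2*mean); amplitudes start equal.  Returns
    (amplitudes, taus, log-likelihood).
    """
    n = x.size
    mean = x.mean()
    if k == 1:
        tau = mean  # closed-form MLE
        ll = float(-n * np.log(tau) - x.sum() / tau)
        return np.array([1.0]), np.array([tau]), ll
    spread = 2.0 ** (np.arange(k) - (k - 1) / 2.0)
    taus = mean * spread
    w = np.full(k, 1.0 / k)
    ll_old = -np.inf
    for _ in range(EM_MAX_ITER):
        # E step in log space for stability
        logp = np.log(w)[:, None] - np.log(taus)[:, None] - x[None, :] / taus[:, None]
        lse = np.logaddexp.reduce(logp, axis=0)
        resp = np.exp(logp - lse[None, :])
        ll = float(lse.sum())
        if abs(ll - ll_old) <= EM_TOL * max(1.0, abs(ll)):
            ll_old = ll
            break
        ll_old = ll
        # M step
        nk = resp.sum(axis=1)
        nk = np.maximum(nk, 1e-300)
        taus = np.maximum((resp * x[None, :]).sum(axis=1) / nk, 1e-300)
        w = nk / n
    order = np.argsort(taus)
    return w[order], taus[order], ll_old


def _mixture_cdf(x: np.ndarray, w: np.ndarray, taus: np.ndarray) -> np.ndarray:
    return np.sum(w[:, None] * (1.0 - np.exp(-x[None, :] / taus[:, None])), axis=0)


def _chi2_gof(
    x: np.ndarray, w: np.ndarray, taus: np.ndarray, n_params: int
) -> tuple[float, float]:
    """Pearson chi-square on log-spaced bins with >= 5 expected counts.

    Bins are pooled left-to-right until each reaches five expected counts
    (Poisson-error regime); dof = bins - 1 - fitted parameters.
    """
    n = x.size
    nbins = max(6, int(round(2.0 * n**0.4)))
    lo, hi = x.min(), x.max()
    edges = np.geomspace(lo, hi, nbins + 1)
    edges[0], edges[-1] = 0.0, np.inf  # cover the full support
    cdf = _mixture_cdf(np.concatenate(([0.0], edges[1:-1], [np.inf])), w, taus)
    cdf[-1] = 1.0
    expected = n * np.diff(cdf)
    observed, _ = np.histogram(x, bins=np.concatenate(([lo * 0.999999], edges[1:-1], [hi])))
    # pool adjacent bins until expected >= 5
    pe, po = [], []
    acc_e = acc_o = 0.0
    for e, o in zip(expected, observed):
        acc_e += e
        acc_o += o
        if acc_e >= 5.0:
            pe.append(acc_e)
            po.append(acc_o)
            acc_e = acc_o = 0.0
    if acc_e > 0 or acc_o > 0:
        if pe:
            pe[-1] += acc_e
            po[-1] += acc_o
        else:
            pe, po = [acc_e], [acc_o]
    pe_arr = np.array(pe)
    po_arr = np.array(po)
    stat = float(((po_arr - pe_arr) ** 2 / pe_arr).sum())
    dof = max(1, len(pe_arr) - 1 - n_params)
    pvalue = float(stats.chi2.sf(stat, dof))
    return stat, pvalue


def fit_exponential_mixture(samples, k: int = 1) -> ExpFitResult:
    """Maximum-likelihood fit of a k-component exponential mixture.

    Amplitudes sum to one; time constants are in ms.  The fit is flagged
    ``accepted`` when the chi-square goodness of fit does not reject at
    the 5% level, and ``degenerate`` when components collapse (nearly
    equal time constants or a vanishing amplitude), which signals that k
    exceeds the number of identifiable components.
    """
    x = np.asarray(samples, dtype=float)
    if x.ndim != 1 or x.size < MIN_SAMPLES:
        raise ValidationError(f"need at least {MIN_SAMPLES} positive samples")
    if not np.all(x > 0):
        raise ValidationError("samples must be positive durations")
    if k < 1:
        raise ValidationError("k must be >= 1")
    w, taus, ll = _em_exponential(x, k)
    degenerate = False
    if k > 1:
        # the k-mixture family nests k=1; if EM stalled short of the embedded
        # single-exponential optimum, return that boundary solution instead
        ll1 = float(-x.size * (np.log(x.mean()) + 1.0))
        if ll < ll1:
            w = np.full(k, 1.0 / k)
            taus = np.full(k, x.mean())
            ll = ll1
        rel_gap = np.min(np.diff(taus) / taus[1:])
        degenerate = bool(rel_gap < 1e-3 or w.min() < 1e-6)
    n_params = 2 * k - 1
    stat, pvalue = _chi2_gof(x, w, taus, n_params)
    return ExpFitResult(
        n_components=k,
        amplitudes=w,
        time_constants=taus,
        log_likelihood=ll,
        gof_statistic=stat,
        gof_pvalue=pvalue,
        accepted=bool(pvalue >= GOF_LEVEL),
        degenerate=degenerate,
        n_samples=x.size,
    )


# ---------------------------------------------------------------------------
# threshold scoring and the R0 scan
# ---------------------------------------------------------------------------


def score_threshold(
    clusters: list[Cluster],
    sequences: list[DwellSequence],
    min_cluster_size: int = 50,
) -> tuple[int, int, float]:
    """Classify each sufficiently occupied cluster as mono- or bi-exponential.

    For every cluster with more than ``min_cluster_size`` members, single
    and double exponential fits are made to the member dwell-times along
    each of the N coordinate dimensions.  A dimension *needs* the double
    fit when the mono-exponential fit is rejected by the goodness-of-fit
    test and the two-component fit improves the likelihood significantly
    (ratio test, 5% level) — a rejection that a second component cannot
    absorb (e.g. an under-dispersed multi-substate dwell) does not count
    against route purity.  A cluster is "single-ok" when no dimension
    needs the double fit, otherwise "double-needed".  Returns
    (n_single_ok, n_double_needed, ratio) with ratio = NaN when no
    cluster is single-ok (undefined).
    """
    lr_crit = stats.chi2.ppf(1.0 - GOF_LEVEL, 2)  # 2 extra mixture params
    by_origin = {s.origin_index: s.values for s in sequences}
    n_single = n_double = 0
    for c in clusters:
        if c.cardinality <= min_cluster_size:
            continue
        vals = np.array([by_origin[m] for m in c.members])
        single_ok = True
        for d in range(vals.shape[1]):
            f1 = fit_exponential_mixture(vals[:, d], k=1)
            if f1.accepted:
                continue
            # mono-exponential rejected: the double fit is "needed" only if
            # it actually improves significantly (likelihood ratio); a
            # misfit a second component cannot absorb does not count
            f2 = fit_exponential_mixture(vals[:, d], k=2)
            if not f2.degenerate and 2.0 * (f2.log_likelihood - f1.log_likelihood) > lr_crit:
                single_ok = False
                break
        if single_ok:
            n_single += 1
        else:
            n_double += 1
    ratio = (n_double / n_single) if n_single > 0 else float("nan")
    return n_single, n_double, ratio


def _evaluate_r0(
    pools: dict[str, list[DwellSequence]],
    r0: float,
    min_cluster_size: int,
    large_size: int,
    max_iter: int,
) -> R0ScanRow:
    all_clusters: list[Cluster] = []
    for pool in pools.values():
        passed = cluster_pass(pool, r0)
        refined, _ = refine_clusters(passed, pool, r0, max_iter=max_iter)
        all_clusters.extend(refined)
    # score against the matching pool per cluster
    n_single = n_double = 0
    for state, pool in pools.items():
        sub = [c for c in all_clusters if c.start_state == state]
        s, d, _ = score_threshold(sub, pool, min_cluster_size)
        n_single += s
        n_double += d
    ratio = (n_double / n_single) if n_single > 0 else float("nan")
    n_large = sum(1 for c in all_clusters if c.cardinality >= large_size)
    return R0ScanRow(
        r0=r0,
        n_clusters=len(all_clusters),
        n_large_clusters=n_large,
        n_single_ok=n_single,
        n_double_needed=n_double,
        ratio=ratio,
    )


def scan_R0(
    sequences: list[DwellSequence],
    coarse_grid: tuple[float, ...] = COARSE_GRID,
    fine_step: float = 0.01,
    min_cluster_size: int = 50,
    small_data_limit: int = 6000,
    retention_fraction: float = 0.75,
    max_iter: int = 100,
) -> R0ScanResult:
    """Screen the correlation threshold and pick the optimum.

    Clusters and refines the O- and C-start pools at every coarse R0, then
    on a fine grid (step ``fine_step``) spanning the neighbours of the
    coarse minimum, and selects the R0 minimizing the double/single
    exponential-fit ratio.  With fewer than ``small_data_limit`` sequences
    the candidates are restricted to thresholds that retain at least
    ``retention_fraction`` of the grid-maximum number of highly occupied
    clusters (>= ``min_cluster_size`` members), guarding against the
    proliferation of poorly occupied clusters at high R0.
    """
    if len(sequences) < 100:
        warnings.warn("fewer than 100 sequences: the R0 scan may be unstable")
    pools: dict[str, list[DwellSequence]] = {}
    for state in ("O", "C"):
        pool = [s for s in sequences if s.start_state == state]
        if pool:
            pools[state] = sort_by_product(pool)
    if not pools:
        raise ValidationError("no sequences to scan")

    coarse = sorted(set(round(float(g), 6) for g in coarse_grid))
    rows: dict[float, R0ScanRow] = {}
    for g in coarse:
        rows[g] = _evaluate_r0(pools, g, min_cluster_size, min_cluster_size, max_iter)
        log.info(
            "R0=%.2f: %d clusters, %d large, single=%d double=%d ratio=%s",
            g, rows[g].n_clusters, rows[g].n_large_clusters,
            rows[g].n_single_ok, rows[g].n_double_needed, rows[g].ratio,
        )

    defined = [g for g in coarse if rows[g].ratio_defined]
    if not defined:
        raise ValidationError(
            "double/single ratio undefined at every screened R0; choose R0 manually"
        )
    coarse_opt = min(defined, key=lambda g: (rows[g].ratio, g))
    # fine grid between the coarse optimum's neighbours
    i = coarse.index(coarse_opt)
    lo = coarse[i - 1] if i > 0 else coarse_opt
    hi = coarse[i + 1] if i + 1 < len(coarse) else coarse_opt
    fine = np.round(np.arange(lo, hi + fine_step / 2, fine_step), 6)
    for g in fine:
        g = float(g)
        if g not in rows:
            rows[g] = _evaluate_r0(pools, g, min_cluster_size, min_cluster_size, max_iter)

    grid = [rows[g] for g in sorted(rows)]
    small_data = len(sequences) < small_data_limit
    candidates = [r for r in grid if r.ratio_defined]
    if small_data:
        max_large = max(r.n_large_clusters for r in grid)
        candidates = [
            r for r in candidates
            if r.n_large_clusters >= retention_fraction * max_large
        ]
        if not candidates:
            raise ValidationError(
                "no R0 candidate satisfies the 75% retention rule with a defined "
                "ratio; choose R0 manually"
            )
    optimum = min(candidates, key=lambda r: (r.ratio, r.r0)).r0
    return R0ScanResult(grid=grid, optimum=optimum, small_data_rule_applied=small_data)
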