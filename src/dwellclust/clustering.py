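"""Greedy template-growing clustering of cross-correlated dwell-time
sequences, followed by a consistency refinement.

The pass works on the product-sorted pool of one start state.  The first
unconsumed sequence seeds a cluster and becomes the comparative template;
the remaining pool is scanned in order, and every sequence whose
cross-correlation with the *current* template reaches the threshold R0 is
absorbed: the template becomes the weighted mean

    template <- (w * template + seq) / (w + 1),  w <- w + 1

(so after the pass the template is the plain arithmetic mean of the
members) and the sequence's origin index is excluded.  When the scan is
exhausted the next unconsumed sequence seeds a new cluster, until the pool
is empty.  Because the template drifts while members accrete, an early
member can end up under-correlated with the final template; the refinement
sweep repeatedly displaces such members — each joins the first existing
cluster (descending cardinality) whose template it matches at R0, or seeds
a new singleton — until no corrections are needed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .core_io import Cluster, DwellSequence, DwellSeries, ValidationError
from .sequences import extract_sequences, is_constant, sort_by_product

log = logging.getLogger(__name__)

#: tolerance on R >= R0 comparisons (guards exact-tie cases like R0 = 1.0
#: against rounding in the normalized dot product)
R_TOL = 1e-12

__all__ = ["cluster_pass", "refine_clusters", "cluster", "ClusterResult"]


def _standardize(v: np.ndarray) -> np.ndarray | None:
    """Center and unit-normalize; None for a constant vector."""
    c = v - v.mean()
    n = np.sqrt(np.dot(c, c))
    if n == 0.0:
        return None
    return c / n


def cluster_pass(sequences: list[DwellSequence], r0: float) -> list[Cluster]:
    """One greedy aggregation pass over a product-sorted, same-state pool.

    Every input sequence ends up in exactly one cluster (possibly a
    singleton).  The procedure is fully deterministic.

    Parameters
    ----------
    sequences : list of DwellSequence
        Same start_state, sorted by decreasing dwell-time product, no
        constant (zero-variance) sequences.
    r0 : float
        Cross-correlation acceptance threshold, 0 < r0 <= 1.
    """
    if not sequences:
        return []
    if not (0.0 < r0 <= 1.0):
        raise ValidationError("R0 must lie in (0, 1]")
    start_state = sequences[0].start_state
    if any(s.start_state != start_state for s in sequences):
        raise ValidationError("cluster_pass needs a single start_state pool")
    vals = np.array([s.values for s in sequences], dtype=float)
    if any(is_constant(v) for v in vals):
        raise ValidationError("constant sequences must be filtered out before clustering")
    prods = np.array([s.product for s in sequences])
    if np.any(prods[1:] > prods[:-1] * (1 + 1e-12)):
        raise ValidationError("sequences must be sorted by decreasing product")

    centered = vals - vals.mean(axis=1, keepdims=True)
    z = centered / np.sqrt((centered**2).sum(axis=1, keepdims=True))

    n = len(sequences)
    active = np.ones(n, dtype=bool)
    clusters: list[Cluster] = []
    seed = 0
    while True:
        while seed < n and not active[seed]:
            seed += 1
        if seed >= n:
            break
        active[seed] = False
        members = [seed]
        tsum = vals[seed].copy()
        w = 1
        j = seed + 1
        while j < n:
            zt = _standardize(tsum / w)
            if zt is None:  # template degenerated to a constant: R undefined
                break
            cand = np.nonzero(active[j:])[0]
            if cand.size == 0:
                break
            r = z[j + cand] @ zt
            hits = np.nonzero(r >= r0 - R_TOL)[0]
            if hits.size == 0:
                break
            k = j + int(cand[hits[0]])
            members.append(k)
            tsum += vals[k]
            w += 1
            active[k] = False
            j = k + 1
        clusters.append(
            Cluster(
                template=tsum / w,
                members=[sequences[m].origin_index for m in members],
                start_state=start_state,
            )
        )
    log.debug("cluster_pass: %d sequences -> %d clusters at R0=%.3g", n, len(clusters), r0)
    return clusters


def refine_clusters(
    clusters: list[Cluster],
    sequences: list[DwellSequence],
    r0: float,
    max_iter: int = 100,
) -> tuple[list[Cluster], bool]:
    """Displace under-correlated members until every cluster is consistent.

    A member whose cross-correlation with its own cluster's template falls
    below ``r0`` is removed (template updated immediately) and joins the
    first existing other cluster, in descending-cardinality order, whose
    template it matches at ``r0``; failing that it seeds a new singleton.
    Sweeps repeat until a fixed point — every member correlates at least
    ``r0`` with its final template — or ``max_iter`` sweeps.

    Returns the refined clusters and a convergence flag.
    """
    if max_iter < 1:
        raise ValidationError("max_iter must be >= 1")
    by_origin = {s.origin_index: s.values for s in sequences}
    # mutable working copies: member origin lists + running sums
    work = [
        {"members": list(c.members), "sum": np.sum([by_origin[m] for m in c.members], axis=0),
         "state": c.start_state}
        for c in clusters
    ]

    def template(wc) -> np.ndarray:
        return wc["sum"] / len(wc["members"])

    converged = False
    for sweep in range(max_iter):
        moved = False
        ci = 0
        while ci < len(work):
            wc = work[ci]
            # audit members in membership order against the current template;
            # fix the first violation and re-audit (template moved)
            while len(wc["members"]) > 1:
                t = template(wc)
                zt = _standardize(t)
                bad = None
                if zt is None:
                    bad = 0  # constant template: nobody can satisfy R >= r0
                else:
                    mv = np.array([by_origin[m] for m in wc["members"]])
                    mc = mv - mv.mean(axis=1, keepdims=True)
                    norms = np.sqrt((mc**2).sum(axis=1))
                    r = (mc @ zt) / norms
                    viol = np.nonzero(r < r0 - R_TOL)[0]
                    if viol.size:
                        bad = int(viol[0])
                if bad is None:
                    break
                origin = wc["members"].pop(bad)
                wc["sum"] = wc["sum"] - by_origin[origin]
                moved = True
                _reassign(origin, by_origin[origin], work, wc, r0)
            ci += 1
        work = [wc for wc in work if wc["members"]]
        if not moved:
            converged = True
            break
    if not converged:
        log.warning("refinement did not converge within %d sweeps", max_iter)
    refined = [
        Cluster(template=template(wc), members=list(wc["members"]), start_state=wc["state"])
        for wc in work
    ]
    return refined, converged


def _reassign(origin: int, values: np.ndarray, work: list[dict], source: dict, r0: float) -> None:
    """Place a displaced sequence: first fitting cluster by descending
    cardinality (stable order on ties), else a new singleton."""
    order = sorted(
        (wc for wc in work if wc is not source and wc["members"]),
        key=lambda wc: -len(wc["members"]),
    )
    zx = _standardize(values)
    for wc in order:
        zt = _standardize(wc["sum"] / len(wc["members"]))
        if zt is None:
            continue
        if float(zx @ zt) >= r0 - R_TOL:
            wc["members"].append(origin)
            wc["sum"] = wc["sum"] + values
            return
    work.append({"members": [origin], "sum": values.copy(), "state": source["state"]})


@dataclass
class ClusterResult:
    """Clusters of both start-state pools plus coverage diagnostics."""

    o_clusters: list[Cluster]
    c_clusters: list[Cluster]
    coverage: float
    diagnostics: dict = field(default_factory=dict)

    @property
    def clusters(self) -> list[Cluster]:
        return self.o_clusters + self.c_clusters


def cluster(
    series: DwellSeries,
    n: int,
    r0: float,
    min_members_for_coverage: int = 10,
    max_iter: int = 100,
) -> ClusterResult:
    """Full pipeline: extract -> sort -> greedy pass -> refinement, run
    independently for the O-start and C-start pools.

    ``coverage`` is the fraction of dwell events that appear in at least
    one sequence belonging to a cluster with >= ``min_members_for_coverage``
    members — the guidance being that well-chosen N leaves clusters with at
    least 10 representatives covering more than half of the raw data.
    """
    pools: dict[str, list[DwellSequence]] = {}
    results: dict[str, list[Cluster]] = {}
    diagnostics: dict = {"n_constant_excluded": 0, "converged": {}}
    for state in ("O", "C"):
        seqs = extract_sequences(series, n, state)
        nonconst = [s for s in seqs if not is_constant(s.values)]
        n_const = len(seqs) - len(nonconst)
        if n_const:
            log.warning(
                "%d constant %s-start sequences excluded (correlation undefined)",
                n_const, state,
            )
        diagnostics["n_constant_excluded"] += n_const
        pool = sort_by_product(nonconst)
        pools[state] = pool
        passed = cluster_pass(pool, r0)
        refined, conv = refine_clusters(passed, pool, r0, max_iter=max_iter)
        results[state] = refined
        diagnostics["converged"][state] = conv
        diagnostics[f"n_{state}_sequences"] = len(pool)

    covered = np.zeros(len(series), dtype=bool)
    for state in ("O", "C"):
        for c in results[state]:
            if c.cardinality >= min_members_for_coverage:
                for origin in c.members:
                    covered[origin : origin + n] = True
    coverage = float(covered.mean())
    diagnostics["coverage_rule"] = (
        f">= {min_members_for_coverage} members; target coverage > 0.5"
    )
    return ClusterResult(
        o_clusters=results["O"],
        c_clusters=results["C"],
        coverage=coverage,
        diagnostics=diagnostics,
    )
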