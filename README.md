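# dwellclust

Cross-correlation clustering of single-ion-channel dwell-time sequences.

Single-channel patch-clamp recordings reduce to an alternating series of
open (O) and closed (C) dwell-times τ.  A channel's gating is usually
modelled as an *aggregated Markov process*: a chain over conformational
substates of which the recording only reveals the functional class, so a
sojourn through two closed substates lasting 3 and 9 time units is observed
as a single 12-unit closure.  Instead of reconstructing the full rate
matrix — a famously ill-posed problem — `dwellclust` builds a *phase-space
fingerprint* of the channel: it finds short dwell-time sequences that
repeat throughout the record, groups the mutually correlated ones, and
represents each group as a point (with occupancy and dispersion) in the
N-dimensional space of dwell-times.  Those clusters track the channel's
dominant substate routes and how they move when conditions (e.g. membrane
potential) change.

## Method

1. **Idealization** — a current trace is thresholded into O/C events; the
   threshold is the equal-posterior crossing of a two-Gaussian fit to the
   amplitude histogram.
2. **Sequences** — all overlapping N-element windows (default N = 3) of
   O–C–O–… and C–O–C–… type are enumerated and sorted by decreasing
   product of their dwell-times, so the search starts from the longest
   sequences.  Similarity between windows X and Y is the cross-correlation

   R = Σᵢ(Xᵢ−X̄)(Yᵢ−Ȳ) / √( Σᵢ(Xᵢ−X̄)² · Σᵢ(Yᵢ−Ȳ)² ),

   which is invariant under positive affine rescaling: sequences equal in
   *shape* but different in amplitude — the signature of broad exponential
   dwell-time distributions — count as realizations of the same route.
3. **Clustering** — a greedy pass grows clusters by absorbing, in sorted
   order, every window with R ≥ R₀ against the running weighted-mean
   template; a refinement sweep then displaces members that ended up
   under-correlated with their final template, until no corrections are
   needed.  O-start and C-start pools are clustered independently.
4. **Threshold selection** — R₀ is screened over a grid (0.80–0.97); at
   each value the member dwell-times of every well-occupied cluster are fit
   with single and double exponential mixtures per coordinate, and the R₀
   minimizing the ratio of double- to single-exponential verdicts is
   selected.  With < 6000 sequences, candidates must retain ≥ 75 % of the
   grid-maximum number of clusters with ≥ 50 members.
5. **Phase space** — clusters become spheres at their template coordinates
   (ms), with volume growing with log occupancy; distances between centers
   are Euclidean.

A built-in aggregated-Markov simulator (continuous-time Markov chain over
substates, exponential sojourns, class aggregation, optional Gaussian-noise
current synthesis at 10 kHz) provides ground-truth data for every stage.

## Worked example

```python
import numpy as np
import dwellclust as dc

# simulate a channel with two weakly coupled gating pathways:
# O-C-O mean triples (1, 20, 1) ms and (8, 2, 8) ms
series = dc.simulate_dwell_series(dc.fixture_scheme("two_pathway"), 30000, 7)
print("events:", len(series), " p_open:", round(dc.open_probability(series), 3))

res = dc.cluster(series, n=3, r0=0.9)
big = sorted((c for c in res.o_clusters if c.cardinality >= 10),
             key=lambda c: -c.cardinality)
print("O-clusters with >=10 members:", len(big))
for c in big[:3]:
    print(f"  cardinality {c.cardinality:5d}  center {np.round(c.template, 2)}")
print("coverage:", round(res.coverage, 3))
```

prints

```
events: 7878  p_open: 0.318
O-clusters with >=10 members: 9
  cardinality  1795  center [ 1.02 20.01  1.08]
  cardinality   786  center [11.08  1.9   5.23]
  cardinality   728  center [ 6.56  1.85 10.11]
coverage: 1.0
```

The largest cluster sits on the short-open pathway's true mean triple
(1, 20, 1) ms; the next two are shape-split halves of the long-open
pathway (8, 2, 8) ms.  Every dwell event is covered by a cluster with at
least 10 members (`coverage` = 1.0), the regime in which the sequence
length N is considered well chosen.

The same pipeline is available from the shell:

```sh
dwellclust simulate --scheme two_pathway --sojourns 30000 --seed 7 --dwells-out d.csv
dwellclust cluster  --dwells d.csv --n 3 --r0 0.9 --output clusters.json
dwellclust scan-r0  --dwells d.csv --n 3 --output scan.json
dwellclust plot     --clusters clusters.json --start O --output phase.png
```

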