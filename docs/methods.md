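# Methods

## Signal model and assumptions

Channel gating is modelled as a continuous-time Markov chain over
conformational substates, each belonging to a functional class, open (O)
or closed (C).  Sojourns are exponential with mean 1/Σⱼ kᵢⱼ and the
successor is drawn with probability kᵢⱼ/Σⱼ kᵢⱼ.  Only the class is
observable, so consecutive same-class sojourns aggregate into one observed
dwell; an observed dwell is therefore a single exponential (one substate)
or a hypoexponential (a route through several).  All durations are in ms;
traces carry a sampling interval `dt` defaulting to 0.1 ms (10 kHz
acquisition with 1 kHz analog filtering is the regime the defaults are
chosen for).

The method assumes that a stable substate's entry/exit routes recur many
times in a long recording, so windows of N consecutive dwell-times repeat
in *shape* (amplitudes vary because exponential dwells are broad).  The
cross-correlation of two windows is used as the similarity measure exactly
because it is invariant under positive affine rescaling.

## Idealization

The O/C threshold is the equal-posterior crossing of a two-component
Gaussian mixture fitted to the amplitude histogram
(`sklearn.mixture.GaussianMixture`, deterministic percentile
initialization).  Bimodality is enforced before the threshold is returned:
the fitted modes must be separated by at least twice the pooled standard
deviation and both weights must exceed 2 %; otherwise the caller is asked
for a manual threshold.  When the posteriors do not cross between the
modes the midpoint is used.

Run-length encoding converts samples to events (duration = count × dt).
An optional dead-time filter folds events shorter than `min_duration` into
the *preceding* event and re-merges same-state neighbours; a leading short
event, which has no predecessor, is carried into the first surviving
event.  First and last events are kept but flagged censored, and sequence
extraction skips windows touching them by default.  The summed event
durations always equal the trace duration.

The dead-time interacts with noise near true transitions: a noise blip
landing within the dead time *after* an edge can erase the edge (the short
first run of the new state folds backwards).  With a 2-sample dead time
(0.2 ms at 10 kHz) only a blip in the single sample adjacent to the edge
can do this, which is what keeps transition recovery above 99 % at a noise
SD of 20 % of the amplitude; longer dead times lose proportionally more
edges.  The transition-recovery experiment in the test-suite/acceptance
script uses 3-stage (Erlang) dwells with means 10/30 ms: with
single-exponential dwells, the probability of a true dwell shorter than
any fixed dead time is ~deadtime/τ and unresolvable events would dominate
the error budget regardless of the detector.

## Sequences and clustering

Windows of N dwell-times are enumerated per start state (O-start windows
are never compared with C-start windows) and sorted by decreasing product
of their durations, ties stable by origin.  N defaults to 3 — the smallest
length that still allows direct 3-D visualization; N = 2 is allowed but
degenerate (R = ±1 always) and warned about.  Constant windows (zero
variance, correlation undefined) are excluded from clustering and counted
in the diagnostics.

The greedy pass seeds a cluster with the first unconsumed window, scans
the remainder in sorted order, and absorbs any window with R ≥ R₀ against
the *current* template, updating template ← (w·template + x)/(w+1); with
unit member weights the final template equals the plain mean of the
members.  Because the template drifts as members accrete, a refinement
sweep audits every member against its cluster's final template: a member
below R₀ is removed (template updated immediately) and joins the first
other cluster, in descending cardinality order, whose template it matches,
or seeds a new singleton.  Sweeps repeat to a fixed point (bounded by
`max_iter` = 100, with a convergence flag).  Both stages are fully
deterministic; R ≥ R₀ comparisons carry a 1e-12 tolerance so that exact
ties (R₀ = 1 with identical windows) behave.

One empirical caveat: the maximum cluster cardinality is *not* monotone in
R₀ — refinement reassignment can concentrate membership so that a higher
threshold occasionally yields a larger top cluster.

Coverage is reported as the fraction of dwell events appearing in at
least one window that belongs to a cluster with ≥ 10 members; a sequence
length is considered well chosen when such clusters cover more than half
of the data.

## Exponential mixture fits and threshold selection

Mixtures of k exponentials are fit by maximum likelihood: k = 1 in closed
form (τ̂ = sample mean), k ≥ 2 by EM with deterministic moment-based
initialization (τ init = mean × {1/2, 2} for k = 2, equal amplitudes),
relative log-likelihood tolerance 1e-8, 500-iteration cap.  If EM stalls
below the embedded single-exponential optimum the collapsed boundary
solution is returned, so nesting (LL(k=2) ≥ LL(k=1)) always holds;
collapsed or vanishing components are flagged `degenerate` rather than
raised.  Goodness of fit is a Pearson χ² on log-spaced histogram bins
pooled left-to-right to ≥ 5 expected counts, with dof = bins − 1 − (2k−1);
a fit is `accepted` at p ≥ 0.05.  On pure exponential samples the
acceptance rate of the k = 1 fit sits at the nominal level (~95 %); the
usual caveat applies that parameters are estimated from unbinned data, so
the statistic's null distribution lies between χ²(m−1−p) and χ²(m−1).

For threshold selection, every cluster with more than 50 members is
classified per coordinate dimension.  A dimension *needs* the double fit
only when (a) the χ² test rejects the mono-exponential fit **and** (b) the
two-component fit improves the log-likelihood significantly (likelihood
ratio > χ²₀.₉₅(2)).  Condition (b) matters: within a cluster the
coordinate marginals are shape-conditioned (the cluster membership itself
truncates them) and composite dwells are hypoexponential, so a pure-route
cluster still fails a raw χ² test at large n even though a second
exponential component cannot improve the fit — exponential mixtures can
only widen a distribution (CV ≥ 1), never narrow it.  Classifying by χ²
alone makes every well-occupied cluster "double-needed" and the selection
ratio degenerate; the LR condition restores the intended meaning of
"double exponential fits versus single exponential fits".  A cluster is
single-ok when no dimension needs the double fit.

The scan screens R₀ over a coarse grid (default 0.80–0.97 in steps of
0.05, endpoints included) plus a 0.01-step fine grid spanning the coarse
minimum's neighbours, and selects the R₀ minimizing the
double-needed/single-ok ratio (ties to the lower R₀).  Below 6000
sequences, candidates are restricted to thresholds retaining at least 75 %
of the grid-maximum number of clusters with ≥ 50 members; the reference
count is the grid maximum (the rule's alternative reading — the count at
the coarsest R₀ — is not used).

## Phase space

A cluster summary is its template (center, ms), cardinality, occupancy
fraction (cardinality / total windows; > 5 % flags a dominant route) and
per-dimension member standard deviation.  Distances between centers are
Euclidean.  In renderings, sphere volume is log(1 + s·occupancy) with
scale s = 100 by default — the logarithm keeps rare clusters visible —
and centers are orthographically projected as dots onto the τ₁τ₃ plane.
Cross-condition comparisons draw each condition in its own color; no
numeric output depends on plotting.

## Synthetic data

The simulator is the package's ground-truth backbone.  Three schemes ship
as YAML configs:

- **fig1** — a five-substate toy (C5, O3, O4, C6, C7; mean dwells 5, 1,
  3, 3, 9 time units).  Routing probabilities (0.85 for O3→O4, 0.9 for
  C6→C7) make the composite 12-unit closure and 4-unit opening the modal
  observations; only the five mean dwells are externally fixed, the rates
  realizing them are this package's choice and live in the config.
- **two_pathway** — two weakly coupled O/C loops for recovery
  experiments, with O–C–O mean triples (1, 20, 1) and (8, 2, 8) ms and a
  2 % cross-link per closed cycle.  The pathways must differ in *shape*:
  correlation is amplitude-invariant, so proportional triples (e.g.
  (1, 2, 1) vs (8, 20, 8)) are indistinguishable by construction.  Dwells
  are multi-stage hypoexponentials (open 3 stages; closed 3 stages in A,
  6 in B), narrowing the dwell CV so that shape-selection bias on the
  cluster templates stays well inside the 15 % recovery tolerance; with
  single-stage (CV = 1) dwells the conditional mean of a shape-selected
  cluster is biased by ~30 % and recovery at that tolerance is impossible
  for any clustering method using this similarity measure.
- **bk_like** — 3 open + 5 closed substates with plausible (not fitted)
  rates, for topology-scale smoke tests.

What the generator does *not* emulate: voltage- or Ca²⁺-dependent rates,
sub-conductance levels, 1/f or correlated instrument noise, analog-filter
rise times, baseline drift, or missed-event artifacts beyond the dead-time
filter itself.  Passing tests therefore validate the algorithmic chain
under ideal aggregated-Markov assumptions, not robustness to every
artifact of real recordings.

## Problem sizes and defaults in the shipped experiments

The recovery experiment clusters 5000 aggregated events (N = 3,
R₀ = 0.9); the threshold scan uses ~12 000 windows over the reduced grid
{0.80, 0.90, 0.95} plus the fine grid, with the 75 %-retention branch
audited on a 500-window subsample; simulator calibration uses 10⁴
sojourns; fit calibration uses 200 replicates of 300 samples.  These sizes
keep every experiment deterministic-seeded and fast while leaving the
statistical tolerances (3 SE bounds, 15 % recovery, ±5 points on the
calibration rate) meaningful.

## Known limitations

- Greedy, order-dependent clustering: results depend on the
  product-descending processing order (by design, matching the published
  procedure); there is no probabilistic assignment.
- The refinement fixed point is not guaranteed to be unique; `max_iter`
  caps pathological cycling and the convergence flag reports it.
- Correlation of N = 3 windows lives on a one-dimensional shape circle,
  so distinct routes with proportional mean triples cannot be separated —
  a structural property of the similarity measure, not an implementation
  limit.
- No rate-matrix reconstruction is attempted from the clusters.
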