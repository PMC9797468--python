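# Methods

`demeflow` turns longitudinal RFID nest-box records of a rodent enclosure
into a time-layered social network, finds modules that persist across time by
minimizing the map-equation description length, and asks which of those
modules behave as reproductive units (demes) given a resolved pedigree. This
note documents the models, the parameter choices and their rationale, the
numerical decisions, and the limits of what the synthetic-data tests show.

## From reader events to visits

Every nest box has a pair of antennas at its entrance. A credible *entry* is
an outer read immediately followed by an inner read at the same box by the
same individual (entry time = the inner-read time); a credible *exit* is the
reverse pair (exit time = the outer-read time). An entry is paired with the
next exit from the same box; a new credible entry before that exit closes
the open visit at the new entry's inner-read time, since the animal has
demonstrably left. Every other signal is *equivocal*: it is dropped and
counted in a log summary, never raised as an error, because stray reads are
a normal feature of transponder hardware.

The convention that a visit runs from the inner-read of the entry to the
outer-read of the exit is one of several defensible choices; any consistent
convention shifts all pairwise overlaps by the same sub-second amounts, so
nothing downstream depends on it.

Records made during an enclosure check, and from then until the next
midnight, are censored: checks are experimenter disturbances and the animals'
behaviour afterwards is not representative. Visits that span a censored
window are clipped at its boundaries so that every retained second of visit
time lies outside censored periods. Time is held internally as seconds since
the start of the record, with one day = 86 400 s; midnight boundaries are
multiples of a day on this axis.

## Time layers

The censored record is cut into *time layers*, each treated as one snapshot
of the social structure:

1. split at every enclosure-wide silence longer than `gap_max_hours`
   (default 1 h) — a gap is an interval with no reads from any reader, since
   layers are population snapshots, not per-individual ones;
2. split any fragment longer than `layer_max_hours` (default 48 h) into
   consecutive pieces measured from the fragment start;
3. iteratively merge any layer whose first-to-last-event span is under
   `layer_min_hours_for_merge` (default 24 h) into its nearest neighbour
   (smaller inter-event gap; ties go to the earlier neighbour), shortest
   first, until none remains or only one layer is left.

Merging can produce layers longer than 48 h; spans of roughly 24–107 h, most
under 72 h, are the expected outcome on realistic check schedules. A layer's
position on the time axis is its mid-time in days. A visit spanning a layer
boundary is split and its time apportioned to each side, preserving total
co-occupancy time.

## The per-layer social network

The edge weight between two individuals in a layer is the total time their
visit intervals overlap in the same box, in seconds, irrespective of who else
was present — a triple co-stay credits all three pairs. Individuals with at
least one visit but no overlaps remain as isolated vertices; individuals with
no visits in a layer are absent from it. The result is a symmetric
nonnegative matrix with zero diagonal per layer.

## Map equation, modularity, and the multilayer extension

A partition of the network's nodes into modules is scored by the two-level
map equation: the expected per-step description length, in bits, of a random
walk encoded with one index codebook over modules and one codebook per
module,

    L = q H(Q) + Σ_m p_m⟳ H(P_m),

where q is the total module-exit flow, H(Q) the entropy of the normalized
exit flows, and each module codebook covers its members' visit rates plus
the module's exit flow. The one-module partition has no index codebook and
L equals the entropy of the visit rates. Modularity is reported as the
compression rate

    M = L_before / L_after,

the one-module codelength over the partitioned one. M = 1 means no
compressible structure; the optimizer only ever accepts improvements over
the one-module solution, so M ≥ 1 by construction.

Visit rates are the stationary distribution of the row-normalized flow with
a uniform teleportation τ = 0.01 (configurable) guaranteeing ergodicity;
dangling nodes teleport uniformly. Teleportation flow is recorded in module
transitions. τ = 0 is accepted for exact hand-checkable fixtures. The power
iteration is *lazy* (each step averages with the previous iterate), which
leaves the fixed point unchanged but converges on periodic structures such
as bipartite paths.

Layers are coupled into one directed state network over (individual, layer)
pairs. Intra-layer links carry (1 − r) of a state node's strength, where
r ∈ [0, 1] is the relax rate. The remaining fraction r is spread over the
individual's neighborhoods in other layers, each candidate layer weighted by
the similarity of the individual's normalized neighbor-weight profile there
to its profile in the current layer. Similarity is the overlap coefficient
σ_i(l,l′) = Σ_j min(ŵ_ij^l, ŵ_ij^l′) ∈ [0, 1], normalized over candidate
layers; links then point at the other layer's neighbors in proportion to
their normalized weights, scaled by the node's current-layer strength. Cross-
layer links are therefore strong exactly when an individual keeps the same
neighbors with similar weights. Disjoint neighborhoods get no cross-layer
flow. When an individual has *no* similar layer at all (total σ = 0, e.g. a
single-layer record), the relaxed share has nowhere to go and stays within
the layer; this keeps single-layer networks well-defined at every r. The
overlap-coefficient construction is isolated behind one function so that
alternatives (e.g. cosine similarity) can be swapped without touching the
optimizer.

## Minimizing L

Optimization is Louvain-style: starting from singletons, nodes are swept in
rng-shuffled order and each is moved to the best-improving module among
those it touches; converged levels are aggregated and the sweep repeats,
until no move reduces L by more than 1e-10 bits (at most 100 outer passes).
Moves are evaluated by an exact incremental form of L maintained from
per-module aggregates (visit rate, teleporting mass, node count, internal
flow).

Temporal networks expose a known weakness of plain Louvain: when a
persistent module crystallizes as per-layer blocks, merging any *two* blocks
increases L (the index codebook grows faster than exit flow shrinks) even
though merging *all* of them decreases it, so greedy local moves stall. The
optimizer therefore runs from two starting points — all singletons, and one
module per individual (the natural prior for temporal data, since an
individual is its own best cross-layer anchor) — and returns the partition
with the smaller codelength. On all fixtures small enough to enumerate
exhaustively (≤ 8 state nodes), this procedure reaches the global minimum;
that equivalence is asserted in the test suite.

Module labels are assigned in order of first appearance (by layer, then by
individual id), which keeps labels stable for longitudinal plots. Ties in
local moves resolve to the first best-improving module in sweep order;
runs are deterministic given the rng seed.

Sex-specific modularity re-evaluates M on a filtered network (female–female,
male–male or female–male edges only, adults only, where adulthood is age ≥
50 days at the layer mid-time) while keeping the partition fixed: it asks
how much of the existing structure each interaction class carries, not what
structure that class alone would produce.

## Choosing the relax rate; the bootstrap

The relax rate is selected by consensus: each experiment is clustered at 21
r values equally spaced on [0, 1]; solutions are compared pairwise with
normalized mutual information, NMI(A,B) = I(A;B)/√(H(A)H(B)) over state
nodes; each r is scored by its mean NMI against the other 20 solutions; the
chosen r* maximizes the median across experiments of these means, with ties
going to the smaller r (less coupling assumed when indifferent). NMI is
defined as 1 when both partitions are single-module and 0 when exactly one
is.

Robustness of M to the record's idiosyncrasies is probed by a
visit-reordering bootstrap: per individual, the ordered sequence of visit
start times stays fixed and the (box, duration) payloads are permuted among
those slots. Every individual then spends exactly the same total time in the
same boxes — conserved bit-exactly on integer-second data — but pairwise
synchrony is disturbed. Associations resting on many repeated synchronized
co-stays largely survive; associations resting on one long coincidental
overlap are typically destroyed. The wording "random reordering" admits more
than one scheme; the fixed-start-slot payload permutation is the default
because it satisfies the conservation property exactly, and a variant that
permutes visits and inter-visit gaps jointly is available
(`bootstrap_replicate_gap_shuffle`). Bootstrap summaries report min/max and
2.5/97.5 % quantiles of M per r.

## Spatial and pedigree-linked statistics

*Distinctiveness* of a layer is the unweighted mean, over individuals with
any interaction time, of the fraction of their interaction time spent with
members of their own module; a time-pooled variant is emitted alongside.
*Spatial separation* divides each box's occupancy time among modules
(solitary time included), takes the maximum share as the box's usage
exclusivity, and averages exclusivities over occupied boxes weighted by
total usage. *Summary networks* average edge weights over a 10-layer window
(absent layers contribute zero), restricted to founders and proven
reproducers, with each vertex labelled by its modal module over the window
(ties to the earliest label) and its sex.

*Multiple paternity* is the mean, over litters with at least two
assigned-father offspring, of the probability that two distinct offspring
drawn without replacement have different fathers,
1 − Σ_f n_f(n_f−1)/(n(n−1)). Offspring with unassigned fathers are excluded
before the litter qualifies.

*Bond persistence* in a layer is the fraction of parent→offspring arrows
whose two ends are assigned to the same module, among arrows with both ends
assigned; mother–daughter and father–son variants filter by parent role and
offspring sex.

*Deme support*: each litter's conception is placed `gestation_days`
(default 20 d) before delivery; the candidate module is the mother's
assignment in the layer containing the conception time (nearest layer if
none contains it); the gestation window is the set of layers whose mid-times
fall between conception and delivery; the litter's support is the fraction
of window layers in which *both* parents are assigned to the candidate
module. Window layers where a parent is unassigned (no visits) count against
the support — the denominator is the layers covering gestation, not the
layers observed; a variant with the reduced denominator can be derived from
the per-litter outputs. Supports are summed per candidate module into an
effective number of parental pairs; a module with zero support is not a
deme. Litters with no assigned father, with an unassignable mother at
conception, or with an empty window are skipped with a warning.

## The synthetic enclosure

The generator emulates the data-generating setting the pipeline targets: a
six-box enclosure with dual-reader entrances, twelve adult founders (six of
each sex, 90 days old at start), 20-day gestation, litters of 3–7, maturity
at 50 days, transpondering of pups at 14 days, occasional emigration, and a
check schedule (1 h every 3 days, 6 h every ~35 days). Modules partition the
boxes as evenly as possible, mirroring observed spatial monopolies.

Movement is built around *communal co-nesting*: each module alternates
dispersed periods (exponential gaps, mean 1 h) with group visits at one of
its home boxes (exponential durations, mean 2 h); members join with
probability 0.85 and ≤ 60 s entry/exit jitter, and make short solo visits
(mean 10 min) in between. A mixing parameter ε sends any given visit to a
box outside the module's home set with probability ε. This makes
within-module edges rest on many long synchronized overlaps — the regime in
which the bootstrap comparison is informative — while cross-module edges
arise from occasional defections. Demography runs at day resolution:
non-pregnant adult females conceive at 0.04/day; the sire is the module's
dominant male with probability `paternity_skew` (default 0.9), otherwise a
uniform draw among the module's adult males. All event times are integer
seconds; the same seed yields byte-identical files.

What the simulator does *not* emulate: light–dark activity cycles, dominance
turnover, density dependence, module fission/fusion, inter-enclosure
connections (migration detection is tested on hand fixtures), and reader
failure beyond optional stray reads. Passing the recovery and monotonicity
tests therefore shows the pipeline recovers planted co-nesting structure of
realistic scale and noise, not that it resolves every structure wild
populations can produce.

Test and validation runs use 10–20 simulated days with the twelve founders
(a few hundred to a few thousand visits, 5–10 layers), which is ample for
two- to three-module recovery while keeping the full suite fast;
longer runs (≥ 45 days) are used where litters must exist.

## Known limitations

- The two-level (non-hierarchical) map equation is implemented; deeply
  nested module structure would be summarized at one level.
- The Louvain search, even with the dual start, is a heuristic; global
  optimality is only guaranteed where enumeration verifies it.
- Teleportation at τ = 0.01 slightly smooths visit rates; M values are
  comparable across runs at fixed τ but not across different τ.
- The deme-support statistic inherits the hard per-layer module assignment;
  "preferential association" below the clustering's resolution is invisible.
- Codelength-based M depends on network size; it is a within-study
  comparison tool, not an absolute effect size.
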