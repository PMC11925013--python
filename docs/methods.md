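# Methods

This note documents the models and procedures implemented in `sdupnet`,
the defaults and why they were chosen, and what the test suite does and
does not establish.

## The SD network

Coordinates are 0-based half-open everywhere internally; BED input is used
unchanged and 1-based table dialects must be converted at parse time (the
`ColumnMap` of `parse_sd_annotation` selects columns, defaulting to the
genomicSuperDups layout with the partner interval in columns 6–8 and
fraction identity in column 26). Sex-chromosome alignments are dropped by
default: the analysis targets autosomal duplications.

Duplicated regions merge alignment intervals that overlap by at least
1 bp; intervals that merely touch are kept separate, since a zero-length
overlap is not evidence of shared sequence. Region construction is
idempotent and regions on a chromosome are disjoint, which makes the
interval→region lookup unambiguous.

The network is a simple graph. An alignment whose two intervals fall in
one region increments that node's self-loop count; parallel alignments
collapse onto one edge carrying their count and maximum identity. These
pre-trim multiplicities are retained because double edges and self-loops
are themselves markers of actively duplicating loci and feed the signature
analysis.

**Suspicious edges.** Two alignments incident to the same region that
share a breakpoint coordinate (start with start, end with end; tolerance
`tol_bp`, default 0) are both flagged, unless the shared breakpoint lies
within `gap_pad_bp` (default 50 bp, the flank width used throughout) of an
assembly gap — gaps truncate alignments at identical coordinates for
reasons unrelated to duplication history. The exact matching rule is a
documented house definition: the precise published rule lives in
supplementary material that only states the idea.

**Communities** use asynchronous label propagation with a seeded node
order and seeded tie-breaks, iterated to a fixed point (networkx's
implementation). Labels are arbitrary; only the partition is meaningful,
and it is deterministic given the seed.

**Cycle census.** Chordless cycles are enumerated up to a configurable
bound (enumeration is exponential; keep the bound ≤ 8) and per-node
shortest self-paths are computed by removing each incident edge and
re-routing. This is a diagnostic, not part of reconstruction.

## Event reconstruction

Edge weights are w(a,b) = 1 − |N(a) ∩ N(b)| / min(k_a, k_b). The weight
is 1 exactly when the endpoints share no neighbors and is always positive
because a ∉ N(a) and b ∉ N(b). Suspicious edges receive a penalty weight
of 2.0 — above the weight range of any normal edge — so they enter the
forest only when a component offers nothing else (a warning is emitted in
that degenerate case).

Kruskal's algorithm runs with a seeded, stable order on equal-weight
edges, making runs bit-reproducible; the source method is silent on ties.
The forest always has exactly N − C edges; acyclicity and size are
asserted on every run.

**Duplication count = forest degree.** With an unrooted forest the
direction of events is unknowable, but the per-node event count is
invariant to the choice of root except at the roots themselves; degree is
the root-free convention and is what all accuracy metrics use.

**Enrichment tests** draw |forest| edges uniformly without replacement
from the non-forest edges per round and use the add-one empirical p-value
(1 + #as-extreme)/(rounds + 1), so p is never exactly 0 and "<10⁻⁴" is
the floor at the default 10,000 rounds.

## The extended copying-model simulator

One simulation step is one event: with probability `p_new` a fresh
two-node component is seeded (an innovation — a duplication whose source
is outside the modeled network), otherwise a mother is drawn with
probability ∝ (degree + α) and duplicated; the daughter always gets the
primary mother–daughter edge and inherits each mother edge independently
with probability `f` at the mother edge's *current* identity. α = 1 keeps
nodes that lost all edges selectable. Within a step the order is growth →
gene conversion → decay; the order is configurable in code but fixed by
default so event logs are comparable.

Identity is a scalar clock per edge: 1.0 at creation, minus `delta` per
step, removed below 0.9 (the SD annotation threshold). Decay is
deterministic-linear; a stochastic clock would only add variance around
the same mean behavior. Identities are stored lazily against a global
decay counter with heap-scheduled expiries, so steps cost O(changes)
rather than O(edges) — a 6,656-node run takes under a second.

NAGC converts each eligible edge per step with probability `r_gc`: the
edge resets to identity 1.0, one endpoint (uniformly chosen — the source
does not specify a donor rule) becomes donor, and for every shared
neighbor the acceptor's identity to that neighbor is overwritten by the
donor's. With evasion (default) only surviving edges are eligible; the
no-evasion variant may resurrect lost edges at identity 1.0.

### Calibration

Defaults were fixed once, against the published human SD-network summary
statistics, before any accuracy benchmarking, and are not tuned further:

| parameter | default | rationale |
|---|---|---|
| `n_final` | 6,656 | SD-network node count |
| `f` | 0.33 | mean edge count ≈ 16k at n_final (SD network: 16,042) |
| `p_new` | 0.42 | mean component count ≈ 2k (SD network: 1,999) |
| `alpha` | 1.0 | keeps degree-0 remnants selectable |
| `delta` | 2.1 × 10⁻⁵ /step | edge lifetime 0.1/delta ≈ run length, so the oldest edges cross the 0.9 floor by run end and mean surviving divergence sits at 5–10%, the regime where per-base mutation and duplication rates are comparable (r_d/r_m ∈ [1, 2]) |
| `r_gc` | 2.25 × 10⁻⁴ /edge/step | ≈ 34% of surviving edges NAGC-affected at run end, matching the published genome-wide estimate |

`calibrate_rgc` re-derives the last value by bisection for any other
parameter set. Edge count in this regime is strongly seed-dependent
(densification is near-critical in f), which is why benchmark results are
reported as means over ≥ 20 replicates.

A consequence of calibrating to ≈ 2,000 components: most components are
small innovation-seeded trees whose every edge is primary. On such
components *any* spanning-tree predictor is exact, so pooled random-tree
baselines are far stronger than they would be on a single dense network,
and pooled degree-based R² suffers from the scale mismatch between dense
and tree-like components. Comparisons with accuracy figures obtained on
denser validation networks should be made on the giant component, where
behavior is qualitatively different from the trivial components.

### A note on cycles

A daughter can only acquire neighbors from its mother, so every inherited
edge is born inside a daughter–mother–neighbor triangle — the classic
argument that copying models produce only 3-cycles. Taken literally for
chordless cycles the claim is false: compositions of several duplication
events produce chordless 4- and 5-cycles (e.g. a daughter inheriting two
non-adjacent neighbors of its mother that share another common neighbor),
and simulations contain them in quantity. The suite therefore asserts the
mechanistic per-event triangle property; depletion of long cycles relative
to other network families is the right empirical expectation, not absence.

## Accuracy evaluation

Two metrics: **edge precision** (percent of predicted-forest edges that
are true primary edges — with |forest| = N − C this equals recall against
surviving primaries only when no primary edge was lost to decay) and
**variance explained**, the squared Pearson correlation between a
predictor's node scores and true duplication counts. Squared correlation
is used rather than 1 − SSE/SST because centralities live on arbitrary
scales; affine invariance makes all predictors commensurable.

Baselines: raw degrees; a random spanning forest (Kruskal on i.i.d.
uniform weights — not uniform over trees, but exchangeable over edges,
which is all the baseline needs); betweenness, closeness, eigenvector,
PageRank (damping 0.85) and radiality, computed per component with
igraph and concatenated (PageRank on the whole graph, summing to 1).
Radiality of node v in a component of n nodes and diameter d is
Σ_u (d + 1 − dist(v,u)) / (n − 1).

## Genomic features

Feature kinds: `count` (≥ 1 bp overlap; one rule for all count features),
`mean`/`fraction` (overlap-length-weighted mean of interval values) and
`span` (max − min of the value over the query; applied to replication
timing as a proxy for replication pausing). Flank features use the two
50-bp flanks without distinguishing them: counts summed, means averaged.
A mean/fraction feature with no overlapping track interval falls back to
the chromosome-wide track mean, span to 0, with a per-feature missingness
indicator column (arm-level means would need centromere input at
extraction time; the chromosome mean is the coarser but dependency-free
choice).

**Shuffled background.** Each of `n_shuffles` (default 100; the published
figure does not print its count) rounds re-places every region, length
preserved, uniformly in the gap-free autosomal genome; the observed
feature mean is tested two-sided against a normal with the shuffle means'
mean and sample variance, Bonferroni-corrected across features.

**Breakpoint profiles** slide 50-bp windows as symmetric pairs from both
breakpoints: 30 steps outward (offset 0 touches the breakpoint), 5 steps
inward (offset −1 touches it from inside; short regions contribute only
windows that fit), and 10 random placements of the same scheme give the
background band. Frequency at an offset is total repeat overlaps divided
by windows evaluated.

**Associations.** The random forest uses 500 trees, sqrt-features per
split (no hyperparameters are published; these are the standard
regression-forest defaults), with the response-permutation importance
test: the empirical p of a feature is the fraction of `n_perm` (default
1,000) permutation refits whose importance meets or exceeds the observed
one; model quality is 5-fold cross-validated R². Partial Spearman
correlations rank-transform all columns and residualize feature and
response on the remaining features (the precision-matrix identity is
implemented as an alternative route and agrees to numerical precision;
the residual route also handles a feature perfectly correlated with the
response). Confidence intervals use the Fisher transformation with
variance 1/(n − g − 3), p-values the t distribution with n − 2 − g
degrees of freedom, g being the number of controls.

## Signatures

Region features are summed into non-overlapping 10-Mbp windows; a region
contributes to every window it overlaps. Four magnitude-like features
(length, G/C inside, G/C at flanks, identity) are first replaced by
below-/above-mean indicator pairs so that NMF sees composition rather
than magnitude; columns are then min–max scaled to [0, 1]. All-zero
windows are dropped.

NMF minimizes generalized KL divergence with the classic multiplicative
updates from seeded uniform-random initialization scaled by mean(A)/k;
the loss is provably nonincreasing and the trace is kept. Stopping:
relative loss change < 10⁻⁶ or 500 iterations. Rank selection reports the
Fogel–Young volume — implemented as the determinant of the Gram (cosine)
matrix of unit-normalized signature rows, since Pearson correlation is
undefined for constant rows — and cross-restart stability, the mean
cosine similarity of optimally (Hungarian) matched signature pairs over
all restart pairs. Both are diagnostics; no rank is auto-selected, and
published experience with this class of data chose k = 3 as the
compromise between the two.

Regions are assigned by NNLS of their identically encoded feature vector
on the signature rows; the argmax weight wins, exact ties and all-zero
vectors are left unassigned. Assignments are invariant to positive
scaling of the region vector. Zones: a region within 5 Mbp of a
centromere is pericentromeric (taking precedence when both are within
reach), within 5 Mbp of a telomere subtelomeric, else interstitial.

## The synthetic fixture

The fixture forward-simulates duplications on a coordinate genome
(default 4 chromosomes × 4 Mbp, 120 events of 1–20 kbp): each event
copies a source interval to a fresh non-overlapping locus and emits one
primary alignment; with probability `overlap_prob` the source is placed
over an earlier alignment footprint, and the implied secondary alignments
are emitted for overlapped portions ≥ 1 kbp (the SD length threshold).
Identities decrease linearly with event age into [0.9, 1.0], mimicking
the clock. Planted effects — breakpoint repeat enrichment and a value
track correlated with per-locus event counts — have known strengths, so
the profile and association machinery can be tested for detection, not
just execution.

What the fixture does *not* emulate: sequence content (tracks are
interval/value stand-ins), realistic repeat families, chromosome-scale
heterogeneity, or the preferential (degree-dependent) placement of real
duplications. Passing roundtrip tests therefore demonstrates correctness
of the machinery on annotation-shaped data, not biological fidelity.
Region-level truth is intrinsically lossy — parallel events between the
same region pair collapse onto one network edge — so count-R² on small
fixtures is moderate even for a perfect method.

## Problem sizes in the test suite

Unit tests use graphs of 3–60 nodes with exhaustive oracles (spanning-tree
enumeration up to 7 nodes, 16-tree K4 census, hypergeometric and
grid-search references). Simulator property tests run 250–2,000-node
networks; the benchmark acceptance checks run 5 replicates at the full
6,656-node scale (a replicate simulates and scores in about a second);
the acceptance script runs 20. The full suite completes in about a minute
on one CPU.

## Known limitations

- Reconstruction precision is bounded by information in the graph: where
  a triangle's three edges are topologically interchangeable the forest
  picks one, and ties are resolved by seed.
- The simulator's edge count near the calibrated f is highly variable
  across seeds; single-replicate numbers are not meaningful.
- The attachment kernel (degree + α) is the simplest preferential form;
  the original copying-model literature fits richer kernels.
- No rooting or directionality of events is attempted, and no
  coordinate-level liftover is provided: all inputs must share one
  assembly.
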