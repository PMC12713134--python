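# Methods

## Alternation statistics

For a syllable sequence S<sub>1</sub>…S<sub>T</sub> (integer labels, no
immediate self-repeats), each overlapping triplet is scored
b<sub>t</sub> = 1 iff S<sub>t</sub> ≠ S<sub>t+2</sub> (t = 1…T−2). The
non-repetitive fraction is f = mean(b); a *run* is a maximal constant block
of b, with 0-runs interpreted as perseveration bouts and 1-runs as flexible
stretches. Sequences shorter than 3 emissions are rejected rather than
silently skipped. Per-animal empirical CDFs are expressed in relative-
frequency percent; group-average curves evaluate each animal's step CDF on
the union grid of all observed values and average pointwise, so the average
of identical curves is the curve itself.

Run-length group comparisons default to pooling runs across the animals of a
group and applying a two-sample Kolmogorov-Smirnov test to the pooled
samples; per-animal summaries remain available in the profile tables for
median-based comparisons. Pooling mirrors how node-level distributions are
compared elsewhere in the pipeline and uses the bout-level resolution of the
data; the per-animal route is more conservative with respect to
animal-to-animal dependence.

## Transition matrices and networks

Transitions are ordered pairs S<sub>t</sub> → S<sub>t+1</sub>, accumulated
into a per-animal, non-normalized n×n count matrix (rows incoming, columns
outgoing); the grand total equals T−1 when nothing is excluded. Syllable
inclusion uses cumulative usage coverage: syllables are ranked by descending
usage (ties broken by ascending id) and the shortest prefix reaching the
coverage fraction (default 0.99) is kept — the standard motion-sequencing
reading of "syllables explaining 99% of the behavior". Inclusion is computed
cohort-wide so every animal's matrix lives on a common vocabulary. When
excluded emissions are dropped, the surviving neighbors are paired as if
adjacent (default); `break_at_gaps=True` instead severs the sequence at each
exclusion. The bridging default keeps T−1-like totals and reflects that
excluded syllables are rare by construction; the alternative is exposed
because either convention is defensible.

The matrix maps onto a directed graph: one edge per nonzero cell, weighted
by frequency; nodes are syllables with at least one incident transition
(isolated ids can be retained explicitly). `replicate_edges` produces the
equivalent multigraph in which an edge of weight w becomes w parallel
unit-weight edges — useful for edge-count analyses; node strengths are
identical in both representations.

## Network measures

* **Strength (weighted edge count)** s<sub>i</sub>: sum of incident edge
  weights, with `in`/`out`/`total` directions; `total` is the default used
  in distribution summaries, since the underlying analyses do not separate
  directions.
* **Average neighbor degree**
  k<sup>w</sup><sub>nn,i</sub> = s<sub>i</sub><sup>−1</sup> Σ<sub>j∈N<sub>i</sub></sub> w<sub>ij</sub> k<sub>j</sub>,
  with N<sub>i</sub> the union of predecessors and successors (the
  neighborhood "determined by incoming and outgoing nodes"), w<sub>ij</sub>
  the summed weight of edges between i and j in both directions, and
  k<sub>j</sub> the unweighted total degree of j. Undefined (NaN) for
  isolated nodes.
* **Average degree connectivity**: nodes are grouped by unweighted total
  degree k; the table maps each observed k to the mean average-neighbor-
  degree of its group. Isolated nodes are excluded.
* **Wiener index / closeness vitality**: W<sub>G</sub> is the sum of
  shortest-path distances over ordered *reachable* pairs; vitality(v) =
  W(G) − W(G∖v). If removing v disconnects a pair of the remaining nodes
  that was connected before, the definitional change is unbounded and the
  sentinel −inf is reported, keeping one entry per node in distributions
  (downstream statistics drop non-finite entries explicitly).
* **Betweenness centrality**: Σ over ordered pairs s ≠ v ≠ t of
  σ<sub>st</sub>(v)/σ<sub>st</sub>, endpoints excluded, unreachable pairs
  contributing zero; unnormalized by default with optional division by
  (n−1)(n−2).
* **Closeness centrality**: incoming-distance closeness with the
  reachable-count scaling C(u) = ((r−1)/Σ<sub>v</sub> d(v,u))·((r−1)/(n−1)),
  where r counts the nodes that can reach u; on a strongly connected graph
  this reduces to the plain (n−1)/Σd formula, and a node nothing reaches
  scores 0.

Shortest paths and path counts are computed with Dijkstra (non-negative
lengths enforced); betweenness and closeness are delegated to networkx,
configured to these conventions, while the Wiener/vitality machinery is
implemented here because the reachable-pair Wiener sum and the disconnect
sentinel differ from the library's strongly-connected-only definition. All
path-based measures are verified in the test suite against independent
Floyd-Warshall and exhaustive path-enumeration oracles on random digraphs.

**Weight → distance convention.** Frequency weights enter shortest paths
under three modes: `raw` (length = frequency, the graph library's default
reading of a `weight` attribute, and the convention under which the analyses
this package reproduces were run — hence the default), `inverse`
(length = 1/frequency, the frequency-as-affinity reading practitioners may
prefer semantically), and `unweighted`. Results are mode-dependent; the mode
is recorded in every output.

**Distribution summaries.** `first_quartile` is the 25th percentile with
linear interpolation; `robust_max` is the mean of the three largest values —
reading "calculated using the top three values" as their mean, since taking
their max would equal the plain maximum and make the qualifier vacuous. With
fewer than three values robust_max is reported missing.

## Racing usage

Usage is occurrence-based: per-syllable emission counts divided by T
(fractions sum to 1). A duration-weighted variant is available when
per-emission durations (e.g. frame counts) are supplied. Racing-flagged
syllables are binarized at a threshold on normalized usage, default 0.025;
the comparison is strict (>) because the threshold is defined as the highest
racing usage among reference control animals, which must themselves binarize
to zero. Word-count tables map node sets to behavior-name multiplicities
(rendering of word-cloud images is out of scope); ids missing from the label
map count under "unlabeled".

## Group statistics

All tests are two-tailed. Mann-Whitney U uses exact enumeration when both
samples have ≤ 8 observations and no ties, otherwise the normal
approximation with tie correction. The Kolmogorov-Smirnov test reports
D = max|ECDF₁ − ECDF₂|. Multiplicity is controlled with the two-stage
step-up of Benjamini, Krieger and Yekutieli: stage 1 runs the
Benjamini-Hochberg step-up at q′ = q/(1+q) and estimates the number of true
nulls as m₀ = m − r₁; stage 2 reruns the step-up at q′·m/m₀ (stage 1 stands
when r₁ is 0 or m). Reported q-values are calibrated so that
rejection ⇔ q ≤ q-level at the supplied level; because m₀ depends on the
level they are not transferable across levels. The implementation is checked
for exact rejection agreement against an independent reference
implementation on simulated p-value mixtures. Two-way ANOVA / mixed-effects
modeling is deliberately delegated: the pipeline emits tidy long tables that
drop into any statistics environment.

## Synthetic cohort generator

The generator emulates motion-sequencing output for a two-group longitudinal
study. One sequence of length T over vocabulary V with return bias ρ and
base distribution π (uniform by default; racing ids' mass multiplied by a
boost and renormalized): S₁ ~ π; S₂ ~ π restricted to V∖{S₁}; for t ≥ 3,
with probability ρ emit S<sub>t−2</sub> (always legal since
S<sub>t−2</sub> ≠ S<sub>t−1</sub>; the impossible branch falls through for
safety), otherwise draw from π restricted to V∖{S<sub>t−1</sub>}. With a
uniform base this yields the closed-form repetitive-triplet fraction
ρ + (1−ρ)/(n−1), the anchor for the analytic recovery tests.

Cohort structure: two groups ("naive" control, any other name treated as the
diseased group) × three timepoints ("1.5w", "12w", "20w" post-insult).
The diseased group carries the elevated return bias `return_bias`
throughout (control animals use `baseline_return_bias`); it gains the
group-specific vocabulary and the racing boost at the chronic timepoints
(12w, 20w) — at 1.5w both groups share one vocabulary, matching the early
indistinguishability of the groups — and its sessions shorten by
`length_factor` at 20w (sedentary phenotype). Per-animal seeds are the
master seed plus a CRC-32 of (group, timepoint, animal index), kept below
2³¹, making cohorts reproducible while keeping animals independent.

Defaults: n = 37 syllables, of which ids 30–36 are disease-specific and
30–33 racing (so a two-group cohort partitions into 30 shared and 7
specific nodes); T = 1500 emissions per 20-minute session — session lengths
are not pinned down by published counts, and hundreds-to-low-thousands of
emissions per 20-minute session is the realistic range, so a mid-range value
was fixed once and is user-overridable; 15 animals per group; ρ = 0.30
diseased vs 0.05 control; racing boost 3; length factor 0.7. Racing ids
default to a subset of the disease-specific ids, reflecting that racing
behaviors were essentially absent from control vocabularies; consequently
control animals binarize to zero racing presence at any nonnegative
threshold.

**What the generator does not emulate** — and therefore what passing tests
do not establish about real recordings: syllable duration distributions and
their autocorrelation, non-stationarity within a session, smooth kinematic
similarity between syllables, observation noise in syllable assignment, and
animal-level random effects beyond seed-to-seed variation. Directional
group-contrast checks on synthetic cohorts validate the *pipeline*, not the
biology.

## Numerical choices and degenerate inputs

* Shortest-path tie detection uses a relative tolerance of 1e−12; in `raw`
  and `unweighted` modes all lengths are integers and comparisons are exact.
* Syllable-inclusion coverage comparisons use a 1e−12 slack so that exact
  boundary fractions (e.g. coverage 1.0) are not lost to rounding.
* Empty sequences, sequences shorter than the operation's minimum (3 for
  alternation, 2 for transitions), non-integer ids, non-square or negative
  matrices, unknown nodes, and p-values outside [0,1] all raise ValueError /
  KeyError rather than degrading silently.
* An all-zero transition matrix yields an empty network; empty networks
  export as valid zero-edge files.
* CLI stages validate configuration before writing and remove partial
  outputs if a stage fails midway.

## Known limitations

* The `raw` distance mode is semantically counterintuitive (frequent
  transitions are "far"); it is retained as the default for comparability,
  with `inverse` one flag away.
* Closeness-vitality sentinels (−inf) concentrate on cut vertices; on very
  sparse networks many nodes may carry the sentinel, thinning the finite
  distribution that downstream tests compare.
* Pooled K-S tests across animals treat bouts/nodes as exchangeable within
  a group and will overstate significance under strong per-animal
  clustering; per-animal summaries are provided as the conservative
  alternative.
* The generator's first-order return-bias rule cannot produce higher-order
  motifs (e.g. A→B→C→A cycles) beyond what chance gives.
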