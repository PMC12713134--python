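# syllnet

Sequence and transition-network analysis of behavioral **syllables** — the
sub-second, stereotyped movement modules (e.g. "scrunch", "rear up", "edge
racing") that motion-sequencing pipelines extract from depth video and emit
as integer label sequences. `syllnet` is written for behavioral
neuroscientists studying disease models (its defaults emulate a longitudinal
naive-vs-epileptic mouse study), but every operation takes plain integer
sequences and works for any two-group syllable dataset.

## What it computes

**Repetitive alternation and perseveration.** For a sequence
S<sub>1</sub>…S<sub>T</sub>, every overlapping triplet is classified by the
indicator b<sub>t</sub> = 1 if S<sub>t</sub> ≠ S<sub>t+2</sub> (non-repetitive)
and 0 if S<sub>t</sub> = S<sub>t+2</sub> (repetitive, A→B→A). The fraction
f = (T−2)<sup>−1</sup> Σ b<sub>t</sub> measures behavioral flexibility, and the
maximal constant runs of b quantify bouts: runs of 0s are perseveration bouts,
runs of 1s flexible stretches.

**Transition networks.** Counts of ordered pairs S<sub>t</sub> → S<sub>t+1</sub>
form a per-animal n×n transition matrix (n restricted to the syllables
covering 99% of usage), which maps onto a directed graph with
frequency-weighted edges. Six node measures are computed: strength (weighted
edge count, equivalently the count of replicated unit edges), average neighbor
degree k<sup>w</sup><sub>nn,i</sub> = s<sub>i</sub><sup>−1</sup> Σ<sub>j∈N<sub>i</sub></sub> w<sub>ij</sub>k<sub>j</sub>,
average degree connectivity, closeness vitality (the change in the Wiener
index W<sub>G</sub> = Σ<sub>u,v</sub> d(u,v) when the node is removed),
betweenness centrality c<sub>B</sub>(v) = Σ<sub>s≠v≠t</sub> σ<sub>st</sub>(v)/σ<sub>st</sub>,
and incoming closeness centrality. Distribution tails are summarized by the
first quartile and the *robust max* (mean of the top three values).

**Racing syllables.** Per-animal syllable usage is normalized to fractions;
usage of syllables labeled "racing" (fast circular locomotion) is binarized at
a strict threshold (default 0.025) into a racing-by-animal presence heatmap,
plus word-count tables of behavior names for node sets.

**Group statistics.** Mann-Whitney U, two-sample Kolmogorov-Smirnov (with the
D statistic), Fisher's exact test — all two-tailed — and the two-stage
step-up FDR procedure of Benjamini, Krieger and Yekutieli for multiplicity.

**Synthetic cohorts.** A seeded generator produces cohorts with the structure
the analysis targets: no immediate self-repeats, a tunable probability ρ of
returning to the syllable two steps back (with uniform base over n syllables
the repetitive-triplet fraction is exactly ρ + (1−ρ)/(n−1)), group-specific
syllables, boosted racing usage, and shortened "sedentary" sessions.

## Worked example

```python
import numpy as np
from syllnet import (CohortConfig, simulate_cohort, classify_triplets,
                     count_transitions, build_network, node_partition,
                     strength, summarize_distribution, ks_two_sample)
from syllnet.alternation import AlternationProfile
from syllnet.transitions import syllable_inclusion, usage_counts

cfg = CohortConfig(seed=1)                    # 15 animals/group, T=1500, n=37
cohort = simulate_cohort(cfg, timepoints=["12w"])
naive = [s for s in cohort if s.group == "naive"]
epi   = [s for s in cohort if s.group == "epileptic"]

pct = lambda grp: np.mean([100 * (1 - classify_triplets(s).mean()) for s in grp])
print(f"percent repetitive: naive {pct(naive):.1f}%, epileptic {pct(epi):.1f}%")

runs = lambda grp: sum((AlternationProfile.from_sequence(s).repetitive_runs
                        for s in grp), [])
r = ks_two_sample(runs(naive), runs(epi))
print(f"repetitive bout KS: D={r.statistic:.3f}, p={r.p_value:.2e}")

included = syllable_inclusion(usage_counts(cohort), 0.99)
nets = {g: [build_network(count_transitions(s, included)) for s in grp]
        for g, grp in [("naive", naive), ("epileptic", epi)]}
shared, specific = node_partition(nets)
print("shared nodes:", len(shared),
      "epileptic-specific:", sorted(specific["epileptic"]))
```

prints

```
percent repetitive: naive 8.0%, epileptic 32.7%
repetitive bout KS: D=0.252, p=8.79e-70
shared nodes: 30 epileptic-specific: [30, 31, 32, 33, 34, 35, 36]
```

The diseased group repeats behaviors roughly four times as often, its
perseveration-bout distribution is shifted to longer bouts, and the seven
syllables seeded as disease-specific are recovered exactly from the network
node partition (30 nodes shared between groups).

## Command line

The same pipeline runs from a shell; every stage reads a cohort manifest and
writes tidy CSVs, and a fixed seed makes reruns byte-identical:

```sh
syllnet simulate --out-dir cohort/ --seed 1
syllnet report --manifest cohort/manifest.csv --labels cohort/labels.csv \
               --out-dir analysis/
```

`report` writes alternation profiles and bout tables, per-animal long-format
matrices / GraphML / Cytoscape edge tables, node-metric and
degree-connectivity tables, usage and racing-heatmap tables, the shared vs.
group-specific node partition with word counts, and the group-comparison
table with BKY q-values. Individual stages (`alternation`, `networks`,
`metrics`, `racing`, `stats`) run the same steps separately.

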