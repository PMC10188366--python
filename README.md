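# bequant

Quantification of base-editing outcomes on paired sgRNA/target-site
libraries.

Base editors — Cas9-nickase/deaminase fusions that convert one base pair to
another without double-strand breaks — are profiled at scale with libraries
of thousands of genomically integrated cassettes, each pairing a guide-RNA
spacer with a matching target site that places a substrate C or A at
protospacer position 6 inside variable sequence context. After editing, the
library is sequenced as paired-end reads (forward over the target site,
reverse over the spacer) at a few hundred reads per member per biological
replicate. `bequant` turns those reads into the statistics editor engineers
compare: per-position editing profiles, the editing window, C→T : A→G
selectivity, average efficiency, read-level co-editing, sequence-context
motifs, and fold changes between editor variants. A synthetic-data generator
emulating the library makes every stage verifiable without any download.

## The statistics at the core

With protospacer positions 1–20, PAM 21–23 and position 0 immediately
upstream, only A→G, C→T, C→G, C→A calls in window −9..20 are tracked.

* **Read assignment**: reads below Q28 in the spacer/target regions are
  discarded; candidates are nominated by locality-sensitive hashing over
  tiled 6-mers, filtered by exact spacer match, and genotyped by
  Needleman–Wunsch (match +1, mismatch −1, gap open −5, gap extend 0, free
  start gaps).
* **Noise filter**: a mutation with counts k₁/n₁ and k₂/n₂ in two replicates
  is kept iff P(X₁ ≥ k₁)·P(X₂ ≥ k₂) < 0.05 with Xᵢ ~ Binomial(nᵢ, 10⁻³) —
  so reproducibly rare edits survive while one-off sequencer errors do not.
  A one-way ANOVA screen (family-wise α = 0.005, Bonferroni) flags
  batch-dependent mutations.
* **Pooling**: replicate counts are summed (Σk/Σn, the maximum-likelihood
  Bernoulli rate). The editing window is every position with efficiency
  ≥ 30% of the peak; selectivity is the geometric mean over the window of
  the per-position C→T : A→G ratio.
* **Motifs**: member efficiencies are mapped through the stabilised logit
  log((x+ε)/(1+ε−x)), ε = 0.001, and regressed (ridge, α = 10⁻⁵, 80:20
  split) on one-hot context bases at offsets −3..+3; held-out Pearson R is
  the motif confidence.
* **Editor comparison**: paired member efficiencies of two editors are
  fitted by total least squares through the origin (both axes carry
  measurement error); the fold change is the reciprocal of the slope.

## Worked example

```python
from bequant import assign_and_genotype, quantify
from bequant.simulate import SimConfig, cbe_preset, simulate_experiment

config = SimConfig(n_members=100, mean_depth=200, rng_seed=4)
exp = simulate_experiment(config, cbe_preset())
assignment = assign_and_genotype({r: exp.read_pairs(r) for r in exp.reads},
                                 exp.library)
results = quantify(assignment)
print(results.summary())
```

prints

```
Base-editing library quantification
===================================
members quantified        100
peak C>T position         6
peak C>T efficiency       0.321
editing window (>=30%)    3..8
C>T : A>G selectivity     23.7
avg C>T efficiency        0.339
avg A>G efficiency        0.021
A>G : C>T ratio           0.06
P(A>G | C>T) per read     0.041
batch-effect hypotheses   120 tested, 0 flagged
```

Read it as: editing peaks at protospacer position 6 (32% of reads at the
peak), the ≥30%-of-peak window spans positions 3–8, cytosine conversion is
~24-fold preferred over adenine conversion inside that window, 34% of each
member's reads carry at least one C→T edit on average, and only 4% of
C-edited reads also carry an A edit — a selective cytosine editor. No
mutation shows a batch effect at the corrected 0.005 level.

The same workflow is available from the shell:

```sh
bequant simulate --n-members 200 --depth 300 --preset cbe --seed 1 --out-dir sim/
bequant assign --library sim/library.tsv \
    --r1 sim/fwd_r1.fastq --r2 sim/rev_r1.fastq \
    --r1 sim/fwd_r2.fastq --r2 sim/rev_r2.fastq \
    --out counts.tsv --calls-out calls.tsv.gz --report report.json
bequant quantify --counts counts.tsv --calls calls.tsv.gz \
    --out profile.tsv --stats stats.json
bequant motif --counts counts.tsv --library sim/library.tsv --class C2T --out motif.json
```

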