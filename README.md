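# polysome

Isoform-level analysis of polysome-profiling RNA-seq (TrIP-seq-style
data): how well is each *transcript isoform* of a gene translated, and
which transcript features explain the difference?

In a polysome-profiling experiment, cytoplasmic extract is resolved on
a sucrose gradient and RNA is sequenced from nine sample types — total
cytoplasmic RNA, the 80S monosome, and fractions carrying two through
seven and eight-or-more ribosomes — in biological duplicate, with
transcript-isoform-level quantification. This package implements the
downstream analysis of such data for computational biologists who start
from an isoform × fraction count matrix:

- **Normalization & translational statistics** — TPM/RPKM, a
  variance-stabilizing transformation (VST) for overdispersed counts,
  abundance filters, and the **weighted polysome count**

  $$\mathrm{polysome\ count} = \sum_{i=1}^{7} i\,n_i + 24\,n_{8+},$$

  where $n_i$ is the (replicate-averaged) read count in the fraction
  with $i$ ribosomes. The pooled 8+ fraction is weighted by the
  midpoint of 8 and an assumed ~40-ribosome ceiling, $(40+8)/2 = 24$.
  Ribosome density divides this sum by cytoplasmic reads.
- **Profile clustering** — hierarchical clustering of
  mean-centered, replicate-averaged VST profiles across the gradient
  (Spearman distance $1-\rho_s$, Ward linkage) into translational
  classes; sample-level clustering (Euclidean, complete linkage); and
  cluster stability by bootstrap / jitter / noise-replacement
  resampling scored with per-cluster mean Jaccard similarity
  (≥ 0.75 ⇒ stable).
- **Feature tabulation** — each transcript is decomposed into 5′
  leader, CDS and 3′ UTR, and 24 features with documented translational
  relevance are tabulated: region lengths and GC, exon count, leader
  secondary-structure proxies (base-pair maximization in 75-nt
  windows; a thermodynamic folder can be plugged in), codon-usage
  statistics and rare-codon stretches, the AU-element fraction of the
  3′ UTR, cognate (ATG) and near-cognate upstream ORFs, miRNA site
  counts/scores, half-life, and expression summaries.
- **Gene-linked effect sizes** — isoforms of the *same gene* that land
  in well- vs poorly-translated clusters are paired, and per-feature
  differences are scored with Cliff's
  $d = \bigl(\#(x_i > x_j) - \#(x_i < x_j)\bigr)/(mn) \in [-1, 1]$
  (related to the Mann–Whitney statistic by $d = 2U/(mn) - 1$), with
  percentile-bootstrap 95% CIs and two-tailed U tests.
- **Projection** — an external transcript × cell/stage expression
  matrix is mapped onto the reference clusters (per-stage cluster
  occupancy percentages, mean ± s.d. across cells) and scanned for
  **isoform switches**: genes whose isoforms change external cluster
  and sit on opposite sides of the high/low polysome divide.
- **Synthetic data** — a first-class generator plants translational
  classes ("archetypes" of fraction distribution), gene-linked feature
  differences (3′ UTR length, AU runs, uORFs, miRNA sites,
  half-life), and stage-resolved isoform switches, with
  negative-binomial noise and full ground truth, so every stage is
  testable by recovery — no downloads required.

The transform/cluster-shaped stages are scikit-learn style estimators
(`VarianceStabilizer`, `ProfileClusterer`, `SampleClusterer`,
`ReferenceProjector`) and compose with sklearn pipelines; module-level
functions wrap them for one-shot use.

## Worked example

```python
from polysome import (vst, filter_and_center, ProfileClusterer,
                      cluster_samples, polysome_count, ribosome_density)
from polysome.simulate import make_archetypes, simulate_counts, replicate_map_for
from sklearn.metrics import adjusted_rand_score

archetypes = make_archetypes(8)
counts, truth = simulate_counts(archetypes, n_genes=700, depth=1e6,
                                dispersion=10.0, seed=42)

rmap = replicate_map_for(counts.columns)
v = vst(counts, replicate_map=rmap)          # variance-stabilized counts
rel = filter_and_center(v, rmap)             # replicate-avg, filter, center

clusterer = ProfileClusterer(n_clusters=8).fit(rel)
ari = adjusted_rand_score(truth.loc[rel.index, "archetype"], clusterer.labels_)
print(f"adjusted Rand index vs planted classes: {ari:.3f}")

samples = cluster_samples(v, k=4)
for label in sorted(set(samples.assignments)):
    members = sorted({c.rsplit('_', 1)[0] for c in samples.members(label)})
    print(f"sample group {label}: {members}")

row = counts.loc["G0001.T1"].T.groupby(
    counts.columns.map(rmap.__getitem__)).mean()
print(f"weighted polysome count: {polysome_count(row):.1f}")
print(f"ribosome density: {ribosome_density(row, row['cyto']):.2f}")
```

prints

```
adjusted Rand index vs planted classes: 0.972
sample group 1: ['cyto']
sample group 2: ['mono']
sample group 3: ['p2', 'p3', 'p4']
sample group 4: ['p5', 'p6', 'p7', 'p8plus']
weighted polysome count: 1109.0
ribosome density: 1.91
```

The clustering recovers the 8 planted translational classes nearly
perfectly (ARI 0.97), and the sample dendrogram reproduces the
canonical gradient structure: cytoplasmic RNA, the 80S monosome, low
polysomes (2–4 ribosomes) and high polysomes (5–8+) each form their
own group. The weighted count of ~1109 ribosome-passages against a
cytoplasmic signal of ~580 reads gives a ribosome density of 1.91 for
this (well-translated) isoform.

A command-line pipeline covers the same stages on files:

```sh
polysome run-all --out results/demo --seed 0 --n-genes 200
polysome simulate --out data --seed 0       # counts, GTF, FASTA, aux tables
polysome normalize --counts data/counts.tsv --out norm
polysome cluster --relative norm/relative_expression.tsv \
                 --vst norm/vst.tsv --stability --out clusters
```

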