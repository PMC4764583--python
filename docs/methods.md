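# Methods

This note documents the models, numerical choices and limitations
behind the package. Everything quantitative stated here is computed by
the test suite or the acceptance script; nothing is quoted from
external data.

## The measurement model

A fractionated polysome profile yields nine sample types per
replicate: total cytoplasmic RNA (`cyto`), the 80S monosome (`mono`),
and fractions with two to seven (`p2`..`p7`) and eight-plus
(`p8plus`) ribosomes. An isoform's read-count distribution across the
eight ribosome-containing fractions is its *polysome profile*; its
shape reports how many ribosomes typically engage that isoform and is
the unit of every downstream analysis.

### Weighted polysome count, density, TE

The weighted polysome count multiplies each fraction's
replicate-averaged reads by its ribosome number, `1·n_mono + 2·n_2 +
… + 7·n_7 + 24·n_8plus`. The pooled 8+ fraction has no single
ribosome number; assuming transcripts carry at most ~40 ribosomes
(`WeightScheme.ceiling`, default 40), its weight is the midpoint
`(ceiling + 8)/2 = 24`. The monosome term is included by default
(eight-term sum); `include_monosome=False` restricts to fractions with
two or more ribosomes, which zeroes that weight. Ribosome density is
the weighted count divided by cytoplasmic reads; translation
efficiency generalizes the same ratio to arbitrary
ribosome-association signals. Since the weighted sum is linear,
averaging replicates before or after weighting is mathematically
identical; replicates are averaged first.

### Variance stabilization

Counts are transformed with the analytic negative-binomial
variance-stabilizing map `vst(x) = 2·asinh(√(x/d)) / ln 2`, where `d`
is the NB size parameter of `var = μ + μ²/d`. The map is strictly
monotone, zero at zero, and approaches `log2(x)` plus a constant for
large `x` while compressing the Poisson-dominated low-count range —
the three properties downstream clustering relies on. `d` is estimated
by method of moments across replicate groups (`d = Σμ̂² / Σ(v̂ − μ̂)`
over rows with `v̂ > μ̂`), clamped to `[0.1, 1e6]`; with no
overdispersed rows the transform degrades gracefully toward a scaled
`√x` ≈ Poisson behavior. The exact closed form is a package choice —
any transform with the three contract properties would serve.

### Filtering and centering

Replicate columns are averaged per fraction type *after* the VST; rows
whose mean over the nine fraction types is not strictly greater than 1
are removed (roughly a 100-read abundance floor); surviving rows are
mean-subtracted so that clustering sees relative shape, not abundance.
The read-count filter (`threshold_by_reads`) is likewise strict:
exactly `min_reads` is dropped.

## Clustering

Isoform profiles: pairwise Spearman correlation distance `1 − ρ_s`
(range [0, 2]) and Ward agglomeration. Rows with no rank variation
have undefined `ρ_s`; they are flagged with a warning and placed at
the neutral distance 1 from everything (and removed before external
clustering). Samples: Euclidean distance between VST column vectors,
complete agglomeration. Merging is deterministic; equal-height ties
resolve by lowest index (SciPy's nearest-neighbor chain).

`cut_to_clusters` exposes both a fixed-`k` cut and an iterative
refinement mode that deepens the cut until all pairs of cluster mean
profiles are distinguishable (pairwise Spearman < 0.95 by default) —
an explicit, parameterized version of the judgment call of splitting a
dendrogram "until clusters look distinct".

### Stability

`jaccard_stability` reclusters perturbed data and scores each
reference cluster by its best Jaccard similarity `|A∩B| / |A∪B|`
against the perturbed clustering; per-cluster means ≥ 0.75 over 100
resamples are called stable. Three schemes: bootstrap (resample
observations with replacement; memberships compared on the
observations present in the resample), jitter (Gaussian noise, s.d. =
0.1 × each feature's s.d.), and noise replacement (each observation
replaced with probability 5% by a uniform draw over the feature
range). The jitter and noise magnitudes are package defaults; only
the schemes themselves are canonical. Bootstrap resamples in which a
reference cluster has no member are excluded from that cluster's mean
and counted separately as dissolutions: with ~9–18 observations a
two-member cluster is absent from a substantial share of resamples,
and absence by sampling carries no information about stability.

## Feature registry

Transcripts are decomposed strand-aware into 5′ leader, CDS (start
codon through stop codon; must begin ATG, end in a stop, length
divisible by 3) and 3′ UTR. Coordinates are 1-based inclusive in GTF
files and 0-based half-open internally. The 24 tabulated features and
their conventions:

| group | columns | notes |
|---|---|---|
| lengths | leader_length, cds_length, utr3_length, transcript_length | nt |
| composition | leader_gc, cds_gc, utr3_gc, transcript_gc | fraction |
| architecture | exon_count | |
| leader structure | cap_structure_score, min_window_structure_score | negated max base pairs; lower = more structured |
| codon usage | mean_codon_frequency, min_window_codon_frequency, rare_codon_stretches | per-thousand units |
| 3′ UTR elements | au_element_fraction | runs of A/U longer than 5 nt |
| uORFs | cognate_uorfs, noncognate_uorfs | ATG vs near-cognate starts |
| miRNA sites | mirna_site_count, mirna_context_score, …_expressed | from a site table |
| decay | half_life | hours, from a lookup table |
| expression | cytoplasmic_expression, median_polysome_expression | median over mono..8+ |

Numerical conventions: "more than 5 nt in a row" is read as runs of
length ≥ 6; the near-cognate start set is {CTG, GTG, TTG, ACG, ATA,
ATT, ATC}; rare codons are the bottom decile of the usage table and a
stretch is ≥ 3 consecutive rare codons; the codon window is 5 codons
(shorter CDSs use one full-length window); uORF calls require an
in-frame stop within the leader. Missing evidence (no half-life
record, noncoding transcript) yields missing values, never zero.

The structure backend is pluggable. The shipped default maximizes
Watson–Crick + GU base pairs by dynamic programming (minimum hairpin
loop 3), negated so lower = more structured, over 75-nt windows at
step 1 (cap score = first window; leaders shorter than the window are
scored whole). It is a fast pairing-capacity proxy, not a free-energy
model; a thermodynamic folder can be passed as `backend` where
absolute energies matter. The default is verified against an
exhaustive pairing enumeration for short sequences in the test suite.

## Gene-linked comparison

For disjoint high/low cluster-label sets, every gene with isoforms on
both sides contributes all cross pairs; each member's features join
its side's pooled distribution (pooled-side comparison, not per-pair
differences). Cliff's `d` counts greater/less pairs (ties contribute
zero, computed by sorted search in O((m+n) log n)); the identity
`d = 2U/(mn) − 1` holds exactly with the count-of-greater-pairs U
(+½ per tie), which is what `mann_whitney` returns. The U test uses
the exact null for tie-free samples with m, n ≤ 20 and the
tie-corrected normal approximation otherwise. Confidence intervals are
percentile bootstrap (both samples resampled independently, default
2,000 resamples, seeded); coverage at nominal 95% is verified by
simulation in the test suite (90–99% band). Raw p-values are reported
with a default significance cut of α = 0.001 and no multiplicity
correction, matching the convention of reporting each feature's test
on its own.

## Projection and switches

External expression is mapped by transcript-identifier identity (both
datasets must be quantified on the same annotation). Per cell,
transcripts with expression strictly above the threshold (default
TPM > 1) that exist in the reference clustering are assigned their
reference cluster; per-cluster percentages are computed per cell
(summing to 100) and then averaged within stages, with the s.d. taken
across cells. An isoform switch is a same-gene pair in different
external clusters whose reference clusters fall on opposite sides of
the high/low partition; pair count and distinct gene count are
reported. Switch detection is symmetric in stage order up to a
direction flip.

## Synthetic data: what it emulates, and what it does not

The generator is the package's test bed and defines its study
conditions.

**Archetypes.** Translational classes are planted as relative
abundance shapes over the eight ribosome fractions (normalized to sum
1), drawn from a fixed library of 12 rank-distinct shapes (all
pairwise Spearman ρ < 0.95, checked at construction). The default
population is bimodal — ~16% strongly polysome-associated, ~20%
monosome-dominated, with low-polysome, mid and plateau classes between
— and every class's largest abundance steps fall at the mono|2 and 4|5
boundaries. This encodes the empirical picture the generator is meant
to emulate: isoforms are predominantly either well or poorly
ribosome-associated, which is precisely what makes low polysomes
(2–4) cluster away from high polysomes (5–8+) and the 80S and
cytoplasmic samples stand alone. The cytoplasmic sample is a mixture
of the ribosome-fraction signal plus a free cytoplasmic-only excess
that grows as the class's mean ribosome load falls, so ribosome
density is an independently planted property.

**Counts.** Isoform abundances are log-normal (σ = 1); the expected
count of isoform *i* in ribosome fraction *f* is `8 · depth · p_i ·
w_f` so an average sample totals ≈ `depth` reads (default 10⁶, a
deliberately modest sequencing depth; dispersion default 10).
Replicates share expectations; observed counts are negative binomial
(`var = μ + μ²/d`), the standard RNA-seq count model. Zero expected
weight gives exactly zero counts.

**Annotation.** Each gene gets its own contig; isoforms are laid out
sequentially with 1–3 exons on a per-gene random strand. CDSs always
begin ATG and end in a stop. Low-polysome class members draw 3′ UTR
lengths around 1551 nt and their high-polysome gene-mates around
982 nt (gamma, CV 0.25), and additionally receive denser AU runs,
more miRNA sites, shorter half-lives and cognate-uORF cassettes at a
higher rate (35% vs 10%) — so gene-linked comparisons have a known
direction to recover. Leaders are scrubbed of incidental ATGs so
cognate-uORF planting stays controlled; near-cognate starts occur at
background rates.

**External matrix.** Genes follow one of five rank-distinct stage
trajectories (monotone up/down, early/late/mid peaks); isoforms of a
non-switching gene share their gene's trajectory and therefore
co-cluster under rank-correlation distance. A planted switch flips the
dominant isoform (75% expression share) between the low- and
high-polysome member of a gene-linked pair at the midpoint stage.
Switch-recovery is validated at the generator's natural granularity
(k = 5 external clusters, matching the five trajectory families);
coarser or finer k blurs or splits trajectory families and over-calls
pairs.

**What passing tests do not show.** The generator does not emulate
read-level artifacts (mappability, positional bias, isoform
quantification uncertainty from shared exons — isoforms here are
independent), compositional library effects beyond depth scaling,
splice-graph overlap between isoforms, or biological correlation
between features (planted features are independent given the class).
Recovery results on synthetic data therefore certify the statistical
machinery, not performance on real libraries with quantification
noise.

**Validated conditions.** Under the defaults (700 genes → ≈ 2,000
isoforms, depth 10⁶, dispersion 10, 2 replicates), across 26 seeds:
isoform clustering recovers planted classes with ARI ≥ 0.90; the
sample dendrogram cut at 4 reproduces {cyto}, {80S}, {2–4}, {5–8+} in
every seed; and every sample cluster's mean Jaccard stability is
≥ 0.89 under all three resampling schemes.

## Problem sizes

The test suite runs at 700 genes (≈ 2,000 isoforms) for clustering and
stability checks, 400 genes for annotation length statistics, 40 genes
for sequence-level tests, and 25-gene toys for the CLI smoke test —
sizes at which each property being tested is already stable. The
acceptance script uses the full ≈ 2,000-isoform default.

## Known limitations

- The Nussinov-style structure proxy ignores stacking energies and
  pseudoknots; scores are comparable between sequences of equal window
  length only.
- The NB dispersion estimate pools all rows (one global `d`);
  gene-wise dispersion shrinkage is out of scope.
- `mann_whitney`'s exact mode is limited to small tie-free samples;
  heavily tied small samples use the normal approximation.
- Sample-level clustering assumes the 18-column layout carries enough
  isoforms (hundreds+) for distances to concentrate; very small panels
  will be unstable under bootstrap by construction.
- Projection matches transcripts by identifier only; cross-annotation
  projection (lift-over, sequence matching) is not implemented.
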