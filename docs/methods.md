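# Methods

`mastkit` implements strain-level analysis of deep single-fragment amplicon
sequencing of species-specific protein-coding marker genes (metagenomic
amplicon strain typing).  The emulated study design is the honey-bee gut
microbiome: four markers under 500 bp (guaA and gluS for *Snodgrassella
alvi*; pflA and rimM for *Gilliamella* spp.), 144 bees from four U.S.
locations (103/21/9/11), and a mean coverage of 46,000 merged reads per
(bee, marker).

## Strain calling

A *strain* is a distinct full-length amplicon haplotype: two strains differ
iff their sequences differ at ≥1 position.  The calling chain is:

1. **Quality filter.** A read is discarded iff the arithmetic mean of its
   Phred scores is strictly below 30 (a mean of exactly 30 is retained).
   Reads containing N are discarded by default; the data we emulate are
   merged MiSeq fragments where Ns are rare, and a haplotype-exact method
   cannot use them.
2. **Ungapped placement.** Merged amplicons are fixed-length, so any indel
   changes the read length.  A read is accepted iff its length equals the
   reference length, standing in for "aligns end-to-end without gaps"; no
   mismatch limit is imposed.  Gapped reads are a normal, counted rejection.
3. **Thresholding.** Identical haplotypes are pooled per (sample, marker);
   frequency is computed against that sample's retained, aligned reads
   (the denominator is a deliberate choice — all-reads and aligned-reads
   denominators differ only through the discarded fraction).  A haplotype
   enters the global registry iff its frequency strictly exceeds 1% in at
   least one sample; at 46,000 reads that is >460 reads.  Registry strains
   are reported everywhere with raw counts, but presence/absence applies
   the strict threshold per sample.
4. **Ids.** Strains are numbered per marker by descending total read
   count, ties broken lexicographically by haplotype, so ids are stable
   across runs and read orderings.

Samples with no reads for a marker are carried as explicit missing entries
(NaN totals), never as zeros.

### Cryptic-strain rescue

For each registry strain, the relaxed search asks in how many samples its
exact haplotype is supported by ≥1 read anywhere in the unfiltered pool
(including low-quality and sub-threshold reads).  Reported per strain:
strict prevalence (threshold calls), relaxed prevalence, and their ratio
(infinite when the strict prevalence is 0).  At a realistic error rate the
single-read search also picks up error-converted neighbours of 1-SNP-apart
strains, which inflates relaxed prevalence; the packaged fold-recovery
experiment therefore runs error-free so the planted fold is identifiable.

## Co-occurrence and clustering

The co-occurrence score of strains A and B is S = 2·b_AB/(b_A+b_B), with
b_AB the number of bees containing both and b_A, b_B the numbers containing
each — the Sørensen–Dice coefficient of the two host sets (1 = identical
host sets, 0 = disjoint).  The same form applied bee-wise to called strain
sets gives the bee-by-bee similarity used for composition heatmaps; the
equivalent Jaccard or frequency-weighted variants were genuine options, and
Dice was chosen to mirror S's endpoint semantics.

Strains are partitioned by the Markov Cluster algorithm on the S matrix:
column-normalise, then iterate expansion (matrix power 2) and inflation
(entrywise power I, then renormalisation) with pruning until stationary.
Numerical choices, all configurable: pruning threshold 1e-5 (a column's
maximum entry is never pruned, which keeps high-inflation iterations from
emptying near-uniform columns), convergence tolerance 1e-8 on the max
entrywise change, at most 200 iterations (non-convergence returns the
current clustering with a warning).  Self-loops are added only to
zero-diagonal nodes, with the column's maximum weight (1 on isolated
nodes); S matrices carry unit diagonals anyway, and this rule keeps the
partition exactly invariant under rescaling of S.  Clusters are read off
attractor rows (nonzero diagonal); attractor systems that contain each
other are merged; a node claimed by several clusters goes to the largest,
ties broken by smallest member strain id.  The default inflation is 2.0,
with 1.2, 4.0 and 6.0 as the conventional sweep.  The test suite holds the
implementation to an independently written dense reference MCL on random
weighted graphs at all four inflations.

Cluster statistics: a cluster is present in a bee iff ≥1 member strain is
present; within- vs between-cluster pairwise SNP distances are compared
with a two-sided Wilcoxon rank-sum test (scipy's tie-corrected normal
approximation).

## Permutation tests

All tests are seeded and reproducible bit for bit.  Each test forms a
chi-square discrepancy X² = Σ (O−E)²/E between observed category counts
and their permutation means E, but the p-value is the empirical tail
probability of X² in its own permutation distribution,
p = (1 + #{null ≥ observed})/(n_reps + 1).  Because the observed data is
exchangeable with the null draws, this p-value is calibrated regardless of
the categories' joint distribution — a plain χ²_df reference would not be,
since per-location strain counts are neither independent nor Poisson.
X² and df are still reported for interpretability.  Bonferroni correction
multiplies p by the number of markers tested in the run.

* **Location shuffle** — distinct strains per location, null = random
  reallocation of bees to locations preserving location sizes.
* **Reassortment** — histogram of pairwise co-occurrence counts over all
  strain pairs, adjacent categories merged until every null-expected
  category holds ≥5 pairs (the classical validity rule).  The default null
  is curveball trading, which preserves per-bee richness and per-strain
  prevalence exactly and therefore keeps the observed table exchangeable
  with the null ensemble; measured type-I error over 200 null replicates
  is ≈0.05–0.07.  A faster prevalence-weighted per-bee redraw is available
  (`scheme="prevalence"`) but is mildly conservative (≈0.025–0.03),
  because its null draws are generated from the realized prevalence of the
  observed table itself.
* **Interspecies association** — cross-marker strain pairs (one strain per
  marker) over the shared bees, both markers reassorted independently.
* **Saturation curves** — mean distinct strains over random bee subsets of
  every size 1..N.  Each of the (default 100) combinations is a uniform
  random permutation of bees evaluated at all prefixes, so every realised
  curve is monotone non-decreasing and ends at the total strain count;
  prefixes of a uniform permutation are uniform k-subsets, so the
  estimator's distribution matches independent subset draws.

## Sequence-evolution simulations

Two in-silico experiments ask whether identical strains in different bees
could be artifacts.  Starting from each marker reference, every simulated
strain draws k ~ Poisson(mean SNPs) distinct sites and substitutes each
with a uniform choice among the three alternative bases (the substitution
matrix is deliberately uniform; nothing downstream depends on transition
bias).  Sites within one sequence are drawn without replacement, i.e. no
back-mutation inside a strain.

* *PCR-artifact mode* places sites uniformly along the sequence.
* *Purifying-selection mode* first draws a codon position with empirical
  weights, then a uniform unused site within that class.  The codon
  position of 1-based site q with frame offset f is ((q−f−1) mod 3)+1;
  sites before the first complete codon are excluded from the classes, and
  an incomplete terminal codon keeps its true positions.  Default weights
  per marker (first/second/third): guaA 0.12/0.10/0.78, gluS
  0.17/0.04/0.79, pflA 0.14/0.04/0.82, rimM 0.20/0.09/0.71 — empirical
  values for these markers, re-estimable from any strain registry with
  `estimate_codon_weights`.

The study-scale run is 144 bees with 6 strains per bee for guaA, gluS and
rimM and 16 for pflA (4,896 sequences), Poisson means 8/8/8/20.  The key
output is the *convergence count*: distinct non-reference sequences
independently generated in ≥2 bees (within-bee duplicates are tallied
separately).  At these parameters the expected number of cross-bee
collisions is far below 1 — with ~450 positions and ~8 SNPs the space of
reachable haplotypes is astronomically larger than 4,896 — and runs at
study scale reproduce zero convergent sequences, with ~4,895 of 4,896
sequences distinct.

## Synthetic data generator

The generator's defaults are the emulated study's conditions: four markers
of 444–456 bp, 144 bees split 103/21/9/11 across four locations, mean
coverage 46,000.  Planted structure: each cluster is founded 8 SNPs from
the reference (well separated from other founders), and its members each
carry one private additional SNP, so members sit 1–2 SNPs apart.  Each
cluster's members get a shared abundance profile (Dirichlet with a 5%
floor, so every member clears the 1% threshold at the default cluster
count) used identically by every carrier bee.  By default 10% of bees carry
a second cluster, mixed 50/50.  Clusters are assigned to bees independently
of location unless a location bias is requested (bias 1.0 makes clusters
location-exclusive — the positive control for the location test).
Coverage is negative-binomial (dispersion 8; the emulated study reports
only the mean, and amplicon libraries are overdispersed); errors are
independent per-base substitutions, uniform over the three alternatives;
erroneous bases carry the low Phred value and correct bases the high one,
so the quality filter can be exercised deliberately.  Indel errors are not
modelled (the pipeline rejects gapped reads anyway), nor are chimeras,
PCR jackpots, or paired-end merging.

What passing tests on this generator do **not** show about real data: real
error profiles are position- and motif-dependent, real abundance profiles
drift across hosts, real communities contain relatives at every
divergence, and chimeric amplicons exist.  The generator is an oracle for
the pipeline's logic, not a sequencer model.

## Problem sizes in the packaged experiments

Test and acceptance experiments run at desk scale as the package's own
standard configuration: 12–60 bees and coverage 2,000 for read-level
experiments (at 2,000 reads the 1% threshold is 20 reads, and planted
frequencies ≥5% sit hundreds of standard errors above it, so the scaled
coverage does not change any call), 200 replicates × 199 permutations for
calibration experiments, and the full 144-bee scale for the sequence
evolution experiments, which are cheap.

## Known limitations

* The exact-length rule cannot rescue reads with compensating indels
  (equal-length insertion plus deletion); such reads become spurious
  haplotypes only above the 1% threshold, which substitution errors at
  realistic rates do not reach.
* The reassortment null conditions on per-bee richness; mechanisms that
  change richness itself are outside its alternative.
* MCL attractor-overlap resolution is deterministic but heuristic; on
  graphs with exact symmetries the partition can depend on strain ids.
* `estimate_codon_weights` weights each distinct SNP equally regardless of
  its frequency across strains.
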