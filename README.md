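# mastkit

Strain-level analysis of deep amplicon sequencing of species-specific
protein-coding marker genes ("metagenomic amplicon strain typing"), built
around the honey-bee gut microbiome use case: two core symbionts
(*Snodgrassella alvi*, *Gilliamella* spp.), four short marker genes
(guaA, gluS, pflA, rimM, each <500 bp), and one deeply sequenced amplicon
library per bee and marker.  It is aimed at microbiome researchers who want
to resolve within-species strain structure across many host individuals
without shotgun metagenomics.

The core objects and statistics:

* **Strain calling.**  A strain is a distinct full-length amplicon
  haplotype (≥1 nucleotide difference).  Reads with mean Phred < 30 are
  discarded, reads that could only align with gaps are rejected, and a
  haplotype is called iff its frequency exceeds 1% in at least one sample
  (460 reads at the design coverage of 46,000 reads/sample/marker).
* **Co-occurrence score.**  For strains A and B,
  S = 2·b_AB / (b_A + b_B), where b_AB counts bees containing both strains
  and b_A, b_B the bees containing each: 1 means identical host sets, 0
  means never together.  Strains are grouped into clusters with the Markov
  Cluster algorithm (inflation I = 2.0 by default; 1.2/2/4/6 sweep).
* **Permutation nulls.**  Location shuffling (is strain richness per
  location random?), strain reassortment across bees (do strains travel
  together?), interspecies association, and saturation/rarefaction curves,
  all with seeded, exchangeable permutation p-values.
* **Evolution simulations.**  Poisson-SNP sequence simulation from each
  marker reference — uniform placement (PCR-artifact scenario) or
  codon-position-weighted placement (purifying-selection scenario) — to
  show that independent mutation essentially never regenerates the same
  haplotype in two hosts (zero "convergence").
* **Synthetic data.**  A generator that plants clusters of 1-SNP-apart
  strains with conserved abundance profiles into simulated bees and emits
  FASTQ, so every stage can be tested against known ground truth.

## Worked example

Simulate a small community with known truth, call strains, cluster them,
and test co-occurrence against reassortment:

```python
import mastkit as mk

truth = mk.make_truth(
    n_bees=12, locations={"Texas": 6, "Tennessee": 3, "Utah": 2, "Florida": 1},
    n_clusters=5, strains_per_cluster=4, two_cluster_fraction=0.0, seed=11,
)
sim = mk.simulate_reads(truth, mk.ReadSimParams(coverage_mean=2000, error_rate=0.0, seed=11))
pools, accounting = mk.pools_from_reads(sim.quality_reads(), truth.references)
table = mk.call_strains(pools, truth.references)
print(mk.summarize_strain_diversity(table).round(2).to_string())

graph = mk.build_cooccurrence_graph(table, "guaA")
clusters = mk.mcl_cluster(graph)
print("guaA clusters:", len(clusters.partition),
      "sizes:", sorted(len(m) for m in clusters.partition.values()))

res = mk.reassortment_null(table, "guaA", n_reps=199, seed=1)
print(f"reassortment chi2={res.chi_square:.1f} p={res.p_raw:.3f}")
```

prints

```
        total_strains  mean_strains_per_bee  sd_strains_per_bee  mean_pairwise_snps
marker
guaA               16                   4.0                 0.0               13.93
gluS               20                   4.0                 0.0               14.62
pflA               12                   4.0                 0.0               13.14
rimM               20                   4.0                 0.0               14.97
guaA clusters: 4 sizes: [4, 4, 4, 4]
reassortment chi2=40.8 p=0.005
```

Reading this: each marker recovers exactly the planted strains (every bee
carries one 4-strain cluster, hence 4.0 strains per bee with zero spread;
only clusters actually assigned to a bee can be seen, so guaA shows 16 of
the 20 planted strains).  MCL reassembles the four carried guaA clusters
perfectly, and the reassortment test rejects random strain assortment at
p = 0.005 — strains of a cluster travel together.

The same stages are available from the shell:

```bash
mastkit simulate --out demo --bees 12 --clusters 5 --seed 11
mastkit call --reads demo/reads --ref demo/references.fasta \
             --meta demo/metadata.tsv --out demo/table
mastkit cluster --table demo/table --marker guaA --sweep 1.2,2,4,6 --out demo/mcl
mastkit randomize --table demo/table --test reassort --marker guaA \
                  --reps 999 --seed 1 --out demo/reassort.json
mastkit evolve --mode pcr --seed 7 --out demo/evolve.json
```

or end to end via `mastkit run --config config.yaml`.

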