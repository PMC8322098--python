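# glpop

Genotype-likelihood population genetics for low-coverage whole-genome
resequencing of colonially breeding seabirds — and for any study design like
it: a few dozen diploids sampled from many breeding sites at 3–10×
coverage, where hard genotype calls are unreliable and every downstream
statistic must integrate over genotype uncertainty.

The package implements, as one tested pipeline:

- **Genotype likelihoods and the analysis panel** — biallelic GL triples
  `L(g) ∝ Π_reads P(read | g)` from read counts, per-site allele-frequency
  EM, "covered in all individuals" / MAF filtering, and LD pruning that
  keeps the most central site of each block of linked sites (r² > 0.2).
- **Folded site-frequency spectra** — 1D and 2D folded SFS by EM over
  `P(data | minor count)`, computed by dynamic programming over individual
  GL triples; from them θ_π, Watterson's θ, Tajima's D and per-individual
  heterozygosity (polymorphic fraction of the single-individual SFS).
- **Runs of homozygosity** — heterozygosity in 100 kb sliding windows
  (50 kb step); the 10 % quantile of the across-sample window means as the
  low-heterozygosity cutoff; RoH = ≥ 2 consecutive windows below the
  cutoff; F_RoH = RoH fraction of the scanned genome (segments ≥ 150 kb).
- **Structure** — covariance PCA of standardized posterior mean genotypes;
  admixture-proportion EM (`P(g | q, F) = Binom(2, Σ_k q_k F_k)`) with
  SQUAREM acceleration, replicate alignment/averaging, and Evanno ΔK model
  choice.
- **Divergence and admixture tests** — Hudson F_ST (ratio of averages) from
  the folded 2D SFS, globally and in 50 kb / 12.5 kb sliding windows, with
  Slatkin's linearisation F/(1−F); f3- and ABBA-BABA D-statistics with
  weighted block-jackknife Z-scores.
- **Trees** — consensus-base p-distances, canonical neighbor joining with
  deterministic tie-breaks, outgroup rooting, block-bootstrap support.
- **Isolation by distance** — least-cost-path distances over the water
  cells of a rasterised map (Dijkstra, great-circle edge costs), Mantel
  tests (999 permutations), multiple regression on distance matrices, and
  greedy progressive removal of the colonies that mask the IBD signal.
- **Mitogenomes** — haplotype collapsing, haplotype/nucleotide diversity,
  Tajima's D, pairwise Φ_ST and hierarchical AMOVA with permutation tests.
- **A synthetic data generator** (`glpop.simdata`) that emulates the study
  design end to end: 12 colonies × 6 diploids in four divergent clusters
  (Balding–Nichols drift down a population tree), stepping-stone IBD within
  the large central cluster with drift proportional to sea-route distance,
  one colony that is a recent 50/50 mixture of two clusters, one
  bottlenecked colony with implanted RoH tracts, an outgroup population, a
  star-genealogy mitochondrial alignment, and a rasterised North-Atlantic-
  like sea map — with full ground truth recorded for every stage.

## Worked example

```sh
python analysis/01_simulate.py 1      # write the simulated study inputs
python analysis/04_structure.py       # PCA + admixture + Evanno
python analysis/07_ibd.py             # sea distances, Mantel/MRM, removal
```

Output of the structure stage (seed 1):

```
variance explained: PC1 4.98%, PC2 4.35%, PC3 3.43%, PC4 1.59%
Evanno delta-K selects K = 4
mean ancestry of the admixed colony at K=4: [0.021 0.405 0.058 0.515]
```

PC1/PC2 separate the four simulated clusters, Evanno's ΔK recovers the true
K = 4, and the contact-zone colony is inferred to be a roughly half-and-half
mixture of the high-Arctic and central ancestries — its true mixing
proportion is 0.5. The IBD stage then prints:

```
all 12 colonies: Mantel r = 0.379, p = 0.063 (isolated clusters mask the within-cluster signal)
progressively removed: ['IsleOfMay', 'Spitsbergen', 'Hornoya', 'Rost', 'Bjornoya']
R^2 trajectory: 0.143 -> 0.366 -> 0.745 -> 0.866 -> 0.926 -> 0.970
central chain only (n = 7): Mantel r = 0.875, p = 0.006; MRM slope = 1.76e-06 per km, R^2 = 0.766
```

i.e. geography explains little of the genetic distance while the strongly
diverged colonies are included, and most of it once they are removed —
isolation by distance operating within, not between, clusters.

Every library function is also exposed through a thin CLI
(`glpop simulate | panel | diversity | roh | pca | admix | fst | dstat | f3 |
dist | nj | nj-boot | ibd | mito`); identical seeds give byte-identical
output files.

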