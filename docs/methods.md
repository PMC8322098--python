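# Methods

This note documents the models, estimators and design choices behind
`glpop`, and what the synthetic study the package ships with does — and does
not — establish about real data.

## Genotype likelihoods

A biallelic site with `n_major`/`n_minor` read counts and symmetric base
error ε has, for minor-allele dose g ∈ {0, 1, 2},

    P(minor read | g) = (g/2)(1 − ε) + (1 − g/2) ε
    L(g) ∝ P(minor read | g)^n_minor · (1 − P(minor read | g))^n_major

computed in log space and max-normalised. A site with zero reads is a flat
triple; flat triples are the missing-data convention every downstream EM
relies on (they contribute nothing to any update). The per-site ML allele
frequency comes from an EM on the HWE mixture Σ_g L(g)·HWE(g | f)
(tolerance 1e−8 on f, ≤ 200 iterations), and posterior mean dosages use an
HWE prior at that frequency.

LD pruning computes composite r² between posterior mean dosages of site
pairs within 100 kb (the window bound keeps pruning linear in panel size;
the threshold r² > 0.2 is the conventional one), takes connected components
of the r² graph, and keeps the member closest to the block's bp midpoint,
lower position on ties. "Central" is interpreted positionally; pruning a
pruned panel is a no-op.

## Folded spectra and diversity

For N diploids, P(data | j minor alleles among 2N chromosomes) is the
coefficient of z^j in Π_i (L_i0 + 2 L_i1 z + L_i2 z²) divided by C(2N, j)
(hypergeometric configuration weights), computed by per-site polynomial
convolution. Folding averages the two unfolded assignments of each folded
class, `P(data | k) = (P(j=k) + P(j=2N−k))/2`. The folded spectrum is then
the EM-estimated mixture weight vector (tolerance 1e−6, ≤ 500 iterations,
monotone log-likelihood); sites missing in every sampled individual carry no
information and are dropped from the spectrum. The joint 2D spectrum is the
same construction on the product grid with joint folding; its stored form
splits mass equally between the two conjugate assignments, which keeps all
downstream F_ST algebra well-defined because the Hudson per-cell terms are
themselves conjugation-symmetric.

θ_π uses the pairwise-difference weights k(2N−k)/C(2N,2), which are
invariant under folding; θ_W = S/a₁; Tajima's D uses the standard 1989
variance constants and is reported as missing when S = 0. Individual
heterozygosity is SFS₁/(SFS₀+SFS₁) of the single-individual folded
spectrum. Because the panel contains only sites that are polymorphic in the
ancestral pool, these statistics are per *panel* site, roughly two orders of
magnitude larger than genome-wide per-bp values, and Tajima's D on the panel
reflects the ascertainment of the site set as much as demography; the
mitochondrial D below is free of that ascertainment.

## Runs of homozygosity

Windows are anchored at multiples of the 50 kb step from position 0 and
truncated at the chromosome end; trailing windows shorter than one step are
dropped — a deterministic tiling that makes window arithmetic testable.
Windows with fewer than 10 informative sites are flagged unusable (variance
control at 3× coverage). The low-heterozygosity cutoff is the 10 % quantile
(linear interpolation) of the per-window heterozygosity averaged across
individuals; a run of ≥ 2 consecutive usable below-cutoff windows becomes
one segment from the first window's start to the last window's end
(unusable windows break runs), and F_RoH divides the summed length of
segments ≥ 150 kb by the union span of usable windows.

The window scan needs on the order of 100 informative sites per 100 kb
window before the cutoff separates genuine homozygous tracts from sampling
noise in the window estimates; the genome-wide default panel (one site per
5 kb) is far too sparse for it. The RoH analyses therefore run on a
dedicated dense simulation (one site per kb), which is also how the
acceptance checks exercise them. At that density, implanted tracts covering
30 % of a 50 Mb genome are recovered with segment-level recall and
precision 1.0 and F_RoH within 0.01–0.02 of truth at 10× coverage.

## Structure

PCA standardises posterior mean dosages by √(2f(1−f)) at the panel EM
frequency (a single-pass frequency estimate — no iterative individual-
frequency refinement), averages the covariance over non-missing pairs, and
fixes eigenvector signs by making the largest-magnitude entry positive.

The admixture model is the usual GL-aware mixture: individual allele
frequency h_is = Σ_k q_ik F_sk and P(data) = Σ_g L(g)·Binom(g; 2, h). The
EM map is wrapped in SQUAREM extrapolation with a monotonicity safeguard
(the extrapolated point is only accepted when it does not decrease the
likelihood), which cuts iteration counts by roughly an order of magnitude;
`n_init` independent starts with best-of selection guard against the rare
local optimum in which one small cluster is modelled away as an admixture
combination, exactly as scikit-learn's mixture EMs do. Q rows start
Dirichlet(1), F uniform in (0.05, 0.95) with a 1e−5 floor. Replicates are
aligned to the best-likelihood run by optimal column assignment, clustered
by post-alignment RMSD (single linkage, default 0.05), and averaged within
the largest cluster. Evanno's ΔK = |L′(K+1) − L′(K)|/sd(K) over interior K;
K values whose replicate sd is zero are reported infinite but excluded from
the argmax.

## Divergence and admixture tests

F_ST is Hudson's estimator in Bhatia et al.'s ratio-of-averages form, with
per-cell unbiased numerators (p̂₁−p̂₂)² − p̂₁(1−p̂₁)/(n₁−1) − p̂₂(1−p̂₂)/(n₂−1)
and denominators p̂₁(1−p̂₂)+p̂₂(1−p̂₁), weighted by folded 2D-SFS mass
(both grids are conjugation-symmetric, so folding is unambiguous).
Sliding windows sum per-site posterior expectations of the same terms under
the global 2D-SFS prior; the tiling includes truncated edge windows so each
position falls in exactly window/step windows, and the ratio of summed
window terms reproduces the global estimate exactly (at the EM fixed point
it also equals the SFS-mass estimate). Slatkin's linearised value is
F/(1−F).

f3(C; A, B) = mean[(ĉ−â)(ĉ−b̂) − ĉ(1−ĉ)/(n_C−1)] over sites with EM
allele frequencies; the correction assumes C's individuals are sampled
independently of A and B. The D-statistic defines the ancestral allele as
the outgroup's consensus (majority) allele, skipping and counting sites
whose outgroup majority frequency is below 0.9; per population one allele is
sampled by its frequency (a frequency-weighted mode is available behind a
flag). Significance comes from a weighted delete-one block jackknife
(Busing's estimator; 5 Mb blocks by default — with equal weights it reduces
to the textbook delete-one variance, which the tests assert to 1e−12).

## Trees

Consensus bases are the majority allele of the argmax posterior genotype,
heterozygotes resolved by a seeded fair coin; distances are mismatch
fractions over co-called sites. NJ is canonical Saitou–Nei with the
Studier–Keppler Q criterion and a deterministic lexicographic tie-break;
rooting bisects the outgroup's pendant edge. Bootstrap support resamples
5 Mb site blocks with replacement. Negative branch lengths are retained in
the output (display layers may clamp them).

## Geography and isolation by distance

The water mask is a rectangular lat/lon grid; least-cost paths run Dijkstra
over water cells with 8-neighbour moves costed by great-circle distance
between cell centres (inputs are geographic coordinates, so planar costs
would distort the high latitudes). Colonies snap to the nearest water cell
within two cells. The Mantel test is one-tailed (IBD is a directional
hypothesis) with p = (#{r_perm ≥ r_obs}+1)/(n_perm+1); MRM is OLS on
vectorised lower triangles with label-permutation significance and a
condition-number guard against collinear predictors. Progressive removal
greedily drops, at each step, the colony whose removal most increases the
single-predictor R², stopping after `max_removals` (default 4), when the
best gain falls below 0.01, or when fewer than five colonies would remain —
by construction the reported R² trajectory is non-decreasing.

## Mitochondrial analyses

Haplotypes collapse by identity at all co-called columns; sequences
differing only by missingness merge, with the most complete sequence kept
as representative. Distances are raw counts of differing called positions
(no substitution-model correction — a config hook exists), which serve
directly as the squared distances of the AMOVA sums of squares. The
hierarchical AMOVA uses the classical three-level moment equations;
permutation schemes follow the level being tested (colonies among groups
for Φ_CT, individuals among colonies within groups for Φ_SC, individuals
among all colonies for Φ_ST). Variance components are reported raw (they
may be negative).

## The synthetic study

The generator draws ancestral frequencies from Beta(0.8, 0.8) truncated to
[0.05, 0.95] (all panel sites polymorphic in the ancestral pool), drifts
them down a population tree by Balding–Nichols Beta sampling per branch —
analytically tractable where a forward Wright–Fisher simulation would not
be — and emits Poisson reads with per-individual mean depth uniform on
3–10× (outgroup 20×) and 1 % base error, the coverage profile typical of
this study design. Sites are independent by default (the analyses assume a
pruned panel); an optional block-copy correlation exists to exercise the
pruner.

Default layout (decided once; all drift values below are per-branch F):

- Four clusters: a high-Arctic isolate (branch 0.18 + colony 0.01, with a
  bottleneck signature), a two-colony western cluster (0.11 + 0.004 each),
  a southern isolate, and a seven-colony central chain (ancestor 0.025).
- The southern isolate's ancestor sits midway between the western and
  central lineages (frequency mixture) before a long private branch
  (0.25 + 0.004). This geometry is deliberate: it keeps the four cluster
  means mutually separated in *any* two-dimensional principal-component
  projection (with four mutually orthogonal island lineages, the two
  lightest clusters collapse onto each other in the PC1/PC2 plane), while
  the long private branch means no three-cluster model can absorb the
  fourth cluster as an admixture combination — which is what gives the
  Evanno curve its elbow at the true K.
- Within the central cluster, colonies form a stepping-stone chain whose
  per-leg drift is proportional to the sea-route distance of the leg
  (0.0033, 0.0041, 0.0018, 0.0012, 0.0007, 0.0008), so expected
  differentiation grows with geographic distance by construction.
- One colony is a recent 50/50 genotype-level mixture of the high-Arctic
  colony and the nearest chain colony (secondary contact; each allele copy
  draws its source population independently).
- The bottlenecked colony carries implanted homozygous tracts (0.5–2.5 Mb,
  totalling 16 % of the genome per individual by default).
- The mitochondrial alignment is a star genealogy with Poisson(3) private
  substitutions per individual on a 5 kb sequence — an excess of rare
  variants (Tajima's D ≈ −3) and nearly as many haplotypes as individuals,
  with no population structure; a two-island variant exists for Φ_ST truth
  checks.
- The map is a 36° × 94° one-degree grid with five rectangular land blocks;
  colony coordinates are realistic North-Atlantic positions and all
  colonies are mutually reachable through water.

Cluster drift coefficients are an order of magnitude larger than the
pairwise F_ST values typical of real seabird colonies. This is the
deliberate desk-scale calibration: statistical signal scales with
sites × F, and the default panel holds 2×10⁴ independent sites where a real
panel holds 10⁶, so drift is scaled up to keep cluster detectability
comparable. Consequently the simulation demonstrates that the *machinery*
recovers structure, admixture, RoH and IBD correctly at its signal-to-noise
level — it does not demonstrate sensitivity at real-data effect sizes, nor
does it model linked sites, batch effects, reference bias or mapping error.

All randomness flows from one seed through named child streams; identical
config + seed reproduces every output byte-for-byte.

## Problem sizes and tolerances used in the shipped analyses

Default panel 20,000 sites / 100 Mb in five chromosomes; Evanno runs on a
2,000-site subsample with three replicates of a best-of-two-starts EM
(tolerance 0.05 on the log-likelihood — model choice needs differences of
thousands of log-units, not the last decimals); full-panel admixture fits
use tolerance 1e−3–1e−4; the RoH scan uses a dense 50,000-site / 50 Mb
single-colony simulation at 10×; jackknife and bootstrap blocks are 5 Mb;
permutation tests use 999 permutations (199 where a p-value is only
reported, not tested). The acceptance checks state their thresholds
directly in `tests/test_acceptance.py`.
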