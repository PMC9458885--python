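# Methods

This note records the statistical methods, the default parameters and
why they were chosen, and the known limitations of the package.

## Data model and encoding

**Genotypes.** Biallelic SNPs on an inbred (selfing) variety panel,
coded as alternate-allele dosage 0 / 0.5 / 1 per variety (0.5 =
residual heterozygote), missing as NaN.  VCF input is read with cyvcf2;
multiallelic or non-diploid records are rejected rather than silently
recoded.  Loci are kept in (chromosome, position) order.

**Filtering** keeps loci with minor-allele frequency strictly above
0.05 and missing rate strictly below 0.2.  MAF is computed from allele
dosages over *non-missing* calls only; loci with no observed calls have
undefined frequency and are always dropped.

**Imputation** replaces missing calls with the per-locus modal code;
ties resolve to the smallest code (0 < 0.5 < 1) so the result is
deterministic.  Imputation is the only data-completion step — ordinal
trait codes are never imputed.

**Phenotypes.** Each trait is an ordinal grade in 1–9.  The indicator
encoding expands a trait into one 0/1 column per *observed* level; a
variety with a missing grade gets an all-zero row in that trait's
block.  Both encodings live on a 0–1 scale, which is what makes a
single distance measure applicable to either side.

## Distance measures

Ten measures are implemented (`ricedus.distances.TEN_METRICS`):
euclidean, squared euclidean, manhattan, gower (range-normalised
manhattan / p), canberra, cosine (1 − cosine similarity), pearson
(1 − Pearson correlation of the two profiles), harmonic mean
(1 − (2/p) Σ xy/(x+y)), and the continuous (Tanimoto) extensions of
jaccard, 1 − Σxy / (Σx² + Σy² − Σxy), and dice, here
Σ(x−y)² / (Σx² + Σy²).

Degenerate-vector conventions are fixed rather than left to NaN: for
the similarity-derived measures two all-zero vectors are at distance 0,
one zero vector against a non-zero one is at distance 1; the pearson
measure treats two constant vectors as distance 0 and a constant
against a non-constant as 1.  A chi-square-style alternative
(`pearson_chi2`) is provided for users who read "Pearson distance" as
the chi-square coefficient rather than 1 − r.

Every measure exists twice: a scalar reference implementation
(`pair_distance`, transcribing the formula directly) and a vectorised
matrix implementation (`distance_matrix`, scipy `pdist` or Gram-matrix
algebra).  The test suite checks them against each other and against
independently coded oracles; tiny negative values from floating-point
cancellation are clipped to zero and matrices are symmetrised exactly.

## Distance-matrix correlation

Agreement between the molecular and phenotypic matrices is the Pearson
correlation of their strict lower triangles (n(n−1)/2 variety pairs).
Significance uses a Mantel permutation test: rows and columns of one
matrix are permuted jointly, and the one-sided p-value is
(1 + #{r_perm ≥ r_obs}) / (1 + n_perm), default 999 permutations.
`metric_screen` ranks all ten measures by r (ties broken
alphabetically).

`subsample_curve` recomputes the correlation on random SNP subsets (or
trait subsets — trait indicator blocks are kept atomic) of increasing
size.  On realistic panels the curve saturates well below the full
panel size: a few hundred informative SNPs carry nearly all of the
phenotype-relevant relationship signal, so adding markers stops adding
correlation (the ceiling effect).

## Genomic prediction

Each trait's codes are treated as a quantitative response in the ridge
BLUP mixed model y = μ1 + Xα + e with α ~ N(0, σ²_u I),
e ~ N(0, σ²_e I).  `mixed_solve` estimates λ = σ²_e/σ²_u by REML on
the spectral decomposition of the projected kinship K = X_c X_c'
(column-centred X): the fixed effect is projected out, the profiled
REML criterion (n−1)·log Σ η²/(θ+λ) + Σ log(θ+λ) is minimised by
bounded Brent search on log λ ∈ [−10, 10], and marker effects are
recovered as α = X_c'(K+λI)⁻¹(y − μ̂1) with a GLS intercept.  The
implementation is validated against an independent dense
log-determinant REML criterion evaluated on a grid.

Cross-validation (`cv_accuracy`) repeatedly splits the varieties with a
non-missing grade into a training set of fixed size (default 90, the
classic 90-of-122 design; `proportional_n_train` scales it to other
panels) and scores the Pearson correlation between predicted and
observed codes on the hold-out.  Replicates with constant truth or
prediction yield NaN and are excluded from the mean.

`stratify_traits` splits traits at a mean-accuracy threshold (default
0.443, the midpoint separating the two clusters in the bundled
benchmark table) into a hard-to-predict group A and an easy group B,
and `group_distance_correlation` recomputes the phenotypic distance on
each group's indicator blocks against the full-panel molecular
distance.  On synthetic data, low-heritability trait groups correlate
with molecular distance systematically less than high-heritability
groups.

## Distinctness ("D" sets)

A variety's separation score is its distance to its nearest neighbour
in the panel.  The "D" set of size k contains the k highest-scoring
varieties (ties broken by variety id), with the realized threshold
reported as the last admitted score.  This rule makes D sets *nested*
in k, which in turn forces every row and column of the reproduction
matrix — shared counts between phenotypic D sets and molecular D sets
over ladders of sizes — to be monotone non-decreasing, with the full
panel recovering the marginal sizes.

Two size ladders are available: `ladder_sizes` (default) uses
round(0.1·n) × (1, 2, 4, 6, 8) plus the full panel — 12, 24, 48, 72,
96, 122 on a 122-variety panel — while `fraction_sizes` applies
round-half-up to arbitrary fractions.

## Cluster comparison

UPGMA (and complete linkage) is implemented directly rather than via
scipy so that ties merge deterministically: among equal-distance pairs
the one whose clusters contain the lexicographically smallest leaves
merges first.  Heights follow the ultrametric convention (two leaves at
distance d merge at height d/2, monotonized), so Newick export places
every leaf at the same depth.  On tie-free matrices the trees agree
with scipy's `average`/`complete` linkage cophenetic structure to
1e-10.  Concordance between two trees is the set of shared *cherries*
(pairs of leaves that are mutual sisters); unrelated trees share
essentially none.

## SNP panel summaries

Per-locus heterozygosity is the fraction of 0.5 calls among non-missing
calls.  Inter-SNP intervals are computed within chromosomes only and
binned into < 1 kb, 1–3 kb and ≥ 3 kb (left-closed bins).
Per-chromosome density is length_Mb × 1000 / n_SNP in kb per SNP,
rounded to 2 decimals; `ricedus.reference.CHROMOSOME_SNP_PANEL` bundles
a published 12-chromosome benchmark whose density column the code
reproduces exactly.

## Synthetic data generator

`simulate_genotypes` draws subpopulation allele frequencies from the
Balding–Nichols model: ancestral frequency p ~ U(maf_range), then per
subpopulation Beta(p(1−F)/F, (1−p)(1−F)/F) with F = Fst.  Varieties
are split evenly over subpopulations; two allele draws per variety give
the genotype, after which heterozygotes are collapsed to a random
homozygote except with probability `het_rate` (default 0.02) —
mimicking inbred lines with residual heterozygosity.  Loci sit on 12
chromosomes with exponential inter-SNP gaps (mean 3 kb); missing calls
are injected uniformly at the requested rate.

`simulate_traits` assigns each trait `n_causal` loci (default 100) with
N(0,1) effects, adds Gaussian noise with variance
var_g·(1−h²)/h² to hit the requested narrow-sense heritability, and
ordinalises the liability by sample quantiles (or equal-width bins)
into the trait's number of levels.

`benchmark_config` freezes a study-scale default: 122 varieties, 4
subpopulations, Fst 0.3, 5000 SNPs, 30 traits with h² evenly spaced
0.10–0.85, alternating 3-level and 9-level grades.  Fst 0.3 and the
mixed level counts were fixed by a sensitivity sweep *before* any
acceptance checks were written: uniform fine-grained (9-level) grading
of every trait makes nearly all variety pairs mismatch on every trait
and destroys the molecular–phenotypic correlation, which real DUS
traits (many of which are coarse categorical notes) do not do.

**What the generator does not emulate:** linkage disequilibrium beyond
population structure, selection, pedigree relationships, or
trait–trait genetic correlation.  Real panels carry strong kinship and
LD, so absolute distance correlations on synthetic data (r ≈ 0.1–0.2)
sit below values observed on real variety panels; orderings and
qualitative effects (ceiling, heritability ordering) are preserved and
are what the acceptance checks assert.

## Determinism

All stochastic stages take explicit seeds.  The CLI derives per-stage
sub-seeds as blake2b(f"{seed}:{stage}") mod 2³¹, so stages are
independent, reproducible and stable across runs; pipeline reruns with
identical inputs and seed produce byte-identical reports (verified by
SHA-256 manifest).

## Limitations

- Ordinal codes are modelled as quantitative responses in prediction;
  no threshold/ordinal-link model is provided.
- Mode imputation ignores population structure; for high missing rates
  a model-based imputer would be preferable.
- The Mantel test's permutation count bounds the smallest attainable
  p-value at 1/(n_perm+1).
- UPGMA comparison uses cherries only; it does not score deeper
  topological agreement (e.g. Robinson–Foulds), which would be a
  natural extension.
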