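# Methods

`tricross` implements, end to end, the analysis chain used to triangulate
candidate genes for a heritable behavioral temperament in a two-line
selective-breeding rat cross: bred High Responders (bHR; highly
exploratory) versus bred Low Responders (bLR; inhibited, anxious), their
F1, and a re-segregating F2 intercross. Because the real cohorts are not
reproducible at desk scale, the package ships a synthetic cross whose
planted effects every stage must recover; the generator is first-class,
tested code, and its defaults define the study conditions used by the
test suite and `scripts/acceptance.py`.

## The synthetic cross

**Genome.** Three chromosomes of 100 Mb carrying 2,000 SNPs and 100 gene
TSSs each, positions uniform, genetic map linear in physical position.
The three desk-scale chromosomes stand in for the ~20 rat autosomes, so
each carries 500 cM: compressing the genome while conserving its total
recombination budget (~1,500 cM) preserves the rate at which linkage
disequilibrium decays between unlinked planted effects, which is what
controls the resolution of QTL mapping and SMR colocalization downstream.
Compressing the map as well (e.g. 3 x 100 cM) leaves every segregated
variant within ~20 cM of some QTL and makes colocalization uninformative.

**Founders.** Two lines of 10 animals each (matching the 10+10 sequenced
founders of such designs). Per SNP, a category fixed deterministically by
count: 5% fixed-divergent (lines homozygous for opposite alleles; which
line carries the alternate allele is randomized), 10% partially
segregated (line frequencies 0.0 vs 0.55 — chosen so the G'st > 0.27
segregation threshold is genuinely exercisable in both directions), the
rest sharing a Beta(2, 2) frequency. Within-line genotypes are drawn
under Hardy-Weinberg; phase is tracked throughout so Mendelian
consistency is testable.

**Cross.** Each F1 receives one unrecombined gamete from a founder of
each line; 250 F2 animals come from random non-sib F1 x F1 pairs (the F1
mating design is not constrained by the source study; random non-sib
pairing is the neutral default). Gametes follow the Haldane model:
Poisson(length in Morgans) crossovers, positions uniform on the cM map,
no interference — chosen for its closed-form map function, which the
tests use as an oracle.

**Expression.** Counts are negative binomial with gene-specific
dispersion (log-normal around 0.05, log-SD 0.5) and log-normal library
factors (CV 0.3), giving a realistic mean-variance relation for the
voom-style weighting stage. A planted cis-eQTL with allelic fold change
aFC multiplies the mean by ((2 - d) + d 2^aFC)/2 at dosage d, so the
log2 ratio of homozygote means equals aFC exactly in expectation — the
same additive cis-regulatory model the estimator inverts. Sparse log2
effects of sex, batch, dissector, prior Pavlovian training, and the
%rRNA / %intergenic quality covariates are planted so the covariate
machinery has real work to do.

**Behaviors.** Five adult behaviors (LocoScore, EPM distance, EPM time
immobile, EPM % open arms, PavCA index), each the sum of planted QTL
effects, a sex shift (0.3 SD, absent for LocoScore), a shared "bLR-like"
polygenic factor (loading 0.3, entering each behavior through its sign
convention so behaviors correlate along the temperament axis), and
N(0, 0.85^2) noise. The PavCA index can also be computed from trial
summaries via `compute_pavca_index` (mean of probability difference,
response bias, latency score; sign-tracker > 0.5, goal-tracker < -0.5);
no trial-level learning model is simulated.

**Planted architecture (defaults).** 10 pleiotropic genes whose
fixed-divergent eVariant carries both |aFC| in [1, 2] (random sign) and a
0.5 SD-per-allele effect on LocoScore plus one rotating second behavior,
oriented so the bLR-enriched allele pushes behavior in the bLR-like
direction; 6 non-behavioral cis-eQTLs at partially segregated variants;
10 at background variants; 30 genes with a direct (non-cis) line effect
of |log2FC| = 1 on founder expression. A second, independently drawn
founder expression cohort fills the replication slot of the two-dataset
DEG rule (the real study's slot is a published meta-analysis, which is
data-bound). An optional disjoint juvenile F2 cohort (n = 216, open-field
battery) shares the founder genetics for SMR replication runs.

## Analysis stages

**Differential expression.** Genes with <1 read in >=75% of samples are
removed (boundary inclusive). TMM factors (30%/5% M/A trims,
precision-weighted, geometric mean 1; validated against edgeR), log2 CPM
with prior count 0.5, voom-style weights (LOWESS span 0.5 on sqrt
residual SD vs mean log2 count; inverse fourth power at each fitted
log-count), per-gene WLS, and empirical-Bayes moderation with the
log-variance moment fit of (d0, s0^2) (validated against limma; the
d0 = infinity branch pools all genes onto s0^2). Models: founder line
contrast (Lineage + Sex + %rRNA + %intergenic) and F2 behavior (behavior
+ Sex + %rRNA + %intergenic + Dissector + STGT experience + batch
dummies; 3 batches by default), bHR and male as reference levels so
positive log2FC = up in bLR. An optional sex x behavior interaction term
is available. BH FDR throughout.

**Concordance.** Pearson/Spearman agreement of effect sizes; a two-sided
RRHO map (signed hypergeometric tails on a rank grid, step N/100); the
DEG rule (FDR < 0.10 in either dataset, or nominal p < 0.05 in both with
consistent direction); per-gene behavior flags (a bLR-up DEG is bLR-like
iff some behavior shows a nominal association whose sign, after the
bLR-positive convention, matches); Fisher exact overlap enrichment
(sample OR, exact p, conditional-MLE CI).

**GSEA.** Ranking statistic = mean sign-harmonized moderated t over the
seven analyses (two line contrasts, five behaviors); genes missing from
some analyses are averaged over those available (count recorded; a drop
policy is selectable). Weighted-KS enrichment score (weight exponent 1)
with a size-matched gene-permutation null; p = (1 + #{|null ES| >=
|ES|})/(1 + nperm) — the two-sided count keeps null p-values uniform,
which the one-sided count over a both-signs denominator does not;
NES = ES / mean(|null ES| of matching sign).

**cis-eQTL mapping.** Expression residualized on the technical design,
rank-inverse-normal transformed (Blom offset 3/8, average ranks), and
scanned against MAF > 0.01 dosages within TSS +/- 1 Mb with 5 expression
PCs + 5 PCs of LD-pruned genotypes (50-SNP window, step 5, r^2 > 0.5,
greedy later-index removal) as covariates. Gene-level significance: the
covariate-residualized phenotype is permuted (preserving LD among SNPs,
which the approximation requires), a Beta(a, b) is fitted by maximum
likelihood (moment initialization) to the per-permutation minimum
nominal p, and the empirical p is the Beta CDF at the observed minimum;
degenerate minima fall back to the rank-based p. BH over genes at 0.05
calls eGenes (the upstream tool's qvalue variant is not mandated; BH is
parameter-free and conservative). Top-association ties (perfect LD) are
broken by a seeded uniform choice. Conditional signals: forward stepwise
rescans conditioning on accepted eVariants, accepting a signal iff its
nominal p is below the gene's threshold (the nominal p mapping to
empirical p = 0.05 through the primary beta null). Default n_perm = 500
in the pipeline (1,000 in the op default; config up to 10,000) — at the
desk-scale window sizes the beta fit is already stable there.

**aFC and segregation.** aFC is fitted in log2 space on count + 1: for a
trial aFC the dosage term is a fixed offset and the covariates are
profiled out by OLS, leaving a smooth 1-D RSS minimized by a
deterministic coarse-grid + bounded-Brent search, box-constrained to
|aFC| <= log2(100) with the cap flagged. Founder allele frequencies per
line feed Hedrick's standardized G'st with Nei-Chesser small-sample
estimators (harmonic-mean n, observed-heterozygosity correction);
eVariants with G'st strictly > 0.27 count as line-segregated (threshold
config-exposed). The signed prediction is aFC x sign(p_bLR - p_bHR)
(frequency direction only, no significance test), compared against the
observed F0 line contrast by correlation and sign concordance.

**SMR and the gate.** The stand-in GWAS is per-SNP OLS of behavior on
dosage with a sex covariate (the original study's mixed-model GWAS is
external; genotype-PC covariates were evaluated and do not change the
picture because the relevant confounding is local co-segregation, not
global structure). SMR: T = z_e^2 z_g^2/(z_e^2 + z_g^2), p from the
chi-squared(1) upper tail, BH within behavior; the directional statistic
is sign(beta_eQTL beta_GWAS) sqrt(T) (the signed square root; a signed-T
variant is a config switch). Candidate genes must pass all six criteria:
line DEG; concordant nominal behavioral association; segregated eGene;
aFC sign predicting the F0 contrast; SMR q < 0.10 for some behavior; and
SMR direction matching that behavior's F2 log2FC sign. The
chance-expectation analogue permutes only the DE-side gene labels
(F0 DE, DEG membership, flags, F2 DE) and recomputes the gate; the
genetic tables stay fixed, since permuting them with the same mapping
would preserve the criterion-4 match and defeat the null.

## Numerical choices and degenerate inputs

- Seeds: every stage derives its seed from the master seed and the stage
  name (CRC-keyed SeedSequence, < 2^31); identical configs reproduce
  bit-identical outputs.
- Zero residual variance genes stay finite through variance shrinkage;
  all-zero counts give a flagged aFC record; constant vectors are
  rejected by RINT and the GWAS scan; a 2x2 table with an empty margin
  is reported as degenerate (OR undefined, p = 1).
- Beta fit minima are clipped to (1e-12, 1 - 1e-12); the conditional
  scan drops collinear conditioning dosages.
- Coordinates are 1-based inclusive (VCF convention); the cis window is
  [TSS - 1e6, TSS + 1e6] inclusive; strand is ignored for windows.

## Problem sizes

The shipped configuration is desk-scale by design: 300 genes, 6,000
SNPs, 250 F2 animals, n_perm = 500, 10 seeded end-to-end replicates in
the acceptance script; single runs take ~15 s on one CPU. Calibration
analyses use 5,000 null genes (DE), 200 null genes (eGene rate), and 50
genes for the beta-approximation fidelity check.

## What passing tests do and do not show

The generator emulates the design features the pipeline's logic depends
on — line-segregated allele frequencies, F2 re-segregation under
recombination, cis-dosage effects on NB counts, correlated behaviors
with shared QTLs, nuisance covariates — but not read-level noise,
litter/maternal structure, selection over 37 generations, founder
haplotype LD, trans-eQTLs, or cell-type composition. Recovery of planted
effects therefore validates the statistical machinery and its wiring,
not performance on real tissue RNA-seq.

Known limitations:

- **LD contamination is real and intended.** In an F2, line-origin
  correlation decays only as (1 - 2c); a non-behavioral eGene whose
  segregated eVariant sits within ~15-20 cM of a true behavioral QTL
  genuinely colocalizes at F2 resolution and will pass the gate. With
  the default map (1,500 cM total) this costs the gate ~0.1-0.2 in
  precision; on a compressed map (or with many fixed-divergent
  non-behavioral eQTLs, constructible via `CohortParams`) precision
  degrades toward 0.5-0.6. No heterogeneity (HEIDI-style) test is
  implemented.
- The stand-in GWAS is OLS; relatedness among F2s (shared F1 parents) is
  ignored, which is acceptable at n = 250 with ~20 F1 parents but would
  not be for a structured real cohort.
- The replication cohort redraws founders from the same line
  frequencies, so it is a same-generation biological replicate, not a
  cross-generation meta-analysis; cross-region meta-analysis is out of
  scope.
- `aFC` is fitted by log-space least squares, not the count-likelihood
  fit of dedicated tools; the two agree in expectation under the
  generative model (tested in the noise-free limit) but differ in finite
  samples at very low counts.
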