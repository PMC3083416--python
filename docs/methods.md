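# Methods

## Statistical model

### Allelic case-control test

For a biallelic SNP the 2×2 table of allele counts (two per genotyped
individual) is

|          | minor (A1) | major (A2) |
|----------|-----------|-----------|
| cases    | a         | b         |
| controls | c         | d         |

and the statistic is the uncorrected 1-df Pearson chi-square,
χ² = N(ad−bc)² / ((a+b)(c+d)(a+c)(b+d)), with p the upper χ²₁ tail.  No
Yates continuity correction is applied; at the allele-count sample sizes
this package targets (hundreds of cases, thousands of controls) the
uncorrected statistic matches the convention of standard GWAS toolkits and
reproduces the published worked-example values.

The minor allele A1 is the allele with the lower *combined*
(cases + controls) frequency at that SNP, computed from non-missing calls
only; an exact tie breaks lexicographically on the allele label so results
are deterministic.  The odds ratio OR = ad/bc is oriented to A1: OR > 1
means the minor allele is enriched in cases.  The worked-example table's
footnote describes its OR as "with respect to the major allele", but every
printed OR in it equals the minor-allele odds ratio recomputed from the
printed frequencies (e.g. 0.391/0.447 → 0.79), so the numerically
consistent orientation is implemented and this note records the
discrepancy.  A zero cell leaves the OR undefined (NaN) unless the
Haldane–Anscombe +0.5 correction is requested; a zero table margin is an
error rather than a silent zero statistic.

### Quantitative-trait regression

Traits are per-case sums of 0–3 item severities within a behavioural
category (sum over observed items; a case missing more than
`max_missing_fraction` — default 0.2 — of a trait's items gets a missing
trait value and drops out of that trait's analyses).  The default recode
map sends raw codes 0–3 to themselves, 7 (non-severity abnormality) to 0,
and 8/9 (not applicable / not asked) to missing; the map is configurable
because instruments differ in their special codes.  Each SNP is tested by
simple linear regression of the trait on additive dosage (0/1/2 copies of
A1), with the two-sided p from t with n−2 df — exact at small n and
indistinguishable from the asymptotic normal at cohort scale.  Monomorphic
SNPs or SNPs with fewer than three usable case observations are flagged
untestable and never enter QTL sets.  The screen threshold p ≤ 10⁻⁵ is
inclusive; the boundary has probability zero so the choice is cosmetic.

### Quality control

Variants are removed when missing in more than 10% of all samples, when
the minor allele frequency over non-missing calls is below 0.01, or when
the Hardy–Weinberg goodness-of-fit p (1-df Pearson chi-square against
p², 2pq, q² at the sample allele frequency) is below 0.001 *in controls
only* — cases may legitimately deviate at associated loci.  The chi-square
HWE test (rather than the exact test) matches the era of the cleaning
protocol being reproduced; swapping in an exact test would only tighten
behaviour at rare alleles, where the MAF filter already acts.

### Multiple testing

Bonferroni (min(1, p·m)) and Benjamini–Hochberg step-up adjustments take an
explicit m because the set of SNPs *tested* in a run can exceed the rows a
report shows.  In the pipeline m is always the size of the SNP set tested
in that (trait × subtype) run — the trait's QTL-set size in stage 2, the
combined-list size in stage 3 — and adjustments are computed within each
run, never pooled across subtypes.

## Subtyping

Cases are clustered by Lloyd's K-means on the cases × 123 item-severity
matrix.  Missing entries are handled by the scaled observed-only distance
d(x,c) = (P/|O|)·Σ_{i∈O}(x_i−c_i)² (P items total, O observed), which
keeps sparsely scored individuals comparable without imputation; centroids
are per-cluster means over observed entries.  Defaults: 10 restarts with
centroids seeded from data rows, at most 100 iterations, convergence on an
unchanged assignment; a cluster that empties is re-seeded from the point
farthest from its current centroid.  The restart with the lowest total
within-cluster distance wins, and the per-iteration objective history is
retained so monotonicity is checkable.  Because the centroid update uses
unweighted observed means (not means weighted by P/|O|), strict objective
monotonicity is guaranteed only for complete data; with the low
missingness rates simulated here the distinction has never been observed
to matter.

K is chosen by a leave-one-item-out figure of merit: cluster on all items
but e, then FOM(e) is the root-mean-square deviation of item e from its
cluster means, summed over e and divided by √((n−K)/n).  The curve
decreases in K, so the selected K is the elbow — the interior K with the
largest second difference.  PCA (scikit-learn, full SVD, column-mean
imputation) provides the visual separation check.  Clusters are named by
descending mean severity; with K = 4 the conventional labels are
Language-impaired, Intermediate, Moderate, Mild.  Distinguishing
"Moderate" from "Intermediate" by savant-item semantics is deliberately
not automated — naming is strictly severity-rank-based, with ties broken
by cluster index.

## Synthetic cohort generator

The generator emulates the study conditions rather than any particular
dataset: 639/478/363/387 cases in four severity archetypes plus 2438
shared controls by default, biallelic SNPs with control minor-allele
frequency m ~ U(0.05, 0.5), genotypes drawn per individual as
Binomial(2, m) (Hardy–Weinberg).  A planted case-control effect shifts the
risk-allele frequency on the logit scale in the targeted subtypes —
m′ = OR·m/(1−m) / (1 + OR·m/(1−m)) — because the pipeline's statistic is
allelic, making the planted OR directly the estimand.  A planted
quantitative-trait effect adds β per risk-allele copy to one trait.

Item scores are clamp(round(archetype + N(0, σ)), 0, 3) with σ = 0.3 by
default, plus a 2% rate of not-applicable codes (8/9).  The default
archetype matrix assigns block severities over seven item blocks (the five
trait blocks, an "other" block, and a 12-item savant block elevated only
in the moderate archetype); pairwise archetype separations of ~7–9 in L2
make label recovery essentially deterministic at σ ≤ 0.3, which is what
the exact-size-recovery check relies on.  One global seed drives spawned
per-component streams (MAFs, allele labels, genotypes, missingness, item
noise), so outputs are bit-reproducible and components are independent.

Genotype coding is canonicalised to PED file-observation order (allele_a
is the allele a reader of the written file would meet first), so
write-then-read round-trips are exact; the ground-truth record keeps the
risk-allele label and exposes `risk_dosage` to recover oriented dosages.

What the generator does **not** emulate: linkage disequilibrium between
SNPs, family structure, sex chromosomes, population stratification, and
item-level correlation beyond the block archetypes.  Passing recovery
tests therefore demonstrate correctness of the statistical machinery under
the assumed model, not robustness to confounding present in real cohorts.

## Validation experiments

`stratqtl.validation` packages four seeded experiments, reported by
`scripts/acceptance.py`:

* **Type-I error** — 5000 null SNPs at MAF 0.3, 500 cases vs 500 controls;
  the allelic test's rejection rate at α = 0.05 should sit in [0.04, 0.06].
* **Subtype detection** — 50 cohort replicates at full scale with one
  OR = 2 SNP planted in the largest subtype inside a 20-SNP QTL set; the
  planted SNP should be Bonferroni-significant in its subtype and clean in
  an unaffected subtype in ≥ 90% of replicates.
* **Screen power** — 100 replicates of a β = 3 effect on the
  insistence-on-sameness trait at MAF 0.3 with 1500 cases; the 10⁻⁵
  screen should catch it in ≥ 95%.  The sameness trait is used because its
  between-subtype variance is the smallest of the five blocks, making the
  planted effect's t-statistic (≈ 8) comfortably, but not trivially, above
  the screen threshold.
* **Clustering recovery** — one full-scale cohort; adjusted Rand index of
  recovered vs planted labels and exact cluster-size match.

Problem sizes (5000 SNPs, 50/100 replicates, 20-SNP panels) were chosen so
the whole battery completes in seconds while keeping Monte-Carlo standard
errors well inside the asserted bands.

## Numerical and design notes

* Positions are 1-based throughout (MAP convention); no coordinate
  transforms anywhere.
* PED phenotype column: 1 = control, 2 = case; anything else excludes the
  sample with a warning.
* Combined-case association rows are computed and reported at every stage
  but never drive SNP selection; selection is per-subtype only.
* Controls are reused against every subtype; they are never split.
* Replication thresholds: Bonferroni ≤ 0.05 counts as significant,
  BH FDR < 0.09 as suggestive — the same cutoffs the worked-example table
  uses to display rows, which is why appearance-based and threshold-based
  replication counting coincide on it.
* The exact item membership of each behavioural trait is
  instrument-specific and user-supplied (a `name = item,item,...` config);
  the generator ships block definitions aligned with its archetypes.
* Association tables are written with frequencies at 3 decimals, χ²/OR at
  2, p-values at 4, in the conventional column order
  CHR SNP BP A1 F_A F_U A2 CHISQ OR … UNADJ FDR_BH BONF.

## Known limitations

Only the allelic (1-df) model is implemented — no genotypic, trend,
dominant/recessive, covariate-adjusted, or family-based tests, and no
population-stratification correction.  Binary PLINK (BED/BIM/FAM) and VCF
input are out of scope; data arrive as text PED/MAP.  Multi-allelic
variants are rejected at parse time.  Mendelian-error QC is not available
because no pedigree information is modelled.
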