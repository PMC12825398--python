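# Methods

## The inference problem

In a reciprocal cross between two polymorphic diploid plants, endosperm
RNA-seq reads overlapping SNPs that distinguish the parents can be
assigned a parent of origin. The per-gene **maternal proportion**
θ = M / (M + P) — maternal over total parent-assignable read equivalents —
has expectation 0.5 in a diploid (1 maternal : 1 paternal) endosperm such
as *Nymphaea*'s (a typical triploid 2m:1p endosperm would use 2/3, exposed
as `null_maternal_proportion` / `maternal_dosage_ratio`). Genes whose θ
departs from that null in **both** directions of the cross are candidates
for genomic imprinting: maternally expressed genes (MEGs, θ high with
either plant as mother) or paternally expressed genes (PEGs, θ low in both
directions). Requiring both directions separates parent-of-origin effects
from allele (genotype) effects.

## Informative sites and the pooled-transmission model

A biallelic SNP with both parental genotypes called falls into one of:

| category | genotypes | discriminant allele |
|---|---|---|
| `RECIPROCAL_HOM` | both homozygous, different alleles | mother's allele tags maternal reads directly |
| `MOTHER_HET` | mother 0/1, father homozygous | mother's private allele |
| `FATHER_HET` | father 0/1, mother homozygous | father's private allele |
| `UNINFORMATIVE` | both identical-homozygous or both heterozygous | none |

Endosperm dissections pool tissue from many sectioned seeds. A
heterozygous parent transmits its private allele to half the seeds, so in
the pooled read mixture the private allele's expected frequency is (that
parent's expression share)/2 — θ/2 for `MOTHER_HET`, (1−θ)/2 for
`FATHER_HET`. The transformation therefore doubles the private-allele
count to obtain that parent's read equivalents, capping at the site total
(and flagging `truncated`) when sampling noise pushes the doubled count
past 100%. Transformed counts are **summed** over a gene's sites before
dividing, which weights sites by depth and keeps gene totals on the count
scale the chi-squared test needs; averaging per-site proportions would
up-weight shallow sites. Truncation makes the heterozygous-site estimator
slightly conservative near θ ≈ 1 (or 0); at the default depths the
resulting bias on planted θ = 0.95 genes is below 0.01 (measured by the
recovery experiment), well inside the 0.02 acceptance band. Discarding
out-of-range sites instead of capping would discard the most extreme —
hence most informative — imprinting signal, so capping was chosen.

## Filters

Parental variants are kept when biallelic SNPs with quality ≥ 20, depth
≥ 5, both genotypes called, and minor-allele count ≥ 2 (`FilterConfig`).
The minor-allele count is evaluated on the four parental allele copies,
which makes it a deterministic function of the genotype file. Note the
consequence: a site heterozygous in exactly one parent has minor-allele
count 1 and fails the default floor, so default filtering restricts the
analysis to reciprocal-homozygous sites. The floor is a *variant
confidence* heuristic for noisy genotype calls; when genotypes are exact
by construction — as for the simulator's output — the pipeline is run
with `min_minor_allele_count=1` (`SIMULATION_FILTERS`) so that all three
informative categories contribute, which is also what the validation of
the heterozygous-site transformation requires.

SNP-to-gene assignment uses 1-based inclusive intervals; a site inside
two overlapping genes is dropped (and counted as ambiguous) rather than
double-counted in two genes' θ. Replicate libraries of a direction are
pooled by summation before estimation — the count-table analogue of
merging replicate alignments — and genes need ≥ `min_reads` (default 10)
pooled read equivalents per direction, in **both** directions, to be
assayable. `min_reads` guards against θ estimates from a handful of
reads; 10 per direction is a conventional ASE floor.

## Testing and calling

Per assayable gene, maternal/paternal totals pooled across both
directions are tested against the null split with a 1-df chi-squared
goodness of fit; p-values are Benjamini–Hochberg adjusted across genes
(one q per gene). Pooling across directions keeps a single test per gene
and maximizes power; a per-direction testing mode would double the tests
without changing the threshold logic, which is applied per direction
regardless. Thresholds (strict inequalities, both directions): moderate
MEG θ > 0.75, strong MEG θ > 0.9, moderate PEG θ < 0.25, strong PEG
θ < 0.1; strong subsumes moderate, and summaries count strong within the
MEG/PEG totals. With `require_significance` (default) a threshold-passing
gene additionally needs q ≤ 0.05, otherwise it is reported biparental;
`require_significance=False` reproduces a thresholds-only calling mode,
since published imprintomes differ on whether significance is a filter or
a post-hoc observation. Genes estimable in one direction only are
`UNDETERMINED` and excluded from testing.

## Overlap statistics

Gene-set enrichment uses the exact hypergeometric machinery on the 2×2
table: the reported odds ratio is the **sample cross-product ratio**
a·d/(b·c) (the conditional MLE is available behind a flag; the
cross-product is what the headline 4.23 ≈ 4.2 reproduces), and the
p-value is two-sided by point-mass summation, with a one-sided upper-tail
option. p-values at the 1e-35 scale are computed through log-space
factorials inside `scipy`. Cross-species comparisons count in the focal
species' namespace: a focal gene is shared with species S when ≥ 1 of its
orthologs in S is imprinted there, once per species pair regardless of
ortholog multiplicity; species pairs without an ortholog map are reported
not-assessable rather than zero.

## The synthetic-data generator

`simdata` emulates the study design so the whole pipeline is testable
without sequencing data: two diploid parents genotyped at SNPs inside
annotated genes; category mix 40% reciprocal-homozygous, 20% heterozygous
in each parent, 20% uninformative (a realistic split for two outbred
individuals); sites per gene ~ negative binomial(mean 5, size 10);
reciprocal directions `1x2`/`2x1` with 3 replicate libraries each; depth
per site per library ~ negative binomial(mean 50, size 10); allelic
counts ~ beta-binomial with intraclass correlation ρ = 0.01 (ρ = 0 is
binomial); 5% planted MEGs at θ = 0.95 and 5% PEGs at θ = 0.05 among
1000 genes, the rest at the null. Optional maternal sporophytic
contamination draws a fraction ρ_c of reads from the maternal parent's
own genotype (the tissue adjacent to dissected endosperm — seed
coat/perisperm — is maternal sporophyte), shifting the expected alt-read
frequency to (1−ρ_c)·(θ·m_a + (1−θ)·f_a)/2 + ρ_c·m_a/2 for parental alt
dosages m_a, f_a. At ρ_c = 0.3 the null-gene mean θ rises above 0.55–0.6
— the diagnostic signature of contamination.

What the generator does **not** emulate: read mapping and mapping bias,
genotyping error in the parents, linkage between sites of a gene beyond
shared θ, isoform structure, and library-specific composition effects.
Passing recovery tests therefore demonstrate correctness of the
statistical machinery under the stated noise model, not robustness to
alignment artefacts in real data.

## Validation experiments and problem sizes

The test suite and `scripts/acceptance.py` run, per seed, 1000 genes × ~5
sites × 6 libraries, 10 seeds for recovery (≈ 7 s total), 500 all-null
genes for calibration, and exhaustive hypergeometric enumeration up to a
200-gene universe for the exact-test oracle. Typical results (recomputed
at run time, not stored): MEG/PEG recovery ≈ 0.96–0.98, zero false
imprinted calls among 900 nulls per run, |θ bias| ≤ 0.01 per planted
class, null per-direction means within 0.48–0.52. A packaged 20-gene
fixture at seed 42 is frozen as a golden imprintome table for
byte-identical end-to-end determinism.

## Numerical choices and edge cases

* All randomness flows from one `numpy` `Generator`; fixture files embed
  the seed and are byte-stable.
* θ is reported to 6 significant digits in tables; internal arithmetic is
  double precision. Parent-role relabeling maps θ → 1−θ to within one ulp.
* Degenerate 2×2 margins give p = 1 and an odds ratio of ∞ (a·d > 0,
  b·c = 0), 0 (a·d = 0, b·c > 0) or NaN (both zero).
* Sites with zero merged reads in a direction are skipped for that
  direction; genes with no usable site are absent from the ASE table and
  hence from the imprintome.
* Ties in BH are handled by the shared rank minimum (step-up with
  monotonisation), matching the brute-force oracle exactly.

## Known limitations

* The chi-squared test ignores allelic overdispersion; with large ρ it is
  anti-conservative. A beta-binomial likelihood-ratio test is the natural
  extension and is deliberately out of scope.
* The heterozygous-site doubling assumes exactly Mendelian (half/half)
  transmission in the pooled seed population; strong transmission
  distortion would bias θ at those sites.
* The both-directions assayability rule and `min_reads` floor are this
  package's declared inclusion criteria; published assayable-gene counts
  from real datasets depend on the original pipeline's unstated criteria
  and are not reproduced here.
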