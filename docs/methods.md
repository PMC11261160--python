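# Methods

## The LD estimator

For each pair of biallelic loci the package computes Burrows' composite
disequilibrium from unphased genotypes, over the n individuals called at
both loci:

    Delta = n/(n-1) * [ sum(x*y)/(2n) - 2 p_x p_y ]
    tau_x = p_x(1-p_x) + (P_hom_x - p_x^2)
    r^2   = Delta^2 / (tau_x tau_y)

with x, y the alternate-allele counts (0/1/2) and P_hom_x the frequency of
alternate homozygotes. The tau terms include the within-locus
homozygote-excess correction, so no Hardy–Weinberg assumption is made at
either locus; r² is invariant to which allele is labelled "alternate".
The n/(n−1) factor is the standard small-sample correction of the
composite estimator; it is part of the form against which the sampling
expectations below were calibrated. One consequence is that r̂² for a
locus paired with itself equals (n/(n−1))², marginally above 1 — the
estimator's attainable maximum, asserted exactly in the tests.

Pairs in which either locus is monomorphic within the pairwise-complete
subset are undefined; they are skipped and counted. The mean r̂² across
pairs is weighted by the pairwise-complete n (missing data make n unequal
across pairs). Subtracting the weighted mean sampling expectation

    E[r^2 | n] = 1/n + 3.19/n^2            (n >= 30)
                 0.0018 + 0.907/n + 4.44/n^2   (n < 30)

gives the drift component r²_drift, converted at the harmonic-mean sample
size S to the point estimate

    N = (1/3 + sqrt(1/9 - 2.76 r2_drift)) / (2 r2_drift)   (S >= 30)

(with 0.308/2.08 coefficients below S = 30). r²_drift ≤ 0 means the data
carry no detectable drift signal and the estimate is indeterminate,
represented as +inf and serialized as the string "inf".

Rare alleles bias LD estimates; screening is configurable: `no-singletons`
(default, drops loci whose minor allele occurs as exactly one copy),
`pcrit` (minor-allele-frequency threshold), or `none`. The mating model is
random mating throughout — appropriate for a broadcast spawner; no
monogamy variant is provided.

### Jackknife confidence intervals

With thousands of loci the O(L²) pairs are massively pseudoreplicated, so
a locus-pair-based CI would be far too narrow. The package instead deletes
one *individual* at a time, recomputing the weighted mean r̂² from rank-1
downdates of the pairwise sufficient statistics (cost O(L²) per deletion
rather than a fresh O(nL²) pass). The jackknife variance of the mean r̂²
defines effective degrees of freedom df = 2 r̄²² / Var_J; the mean is
treated as df·r̄²/chi²_df, bounds on r̄² are shifted by the same E[r̂²|S]
as the point, and mapped through the (monotone decreasing) drift-to-N
transform. The upper Ne bound is therefore +inf whenever the lower drift
bound reaches zero. If all leave-one-out values coincide the CI collapses
to the point and is flagged (`ci_degenerate`). The exact chi-square
mapping has some freedom; simulated coverage (≥ 80% observed at nominal
95% in the acceptance suite, 100 replicates) is the arbiter.

## The correction calculus

Estimates and both CI bounds are transformed by identical multiplicative
factors, recorded per stage; +inf maps to +inf.

* **Linkage** (both paths): divide by `0.098 + 0.219 ln(chr)`. Below 61
  chromosomes the divisor is < 1 and the correction raises the estimate
  (26% at chr = 24); above ~61 it is slightly > 1 and a warning is issued,
  since the bias is then minimal.
* **Cohort path**: divide by `1.103 − 0.245 log10(ratio)` (age-structure
  correction of Nb), then by `0.485 + 0.758 log10(ratio)` (Nb → Ne per
  generation). No intermediate rounding anywhere in the chain.
* **Mixed-age path**: mixed-age samples of iteroparous species are biased
  downward roughly 20%.  Two conventions are implemented:
  `as_text` divides by 0.8; `as_tables` (default) divides by 0.8 and
  multiplies by 1.103, i.e. a combined factor of ~1.379.

**The ratio convention.** The regression formulas are defined in terms of
AL/α (adult lifespan over age at maturity), but the published snapper
worked values (Nb chains 2670→3363→3754→3333 and 1875→2361→2684→2282 with
α = 5.7/4.9, AL = 40 − α) are reproduced only by using longevity/α = 40/α.
Both conventions are exposed (`ratio_convention`); the default is
`longevity_over_alpha` because it matches the published numeric chains,
and the discrepancy (≈ 2% at these parameters) is deliberately surfaced
rather than resolved. The same situation holds for the mixed-age step:
the published adult chains equal adj1 × 1.103/0.8, not adj1/0.8, and the
stated 74% total adjustment (1/(0.098+0.219 ln 24) × 1.103/0.8 − 1 =
0.736) confirms the composite factor, so `as_tables` is the default and
`as_text` retains the plain-prose reading. Published tables round
intermediate values inconsistently at the ±1 level; tests against them
therefore carry ±1 tolerance.

`LifeHistory` flags (warning only) configurations where AL ≠ longevity −
α. The six regression coefficients are constants of the method and are
not re-derived here.

## Supporting summaries

Per sample: Ho is the heterozygote fraction among called genotypes per
locus, He the unbiased expected heterozygosity 2p̂q̂·n/(n−1), and FIS is
1 − Ho/He per variant locus, averaged (the population-inbreeding reading;
the variance-components FIS is out of scope). Monomorphic loci are
excluded from means, and a fully monomorphic sample yields NaN with no
error.

Pairwise FST uses the Weir–Cockerham (1984) variance components with
per-locus called sample sizes, combined across loci as a ratio of sums.
Significance comes from permuting individuals' population labels (diploid
genotypes intact), p = (1 + #{perm ≥ obs}) / (1 + permutations), with
Benjamini–Hochberg adjustment across pairs. PCA replaces missing calls
with the per-locus modal genotype (ties to the smaller allele count,
deterministically) and takes scores from a full SVD; scores are
deterministic up to component sign.

## The synthetic-data generator

The simulator emulates the statistical structure the estimator assumes,
not any particular sequencing pipeline.

* **discrete_wf**: N diploid adults, non-overlapping generations, both
  parents of each offspring drawn uniformly (selfing allowed), Mendelian
  transmission. True Ne = N; the realised parental offspring-count
  distribution also gives a pedigree Nb via
  `Nb = (k̄·Np − 2)/(k̄ − 1 + Vk/k̄)`. Default burn-in is N generations
  from initial allele frequencies uniform on [0.05, 0.95]; loci fixed
  during burn-in are dropped and counted.
* **age_structured**: a yearly cycle with age at maturity α = 5, longevity
  40 and annual adult survival 0.85 by default (snapper-like, at desk
  scale). Adults spawn a newborn cohort of configurable size; a fixed
  number recruit to age 1; survival applies from maturity. Overdispersed
  reproductive success (gamma fecundity multipliers with a
  variance-inflation factor) lowers the pedigree Nb, mirroring the high
  fecundity variance plausible for broadcast spawners; the factor is a
  free parameter, not a calibrated one. Per-cycle truth records and a
  parental snapshot for pedigree audits are kept.

Loci are assigned round-robin to 24 chromosomes. Transmission is free
recombination by default; setting `recomb_fraction < 0.5` creates
within-chromosome linkage (Markov switch process along each chromosome),
used only to verify the direction of the linkage bias. Missing genotypes
are applied uniformly at random (the emulated datasets show ~0.2–0.6%
missingness; there is no informative-missingness model).

What passing tests show — and what they do not: the generator produces
unstructured, neutrally evolving, randomly mating populations with clean
biallelic genotypes. Recovery and coverage results therefore validate the
estimator's math, not its robustness to ascertainment bias, genotyping
error, selection, migration or spatial structure in real ddRAD data.

## Problem sizes and numerical choices

Simulation-backed tests run at desk scale chosen as the smallest designs
that leave the tested signal clearly above simulation noise: parameter
recovery at true Ne = 100 with 50 individuals × 300 loci (50 replicates,
median within 25%); CI coverage at true Ne = 200 with 100 × 500 (100
replicates, ≥ 80%); bias-direction checks over 30 replicates. Pair
validity requires n ≥ 2 and tau > 1e-12; the sqrt discriminant in the
drift-to-N transform is clamped at zero; the r² oracle tolerance is
1e-12. Estimates are invariant to locus order, individual order and
allele relabelling (tested). All randomness flows from named integer
seeds; runs are bit-reproducible.

## Known limitations

* Single-sample LD method only: no temporal, sibship or
  molecular-coancestry estimators, and no monogamy mating model.
* Parity with existing LD-method software is not asserted numerically;
  the implementation contract is the published formulas plus the
  simulation-based validation above.
* The Genepop dialect supported is the common 2/3-digit genotype form;
  exotic variants (haploid rows, mixed ploidy) are rejected rather than
  guessed.
* FST permutation tests shuffle individuals; family structure within
  samples would invalidate the exchangeability assumption.
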