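# Methods

## Setting

A small, closed breeding population is genotyped at a fixed panel of
autosomal STR loci at successive monitoring rounds (cohorts). Each
animal contributes one unordered diploid allele pair per locus; alleles
are labelled with letters scoped by locus, following international
equine STR nomenclature (the compound name `AHT4O` is stored as allele
`O` at locus `AHT4`, and compounds are only rendered in reports —
this avoids parsing ambiguity for multi-letter locus names). Cohort
labels are opaque strings: nothing parses them as years, so the tool
applies to any longitudinal design.

## Indicators

For a cohort with `n` typed animals at a locus (missing genotypes are
excluded from numerator and denominator — per-locus complete-case
analysis, the standard convention when a panel is assembled from
heterogeneous certificates):

* Allele frequencies: copy counting over `2n` chromosomes; a homozygote
  contributes two copies of its allele.
* `Na`: number of distinct alleles observed.
* `Ae = 1 / Σ p²`: effective number of alleles — the size of an
  idealized uniform-frequency locus with the same expected homozygosity.
  `1 ≤ Ae ≤ Na` with equality iff all frequencies are equal.
* `Ho`: fraction of typed animals with two different alleles.
* `He = 1 − Σ p²`: plug-in gene diversity. The default is deliberately
  uncorrected: the breed-level arithmetic it feeds (see below) then
  reproduces the ratios reported in monitoring tables computed the same
  way. Nei's unbiased variant `2n/(2n−1) · (1 − Σ p²)` is available via
  `expected_heterozygosity(..., unbiased=True)` for parity with GenAlEx
  output. The plug-in estimator is biased low by a factor `(2n−1)/2n`,
  which matters when testing `E[Ho − He] = 0` (see *Validation*).
* `Fis = (He − Ho)/He`, defined as 0 at a fixed locus (`He = 0`);
  algebraically identical to `1 − Ho/He`.

Breed-wide summaries are unweighted means over loci. The breed-level
`Fis` is computed from mean `Ho` and mean `He`, not as the mean of
per-locus `Fis`: the ratio-of-means form is stable when some loci have
very low `He` (a near-fixed locus can produce an arbitrarily large
per-locus `Fis` from a tiny denominator) and matches how breed-level
values in monitoring reports are derived from the printed mean
heterozygosities. Loci with no typed animal in a cohort are excluded
from the means with a logged warning rather than imputed.

Report rounding is half-up (ties away from zero): `Ae`, `Ho`, `He` to
2 decimals; frequencies and `Fis` to 3. Internal computation is at full
precision; rounding is applied only at the serialization boundary.

## Allele classification

* **Rare**: `0 < p < 0.05`, strict — an allele at exactly the threshold
  is not rare. 0.05 is the threshold conventionally used in breed
  monitoring tables.
* **Common**: `p ≥ 0.25` (configurable). There is no canonical
  published cut-off for "common"; 0.25 puts the modal allele of a
  typical equine STR locus in the common set while keeping the set
  small. Alleles between the thresholds are *intermediate*; for any
  common threshold ≥ rare threshold, the three sets partition the
  observed alleles.
* **Unique (private)**: observed in the focal cohort and absent from
  every supplied reference frequency table. No reference populations
  are bundled; with no references, no allele is called unique rather
  than every allele being called unique.

## Temporal comparison

For two cohorts the package reports per locus: alleles gained (present
only in the later cohort), lost (present only in the earlier one),
frequency ratios for shared alleles, and two tests.

**Allele test.** The k × 2 contingency table of allele *copy* counts
over the union of alleles is tested with the Pearson statistic on
k − 1 degrees of freedom. Alleles absent from one cohort stay in the
table as zero cells (their row margin is positive, so every expected
count is positive). Copy counts within a diploid are not independent
draws — a homozygote contributes two correlated copies — so the
chi-square reference distribution is an approximation; the package
therefore also offers an individual-level permutation test (cohort
labels shuffled over animals, Pearson statistic recomputed,
`p = (1 + #{perm ≥ obs}) / (1 + n_perm)`), which is the recommended
headline p-value. A per-allele Fisher-exact option collapses each
allele against the rest into a 2 × 2 table; the locus-level p for that
mode is the Bonferroni-corrected minimum across alleles. Raw p-values
are reported alongside Holm-adjusted values across the panel, at both
the locus and (for Fisher mode) allele granularity, since monitoring
reports conventionally quote raw thresholds only.

**Genotype test.** The distinct-genotype inventory (counts of each
observed unordered pair per cohort) is tested the same way — Pearson
over the union of genotype categories — and the pair of
distinct-genotype counts is reported beside it. The test is a genotype-
distribution comparison; no published convention fixes a test for "the
number of genotypes differs", so the distributional test plus the raw
counts is what the package commits to.

**Trajectories.** Over ≥ 2 ordered cohorts, each allele's frequency
series is reported with fold-changes relative to the first cohort. An
allele absent at baseline gets no fold (division-by-zero guard) and a
`gained` flag.

## Synthetic data generator

The generator emulates the statistical regime of a small monitored
breed; its defaults are the study conditions the rest of the package is
validated under.

| parameter | default | meaning |
|---|---|---|
| `n_loci` | 17 | panel size (standard equine STR panel names) |
| `min_alleles`..`max_alleles` | 4..16 | per-locus allele count, drawn uniformly |
| `concentration` | 0.6 | symmetric Dirichlet concentration for spectra; 0.6 yields skewed spectra with modal alleles up to ~0.75 and single-copy tails |
| `f` | 0.0 | inbreeding coefficient of the genotype law |
| `cohorts` | 2000:62, 2010:163, 2020:143 | labels and sizes of successive rounds |
| `drift_sd` | 0.15 | per-step s.d. of the logit-scale frequency perturbation |
| `seed` | — | all randomness; identical config+seed ⇒ byte-identical output |

Genotypes are drawn from the two-parameter inbreeding law
`P(AᵢAᵢ) = pᵢ² + f pᵢ(1 − pᵢ)`, `P(AᵢAⱼ) = 2 pᵢ pⱼ (1 − f)` by direct
categorical sampling over the genotype simplex (not the
draw-one-allele-twice shortcut, which cannot represent f < 0 or f = 1
heterozygote exclusion uniformly). Negative `f` requires
`f ≥ −p_min/(1 − p_min)`; infeasible spectra are rejected and redrawn
up to a cap, then an error is raised — the generative law itself is
never altered.

Drift between cohorts is a logit-normal perturbation of the truth
frequencies followed by renormalization, not explicit Wright–Fisher
generations: monitoring rounds are years apart with unknown pedigree
structure, and the analysis only needs realistic frequency change.
Truth frequencies stay positive; allele loss and gain in the observed
tables arise from finite-sample draws, which also means a "lost" allele
can re-enter later, as in real studbook data. The generator has no
mutation model: genuinely novel alleles (as opposed to resampled rare
ones) are outside its scope, so gained-allele counts in simulations are
conservative relative to real panels. It also draws animals i.i.d. —
no family structure, no shared sires — so its cohorts are cleaner than
real ones; passing recovery tests demonstrates estimator correctness
under the stated law, not robustness to pedigree correlation.

The truth record carries, per cohort × locus, the frequency vector,
`He = 1 − Σp²` and `E[Ho] = (1 − f)·He`, so recovery of `f` by the
breed-level fixation index can be measured exactly.

## Validation and problem sizes

The test suite validates each stage against independent oracles:

* every index against a naive enumeration over allele copies and pairs
  (agreement to 1e−12 on hundreds of small random tables);
* the Pearson statistic against `scipy.stats.chi2_contingency` on dense
  tables, and a hand-computed 2 × 2 value (20.0);
* the permutation p-value against exhaustive enumeration of all label
  assignments for ≤ 8 animals;
* genotype category frequencies against the exact law within 3σ
  multinomial error at 10,000 draws;
* recovery of `f ∈ {0, 0.1, 0.2}` from 17-locus, n = 500 cohorts over
  100 replicates (|bias| < 0.02; single-replicate error ≤ 0.05 in ≥ 95
  of 100 at f = 0.2);
* type-I error of the copy-count chi-square on identically distributed
  cohorts (n = 100 each, 3 loci per replicate, 1000 replicates ⇒ 3000
  locus-level tests, tightening the Monte-Carlo error at fixed cost):
  rejection rate within 0.05 ± 0.02 at α = 0.05, with a separate seeded
  calibration check for the permutation test at a smaller replicate
  count;
* Hardy–Weinberg consistency at f = 0: per-locus mean of `Ho − He`
  within ±3 SE of 0 over 200 replicates. This check uses the unbiased
  `He` estimator: with the plug-in form the difference has expectation
  `He/2n` by construction (estimator bias, not a sampling failure),
  which at n = 100 is comparable to 3 SE of a 200-replicate mean and
  would make the check test the wrong null.

These sizes were chosen so the full suite runs in about a minute on a
single core while keeping Monte-Carlo error well inside each asserted
band.

## Known limitations

* No F-statistics hierarchy beyond Fis (no Fst/Fit), no exact
  Hardy–Weinberg tests, no linkage disequilibrium — deliberately out of
  scope for a single-population monitoring tool.
* The chi-square allele test treats allele copies as independent; use
  the permutation test when homozygosity is high.
* Unique-allele calls are only as complete as the supplied reference
  tables.
* GenePop output depends on its JSON sidecar for lossless round-trips;
  a bare GenePop file read without a sidecar yields numeric allele
  labels and positional population names.
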