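"""Per-locus and breed-wide diversity indicators.

For each (cohort, locus) the package computes the standard monitoring
indicator set:

* allele counts and frequencies ``p_i`` (copy counting: a homozygote
  contributes two copies; missing genotypes are excluded from numerator
  and denominator),
* ``Na`` — the observed number of alleles,
* ``Ae = 1 / sum(p_i^2)`` — the effective number of alleles
  ("polymorphism level"): the allele count of a uniform-frequency locus
  with the same expected homozygosity,
* ``Ho`` — observed heterozygosity, the fraction of typed animals
  carrying two different alleles,
* ``He = 1 - sum(p_i^2)`` — expected heterozygosity (gene diversity)
  under Hardy-Weinberg proportions, uncorrected by default; the unbiased
  ``2n/(2n-1)`` variant is available behind a flag for parity with
  GenAlEx-style output,
* ``Fis = (He - Ho) / He`` — the fixation index; positive values signal
  a heterozygote deficit (inbreeding), negative values an excess,
* the number of distinct diploid genotypes observed.

Breed-wide summaries average the per-locus values without weighting,
and compute the breed-level ``Fis`` from mean ``Ho`` and mean ``He``
(not as the mean of per-locus ``Fis``), which is the convention stable
at low-``He`` loci.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, asdict
from decimal import Decimal, ROUND_HALF_UP
from typing import Iterable, Mapping, Optional, Sequence

from .model import GenotypeTable

__all__ = [
    "AlleleFrequencyTable",
    "LocusDiversity",
    "CohortSummary",
    "DegenerateLocusError",
    "allele_frequencies",
    "effective_alleles",
    "observed_heterozygosity",
    "expected_heterozygosity",
    "fixation_index",
    "count_genotypes",
    "locus_diversity",
    "cohort_summary",
    "mean_alleles_per_locus",
    "round_half_up",
    "summary_to_tsv",
    "summary_to_json",
]

logger = logging.getLogger(__name__)

_NORM_TOL = 1e-12


class DegenerateLocusError(ValueError):
    """A locus with zero typed individuals in the requested cohort."""


def round_half_up(value: float, ndigits: int) -> float:
    """Decimal round-half-up, the convention used in printed report tables.

    Python's builtin ``round`` is banker's rounding; report tables in
    this field round 0.5 up, so 7.525 -> 7.53 at two digits.
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class AlleleFrequencyTable:
    """Allele copy counts and frequencies for one locus in one cohort."""

    cohort: str
    locus: str
    n_typed: int
    counts: dict[str, int]
    freqs: dict[str, float]

    def __post_init__(self) -> None:
        total = sum(self.counts.values())
        if total != 2 * self.n_typed:
            raise ValueError(
                f"{self.locus}/{self.cohort}: allele copies ({total}) != "
                f"2 x n_typed ({2 * self.n_typed})"
            )
        if self.freqs and abs(sum(self.freqs.values()) - 1.0) > _NORM_TOL:
            raise ValueError(f"{self.locus}/{self.cohort}: frequencies do not sum to 1")

    @property
    def alleles(self) -> tuple[str, ...]:
        return tuple(self.counts)

    @property
    def na(self) -> int:
        return len(self.counts)


@dataclass(frozen=True)
class LocusDiversity:
    """The indicator bundle for one locus in one cohort."""

    cohort: str
    locus: str
    n_typed: int
    na: int
    ae: float
    ho: float
    he: float
    fis: float
    n_genotypes: int


@dataclass(frozen=True)
class CohortSummary:
    """Per-locus indicators plus breed-wide means for one cohort.

    ``breed_fis`` is ``(mean_He - mean_Ho) / mean_He``; its sign always
    matches the sign of ``mean_He - mean_Ho``.  ``excluded_loci`` lists
    panel loci with no typed individual in the cohort; they are dropped
    from the means rather than imputed.
    """

    cohort: str
    per_locus: tuple[LocusDiversity, ...]
    excluded_loci: tuple[str, ...]
    total_alleles: int
    mean_na: float
    mean_ae: float
    mean_ho: float
    mean_he: float
    breed_fis: float
    n_samples: int


# ---------------------------------------------------------------------------
# Elementary operations


def allele_frequencies(
    table: GenotypeTable, cohort: str, locus: str
) -> AlleleFrequencyTable:
    """Copy-count allele frequencies at *locus* within *cohort*.

    Each typed animal contributes two allele copies (a homozygote
    contributes two of the same allele); animals with a missing genotype
    at the locus are excluded entirely.
    """
    genos = table.genotypes_at(locus, cohort)
    if not genos:
        raise DegenerateLocusError(
            f"locus {locus!r} has no typed individuals in cohort {cohort!r}"
        )
    counts: dict[str, int] = {}
    for g in genos:
        for a in g.alleles():
            counts[a] = counts.get(a, 0) + 1
    counts = dict(sorted(counts.items()))
    n_typed = len(genos)
    denom = 2 * n_typed
    freqs = {a: c / denom for a, c in counts.items()}
    return AlleleFrequencyTable(
        cohort=cohort, locus=locus, n_typed=n_typed, counts=counts, freqs=freqs
    )


def effective_alleles(freqs: AlleleFrequencyTable) -> float:
    """Effective number of alleles ``Ae = 1 / sum(p^2)``; ``1 <= Ae <= Na``."""
    return 1.0 / sum(p * p for p in freqs.freqs.values())


def observed_heterozygosity(table: GenotypeTable, cohort: str, locus: str) -> float:
    """Fraction of typed animals with two different alleles at *locus*."""
    genos = table.genotypes_at(locus, cohort)
    if not genos:
        raise DegenerateLocusError(
            f"locus {locus!r} has no typed individuals in cohort {cohort!r}"
        )
    return sum(1 for g in genos if g.is_heterozygous) / len(genos)


def expected_heterozygosity(
    freqs: AlleleFrequencyTable, unbiased: bool = False
) -> float:
    """Gene diversity ``He = 1 - sum(p^2)``.

    With ``unbiased=True`` the small-sample correction ``2n/(2n-1)`` is
    applied (Nei's unbiased estimator), for parity with tools that
    report the corrected form.
    """
    he = 1.0 - sum(p * p for p in freqs.freqs.values())
    if unbiased:
        two_n = 2 * freqs.n_typed
        if two_n > 1:
            he *= two_n / (two_n - 1)
    return he


def fixation_index(ho: float, he: float) -> float:
    """``Fis = (He - Ho)/He`` for ``He > 0``; defined as 0 at a fixed locus.

    Algebraically identical to ``1 - Ho/He``.  Negative values mean more
    heterozygotes than Hardy-Weinberg proportions predict.
    """
    if not (0.0 <= ho <= 1.0):
        raise ValueError(f"Ho must be in [0, 1], got {ho}")
    if not (0.0 <= he < 1.0):
        raise ValueError(f"He must be in [0, 1), got {he}")
    if he == 0.0:
        return 0.0
    return (he - ho) / he


def count_genotypes(table: GenotypeTable, cohort: str, locus: str) -> int:
    """Number of distinct unordered allele pairs observed at *locus*."""
    genos = table.genotypes_at(locus, cohort)
    return len({(g.allele_a, g.allele_b) for g in genos})


def locus_diversity(table: GenotypeTable, cohort: str, locus: str) -> LocusDiversity:
    """All indicators for one (cohort, locus), from the elementary operations."""
    freqs = allele_frequencies(table, cohort, locus)
    ho = observed_heterozygosity(table, cohort, locus)
    he = expected_heterozygosity(freqs)
    return LocusDiversity(
        cohort=cohort,
        locus=locus,
        n_typed=freqs.n_typed,
        na=freqs.na,
        ae=effective_alleles(freqs),
        ho=ho,
        he=he,
        fis=fixation_index(ho, he),
        n_genotypes=count_genotypes(table, cohort, locus),
    )


def mean_alleles_per_locus(total_alleles: int, n_loci: int) -> float:
    """Breed-wide mean ``Na``: total distinct alleles over the panel size.

    This is the rule behind a summary's ``mean_na``; exposed separately
    so published allele totals can be turned into the per-locus mean.
    """
    if n_loci <= 0:
        raise ValueError("panel must contain at least one locus")
    return total_alleles / n_loci


# ---------------------------------------------------------------------------
# Cohort summary


def cohort_summary(table: GenotypeTable, cohort: str) -> CohortSummary:
    """Per-locus indicator records plus unweighted breed-wide means.

    Panel loci with no typed individual in the cohort are excluded from
    the means with a logged warning.  The breed-level fixation index is
    computed from the mean Ho and mean He, not by averaging per-locus
    Fis values.
    """
    if cohort not in table.cohorts():
        raise KeyError(
            f"cohort {cohort!r} not present; available: {', '.join(table.cohorts())}"
        )
    per_locus: list[LocusDiversity] = []
    excluded: list[str] = []
    for locus in table.locus_names:
        try:
            per_locus.append(locus_diversity(table, cohort, locus))
        except DegenerateLocusError:
            logger.warning(
                "cohort %s: locus %s has no typed individuals; excluded from means",
                cohort, locus,
            )
            excluded.append(locus)
    if not per_locus:
        raise DegenerateLocusError(f"cohort {cohort!r}: no locus has typed data")
    k = len(per_locus)
    total_alleles = sum(d.na for d in per_locus)
    mean_ho = sum(d.ho for d in per_locus) / k
    mean_he = sum(d.he for d in per_locus) / k
    n_samples = len([r for r in table.samples if r.cohort == cohort])
    return CohortSummary(
        cohort=cohort,
        per_locus=tuple(per_locus),
        excluded_loci=tuple(excluded),
        total_alleles=total_alleles,
        mean_na=mean_alleles_per_locus(total_alleles, k),
        mean_ae=sum(d.ae for d in per_locus) / k,
        mean_ho=mean_ho,
        mean_he=mean_he,
        breed_fis=fixation_index(mean_ho, mean_he) if mean_he < 1.0 else 0.0,
        n_samples=n_samples,
    )


# ---------------------------------------------------------------------------
# Report rendering

#: Report rounding profile: Ae/Ho/He to 2 decimals, Fis to 3, half-up.
_ROUND_2 = ("ae", "ho", "he")
_ROUND_3 = ("fis",)

_SUMMARY_COLUMNS = (
    "cohort", "locus", "n_typed", "na", "ae", "ho", "he", "fis", "n_genotypes",
)


def _format_locus_row(d: LocusDiversity) -> list[str]:
    row = []
    for col in _SUMMARY_COLUMNS:
        v = getattr(d, col)
        if col in _ROUND_2:
            v = f"{round_half_up(v, 2):.2f}"
        elif col in _ROUND_3:
            v = f"{round_half_up(v, 3):.3f}"
        row.append(str(v))
    return row


def summary_to_tsv(summaries: Sequence[CohortSummary]) -> str:
    """Render summaries as TSV: one row per (cohort, locus), then a MEAN row."""
    lines = ["\t".join(_SUMMARY_COLUMNS)]
    for s in summaries:
        for d in s.per_locus:
            lines.append("\t".join(_format_locus_row(d)))
        mean_row = [
            s.cohort,
            "MEAN",
            str(s.n_samples),
            f"{round_half_up(s.mean_na, 2):.2f}",
            f"{round_half_up(s.mean_ae, 2):.2f}",
            f"{round_half_up(s.mean_ho, 2):.2f}",
            f"{round_half_up(s.mean_he, 2):.2f}",
            f"{round_half_up(s.breed_fis, 3):.3f}",
            str(sum(d.n_genotypes for d in s.per_locus)),
        ]
        lines.append("\t".join(mean_row))
    return "\n".join(lines) + "\n"


def summary_to_json(summaries: Sequence[CohortSummary]) -> str:
    """Machine-readable JSON form of the summaries, full precision."""
    return json.dumps([asdict(s) for s in summaries], indent=2) + "\n"
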