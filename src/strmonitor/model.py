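"""Core genotype data model.

A diploid animal carries an unordered pair of allele labels at each STR
locus.  Allele labels follow the international equine nomenclature: a
single letter scoped by the locus (allele ``O`` at locus ``HTG6`` is the
marker usually written ``HTG6O``).  Arbitrary non-letter tokens are
accepted so the model generalises to other labelling schemes.

Missing data are all-or-nothing per genotype: either both alleles are
observed or the whole genotype is missing.  A missing genotype removes
the animal from that locus's counts entirely (complete-case analysis
per locus).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Optional, Sequence

__all__ = [
    "EQUINE_STR_PANEL",
    "MISSING",
    "LocusSpec",
    "Genotype",
    "SampleRecord",
    "GenotypeTable",
    "ValidationError",
]

#: The 17-locus nuclear STR panel used in routine horse parentage testing.
EQUINE_STR_PANEL: tuple[str, ...] = (
    "VHL20", "HTG4", "AHT4", "HMS7", "HTG6", "AHT5", "HMS6", "ASB23",
    "ASB2", "HTG10", "HTG7", "HMS3", "HMS2", "ASB17", "LEX3", "HMS1",
    "CA425",
)

#: Sentinel for an untyped genotype (both alleles unobserved).
MISSING: None = None


class ValidationError(ValueError):
    """Raised when a table or record violates a model invariant."""


def _check_allele_label(label: str) -> str:
    if not isinstance(label, str) or not label:
        raise ValidationError(f"allele label must be a non-empty string, got {label!r}")
    if "/" in label or any(c.isspace() for c in label):
        raise ValidationError(f"allele label {label!r} contains '/' or whitespace")
    return label


@dataclass(frozen=True)
class LocusSpec:
    """A marker locus and the allele labels observed (or permitted) at it."""

    name: str
    allele_alphabet: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.name or not isinstance(self.name, str):
            raise ValidationError(f"locus name must be non-empty, got {self.name!r}")
        for a in self.allele_alphabet:
            _check_allele_label(a)
        object.__setattr__(self, "allele_alphabet", tuple(self.allele_alphabet))

    def with_alleles(self, labels: Iterable[str]) -> "LocusSpec":
        """Return a copy whose alphabet additionally contains *labels* (sorted)."""
        merged = sorted(set(self.allele_alphabet) | set(labels))
        return replace(self, allele_alphabet=tuple(merged))


@dataclass(frozen=True)
class Genotype:
    """An unordered diploid allele pair, stored canonically (a <= b).

    Both alleles are present, or both are :data:`MISSING` — half-typed
    genotypes are rejected.
    """

    allele_a: Optional[str]
    allele_b: Optional[str]

    def __post_init__(self) -> None:
        a, b = self.allele_a, self.allele_b
        if (a is MISSING) != (b is MISSING):
            raise ValidationError(
                f"half-typed genotype ({a!r}/{b!r}): both alleles must be "
                "observed or both missing"
            )
        if a is not MISSING:
            _check_allele_label(a)
            _check_allele_label(b)
            if a > b:  # canonical unordered pair
                object.__setattr__(self, "allele_a", b)
                object.__setattr__(self, "allele_b", a)

    @property
    def is_missing(self) -> bool:
        return self.allele_a is MISSING

    @property
    def is_heterozygous(self) -> bool:
        if self.is_missing:
            raise ValidationError("heterozygosity undefined for a missing genotype")
        return self.allele_a != self.allele_b

    def alleles(self) -> tuple[str, str]:
        if self.is_missing:
            raise ValidationError("missing genotype has no alleles")
        return (self.allele_a, self.allele_b)


#: Convenience constructor for the missing genotype.
MISSING_GENOTYPE = Genotype(MISSING, MISSING)


@dataclass(frozen=True)
class SampleRecord:
    """One animal: its identifier, cohort label, and one genotype per panel locus."""

    sample_id: str
    cohort: str
    genotypes: tuple[Genotype, ...]

    def __post_init__(self) -> None:
        if not self.sample_id:
            raise ValidationError("sample_id must be non-empty")
        if not self.cohort:
            raise ValidationError("cohort label must be non-empty")
        object.__setattr__(self, "genotypes", tuple(self.genotypes))


@dataclass(frozen=True)
class GenotypeTable:
    """Animals x loci matrix of diploid genotypes with cohort labels.

    Cohort labels are opaque strings (typically sampling years such as
    ``"2000"``), never parsed.  On construction every non-missing allele
    label is folded into its locus's observed alphabet, sample ids are
    checked for uniqueness, and row widths are checked against the panel.
    """

    panel: tuple[LocusSpec, ...]
    samples: tuple[SampleRecord, ...] = ()

    def __post_init__(self) -> None:
        panel = tuple(self.panel)
        names = [l.name for l in panel]
        if len(set(names)) != len(names):
            raise ValidationError(f"duplicate locus names in panel: {names}")
        seen_ids: set[str] = set()
        observed: list[set[str]] = [set() for _ in panel]
        for rec in self.samples:
            if rec.sample_id in seen_ids:
                raise ValidationError(f"duplicate sample_id {rec.sample_id!r}")
            seen_ids.add(rec.sample_id)
            if len(rec.genotypes) != len(panel):
                raise ValidationError(
                    f"sample {rec.sample_id!r} has {len(rec.genotypes)} genotypes "
                    f"for a {len(panel)}-locus panel"
                )
            for i, g in enumerate(rec.genotypes):
                if not g.is_missing:
                    observed[i].update(g.alleles())
        object.__setattr__(
            self, "panel", tuple(l.with_alleles(obs) for l, obs in zip(panel, observed))
        )
        object.__setattr__(self, "samples", tuple(self.samples))

    # -- introspection -------------------------------------------------

    @property
    def locus_names(self) -> tuple[str, ...]:
        return tuple(l.name for l in self.panel)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def cohorts(self) -> tuple[str, ...]:
        """Cohort labels in first-appearance order."""
        seen: dict[str, None] = {}
        for rec in self.samples:
            seen.setdefault(rec.cohort, None)
        return tuple(seen)

    def locus_index(self, locus: str) -> int:
        try:
            return self.locus_names.index(locus)
        except ValueError:
            raise KeyError(
                f"unknown locus {locus!r}; panel loci: {', '.join(self.locus_names)}"
            ) from None

    def genotypes_at(self, locus: str, cohort: Optional[str] = None) -> list[Genotype]:
        """Non-missing genotypes at *locus*, optionally restricted to *cohort*."""
        i = self.locus_index(locus)
        return [
            rec.genotypes[i]
            for rec in self.samples
            if (cohort is None or rec.cohort == cohort)
            and not rec.genotypes[i].is_missing
        ]

    def canonical(self) -> "GenotypeTable":
        """Equivalent table whose locus alphabets are exactly the observed labels.

        Serialization carries only observed alleles, so round-trip
        equality is defined on this form: a permitted-but-unobserved
        allele in a panel alphabet is not recoverable from a file.
        """
        bare = tuple(LocusSpec(l.name) for l in self.panel)
        return GenotypeTable(panel=bare, samples=self.samples)

    def __iter__(self) -> Iterator[SampleRecord]:
        return iter(self.samples)


def subset_cohort(table: GenotypeTable, cohort: str) -> GenotypeTable:
    """Rows of *table* belonging to *cohort*; panel unchanged.

    Raises ``KeyError`` listing the available labels when the cohort is
    absent, so a typo in a monitoring script fails loudly.
    """
    available = table.cohorts()
    if cohort not in available:
        raise KeyError(
            f"cohort {cohort!r} not present; available cohorts: "
            f"{', '.join(available) if available else '(none)'}"
        )
    rows = tuple(rec for rec in table.samples if rec.cohort == cohort)
    return GenotypeTable(panel=table.panel, samples=rows)
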