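"""Reading and writing genotype tables.

Two dialects are supported:

``tsv``
    ``sample_id<TAB>cohort<TAB><locus1><TAB>...`` header, one row per
    animal, each locus cell ``X/Y`` with the alleles joined by ``/`` in
    canonical (sorted) order; a missing genotype is ``-/-``.  UTF-8, no
    quoting.  This dialect is the package's own and round-trips losslessly.

``genepop``
    GenePop 4.x text: a title line, one locus name per line, ``Pop``
    separators (one population per cohort), then
    ``sample_id ,  0101 0203 ...`` with two-digit allele codes and
    ``0000`` for missing.  GenePop carries neither cohort labels nor
    letter-coded alleles, so the writer emits a JSON sidecar
    (``<path>.map.json``) holding the ordered cohort labels and the
    per-locus letter-to-code maps; the reader uses the sidecar when
    present and otherwise falls back to ``pop_1, pop_2, ...`` labels and
    the raw numeric codes as allele labels.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Literal, Union

from .model import (
    Genotype,
    GenotypeTable,
    LocusSpec,
    MISSING_GENOTYPE,
    SampleRecord,
    ValidationError,
)

__all__ = ["read_table", "write_table", "ParseError", "sidecar_path"]

Dialect = Literal["tsv", "genepop"]

MISSING_CELL = "-/-"
GENEPOP_MISSING = "0000"


class ParseError(ValueError):
    """Malformed input file; carries the offending line number in the message."""


def sidecar_path(path: Union[str, Path]) -> Path:
    """Location of the GenePop allele-code/cohort mapping sidecar."""
    p = Path(path)
    return p.with_name(p.name + ".map.json")


# ---------------------------------------------------------------------------
# TSV dialect


def _parse_cell(cell: str, lineno: int) -> Genotype:
    if cell == MISSING_CELL:
        return MISSING_GENOTYPE
    parts = cell.split("/")
    if len(parts) != 2:
        raise ParseError(
            f"line {lineno}: genotype cell {cell!r} is not of the form 'X/Y'"
        )
    a, b = parts
    if (a == "-") != (b == "-"):
        raise ValidationError(
            f"line {lineno}: half-typed genotype {cell!r} (use '-/-' for missing)"
        )
    try:
        return Genotype(a, b)
    except ValidationError as exc:
        raise ValidationError(f"line {lineno}: {exc}") from None


def _format_cell(g: Genotype) -> str:
    if g.is_missing:
        return MISSING_CELL
    return f"{g.allele_a}/{g.allele_b}"


def _read_tsv(path: Path) -> GenotypeTable:
    lines = path.read_text(encoding="utf-8").splitlines()
    if not lines:
        raise ParseError("line 1: empty file, expected a header row")
    header = lines[0].split("\t")
    if len(header) < 2 or header[0] != "sample_id" or header[1] != "cohort":
        raise ParseError(
            "line 1: header must start with 'sample_id<TAB>cohort' "
            f"followed by locus names, got {lines[0]!r}"
        )
    panel = tuple(LocusSpec(name) for name in header[2:])
    samples = []
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) != len(header):
            raise ParseError(
                f"line {lineno}: expected {len(header)} columns, got {len(fields)}"
            )
        genotypes = tuple(_parse_cell(c, lineno) for c in fields[2:])
        samples.append(SampleRecord(fields[0], fields[1], genotypes))
    return GenotypeTable(panel=panel, samples=tuple(samples))


def _write_tsv(table: GenotypeTable, path: Path) -> None:
    out = ["\t".join(("sample_id", "cohort") + table.locus_names)]
    for rec in table.samples:
        out.append(
            "\t".join((rec.sample_id, rec.cohort)
                      + tuple(_format_cell(g) for g in rec.genotypes))
        )
    path.write_text("\n".join(out) + "\n", encoding="utf-8")


# ---------------------------------------------------------------------------
# GenePop dialect


def _allele_codes(table: GenotypeTable) -> dict[str, dict[str, str]]:
    codes: dict[str, dict[str, str]] = {}
    for spec in table.panel:
        alleles = sorted(spec.allele_alphabet)
        if len(alleles) > 99:
            raise ValidationError(
                f"locus {spec.name}: {len(alleles)} alleles exceed the "
                "two-digit GenePop code space"
            )
        codes[spec.name] = {a: f"{i:02d}" for i, a in enumerate(alleles, start=1)}
    return codes


def _write_genepop(table: GenotypeTable, path: Path) -> None:
    codes = _allele_codes(table)
    cohort_order = table.cohorts()
    lines = ["strmonitor genotype export"]
    lines.extend(table.locus_names)
    for cohort in cohort_order:
        lines.append("Pop")
        for rec in table.samples:
            if rec.cohort != cohort:
                continue
            cells = []
            for spec, g in zip(table.panel, rec.genotypes):
                if g.is_missing:
                    cells.append(GENEPOP_MISSING)
                else:
                    cmap = codes[spec.name]
                    cells.append(cmap[g.allele_a] + cmap[g.allele_b])
            lines.append(f"{rec.sample_id} ,  " + " ".join(cells))
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    sidecar = {"cohorts": list(cohort_order), "allele_codes": codes}
    sidecar_path(path).write_text(
        json.dumps(sidecar, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )


def _read_genepop(path: Path) -> GenotypeTable:
    lines = path.read_text(encoding="utf-8").splitlines()
    if len(lines) < 2:
        raise ParseError("line 1: GenePop file needs a title line and locus names")
    mapping = None
    sc = sidecar_path(path)
    if sc.exists():
        mapping = json.loads(sc.read_text(encoding="utf-8"))

    locus_names: list[str] = []
    i = 1
    while i < len(lines) and lines[i].strip().lower() != "pop":
        name_line = lines[i].strip()
        if name_line:
            # GenePop permits comma-separated locus names on one line
            locus_names.extend(n.strip() for n in name_line.split(",") if n.strip())
        i += 1
    if not locus_names:
        raise ParseError(f"line {i + 1}: no locus names before first 'Pop'")

    decode: dict[str, dict[str, str]] = {}
    cohort_labels: list[str] = []
    if mapping is not None:
        for locus, cmap in mapping["allele_codes"].items():
            decode[locus] = {code: allele for allele, code in cmap.items()}
        cohort_labels = list(mapping["cohorts"])

    panel = tuple(LocusSpec(n) for n in locus_names)
    samples: list[SampleRecord] = []
    pop_index = -1
    for lineno in range(i, len(lines)):
        line = lines[lineno].strip()
        if not line:
            continue
        if line.lower() == "pop":
            pop_index += 1
            continue
        if pop_index < 0:
            raise ParseError(f"line {lineno + 1}: sample row before first 'Pop'")
        if "," not in line:
            raise ParseError(
                f"line {lineno + 1}: expected 'sample_id , codes', got {line!r}"
            )
        sid, _, rest = line.partition(",")
        sid = sid.strip()
        cells = rest.split()
        if len(cells) != len(panel):
            raise ParseError(
                f"line {lineno + 1}: expected {len(panel)} genotype codes, "
                f"got {len(cells)}"
            )
        genotypes = []
        for locus, cell in zip(locus_names, cells):
            if len(cell) != 4 or not cell.isdigit():
                raise ParseError(
                    f"line {lineno + 1}: bad genotype code {cell!r} at {locus} "
                    "(expected four digits)"
                )
            ca, cb = cell[:2], cell[2:]
            if (ca == "00") != (cb == "00"):
                raise ValidationError(
                    f"line {lineno + 1}: half-typed genotype code {cell!r} at {locus}"
                )
            if ca == "00":
                genotypes.append(MISSING_GENOTYPE)
                continue
            if locus in decode:
                try:
                    a, b = decode[locus][ca], decode[locus][cb]
                except KeyError as exc:
                    raise ParseError(
                        f"line {lineno + 1}: code {exc.args[0]} at {locus} absent "
                        "from the sidecar mapping"
                    ) from None
            else:
                a, b = ca, cb
            genotypes.append(Genotype(a, b))
        if cohort_labels and pop_index < len(cohort_labels):
            cohort = cohort_labels[pop_index]
        else:
            cohort = f"pop_{pop_index + 1}"
        samples.append(SampleRecord(sid, cohort, tuple(genotypes)))
    return GenotypeTable(panel=panel, samples=tuple(samples))


# ---------------------------------------------------------------------------
# Public API


def read_table(path: Union[str, Path], dialect: Dialect = "tsv") -> GenotypeTable:
    """Parse a genotype file into a validated :class:`GenotypeTable`.

    Allele pairs are canonicalized (sorted within each genotype) on the
    way in, so ``L/K`` in a file and ``K/L`` in memory are the same
    observation.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect == "tsv":
        return _read_tsv(path)
    if dialect == "genepop":
        return _read_genepop(path)
    raise ValueError(f"unknown dialect {dialect!r}; expected 'tsv' or 'genepop'")


def write_table(
    table: GenotypeTable, path: Union[str, Path], dialect: Dialect = "tsv"
) -> None:
    """Serialize *table*; ``read_table(write_table(t)) == t`` in canonical form.

    Output is deterministic: repeated writes of the same table are
    byte-identical.
    """
    path = Path(path)
    if dialect == "tsv":
        _write_tsv(table, path)
    elif dialect == "genepop":
        _write_genepop(table, path)
    else:
        raise ValueError(f"unknown dialect {dialect!r}; expected 'tsv' or 'genepop'")
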