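"""Germline V/D/J allele databases.

A germline database is a FASTA file of full-length, end-corrected allelic
nucleotide sequences, one record per allele, named ``GENE*ALLELE`` (IMGT
nomenclature, e.g. ``IGHV1-2*02``). All downstream core derivation assumes the
database sequences extend to the true recombination signal boundary: a
reference set containing 3'-truncated V or 5'-truncated J alleles will yield
cores that systematically undercount, which is why validation warnings are
surfaced here rather than silently ignored.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "Segment",
    "AlleleSequence",
    "AlleleDatabase",
    "ValidationReport",
    "DatabaseError",
    "gene_of",
    "read_allele_fasta",
    "write_allele_fasta",
    "validate_database",
]

_VALID_SEQ = re.compile(r"^[ACGT]+$")

#: Terminal 4-mer shared by all functional human IGHJ alleles once their 3'
#: ends are corrected to the splice donor boundary. Used as a truncation
#: warning heuristic for J databases.
DEFAULT_J_END_MOTIF = "TCAG"


class Segment(str, Enum):
    """Gene segment kind of a germline database."""

    V = "V"
    D = "D"
    J = "J"


class DatabaseError(ValueError):
    """Raised for malformed or inconsistent germline databases."""


def gene_of(name: str) -> str:
    """Return the gene part of an allele name (everything before the ``*``).

    >>> gene_of("IGHV1-2*05")
    'IGHV1-2'
    """
    if "*" not in name:
        raise DatabaseError(f"allele name {name!r} has no '*' gene/allele separator")
    return name.split("*", 1)[0]


@dataclass(frozen=True)
class AlleleSequence:
    """One named germline allele.

    Attributes
    ----------
    name:
        Full allele name ``GENE*ALLELE``; must contain exactly one ``*``.
    seq:
        Uppercase nucleotide sequence over A/C/G/T. Ambiguity codes are
        rejected: cores are exact-match search strings and must be fully
        resolved.
    segment:
        Which segment kind (V, D or J) this allele belongs to.
    """

    name: str
    seq: str
    segment: Segment

    def __post_init__(self) -> None:
        if self.name.count("*") != 1:
            raise DatabaseError(
                f"allele name {self.name!r} must contain exactly one '*'"
            )
        if not gene_of(self.name):
            raise DatabaseError(f"allele name {self.name!r} has an empty gene part")
        if not self.seq:
            raise DatabaseError(f"allele {self.name}: empty sequence")
        if not _VALID_SEQ.match(self.seq):
            bad = sorted(set(self.seq) - set("ACGT"))
            raise DatabaseError(
                f"allele {self.name}: sequence contains non-ACGT characters {bad}"
            )

    @property
    def gene(self) -> str:
        return gene_of(self.name)

    @property
    def allele_id(self) -> str:
        return self.name.split("*", 1)[1]

    def __len__(self) -> int:
        return len(self.seq)


class AlleleDatabase:
    """Ordered, name-indexed collection of alleles of one segment kind."""

    def __init__(self, segment: Segment, alleles: Iterable[AlleleSequence]):
        self.segment = Segment(segment)
        self.alleles: list[AlleleSequence] = list(alleles)
        self.by_name: dict[str, AlleleSequence] = {}
        self.genes: dict[str, list[AlleleSequence]] = {}
        for a in self.alleles:
            if a.segment != self.segment:
                raise DatabaseError(
                    f"allele {a.name} has segment {a.segment.value}, "
                    f"database is {self.segment.value}"
                )
            if a.name in self.by_name:
                raise DatabaseError(f"duplicate allele name: {a.name}")
            self.by_name[a.name] = a
            self.genes.setdefault(a.gene, []).append(a)

    def __len__(self) -> int:
        return len(self.alleles)

    def __iter__(self) -> Iterator[AlleleSequence]:
        return iter(self.alleles)

    def __contains__(self, name: str) -> bool:
        return name in self.by_name

    def __getitem__(self, name: str) -> AlleleSequence:
        return self.by_name[name]

    def with_added(self, *extra: AlleleSequence) -> "AlleleDatabase":
        """Return a new database with ``extra`` alleles appended."""
        return AlleleDatabase(self.segment, self.alleles + list(extra))


def _header_name(description: str) -> str:
    """Extract the allele name from a FASTA header.

    The first whitespace-delimited token is the name; if that token is an
    IMGT-style ``|``-delimited multi-field header, the field containing ``*``
    (the allele-name field) is used instead.
    """
    token = description.split()[0]
    if "|" in token:
        for part in token.split("|"):
            if "*" in part:
                return part
        raise DatabaseError(
            f"'|'-delimited FASTA header {token!r} has no GENE*ALLELE field"
        )
    return token


def read_allele_fasta(path: str | Path, segment: Segment | str) -> AlleleDatabase:
    """Read a germline allele database from FASTA.

    Sequences are uppercased; input order is preserved. Duplicate allele
    names, an empty file, or non-ACGT characters are hard errors.
    """
    segment = Segment(segment)
    alleles: list[AlleleSequence] = []
    seen: dict[str, int] = {}
    duplicates: list[str] = []
    bad_records: list[str] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        name = _header_name(rec.description)
        if name in seen:
            duplicates.append(name)
            continue
        seen[name] = 1
        seq = str(rec.seq).upper()
        try:
            alleles.append(AlleleSequence(name=name, seq=seq, segment=segment))
        except DatabaseError as exc:
            bad_records.append(f"{name}: {exc}")
    if duplicates:
        raise DatabaseError(
            "duplicate allele names in database: " + ", ".join(sorted(set(duplicates)))
        )
    if bad_records:
        raise DatabaseError("invalid database records: " + "; ".join(bad_records))
    if not alleles:
        raise DatabaseError(f"no FASTA records found in {path}")
    return AlleleDatabase(segment, alleles)


def write_allele_fasta(db: AlleleDatabase, path: str | Path) -> None:
    """Write a database back to FASTA (round-trips names and sequences)."""
    records = [
        SeqRecord(Seq(a.seq), id=a.name, description="") for a in db.alleles
    ]
    SeqIO.write(records, str(path), "fasta-2line")


@dataclass
class ValidationReport:
    """Result of database validation checks.

    ``duplicate_sequences`` lists groups of differently named alleles with
    byte-identical sequences. These are flagged, not fatal: duplicated IGH
    genes (the ``-D`` suffix genes) legitimately share alleles, and core
    derivation later merges their identical cores. ``j_end_warnings`` lists J
    alleles whose terminal 4-mer differs from the expected motif, a heuristic
    for 3'-truncated J references.
    """

    duplicate_names: list[str] = field(default_factory=list)
    duplicate_sequences: list[list[str]] = field(default_factory=list)
    non_acgt: list[str] = field(default_factory=list)
    j_end_warnings: list[str] = field(default_factory=list)

    @property
    def is_clean(self) -> bool:
        return not (
            self.duplicate_names
            or self.duplicate_sequences
            or self.non_acgt
            or self.j_end_warnings
        )

    def to_frame(self):
        """Tabular (issue, detail) view of the report, for TSV export."""
        import pandas as pd

        rows = []
        for n in self.duplicate_names:
            rows.append(("duplicate_name", n))
        for grp in self.duplicate_sequences:
            rows.append(("duplicate_sequence", "/".join(grp)))
        for n in self.non_acgt:
            rows.append(("non_acgt", n))
        for n in self.j_end_warnings:
            rows.append(("j_end_warning", n))
        return pd.DataFrame(rows, columns=["issue", "detail"])


def validate_database(
    db: AlleleDatabase, j_end_motif: str = DEFAULT_J_END_MOTIF
) -> ValidationReport:
    """Run non-fatal consistency checks on a germline database."""
    report = ValidationReport()
    # name uniqueness and ACGT content are enforced at construction, so these
    # report fields stay empty for databases built through the public API.
    by_seq: dict[str, list[str]] = {}
    for a in db:
        by_seq.setdefault(a.seq, []).append(a.name)
    for seq, names in by_seq.items():
        if len(names) > 1:
            report.duplicate_sequences.append(sorted(names))
    report.duplicate_sequences.sort()
    if db.segment == Segment.J and j_end_motif:
        for a in db:
            if not a.seq.endswith(j_end_motif):
                report.j_end_warnings.append(a.name)
    return report
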