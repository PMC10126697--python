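"""Exact-match core counting.

Counting is exact substring occurrence, anywhere in the read: repertoire
reads carry primer/UTR prefixes of varying length, so cores are not anchored.
A single mismatch — sequencing error or somatic hypermutation — makes a read
not count, which is the point: only unmutated germline usage is tallied, and
error-derived artifacts are left to the allelic-ratio filter downstream.

Both raw matches and UMI-deduplicated matches are registered, along with the
CDR3 length histogram and unique-CDR3 count per allele that feed the
clonal-expansion filters.
"""

from __future__ import annotations

from collections import Counter as TallyCounter
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd

from .allele_db import AlleleSequence, gene_of
from .core_builder import CoreDatabase, DCoreSet
from .rearrangement_io import RearrangementRecord

__all__ = [
    "AlleleCount",
    "TruncationScan",
    "LcsCountResult",
    "count_cores",
    "count_lcs",
    "truncation_scan",
    "counts_to_frame",
]


@dataclass
class AlleleCount:
    """Match statistics for one core (possibly a merged-name core).

    Invariants: ``umi_count <= raw_count <= total_rows``; the CDR3 length
    histogram sums to ``raw_count`` (rows with an empty CDR3 are binned at
    length 0); ``unique_cdr3 <= raw_count``.
    """

    allele: str
    raw_count: int = 0
    umi_count: int = 0
    cdr3_len_hist: dict[int, int] = field(default_factory=dict)
    unique_cdr3: int = 0
    total_rows: int = 0

    @property
    def frequency(self) -> float:
        return self.raw_count / self.total_rows if self.total_rows else 0.0

    @property
    def modal_cdr3_len_share(self) -> float:
        """Share of the most common CDR3 length among this allele's matches."""
        if not self.raw_count or not self.cdr3_len_hist:
            return 0.0
        return max(self.cdr3_len_hist.values()) / self.raw_count


class _Accumulator:
    __slots__ = ("raw", "umis", "cdr3_lens", "cdr3s")

    def __init__(self) -> None:
        self.raw = 0
        self.umis: set[str] = set()
        self.cdr3_lens: TallyCounter[int] = TallyCounter()
        self.cdr3s: set[str] = set()

    def add(self, rec: RearrangementRecord) -> None:
        self.raw += 1
        self.umis.add(rec.umi)
        self.cdr3_lens[len(rec.cdr3)] += 1
        self.cdr3s.add(rec.cdr3)

    def finalize(self, allele: str, total_rows: int) -> AlleleCount:
        return AlleleCount(
            allele=allele,
            raw_count=self.raw,
            umi_count=len(self.umis),
            cdr3_len_hist=dict(self.cdr3_lens),
            unique_cdr3=len(self.cdr3s),
            total_rows=total_rows,
        )


def count_cores(
    records: Iterable[RearrangementRecord], core_db: CoreDatabase
) -> dict[str, AlleleCount]:
    """Count exact core occurrences per allele over a library.

    A record contributes one raw count to every core it literally contains
    (within one segment's database a read normally matches at most one core
    per gene once identical cores are merged). Every database core appears in
    the result, zero-count cores included.
    """
    if not core_db.cores:
        raise ValueError("empty core database")
    items = list(core_db.cores.items())
    acc = {name: _Accumulator() for name, _ in items}
    total = 0
    for rec in records:
        total += 1
        seq = rec.sequence
        for name, core in items:
            if core in seq:
                acc[name].add(rec)
    return {name: a.finalize(name, total) for name, a in acc.items()}


@dataclass
class LcsCountResult:
    """LCS D counting output: per-allele counts plus the per-substring
    breakdown (which specific substring won each read) and the number of
    reads where two alleles tied on match length."""

    counts: dict[str, AlleleCount]
    substring_tallies: dict[str, TallyCounter]
    ambiguous_rows: int = 0


def count_lcs(
    records: Iterable[RearrangementRecord], dcores: DCoreSet
) -> LcsCountResult:
    """Count D alleles through their allele-specific substring sets.

    Each read yields at most one count in total: among all alleles with a
    specific substring present in the read, only the allele with the longest
    matching substring is credited (ties go to the alphabetically first
    allele and the read is flagged ambiguous). The winning substring's tally
    is recorded, giving the per-substring usage breakdown.
    """
    alleles = sorted(dcores.substrings)
    acc = {a: _Accumulator() for a in alleles}
    tallies: dict[str, TallyCounter] = {a: TallyCounter() for a in alleles}
    ambiguous = 0
    total = 0
    probe_items = [(a, dcores.probes.get(a, [])) for a in alleles]
    for rec in records:
        total += 1
        seq = rec.sequence
        best_allele = None
        best_sub = None
        best_len = -1
        tie = False
        for a, probes in probe_items:
            if not dcores.substrings[a]:
                continue
            if not any(p in seq for p in probes):
                continue
            # allele shares a >=min-length substring with the read; find its
            # longest *specific* match, if any
            for s in dcores.search_order[a]:
                if s in seq:
                    if len(s) > best_len:
                        best_allele, best_sub, best_len, tie = a, s, len(s), False
                    elif len(s) == best_len:
                        tie = True  # best_allele stays: alphabetical order
                    break
        if best_allele is not None:
            acc[best_allele].add(rec)
            tallies[best_allele][best_sub] += 1
            if tie:
                ambiguous += 1
    counts = {a: acc[a].finalize(a, total) for a in alleles}
    return LcsCountResult(
        counts=counts, substring_tallies=tallies, ambiguous_rows=ambiguous
    )


@dataclass
class TruncationScan:
    """Counts of an allele's progressively truncated sequence in a library.

    ``counts[t]`` is the number of reads containing the allele truncated by
    ``t`` nucleotides from the chosen end. Counts are non-decreasing in t by
    construction (a longer match implies every shorter one); the plateau
    locates the end region altered by recombination, and an abrupt jump
    reveals a near-end variant shared with another allele of the gene.
    """

    allele: str
    end: str
    counts: dict[int, int]


def truncation_scan(
    records: Iterable[RearrangementRecord],
    allele: AlleleSequence,
    max_trim: int,
    end: str = "3prime",
) -> TruncationScan:
    """Iterative single-nucleotide truncation counting for one allele."""
    if end not in ("3prime", "5prime"):
        raise ValueError("end must be '3prime' or '5prime'")
    if max_trim >= len(allele.seq):
        raise ValueError("max_trim must be smaller than the allele length")
    seq = allele.seq
    truncs = [
        seq[: len(seq) - t] if end == "3prime" else seq[t:]
        for t in range(max_trim + 1)
    ]
    counts = {t: 0 for t in range(max_trim + 1)}
    for rec in records:
        read = rec.sequence
        # find the smallest t whose truncation occurs; all larger t match too
        for t in range(max_trim + 1):
            if truncs[t] in read:
                for u in range(t, max_trim + 1):
                    counts[u] += 1
                break
    return TruncationScan(allele=allele.name, end=end, counts=counts)


def counts_to_frame(counts: Mapping[str, AlleleCount]) -> pd.DataFrame:
    """Tabulate counts for TSV export."""
    rows = []
    for name, c in counts.items():
        rows.append(
            {
                "allele": name,
                "gene": gene_of(name.split("/", 1)[0]),
                "raw_count": c.raw_count,
                "umi_count": c.umi_count,
                "frequency": c.frequency,
                "unique_cdr3": c.unique_cdr3,
                "max_cdr3_len_freq": c.modal_cdr3_len_share,
            }
        )
    return pd.DataFrame(rows)
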