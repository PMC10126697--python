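"""Derivation of recombination-aware core search strings.

VDJ recombination trims and pads the gene ends that flank the junction: the
3' end of V, the 5' end of J and both ends of D. A "core" is the part of a
germline allele that recombination leaves intact in most rearrangements, so
exact occurrences of the core in repertoire reads count unmutated usage of
that allele far more completely than full-length matching would.

Core derivation works per gene. All alleles of one gene are trimmed by the
same amount, so their counts stay directly comparable (the allelic-ratio
filter depends on this). The trim is the configured default unless an
allele-distinguishing variant sits inside the trim region, in which case the
whole gene is trimmed only down to (and including) the most terminal
distinguishing position — possibly a zero-nucleotide trim when two alleles
differ at the very last base. This variant preservation is what lets end
variants, normally invisible to inference tools, be genotyped at all.

D genes are additionally served by a longest-common-substring (LCS) scheme:
every allele-specific substring covering at least ``min_fraction`` of the
allele is an independent search string, so rearrangements that kept only a
5'- or 3'-biased piece of the D gene still count (at most once per read; the
counter enforces that).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

from .allele_db import AlleleDatabase, DatabaseError, Segment, gene_of

__all__ = [
    "CoreDatabase",
    "DCoreSet",
    "CoreBuildError",
    "derive_v_cores",
    "derive_j_cores",
    "derive_d_cores",
    "derive_d_lcs_cores",
    "write_cores_fasta",
    "read_cores_fasta",
]


class CoreBuildError(DatabaseError):
    """Raised when a database cannot yield valid cores."""


@dataclass
class CoreDatabase:
    """Per-allele core search strings plus trim metadata.

    ``cores`` maps allele name -> core string; names may be joined
    (``"a/b"``) where identical cores were merged. ``gene_trim`` maps gene ->
    (trim5, trim3) in nucleotides. ``allele_trim`` carries per-allele trims
    where a D trimming table overrides the gene-level values.
    """

    segment: Segment
    cores: dict[str, str]
    gene_trim: dict[str, tuple[int, int]]
    merged_groups: list[list[str]] = field(default_factory=list)
    allele_trim: dict[str, tuple[int, int]] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.cores)


@dataclass
class DCoreSet:
    """Allele-specific substring sets for LCS-based D counting.

    ``substrings`` maps allele name -> the set of substrings of that allele
    of length >= ceil(min_fraction * allele length) that occur in no other
    database allele. ``search_order`` holds the same strings sorted longest
    first (the counter assigns a read to the allele with the longest match).
    ``probes`` are all minimum-length windows of the full allele; a read
    shares a >=min-length substring with the allele iff one probe occurs in
    it, which gives a cheap pre-filter before the full search.
    """

    substrings: dict[str, set[str]]
    min_fraction: float
    min_len: dict[str, int]
    search_order: dict[str, list[str]] = field(default_factory=dict)
    probes: dict[str, list[str]] = field(default_factory=dict)
    excluded: list[str] = field(default_factory=list)


def _pair_variant_offsets(seq_a: str, seq_b: str, from_end: bool) -> list[int]:
    """Offsets (0-based, from the trimmed end) where two alleles differ.

    Alleles are aligned at the conserved end: at the 5' start for V genes
    (``from_end=True``: offsets measured from the 3' end) and at the 3' end
    for J genes (offsets measured from the 5' start). For unequal lengths the
    more terminal of the two per-allele offsets is used.
    """
    la, lb = len(seq_a), len(seq_b)
    n = min(la, lb)
    offsets = []
    if from_end:  # V: align 5', measure from 3' end
        for i in range(n):
            if seq_a[i] != seq_b[i]:
                offsets.append(min(la - 1 - i, lb - 1 - i))
    else:  # J: align 3', measure from 5' start
        for k in range(n):
            if seq_a[la - 1 - k] != seq_b[lb - 1 - k]:
                offsets.append(n - 1 - k)
    return offsets


def _gene_trim_amount(
    alleles, default_trim: int, variant_window: int, from_end: bool
) -> int:
    """Trim for one gene under the variant-preservation rule."""
    d_min = None
    for i in range(len(alleles)):
        for j in range(i + 1, len(alleles)):
            for off in _pair_variant_offsets(
                alleles[i].seq, alleles[j].seq, from_end
            ):
                if off < variant_window and (d_min is None or off < d_min):
                    d_min = off
    if d_min is None:
        return default_trim
    return min(default_trim, d_min)


def _merge_identical(cores: dict[str, str]) -> tuple[dict[str, str], list[list[str]]]:
    """Merge byte-identical cores under a joined ``a/b`` name.

    Exact matching cannot distinguish identical cores (duplicated genes such
    as the -D suffix genes share alleles); merging avoids silent double
    counting while keeping the signal.
    """
    by_core: dict[str, list[str]] = {}
    order: list[str] = []
    for name, core in cores.items():
        if core not in by_core:
            order.append(core)
        by_core.setdefault(core, []).append(name)
    merged: dict[str, str] = {}
    groups: list[list[str]] = []
    for core in order:
        names = sorted(by_core[core])
        if len(names) > 1:
            groups.append(names)
        merged["/".join(names)] = core
    return merged, groups


def _derive_end_trimmed(
    db: AlleleDatabase,
    default_trim: int,
    variant_window: int,
    from_end: bool,
) -> CoreDatabase:
    if default_trim < 0:
        raise CoreBuildError("trim must be >= 0")
    if variant_window < default_trim:
        raise CoreBuildError("variant_window must be >= the default trim")
    cores: dict[str, str] = {}
    gene_trim: dict[str, tuple[int, int]] = {}
    for gene, alleles in db.genes.items():
        trim = _gene_trim_amount(alleles, default_trim, variant_window, from_end)
        gene_trim[gene] = (0, trim) if from_end else (trim, 0)
        gene_cores: dict[str, str] = {}
        for a in alleles:
            if trim >= len(a.seq):
                raise CoreBuildError(
                    f"allele {a.name} (length {len(a.seq)}) shorter than trim {trim}"
                )
            core = a.seq[: len(a.seq) - trim] if from_end else a.seq[trim:]
            for other, other_core in gene_cores.items():
                if core == other_core or core in other_core or other_core in core:
                    raise CoreBuildError(
                        f"alleles {other} and {a.name} of gene {gene} are "
                        "indistinguishable over the retained region "
                        "(they differ only by length)"
                    )
            gene_cores[a.name] = core
        cores.update(gene_cores)
    merged, groups = _merge_identical(cores)
    return CoreDatabase(
        segment=db.segment, cores=merged, gene_trim=gene_trim, merged_groups=groups
    )


def derive_v_cores(
    db: AlleleDatabase, default_trim: int = 6, variant_window: int = 6
) -> CoreDatabase:
    """3'-trim V alleles into cores, preserving 3'-proximal variants.

    Per gene: if no position within the last ``variant_window`` nucleotides
    distinguishes any allele pair, every allele is trimmed by
    ``default_trim`` from the 3' end; otherwise the gene is trimmed only down
    to the most 3' distinguishing position, which that trim retains as the
    final core base.
    """
    if db.segment != Segment.V:
        raise CoreBuildError("derive_v_cores requires a V database")
    return _derive_end_trimmed(db, default_trim, variant_window, from_end=True)


def derive_j_cores(
    db: AlleleDatabase, trim5: int = 6, variant_window: int = 6
) -> CoreDatabase:
    """5'-trim J alleles into cores, preserving 5'-proximal variants."""
    if db.segment != Segment.J:
        raise CoreBuildError("derive_j_cores requires a J database")
    return _derive_end_trimmed(db, trim5, variant_window, from_end=False)


def derive_d_cores(
    db: AlleleDatabase,
    trim5: int = 4,
    trim3: int = 4,
    trim_table: Mapping[str, tuple[int, int]] | None = None,
    min_core_len: int = 8,
) -> CoreDatabase:
    """Dual-end trim D alleles into cores.

    ``trim_table`` maps allele name -> (trim5, trim3) and overrides the
    global trims for the listed alleles only. Cores must stay gene specific:
    a core occurring as a substring of another gene's full-length allele is a
    hard error, because exact counting could then credit the wrong gene.
    """
    if db.segment != Segment.D:
        raise CoreBuildError("derive_d_cores requires a D database")
    if trim5 < 0 or trim3 < 0:
        raise CoreBuildError("trims must be >= 0")
    trim_table = dict(trim_table or {})
    unknown = set(trim_table) - set(db.by_name)
    if unknown:
        warnings.warn(
            f"D trim table names unknown alleles: {sorted(unknown)}", stacklevel=2
        )
    cores: dict[str, str] = {}
    allele_trim: dict[str, tuple[int, int]] = {}
    for a in db:
        t5, t3 = trim_table.get(a.name, (trim5, trim3))
        core = a.seq[t5 : len(a.seq) - t3] if t3 else a.seq[t5:]
        if len(core) < min_core_len:
            raise CoreBuildError(
                f"D core for {a.name} is {len(core)} nt after trims ({t5},{t3}); "
                f"minimum is {min_core_len}"
            )
        cores[a.name] = core
        allele_trim[a.name] = (t5, t3)
    # gene-specificity check against every other gene's full allele
    for name, core in cores.items():
        gene = gene_of(name)
        for other in db:
            if other.gene != gene and core in other.seq:
                raise CoreBuildError(
                    f"D core of {name} occurs within {other.name}: cores must "
                    "be gene specific (increase trims or supply a trim table)"
                )
    merged, groups = _merge_identical(cores)
    gene_trim = {gene: (trim5, trim3) for gene in db.genes}
    return CoreDatabase(
        segment=db.segment,
        cores=merged,
        gene_trim=gene_trim,
        merged_groups=groups,
        allele_trim=allele_trim,
    )


def derive_d_lcs_cores(db: AlleleDatabase, min_fraction: float = 0.5) -> DCoreSet:
    """Enumerate allele-specific substrings for LCS-based D counting.

    For each allele, all contiguous substrings of length >=
    ceil(min_fraction * allele length) that occur in no other database allele
    are retained. An allele with no specific substring at the chosen fraction
    is excluded from LCS counting with a warning (the standard D core still
    applies to it).
    """
    if db.segment != Segment.D:
        raise CoreBuildError("derive_d_lcs_cores requires a D database")
    if not (0 < min_fraction <= 1):
        raise CoreBuildError("min_fraction must be in (0, 1]")
    substrings: dict[str, set[str]] = {}
    min_len: dict[str, int] = {}
    search_order: dict[str, list[str]] = {}
    probes: dict[str, list[str]] = {}
    excluded: list[str] = []
    others_cache = {a.name: [b.seq for b in db if b.name != a.name] for a in db}
    for a in db:
        m = math.ceil(min_fraction * len(a.seq))
        min_len[a.name] = m
        seen: set[str] = set()
        for i in range(len(a.seq) - m + 1):
            for j in range(i + m, len(a.seq) + 1):
                seen.add(a.seq[i:j])
        others = others_cache[a.name]
        specific = {s for s in seen if not any(s in o for o in others)}
        if not specific:
            warnings.warn(
                f"D allele {a.name}: no allele-specific substring at "
                f"min_fraction={min_fraction}; excluded from LCS counting",
                stacklevel=2,
            )
            excluded.append(a.name)
        substrings[a.name] = specific
        search_order[a.name] = sorted(specific, key=lambda s: (-len(s), s))
        probes[a.name] = sorted(
            {a.seq[i : i + m] for i in range(len(a.seq) - m + 1)}
        )
    return DCoreSet(
        substrings=substrings,
        min_fraction=min_fraction,
        min_len=min_len,
        search_order=search_order,
        probes=probes,
        excluded=excluded,
    )


def write_cores_fasta(core_db: CoreDatabase, path: str | Path) -> None:
    """Write cores as FASTA; headers carry trim metadata as key=value."""
    with open(path, "w") as fh:
        for name, core in core_db.cores.items():
            gene = gene_of(name.split("/", 1)[0])
            t5, t3 = core_db.allele_trim.get(name, core_db.gene_trim.get(gene, (0, 0)))
            fh.write(f">{name} trim5={t5} trim3={t3} segment={core_db.segment.value}\n")
            fh.write(core + "\n")


def read_cores_fasta(path: str | Path) -> CoreDatabase:
    """Read a core database written by :func:`write_cores_fasta`."""
    cores: dict[str, str] = {}
    gene_trim: dict[str, tuple[int, int]] = {}
    segment: Segment | None = None
    name = None
    meta: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                fields = line[1:].split()
                name = fields[0]
                meta = dict(f.split("=", 1) for f in fields[1:] if "=" in f)
            else:
                assert name is not None, "FASTA sequence line before any header"
                cores[name] = cores.get(name, "") + line.upper()
                gene = gene_of(name.split("/", 1)[0])
                gene_trim[gene] = (
                    int(meta.get("trim5", 0)),
                    int(meta.get("trim3", 0)),
                )
                if "segment" in meta:
                    segment = Segment(meta["segment"])
    if segment is None:
        raise CoreBuildError(f"no segment metadata found in {path}")
    return CoreDatabase(segment=segment, cores=cores, gene_trim=gene_trim)
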