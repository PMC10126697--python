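"""Genotype filtering and end-to-end library genotyping.

Raw core counts become an expressed genotype through a filter chain applied
per gene:

1. **Allelic ratio** — each allele's count divided by the top allele count of
   its gene. True heterozygous pairs sit near 0.5–1.0, while counts created
   by sequencing errors on a sibling allele sit orders of magnitude lower; a
   0.1 cutoff removes them for V and J, and 0.2 for the much shorter D cores.
2. **Minimum count** — absolute evidence floor, on UMI counts when a UMI
   column exists (consensus molecules), raw counts otherwise.
3. **Expected frequency** — an optional per-allele minimum library frequency
   derived from multiple independent libraries. It excludes alleles that
   appear by index hopping, and conversely *rescues* alleles that genuinely
   run at low frequency relative to the other alleles of their gene (and
   would fail the ratio) when their library frequency clears the table
   minimum. Rescue never overrides the minimum count or the CDR3 filters.
4. **CDR3 diversity** — germline usage shows many junctions of many lengths;
   an expanded clone shows one. Alleles whose matches concentrate on a
   single CDR3 length (share > lenmaxfreq) or with too few distinct CDR3
   sequences per match are removed as clonal artifacts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml

from .allele_db import AlleleDatabase, AlleleSequence, Segment, gene_of
from .core_builder import (
    CoreDatabase,
    derive_d_cores,
    derive_d_lcs_cores,
    derive_j_cores,
    derive_v_cores,
)
from .counter import AlleleCount, count_cores, count_lcs
from .rearrangement_io import ColumnMap, RearrangementRecord, read_rearrangements

__all__ = [
    "CoreConfig",
    "FilterConfig",
    "filter_genotype",
    "genotype_library",
    "batch_genotype",
    "BatchResult",
    "end_variant_test",
]


@dataclass
class CoreConfig:
    """Core-derivation parameters.

    Defaults: V 3' trim 6 nt (the truncation scan plateaus at −4/−5 nt;
    6 adds margin), J 5' trim 6 nt, D 4+4 nt with optional per-allele
    overrides, variant window 6 nt at the recombination-proximal end.
    """

    v_trim3: int = 6
    j_trim5: int = 6
    d_trim5: int = 4
    d_trim3: int = 4
    variant_window: int = 6
    d_min_core_len: int = 8
    d_trim_table: dict[str, tuple[int, int]] | None = None
    lcs_min_fraction: float = 0.5

    def derive(self, db: AlleleDatabase) -> CoreDatabase:
        if db.segment == Segment.V:
            return derive_v_cores(db, self.v_trim3, self.variant_window)
        if db.segment == Segment.J:
            return derive_j_cores(db, self.j_trim5, self.variant_window)
        return derive_d_cores(
            db,
            self.d_trim5,
            self.d_trim3,
            trim_table=self.d_trim_table,
            min_core_len=self.d_min_core_len,
        )


@dataclass
class FilterConfig:
    """Genotype filter thresholds; see the module docstring for semantics."""

    allelic_ratio: float = 0.1
    min_count: int = 10
    count_basis: str = "auto"  # "raw" | "umi" | "auto"
    expected_freq_table: dict[str, float] | None = None
    lenmaxfreq: float = 0.6
    min_unique_cdr3_frac: float = 0.1

    def __post_init__(self) -> None:
        if not (0 < self.allelic_ratio <= 1):
            raise ValueError("allelic_ratio must be in (0, 1]")
        if self.min_count < 0:
            raise ValueError("min_count must be >= 0")
        if self.count_basis not in ("raw", "umi", "auto"):
            raise ValueError("count_basis must be 'raw', 'umi' or 'auto'")

    @classmethod
    def for_segment(cls, segment: Segment | str, **overrides) -> "FilterConfig":
        """Segment defaults: allelic ratio 0.1 for V/J, 0.2 for D."""
        segment = Segment(segment)
        kwargs = {"allelic_ratio": 0.2 if segment == Segment.D else 0.1}
        kwargs.update(overrides)
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "FilterConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        data = {
            "allelic_ratio": self.allelic_ratio,
            "min_count": self.min_count,
            "count_basis": self.count_basis,
            "expected_freq_table": self.expected_freq_table,
            "lenmaxfreq": self.lenmaxfreq,
            "min_unique_cdr3_frac": self.min_unique_cdr3_frac,
        }
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh)


def _basis_count(c: AlleleCount, basis: str) -> int:
    return c.umi_count if basis == "umi" else c.raw_count


def filter_genotype(
    counts: Mapping[str, AlleleCount], config: FilterConfig | None = None
) -> pd.DataFrame:
    """Apply the filter chain to one segment's counts.

    Returns one row per database core with all per-stage verdicts and the
    final ``in_genotype`` flag; alleles of one gene are compared against the
    gene's top count to form the allelic ratio.
    """
    config = config or FilterConfig()
    if not counts:
        return pd.DataFrame(
            columns=[
                "allele", "gene", "raw_count", "umi_count", "frequency",
                "allelic_ratio", "pass_ratio", "pass_min_count",
                "pass_expected_freq", "rescued", "pass_cdr3_len",
                "pass_cdr3_div", "in_genotype",
            ]
        )
    basis = config.count_basis
    if basis == "auto":
        basis = "umi" if any(c.umi_count for c in counts.values()) else "raw"
    table = config.expected_freq_table or {}
    unknown = set(table) - set(counts)
    if unknown:
        warnings.warn(
            f"expected-frequency table names unknown alleles: {sorted(unknown)}",
            stacklevel=2,
        )
    gene_max: dict[str, int] = {}
    gene_key = {name: gene_of(name.split("/", 1)[0]) for name in counts}
    for name, c in counts.items():
        g = gene_key[name]
        gene_max[g] = max(gene_max.get(g, 0), _basis_count(c, basis))
    rows = []
    for name, c in counts.items():
        n = _basis_count(c, basis)
        top = gene_max[gene_key[name]]
        ratio = n / top if top else 0.0
        pass_ratio = ratio >= config.allelic_ratio
        pass_min = n >= config.min_count
        freq = c.frequency
        in_table = name in table
        pass_exp = (not in_table) or freq >= table[name]
        rescued = (not pass_ratio) and in_table and freq >= table[name]
        share = c.modal_cdr3_len_share
        pass_len = share <= config.lenmaxfreq if c.raw_count else True
        div = c.unique_cdr3 / c.raw_count if c.raw_count else 1.0
        pass_div = div >= config.min_unique_cdr3_frac
        in_geno = (
            (pass_ratio or rescued)
            and pass_min
            and pass_exp
            and pass_len
            and pass_div
        )
        rows.append(
            {
                "allele": name,
                "gene": gene_key[name],
                "raw_count": c.raw_count,
                "umi_count": c.umi_count,
                "frequency": freq,
                "allelic_ratio": ratio,
                "pass_ratio": pass_ratio,
                "pass_min_count": pass_min,
                "pass_expected_freq": pass_exp,
                "rescued": rescued,
                "pass_cdr3_len": pass_len,
                "pass_cdr3_div": pass_div,
                "in_genotype": in_geno,
            }
        )
    return pd.DataFrame(rows)


def _materialize(
    library, column_map: ColumnMap | None
) -> list[RearrangementRecord]:
    if isinstance(library, (str, Path)):
        return list(read_rearrangements(library, column_map))
    return list(library)


def genotype_library(
    library,
    db: AlleleDatabase,
    core_config: CoreConfig | None = None,
    filter_config: FilterConfig | None = None,
    use_lcs: bool = False,
    column_map: ColumnMap | None = None,
) -> pd.DataFrame:
    """Genotype one library against one segment's database.

    ``library`` is a path to an AIRR TSV or an iterable of records. Cores
    are derived from ``db``, counted exactly (the LCS substring path for D
    when ``use_lcs``), and filtered into the genotype table.
    """
    records = _materialize(library, column_map)
    cc = core_config or CoreConfig()
    fc = filter_config or FilterConfig.for_segment(db.segment)
    if use_lcs:
        if db.segment != Segment.D:
            raise ValueError("LCS counting applies to D databases only")
        dcores = derive_d_lcs_cores(db, cc.lcs_min_fraction)
        counts = count_lcs(records, dcores).counts
    else:
        counts = count_cores(records, cc.derive(db))
    return filter_genotype(counts, fc)


@dataclass
class BatchResult:
    """Per-library genotype tables plus the combined presence matrix."""

    tables: dict[str, pd.DataFrame]
    matrix: pd.DataFrame  # alleles x libraries, boolean IN/OUT
    failures: dict[str, str] = field(default_factory=dict)

    @property
    def union_alleles(self) -> list[str]:
        present = self.matrix.any(axis=1)
        return [a for a in self.matrix.index if present[a]]


def batch_genotype(
    libraries: Sequence,
    db: AlleleDatabase,
    core_config: CoreConfig | None = None,
    filter_config: FilterConfig | None = None,
    use_lcs: bool = False,
    column_map: ColumnMap | None = None,
    labels: Sequence[str] | None = None,
) -> BatchResult:
    """Genotype a set of libraries and combine them into one matrix.

    A failing library aborts only itself; the failure message is recorded
    and its column is omitted from the matrix.
    """
    if not libraries:
        raise ValueError("batch_genotype needs at least one library")
    if labels is None:
        labels = [
            Path(lib).name if isinstance(lib, (str, Path)) else f"library{i}"
            for i, lib in enumerate(libraries)
        ]
    if len(set(labels)) != len(labels):
        labels = [f"{label}#{i}" for i, label in enumerate(labels)]
    tables: dict[str, pd.DataFrame] = {}
    failures: dict[str, str] = {}
    for label, lib in zip(labels, libraries):
        try:
            tables[label] = genotype_library(
                lib, db, core_config, filter_config, use_lcs, column_map
            )
        except Exception as exc:  # noqa: BLE001 - batch isolation contract
            failures[label] = str(exc)
    columns = {}
    for label, tbl in tables.items():
        columns[label] = tbl.set_index("allele")["in_genotype"]
    matrix = pd.DataFrame(columns).fillna(False).astype(bool)
    return BatchResult(tables=tables, matrix=matrix, failures=failures)


def end_variant_test(
    records: Iterable[RearrangementRecord],
    target_allele: AlleleSequence,
    position: int,
    new_base: str,
    db: AlleleDatabase,
    core_config: CoreConfig | None = None,
    filter_config: FilterConfig | None = None,
) -> pd.DataFrame:
    """Probe a candidate end variant by computational modification.

    Every read containing the *full-length* target allele has the base at
    ``position`` (1-based from the 3' end) substituted with ``new_base``;
    reads carrying recombination-truncated copies of the allele are left
    untouched. The database is supplemented with the modified variant
    (named ``<target>_<new_base>``). Because the gene then holds alleles
    differing at a terminal position, core derivation retains the full
    length for that gene, so genotyping discriminates the variant from the
    original at the modified base.
    """
    records = list(records)
    seq = target_allele.seq
    idx = len(seq) - position
    if not (0 <= idx < len(seq)):
        raise ValueError(f"position {position} outside allele of length {len(seq)}")
    if seq[idx] == new_base:
        raise ValueError(
            f"new_base {new_base!r} equals the original base at position -{position}"
        )
    variant_seq = seq[:idx] + new_base + seq[idx + 1 :]
    modified: list[RearrangementRecord] = []
    n_modified = 0
    for rec in records:
        i = rec.sequence.find(seq)
        if i >= 0:
            n_modified += 1
            new_seq = rec.sequence[: i + idx] + new_base + rec.sequence[i + idx + 1 :]
            rec = RearrangementRecord(
                row_id=rec.row_id,
                sequence=new_seq,
                umi=rec.umi,
                cdr3=rec.cdr3,
                v_call=rec.v_call,
                d_call=rec.d_call,
                j_call=rec.j_call,
            )
        modified.append(rec)
    if n_modified == 0:
        raise ValueError(
            f"no full-length occurrences of {target_allele.name} in the library; "
            "end-variant test impossible"
        )
    variant = AlleleSequence(
        name=f"{target_allele.name}_{new_base}",
        seq=variant_seq,
        segment=db.segment,
    )
    return genotype_library(
        modified, db.with_added(variant), core_config, filter_config
    )
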