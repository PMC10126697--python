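"""Streaming I/O for AIRR Rearrangement tables.

Libraries arrive as AIRR Rearrangement TSV (optionally gzip-compressed), one
row per read or UMI consensus. Only a handful of columns matter here — the
nucleotide sequence, the junction/CDR3, the UMI, and optionally the upstream
v/d/j assignment calls — and column names vary between dialects (the
IgDiscover "filtered" table being the canonical one), so a ColumnMap bridges
them. Rows are streamed, never materialized wholesale.
"""

from __future__ import annotations

import csv
import gzip
import random
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import IO, Iterable, Iterator

__all__ = [
    "RearrangementRecord",
    "ColumnMap",
    "read_rearrangements",
    "write_rearrangements",
    "subsample",
]


@dataclass(slots=True)
class RearrangementRecord:
    """One library row: a full-length VDJ read plus its annotations."""

    row_id: int
    sequence: str
    umi: str = ""
    cdr3: str = ""
    v_call: str = ""
    d_call: str = ""
    j_call: str = ""


@dataclass
class ColumnMap:
    """Input-dialect column names.

    ``sequence`` is always required. ``umi`` and ``cdr3`` may be set to None
    when the input genuinely lacks them (UMI deduplication and the CDR3
    diversity filters are then unavailable); if named but absent from the
    file, that is a hard error. Call columns are picked up when present.
    """

    sequence: str = "sequence"
    cdr3: str | None = "junction"
    umi: str | None = "umi"
    v_call: str = "v_call"
    d_call: str = "d_call"
    j_call: str = "j_call"


def _open_text(path: str | Path) -> IO[str]:
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path, "rt")


def read_rearrangements(
    path: str | Path, column_map: ColumnMap | None = None
) -> Iterator[RearrangementRecord]:
    """Stream records from an AIRR Rearrangement TSV (gzip-aware).

    Yields records in file order with sequences uppercased. Rows with an
    empty sequence are skipped and counted in a single summary warning.
    """
    cm = column_map or ColumnMap()
    with _open_text(path) as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise ValueError(f"{path}: empty file, no header row") from None
        col = {name: i for i, name in enumerate(header)}
        required = {"sequence": cm.sequence}
        if cm.umi is not None:
            required["umi"] = cm.umi
        if cm.cdr3 is not None:
            required["cdr3"] = cm.cdr3
        missing = [name for name in required.values() if name not in col]
        if missing:
            raise ValueError(
                f"{path}: missing mapped column(s) {missing}; "
                f"available columns: {header}"
            )
        i_seq = col[cm.sequence]
        i_umi = col.get(cm.umi) if cm.umi else None
        i_cdr3 = col.get(cm.cdr3) if cm.cdr3 else None
        i_v = col.get(cm.v_call)
        i_d = col.get(cm.d_call)
        i_j = col.get(cm.j_call)

        def cell(row: list[str], i: int | None) -> str:
            return row[i] if i is not None and i < len(row) else ""

        skipped = 0
        for row_id, row in enumerate(reader):
            seq = cell(row, i_seq).strip().upper()
            if not seq:
                skipped += 1
                continue
            yield RearrangementRecord(
                row_id=row_id,
                sequence=seq,
                umi=cell(row, i_umi),
                cdr3=cell(row, i_cdr3).upper(),
                v_call=cell(row, i_v),
                d_call=cell(row, i_d),
                j_call=cell(row, i_j),
            )
        if skipped:
            warnings.warn(
                f"{path}: skipped {skipped} row(s) with empty sequence",
                stacklevel=2,
            )


def write_rearrangements(
    records: Iterable[RearrangementRecord],
    path: str | Path,
    column_map: ColumnMap | None = None,
) -> int:
    """Write records as AIRR Rearrangement TSV (gzip if path ends in .gz).

    Returns the number of rows written.
    """
    cm = column_map or ColumnMap()
    n = 0
    with (gzip.open(str(path), "wt") if str(path).endswith(".gz") else open(path, "w")) as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        header = ["sequence_id", cm.sequence]
        if cm.cdr3:
            header.append(cm.cdr3)
        if cm.umi:
            header.append(cm.umi)
        header += [cm.v_call, cm.d_call, cm.j_call]
        writer.writerow(header)
        for rec in records:
            row = [f"read{rec.row_id}", rec.sequence]
            if cm.cdr3:
                row.append(rec.cdr3)
            if cm.umi:
                row.append(rec.umi)
            row += [rec.v_call, rec.d_call, rec.j_call]
            writer.writerow(row)
            n += 1
    return n


def subsample(
    records: Iterable[RearrangementRecord],
    fraction: float,
    seed: int,
    exact: bool = False,
) -> Iterator[RearrangementRecord]:
    """Reproducibly subsample a library.

    Default is Bernoulli thinning: each record is retained independently
    with probability ``fraction``, in one streaming pass, matching the
    replicate-to-replicate size variance of repeated random samplings.
    ``exact=True`` instead keeps exactly round(fraction * n) records (order
    preserved), at the cost of materializing the input.
    """
    if not (0 < fraction <= 1):
        raise ValueError("fraction must be in (0, 1]")
    rng = random.Random(seed)
    if exact:
        pool = list(records)
        k = round(fraction * len(pool))
        keep = set(rng.sample(range(len(pool)), k))
        for i, rec in enumerate(pool):
            if i in keep:
                yield rec
    else:
        for rec in records:
            if rng.random() < fraction:
                yield rec
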