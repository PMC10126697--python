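"""Inferred haplotyping of V alleles via heterozygous anchor alleles.

VDJ recombination happens in cis: a rearrangement joins V, D and J segments
from the same chromosome. When an individual is heterozygous for a J (or D)
gene — classically IGHJ6 — the two anchor alleles label the two chromosomes,
and each V allele can be assigned to a haplotype from which anchor its reads
co-occur with. A V allele present on both chromosomes (homozygous gene)
co-occurs with both anchors at similar rates and is called "both".
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .allele_db import gene_of
from .core_builder import CoreDatabase
from .rearrangement_io import RearrangementRecord

__all__ = ["HaplotypeResult", "infer_haplotype", "infer_haplotype_from_calls"]


@dataclass
class HaplotypeResult:
    """Anchor pair plus the per-V-allele co-occurrence table."""

    anchor_alleles: tuple[str, str]
    table: pd.DataFrame  # allele, c_anchor1, c_anchor2, fraction, assignment


def _assign(c1: int, c2: int, threshold: float) -> tuple[float, str]:
    total = c1 + c2
    if total == 0:
        return float("nan"), "unassigned"
    frac = c1 / total
    if frac >= threshold:
        return frac, "1"
    if frac <= 1 - threshold:
        return frac, "2"
    return frac, "both"


def _finish(
    pair: tuple[str, str],
    co: dict[str, list[int]],
    threshold: float,
    gene_order: Sequence[str] | None,
) -> HaplotypeResult:
    rows = []
    for v_name, (c1, c2) in co.items():
        frac, assignment = _assign(c1, c2, threshold)
        rows.append(
            {
                "allele": v_name,
                "gene": gene_of(v_name.split("/", 1)[0]),
                "c_anchor1": c1,
                "c_anchor2": c2,
                "fraction": frac,
                "assignment": assignment,
            }
        )
    table = pd.DataFrame(rows)
    if gene_order is not None and not table.empty:
        rank = {g: i for i, g in enumerate(gene_order)}
        table = table.sort_values(
            by=["gene", "allele"],
            key=lambda s: s.map(rank).fillna(len(rank)) if s.name == "gene" else s,
            kind="stable",
        ).reset_index(drop=True)
    return HaplotypeResult(anchor_alleles=pair, table=table)


def infer_haplotype(
    records: Iterable[RearrangementRecord],
    v_cores: CoreDatabase,
    anchor_cores: CoreDatabase,
    anchor_gene: str,
    threshold: float = 0.9,
    gene_order: Sequence[str] | None = None,
) -> HaplotypeResult:
    """Assign V alleles to haplotypes from core co-occurrence.

    Co-occurrence is counted directly from core matches within the same
    record, so the result does not depend on upstream v_call/j_call columns.
    Exactly two anchor alleles of ``anchor_gene`` must be observed; reads
    matching neither (or both) anchors are ignored. A V allele is assigned
    haplotype 1 when its anchor-1 fraction is at least ``threshold``,
    haplotype 2 when at most ``1 - threshold``, and "both" in between.
    """
    if not (0.5 < threshold <= 1):
        raise ValueError("threshold must be in (0.5, 1]")
    candidates = {
        name: core
        for name, core in anchor_cores.cores.items()
        if gene_of(name.split("/", 1)[0]) == anchor_gene
    }
    if len(candidates) < 2:
        raise ValueError(
            f"anchor gene {anchor_gene} has {len(candidates)} allele core(s); "
            "a heterozygous anchor needs two"
        )
    anchor_names = sorted(candidates)
    anchor_totals = {a: 0 for a in anchor_names}
    v_items = list(v_cores.cores.items())
    co: dict[str, list[int]] = {name: [0, 0] for name, _ in v_items}
    pending: list[tuple[str, str]] = []  # (anchor, v_allele) observations
    for rec in records:
        seq = rec.sequence
        hits = [a for a in anchor_names if candidates[a] in seq]
        if len(hits) != 1:
            continue
        anchor = hits[0]
        anchor_totals[anchor] += 1
        for v_name, core in v_items:
            if core in seq:
                pending.append((anchor, v_name))
    observed = [a for a in anchor_names if anchor_totals[a] > 0]
    if len(observed) != 2:
        raise ValueError(
            f"anchor gene {anchor_gene} is not heterozygous in this library: "
            f"observed nonzero counts for {observed or 'no alleles'}"
        )
    pair = (observed[0], observed[1])
    for anchor, v_name in pending:
        if anchor == pair[0]:
            co[v_name][0] += 1
        elif anchor == pair[1]:
            co[v_name][1] += 1
    return _finish(pair, co, threshold, gene_order)


def infer_haplotype_from_calls(
    records: Iterable[RearrangementRecord],
    anchor_gene: str,
    threshold: float = 0.9,
    gene_order: Sequence[str] | None = None,
) -> HaplotypeResult:
    """Haplotype from existing v_call/j_call columns instead of core matches.

    Trusts the upstream aligner's single-allele assignments; rows with empty
    or ambiguous (comma-separated) calls are ignored.
    """
    if not (0.5 < threshold <= 1):
        raise ValueError("threshold must be in (0.5, 1]")
    anchor_totals: dict[str, int] = {}
    obs: list[tuple[str, str]] = []
    for rec in records:
        j = rec.j_call
        v = rec.v_call
        if not j or not v or "," in j or "," in v:
            continue
        if "*" not in j or gene_of(j) != anchor_gene:
            continue
        anchor_totals[j] = anchor_totals.get(j, 0) + 1
        obs.append((j, v))
    observed = sorted(a for a, n in anchor_totals.items() if n > 0)
    if len(observed) != 2:
        raise ValueError(
            f"anchor gene {anchor_gene} is not heterozygous in this library: "
            f"observed {observed or 'no alleles'}"
        )
    pair = (observed[0], observed[1])
    co: dict[str, list[int]] = {}
    for j, v in obs:
        co.setdefault(v, [0, 0])
        if j == pair[0]:
            co[v][0] += 1
        else:
            co[v][1] += 1
    return _finish(pair, co, threshold, gene_order)
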