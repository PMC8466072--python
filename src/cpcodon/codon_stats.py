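"""Codon counting, positional GC composition, RSCU/RFSC and
high-frequency codon screening.

Relative synonymous codon usage (RSCU) of codon *j* for amino acid *i*
is the observed count divided by the family mean,

    RSCU_ij = x_ij * n_i / sum_j x_ij,

so an unbiased family has RSCU = 1 for every member. The relative
frequency of a synonymous codon (RFSC) is its share of the family,
x_ij / sum_j x_ij, and the two are linked by RSCU = n_i * RFSC.

A codon is called *high-frequency* when its RFSC exceeds 0.6, or when it
exceeds the family-average frequency 1/n_i by half again (RFSC > 1.5/n_i).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from .cds_io import CdsRecord
from .genetic_code import (
    AA_TO_CODONS,
    CODON_TO_AA,
    CODONS,
    FAMILY_SIZE,
    NON_SYNONYMOUS_CODONS,
    codons_of,
)

log = logging.getLogger(__name__)

_GC = frozenset("GC")


@dataclass
class CodonCountTable:
    """Integer occurrence counts for all 64 codons (one gene or a pooled set)."""

    counts: dict[str, int]
    scope: str = "gene"

    def __post_init__(self) -> None:
        full = {c: 0 for c in CODONS}
        full.update(self.counts)
        if set(full) != set(CODONS):
            extra = sorted(set(full) - set(CODONS))
            raise ValueError(f"non-codon keys: {extra}")
        self.counts = full

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def family_total(self, aa: str) -> int:
        return sum(self.counts[c] for c in AA_TO_CODONS[aa])

    def __add__(self, other: "CodonCountTable") -> "CodonCountTable":
        merged = {c: self.counts[c] + other.counts[c] for c in CODONS}
        return CodonCountTable(merged, scope="pooled")


@dataclass
class GcComposition:
    """GC fractions by codon position, plus synonymous third-position makeup.

    ``gc3s`` and the four base shares ``t3s/c3s/a3s/g3s`` are computed
    over synonymously variable codons only (Met, Trp and stops excluded)
    and are NaN when no such codon was counted.
    """

    gc1: float
    gc2: float
    gc3: float
    gc3s: float
    t3s: float
    c3s: float
    a3s: float
    g3s: float

    @property
    def gc123(self) -> float:
        return (self.gc1 + self.gc2 + self.gc3) / 3.0

    @property
    def gc12(self) -> float:
        return (self.gc1 + self.gc2) / 2.0


@dataclass
class RscuTable:
    """Per-codon RSCU with the family sizes used to normalize."""

    values: dict[str, float]
    family_sizes: dict[str, int] = field(default_factory=lambda: dict(FAMILY_SIZE))
    unobserved: set[str] = field(default_factory=set)


@dataclass
class RfscTable:
    """Per-codon family share; each observed family sums to 1."""

    values: dict[str, float]
    unobserved: set[str] = field(default_factory=set)


def count_codons(
    records: CdsRecord | Sequence[CdsRecord], pool: bool = True
) -> CodonCountTable | list[CodonCountTable]:
    """Count non-overlapping triplets 5'->3'.

    With ``pool=True`` (default) a single pooled table is returned;
    otherwise one table per record. Codons containing N are skipped and
    logged. Sequences whose length is not a multiple of 3 are an error.
    """
    if isinstance(records, CdsRecord):
        records = [records]
    tables: list[CodonCountTable] = []
    for rec in records:
        if len(rec.sequence) % 3:
            raise ValueError(
                f"{rec.gene_id}: length {len(rec.sequence)} not divisible by 3"
            )
        counts = {c: 0 for c in CODONS}
        skipped = 0
        for codon in codons_of(rec.sequence):
            if "N" in codon:
                skipped += 1
                continue
            counts[codon] += 1
        if skipped:
            log.warning("%s: skipped %d ambiguous codons", rec.gene_id, skipped)
        tables.append(CodonCountTable(counts, scope="gene"))
    if not pool:
        return tables
    pooled = {c: 0 for c in CODONS}
    for t in tables:
        for c in CODONS:
            pooled[c] += t.counts[c]
    return CodonCountTable(pooled, scope="pooled" if len(tables) > 1 else "gene")


def gc_by_position(table: CodonCountTable) -> GcComposition:
    """Positional GC content of a codon count table.

    gcK is the G+C fraction at codon position K over every counted
    codon; gc3s and the t3s/c3s/a3s/g3s shares are restricted to
    synonymous codons (excluding ATG, TGG and stops).
    """
    total = table.total
    if total == 0:
        raise ValueError("empty codon table")
    pos_gc = [0, 0, 0]
    for codon, n in table.counts.items():
        for k in range(3):
            if codon[k] in _GC:
                pos_gc[k] += n
    syn_total = 0
    third = {b: 0 for b in "TCAG"}
    for codon, n in table.counts.items():
        if codon in NON_SYNONYMOUS_CODONS:
            continue
        syn_total += n
        third[codon[2]] += n
    if syn_total:
        gc3s = (third["G"] + third["C"]) / syn_total
        shares = {b: third[b] / syn_total for b in "TCAG"}
    else:
        gc3s = math.nan
        shares = {b: math.nan for b in "TCAG"}
    return GcComposition(
        gc1=pos_gc[0] / total,
        gc2=pos_gc[1] / total,
        gc3=pos_gc[2] / total,
        gc3s=gc3s,
        t3s=shares["T"],
        c3s=shares["C"],
        a3s=shares["A"],
        g3s=shares["G"],
    )


def compute_rscu(table: CodonCountTable) -> RscuTable:
    """Relative synonymous codon usage: observed count over family mean."""
    if table.total == 0:
        raise ValueError("empty codon table")
    values: dict[str, float] = {}
    unobserved: set[str] = set()
    for aa, codons in AA_TO_CODONS.items():
        fam_total = sum(table.counts[c] for c in codons)
        if fam_total == 0:
            unobserved.add(aa)
            for c in codons:
                values[c] = 0.0
            continue
        n_i = len(codons)
        for c in codons:
            values[c] = table.counts[c] * n_i / fam_total
    return RscuTable(values=values, unobserved=unobserved)


def compute_rfsc(table: CodonCountTable) -> RfscTable:
    """Relative frequency of synonymous codons: each family sums to 1."""
    if table.total == 0:
        raise ValueError("empty codon table")
    values: dict[str, float] = {}
    unobserved: set[str] = set()
    for aa, codons in AA_TO_CODONS.items():
        fam_total = sum(table.counts[c] for c in codons)
        if fam_total == 0:
            unobserved.add(aa)
            for c in codons:
                values[c] = 0.0
            continue
        for c in codons:
            values[c] = table.counts[c] / fam_total
    return RfscTable(values=values, unobserved=unobserved)


def high_frequency_codons(rfsc: RfscTable) -> set[str]:
    """Codons passing the high-frequency screen.

    Included iff RFSC > 0.6 or RFSC > 1.5 * (1/n_i), i.e. the codon
    exceeds its family's average share by half again. Unobserved
    families contribute nothing; the stop family participates like any
    other.
    """
    selected: set[str] = set()
    for aa, codons in AA_TO_CODONS.items():
        if aa in rfsc.unobserved:
            continue
        n_i = len(codons)
        for c in codons:
            v = rfsc.values[c]
            if v > 0.6 or v > 1.5 / n_i:
                selected.add(c)
    return selected


def rscu_rfsc_tsv(
    table: CodonCountTable,
    path: str | Path,
    high_frequency: set[str] | None = None,
) -> None:
    """Write the per-codon usage table (codon, aa, count, RSCU, RFSC, flag)."""
    rscu = compute_rscu(table)
    rfsc = compute_rfsc(table)
    if high_frequency is None:
        high_frequency = high_frequency_codons(rfsc)
    with open(path, "w") as fh:
        fh.write("codon\tamino_acid\tcount\trscu\trfsc\thigh_frequency\n")
        for codon in CODONS:
            fh.write(
                f"{codon}\t{CODON_TO_AA[codon]}\t{table.counts[codon]}\t"
                f"{rscu.values[codon]:.6f}\t{rfsc.values[codon]:.6f}\t"
                f"{int(codon in high_frequency)}\n"
            )


def pool_tables(tables: Iterable[CodonCountTable]) -> CodonCountTable:
    """Elementwise sum of count tables (pooled scope)."""
    pooled = {c: 0 for c in CODONS}
    for t in tables:
        for c in CODONS:
            pooled[c] += t.counts[c]
    return CodonCountTable(pooled, scope="pooled")
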