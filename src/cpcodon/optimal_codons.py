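"""Optimal-codon determination from ENC-ranked expression libraries.

Genes are ranked by ENC and the lowest-ENC 10% (strongest bias, the
standard proxy for high expression) and highest-ENC 10% form the high-
and low-expression libraries. RSCU is computed on the pooled counts of
each library and a codon is *optimal* when

    delta RSCU = RSCU_high - RSCU_low > 0.08,
    RSCU_high > 1  and  RSCU_low < 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

from .codon_stats import CodonCountTable, compute_rscu
from .genetic_code import CODON_TO_AA, CODONS
from .usage_indices import GeneIndices


@dataclass
class ExpressionLibraries:
    """Gene-id lists of the putative high- and low-expression libraries."""

    high: list[str]
    low: list[str]
    fraction: float = 0.10


@dataclass
class CodonDelta:
    codon: str
    rscu_high: float
    rscu_low: float

    @property
    def delta_rscu(self) -> float:
        return self.rscu_high - self.rscu_low

    def is_optimal(self, threshold: float = 0.08) -> bool:
        return (
            self.delta_rscu > threshold
            and self.rscu_high > 1.0
            and self.rscu_low < 1.0
        )


@dataclass
class OptimalCodonResult:
    """Per-codon audit triples and the resulting optimal set."""

    records: list[CodonDelta]
    optimal_set: set[str]
    threshold: float = 0.08

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("codon\tamino_acid\trscu_high\trscu_low\tdelta_rscu\toptimal\n")
            for r in self.records:
                fh.write(
                    f"{r.codon}\t{CODON_TO_AA[r.codon]}\t{r.rscu_high:.6f}\t"
                    f"{r.rscu_low:.6f}\t{r.delta_rscu:.6f}\t"
                    f"{int(r.codon in self.optimal_set)}\n"
                )


def split_expression_libraries(
    indices: list[GeneIndices], fraction: float = 0.10
) -> ExpressionLibraries:
    """Take the lowest- and highest-ENC ``fraction`` of genes.

    Library size k = max(1, round-half-up(fraction * N)) over the genes
    with defined ENC; ties in ENC break lexicographically on gene_id so
    the split is deterministic.
    """
    usable = [g for g in indices if not math.isnan(g.enc)]
    if len(usable) < 10:
        raise ValueError(
            f"only {len(usable)} genes with defined ENC; need >= 10 "
            "(consider a smaller library fraction)"
        )
    ranked = sorted(usable, key=lambda g: (g.enc, g.gene_id))
    k = max(1, math.floor(fraction * len(ranked) + 0.5))
    return ExpressionLibraries(
        high=[g.gene_id for g in ranked[:k]],
        low=[g.gene_id for g in ranked[-k:]],
        fraction=fraction,
    )


def delta_rscu_optimal(
    high_counts: CodonCountTable,
    low_counts: CodonCountTable,
    threshold: float = 0.08,
) -> OptimalCodonResult:
    """Apply the delta-RSCU rule to pooled high/low library counts."""
    if high_counts.total == 0 or low_counts.total == 0:
        raise ValueError("both expression libraries must contain codons")
    rscu_high = compute_rscu(high_counts)
    rscu_low = compute_rscu(low_counts)
    records = [
        CodonDelta(c, rscu_high.values[c], rscu_low.values[c]) for c in CODONS
    ]
    optimal = {r.codon for r in records if r.is_optimal(threshold)}
    return OptimalCodonResult(records=records, optimal_set=optimal, threshold=threshold)
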