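"""Mutation-versus-selection diagnostics: ENC-plot, PR2-plot, neutrality plot.

Three classical views of what shapes codon usage:

* **ENC-plot** — per-gene ENC against synonymous GC3. Under mutation
  pressure alone ENC follows the expected curve
  ``2 + s + 29/(s^2 + (1-s)^2)``; genes under translational selection
  fall below it.
* **PR2-plot** — parity-rule-2 bias of third-position bases within
  fourfold-degenerate codon boxes, A3/(A3+T3) against G3/(G3+C3). With
  no strand-specific mutation or selection bias both coordinates sit at
  0.5.
* **Neutrality plot** — per-gene GC12 (mean GC of positions 1 and 2)
  regressed on GC3. A slope of 1 indicates pure mutation pressure
  (complete neutrality); a slope near 0 indicates selection holding
  positions 1-2 away from the mutational equilibrium of position 3.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .codon_stats import CodonCountTable
from .genetic_code import (
    FOURFOLD_CODONS,
    ILE_CODONS,
    NON_SYNONYMOUS_CODONS,
    STOP_CODONS,
)
from .usage_indices import GeneIndices


@dataclass
class EncPlotPoint:
    gene_id: str
    gc3s: float
    enc: float
    enc_expected: float

    @property
    def deviation(self) -> float:
        return self.enc - self.enc_expected


@dataclass
class Pr2Point:
    """Third-position parity biases; NaN coordinate when a denominator is 0."""

    gene_id: str
    at_bias: float  # A3 / (A3 + T3)
    gc_bias: float  # G3 / (G3 + C3)


@dataclass
class NeutralityFit:
    slope: float
    intercept: float
    pearson_r: float
    p_value: float
    gc12_per_gene: list[float]
    gc3_per_gene: list[float]


def enc_plot_points(genes: Sequence[GeneIndices]) -> list[EncPlotPoint]:
    """One ENC-plot point per gene with defined ENC and GC3s."""
    points = []
    for g in genes:
        if math.isnan(g.enc) or math.isnan(g.gc.gc3s):
            continue
        points.append(EncPlotPoint(g.gene_id, g.gc.gc3s, g.enc, g.enc_expected))
    return points


def fraction_below_curve(points: Sequence[EncPlotPoint]) -> float:
    """Share of genes lying below the mutation-only expectation."""
    if not points:
        return math.nan
    return sum(1 for p in points if p.deviation < 0) / len(points)


def pr2_point(
    table: CodonCountTable, codon_set: str = "fourfold", gene_id: str = ""
) -> Pr2Point:
    """Parity-rule-2 coordinates of one count table.

    ``codon_set`` selects the third positions counted: "fourfold"
    (default, Sueoka's convention — only fourfold-degenerate codon
    boxes) or "all_synonymous" (everything but Met, Trp and stops).
    """
    if table.total == 0:
        raise ValueError("empty codon table")
    if codon_set == "fourfold":
        eligible = FOURFOLD_CODONS
    elif codon_set == "all_synonymous":
        eligible = set(table.counts) - NON_SYNONYMOUS_CODONS
    else:
        raise ValueError(f"unknown codon_set {codon_set!r}")
    third = {b: 0 for b in "ACGT"}
    for codon, n in table.counts.items():
        if codon in eligible:
            third[codon[2]] += n
    at = third["A"] + third["T"]
    gc = third["G"] + third["C"]
    return Pr2Point(
        gene_id=gene_id,
        at_bias=third["A"] / at if at else math.nan,
        gc_bias=third["G"] / gc if gc else math.nan,
    )


def species_pr2(points: Sequence[Pr2Point]) -> Pr2Point:
    """Species-level PR2 value: unweighted mean of per-gene coordinates."""
    at = [p.at_bias for p in points if not math.isnan(p.at_bias)]
    gc = [p.gc_bias for p in points if not math.isnan(p.gc_bias)]
    return Pr2Point(
        gene_id="mean",
        at_bias=float(np.mean(at)) if at else math.nan,
        gc_bias=float(np.mean(gc)) if gc else math.nan,
    )


def neutrality_gc3(
    table: CodonCountTable,
    exclude_met_trp: bool = True,
    exclude_stops: bool = True,
    exclude_ile: bool = True,
) -> float:
    """Third-position GC for the neutrality plot.

    The default excludes ATG/TGG, the stop codons and the three Ile
    codons; each exclusion is independently toggleable since
    conventions differ.
    """
    excluded: set[str] = set()
    if exclude_met_trp:
        excluded |= {"ATG", "TGG"}
    if exclude_stops:
        excluded |= STOP_CODONS
    if exclude_ile:
        excluded |= ILE_CODONS
    total = 0
    gc = 0
    for codon, n in table.counts.items():
        if codon in excluded:
            continue
        total += n
        if codon[2] in "GC":
            gc += n
    return gc / total if total else math.nan


def neutrality_fit(
    gene_tables: Sequence[CodonCountTable],
    genes: Sequence[GeneIndices],
    **gc3_kwargs,
) -> NeutralityFit:
    """Ordinary least squares of per-gene GC12 on GC3.

    GC12 is the mean of the gene's position-1 and position-2 GC
    fractions; GC3 applies the neutrality exclusions (see
    :func:`neutrality_gc3`). Pearson r and its two-sided p accompany the
    fit. Zero variance in GC3 yields NaN slope.
    """
    if len(genes) < 3:
        raise ValueError("need >= 3 genes for the neutrality fit")
    gc12 = [g.gc.gc12 for g in genes]
    gc3 = [neutrality_gc3(t, **gc3_kwargs) for t in gene_tables]
    x = np.asarray(gc3, dtype=float)
    y = np.asarray(gc12, dtype=float)
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    if x.size < 3 or np.ptp(x) == 0:
        return NeutralityFit(math.nan, math.nan, math.nan, math.nan, gc12, gc3)
    res = stats.linregress(x, y)
    return NeutralityFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        pearson_r=float(res.rvalue),
        p_value=float(res.pvalue),
        gc12_per_gene=gc12,
        gc3_per_gene=gc3,
    )


def pairwise_gc_correlations(
    genes: Sequence[GeneIndices],
) -> dict[tuple[str, str], tuple[float, float]]:
    """Pearson r (and two-sided p) between GC1, GC2 and GC3 across genes."""
    if len(genes) < 3:
        raise ValueError("need >= 3 genes")
    series = {
        "GC1": np.array([g.gc.gc1 for g in genes]),
        "GC2": np.array([g.gc.gc2 for g in genes]),
        "GC3": np.array([g.gc.gc3 for g in genes]),
    }
    out: dict[tuple[str, str], tuple[float, float]] = {}
    for a, b in (("GC1", "GC2"), ("GC1", "GC3"), ("GC2", "GC3")):
        if np.ptp(series[a]) == 0 or np.ptp(series[b]) == 0:
            out[(a, b)] = (math.nan, math.nan)
            continue
        r, p = stats.pearsonr(series[a], series[b])
        out[(a, b)] = (float(r), float(p))
    return out
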