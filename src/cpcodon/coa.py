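"""Correspondence analysis of the gene x 59-codon RSCU matrix.

Each gene contributes its RSCU profile over the 59 synonymously
variable codons (64 minus ATG, TGG and the three stops). Standard
chi-square-metric correspondence analysis is applied: the matrix is
normalized to its grand total, the standardized residual matrix
S = D_r^{-1/2} (P - r c^T) D_c^{-1/2} is decomposed by SVD, and genes
are placed in principal coordinates. Axis 1 captures the major trend in
codon usage; per-axis inertia fractions say how much of the total
chi-square variation (inertia = chi2 / N) each axis carries.

Correlating the axis-1 gene coordinates with usage indices (GC3s, CAI,
ENC, L_aa, ...) identifies which forces drive that trend.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cds_io import CdsRecord
from .codon_stats import compute_rscu, count_codons
from .genetic_code import SYNONYMOUS_CODONS
from .usage_indices import GeneIndices

log = logging.getLogger(__name__)


@dataclass
class CoaResult:
    """Gene and codon principal coordinates plus per-axis inertia fractions."""

    gene_coords: pd.DataFrame  # genes x axes
    codon_coords: pd.DataFrame  # codons x axes
    inertia_fraction: np.ndarray  # per retained axis
    total_inertia: float


@dataclass
class AxisCorrelationRow:
    index_name: str
    pearson_r: float
    p_value: float

    @property
    def mark(self) -> str:
        if math.isnan(self.p_value):
            return ""
        if self.p_value < 0.01:
            return "**"
        if self.p_value < 0.05:
            return "*"
        return ""


def rscu_matrix(genes: Sequence[CdsRecord]) -> pd.DataFrame:
    """Per-gene RSCU over the 59 synonymously variable codons.

    Families a gene does not use contribute zeros for that gene's row.
    """
    if len(genes) < 2:
        raise ValueError("need >= 2 genes")
    rows = {}
    for gene in genes:
        table = count_codons(gene)
        rscu = compute_rscu(table)
        rows[gene.gene_id] = [rscu.values[c] for c in SYNONYMOUS_CODONS]
    return pd.DataFrame.from_dict(
        rows, orient="index", columns=list(SYNONYMOUS_CODONS)
    )


def correspondence_analysis(matrix: pd.DataFrame, n_axes: int = 4) -> CoaResult:
    """Chi-square-metric correspondence analysis of a non-negative matrix.

    Axis signs are fixed so the codon with the largest absolute loading
    on each axis loads positively (CA axes are inherently sign-ambiguous).
    """
    X = np.asarray(matrix, dtype=float)
    if (X < 0).any():
        raise ValueError("matrix must be non-negative")
    if not (X.sum(axis=1) > 0).all():
        raise ValueError("every row needs at least one positive entry")
    grand = X.sum()
    P = X / grand
    r = P.sum(axis=1)
    c = P.sum(axis=0)
    keep_cols = c > 0
    S = (P - np.outer(r, c))[:, keep_cols] / np.sqrt(
        np.outer(r, c[keep_cols])
    )
    U, sigma, Vt = np.linalg.svd(S, full_matrices=False)
    # P is normalized to grand total 1, so singular values are <= 1 and an
    # absolute cutoff suffices to separate numerical noise from structure
    tol = max(S.shape) * np.finfo(float).eps
    rank = int((sigma > tol).sum())
    if rank == 0:
        raise ValueError("no variation: the residual matrix has rank 0")
    k = min(n_axes, rank)
    total_inertia = float((sigma[:rank] ** 2).sum())
    inertia_fraction = sigma[:k] ** 2 / total_inertia

    row_coords = (U[:, :k] * sigma[:k]) / np.sqrt(r)[:, None]
    col_coords_kept = (Vt[:k].T * sigma[:k]) / np.sqrt(c[keep_cols])[:, None]
    col_coords = np.zeros((X.shape[1], k))
    col_coords[keep_cols] = col_coords_kept
    for ax in range(k):
        j = int(np.argmax(np.abs(col_coords[:, ax])))
        if col_coords[j, ax] < 0:
            col_coords[:, ax] *= -1
            row_coords[:, ax] *= -1
    axis_names = [f"axis{i + 1}" for i in range(k)]
    return CoaResult(
        gene_coords=pd.DataFrame(row_coords, index=matrix.index, columns=axis_names),
        codon_coords=pd.DataFrame(
            col_coords, index=matrix.columns, columns=axis_names
        ),
        inertia_fraction=np.asarray(inertia_fraction),
        total_inertia=total_inertia,
    )


def axis_correlations(
    coa: CoaResult, indices: Sequence[GeneIndices], axis: int = 1
) -> list[AxisCorrelationRow]:
    """Pearson correlation of an axis's gene coordinates with usage indices.

    The index set mirrors the classical per-gene table: T3s, C3s, A3s,
    G3s, CAI, CBI, Fop, Nc, GC3s, GC (overall positional mean) and
    L_aa. Genes with missing values are dropped pairwise (logged).
    """
    by_id = {g.gene_id: g for g in indices}
    if set(coa.gene_coords.index) != set(by_id):
        raise ValueError("gene sets of ordination and indices do not match")
    coords = coa.gene_coords[f"axis{axis}"]
    extractors = {
        "T3s": lambda g: g.gc.t3s,
        "C3s": lambda g: g.gc.c3s,
        "A3s": lambda g: g.gc.a3s,
        "G3s": lambda g: g.gc.g3s,
        "CAI": lambda g: g.cai,
        "CBI": lambda g: g.cbi,
        "Fop": lambda g: g.fop,
        "Nc": lambda g: g.enc,
        "GC3s": lambda g: g.gc.gc3s,
        "GC": lambda g: g.gc.gc123,
        "L_aa": lambda g: float(g.l_aa),
    }
    rows: list[AxisCorrelationRow] = []
    for name, get in extractors.items():
        x = []
        y = []
        dropped = 0
        for gene_id, coord in coords.items():
            v = get(by_id[gene_id])
            if math.isnan(v):
                dropped += 1
                continue
            x.append(coord)
            y.append(v)
        if dropped:
            log.info("%s: %d genes dropped (missing values)", name, dropped)
        if len(x) < 3 or np.ptp(x) == 0 or np.ptp(y) == 0:
            rows.append(AxisCorrelationRow(name, math.nan, math.nan))
            continue
        r, p = stats.pearsonr(x, y)
        rows.append(AxisCorrelationRow(name, float(r), float(p)))
    return rows
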