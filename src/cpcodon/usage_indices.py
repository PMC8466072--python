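"""Per-gene codon-usage indices: ENC, CAI, CBI, Fop and L_aa.

The effective number of codons (ENC, often written Nc) is Wright's
estimator of how far a gene departs from uniform synonymous usage. Per
synonymous family with total count n >= 2 and within-family shares p_j,
the codon homozygosity is

    F_hat = (n * sum_j p_j^2 - 1) / (n - 1),

and with F-bar_k the mean F_hat over families of degeneracy k,

    ENC = 2 + 9 / F_bar_2 + 1 / F_bar_3 + 5 / F_bar_4 + 3 / F_bar_6,

ranging from 20 (one codon per amino acid) to 61 (uniform usage).

The codon adaptation index (CAI) is the geometric mean, over a gene's
codons, of relative adaptiveness values w_j = RSCU_ref(j) / max-in-family
RSCU_ref derived from a high-expression reference set; Met, Trp and
stops are excluded. CBI and Fop measure enrichment of a designated
optimal-codon set: Fop is the optimal fraction N_opt / N_tot, and
CBI = (N_opt - N_rand) / (N_tot - N_rand) rescales it so that random
usage scores 0 and purely optimal usage 1.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

from .codon_stats import CodonCountTable, GcComposition, RscuTable
from .genetic_code import (
    AA_TO_CODONS,
    CODON_TO_AA,
    NON_SYNONYMOUS_CODONS,
    SENSE_FAMILIES,
)

log = logging.getLogger(__name__)

#: Number of amino-acid families per degeneracy class (six-fold kept whole).
_CLASS_FAMILY_COUNT = {2: 9, 3: 1, 4: 5, 6: 3}

#: Six-fold families split into their two- and four-fold codon boxes, for the
#: alternative ENC classing.
_SPLIT_SIXFOLD = {
    "L": (("TTA", "TTG"), ("CTT", "CTC", "CTA", "CTG")),
    "S": (("AGT", "AGC"), ("TCT", "TCC", "TCA", "TCG")),
    "R": (("AGA", "AGG"), ("CGT", "CGC", "CGA", "CGG")),
}


def _family_homozygosity(counts: list[int]) -> float | None:
    """F_hat for one family; None when undefined (family total < 2)."""
    n = sum(counts)
    if n < 2:
        return None
    s = sum((c / n) ** 2 for c in counts)
    return (n * s - 1.0) / (n - 1.0)


def effective_number_of_codons(
    table: CodonCountTable, split_sixfold: bool = False
) -> float:
    """Wright's ENC for a codon count table, clamped to [20, 61].

    Families with total count < 2 are excluded from the class means
    (F_hat is undefined at n = 1). An empty 3-fold class (Ile absent)
    is imputed as F_bar_3 = (F_bar_2 + F_bar_4) / 2; any other empty
    class drops out and the result is rescaled to the full 20-amino-acid
    basis. NaN when no class has a usable family.

    With ``split_sixfold=True`` the Leu/Ser/Arg families are split into
    their two- and four-fold codon boxes before classing (ENC then spans
    [20, 61] with class counts 2-fold: 12, 4-fold: 8).
    """
    if table.total == 0:
        raise ValueError("empty codon table")
    if split_sixfold:
        families: list[tuple[int, list[int]]] = []
        for aa, codons in SENSE_FAMILIES.items():
            if aa in ("M", "W"):
                continue
            if aa in _SPLIT_SIXFOLD:
                for box in _SPLIT_SIXFOLD[aa]:
                    families.append((len(box), [table.counts[c] for c in box]))
            else:
                families.append((len(codons), [table.counts[c] for c in codons]))
        class_sizes = {2: 12, 3: 1, 4: 8}
    else:
        families = [
            (len(codons), [table.counts[c] for c in codons])
            for aa, codons in SENSE_FAMILIES.items()
            if aa not in ("M", "W")
        ]
        class_sizes = dict(_CLASS_FAMILY_COUNT)

    f_by_class: dict[int, list[float]] = {k: [] for k in class_sizes}
    for k, counts in families:
        f = _family_homozygosity(counts)
        if f is not None:
            f_by_class[k].append(f)

    f_bar = {k: (sum(v) / len(v) if v else None) for k, v in f_by_class.items()}
    if (
        3 in f_bar
        and (f_bar[3] is None or f_bar[3] <= 0)
        and (f_bar.get(2) or 0) > 0
        and (f_bar.get(4) or 0) > 0
    ):
        # Ile absent or its homozygosity degenerate: impute from neighbours
        f_bar[3] = (f_bar[2] + f_bar[4]) / 2.0

    enc = 2.0
    aa_included = 2  # Met + Trp
    for k, n_fam in class_sizes.items():
        if f_bar.get(k) is None:
            continue
        if f_bar[k] <= 0:
            log.warning("non-positive mean homozygosity in class %d; skipped", k)
            continue
        enc += n_fam / f_bar[k]
        aa_included += n_fam
    if aa_included == 2:
        log.warning("no degeneracy class with a usable family; ENC undefined")
        return math.nan
    if aa_included < 20:
        enc *= 20.0 / aa_included
    return min(61.0, max(20.0, enc))


def expected_enc(gc3s: float) -> float:
    """ENC expected under mutation pressure alone at synonymous GC3 = s:

        ENC(s) = 2 + s + 29 / (s^2 + (1 - s)^2).
    """
    if not 0.0 < gc3s < 1.0:
        raise ValueError(f"gc3s must be in (0, 1), got {gc3s}")
    return 2.0 + gc3s + 29.0 / (gc3s**2 + (1.0 - gc3s) ** 2)


def relative_adaptiveness(reference: RscuTable) -> dict[str, float]:
    """w_j = RSCU_ref(j) / max RSCU_ref within the family, for the 59 codons.

    Codons with zero reference usage are floored at w = 0.01 (logged) so
    the geometric mean stays defined.
    """
    w: dict[str, float] = {}
    floored = []
    for aa, codons in AA_TO_CODONS.items():
        if aa in ("M", "W", "*"):
            continue
        top = max(reference.values[c] for c in codons)
        if top <= 0:
            for c in codons:
                w[c] = 1.0  # family absent from reference: uninformative
            continue
        for c in codons:
            val = reference.values[c] / top
            if val <= 0:
                val = 0.01
                floored.append(c)
            w[c] = val
    if floored:
        log.info("CAI weights floored at 0.01 for %d codons: %s", len(floored), floored)
    return w


def codon_adaptation_index(table: CodonCountTable, reference: RscuTable) -> float:
    """Geometric mean of relative adaptiveness over the gene's codons.

    Met, Trp and stop codons are excluded. NaN when the gene contains no
    eligible codon.
    """
    w = relative_adaptiveness(reference)
    log_sum = 0.0
    n = 0
    for codon, count in table.counts.items():
        if codon in NON_SYNONYMOUS_CODONS or count == 0:
            continue
        log_sum += count * math.log(w[codon])
        n += count
    if n == 0:
        return math.nan
    return math.exp(log_sum / n)


def cbi_fop(table: CodonCountTable, optimal: set[str]) -> tuple[float, float]:
    """Codon bias index and frequency of optimal codons.

    Both are computed over codons of amino acids possessing at least one
    optimal codon. Fop = N_opt / N_tot; CBI = (N_opt - N_rand) /
    (N_tot - N_rand) with N_rand the count expected under uniform
    within-family usage. Returns (NaN, NaN) when no codon is eligible.
    """
    if not optimal:
        raise ValueError("optimal codon set is empty")
    n_opt = 0
    n_tot = 0
    n_rand = 0.0
    for aa, codons in AA_TO_CODONS.items():
        k_i = sum(1 for c in codons if c in optimal)
        if k_i == 0:
            continue
        fam_total = sum(table.counts[c] for c in codons)
        if fam_total == 0:
            continue
        n_tot += fam_total
        n_opt += sum(table.counts[c] for c in codons if c in optimal)
        n_rand += fam_total * k_i / len(codons)
    if n_tot == 0:
        return math.nan, math.nan
    fop = n_opt / n_tot
    denom = n_tot - n_rand
    cbi = (n_opt - n_rand) / denom if denom else math.nan
    return cbi, fop


@dataclass
class GeneIndices:
    """Bundle of per-gene usage indices feeding the diagnostic plots."""

    gene_id: str
    enc: float
    gc: GcComposition
    l_aa: int
    cai: float = math.nan
    cbi: float = math.nan
    fop: float = math.nan

    @property
    def enc_expected(self) -> float:
        s = self.gc.gc3s
        if not (0.0 < s < 1.0) or math.isnan(s):
            return math.nan
        return expected_enc(s)


def gene_l_aa(table: CodonCountTable) -> int:
    """Encoded amino-acid count: codons minus the terminal stop."""
    stops = sum(table.counts[c] for c in AA_TO_CODONS["*"])
    return table.total - min(stops, 1)
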