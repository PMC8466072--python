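"""Genetic-code bookkeeping shared by every statistic in the package.

The plastid genetic code (NCBI translation table 11) is used throughout;
for the 61 sense and 3 stop assignments relevant here it coincides with
the standard code. Synonymous-family structure is derived once at import
time from Biopython's codon tables.

Stop codons are grouped as a single three-member "family" (labelled
``*``) so that termination-codon usage can participate in RSCU/RFSC,
high-frequency screening and the optimal-codon rule; composition and
bias indices (GC3s, ENC, CAI, PR2) exclude stops as well as the
non-degenerate Met and Trp codons.
"""

from __future__ import annotations

from itertools import product

from Bio.Data import CodonTable

BASES = ("T", "C", "A", "G")

#: All 64 codons in TCAG order (the order codon tables are conventionally printed).
CODONS: tuple[str, ...] = tuple("".join(p) for p in product(BASES, repeat=3))

_TABLE = CodonTable.unambiguous_dna_by_id[11]

#: Codon -> one-letter amino acid, with stops mapped to "*".
CODON_TO_AA: dict[str, str] = {c: _TABLE.forward_table[c] for c in _TABLE.forward_table}
for _stop in _TABLE.stop_codons:
    CODON_TO_AA[_stop] = "*"

STOP_CODONS: frozenset[str] = frozenset(_TABLE.stop_codons)
START_CODON = "ATG"

#: Amino acid -> tuple of synonymous codons (TCAG order). "*" is the stop family.
AA_TO_CODONS: dict[str, tuple[str, ...]] = {}
for _codon in CODONS:
    AA_TO_CODONS.setdefault(CODON_TO_AA[_codon], ())
    AA_TO_CODONS[CODON_TO_AA[_codon]] += (_codon,)

#: Family degeneracy n_i per amino acid (Met/Trp 1, stop family 3).
FAMILY_SIZE: dict[str, int] = {aa: len(cods) for aa, cods in AA_TO_CODONS.items()}

#: Codons excluded from synonymous third-position statistics:
#: Met (ATG) and Trp (TGG) are non-degenerate, stops do not encode residues.
NON_SYNONYMOUS_CODONS: frozenset[str] = frozenset({"ATG", "TGG"} | STOP_CODONS)

#: The 59 synonymously variable sense codons (64 minus ATG, TGG and 3 stops).
SYNONYMOUS_CODONS: tuple[str, ...] = tuple(
    c for c in CODONS if c not in NON_SYNONYMOUS_CODONS
)

#: Fourfold-degenerate codon boxes XY{T,C,A,G} whose four members are synonymous
#: (Sueoka's parity-rule-2 codon set): Leu-CTN, Val, Ser-TCN, Pro, Thr, Ala,
#: Arg-CGN and Gly.
FOURFOLD_BOXES: tuple[tuple[str, ...], ...] = tuple(
    tuple(pre + b for b in BASES)
    for pre in ("".join(p) for p in product(BASES, repeat=2))
    if len({CODON_TO_AA[pre + b] for b in BASES}) == 1
)
FOURFOLD_CODONS: frozenset[str] = frozenset(c for box in FOURFOLD_BOXES for c in box)

#: Ile codons, individually excludable from the neutrality-plot GC3 per the
#: convention this pipeline follows.
ILE_CODONS: frozenset[str] = frozenset(AA_TO_CODONS["I"])

#: Degeneracy classes for Wright's effective-number-of-codons estimator,
#: six-fold families (Leu, Ser, Arg) kept whole.
SENSE_FAMILIES: dict[str, tuple[str, ...]] = {
    aa: cods for aa, cods in AA_TO_CODONS.items() if aa != "*"
}


def is_valid_dna(seq: str) -> bool:
    """True if *seq* uses only the {A,C,G,T,N} alphabet."""
    return not set(seq) - set("ACGTN")


def codons_of(seq: str) -> list[str]:
    """Split an in-frame sequence into consecutive triplets (5'->3')."""
    if len(seq) % 3:
        raise ValueError(f"sequence length {len(seq)} is not a multiple of 3")
    return [seq[i : i + 3] for i in range(0, len(seq), 3)]
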