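import math

import numpy as np
import pytest

from cpcodon.cds_io import CdsRecord
from cpcodon.codon_stats import CodonCountTable, GcComposition
from cpcodon.genetic_code import AA_TO_CODONS, CODONS
from cpcodon.usage_indices import GeneIndices


def make_table(counts: dict[str, int], scope: str = "gene") -> CodonCountTable:
    return CodonCountTable(dict(counts), scope=scope)


def make_gc(
    gc1=0.5, gc2=0.5, gc3=0.5, gc3s=0.5, t3s=0.25, c3s=0.25, a3s=0.25, g3s=0.25
) -> GcComposition:
    return GcComposition(gc1, gc2, gc3, gc3s, t3s, c3s, a3s, g3s)


def make_indices(gene_id: str, enc: float = 50.0, **gc_kwargs) -> GeneIndices:
    return GeneIndices(gene_id=gene_id, enc=enc, gc=make_gc(**gc_kwargs), l_aa=100)


@pytest.fixture
def random_count_table():
    """Factory for seeded random 64-codon count tables."""

    def factory(seed: int, low: int = 0, high: int = 50) -> CodonCountTable:
        rng = np.random.default_rng(seed)
        counts = {c: int(rng.integers(low, high)) for c in CODONS}
        return CodonCountTable(counts)

    return factory


@pytest.fixture
def degenerate_table():
    """One codon per amino-acid family, used 10 times each (maximal bias)."""
    counts = {cods[0]: 10 for cods in AA_TO_CODONS.values()}
    return CodonCountTable(counts)


@pytest.fixture
def uniform_table():
    """Every sense codon used equally often (no bias; ~10^4 codons total)."""
    counts = {c: 170 for c in CODONS if c not in ("TAA", "TAG", "TGA")}
    return CodonCountTable(counts)


def valid_cds(n_sense_codons: int = 101, body_codon: str = "AAA") -> str:
    """A structurally valid CDS: ATG + n sense codons + TAA."""
    return "ATG" + body_codon * n_sense_codons + "TAA"


@pytest.fixture
def toy_genbank(tmp_path):
    """A hand-built two-record GenBank file with spliced/complemented CDS.

    The genome sequence is 60 bp; features:
      * gene fwd  : single exon 4..15
      * gene rc   : complement(join(10..18, 25..33))
    Returns (path, genome_sequence).
    """
    genome = "AAATGGCTGCTTAATTTCCCGGGATGATTATTTGATTTTTTCCCCGGGGAAAACCCCTT"
    genome = genome + "A" * (60 - len(genome))
    lines = [
        "LOCUS       TOY00001                  60 bp    DNA     linear   PLN 01-JAN-2000",
        "DEFINITION  toy chloroplast fragment.",
        "ACCESSION   TOY00001",
        "VERSION     TOY00001.1",
        "SOURCE      synthetic construct",
        "  ORGANISM  synthetic construct",
        "FEATURES             Location/Qualifiers",
        "     source          1..60",
        "     CDS             4..15",
        '                     /gene="fwd"',
        "     CDS             complement(join(10..18,25..33))",
        '                     /gene="rc"',
        "ORIGIN",
    ]
    for i in range(0, 60, 60):
        chunk = genome[i : i + 60]
        blocks = " ".join(chunk[j : j + 10] for j in range(0, len(chunk), 10))
        lines.append(f"{i + 1:>9} {blocks}")
    lines.append("//")
    path = tmp_path / "toy.gb"
    path.write_text("\n".join(lines) + "\n")
    return path, genome
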