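"""Reading and screening protein-coding sequences.

Annotated chloroplast genomes (GenBank flat files) or plain FASTA CDS
sets are turned into validated :class:`CdsRecord` lists. Screening
applies the four structural rules every downstream statistic assumes:
an ATG start, a canonical stop, no in-frame internal stop, and a length
that is a multiple of three and at least ``min_length`` (300 bp by
default). Records containing ambiguous bases are rejected outright.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO

from .genetic_code import STOP_CODONS, is_valid_dna

log = logging.getLogger(__name__)

#: Rejection reasons, checked in this fixed order; the first failure is recorded.
REASON_ORDER = (
    "AMBIGUOUS",
    "NOT_TRIPLET",
    "NO_START",
    "BAD_STOP",
    "INTERNAL_STOP",
    "TOO_SHORT",
)


@dataclass(frozen=True)
class CdsRecord:
    """One coding sequence with its identity and species label."""

    gene_id: str
    species_label: str
    sequence: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", self.sequence.upper())
        if not is_valid_dna(self.sequence):
            bad = sorted(set(self.sequence) - set("ACGTN"))
            raise ValueError(f"{self.gene_id}: non-DNA characters {bad}")

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class FilterReport:
    """Outcome of CDS screening: kept records, rejections and rule tallies."""

    kept: list[CdsRecord]
    rejected: list[tuple[str, str]]
    rule_counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.rule_counts:
            self.rule_counts = dict(Counter(reason for _, reason in self.rejected))

    @property
    def n_input(self) -> int:
        return len(self.kept) + len(self.rejected)

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("gene_id\tstatus\treason\n")
            for rec in self.kept:
                fh.write(f"{rec.gene_id}\tkept\t\n")
            for gene_id, reason in self.rejected:
                fh.write(f"{gene_id}\trejected\t{reason}\n")


def _cds_id(feature, index: int) -> str:
    for key in ("gene", "locus_tag", "protein_id"):
        if key in feature.qualifiers:
            return str(feature.qualifiers[key][0])
    return f"cds_{index}"


def read_cds(
    path: str | Path,
    format: str = "genbank",
    species_label: str | None = None,
) -> list[CdsRecord]:
    """Read CDS records from a GenBank or FASTA file.

    GenBank CDS features are extracted honoring their location strings:
    ``join`` splices exons and ``complement`` reverse-complements, so
    multi-exon and minus-strand genes come out 5'->3' in coding
    orientation. FASTA entries are taken as given, one record per entry.

    Parameters
    ----------
    path : file path
    format : {"genbank", "fasta"}
    species_label : label attached to every record; defaults to the
        organism annotation (GenBank) or the file stem (FASTA).
    """
    path = Path(path)
    if format not in ("genbank", "fasta"):
        raise ValueError(f"unknown format {format!r}")
    records: list[CdsRecord] = []
    if format == "fasta":
        label = species_label or path.stem
        for entry in SeqIO.parse(str(path), "fasta"):
            records.append(CdsRecord(entry.id, label, str(entry.seq)))
        return records
    index = 0
    for gb in SeqIO.parse(str(path), "genbank"):
        label = species_label or gb.annotations.get("organism", gb.id)
        for feature in gb.features:
            if feature.type != "CDS":
                continue
            index += 1
            gene_id = _cds_id(feature, index)
            try:
                seq = str(feature.extract(gb.seq))
            except Exception as exc:  # malformed location: skip, keep going
                log.warning("skipping %s: unparseable location (%s)", gene_id, exc)
                continue
            records.append(CdsRecord(gene_id, label, seq))
    return records


def classify(record: CdsRecord, min_length: int = 300) -> str | None:
    """Return the first failed screening rule, or None if the CDS passes."""
    seq = record.sequence
    if "N" in seq:
        return "AMBIGUOUS"
    if len(seq) % 3:
        return "NOT_TRIPLET"
    if not seq.startswith("ATG"):
        return "NO_START"
    if seq[-3:] not in STOP_CODONS:
        return "BAD_STOP"
    if any(seq[i : i + 3] in STOP_CODONS for i in range(0, len(seq) - 3, 3)):
        return "INTERNAL_STOP"
    if len(seq) < min_length:
        return "TOO_SHORT"
    return None


def filter_cds(records: Sequence[CdsRecord], min_length: int = 300) -> FilterReport:
    """Screen CDS records by the four structural rules.

    Kept records start with ATG, end with TAA/TAG/TGA, contain no
    in-frame internal stop, have length divisible by 3 and at least
    *min_length* bp. Each rejection records the first failed rule in
    the fixed order AMBIGUOUS, NOT_TRIPLET, NO_START, BAD_STOP,
    INTERNAL_STOP, TOO_SHORT.
    """
    if not records:
        raise ValueError("no CDS to filter")
    kept: list[CdsRecord] = []
    rejected: list[tuple[str, str]] = []
    for rec in records:
        reason = classify(rec, min_length)
        if reason is None:
            kept.append(rec)
        else:
            rejected.append((rec.gene_id, reason))
    return FilterReport(kept=kept, rejected=rejected)


def dedupe_identical(records: Iterable[CdsRecord]) -> list[CdsRecord]:
    """Drop exact duplicate (gene_id, sequence) pairs, keeping first occurrence.

    Chloroplast inverted repeats carry duplicated gene copies; whether to
    collapse them is a reporting choice, so this is a separate opt-in step.
    """
    seen: set[tuple[str, str]] = set()
    out: list[CdsRecord] = []
    for rec in records:
        key = (rec.gene_id, rec.sequence)
        if key not in seen:
            seen.add(key)
            out.append(rec)
    return out
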