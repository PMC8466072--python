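"""Heterologous-host codon-frequency comparison.

Usage is expressed as occurrences per 1000 codons (the layout of the
Kazusa codon usage database tables). A codon differs *significantly*
between a query species and a candidate expression host when the
frequency ratio is at least 2-fold in either direction (ratio >= 2 or
<= 0.5); the count of such codons over all 64 ranks candidate hosts.
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass
from pathlib import Path

from .codon_stats import CodonCountTable
from .genetic_code import CODONS

log = logging.getLogger(__name__)

_ROW_RE = re.compile(r"([ACGTU]{3})\s+(\d+(?:\.\d+)?)\s*(?:\(\s*(\d+(?:\.\d+)?)\s*\))?")


@dataclass
class FrequencyTable:
    """Codon usage in occurrences per 1000 codons."""

    freq: dict[str, float]
    source_label: str = ""

    def __post_init__(self) -> None:
        missing = set(CODONS) - set(self.freq)
        if missing:
            raise ValueError(f"missing codons: {sorted(missing)}")
        total = sum(self.freq.values())
        if abs(total - 1000.0) > 0.5:
            log.warning(
                "%s: frequencies sum to %.2f, not 1000", self.source_label, total
            )


@dataclass
class HostComparison:
    """Per-codon frequency ratios against one host and the significant tally."""

    query_label: str
    host_label: str
    freq_query: dict[str, float]
    freq_host: dict[str, float]
    ratio: dict[str, float]
    significant: set[str]

    @property
    def n_significant(self) -> int:
        return len(self.significant)

    @property
    def pct_significant(self) -> float:
        return 100.0 * self.n_significant / 64.0

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("codon\tfreq_query\tfreq_host\tratio\tsignificant\n")
            for codon in CODONS:
                r = self.ratio[codon]
                r_str = "inf" if math.isinf(r) else ("NA" if math.isnan(r) else f"{r:.6f}")
                fh.write(
                    f"{codon}\t{self.freq_query[codon]:.6f}\t"
                    f"{self.freq_host[codon]:.6f}\t{r_str}\t"
                    f"{int(codon in self.significant)}\n"
                )


def frequency_per_thousand(
    table: CodonCountTable, source_label: str = ""
) -> FrequencyTable:
    """Scale a 64-codon count table (stops included) to per-1000 usage."""
    total = table.total
    if total == 0:
        raise ValueError("empty codon table")
    freq = {c: 1000.0 * table.counts[c] / total for c in CODONS}
    return FrequencyTable(freq=freq, source_label=source_label)


def parse_host_table(text: str, source_label: str = "") -> FrequencyTable:
    """Parse a Kazusa-layout codon usage table.

    The expected layout is rows of ``CODON  freq-per-1000 ( count )``
    blocks, four codons per line, in either the RNA (U) or DNA (T)
    alphabet; U is mapped to T. All 64 codons must be present.
    """
    freq: dict[str, float] = {}
    for lineno, line in enumerate(text.splitlines(), start=1):
        stripped = line.strip()
        if not stripped:
            continue
        matches = list(_ROW_RE.finditer(stripped))
        if not matches and any(ch.isdigit() for ch in stripped):
            raise ValueError(f"malformed row at line {lineno}: {stripped!r}")
        for m in matches:
            codon = m.group(1).replace("U", "T")
            if codon in freq:
                raise ValueError(f"duplicate codon {codon} at line {lineno}")
            freq[codon] = float(m.group(2))
    missing = set(CODONS) - set(freq)
    if missing:
        raise ValueError(f"incomplete table; missing {sorted(missing)}")
    return FrequencyTable(freq=freq, source_label=source_label)


def read_host_table(path: str | Path) -> FrequencyTable:
    path = Path(path)
    return parse_host_table(path.read_text(), source_label=path.stem)


def compare_hosts(query: FrequencyTable, host: FrequencyTable) -> HostComparison:
    """Flag codons whose usage differs >= 2-fold between query and host.

    Ratios are reported query/host. A codon absent from the host but
    used by the query is flagged (ratio inf); absent from both is not
    (ratio NaN). The flag rule is symmetric under table exchange.
    """
    ratio: dict[str, float] = {}
    significant: set[str] = set()
    for codon in CODONS:
        q = query.freq[codon]
        h = host.freq[codon]
        if h == 0.0:
            r = math.inf if q > 0 else math.nan
            if q > 0:
                log.info("%s: absent from host %s", codon, host.source_label)
        else:
            r = q / h
        ratio[codon] = r
        if not math.isnan(r) and (r >= 2.0 or r <= 0.5):
            significant.add(codon)
    return HostComparison(
        query_label=query.source_label,
        host_label=host.source_label,
        freq_query=dict(query.freq),
        freq_host=dict(host.freq),
        ratio=ratio,
        significant=significant,
    )
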