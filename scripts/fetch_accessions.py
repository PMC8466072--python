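"""Download the seven pinned RefSeq chloroplast genomes from NCBI.

The analysis library only reads local files; this helper documents the
exact records the published chloroplast comparison used and fetches them
into ``data/accessions/`` so that the accession-reproduction checks in
``tests/test_acceptance.py`` can run. Requires network access.

Usage::

    python scripts/fetch_accessions.py [--out data/accessions]

Host codon-usage tables (Kazusa layout, for `cpcodon compare --hosts`)
are available from the Codon Usage Database, e.g.
http://www.kazusa.or.jp/codon/cgi-bin/showcodon.cgi?species=199310
(Escherichia coli), 4932 (S. cerevisiae), 3694 (P. trichocarpa),
3702 (A. thaliana); save the codon table block as plain text.
"""

from __future__ import annotations

import argparse
import time
import urllib.parse
import urllib.request
from pathlib import Path

ACCESSIONS = {
    "NC_035750.1": "Miscanthus floridulus",
    "NC_028720.1": "Miscanthus sacchariflorus",
    "NC_028721.1": "Miscanthus sinensis",
    "NC_035753.1": "Miscanthus x giganteus",
    "NC_035752.1": "Miscanthus transmorrisonensis",
    "NC_008602": "Sorghum bicolor",
    "NC_034802.1": "Saccharum spontaneum",
}

EFETCH = "https://eutils.ncbi.nlm.nih.gov/entrez/eutils/efetch.fcgi"


def fetch(accession: str, out_dir: Path) -> Path:
    params = urllib.parse.urlencode(
        {"db": "nuccore", "id": accession, "rettype": "gbwithparts", "retmode": "text"}
    )
    out = out_dir / f"{accession}.gb"
    with urllib.request.urlopen(f"{EFETCH}?{params}", timeout=120) as resp:
        out.write_bytes(resp.read())
    return out


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument(
        "--out", type=Path, default=Path(__file__).resolve().parent.parent / "data" / "accessions"
    )
    args = parser.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)
    for accession, species in ACCESSIONS.items():
        path = fetch(accession, args.out)
        print(f"{accession} ({species}) -> {path}")
        time.sleep(0.4)  # NCBI rate limit


if __name__ == "__main__":
    main()
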