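#!/usr/bin/env python
"""Fetch the deposited reference sequences used by the published-data tests.

Requires network access to NCBI/UniProt/RCSB; writes plain FASTA files
under ``data/reference/``. The test suite's published-characterization
tests fail with an explicit message until these files exist.

Records fetched:

* MH737701 — the cloned jellyfish transporter cDNA (GenBank, nuccore)
* QBP15011 — its 651-aa translation (GenBank, protein)
* A7RFF4 — Nematostella vectensis homolog (UniProt)
* A0A2B45J71 — Stylophora pistillata homolog (UniProt)
* LeuT_2A65 — Aquifex aeolicus LeuT chain A (RCSB, PDB 2A65)
* SERT_NP_001036 — human serotonin transporter (RefSeq NP_001036.1)
"""

from __future__ import annotations

import sys
import urllib.request
from pathlib import Path

OUT = Path(__file__).resolve().parent.parent / "data" / "reference"

EUTILS = "https://eutils.ncbi.nlm.nih.gov/entrez/eutils/efetch.fcgi"
TARGETS = {
    "MH737701.fasta":
        f"{EUTILS}?db=nuccore&id=MH737701&rettype=fasta&retmode=text",
    "QBP15011.fasta":
        f"{EUTILS}?db=protein&id=QBP15011&rettype=fasta&retmode=text",
    "SERT_NP_001036.fasta":
        f"{EUTILS}?db=protein&id=NP_001036.1&rettype=fasta&retmode=text",
    "A7RFF4.fasta": "https://rest.uniprot.org/uniprotkb/A7RFF4.fasta",
    "A0A2B45J71.fasta":
        "https://rest.uniprot.org/uniprotkb/A0A2B45J71.fasta",
    "LeuT_2A65.fasta": "https://www.rcsb.org/fasta/entry/2A65",
}


def main() -> int:
    OUT.mkdir(parents=True, exist_ok=True)
    failures = 0
    for name, url in TARGETS.items():
        dest = OUT / name
        if dest.exists():
            print(f"{name}: already present")
            continue
        try:
            with urllib.request.urlopen(url, timeout=60) as resp:
                text = resp.read().decode()
        except Exception as exc:  # noqa: BLE001
            print(f"{name}: FAILED ({exc})")
            failures += 1
            continue
        if not text.startswith(">"):
            print(f"{name}: unexpected response, skipped")
            failures += 1
            continue
        if name == "LeuT_2A65.fasta":
            # keep only the first chain record
            first = text.split("\n>")[0]
            text = first if first.startswith(">") else ">" + first
        dest.write_text(text if text.endswith("\n") else text + "\n")
        print(f"{name}: ok ({len(text)} bytes)")
    return 1 if failures else 0


if __name__ == "__main__":
    sys.exit(main())
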