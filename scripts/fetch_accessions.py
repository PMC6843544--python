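#!/usr/bin/env python
"""Download HKT1;5 sequence accessions from NCBI (network required).

Convenience helper only — no part of the package or its tests depends on
it.  Writes one FASTA per database ('protein', 'nucleotide').

Usage:
    python scripts/fetch_accessions.py --email you@example.org \
        --protein AFY08293.1 XP_015631953.1 AMY98961.1 --out data/
"""

from __future__ import annotations

import argparse
from pathlib import Path

from Bio import Entrez, SeqIO


def fetch(db: str, accessions: list[str], out: Path) -> None:
    handle = Entrez.efetch(db=db, id=",".join(accessions), rettype="fasta", retmode="text")
    records = list(SeqIO.parse(handle, "fasta"))
    out.parent.mkdir(parents=True, exist_ok=True)
    SeqIO.write(records, str(out), "fasta")
    print(f"{len(records)} {db} records -> {out}")


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--email", required=True, help="NCBI Entrez contact email")
    parser.add_argument("--protein", nargs="*", default=[])
    parser.add_argument("--nucleotide", nargs="*", default=[])
    parser.add_argument("--out", type=Path, default=Path("data"))
    args = parser.parse_args()

    Entrez.email = args.email
    if args.protein:
        fetch("protein", args.protein, args.out / "proteins.fasta")
    if args.nucleotide:
        fetch("nucleotide", args.nucleotide, args.out / "nucleotides.fasta")


if __name__ == "__main__":
    main()
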