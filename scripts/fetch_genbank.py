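#!/usr/bin/env python
"""Fetch the deposited control-region sequences from GenBank (convenience).

Downloads accessions MT339714-MT340074 via NCBI Entrez, splits them by
organism into the two study species, and writes per-species FASTA files
under ``data/empirical/``.  The downloaded sequences are *unaligned*;
align each species (e.g. ``mafft --auto``) and trim to the study's locus
lengths before computing statistics against them.

Requires network access and an e-mail address for Entrez::

    python scripts/fetch_genbank.py --email you@example.org
"""

from __future__ import annotations

import argparse
from pathlib import Path

from Bio import Entrez, SeqIO


def accession_range(start: str = "MT339714", stop: str = "MT340074") -> list[str]:
    prefix = start[:2]
    lo, hi = int(start[2:]), int(stop[2:])
    return [f"{prefix}{i}" for i in range(lo, hi + 1)]


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--email", required=True, help="Entrez contact e-mail")
    parser.add_argument(
        "--outdir", type=Path,
        default=Path(__file__).resolve().parent.parent / "data" / "empirical",
    )
    args = parser.parse_args()
    Entrez.email = args.email

    accs = accession_range()
    args.outdir.mkdir(parents=True, exist_ok=True)
    by_species: dict[str, list] = {"maculatus": [], "platei": []}
    chunk = 100
    for i in range(0, len(accs), chunk):
        handle = Entrez.efetch(
            db="nucleotide", id=",".join(accs[i : i + chunk]),
            rettype="fasta", retmode="text",
        )
        for rec in SeqIO.parse(handle, "fasta"):
            for key in by_species:
                if key in rec.description:
                    by_species[key].append(rec)
        handle.close()

    for key, records in by_species.items():
        out = args.outdir / f"{key}.raw.fasta"
        SeqIO.write(records, out, "fasta")
        print(f"{key}: {len(records)} sequences -> {out}")
    print(
        "Align each file (e.g. mafft --auto) and save as "
        f"{args.outdir}/maculatus.fasta and {args.outdir}/platei.fasta"
    )


if __name__ == "__main__":
    main()
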