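#!/usr/bin/env python
"""Download PDB entries listed in an accession manifest (network required).

Usage:
    python scripts/fetch_pdb.py --manifest docs/accessions.tsv --out scratch/pdb/

The manifest is a TSV with columns: pdb_id, ligand, chain (optional),
residue_seq (optional), group.  Files are fetched from the RCSB download
service as uncompressed .pdb text.  See docs/benchmark_walkthrough.md for
how to assemble the manifest for the benchmark sets.
"""

from __future__ import annotations

import argparse
import sys
import urllib.request
from pathlib import Path

RCSB_URL = "https://files.rcsb.org/download/{pdb_id}.pdb"


def main() -> int:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--manifest", type=Path, required=True)
    parser.add_argument("--out", type=Path, required=True)
    args = parser.parse_args()

    args.out.mkdir(parents=True, exist_ok=True)
    lines = args.manifest.read_text().splitlines()
    header = lines[0].split("\t")
    idx = header.index("pdb_id")
    failures = []
    for line in lines[1:]:
        if not line.strip() or line.startswith("#"):
            continue
        pdb_id = line.split("\t")[idx].strip().lower()
        dest = args.out / f"{pdb_id}.pdb"
        if dest.exists():
            continue
        try:
            urllib.request.urlretrieve(RCSB_URL.format(pdb_id=pdb_id), dest)
            print(f"fetched {pdb_id}", file=sys.stderr)
        except Exception as err:  # entries do get withdrawn from the PDB
            failures.append(pdb_id)
            print(f"FAILED  {pdb_id}: {err}", file=sys.stderr)
    if failures:
        print(f"{len(failures)} entries unavailable: {failures}", file=sys.stderr)
    return 0


if __name__ == "__main__":
    raise SystemExit(main())
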