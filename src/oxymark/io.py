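"""Format I/O helpers: FASTA, BED, TSV tables and the JSON run manifest.

All genomic coordinates are 0-based, half-open; BED output is BED6 with a
mandatory strand column. Tables are tab-separated with a header row.
"""

from __future__ import annotations

import hashlib
import json
import os
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "read_fasta",
    "write_fasta",
    "write_bed",
    "read_bed",
    "write_tsv",
    "read_tsv",
    "file_sha256",
    "write_manifest",
]


def read_fasta(path: str) -> dict[str, str]:
    """Read a FASTA file into an ordered ``{id: sequence}`` mapping."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(path, "fasta")}


def write_fasta(path: str, records: Iterable[tuple[str, str]]) -> None:
    seqrecs = (SeqRecord(Seq(seq), id=name, description="") for name, seq in records)
    SeqIO.write(seqrecs, path, "fasta")


def write_bed(path: str, intervals: Iterable[tuple]) -> None:
    """Write BED6 rows: (chrom, start, end, name, score, strand)."""
    with open(path, "w") as fh:
        for row in intervals:
            chrom, start, end, name, score, strand = row
            fh.write(f"{chrom}\t{start}\t{end}\t{name}\t{score}\t{strand}\n")


def read_bed(path: str) -> list[tuple[str, int, int, str, float, str]]:
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            name = parts[3] if len(parts) > 3 else "."
            score = float(parts[4]) if len(parts) > 4 and parts[4] != "." else 0.0
            strand = parts[5] if len(parts) > 5 else "."
            out.append((chrom, start, end, name, score, strand))
    return out


def write_tsv(path: str, frame: pd.DataFrame, index: bool = False) -> None:
    frame.to_csv(path, sep="\t", index=index)


def read_tsv(path: str, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", **kwargs)


def file_sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(
    outdir: str,
    config: Mapping,
    seed: int | None,
    files: Sequence[str],
    name: str = "manifest.json",
) -> str:
    """Write a JSON run manifest: config echo, seed, and per-file content hashes.

    Re-running with the manifest's config and seed must reproduce the hashes.
    """
    import oxymark

    manifest = {
        "package": "oxymark",
        "version": oxymark.__version__,
        "seed": seed,
        "config": dict(config),
        "files": {
            os.path.relpath(f, outdir): file_sha256(f) for f in files if os.path.exists(f)
        },
    }
    path = os.path.join(outdir, name)
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
    return path
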