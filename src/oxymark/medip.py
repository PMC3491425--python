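"""meDIP-seq per-contig counting, RPKM normalization and vegetative-subtracted
signal.

The two-step normalization: (1) per-library reads are scaled for sequencing
depth and contig length (RPKM); (2) the vegetative library's RPKM for the
same antibody is subtracted from the 46 h value, removing antibody
cross-reactivity to unmodified cytosine and bead background. The residual is
the "signal" for that antibody. Cohort thresholds are quoted in reads, so a
depth-normalized raw-count difference ("excess reads") is carried alongside
the RPKM signal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import pysam

from .errors import InputError, PairingError, ParseError, ReferenceMismatchError

__all__ = [
    "LibraryCounts",
    "count_reads",
    "compute_rpkm",
    "compute_signal",
    "build_signal_table",
    "map_reads_exact",
    "write_sam",
]

SIGNAL_COLUMNS = [
    "contig",
    "length",
    "rpkm_igg_veg",
    "rpkm_igg_46h",
    "rpkm_mc_veg",
    "rpkm_mc_46h",
    "rpkm_hmc_veg",
    "rpkm_hmc_46h",
    "signal_mc",
    "signal_hmc",
    "signal_igg",
    "excess_mc",
    "excess_hmc",
]


@dataclass
class LibraryCounts:
    """Per-contig primary-alignment counts for one IP library."""

    library_id: str
    antibody: str  # 'IgG' | 'mC' | 'hmC'
    timepoint: str  # 'veg' | '46h'
    counts: pd.Series  # index: contig
    total_mapped: int
    lengths: pd.Series  # index: contig, bp

    def __post_init__(self):
        self.counts = self.counts.astype(int)
        if (self.counts < 0).any():
            raise InputError("negative read count")
        if int(self.counts.sum()) > self.total_mapped:
            raise InputError("per-contig counts exceed total_mapped")
        missing = set(self.counts.index) - set(self.lengths.index)
        if missing:
            raise ReferenceMismatchError(
                f"counted contigs missing from FASTA index: {sorted(missing)[:5]}"
            )

    def rpkm(self) -> pd.Series:
        if self.total_mapped <= 0:
            return pd.Series(0.0, index=self.counts.index)
        lens = self.lengths.reindex(self.counts.index)
        return self.counts / (lens / 1e3) / (self.total_mapped / 1e6)


def count_reads(
    path: str,
    lengths: pd.Series,
    library_id: str,
    antibody: str,
    timepoint: str,
) -> LibraryCounts:
    """Count primary alignments per contig from a SAM file or a TSV table.

    SAM: unmapped, secondary and supplementary records are excluded; a contig
    absent from the FASTA index raises :class:`ReferenceMismatchError`. TSV:
    two columns ``contig<TAB>count`` and a ``#total=N`` header line.
    """
    if path.endswith((".sam", ".bam")):
        counts = pd.Series(0, index=lengths.index, dtype=int)
        total = 0
        with pysam.AlignmentFile(path, check_sq=False) as sam:
            for rec in sam:
                if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                    continue
                contig = rec.reference_name
                if contig not in lengths.index:
                    raise ReferenceMismatchError(
                        f"contig {contig!r} in SAM absent from FASTA index"
                    )
                counts[contig] += 1
                total += 1
        return LibraryCounts(library_id, antibody, timepoint, counts, total, lengths)

    counts = pd.Series(0, index=lengths.index, dtype=int)
    total = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#total="):
                total = int(line.split("=", 1)[1])
                continue
            if line.startswith("#") or line.lower().startswith("contig\t"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ParseError(f"{path}:{lineno}: expected 'contig<TAB>count'")
            contig, value = parts
            if contig not in lengths.index:
                raise ReferenceMismatchError(
                    f"{path}:{lineno}: contig {contig!r} absent from FASTA index"
                )
            try:
                counts[contig] = int(value)
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: bad count {value!r}") from exc
    if total is None:
        total = int(counts.sum())
    return LibraryCounts(library_id, antibody, timepoint, counts, total, lengths)


def compute_rpkm(count: float, contig_length_bp: float, total_mapped: float) -> float:
    """Reads per kilobase of contig per million mapped reads."""
    if contig_length_bp <= 0:
        raise InputError(f"contig length must be positive, got {contig_length_bp}")
    if total_mapped <= 0:
        raise InputError(f"total mapped reads must be positive, got {total_mapped}")
    return count / (contig_length_bp / 1e3) / (total_mapped / 1e6)


def _round_half_away(x: np.ndarray) -> np.ndarray:
    return np.sign(x) * np.floor(np.abs(x) + 0.5)


def compute_signal(
    table_46h: LibraryCounts, table_veg: LibraryCounts, antibody: str | None = None
) -> pd.DataFrame:
    """Vegetative-subtracted signal for one antibody.

    ``signal`` is the per-contig RPKM difference (46 h minus vegetative; may
    be negative and is not clamped). ``excess_reads`` is the depth-normalized
    raw-count difference ``count_46h - count_veg * (total_46h / total_veg)``,
    rounded half away from zero.
    """
    if antibody is None:
        antibody = table_46h.antibody
    if table_46h.antibody != table_veg.antibody or table_46h.antibody != antibody:
        raise PairingError(
            f"antibody mismatch: {table_46h.antibody} (46h) vs {table_veg.antibody} (veg)"
        )
    if set(table_46h.counts.index) != set(table_veg.counts.index):
        raise PairingError("contig sets differ between the 46h and vegetative libraries")
    idx = table_46h.counts.index
    r46, rveg = table_46h.rpkm(), table_veg.rpkm().reindex(idx)
    scale = table_46h.total_mapped / table_veg.total_mapped
    excess = _round_half_away(
        table_46h.counts.to_numpy(float) - table_veg.counts.reindex(idx).to_numpy(float) * scale
    ).astype(int)
    return pd.DataFrame(
        {
            "contig": idx,
            "rpkm_46h": r46.to_numpy(),
            "rpkm_veg": rveg.to_numpy(),
            "signal": (r46 - rveg).to_numpy(),
            "excess_reads": excess,
        }
    ).set_index("contig")


def build_signal_table(libraries: dict[tuple[str, str], LibraryCounts]) -> pd.DataFrame:
    """Assemble the full per-contig signal table from six libraries.

    ``libraries`` maps (antibody, timepoint) to counts for all of IgG/mC/hmC
    at veg and 46h. Output columns follow ``SIGNAL_COLUMNS`` with the contig
    as index.
    """
    needed = {(ab, tp) for ab in ("IgG", "mC", "hmC") for tp in ("veg", "46h")}
    missing = needed - set(libraries)
    if missing:
        raise PairingError(f"missing libraries: {sorted(missing)}")
    any_lib = libraries[("IgG", "veg")]
    idx = any_lib.counts.index
    out = pd.DataFrame(index=idx)
    out.index.name = "contig"
    out["length"] = any_lib.lengths.reindex(idx)
    key = {"IgG": "igg", "mC": "mc", "hmC": "hmc"}
    for ab in ("IgG", "mC", "hmC"):
        for tp in ("veg", "46h"):
            out[f"rpkm_{key[ab]}_{tp}"] = libraries[(ab, tp)].rpkm().reindex(idx)
    for ab in ("IgG", "mC", "hmC"):
        sig = compute_signal(libraries[(ab, "46h")], libraries[(ab, "veg")])
        out[f"signal_{key[ab]}"] = sig["signal"].reindex(idx)
        if ab != "IgG":
            out[f"excess_{key[ab]}"] = sig["excess_reads"].reindex(idx)
    return out[SIGNAL_COLUMNS[1:]]


# ---------------------------------------------------------------------------
# naive exact matcher for synthetic reads (not a general-purpose aligner)
# ---------------------------------------------------------------------------

def map_reads_exact(
    reads: list[tuple[str, str]], sequences: dict[str, str], seed_len: int = 20
) -> list[tuple[str, str | None, int]]:
    """Map reads by exact substring match against the supplied contigs.

    A seed index of all ``seed_len``-mers locates candidates; the full read
    must match exactly. Returns ``(read_id, contig_or_None, 0-based start)``;
    ties resolve to the first indexed occurrence. Only suitable for
    error-free synthetic reads.
    """
    index: dict[str, tuple[str, int]] = {}
    for cid, seq in sequences.items():
        for i in range(len(seq) - seed_len + 1):
            index.setdefault(seq[i : i + seed_len], (cid, i))
    out = []
    for rid, read in reads:
        hit = index.get(read[:seed_len])
        placed = None
        if hit is not None:
            cid, i = hit
            if sequences[cid][i : i + len(read)] == read:
                placed = (cid, i)
        if placed is None:
            # fall back to a scan (seed position may not be the leftmost match)
            for cid, seq in sequences.items():
                j = seq.find(read)
                if j >= 0:
                    placed = (cid, j)
                    break
        if placed is None:
            out.append((rid, None, -1))
        else:
            out.append((rid, placed[0], placed[1]))
    return out


def write_sam(
    path: str,
    mapped: list[tuple[str, str | None, int]],
    reads: dict[str, str],
    lengths: pd.Series,
) -> None:
    """Write exact-match placements as a minimal single-end SAM file."""
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": str(c), "LN": int(l)} for c, l in lengths.items()],
    }
    ref_ids = {str(c): i for i, c in enumerate(lengths.index)}
    with pysam.AlignmentFile(path, "w", header=header) as sam:
        for rid, contig, start in mapped:
            rec = pysam.AlignedSegment(sam.header)
            rec.query_name = rid
            rec.query_sequence = reads[rid]
            if contig is None:
                rec.is_unmapped = True
            else:
                rec.reference_id = ref_ids[contig]
                rec.reference_start = start
                rec.mapping_quality = 60
                rec.cigarstring = f"{len(reads[rid])}M"
            sam.write(rec)
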