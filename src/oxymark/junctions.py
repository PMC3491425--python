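"""Rearrangement-product annotation against a scrambled germline locus map.

In stichotrichous ciliates a macronuclear (MAC) gene is assembled from
micronuclear (MIC) Macronuclear Destined Segments (MDSs) that may lie in
scrambled order and orientation, separated by Internal Eliminated Sequences
(IESs). Adjacent-in-MAC MDSs share a short direct repeat (the "pointer") that
is retained as a single copy after joining. Aberrant products delete normally
retained DNA between short 3-4 bp microhomologies ("cryptic pointers")
without reordering segments.

This module validates a locus map, tiles a product sequence back onto the MIC
locus by greedy maximal exact matching, extracts the pointer at every
junction, and classifies each junction and product as programmed or aberrant.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field

from .errors import MapError, ProductMapError

__all__ = [
    "MdsSegment",
    "ScrambledLocusMap",
    "Segment",
    "JunctionCall",
    "revcomp",
    "validate_map",
    "tile_product",
    "find_junctions",
    "classify_product",
    "read_locus_map_json",
    "write_locus_map_json",
]

_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclass(frozen=True)
class MdsSegment:
    """One MDS: MIC interval (0-based half-open) and orientation in the MAC."""

    index: int  # MAC-order index, 1-based as in locus diagrams
    mic_start: int
    mic_end: int
    orientation: str  # '+' or '-'

    def mac_sense_seq(self, mic_sequence: str) -> str:
        s = mic_sequence[self.mic_start : self.mic_end]
        return revcomp(s) if self.orientation == "-" else s


@dataclass
class ScrambledLocusMap:
    """A scrambled locus: MIC sequence, MAC-ordered MDS list and pointers.

    ``mds_list`` is ordered by MAC position. ``programmed_pointers[i]`` is the
    pointer shared by MDS i and MDS i+1 (the MAC-sense suffix of the former
    and prefix of the latter); it may be left empty and derived by
    :func:`validate_map`.
    """

    mic_sequence: str
    mds_list: list[MdsSegment]
    programmed_pointers: list[str] = field(default_factory=list)

    @property
    def ies_list(self) -> list[tuple[int, int]]:
        """MIC intervals not covered by any MDS (complement intervals)."""
        covered = sorted((m.mic_start, m.mic_end) for m in self.mds_list)
        out, pos = [], 0
        for start, end in covered:
            if start > pos:
                out.append((pos, start))
            pos = max(pos, end)
        if pos < len(self.mic_sequence):
            out.append((pos, len(self.mic_sequence)))
        return out

    def mac_sequence(self) -> str:
        """Splice MDSs in MAC order, joining at single pointer copies."""
        parts = [self.mds_list[0].mac_sense_seq(self.mic_sequence)]
        for i in range(1, len(self.mds_list)):
            seg = self.mds_list[i].mac_sense_seq(self.mic_sequence)
            parts.append(seg[len(self.programmed_pointers[i - 1]) :])
        return "".join(parts)


def _max_overlap(left: str, right: str) -> str:
    """Longest string that is both a suffix of ``left`` and a prefix of ``right``."""
    kmax = min(len(left), len(right))
    for k in range(kmax, 0, -1):
        if left[-k:] == right[:k]:
            return left[-k:]
    return ""


def validate_map(locus_map: ScrambledLocusMap) -> ScrambledLocusMap:
    """Check map invariants; derive programmed pointers when absent.

    Raises :class:`MapError` on out-of-bounds MDS coordinates, on same-strand
    MDS overlaps that are not pointer overlaps, or when a stated pointer
    disagrees with the pointer derived from the coordinates.
    """
    n = len(locus_map.mic_sequence)
    for mds in locus_map.mds_list:
        if not (0 <= mds.mic_start < mds.mic_end <= n):
            raise MapError(
                f"MDS {mds.index} interval [{mds.mic_start}, {mds.mic_end}) "
                f"outside MIC sequence of length {n}"
            )
        if mds.orientation not in "+-":
            raise MapError(f"MDS {mds.index}: bad orientation {mds.orientation!r}")
    # same-strand overlap check: allow at most pointer-sized overlaps
    by_strand: dict[str, list[MdsSegment]] = {"+": [], "-": []}
    for mds in locus_map.mds_list:
        by_strand[mds.orientation].append(mds)
    for strand, group in by_strand.items():
        group = sorted(group, key=lambda m: m.mic_start)
        for a, b in zip(group, group[1:]):
            overlap = a.mic_end - b.mic_start
            if overlap > 0 and overlap >= min(a.mic_end - a.mic_start, b.mic_end - b.mic_start):
                raise MapError(
                    f"MDS {a.index} and MDS {b.index} overlap by {overlap} bp on "
                    f"strand {strand}: not a pointer overlap"
                )
    derived: list[str] = []
    for left, right in zip(locus_map.mds_list, locus_map.mds_list[1:]):
        ptr = _max_overlap(
            left.mac_sense_seq(locus_map.mic_sequence),
            right.mac_sense_seq(locus_map.mic_sequence),
        )
        if not ptr:
            raise MapError(
                f"MDS {left.index} -> MDS {right.index}: no shared pointer "
                "(adjacent MAC-order MDSs must overlap by >= 1 bp)"
            )
        derived.append(ptr)
    if locus_map.programmed_pointers:
        for i, (stated, got) in enumerate(zip(locus_map.programmed_pointers, derived)):
            if stated != got:
                pair = (locus_map.mds_list[i].index, locus_map.mds_list[i + 1].index)
                raise MapError(
                    f"MDS {pair[0]} -> MDS {pair[1]}: stated pointer {stated!r} "
                    f"differs from derived {got!r}"
                )
    locus_map.programmed_pointers = derived
    return locus_map


@dataclass(frozen=True)
class Segment:
    """A tiled product segment: product interval, MIC interval, orientation."""

    product_start: int
    product_end: int
    mic_start: int
    mic_end: int
    orientation: str
    mds_index: int | None  # MAC-order index of the best-overlapping MDS
    mds_order: int | None  # 0-based rank of that MDS in the MAC order


@dataclass(frozen=True)
class JunctionCall:
    product_id: str
    left: Segment
    right: Segment
    pointer_sequence: str
    pointer_length: int
    junction_class: str  # 'programmed' | 'cryptic'
    order_preserved: bool


def _longest_match_at(product: str, p: int, mic_f: str, mic_r: str) -> tuple[int, int, str]:
    """Longest exact match of ``product[p:]`` in the locus (either strand).

    Returns (length, mic_start_forward_frame, orientation); length 0 if none.
    Ties between strands go to the forward strand; within a strand, to the
    leftmost occurrence (``str.find``).
    """
    n = len(product) - p
    lo, hi = 0, n  # invariant: product[p:p+lo] occurs; product[p:p+hi+1] may not
    best = (0, -1, "+")

    def occurs(k: int) -> tuple[int, str] | None:
        sub = product[p : p + k]
        i = mic_f.find(sub)
        if i >= 0:
            return i, "+"
        i = mic_r.find(sub)
        if i >= 0:
            return len(mic_f) - (i + k), "-"
        return None

    # binary search on match length (occurrence of a prefix is monotone)
    while lo < hi:
        mid = (lo + hi + 1) // 2
        if occurs(mid) is not None:
            lo = mid
        else:
            hi = mid - 1
    if lo > 0:
        where = occurs(lo)
        assert where is not None
        best = (lo, where[0], where[1])
    return best


def _assign_mds(seg_start: int, seg_end: int, locus_map: ScrambledLocusMap) -> tuple[int | None, int | None]:
    best, best_ov = None, 0
    for order, mds in enumerate(locus_map.mds_list):
        ov = min(seg_end, mds.mic_end) - max(seg_start, mds.mic_start)
        if ov > best_ov:
            best, best_ov = order, ov
    if best is None:
        return None, None
    return locus_map.mds_list[best].index, best


def tile_product(
    product_sequence: str,
    locus_map: ScrambledLocusMap,
    min_seed: int = 20,
) -> list[Segment]:
    """Greedy maximal exact-match tiling of a product onto the MIC locus.

    Scans left to right; at each position takes the longest exact match to the
    MIC sequence (either orientation). Raises :class:`ProductMapError` when no
    segment of at least ``min_seed`` bp matches. Emits a warning when more
    than 5% of product bases remain uncovered.
    """
    import warnings

    mic_f = locus_map.mic_sequence
    mic_r = revcomp(mic_f)
    segments: list[Segment] = []
    p, uncovered = 0, 0
    while p < len(product_sequence):
        length, mstart, orient = _longest_match_at(product_sequence, p, mic_f, mic_r)
        if length < min_seed:
            uncovered += 1
            p += 1
            continue
        idx, order = _assign_mds(mstart, mstart + length, locus_map)
        segments.append(
            Segment(p, p + length, mstart, mstart + length, orient, idx, order)
        )
        p += length
    if not segments:
        raise ProductMapError(
            f"no segment of >= {min_seed} bp matches the locus: product not from locus"
        )
    if uncovered > 0.05 * len(product_sequence):
        warnings.warn(
            f"tiling incomplete: {uncovered} of {len(product_sequence)} product bases uncovered",
            stacklevel=2,
        )
    return segments


def _mic_prefix_context(seg: Segment, k: int, mic_f: str) -> str | None:
    """The k bases immediately preceding ``seg`` in MAC sense, from the MIC."""
    if seg.orientation == "+":
        if seg.mic_start - k < 0:
            return None
        return mic_f[seg.mic_start - k : seg.mic_start]
    if seg.mic_end + k > len(mic_f):
        return None
    return revcomp(mic_f[seg.mic_end : seg.mic_end + k])


def find_junctions(
    segments: list[Segment],
    locus_map: ScrambledLocusMap,
    product_sequence: str,
    product_id: str = "product",
) -> list[JunctionCall]:
    """Extract the pointer at each adjacent segment pair and classify it.

    The pointer is the maximal string that is simultaneously a suffix of the
    left segment's MIC match and the MIC context immediately preceding the
    right segment's match (MAC sense), spanning the product junction as a
    single retained copy. A junction is programmed iff the two MDSs are
    adjacent in MAC order and the pointer equals the map's programmed pointer;
    otherwise it is cryptic (a zero-length microhomology is a blunt cryptic
    join).
    """
    mic_f = locus_map.mic_sequence
    starts = [s.mic_start for s in segments]
    order_preserved = all(a < b for a, b in zip(starts, starts[1:])) or all(
        a > b for a, b in zip(starts, starts[1:])
    )
    calls: list[JunctionCall] = []
    for left, right in zip(segments, segments[1:]):
        e = left.product_end
        kmax = min(left.product_end - left.product_start, e)
        k = 0
        while k < kmax:
            ctx = _mic_prefix_context(right, k + 1, mic_f)
            if ctx is None or ctx != product_sequence[e - (k + 1) : e]:
                break
            k += 1
        pointer = product_sequence[e - k : e] if k else ""
        programmed = False
        if left.mds_order is not None and right.mds_order is not None:
            if right.mds_order == left.mds_order + 1:
                programmed = pointer == locus_map.programmed_pointers[left.mds_order]
            elif right.mds_order == left.mds_order - 1:
                # product annotated in reverse-complement orientation
                programmed = pointer == revcomp(
                    locus_map.programmed_pointers[right.mds_order]
                )
        calls.append(
            JunctionCall(
                product_id=product_id,
                left=left,
                right=right,
                pointer_sequence=pointer,
                pointer_length=k,
                junction_class="programmed" if programmed else "cryptic",
                order_preserved=order_preserved,
            )
        )
    return calls


def classify_product(junctions: list[JunctionCall]) -> tuple[str, dict]:
    """Classify a product as correct or aberrant and summarize cryptic pointers.

    A product is aberrant iff any of its junctions is cryptic (a missing
    programmed junction surfaces as a cryptic one, since either the MDS pair
    is non-adjacent in MAC order or the pointer differs).
    """
    cryptic = [j for j in junctions if j.junction_class == "cryptic"]
    summary = {
        "n_junctions": len(junctions),
        "n_cryptic": len(cryptic),
        "cryptic_pointer_lengths": dict(Counter(j.pointer_length for j in cryptic)),
    }
    return ("aberrant" if cryptic else "correct"), summary


def write_locus_map_json(locus_map: ScrambledLocusMap, path: str) -> None:
    payload = {
        "mic_sequence": locus_map.mic_sequence,
        "mds_list": [
            {
                "index": m.index,
                "mic_start": m.mic_start,
                "mic_end": m.mic_end,
                "orientation": m.orientation,
            }
            for m in locus_map.mds_list
        ],
        "programmed_pointers": locus_map.programmed_pointers,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)


def read_locus_map_json(path: str) -> ScrambledLocusMap:
    with open(path) as fh:
        payload = json.load(fh)
    return validate_map(
        ScrambledLocusMap(
            mic_sequence=payload["mic_sequence"],
            mds_list=[MdsSegment(**m) for m in payload["mds_list"]],
            programmed_pointers=payload.get("programmed_pointers", []),
        )
    )
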