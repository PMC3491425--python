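"""All-context bisulfite methylation calling from clone sequences.

Bisulfite deaminates unmethylated cytosine to uracil (read as thymine);
methylated and hydroxymethylated cytosines both resist conversion and cannot
be told apart. A clone from the forward template therefore shows C-to-T
substitutions at unmethylated cytosines, while a reverse-template clone
shows G-to-A substitutions in the forward frame. Clones are globally aligned
to the reference with bisulfite-aware scoring, the template strand is chosen
by mismatch minimization, and per-cytosine calls are made in every sequence
context (CpG, CpHpG, CpHpH), with primer-interval masking, skip-run
statistics and a conversion-control QC.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices

from .errors import CloneMapError, CoordinateError, InputError, QCIndeterminateError

__all__ = [
    "SiteCall",
    "CloneAlignment",
    "CloneReport",
    "align_clone",
    "call_sites",
    "classify_context",
    "skip_runs",
    "conversion_qc",
    "pool_report",
]

_BASES = "ACGT"


@dataclass(frozen=True)
class SiteCall:
    contig: str
    ref_position: int  # 0-based, forward frame
    strand: str  # '+' (ref C) or '-' (ref G)
    context: str  # 'CpG' | 'CpHpG' | 'CpHpH' | 'NA'
    call: str  # 'methylated' | 'unmethylated' | 'ambiguous' | 'masked'
    clone_id: str = ""


@dataclass
class CloneAlignment:
    reference: str
    clone: str
    template_strand: str  # '+' forward template (C->T), '-' reverse (G->A)
    pairs: list[tuple[int | None, int | None]]  # aligned (ref_idx, clone_idx)
    identity: float
    n_bisulfite_mismatches: int
    n_other_mismatches: int


def _bisulfite_matrix(template_strand: str, match: float = 2.0, mismatch: float = -3.0):
    m = substitution_matrices.Array(alphabet=_BASES, dims=2)
    for a in _BASES:
        for b in _BASES:
            m[a, b] = match if a == b else mismatch
    if template_strand == "+":
        m["C", "T"] = match  # conversion, not a mismatch
    else:
        m["G", "A"] = match
    return m


def _aligner(template_strand: str) -> Align.PairwiseAligner:
    al = Align.PairwiseAligner()
    al.mode = "global"
    al.substitution_matrix = _bisulfite_matrix(template_strand)
    al.open_gap_score = -6.0
    al.extend_gap_score = -1.0
    # clones may cover a sub-interval of the reference: cheap end gaps
    try:
        al.end_insertion_score = -1.0
        al.end_deletion_score = -1.0
    except AttributeError:  # older Biopython
        al.target_end_gap_score = -1.0
        al.query_end_gap_score = -1.0
    return al


def _column_pairs(alignment) -> list[tuple[int | None, int | None]]:
    pairs: list[tuple[int | None, int | None]] = []
    blocks_t, blocks_q = alignment.aligned
    rt = rq = 0
    first = True
    for (ts, te), (qs, qe) in zip(blocks_t, blocks_q):
        if first:
            rt, rq = ts, qs
            first = False
        while rt < ts:
            pairs.append((rt, None))
            rt += 1
        while rq < qs:
            pairs.append((None, rq))
            rq += 1
        for k in range(te - ts):
            pairs.append((ts + k, qs + k))
        rt, rq = te, qe
    return pairs


def align_clone(reference_region: str, clone_sequence: str) -> CloneAlignment:
    """Globally align a clone to its reference with bisulfite-aware scoring.

    Both template orientations are tried (forward: ref C vs clone T scored as
    a match; reverse: ref G vs clone A) and the orientation with fewer
    non-bisulfite mismatches wins. Raises :class:`CloneMapError` when the
    alignment identity (bisulfite-equivalent pairs counted as matches) is
    below 70% in both orientations.
    """
    if not reference_region or not clone_sequence:
        raise InputError("reference and clone must be non-empty")
    best = None
    for strand in "+-":
        aln = _aligner(strand).align(reference_region, clone_sequence)[0]
        pairs = _column_pairs(aln)
        n_match = n_bis = n_other = n_cols = 0
        for ri, qi in pairs:
            if ri is None or qi is None:
                continue
            n_cols += 1
            a, b = reference_region[ri], clone_sequence[qi]
            if a == b:
                n_match += 1
            elif strand == "+" and a == "C" and b == "T":
                n_bis += 1
            elif strand == "-" and a == "G" and b == "A":
                n_bis += 1
            else:
                n_other += 1
        identity = (n_match + n_bis) / n_cols if n_cols else 0.0
        cand = CloneAlignment(
            reference=reference_region,
            clone=clone_sequence,
            template_strand=strand,
            pairs=pairs,
            identity=identity,
            n_bisulfite_mismatches=n_bis,
            n_other_mismatches=n_other,
        )
        if best is None or cand.n_other_mismatches < best.n_other_mismatches:
            best = cand
    if best.identity < 0.70:
        raise CloneMapError(
            f"clone does not map: best identity {best.identity:.2f} < 0.70 "
            "in both orientations"
        )
    return best


def classify_context(reference: str, position: int, strand: str) -> str:
    """Sequence context of a cytosine in the template strand's own sense.

    Forward strand: CpG if the next base is G; CpHpG if the next base is H
    (A/C/T) and the base after is G; CpHpH otherwise. Reverse-strand contexts
    read the reverse complement (upstream bases in forward frame). Returns
    'NA' when fewer than 2 downstream bases are available.
    """
    n = len(reference)
    if strand == "+":
        if reference[position] != "C":
            raise InputError(f"position {position} is not a forward-strand cytosine")
        if position + 1 >= n:
            return "NA"
        nxt = reference[position + 1]
        if nxt == "G":
            return "CpG"
        if position + 2 >= n:
            return "NA"
        return "CpHpG" if reference[position + 2] == "G" else "CpHpH"
    if reference[position] != "G":
        raise InputError(f"position {position} is not a reverse-strand cytosine")
    if position - 1 < 0:
        return "NA"
    nxt = reference[position - 1]  # complement sense: C<->G, A<->T
    if nxt == "C":
        return "CpG"
    if position - 2 < 0:
        return "NA"
    return "CpHpG" if reference[position - 2] == "C" else "CpHpH"


def call_sites(
    alignment: CloneAlignment,
    primer_intervals: list[tuple[int, int]] | None = None,
    contig: str = "",
    region_start: int = 0,
    clone_id: str = "",
) -> list[SiteCall]:
    """Per-cytosine methylation calls from one aligned clone.

    Forward template: ref C with clone C is methylated, with clone T
    unmethylated, anything else (including a gap) ambiguous; the reverse
    template is symmetric on ref G with clone G/A. Positions inside primer
    intervals (region coordinates) are masked regardless of pairing. When no
    primer intervals are supplied the outermost 20 bp of the region are
    masked with a warning.
    """
    ref = alignment.reference
    if primer_intervals is None:
        warnings.warn(
            "no primer intervals supplied; masking the outermost 20 bp",
            stacklevel=2,
        )
        primer_intervals = [(0, min(20, len(ref))), (max(0, len(ref) - 20), len(ref))]
    for start, end in primer_intervals:
        if not (0 <= start <= end <= len(ref)):
            raise CoordinateError(
                f"primer interval [{start}, {end}) outside region of length {len(ref)}"
            )

    def masked(pos: int) -> bool:
        return any(s <= pos < e for s, e in primer_intervals)

    strand = alignment.template_strand
    ref_base = "C" if strand == "+" else "G"
    meth_base = ref_base
    unmeth_base = "T" if strand == "+" else "A"
    clone_at = {ri: qi for ri, qi in alignment.pairs if ri is not None}
    aligned_ref = [ri for ri, qi in alignment.pairs if ri is not None]
    if not aligned_ref:
        return []
    lo, hi = min(aligned_ref), max(aligned_ref)
    calls = []
    for pos in range(lo, hi + 1):
        if ref[pos] != ref_base:
            continue
        if masked(pos):
            call = "masked"
        else:
            qi = clone_at.get(pos)
            if qi is None:
                call = "ambiguous"
            else:
                b = alignment.clone[qi]
                if b == meth_base:
                    call = "methylated"
                elif b == unmeth_base:
                    call = "unmethylated"
                else:
                    call = "ambiguous"
        calls.append(
            SiteCall(
                contig=contig,
                ref_position=region_start + pos,
                strand=strand,
                context=classify_context(ref, pos, strand),
                call=call,
                clone_id=clone_id,
            )
        )
    return calls


def skip_runs(calls: list[SiteCall]) -> list[int]:
    """Lengths of maximal runs of consecutive unmethylated cytosines.

    Calls must be ordered by reference position within one clone and strand;
    masked and ambiguous sites are ignored (they neither break nor extend a
    run).
    """
    runs, current = [], 0
    for c in calls:
        if c.call == "unmethylated":
            current += 1
        elif c.call == "methylated":
            if current:
                runs.append(current)
            current = 0
        # masked/ambiguous: skipped without breaking the run
    if current:
        runs.append(current)
    return runs


def conversion_qc(
    calls: list[SiteCall], max_unconverted: float = 0.005
) -> tuple[float, bool]:
    """Unconverted fraction on a declared-unmethylated control.

    Returns ``(fraction, passed)`` where fraction is
    methylated / (methylated + unmethylated); passes when below
    ``max_unconverted`` (0.5% by default). Raises
    :class:`QCIndeterminateError` with zero informative sites.
    """
    n_meth = sum(1 for c in calls if c.call == "methylated")
    n_unmeth = sum(1 for c in calls if c.call == "unmethylated")
    if n_meth + n_unmeth == 0:
        raise QCIndeterminateError("no informative sites in conversion control")
    frac = n_meth / (n_meth + n_unmeth)
    return frac, frac < max_unconverted


@dataclass
class CloneReport:
    """Pooled per-strand/per-context counts, percentages and skip runs."""

    n_meth: dict
    n_unmeth: dict
    percent_by_strand: dict  # strand -> float or None (NA)
    percent_by_context: dict
    skip_run_lengths: list[int]
    n_clones: int
    conversion_note: str = ""


def pool_report(
    calls_by_clone: dict[str, list[SiteCall]], per_clone_average: bool = False
) -> CloneReport:
    """Aggregate clone call sets into one report.

    Percentages pool counts across clones by default
    (methylated / scored cytosines, masked and ambiguous excluded); with
    ``per_clone_average`` each clone's percentage is computed first and the
    clone values averaged.
    """
    n_meth: dict = {}
    n_unmeth: dict = {}
    run_lengths: list[int] = []
    per_clone: dict[str, dict[str, list[int]]] = {}
    for clone_id, calls in calls_by_clone.items():
        by_strand: dict[str, list[SiteCall]] = {}
        for c in calls:
            by_strand.setdefault(c.strand, []).append(c)
        for strand, sc in by_strand.items():
            sc = sorted(sc, key=lambda c: c.ref_position)
            run_lengths.extend(skip_runs(sc))
            m = sum(1 for c in sc if c.call == "methylated")
            u = sum(1 for c in sc if c.call == "unmethylated")
            n_meth[strand] = n_meth.get(strand, 0) + m
            n_unmeth[strand] = n_unmeth.get(strand, 0) + u
            per_clone.setdefault(strand, {}).setdefault(clone_id, [m, u])
        for c in calls:
            if c.call == "methylated":
                n_meth[c.context] = n_meth.get(c.context, 0) + 1
            elif c.call == "unmethylated":
                n_unmeth[c.context] = n_unmeth.get(c.context, 0) + 1

    def percent(m: int, u: int) -> float | None:
        return None if m + u == 0 else 100.0 * m / (m + u)

    if per_clone_average:
        percent_by_strand = {}
        for strand, clones in per_clone.items():
            vals = [percent(m, u) for m, u in clones.values()]
            vals = [v for v in vals if v is not None]
            percent_by_strand[strand] = float(np.mean(vals)) if vals else None
    else:
        percent_by_strand = {
            s: percent(n_meth.get(s, 0), n_unmeth.get(s, 0)) for s in ("+", "-")
        }
    percent_by_context = {
        ctx: percent(n_meth.get(ctx, 0), n_unmeth.get(ctx, 0))
        for ctx in ("CpG", "CpHpG", "CpHpH")
    }
    return CloneReport(
        n_meth=n_meth,
        n_unmeth=n_unmeth,
        percent_by_strand=percent_by_strand,
        percent_by_context=percent_by_context,
        skip_run_lengths=run_lengths,
        n_clones=len(calls_by_clone),
    )


def calls_to_frame(calls: list[SiteCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "contig": c.contig,
                "pos": c.ref_position,
                "strand": c.strand,
                "context": c.context,
                "call": c.call,
                "clone_id": c.clone_id,
            }
            for c in calls
        ]
    )
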