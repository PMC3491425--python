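"""PWM motif scanning with an exact discretized null distribution.

Windows are scored as log2 odds against an order-0 background. The null
score distribution is computed exactly for the integer-discretized matrix by
dynamic-programming convolution across columns, which calibrates a score
threshold at a per-occurrence false-discovery rate (the probability that a
single background-drawn window reaches the threshold). Hit decisions use the
same discretized scores as the null, so the achieved tail probability is
exact by construction. By default the background is the scanned genome's
mononucleotide composition (the Oxytricha MAC genome is AT-rich), not
uniform.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import CalibrationError, InputError
from .junctions import revcomp

__all__ = [
    "PositionWeightMatrix",
    "MotifHit",
    "ScoreDistribution",
    "score_window",
    "exact_score_distribution",
    "calibrate_threshold",
    "scan_genome",
    "genome_background",
    "read_meme_minimal",
]

logger = logging.getLogger(__name__)

ALPHABET = "ACGT"
_IDX = {b: i for i, b in enumerate(ALPHABET)}
DEFAULT_RESOLUTION = 0.01  # bits per discretization step


@dataclass
class PositionWeightMatrix:
    """Column-stochastic base probabilities with a background distribution."""

    probs: np.ndarray  # (width, 4) over ACGT
    background: np.ndarray  # (4,)
    name: str = "motif"

    def __post_init__(self):
        self.probs = np.asarray(self.probs, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.probs.ndim != 2 or self.probs.shape[1] != 4:
            raise InputError("PWM must have shape (width, 4)")
        if not np.allclose(self.probs.sum(axis=1), 1.0, atol=1e-9):
            raise InputError("PWM columns must each sum to 1")
        if not np.isclose(self.background.sum(), 1.0, atol=1e-9):
            raise InputError("background must sum to 1")
        if (self.probs <= 0).any() or (self.background <= 0).any():
            raise InputError("PWM and background entries must be positive (add a pseudocount)")

    @property
    def width(self) -> int:
        return self.probs.shape[0]

    def log_odds(self) -> np.ndarray:
        """(width, 4) log2(p / q) scoring matrix in bits."""
        return np.log2(self.probs / self.background[None, :])

    @classmethod
    def from_counts(
        cls,
        counts: np.ndarray,
        background: np.ndarray | None = None,
        pseudocount: float = 0.1,
        name: str = "motif",
    ) -> "PositionWeightMatrix":
        counts = np.asarray(counts, dtype=float) + pseudocount
        probs = counts / counts.sum(axis=1, keepdims=True)
        if background is None:
            background = np.full(4, 0.25)
        return cls(probs, background, name=name)

    @classmethod
    def from_consensus(
        cls,
        consensus: str,
        certainty: float = 0.97,
        background: np.ndarray | None = None,
        name: str = "motif",
    ) -> "PositionWeightMatrix":
        """A PWM concentrated on a consensus word.

        Each column puts ``certainty`` on the consensus base and splits the
        remainder over the other three.
        """
        if set(consensus) - set(ALPHABET):
            raise InputError(f"consensus must be over {ALPHABET}")
        probs = np.full((len(consensus), 4), (1.0 - certainty) / 3.0)
        for i, base in enumerate(consensus):
            probs[i, _IDX[base]] = certainty
        if background is None:
            background = np.full(4, 0.25)
        return cls(probs, background, name=name)


@dataclass(frozen=True)
class MotifHit:
    contig: str
    position: int  # 0-based forward-frame start
    strand: str
    score: float  # bits
    p_value: float


def score_window(pwm: PositionWeightMatrix, window: str) -> float | None:
    """Log2-odds score of one window in bits; None for ambiguous bases."""
    if len(window) != pwm.width:
        raise InputError(f"window length {len(window)} != PWM width {pwm.width}")
    lo = pwm.log_odds()
    total = 0.0
    for i, base in enumerate(window):
        j = _IDX.get(base)
        if j is None:
            logger.debug("skipping window with ambiguous base %r", base)
            return None
        total += lo[i, j]
    return total


@dataclass
class ScoreDistribution:
    """Discretized null PMF of window scores under the background."""

    int_matrix: np.ndarray  # (width, 4) integer scores
    resolution: float  # bits per integer step
    offset: int  # integer score of pmf[0]
    pmf: np.ndarray

    def scores_bits(self) -> np.ndarray:
        return (self.offset + np.arange(len(self.pmf))) * self.resolution

    def tail(self, int_score: int) -> float:
        """P(null integer score >= int_score)."""
        i = int_score - self.offset
        if i <= 0:
            return 1.0
        if i >= len(self.pmf):
            return 0.0
        return float(self.pmf[i:].sum())


def exact_score_distribution(
    pwm: PositionWeightMatrix, resolution: float = DEFAULT_RESOLUTION
) -> ScoreDistribution:
    """Exact null PMF of the integer-discretized score by DP convolution.

    Each column's log-odds scores are rounded to integer multiples of
    ``resolution`` bits; the PMF of their sum under the background is built
    column by column. The worst-case discretization error is
    ``width * resolution / 2``; a resolution coarse enough to allow more than
    0.5 bit of error raises :class:`CalibrationError`.
    """
    if resolution <= 0:
        raise CalibrationError("resolution must be positive")
    if pwm.width * resolution / 2.0 > 0.5:
        raise CalibrationError(
            f"resolution {resolution} too coarse: max discretization error "
            f"{pwm.width * resolution / 2.0:.3f} bits exceeds 0.5"
        )
    int_matrix = np.rint(pwm.log_odds() / resolution).astype(np.int64)
    pmf = np.array([1.0])
    offset = 0
    for col in range(pwm.width):
        scores = int_matrix[col]
        lo, hi = int(scores.min()), int(scores.max())
        new = np.zeros(len(pmf) + (hi - lo), dtype=float)
        for j in range(4):
            new[scores[j] - lo : scores[j] - lo + len(pmf)] += pwm.background[j] * pmf
        pmf = new
        offset += lo
    if abs(pmf.sum() - 1.0) > 1e-6:
        raise CalibrationError(f"null PMF mass {pmf.sum()} deviates from 1")
    return ScoreDistribution(int_matrix=int_matrix, resolution=resolution, offset=offset, pmf=pmf)


def calibrate_threshold(
    pwm: PositionWeightMatrix,
    fdr_per_occurrence: float = 1e-7,
    resolution: float = DEFAULT_RESOLUTION,
    dist: ScoreDistribution | None = None,
) -> tuple[float, float, ScoreDistribution]:
    """Smallest score threshold with null tail <= ``fdr_per_occurrence``.

    Returns ``(threshold_bits, achieved_tail, dist)``. The threshold is the
    smallest attainable discretized score t with P_null(score >= t) <= fdr;
    hit decisions made with the returned distribution achieve exactly the
    reported tail. Raises :class:`CalibrationError` when even the maximum
    attainable score exceeds the requested rate.
    """
    if not 0 < fdr_per_occurrence <= 1:
        raise CalibrationError("fdr_per_occurrence must be in (0, 1]")
    if dist is None:
        dist = exact_score_distribution(pwm, resolution)
    tails = dist.pmf[::-1].cumsum()[::-1]  # tails[i] = P(score >= offset + i)
    ok = np.nonzero(tails <= fdr_per_occurrence)[0]
    if len(ok) == 0:
        raise CalibrationError(
            "requested FDR unreachable at this resolution; use a finer resolution "
            "or a more informative PWM"
        )
    i = int(ok[0])
    # walk back to the smallest threshold still meeting the rate (identical tails)
    while i > 0 and tails[i - 1] <= fdr_per_occurrence:
        i -= 1
    t_int = dist.offset + i
    return t_int * dist.resolution, float(tails[i]), dist


def genome_background(sequences: dict[str, str]) -> np.ndarray:
    """Order-0 (mononucleotide) background from a set of contigs."""
    counts = np.zeros(4)
    for seq in sequences.values():
        arr = np.frombuffer(seq.encode(), dtype=np.uint8)
        for j, base in enumerate(ALPHABET):
            counts[j] += int((arr == ord(base)).sum())
    if counts.sum() == 0:
        raise InputError("no unambiguous bases in genome")
    counts = np.maximum(counts, 1.0)
    return counts / counts.sum()


def _encode(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    out = np.full(len(arr), -1, dtype=np.int64)
    for j, base in enumerate(ALPHABET):
        out[arr == ord(base)] = j
    return out


def _scan_strand(enc: np.ndarray, dist: ScoreDistribution) -> np.ndarray:
    """Integer window scores; windows containing ambiguous bases get INT_MIN."""
    w = dist.int_matrix.shape[0]
    n = len(enc) - w + 1
    if n <= 0:
        return np.zeros(0, dtype=np.int64)
    scores = np.zeros(n, dtype=np.int64)
    bad = np.zeros(n, dtype=bool)
    for col in range(w):
        sl = enc[col : col + n]
        bad |= sl < 0
        scores += dist.int_matrix[col][np.clip(sl, 0, 3)]
    scores[bad] = np.iinfo(np.int64).min
    return scores


def scan_genome(
    pwm: PositionWeightMatrix,
    sequences: dict[str, str],
    threshold_bits: float,
    dist: ScoreDistribution | None = None,
    resolution: float = DEFAULT_RESOLUTION,
    cluster_gap_bp: int = 200,
) -> tuple[list[MotifHit], pd.Series, list[dict]]:
    """Scan both strands of every contig for windows at or above the threshold.

    Returns ``(hits, per_contig_counts, clusters)``. Hits are sorted by
    (contig, position); a cluster is a maximal run of hits on one contig with
    inter-hit start gaps of at most ``cluster_gap_bp``. Windows containing
    ambiguous bases are skipped; contigs shorter than the PWM width are
    skipped with a warning.
    """
    import warnings

    if dist is None:
        dist = exact_score_distribution(pwm, resolution)
    t_int = int(np.rint(threshold_bits / dist.resolution))
    w = pwm.width
    hits: list[MotifHit] = []
    counts = pd.Series(0, index=list(sequences), dtype=int)
    for cid, seq in sequences.items():
        if len(seq) < w:
            warnings.warn(f"contig {cid} shorter than PWM width; skipped", stacklevel=2)
            continue
        enc_f = _encode(seq)
        enc_r = _encode(revcomp(seq))
        for strand, enc in (("+", enc_f), ("-", enc_r)):
            scores = _scan_strand(enc, dist)
            for i in np.nonzero(scores >= t_int)[0]:
                pos = int(i) if strand == "+" else len(seq) - int(i) - w
                s_int = int(scores[i])
                hits.append(
                    MotifHit(
                        contig=cid,
                        position=pos,
                        strand=strand,
                        score=s_int * dist.resolution,
                        p_value=dist.tail(s_int),
                    )
                )
        counts[cid] = sum(1 for h in hits if h.contig == cid)
    hits.sort(key=lambda h: (h.contig, h.position, h.strand))
    clusters = []
    for cid in sequences:
        chits = [h for h in hits if h.contig == cid]
        run: list[MotifHit] = []
        for h in chits:
            if run and h.position - run[-1].position > cluster_gap_bp:
                clusters.append(_cluster_record(cid, run))
                run = []
            run.append(h)
        if run:
            clusters.append(_cluster_record(cid, run))
    return hits, counts, clusters


def _cluster_record(cid: str, run: list[MotifHit]) -> dict:
    return {
        "contig": cid,
        "start": run[0].position,
        "end": run[-1].position,
        "n_hits": len(run),
    }


def read_meme_minimal(path: str) -> list[PositionWeightMatrix]:
    """Read PWMs from a MEME minimal-format motif file."""
    from Bio import motifs as bio_motifs

    out = []
    with open(path) as fh:
        record = bio_motifs.parse(fh, "minimal")
    for m in record:
        counts = np.array([[m.counts[b][i] for b in ALPHABET] for i in range(m.length)])
        bg = np.array([record.background[b] for b in ALPHABET])
        bg = bg / bg.sum()
        out.append(
            PositionWeightMatrix.from_counts(
                counts, background=bg, pseudocount=0.1, name=m.name or "motif"
            )
        )
    return out
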