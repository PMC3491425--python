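"""Synthetic genome, modification-track, meDIP, bisulfite, rearrangement and
qPCR generators.

The generator emulates the data structure of a conjugating *Oxytricha
trifallax* population: ~2 kb telomere-capped MAC nanochromosomes; germline
(MIC) satellite-repeat and transposon-like contigs amplified ~5-fold by
polytenization at 46 h; regionally dense all-context cytosine
methylation/hydroxymethylation with short skipped runs of unmodified
cytosines; a planted 20 bp bipartite pyrimidine-rich motif clustered on
cohort chromosomes; antibody immunoprecipitation libraries with weak
cross-reactivity to unmodified cytosine plus bead background; near-complete
bisulfite conversion; and rearrangement errors that delete false IESs
between 3-4 bp cryptic microhomologies.

All generators are deterministic for a fixed ``rng_seed``: the same seed
produces byte-identical outputs. Coordinates are 0-based half-open; a
minus-strand position refers to the forward-frame index of the complementary
cytosine (a G on the forward strand).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .errors import ConfigurationError, CoordinateError, InputError, SimulationError
from .junctions import MdsSegment, ScrambledLocusMap, revcomp, validate_map

__all__ = [
    "SimulationConfig",
    "MacRecord",
    "MicRecord",
    "GenomeModel",
    "ModificationTrack",
    "generate_genome",
    "plant_modifications",
    "simulate_medip_library",
    "simulate_bisulfite_clones",
    "simulate_rearrangement_products",
    "simulate_qpcr",
    "make_scrambled_locus_map",
]

TELOMERE_UNIT = "GGGGTTTT"
# AT-rich background, as in the Oxytricha MAC genome
BASE_PROBS = {"A": 0.3, "T": 0.3, "C": 0.2, "G": 0.2}
ANTIBODIES = ("IgG", "mC", "hmC")
TIMEPOINTS = ("veg", "46h")


@dataclass
class SimulationConfig:
    """Parameters of the stated synthetic world.

    Defaults mirror the study's conditions where stated (2 kb nanochromosomes,
    300 bp fragments, ~5-fold polytenization at 46 h, 0.91/0.84 per-strand
    modification densities, skip runs of at most 8 cytosines, 170 bp satellite
    unit, a 20 bp bipartite pyrimidine-rich motif planted ~5 times per cohort
    chromosome, 11 cohort chromosomes) and are otherwise fixed at desk scale
    (200 MAC chromosomes, 100k reads per library).
    """

    n_mac_chromosomes: int = 200
    mac_length_mean_bp: int = 2000
    n_cohort_chromosomes: int = 11
    n_hmc_only_chromosomes: int = 3
    # (kind, repeat_unit_bp, total_len_bp); repeat_unit_bp ignored for transposons.
    # MIC-limited contigs are short assembly fragments whose total mass is a
    # small fraction of the MAC genome, as in the real assembly.
    mic_contigs: list = field(
        default_factory=lambda: [("satellite", 170, 850)] * 5
        + [("transposon", 0, 800)] * 5
    )
    polyteny_fold: float = 5.0
    n_reads_per_library: int = 100_000
    fragment_len_bp: int = 300
    antibody_affinity: dict = field(
        default_factory=lambda: {"IgG": 0.0, "mC": 0.08, "hmC": 0.08}
    )
    # lognormal copy-number spread (sigma of log): nanochromosome ploidy varies
    # moderately; germline repeat families span orders of magnitude
    mac_abundance_sigma: float = 0.4
    mic_abundance_sigma: float = 1.0
    antibody_cross: float = 0.0  # mC<->hmC cross-recognition
    crossreact_gamma: float = 0.005  # per unmodified cytosine
    background_beta: float = 1.0  # bead background per fragment
    mod_density_fwd: float = 0.91
    mod_density_rev: float = 0.84
    skip_run_geometric_p: float = 0.5
    max_skip_run: int = 8
    hmc_fraction: float = 0.3
    satellite_hmc_fraction: float = 0.9
    transposon_hmc_fraction: float = 0.1
    conversion_rate: float = 0.998
    # fraction of molecules escaping conversion entirely (incomplete
    # denaturation of duplex DNA); keeps unmethylated templates faintly
    # amplifiable in bisulfite-qPCR, as real conversion chemistry does
    unconverted_molecule_fraction: float = 0.01
    motif_consensus: str = "CCCCTTTATTCCCCTTTATT"
    motifs_per_cohort_chrom: int = 5
    motif_cluster_gap_bp: int = 200
    modified_region_fraction: float = 0.6
    telomere_unit: str = TELOMERE_UNIT
    qpcr_c0: float = 30.0
    rng_seed: int = 0

    def validate(self) -> "SimulationConfig":
        fractions = [
            ("mod_density_fwd", self.mod_density_fwd),
            ("mod_density_rev", self.mod_density_rev),
            ("skip_run_geometric_p", self.skip_run_geometric_p),
            ("hmc_fraction", self.hmc_fraction),
            ("satellite_hmc_fraction", self.satellite_hmc_fraction),
            ("transposon_hmc_fraction", self.transposon_hmc_fraction),
            ("conversion_rate", self.conversion_rate),
            ("unconverted_molecule_fraction", self.unconverted_molecule_fraction),
            ("modified_region_fraction", self.modified_region_fraction),
        ]
        for name, value in fractions:
            if not 0.0 <= value <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1], got {value}")
        if self.skip_run_geometric_p <= 0.0:
            raise ConfigurationError("skip_run_geometric_p must be > 0")
        positives = [
            ("n_mac_chromosomes", self.n_mac_chromosomes),
            ("mac_length_mean_bp", self.mac_length_mean_bp),
            ("n_reads_per_library", self.n_reads_per_library),
            ("fragment_len_bp", self.fragment_len_bp),
            ("background_beta", self.background_beta),
        ]
        for name, value in positives:
            if value <= 0:
                raise ConfigurationError(f"{name} must be positive, got {value}")
        if self.polyteny_fold < 1:
            raise ConfigurationError("polyteny_fold must be >= 1")
        if self.crossreact_gamma < 0:
            raise ConfigurationError("crossreact_gamma must be >= 0")
        for ab, alpha in self.antibody_affinity.items():
            if alpha < 0:
                raise ConfigurationError(f"antibody_affinity[{ab}] must be >= 0")
        if self.fragment_len_bp >= self.mac_length_mean_bp:
            raise ConfigurationError(
                "fragment_len_bp must be smaller than mac_length_mean_bp"
            )
        if self.n_cohort_chromosomes + self.n_hmc_only_chromosomes > self.n_mac_chromosomes:
            raise ConfigurationError(
                "n_cohort_chromosomes + n_hmc_only_chromosomes exceeds n_mac_chromosomes"
            )
        if set(self.motif_consensus) - set("ACGT") or len(self.motif_consensus) < 4:
            raise ConfigurationError("motif_consensus must be a >=4-mer over ACGT")
        for kind, unit, total in self.mic_contigs:
            if kind not in ("satellite", "transposon"):
                raise ConfigurationError(f"mic_contigs: unknown kind {kind!r}")
            if kind == "satellite" and (unit <= 0 or total < unit):
                raise ConfigurationError("mic_contigs: satellite needs 0 < unit <= total")
            if total <= 0:
                raise ConfigurationError("mic_contigs: total_len_bp must be positive")
        return self

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class MacRecord:
    id: str
    sequence: str
    cohort_truth_flag: bool
    hmc_only_flag: bool = False
    copy_multiplier: float = 1.0
    abundance: float = 1.0  # relative ploidy of this nanochromosome


@dataclass(frozen=True)
class MicRecord:
    id: str
    sequence: str
    kind: str  # 'satellite' | 'transposon'
    copy_multiplier: float = 5.0
    abundance: float = 1.0  # germline copy number of the repeat family


@dataclass
class GenomeModel:
    """Ground-truth genome: MAC + MIC records, locus maps and planted truth."""

    mac_records: list[MacRecord]
    mic_records: list[MicRecord]
    locus_maps: list[ScrambledLocusMap]
    motif_truth: list[tuple[str, int, str]]  # (contig_id, 0-based pos, strand)
    modified_regions: dict[str, tuple[int, int]]
    hmc_fraction_by_contig: dict[str, float]

    def sequences(self) -> dict[str, str]:
        out = {r.id: r.sequence for r in self.mac_records}
        out.update({r.id: r.sequence for r in self.mic_records})
        return out

    def lengths(self) -> pd.Series:
        return pd.Series({cid: len(s) for cid, s in self.sequences().items()})

    def copy_multipliers(self, timepoint: str = "46h") -> dict[str, float]:
        """Per-contig copy number; MIC polytenization applies only at 46 h."""
        out = {r.id: r.abundance for r in self.mac_records}
        for r in self.mic_records:
            out[r.id] = r.abundance * (r.copy_multiplier if timepoint == "46h" else 1.0)
        return out


class ModificationTrack:
    """Per-cytosine, per-strand modification states on a genome.

    ``states[contig][(pos, strand)]`` is one of ``"U"``, ``"mC"``, ``"hmC"``
    and is defined exactly at the cytosine positions of that strand (a minus
    strand cytosine sits at a forward-frame G).
    """

    def __init__(self, states: dict[str, dict[tuple[int, str], str]]):
        self.states = states

    @classmethod
    def all_unmodified(cls, genome: GenomeModel) -> "ModificationTrack":
        states: dict[str, dict[tuple[int, str], str]] = {}
        for cid, seq in genome.sequences().items():
            d: dict[tuple[int, str], str] = {}
            for i, base in enumerate(seq):
                if base == "C":
                    d[(i, "+")] = "U"
                elif base == "G":
                    d[(i, "-")] = "U"
            states[cid] = d
        return cls(states)

    def state(self, contig: str, pos: int, strand: str) -> str:
        return self.states[contig][(pos, strand)]

    def modified_positions(self, contig: str, kind: str | None = None) -> set[tuple[int, str]]:
        wanted = {"mC", "hmC"} if kind is None else {kind}
        return {k for k, v in self.states.get(contig, {}).items() if v in wanted}

    def to_bed_rows(self) -> list[tuple]:
        rows = []
        for cid, d in self.states.items():
            for (pos, strand), state in sorted(d.items()):
                if state != "U":
                    rows.append((cid, pos, pos + 1, state, 0, strand))
        return rows


def _random_seq(rng: np.random.Generator, n: int) -> str:
    bases = np.array(list("ATCG"))
    probs = [BASE_PROBS[b] for b in "ATCG"]
    return "".join(rng.choice(bases, size=n, p=probs))


# ---------------------------------------------------------------------------
# genome generation
# ---------------------------------------------------------------------------

def generate_genome(config: SimulationConfig) -> GenomeModel:
    """Generate the ground-truth genome for a simulation run.

    MAC nanochromosomes are capped at both ends with two tandem telomere
    units (G4T4 at the 5' end, its reverse complement at the 3' end). The
    first ``n_cohort_chromosomes`` MAC records are the methylation-cohort
    truth set and carry ``motifs_per_cohort_chrom`` planted motif instances
    clustered within the modified region (consecutive instances <= 200 bp
    apart); the next ``n_hmc_only_chromosomes`` records are hmC-only analogs
    of the ribosomal-gene chromosomes. Satellite MIC contigs are exact tandem
    arrays of their repeat unit; MIC contigs carry no terminal telomeres and
    a 46 h copy multiplier of ``polyteny_fold``.
    """
    config.validate()
    rng = np.random.default_rng(config.rng_seed)
    telo = config.telomere_unit * 2
    telo_rc = revcomp(telo)
    width = len(config.motif_consensus)

    mac_records: list[MacRecord] = []
    motif_truth: list[tuple[str, int, str]] = []
    modified_regions: dict[str, tuple[int, int]] = {}
    hmc_frac: dict[str, float] = {}

    for i in range(config.n_mac_chromosomes):
        cid = f"mac{i:04d}"
        cohort = i < config.n_cohort_chromosomes
        hmc_only = (
            config.n_cohort_chromosomes
            <= i
            < config.n_cohort_chromosomes + config.n_hmc_only_chromosomes
        )
        length = int(
            np.clip(
                rng.normal(config.mac_length_mean_bp, 0.15 * config.mac_length_mean_bp),
                config.fragment_len_bp + 4 * len(telo),
                None,
            )
        )
        core = list(_random_seq(rng, length - 2 * len(telo)))
        if cohort or hmc_only:
            frac = config.modified_region_fraction
            rstart = int(len(core) * (1 - frac) / 2)
            rend = rstart + int(len(core) * frac)
            modified_regions[cid] = (rstart + len(telo), rend + len(telo))
            hmc_frac[cid] = 1.0 if hmc_only else config.hmc_fraction
        if cohort:
            # plant a cluster of motif instances inside the modified region
            rstart, rend = modified_regions[cid]
            pos = rstart - len(telo) + int(rng.integers(0, 40))
            for _ in range(config.motifs_per_cohort_chrom):
                if pos + width > rend - len(telo):
                    break
                strand = "+" if rng.random() < 0.5 else "-"
                inst = config.motif_consensus if strand == "+" else revcomp(
                    config.motif_consensus
                )
                core[pos : pos + width] = list(inst)
                motif_truth.append((cid, pos + len(telo), strand))
                pos += width + int(rng.integers(10, config.motif_cluster_gap_bp - width))
        seq = telo + "".join(core) + telo_rc
        abundance = float(np.exp(rng.normal(0.0, config.mac_abundance_sigma)))
        mac_records.append(MacRecord(cid, seq, cohort, hmc_only, abundance=abundance))

    mic_records: list[MicRecord] = []
    for j, (kind, unit_bp, total_bp) in enumerate(config.mic_contigs):
        cid = f"mic{j:04d}_{kind}"
        if kind == "satellite":
            unit = _random_seq(rng, unit_bp)
            seq = unit * (total_bp // unit_bp)
        else:
            seq = _random_seq(rng, total_bp)
        abundance = float(np.exp(rng.normal(0.0, config.mic_abundance_sigma)))
        mic_records.append(
            MicRecord(cid, seq, kind, float(config.polyteny_fold), abundance=abundance)
        )
        modified_regions[cid] = (0, len(seq))
        hmc_frac[cid] = (
            config.satellite_hmc_fraction
            if kind == "satellite"
            else config.transposon_hmc_fraction
        )

    locus_map = make_scrambled_locus_map(config, rng)
    return GenomeModel(
        mac_records=mac_records,
        mic_records=mic_records,
        locus_maps=[locus_map],
        motif_truth=motif_truth,
        modified_regions=modified_regions,
        hmc_fraction_by_contig=hmc_frac,
    )


# ---------------------------------------------------------------------------
# modification planting
# ---------------------------------------------------------------------------

def _truncated_geometric(rng: np.random.Generator, p: float, kmax: int) -> int:
    """Geometric on {1, 2, ...} truncated (by rejection) to [1, kmax]."""
    while True:
        k = int(rng.geometric(p))
        if k <= kmax:
            return k


def _strand_states(
    rng: np.random.Generator,
    n_sites: int,
    density: float,
    skip_p: float,
    max_skip: int,
) -> np.ndarray:
    """Modified/unmodified run process over ``n_sites`` cytosines.

    Unmodified ("skip") runs are truncated-geometric on [1, max_skip];
    modified run lengths are geometric with mean chosen so the long-run
    modified fraction equals ``density``.
    """
    if density >= 1.0:
        return np.ones(n_sites, dtype=bool)
    if density <= 0.0 or n_sites == 0:
        return np.zeros(n_sites, dtype=bool)
    ks = np.arange(1, max_skip + 1)
    w = (1 - skip_p) ** (ks - 1) * skip_p
    mu_skip = float((ks * w).sum() / w.sum())
    mu_mod = density / (1.0 - density) * mu_skip
    p_mod = min(1.0, 1.0 / mu_mod)
    out = np.zeros(n_sites, dtype=bool)
    i = 0
    modified_phase = rng.random() < density
    while i < n_sites:
        if modified_phase:
            run = int(rng.geometric(p_mod))
            out[i : i + run] = True
        else:
            run = _truncated_geometric(rng, skip_p, max_skip)
        i += run
        modified_phase = not modified_phase
    return out


def plant_modifications(
    genome: GenomeModel, config: SimulationConfig
) -> ModificationTrack:
    """Plant mC/hmC states in each contig's designated modified region.

    Within a region each strand's cytosines are modified at the configured
    per-strand density; unmodified cytosines occur in truncated-geometric
    runs of at most ``max_skip_run`` sites; a per-contig fraction of modified
    sites is hmC (hydroxymethylation relabels pre-existing methylation), the
    rest mC. Cytosines outside modified regions are unmodified.
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([config.rng_seed, 1]))
    sequences = genome.sequences()
    track = ModificationTrack.all_unmodified(genome)
    for cid, (rstart, rend) in genome.modified_regions.items():
        seq = sequences[cid]
        if not (0 <= rstart <= rend <= len(seq)):
            raise CoordinateError(
                f"modified region [{rstart}, {rend}) outside contig {cid} "
                f"of length {len(seq)}"
            )
        hf = genome.hmc_fraction_by_contig.get(cid, config.hmc_fraction)
        for strand, base, density in (
            ("+", "C", config.mod_density_fwd),
            ("-", "G", config.mod_density_rev),
        ):
            sites = [i for i in range(rstart, rend) if seq[i] == base]
            states = _strand_states(
                rng,
                len(sites),
                density,
                config.skip_run_geometric_p,
                config.max_skip_run,
            )
            is_hmc = rng.random(len(sites)) < hf
            for pos, mod, h in zip(sites, states, is_hmc):
                if mod:
                    track.states[cid][(pos, strand)] = "hmC" if h else "mC"
    return track


# ---------------------------------------------------------------------------
# meDIP library simulation
# ---------------------------------------------------------------------------

def simulate_medip_library(
    genome: GenomeModel,
    track: ModificationTrack,
    antibody: str,
    timepoint: str,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
    emit_reads: bool = False,
):
    """Sample one immunoprecipitation library as fixed-length fragments.

    Every possible fragment (sliding window of ``fragment_len_bp``) carries
    IP weight ``beta + gamma * nC + alpha_antibody * n_recognized`` where nC
    counts cytosines on both strands of the fragment and n_recognized counts
    the modified cytosines the antibody binds (mC antibody binds mC, hmC
    antibody binds hmC, IgG binds neither; ``antibody_cross`` adds symmetric
    cross-recognition). Fragment origin is additionally weighted by the
    contig's copy multiplier at the library's timepoint. Fragments are drawn
    with replacement (multinomial at ``n_reads_per_library``).

    Returns ``(counts, reads)``: a per-contig ``pandas.Series`` of read
    counts (its sum is exactly ``n_reads_per_library``) and, when
    ``emit_reads`` is true, a list of ``(read_id, sequence, contig, start)``.
    """
    if antibody not in ANTIBODIES:
        raise ConfigurationError(f"unknown antibody {antibody!r}")
    if timepoint not in TIMEPOINTS:
        raise ConfigurationError(f"unknown timepoint {timepoint!r}")
    if rng is None:
        rng = np.random.default_rng(
            np.random.SeedSequence(
                [config.rng_seed, 2, ANTIBODIES.index(antibody), TIMEPOINTS.index(timepoint)]
            )
        )
    frag = config.fragment_len_bp
    alpha = config.antibody_affinity.get(antibody, 0.0)
    cross = config.antibody_cross
    copy_mult = genome.copy_multipliers(timepoint)
    sequences = genome.sequences()

    contig_ids, weights, offsets = [], [], [0]
    for cid, seq in sequences.items():
        n_win = len(seq) - frag + 1
        if n_win <= 0:
            continue
        arr = np.frombuffer(seq.encode(), dtype=np.uint8)
        is_c = ((arr == ord("C")) | (arr == ord("G"))).astype(np.float64)
        csum = np.concatenate([[0.0], np.cumsum(is_c)])
        c_in_win = csum[frag:] - csum[:-frag]

        mod = np.zeros(len(seq))
        if alpha > 0 or cross > 0:
            primary = "mC" if antibody == "mC" else ("hmC" if antibody == "hmC" else None)
            other = "hmC" if antibody == "mC" else ("mC" if antibody == "hmC" else None)
            for (pos, _strand), state in track.states.get(cid, {}).items():
                if state == "U":
                    continue
                if state == primary:
                    mod[pos] += 1.0
                elif state == other:
                    mod[pos] += cross / alpha if alpha > 0 else 0.0
        msum = np.concatenate([[0.0], np.cumsum(mod)])
        m_in_win = msum[frag:] - msum[:-frag]

        w = config.background_beta + config.crossreact_gamma * c_in_win + alpha * m_in_win
        w *= copy_mult[cid]
        contig_ids.append(cid)
        weights.append(w)
        offsets.append(offsets[-1] + n_win)

    if not weights:
        raise SimulationError("no contig long enough to yield a fragment")
    allw = np.concatenate(weights)
    total = allw.sum()
    if total <= 0:
        raise SimulationError("zero total immunoprecipitation weight")
    win_counts = rng.multinomial(config.n_reads_per_library, allw / total)

    counts = pd.Series(
        {
            cid: int(win_counts[offsets[i] : offsets[i + 1]].sum())
            for i, cid in enumerate(contig_ids)
        },
        name=f"{antibody}_{timepoint}",
    )
    reads = None
    if emit_reads:
        reads = []
        k = 0
        for i, cid in enumerate(contig_ids):
            seq = sequences[cid]
            nz = np.nonzero(win_counts[offsets[i] : offsets[i + 1]])[0]
            for start in nz:
                for _ in range(int(win_counts[offsets[i] + start])):
                    reads.append(
                        (f"read{k:07d}", seq[start : start + frag], cid, int(start))
                    )
                    k += 1
    return counts, reads


# ---------------------------------------------------------------------------
# bisulfite clone simulation
# ---------------------------------------------------------------------------

def simulate_bisulfite_clones(
    genome: GenomeModel,
    region: tuple[str, int, int],
    track: ModificationTrack,
    n_clones: int,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
    strands: str | None = None,
    molecule_escape: bool = False,
) -> list[tuple[str, str, str]]:
    """Simulate bisulfite-converted clone sequences from a region.

    Per clone a template strand is chosen (alternating unless ``strands``
    fixes one). On the forward template each unmodified C becomes T with
    probability ``conversion_rate``; modified cytosines (mC or hmC alike,
    indistinguishable by bisulfite) never convert. Reverse-strand templates
    are reported on the forward coordinate frame as G-to-A substitutions.
    With ``molecule_escape`` a clone escapes conversion entirely with
    probability ``unconverted_molecule_fraction`` (incomplete denaturation).

    Returns ``[(clone_id, strand, sequence)]`` with sequences in the forward
    frame of the reference region.
    """
    contig, start, end = region
    seq = genome.sequences().get(contig)
    if seq is None:
        raise CoordinateError(f"unknown contig {contig!r}")
    if not (0 <= start < end <= len(seq)):
        raise CoordinateError(f"empty or out-of-bounds region [{start}, {end}) on {contig}")
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([config.rng_seed, 3]))
    template = seq[start:end]
    out = []
    for k in range(n_clones):
        if strands in ("+", "-"):
            strand = strands
        else:
            strand = "+" if k % 2 == 0 else "-"
        if molecule_escape and rng.random() < config.unconverted_molecule_fraction:
            out.append((f"clone{k:04d}", strand, template))
            continue
        clone = list(template)
        for i, base in enumerate(template):
            pos = start + i
            if strand == "+" and base == "C":
                state = track.states[contig][(pos, "+")]
                if state == "U" and rng.random() < config.conversion_rate:
                    clone[i] = "T"
            elif strand == "-" and base == "G":
                state = track.states[contig][(pos, "-")]
                if state == "U" and rng.random() < config.conversion_rate:
                    clone[i] = "A"
        out.append((f"clone{k:04d}", strand, "".join(clone)))
    return out


# ---------------------------------------------------------------------------
# scrambled locus and rearrangement products
# ---------------------------------------------------------------------------

def make_scrambled_locus_map(
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
    n_mds: int = 17,
    mds_len_range: tuple[int, int] = (60, 120),
    pointer_len_range: tuple[int, int] = (4, 12),
    ies_len_range: tuple[int, int] = (25, 80),
    invert_prob: float = 0.3,
) -> ScrambledLocusMap:
    """Build a scrambled locus in the style of the TEBPalpha precursor.

    A MAC core sequence is generated first, cut into ``n_mds`` MDSs whose
    adjacent pairs overlap by a programmed pointer; the MDSs are placed in
    the MIC in a scrambled order, some inverted, separated by random IESs.
    IES bases flanking each MDS are chosen so that every programmed pointer
    is strictly maximal (greedy tiling recovers it exactly).
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([config.rng_seed, 4]))

    for _attempt in range(50):
        mds_lens = rng.integers(mds_len_range[0], mds_len_range[1] + 1, size=n_mds)
        ptr_lens = rng.integers(
            pointer_len_range[0], pointer_len_range[1] + 1, size=n_mds - 1
        )
        mac_len = int(mds_lens.sum() - ptr_lens.sum())
        mac = _random_seq(rng, mac_len)
        # MAC intervals of each MDS (consecutive, overlapping by pointers)
        mac_ivs = []
        pos = 0
        for i in range(n_mds):
            mac_ivs.append((pos, pos + int(mds_lens[i])))
            pos += int(mds_lens[i]) - (int(ptr_lens[i]) if i < n_mds - 1 else 0)
        mac_seqs = [mac[a:b] for a, b in mac_ivs]
        # reject MAC draws where a pointer is extendable (non-maximal overlap)
        ok = True
        for i in range(n_mds - 1):
            q = int(ptr_lens[i])
            if _overlap_len(mac_seqs[i], mac_seqs[i + 1]) != q:
                ok = False
                break
        if not ok:
            continue

        order = rng.permutation(n_mds)
        orient = ["-" if rng.random() < invert_prob else "+" for _ in range(n_mds)]
        # forbidden flanking bases in MAC sense, per MDS
        succ_forbid = [None] * n_mds  # base that may NOT follow the MDS
        pred_forbid = [None] * n_mds  # base that may NOT precede the MDS
        for i in range(n_mds - 1):
            q = int(ptr_lens[i])
            succ_forbid[i] = mac_seqs[i + 1][q]  # B[0]
            pred_forbid[i + 1] = mac_seqs[i][-q - 1]  # A[-1]

        mic_parts: list[str] = []
        mds_by_micorder: list[tuple[int, int, int, str]] = []  # (mac_order, start, end, orient)
        pos = 0
        for mic_slot, mac_order in enumerate(order):
            ies_len = int(rng.integers(ies_len_range[0], ies_len_range[1] + 1))
            ies = list(_random_seq(rng, ies_len))
            # constrain the IES base adjacent to the upcoming MDS
            o = orient[mac_order]
            if o == "+":
                forbid = pred_forbid[mac_order]
                if forbid is not None:
                    ies[-1] = _pick_base(rng, forbid)
            else:
                forbid = succ_forbid[mac_order]
                if forbid is not None:
                    ies[-1] = _pick_base(rng, revcomp(forbid))
            mic_parts.append("".join(ies))
            pos += ies_len
            seg = mac_seqs[mac_order] if o == "+" else revcomp(mac_seqs[mac_order])
            mic_parts.append(seg)
            mds_by_micorder.append((int(mac_order), pos, pos + len(seg), o))
            pos += len(seg)
        # trailing IES, constraining the base after the last-placed MDS
        ies_len = int(rng.integers(ies_len_range[0], ies_len_range[1] + 1))
        ies = list(_random_seq(rng, ies_len))
        mic_parts.append("".join(ies))
        mic = list("".join(mic_parts))
        # fix the MIC base *after* each MDS (MAC-sense successor constraint)
        for mac_order, s, e, o in mds_by_micorder:
            if o == "+":
                forbid = succ_forbid[mac_order]
                if forbid is not None:
                    mic[e] = _pick_base(rng, forbid)
            else:
                forbid = pred_forbid[mac_order]
                if forbid is not None:
                    mic[e] = _pick_base(rng, revcomp(forbid))
        mic_seq = "".join(mic)
        mds_list = [
            MdsSegment(index=mo + 1, mic_start=s, mic_end=e, orientation=o)
            for mo, s, e, o in sorted(mds_by_micorder)
        ]
        locus = ScrambledLocusMap(mic_sequence=mic_seq, mds_list=mds_list)
        try:
            locus = validate_map(locus)
        except Exception:
            continue
        if [len(p) for p in locus.programmed_pointers] == [int(q) for q in ptr_lens]:
            if locus.mac_sequence() == mac:
                return locus
    raise SimulationError("could not construct a maximal-pointer scrambled locus")


def _overlap_len(left: str, right: str) -> int:
    kmax = min(len(left), len(right))
    for k in range(kmax, 0, -1):
        if left[-k:] == right[:k]:
            return k
    return 0


def _pick_base(rng: np.random.Generator, forbidden: str) -> str:
    choices = [b for b in "ACGT" if b != forbidden]
    return choices[int(rng.integers(0, 3))]


def simulate_rearrangement_products(
    locus_map: ScrambledLocusMap,
    n_products: int,
    error_rate: float,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> tuple[list[tuple[str, str]], list[dict]]:
    """Emit correctly spliced and aberrant products with truth junctions.

    A correct product concatenates the MDSs in MAC order, joining at single
    programmed pointer copies. With probability ``error_rate`` a product is
    instead aberrant: a contiguous stretch of the unscrambled MIC sequence
    from which the interval between two maximal 3-4 bp microhomologies has
    been deleted (a "false IES"), retaining one microhomology copy and
    preserving segment order.

    Returns ``(products, truth)``: ``products`` is ``[(product_id, seq)]``;
    each truth record carries the product class and its junction list
    ``[(pointer_sequence, pointer_length, class)]``.
    """
    locus_map = validate_map(locus_map)
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([config.rng_seed, 5]))
    mic = locus_map.mic_sequence
    mac = locus_map.mac_sequence()
    products, truth = [], []
    for k in range(n_products):
        pid = f"product{k:04d}"
        if rng.random() < error_rate:
            seq, junction = _aberrant_product(mic, rng)
            products.append((pid, seq))
            truth.append(
                {
                    "product_id": pid,
                    "class": "aberrant",
                    "junctions": [junction],
                }
            )
        else:
            products.append((pid, mac))
            truth.append(
                {
                    "product_id": pid,
                    "class": "correct",
                    "junctions": [
                        (p, len(p), "programmed") for p in locus_map.programmed_pointers
                    ],
                }
            )
    return products, truth


def _aberrant_product(
    mic: str,
    rng: np.random.Generator,
    flank: int = 150,
    min_deletion: int = 30,
    max_scan: int = 350,
) -> tuple[str, tuple[str, int, str]]:
    """One false-IES deletion between maximal 3-4 bp microhomologies."""
    n = len(mic)
    for _ in range(2000):
        lp = int(rng.integers(3, 5))
        i = int(rng.integers(flank, n - flank - max_scan))
        pat = mic[i : i + lp]
        j = mic.find(pat, i + min_deletion, i + max_scan)
        if j < 0:
            continue
        # extend the microhomology to maximality on both sides
        while i > 0 and j > i + lp and mic[i - 1] == mic[j - 1]:
            i, j = i - 1, j - 1
            lp += 1
        while j + lp < n and i + lp < j and mic[i + lp] == mic[j + lp]:
            lp += 1
        if not 3 <= lp <= 4:
            continue
        if j - i - lp < min_deletion:
            continue
        a = max(0, i - flank)
        b = min(n, j + lp + flank)
        if i + lp - a < 25 or b - (j + lp) < 25:
            continue
        seq = mic[a : i + lp] + mic[j + lp : b]
        return seq, (mic[i : i + lp], lp, "cryptic")
    raise SimulationError("failed to sample a cryptic microhomology deletion")


# ---------------------------------------------------------------------------
# qPCR simulation
# ---------------------------------------------------------------------------

def simulate_qpcr(
    abundance_table: pd.DataFrame,
    replicates: int = 3,
    noise_sd: float = 0.2,
    config: SimulationConfig | None = None,
    rng: np.random.Generator | None = None,
    include_water_controls: bool = True,
) -> pd.DataFrame:
    """Simulate a triplicate Ct table from relative template abundances.

    ``abundance_table`` columns: target, sample, treatment, template,
    abundance (> 0). Ct = c0 - log2(abundance) + Normal(0, noise_sd). Water
    controls emit Ct uniform in [35, 38].
    """
    c0 = config.qpcr_c0 if config is not None else 30.0
    if rng is None:
        seed = config.rng_seed if config is not None else 0
        rng = np.random.default_rng(np.random.SeedSequence([seed, 6]))
    required = {"target", "sample", "treatment", "template", "abundance"}
    missing = required - set(abundance_table.columns)
    if missing:
        raise InputError(f"abundance table missing columns: {sorted(missing)}")
    if (abundance_table["abundance"] <= 0).any():
        bad = abundance_table.loc[abundance_table["abundance"] <= 0, "target"].iloc[0]
        raise InputError(f"non-positive abundance for target {bad!r}")
    rows = []
    for _, rec in abundance_table.iterrows():
        base_ct = c0 - math.log2(rec["abundance"])
        for r in range(replicates):
            ct = base_ct + (rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0)
            rows.append(
                {
                    "target": rec["target"],
                    "sample": rec["sample"],
                    "treatment": rec["treatment"],
                    "template": rec["template"],
                    "replicate": r + 1,
                    "ct": ct,
                }
            )
    if include_water_controls:
        samples = abundance_table[["sample", "treatment"]].drop_duplicates()
        for _, rec in samples.iterrows():
            for r in range(replicates):
                rows.append(
                    {
                        "target": "water",
                        "sample": rec["sample"],
                        "treatment": rec["treatment"],
                        "template": "native",
                        "replicate": r + 1,
                        "ct": float(rng.uniform(35.0, 38.0)),
                    }
                )
    return pd.DataFrame(rows)
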