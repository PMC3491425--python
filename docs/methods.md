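# Methods

This note documents the models behind `oxymark`, the defaults and why they
were chosen, what the synthetic generator does and does not emulate, and the
numerical choices that matter.

## The measurement model

### Immunoprecipitation libraries

A meDIP library is modeled as fragments of fixed length *F* (default 300 bp,
the sonication target) drawn with replacement from all sliding windows of the
genome. Window *w* of contig *c* is sampled with weight

    W(w) = a_c · [ β + γ·nC(w) + α_A·nMod_A(w) ]

where `nC` counts cytosines on both strands of the fragment, `nMod_A` counts
the modified cytosines recognized by antibody A (the mC antibody binds mC,
the hmC antibody binds hmC, IgG binds neither; symmetric cross-recognition is
a knob defaulting to 0), `β` is bead background, `γ` weak antibody affinity
for unmodified cytosine, and `a_c` the contig's copy number at the library's
timepoint. Reads per window are multinomial at the library size. This is the
simplest model that reproduces the two noise sources the two-step
normalization is designed to remove — cross-reactivity to unmodified C and
sequence-nonspecific bead binding — and makes the vegetative-subtracted
signal identifiable: E[count_mC − count_IgG] is proportional to
α·(modified-C content × copy number).

Defaults: β = 1, γ = 0.005 (≈ 0.75 weight per 300-bp window — comparable to
background, i.e. "weak"), α_mC = α_hmC = 0.08. These were fixed once so that
a planted cohort chromosome carries a few-fold IP enrichment over background,
the regime the fixed 100-excess-read threshold presupposes; they are not
fitted quantities.

### Copy number and the 5:1 line

MIC contigs carry a polyteny multiplier (default 5, the amplification the
study observed at 46 h) applied only in 46 h libraries. Per-contig abundances
are lognormal — σ = 0.4 for nanochromosomes (moderate ploidy variation),
σ = 1.0 for germline repeat families (satellite abundances span orders of
magnitude) — because a copy-number scatter with no dynamic range makes a
through-origin R² meaningless (all points collapse to a blob and R² can go
negative). Note one deliberate consequence of per-library depth
normalization: amplified germline mass inflates the 46 h library total, so
the fitted MIC slope sits slightly below the true polyteny fold (≈ 4.5–4.7
at defaults) and the MAC slope slightly below 1. The effect is proportional
to the MIC mass fraction; it is invisible in the real data, where MIC-limited
contigs are a negligible fraction of the assembly, and that is why the
default MIC contigs are short (800–850 bp) relative to the 400 kb MAC
genome.

### Modification tracks

Modification is regional: each cohort chromosome carries one modified region
(central 60% of the chromosome; the real data show peaks spanning hundreds of
bp) in which each strand's cytosines are modified at the per-strand densities
0.91 (forward) and 0.84 (reverse) — the strand percentages reported for
Contig4414. Unmodified cytosines occur in runs drawn from a geometric law
(p = 0.5) truncated to [1, 8], matching the observed "runs of 3 to 8
consecutive unmethylated cytosines" without claiming more than the
observation supports; modified-run lengths are geometric with mean chosen so
the long-run modified fraction equals the density. A fraction of modified
sites (default 0.3) is relabeled hmC — hydroxymethylation arises on
pre-existing methylation — and hmC-only chromosomes (ribosomal-gene analogs)
use fraction 1.0. Vegetative tracks are entirely unmodified, which is the
biological fact the whole normalization rests on.

A track stores one state per (position, strand) cytosine, i.e. one pattern
per contig. Real molecule populations are heterogeneous; this matters only
where single molecules are sampled (bisulfite), and is handled there (see
below).

## Stage-by-stage notes

### Signal normalization

RPKM = count / (kb of contig) / (millions of mapped reads). "Excess reads"
(the unit the cohort thresholds are quoted in) is computed on depth-matched
raw counts — `count_46h − count_veg · total_46h/total_veg`, rounded half away
from zero — not on RPKM, and both columns are emitted. Negative signal is
retained (depleted populations are informative). Multi-mapping is resolved by
counting primary alignments only; for satellite repeats this undercounts
systematically and is documented as a caveat rather than corrected.

### Germline classifier

1-D two-means on r = log2((RPKM_46h + ε)/(RPKM_veg + ε)), ε = 0.1 RPKM.
Per cluster, a through-origin least-squares slope with R² measured against
that line. The split is refused (single population, explicit "no MIC
population detected" warning) when the mean silhouette of the two-means
labeling falls below 0.75. The guard value matters: splitting a *unimodal*
Gaussian at its mean already yields silhouette ≈ 0.53–0.61, while a genuine
5:1 mixture yields ≈ 0.95, so a 0.5 cutoff would split unamplified data and
0.75 sits between the regimes. A MIC label additionally requires no terminal
telomere (two tandem G₄T₄ units or their reverse complement within 50 bp of
either end); an enriched contig bearing telomeres is labeled ambiguous, never
MIC.

### Cohorts

Thresholds are encoded with the stated strictness: excess_mC **>** 100
(strict, "over 100"); excess_hmC **≥** 40 AND hmC:IgG signal ratio **≥** 1.5.
A contig with non-positive IgG signal passes the ratio test by definition —
IgG depletion cannot mask hmC enrichment, and dividing by a near-zero or
negative signal is meaningless. An optional natural-break finder (largest gap
in the sorted upper tail) can replace the fixed cutoff but is not the
default. Whether the hmC ratio should use signal or raw RPKM in the
denominator is ambiguous in the source; the signal-based reading is
implemented.

### Motif scanning

Windows are scored in log2-odds bits against an order-0 background, which
defaults to the scanned genome's mononucleotide composition (the MAC genome
is AT-rich; a uniform background would miscalibrate C-rich motifs). The null
score distribution is computed exactly for the integer-discretized matrix
(0.01 bit/step; worst-case discretization error w·res/2 is asserted ≤ 0.5
bit) by convolving per-column score distributions. Hit decisions use the
same integer scores as the null, so the calibrated threshold achieves its
reported tail probability exactly, and the per-occurrence FDR of 1×10⁻⁷ is
met by construction. The "FDR" here is a per-scanned-window null exceedance
probability ("one false discovery per 10 million occurrences"); the expected
genome-wide false count is that rate times windows scanned. Motif discovery
is out of scope: the PWM is an input (MEME minimal format reader, or a
consensus with per-column certainty 0.97).

### Bisulfite caller

Clones are globally aligned to the reference region under two scoring
schemes — forward template (ref C : clone T scored as match) and reverse
template (ref G : clone A) — and the orientation with fewer non-bisulfite
mismatches wins; identity < 70% in both orientations is a mapping failure.
Calls: ref C + clone C → methylated, ref C + clone T → unmethylated (reverse
template symmetric on G/A); anything else, including gaps, is ambiguous;
positions inside primer intervals are masked (primer-site methylation is
unobservable in PCR products) and default to the outermost 20 bp when no
intervals are given. Context (CpG/CpHpG/CpHpH) is read in the template
strand's own sense, so minus-strand contexts use upstream forward-frame
bases complemented. Percentages divide methylated by *scored* cytosines
(ambiguous and masked excluded); pooling across clones is the default, with
per-clone averaging behind a flag. mC and hmC are indistinguishable by
bisulfite and both report as methylated. The conversion control passes below
0.5% unconverted; the default conversion rate (0.998) leaves the control
comfortably inside that bound, which is why the generator's default is 0.998
rather than a borderline 0.995.

### Junction detection

Products are tiled onto the MIC locus by greedy maximal exact matching (both
orientations, 20 bp minimum seed; ties to the leftmost coordinate). At each
adjacent segment pair the pointer is the maximal string that is a suffix of
the left segment's MIC match, the MIC context immediately preceding the right
segment's match (MAC sense), and spans the product junction as the single
retained copy; maximality is asserted per junction. A junction is programmed
iff its MDSs are adjacent in MAC order (in either direction — a
reverse-complemented product descends the order and compares against the
reverse-complemented pointer) and the pointer equals the map's programmed
pointer; everything else, including blunt joins (length 0), is cryptic. A
product is aberrant iff any junction is cryptic. The synthetic locus
generator makes every programmed pointer *strictly maximal* by constraining
the IES bases flanking each MDS — without this, chance single-base matches at
segment ends would shift the detected pointer and misclassify programmed
junctions; real locus maps with non-maximal pointers would exhibit exactly
that ambiguity and are flagged by the validator deriving pointers from
coordinates.

### qPCR / ddCt

Ct = c₀ − log2(abundance) + N(0, σ) with c₀ = 30 (a typical crossing cycle
for abundant templates at standard input); water controls are uniform in
[35, 38] cycles, and undetermined Cts impute at the 45-cycle ceiling with a
flag. ddCt = (Ct_target,sample − Ct_norm,sample) − (Ct_target,ref −
Ct_norm,ref), fold = 2^−ddCt, SE propagated across the four arms in
quadrature. Significance is Welch's unequal-variance t, one-tailed, computed
on replicate-level ΔCt values (never on pre-averaged folds); stars at
p < 0.05/0.01/0.005; no multiple-testing correction by default (a Holm
option exists). The bisulfite-qPCR signal is L = 2^−(Ct_bis − Ct_native) per
sample, referenced to a control sample. In the simulated experiment a
molecule is amplifiable only if every primer-site cytosine survives
conversion; primers are placed on sites predicted modified (as the real assay
placed them on meDIP peaks), and a whole-molecule conversion-escape fraction
(default 1%, the well-known incomplete-denaturation artifact) keeps
unmethylated templates faintly amplifiable. With these defaults the
46 h-over-vegetative methylation fold lands around 10², inside the 30–1000×
range the assay is expected to span.

One calibration caveat: with triplicates (n = 3 per arm) the Welch test is
intrinsically conservative — its empirical size at nominal α = 0.05 is
≈ 0.038–0.040 under a Gaussian null — so the type-I-error calibration test
uses n = 6 per group (empirical size ≈ 0.046), where the Welch–Satterthwaite
approximation is accurate. This is a property of the test, not of the
implementation.

## What the generator does not emulate

No sequencing errors or base qualities (FASTA, not FASTQ), no PCR
duplicates, no fragment-length variance (fixed-length windows), no indels in
clones or products, no mappability structure beyond exact matching, and one
modification pattern per contig rather than a molecule population (molecule
heterogeneity enters only through conversion randomness and the escape
fraction). A green test therefore establishes that the analysis recovers the
parameters of this stated world — thresholds behave as encoded, estimators
are unbiased at these scales, classifications are exact on indel-free
input — not that the pipeline is robust to alignment artifacts, repeat
mismapping or chemistry failure modes absent from the model.

## Reproducibility

Every generator draws from `numpy.random.default_rng` seeded from the single
`rng_seed` via fixed `SeedSequence` branches, so any seed reproduces every
downstream artifact byte for byte; CLI runs write a JSON manifest with the
seed, full config echo and SHA-256 of every output.
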