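"""End-to-end pipeline on the synthetic world and report/plot generation.

``run_pipeline`` exercises every stage in analysis order: genome and
modification-track generation, the six IP libraries, RPKM/signal
normalization, germline-contig extraction, motif threshold calibration and
scanning, cohort calling with the Venn overlap, bisulfite clone calling with
conversion QC, rearrangement-product junction annotation, and ddCt
quantification. ``write_report`` emits the TSV/JSON bundle and the scatter,
signal and track plots.
"""

from __future__ import annotations

import json
import os
import warnings

import numpy as np
import pandas as pd

from . import bisulfite, cohorts, germline, io, junctions, medip, motifs, qpcr, synth

__all__ = ["run_pipeline", "write_report"]


def run_pipeline(
    config: synth.SimulationConfig,
    emit_reads_for: tuple[str, str] | None = ("mC", "46h"),
    n_products: int = 100,
    product_error_rate: float = 0.3,
    n_clones: int = 20,
) -> dict:
    """Run the full analysis on a freshly generated synthetic dataset.

    Returns a results dictionary holding the genome, tracks, signal table,
    germline classification, motif scan, cohort assignments, bisulfite
    report, junction calls and qPCR fold-change tables, plus the ground
    truth needed to score each stage.
    """
    config.validate()
    genome = synth.generate_genome(config)
    track_46h = synth.plant_modifications(genome, config)
    track_veg = synth.ModificationTrack.all_unmodified(genome)
    lengths = genome.lengths()

    libraries: dict[tuple[str, str], medip.LibraryCounts] = {}
    reads = None
    for ab in synth.ANTIBODIES:
        for tp in synth.TIMEPOINTS:
            track = track_46h if tp == "46h" else track_veg
            emit = emit_reads_for == (ab, tp)
            counts, lib_reads = synth.simulate_medip_library(
                genome, track, ab, tp, config, emit_reads=emit
            )
            if emit:
                reads = lib_reads
            libraries[(ab, tp)] = medip.LibraryCounts(
                library_id=f"{ab}_{tp}",
                antibody=ab,
                timepoint=tp,
                counts=counts,
                total_mapped=int(counts.sum()),
                lengths=lengths,
            )

    signal_table = medip.build_signal_table(libraries)

    telomere_flags = pd.Series(
        {
            cid: germline.detect_telomere(seq, config.telomere_unit)
            for cid, seq in genome.sequences().items()
        }
    )
    points = signal_table.rename(
        columns={"rpkm_igg_veg": "rpkm_veg", "rpkm_igg_46h": "rpkm_46h"}
    )[["rpkm_veg", "rpkm_46h"]]
    fit = germline.fit_enrichment_populations(points)
    labels = germline.classify_mic_contigs(fit, telomere_flags)
    mac_ids = labels.index[labels["label"] == "MAC"]
    mac_table = signal_table.loc[signal_table.index.isin(mac_ids)]

    mac_seqs = {r.id: r.sequence for r in genome.mac_records if r.id in set(mac_ids)}
    background = motifs.genome_background(mac_seqs)
    pwm = motifs.PositionWeightMatrix.from_consensus(
        config.motif_consensus, background=background, name="CC_motif"
    )
    threshold, achieved_tail, dist = motifs.calibrate_threshold(pwm, 1e-7)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        hits, motif_counts, clusters = motifs.scan_genome(
            pwm, mac_seqs, threshold, dist=dist, cluster_gap_bp=config.motif_cluster_gap_bp
        )

    mc_cohort = cohorts.build_methylation_cohort(mac_table)
    hmc_cohort = cohorts.build_hmc_cohort(mac_table)
    cc_cohort = cohorts.build_cc_cohort(motif_counts)
    venn = cohorts.cohort_overlap(mc_cohort, hmc_cohort, cc_cohort)
    cohort_tbl = cohorts.cohort_table(mac_table, motif_counts)

    # bisulfite validation on the top cohort chromosome's modified region
    bis_contig = genome.mac_records[0].id
    rstart, rend = genome.modified_regions[bis_contig]
    region = (bis_contig, rstart, rend)
    ref_region = genome.sequences()[bis_contig][rstart:rend]
    clones = synth.simulate_bisulfite_clones(genome, region, track_46h, n_clones, config)
    calls_by_clone = {}
    for clone_id, _strand, seq in clones:
        aln = bisulfite.align_clone(ref_region, seq)
        calls_by_clone[clone_id] = bisulfite.call_sites(
            aln,
            primer_intervals=[],
            contig=bis_contig,
            region_start=rstart,
            clone_id=clone_id,
        )
    bis_report = bisulfite.pool_report(calls_by_clone)
    # conversion control: vegetative (unmethylated) template
    control = synth.simulate_bisulfite_clones(
        genome, region, track_veg, max(4, n_clones // 4), config
    )
    control_calls = []
    for clone_id, _strand, seq in control:
        aln = bisulfite.align_clone(ref_region, seq)
        control_calls.extend(
            bisulfite.call_sites(aln, primer_intervals=[], clone_id=clone_id)
        )
    conv_fraction, conv_pass = bisulfite.conversion_qc(control_calls)

    # rearrangement products
    locus = genome.locus_maps[0]
    products, product_truth = synth.simulate_rearrangement_products(
        locus, n_products, product_error_rate, config
    )
    junction_calls = {}
    product_classes = {}
    for pid, seq in products:
        segs = junctions.tile_product(seq, locus)
        jcalls = junctions.find_junctions(segs, locus, seq, product_id=pid)
        cls, _summary = junctions.classify_product(jcalls)
        junction_calls[pid] = jcalls
        product_classes[pid] = cls

    # bisulfite-qPCR methylation signal: 46 h vs vegetative fold
    bis_qpcr = bisulfite_qpcr_experiment(genome, track_46h, track_veg, config)

    # qPCR: MIC retention under a demethylating drug + bisulfite signal
    rng = np.random.default_rng(np.random.SeedSequence([config.rng_seed, 7]))
    abundances = pd.DataFrame(
        [
            {"target": "mito_rDNA", "sample": "s1", "treatment": "untreated", "template": "native", "abundance": 1.0},
            {"target": "mito_rDNA", "sample": "s1", "treatment": "treated", "template": "native", "abundance": 1.0},
            {"target": "satellite_170bp", "sample": "s1", "treatment": "untreated", "template": "native", "abundance": 1.0},
            {"target": "satellite_170bp", "sample": "s1", "treatment": "treated", "template": "native", "abundance": 2.0},
        ]
    )
    ct_table = synth.simulate_qpcr(abundances, replicates=3, noise_sd=0.15, config=config, rng=rng)
    fold_table = qpcr.fold_change_table(
        ct_table[ct_table["target"] != "water"], reference_treatment="untreated"
    )

    return {
        "config": config,
        "genome": genome,
        "track_46h": track_46h,
        "libraries": libraries,
        "reads": reads,
        "signal_table": signal_table,
        "telomere_flags": telomere_flags,
        "fit": fit,
        "labels": labels,
        "mac_table": mac_table,
        "pwm": pwm,
        "motif_threshold": threshold,
        "motif_achieved_tail": achieved_tail,
        "motif_hits": hits,
        "motif_counts": motif_counts,
        "motif_clusters": clusters,
        "mc_cohort": mc_cohort,
        "hmc_cohort": hmc_cohort,
        "cc_cohort": cc_cohort,
        "venn": venn,
        "cohort_table": cohort_tbl,
        "bisulfite_report": bis_report,
        "bisulfite_region": region,
        "conversion_fraction": conv_fraction,
        "conversion_pass": conv_pass,
        "products": products,
        "product_truth": product_truth,
        "junction_calls": junction_calls,
        "product_classes": product_classes,
        "ct_table": ct_table,
        "fold_table": fold_table,
        "bisulfite_qpcr": bis_qpcr,
    }


def bisulfite_qpcr_experiment(
    genome: synth.GenomeModel,
    track_46h: synth.ModificationTrack,
    track_veg: synth.ModificationTrack,
    config: synth.SimulationConfig,
    n_molecules: int = 3000,
    amplicon_len: int = 200,
    primer_len: int = 20,
) -> pd.DataFrame:
    """Simulated bisulfite-qPCR: loss of signal induced by conversion.

    An amplicon inside the modified region of the top cohort chromosome is
    "amplified" from simulated bisulfite molecules: a molecule is amplifiable
    only when every primer-site cytosine is retained (cytosine-retaining
    primers). Primers are placed the way the real assay places them — on
    sites predicted to be modified — by choosing the amplicon whose primer
    cytosines are all modified in the 46 h track. The retained fraction per
    timepoint becomes the bisulfite template abundance in a noiseless Ct
    simulation, normalized per sample to its native template, giving the
    46 h-over-vegetative methylation fold.
    """
    contig = genome.mac_records[0].id
    rstart, rend = genome.modified_regions[contig]
    seq = genome.sequences()[contig]

    def primer_sites(a: int, b: int) -> list[int]:
        return [
            i
            for i in list(range(a, a + primer_len)) + list(range(b - primer_len, b))
            if seq[i] == "C"
        ]

    best = None
    for a_start in range(rstart, rend - amplicon_len, 10):
        a_end = a_start + amplicon_len
        sites = primer_sites(a_start, a_end)
        n_mod = sum(
            1 for i in sites if track_46h.states[contig][(i, "+")] != "U"
        )
        score = (len(sites) > 0 and n_mod == len(sites), n_mod, -a_start)
        if best is None or score > best[0]:
            best = (score, a_start, a_end, sites)
    _score, a_start, a_end, primer_cs = best
    fractions = {}
    for sample, track in (("veg", track_veg), ("46h", track_46h)):
        clones = synth.simulate_bisulfite_clones(
            genome,
            (contig, a_start, a_end),
            track,
            n_molecules,
            config,
            strands="+",
            molecule_escape=True,
        )
        n_ok = sum(
            1
            for _cid, _s, cseq in clones
            if all(cseq[i - a_start] == "C" for i in primer_cs)
        )
        fractions[sample] = max(n_ok, 1) / n_molecules
    c0 = config.qpcr_c0
    ct_bis = {s: [c0 - np.log2(f)] * 3 for s, f in fractions.items()}
    ct_native = {s: [c0] * 3 for s in fractions}
    return qpcr.bisulfite_methylation_signal(ct_bis, ct_native, control_sample="veg")


def depth_track(
    reads: list[tuple[str, str, str, int]], contig: str, length: int, bin_bp: int = 25
) -> pd.DataFrame:
    """Per-window read-start counts for one contig (sums to its read count)."""
    n_bins = (length + bin_bp - 1) // bin_bp
    counts = np.zeros(n_bins, dtype=int)
    for _rid, _seq, cid, start in reads:
        if cid == contig:
            counts[start // bin_bp] += 1
    return pd.DataFrame(
        {
            "start": np.arange(n_bins) * bin_bp,
            "end": np.minimum((np.arange(n_bins) + 1) * bin_bp, length),
            "depth": counts,
        }
    )


def write_report(results: dict, outdir: str, make_plots: bool = True) -> list[str]:
    """Write the TSV/JSON report bundle (and plots) for a pipeline run."""
    os.makedirs(outdir, exist_ok=True)
    files = []

    def out(name: str) -> str:
        path = os.path.join(outdir, name)
        files.append(path)
        return path

    io.write_tsv(out("signal_table.tsv"), results["signal_table"].reset_index())
    io.write_tsv(out("germline_labels.tsv"), results["labels"].reset_index())
    io.write_tsv(out("cohort_table.tsv"), results["cohort_table"].reset_index())
    with open(out("venn.json"), "w") as fh:
        json.dump(results["venn"], fh, indent=2)
    io.write_bed(
        out("motif_hits.bed"),
        [
            (h.contig, h.position, h.position + results["pwm"].width, results["pwm"].name,
             int(round(h.score * 100)), h.strand)
            for h in results["motif_hits"]
        ],
    )
    io.write_tsv(
        out("motif_counts.tsv"),
        results["motif_counts"].rename("n_motifs").rename_axis("contig").reset_index(),
    )
    with open(out("motif_clusters.json"), "w") as fh:
        json.dump(results["motif_clusters"], fh, indent=2)

    junction_rows = []
    for pid, calls in results["junction_calls"].items():
        for j in calls:
            junction_rows.append(
                {
                    "product_id": pid,
                    "left_mds": j.left.mds_index,
                    "right_mds": j.right.mds_index,
                    "pointer": j.pointer_sequence,
                    "pointer_length": j.pointer_length,
                    "class": j.junction_class,
                    "order_preserved": j.order_preserved,
                    "product_class": results["product_classes"][pid],
                }
            )
    io.write_tsv(out("junctions.tsv"), pd.DataFrame(junction_rows))
    io.write_tsv(out("qpcr_folds.tsv"), results["fold_table"])

    rep = results["bisulfite_report"]
    io.write_tsv(
        out("bisulfite_report.tsv"),
        pd.DataFrame(
            [
                {
                    "strand": s,
                    "n_meth": rep.n_meth.get(s, 0),
                    "n_unmeth": rep.n_unmeth.get(s, 0),
                    "percent_methylated": rep.percent_by_strand.get(s),
                }
                for s in ("+", "-")
            ]
        ),
    )
    runs = pd.Series(rep.skip_run_lengths, dtype=int).value_counts().sort_index()
    io.write_tsv(
        out("skip_run_histogram.tsv"),
        runs.rename("n_runs").rename_axis("run_length").reset_index(),
    )

    # per-window depth track for the top cohort chromosome, with motif marks
    if results["reads"] is not None:
        contig = results["genome"].mac_records[0].id
        track = depth_track(
            results["reads"], contig, int(results["signal_table"].loc[contig, "length"])
        )
        io.write_tsv(out(f"track_{contig}.tsv"), track)

    if make_plots:
        _plots(results, outdir, files)
    return files


def _plots(results: dict, outdir: str, files: list[str]) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    st = results["signal_table"]
    labels = results["labels"]

    fig, ax = plt.subplots(figsize=(5, 5))
    for label, color in (("MAC", "tab:red"), ("MIC", "tab:blue"), ("ambiguous", "grey")):
        sel = labels.index[labels["label"] == label]
        sub = st.loc[st.index.isin(sel)]
        ax.scatter(sub["rpkm_igg_veg"], sub["rpkm_igg_46h"], s=8, label=label, color=color)
    lim = max(st["rpkm_igg_veg"].max(), st["rpkm_igg_46h"].max())
    ax.plot([0, lim], [0, lim], "k--", lw=0.8)
    fit = results["fit"]
    if np.isfinite(fit.slope_mic):
        ax.plot([0, lim], [0, lim * fit.slope_mic], "b--", lw=0.8)
    ax.set_xlabel("IgG vegetative (RPKM)")
    ax.set_ylabel("IgG 46 h (RPKM)")
    ax.legend()
    path = os.path.join(outdir, "scatter_igg.png")
    fig.savefig(path, dpi=100)
    plt.close(fig)
    files.append(path)

    fig, ax = plt.subplots(figsize=(5, 5))
    mac = results["mac_table"]
    ax.scatter(mac["signal_igg"], mac["signal_mc"], s=8, color="tab:red")
    ax.axhline(0, color="k", lw=0.5)
    ax.axvline(0, color="k", lw=0.5)
    ax.set_xlabel("IgG signal (RPKM)")
    ax.set_ylabel("mC signal (RPKM)")
    path = os.path.join(outdir, "signal_mc_vs_igg.png")
    fig.savefig(path, dpi=100)
    plt.close(fig)
    files.append(path)

    if results["reads"] is not None:
        contig = results["genome"].mac_records[0].id
        track = depth_track(
            results["reads"], contig, int(st.loc[contig, "length"])
        )
        fig, ax = plt.subplots(figsize=(7, 2.5))
        ax.fill_between(track["start"], track["depth"], step="post", color="tab:red")
        for h in results["motif_hits"]:
            if h.contig == contig:
                ax.annotate(
                    "",
                    xy=(h.position, 0),
                    xytext=(h.position, -max(track["depth"]) * 0.12),
                    arrowprops={"arrowstyle": "-|>", "color": "purple"},
                    annotation_clip=False,
                )
        ax.set_xlabel(f"{contig} position (bp)")
        ax.set_ylabel("read starts")
        fig.tight_layout()
        path = os.path.join(outdir, f"track_{contig}.png")
        fig.savefig(path, dpi=100)
        plt.close(fig)
        files.append(path)
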