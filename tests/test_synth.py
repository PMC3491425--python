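"""Unit and property tests for the synthetic-data generators."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from oxymark.errors import ConfigurationError, CoordinateError, InputError
from oxymark.junctions import revcomp
from oxymark.synth import (
    ModificationTrack,
    SimulationConfig,
    generate_genome,
    plant_modifications,
    simulate_bisulfite_clones,
    simulate_medip_library,
    simulate_qpcr,
    simulate_rearrangement_products,
)


def _single_contig_config(length=10_000, **kw):
    defaults = dict(
        n_mac_chromosomes=1,
        n_cohort_chromosomes=1,
        n_hmc_only_chromosomes=0,
        mac_length_mean_bp=length,
        modified_region_fraction=0.9,
        mic_contigs=[],
        rng_seed=3,
    )
    defaults.update(kw)
    return SimulationConfig(**defaults)


class TestGenerateGenome:
    def test_mac_records_are_telomere_capped(self, small_world):
        _, genome, _ = small_world
        for rec in genome.mac_records:
            assert rec.sequence.startswith("GGGGTTTTGGGGTTTT")
            assert rec.sequence.endswith("AAAACCCCAAAACCCC")

    def test_satellite_is_exact_tandem_array(self):
        cfg = SimulationConfig(
            n_mac_chromosomes=1,
            n_cohort_chromosomes=0,
            n_hmc_only_chromosomes=0,
            mic_contigs=[("satellite", 170, 1700)],
            rng_seed=0,
        )
        genome = generate_genome(cfg)
        sat = genome.mic_records[0]
        unit = sat.sequence[:170]
        assert sat.sequence == unit * 10
        assert "GGGGTTTTGGGGTTTT" not in sat.sequence[:50]

    def test_same_seed_is_byte_identical(self):
        cfg = SimulationConfig(n_mac_chromosomes=5, n_cohort_chromosomes=2,
                               n_hmc_only_chromosomes=1, rng_seed=42)
        g1 = generate_genome(cfg)
        g2 = generate_genome(SimulationConfig(n_mac_chromosomes=5, n_cohort_chromosomes=2,
                                              n_hmc_only_chromosomes=1, rng_seed=42))
        assert g1.sequences() == g2.sequences()
        assert g1.motif_truth == g2.motif_truth

    def test_cohort_chromosomes_carry_clustered_motifs(self, small_world):
        cfg, genome, _ = small_world
        by_contig = {}
        for cid, pos, _strand in genome.motif_truth:
            by_contig.setdefault(cid, []).append(pos)
        cohort = [r.id for r in genome.mac_records if r.cohort_truth_flag]
        for cid in cohort:
            positions = sorted(by_contig[cid])
            assert len(positions) >= cfg.motifs_per_cohort_chrom
            gaps = np.diff(positions)
            assert (gaps <= cfg.motif_cluster_gap_bp + len(cfg.motif_consensus)).all()
            # planted instances really are in the sequence
            seq = genome.sequences()[cid]
            for cid2, pos, strand in genome.motif_truth:
                if cid2 != cid:
                    continue
                inst = seq[pos : pos + len(cfg.motif_consensus)]
                want = cfg.motif_consensus if strand == "+" else revcomp(cfg.motif_consensus)
                assert inst == want

    @pytest.mark.parametrize(
        "field,value",
        [
            ("mod_density_fwd", 1.5),
            ("polyteny_fold", 0.5),
            ("n_reads_per_library", 0),
            ("conversion_rate", -0.1),
            ("motif_consensus", "CCNN"),
        ],
    )
    def test_invalid_config_names_field(self, field, value):
        cfg = SimulationConfig(**{field: value})
        with pytest.raises(ConfigurationError):
            cfg.validate()


class TestPlantModifications:
    def test_density_one_modifies_every_cytosine(self):
        cfg = _single_contig_config(2000, mod_density_fwd=1.0, mod_density_rev=1.0)
        genome = generate_genome(cfg)
        track = plant_modifications(genome, cfg)
        cid = genome.mac_records[0].id
        rstart, rend = genome.modified_regions[cid]
        in_region = [
            s for (pos, _), s in track.states[cid].items() if rstart <= pos < rend
        ]
        assert all(s != "U" for s in in_region)

    def test_density_zero_is_all_unmodified(self):
        cfg = _single_contig_config(2000, mod_density_fwd=0.0, mod_density_rev=0.0)
        genome = generate_genome(cfg)
        track = plant_modifications(genome, cfg)
        cid = genome.mac_records[0].id
        assert set(track.states[cid].values()) == {"U"}

    def test_density_recovery_on_10kb_region(self):
        # per-strand empirical modified fraction within +-0.03 of 0.91 / 0.84
        cfg = _single_contig_config(12_000)
        genome = generate_genome(cfg)
        track = plant_modifications(genome, cfg)
        cid = genome.mac_records[0].id
        rstart, rend = genome.modified_regions[cid]
        assert rend - rstart >= 10_000
        for strand, target in (("+", 0.91), ("-", 0.84)):
            states = [
                s
                for (pos, st), s in track.states[cid].items()
                if st == strand and rstart <= pos < rend
            ]
            frac = np.mean([s != "U" for s in states])
            assert abs(frac - target) <= 0.03

    def test_skip_runs_truncated_at_eight(self):
        cfg = _single_contig_config(50_000)
        genome = generate_genome(cfg)
        track = plant_modifications(genome, cfg)
        cid = genome.mac_records[0].id
        rstart, rend = genome.modified_regions[cid]
        for strand in "+-":
            sites = sorted(
                pos
                for (pos, st) in track.states[cid]
                if st == strand and rstart <= pos < rend
            )
            run = 0
            for pos in sites:
                if track.states[cid][(pos, strand)] == "U":
                    run += 1
                    assert run <= 8
                else:
                    run = 0

    def test_skip_run_law_matches_truncated_geometric(self):
        # total-variation distance <= 0.1 from the stated law at ~1e4 runs
        cfg = _single_contig_config(600_000, mod_density_fwd=0.91, mod_density_rev=0.91)
        genome = generate_genome(cfg)
        track = plant_modifications(genome, cfg)
        cid = genome.mac_records[0].id
        rstart, rend = genome.modified_regions[cid]
        runs = []
        for strand in "+-":
            sites = sorted(
                pos
                for (pos, st) in track.states[cid]
                if st == strand and rstart <= pos < rend
            )
            current = 0
            for pos in sites:
                if track.states[cid][(pos, strand)] == "U":
                    current += 1
                else:
                    if current:
                        runs.append(current)
                    current = 0
        assert len(runs) >= 10_000
        emp = np.bincount(runs, minlength=9)[1:9] / len(runs)
        ks = np.arange(1, 9)
        p = cfg.skip_run_geometric_p
        theory = (1 - p) ** (ks - 1) * p
        theory = theory / theory.sum()
        assert 0.5 * np.abs(emp - theory).sum() <= 0.1

    def test_hmc_fraction_split(self, small_world):
        cfg, genome, track = small_world
        cid = genome.mac_records[0].id
        mods = [s for s in track.states[cid].values() if s != "U"]
        frac = np.mean([s == "hmC" for s in mods])
        assert abs(frac - cfg.hmc_fraction) < 0.1
        hmc_only = genome.mac_records[cfg.n_cohort_chromosomes].id
        mods = [s for s in track.states[hmc_only].values() if s != "U"]
        assert set(mods) == {"hmC"}


class TestMedipLibrary:
    def _uniform_world(self, n_contigs=4, length=1300, seed=9):
        cfg = SimulationConfig(
            n_mac_chromosomes=n_contigs,
            n_cohort_chromosomes=0,
            n_hmc_only_chromosomes=0,
            mac_length_mean_bp=length,
            mic_contigs=[],
            mac_abundance_sigma=0.0,
            n_reads_per_library=100_000,
            rng_seed=seed,
        )
        # equal-length contigs: override with copies of one sequence
        genome = generate_genome(cfg)
        from oxymark.synth import MacRecord

        base = genome.mac_records[0].sequence
        genome.mac_records = [
            MacRecord(f"mac{i:04d}", base, False) for i in range(n_contigs)
        ]
        return cfg, genome

    def test_uniform_null_chi_square(self):
        # alpha = gamma = 0, identical contigs -> uniform multinomial
        cfg, genome = self._uniform_world()
        cfg.antibody_affinity = {"IgG": 0.0, "mC": 0.0, "hmC": 0.0}
        cfg.crossreact_gamma = 0.0
        track = ModificationTrack.all_unmodified(genome)
        counts, _ = simulate_medip_library(genome, track, "mC", "46h", cfg)
        assert counts.sum() == cfg.n_reads_per_library
        _, p = stats.chisquare(counts.to_numpy())
        assert p > 0.01

    def test_vegetative_null_across_antibodies(self):
        # at veg every antibody library has the same expected proportions
        cfg, genome = self._uniform_world(n_contigs=6)
        track = ModificationTrack.all_unmodified(genome)
        c_mc, _ = simulate_medip_library(genome, track, "mC", "veg", cfg)
        c_igg, _ = simulate_medip_library(genome, track, "IgG", "veg", cfg)
        table = np.vstack([c_mc.to_numpy(), c_igg.to_numpy()])
        _, p, _, _ = stats.chi2_contingency(table)
        assert p > 0.01

    def test_polyteny_ratio_five(self):
        # MIC contig at 5x copy number vs equal-composition MAC contig:
        # IgG 46h/veg count ratio within 3 binomial SE of 5
        cfg = SimulationConfig(
            n_mac_chromosomes=2,
            n_cohort_chromosomes=0,
            n_hmc_only_chromosomes=0,
            mac_length_mean_bp=1300,
            mic_contigs=[],
            mac_abundance_sigma=0.0,
            mic_abundance_sigma=0.0,
            n_reads_per_library=100_000,
            rng_seed=7,
        )
        genome = generate_genome(cfg)
        from oxymark.synth import MacRecord, MicRecord

        core = genome.mac_records[0].sequence[16:-16]
        genome.mac_records = [MacRecord("macA", genome.mac_records[0].sequence, False)]
        genome.mic_records = [MicRecord("micA", core, "transposon", 5.0)]
        track = ModificationTrack.all_unmodified(genome)
        c46, _ = simulate_medip_library(genome, track, "IgG", "46h", cfg)
        cveg, _ = simulate_medip_library(genome, track, "IgG", "veg", cfg)
        # compare MIC share odds between timepoints
        ratio = (c46["micA"] / c46["macA"]) / (cveg["micA"] / cveg["macA"])
        se = ratio * np.sqrt(sum(1.0 / c for c in [c46["micA"], c46["macA"], cveg["micA"], cveg["macA"]]))
        assert abs(ratio - 5.0) <= 3 * se

    def test_ip_model_identifiability_three_contig_toy(self):
        # E[count_mC - count_IgG] proportional to alpha * modified content x copy,
        # against the closed-form multinomial expectation
        cfg = SimulationConfig(
            n_mac_chromosomes=3,
            n_cohort_chromosomes=2,
            n_hmc_only_chromosomes=0,
            mac_length_mean_bp=1300,
            mic_contigs=[],
            mac_abundance_sigma=0.0,
            hmc_fraction=0.0,
            mod_density_fwd=1.0,
            mod_density_rev=1.0,
            n_reads_per_library=400_000,
            rng_seed=13,
        )
        genome = generate_genome(cfg)
        track = plant_modifications(genome, cfg)
        c_mc, _ = simulate_medip_library(genome, track, "mC", "46h", cfg)
        c_igg, _ = simulate_medip_library(genome, track, "IgG", "46h", cfg)
        n = cfg.n_reads_per_library
        frag = cfg.fragment_len_bp
        alpha = cfg.antibody_affinity["mC"]
        expected = {}
        for ab, out in (("mC", {}), ("IgG", {})):
            a = alpha if ab == "mC" else 0.0
            weights = {}
            for rec in genome.mac_records:
                seq = rec.sequence
                w = 0.0
                for start in range(len(seq) - frag + 1):
                    fragment = seq[start : start + frag]
                    n_c = fragment.count("C") + fragment.count("G")
                    n_mod = sum(
                        1
                        for i in range(start, start + frag)
                        if track.states[rec.id].get((i, "+"), "U") == "mC"
                        or track.states[rec.id].get((i, "-"), "U") == "mC"
                    )
                    w += cfg.background_beta + cfg.crossreact_gamma * n_c + a * n_mod
                weights[rec.id] = w
            total = sum(weights.values())
            for cid, w in weights.items():
                out[cid] = n * w / total
            expected[ab] = out
        for cid in c_mc.index:
            diff = c_mc[cid] - c_igg[cid]
            want = expected["mC"][cid] - expected["IgG"][cid]
            sd = np.sqrt(expected["mC"][cid] + expected["IgG"][cid])
            assert abs(diff - want) <= 4 * sd

    def test_conservation_and_determinism(self, small_world):
        cfg, genome, track = small_world
        c1, _ = simulate_medip_library(genome, track, "hmC", "46h", cfg)
        c2, _ = simulate_medip_library(genome, track, "hmC", "46h", cfg)
        assert c1.sum() == cfg.n_reads_per_library
        assert (c1 == c2).all()


class TestBisulfiteClones:
    def test_full_conversion_all_u(self):
        cfg = _single_contig_config(2000, mod_density_fwd=0.0, mod_density_rev=0.0,
                                    conversion_rate=1.0)
        genome = generate_genome(cfg)
        track = plant_modifications(genome, cfg)
        cid = genome.mac_records[0].id
        clones = simulate_bisulfite_clones(genome, (cid, 100, 600), track, 2, cfg, strands="+")
        for _id, _s, seq in clones:
            assert "C" not in seq

    def test_fully_modified_identical_to_reference(self):
        cfg = _single_contig_config(2000, mod_density_fwd=1.0, mod_density_rev=1.0)
        genome = generate_genome(cfg)
        track = plant_modifications(genome, cfg)
        cid = genome.mac_records[0].id
        rstart, rend = genome.modified_regions[cid]
        ref = genome.sequences()[cid][rstart : rstart + 500]
        clones = simulate_bisulfite_clones(
            genome, (cid, rstart, rstart + 500), track, 4, cfg
        )
        for _id, _s, seq in clones:
            assert seq == ref

    def test_unconverted_fraction_tail_bound(self):
        # at conversion 0.995 and ~1e4 cytosines the unconverted fraction <= 1%
        cfg = _single_contig_config(60_000, mod_density_fwd=0.0, mod_density_rev=0.0,
                                    conversion_rate=0.995)
        genome = generate_genome(cfg)
        track = plant_modifications(genome, cfg)
        cid = genome.mac_records[0].id
        seq = genome.sequences()[cid][0:55_000]
        n_c = seq.count("C")
        assert n_c >= 10_000
        clones = simulate_bisulfite_clones(genome, (cid, 0, 55_000), track, 1, cfg, strands="+")
        unconverted = clones[0][2].count("C")
        assert unconverted / n_c <= 0.01

    def test_empty_region_raises(self, small_world):
        cfg, genome, track = small_world
        with pytest.raises(CoordinateError):
            simulate_bisulfite_clones(genome, ("mac0000", 50, 50), track, 1, cfg)


class TestRearrangementProducts:
    def test_error_rate_zero_gives_mac_sequence(self, small_world):
        cfg, genome, _ = small_world
        locus = genome.locus_maps[0]
        products, truth = simulate_rearrangement_products(locus, 5, 0.0, cfg)
        for (_pid, seq), tr in zip(products, truth):
            assert seq == locus.mac_sequence()
            assert tr["class"] == "correct"

    def test_aberrant_fraction_binomial(self, small_world):
        cfg, genome, _ = small_world
        locus = genome.locus_maps[0]
        _, truth = simulate_rearrangement_products(locus, 100, 0.3, cfg)
        frac = np.mean([t["class"] == "aberrant" for t in truth])
        se = np.sqrt(0.3 * 0.7 / 100)
        assert abs(frac - 0.3) <= 3 * se

    def test_cryptic_pointer_lengths(self, small_world):
        cfg, genome, _ = small_world
        locus = genome.locus_maps[0]
        _, truth = simulate_rearrangement_products(locus, 60, 1.0, cfg)
        for t in truth:
            (_ptr, length, cls) = t["junctions"][0]
            assert cls == "cryptic"
            assert length in (3, 4)


class TestQpcrSimulation:
    def _table(self, abundances):
        return pd.DataFrame(
            [
                {"target": f"t{i}", "sample": "s", "treatment": "u",
                 "template": "native", "abundance": a}
                for i, a in enumerate(abundances)
            ]
        )

    def test_doubling_abundance_drops_ct_by_one(self):
        table = simulate_qpcr(self._table([1.0, 2.0]), replicates=1, noise_sd=0.0,
                              include_water_controls=False)
        cts = table.set_index("target")["ct"]
        assert cts["t0"] - cts["t1"] == pytest.approx(1.0)

    def test_equal_abundances_identical_cts(self):
        table = simulate_qpcr(self._table([3.0, 3.0]), replicates=3, noise_sd=0.0,
                              include_water_controls=False)
        assert table["ct"].nunique() == 1

    def test_noise_sd_chi_square_interval(self):
        table = simulate_qpcr(self._table([1.0]), replicates=1000, noise_sd=0.2,
                              include_water_controls=False)
        assert 0.17 <= table["ct"].std(ddof=1) <= 0.23

    def test_water_controls_in_range(self):
        table = simulate_qpcr(self._table([1.0]), replicates=3, noise_sd=0.0)
        water = table[table["target"] == "water"]["ct"]
        assert ((water >= 35) & (water <= 38)).all()

    def test_nonpositive_abundance_raises(self):
        with pytest.raises(InputError):
            simulate_qpcr(self._table([0.0]))
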