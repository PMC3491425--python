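"""Tests for read counting, RPKM and vegetative-subtracted signal."""

import numpy as np
import pandas as pd
import pytest

from oxymark import medip
from oxymark.errors import InputError, PairingError, ReferenceMismatchError
from oxymark.medip import LibraryCounts, compute_rpkm, compute_signal, count_reads
from oxymark.synth import ModificationTrack, simulate_medip_library


def _lib(counts, total=None, lengths=None, antibody="mC", timepoint="46h"):
    counts = pd.Series(counts)
    if lengths is None:
        lengths = pd.Series(1000, index=counts.index)
    if total is None:
        total = int(counts.sum())
    return LibraryCounts("lib", antibody, timepoint, counts, total, lengths)


class TestComputeRpkm:
    @pytest.mark.parametrize(
        "count,length,total,expected",
        [
            (10, 1000, 1_000_000, 10.0),
            (0, 500, 123, 0.0),
            (50, 2500, 5_000_000, 4.0),
        ],
    )
    def test_values(self, count, length, total, expected):
        assert compute_rpkm(count, length, total) == pytest.approx(expected)

    def test_zero_length_or_total_raises(self):
        with pytest.raises(InputError):
            compute_rpkm(1, 0, 100)
        with pytest.raises(InputError):
            compute_rpkm(1, 100, 0)

    def test_read_duplication_invariance(self):
        # doubling count and total together leaves RPKM unchanged
        assert compute_rpkm(20, 1500, 2_000_000) == pytest.approx(
            compute_rpkm(10, 1500, 1_000_000)
        )


class TestCountReads:
    def _write_sam(self, path, lengths, rows):
        header = "\n".join(
            ["@HD\tVN:1.6\tSO:unsorted"]
            + [f"@SQ\tSN:{c}\tLN:{l}" for c, l in lengths.items()]
        )
        with open(path, "w") as fh:
            fh.write(header + "\n")
            for name, flag, ref, pos, seq in rows:
                fh.write(
                    f"{name}\t{flag}\t{ref}\t{pos}\t60\t{len(seq)}M\t*\t0\t0\t{seq}\t*\n"
                )

    def test_sam_primary_only(self, tmp_path):
        lengths = pd.Series({"contigA": 500, "contigB": 400})
        path = tmp_path / "reads.sam"
        self._write_sam(
            path,
            lengths,
            [
                ("r1", 0, "contigA", 1, "ACGT"),
                ("r2", 0, "contigA", 10, "ACGT"),
                ("r3", 16, "contigA", 20, "ACGT"),
                ("r4", 4, "*", 0, "ACGT"),  # unmapped
                ("r5", 256, "contigB", 5, "ACGT"),  # secondary
            ],
        )
        lib = count_reads(str(path), lengths, "lib", "IgG", "veg")
        assert lib.counts["contigA"] == 3
        assert lib.counts["contigB"] == 0
        assert lib.total_mapped == 3

    def test_empty_sam_all_zero(self, tmp_path):
        lengths = pd.Series({"contigA": 500})
        path = tmp_path / "empty.sam"
        self._write_sam(path, lengths, [])
        lib = count_reads(str(path), lengths, "lib", "IgG", "veg")
        assert lib.total_mapped == 0
        assert (lib.counts == 0).all()
        with pytest.raises(InputError):
            compute_rpkm(0, 500, lib.total_mapped)

    def test_unknown_contig_raises(self, tmp_path):
        lengths = pd.Series({"contigA": 500})
        path = tmp_path / "bad.sam"
        self._write_sam(
            path,
            pd.Series({"contigA": 500, "other": 100}),
            [("r1", 0, "other", 1, "ACGT")],
        )
        with pytest.raises(ReferenceMismatchError):
            count_reads(str(path), lengths, "lib", "IgG", "veg")

    def test_tsv_round_trip(self, tmp_path):
        lengths = pd.Series({"a": 100, "b": 200})
        path = tmp_path / "counts.tsv"
        path.write_text("#total=7\na\t3\nb\t4\n")
        lib = count_reads(str(path), lengths, "lib", "mC", "46h")
        assert lib.counts.to_dict() == {"a": 3, "b": 4}
        assert lib.total_mapped == 7

    def test_synthetic_library_sam_round_trip(self, small_world):
        # regenerate -> exact-map -> SAM -> count == generator's table
        cfg, genome, track = small_world
        import copy

        cfg = copy.deepcopy(cfg)
        cfg.n_reads_per_library = 10_000
        counts, reads = simulate_medip_library(
            genome, track, "IgG", "veg", cfg, emit_reads=True
        )
        sequences = genome.sequences()
        mapped = medip.map_reads_exact([(rid, seq) for rid, seq, _c, _p in reads], sequences)
        assert all(c is not None for _r, c, _p in mapped)
        lengths = genome.lengths()
        import tempfile, os

        with tempfile.TemporaryDirectory() as d:
            sam = os.path.join(d, "lib.sam")
            medip.write_sam(sam, mapped, {rid: seq for rid, seq, _c, _p in reads}, lengths)
            lib = count_reads(sam, lengths, "lib", "IgG", "veg")
        assert lib.total_mapped == 10_000
        assert (lib.counts.sort_index() == counts.sort_index()).all()


class TestComputeSignal:
    def test_signal_arithmetic(self):
        lib46 = _lib({"a": 25}, total=2_000_000, lengths=pd.Series({"a": 1000}))
        libveg = _lib({"a": 5}, total=2_000_000, lengths=pd.Series({"a": 1000}))
        sig = compute_signal(lib46, libveg)
        assert sig.loc["a", "rpkm_46h"] == pytest.approx(12.5)
        assert sig.loc["a", "signal"] == pytest.approx(10.0)
        assert sig.loc["a", "excess_reads"] == 20

    def test_identical_libraries_zero_signal(self):
        lib = _lib({"a": 10, "b": 20})
        sig = compute_signal(lib, lib)
        assert (sig["signal"] == 0).all()
        assert (sig["excess_reads"] == 0).all()

    def test_antibody_mismatch_raises(self):
        with pytest.raises(PairingError):
            compute_signal(_lib({"a": 1}, antibody="mC"), _lib({"a": 1}, antibody="hmC"))

    def test_contig_set_mismatch_raises(self):
        with pytest.raises(PairingError):
            compute_signal(_lib({"a": 1}), _lib({"b": 1}))

    def test_antisymmetry(self):
        lib46 = _lib({"a": 30, "b": 4}, total=100)
        libveg = _lib({"a": 9, "b": 11}, total=100)
        fwd = compute_signal(lib46, libveg)
        rev = compute_signal(libveg, lib46)
        assert np.allclose(fwd["signal"], -rev["signal"])

    def test_excess_depth_normalization_rounding(self):
        # count_veg scaled by total ratio, then rounded half away from zero
        lib46 = _lib({"a": 10}, total=200)
        libveg = _lib({"a": 3}, total=100)
        sig = compute_signal(lib46, libveg)
        assert sig.loc["a", "excess_reads"] == 4  # 10 - 3*2

    def test_null_veg_signal_centered_at_zero(self, small_world):
        cfg, genome, _track = small_world
        veg_track = ModificationTrack.all_unmodified(genome)
        libs = {}
        import numpy as np

        for i, tp in enumerate(("veg", "46h")):
            rng = np.random.default_rng(100 + i)
            counts, _ = simulate_medip_library(genome, veg_track, "mC", "veg", cfg, rng=rng)
            libs[tp] = LibraryCounts(tp, "mC", tp, counts, int(counts.sum()), genome.lengths())
        sig = compute_signal(libs["46h"], libs["veg"])
        excess = sig["excess_reads"].to_numpy(float)
        se = np.sqrt(2 * libs["veg"].counts.to_numpy(float).clip(min=1))
        assert abs(excess.mean()) < 2 * se.mean() / np.sqrt(len(excess))


class TestProperties:
    from hypothesis import given, settings
    from hypothesis import strategies as st

    @given(
        count=st.integers(min_value=0, max_value=10**6),
        length=st.integers(min_value=1, max_value=10**5),
        total=st.integers(min_value=1, max_value=10**7),
    )
    @settings(max_examples=100, derandomize=True)
    def test_rpkm_duplication_invariance(self, count, length, total):
        # duplicating every read (count and total x2) leaves RPKM unchanged
        assert compute_rpkm(2 * count, length, 2 * total) == pytest.approx(
            compute_rpkm(count, length, total)
        )

    @given(
        c46=st.lists(st.integers(min_value=0, max_value=1000), min_size=2, max_size=6),
        cveg=st.lists(st.integers(min_value=0, max_value=1000), min_size=2, max_size=6),
    )
    @settings(max_examples=50, derandomize=True)
    def test_signal_antisymmetry(self, c46, cveg):
        n = min(len(c46), len(cveg))
        idx = [f"c{i}" for i in range(n)]
        lib46 = _lib(dict(zip(idx, c46[:n])), total=sum(c46[:n]) + 1)
        libveg = _lib(dict(zip(idx, cveg[:n])), total=sum(cveg[:n]) + 1)
        fwd = compute_signal(lib46, libveg)
        rev = compute_signal(libveg, lib46)
        assert np.allclose(fwd["signal"], -rev["signal"])


def test_build_signal_table_columns(default_run):
    table = default_run["signal_table"]
    assert list(table.columns) == medip.SIGNAL_COLUMNS[1:]
    assert table.notna().all().all()
    rpkm_cols = [c for c in table.columns if c.startswith("rpkm")]
    assert (table[rpkm_cols] >= 0).all().all()
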