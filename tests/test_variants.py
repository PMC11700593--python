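import gzip
import shutil

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bottlescan.simdata import make_fixture
from bottlescan.variants import (FilterConfig, LDPruneConfig, MISSING,
                                 VariantTable, apply_site_filters, ld_prune,
                                 ld_prune_violations, r2, read_vcf, write_vcf)

VCF_TEXT = """\
##fileformat=VCFv4.2
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##contig=<ID=chr1,length=10000>
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1\ts2
chr1\t100\t.\tA\tG\t50\t.\t.\tGT\t0/0\t0/1
chr1\t200\t.\tC\tT\t60\t.\t.\tGT\t1/1\t./.
chr1\t300\t.\tG\tA\t.\t.\t.\tGT\t0/1\t1/1
"""


class TestReadVcf:
    def test_small_fixture(self, tmp_path):
        p = tmp_path / "a.vcf"
        p.write_text(VCF_TEXT)
        vt = read_vcf(p)
        assert vt.n_sites == 3 and vt.samples == ["s1", "s2"]
        assert vt.dosage.tolist() == [[0, 1], [2, MISSING], [1, 2]]
        assert vt.pos.tolist() == [100, 200, 300]
        assert np.isnan(vt.qual[2]) and vt.qual[0] == 50

    def test_gzip_identical(self, tmp_path):
        p = tmp_path / "a.vcf"
        p.write_text(VCF_TEXT)
        gz = tmp_path / "a.vcf.gz"
        with open(p, "rb") as fin, gzip.open(gz, "wb") as fout:
            shutil.copyfileobj(fin, fout)
        assert read_vcf(p).equals(read_vcf(gz))

    def test_unsorted_positions_error(self, tmp_path):
        bad = VCF_TEXT.replace("chr1\t300", "chr1\t150")
        p = tmp_path / "bad.vcf"
        p.write_text(bad)
        with pytest.raises(ValueError, match="unsorted"):
            read_vcf(p)

    def test_unknown_contig_error(self, tmp_path):
        bad = VCF_TEXT.replace("chr1\t300", "chr9\t300")
        p = tmp_path / "bad.vcf"
        p.write_text(bad)
        with pytest.raises(ValueError):
            read_vcf(p)

    def test_roundtrip_write_read(self, tmp_path, toy_table):
        toy_table.qual = np.array([40.0, 50.0, np.nan, 30.0, 99.0])
        toy_table.depth = np.full((5, 3), 9, dtype=np.int32)
        toy_table.depth[1, 2] = -1
        p = tmp_path / "rt.vcf"
        write_vcf(toy_table, p)
        back = read_vcf(p)
        assert back.equals(toy_table)


class TestSiteFilters:
    def _table(self, dosages, depth=None, qual=None):
        n, k = dosages.shape
        return VariantTable(
            chrom=np.array(["chr1"] * n, dtype=object),
            pos=np.arange(1, n + 1) * 1000,
            ref=np.array(["A"] * n, dtype=object),
            alt=np.array(["G"] * n, dtype=object),
            dosage=dosages,
            samples=[f"s{i}" for i in range(k)],
            qual=qual,
            depth=depth,
        )

    def test_maf_removal(self):
        # 25 samples, 2 het carriers -> alt frequency 2/50 = 0.04 < 0.05
        d = np.zeros((1, 25), dtype=np.int8)
        d[0, :2] = 1
        out, rep = apply_site_filters(self._table(d), FilterConfig())
        assert out.n_sites == 0 and rep.removed["maf"] == 1

    def test_missingness_removal(self):
        # 17/20 present = 0.85 < 0.9; make MAF pass otherwise
        d = np.array([[0] * 7 + [1] * 10 + [-1] * 3], dtype=np.int8)
        out, rep = apply_site_filters(self._table(d), FilterConfig())
        assert out.n_sites == 0 and rep.removed["missingness"] == 1

    def test_depth_masking_before_missingness(self):
        d = np.array([[1] * 10 + [0] * 10], dtype=np.int8)
        depth = np.full((1, 20), 10, dtype=np.int32)
        depth[0, :3] = 2  # masked -> 17/20 present -> missingness failure
        out, rep = apply_site_filters(self._table(d, depth=depth), FilterConfig())
        assert out.n_sites == 0 and rep.removed["missingness"] == 1

    def test_qual_and_mean_depth(self):
        d = np.array([[1] * 6 + [0] * 6, [1] * 6 + [0] * 6], dtype=np.int8)
        qual = np.array([10.0, 60.0])
        depth = np.full((2, 12), 6, dtype=np.int32)
        depth[1, :] = 4  # mean depth 4 < 5, but calls also masked by minDP
        out, rep = apply_site_filters(
            self._table(d, depth=depth, qual=qual), FilterConfig()
        )
        assert out.n_sites == 0
        assert rep.removed["qual"] == 1

    def test_idempotent(self):
        rng = np.random.default_rng(0)
        d = rng.choice([0, 1, 2, -1], size=(60, 12), p=[0.4, 0.3, 0.2, 0.1]).astype(np.int8)
        cfg = FilterConfig()
        once, _ = apply_site_filters(self._table(d), cfg)
        twice, rep2 = apply_site_filters(once, cfg)
        assert twice.equals(once)
        assert sum(rep2.removed.values()) == 0

    def test_empty_table_warning(self):
        empty = self._table(np.zeros((0, 3), dtype=np.int8))
        out, rep = apply_site_filters(empty, FilterConfig())
        assert out.n_sites == 0 and rep.warnings


class TestR2:
    def test_identical_vectors(self, toy_table):
        t = make_fixture({"chr1": ([10, 20], {"a": "01", "b": "11", "c": "21",
                                              "d": "00", "e": "22"})})
        # site0 and a duplicate of itself
        t2 = make_fixture({"chr1": ([10, 20], {"a": "00", "b": "11", "c": "22",
                                               "d": "01", "e": "10"})})
        assert r2(t2, 0, 1) == pytest.approx(
            np.corrcoef([0, 1, 2, 0, 1], [0, 1, 2, 1, 0])[0, 1] ** 2
        )

    def test_hand_computed_zero(self):
        t = make_fixture({"chr1": ([10, 20], {"a": "00", "b": "01", "c": "10",
                                              "d": "11"})})
        assert r2(t, 0, 1) == pytest.approx(0.0)

    def test_perfect_correlation(self):
        t = make_fixture({"chr1": ([10, 20], {"a": "00", "b": "11", "c": "22"})})
        assert r2(t, 0, 1) == pytest.approx(1.0)

    def test_monomorphic_undefined(self):
        t = make_fixture({"chr1": ([10, 20], {"a": "00", "b": "01", "c": "02"})})
        assert np.isnan(r2(t, 0, 1))

    def test_independent_sites_near_zero(self):
        rng = np.random.default_rng(1)
        x = rng.choice([0, 1, 2], size=2000)
        y = rng.choice([0, 1, 2], size=2000)
        vt = VariantTable(
            chrom=np.array(["chr1", "chr1"], dtype=object),
            pos=np.array([10, 20]),
            ref=np.array(["A", "A"], dtype=object),
            alt=np.array(["G", "G"], dtype=object),
            dosage=np.stack([x, y]).astype(np.int8),
            samples=[f"s{i}" for i in range(2000)],
        )
        assert r2(vt, 0, 1) < 0.01


class TestLDPrune:
    def test_duplicate_site_one_kept(self):
        t = make_fixture({"chr1": ([100, 200], {"a": "00", "b": "11", "c": "22"})})
        kept = ld_prune(t)
        assert kept.tolist() == [0]  # equal MAF -> drop larger position

    def test_all_below_threshold_all_kept(self):
        rng = np.random.default_rng(2)
        d = rng.choice([0, 1, 2], size=(5, 200)).astype(np.int8)
        t = VariantTable(
            chrom=np.array(["chr1"] * 5, dtype=object),
            pos=np.array([100, 300, 500, 700, 900]),
            ref=np.array(["A"] * 5, dtype=object),
            alt=np.array(["G"] * 5, dtype=object),
            dosage=d,
            samples=[f"s{i}" for i in range(200)],
        )
        assert len(ld_prune(t)) == 5

    @pytest.mark.parametrize("seed", range(6))
    def test_postcondition_scan_random(self, seed):
        rng = np.random.default_rng(seed)
        n = 30
        base = rng.choice([0, 1, 2], size=(12,))
        d = np.empty((n, 12), dtype=np.int8)
        for i in range(n):
            if rng.random() < 0.5:  # correlated with base
                d[i] = np.where(rng.random(12) < 0.8, base, rng.choice([0, 1, 2], 12))
            else:
                d[i] = rng.choice([0, 1, 2], size=12)
        t = VariantTable(
            chrom=np.array(["chr1"] * n, dtype=object),
            pos=np.sort(rng.choice(np.arange(1, 30_000), n, replace=False)),
            ref=np.array(["A"] * n, dtype=object),
            alt=np.array(["G"] * n, dtype=object),
            dosage=d,
            samples=[f"s{i}" for i in range(12)],
        )
        cfg = LDPruneConfig()
        kept = ld_prune(t, cfg)
        assert ld_prune_violations(t, kept, cfg) == []
        # deterministic
        assert ld_prune(t, cfg).tolist() == kept.tolist()

    def test_empty_input(self):
        t = make_fixture({})
        assert len(ld_prune(t)) == 0


@settings(max_examples=25, deadline=None)
@given(st.lists(st.sampled_from("012."), min_size=1, max_size=20))
def test_make_fixture_roundtrips_symbols(symbols):
    g = "".join(symbols)
    t = make_fixture({"chr1": (list(range(1, len(g) + 1)), {"s": g})})
    expect = [-1 if ch == "." else int(ch) for ch in g]
    assert t.dosage[:, 0].tolist() == expect
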