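"""Readers, writers, map interpolation and haplotype subsetting."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from lrldscan.haplotype_io import (
    GeneticMap,
    RegionSet,
    Site,
    attach_map,
    read_genetic_map,
    read_hap_legend,
    read_phased_vcf,
    read_regions,
    read_patches,
    subset_haplotypes,
    write_hap_legend,
    write_patches,
)
from lrldscan.scan import ScanConfig, scan_chromosome
from conftest import make_panel


VCF_HEADER = """##fileformat=VCFv4.2
##contig=<ID=chr1>
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\tS2\tS3
"""


def write_vcf(tmp_path, body):
    p = tmp_path / "panel.vcf"
    p.write_text(VCF_HEADER + body)
    return str(p)


class TestVcfReader:
    def test_dimensions_and_order(self, tmp_path):
        path = write_vcf(
            tmp_path,
            "chr1\t100\trs1\tA\tG\t.\t.\t.\tGT\t0|1\t1|1\t0|0\n"
            "chr1\t200\trs2\tC\tT\t.\t.\t.\tGT\t1|0\t0|0\t0|1\n",
        )
        hm = read_phased_vcf(path, "chr1")
        assert hm.alleles.shape == (6, 2)
        assert [s.bp for s in hm.sites] == [100, 200]
        assert hm.alleles[:, 0].tolist() == [0, 1, 1, 1, 0, 0]

    def test_unphased_is_hard_error(self, tmp_path):
        path = write_vcf(tmp_path, "chr1\t100\trs1\tA\tG\t.\t.\t.\tGT\t0/1\t1|1\t0|0\n")
        with pytest.raises(ValueError, match="unphased"):
            read_phased_vcf(path, "chr1")

    def test_missing_is_hard_error(self, tmp_path):
        path = write_vcf(tmp_path, "chr1\t100\trs1\tA\tG\t.\t.\t.\tGT\t.|.\t1|1\t0|0\n")
        with pytest.raises(ValueError, match="missing"):
            read_phased_vcf(path, "chr1")

    def test_monomorphic_dropped(self, tmp_path):
        path = write_vcf(
            tmp_path,
            "chr1\t100\trs1\tA\tG\t.\t.\t.\tGT\t0|0\t0|0\t0|0\n"
            "chr1\t200\trs2\tC\tT\t.\t.\t.\tGT\t1|0\t0|0\t0|1\n",
        )
        hm = read_phased_vcf(path, "chr1")
        assert [s.id for s in hm.sites] == ["rs2"]


class TestHapLegend:
    def test_round_trip_equals_vcf_reader(self, tmp_path):
        vcf = write_vcf(
            tmp_path,
            "chr1\t100\trs1\tA\tG\t.\t.\t.\tGT\t0|1\t1|1\t0|0\n"
            "chr1\t200\trs2\tC\tT\t.\t.\t.\tGT\t1|0\t0|0\t0|1\n",
        )
        hm_vcf = read_phased_vcf(vcf, "chr1")
        write_hap_legend(hm_vcf, str(tmp_path / "p.hap"), str(tmp_path / "p.legend"))
        hm_hl = read_hap_legend(str(tmp_path / "p.hap"), str(tmp_path / "p.legend"), "chr1")
        assert np.array_equal(hm_vcf.alleles, hm_hl.alleles)
        assert [s.bp for s in hm_vcf.sites] == [s.bp for s in hm_hl.sites]

    def test_dimensions(self, tmp_path):
        legend = tmp_path / "l.legend"
        legend.write_text("id pos a0 a1\n" + "".join(f"s{k} {100 * (k + 1)} A G\n" for k in range(5)))
        rng = np.random.default_rng(1)
        rows = ["".join(f"{v} " for v in rng.integers(0, 2, 120)) for _ in range(5)]
        hap = tmp_path / "l.hap"
        hap.write_text("\n".join(rows) + "\n")
        hm = read_hap_legend(str(hap), str(legend))
        assert hm.n_hap == 120 and hm.n_site <= 5

    def test_bad_token_and_row_mismatch(self, tmp_path):
        legend = tmp_path / "l.legend"
        legend.write_text("id pos a0 a1\ns1 100 A G\ns2 200 A G\n")
        hap = tmp_path / "l.hap"
        hap.write_text("0 1 2 0\n1 0 1 0\n")
        with pytest.raises(ValueError, match="non-binary"):
            read_hap_legend(str(hap), str(legend))
        hap.write_text("0 1 1 0\n")
        with pytest.raises(ValueError, match="row"):
            read_hap_legend(str(hap), str(legend))


class TestGeneticMap:
    def test_read_two_anchor_map(self, tmp_path):
        p = tmp_path / "m.map"
        p.write_text("position\trate\tcM\n1000\t1.0\t0.0\n1001000\t1.0\t1.0\n")
        gm = read_genetic_map(str(p))
        assert len(gm.anchors) == 2

    def test_single_row_and_decreasing_cm_rejected(self, tmp_path):
        p = tmp_path / "m.map"
        p.write_text("position\trate\tcM\n1000\t1.0\t0.0\n")
        with pytest.raises(ValueError):
            read_genetic_map(str(p))
        p.write_text("position\trate\tcM\n1000\t1.0\t1.0\n2000\t1.0\t0.5\n")
        with pytest.raises(ValueError):
            read_genetic_map(str(p))

    def test_interpolation_examples(self):
        gm = GeneticMap(((1000, 0.0), (2000, 1.0)))
        assert gm.interpolate([1500])[0] == pytest.approx(0.5)
        assert gm.interpolate([2000])[0] == pytest.approx(1.0)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_matches_piecewise_linear_oracle(self, seed):
        rng = np.random.default_rng(seed)
        bp = np.sort(rng.choice(np.arange(1, 10_000_000), size=6, replace=False))
        cm = np.cumsum(rng.uniform(0, 1, size=6))
        gm = GeneticMap(tuple(zip(bp.tolist(), cm.tolist())))
        qs = rng.integers(bp[0], bp[-1] + 1, size=10)
        for q in qs:
            k = np.searchsorted(bp, q, side="right") - 1
            k = min(k, len(bp) - 2)
            want = cm[k] + (q - bp[k]) * (cm[k + 1] - cm[k]) / (bp[k + 1] - bp[k])
            assert gm.interpolate([q])[0] == pytest.approx(want, abs=1e-12)

    def test_extrapolation_uses_terminal_rate_floored_at_zero(self):
        gm = GeneticMap(((1_000_000, 1.0), (2_000_000, 2.0)))
        # 1 cM/Mb on both ends; 0.5 Mb beyond each end
        assert gm.interpolate([2_500_000])[0] == pytest.approx(2.5)
        assert gm.interpolate([500_000])[0] == pytest.approx(0.5)
        gm2 = GeneticMap(((500_000, 0.1), (1_500_000, 1.1)))
        assert gm2.interpolate([1])[0] == 0.0  # would be negative; floored

    def test_attach_map_sets_monotone_cm(self, tmp_path):
        hm = make_panel([[0, 1, 0], [1, 0, 1], [0, 1, 1], [1, 0, 0]], bps=[10, 500_000, 1_200_000])
        gm = GeneticMap(((1, 0.0), (1_000_000, 1.0)))
        out = attach_map(hm, gm)
        cm = out.cm
        assert np.all(np.diff(cm) >= 0)
        assert cm[1] == pytest.approx(0.499999, rel=1e-4)


class TestSubset:
    def test_identity_and_composition(self, mosaic_panel):
        hm = mosaic_panel
        same = subset_haplotypes(hm, list(hm.haplotype_ids))
        assert np.array_equal(same.alleles, hm.alleles)
        a = subset_haplotypes(hm, hm.haplotype_ids[:30])
        b = subset_haplotypes(a, hm.haplotype_ids[:20])
        direct = subset_haplotypes(hm, hm.haplotype_ids[:20])
        assert np.array_equal(b.alleles, direct.alleles)
        assert [s.id for s in b.sites] == [s.id for s in direct.sites]

    def test_single_carrier_site_dropped(self):
        alleles = np.zeros((6, 2), dtype=np.int8)
        alleles[0, 0] = 1  # site 0 carried only by H0
        alleles[:3, 1] = 1
        hm = make_panel(alleles)
        sub = subset_haplotypes(hm, ["H1", "H2", "H3", "H4"])
        assert [s.id for s in sub.sites] == ["s1"]

    def test_too_few_or_unknown_ids(self, mosaic_panel):
        with pytest.raises(ValueError):
            subset_haplotypes(mosaic_panel, mosaic_panel.haplotype_ids[:3])
        with pytest.raises(ValueError, match="unknown"):
            subset_haplotypes(mosaic_panel, ["nope"] + mosaic_panel.haplotype_ids[:3])


class TestRegionsAndPatches:
    def test_bed_reading(self, tmp_path):
        p = tmp_path / "r.bed"
        p.write_text("chr1\t100\t200\nchr2\t5\t10\textra\n")
        rs = read_regions(str(p))
        assert rs.intervals[0] == ("chr1", 100, 200)
        p.write_text("")
        assert len(read_regions(str(p))) == 0
        p.write_text("chr1\t100\n")
        with pytest.raises(ValueError, match=":1"):
            read_regions(str(p))

    def test_patch_table_round_trip(self, tmp_path, mosaic_panel):
        res = scan_chromosome(mosaic_panel, ScanConfig(p_cap=5e-3, n_1=5))
        path = str(tmp_path / "patches.tsv")
        write_patches(res.patches, path, mosaic_panel.chromosome)
        df = read_patches(path)
        assert len(df) == len(res.patches)
        assert df["n_pairs"].tolist() == [len(p) for p in res.patches]
        assert np.allclose(df["min_p"], [p.min_p for p in res.patches], rtol=1e-9)
        assert df["left_bp_min"].tolist() == [p.left_span_bp[0] for p in res.patches]
        assert df["extreme_left_id"].tolist() == [p.extreme_left_id for p in res.patches]


class TestInvariants:
    def test_site_bp_positive(self):
        with pytest.raises(ValueError):
            Site("bad", 0)

    def test_region_start_before_end(self):
        with pytest.raises(ValueError):
            RegionSet([("chr1", 5, 5)])
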