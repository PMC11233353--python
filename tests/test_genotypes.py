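"""VCF ingestion, the marker QC chain and marker summary statistics."""

import textwrap

import numpy as np
import pandas as pd
import pytest

from tetragwas.genotypes import (QCThresholds, classify_location, density_bins,
                                 effect_summary, missense_silent_ratio,
                                 non_intergenic_percent, qc_filter,
                                 read_dosage_vcf, snp_rate, tstv)

from conftest import make_dosage_matrix

VCF_HEADER = textwrap.dedent("""\
    ##fileformat=VCFv4.2
    ##contig=<ID=chr01,length=1000000>
    ##INFO=<ID=QD,Number=1,Type=Float,Description="QualByDepth">
    ##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
    ##FORMAT=<ID=DS,Number=1,Type=Float,Description="Dosage">
    ##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Depth">
    ##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Quality">
    #CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\tS2
    """)


def write_vcf(tmp_path, body):
    p = tmp_path / "t.vcf"
    p.write_text(VCF_HEADER + textwrap.dedent(body))
    return p


class TestReadDosageVcf:
    def test_gt_to_dosage(self, tmp_path):
        p = write_vcf(tmp_path, """\
            chr01\t100\tm1\tA\tG\t50\tPASS\tQD=10\tGT\t1/1/1/1\t0/0/1/1
            chr01\t200\tm2\tC\tT\t50\tPASS\tQD=10\tGT\t./././.\t0/0/0/1
            """)
        dm = read_dosage_vcf(p)
        assert dm.values[0].tolist() == [4.0, 2.0]
        assert np.isnan(dm.values[1, 0]) and dm.values[1, 1] == 1.0

    def test_invalid_allele_code_rejected(self, tmp_path):
        p = write_vcf(tmp_path, """\
            chr01\t100\tm1\tA\tG\t50\tPASS\tQD=10\tGT\t0/1/1/2\t0/0/0/0
            """)
        with pytest.raises(ValueError, match="invalid allele"):
            read_dosage_vcf(p)

    def test_mixed_ploidy_rejected(self, tmp_path):
        p = write_vcf(tmp_path, """\
            chr01\t100\tm1\tA\tG\t50\tPASS\tQD=10\tGT\t0/1\t0/0/0/0
            """)
        with pytest.raises(ValueError, match="ploidy"):
            read_dosage_vcf(p)

    def test_multiallelic_excluded(self, tmp_path):
        p = write_vcf(tmp_path, """\
            chr01\t100\tm1\tA\tG,T\t50\tPASS\tQD=10\tGT\t0/0/0/0\t0/0/0/0
            chr01\t200\tm2\tC\tT\t50\tPASS\tQD=10\tGT\t0/0/1/1\t0/0/0/0
            """)
        dm = read_dosage_vcf(p)
        assert dm.n_markers == 1 and dm.markers.at[0, "id"] == "m2"

    def test_genotype_and_site_quality_filters(self, tmp_path):
        p = write_vcf(tmp_path, """\
            chr01\t100\tm1\tA\tG\t50\tPASS\tQD=10\tGT:DP:GQ\t1/1/1/1:5:99\t0/0/1/1:50:5
            chr01\t200\tm2\tC\tT\t50\tPASS\tQD=1.0\tGT:DP:GQ\t0/0/1/1:50:99\t0/0/0/1:50:99
            """)
        dm = read_dosage_vcf(p, thresholds=QCThresholds())
        assert dm.n_markers == 1                      # m2 dropped by QD
        assert np.isnan(dm.values[0]).all()           # low DP / low GQ masked

    def test_ds_used_when_gt_absent(self, tmp_path):
        p = write_vcf(tmp_path, """\
            chr01\t100\tm1\tA\tG\t50\tPASS\tQD=10\tDS\t3\t0
            """)
        dm = read_dosage_vcf(p)
        assert dm.values[0].tolist() == [3.0, 0.0]


class TestQcFilter:
    def test_toy_matrix_matches_hand_enumeration(self):
        # 10 markers x 10 samples with known violations
        nan = np.nan
        base = [1, 2, 0, 3, 1, 2, 4, 0, 1, 2]        # polymorphic, clean
        rows = [
            base,                                      # keep
            [2] * 10,                                  # monomorphic
            [nan, nan, nan] + base[3:],                # 30% missing
            [0] * 9 + [1],                             # maf = 1/40 = 0.025 keep
            [0] * 39 + [1],                            # (below, see maf_row)
            base,                                      # keep (duplicate ok)
            [nan] * 10,                                # all-missing -> monomorphic
            [0, 4, 0, 4, 0, 4, 0, 4, 0, 4],            # keep
            [1] * 9 + [2],                             # max geno freq 0.9 keep...
            [4, 4, 4, 4, 4, 4, 4, 4, 4, 0],            # maf 0.1? keep
        ]
        rows[4] = [0] * 10                             # monomorphic
        dm = make_dosage_matrix(rows)
        out, report = qc_filter(dm, QCThresholds(max_missing=0.2, min_maf=0.05,
                                                 max_geno_freq=0.85))
        # hand enumeration with these thresholds:
        # removed: r1 (mono), r4 (mono), r6 (mono), r2 (missing 0.3),
        #          r3 (maf 0.025 < 0.05), r8 and r9 (modal class freq 0.9 > 0.85)
        assert report.removed == {"monomorphic": 3, "missingness": 1,
                                  "maf": 1, "max_geno_freq": 2}
        assert out.n_markers == 3
        assert set(out.markers["id"]) == {"m0", "m5", "m7"}

    def test_monomorphic_attribution_precedes_geno_freq(self):
        dm = make_dosage_matrix([[2] * 10, [0, 1, 2, 3, 4, 0, 1, 2, 3, 4]])
        _, report = qc_filter(dm)
        assert report.removed["monomorphic"] == 1
        assert report.removed["max_geno_freq"] == 0

    def test_extreme_thresholds_only_monomorphic_removed(self, small_panel):
        t = QCThresholds(max_missing=1.0, min_maf=0.0, max_geno_freq=1.0)
        out, report = qc_filter(small_panel.dosages, t)
        assert report.removed["missingness"] == 0
        assert report.removed["maf"] == 0
        assert report.removed["max_geno_freq"] == 0
        assert out.n_markers == small_panel.dosages.n_markers \
            - report.removed["monomorphic"]

    def test_idempotent(self, small_panel):
        once, _ = qc_filter(small_panel.dosages)
        twice, report2 = qc_filter(once)
        assert sum(report2.removed.values()) == 0
        assert twice.n_markers == once.n_markers


class TestMarkerSummaries:
    def test_snp_rate_reference_rows(self):
        # chromosome-1 and whole-genome rows of a published tetraploid panel
        assert snp_rate(88_591_686, 15_190) == 5832
        assert snp_rate(741_585_035, 116_048) == 6390
        assert snp_rate(1000, 1) == 1000
        assert snp_rate(1000, 0) is None

    def test_density_bins_conservation_and_oracle(self):
        rng = np.random.default_rng(8)
        pos = np.sort(rng.integers(1, 10_000_000, size=500))
        markers = pd.DataFrame({"chrom": "chr01", "pos": pos})
        bins = density_bins(markers, bin_bp=1e6)
        assert bins["count"].sum() == 500
        expected = np.bincount(pos // 1_000_000)
        got = bins.set_index(bins["bin_start"] // 1_000_000)["count"]
        for k, e in enumerate(expected):
            assert got.get(k, 0) == e

    def test_tstv_tally(self):
        mk = pd.DataFrame({"ref": ["A", "C", "A", "G"],
                           "alt": ["G", "T", "C", "T"]})
        assert tstv(mk) == 1.0
        rng = np.random.default_rng(9)
        bases = np.array(list("ACGT"))
        ref = rng.choice(bases, 1000)
        alt = np.array([rng.choice([b for b in bases if b != r])
                        for r in ref])
        mk = pd.DataFrame({"ref": ref, "alt": alt})
        ts = sum((r, a) in {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}
                 for r, a in zip(ref, alt))
        assert tstv(mk) == pytest.approx(ts / (1000 - ts))

    def test_tstv_infinite_warns(self):
        mk = pd.DataFrame({"ref": ["A", "C"], "alt": ["G", "T"]})
        with pytest.warns(UserWarning):
            assert tstv(mk) == np.inf


class TestClassifyLocation:
    genes = pd.DataFrame({"chrom": ["chr01", "chr01"],
                          "start": [10_000, 50_000], "end": [20_000, 60_000]})

    def classify(self, positions):
        mk = pd.DataFrame({"chrom": "chr01", "pos": positions})
        return classify_location(mk, self.genes).tolist()

    def test_inside_gene_is_genic(self):
        assert self.classify([15_000]) == ["genic"]

    def test_flank_boundary_inclusive(self):
        # gene ends at 20_000: 25_000 is exactly 5 kb away -> associated;
        # 25_001 is beyond the flank -> intergenic
        assert self.classify([25_000, 25_001]) == ["gene_associated",
                                                   "intergenic"]

    def test_partitions_markers(self):
        rng = np.random.default_rng(10)
        pos = rng.integers(1, 100_000, size=200)
        mk = pd.DataFrame({"chrom": "chr01", "pos": pos})
        classes = classify_location(mk, self.genes)
        assert len(classes) == 200

        def oracle(p):
            for _, g in self.genes.iterrows():
                if g.start <= p <= g.end:
                    return "genic"
            for _, g in self.genes.iterrows():
                if g.start - 5000 <= p <= g.end + 5000:
                    return "gene_associated"
            return "intergenic"

        assert classes.tolist() == [oracle(p) for p in pos]


class TestEffectSummary:
    TYPE_COUNTS = {
        "3_prime_UTR_variant": 3849,
        "5_prime_UTR_premature_start_codon_gain_variant": 172,
        "5_prime_UTR_variant": 1246, "downstream_gene_variant": 52298,
        "initiator_codon_variant": 2, "intergenic_region": 20860,
        "intron_variant": 37281, "missense_variant": 24376,
        "splice_acceptor_variant": 44, "splice_donor_variant": 50,
        "splice_region_variant": 2430, "start_lost": 17, "stop_gained": 216,
        "stop_lost": 29, "stop_retained_variant": 26,
        "synonymous_variant": 28595, "upstream_gene_variant": 32301,
    }
    REGION_COUNTS = {
        "DOWNSTREAM": 52298, "EXON": 52915, "INTERGENIC": 20860,
        "INTRON": 35387, "SPLICE_SITE_ACCEPTOR": 44, "SPLICE_SITE_DONOR": 50,
        "SPLICE_SITE_REGION": 2181, "UPSTREAM": 32301, "UTR_3_PRIME": 3849,
        "UTR_5_PRIME": 1418,
    }

    def test_reference_percentages(self):
        tab = effect_summary(self.TYPE_COUNTS)
        assert tab.loc["downstream_gene_variant", "percent"] == 25.66
        assert tab["percent"].sum() == pytest.approx(100.0, abs=0.05)

    def test_non_intergenic_and_ratio(self):
        assert non_intergenic_percent(self.REGION_COUNTS) == 89.6
        assert missense_silent_ratio(45.86, 53.74) == 0.85

    def test_single_category_and_zero_total(self):
        assert effect_summary({"only": 7}).loc["only", "percent"] == 100.00
        with pytest.raises(ValueError):
            effect_summary({"a": 0})
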