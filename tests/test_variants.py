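"""Format IO, variant normalization and classification."""

import gzip

import numpy as np
import pytest

from conftest import make_record
from panscan.variants import (
    GeneModel,
    GenomicInterval,
    PafParseError,
    VariantRecord,
    VcfParseError,
    classify_variant,
    merge_intervals,
    read_bed,
    read_gff3_genes,
    read_paf,
    read_vcf,
    split_multiallelic,
    write_bed,
    write_vcf,
)


class TestReadVcf:
    def test_toy_vcf_round_trip_identity(self, toy_vcf):
        records, samples = read_vcf(toy_vcf)
        assert samples == ["S1", "S2", "S3"]
        assert len(records) == 2
        r = records[0]
        assert (r.chrom, r.pos, r.ref, r.alts) == ("1", 100, "A", ("G",))
        assert r.genotypes == {"S1": (0, 1), "S2": (1, 1), "S3": (None, None)}
        assert r.gq == {"S1": 30, "S2": 24, "S3": 10}
        assert r.info["SUPP_VEC"] == "101"
        assert r.phased

    def test_missing_genotype_convention(self, toy_vcf):
        records, _ = read_vcf(toy_vcf)
        assert records[0].genotypes["S3"] == (None, None)

    def test_truncated_line_raises_parse_error(self, tmp_path):
        bad = tmp_path / "bad.vcf"
        bad.write_text(
            "##fileformat=VCFv4.2\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="g">\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\n"
            "1\t100\t.\tA\tG\n"
        )
        with pytest.raises(VcfParseError):
            read_vcf(bad)

    def test_malformed_header_raises(self, tmp_path):
        bad = tmp_path / "bad.vcf"
        bad.write_text("##fileformat=VCFv4.2\n#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\n")
        with pytest.raises(VcfParseError):
            read_vcf(bad)


class TestWriteVcf:
    @pytest.mark.parametrize("gz", [False, True])
    def test_random_round_trip(self, rng, tmp_path, gz):
        samples = [f"S{i}" for i in range(4)]
        records = []
        for k in range(30):
            genos = {}
            for s in samples:
                if rng.random() < 0.1:
                    genos[s] = (None, None)
                else:
                    genos[s] = (int(rng.integers(2)), int(rng.integers(2)))
            ref = "ACGT"[int(rng.integers(4))]
            alt = ref
            while alt == ref:
                alt = "ACGT"[int(rng.integers(4))]
            records.append(
                make_record(
                    chrom="1", pos=100 + 10 * k, ref=ref, alts=(alt,),
                    genotypes=genos, phased=True,
                )
            )
        path = tmp_path / ("rt.vcf.gz" if gz else "rt.vcf")
        write_vcf(records, samples, path)
        back, back_samples = read_vcf(path)
        assert back_samples == samples
        for orig, new in zip(records, back):
            assert (orig.chrom, orig.pos, orig.ref, orig.alts) == (
                new.chrom, new.pos, new.ref, new.alts,
            )
            assert orig.genotypes == new.genotypes

    def test_supp_vec_survives_round_trip(self, tmp_path):
        rec = make_record(info={"SUPP_VEC": "0110"},
                          genotypes={"S1": (0, 1)}, phased=True)
        write_vcf([rec], ["S1"], tmp_path / "sv.vcf")
        back, _ = read_vcf(tmp_path / "sv.vcf")
        assert back[0].info["SUPP_VEC"] == "0110"


class TestSplitMultiallelic:
    def test_het_alt_recoding(self):
        # REF=A ALT=G,T with GT 1/2: in the G record allele 2 becomes missing,
        # in the T record allele 1 becomes missing
        rec = make_record(ref="A", alts=("G", "T"),
                          genotypes={"S1": (1, 2), "S2": (0, 1), "S3": (2, 2)})
        g_rec, t_rec = split_multiallelic(rec)
        assert g_rec.alt == "G" and t_rec.alt == "T"
        assert g_rec.genotypes == {"S1": (1, None), "S2": (0, 1), "S3": (None, None)}
        assert t_rec.genotypes == {"S1": (None, 1), "S2": (0, None), "S3": (1, 1)}

    def test_identical_ref_alt_rejected(self):
        rec = make_record(ref="AC", alts=("AC",))
        with pytest.raises(ValueError):
            split_multiallelic(rec)

    def test_biallelic_identity(self):
        rec = make_record(ref="A", alts=("G",), genotypes={"S1": (0, 1)})
        assert split_multiallelic(rec) == [rec]

    def test_shared_base_trimming(self):
        rec = make_record(pos=100, ref="CAT", alts=("CGT", "CAT" + "A" * 60))
        snv, ins = split_multiallelic(rec)
        # CAT->CGT trims to A->G at pos 101
        assert (snv.pos, snv.ref, snv.alt) == (101, "A", "G")
        # trailing-then-leading trim keeps the anchor base of the insertion
        assert ins.length_delta == 60

    def test_symbolic_alt_rejected(self):
        with pytest.raises(ValueError):
            make_record(ref="A", alts=("<DEL>",))


class TestClassifyVariant:
    @pytest.mark.parametrize(
        "ref,alt,kind",
        [
            ("A", "G", "SNV"),
            ("A", "A" + "C" * 49, "INDEL"),  # +49 bp: below the SV threshold
            ("A", "A" + "C" * 50, "SV_INS"),  # +50 bp: at the SV threshold
            ("A" + "C" * 50, "A", "SV_DEL"),
            ("AT", "A", "INDEL"),
        ],
    )
    def test_classification(self, ref, alt, kind):
        assert classify_variant(make_record(ref=ref, alts=(alt,))).kind == kind

    def test_every_biallelic_maps_to_exactly_one_class(self, rng):
        for _ in range(200):
            rl, al = int(rng.integers(1, 80)), int(rng.integers(1, 80))
            ref = "A" * rl
            alt = "C" * al
            vc = classify_variant(make_record(ref=ref, alts=(alt,)))
            assert vc.kind in vc.KINDS
            assert (abs(len(alt) - len(ref)) >= 50) == vc.is_sv


class TestPaf:
    PAF_LINE = "chr1\t1000\t0\t500\t+\tchr4\t2000\t100\t600\t450\t500\t60"

    def test_canonical_line(self, tmp_path):
        p = tmp_path / "a.paf"
        p.write_text(self.PAF_LINE + "\tcg:Z:500M\n")
        (rec,) = read_paf(p)
        assert rec.query_name == "chr1"
        assert (rec.query_start, rec.query_end) == (0, 500)
        assert (rec.target_name, rec.target_start, rec.target_end) == ("chr4", 100, 600)

    def test_inverted_interval_rejected(self, tmp_path):
        p = tmp_path / "b.paf"
        p.write_text("chr1\t1000\t500\t100\t+\tchr4\t2000\t100\t600\t450\t500\t60\n")
        with pytest.raises(PafParseError):
            read_paf(p)

    def test_empty_file(self, tmp_path):
        p = tmp_path / "c.paf"
        p.write_text("")
        assert read_paf(p) == []

    def test_non_integer_coordinate_names_line(self, tmp_path):
        p = tmp_path / "d.paf"
        p.write_text(self.PAF_LINE + "\n" + self.PAF_LINE.replace("1000", "10x0") + "\n")
        with pytest.raises(PafParseError, match="line 2"):
            read_paf(p)


GFF = """##gff-version 3
1\t.\tgene\t100\t500\t.\t+\t.\tID=gene1;Name=BOLA
1\t.\tmRNA\t100\t500\t.\t+\t.\tID=rna1;Parent=gene1
1\t.\texon\t100\t200\t.\t+\t.\tID=exon1;Parent=rna1
2\t.\tgene\t900\t1200\t.\t-\t.\tID=gene2
"""


class TestGff3:
    def test_genes_only(self, tmp_path):
        p = tmp_path / "g.gff3"
        p.write_text(GFF)
        genes = read_gff3_genes(p)
        assert [g.gene_id for g in genes] == ["gene1", "gene2"]
        assert {g.chrom for g in genes} == {"1", "2"}
        assert genes[0].start == 100 and genes[0].end == 500

    def test_inverted_gene_rejected(self):
        with pytest.raises(ValueError):
            GeneModel("g", "1", 500, 100)


class TestBed:
    def test_coordinate_conversion(self, tmp_path):
        p = tmp_path / "a.bed"
        write_bed([GenomicInterval("1", 101, 200)], p)
        assert p.read_text() == "1\t100\t200\n"

    def test_overlap_merge(self, tmp_path):
        p = tmp_path / "b.bed"
        write_bed([GenomicInterval("1", 5, 20), GenomicInterval("1", 1, 10)], p)
        assert p.read_text() == "1\t0\t20\n"

    def test_empty(self, tmp_path):
        p = tmp_path / "c.bed"
        write_bed([], p)
        assert p.read_text() == ""

    def test_output_disjoint_and_sorted(self, rng, tmp_path):
        ivs = [
            GenomicInterval(str(rng.integers(1, 3)), int(s), int(s + rng.integers(1, 50)))
            for s in rng.integers(1, 500, size=40)
        ]
        merged = merge_intervals(ivs)
        for a, b in zip(merged, merged[1:]):
            if a.chrom == b.chrom:
                assert a.end + 1 < b.start  # disjoint and not even adjacent
            else:
                assert a.chrom < b.chrom
        p = tmp_path / "d.bed"
        write_bed(ivs, p)
        assert read_bed(p) == merged


from hypothesis import given, settings, strategies as st


@settings(derandomize=True, max_examples=100)
@given(
    st.lists(
        st.tuples(
            st.sampled_from(["1", "2"]),
            st.integers(min_value=1, max_value=300),
            st.integers(min_value=1, max_value=60),
        ),
        max_size=25,
    )
)
def test_merge_intervals_is_a_sorted_disjoint_cover(raw):
    """The merged set is sorted, pairwise non-adjacent, covers every input
    base, and adds no base outside the inputs."""
    ivs = [GenomicInterval(c, s, s + l - 1) for c, s, l in raw]
    merged = merge_intervals(ivs)
    for a, b in zip(merged, merged[1:]):
        assert (a.chrom, a.start) <= (b.chrom, b.start)
        if a.chrom == b.chrom:
            assert a.end + 1 < b.start
    covered = {(iv.chrom, p) for iv in merged for p in range(iv.start, iv.end + 1)}
    original = {(iv.chrom, p) for iv in ivs for p in range(iv.start, iv.end + 1)}
    assert covered == original
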