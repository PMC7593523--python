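"""Region extraction: refFlat parsing, flank arithmetic, intergenic complement."""

import pytest

from dmrkit.genome_regions import (
    GeneModel,
    ParseError,
    extract_regions,
    read_chrom_sizes,
    read_refflat,
    read_region_bed,
    read_region_beds,
    write_region_beds,
)


def refflat_line(name="GENE1", tx="NM_1", chrom="chr1", strand="+", s=1000, e=5000):
    return f"{name}\t{tx}\t{chrom}\t{strand}\t{s}\t{e}\t{s}\t{e}\t1\t{s},\t{e},\n"


class TestReadRefflat:
    def test_field_mapping(self, tmp_path):
        p = tmp_path / "rf.txt"
        p.write_text(refflat_line())
        (g,) = read_refflat(p)
        assert g == GeneModel("GENE1", "NM_1", "chr1", "+", 1000, 5000)

    def test_empty_file(self, tmp_path):
        p = tmp_path / "rf.txt"
        p.write_text("")
        assert read_refflat(p) == []

    @pytest.mark.parametrize(
        "line",
        [
            refflat_line(s=5000, e=1000),  # start >= end
            refflat_line(strand="*"),
            "GENE1\tNM_1\tchr1\t+\tabc\t5000\t.\t.\t1\t,\t,\n",
        ],
    )
    def test_malformed_rows_name_the_line(self, tmp_path, line):
        p = tmp_path / "rf.txt"
        p.write_text(line)
        with pytest.raises(ParseError, match=":1"):
            read_refflat(p)

    def test_unknown_chromosome_dropped(self, tmp_path, sizes):
        p = tmp_path / "rf.txt"
        p.write_text(refflat_line() + refflat_line(name="G2", chrom="chrUn"))
        genes = read_refflat(p, sizes)
        assert [g.gene_name for g in genes] == ["GENE1"]


class TestExtractRegions:
    def by_class(self, regions):
        out = {}
        for r in regions:
            out.setdefault(r.region_class, []).append(r)
        return out

    def test_plus_strand_defaults(self, plus_gene, sizes):
        # gene chr1:10000-50000 '+': TSS [9000,11000), TES [49000,51000),
        # body [11000,49000), 5'distance [-90000,0) clips away entirely
        regions = self.by_class(extract_regions([plus_gene], sizes))
        (tss,) = regions["TSS"]
        (tes,) = regions["TES"]
        (body,) = regions["gene_body"]
        assert (tss.start, tss.end) == (9000, 11000)
        assert (tes.start, tes.end) == (49000, 51000)
        assert (body.start, body.end) == (11000, 49000)
        assert "five_prime_distance" not in regions
        assert all(r.gene_name == "GENE1" for r in (tss, tes, body))

    def test_minus_strand_swaps_and_upstream(self, minus_gene, sizes):
        regions = self.by_class(extract_regions([minus_gene], sizes))
        (tss,) = regions["TSS"]
        (tes,) = regions["TES"]
        (fpd,) = regions["five_prime_distance"]
        assert (tss.start, tss.end) == (49000, 51000)
        assert (tes.start, tes.end) == (9000, 11000)
        # upstream of a '-' TSS extends to higher coordinates, mirroring the
        # '+' definition [tss - far, tss - near): same 90 kb span
        assert (fpd.start, fpd.end) == (60000, 150000)

    def test_fpd_clipped_to_chrom_length(self, minus_gene):
        regions = self.by_class(extract_regions([minus_gene], {"chr1": 100_000}))
        (fpd,) = regions["five_prime_distance"]
        assert (fpd.start, fpd.end) == (60000, 100_000)

    def test_gene_free_chromosome_is_one_intergenic_candidate(self, plus_gene, sizes):
        regions = self.by_class(extract_regions([plus_gene], sizes))
        chr2 = [r for r in regions["intergenic"] if r.chrom == "chr2"]
        assert len(chr2) == 1
        assert (chr2[0].start, chr2[0].end) == (0, 30_000)

    def test_intergenic_truncate_vs_split(self, plus_gene, sizes):
        trunc = [
            r
            for r in extract_regions([plus_gene], sizes)
            if r.region_class == "intergenic" and r.chrom == "chr1" and r.start > 50000
        ]
        # tail gap [51000, 1e6) is 949 kb: truncated to first 100 kb
        assert len(trunc) == 1 and trunc[0].length == 100_000
        split = [
            r
            for r in extract_regions([plus_gene], sizes, intergenic_mode="split")
            if r.region_class == "intergenic" and r.chrom == "chr1" and r.start > 50000
        ]
        assert sum(r.length for r in split) == 1_000_000 - 51_000
        assert all(r.length <= 100_000 for r in split)

    def test_short_gene_has_no_body_but_keeps_flanks(self, sizes, caplog):
        short = GeneModel("S", "T", "chr1", "+", 10_000, 11_500)  # < 2 x 1 kb flanks
        regions = self.by_class(extract_regions([short], sizes))
        assert "gene_body" not in regions
        assert "TSS" in regions and "TES" in regions

    def test_order_independent_and_deduplicated(self, sizes, rng):
        genes = [
            GeneModel(f"G{i}", f"T{i}", "chr1", "+" if i % 2 else "-", 10_000 + 7000 * i, 15_000 + 7000 * i)
            for i in range(20)
        ]
        genes.append(genes[0])  # duplicate transcript
        a = extract_regions(genes, sizes)
        perm = [genes[i] for i in rng.permutation(len(genes))]
        b = extract_regions(perm, sizes)
        assert a == b
        assert len(a) == len(set(a))


def random_genome(rng):
    sizes = {f"chr{c}": int(rng.integers(200_000, 2_000_000)) for c in range(1, 4)}
    genes = []
    for i in range(int(rng.integers(1, 40))):
        chrom = f"chr{rng.integers(1, 4)}"
        start = int(rng.integers(0, sizes[chrom] - 10_000))
        length = int(rng.integers(500, 60_000))
        end = min(start + length, sizes[chrom] - 1)
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append(GeneModel(f"G{i}", f"T{i}", chrom, strand, start, end))
    return genes, sizes


def test_partition_invariants_on_random_genomes(rng):
    """Intergenic never overlaps genic classes; all regions in bounds."""
    for _ in range(30):
        genes, sizes = random_genome(rng)
        regions = extract_regions(genes, sizes)
        genic = [r for r in regions if r.region_class in ("TSS", "TES", "gene_body")]
        inter = [r for r in regions if r.region_class == "intergenic"]
        for r in regions:
            assert 0 <= r.start < r.end <= sizes[r.chrom]
        for i in inter:
            assert 2000 <= i.length <= 100_000
            for g in genic:
                if g.chrom == i.chrom:
                    assert g.end <= i.start or i.end <= g.start, (i, g)


def test_within_gene_disjointness(plus_gene, minus_gene, sizes):
    for gene in (plus_gene, minus_gene):
        rs = [
            r
            for r in extract_regions([gene], sizes)
            if r.region_class in ("TSS", "TES", "gene_body")
        ]
        assert len(rs) == 3
        for a in rs:
            for b in rs:
                if a != b:
                    assert a.end <= b.start or b.end <= a.start


class TestRegionBed:
    def test_basic_and_header(self, tmp_path):
        p = tmp_path / "enh.bed"
        p.write_text("track name=x\nchr1\t100\t900\n")
        (r,) = read_region_bed(p)
        assert (r.chrom, r.start, r.end, r.strand, r.region_class) == ("chr1", 100, 900, ".", "enhancer")

    def test_overlapping_rows_kept(self, tmp_path):
        p = tmp_path / "enh.bed"
        p.write_text("chr1\t100\t900\nchr1\t500\t1200\n")
        assert len(read_region_bed(p)) == 2

    def test_invalid_interval(self, tmp_path):
        p = tmp_path / "enh.bed"
        p.write_text("chr1\t900\t100\n")
        with pytest.raises(ParseError):
            read_region_bed(p)

    def test_write_read_round_trip(self, tmp_path, plus_gene, sizes):
        regions = extract_regions([plus_gene], sizes)
        write_region_beds(regions, tmp_path / "out")
        back = read_region_beds(tmp_path / "out")
        assert sorted(back) == sorted(regions)


def test_read_chrom_sizes(tmp_path):
    p = tmp_path / "sizes.txt"
    p.write_text("chr1\t1000000\nchr2\t30000\n")
    assert read_chrom_sizes(p) == {"chr1": 1_000_000, "chr2": 30_000}
    p.write_text("chr1\t-5\n")
    with pytest.raises(ParseError):
        read_chrom_sizes(p)
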