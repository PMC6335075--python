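import numpy as np
import pandas as pd
import pytest
from Bio.Seq import Seq

from carballoc import simdata, varkit
from carballoc.varkit import GeneModel, VcfParseError

from conftest import small_config

VCF_HEADER = (
    "##fileformat=VCFv4.2\n"
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
    '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Depth">\n'
    "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\n"
)


def write_vcf(tmp_path, body: str, name="t.vcf"):
    p = tmp_path / name
    p.write_text(VCF_HEADER + body)
    return str(p)


class TestReadVcf:
    def test_empty_body(self, tmp_path):
        assert varkit.read_vcf(write_vcf(tmp_path, "")).empty

    def test_field_mapping(self, tmp_path):
        path = write_vcf(tmp_path, "chr1\t100\t.\tG\tA\t.\tPASS\t.\tGT:DP\t1/1:20\n")
        df = varkit.read_vcf(path)
        row = df.iloc[0]
        assert (row.chrom, row.pos, row.ref, row.alt) == ("chr1", 100, "G", "A")
        assert row["gt"] == "hom_alt" and row["depth"] == 20

    def test_skips_multiallelic_and_indels(self, tmp_path):
        body = (
            "chr1\t100\t.\tG\tA,T\t.\tPASS\t.\tGT:DP\t1/1:10\n"
            "chr1\t200\t.\tGT\tG\t.\tPASS\t.\tGT:DP\t1/1:10\n"
            "chr1\t300\t.\tC\tT\t.\tPASS\t.\tGT:DP\t0/1:10\n"
        )
        df = varkit.read_vcf(write_vcf(tmp_path, body))
        assert list(df["pos"]) == [300]
        assert df.iloc[0]["gt"] == "het"

    def test_malformed_header(self, tmp_path):
        p = tmp_path / "bad.vcf"
        p.write_text("not a vcf at all\n")
        with pytest.raises(VcfParseError):
            varkit.read_vcf(str(p))

    def test_fixture_record_count(self, bundle, fixture_dir):
        df = varkit.read_vcf(fixture_dir["vcf_CL"])
        assert len(df) == len(bundle.snps["CL"])


def snp_frame(rows):
    return pd.DataFrame(
        rows, columns=["chrom", "pos", "ref", "alt", "gt", "depth"]
    )


class TestFilterHomozygous:
    def test_all_het_empty(self):
        df = snp_frame([("chr1", i, "G", "A", "het", 30) for i in range(1, 6)])
        assert varkit.filter_homozygous(df).empty

    def test_min_depth_zero_keeps_homs(self):
        df = snp_frame(
            [
                ("chr1", 1, "G", "A", "hom_alt", 0),
                ("chr1", 2, "G", "A", "het", 50),
                ("chr1", 3, "G", "A", "hom_ref", 5),
                ("chr1", 4, "G", "A", "missing", 50),
            ]
        )
        out = varkit.filter_homozygous(df, 0)
        assert list(out["pos"]) == [1, 3]

    def test_brute_force_recount(self, bundle):
        df = bundle.snps["CL"]
        out = varkit.filter_homozygous(df, 10)
        expected = sum(
            1
            for r in df.itertuples()
            if r.gt in ("hom_ref", "hom_alt") and r.depth >= 10
        )
        assert len(out) == expected
        assert (out["depth"] >= 10).all()


class TestClassifyTrio:
    def row(self, pos, ref, alt, gt):
        return ("chr1", pos, ref, alt, gt, 30)

    def test_definitional_groups(self):
        conv = snp_frame([
            self.row(1, "G", "G", "hom_ref"),   # matches parent1 -> group1
            self.row(2, "G", "A", "hom_alt"),   # matches parent2 -> group2
            self.row(3, "G", "A", "hom_alt"),   # parents agree -> uninformative
            self.row(4, "G", "C", "hom_alt"),   # matches neither -> conflicting
        ])
        p1 = snp_frame([
            self.row(1, "G", "G", "hom_ref"),
            self.row(2, "G", "G", "hom_ref"),
            self.row(3, "G", "A", "hom_alt"),
            self.row(4, "G", "G", "hom_ref"),
        ])
        p2 = snp_frame([
            self.row(1, "G", "A", "hom_alt"),
            self.row(2, "G", "A", "hom_alt"),
            self.row(3, "G", "A", "hom_alt"),
            self.row(4, "G", "A", "hom_alt"),
        ])
        out = varkit.classify_trio(conv, p1, p2)
        assert list(out["group"]) == [
            "group1", "group2", "uninformative", "conflicting"
        ]

    def test_missing_parent_uninformative(self):
        conv = snp_frame([self.row(1, "G", "A", "hom_alt")])
        p1 = snp_frame([self.row(1, "G", "G", "hom_ref")])
        p2 = snp_frame([])
        out = varkit.classify_trio(conv, p1, p2)
        assert list(out["group"]) == ["uninformative"]

    def test_duplicate_positions_error(self):
        conv = snp_frame([self.row(1, "G", "A", "hom_alt")] * 2)
        p = snp_frame([self.row(1, "G", "A", "hom_alt")])
        with pytest.raises(ValueError, match="duplicate"):
            varkit.classify_trio(conv, p, p)

    def test_partition_property(self, bundle):
        out = varkit.classify_trio(
            varkit.filter_homozygous(bundle.snps["CL"]),
            varkit.filter_homozygous(bundle.snps["P1"]),
            varkit.filter_homozygous(bundle.snps["P2"]),
        )
        assert out["group"].isin(varkit.GROUPS).all()
        assert len(out) == len(varkit.filter_homozygous(bundle.snps["CL"]))


@pytest.fixture(scope="module")
def classified(bundle):
    return varkit.classify_trio(
        varkit.filter_homozygous(bundle.snps["CL"]),
        varkit.filter_homozygous(bundle.snps["P1"]),
        varkit.filter_homozygous(bundle.snps["P2"]),
    )


class TestBinGenome:
    def test_forced_parent2(self):
        df = snp_frame(
            [("chr1", 10 + i, "G", "A", "hom_alt", 30) for i in range(10)]
        )
        df = df.assign(group="group2")
        bins = varkit.bin_genome(df, 100_000, 5, 0.9)
        assert list(bins["call"]) == ["parent2"]

    def test_below_min_snps_unassigned(self):
        df = snp_frame(
            [("chr1", 10 + i, "G", "A", "hom_alt", 30) for i in range(3)]
        ).assign(group="group2")
        bins = varkit.bin_genome(df, 100_000, 5, 0.9)
        assert list(bins["call"]) == ["unassigned"]

    def test_count_conservation(self, classified):
        bins = varkit.bin_genome(classified, 100_000, 5, 0.9)
        total = (bins["n_group1"] + bins["n_group2"]).sum()
        assert total == classified["group"].isin(["group1", "group2"]).sum()

    def test_error_free_bins_match_truth(self):
        cfg = small_config(genotype_error_rate=0.0)
        bundle = simdata.simulate_all(cfg)
        cls = varkit.classify_trio(
            varkit.filter_homozygous(bundle.snps["CL"]),
            varkit.filter_homozygous(bundle.snps["P1"]),
            varkit.filter_homozygous(bundle.snps["P2"]),
        )
        bins = varkit.bin_genome(
            cls, 100_000, 5, 0.9, chrom_sizes={"chr1": cfg.chrom_len}
        )
        called = set(
            bins.loc[bins["call"] == "parent2", ["chrom", "start"]]
            .itertuples(index=False, name=None)
        )
        # oracle: bins that contain classified SNPs and whose SNPs are all
        # inside truth segments must be parent2; interior truth bins must be
        # recovered
        for chrom, s, e in bundle.truth.segments:
            b0 = (s // 100_000 + 1) * 100_000  # first fully-covered bin
            while b0 + 100_000 <= e:
                assert (chrom, b0) in called
                b0 += 100_000

    def test_majority_bounds(self, classified):
        with pytest.raises(ValueError):
            varkit.bin_genome(classified, 100_000, 5, 0.5)
        with pytest.raises(ValueError):
            varkit.bin_genome(classified, 0, 5, 0.9)


def make_bins(calls, chrom="chr1", width=100):
    rows = []
    for i, call in enumerate(calls):
        rows.append((chrom, i * width, (i + 1) * width, 0, 0, call))
    return pd.DataFrame(
        rows, columns=["chrom", "start", "end", "n_group1", "n_group2", "call"]
    )


class TestCallSegments:
    def test_no_bridging(self):
        bins = make_bins(["parent2", "parent2", "unassigned", "parent2"])
        seg = varkit.call_segments(bins)
        assert list(seg["n_bins"]) == [2, 1]

    def test_all_parent1_empty(self):
        assert varkit.call_segments(make_bins(["parent1"] * 4)).empty

    def test_unsorted_error(self):
        bins = make_bins(["parent2", "parent2"]).iloc[::-1].reset_index(drop=True)
        with pytest.raises(ValueError, match="sorted"):
            varkit.call_segments(bins)

    def test_gene_overlap_oracle(self, classified, bundle):
        bins = varkit.bin_genome(
            classified, 100_000, 5, 0.9,
            chrom_sizes={"chr1": bundle.config.chrom_len},
        )
        genes = bundle.truth.genes
        segs = varkit.call_segments(bins, genes)
        assert len(segs) > 0
        for seg in segs.itertuples(index=False):
            brute = [
                g.gene_id
                for g in genes.itertuples(index=False)
                if g.chrom == seg.chrom
                and g.start < seg.end and g.end > seg.start
            ]
            assert sorted(seg.genes) == sorted(brute)


# ---------------------------------------------------------------------------
# variant effects


class Snp:
    def __init__(self, chrom, pos, ref, alt):
        self.chrom, self.pos, self.ref, self.alt = chrom, pos, ref, alt


def toy_gene(seq_codons, strand="+", chrom="chr1", offset=10):
    """Single-exon gene whose CDS is seq_codons on the given strand."""
    cds = "".join(seq_codons)
    if strand == "-":
        genomic = str(Seq(cds).reverse_complement())
    else:
        genomic = cds
    chrom_seq = "N" * offset + genomic + "N" * 10
    model = GeneModel("g", chrom, strand, [(offset, offset + len(genomic))])
    return model, chrom_seq


class TestPredictEffect:
    def test_stop_gain(self):
        model, seq = toy_gene(["ATG", "TGG", "TAA"])
        # TGG -> TGA at codon 2, third base (genomic pos offset+5, 1-based +1)
        snp = Snp("chr1", 16, "G", "A")
        assert varkit.predict_effect(snp, model, seq).effect == "HIGH"

    def test_synonymous(self):
        model, seq = toy_gene(["ATG", "GCT", "TAA"])
        snp = Snp("chr1", 16, "T", "C")  # GCT -> GCC (Ala -> Ala)
        assert varkit.predict_effect(snp, model, seq).effect == "LOW"

    def test_missense(self):
        model, seq = toy_gene(["ATG", "GCT", "TAA"])
        snp = Snp("chr1", 15, "C", "T")  # GCT -> GTT (Ala -> Val)
        assert varkit.predict_effect(snp, model, seq).effect == "MODERATE"

    def test_start_loss(self):
        model, seq = toy_gene(["ATG", "GCT", "TAA"])
        snp = Snp("chr1", 11, "A", "C")
        assert varkit.predict_effect(snp, model, seq).effect == "HIGH"

    def test_reverse_strand_missense(self):
        model, seq = toy_gene(["ATG", "GCT", "TAA"], strand="-")
        # genomic = revcomp(ATGGCTTAA) = TTAAGCCAT; codon2 base2 (C, cds idx 4)
        # genomic index = len-1-4 = 4 -> base 'G', pos 10+4+1 = 15
        snp = Snp("chr1", 15, "G", "A")  # G->A genomic = C->T cds: GCT->GTT
        assert varkit.predict_effect(snp, model, seq).effect == "MODERATE"

    def test_splice_site(self):
        chrom_seq = "N" * 10 + "ATG" + "GTXXAG" + "GCTTAA" + "N" * 5
        model = GeneModel("g", "chr1", "+", [(10, 13), (19, 25)])
        snp = Snp("chr1", 14, "G", "A")  # first intron base
        assert varkit.predict_effect(snp, model, chrom_seq).effect == "HIGH"
        deep = Snp("chr1", 16, "X", "A")  # intron interior
        assert varkit.predict_effect(deep, model, chrom_seq).effect == "MODIFIER"

    def test_intergenic(self):
        model, seq = toy_gene(["ATG", "GCT", "TAA"])
        snp = Snp("chr1", 2, "N", "A")
        assert varkit.predict_effect(snp, model, seq).effect == "MODIFIER"

    def test_partial_cds_warns(self):
        model, seq = toy_gene(["ATG", "GC"])
        snp = Snp("chr1", 12, "G", "A")
        with pytest.warns(UserWarning, match="divisible"):
            assert varkit.predict_effect(snp, model, seq).effect == "MODIFIER"

    def test_reference_mismatch(self):
        model, seq = toy_gene(["ATG", "GCT", "TAA"])
        snp = Snp("chr1", 15, "T", "A")  # true base is C
        with pytest.raises(ValueError, match="mismatch"):
            varkit.predict_effect(snp, model, seq)


# oracle shared with the acceptance suite
def oracle_effect(snp, model, chrom_seq):
    """Translate both whole haplotype CDSs and diff the proteins."""
    exons = sorted(model.cds_exons)
    pos0 = snp.pos - 1
    in_exon = any(s <= pos0 < e for s, e in exons)
    if not in_exon:
        for (s1, e1), (s2, e2) in zip(exons, exons[1:]):
            if e1 <= pos0 < e1 + 2 or s2 - 2 <= pos0 < s2:
                return "HIGH"
        return "MODIFIER"
    mutated = chrom_seq[:pos0] + snp.alt + chrom_seq[pos0 + 1 :]

    def protein(seq):
        cds = "".join(seq[s:e] for s, e in exons)
        if model.strand == "-":
            cds = str(Seq(cds).reverse_complement())
        return str(Seq(cds).translate())

    if model.cds_length() % 3 != 0:
        return "MODIFIER"
    p_ref, p_alt = protein(chrom_seq), protein(mutated)
    diffs = [i for i, (a, b) in enumerate(zip(p_ref, p_alt)) if a != b]
    if not diffs:
        return "LOW"
    i = diffs[0]
    if p_alt[i] == "*":
        return "HIGH"
    if p_ref[i] == "*":
        return "HIGH"
    if i == 0 and p_ref[0] == "M":
        return "HIGH"
    return "MODERATE"


def random_gene_and_snps(rng, n_snps):
    strand = rng.choice(["+", "-"])
    n_exons = int(rng.integers(1, 4))
    exon_lens = rng.integers(9, 60, size=n_exons)
    total = exon_lens.sum()
    total -= total % 3  # keep CDS in frame
    exon_lens[-1] -= exon_lens.sum() - total
    if exon_lens[-1] < 3:
        exon_lens[-1] += 3
        total = exon_lens.sum()
    pos = 10
    exons = []
    for L in exon_lens:
        exons.append((pos, pos + int(L)))
        pos += int(L) + int(rng.integers(8, 30))
    seq_len = pos + 10
    chrom_seq = "".join(rng.choice(list("ACGT"), size=seq_len))
    model = GeneModel("g", "chr1", strand, exons)
    lo, hi = exons[0][0], exons[-1][1]
    snps = []
    for _ in range(n_snps):
        p0 = int(rng.integers(max(lo - 5, 0), hi + 5))
        ref = chrom_seq[p0]
        alt = rng.choice([b for b in "ACGT" if b != ref])
        snps.append(Snp("chr1", p0 + 1, ref, alt))
    return model, chrom_seq, snps


def test_effect_oracle_agreement():
    rng = np.random.default_rng(42)
    checked = 0
    while checked < 1000:
        model, chrom_seq, snps = random_gene_and_snps(rng, 10)
        for snp in snps:
            assert (
                varkit.predict_effect(snp, model, chrom_seq).effect
                == oracle_effect(snp, model, chrom_seq)
            )
            checked += 1
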