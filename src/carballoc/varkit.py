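"""Trio SNP classification, genome painting and variant-effect annotation.

Coordinates are 0-based half-open internally; VCF (1-based) and GFF3 (1-based
inclusive) are converted at the I/O boundary. The conversion line's SNPs are
classified against the two parents: sites where the parents are homozygous for
different alleles are informative, and the conversion-line allele decides
group1 (matches parent 1) vs group2 (matches parent 2).
"""

from __future__ import annotations

import logging
import re
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio.Data import CodonTable
from Bio.Seq import Seq

logger = logging.getLogger(__name__)

GT_LABELS = ("hom_ref", "hom_alt", "het", "missing")
GROUPS = ("group1", "group2", "uninformative", "conflicting")
EFFECTS = ("HIGH", "MODERATE", "LOW", "MODIFIER")


class VcfParseError(ValueError):
    """Malformed VCF input."""


@dataclass
class GeneModel:
    """Minimal protein-coding gene model: spliced CDS on one strand.

    ``cds_exons`` are (start, end) 0-based half-open intervals sorted by
    genomic coordinate; translation starts at the first exon base on '+'
    strand and at the last exon base on '-'.
    """

    gene_id: str
    chrom: str
    strand: str
    cds_exons: list[tuple[int, int]] = field(default_factory=list)

    @property
    def span(self) -> tuple[int, int]:
        return self.cds_exons[0][0], self.cds_exons[-1][1]

    def cds_length(self) -> int:
        return sum(e - s for s, e in self.cds_exons)


@dataclass
class EffectCall:
    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    gene: str
    effect: str
    detail: str = ""


# ---------------------------------------------------------------------------
# I/O


def read_vcf(path: str) -> pd.DataFrame:
    """Read biallelic SNP records into a table.

    Columns: chrom, pos (1-based), ref, alt, gt (hom_ref/hom_alt/het/missing),
    depth. Multiallelic and indel records are skipped with a logged count.
    """
    from cyvcf2 import VCF

    try:
        vcf = VCF(path)
    except Exception as exc:  # htslib reports its own context
        raise VcfParseError(f"{path}: cannot parse VCF header: {exc}") from exc
    rows = []
    skipped = 0
    gt_map = {0: "hom_ref", 1: "het", 2: "missing", 3: "hom_alt"}
    try:
        for v in vcf:
            if len(v.ALT) != 1 or len(v.REF) != 1 or len(v.ALT[0]) != 1:
                skipped += 1
                continue
            gt = gt_map.get(int(v.gt_types[0]), "missing")
            dp = v.format("DP")
            depth = int(dp[0][0]) if dp is not None and dp[0][0] >= 0 else 0
            rows.append((v.CHROM, v.POS, v.REF, v.ALT[0], gt, depth))
    except Exception as exc:
        raise VcfParseError(f"{path}: malformed VCF record: {exc}") from exc
    if skipped:
        logger.info("%s: skipped %d multiallelic/indel records", path, skipped)
    return pd.DataFrame(
        rows, columns=["chrom", "pos", "ref", "alt", "gt", "depth"]
    ).astype({"pos": int, "depth": int})


_ATTR_ID = re.compile(r"ID=([^;]+)")


def read_gff_genes(path: str, feature: str = "gene") -> pd.DataFrame:
    """Gene spans from GFF3 as a frame with 0-based half-open coordinates."""
    df = pd.read_csv(
        path,
        sep="\t",
        comment="#",
        header=None,
        names=["chrom", "source", "type", "start", "end", "score", "strand",
               "phase", "attributes"],
        dtype={"chrom": str},
    )
    df = df[df["type"] == feature].copy()
    df["gene_id"] = df["attributes"].str.extract(_ATTR_ID, expand=False)
    df["start"] = df["start"].astype(int) - 1  # to 0-based half-open
    df["end"] = df["end"].astype(int)
    return df[["gene_id", "chrom", "start", "end", "strand"]].reset_index(drop=True)


# ---------------------------------------------------------------------------
# trio classification


def filter_homozygous(snps: pd.DataFrame, min_depth: int = 0) -> pd.DataFrame:
    """Keep homozygous calls with depth >= min_depth, preserving order."""
    if min_depth < 0:
        raise ValueError("min_depth must be >= 0")
    mask = snps["gt"].isin(["hom_ref", "hom_alt"]) & (snps["depth"] >= min_depth)
    return snps[mask].reset_index(drop=True)


def _allele(df: pd.DataFrame) -> pd.Series:
    """Observed allele of a homozygous call; NaN for het/missing."""
    allele = pd.Series(np.nan, index=df.index, dtype=object)
    allele[df["gt"] == "hom_ref"] = df.loc[df["gt"] == "hom_ref", "ref"]
    allele[df["gt"] == "hom_alt"] = df.loc[df["gt"] == "hom_alt", "alt"]
    return allele


def _check_unique(df: pd.DataFrame, name: str) -> None:
    dup = df.duplicated(subset=["chrom", "pos"])
    if dup.any():
        where = df.loc[dup, ["chrom", "pos"]].iloc[0]
        raise ValueError(
            f"duplicate position in {name}: {where.chrom}:{where.pos}"
        )


def classify_trio(
    conv: pd.DataFrame, parent1: pd.DataFrame, parent2: pd.DataFrame
) -> pd.DataFrame:
    """Classify conversion-line SNPs by parental origin.

    Returns the conversion-line table plus a ``group`` column in
    {group1, group2, uninformative, conflicting}.
    """
    for df, name in ((conv, "conversion"), (parent1, "parent1"), (parent2, "parent2")):
        _check_unique(df, name)
    out = conv.copy()
    out["allele"] = _allele(conv)
    key = ["chrom", "pos"]
    p1 = parent1[key].copy()
    p1["p1_allele"] = _allele(parent1)
    p2 = parent2[key].copy()
    p2["p2_allele"] = _allele(parent2)
    out = out.merge(p1, on=key, how="left").merge(p2, on=key, how="left")

    informative = (
        out["p1_allele"].notna()
        & out["p2_allele"].notna()
        & (out["p1_allele"] != out["p2_allele"])
        & out["allele"].notna()
    )
    group = np.full(len(out), "uninformative", dtype=object)
    group[informative & (out["allele"] == out["p1_allele"])] = "group1"
    group[informative & (out["allele"] == out["p2_allele"])] = "group2"
    group[
        informative
        & (out["allele"] != out["p1_allele"])
        & (out["allele"] != out["p2_allele"])
    ] = "conflicting"
    out["group"] = group
    return out.drop(columns=["allele", "p1_allele", "p2_allele"])


# ---------------------------------------------------------------------------
# binning and segments


def bin_genome(
    classified: pd.DataFrame,
    bin_width: int = 100_000,
    min_snps: int = 5,
    majority: float = 0.9,
    chrom_sizes: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Paint fixed-width genome bins by parental origin.

    A bin is called parent2 iff it holds >= min_snps classified SNPs of which
    a fraction >= majority are group2 (symmetric for parent1), else unassigned.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be > 0")
    if not 0.5 < majority <= 1.0:
        raise ValueError("majority must be in (0.5, 1]")
    if min_snps < 0:
        raise ValueError("min_snps must be >= 0")
    rows = []
    grouped = classified[classified["group"].isin(["group1", "group2"])]
    sizes = dict(chrom_sizes) if chrom_sizes else {}
    chroms = sorted(set(classified["chrom"]) | set(sizes))
    for chrom in chroms:
        sub = grouped[grouped["chrom"] == chrom]
        size = sizes.get(chrom)
        if size is None:
            here = classified[classified["chrom"] == chrom]
            size = int(here["pos"].max()) if len(here) else 0
        n_bins = max(-(-size // bin_width), 1) if size else 0
        if n_bins == 0:
            continue
        idx = (sub["pos"].to_numpy() - 1) // bin_width
        g1 = np.bincount(idx[sub["group"] == "group1"], minlength=n_bins)
        g2 = np.bincount(idx[sub["group"] == "group2"], minlength=n_bins)
        for b in range(n_bins):
            total = int(g1[b] + g2[b])
            call = "unassigned"
            if total >= min_snps and total > 0:
                if g2[b] / total >= majority:
                    call = "parent2"
                elif g1[b] / total >= majority:
                    call = "parent1"
            rows.append(
                (chrom, b * bin_width, min((b + 1) * bin_width, size),
                 int(g1[b]), int(g2[b]), call)
            )
    return pd.DataFrame(
        rows, columns=["chrom", "start", "end", "n_group1", "n_group2", "call"]
    )


def call_segments(
    bins: pd.DataFrame, genes: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Merge maximal runs of consecutive parent2 bins into segments.

    Unassigned bins break runs (no bridging). If a gene table is supplied,
    each segment carries the ids of genes it overlaps (any-overlap,
    half-open intervals).
    """
    b = bins.reset_index(drop=True)
    order = b.sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)
    if not order[["chrom", "start"]].equals(b[["chrom", "start"]]):
        raise ValueError("bins must be sorted by (chrom, start)")
    rows = []
    cur = None  # [chrom, start, end, n_bins]
    for row in b.itertuples(index=False):
        if row.call == "parent2":
            if (
                cur is not None
                and cur[0] == row.chrom
                and cur[2] == row.start
            ):
                cur[2] = row.end
                cur[3] += 1
            else:
                if cur is not None:
                    rows.append(tuple(cur))
                cur = [row.chrom, row.start, row.end, 1]
        else:
            if cur is not None:
                rows.append(tuple(cur))
                cur = None
    if cur is not None:
        rows.append(tuple(cur))
    seg = pd.DataFrame(rows, columns=["chrom", "start", "end", "n_bins"])
    seg["genes"] = [[] for _ in range(len(seg))]
    if genes is not None and len(seg):
        for i, s in seg.iterrows():
            hit = genes[
                (genes["chrom"] == s.chrom)
                & (genes["start"] < s.end)
                & (genes["end"] > s.start)
            ]
            seg.at[i, "genes"] = list(hit["gene_id"])
    return seg


def segment_gene_ids(segments: pd.DataFrame) -> set[str]:
    out: set[str] = set()
    for genes in segments["genes"]:
        out.update(genes)
    return out


def write_bed(path: str, table: pd.DataFrame, extra_cols: list[str] = ()) -> None:
    cols = ["chrom", "start", "end", *extra_cols]
    table[cols].to_csv(path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# variant effects

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


def predict_effect(
    snp,
    gene_model: GeneModel,
    chrom_seq: str,
    codon_table: int = 1,
) -> EffectCall:
    """Classify a SNP's coding effect against one gene model.

    HIGH: stop gain/loss, start loss, splice site (first/last 2 bp of an
    intron). MODERATE: nonsynonymous. LOW: synonymous. MODIFIER: non-coding,
    intergenic, or a CDS whose length is not a multiple of 3 (with a warning).
    """
    chrom, pos, ref, alt = snp.chrom, int(snp.pos), snp.ref, snp.alt
    pos0 = pos - 1
    mk = lambda eff, detail="": EffectCall(
        chrom, pos, ref, alt, gene_model.gene_id, eff, detail
    )
    if chrom != gene_model.chrom:
        return mk("MODIFIER", "other_chrom")
    exons = sorted(gene_model.cds_exons)
    lo, hi = exons[0][0], exons[-1][1]
    if not lo <= pos0 < hi:
        return mk("MODIFIER", "intergenic")
    in_exon = any(s <= pos0 < e for s, e in exons)
    if not in_exon:
        for (s1, e1), (s2, e2) in zip(exons, exons[1:]):
            # intron is [e1, s2); splice sites are its first/last 2 bases
            if e1 <= pos0 < e1 + 2 or s2 - 2 <= pos0 < s2:
                return mk("HIGH", "splice_site")
        return mk("MODIFIER", "intronic")
    if gene_model.cds_length() % 3 != 0:
        warnings.warn(
            f"{gene_model.gene_id}: CDS length not divisible by 3; "
            "reporting MODIFIER",
            stacklevel=2,
        )
        return mk("MODIFIER", "partial_cds")
    # offset of pos0 within the spliced CDS in genomic (forward) order
    offset = 0
    for s, e in exons:
        if pos0 >= e:
            offset += e - s
        elif pos0 >= s:
            offset += pos0 - s
            break
    cds_len = gene_model.cds_length()
    if gene_model.strand == "-":
        cds_index = cds_len - 1 - offset
        ref_base = ref.translate(_COMPLEMENT)
        alt_base = alt.translate(_COMPLEMENT)
    else:
        cds_index = offset
        ref_base = ref
        alt_base = alt
    cds = _spliced_cds(gene_model, chrom_seq)
    if cds[cds_index].upper() != ref_base.upper():
        raise ValueError(
            f"{gene_model.gene_id}: reference mismatch at {chrom}:{pos} "
            f"(sequence {cds[cds_index]}, VCF ref {ref_base})"
        )
    ci = cds_index // 3
    within = cds_index % 3
    ref_codon = cds[3 * ci : 3 * ci + 3]
    alt_codon = ref_codon[:within] + alt_base + ref_codon[within + 1 :]
    table = CodonTable.unambiguous_dna_by_id[codon_table]
    ref_aa = _translate_codon(ref_codon, table)
    alt_aa = _translate_codon(alt_codon, table)
    if ref_aa == alt_aa:
        return mk("LOW", "synonymous")
    if alt_aa == "*":
        return mk("HIGH", "stop_gain")
    if ref_aa == "*":
        return mk("HIGH", "stop_loss")
    if ci == 0 and ref_aa == "M":
        return mk("HIGH", "start_loss")
    return mk("MODERATE", "nonsynonymous")


def _spliced_cds(gene_model: GeneModel, chrom_seq: str) -> str:
    parts = [chrom_seq[s:e] for s, e in sorted(gene_model.cds_exons)]
    cds = "".join(parts)
    if gene_model.strand == "-":
        cds = str(Seq(cds).reverse_complement())
    return cds


def _translate_codon(codon: str, table) -> str:
    codon = codon.upper()
    if codon in table.stop_codons:
        return "*"
    return table.forward_table.get(codon, "X")
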