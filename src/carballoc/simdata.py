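"""Synthetic trio datasets with known ground truth.

Simulates a two-parent + conversion-line trio: homozygous SNP calls with depth
noise, GFF3 gene models, a genotype x timepoint x replicate count matrix with
planted co-expression modules / fold changes, directional gene sets tied to a
metabolite signal, and a metabolite time course whose signal trajectory runs in
opposite directions between the first genotype and the other two.

All randomness flows through one :class:`numpy.random.Generator` so a fixed
seed yields byte-identical fixtures.
"""

from __future__ import annotations

import dataclasses
import json
import math
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

GENOTYPES = ("P1", "P2", "CL")
#: metabolite categories emitted by :func:`simulate_metabolome`
CATEGORIES = (
    "amino acids",
    "carbohydrates",
    "cofactors",
    "lipids",
    "nucleotides",
    "peptides",
    "secondary metabolites",
    "hormones",
)
T6P_ID = "T6P"
BASES = np.array(["A", "C", "G", "T"])


class SimConfigError(ValueError):
    """Invalid simulation configuration."""


class SimulationError(RuntimeError):
    """Requested simulation is geometrically impossible."""


@dataclass(frozen=True)
class SimConfig:
    seed: int = 0
    # genome / trio
    n_chrom: int = 1
    chrom_len: int = 20_000_000
    snp_density: float = 1e-3
    n_segments: int = 5
    segment_len_range: tuple[int, int] = (150_000, 250_000)
    min_segment_gap: int = 300_000
    genotype_error_rate: float = 0.02
    mean_depth: float = 30.0
    frac_uninformative: float = 0.1
    # gene models
    n_genes: int = 5000
    gene_len: int = 1200
    # expression
    n_modules: int = 6
    module_size_range: tuple[int, int] = (100, 160)
    n_timepoints: int = 4
    n_reps: int = 3
    de_fold: float = 4.0
    n_de_genes: int = 300
    nb_dispersion: float = 0.05
    module_amplitude: float = 1.2
    base_log_mean: float = math.log(200.0)
    base_log_sd: float = 0.8
    # T6P signature
    t6p_set_size: int = 200
    frac_t6p_in_introgression: float = 0.05
    candidate_margin: int = 25_000
    # metabolome
    n_metabolites_per_category: int = 8
    metab_noise: float = 0.08
    bin_width: int = 100_000  # only used for the segment-length invariant

    def validate(self) -> None:
        positive = {
            "n_chrom": self.n_chrom,
            "chrom_len": self.chrom_len,
            "n_genes": self.n_genes,
            "gene_len": self.gene_len,
            "n_modules": self.n_modules,
            "n_timepoints": self.n_timepoints,
            "n_reps": self.n_reps,
            "t6p_set_size": self.t6p_set_size,
            "n_metabolites_per_category": self.n_metabolites_per_category,
        }
        for name, value in positive.items():
            if value <= 0:
                raise SimConfigError(f"{name} must be positive, got {value}")
        for name, value in {
            "genotype_error_rate": self.genotype_error_rate,
            "frac_uninformative": self.frac_uninformative,
            "frac_t6p_in_introgression": self.frac_t6p_in_introgression,
        }.items():
            if not 0.0 <= value <= 1.0:
                raise SimConfigError(f"{name} must be in [0, 1], got {value}")
        if self.n_segments < 0:
            raise SimConfigError("n_segments must be >= 0")
        lo, hi = self.segment_len_range
        if not 0 < lo <= hi:
            raise SimConfigError("segment_len_range must satisfy 0 < lo <= hi")
        if self.n_segments > 0 and lo < self.bin_width:
            raise SimConfigError(
                f"segment lengths ({lo}) must be >= bin width ({self.bin_width})"
            )
        mlo, mhi = self.module_size_range
        if not 0 < mlo <= mhi:
            raise SimConfigError("module_size_range must satisfy 0 < lo <= hi")
        if self.nb_dispersion < 0:
            raise SimConfigError("nb_dispersion must be >= 0")
        if self.de_fold <= 0:
            raise SimConfigError("de_fold must be > 0")


@dataclass
class TruthSet:
    """Ground truth for one simulated dataset."""

    segments: list[tuple[str, int, int]] = field(default_factory=list)
    module_labels: dict[str, int] = field(default_factory=dict)
    de_genes: dict[str, list[str]] = field(default_factory=dict)
    t6p_set: list[str] = field(default_factory=list)
    t6p_induced: list[str] = field(default_factory=list)
    t6p_repressed: list[str] = field(default_factory=list)
    candidates: list[str] = field(default_factory=list)
    t6p_profile: dict[str, list[float]] = field(default_factory=dict)
    genes: pd.DataFrame | None = None

    def to_dict(self) -> dict:
        d = {
            "segments": [list(s) for s in self.segments],
            "module_labels": self.module_labels,
            "de_genes": self.de_genes,
            "t6p_set": self.t6p_set,
            "t6p_induced": self.t6p_induced,
            "t6p_repressed": self.t6p_repressed,
            "candidates": self.candidates,
            "t6p_profile": self.t6p_profile,
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "TruthSet":
        t = cls(
            segments=[tuple(s) for s in d["segments"]],
            module_labels={k: int(v) for k, v in d["module_labels"].items()},
            de_genes=d["de_genes"],
            t6p_set=d["t6p_set"],
            t6p_induced=d.get("t6p_induced", []),
            t6p_repressed=d.get("t6p_repressed", []),
            candidates=d.get("candidates", []),
            t6p_profile=d.get("t6p_profile", {}),
        )
        return t


@dataclass
class SimBundle:
    """Everything one simulation run produced."""

    config: SimConfig
    snps: dict[str, pd.DataFrame]
    truth: TruthSet
    counts: pd.DataFrame
    samples: pd.DataFrame
    gene_sets: pd.DataFrame
    metabolites: pd.DataFrame


# ---------------------------------------------------------------------------
# trajectory templates


def t6p_templates(n_timepoints: int) -> dict[str, list[float]]:
    """Noiseless signal trajectories per genotype.

    Genotypes P2/CL rise to the second timepoint and then decay; P1 dips at the
    second timepoint and then increases strictly.
    """
    if n_timepoints < 3:
        raise SimConfigError("t6p templates require n_timepoints >= 3")
    conv = [1.0, 1.6]
    while len(conv) < n_timepoints:
        conv.append(conv[-1] * 0.55)
    p1 = [1.0, 0.85]
    while len(p1) < n_timepoints:
        p1.append(p1[-1] + 0.30)
    return {"P1": p1, "P2": list(conv), "CL": list(conv)}


def _zscore(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    sd = x.std()
    if sd == 0:
        return np.zeros_like(x)
    return (x - x.mean()) / sd


# ---------------------------------------------------------------------------
# gene models


def make_gene_models(config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Non-overlapping single-exon gene models on a jittered grid.

    Returns a frame with gene_id, chrom, start, end (0-based half-open), strand.
    """
    total = config.n_chrom * config.chrom_len
    rows = []
    gid = 0
    for c in range(config.n_chrom):
        chrom = f"chr{c + 1}"
        n_here = int(round(config.n_genes * config.chrom_len / total))
        if c == config.n_chrom - 1:
            n_here = config.n_genes - gid
        spacing = config.chrom_len // (n_here + 1)
        if spacing <= config.gene_len:
            raise SimulationError(
                f"{n_here} genes of {config.gene_len} bp do not fit on "
                f"{chrom} ({config.chrom_len} bp)"
            )
        jitter = rng.integers(0, spacing - config.gene_len, size=n_here)
        strands = rng.choice(["+", "-"], size=n_here)
        for i in range(n_here):
            gid += 1
            start = int(i * spacing + jitter[i])  # one gene per grid slot
            rows.append(
                (f"gene{gid:05d}", chrom, start, start + config.gene_len, strands[i])
            )
    genes = pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end", "strand"])
    genes = genes.sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)
    return genes


# ---------------------------------------------------------------------------
# trio SNPs


def _place_segments(config: SimConfig, rng: np.random.Generator):
    lo, hi = config.segment_len_range
    chroms = [f"chr{c + 1}" for c in range(config.n_chrom)]
    placed: list[tuple[str, int, int]] = []
    attempts = 0
    while len(placed) < config.n_segments:
        attempts += 1
        if attempts > 1000 * max(config.n_segments, 1):
            raise SimulationError(
                f"could not place {config.n_segments} segments of {lo}-{hi} bp "
                f"with gap {config.min_segment_gap} on {config.n_chrom} "
                f"chromosome(s) of {config.chrom_len} bp; reduce n_segments or "
                "segment lengths"
            )
        chrom = chroms[int(rng.integers(len(chroms)))]
        length = int(rng.integers(lo, hi + 1))
        if length >= config.chrom_len:
            raise SimulationError("segment longer than chromosome")
        start = int(rng.integers(0, config.chrom_len - length))
        end = start + length
        ok = all(
            c != chrom
            or end + config.min_segment_gap <= s
            or start >= e + config.min_segment_gap
            for c, s, e in placed
        )
        if ok:
            placed.append((chrom, start, end))
    placed.sort(key=lambda t: (t[0], t[1]))
    return placed


def _snp_positions(config: SimConfig, rng: np.random.Generator, chrom_len: int):
    n = int(round(chrom_len * config.snp_density))
    pos: np.ndarray = np.unique(rng.integers(1, chrom_len + 1, size=int(n * 1.2)))
    while pos.size < n:
        extra = rng.integers(1, chrom_len + 1, size=n)
        pos = np.unique(np.concatenate([pos, extra]))
    keep = np.sort(rng.choice(pos.size, size=n, replace=False))
    return pos[keep]


def simulate_trio(
    config: SimConfig, rng: np.random.Generator | None = None
) -> tuple[dict[str, pd.DataFrame], TruthSet]:
    """Simulate per-genotype SNP tables and the truth segment list.

    Informative sites carry two distinct non-reference alleles, one per
    parent; the conversion line matches parent 2 inside truth segments and
    parent 1 elsewhere, with genotype errors injected into the conversion
    line at ``genotype_error_rate``.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    segments = _place_segments(config, rng)
    frames = {g: [] for g in GENOTYPES}
    for c in range(config.n_chrom):
        chrom = f"chr{c + 1}"
        pos = _snp_positions(config, rng, config.chrom_len)
        n = pos.size
        # ref plus two distinct alternate alleles per site
        trip = np.stack(
            [rng.permutation(4)[:3] for _ in range(n)]
        )  # columns: ref, altA, altB
        ref = BASES[trip[:, 0]]
        alt_a = BASES[trip[:, 1]]
        alt_b = BASES[trip[:, 2]]
        informative = rng.random(n) >= config.frac_uninformative
        p1_allele = alt_a.copy()
        p2_allele = np.where(informative, alt_b, alt_a)
        in_seg = np.zeros(n, dtype=bool)
        for sc, ss, se in segments:
            if sc == chrom:
                in_seg |= (pos > ss) & (pos <= se)  # pos is 1-based
        conv_allele = np.where(in_seg, p2_allele, p1_allele)
        conv_gt = np.full(n, "hom_alt", dtype=object)
        # conversion-line genotype errors: flip to the other parental allele
        # (70%) or to a het call (30%)
        err = rng.random(n) < config.genotype_error_rate
        flip_kind = rng.random(n) < 0.7
        other = np.where(conv_allele == p1_allele, p2_allele, p1_allele)
        conv_allele = np.where(err & flip_kind, other, conv_allele)
        conv_gt[err & ~flip_kind] = "het"
        for geno, allele, gt in (
            ("P1", p1_allele, np.full(n, "hom_alt", dtype=object)),
            ("P2", p2_allele, np.full(n, "hom_alt", dtype=object)),
            ("CL", conv_allele, conv_gt),
        ):
            depth = rng.poisson(config.mean_depth, size=n).clip(min=1)
            frames[geno].append(
                pd.DataFrame(
                    {
                        "chrom": chrom,
                        "pos": pos,
                        "ref": ref,
                        "alt": allele,
                        "gt": gt,
                        "depth": depth,
                    }
                )
            )
    snps = {g: pd.concat(fs, ignore_index=True) for g, fs in frames.items()}
    truth = TruthSet(segments=segments, t6p_profile=t6p_templates(config.n_timepoints))
    return snps, truth


# ---------------------------------------------------------------------------
# expression


def _gene_overlaps(genes: pd.DataFrame, segments, margin: int = 0) -> np.ndarray:
    """Boolean mask of genes overlapping (margin=0) or comfortably inside
    (margin>0) any truth segment."""
    mask = np.zeros(len(genes), dtype=bool)
    for chrom, start, end in segments:
        if margin > 0:
            lo, hi = start + margin, end - margin
            hit = (
                (genes["chrom"] == chrom)
                & (genes["start"] >= lo)
                & (genes["end"] <= hi)
            )
        else:
            hit = (
                (genes["chrom"] == chrom)
                & (genes["start"] < end)
                & (genes["end"] > start)
            )
        mask |= hit.to_numpy()
    return mask


def simulate_expression(
    config: SimConfig,
    truth: TruthSet,
    rng: np.random.Generator | None = None,
    genes: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Counts (genes x samples) plus a sample sheet; fills the truth labels.

    Module 1 follows the +T6P template and module 2 the -template; the
    inducible/repressible gene sets are drawn from those modules, with the
    in-segment portion of the inducible set forming the planted candidates.
    Remaining modules follow random smooth genotype-specific trajectories.
    Counts are negative binomial around the planted means.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    if genes is None:
        genes = truth.genes
    if genes is None:
        genes = make_gene_models(config, rng)
    truth.genes = genes
    gene_ids = genes["gene_id"].to_numpy()
    n_genes = len(gene_ids)
    T, R = config.n_timepoints, config.n_reps

    mlo, mhi = config.module_size_range
    sizes = rng.integers(mlo, mhi + 1, size=config.n_modules)
    if sizes.sum() + config.n_de_genes + config.t6p_set_size > n_genes:
        raise SimulationError(
            f"planted structure ({sizes.sum()} module genes, "
            f"{config.n_de_genes} DE genes, {config.t6p_set_size} set genes) "
            f"exceeds n_genes={n_genes}"
        )

    introgressed = _gene_overlaps(genes, truth.segments)
    inside_margin = _gene_overlaps(
        genes, truth.segments, margin=config.candidate_margin
    )
    n_cand = int(round(config.frac_t6p_in_introgression * config.t6p_set_size))
    candidate_pool = np.flatnonzero(inside_margin)
    if candidate_pool.size < n_cand:
        raise SimulationError(
            f"only {candidate_pool.size} genes lie inside truth segments with "
            f"margin {config.candidate_margin}; cannot plant {n_cand} candidates"
        )
    cand_idx = rng.choice(candidate_pool, size=n_cand, replace=False)

    outside_pool = np.flatnonzero(~introgressed)
    rng.shuffle(outside_pool)
    cursor = 0
    labels = np.zeros(n_genes, dtype=int)
    for m in range(1, config.n_modules + 1):
        take = int(sizes[m - 1])
        members = outside_pool[cursor : cursor + take]
        cursor += take
        labels[members] = m
    labels[cand_idx] = 1  # candidates share the +signal module trajectory

    # directional gene sets
    n_induced = config.t6p_set_size // 2
    mod1 = np.setdiff1d(np.flatnonzero(labels == 1), cand_idx)
    extra = min(max(n_induced - n_cand, 0), mod1.size)
    induced_idx = np.concatenate(
        [cand_idx, rng.choice(mod1, size=extra, replace=False)]
    )
    mod2 = np.flatnonzero(labels == 2)
    n_repressed = min(config.t6p_set_size - induced_idx.size, mod2.size)
    repressed_idx = rng.choice(mod2, size=n_repressed, replace=False)

    # step-change DE genes, outside truth segments and outside planted modules
    free = outside_pool[cursor:]
    de_idx = free[: config.n_de_genes]

    # planted mean matrix
    base = rng.lognormal(config.base_log_mean, config.base_log_sd, size=n_genes)
    base[np.concatenate([induced_idx, repressed_idx])] = rng.lognormal(
        math.log(300.0), 0.4, size=induced_idx.size + repressed_idx.size
    )
    loading = rng.uniform(0.8, 1.2, size=n_genes)
    traj = np.zeros((config.n_modules + 1, len(GENOTYPES), T))
    for gi, geno in enumerate(GENOTYPES):
        tz = _zscore(truth.t6p_profile[geno])
        traj[1, gi] = tz
        traj[2, gi] = -tz
    # remaining modules get random smooth genotype-specific trajectories,
    # rejection-sampled so no two modules share a near-collinear profile
    # (otherwise they are indistinguishable by construction)
    for m in range(3, config.n_modules + 1):
        for _ in range(500):
            cand = np.stack(
                [_zscore(np.cumsum(rng.normal(size=T))) for _ in GENOTYPES]
            )
            flatc = cand.ravel()
            cors = [
                abs(float(np.corrcoef(flatc, traj[m2].ravel())[0, 1]))
                for m2 in range(1, m)
            ]
            if not cors or max(cors) < 0.6:
                break
        traj[m] = cand

    mean = np.zeros((n_genes, len(GENOTYPES), T))
    for gi in range(len(GENOTYPES)):
        mean[:, gi, :] = base[:, None]
        modgenes = labels > 0
        mean[modgenes, gi, :] = base[modgenes, None] * np.exp(
            config.module_amplitude
            * loading[modgenes, None]
            * traj[labels[modgenes], gi, :]
        )
    de_sign = rng.choice([1.0, -1.0], size=de_idx.size)
    for gi, geno in enumerate(GENOTYPES):
        if geno == "P1":
            continue  # step DE planted in P2 and CL only
        fold = config.de_fold ** de_sign
        mean[de_idx, gi, 1:] = mean[de_idx, gi, 1:] * fold[:, None]

    # sample sheet and counts
    cols, rows = [], []
    for gi, geno in enumerate(GENOTYPES):
        for t in range(T):
            for r in range(R):
                cols.append(f"{geno}_T{t + 1}_r{r + 1}")
                rows.append((cols[-1], geno, f"T{t + 1}", r + 1))
    samples = pd.DataFrame(rows, columns=["sample", "genotype", "timepoint", "replicate"])
    mu = np.repeat(mean.reshape(n_genes, -1), R, axis=1)
    counts = _nb_draw(mu, config.nb_dispersion, rng)
    counts = pd.DataFrame(counts, index=gene_ids, columns=cols)
    counts.index.name = "gene_id"

    # truth bookkeeping
    truth.module_labels = {g: int(l) for g, l in zip(gene_ids, labels)}
    truth.t6p_induced = sorted(gene_ids[induced_idx])
    truth.t6p_repressed = sorted(gene_ids[repressed_idx])
    truth.t6p_set = sorted(set(truth.t6p_induced) | set(truth.t6p_repressed))
    truth.candidates = sorted(gene_ids[cand_idx])
    truth.de_genes = {}
    for gi, geno in enumerate(GENOTYPES):
        ratio = np.abs(np.log2(mean[:, gi, 1:] / mean[:, gi, :-1]))
        truth.de_genes[geno] = sorted(gene_ids[(ratio >= 1.0).any(axis=1)])
    return counts, samples


def _nb_draw(mu: np.ndarray, dispersion: float, rng: np.random.Generator) -> np.ndarray:
    if dispersion <= 0:
        return rng.poisson(mu)
    r = 1.0 / dispersion
    return rng.negative_binomial(r, r / (r + mu))


def gene_sets_table(truth: TruthSet) -> pd.DataFrame:
    """Long-format gene-set table (set_id, species, direction, gene)."""
    rows = []
    for g in truth.t6p_induced:
        rows.append(("t6p_induced", "native", "induced", g))
    for g in truth.t6p_repressed:
        rows.append(("t6p_repressed", "native", "repressed", g))
    for g in truth.t6p_set:
        rows.append(("t6p_regulated", "native", "none", g))
    return pd.DataFrame(rows, columns=["set_id", "species", "direction", "gene"])


# ---------------------------------------------------------------------------
# metabolome


def simulate_metabolome(
    config: SimConfig,
    rng: np.random.Generator | None = None,
    noise: float | None = None,
) -> pd.DataFrame:
    """Long-format metabolite table with a planted T6P-like signal.

    Other metabolites follow monotone or flat multiplicative trends, shared
    between P2 and CL for roughly 70% of them and genotype-specific otherwise.
    """
    config.validate()
    if config.n_timepoints < 3:
        raise SimConfigError("metabolome simulation needs n_timepoints >= 3")
    if rng is None:
        rng = np.random.default_rng(config.seed + 2)
    if noise is None:
        noise = config.metab_noise
    T, R = config.n_timepoints, config.n_reps
    templates = t6p_templates(T)
    trends = {
        "up": np.geomspace(1.0, 2.2, T),
        "down": np.geomspace(2.2, 1.0, T),
        "flat": np.ones(T),
    }
    rows = []

    def emit(met, category, geno, template):
        for t in range(T):
            eps = rng.normal(0.0, noise, size=R) if noise > 0 else np.zeros(R)
            for r in range(R):
                rows.append(
                    (met, category, geno, f"T{t + 1}", r + 1,
                     float(template[t] * math.exp(eps[r])))
                )

    for geno in GENOTYPES:
        emit(T6P_ID, "carbohydrates", geno, templates[geno])
    trend_names = list(trends)
    for category in CATEGORIES:
        for i in range(config.n_metabolites_per_category):
            met = f"{category.replace(' ', '_')}_{i + 1}"
            scale = float(rng.lognormal(0.0, 0.5))
            shared = trend_names[int(rng.integers(3))]
            p1_own = (
                trend_names[int(rng.integers(3))] if rng.random() < 0.3 else shared
            )
            for geno in GENOTYPES:
                tmpl = trends[p1_own if geno == "P1" else shared] * scale
                emit(met, category, geno, tmpl)
    return pd.DataFrame(
        rows,
        columns=["metabolite", "category", "genotype", "timepoint", "replicate",
                 "abundance"],
    )


# ---------------------------------------------------------------------------
# one-call driver and fixture I/O


def simulate_all(config: SimConfig) -> SimBundle:
    rng = np.random.default_rng(config.seed)
    snps, truth = simulate_trio(config, rng)
    counts, samples = simulate_expression(config, truth, rng)
    metab = simulate_metabolome(config, rng)
    return SimBundle(
        config=config,
        snps=snps,
        truth=truth,
        counts=counts,
        samples=samples,
        gene_sets=gene_sets_table(truth),
        metabolites=metab,
    )


def write_vcf(path: str, snps: pd.DataFrame, config: SimConfig, sample: str) -> None:
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=carballoc-simdata\n")
        for c in range(config.n_chrom):
            fh.write(f"##contig=<ID=chr{c + 1},length={config.chrom_len}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + sample + "\n"
        )
        gt_codes = {"hom_ref": "0/0", "hom_alt": "1/1", "het": "0/1", "missing": "./."}
        for row in snps.itertuples(index=False):
            gt = gt_codes[row.gt]
            alt = row.alt if row.alt != row.ref else "."
            fh.write(
                f"{row.chrom}\t{row.pos}\t.\t{row.ref}\t{alt}\t.\tPASS\t.\t"
                f"GT:DP\t{gt}:{row.depth}\n"
            )


def write_gff3(path: str, genes: pd.DataFrame) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for row in genes.itertuples(index=False):
            start1 = row.start + 1  # GFF3 is 1-based inclusive
            common = f"{row.chrom}\tcarballoc\t"
            fh.write(
                f"{common}gene\t{start1}\t{row.end}\t.\t{row.strand}\t.\t"
                f"ID={row.gene_id}\n"
            )
            fh.write(
                f"{common}mRNA\t{start1}\t{row.end}\t.\t{row.strand}\t.\t"
                f"ID={row.gene_id}.1;Parent={row.gene_id}\n"
            )
            fh.write(
                f"{common}CDS\t{start1}\t{row.end}\t.\t{row.strand}\t0\t"
                f"ID={row.gene_id}.1.cds;Parent={row.gene_id}.1\n"
            )


def write_fixtures(outdir: str, bundle: SimBundle) -> dict[str, str]:
    """Write the full fixture set; returns a name -> path map."""
    os.makedirs(outdir, exist_ok=True)
    paths: dict[str, str] = {}
    for geno, table in bundle.snps.items():
        p = os.path.join(outdir, f"{geno}.vcf")
        write_vcf(p, table, bundle.config, geno)
        paths[f"vcf_{geno}"] = p
    p = os.path.join(outdir, "genes.gff3")
    write_gff3(p, bundle.truth.genes)
    paths["gff3"] = p
    p = os.path.join(outdir, "counts.tsv")
    bundle.counts.to_csv(p, sep="\t")
    paths["counts"] = p
    p = os.path.join(outdir, "samples.tsv")
    bundle.samples.to_csv(p, sep="\t", index=False)
    paths["samples"] = p
    p = os.path.join(outdir, "gene_sets.tsv")
    bundle.gene_sets.to_csv(p, sep="\t", index=False)
    paths["gene_sets"] = p
    p = os.path.join(outdir, "metabolites.tsv")
    bundle.metabolites.to_csv(p, sep="\t", index=False)
    paths["metabolites"] = p
    p = os.path.join(outdir, "truth.json")
    with open(p, "w") as fh:
        json.dump(bundle.truth.to_dict(), fh, indent=1)
    paths["truth"] = p
    p = os.path.join(outdir, "sim_config.json")
    with open(p, "w") as fh:
        json.dump(dataclasses.asdict(bundle.config), fh, indent=1)
    paths["config"] = p
    return paths


def read_truth(path: str) -> TruthSet:
    with open(path) as fh:
        return TruthSet.from_dict(json.load(fh))


def read_counts(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def read_samples(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def read_metabolites(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
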