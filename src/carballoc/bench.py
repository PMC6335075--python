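"""Self-contained acceptance measurements.

Each function regenerates its inputs from scratch with a seeded generator,
runs the package end to end and returns the measured quantities. They are
shared by the acceptance test suite (which asserts thresholds) and by
``scripts/acceptance.py`` (which reports the numbers).
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
from scipy import stats

from . import exprkit, metkit, netkit, setkit, sigkit, simdata, varkit

GENOTYPE = "CL"
TIMEPOINTS = ("T1", "T2", "T3", "T4")


# ---------------------------------------------------------------------------
# 1. introgression recovery


def introgression_recovery(seed: int, genotype_error_rate: float = 0.02) -> dict:
    cfg = simdata.SimConfig(
        seed=seed,
        chrom_len=10_000_000,
        snp_density=1e-3,
        n_segments=5,
        segment_len_range=(200_000, 800_000),
        min_segment_gap=400_000,
        genotype_error_rate=genotype_error_rate,
    )
    snps, truth = simdata.simulate_trio(cfg)
    classified = varkit.classify_trio(
        varkit.filter_homozygous(snps["CL"]),
        varkit.filter_homozygous(snps["P1"]),
        varkit.filter_homozygous(snps["P2"]),
    )
    bins = varkit.bin_genome(
        classified, 100_000, 5, 0.9, chrom_sizes={"chr1": cfg.chrom_len}
    )
    called = bins["call"] == "parent2"
    overlap = np.zeros(len(bins))
    for chrom, s, e in truth.segments:
        lo = np.maximum(bins["start"], s)
        hi = np.minimum(bins["end"], e)
        overlap = np.maximum(
            overlap,
            np.where(bins["chrom"] == chrom, (hi - lo).clip(lower=0), 0),
        )
    width = (bins["end"] - bins["start"]).to_numpy()
    fully_inside = overlap >= width
    touches = overlap > 0
    recall = float((called & fully_inside).sum() / fully_inside.sum())
    precision = float((called & touches).sum() / max(called.sum(), 1))
    segments = varkit.call_segments(bins)
    boundary_ok = len(segments) == len(truth.segments) and all(
        abs(seg.start - s) <= 100_000 and abs(seg.end - e) <= 100_000
        for seg, (c, s, e) in zip(
            segments.itertuples(index=False), truth.segments
        )
    )
    return {
        "bin_precision": precision,
        "bin_recall": recall,
        "boundaries_within_one_bin": float(boundary_ok),
        "n_bins": int(len(bins)),
    }


# ---------------------------------------------------------------------------
# 2. hypergeometric oracle


def _enumeration_tail(k, n, K, N, tail):
    marked = set(range(K))
    total = hits = 0
    for draw in itertools.combinations(range(N), n):
        total += 1
        ov = len(marked.intersection(draw))
        if (tail == "upper" and ov >= k) or (tail == "lower" and ov <= k):
            hits += 1
    return hits / total


def hypergeom_exhaustive(max_n: int = 12) -> dict:
    worst = 0.0
    checked = 0
    for N in range(1, max_n + 1):
        for K in range(N + 1):
            for n in range(N + 1):
                for k in range(min(n, K) + 1):
                    for tail in ("upper", "lower"):
                        got = setkit.hypergeom_tail(k, n, K, N, tail)
                        want = _enumeration_tail(k, n, K, N, tail)
                        rel = abs(got - want) / max(want, 1e-300)
                        worst = max(worst, rel)
                        checked += 1
    spec_cases = (
        setkit.hypergeom_tail(3, 5, 4, 10, "upper"),
        setkit.hypergeom_tail(4, 5, 4, 10, "upper"),
    )
    return {
        "max_relative_error": worst,
        "n_checked": checked,
        "case_11_42": spec_cases[0],
        "case_6_252": spec_cases[1],
    }


# ---------------------------------------------------------------------------
# 3. BH oracle


def _bh_definition(p):
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    q = [0.0] * m
    prev = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        prev = min(prev, p[i] * m / rank)
        q[i] = prev
    return np.array(q)


def bh_oracle(seed: int, n_vectors: int = 1000) -> dict:
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_vectors):
        m = int(rng.integers(1, 60))
        p = rng.uniform(size=m)
        diff = np.abs(setkit.bh_adjust(p) - _bh_definition(list(p)))
        worst = max(worst, float(diff.max()))
    return {"max_abs_error": worst, "n_vectors": n_vectors}


# ---------------------------------------------------------------------------
# 4. DE calibration


def _two_group(rng, n_genes, n_reps, mu, dispersion, fold=None):
    mu = np.broadcast_to(np.asarray(mu, dtype=float), (n_genes,))
    mu_b = mu if fold is None else mu * np.asarray(fold)
    r = 1.0 / dispersion
    a = rng.negative_binomial(r, r / (r + mu[:, None]), size=(n_genes, n_reps))
    b = rng.negative_binomial(r, r / (r + mu_b[:, None]), size=(n_genes, n_reps))
    cols = [f"A_T1_r{i}" for i in range(n_reps)] + [
        f"A_T2_r{i}" for i in range(n_reps)
    ]
    counts = pd.DataFrame(
        np.hstack([a, b]), columns=cols,
        index=[f"g{i}" for i in range(n_genes)],
    )
    samples = pd.DataFrame(
        {
            "sample": cols,
            "genotype": "A",
            "timepoint": ["T1"] * n_reps + ["T2"] * n_reps,
            "replicate": list(range(n_reps)) * 2,
        }
    )
    return counts, samples


def de_calibration(seed: int) -> dict:
    rng = np.random.default_rng(seed)
    n_genes = 2000
    mu = rng.lognormal(np.log(200), 0.8, size=n_genes)
    counts, samples = _two_group(rng, n_genes, 3, mu, 0.1)
    null = exprkit.de_test(counts, samples, "A", ("T1", "T2"))
    type1 = float((null["p"] < 0.05).mean())
    ks = float(stats.kstest(null["p"], "uniform").statistic)
    # planted 4-fold genes among nulls at simdata's default dispersion
    fold = np.ones(n_genes)
    planted = np.zeros(n_genes, dtype=bool)
    planted[rng.choice(n_genes, 200, replace=False)] = True
    fold[planted] = 4.0
    counts2, _ = _two_group(rng, n_genes, 3, mu, 0.05, fold=fold)
    res = exprkit.de_test(counts2, samples, "A", ("T1", "T2"))
    power = float((res.loc[planted.nonzero()[0], "direction"] != "ns").mean())
    return {"type1_at_p05": type1, "ks_statistic": ks, "power_q05": power}


# ---------------------------------------------------------------------------
# 5. module recovery


def module_recovery(seed: int) -> dict:
    cfg = simdata.SimConfig(seed=seed)  # 5000 genes, 6 planted modules
    bundle = simdata.simulate_all(cfg)
    genes = bundle.truth.genes
    lengths = pd.Series(
        (genes["end"] - genes["start"]).to_numpy(), index=genes["gene_id"]
    )
    log = exprkit.log_rpkm(exprkit.rpkm(bundle.counts, lengths))
    cols = [c for c in log.columns if c.startswith(f"{GENOTYPE}_")]
    mods = netkit.detect_modules(log[cols])
    truth_labels = np.array(
        [bundle.truth.module_labels[g] for g in log.index]
    )
    ari = _adjusted_rand(truth_labels, mods.labels.to_numpy())
    # single-gene eigengene identity
    rng = np.random.default_rng(seed)
    profile = pd.DataFrame([rng.normal(size=12)], index=["g"])
    eg = netkit.module_eigengene(profile, pd.Series({"g": 1}))[0]
    z = (profile.loc["g"] - profile.loc["g"].mean()) / profile.loc["g"].std(
        ddof=0
    )
    single_err = float(np.max(np.abs(eg.profile.to_numpy() - z.to_numpy())))
    # orthogonal two-gene module: var_explained exactly 0.5
    a = np.array([1.0, -1.0, 1.0, -1.0])
    b = np.array([1.0, 1.0, -1.0, -1.0])
    pair = pd.DataFrame([a, b], index=["g1", "g2"])
    eg2 = netkit.module_eigengene(pair, pd.Series({"g1": 1, "g2": 1}))[0]
    return {
        "adjusted_rand_index": float(ari),
        "single_gene_eigengene_max_error": single_err,
        "orthogonal_pair_var_explained": float(eg2.var_explained),
    }


def _adjusted_rand(a: np.ndarray, b: np.ndarray) -> float:
    """Adjusted Rand index from the pair-counting contingency table."""
    ai = {v: i for i, v in enumerate(np.unique(a))}
    bi = {v: i for i, v in enumerate(np.unique(b))}
    table = np.zeros((len(ai), len(bi)), dtype=np.int64)
    for x, y in zip(a, b):
        table[ai[x], bi[y]] += 1
    comb = lambda x: x * (x - 1) / 2.0
    sum_ij = comb(table).sum()
    sum_a = comb(table.sum(axis=1)).sum()
    sum_b = comb(table.sum(axis=0)).sum()
    n = comb(len(a))
    expected = sum_a * sum_b / n
    max_index = (sum_a + sum_b) / 2.0
    if max_index == expected:
        return 1.0
    return float((sum_ij - expected) / (max_index - expected))


# ---------------------------------------------------------------------------
# 6. directional enrichment end to end


def directional_enrichment_once(seed: int) -> tuple[float, bool]:
    """One scaled rerun: (hypergeometric p, planted over/under reproduced)."""
    cfg = simdata.SimConfig(
        seed=seed,
        n_genes=1500,
        n_modules=3,
        module_size_range=(90, 140),
        t6p_set_size=150,
        n_de_genes=100,
        frac_t6p_in_introgression=0.25,
    )
    bundle = simdata.simulate_all(cfg)
    genes = bundle.truth.genes
    classified = varkit.classify_trio(
        varkit.filter_homozygous(bundle.snps["CL"]),
        varkit.filter_homozygous(bundle.snps["P1"]),
        varkit.filter_homozygous(bundle.snps["P2"]),
    )
    bins = varkit.bin_genome(
        classified, 20_000, 3, 0.9, chrom_sizes={"chr1": cfg.chrom_len}
    )
    segments = varkit.call_segments(bins, genes)
    seg_genes = varkit.segment_gene_ids(segments)
    de_cl = exprkit.de_any(
        [
            exprkit.de_test(bundle.counts, bundle.samples, GENOTYPE, (a, b))
            for a, b in zip(TIMEPOINTS, TIMEPOINTS[1:])
        ]
    )
    universe = set(bundle.counts.index)
    introgressed_degs = seg_genes & de_cl
    t6p = set(bundle.truth.t6p_set)
    p = setkit.hypergeom_tail(
        len(introgressed_degs & t6p),
        len(introgressed_degs),
        len(t6p),
        len(universe),
        "upper",
    )
    lengths = pd.Series(
        (genes["end"] - genes["start"]).to_numpy(), index=genes["gene_id"]
    )
    log = exprkit.log_rpkm(exprkit.rpkm(bundle.counts, lengths))
    cols = [c for c in log.columns if c.startswith(f"{GENOTYPE}_")]
    mods = netkit.detect_modules(log[cols])
    sets = [
        setkit.GeneSet("t6p_induced", "native", "induced",
                       frozenset(bundle.truth.t6p_induced)),
        setkit.GeneSet("t6p_repressed", "native", "repressed",
                       frozenset(bundle.truth.t6p_repressed)),
    ]
    mat = setkit.directional_matrix(mods.labels, sets, universe)
    truth_mod1 = {
        g for g, m in bundle.truth.module_labels.items() if m == 1
    }
    best, best_overlap = None, 0
    for m in mods.modules():
        overlap = len(set(mods.labels.index[mods.labels == m]) & truth_mod1)
        if overlap > best_overlap:
            best, best_overlap = m, overlap
    pattern_ok = (
        best is not None
        and mat.at[str(best), "t6p_induced"] == "over"
        and mat.at[str(best), "t6p_repressed"] == "under"
    )
    return p, bool(pattern_ok)


def directional_enrichment(seed: int, n_reruns: int = 100) -> dict:
    successes = 0
    worst_p = 0.0
    for i in range(n_reruns):
        p, pattern_ok = directional_enrichment_once(seed * 100_003 + i)
        worst_p = max(worst_p, p)
        successes += int(p < 1e-6 and pattern_ok)
    return {
        "n_success": successes,
        "n_reruns": n_reruns,
        "worst_p": worst_p,
    }


# ---------------------------------------------------------------------------
# 7. candidate filter exactness


def candidate_exactness(seed: int) -> dict:
    cfg = simdata.SimConfig(seed=seed)
    bundle = simdata.simulate_all(cfg)
    genes = bundle.truth.genes
    classified = varkit.classify_trio(
        varkit.filter_homozygous(bundle.snps["CL"]),
        varkit.filter_homozygous(bundle.snps["P1"]),
        varkit.filter_homozygous(bundle.snps["P2"]),
    )
    bins = varkit.bin_genome(
        classified, 20_000, 3, 0.9, chrom_sizes={"chr1": cfg.chrom_len}
    )
    segments = varkit.call_segments(bins)
    de_cl = exprkit.de_any(
        [
            exprkit.de_test(bundle.counts, bundle.samples, GENOTYPE, (a, b))
            for a, b in zip(TIMEPOINTS, TIMEPOINTS[1:])
        ]
    )
    lengths = pd.Series(
        (genes["end"] - genes["start"]).to_numpy(), index=genes["gene_id"]
    )
    log = exprkit.log_rpkm(exprkit.rpkm(bundle.counts, lengths))
    means = exprkit.group_means(log, bundle.samples)
    signal = sigkit.metabolite_means(bundle.metabolites, simdata.T6P_ID)
    r = sigkit.correlate_with_signal(means, signal)
    got = set(
        sigkit.candidate_filter(genes, segments, de_cl, r, r_min=0.7)["gene"]
    )
    want = set(bundle.truth.candidates)
    sizes = []
    for r_min in (0.5, 0.6, 0.7, 0.8, 0.9):
        sizes.append(
            len(sigkit.candidate_filter(genes, segments, de_cl, r, r_min))
        )
    monotone = all(a >= b for a, b in zip(sizes, sizes[1:]))
    return {
        "n_planted": len(want),
        "n_recovered": len(got & want),
        "n_extra": len(got - want),
        "exact_match": float(got == want),
        "r_min_monotone": float(monotone),
        "sizes_by_r_min": sizes,
    }


# ---------------------------------------------------------------------------
# 8. variant-effect oracle (the brute-force oracle lives in the test suite;
# here we re-implement it so the script is standalone)


def effect_oracle(seed: int, n_snps: int = 1000) -> dict:
    from Bio.Seq import Seq

    rng = np.random.default_rng(seed)

    def oracle(snp, model, chrom_seq):
        exons = sorted(model.cds_exons)
        pos0 = snp.pos - 1
        if not any(s <= pos0 < e for s, e in exons):
            for (s1, e1), (s2, e2) in zip(exons, exons[1:]):
                if e1 <= pos0 < e1 + 2 or s2 - 2 <= pos0 < s2:
                    return "HIGH"
            return "MODIFIER"
        if model.cds_length() % 3 != 0:
            return "MODIFIER"
        mutated = chrom_seq[:pos0] + snp.alt + chrom_seq[pos0 + 1:]

        def protein(seq):
            cds = "".join(seq[s:e] for s, e in exons)
            if model.strand == "-":
                cds = str(Seq(cds).reverse_complement())
            return str(Seq(cds).translate())

        p_ref, p_alt = protein(chrom_seq), protein(mutated)
        diffs = [i for i, (x, y) in enumerate(zip(p_ref, p_alt)) if x != y]
        if not diffs:
            return "LOW"
        i = diffs[0]
        if p_alt[i] == "*" or p_ref[i] == "*":
            return "HIGH"
        if i == 0 and p_ref[0] == "M":
            return "HIGH"
        return "MODERATE"

    class Snp:
        def __init__(self, chrom, pos, ref, alt):
            self.chrom, self.pos, self.ref, self.alt = chrom, pos, ref, alt

    agree = checked = 0
    while checked < n_snps:
        strand = rng.choice(["+", "-"])
        n_exons = int(rng.integers(1, 4))
        lens = rng.integers(9, 60, size=n_exons)
        total = lens.sum() - lens.sum() % 3
        lens[-1] -= lens.sum() - total
        if lens[-1] < 3:
            lens[-1] += 3
        pos = 10
        exons = []
        for L in lens:
            exons.append((pos, pos + int(L)))
            pos += int(L) + int(rng.integers(8, 30))
        chrom_seq = "".join(rng.choice(list("ACGT"), size=pos + 10))
        model = varkit.GeneModel("g", "chr1", strand, exons)
        lo, hi = exons[0][0], exons[-1][1]
        for _ in range(10):
            p0 = int(rng.integers(max(lo - 5, 0), hi + 5))
            ref = chrom_seq[p0]
            alt = rng.choice([b for b in "ACGT" if b != ref])
            snp = Snp("chr1", p0 + 1, ref, alt)
            got = varkit.predict_effect(snp, model, chrom_seq).effect
            agree += got == oracle(snp, model, chrom_seq)
            checked += 1
    return {"agreement": agree / checked, "n_snps": checked}


# ---------------------------------------------------------------------------
# 9. metabolome statistics


def metabolome_stats(seed: int) -> dict:
    rng = np.random.default_rng(seed)
    consistent = 0
    n_fixtures = 100
    for _ in range(n_fixtures):
        k = int(rng.integers(3, 6))
        groups = {
            f"g{i}": rng.normal(rng.uniform(0, 3), rng.uniform(0.5, 2.0),
                                int(rng.integers(3, 7)))
            for i in range(k)
        }
        res = metkit.anova_tukey_letters(groups)
        letters = dict(zip(res["group"], res["letters"]))
        pairs = metkit.tukey_pairwise(groups)
        ok = all(
            bool(set(letters[r.group_a]) & set(letters[r.group_b]))
            != bool(r.significant)
            for r in pairs.itertuples(index=False)
        )
        consistent += ok
    # Welch p vs a permutation null of the Welch t statistic itself
    worst_dp = 0.0
    n_perm = 100_000
    m = 12
    for _ in range(5):
        a = rng.normal(0.0, 1.0, m)
        b = rng.normal(rng.uniform(0, 1.5), 1.3, m)
        t_obs, _, p = metkit.welch_t(a, b)
        pooled = np.concatenate([a, b])
        idx = rng.random((n_perm, 2 * m)).argsort(axis=1)
        perm = pooled[idx]
        x, y = perm[:, :m], perm[:, m:]
        se2 = x.var(1, ddof=1) / m + y.var(1, ddof=1) / m
        t_perm = np.abs(x.mean(1) - y.mean(1)) / np.sqrt(se2)
        p_perm = float((t_perm >= abs(t_obs) - 1e-12).mean())
        worst_dp = max(worst_dp, abs(p - p_perm))
    # PCA closed form (exact construction, r = 0.8)
    n, r = 200, 0.8
    z1 = rng.normal(size=n)
    z2 = rng.normal(size=n)
    z1 = (z1 - z1.mean()) / z1.std()
    z2 = z2 - z2.mean()
    z2 -= z1 * (z1 @ z2) / (z1 @ z1)
    z2 /= z2.std()
    mat = pd.DataFrame({"x": z1, "y": r * z1 + np.sqrt(1 - r**2) * z2})
    _, frac = metkit.pca_summary(mat)
    return {
        "tukey_letters_consistent": consistent,
        "n_fixtures": n_fixtures,
        "welch_vs_permutation_max_dp": worst_dp,
        "pca_pc1_fraction": float(frac[0]),
    }
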