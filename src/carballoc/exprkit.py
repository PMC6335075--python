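"""Expression normalization, NB exact differential expression and z-scoring.

The differential test is a single documented negative-binomial exact test on
replicate sums (conditional two-sided "minimum likelihood" rule), with
method-of-moments tagwise dispersion shrunk toward a trimmed common value.
It stands in for the DESeq/edgeR intersection used upstream of this artifact.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .setkit import bh_adjust

DIRECTIONS = ("up", "down", "ns")


def rpkm(
    counts: pd.DataFrame,
    gene_lengths: pd.Series,
    library_sizes: pd.Series | None = None,
) -> pd.DataFrame:
    """Reads per kilobase per million mapped reads.

    value = count / ((length/1e3) * (library_size/1e6)).
    """
    missing = counts.index.difference(gene_lengths.index)
    if len(missing):
        raise KeyError(
            f"missing gene lengths for {len(missing)} genes: "
            f"{', '.join(map(str, missing[:5]))}"
        )
    lengths = gene_lengths.loc[counts.index].astype(float)
    if (lengths <= 0).any():
        raise ValueError("gene lengths must be > 0")
    if library_sizes is None:
        library_sizes = counts.sum(axis=0).astype(float)
    else:
        library_sizes = library_sizes.loc[counts.columns].astype(float)
    if (library_sizes <= 0).any():
        raise ValueError("library sizes must be > 0")
    denom = np.outer(lengths / 1e3, library_sizes / 1e6)
    return counts / denom


def log_rpkm(rpkm_values: pd.DataFrame) -> pd.DataFrame:
    """Companion transform log2(RPKM + 1)."""
    return np.log2(rpkm_values + 1.0)


def expressed_filter(
    expr: pd.DataFrame,
    samples: pd.DataFrame,
    min_rpkm: float = 1.0,
    min_samples: int = 2,
) -> list[str]:
    """Genes with RPKM >= min_rpkm in >= min_samples samples of any genotype."""
    if min_rpkm < 0 or min_samples < 0:
        raise ValueError("thresholds must be >= 0")
    keep = pd.Series(False, index=expr.index)
    for _, sub in samples.groupby("genotype"):
        cols = [c for c in sub["sample"] if c in expr.columns]
        keep |= (expr[cols] >= min_rpkm).sum(axis=1) >= min_samples
    return list(expr.index[keep])


# ---------------------------------------------------------------------------
# NB exact test


def _pseudo_counts(counts: np.ndarray) -> np.ndarray:
    """Equalize sequencing depth across columns and round.

    Size factors are median-of-ratios to the per-gene geometric mean
    (composition-robust); falls back to total counts when too few genes are
    everywhere-positive.
    """
    counts = np.asarray(counts)
    pos = (counts > 0).all(axis=1)
    if pos.sum() >= 50:
        logc = np.log(counts[pos].astype(float))
        ratios = logc - logc.mean(axis=1, keepdims=True)
        factors = np.exp(np.median(ratios, axis=0))
    else:
        lib = counts.sum(axis=0).astype(float)
        lib[lib == 0] = 1.0
        factors = lib / lib.mean()
    factors = factors / factors.mean()
    return np.rint(counts / factors).astype(np.int64)


def _mom_dispersion(a: np.ndarray, b: np.ndarray, shrink: float) -> np.ndarray:
    """Per-gene NB dispersion: pooled within-condition method of moments,
    shrunk toward the trimmed common value."""
    means = np.stack([a.mean(1), b.mean(1)])
    variances = np.stack([a.var(1, ddof=1), b.var(1, ddof=1)])
    mu = means.mean(0)
    pooled_var = variances.mean(0)
    with np.errstate(divide="ignore", invalid="ignore"):
        tag = (pooled_var - mu) / np.square(mu)
    raw = np.where(np.isfinite(tag), tag, 0.0)
    tag = raw.clip(min=0.0)
    usable = mu > 0
    # common dispersion: mean of the *unclipped* per-gene moment estimates
    # (clipping at zero before averaging biases the common value upward only
    # for the clipped genes and downward overall)
    common = max(float(raw[usable].mean()), 0.0) if usable.any() else 0.0
    return shrink * common + (1.0 - shrink) * tag


def _exact_nb_pvalue(s1: int, s2: int, n1: int, n2: int, alpha: float) -> float:
    """Two-sided conditional exact test for S1 + S2 = s.

    Under H0 both groups share the per-replicate mean; outcomes (a, s-a) with
    joint likelihood <= the observed one contribute to p.
    """
    s = s1 + s2
    if s == 0:
        return 1.0
    a = np.arange(s + 1)
    mu = s / (n1 + n2)
    if alpha < 1e-8:
        # Poisson limit: conditionally binomial (already normalized)
        joint = stats.binom.logpmf(a, s, n1 / (n1 + n2))
        norm = 0.0
    else:
        r1, r2 = n1 / alpha, n2 / alpha
        m1, m2 = n1 * mu, n2 * mu
        lp1 = stats.nbinom.logpmf(a, r1, r1 / (r1 + m1))
        lp2 = stats.nbinom.logpmf(s - a, r2, r2 / (r2 + m2))
        joint = lp1 + lp2
        norm = _logsumexp(joint)
    keep = joint - joint[s1] <= 1e-10
    return float(np.exp(_logsumexp(joint[keep]) - norm))


def _logsumexp(x: np.ndarray) -> float:
    m = np.max(x)
    if np.isneginf(m):
        return m
    return float(m + np.log(np.sum(np.exp(x - m))))


def de_test(
    counts: pd.DataFrame,
    samples: pd.DataFrame,
    genotype: str,
    contrast: tuple[str, str],
    shrink: float = 0.5,
    q_max: float = 0.05,
    lfc_min: float = 1.0,
) -> pd.DataFrame:
    """Per-gene NB exact test between two timepoints within one genotype.

    Returns a frame with gene, contrast, log2fc (timepoint_b over
    timepoint_a), p, BH-adjusted q, and direction in {up, down, ns} under the
    rule q < q_max and |log2fc| >= lfc_min.
    """
    t_a, t_b = contrast
    sub = samples[samples["genotype"] == genotype]
    cols_a = list(sub.loc[sub["timepoint"] == t_a, "sample"])
    cols_b = list(sub.loc[sub["timepoint"] == t_b, "sample"])
    if len(cols_a) < 2 or len(cols_b) < 2:
        raise ValueError(
            f"contrast level missing or unreplicated for genotype {genotype}: "
            f"{t_a} ({len(cols_a)} reps), {t_b} ({len(cols_b)} reps)"
        )
    raw = counts[cols_a + cols_b].to_numpy()
    pseudo = _pseudo_counts(raw)
    a = pseudo[:, : len(cols_a)]
    b = pseudo[:, len(cols_a) :]
    alpha = _mom_dispersion(a, b, shrink)
    s1 = a.sum(1)
    s2 = b.sum(1)
    n1, n2 = a.shape[1], b.shape[1]
    p = np.array(
        [
            _exact_nb_pvalue(int(s1[i]), int(s2[i]), n1, n2, float(alpha[i]))
            for i in range(len(s1))
        ]
    ).clip(max=1.0)
    log2fc = np.log2((s2 / n2 + 0.5) / (s1 / n1 + 0.5))
    q = bh_adjust(p)
    direction = np.where(
        (q < q_max) & (np.abs(log2fc) >= lfc_min),
        np.where(log2fc > 0, "up", "down"),
        "ns",
    )
    return pd.DataFrame(
        {
            "gene": counts.index,
            "timepoint_a": t_a,
            "timepoint_b": t_b,
            "log2fc": log2fc,
            "p": p,
            "q": q,
            "direction": direction,
        }
    )


def de_any(results: list[pd.DataFrame]) -> set[str]:
    """Genes called up or down in any of the given DE result frames."""
    out: set[str] = set()
    for df in results:
        out.update(df.loc[df["direction"] != "ns", "gene"])
    return out


# ---------------------------------------------------------------------------
# standardization


def group_means(
    expr: pd.DataFrame, samples: pd.DataFrame
) -> pd.DataFrame:
    """Replicate means per genotype x timepoint; columns '<geno>_<tp>'."""
    cols = {}
    for (geno, tp), sub in samples.groupby(["genotype", "timepoint"], sort=False):
        use = [c for c in sub["sample"] if c in expr.columns]
        cols[f"{geno}_{tp}"] = expr[use].mean(axis=1)
    return pd.DataFrame(cols)


def zscore(
    expr: pd.DataFrame,
    samples: pd.DataFrame | None = None,
    replicate_level: bool = False,
) -> pd.DataFrame:
    """Per-gene z-score across genotype x timepoint replicate means.

    With ``replicate_level=True`` (or no sample sheet) standardization runs
    across the supplied columns directly. Zero-variance genes map to zeros.
    """
    if samples is not None and not replicate_level:
        mat = group_means(expr, samples)
    else:
        mat = expr
    mean = mat.mean(axis=1)
    sd = mat.std(axis=1, ddof=0)
    z = mat.sub(mean, axis=0).div(sd.replace(0.0, np.nan), axis=0)
    return z.fillna(0.0)
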