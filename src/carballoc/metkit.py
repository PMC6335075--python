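"""Metabolome statistics: median normalization, PCA, one-way ANOVA with Tukey
HSD compact letters, Welch tests, category summaries and Brix-sugar
correlation."""

from __future__ import annotations

import string

import numpy as np
import pandas as pd
from scipy import stats

SUGARS = ("sucrose", "glucose", "fructose")


def median_normalize(
    table: pd.DataFrame,
    value_col: str = "abundance",
    batch_col: str | None = None,
) -> pd.DataFrame:
    """Divide each run block by its median so the block median becomes 1.

    With no batch column the whole table is one block. Idempotent; a zero
    block median is an error.
    """
    out = table.copy()
    if batch_col is None or batch_col not in out.columns:
        groups = [(None, out.index)]
    else:
        groups = [(b, idx) for b, idx in out.groupby(batch_col).groups.items()]
    for batch, idx in groups:
        med = float(out.loc[idx, value_col].median())
        if med == 0:
            raise ValueError(f"zero median in block {batch!r}")
        out.loc[idx, value_col] = out.loc[idx, value_col] / med
    return out


def impute_minimum(table: pd.DataFrame, value_col: str = "abundance") -> pd.DataFrame:
    """Fill missing values per metabolite with its minimum observed value."""
    out = table.copy()
    out[value_col] = out.groupby("metabolite")[value_col].transform(
        lambda s: s.fillna(s.min())
    )
    return out


def pca_summary(matrix: pd.DataFrame) -> tuple[pd.DataFrame, np.ndarray]:
    """Column-standardized PCA via SVD.

    ``matrix`` is samples x variables. Returns (scores, variance fractions);
    fractions sum to 1, scores are reproducible up to sign. Zero-variance
    columns are dropped; an all-constant matrix is an error.
    """
    if matrix.shape[0] < 3:
        raise ValueError("PCA needs at least 3 samples")
    x = matrix.to_numpy(dtype=float)
    sd = x.std(axis=0, ddof=0)
    keep = sd > 0
    if not keep.any():
        raise ValueError("matrix is constant; PCA undefined")
    z = (x[:, keep] - x[:, keep].mean(axis=0)) / sd[keep]
    u, s, _ = np.linalg.svd(z, full_matrices=False)
    frac = s**2 / np.sum(s**2)
    scores = pd.DataFrame(
        u * s,
        index=matrix.index,
        columns=[f"PC{i + 1}" for i in range(len(s))],
    )
    return scores, frac


# ---------------------------------------------------------------------------
# ANOVA + Tukey compact letter display


def tukey_pairwise(
    values_by_group: dict[str, np.ndarray], alpha: float = 0.05
) -> pd.DataFrame:
    """Tukey(-Kramer) HSD p-values for all group pairs.

    Uses the studentized-range distribution on the one-way ANOVA MSE. With
    zero within-group variance, differing means get p=0 and equal means p=1.
    """
    names = list(values_by_group)
    if len(names) < 2:
        raise ValueError("need at least 2 groups")
    arrays = [np.asarray(values_by_group[g], dtype=float) for g in names]
    if any(len(a) < 2 for a in arrays):
        raise ValueError("need >= 2 replicates per group")
    k = len(names)
    ns = np.array([len(a) for a in arrays])
    means = np.array([a.mean() for a in arrays])
    df_err = int(ns.sum() - k)
    sse = sum(((a - a.mean()) ** 2).sum() for a in arrays)
    mse = sse / df_err
    rows = []
    for i in range(k):
        for j in range(i + 1, k):
            diff = abs(means[i] - means[j])
            if mse == 0:
                p = 1.0 if diff == 0 else 0.0
            else:
                se = np.sqrt(mse / 2.0 * (1.0 / ns[i] + 1.0 / ns[j]))
                q = diff / se
                p = float(stats.studentized_range.sf(q, k, df_err))
            rows.append((names[i], names[j], means[i], means[j], p, p < alpha))
    return pd.DataFrame(
        rows, columns=["group_a", "group_b", "mean_a", "mean_b", "p", "significant"]
    )


def compact_letter_display(
    names: list[str],
    means: dict[str, float],
    significant_pairs: set[tuple[str, str]],
) -> dict[str, str]:
    """Insert-and-absorb compact letters.

    Two groups share a letter iff their pair is not in ``significant_pairs``.
    Letters are assigned in decreasing group-mean order.
    """
    order = sorted(names, key=lambda g: means[g])  # lowest mean gets 'a'
    columns: list[set[str]] = [set(order)]
    for a, b in significant_pairs:
        new_columns: list[set[str]] = []
        for col in columns:
            if a in col and b in col:
                new_columns.append(col - {a})
                new_columns.append(col - {b})
            else:
                new_columns.append(col)
        # absorb: drop columns contained in another
        columns = []
        for col in new_columns:
            if not col:
                continue
            if any(col < other for other in new_columns if other is not col):
                continue
            if col in columns:
                continue
            columns.append(col)
    # stable letter order: by the highest-mean member of each column
    columns.sort(key=lambda col: min(order.index(g) for g in col))
    alphabet = string.ascii_lowercase
    letters = {g: "" for g in names}
    for i, col in enumerate(columns):
        ch = alphabet[i % len(alphabet)] * (1 + i // len(alphabet))
        for g in order:
            if g in col:
                letters[g] += ch
    return letters


def anova_tukey_letters(
    values_by_group: dict[str, np.ndarray], alpha: float = 0.05
) -> pd.DataFrame:
    """One-way ANOVA, Tukey HSD and compact letters per group."""
    pairs = tukey_pairwise(values_by_group, alpha=alpha)
    arrays = [np.asarray(v, dtype=float) for v in values_by_group.values()]
    try:
        anova_p = float(stats.f_oneway(*arrays).pvalue)
    except Exception:
        anova_p = np.nan
    sig = {
        (r.group_a, r.group_b)
        for r in pairs.itertuples(index=False)
        if r.significant
    }
    sig |= {(b, a) for a, b in sig}
    means = {g: float(np.mean(v)) for g, v in values_by_group.items()}
    letters = compact_letter_display(list(values_by_group), means, sig)
    return pd.DataFrame(
        {
            "group": list(values_by_group),
            "mean": [means[g] for g in values_by_group],
            "letters": [letters[g] for g in values_by_group],
            "anova_p": anova_p,
        }
    )


def welch_t(sample_a, sample_b) -> tuple[float, float, float]:
    """Welch unequal-variance t test: (t, Welch-Satterthwaite df, two-sided p)."""
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need n >= 2 in each sample")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    na, nb = len(a), len(b)
    if va == 0 and vb == 0:
        if a.mean() == b.mean():
            return 0.0, float(na + nb - 2), 1.0
        return float(np.inf * np.sign(a.mean() - b.mean())), float(na + nb - 2), 0.0
    se2 = va / na + vb / nb
    t = (a.mean() - b.mean()) / np.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p = 2.0 * float(stats.t.sf(abs(t), df))
    return float(t), float(df), p


def diff_metabolite_summary(
    metabolites: pd.DataFrame,
    alpha: float = 0.05,
    factor: str = "timepoint",
) -> pd.DataFrame:
    """Counts of significant metabolites per category per genotype.

    Per genotype and metabolite, a one-way ANOVA across ``factor`` levels
    (replicates as observations); significant if p < alpha.
    """
    rows = []
    for (geno, met), sub in metabolites.groupby(["genotype", "metabolite"]):
        groups = [g["abundance"].to_numpy() for _, g in sub.groupby(factor)]
        if len(groups) < 2 or any(len(g) < 2 for g in groups):
            continue
        if all(np.allclose(g, groups[0][0]) for g in groups):
            p = 1.0
        else:
            p = float(stats.f_oneway(*groups).pvalue)
        rows.append((geno, met, sub["category"].iloc[0], p, p < alpha))
    tests = pd.DataFrame(
        rows, columns=["genotype", "metabolite", "category", "p", "significant"]
    )
    summary = (
        tests[tests["significant"]]
        .groupby(["genotype", "category"])
        .size()
        .unstack(fill_value=0)
    )
    genotypes = sorted(metabolites["genotype"].unique())
    categories = sorted(metabolites["category"].unique())
    summary = summary.reindex(index=genotypes, columns=categories, fill_value=0)
    return summary.fillna(0).astype(int)


def brix_sugar_correlation(
    brix: pd.DataFrame, sugars: pd.DataFrame
) -> pd.Series:
    """Pearson r between Brix and total sugar per genotype.

    ``brix`` holds (genotype, timepoint, brix); ``sugars`` is a long
    metabolite table containing sucrose/glucose/fructose. Means are matched
    on genotype x timepoint; genotypes with < 3 matched points give NaN.
    """
    sug = sugars[sugars["metabolite"].isin(SUGARS)]
    total = (
        sug.groupby(["genotype", "timepoint", "metabolite"])["abundance"]
        .mean()
        .groupby(["genotype", "timepoint"])
        .sum()
        .rename("total_sugar")
        .reset_index()
    )
    bx = (
        brix.groupby(["genotype", "timepoint"])["brix"].mean().reset_index()
    )
    merged = bx.merge(total, on=["genotype", "timepoint"])
    out = {}
    for geno, sub in merged.groupby("genotype"):
        if len(sub) < 3:
            out[geno] = np.nan
            continue
        out[geno] = float(
            np.corrcoef(sub["brix"], sub["total_sugar"])[0, 1]
        )
    return pd.Series(out, name="r")
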