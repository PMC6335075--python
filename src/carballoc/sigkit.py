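"""Metabolite-signature layer: signal correlation, marker-panel scoring and
the stringent candidate filter (introgressed ∩ DE ∩ signal-correlated, with an
optional distinct-trend requirement between genotypes)."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .netkit import classify_trend

logger = logging.getLogger(__name__)


@dataclass
class CandidateGene:
    gene: str
    introgressed: bool
    de: bool
    r_t6p: float
    distinct_pattern: bool | None = None
    category: str = ""


def metabolite_means(
    metabolites: pd.DataFrame, metabolite: str, genotypes=None
) -> pd.Series:
    """Replicate-mean signal per (genotype, timepoint), concatenated in
    genotype then timepoint order; index '<geno>_<tp>'."""
    sub = metabolites[metabolites["metabolite"] == metabolite]
    if sub.empty:
        raise ValueError(f"metabolite {metabolite!r} not in table")
    if genotypes is not None:
        sub = sub[sub["genotype"].isin(genotypes)]
    means = (
        sub.groupby(["genotype", "timepoint"], sort=True)["abundance"]
        .mean()
    )
    means.index = [f"{g}_{t}" for g, t in means.index]
    return means


def correlate_with_signal(
    expr_means: pd.DataFrame,
    signal: pd.Series,
    mode: str = "signed",
) -> pd.Series:
    """Pearson correlation of each gene's genotype x timepoint mean profile
    with the signal over the shared columns.

    ``expr_means`` columns and the signal index share the '<geno>_<tp>'
    convention (see :func:`carballoc.exprkit.group_means`). Genes are skipped
    (NaN) when fewer than 3 aligned points or zero variance; ``mode`` is
    'signed' or 'absolute'.
    """
    shared = [c for c in expr_means.columns if c in signal.index]
    if len(shared) < 3:
        raise ValueError(
            f"only {len(shared)} aligned genotype/timepoint means (need >= 3)"
        )
    x = expr_means[shared].to_numpy(dtype=float)
    y = signal.loc[shared].to_numpy(dtype=float)
    yz = y - y.mean()
    ysd = yz.std(ddof=0)
    xz = x - x.mean(axis=1, keepdims=True)
    xsd = xz.std(axis=1, ddof=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (xz @ (yz / ysd)) / (xsd * len(shared))
    bad = ~np.isfinite(r)
    if bad.any():
        logger.info("skipped %d zero-variance genes in signal correlation",
                    int(bad.sum()))
    r[bad] = np.nan
    if mode == "absolute":
        r = np.abs(r)
    elif mode != "signed":
        raise ValueError("mode must be 'signed' or 'absolute'")
    return pd.Series(r, index=expr_means.index, name="r")


def marker_panel_score(
    zexpr: pd.DataFrame, panel: dict[str, str]
) -> pd.Series:
    """Mean signed z-score of a marker panel per column.

    ``panel`` maps gene -> expected direction ('induced' contributes +z,
    'repressed' contributes -z). Genes absent from the matrix are dropped;
    an empty mapped panel is an error.
    """
    signs = {"induced": 1.0, "repressed": -1.0}
    rows, weights = [], []
    for gene, direction in panel.items():
        if direction not in signs:
            raise ValueError(f"panel direction {direction!r} invalid")
        if gene in zexpr.index:
            rows.append(gene)
            weights.append(signs[direction])
    if not rows:
        raise ValueError("no panel genes present in the expression matrix")
    w = np.array(weights)
    return pd.Series(
        (zexpr.loc[rows].to_numpy() * w[:, None]).mean(axis=0),
        index=zexpr.columns,
        name="snrk1_score",
    )


def trend_classes(
    zexpr: pd.DataFrame, genotype_prefix: str, eps: float = 0.1
) -> pd.Series:
    """Per-gene trend class over one genotype's timepoint means."""
    cols = [c for c in zexpr.columns if c.startswith(genotype_prefix + "_")]
    return pd.Series(
        [classify_trend(row, eps) for row in zexpr[cols].to_numpy()],
        index=zexpr.index,
    )


def candidate_filter(
    genes: pd.DataFrame,
    segments: pd.DataFrame,
    de_genes: set,
    r_t6p: pd.Series,
    r_min: float = 0.7,
    trends_parent1: pd.Series | None = None,
    trends_conversion: pd.Series | None = None,
    require_distinct_pattern: bool = False,
) -> pd.DataFrame:
    """Genes that are introgressed, DE in the conversion line and
    |r| >= r_min against the signal; optionally also showing distinct trend
    classes between parent 1 and the conversion line.

    ``genes`` needs gene_id/chrom/start/end; ``segments`` chrom/start/end.
    Output rows pass every active filter.
    """
    for name, layer in (
        ("gene models", genes),
        ("introgression segments", segments),
        ("differential expression", de_genes),
        ("signal correlation", r_t6p),
    ):
        if layer is None:
            raise ValueError(f"missing upstream layer: {name}")
    if require_distinct_pattern and (
        trends_parent1 is None or trends_conversion is None
    ):
        raise ValueError("missing upstream layer: trend classes")
    introgressed = np.zeros(len(genes), dtype=bool)
    for seg in segments.itertuples(index=False):
        introgressed |= (
            (genes["chrom"] == seg.chrom)
            & (genes["start"] < seg.end)
            & (genes["end"] > seg.start)
        ).to_numpy()
    rows = []
    for i, g in enumerate(genes.itertuples(index=False)):
        gid = g.gene_id
        if not introgressed[i] or gid not in de_genes:
            continue
        r = float(r_t6p.get(gid, np.nan))
        if not np.isfinite(r) or abs(r) < r_min:
            continue
        distinct = None
        if require_distinct_pattern:
            tp = trends_parent1.get(gid)
            tc = trends_conversion.get(gid)
            distinct = tp is not None and tc is not None and tp != tc
            if not distinct:
                continue
        rows.append((gid, True, True, r, distinct))
    return pd.DataFrame(
        rows, columns=["gene", "introgressed", "de", "r_t6p", "distinct_pattern"]
    )


#: annotation keyword precedence: first match wins
CATEGORY_RULES: tuple[tuple[str, tuple[str, ...]], ...] = (
    ("regulation", ("transcription factor", "tf", "rna binding", "kinase",
                    "phosphatase regulator", "ubiquitin")),
    ("transport", ("transporter", "transport", "channel", "carrier")),
    ("metabolism", ("metabolism", "synthase", "synthetase", "hydrolase",
                    "invertase", "enzyme", "dehydrogenase", "transferase")),
)


def categorize_candidates(
    candidates: pd.DataFrame, annotation: pd.DataFrame
) -> tuple[pd.DataFrame, pd.Series]:
    """Assign one primary category per candidate by keyword precedence.

    ``annotation`` has columns (gene, annotation). Unannotated candidates get
    'unannotated'; annotated ones failing every rule get 'other'. Returns the
    annotated candidate frame and per-category counts (all categories
    present, zero-filled).
    """
    ann = dict(
        zip(annotation["gene"].astype(str), annotation["annotation"].astype(str))
    )
    cats = []
    for gene in candidates["gene"]:
        text = ann.get(gene)
        if text is None:
            cats.append("unannotated")
            continue
        low = text.lower()
        for category, keywords in CATEGORY_RULES:
            if any(k in low for k in keywords):
                cats.append(category)
                break
        else:
            cats.append("other")
    out = candidates.copy()
    out["category"] = cats
    all_cats = [c for c, _ in CATEGORY_RULES] + ["other", "unannotated"]
    counts = pd.Series(
        {c: int((out["category"] == c).sum()) for c in all_cats}, name="count"
    )
    return out, counts
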