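"""Gene-set machinery: ortholog mapping, hypergeometric over/under
enrichment with closed tails, BH adjustment, and module x set directional
calls.

Tail convention: both tails include P(X = k) (documented, since upstream
sources rarely state theirs). The universe is explicit and mandatory for
every test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

DIRECTIONS = ("induced", "repressed", "none")


@dataclass(frozen=True)
class GeneSet:
    id: str
    species: str = "native"
    direction: str = "none"
    members: frozenset = frozenset()

    def __post_init__(self):
        if self.direction not in DIRECTIONS:
            raise ValueError(f"direction must be one of {DIRECTIONS}")


def read_gene_sets(path: str) -> list[GeneSet]:
    """Long-format TSV (set_id, species, direction, gene) -> GeneSet list."""
    df = pd.read_csv(path, sep="\t")
    sets = []
    for sid, sub in df.groupby("set_id", sort=False):
        sets.append(
            GeneSet(
                id=str(sid),
                species=str(sub["species"].iloc[0]),
                direction=str(sub["direction"].iloc[0]),
                members=frozenset(sub["gene"].astype(str)),
            )
        )
    return sets


def read_gmt(path: str) -> list[GeneSet]:
    sets = []
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            sets.append(GeneSet(id=parts[0], members=frozenset(parts[2:])))
    return sets


def map_orthologs(
    sets: list[GeneSet], ortholog_map: pd.DataFrame
) -> list[GeneSet]:
    """Translate set members into the native id space.

    ``ortholog_map`` has columns (foreign, native); one-to-many expands and
    duplicates collapse. Unmapped members are dropped with a logged count;
    sets mapping to nothing are kept with size 0.
    """
    lut: dict[str, set[str]] = {}
    for foreign, native in ortholog_map.itertuples(index=False):
        lut.setdefault(str(foreign), set()).add(str(native))
    out = []
    for s in sets:
        mapped: set[str] = set()
        n_unmapped = 0
        for g in s.members:
            hits = lut.get(g)
            if hits:
                mapped.update(hits)
            else:
                n_unmapped += 1
        if n_unmapped:
            logger.info(
                "set %s: dropped %d/%d unmapped members", s.id, n_unmapped,
                len(s.members),
            )
        if not mapped:
            logger.warning("set %s mapped to zero native genes", s.id)
        out.append(
            GeneSet(s.id, s.species, s.direction, frozenset(mapped))
        )
    return out


# ---------------------------------------------------------------------------
# primitives


def hypergeom_tail(k: int, n: int, K: int, N: int, tail: str = "upper") -> float:
    """Closed hypergeometric tail, computed in log space.

    upper = P(X >= k), lower = P(X <= k) for X ~ Hypergeom(N, K, n).
    """
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError(f"require 0 <= K, n <= N (got K={K}, n={n}, N={N})")
    if not (0 <= k <= min(n, K)):
        raise ValueError(f"require 0 <= k <= min(n, K) (got k={k})")
    dist = stats.hypergeom(N, K, n)
    if tail == "upper":
        return float(np.exp(dist.logsf(k - 1))) if k > 0 else 1.0
    if tail == "lower":
        return float(np.exp(dist.logcdf(k)))
    raise ValueError("tail must be 'upper' or 'lower'")


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up; output order matches input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1].clip(max=1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


# ---------------------------------------------------------------------------
# enrichment


def enrich(
    query_lists: dict[str, set],
    sets: list[GeneSet],
    universe: set,
    p_max: float = 0.05,
    q_max: float = 0.2,
) -> pd.DataFrame:
    """Both-tail hypergeometric enrichment of each query against each set.

    Queries and sets are intersected with the universe first; BH runs within
    each query across sets, separately per tail. Rows carry significance
    flags under p <= p_max and q <= q_max.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    N = len(universe)
    rows = []
    for qid, qgenes in query_lists.items():
        qset = set(qgenes) & universe
        n = len(qset)
        p_over, p_under = [], []
        meta = []
        for s in sets:
            members = set(s.members) & universe
            K = len(members)
            k = len(qset & members)
            p_over.append(hypergeom_tail(k, n, K, N, "upper"))
            p_under.append(hypergeom_tail(k, n, K, N, "lower"))
            meta.append((qid, s.id, N, K, n, k))
        q_over = bh_adjust(p_over)
        q_under = bh_adjust(p_under)
        for i, (qid_, sid, N_, K_, n_, k_) in enumerate(meta):
            rows.append(
                (
                    qid_, sid, N_, K_, n_, k_,
                    p_over[i], p_under[i], q_over[i], q_under[i],
                    bool(p_over[i] <= p_max and q_over[i] <= q_max),
                    bool(p_under[i] <= p_max and q_under[i] <= q_max),
                )
            )
    return pd.DataFrame(
        rows,
        columns=[
            "query", "set", "N", "K", "n", "k",
            "p_over", "p_under", "q_over", "q_under",
            "sig_over", "sig_under",
        ],
    )


def directional_matrix(
    module_labels: pd.Series,
    sets: list[GeneSet],
    universe: set,
    p_max: float = 0.05,
    q_max: float = 0.2,
) -> pd.DataFrame:
    """Module x set matrix of {over, under, ns} calls.

    ``module_labels`` maps gene -> module id; module 0 (unassigned) is
    skipped. Significance follows :func:`enrich`.
    """
    queries = {
        str(m): set(module_labels.index[module_labels == m])
        for m in sorted(set(module_labels)) if m != 0
    }
    result = enrich(queries, sets, universe, p_max=p_max, q_max=q_max)
    mat = pd.DataFrame(
        "ns",
        index=list(queries),
        columns=[s.id for s in sets],
        dtype=object,
    )
    for row in result.itertuples(index=False):
        if row.sig_over:
            mat.at[row.query, row.set] = "over"
        elif row.sig_under:
            mat.at[row.query, row.set] = "under"
    return mat
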