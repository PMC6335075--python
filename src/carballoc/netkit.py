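"""Signed weighted co-expression modules, eigengenes, kME and preservation.

Adjacency is ((1 + cor) / 2) ** power; modules come from average-linkage
hierarchical clustering of 1 - adjacency with a static tree cut. Dynamic tree
cut and topological overlap are deliberately out of scope: the static cut is
fully specifiable and testable. Eigengenes are first right singular vectors of
the gene-standardized module submatrix, sign-oriented so the mean member
correlation is non-negative.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from scipy.stats import linregress

TRENDS = ("up", "down", "up-and-down", "down-and-up", "flat", "mixed")


class NetworkError(ValueError):
    pass


@dataclass
class ModuleSet:
    genotype: str
    labels: pd.Series  # gene -> module id, 0 = unassigned
    power: float
    cut_height: float
    linkage: np.ndarray | None = None

    def modules(self) -> list[int]:
        return sorted(m for m in set(self.labels) if m != 0)

    def members(self, module: int) -> list[str]:
        return list(self.labels.index[self.labels == module])


@dataclass
class Eigengene:
    module: int
    values: pd.Series  # unit-norm over samples
    var_explained: float

    @property
    def profile(self) -> pd.Series:
        """Eigengene rescaled to sd 1 (population sd) for plotting/trends."""
        sd = self.values.std(ddof=0)
        if sd == 0:
            return self.values * 0.0
        return (self.values - self.values.mean()) / sd


def _standardize(expr: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    x = expr.to_numpy(dtype=float)
    mean = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, ddof=0, keepdims=True)
    ok = sd[:, 0] > 0
    z = np.zeros_like(x)
    z[ok] = (x[ok] - mean[ok]) / sd[ok]
    return z, ok


def adjacency(expr: pd.DataFrame, power: float) -> np.ndarray:
    """Signed adjacency ((1 + cor)/2)^power over genes (rows)."""
    z, ok = _standardize(expr)
    n = z.shape[1]
    cor = (z @ z.T) / n
    cor[~ok, :] = 0.0
    cor[:, ~ok] = 0.0
    np.clip(cor, -1.0, 1.0, out=cor)
    np.fill_diagonal(cor, 1.0)
    return ((1.0 + cor) / 2.0) ** power


def pick_soft_threshold(
    expr: pd.DataFrame,
    candidate_powers=(1, 2, 3, 4, 5, 6, 7, 8, 9, 10, 12, 14, 16),
    r2_threshold: float = 0.8,
    n_bins: int = 10,
) -> float:
    """Smallest power reaching scale-free fit R^2 >= threshold.

    Fit: regression of log10(frequency) on log10(mean connectivity) over
    degree bins; only negative-slope fits count toward the threshold. Falls
    back to the power maximizing (signed) R^2.
    """
    candidate_powers = list(candidate_powers)
    if len(candidate_powers) == 1:
        return float(candidate_powers[0])
    best_power, best_r2 = None, -np.inf
    for power in candidate_powers:
        adj = adjacency(expr, power)
        k = adj.sum(axis=1) - 1.0
        r2, slope = _scale_free_fit(k, n_bins)
        signed = r2 if slope < 0 else -r2
        if slope < 0 and r2 >= r2_threshold:
            return float(power)
        if signed > best_r2:
            best_r2, best_power = signed, power
    return float(best_power)


def _scale_free_fit(k: np.ndarray, n_bins: int) -> tuple[float, float]:
    k = k[k > 0]
    if k.size == 0:
        raise NetworkError("no positive connectivities")
    edges = np.linspace(k.min(), k.max() + 1e-12, n_bins + 1)
    idx = np.clip(np.digitize(k, edges) - 1, 0, n_bins - 1)
    freq = np.bincount(idx, minlength=n_bins).astype(float)
    mean_k = np.array(
        [k[idx == b].mean() if freq[b] > 0 else np.nan for b in range(n_bins)]
    )
    usable = (freq > 0) & (mean_k > 0)
    if usable.sum() < 3:
        raise NetworkError(
            f"only {int(usable.sum())} usable degree bins (need >= 3)"
        )
    fit = linregress(np.log10(mean_k[usable]), np.log10(freq[usable]))
    return float(fit.rvalue**2), float(fit.slope)


def detect_modules(
    expr: pd.DataFrame,
    power: float = 6,
    min_module_size: int = 30,
    cut_height: float | None = None,
    genotype: str = "",
) -> ModuleSet:
    """Average-linkage clustering of 1 - signed adjacency, static cut.

    ``cut_height`` defaults to 0.25 x the maximum merge height. Clusters
    smaller than ``min_module_size`` (and zero-variance genes) become module
    0; surviving modules are renumbered 1.. by decreasing size.
    """
    genes = expr.index
    if len(genes) < max(min_module_size, 2):
        return ModuleSet(
            genotype,
            pd.Series(0, index=genes, dtype=int),
            power,
            float("nan"),
        )
    z, ok = _standardize(expr)
    adj = adjacency(expr, power)
    diss = 1.0 - adj
    diss = (diss + diss.T) / 2.0
    np.fill_diagonal(diss, 0.0)
    Z = hierarchy.linkage(squareform(diss, checks=False), method="average")
    if cut_height is None:
        cut_height = 0.25 * float(Z[:, 2].max())
    raw = hierarchy.fcluster(Z, t=cut_height, criterion="distance")
    labels = np.zeros(len(genes), dtype=int)
    sizes = pd.Series(raw).value_counts()
    next_id = 1
    for cid, size in sizes.sort_values(ascending=False).items():
        if size < min_module_size:
            continue
        labels[raw == cid] = next_id
        next_id += 1
    labels[~ok] = 0  # zero-variance genes are never assigned
    return ModuleSet(
        genotype,
        pd.Series(labels, index=genes, dtype=int),
        power,
        float(cut_height),
        Z,
    )


def module_eigengene(expr: pd.DataFrame, labels: pd.Series) -> list[Eigengene]:
    """First right singular vector per module over standardized member rows."""
    out = []
    for m in sorted(set(labels)):
        if m == 0:
            continue
        members = labels.index[labels == m]
        if len(members) == 0:
            continue
        z, _ = _standardize(expr.loc[members])
        u, s, vt = np.linalg.svd(z, full_matrices=False)
        v = vt[0]
        total = float(np.sum(s**2))
        var = float(s[0] ** 2 / total) if total > 0 else 0.0
        # orient: mean correlation with member genes >= 0
        vz = v - v.mean()
        vsd = vz.std(ddof=0)
        if vsd > 0:
            cors = (z @ (vz / vsd)) / z.shape[1]
            if cors.mean() < 0:
                v = -v
        out.append(
            Eigengene(
                module=int(m),
                values=pd.Series(v, index=expr.columns),
                var_explained=var,
            )
        )
    return out


def module_membership(
    expr: pd.DataFrame, eigengenes: list[Eigengene]
) -> pd.DataFrame:
    """kME: Pearson correlation of each gene with each module eigengene.

    Zero-variance genes get kME 0 by convention.
    """
    z, ok = _standardize(expr)
    n = z.shape[1]
    cols = {}
    for eg in eigengenes:
        v = eg.values.to_numpy()
        vz = v - v.mean()
        vsd = vz.std(ddof=0)
        if vsd == 0:
            cols[eg.module] = np.zeros(len(expr))
            continue
        kme = (z @ (vz / vsd)) / n
        kme[~ok] = 0.0
        cols[eg.module] = kme
    return pd.DataFrame(cols, index=expr.index)


def module_preservation(
    ref_labels: pd.Series,
    test_expr: pd.DataFrame,
    power: float = 6,
    n_permutations: int = 200,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Permutation z-summary of mean intramodular adjacency in test data.

    observed = mean off-diagonal signed adjacency among the module's genes in
    the test expression; null = the same statistic over random gene sets of
    equal size drawn from the shared universe.
    """
    if n_permutations <= 0:
        raise ValueError("n_permutations must be positive")
    if rng is None:
        rng = np.random.default_rng(0)
    universe = [g for g in ref_labels.index if g in test_expr.index]
    adj = adjacency(test_expr.loc[universe], power)
    index = {g: i for i, g in enumerate(universe)}
    rows = []
    for m in sorted(set(ref_labels)):
        if m == 0:
            continue
        declared = list(ref_labels.index[ref_labels == m])
        if len(declared) > len(universe):
            raise ValueError(f"module {m} larger than shared universe")
        members = [g for g in declared if g in index]
        size = len(members)
        if size < 2:
            continue
        obs = _mean_intra(adj, [index[g] for g in members])
        null = np.array(
            [
                _mean_intra(
                    adj, rng.choice(len(universe), size=size, replace=False)
                )
                for _ in range(n_permutations)
            ]
        )
        sd = null.std(ddof=1)
        z = (obs - null.mean()) / sd if sd > 0 else np.inf
        rows.append((int(m), size, obs, null.mean(), sd, float(z), n_permutations))
    return pd.DataFrame(
        rows,
        columns=["module", "size", "observed", "null_mean", "null_sd",
                 "z_summary", "n_permutations"],
    )


def _mean_intra(adj: np.ndarray, idx) -> float:
    idx = np.asarray(idx)
    sub = adj[np.ix_(idx, idx)]
    n = len(idx)
    return float((sub.sum() - np.trace(sub)) / (n * (n - 1)))


def classify_trend(profile, eps: float = 0.1) -> str:
    """Sign-pattern classification of successive differences.

    Differences within ``eps`` of zero are flat; collapsed sign runs map to
    up / down / up-and-down / down-and-up; anything longer is 'mixed' and an
    all-flat profile is 'flat'.
    """
    x = np.asarray(profile, dtype=float)
    d = np.diff(x)
    signs = [int(np.sign(v)) for v in d if abs(v) > eps]
    collapsed: list[int] = []
    for s in signs:
        if not collapsed or collapsed[-1] != s:
            collapsed.append(s)
    if not collapsed:
        return "flat"
    if collapsed == [1]:
        return "up"
    if collapsed == [-1]:
        return "down"
    if collapsed == [1, -1]:
        return "up-and-down"
    if collapsed == [-1, 1]:
        return "down-and-up"
    return "mixed"
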