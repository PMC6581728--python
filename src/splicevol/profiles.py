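"""PSI / presence-absence AS profiles, correlations, and bootstrap clustering.

Samples are clustered by average linkage on 1 - Spearman correlation of
PSI profiles (rows filtered to events with 0.05 < PSI < 0.95 in at least
one sample), or on asymmetric binary (Jaccard) distance of per-gene AS
presence/absence.  Node support is the fraction of feature-bootstrap
replicates that reproduce the node's leaf set.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from scipy.stats import spearmanr

PSI_LOWER = 0.05
PSI_UPPER = 0.95
TPM_EXPRESSED = 5.0
MIN_PAIRWISE = 3


def filter_psi_matrix(raw: pd.DataFrame) -> pd.DataFrame:
    """Keep rows with 0.05 < PSI < 0.95 in at least one sample."""
    if raw.empty:
        return raw
    mask = ((raw > PSI_LOWER) & (raw < PSI_UPPER)).any(axis=1)
    return raw.loc[mask]


def filter_expressed(tpm: pd.DataFrame) -> pd.DataFrame:
    """Keep genes with TPM > 5 in at least one sample."""
    return tpm.loc[(tpm > TPM_EXPRESSED).any(axis=1)]


def correlation_matrix(matrix: pd.DataFrame, method: str = "spearman_psi") -> pd.DataFrame:
    """Sample x sample correlation matrix.

    ``spearman_psi`` uses pairwise-complete Spearman correlation on the
    (already filtered) PSI matrix; ``pearson_log_expression`` first applies
    the TPM>5 expressed-gene filter and log2(TPM+1).  Pairs with fewer
    than 3 complete observations are reported as missing.
    """
    if matrix.shape[1] < 2:
        raise ValueError("need at least 2 samples")
    if method == "spearman_psi":
        data = matrix
        corr_fn = lambda x, y: spearmanr(x, y).statistic  # noqa: E731
    elif method == "pearson_log_expression":
        data = np.log2(filter_expressed(matrix) + 1.0)
        corr_fn = lambda x, y: float(np.corrcoef(x, y)[0, 1])  # noqa: E731
    else:
        raise ValueError(f"unknown method {method!r}")
    cols = list(data.columns)
    out = pd.DataFrame(np.eye(len(cols)), index=cols, columns=cols)
    for i, ci in enumerate(cols):
        for j in range(i + 1, len(cols)):
            cj = cols[j]
            pair = data[[ci, cj]].dropna()
            if len(pair) < MIN_PAIRWISE or pair[ci].nunique() == 1 or pair[cj].nunique() == 1:
                val = np.nan
            else:
                val = corr_fn(pair[ci].to_numpy(), pair[cj].to_numpy())
            out.loc[ci, cj] = out.loc[cj, ci] = val
    return out


def binary_distance(matrix: pd.DataFrame) -> pd.DataFrame:
    """Asymmetric binary (Jaccard) distance between columns of a 0/1 matrix:
    among rows where at least one member is 1, the fraction where exactly
    one is 1.  Pairs with no informative rows are missing."""
    arr = matrix.to_numpy()
    if not np.isin(arr[~np.isnan(arr.astype(float))], [0, 1]).all():
        raise ValueError("matrix entries must be binary")
    cols = list(matrix.columns)
    out = pd.DataFrame(0.0, index=cols, columns=cols)
    for i, ci in enumerate(cols):
        for j in range(i + 1, len(cols)):
            x = matrix[ci].to_numpy()
            y = matrix[cols[j]].to_numpy()
            informative = (x == 1) | (y == 1)
            n_inf = int(informative.sum())
            if n_inf == 0:
                d = np.nan
            else:
                d = float(((x != y) & informative).sum() / n_inf)
            out.loc[ci, cols[j]] = out.loc[cols[j], ci] = d
    return out


@dataclass
class ClusterResult:
    linkage: np.ndarray
    leaves: list[str]
    supports: dict[frozenset, float]
    n_bootstrap: int

    def support_for(self, leaf_set: set[str]) -> Optional[float]:
        return self.supports.get(frozenset(leaf_set))

    def to_newick(self) -> str:
        """Newick string with bootstrap supports as internal node labels."""
        tree = hierarchy.to_tree(self.linkage)

        def render(node) -> str:
            if node.is_leaf():
                return self.leaves[node.id]
            left, right = render(node.left), render(node.right)
            leafset = frozenset(
                self.leaves[i] for i in _leaf_ids(node)
            )
            support = self.supports.get(leafset, float("nan"))
            return f"({left},{right}){support:.3f}:{node.dist:.5f}"

        def _leaf_ids(node):
            if node.is_leaf():
                return [node.id]
            return _leaf_ids(node.left) + _leaf_ids(node.right)

        return render(tree) + ";"


def _distance_matrix(data: pd.DataFrame, mode: str) -> pd.DataFrame:
    if mode == "psi":
        corr = correlation_matrix(data, "spearman_psi")
        dist = 1.0 - corr
    elif mode == "binary":
        dist = binary_distance(data)
    elif mode == "expression":
        corr = correlation_matrix(data, "pearson_log_expression")
        dist = 1.0 - corr
    else:
        raise ValueError(f"unknown mode {mode!r}")
    dist = dist.fillna(dist.max().max() if np.isfinite(dist.to_numpy()).any() else 1.0)
    np.fill_diagonal(dist.values, 0.0)
    return dist


def _cluster_nodes(dist: pd.DataFrame) -> tuple[np.ndarray, list[frozenset]]:
    condensed = squareform(dist.to_numpy(), checks=False)
    link = hierarchy.average(condensed)
    leaves = list(dist.columns)
    sets: list[frozenset] = []
    clusters: dict[int, frozenset] = {i: frozenset([leaves[i]]) for i in range(len(leaves))}
    for k, (a, b, _, _) in enumerate(link):
        merged = clusters[int(a)] | clusters[int(b)]
        clusters[len(leaves) + k] = merged
        sets.append(merged)
    return link, sets


def bootstrap_cluster(
    data: pd.DataFrame,
    mode: str = "psi",
    n_bootstrap: int = 1000,
    seed: int = 0,
) -> ClusterResult:
    """Average-linkage clustering of samples with feature-bootstrap support.

    ``data`` is features x samples.  Each replicate resamples rows with
    replacement, rebuilds the distance matrix and tree, and counts how
    often each reference node's leaf set reappears.
    """
    if data.shape[1] < 3:
        raise ValueError("need at least 3 samples to cluster")
    if data.shape[0] < 2:
        raise ValueError("too few features to resample")
    dist = _distance_matrix(data, mode)
    link, node_sets = _cluster_nodes(dist)
    counts = {s: 0 for s in node_sets}
    rng = np.random.default_rng(seed)
    n = data.shape[0]
    for _ in range(n_bootstrap):
        take = rng.integers(0, n, size=n)
        boot = data.iloc[take]
        try:
            bdist = _distance_matrix(boot, mode)
        except ValueError:
            continue
        _, bsets = _cluster_nodes(bdist)
        bset = set(bsets)
        for s in counts:
            if s in bset:
                counts[s] += 1
    supports = {s: c / n_bootstrap for s, c in counts.items()}
    return ClusterResult(
        linkage=link,
        leaves=list(data.columns),
        supports=supports,
        n_bootstrap=n_bootstrap,
    )
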