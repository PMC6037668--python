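"""Clustering of association profiles with multiscale bootstrap support.

The scan's beta-coefficient matrix is sparsified (coefficients from
non-significant associations set to zero, empty rows/columns dropped) and
traits or phenotypes are clustered by complete linkage on cosine
distances between their association profiles -- cosine being robust to
the sparsity the zeroing introduces.

Cluster support is assessed by multiscale bootstrap: the profile
coordinates (phenotype columns when clustering traits) are resampled with
replacement at several sample-size ratios r, the clustering is recomputed,
and the recovery frequency BP_r of each original cluster is recorded.
Fitting ``z_r = Phi^-1(1 - BP_r) = v*sqrt(r) + c/sqrt(r)`` by weighted
least squares separates the signed distance v of the cluster boundary from
its curvature c, giving the approximately unbiased support
``AU = 1 - Phi(v - c)``.  Clusters with AU-based p-value below 0.05
(AU > 0.95) are flagged significant.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform
from scipy.stats import norm

logger = logging.getLogger(__name__)

DEFAULT_SCALES = tuple(np.round(np.linspace(0.5, 1.4, 10), 3))

__all__ = [
    "sparsify",
    "cosine_distance",
    "complete_linkage",
    "arcsine_viz",
    "multiscale_bootstrap",
    "Dendrogram",
    "ClusterSupportTree",
    "to_newick",
]


def sparsify(results: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Traits x phenotypes matrix of betas from nominally significant tests.

    Coefficients with ``p >= alpha`` (or from non-converged fits) are set
    to zero; traits and phenotypes left without any nonzero entry are
    dropped (their names are recorded in ``attrs``).
    """
    if not 0.0 < alpha <= 1.0:
        raise ValueError("alpha must be in (0, 1]")
    ok = results[results["status"] == "ok"].copy()
    ok["kept_beta"] = np.where(ok["p"] < alpha, ok["beta"], 0.0)
    matrix = ok.pivot_table(
        index="trait", columns="phenotype", values="kept_beta", fill_value=0.0
    )
    empty_rows = matrix.index[(matrix == 0).all(axis=1)]
    empty_cols = matrix.columns[(matrix == 0).all(axis=0)]
    matrix = matrix.drop(index=empty_rows, columns=empty_cols)
    if matrix.empty:
        raise ValueError(
            f"no associations left at alpha={alpha}: every row/column was all zero"
        )
    matrix.attrs["dropped_traits"] = list(empty_rows)
    matrix.attrs["dropped_phenotypes"] = list(empty_cols)
    matrix.attrs["alpha"] = alpha
    return matrix


def _cosine_distance_values(M: np.ndarray) -> np.ndarray:
    norms = np.linalg.norm(M, axis=1)
    zero = norms == 0
    if zero.any():
        logger.debug("%d zero-norm profiles; similarity defined as 0", int(zero.sum()))
    safe = np.where(zero, 1.0, norms)
    sim = (M @ M.T) / np.outer(safe, safe)
    sim[zero, :] = 0.0
    sim[:, zero] = 0.0
    dist = np.clip(1.0 - sim, 0.0, 2.0)
    np.fill_diagonal(dist, 0.0)
    return dist


def cosine_distance(matrix: pd.DataFrame, axis: str = "rows") -> pd.DataFrame:
    """Pairwise cosine distances ``1 - u.v/(|u||v|)`` between profiles.

    Zero vectors (possible inside bootstrap resamples) get similarity 0,
    hence distance 1, to every other profile.
    """
    if axis not in {"rows", "columns"}:
        raise ValueError("axis must be 'rows' or 'columns'")
    M = matrix.to_numpy(dtype=float)
    labels = matrix.index
    if axis == "columns":
        M = M.T
        labels = matrix.columns
    dist = _cosine_distance_values(M)
    return pd.DataFrame(dist, index=labels, columns=labels)


@dataclass
class Dendrogram:
    """Agglomerative merge tree: scipy linkage matrix plus leaf labels."""

    labels: list[str]
    linkage: np.ndarray


def complete_linkage(dist: pd.DataFrame) -> Dendrogram:
    """Complete-linkage hierarchical clustering of a distance matrix."""
    if dist.shape[0] < 2:
        raise ValueError("need at least two items to cluster")
    condensed = squareform(dist.to_numpy(dtype=float), checks=False)
    Z = linkage(condensed, method="complete")
    return Dendrogram(labels=[str(x) for x in dist.index], linkage=Z)


def arcsine_viz(matrix: pd.DataFrame) -> pd.DataFrame:
    """Arcsine transform for heatmap display, boosting small coefficients.

    Values are rescaled by the global max |value| only when that max
    exceeds 1 (arcsin is undefined outside [-1, 1]).  Sign and zero
    pattern are preserved; an all-zero matrix is returned unchanged.
    """
    values = matrix.to_numpy(dtype=float)
    peak = np.nanmax(np.abs(values)) if values.size else 0.0
    if peak == 0.0:
        return matrix.copy()
    scale = peak if peak > 1.0 else 1.0
    return pd.DataFrame(
        np.arcsin(values / scale), index=matrix.index, columns=matrix.columns
    )


def _cluster_sets(Z: np.ndarray, n: int) -> list[frozenset]:
    """Leaf-index sets of every internal node of a linkage matrix."""
    members: dict[int, frozenset] = {i: frozenset([i]) for i in range(n)}
    sets = []
    for k, (a, b, _h, _c) in enumerate(Z):
        merged = members[int(a)] | members[int(b)]
        members[n + k] = merged
        sets.append(merged)
    return sets


@dataclass
class ClusterSupportTree:
    """Dendrogram plus per-cluster bootstrap (BP) and approximately unbiased (AU) support."""

    dendrogram: Dendrogram
    support: pd.DataFrame       # cluster_id, members, size, bp, au, significant, flag
    bp_by_scale: pd.DataFrame   # clusters x scales recovery frequencies
    n_boot: int
    scales: tuple[float, ...]


def _fit_au(bp_row: np.ndarray, scales: np.ndarray, n_boot: int) -> tuple[float, str]:
    """WLS fit of the two-parameter signed-distance model; returns (AU, flag)."""
    if np.all(bp_row == 0.0):
        return 0.0, "never_recovered"
    if np.all(bp_row == 1.0):
        return 1.0, "always_recovered"
    eps = 1.0 / (n_boot + 1)
    bp = np.clip(bp_row, eps, 1.0 - eps)
    z = norm.ppf(1.0 - bp)
    X = np.column_stack([np.sqrt(scales), 1.0 / np.sqrt(scales)])
    # delta-method weights: var(z_r) ~ bp(1-bp) / (B * phi(z)^2)
    w = n_boot * norm.pdf(z) ** 2 / (bp * (1.0 - bp))
    Xw = X * w[:, None]
    try:
        coef = np.linalg.solve(X.T @ Xw, Xw.T @ z)
    except np.linalg.LinAlgError:
        return float("nan"), "degenerate_fit"
    v, c = coef
    au = float(np.clip(1.0 - norm.cdf(v - c), 0.0, 1.0))
    return au, "ok"


def multiscale_bootstrap(
    matrix: pd.DataFrame,
    axis: str = "rows",
    n_boot: int = 1000,
    scales: tuple[float, ...] | None = None,
    seed: int = 0,
) -> ClusterSupportTree:
    """Complete-linkage clustering with multiscale bootstrap support values.

    The resampling unit is the profile coordinate: when clustering traits
    (rows), bootstrap replicates draw phenotype columns with replacement
    at each scale ratio ``r`` (resample size ``round(r * p)``).
    """
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100 for meaningful support values")
    scales = DEFAULT_SCALES if scales is None else tuple(scales)
    if any(r <= 0 for r in scales):
        raise ValueError("scales must be positive")
    M = matrix.to_numpy(dtype=float)
    labels = list(matrix.index)
    if axis == "columns":
        M = M.T
        labels = list(matrix.columns)
    elif axis != "rows":
        raise ValueError("axis must be 'rows' or 'columns'")
    n, p = M.shape
    if n < 2:
        raise ValueError("need at least two profiles to cluster")

    dist = _cosine_distance_values(M)
    dend = Dendrogram(labels=[str(x) for x in labels],
                      linkage=linkage(squareform(dist, checks=False), method="complete"))
    original = _cluster_sets(dend.linkage, n)
    counts = np.zeros((len(original), len(scales)), dtype=int)
    index_of = {s: i for i, s in enumerate(original)}

    rng = np.random.default_rng(seed)
    for si, r in enumerate(scales):
        m = max(2, int(round(r * p)))
        for _ in range(n_boot):
            cols = rng.integers(0, p, size=m)
            db = _cosine_distance_values(M[:, cols])
            Zb = linkage(squareform(db, checks=False), method="complete")
            for s in _cluster_sets(Zb, n):
                i = index_of.get(s)
                if i is not None:
                    counts[i, si] += 1

    bp = counts / n_boot
    scale_arr = np.asarray(scales, dtype=float)
    nearest_one = int(np.argmin(np.abs(scale_arr - 1.0)))
    multi_scale = len(set(scales)) >= 2

    rows = []
    for ci, members in enumerate(original):
        if multi_scale:
            au, flag = _fit_au(bp[ci], scale_arr, n_boot)
        else:
            au, flag = float("nan"), "single_scale"
        rows.append(
            {
                "cluster_id": ci,
                "members": tuple(sorted(dend.labels[i] for i in members)),
                "size": len(members),
                "bp": float(bp[ci, nearest_one]),
                "au": au,
                "significant": bool(au > 0.95) if np.isfinite(au) else False,
                "flag": flag,
            }
        )
    support = pd.DataFrame(rows).set_index("cluster_id")
    bp_frame = pd.DataFrame(bp, index=support.index, columns=[f"r={r}" for r in scales])
    return ClusterSupportTree(
        dendrogram=dend, support=support, bp_by_scale=bp_frame,
        n_boot=n_boot, scales=tuple(scales),
    )


def to_newick(tree: ClusterSupportTree | Dendrogram, support_label: str = "au") -> str:
    """Newick string with branch lengths from merge heights.

    For a :class:`ClusterSupportTree`, internal nodes are labelled with
    the chosen support value (AU by default) rounded to 3 digits.
    """
    if isinstance(tree, ClusterSupportTree):
        dend = tree.dendrogram
        labels_for_cluster = tree.support[support_label].to_numpy()
    else:
        dend = tree
        labels_for_cluster = None
    Z = dend.linkage
    n = len(dend.labels)
    heights = {i: 0.0 for i in range(n)}
    for k, row in enumerate(Z):
        heights[n + k] = float(row[2])

    def render(node: int) -> str:
        if node < n:
            return dend.labels[node].replace(" ", "_")
        k = node - n
        a, b = int(Z[k, 0]), int(Z[k, 1])
        la = heights[node] - heights[a]
        lb = heights[node] - heights[b]
        label = ""
        if labels_for_cluster is not None and np.isfinite(labels_for_cluster[k]):
            label = f"{labels_for_cluster[k]:.3f}"
        return f"({render(a)}:{la:.6g},{render(b)}:{lb:.6g}){label}"

    return render(2 * n - 2) + ";"
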