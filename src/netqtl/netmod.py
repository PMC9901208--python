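"""Co-occurrence network construction and module detection.

Compositional correlations between genera are estimated with the SparCC
estimator (log-ratio variation matrix, basis variances solved under a
sparsity approximation, iterative exclusion of strongly correlated
pairs).  A signed weighted adjacency is built from the correlations,
genera are clustered by average linkage on a topological-overlap
dissimilarity, and modules are cut out of the dendrogram with a
dynamic (adaptive-height) tree cut.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
from scipy.spatial.distance import squareform

from netqtl.containers import AbundanceTable, ModuleAssignment

__all__ = [
    "intersect_genera",
    "sparcc_correlations",
    "signed_adjacency",
    "topological_overlap",
    "average_linkage_dendrogram",
    "dynamic_tree_cut",
    "match_modules",
    "pick_soft_threshold",
    "detect_modules",
]


def intersect_genera(
    a: AbundanceTable, b: AbundanceTable, min_prevalence: float = 0.0
) -> tuple[AbundanceTable, AbundanceTable]:
    """Restrict both tables to the genera present in both cohorts.

    "Present" means nonzero in at least one sample (prevalence > 0); a
    stricter prevalence threshold can be supplied.  Output columns are
    identically sorted.
    """
    def present(t: AbundanceTable) -> set[str]:
        prev = t.prevalence()
        if min_prevalence > 0:
            return set(prev.index[prev >= min_prevalence])
        return set(prev.index[prev > 0])

    shared = sorted(present(a) & present(b))
    if not shared:
        raise ValueError("no genera shared between the two tables")
    return a.subset_genera(shared), b.subset_genera(shared)


# ---------------------------------------------------------------------------
# SparCC


def _variation_matrix(counts: np.ndarray, pseudocount: float) -> np.ndarray:
    """t_ij = Var[log((x_i + c) / (x_j + c))] across samples."""
    logx = np.log(counts + pseudocount)
    cov = np.cov(logx, rowvar=False)
    v = np.diag(cov)
    return v[:, None] + v[None, :] - 2.0 * cov


def _basis_variances(T: np.ndarray, M: np.ndarray) -> np.ndarray:
    """Solve the SparCC sparsity approximation M @ omega = rowsums(T)."""
    omega = np.linalg.solve(M, T.sum(axis=1))
    # negative basis variances can arise when the sparsity assumption is
    # badly violated; clip to a small positive floor
    floor = 1e-6 * max(T.max(), 1.0)
    return np.maximum(omega, floor)


def sparcc_correlations(
    table: AbundanceTable,
    exclusion_threshold: float = 0.1,
    n_exclusion_rounds: int = 10,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """SparCC correlation matrix of a counts table.

    Basis variances omega are solved from the variation matrix under the
    sparsity approximation; r_ij = (omega_i + omega_j - t_ij) /
    (2 sqrt(omega_i omega_j)), clipped to [-1, 1].  The most strongly
    correlated pair above ``exclusion_threshold`` is excluded from the
    basis system and the system re-solved, for ``n_exclusion_rounds``
    rounds (the estimator's standard iterative refinement).
    """
    counts = table.counts.to_numpy(dtype=float)
    n_samples, D = counts.shape
    if D < 4:
        raise ValueError("SparCC needs >= 4 genera (basis system unsolvable)")
    if n_samples < 3:
        raise ValueError("SparCC needs >= 3 samples")
    zero_cols = np.nonzero((counts == 0).all(axis=0))[0]
    if zero_cols.size:
        names = [table.genera[i] for i in zero_cols]
        raise ValueError(f"all-zero genus columns (filter first): {names}")

    T = _variation_matrix(counts, pseudocount)
    M = np.ones((D, D)) + np.diag(np.full(D, D - 2.0))
    Twork = T.copy()
    excluded = np.zeros((D, D), dtype=bool)

    def corr(omega: np.ndarray) -> np.ndarray:
        denom = 2.0 * np.sqrt(np.outer(omega, omega))
        r = (omega[:, None] + omega[None, :] - T) / denom
        np.clip(r, -1.0, 1.0, out=r)
        np.fill_diagonal(r, 1.0)
        return r

    omega = _basis_variances(Twork, M)
    r = corr(omega)
    for _ in range(n_exclusion_rounds):
        cand = np.abs(np.triu(r, k=1))
        cand[excluded] = 0.0
        i, j = np.unravel_index(np.argmax(cand), cand.shape)
        if cand[i, j] <= exclusion_threshold:
            break
        excluded[i, j] = excluded[j, i] = True
        # a component excluded from too many pairs leaves the system
        n_excl = excluded.sum(axis=1)
        if (n_excl >= D - 3).any():
            break
        M[i, j] = M[j, i] = 0.0
        M[i, i] -= 1.0
        M[j, j] -= 1.0
        Twork[i, j] = Twork[j, i] = 0.0
        omega = _basis_variances(Twork, M)
        r = corr(omega)
    return pd.DataFrame(r, index=table.genera, columns=table.genera)


# ---------------------------------------------------------------------------
# Adjacency, TOM, clustering


def signed_adjacency(r: pd.DataFrame, beta: float = 4.0) -> pd.DataFrame:
    """Signed weighted adjacency a_ij = ((1 + r_ij)/2)^beta, zero diagonal."""
    if beta <= 0:
        raise ValueError("beta must be positive")
    a = ((1.0 + r.to_numpy(dtype=float)) / 2.0) ** beta
    np.fill_diagonal(a, 0.0)
    return pd.DataFrame(a, index=r.index, columns=r.columns)


def topological_overlap(adj: pd.DataFrame) -> pd.DataFrame:
    """Topological overlap matrix of a weighted adjacency (unit diagonal)."""
    a = adj.to_numpy(dtype=float)
    L = a @ a
    k = a.sum(axis=1)
    denom = np.minimum.outer(k, k) + 1.0 - a
    tom = (L + a) / denom
    np.fill_diagonal(tom, 1.0)
    return pd.DataFrame(tom, index=adj.index, columns=adj.columns)


def pick_soft_threshold(
    r: pd.DataFrame,
    betas=(1, 2, 3, 4, 5, 6, 8, 10, 12),
    target_r2: float = 0.8,
) -> tuple[float, pd.DataFrame]:
    """Scale-free-fit helper for choosing the soft threshold beta.

    For each candidate beta, regresses log10 p(k) on log10 k over degree
    bins and reports the signed fit R^2; returns the smallest beta
    reaching ``target_r2`` (or the best-fitting beta if none does).
    """
    rows = []
    for beta in betas:
        k = signed_adjacency(r, beta).to_numpy().sum(axis=1)
        hist, edges = np.histogram(k, bins=10)
        centers = 0.5 * (edges[:-1] + edges[1:])
        keep = (hist > 0) & (centers > 0)
        if keep.sum() < 3:
            rows.append((beta, 0.0, float(np.mean(k))))
            continue
        x = np.log10(centers[keep])
        y = np.log10(hist[keep] / hist.sum())
        slope, intercept = np.polyfit(x, y, 1)
        resid = y - (slope * x + intercept)
        r2 = 1.0 - resid.var() / max(y.var(), 1e-12)
        rows.append((beta, float(-np.sign(slope) * r2), float(np.mean(k))))
    fit = pd.DataFrame(rows, columns=["beta", "signed_r2", "mean_k"])
    ok = fit.loc[fit["signed_r2"] >= target_r2]
    beta = float(ok["beta"].iloc[0]) if len(ok) else float(
        fit.loc[fit["signed_r2"].idxmax(), "beta"]
    )
    return beta, fit


def average_linkage_dendrogram(diss: pd.DataFrame) -> np.ndarray:
    """UPGMA merge tree (scipy linkage matrix) from a dissimilarity matrix."""
    d = diss.to_numpy(dtype=float)
    if np.isnan(d).any():
        raise ValueError("NaN dissimilarities")
    if not np.allclose(d, d.T, atol=1e-10):
        raise ValueError("dissimilarity matrix must be symmetric")
    if not np.allclose(np.diag(d), 0.0, atol=1e-10):
        raise ValueError("dissimilarity matrix must have zero diagonal")
    return sch.linkage(squareform(d, checks=False), method="average")


# ---------------------------------------------------------------------------
# Dynamic tree cut


def _deep_split_params(deep_split: int, heights: np.ndarray) -> tuple[float, float]:
    """Map the deepSplit preset {0..4} to absolute core-scatter and gap
    thresholds, interpolated over the dendrogram height range (the
    published sensitivity presets: max core scatter 0.64..0.95 of the
    height range, min gap 3/4 of its complement)."""
    if deep_split not in (0, 1, 2, 3, 4):
        raise ValueError("deep_split must be in {0, 1, 2, 3, 4}")
    hmin, hmax = float(heights.min()), float(heights.max())
    span = max(hmax - hmin, 1e-12)
    max_core_scatter = 0.64 + deep_split * (0.95 - 0.64) / 4.0
    min_gap = (1.0 - max_core_scatter) * 0.75
    return hmin + max_core_scatter * span, min_gap * span


def dynamic_tree_cut(
    linkage_matrix: np.ndarray,
    genus_ids: list[str],
    min_module_size: int = 10,
    deep_split: int = 2,
) -> ModuleAssignment:
    """Adaptive (dynamic-hybrid core) cut of a dendrogram into modules.

    Merges are processed bottom-up.  When two branches meet, each is
    kept as a separate module candidate only if it is "viable": at least
    ``min_module_size`` leaves, a core scatter (mean height of its
    earliest merges) below the deepSplit-dependent threshold, and a
    sufficient gap between the joining height and its core.  Non-viable
    branches are absorbed into their sibling; branches joining an
    already-split subtree without being viable are left unassigned.
    Leaves that were absorbed into a cluster's branch above the core
    scatter threshold (stray outliers attached near the top of the
    dendrogram) are trimmed back to unassigned.  Modules are labelled
    1, 2, ... in decreasing size order (0 = unassigned).
    """
    if min_module_size < 2:
        raise ValueError("min_module_size must be >= 2")
    n = len(genus_ids)
    if linkage_matrix.shape[0] != n - 1:
        raise ValueError("linkage matrix does not match number of leaves")
    heights = linkage_matrix[:, 2]
    max_scatter_abs, min_gap_abs = _deep_split_params(deep_split, heights)
    hmin = float(heights.min())

    class _Branch:
        __slots__ = ("leaves", "merge_heights", "composite", "closed")

        def __init__(self, leaves, merge_heights, composite=False):
            self.leaves = leaves
            self.merge_heights = merge_heights
            self.composite = composite

    def core_scatter(br: _Branch) -> float:
        if not br.merge_heights:
            return hmin
        core = sorted(br.merge_heights)[: max(min_module_size - 1, 1)]
        return float(np.mean(core))

    def viable(br: _Branch, join_height: float) -> bool:
        return (
            len(br.leaves) >= min_module_size
            and core_scatter(br) <= max_scatter_abs
            and join_height - core_scatter(br) >= min_gap_abs
        )

    join_height = np.full(n, hmin)  # height at which each leaf last joined
    nodes: dict[int, _Branch] = {i: _Branch([i], []) for i in range(n)}
    clusters: list[list[int]] = []
    root = None
    for m in range(n - 1):
        a, b = int(linkage_matrix[m, 0]), int(linkage_matrix[m, 1])
        h = float(heights[m])
        pa, pb = nodes.pop(a), nodes.pop(b)
        if not pa.composite and not pb.composite:
            if viable(pa, h) and viable(pb, h):
                clusters.append(pa.leaves)
                clusters.append(pb.leaves)
                merged = _Branch(pa.leaves + pb.leaves, [], composite=True)
            else:
                # trunk choice: a core-qualified branch (min size reached,
                # tight core) beats an unqualified one; otherwise the
                # larger branch is the trunk.  The absorbed side's leaves
                # are stamped with this joining height.
                def qualified(br: _Branch) -> bool:
                    return (
                        len(br.leaves) >= min_module_size
                        and core_scatter(br) <= max_scatter_abs
                    )

                qa, qb = qualified(pa), qualified(pb)
                if qa != qb:
                    absorbed = pb if qa else pa
                else:
                    absorbed = pb if len(pa.leaves) >= len(pb.leaves) else pa
                join_height[absorbed.leaves] = h
                merged = _Branch(
                    pa.leaves + pb.leaves, pa.merge_heights + pb.merge_heights + [h]
                )
        else:
            for br in (pa, pb):
                if not br.composite:
                    if viable(br, h):
                        clusters.append(br.leaves)
                    # else: unassigned
            merged = _Branch(pa.leaves + pb.leaves, [], composite=True)
        nodes[n + m] = merged
        root = merged
    if root is not None and not root.composite:
        clusters.append(root.leaves)

    # trim stray leaves absorbed above the core-scatter threshold
    clusters = [
        [leaf for leaf in c if join_height[leaf] <= max_scatter_abs]
        for c in clusters
    ]
    clusters = [c for c in clusters if len(c) >= min_module_size]
    clusters.sort(key=lambda c: (-len(c), min(c)))
    labels = np.zeros(n, dtype=int)
    for lab, c in enumerate(clusters, start=1):
        labels[c] = lab
    return ModuleAssignment(
        labels=pd.Series(labels, index=genus_ids),
        merge_heights=heights.copy(),
        params=dict(min_module_size=min_module_size, deep_split=deep_split),
    )


def dendrogram_to_newick(linkage_matrix: np.ndarray, leaf_ids: list[str]) -> str:
    """Render a scipy linkage matrix as a Newick string with leaf labels."""
    tree = sch.to_tree(linkage_matrix)

    def walk(node, parent_height: float) -> str:
        length = max(parent_height - (node.dist if not node.is_leaf() else 0.0), 0.0)
        if node.is_leaf():
            return f"{leaf_ids[node.id]}:{length:.6g}"
        left = walk(node.left, node.dist)
        right = walk(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    return walk(tree, tree.dist) + ";"


# ---------------------------------------------------------------------------
# Module matching across cohorts


def match_modules(
    a: ModuleAssignment, b: ModuleAssignment
) -> pd.DataFrame:
    """Greedy maximum-overlap matching of module labels across cohorts.

    Largest overlap matched first; ties broken by the smaller module ids.
    Returns a frame with columns module_a, module_b, overlap, size_a,
    size_b (module_b is NA for unmatched modules of a, and vice versa).
    """
    if set(a.labels.index) != set(b.labels.index):
        raise ValueError("module assignments cover different genus universes")
    mods_a, mods_b = a.modules(), b.modules()
    overlaps = []
    for ma, ga in mods_a.items():
        for mb, gb in mods_b.items():
            ov = len(set(ga) & set(gb))
            overlaps.append((ov, ma, mb))
    overlaps.sort(key=lambda t: (-t[0], t[1], t[2]))
    used_a: set[int] = set()
    used_b: set[int] = set()
    rows = []
    for ov, ma, mb in overlaps:
        if ma in used_a or mb in used_b:
            continue
        used_a.add(ma)
        used_b.add(mb)
        rows.append(dict(module_a=ma, module_b=mb, overlap=ov,
                         size_a=len(mods_a[ma]), size_b=len(mods_b[mb])))
        if ov == 0:
            warnings.warn(
                f"modules {ma} (cohort A) and {mb} (cohort B) matched with "
                "zero overlap"
            )
    for ma in mods_a:
        if ma not in used_a:
            rows.append(dict(module_a=ma, module_b=pd.NA, overlap=0,
                             size_a=len(mods_a[ma]), size_b=pd.NA))
    for mb in mods_b:
        if mb not in used_b:
            rows.append(dict(module_a=pd.NA, module_b=mb, overlap=0,
                             size_a=pd.NA, size_b=len(mods_b[mb])))
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Convenience chain


def detect_modules(
    table: AbundanceTable,
    beta: float = 4.0,
    min_module_size: int = 10,
    deep_split: int = 2,
    dissimilarity: str = "tom",
    exclusion_threshold: float = 0.1,
    n_exclusion_rounds: int = 10,
    pseudocount: float = 1.0,
) -> tuple[pd.DataFrame, ModuleAssignment]:
    """Full chain: SparCC -> signed adjacency -> dissimilarity -> UPGMA ->
    dynamic tree cut.  Returns (correlation matrix, module assignment)."""
    r = sparcc_correlations(
        table,
        exclusion_threshold=exclusion_threshold,
        n_exclusion_rounds=n_exclusion_rounds,
        pseudocount=pseudocount,
    )
    adj = signed_adjacency(r, beta=beta)
    if dissimilarity == "tom":
        diss = 1.0 - topological_overlap(adj)
        diss = (diss + diss.T) / 2.0
        np.fill_diagonal(diss.values, 0.0)
    elif dissimilarity == "adjacency":
        diss = 1.0 - adj
        np.fill_diagonal(diss.values, 0.0)
    else:
        raise ValueError("dissimilarity must be 'tom' or 'adjacency'")
    Z = average_linkage_dendrogram(diss)
    assignment = dynamic_tree_cut(
        Z, table.genera, min_module_size=min_module_size, deep_split=deep_split
    )
    assignment.params.update(
        dict(beta=beta, dissimilarity=dissimilarity,
             exclusion_threshold=exclusion_threshold,
             n_exclusion_rounds=n_exclusion_rounds, pseudocount=pseudocount)
    )
    return r, assignment
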