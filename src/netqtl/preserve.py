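"""Permutation-based cross-cohort module preservation.

Four preservation statistics suited to sparse microbiome data are
computed for each module in a test cohort: average edge weight,
coherence (variance explained by the module summary profile), average
node contribution, and correlation density.  Their null distributions
come from drawing random node sets of the same size from all test-
dataset nodes ("a module is a random gene set"); one-sided p-values use
the add-one convention, and a module is classified strongly preserved
when all four p-values fall below alpha / 4.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from netqtl.containers import AbundanceTable, ModuleAssignment, clr_transform

__all__ = [
    "module_summary_profile",
    "preservation_statistics",
    "permutation_preservation_test",
    "classify_preservation",
    "preservation_report",
    "PreservationResult",
]

STATISTIC_NAMES = (
    "avg_edge_weight",
    "coherence",
    "avg_node_contribution",
    "correlation_density",
)


@dataclass
class PreservationResult:
    module: int
    statistics: dict[str, float]
    p_values: dict[str, float]
    classification: str
    n_permutations: int
    seed: int | None

    def to_row(self) -> dict:
        row: dict = {"module": self.module}
        for s in STATISTIC_NAMES:
            row[s] = self.statistics[s]
        for s in STATISTIC_NAMES:
            row[f"p_{s}"] = self.p_values[s]
        row["classification"] = self.classification
        return row


def module_summary_profile(
    data: pd.DataFrame, nodes: list[str]
) -> tuple[pd.Series, pd.Series]:
    """Summary profile (first right singular vector, on the sample-score
    scale) of the standardized sample x node submatrix.

    Returns (summary scores per sample, node contributions = correlation
    of each node with the summary).  Orientation is fixed so the mean
    node-summary correlation is positive.  Constant columns are dropped
    from the SVD with a warning.
    """
    sub = data.loc[:, list(nodes)]
    if sub.shape[1] < 2 or sub.shape[0] < 3:
        raise ValueError("need >= 2 nodes and >= 3 samples")
    X = sub.to_numpy(dtype=float)
    sd = X.std(axis=0)
    keep = sd > 0
    if not keep.all():
        dropped = [n for n, k in zip(nodes, keep) if not k]
        warnings.warn(f"constant columns dropped from summary profile: {dropped}")
        X = X[:, keep]
        if X.shape[1] < 2:
            raise ValueError("fewer than 2 non-constant nodes")
    Z = (X - X.mean(axis=0)) / X.std(axis=0)
    U, s, Vt = np.linalg.svd(Z, full_matrices=False)
    scores = U[:, 0] * s[0]
    contrib_full = np.array(
        [np.corrcoef(Z[:, j], scores)[0, 1] for j in range(Z.shape[1])]
    )
    if contrib_full.mean() < 0:
        scores = -scores
        contrib_full = -contrib_full
    kept_nodes = [n for n, k in zip(nodes, keep) if k]
    return (
        pd.Series(scores, index=sub.index),
        pd.Series(contrib_full, index=kept_nodes),
    )


def _stats_from_matrices(
    corr: np.ndarray, adj: np.ndarray, idx: np.ndarray
) -> np.ndarray:
    """The four statistics for node subset ``idx``, computed from the test
    correlation and adjacency matrices.

    For standardized data the summary profile is the first PC of the
    node correlation submatrix, so coherence = lambda_1 / m and node
    contributions are sqrt(lambda_1) * |v_1|; this avoids one SVD per
    permutation.
    """
    m = idx.size
    sub_r = corr[np.ix_(idx, idx)]
    sub_a = adj[np.ix_(idx, idx)]
    off = ~np.eye(m, dtype=bool)
    avg_edge = sub_a[off].mean()
    density = np.abs(sub_r[off]).mean()
    vals, vecs = np.linalg.eigh(sub_r)
    lam = max(vals[-1], 0.0)
    coherence = lam / m
    contrib = np.sqrt(lam) * np.abs(vecs[:, -1])
    return np.array([avg_edge, coherence, contrib.mean(), density])


def preservation_statistics(
    test_corr: pd.DataFrame,
    test_adj: pd.DataFrame,
    nodes: list[str],
    data_corr: pd.DataFrame | None = None,
) -> dict[str, float]:
    """Observed preservation statistics of a module in the test dataset.

    ``test_corr`` is the correlation matrix used for density;
    ``data_corr`` (defaults to ``test_corr``) is the Pearson correlation
    of the transformed test data from which coherence and node
    contributions are derived.
    """
    if len(nodes) < 2:
        raise ValueError("singleton module")
    missing = [n for n in nodes if n not in test_corr.index]
    if missing:
        raise ValueError(f"module nodes absent from test dataset: {missing}")
    dcorr = test_corr if data_corr is None else data_corr
    all_nodes = list(test_corr.index)
    pos = {n: i for i, n in enumerate(all_nodes)}
    idx = np.array([pos[n] for n in nodes])
    corr_np = test_corr.to_numpy(dtype=float)
    adj_np = test_adj.to_numpy(dtype=float)
    dcorr_np = dcorr.to_numpy(dtype=float)
    m = idx.size
    off = ~np.eye(m, dtype=bool)
    sub_r = corr_np[np.ix_(idx, idx)]
    sub_a = adj_np[np.ix_(idx, idx)]
    vals, vecs = np.linalg.eigh(dcorr_np[np.ix_(idx, idx)])
    lam = max(vals[-1], 0.0)
    return {
        "avg_edge_weight": float(sub_a[off].mean()),
        "coherence": float(lam / m),
        "avg_node_contribution": float((np.sqrt(lam) * np.abs(vecs[:, -1])).mean()),
        "correlation_density": float(np.abs(sub_r[off]).mean()),
    }


def permutation_preservation_test(
    test_corr: pd.DataFrame,
    test_adj: pd.DataFrame,
    nodes: list[str],
    n_perm: int = 10_000,
    seed: int | None = None,
    data_corr: pd.DataFrame | None = None,
) -> tuple[dict[str, float], dict[str, float]]:
    """Permutation p-values for the four statistics.

    Null node sets of the module's size are drawn uniformly from all
    test-dataset nodes; one-sided p = (1 + #{null >= observed}) /
    (1 + n_perm).
    """
    if n_perm < 100:
        warnings.warn("fewer than 100 permutations: p-values are coarse")
    if len(nodes) >= len(test_corr.index):
        raise ValueError("test dataset must contain more nodes than the module")
    observed = preservation_statistics(test_corr, test_adj, nodes, data_corr)
    obs_vec = np.array([observed[s] for s in STATISTIC_NAMES])
    rng = np.random.default_rng(seed)
    n_nodes = len(test_corr.index)
    m = len(nodes)
    corr_np = test_corr.to_numpy(dtype=float)
    adj_np = test_adj.to_numpy(dtype=float)
    dcorr_np = (test_corr if data_corr is None else data_corr).to_numpy(dtype=float)
    exceed = np.zeros(4)
    for _ in range(n_perm):
        idx = rng.choice(n_nodes, size=m, replace=False)
        null_density_edge = _stats_from_matrices(corr_np, adj_np, idx)
        # coherence/contribution from the data correlation matrix
        if data_corr is not None:
            null_coh = _stats_from_matrices(dcorr_np, adj_np, idx)
            null_density_edge[1] = null_coh[1]
            null_density_edge[2] = null_coh[2]
        exceed += null_density_edge >= obs_vec
    pvals = (1.0 + exceed) / (1.0 + n_perm)
    return observed, dict(zip(STATISTIC_NAMES, pvals))


def classify_preservation(
    p_values: dict[str, float], n_statistics: int = 4, alpha: float = 0.05
) -> tuple[str, float]:
    """Strong/weak/none classification against the Bonferroni threshold.

    The threshold alpha / n_statistics is reported truncated to 3
    decimals (0.05 / 4 -> 0.012): strong if all p-values fall below it,
    weak if at least one (but not all) does, none otherwise.
    """
    if len(p_values) != n_statistics:
        raise ValueError(f"expected {n_statistics} p-values, got {len(p_values)}")
    threshold = np.floor(alpha / n_statistics * 1000.0) / 1000.0
    below = [p < threshold for p in p_values.values()]
    if all(below):
        return "strong", threshold
    if any(below):
        return "weak", threshold
    return "none", threshold


def preservation_report(
    discovery_assignment: ModuleAssignment,
    test_table: AbundanceTable,
    test_corr: pd.DataFrame,
    test_adj: pd.DataFrame,
    n_perm: int = 10_000,
    seed: int | None = None,
    alpha: float = 0.05,
    transform=clr_transform,
) -> list[PreservationResult]:
    """Preservation of every discovery module in the test cohort.

    The test data matrix is put on the transform's log-ratio scale and
    its Pearson correlations drive coherence / node contribution, while
    density and edge weight use the supplied (SparCC) correlation and
    adjacency matrices — matching how each statistic is defined.
    """
    data = transform(test_table.counts)
    with np.errstate(invalid="ignore"):
        data_corr = pd.DataFrame(
            np.nan_to_num(np.corrcoef(data.to_numpy(dtype=float), rowvar=False)),
            index=data.columns,
            columns=data.columns,
        )
    data_corr = data_corr.loc[test_corr.index, test_corr.columns]
    results = []
    ss = np.random.SeedSequence(seed) if seed is not None else np.random.SeedSequence()
    child_seeds = ss.generate_state(max(discovery_assignment.n_modules, 1))
    for k, (module, nodes) in enumerate(discovery_assignment.modules().items()):
        mod_seed = int(child_seeds[k])
        observed, pvals = permutation_preservation_test(
            test_corr, test_adj, nodes, n_perm=n_perm, seed=mod_seed,
            data_corr=data_corr,
        )
        classification, _ = classify_preservation(pvals, alpha=alpha)
        results.append(
            PreservationResult(
                module=module,
                statistics=observed,
                p_values=pvals,
                classification=classification,
                n_permutations=n_perm,
                seed=mod_seed,
            )
        )
    return results


def results_to_frame(results: list[PreservationResult]) -> pd.DataFrame:
    return pd.DataFrame([r.to_row() for r in results])
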