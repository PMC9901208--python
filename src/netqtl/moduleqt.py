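"""Module quantitative traits: control-cohort PCA and sample projection.

Each preserved module is turned into a per-individual quantitative
trait: a PCA is fitted on the transformed abundances of the module's
genera in the control cohort, and every family sample is projected onto
the first principal component.  The PC1 score measures how strongly a
sample expresses the module's joint co-occurrence pattern.

Group comparisons respect the family structure: control-vs-group tests
use one randomly chosen individual per family (Mann-Whitney U), and the
affected-vs-unaffected comparison uses one random affected/unaffected
pair per family (Wilcoxon signed-rank).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from netqtl.containers import AbundanceTable, log_relative

__all__ = [
    "PCAModel",
    "fit_control_pca",
    "project_samples",
    "qt_group_comparisons",
]


@dataclass
class PCAModel:
    """Control-fitted PCA of one module's genera.

    ``loadings`` rows are orthonormal component vectors over the module
    genera; ``center`` holds the control means on the transform scale;
    ``explained`` the explained-variance fractions (non-increasing).
    """

    genera: list[str]
    center: np.ndarray
    loadings: np.ndarray  # (n_components, n_genera)
    explained: np.ndarray
    transform_tag: str = "log_relative"
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not np.all(np.diff(self.explained) <= 1e-12):
            raise ValueError("explained-variance fractions must be non-increasing")

    @property
    def pc1_explained(self) -> float:
        return float(self.explained[0])


_TRANSFORMS = {"log_relative": log_relative}


def fit_control_pca(
    controls: AbundanceTable,
    nodes: list[str],
    transform: str = "log_relative",
) -> PCAModel:
    """PCA of the transformed module abundances in the control cohort.

    Centered on control means; PC1 orientation fixed so the sum of its
    loadings is nonnegative (the orientation is otherwise arbitrary and
    would flip every downstream effect direction).
    """
    if len(nodes) < 2:
        raise ValueError("need >= 2 module genera")
    if controls.n_samples < 3:
        raise ValueError("need >= 3 control samples")
    data = _TRANSFORMS[transform](controls.counts).loc[:, list(nodes)]
    X = data.to_numpy(dtype=float)
    if np.allclose(controls.counts.loc[:, list(nodes)].to_numpy(), 0):
        raise ValueError("module submatrix is all zero in controls")
    center = X.mean(axis=0)
    Xc = X - center
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    var = s**2
    explained = var / var.sum() if var.sum() > 0 else var
    if Vt[0].sum() < 0:
        Vt = Vt.copy()
        Vt[0] = -Vt[0]
        U = U.copy()
        U[:, 0] = -U[:, 0]
    return PCAModel(
        genera=list(nodes),
        center=center,
        loadings=Vt,
        explained=explained,
        transform_tag=transform,
    )


def project_samples(
    model: PCAModel,
    table: AbundanceTable,
    max_missing_fraction: float = 0.0,
) -> pd.Series:
    """PC1 quantitative trait: (transformed abundance - control center)
    projected on the PC1 loadings.

    Genera absent from the table are zero-filled (counts of 0) and
    reported; more than ``max_missing_fraction`` missing genera is an
    error.
    """
    missing = [g for g in model.genera if g not in table.counts.columns]
    if len(missing) / len(model.genera) > max_missing_fraction:
        raise ValueError(
            f"{len(missing)}/{len(model.genera)} module genera missing from table"
        )
    counts = table.counts.copy()
    if missing:
        warnings.warn(f"zero-filling missing module genera: {missing}")
        for g in missing:
            counts[g] = 0
    data = _TRANSFORMS[model.transform_tag](counts).loc[:, model.genera]
    qt = (data.to_numpy(dtype=float) - model.center) @ model.loadings[0]
    return pd.Series(qt, index=table.counts.index, name="qt")


def _one_per_family(
    values: pd.Series, families: pd.Series, rng: np.random.Generator
) -> pd.Series:
    chosen = []
    for fam, idx in values.groupby(families).groups.items():
        chosen.append(rng.choice(list(idx)))
    return values.loc[chosen]


def qt_group_comparisons(
    qt: pd.Series,
    groups: pd.Series,
    families: pd.Series,
    seed: int | None = None,
) -> dict:
    """Family-aware comparisons of a module QT between study groups.

    ``groups`` maps individual -> {'control', 'affected', 'unaffected'};
    ``families`` maps the non-control individuals to family ids.
    Control-vs-affected and control-vs-unaffected use a two-sided
    Mann-Whitney U with one random individual per family; the
    affected-vs-unaffected contrast uses a two-sided Wilcoxon
    signed-rank on one random affected/unaffected pair per family
    (families without such a pair are skipped and counted).
    """
    valid = {"control", "affected", "unaffected"}
    bad = set(groups.unique()) - valid
    if bad:
        raise ValueError(f"unknown group labels: {bad}")
    rng = np.random.default_rng(seed)
    report: dict = {"seed": seed, "groups": {}}
    for g in ("control", "affected", "unaffected"):
        vals = qt.loc[groups.index[groups == g]]
        if len(vals):
            q1, med, q3 = np.percentile(vals, [25, 50, 75])
            report["groups"][g] = dict(
                n=int(len(vals)), median=float(med), q1=float(q1), q3=float(q3)
            )

    controls = qt.loc[groups.index[groups == "control"]]
    for g in ("affected", "unaffected"):
        ids = groups.index[groups == g]
        if len(ids) == 0 or len(controls) == 0:
            continue
        sampled = _one_per_family(qt.loc[ids], families.loc[ids], rng)
        if len(sampled) == 0:
            raise ValueError(f"group {g} empty after per-family sampling")
        stat, p = stats.mannwhitneyu(controls, sampled, alternative="two-sided")
        entry = dict(
            test="mann-whitney", n_control=int(len(controls)),
            n_group=int(len(sampled)), statistic=float(stat), p=float(p),
        )
        if len(sampled) < 10:
            entry["low_power"] = True
        report[f"control_vs_{g}"] = entry

    aff_ids = groups.index[groups == "affected"]
    una_ids = groups.index[groups == "unaffected"]
    if len(aff_ids) and len(una_ids):
        pairs = []
        skipped = 0
        fam_aff = families.loc[aff_ids]
        fam_una = families.loc[una_ids]
        for fam in sorted(set(fam_aff) | set(fam_una)):
            a_ids = list(fam_aff.index[fam_aff == fam])
            u_ids = list(fam_una.index[fam_una == fam])
            if not a_ids or not u_ids:
                skipped += 1
                continue
            pairs.append((rng.choice(a_ids), rng.choice(u_ids)))
        if pairs:
            diffs = np.array([qt[a] - qt[u] for a, u in pairs])
            mode = "exact" if len(diffs) <= 25 else "approx"
            if np.all(diffs == 0):
                stat, p = 0.0, 1.0
            else:
                stat, p = stats.wilcoxon(
                    diffs, alternative="two-sided", correction=(mode == "approx"),
                    mode=mode if mode == "exact" else "auto",
                )
            report["affected_vs_unaffected"] = dict(
                test="wilcoxon-signed-rank", n_pairs=len(pairs),
                n_families_skipped=skipped, statistic=float(stat), p=float(p),
            )
    return report
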