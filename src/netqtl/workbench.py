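"""Configuration, participant filtering, and the end-to-end pipeline.

``run_all`` executes the whole analysis on simulated data: module
detection per control cohort, cross-cohort preservation in both
directions, module re-detection on the combined controls, PC1 trait
projection of the family samples, covariate adjustment, heritability,
multipoint IBD, the genome-wide linkage scan with support intervals,
within-interval mixed-model association, and the single-taxon
randomization comparison.  Every stage's parameters and seeds go into a
run manifest so a run can be reproduced exactly.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from netqtl import compare as compare_mod
from netqtl import datagen, linkage, moduleqt, netmod, preserve
from netqtl.containers import AbundanceTable
from netqtl.pedigree import multipoint_ibd, write_plink

__all__ = ["PipelineConfig", "filter_participants", "run_all"]

log = logging.getLogger("netqtl")


@dataclass
class PipelineConfig:
    """All pipeline parameters, defaulting to the published settings
    where one exists (minimum module size 10, deepSplit 2, 10,000
    permutations, LOD threshold 3, 2-unit support drop, BMI cutoff 35,
    10,000 random regions)."""

    out_dir: str = "netqtl_out"
    seed: int = 0

    # network / modules
    beta: float = 4.0
    min_module_size: int = 10
    deep_split: int = 2
    dissimilarity: str = "tom"
    sparcc_exclusion_threshold: float = 0.1
    sparcc_rounds: int = 10
    pseudocount: float = 1.0
    min_prevalence: float = 0.0

    # preservation
    n_perm: int = 10_000
    preservation_alpha: float = 0.05

    # traits
    qt_transform: str = "log_relative"

    # filtering
    bmi_cutoff: float = 35.0

    # linkage
    lod_threshold: float = 3.0
    support_drop: float = 2.0
    max_meioses: int = 10

    # comparison
    n_regions: int = 10_000

    # simulation (used with simulate=True)
    simulation: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


def filter_participants(
    covariates: pd.DataFrame,
    bmi_cutoff: float = 35.0,
    missing_policy: str = "drop",
) -> tuple[list, list, dict]:
    """Strict BMI < cutoff filter.

    Returns (kept ids, dropped ids, report).  Individuals with missing
    BMI are dropped or kept according to ``missing_policy``.
    """
    if "bmi" not in covariates.columns:
        raise ValueError("covariate table lacks a 'bmi' column")
    if missing_policy not in ("drop", "keep"):
        raise ValueError("missing_policy must be 'drop' or 'keep'")
    bmi = pd.to_numeric(covariates["bmi"], errors="coerce")
    missing = bmi.isna()
    keep = bmi < bmi_cutoff  # strict inequality: BMI == cutoff is dropped
    if missing_policy == "keep":
        if missing.any():
            warnings.warn(f"keeping {int(missing.sum())} individuals with missing BMI")
        keep = keep | missing
    kept = list(covariates.index[keep])
    dropped = list(covariates.index[~keep])
    report = dict(
        n_kept=len(kept),
        n_dropped=len(dropped),
        n_missing_bmi=int(missing.sum()),
        bmi_cutoff=bmi_cutoff,
        missing_policy=missing_policy,
    )
    return kept, dropped, report


def _detect(table: AbundanceTable, cfg: PipelineConfig):
    return netmod.detect_modules(
        table,
        beta=cfg.beta,
        min_module_size=cfg.min_module_size,
        deep_split=cfg.deep_split,
        dissimilarity=cfg.dissimilarity,
        exclusion_threshold=cfg.sparcc_exclusion_threshold,
        n_exclusion_rounds=cfg.sparcc_rounds,
        pseudocount=cfg.pseudocount,
    )


def run_all(config: PipelineConfig, simulate: bool = True) -> dict:
    """Run the full pipeline on simulated inputs and write all reports.

    Returns a results bundle (also summarised in ``manifest.json``).
    A stage failure raises with the stage name; outputs written by
    earlier stages are preserved.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": asdict(config), "stages": []}
    results: dict = {}
    stage = "init"
    try:
        # -- datagen -------------------------------------------------------
        stage = "datagen"
        if not simulate:
            raise NotImplementedError(
                "external inputs are loaded via the library API; the driver "
                "currently runs on simulated data"
            )
        sim_kwargs = dict(config.simulation)
        sim_kwargs.setdefault("seed", config.seed)
        sim = datagen.SimulationConfig(**sim_kwargs)
        truth = datagen.make_truth(sim)
        cohort_a = datagen.simulate_control_cohort(sim, truth, "A")
        cohort_b = datagen.simulate_control_cohort(sim, truth, "B")
        gmap = datagen.default_genetic_map()
        bundle = datagen.simulate_families(sim, gmap, truth)
        ped = bundle["pedigree"]
        geno = bundle["genotypes"]
        fam_table = bundle["abundance"]
        covariates = bundle["covariates"]
        cohort_a.to_tsv(out / "cohort_a.tsv")
        cohort_b.to_tsv(out / "cohort_b.tsv")
        fam_table.to_tsv(out / "families_abundance.tsv")
        covariates.to_csv(out / "covariates.tsv", sep="\t", index_label="id")
        write_plink(ped, geno, out / "families.ped", out / "families.map")
        truth_json = {
            "module_membership": truth.module_membership.to_dict(),
            "qtl": dict(chrom=sim.qtl_chrom, pos_cm=sim.qtl_pos_cm,
                        variance_fraction=sim.qtl_variance_fraction),
        }
        (out / "truth.json").write_text(json.dumps(truth_json, indent=2))
        manifest["stages"].append(dict(stage=stage, seed=sim.seed))

        # -- participant filter -------------------------------------------
        stage = "filter"
        kept, dropped, filt_report = filter_participants(
            covariates, bmi_cutoff=config.bmi_cutoff
        )
        manifest["stages"].append(dict(stage=stage, **filt_report))
        fam_table = fam_table.subset_samples(kept)
        covariates = covariates.loc[kept]

        # -- network per cohort -------------------------------------------
        stage = "netmod"
        a_shared, b_shared = netmod.intersect_genera(
            cohort_a, cohort_b, min_prevalence=config.min_prevalence
        )
        corr_a, modules_a = _detect(a_shared, config)
        corr_b, modules_b = _detect(b_shared, config)
        corr_a.to_csv(out / "sparcc_a.tsv", sep="\t")
        corr_b.to_csv(out / "sparcc_b.tsv", sep="\t")
        modules_a.to_frame().to_csv(out / "modules_a.tsv", sep="\t", index=False)
        modules_b.to_frame().to_csv(out / "modules_b.tsv", sep="\t", index=False)
        matching = netmod.match_modules(modules_a, modules_b)
        matching.to_csv(out / "module_matching.tsv", sep="\t", index=False)
        manifest["stages"].append(
            dict(stage=stage, n_shared_genera=len(a_shared.genera),
                 n_modules_a=modules_a.n_modules, n_modules_b=modules_b.n_modules)
        )

        # -- preservation, both directions --------------------------------
        stage = "preserve"
        adj_a = netmod.signed_adjacency(corr_a, beta=config.beta)
        adj_b = netmod.signed_adjacency(corr_b, beta=config.beta)
        rng = np.random.default_rng(config.seed)
        pres_ab = preserve.preservation_report(
            modules_a, b_shared, corr_b, adj_b, n_perm=config.n_perm,
            seed=int(rng.integers(2**31)), alpha=config.preservation_alpha,
        )
        pres_ba = preserve.preservation_report(
            modules_b, a_shared, corr_a, adj_a, n_perm=config.n_perm,
            seed=int(rng.integers(2**31)), alpha=config.preservation_alpha,
        )
        preserve.results_to_frame(pres_ab).to_csv(
            out / "preservation_a_in_b.tsv", sep="\t", index=False
        )
        preserve.results_to_frame(pres_ba).to_csv(
            out / "preservation_b_in_a.tsv", sep="\t", index=False
        )
        manifest["stages"].append(
            dict(stage=stage, n_perm=config.n_perm,
                 a_in_b=[r.classification for r in pres_ab],
                 b_in_a=[r.classification for r in pres_ba])
        )

        # -- combined controls + traits ------------------------------------
        stage = "moduleqt"
        combined = AbundanceTable(
            pd.concat([a_shared.counts, b_shared.counts]), cohort="combined"
        )
        corr_c, modules_c = _detect(combined, config)
        modules_c.to_frame().to_csv(out / "modules_combined.tsv", sep="\t", index=False)
        qts = {}
        comparisons = {}
        groups = pd.Series(
            np.where(covariates["disease"] > 0, "affected", "unaffected"),
            index=covariates.index,
        )
        fam_ids = covariates["family"]
        for module, nodes in modules_c.modules().items():
            model = moduleqt.fit_control_pca(
                combined, nodes, transform=config.qt_transform
            )
            qt_fam = moduleqt.project_samples(
                model, fam_table.subset_genera(
                    [g for g in fam_table.genera]
                )
            )
            qt_ctrl = moduleqt.project_samples(model, combined)
            qts[module] = qt_fam
            all_qt = pd.concat([qt_ctrl, qt_fam])
            all_groups = pd.concat(
                [pd.Series("control", index=qt_ctrl.index), groups]
            )
            all_fams = pd.concat(
                [pd.Series("none", index=qt_ctrl.index), fam_ids]
            )
            comparisons[module] = moduleqt.qt_group_comparisons(
                all_qt, all_groups, all_fams, seed=config.seed + module
            )
        qt_frame = pd.DataFrame(qts)
        qt_frame.to_csv(out / "module_qts.tsv", sep="\t", index_label="id")
        (out / "qt_comparisons.json").write_text(
            json.dumps(comparisons, indent=2, default=float)
        )
        manifest["stages"].append(
            dict(stage=stage, n_modules=modules_c.n_modules,
                 pc1_explained={
                     m: moduleqt.fit_control_pca(
                         combined, nodes, transform=config.qt_transform
                     ).pc1_explained
                     for m, nodes in modules_c.modules().items()
                 })
        )

        # -- IBD ------------------------------------------------------------
        stage = "ibd"
        ibd = multipoint_ibd(ped, geno, max_meioses=config.max_meioses)
        ibd.to_tsv(out / "ibd_profile.tsv")
        manifest["stages"].append(
            dict(stage=stage, n_families=len({f.family for f in ibd.families}),
                 n_skipped=len(ibd.skipped))
        )

        # -- linkage --------------------------------------------------------
        stage = "linkage"
        scans = {}
        intervals_all = []
        herit = {}
        for module, qt in qts.items():
            adj_trait, _ = linkage.adjust_covariates(
                qt, covariates[["sex", "age", "bmi", "smoking", "disease"]]
            )
            est = linkage.heritability_vc(adj_trait, ped)
            herit[module] = est
            model = est.trait_model(adj_trait)
            scan = linkage.sham_regression_scan(adj_trait, ibd, model, ped)
            scans[module] = (scan, adj_trait, model)
            scan.to_csv(out / f"scan_module{module}.tsv", sep="\t", index=False)
            for iv in linkage.find_peaks_and_support(
                scan, lod_threshold=config.lod_threshold,
                drop=config.support_drop, gmap=gmap,
            ):
                intervals_all.append((module, iv))
        linkage.intervals_to_frame([iv for _, iv in intervals_all]).assign(
            module=[m for m, _ in intervals_all]
        ).to_csv(out / "support_intervals.tsv", sep="\t", index=False)
        manifest["stages"].append(
            dict(stage=stage,
                 heritability={m: est.h2 for m, est in herit.items()},
                 n_intervals=len(intervals_all))
        )

        # -- association within intervals ----------------------------------
        stage = "associate"
        assoc_frames = []
        for module, iv in intervals_all:
            mk = gmap.chrom_markers(iv.chrom)
            in_iv = mk.loc[
                (mk["cm"] >= iv.start_cm) & (mk["cm"] <= iv.end_cm), "marker"
            ].tolist()
            if not in_iv:
                continue
            _, adj_trait, _ = scans[module]
            res = linkage.lmm_association(adj_trait, geno, ped, markers=in_iv)
            res["module"] = module
            res["chrom"] = iv.chrom
            assoc_frames.append(res)
        if assoc_frames:
            pd.concat(assoc_frames).to_csv(
                out / "association.tsv", sep="\t", index=False
            )
        manifest["stages"].append(dict(stage=stage, n_intervals=len(assoc_frames)))

        # -- single-taxon comparison ----------------------------------------
        stage = "compare"
        comp_rows = []
        if intervals_all:
            module_nodes = modules_c.modules()
            rng2 = np.random.default_rng(config.seed + 1)
            for module, iv in intervals_all:
                nodes = [g for g in module_nodes[module] if g in fam_table.genera]
                taxon_scans = compare_mod.single_taxon_scans(
                    fam_table, ibd, ped,
                    covariates=covariates[["sex", "age", "bmi", "smoking", "disease"]],
                    genera=nodes,
                )
                if not taxon_scans:
                    continue
                res = compare_mod.random_region_pvalue(
                    taxon_scans, nodes, iv, n_regions=config.n_regions,
                    seed=int(rng2.integers(2**31)), module=module,
                )
                row = res.to_row()
                row["module_max_lod"] = iv.max_lod
                comp_rows.append(row)
        if comp_rows:
            pd.DataFrame(comp_rows).to_csv(
                out / "single_taxon_comparison.tsv", sep="\t", index=False
            )
        manifest["stages"].append(dict(stage=stage, n_signals=len(comp_rows)))

        results = dict(
            modules_a=modules_a, modules_b=modules_b, modules_combined=modules_c,
            preservation=(pres_ab, pres_ba), qts=qts, heritability=herit,
            intervals=intervals_all, comparisons=comparisons,
        )
    except Exception as exc:
        manifest["failed_stage"] = stage
        manifest["error"] = str(exc)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
        raise RuntimeError(f"pipeline failed at stage '{stage}': {exc}") from exc
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    results["manifest"] = manifest
    return results
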