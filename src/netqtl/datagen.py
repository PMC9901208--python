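"""Synthetic cohorts and families with planted co-occurrence modules and
a planted QTL.

The generator emulates the study design the pipeline targets: two
population control cohorts sharing the same latent module structure
(zero-inflated compositional counts), plus families of first/second
degree relatives in which each module's latent factor carries a QTL
effect at a known map position, a polygenic component, covariate
effects, and a disease-status shift.

Counts are drawn multinomially from the softmax of per-genus log-scale
signals at a fixed expected sequencing depth (the simplest compositional
mechanism consistent with the log-ratio correlation model); zero
inflation is applied afterwards as independent dropout, which reproduces
the high fraction of zero abundances seen in real genus tables without
altering the latent factor structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from netqtl.containers import AbundanceTable
from netqtl.pedigree import (
    FamilyIBD,
    GeneticMap,
    GenotypeMatrix,
    IBDProfile,
    Pedigree,
    _structure_signature,
    haldane_theta,
    kinship,
)

__all__ = [
    "SimulationConfig",
    "PlantedTruth",
    "make_truth",
    "simulate_control_cohort",
    "simulate_pedigrees",
    "simulate_genotypes",
    "simulate_family_microbiome",
    "default_genetic_map",
    "true_ibd_profile",
]


@dataclass
class SimulationConfig:
    """Study-design parameters for the synthetic data.

    Defaults mirror the scale of the target design: two control cohorts
    of several hundred samples, 256 families, genus tables with a few
    hundred taxa, four planted modules, and a module QT with a QTL
    explaining a realistic minor fraction of variance.
    """

    n_cohort_a: int = 800
    n_cohort_b: int = 800
    n_families: int = 256
    family_structure: str = "nuclear"  # or "three_generation"
    n_offspring: int = 2
    n_genera: int = 200
    planted_modules: list[tuple[int, float]] = field(
        default_factory=lambda: [(40, 2.0), (30, 2.0), (20, 2.0), (15, 2.0)]
    )
    zero_inflation: float = 0.1
    sequencing_depth: int = 20_000
    noise_sd: float = 1.0
    baseline_sd: float = 1.5
    qtl_chrom: object = 1
    qtl_pos_cm: float = 50.0
    qtl_variance_fraction: float = 0.3
    polygenic_variance_fraction: float = 0.2
    covariate_effects: np.ndarray = field(
        default_factory=lambda: np.zeros(4)
    )  # (sex, age, bmi, smoking), per-SD effect on the latent factor
    disease_shift: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sequencing_depth <= 0:
            raise ValueError("sequencing_depth must be positive")
        if not self.planted_modules:
            raise ValueError("at least one planted module is required")
        if any(size < 2 for size, _ in self.planted_modules):
            raise ValueError("each planted module needs >= 2 genera")
        if sum(size for size, _ in self.planted_modules) > self.n_genera:
            raise ValueError("planted module sizes exceed n_genera")
        q, h = self.qtl_variance_fraction, self.polygenic_variance_fraction
        if not (0 <= q <= 1 and 0 <= h <= 1 and q + h <= 1):
            raise ValueError("variance fractions must be in [0,1] and sum <= 1")
        if self.family_structure not in ("nuclear", "three_generation"):
            raise ValueError("family_structure must be nuclear or three_generation")
        self.covariate_effects = np.asarray(self.covariate_effects, dtype=float)

    def rng(self, stream: str) -> np.random.Generator:
        """Named substream of the global seed (reproducible per operation)."""
        ss = np.random.SeedSequence(
            self.seed, spawn_key=tuple(ord(c) for c in stream)
        )
        return np.random.default_rng(ss)


@dataclass
class PlantedTruth:
    """Ground truth shared by the two cohorts and the families."""

    module_membership: pd.Series  # genus -> module id (0 = background)
    loadings: pd.Series  # genus -> log-scale loading on its module factor
    baselines: pd.Series  # genus -> baseline log abundance

    def module_genera(self, module: int) -> list[str]:
        return list(self.module_membership.index[self.module_membership == module])

    @property
    def n_modules(self) -> int:
        return int(self.module_membership.max())


def make_truth(config: SimulationConfig) -> PlantedTruth:
    rng = config.rng("truth")
    genera = [f"g{i:04d}" for i in range(config.n_genera)]
    membership = np.zeros(config.n_genera, dtype=int)
    loadings = np.zeros(config.n_genera)
    start = 0
    for m, (size, scale) in enumerate(config.planted_modules, start=1):
        membership[start:start + size] = m
        loadings[start:start + size] = scale
        start += size
    baselines = rng.normal(0.0, config.baseline_sd, size=config.n_genera)
    return PlantedTruth(
        module_membership=pd.Series(membership, index=genera),
        loadings=pd.Series(loadings, index=genera),
        baselines=pd.Series(baselines, index=genera),
    )


def _counts_from_factors(
    factors: np.ndarray,  # (n_samples, n_modules)
    truth: PlantedTruth,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    n = factors.shape[0]
    membership = truth.module_membership.to_numpy()
    loadings = truth.loadings.to_numpy()
    base = truth.baselines.to_numpy()
    signal = np.zeros((n, config.n_genera))
    planted = membership > 0
    signal[:, planted] = factors[:, membership[planted] - 1] * loadings[planted]
    logits = base + signal + rng.normal(0.0, config.noise_sd, size=signal.shape)
    probs = np.exp(logits - logits.max(axis=1, keepdims=True))
    probs /= probs.sum(axis=1, keepdims=True)
    counts = np.empty((n, config.n_genera), dtype=np.int64)
    for i in range(n):
        counts[i] = rng.multinomial(config.sequencing_depth, probs[i])
    if np.ndim(config.zero_inflation) == 0:
        zi = np.full(config.n_genera, float(config.zero_inflation))
    else:
        zi = np.asarray(config.zero_inflation, dtype=float)
    dropout = rng.random(counts.shape) < zi[None, :]
    counts[dropout] = 0
    return counts


def simulate_control_cohort(
    config: SimulationConfig, truth: PlantedTruth, cohort_id: str
) -> AbundanceTable:
    """Control cohort with planted module structure.

    Per sample, each module's latent factor is standard normal; genus
    log-signals are loading * factor plus independent noise; counts are
    multinomial at the configured depth with per-genus dropout.
    """
    rng = config.rng(f"cohort:{cohort_id}")
    n = config.n_cohort_a if cohort_id == "A" else config.n_cohort_b
    factors = rng.standard_normal((n, truth.n_modules))
    counts = _counts_from_factors(factors, truth, config, rng)
    samples = [f"{cohort_id}_{i:05d}" for i in range(n)]
    df = pd.DataFrame(counts, index=samples, columns=truth.module_membership.index)
    return AbundanceTable(df, cohort=cohort_id)


def simulate_pedigrees(config: SimulationConfig) -> Pedigree:
    """Families of first/second-degree relatives with >= 1 affected member.

    ``nuclear``: two founders and ``n_offspring`` children.
    ``three_generation``: grandparental couple, two of their children,
    one married-in founder, and two grandchildren (adds grandparent-
    grandchild and avuncular second-degree pairs).
    """
    if config.n_families < 1:
        raise ValueError("n_families must be >= 1")
    rng = config.rng("pedigrees")
    rows = []
    for f in range(config.n_families):
        fam = f"F{f:04d}"
        if config.family_structure == "nuclear":
            members = [
                (f"{fam}_p1", "0", "0", 1),
                (f"{fam}_p2", "0", "0", 2),
            ]
            kids = [
                (f"{fam}_c{k+1}", f"{fam}_p1", f"{fam}_p2",
                 int(rng.integers(1, 3)))
                for k in range(config.n_offspring)
            ]
            members += kids
            affected_pool = [m[0] for m in kids]
        else:
            members = [
                (f"{fam}_gp1", "0", "0", 1),
                (f"{fam}_gp2", "0", "0", 2),
                (f"{fam}_c1", f"{fam}_gp1", f"{fam}_gp2", 2),
                (f"{fam}_c2", f"{fam}_gp1", f"{fam}_gp2",
                 int(rng.integers(1, 3))),
                (f"{fam}_s1", "0", "0", 1),
                (f"{fam}_g1", f"{fam}_s1", f"{fam}_c1",
                 int(rng.integers(1, 3))),
                (f"{fam}_g2", f"{fam}_s1", f"{fam}_c1",
                 int(rng.integers(1, 3))),
            ]
            affected_pool = [f"{fam}_g1", f"{fam}_g2", f"{fam}_c2"]
        affected = set(
            rng.choice(affected_pool, size=max(1, len(affected_pool) // 2),
                       replace=False)
        )
        for iid, fa, mo, sex in members:
            rows.append(
                dict(family=fam, id=iid, father=fa, mother=mo, sex=sex,
                     affected=iid in affected)
            )
    return Pedigree(pd.DataFrame(rows))


def default_genetic_map(
    n_chrom: int = 2,
    chrom_length_cm: float = 100.0,
    marker_spacing_cm: float = 10.0,
    start_cm: float = 0.0,
) -> GeneticMap:
    """Evenly spaced markers; bp positions at 1 Mb per cM."""
    rows = []
    for c in range(1, n_chrom + 1):
        positions = np.arange(start_cm, chrom_length_cm + 1e-9, marker_spacing_cm)
        for i, cm in enumerate(positions):
            rows.append(
                dict(marker=f"m{c}_{i:03d}", chrom=c, bp=int(cm * 1e6),
                     cm=float(cm))
            )
    return GeneticMap(pd.DataFrame(rows))


def simulate_genotypes(
    ped: Pedigree,
    gmap: GeneticMap,
    maf_range: tuple[float, float] = (0.2, 0.5),
    seed: int | np.random.Generator = 0,
    n_alleles: int = 2,
    return_origins: bool = False,
):
    """Gene-dropping genotype simulation along the genetic map.

    Founder alleles are drawn from per-marker allele frequencies;
    non-founders inherit by meiosis, with recombination between adjacent
    markers at the Haldane fraction for their cM distance.  With
    ``n_alleles > 2`` markers are multi-allelic with equal frequencies
    (``n_alleles`` >= 2 * number of founders makes a marker fully
    informative with high probability).

    With ``return_origins=True`` additionally returns the founder-
    haplotype origin label of every transmitted allele — the simulator's
    own IBD bookkeeping, usable as ground truth.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    t = gmap.table
    n_markers = len(t)
    ids = ped.ids
    pos = {iid: i for i, iid in enumerate(ids)}
    pt = ped.table
    founder_mask = (pt["father"] == "0").to_numpy()
    alleles = np.zeros((len(ids), n_markers, 2), dtype=np.int16)
    origins = np.zeros((len(ids), n_markers, 2), dtype=np.int32)

    if n_alleles == 2:
        maf = rng.uniform(maf_range[0], maf_range[1], size=n_markers)
        freq2 = maf  # allele code 2 is the minor allele

    # per-chromosome switch probabilities between adjacent markers
    chrom_arr = t["chrom"].to_numpy()
    cm = t["cm"].to_numpy(dtype=float)
    theta = np.zeros(n_markers)  # P(switch before marker m)
    theta[0] = 0.5
    for m in range(1, n_markers):
        if chrom_arr[m] != chrom_arr[m - 1]:
            theta[m] = 0.5
        else:
            theta[m] = haldane_theta(cm[m] - cm[m - 1])

    next_origin = 0
    fathers = pt["father"].to_numpy()
    mothers = pt["mother"].to_numpy()
    for i in range(len(ids)):
        if founder_mask[i]:
            if n_alleles == 2:
                draws = rng.random((n_markers, 2)) < freq2[:, None]
                alleles[i] = np.where(draws, 2, 1)
            else:
                alleles[i] = rng.integers(1, n_alleles + 1, size=(n_markers, 2))
            origins[i, :, 0] = next_origin
            origins[i, :, 1] = next_origin + 1
            next_origin += 2
        else:
            for slot, parent in ((0, fathers[i]), (1, mothers[i])):
                p = pos[parent]
                switch = rng.random(n_markers) < theta
                which = np.cumsum(switch) % 2  # 0/1 parental haplotype track
                start = rng.integers(0, 2)
                which = (which + start) % 2
                alleles[i, :, slot] = alleles[p, np.arange(n_markers), which]
                origins[i, :, slot] = origins[p, np.arange(n_markers), which]
    geno = GenotypeMatrix(ids, gmap, alleles)
    if return_origins:
        return geno, origins
    return geno


def true_ibd_profile(
    ped: Pedigree,
    origins: np.ndarray,
    gmap: GeneticMap,
    max_pairs_kinship: float = 0.25,
) -> IBDProfile:
    """Perfect-information IBD profile from the simulator's own founder-
    origin labels (post_cov = 0; prior covariance from enumeration).

    Useful for calibration studies of the linkage statistic without
    running the marker HMM.
    """
    from netqtl.pedigree import _FamilyHMM

    pos = {iid: i for i, iid in enumerate(ped.ids)}
    profile = IBDProfile()
    prior_cache: dict[tuple, np.ndarray] = {}
    kin_cache: dict[tuple, np.ndarray] = {}
    t = gmap.table
    for fam_id in ped.families:
        fam = ped.family(fam_id)
        ids = fam.ids
        pairs = [
            (i, j)
            for i in range(len(ids))
            for j in range(i + 1, len(ids))
        ]
        sig = _structure_signature(fam)
        if sig not in prior_cache:
            hmm = _FamilyHMM(fam, max_meioses=20)
            S = hmm.n_states
            pi_states = hmm.pair_ibd * 0.5
            mean = pi_states.mean(axis=1)
            cov = pi_states @ pi_states.T / S - np.outer(mean, mean)
            prior_cache[sig] = cov
            phi = kinship(fam).to_numpy()
            kin_cache[sig] = np.array([2.0 * phi[i, j] for i, j in pairs])
        prior_cov = prior_cache[sig]
        expected_pi = kin_cache[sig]
        for chrom in gmap.chroms:
            midx = t.index[t["chrom"] == chrom].to_numpy()
            positions = t.loc[midx, "cm"].to_numpy(dtype=float)
            n_pos = len(positions)
            p012 = np.zeros((n_pos, len(pairs), 3))
            for p, (i, j) in enumerate(pairs):
                oi = origins[pos[ids[i]]][midx]  # (n_pos, 2)
                oj = origins[pos[ids[j]]][midx]
                shared = (
                    (oi[:, 0:1] == oj).any(axis=1).astype(int)
                    + (oi[:, 1:2] == oj).any(axis=1).astype(int)
                )
                p012[np.arange(n_pos), p, shared] = 1.0
            profile.families.append(
                FamilyIBD(
                    family=fam_id,
                    pairs=[(ids[i], ids[j]) for i, j in pairs],
                    expected_pi=expected_pi,
                    chrom=chrom,
                    positions=positions,
                    p012=p012,
                    post_cov=np.zeros((n_pos, len(pairs), len(pairs))),
                    prior_cov=prior_cov,
                )
            )
    return profile


def simulate_families(
    config: SimulationConfig,
    gmap: GeneticMap,
    truth: PlantedTruth,
    qtl_module: int = 1,
    marker_alleles: int = 2,
    maf_range: tuple[float, float] = (0.2, 0.5),
):
    """One-stop family simulation with the QTL cosegregating on the same
    meioses as the marker panel.

    The QTL is inserted as an extra locus at its map position, the whole
    panel is gene-dropped once, and the QTL column is split out before
    the marker genotypes are returned.  The QTL is scored biallelically
    regardless of ``marker_alleles`` (allele codes in the lower half of
    the code range count as the trait-increasing allele, frequency 1/2),
    so highly informative multi-allelic marker panels can be combined
    with a realistic biallelic QTL.  Returns a dict with pedigree,
    genotypes, founder-origin labels, abundance table, covariates, true
    latent factors and the QTL dosage.
    """
    ped = simulate_pedigrees(config)
    t = gmap.table
    if (t["chrom"] == config.qtl_chrom).sum() == 0:
        raise ValueError(f"QTL chromosome {config.qtl_chrom} not on the map")
    qtl_row = pd.DataFrame(
        [dict(marker="__QTL__", chrom=config.qtl_chrom,
              bp=int(config.qtl_pos_cm * 1e6), cm=float(config.qtl_pos_cm))]
    )
    ext = pd.concat([t, qtl_row]).sort_values(["chrom", "cm"], kind="stable")
    ext_map = GeneticMap(ext.reset_index(drop=True))
    geno_ext, origins_ext = simulate_genotypes(
        ped, ext_map, maf_range=maf_range,
        seed=config.rng("genotypes"), n_alleles=marker_alleles,
        return_origins=True,
    )
    qtl_idx = ext_map.marker_index()["__QTL__"]
    qtl_alleles = geno_ext.alleles[:, qtl_idx, :]
    qtl_dosage = pd.Series(
        (qtl_alleles <= max(marker_alleles // 2, 1)).sum(axis=1).astype(float),
        index=geno_ext.ids,
    )
    keep = [m for m in ext_map.table["marker"] if m != "__QTL__"]
    keep_idx = [ext_map.marker_index()[m] for m in keep]
    geno = GenotypeMatrix(
        geno_ext.ids, GeneticMap(ext_map.table.iloc[keep_idx].reset_index(drop=True)),
        geno_ext.alleles[:, keep_idx, :],
    )
    origins = origins_ext[:, keep_idx, :]
    table, covariates, factors = simulate_family_microbiome(
        ped, qtl_dosage, truth, config, qtl_module=qtl_module
    )
    return dict(
        pedigree=ped, genotypes=geno, origins=origins,
        abundance=table, covariates=covariates, factors=factors,
        qtl_dosage=qtl_dosage,
    )


def simulate_family_microbiome(
    ped: Pedigree,
    qtl_dosage: pd.Series | None,
    truth: PlantedTruth,
    config: SimulationConfig,
    qtl_module: int = 1,
) -> tuple[AbundanceTable, pd.DataFrame, pd.DataFrame]:
    """Family abundance table + covariates with a planted QTL on one module.

    The targeted module's latent factor decomposes per individual as
    f = a*(standardised QTL dosage) + g + c'x + e with Var(a*dosage) =
    qtl_variance_fraction, g ~ MVN(0, 2*Phi*sigma_g^2) within families,
    and e filling the remaining unit variance; the disease shift is then
    added for affected individuals.  Other modules' factors carry the
    same polygenic/environmental split but no QTL.

    ``qtl_dosage`` should come from the same gene-drop as the marker
    panel (see :func:`simulate_families`) so that the trait cosegregates
    with the markers; with ``None`` an independent gene-drop at the QTL
    position is used (the trait then carries family resemblance but no
    marker linkage — useful for null studies).

    Returns (abundances, covariates, factors); factors holds the true
    per-individual latent factors for parameter-recovery studies.
    """
    rng = config.rng("families")
    ids = ped.ids
    n = len(ids)
    q = config.qtl_variance_fraction
    h = config.polygenic_variance_fraction

    if qtl_dosage is None:
        qtl_map = GeneticMap(
            pd.DataFrame(
                [dict(marker="QTL", chrom=config.qtl_chrom,
                      bp=int(config.qtl_pos_cm * 1e6), cm=config.qtl_pos_cm)]
            )
        )
        qtl_geno = simulate_genotypes(
            ped, qtl_map, maf_range=(0.5, 0.5), seed=config.rng("qtl-locus")
        )
        qtl_dosage = qtl_geno.dosage("QTL")
    dosage = qtl_dosage.loc[ids].to_numpy(dtype=float)
    sd = dosage.std()
    if q > 0 and sd == 0:
        raise ValueError("QTL locus is monomorphic; cannot plant a QTL effect")
    score = (dosage - dosage.mean()) / (sd if sd > 0 else 1.0)

    # polygenic component: block-diagonal MVN with covariance 2*Phi*h
    g = np.zeros((n, truth.n_modules))
    pos = {iid: i for i, iid in enumerate(ids)}
    if h > 0:
        for fam_id in ped.families:
            fam = ped.family(fam_id)
            K = 2.0 * kinship(fam).to_numpy()
            L = np.linalg.cholesky(K + 1e-10 * np.eye(len(K)))
            z = rng.standard_normal((len(K), truth.n_modules))
            rows = [pos[iid] for iid in fam.ids]
            g[rows, :] = np.sqrt(h) * (L @ z)

    factors = np.zeros((n, truth.n_modules))
    for m in range(truth.n_modules):
        e_var = 1.0 - h - (q if (m + 1) == qtl_module else 0.0)
        e = rng.normal(0.0, np.sqrt(e_var), size=n)
        factors[:, m] = g[:, m] + e
        if (m + 1) == qtl_module and q > 0:
            factors[:, m] += np.sqrt(q) * score

    # covariates
    pt = ped.table
    founder_mask = (pt["father"] == "0").to_numpy()
    sex = (pt["sex"].to_numpy() == 2).astype(float)  # 1 = female
    age = np.where(
        founder_mask,
        rng.normal(55.0, 8.0, size=n),
        rng.normal(28.0, 8.0, size=n),
    ).clip(18, 90)
    bmi = rng.normal(25.5, 3.5, size=n).clip(16, 45)
    smoking = (rng.random(n) < 0.35).astype(float)
    disease = pt["affected"].to_numpy().astype(float)
    covs = np.column_stack([sex, age, bmi, smoking])
    covs_std = (covs - covs.mean(axis=0)) / covs.std(axis=0)
    cov_effect = covs_std @ config.covariate_effects
    factors += cov_effect[:, None]
    factors += (config.disease_shift * disease)[:, None]

    counts = _counts_from_factors(factors, truth, config, rng)
    table = AbundanceTable(
        pd.DataFrame(counts, index=ids, columns=truth.module_membership.index),
        cohort="families",
        meta=pd.DataFrame(
            {"family": pt["family"].to_numpy(), "affected": pt["affected"].to_numpy()},
            index=ids,
        ),
    )
    covariates = pd.DataFrame(
        dict(sex=sex, age=age, bmi=bmi, smoking=smoking, disease=disease,
             family=pt["family"].to_numpy()),
        index=ids,
    )
    factor_df = pd.DataFrame(
        factors, index=ids,
        columns=[f"module{m+1}" for m in range(truth.n_modules)],
    )
    return table, covariates, factor_df
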