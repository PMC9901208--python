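import numpy as np
import pandas as pd
import pytest

from netqtl import datagen
from netqtl.pedigree import GeneticMap, Pedigree


@pytest.fixture
def sib_pair_pedigree() -> Pedigree:
    """Two parents and two full sibs."""
    return Pedigree(pd.DataFrame([
        dict(family="F1", id="p1", father="0", mother="0", sex=1, affected=False),
        dict(family="F1", id="p2", father="0", mother="0", sex=2, affected=False),
        dict(family="F1", id="c1", father="p1", mother="p2", sex=1, affected=True),
        dict(family="F1", id="c2", father="p1", mother="p2", sex=2, affected=False),
    ]))


@pytest.fixture
def three_marker_map() -> GeneticMap:
    return GeneticMap(pd.DataFrame([
        dict(marker="m1", chrom=1, bp=10_000_000, cm=10.0),
        dict(marker="m2", chrom=1, bp=30_000_000, cm=30.0),
        dict(marker="m3", chrom=1, bp=60_000_000, cm=60.0),
    ]))


@pytest.fixture(scope="session")
def planted_cohorts():
    """A pair of control cohorts sharing four planted modules, at the
    default study scale (200 genera, 800 samples per cohort)."""
    cfg = datagen.SimulationConfig(seed=4)
    truth = datagen.make_truth(cfg)
    a = datagen.simulate_control_cohort(cfg, truth, "A")
    b = datagen.simulate_control_cohort(cfg, truth, "B")
    return cfg, truth, a, b


def one_random_instance(rng, ped, gmap, missing_prob=0.15):
    """Random genotype instance for a small family, with missingness."""
    geno = datagen.simulate_genotypes(ped, gmap, maf_range=(0.2, 0.5), seed=rng)
    alleles = geno.alleles.copy()
    n_ind, n_mark, _ = alleles.shape
    drop = rng.random((n_ind, n_mark)) < missing_prob
    alleles[drop] = 0
    from netqtl.pedigree import GenotypeMatrix

    return GenotypeMatrix(geno.ids, gmap, alleles)
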