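"""Pedigree I/O, kinship identities, and the multipoint IBD HMM.

The HMM is checked against an independent brute-force oracle that sums
the joint likelihood over every combination of per-marker inheritance
vectors and founder-allele assignments, with no dynamic programming.
"""

import itertools

import numpy as np
import pandas as pd
import pytest

from netqtl import datagen
from netqtl.pedigree import (
    GeneticMap,
    GenotypeMatrix,
    Pedigree,
    haldane_theta,
    kinship,
    multipoint_ibd,
    read_pedigree,
    read_plink,
    write_plink,
)
from tests.conftest import one_random_instance


class TestPedigreeIO:
    def test_nuclear_family_parsing(self, tmp_path):
        p = tmp_path / "fam.ped"
        p.write_text(
            "F1 p1 0 0 1 1\nF1 p2 0 0 2 1\nF1 c1 p1 p2 1 2\nF1 c2 p1 p2 2 1\n"
        )
        ped = read_pedigree(p)
        assert len(ped.founders) == 2
        assert len(ped) == 4
        assert ped.table.loc[ped.table["id"] == "c1", "affected"].item()

    def test_child_before_parent_is_sorted(self, tmp_path):
        p = tmp_path / "fam.ped"
        p.write_text(
            "F1 c1 p1 p2 1 2\nF1 p1 0 0 1 1\nF1 p2 0 0 2 1\n"
        )
        ped = read_pedigree(p)
        order = list(ped.table["id"])
        assert order.index("p1") < order.index("c1")
        assert order.index("p2") < order.index("c1")

    def test_own_parent_rejected_with_position(self):
        with pytest.raises(ValueError, match="own parent.*row 1"):
            Pedigree(pd.DataFrame([
                dict(family="F1", id="x", father="x", mother="y",
                     sex=1, affected=False),
                dict(family="F1", id="y", father="0", mother="0",
                     sex=2, affected=False),
            ]))

    def test_half_specified_parents_rejected(self):
        with pytest.raises(ValueError, match="only one parent"):
            Pedigree(pd.DataFrame([
                dict(family="F1", id="p1", father="0", mother="0", sex=1,
                     affected=False),
                dict(family="F1", id="c", father="p1", mother="0", sex=1,
                     affected=False),
            ]))

    def test_duplicate_ids_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            Pedigree(pd.DataFrame([
                dict(family="F1", id="a", father="0", mother="0", sex=1,
                     affected=False),
                dict(family="F1", id="a", father="0", mother="0", sex=2,
                     affected=False),
            ]))

    def test_plink_roundtrip(self, tmp_path, sib_pair_pedigree, three_marker_map):
        geno = datagen.simulate_genotypes(sib_pair_pedigree, three_marker_map, seed=0)
        write_plink(sib_pair_pedigree, geno,
                    tmp_path / "f.ped", tmp_path / "f.map")
        ped2, geno2 = read_plink(tmp_path / "f.ped", tmp_path / "f.map")
        assert ped2.ids == sib_pair_pedigree.ids
        assert np.array_equal(geno2.alleles, geno.alleles)
        assert list(geno2.gmap.table["marker"]) == ["m1", "m2", "m3"]


class TestKinship:
    def test_standard_identities(self, sib_pair_pedigree):
        phi = kinship(sib_pair_pedigree)
        assert phi.loc["p1", "p1"] == 0.5
        assert phi.loc["p1", "c1"] == 0.25
        assert phi.loc["c1", "c2"] == 0.25
        assert phi.loc["p1", "p2"] == 0.0

    def test_half_sibs_and_grandparents(self):
        ped = Pedigree(pd.DataFrame([
            dict(family="F", id="gp1", father="0", mother="0", sex=1, affected=False),
            dict(family="F", id="gp2", father="0", mother="0", sex=2, affected=False),
            dict(family="F", id="m1", father="0", mother="0", sex=2, affected=False),
            dict(family="F", id="m2", father="0", mother="0", sex=2, affected=False),
            dict(family="F", id="dad", father="gp1", mother="gp2", sex=1, affected=False),
            dict(family="F", id="k1", father="dad", mother="m1", sex=1, affected=False),
            dict(family="F", id="k2", father="dad", mother="m2", sex=2, affected=False),
        ]))
        phi = kinship(ped)
        assert phi.loc["k1", "k2"] == 0.125  # half sibs
        assert phi.loc["gp1", "k1"] == 0.125  # grandparent-grandchild

    def test_cross_family_founders_unrelated(self):
        cfg = datagen.SimulationConfig(n_families=2, seed=0)
        ped = datagen.simulate_pedigrees(cfg)
        phi = kinship(ped)
        f0 = [i for i in ped.ids if i.startswith("F0000")]
        f1 = [i for i in ped.ids if i.startswith("F0001")]
        assert (phi.loc[f0, f1].to_numpy() == 0).all()

    def test_two_phi_positive_semidefinite(self):
        cfg = datagen.SimulationConfig(
            n_families=3, family_structure="three_generation", seed=1
        )
        ped = datagen.simulate_pedigrees(cfg)
        w = np.linalg.eigvalsh(2 * kinship(ped).to_numpy())
        assert w.min() > -1e-10


# ---------------------------------------------------------------------------
# Brute-force oracle for the sib-pair HMM


def brute_force_sibpair_posterior(alleles, freqs, cm, pos_idx):
    """Direct summation over all (state per marker) combinations and all
    founder-allele assignments for a 2-parent/2-child family.

    State bits: (c1 paternal, c1 maternal, c2 paternal, c2 maternal);
    founder slots 0,1 belong to p1 and 2,3 to p2.  Individual order in
    ``alleles`` is (p1, p2, c1, c2).
    """
    M = alleles.shape[1]

    def slots_for(state):
        b = [(state >> k) & 1 for k in range(4)]
        return [(0, 1), (2, 3), (b[0], 2 + b[1]), (b[2], 2 + b[3])]

    emissions = np.zeros((M, 16))
    for m in range(M):
        fr = freqs[m]
        codes = sorted(fr)
        for state in range(16):
            sl = slots_for(state)
            tot = 0.0
            for assign in itertools.product(codes, repeat=4):
                pr = 1.0
                for a in assign:
                    pr *= fr[a]
                ok = True
                for i in range(4):
                    g = alleles[i, m, :]
                    if g[0] == 0 or g[1] == 0:
                        continue
                    if sorted((assign[sl[i][0]], assign[sl[i][1]])) != sorted(g.tolist()):
                        ok = False
                        break
                if ok:
                    tot += pr
            emissions[m, state] = tot

    thetas = [float(haldane_theta(cm[m + 1] - cm[m])) for m in range(M - 1)]
    post = np.zeros(16)
    total = 0.0
    for states in itertools.product(range(16), repeat=M):
        w = 1.0 / 16
        for m in range(M - 1):
            nf = bin(states[m] ^ states[m + 1]).count("1")
            w *= thetas[m] ** nf * (1 - thetas[m]) ** (4 - nf)
        for m in range(M):
            w *= emissions[m, states[m]]
        post[states[pos_idx]] += w
        total += w
    return post / total


def sibpair_state_to_ibd(state):
    """Alleles shared IBD by the two sibs for an inheritance vector."""
    b = [(state >> k) & 1 for k in range(4)]
    return int(b[0] == b[2]) + int(b[1] == b[3])


class TestMultipointIBD:
    def test_no_genotypes_give_pedigree_prior(self, sib_pair_pedigree,
                                              three_marker_map):
        prof = multipoint_ibd(sib_pair_pedigree, None, three_marker_map)
        fam = prof.families[0]
        sib_idx = fam.pairs.index(("c1", "c2"))
        assert np.allclose(fam.p012[:, sib_idx, :], [0.25, 0.5, 0.25])
        assert np.allclose(fam.pihat[:, sib_idx], 0.5)
        po_idx = fam.pairs.index(("p1", "c1"))
        assert np.allclose(fam.pihat[:, po_idx], 0.5)
        assert np.allclose(fam.p012[:, po_idx, :], [0.0, 1.0, 0.0])

    def test_fully_informative_marker_pins_ibd(self, sib_pair_pedigree):
        """All four parental alleles distinct and both sibs identical:
        IBD = 2 with certainty at the marker."""
        gmap = GeneticMap(pd.DataFrame([dict(marker="m1", chrom=1, bp=1, cm=0.0)]))
        alleles = np.zeros((4, 1, 2), dtype=np.int64)
        alleles[0, 0] = [1, 2]  # p1
        alleles[1, 0] = [3, 4]  # p2
        alleles[2, 0] = [1, 3]  # c1
        alleles[3, 0] = [1, 3]  # c2
        geno = GenotypeMatrix(sib_pair_pedigree.ids, gmap, alleles)
        prof = multipoint_ibd(sib_pair_pedigree, geno)
        fam = prof.families[0]
        sib_idx = fam.pairs.index(("c1", "c2"))
        assert fam.p012[0, sib_idx, 2] == pytest.approx(1.0)

    def test_sibpair_posteriors_match_brute_force(self, sib_pair_pedigree,
                                                  three_marker_map):
        """25 random 3-marker instances (with missing genotypes): HMM
        pairwise posteriors equal the exact enumeration to 1e-10."""
        rng = np.random.default_rng(0)
        cm = three_marker_map.table["cm"].to_numpy(float)
        from netqtl.pedigree import _founder_allele_freqs

        worst = 0.0
        for _ in range(25):
            geno = one_random_instance(rng, sib_pair_pedigree, three_marker_map)
            prof = multipoint_ibd(sib_pair_pedigree, geno)
            if not prof.families:
                continue
            fam = prof.families[0]
            sib_idx = fam.pairs.index(("c1", "c2"))
            freqs = _founder_allele_freqs(geno, sib_pair_pedigree)
            for t, pos in enumerate(cm):
                bf_states = brute_force_sibpair_posterior(
                    geno.alleles, freqs, cm, t
                )
                bf_p012 = np.zeros(3)
                for s in range(16):
                    bf_p012[sibpair_state_to_ibd(s)] += bf_states[s]
                worst = max(worst,
                            np.abs(fam.p012[t, sib_idx, :] - bf_p012).max())
        assert worst < 1e-10

    def test_posterior_invariant_to_allele_relabeling(self, sib_pair_pedigree,
                                                      three_marker_map):
        rng = np.random.default_rng(1)
        geno = one_random_instance(rng, sib_pair_pedigree, three_marker_map,
                                   missing_prob=0.0)
        relabeled = geno.alleles.copy()
        relabeled[relabeled == 1] = 9  # swap allele codes 1 <-> 2
        relabeled[relabeled == 2] = 1
        relabeled[relabeled == 9] = 2
        p1 = multipoint_ibd(sib_pair_pedigree, geno).families[0].p012
        p2 = multipoint_ibd(
            sib_pair_pedigree,
            GenotypeMatrix(geno.ids, three_marker_map, relabeled),
        ).families[0].p012
        assert np.allclose(p1, p2, atol=1e-12)

    def test_zero_recombination_equals_single_locus(self, sib_pair_pedigree):
        """Markers at zero genetic distance act like one concatenated
        locus: the posterior equals the product of the per-marker
        emissions under the uniform inheritance prior."""
        from netqtl.pedigree import _FamilyHMM, _founder_allele_freqs

        gmap = GeneticMap(pd.DataFrame([
            dict(marker="a", chrom=1, bp=1, cm=5.0),
            dict(marker="b", chrom=1, bp=2, cm=5.0),
        ]))
        rng = np.random.default_rng(2)
        geno = datagen.simulate_genotypes(sib_pair_pedigree, gmap, seed=rng)
        prof = multipoint_ibd(sib_pair_pedigree, geno)
        fam = prof.families[0]
        hmm = _FamilyHMM(sib_pair_pedigree)
        em = hmm.emissions(geno.alleles,
                           _founder_allele_freqs(geno, sib_pair_pedigree))
        joint = em[0] * em[1]
        joint /= joint.sum()
        sib_idx = fam.pairs.index(("c1", "c2"))
        expect = np.zeros(3)
        for s in range(hmm.n_states):
            expect[hmm.pair_ibd[sib_idx, s]] += joint[s]
        assert np.allclose(fam.p012[0, sib_idx], expect, atol=1e-12)

    def test_mean_pihat_matches_pedigree_expectation(self):
        """Over gene-dropped replicates, E[pihat] at each marker equals
        2*phi for every pair type."""
        cfg = datagen.SimulationConfig(n_families=300, n_offspring=2, seed=0)
        ped = datagen.simulate_pedigrees(cfg)
        gmap = datagen.default_genetic_map(n_chrom=1, marker_spacing_cm=25.0)
        _, origins = datagen.simulate_genotypes(ped, gmap, seed=3,
                                                return_origins=True)
        prof = datagen.true_ibd_profile(ped, origins, gmap)
        sib_vals, po_vals = [], []
        for fam in prof.families:
            for p, (a, b) in enumerate(fam.pairs):
                if fam.expected_pi[p] == 0.5 and a.endswith(("c1", "c2")) \
                        and b.endswith(("c1", "c2")):
                    sib_vals.append(fam.pihat[:, p])
                elif fam.expected_pi[p] == 0.5:
                    po_vals.append(fam.pihat[:, p])
        assert abs(np.mean(sib_vals) - 0.5) < 0.02
        assert np.allclose(po_vals, 0.5)

    def test_bit_limit_enforced(self):
        cfg = datagen.SimulationConfig(n_families=1, n_offspring=6, seed=0)
        ped = datagen.simulate_pedigrees(cfg)
        gmap = datagen.default_genetic_map(n_chrom=1, marker_spacing_cm=50.0)
        geno = datagen.simulate_genotypes(ped, gmap, seed=0)
        prof = multipoint_ibd(ped, geno, max_meioses=10)
        assert prof.families == []
        assert "bit limit" in prof.skipped[0][1]

    def test_mendelian_inconsistency_skips_or_drops(self, sib_pair_pedigree):
        gmap = GeneticMap(pd.DataFrame([
            dict(marker="a", chrom=1, bp=1, cm=0.0),
            dict(marker="b", chrom=1, bp=2, cm=20.0),
        ]))
        alleles = np.ones((4, 2, 2), dtype=np.int64)
        alleles[2, 0] = [2, 2]  # child 2/2 with both parents 1/1 at marker a
        geno = GenotypeMatrix(sib_pair_pedigree.ids, gmap, alleles)
        prof = multipoint_ibd(sib_pair_pedigree, geno)
        assert prof.families == [] and len(prof.skipped) == 1
        prof2 = multipoint_ibd(sib_pair_pedigree, geno,
                               on_mendel_error="drop_marker")
        assert len(prof2.families) == 1
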