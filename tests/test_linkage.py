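"""Covariate adjustment, REML heritability, the regression linkage
statistic, support intervals, and the kinship LMM."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from netqtl import datagen, linkage
from netqtl.linkage import LOD_SCALE, SupportInterval, TraitModel
from netqtl.pedigree import GeneticMap, Pedigree


class TestAdjustCovariates:
    def test_recovers_planted_coefficient(self):
        rng = np.random.default_rng(0)
        n = 1000
        covs = pd.DataFrame(
            dict(bmi=rng.normal(25, 4, n), age=rng.normal(50, 10, n)),
            index=[f"i{k}" for k in range(n)],
        )
        qt = pd.Series(2.0 * covs["bmi"] + rng.standard_normal(n),
                       index=covs.index)
        resid, coefs = linkage.adjust_covariates(qt, covs)
        assert coefs["bmi"] == pytest.approx(2.0, abs=0.05)
        assert abs(resid.mean()) < 1e-8

    def test_zero_effects_leave_centered_trait(self):
        rng = np.random.default_rng(1)
        n = 500
        covs = pd.DataFrame(dict(bmi=rng.normal(25, 4, n)),
                            index=[f"i{k}" for k in range(n)])
        qt = pd.Series(rng.standard_normal(n), index=covs.index)
        resid, _ = linkage.adjust_covariates(qt, covs)
        assert np.corrcoef(resid, qt - qt.mean())[0, 1] > 0.99

    def test_constant_column_dropped_with_warning(self):
        rng = np.random.default_rng(2)
        covs = pd.DataFrame(dict(bmi=rng.normal(25, 4, 50), site=np.ones(50)),
                            index=[f"i{k}" for k in range(50)])
        qt = pd.Series(rng.standard_normal(50), index=covs.index)
        with pytest.warns(UserWarning, match="constant covariate"):
            _, coefs = linkage.adjust_covariates(qt, covs)
        assert "site" not in coefs.index


class TestHeritability:
    def test_pure_noise_trait_estimates_near_zero(self):
        cfg = datagen.SimulationConfig(
            n_families=150, n_offspring=2, qtl_variance_fraction=0.0,
            polygenic_variance_fraction=0.0, seed=0,
        )
        truth = datagen.make_truth(cfg)
        ped = datagen.simulate_pedigrees(cfg)
        ests = []
        for rep in range(8):
            cfg_r = datagen.SimulationConfig(
                n_families=150, n_offspring=2, qtl_variance_fraction=0.0,
                polygenic_variance_fraction=0.0, seed=rep,
            )
            _, _, factors = datagen.simulate_family_microbiome(
                ped, None, truth, cfg_r
            )
            ests.append(linkage.heritability_vc(factors["module1"], ped).h2)
        assert np.median(ests) < 0.05

    def test_moderate_h2_recovered(self):
        ests = []
        for rep in range(10):
            cfg = datagen.SimulationConfig(
                n_families=300, n_offspring=2, qtl_variance_fraction=0.0,
                polygenic_variance_fraction=0.4, seed=100 + rep,
            )
            truth = datagen.make_truth(cfg)
            ped = datagen.simulate_pedigrees(cfg)
            _, _, factors = datagen.simulate_family_microbiome(ped, None, truth, cfg)
            ests.append(linkage.heritability_vc(factors["module1"], ped).h2)
        assert abs(np.mean(ests) - 0.4) < 0.08

    def test_duplicated_sib_trait_hits_upper_boundary(self):
        cfg = datagen.SimulationConfig(n_families=80, n_offspring=2, seed=3)
        ped = datagen.simulate_pedigrees(cfg)
        rng = np.random.default_rng(3)
        fam_effect = {f: rng.standard_normal() for f in ped.families}
        y = pd.Series(
            [fam_effect[f] for f in ped.table["family"]], index=ped.ids
        )
        est = linkage.heritability_vc(y, ped)
        assert est.h2 > 0.9

    def test_covariates_absorbed(self):
        cfg = datagen.SimulationConfig(
            n_families=200, n_offspring=2, qtl_variance_fraction=0.0,
            polygenic_variance_fraction=0.3,
            covariate_effects=np.array([0.0, 0.0, 1.0, 0.0]), seed=5,
        )
        truth = datagen.make_truth(cfg)
        ped = datagen.simulate_pedigrees(cfg)
        _, covs, factors = datagen.simulate_family_microbiome(ped, None, truth, cfg)
        y = factors["module1"]
        raw = linkage.heritability_vc(y, ped).h2
        adj, _ = linkage.adjust_covariates(y, covs[["sex", "age", "bmi", "smoking"]])
        corrected = linkage.heritability_vc(adj, ped).h2
        # the BMI effect inflates apparent residual variance; adjusting
        # restores the planted signal-to-noise
        assert corrected > raw - 0.05
        assert abs(corrected - 0.3) < 0.12


class TestShamScan:
    def test_chi2_to_lod_conversion(self):
        assert 4.605 / LOD_SCALE == pytest.approx(1.0, abs=1e-3)

    def test_no_marker_information_gives_zero_statistic(self, sib_pair_pedigree,
                                                        three_marker_map):
        from netqtl.pedigree import multipoint_ibd

        rng = np.random.default_rng(0)
        prof = multipoint_ibd(sib_pair_pedigree, None, three_marker_map)
        y = pd.Series(rng.standard_normal(4), index=sib_pair_pedigree.ids)
        model = TraitModel(0.0, 1.0, 0.0)
        # pihat == pedigree expectation everywhere -> zero statistic
        scan = linkage.sham_regression_scan(y, prof, model, sib_pair_pedigree)
        assert (scan["statistic"] == 0).all()
        assert (scan["lod"] == 0).all()

    def test_null_calibration_and_no_false_peaks(self):
        """Null trait on 500 sib-pair families: pointwise statistic is
        chi2(1)-calibrated and LOD never clears the genome-wide bar."""
        cfg = datagen.SimulationConfig(
            n_families=500, n_offspring=2, qtl_variance_fraction=0.0,
            polygenic_variance_fraction=0.0, seed=0,
        )
        ped = datagen.simulate_pedigrees(cfg)
        gmap = datagen.default_genetic_map(n_chrom=1, marker_spacing_cm=20.0)
        rng = np.random.default_rng(1)
        pv, lods = [], []
        for rep in range(40):
            _, origins = datagen.simulate_genotypes(
                ped, gmap, seed=rng, return_origins=True
            )
            ibd = datagen.true_ibd_profile(ped, origins, gmap)
            y = pd.Series(rng.standard_normal(len(ped.ids)), index=ped.ids)
            scan = linkage.sham_regression_scan(
                y, ibd, TraitModel(0.0, 1.0, 0.0), ped
            )
            s = scan["statistic"].iloc[len(scan) // 2]
            pv.append(stats.chi2.sf(abs(s), 1) / 2 if s > 0
                      else 1 - stats.chi2.sf(abs(s), 1) / 2)
            lods.append(scan["lod"].max())
        assert stats.kstest(pv, "uniform").pvalue > 0.01
        assert max(lods) < 3.0

    def test_planted_qtl_detected_at_position(self):
        """A QTL explaining 30% of trait variance in 300 sibship-of-4
        families produces a genome-wide significant peak at its locus."""
        cfg = datagen.SimulationConfig(
            n_families=300, n_offspring=4, qtl_chrom=1, qtl_pos_cm=50.0,
            qtl_variance_fraction=0.3, polygenic_variance_fraction=0.2, seed=7,
        )
        truth = datagen.make_truth(cfg)
        gmap = datagen.default_genetic_map(n_chrom=1, marker_spacing_cm=10.0)
        bundle = datagen.simulate_families(cfg, gmap, truth)
        ped = bundle["pedigree"]
        ibd = datagen.true_ibd_profile(ped, bundle["origins"], gmap)
        y = bundle["factors"]["module1"]
        model = TraitModel(float(y.mean()), float(y.var(ddof=1)), 0.5)
        scan = linkage.sham_regression_scan(y, ibd, model, ped)
        peak = scan.loc[scan["lod"].idxmax()]
        assert peak["lod"] > 3.0
        assert abs(peak["pos_cm"] - 50.0) <= 10.0

    def test_lod_invariant_to_trait_rescaling(self):
        cfg = datagen.SimulationConfig(n_families=100, n_offspring=2, seed=2,
                                       qtl_variance_fraction=0.0,
                                       polygenic_variance_fraction=0.2)
        ped = datagen.simulate_pedigrees(cfg)
        gmap = datagen.default_genetic_map(n_chrom=1, marker_spacing_cm=25.0)
        rng = np.random.default_rng(3)
        _, origins = datagen.simulate_genotypes(ped, gmap, seed=rng,
                                                return_origins=True)
        ibd = datagen.true_ibd_profile(ped, origins, gmap)
        y = pd.Series(rng.standard_normal(len(ped.ids)), index=ped.ids)
        s1 = linkage.sham_regression_scan(
            y, ibd, TraitModel(0.0, 1.0, 0.2), ped
        )
        s2 = linkage.sham_regression_scan(
            5.0 * y + 3.0, ibd, TraitModel(3.0, 25.0, 0.2), ped
        )
        assert np.allclose(s1["lod"], s2["lod"], atol=1e-8)


class TestPeaksAndSupport:
    def _scan(self, lods, chrom=1):
        return pd.DataFrame(dict(
            chrom=chrom, pos_cm=np.arange(len(lods), dtype=float),
            statistic=np.array(lods) * LOD_SCALE, lod=lods,
        ))

    def test_triangular_peak_interval_geometry(self):
        """Unit-slope triangle peaking at 4: the drop-2 run spans peak
        +/- 2 cM, snapped one evaluated point outward."""
        lods = [0, 1, 2, 3, 4, 3, 2, 1, 0.0]
        ivs = linkage.find_peaks_and_support(self._scan(lods))
        assert len(ivs) == 1
        iv = ivs[0]
        assert iv.peak_cm == 4.0 and iv.max_lod == 4.0
        assert (iv.start_cm, iv.end_cm) == (2.0, 6.0)  # peak +/- 2 cM

    def test_flat_low_curve_has_no_peaks(self):
        assert linkage.find_peaks_and_support(self._scan([1.0] * 10)) == []

    def test_two_separated_peaks_give_two_intervals(self):
        lods = [0, 3.5, 1.0, 3.2, 0.0]
        ivs = linkage.find_peaks_and_support(self._scan(lods))
        assert len(ivs) == 2
        assert {iv.peak_cm for iv in ivs} == {1.0, 3.0}
        # brute-force check of the interval membership rule
        for iv in ivs:
            inner = [p for p in range(5) if iv.start_cm < p < iv.end_cm]
            for p in inner:
                assert lods[p] > iv.max_lod - 2.0

    def test_intervals_contain_peak_and_widen_with_drop(self):
        rng = np.random.default_rng(4)
        lods = np.clip(rng.normal(1, 1, 50), 0, None)
        lods[25] = 5.0
        narrow = linkage.find_peaks_and_support(self._scan(list(lods)), drop=1.0)
        wide = linkage.find_peaks_and_support(self._scan(list(lods)), drop=3.0)
        for ivs in (narrow, wide):
            for iv in ivs:
                assert iv.start_cm <= iv.peak_cm <= iv.end_cm
        assert wide[0].length_cm >= narrow[0].length_cm


class TestLmmAssociation:
    def _unrelated_pedigree(self, n=120):
        rows = []
        for i in range(n // 2):
            rows.append(dict(family=f"F{i}", id=f"i{i}a", father="0", mother="0",
                             sex=1, affected=False))
            rows.append(dict(family=f"F{i}", id=f"i{i}b", father="0", mother="0",
                             sex=2, affected=False))
        return Pedigree(pd.DataFrame(rows))

    def test_identity_kinship_equals_ols(self):
        ped = self._unrelated_pedigree()
        gmap = datagen.default_genetic_map(n_chrom=1, chrom_length_cm=20,
                                           marker_spacing_cm=10.0)
        rng = np.random.default_rng(5)
        geno = datagen.simulate_genotypes(ped, gmap, seed=rng)
        y = pd.Series(rng.standard_normal(len(ped.ids)), index=ped.ids)
        res = linkage.lmm_association(y, geno, ped)
        for _, row in res.iterrows():
            d = geno.dosage(row["marker"]).loc[ped.ids].to_numpy()
            X = np.column_stack([np.ones(len(d)), d])
            beta = np.linalg.lstsq(X, y.to_numpy(), rcond=None)[0]
            assert abs(row["effect"] - beta[1]) < 1e-8

    def test_causal_snp_detected(self):
        cfg = datagen.SimulationConfig(n_families=150, n_offspring=2, seed=6,
                                       qtl_variance_fraction=0.0,
                                       polygenic_variance_fraction=0.2)
        ped = datagen.simulate_pedigrees(cfg)
        gmap = datagen.default_genetic_map(n_chrom=1, chrom_length_cm=40,
                                           marker_spacing_cm=20.0)
        rng = np.random.default_rng(6)
        geno = datagen.simulate_genotypes(ped, gmap, seed=rng)
        d = geno.dosage("m1_001").loc[ped.ids].to_numpy()
        dz = (d - d.mean()) / d.std()
        y = pd.Series(np.sqrt(0.10) * dz
                      + np.sqrt(0.90) * rng.standard_normal(len(ped.ids)),
                      index=ped.ids)
        res = linkage.lmm_association(y, geno, ped).set_index("marker")
        assert res.loc["m1_001", "p"] < res["bonferroni_threshold"].iloc[0]

    def test_monomorphic_snp_skipped(self):
        ped = self._unrelated_pedigree(60)
        gmap = GeneticMap(pd.DataFrame([
            dict(marker="mono", chrom=1, bp=1, cm=0.0),
            dict(marker="poly", chrom=1, bp=2, cm=10.0),
        ]))
        rng = np.random.default_rng(7)
        geno = datagen.simulate_genotypes(ped, gmap, seed=rng)
        geno.alleles[:, 0, :] = 1  # force monomorphic
        y = pd.Series(rng.standard_normal(len(ped.ids)), index=ped.ids)
        res = linkage.lmm_association(y, geno, ped)
        assert list(res["marker"]) == ["poly"]
        assert res.attrs["skipped_monomorphic"] == ["mono"]

    def test_too_few_individuals_rejected(self):
        ped = self._unrelated_pedigree(20)
        gmap = datagen.default_genetic_map(n_chrom=1, chrom_length_cm=10,
                                           marker_spacing_cm=10.0)
        geno = datagen.simulate_genotypes(ped, gmap, seed=0)
        y = pd.Series(np.zeros(20), index=ped.ids)
        with pytest.raises(ValueError, match=">= 30"):
            linkage.lmm_association(y, geno, ped)
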