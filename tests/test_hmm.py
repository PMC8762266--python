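"""Copying-HMM engine: posteriors, interpolation, genotypes, INFO, merging."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from admiximpute import (AdmixtureConfig, ChromosomeSpec, HaplotypeSet,
                         LSParams, dosage, info_score, info_scores,
                         interpolate_alleles, leave_one_out_impute,
                         ls_posteriors, merge_panels, simulate_admixed)
from admiximpute.hmm import (haploid_to_genotype, impute_haplotypes,
                             impute_individual)
from conftest import make_sources
from helpers import brute_posteriors


def toy_panel(alleles, positions_bp, pops=None):
    alleles = np.asarray(alleles, dtype=np.uint8)
    H = alleles.shape[0]
    ids = np.repeat([f"P{i}" for i in range((H + 1) // 2)], 2)[:H]
    chrom = ChromosomeSpec(int(max(positions_bp)) + 1000, rate_cM_per_Mb=1000.0)
    return HaplotypeSet(alleles, positions_bp, chrom.bp_to_cM(positions_bp),
                        ids, pops if pops is not None else np.repeat("EUR", H))


class TestLsPosteriors:
    def test_single_reference_state(self):
        panel = np.array([[0, 1, 0, 1]])
        gamma = ls_posteriors([0, 0, 1, 1], panel, [0.0, 1.0, 2.0, 3.0], LSParams())
        assert np.allclose(gamma, 1.0)

    def test_perfect_copy_concentrates_posterior(self):
        rng = np.random.default_rng(1)
        panel = rng.integers(0, 2, (5, 30))
        target = panel[2].copy()
        # make all other haplotypes mismatch somewhere
        for h in [0, 1, 3, 4]:
            if np.array_equal(panel[h], target):
                panel[h, 0] ^= 1
        cm = np.linspace(0, 1, 30)
        gamma = ls_posteriors(target, panel, cm,
                              LSParams(ne_eff=10.0, miscopy_lambda=1e-6))
        assert np.all(gamma[:, 2] > 0.99)

    def test_matches_exhaustive_path_enumeration(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            H = int(rng.integers(1, 5))
            T = int(rng.integers(1, 7))
            panel = rng.integers(0, 2, (H, T))
            target = rng.integers(0, 2, T)
            cm = np.sort(rng.uniform(0, 5, T))
            params = LSParams(ne_eff=float(rng.uniform(100, 20000)),
                              miscopy_lambda=float(rng.uniform(1e-4, 0.2)))
            gamma = ls_posteriors(target, panel, cm, params)
            oracle = brute_posteriors(target, panel, cm, params.ne_eff,
                                      params.miscopy_lambda, params.min_switch)
            assert np.abs(gamma - oracle).max() < 1e-10

    def test_rows_sum_to_one(self, rng):
        panel = rng.integers(0, 2, (20, 50))
        target = rng.integers(0, 2, 50)
        gamma = ls_posteriors(target, panel, np.linspace(0, 10, 50), LSParams())
        assert np.allclose(gamma.sum(axis=1), 1.0, atol=1e-9)

    def test_reference_relabeling_permutes_posteriors(self, rng):
        panel = rng.integers(0, 2, (8, 20))
        target = rng.integers(0, 2, 20)
        cm = np.linspace(0, 4, 20)
        perm = rng.permutation(8)
        g1 = ls_posteriors(target, panel, cm, LSParams())
        g2 = ls_posteriors(target, panel[perm], cm, LSParams())
        assert np.allclose(g1[:, perm], g2, atol=1e-12)

    def test_rejects_empty_and_nonbinary(self):
        with pytest.raises(ValueError):
            ls_posteriors(np.array([]), np.zeros((2, 0)), np.array([]), LSParams())
        with pytest.raises(ValueError):
            ls_posteriors([0, 2], np.zeros((2, 2), dtype=int), [0.0, 1.0], LSParams())


class TestInterpolateAlleles:
    def test_untyped_at_typed_genetic_position(self):
        # an untyped site at the same cM as a typed site inherits its posterior
        panel_all = np.array([[1, 1, 0], [0, 0, 1]])
        cm = np.array([0.0, 0.0, 1.0])  # site 1 untyped, same cM as site 0
        typed_idx = np.array([0, 2])
        gamma = np.array([[0.8, 0.2], [0.3, 0.7]])
        params = LSParams(miscopy_lambda=0.01)
        p = interpolate_alleles(gamma, panel_all, cm, typed_idx, params)
        lam = 0.01
        assert p[1] == pytest.approx(lam + (1 - 2 * lam) * 0.8)

    def test_unanimous_panel_gives_one_minus_lambda(self, rng):
        panel_all = np.ones((4, 5), dtype=int)
        cm = np.linspace(0, 2, 5)
        typed_idx = np.array([0, 4])
        gamma = rng.dirichlet(np.ones(4), size=2)
        params = LSParams(miscopy_lambda=0.001)
        p = interpolate_alleles(gamma, panel_all, cm, typed_idx, params)
        assert np.allclose(p, 1 - 0.001, atol=1e-12)

    def test_midpoint_blend_two_haplotypes(self):
        # posteriors fully on hap0 at the left typed site and hap1 at the
        # right; at the genetic midpoint the blend is 50/50
        panel_all = np.array([[1, 1, 0], [0, 0, 0]])
        cm = np.array([0.0, 0.5, 1.0])
        typed_idx = np.array([0, 2])
        gamma = np.array([[1.0, 0.0], [0.0, 1.0]])
        lam = 0.01
        p = interpolate_alleles(gamma, panel_all, cm, typed_idx,
                                LSParams(miscopy_lambda=lam))
        # dose at midpoint = 0.5*allele(h0) + 0.5*allele(h1) = 0.5
        assert p[1] == pytest.approx(lam + (1 - 2 * lam) * 0.5)

    def test_extrapolation_uses_nearest_posterior(self):
        panel_all = np.array([[1, 1, 0, 0], [0, 0, 1, 1]])
        cm = np.array([0.0, 1.0, 2.0, 3.0])
        typed_idx = np.array([1, 2])
        gamma = np.array([[0.9, 0.1], [0.2, 0.8]])
        lam = 0.001
        p = interpolate_alleles(gamma, panel_all, cm, typed_idx,
                                LSParams(miscopy_lambda=lam))
        assert p[0] == pytest.approx(lam + (1 - 2 * lam) * 0.9)
        assert p[3] == pytest.approx(lam + (1 - 2 * lam) * 0.8)


class TestGenotypeAssembly:
    @pytest.mark.parametrize("a,b,expected", [
        (0.0, 0.0, (1.0, 0.0, 0.0)),
        (1.0, 0.0, (0.0, 1.0, 0.0)),
        (0.5, 0.3, (0.35, 0.50, 0.15)),
    ])
    def test_product_formula(self, a, b, expected):
        assert haploid_to_genotype(a, b) == pytest.approx(expected)

    def test_mismatched_haplotypes_rejected(self, toy_sources):
        with pytest.raises(ValueError):
            impute_individual(np.zeros(3, dtype=int), np.zeros(4, dtype=int),
                              toy_sources, np.arange(3), LSParams())

    @given(st.floats(0, 1), st.floats(0, 1))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_triplets_sum_to_one(self, a, b):
        assert haploid_to_genotype(a, b).sum() == pytest.approx(1.0)


class TestDosageAndInfo:
    @pytest.mark.parametrize("triplet,expected", [
        ((1.0, 0.0, 0.0), 0.0),
        ((0.0, 0.0, 1.0), 2.0),
        ((0.2, 0.5, 0.3), 1.1),
    ])
    def test_dosage_formula(self, triplet, expected):
        assert dosage(np.array(triplet)) == pytest.approx(expected)

    def test_certain_triplets_info_one(self):
        probs = np.array([[0.0, 1.0, 0.0], [0.0, 0.0, 1.0], [1.0, 0.0, 0.0]])
        assert info_score(probs) == pytest.approx(1.0)

    def test_monomorphic_convention(self):
        probs = np.array([[1.0, 0.0, 0.0]] * 4)
        assert info_score(probs) == pytest.approx(1.0)

    def test_hand_computed_zero_information(self):
        # two Hardy-Weinberg-uncertain individuals: e=(1,1), f=(1.5,1.5),
        # theta=0.5 -> info = 1 - 1.0/(4*0.25) = 0
        probs = np.array([[0.25, 0.5, 0.25], [0.25, 0.5, 0.25]])
        assert info_score(probs) == pytest.approx(0.0, abs=1e-12)

    def test_zero_individuals_rejected(self):
        with pytest.raises(ValueError):
            info_score(np.zeros((0, 3)))

    def test_allele_flip_equivariance(self, rng):
        # flipping alleles swaps P(AA) and P(aa): dosage maps d -> 2 - d
        # and INFO is unchanged
        probs = rng.dirichlet(np.ones(3), size=(10, 7, 1)).squeeze(-2)
        flipped = probs[..., ::-1]
        assert np.allclose(dosage(flipped), 2.0 - dosage(probs))
        assert np.allclose(info_scores(flipped), info_scores(probs), atol=1e-12)


class TestMergePanels:
    def test_identical_sites_concatenate(self, toy_sources):
        a = toy_sources.take_haplotypes(np.arange(0, 20))
        b = toy_sources.take_haplotypes(np.arange(20, 30))
        for mode in ("intersect", "cross_impute"):
            merged = merge_panels(a, b, mode)
            assert merged.n_haplotypes == 30
            assert np.array_equal(merged.alleles,
                                  toy_sources.alleles[:30])

    def test_subset_union_keeps_superset_sites(self, toy_sources):
        a = toy_sources.take_haplotypes(np.arange(0, 10))
        b = toy_sources.take_haplotypes(np.arange(10, 20)).take_sites(
            np.arange(0, toy_sources.n_sites, 2))
        merged = merge_panels(a, b, "cross_impute")
        assert np.array_equal(merged.positions_bp, a.positions_bp)
        assert merged.n_haplotypes == 20

    def test_disjoint_intersect_rejected(self, toy_sources):
        a = toy_sources.take_sites(np.arange(0, 100))
        b = toy_sources.take_sites(np.arange(100, 200))
        with pytest.raises(ValueError):
            merge_panels(a, b, "intersect")

    def test_cross_impute_fills_ld_determined_allele(self):
        # in panel A the middle allele is perfectly determined by the
        # flanks; panel B lacks the middle site and must recover it
        A = toy_panel(np.array([[1, 1, 1], [1, 1, 1], [0, 0, 0], [0, 0, 0]]),
                      np.array([100, 200, 300]))
        B = toy_panel(np.array([[1, 1], [0, 0]]), np.array([100, 300]))
        merged = merge_panels(A, B, "cross_impute",
                              LSParams(miscopy_lambda=1e-4))
        filled = merged.alleles[4:, 1]
        assert list(filled) == [1, 0]


class TestLeaveOneOut:
    def _cohort_in_panel(self, toy_chrom, toy_sources):
        cfg = AdmixtureConfig((1 / 6, 1 / 3, 1 / 2), 12, 3)
        cohort, _ = simulate_admixed(toy_sources, cfg, toy_chrom, seed=11)
        panel = HaplotypeSet.concat_haplotypes([cohort, toy_sources])
        return cohort, panel

    def test_target_haplotypes_removed(self, toy_chrom, toy_sources):
        cohort, panel = self._cohort_in_panel(toy_chrom, toy_sources)
        typed_idx = np.arange(0, cohort.n_sites, 4)
        gp = leave_one_out_impute(cohort, panel, typed_idx, LSParams())
        gp.validate()
        # manual check for individual 0: impute against panel minus its haps
        keep = np.flatnonzero(panel.sample_ids != cohort.sample_ids[0])
        manual = impute_individual(cohort.alleles[0, typed_idx],
                                   cohort.alleles[1, typed_idx],
                                   panel.take_haplotypes(keep), typed_idx,
                                   LSParams())
        assert np.allclose(gp.probs[0], manual, atol=1e-12)

    def test_absent_individual_rejected(self, toy_chrom, toy_sources):
        cohort, _ = self._cohort_in_panel(toy_chrom, toy_sources)
        with pytest.raises(ValueError, match="not found"):
            leave_one_out_impute(cohort, toy_sources, np.arange(5), LSParams())

    def test_identical_twin_gives_near_perfect_recovery(self, toy_chrom, toy_sources):
        cohort, panel = self._cohort_in_panel(toy_chrom, toy_sources)
        twin = cohort.take_individuals([0])
        twin.sample_ids = np.array(["TWIN0", "TWIN0"])
        panel = HaplotypeSet.concat_haplotypes([panel, twin])
        typed_idx = np.arange(0, cohort.n_sites, 4)
        heldout = np.setdiff1d(np.arange(cohort.n_sites), typed_idx)
        gp = leave_one_out_impute(cohort.take_individuals([0]), panel,
                                  typed_idx, LSParams(miscopy_lambda=1e-4))
        true = (cohort.alleles[0] + cohort.alleles[1]).astype(float)[heldout]
        imp = gp.dosages()[0][heldout]
        r = np.corrcoef(imp, true)[0, 1]
        assert r * r > 0.99

    def test_private_variant_drops_without_carrier(self, toy_chrom, toy_sources):
        cohort, panel = self._cohort_in_panel(toy_chrom, toy_sources)
        # make individual 0 the sole carrier at a held-out site
        site = 101
        panel.alleles[:, site] = 0
        cohort.alleles[:, site] = 0
        cohort.alleles[0, site] = 1
        own = np.flatnonzero(panel.sample_ids == cohort.sample_ids[0])
        panel.alleles[own[0], site] = 1
        typed_idx = np.arange(0, cohort.n_sites, 4)
        assert site not in typed_idx
        params = LSParams(ne_eff=200.0, miscopy_lambda=1e-3)
        loo = leave_one_out_impute(cohort.take_individuals([0]), panel,
                                   typed_idx, params)
        kept = impute_individual(cohort.alleles[0, typed_idx],
                                 cohort.alleles[1, typed_idx], panel,
                                 typed_idx, params)
        loo_dose = loo.dosages()[0][site]
        kept_dose = dosage(kept)[site]
        assert loo_dose < 0.1
        # with the carrier haplotype retained, posterior mass on it keeps the
        # dosage well above the leave-one-out value
        assert kept_dose > 0.2
        assert kept_dose > 10 * loo_dose


class TestPerfectPanelRecovery:
    def test_mosaic_targets_recovered(self, toy_chrom):
        # targets built as pure mosaics of panel haplotypes (no mutation):
        # held-out dosages must track truth almost perfectly
        src = make_sources(toy_chrom, n_sites=400, n_haps=40, seed=21, flip=0.0)
        cfg = AdmixtureConfig((1 / 6, 1 / 3, 1 / 2), 12, 10)
        targets, _ = simulate_admixed(src, cfg, toy_chrom, seed=22)
        typed_idx = np.arange(0, src.n_sites, 3)
        heldout = np.setdiff1d(np.arange(src.n_sites), typed_idx)
        probs = impute_haplotypes(targets.alleles[:, typed_idx], src,
                                  typed_idx,
                                  LSParams(ne_eff=300.0, miscopy_lambda=1e-4))
        gp = haploid_to_genotype(probs[0::2], probs[1::2])
        imp = dosage(gp)[:, heldout].ravel()
        true = (targets.alleles[0::2] + targets.alleles[1::2])[:, heldout].ravel()
        r = np.corrcoef(imp, true.astype(float))[0, 1]
        assert r * r >= 0.99
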