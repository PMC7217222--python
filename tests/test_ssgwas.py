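"""Single-step GWAS: BLUP oracle, SNP back-solution, weighting loop, windows."""

import numpy as np
import pandas as pd
import pytest

from lactgwas.kinship import GenotypeSet, a_matrix, g_matrix
from lactgwas.reml import ModelSpec, VarianceComponents
from lactgwas.ssgwas import (
    backsolve_snp_effects,
    candidate_windows,
    iterate_weights,
    solve_ssgblup,
    window_variance,
)
from tests.conftest import random_genotypes

MEAN_ONLY = ModelSpec(response="y", fixed_effects=(), covariates=())


@pytest.fixture(scope="module")
def toy_system():
    ped = pd.DataFrame({"animal": [1, 2, 3, 4, 5],
                        "sire": [0, 0, 1, 1, 3],
                        "dam": [0, 0, 2, 2, 4]})
    A = a_matrix(ped)
    ph = pd.DataFrame({"animal": [1, 2, 3, 4], "y": [12.0, 9.0, 11.0, 10.0]})
    comp = VarianceComponents(sigma_a2=2.0, sigma_p2=0.0, sigma_e2=3.0, converged=True)
    return ped, A, ph, comp


class TestSolveSsgblup:
    def test_matches_direct_blup_oracle(self, toy_system):
        ped, A, ph, comp = toy_system
        sol = solve_ssgblup(MEAN_ONLY, ph, np.linalg.inv(A),
                            ped["animal"].to_numpy(), comp)
        # direct GLS/BLUP through V for the recorded animals, extended to
        # animal 5 through its relationships
        Zr = np.zeros((4, 5))
        Zr[np.arange(4), np.arange(4)] = 1.0
        V = comp.sigma_a2 * Zr @ A @ Zr.T + comp.sigma_e2 * np.eye(4)
        X = np.ones((4, 1))
        Vi = np.linalg.inv(V)
        beta = np.linalg.solve(X.T @ Vi @ X, X.T @ Vi @ ph["y"])
        u = comp.sigma_a2 * A @ Zr.T @ Vi @ (ph["y"].to_numpy() - (X @ beta))
        np.testing.assert_allclose(sol.gebv, u, atol=1e-8)

    def test_unrelated_unrecorded_animal_zero(self, toy_system):
        ped, A, ph, comp = toy_system
        ped6 = pd.concat([ped, pd.DataFrame([{"animal": 6, "sire": 0, "dam": 0}])],
                         ignore_index=True)
        A6 = a_matrix(ped6)
        sol = solve_ssgblup(MEAN_ONLY, ph, np.linalg.inv(A6),
                            ped6["animal"].to_numpy(), comp)
        assert sol.gebv[5] == pytest.approx(0.0, abs=1e-10)
        assert sol.accuracy[5] == pytest.approx(0.0, abs=1e-6)

    def test_shrinkage_limit(self, toy_system):
        ped, A, ph, _ = toy_system
        tiny = VarianceComponents(sigma_a2=1e-8, sigma_p2=0.0, sigma_e2=3.0,
                                  converged=True)
        sol = solve_ssgblup(MEAN_ONLY, ph, np.linalg.inv(A),
                            ped["animal"].to_numpy(), tiny)
        assert np.max(np.abs(sol.gebv)) < 1e-6

    def test_accuracy_in_unit_interval(self, toy_system):
        ped, A, ph, comp = toy_system
        sol = solve_ssgblup(MEAN_ONLY, ph, np.linalg.inv(A),
                            ped["animal"].to_numpy(), comp)
        assert np.all((sol.accuracy >= 0) & (sol.accuracy <= 1))
        assert np.all(sol.pev >= 0)


class TestBacksolve:
    def test_constructed_consistency(self):
        """a_g exactly in the span of Z: Z u_hat reproduces a_g."""
        rng = np.random.default_rng(12)
        gs = random_genotypes(rng, 40, 25)
        Z = gs.centered()
        u_true = rng.normal(0, 0.3, 25)
        a_g = Z @ u_true
        p = gs.allele_freq
        lam = 1.0 / np.sum(2 * p * (1 - p))
        G = lam * Z @ Z.T + 1e-8 * np.eye(40)
        eff = backsolve_snp_effects(a_g, gs, np.ones(25), G)
        np.testing.assert_allclose(Z @ eff.u_hat, a_g, atol=1e-5)

    def test_weight_reparameterization_keeps_fitted_values(self):
        """Scaling D leaves Z u_hat invariant when G is rebuilt accordingly."""
        rng = np.random.default_rng(13)
        gs = random_genotypes(rng, 30, 20)
        Z = gs.centered()
        a_g = Z @ rng.normal(0, 0.2, 20)
        p = gs.allele_freq
        lam = 1.0 / np.sum(2 * p * (1 - p))
        for scale in (1.0, 2.0):
            D = scale * np.ones(20)
            G = lam * (Z * D) @ Z.T + 1e-8 * np.eye(30)
            eff = backsolve_snp_effects(a_g, gs, D, G)
            np.testing.assert_allclose(Z @ eff.u_hat, a_g, atol=1e-4)

    def test_hand_case_three_animals_two_snp(self):
        """Symbolically checked: Z = [[-1,0],[0,-1],[1,1]], a_g in span(Z)."""
        dos = np.array([[0.0, 1.0], [1.0, 0.0], [2.0, 2.0]])
        mm = pd.DataFrame({"snp": ["s1", "s2"], "chrom": 1, "bp": [1, 2]})
        gs = GenotypeSet(dos, mm, np.array([1, 2, 3]))  # p = (0.5, 0.5)
        Z = gs.centered()
        u = np.array([0.5, -0.25])
        a_g = Z @ u
        lam = 1.0  # sum 2p(1-p) = 1
        G = lam * Z @ Z.T + 1e-10 * np.eye(3)
        eff = backsolve_snp_effects(a_g, gs, np.ones(2), G)
        # minimum-norm preimage of a rank-2 Z recovers u exactly
        np.testing.assert_allclose(eff.u_hat, u, atol=1e-4)

    def test_dimension_mismatch_rejected(self):
        rng = np.random.default_rng(1)
        gs = random_genotypes(rng, 10, 5)
        with pytest.raises(ValueError, match="GEBV vector"):
            backsolve_snp_effects(np.zeros(7), gs, np.ones(5), np.eye(10))


@pytest.fixture(scope="module")
def gwas_population():
    from lactgwas.kinship import qc_maf
    from lactgwas.simulate import (
        SimulationConfig, drop_genotypes, simulate_pedigree,
        simulate_single_trait, subset_genotypes,
    )
    sc = SimulationConfig(n_founders=80, n_generations=2, n_animals_target=400,
                          n_snp=300, n_chromosomes=3, n_qtl=1,
                          qtl_variance_fraction=0.3, seed=21)
    rng = sc.rng()
    ped = simulate_pedigree(sc, rng)
    geno = drop_genotypes(ped, sc, rng)
    ph, truth = simulate_single_trait(ped, geno, sc, sigma_a2=100.0,
                                      sigma_e2=150.0, rng=rng)
    gs = qc_maf(subset_genotypes(
        geno, ped[ped["generation"] > 0]["animal"].to_numpy()), 0.05)
    comp = VarianceComponents(sigma_a2=100.0, sigma_p2=0.0, sigma_e2=150.0,
                              converged=True)
    return ped, geno, gs, ph, truth, comp


class TestIterateWeights:
    def test_single_iteration_is_unweighted(self, gwas_population):
        ped, _, gs, ph, _, comp = gwas_population
        out = iterate_weights(MEAN_ONLY, ph, ped, gs, comp, n_iterations=1)
        assert len(out) == 1
        np.testing.assert_array_equal(out[0][0].weights, np.ones(gs.n_snp))

    def test_weights_normalized_each_iteration(self, gwas_population):
        ped, _, gs, ph, _, comp = gwas_population
        out = iterate_weights(MEAN_ONLY, ph, ped, gs, comp, n_iterations=3)
        for eff, _ in out:
            assert np.sum(eff.weights) == pytest.approx(gs.n_snp, rel=1e-10)
            assert np.all(eff.weights >= 0)

    def test_planted_qtl_weight_increases(self, gwas_population):
        ped, geno, gs, ph, truth, comp = gwas_population
        qtl_name = geno.marker_map.loc[truth.qtl_positions[0], "snp"]
        q = int(gs.marker_map.index[gs.marker_map["snp"] == qtl_name][0])
        out = iterate_weights(MEAN_ONLY, ph, ped, gs, comp, n_iterations=2)
        assert out[1][0].weights[q] > out[0][0].weights[q]

    def test_zero_iterations_rejected(self, gwas_population):
        ped, _, gs, ph, _, comp = gwas_population
        with pytest.raises(ValueError):
            iterate_weights(MEAN_ONLY, ph, ped, gs, comp, n_iterations=0)


class TestWindowVariance:
    def test_zero_effects_zero_windows(self):
        rng = np.random.default_rng(2)
        gs = random_genotypes(rng, 50, 120)
        eff = _effects(np.zeros(120), gs)
        scan = window_variance(eff, gs, sigma_a2=1.0)
        assert (scan.table["pct_variance"] == 0).all()

    def test_single_nonzero_effect(self):
        rng = np.random.default_rng(3)
        gs = random_genotypes(rng, 80, 120)
        u = np.zeros(120)
        u[71] = 0.8
        eff = _effects(u, gs)
        scan = window_variance(eff, gs, sigma_a2=2.0, window_size=50)
        Z = gs.centered()
        expected = 100 * 0.8 ** 2 * np.var(Z[:, 71], ddof=1) / 2.0
        tab = scan.table
        assert tab.loc[1, "pct_variance"] == pytest.approx(expected, rel=1e-10)
        assert (tab.drop(index=1)["pct_variance"] == 0).all()

    def test_matches_bruteforce_recomputation(self):
        rng = np.random.default_rng(4)
        gs = random_genotypes(rng, 60, 137)
        u = rng.normal(0, 0.1, 137)
        eff = _effects(u, gs)
        scan = window_variance(eff, gs, sigma_a2=3.0, window_size=50)
        Z = gs.centered()
        for w, row in scan.table.iterrows():
            cols = np.arange(int(row["snp_start"]), int(row["snp_stop"]) + 1)
            brute = 100 * np.var(Z[:, cols] @ u[cols], ddof=1) / 3.0
            assert row["pct_variance"] == pytest.approx(brute, rel=1e-10)

    def test_covariance_attribution_partitions_total(self):
        """The covariance decomposition sums exactly to the total genomic
        score variance even with LD between windows."""
        rng = np.random.default_rng(5)
        gs = random_genotypes(rng, 60, 200)
        # induce cross-window LD by duplicating a column far away
        gs.dosages[:, 150] = gs.dosages[:, 10]
        gs = GenotypeSet(gs.dosages, gs.marker_map, gs.animal_ids)
        u = rng.normal(0, 0.1, 200)
        eff = _effects(u, gs)
        scan = window_variance(eff, gs, sigma_a2=2.5, window_size=50)
        Z = gs.centered()
        total = 100 * np.var(Z @ u, ddof=1) / 2.5
        assert scan.table["pct_covariance"].sum() == pytest.approx(total, rel=1e-8)

    def test_windows_tile_without_overlap(self):
        rng = np.random.default_rng(6)
        gs = random_genotypes(rng, 30, 137)
        scan = window_variance(_effects(np.zeros(137), gs), gs, sigma_a2=1.0,
                               window_size=50)
        covered = []
        for _, row in scan.table.iterrows():
            covered.extend(range(int(row["snp_start"]), int(row["snp_stop"]) + 1))
        assert sorted(covered) == list(range(137))

    def test_unsorted_map_rejected(self):
        rng = np.random.default_rng(7)
        gs = random_genotypes(rng, 20, 30)
        gs.marker_map = gs.marker_map.iloc[::-1].reset_index(drop=True)
        with pytest.raises(ValueError, match="sorted"):
            window_variance(_effects(np.zeros(30), gs), gs, sigma_a2=1.0)


class TestCandidateWindows:
    def test_threshold_filtering(self):
        rng = np.random.default_rng(8)
        gs = random_genotypes(rng, 40, 100)
        u = np.zeros(100)
        u[10] = 1.0
        scan = window_variance(_effects(u, gs), gs, sigma_a2=1.0, window_size=50)
        assert len(candidate_windows(scan, threshold=1e9)) == 0
        flagged = candidate_windows(scan, threshold=0.0)
        assert (flagged["pct_variance"] > 0).all() and len(flagged) == 1


def _effects(u, gs):
    from lactgwas.ssgwas import SNPEffectSet
    p = gs.allele_freq
    return SNPEffectSet(u_hat=np.asarray(u, dtype=float),
                        weights=np.ones(gs.n_snp), iteration=1,
                        allele_freq=p, lam=1.0 / np.sum(2 * p * (1 - p)),
                        marker_map=gs.marker_map)
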