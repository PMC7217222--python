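"""Mixed-model equations and AI-REML against closed-form and GLS oracles."""

import numpy as np
import pandas as pd
import pytest

from lactgwas.kinship import a_matrix
from lactgwas.reml import (
    ModelSpec,
    aireml,
    bivariate_aireml,
    build_mme,
    heritability_from_components,
)
from lactgwas.simulate import SimulationConfig, simulate_pedigree


def _mean_only(response="y", pe=False):
    return ModelSpec(response=response, fixed_effects=(), covariates=(),
                     permanent_env=pe)


@pytest.fixture(scope="module")
def five_animal_system():
    ped = pd.DataFrame({"animal": [1, 2, 3, 4, 5],
                        "sire": [0, 0, 1, 1, 3],
                        "dam": [0, 0, 2, 2, 4]})
    A = a_matrix(ped)
    rng = np.random.default_rng(17)
    y = rng.normal(10, 2, 5)
    ph = pd.DataFrame({"animal": [1, 2, 3, 4, 5], "y": y})
    return ped, A, ph


class TestBuildMME:
    def test_solution_matches_direct_gls(self, five_animal_system):
        """BLUE/BLUP from the MME equal the direct V-inverse GLS solution."""
        ped, A, ph = five_animal_system
        sa2, se2 = 2.0, 3.0
        mme = build_mme(_mean_only(), ph, np.linalg.inv(A),
                        ped["animal"].to_numpy(), sa2, se2)
        sol = mme.solve()
        V = sa2 * A + se2 * np.eye(5)
        X = np.ones((5, 1))
        Vi = np.linalg.inv(V)
        beta = np.linalg.solve(X.T @ Vi @ X, X.T @ Vi @ ph["y"])
        u = sa2 * A @ Vi @ (ph["y"].to_numpy() - X @ beta)
        assert sol["fixed"][0] == pytest.approx(beta[0], rel=1e-8)
        np.testing.assert_allclose(sol["additive"], u, atol=1e-8)

    def test_huge_variance_ratio_approaches_ols(self, five_animal_system):
        """As the additive variance vanishes the fixed solution tends to OLS."""
        ped, A, ph = five_animal_system
        mme = build_mme(_mean_only(), ph, np.linalg.inv(A),
                        ped["animal"].to_numpy(), 1e-10, 1.0)
        sol = mme.solve()
        assert sol["fixed"][0] == pytest.approx(ph["y"].mean(), rel=1e-6)
        assert np.max(np.abs(sol["additive"])) < 1e-6

    def test_pe_block_dimension(self, five_animal_system):
        ped, A, _ = five_animal_system
        ph = pd.DataFrame({"animal": [1, 1, 2, 2, 3], "y": [1.0, 2, 3, 4, 5]})
        mme = build_mme(_mean_only(pe=True), ph, np.linalg.inv(A),
                        ped["animal"].to_numpy(), 1.0, 1.0, sigma_p2=1.0)
        pe = mme.slices["pe"]
        assert pe.stop - pe.start == 3  # animals with records

    def test_unknown_animal_rejected(self, five_animal_system):
        ped, A, _ = five_animal_system
        ph = pd.DataFrame({"animal": [1, 99], "y": [1.0, 2.0]})
        with pytest.raises(KeyError, match="99"):
            build_mme(_mean_only(), ph, np.linalg.inv(A),
                      ped["animal"].to_numpy(), 1.0, 1.0)


class TestAIREML:
    def test_balanced_oneway_matches_anova(self):
        """Unrelated animals with r repeated records: REML equals the
        closed-form intraclass ANOVA estimators on a balanced design."""
        rng = np.random.default_rng(23)
        n, r = 150, 4
        sa2, se2 = 4.0, 2.0
        a = rng.normal(0, np.sqrt(sa2), n)
        y = (a[:, None] + rng.normal(0, np.sqrt(se2), (n, r))).ravel()
        animals = np.repeat(np.arange(1, n + 1), r)
        ph = pd.DataFrame({"animal": animals, "y": y})
        # ANOVA oracle: MSB/MSW from the one-way layout
        ybar_i = ph.groupby("animal")["y"].mean().to_numpy()
        msb = r * np.sum((ybar_i - y.mean()) ** 2) / (n - 1)
        msw = np.sum((y - np.repeat(ybar_i, r)) ** 2) / (n * (r - 1))
        sa2_hat_anova = (msb - msw) / r
        vc = aireml(_mean_only(), ph, np.eye(n), np.arange(1, n + 1))
        assert vc.converged
        assert vc.sigma_e2 == pytest.approx(msw, rel=1e-4)
        assert vc.sigma_a2 == pytest.approx(sa2_hat_anova, rel=1e-3)

    def test_null_heritability_with_shuffled_pedigree(self):
        """Phenotypes carrying no additive signal give h2 near zero."""
        rng = np.random.default_rng(31)
        cfg = SimulationConfig(n_founders=100, n_generations=2,
                               n_animals_target=500, seed=3)
        ped = simulate_pedigree(cfg)
        A = a_matrix(ped[["animal", "sire", "dam"]])
        ids = ped["animal"].to_numpy()
        ph = pd.DataFrame({"animal": ids[100:], "y": rng.normal(0, 1, len(ids) - 100)})
        vc = aireml(_mean_only(), ph, np.linalg.inv(A), ids)
        assert vc.heritability < 0.05

    def test_noise_free_additive_data_gives_h2_one(self):
        """Phenotype == breeding value drives the residual to the boundary."""
        cfg = SimulationConfig(n_founders=80, n_generations=2,
                               n_animals_target=400, seed=9)
        ped = simulate_pedigree(cfg)
        A = a_matrix(ped[["animal", "sire", "dam"]])
        rng = np.random.default_rng(2)
        L = np.linalg.cholesky(A + 1e-8 * np.eye(len(A)))
        bv = 3.0 * (L @ rng.standard_normal(len(A)))
        ids = ped["animal"].to_numpy()
        ph = pd.DataFrame({"animal": ids[80:], "y": bv[80:]})
        vc = aireml(_mean_only(), ph, np.linalg.inv(A), ids)
        assert vc.heritability > 0.98

    def test_mvn_recovery_with_pedigree(self):
        """Exact multivariate-normal data on a known pedigree: averaged over
        seeds the estimate recovers the simulated h2."""
        cfg = SimulationConfig(n_founders=150, n_generations=2,
                               n_animals_target=900, seed=5)
        ped = simulate_pedigree(cfg)
        A = a_matrix(ped[["animal", "sire", "dam"]])
        L = np.linalg.cholesky(A + 1e-8 * np.eye(len(A)))
        ids = ped["animal"].to_numpy()
        A_inv = np.linalg.inv(A)
        h2s = []
        for seed in range(4):
            rng = np.random.default_rng(seed)
            a = 2.0 * (L @ rng.standard_normal(len(A)))
            y = a[150:] + rng.normal(0, np.sqrt(6.0), len(A) - 150)
            ph = pd.DataFrame({"animal": ids[150:], "y": y})
            h2s.append(aireml(_mean_only(), ph, A_inv, ids).heritability)
        assert np.mean(h2s) == pytest.approx(0.4, abs=0.06)


class TestHeritabilityFromComponents:
    # (sigma_a2, sigma_p2, sigma_e2) -> reported 2-d.p. (h2, r)
    @pytest.mark.parametrize("comps, h2, r", [
        ((526_630.0, 0.0, 892_670.0), 0.37, 0.37),
        ((685_000.0, 414_700.0, 1_498_600.0), 0.26, 0.42),
        ((14.39, 0.0, 69.86), 0.17, 0.17),
        ((0.0056, 0.0, 0.0408), 0.12, 0.12),
        ((0.0, 0.0, 5.0), 0.0, 0.0),
    ])
    def test_reference_ratios(self, comps, h2, r):
        got_h2, got_r = heritability_from_components(*comps)
        assert round(got_h2, 2) == pytest.approx(h2)
        assert round(got_r, 2) == pytest.approx(r)

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            heritability_from_components(0.0, 0.0, 0.0)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            heritability_from_components(-1.0, 0.0, 1.0)


@pytest.fixture(scope="module")
def ped_system():
    cfg = SimulationConfig(n_founders=120, n_generations=2,
                           n_animals_target=600, seed=7)
    ped = simulate_pedigree(cfg)
    A = a_matrix(ped[["animal", "sire", "dam"]])
    return ped, A, np.linalg.inv(A)


class TestBivariate:
    def _simulate_pair(self, ped, A, rg, seed, h2=0.4):
        rng = np.random.default_rng(seed)
        n = len(A)
        L = np.linalg.cholesky(A + 1e-8 * np.eye(n))
        g = L @ rng.standard_normal((n, 2))
        Gc = np.array([[1.0, rg], [rg, 1.0]])
        g = g @ np.linalg.cholesky(Gc).T * np.sqrt(h2)
        e = rng.standard_normal((n, 2)) * np.sqrt(1 - h2)
        y = g + e
        ids = ped["animal"].to_numpy()
        rec = ped["generation"] > 0
        return pd.DataFrame({"animal": ids[rec], "y1": y[rec.to_numpy(), 0],
                             "y2": y[rec.to_numpy(), 1]})

    def test_duplicate_trait_correlation_one(self, ped_system):
        ped, A, A_inv = ped_system
        ph = self._simulate_pair(ped, A, 0.5, seed=1)
        ph["y2"] = ph["y1"]
        res = bivariate_aireml((_mean_only("y1"), _mean_only("y2")), ph,
                               A_inv, ped["animal"].to_numpy())
        assert res.genetic_correlation == pytest.approx(1.0, abs=1e-3)

    @pytest.mark.parametrize("rg_true", [0.8, 0.0])
    def test_genetic_correlation_recovery(self, ped_system, rg_true):
        ped, A, A_inv = ped_system
        ests = []
        for seed in range(5):
            ph = self._simulate_pair(ped, A, rg_true, seed=10 + seed)
            res = bivariate_aireml((_mean_only("y1"), _mean_only("y2")), ph,
                                   A_inv, ped["animal"].to_numpy())
            ests.append(res.genetic_correlation)
        assert np.mean(ests) == pytest.approx(rg_true, abs=0.1)
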