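import numpy as np
import pytest
from scipy import stats as sps

from ideadna.alphabets import N_FEATURES
from ideadna.optimize import (EnergyModel, R_KCAL, compute_gap_statistics,
                              ddg_from_kd, energy_gap_ratio, fit_gamma_selex,
                              kd_from_ddg, load_model, plot_heatmap,
                              predict_energy, save_model, solve_gamma)


def _random_stats(rng, n_decoy=300, d=N_FEATURES):
    decoys = rng.normal(size=(n_decoy, d))
    strong = rng.normal(size=(3, d))
    return compute_gap_statistics(strong, decoys)


class TestGapStatistics:
    def test_strong_equals_decoys_gives_zero_gap(self, rng):
        phis = rng.normal(size=(50, N_FEATURES))
        stats = compute_gap_statistics(phis, phis)
        np.testing.assert_allclose(stats.A, 0, atol=1e-12)

    def test_identical_decoys_give_zero_covariance(self, rng):
        phi = rng.normal(size=N_FEATURES)
        stats = compute_gap_statistics(phi[None], np.tile(phi, (5, 1)))
        np.testing.assert_allclose(stats.B, 0, atol=1e-12)

    def test_covariance_matches_moment_formula(self, rng):
        decoys = rng.normal(size=(100, N_FEATURES))
        stats = compute_gap_statistics(decoys[:1], decoys)
        expected = (decoys[:, :, None] * decoys[:, None, :]).mean(0) \
            - np.outer(decoys.mean(0), decoys.mean(0))
        np.testing.assert_allclose(stats.B, expected, atol=1e-10)
        # positive semidefinite up to tolerance
        assert np.linalg.eigvalsh(stats.B).min() > -1e-10

    def test_too_few_decoys_rejected(self, rng):
        phi = rng.normal(size=(1, N_FEATURES))
        with pytest.raises(ValueError):
            compute_gap_statistics(phi, phi)


class TestSolveGamma:
    def test_identity_covariance_gives_gamma_parallel_to_A(self, rng):
        stats = _random_stats(rng)
        stats.B = np.eye(N_FEATURES)
        model = solve_gamma(stats, n_modes=N_FEATURES)
        cos = model.vector @ stats.A / np.linalg.norm(stats.A)
        assert cos == pytest.approx(1.0, abs=1e-12)

    def test_full_rank_matches_dense_solve(self, rng):
        stats = _random_stats(rng, n_decoy=500)
        model = solve_gamma(stats, n_modes=N_FEATURES)
        dense = np.linalg.solve(stats.B, stats.A)
        dense /= np.linalg.norm(dense)
        assert abs(model.vector @ dense) >= 0.999

    def test_unit_norm_and_positive_gap(self, trained16):
        model, stats = trained16
        assert np.linalg.norm(model.vector) == pytest.approx(1.0)
        assert stats.A @ model.vector > 0

    def test_excess_modes_rejected(self, rng):
        decoys = rng.normal(size=(10, N_FEATURES))  # rank <= 9
        stats = compute_gap_statistics(decoys[:1], decoys)
        with pytest.raises(ValueError, match="insufficient decoy diversity"):
            solve_gamma(stats, n_modes=40)
        # adaptive default clips to the rank instead
        model = solve_gamma(stats)
        assert model.n_modes <= 9

    def test_recovery_improves_with_decoy_count(self):
        """Planted-matrix cosine rises with decoy count (20-seed average)."""
        from ideadna import synthfix
        means = []
        for n_dna in (50, 200, 1000):
            cs = []
            for seed in range(20):
                sc = synthfix.planted_scenario(100 + seed, n_protein=16,
                                               n_dna=8, n_contacts=20,
                                               n_strong_dna=100,
                                               n_strong_protein=1000)
                model, _ = synthfix.train_planted(sc, n_dna_decoys=n_dna,
                                                  n_protein_decoys=10 * n_dna,
                                                  seed=seed)
                cs.append(float(model.vector @ sc.gamma_star.ravel()))
            means.append(np.mean(cs))
        assert means[0] < means[1] < means[2]

    def test_objective_beats_random_directions(self, trained16, rng):
        model, stats = trained16
        best = energy_gap_ratio(model.vector, stats)
        for _ in range(200):
            g = rng.normal(size=N_FEATURES)
            g /= np.linalg.norm(g)
            assert energy_gap_ratio(g, stats) <= best + 1e-9


class TestPredictEnergy:
    def test_zero_phi_gives_zero(self, rng):
        model = EnergyModel(gamma=rng.normal(size=(20, 4)))
        assert predict_energy(model, np.zeros((20, 4))) == 0.0

    def test_linear_in_gamma_scale(self, rng):
        g = rng.normal(size=(20, 4))
        phi = rng.uniform(size=(20, 4))
        e1 = predict_energy(EnergyModel(gamma=g), phi)
        e3 = predict_energy(EnergyModel(gamma=3 * g), phi)
        assert e3 == pytest.approx(3 * e1)

    def test_matches_elementwise_sum_oracle(self, rng):
        g = rng.normal(size=(20, 4))
        phi = rng.uniform(size=(20, 4))
        expected = sum(g[i, j] * phi[i, j] for i in range(20) for j in range(4))
        assert predict_energy(EnergyModel(gamma=g), phi) == pytest.approx(expected)

    def test_ranking_invariant_under_positive_scaling(self, rng):
        g = rng.normal(size=(20, 4))
        phis = rng.uniform(size=(30, 20, 4))
        e1 = [predict_energy(EnergyModel(gamma=g), p) for p in phis]
        e2 = [predict_energy(EnergyModel(gamma=7.3 * g), p) for p in phis]
        assert sps.spearmanr(e1, e2).statistic == pytest.approx(1.0)

    def test_shape_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            predict_energy(EnergyModel(gamma=rng.normal(size=(20, 4))),
                           np.zeros(10))


class TestDdgFromKd:
    def test_unit_ratio_is_zero(self):
        assert ddg_from_kd(1.0) == 0.0

    def test_e_fold_ratio_equals_rt(self):
        assert ddg_from_kd(np.e) == pytest.approx(R_KCAL * 298.15)
        assert R_KCAL * 298.15 == pytest.approx(0.5925, abs=2e-4)

    def test_log_antisymmetry(self):
        assert ddg_from_kd(3.7) == pytest.approx(-ddg_from_kd(1 / 3.7))

    def test_inverse_round_trip(self):
        assert kd_from_ddg(ddg_from_kd(2.5)) == pytest.approx(2.5)

    def test_nonpositive_ratio_rejected(self):
        with pytest.raises(ValueError):
            ddg_from_kd(0.0)


class TestSelexRidge:
    def test_exact_recovery_noiseless(self, rng):
        gamma_star = rng.normal(size=N_FEATURES)
        phi = rng.normal(size=(200, N_FEATURES))
        model = fit_gamma_selex(phi, phi @ gamma_star, alpha=1e-10)
        err = np.linalg.norm(model.vector - gamma_star) / np.linalg.norm(gamma_star)
        assert err <= 1e-6

    def test_matches_closed_form_oracle(self, rng):
        phi = rng.normal(size=(50, N_FEATURES))
        y = rng.normal(size=50)
        model = fit_gamma_selex(phi, y, alpha=0.01)
        oracle = np.linalg.solve(phi.T @ phi + 0.01 * np.eye(N_FEATURES),
                                 phi.T @ y)
        np.testing.assert_allclose(model.vector, oracle, atol=1e-10)

    def test_shrinkage_monotone_in_alpha(self, rng):
        phi = rng.normal(size=(60, N_FEATURES))
        y = rng.normal(size=60)
        norms = [np.linalg.norm(fit_gamma_selex(phi, y, alpha=a).vector)
                 for a in (1e-3, 1e-1, 10, 1e3, 1e6)]
        assert all(a > b for a, b in zip(norms, norms[1:]))
        assert norms[-1] < 1e-2

    def test_all_zero_features_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            fit_gamma_selex(np.zeros((5, N_FEATURES)), np.ones(5))

    def test_provenance_tag(self, rng):
        phi = rng.normal(size=(10, N_FEATURES))
        model = fit_gamma_selex(phi, rng.normal(size=10))
        assert model.provenance == "selex-ridge"


class TestSerialization:
    def test_tsv_json_round_trip(self, trained16, tmp_path):
        model, _ = trained16
        tsv, js = tmp_path / "g.tsv", tmp_path / "g.json"
        save_model(model, tsv, js)
        back = load_model(tsv, js)
        np.testing.assert_allclose(back.gamma, model.gamma, atol=1e-10)
        assert back.n_modes == model.n_modes
        assert back.provenance == model.provenance

    def test_heatmap_renders(self, trained16, tmp_path):
        model, _ = trained16
        out = tmp_path / "gamma.png"
        plot_heatmap(model, out)
        assert out.stat().st_size > 0
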