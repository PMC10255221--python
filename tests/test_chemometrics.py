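"""PCA retention, SOM/HCA, peak deconvolution, freshness indices, HQI."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from fishspec import (
    CalibrationCurve,
    CatabolitesProfile,
    catabolite_indices,
    euclidean_distance,
    fit_two_peak_model,
    hca_classes,
    hqi,
    pca_fit,
    predict_day_from_feature,
    select_pc_count,
    simulate_catabolites,
    simulate_spectrum,
    som_fit,
)
from fishspec.synthetic_data import fluorescence_archetypes


class TestPca:
    def test_pct_variation_sums_to_one(self, rng):
        r = pca_fit(rng.normal(size=(20, 10)))
        assert r.pct_variation.sum() == pytest.approx(1.0)

    def test_line_cloud_concentrates_on_pc1(self, rng):
        t = rng.normal(size=100)
        X = np.column_stack([t, 2 * t]) + rng.normal(0, 1e-3, (100, 2))
        r = pca_fit(X, pretreat=False)
        assert r.pct_variation[0] >= 0.99

    def test_eigenvalues_match_direct_eigensolver(self, rng):
        X = rng.normal(size=(5, 4))
        r = pca_fit(X, pretreat=False)
        direct = np.sort(np.linalg.eigvalsh(np.cov(X.T)))[::-1]
        np.testing.assert_allclose(r.eigenvalues, np.clip(direct, 0, None),
                                   atol=1e-10)

    def test_loadings_orthonormal(self, rng):
        r = pca_fit(rng.normal(size=(30, 8)))
        np.testing.assert_allclose(r.loadings.T @ r.loadings, np.eye(8),
                                   atol=1e-8)

    def test_too_many_components_errors(self, rng):
        with pytest.raises(ValueError):
            pca_fit(rng.normal(size=(3, 10)), n_components=8)


class TestPcRetention:
    def test_eigenvalue_gt1_counts(self):
        assert select_pc_count([3.2, 1.4, 1.1, 0.6, 0.2]) == 3

    def test_eigenvalue_gt1_zero_with_warning(self):
        with pytest.warns(UserWarning):
            assert select_pc_count([0.9, 0.5]) == 0

    def test_scree_matches_bruteforce_second_difference(self):
        lam = np.array([10.0, 5.0, 1.0, 0.9, 0.8])
        # exhaustive scan oracle over interior eigenvalues
        second = [lam[i - 1] - 2 * lam[i] + lam[i + 1]
                  for i in range(1, len(lam) - 1)]
        oracle = int(np.argmax(second)) + 2
        got = select_pc_count(lam, rule="scree")
        assert got == oracle and got <= 3

    def test_empty_list_errors(self):
        with pytest.raises(ValueError):
            select_pc_count([])


class TestSom:
    def test_distance_identity_and_pythagoras(self):
        assert euclidean_distance([1.0, 2.0], [1.0, 2.0]) == 0.0
        assert euclidean_distance([0.0, 0.0], [3.0, 4.0]) == 5.0

    def test_assignments_are_nearest_codebook(self, rng):
        X = rng.normal(size=(40, 6))
        som = som_fit(X, 3, 3, epochs=5, seed=0)
        d = ((X[:, None, :] - som.codebook[None]) ** 2).sum(axis=2)
        np.testing.assert_array_equal(som.assignments, d.argmin(axis=1))

    def test_deterministic_per_seed(self, rng):
        X = rng.normal(size=(30, 5))
        a = som_fit(X, 3, 3, epochs=5, seed=4)
        b = som_fit(X, 3, 3, epochs=5, seed=4)
        np.testing.assert_array_equal(a.codebook, b.codebook)

    def test_distance_matrix_properties(self, rng):
        X = rng.normal(size=(30, 5))
        som = som_fit(X, 3, 3, epochs=5, seed=0)
        D = som.inter_node_distance
        assert np.allclose(D, D.T) and np.all(np.diag(D) == 0) and np.all(D >= 0)

    def test_separated_clusters_occupy_disjoint_nodes(self, rng):
        a = rng.normal(0, 0.05, size=(25, 8))
        b = rng.normal(5, 0.05, size=(25, 8))
        som = som_fit(np.vstack([a, b]), 3, 3, epochs=10, seed=1)
        assert not set(som.assignments[:25]) & set(som.assignments[25:])

    def test_more_nodes_than_spectra_warns(self, rng):
        with pytest.warns(UserWarning):
            som_fit(rng.normal(size=(5, 4)), 3, 3, epochs=2, seed=0)


class TestHca:
    def test_singletons_when_k_equals_nodes(self, rng):
        codebook = rng.normal(size=(6, 4))
        assert len(set(hca_classes(codebook, k=6))) == 6

    def test_single_class(self, rng):
        assert set(hca_classes(rng.normal(size=(6, 4)), k=1)) == {0}

    def test_recovers_planted_archetypes(self, rng):
        spectra, _ = fluorescence_archetypes()
        X = np.repeat(spectra, 10, axis=0)
        X = X + rng.normal(0, 0.01, X.shape)
        som = som_fit(X, 4, 4, epochs=10, seed=0)
        classes = hca_classes(som.codebook, k=4)
        labels = classes[som.assignments]
        per_archetype = [set(labels[i * 10:(i + 1) * 10]) for i in range(4)]
        assert all(len(s) == 1 for s in per_archetype)
        assert len(set.union(*per_archetype)) == 4

    def test_invalid_k(self, rng):
        with pytest.raises(ValueError):
            hca_classes(rng.normal(size=(6, 4)), k=0)


class TestTwoPeakFit:
    def test_noise_free_recovery_of_known_centers(self, fl_wavelengths):
        wl = fl_wavelengths
        y = (np.exp(-0.5 * ((wl - 452) / 25) ** 2)
             + 0.8 * np.exp(-0.5 * ((wl - 512) / 45) ** 2))
        fit = fit_two_peak_model(y, wl)
        assert fit.p1_center == pytest.approx(452.0, abs=0.5)
        assert fit.p2_center == pytest.approx(512.0, abs=0.5)
        assert fit.delta_lambda == pytest.approx(60.0, abs=1.0)

    def test_single_gaussian_triggers_inflexion_fallback(self, fl_wavelengths):
        wl = fl_wavelengths
        y = np.exp(-0.5 * ((wl - 520) / 40) ** 2)
        fit = fit_two_peak_model(y, wl)
        assert not fit.p2_resolved
        assert fit.p1_center == pytest.approx(520.0, abs=1.0)
        # red-flank inflexion of a Gaussian sits near center + sigma
        assert fit.p2_center == pytest.approx(560.0, abs=10.0)
        assert fit.delta_lambda_error > 0

    def test_p1_stays_within_three_nm_on_default_data(self, aging_model,
                                                      fl_wavelengths):
        for day in (1, 3, 5, 7, 9, 11):
            y = simulate_spectrum("FL", day, "head_top", aging_model)
            fit = fit_two_peak_model(y, fl_wavelengths)
            assert abs(fit.p1_center - 452.6) <= 3.0

    def test_monotone_trends_recovered_noise_free(self, aging_model,
                                                  fl_wavelengths):
        fits = [
            fit_two_peak_model(
                simulate_spectrum("FL", d, "tail_bottom", aging_model),
                fl_wavelengths,
            )
            for d in (1, 3, 5, 7, 9)
        ]
        dl = [f.delta_lambda for f in fits]
        ratio = [f.ratio for f in fits]
        assert np.all(np.diff(dl) < 0)
        assert np.all(np.diff(ratio) > 0)

    def test_scale_invariance(self, fl_wavelengths):
        wl = fl_wavelengths
        y = (np.exp(-0.5 * ((wl - 452) / 25) ** 2)
             + 0.8 * np.exp(-0.5 * ((wl - 512) / 45) ** 2))
        a = fit_two_peak_model(y, wl)
        b = fit_two_peak_model(2000 * y, wl)
        assert a.delta_lambda == pytest.approx(b.delta_lambda, abs=0.05)
        assert a.ratio == pytest.approx(b.ratio, rel=1e-3)

    def test_length_mismatch_errors(self, fl_wavelengths):
        with pytest.raises(ValueError):
            fit_two_peak_model(np.ones(10), fl_wavelengths)


class TestCatabolitesIndices:
    def test_fresh_endpoint(self):
        assert catabolite_indices(CatabolitesProfile(1, 0, 0)) == (0.0, 0.0)

    def test_degraded_endpoint(self):
        assert catabolite_indices(CatabolitesProfile(0, 0, 1)) == (1.0, 1.0)

    def test_formula_arithmetic(self):
        k, h = catabolite_indices(CatabolitesProfile(20, 60, 20))
        assert k == pytest.approx(0.8)
        assert h == pytest.approx(0.2)

    def test_monotone_along_kinetics(self):
        days = np.linspace(0, 14, 29)
        ks, hs = zip(*(catabolite_indices(simulate_catabolites(d, 0.35, 0.2))
                       for d in days))
        assert np.all(np.diff(ks) >= 0)
        assert np.all(np.diff(hs) >= 0)

    def test_all_zero_errors(self):
        with pytest.raises(ValueError):
            catabolite_indices(CatabolitesProfile(0, 0, 0))


class TestHqi:
    def test_identity_and_simple_pair(self):
        assert hqi([1.0, 2.0], [1.0, 2.0]) == 0.0
        assert hqi([0.0, 0.0], [1.0, -1.0]) == 2.0

    @given(st.integers(0, 2**31 - 1))
    def test_matches_loop_oracle(self, seed):
        rng = np.random.default_rng(seed)
        x, y = rng.normal(size=(2, 60))
        assert hqi(x, y) == pytest.approx(
            sum(abs(a - b) for a, b in zip(x, y))
        )

    def test_symmetry_and_nonnegativity(self, rng):
        x, y = rng.normal(size=(2, 30))
        assert hqi(x, y) == hqi(y, x) >= 0

    def test_length_mismatch_errors(self):
        with pytest.raises(ValueError):
            hqi([1.0], [1.0, 2.0])


class TestDayPrediction:
    curve = CalibrationCurve("delta_lambda", days=[1, 3, 5, 7, 9, 11],
                             values=[60.0, 56.0, 52.0, 48.0, 44.0, 40.0])

    def test_exact_match(self):
        assert predict_day_from_feature(56.0, self.curve) == 3

    def test_clamps_to_endpoints(self):
        assert predict_day_from_feature(75.0, self.curve) == 1
        assert predict_day_from_feature(10.0, self.curve) == 11

    def test_tie_goes_to_earlier_day(self):
        assert predict_day_from_feature(58.0, self.curve) == 1

    def test_empty_curve_errors(self):
        with pytest.raises(ValueError):
            CalibrationCurve("ratio", days=[], values=[])
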