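"""Two-population mixture: densities, the paradox, CDF fitting, KS, Hi-C comparison."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.integrate import quad

from grmc.mixture import (
    FISHDataset,
    MixtureModel,
    compare_to_hic,
    empirical_cdf,
    find_paradox_pairs,
    fit_mixture,
    ks_statistic,
    mixture_cdf,
    mixture_contact_prob,
    mixture_mean,
    mixture_pdf,
    paradox_heatmaps,
    relative_contact_frequencies,
)
from grmc.synth import GeneratorConfig, sample_distances

# the two illustrative loci pairs: (eta, sigma1, sigma2) in um
PAIR1 = MixtureModel.from_sigmas(0.4, 0.3, 0.8)
PAIR2 = MixtureModel.from_sigmas(0.4, 0.4, 0.5)


class TestMixtureDistribution:
    def test_eta_one_is_single_population(self):
        m = MixtureModel(eta=1.0, R1=0.5, R2=2.0)
        single = MixtureModel(eta=1.0, R1=0.5, R2=0.5)
        r = np.linspace(0.01, 3, 50)
        assert np.allclose(mixture_pdf(r, m), mixture_pdf(r, single))

    def test_equal_components_collapse(self):
        m = MixtureModel(eta=0.5, R1=0.8, R2=0.8)
        one = MixtureModel(eta=1.0, R1=0.8, R2=0.8)
        r = np.linspace(0.01, 3, 50)
        assert np.allclose(mixture_cdf(r, m), mixture_cdf(r, one))

    def test_mixture_mean_identity(self):
        # eta*R1 + (1-eta)*R2, checked against quadrature of the mixture pdf
        numeric, _ = quad(lambda r: r * mixture_pdf(r, PAIR1), 0, np.inf)
        expected = 2 * np.sqrt(2 / np.pi) * (0.4 * 0.3 + 0.6 * 0.8)
        assert mixture_mean(PAIR1) == pytest.approx(expected, abs=1e-9)
        assert numeric == pytest.approx(expected, abs=1e-9)
        assert expected == pytest.approx(0.957, abs=1e-3)

    def test_contact_prob_convex_combination(self):
        numeric, _ = quad(lambda r: mixture_pdf(r, PAIR1), 0, 0.02)
        assert mixture_contact_prob(PAIR1, 0.02) == pytest.approx(numeric, abs=1e-12)

    def test_contact_prob_vanishing_threshold(self):
        assert mixture_contact_prob(PAIR1, 1e-9) == pytest.approx(0.0, abs=1e-12)

    @given(
        eta=st.floats(0.0, 1.0),
        R1=st.floats(0.05, 2.0),
        R2=st.floats(0.05, 5.0),
    )
    def test_cdf_is_proper(self, eta, R1, R2):
        m = MixtureModel(eta=eta, R1=R1, R2=R2)
        r = np.linspace(0, 50, 400)
        F = mixture_cdf(r, m)
        assert np.all(np.diff(F) >= -1e-12)
        assert F[0] == pytest.approx(0.0, abs=1e-12)
        assert F[-1] == pytest.approx(1.0, abs=1e-6)

    def test_relabeling_symmetry(self):
        m = MixtureModel(eta=0.3, R1=1.2, R2=0.4)
        c = m.canonicalized()
        r = np.linspace(0.01, 4, 100)
        assert c.R1 <= c.R2
        assert np.allclose(mixture_cdf(r, m), mixture_cdf(r, c))


class TestParadox:
    def test_fig2_parameters_exhibit_paradox(self):
        # pair 1 has both the larger mean distance and the larger contact
        # probability at r_c = 20 nm — the FISH–Hi-C paradox
        r_c = 0.02
        assert mixture_mean(PAIR1) > mixture_mean(PAIR2)
        assert mixture_contact_prob(PAIR1, r_c) > mixture_contact_prob(PAIR2, r_c)
        assert mixture_contact_prob(PAIR1, r_c) == pytest.approx(3.40e-5, rel=2e-2)
        assert mixture_contact_prob(PAIR2, r_c) == pytest.approx(2.35e-5, rel=2e-2)

    def test_homogeneous_maps_depend_on_R2_alone(self):
        R1g = np.linspace(1.0, 10.0, 6)
        R2g = np.linspace(2.0, 20.0, 7)
        R_mat, P_mat = paradox_heatmaps(0.0, R1g, R2g, r_c=2.0)
        assert np.allclose(R_mat, R_mat[0, :][None, :])
        assert np.allclose(P_mat, P_mat[0, :][None, :])

    def test_homogeneous_sorting_is_one_to_one(self):
        R2g = np.linspace(2.0, 30.0, 15)
        R_mat, P_mat = paradox_heatmaps(0.0, np.array([5.0]), R2g, r_c=2.0)
        order_P = np.argsort(P_mat[0])
        order_R = np.argsort(R_mat[0])[::-1]
        assert np.array_equal(order_P, order_R)

    def test_heterogeneous_grid_contains_paradox_cells(self):
        grid = np.linspace(10.0, 100.0, 12)
        R_mat, P_mat = paradox_heatmaps(0.3, grid, grid, r_c=2.0)
        assert len(find_paradox_pairs(R_mat, P_mat, limit=1)) >= 1

    def test_homogeneous_grid_has_no_paradox_cells(self):
        R2g = np.linspace(5.0, 60.0, 10)
        R_mat, P_mat = paradox_heatmaps(0.0, np.array([5.0]), R2g, r_c=2.0)
        assert find_paradox_pairs(R_mat, P_mat) == []


class TestFitting:
    def test_exact_cdf_curve_recovered(self):
        # empirical CDF equal to the model CDF on a dense grid -> near-zero objective
        truth = MixtureModel(eta=0.42, R1=0.30, R2=1.21, family="rdc")
        r = np.linspace(0.005, 6.0, 400)
        ds = FISHDataset(pair_id="exact", cdf_r=r, cdf_values=mixture_cdf(r, truth))
        res = fit_mixture(ds, family="rdc")
        assert res.objective < 1e-8
        assert res.model.eta == pytest.approx(0.42, abs=0.01)
        assert res.model.R1 == pytest.approx(0.30, rel=0.02)
        assert res.model.R2 == pytest.approx(1.21, rel=0.02)

    def test_single_population_data_fits_degenerate_mixture(self):
        truth = MixtureModel(eta=1.0, R1=0.5, R2=0.5, family="rdc")
        ds = sample_distances(GeneratorConfig(model=truth, n_cells=2000, seed=7))
        res = fit_mixture(ds, family="rdc")
        m = res.model
        assert m.eta >= 0.95 or m.R1 == pytest.approx(m.R2, rel=0.1) or m.eta <= 0.05

    def test_parameter_recovery_from_samples(self):
        truth = MixtureModel(eta=0.42, R1=0.30, R2=1.21, family="rdc")
        ds = sample_distances(GeneratorConfig(model=truth, n_cells=2000, seed=11))
        m = fit_mixture(ds, family="rdc").model
        assert m.eta == pytest.approx(0.42, abs=0.1)
        assert m.R1 == pytest.approx(0.30, rel=0.15)
        assert m.R2 == pytest.approx(1.21, rel=0.15)

    def test_degenerate_data_flagged(self):
        ds = FISHDataset(pair_id="const", distances=np.full(100, 0.4))
        res = fit_mixture(ds)
        assert res.degenerate
        assert res.model.R1 == pytest.approx(0.4)

    def test_fit_output_canonicalized(self):
        truth = MixtureModel(eta=0.42, R1=0.30, R2=1.21, family="rdc")
        ds = sample_distances(GeneratorConfig(model=truth, n_cells=1000, seed=3))
        m = fit_mixture(ds, family="rdc").model
        assert m.R1 <= m.R2


class TestKSStatistic:
    def test_zero_for_own_cdf_curve(self):
        m = MixtureModel(eta=0.5, R1=0.4, R2=1.0)
        r = np.linspace(0.01, 5, 200)
        ds = FISHDataset(pair_id="x", cdf_r=r, cdf_values=mixture_cdf(r, m))
        assert ks_statistic(m, ds) == pytest.approx(0.0, abs=1e-12)

    def test_constant_probability_shift(self):
        m = MixtureModel(eta=0.5, R1=0.4, R2=1.0)
        r = np.linspace(0.05, 5, 200)
        shifted = np.clip(mixture_cdf(r, m) - 0.07, 0.0, 1.0)
        shifted = np.maximum.accumulate(shifted)
        ds = FISHDataset(pair_id="x", cdf_r=r, cdf_values=shifted)
        assert ks_statistic(m, ds) == pytest.approx(0.07, abs=1e-6)

    def test_small_against_own_sample(self):
        ds = sample_distances(GeneratorConfig(model=PAIR1, n_cells=5000, seed=5))
        assert ks_statistic(PAIR1, ds) < 0.05


class TestHiCComparison:
    def test_equal_probs_give_unit_relative_frequency(self):
        assert np.allclose(relative_contact_frequencies([0.2, 0.2, 0.2]), 1.0)

    def test_relative_frequencies_average_to_one(self, rng):
        v = rng.uniform(0.1, 5.0, size=9)
        assert relative_contact_frequencies(v).mean() == pytest.approx(1.0)

    def test_perfect_scaling_gives_unit_correlation(self):
        p = np.array([1.0, 2.0, 4.0, 8.0])
        assert compare_to_hic(p, 100 * p) == pytest.approx(1.0)

    def test_empirical_cdf_convention(self):
        r, F = empirical_cdf([0.3, 0.1, 0.2])
        assert np.array_equal(r, [0.1, 0.2, 0.3])
        assert np.allclose(F, [1 / 3, 2 / 3, 1.0])
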