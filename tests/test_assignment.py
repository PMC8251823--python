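import numpy as np
import pytest
from scipy import integrate, stats

from isoassign.assignment import (GAMMA1, GAMMA2, GAMMA3, SIGMA_DEFAULT,
                                  KernelPrior, kernel_log_weight, kernel_weight,
                                  marker_likelihood, marker_log_likelihood,
                                  posterior_surface, validate_sigma)
from isoassign.basemaps import distance_matrix


class TestMarkerLikelihood:
    def test_identity_sigma_at_mean(self):
        val = marker_likelihood([0.0, 0.0], [0.0, 0.0], np.eye(2))
        assert val == pytest.approx(1.0 / (2.0 * np.pi), rel=1e-12)

    def test_diagonal_study_variances_at_mean(self):
        sigma = np.diag([47.88, 9.20])
        expected = 1.0 / (2.0 * np.pi * np.sqrt(47.88 * 9.20))  # det 440.496
        val = marker_likelihood([-60.0, 104.0], [-60.0, 104.0], sigma)
        assert val == pytest.approx(expected, rel=1e-12)
        assert val == pytest.approx(0.0075831, rel=1e-4)

    def test_matches_scipy_multivariate_normal(self):
        """Dual-route check of the hand-written log-space density against
        scipy's multivariate normal on the study covariance."""
        rng = np.random.default_rng(42)
        mu = rng.normal(size=(40, 2)) * [10.0, 3.0] + [-60.0, 104.0]
        y = np.array([-55.0, 103.2])
        mine = marker_log_likelihood(y, mu, SIGMA_DEFAULT)
        ref = stats.multivariate_normal(mean=y, cov=SIGMA_DEFAULT).logpdf(mu)
        np.testing.assert_allclose(mine, ref, rtol=1e-10)

    def test_integrates_to_one(self):
        """Quadrature oracle: the density with the study Sigma integrates
        to 1 over the marker plane."""
        pdf = lambda w, i: marker_likelihood(  # noqa: E731
            [i, w], [-60.0, 104.0], SIGMA_DEFAULT)
        total, _ = integrate.dblquad(pdf, -60.0 - 40, -60.0 + 40,
                                     104.0 - 20, 104.0 + 20, epsabs=1e-10)
        assert total == pytest.approx(1.0, abs=1e-6)

    @pytest.mark.parametrize("bad", [
        np.array([[1.0, 2.0], [2.0, 1.0]]),       # not positive definite
        np.array([[1.0, 0.0], [0.5, 1.0]]),       # asymmetric
        np.zeros((2, 2)),                          # singular
    ])
    def test_rejects_invalid_sigma(self, bad):
        with pytest.raises(ValueError):
            validate_sigma(bad)

    def test_singular_sigma_message_has_diagnostic(self):
        with pytest.raises(ValueError, match="condition number"):
            validate_sigma(np.array([[1.0, 1.0], [1.0, 1.0]]))


class TestKernelWeight:
    def test_exponential_limit_at_zero(self):
        assert kernel_weight(0.0, KernelPrior(1.0, 10.0)) == pytest.approx(0.1)

    def test_direct_pdf_value(self):
        # shape 2, scale 10 at d=10: (2/10)*1*e^-1
        assert kernel_weight(10.0, KernelPrior(2.0, 10.0)) == pytest.approx(
            0.2 * np.exp(-1.0), rel=1e-12)

    @pytest.mark.parametrize("prior", [GAMMA1, GAMMA2, GAMMA3,
                                       KernelPrior(2.0, 50.0)])
    def test_half_mass_below_median(self, prior):
        """Numerical integration: cumulative mass below scale*(ln2)^(1/shape)
        is exactly one half for every parameterisation."""
        med = prior.scale * np.log(2.0) ** (1.0 / prior.shape)
        mass, _ = integrate.quad(lambda d: kernel_weight(d, prior), 0, med,
                                 points=[med / 2], limit=200)
        assert mass == pytest.approx(0.5, abs=1e-7)

    def test_matches_scipy_weibull(self):
        d = np.linspace(0.5, 400, 50)
        for prior in (GAMMA1, GAMMA3):
            ref = stats.weibull_min.pdf(d, prior.shape, scale=prior.scale)
            np.testing.assert_allclose(kernel_weight(d, prior), ref, rtol=1e-10)

    def test_floor_caps_divergence(self):
        # shape < 1 diverges at 0; the floor evaluates at d_floor instead
        v = kernel_weight(0.0, GAMMA1, d_floor_km=15.0)
        assert v == pytest.approx(kernel_weight(15.0, GAMMA1), rel=1e-12)
        assert np.isfinite(v)

    def test_rejects_negative_distance(self):
        with pytest.raises(ValueError, match="non-negative"):
            kernel_weight(-1.0, GAMMA1)


def brute_force_posterior(y, basemap, prior, distances, sigma, d_floor,
                          scale_lik=1.0, scale_kern=1.0, scale_ab=1.0):
    """Independent linear-space evaluation of the assignment posterior using
    scipy densities term by term."""
    lik = stats.multivariate_normal(mean=np.asarray(y), cov=sigma).pdf(basemap.mu)
    kern = stats.weibull_min.pdf(np.maximum(distances, d_floor), prior.shape,
                                 scale=prior.scale)
    unnorm = (scale_lik * lik) * (scale_kern * kern) * (scale_ab * basemap.abundance)
    return unnorm / unnorm.sum()


class TestPosteriorSurface:
    def test_symmetry_two_identical_cells(self):
        """Two cells with identical markers, abundance and distance split the
        posterior evenly."""
        import pandas as pd

        from isoassign.basemaps import Basemap, StudyPlots
        bm = Basemap.from_layers(
            lon=[-86.3, -85.7], lat=[37.0, 37.0],
            expected_isotope=[-60.0, -60.0], expected_wing=[104.0, 104.0],
            abundance=[1.0, 1.0])
        plots = StudyPlots(table=pd.DataFrame(
            {"plot_id": [1], "lon": [-86.0], "lat": [37.0]}))
        d = distance_matrix(plots, bm)[0]
        pi = posterior_surface([-58.0, 103.0], bm, GAMMA1, d)
        np.testing.assert_allclose(pi, [0.5, 0.5], atol=1e-12)

    def test_prior_only_limit_recovers_abundance(self, toy_basemap):
        """Flat likelihood (identical expected markers) and flat kernel
        (equidistant cells via a common floor) leave only the abundance."""
        bm = toy_basemap
        flat_mu = bm.cells.copy()
        flat_mu["expected_isotope"] = -60.0
        flat_mu["expected_wing"] = 104.0
        from isoassign.basemaps import Basemap
        bm_flat = Basemap(cells=flat_mu, cell_size_km=bm.cell_size_km)
        d = np.linspace(0, 120, bm.n_cells)
        # floor above the largest distance => kernel constant across cells
        pi = posterior_surface([-61.0, 103.0], bm_flat, GAMMA1, d,
                               d_floor_km=500.0)
        np.testing.assert_allclose(pi, bm.abundance, rtol=1e-10)

    def test_matches_brute_force_oracle(self, toy_basemap, toy_plots):
        d = distance_matrix(toy_plots, toy_basemap)[0]
        y = [-57.0, 103.4]
        pi = posterior_surface(y, toy_basemap, GAMMA2, d)
        ref = brute_force_posterior(y, toy_basemap, GAMMA2, d, SIGMA_DEFAULT,
                                    toy_basemap.cell_size_km / 2.0)
        np.testing.assert_allclose(pi, ref, rtol=1e-12)
        assert pi.sum() == pytest.approx(1.0, abs=1e-12)

    def test_invariant_to_factor_rescaling(self, toy_basemap, toy_plots):
        """Multiplying likelihood, kernel and abundance by arbitrary positive
        constants leaves the normalised posterior unchanged."""
        d = distance_matrix(toy_plots, toy_basemap)[0]
        y = [-57.0, 103.4]
        base = brute_force_posterior(y, toy_basemap, GAMMA1, d, SIGMA_DEFAULT, 15.0)
        scaled = brute_force_posterior(y, toy_basemap, GAMMA1, d, SIGMA_DEFAULT,
                                       15.0, scale_lik=1e7, scale_kern=3.2,
                                       scale_ab=0.004)
        np.testing.assert_allclose(base, scaled, rtol=1e-12)
        np.testing.assert_allclose(
            posterior_surface(y, toy_basemap, GAMMA1, d), base, rtol=1e-12)

    def test_monotone_in_abundance(self, toy_basemap, toy_plots):
        """Raising one cell's abundance (then renormalising) strictly raises
        its posterior probability."""
        from isoassign.basemaps import Basemap, normalize_abundance
        d = distance_matrix(toy_plots, toy_basemap)[0]
        y = [-57.0, 103.4]
        pi0 = posterior_surface(y, toy_basemap, GAMMA1, d)
        cells = toy_basemap.cells.copy()
        raw = cells["rel_abundance"].to_numpy().copy()
        raw[3] *= 2.5
        cells["rel_abundance"] = normalize_abundance(raw)
        bm2 = Basemap(cells=cells, cell_size_km=30.0)
        pi1 = posterior_surface(y, bm2, GAMMA1, d)
        assert pi1[3] > pi0[3]

    def test_wide_kernel_converges_to_no_kernel_posterior(self, toy_basemap,
                                                          toy_plots):
        """With shape 1 and scale -> infinity the kernel flattens, so the
        posterior converges to likelihood x abundance alone."""
        d = distance_matrix(toy_plots, toy_basemap)[0]
        y = [-57.0, 103.4]
        pi = posterior_surface(y, toy_basemap, KernelPrior(1.0, 1e6), d)
        lik = stats.multivariate_normal(mean=np.asarray(y),
                                        cov=SIGMA_DEFAULT).pdf(toy_basemap.mu)
        ref = lik * toy_basemap.abundance
        ref = ref / ref.sum()
        np.testing.assert_allclose(pi, ref, rtol=1e-4)

    def test_log_space_matches_naive_linear(self, toy_basemap, toy_plots):
        d = distance_matrix(toy_plots, toy_basemap)[0]
        y = [-59.0, 104.2]
        pi = posterior_surface(y, toy_basemap, GAMMA1, d)
        lik = np.array([marker_likelihood(y, m, SIGMA_DEFAULT)
                        for m in toy_basemap.mu])
        kern = kernel_weight(d, GAMMA1, d_floor_km=15.0)
        naive = lik * kern * toy_basemap.abundance
        naive = naive / naive.sum()
        np.testing.assert_allclose(pi, naive, rtol=1e-10)

    def test_misaligned_distances_rejected(self, toy_basemap):
        with pytest.raises(ValueError, match="aligned"):
            posterior_surface([-60.0, 104.0], toy_basemap, GAMMA1,
                              np.zeros(3))

    def test_underflow_everywhere_rejected(self, toy_basemap, toy_plots):
        d = distance_matrix(toy_plots, toy_basemap)[0]
        with pytest.raises(FloatingPointError, match="underflow"):
            # Mahalanobis distance overflows: -inf log density in every cell
            posterior_surface([1e200, 0.0], toy_basemap, GAMMA1, d)


def test_kernel_log_weight_consistent_with_linear():
    d = np.array([0.0, 1.0, 5.0, 50.0])
    for prior in (GAMMA1, KernelPrior(1.0, 10.0)):
        np.testing.assert_allclose(
            np.exp(kernel_log_weight(d, prior, d_floor_km=2.0)),
            kernel_weight(d, prior, d_floor_km=2.0), rtol=1e-12)
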