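"""True-MTR template: flattened gamma, discretization, error convolution."""

import json
import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.integrate import quad

from glyctest.hydrops_model import (
    ErrorModel,
    TemplateParams,
    TrueMtrTemplate,
    build_template,
    convolve_with_error,
    flattened_cdf,
    flattened_pdf,
    gamma2_pdf,
    model_cdf_on_grid,
)

THETA_GRID = [1.0, 3.89, 5.67, 10.0]


def _flattened_oracle(theta):
    """Numerically renormalized flattening of the shape-2 gamma density:
    the rising flank on [0, theta] is replaced by the density maximum."""
    peak = gamma2_pdf(theta, theta)
    unnorm = lambda x: (peak if x <= theta else gamma2_pdf(x, theta)) if x >= 0 else 0.0
    z, _ = quad(unnorm, 0, 60 * theta, points=[theta], limit=200)
    return lambda x: unnorm(x) / z


class TestGamma2:
    def test_vanishes_at_origin_and_below(self):
        assert gamma2_pdf(0.0, 3.0) == 0.0
        assert gamma2_pdf(-2.0, 3.0) == 0.0

    def test_value_at_mode(self):
        # density maximum sits at x = theta; at theta = 3 it equals e^-1 / 3
        assert gamma2_pdf(3.0, 3.0) == pytest.approx(math.exp(-1) / 3.0, abs=1e-12)

    @pytest.mark.parametrize("theta", THETA_GRID)
    def test_normalizes(self, theta):
        total, _ = quad(gamma2_pdf, 0, 80 * theta, args=(theta,), limit=200)
        assert total == pytest.approx(1.0, abs=1e-8)

    @pytest.mark.parametrize("theta", [0.0, -1.0])
    def test_rejects_nonpositive_scale(self, theta):
        with pytest.raises(ValueError):
            gamma2_pdf(1.0, theta)


class TestFlattened:
    @pytest.mark.parametrize("theta", THETA_GRID)
    def test_plateau_height_matches_numeric_renormalization(self, theta):
        oracle = _flattened_oracle(theta)
        for x in (0.0, theta / 2, theta):
            assert flattened_pdf(x, theta) == pytest.approx(oracle(x), abs=1e-10)
        assert flattened_pdf(0.3, theta) == pytest.approx(1.0 / (3.0 * theta), abs=1e-12)

    @pytest.mark.parametrize("theta", THETA_GRID)
    def test_one_third_of_mass_below_the_mode(self, theta):
        assert flattened_cdf(theta, theta) == pytest.approx(1.0 / 3.0, abs=1e-12)
        below, _ = quad(flattened_pdf, 0, theta, args=(theta,))
        assert below == pytest.approx(1.0 / 3.0, abs=1e-9)

    @pytest.mark.parametrize("theta", THETA_GRID)
    def test_integrates_to_one(self, theta):
        total, _ = quad(flattened_pdf, 0, 80 * theta, args=(theta,), points=[theta], limit=200)
        assert total == pytest.approx(1.0, abs=1e-8)

    @pytest.mark.parametrize("theta", [1.0, 3.89])
    def test_cdf_consistent_with_pdf(self, theta):
        for x in (0.5, theta, 2.7 * theta, 8 * theta):
            integral, _ = quad(flattened_pdf, 0, x, args=(theta,), points=[theta], limit=200)
            assert flattened_cdf(x, theta) == pytest.approx(integral, abs=1e-9)
        assert flattened_cdf(-1.0, theta) == 0.0


class TestBuildTemplate:
    def test_pure_no_effect_is_uniform_on_minus1_0_1(self):
        t = build_template(TemplateParams(1.0, 3.0))
        np.testing.assert_array_equal(t.support, [-1, 0, 1])
        np.testing.assert_allclose(t.probs, 1.0 / 3.0, atol=1e-15)

    @given(
        p0=st.floats(0.0, 1.0),
        theta=st.floats(0.2, 30.0),
    )
    def test_is_a_pooled_probability_mass_function(self, p0, theta):
        t = build_template(TemplateParams(p0, theta))
        assert abs(t.probs.sum() - 1.0) < 1e-12
        assert np.all(t.probs >= 0)
        assert t.support[0] == -1
        # the pooled no-effect group is spread equally over -1, 0, 1
        assert t.probs[0] == pytest.approx(t.probs[1], abs=1e-15)
        assert t.probs[1] == pytest.approx(t.probs[2], abs=1e-15)

    @pytest.mark.parametrize("theta", THETA_GRID)
    def test_matches_fine_quadrature_oracle(self, theta):
        p0 = 0.3
        t = build_template(TemplateParams(p0, theta))
        oracle = _flattened_oracle(theta)
        dx = 1e-4
        for n, prob in zip(t.support[3:8], t.probs[3:8]):
            xs = np.arange(n - 0.5, n + 0.5, dx) + dx / 2
            brute = (1 - p0) * np.sum([oracle(x) for x in xs]) * dx
            assert prob == pytest.approx(brute, abs=1e-7)

    def test_pooled_mass_agrees_with_direct_quadrature(self):
        # reference-cohort parameters; pool = p0 + (1-p0) * integral over [0, 1.5]
        p0, theta = 0.378, 3.89
        t = build_template(TemplateParams(p0, theta))
        tail, _ = quad(flattened_pdf, 0, 1.5, args=(theta,))
        assert t.prob_at_most(1) == pytest.approx(p0 + (1 - p0) * tail, abs=1e-9)

    def test_mean_increases_with_theta(self):
        means = [build_template(TemplateParams(0.4, th)).mean() for th in [1, 2, 3.89, 5.67, 10]]
        assert np.all(np.diff(means) > 0)

    def test_serialization_round_trip(self, tmp_path):
        t = build_template(TemplateParams(0.244, 5.67))
        path = tmp_path / "template.json"
        t.to_json(path)
        back = TrueMtrTemplate.from_json(path)
        np.testing.assert_array_equal(back.support, t.support)
        np.testing.assert_allclose(back.probs, t.probs, atol=1e-15)
        assert back.params == t.params
        assert "support" in json.loads(path.read_text())

    def test_rejects_invalid_params(self):
        with pytest.raises(ValueError):
            TemplateParams(-0.1, 3.0)
        with pytest.raises(ValueError):
            TemplateParams(0.5, 0.0)


class TestConvolution:
    def test_delta_error_limit_recovers_template(self):
        t = build_template(TemplateParams(0.378, 3.89))
        obs = convolve_with_error(t, ErrorModel(1e-6))
        on_support = np.isin(obs.support, t.support)
        np.testing.assert_allclose(obs.pmf[on_support], t.probs, atol=1e-9)
        assert np.all(obs.pmf[~on_support] < 1e-9)

    @pytest.mark.parametrize("sigma", [1.2, 2.45, 4.0])
    def test_conserves_mass_and_mean(self, sigma):
        t = build_template(TemplateParams(0.378, 3.89))
        obs = convolve_with_error(t, ErrorModel(sigma))
        assert obs.pmf.sum() == pytest.approx(1.0, abs=1e-9)
        assert obs.mean() == pytest.approx(t.mean(), abs=1e-6)
        assert np.all(np.diff(obs.cdf) >= -1e-15)

    def test_variance_adds_sigma_squared_up_to_binning(self):
        # integer binning contributes at most the 1/12 dB^2 grid variance
        t = build_template(TemplateParams(0.378, 3.89))
        sigma = 2.45
        obs = convolve_with_error(t, ErrorModel(sigma))
        excess = obs.variance() - t.variance() - sigma**2
        assert 0.0 <= excess < 1.0 / 12.0

    def test_commutes_with_support_shift(self):
        t = build_template(TemplateParams(0.4, 3.0))
        shifted = TrueMtrTemplate(t.support + 7, t.probs)
        a = convolve_with_error(t, ErrorModel(2.0))
        b = convolve_with_error(shifted, ErrorModel(2.0))
        np.testing.assert_array_equal(b.support, a.support + 7)
        np.testing.assert_allclose(b.pmf, a.pmf, atol=1e-12)

    def test_cdf_on_grid_matches_binned_distribution(self):
        t = build_template(TemplateParams(0.3, 4.0))
        obs = convolve_with_error(t, ErrorModel(2.45))
        grid = np.arange(-8, 25)
        np.testing.assert_allclose(
            model_cdf_on_grid(t, 2.45, grid), obs.cdf_at(grid), atol=1e-9
        )

    def test_rejects_nonpositive_sigma(self):
        with pytest.raises(ValueError):
            ErrorModel(0.0)
        with pytest.raises(ValueError):
            model_cdf_on_grid(build_template(TemplateParams(0.5, 3.0)), -1.0, [0])
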