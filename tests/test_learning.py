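"""Bayesian updating, the fluctuation-dissipation identity, Fisher form,
learning trajectories and the entropy-decay report."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from bayescell.distributions import (
    Grid1D,
    GridDensity1D,
    JointTable,
    kl_divergence,
    mutual_information,
    normalize,
)
from bayescell.fixtures import gaussian_density, quartic_density, random_joint
from bayescell.learning import (
    CoverageError,
    DegenerateEvidenceError,
    LearningConfig,
    bayes_update,
    beta_tilde,
    entropy_decay_report,
    expected_update_divergence,
    fisher_quadratic_form,
    iterate_learning,
    mutual_information_grid,
    pointwise_mi_given_x,
    product_form_pmi,
)
from bayescell.sensing import SensingModel


@pytest.fixture
def conjugate_setup():
    """Prior N(0,1), identity sensing with unit observation noise (g=0)."""
    prior = gaussian_density(0.0, 1.0, -8.0, 8.0, 2001)
    model = SensingModel(b=1.0, g=0.0, x_bar=0.0, domain=(-8.0, 8.0))
    y_grid = Grid1D(-12.0, 12.0, 1201)
    return prior, model, y_grid


class TestBayesUpdate:
    def test_uninformative_observation_keeps_prior(self, conjugate_setup):
        prior, _, _ = conjugate_setup
        # constant sensing mean: likelihood is constant in x
        flat = SensingModel(F=lambda x: 0.0, b=1.0, g=0.0, x_bar=0.0, domain=(-8, 8))
        post = bayes_update(prior, flat, y_obs=0.3)
        assert np.max(np.abs(post.values - prior.values)) < 1e-12

    def test_two_state_hand_bayes(self):
        # discrete analogue on a two-cell table: prior (.5,.5), L=(.8,.4)
        post = np.array([0.5 * 0.8, 0.5 * 0.4])
        post /= post.sum()
        np.testing.assert_allclose(post, [2 / 3, 1 / 3])

    def test_gaussian_conjugate_closed_form(self, conjugate_setup):
        prior, model, _ = conjugate_setup
        post = bayes_update(prior, model, y_obs=2.0)
        # N(0,1) prior x N(y; x, 1) likelihood -> N(1, 1/2) posterior
        expected = np.exp(-0.5 * (post.x - 1.0) ** 2 / 0.5) / math.sqrt(2 * math.pi * 0.5)
        assert np.max(np.abs(post.values - expected)) < 1e-6

    def test_degenerate_evidence_raises(self, conjugate_setup):
        prior, _, _ = conjugate_setup
        sharp = SensingModel(b=1e-6, g=0.0, x_bar=0.0, domain=(-8, 8))
        with pytest.raises(DegenerateEvidenceError):
            bayes_update(prior, sharp, y_obs=2000.0)


class TestFluctuationDissipation:
    """E_Y[KL(posterior || prior)] equals the mutual information."""

    def test_canonical_2x2(self):
        joint = JointTable(probs=np.array([[0.4, 0.1], [0.1, 0.4]]))
        d = expected_update_divergence(joint)
        assert d == pytest.approx(0.19274, abs=1e-5)
        assert d == pytest.approx(mutual_information(joint), abs=1e-12)

    @given(st.integers(min_value=0, max_value=10_000))
    @settings(max_examples=30, deadline=None)
    def test_discrete_identity(self, seed):
        joint = random_joint(4, 3, seed)
        d = expected_update_divergence(joint)
        assert d >= 0.0
        assert d == pytest.approx(mutual_information(joint), abs=1e-8)

    def test_independent_channel_gives_zero(self, conjugate_setup):
        prior, _, y_grid = conjugate_setup
        flat = SensingModel(F=lambda x: 0.0, b=1.0, g=0.0, x_bar=0.0, domain=(-8, 8))
        assert expected_update_divergence(prior, flat, y_grid) == pytest.approx(0.0, abs=1e-10)

    @pytest.mark.parametrize("g", [0.0, 0.2])
    def test_grid_identity_two_routes(self, g):
        model = SensingModel(b=1.0, g=g, x_bar=0.0, domain=(-4.0, 4.0))
        prior = gaussian_density(0.0, 1.0, -4.0, 4.0, 801)
        y_grid = Grid1D(-10.0, 10.0, 1401)
        d = expected_update_divergence(prior, model, y_grid)
        mi = mutual_information_grid(prior, model, y_grid)
        assert d == pytest.approx(mi, abs=1e-8)

    def test_narrow_y_grid_raises_coverage(self, conjugate_setup):
        prior, model, _ = conjugate_setup
        with pytest.raises(CoverageError):
            expected_update_divergence(prior, model, Grid1D(-0.5, 0.5, 64))


class TestPointwiseMI:
    def test_independent_channel_zero_everywhere(self, conjugate_setup):
        prior, _, y_grid = conjugate_setup
        flat = SensingModel(F=lambda x: 0.0, b=1.0, g=0.0, x_bar=0.0, domain=(-8, 8))
        for x in (-1.0, 0.0, 2.0):
            assert pointwise_mi_given_x(flat, prior, x, y_grid) == pytest.approx(0.0, abs=1e-12)

    def test_nonnegative_and_fubini_average(self):
        model = SensingModel(b=1.0, g=0.2, x_bar=0.0, domain=(-4.0, 4.0))
        prior = gaussian_density(0.0, 1.0, -4.0, 4.0, 401)
        y_grid = Grid1D(-10.0, 10.0, 1401)
        pmi = np.array(
            [pointwise_mi_given_x(model, prior, float(x), y_grid) for x in prior.x]
        )
        assert np.all(pmi >= 0.0)
        avg = float(np.trapezoid(prior.values * pmi, dx=prior.grid.spacing))
        assert avg == pytest.approx(
            expected_update_divergence(prior, model, y_grid), abs=1e-8
        )

    def test_product_form_sums_components(self):
        assert product_form_pmi([0.3]) == pytest.approx(0.3)
        assert product_form_pmi([0.1, 0.2]) == pytest.approx(0.3)
        assert product_form_pmi([0.0, 0.0, 0.0]) == 0.0


class TestBetaTilde:
    def test_full_supports_give_unity(self, conjugate_setup):
        prior, model, y_grid = conjugate_setup
        bt = beta_tilde((-8, 8), ((-8, 8), (-12, 12)), model, prior, y_grid)
        assert bt == pytest.approx(1.0, abs=1e-6)

    def test_half_mass_numerator_window(self, conjugate_setup):
        prior, _, y_grid = conjugate_setup
        # independent channel: posterior = prior for every y, so a window
        # capturing half the prior mass halves the ratio
        flat = SensingModel(F=lambda x: 0.0, b=1.0, g=0.0, x_bar=0.0, domain=(-8, 8))
        bt = beta_tilde((-8, 0), ((-8, 8), (-12, 12)), flat, prior, y_grid)
        assert bt == pytest.approx(0.5, abs=1e-6)

    def test_symmetric_truncation_of_symmetric_model(self, conjugate_setup):
        prior, _, y_grid = conjugate_setup
        flat = SensingModel(F=lambda x: 0.0, b=1.0, g=0.0, x_bar=0.0, domain=(-8, 8))
        bt = beta_tilde((-2, 2), ((-2, 2), (-12, 12)), flat, prior, y_grid)
        assert bt == pytest.approx(1.0, abs=1e-6)

    def test_empty_window_rejected(self, conjugate_setup):
        prior, model, y_grid = conjugate_setup
        with pytest.raises(ValueError):
            beta_tilde((2, -2), ((-8, 8), (-12, 12)), model, prior, y_grid)


class TestFisherQuadraticForm:
    @pytest.mark.parametrize(
        "sigma,delta,lo,hi,n",
        [(1.0, 0.1, -8.0, 8.0, 4001), (2.0, 0.2, -16.0, 16.0, 8001)],
    )
    def test_gaussian_shift_kl_is_exactly_quadratic(self, sigma, delta, lo, hi, n):
        d = gaussian_density(0.0, sigma, lo, hi, n)
        rep = fisher_quadratic_form(d, delta)
        expected = delta**2 / (2.0 * sigma**2)
        assert rep.quadratic_form == pytest.approx(expected, abs=1e-6)
        assert rep.exact_kl == pytest.approx(expected, abs=1e-6)

    def test_zero_shift(self, unit_gaussian):
        rep = fisher_quadratic_form(unit_gaussian, 0.0)
        assert rep.quadratic_form == 0.0
        assert rep.exact_kl == 0.0

    def test_quartic_error_superquadratic(self):
        # p propto exp(-x^4/4): the KL is symmetric in the shift, so the
        # quadratic-approximation error is O(delta^4) and err/delta^2
        # shrinks by ~4 per halving
        q = quartic_density(-6.0, 6.0, 2401)
        ratios = []
        for delta in (0.2, 0.1, 0.05):
            rep = fisher_quadratic_form(q, delta)
            ratios.append(abs(rep.exact_kl - rep.quadratic_form) / delta**2)
        assert ratios[0] / ratios[1] > 2.0
        assert ratios[1] / ratios[2] > 2.0

    def test_mass_off_grid_rejected(self):
        d = gaussian_density(0.0, 1.0, -3.0, 3.0, 601)
        with pytest.raises(ValueError, match="off-grid"):
            fisher_quadratic_form(d, 0.5)


class TestLearningTrajectories:
    def test_zero_steps_is_noop(self, conjugate_setup):
        prior, model, y_grid = conjugate_setup
        cfg = LearningConfig(prior=prior, sensing=model, y_grid=y_grid, n_steps=0)
        traj = iterate_learning(cfg)
        assert len(traj) == 0
        np.testing.assert_allclose(traj.final_prior.values, prior.values, atol=1e-12)

    @pytest.mark.parametrize("mode", ["observed", "averaged"])
    def test_conjugate_chain_posterior_variance(self, conjugate_setup, mode):
        prior, model, y_grid = conjugate_setup
        cfg = LearningConfig(
            prior=prior, sensing=model, y_grid=y_grid, n_steps=10, seed=7,
            update_mode=mode,
        )
        traj = iterate_learning(cfg)
        # unit-variance prior + 10 unit-noise observations -> variance 1/11
        assert traj.final_prior.variance() == pytest.approx(1 / 11, rel=0.02)

    def test_averaged_mode_contracts_variance_monotonically(self, conjugate_setup):
        prior, model, y_grid = conjugate_setup
        cfg = LearningConfig(
            prior=prior, sensing=model, y_grid=y_grid, n_steps=8, seed=0,
            update_mode="averaged",
        )
        traj = iterate_learning(cfg)
        s = np.append(traj.sigma_x2_series(), traj.final_prior.variance())
        assert np.all(np.diff(s) <= 1e-9)

    def test_averaged_mode_martingale_mean(self, conjugate_setup):
        prior, model, y_grid = conjugate_setup
        cfg = LearningConfig(
            prior=prior, sensing=model, y_grid=y_grid, n_steps=5,
            update_mode="averaged",
        )
        traj = iterate_learning(cfg)
        assert abs(traj.final_prior.mean() - prior.mean()) < 1e-10

    def test_observed_mode_reproducible(self, conjugate_setup):
        prior, model, y_grid = conjugate_setup
        cfg = LearningConfig(prior=prior, sensing=model, y_grid=y_grid, n_steps=4, seed=42)
        a = iterate_learning(cfg)
        b = iterate_learning(cfg)
        assert [s.y_obs for s in a.steps] == [s.y_obs for s in b.steps]
        assert all(s.kl >= 0 for s in a.steps)


class TestEntropyDecay:
    def test_sensor_off_constant_entropy(self, conjugate_setup):
        prior, _, y_grid = conjugate_setup
        model = SensingModel(b=2.0, g=0.0, x_bar=0.0, domain=(-8, 8))
        cfg = LearningConfig(prior=prior, sensing=model, y_grid=Grid1D(-16, 16, 1201),
                             n_steps=4, update_mode="averaged")
        traj = iterate_learning(cfg)
        rep = entropy_decay_report(traj, model)
        ent = np.array(rep["cond_entropy"])
        expected = math.log(2.0) + 0.5 * math.log(2 * math.pi * math.e)
        np.testing.assert_allclose(ent, expected, atol=1e-12)

    def test_sensing_chain_decays_toward_limit(self):
        # g > 0: sharpening prior drives sigma_{Y|X}^2 -> b^2
        prior = gaussian_density(2.0, 0.5, 1.6, 3.0, 801)
        model = SensingModel(b=0.5, g=1.0, x_bar=2.0, domain=(1.6, 3.0))
        y_grid = Grid1D(-3.0, 8.0, 1401)
        cfg = LearningConfig(prior=prior, sensing=model, y_grid=y_grid,
                             n_steps=10, update_mode="averaged")
        traj = iterate_learning(cfg)
        rep = entropy_decay_report(traj, model)
        assert rep["verdict"] == "nonincreasing"
        ent = np.array(rep["cond_entropy"])
        assert np.all(np.diff(ent) <= 1e-9)
        assert rep["limit_gap"] < 0.05
        assert ent[-1] > rep["entropy_limit"]

    def test_single_step_insufficient_data(self, conjugate_setup):
        prior, model, y_grid = conjugate_setup
        cfg = LearningConfig(prior=prior, sensing=model, y_grid=y_grid, n_steps=1)
        rep = entropy_decay_report(iterate_learning(cfg), model)
        assert rep["verdict"] == "insufficient data"
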