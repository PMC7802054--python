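"""Closed-form and oracle checks of the joint model's building blocks."""

import numpy as np
import pytest
from scipy.special import expit, ndtr
from scipy.stats import multivariate_normal

from ldsirt import (
    LdsIrtModel,
    PriorLedger,
    joint_logdensity,
    latent_prior_logdensity,
    loglik_2pl,
    ordinal_probit_logpmf,
    parent_trait,
    regression_predictor,
)
from ldsirt.model import make_param_set


class TestLoglik2pl:
    @pytest.mark.parametrize("theta,a,b", [(0.0, 1.0, 0.0), (1.0, 2.0, 1.0)])
    def test_symmetry_at_difficulty(self, theta, a, b):
        assert loglik_2pl(1, theta, a, b) == pytest.approx(np.log(0.5))

    def test_matches_logistic(self):
        # response 0 at a*(theta-b) = 1.5
        expected = np.log(1.0 - expit(1.5))
        assert loglik_2pl(0, 0.5, 1.5, -0.5) == pytest.approx(expected, abs=1e-12)

    def test_rejects_nonbinary(self):
        with pytest.raises(ValueError):
            loglik_2pl(2, 0.0, 1.0, 0.0)

    def test_rejects_nonpositive_discrimination(self):
        with pytest.raises(ValueError):
            loglik_2pl(1, 0.0, -1.0, 0.0)


def test_parent_trait_is_sum():
    assert parent_trait(0.5, 0.3) == pytest.approx(0.8)
    assert parent_trait(1.7, 0.0) == pytest.approx(1.7)
    assert parent_trait(0.0, -1.2) == pytest.approx(-1.2)


class TestLatentPrior:
    def test_standard_origin(self):
        assert latent_prior_logdensity(0, 0, 0, 0) == pytest.approx(-np.log(2 * np.pi))

    def test_independence_factorization(self):
        theta, delta, mu = 0.7, -1.1, 0.4
        got = latent_prior_logdensity(theta, delta, mu, 0.0)
        uni = -0.5 * np.log(2 * np.pi)
        expected = (uni - 0.5 * theta**2) + (uni - 0.5 * (delta - mu) ** 2)
        assert got == pytest.approx(expected, abs=1e-12)

    def test_matches_matrix_form_oracle(self):
        rho, mu = 0.5, 0.1
        cov = np.array([[1, rho], [rho, 1]])
        oracle = multivariate_normal(mean=[0, mu], cov=cov).logpdf([0.3, -0.2])
        got = latent_prior_logdensity(0.3, -0.2, mu, rho)
        assert got == pytest.approx(oracle, abs=1e-10)

    def test_rejects_degenerate_correlation(self):
        with pytest.raises(ValueError):
            latent_prior_logdensity(0, 0, 0, 1.0)


class TestOrdinalProbit:
    def test_symmetry(self):
        assert ordinal_probit_logpmf(1, 0.0, (0.0, 10.0)) == pytest.approx(np.log(0.5))

    def test_normal_cdf_oracle(self):
        got = ordinal_probit_logpmf(1, 0.0, (-0.88, 0.05))
        assert got == pytest.approx(np.log(ndtr(-0.88)), abs=1e-12)

    @pytest.mark.parametrize("eta,c", [(0.7, (-0.9, 0.1)), (-3.0, (0.0, 0.5)),
                                       (8.0, (-1.0, 1.0))])
    def test_categories_normalize(self, eta, c):
        probs = [np.exp(ordinal_probit_logpmf(y, eta, c)) for y in (1, 2, 3)]
        assert sum(probs) == pytest.approx(1.0, abs=1e-12)

    def test_rejects_unordered_cutpoints(self):
        with pytest.raises(ValueError):
            ordinal_probit_logpmf(1, 0.0, (0.5, -0.5))

    def test_p3_decreasing_in_delta_for_negative_beta(self):
        # monotonicity of the discrepancy model's clinical-category risk
        beta = -0.4
        deltas = np.linspace(-2, 2, 21)
        p3 = np.exp([ordinal_probit_logpmf(3, beta * d, (-0.88, 0.05)) for d in deltas])
        assert np.all(np.diff(p3) < 0)


class TestRegressionPredictor:
    def test_discrepancy_uses_published_scale(self):
        assert regression_predictor("discrepancy", 0, 0, 1.0, -0.25) == pytest.approx(-0.25)

    @pytest.mark.parametrize("variant,beta", [
        ("adolescent", 0.0), ("parent", 0.0), ("discrepancy", 0.0),
        ("multi", (0.0, 0.0)),
    ])
    def test_zero_coefficient(self, variant, beta):
        assert regression_predictor(variant, 0.4, 0.9, -0.3, beta) == 0.0

    def test_multi_sums_traits(self):
        assert regression_predictor("multi", 0.2, 0.3, 0.0, (1.0, 1.0)) == pytest.approx(0.5)

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            regression_predictor("multi", 0, 0, 0, 0.5)
        with pytest.raises(ValueError):
            regression_predictor("discrepancy", 0, 0, 0, (0.5, 0.2))


class TestJointLogdensity:
    def test_single_dyad_term_by_term(self, small_dataset):
        """Joint density of one complete dyad equals the hand-computed sum."""
        from ldsirt.data import DyadDataset, RoleBlock

        rng = np.random.default_rng(0)
        items = rng.integers(0, 2, size=(1, 4))
        par_items = rng.integers(0, 2, size=(1, 4))
        blk = RoleBlock(ids=[0], adol_items=items, adol_mask=np.ones((1, 4), bool),
                        par_items=par_items, par_mask=np.ones((1, 4), bool),
                        outcome=[2])
        ds = DyadDataset(n_adolescents=1, roles={"mother": blk})
        model = LdsIrtModel(ds, "discrepancy")
        a = np.array([1.0, 1.5, 0.8, 2.0])
        b = np.array([-0.5, 0.0, 0.5, 1.0])
        ps = make_param_set(model, a, b, beta=[-0.4], cutpoints=[-0.8, 0.1],
                            mu_delta=0.2, rho=-0.3, theta=[0.6], delta=[-0.4])
        got = joint_logdensity(ds, ps, "discrepancy")

        pr = PriorLedger()
        theta, delta = 0.6, -0.4
        expected = float(np.sum(loglik_2pl(items[0], theta, a, b)))
        expected += float(np.sum(loglik_2pl(par_items[0], theta + delta, a, b)))
        expected += float(latent_prior_logdensity(theta, delta, 0.2, -0.3))
        expected += float(ordinal_probit_logpmf(2, -0.4 * delta, (-0.8, 0.1)))
        # priors: LogNormal on a, normals on b, beta, cutpoints, mu; uniform rho
        def norm_lp(x, sd):
            x = np.asarray(x, float)
            return np.sum(-0.5 * (x / sd) ** 2 - np.log(sd) - 0.5 * np.log(2 * np.pi))
        expected += norm_lp(np.log(a), pr.a_log_sd) - np.sum(np.log(a))
        expected += norm_lp(b, pr.b_sd)
        expected += norm_lp([-0.4], pr.beta_sd)
        expected += norm_lp([-0.8, 0.1], pr.cutpoint_sd)
        expected += norm_lp(0.2, pr.mu_delta_sd)
        expected += -np.log(2.0)
        assert got == pytest.approx(expected, rel=1e-12)

    def test_all_items_missing_removes_only_those_terms(self, small_dataset):
        dataset, _ = small_dataset
        model = LdsIrtModel(dataset, "discrepancy")
        z = model.initial_value(np.random.default_rng(3))
        ps = model.unpack(z)
        base = joint_logdensity(dataset, ps, "discrepancy")

        import copy
        ds2 = copy.deepcopy(dataset)
        blk = ds2.roles["mother"]
        removed = blk.adol_mask[0].copy()
        blk.adol_mask[0] = False
        reduced = joint_logdensity(ds2, ps, "discrepancy")
        ip = ps.items["all"]
        terms = loglik_2pl(dataset.roles["mother"].adol_items[0],
                           ps.roles["mother"].theta[0], ip.a, ip.b)
        assert base - reduced == pytest.approx(float(np.sum(terms[removed])), rel=1e-10)

    def test_variant_difference_is_regression_term_only(self, small_dataset):
        dataset, _ = small_dataset
        model = LdsIrtModel(dataset, "adolescent")
        ps = make_param_set(model, np.full(dataset.n_items, 1.2),
                            np.zeros(dataset.n_items), beta=[-0.3],
                            cutpoints=[-0.9, 0.1], mu_delta=0.1, rho=-0.2,
                            theta=np.linspace(-1, 1, 60),
                            delta=np.linspace(1, -1, 60))
        lp_a = joint_logdensity(dataset, ps, "adolescent")
        lp_d = joint_logdensity(dataset, ps, "discrepancy")
        reg_a = reg_d = 0.0
        for role in dataset.role_names:
            blk = dataset.roles[role]
            rp = ps.roles[role]
            reg_a += np.sum(ordinal_probit_logpmf(
                blk.outcome, -0.3 * rp.theta, (-0.9, 0.1)))
            reg_d += np.sum(ordinal_probit_logpmf(
                blk.outcome, -0.3 * rp.delta, (-0.9, 0.1)))
        assert lp_a - lp_d == pytest.approx(reg_a - reg_d, rel=1e-10)

    def test_reflection_changes_density(self, small_dataset):
        """theta -> -theta, b -> -b is not a symmetry: the sign convention
        (positive discriminations, higher theta = more conflict) is fixed."""
        dataset, _ = small_dataset
        model = LdsIrtModel(dataset, "discrepancy")
        rng = np.random.default_rng(5)
        z = model.initial_value(rng)
        ps = model.unpack(z)
        lp = joint_logdensity(dataset, ps, "discrepancy")
        for role in ps.roles.values():
            role.theta = -role.theta
        ps.items["all"].b = -ps.items["all"].b
        lp_ref = joint_logdensity(dataset, ps, "discrepancy")
        assert abs(lp - lp_ref) > 1.0


def test_packed_gradient_matches_finite_differences(small_dataset):
    dataset, _ = small_dataset
    for variant in ("multi", "discrepancy"):
        model = LdsIrtModel(dataset, variant)
        rng = np.random.default_rng(11)
        z = model.initial_value(rng)
        lp, grad = model.logp_grad(z)
        idx = rng.choice(model.dim, size=25, replace=False)
        eps = 1e-6
        for i in idx:
            zp, zm = z.copy(), z.copy()
            zp[i] += eps
            zm[i] -= eps
            fd = (model.logp(zp) - model.logp(zm)) / (2 * eps)
            assert grad[i] == pytest.approx(fd, rel=1e-4, abs=1e-5)


def test_pack_unpack_roundtrip(small_dataset):
    dataset, _ = small_dataset
    model = LdsIrtModel(dataset, "multi")
    z = model.initial_value(np.random.default_rng(2))
    z2 = model.pack(model.unpack(z))
    assert np.allclose(z, z2, atol=1e-12)
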