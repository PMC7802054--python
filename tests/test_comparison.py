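"""PSIS-LOO, stacking and exact-refit oracle checks."""

import numpy as np
import pytest
from scipy.special import logsumexp
from scipy.stats import genpareto

from ldsirt import (
    elpd_loo,
    loo_compare,
    ordinal_probit_logpmf,
    pointwise_loglik,
    psis,
    stacking_weights,
)
from ldsirt.comparison import PointwiseLogLik
from ldsirt.inference import PosteriorDraws


def _tiny_fit(role="mother", beta=(-0.4,), c=( -0.9, 0.1), theta=(0.3,), delta=(-0.5,)):
    """A 1-chain, 1-draw posterior for shape contracts."""
    params = {
        f"beta_{role}": np.array(beta)[None, None, :],
        f"c1_{role}": np.array([[c[0]]]),
        f"c2_{role}": np.array([[c[1]]]),
        f"theta_{role}": np.array(theta)[None, None, :],
        f"delta_{role}": np.array(delta)[None, None, :],
        f"mu_delta_{role}": np.array([[0.0]]),
        f"rho_{role}": np.array([[0.0]]),
    }
    return PosteriorDraws(params=params, meta={})


class TestPointwiseLoglik:
    def test_single_draw_single_obs_matches_scalar_op(self):
        from ldsirt.data import DyadDataset, RoleBlock

        blk = RoleBlock(ids=[0], adol_items=np.ones((1, 2), int),
                        adol_mask=np.ones((1, 2), bool),
                        par_items=np.zeros((1, 2), int),
                        par_mask=np.ones((1, 2), bool), outcome=[3])
        ds = DyadDataset(n_adolescents=1, roles={"mother": blk})
        fit = _tiny_fit()
        ll = pointwise_loglik(fit, ds, "discrepancy")
        expected = ordinal_probit_logpmf(3, -0.4 * -0.5, (-0.9, 0.1))
        assert ll.ll.shape == (1, 1)
        assert ll.ll[0, 0] == pytest.approx(float(expected), abs=1e-12)

    def test_category_probabilities_normalize_per_draw(self, small_fits):
        dataset, fits = small_fits
        fit = fits["discrepancy"]
        import copy

        total = 0.0
        for y in (1, 2, 3):
            ds = copy.deepcopy(dataset)
            for role in ds.role_names:
                ds.roles[role].outcome[:] = y
            ll = pointwise_loglik(fit, ds, "discrepancy")
            total = total + np.exp(ll.ll)
        assert np.allclose(total, 1.0, atol=1e-10)

    def test_lpd_equals_log_mean_likelihood(self, small_fits):
        dataset, fits = small_fits
        ll = pointwise_loglik(fits["discrepancy"], dataset, "discrepancy")
        res = elpd_loo(ll)
        s = ll.ll.shape[0]
        oracle = logsumexp(ll.ll, axis=0) - np.log(s)
        assert np.allclose(res.lpd, oracle, atol=1e-12)


class TestPsis:
    def test_constant_ratios_uniform_weights(self):
        w, k = psis(np.zeros(400))
        assert np.allclose(w, 1 / 400)
        assert k == -np.inf

    def test_weights_are_normalized_and_nonnegative(self):
        rng = np.random.default_rng(0)
        for _ in range(5):
            w, k = psis(rng.normal(size=1000) * rng.uniform(0.5, 3))
            assert np.all(w >= 0)
            assert np.sum(w) == pytest.approx(1.0, abs=1e-10)

    def test_recovers_known_pareto_tail_shape(self):
        """Ratios with a generalized-Pareto tail of shape 0.5 give k-hat
        near 0.5 at S = 4,000."""
        rng = np.random.default_rng(42)
        khats = []
        for rep in range(5):
            ratios = genpareto.rvs(0.5, size=4000, random_state=rng)
            _, k = psis(np.log(ratios))
            khats.append(k)
        assert abs(np.mean(khats) - 0.5) < 0.15

    def test_shift_invariance_of_weights(self):
        rng = np.random.default_rng(3)
        lr = rng.normal(size=2000)
        w1, k1 = psis(lr)
        w2, k2 = psis(lr + 7.3)
        assert np.allclose(w1, w2, atol=1e-12)
        assert k1 == pytest.approx(k2, abs=1e-10)

    def test_few_draws_fall_back_with_warning(self):
        with pytest.warns(UserWarning):
            w, k = psis(np.arange(10.0))
        assert np.sum(w) == pytest.approx(1.0)


class TestElpdLoo:
    def test_single_unit_has_zero_se(self):
        rng = np.random.default_rng(1)
        ll = PointwiseLogLik(ll=rng.normal(-1.0, 0.3, size=(500, 1)),
                             units=[("mother", 0)])
        res = elpd_loo(ll)
        assert res.se == 0.0
        assert res.pointwise.shape == (1,)

    def test_pointwise_sums_to_total_and_elpd_below_lpd(self, small_fits):
        dataset, fits = small_fits
        ll = pointwise_loglik(fits["discrepancy"], dataset, "discrepancy")
        res = elpd_loo(ll)
        assert res.elpd_loo == pytest.approx(res.pointwise.sum(), rel=1e-12)
        assert res.elpd_loo <= res.lpd.sum() + 1e-9
        assert res.p_loo >= -0.5  # nonnegative up to estimator noise

    def test_multi_informant_model_has_larger_p_loo(self, small_fits):
        """The two-coefficient multi-informant variant is effectively more
        flexible than a single-predictor variant on the same data."""
        dataset, fits = small_fits
        res = {
            v: elpd_loo(pointwise_loglik(fits[v], dataset, v))
            for v in ("adolescent", "multi")
        }
        assert res["multi"].p_loo > res["adolescent"].p_loo


class TestLooCompare:
    @staticmethod
    def _fake_result(pointwise):
        ll = PointwiseLogLik(
            ll=np.tile(pointwise, (50, 1)) + np.random.default_rng(0).normal(
                0, 0.01, size=(50, len(pointwise))),
            units=[("mother", i) for i in range(len(pointwise))])
        return elpd_loo(ll)

    def test_self_comparison_zero(self):
        r = self._fake_result(np.array([-1.0, -0.5, -2.0]))
        table = loo_compare({"m": r}).set_index("model")
        assert table.loc["m", "elpd_diff"] == 0.0
        assert table.loc["m", "diff_se"] == 0.0

    def test_duplicated_models_both_zero(self):
        r = self._fake_result(np.array([-1.0, -0.5, -2.0]))
        table = loo_compare({"a": r, "b": r})
        assert np.allclose(table["elpd_diff"], 0.0)

    def test_difference_formula_oracle(self, small_fits):
        dataset, fits = small_fits
        res = {v: elpd_loo(pointwise_loglik(fits[v], dataset, v))
               for v in ("discrepancy", "adolescent")}
        table = loo_compare(res).set_index("model")
        best = table["elpd_loo"].idxmax()
        other = [m for m in res if m != best][0]
        d = res[other].pointwise - res[best].pointwise
        n = len(d)
        assert table.loc[other, "elpd_diff"] == pytest.approx(d.sum(), rel=1e-10)
        assert table.loc[other, "diff_se"] == pytest.approx(np.sqrt(n * np.var(d)), rel=1e-10)

    def test_mismatched_units_rejected(self):
        r1 = self._fake_result(np.array([-1.0, -0.5]))
        r2 = self._fake_result(np.array([-1.0, -0.5, -2.0]))
        with pytest.raises(ValueError):
            loo_compare({"a": r1, "b": r2})


class TestStacking:
    def test_single_model_gets_weight_one(self):
        w = stacking_weights(np.random.default_rng(0).normal(size=(20, 1)))
        assert w.shape == (1,)
        assert w[0] == pytest.approx(1.0)

    def test_identical_models_tie_broken_to_equal_weights(self):
        col = np.random.default_rng(1).normal(-1, 0.5, size=30)
        w = stacking_weights(np.column_stack([col, col]))
        assert np.allclose(w, [0.5, 0.5], atol=1e-4)

    def test_dominating_model_takes_all_weight(self):
        rng = np.random.default_rng(2)
        base = rng.normal(-1.0, 0.3, size=40)
        mat = np.column_stack([base, base - 2.0, base - 3.0])
        w = stacking_weights(mat)
        assert w[0] > 0.99

    def test_matches_fine_grid_search(self):
        """Optimizer objective matches a 0.001-step simplex grid search."""
        rng = np.random.default_rng(5)
        for rep in range(3):
            mat = rng.normal(-1.2, 0.8, size=(12, 3))

            def obj(w, p=np.exp(mat - mat.max(axis=1, keepdims=True))):
                return float(np.sum(np.log(p @ w)))

            w_opt = stacking_weights(mat)
            step = 0.001
            ij = np.mgrid[0:1001, 0:1001].reshape(2, -1).T
            ij = ij[ij.sum(axis=1) <= 1000]
            grid = np.column_stack([ij * step, 1.0 - ij.sum(axis=1) * step])
            p = np.exp(mat - mat.max(axis=1, keepdims=True))
            vals = np.log(grid @ p.T).sum(axis=1)
            assert obj(w_opt) >= vals.max() - 1e-3

    def test_start_invariance(self):
        """Concave objective: repeated calls agree regardless of internal
        multi-start order (deterministic result)."""
        mat = np.random.default_rng(9).normal(-1, 1, size=(25, 4))
        w1 = stacking_weights(mat)
        w2 = stacking_weights(np.array(mat))
        assert np.allclose(w1, w2, atol=1e-8)

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            stacking_weights(np.array([[0.0, -np.inf]]))
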