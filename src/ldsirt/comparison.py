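"""Model comparison: PSIS-LOO cross-validation, stacking, and checks.

The comparison currency is the ordinal outcome likelihood: one held-out
unit is one adolescent's hopelessness observation within one parent-role
regression, evaluated at each posterior draw's sampled latent variables
(the conditional pointwise likelihood that is standard when latent
variables are sampled rather than marginalised). Importance ratios are
stabilised by fitting a generalised Pareto distribution to their tail
(PSIS); stacking weights maximise the combined leave-one-out predictive
density over the simplex.

``exact_loo`` provides the brute-force oracle — one refit per held-out
unit — used to validate the importance-sampling approximation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import logsumexp, log_ndtr, ndtr

from .data import DyadDataset
from .inference import PosteriorDraws, convergence_gate, sample_posterior
from .model import LdsIrtModel, PriorLedger

with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    import arviz as az

PARETO_K_WARN = 0.7


# ---------------------------------------------------------------------------
# Pointwise log-likelihood
# ---------------------------------------------------------------------------

def _ordinal_logpmf_draws(y, eta, c1, c2):
    """Vectorised ordinal probit log-pmf with per-draw cutpoints.

    eta: (S, n); c1, c2: (S,); y: (n,) in {1,2,3}. Returns (S, n).
    """
    x1 = c1[:, None] - eta
    x2 = c2[:, None] - eta
    lp1 = log_ndtr(x1)
    lp3 = log_ndtr(-x2)
    mid = np.where(x1 + x2 > 0, ndtr(-x1) - ndtr(-x2), ndtr(x2) - ndtr(x1))
    lp2 = np.log(np.clip(mid, 1e-300, None))
    y = np.asarray(y)
    return np.where(y == 1, lp1, np.where(y == 2, lp2, lp3))


@dataclass
class PointwiseLogLik:
    """S x N matrix of outcome log-likelihoods with unit labels.

    Columns are labelled ``(role, dyad_index)`` so per-role comparisons can
    slice the matrix.
    """

    ll: np.ndarray
    units: list
    n_chains: int = 1

    def __post_init__(self):
        if not np.isfinite(self.ll).all():
            raise ValueError("pointwise log-likelihood contains non-finite values")

    @property
    def n_units(self) -> int:
        return self.ll.shape[1]

    def role_columns(self, role: str) -> np.ndarray:
        return np.array([i for i, (r, _) in enumerate(self.units) if r == role])

    def subset(self, role: str) -> "PointwiseLogLik":
        cols = self.role_columns(role)
        return PointwiseLogLik(ll=self.ll[:, cols],
                               units=[self.units[i] for i in cols],
                               n_chains=self.n_chains)

    def relative_ess(self) -> np.ndarray:
        """Relative ESS of the per-unit likelihood values (r_eff for PSIS)."""
        s, n = self.ll.shape
        if self.n_chains < 1 or s % self.n_chains or s < 8:
            return np.ones(n)
        lik = np.exp(self.ll.reshape(self.n_chains, s // self.n_chains, n))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ess = az.ess(az.convert_to_dataset(lik), method="mean")["x"].values
        reff = np.asarray(ess, dtype=float) / s
        return np.clip(np.nan_to_num(reff, nan=1.0), 1e-3, 1.0)


def pointwise_loglik(draws: PosteriorDraws, dataset: DyadDataset,
                     variant: str) -> PointwiseLogLik:
    """Outcome log-likelihood per posterior draw and hopelessness observation."""
    blocks = []
    units = []
    for role in dataset.role_names:
        blk = dataset.roles[role]
        if blk.n_dyads == 0:
            continue
        beta = draws.stacked(f"beta_{role}")
        theta = draws.stacked(f"theta_{role}")
        delta = draws.stacked(f"delta_{role}")
        c1 = draws.stacked(f"c1_{role}")
        c2 = draws.stacked(f"c2_{role}")
        if theta.shape[1] != blk.n_dyads:
            raise ValueError("draws do not match the dataset's dyad count")
        tpar = theta + delta
        if variant == "adolescent":
            eta = beta[:, [0]] * theta
        elif variant == "parent":
            eta = beta[:, [0]] * tpar
        elif variant == "multi":
            eta = beta[:, [0]] * theta + beta[:, [1]] * tpar
        elif variant == "discrepancy":
            eta = beta[:, [0]] * delta
        else:
            raise ValueError(f"unknown variant {variant!r}")
        lp = _ordinal_logpmf_draws(blk.outcome, eta, c1, c2)
        keep = np.flatnonzero(blk.outcome_mask)
        blocks.append(lp[:, keep])
        units.extend((role, int(i)) for i in keep)
    return PointwiseLogLik(ll=np.concatenate(blocks, axis=1), units=units,
                           n_chains=draws.n_chains)


# ---------------------------------------------------------------------------
# PSIS and LOO
# ---------------------------------------------------------------------------

def psis(log_ratios: np.ndarray):
    """Pareto-smoothed importance weights for one unit.

    Returns ``(weights, k)`` with weights normalised to sum to 1. Constant
    log-ratios give uniform weights and ``k = -inf`` (no tail to fit); for
    fewer than 25 draws the raw normalised weights are returned with a
    warning.
    """
    lr = np.asarray(log_ratios, dtype=float)
    if lr.ndim != 1:
        raise ValueError("log_ratios must be a vector")
    s = lr.size
    if np.ptp(lr) == 0:
        return np.full(s, 1.0 / s), float("-inf")
    if s < 25:
        warnings.warn("too few draws for Pareto smoothing; using raw weights")
        w = np.exp(lr - logsumexp(lr))
        return w, float("nan")
    lw, k = az.psislw(lr)
    w = np.exp(lw - logsumexp(lw))
    return w, float(k)


@dataclass
class LooResult:
    """PSIS-LOO estimate: total elpd, effective parameters and diagnostics."""

    elpd_loo: float
    se: float
    p_loo: float
    p_loo_se: float
    pointwise: np.ndarray
    pareto_k: np.ndarray
    lpd: np.ndarray
    units: list = field(default_factory=list)

    @property
    def n_units(self) -> int:
        return len(self.pointwise)

    @property
    def flagged_units(self) -> list:
        return [self.units[i] if self.units else i
                for i in np.flatnonzero(self.pareto_k > PARETO_K_WARN)]


def elpd_loo(ll: PointwiseLogLik) -> LooResult:
    """PSIS-LOO expected log pointwise predictive density.

    Per unit, importance log-ratios are the negative per-draw log-
    likelihoods; after Pareto smoothing, elpd_i is the log weighted mean
    likelihood. p_loo is the summed gap between the in-sample log pointwise
    density and elpd.
    """
    mat = ll.ll
    s, n = mat.shape
    lpd = logsumexp(mat, axis=0) - np.log(s)
    reff = ll.relative_ess()
    lw = np.empty((n, s))
    k = np.empty(n)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for i in range(n):  # per-unit r_eff, as the PSIS methodology requires
            lw[i], k[i] = az.psislw(-mat[:, i], reff=float(reff[i]))
    elpd_i = logsumexp(lw + mat.T, axis=1)
    k = np.atleast_1d(np.asarray(k, dtype=float))
    se = float(np.sqrt(n * np.var(elpd_i))) if n > 1 else 0.0
    p_i = lpd - elpd_i
    p_se = float(np.sqrt(n * np.var(p_i))) if n > 1 else 0.0
    return LooResult(
        elpd_loo=float(np.sum(elpd_i)),
        se=se,
        p_loo=float(np.sum(p_i)),
        p_loo_se=p_se,
        pointwise=elpd_i,
        pareto_k=k,
        lpd=lpd,
        units=list(ll.units),
    )


def loo_compare(results: dict) -> pd.DataFrame:
    """Difference table relative to the best model.

    ``results`` maps model name to :class:`LooResult` computed on identical
    units. The best model has difference 0; standard errors of differences
    come from the pointwise elpd differences.
    """
    names = list(results)
    n_units = {results[m].n_units for m in names}
    if len(n_units) != 1:
        raise ValueError("all models must be evaluated on the same units")
    n = n_units.pop()
    best = max(names, key=lambda m: results[m].elpd_loo)
    rows = []
    for m in names:
        d = results[m].pointwise - results[best].pointwise
        rows.append(
            {
                "model": m,
                "elpd_loo": results[m].elpd_loo,
                "se": results[m].se,
                "elpd_diff": float(np.sum(d)),
                "diff_se": float(np.sqrt(n * np.var(d))) if n > 1 else 0.0,
                "p_loo": results[m].p_loo,
                "p_loo_se": results[m].p_loo_se,
            }
        )
    out = pd.DataFrame(rows).sort_values("elpd_loo", ascending=False)
    return out.reset_index(drop=True)


# ---------------------------------------------------------------------------
# Stacking
# ---------------------------------------------------------------------------

def stacking_weights(elpd_matrix: np.ndarray, tol: float = 1e-8) -> np.ndarray:
    """Stacking weights maximising the combined LOO predictive density.

    ``elpd_matrix`` is N units x K models of pointwise elpd values. The
    objective sum_i log sum_k w_k exp(elpd_ik) is concave on the simplex;
    among optimal vectors the maximum-entropy one is returned, so identical
    models receive equal weights.
    """
    mat = np.asarray(elpd_matrix, dtype=float)
    if mat.ndim == 1:
        mat = mat[:, None]
    if not np.isfinite(mat).all():
        raise ValueError("pointwise elpd matrix must be finite")
    n, k = mat.shape
    if k == 1:
        return np.ones(1)
    # stabilise: per-unit shift changes the objective by a constant only
    p = np.exp(mat - mat.max(axis=1, keepdims=True))

    def neg_obj(w):
        mix = p @ w
        return -float(np.sum(np.log(np.clip(mix, 1e-300, None))))

    def neg_grad(w):
        mix = np.clip(p @ w, 1e-300, None)
        return -(p / mix[:, None]).sum(axis=0)

    cons = [{"type": "eq", "fun": lambda w: np.sum(w) - 1.0,
             "jac": lambda w: np.ones_like(w)}]
    bounds = [(0.0, 1.0)] * k
    starts = [np.full(k, 1.0 / k)]
    for j in range(k):
        v = np.full(k, 0.1 / (k - 1))
        v[j] = 0.9
        starts.append(v)
    best_w, best_f = None, np.inf
    for x0 in starts:
        res = minimize(neg_obj, x0, jac=neg_grad, method="SLSQP",
                       bounds=bounds, constraints=cons,
                       options={"ftol": tol, "maxiter": 1000})
        if res.fun < best_f - 1e-12:
            best_f, best_w = res.fun, res.x
    # tie-break: the maximum-entropy weight vector among near-optima
    def neg_entropy(w):
        w = np.clip(w, 1e-12, 1.0)
        return float(np.sum(w * np.log(w)))

    cons_tie = cons + [{"type": "ineq",
                        "fun": lambda w: (best_f + 1e-9) - neg_obj(w)}]
    res = minimize(neg_entropy, best_w, method="SLSQP", bounds=bounds,
                   constraints=cons_tie, options={"ftol": 1e-12, "maxiter": 500})
    w = res.x if (res.success and neg_obj(res.x) <= best_f + 1e-6) else best_w
    w = np.clip(w, 0.0, None)
    return w / w.sum()


# ---------------------------------------------------------------------------
# Exact leave-one-out (oracle)
# ---------------------------------------------------------------------------

def exact_loo(dataset: DyadDataset, variant: str,
              priors: PriorLedger | None = None, chains: int = 2,
              warmup: int = 400, draws_per_chain: int = 600, seed: int = 0,
              require_convergence: bool = True) -> LooResult:
    """Exact leave-one-out elpd by refitting once per held-out outcome.

    For each hopelessness observation, the model is refit with that
    outcome's likelihood term removed (its item responses stay in, so the
    latent variables remain informed by the measurement model), and the log
    posterior-predictive density of the held-out category is evaluated.
    Tractable only for small N.
    """
    units = []
    for role in dataset.role_names:
        blk = dataset.roles[role]
        units.extend((role, int(i)) for i in np.flatnonzero(blk.outcome_mask))
    pointwise = np.empty(len(units))
    for u, (role, i) in enumerate(units):
        ds = DyadDataset(
            n_adolescents=dataset.n_adolescents,
            roles={r: (dataset.roles[r].drop_outcome(i) if r == role
                       else dataset.roles[r])
                   for r in dataset.role_names},
        )
        model = LdsIrtModel(ds, variant, priors=priors)
        fit = sample_posterior(model, chains=chains, warmup=warmup,
                               draws_per_chain=draws_per_chain,
                               seed=(int(seed) * 9973 + u) % (2**31))
        if require_convergence:
            report = convergence_gate(fit, include_latent=False)
            if not report.passed:
                raise RuntimeError(f"refit without unit {(role, i)} failed: {report}")
        ll = _heldout_loglik(fit, dataset, variant, role, i)
        pointwise[u] = logsumexp(ll) - np.log(ll.size)
    n = len(units)
    se = float(np.sqrt(n * np.var(pointwise))) if n > 1 else 0.0
    return LooResult(elpd_loo=float(np.sum(pointwise)), se=se,
                     p_loo=float("nan"), p_loo_se=float("nan"),
                     pointwise=pointwise, pareto_k=np.full(n, np.nan),
                     lpd=np.full(n, np.nan), units=units)


def _heldout_loglik(fit: PosteriorDraws, dataset: DyadDataset, variant: str,
                    role: str, i: int) -> np.ndarray:
    blk = dataset.roles[role]
    beta = fit.stacked(f"beta_{role}")
    theta = fit.stacked(f"theta_{role}")[:, i]
    delta = fit.stacked(f"delta_{role}")[:, i]
    c1 = fit.stacked(f"c1_{role}")
    c2 = fit.stacked(f"c2_{role}")
    tpar = theta + delta
    if variant == "adolescent":
        eta = beta[:, 0] * theta
    elif variant == "parent":
        eta = beta[:, 0] * tpar
    elif variant == "multi":
        eta = beta[:, 0] * theta + beta[:, 1] * tpar
    else:
        eta = beta[:, 0] * delta
    return _ordinal_logpmf_draws(
        np.array([blk.outcome[i]]), eta[:, None], c1, c2)[:, 0]


# ---------------------------------------------------------------------------
# Measurement-invariance check
# ---------------------------------------------------------------------------

@dataclass
class InvarianceReport:
    """Shared vs respondent-specific item parameters, compared by LOO over
    item-response likelihoods, with per-item parameter contrasts."""

    comparison: pd.DataFrame
    contrasts: pd.DataFrame
    loo_shared: LooResult
    loo_specific: LooResult


def _item_pointwise_loglik(fit: PosteriorDraws, dataset: DyadDataset) -> PointwiseLogLik:
    """Per-draw log-likelihood of every observed item response."""
    blocks, units = [], []
    specific = "a_adolescent" in fit.params
    for role in dataset.role_names:
        blk = dataset.roles[role]
        theta = fit.stacked(f"theta_{role}")
        delta = fit.stacked(f"delta_{role}")
        sets = (
            ("adolescent", blk.adol_items, blk.adol_mask, theta),
            ("parent", blk.par_items, blk.par_mask, theta + delta),
        )
        for resp, items, mask, trait in sets:
            a = fit.stacked(f"a_{resp}" if specific else "a")
            b = fit.stacked(f"b_{resp}" if specific else "b")
            logit = a[:, None, :] * (trait[:, :, None] - b[:, None, :])
            ll = items[None] * logit - np.logaddexp(0.0, logit)  # (S, n, J)
            rows, cols = np.nonzero(mask)
            blocks.append(ll[:, rows, cols])
            units.extend((f"{role}:{resp}", (int(r), int(c)))
                         for r, c in zip(rows, cols))
    return PointwiseLogLik(ll=np.concatenate(blocks, axis=1), units=units,
                           n_chains=fit.n_chains)


def invariance_check(dataset: DyadDataset, variant: str = "discrepancy",
                     priors: PriorLedger | None = None, chains: int = 2,
                     warmup: int = 400, draws_per_chain: int = 600,
                     seed: int = 0) -> InvarianceReport:
    """Compare shared item parameters against adolescent/parent-specific ones.

    Latent difference scores are only interpretable when both informants'
    responses measure the trait on the same scale; this check fits both
    configurations and compares them by PSIS-LOO over the item-response
    likelihood (the outcome likelihood barely reacts to non-invariance,
    while item fit does). It also reports per-item posterior contrasts
    (parent minus adolescent) of both item parameters with 66%/90% HDIs.
    """
    from .reporting import hdi

    fits = {}
    loos = {}
    for name, by_resp in (("shared", False), ("group_specific", True)):
        model = LdsIrtModel(dataset, variant, priors=priors,
                            item_params_by_respondent=by_resp)
        fit = sample_posterior(model, chains=chains, warmup=warmup,
                               draws_per_chain=draws_per_chain, seed=seed)
        fits[name] = fit
        loos[name] = elpd_loo(_item_pointwise_loglik(fit, dataset))
    comparison = loo_compare(loos)

    gs_fit = fits["group_specific"]
    rows = []
    for pname in ("a", "b"):
        par = gs_fit.stacked(f"{pname}_parent")
        adol = gs_fit.stacked(f"{pname}_adolescent")
        diff = par - adol
        for j in range(diff.shape[1]):
            lo66, hi66 = hdi(diff[:, j], 0.66)
            lo90, hi90 = hdi(diff[:, j], 0.90)
            rows.append(
                {
                    "parameter": pname,
                    "item": j,
                    "contrast_mean": float(diff[:, j].mean()),
                    "hdi66_lower": lo66,
                    "hdi66_upper": hi66,
                    "hdi90_lower": lo90,
                    "hdi90_upper": hi90,
                }
            )
    return InvarianceReport(comparison=comparison, contrasts=pd.DataFrame(rows),
                            loo_shared=loos["shared"],
                            loo_specific=loos["group_specific"])
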