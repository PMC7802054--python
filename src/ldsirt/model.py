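"""Joint probability model: latent difference score 2PL IRT with an ordinal
probit regression of hopelessness on latent quantities.

Measurement model
-----------------
Each binary conflict item j answered by a respondent with latent trait t
follows a two-parameter logistic (2PL) law,

    P(y_j = 1 | t) = logistic(a_j * (t - b_j)),       a_j > 0,

with discrimination a_j and difficulty b_j shared across all four response
sets (adolescent-about-mother, mother, adolescent-about-father, father) —
the measurement-invariance assumption that makes latent difference scores
interpretable.

Structural model
----------------
Per dyad, the adolescent's latent conflict trait theta and the latent
difference score delta are bivariate normal with mean (0, mu_delta), unit
variances and correlation rho; the parent's latent trait is theta + delta,
so delta is the amount by which the parent's representation of conflict
exceeds the adolescent's (negative delta: the parent reports less conflict).

Outcome model
-------------
Clinician-rated hopelessness (1/2/3) follows an ordinal probit regression
with linear predictor eta chosen by the model variant — adolescent trait,
parent trait, both (multi-informant), or the difference score — and ordered
cutpoints c1 < c2, all role-specific.

The module exposes the individual log-density pieces (useful for testing and
for pointwise likelihood computations) and a :class:`LdsIrtModel` that packs
everything into an unconstrained parameter vector with an analytic gradient,
the interface consumed by the Hamiltonian Monte Carlo sampler.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit, log_ndtr, ndtr

from .data import DyadDataset

VARIANTS = ("adolescent", "parent", "multi", "discrepancy")

_LOG_2PI = np.log(2.0 * np.pi)
_INV_SQRT_2PI = 1.0 / np.sqrt(2.0 * np.pi)


def n_coefficients(variant: str) -> int:
    if variant not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}; expected one of {VARIANTS}")
    return 2 if variant == "multi" else 1


# ---------------------------------------------------------------------------
# Elementary log-density pieces
# ---------------------------------------------------------------------------

def loglik_2pl(response, theta, a, b):
    """Log-likelihood of a binary 2PL item response.

    ``log logistic(a*(theta-b))`` for a positive response, the log complement
    otherwise. Vectorises over any broadcastable shapes.
    """
    response = np.asarray(response)
    if not np.isin(response, (0, 1)).all():
        raise ValueError("2PL responses must be binary 0/1")
    if np.any(np.asarray(a) <= 0):
        raise ValueError("discriminations must be positive")
    z = np.asarray(a) * (np.asarray(theta) - np.asarray(b))
    # log sigma(z) = z - softplus(z); log(1-sigma(z)) = -softplus(z)
    return response * z - np.logaddexp(0.0, z)


def parent_trait(theta, delta):
    """Parent latent trait under the latent-difference-score constraint."""
    return np.asarray(theta) + np.asarray(delta)


def latent_prior_logdensity(theta, delta, mu_delta, rho):
    """Log-density of the bivariate-normal latent prior.

    (theta, delta) ~ N((0, mu_delta), [[1, rho], [rho, 1]]).
    """
    rho = float(rho)
    if abs(rho) >= 1:
        raise ValueError("correlation must satisfy |rho| < 1")
    u = np.asarray(theta, dtype=float)
    v = np.asarray(delta, dtype=float) - mu_delta
    omr2 = 1.0 - rho * rho
    quad = (u * u - 2.0 * rho * u * v + v * v) / omr2
    return -_LOG_2PI - 0.5 * np.log(omr2) - 0.5 * quad


def ordinal_probit_logpmf(y, eta, cutpoints):
    """Log-probability of ordered category y in {1, 2, 3} under a probit link.

    Categories have probabilities Phi(c1-eta), Phi(c2-eta)-Phi(c1-eta) and
    1-Phi(c2-eta). Middle-category mass is evaluated on whichever tail keeps
    the subtraction well conditioned.
    """
    c1, c2 = float(cutpoints[0]), float(cutpoints[1])
    if not c1 < c2:
        raise ValueError("cutpoints must be strictly increasing")
    y = np.asarray(y)
    if not np.isin(y, (1, 2, 3)).all():
        raise ValueError("ordinal categories must be in {1, 2, 3}")
    eta = np.asarray(eta, dtype=float)
    x1 = c1 - eta
    x2 = c2 - eta
    lp1 = log_ndtr(x1)
    lp3 = log_ndtr(-x2)
    mid = np.where(x1 + x2 > 0, ndtr(-x1) - ndtr(-x2), ndtr(x2) - ndtr(x1))
    lp2 = np.log(np.clip(mid, 1e-300, None))
    return np.where(y == 1, lp1, np.where(y == 2, lp2, lp3))


def regression_predictor(variant, theta, theta_parent, delta, beta):
    """Linear predictor eta for the hopelessness regression of a variant."""
    beta = np.atleast_1d(np.asarray(beta, dtype=float))
    k = n_coefficients(variant)
    if beta.shape[-1] != k:
        raise ValueError(f"variant {variant!r} takes {k} coefficient(s), got {beta.shape[-1]}")
    if variant == "adolescent":
        return beta[..., 0] * np.asarray(theta)
    if variant == "parent":
        return beta[..., 0] * np.asarray(theta_parent)
    if variant == "multi":
        return beta[..., 0] * np.asarray(theta) + beta[..., 1] * np.asarray(theta_parent)
    return beta[..., 0] * np.asarray(delta)


# ---------------------------------------------------------------------------
# Parameter containers and priors
# ---------------------------------------------------------------------------

@dataclass
class ItemParams:
    """2PL discriminations and difficulties, one shared set per fit."""

    a: np.ndarray
    b: np.ndarray

    def __post_init__(self):
        self.a = np.asarray(self.a, dtype=float)
        self.b = np.asarray(self.b, dtype=float)
        if self.a.shape != self.b.shape:
            raise ValueError("a and b must have the same length")
        if np.any(self.a <= 0):
            raise ValueError("discriminations must be positive")


@dataclass
class RoleParams:
    """Structural and outcome parameters of one parent role."""

    beta: np.ndarray
    cutpoints: np.ndarray
    mu_delta: float
    rho: float
    theta: np.ndarray
    delta: np.ndarray

    def __post_init__(self):
        self.beta = np.atleast_1d(np.asarray(self.beta, dtype=float))
        self.cutpoints = np.asarray(self.cutpoints, dtype=float)
        if not self.cutpoints[0] < self.cutpoints[1]:
            raise ValueError("cutpoints must be strictly increasing")
        if not abs(self.rho) < 1:
            raise ValueError("|rho| must be < 1")
        self.theta = np.asarray(self.theta, dtype=float)
        self.delta = np.asarray(self.delta, dtype=float)


@dataclass
class ParamSet:
    """Full parameter set of one fit: shared item parameters plus one
    :class:`RoleParams` per parent role.

    ``items`` maps respondent group ("all" when parameters are shared, else
    "adolescent"/"parent") to :class:`ItemParams`.
    """

    items: dict
    roles: dict


@dataclass
class PriorLedger:
    """Weakly informative priors for every free parameter, centralised.

    All scales are on the unit-variance latent metric: discriminations are
    LogNormal(0, 0.5); difficulties Normal(0, 2); regression coefficients
    Normal(0, 1); cutpoints independent Normal(0, 2) restricted to the
    ordered region; the discrepancy mean Normal(0, 1); the latent
    correlation uniform on (-1, 1).
    """

    a_log_mean: float = 0.0
    a_log_sd: float = 0.5
    b_sd: float = 2.0
    beta_sd: float = 1.0
    cutpoint_sd: float = 2.0
    mu_delta_sd: float = 1.0

    def to_dict(self) -> dict:
        return {
            "a": f"LogNormal({self.a_log_mean}, {self.a_log_sd})",
            "b": f"Normal(0, {self.b_sd})",
            "beta": f"Normal(0, {self.beta_sd})",
            "cutpoints": f"ordered Normal(0, {self.cutpoint_sd})",
            "mu_delta": f"Normal(0, {self.mu_delta_sd})",
            "rho": "Uniform(-1, 1)",
        }


# ---------------------------------------------------------------------------
# Joint model
# ---------------------------------------------------------------------------

def _norm_lp(x, sd):
    x = np.asarray(x, dtype=float)
    return float(np.sum(-0.5 * (x / sd) ** 2 - np.log(sd) - 0.5 * _LOG_2PI))


def joint_logdensity(dataset: DyadDataset, params: ParamSet, variant: str,
                     priors: PriorLedger | None = None) -> float:
    """Joint log-density (likelihood + latent prior + parameter priors).

    Sums 2PL log-likelihoods over observed items in all response sets, the
    bivariate-normal latent prior per dyad, the ordinal probit outcome
    likelihood per role (masked outcomes contribute nothing), and the prior
    log-densities from the ledger. Natural-scale entry point; the sampler
    uses the packed unconstrained version in :class:`LdsIrtModel`.
    """
    priors = priors or PriorLedger()
    total = 0.0
    for role in dataset.role_names:
        blk = dataset.roles[role]
        rp: RoleParams = params.roles[role]
        ip_adol = params.items["all"] if "all" in params.items else params.items["adolescent"]
        ip_par = params.items["all"] if "all" in params.items else params.items["parent"]
        tpar = parent_trait(rp.theta, rp.delta)
        for items, mask, ip, trait in (
            (blk.adol_items, blk.adol_mask, ip_adol, rp.theta),
            (blk.par_items, blk.par_mask, ip_par, tpar),
        ):
            ll = loglik_2pl(items, trait[:, None], ip.a[None, :], ip.b[None, :])
            total += float(np.sum(ll[mask]))
        total += float(np.sum(latent_prior_logdensity(rp.theta, rp.delta, rp.mu_delta, rp.rho)))
        eta = regression_predictor(variant, rp.theta, tpar, rp.delta, rp.beta)
        lp_out = ordinal_probit_logpmf(blk.outcome, eta, rp.cutpoints)
        total += float(np.sum(lp_out[blk.outcome_mask]))
        total += _norm_lp(rp.beta, priors.beta_sd)
        total += _norm_lp(rp.cutpoints, priors.cutpoint_sd)
        total += _norm_lp(rp.mu_delta, priors.mu_delta_sd)
        total += float(-np.log(2.0))  # Uniform(-1,1) density for rho
    seen = []
    for key, ip in params.items.items():
        if any(ip is s for s in seen):
            continue
        seen.append(ip)
        total += _norm_lp(np.log(ip.a) - priors.a_log_mean, priors.a_log_sd)
        total += float(-np.sum(np.log(ip.a)))  # LogNormal Jacobian on the a scale
        total += _norm_lp(ip.b, priors.b_sd)
    return total


class LdsIrtModel:
    """Packed unconstrained parameterisation of the joint model.

    Layout of the unconstrained vector z::

        [log_a, b] per item group, then per role:
        [beta (1 or 2), c1, log(c2 - c1), mu_delta, atanh(rho),
         theta (n dyads), delta (n dyads)]

    ``item_params_by_respondent=True`` gives adolescent and parent response
    sets their own item parameters (used by the measurement-invariance
    check); the default shares one set, as the latent-difference-score
    interpretation requires.
    """

    def __init__(self, dataset: DyadDataset, variant: str,
                 priors: PriorLedger | None = None,
                 item_params_by_respondent: bool = False):
        if variant not in VARIANTS:
            raise ValueError(f"unknown variant {variant!r}")
        self.dataset = dataset
        self.variant = variant
        self.priors = priors or PriorLedger()
        self.by_respondent = bool(item_params_by_respondent)
        self.n_items = dataset.n_items
        self.roles = dataset.role_names
        self.n_beta = n_coefficients(variant)
        self.item_groups = ["adolescent", "parent"] if self.by_respondent else ["all"]

        self._index = {}
        pos = 0
        for g in self.item_groups:
            self._index[f"log_a_{g}"] = slice(pos, pos + self.n_items)
            pos += self.n_items
            self._index[f"b_{g}"] = slice(pos, pos + self.n_items)
            pos += self.n_items
        for role in self.roles:
            n = dataset.roles[role].n_dyads
            self._index[f"beta_{role}"] = slice(pos, pos + self.n_beta)
            pos += self.n_beta
            self._index[f"c1_{role}"] = pos
            pos += 1
            self._index[f"logdc_{role}"] = pos
            pos += 1
            self._index[f"mu_delta_{role}"] = pos
            pos += 1
            self._index[f"zrho_{role}"] = pos
            pos += 1
            self._index[f"theta_{role}"] = slice(pos, pos + n)
            pos += n
            self._index[f"delta_{role}"] = slice(pos, pos + n)
            pos += n
        self.dim = pos

    # -- parameter transforms ------------------------------------------------

    def unpack(self, z: np.ndarray) -> ParamSet:
        """Map an unconstrained vector to natural-scale parameters."""
        z = np.asarray(z, dtype=float)
        items = {}
        for g in self.item_groups:
            items[g] = ItemParams(a=np.exp(z[self._index[f"log_a_{g}"]]),
                                  b=z[self._index[f"b_{g}"]].copy())
        roles = {}
        for role in self.roles:
            c1 = z[self._index[f"c1_{role}"]]
            c2 = c1 + np.exp(z[self._index[f"logdc_{role}"]])
            roles[role] = RoleParams(
                beta=z[self._index[f"beta_{role}"]].copy(),
                cutpoints=np.array([c1, c2]),
                mu_delta=float(z[self._index[f"mu_delta_{role}"]]),
                rho=float(np.tanh(z[self._index[f"zrho_{role}"]])),
                theta=z[self._index[f"theta_{role}"]].copy(),
                delta=z[self._index[f"delta_{role}"]].copy(),
            )
        return ParamSet(items=items, roles=roles)

    def pack(self, params: ParamSet) -> np.ndarray:
        z = np.zeros(self.dim)
        for g in self.item_groups:
            ip = params.items[g] if g in params.items else params.items["all"]
            z[self._index[f"log_a_{g}"]] = np.log(ip.a)
            z[self._index[f"b_{g}"]] = ip.b
        for role in self.roles:
            rp = params.roles[role]
            z[self._index[f"beta_{role}"]] = rp.beta
            z[self._index[f"c1_{role}"]] = rp.cutpoints[0]
            z[self._index[f"logdc_{role}"]] = np.log(rp.cutpoints[1] - rp.cutpoints[0])
            z[self._index[f"mu_delta_{role}"]] = rp.mu_delta
            z[self._index[f"zrho_{role}"]] = np.arctanh(rp.rho)
            z[self._index[f"theta_{role}"]] = rp.theta
            z[self._index[f"delta_{role}"]] = rp.delta
        return z

    def initial_value(self, rng: np.random.Generator, jitter: float = 0.5) -> np.ndarray:
        """Random initialisation: modest draws around the prior centres."""
        z = rng.normal(scale=jitter, size=self.dim)
        for role in self.roles:
            z[self._index[f"c1_{role}"]] = -0.5 + jitter * rng.normal()
            z[self._index[f"logdc_{role}"]] = jitter * rng.normal() * 0.2
            z[self._index[f"zrho_{role}"]] = 0.2 * jitter * rng.normal()
        return z

    # -- log-density and gradient -------------------------------------------

    def logp(self, z: np.ndarray) -> float:
        return self.logp_grad(z)[0]

    def logp_grad(self, z: np.ndarray):
        """Joint log-density (including transform Jacobians) and its gradient."""
        z = np.asarray(z, dtype=float)
        g = np.zeros_like(z)
        pr = self.priors
        total = 0.0

        item_cache = {}
        for grp in self.item_groups:
            sl_a = self._index[f"log_a_{grp}"]
            sl_b = self._index[f"b_{grp}"]
            log_a = z[sl_a]
            a = np.exp(log_a)
            b = z[sl_b]
            item_cache[grp] = (a, b, sl_a, sl_b)
            # prior on log a: Normal(mu, sd) == LogNormal on a (incl. Jacobian)
            total += _norm_lp(log_a - pr.a_log_mean, pr.a_log_sd)
            g[sl_a] += -(log_a - pr.a_log_mean) / pr.a_log_sd**2
            total += _norm_lp(b, pr.b_sd)
            g[sl_b] += -b / pr.b_sd**2

        grp_adol = "adolescent" if self.by_respondent else "all"
        grp_par = "parent" if self.by_respondent else "all"

        for role in self.roles:
            blk = self.dataset.roles[role]
            sl_th = self._index[f"theta_{role}"]
            sl_de = self._index[f"delta_{role}"]
            sl_be = self._index[f"beta_{role}"]
            i_c1 = self._index[f"c1_{role}"]
            i_dc = self._index[f"logdc_{role}"]
            i_mu = self._index[f"mu_delta_{role}"]
            i_zr = self._index[f"zrho_{role}"]

            theta = z[sl_th]
            delta = z[sl_de]
            beta = z[sl_be]
            c1 = z[i_c1]
            dc = np.exp(z[i_dc])
            c2 = c1 + dc
            mu = z[i_mu]
            zr = z[i_zr]
            # clip so 1 - rho^2 never underflows to 0 when warmup explores
            # extreme zr; such points have vanishing posterior mass anyway
            rho = float(np.clip(np.tanh(zr), -1 + 1e-10, 1 - 1e-10))
            tpar = theta + delta

            # --- 2PL likelihoods over the two response sets
            for items, mask, grp, trait, grad_targets in (
                (blk.adol_items, blk.adol_mask, grp_adol, theta, (sl_th,)),
                (blk.par_items, blk.par_mask, grp_par, tpar, (sl_th, sl_de)),
            ):
                a, b, sl_a, sl_b = item_cache[grp]
                logit = a[None, :] * (trait[:, None] - b[None, :])
                ll = items * logit - np.logaddexp(0.0, logit)
                total += float(np.sum(ll[mask]))
                resid = mask * (items - expit(logit))  # d ll / d logit
                g_trait = resid @ a
                for sl in grad_targets:
                    g[sl] += g_trait
                g[sl_a] += (resid * (trait[:, None] - b[None, :])).sum(0) * a  # chain to log a
                g[sl_b] += -resid.sum(0) * a

            # --- bivariate-normal latent prior
            u = theta
            v = delta - mu
            omr2 = 1.0 - rho * rho
            quad = u * u - 2.0 * rho * u * v + v * v
            n = len(u)
            total += float(-n * _LOG_2PI - 0.5 * n * np.log(omr2) - 0.5 * np.sum(quad) / omr2)
            du = -(u - rho * v) / omr2
            dv = -(v - rho * u) / omr2
            g[sl_th] += du
            g[sl_de] += dv
            g[i_mu] += -np.sum(dv)
            # d/drho of [-n/2 log(1-rho^2) - sum(quad)/(2(1-rho^2))]
            drho = n * rho / omr2 + float(np.sum(u * v)) / omr2 \
                - rho * float(np.sum(quad)) / omr2**2
            g[i_zr] += drho * omr2  # chain rule: drho/dzr = 1 - rho^2

            # rho ~ Uniform(-1,1): log Jacobian of tanh
            total += float(np.log(omr2)) - np.log(2.0)
            g[i_zr] += -2.0 * rho

            # --- ordinal probit outcome likelihood
            eta = regression_predictor(self.variant, theta, tpar, delta, beta)
            y = blk.outcome
            omask = blk.outcome_mask
            x1 = c1 - eta
            x2 = c2 - eta
            pdf1 = _INV_SQRT_2PI * np.exp(-0.5 * x1 * x1)
            pdf2 = _INV_SQRT_2PI * np.exp(-0.5 * x2 * x2)
            lp1 = log_ndtr(x1)
            lp3 = log_ndtr(-x2)
            mid = np.where(x1 + x2 > 0, ndtr(-x1) - ndtr(-x2), ndtr(x2) - ndtr(x1))
            mid = np.clip(mid, 1e-300, None)
            lp = np.where(y == 1, lp1, np.where(y == 2, np.log(mid), lp3))
            total += float(np.sum(lp[omask]))
            # d lp / d eta, c1, c2 by category
            r1 = pdf1 / np.clip(ndtr(x1), 1e-300, None)
            r3 = pdf2 / np.clip(ndtr(-x2), 1e-300, None)
            deta = np.where(y == 1, -r1, np.where(y == 2, (pdf1 - pdf2) / mid, r3))
            dc1 = np.where(y == 1, r1, np.where(y == 2, -pdf1 / mid, 0.0))
            dc2 = np.where(y == 1, 0.0, np.where(y == 2, pdf2 / mid, -r3))
            deta = deta * omask
            dc1 = dc1 * omask
            dc2 = dc2 * omask
            # eta gradients by variant
            if self.variant == "adolescent":
                g[sl_be] += np.array([np.sum(deta * theta)])
                g[sl_th] += deta * beta[0]
            elif self.variant == "parent":
                g[sl_be] += np.array([np.sum(deta * tpar)])
                g[sl_th] += deta * beta[0]
                g[sl_de] += deta * beta[0]
            elif self.variant == "multi":
                g[sl_be] += np.array([np.sum(deta * theta), np.sum(deta * tpar)])
                g[sl_th] += deta * (beta[0] + beta[1])
                g[sl_de] += deta * beta[1]
            else:  # discrepancy
                g[sl_be] += np.array([np.sum(deta * delta)])
                g[sl_de] += deta * beta[0]
            sum_dc1 = np.sum(dc1)
            sum_dc2 = np.sum(dc2)
            g[i_c1] += sum_dc1 + sum_dc2  # c2 = c1 + exp(logdc)
            g[i_dc] += sum_dc2 * dc

            # --- priors on role parameters
            total += _norm_lp(beta, pr.beta_sd)
            g[sl_be] += -beta / pr.beta_sd**2
            total += _norm_lp(np.array([c1, c2]), pr.cutpoint_sd)
            g[i_c1] += -(c1 + c2) / pr.cutpoint_sd**2
            g[i_dc] += -(c2 / pr.cutpoint_sd**2) * dc
            total += float(z[i_dc])  # Jacobian of c2 = c1 + exp(logdc)
            g[i_dc] += 1.0
            total += _norm_lp(mu, pr.mu_delta_sd)
            g[i_mu] += -mu / pr.mu_delta_sd**2

        return total, g


def make_param_set(model: LdsIrtModel, a, b, beta, cutpoints, mu_delta, rho,
                   theta=None, delta=None) -> ParamSet:
    """Convenience constructor sharing the same values across roles."""
    items = {g: ItemParams(a=a, b=b) for g in model.item_groups}
    roles = {}
    for role in model.roles:
        n = model.dataset.roles[role].n_dyads
        roles[role] = RoleParams(
            beta=beta,
            cutpoints=cutpoints,
            mu_delta=mu_delta,
            rho=rho,
            theta=np.zeros(n) if theta is None else np.asarray(theta, float)[:n],
            delta=np.zeros(n) if delta is None else np.asarray(delta, float)[:n],
        )
    return ParamSet(items=items, roles=roles)
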