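"""Bayesian intraclass correlation for two raters of a 3-level clinical item.

A one-way random-effects model treats the 1-3 scores as continuous:

    y_ij = mu + b_i + e_ij,   b_i ~ N(0, sigma_b^2),  e_ij ~ N(0, sigma_w^2)

with half-normal priors on both standard deviations; the ICC posterior is
sigma_b^2 / (sigma_b^2 + sigma_w^2), bounded in [0, 1] by construction.
Sampling uses the package's NUTS engine on a non-centred parameterisation.
This is documented as an interpretation of the reliability analysis design
(two blinded clinicians re-scoring the same interviews), not a claim about
the original computation's exact likelihood.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import nuts
from .reporting import hdi


@dataclass
class RatingTable:
    """Two raters' scores (1-3) per subject."""

    subjects: np.ndarray
    rater1: np.ndarray
    rater2: np.ndarray

    def __post_init__(self):
        self.subjects = np.asarray(self.subjects)
        self.rater1 = np.asarray(self.rater1, dtype=float)
        self.rater2 = np.asarray(self.rater2, dtype=float)
        n = len(self.subjects)
        if len(self.rater1) != n or len(self.rater2) != n:
            raise ValueError("ratings must align with subjects")
        scores = np.concatenate([self.rater1, self.rater2])
        if not np.isin(scores, (1, 2, 3)).all():
            raise ValueError("scores must be in {1, 2, 3}")

    @classmethod
    def from_csv(cls, path) -> "RatingTable":
        df = pd.read_csv(path)
        return cls(df["subject"].to_numpy(), df["rater1"].to_numpy(),
                   df["rater2"].to_numpy())

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)


@dataclass
class IccResult:
    draws: np.ndarray
    mean: float
    hdi66: tuple
    hdi90: tuple
    boundary_warning: bool = False

    def to_dict(self) -> dict:
        return {
            "posterior_mean": self.mean,
            "hdi66": list(self.hdi66),
            "hdi90": list(self.hdi90),
            "n_draws": int(self.draws.size),
        }


class _OneWayRandomEffects:
    """Packed model: z = [mu, log sigma_b, log sigma_w, u_1..u_n]."""

    def __init__(self, y: np.ndarray, prior_sd: float = 2.0,
                 mu_loc: float = 2.0, mu_sd: float = 2.0):
        self.y = np.asarray(y, dtype=float)  # (n, 2)
        self.n = self.y.shape[0]
        self.prior_sd = prior_sd
        self.mu_loc = mu_loc
        self.mu_sd = mu_sd
        self.dim = 3 + self.n

    def initial_value(self, rng, jitter: float = 0.5):
        z = rng.normal(scale=0.2 * jitter, size=self.dim)
        z[0] += self.y.mean()
        z[1] -= 0.5
        z[2] -= 0.5
        return z

    def logp_grad(self, z):
        mu, lsb, lsw = z[0], z[1], z[2]
        u = z[3:]
        sb, sw = np.exp(lsb), np.exp(lsw)
        b = sb * u  # non-centred subject effects
        resid = self.y - (mu + b)[:, None]
        m = self.y.shape[1]

        lp = -0.5 * np.sum(resid**2) / sw**2 - self.n * m * (lsw + 0.5 * np.log(2 * np.pi))
        lp += -0.5 * np.sum(u**2)  # u ~ N(0,1)
        # half-normal priors on sigma (log-scale sampling Jacobian included)
        lp += -0.5 * (sb / self.prior_sd) ** 2 + lsb
        lp += -0.5 * (sw / self.prior_sd) ** 2 + lsw
        lp += -0.5 * ((mu - self.mu_loc) / self.mu_sd) ** 2

        g = np.zeros_like(z)
        r_over = resid / sw**2
        row = r_over.sum(axis=1)
        g[0] = np.sum(row) - (mu - self.mu_loc) / self.mu_sd**2
        g[3:] = row * sb - u
        g[1] = np.sum(row * u) * sb - (sb / self.prior_sd) ** 2 + 1.0
        g[2] = np.sum(resid**2) / sw**2 - self.n * m - (sw / self.prior_sd) ** 2 + 1.0
        return float(lp), g


def icc_bayes(ratings, prior_sd: float = 2.0, chains: int = 2,
              warmup: int = 500, draws_per_chain: int = 1000,
              seed: int = 0) -> IccResult:
    """Posterior of the intraclass correlation from two raters' scores.

    ``ratings`` is a :class:`RatingTable` (1-3 clinical scores) or a raw
    ``(n_subjects, 2)`` array of continuous scores, the latter mainly for
    simulation studies of the variance-components model itself. Requires at
    least 5 subjects. When all ratings are identical the residual variance
    is unidentified and a boundary warning is attached.
    """
    if isinstance(ratings, RatingTable):
        y = np.stack([ratings.rater1, ratings.rater2], axis=1)
    else:
        y = np.asarray(ratings, dtype=float)
        if y.ndim != 2 or y.shape[1] != 2:
            raise ValueError("expected a RatingTable or an (n, 2) array")
    if y.shape[0] < 5:
        raise ValueError("need at least 5 subjects")
    boundary = bool(np.ptp(y) == 0)
    if boundary:
        warnings.warn("all ratings identical: ICC posterior driven by priors")
    model = _OneWayRandomEffects(y, prior_sd=prior_sd)
    draws = []
    for c in range(chains):
        rng = np.random.default_rng(np.random.SeedSequence([int(seed), c]))
        res = nuts.sample_chain(model.logp_grad, model.initial_value(rng),
                                warmup, draws_per_chain, rng)
        sb2 = np.exp(2 * res.draws[:, 1])
        sw2 = np.exp(2 * res.draws[:, 2])
        draws.append(sb2 / (sb2 + sw2))
    icc = np.concatenate(draws)
    return IccResult(
        draws=icc,
        mean=float(icc.mean()),
        hdi66=hdi(icc, 0.66),
        hdi90=hdi(icc, 0.90),
        boundary_warning=boundary,
    )
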