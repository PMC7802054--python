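"""Posterior sampling and convergence diagnostics.

``sample_posterior`` runs independent NUTS chains over the packed
unconstrained parameter vector of an :class:`~ldsirt.model.LdsIrtModel`
(or any object exposing ``dim``, ``logp_grad``, ``initial_value`` and
``unpack``) and returns a chain-structured :class:`PosteriorDraws` on the
natural parameter scale. Split-R-hat and effective sample size are computed
with arviz; ``convergence_gate`` applies the R-hat < 1.01, zero-divergence
acceptance rule.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np

from . import nuts

with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    import arviz as az


@dataclass
class PosteriorDraws:
    """Posterior draws indexed by (chain, iteration) per parameter.

    ``params`` maps a parameter name to an array of shape
    ``(chains, draws)`` or ``(chains, draws, k)`` for vector parameters.
    """

    params: dict
    meta: dict = field(default_factory=dict)

    @property
    def n_chains(self) -> int:
        return next(iter(self.params.values())).shape[0]

    @property
    def n_draws(self) -> int:
        return next(iter(self.params.values())).shape[1]

    @property
    def total_draws(self) -> int:
        return self.n_chains * self.n_draws

    def stacked(self, name: str) -> np.ndarray:
        """All chains concatenated: shape (chains*draws,) or (chains*draws, k)."""
        arr = self.params[name]
        return arr.reshape(arr.shape[0] * arr.shape[1], *arr.shape[2:])

    def scalar_names(self):
        """Expanded names, vector parameters suffixed with their index."""
        out = []
        for name, arr in self.params.items():
            if arr.ndim == 2:
                out.append(name)
            else:
                out.extend(f"{name}[{i}]" for i in range(arr.shape[2]))
        return out

    def scalar_array(self, name: str) -> np.ndarray:
        """(chains, draws) array for an expanded scalar name."""
        if name in self.params and self.params[name].ndim == 2:
            return self.params[name]
        base, idx = name.rsplit("[", 1)
        return self.params[base][:, :, int(idx[:-1])]

    def to_inference_data(self):
        return az.from_dict(posterior=self.params)

    def save(self, prefix) -> None:
        """Persist draws as one CSV per chain plus a JSON metadata sidecar."""
        import pandas as pd

        names = self.scalar_names()
        for c in range(self.n_chains):
            cols = {n: self.scalar_array(n)[c] for n in names}
            pd.DataFrame(cols).to_csv(f"{prefix}_chain{c}.csv", index=False)
        with open(f"{prefix}_meta.json", "w") as fh:
            json.dump({**self.meta, "n_chains": self.n_chains,
                       "n_draws": self.n_draws}, fh, indent=1, default=str)


def sample_posterior(model, chains: int = 4, warmup: int = 1000,
                     draws_per_chain: int = 2500, seed: int = 0,
                     target_accept: float = 0.8,
                     max_treedepth: int = 10) -> PosteriorDraws:
    """Draw posterior samples with NUTS; defaults follow the published
    analysis (4 chains, 1,000 warmup iterations, 2,500 draws per chain).

    Chains run sequentially with independent seeded generators, so reruns
    with the same seed reproduce draws exactly.
    """
    chain_results = []
    raw = np.empty((chains, draws_per_chain, model.dim))
    for c in range(chains):
        rng = np.random.default_rng(np.random.SeedSequence([int(seed), c]))
        x0 = model.initial_value(rng)
        res = nuts.sample_chain(
            model.logp_grad, x0, warmup, draws_per_chain, rng,
            max_treedepth=max_treedepth, target_accept=target_accept)
        raw[c] = res.draws
        chain_results.append(res)

    params = _expand_draws(model, raw)
    meta = {
        "seed": int(seed),
        "warmup": warmup,
        "draws_per_chain": draws_per_chain,
        "chains": chains,
        "divergences": [r.divergences for r in chain_results],
        "step_size": [r.step_size for r in chain_results],
        "mean_accept": [r.mean_accept for r in chain_results],
        "variant": getattr(model, "variant", None),
    }
    return PosteriorDraws(params=params, meta=meta)


def _expand_draws(model, raw: np.ndarray) -> dict:
    """Natural-scale parameter arrays from packed unconstrained draws."""
    chains, draws, _ = raw.shape
    flat = raw.reshape(chains * draws, -1)
    idx = model._index
    params = {}

    def take(key):
        sl = idx[key]
        if isinstance(sl, slice):
            return flat[:, sl].reshape(chains, draws, -1)
        return flat[:, sl].reshape(chains, draws)

    for g in model.item_groups:
        suffix = "" if g == "all" else f"_{g}"
        params[f"a{suffix}"] = np.exp(take(f"log_a_{g}"))
        params[f"b{suffix}"] = take(f"b_{g}")
    for role in model.roles:
        params[f"beta_{role}"] = take(f"beta_{role}")
        c1 = take(f"c1_{role}")
        c2 = c1 + np.exp(take(f"logdc_{role}"))
        params[f"c1_{role}"] = c1
        params[f"c2_{role}"] = c2
        params[f"mu_delta_{role}"] = take(f"mu_delta_{role}")
        params[f"rho_{role}"] = np.tanh(take(f"zrho_{role}"))
        params[f"theta_{role}"] = take(f"theta_{role}")
        params[f"delta_{role}"] = take(f"delta_{role}")
    return params


def rhat(draws: np.ndarray) -> float:
    """Split rank-normalised potential scale reduction for one parameter.

    ``draws`` has shape (chains, iterations). Returns NaN when the draws are
    constant (R-hat undefined).
    """
    draws = np.asarray(draws, dtype=float)
    if draws.ndim != 2 or draws.shape[0] < 2 or draws.shape[1] < 4:
        raise ValueError("need (chains >= 2, iterations >= 4) draws")
    if np.ptp(draws) == 0:
        return float("nan")
    return float(az.rhat(az.convert_to_dataset(draws))["x"].values)


def ess(draws: np.ndarray) -> float:
    """Bulk effective sample size; NaN for constant draws."""
    draws = np.asarray(draws, dtype=float)
    if draws.ndim == 1:
        draws = draws[np.newaxis, :]
    if draws.shape[1] < 4:
        raise ValueError("need at least 4 iterations")
    if np.ptp(draws) == 0:
        return float("nan")
    return float(az.ess(az.convert_to_dataset(draws))["x"].values)


@dataclass
class ConvergenceReport:
    passed: bool
    max_rhat: float
    offenders: list
    divergences: int

    def __str__(self) -> str:
        status = "PASS" if self.passed else "FAIL"
        msg = f"convergence {status}: max R-hat {self.max_rhat:.4f}, " \
              f"{self.divergences} divergences"
        if self.offenders:
            msg += "; offenders: " + ", ".join(self.offenders[:10])
        return msg


def convergence_gate(draws: PosteriorDraws, rhat_threshold: float = 1.01,
                     include_latent: bool = True) -> ConvergenceReport:
    """Check R-hat < threshold for every parameter and zero divergences."""
    names = draws.scalar_names()
    if not include_latent:
        names = [n for n in names if not n.startswith(("theta", "delta"))]
    if not names:
        raise ValueError("no parameters to check")
    offenders = []
    max_rhat = -np.inf
    idata = draws.to_inference_data()
    rhats = az.rhat(idata)
    for name, arr in rhats.data_vars.items():
        if not include_latent and name.startswith(("theta", "delta")):
            continue
        vals = np.atleast_1d(arr.values)
        for i, v in enumerate(vals):
            label = name if vals.size == 1 else f"{name}[{i}]"
            if np.isnan(v):
                continue
            max_rhat = max(max_rhat, float(v))
            if v >= rhat_threshold:
                offenders.append(label)
    div = int(np.sum(draws.meta.get("divergences", [0])))
    if div > 0:
        offenders.append(f"{div} divergent transitions")
    return ConvergenceReport(
        passed=not offenders,
        max_rhat=float(max_rhat),
        offenders=offenders,
        divergences=div,
    )
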