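"""Posterior summaries: HDIs, tail and contrast probabilities, summary
tables, and stacked predictive category distributions."""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import ndtr

from .inference import PosteriorDraws, ess


def hdi(samples, mass: float = 0.90):
    """Shortest contiguous interval containing the given posterior mass.

    Computed by sliding a window of ceil(mass * S) order statistics over the
    sorted sample and picking the narrowest.
    """
    if not 0.0 < mass < 1.0:
        raise ValueError("mass must lie in (0, 1)")
    x = np.sort(np.asarray(samples, dtype=float).ravel())
    s = x.size
    if s < 2:
        raise ValueError("need at least 2 samples")
    k = min(int(math.ceil(mass * s)), s)
    widths = x[k - 1:] - x[: s - k + 1]
    j = int(np.argmin(widths))
    return float(x[j]), float(x[j + k - 1])


def posterior_prob_below(samples, threshold: float) -> float:
    """Fraction of draws strictly below the threshold (ties count as not below)."""
    x = np.asarray(samples, dtype=float)
    if x.size == 0:
        raise ValueError("empty sample")
    return float(np.mean(x < threshold))


def contrast_prob(samples_a, samples_b):
    """Paired posterior contrast of two parameters from one joint fit.

    Returns ``(mean difference a-b, sd of difference, P(a < b))``; ties
    count against ``a < b`` (strict inequality).
    """
    a = np.asarray(samples_a, dtype=float)
    b = np.asarray(samples_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired draws must have equal length")
    d = a - b
    return float(d.mean()), float(d.std()), float(np.mean(a < b))


def summary_table(draws: PosteriorDraws, parameters=None) -> pd.DataFrame:
    """Table-style posterior summary: mean, SD, median, 66%/90% HDIs, ESS."""
    names = parameters or [n for n in draws.scalar_names()
                           if not n.startswith(("theta", "delta"))]
    rows = []
    for name in names:
        arr = draws.scalar_array(name)
        flat = arr.ravel()
        if np.ptp(flat) == 0:
            lo66 = hi66 = lo90 = hi90 = float(flat[0])
            ess_val = float("nan")
        else:
            lo66, hi66 = hdi(flat, 0.66)
            lo90, hi90 = hdi(flat, 0.90)
            ess_val = ess(arr)
        rows.append(
            {
                "parameter": name,
                "mean": float(flat.mean()),
                "sd": float(flat.std()),
                "median": float(np.median(flat)),
                "hdi66_lower": lo66,
                "hdi66_upper": hi66,
                "hdi90_lower": lo90,
                "hdi90_upper": hi90,
                "ess": ess_val,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class PredictiveCurve:
    """Stacked posterior-predictive category probabilities over a grid."""

    grid: np.ndarray
    probs: np.ndarray  # (n_grid, 3) mean category probabilities
    bands: dict  # mass -> (lower, upper) arrays of shape (n_grid, 3)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "delta": self.grid,
                "p1": self.probs[:, 0],
                "p2": self.probs[:, 1],
                "p3": self.probs[:, 2],
            }
        )
        for mass, (lo, hi) in self.bands.items():
            tag = int(round(mass * 100))
            for c in range(3):
                df[f"p{c + 1}_lo{tag}"] = lo[:, c]
                df[f"p{c + 1}_hi{tag}"] = hi[:, c]
        return df


def plot_predictive(curve: "PredictiveCurve", path, role: str = "",
                    band_mass: float = 0.90) -> None:
    """Save a plot of the stacked predictive category probabilities across
    the discrepancy range, with an HDI band per category."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    labels = ["absent", "subclinical", "clinical"]
    fig, ax = plt.subplots(figsize=(6, 4))
    for c in range(3):
        ax.plot(curve.grid, curve.probs[:, c], label=labels[c])
        if band_mass in curve.bands:
            lo, hi = curve.bands[band_mass]
            ax.fill_between(curve.grid, lo[:, c], hi[:, c], alpha=0.2)
    ax.set_xlabel("latent difference score (parent - adolescent)")
    ax.set_ylabel("predicted hopelessness probability")
    if role:
        ax.set_title(f"{role} dyads")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def _category_probs(eta, c1, c2):
    p1 = ndtr(c1 - eta)
    p2 = ndtr(c2 - eta) - p1
    return np.stack([p1, p2, 1.0 - p1 - p2], axis=-1)


def stacked_predictive(fits: dict, weights, role: str, delta_grid,
                       theta: float = 0.0, seed: int = 0,
                       band_masses=(0.66, 0.90)) -> PredictiveCurve:
    """Predictive hopelessness distribution of the stacked model ensemble.

    ``fits`` maps variant name to its :class:`PosteriorDraws`; ``weights``
    are stacking weights over the same variants (any simplex-conforming
    mapping or array). Draws are combined by proportional subsampling:
    ceil(w_k * S) deterministic draws from model k. The linear predictor
    holds the adolescent trait fixed (default: the latent mean, 0) and
    sweeps the difference score over ``delta_grid``.
    """
    variants = list(fits)
    w = np.asarray([weights[v] for v in variants] if isinstance(weights, dict)
                   else weights, dtype=float)
    if w.shape != (len(variants),) or np.any(w < 0) or abs(w.sum() - 1) > 1e-8:
        raise ValueError("weights must be a simplex over the fitted models")
    grid = np.asarray(delta_grid, dtype=float)
    if grid.size == 0:
        raise ValueError("empty grid")

    rng = np.random.default_rng(seed)
    pieces = []
    for v, wk in zip(variants, w):
        if wk <= 0:
            continue
        fit = fits[v]
        s = fit.total_draws
        take = min(int(math.ceil(wk * s)), s)
        idx = rng.choice(s, size=take, replace=False)
        beta = fit.stacked(f"beta_{role}")[idx]
        c1 = fit.stacked(f"c1_{role}")[idx]
        c2 = fit.stacked(f"c2_{role}")[idx]
        tpar = theta + grid[None, :]
        if v == "adolescent":
            eta = np.broadcast_to(beta[:, [0]] * theta, (take, grid.size))
        elif v == "parent":
            eta = beta[:, [0]] * tpar
        elif v == "multi":
            eta = beta[:, [0]] * theta + beta[:, [1]] * tpar
        else:
            eta = beta[:, [0]] * grid[None, :]
        pieces.append(_category_probs(eta, c1[:, None], c2[:, None]))
    allp = np.concatenate(pieces, axis=0)  # (draws, n_grid, 3)
    mean = allp.mean(axis=0)
    bands = {}
    for mass in band_masses:
        lo = np.empty_like(mean)
        hi = np.empty_like(mean)
        for gi in range(grid.size):
            for c in range(3):
                lo[gi, c], hi[gi, c] = hdi(allp[:, gi, c], mass)
        bands[mass] = (lo, hi)
    return PredictiveCurve(grid=grid, probs=mean, bands=bands)
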