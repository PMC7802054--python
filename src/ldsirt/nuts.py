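"""Dynamic Hamiltonian Monte Carlo (multinomial NUTS) in plain numpy.

A self-contained implementation of the No-U-Turn sampler with dual-averaging
step-size adaptation and windowed diagonal mass-matrix estimation, the
standard dynamic-HMC recipe. It takes any callable returning the log-density
and its gradient on an unconstrained space and is deliberately generic: the
latent-difference-score model, the ICC variance-components model and the
test-suite toy posteriors all run through the same code path.

Numerical conventions: trajectories diverge when the Hamiltonian error
exceeds 1000; trees are doubled to at most ``max_treedepth``; the mass
matrix is diagonal, estimated from warmup draws in expanding windows with
the estimate shrunk slightly toward unity for stability.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

_MAX_DELTA_H = 1000.0


@dataclass
class ChainResult:
    """Post-warmup draws of one chain plus sampler metadata."""

    draws: np.ndarray  # (n_draws, dim)
    logp: np.ndarray  # (n_draws,)
    divergences: int
    step_size: float
    inv_mass: np.ndarray
    mean_accept: float


class _DualAveraging:
    """Nesterov dual averaging targeting a given acceptance statistic."""

    def __init__(self, eps0: float, target: float = 0.8,
                 gamma: float = 0.05, t0: float = 10.0, kappa: float = 0.75):
        self.mu = np.log(10.0 * eps0)
        self.target = target
        self.gamma = gamma
        self.t0 = t0
        self.kappa = kappa
        self.count = 0
        self.h_bar = 0.0
        self.log_eps_bar = 0.0

    def update(self, accept_stat: float) -> float:
        self.count += 1
        m = self.count
        eta = 1.0 / (m + self.t0)
        self.h_bar = (1 - eta) * self.h_bar + eta * (self.target - accept_stat)
        log_eps = self.mu - np.sqrt(m) / self.gamma * self.h_bar
        w = m ** (-self.kappa)
        self.log_eps_bar = w * log_eps + (1 - w) * self.log_eps_bar
        return float(np.exp(log_eps))

    @property
    def adapted(self) -> float:
        return float(np.exp(self.log_eps_bar))


class _Welford:
    def __init__(self, dim: int):
        self.n = 0
        self.mean = np.zeros(dim)
        self.m2 = np.zeros(dim)

    def push(self, x: np.ndarray) -> None:
        self.n += 1
        d = x - self.mean
        self.mean += d / self.n
        self.m2 += d * (x - self.mean)

    def variance(self) -> np.ndarray:
        if self.n < 2:
            return np.ones_like(self.mean)
        var = self.m2 / (self.n - 1)
        # shrink toward unit scale, as adaptive HMC implementations do
        return (self.n / (self.n + 5.0)) * var + 1e-3 * (5.0 / (self.n + 5.0))


def _find_initial_step(logp_grad, x, rng, inv_mass):
    """Heuristic: double/halve until the one-step acceptance crosses 1/2."""
    eps = 1.0
    lp, grad = logp_grad(x)
    p = rng.normal(size=x.shape) / np.sqrt(inv_mass)
    h0 = lp - 0.5 * np.sum(p * p * inv_mass)

    def one_step(eps):
        p1 = p + 0.5 * eps * grad
        x1 = x + eps * inv_mass * p1
        lp1, g1 = logp_grad(x1)
        p1 = p1 + 0.5 * eps * g1
        return lp1 - 0.5 * np.sum(p1 * p1 * inv_mass)

    h1 = one_step(eps)
    if not np.isfinite(h1):
        while not np.isfinite(h1) and eps > 1e-10:
            eps *= 0.5
            h1 = one_step(eps)
    direction = 1.0 if (h1 - h0) > np.log(0.5) else -1.0
    for _ in range(100):
        eps_new = eps * (2.0 ** direction)
        h1 = one_step(eps_new)
        if not np.isfinite(h1):
            break
        if direction * (h1 - h0) < direction * np.log(0.5):
            break
        eps = eps_new
    return max(eps, 1e-10)


class _Tree:
    __slots__ = ("x_minus", "p_minus", "g_minus", "x_plus", "p_plus", "g_plus",
                 "x_prop", "lp_prop", "log_weight", "sum_accept", "n_leapfrog",
                 "diverged", "turned")


def _leapfrog(logp_grad, x, p, grad, eps, inv_mass):
    p = p + 0.5 * eps * grad
    x = x + eps * inv_mass * p
    lp, grad = logp_grad(x)
    p = p + 0.5 * eps * grad
    return x, p, lp, grad


def _build_tree(logp_grad, x, p, grad, direction, depth, eps, inv_mass, h0, rng):
    if depth == 0:
        x1, p1, lp1, g1 = _leapfrog(logp_grad, x, p * 1.0, grad, direction * eps, inv_mass)
        h1 = lp1 - 0.5 * np.sum(p1 * p1 * inv_mass)
        t = _Tree()
        t.x_minus = t.x_plus = t.x_prop = x1
        t.p_minus = t.p_plus = p1
        t.g_minus = t.g_plus = g1
        t.lp_prop = lp1
        dh = h1 - h0
        if not np.isfinite(dh):
            dh = -np.inf
        t.log_weight = dh
        t.sum_accept = float(np.exp(min(0.0, dh)))
        t.n_leapfrog = 1
        t.diverged = (h0 - h1) > _MAX_DELTA_H if np.isfinite(h1) else True
        t.turned = False
        return t

    first = _build_tree(logp_grad, x, p, grad, direction, depth - 1, eps, inv_mass, h0, rng)
    if first.diverged or first.turned:
        return first
    if direction > 0:
        second = _build_tree(logp_grad, first.x_plus, first.p_plus, first.g_plus,
                             direction, depth - 1, eps, inv_mass, h0, rng)
        first.x_plus, first.p_plus, first.g_plus = second.x_plus, second.p_plus, second.g_plus
    else:
        second = _build_tree(logp_grad, first.x_minus, first.p_minus, first.g_minus,
                             direction, depth - 1, eps, inv_mass, h0, rng)
        first.x_minus, first.p_minus, first.g_minus = second.x_minus, second.p_minus, second.g_minus
    first.n_leapfrog += second.n_leapfrog
    first.sum_accept += second.sum_accept
    first.diverged = second.diverged
    total = np.logaddexp(first.log_weight, second.log_weight)
    if np.isfinite(second.log_weight) and np.log(rng.uniform()) < second.log_weight - total:
        first.x_prop = second.x_prop
        first.lp_prop = second.lp_prop
    first.log_weight = total
    dx = first.x_plus - first.x_minus
    first.turned = second.turned or (
        np.dot(dx, inv_mass * first.p_minus) < 0
        or np.dot(dx, inv_mass * first.p_plus) < 0
    )
    return first


def _nuts_step(logp_grad, x, lp, grad, eps, inv_mass, rng, max_treedepth):
    p = rng.normal(size=x.shape) / np.sqrt(inv_mass)
    h0 = lp - 0.5 * np.sum(p * p * inv_mass)
    x_minus = x_plus = x
    p_minus = p_plus = p
    g_minus = g_plus = grad
    x_prop, lp_prop, g_prop = x, lp, grad
    log_weight = 0.0  # weight of the initial point relative to h0
    sum_accept = 0.0
    n_leapfrog = 0
    diverged = False
    for depth in range(max_treedepth):
        direction = 1.0 if rng.uniform() < 0.5 else -1.0
        if direction > 0:
            sub = _build_tree(logp_grad, x_plus, p_plus, g_plus, direction,
                              depth, eps, inv_mass, h0, rng)
            x_plus, p_plus, g_plus = sub.x_plus, sub.p_plus, sub.g_plus
        else:
            sub = _build_tree(logp_grad, x_minus, p_minus, g_minus, direction,
                              depth, eps, inv_mass, h0, rng)
            x_minus, p_minus, g_minus = sub.x_minus, sub.p_minus, sub.g_minus
        sum_accept += sub.sum_accept
        n_leapfrog += sub.n_leapfrog
        if sub.diverged:
            diverged = True
            break
        if sub.turned:
            break
        # progressive multinomial sampling: biased toward the new subtree
        if np.isfinite(sub.log_weight) and np.log(rng.uniform()) < sub.log_weight - log_weight:
            x_prop, lp_prop = sub.x_prop, sub.lp_prop
        log_weight = np.logaddexp(log_weight, sub.log_weight)
        dx = x_plus - x_minus
        if np.dot(dx, inv_mass * p_minus) < 0 or np.dot(dx, inv_mass * p_plus) < 0:
            break
    accept_stat = sum_accept / max(n_leapfrog, 1)
    _, g_prop = logp_grad(x_prop) if x_prop is not x else (lp, grad)
    return x_prop, lp_prop, g_prop, accept_stat, diverged


def sample_chain(logp_grad, x0, n_warmup, n_draws, rng,
                 max_treedepth=10, target_accept=0.8,
                 adapt_mass=True) -> ChainResult:
    """Run one NUTS chain: warmup with adaptation, then sampling."""
    x = np.array(x0, dtype=float)
    dim = x.size
    lp, grad = logp_grad(x)
    if not np.isfinite(lp):
        raise ValueError(
            f"non-finite log-density at initialization (logp={lp}); "
            "check starting values and data"
        )
    inv_mass = np.ones(dim)
    eps = _find_initial_step(logp_grad, x, rng, inv_mass)
    da = _DualAveraging(eps, target=target_accept)

    # warmup schedule: step-size-only head/tail with expanding variance
    # windows in between (skipped for very short warmups)
    if adapt_mass and n_warmup >= 120:
        head = max(int(0.15 * n_warmup), 20)
        tail = max(int(0.1 * n_warmup), 20)
        slow_total = n_warmup - head - tail
        windows = []
        w = 25
        start = head
        while slow_total > 0:
            size = w if slow_total >= 2 * w else slow_total
            windows.append((start, start + size))
            start += size
            slow_total -= size
            w *= 2
        window_ends = {end: (s, end) for s, end in windows}
        window_starts = {s for s, _ in windows}
    else:
        window_ends, window_starts = {}, set()

    acc = None
    divergences = 0
    for i in range(n_warmup):
        if i in window_starts:
            acc = _Welford(dim)
        x, lp, grad, a_stat, div = _nuts_step(
            logp_grad, x, lp, grad, eps, inv_mass, rng, max_treedepth)
        eps = da.update(a_stat)
        if acc is not None:
            acc.push(x)
        if (i + 1) in window_ends and acc is not None and acc.n >= 10:
            inv_mass = acc.variance()
            acc = None
            # re-tune the step size on the new metric
            eps = _find_initial_step(logp_grad, x, rng, inv_mass)
            da = _DualAveraging(eps, target=target_accept)
    eps = da.adapted if n_warmup > 0 else eps

    draws = np.empty((n_draws, dim))
    logps = np.empty(n_draws)
    accept_sum = 0.0
    for s in range(n_draws):
        x, lp, grad, a_stat, div = _nuts_step(
            logp_grad, x, lp, grad, eps, inv_mass, rng, max_treedepth)
        if div:
            divergences += 1
        draws[s] = x
        logps[s] = lp
        accept_sum += a_stat
    return ChainResult(
        draws=draws,
        logp=logps,
        divergences=divergences,
        step_size=float(eps),
        inv_mass=inv_mass,
        mean_accept=accept_sum / max(n_draws, 1),
    )
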