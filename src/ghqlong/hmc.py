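"""Hamiltonian Monte Carlo with dual-averaging step-size and diagonal mass adaptation.

A small, self-contained sampler for smooth unconstrained posteriors whose
log-density and gradient are available analytically.  Adaptation follows the
standard recipe: an initial step-size search, dual averaging toward a target
acceptance statistic, and a mid-warmup re-estimation of a diagonal mass matrix
from the early chain history.  Trajectory lengths are jittered uniformly to
avoid resonances.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["ChainStats", "hmc_chain", "sample_chains"]

# energy error beyond which a transition is declared divergent
_DIVERGENCE_THRESHOLD = 1000.0


@dataclass
class ChainStats:
    """Per-chain sampler diagnostics."""

    accept_rate: float
    step_size: float
    n_divergent: int
    n_leapfrog_mean: float
    extra: dict = field(default_factory=dict)


def _leapfrog(logp_grad, q, p, grad, eps, n_steps, inv_mass):
    """Standard leapfrog integration; returns (q, p, logp, grad)."""
    p = p + 0.5 * eps * grad
    for step in range(n_steps):
        q = q + eps * inv_mass * p
        lp, grad = logp_grad(q)
        if not np.isfinite(lp):
            return q, p, -np.inf, grad
        if step != n_steps - 1:
            p = p + eps * grad
    p = p + 0.5 * eps * grad
    return q, p, lp, grad


def _find_initial_step(logp_grad, q0, inv_mass, rng, eps=0.1):
    """Crude doubling/halving search so the first accept prob straddles 0.5."""
    lp0, grad0 = logp_grad(q0)
    p0 = rng.standard_normal(q0.size) / np.sqrt(inv_mass)
    h0 = lp0 - 0.5 * np.sum(inv_mass * p0 * p0)

    def accept_logprob(e):
        with np.errstate(over="ignore", invalid="ignore"):
            _, p1, lp1, _ = _leapfrog(logp_grad, q0, p0.copy(), grad0, e, 1, inv_mass)
            if not np.isfinite(lp1):
                return -np.inf
            h1 = lp1 - 0.5 * np.sum(inv_mass * p1 * p1)
        return (h1 - h0) if np.isfinite(h1) else -np.inf

    a = accept_logprob(eps)
    direction = 1.0 if a > np.log(0.5) else -1.0
    for _ in range(30):
        eps = eps * (2.0 ** direction)
        a = accept_logprob(eps)
        if (direction == 1.0 and a <= np.log(0.5)) or (
            direction == -1.0 and a >= np.log(0.5)
        ):
            break
    return min(max(eps, 1e-6), 10.0)


class _DualAveraging:
    """Nesterov dual averaging of log step size (Hoffman & Gelman scheme)."""

    def __init__(self, eps0, target=0.8, gamma=0.05, t0=10.0, kappa=0.75):
        self.mu = np.log(10.0 * eps0)
        self.target = target
        self.gamma = gamma
        self.t0 = t0
        self.kappa = kappa
        self.h_bar = 0.0
        self.log_eps = np.log(eps0)
        self.log_eps_bar = np.log(eps0)
        self.count = 0

    def update(self, accept_prob):
        self.count += 1
        m = self.count
        w = 1.0 / (m + self.t0)
        self.h_bar = (1.0 - w) * self.h_bar + w * (self.target - accept_prob)
        self.log_eps = self.mu - np.sqrt(m) / self.gamma * self.h_bar
        # keep adaptation inside a sane band so a run of rejections cannot
        # freeze the chain entirely
        self.log_eps = float(np.clip(self.log_eps, np.log(1e-6), np.log(10.0)))
        step_w = m ** (-self.kappa)
        self.log_eps_bar = step_w * self.log_eps + (1.0 - step_w) * self.log_eps_bar

    @property
    def eps(self):
        return float(np.exp(self.log_eps))

    @property
    def eps_final(self):
        return float(np.exp(self.log_eps_bar))


def hmc_chain(
    logp_grad,
    q0,
    n_warmup,
    n_draws,
    rng,
    target_accept=0.8,
    max_leapfrog=64,
    traj_len=1.2,
):
    """Run one adaptive HMC chain.

    Parameters
    ----------
    logp_grad : callable
        ``q -> (log_density, gradient)`` on the unconstrained space.
    q0 : ndarray
        Initial position.
    n_warmup, n_draws : int
        Adaptation and retained-draw counts.
    rng : numpy.random.Generator
    target_accept : float
        Dual-averaging target for the acceptance statistic.
    max_leapfrog : int
        Cap on leapfrog steps per trajectory.
    traj_len : float
        Nominal integration time; the step count is ``traj_len / eps`` capped
        at ``max_leapfrog`` and jittered.

    Returns
    -------
    (draws, stats) : (ndarray of shape (n_draws, dim), ChainStats)
    """
    q = np.asarray(q0, dtype=float).copy()
    dim = q.size
    inv_mass = np.ones(dim)
    lp, grad = logp_grad(q)
    if not np.isfinite(lp):
        raise ValueError("initial point has non-finite log density")

    eps = _find_initial_step(logp_grad, q, inv_mass, rng)
    da = _DualAveraging(eps, target=target_accept)

    # warmup phases: [0, w1) step size only; [w1, w2) also collect history;
    # at w2 re-estimate the diagonal mass and restart dual averaging.
    w1 = max(1, int(0.25 * n_warmup))
    w2 = max(w1 + 1, int(0.75 * n_warmup))
    history = []

    draws = np.empty((n_draws, dim))
    n_div = 0
    accept_sum = 0.0
    n_leap_sum = 0
    best_lp, best_q = lp, q.copy()

    total = n_warmup + n_draws
    for it in range(total):
        warm = it < n_warmup
        eps_it = da.eps if warm else da.eps_final
        base_l = int(np.clip(np.ceil(traj_len / eps_it), 1, max_leapfrog))
        n_steps = int(rng.integers(max(1, base_l // 2), base_l + 1))

        p = rng.standard_normal(dim) / np.sqrt(inv_mass)
        h0 = lp - 0.5 * np.sum(inv_mass * p * p)
        with np.errstate(over="ignore", invalid="ignore"):
            q_new, p_new, lp_new, grad_new = _leapfrog(
                logp_grad, q, p, grad, eps_it, n_steps, inv_mass
            )
            if np.isfinite(lp_new):
                h1 = lp_new - 0.5 * np.sum(inv_mass * p_new * p_new)
                delta = h1 - h0 if np.isfinite(h1) else -np.inf
            else:
                delta = -np.inf

        divergent = (not np.isfinite(delta)) or (delta < -_DIVERGENCE_THRESHOLD)
        accept_prob = 0.0 if divergent else min(1.0, float(np.exp(min(delta, 0.0))))
        if (not divergent) and np.log(rng.uniform()) < delta:
            q, lp, grad = q_new, lp_new, grad_new

        if warm:
            da.update(accept_prob)
            if lp > best_lp:
                best_lp, best_q = lp, q.copy()
            if w1 <= it < w2:
                history.append(q.copy())
            if it == w2 - 1 and len(history) >= 10:
                hist = np.asarray(history)
                var = hist.var(axis=0)
                n = hist.shape[0]
                # shrink toward unit scale to guard short windows
                inv_mass = (n * var + 5.0) / (n + 5.0)
                inv_mass = np.clip(inv_mass, 1e-6, 1e6)
                # rescue a chain marooned far below the typical set before
                # the final adaptation phase
                if lp < best_lp - 50.0:
                    q = best_q.copy()
                    lp, grad = logp_grad(q)
                eps = _find_initial_step(logp_grad, q, inv_mass, rng, eps=max(da.eps, 1e-4))
                da = _DualAveraging(eps, target=target_accept)
        else:
            draws[it - n_warmup] = q
            accept_sum += accept_prob
            n_leap_sum += n_steps
            if divergent:
                n_div += 1

    stats = ChainStats(
        accept_rate=accept_sum / max(n_draws, 1),
        step_size=da.eps_final,
        n_divergent=n_div,
        n_leapfrog_mean=n_leap_sum / max(n_draws, 1),
    )
    return draws, stats


def sample_chains(
    logp_grad,
    init_fn,
    n_chains,
    n_warmup,
    n_draws,
    seed,
    **kwargs,
):
    """Run ``n_chains`` independent chains; returns (chains, draws, dim) array and stats.

    ``init_fn(rng) -> q0`` supplies an overdispersed start per chain.
    """
    seeds = np.random.SeedSequence(seed).spawn(n_chains)
    all_draws = []
    all_stats = []
    for child in seeds:
        rng = np.random.default_rng(child)
        q0 = init_fn(rng)
        draws, stats = hmc_chain(
            logp_grad, q0, n_warmup, n_draws, rng, **kwargs
        )
        all_draws.append(draws)
        all_stats.append(stats)
    return np.asarray(all_draws), all_stats
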