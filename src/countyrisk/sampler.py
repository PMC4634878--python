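"""No-U-Turn sampler with dual-averaging step-size and diagonal mass adaptation.

A self-contained gradient-based MCMC engine used by both model stages.  The
implementation follows the multinomial NUTS scheme: trajectories are doubled
until a U-turn or divergence, and the next state is drawn from the visited
states with weights proportional to ``exp(-energy_error)``.  Warmup
interleaves dual averaging of the step size (targeting a given mean
acceptance statistic) with windowed estimation of a diagonal mass matrix
from the warmup draws.

Models supply ``logp_and_grad(x) -> (float, ndarray)`` on an unconstrained
parameter vector; all constraint transforms and their Jacobians live in the
model modules.
"""

from __future__ import annotations

import dataclasses
from typing import Callable, Sequence

import numpy as np

__all__ = ["NUTSConfig", "ChainResult", "ConvergenceError", "sample_nuts", "run_chains"]

_DIVERGENCE_THRESHOLD = 1000.0  # energy error beyond which a leapfrog has diverged


class ConvergenceError(RuntimeError):
    """Sampling failed its convergence contract; carries the diagnostics."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


@dataclasses.dataclass
class NUTSConfig:
    n_warmup: int = 500
    n_draws: int = 500
    target_accept: float = 0.85
    max_treedepth: int = 10
    init_step_size: float | None = None


@dataclasses.dataclass
class ChainResult:
    draws: np.ndarray           # (n_draws, dim)
    accept_stat: np.ndarray     # (n_draws,)
    n_divergent: int
    step_size: float
    inv_mass: np.ndarray        # (dim,)
    treedepth: np.ndarray       # (n_draws,)


@dataclasses.dataclass
class _State:
    q: np.ndarray
    p: np.ndarray
    logp: float
    grad: np.ndarray


@dataclasses.dataclass
class _Tree:
    """One subtree: outermost states, multinomial proposal, and statistics."""

    minus: _State
    plus: _State
    proposal_q: np.ndarray
    proposal_logp: float
    log_sum_w: float
    sum_accept: float
    n_steps: int
    turning: bool
    diverging: bool


def _energy(state: _State, inv_mass: np.ndarray) -> float:
    return -state.logp + 0.5 * float(np.dot(state.p, inv_mass * state.p))


def _leapfrog(f, state: _State, eps: float, inv_mass: np.ndarray) -> _State:
    p_half = state.p + 0.5 * eps * state.grad
    q_new = state.q + eps * inv_mass * p_half
    logp, grad = f(q_new)
    p_new = p_half + 0.5 * eps * grad
    return _State(q_new, p_new, logp, grad)


def _is_turning(minus: _State, plus: _State, inv_mass: np.ndarray) -> bool:
    dq = plus.q - minus.q
    return (
        float(np.dot(dq, inv_mass * minus.p)) < 0.0
        or float(np.dot(dq, inv_mass * plus.p)) < 0.0
    )


def _build_tree(
    f,
    state: _State,
    direction: int,
    depth: int,
    eps: float,
    energy0: float,
    inv_mass: np.ndarray,
    rng: np.random.Generator,
) -> _Tree:
    if depth == 0:
        new = _leapfrog(f, state, direction * eps, inv_mass)
        energy = _energy(new, inv_mass)
        delta = energy - energy0
        if not np.isfinite(delta):
            delta = np.inf
        diverging = delta > _DIVERGENCE_THRESHOLD
        log_w = -delta if np.isfinite(delta) else -np.inf
        accept = float(np.exp(min(0.0, -delta))) if np.isfinite(delta) else 0.0
        return _Tree(new, new, new.q, new.logp, log_w, accept, 1, False, diverging)

    inner = _build_tree(f, state, direction, depth - 1, eps, energy0, inv_mass, rng)
    if inner.turning or inner.diverging:
        return inner
    edge = inner.plus if direction == 1 else inner.minus
    outer = _build_tree(f, edge, direction, depth - 1, eps, energy0, inv_mass, rng)

    log_sum_w = np.logaddexp(inner.log_sum_w, outer.log_sum_w)
    proposal_q, proposal_logp = inner.proposal_q, inner.proposal_logp
    if np.isfinite(outer.log_sum_w) and np.log(rng.uniform()) < outer.log_sum_w - log_sum_w:
        proposal_q, proposal_logp = outer.proposal_q, outer.proposal_logp
    minus = inner.minus if direction == 1 else outer.minus
    plus = outer.plus if direction == 1 else inner.plus
    return _Tree(
        minus,
        plus,
        proposal_q,
        proposal_logp,
        log_sum_w,
        inner.sum_accept + outer.sum_accept,
        inner.n_steps + outer.n_steps,
        outer.turning or _is_turning(minus, plus, inv_mass),
        outer.diverging,
    )


def _transition(
    f,
    q: np.ndarray,
    logp: float,
    grad: np.ndarray,
    eps: float,
    inv_mass: np.ndarray,
    max_treedepth: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, float, np.ndarray, float, bool, int]:
    """One NUTS draw; returns (q, logp, grad, accept_stat, divergent, depth)."""
    p0 = rng.normal(size=q.shape) / np.sqrt(inv_mass)
    start = _State(q, p0, logp, grad)
    energy0 = _energy(start, inv_mass)

    minus = plus = start
    prop_q, prop_logp = q, logp
    log_sum_w = 0.0  # the initial state enters with weight exp(0)
    sum_accept = 0.0
    n_steps = 0
    divergent = False
    depth = 0
    while depth < max_treedepth:
        direction = 1 if rng.uniform() < 0.5 else -1
        edge = plus if direction == 1 else minus
        tree = _build_tree(f, edge, direction, depth, eps, energy0, inv_mass, rng)
        sum_accept += tree.sum_accept
        n_steps += tree.n_steps
        if tree.diverging:
            divergent = True
            break
        if tree.turning:
            break
        # biased progressive sampling: favour the fresh subtree
        if np.log(rng.uniform()) < tree.log_sum_w - log_sum_w:
            prop_q, prop_logp = tree.proposal_q, tree.proposal_logp
        log_sum_w = np.logaddexp(log_sum_w, tree.log_sum_w)
        if direction == 1:
            plus = tree.plus
        else:
            minus = tree.minus
        depth += 1
        if _is_turning(minus, plus, inv_mass):
            break

    accept_stat = sum_accept / max(n_steps, 1)
    if not np.array_equal(prop_q, q):
        _, grad = f(prop_q)  # cache-free models recompute; cheap relative to the tree
    return prop_q, prop_logp, grad, accept_stat, divergent, depth


def _find_initial_step(f, q, logp, grad, inv_mass, rng) -> float:
    """Coarse bisection of the step size to a ~50% one-step acceptance."""
    eps = 1.0
    p0 = rng.normal(size=q.shape) / np.sqrt(inv_mass)
    start = _State(q, p0, logp, grad)
    energy0 = _energy(start, inv_mass)

    def log_ratio(eps: float) -> float:
        try:
            new = _leapfrog(f, start, eps, inv_mass)
        except FloatingPointError:
            return -np.inf
        delta = _energy(new, inv_mass) - energy0
        return -delta if np.isfinite(delta) else -np.inf

    direction = 1.0 if log_ratio(eps) > np.log(0.5) else -1.0
    for _ in range(64):
        if direction * log_ratio(eps) <= direction * np.log(0.5):
            break
        eps *= 2.0**direction
    return eps


class _Welford:
    def __init__(self, dim: int):
        self.n = 0
        self.mean = np.zeros(dim)
        self.m2 = np.zeros(dim)

    def update(self, x: np.ndarray) -> None:
        self.n += 1
        delta = x - self.mean
        self.mean += delta / self.n
        self.m2 += delta * (x - self.mean)

    def variance(self) -> np.ndarray:
        if self.n < 2:
            return np.ones_like(self.mean)
        return self.m2 / (self.n - 1)


def _adaptation_windows(n_warmup: int) -> list[tuple[int, int]]:
    """Stan-style expanding covariance windows inside the warmup phase."""
    init_buffer, term_buffer, base = 75, 50, 25
    if n_warmup < init_buffer + term_buffer + base:
        init_buffer = max(1, int(0.15 * n_warmup))
        term_buffer = max(1, int(0.10 * n_warmup))
        base = max(1, n_warmup - init_buffer - term_buffer)
    windows = []
    start, size = init_buffer, base
    while start < n_warmup - term_buffer:
        end = min(start + size, n_warmup - term_buffer)
        # absorb a final stub that could not double
        if end + 2 * size > n_warmup - term_buffer:
            end = n_warmup - term_buffer
        windows.append((start, end))
        start, size = end, size * 2
    return windows


def sample_nuts(
    logp_and_grad: Callable[[np.ndarray], tuple[float, np.ndarray]],
    x0: np.ndarray,
    rng: np.random.Generator,
    config: NUTSConfig | None = None,
) -> ChainResult:
    """Run one NUTS chain from ``x0`` and return its kept draws."""
    config = config or NUTSConfig()
    q = np.asarray(x0, dtype=float).copy()
    dim = q.size
    logp, grad = logp_and_grad(q)
    if not np.isfinite(logp):
        raise ValueError("initial point has non-finite log density")

    inv_mass = np.ones(dim)
    eps = config.init_step_size or _find_initial_step(
        logp_and_grad, q, logp, grad, inv_mass, rng
    )

    # dual-averaging state
    gamma, t0, kappa = 0.05, 10.0, 0.75
    mu = np.log(10.0 * eps)
    h_bar, log_eps_bar, m_adapt = 0.0, 0.0, 0

    windows = _adaptation_windows(config.n_warmup)
    welford = _Welford(dim)
    window_idx = 0

    n_divergent_warmup = 0
    for it in range(config.n_warmup):
        q, logp, grad, accept, divergent, _ = _transition(
            logp_and_grad, q, logp, grad, eps, inv_mass, config.max_treedepth, rng
        )
        n_divergent_warmup += divergent
        m_adapt += 1
        frac = 1.0 / (m_adapt + t0)
        h_bar = (1 - frac) * h_bar + frac * (config.target_accept - accept)
        log_eps = mu - np.sqrt(m_adapt) / gamma * h_bar
        weight = m_adapt ** (-kappa)
        log_eps_bar = weight * log_eps + (1 - weight) * log_eps_bar
        eps = float(np.exp(log_eps))

        if window_idx < len(windows):
            w_start, w_end = windows[window_idx]
            if w_start <= it < w_end:
                welford.update(q)
            if it == w_end - 1:
                n = welford.n
                var = welford.variance()
                inv_mass = var * n / (n + 5.0) + 1e-3 * (5.0 / (n + 5.0))
                welford = _Welford(dim)
                window_idx += 1
                # re-anchor dual averaging around the refreshed geometry
                eps = float(np.exp(log_eps_bar))
                mu = np.log(10.0 * eps)
                h_bar, log_eps_bar, m_adapt = 0.0, 0.0, 0

    eps = float(np.exp(log_eps_bar)) if config.n_warmup > 0 else eps

    draws = np.empty((config.n_draws, dim))
    accept_stats = np.empty(config.n_draws)
    depths = np.empty(config.n_draws, dtype=int)
    n_divergent = 0
    for it in range(config.n_draws):
        q, logp, grad, accept, divergent, depth = _transition(
            logp_and_grad, q, logp, grad, eps, inv_mass, config.max_treedepth, rng
        )
        draws[it] = q
        accept_stats[it] = accept
        depths[it] = depth
        n_divergent += divergent

    return ChainResult(draws, accept_stats, n_divergent, eps, inv_mass, depths)


def run_chains(
    logp_and_grad,
    x0_per_chain: Sequence[np.ndarray],
    seed: int,
    config: NUTSConfig | None = None,
) -> tuple[np.ndarray, dict]:
    """Run independent chains; returns draws of shape (chains, n_draws, dim).

    Chain RNGs are spawned from a single seed sequence, so results are fully
    reproducible for a given (seed, config, initial points).
    """
    config = config or NUTSConfig()
    streams = np.random.SeedSequence(seed).spawn(len(x0_per_chain))
    results = [
        sample_nuts(logp_and_grad, x0, np.random.default_rng(stream), config)
        for x0, stream in zip(x0_per_chain, streams)
    ]
    draws = np.stack([r.draws for r in results])
    stats = {
        "n_divergent": int(sum(r.n_divergent for r in results)),
        "step_size": [r.step_size for r in results],
        "mean_accept": float(np.mean([r.accept_stat.mean() for r in results])),
        "mean_treedepth": float(np.mean([r.treedepth.mean() for r in results])),
    }
    return draws, stats
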