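"""No-U-Turn sampler with dual-averaging step-size and diagonal mass adaptation.

A self-contained implementation of adaptive Hamiltonian Monte Carlo: the
multinomial No-U-Turn variant with a Stan-style three-phase warmup schedule
(fast start / expanding slow windows estimating a diagonal metric / fast
finish).  Divergent transitions (energy error beyond ``MAX_DELTA_ENERGY``)
and per-draw Hamiltonian energies are recorded so downstream diagnostics can
enforce the no-divergence and E-BFMI criteria.

The sampler is deterministic given the ``rng`` it is handed.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

MAX_DELTA_ENERGY = 1000.0


@dataclass
class ChainStats:
    """Per-draw sampler metadata for one chain (post-warmup only)."""

    energy: np.ndarray        # Hamiltonian at each draw
    divergent: np.ndarray     # bool per draw
    accept_stat: np.ndarray   # mean Metropolis acceptance statistic
    treedepth: np.ndarray
    step_size: float
    inv_mass: np.ndarray

    @property
    def n_divergent(self) -> int:
        return int(self.divergent.sum())


class _DualAveraging:
    """Nesterov dual averaging targeting a fixed acceptance statistic."""

    def __init__(self, eps0, target, gamma=0.05, t0=10.0, kappa=0.75):
        self.mu = np.log(10.0 * eps0)
        self.target = target
        self.gamma, self.t0, self.kappa = gamma, t0, kappa
        self.log_eps = np.log(eps0)
        self.log_eps_bar = 0.0
        self.h_bar = 0.0
        self.count = 0

    def update(self, accept):
        self.count += 1
        m = self.count
        eta = 1.0 / (m + self.t0)
        self.h_bar = (1 - eta) * self.h_bar + eta * (self.target - accept)
        self.log_eps = self.mu - np.sqrt(m) / self.gamma * self.h_bar
        w = m ** (-self.kappa)
        self.log_eps_bar = w * self.log_eps + (1 - w) * self.log_eps_bar

    @property
    def eps(self):
        return float(np.exp(self.log_eps))

    @property
    def eps_final(self):
        return float(np.exp(self.log_eps_bar))


class _Welford:
    """Online mean/variance for the diagonal metric."""

    def __init__(self, dim):
        self.n = 0
        self.mean = np.zeros(dim)
        self.m2 = np.zeros(dim)

    def add(self, x):
        self.n += 1
        d = x - self.mean
        self.mean += d / self.n
        self.m2 += d * (x - self.mean)

    def variance(self):
        if self.n < 2:
            return np.ones_like(self.mean)
        var = self.m2 / (self.n - 1)
        # Stan's regularization toward unity for short windows
        w = self.n / (self.n + 5.0)
        return w * var + 1e-3 * (1 - w)


def _build_schedule(warmup):
    """(fast_start_end, window_ends, term_start) a la Stan."""
    if warmup < 20:
        return warmup, [], warmup
    init_buffer, term_buffer, base_window = 75, 50, 25
    if init_buffer + term_buffer + base_window > warmup:
        init_buffer = max(1, int(0.15 * warmup))
        term_buffer = max(1, int(0.10 * warmup))
        base_window = warmup - init_buffer - term_buffer
    window_ends = []
    pos = init_buffer
    w = base_window
    while pos + w < warmup - term_buffer:
        if pos + 3 * w >= warmup - term_buffer:
            # absorb the remainder into the final window
            window_ends.append(warmup - term_buffer)
            pos = warmup - term_buffer
            break
        window_ends.append(pos + w)
        pos += w
        w *= 2
    if pos < warmup - term_buffer:
        window_ends.append(warmup - term_buffer)
    return init_buffer, window_ends, warmup - term_buffer


def _find_reasonable_step_size(logp_grad, x, rng, inv_mass):
    lp0, g0 = logp_grad(x)
    eps = 1.0
    p = rng.standard_normal(x.size) / np.sqrt(inv_mass)
    h0 = -lp0 + 0.5 * np.dot(p * inv_mass, p)
    x1, p1, lp1, _ = _leapfrog(logp_grad, x, p, g0, eps, inv_mass)
    h1 = -lp1 + 0.5 * np.dot(p1 * inv_mass, p1)
    d_h = h0 - h1
    direction = 1 if d_h > np.log(0.5) else -1
    for _ in range(50):
        eps *= 2.0**direction
        x1, p1, lp1, _ = _leapfrog(logp_grad, x, p, g0, eps, inv_mass)
        if not np.isfinite(lp1):
            d_h = -np.inf
        else:
            h1 = -lp1 + 0.5 * np.dot(p1 * inv_mass, p1)
            d_h = h0 - h1
        if direction == 1 and not d_h > np.log(0.5):
            break
        if direction == -1 and not d_h < np.log(0.5):
            break
    return max(eps, 1e-10)


def _leapfrog(logp_grad, x, p, grad, eps, inv_mass):
    p = p + 0.5 * eps * grad
    x = x + eps * inv_mass * p
    lp, g = logp_grad(x)
    p = p + 0.5 * eps * g
    return x, p, lp, g


class _Tree:
    __slots__ = (
        "x_minus", "p_minus", "g_minus", "x_plus", "p_plus", "g_plus",
        "x_prop", "lp_prop", "g_prop", "log_sum_w", "sum_accept", "n_accept",
        "divergent", "turning", "h_prop",
    )


def _build_tree(logp_grad, x, p, grad, direction, depth, eps, h0, inv_mass, rng):
    if depth == 0:
        x1, p1, lp1, g1 = _leapfrog(logp_grad, x, p, grad, direction * eps, inv_mass)
        t = _Tree()
        if np.isfinite(lp1):
            h1 = -lp1 + 0.5 * np.dot(p1 * inv_mass, p1)
        else:
            h1 = np.inf
        dh = h1 - h0
        t.divergent = dh > MAX_DELTA_ENERGY or not np.isfinite(dh)
        t.turning = False
        t.x_minus = t.x_plus = t.x_prop = x1
        t.p_minus = t.p_plus = p1
        t.g_minus = t.g_plus = t.g_prop = g1
        t.lp_prop = lp1
        t.h_prop = h1
        t.log_sum_w = -dh if np.isfinite(dh) else -np.inf
        t.sum_accept = float(min(1.0, np.exp(-dh))) if np.isfinite(dh) else 0.0
        t.n_accept = 1
        return t

    first = _build_tree(
        logp_grad, x, p, grad, direction, depth - 1, eps, h0, inv_mass, rng
    )
    if first.divergent or first.turning:
        return first
    if direction == 1:
        second = _build_tree(
            logp_grad, first.x_plus, first.p_plus, first.g_plus,
            direction, depth - 1, eps, h0, inv_mass, rng,
        )
        first.x_plus, first.p_plus, first.g_plus = (
            second.x_plus, second.p_plus, second.g_plus,
        )
    else:
        second = _build_tree(
            logp_grad, first.x_minus, first.p_minus, first.g_minus,
            direction, depth - 1, eps, h0, inv_mass, rng,
        )
        first.x_minus, first.p_minus, first.g_minus = (
            second.x_minus, second.p_minus, second.g_minus,
        )
    first.divergent = second.divergent
    total = np.logaddexp(first.log_sum_w, second.log_sum_w)
    # multinomial sampling within the subtree
    if np.isfinite(second.log_sum_w) and rng.random() < np.exp(
        second.log_sum_w - total
    ):
        first.x_prop = second.x_prop
        first.lp_prop = second.lp_prop
        first.g_prop = second.g_prop
        first.h_prop = second.h_prop
    first.log_sum_w = total
    first.sum_accept += second.sum_accept
    first.n_accept += second.n_accept
    first.turning = second.turning or _is_turning(
        first.x_minus, first.x_plus, first.p_minus, first.p_plus, inv_mass
    )
    return first


def _is_turning(x_minus, x_plus, p_minus, p_plus, inv_mass):
    dx = x_plus - x_minus
    return (
        np.dot(dx, inv_mass * p_minus) < 0 or np.dot(dx, inv_mass * p_plus) < 0
    )


def nuts_sample(
    logp_grad,
    x0,
    warmup: int,
    draws: int,
    rng: np.random.Generator,
    target_accept: float = 0.9,
    max_treedepth: int = 10,
):
    """Run one NUTS chain; returns (draws (n, dim), ChainStats)."""
    x = np.asarray(x0, dtype=float).copy()
    dim = x.size
    inv_mass = np.ones(dim)
    lp, grad = logp_grad(x)
    if not np.isfinite(lp):
        raise ValueError("non-finite log-probability at the initial point")

    eps = _find_reasonable_step_size(logp_grad, x, rng, inv_mass)
    da = _DualAveraging(eps, target_accept)
    fast_end, window_ends, term_start = _build_schedule(warmup)
    welford = _Welford(dim)

    out = np.empty((draws, dim))
    energy = np.empty(draws)
    divergent = np.zeros(draws, bool)
    accept_stat = np.empty(draws)
    treedepth = np.zeros(draws, int)
    window_idx = 0

    total = warmup + draws
    for it in range(total):
        in_warmup = it < warmup
        p = rng.standard_normal(dim) / np.sqrt(inv_mass)
        h0 = -lp + 0.5 * np.dot(p * inv_mass, p)

        tree = _Tree()
        tree.x_minus = tree.x_plus = x
        tree.p_minus = tree.p_plus = p
        tree.g_minus = tree.g_plus = grad
        tree.x_prop, tree.lp_prop, tree.g_prop = x, lp, grad
        tree.h_prop = h0
        tree.log_sum_w = 0.0
        sum_accept, n_accept = 0.0, 0
        diverged = False
        depth = 0
        while depth < max_treedepth:
            direction = 1 if rng.random() < 0.5 else -1
            if direction == 1:
                sub = _build_tree(
                    logp_grad, tree.x_plus, tree.p_plus, tree.g_plus,
                    1, depth, eps, h0, inv_mass, rng,
                )
                tree.x_plus, tree.p_plus, tree.g_plus = (
                    sub.x_plus, sub.p_plus, sub.g_plus,
                )
            else:
                sub = _build_tree(
                    logp_grad, tree.x_minus, tree.p_minus, tree.g_minus,
                    -1, depth, eps, h0, inv_mass, rng,
                )
                tree.x_minus, tree.p_minus, tree.g_minus = (
                    sub.x_minus, sub.p_minus, sub.g_minus,
                )
            sum_accept += sub.sum_accept
            n_accept += sub.n_accept
            if sub.divergent:
                diverged = True
                break
            if sub.turning:
                break
            # biased progressive sampling between the old tree and new subtree
            if rng.random() < np.exp(
                min(0.0, sub.log_sum_w - tree.log_sum_w)
            ):
                tree.x_prop = sub.x_prop
                tree.lp_prop = sub.lp_prop
                tree.g_prop = sub.g_prop
                tree.h_prop = sub.h_prop
            tree.log_sum_w = np.logaddexp(tree.log_sum_w, sub.log_sum_w)
            depth += 1
            if _is_turning(
                tree.x_minus, tree.x_plus, tree.p_minus, tree.p_plus, inv_mass
            ):
                break

        x, lp, grad = tree.x_prop, tree.lp_prop, tree.g_prop
        a_stat = sum_accept / max(n_accept, 1)

        if in_warmup:
            da.update(a_stat)
            eps = da.eps
            if fast_end <= it < term_start:
                welford.add(x)
                if window_idx < len(window_ends) and it + 1 == window_ends[window_idx]:
                    inv_mass = welford.variance()
                    welford = _Welford(dim)
                    window_idx += 1
                    eps = _find_reasonable_step_size(logp_grad, x, rng, inv_mass)
                    da = _DualAveraging(eps, target_accept)
            if it + 1 == warmup:
                eps = da.eps_final
        else:
            i = it - warmup
            out[i] = x
            energy[i] = tree.h_prop
            divergent[i] = diverged
            accept_stat[i] = a_stat
            treedepth[i] = depth

    stats = ChainStats(
        energy=energy,
        divergent=divergent,
        accept_stat=accept_stat,
        treedepth=treedepth,
        step_size=eps,
        inv_mass=inv_mass,
    )
    return out, stats
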