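"""Minimal No-U-Turn sampler with dual-averaging step-size adaptation
and diagonal mass-matrix estimation during warmup.

Implements the tree-doubling algorithm with a slice variable and a
divergence guard; enough machinery to sample log-concave-ish posteriors
such as a Poisson GLMM reliably, without pulling in a PPL.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

_DIVERGENCE = 1000.0  # max energy error before a trajectory is divergent


@dataclass
class NUTSResult:
    draws: np.ndarray  # (n_draws, dim)
    step_size: float
    mass_diag: np.ndarray
    n_divergent: int
    mean_accept: float


def _leapfrog(value_grad, theta, r, grad, eps, m_inv):
    r1 = r + 0.5 * eps * grad
    theta1 = theta + eps * m_inv * r1
    logp1, grad1 = value_grad(theta1)
    r1 = r1 + 0.5 * eps * grad1
    return theta1, r1, logp1, grad1


def _kinetic(r, m_inv):
    return 0.5 * float(r @ (m_inv * r))


def _find_reasonable_eps(value_grad, theta, grad, logp, m_inv, rng):
    eps = 1.0
    r = rng.standard_normal(theta.size) / np.sqrt(m_inv)
    h0 = logp - _kinetic(r, m_inv)
    _, r1, logp1, _ = _leapfrog(value_grad, theta, r, grad, eps, m_inv)
    h1 = logp1 - _kinetic(r1, m_inv)
    if not np.isfinite(h1):
        h1 = -np.inf
    direction = 1.0 if (h1 - h0) > np.log(0.5) else -1.0
    for _ in range(50):
        eps *= 2.0 ** direction
        _, r1, logp1, _ = _leapfrog(value_grad, theta, r, grad, eps, m_inv)
        h1 = logp1 - _kinetic(r1, m_inv)
        if not np.isfinite(h1):
            h1 = -np.inf
        if direction * (h1 - h0) <= direction * np.log(0.5):
            break
    return eps


class _Tree:
    """State bundle for the recursive doubling procedure."""

    __slots__ = ("vg", "m_inv", "rng", "log_u", "h0", "divergent",
                 "alpha_sum", "n_alpha")

    def __init__(self, vg, m_inv, rng, log_u, h0):
        self.vg = vg
        self.m_inv = m_inv
        self.rng = rng
        self.log_u = log_u
        self.h0 = h0
        self.divergent = False
        self.alpha_sum = 0.0
        self.n_alpha = 0

    def build(self, theta, r, grad, v, j, eps):
        if j == 0:
            theta1, r1, logp1, grad1 = _leapfrog(
                self.vg, theta, r, grad, v * eps, self.m_inv
            )
            h1 = logp1 - _kinetic(r1, self.m_inv)
            if not np.isfinite(h1):
                h1 = -np.inf
            n1 = int(self.log_u <= h1)
            s1 = int(self.log_u < h1 + _DIVERGENCE)
            if not s1:
                self.divergent = True
            self.alpha_sum += min(1.0, np.exp(min(h1 - self.h0, 0.0)))
            self.n_alpha += 1
            return (theta1, r1, grad1, theta1, r1, grad1,
                    theta1, logp1, grad1, n1, s1)
        (tm, rm, gm, tp, rp, gp, tprop, lprop, gprop, n1, s1) = self.build(
            theta, r, grad, v, j - 1, eps
        )
        if s1:
            if v == -1:
                (tm, rm, gm, _, _, _, t2, l2, g2, n2, s2) = self.build(
                    tm, rm, gm, v, j - 1, eps
                )
            else:
                (_, _, _, tp, rp, gp, t2, l2, g2, n2, s2) = self.build(
                    tp, rp, gp, v, j - 1, eps
                )
            if n2 > 0 and self.rng.uniform() < n2 / max(n1 + n2, 1):
                tprop, lprop, gprop = t2, l2, g2
            n1 += n2
            s1 = s2 * _no_u_turn(tp, tm, rp, rm, self.m_inv)
        return tm, rm, gm, tp, rp, gp, tprop, lprop, gprop, n1, s1


def _no_u_turn(tp, tm, rp, rm, m_inv):
    d = tp - tm
    return int((d @ (m_inv * rm)) >= 0 and (d @ (m_inv * rp)) >= 0)


def nuts(value_grad, theta0, n_warmup, n_draws, rng, *,
         target_accept: float = 0.8, max_depth: int = 10,
         adapt_mass: bool = True, mass_diag_init=None) -> NUTSResult:
    """Sample ``n_draws`` states after ``n_warmup`` adaptation steps.

    ``value_grad(theta) -> (logp, grad)`` must be finite at ``theta0``.
    ``mass_diag_init`` seeds the inverse mass diagonal (e.g. from a
    Laplace approximation); it is refined during warmup.
    """
    theta = np.asarray(theta0, dtype=float).copy()
    dim = theta.size
    logp, grad = value_grad(theta)
    if not np.isfinite(logp):
        raise ValueError("initial point has non-finite log density")
    if mass_diag_init is None:
        m_inv = np.ones(dim)
    else:
        m_inv = np.clip(np.asarray(mass_diag_init, dtype=float), 1e-12, None)

    eps = _find_reasonable_eps(value_grad, theta, grad, logp, m_inv, rng)
    mu = np.log(10.0 * eps)
    log_eps_bar, h_bar = 0.0, 0.0
    gamma, t0, kappa = 0.05, 10.0, 0.75

    # warmup windows for diagonal mass estimation
    win_start = int(0.15 * n_warmup)
    win_end = int(0.75 * n_warmup)
    warm_buf = []

    draws = np.empty((n_draws, dim))
    n_divergent = 0
    accept_sum = 0.0
    total = n_warmup + n_draws

    m_offset = 0  # dual-averaging restart point after metric updates

    errstate = np.errstate(over="ignore", invalid="ignore")
    errstate.__enter__()
    for it in range(total):
        r0 = rng.standard_normal(dim) / np.sqrt(m_inv)
        h0 = logp - _kinetic(r0, m_inv)
        log_u = h0 + np.log1p(-rng.uniform())  # log of u ~ U(0, exp(h0))
        tree = _Tree(value_grad, m_inv, rng, log_u, h0)
        tm = tp = theta
        rm = rp = r0
        gm = gp = grad
        tprop, lprop, gprop = theta, logp, grad
        n_valid, s, depth = 1, 1, 0
        while s and depth < max_depth:
            v = 1 if rng.uniform() < 0.5 else -1
            if v == -1:
                (tm, rm, gm, _, _, _, t2, l2, g2, n2, s2) = tree.build(
                    tm, rm, gm, v, depth, eps
                )
            else:
                (_, _, _, tp, rp, gp, t2, l2, g2, n2, s2) = tree.build(
                    tp, rp, gp, v, depth, eps
                )
            if s2 and rng.uniform() < min(1.0, n2 / max(n_valid, 1)):
                tprop, lprop, gprop = t2, l2, g2
            n_valid += n2
            s = s2 * _no_u_turn(tp, tm, rp, rm, m_inv)
            depth += 1
        theta, logp, grad = tprop, lprop, gprop
        accept_stat = tree.alpha_sum / max(tree.n_alpha, 1)

        if it < n_warmup:
            # dual averaging
            m_t = it + 1 - m_offset
            h_bar = (1 - 1 / (m_t + t0)) * h_bar + (
                (target_accept - accept_stat) / (m_t + t0)
            )
            log_eps = mu - np.sqrt(m_t) / gamma * h_bar
            w = m_t ** (-kappa)
            log_eps_bar = w * log_eps + (1 - w) * log_eps_bar
            eps = float(np.exp(log_eps))
            if adapt_mass and win_start <= it < win_end:
                warm_buf.append(theta.copy())
            if adapt_mass and it == win_end and len(warm_buf) >= 10:
                var = np.var(np.asarray(warm_buf), axis=0, ddof=1)
                m_inv = np.clip(var, 1e-10, None)
                # re-find a sane step size for the new metric
                eps = _find_reasonable_eps(
                    value_grad, theta, grad, logp, m_inv, rng
                )
                mu = np.log(10.0 * eps)
                log_eps_bar, h_bar = 0.0, 0.0
                m_offset = it + 1
            if it == n_warmup - 1:
                eps = float(np.exp(log_eps_bar))
        else:
            draws[it - n_warmup] = theta
            if tree.divergent:
                n_divergent += 1
            accept_sum += accept_stat

    errstate.__exit__(None, None, None)
    return NUTSResult(draws, eps, m_inv, n_divergent,
                      accept_sum / max(n_draws, 1))
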