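"""No-U-Turn sampler (NUTS) over a differentiable log density.

A self-contained implementation of the tree-doubling No-U-Turn sampler
(slice-sampling variant) with dual-averaging step-size adaptation and a
fixed diagonal mass matrix supplied by the caller (here: local curvature at
the MAP mode).  The target callable must return ``(log_prob, grad)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["NutsResult", "nuts_sample"]

_DELTA_MAX = 1000.0  # divergence threshold on the energy error


@dataclass
class NutsResult:
    samples: np.ndarray  # (S, dim)
    log_probs: np.ndarray  # (S,)
    step_size: float
    divergences: int
    mean_accept: float
    max_tree_depths: int


def _leapfrog(logp_grad, theta, p, grad, eps, inv_mass):
    p_half = p + 0.5 * eps * grad
    theta_new = theta + eps * inv_mass * p_half
    lp, grad_new = logp_grad(theta_new)
    p_new = p_half + 0.5 * eps * grad_new
    return theta_new, p_new, lp, grad_new


def _energy(lp, p, inv_mass):
    return lp - 0.5 * float(p @ (inv_mass * p))


def _find_reasonable_eps(logp_grad, theta, rng, inv_mass, mass):
    eps = 1.0
    lp, grad = logp_grad(theta)
    p = rng.normal(size=len(theta)) * np.sqrt(mass)
    h0 = _energy(lp, p, inv_mass)
    _, p1, lp1, _ = _leapfrog(logp_grad, theta, p, grad, eps, inv_mass)
    h1 = _energy(lp1, p1, inv_mass)
    if not np.isfinite(h1):
        h1 = -np.inf
    direction = 1.0 if (h1 - h0) > np.log(0.5) else -1.0
    for _ in range(60):
        eps *= 2.0 ** direction
        _, p1, lp1, _ = _leapfrog(logp_grad, theta, p, grad, eps, inv_mass)
        h1 = _energy(lp1, p1, inv_mass)
        if not np.isfinite(h1):
            h1 = -np.inf
        if direction * (h1 - h0) <= direction * np.log(0.5):
            break
    return eps


def nuts_sample(
    logp_grad,
    theta0: np.ndarray,
    n_samples: int,
    warmup: int = 500,
    seed: int | np.random.Generator | None = 0,
    mass_diag: np.ndarray | None = None,
    max_depth: int = 10,
    target_accept: float = 0.8,
) -> NutsResult:
    """Draw ``n_samples`` post-warmup samples from ``exp(logp)``.

    ``mass_diag`` is the diagonal of the (position-space) metric; momenta are
    drawn as N(0, mass) and the kinetic energy uses its inverse.
    """
    rng = np.random.default_rng(seed)
    theta = np.asarray(theta0, float).copy()
    dim = len(theta)
    mass = np.ones(dim) if mass_diag is None else np.asarray(mass_diag, float)
    if np.any(mass <= 0) or not np.all(np.isfinite(mass)):
        raise ValueError("mass_diag must be positive and finite")
    inv_mass = 1.0 / mass

    lp, grad = logp_grad(theta)
    if not np.isfinite(lp):
        raise ValueError("initial point has non-finite log probability")

    eps = _find_reasonable_eps(logp_grad, theta, rng, inv_mass, mass)
    mu = np.log(10.0 * eps)
    log_eps_bar, h_bar = 0.0, 0.0
    gamma, t0_da, kappa = 0.05, 10.0, 0.75

    samples = np.empty((n_samples, dim))
    log_probs = np.empty(n_samples)
    divergences = 0
    accept_sum = 0.0
    accept_n = 0
    max_depth_hits = 0

    state = {"div": False}

    def build_tree(th, p, gr, logu, v, j, h0):
        nonlocal divergences
        if j == 0:
            th1, p1, lp1, gr1 = _leapfrog(logp_grad, th, p, gr, v * eps, inv_mass)
            h1 = _energy(lp1, p1, inv_mass)
            if not np.isfinite(h1):
                h1 = -np.inf
            n1 = 1 if logu <= h1 else 0
            s1 = 1 if logu < h1 + _DELTA_MAX else 0
            if s1 == 0:
                state["div"] = True
            alpha = min(1.0, np.exp(min(h1 - h0, 0.0)))
            return th1, p1, gr1, th1, p1, gr1, th1, lp1, n1, s1, alpha, 1
        (thm, pm, grm, thp, pp, grp, thq, lpq, n1, s1, a1, na1) = build_tree(
            th, p, gr, logu, v, j - 1, h0)
        if s1 == 1:
            if v == -1:
                (thm, pm, grm, _, _, _, thq2, lpq2, n2, s2, a2, na2) = build_tree(
                    thm, pm, grm, logu, v, j - 1, h0)
            else:
                (_, _, _, thp, pp, grp, thq2, lpq2, n2, s2, a2, na2) = build_tree(
                    thp, pp, grp, logu, v, j - 1, h0)
            if n1 + n2 > 0 and rng.uniform() < n2 / (n1 + n2):
                thq, lpq = thq2, lpq2
            dth = thp - thm
            s1 = s2 * (1 if dth @ (inv_mass * pm) >= 0 else 0) \
                * (1 if dth @ (inv_mass * pp) >= 0 else 0)
            n1 += n2
            a1 += a2
            na1 += na2
        return thm, pm, grm, thp, pp, grp, thq, lpq, n1, s1, a1, na1

    total_iters = warmup + n_samples
    for it in range(total_iters):
        p0 = rng.normal(size=dim) * np.sqrt(mass)
        h0 = _energy(lp, p0, inv_mass)
        logu = h0 + np.log(rng.uniform())
        thm = thp = theta
        pm = pp = p0
        grm = grp = grad
        theta_prop, lp_prop = theta, lp
        n, s, j = 1, 1, 0
        alpha_sum, n_alpha = 0.0, 0
        state["div"] = False
        while s == 1 and j < max_depth:
            v = 1 if rng.uniform() < 0.5 else -1
            if v == -1:
                (thm, pm, grm, _, _, _, thq, lpq, n1, s1, a1, na1) = build_tree(
                    thm, pm, grm, logu, v, j, h0)
            else:
                (_, _, _, thp, pp, grp, thq, lpq, n1, s1, a1, na1) = build_tree(
                    thp, pp, grp, logu, v, j, h0)
            if s1 == 1 and n1 > 0 and rng.uniform() < min(1.0, n1 / n):
                theta_prop, lp_prop = thq, lpq
            n += n1
            alpha_sum += a1
            n_alpha += na1
            dth = thp - thm
            s = s1 * (1 if dth @ (inv_mass * pm) >= 0 else 0) \
                * (1 if dth @ (inv_mass * pp) >= 0 else 0)
            j += 1
        if j >= max_depth:
            max_depth_hits += 1
        if state["div"] and it >= warmup:
            divergences += 1
        theta, lp = theta_prop, lp_prop
        _, grad = logp_grad(theta)

        accept_frac = alpha_sum / max(n_alpha, 1)
        if it < warmup:
            # dual averaging toward the target acceptance statistic
            frac = 1.0 / (it + 1 + t0_da)
            h_bar = (1 - frac) * h_bar + frac * (target_accept - accept_frac)
            log_eps = mu - np.sqrt(it + 1) / gamma * h_bar
            eta = (it + 1.0) ** (-kappa)
            log_eps_bar = eta * log_eps + (1 - eta) * log_eps_bar
            eps = float(np.exp(log_eps))
            if it == warmup - 1:
                eps = float(np.exp(log_eps_bar))
        else:
            accept_sum += accept_frac
            accept_n += 1
            samples[it - warmup] = theta
            log_probs[it - warmup] = lp

    return NutsResult(
        samples=samples, log_probs=log_probs, step_size=eps,
        divergences=divergences,
        mean_accept=accept_sum / max(accept_n, 1),
        max_tree_depths=max_depth_hits,
    )
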