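"""Laplace-marginalized likelihoods for GLMMs with crossed random effects.

The joint negative log-density over observations and random-effect vectors
is minimized over the random effects (inner Newton problem); the marginal
likelihood is then the Laplace approximation at the joint mode.  For a
Gaussian observation family the inner problem is quadratic and the
"approximation" is exact.

Observation families expose per-observation value/gradient/curvature of the
negative log-likelihood with respect to the linear predictor ``eta``.  The
curvature of both families implemented here is positive everywhere, so the
inner problem is strictly convex and Newton with step-halving is globally
convergent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln

__all__ = [
    "nb_logpmf",
    "NegBinFamily",
    "GaussianFamily",
    "RandomEffectBlock",
    "laplace_marginal_nll",
]

_LOG_2PI = np.log(2.0 * np.pi)


def nb_logpmf(y, mu, phi):
    """Log-pmf of a count with mean ``mu`` and variance ``mu + phi*mu**2``.

    ``phi = 0`` evaluates the Poisson limit.  ``y`` must be a non-negative
    integer (arrays allowed); a non-integer value raises ``ValueError``.
    """
    y = np.asarray(y, dtype=float)
    mu = np.asarray(mu, dtype=float)
    if np.any(y < 0) or np.any(y != np.floor(y)):
        raise ValueError("y must consist of non-negative integers")
    if np.any(mu <= 0):
        raise ValueError("mu must be positive")
    if phi < 0:
        raise ValueError("phi must be >= 0")
    if phi == 0:
        return y * np.log(mu) - mu - gammaln(y + 1)
    r = 1.0 / phi
    return (
        gammaln(y + r)
        - gammaln(r)
        - gammaln(y + 1)
        + r * np.log(r / (r + mu))
        + y * np.log(mu / (r + mu))
    )


class NegBinFamily:
    """Negative-binomial observations, log link, variance mu + phi*mu^2."""

    def __init__(self, y: np.ndarray, phi: float):
        self.y = np.asarray(y, dtype=float)
        if np.any(self.y < 0) or np.any(self.y != np.floor(self.y)):
            raise ValueError("counts must be non-negative integers")
        if phi < 0:
            raise ValueError("phi must be >= 0")
        self.phi = float(phi)

    def nll(self, eta):
        return -float(np.sum(nb_logpmf(self.y, np.exp(eta), self.phi)))

    def grad_hess(self, eta):
        """Per-observation d(nll)/d(eta) and d2(nll)/d(eta)^2."""
        mu = np.exp(eta)
        y = self.y
        if self.phi == 0:
            return mu - y, mu
        r = 1.0 / self.phi
        frac = mu / (r + mu)
        grad = (y + r) * frac - y
        hess = (y + r) * r * mu / (r + mu) ** 2
        return grad, hess


class GaussianFamily:
    """Gaussian observations with per-observation SD; identity link on eta."""

    def __init__(self, z: np.ndarray, sd: np.ndarray):
        self.z = np.asarray(z, dtype=float)
        self.sd = np.broadcast_to(np.asarray(sd, dtype=float), self.z.shape)
        if np.any(self.sd <= 0):
            raise ValueError("observation SDs must be positive")

    def nll(self, eta):
        resid = (self.z - eta) / self.sd
        return float(np.sum(0.5 * resid**2 + np.log(self.sd) + 0.5 * _LOG_2PI))

    def grad_hess(self, eta):
        inv_var = 1.0 / self.sd**2
        return (eta - self.z) * inv_var, inv_var


@dataclass
class RandomEffectBlock:
    """One iid Normal(0, sigma) random-effect vector entering the predictor.

    ``index[i]`` is the level of observation ``i``; ``weight[i]`` multiplies
    the effect in the linear predictor (1.0 for a random intercept, the
    covariate value for a random slope).
    """

    index: np.ndarray
    weight: np.ndarray
    sigma: float
    n_levels: int

    def __post_init__(self):
        self.index = np.asarray(self.index, dtype=np.intp)
        self.weight = np.asarray(self.weight, dtype=float)
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if self.index.min(initial=0) < 0 or self.index.max(initial=-1) >= self.n_levels:
            raise ValueError("index out of range")


def _eta(eta0, blocks, u_parts):
    eta = eta0.copy()
    for b, u in zip(blocks, u_parts):
        eta += b.weight * u[b.index]
    return eta


def _joint_nll(family, eta0, blocks, u_parts):
    val = family.nll(_eta(eta0, blocks, u_parts))
    for b, u in zip(blocks, u_parts):
        val += float(
            0.5 * np.sum(u**2) / b.sigma**2
            + b.n_levels * (np.log(b.sigma) + 0.5 * _LOG_2PI)
        )
    return val


def _split(u, sizes):
    out, pos = [], 0
    for s in sizes:
        out.append(u[pos : pos + s])
        pos += s
    return out


def laplace_marginal_nll(
    family,
    eta0: np.ndarray,
    blocks: list[RandomEffectBlock],
    u0: np.ndarray | None = None,
    max_iter: int = 100,
    tol: float = 1e-9,
):
    """Marginal negative log-likelihood with random effects integrated out.

    Blocks with ``sigma == 0`` are treated as exactly absent (their effects
    pinned at zero), so with no active blocks the result is the plain
    observation likelihood.

    Returns ``(nll, u_hat)`` where ``u_hat`` is the joint conditional mode
    over the *active* blocks, concatenated in block order (zeros for
    inactive blocks), reusable as a warm start.
    """
    eta0 = np.asarray(eta0, dtype=float)
    active = [b for b in blocks if b.sigma > 0]
    sizes_all = [b.n_levels for b in blocks]
    if not active:
        return family.nll(eta0), np.zeros(sum(sizes_all))

    sizes = [b.n_levels for b in active]
    q = sum(sizes)
    if u0 is not None and u0.size == sum(sizes_all):
        # extract active-block slices from a full-length warm start
        parts, pos = [], 0
        for b in blocks:
            piece = u0[pos : pos + b.n_levels]
            pos += b.n_levels
            if b.sigma > 0:
                parts.append(piece.astype(float).copy())
        u_parts = parts
    else:
        u_parts = [np.zeros(s) for s in sizes]

    f = _joint_nll(family, eta0, active, u_parts)
    for _ in range(max_iter):
        eta = _eta(eta0, active, u_parts)
        g_eta, h_eta = family.grad_hess(eta)
        grads = []
        for b, u in zip(active, u_parts):
            g = np.zeros(b.n_levels)
            np.add.at(g, b.index, b.weight * g_eta)
            g += u / b.sigma**2
            grads.append(g)
        grad = np.concatenate(grads)
        gnorm = np.max(np.abs(grad))
        H = _build_hessian(active, h_eta)
        try:
            L = np.linalg.cholesky(H)
        except np.linalg.LinAlgError:
            H = H + 1e-8 * np.eye(q)
            L = np.linalg.cholesky(H)
        step = np.linalg.solve(H, grad)
        if gnorm < tol * (1.0 + abs(f)):
            break
        # step-halving line search on the joint objective
        scale = 1.0
        for _ in range(30):
            trial = [u - scale * s for u, s in zip(u_parts, _split(step, sizes))]
            f_trial = _joint_nll(family, eta0, active, trial)
            if f_trial <= f + 1e-12 * (1.0 + abs(f)):
                u_parts, f = trial, f_trial
                break
            scale *= 0.5
        else:  # no improvement possible: at numerical optimum
            break
    logdet = 2.0 * float(np.sum(np.log(np.diag(L))))
    nll = f + 0.5 * logdet - 0.5 * q * _LOG_2PI
    # re-assemble a full-length u_hat (zeros for pinned blocks)
    full, it = [], iter(u_parts)
    for b in blocks:
        full.append(next(it) if b.sigma > 0 else np.zeros(b.n_levels))
    return nll, np.concatenate(full)


def _build_hessian(blocks, h_eta):
    """Dense Hessian of the joint objective over active random effects."""
    sizes = [b.n_levels for b in blocks]
    offs = np.cumsum([0] + sizes)
    q = offs[-1]
    H = np.zeros((q, q))
    for a, ba in enumerate(blocks):
        da = np.zeros(ba.n_levels)
        np.add.at(da, ba.index, ba.weight**2 * h_eta)
        da += 1.0 / ba.sigma**2
        ia = slice(offs[a], offs[a + 1])
        H[ia, ia] += np.diag(da)
        for bnum in range(a + 1, len(blocks)):
            bb = blocks[bnum]
            C = np.zeros((ba.n_levels, bb.n_levels))
            np.add.at(C, (ba.index, bb.index), ba.weight * bb.weight * h_eta)
            ib = slice(offs[bnum], offs[bnum + 1])
            H[ia, ib] += C
            H[ib, ia] += C.T
    return H


def conditional_mode_cov(family, eta0, blocks, u_hat):
    """Covariance of the Laplace conditional distribution of active effects."""
    active = [b for b in blocks if b.sigma > 0]
    if not active:
        return np.zeros((0, 0))
    parts, pos = [], 0
    for b in blocks:
        piece = u_hat[pos : pos + b.n_levels]
        pos += b.n_levels
        if b.sigma > 0:
            parts.append(piece)
    eta = _eta(np.asarray(eta0, float), active, parts)
    _, h_eta = family.grad_hess(eta)
    H = _build_hessian(active, h_eta)
    return np.linalg.inv(H)
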