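"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's Laplace machinery except to centre
the quadrature grid (standard adaptive Gauss-Hermite practice).
"""

import itertools

import numpy as np
from numpy.polynomial.hermite_e import hermegauss
from scipy.special import logsumexp

from lekscale._laplace import (
    NegBinFamily,
    RandomEffectBlock,
    _build_hessian,
    _eta,
    laplace_marginal_nll,
    nb_logpmf,
)


def gh_local_loglik(design, params, n_nodes=10):
    """Adaptive Gauss-Hermite quadrature of the lek-count marginal
    likelihood over ALL random effects jointly (crossed, so the integral
    does not factorize).  Feasible only for tiny designs."""
    y = design["count"].to_numpy(float)
    area = design["area"].to_numpy(float)
    pdo = design["pdo"].to_numpy(float)
    lek_levels, lek_idx = np.unique(design["lek_id"], return_inverse=True)
    year_levels, year_idx = np.unique(design["year"], return_inverse=True)
    n_l, n_y = len(lek_levels), len(year_levels)
    q = n_l + n_y
    eta0 = params["beta0"] + params["betaA"] * area + params["betaP"] * pdo
    fam = NegBinFamily(y, params["phi"])
    blocks = [
        RandomEffectBlock(lek_idx, np.ones_like(y), params["sigmaL"], n_l),
        RandomEffectBlock(year_idx, np.ones_like(y), params["sigmaY"], n_y),
    ]
    # centre and scale the grid at the joint mode (does not affect the
    # integral's value, only the quadrature's accuracy)
    _, u_hat = laplace_marginal_nll(fam, eta0, blocks)
    _, h_eta = fam.grad_hess(_eta(eta0, blocks, [u_hat[:n_l], u_hat[n_l:]]))
    H = _build_hessian(blocks, h_eta)
    L = np.linalg.cholesky(np.linalg.inv(H))

    nodes, wts = hermegauss(n_nodes)
    half = q // 2
    rest = np.array(list(itertools.product(nodes, repeat=q - half)))
    wrest = np.prod(np.array(list(itertools.product(wts, repeat=q - half))), axis=1)
    acc = []
    for head in itertools.product(range(n_nodes), repeat=half):
        ghead = np.array([nodes[i] for i in head])
        whead = np.prod([wts[i] for i in head])
        grids = np.hstack([np.broadcast_to(ghead, (len(rest), half)), rest])
        U = u_hat[None, :] + grids @ L.T
        eta_all = eta0[None, :] + U[:, :n_l][:, lek_idx] + U[:, n_l:][:, year_idx]
        obs = np.sum(
            nb_logpmf(np.broadcast_to(y, eta_all.shape), np.exp(eta_all),
                      params["phi"]),
            axis=1,
        )
        pen = (
            -0.5 * np.sum(U[:, :n_l] ** 2, axis=1) / params["sigmaL"] ** 2
            - n_l * np.log(params["sigmaL"] * np.sqrt(2 * np.pi))
            - 0.5 * np.sum(U[:, n_l:] ** 2, axis=1) / params["sigmaY"] ** 2
            - n_y * np.log(params["sigmaY"] * np.sqrt(2 * np.pi))
        )
        core = obs + pen + 0.5 * np.sum(grids**2, axis=1)
        m = core.max()
        acc.append(np.log(np.sum(whead * wrest * np.exp(core - m))) + m)
    return float(logsumexp(acc) + np.log(np.linalg.det(L)))


def mc_r2_decomposition(params, design, n_rep=400, seed=0):
    """Monte-Carlo observation-scale variance decomposition for the
    lek-count model: total-variance law estimated by simulation."""
    rng = np.random.default_rng(seed)
    f = params["betaA"] * design["area"].to_numpy(float) + params[
        "betaP"
    ] * design["pdo"].to_numpy(float)
    n = len(f)
    sr = np.sqrt(params["sigmaL"] ** 2 + params["sigmaY"] ** 2)
    mu_f = np.empty((n_rep, n))
    y_all = np.empty((n_rep, n))
    for r in range(n_rep):
        alpha = rng.normal(0.0, sr, n)
        mu = np.exp(params["beta0"] + f + alpha)
        mu_f[r] = mu
        lam = rng.gamma(1 / params["phi"], params["phi"] * mu) if params["phi"] > 0 else mu
        y_all[r] = rng.poisson(lam)
    e_mu_given_f = mu_f.mean(axis=0)  # approximates E[mu | f_i]
    var_f = np.var(e_mu_given_f)
    var_r = np.mean(np.var(mu_f, axis=0))
    var_d = np.mean(np.var(y_all, axis=0) - np.var(mu_f, axis=0))
    total = var_f + var_r + var_d
    return var_f / total, (var_f + var_r) / total
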