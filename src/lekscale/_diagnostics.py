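"""MCMC convergence diagnostics: split-Rhat and effective sample size."""

from __future__ import annotations

import numpy as np

__all__ = ["split_rhat", "ess", "summarize_chains"]


def _split_chains(chains: np.ndarray) -> np.ndarray:
    """Split each chain in half along the draw axis. chains: (m, n)."""
    chains = np.asarray(chains, dtype=float)
    if chains.ndim != 2:
        raise ValueError("chains must be (n_chains, n_draws)")
    m, n = chains.shape
    half = n // 2
    return np.vstack([chains[:, :half], chains[:, half : 2 * half]])


def split_rhat(chains: np.ndarray) -> float:
    """Potential scale-reduction factor on split chains (Gelman et al.)."""
    s = _split_chains(chains)
    m, n = s.shape
    means = s.mean(axis=1)
    B = n * np.var(means, ddof=1)
    W = np.mean(np.var(s, axis=1, ddof=1))
    if W == 0:
        return 1.0
    var_plus = (n - 1) / n * W + B / n
    return float(np.sqrt(var_plus / W))

def ess(chains: np.ndarray) -> float:
    """Effective sample size via the multi-chain variogram estimator with
    Geyer's initial monotone positive sequence (BDA3, §11.5)."""
    s = _split_chains(chains)
    m, n = s.shape
    means = s.mean(axis=1)
    W = np.mean(np.var(s, axis=1, ddof=1))
    B = n * np.var(means, ddof=1) if m > 1 else 0.0
    var_plus = (n - 1) / n * W + B / n
    if var_plus == 0:
        return float(m * n)
    centered = s - means[:, None]
    # per-chain autocovariances via FFT
    nfft = int(2 ** np.ceil(np.log2(2 * n)))
    f = np.fft.rfft(centered, nfft, axis=1)
    acov = np.fft.irfft(f * np.conj(f), nfft, axis=1)[:, :n].real / n
    rho = 1.0 - (W - acov.mean(axis=0)) / var_plus
    # Geyer: sum consecutive pairs while positive, enforce monotone decrease
    tau = 1.0
    prev_pair = np.inf
    t = 1
    while t + 1 < n:
        pair = rho[t] + rho[t + 1]
        if pair < 0:
            break
        pair = min(pair, prev_pair)
        tau += 2.0 * pair
        prev_pair = pair
        t += 2
    return float(m * n / tau)


def summarize_chains(chains_by_param: dict[str, np.ndarray]) -> dict[str, dict]:
    """Per-parameter Rhat/ESS plus posterior median and 95% interval."""
    out = {}
    for name, ch in chains_by_param.items():
        flat = np.asarray(ch, float).ravel()
        out[name] = {
            "rhat": split_rhat(ch),
            "ess": ess(ch),
            "median": float(np.median(flat)),
            "lower": float(np.percentile(flat, 2.5)),
            "upper": float(np.percentile(flat, 97.5)),
        }
    return out
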