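"""Convergence diagnostics: rank-normalized split R-hat and bulk/tail ESS.

Implemented directly (Vehtari, Gelman, Simpson, Carpenter & Bürkner 2021
formulation) so the computation can be cross-checked against an independent
implementation in the test suite. Constant chains return NaN sentinels.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

__all__ = ["rhat", "ess"]


def _split_chains(draws: np.ndarray) -> np.ndarray:
    """(m, n) -> (2m, n//2), dropping a trailing odd draw."""
    draws = np.atleast_2d(np.asarray(draws, float))
    m, n = draws.shape
    half = n // 2
    return np.vstack([draws[:, :half], draws[:, n - half:]])


def _rank_normalize(draws: np.ndarray) -> np.ndarray:
    flat = draws.ravel()
    ranks = stats.rankdata(flat, method="average")
    z = stats.norm.ppf((ranks - 3.0 / 8) / (flat.size + 1.0 / 4))
    return z.reshape(draws.shape)


def _rhat_basic(chains: np.ndarray) -> float:
    m, n = chains.shape
    means = chains.mean(axis=1)
    variances = chains.var(axis=1, ddof=1)
    W = variances.mean()
    B = n * means.var(ddof=1)
    var_plus = (n - 1) / n * W + B / n
    if W == 0:
        return np.nan
    return float(np.sqrt(var_plus / W))


def rhat(draws: np.ndarray) -> float:
    """Rank-normalized split-chain potential scale reduction factor.

    ``draws`` has shape (chains, draws); requires >= 2 chains and >= 4 draws
    per chain. The reported value is the max of the bulk (rank-normalized)
    and tail (folded rank-normalized) split R-hat.
    """
    draws = np.atleast_2d(np.asarray(draws, float))
    if draws.shape[0] < 2 or draws.shape[1] < 4:
        raise ValueError("rhat requires >= 2 chains of >= 4 draws")
    if np.ptp(draws) == 0:
        return np.nan
    split = _split_chains(draws)
    bulk = _rhat_basic(_rank_normalize(split))
    folded = np.abs(draws - np.median(draws))
    tail = _rhat_basic(_rank_normalize(_split_chains(folded)))
    return float(np.nanmax([bulk, tail]))


def _autocovariance(x: np.ndarray) -> np.ndarray:
    """Biased autocovariance of one chain via FFT (normalized by n)."""
    n = len(x)
    xc = x - x.mean()
    nfft = int(2 ** np.ceil(np.log2(2 * n)))
    f = np.fft.rfft(xc, nfft)
    acov = np.fft.irfft(f * np.conjugate(f), nfft)[:n].real
    return acov / n


def _ess_from_chains(chains: np.ndarray) -> float:
    m, n = chains.shape
    if n < 4 or np.ptp(chains) == 0:
        return np.nan
    acovs = np.vstack([_autocovariance(c) for c in chains])
    chain_var = acovs[:, 0] * n / (n - 1.0)
    W = chain_var.mean()
    mean_acov = acovs.mean(axis=0)
    if m > 1:
        var_plus = W * (n - 1.0) / n + chains.mean(axis=1).var(ddof=1)
    else:
        var_plus = W * (n - 1.0) / n
    if var_plus == 0:
        return np.nan
    # Geyer initial positive + monotone sequence on paired sums
    # P_k = rho_{2k} + rho_{2k+1}; stop at first negative pair, then enforce
    # monotone non-increasing; tau = -1 + 2 * sum P_k
    rho = 1.0 - (W - mean_acov) / var_plus
    rho[0] = 1.0
    pair_sums = []
    t = 0
    while t + 1 < n:
        s = rho[t] + rho[t + 1]
        if s < 0:
            break
        pair_sums.append(s)
        t += 2
    for i in range(1, len(pair_sums)):
        pair_sums[i] = min(pair_sums[i], pair_sums[i - 1])
    tau = -1.0 + 2.0 * sum(pair_sums)
    tau = max(tau, 1.0 / np.log10(m * n + 10))
    return float(m * n / tau)


def ess(draws: np.ndarray, kind: str = "bulk") -> float:
    """Effective sample size from split chains.

    ``bulk`` computes ESS of the rank-normalized split draws; ``tail`` is the
    minimum of the ESS of the 5% and 95% quantile exceedance indicators.
    Constant sequences return NaN.
    """
    draws = np.atleast_2d(np.asarray(draws, float))
    if draws.shape[0] < 2 or draws.shape[1] < 4:
        raise ValueError("ess requires >= 2 chains of >= 4 draws")
    if np.ptp(draws) == 0:
        return np.nan
    split = _split_chains(draws)
    if kind == "bulk":
        return _ess_from_chains(_rank_normalize(split))
    if kind == "tail":
        out = []
        for q in (0.05, 0.95):
            thresh = np.quantile(draws, q)
            ind = (split <= thresh).astype(float)
            out.append(_ess_from_chains(_rank_normalize(ind)))
        return float(np.nanmin(out))
    raise ValueError(f"unknown ESS kind {kind!r}")
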