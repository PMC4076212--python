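"""MCMC chain-health diagnostics: effective sample size and Geweke z-scores."""

from __future__ import annotations

import numpy as np

__all__ = ["effective_sample_size", "geweke_z"]


def _autocovariance(x: np.ndarray) -> np.ndarray:
    n = x.size
    xc = x - x.mean()
    nfft = int(2 ** np.ceil(np.log2(2 * n)))
    f = np.fft.rfft(xc, nfft)
    acov = np.fft.irfft(f * np.conjugate(f), nfft)[:n].real / n
    return acov


def effective_sample_size(x: np.ndarray) -> float:
    """ESS via Geyer's initial positive sequence of autocorrelations."""
    x = np.asarray(x, dtype=float)
    n = x.size
    acov = _autocovariance(x)
    if acov[0] <= 0:
        return float(n)
    rho = acov / acov[0]
    # sum consecutive pairs; stop at the first negative pair sum
    s = 0.0
    for k in range(1, n - 1, 2):
        pair = rho[k] + rho[k + 1]
        if pair < 0:
            break
        s += pair
    ess = n / (1.0 + 2.0 * s)
    return float(min(max(ess, 1.0), n))


def _spectral_var(x: np.ndarray) -> float:
    """Variance of the sample mean, accounting for autocorrelation."""
    ess = effective_sample_size(x)
    return float(np.var(x, ddof=1) / ess)


def geweke_z(x: np.ndarray, first: float = 0.1, last: float = 0.5) -> float:
    """Geweke convergence z-score comparing early and late chain segments."""
    x = np.asarray(x, dtype=float)
    n = x.size
    a = x[: max(2, int(first * n))]
    b = x[n - max(2, int(last * n)):]
    denom = np.sqrt(_spectral_var(a) + _spectral_var(b))
    if denom == 0:
        return 0.0
    return float((a.mean() - b.mean()) / denom)
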