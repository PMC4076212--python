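"""Exact Pólya-Gamma PG(1, z) sampling.

A random variable X ~ PG(1, z) has Laplace transform
``E[exp(-t X)] = cosh(z/2) / cosh(sqrt(z^2/2 + t) / sqrt(2))`` and arises as
the latent augmentation that turns Bernoulli-logit likelihoods into Gaussian
full conditionals: with omega_i ~ PG(1, eta_i), the conditional likelihood of
the linear predictor eta is Gaussian with precision omega and working
response (y - 1/2) / omega.

The sampler is the alternating-series rejection method of Devroye, applied to
J*(1, z/2) (PG(1, z) = J*(1, z/2) / 4): proposals come from a two-piece
mixture of a truncated inverse-Gaussian body and an exponential tail, and are
accepted by squeezing the target density between partial sums of its
alternating series. It is exact (no truncation bias) and vectorized over the
input array, with rejection handled by index masking.
"""

from __future__ import annotations

import numpy as np
from scipy.special import log_ndtr

__all__ = ["sample_pg", "pg_mean", "pg_var"]

_TRUNC = 0.64  # series switch-over point of the J*(1,z) density
_MAX_ROUNDS = 10_000


def pg_mean(psi: np.ndarray | float) -> np.ndarray | float:
    """E[PG(1, psi)] = tanh(psi/2) / (2 psi), with limit 1/4 at psi = 0."""
    psi = np.asarray(psi, dtype=float)
    out = np.full(psi.shape, 0.25)
    nz = np.abs(psi) > 1e-8
    out[nz] = np.tanh(psi[nz] / 2.0) / (2.0 * psi[nz])
    return out if out.ndim else float(out)


def pg_var(psi: np.ndarray | float) -> np.ndarray | float:
    """Var[PG(1, psi)]; limit 1/24 at psi = 0."""
    psi = np.asarray(psi, dtype=float)
    out = np.full(psi.shape, 1.0 / 24.0)
    nz = np.abs(psi) > 1e-4
    c = psi[nz]
    out[nz] = (np.sinh(c) - c) / (4.0 * c**3 * np.cosh(c / 2.0) ** 2)
    return out if out.ndim else float(out)


def _series_coef(n: np.ndarray | int, x: np.ndarray) -> np.ndarray:
    """n-th coefficient a_n(x) of the alternating series for J*(1, .)."""
    half = np.asarray(n, dtype=float) + 0.5
    small = x <= _TRUNC
    out = np.empty_like(x)
    xs = x[small]
    with np.errstate(divide="ignore", over="ignore"):
        out[small] = (
            np.pi * half * (2.0 / (np.pi * xs)) ** 1.5 * np.exp(-2.0 * half**2 / xs)
        )
    xl = x[~small]
    out[~small] = np.pi * half * np.exp(-(half**2) * np.pi**2 * xl / 2.0)
    return out


def _trunc_invgauss(rng: np.random.Generator, z: np.ndarray) -> np.ndarray:
    """Draw IG(mu=1/z, lambda=1) truncated to (0, _TRUNC], elementwise."""
    t = _TRUNC
    x = np.empty_like(z)
    big_mu = z < 1.0 / t  # mu > t: rejection from the z=0 kernel, thinned
    idx = np.flatnonzero(big_mu)
    while idx.size:
        m = idx.size
        e1 = rng.exponential(size=m)
        e2 = rng.exponential(size=m)
        ok = e1**2 <= 2.0 * e2 / t
        cand = t / (1.0 + t * e1) ** 2
        acc = ok & (rng.random(m) <= np.exp(-0.5 * z[idx] ** 2 * cand))
        x[idx[acc]] = cand[acc]
        idx = idx[~acc]
    idx = np.flatnonzero(~big_mu)
    while idx.size:
        mu = 1.0 / z[idx]
        v = rng.standard_normal(idx.size) ** 2
        cand = mu + 0.5 * mu**2 * v - 0.5 * mu * np.sqrt(4.0 * mu * v + (mu * v) ** 2)
        flip = rng.random(idx.size) > mu / (mu + cand)
        cand[flip] = mu[flip] ** 2 / cand[flip]
        acc = cand <= t
        x[idx[acc]] = cand[acc]
        idx = idx[~acc]
    return x


def _propose(rng: np.random.Generator, z: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """One proposal per element plus its series accept/reject decision."""
    t = _TRUNC
    k = np.pi**2 / 8.0 + z**2 / 2.0
    log_p = np.log(np.pi / (2.0 * k)) - k * t  # exponential tail mass
    sqt = np.sqrt(t)
    log_f_ig = np.logaddexp(
        log_ndtr((t * z - 1.0) / sqt), 2.0 * z + log_ndtr(-(t * z + 1.0) / sqt)
    )
    log_q = np.log(2.0) - z + log_f_ig  # truncated inverse-Gaussian mass
    prob_right = np.exp(log_p - np.logaddexp(log_p, log_q))

    right = rng.random(z.size) < prob_right
    x = np.empty_like(z)
    x[right] = t + rng.exponential(size=int(right.sum())) / k[right]
    x[~right] = _trunc_invgauss(rng, z[~right])

    # alternating-series squeeze
    s = _series_coef(0, x)
    y = rng.random(z.size) * s
    accepted = np.zeros(z.size, dtype=bool)
    undecided = np.ones(z.size, dtype=bool)
    n = 1
    while undecided.any():
        if n > _MAX_ROUNDS:  # pragma: no cover - safety net
            raise RuntimeError("Polya-Gamma series squeeze failed to terminate")
        a = _series_coef(n, x[undecided])
        iu = np.flatnonzero(undecided)
        if n % 2 == 1:
            s[iu] -= a
            acc = y[iu] <= s[iu]
            accepted[iu[acc]] = True
            undecided[iu[acc]] = False
        else:
            s[iu] += a
            rej = y[iu] > s[iu]
            undecided[iu[rej]] = False
        n += 1
    return x, accepted


def sample_pg(rng: np.random.Generator, psi: np.ndarray | float) -> np.ndarray:
    """Draw PG(1, psi_i) for every element of ``psi``.

    Parameters
    ----------
    rng
        numpy Generator; the draw is deterministic given its state.
    psi
        Tilting parameters (the linear predictors); sign is irrelevant.
    """
    psi = np.atleast_1d(np.asarray(psi, dtype=float))
    if not np.all(np.isfinite(psi)):
        raise ValueError("non-finite tilting parameter passed to sample_pg")
    z = np.abs(psi) / 2.0
    out = np.empty_like(z)
    todo = np.arange(z.size)
    rounds = 0
    while todo.size:
        rounds += 1
        if rounds > _MAX_ROUNDS:  # pragma: no cover - safety net
            raise RuntimeError("Polya-Gamma rejection sampler failed to terminate")
        x, acc = _propose(rng, z[todo])
        out[todo[acc]] = x[acc]
        todo = todo[~acc]
    return out / 4.0
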