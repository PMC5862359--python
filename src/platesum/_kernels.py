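"""JIT-compiled elementwise kernels for the NB GLM fitting loops.

These fuse the per-observation arithmetic of Fisher scoring (fitted means,
deviances, working weights, log-likelihoods) into single passes over the
gene x sample arrays; the surrounding linear algebra stays in NumPy.
Dispersion below ``1e-8`` switches to the Poisson limit.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

PHI_POISSON = 1e-8
MU_FLOOR = 1e-12


@njit(cache=True)
def mu_and_deviance(y: np.ndarray, eta: np.ndarray, phi: np.ndarray):
    """Fitted means from linear predictors plus per-gene residual deviance."""
    G, n = y.shape
    mu = np.empty((G, n))
    dev = np.empty(G)
    for g in range(G):
        p = phi[g]
        acc = 0.0
        if p < PHI_POISSON:
            for j in range(n):
                e = eta[g, j]
                if e > 700.0:
                    e = 700.0
                elif e < -700.0:
                    e = -700.0
                m = math.exp(e)
                if m < MU_FLOOR:
                    m = MU_FLOOR
                mu[g, j] = m
                yy = y[g, j]
                if yy > 0.0:
                    acc += yy * math.log(yy / m)
                acc -= yy - m
        else:
            r = 1.0 / p
            for j in range(n):
                e = eta[g, j]
                if e > 700.0:
                    e = 700.0
                elif e < -700.0:
                    e = -700.0
                m = math.exp(e)
                if m < MU_FLOOR:
                    m = MU_FLOOR
                mu[g, j] = m
                yy = y[g, j]
                if yy > 0.0:
                    acc += yy * math.log(yy / m)
                acc -= (yy + r) * math.log((yy + r) / (m + r))
        dev[g] = 2.0 * acc if acc > 0.0 else 0.0
    return mu, dev


@njit(cache=True)
def working_weights(
    y: np.ndarray, mu: np.ndarray, eta: np.ndarray, offsets: np.ndarray, phi: np.ndarray
):
    """Fisher weights W = mu/(1 + phi*mu) and W * working response."""
    G, n = y.shape
    W = np.empty((G, n))
    Wz = np.empty((G, n))
    for g in range(G):
        p = phi[g]
        for j in range(n):
            m = mu[g, j]
            w = m / (1.0 + p * m)
            ratio = (y[g, j] - m) / m
            if ratio > 1e8:
                ratio = 1e8
            elif ratio < -1e8:
                ratio = -1e8
            W[g, j] = w
            Wz[g, j] = w * ((eta[g, j] - offsets[j]) + ratio)
    return W, Wz


@njit(cache=True)
def nb_loglik_kernel(y: np.ndarray, mu: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """Per-gene NB log-likelihood (Poisson limit below PHI_POISSON)."""
    G, n = y.shape
    out = np.empty(G)
    for g in range(G):
        p = phi[g]
        acc = 0.0
        if p < PHI_POISSON:
            for j in range(n):
                yy = y[g, j]
                m = mu[g, j]
                if m < MU_FLOOR:
                    m = MU_FLOOR
                acc += yy * math.log(m) - m - math.lgamma(yy + 1.0)
        else:
            r = 1.0 / p
            for j in range(n):
                yy = y[g, j]
                m = mu[g, j]
                if m < MU_FLOOR:
                    m = MU_FLOOR
                acc += (
                    math.lgamma(yy + r)
                    - math.lgamma(r)
                    - math.lgamma(yy + 1.0)
                    + r * math.log(r / (r + m))
                )
                if yy > 0.0:
                    acc += yy * math.log(m / (r + m))
        out[g] = acc
    return out
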