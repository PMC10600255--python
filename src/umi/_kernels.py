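"""Numba kernels for the acquisition simulator.

All kernels accumulate band-limited echoes into baseband (IQ) traces:
an echo with round-trip delay tau contributes
``amp * env(t - tau) * exp(-2i pi f_c tau)`` where ``env`` is the Gaussian
pulse envelope.  The carrier phase factors are precomputed per element (or
per illumination) so that the pairwise amplitude is a plain product, which
keeps transducer-basis traces exactly symmetric under element exchange.
"""

from __future__ import annotations

import numpy as np
from numba import njit, prange

__all__ = ["accumulate_born_transducer", "accumulate_born_planewave"]


@njit(cache=True, parallel=True)
def accumulate_born_transducer(
    out: np.ndarray,  # (n_el, n_el, n_t) complex128, modified in place
    gamma: np.ndarray,  # (n_s,) complex128
    tau: np.ndarray,  # (n_el, n_s) float64, one-way delays [µs]
    cfac: np.ndarray,  # (n_el, n_s) complex128: T(u) g(u,s) exp(-2i pi f_c tau)
    t0: float,
    dt: float,
    sigma_t: float,
    n_support: int,
) -> None:
    n_el, n_s = tau.shape
    n_t = out.shape[2]
    inv_two_sig2 = 1.0 / (2.0 * sigma_t * sigma_t)
    for i in prange(n_el):
        for s in range(n_s):
            ci = cfac[i, s]
            if ci == 0.0:
                continue
            ti = tau[i, s]
            for j in range(n_el):
                cj = cfac[j, s]
                if cj == 0.0:
                    continue
                # gamma * (ci * cj): the element factors commute exactly in
                # IEEE arithmetic, so R(i, j, t) == R(j, i, t) bit for bit.
                amp = gamma[s] * (ci * cj)
                t_arr = ti + tau[j, s]
                k0 = int(np.floor((t_arr - t0) / dt)) - n_support
                k1 = k0 + 2 * n_support + 1
                if k0 < 0:
                    k0 = 0
                if k1 > n_t:
                    k1 = n_t
                for k in range(k0, k1):
                    u = t0 + k * dt - t_arr
                    out[i, j, k] += amp * np.exp(-u * u * inv_two_sig2)


@njit(cache=True, parallel=True)
def accumulate_born_planewave(
    out: np.ndarray,  # (n_a, n_el, n_t) complex128, modified in place
    b: np.ndarray,  # (n_a, n_s) complex128: gamma * A_tx * exp(-2i pi f_c tau_pw)
    tau_pw: np.ndarray,  # (n_a, n_s) float64
    cfac: np.ndarray,  # (n_el, n_s) complex128 receive factors
    tau_out: np.ndarray,  # (n_el, n_s) float64
    t0: float,
    dt: float,
    sigma_t: float,
    n_support: int,
) -> None:
    n_a, n_s = tau_pw.shape
    n_el = cfac.shape[0]
    n_t = out.shape[2]
    inv_two_sig2 = 1.0 / (2.0 * sigma_t * sigma_t)
    for a in prange(n_a):
        for s in range(n_s):
            ba = b[a, s]
            if ba == 0.0:
                continue
            ta = tau_pw[a, s]
            for j in range(n_el):
                cj = cfac[j, s]
                if cj == 0.0:
                    continue
                amp = ba * cj
                t_arr = ta + tau_out[j, s]
                k0 = int(np.floor((t_arr - t0) / dt)) - n_support
                k1 = k0 + 2 * n_support + 1
                if k0 < 0:
                    k0 = 0
                if k1 > n_t:
                    k1 = n_t
                for k in range(k0, k1):
                    u = t0 + k * dt - t_arr
                    out[a, j, k] += amp * np.exp(-u * u * inv_two_sig2)
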