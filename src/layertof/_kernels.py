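"""Numba-compiled numerical kernels (layered diffusion spectrum)."""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True, fastmath=True)
def two_layer_spectrum(
    s: np.ndarray,
    ws: np.ndarray,
    omega: np.ndarray,
    d1: float,
    d2: float,
    v1: float,
    v2: float,
    mua1: float,
    mua2: float,
    z0: float,
    thickness: float,
    zb: float,
) -> np.ndarray:
    """Inverse-Hankel-transformed surface fluence of the two-layer diffusion
    Green's function at each temporal frequency.

    ``s``/``ws`` are quadrature nodes and complex weights already carrying
    the ``s J0(s rho) / (2 pi)`` factor.  All exponentials decay for
    ``Re(a1) > 0`` so the evaluation is overflow-safe at large ``s``.
    """
    nw = omega.shape[0]
    out = np.zeros(nw, dtype=np.complex128)
    for k in range(nw):
        q1 = (mua1 + 1j * omega[k] / v1) / d1
        q2 = (mua2 + 1j * omega[k] / v2) / d2
        acc = 0.0 + 0.0j
        for i in range(s.shape[0]):
            s2 = s[i] * s[i]
            a1 = np.sqrt(s2 + q1)
            a2 = np.sqrt(s2 + q2)
            d1a1 = d1 * a1
            d2a2 = d2 * a2
            u = np.exp(-a1 * z0)
            ezb = np.exp(-2.0 * a1 * zb)
            e1 = np.exp(-2.0 * a1 * (thickness - z0))
            ee = e1 * ezb * u * u
            num = u * (1.0 - ezb) * (d1a1 * (1.0 + e1) + d2a2 * (1.0 - e1))
            den = 2.0 * d1a1 * (d1a1 * (1.0 + ee) + d2a2 * (1.0 - ee))
            acc += ws[i] * num / den
        out[k] = acc
    return out
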