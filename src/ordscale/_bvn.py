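"""Bivariate standard-normal probabilities.

Rectangle probabilities over a correlated standard-normal pair are the
building block of every polychoric likelihood in this package.  The CDF is
evaluated from Owen's T function, which is deterministic and accurate to
roughly 1e-14 in absolute terms — comfortably inside the 1e-10 budget the
polychoric optimiser assumes.
"""

from __future__ import annotations

import numpy as np
from scipy.special import ndtr, owens_t

__all__ = ["bvn_cdf", "rectangle_probabilities"]

_TINY = 1e-13


def bvn_cdf(h, k, rho):
    """P(X <= h, Y <= k) for standard bivariate normal with correlation rho.

    All three arguments broadcast. Infinite limits are allowed.
    """
    h, k, rho = np.broadcast_arrays(
        np.asarray(h, dtype=float), np.asarray(k, dtype=float), np.asarray(rho, dtype=float)
    )
    out = np.empty(h.shape, dtype=float)

    # Degenerate correlation: comonotone / antimonotone limits.
    hi_rho = rho >= 1.0 - 1e-12
    lo_rho = rho <= -1.0 + 1e-12
    general = ~(hi_rho | lo_rho)
    if hi_rho.any():
        out[hi_rho] = ndtr(np.minimum(h[hi_rho], k[hi_rho]))
    if lo_rho.any():
        out[lo_rho] = np.maximum(ndtr(h[lo_rho]) + ndtr(k[lo_rho]) - 1.0, 0.0)

    if general.any():
        hg = h[general].copy()
        kg = k[general].copy()
        rg = rho[general]
        # Owen's formula is singular at h=0 or k=0; the CDF is continuous,
        # so nudge exact zeros to +tiny (the limit from either side agrees).
        hg[np.abs(hg) < _TINY] = _TINY
        kg[np.abs(kg) < _TINY] = _TINY

        # Infinite limits short-circuit to the univariate CDF.
        res = np.empty(hg.shape, dtype=float)
        h_ninf = np.isneginf(hg)
        k_ninf = np.isneginf(kg)
        h_pinf = np.isposinf(hg)
        k_pinf = np.isposinf(kg)
        res[h_ninf | k_ninf] = 0.0
        only_h_inf = h_pinf & ~k_ninf
        res[only_h_inf] = ndtr(kg[only_h_inf])
        only_k_inf = k_pinf & ~h_ninf & ~h_pinf
        res[only_k_inf] = ndtr(hg[only_k_inf])
        both_inf = h_pinf & k_pinf
        res[both_inf] = 1.0

        fin = ~(h_ninf | k_ninf | h_pinf | k_pinf)
        if fin.any():
            hf, kf, rf = hg[fin], kg[fin], rg[fin]
            denom = np.sqrt(1.0 - rf * rf)
            a_h = (kf - rf * hf) / (hf * denom)
            a_k = (hf - rf * kf) / (kf * denom)
            beta = np.where(hf * kf > 0, 0.0, 0.5)
            val = 0.5 * (ndtr(hf) + ndtr(kf)) - owens_t(hf, a_h) - owens_t(kf, a_k) - beta
            res[fin] = val
        out[general] = res

    return np.clip(out, 0.0, 1.0)


def rectangle_probabilities(tau_row, tau_col, rho):
    """Cell probabilities of a cross-table of two discretised normals.

    ``tau_row`` / ``tau_col`` are the interior cut points of each margin
    (lengths m_r, m_c; entries of +/-inf are allowed for unobserved
    categories).  Returns an (m_r+1) x (m_c+1) matrix of rectangle
    probabilities P(tau_r[c] < X <= tau_r[c+1], tau_c[d] < Y <= tau_c[d+1])
    under correlation ``rho``.
    """
    tr = np.concatenate(([-np.inf], np.asarray(tau_row, dtype=float), [np.inf]))
    tc = np.concatenate(([-np.inf], np.asarray(tau_col, dtype=float), [np.inf]))
    grid = bvn_cdf(tr[:, None], tc[None, :], rho)
    cells = grid[1:, 1:] - grid[:-1, 1:] - grid[1:, :-1] + grid[:-1, :-1]
    return np.clip(cells, 0.0, 1.0)
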