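"""Independent numerical oracles used by the tests.

These deliberately avoid the package's adaptive-quadrature path: energies
are recomputed with dense-grid trapezoid integration of the same physical
kernels, and distribution properties are checked by Monte-Carlo sampling,
so that implementation and check share no code.
"""

from __future__ import annotations

import numpy as np

EPS0 = 8.8541878128e-12


def disk_pdf(x: np.ndarray) -> np.ndarray:
    """Unit-radius disk pair-distance density on [0, 2] (independent copy)."""
    x = np.asarray(x, float)
    out = np.zeros_like(x)
    m = (x > 0) & (x < 2)
    xm = x[m]
    out[m] = (2 * xm) * (
        (2 / np.pi) * np.arccos(xm / 2) - (xm / np.pi) * np.sqrt(1 - xm**2 / 4)
    )
    return out


def trapezoid_expectation(kernel, R: float, r_lo: float, n: int = 20000) -> float:
    """∫ p(r; R) k(r) dr on [r_lo, 2R] by log-spaced trapezoid."""
    lo = max(r_lo, 2 * R * 1e-12)
    r = np.geomspace(lo, 2 * R, n)
    y = disk_pdf(r / R) / R * kernel(r)
    return float(np.trapezoid(y, r))


def oracle_total_energy(R_grid: np.ndarray, params, n: int = 8000) -> np.ndarray:
    """E_total on a radius grid via trapezoid integration of both kernels.

    ``params`` is a raftsize BilayerParams; only its plain float fields are
    read, no package integration code is touched.
    """
    R_grid = np.atleast_1d(np.asarray(R_grid, float))
    mu = params.eps * params.eps0 * params.delta_V * params.A_L
    k0 = mu * mu / (4 * np.pi * params.eps * params.eps0)
    h2 = params.h**2
    out = np.empty_like(R_grid)
    for i, R in enumerate(R_grid):
        scale = (params.A_tot / (np.pi * R**2)) * (np.pi * R**2 / params.A_L) ** 2
        e_perim = 2 * params.A_tot * params.sigma / R
        if params.delta_V == 0.0:
            out[i] = e_perim
            continue
        e_intra = scale * trapezoid_expectation(lambda r: k0 / r**3, R, params.d_min, n)
        e_inter = scale * trapezoid_expectation(
            lambda r: k0 * (r**2 - 2 * h2) / (r**2 + h2) ** 2.5, R, 0.0, n
        )
        out[i] = e_perim + e_intra + e_inter
    return out
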