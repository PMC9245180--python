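"""Finite-difference quasi-1D reference for the lateral capacitance.

Independent numerical route to C_s used to cross-check the closed form in
:func:`icekpore.continuum.lateral_capacitance`.  Instead of assuming a linear
lumen potential, the axial potential φ(z) is obtained by solving the 1D
steady conduction equation d²φ/dz² = 0 on a uniform grid (tridiagonal system)
with reservoir boundary conditions φ(0) = ΔV at the cavity-opening face and
φ(L) = 0.  The dead-end cavity carries no steady current and sits at the
potential of the reservoir it opens toward.  The induced lumen charge is then
accumulated cell by cell over the cavity depth,

    q_N = −Σ_cells c'·Δz·(ΔV − φ(z_mid)),   c' = 2π ε0 εS / ln(1 + s/R),

and C_s = −q_N/ΔV.  c' is the capacitance per unit length of the annular
solid wall between lumen (radius R) and cavity (inner radius R+s).
"""

from __future__ import annotations

import numpy as np
from scipy.linalg import solve_banded

from .continuum import PoreGeometry
from .units import EPS0

__all__ = ["lateral_capacitance_fd"]


def lateral_capacitance_fd(geom: PoreGeometry, n_cells: int = 2000) -> float:
    """C_s (e/V) from the discretised quasi-1D cavity–lumen potential problem.

    Parameters
    ----------
    geom : PoreGeometry
    n_cells : int
        Number of axial grid cells along the lumen.
    """
    if n_cells < 8:
        raise ValueError("n_cells must be >= 8")
    d = geom.d
    if d < 0:
        raise ValueError("cavity depth d = L - h must be >= 0")
    if d == 0.0:
        return 0.0

    L = geom.L
    dz = L / n_cells
    n_int = n_cells - 1  # interior nodes z_k = k*dz, k=1..n-1
    # tridiagonal Laplace stencil φ_{k-1} - 2φ_k + φ_{k+1} = 0
    ab = np.zeros((3, n_int))
    ab[0, 1:] = 1.0
    ab[1, :] = -2.0
    ab[2, :-1] = 1.0
    rhs = np.zeros(n_int)
    dv = 1.0  # unit drive; C_s is ΔV-independent
    rhs[0] = -dv  # boundary φ(0) = ΔV
    phi_int = solve_banded((1, 1), ab, rhs)
    phi = np.concatenate(([dv], phi_int, [0.0]))

    # per-unit-length annular wall capacitance, e/(V·Å)
    c_prime = 2.0 * np.pi * EPS0 * geom.epsilon_S / np.log1p(geom.s / geom.R)

    # accumulate charge over cells whose extent overlaps the cavity depth [0, d]
    z_lo = np.arange(n_cells) * dz
    z_hi = z_lo + dz
    overlap = np.clip(np.minimum(z_hi, d) - z_lo, 0.0, None)
    z_mid = np.clip((z_lo + np.minimum(z_hi, d)) / 2.0, 0.0, d)
    phi_mid = np.interp(z_mid, np.linspace(0.0, L, n_cells + 1), phi)
    q_n = -np.sum(c_prime * overlap * (dv - phi_mid))
    return float(-q_n / dv)
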