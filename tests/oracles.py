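"""Independent numerical oracles used by the test suite.

These re-derive the uniaxial stress from the strain-energy definition by a
different route than the package: finite-difference energy derivatives and a
numerical solve for the incompressibility pressure, instead of the
hand-derived component formulas and closed-form pressure elimination.
"""

import math

import numpy as np
from scipy import optimize


def energy_independent(params, cbar: np.ndarray) -> float:
    """Strain energy evaluated directly from its invariant definition."""
    b1 = math.radians(params.beta1)
    b2 = math.radians(params.beta2)
    a = np.array([math.cos(b1), math.sin(b1), 0.0])
    g = np.array([math.cos(b2), math.sin(b2), 0.0])
    i1 = float(np.trace(cbar))
    i4 = float(a @ cbar @ a)
    i6 = float(g @ cbar @ g)
    psi = 0.0
    for i, coef in zip((1, 2, 3), (params.a1, params.a2, params.a3)):
        psi += coef * (i1 - 3.0) ** i
    for j, coef in zip((2, 3, 4), (params.c2, params.c3, params.c4)):
        psi += coef * (i4 - 1.0) ** j
    for k, coef in zip((2, 3, 4), (params.e2, params.e3, params.e4)):
        psi += coef * (i6 - 1.0) ** k
    return psi


def stilde_fd(params, cbar: np.ndarray, h: float = 1e-6) -> np.ndarray:
    """Diagonal of 2 dPsi/dC by central finite differences."""
    out = np.empty(3)
    for i in range(3):
        step = h * max(abs(cbar[i, i]), 1.0)
        cp, cm = cbar.copy(), cbar.copy()
        cp[i, i] += step
        cm[i, i] -= step
        out[i] = 2.0 * (energy_independent(params, cp) - energy_independent(params, cm)) / (2.0 * step)
    return out


def uniaxial_stress_oracle(params, lam: float, axis: int) -> float:
    """Axial second Piola-Kirchhoff stress via an explicit Lagrange multiplier.

    Builds the incompressible uniaxial Cauchy-Green tensor, takes
    finite-difference energy derivatives, and solves S33(p) = 0 numerically
    for the pressure before reading off the axial component.
    """
    diag = np.full(3, 1.0 / lam)
    diag[axis - 1] = lam * lam
    cbar = np.diag(diag)
    st = stilde_fd(params, cbar)
    cinv = np.linalg.inv(cbar)

    def s33(p: float) -> float:
        return st[2] + p * cinv[2, 2]

    scale = max(abs(st[2]) / cinv[2, 2], 1.0)
    p = optimize.brentq(s33, -1e3 * scale, 1e3 * scale, xtol=1e-12, rtol=1e-15)
    return st[axis - 1] + p * cinv[axis - 1, axis - 1]
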