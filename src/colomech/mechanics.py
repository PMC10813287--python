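"""Incompressible uniaxial response of the fiber-reinforced Yeoh model.

Strain energy (per unit reference volume, Pa)::

    Psi = sum_{i=1..3} a_i (I1b - 3)^i
        + sum_{j=2..4} c_j (I4b - 1)^j
        + sum_{k=2..4} e_k (I6b - 1)^k

with I1b = tr(Cb), I4b = a.Cb.a, I6b = g.Cb.g, where Cb is the (unimodular,
J = 1) right Cauchy-Green tensor and a, g are the unit direction vectors of
the two fiber families, both lying in the circumferential-longitudinal
(1-2) plane.

Uniaxial tension along axis d with incompressibility gives
lambda_d = lam, transverse stretches lam^(-1/2), so Cb is diagonal.  The
second Piola-Kirchhoff stress follows from S = Sb + p Cb^{-1}; the
hydrostatic multiplier p is eliminated by the traction-free out-of-plane
condition S33 = 0, yielding the closed form

    S_axial = Sb_axial - Sb33 * lam^-3

where Sb = 2 dPsi/dCb (components "stilde").  Cauchy stress is
sigma = lam^2 S_axial and engineering (first Piola-Kirchhoff) stress is
P = lam * S_axial.
"""

from __future__ import annotations

import dataclasses
import enum
import math

import numpy as np

from .params import MaterialParameters

__all__ = [
    "LoadingAxis",
    "StressKind",
    "UniaxialKinematics",
    "InvariantSet",
    "StressResult",
    "fiber_direction",
    "uniaxial_kinematics",
    "invariants",
    "strain_energy",
    "stilde_components",
    "uniaxial_second_pk",
    "uniaxial_stress_array",
    "predict_curve",
]


class LoadingAxis(enum.IntEnum):
    """Loading direction: 1 = circumferential, 2 = longitudinal."""

    CIRCUMFERENTIAL = 1
    LONGITUDINAL = 2

    @classmethod
    def coerce(cls, value) -> "LoadingAxis":
        if isinstance(value, cls):
            return value
        if isinstance(value, str):
            v = value.strip().lower()
            if v in ("circ", "circumferential", "1"):
                return cls.CIRCUMFERENTIAL
            if v in ("long", "longitudinal", "2"):
                return cls.LONGITUDINAL
            raise ValueError(f"unknown loading axis {value!r}")
        return cls(int(value))


class StressKind(str, enum.Enum):
    ENGINEERING = "engineering"
    TRUE = "true"


@dataclasses.dataclass(frozen=True)
class UniaxialKinematics:
    """Diagonal unimodular Cauchy-Green state of an incompressible pull."""

    stretch: float
    loading_axis: LoadingAxis
    cbar: np.ndarray  # 3x3 diagonal, det = 1
    J: float = 1.0


@dataclasses.dataclass(frozen=True)
class InvariantSet:
    I1bar: float
    I4bar: float
    I6bar: float
    a_vec: np.ndarray
    g_vec: np.ndarray


@dataclasses.dataclass(frozen=True)
class StressResult:
    """Uniaxial stress measures (Pa) at one stretch."""

    S_axial: float          # second Piola-Kirchhoff
    sigma_true: float       # Cauchy, lam^2 * S_axial
    P_eng: float            # engineering / first P-K, lam * S_axial
    p_pressure: float       # eliminated hydrostatic multiplier (diagnostic)
    stilde: tuple[float, float, float]


def fiber_direction(beta_deg: float) -> np.ndarray:
    """Unit fiber direction (cos b, sin b, 0) for an angle in degrees."""
    if not math.isfinite(beta_deg):
        raise ValueError(f"fiber angle must be finite, got {beta_deg!r}")
    b = math.radians(beta_deg)
    return np.array([math.cos(b), math.sin(b), 0.0])


def uniaxial_kinematics(stretch: float, loading_axis) -> UniaxialKinematics:
    """Incompressible uniaxial kinematics: diag entries lam^2 and lam^-1."""
    axis = LoadingAxis.coerce(loading_axis)
    lam = float(stretch)
    if not (lam > 0.0) or not math.isfinite(lam):
        raise ValueError(f"stretch must be positive and finite, got {stretch!r}")
    diag = np.full(3, 1.0 / lam)
    diag[axis - 1] = lam * lam
    return UniaxialKinematics(stretch=lam, loading_axis=axis, cbar=np.diag(diag))


def invariants(kin: UniaxialKinematics, params: MaterialParameters) -> InvariantSet:
    """I1b = tr(Cb) and the fiber pseudo-invariants I4b = a.Cb.a, I6b = g.Cb.g."""
    a = fiber_direction(params.beta1)
    g = fiber_direction(params.beta2)
    c = kin.cbar
    return InvariantSet(
        I1bar=float(np.trace(c)),
        I4bar=float(a @ c @ a),
        I6bar=float(g @ c @ g),
        a_vec=a,
        g_vec=g,
    )


def strain_energy(params: MaterialParameters, inv: InvariantSet) -> float:
    """Strain-energy density (Pa); zero in the reference state."""
    x1 = inv.I1bar - 3.0
    x4 = inv.I4bar - 1.0
    x6 = inv.I6bar - 1.0
    psi = 0.0
    for i, ai in enumerate(params.iso, start=1):
        psi += ai * x1**i
    for j, cj in enumerate(params.fiber1, start=2):
        psi += cj * x4**j
    for k, ek in enumerate(params.fiber2, start=2):
        psi += ek * x6**k
    return psi


def _dpsi_diso(params: MaterialParameters, x1: float) -> float:
    # d(Psi_iso)/d(I1b) = sum_i a_i i (I1b-3)^(i-1), with 0^0 := 1 at i=1
    return sum(ai * i * x1 ** (i - 1) for i, ai in enumerate(params.iso, start=1))


def _dpsi_dfiber(coeffs, x: float) -> float:
    # sum_j c_j j (I-1)^(j-1) for j = 2..4
    return sum(cj * j * x ** (j - 1) for j, cj in enumerate(coeffs, start=2))


def stilde_components(
    params: MaterialParameters, inv: InvariantSet, loading_axis
) -> tuple[float, float, float]:
    """Diagonal components of Sb = 2 dPsi/dCb (Pa).

    Sb11 and Sb22 weight the fiber terms by cos^2 and sin^2 of the fiber
    angles; Sb33 carries only the isotropic part because both fiber families
    lie in the 1-2 plane.  ``loading_axis`` is accepted for interface symmetry
    but the triple itself is axis-independent given the invariants.
    """
    LoadingAxis.coerce(loading_axis)
    diso = _dpsi_diso(params, inv.I1bar - 3.0)
    d4 = _dpsi_dfiber(params.fiber1, inv.I4bar - 1.0)
    d6 = _dpsi_dfiber(params.fiber2, inv.I6bar - 1.0)
    ca2, sa2 = inv.a_vec[0] ** 2, inv.a_vec[1] ** 2
    cg2, sg2 = inv.g_vec[0] ** 2, inv.g_vec[1] ** 2
    s11 = 2.0 * (diso + d4 * ca2 + d6 * cg2)
    s22 = 2.0 * (diso + d4 * sa2 + d6 * sg2)
    s33 = 2.0 * diso
    return (s11, s22, s33)


def uniaxial_second_pk(
    params: MaterialParameters,
    stretch: float,
    loading_axis,
    *,
    legacy_denominator: bool = False,
) -> StressResult:
    """Closed-form axial stress of the incompressible uniaxial pull.

    The hydrostatic multiplier p is eliminated via the traction-free
    out-of-plane condition S33 = Sb33 + p/lam_3^... = 0, giving
    S_axial = Sb_axial - Sb33 * lam^-3.

    ``legacy_denominator`` switches to the alternative reading
    S_axial = Sb_axial - Sb33 / (3 lam^3), retained only for sensitivity
    analysis; it does not reduce to the classical Yeoh closed form.
    """
    axis = LoadingAxis.coerce(loading_axis)
    kin = uniaxial_kinematics(stretch, axis)
    inv = invariants(kin, params)
    st = stilde_components(params, inv, axis)
    lam = kin.stretch
    s_axial = float(
        _axial_second_pk_array(params, np.asarray(lam), axis, legacy_denominator)
    )
    # S33 = Sb33 + p*(Cb^-1)_33 = Sb33 + p*lam = 0
    p = -st[2] / lam
    return StressResult(
        S_axial=s_axial,
        sigma_true=lam * lam * s_axial,
        P_eng=lam * s_axial,
        p_pressure=p,
        stilde=st,
    )


def _axial_second_pk_array(
    params: MaterialParameters, lam: np.ndarray, axis: LoadingAxis, legacy: bool
) -> np.ndarray:
    """Axial second P-K stress; shared by the scalar and vector interfaces.

    The invariant excesses are built from lam^2 - 1 and 1/lam - 1 directly so
    they vanish identically (not just to round-off) at the reference state.
    """
    du = lam**2 - 1.0  # axial Cb excess
    dt = 1.0 / lam - 1.0  # transverse Cb excess
    x1 = du + 2.0 * dt

    a = fiber_direction(params.beta1)
    g = fiber_direction(params.beta2)
    ax = axis - 1  # 0 or 1, in-plane
    tr = 1 - ax
    x4 = du * a[ax] ** 2 + dt * (a[tr] ** 2 + a[2] ** 2)
    x6 = du * g[ax] ** 2 + dt * (g[tr] ** 2 + g[2] ** 2)

    diso = sum(ai * i * x1 ** (i - 1) for i, ai in enumerate(params.iso, start=1))
    d4 = sum(cj * j * x4 ** (j - 1) for j, cj in enumerate(params.fiber1, start=2))
    d6 = sum(ek * k * x6 ** (k - 1) for k, ek in enumerate(params.fiber2, start=2))

    sb_axial = 2.0 * (diso + d4 * a[ax] ** 2 + d6 * g[ax] ** 2)
    sb33 = 2.0 * diso
    denom = 3.0 * lam**3 if legacy else lam**3
    return sb_axial - sb33 / denom


def uniaxial_stress_array(
    params: MaterialParameters,
    strain,
    loading_axis,
    stress_kind: StressKind | str = StressKind.ENGINEERING,
    *,
    legacy_denominator: bool = False,
) -> np.ndarray:
    """Vectorised axial stress (Pa) at arbitrary engineering strains >= 0."""
    axis = LoadingAxis.coerce(loading_axis)
    kind = StressKind(stress_kind)
    lam = 1.0 + np.asarray(strain, dtype=float)
    s_axial = _axial_second_pk_array(params, lam, axis, legacy_denominator)
    return lam * s_axial if kind is StressKind.ENGINEERING else lam**2 * s_axial


def predict_curve(
    params: MaterialParameters,
    strain_grid,
    loading_axis,
    stress_kind: StressKind | str = StressKind.ENGINEERING,
    *,
    legacy_denominator: bool = False,
):
    """Vectorised stress along a grid of engineering strains.

    Returns a :class:`~colomech.curves.StressStrainCurve` sampled at
    lam = 1 + strain; stresses are engineering or true (Cauchy) per
    ``stress_kind``.
    """
    from .curves import StressStrainCurve  # local import: avoid cycle

    axis = LoadingAxis.coerce(loading_axis)
    kind = StressKind(stress_kind)
    eps = np.asarray(strain_grid, dtype=float)
    if eps.ndim != 1 or eps.size == 0:
        raise ValueError("strain grid must be a non-empty 1-D array")
    if np.any(eps < 0.0):
        raise ValueError("engineering strains must be >= 0")
    if eps.size > 1 and np.any(np.diff(eps) <= 0.0):
        raise ValueError("strain grid must be strictly increasing")

    stress = uniaxial_stress_array(
        params, eps, axis, kind, legacy_denominator=legacy_denominator
    )
    return StressStrainCurve(
        strain=eps, stress=stress, orientation=axis, stress_kind=kind.value
    )
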