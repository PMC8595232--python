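"""Closed-form material laws used by the ring-model simulator.

Four constituents are modelled:

* the dissected aortic wall — incompressible Yeoh hyperelasticity,
  :math:`W = c_{10}(\\bar I_1-3) + c_{20}(\\bar I_1-3)^2 + c_{30}(\\bar I_1-3)^3`,
  with Cauchy-stress specialisations for the uniaxial strip test and for the
  plane-strain thin ring used at every vessel station;
* the intimal flap — 1D linear elasticity;
* the stent wire — a 1D history-dependent superelastic (flag-shaped) Nitinol
  law with an evolving martensite volume fraction;
* the graft fabric — handled elsewhere as a radius cap (see ``deployment``).

Unit policy: tissue stresses and moduli in kPa, Nitinol in MPa, strains and
stretches dimensionless.  The two scales are never mixed inside this module.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from enum import Enum

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "DomainError",
    "InvalidStateError",
    "YeohParams",
    "LinearElasticParams",
    "NitinolParams",
    "NitinolState",
    "Branch",
    "yeoh_energy",
    "yeoh_uniaxial_cauchy",
    "yeoh_ring_hoop_cauchy",
    "linear_stress",
    "nitinol_step",
    "nitinol_strain_path",
    "nitinol_drive_to_stress",
    "YEOH_DISSECTED_AORTA",
    "YEOH_STIFF_AORTA",
    "FLAP_LINEAR",
    "NITINOL_VALIANT",
]


class DomainError(ValueError):
    """Input outside the physical domain of a material law."""


class InvalidStateError(ValueError):
    """A Nitinol state violating its invariants (e.g. martensite fraction outside [0, 1])."""


# ---------------------------------------------------------------------------
# Yeoh hyperelasticity (aortic wall)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class YeohParams:
    """Yeoh strain-energy coefficients, in kPa.

    ``c10`` must be positive (it sets the small-strain shear modulus
    ``mu = 2 c10``); ``c20`` and ``c30`` control progressive stiffening and
    only need to be finite.
    """

    c10: float
    c20: float
    c30: float

    def __post_init__(self) -> None:
        if not (self.c10 > 0):
            raise ValueError(f"c10 must be positive, got {self.c10}")
        for name in ("c10", "c20", "c30"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")

    def dW_dI1(self, i1):
        """Derivative of the strain-energy density w.r.t. the first invariant."""
        x = np.asarray(i1, dtype=float) - 3.0
        out = self.c10 + 2.0 * self.c20 * x + 3.0 * self.c30 * x**2
        return out if out.shape else float(out)


#: Averaged coefficients fitted to uniaxial tests on dissected descending
#: aortic wall strips (12 samples from type B dissection patients).
YEOH_DISSECTED_AORTA = YeohParams(c10=17.5, c20=58.9, c30=116.1)

#: Roughly twofold-stiffer alternative wall, derived from an anisotropic
#: literature model; shipped for sensitivity studies, never fitted here.
YEOH_STIFF_AORTA = YeohParams(c10=37.1, c20=503.9, c30=721.4)


def yeoh_energy(i1bar, params: YeohParams):
    """Yeoh strain-energy density (kPa) at first deviatoric invariant ``i1bar``.

    Zero at the undeformed state (``i1bar == 3``).  Raises
    :class:`DomainError` for ``i1bar < 3``, which no real deformation of an
    incompressible solid can produce.
    """
    i1 = np.asarray(i1bar, dtype=float)
    if np.any(i1 < 3.0 - 1e-12):
        raise DomainError(f"I1bar must be >= 3, got {i1bar}")
    x = np.maximum(i1 - 3.0, 0.0)
    w = params.c10 * x + params.c20 * x**2 + params.c30 * x**3
    return w if w.shape else float(w)


def yeoh_uniaxial_cauchy(lam, params: YeohParams):
    """Cauchy stress (kPa) in incompressible uniaxial tension at stretch ``lam``.

    Kinematics: ``lambda_1 = lam``, ``lambda_2 = lambda_3 = lam**-0.5`` so
    ``I1 = lam**2 + 2/lam``; the lateral stress is zero, which eliminates the
    pressure and gives ``sigma = 2 (lam**2 - 1/lam) dW/dI1``.
    """
    lam = np.asarray(lam, dtype=float)
    if np.any(lam <= 0):
        raise DomainError("stretch must be positive")
    i1 = lam**2 + 2.0 / lam
    sig = 2.0 * (lam**2 - 1.0 / lam) * params.dW_dI1(i1)
    return sig if sig.shape else float(sig)


def yeoh_ring_hoop_cauchy(lam_theta, params: YeohParams):
    """Hoop Cauchy stress (kPa) of a thin plane-strain ring at hoop stretch ``lam_theta``.

    Kinematics: fixed axial stretch ``lambda_z = 1`` and incompressible
    through-thickness thinning ``lambda_r = 1/lambda_theta``, so
    ``I1 = lam**2 + 1 + lam**-2``.  The radial stress vanishes on a thin wall,
    giving ``sigma_theta = 2 (lam**2 - lam**-2) dW/dI1``; the small-strain
    slope is ``8 c10`` per unit hoop strain.
    """
    lam = np.asarray(lam_theta, dtype=float)
    if np.any(lam <= 0):
        raise DomainError("stretch must be positive")
    i1 = lam**2 + 1.0 + lam**-2
    sig = 2.0 * (lam**2 - lam**-2) * params.dW_dI1(i1)
    return sig if sig.shape else float(sig)


# ---------------------------------------------------------------------------
# Linear elasticity (intimal flap)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LinearElasticParams:
    """Linear-elastic constants in kPa; Poisson ratio kept for input validation only."""

    E: float
    nu: float = 0.49

    def __post_init__(self) -> None:
        if not (self.E > 0):
            raise ValueError(f"E must be positive, got {self.E}")
        if not (-1.0 < self.nu < 0.5):
            raise ValueError(f"nu must lie in (-1, 0.5), got {self.nu}")


#: Intimal flap: linear elastic, 277 kPa, nu = 0.49.
FLAP_LINEAR = LinearElasticParams(E=277.0, nu=0.49)


def linear_stress(eps, params: LinearElasticParams):
    """1D linear stress sigma = E * eps (kPa)."""
    sig = params.E * np.asarray(eps, dtype=float)
    return sig if sig.shape else float(sig)


# ---------------------------------------------------------------------------
# Superelastic Nitinol (stent wire), 1D flag-shaped model
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class NitinolParams:
    """Superelastic constants for the stent wire (stresses and moduli in MPa).

    ``sigma_CLs`` (compressive transformation onset) is stored and validated
    but deliberately unused: the ring model loads the wire in tension only.
    ``T_ref`` and ``rho`` are metadata for a quasi-static isothermal model.
    Poisson ratios are unused in 1D and retained for input validation.
    """

    E_A: float = 51700.0
    nu_A: float = 0.3
    E_M: float = 47800.0
    nu_M: float = 0.3
    eps_L: float = 0.063
    sigma_Ls: float = 600.0
    sigma_LE: float = 670.0
    sigma_Us: float = 288.0
    sigma_UE: float = 254.0
    sigma_CLs: float = 900.0
    T_ref: float = 37.0
    rho: float = 6.5

    def __post_init__(self) -> None:
        if not (self.E_A > 0 and self.E_M > 0):
            raise ValueError("elastic moduli must be positive")
        if not (0.0 < self.eps_L < 1.0):
            raise ValueError(f"eps_L must lie in (0, 1), got {self.eps_L}")
        if not (self.sigma_Ls < self.sigma_LE):
            raise ValueError("loading plateau must satisfy sigma_Ls < sigma_LE")
        if not (self.sigma_UE < self.sigma_Us < self.sigma_Ls):
            raise ValueError("plateaus must satisfy sigma_UE < sigma_Us < sigma_Ls")

    def mixture_modulus(self, xi: float) -> float:
        """Voigt-style linear mixture modulus E(xi) = E_A + xi (E_M - E_A)."""
        return self.E_A + xi * (self.E_M - self.E_A)


#: Constants for the self-expanding Nitinol scaffold of the 28-28-150 device.
NITINOL_VALIANT = NitinolParams()


class Branch(str, Enum):
    """Loading-history flag of the 1D superelastic state."""

    AUSTENITE = "elastic-austenite"
    FORWARD = "forward-transforming"
    MIXTURE = "elastic-mixture"
    REVERSE = "reverse-transforming"
    MARTENSITE = "elastic-martensite"


@dataclass(frozen=True)
class NitinolState:
    """Current 1D wire state: total strain, stress (MPa), martensite fraction, branch.

    Invariant: ``strain = stress / E(xi) + xi * eps_L`` (additive elastic +
    transformation strain decomposition), maintained by :func:`nitinol_step`.
    """

    strain: float = 0.0
    stress: float = 0.0
    xi: float = 0.0
    branch: Branch = Branch.AUSTENITE


def _plateau_xi(eps: float, sig0: float, sig1: float, params: NitinolParams) -> float:
    """Solve strain = sigma(xi)/E(xi) + xi*eps_L for xi on a linear plateau.

    ``sigma(xi) = sig0 + xi (sig1 - sig0)``.  The residual is strictly
    increasing in xi for both plateaus, so the root is unique; values beyond
    the plateau are clamped to 0 / 1 by the caller.
    """

    def g(xi: float) -> float:
        sig = sig0 + xi * (sig1 - sig0)
        return sig / params.mixture_modulus(xi) + xi * params.eps_L - eps

    if g(0.0) >= 0.0:
        return 0.0
    if g(1.0) <= 0.0:
        return 1.0
    return brentq(g, 0.0, 1.0, xtol=1e-15, rtol=1e-15)


def _elastic_branch(xi: float) -> Branch:
    if xi <= 0.0:
        return Branch.AUSTENITE
    if xi >= 1.0:
        return Branch.MARTENSITE
    return Branch.MIXTURE


def nitinol_step(state: NitinolState, d_eps: float, params: NitinolParams) -> NitinolState:
    """Advance the 1D superelastic state by a strain increment ``d_eps``.

    The response is the standard flag-shaped idealisation: austenite elasticity
    up to the loading plateau (``sigma_Ls`` -> ``sigma_LE``, xi rising 0 -> 1,
    transformation strain ``xi * eps_L``), martensite elasticity beyond; on
    unloading, elastic until ``sigma_Us`` then the reverse plateau
    (``sigma_Us`` -> ``sigma_UE``, xi falling to 0) with full strain recovery
    at zero stress.  Monotone increments of any size are resolved exactly
    because plateau states solve the implicit strain decomposition rather than
    integrating a rate.
    """
    if not (0.0 <= state.xi <= 1.0):
        raise InvalidStateError(f"martensite fraction outside [0, 1]: {state.xi}")
    eps = state.strain + d_eps
    xi = state.xi
    trial = params.mixture_modulus(xi) * (eps - xi * params.eps_L)

    if d_eps >= 0.0:
        sig_fwd = params.sigma_Ls + xi * (params.sigma_LE - params.sigma_Ls)
        if xi < 1.0 and trial >= sig_fwd - 1e-12:
            xi_new = _plateau_xi(eps, params.sigma_Ls, params.sigma_LE, params)
            if xi_new >= 1.0:
                return NitinolState(eps, params.E_M * (eps - params.eps_L), 1.0, Branch.MARTENSITE)
            sig = params.sigma_Ls + xi_new * (params.sigma_LE - params.sigma_Ls)
            return NitinolState(eps, sig, xi_new, Branch.FORWARD)
        return NitinolState(eps, trial, xi, _elastic_branch(xi))

    sig_rev = params.sigma_UE + xi * (params.sigma_Us - params.sigma_UE)
    if xi > 0.0 and trial <= sig_rev + 1e-12:
        xi_new = _plateau_xi(eps, params.sigma_UE, params.sigma_Us, params)
        if xi_new <= 0.0:
            return NitinolState(eps, params.E_A * eps, 0.0, Branch.AUSTENITE)
        sig = params.sigma_UE + xi_new * (params.sigma_Us - params.sigma_UE)
        return NitinolState(eps, sig, xi_new, Branch.REVERSE)
    return NitinolState(eps, trial, xi, _elastic_branch(xi))


def nitinol_strain_path(strains, params: NitinolParams, state: NitinolState | None = None):
    """Drive the state through a sequence of total strains; return (stress, xi, final state).

    ``strains`` are absolute strain waypoints, visited in order starting from
    ``state`` (virgin austenite by default).
    """
    st = state if state is not None else NitinolState()
    stresses = np.empty(len(strains))
    xis = np.empty(len(strains))
    for k, e in enumerate(np.asarray(strains, dtype=float)):
        st = nitinol_step(st, e - st.strain, params)
        stresses[k] = st.stress
        xis[k] = st.xi
    return stresses, xis, st


def nitinol_drive_to_stress(
    state: NitinolState,
    target_stress: float,
    params: NitinolParams,
    direction: int = 1,
    max_strain: float = 0.12,
) -> NitinolState:
    """Stress-controlled query: find the state at ``target_stress`` by
    root-finding on the strain-controlled law along a monotone path.

    ``direction`` is +1 to load, -1 to unload.  Raises :class:`DomainError`
    if the target cannot be reached within ``max_strain`` of travel.
    """

    def f(e: float) -> float:
        return nitinol_step(state, direction * e, params).stress - target_stress

    lo, hi = 0.0, max_strain
    if f(lo) == 0.0:
        return state
    if f(lo) * f(hi) > 0:
        raise DomainError("target stress not reachable along this path")
    e = brentq(f, lo, hi, xtol=1e-14)
    return nitinol_step(state, direction * e, params)
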