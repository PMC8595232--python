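"""Diastolic pre-stress of the imaged vessel by fixed-point iteration.

The imaged (CT-analog) geometry corresponds to 80 mmHg of luminal pressure,
so the wall cannot be treated as stress-free at that shape.  Per station, a
scalar hoop pre-stress ``sigma0`` is sought such that pressurising the ring
from the imaged radius reproduces the imaged radius: pressurise, read off the
total hoop stress at equilibrium, feed it back as the new ``sigma0``
(under-relaxed), and stop when the worst radial deviation over all stations
drops below the tolerance (0.5 mm by default).  The converged field is mapped
back onto the imaged geometry and consumed by the deployment step.

Equilibrium closure: a thin membrane ring with reference-thickness stress
resultant, ``P = sigma_total(lam) * h0 / r`` with ``lam = r / r_ct``.  The
resultant deliberately omits geometric thinning: the isolated ring
under-represents axial and perivascular tethering, and with physiological
parameters a thinning resultant has no stable equilibrium branch near the
imaged radius.  The closure preserves the Laplace limit ``sigma = P r / h``
exactly at ``lam = 1``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from .materials import (
    LinearElasticParams,
    YEOH_DISSECTED_AORTA,
    YeohParams,
    linear_stress,
    yeoh_ring_hoop_cauchy,
)
from .synthetic import VesselModel, VesselStation

__all__ = [
    "SolverError",
    "ConvergenceError",
    "RingEquilibriumProblem",
    "PrestressResult",
    "mmhg_to_kpa",
    "ring_equilibrium_radius",
    "prestress_fixed_point",
]

MMHG_TO_KPA = 0.1333224


class SolverError(RuntimeError):
    """Ring equilibrium root not bracketed; carries diagnostics."""


class ConvergenceError(RuntimeError):
    """Fixed point did not reach tolerance; carries the deviation history."""

    def __init__(self, message: str, history: list[float]):
        super().__init__(message)
        self.history = history


def mmhg_to_kpa(p):
    """Pressure unit bridge: mmHg -> kPa (1 mmHg = 0.1333224 kPa)."""
    q = np.asarray(p, dtype=float) * MMHG_TO_KPA
    return q if q.shape else float(q)


@dataclass
class RingEquilibriumProblem:
    """One pressurisation solve: a station, its current pre-stress, pressure in kPa."""

    station: VesselStation
    sigma0: float
    pressure: float  # kPa
    wall_params: YeohParams = field(default_factory=lambda: YEOH_DISSECTED_AORTA)

    def __post_init__(self) -> None:
        if self.pressure < 0:
            raise ValueError("pressure must be non-negative")


def _total_hoop_stress(lam: float, problem: RingEquilibriumProblem) -> float:
    """Wall + pre-stress + flap hoop stress, folded onto the wall thickness h0.

    The flap ring acts in parallel; its force per unit length is scaled by
    ``flap_thickness / h0`` so that ``sigma_total * h0`` is the combined
    membrane force resultant.
    """
    st = problem.station
    sig = yeoh_ring_hoop_cauchy(lam, problem.wall_params) + problem.sigma0
    if st.flap_present and st.flap_thickness > 0:
        flap = LinearElasticParams(E=st.flap_E)
        sig += linear_stress(lam - 1.0, flap) * st.flap_thickness / st.h0
    return sig


def ring_equilibrium_radius(
    problem: RingEquilibriumProblem,
    bracket: tuple[float, float] = (0.2, 4.0),
) -> tuple[float, float, float]:
    """Equilibrium of one pressurised ring: returns (radius mm, stretch, total hoop stress kPa).

    Solves ``P = sigma_total(lam) * h0 / (lam * r_ct)`` for the hoop stretch.
    The residual is strictly increasing in ``lam`` whenever the wall's
    small-strain ring stiffness ``8 c10`` (plus the flap contribution) exceeds
    the Laplace demand slope ``P r_ct / h0``, which holds for all shipped
    configurations, so the root is unique.
    """
    st = problem.station
    r_ref, h0, p = st.ct_radius, st.h0, problem.pressure

    def f(lam: float) -> float:
        return _total_hoop_stress(lam, problem) - p * lam * r_ref / h0

    lo, hi = bracket
    flo, fhi = f(lo), f(hi)
    if flo == 0.0:
        lam = lo
    elif flo * fhi > 0:
        raise SolverError(
            f"no equilibrium in stretch bracket {bracket} at s={st.s:.1f} mm "
            f"(f(lo)={flo:.3g}, f(hi)={fhi:.3g}, sigma0={problem.sigma0:.3g} kPa, P={p:.3g} kPa)"
        )
    else:
        lam = brentq(f, lo, hi, xtol=1e-12, rtol=8.9e-16)
    return lam * r_ref, lam, _total_hoop_stress(lam, problem)


def _pressurise(
    station: VesselStation,
    sigma0: float,
    pressure_kpa: float,
    wall_params: YeohParams,
    n_ramp: int = 8,
) -> tuple[float, float, float]:
    """Ramp the pressure in ``n_ramp`` continuation steps (solver robustness only).

    The final state is a static equilibrium and is ramp-independent; the ramp
    merely keeps the root bracketed near the previous load step.
    """
    lam = 1.0
    out = (station.ct_radius, 1.0, sigma0)
    for p in np.linspace(pressure_kpa / n_ramp, pressure_kpa, n_ramp):
        problem = RingEquilibriumProblem(station, sigma0, p, wall_params)
        lo, hi = max(0.05, lam - 0.5), lam + 0.5
        while True:  # expand the warm bracket if the root moved further
            try:
                out = ring_equilibrium_radius(problem, (lo, hi))
                break
            except SolverError:
                lo, hi = max(0.05, lo - 0.5), hi + 0.5
                if hi > 6.0:
                    raise
        lam = out[1]
    return out


@dataclass
class PrestressResult:
    """Converged per-station hoop pre-stress field plus iteration diagnostics."""

    sigma0_field: np.ndarray
    n_iterations: int
    max_deviation: float
    converged: bool
    deviation_history: list[float] = field(default_factory=list)


def prestress_fixed_point(
    vessel: VesselModel,
    pressure: float = 80.0,
    tol: float = 0.5,
    max_iter: int = 50,
    relax: float = 0.35,
    wall_params: YeohParams = YEOH_DISSECTED_AORTA,
    n_ramp: int = 8,
    raise_on_failure: bool = True,
) -> PrestressResult:
    """Find the per-station hoop pre-stress that makes 80 mmHg reproduce the imaged radii.

    ``pressure`` is in mmHg, ``tol`` in mm (0.5 mm default, the imaging
    criterion).  Each iteration pressurises every ring with the current
    ``sigma0``, then under-relaxes ``sigma0`` toward the total equilibrium
    hoop stress.  ``relax = 0.35`` keeps the Picard map contractive for the
    compliant large-radius sections (the un-relaxed map overshoots there).
    On convergence the pre-stress field is returned mapped onto the imaged
    geometry: re-pressurising with it reproduces the imaged radii within the
    tolerance.
    """
    if tol <= 0:
        raise ValueError("tolerance must be positive")
    p_kpa = mmhg_to_kpa(pressure)
    n = len(vessel.stations)
    sigma0 = np.array(vessel.prestress, dtype=float).copy()
    sigma_eq = sigma0.copy()
    history: list[float] = []

    for it in range(1, max_iter + 1):
        dev = np.empty(n)
        for k, st in enumerate(vessel.stations):
            r_eq, _, sig_tot = _pressurise(st, sigma0[k], p_kpa, wall_params, n_ramp)
            dev[k] = abs(r_eq - st.ct_radius)
            sigma_eq[k] = sig_tot
        max_dev = float(dev.max())
        history.append(max_dev)
        if max_dev < tol:
            # of the pair (current field, updated field) return whichever
            # reproduces the imaged radii better: the update is exact in the
            # stiff-wall (Laplace) limit but overshoots for compliant rings,
            # where the current field is the demonstrably idempotent one
            dev_upd = max(
                abs(_pressurise(st, sigma_eq[k], p_kpa, wall_params, n_ramp)[0] - st.ct_radius)
                for k, st in enumerate(vessel.stations)
            )
            if dev_upd <= max_dev:
                return PrestressResult(sigma_eq.copy(), it, dev_upd, True, history)
            return PrestressResult(sigma0.copy(), it, max_dev, True, history)
        sigma0 += relax * (sigma_eq - sigma0)

    if raise_on_failure:
        raise ConvergenceError(
            f"pre-stress fixed point did not reach {tol} mm in {max_iter} iterations "
            f"(last deviation {history[-1]:.3g} mm)",
            history,
        )
    return PrestressResult(sigma_eq.copy(), max_iter, history[-1], False, history)
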