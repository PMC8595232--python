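"""Virtual deployment: crimp, pre-dilation, release and the A/B/C loading variants.

The device is reduced to one superelastic ring per strut end.  Crimping the
28 mm device into the 7 mm sheath drives a representative wire strain up the
loading plateau; release lets the ring re-expand along the unloading branch
(chronic outward force < radial resistive force, the superelastic
hysteresis).  At every strut-end station the deployed radius solves the
radial equilibrium

    P_stent(r) + P_graft = P_wall(r)

by bracketed scalar root finding.  The graft fabric acts as a steep linear
radius cap above the nominal radius and, in variant C, transmits the luminal
pressure to covered ends.

Variants (increasing fidelity):

* A — wall stress-free at the imaged geometry, no pressure anywhere;
* B — wall pre-stress applied, luminal pressure removed (wall recoils in);
* C — pre-stress applied and 80 mmHg acting inside the graft at covered
  ends (the proximal bare ring P1 is not covered and gets no graft pressure).

Pre-stress enters the wall response as an equivalent circumferential
pre-stretch: the hoop stress field from the fixed point is inverted through
the ring law, so the wall's stress-free radius is smaller than its imaged
radius and the wall stiffens accordingly when pushed beyond it.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from . import metrics
from .materials import (
    LinearElasticParams,
    NitinolState,
    YEOH_DISSECTED_AORTA,
    YeohParams,
    linear_stress,
    nitinol_step,
    yeoh_ring_hoop_cauchy,
)
from .prestress import SolverError, mmhg_to_kpa
from .synthetic import StentGraft, VesselModel, VesselStation, circle_points, strut_end_arclengths

__all__ = [
    "DeploymentConfig",
    "DeploymentResult",
    "StentRing",
    "stent_radial_pressure",
    "predilate",
    "deploy",
    "wall_stress_report",
]

VARIANTS = ("A", "B", "C")


@dataclass(frozen=True)
class DeploymentConfig:
    """Deployment procedure parameters (lengths mm, pressures mmHg).

    ``kappa`` maps ring radius change to representative wire strain,
    ``eps = kappa * (R_nom - r) / R_nom``; ``alpha`` maps wire stress (MPa)
    to outward ring pressure (kPa).  Both are calibration constants of the
    reduced model — the device's wire-level geometry is not modelled.  The
    defaults put the fully crimped wire strain just past the end of the
    loading plateau.
    """

    variant: str = "C"
    lumen_pressure: float = 80.0
    crimp_diameter: float = 7.0
    sheath_diameter: float = 29.0
    predilation: tuple[float, float] = (6.0, 8.0)
    landing_offset: float = 20.0
    kappa: float = 0.1
    alpha: float = 0.1  # kPa of outward pressure per MPa of wire stress
    cap_stiffness: float = 1000.0  # kPa per mm beyond the nominal radius
    cap_tolerance: float = 0.05
    n_crimp_steps: int = 400
    n_release_samples: int = 1500

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ValueError(f"variant must be one of {VARIANTS}, got {self.variant!r}")
        if self.predilation[1] <= self.predilation[0]:
            raise ValueError("predilation target must exceed the starting diameter")


@dataclass
class StentRing:
    """History-carrying state of one strut-end ring (wire state + geometry map)."""

    sg: StentGraft
    config: DeploymentConfig
    state: NitinolState = field(default_factory=NitinolState)

    def wire_strain(self, radius: float) -> float:
        R = self.sg.nominal_radius
        return self.config.kappa * (R - radius) / R

    def radius_of_strain(self, eps: float) -> float:
        R = self.sg.nominal_radius
        return R * (1.0 - eps / self.config.kappa)


def stent_radial_pressure(
    radius: float,
    history: NitinolState,
    sg: StentGraft,
    config: DeploymentConfig,
) -> tuple[float, NitinolState]:
    """Outward radial pressure (kPa) of one ring at ``radius``, advancing the wire history.

    The wire strain implied by the radius is driven through the superelastic
    law from ``history`` (so crimping follows the loading plateau and release
    the unloading plateau); outward pressure is ``alpha`` times the wire
    stress, minus a steep linear graft-cap penalty above the nominal radius.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    eps = config.kappa * (sg.nominal_radius - radius) / sg.nominal_radius
    if eps > config.kappa:  # radius would be negative
        raise ValueError("radius outside model validity")
    state = nitinol_step(history, eps - history.strain, sg.wire)
    pressure = config.alpha * state.stress
    if radius > sg.nominal_radius:
        pressure -= config.cap_stiffness * (radius - sg.nominal_radius)
    return pressure, state


def _crimp(sg: StentGraft, config: DeploymentConfig) -> NitinolState:
    """Crimp a virgin ring from the nominal radius into the sheath (7 mm)."""
    state = NitinolState()
    eps_max = config.kappa * (sg.nominal_radius - config.crimp_diameter / 2) / sg.nominal_radius
    for e in np.linspace(0.0, eps_max, config.n_crimp_steps)[1:]:
        state = nitinol_step(state, e - state.strain, sg.wire)
    return state


def _release_curve(sg: StentGraft, config: DeploymentConfig):
    """Tabulate the unloading (release) branch: radius -> outward pressure (kPa).

    Built once per deployment by crimping a virgin ring and then expanding it
    monotonically back to (slightly past) the nominal radius, recording the
    wire stress along the way.  Monotone in radius, so linear interpolation
    of the table is a faithful stand-in for stepping the state machine inside
    the equilibrium root search.
    """
    crimped = _crimp(sg, config)
    # the nominal radius is a grid node so the graft-cap kink is not smeared
    # by linear interpolation of the table
    radii = np.concatenate(
        [
            np.linspace(config.crimp_diameter / 2, sg.nominal_radius, config.n_release_samples),
            np.linspace(sg.nominal_radius, sg.nominal_radius + 1.0, 200)[1:],
        ]
    )
    pressures = np.empty_like(radii)
    st = crimped
    for k, r in enumerate(radii):
        eps = config.kappa * (sg.nominal_radius - r) / sg.nominal_radius
        st = nitinol_step(st, eps - st.strain, sg.wire)
        p = config.alpha * st.stress
        if r > sg.nominal_radius:
            p -= config.cap_stiffness * (r - sg.nominal_radius)
        pressures[k] = p
    return radii, pressures, crimped


def predilate(vessel: VesselModel, config: DeploymentConfig) -> VesselModel:
    """Balloon pre-dilation of the narrowed true lumen.

    Every station with lumen diameter below the dilation target (8 mm) has
    its target radius raised to the target; this becomes the new reference
    configuration for the subsequent equilibrium.  The pre-stress field is
    carried over unchanged.
    """
    target_r = config.predilation[1] / 2.0
    stations = []
    for st in vessel.stations:
        if 2.0 * st.ct_radius < config.predilation[1]:
            stations.append(replace(st, ct_radius=target_r))
        else:
            stations.append(replace(st))
    return VesselModel(stations, vessel.lumen_pressure, vessel.prestress.copy())


def _prestretch_from_sigma0(sigma0: float, wall: YeohParams) -> float:
    """Equivalent circumferential pre-stretch carrying hoop stress ``sigma0``.

    Inverts the plane-strain ring law on [1, 6]; ``sigma0 <= 0`` maps to 1
    (no pre-stretch).  This converts the fixed-point stress field into a
    smaller stress-free radius, the faithful ring reduction of an
    initial-stress tensor.
    """
    if sigma0 <= 0:
        return 1.0
    f = lambda lam: yeoh_ring_hoop_cauchy(lam, wall) - sigma0
    return brentq(f, 1.0, 6.0, xtol=1e-12)


def _wall_pressure(r: float, st: VesselStation, lam_pre: float, wall: YeohParams) -> float:
    """Inward pressure (kPa) the wall+flap exerts when held at radius ``r``.

    Membrane resultant with reference thickness: ``sigma(lam_tot) h0 / r``
    with total stretch ``lam_tot = (r / r_ref) * lam_pre``.  Negative values
    mean the wall pushes outward (it is below its own equilibrium radius).
    """
    lam = r / st.ct_radius
    p = yeoh_ring_hoop_cauchy(lam * lam_pre, wall) * st.h0 / r
    if st.flap_present and st.flap_thickness > 0:
        flap = LinearElasticParams(E=st.flap_E)
        p += linear_stress(lam - 1.0, flap) * st.flap_thickness / r
    return p


@dataclass
class DeploymentResult:
    """Per-strut-end configuration and per-station wall stresses of one deployment."""

    variant: str
    ends: pd.DataFrame  # label, s_mm, radius_mm, loa_mm2, centre xyz
    apex_points: dict[str, np.ndarray]
    station_s: np.ndarray
    wall_pre_kpa: np.ndarray
    wall_post_kpa: np.ndarray
    covered: np.ndarray  # boolean mask over stations
    sections: list[str]

    def radius(self, label: str) -> float:
        return float(self.ends.set_index("label").loc[label, "radius_mm"])

    def loa(self, label: str) -> float:
        return float(self.ends.set_index("label").loc[label, "loa_mm2"])


def _end_equilibrium(
    st: VesselStation,
    lam_pre: float,
    p_graft: float,
    release: tuple[np.ndarray, np.ndarray],
    sg: StentGraft,
    config: DeploymentConfig,
    wall: YeohParams,
    label: str,
) -> float:
    """Deployed radius of one ring: root of P_stent(r) + P_graft - P_contact(r).

    Contact is unilateral: the wall can only push inward, so its contribution
    is clamped at zero.  ``P_wall(r) > 0`` holds exactly when the stent radius
    exceeds the wall's own zero-pressure recoil radius, i.e. when wall and
    device overlap; a wall hanging outside the device leaves a gap and the
    device opens to the graft cap.
    """
    radii, pressures = release
    p_stent = lambda r: float(np.interp(r, radii, pressures))
    f = lambda r: p_stent(r) + p_graft - max(_wall_pressure(r, st, lam_pre, wall), 0.0)

    lo, hi = radii[0], sg.nominal_radius + 1.0
    flo, fhi = f(lo), f(hi)
    if flo < 0 or fhi > 0:
        raise SolverError(
            f"{label}: no radial equilibrium in [{lo:.2f}, {hi:.2f}] mm "
            f"(f(lo)={flo:.3g}, f(hi)={fhi:.3g} kPa)"
        )
    return brentq(f, lo, hi, xtol=1e-10)


def deploy(sg: StentGraft, vessel: VesselModel, config: DeploymentConfig) -> DeploymentResult:
    """Crimp, position, release and pressurise the device; solve every strut-end ring.

    ``vessel.prestress`` must already hold the fixed-point field for variants
    B and C (it is ignored — forced to zero — for variant A).  Pre-dilation
    of the narrowed lumen is applied internally before equilibrium.
    """
    ends_s = strut_end_arclengths(sg, config.landing_offset)
    smax = vessel.arclengths.max()
    if max(ends_s.values()) > smax + 1e-9:
        raise ValueError("device does not fit on the centreline from the landing offset")

    wall = YEOH_DISSECTED_AORTA
    vessel_d = predilate(vessel, config)
    sigma0 = np.zeros_like(vessel_d.prestress) if config.variant == "A" else vessel_d.prestress
    p_graft_cov = mmhg_to_kpa(config.lumen_pressure) if config.variant == "C" else 0.0

    radii_tab, pressures_tab, _ = _release_curve(sg, config)
    release = (radii_tab, pressures_tab)

    lam_pre_cache: dict[int, float] = {}

    def lam_pre_at(k: int) -> float:
        if k not in lam_pre_cache:
            lam_pre_cache[k] = _prestretch_from_sigma0(float(sigma0[k]), wall)
        return lam_pre_cache[k]

    rows = []
    apexes: dict[str, np.ndarray] = {}
    for label in sg.end_labels:
        s_e = ends_s[label]
        k = vessel_d.nearest_station(s_e)
        st = vessel_d.stations[k]
        covered_end = not (sg.bare_proximal and label == "P1")
        p_graft = p_graft_cov if covered_end else 0.0
        r_dep = _end_equilibrium(st, lam_pre_at(k), p_graft, release, sg, config, wall, label)
        pts = circle_points(st.centre, st.tangent, r_dep, sg.strut_apexes_per_end)
        rows.append(
            {
                "label": label,
                "s_mm": s_e,
                "radius_mm": r_dep,
                "loa_mm2": metrics.local_open_area(pts, label=label),
                "cx_mm": st.centre[0],
                "cy_mm": st.centre[1],
                "cz_mm": st.centre[2],
                "section": st.section,
            }
        )
        apexes[label] = pts

    ends = pd.DataFrame(rows)

    # per-station wall stress before/after: the graft tube is interpolated
    # linearly between strut-end radii over the covered span
    s_all = vessel_d.arclengths
    covered = (s_all >= config.landing_offset - 1e-9) & (s_all <= config.landing_offset + sg.length + 1e-9)
    end_s_sorted = ends.sort_values("s_mm")
    r_interp = np.interp(s_all, end_s_sorted["s_mm"], end_s_sorted["radius_mm"])
    pre = np.asarray(sigma0, dtype=float).copy()
    post = pre.copy()
    for k, st in enumerate(vessel_d.stations):
        if covered[k]:
            lam_tot = (r_interp[k] / st.ct_radius) * lam_pre_at(k)
            post[k] = yeoh_ring_hoop_cauchy(lam_tot, wall)
    return DeploymentResult(
        variant=config.variant,
        ends=ends,
        apex_points=apexes,
        station_s=s_all,
        wall_pre_kpa=pre,
        wall_post_kpa=post,
        covered=covered,
        sections=[st.section for st in vessel_d.stations],
    )


def wall_stress_report(result: DeploymentResult, vessel: VesselModel) -> pd.DataFrame:
    """Pre- vs post-deployment wall hoop stress per landing section.

    Summaries (mean, 10th, 90th percentile) over the covered stations of each
    section, with the direction of the change flagged: on the default patient
    the entry tear is shielded (post < pre) while the narrowed dissection is
    pushed open (post > pre).
    """
    rows = []
    sections = np.array(result.sections)
    for sec in pd.unique(sections):
        mask = (sections == sec) & result.covered
        if not mask.any():
            continue
        pre = result.wall_pre_kpa[mask]
        post = result.wall_post_kpa[mask]
        d = float(post.mean() - pre.mean())
        rows.append(
            {
                "section": sec,
                "n_stations": int(mask.sum()),
                "pre_mean_kpa": float(pre.mean()),
                "pre_p10_kpa": float(np.percentile(pre, 10)),
                "pre_p90_kpa": float(np.percentile(pre, 90)),
                "post_mean_kpa": float(post.mean()),
                "post_p10_kpa": float(np.percentile(post, 10)),
                "post_p90_kpa": float(np.percentile(post, 90)),
                "mean_change_kpa": d,
                "direction": "increase" if d > 0 else ("decrease" if d < 0 else "unchanged"),
            }
        )
    return pd.DataFrame(rows)
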