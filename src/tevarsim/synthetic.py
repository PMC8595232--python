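"""Synthetic patient: reduced-order vessel, tensile records and reference stent fixtures.

The vessel stands in for CT-derived anatomy.  It is a list of centreline
stations, each a thin ring with a target (imaged, diastolic) radius, wall
thickness, section label and optional intimal flap.  Defaults emulate a
complicated type B dissection: a healthy proximal aorta, an aneurysmally
enlarged entry-tear region, and a dissection section whose true lumen tapers
to a 6.5 mm minimum diameter, wall thickness 1.5 mm, flap 0.6-1.6 mm.

All generators are pure functions of (config, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator

from .materials import NITINOL_VALIANT, NitinolParams, YeohParams, yeoh_uniaxial_cauchy

__all__ = [
    "ConfigError",
    "AnatomyConfig",
    "VesselStation",
    "VesselModel",
    "StentGraft",
    "generate_vessel",
    "generate_tensile_data",
    "reference_stent_configuration",
    "strut_end_arclengths",
    "circle_points",
]

HEALTHY = "healthy"
ENTRY_TEAR = "entry_tear"
DISSECTION = "dissection"


class ConfigError(ValueError):
    """Inconsistent anatomy / device configuration."""


@dataclass(frozen=True)
class AnatomyConfig:
    """Geometry of the synthetic dissected aorta (lengths in mm, radii in mm).

    The three sections are contiguous along arclength:
    healthy [0, healthy_end), entry tear [healthy_end, entry_end),
    dissection [entry_end, length].  The radius profile is a smooth
    (monotone-segment PCHIP) blend through section target radii, tapering to
    ``min_lumen_diameter / 2`` inside the dissection.
    """

    length: float = 180.0
    ds: float = 1.0
    healthy_end: float = 61.0
    entry_end: float = 95.0
    healthy_radius: float = 13.0
    entry_radius: float = 15.0
    min_lumen_diameter: float = 6.5
    distal_radius: float = 5.0
    taper_end: float = 120.0
    throat_end: float = 150.0
    wall_thickness: float = 1.5
    flap_thickness_range: tuple[float, float] = (0.6, 1.6)
    flap_E: float = 277.0
    lumen_pressure: float = 80.0
    radius_noise_sd: float = 0.0
    bend_radius: float | None = None

    def __post_init__(self) -> None:
        if not (0 < self.healthy_end < self.entry_end < self.taper_end < self.throat_end < self.length):
            raise ConfigError("section boundaries must be ordered within the vessel length")
        for r in (self.healthy_radius, self.entry_radius, self.min_lumen_diameter, self.distal_radius):
            if r <= 0:
                raise ConfigError("radii must be positive")
        if self.radius_noise_sd < 0:
            raise ConfigError("radius noise must be non-negative")


@dataclass
class VesselStation:
    """One cross-section of the reduced-order vessel."""

    s: float
    centre: np.ndarray
    tangent: np.ndarray
    ct_radius: float
    h0: float = 1.5
    section: str = HEALTHY
    flap_present: bool = False
    flap_thickness: float = 0.0
    flap_E: float = 277.0

    def __post_init__(self) -> None:
        self.centre = np.asarray(self.centre, dtype=float)
        self.tangent = np.asarray(self.tangent, dtype=float)
        if self.ct_radius <= 0 or self.h0 <= 0:
            raise ConfigError("station radius and wall thickness must be positive")


@dataclass
class VesselModel:
    """Ordered stations plus luminal pressure and the per-station pre-stress field."""

    stations: list[VesselStation]
    lumen_pressure: float = 80.0
    prestress: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.prestress is None:
            self.prestress = np.zeros(len(self.stations))
        self.prestress = np.asarray(self.prestress, dtype=float)
        if self.lumen_pressure < 0:
            raise ConfigError("pressure must be non-negative")
        if len(self.prestress) != len(self.stations):
            raise ConfigError("prestress field length must match the station count")
        s = self.arclengths
        if np.any(np.diff(s) <= 0):
            raise ConfigError("stations must be ordered by arclength")

    @property
    def arclengths(self) -> np.ndarray:
        return np.array([st.s for st in self.stations])

    @property
    def radii(self) -> np.ndarray:
        return np.array([st.ct_radius for st in self.stations])

    def nearest_station(self, s: float) -> int:
        return int(np.argmin(np.abs(self.arclengths - s)))

    def with_prestress(self, sigma0: np.ndarray) -> "VesselModel":
        return VesselModel([replace(st) for st in self.stations], self.lumen_pressure, np.asarray(sigma0, float).copy())

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for st, s0 in zip(self.stations, self.prestress):
            rows.append(
                {
                    "s_mm": st.s,
                    "x_mm": st.centre[0],
                    "y_mm": st.centre[1],
                    "z_mm": st.centre[2],
                    "ct_radius_mm": st.ct_radius,
                    "wall_thickness_mm": st.h0,
                    "section": st.section,
                    "flap_present": st.flap_present,
                    "flap_thickness_mm": st.flap_thickness,
                    "prestress_kPa": s0,
                }
            )
        return pd.DataFrame(rows)


@dataclass
class StentGraft:
    """Device specification: a 28-28-150 self-expanding stent-graft, 9 Z-stent struts.

    ``strut_length`` is the axial span of one strut ring; rings are evenly
    pitched so that D9 lands at ``length`` from P1.  The proximal ring (P1) is
    a bare metal stent not covered by graft fabric.
    """

    nominal_diameter: float = 28.0
    length: float = 150.0
    n_struts: int = 9
    strut_length: float = 14.0
    strut_apexes_per_end: int = 5
    wire: NitinolParams = field(default_factory=lambda: NITINOL_VALIANT)
    graft_thickness: float = 0.1
    graft_E: float = 1.0e6
    bare_proximal: bool = True

    def __post_init__(self) -> None:
        if self.n_struts < 1 or self.nominal_diameter <= 0:
            raise ConfigError("device must have at least one strut and a positive diameter")

    @property
    def nominal_radius(self) -> float:
        return self.nominal_diameter / 2.0

    @property
    def end_labels(self) -> list[str]:
        out = []
        for i in range(1, self.n_struts + 1):
            out += [f"P{i}", f"D{i}"]
        return out


def strut_end_arclengths(sg: StentGraft, landing_offset: float) -> dict[str, float]:
    """Arclength of every strut end (P1..P9, D1..D9) measured along the centreline."""
    pitch = (sg.length - sg.strut_length) / max(sg.n_struts - 1, 1)
    out: dict[str, float] = {}
    for i in range(1, sg.n_struts + 1):
        p = landing_offset + (i - 1) * pitch
        out[f"P{i}"] = p
        out[f"D{i}"] = p + sg.strut_length
    return out


def generate_vessel(config: AnatomyConfig | None = None, seed: int = 0) -> VesselModel:
    """Build the synthetic dissected vessel: smooth radius profile, three sections.

    Deterministic for fixed (config, seed).  At default settings the minimum
    lumen diameter over the dissection section equals ``min_lumen_diameter``
    exactly and the centreline is a straight line (set ``bend_radius`` for a
    circular-arc bend in the x-z plane).
    """
    cfg = config if config is not None else AnatomyConfig()
    rng = np.random.default_rng(seed)
    s = np.arange(0.0, cfg.length + cfg.ds / 2, cfg.ds)

    r_min = cfg.min_lumen_diameter / 2.0
    knots_s = [0.0, cfg.healthy_end - 6.0, cfg.healthy_end + 4.0, cfg.entry_end - 10.0,
               cfg.taper_end, cfg.throat_end, cfg.length]
    knots_r = [cfg.healthy_radius, cfg.healthy_radius, cfg.entry_radius, cfg.entry_radius,
               r_min, r_min, cfg.distal_radius]
    if np.any(np.diff(knots_s) <= 0):
        raise ConfigError("radius-profile knots are not ordered; check section boundaries")
    radii = PchipInterpolator(knots_s, knots_r)(s)
    if cfg.radius_noise_sd > 0:
        radii = np.maximum(radii + rng.normal(0.0, cfg.radius_noise_sd, size=s.size), 0.5)

    if cfg.bend_radius is None:
        centres = np.column_stack([np.zeros_like(s), np.zeros_like(s), s])
        tangents = np.tile([0.0, 0.0, 1.0], (s.size, 1))
    else:
        R = cfg.bend_radius
        th = s / R
        centres = np.column_stack([R * (1 - np.cos(th)), np.zeros_like(s), R * np.sin(th)])
        tangents = np.column_stack([np.sin(th), np.zeros_like(s), np.cos(th)])

    lo, hi = cfg.flap_thickness_range
    stations = []
    for k, sk in enumerate(s):
        if sk < cfg.healthy_end:
            section = HEALTHY
        elif sk < cfg.entry_end:
            section = ENTRY_TEAR
        else:
            section = DISSECTION
        flap = section == DISSECTION
        t = (sk - cfg.entry_end) / max(cfg.length - cfg.entry_end, 1e-9)
        stations.append(
            VesselStation(
                s=float(sk),
                centre=centres[k],
                tangent=tangents[k],
                ct_radius=float(radii[k]),
                h0=cfg.wall_thickness,
                section=section,
                flap_present=flap,
                flap_thickness=float(lo + t * (hi - lo)) if flap else 0.0,
                flap_E=cfg.flap_E,
            )
        )
    return VesselModel(stations, lumen_pressure=cfg.lumen_pressure)


def generate_tensile_data(
    params: YeohParams,
    n_samples: int = 12,
    noise_sd: float = 0.02,
    lam_max: float = 1.3,
    seed: int = 0,
    n_points: int = 50,
    width: float = 10.0,
    thickness: float = 1.5,
    grip_distance: float = 25.0,
    preload: float = 0.05,
):
    """Synthetic strip-test records consistent with the uniaxial Yeoh law.

    Inverts the ``to_stress_stretch`` conversion exactly: at ``noise_sd = 0``
    the pipeline generate -> convert -> fit is the identity on ``params``.
    Noise is multiplicative Gaussian on the stress, per point, seeded.
    Defaults emulate the wet-lab protocol (12 samples, 25 mm grips, 40 x 10 mm
    strips, preconditioning load 0.05 N).
    """
    from .tensile import TensileSample  # local import to avoid a cycle

    if n_samples < 1:
        raise ValueError("need at least one sample")
    if lam_max <= 1:
        raise ValueError("lam_max must exceed 1")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    rng = np.random.default_rng(seed)
    area = width * thickness
    sigma_pre = preload / area * 1e3  # kPa carried by the preload itself
    samples = []
    for k in range(n_samples):
        lam = np.linspace(1.0, lam_max, n_points)
        sigma = yeoh_uniaxial_cauchy(lam, params)
        if noise_sd > 0:
            sigma = sigma * (1.0 + noise_sd * rng.standard_normal(n_points))
        disp = (lam - 1.0) * grip_distance
        force = (sigma + sigma_pre) * area / (1e3 * lam)
        samples.append(
            TensileSample(
                sample_id=f"synthetic-{k + 1:02d}",
                width_0=width,
                thickness_0=thickness,
                series=np.column_stack([disp, force]),
                grip_distance_0=grip_distance,
                preload=preload,
            )
        )
    return samples


def circle_points(centre, tangent, radius: float, n: int, phase: float = 0.0) -> np.ndarray:
    """``n`` points on a circle of given radius in the plane normal to ``tangent``."""
    t = np.asarray(tangent, dtype=float)
    t = t / np.linalg.norm(t)
    helper = np.array([1.0, 0.0, 0.0])
    if abs(t @ helper) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    u = np.cross(t, helper)
    u /= np.linalg.norm(u)
    v = np.cross(t, u)
    ang = phase + 2 * np.pi * np.arange(n) / n
    return np.asarray(centre) + radius * (np.outer(np.cos(ang), u) + np.outer(np.sin(ang), v))


def reference_stent_configuration(
    loa_targets: dict[str, float],
    vessel: VesselModel,
    landing_offset: float = 20.0,
    sg: StentGraft | None = None,
    n_points: int = 16,
) -> dict[str, np.ndarray]:
    """Build labelled apex-point sets whose true open areas are known.

    For each strut end the points lie on a circle normal to the local
    centreline tangent with area equal to the target, so recomputing the
    open-area metric on them recovers the target (up to spline
    discretisation).  Serves as the stand-in for a follow-up-scan stent
    reconstruction when testing the validation metrics.
    """
    device = sg if sg is not None else StentGraft()
    ends = strut_end_arclengths(device, landing_offset)
    out: dict[str, np.ndarray] = {}
    for label, area in loa_targets.items():
        if area <= 0:
            raise ValueError(f"{label}: open-area target must be positive, got {area}")
        if label not in ends:
            raise ValueError(f"unknown strut end label {label!r}")
        st = vessel.stations[vessel.nearest_station(ends[label])]
        out[label] = circle_points(st.centre, st.tangent, math.sqrt(area / math.pi), n_points)
    return out
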