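"""Configuration metrics: local open area (LOA), strut-centre deviation, section tables.

The stent deforms to a non-cylindrical shape in a narrowed true lumen, so
cross-sections are assessed end-by-end: a periodic spline through the apex
points of each strut end encloses the local open area; the Euclidean
distance between simulated and reference apex centroids gives the strut
position deviation ``e_c``.  Per-end deviations are summarised per landing
section (healthy aorta / entry tear / dissection) as mean, population SD and
extremes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline
from shapely.geometry import LineString

__all__ = [
    "GeometryError",
    "StrutEndMeasurement",
    "local_open_area",
    "strut_centre_deviation",
    "section_summary",
    "loa_border_jump",
    "validation_report",
    "DEFAULT_SECTION_MAP",
]

#: Landing-section assignment of the 18 strut ends: struts 1-2 and the
#: proximal end of strut 3 land in the healthy aorta, D3 through P5 in the
#: entry-tear region, D5 and everything distal in the dissected true lumen.
DEFAULT_SECTION_MAP: dict[str, str] = {
    **{lbl: "healthy" for lbl in ("P1", "D1", "P2", "D2", "P3")},
    **{lbl: "entry_tear" for lbl in ("D3", "P4", "D4", "P5")},
    **{lbl: "dissection" for lbl in ("D5", "P6", "D6", "P7", "D7", "P8", "D8", "P9", "D9")},
}


class GeometryError(ValueError):
    """Degenerate apex geometry (collinear points, self-intersecting loop)."""


def _project_to_plane(points: np.ndarray) -> np.ndarray:
    """Project 3D apex points onto their least-squares plane (principal axes)."""
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3 or pts.shape[0] < 3:
        raise GeometryError("need at least 3 points in 3D")
    centred = pts - pts.mean(axis=0)
    _, s, vt = np.linalg.svd(centred, full_matrices=False)
    if s[1] <= 1e-9 * max(s[0], 1e-30):
        raise GeometryError("apex points are collinear")
    return centred @ vt[:2].T


def _shoelace(x: np.ndarray, y: np.ndarray) -> float:
    return 0.5 * abs(float(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))))


def local_open_area(
    apex_points,
    mode: str = "spline",
    samples: int = 2048,
    label: str = "",
) -> float:
    """Area (mm^2) enclosed by a closed curve through ordered apex points.

    The points are projected onto their least-squares plane; the loop is
    closed with a periodic cubic spline under chord-length parameterisation
    and the area evaluated by the shoelace rule on a dense sampling
    (``mode="polygon"`` skips the spline and uses the polygon directly, as a
    cross-check).  Invariant under rigid-body transforms of the points.
    """
    xy = _project_to_plane(apex_points)
    tag = f"{label}: " if label else ""
    if mode == "polygon":
        x, y = xy[:, 0], xy[:, 1]
    elif mode == "spline":
        closed = np.vstack([xy, xy[:1]])
        chord = np.linalg.norm(np.diff(closed, axis=0), axis=1)
        if np.any(chord <= 0):
            raise GeometryError(f"{tag}coincident consecutive apex points")
        t = np.concatenate([[0.0], np.cumsum(chord)])
        spl = CubicSpline(t, closed, bc_type="periodic")
        dense = spl(np.linspace(0.0, t[-1], samples, endpoint=False))
        x, y = dense[:, 0], dense[:, 1]
    else:
        raise ValueError(f"unknown mode {mode!r}")
    ring = np.column_stack([x, y])
    if not LineString(np.vstack([ring, ring[:1]])).is_simple:
        raise GeometryError(f"{tag}projected apex loop is self-intersecting")
    return _shoelace(x, y)


@dataclass
class StrutEndMeasurement:
    """One strut end: ordered apex points with the derived LOA and centre."""

    label: str
    apex_points: np.ndarray
    loa: float = field(init=False)
    centre: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.apex_points = np.asarray(self.apex_points, dtype=float)
        self.loa = local_open_area(self.apex_points, label=self.label)
        self.centre = self.apex_points.mean(axis=0)


def strut_centre_deviation(sim: StrutEndMeasurement, ref: StrutEndMeasurement) -> float:
    """Euclidean distance (mm) between simulated and reference apex centroids."""
    if sim.label != ref.label:
        raise ValueError(f"label mismatch: {sim.label!r} vs {ref.label!r}")
    return float(np.linalg.norm(sim.centre - ref.centre))


def section_summary(
    per_end_values: dict[str, float],
    section_map: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Mean, population SD and [min, max] of a per-end quantity, per landing section."""
    smap = section_map if section_map is not None else DEFAULT_SECTION_MAP
    missing = [lbl for lbl in per_end_values if lbl not in smap]
    if missing:
        raise ValueError(f"strut ends not assigned to a section: {missing}")
    rows = []
    order = list(dict.fromkeys(smap.values()))
    for sec in order:
        vals = np.array([v for lbl, v in per_end_values.items() if smap[lbl] == sec])
        if vals.size == 0:
            continue
        rows.append(
            {
                "section": sec,
                "n": int(vals.size),
                "mean": float(vals.mean()),
                "sd": float(vals.std(ddof=0)),
                "min": float(vals.min()),
                "max": float(vals.max()),
            }
        )
    return pd.DataFrame(rows)


def loa_border_jump(loa: dict[str, float]) -> dict[str, float]:
    """Absolute LOA differences across the landing-section borders (P3|D3 and P5|D5)."""
    for lbl in ("P3", "D3", "P5", "D5"):
        if lbl not in loa:
            raise ValueError(f"missing strut end {lbl!r}")
    return {
        "P3-D3": abs(loa["D3"] - loa["P3"]),
        "P5-D5": abs(loa["D5"] - loa["P5"]),
    }


def validation_report(
    sim_ends: dict[str, np.ndarray],
    ref_ends: dict[str, np.ndarray],
    section_map: dict[str, str] | None = None,
) -> dict[str, pd.DataFrame]:
    """Per-end and per-section comparison of two labelled apex-point sets.

    Returns a dict with ``per_end`` (label, LOA sim/ref, e_LOA %, e_c mm) and
    ``e_loa_sections`` / ``e_c_sections`` summary tables.  ``e_LOA`` is the
    signed relative area deviation ``100 (sim - ref) / ref``; both point sets
    must share a coordinate frame (apply any rigid pre-alignment first).
    """
    labels = [lbl for lbl in sim_ends if lbl in ref_ends]
    if not labels:
        raise ValueError("no common strut-end labels between simulation and reference")
    rows = []
    e_loa: dict[str, float] = {}
    e_c: dict[str, float] = {}
    for lbl in labels:
        sim = StrutEndMeasurement(lbl, sim_ends[lbl])
        ref = StrutEndMeasurement(lbl, ref_ends[lbl])
        e_loa[lbl] = 100.0 * (sim.loa - ref.loa) / ref.loa
        e_c[lbl] = strut_centre_deviation(sim, ref)
        rows.append(
            {
                "label": lbl,
                "loa_sim_mm2": sim.loa,
                "loa_ref_mm2": ref.loa,
                "e_loa_pct": e_loa[lbl],
                "e_c_mm": e_c[lbl],
            }
        )
    return {
        "per_end": pd.DataFrame(rows),
        "e_loa_sections": section_summary(e_loa, section_map),
        "e_c_sections": section_summary(e_c, section_map),
    }
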