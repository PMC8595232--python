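"""Uniaxial strip-test processing and Yeoh parameter fitting.

Raw records are force-displacement series from circumferential wall strips
(40 x 10 mm, 25 mm grip distance, 0.05 N preconditioning load).  The pipeline
is: reference the stretch at the preload point, convert to Cauchy stress via
the incompressible area reduction ``A = A0 / lam``, truncate at the yield
point, and fit the three Yeoh coefficients per sample by nonlinear least
squares; coefficients are then averaged across samples.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .materials import YeohParams, yeoh_uniaxial_cauchy

__all__ = [
    "DataError",
    "FitError",
    "NoYieldWarning",
    "TensileSample",
    "StressStretchCurve",
    "FitResult",
    "AveragedFit",
    "to_stress_stretch",
    "detect_yield",
    "fit_yeoh",
    "average_params",
    "read_samples",
    "fit_table",
]


class DataError(ValueError):
    """Malformed or unphysical tensile-test data."""


class FitError(RuntimeError):
    """Nonlinear fit failed to converge; carries the best iterate."""

    def __init__(self, message: str, best: "FitResult | None" = None):
        super().__init__(message)
        self.best = best


class NoYieldWarning(UserWarning):
    """The stress curve rises monotonically; no yield point was found."""


@dataclass
class TensileSample:
    """One strip sample: initial geometry plus the grip displacement / force series.

    ``series`` is an (n, 2) array of (displacement mm, force N), displacement
    non-decreasing.  Defaults follow the test protocol: 25 mm grips, 0.05 N
    preconditioning load.
    """

    sample_id: str
    width_0: float
    thickness_0: float
    series: np.ndarray
    grip_distance_0: float = 25.0
    preload: float = 0.05

    def __post_init__(self) -> None:
        self.series = np.asarray(self.series, dtype=float)
        if self.series.ndim != 2 or self.series.shape[1] != 2:
            raise DataError("series must be an (n, 2) array of (displacement, force)")
        if self.grip_distance_0 <= 0:
            raise DataError("grip distance must be positive")
        if self.width_0 * self.thickness_0 <= 0:
            raise DataError("cross-section must be positive")
        if np.any(np.diff(self.series[:, 0]) < -1e-12):
            raise DataError(f"{self.sample_id}: displacement must be non-decreasing")

    @property
    def area_0(self) -> float:
        """Reference cross-section in mm^2."""
        return self.width_0 * self.thickness_0


@dataclass
class StressStretchCurve:
    """Preload-referenced stretch / Cauchy-stress curve (stress in kPa)."""

    lam: np.ndarray
    sigma: np.ndarray
    yield_index: int | None = None
    sample_id: str = ""

    def __post_init__(self) -> None:
        self.lam = np.asarray(self.lam, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        if np.any(np.diff(self.lam) <= 0):
            raise DataError("stretch values must be strictly increasing")


@dataclass
class FitResult:
    params: YeohParams
    r_squared: float
    residuals: np.ndarray = field(repr=False)
    sample_id: str = ""


@dataclass(frozen=True)
class AveragedFit:
    """Arithmetic mean of per-sample coefficients and of R^2."""

    params: YeohParams
    mean_r_squared: float
    n_samples: int


def to_stress_stretch(sample: TensileSample) -> StressStretchCurve:
    """Convert a raw force-displacement record into a stretch / Cauchy-stress curve.

    The stretch reference is the grip distance at which the force first
    reaches the preconditioning load (linearly interpolated between samples);
    stretch is ``lam = (L0 + d) / L_ref``.  Cauchy stress uses the
    incompressible area reduction: ``sigma = F * lam / A0`` (N, mm -> MPa,
    reported in kPa), minus the small preload stress so the referenced curve
    starts at ~0.
    """
    disp = sample.series[:, 0]
    force = sample.series[:, 1]
    above = np.nonzero(force >= sample.preload)[0]
    if above.size == 0:
        raise DataError(f"{sample.sample_id}: force never reaches the preload")
    i = int(above[0])
    if i == 0 or force[i] == sample.preload:
        d_ref = disp[i]
        keep = slice(i, None)
        lam = (sample.grip_distance_0 + disp[keep]) / (sample.grip_distance_0 + d_ref)
        f = force[keep]
    else:
        # interpolate the exact preload crossing and prepend it as the reference point
        t = (sample.preload - force[i - 1]) / (force[i] - force[i - 1])
        d_ref = disp[i - 1] + t * (disp[i] - disp[i - 1])
        lam = np.concatenate(
            [[1.0], (sample.grip_distance_0 + disp[i:]) / (sample.grip_distance_0 + d_ref)]
        )
        f = np.concatenate([[sample.preload], force[i:]])

    # collapse exact stretch ties (grips stationary between readings), keep first
    keep_mask = np.concatenate([[True], np.diff(lam) > 0])
    lam, f = lam[keep_mask], f[keep_mask]

    sigma_raw = f * lam / sample.area_0 * 1e3  # kPa
    sigma = sigma_raw - sample.preload / sample.area_0 * 1e3
    return StressStretchCurve(lam=lam, sigma=sigma, sample_id=sample.sample_id)


def detect_yield(curve: StressStretchCurve) -> int:
    """Index of the yield point: first occurrence of the global stress maximum.

    Physically the onset of tearing in a strip test; later points are excluded
    from fitting.  A monotonically rising curve has no interior maximum: the
    last index is returned with a :class:`NoYieldWarning`.
    """
    if curve.sigma.size < 5:
        raise DataError("need at least 5 points to locate a yield point")
    idx = int(np.argmax(curve.sigma))  # argmax returns the first maximum
    if idx == curve.sigma.size - 1:
        warnings.warn(
            f"{curve.sample_id or 'curve'}: stress rises to the last point; no yield detected",
            NoYieldWarning,
            stacklevel=2,
        )
    return idx


_DEFAULT_INIT = YeohParams(10.0, 10.0, 10.0)


def fit_yeoh(
    curve: StressStretchCurve,
    init: YeohParams = _DEFAULT_INIT,
    yield_index: int | None = None,
    n_starts: int = 3,
    seed: int = 0,
) -> FitResult:
    """Least-squares fit of the incompressible uniaxial Yeoh stress to a curve.

    The curve is truncated at the yield point (explicit ``yield_index``
    overrides the curve's own, which overrides automatic detection).  A small
    multi-start (``n_starts`` jittered initialisations, fixed ``seed``) guards
    against local minima; only ``c10`` is bounded positive.
    """
    if yield_index is None:
        yield_index = curve.yield_index
    if yield_index is None:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", NoYieldWarning)
            yield_index = detect_yield(curve)
    lam = curve.lam[: yield_index + 1]
    sig = curve.sigma[: yield_index + 1]
    if lam.size < 4:
        raise DataError("need at least 4 points below the yield point to fit 3 parameters")

    def resid(c):
        return yeoh_uniaxial_cauchy(lam, YeohParams(max(c[0], 1e-12), c[1], c[2])) - sig

    rng = np.random.default_rng(seed)
    x0s = [np.array([init.c10, init.c20, init.c30], dtype=float)]
    for _ in range(max(0, n_starts - 1)):
        x0s.append(x0s[0] * rng.lognormal(0.0, 0.3, size=3))

    best = None
    for x0 in x0s:
        res = least_squares(
            resid,
            x0,
            bounds=([1e-12, -np.inf, -np.inf], [np.inf, np.inf, np.inf]),
            xtol=1e-14,
            ftol=1e-14,
            gtol=1e-14,
        )
        if best is None or res.cost < best.cost:
            best = res

    params = YeohParams(*best.x)
    residuals = resid(best.x)
    ss_res = float(np.sum(residuals**2))
    ss_tot = float(np.sum((sig - sig.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    result = FitResult(params, max(r2, 0.0), residuals, curve.sample_id)
    if not best.success:
        raise FitError(f"fit did not converge: {best.message}", best=result)
    return result


def average_params(fits: list[FitResult]) -> AveragedFit:
    """Arithmetic mean of each Yeoh coefficient (and of R^2) across samples."""
    if not fits:
        raise ValueError("cannot average an empty list of fits")
    c10 = float(np.mean([f.params.c10 for f in fits]))
    c20 = float(np.mean([f.params.c20 for f in fits]))
    c30 = float(np.mean([f.params.c30 for f in fits]))
    r2 = float(np.mean([f.r_squared for f in fits]))
    return AveragedFit(YeohParams(c10, c20, c30), r2, len(fits))


# ---------------------------------------------------------------------------
# I/O: one CSV per sample (displacement_mm, force_N) plus a manifest
# ---------------------------------------------------------------------------


def read_samples(manifest_path) -> list[TensileSample]:
    """Read samples listed in a manifest CSV.

    Manifest columns: ``sample_id, file, width_mm, thickness_mm`` and
    optionally ``grip_distance_mm, preload_N``; ``file`` paths are resolved
    relative to the manifest.
    """
    import pathlib

    manifest_path = pathlib.Path(manifest_path)
    man = pd.read_csv(manifest_path)
    samples = []
    for _, row in man.iterrows():
        data = pd.read_csv(manifest_path.parent / row["file"])
        samples.append(
            TensileSample(
                sample_id=str(row["sample_id"]),
                width_0=float(row["width_mm"]),
                thickness_0=float(row["thickness_mm"]),
                series=data[["displacement_mm", "force_N"]].to_numpy(),
                grip_distance_0=float(row.get("grip_distance_mm", 25.0)),
                preload=float(row.get("preload_N", 0.05)),
            )
        )
    return samples


def fit_table(fits: list[FitResult], averaged: AveragedFit | None = None) -> pd.DataFrame:
    """Per-sample fitted coefficients (plus an 'average' row) as a DataFrame."""
    rows = [
        {
            "sample_id": f.sample_id,
            "c10_kPa": f.params.c10,
            "c20_kPa": f.params.c20,
            "c30_kPa": f.params.c30,
            "r_squared": f.r_squared,
        }
        for f in fits
    ]
    if averaged is not None:
        rows.append(
            {
                "sample_id": "average",
                "c10_kPa": averaged.params.c10,
                "c20_kPa": averaged.params.c20,
                "c30_kPa": averaged.params.c30,
                "r_squared": averaged.mean_r_squared,
            }
        )
    return pd.DataFrame(rows)
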