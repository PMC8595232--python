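"""End-to-end run: fit tissue -> synth vessel -> pre-stress -> deploy -> validate.

Every artifact embeds the seed and a hash of the effective configuration, so
re-running with the same config reproduces identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import pathlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import metrics
from .deployment import DeploymentConfig, DeploymentResult, deploy, wall_stress_report
from .materials import YEOH_DISSECTED_AORTA
from .prestress import prestress_fixed_point
from .synthetic import (
    AnatomyConfig,
    StentGraft,
    VesselModel,
    generate_tensile_data,
    generate_vessel,
    reference_stent_configuration,
)
from .tensile import average_params, fit_table, fit_yeoh, to_stress_stretch

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """Configuration of one pipeline run."""

    outdir: str = "tevarsim-out"
    seed: int = 0
    variants: tuple[str, ...] = ("A", "B", "C")
    anatomy: AnatomyConfig = field(default_factory=AnatomyConfig)
    device: StentGraft = field(default_factory=StentGraft)
    deployment: DeploymentConfig = field(default_factory=lambda: DeploymentConfig(variant="C"))
    tensile_noise_sd: float = 0.02
    tensile_n_samples: int = 12
    reference_variant: str = "C"

    def config_hash(self) -> str:
        payload = _as_jsonable(self)
        payload.pop("outdir", None)  # where results land does not change what they are
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def _as_jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _as_jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, (np.ndarray, list, tuple)):
        return [_as_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, dict):
        return {k: _as_jsonable(v) for k, v in obj.items()}
    return obj


def _write_apexes(path: pathlib.Path, apexes: dict[str, np.ndarray]) -> None:
    rows = []
    for lbl, pts in apexes.items():
        for i, p in enumerate(pts):
            rows.append({"label": lbl, "point_index": i, "x": p[0], "y": p[1], "z": p[2]})
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.9g")
    xyz = path.with_suffix(".xyz")
    with open(xyz, "w") as fh:  # plain-text point cloud for quick visualisation
        for row in rows:
            fh.write(f"{row['x']:.6f} {row['y']:.6f} {row['z']:.6f}\n")


def run_pipeline(config: RunConfig | None = None) -> dict:
    """Execute the full stage sequence and write per-stage artifacts.

    Stages: synthetic tensile data -> per-sample Yeoh fits -> averaged wall
    parameters; synthetic vessel; pre-stress fixed point; deployment of the
    requested variants (vessel and pre-stress artifacts shared across
    variants); validation of every variant against a reference configuration
    built from the ``reference_variant`` deployment.  Returns the summary
    dict that is also written to ``summary.json``.
    """
    cfg = config if config is not None else RunConfig()
    out = pathlib.Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    stamp = {"seed": cfg.seed, "config_hash": cfg.config_hash()}

    # --- tissue fitting on synthetic strip tests -------------------------
    samples = generate_tensile_data(
        YEOH_DISSECTED_AORTA,
        n_samples=cfg.tensile_n_samples,
        noise_sd=cfg.tensile_noise_sd,
        seed=cfg.seed,
    )
    fits = [fit_yeoh(to_stress_stretch(s)) for s in samples]
    averaged = average_params(fits)
    fit_table(fits, averaged).to_csv(out / "tissue_fits.csv", index=False, float_format="%.9g")

    # --- vessel + pre-stress (shared across variants) --------------------
    vessel = generate_vessel(cfg.anatomy, seed=cfg.seed)
    pres = prestress_fixed_point(vessel, pressure=vessel.lumen_pressure)
    vessel_ps = vessel.with_prestress(pres.sigma0_field)
    vessel_ps.to_frame().to_csv(out / "vessel.csv", index=False, float_format="%.9g")
    pd.DataFrame(
        {"iteration": np.arange(1, len(pres.deviation_history) + 1),
         "max_deviation_mm": pres.deviation_history}
    ).to_csv(out / "prestress_convergence.csv", index=False, float_format="%.9g")

    # --- deployments ------------------------------------------------------
    results: dict[str, DeploymentResult] = {}
    for variant in cfg.variants:
        dcfg = dataclasses.replace(cfg.deployment, variant=variant)
        res = deploy(cfg.device, vessel_ps, dcfg)
        results[variant] = res
        res.ends.to_csv(out / f"deployment_{variant}.csv", index=False, float_format="%.9g")
        _write_apexes(out / f"apexes_{variant}.csv", res.apex_points)
        wall_stress_report(res, vessel_ps).to_csv(
            out / f"wall_stress_{variant}.csv", index=False, float_format="%.9g"
        )

    # --- validation against the reference configuration ------------------
    ref_res = results.get(cfg.reference_variant)
    summary: dict = {
        **stamp,
        "fitted_params_kpa": {
            "c10": averaged.params.c10, "c20": averaged.params.c20, "c30": averaged.params.c30,
            "mean_r_squared": averaged.mean_r_squared,
        },
        "prestress": {
            "converged": pres.converged,
            "n_iterations": pres.n_iterations,
            "max_deviation_mm": pres.max_deviation,
        },
        "variants": {},
    }
    if ref_res is not None:
        loa_targets = {row["label"]: row["loa_mm2"] for _, row in ref_res.ends.iterrows()}
        reference = reference_stent_configuration(
            loa_targets, vessel_ps, cfg.deployment.landing_offset, cfg.device
        )
        for variant, res in results.items():
            report = metrics.validation_report(res.apex_points, reference)
            report["per_end"].to_csv(out / f"validation_{variant}.csv", index=False, float_format="%.9g")
            report["e_loa_sections"].to_csv(
                out / f"e_loa_sections_{variant}.csv", index=False, float_format="%.9g"
            )
            report["e_c_sections"].to_csv(
                out / f"e_c_sections_{variant}.csv", index=False, float_format="%.9g"
            )
            summary["variants"][variant] = {
                "mean_e_loa_pct": float(report["per_end"]["e_loa_pct"].mean()),
                "mean_e_c_mm": float(report["per_end"]["e_c_mm"].mean()),
                "loa_border_jump_mm2": metrics.loa_border_jump(
                    {row["label"]: row["loa_mm2"] for _, row in res.ends.iterrows()}
                ),
                "n_ends": int(len(res.ends)),
            }

    with open(out / "summary.json", "w") as fh:
        json.dump(_as_jsonable(summary), fh, indent=2, sort_keys=True)
    return summary
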