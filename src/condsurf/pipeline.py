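"""End-to-end orchestration: generate -> quantify -> fit -> report.

A single configuration dictionary drives every stage; all randomness
flows from one root seed, split per stage with ``numpy.random
.SeedSequence`` so reruns with the same config are bit-identical.  The
report collects tension summaries, the global Hill fit (per-construct
KD, shared gamma0/gamma_inf/p, KD ratio), the capillary-velocity
comparison between the fusion and aspiration routes, partition
triplets, and the size-suppression fit.  Outputs land in a
seed-named, timestamp-free directory together with a run manifest.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .adsorption_fit import global_fit, kd_ratio
from .droplet_imaging import (
    detect_droplets,
    line_profile,
    partition_triplet,
    size_summary,
)
from .fusion_kinetics import cross_validate, fit_fusion_event, inverse_capillary_velocity
from .mpa_mechanics import tension_from_experiment, viscosity_from_experiment
from .synthetic_data import (
    GeneratorConfig,
    gen_aspiration,
    gen_droplet_image,
    gen_fusion_events,
    gen_size_series,
    gen_tension_curves,
)

__all__ = ["DEFAULT_CONFIG", "run_pipeline", "validate_inputs"]

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "stages": ["mpa", "adsorb", "fusion", "image", "size"],
    "constructs": ["MBP-GFP-RGG", "GST-GFP-RGG"],
    "concentrations_um": list(np.geomspace(0.1, 10.0, 8)),
    "replicates": 3,
    "fusion_events": 12,
    "fusion_length_range_um": [4.0, 12.0],
    "image_droplets": 80,
    "image_shape": [900, 900],
    "size_concentrations_um": [0.1, 0.25, 0.5, 1.0, 2.5, 5.0],
    "size_droplets_per_group": 100,
    "completion_epsilon": 0.01,
    # intensities above this in a uN/m column suggest N/m-scale data
    "unit_suspicion_gamma": 1e4,
}


def _stage_seeds(root_seed: int, stages: list[str]) -> dict[str, int]:
    children = np.random.SeedSequence(root_seed).spawn(len(stages))
    return {
        stage: int(child.generate_state(1, dtype=np.uint32)[0]) & 0x7FFFFFFF
        for stage, child in zip(stages, children)
    }


def run_pipeline(config: dict | None = None, outdir: str | Path | None = None) -> dict:
    """Run the requested stages on synthetic data and write the report.

    Returns the report dict; when ``outdir`` is given, also writes
    ``report.json``, per-stage CSV tables, and ``manifest.json`` under
    ``outdir/run_seed<seed>``.  An empty stage list is a no-op that
    still produces a manifest.
    """
    cfg = {**DEFAULT_CONFIG, **(config or {})}
    gen = GeneratorConfig(seed=int(cfg["seed"]))
    seeds = _stage_seeds(int(cfg["seed"]), list(cfg["stages"]))
    report: dict = {"seed": int(cfg["seed"]), "stages": {}}
    tables: dict[str, pd.DataFrame] = {}

    if "mpa" in cfg["stages"]:
        exp = gen_aspiration(gen, seed=seeds["mpa"])
        tension = tension_from_experiment(exp)
        visc = viscosity_from_experiment(exp)
        report["stages"]["mpa"] = {
            "gamma_mean_un_per_m": tension.gamma_mean,
            "gamma_sem_un_per_m": tension.gamma_sem,
            "n_steps": tension.n_steps,
            "viscosity_pa_s": visc.viscosity,
            "intercept_pressure_pa": visc.intercept_pressure,
            "fit_r2": visc.fit_r2,
        }
        tables["mpa_per_step"] = pd.DataFrame(
            {"gamma_un_per_m": tension.gamma_per_step}
        )

    if "adsorb" in cfg["stages"]:
        datasets = gen_tension_curves(
            gen,
            constructs=list(cfg["constructs"]),
            concentrations=np.asarray(cfg["concentrations_um"]),
            replicates=int(cfg["replicates"]),
            seed=seeds["adsorb"],
        )
        fit = global_fit(datasets)
        entry = {
            "gamma0_un_per_m": fit.gamma0,
            "gamma_inf_un_per_m": fit.gamma_inf,
            "p": fit.p,
            "kd_um": fit.kd_per_dataset,
            "r2": fit.r2_per_dataset,
        }
        if len(cfg["constructs"]) >= 2:
            a, b = cfg["constructs"][0], cfg["constructs"][1]
            entry["kd_ratio"] = kd_ratio(fit, a, b)
        report["stages"]["adsorb"] = entry
        tables["hill_fit"] = pd.DataFrame(
            [{"dataset": k, "kd_um": v, "r2": fit.r2_per_dataset[k]} for k, v in fit.kd_per_dataset.items()]
        )

    if "fusion" in cfg["stages"]:
        events = gen_fusion_events(
            gen,
            n_events=int(cfg["fusion_events"]),
            length_range=tuple(cfg["fusion_length_range_um"]),
            seed=seeds["fusion"],
        )
        fits = [fit_fusion_event(e) for e in events]
        icv = inverse_capillary_velocity(fits)
        entry = {
            "inv_cap_velocity_s_per_um": icv.inv_cap_velocity,
            "stderr": icv.stderr,
            "n_events": icv.n_events,
            "r2": icv.r2,
        }
        if "mpa" in report["stages"]:
            entry["vs_mpa"] = cross_validate(
                icv,
                eta=report["stages"]["mpa"]["viscosity_pa_s"],
                gamma=report["stages"]["mpa"]["gamma_mean_un_per_m"],
            )
        report["stages"]["fusion"] = entry
        tables["fusion_fits"] = pd.DataFrame(
            [{"length_um": f.length, "tau_s": f.tau, "ar0": f.ar0} for f in fits]
        )

    if "image" in cfg["stages"]:
        img, truth = gen_droplet_image(
            gen,
            n_droplets=int(cfg["image_droplets"]),
            shape=tuple(cfg["image_shape"]),
            seed=seeds["image"],
        )
        r_lo = float(truth["radius_um"].min()) * 0.6
        r_hi = float(truth["radius_um"].max()) * 1.5
        det = detect_droplets(img, gen.pixel_size, (r_lo, r_hi))
        triplets = []
        for (row, col), r_px in zip(det.centers, det.radii_px):
            try:
                prof = line_profile(img, (row, col), r_px)
            except ValueError:
                continue
            triplets.append(partition_triplet(prof).as_tuple())
        trip = np.array(triplets) if triplets else np.empty((0, 3))
        report["stages"]["image"] = {
            "n_rendered": len(truth),
            "n_detected": len(det),
            "median_radius_um": float(np.median(det.radii)) if len(det) else np.nan,
            "partition_mean": trip.mean(axis=0).tolist() if trip.size else None,
        }
        tables["detections"] = pd.DataFrame(
            {"row": det.centers[:, 0] if len(det) else [], "col": det.centers[:, 1] if len(det) else [], "radius_um": det.radii}
        )

    if "size" in cfg["stages"]:
        series = gen_size_series(
            gen,
            concentrations=np.asarray(cfg["size_concentrations_um"]),
            n_per_group=int(cfg["size_droplets_per_group"]),
            seed=seeds["size"],
        )
        table, fit = size_summary(series)
        report["stages"]["size"] = {
            "c50_um": fit.c50 if fit else None,
            "r0_um": fit.r0 if fit else None,
            "r_inf_um": fit.r_inf if fit else None,
            "n": fit.n if fit else None,
        }
        tables["size_summary"] = table

    if outdir is not None:
        run_dir = Path(outdir) / f"run_seed{cfg['seed']}"
        run_dir.mkdir(parents=True, exist_ok=True)
        (run_dir / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
        for name, df in tables.items():
            df.to_csv(run_dir / f"{name}.csv", index=False)
        from . import __version__ as tool_version

        manifest = {
            "tool_version": tool_version,
            "config": {k: v for k, v in sorted(cfg.items())},
            "config_hash": hashlib.sha256(
                json.dumps(cfg, sort_keys=True, default=str).encode()
            ).hexdigest(),
            "stage_seeds": seeds,
            "outputs": sorted(p.name for p in run_dir.iterdir()),
            "generator": asdict(GeneratorConfig(seed=int(cfg["seed"]))),
        }
        (run_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return report


_SCHEMAS = {
    "aspiration": {"step_id", "p_asp_pa", "r_inner_um", "r_outer_um"},
    "tension": {"construct", "dtt", "conc_um", "conc_basis", "gamma_un_per_m", "sem"},
    "fusion": {"t_s", "aspect_ratio"},
}


def validate_inputs(
    paths: dict[str, str | Path], unit_suspicion_gamma: float = 1e4
) -> list[dict]:
    """Schema and unit sanity checks on input CSVs; returns violations.

    ``paths`` maps a schema name (``aspiration``, ``tension``,
    ``fusion``) to a CSV path.  Checks required columns, positivity of
    radii and tensions, and flags tension columns whose magnitude
    suggests N/m instead of uN/m.  Inputs are never modified.
    """
    violations = []
    for kind, path in paths.items():
        if kind not in _SCHEMAS:
            violations.append({"file": str(path), "issue": f"unknown schema {kind!r}"})
            continue
        try:
            df = pd.read_csv(path)
        except Exception as err:
            violations.append({"file": str(path), "issue": f"unreadable: {err}"})
            continue
        missing = _SCHEMAS[kind] - set(df.columns)
        if missing:
            violations.append(
                {"file": str(path), "issue": f"missing columns {sorted(missing)}"}
            )
            continue
        if kind == "aspiration":
            for col in ("r_inner_um", "r_outer_um"):
                bad = df.index[df[col] <= 0].tolist()
                for i in bad:
                    violations.append(
                        {"file": str(path), "issue": f"row {i}: {col} must be positive"}
                    )
        if kind == "tension":
            for i in df.index[df["gamma_un_per_m"] <= 0]:
                violations.append(
                    {"file": str(path), "issue": f"row {i}: tension must be positive"}
                )
            if (df["gamma_un_per_m"] > unit_suspicion_gamma).any():
                violations.append(
                    {
                        "file": str(path),
                        "issue": "tension magnitudes suggest N/m-scale values in a uN/m column",
                        "severity": "warning",
                    }
                )
    return violations
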