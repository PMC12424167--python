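"""CSV readers and writers for the analysis inputs and outputs.

File dialects (all plain CSV with headers):

* aspiration steps: ``step_id, p_asp_pa, r_inner_um, r_outer_um``; the
  optional long-format trace file carries ``step_id, t_s, lp_um``
  (aspiration length Lp in um, normalized by the pipette radius here).
* fusion events: ``t_s, aspect_ratio`` per event, with diameters and
  condition in the manifest or sidecar metadata.
* tension datasets: ``construct, dtt, conc_um, conc_basis,
  gamma_un_per_m, sem`` (one row per point).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .adsorption_fit import TensionDataset
from .fusion_kinetics import FusionEvent
from .mpa_mechanics import AspirationExperiment, AspirationStep

__all__ = [
    "read_aspiration_experiment",
    "write_aspiration_experiment",
    "read_fusion_event",
    "read_tension_datasets",
    "write_tension_datasets",
    "read_image",
    "write_image",
]


def write_image(image: np.ndarray, path: str | Path) -> None:
    """Write a 16-bit grayscale TIFF."""
    import tifffile

    tifffile.imwrite(path, np.asarray(image, dtype=np.uint16))


def read_image(path: str | Path) -> np.ndarray:
    """Read a 16-bit grayscale TIFF (first plane of a multi-page file)."""
    import tifffile

    img = tifffile.imread(path)
    if img.ndim == 3:
        img = img[0]
    return img


def write_aspiration_experiment(
    exp: AspirationExperiment, steps_path: str | Path, traces_path: str | Path | None = None
) -> None:
    rows, trace_rows = [], []
    for i, s in enumerate(exp.steps):
        rows.append(
            {"step_id": i, "p_asp_pa": s.p_asp, "r_inner_um": s.r_inner, "r_outer_um": s.r_outer}
        )
        if s.is_dynamic:
            for t, y in zip(s.times, s.lp_over_rp_sq):
                trace_rows.append(
                    {"step_id": i, "t_s": t, "lp_um": np.sqrt(y) * exp.pipette_radius}
                )
    pd.DataFrame(rows).to_csv(steps_path, index=False)
    if traces_path is not None and trace_rows:
        pd.DataFrame(trace_rows).to_csv(traces_path, index=False)


def read_aspiration_experiment(
    steps_path: str | Path,
    pipette_radius: float,
    traces_path: str | Path | None = None,
    label: str = "",
) -> AspirationExperiment:
    steps_df = pd.read_csv(steps_path)
    traces = pd.read_csv(traces_path) if traces_path is not None else None
    steps = []
    for _, row in steps_df.iterrows():
        times = lp_sq = None
        if traces is not None:
            tr = traces[traces["step_id"] == row["step_id"]]
            if len(tr) >= 2:
                times = tr["t_s"].to_numpy()
                lp_sq = (tr["lp_um"].to_numpy() / pipette_radius) ** 2
        steps.append(
            AspirationStep(
                p_asp=float(row["p_asp_pa"]),
                r_inner=float(row["r_inner_um"]),
                r_outer=float(row["r_outer_um"]),
                times=times,
                lp_over_rp_sq=lp_sq,
            )
        )
    return AspirationExperiment(pipette_radius=pipette_radius, steps=tuple(steps), label=label)


def read_fusion_event(
    path: str | Path, d1: float, d2: float, label: str = ""
) -> FusionEvent:
    df = pd.read_csv(path)
    return FusionEvent(
        times=df["t_s"].to_numpy(),
        aspect_ratio=df["aspect_ratio"].to_numpy(),
        d1=d1,
        d2=d2,
        label=label,
    )


def write_tension_datasets(datasets: list[TensionDataset], path: str | Path) -> None:
    rows = []
    for ds in datasets:
        dtt = ds.label.endswith("+DTT")
        construct = ds.label.removesuffix("+DTT")
        sems = ds.uncertainties if ds.uncertainties is not None else np.full_like(ds.tensions, np.nan)
        for c, g, s in zip(ds.concentrations, ds.tensions, sems):
            rows.append(
                {
                    "construct": construct,
                    "dtt": dtt,
                    "conc_um": c,
                    "conc_basis": ds.concentration_basis,
                    "gamma_un_per_m": g,
                    "sem": s,
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_tension_datasets(path: str | Path) -> list[TensionDataset]:
    df = pd.read_csv(path)
    out = []
    for (construct, dtt), grp in df.groupby(["construct", "dtt"], sort=False):
        label = f"{construct}+DTT" if dtt else str(construct)
        sem = grp["sem"].to_numpy()
        out.append(
            TensionDataset(
                concentrations=grp["conc_um"].to_numpy(),
                tensions=grp["gamma_un_per_m"].to_numpy(),
                uncertainties=None if np.all(np.isnan(sem)) else sem,
                label=label,
                concentration_basis=str(grp["conc_basis"].iloc[0]),
            )
        )
    return out
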