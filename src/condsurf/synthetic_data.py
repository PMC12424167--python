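"""Synthetic data generators for every stage of the condensate pipeline.

No raw measurements are deposited for this system, so each analysis
stage is exercised on synthetic inputs generated from the same forward
models the analysis inverts, at the study's reported operating points:

* aspiration experiments whose static protrusion geometry follows the
  Laplace relation for a chosen tension and whose dynamic inflow traces
  follow ``(Lp/Rp)^2 = (P - Pc)/(4*eta) * t`` above the critical
  pressure ``Pc = 2*gamma*(1/Rp - 1/R0)``;
* fusion events with stretched-exponential aspect-ratio decay and
  ``tau = (eta/gamma) * l``;
* tension-vs-concentration curves from the Hill isotherm, with optional
  dilute-phase depletion for testing equilibrium re-basing;
* 16-bit core-shell droplet images (dim core, bright surfactant rim,
  intermediate dilute background; lognormal radii; PSF blur;
  Poisson-Gaussian noise) with ground-truth tables;
* per-concentration droplet-radius samples whose means follow the
  sigmoidal size-suppression model.

Noise channels are Gaussian on geometry and aspect ratio and
Poisson-Gaussian (shot + read) on images — standard choices for
digitized microscopy data.  Every generator is driven by an explicit
seed and is byte-reproducible; noiseless modes compose with their
analysis counterparts to exact round trips.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .adsorption_fit import TensionDataset, hill_occupancy, hill_tension
from .droplet_imaging import DYNAMIC_RANGE, size_model
from .fusion_kinetics import FusionEvent, stretched_exponential
from .mpa_mechanics import AspirationExperiment, AspirationStep

__all__ = ["GeneratorConfig", "gen_aspiration", "gen_fusion_events",
           "gen_tension_curves", "gen_droplet_image", "gen_size_series"]


@dataclass(frozen=True)
class GeneratorConfig:
    """Ground-truth parameters and noise levels for all generators.

    Defaults are the study's operating points: bare tension 260 uN/m,
    viscosity 3.64 Pa*s (so eta/gamma matches the aspiration-derived
    0.014 s/um), Hill parameters gamma0=260, gamma_inf=100 uN/m, p=1.6
    with per-construct KD (MBP 2.7, GST 0.3; with DTT 2.1 and 2.6 uM),
    surfactant-free inverse capillary velocity 0.010 s/um, 20 Hz frame
    rate, initial aspect ratio ~2, median droplet radius 1.2 um, and
    MBP-like partition amplitudes (0.26, 0.70, 0.11) of the 16-bit
    dynamic range.
    """

    seed: int = 0
    # mechanics
    gamma_true: float = 260.0  # uN/m
    eta_true: float = 3.64  # Pa*s
    pipette_radius: float = 2.5  # um
    droplet_radius: float = 10.0  # R0 during aspiration, um
    geometry_noise: float = 0.01  # multiplicative, on Ri and R0
    trace_noise: float = 0.02  # fraction of final (Lp/Rp)^2
    # adsorption
    hill_gamma0: float = 260.0
    hill_gamma_inf: float = 100.0
    hill_p: float = 1.6
    hill_kd: dict = field(
        default_factory=lambda: {
            "MBP-GFP-RGG": 2.7,
            "GST-GFP-RGG": 0.3,
            "MBP-GFP-RGG+DTT": 2.1,
            "GST-GFP-RGG+DTT": 2.6,
        }
    )
    tension_noise: float = 15.0  # uN/m per replicate
    depletion_bound: float = 0.5  # uM bound at full coverage (depletion mode)
    # fusion
    inv_cap_velocity: float = 0.010  # s/um, surfactant-free
    ar0: float = 2.0
    frame_rate: float = 20.0  # Hz
    ar_noise: float = 0.02
    tau_jitter: float = 0.10  # relative event-to-event scatter of tau
    # imaging
    pixel_size: float = 0.1  # um/px
    radius_median: float = 1.2  # um, surfactant-free
    radius_sigma_log: float = 0.4
    ring_width_frac: float = 0.06  # Gaussian ring sigma as fraction of radius
    amp_dilute: float = 0.26  # fractions of the 16-bit dynamic range
    amp_interface: float = 0.70
    amp_condensed: float = 0.11
    psf_sigma_px: float = 0.7
    photon_gain: float = 4.0  # ADU per photon
    read_noise: float = 50.0  # ADU
    # size suppression
    size_r0: float = 1.2  # um
    size_r_inf: float = 0.55  # um
    size_c50: float = 0.75  # uM
    size_n: float = 2.0

    def with_(self, **kwargs) -> "GeneratorConfig":
        return replace(self, **kwargs)


def _rng(config: GeneratorConfig, seed: int | None) -> np.random.Generator:
    return np.random.default_rng(config.seed if seed is None else seed)


def gen_aspiration(
    config: GeneratorConfig,
    n_static_steps: int = 5,
    n_dynamic_steps: int = 4,
    n_trace_samples: int = 50,
    noiseless: bool = False,
    seed: int | None = None,
    label: str = "synthetic",
) -> AspirationExperiment:
    """Synthesize one aspiration experiment (static + dynamic steps).

    Static pressures span 20-90% of the critical pressure
    ``Pc = 2*gamma*(1/Rp - 1/R0)``; protrusion curvature follows
    ``1/Ri = P/(2*gamma) + 1/R0`` with multiplicative geometry noise.
    Dynamic pressures sit above ``Pc`` and carry linear inflow traces of
    slope ``(P - Pc)/(4*eta)`` with additive trace noise.
    """
    if config.gamma_true <= 0 or config.eta_true <= 0:
        raise ValueError("gamma_true and eta_true must be positive")
    rng = _rng(config, seed)
    gamma, eta = config.gamma_true, config.eta_true
    rp, r0 = config.pipette_radius, config.droplet_radius
    pc = 2.0 * gamma * (1.0 / rp - 1.0 / r0)

    steps: list[AspirationStep] = []
    for p in np.linspace(0.2 * pc, 0.9 * pc, n_static_steps):
        ri = 1.0 / (p / (2.0 * gamma) + 1.0 / r0)
        ri = max(ri, rp)
        ro = r0
        if not noiseless:
            ri *= 1.0 + config.geometry_noise * rng.standard_normal()
            ro *= 1.0 + config.geometry_noise * rng.standard_normal()
        steps.append(AspirationStep(p_asp=float(p), r_inner=float(ri), r_outer=float(ro)))

    for p in np.linspace(1.2 * pc, 2.0 * pc, n_dynamic_steps):
        slope = (p - pc) / (4.0 * eta)
        duration = 2.0 / slope  # reach (Lp/Rp)^2 = 2 by the end of the step
        t = np.linspace(0.0, duration, n_trace_samples)
        y = slope * t
        if not noiseless:
            # digitized aspiration lengths are non-negative
            y = np.clip(y + config.trace_noise * y[-1] * rng.standard_normal(t.shape), 0.0, None)
        steps.append(
            AspirationStep(
                p_asp=float(p), r_inner=rp, r_outer=r0, times=t, lp_over_rp_sq=y
            )
        )
    return AspirationExperiment(pipette_radius=rp, steps=tuple(steps), label=label)


def gen_fusion_events(
    config: GeneratorConfig,
    n_events: int = 12,
    length_range: tuple[float, float] = (4.0, 12.0),
    noiseless: bool = False,
    seed: int | None = None,
    label: str = "synthetic",
) -> list[FusionEvent]:
    """Synthesize fusion events with ``tau = (eta/gamma) * l``.

    Droplet lengths are evenly spaced across ``length_range`` (um); both
    pre-fusion diameters are set to l so the geometric mean is exact.
    Event-to-event tau jitter (relative, Gaussian) models biological
    scatter about the proportionality; per-frame aspect-ratio noise
    models the ellipse-fit measurement error.
    """
    if n_events < 1:
        raise ValueError("need at least one event")
    rng = _rng(config, seed)
    lengths = np.linspace(length_range[0], length_range[1], n_events)
    dt = 1.0 / config.frame_rate
    events = []
    for l in lengths:
        tau = config.inv_cap_velocity * l
        if not noiseless and config.tau_jitter > 0:
            tau *= max(1.0 + config.tau_jitter * rng.standard_normal(), 0.2)
        t_end = max(0.5, 3.0 * tau * np.log(100.0) ** (2.0 / 3.0))
        t = np.arange(0.0, t_end, dt)
        ar = stretched_exponential(t, config.ar0, tau)
        if not noiseless:
            ar = ar + config.ar_noise * rng.standard_normal(t.shape)
        events.append(
            FusionEvent(times=t, aspect_ratio=ar, d1=float(l), d2=float(l), label=label)
        )
    return events


def gen_tension_curves(
    config: GeneratorConfig,
    constructs: list[str],
    concentrations: np.ndarray | None = None,
    replicates: int = 3,
    noiseless: bool = False,
    depletion: bool = False,
    seed: int | None = None,
) -> list[TensionDataset]:
    """Synthesize tension-vs-concentration datasets from the Hill model.

    One dataset per construct label (which must key ``config.hill_kd``).
    Per point, ``replicates`` tension draws with additive Gaussian noise
    are averaged; the SEM across replicates becomes the point
    uncertainty.  With ``depletion=True`` the concentration axis is the
    equilibrium dilute-phase value ``C - bound*theta(C)``, emulating
    surfactant loss to the interface.
    """
    rng = _rng(config, seed)
    if concentrations is None:
        concentrations = np.geomspace(0.1, 10.0, 8)
    c = np.asarray(concentrations, dtype=float)
    out = []
    for construct in constructs:
        kd = config.hill_kd[construct]
        truth = hill_tension(c, config.hill_gamma0, config.hill_gamma_inf, kd, config.hill_p)
        if noiseless:
            g, sem = np.asarray(truth, dtype=float), None
        else:
            draws = truth + config.tension_noise * rng.standard_normal((replicates, c.size))
            g = draws.mean(axis=0)
            sem = draws.std(axis=0, ddof=1) / np.sqrt(replicates)
        g = np.clip(g, 1e-3, None)
        c_axis = c
        basis = "total"
        if depletion:
            theta = hill_occupancy(c, kd, config.hill_p)
            c_axis = np.maximum(c - config.depletion_bound * np.asarray(theta), 0.02 * c)
            basis = "equilibrium"
        out.append(
            TensionDataset(
                concentrations=c_axis,
                tensions=g,
                uncertainties=sem,
                label=construct,
                concentration_basis=basis,
            )
        )
    return out


def _render_droplet(
    canvas: np.ndarray,
    center: tuple[float, float],
    radius_px: float,
    config: GeneratorConfig,
) -> None:
    """Paint one core-shell droplet (values as fractions of the dynamic
    range) onto the float canvas, replacing the dilute background locally.

    The rim ring is a Gaussian of sigma ``ring_width_frac * radius``; its
    amplitude is pre-compensated for the later PSF blur (a Gaussian ridge
    of width s blurred by s_psf keeps s/sqrt(s^2+s_psf^2) of its height)
    so the configured interface level is what the blurred image shows.
    """
    row0, col0 = center
    sig_ring = config.ring_width_frac * radius_px
    reach = int(np.ceil(radius_px + 5 * sig_ring + 3 * config.psf_sigma_px))
    r_lo = max(int(row0) - reach, 0)
    r_hi = min(int(row0) + reach + 1, canvas.shape[0])
    c_lo = max(int(col0) - reach, 0)
    c_hi = min(int(col0) + reach + 1, canvas.shape[1])
    rr, cc = np.mgrid[r_lo:r_hi, c_lo:c_hi]
    rho = np.hypot(rr - row0, cc - col0)

    edge_w = sig_ring / 2.0  # core->dilute transition width
    bg = config.amp_condensed + (config.amp_dilute - config.amp_condensed) / (
        1.0 + np.exp(-(rho - radius_px) / edge_w)
    )
    attenuation = sig_ring / np.hypot(sig_ring, config.psf_sigma_px)
    ring_amp = (
        config.amp_interface - (config.amp_condensed + config.amp_dilute) / 2.0
    ) / attenuation
    ring = ring_amp * np.exp(-((rho - radius_px) ** 2) / (2.0 * sig_ring**2))
    patch = bg + ring
    # replace (not add) so overlapping halos do not stack backgrounds
    inside = rho <= radius_px + 5 * sig_ring
    region = canvas[r_lo:r_hi, c_lo:c_hi]
    region[inside] = patch[inside]


def gen_droplet_image(
    config: GeneratorConfig,
    n_droplets: int,
    concentration: float = 0.0,
    shape: tuple[int, int] = (1200, 1200),
    noiseless: bool = False,
    seed: int | None = None,
    max_placement_tries: int = 50_000,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Render a 16-bit field of core-shell droplets plus ground truth.

    Radii are lognormal with median ``radius_median`` scaled by the size
    model at ``concentration``; centers are rejection-sampled to be
    non-overlapping and clear of borders.  Returns ``(uint16 image,
    DataFrame with droplet_id, row, col, radius_um)``.  Raises if the
    requested droplets cannot be packed.
    """
    from scipy.ndimage import gaussian_filter

    rng = _rng(config, seed)
    median = config.radius_median
    if concentration > 0:
        median *= size_model(
            concentration, config.size_r0, config.size_r_inf, config.size_c50, config.size_n
        ) / config.size_r0
    radii_um = median * np.exp(config.radius_sigma_log * rng.standard_normal(n_droplets))
    radii_px = radii_um / config.pixel_size

    centers: list[tuple[float, float]] = []
    placed_r: list[float] = []
    tries = 0
    for r in sorted(radii_px, reverse=True):  # place big droplets first
        margin = 1.6 * r + 3 * config.psf_sigma_px
        if 2 * margin >= min(shape):
            raise RuntimeError(
                f"could not pack {n_droplets} droplets into {shape} image"
            )
        while True:
            tries += 1
            if tries > max_placement_tries:
                raise RuntimeError(
                    f"could not pack {n_droplets} droplets into {shape} image"
                )
            row = rng.uniform(margin, shape[0] - margin)
            col = rng.uniform(margin, shape[1] - margin)
            ok = all(
                np.hypot(row - r2, col - c2) > 1.4 * (r + rr2)
                for (r2, c2), rr2 in zip(centers, placed_r)
            )
            if ok:
                centers.append((row, col))
                placed_r.append(r)
                break

    canvas = np.full(shape, config.amp_dilute, dtype=float)
    for (row, col), r in zip(centers, placed_r):
        _render_droplet(canvas, (row, col), r, config)
    if config.psf_sigma_px > 0:
        canvas = gaussian_filter(canvas, config.psf_sigma_px)
    img = canvas * DYNAMIC_RANGE
    if not noiseless:
        photons = np.clip(img, 0, None) / config.photon_gain
        img = rng.poisson(photons) * config.photon_gain + config.read_noise * rng.standard_normal(shape)
    img = np.clip(img, 0, DYNAMIC_RANGE).astype(np.uint16)

    truth = pd.DataFrame(
        {
            "droplet_id": np.arange(len(centers)),
            "row": [c[0] for c in centers],
            "col": [c[1] for c in centers],
            "radius_um": np.array(placed_r) * config.pixel_size,
        }
    )
    return img, truth


def gen_size_series(
    config: GeneratorConfig,
    concentrations: np.ndarray,
    n_per_group: int = 100,
    noiseless: bool = False,
    seed: int | None = None,
) -> dict[float, np.ndarray]:
    """Per-concentration droplet radius samples for the size analysis.

    Radii are lognormal with sigma ``radius_sigma_log`` and **mean**
    pinned to the sigmoidal size model at each concentration (the
    lognormal mu is offset by sigma^2/2 accordingly); ``noiseless``
    collapses the scatter so every radius equals the model mean.
    """
    rng = _rng(config, seed)
    out: dict[float, np.ndarray] = {}
    for c in np.asarray(concentrations, dtype=float):
        mean_r = size_model(c, config.size_r0, config.size_r_inf, config.size_c50, config.size_n)
        if noiseless:
            out[float(c)] = np.full(n_per_group, mean_r)
        else:
            sig = config.radius_sigma_log
            mu = np.log(mean_r) - sig**2 / 2.0
            out[float(c)] = np.exp(mu + sig * rng.standard_normal(n_per_group))
    return out
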