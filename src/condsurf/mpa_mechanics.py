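"""Micropipette-aspiration (MPA) mechanics of liquid condensates.

A condensate held at a glass micropipette deforms under a controlled
suction pressure.  Two protocols are implemented:

* **Static tension.**  At each pressure step the protrusion inside the
  pipette has a radius of curvature ``Ri`` and the droplet body outside
  has radius ``R0``.  The Laplace pressure balance across the two caps
  gives the interfacial tension

      gamma = P_asp / (2 * (1/Ri - 1/R0))

  Per-step tensions are averaged with equal weight per step.

* **Dynamic viscosity.**  Above the critical suction pressure the
  condensate flows into the pipette.  The slope of the normalized
  aspiration length squared, ``(Lp/Rp)^2``, against time is an effective
  shear rate; regressing aspiration pressure on shear rate across steps
  gives a slope of ``4*eta``.  The regression intercept is retained for
  inspection but is never converted to a tension, because a slowly
  equilibrating surfactant film makes that intercept unreliable.

Units are Pa for pressure, micrometres for lengths, seconds for time.
With these units ``Pa * um`` is numerically ``uN/m``, the natural scale
of condensate interfacial tension, and ``Pa * s`` is the viscosity unit;
no hidden conversion factors are needed anywhere in this module.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "AspirationStep",
    "AspirationExperiment",
    "TensionMeasurement",
    "ViscosityMeasurement",
    "DegenerateGeometryError",
    "InvalidGeometryError",
    "tension_from_step",
    "tension_from_experiment",
    "shear_rate_of_step",
    "viscosity_from_experiment",
]


class DegenerateGeometryError(ValueError):
    """Protrusion and droplet curvatures are equal: tension is undefined."""


class InvalidGeometryError(ValueError):
    """Protrusion curvature exceeds the droplet radius: unphysical step."""


@dataclass(frozen=True)
class AspirationStep:
    """One pressure step of an aspiration experiment.

    Parameters
    ----------
    p_asp : float
        Aspiration (suction) pressure, Pa.  Non-negative.
    r_inner : float
        Radius of curvature ``Ri`` of the condensate interface inside
        the pipette, um.
    r_outer : float
        Radius ``R0`` of the condensate body outside the pipette, um.
    times : ndarray, optional
        Sample times (s) of the dynamic inflow trace, strictly increasing.
    lp_over_rp_sq : ndarray, optional
        ``(Lp/Rp)^2`` series aligned with ``times`` (dimensionless);
        present only for dynamic (viscosity-protocol) steps.
    """

    p_asp: float
    r_inner: float
    r_outer: float
    times: np.ndarray | None = None
    lp_over_rp_sq: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.p_asp < 0:
            raise ValueError(f"aspiration pressure must be >= 0, got {self.p_asp}")
        if self.r_inner <= 0 or self.r_outer <= 0:
            raise ValueError("radii must be positive")
        if self.times is not None:
            t = np.asarray(self.times, dtype=float)
            if t.ndim != 1 or np.any(np.diff(t) <= 0):
                raise ValueError("times must be 1-D and strictly increasing")
            object.__setattr__(self, "times", t)
        if self.lp_over_rp_sq is not None:
            y = np.asarray(self.lp_over_rp_sq, dtype=float)
            if self.times is None or y.shape != self.times.shape:
                raise ValueError("lp_over_rp_sq must align with times")
            object.__setattr__(self, "lp_over_rp_sq", y)

    @property
    def is_dynamic(self) -> bool:
        return self.times is not None and self.lp_over_rp_sq is not None


@dataclass(frozen=True)
class AspirationExperiment:
    """Ordered pressure steps on a single condensate at one pipette."""

    pipette_radius: float  # Rp, um
    steps: tuple[AspirationStep, ...]
    label: str = ""

    def __post_init__(self) -> None:
        if self.pipette_radius <= 0:
            raise ValueError("pipette radius must be positive")
        object.__setattr__(self, "steps", tuple(self.steps))


@dataclass(frozen=True)
class TensionMeasurement:
    """Equal-weight summary of per-step interfacial tensions (uN/m)."""

    gamma_per_step: np.ndarray
    gamma_mean: float
    gamma_sem: float
    n_steps: int


@dataclass(frozen=True)
class ViscosityMeasurement:
    """Viscosity from the pressure-vs-shear-rate regression.

    ``intercept_pressure`` is reported for inspection only; it is not a
    tension estimate.
    """

    shear_rates: np.ndarray  # 1/s, one per dynamic step
    viscosity: float  # Pa*s
    intercept_pressure: float  # Pa
    fit_r2: float
    pressures: np.ndarray = field(default_factory=lambda: np.array([]))


def tension_from_step(step: AspirationStep) -> float:
    """Interfacial tension (uN/m) of one static pressure step.

    Applies the Laplace balance ``gamma = P_asp / (2*(1/Ri - 1/R0))``.
    ``Ri == R0`` is degenerate (no curvature difference) and ``Ri > R0``
    unphysical; both raise.
    """
    if step.r_inner == step.r_outer:
        raise DegenerateGeometryError(
            f"Ri == R0 == {step.r_inner} um: curvature difference vanishes"
        )
    if step.r_inner > step.r_outer:
        raise InvalidGeometryError(
            f"Ri = {step.r_inner} um exceeds R0 = {step.r_outer} um"
        )
    # Pa * um == uN/m exactly in these units.
    return step.p_asp / (2.0 * (1.0 / step.r_inner - 1.0 / step.r_outer))


def tension_from_experiment(exp: AspirationExperiment) -> TensionMeasurement:
    """Equal-weight mean tension over the valid static steps.

    Only static steps enter the average: dynamic steps sit above the
    critical pressure, where the protrusion flows and carries no
    equilibrium curvature.  Steps with invalid geometry (protrusion
    curvature not measurable, or exceeding the droplet radius) are
    excluded with a logged warning, as are steps whose protrusion has
    passed the hemisphere (``Ri < Rp``).  Raises ``ValueError`` if no
    step survives.
    """
    if not exp.steps:
        raise ValueError("experiment has no steps")
    gammas = []
    for i, step in enumerate(exp.steps):
        if step.is_dynamic:
            continue
        if step.r_inner < exp.pipette_radius:
            logger.warning("step %d excluded: Ri < Rp (beyond hemisphere)", i)
            continue
        try:
            gammas.append(tension_from_step(step))
        except (DegenerateGeometryError, InvalidGeometryError) as err:
            logger.warning("step %d excluded: %s", i, err)
    if not gammas:
        raise ValueError("all steps excluded; no valid static geometry")
    g = np.asarray(gammas)
    sem = float(g.std(ddof=1) / np.sqrt(g.size)) if g.size > 1 else 0.0
    return TensionMeasurement(
        gamma_per_step=g,
        gamma_mean=float(g.mean()),
        gamma_sem=sem,
        n_steps=g.size,
    )


def shear_rate_of_step(step: AspirationStep) -> float:
    """Effective shear rate (1/s): OLS slope of ``(Lp/Rp)^2`` vs time."""
    if not step.is_dynamic:
        raise ValueError("step carries no dynamic trace")
    t, y = step.times, step.lp_over_rp_sq
    if t.size < 3:
        raise ValueError(f"need >= 3 samples for a slope, got {t.size}")
    slope, _ = np.polyfit(t, y, 1)
    return float(slope)


def viscosity_from_experiment(exp: AspirationExperiment) -> ViscosityMeasurement:
    """Condensate viscosity (Pa*s) from the dynamic protocol.

    Per-step shear rates are regressed against aspiration pressure; the
    slope equals ``4*eta``.  The intercept (the pressure at zero inflow)
    is kept as ``intercept_pressure`` without interpreting it further.
    """
    dynamic = [s for s in exp.steps if s.is_dynamic]
    if len(dynamic) < 2:
        raise ValueError("need >= 2 dynamic steps for the viscosity regression")
    rates = np.array([shear_rate_of_step(s) for s in dynamic])
    pressures = np.array([s.p_asp for s in dynamic])
    if np.ptp(rates) == 0:
        raise ValueError("identical shear rates across steps: regression ill-conditioned")
    slope, intercept = np.polyfit(rates, pressures, 1)
    pred = slope * rates + intercept
    ss_res = float(np.sum((pressures - pred) ** 2))
    ss_tot = float(np.sum((pressures - pressures.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return ViscosityMeasurement(
        shear_rates=rates,
        viscosity=float(slope / 4.0),
        intercept_pressure=float(intercept),
        fit_r2=r2,
        pressures=pressures,
    )
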