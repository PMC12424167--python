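"""Droplet-fusion relaxation kinetics and the inverse capillary velocity.

When two condensate droplets are brought into contact they merge and the
fused pair relaxes from a dumbbell toward a sphere.  The aspect ratio AR
of the ellipse fitted to the pair decays empirically as a stretched
exponential with fixed exponent 3/2:

    AR(t) = 1 + (AR0 - 1) * exp(-(t / tau)**1.5)

For Newtonian droplets the relaxation time scale is proportional to the
droplet length l (geometric mean of the two pre-fusion diameters), and
the proportionality constant is the inverse capillary velocity eta/gamma:

    eta / gamma ~= tau / l

so regressing tau on l through the origin across fusion events of
different sizes yields eta/gamma in s/um.  An independent estimate of
the same ratio from micropipette aspiration (eta in Pa*s, gamma in uN/m;
the ratio of those numbers is already s/um) cross-validates the two
measurement routes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "FusionEvent",
    "FusionFit",
    "CapillaryVelocityFit",
    "UnidentifiableTauError",
    "stretched_exponential",
    "fit_fusion_event",
    "completion_time",
    "inverse_capillary_velocity",
    "cross_validate",
]

STRETCH_EXPONENT = 1.5  # fixed, never fitted


class UnidentifiableTauError(ValueError):
    """The AR series never departs from 1: no relaxation to time."""


@dataclass(frozen=True)
class FusionEvent:
    """One optical-tweezers fusion event.

    ``times`` are frame times in seconds (nominally 20 Hz), ``aspect_ratio``
    the ellipse long/short axis ratio per frame, ``d1``/``d2`` the two
    pre-fusion droplet diameters in um.
    """

    times: np.ndarray
    aspect_ratio: np.ndarray
    d1: float
    d2: float
    label: str = ""

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        ar = np.asarray(self.aspect_ratio, dtype=float)
        if t.ndim != 1 or np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        if ar.shape != t.shape:
            raise ValueError("aspect_ratio must align with times")
        if self.d1 <= 0 or self.d2 <= 0:
            raise ValueError("pre-fusion diameters must be positive")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "aspect_ratio", ar)

    @property
    def length(self) -> float:
        """Droplet length l = sqrt(d1*d2), um."""
        return float(np.sqrt(self.d1 * self.d2))


@dataclass(frozen=True)
class FusionFit:
    ar0: float
    tau: float  # s
    residual_rms: float
    length: float  # um
    label: str = ""


@dataclass(frozen=True)
class CapillaryVelocityFit:
    inv_cap_velocity: float  # eta/gamma, s/um
    stderr: float
    n_events: int
    r2: float


def stretched_exponential(t: np.ndarray, ar0: float, tau: float) -> np.ndarray:
    """Forward model AR(t) = 1 + (AR0-1)*exp(-(t/tau)^1.5)."""
    t = np.asarray(t, dtype=float)
    return 1.0 + (ar0 - 1.0) * np.exp(-((t / tau) ** STRETCH_EXPONENT))


def fit_fusion_event(event: FusionEvent) -> FusionFit:
    """Nonlinear least-squares fit of (AR0, tau), exponent fixed at 1.5.

    Time zero is the first supplied frame (callers pre-trim the series to
    the start of fusion).  Initialization: AR0 from the first sample, tau
    from the time at which AR crosses halfway between AR0 and 1, refined
    from log-spaced perturbations of that guess to avoid local minima.
    """
    t = event.times - event.times[0]
    ar = event.aspect_ratio
    if t.size < 5:
        raise ValueError(f"need >= 5 frames, got {t.size}")
    if np.max(ar) <= 1.0 + 1e-9:
        raise UnidentifiableTauError("aspect ratio never exceeds 1; tau unidentifiable")

    ar0_init = max(float(ar[0]), 1.01)
    half = 1.0 + 0.5 * (ar0_init - 1.0)
    below = np.nonzero(ar <= half)[0]
    tau_init = float(t[below[0]]) if below.size and t[below[0]] > 0 else float(t[-1] / 2)
    tau_init = max(tau_init, float(t[1]))

    def resid(params: np.ndarray) -> np.ndarray:
        ar0, log_tau = params
        return stretched_exponential(t, ar0, np.exp(log_tau)) - ar

    best = None
    for factor in (1.0, 0.25, 1.0 / np.sqrt(2), np.sqrt(2), 4.0):
        x0 = np.array([ar0_init, np.log(tau_init * factor)])
        try:
            sol = least_squares(resid, x0, bounds=([1.0, -20.0], [np.inf, 20.0]))
        except Exception:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None or not best.success:
        raise RuntimeError("fusion fit failed to converge from any start")

    ar0, log_tau = best.x
    rms = float(np.sqrt(np.mean(best.fun**2)))
    return FusionFit(
        ar0=float(ar0),
        tau=float(np.exp(log_tau)),
        residual_rms=rms,
        length=event.length,
        label=event.label,
    )


def completion_time(fit: FusionFit, epsilon: float = 0.01) -> float:
    """Time (s) at which the residual deformation AR-1 falls to
    ``epsilon`` of its initial value: ``t = tau * ln(1/epsilon)**(2/3)``."""
    if not 0.0 < epsilon < 1.0:
        raise ValueError("epsilon must lie in (0, 1)")
    return fit.tau * np.log(1.0 / epsilon) ** (1.0 / STRETCH_EXPONENT)


def inverse_capillary_velocity(
    fits: list[FusionFit], through_origin: bool = True
) -> CapillaryVelocityFit:
    """Slope of tau vs droplet length l across events: eta/gamma in s/um.

    Through-origin OLS by default (the relaxation law is a pure
    proportionality); ``through_origin=False`` fits a free intercept and
    reports its slope instead.
    """
    if len(fits) < 2:
        raise ValueError("need >= 2 fusion events")
    lengths = np.array([f.length for f in fits])
    taus = np.array([f.tau for f in fits])
    if np.ptp(lengths) == 0:
        raise ValueError("all droplet lengths identical: slope undefined")

    if through_origin:
        slope = float(np.sum(taus * lengths) / np.sum(lengths**2))
        resid = taus - slope * lengths
        dof = lengths.size - 1
        stderr = float(
            np.sqrt(np.sum(resid**2) / dof / np.sum(lengths**2))
        ) if dof > 0 else 0.0
        pred = slope * lengths
    else:
        slope, intercept = np.polyfit(lengths, taus, 1)
        pred = slope * lengths + intercept
        resid = taus - pred
        dof = lengths.size - 2
        sxx = np.sum((lengths - lengths.mean()) ** 2)
        stderr = float(np.sqrt(np.sum(resid**2) / dof / sxx)) if dof > 0 else 0.0
        slope = float(slope)
    ss_tot = float(np.sum((taus - taus.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 1.0
    return CapillaryVelocityFit(
        inv_cap_velocity=slope, stderr=stderr, n_events=len(fits), r2=r2
    )


def cross_validate(
    capillary: CapillaryVelocityFit,
    eta: float,
    gamma: float,
    agreement_factor: float = 2.0,
) -> dict:
    """Compare fusion-derived eta/gamma with the aspiration-derived ratio.

    ``eta`` in Pa*s and ``gamma`` in uN/m give eta/gamma directly in s/um.
    Returns the two values, their ratio and difference, and whether they
    agree within ``agreement_factor`` (default: within a factor of 2).
    """
    if eta <= 0 or gamma <= 0 or capillary.inv_cap_velocity <= 0:
        raise ValueError("all inputs must be positive")
    mpa_icv = eta / gamma  # Pa*s / (uN/m) == s/um
    ratio = capillary.inv_cap_velocity / mpa_icv
    return {
        "fusion_icv_s_per_um": capillary.inv_cap_velocity,
        "mpa_icv_s_per_um": mpa_icv,
        "ratio": ratio,
        "abs_difference_s_per_um": abs(capillary.inv_cap_velocity - mpa_icv),
        "agrees": (1.0 / agreement_factor) <= ratio <= agreement_factor,
    }
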