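"""Surfactant adsorption isotherms for condensate interfacial tension.

The interfacial tension gamma of a condensate decreases sigmoidally with
the concentration C of an adsorbing amphiphilic protein.  The working
model is a Hill isotherm mapped linearly onto tension:

    gamma(C) = gamma0 - (gamma0 - gamma_inf) / (1 + (KD / C)**p)

where gamma0 and gamma_inf are the bare and saturated tensions, KD the
dissociation constant of interfacial adsorption and p the cooperativity
coefficient.  Equivalently, if theta(C) = C^p / (C^p + KD^p) is the
fractional surface coverage, gamma = gamma0 - theta*(gamma0-gamma_inf):
surface density reduces tension linearly.

Several constructs or buffer conditions are fit **globally**: gamma0,
gamma_inf and p are shared across datasets while each dataset gets its
own KD.  The ratio of two fitted KDs compares surfactant efficiency.
The classical Szyszkowski-Langmuir form gamma = gamma0 - A*ln(1 + C/a)
is provided as the non-cooperative alternative for model comparison; it
cannot produce a sigmoidal plateau at low C.

Fitting is weighted nonlinear least squares (weights 1/SEM^2 when point
uncertainties are given), parameterized internally in log-KD for
conditioning, with multi-start over KD decades.  Parameter standard
errors come from the Jacobian at the optimum; a seeded within-dataset
bootstrap is available as an alternative error model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "TensionDataset",
    "HillGlobalFit",
    "SzyszkowskiFit",
    "hill_tension",
    "hill_occupancy",
    "coverage_to_tension",
    "global_fit",
    "kd_ratio",
    "szyszkowski_fit",
]


@dataclass(frozen=True)
class TensionDataset:
    """Tension-vs-concentration points for one construct/condition.

    ``concentration_basis`` records whether C is the total added
    surfactant or the equilibrium dilute-phase concentration.
    """

    concentrations: np.ndarray  # uM
    tensions: np.ndarray  # uN/m
    uncertainties: np.ndarray | None = None  # SEM, uN/m
    label: str = ""
    concentration_basis: str = "total"

    def __post_init__(self) -> None:
        c = np.asarray(self.concentrations, dtype=float)
        g = np.asarray(self.tensions, dtype=float)
        if c.shape != g.shape or c.ndim != 1:
            raise ValueError("concentrations and tensions must be 1-D and aligned")
        if np.any(c < 0):
            raise ValueError("concentrations must be >= 0")
        if np.any(g <= 0):
            raise ValueError("tensions must be positive")
        object.__setattr__(self, "concentrations", c)
        object.__setattr__(self, "tensions", g)
        if self.uncertainties is not None:
            u = np.asarray(self.uncertainties, dtype=float)
            if u.shape != c.shape:
                raise ValueError("uncertainties must align with concentrations")
            object.__setattr__(self, "uncertainties", u)


@dataclass(frozen=True)
class HillGlobalFit:
    """Shared (gamma0, gamma_inf, p) plus one KD per dataset."""

    gamma0: float
    gamma_inf: float
    p: float
    kd_per_dataset: dict[str, float]
    stderr: dict[str, float] = field(default_factory=dict)
    r2_per_dataset: dict[str, float] = field(default_factory=dict)
    objective: float = np.nan  # weighted SSR at optimum


@dataclass(frozen=True)
class SzyszkowskiFit:
    gamma0: float
    amplitude: float  # RT*Gamma_max-equivalent prefactor, uN/m
    a: float  # concentration scale, uM
    objective: float


def hill_tension(
    c: float | np.ndarray, gamma0: float, gamma_inf: float, kd: float, p: float
) -> float | np.ndarray:
    """Hill isotherm tension; C = 0 returns gamma0 (the exact limit)."""
    c_arr = np.asarray(c, dtype=float)
    with np.errstate(divide="ignore"):
        occ = np.where(c_arr > 0, 1.0 / (1.0 + (kd / np.where(c_arr > 0, c_arr, 1.0)) ** p), 0.0)
    out = gamma0 - (gamma0 - gamma_inf) * occ
    return float(out) if np.isscalar(c) or np.ndim(c) == 0 else out


def hill_occupancy(c: float | np.ndarray, kd: float, p: float) -> float | np.ndarray:
    """Fractional surface coverage theta(C) = C^p / (C^p + KD^p)."""
    c_arr = np.asarray(c, dtype=float)
    out = np.where(c_arr > 0, c_arr**p / (c_arr**p + kd**p), 0.0)
    return float(out) if np.isscalar(c) or np.ndim(c) == 0 else out


def coverage_to_tension(
    theta: float | np.ndarray, gamma0: float, gamma_inf: float
) -> float | np.ndarray:
    """Linear coverage-to-tension map gamma = gamma0 - theta*(gamma0-gamma_inf)."""
    theta_arr = np.asarray(theta, dtype=float)
    if np.any(theta_arr < 0) or np.any(theta_arr > 1):
        raise ValueError("coverage must lie in [0, 1]")
    out = gamma0 - theta_arr * (gamma0 - gamma_inf)
    return float(out) if np.isscalar(theta) or np.ndim(theta) == 0 else out


def _pack_weights(datasets: list[TensionDataset]) -> list[np.ndarray]:
    weights = []
    for ds in datasets:
        if ds.uncertainties is not None and np.all(ds.uncertainties > 0):
            weights.append(1.0 / ds.uncertainties)
        else:
            weights.append(np.ones_like(ds.tensions))
    return weights


def global_fit(
    datasets: list[TensionDataset],
    n_bootstrap: int = 0,
    seed: int | None = None,
) -> HillGlobalFit:
    """Shared-parameter global Hill fit across datasets.

    gamma0, gamma_inf, p are common; each dataset contributes one free
    KD.  Residuals are weighted by 1/SEM where uncertainties exist.
    Multi-start over log-KD decades guards against the sigmoid's local
    minima.  ``n_bootstrap > 0`` replaces Jacobian-based standard errors
    with a seeded within-dataset resampling bootstrap.
    """
    if not datasets:
        raise ValueError("need at least one dataset")
    labels = [ds.label or f"dataset_{i}" for i, ds in enumerate(datasets)]
    if len(set(labels)) != len(labels):
        raise ValueError("dataset labels must be unique")
    for ds in datasets:
        if ds.concentrations.size < 4:
            raise ValueError("each dataset needs >= 4 points")
        if np.ptp(ds.concentrations) == 0:
            raise ValueError("dataset concentrations are all identical")
    weights = _pack_weights(datasets)

    all_gamma = np.concatenate([ds.tensions for ds in datasets])
    g0_init = float(all_gamma.max())
    ginf_init = float(all_gamma.min())
    pos_c = np.concatenate(
        [ds.concentrations[ds.concentrations > 0] for ds in datasets]
    )
    kd_guess = float(np.exp(np.mean(np.log(pos_c))))

    n_ds = len(datasets)

    def unpack(x: np.ndarray):
        gamma0, gamma_inf_frac, log_p = x[0], x[1], x[2]
        gamma_inf = gamma0 * gamma_inf_frac  # keeps gamma_inf in (0, gamma0)
        p = np.exp(log_p)
        kds = np.exp(x[3 : 3 + n_ds])
        return gamma0, gamma_inf, p, kds

    def resid(x: np.ndarray) -> np.ndarray:
        gamma0, gamma_inf, p, kds = unpack(x)
        out = []
        for ds, w, kd in zip(datasets, weights, kds):
            model = hill_tension(ds.concentrations, gamma0, gamma_inf, kd, p)
            out.append(w * (model - ds.tensions))
        return np.concatenate(out)

    lb = np.concatenate(([1e-6, 1e-4, np.log(0.1)], np.full(n_ds, np.log(1e-6))))
    ub = np.concatenate(([np.inf, 0.9999, np.log(10.0)], np.full(n_ds, np.log(1e6))))

    best = None
    for kd0 in (kd_guess, kd_guess / 10, kd_guess * 10, kd_guess / 100):
        x0 = np.concatenate(
            (
                [g0_init, max(ginf_init / g0_init, 2e-4), np.log(1.5)],
                np.full(n_ds, np.log(kd0)),
            )
        )
        x0 = np.clip(x0, lb + 1e-9, ub - 1e-9)
        try:
            sol = least_squares(resid, x0, bounds=(lb, ub), max_nfev=5000)
        except Exception:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None or not best.success:
        raise RuntimeError("global Hill fit failed to converge from any start")

    gamma0, gamma_inf, p, kds = unpack(best.x)
    kd_map = {lab: float(kd) for lab, kd in zip(labels, kds)}

    r2_map = {}
    for ds, lab, kd in zip(datasets, labels, kds):
        model = hill_tension(ds.concentrations, gamma0, gamma_inf, kd, p)
        ss_res = float(np.sum((ds.tensions - model) ** 2))
        ss_tot = float(np.sum((ds.tensions - ds.tensions.mean()) ** 2))
        r2_map[lab] = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0

    if n_bootstrap > 0:
        stderr = _bootstrap_stderr(datasets, labels, n_bootstrap, seed)
    else:
        stderr = _jacobian_stderr(best, unpack, labels, n_ds)

    return HillGlobalFit(
        gamma0=float(gamma0),
        gamma_inf=float(gamma_inf),
        p=float(p),
        kd_per_dataset=kd_map,
        stderr=stderr,
        r2_per_dataset=r2_map,
        objective=float(2 * best.cost),
    )


def _jacobian_stderr(sol, unpack, labels, n_ds) -> dict[str, float]:
    """Delta-method standard errors from the Jacobian at the optimum."""
    m, n = sol.jac.shape
    dof = max(m - n, 1)
    s2 = 2 * sol.cost / dof
    try:
        cov_x = s2 * np.linalg.inv(sol.jac.T @ sol.jac)
    except np.linalg.LinAlgError:
        return {}
    sd_x = np.sqrt(np.clip(np.diag(cov_x), 0, None))
    gamma0, gamma_inf, p, kds = unpack(sol.x)
    out = {
        "gamma0": float(sd_x[0]),
        # gamma_inf = gamma0 * frac: first-order propagation
        "gamma_inf": float(
            np.sqrt((sol.x[1] * sd_x[0]) ** 2 + (sol.x[0] * sd_x[1]) ** 2)
        ),
        "p": float(p * sd_x[2]),  # p = exp(log_p)
    }
    for lab, kd, sd in zip(labels, kds, sd_x[3 : 3 + n_ds]):
        out[f"kd:{lab}"] = float(kd * sd)
    return out


def _bootstrap_stderr(datasets, labels, n_boot: int, seed: int | None) -> dict[str, float]:
    rng = np.random.default_rng(seed)
    samples: dict[str, list[float]] = {k: [] for k in ("gamma0", "gamma_inf", "p")}
    for lab in labels:
        samples[f"kd:{lab}"] = []
    for _ in range(n_boot):
        resampled = []
        for ds in datasets:
            idx = rng.integers(0, ds.concentrations.size, ds.concentrations.size)
            resampled.append(
                TensionDataset(
                    ds.concentrations[idx],
                    ds.tensions[idx],
                    None if ds.uncertainties is None else ds.uncertainties[idx],
                    label=ds.label,
                )
            )
        try:
            fit = global_fit(resampled)
        except (RuntimeError, ValueError):
            continue
        samples["gamma0"].append(fit.gamma0)
        samples["gamma_inf"].append(fit.gamma_inf)
        samples["p"].append(fit.p)
        for lab in labels:
            samples[f"kd:{lab}"].append(fit.kd_per_dataset[lab])
    return {
        k: float(np.std(v, ddof=1)) if len(v) > 1 else np.nan
        for k, v in samples.items()
    }


def kd_ratio(fit: HillGlobalFit, a: str, b: str) -> float:
    """KD(a) / KD(b): how much more surfactant a needs than b."""
    for lab in (a, b):
        if lab not in fit.kd_per_dataset:
            raise KeyError(f"no dataset labelled {lab!r} in fit")
    return fit.kd_per_dataset[a] / fit.kd_per_dataset[b]


def szyszkowski_fit(dataset: TensionDataset) -> SzyszkowskiFit:
    """Fit the Szyszkowski-Langmuir form gamma = gamma0 - A*ln(1 + C/a).

    Returns the (unweighted-consistent) weighted SSR so the objective is
    directly comparable with the Hill fit on the same data.
    """
    if dataset.concentrations.size < 4:
        raise ValueError("need >= 4 points")
    c, g = dataset.concentrations, dataset.tensions
    w = _pack_weights([dataset])[0]

    def resid(x: np.ndarray) -> np.ndarray:
        gamma0, amp, log_a = x
        model = gamma0 - amp * np.log1p(c / np.exp(log_a))
        return w * (model - g)

    g0_init = float(g.max())
    amp_init = max(float(g.max() - g.min()) / 3.0, 1e-3)
    pos = c[c > 0]
    a_init = float(np.exp(np.mean(np.log(pos)))) if pos.size else 1.0

    best = None
    for fa in (1.0, 0.1, 10.0):
        x0 = np.array([g0_init, amp_init, np.log(a_init * fa)])
        try:
            sol = least_squares(
                resid, x0, bounds=([1e-6, 1e-9, -25], [np.inf, np.inf, 25]),
                max_nfev=5000,
            )
        except Exception:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None or not best.success:
        raise RuntimeError("Szyszkowski fit failed to converge")
    gamma0, amp, log_a = best.x
    return SzyszkowskiFit(
        gamma0=float(gamma0),
        amplitude=float(amp),
        a=float(np.exp(log_a)),
        objective=float(2 * best.cost),
    )
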