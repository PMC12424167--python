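"""Quantification of core-shell condensate fluorescence images.

Amphiphilic GFP-tagged surfactant proteins coat condensate droplets, so
a 16-bit confocal image of a field of droplets shows rings of elevated
intensity at droplet rims over a dim condensed core and an intermediate
dilute background.  This module:

* detects droplets with a circular Hough transform on Canny edges;
* extracts orientation-averaged intensity line profiles spanning the
  droplet diameter plus 25% of the radius on each side, with positions
  normalized to droplet radii and intensities normalized by 65535 (the
  16-bit dynamic range) so they scale 0-1;
* reduces a profile to a (dilute, interface, condensed) partition
  triplet of region intensities — the endpoints' mean, the rim peak,
  and the core mean respectively;
* converts fluorescence to molar concentration through a linear
  standard curve, yielding equilibrium dilute-phase concentrations for
  re-basing tension-vs-concentration data;
* summarizes droplet size distributions per surfactant concentration
  and fits the sigmoidal size-suppression model

      r(C) = r0 - (r0 - r_inf) / (1 + (C50/C)**n)

  whose C50 is the concentration halving the mean droplet radius.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import map_coordinates
from scipy.optimize import least_squares
from skimage.feature import canny
from skimage.transform import hough_circle, hough_circle_peaks

logger = logging.getLogger(__name__)

DYNAMIC_RANGE = 65535.0  # 16-bit images

__all__ = [
    "DropletDetection",
    "LineProfile",
    "PartitionTriplet",
    "SizeFit",
    "StandardCurve",
    "detect_droplets",
    "line_profile",
    "partition_triplet",
    "interface_reduction",
    "fit_standard_curve",
    "equilibrium_dilute_concentration",
    "size_model",
    "size_summary",
]


@dataclass(frozen=True)
class DropletDetection:
    """Detected circles: pixel centers (row, col), radii in um, scores."""

    centers: np.ndarray  # (n, 2) pixel coordinates
    radii: np.ndarray  # um
    scores: np.ndarray
    pixel_size: float  # um/px

    @property
    def radii_px(self) -> np.ndarray:
        return self.radii / self.pixel_size

    def __len__(self) -> int:
        return len(self.radii)


@dataclass(frozen=True)
class LineProfile:
    """Size-normalized, dynamic-range-normalized intensity profile."""

    positions: np.ndarray  # droplet radii, spanning [-1.25, 1.25]
    intensities: np.ndarray  # in [0, 1]


@dataclass(frozen=True)
class PartitionTriplet:
    """Region intensities (not fractions; they need not sum to 1)."""

    dilute: float
    interface: float
    condensed: float

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.dilute, self.interface, self.condensed)


@dataclass(frozen=True)
class SizeFit:
    r0: float  # um
    r_inf: float  # um
    c50: float  # uM
    n: float
    stderr: dict[str, float] = field(default_factory=dict)


@dataclass(frozen=True)
class StandardCurve:
    """Linear intensity-vs-concentration calibration."""

    slope: float  # intensity per uM
    intercept: float  # background intensity
    r2: float

    def concentration(self, intensity: float | np.ndarray) -> float | np.ndarray:
        """Inverse map intensity -> concentration (uM), clipped at 0."""
        c = (np.asarray(intensity, dtype=float) - self.intercept) / self.slope
        if np.any(c < 0):
            logger.warning("intensity below calibration intercept; clipping to 0 uM")
        out = np.clip(c, 0.0, None)
        return float(out) if np.ndim(intensity) == 0 else out


def _radial_profile(
    img: np.ndarray, center: tuple[float, float], rho: np.ndarray, n_angles: int = 48
) -> np.ndarray:
    """Orientation-averaged, lightly smoothed radial intensity profile."""
    from scipy.ndimage import gaussian_filter1d

    row, col = center
    thetas = np.linspace(0.0, 2.0 * np.pi, n_angles, endpoint=False)
    rr = row + rho[None, :] * np.sin(thetas)[:, None]
    cc = col + rho[None, :] * np.cos(thetas)[:, None]
    prof = map_coordinates(img, [rr.ravel(), cc.ravel()], order=1, mode="nearest")
    return gaussian_filter1d(prof.reshape(n_angles, -1).mean(axis=0), 2.0)


def _refine_radius(img: np.ndarray, center: tuple[float, float], r_hough: float) -> float:
    """Sub-pixel radius from the radial profile around a Hough circle.

    The Hough accumulator locks onto whichever Canny edge of the bright
    surfactant rim is stronger, biasing the radius by the rim width.
    For core-shell droplets the rim peak position is the radius, so a
    local parabolic fit around the radial-profile maximum is used when
    an interior peak exists; plain bright disks have no rim, and there
    the centroid of the squared radial gradient locates the edge.
    """
    rho = np.arange(max(0.4 * r_hough, 1.0), 1.6 * r_hough, 0.25)
    if rho.size < 5:
        return r_hough
    prof = _radial_profile(img, center, rho)
    i = int(np.argmax(prof))
    if 0 < i < prof.size - 1 and prof[i] > prof[0] + 0.02 and prof[i] > prof[-1] + 0.02:
        a, b, c = prof[i - 1], prof[i], prof[i + 1]
        denom = a - 2.0 * b + c
        shift = 0.5 * (a - c) / denom if denom != 0 else 0.0
        return float(rho[i] + shift * (rho[1] - rho[0]))
    grad = np.abs(np.gradient(prof, rho))
    w = np.clip(grad - grad.min(), 0.0, None) ** 2
    if w.sum() == 0:
        return r_hough
    return float((w * rho).sum() / w.sum())


def detect_droplets(
    image: np.ndarray,
    pixel_size: float,
    radius_range: tuple[float, float],
    canny_sigma: float = 2.0,
    peak_threshold: float = 0.5,
    max_droplets: int = 10_000,
    refine: bool = True,
) -> DropletDetection:
    """Circular-Hough droplet detection on a 16-bit grayscale image.

    Edges come from a Canny filter on the normalized image; the Hough
    accumulator is scanned over integer pixel radii spanning
    ``radius_range`` (um).  Accumulator peaks are greedily
    overlap-suppressed (strongest first; a weaker circle whose center
    falls within 0.8 of the summed radii of an accepted one is dropped)
    and, with ``refine=True``, each radius is re-estimated sub-pixel
    from the droplet's radial intensity profile.  A blank image yields
    an empty detection rather than an error.
    """
    img = np.asarray(image, dtype=float) / DYNAMIC_RANGE
    r_min_px = max(int(np.floor(radius_range[0] / pixel_size)), 2)
    r_max_px = int(np.ceil(radius_range[1] / pixel_size))
    if r_max_px <= r_min_px:
        raise ValueError("radius range collapses below one pixel")

    empty = DropletDetection(
        np.empty((0, 2)), np.empty((0,)), np.empty((0,)), pixel_size
    )
    edges = canny(img, sigma=canny_sigma)
    if not edges.any():
        return empty

    tried = np.arange(r_min_px, r_max_px + 1)
    accum = hough_circle(edges, tried)
    scores, cx, cy, radii_px = hough_circle_peaks(
        accum,
        tried,
        min_xdistance=2 * r_min_px,
        min_ydistance=2 * r_min_px,
        threshold=peak_threshold * accum.max(),
        total_num_peaks=max_droplets,
    )
    if scores.size == 0:
        return empty

    keep: list[int] = []
    for i in np.argsort(scores)[::-1]:
        if all(
            np.hypot(cx[i] - cx[j], cy[i] - cy[j]) >= 0.8 * (radii_px[i] + radii_px[j])
            for j in keep
        ):
            keep.append(i)
    idx = np.array(keep)
    centers = np.column_stack([cy[idx], cx[idx]]).astype(float)
    out_r = radii_px[idx].astype(float)
    if refine:
        out_r = np.array(
            [_refine_radius(img, tuple(c), r) for c, r in zip(centers, out_r)]
        )
    return DropletDetection(
        centers=centers,
        radii=out_r * pixel_size,
        scores=scores[idx],
        pixel_size=pixel_size,
    )


def line_profile(
    image: np.ndarray,
    center: tuple[float, float],
    radius_px: float,
    n_orientations: int = 8,
    samples_per_radius: int = 40,
    extent: float = 1.25,
) -> LineProfile:
    """Orientation-averaged diameter profile of one droplet.

    Samples ``n_orientations`` diameters through ``center`` (row, col)
    out to ``extent`` droplet radii each side by bilinear interpolation,
    averages them, normalizes positions to radius units and intensities
    by 65535.  Raises ``ValueError`` if the profile window leaves the
    image (callers skip such border droplets).
    """
    img = np.asarray(image, dtype=float)
    row, col = center
    half = extent * radius_px
    if (
        row - half < 0
        or col - half < 0
        or row + half > img.shape[0] - 1
        or col + half > img.shape[1] - 1
    ):
        raise ValueError("profile window exits the image; droplet skipped")

    n_samples = 2 * int(extent * samples_per_radius) + 1
    positions = np.linspace(-extent, extent, n_samples)
    dist_px = positions * radius_px
    profiles = np.empty((n_orientations, n_samples))
    for k in range(n_orientations):
        theta = np.pi * k / n_orientations
        rows = row + dist_px * np.sin(theta)
        cols = col + dist_px * np.cos(theta)
        profiles[k] = map_coordinates(img, [rows, cols], order=1, mode="nearest")
    return LineProfile(
        positions=positions, intensities=profiles.mean(axis=0) / DYNAMIC_RANGE
    )


def partition_triplet(
    profile: LineProfile,
    dilute_window: tuple[float, float] = (1.15, 1.25),
    interface_window: tuple[float, float] = (0.8, 1.1),
    condensed_max: float = 0.5,
) -> PartitionTriplet:
    """Reduce a profile to (dilute, interface, condensed) intensities.

    Defaults: dilute = mean over |x| in [1.15, 1.25]; interface = peak
    over |x| in [0.8, 1.1]; condensed = mean over |x| <= 0.5.  The rim
    maximum is used for the interface because the surfactant shell shows
    as a sharp ring whose peak height is the quantity of interest.
    """
    x = np.abs(profile.positions)
    y = profile.intensities
    if x.max() < dilute_window[1] - 1e-9:
        raise ValueError("profile does not cover the dilute window")
    dil = y[(x >= dilute_window[0]) & (x <= dilute_window[1])]
    inter = y[(x >= interface_window[0]) & (x <= interface_window[1])]
    cond = y[x <= condensed_max]
    return PartitionTriplet(
        dilute=float(dil.mean()),
        interface=float(inter.max()),
        condensed=float(cond.mean()),
    )


def interface_reduction(before: PartitionTriplet, after: PartitionTriplet) -> float:
    """Percent reduction in interface partitioning, 100*(1 - after/before)."""
    if before.interface <= 0:
        raise ValueError("reference interface intensity must be positive")
    return 100.0 * (1.0 - after.interface / before.interface)


def fit_standard_curve(
    concentrations: np.ndarray, intensities: np.ndarray
) -> StandardCurve:
    """OLS line intensity = slope*C + intercept for calibration."""
    c = np.asarray(concentrations, dtype=float)
    i = np.asarray(intensities, dtype=float)
    if np.unique(c).size < 3:
        raise ValueError("need >= 3 distinct calibration concentrations")
    slope, intercept = np.polyfit(c, i, 1)
    pred = slope * c + intercept
    ss_tot = float(np.sum((i - i.mean()) ** 2))
    r2 = 1.0 - float(np.sum((i - pred) ** 2)) / ss_tot if ss_tot > 0 else 1.0
    return StandardCurve(slope=float(slope), intercept=float(intercept), r2=r2)


def equilibrium_dilute_concentration(
    dilute_intensity: float | np.ndarray, curve: StandardCurve
) -> float | np.ndarray:
    """Equilibrium dilute-phase surfactant concentration (uM).

    Maps the dilute-phase fluorescence through the inverse standard
    curve.  Interfacial adsorption depletes the dilute phase, so tension
    curves replotted on this basis shift to lower concentrations.
    """
    return curve.concentration(dilute_intensity)


def size_model(
    c: float | np.ndarray, r0: float, r_inf: float, c50: float, n: float
) -> float | np.ndarray:
    """Sigmoidal size suppression r(C); C = 0 returns r0 (the limit)."""
    c_arr = np.asarray(c, dtype=float)
    occ = np.where(c_arr > 0, 1.0 / (1.0 + (c50 / np.where(c_arr > 0, c_arr, 1.0)) ** n), 0.0)
    out = r0 - (r0 - r_inf) * occ
    return float(out) if np.ndim(c) == 0 else out


def size_summary(
    radii_by_concentration: dict[float, np.ndarray],
    fit: bool = True,
) -> tuple["pd.DataFrame", SizeFit | None]:  # noqa: F821
    """Per-concentration radius summaries plus the sigmoidal size fit.

    ``radii_by_concentration`` maps surfactant concentration (uM) to the
    detected droplet radii (um) at that concentration.  The size model
    is fit to the per-group **means** (medians are reported alongside);
    needs >= 4 concentration groups, else only the table is returned.
    """
    import pandas as pd

    if not radii_by_concentration:
        raise ValueError("no concentration groups supplied")
    rows = []
    for conc in sorted(radii_by_concentration):
        r = np.asarray(radii_by_concentration[conc], dtype=float)
        rows.append(
            {
                "concentration_um": conc,
                "n_droplets": r.size,
                "mean_radius_um": float(r.mean()),
                "median_radius_um": float(np.median(r)),
                "sem_radius_um": float(r.std(ddof=1) / np.sqrt(r.size))
                if r.size > 1
                else np.nan,
            }
        )
    table = pd.DataFrame(rows)
    if not fit or len(rows) < 4:
        return table, None

    c = table["concentration_um"].to_numpy()
    r_mean = table["mean_radius_um"].to_numpy()

    def resid(x: np.ndarray) -> np.ndarray:
        r0, rinf_frac, log_c50, log_n = x
        return (
            size_model(c, r0, r0 * rinf_frac, np.exp(log_c50), np.exp(log_n)) - r_mean
        )

    pos = c[c > 0]
    c50_init = float(np.exp(np.mean(np.log(pos)))) if pos.size else 1.0
    lb = [1e-6, 1e-4, np.log(1e-4), np.log(0.1)]
    ub = [np.inf, 0.9999, np.log(1e4), np.log(10.0)]
    best = None
    for fa in (1.0, 0.3, 3.0):
        x0 = np.clip(
            [float(r_mean.max()), max(float(r_mean.min() / r_mean.max()), 2e-4),
             np.log(c50_init * fa), np.log(2.0)],
            np.asarray(lb) + 1e-9,
            np.asarray(ub) - 1e-9,
        )
        try:
            sol = least_squares(resid, x0, bounds=(lb, ub), max_nfev=5000)
        except Exception:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None or not best.success:
        raise RuntimeError("size-suppression fit failed to converge")
    r0, rinf_frac, log_c50, log_n = best.x

    stderr: dict[str, float] = {}
    m, npar = best.jac.shape
    if m > npar:
        s2 = 2 * best.cost / (m - npar)
        try:
            cov = s2 * np.linalg.inv(best.jac.T @ best.jac)
            sd = np.sqrt(np.clip(np.diag(cov), 0, None))
            stderr = {
                "r0": float(sd[0]),
                "r_inf": float(np.sqrt((rinf_frac * sd[0]) ** 2 + (r0 * sd[1]) ** 2)),
                "c50": float(np.exp(log_c50) * sd[2]),
                "n": float(np.exp(log_n) * sd[3]),
            }
        except np.linalg.LinAlgError:
            pass
    return table, SizeFit(
        r0=float(r0),
        r_inf=float(r0 * rinf_frac),
        c50=float(np.exp(log_c50)),
        n=float(np.exp(log_n)),
        stderr=stderr,
    )
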