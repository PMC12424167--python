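# Methods

This note documents the models, the numerical choices, and the
assumptions behind the synthetic data, in enough detail to judge what
passing tests do and do not demonstrate.

## Units

Public interfaces use Pa (pressure), µm (length), s (time), µN/m
(interfacial tension), Pa·s (viscosity), µM (concentration). These are
chosen so that no conversion constants appear in formulas: Pa·µm is
identically µN/m, and a viscosity in Pa·s divided by a tension in µN/m
is identically an inverse capillary velocity in s/µm.

## Aspiration mechanics

The static protocol treats each pressure step as an equilibrium of
Laplace pressures across the protrusion cap (radius of curvature R_i)
and the droplet body (radius R_0): γ = P_asp / [2(1/R_i − 1/R_0)].
Assumptions: both interfaces are spherical caps, the droplet wets the
pipette wall, and the protrusion has not passed the hemisphere (once
R_i would fall below the pipette radius R_p the geometry is no longer
single-valued; such steps are excluded from the average, as are steps
with R_i ≥ R_0). Per-step tensions get equal weight; the SEM uses
n = number of valid steps — the error model for per-condensate
averaging is a package choice, since reasonable alternatives
(per-condition pooling, inverse-variance weighting) are equally
defensible.

The dynamic protocol uses plain OLS twice: (L_p/R_p)² against time per
step (slope = effective shear rate, minimum 3 samples), then P_asp
against shear rate across steps (slope = 4η, minimum 2 steps with
distinct rates). The intercept of the second regression is the
pressure at zero inflow; it is reported (`intercept_pressure`) but
deliberately never converted into a tension, because with a slowly
equilibrating surfactant film that intercept is only meaningful in the
limit of infinitely slow ramping. No robust loss is used anywhere — the
digitized traces are short and outlier handling would be untestable
against the available descriptions.

## Fusion kinetics

Aspect-ratio relaxations are fit to AR(t) = 1 + (AR₀−1)exp[−(t/τ)^1.5]
with the stretching exponent fixed (it is part of the model, not a
parameter), by bounded Levenberg–Marquardt in (AR₀, log τ).
Initialization: AR₀ from the first frame; τ from the time the series
first crosses halfway between AR₀ and 1; plus four log-spaced
perturbations of that τ guess (×0.25 … ×4), keeping the lowest-cost
solution. Time zero is the first supplied frame — callers must
pre-trim movies to the start of fusion; event segmentation is out of
scope. A series that never exceeds AR = 1 raises an unidentifiability
error rather than returning an arbitrary τ.

The inverse capillary velocity is the through-origin OLS slope of τ on
droplet length l = √(d₁d₂), i.e. mean(τl)/mean(l²); a free-intercept
variant exists because the underlying proportionality is exact only for
ideal Newtonian coalescence. "Fusion complete" is operationalized as
the residual deformation AR−1 reaching ε of its initial value,
t = τ·(ln 1/ε)^(2/3), with ε = 0.01 by default (a 1%-of-round
criterion); ε is a parameter, not a constant, because no standard
definition exists.

Cross-validation against aspiration compares the fusion slope with
η/γ; the two routes are declared in agreement within a configurable
factor (default 2), reflecting that the two estimates share no data
and each carries tens-of-percent systematic uncertainty.

## Adsorption fitting

The working isotherm is a Hill curve mapped linearly onto tension:
γ(C) = γ₀ − (γ₀−γ∞)·θ(C) with θ = C^p/(C^p + K_D^p). C = 0 is handled
as the exact γ₀ limit rather than excluded. The global fit shares
(γ₀, γ∞, p) across datasets with one free K_D each, minimizing the
pooled weighted SSR (weights 1/SEM² when point uncertainties exist,
unweighted otherwise; the choice of weighting matters little at the
noise levels tested but is exposed). Internally the fit runs in
(γ₀, γ∞/γ₀, log p, log K_D): the fraction parameterization enforces
0 < γ∞ < γ₀, log-K_D conditions the sigmoid on few points, and p is
bounded to (0.1, 10). Multi-start over K_D decades (geometric-mean
initial guess ×{1, 0.1, 10, 0.01}) guards against the local minima a
single sigmoid fit on 8 points is prone to. Standard errors are
delta-method propagations from the Jacobian at the optimum; a seeded
within-dataset bootstrap (resampling points) is available because
covariance-based errors understate uncertainty when γ∞ is weakly
identified (K_D near the top of the concentration range — exactly the
situation for the weakened-surfactant conditions).

The Szyszkowski–Langmuir comparison uses the textbook form
γ = γ₀ − A·ln(1 + C/a). Its objective is computed with the same
weights as the Hill fit so the two SSRs are directly comparable; no
information criterion is applied since the comparison of interest is
shape (sigmoidal plateau at low C) rather than parsimony.

## Image quantification

Detection: Canny edges (σ = 2 px) on the 65,535-normalized image, a
circular-Hough accumulator over integer pixel radii in the search
range, peak extraction, then greedy overlap suppression (strongest
first; a circle whose center lies within 0.8× the summed radii of an
accepted one is dropped). Because the surfactant rim produces *two*
Canny edges, the raw Hough radius is biased by roughly the rim width
toward whichever edge is stronger; each radius is therefore re-estimated
from the orientation-averaged radial intensity profile — parabolic
interpolation around the rim-peak position when an interior maximum
exists (core–shell droplets), centroid of the squared radial gradient
otherwise (plain disks). This refinement is matched to the core–shell
appearance of surfactant-coated condensates and removes the edge bias
without any per-image tuning.

Line profiles span ±1.25 droplet radii, sampled bilinearly (0-based
pixel centers) along 8 diameters by default and averaged; a single
diameter reproduces the averaged profile on symmetric droplets within
2%, so averaging only suppresses noise. Partition triplets use fixed
windows on the radius-normalized axis: dilute = mean over
|x| ∈ [1.15, 1.25], interface = maximum over |x| ∈ [0.8, 1.1],
condensed = mean over |x| ≤ 0.5. The windows are a package
operationalization (configurable); the interface uses the peak rather
than a shell mean because the rim is sharp and its height is the
quantity of interest. Droplets whose profile window exits the image
are skipped.

The standard curve is an OLS line of intensity on concentration;
its inverse clips negative concentrations to zero with a warning.
The size-suppression model r(C) = r₀ − (r₀−r∞)/(1 + (C₅₀/C)^n) is fit
to per-concentration **mean** radii (medians are reported alongside)
with the same parameterization tricks as the Hill fit; it obeys the
midpoint identity r(C₅₀) = (r₀+r∞)/2 exactly.

## Synthetic data

The generators define the conditions under which everything is tested;
their defaults are the study's operating points: γ = 260 µN/m bare
tension; η = 3.64 Pa·s (chosen so the aspiration-route η/γ is
0.014 s/µm); pipette radius 2.5 µm, droplet radius 10 µm during
aspiration; Hill parameters γ₀ = 260, γ∞ = 100 µN/m, p = 1.6 with
K_D = 2.7 µM (MBP construct), 0.3 µM (GST), 2.1 µM (MBP+DTT), 2.6 µM
(GST+DTT); surfactant-free inverse capillary velocity 0.010 s/µm with
AR₀ = 2 and 20 Hz frames; image scale 0.1 µm/px with lognormal radii
(median 1.2 µm, σ_log 0.4) and MBP-like partition amplitudes
(0.26, 0.70, 0.11) of the 16-bit range; size-model parameters
r₀ = 1.2 µm, r∞ = 0.55 µm, C₅₀ = 0.75 µM, n = 2 (the size-model Hill
coefficient is not reported anywhere, so the generator uses a mildly
cooperative value and the fit treats n as free). γ∞ = 100 µN/m is the
saturating tension quoted for the overall effect; the strongest
surfactant condition plateaus lower (~65 µN/m), and nothing in the
fitting code assumes either value.

Noise models: multiplicative Gaussian on aspiration geometry (1%) and
additive on inflow traces (2% of the final value, clipped at zero since
digitized lengths are non-negative); additive Gaussian on aspect ratios
(σ = 0.02) plus 10% relative event-to-event jitter on τ (biological
scatter about the τ ∝ l law); additive Gaussian on tension replicates
(σ = 15 µN/m, 3 replicates per point, SEM taken across replicates);
Poisson–Gaussian (shot + read) on images. The aspiration noise
magnitudes are plausible digitization errors, not measured ones — no
noise model is reported for the original data.

The image renderer paints each droplet as a dim core and a Gaussian rim
ring (σ_ring = 0.06·radius) over the dilute background, blurs with a
Gaussian PSF (σ = 0.7 px), and pre-compensates the ring amplitude for
the blur attenuation of a Gaussian ridge (factor
σ_ring/√(σ_ring² + σ_PSF²)), so the configured region amplitudes are
the levels an observer measures on the blurred image. Droplet centers
are rejection-sampled to be non-overlapping with generous margins;
infeasible packings raise.

What the generators do **not** emulate: real point-spread-function
anisotropy and z-sectioning, uneven illumination, droplet clustering
and coalescence during imaging, non-spherical droplets, optical-trap
perturbations of the fusion geometry, surfactant-film viscoelasticity
(which the study itself flags as slowing fusion beyond the tension
effect), and dilute-phase depletion beyond a one-parameter toy (bound
amount ∝ Hill occupancy, default 0.5 µM at saturation — enough to
exercise equilibrium re-basing, with no claim to reproduce the
measured total-vs-equilibrium K_D shift). Parameter-recovery tests
passing on these synthetics therefore validate the estimators and
their implementation, not the instrument-level systematics of real
measurements.

## Problem sizes and determinism

Stochastic recovery experiments use 20 seeded repeats of: 2 constructs
× 8 log-spaced concentrations (0.1–10 µM) × 3 replicates for the
global Hill fit; 12 fusion events with lengths 4–12 µm; 6
concentrations × 100 droplets for the size fit. Detection runs on one
1200×1200 px field holding 220 droplets. These sizes give medians
stable to a few percent while keeping any single analysis in seconds.
All randomness flows from explicit seeds through
`numpy.random.default_rng`; the pipeline splits one root seed per stage
via `SeedSequence`, and identical configurations produce byte-identical
outputs (tested).

## Known limitations

* The viscosity regression assumes fully developed wetting flow in the
  pipette and ignores entrance effects; the generator builds in the
  same assumption, so the round trip cannot detect its violation.
* Hill-fit standard errors from the covariance are optimistic when the
  concentration grid does not bracket saturation; use the bootstrap
  for those conditions.
* The Hough detector expects bright rims or bright disks; droplets
  rendered darker than background would need an inverted-polarity pass.
* `completion_time` extrapolates the fitted model; it is not an
  independent measurement of when fusion ends.
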