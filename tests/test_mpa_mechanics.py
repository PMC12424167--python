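"""Micropipette-aspiration mechanics: Laplace tension and viscosity."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from condsurf.mpa_mechanics import (
    AspirationExperiment,
    AspirationStep,
    DegenerateGeometryError,
    InvalidGeometryError,
    shear_rate_of_step,
    tension_from_experiment,
    tension_from_step,
    viscosity_from_experiment,
)
from condsurf.synthetic_data import GeneratorConfig, gen_aspiration


@pytest.mark.parametrize(
    "p_asp, ri, r0, expected",
    [
        (0.0, 2.0, 10.0, 0.0),  # zero suction, zero tension
        (10.0, 2.0, 1e9, pytest.approx(10.0, rel=1e-6)),  # Laplace cap limit P*Ri/2
        (10.0, 2.0, 10.0, pytest.approx(12.5)),  # 10 / (2*(0.5 - 0.1))
    ],
)
def test_tension_from_step_closed_form(p_asp, ri, r0, expected):
    step = AspirationStep(p_asp=p_asp, r_inner=ri, r_outer=r0)
    assert tension_from_step(step) == expected


def test_tension_degenerate_and_invalid_geometry():
    with pytest.raises(DegenerateGeometryError):
        tension_from_step(AspirationStep(p_asp=10.0, r_inner=5.0, r_outer=5.0))
    with pytest.raises(InvalidGeometryError):
        tension_from_step(AspirationStep(p_asp=10.0, r_inner=8.0, r_outer=5.0))


@settings(derandomize=True, max_examples=200)
@given(
    gamma=st.floats(10.0, 1000.0),
    r0=st.floats(5.0, 50.0),
    p_frac=st.floats(0.05, 0.95),
)
def test_laplace_round_trip_machine_precision(gamma, r0, p_frac):
    """Inverting the Laplace relation and re-applying it recovers gamma."""
    rp = 2.5
    p_crit = 2.0 * gamma * (1.0 / rp - 1.0 / r0)
    p = p_frac * p_crit
    ri = 1.0 / (p / (2.0 * gamma) + 1.0 / r0)
    step = AspirationStep(p_asp=p, r_inner=ri, r_outer=r0)
    assert tension_from_step(step) == pytest.approx(gamma, rel=1e-12)


@settings(derandomize=True, max_examples=100)
@given(scale=st.floats(0.01, 100.0))
def test_scale_equivariance(scale):
    """Scaling lengths by s and pressures by 1/s leaves tension unchanged."""
    base = AspirationStep(p_asp=10.0, r_inner=2.0, r_outer=10.0)
    scaled = AspirationStep(
        p_asp=10.0 / scale, r_inner=2.0 * scale, r_outer=10.0 * scale
    )
    assert tension_from_step(scaled) == pytest.approx(tension_from_step(base), rel=1e-12)


def test_experiment_mean_and_permutation_invariance():
    steps = [
        AspirationStep(p_asp=4.0, r_inner=5.0, r_outer=10.0),  # gamma = 20
        AspirationStep(p_asp=2.0, r_inner=5.0, r_outer=10.0),  # gamma = 10
    ]
    exp = AspirationExperiment(pipette_radius=0.5, steps=steps, label="x")
    m = tension_from_experiment(exp)
    assert m.gamma_mean == pytest.approx(15.0)
    assert m.n_steps == 2
    exp_rev = AspirationExperiment(pipette_radius=0.5, steps=steps[::-1])
    m_rev = tension_from_experiment(exp_rev)
    assert m_rev.gamma_mean == m.gamma_mean
    assert m_rev.gamma_sem == m.gamma_sem


def test_experiment_excludes_invalid_steps_and_errors_when_all_bad():
    bad = AspirationStep(p_asp=5.0, r_inner=9.0, r_outer=5.0)
    good = AspirationStep(p_asp=4.0, r_inner=5.0, r_outer=10.0)
    exp = AspirationExperiment(pipette_radius=1.0, steps=(bad, good))
    assert tension_from_experiment(exp).n_steps == 1
    with pytest.raises(ValueError):
        tension_from_experiment(AspirationExperiment(pipette_radius=1.0, steps=(bad,)))
    with pytest.raises(ValueError):
        tension_from_experiment(AspirationExperiment(pipette_radius=1.0, steps=()))


def test_shear_rate_flat_exact_and_noisy():
    t = np.linspace(0.0, 10.0, 50)
    flat = AspirationStep(p_asp=1.0, r_inner=2.0, r_outer=10.0,
                          times=t, lp_over_rp_sq=np.full_like(t, 4.0))
    assert shear_rate_of_step(flat) == pytest.approx(0.0, abs=1e-12)
    exact = AspirationStep(p_asp=1.0, r_inner=2.0, r_outer=10.0,
                           times=t, lp_over_rp_sq=0.2 * t)
    assert shear_rate_of_step(exact) == pytest.approx(0.2, rel=1e-12)
    rng = np.random.default_rng(0)
    noisy = AspirationStep(p_asp=1.0, r_inner=2.0, r_outer=10.0,
                           times=t, lp_over_rp_sq=0.2 * t + rng.normal(0, 0.01, t.size))
    assert shear_rate_of_step(noisy) == pytest.approx(0.2, abs=0.01)


def test_viscosity_constructed_inverse_and_degenerate():
    t = np.linspace(0.0, 5.0, 20)
    steps = [
        AspirationStep(p_asp=p, r_inner=2.0, r_outer=10.0,
                       times=t, lp_over_rp_sq=(p - 50.0) / 4.0 * t)
        for p in (60.0, 80.0, 100.0)
    ]
    exp = AspirationExperiment(pipette_radius=2.0, steps=steps)
    v = viscosity_from_experiment(exp)
    assert v.viscosity == pytest.approx(1.0, rel=1e-9)
    assert v.intercept_pressure == pytest.approx(50.0, rel=1e-9)
    assert v.fit_r2 == pytest.approx(1.0)

    same_rate = [
        AspirationStep(p_asp=p, r_inner=2.0, r_outer=10.0,
                       times=t, lp_over_rp_sq=2.0 * t)
        for p in (60.0, 80.0)
    ]
    with pytest.raises(ValueError, match="ill-conditioned"):
        viscosity_from_experiment(
            AspirationExperiment(pipette_radius=2.0, steps=same_rate)
        )


def test_viscosity_recovery_from_noisy_synthetic():
    """Forward-simulate inflow at 2% trace noise, invert: eta within 10%."""
    cfg = GeneratorConfig(seed=0, eta_true=3.5)
    exp = gen_aspiration(cfg, seed=42)
    v = viscosity_from_experiment(exp)
    assert v.viscosity == pytest.approx(3.5, rel=0.10)


def test_viscosity_recovery_population_median_error():
    """Median relative error < 5% over 100 seeded experiments, eta in [1, 10]."""
    rng = np.random.default_rng(7)
    errors = []
    for k in range(100):
        eta = float(rng.uniform(1.0, 10.0))
        cfg = GeneratorConfig(seed=0, eta_true=eta)
        v = viscosity_from_experiment(gen_aspiration(cfg, seed=10_000 + k))
        errors.append(abs(v.viscosity - eta) / eta)
    assert float(np.median(errors)) < 0.05
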