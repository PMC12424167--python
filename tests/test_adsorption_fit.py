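"""Hill adsorption isotherm, global fitting, and model comparison."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from condsurf.adsorption_fit import (
    HillGlobalFit,
    TensionDataset,
    coverage_to_tension,
    global_fit,
    hill_occupancy,
    hill_tension,
    kd_ratio,
    szyszkowski_fit,
)
from condsurf.synthetic_data import GeneratorConfig, gen_tension_curves


def test_hill_limits_and_midpoint():
    g0, ginf, kd, p = 260.0, 100.0, 2.7, 1.6
    assert hill_tension(0.0, g0, ginf, kd, p) == g0
    assert hill_tension(kd, g0, ginf, kd, p) == pytest.approx((g0 + ginf) / 2)
    assert hill_tension(1e9, g0, ginf, kd, p) == pytest.approx(ginf, rel=1e-6)


@settings(derandomize=True, max_examples=200)
@given(
    c=st.floats(1e-3, 1e3),
    kd=st.floats(0.01, 100.0),
    p=st.floats(0.2, 8.0),
)
def test_coverage_composition_identity(c, kd, p):
    """hill_tension == coverage_to_tension(hill_occupancy) for all C, KD, p."""
    g0, ginf = 260.0, 100.0
    theta = hill_occupancy(c, kd, p)
    assert coverage_to_tension(theta, g0, ginf) == pytest.approx(
        hill_tension(c, g0, ginf, kd, p), rel=1e-12
    )


def test_coverage_endpoints_and_bounds():
    assert coverage_to_tension(0.0, 260.0, 100.0) == 260.0
    assert coverage_to_tension(1.0, 260.0, 100.0) == 100.0
    with pytest.raises(ValueError):
        coverage_to_tension(1.5, 260.0, 100.0)


@settings(derandomize=True, max_examples=100)
@given(
    c1=st.floats(1e-3, 1e2),
    factor=st.floats(1.01, 100.0),
)
def test_hill_monotone_nonincreasing(c1, factor):
    g0, ginf, kd, p = 260.0, 100.0, 1.0, 1.6
    assert hill_tension(c1 * factor, g0, ginf, kd, p) <= hill_tension(c1, g0, ginf, kd, p)


def test_global_fit_exact_recovery_single_dataset():
    c = np.geomspace(0.1, 10.0, 8)
    ds = TensionDataset(c, hill_tension(c, 260.0, 100.0, 2.7, 1.6), label="a")
    fit = global_fit([ds])
    assert fit.gamma0 == pytest.approx(260.0, rel=1e-5)
    assert fit.gamma_inf == pytest.approx(100.0, rel=1e-5)
    assert fit.p == pytest.approx(1.6, rel=1e-4)
    assert fit.kd_per_dataset["a"] == pytest.approx(2.7, rel=1e-4)


def test_global_fit_handles_c_zero_as_limit():
    c = np.array([0.0, 0.3, 1.0, 3.0, 10.0])
    ds = TensionDataset(c, hill_tension(c, 260.0, 100.0, 1.0, 2.0), label="z")
    fit = global_fit([ds])
    assert fit.kd_per_dataset["z"] == pytest.approx(1.0, rel=1e-3)


def test_global_fit_shared_parameter_recovery_monte_carlo():
    """Two constructs sharing (gamma0, gamma_inf, p); per-construct KD.

    Median over 20 seeds lands within 20% of the generating values and
    the KD ratio near 9."""
    cfg = GeneratorConfig(seed=0)
    kd_a, kd_b, ps = [], [], []
    for s in range(20):
        datasets = gen_tension_curves(
            cfg, ["MBP-GFP-RGG", "GST-GFP-RGG"], seed=500 + s
        )
        fit = global_fit(datasets)
        kd_a.append(fit.kd_per_dataset["MBP-GFP-RGG"])
        kd_b.append(fit.kd_per_dataset["GST-GFP-RGG"])
        ps.append(fit.p)
    assert np.median(kd_a) == pytest.approx(2.7, rel=0.20)
    assert np.median(kd_b) == pytest.approx(0.3, rel=0.20)
    assert np.median(ps) == pytest.approx(1.6, abs=0.3)  # reported 1.6 +/- 0.3
    assert np.median(kd_a) / np.median(kd_b) == pytest.approx(9.0, rel=0.25)


def test_global_fit_input_validation():
    c = np.geomspace(0.1, 10.0, 8)
    good = TensionDataset(c, hill_tension(c, 260.0, 100.0, 1.0, 1.6), label="a")
    with pytest.raises(ValueError):
        global_fit([])
    with pytest.raises(ValueError):
        global_fit([TensionDataset(c[:3], good.tensions[:3], label="short")])
    with pytest.raises(ValueError):
        global_fit(
            [TensionDataset(np.full(5, 2.0), np.linspace(200, 100, 5), label="flat")]
        )


def test_global_fit_objective_beats_grid_oracle():
    """On a 5-point dataset the optimizer matches a dense brute-force
    grid over (KD, p) with (gamma0, gamma_inf) solved linearly."""
    rng = np.random.default_rng(2)
    c = np.geomspace(0.2, 8.0, 5)
    g = hill_tension(c, 260.0, 100.0, 1.5, 1.8) + rng.normal(0, 8.0, 5)
    ds = TensionDataset(c, g, label="a")
    fit = global_fit([ds])

    best = np.inf
    for kd in np.geomspace(0.05, 50.0, 80):
        for p in np.geomspace(0.2, 6.0, 60):
            occ = hill_occupancy(c, kd, p)
            design = np.column_stack([1.0 - occ, occ])  # gamma0, gamma_inf
            coef, *_ = np.linalg.lstsq(design, g, rcond=None)
            if not (coef[0] > coef[1] > 0):
                continue
            best = min(best, float(np.sum((design @ coef - g) ** 2)))
    assert fit.objective <= best + 1e-6 * best


def test_kd_ratio_printed_values_and_errors():
    fit = HillGlobalFit(
        gamma0=260.0, gamma_inf=100.0, p=1.6,
        kd_per_dataset={"MBP": 2.7, "GST": 0.3, "GST+DTT": 2.6, "MBP+DTT": 2.1},
    )
    assert kd_ratio(fit, "MBP", "GST") == pytest.approx(9.0)
    assert kd_ratio(fit, "MBP", "MBP") == 1.0
    assert kd_ratio(fit, "GST+DTT", "MBP+DTT") == pytest.approx(1.2381, rel=1e-3)
    with pytest.raises(KeyError):
        kd_ratio(fit, "MBP", "missing")


def test_szyszkowski_exact_self_recovery():
    c = np.geomspace(0.05, 20.0, 10)
    g = 260.0 - 40.0 * np.log1p(c / 1.0)
    fit = szyszkowski_fit(TensionDataset(c, g, label="s"))
    assert fit.gamma0 == pytest.approx(260.0, rel=1e-4)
    assert fit.amplitude == pytest.approx(40.0, rel=1e-3)
    assert fit.a == pytest.approx(1.0, rel=1e-3)
    assert fit.objective < 1e-8


def test_hill_beats_szyszkowski_on_sigmoidal_data():
    """Cooperative (p = 1.6) tension curves: the Hill objective is lower
    than the Szyszkowski objective in at least 18 of 20 noisy draws."""
    cfg = GeneratorConfig(seed=0)
    wins = 0
    for s in range(20):
        (ds,) = gen_tension_curves(cfg, ["MBP-GFP-RGG"], seed=900 + s)
        unweighted = TensionDataset(ds.concentrations, ds.tensions, label=ds.label)
        hill_obj = global_fit([unweighted]).objective
        szy_obj = szyszkowski_fit(unweighted).objective
        wins += hill_obj < szy_obj
    assert wins >= 18


def test_equilibrium_basis_shifts_kd_downward():
    """Dilute-phase depletion moves the fitted KD below the total-basis KD."""
    cfg = GeneratorConfig(seed=0)
    total = gen_tension_curves(cfg, ["MBP-GFP-RGG"], noiseless=True)
    eq = gen_tension_curves(cfg, ["MBP-GFP-RGG"], noiseless=True, depletion=True)
    kd_total = global_fit(total).kd_per_dataset["MBP-GFP-RGG"]
    kd_eq = global_fit(eq).kd_per_dataset["MBP-GFP-RGG"]
    assert kd_eq < kd_total
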