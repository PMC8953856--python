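"""Isotherm fitting, jackknife uncertainties and model comparison."""

import numpy as np
import pytest
from scipy.optimize import least_squares

from raftitc import (
    BindingParams1Site,
    BindingParams2Site,
    NoiseModel,
    SiteParams,
    TitrationDesign,
    compare_models,
    fit_isotherm,
    heats_from_normalized,
    injection_heats,
    jackknife,
    jackknife_errors,
    normalize_per_mole,
    simulate_heats,
    wiseman_c_value,
)
from raftitc.thermogram import InjectionHeats


def test_null_signal_recovers_dilution_constant(design):
    params = BindingParams1Site(n=0.5, kd_nm=23.8, dh_kcal_per_mol=0.0, q_dil_ucal=-0.37)
    fit = fit_isotherm(injection_heats(design, params), design)
    assert abs(fit.params.dh_kcal_per_mol) < 1e-3
    assert fit.params.q_dil_ucal == pytest.approx(-0.37, abs=1e-3)


def test_one_site_round_trip_parent_affinity(design, parent_params):
    """Noise-free parent-sequence data: all parameters to < 0.1%."""
    fit = fit_isotherm(injection_heats(design, parent_params), design)
    assert fit.converged
    assert fit.params.n == pytest.approx(parent_params.n, rel=1e-3)
    assert fit.params.kd_nm == pytest.approx(parent_params.kd_nm, rel=1e-3)
    assert fit.params.dh_kcal_per_mol == pytest.approx(
        parent_params.dh_kcal_per_mol, rel=1e-3
    )
    assert fit.params.q_dil_ucal == pytest.approx(parent_params.q_dil_ucal, abs=1e-3)


def test_two_site_round_trip(design):
    truth = BindingParams2Site(
        SiteParams(0.3, 5.0, -8.0), SiteParams(0.7, 500.0, 4.0), q_dil_ucal=-0.2
    )
    fit = fit_isotherm(injection_heats(design, truth), design, model="two_site")
    assert fit.converged
    got = fit.params.canonical()
    for g, t in ((got.site1, truth.site1), (got.site2, truth.site2)):
        assert g.n == pytest.approx(t.n, rel=0.01)
        assert g.kd_nm == pytest.approx(t.kd_nm, rel=0.01)
        assert g.dh_kcal_per_mol == pytest.approx(t.dh_kcal_per_mol, rel=0.01)


@pytest.mark.parametrize("c_value", [1.0, 10.0, 100.0, 1000.0])
def test_parameter_recovery_across_c_values(design, c_value):
    """Noise-free recovery to < 0.5% across the informative c range."""
    n = 0.5
    kd_nm = n * design.cell_conc_um / c_value * 1e3
    truth = BindingParams1Site(n=n, kd_nm=kd_nm, dh_kcal_per_mol=-8.0, q_dil_ucal=-0.2)
    assert wiseman_c_value(design, n, kd_nm) == pytest.approx(c_value)
    fit = fit_isotherm(injection_heats(design, truth), design)
    assert fit.params.n == pytest.approx(n, rel=5e-3)
    assert fit.params.kd_nm == pytest.approx(kd_nm, rel=5e-3)
    assert fit.params.dh_kcal_per_mol == pytest.approx(-8.0, rel=5e-3)


def test_fit_invariant_to_heat_units(design, parent_params):
    """Fitting ucal heats or round-tripped normalized heats is identical."""
    heats = InjectionHeats(injection_heats(design, parent_params))
    norm = normalize_per_mole(heats, design)
    back = heats_from_normalized(norm.normalized_kcal_per_mol, design)
    fit_a = fit_isotherm(heats, design)
    fit_b = fit_isotherm(back, design)
    np.testing.assert_allclose(
        list(fit_a.param_dict.values()), list(fit_b.param_dict.values()), rtol=1e-9
    )


def test_discard_first_flag(design, parent_params):
    obs = injection_heats(design, parent_params)
    obs = obs.copy()
    obs[0] *= 0.5  # corrupted first injection
    fit = fit_isotherm(obs, design, discard_first=True)
    assert fit.n_used == design.n_injections - 1
    assert fit.params.kd_nm == pytest.approx(parent_params.kd_nm, rel=1e-3)


def test_c_value_warning_for_uninformative_design(design):
    weak = BindingParams1Site(n=0.5, kd_nm=5e5, dh_kcal_per_mol=-8.0)
    fit = fit_isotherm(injection_heats(design, weak), design)
    assert any("c-value" in w for w in fit.warnings)


def test_too_few_injections_rejected(parent_params):
    design = TitrationDesign(injection_volumes_ul=(15.0,) * 5)
    with pytest.raises(ValueError):
        fit_isotherm(injection_heats(design, parent_params), design)


# ------------------------------------------------------------- jackknife


def test_jackknife_zero_for_exactly_reproduced_data(design, parent_params):
    obs = injection_heats(design, parent_params)
    fit = fit_isotherm(obs, design)
    se = jackknife_errors(obs, design, "one_site", fit)
    assert se["kd_nm"] < 1e-6 * parent_params.kd_nm
    assert se["n"] < 1e-6
    assert fit.se_jackknife is se


def test_jackknife_matches_ols_standard_error_linear_model():
    """Leave-one-out SE of a regression slope vs the closed form, n = 20."""
    rng = np.random.default_rng(7)
    x = np.linspace(0.0, 1.0, 20)
    y = 2.0 * x + rng.normal(0.0, 0.1, x.size)

    def estimate(keep):
        res = least_squares(
            lambda p: p[0] * x[keep] + p[1] - y[keep], [1.0, 0.0]
        )
        return res.x

    se, _ = jackknife(estimate, x.size)

    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    sigma2 = resid @ resid / (x.size - 2)
    se_ols = np.sqrt(sigma2 / ((x - x.mean()) ** 2).sum())
    assert se[0] == pytest.approx(se_ols, rel=0.15)


# ------------------------------------------------------- model comparison


def test_compare_identical_fits_differ_only_by_penalty(design, parent_params):
    obs = simulate_heats(design, parent_params, NoiseModel(heat_sigma_ucal=0.3, seed=5))
    f1 = fit_isotherm(obs, design, model="one_site")
    f1b = fit_isotherm(obs, design, model="one_site")
    report = compare_models(f1, f1b)
    assert report.aicc1 == pytest.approx(report.aicc2)
    f2 = fit_isotherm(obs, design, model="two_site")
    report = compare_models(f1, f2)
    assert report.k2 > report.k1
    assert f2.sse <= f1.sse + 1e-9  # nested model fits at least as well
    assert report.recommended == "one_site"  # but the penalty dominates
    with pytest.raises(ValueError):
        compare_models(f1, fit_isotherm(obs.heats_ucal * 1.5, design))


@pytest.mark.parametrize(
    "truth, expected",
    [
        (
            BindingParams1Site(n=0.5, kd_nm=23.8, dh_kcal_per_mol=-8.0, q_dil_ucal=-0.2),
            "one_site",
        ),
        (
            BindingParams2Site(
                SiteParams(0.3, 2.0, -8.0), SiteParams(0.5, 200.0, 6.0), q_dil_ucal=-0.2
            ),
            "two_site",
        ),
    ],
    ids=["one_site_truth", "two_site_truth"],
)
def test_model_selection_simulation(design, truth, expected):
    """AICc picks the generating model in >= 95% of noisy replicates."""
    n_rep, hits = 30, 0
    for seed in range(n_rep):
        noise = NoiseModel(heat_sigma_ucal=0.3, seed=seed)
        obs = simulate_heats(design, truth, noise)
        f1 = fit_isotherm(obs, design, model="one_site")
        f2 = fit_isotherm(obs, design, model="two_site")
        if compare_models(f1, f2).recommended == expected:
            hits += 1
    assert hits >= 0.95 * n_rep
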