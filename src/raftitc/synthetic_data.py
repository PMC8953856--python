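"""Seeded generators of synthetic ITC experiments and spectra.

Stands in for instrument output with known ground truth: integrated
per-injection heats, raw differential-power traces (exponential
instrument response superposed on linear drift and Gaussian noise), a
dilution-only control titration, and Gaussian emission bands.  Default
design parameters mirror the study conditions (reverse titration of
300 uM GM1:DPC into 15 uM peptide, 20 x 15 uL injections at 300 s,
35 C); default noise magnitudes are typical VP-ITC integrated-heat
scatter of a few tenths of a ucal.

All generators are deterministic under a fixed seed, and zero-noise
output equals the deterministic model layer exactly.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass

import numpy as np

from . import binding_models as bm
from .binding_models import BindingParams, BindingParams1Site, TitrationDesign
from .spectro import EmissionSpectrum
from .thermogram import InjectionHeats, PowerTrace


@dataclass(frozen=True)
class NoiseModel:
    """Instrument-noise description for the generators.

    heat_sigma_ucal:   Gaussian scatter per integrated injection heat.
    trace_sigma_ucal_per_s: Gaussian scatter per raw power sample.
    drift_rate_ucal_per_s2: linear baseline drift slope.
    response_tau_s:    exponential instrument response time constant.
    seed:              RNG seed; equal seeds give identical output.
    """

    heat_sigma_ucal: float = 0.3
    trace_sigma_ucal_per_s: float = 0.01
    drift_rate_ucal_per_s2: float = 2e-5
    response_tau_s: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.heat_sigma_ucal < 0 or self.trace_sigma_ucal_per_s < 0:
            raise ValueError("noise sigmas must be non-negative")
        if self.response_tau_s <= 0:
            raise ValueError("response_tau_s must be positive")


def _ground_truth(params: BindingParams) -> dict:
    truth = dataclasses.asdict(params)
    truth["model"] = "one_site" if isinstance(params, BindingParams1Site) else "two_site"
    return truth


def simulate_heats(
    design: TitrationDesign, params: BindingParams, noise: NoiseModel = NoiseModel()
) -> InjectionHeats:
    """Model injection heats plus i.i.d. Gaussian noise.

    With ``heat_sigma_ucal = 0`` the output equals
    :func:`raftitc.binding_models.injection_heats` bitwise.  Ground
    truth is recorded in the metadata.
    """
    truth = bm.injection_heats(design, params)
    heats = truth.copy()
    if noise.heat_sigma_ucal > 0:
        rng = np.random.default_rng(noise.seed)
        heats = truth + rng.normal(0.0, noise.heat_sigma_ucal, truth.size)
    meta = {
        "ground_truth": _ground_truth(params),
        "seed": noise.seed,
        "heat_sigma_ucal": noise.heat_sigma_ucal,
    }
    return InjectionHeats(heats, metadata=meta)


def simulate_trace(
    design: TitrationDesign,
    params: BindingParams,
    noise: NoiseModel = NoiseModel(),
    pre_injection_s: float = 60.0,
    sampling_s: float = 1.0,
) -> PowerTrace:
    """Raw differential-power trace for a titration.

    Each injection ``i`` contributes an exponential pulse
    ``h(t) = (dQ_i / tau) * exp(-(t - t_i)/tau)`` for ``t >= t_i``
    (unit area ``dQ_i``), superposed on linear drift and per-sample
    Gaussian noise, sampled every ``sampling_s`` seconds.
    """
    tau = noise.response_tau_s
    if design.injection_interval_s < 5.0 * tau:
        warnings.warn(
            f"injection interval {design.injection_interval_s:g} s is shorter than "
            f"5*tau = {5 * tau:g} s; pulse truncation will bias integrated heats"
        )
    n = design.n_injections
    t_end = pre_injection_s + n * design.injection_interval_s
    t = np.arange(0.0, t_end + sampling_s / 2, sampling_s)
    dq = bm.injection_heats(design, params)
    inj_t = pre_injection_s + design.injection_interval_s * np.arange(n)

    power = noise.drift_rate_ucal_per_s2 * t
    for ti, qi in zip(inj_t, dq):
        sel = t >= ti
        power[sel] += (qi / tau) * np.exp(-(t[sel] - ti) / tau)
    if noise.trace_sigma_ucal_per_s > 0:
        rng = np.random.default_rng(noise.seed)
        power = power + rng.normal(0.0, noise.trace_sigma_ucal_per_s, t.size)
    return PowerTrace(t, power, inj_t)


def simulate_control(
    design: TitrationDesign, noise: NoiseModel = NoiseModel(), q_dil_ucal: float = 0.0
) -> InjectionHeats:
    """Dilution-only control: titrant into buffer without the binder.

    Equivalent to :func:`simulate_heats` with zero binding enthalpy, so
    every noise-free heat equals ``q_dil_ucal``.
    """
    params = BindingParams1Site(n=1.0, kd_nm=1.0, dh_kcal_per_mol=0.0, q_dil_ucal=q_dil_ucal)
    out = simulate_heats(design, params, noise)
    out.metadata["control"] = True
    return out


def simulate_emission_spectrum(
    peak_nm: float,
    width_nm: float = 30.0,
    amplitude: float = 1000.0,
    grid_nm: np.ndarray | None = None,
    noise_sigma: float = 0.0,
    seed: int = 0,
    label: str = "",
) -> EmissionSpectrum:
    """Gaussian emission band on a wavelength grid (default 300-400 nm, 1 nm).

    ``width_nm`` is the Gaussian sigma.  The exact (possibly off-grid)
    peak position is recorded as ``metadata["true_peak_nm"]``.
    """
    if grid_nm is None:
        grid_nm = np.arange(300.0, 401.0)
    grid_nm = np.asarray(grid_nm, dtype=float)
    if not grid_nm[0] <= peak_nm <= grid_nm[-1]:
        warnings.warn(f"peak {peak_nm} nm lies outside the grid "
                      f"[{grid_nm[0]}, {grid_nm[-1]}] nm")
    intensity = amplitude * np.exp(-((grid_nm - peak_nm) ** 2) / (2.0 * width_nm ** 2))
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        intensity = intensity + rng.normal(0.0, noise_sigma, grid_nm.size)
    return EmissionSpectrum(
        grid_nm, intensity, label=label,
        metadata={"true_peak_nm": float(peak_nm), "seed": seed, "noise_sigma": noise_sigma},
    )
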