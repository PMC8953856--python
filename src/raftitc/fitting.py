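"""Nonlinear least-squares estimation of binding parameters from heats.

The objective is the sum of squared differences between observed and
model per-injection heats (ucal).  ``K_d`` is optimized on a log10
scale in molar units; the dilution constant ``q_dil`` enters linearly.
Initialization is deterministic and derivative-free: ``dH`` from the
first normalized heat, ``n`` from the molar ratio at half-maximal
cumulative heat, and ``K_d`` from a coarse log-grid scan in which the
linear parameters (dH, q_dil) are solved exactly.

Uncertainties come from jack-knife resampling: each injection is left
out in turn, the model is refit from the full-data optimum, and

    SE_jack(theta) = sqrt((N - 1)/N * sum_i (theta_(i) - mean)^2).

A model-comparison utility reports SSE, AICc and the nested F-test for
the one-site vs two-site pair.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy import stats
from scipy.optimize import least_squares

from . import binding_models as bm
from .binding_models import (
    BindingParams,
    BindingParams1Site,
    BindingParams2Site,
    SiteParams,
    TitrationDesign,
)
from .thermogram import InjectionHeats

_PARAM_NAMES = {
    "one_site": ("n", "kd_nm", "dh_kcal_per_mol", "q_dil_ucal"),
    "two_site": (
        "n1", "kd1_nm", "dh1_kcal_per_mol",
        "n2", "kd2_nm", "dh2_kcal_per_mol",
        "q_dil_ucal",
    ),
}

# Internal optimizer scale: (n, log10 Kd [M], dH, q_dil).
_DEFAULT_BOUNDS = {
    "one_site": (
        np.array([0.05, -12.0, -100.0, -50.0]),
        np.array([10.0, -2.0, 100.0, 50.0]),
    ),
    "two_site": (
        np.array([0.05, -12.0, -100.0, 0.0, -12.0, -100.0, -50.0]),
        np.array([10.0, -2.0, 100.0, 10.0, -2.0, 100.0, 50.0]),
    ),
}


@dataclass
class FitResult:
    """Outcome of an isotherm fit."""

    model: str
    params: BindingParams
    residuals: np.ndarray
    sse: float
    converged: bool
    n_used: int
    heats_ucal: np.ndarray
    mask: np.ndarray
    design: TitrationDesign
    se_jackknife: dict[str, float] | None = None
    warnings: list[str] = field(default_factory=list)
    theta: np.ndarray | None = None  # optimizer-scale vector

    @property
    def param_dict(self) -> dict[str, float]:
        return dict(zip(_PARAM_NAMES[self.model], _natural(self.theta, self.model)))


@dataclass(frozen=True)
class ModelComparison:
    """Side-by-side report for two fits of the same data."""

    model1: str
    model2: str
    sse1: float
    sse2: float
    k1: int
    k2: int
    aicc1: float
    aicc2: float
    f_statistic: float | None
    f_pvalue: float | None
    recommended: str


def _theta_to_params(theta: np.ndarray, model: str) -> BindingParams:
    if model == "one_site":
        n, logkd, dh, qd = theta
        return BindingParams1Site(n, 10.0 ** logkd * 1e9, dh, qd)
    n1, k1, d1, n2, k2, d2, qd = theta
    return BindingParams2Site(
        SiteParams(max(n1, 0.0), 10.0 ** k1 * 1e9, d1),
        SiteParams(max(n2, 0.0), 10.0 ** k2 * 1e9, d2),
        qd,
    )


def _natural(theta: np.ndarray, model: str) -> np.ndarray:
    """Optimizer-scale vector -> natural units (Kd in nM)."""
    out = np.array(theta, dtype=float)
    if model == "one_site":
        out[1] = 10.0 ** out[1] * 1e9
    else:
        out[1] = 10.0 ** out[1] * 1e9
        out[4] = 10.0 ** out[4] * 1e9
    return out


def _model_heats(design: TitrationDesign, theta: np.ndarray, model: str) -> np.ndarray:
    return bm.injection_heats(design, _theta_to_params(theta, model))


def _as_heat_array(heats, design: TitrationDesign) -> np.ndarray:
    if isinstance(heats, InjectionHeats):
        arr = heats.heats_ucal
    else:
        arr = np.asarray(heats, dtype=float)
    if arr.size != design.n_injections:
        raise ValueError(
            f"got {arr.size} heats but the design schedules {design.n_injections} injections"
        )
    return arr


def _warm_start_one_site(
    obs: np.ndarray, design: TitrationDesign, mask: np.ndarray
) -> np.ndarray:
    m, x = bm._states(design)
    used = np.flatnonzero(mask)
    dv = np.asarray(design.injection_volumes_ul)
    moles = design.syringe_conc_um * 1e-6 * dv * 1e-6

    tail = used[-max(2, len(used) // 5):]
    qd0 = float(np.median(obs[tail]))
    first = used[0]
    dh0 = float((obs[first] - qd0) * 1e-9 / moles[first])
    if dh0 == 0.0:
        dh0 = -1e-3

    corrected = np.where(mask, obs - qd0, 0.0)
    cum = np.cumsum(corrected)
    total = cum[-1]
    if total != 0.0:
        half_idx = int(np.argmax(np.abs(cum) >= abs(total) / 2.0)) + 1
        ratio = x[half_idx] / m[half_idx]
        n0 = float(np.clip(ratio, 0.06, 9.5))
    else:
        n0 = 1.0

    best = None
    for logkd in np.linspace(-11.0, -4.0, 29):
        params = BindingParams1Site(n0, 10.0 ** logkd * 1e9, 1.0, 0.0)
        g = bm.injection_heats(design, params)
        a = np.column_stack([g[mask], np.ones(mask.sum())])
        coef, *_ = np.linalg.lstsq(a, obs[mask], rcond=None)
        resid = obs[mask] - a @ coef
        sse = float(resid @ resid)
        if best is None or sse < best[0]:
            best = (sse, logkd, coef)
    _, logkd0, coef = best
    dh_grid, qd_grid = float(coef[0]), float(coef[1])
    if abs(dh_grid) > 1e-6:
        dh0, qd0 = dh_grid, qd_grid
    lo, hi = _DEFAULT_BOUNDS["one_site"]
    return np.clip(np.array([n0, logkd0, dh0, qd0]), lo + 1e-9, hi - 1e-9)


def _two_site_starts(theta1: np.ndarray) -> list[np.ndarray]:
    n0, k0, dh0, qd0 = theta1
    lo, hi = _DEFAULT_BOUNDS["two_site"]
    starts = [
        np.array([n0 / 2, k0 - 0.7, dh0, n0 / 2, k0 + 0.7, dh0, qd0]),
        np.array([n0 / 2, k0 - 0.7, dh0, n0 / 2, k0 + 0.7, -dh0, qd0]),
        np.array([n0, k0, dh0, n0 / 2, k0 + 2.0, dh0 / 2, qd0]),
    ]
    return [np.clip(s, lo + 1e-9, hi - 1e-9) for s in starts]


def _solve(
    obs: np.ndarray,
    design: TitrationDesign,
    model: str,
    mask: np.ndarray,
    theta0: np.ndarray,
    bounds: tuple[np.ndarray, np.ndarray],
):
    def residual(theta: np.ndarray) -> np.ndarray:
        return _model_heats(design, theta, model)[mask] - obs[mask]

    # the two-site surface is flat along site-splitting directions when
    # the data carry one site; looser tolerances avoid grinding there
    tol = 1e-12 if model == "one_site" else 1e-8
    return least_squares(
        residual, theta0, bounds=bounds, method="trf",
        xtol=tol, ftol=tol, gtol=tol, max_nfev=800, x_scale="jac",
    )


def fit_isotherm(
    heats,
    design: TitrationDesign,
    model: str = "one_site",
    init: BindingParams | Sequence[float] | None = None,
    bounds: tuple[np.ndarray, np.ndarray] | None = None,
    discard_first: bool = False,
) -> FitResult:
    """Fit a binding model to per-injection heats.

    Parameters
    ----------
    heats:
        :class:`~raftitc.thermogram.InjectionHeats` or a plain ucal
        vector matching the design's schedule.
    model:
        ``"one_site"`` or ``"two_site"``.
    init:
        Optional starting parameters (a params object or an
        optimizer-scale vector); by default a deterministic warm start
        is computed from the data.
    discard_first:
        Drop the first injection from the objective (common ITC
        practice for the diffusion-compromised first injection); the
        concentration bookkeeping still counts it.
    """
    if model not in _PARAM_NAMES:
        raise ValueError(f"unknown model {model!r}")
    obs = _as_heat_array(heats, design)
    mask = np.ones(obs.size, dtype=bool)
    if discard_first:
        mask[0] = False
    k = len(_PARAM_NAMES[model])
    if mask.sum() < k + 2:
        raise ValueError(
            f"need at least {k + 2} usable injections to fit {model}, have {mask.sum()}"
        )
    if bounds is None:
        bounds = _DEFAULT_BOUNDS[model]
    lo, hi = bounds

    theta1 = _warm_start_one_site(obs, design, mask)
    if init is not None:
        starts = [np.clip(np.asarray(_init_vector(init, model)), lo + 1e-12, hi - 1e-12)]
    elif model == "one_site":
        starts = [theta1]
    else:
        starts = _two_site_starts(theta1)

    best = None
    for theta0 in starts:
        res = _solve(obs, design, model, mask, theta0, bounds)
        if best is None or res.cost < best.cost:
            best = res
    res = best

    theta = res.x.copy()
    if model == "two_site" and theta[1] > theta[4]:
        theta = np.array([theta[3], theta[4], theta[5], theta[0], theta[1], theta[2], theta[6]])
    params = _theta_to_params(theta, model)
    if model == "two_site":
        params = params.canonical()
    residuals = _model_heats(design, theta, model)[mask] - obs[mask]
    sse = float(residuals @ residuals)

    warns: list[str] = []
    if model == "one_site":
        c = bm.wiseman_c_value(design, params.n, params.kd_nm)
        if not 1.0 <= c <= 1000.0:
            warns.append(
                f"Wiseman c-value {c:.3g} outside the informative range [1, 1000]; "
                "K_d is weakly determined"
            )
    converged = bool(res.status > 0)
    if not converged:
        warns.append(f"optimizer did not converge: {res.message}")

    return FitResult(
        model=model, params=params, residuals=residuals, sse=sse,
        converged=converged, n_used=int(mask.sum()), heats_ucal=obs,
        mask=mask, design=design, warnings=warns, theta=theta,
    )


def _init_vector(init, model: str) -> np.ndarray:
    if isinstance(init, BindingParams1Site):
        return np.array([
            init.n, math.log10(init.kd_nm * 1e-9), init.dh_kcal_per_mol, init.q_dil_ucal,
        ])
    if isinstance(init, BindingParams2Site):
        return np.array([
            init.site1.n, math.log10(init.site1.kd_nm * 1e-9), init.site1.dh_kcal_per_mol,
            init.site2.n, math.log10(init.site2.kd_nm * 1e-9), init.site2.dh_kcal_per_mol,
            init.q_dil_ucal,
        ])
    vec = np.asarray(init, dtype=float)
    if vec.size != len(_PARAM_NAMES[model]):
        raise ValueError("init vector has the wrong length for the model")
    return vec


def jackknife(
    estimate: Callable[[np.ndarray], np.ndarray], n_points: int
) -> tuple[np.ndarray, np.ndarray]:
    """Generic leave-one-out jackknife.

    ``estimate`` maps a boolean keep-mask of length ``n_points`` to a
    parameter vector.  Returns ``(se, replicates)`` where ``se`` is the
    jackknife standard error per parameter and ``replicates`` the
    (n_points, p) matrix of leave-one-out estimates.
    """
    reps = []
    for i in range(n_points):
        keep = np.ones(n_points, dtype=bool)
        keep[i] = False
        reps.append(np.asarray(estimate(keep), dtype=float))
    reps = np.vstack(reps)
    n = reps.shape[0]
    center = reps.mean(axis=0)
    se = np.sqrt((n - 1) / n * ((reps - center) ** 2).sum(axis=0))
    return se, reps


def jackknife_errors(
    heats,
    design: TitrationDesign,
    model: str,
    fit: FitResult,
    min_converged_fraction: float = 0.8,
) -> dict[str, float]:
    """Leave-one-injection-out standard errors for a converged fit.

    Each replicate is refit starting from the full-data optimum.
    Non-converged replicates are dropped with a warning; if fewer than
    ``min_converged_fraction`` converge, an error is raised.  SEs are
    reported on natural scales (K_d in nM).  The result is also stored
    on ``fit.se_jackknife``.
    """
    if not fit.converged:
        raise ValueError("jackknife requires a converged fit")
    obs = _as_heat_array(heats, design)
    k = len(_PARAM_NAMES[model])
    used = np.flatnonzero(fit.mask)
    if used.size < k + 2:
        raise ValueError("too few injections for jackknife resampling")
    bounds = _DEFAULT_BOUNDS[model]

    reps, dropped = [], 0
    for i in used:
        mask = fit.mask.copy()
        mask[i] = False
        res = _solve(obs, design, model, mask, fit.theta, bounds)
        if res.status > 0:
            theta = res.x.copy()
            if model == "two_site" and theta[1] > theta[4]:
                theta = np.array([
                    theta[3], theta[4], theta[5], theta[0], theta[1], theta[2], theta[6],
                ])
            reps.append(_natural(theta, model))
        else:
            dropped += 1
            warnings.warn(f"jackknife replicate without injection {i} did not converge")
    if len(reps) < min_converged_fraction * used.size:
        raise RuntimeError(
            f"only {len(reps)}/{used.size} jackknife replicates converged"
        )
    reps = np.vstack(reps)
    n = reps.shape[0]
    center = reps.mean(axis=0)
    se = np.sqrt((n - 1) / n * ((reps - center) ** 2).sum(axis=0))
    out = dict(zip(_PARAM_NAMES[model], (float(s) for s in se)))
    fit.se_jackknife = out
    return out


def _aicc(sse: float, n: int, k: int) -> float:
    if n - k - 1 <= 0:
        return math.inf
    sse = max(sse, 1e-300)
    return n * math.log(sse / n) + 2 * k + 2 * k * (k + 1) / (n - k - 1)


def compare_models(fit1: FitResult, fit2: FitResult) -> ModelComparison:
    """Compare two fits of the same data by AICc and a nested F-test.

    The recommendation is the model with the lower AICc (small-sample
    corrected Akaike criterion).  The F-test assumes the smaller model
    is nested in the larger, which holds for one-site vs two-site.
    """
    if fit1.n_used != fit2.n_used or not np.array_equal(fit1.heats_ucal, fit2.heats_ucal):
        raise ValueError("model comparison requires fits of identical data")
    n = fit1.n_used
    k1, k2 = len(_PARAM_NAMES[fit1.model]), len(_PARAM_NAMES[fit2.model])
    aicc1, aicc2 = _aicc(fit1.sse, n, k1), _aicc(fit2.sse, n, k2)

    f_stat = f_p = None
    small, large = (fit1, fit2) if k1 < k2 else (fit2, fit1)
    ks, kl = min(k1, k2), max(k1, k2)
    if kl > ks and n > kl and large.sse > 0:
        f_stat = ((small.sse - large.sse) / (kl - ks)) / (large.sse / (n - kl))
        f_stat = max(f_stat, 0.0)
        f_p = float(stats.f.sf(f_stat, kl - ks, n - kl))
    recommended = fit1.model if aicc1 <= aicc2 else fit2.model
    return ModelComparison(
        model1=fit1.model, model2=fit2.model, sse1=fit1.sse, sse2=fit2.sse,
        k1=k1, k2=k2, aicc1=aicc1, aicc2=aicc2,
        f_statistic=f_stat, f_pvalue=f_p, recommended=recommended,
    )
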