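"""Equilibrium binding isotherms for isothermal titration calorimetry.

This is the deterministic model layer of the package: given a titration
design (cell geometry, concentrations, injection schedule) and a set of
thermodynamic parameters, it predicts the heat evolved per injection.
The geometry is a *reverse* titration as used for peptide-ganglioside
work: the peptide ("cell species", total concentration ``M_t``) sits in
the calorimeter cell and the receptor-bearing species -- GM1 presented
in GM1:DPC micelles ("titrant", ``X_t``) -- is injected from the
syringe.

Two standard models are implemented:

* a single set of ``n`` identical independent sites per cell-species
  molecule (the Wiseman one-site isotherm), where the bound fraction
  ``theta`` of sites solves::

      theta**2 - theta*(1 + X_t/(n*M_t) + K_d/(n*M_t)) + X_t/(n*M_t) = 0

  with the physical (smaller) root taken in a cancellation-free form;

* two independent classes of sites ``(n1, K_d1, dH1)`` and
  ``(n2, K_d2, dH2)``, where the free titrant concentration ``x`` solves
  the mass balance::

      X_t = x + M_t*(n1*x/(K_d1 + x) + n2*x/(K_d2 + x))

  by bracketed root finding on ``[0, X_t]``.

Concentration bookkeeping uses the overfilled-cell displacement
correction: each injection pushes an equal volume of cell liquid out of
the sensed volume, so with cumulative injected volume ``dV`` the totals
in the cell are::

    M_t = M_0   * (1 - dV/(2*V_0)) / (1 + dV/(2*V_0))
    X_t = X_syr * (dV/V_0)         / (1 + dV/(2*V_0))

An exponential-dilution alternative (continuous-perfusion limit) is
available through ``TitrationDesign.perfusion``.

Units follow calorimetry practice: volumes in mL (cell) and uL
(injections), concentrations in uM, ``K_d`` in nM, enthalpies in
kcal/mol of titrant, heats in ucal.  Dilution/mixing heat ``q_dil`` is a
constant number of ucal per injection, fitted as a nuisance term.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Union

import numpy as np
from scipy.optimize import brentq

#: 1 kcal expressed in ucal.
KCAL_TO_UCAL = 1.0e9
#: uL per mL.
UL_PER_ML = 1.0e3

PerfusionConvention = Literal["displacement", "exponential"]


@dataclass(frozen=True)
class TitrationDesign:
    """Geometry and schedule of an ITC titration.

    Defaults reproduce the study design for the pentapeptide work:
    15 uM peptide in a 1.4 mL cell (VP-ITC nominal working volume),
    300 uM GM1 (as 1:5 GM1:DPC micelles) in a 300 uL syringe delivered
    as 20 x 15 uL injections spaced 300 s apart, at 35 C (308.15 K).
    """

    cell_volume_ml: float = 1.4
    cell_conc_um: float = 15.0
    syringe_conc_um: float = 300.0
    injection_volumes_ul: tuple[float, ...] = tuple([15.0] * 20)
    injection_interval_s: float = 300.0
    temperature_k: float = 308.15
    syringe_capacity_ul: float | None = 300.0
    perfusion: PerfusionConvention = "displacement"

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "injection_volumes_ul", tuple(float(v) for v in self.injection_volumes_ul)
        )
        if self.cell_volume_ml <= 0:
            raise ValueError("cell_volume_ml must be positive")
        if self.cell_conc_um <= 0:
            raise ValueError("cell_conc_um must be positive")
        if self.syringe_conc_um < 0:
            raise ValueError("syringe_conc_um must be non-negative")
        if not self.injection_volumes_ul:
            raise ValueError("at least one injection is required")
        if any(v <= 0 for v in self.injection_volumes_ul):
            raise ValueError("injection volumes must be positive")
        if self.injection_interval_s <= 0:
            raise ValueError("injection_interval_s must be positive")
        if self.temperature_k <= 0:
            raise ValueError("temperature_k must be positive")
        if self.perfusion not in ("displacement", "exponential"):
            raise ValueError(f"unknown perfusion convention {self.perfusion!r}")
        if self.syringe_capacity_ul is not None:
            total = sum(self.injection_volumes_ul)
            if total > self.syringe_capacity_ul + 1e-9:
                raise ValueError(
                    f"schedule delivers {total:g} uL but syringe capacity is "
                    f"{self.syringe_capacity_ul:g} uL"
                )

    @property
    def n_injections(self) -> int:
        return len(self.injection_volumes_ul)

    def cumulative_volume_ul(self, i: int) -> float:
        """Total volume injected after the first ``i`` injections."""
        if not 0 <= i <= self.n_injections:
            raise IndexError(f"injection index {i} out of range 0..{self.n_injections}")
        return float(sum(self.injection_volumes_ul[:i]))


@dataclass(frozen=True)
class BindingParams1Site:
    """Single-set-of-sites parameters.

    ``n`` is the number of titrant-binding sites per cell-species
    molecule; n = 0.5 encodes a 2:1 peptide:GM1 complex in the reverse
    titration.  ``q_dil_ucal`` is the constant per-injection
    mixing/dilution heat nuisance term.
    """

    n: float
    kd_nm: float
    dh_kcal_per_mol: float
    q_dil_ucal: float = 0.0

    def __post_init__(self) -> None:
        if self.n <= 0:
            raise ValueError("n must be positive")
        if self.kd_nm < 0:
            raise ValueError("kd_nm must be non-negative")
        if not math.isfinite(self.q_dil_ucal):
            raise ValueError("q_dil_ucal must be finite")


@dataclass(frozen=True)
class SiteParams:
    """One class of sites within a two-independent-site model."""

    n: float
    kd_nm: float
    dh_kcal_per_mol: float

    def __post_init__(self) -> None:
        if self.n < 0:
            raise ValueError("n must be non-negative")
        if self.kd_nm <= 0:
            raise ValueError("kd_nm must be positive")


@dataclass(frozen=True)
class BindingParams2Site:
    """Two independent classes of sites with a shared dilution term.

    Site labels are exchangeable; :meth:`canonical` orders them so that
    ``kd1 <= kd2``.
    """

    site1: SiteParams
    site2: SiteParams
    q_dil_ucal: float = 0.0

    def __post_init__(self) -> None:
        if not math.isfinite(self.q_dil_ucal):
            raise ValueError("q_dil_ucal must be finite")

    def canonical(self) -> "BindingParams2Site":
        if self.site1.kd_nm <= self.site2.kd_nm:
            return self
        return BindingParams2Site(self.site2, self.site1, self.q_dil_ucal)


BindingParams = Union[BindingParams1Site, BindingParams2Site]


@dataclass(frozen=True)
class CellState:
    """Total concentrations in the cell after a number of injections."""

    injection_index: int
    m_total_um: float
    x_total_um: float


def concentrations_after_injection(design: TitrationDesign, i: int) -> CellState:
    """Total cell-species and titrant concentrations after ``i`` injections.

    Applies the perfusion convention of ``design`` (overfill-displacement
    by default).  ``i = 0`` returns the pristine cell.
    """
    dv = design.cumulative_volume_ul(i)  # validates the index
    r = dv / (design.cell_volume_ml * UL_PER_ML)
    if design.perfusion == "displacement":
        m = design.cell_conc_um * (1.0 - r / 2.0) / (1.0 + r / 2.0)
        x = design.syringe_conc_um * r / (1.0 + r / 2.0)
    else:
        m = design.cell_conc_um * math.exp(-r)
        x = design.syringe_conc_um * (1.0 - math.exp(-r))
    return CellState(i, m, x)


def bound_fraction_one_site(state: CellState, params: BindingParams1Site) -> float:
    """Fraction of sites occupied under the one-site isotherm.

    Solves the Wiseman quadratic for the physical root using the
    cancellation-free form ``theta = 2c / (b + sqrt(b^2 - 4c))`` with
    ``c = X_t/(n*M_t)`` and ``b = 1 + c + K_d/(n*M_t)``.  The
    stoichiometric limit ``K_d = 0`` and the empty cell ``X_t = 0`` are
    handled by analytic branches.
    """
    m, x = state.m_total_um, state.x_total_um
    if m <= 0:
        raise ValueError("bound fraction undefined for non-positive cell concentration")
    if x <= 0:
        return 0.0
    n = params.n
    c = x / (n * m)
    kd_um = params.kd_nm * 1e-3
    if kd_um == 0.0:
        return min(1.0, c)
    b = 1.0 + c + kd_um / (n * m)
    disc = math.sqrt(max(b * b - 4.0 * c, 0.0))
    theta = 2.0 * c / (b + disc)
    return min(max(theta, 0.0), 1.0)


def free_ligand_two_site(state: CellState, params: BindingParams2Site) -> float:
    """Free titrant concentration (uM) under the two-independent-site model.

    The mass balance has a unique root in ``[0, X_t]`` because the bound
    amount is monotone in the free concentration; it is located with
    Brent's method and verified to a residual below ``1e-10 * X_t``.
    """
    m, x = state.m_total_um, state.x_total_um
    if x < 0 or m < 0:
        raise ValueError("concentrations must be non-negative")
    if x == 0.0:
        return 0.0
    s1, s2 = params.site1, params.site2
    kd1, kd2 = s1.kd_nm * 1e-3, s2.kd_nm * 1e-3

    def balance(xf: float) -> float:
        return xf + m * (s1.n * xf / (kd1 + xf) + s2.n * xf / (kd2 + xf)) - x

    try:
        root = brentq(
            balance, 0.0, x,
            xtol=max(x, 1.0) * 1e-15,
            rtol=4.0 * np.finfo(float).eps,
            maxiter=200,
        )
    except Exception as exc:  # pragma: no cover - diagnostic path
        raise RuntimeError(
            f"free-ligand root finding failed for X_t={x:g} uM, M_t={m:g} uM: {exc}"
        ) from exc
    # Newton polishing: for very steep balances (K_d near zero) brentq's
    # absolute xtol limits the attainable residual, so refine to the
    # rounding floor of the balance terms.
    def slope(xf: float) -> float:
        return 1.0 + m * (
            s1.n * kd1 / (kd1 + xf) ** 2 + s2.n * kd2 / (kd2 + xf) ** 2
        )

    for _ in range(3):
        resid = balance(root)
        if abs(resid) <= 1e-12 * x:
            break
        root = min(max(root - resid / slope(root), 0.0), x)
    resid = balance(root)
    tol = max(1e-10 * x, 16.0 * np.spacing(x))
    if abs(resid) > tol:
        raise RuntimeError(
            f"free-ligand mass-balance residual {resid:.3e} uM exceeds tolerance "
            f"{tol:.3e} uM for X_t={x:g} uM"
        )
    return float(root)


def _states(design: TitrationDesign) -> tuple[np.ndarray, np.ndarray]:
    """Vectors of (M_t, X_t) for i = 0..N injections."""
    dv = np.concatenate([[0.0], np.cumsum(design.injection_volumes_ul)])
    r = dv / (design.cell_volume_ml * UL_PER_ML)
    if design.perfusion == "displacement":
        m = design.cell_conc_um * (1.0 - r / 2.0) / (1.0 + r / 2.0)
        x = design.syringe_conc_um * r / (1.0 + r / 2.0)
    else:
        m = design.cell_conc_um * np.exp(-r)
        x = design.syringe_conc_um * (1.0 - np.exp(-r))
    return m, x


def _cumulative_heats(design: TitrationDesign, params: BindingParams) -> np.ndarray:
    """Q(i) in ucal for i = 0..N (binding heat only, no dilution term)."""
    m, x = _states(design)
    v0_l = design.cell_volume_ml * 1e-3
    if isinstance(params, BindingParams1Site):
        n = params.n
        kd_um = params.kd_nm * 1e-3
        c = np.divide(x, n * m, out=np.zeros_like(x), where=m > 0)
        if kd_um == 0.0:
            theta = np.minimum(1.0, c)
        else:
            b = 1.0 + c + kd_um / (n * m)
            disc = np.sqrt(np.maximum(b * b - 4.0 * c, 0.0))
            theta = np.where(c > 0, 2.0 * c / (b + disc), 0.0)
        site_sum = n * params.dh_kcal_per_mol * theta
    else:
        s1, s2 = params.site1, params.site2
        kd1, kd2 = s1.kd_nm * 1e-3, s2.kd_nm * 1e-3
        site_sum = np.zeros_like(x)
        for i in range(len(x)):
            if x[i] <= 0:
                continue
            xf = free_ligand_two_site(CellState(i, m[i], x[i]), params)
            site_sum[i] = (
                s1.n * s1.dh_kcal_per_mol * xf / (kd1 + xf)
                + s2.n * s2.dh_kcal_per_mol * xf / (kd2 + xf)
            )
    return KCAL_TO_UCAL * v0_l * (m * 1e-6) * site_sum


def cumulative_heat(design: TitrationDesign, params: BindingParams, i: int) -> float:
    """Cumulative binding heat Q(i) in ucal after ``i`` injections.

    ``Q(i) = V_0 * M_t,i * sum_j n_j * dH_j * theta_j,i`` (ucal); the
    per-injection dilution constant is not included here.
    """
    design.cumulative_volume_ul(i)  # range check
    return float(_cumulative_heats(design, params)[i])


def injection_heats(design: TitrationDesign, params: BindingParams) -> np.ndarray:
    """Per-injection heats dQ(i) in ucal, i = 1..N.

    Includes the displaced-volume correction for heat carried out of the
    sensed volume::

        dQ(i) = Q(i) - Q(i-1) + (dV_i/V_0) * (Q(i) + Q(i-1)) / 2 + q_dil
    """
    q = _cumulative_heats(design, params)
    dv_ml = np.asarray(design.injection_volumes_ul) / UL_PER_ML
    v0 = design.cell_volume_ml
    return q[1:] - q[:-1] + (dv_ml / v0) * (q[1:] + q[:-1]) / 2.0 + params.q_dil_ucal


def wiseman_c_value(design: TitrationDesign, n: float, kd_nm: float) -> float:
    """c = n * [cell species] / K_d; gauges how informative a titration is."""
    return n * design.cell_conc_um / (kd_nm * 1e-3)
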