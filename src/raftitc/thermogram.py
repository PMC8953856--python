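"""Raw thermogram processing: baseline correction and peak integration.

Converts a differential-power trace (ucal/s vs s) into per-injection
integrated heats.  The baseline is a cubic spline anchored in the quiet
trailing part of each inter-injection interval, where the instrument has
relaxed back to its drift line; injection peaks are integrated against
that baseline with the trapezoidal rule on the native sampling grid.

Sign convention: exothermic events are negative, both as power
excursions and as integrated heats.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline

from .binding_models import TitrationDesign


class ConfigurationError(ValueError):
    """Raised when a processing step is mis-specified for the given trace."""


@dataclass
class PowerTrace:
    """A sampled differential-power signal with its injection schedule."""

    time_s: np.ndarray
    power_ucal_per_s: np.ndarray
    injection_times_s: np.ndarray

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.power_ucal_per_s = np.asarray(self.power_ucal_per_s, dtype=float)
        self.injection_times_s = np.asarray(self.injection_times_s, dtype=float)
        if self.time_s.shape != self.power_ucal_per_s.shape:
            raise ValueError("time and power vectors must have equal length")
        if self.time_s.size < 2 or np.any(np.diff(self.time_s) <= 0):
            raise ValueError("time vector must be strictly increasing")
        if self.injection_times_s.size == 0:
            raise ValueError("at least one injection time is required")
        if (self.injection_times_s.min() < self.time_s[0]
                or self.injection_times_s.max() > self.time_s[-1]):
            raise ValueError("injection times must lie within the trace time range")


@dataclass
class InjectionHeats:
    """Per-injection integrated heats (ucal), optionally normalized.

    ``normalized_kcal_per_mol`` is the same information expressed per
    mole of injectant; it is populated by
    :func:`normalize_per_mole`.  ``metadata`` carries provenance
    (ground-truth parameters for simulated data, background-subtraction
    flags, ...).
    """

    heats_ucal: np.ndarray
    normalized_kcal_per_mol: np.ndarray | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.heats_ucal = np.asarray(self.heats_ucal, dtype=float)
        if self.normalized_kcal_per_mol is not None:
            self.normalized_kcal_per_mol = np.asarray(
                self.normalized_kcal_per_mol, dtype=float
            )
            if self.normalized_kcal_per_mol.shape != self.heats_ucal.shape:
                raise ValueError("normalized heats must match heats in length")

    def __len__(self) -> int:
        return int(self.heats_ucal.size)


def spline_baseline(trace: PowerTrace, anchor_fraction: float = 0.1) -> np.ndarray:
    """Cubic-spline baseline evaluated on the trace's own time grid.

    One anchor node is placed per quiet segment: the whole
    pre-first-injection stretch, then the trailing ``anchor_fraction``
    of each inter-injection interval (where injection transients have
    decayed).  Each node is the mean (time, power) of its segment's
    samples, and a cubic spline through the nodes is extrapolated over
    the full record.
    """
    if not 0 < anchor_fraction <= 1:
        raise ConfigurationError("anchor_fraction must be in (0, 1]")
    t, p = trace.time_s, trace.power_ucal_per_s
    inj = np.sort(trace.injection_times_s)
    bounds = np.concatenate([inj, [t[-1]]])

    nodes_t, nodes_p = [], []
    pre = t < inj[0]
    if np.any(pre):
        nodes_t.append(t[pre].mean())
        nodes_p.append(p[pre].mean())
    for k in range(len(inj)):
        start, stop = bounds[k], bounds[k + 1]
        lo = stop - anchor_fraction * (stop - start)
        # right-exclusive: the sample at `stop` carries the next
        # injection's onset (last segment keeps its final sample)
        sel = (t >= lo) & ((t < stop) if k < len(inj) - 1 else (t <= stop))
        if np.any(sel):
            nodes_t.append(t[sel].mean())
            nodes_p.append(p[sel].mean())
    if len(nodes_t) < 3:
        raise ConfigurationError(
            f"only {len(nodes_t)} baseline anchors available; need at least 3 "
            "quiet segments (check injection times and anchor_fraction)"
        )
    bc = "not-a-knot" if len(nodes_t) >= 4 else "natural"
    spline = CubicSpline(nodes_t, nodes_p, bc_type=bc, extrapolate=True)
    return np.asarray(spline(t), dtype=float)


def integrate_injections(
    trace: PowerTrace,
    baseline: np.ndarray,
    injection_times_s: np.ndarray | None = None,
) -> InjectionHeats:
    """Integrate baseline-corrected power over each injection window.

    Window ``i`` runs from injection time ``i`` to injection time
    ``i+1`` (or the end of the record for the last injection);
    integration is trapezoidal on the native grid.
    """
    baseline = np.asarray(baseline, dtype=float)
    if baseline.shape != trace.time_s.shape:
        raise ConfigurationError("baseline must be sampled on the trace grid")
    times = (trace.injection_times_s if injection_times_s is None
             else np.asarray(injection_times_s, dtype=float))
    if np.any(np.diff(times) <= 0):
        raise ConfigurationError("injection windows overlap: times must be increasing")
    t = trace.time_s
    net = trace.power_ucal_per_s - baseline
    edges = np.concatenate([times, [t[-1]]])
    heats = np.empty(len(times))
    for i in range(len(times)):
        # right-exclusive windows: the sample at the next injection time
        # belongs to that injection's pulse onset
        last = i == len(times) - 1
        sel = (t >= edges[i]) & ((t <= edges[i + 1]) if last else (t < edges[i + 1]))
        if sel.sum() < 2:
            raise ConfigurationError(f"injection window {i} contains fewer than 2 samples")
        heats[i] = np.trapezoid(net[sel], t[sel])
    return InjectionHeats(heats, metadata={"source": "integrated_trace"})


def subtract_background(sample: InjectionHeats, control: InjectionHeats) -> InjectionHeats:
    """Element-wise sample-minus-control heats (buffer-titration control)."""
    if len(sample) != len(control):
        raise ValueError(
            f"length mismatch: sample has {len(sample)} injections, "
            f"control has {len(control)}"
        )
    meta = dict(sample.metadata)
    meta["background_subtracted"] = True
    return InjectionHeats(sample.heats_ucal - control.heats_ucal, metadata=meta)


def normalize_per_mole(heats: InjectionHeats, design: TitrationDesign) -> InjectionHeats:
    """Express heats in kcal per mole of injectant.

    Moles injected in injection ``i`` are ``syringe_conc * dV_i``; the
    heat in ucal is converted to kcal (1 kcal = 1e9 ucal).
    """
    dv = np.asarray(design.injection_volumes_ul, dtype=float)
    if len(heats) != dv.size:
        raise ValueError("heats length does not match the design's injection schedule")
    if design.syringe_conc_um <= 0 or np.any(dv <= 0):
        raise ValueError("moles injected per injection must be positive")
    moles = design.syringe_conc_um * 1e-6 * dv * 1e-6  # mol/L * L
    normalized = heats.heats_ucal * 1e-9 / moles
    return InjectionHeats(heats.heats_ucal, normalized, dict(heats.metadata))


def heats_from_normalized(
    normalized_kcal_per_mol: np.ndarray, design: TitrationDesign
) -> InjectionHeats:
    """Inverse of :func:`normalize_per_mole` for externally normalized data."""
    norm = np.asarray(normalized_kcal_per_mol, dtype=float)
    dv = np.asarray(design.injection_volumes_ul, dtype=float)
    if norm.size != dv.size:
        raise ValueError("normalized heats length does not match the schedule")
    moles = design.syringe_conc_um * 1e-6 * dv * 1e-6
    return InjectionHeats(norm * moles * 1e9, norm)
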