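# Methods

## The measurement being modeled

Isothermal titration calorimetry (ITC) in *reverse* geometry: the
GM1-binding peptide sits in the calorimeter cell and GM1, solubilized in
GM1:DPC (1:5) mixed micelles, is injected from the syringe. Each
injection releases (or absorbs) heat proportional to the newly formed
complex; the decreasing per-injection heats across the titration encode
the dissociation constant K_D, the binding enthalpy ΔH, and the
stoichiometry n (titrant-binding sites per cell-species molecule — n =
0.5 encodes a 2:1 peptide:GM1 complex).

The default `TitrationDesign` is the study condition set: 15 µM peptide
in a 1.4 mL cell, 300 µM GM1 in a 300 µL syringe delivered as 20 × 15 µL
injections 300 s apart, at 308.15 K. The cell volume is not part of the
study description; 1.4 mL is the nominal working volume of the named
instrument class (MicroCal VP-ITC) and is configurable.

## Binding models

**One set of sites (Wiseman isotherm).** The bound fraction Θ of the
n·M_t sites solves

    Θ² − Θ·(1 + X_t/(n·M_t) + K_d/(n·M_t)) + X_t/(n·M_t) = 0,

taken at the physical root in the cancellation-free form
Θ = 2c/(b + √(b² − 4c)). The limits K_d = 0 (stoichiometric titration)
and X_t = 0 are analytic branches.

**Two independent site classes.** The free titrant concentration x
solves X_t = x + M_t·(n₁x/(K_d1+x) + n₂x/(K_d2+x)), which is monotone in
x and therefore has a unique root in [0, X_t]. It is bracketed with
Brent's method and polished with up to three Newton steps; the residual
is verified against max(1e-10·X_t, 16·ulp(X_t)) — the second term is the
float64 rounding floor of the balance terms, which dominates only when
K_d approaches the optimizer bound of 1e-12 M.

**Concentration bookkeeping.** The cell is overfilled: every injection
displaces an equal volume of sensed liquid. With cumulative injected
volume ΔV,

    M_t = M₀·(1 − ΔV/2V₀)/(1 + ΔV/2V₀),
    X_t = X_syr·(ΔV/V₀)/(1 + ΔV/2V₀).

A continuous-perfusion alternative (`perfusion="exponential"`,
M_t = M₀e^(−ΔV/V₀)) is available. The closed displacement forms are a
midpoint approximation of stepwise perfusion; after 20 × 15 µL into
1.4 mL they differ from a per-injection displacement simulation by
~3×10⁻⁴ (cell species) and ~1.4×10⁻³ (titrant), which bounds the realism
of either convention.

**Heats.** Cumulative binding heat Q(i) = V₀·M_t,i·Σ_j n_j·ΔH_j·Θ_j,i
(µcal; ΔH in kcal/mol of titrant, 1 kcal = 10⁹ µcal). Per-injection
heats add the displaced-heat correction and the constant mixing/dilution
nuisance term:

    ΔQ(i) = Q(i) − Q(i−1) + (dV_i/V₀)·(Q(i)+Q(i−1))/2 + q_dil.

q_dil is µcal per injection (not per mole), matching its role as a
constant correction term. Exothermic heat is negative throughout.

## Thermogram processing

The baseline of a raw differential-power trace is a cubic spline through
one anchor node per quiet segment: the pre-first-injection stretch plus
the trailing 10 % (configurable) of each inter-injection interval, where
the exponential injection transient has decayed. Nodes are segment means
of (time, power); a trace whose quiet segments lie on a line reproduces
that line exactly. Windows and anchors are right-exclusive — the sample
at an injection time belongs to that injection's pulse onset, not to the
preceding window. Integration is trapezoidal on the native grid (no
resampling); at 1 s sampling and τ = 10 s response the quadrature error
is ≲0.1 %, far below instrument noise. Background (buffer-titration)
subtraction is element-wise; normalization divides by moles injected
(syringe concentration × injection volume).

## Fitting

The objective is Σ_i (ΔQ_obs(i) − ΔQ_model(i))² in µcal², minimized with
a bounded trust-region-reflective least-squares solver. Free parameters:
{n, K_d, ΔH, q_dil} (one-site) or {n₁, K_d1, ΔH₁, n₂, K_d2, ΔH₂, q_dil}
(two-site). K_d is optimized as log₁₀ K_d with bounds [1e-12, 1e-2] M;
n ∈ [0.05, 10]; ΔH ∈ [−100, 100] kcal/mol; q_dil ∈ [−50, 50] µcal.

Initialization is deterministic: q_dil from the tail median, ΔH from the
first corrected normalized heat, n from the molar ratio at half-maximal
cumulative heat, and K_d from a 29-point log-grid scan in which the
linearly entering (ΔH, q_dil) pair is solved exactly at each grid point.
Two-site fits run three deterministic starts built from the one-site
warm start (split sites ±0.7 log units, with same- and opposite-sign
ΔH₂, and an asymmetric weak-site start), keeping the lowest SSE;
site labels are canonically reordered to K_d1 ≤ K_d2 after fitting.
Tolerances are 1e-12 (one-site) and 1e-8 (two-site; the 7-parameter
surface is flat along site-splitting directions when the data carry a
single site, and tighter tolerances only grind there). A Wiseman c-value
(c = n·M₀/K_d) outside [1, 1000] is recorded as a warning — the fit is
still returned, but K_d is weakly determined.

**Uncertainties** are leave-one-injection-out jackknife estimates: each
replicate refits from the full-data optimum with one injection removed,
and SE(θ) = √((N−1)/N · Σᵢ (θ₍ᵢ₎ − θ̄)²) on natural scales. Replicates
that fail to converge are dropped with a warning; below 80 % convergence
the procedure errors out. On data the model reproduces exactly, all SEs
are numerically zero.

**Model comparison** reports SSE, the small-sample Akaike criterion
AICc = n·ln(SSE/n) + 2k + 2k(k+1)/(n−k−1), and the nested F-test; the
recommendation is the lower AICc. Note that for noise-free synthetic
data both models reach SSE at rounding level and the log-SSE scale is
degenerate — comparison is meaningful only for data with noise.

## Synthetic data

The generator emulates the study design with known ground truth:

- integrated heats = model heats + i.i.d. Gaussian noise, default
  σ = 0.3 µcal (typical integrated-heat scatter for this instrument
  class; no noise figure is part of the study conditions);
- raw traces: each injection contributes (ΔQ_i/τ)·e^(−(t−t_i)/τ)
  (single-exponential instrument response, τ = 10 s default, area
  exactly ΔQ_i), on a linear drift (2×10⁻⁵ µcal·s⁻² default) with
  per-sample Gaussian noise, 1 s sampling, 60 s of pre-injection
  baseline;
- dilution-only controls (ΔH = 0), and Gaussian emission bands with the
  exact (possibly off-grid) peak recorded in metadata.

ΔH values are not part of the study conditions; the generator's defaults
are −8 kcal/mol for monomeric peptides and −10 kcal/mol for the
multivalent construct — exothermic magnitudes typical of
carbohydrate-directed peptide binding. Everything is deterministic under
a fixed seed, and zero-noise output equals the model layer bitwise.

What the generator does *not* emulate: micelle-phase equilibria and
GM1:DPC composition effects (the 1:5 ratio is treated purely as fixing
the effective GM1 concentration), heat-of-mixing physics beyond the
constant term, baseline artifacts other than linear drift, and
correlated noise. Passing recovery tests therefore demonstrates the
correctness of the estimation machinery under the stated design, not
robustness to every instrumental pathology of real thermograms.

## Spectral computations

Emission maxima: centered moving average (default 5 points,
reflect-padded) followed by three-point parabolic interpolation around
the discrete argmax — deterministic and sub-grid accurate (±0.2 nm on a
1 nm grid for Gaussian bands). A maximum at the range boundary is
flagged and returned unrefined. Blue shift = peak(free) − peak(bound),
positive for the expected aqueous→membrane transfer. CD differences are
computed by linear interpolation of both spectra on their overlap;
the result is the change at the target wavelength (e.g. 198 nm, where
the Trp–Trp exciton band reports on terminal-tryptophan packing) plus
the full difference spectrum.

## Scan analysis

ΔΔG = R·T·ln(K_D,variant/K_D,parent) with R = 1.98720×10⁻³
kcal·mol⁻¹·K⁻¹ and T defaulting to the ITC temperature 308.15 K.
Not-fittable cells are right-censored: they are excluded from the
finite destabilization ranking and reported separately as lower bounds
at least as large as the maximum observed ΔΔG — never imputed. Cells
with ΔΔG < 0 (affinity gains, seen for N-terminal backbone
homologation) are flagged. Avidity enhancement of a multivalent
construct is the plain ratio K_D,monomer/K_D,multivalent.

## Known limitations

- Single-dataset fits only; duplicate titrations are not averaged or
  globally fitted.
- No sequential/cooperative-site or competitive models; no kinetic
  analysis.
- Concentration error (cell/syringe mis-calibration) is not part of the
  error model; jackknife SEs capture only heat-level scatter.
- The displacement bookkeeping is a convention, accurate to a few per
  mille of a stepwise perfusion simulation at the default fill ratio.
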