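# raftitc

Analysis toolkit for isothermal titration calorimetry (ITC) of
peptide–ganglioside GM1 binding, built for the reverse-titration
experiments used to characterize short GM1-binding α/β-peptide tags
(WYKYW and its positional variants): GM1:DPC micelles titrated into a
peptide-containing cell.

It covers the full desk-side pipeline:

- **thermogram processing** — spline baseline correction of raw
  differential-power traces, per-injection peak integration, background
  (buffer-titration) subtraction, per-mole normalization;
- **isotherm fitting** — one-site (Wiseman) and two-independent-site
  models with a constant per-injection dilution-heat nuisance term,
  bounded nonlinear least squares with K_D on a log scale, jack-knife
  standard errors, and AICc/F-test model comparison;
- **structure–affinity analysis** — Ala-/D-/β³-scan ΔΔG ladders with
  right-censored handling of not-fittable titrations, and multivalent
  avidity enhancement;
- **spectral utilities** — tryptophan emission-maximum detection
  (sub-nm parabolic interpolation), blue-shift magnitude, CD difference
  spectra;
- **synthetic data** — a seeded generator of heats, raw traces,
  dilution controls and emission bands with known ground truth,
  emulating the study design (300 µM GM1:DPC into 15 µM peptide,
  20 × 15 µL injections at 300 s, 35 °C).

## The model

For a single set of `n` sites per cell-species molecule the bound
fraction Θ solves

```
Θ² − Θ·(1 + X_t/(n·M_t) + K_d/(n·M_t)) + X_t/(n·M_t) = 0
```

and the cumulative heat after injection *i* is
`Q(i) = V₀·M_t,i·n·ΔH·Θ_i`, with the per-injection observable

```
ΔQ(i) = Q(i) − Q(i−1) + (dV_i/V₀)·(Q(i)+Q(i−1))/2 + q_dil .
```

The two-site model replaces `n·ΔH·Θ` by the sum over two independent
site classes, with the free titrant concentration obtained from the
mass balance by bracketed root finding. Cell concentrations follow the
overfilled-cell displacement correction. `docs/methods.md` has the full
account, including all defaults and numerical choices.

## Worked example

Simulate a noisy titration of the parent peptide (K_D 23.8 nM, n 0.5,
ΔH −8 kcal/mol, q_dil −0.2 µcal, heat noise 0.3 µcal) and fit it:

```python
import raftitc as r

design = r.TitrationDesign()                     # the study design
truth  = r.BindingParams1Site(n=0.5, kd_nm=23.8,
                              dh_kcal_per_mol=-8.0, q_dil_ucal=-0.2)
heats  = r.simulate_heats(design, truth, r.NoiseModel(heat_sigma_ucal=0.3, seed=42))
fit    = r.fit_isotherm(heats, design, model="one_site")
se     = r.jackknife_errors(heats, design, "one_site", fit)
```

prints (via `fit.param_dict` / `se`):

```
n                       0.500  +/- 0.003
kd_nm                  15.236  +/- 5.766
dh_kcal_per_mol        -7.963  +/- 0.058
q_dil_ucal             -0.228  +/- 0.065
converged: True  SSE (ucal^2): 1.134
c-value: 492
```

The stoichiometry and enthalpy come back tightly; K_D is the
least-determined parameter at this noise level (c ≈ 500 means the
titration curve is steep), which the jack-knife error makes explicit —
one noisy realization can sit an SE or two from the truth.

Downstream of fitting, the packaged positional-scan table gives the
structure–affinity summary:

```python
from raftitc.io import load_wykyw_scan
profile = r.scan_profile(load_wykyw_scan())
profile.ranking[0]        # ('ala', 'K3', 3.727)  – central Lys dominates
profile.improvements      # [('beta', 'W1', -1.048)] – β³-hTrp gains affinity
r.avidity_enhancement(r.AvidityPair())   # 8.7-fold for the tetravalent hub
```

and synthetic emission bands at the measured free/bound maxima give
`r.blue_shift(free, bound) == 9.0` nm.

A `raftitc` console script exposes the same steps
(`simulate`, `integrate`, `fit`, `scan`, `spectra`) for shell use; see
`raftitc --help`.

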