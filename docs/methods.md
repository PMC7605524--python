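# Methods

## The twitch model

`twitchlab` simulates isometric cardiac twitches with a six-state
actomyosin scheme of the Negroni–Lascano family.  Each regulatory unit
(troponin–tropomyosin–actin, "RU") is in one of six states:

| state   | Ca²⁺ on troponin | cross-bridge | tension |
|---------|------------------|--------------|---------|
| TS      | no               | detached     | no      |
| TSCa₃   | yes              | detached     | no      |
| TSCa₃~  | yes              | weak         | no      |
| TSCa₃*  | yes              | strong       | yes     |
| TS*     | no (released)    | strong       | yes     |
| TS~     | no               | weak         | no      |

with transitions

```
TS  ⇌[Y_b·Ca^n / Z_b]  TSCa₃  ⇌[f_eff / g]  TSCa₃~  ⇌[Y_p / Z_p]  TSCa₃*
TSCa₃*  ⇌[Y_r / Z_r·Ca^n]  TS*  →[Z_p]  TS~  →[g]  TS
```

Rate units are ms⁻¹ (Y_b and Z_r per µM^n per ms).  Three closure
choices shape the dynamics:

1. **Cooperative Ca²⁺ binding.**  The n = 3 Ca²⁺ ions of the TSCa₃ step
   bind as one cooperative transition, so the association fluxes carry
   Ca^n.  This gives the steep separation between diastolic (0.1 µM) and
   systolic (~1 µM) activation that a single-ion step cannot produce,
   and keeps the resting state clean (occupancy ~1 in TS at diastolic
   Ca²⁺).
2. **One-way deactivation of Ca²⁺-free bridges.**  Once Ca²⁺ has left
   (TS*, TS~), the thin filament no longer supports the power stroke:
   TS* can only slip back to the weak state (Z_p) and detach (g).  This
   bounds the relaxation path independently of Y_p; allowing TS~ → TS*
   re-entry would let a large Y_p trap tension in the strong states
   indefinitely, and the cross-bridge inotropy sweep would grow without
   bound instead of saturating.
3. **Saturable attachment facilitation (end-to-end Tm coupling).**
   Strong cross-bridges hold tropomyosin in the open position and ease
   attachment in neighbouring RUs.  The weak-attachment flux uses
   `f_eff = f · (1 + xb_coop · S/(xb_coop_K + S))` with S the strong-state
   fraction.  In a mean-field single-RU scheme with constant rates the
   peak tension is at best linear in f, so a 43.5 % reduction of f could
   never produce the ~50 % peak drop that defines the mutant emulation;
   the facilitation term supplies the missing cooperative gain, and its
   saturation (half-saturation `xb_coop_K`) keeps the gain bounded when
   strong-state occupancy is driven up by an inotropic sweep.

Free Ca²⁺ follows

```
dCa/dt = J_rel(t) − k_pump·(Ca − Ca_dia) + n·Tn_tot·(J_release − J_binding)
```

with a once-triggered SR release drive `J_rel(t) = J_rel_amp·(t/τ_rel)·
exp(1 − t/τ_rel)` and a linear re-uptake pump.  Because Ca²⁺ bound to an
attached RU can only leave through the slow strong-state release step
(Y_r), cross-bridges shield activator Ca²⁺ from the pump — the second
cooperative mechanism, which prolongs the twitch in proportion to
attachment.

Tension is `A_stiff · overlap(SL) · (TSCa₃* + TS*) · h`: strong-state
occupancy times the mean elastic cross-bridge elongation `h`, which under
isometric conditions (dL/dt = 0) relaxes to its steady value `h_c` with
time constant `τ_h`; `overlap(SL)` is a piecewise-linear thin/thick
filament overlap factor (0.6 at the default SL of 1.8 µm).  Tension is
reported in model units (mN/mm² scale); every analysis downstream
normalizes to the wild-type peak, so the absolute scale cancels.

### Integration

Explicit forward Euler with dt = 0.01 ms over 1000 ms, recording at
1 kHz.  The fastest rate in the default set is ~1.7 ms⁻¹, so λ·dt ≈ 0.02
and the scheme is comfortably stable; halving dt changes peak tension by
< 0.01 % (a convergence test enforces < 0.5 %).  Occupancy conservation
is exact to rounding (sum of state derivatives is identically zero) and
is checked at every recorded sample; an occupancy leaving [0, 1] beyond
10⁻⁶ raises a stability error advising a smaller step.  The resting state
is the diastolic initial condition — binding pre-equilibrium between TS
and TSCa₃ at diastolic Ca²⁺, all cross-bridge states empty — which is
independent of f and drifts by < 1 % of the wild-type peak over 100 ms
of unstimulated integration.

### Calibration of the packaged parameter set

The parameter file `src/twitchlab/data/sixstate_default.yaml` tags every
value with provenance; all numeric values are `calibrated`: the set was
tuned once to jointly reproduce

* a physiologic murine intact-trabecula twitch at SL 1.8 µm —
  time-to-peak ≈ 75 ms, 50 % relaxation ≈ 165 ms after the peak,
  relaxation to ≈ 2 % of peak within the 1000 ms window;
* a peak-tension reduction of ~50 % when f is reduced by 43.5 %
  (the defining property of the mutant emulation);
* a twitch duty (integral/peak ≈ 270 ms over the 1 s window) consistent
  with the reported simulated tension index of the mutant;
* the qualitative behaviour of the two inotropy sweeps: the
  Ca²⁺-sensitivity route drives the mutant TI past zero without
  saturating, while the cross-bridge route saturates (final increment
  < 10 % of the first) at a TI still below zero.

After this one-time calibration the set was frozen; no test outcome fed
back into it.

## Mutation emulation and sweeps

`emulate_mutation(params, f_scale)` scales f only.  `calibrate_f_scale`
finds the scale reaching a target peak fraction by bisection on (0, 1],
verifying monotonicity of peak vs f across the bracket; with the default
set, a 0.5 target returns a scale of ≈ 0.563 (a ~44 % reduction).  Sweep
schedules pair forward factors 2…10 (Y_b capped at 9× — the cap is a
ceiling applied per point, not a rescaling of the schedule) with reverse
factors 0.9…0.5, index-aligned, 9 points by default; the unmodified
mutant is reported separately as the baseline rather than as a sweep
point.

## Tension index

Traces are baseline-subtracted (pre-stimulus diastolic tension, i.e. the
first sample) by default — without subtraction, passive tension would
dominate the integral of a long window; the flag `subtract_baseline=False`
disables it and both conventions are exposed.  Both traces are then
normalized to the wild-type maximum (the WT trace maps to peak = 100)
and integrated with the composite trapezoid rule on the WT time grid
(variants on a different grid are linearly resampled).  TI(WT, WT) is
exactly zero; TI is antisymmetric under role swap against a common
reference and invariant to common unit rescaling.

## Hill analysis

Tension-pCa curves are fit per preparation by nonlinear least squares to
`T_SS = T_SS,Max/(1 + 10^(n_H·(pCa − pCa50)))`, initialized at the pCa of
the sample closest to half-max with n_H = 2, multi-starting n_H ∈ {1, 2, 4};
a fitted pCa50 outside the sampled range is refused rather than
extrapolated.  (Note the exponent sign: tension must fall as pCa rises;
the equivalent form with `(pCa50 − pCa)` in the exponent describes the
mirrored curve and would place maximal tension at minimal Ca²⁺.)  With
`normalize=True` tensions are first expressed as percent of the value at
the saturating point pCa 4.0, falling back to the observed maximum with
a warning.  Group comparison is one-way ANOVA plus Tukey HSD on the
per-preparation estimates; a dataset with zero spread short-circuits to
F = 0, p = 1 instead of the undefined 0/0 statistic.

## Structure analysis

Distances operate on a tidy atom table parsed from PDB files
(Biopython) with a chain-role map (cTnC, cTnI, Tm, actin, ion) supplied
directly or as a YAML sidecar.  Residue-residue distances default to
Cα–Cα with a per-residue mass-weighted center-of-mass option
(`metric="com"`); the choice is recorded in the output.  The
inhibitory-peptide statistic averages the Cα-to-COM distance of cTnI
residues 137–147 against the actin monomer with the smallest mean
distance (ties broken by chain-id order).  Contact-difference maps fix
the pair set from the wild-type structure alone (pairs ≤ cutoff, 10 Å
default) and report variant-minus-WT distances for exactly those pairs.
Frame averaging requires identical atom identity and ordering across
frames; molecular-dynamics production is out of scope — frames are
consumed, never generated.

## Synthetic data

The exponential twitch generator produces
`T(t) = A·c·(1 − e^(−(t−ℓ)/τ_rise))·e^(−(t−ℓ)/τ_decay)` with c chosen so
the realized (sampled) maximum equals A exactly.  The pCa generator adds
seeded Gaussian noise (σ as % of T_SS,Max) to an exact Hill curve and
clips at zero; the recording generator resamples to 1 kHz and adds
seeded Gaussian noise.  These emulate the first-order statistics of the
instruments but deliberately omit drift, autocorrelated noise, stimulus
artifacts and motion artifacts — parameter-recovery results on them
bound estimator bias under ideal noise, not robustness to structured
artifacts.  Toy structures realize designed geometries (explicit points,
lines, arcs, single atoms) so every distance statistic has a hand-
computable oracle; they are labelled synthetic and are not derived from
any deposited structure.

## Known limitations

* The kinetic parameter values are calibrated, not transcribed from a
  published table; quantities tied to absolute twitch duration (e.g. the
  TI in %WT·ms) inherit the calibration's duty-cycle choice.  Relative
  and normalized quantities (peak fractions, sweep shapes, TI signs and
  orderings) are robust to this.
* The model is mean-field over regulatory units; spatially explicit
  nearest-neighbour cooperativity is represented by the saturable
  facilitation term, not by an RU lattice.
* Isometric only: no length ramps, work loops or afterloaded
  contractions; the series elastic element is absorbed into the constant
  half-sarcomere length.
* The Ca²⁺ transient is an intrinsic alpha-function release plus linear
  re-uptake; there is no membrane electrophysiology and no beat-to-beat
  Ca²⁺ handling.
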