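# Default parameter set for the 6-state sarcomere activation / cross-bridge model.
#
# Topology (Negroni-Lascano-style 6-state scheme):
#   TS <-(Y_b*Ca^n / Z_b)-> TSCa3 <-(f / g)-> TSCa3~ <-(Y_p / Z_p)-> TSCa3*
#   TSCa3* <-(Y_r / Z_r*Ca^n)-> TS* -(Z_p)-> TS~ -(g)-> TS
# Only the strong states (TSCa3*, TS*) generate tension.  The deactivation
# path TS* -> TS~ -> TS is one-way: with Ca2+ gone the thin filament no
# longer supports the power stroke, so Ca2+-free bridges can only slip back
# to the weak state and detach.
#
# Provenance: every value tagged "calibrated" was tuned, once, to reproduce
# a physiologic murine intact-trabecula twitch at SL 1.8 um (time-to-peak
# ~75 ms, 50% relaxation ~165 ms after the peak, relaxation to ~2% of peak
# within the 1000 ms window) with a ~50% peak-tension drop when the
# weak-attachment rate f is reduced by 43.5%.  Units are per-ms and per-uM.
f:   {value: 0.0032, units: 1/ms,           provenance: calibrated}
g:   {value: 0.0077, units: 1/ms,           provenance: calibrated}
Y_b: {value: 0.13,   units: 1/(uM^n_Ca*ms), provenance: calibrated}
Z_b: {value: 1.7,    units: 1/ms,           provenance: calibrated}
Y_p: {value: 0.56,   units: 1/ms,           provenance: calibrated}
Z_p: {value: 0.10,   units: 1/ms,           provenance: calibrated}
Y_r: {value: 0.0039, units: 1/ms,           provenance: calibrated}
Z_r: {value: 0.0114, units: 1/(uM^n_Ca*ms), provenance: calibrated}
aux:
  # --- intracellular Ca2+ drive and handling ---
  Ca_dia:    {value: 0.1,    units: uM,       provenance: calibrated}  # diastolic free Ca2+
  J_rel_amp: {value: 0.94,   units: uM/ms,    provenance: calibrated}  # peak SR release flux
  tau_rel:   {value: 8.0,    units: ms,       provenance: calibrated}  # release alpha-function time constant
  k_pump:    {value: 0.318,  units: 1/ms,     provenance: calibrated}  # linear re-uptake rate
  Tn_tot:    {value: 33.5,   units: uM,       provenance: calibrated}  # regulatory-unit concentration
  n_Ca:      {value: 3.0,    units: dimensionless, provenance: negroni-lascano}  # Ca2+ ions bound per unit
  # --- thin-filament cooperativity (end-to-end Tm coupling) ---
  xb_coop:   {value: 4.08,   units: dimensionless, provenance: calibrated}  # facilitation gain by strong XBs
  xb_coop_K: {value: 0.0326, units: dimensionless, provenance: calibrated}  # strong-fraction half-saturation
  # --- cross-bridge mechanics (isometric) ---
  A_stiff:   {value: 24000.0, units: mN/(mm^2*um), provenance: calibrated}  # lumped XB stiffness
  h_c:       {value: 0.005,  units: um,       provenance: calibrated}  # steady cross-bridge elongation
  tau_h:     {value: 2.0,    units: ms,       provenance: calibrated}  # elongation relaxation time
  # --- thin/thick filament overlap geometry ---
  ov_L0:     {value: 1.2,    units: um,       provenance: calibrated}  # SL of zero overlap
  ov_L1:     {value: 2.2,    units: um,       provenance: calibrated}  # SL of full overlap
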