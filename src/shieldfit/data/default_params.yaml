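# Reference parameter set for the PIP2 charge-shielding model of PLC
# inhibition.  Units are explicit in every key.
#
# psi: local electrostatic potential of the substrate (from molecular-
#   dynamics and monolayer estimates for PIP2); never fitted.
# l_ref: half-maximal effective cation concentration, calibrated with the
#   reference small divalent (Mg2+, z_ref = 2); scaled as l_ref*z_ref/z for
#   other valences.
# kd: effective enzyme-substrate dissociation constant, fixed for all PLC
#   isoforms.
# k_assoc: chemical association constant of the cation for the substrate on
#   the effective-concentration scale (1/K is the effective dissociation
#   constant in M).
# w_neomycin: unshieldable residual substrate giving the activity plateau at
#   saturating neomycin; 0 for every other cation.
shielding:
  psi_mV: -25.0
  temperature_K: 295.15
  l_ref_mM: 32.0
  z_ref: 2
  pip2_total_uM: 30.0
  kd_uM: 50.0
  w_neomycin_uM: 4.1

cations:
  Mg:
    valence: 2
    y_factor: 1.0
    k_assoc_per_M: 1.0          # 1/K = 1000 mM
  Ca:
    valence: 2
    y_factor: 1.0
    k_assoc_per_M: 190.0        # 1/K = 5.2 mM
  Ba:
    valence: 2
    y_factor: 1.0
    k_assoc_per_M: 460.0        # 1/K = 2.1 mM
  putrescine:
    valence: 2
    y_factor: 0.12
    k_assoc_per_M: 0.2778       # 1/K = 3600 mM
  spermidine:
    valence: 3
    y_factor: 0.12
    k_assoc_per_M: 52.63        # 1/K = 19 mM
  spermine:
    valence: 4
    y_factor: 0.12
    k_assoc_per_M: 100.0        # 1/K = 10 mM
  neomycin:
    valence: 6
    y_factor: 0.12
    k_assoc_per_M: 1000.0       # 1/K = 1 mM
    plateau_capable: true
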