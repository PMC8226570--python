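# Illustrative OmpF parametrization.
#
# These pore parameters and scoring coefficients are EXAMPLE values chosen
# to be physically plausible for a cation-selective general porin (negative
# internal potential, constriction cross-section ~50 A^2 with sizeable
# fluctuations).  They are NOT trained or published values: calibrate the
# coefficients against your own reference permeabilities with the
# `calibrate` command before quantitative use.
pore:
  name: OmpF
  v_pore_mV: -30.0          # internal electrostatic potential, mV
  e_pore_mV_per_A: 6.0      # characteristic transversal field, mV/A
  area_mean_A2: 50.0        # constriction cross-section mean, A^2
  area_sd_A2: 9.0           # constriction cross-section fluctuation, A^2
coefficients:
  alpha: 1.0                # steric weight
  beta: -0.03               # charge-potential weight (beta*V_pore > 0 favours cations)
  gamma: 0.008              # transversal dipole-field weight
  delta: 0.0                # offset
filters:
  accumulation_cutoff: 45.0 # nmol per 10^12 CFUs, assay detection limit
  alogp_cutoff: 2.9         # above this, compounds bypass porins
descriptors:
  n_directions: 256         # hemisphere directions for the MPA search
  grid_resolution: 0.1      # raster step, A
  seed: 0
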