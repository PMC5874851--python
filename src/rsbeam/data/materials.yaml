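# Material registry: slab media relevant to range-shifter modelling.
#
# range_coeff_alpha / range_exponent_p are Bragg-Kleeman power-law
# coefficients, R [cm] = alpha * E[MeV]**p, fitted over 50-250 MeV against a
# continuous-slowing-down range obtained by integrating the Bethe stopping
# power with the (Z/A, I) values listed per material.  The fit agrees with
# the underlying quadrature to better than 1% over 70-230 MeV.
#
# radiation_length_mass is the mass radiation length in g/cm^2.
water:
  name: water
  density: 1.0                 # g/cm^3
  radiation_length_mass: 36.08 # g/cm^2
  range_coeff_alpha: 2.461612e-03  # cm/MeV^p
  range_exponent_p: 1.742748
  z_over_a: 0.55509
  mean_excitation_ev: 75.0
lexan:
  name: lexan
  density: 1.20
  radiation_length_mass: 41.50
  range_coeff_alpha: 2.148695e-03
  range_exponent_p: 1.743216
  z_over_a: 0.52697
  mean_excitation_ev: 73.1
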