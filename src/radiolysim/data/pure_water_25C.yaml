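# Reaction set for the chemical stage of pure-water radiolysis at 25 degC.
# Rates are the standard ambient-temperature diffusion-controlled set
# (units: M^-1 s^-1). Water is the continuum solvent: "H2O" appearing as a
# reactant or product is notation only and is dropped at load time.
#
# Diffusion coefficients (m^2 s^-1): the solvated-electron value is
# 4.9e-9 m^2/s (25 degC); the remaining values are the Geant4-DNA /
# radiation-chemistry literature defaults and can be overridden in a
# user config.
species:
  - {name: e_aq,  D: 4.9e-9,  charge: -1}
  - {name: OH,    D: 2.8e-9,  charge: 0}
  - {name: H,     D: 7.0e-9,  charge: 0}
  - {name: H3O+,  D: 9.46e-9, charge: 1}
  - {name: H2,    D: 4.8e-9,  charge: 0}
  - {name: OH-,   D: 5.3e-9,  charge: -1}
  - {name: H2O2,  D: 2.3e-9,  charge: 0}

reactions:
  - {reactants: [H, e_aq, H2O],   products: [OH-, H2],       rate: 2.5e10}
  - {reactants: [H, OH],          products: [H2O],           rate: 1.55e10}
  - {reactants: [H, H],           products: [H2],            rate: 0.503e10}
  - {reactants: [H2O2, e_aq],     products: [OH-, OH],       rate: 1.1e10}
  - {reactants: [H3O+, e_aq],     products: [H, H2O],        rate: 2.11e10}
  - {reactants: [H3O+, OH-],      products: [H2O, H2O],      rate: 11.3e10}
  - {reactants: [OH, e_aq],       products: [OH-],           rate: 2.95e10}
  - {reactants: [OH, OH],         products: [H2O2],          rate: 0.55e10}
  - {reactants: [e_aq, e_aq, H2O, H2O], products: [OH-, OH-, H2], rate: 0.636e10}
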