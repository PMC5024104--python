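# Ramachandran-region boxes used to label the (phi, psi) of the two central
# turn residues under two published nomenclatures.
#
# These are axis-aligned approximations: neither nomenclature's original
# publication prints machine-readable boundary coordinates, so the boxes
# below were drawn to cover the conventional regions; users may replace
# this file.  Intervals are [min, max) in degrees; a psi interval with
# min > max wraps through +/-180.  Regions within a scheme must not
# overlap (checked at load time); (phi, psi) outside every box is labelled
# "unassigned".
wilmot_thornton:
  - {name: beta_E,  phi: [-180.0, -45.0], psi: [45.0, -135.0]}   # psi wraps
  - {name: alpha_R, phi: [-180.0, -45.0], psi: [-135.0, 45.0]}
  - {name: alpha_L, phi: [20.0, 125.0],   psi: [-45.0, 90.0]}
  - {name: gamma_L, phi: [20.0, 125.0],   psi: [90.0, -45.0]}    # psi wraps
efimov:
  - {name: beta_E,  phi: [-180.0, -45.0], psi: [90.0, -150.0]}   # psi wraps
  - {name: delta,   phi: [-180.0, -100.0], psi: [30.0, 90.0]}
  - {name: gamma,   phi: [-130.0, -60.0], psi: [-35.0, 30.0]}
  - {name: alpha,   phi: [-90.0, -40.0],  psi: [-75.0, -35.0]}
  - {name: alpha_L, phi: [20.0, 125.0],   psi: [-45.0, 90.0]}
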