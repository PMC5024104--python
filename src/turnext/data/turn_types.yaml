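# Canonical dihedral-angle definitions of beta-turn types.
#
# Each entry gives the canonical (phi_i+1, psi_i+1, phi_i+2, psi_i+2) quad in
# degrees.  A quad matches a type when at least three of the four wrapped
# absolute deviations are <= 30 deg and the remaining one is <= 45 deg
# (inclusive).  Types VIa1, VIa2 and VIb additionally require a cis-proline
# at position i+2.
#
# Tiers:
#   classical - the eight types of the standard (Hutchinson-Thornton)
#               nomenclature, matched first;
#   extended  - the four types added by dihedral-space clustering of the
#               former miscellaneous type IV; matched only when no classical
#               type fits;
#   obsolete  - historical types (III, III', V, V') reported as annotations
#               only, never as the main assignment.
#
# Values are config-driven so any revision can be applied without a code
# change.
classical:
  - {name: I,     canonical: [-60.0,  -30.0,  -90.0,    0.0], cis_pro_i2: false}
  - {name: "I'",  canonical: [ 60.0,   30.0,   90.0,    0.0], cis_pro_i2: false}
  - {name: II,    canonical: [-60.0,  120.0,   80.0,    0.0], cis_pro_i2: false}
  - {name: "II'", canonical: [ 60.0, -120.0,  -80.0,    0.0], cis_pro_i2: false}
  - {name: VIII,  canonical: [-60.0,  -30.0, -120.0,  120.0], cis_pro_i2: false}
  - {name: VIa1,  canonical: [-60.0,  120.0,  -90.0,    0.0], cis_pro_i2: true}
  - {name: VIa2,  canonical: [-120.0, 120.0,  -60.0,    0.0], cis_pro_i2: true}
  - {name: VIb,   canonical: [-135.0, 135.0,  -75.0,  160.0], cis_pro_i2: true}
extended:
  - {name: IV1, canonical: [-120.0,  130.0,   55.0,   41.0], cis_pro_i2: false}
  - {name: IV2, canonical: [ -85.0,  -15.0, -125.0,   55.0], cis_pro_i2: false}
  - {name: IV3, canonical: [ -71.0,  -30.0,  -72.0,  -47.0], cis_pro_i2: false}
  - {name: IV4, canonical: [ -97.0,   -2.0, -117.0,  -11.0], cis_pro_i2: false}
obsolete:
  - {name: III,   canonical: [-60.0, -30.0, -60.0, -30.0], cis_pro_i2: false}
  - {name: "III'", canonical: [60.0,  30.0,  60.0,  30.0], cis_pro_i2: false}
  - {name: V,     canonical: [-80.0,  80.0,  80.0, -80.0], cis_pro_i2: false}
  - {name: "V'",  canonical: [ 80.0, -80.0, -80.0,  80.0], cis_pro_i2: false}
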