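# Default scenario registry.
#
# A1-A6: package-size cap of 375 mL on single-serve SSBs.
# B1-B4: reformulation of all SSBs to a reduced energy density.
# Mandatory scenarios assume 100% industry adherence; voluntary 20%.
A1:
  intervention: package_cap
  cap: 375
  mandatory: true
  adherence: 1.0
A2:
  intervention: package_cap
  cap: 375
  mandatory: true
  adherence: 1.0
  compensation: 0.25
A3:
  intervention: package_cap
  cap: 375
  mandatory: true
  adherence: 1.0
  substitution: 0.10
A4:
  intervention: package_cap
  cap: 375
  mandatory: false
  adherence: 0.2
A5:
  intervention: package_cap
  cap: 375
  mandatory: false
  adherence: 0.2
  compensation: 0.25
A6:
  intervention: package_cap
  cap: 375
  mandatory: false
  adherence: 0.2
  substitution: 0.10
B1:
  intervention: energy_reduction
  kj_reduction: 0.05
  mandatory: true
  adherence: 1.0
B2:
  intervention: energy_reduction
  kj_reduction: 0.30
  mandatory: true
  adherence: 1.0
B3:
  intervention: energy_reduction
  kj_reduction: 0.05
  mandatory: false
  adherence: 0.2
B4:
  intervention: energy_reduction
  kj_reduction: 0.30
  mandatory: false
  adherence: 0.2
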