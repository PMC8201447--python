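# All-ferric cubane with two SHORT bonds (AB, CD) -> class 2B; the ground
# channel is inverted relative to compound 1 (pair singlets along the short
# bonds).  Gaps are the CAS(44e,32o) anchor energies.
schema_version: 1
sites:
  - {label: A, local_spin: 5/2}
  - {label: B, local_spin: 5/2}
  - {label: C, local_spin: 5/2}
  - {label: D, local_spin: 5/2}
bonds:
  AB: 2B
  CD: 2B
  AC: 4B
  AD: 4B
  BC: 4B
  BD: 4B
task:
  unit: meV
  gaps:
    singlet: 54.3
    smax: 550.2
    ground_channel: 0
  seed: 1
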