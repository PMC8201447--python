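# All-ferric cubane with two LONG bonds (AB, CD) -> class 2B.
# Gaps are the CAS(20e,20o) anchor energies; the ground singlet is the
# (S_AB = S_CD = 5) channel.
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
    singlet: 87.6
    smax: 378.5
    ground_channel: 5
  seed: 1
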