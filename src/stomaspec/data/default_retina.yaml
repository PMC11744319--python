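# Placeholder 12-channel midband retina configuration.
#
# The species' measured spectral sensitivities are published only graphically,
# so these lambda-max values are NOT measured constants: they are a documented
# stand-in spanning ~420-690 nm with distal < proximal in every row and a
# long-wavelength-only row 3, reproducing the qualitative row-activation
# structure of the study system. Override any entry with your own
# lambda_max_nm or a sensitivity_file (two-column CSV) for fidelity.
channels:
  - {row: 1, tier: R8,       label: R8-1, lambda_max_nm: 315}
  - {row: 1, tier: distal,   label: R1D,  lambda_max_nm: 420}
  - {row: 1, tier: proximal, label: R1P,  lambda_max_nm: 450}
  - {row: 2, tier: R8,       label: R8-2, lambda_max_nm: 330}
  - {row: 2, tier: distal,   label: R2D,  lambda_max_nm: 460}
  - {row: 2, tier: proximal, label: R2P,  lambda_max_nm: 520}
  - {row: 3, tier: R8,       label: R8-3, lambda_max_nm: 345}
  - {row: 3, tier: distal,   label: R3D,  lambda_max_nm: 570}
  - {row: 3, tier: proximal, label: R3P,  lambda_max_nm: 690}
  - {row: 4, tier: R8,       label: R8-4, lambda_max_nm: 380}
  - {row: 4, tier: distal,   label: R4D,  lambda_max_nm: 535}
  - {row: 4, tier: proximal, label: R4P,  lambda_max_nm: 575}
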