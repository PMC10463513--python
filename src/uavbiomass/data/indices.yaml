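# Default vegetation-index registry: 31 five-band indices over the mean
# plot digital numbers B, G, R, RE, NIR. Formulas use + - * / ^ and
# parentheses. `scale_invariant: true` marks indices unchanged when all
# five DNs are multiplied by the same positive constant.
#
# This registry is data, not code: swap in your own YAML to use a
# different panel without touching the package.
- name: NDVI
  formula: (NIR - R) / (NIR + R)
  scale_invariant: true
- name: GNDVI
  formula: (NIR - G) / (NIR + G)
  scale_invariant: true
- name: NDRE
  formula: (NIR - RE) / (NIR + RE)
  scale_invariant: true
- name: GCI
  formula: NIR / G - 1
  scale_invariant: true
- name: RECI
  formula: NIR / RE - 1
  scale_invariant: true
- name: TGI
  formula: -0.5 * (190 * (R - G) - 120 * (R - B))
  scale_invariant: false
- name: CIVE
  formula: 0.441 * R - 0.811 * G + 0.385 * B + 18.78745
  scale_invariant: false
- name: SR
  formula: NIR / R
  scale_invariant: true
- name: DVI
  formula: NIR - R
  scale_invariant: false
- name: RDVI
  formula: (NIR - R) / (NIR + R) ^ 0.5
  scale_invariant: false
- name: SAVI
  formula: 1.5 * (NIR - R) / (NIR + R + 0.5)
  scale_invariant: false
- name: OSAVI
  formula: 1.16 * (NIR - R) / (NIR + R + 0.16)
  scale_invariant: false
- name: MSAVI
  formula: 0.5 * (2 * NIR + 1 - ((2 * NIR + 1) ^ 2 - 8 * (NIR - R)) ^ 0.5)
  scale_invariant: false
- name: EVI2
  formula: 2.5 * (NIR - R) / (NIR + 2.4 * R + 1)
  scale_invariant: false
- name: ExG
  formula: 2 * G - R - B
  scale_invariant: false
- name: ExR
  formula: 1.4 * R - G
  scale_invariant: false
- name: ExGR
  formula: (2 * G - R - B) - (1.4 * R - G)
  scale_invariant: false
- name: VARI
  formula: (G - R) / (G + R - B)
  scale_invariant: true
- name: NGRDI
  formula: (G - R) / (G + R)
  scale_invariant: true
- name: MGRVI
  formula: (G ^ 2 - R ^ 2) / (G ^ 2 + R ^ 2)
  scale_invariant: true
- name: RGBVI
  formula: (G ^ 2 - B * R) / (G ^ 2 + B * R)
  scale_invariant: true
- name: GLI
  formula: (2 * G - R - B) / (2 * G + R + B)
  scale_invariant: true
- name: MTCI
  formula: (NIR - RE) / (RE - R)
  scale_invariant: true
- name: NDWI
  formula: (G - NIR) / (G + NIR)
  scale_invariant: true
- name: WDRVI
  formula: (0.12 * NIR - R) / (0.12 * NIR + R)
  scale_invariant: true
- name: NLI
  formula: (NIR ^ 2 - R) / (NIR ^ 2 + R)
  scale_invariant: false
- name: MNLI
  formula: 1.5 * (NIR ^ 2 - R) / (NIR ^ 2 + R + 0.5)
  scale_invariant: false
- name: SIPI
  formula: (NIR - B) / (NIR - R)
  scale_invariant: true
- name: PSRI
  formula: (R - G) / RE
  scale_invariant: true
- name: ARVI
  formula: (NIR - (2 * R - B)) / (NIR + (2 * R - B))
  scale_invariant: true
- name: GDVI
  formula: NIR - G
  scale_invariant: false
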