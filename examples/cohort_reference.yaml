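# Cohort layout for `chromolens simulate cohort --config` — the reference
# 13-diagnosis myeloid-malignancy cohort (813 samples, 52 lesion-bearing).
# These rows are also the generator's built-in default.
rows:
  - [Polycythemia vera, 177, 3]
  - [post-PV MF, 48, 3]
  - [post-PV AML, 19, 3]
  - [Essential thrombocythemia, 91, 2]
  - [post-ET MF, 18, 1]
  - [post-ET AML, 9, 1]
  - [Primary Myelofibrosis, 85, 5]
  - [post-PMF AP, 7, 0]
  - [post-PMF AML, 16, 6]
  - [MDS (chronic phase), 61, 3]
  - [post-MDS AML, 40, 5]
  - [de novo AML, 180, 19]
  - [CML, 62, 1]
# DEL:GAIN:UPD proportions of generated lesions (default 30:11:17)
kind_mix: {DEL: 0.5172413793103449, GAIN: 0.18965517241379312, UPD: 0.29310344827586204}
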