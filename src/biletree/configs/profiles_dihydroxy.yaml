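# Default synthetic isomer profiles for the dihydroxy filtering tree.
#
# Each profile generates spectra that satisfy exactly one root-to-leaf path of
# configs/dihydroxy.yaml. Intensities are percent-of-base-peak means; the true
# in-spectrum intensity distributions of diagnostic bile acid fragment ions
# are not published, so these are fixture values, not fragmentation chemistry.
#
# The "ketone" profile deliberately models a MONOhydroxy + monoketone taurine
# amidate: its steroid core fragments carry the dihydroxy class ions
# (321.26/339.27) even though the precursor sits 2 Da below the true
# dihydroxy amidate, so the dihydroxy tree captures it (ketone aliasing).
profiles:
  - bin_label: "3,12a-(OH)2"
    hydroxylation_level: di
    conjugate: taurine
    precursor_mz: 500.3040
    class_ions: [321.26, 339.27]
    diagnostic_ions:
      - [482.2935, 100.0]
      - [201.163, 10.0]
      - [211.147, 2.0]
      - [253.195, 8.0]
    ratio_constraints:
      - [201.163, 211.147, 5.0]
  - bin_label: "7,12a-(OH)2"
    hydroxylation_level: di
    conjugate: taurine
    precursor_mz: 500.3040
    class_ions: [321.26, 339.27]
    diagnostic_ions:
      - [482.2935, 100.0]
      - [201.163, 10.0]
      - [211.147, 2.0]
      - [271.206, 8.0]
    ratio_constraints:
      - [201.163, 211.147, 5.0]
  - bin_label: "3,7-(OH)2"
    hydroxylation_level: di
    conjugate: taurine
    precursor_mz: 500.3040
    class_ions: [321.26, 339.27]
    diagnostic_ions:
      - [482.2935, 100.0]
      - [201.163, 2.0]
      - [211.147, 10.0]
      - [163.148, 8.0]
    ratio_constraints:
      - [201.163, 211.147, 0.2]
  - bin_label: "3,6-(OH)2"
    hydroxylation_level: di
    conjugate: taurine
    precursor_mz: 500.3040
    class_ions: [321.26, 339.27]
    diagnostic_ions:
      - [482.2935, 100.0]
      - [201.163, 2.0]
      - [211.147, 10.0]
      - [175.148, 8.0]
    ratio_constraints:
      - [201.163, 211.147, 0.2]
  - bin_label: "ketone"
    hydroxylation_level: mono
    conjugate: taurine
    precursor_mz: 498.2883
    class_ions: [321.26, 339.27]
    diagnostic_ions:
      - [480.2778, 100.0]
      - [161.132, 20.0]
      - [303.2319, 10.0]
      - [143.1168, 5.0]
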