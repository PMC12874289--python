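# Dihydroxy bile acid filtering tree.
#
# Branch structure: the root detects the dihydroxy steroid-core class ions
# (m/z 321.26 / 339.27); the first split separates ketone-bearing cores via
# the m/z 161.132 marker; the non-ketone branch splits on the intensity ratio
# of the 201.163 / 211.147 diagnostic pair (high ratio -> 12alpha-hydroxyl
# cores), then terminal bins confirm one extra leaf-specific marker ion.
#
# NOTE: the ratio threshold (2.0) and the leaf marker ions are placeholders
# calibrated against the package's synthetic fixtures. For real instrument
# data, replace them with thresholds calibrated on authentic standards.
tree_name: dihydroxy
root:
  name: Dihydroxy
  predicates:
    - {type: presence, target_mz: 321.26, tol_mz: 0.05, min_rel_intensity: 1.0}
    - {type: presence, target_mz: 339.27, tol_mz: 0.05, min_rel_intensity: 1.0}
  children:
    - name: ketone
      predicates:
        - {type: presence, target_mz: 161.132, tol_mz: 0.01, min_rel_intensity: 1.0}
    - name: non-ketone
      predicates:
        - {type: absence, target_mz: 161.132, tol_mz: 0.01, max_rel_intensity: 1.0}
      children:
        - name: "3,12a-(OH)2; 7,12a-(OH)2"
          predicates:
            - {type: ratio, numerator_mz: 201.163, denominator_mz: 211.147,
               comparator: ">=", threshold: 2.0, tol_mz: 0.01}
          children:
            - name: "3,12a-(OH)2"
              predicates:
                - {type: presence, target_mz: 253.195, tol_mz: 0.01, min_rel_intensity: 1.0}
            - name: "7,12a-(OH)2"
              predicates:
                - {type: presence, target_mz: 271.206, tol_mz: 0.01, min_rel_intensity: 1.0}
        - name: other-dihydroxy
          predicates:
            - {type: ratio, numerator_mz: 201.163, denominator_mz: 211.147,
               comparator: "<", threshold: 2.0, tol_mz: 0.01}
          children:
            - name: "3,7-(OH)2"
              predicates:
                - {type: presence, target_mz: 163.148, tol_mz: 0.01, min_rel_intensity: 1.0}
            - name: "3,6-(OH)2"
              predicates:
                - {type: presence, target_mz: 175.148, tol_mz: 0.01, min_rel_intensity: 1.0}
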