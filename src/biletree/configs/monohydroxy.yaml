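# Monohydroxy bile acid filtering tree -- SKELETAL TEMPLATE.
#
# The class ions follow the dihydroxy pattern shifted by one hydroxyl
# (-15.995 Da); the branch structure below the root is a minimal template
# (ketone split only) intended to be extended with calibrated queries.
tree_name: monohydroxy
root:
  name: Monohydroxy
  predicates:
    - {type: presence, target_mz: 305.25, tol_mz: 0.05, min_rel_intensity: 1.0}
    - {type: presence, target_mz: 323.26, tol_mz: 0.05, min_rel_intensity: 1.0}
  children:
    - name: mono-ketone
      predicates:
        - {type: presence, target_mz: 159.117, tol_mz: 0.01, min_rel_intensity: 1.0}
    - name: mono-non-ketone
      predicates:
        - {type: absence, target_mz: 159.117, tol_mz: 0.01, max_rel_intensity: 1.0}
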