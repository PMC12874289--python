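# Trihydroxy bile acid filtering tree -- SKELETAL TEMPLATE.
#
# The class ions follow the dihydroxy pattern shifted by one hydroxyl
# (+15.995 Da); the branch structure below the root is a minimal template
# (ketone split only) intended to be extended with calibrated queries.
tree_name: trihydroxy
root:
  name: Trihydroxy
  predicates:
    - {type: presence, target_mz: 337.25, tol_mz: 0.05, min_rel_intensity: 1.0}
    - {type: presence, target_mz: 355.26, tol_mz: 0.05, min_rel_intensity: 1.0}
  children:
    - name: tri-ketone
      predicates:
        - {type: presence, target_mz: 177.127, tol_mz: 0.01, min_rel_intensity: 1.0}
    - name: tri-non-ketone
      predicates:
        - {type: absence, target_mz: 177.127, tol_mz: 0.01, max_rel_intensity: 1.0}
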