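# Published cohort-level counts for the African (AFR) vs European (EUR)
# advanced prostate cancer study cohorts (50 patients each). These are the
# fixed inputs for recomputing the study's headline ratios and per-capita
# rates; none of the derived quantities are stored here.
cohorts:
  AFR:
    n_patients: 50
    n_snvs: 19045878
    n_rare_snvs: 4465388
    benchmark:
      clinvar: {positives: 39, negatives: 15272}
      intervar: {positives: 135, negatives: 32922}
      merged: {positives: 158, negatives: 41045}
    n_vus: 3479179
    n_pdv: 13269
    n_plof_pov: 23
    n_pov: 234
    cross_workflow_pdv_delta: -338       # PDV change under the EUR workflow
    unique4_pdv_delta: -2367             # change restricted to the 4 unique tools
  EUR:
    n_patients: 50
    n_snvs: 11811487
    n_rare_snvs: 3752976
    benchmark:
      clinvar: {positives: 99, negatives: 21356}
      intervar: {positives: 146, negatives: 93003}
      merged: {positives: 202, negatives: 103886}
    n_vus: 1818267
    n_pdv: 9427
    n_plof_pov: 9
    n_pov: 160
    cross_workflow_pdv_delta: 120
    unique4_pdv_delta: 1435
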