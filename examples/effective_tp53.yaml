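treatments:
- A
- B
- C
- D
baseline_mean_pfs: 8.0
shape_k: 1.0
effects:
- treatment: A
  signature: TP53+
  months: 10.0
control_mix: null
accrual_rate: 7.0
p_nonevaluable: 0.1
horizon_months: 60
burn_in_n: 50
thresholds:
  graduation_prob: 0.85
  futility_prob: 0.15
  min_n_signature: 20
  max_n_signature: 150
  consistency_prob: 0.5
  consistency_min_n: 1
prior:
  alpha: 10.0
  beta: 80.0
  shape_k: 1.0
signatures:
- name: All
  members:
  - 0
  - 1
  - 2
  - 3
  - 4
  - 5
  - 6
  - 7
  - 8
  - 9
  - 10
  - 11
  - 12
  - 13
  - 14
  - 15
  prevalence: 1.0
- name: TP53- and AR-
  members:
  - 0
  - 1
  - 4
  - 5
  prevalence: 0.5
- name: TP53+
  members:
  - 2
  - 3
  - 6
  - 7
  - 10
  - 11
  - 14
  - 15
  prevalence: 0.37
- name: DRD+
  members:
  - 4
  - 5
  - 6
  - 7
  - 12
  - 13
  - 14
  - 15
  prevalence: 0.19
- name: TEfus+
  members:
  - 1
  - 3
  - 5
  - 7
  - 9
  - 11
  - 13
  - 15
  prevalence: 0.32
rerandomize: false
dropout_prob: 0.1
confirmatory_alpha: 0.15
confirmatory_target_events: null
confirmatory_design_effect: 5.0
confirmatory_power: 0.8
seed: null
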