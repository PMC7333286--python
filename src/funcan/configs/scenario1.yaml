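scenario: baseline
components:
- name: Sd
  label: discriminant stimulus (heart racing)
  role: exogenous
- name: Rc
  label: catastrophizing
  role: state
- name: Re
  label: panic
  role: state
- name: Rb
  label: avoidant coping
  role: state
- name: benefits
  label: perceived benefits of avoidance
  role: state
- name: costs
  label: perceived costs of avoidance
  role: state
- name: cred_cat
  label: credibility of catastrophic interpretation
  role: state
  lower_bound: 0.0
  upper_bound: 1.0
terms:
- target: Rc
  form: modulated_linear
  sources:
  - Sd
  - cred_cat
  coefficient: catastrophizing_drive
  sign: 1
  gain: cred_cat_gain
- target: Rc
  form: constant_decay
  sources:
  - Rc
  coefficient: catastrophizing_decay
  sign: -1
- target: Re
  form: linear
  sources:
  - Rc
  coefficient: panic_drive
  sign: 1
- target: Re
  form: bilinear
  sources:
  - Re
  - Rb
  coefficient: avoidance_relief
  sign: -1
- target: Re
  form: constant_decay
  sources:
  - Re
  coefficient: panic_decay
  sign: -1
- target: Rb
  form: bilinear
  sources:
  - Re
  - Rb
  coefficient: avoidance_growth
  sign: 1
  modulators:
  - source: benefits
    gain: benefit_gain
    sign: 1
  - source: costs
    gain: cost_gain
    sign: -1
- target: Rb
  form: constant_decay
  sources:
  - Rb
  coefficient: avoidance_decay
  sign: -1
- target: benefits
  form: bilinear
  sources:
  - Re
  - Rb
  coefficient: benefit_growth
  sign: 1
- target: benefits
  form: constant_decay
  sources:
  - benefits
  coefficient: benefit_decay
  sign: -1
- target: costs
  form: linear
  sources:
  - Rb
  coefficient: cost_growth
  sign: 1
- target: costs
  form: constant_decay
  sources:
  - costs
  coefficient: cost_decay
  sign: -1
- target: cred_cat
  form: linear
  sources:
  - Rb
  coefficient: cred_cat_growth
  sign: 1
- target: cred_cat
  form: constant_decay
  sources:
  - cred_cat
  coefficient: cred_cat_decay
  sign: -1
parameters:
  catastrophizing_drive:
    value: 0.28
    provenance: calibrated
  cred_cat_gain:
    value: 8.0
    provenance: calibrated
  catastrophizing_decay:
    value: 0.8
    provenance: calibrated
  panic_drive:
    value: 1.0
    provenance: calibrated
  avoidance_relief:
    value: 0.1
    provenance: calibrated
  panic_decay:
    value: 0.8
    provenance: calibrated
  avoidance_growth:
    value: 0.55
    provenance: calibrated
  benefit_gain:
    value: 0.05
    provenance: calibrated
  cost_gain:
    value: 0.6
    provenance: calibrated
  avoidance_decay:
    value: 0.08
    provenance: calibrated
  benefit_growth:
    value: 0.3
    provenance: calibrated
  benefit_decay:
    value: 2.0
    provenance: calibrated
  cost_growth:
    value: 0.36
    provenance: calibrated
  cost_decay:
    value: 0.35
    provenance: calibrated
  cred_cat_growth:
    value: 1.2
    provenance: calibrated
  cred_cat_decay:
    value: 0.4
    provenance: calibrated
  cred_competition:
    value: 1.2
    provenance: calibrated
  cred_fun_growth:
    value: 0.9
    provenance: calibrated
  cred_fun_decay:
    value: 0.9
    provenance: calibrated
  reappraisal_inhibition:
    value: 2.6
    provenance: calibrated
initial_values:
  Rc: 0.0
  Re: 0.0
  Rb: 0.01
  benefits: 0.0
  costs: 0.0
  cred_cat: 0.4
forcing:
  Sd:
    kind: constant
    level: 1.0
nonneg_clip: true
intervention:
  scenario_name: baseline
  exposure:
    active: false
    onset: 12.5
    clamp_value: 0.0
    mode: clamp
  reappraisal:
    active: false
    onset: 12.5
    input_level: 1.0
simulation:
  t_max: 50.0
  dt_out: 0.05
  solver: rk_adaptive
  tol: 1.0e-08
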