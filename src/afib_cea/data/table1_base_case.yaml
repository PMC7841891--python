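# Base-case parameter set for the four-strategy oral-anticoagulation model
# in non-valvular atrial fibrillation: annual event probabilities, outcome
# severity splits, costs (US$), health-state utilities, and run settings.
# Scalars may be written either as a bare number (fixed parameter) or as
# {value: x, range: [low, high]} when a plausible range is available for
# sensitivity analysis.
strategies:
  warfarin:
    p_is: {value: 0.040, range: [0.023, 0.0453]}
    p_ich: {value: 0.0121, range: [0.0057, 0.0294]}
    p_ech: {value: 0.027}
    p_mi: {value: 0.0098}
    p_death: {value: 0.026, range: [0.0258, 0.0261]}
  rivaroxaban:
    p_is: {value: 0.0193}
    p_ich: {value: 0.00257, range: [0.0021, 0.0033]}
    p_ech: {value: 0.030}
    p_mi: {value: 0.0098}
    p_death: {value: 0.0164}
  dabigatran110:
    p_is: {value: 0.0183, range: [0.0167, 0.0189]}
    p_ich: {value: 0.00359, range: [0.0028, 0.0039]}
    p_ech: {value: 0.007}
    p_mi: {value: 0.0072}
    p_death: {value: 0.0333}
  dabigatran150:
    p_is: {value: 0.0137}
    p_ich: {value: 0.0027}
    p_ech: {value: 0.0217}
    p_mi: {value: 0.0074}
    p_death: {value: 0.0219}
event_outcomes:
  ischemic_stroke:
    light: {value: 0.091, range: [0.091, 0.133]}
    moderate: {value: 0.425, range: [0.348, 0.425]}
    severe: {value: 0.402, range: [0.402, 0.417]}
    die: {value: 0.082, range: [0.082, 0.101]}
  intracranial_hemorrhage:
    light: {value: 0.12}
    moderate: {value: 0.27}
    severe: {value: 0.43}
    die: {value: 0.18}
  extracranial_hemorrhage:
    die: {value: 0.0147, range: [0.010, 0.040]}
  myocardial_infarction:
    die: {value: 0.166, range: [0.158, 0.174]}
costs:
  annual_treatment:
    warfarin: {value: 253.30, range: [239.70, 280.51]}
    rivaroxaban: {value: 1787.00, range: [1435.86, 2844.52]}
    dabigatran110: {value: 1718.21, range: [1711.17, 2206.93]}
    dabigatran150: {value: 2206.93, range: [1711.17, 2206.93]}
  event:
    IS: {value: 1351.20, range: [851.36, 2681.69]}
    ICH: {value: 2605.43, range: [1935.86, 3862.05]}
    ECH: {value: 1216.72, range: [867.23, 2516.68]}
    MI: {value: 3875.18, range: [1805.02, 5529.89]}
utilities:
  u_min: {value: 0.76, range: [0.70, 0.90]}
  u_mod: {value: 0.39, range: [0.10, 0.50]}
  u_sev: {value: 0.16, range: [0.00, 0.32]}
  m_ich: {value: 0.80, range: [0.79, 0.84]}
  m_ech: {value: 0.80, range: [0.79, 0.84]}
  m_mi: {value: 0.84, range: [0.67, 0.96]}
run:
  horizon_cycles: 30
  discount_rate: 0.03
  wtp: 28445.64
  discount_first_cycle: false
  events_from_moderate: false
  psa_draws: 1000
  seed: 12345
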