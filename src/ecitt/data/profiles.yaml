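# Simulator age-profile library.
#
# Accuracy targets are population means: the cohort simulator solves for the
# logit-scale centre so that the *group mean* accuracy matches these values
# despite between-subject heterogeneity.  Toddler RT parameters (ex-Gaussian
# mu/sigma/tau, inhibitory cost) are plausible values for unhurried toddler
# touch responses; adult-version RT parameters follow the printed condition
# medians (~581 ms prepotent, ~669 ms inhibitory overall) and group RTD values.
# Times in ms; probabilities in [0, 1].

toddler_18m:            # longitudinal visit 1: inhibitory ~63%, prepotent >90%
  age_months: 18
  p_correct_prepotent: 0.92
  p_correct_inhibitory: 0.63
  rt_prepotent: {mu: 1000.0, sigma: 220.0, tau: 420.0}
  inhibitory_cost_ms: 250.0
  p_anticipation: 0.03
  p_distraction: 0.03
  p_invalid: 0.04
  between_subject_sd: 0.9

toddler_21m:            # longitudinal visit 2
  age_months: 21
  p_correct_prepotent: 0.93
  p_correct_inhibitory: 0.73
  rt_prepotent: {mu: 960.0, sigma: 210.0, tau: 400.0}
  inhibitory_cost_ms: 240.0
  p_anticipation: 0.03
  p_distraction: 0.03
  p_invalid: 0.04
  between_subject_sd: 0.9

toddler_24m:            # longitudinal visit 3: inhibitory ~89%
  age_months: 24
  p_correct_prepotent: 0.93
  p_correct_inhibitory: 0.89
  rt_prepotent: {mu: 930.0, sigma: 200.0, tau: 380.0}
  inhibitory_cost_ms: 230.0
  p_anticipation: 0.03
  p_distraction: 0.02
  p_invalid: 0.04
  between_subject_sd: 0.8

toddler_24m_xs:         # cross-sectional 24-month group: inhibitory ~74%
  age_months: 24
  p_correct_prepotent: 0.93
  p_correct_inhibitory: 0.74
  rt_prepotent: {mu: 930.0, sigma: 200.0, tau: 380.0}
  inhibitory_cost_ms: 230.0
  p_anticipation: 0.03
  p_distraction: 0.02
  p_invalid: 0.04
  between_subject_sd: 0.9

toddler_30m:            # cross-sectional 30-month group: inhibitory ~92%
  age_months: 30
  p_correct_prepotent: 0.97
  p_correct_inhibitory: 0.92
  rt_prepotent: {mu: 880.0, sigma: 190.0, tau: 350.0}
  inhibitory_cost_ms: 220.0
  p_anticipation: 0.02
  p_distraction: 0.02
  p_invalid: 0.03
  between_subject_sd: 0.8

child_8y:               # fast-paced version, mid-primary school (AccD ~5.6, RTD ~102)
  age_months: 95
  p_correct_prepotent: 0.998
  p_correct_inhibitory: 0.944
  rt_prepotent: {mu: 520.0, sigma: 70.0, tau: 150.0}
  inhibitory_cost_ms: 102.0
  p_anticipation: 0.01
  p_distraction: 0.0
  p_invalid: 0.0
  between_subject_sd: 0.6

young_adult:            # ceiling accuracy (AccD ~0, RTD ~57)
  age_months: 275
  p_correct_prepotent: 0.998
  p_correct_inhibitory: 0.999
  rt_prepotent: {mu: 390.0, sigma: 45.0, tau: 95.0}
  inhibitory_cost_ms: 57.0
  p_anticipation: 0.005
  p_distraction: 0.0
  p_invalid: 0.0
  between_subject_sd: 0.3

older_adult:            # late-adult decline (AccD ~1.7, RTD ~95)
  age_months: 836
  p_correct_prepotent: 0.998
  p_correct_inhibitory: 0.983
  rt_prepotent: {mu: 540.0, sigma: 60.0, tau: 120.0}
  inhibitory_cost_ms: 95.0
  p_anticipation: 0.005
  p_distraction: 0.0
  p_invalid: 0.0
  between_subject_sd: 0.4
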