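# Base-case parameter registry for the pediatric Ph+ ALL TKI model.
# One record per model quantity: base value, plausible range (null where the
# source gives none; default one-way bounds are then generated at load time:
# +/-10% for transition probabilities, +/-20% for costs and utilities),
# sampling family for the probabilistic sensitivity analysis, and role.
#
# Units: probabilities and utilities are dimensionless in [0, 1]; costs are
# 2019 CNY (per year for recurring state costs, one-off for transplantation);
# durations are years.

settings:
  horizon_years: 10
  discount_rate: 0.05
  discount_rate_low: 0.03
  discount_rate_high: 0.08
  wtp: 70892.0
  body_surface_area: 0.8   # m^2, informational (7-year-old reference patient)

parameters:
  # --- decision-tree transition probabilities (retrospective cohort) ---
  - {id: im_noncr_induction,      base: 1.0,    low: null,   high: null,   family: beta,  role: transition}
  - {id: im_noncr_intensive,      base: 0.5,    low: null,   high: null,   family: beta,  role: transition}
  - {id: da_noncr_induction,      base: 0.833,  low: null,   high: null,   family: beta,  role: transition}
  - {id: da_cr_cr_intensive,      base: 1.0,    low: null,   high: null,   family: beta,  role: transition}
  - {id: da_cr_noncr_intensive,   base: 0.875,  low: null,   high: null,   family: beta,  role: transition}

  # --- annual Markov transition probabilities ---
  - {id: im_relapse_maint,        base: 0.1000, low: 0.0415, high: 0.1729, family: beta,  role: transition}
  - {id: im_death_cr_maint,       base: 0.0879, low: 0.0364, high: 0.1365, family: beta,  role: transition}
  - {id: da_relapse_maint,        base: 0.0537, low: 0.0107, high: 0.1035, family: beta,  role: transition}
  - {id: da_death_cr_maint,       base: 0.0304, low: 0.0099, high: 0.0504, family: beta,  role: transition}
  - {id: death_noncr_maint,       base: 0.6,    low: 0.54,   high: 0.66,   family: beta,  role: transition}
  - {id: p_transplant,            base: 0.1,    low: 0.09,   high: 0.11,   family: beta,  role: transition}
  - {id: p_transplant_success,    base: 0.4,    low: 0.3,    high: 0.5,    family: beta,  role: transition}
  - {id: p_relapse_post_hsct,     base: 0.0582, low: 0.0354, high: 0.0806, family: beta,  role: transition}
  - {id: p_death_cr_post_hsct,    base: 0.23,   low: 0.21,   high: 0.25,   family: beta,  role: transition}
  - {id: p_death_fail_post_hsct,  base: 0.57,   low: 0.49,   high: 0.64,   family: beta,  role: transition}

  # --- costs, 2019 CNY ---
  - {id: im_drug_cost,            base: 104857.2,  low: 83885.76,  high: 125828.64, family: gamma, role: cost}
  - {id: im_cost_induction,       base: 71019.18,  low: 10168.61,  high: 170406.88, family: gamma, role: cost}
  - {id: im_cost_intensive,       base: 266871.23, low: 120615.16, high: 398733.09, family: gamma, role: cost}
  - {id: da_drug_cost,            base: 51100.0,   low: 40880.0,   high: 61320.0,   family: gamma, role: cost}
  - {id: da_cost_induction,       base: 91338.95,  low: 26639.48,  high: 176128.92, family: gamma, role: cost}
  - {id: da_cost_intensive,       base: 208152.13, low: 141714.97, high: 274986.24, family: gamma, role: cost}
  - {id: cost_cr_maint,           base: 57500.0,   low: 46000.0,   high: 69000.0,   family: gamma, role: cost}
  - {id: cost_noncr_maint,        base: 375953.99, low: 244489.6,  high: 531322.71, family: gamma, role: cost}
  - {id: cost_transplant,         base: 250000.0,  low: 200000.0,  high: 300000.0,  family: gamma, role: cost}
  - {id: cost_cr_post_hsct,       base: 399953.99, low: 268489.6,  high: 555322.71, family: gamma, role: cost}
  - {id: cost_fail_post_hsct,     base: 1000000.0, low: 800000.0,  high: 1200000.0, family: gamma, role: cost}

  # --- phase durations, years (fixed) ---
  - {id: im_dur_induction,        base: 0.0795, low: null, high: null, family: fixed, role: duration}
  - {id: im_dur_intensive,        base: 0.8164, low: null, high: null, family: fixed, role: duration}
  - {id: da_dur_induction,        base: 0.0849, low: null, high: null, family: fixed, role: duration}
  - {id: da_dur_intensive,        base: 0.6822, low: null, high: null, family: fixed, role: duration}

  # --- health-state utilities ---
  - {id: u_cr,                    base: 0.88, low: 0.82, high: 0.93, family: beta, role: utility}
  - {id: u_noncr,                 base: 0.76, low: 0.70, high: 0.82, family: beta, role: utility}
  - {id: u_hsct_cr_early,         base: 0.80, low: 0.74, high: 0.86, family: beta, role: utility}
  - {id: u_hsct_cr_late,          base: 0.86, low: 0.80, high: 0.91, family: beta, role: utility}
  - {id: u_hsct_fail,             base: 0.73, low: 0.67, high: 0.79, family: beta, role: utility}
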