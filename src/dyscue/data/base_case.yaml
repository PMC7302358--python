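# Base-case configuration for the post-stroke dysphagia cost-utility models.
# All values are published main-text figures except the fields listed under
# dynamic.assumed, which are reverse-engineered placeholders for inputs that
# were only reported in supplementary material (see docs/methods.md).

meta:
  currency: PLN                 # public payer (NFZ) perspective; EUR 1 ~ 4.5 PLN
  threshold: 147024.0           # Polish cost-effectiveness threshold, PLN/QALY
  seed: 20200617

static:
  dysphagia_weeks: 8            # fixed dysphagia course
  ap_weeks: 2                   # aspiration-pneumonia episode duration
  p_ap_aspirators: {events: 10, n: 82}      # 12.2% observed in aspirators
  p_ap_non_aspirators: {events: 1, n: 57}   # 1.75% observed in non-aspirators
  u_aspiration: 0.15
  u_no_aspiration: 0.37         # 0.15 + 0.22 increment for removed aspiration
  du_ap: 0.13                   # pneumonia utility decrement
  cost_ap_episode: 1924.0       # PLN per episode (DRG tariff)
  nutilis_daily_g: 37.96        # weighted mean daily thickener consumption
  tin_g: 175.0
  tin_price: 77.05              # PLN per tin, payer share

dynamic:
  baseline_ap_ir_weekly: 0.004036   # pooled weekly pneumonia incidence, no dysphagia
  rr_ap_no_asp: 2.77                # pneumonia RR, dysphagia without aspiration
  rr_ap_asp: 8.27                   # pneumonia RR, dysphagia with aspiration
  rr_death_ap: 2.99                 # death RR during a pneumonia episode
  deterioration_weekly: 0.0011      # weekly onset of aspiration (treatment failure)
  u_no_dysphagia: 0.49              # PLACEHOLDER - supplement-only value
  u_dys_asp: 0.15
  u_dys_no_asp: 0.37
  du_ap: 0.13
  cost_ap_episode: 1924.0
  cost_monitoring_visit: 186.0
  monitoring_weeks: [1, 4, 12, 26, 39, 52]
  horizon_weeks: 52
  mortality:
    source: piecewise
    p30_weekly: 0.046           # weeks 1-4 (first 30 days)
    p90_weekly: 0.0096          # weeks 5-13 (days 31-90)
    rest_weekly: 0.0024         # weeks 14-52
  resolution_anchors:           # PLACEHOLDER - synthetic prevalence trajectory
    - [0, 1.0]
    - [7, 0.53]
    - [28, 0.27]
    - [180, 0.07]
  assumed: [u_no_dysphagia, resolution_anchors]

psa:
  n_iterations: 10000
  distributions:
    static.u_aspiration: {dist: beta, mean: 0.15, ci: [0.135, 0.165]}
    static.u_no_aspiration: {dist: beta, mean: 0.37, ci: [0.32, 0.42]}
    static.du_ap: {dist: beta, mean: 0.13, ci: [0.10, 0.15]}
    static.p_ap_aspirators: {dist: beta_counts, events: 10, n: 82}
    static.p_ap_non_aspirators: {dist: beta_counts, events: 1, n: 57}
    static.cost_ap_episode: {dist: gamma, mean: 1924.0, sd_frac: 0.2}

ranges:
  - {path: static.u_aspiration, low: 0.135, high: 0.165, source: stated}
  - {path: static.u_no_aspiration, low: 0.32, high: 0.42, source: stated}
  - {path: static.du_ap, low: 0.10, high: 0.15, source: stated}
  - {path: static.p_ap_aspirators, source: binomial_ci, events: 10, n: 82}
  - {path: static.p_ap_non_aspirators, source: binomial_ci, events: 1, n: 57}
  - {path: dynamic.rr_ap_no_asp, low: 1.03, high: 7.42, source: ci}
  - {path: dynamic.rr_ap_asp, low: 3.28, high: 20.85, source: ci}
  - {path: dynamic.rr_death_ap, low: 2.44, high: 3.66, source: ci}
  - {path: dynamic.baseline_ap_ir_weekly, low: 0.0, high: 0.0256, source: ci}
  - {path: dynamic.u_dys_asp, low: 0.135, high: 0.165, source: stated}
  - {path: dynamic.du_ap, low: 0.10, high: 0.15, source: stated}
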