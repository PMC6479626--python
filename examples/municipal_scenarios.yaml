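# Municipal disposal-site operating scenarios: the unrefurbished baseline
# (per-visit fee, guard present 65% of days) against the refurbished site
# (fence, guard always present) under per-visit and monthly-permit tariffs.
#
#   fs-abm municipal --config examples/municipal_scenarios.yaml --seed 1 --out out/

municipal:
  n_ticks: 2000

grid:
  model: municipal
  repeats: 250
  base_seed: 1
  scenarios:
    baseline: {}
    high_fee: {dumping_fee: 15000}
    high_fine: {fine_company: 15000}
    refurb_per_visit: {refurbished: true, p_guard_present: 1.0}
    refurb_permit_100k:
      refurbished: true
      p_guard_present: 1.0
      tariff_mode: monthly_permit
      permit_fee: 100000
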