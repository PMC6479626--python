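# The four financial scenarios of the Skyloo adoption study:
# start-up capital {MK10M, MK2M} x monthly repayment {MK9320, MK7000}.
#
#   fs-abm skyloo --config examples/skyloo_scenarios.yaml --seed 1 --out out/
#
# Parameters omitted here keep their library defaults (the study values).

environment:
  n_households: 3026

network:
  k: 4
  p_rewire: 0.2

skyloo:
  n_ticks: 2000

grid:
  model: skyloo
  repeats: 100        # the study used 1000; raise for publication-grade bands
  base_seed: 1
  scenarios:
    startup10M_repay9320: {startup_capital: 10000000, monthly_repayment: 9320}
    startup10M_repay7000: {startup_capital: 10000000, monthly_repayment: 7000}
    startup2M_repay9320: {startup_capital: 2000000, monthly_repayment: 9320}
    startup2M_repay7000: {startup_capital: 2000000, monthly_repayment: 7000}
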