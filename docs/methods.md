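# Methods

This note documents the two simulators, the synthetic data they run on,
the parameter choices that matter, and the model's known limitations.
Every number quoted here is computed by the test suite or by
`scripts/acceptance.py`.

## Synthetic household environment

The Skyloo model runs on a generated population that stands in for a
survey- and GIS-derived one.  Defaults (all configurable in
`EnvironmentConfig`):

| quantity | default | notes |
|---|---|---|
| households | 3026 | |
| owner : tenant | 50 : 50 | Bernoulli per household |
| household size | round(N(6, 2)), min 1 | persons |
| monthly income | lognormal, mean = SD = MK44,000 | see below |
| already has a Skyloo | 0.3% | pre-installed, no loan; seeds word of mouth |
| open to FS reuse | 64/148 ≈ 0.432 | hard gate on adoption |
| map | 1000 × 1000 units, uniform locations | abstract units |
| flood strip | width 150 along one edge | proximity = clipped normalised distance |
| plot size | Uniform(100, 2000) | area units |

**Income family.**  With a coefficient of variation of 1, a normal
distribution would put ~16% of households at negative income; we use a
lognormal moment-matched to the stated mean and SD
(σ² = ln(1 + (sd/mean)²) = ln 2, μ = ln mean − σ²/2), which is
non-negative, right-skewed like urban income data, and reproduces both
moments exactly (verified to 1%/3% on 10⁵ pooled draws; implied median
≈ MK31,100).

**Receptivity multipliers.**  Flood exposure and plot size scale a
household's chance of becoming interested when exposed: linearly from 1.5
(inside the flood strip / smallest plot — pit latrines flood or there is
no room to dig new pits) down to 0.75 (far from flooding / largest plot).
Tenants carry an additional 0.8 factor.  The direction of these scales is
empirically grounded; their linear shape and endpoints are modelling
choices and are configurable.

## Contact network

Households sit on a ring ordered by polar angle about the map centroid
(so ring neighbours are geographically close), are linked to their four
nearest ring neighbours, and each lattice edge is rewired with probability
0.2 — the Watts–Strogatz construction, with the home endpoint kept fixed
and the new target drawn uniformly among non-self, non-duplicate nodes.
Edge count is therefore exactly n·k/2 (6052 at full size).  The k = 4
ring lattice has clustering coefficient 0.5; rewiring at 0.2 shortens mean
path length substantially while keeping clustering well above a fully
random graph, which is the regime the diffusion assumptions target.  Each
Monte-Carlo repeat regenerates the network: its randomness is a material
part of run-to-run variance.

## Skyloo adoption model

One tick = one day; 2000 ticks ≈ 5.5 years; a month is 30 ticks.

* **Marketing** (tick 0): the business approaches 300 randomly chosen
  households; each naive contact becomes aware with probability
  0.25 × its receptivity multiplier.
* **Word of mouth** (daily): every *informed* household — one with a
  Skyloo installed or on the build waiting list — exposes each naive
  linked neighbour with probability 0.03 × the neighbour's multiplier
  (independent per edge per day).  Aware households that declined do not
  propagate further, and un-adopters stop propagating.
* **Adoption** is decided once, when a household becomes aware: it adopts
  iff it is open to FS reuse **and** the monthly repayment is at most 22%
  of its monthly income.  Adopters join a FIFO waiting list.
* **Building**: at most one build per day, requiring cash ≥ MK200,000;
  each build opens a loan (principal MK200,000) repaid at the scenario's
  fixed instalment starting at the next month boundary.  Waiting more
  than 30 days ⇒ permanent un-adoption.
* **Monthly settlement**: each active loan accrues 1% interest, then pays
  min(instalment, balance); the business pays MK85,000 operating costs
  from month 1 regardless of sales.  The cash ledger identity
  `cash = startup + repayments − build costs − operating costs` holds
  exactly at every tick and is asserted per tick in the tests.

**Loan arithmetic.**  The standard two-year instalment is the annuity-due
payment P·r / [(1+r)(1 − (1+r)⁻ⁿ)] rounded to MK10 — MK9320 for
MK200,000 at 1%/month over 24 months.  In-simulation repayment follows
the balance recursion B ← B(1+r) − payment with a truncated final
payment: 25 payments at MK9320, 34 at MK7000.

**Financing ceiling (why adoption saturates low).**  The enterprise's only
margin is loan interest: a completed MK200,000 loan returns ≈ MK23,700
over cost, while operations cost MK85,000 every month (MK5.61M over a
run).  Greedy building spends the MK10M float within ~50 builds, after
which building is throttled to roughly the monthly loan surplus
(≈1–2 builds/month), and the 30-day un-adoption rule discards most of the
demand that arrives during the throttled phase.  Consequently mean
installations at tick 2000 sit near 60 (MK7000 repayment) and mean final
cash near MK5–6M in the MK10M scenarios; with MK2M start-up the business
builds ~10 units and operating costs push cash negative.  This is a
structural property of the printed cost/price/interest parameters, not of
the diffusion assumptions: variants with universal word-of-mouth or
wholly patient demand move final installations only between ~60 and the
pure finance ceiling (~220–300), and the latter only by consuming
essentially all cash.  The scenario *orderings* are robust and tested:
more start-up capital and cheaper repayment never reduce mean adoption,
and more capital never reduces mean final cash (paired seeds).

## Municipal disposal-site model

One tick = one day; 2000 ticks; defaults in `MunicipalConfig`:

| quantity | default | tested range |
|---|---|---|
| per-visit dumping fee | MK9,000 | 6,000–15,000 |
| monthly permit | MK70,000 (mode off) | 40,000–100,000 |
| sludge value per 50 kg bag | MK5,000 | 500–10,000 |
| bribe to guard | MK3,000 | ×1–8 |
| fine: company / farmer | MK2,000 / MK20,000 | 2,000–15,000 / — |
| guard present | 65% of days | 100% when refurbished |
| companies / farmers | 5 / 15 | |
| load volume / job probability | 3 m³ / 0.2 per day | |
| farmer attempt probability | 0.1 per day | |
| compost maturation | 180 days, 50% volume yield, 0.05 m³ bags | |
| learning multiplier | 10⁻⁶ | |
| initial p(legal) / p(steal) / p(corrupt) | 0.01 / 0.5 / 0.5 | |

Fleet size, load volume and job probability are calibrated so that the
total sludge stream is ≈1 load/day ≈ 6,000 m³ over a run; the low initial
legal-disposal propensity reflects the observed near-total avoidance of
the site.  Bag mass 50 kg is mapped to 0.05 m³ (density ≈ 1000 kg/m³) and
the 50% compost yield is assumed; both are configurable.

**Event logic.**  Each day the guard's presence and stance
(enforce/corrupt) are drawn once.  A company with a load goes legal with
probability p_legal: a valid monthly permit makes the visit free;
otherwise an enforcing guard collects the fee for the council, a corrupt
one pockets the bribe, an absent one collects nothing.  Illegal dumps are
caught with probability 0.1 and fined to the council.  A farmer attempt
is theft with probability p_steal: it succeeds when the guard is absent
or bribed, an enforcing guard issues the MK20,000 fine, and at the
refurbished site the fence voids every theft (a corrupt guard still keeps
the bribe — refurbishment *raises* bribe income while cutting stolen
volume to exactly zero).  Buying transfers one matured bag at the sludge
value (a payoff wash for the farmer).  Theft draws raw sludge from the
site inventory, oldest first; if none is on site the attempt yields
nothing.

**Learning.**  After each interaction the actor compares its realized
payoff with the counterfactual payoff of the alternative action under the
same day's circumstances (fresh draw for an unresolved catch), and its
propensity moves by 10⁻⁶ × the difference, clamped to [0, 1].  Because
the company fine (MK2,000) is below every legal-disposal cost, p_legal is
driven toward 0 under all per-visit tariffs in the tested ranges — the
illegal volume lands near 6,000 m³ and varies by far less than 10% across
the fee and fine ranges.  Under a monthly permit the marginal visit is
free, so p_legal drifts slightly *up* and the refurbished-permit scenario
maximises both legal volume (≈230 m³ mean, comfortably above the tens of
m³ of the per-visit scenarios) and council revenue (permits plus compost
sales, with a visible cash step at each 180-day bulk sale).

**Conservation laws** (asserted exactly per run): council cash net of
bulk compost sales equals everything companies and farmers paid in minus
guard bribes; and arrivals = raw on site + matured volume + stolen.

## Monte-Carlo protocol and numerics

Repeat r of every scenario runs with seed `base_seed + r` from a single
`numpy` PCG64 generator per run, so scenario comparisons are paired and
any grid is reproducible byte-for-byte from its JSON manifest.  Reference
repeat counts are 1000 (Skyloo) and 250 (municipal); the shipped tests
and the acceptance script use 100 / 250, which put the Monte-Carlo
standard error of every asserted mean at least an order of magnitude
inside its tolerance.  Monies are floats; ledger identities are asserted
to 10⁻⁶ MK.  Loan balances below 10⁻⁹ close; degenerate configurations
(zero diffusion, zero agents, zero multiplier) reduce to closed forms
that the property tests check (e.g. no-diffusion cash =
startup − 66 × 85,000; frozen-propensity illegal volume =
ticks × companies × 0.2 × 0.99 × 3 m³ within 3 standard errors).

## What the synthetic environment does and does not show

The generator reproduces marginal moments and proportions (income, size,
tenure, openness) and a simple flood-strip geometry, but real populations
have spatially correlated income and flood exposure, clustered tenancy,
and GIS-shaped plot distributions; passing tests therefore demonstrate
the mechanics and orderings of the models, not predictions for any
specific city.  Within-model limitations: no re-adoption after
un-adoption, one-off marketing, static prices over 5.5 years, no
compost-demand model beyond a fixed price, no health-risk or
environmental-quality modelling (disposal volumes are the proxy), and a
single guard whose stance is drawn daily rather than strategically.
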