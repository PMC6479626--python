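"""Daily-step game-theoretic ABM of the municipal faecal-sludge site.

Agents and choices:

* **Vacuum-tanker companies** (default 5) get an emptying job on a given
  day with probability 0.2 each, producing a 3 m3 load.  With adaptive
  probability ``p_legal`` they haul it to the municipal site (paying the
  per-visit fee to the council, a bribe to a corrupt guard, or nothing if
  the guard is away or a monthly permit covers the visit); otherwise they
  dump it illegally and risk a fine.
* **The site guard** is present each day with probability 0.65 at the
  unrefurbished site (1.0 after refurbishment adds a shelter) and each day
  either enforces fees/fines for the council or takes bribes for himself,
  with an adaptive enforcement propensity.
* **Farmers** (default 15) want sludge for their fields: each day with
  probability 0.1 a farmer either buys a 50 kg bag of matured compost from
  the council or tries to steal raw sludge from the site, succeeding when
  the guard is away or bribed.  Refurbishment adds a fence: theft then
  yields nothing in any case (though a corrupt guard still pockets the
  bribe, and an enforcing one still issues the MK20,000 fine).

All propensities adapt by a payoff-learning rule: after each interaction
the probability of the action taken moves by ``multiplier`` (default 1e-6)
times the difference between the realized payoff and the counterfactual
payoff of the alternative action under the same circumstances, clamped to
[0, 1].  The multiplier is small, modelling slow behavioural change.

Raw sludge legally disposed at the site matures for six months (180
ticks), then converts to saleable 50 kg compost bags at a 50% volume
yield; matured stock is sold off for the council at each six-month
boundary, and farmers buy single bags in between.  Cumulative legally
disposed / illegally dumped / stolen volumes are the model's proxy for
environmental outcomes.
"""

from __future__ import annotations

import math
from collections import deque
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import ConfigError

__all__ = [
    "MunicipalConfig",
    "BehaviourProbability",
    "CompanyState",
    "GuardState",
    "FarmerState",
    "SiteState",
    "adjust_probability",
    "company_disposal_event",
    "farmer_acquisition_event",
    "renew_permit",
    "compost_step",
    "run_municipal",
    "MunicipalRunResult",
]

PER_VISIT = "per_visit"
MONTHLY_PERMIT = "monthly_permit"


@dataclass
class MunicipalConfig:
    """Parameters of one municipal-site scenario (monies in MK, volumes m3)."""

    dumping_fee: float = 9_000.0          # per-visit charge, tested 6000-15000
    permit_fee: float = 70_000.0          # monthly permit, tested 40000-100000
    tariff_mode: str = PER_VISIT
    sludge_value: float = 5_000.0         # per 50 kg bag, tested 500-10000
    bribe: float = 3_000.0                # paid to the guard, multipliers 1-8
    fine_company: float = 2_000.0         # illegal dumping, tested 2000-15000
    fine_farmer: float = 20_000.0
    p_guard_present: float = 0.65         # 1.0 at the refurbished site
    refurbished: bool = False             # fence present iff true
    compost_lag: int = 180                # six months
    n_companies: int = 5
    n_farmers: int = 15
    load_volume: float = 3.0
    p_company_job: float = 0.2
    p_farmer_attempt: float = 0.1
    bag_volume: float = 0.05              # 50 kg at ~1000 kg/m3
    compost_yield: float = 0.5
    p_catch_illegal_dump: float = 0.1
    p_company_legal_init: float = 0.01
    p_farmer_steal_init: float = 0.5
    p_guard_corrupt_init: float = 0.5
    multiplier: float = 1e-6
    n_ticks: int = 2000
    month_length: int = 30

    def validate(self) -> None:
        if self.tariff_mode not in (PER_VISIT, MONTHLY_PERMIT):
            raise ConfigError("tariff_mode", "must be 'per_visit' or 'monthly_permit'")
        for name in ("p_guard_present", "p_company_job", "p_farmer_attempt",
                     "p_catch_illegal_dump", "p_company_legal_init",
                     "p_farmer_steal_init", "p_guard_corrupt_init"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ConfigError(name, "must be a probability in [0, 1]")
        for name in ("dumping_fee", "permit_fee", "sludge_value", "bribe",
                     "fine_company", "fine_farmer", "load_volume", "bag_volume",
                     "compost_yield", "multiplier"):
            if getattr(self, name) < 0:
                raise ConfigError(name, "must be non-negative")
        for name in ("compost_lag", "n_companies", "n_farmers", "n_ticks", "month_length"):
            if getattr(self, name) < 1:
                raise ConfigError(name, "must be a positive count")
        if self.bag_volume == 0:
            raise ConfigError("bag_volume", "must be positive")


@dataclass(frozen=True)
class BehaviourProbability:
    """Adaptive propensity for one focal action."""

    p: float
    multiplier: float = 1e-6


def adjust_probability(
    bp: BehaviourProbability, actual_payoff: float, potential_payoff: float
) -> BehaviourProbability:
    """Move the propensity toward the better-paying action.

    p' = p + multiplier * (actual - potential), clamped to [0, 1]: the
    probability of the action taken falls when the forgone alternative
    would have paid more, rises when it paid less, and is unchanged on a
    tie.
    """
    p = bp.p + bp.multiplier * (actual_payoff - potential_payoff)
    return replace(bp, p=min(1.0, max(0.0, p)))


@dataclass
class CompanyState:
    """A private emptying company: legal-disposal propensity and cash ledger."""

    p_legal: BehaviourProbability
    fees_paid: float = 0.0
    bribes_paid: float = 0.0
    fines_paid: float = 0.0
    permits_paid: float = 0.0
    permit_valid_until: int | None = None

    @property
    def total_outflow(self) -> float:
        return self.fees_paid + self.bribes_paid + self.fines_paid + self.permits_paid

    def permit_valid(self, tick: int) -> bool:
        return self.permit_valid_until is not None and tick <= self.permit_valid_until


@dataclass
class GuardState:
    """The site guard; bribe income is his own, fees go to the council."""

    p_enforce: BehaviourProbability
    present_today: bool = False
    corrupt_today: bool = False
    bribe_income: float = 0.0
    fees_collected_for_council: float = 0.0


@dataclass
class FarmerState:
    """A farmer acquiring sludge: steal-vs-buy propensity and ledgers."""

    p_steal: BehaviourProbability
    value_gained: float = 0.0
    purchases_paid: float = 0.0
    bribes_paid: float = 0.0
    fines_paid: float = 0.0

    @property
    def total_outflow(self) -> float:
        return self.purchases_paid + self.bribes_paid + self.fines_paid


@dataclass
class SiteState:
    """Site ledgers: volumes, maturing inventory and council cash."""

    raw_parcels: deque = field(default_factory=deque)  # [tick arrived, m3 remaining]
    raw_volume: float = 0.0
    compost_bags: int = 0
    legally_disposed: float = 0.0
    illegally_dumped: float = 0.0
    stolen: float = 0.0
    converted_volume: float = 0.0
    bags_sold_bulk: int = 0
    bags_sold_farmers: int = 0
    council_cash: float = 0.0

    def receive_load(self, tick: int, volume: float) -> None:
        self.raw_parcels.append([tick, volume])
        self.raw_volume += volume
        self.legally_disposed += volume

    def remove_raw(self, volume: float) -> float:
        """Take up to ``volume`` m3 of raw sludge, oldest first."""
        taken = 0.0
        while self.raw_parcels and taken < volume - 1e-12:
            parcel = self.raw_parcels[0]
            grab = min(parcel[1], volume - taken)
            parcel[1] -= grab
            taken += grab
            if parcel[1] <= 1e-12:
                self.raw_parcels.popleft()
        self.raw_volume -= taken
        return taken

    def volume_closure_residual(self) -> float:
        """legally_disposed - (raw on site + converted + stolen); ~0 always."""
        return self.legally_disposed - (self.raw_volume + self.converted_volume + self.stolen)


def _update_guard(guard: GuardState, cfg: MunicipalConfig) -> GuardState:
    # One site interaction: an enforcing guard collects for the council and
    # keeps nothing (counterfactual: the bribe); a corrupt one keeps the
    # bribe (counterfactual: nothing).  Either way the realized-vs-forgone
    # comparison nudges p_enforce by the bribe amount.
    if guard.corrupt_today:
        # action = corrupt: propensity for corruption rises by m*(bribe-0),
        # i.e. p_enforce falls by the same amount
        p = adjust_probability(guard.p_enforce, -cfg.bribe, 0.0)
    else:
        p = adjust_probability(guard.p_enforce, 0.0, cfg.bribe)
    guard.p_enforce = p
    return guard


def company_disposal_event(
    company: CompanyState,
    guard: GuardState,
    site: SiteState,
    cfg: MunicipalConfig,
    rng: np.random.Generator,
    tick: int,
) -> dict:
    """Resolve one load: legal disposal at the site or illegal dumping.

    Returns a transaction record (action, payoff, counterfactual payoff).
    Both the company's legal-disposal propensity and — when the guard took
    part — his enforcement propensity are updated by the learning rule.
    """
    legal = rng.random() < company.p_legal.p
    permit_ok = cfg.tariff_mode == MONTHLY_PERMIT and company.permit_valid(tick)

    def legal_cost() -> tuple[float, str]:
        if permit_ok:
            return 0.0, "permit"
        if guard.present_today and not guard.corrupt_today:
            return cfg.dumping_fee, "fee"
        if guard.present_today and guard.corrupt_today:
            return cfg.bribe, "bribe"
        return 0.0, "free"

    if legal:
        cost, kind = legal_cost()
        if kind == "fee":
            company.fees_paid += cost
            guard.fees_collected_for_council += cost
            site.council_cash += cost
        elif kind == "bribe":
            company.bribes_paid += cost
            guard.bribe_income += cost
        site.receive_load(tick, cfg.load_volume)
        actual = -cost
        # counterfactual: dumped illegally under a fresh catch draw
        potential = -cfg.fine_company if rng.random() < cfg.p_catch_illegal_dump else 0.0
        company.p_legal = adjust_probability(company.p_legal, actual, potential)
        if guard.present_today and kind in ("fee", "bribe"):
            _update_guard(guard, cfg)
        action = "legal"
    else:
        site.illegally_dumped += cfg.load_volume
        caught = rng.random() < cfg.p_catch_illegal_dump
        actual = 0.0
        if caught:
            company.fines_paid += cfg.fine_company
            site.council_cash += cfg.fine_company
            actual = -cfg.fine_company
        cost, _ = legal_cost()  # what going to the site would have cost today
        potential = -cost
        # action taken is "illegal": its propensity (1 - p_legal) moves by
        # m*(actual - potential), so p_legal moves the opposite way
        company.p_legal = adjust_probability(company.p_legal, potential, actual)
        action = "illegal"
    return {"action": action, "payoff": actual, "counterfactual": potential}


def farmer_acquisition_event(
    farmer: FarmerState,
    guard: GuardState,
    site: SiteState,
    cfg: MunicipalConfig,
    rng: np.random.Generator,
    tick: int,
) -> dict:
    """Resolve one farmer's acquisition attempt: steal raw sludge or buy a bag.

    Theft succeeds when the guard is away, or when a present-but-corrupt
    guard is bribed; an enforcing guard fines the farmer.  The fence at the
    refurbished site makes every theft attempt yield zero volume.  Buying
    transfers one matured compost bag at the going sludge value (a payoff
    wash for the farmer: value gained equals price paid).
    """
    steal = rng.random() < farmer.p_steal.p

    def theft_outcome(charge: bool) -> tuple[float, float]:
        """(payoff, volume gained) for a theft under today's guard state."""
        if guard.present_today and not guard.corrupt_today:
            if charge:
                farmer.fines_paid += cfg.fine_farmer
                site.council_cash += cfg.fine_farmer
            return -cfg.fine_farmer, 0.0
        cost = 0.0
        if guard.present_today and guard.corrupt_today:
            cost = cfg.bribe
            if charge:
                farmer.bribes_paid += cost
                guard.bribe_income += cost
        if cfg.refurbished:
            return -cost, 0.0  # the fence blocks removal
        avail = min(cfg.bag_volume, site.raw_volume)
        if avail < cfg.bag_volume - 1e-12:
            return -cost, 0.0  # nothing worth taking on site
        if charge:
            taken = site.remove_raw(cfg.bag_volume)
            site.stolen += taken
            farmer.value_gained += cfg.sludge_value
        return cfg.sludge_value - cost, cfg.bag_volume

    if steal:
        actual, volume = theft_outcome(charge=True)
        # counterfactual: buying a bag is a value-for-money wash (or nothing
        # to buy), payoff 0 either way
        potential = 0.0
        farmer.p_steal = adjust_probability(farmer.p_steal, actual, potential)
        if guard.present_today:
            _update_guard(guard, cfg)
        action = "steal"
    else:
        actual = 0.0
        if site.compost_bags >= 1:
            site.compost_bags -= 1
            site.bags_sold_farmers += 1
            site.council_cash += cfg.sludge_value
            farmer.purchases_paid += cfg.sludge_value
            farmer.value_gained += cfg.sludge_value
            action = "buy"
        else:
            action = "no_stock"
        potential, _ = theft_outcome(charge=False)
        farmer.p_steal = adjust_probability(farmer.p_steal, potential, actual)
    return {"action": action, "payoff": actual, "counterfactual": potential}


def renew_permit(company: CompanyState, site: SiteState, tick: int, cfg: MunicipalConfig) -> None:
    """Monthly permit purchase (no-op in per-visit mode)."""
    if cfg.tariff_mode != MONTHLY_PERMIT:
        return
    company.permits_paid += cfg.permit_fee
    site.council_cash += cfg.permit_fee
    company.permit_valid_until = tick + cfg.month_length


def compost_step(site: SiteState, tick: int, cfg: MunicipalConfig) -> None:
    """Mature raw sludge into bags; bulk-sell stock at six-month boundaries."""
    while site.raw_parcels and tick - site.raw_parcels[0][0] >= cfg.compost_lag:
        arrived, volume = site.raw_parcels.popleft()
        site.raw_volume -= volume
        site.converted_volume += volume
        site.compost_bags += math.floor(volume * cfg.compost_yield / cfg.bag_volume)
    if tick > 0 and tick % cfg.compost_lag == 0 and site.compost_bags > 0:
        site.council_cash += site.compost_bags * cfg.sludge_value
        site.bags_sold_bulk += site.compost_bags
        site.compost_bags = 0


@dataclass
class MunicipalRunResult:
    """Per-tick cumulative series plus the final agent/site states."""

    series: pd.DataFrame
    site: SiteState
    guard: GuardState
    companies: list[CompanyState]
    farmers: list[FarmerState]
    cfg: MunicipalConfig

    @property
    def final(self) -> pd.Series:
        return self.series.iloc[-1]

    def money_conservation_residual(self) -> float:
        """Agent outflows minus (council revenue from agents + guard bribes).

        Bulk compost sales at six-month boundaries go to the outside market,
        so council cash net of them must equal what companies and farmers
        paid in (everything except bribes, which the guard keeps).
        """
        outflows = sum(c.total_outflow for c in self.companies)
        outflows += sum(f.total_outflow for f in self.farmers)
        bulk_revenue = self.site.bags_sold_bulk * self.cfg.sludge_value
        agent_revenue = self.site.council_cash - bulk_revenue
        return (outflows - self.guard.bribe_income) - agent_revenue


def run_municipal(cfg: MunicipalConfig, seed: int | np.random.Generator | None = None) -> MunicipalRunResult:
    """Run one municipal-site simulation for ``cfg.n_ticks`` days."""
    cfg.validate()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    m = cfg.multiplier
    companies = [CompanyState(BehaviourProbability(cfg.p_company_legal_init, m))
                 for _ in range(cfg.n_companies)]
    farmers = [FarmerState(BehaviourProbability(cfg.p_farmer_steal_init, m))
               for _ in range(cfg.n_farmers)]
    guard = GuardState(BehaviourProbability(1.0 - cfg.p_guard_corrupt_init, m))
    site = SiteState()

    records = [(0, 0.0, 0.0, 0.0, 0.0, 0.0, 0)]
    for tick in range(1, cfg.n_ticks + 1):
        guard.present_today = rng.random() < cfg.p_guard_present
        guard.corrupt_today = guard.present_today and (rng.random() >= guard.p_enforce.p)
        for c in companies:
            if rng.random() < cfg.p_company_job:
                company_disposal_event(c, guard, site, cfg, rng, tick)
        for f in farmers:
            if rng.random() < cfg.p_farmer_attempt:
                farmer_acquisition_event(f, guard, site, cfg, rng, tick)
        compost_step(site, tick, cfg)
        if tick % cfg.month_length == 0:
            for c in companies:
                renew_permit(c, site, tick, cfg)
        records.append(
            (tick, site.legally_disposed, site.illegally_dumped, site.stolen,
             site.council_cash, guard.bribe_income, site.compost_bags)
        )

    series = pd.DataFrame(
        records,
        columns=["tick", "legal_m3", "illegal_m3", "stolen_m3",
                 "council_cash", "guard_bribes", "compost_bags"],
    )
    return MunicipalRunResult(series=series, site=site, guard=guard,
                              companies=companies, farmers=farmers, cfg=cfg)
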