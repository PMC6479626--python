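"""Daily-step ABM of Skyloo composting-toilet adoption and business finance.

One tick is one day; a run lasts 2000 ticks (~5.5 years).  Households move
along naive -> aware -> adopter-waiting -> {installed | unadopted}:

* At tick 0 the business markets to a fixed pool of initial contacts
  (default 300); each naive contact becomes aware with probability 0.25
  times its susceptibility multiplier (tenancy, flood exposure, plot size).
* Every day, each informed household (installed, or waiting for a build)
  exposes each naive linked neighbour with probability 0.03 times the
  neighbour's multiplier.
* An aware household adopts iff it is open to reuse of faecal sludge and
  the monthly loan repayment fits within an affordability share of its
  income (default 22%); adopters join the business's build waiting list.
* The business builds at most one Skyloo per day, in list order, whenever
  its cash covers the MK200,000 build cost, issuing a loan repaid monthly
  starting the following month.  Households waiting more than 30 days
  un-adopt permanently.
* At every 30-tick month boundary active loans pay their instalment
  (balance accrues 1% interest first; the last instalment is truncated to
  the payoff) and the business pays its MK85,000 operating cost.

The business cash ledger satisfies, exactly and at every tick::

    cash = startup_capital + repayments - build_costs - operating_costs
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .environment import EnvironmentConfig, generate_households, susceptibility_multiplier
from .errors import ConfigError
from .finance import LoanState
from .network import AdjacencyNetwork, build_small_world, spatial_ring_order

__all__ = [
    "SkylooConfig",
    "BusinessState",
    "SkylooRunResult",
    "SkylooSimulation",
    "adoption_decision",
    "run_skyloo",
    "run_skyloo_replicate",
]

# household status codes
NAIVE, AWARE, WAITING, INSTALLED, UNADOPTED = 0, 1, 2, 3, 4
STATUS_NAMES = ("naive", "aware", "adopter-waiting", "installed", "unadopted")


@dataclass
class SkylooConfig:
    """Financial and behavioural parameters of one Skyloo scenario (MK)."""

    startup_capital: float = 10_000_000.0
    build_cost: float = 200_000.0
    build_capacity: int = 1
    operating_cost: float = 85_000.0
    monthly_repayment: float = 9_320.0
    monthly_interest: float = 0.01
    initial_contacts: int = 300
    p_marketing: float = 0.25
    p_neighbour: float = 0.03
    wait_limit: int = 30
    affordability_fraction: float = 0.22
    n_ticks: int = 2000
    month_length: int = 30

    def validate(self) -> None:
        for name in ("startup_capital", "build_cost", "operating_cost",
                     "monthly_repayment", "monthly_interest"):
            if getattr(self, name) < 0:
                raise ConfigError(name, "must be non-negative")
        for name in ("p_marketing", "p_neighbour"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ConfigError(name, "must be a probability in [0, 1]")
        if self.wait_limit <= 0:
            raise ConfigError("wait_limit", "must be positive")
        if self.build_capacity < 0:
            raise ConfigError("build_capacity", "must be non-negative")
        if self.n_ticks < 1:
            raise ConfigError("n_ticks", "must be positive")
        if self.month_length < 1:
            raise ConfigError("month_length", "must be positive")
        if not 0.0 <= self.affordability_fraction <= 1.0:
            raise ConfigError("affordability_fraction", "must lie in [0, 1]")


@dataclass
class BusinessState:
    """Skyloo enterprise: cash, build queue, loan book and cumulative ledgers."""

    startup_capital: float
    cash: float = field(init=False)
    waiting: deque = field(default_factory=deque)  # (household id, wait_start tick)
    loans: list = field(default_factory=list)
    total_repayments: float = 0.0
    total_build_costs: float = 0.0
    total_operating_costs: float = 0.0
    builds: int = 0
    loans_closed: int = 0

    def __post_init__(self):
        self.cash = float(self.startup_capital)

    def ledger_residual(self) -> float:
        """cash minus the ledger identity; zero (to rounding) at all times."""
        expected = (self.startup_capital + self.total_repayments
                    - self.total_build_costs - self.total_operating_costs)
        return self.cash - expected


def adoption_decision(open_to_reuse: bool, income: float, cfg: SkylooConfig) -> bool:
    """Adopt iff open to reuse and the repayment is affordable.

    Affordable means monthly_repayment <= affordability_fraction * income.
    """
    return bool(open_to_reuse) and cfg.monthly_repayment <= cfg.affordability_fraction * income


class SkylooSimulation:
    """Mutable state of one Skyloo run; drive with :meth:`run` or :meth:`step`."""

    def __init__(
        self,
        households: pd.DataFrame,
        network: AdjacencyNetwork,
        cfg: SkylooConfig,
        env_cfg: EnvironmentConfig,
        rng: np.random.Generator,
    ):
        cfg.validate()
        n = len(households)
        if network.n != n:
            raise ValueError("network size does not match household count")
        self.cfg = cfg
        self.rng = rng
        self.n = n
        self.susceptibility = susceptibility_multiplier(households, env_cfg)
        income = households["income"].to_numpy()
        open_to = households["open_to_reuse"].to_numpy()
        self.eligible = open_to & (cfg.monthly_repayment <= cfg.affordability_fraction * income)
        self.status = np.full(n, NAIVE, dtype=np.int8)
        self.informed = np.zeros(n, dtype=bool)
        pre = households["has_skyloo"].to_numpy()
        self.status[pre] = INSTALLED
        self.informed[pre] = True  # pre-installed households seed word of mouth
        self.indptr, self.indices = network.to_csr()
        self.business = BusinessState(startup_capital=cfg.startup_capital)
        self.tick = 0
        self._records: list[tuple] = []
        self._marketing_done = False

    # -- exposure -----------------------------------------------------------

    def exposure_trial(self, idx: np.ndarray, channel: str) -> np.ndarray:
        """Run one awareness trial per listed household; return new-aware ids.

        Non-naive households are unaffected.  The per-trial success
        probability is the channel base rate times the household's
        susceptibility multiplier, clipped to 1.
        """
        idx = np.asarray(idx, dtype=np.int64)
        base = self.cfg.p_marketing if channel == "marketing" else self.cfg.p_neighbour
        naive = idx[self.status[idx] == NAIVE]
        if naive.size == 0:
            return naive
        p = np.minimum(base * self.susceptibility[naive], 1.0)
        hits = naive[self.rng.random(naive.size) < p]
        return np.unique(hits)

    def _process_new_aware(self, hits: np.ndarray) -> None:
        if hits.size == 0:
            return
        adopt = self.eligible[hits]
        self.status[hits[~adopt]] = AWARE
        for h in hits[adopt]:
            self.status[h] = WAITING
            self.informed[h] = True
            self.business.waiting.append((int(h), self.tick))

    def marketing_step(self) -> None:
        """One-off tick-0 marketing against the business's contact pool."""
        m = min(self.cfg.initial_contacts, self.n)
        contacts = self.rng.choice(self.n, size=m, replace=False)
        self._process_new_aware(self.exposure_trial(contacts, "marketing"))
        self._marketing_done = True

    def neighbour_spread(self) -> None:
        informed = np.flatnonzero(self.informed)
        if informed.size == 0:
            return
        targets = np.concatenate(
            [self.indices[self.indptr[i]:self.indptr[i + 1]] for i in informed]
        )
        self._process_new_aware(self.exposure_trial(targets, "neighbour"))

    # -- business -----------------------------------------------------------

    def business_build_step(self) -> None:
        b, cfg = self.business, self.cfg
        built = 0
        while built < cfg.build_capacity and b.waiting and b.cash >= cfg.build_cost:
            h, _start = b.waiting.popleft()
            if self.status[h] != WAITING:  # defensive: stale queue entry
                continue
            b.cash -= cfg.build_cost
            b.total_build_costs += cfg.build_cost
            b.builds += 1
            self.status[h] = INSTALLED
            first_due = (self.tick // cfg.month_length + 1) * cfg.month_length
            b.loans.append(
                LoanState(
                    principal=cfg.build_cost,
                    payment=cfg.monthly_repayment,
                    balance=cfg.build_cost,
                    first_due_tick=first_due,
                )
            )
            built += 1

    def unadopt_sweep(self) -> None:
        b = self.business
        while b.waiting and self.tick - b.waiting[0][1] > self.cfg.wait_limit:
            h, _start = b.waiting.popleft()
            if self.status[h] == WAITING:
                self.status[h] = UNADOPTED
                self.informed[h] = False

    def monthly_settlement(self) -> None:
        b, cfg = self.business, self.cfg
        still_open = []
        for loan in b.loans:
            if loan.first_due_tick > self.tick:
                still_open.append(loan)
                continue
            loan.balance *= 1.0 + cfg.monthly_interest
            pay = min(loan.payment, loan.balance)
            loan.balance -= pay
            loan.payments_made += 1
            b.cash += pay
            b.total_repayments += pay
            if loan.balance > 1e-9:
                still_open.append(loan)
            else:
                loan.balance = 0.0
                b.loans_closed += 1
        b.loans = still_open
        b.cash -= cfg.operating_cost
        b.total_operating_costs += cfg.operating_cost

    # -- driver -------------------------------------------------------------

    def counts(self) -> np.ndarray:
        return np.bincount(self.status, minlength=5)

    def _record(self) -> None:
        c = self.counts()
        self._records.append(
            (self.tick, c[INSTALLED], c[WAITING], c[UNADOPTED], c[AWARE], c[NAIVE],
             self.business.cash)
        )

    def step(self) -> None:
        """Advance one day: diffusion, builds, un-adoption, monthly settlement."""
        if self.tick == 0 and not self._marketing_done:
            self.marketing_step()
        else:
            self.tick += 1
            self.neighbour_spread()
        self.business_build_step()
        self.unadopt_sweep()
        if self.tick > 0 and self.tick % self.cfg.month_length == 0:
            self.monthly_settlement()
        self._record()

    def run(self) -> "SkylooRunResult":
        for _ in range(self.cfg.n_ticks + 1):
            self.step()
        series = pd.DataFrame(
            self._records,
            columns=["tick", "installed", "waiting", "unadopted", "aware", "naive", "cash"],
        )
        return SkylooRunResult(series=series, business=self.business)


@dataclass
class SkylooRunResult:
    """Per-tick output series and the final business state of one run."""

    series: pd.DataFrame
    business: BusinessState

    @property
    def final(self) -> pd.Series:
        return self.series.iloc[-1]


def run_skyloo(
    households: pd.DataFrame,
    network: AdjacencyNetwork,
    cfg: SkylooConfig,
    env_cfg: EnvironmentConfig,
    seed: int | np.random.Generator | None = None,
) -> SkylooRunResult:
    """Run one Skyloo simulation on a prepared population and network."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return SkylooSimulation(households, network, cfg, env_cfg, rng).run()


def run_skyloo_replicate(
    env_cfg: EnvironmentConfig,
    cfg: SkylooConfig,
    seed: int,
    k: int = 4,
    p_rewire: float = 0.2,
) -> SkylooRunResult:
    """Generate a fresh population and small-world network, then run once.

    Each Monte-Carlo repeat regenerates both — the network construction is
    itself stochastic and contributes materially to run-to-run variation.
    """
    rng = np.random.default_rng(seed)
    hh = generate_households(env_cfg, rng=rng)
    order = spatial_ring_order(hh["x"].to_numpy(), hh["y"].to_numpy())
    net = build_small_world(env_cfg.n_households, k=k, p_rewire=p_rewire, seed=rng, order=order)
    return run_skyloo(hh, net, cfg, env_cfg, seed=rng)
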