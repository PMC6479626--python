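"""Synthetic household environment for the Skyloo adoption model.

Generates the population of urban households that the adoption simulation
runs over: tenure, household size, monthly income, plot size, a point
location on a square map, and a normalised distance to a flood-prone
("dambo") strip along one map edge.  The distributions reproduce the
survey-derived moments the model is parameterised with: 3026 households,
a 50/50 owner/tenant split, household size ~ N(6, 2) rounded to a minimum
of one person, monthly income with mean and SD both MK44,000, a 0.3%
chance of already owning a Skyloo, and a 64/148 probability of being open
to reuse of faecal sludge as compost.

Income is modelled as a lognormal moment-matched to the stated mean/SD:
with a coefficient of variation of 1, a normal would put substantial mass
at negative incomes, while the lognormal is non-negative, right-skewed
(as urban income distributions are), and matches both moments exactly.

Flood exposure and plot size enter adoption through sliding-scale
multipliers: households inside or near the flood strip, and households on
small plots, are more receptive to a raised composting toilet because pit
latrines flood or there is no room to dig replacement pits.  The scale is
linear between a high factor (default 1.5) at maximum exposure / smallest
plot and a low factor (default 0.75) at the other end.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigError

__all__ = [
    "EnvironmentConfig",
    "generate_households",
    "sample_income",
    "flood_multiplier",
    "land_multiplier",
    "susceptibility_multiplier",
]

STATUS_NAIVE = "naive"
STATUS_AWARE = "aware"
STATUS_WAITING = "adopter-waiting"
STATUS_INSTALLED = "installed"
STATUS_UNADOPTED = "unadopted"


@dataclass
class EnvironmentConfig:
    """Parameters of the synthetic household population.

    Monetary values are Malawi Kwacha (MK) per month; lengths/areas are in
    abstract map units (the map is a ``map_side`` x ``map_side`` square with
    a flood-prone strip of width ``flood_zone_width`` along the y=0 edge).
    """

    n_households: int = 3026
    owner_fraction: float = 0.5
    household_size_mean: float = 6.0
    household_size_sd: float = 2.0
    income_mean: float = 44_000.0
    income_sd: float = 44_000.0
    p_initial_skyloo: float = 0.003
    p_open_to_reuse: float = 64 / 148
    map_side: float = 1000.0
    flood_zone_width: float = 150.0
    land_size_range: tuple[float, float] = (100.0, 2000.0)
    #: multiplier endpoints for the sliding scales (most- to least-receptive)
    mult_high: float = 1.5
    mult_low: float = 0.75
    tenant_multiplier: float = 0.8

    def validate(self) -> None:
        if self.n_households <= 0:
            raise ConfigError("n_households", "must be a positive count")
        for name in ("owner_fraction", "p_initial_skyloo", "p_open_to_reuse"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(name, "must be a probability in [0, 1]")
        if self.income_mean <= 0:
            raise ConfigError("income_mean", "must be positive")
        if self.income_sd < 0:
            raise ConfigError("income_sd", "must be non-negative")
        if self.household_size_mean <= 0:
            raise ConfigError("household_size_mean", "must be positive")
        if self.household_size_sd < 0:
            raise ConfigError("household_size_sd", "must be non-negative")
        if self.map_side <= 0:
            raise ConfigError("map_side", "must be positive")
        if not 0 <= self.flood_zone_width < self.map_side:
            raise ConfigError("flood_zone_width", "must lie in [0, map_side)")
        lo, hi = self.land_size_range
        if lo <= 0 or hi <= lo:
            raise ConfigError("land_size_range", "must satisfy 0 < min < max")
        if self.mult_high <= 0 or self.mult_low <= 0:
            raise ConfigError("mult_high", "multiplier endpoints must be positive")
        if not 0.0 <= self.tenant_multiplier:
            raise ConfigError("tenant_multiplier", "must be non-negative")


def sample_income(mean: float, sd: float, rng: np.random.Generator, size=None):
    """Draw monthly income(s) from a lognormal moment-matched to ``mean``/``sd``.

    sigma^2 = ln(1 + (sd/mean)^2), mu = ln(mean) - sigma^2/2, so the draw has
    the requested mean and SD exactly.  ``sd == 0`` returns ``mean``.
    """
    if mean <= 0:
        raise ConfigError("income_mean", "must be positive")
    if sd < 0:
        raise ConfigError("income_sd", "must be non-negative")
    if sd == 0:
        return mean if size is None else np.full(size, float(mean))
    sigma2 = math.log1p((sd / mean) ** 2)
    mu = math.log(mean) - sigma2 / 2.0
    return rng.lognormal(mean=mu, sigma=math.sqrt(sigma2), size=size)


def _sliding_scale(t, cfg: EnvironmentConfig):
    # linear between mult_high at t=0 (most receptive) and mult_low at t=1
    return cfg.mult_high + (cfg.mult_low - cfg.mult_high) * t


def flood_multiplier(flood_proximity, cfg: EnvironmentConfig):
    """Receptivity factor from flood exposure.

    ``flood_proximity`` is the normalised distance to the flood strip
    (0 = inside it).  Households at risk of flooding get the high factor;
    the factor falls linearly to the low endpoint at proximity 1.
    """
    fp = np.asarray(flood_proximity, dtype=float)
    if np.any((fp < 0) | (fp > 1)):
        raise ValueError("flood_proximity must lie in [0, 1]")
    out = _sliding_scale(fp, cfg)
    return float(out) if np.isscalar(flood_proximity) else out


def land_multiplier(land_size, cfg: EnvironmentConfig):
    """Receptivity factor from plot size: small plots cannot fit new pits."""
    ls = np.asarray(land_size, dtype=float)
    if np.any(ls <= 0):
        raise ValueError("land_size must be positive")
    lo, hi = cfg.land_size_range
    t = np.clip((ls - lo) / (hi - lo), 0.0, 1.0)
    out = _sliding_scale(t, cfg)
    return float(out) if np.isscalar(land_size) else out


def susceptibility_multiplier(households: pd.DataFrame, cfg: EnvironmentConfig) -> np.ndarray:
    """Combined per-household awareness multiplier.

    Product of the flood and plot-size sliding scales and the tenant factor.
    Applied to both marketing and word-of-mouth exposure probabilities.
    """
    m = flood_multiplier(households["flood_proximity"].to_numpy(), cfg)
    m = m * land_multiplier(households["land_size"].to_numpy(), cfg)
    tenant = (households["tenure"] == "tenant").to_numpy()
    return np.where(tenant, m * cfg.tenant_multiplier, m)


def generate_households(cfg: EnvironmentConfig, rng: np.random.Generator | None = None,
                        seed: int | None = None) -> pd.DataFrame:
    """Generate the synthetic household table.

    Returns a DataFrame with one row per household and columns: ``id``,
    ``x``, ``y``, ``tenure``, ``size``, ``income``, ``land_size``,
    ``flood_proximity``, ``open_to_reuse``, ``has_skyloo``.  Households
    flagged ``has_skyloo`` start the simulation with the toilet installed
    (and no loan).
    """
    cfg.validate()
    if rng is None:
        rng = np.random.default_rng(seed)
    n = cfg.n_households

    x = rng.uniform(0.0, cfg.map_side, size=n)
    y = rng.uniform(0.0, cfg.map_side, size=n)
    # flood strip along the y=0 edge; proximity normalised by the distance
    # from the strip edge to the far side of the map
    span = cfg.map_side - cfg.flood_zone_width
    flood_proximity = np.clip((y - cfg.flood_zone_width) / span, 0.0, 1.0)

    tenure = np.where(rng.random(n) < cfg.owner_fraction, "owner", "tenant")
    size = np.maximum(
        1, np.rint(rng.normal(cfg.household_size_mean, cfg.household_size_sd, size=n))
    ).astype(int)
    income = sample_income(cfg.income_mean, cfg.income_sd, rng, size=n)
    lo, hi = cfg.land_size_range
    land_size = rng.uniform(lo, hi, size=n)
    open_to_reuse = rng.random(n) < cfg.p_open_to_reuse
    has_skyloo = rng.random(n) < cfg.p_initial_skyloo

    return pd.DataFrame(
        {
            "id": np.arange(n),
            "x": x,
            "y": y,
            "tenure": tenure,
            "size": size,
            "income": income,
            "land_size": land_size,
            "flood_proximity": flood_proximity,
            "open_to_reuse": open_to_reuse,
            "has_skyloo": has_skyloo,
        }
    )
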