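"""Background (non-cancer) demographics: mortality and age structure.

The engine needs an all-cause background mortality to decide which generated
persons survive to the target date.  We use a Gompertz-Makeham hazard per sex,

    mu(a) = lambda + alpha * exp(beta * a),

with ``alpha`` calibrated so period life expectancy at birth hits a chosen
value (defaults: 78 years for men, 83 for women).  A user-supplied life table
(CSV with columns ``age,survival``) can replace it without code changes.

The default population age structure at the target date is the stationary
(life-table) distribution, i.e. the share of persons aged ``a`` is
proportional to the survivorship l(a).  This makes the generated world
demographically self-consistent: the pool of regeneration attempts then
reconstructs every historical birth cohort at equal intensity.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

__all__ = ["GompertzMakeham", "LifeTable", "default_life_table", "WEEKS_PER_YEAR", "MAX_AGE_YEARS"]

WEEKS_PER_YEAR = 52
MAX_AGE_YEARS = 105
DEFAULT_E0 = {"male": 78.0, "female": 83.0}


@dataclass(frozen=True)
class GompertzMakeham:
    """Gompertz-Makeham all-cause mortality hazard (per year)."""

    makeham: float
    alpha: float
    beta: float

    def hazard(self, age_years: np.ndarray | float) -> np.ndarray:
        a = np.asarray(age_years, float)
        return self.makeham + self.alpha * np.exp(self.beta * a)

    def survival(self, age_years: np.ndarray | float) -> np.ndarray:
        """S(a) = exp(-integral of the hazard from 0 to a)."""
        a = np.asarray(age_years, float)
        return np.exp(-self.makeham * a - self.alpha / self.beta * (np.exp(self.beta * a) - 1.0))

    def life_expectancy(self) -> float:
        grid = np.linspace(0.0, 120.0, 12001)
        return float(np.trapezoid(self.survival(grid), grid))

    @classmethod
    def calibrated(cls, e0: float, beta: float = 0.09, makeham: float = 2e-4) -> "GompertzMakeham":
        """Solve for alpha so that life expectancy at birth equals ``e0``."""

        def gap(log_alpha: float) -> float:
            return cls(makeham, float(np.exp(log_alpha)), beta).life_expectancy() - e0

        log_alpha = brentq(gap, np.log(1e-9), np.log(1e-1), xtol=1e-12)
        return cls(makeham, float(np.exp(log_alpha)), beta)


class LifeTable:
    """Weekly-resolution survivorship l(a) used for sampling death ages."""

    def __init__(self, survival_weekly: np.ndarray, sex: str = ""):
        s = np.asarray(survival_weekly, float)
        if s.ndim != 1 or s[0] <= 0:
            raise ValueError("survival grid must be 1-D and start positive")
        if np.any(np.diff(s) > 1e-12):
            raise ValueError("survivorship must be non-increasing")
        self.sex = sex
        self.survival = s / s[0]
        # force an upper bound on lifespan so every sampled death is finite
        self.survival = np.append(self.survival, 0.0)

    @classmethod
    def from_hazard(cls, gm: GompertzMakeham, sex: str = "") -> "LifeTable":
        weeks = np.arange(MAX_AGE_YEARS * WEEKS_PER_YEAR + 1)
        return cls(gm.survival(weeks / WEEKS_PER_YEAR), sex=sex)

    @classmethod
    def from_csv(cls, text: str, sex: str = "") -> "LifeTable":
        """Load from CSV with columns ``age,survival`` (age in years)."""
        rows = [line.split(",") for line in text.strip().splitlines()[1:]]
        ages = np.array([float(r[0]) for r in rows])
        surv = np.array([float(r[1]) for r in rows])
        weeks = np.arange(int(ages.max()) * WEEKS_PER_YEAR + 1)
        grid = np.interp(weeks / WEEKS_PER_YEAR, ages, surv)
        return cls(grid, sex=sex)

    # -- sampling -----------------------------------------------------------

    def sample_death_week(self, rng: np.random.Generator, age_weeks: int = 0) -> int:
        """Sample age at death (in weeks), conditional on being alive at ``age_weeks``."""
        s_now = self.survival[age_weeks]
        u = rng.uniform(0.0, s_now)
        # survival is non-increasing; find first week where S < u
        idx = int(np.searchsorted(-self.survival, -u, side="right"))
        return max(idx, age_weeks)

    def prob_alive(self, age_weeks: int) -> float:
        return float(self.survival[min(age_weeks, len(self.survival) - 1)])

    # -- population structure ----------------------------------------------

    def stationary_year_shares(self, max_age: int = 100) -> np.ndarray:
        """Share of the population aged a (whole years), a = 0..max_age."""
        ages = np.arange(max_age + 1)
        l = self.survival[ages * WEEKS_PER_YEAR]
        return l / l.sum()

    def stationary_bin_shares(self, bins: list[tuple[int, int]]) -> np.ndarray:
        """Shares of the *total* population in the given age bins (years)."""
        shares = self.stationary_year_shares()
        out = np.array([shares[lo:hi].sum() for lo, hi in bins])
        return out


@functools.lru_cache(maxsize=None)
def default_life_table(sex: str) -> LifeTable:
    e0 = DEFAULT_E0[sex]
    return LifeTable.from_hazard(GompertzMakeham.calibrated(e0), sex=sex)
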