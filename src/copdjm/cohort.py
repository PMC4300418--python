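"""Virtual COPD cohort generation.

Covariates are sampled from marginal specifications: Bernoulli proportions
for the categoricals and scaled Beta distributions matched to a printed
median and range for the continuous ones (clinical summary tables rarely
report SDs).  Marginals are sampled independently; a joint sampler can be
supplied through ``CovariateDistributions.joint_sampler`` when correlation
structure matters.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.stats import beta as beta_dist

__all__ = ["ContinuousSpec", "CovariateDistributions", "sample_covariates"]

#: numeric cohort-table columns (categoricals are 0/1 non-reference flags)
COVARIATE_COLUMNS = (
    "age",
    "sex",
    "height",
    "weight",
    "bmi",
    "severity",
    "reversibility",
    "pics",
    "smoking",
)


@dataclass(frozen=True)
class ContinuousSpec:
    """Bounded continuous marginal: scaled Beta matched to median/range."""

    low: float
    high: float
    median: float
    concentration: float = 4.0  # Beta a+b; larger = tighter around the median

    def __post_init__(self) -> None:
        if not self.low < self.median < self.high:
            raise ValueError("need low < median < high")
        if self.concentration <= 0:
            raise ValueError("concentration must be > 0")

    def _shapes(self) -> tuple[float, float]:
        q = (self.median - self.low) / (self.high - self.low)
        kappa = self.concentration

        def med_err(p):
            return beta_dist.ppf(0.5, p * kappa, (1 - p) * kappa) - q

        p = brentq(med_err, 1e-6, 1 - 1e-6)
        return p * kappa, (1 - p) * kappa

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        a, b = self._shapes()
        return self.low + (self.high - self.low) * rng.beta(a, b, size=n)


@dataclass
class CovariateDistributions:
    """Marginal covariate specs for the virtual cohort.

    Proportions are of the *non-reference* category (male, severe,
    reversible, PICS user, smoker).  Weight is derived from BMI and height
    rather than sampled.
    """

    p_male: float = 0.70
    p_severe: float = 0.67
    p_reversible: float = 0.26
    p_pics: float = 0.40
    p_smoker: float = 0.42
    age: ContinuousSpec = field(
        default_factory=lambda: ContinuousSpec(40.0, 90.0, 65.0)
    )
    height: ContinuousSpec = field(
        default_factory=lambda: ContinuousSpec(135.0, 203.0, 170.0)
    )
    bmi: ContinuousSpec = field(
        default_factory=lambda: ContinuousSpec(16.0, 40.0, 26.0)
    )
    joint_sampler: Callable[[int, np.random.Generator], pd.DataFrame] | None = None

    def __post_init__(self) -> None:
        for name in ("p_male", "p_severe", "p_reversible", "p_pics", "p_smoker"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name}={p} must lie in [0, 1]")


def sample_covariates(
    n: int, dist: CovariateDistributions, seed: int | np.random.Generator
) -> pd.DataFrame:
    """Numeric cohort table with one row per subject (reproducible)."""
    if n <= 0:
        raise ValueError("n must be > 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if dist.joint_sampler is not None:
        df = dist.joint_sampler(n, rng)
        missing = set(COVARIATE_COLUMNS) - set(df.columns)
        if missing:
            raise ValueError(f"joint sampler omitted columns {sorted(missing)}")
        return df[list(COVARIATE_COLUMNS)].reset_index(drop=True)
    height = dist.height.sample(n, rng)
    bmi = dist.bmi.sample(n, rng)
    return pd.DataFrame(
        {
            "age": dist.age.sample(n, rng),
            "sex": (rng.uniform(size=n) < dist.p_male).astype(float),
            "height": height,
            "weight": bmi * (height / 100.0) ** 2,
            "bmi": bmi,
            "severity": (rng.uniform(size=n) < dist.p_severe).astype(float),
            "reversibility": (rng.uniform(size=n) < dist.p_reversible).astype(float),
            "pics": (rng.uniform(size=n) < dist.p_pics).astype(float),
            "smoking": (rng.uniform(size=n) < dist.p_smoker).astype(float),
        }
    )
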