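"""Forward simulation of virtual COPD trials.

Per subject: draw covariates, draw lognormal random effects from omega,
build individual parameters, solve the FEV1 trajectory at the visit grid,
sample a dropout time from the IPRED-linked hazard, truncate observations
at dropout and add residual error.  Simulation and the estimation
likelihood share every convention (trough exposure, left-endpoint hazard),
so parameters simulated here are recoverable by the joint fit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import CovariateDistributions, sample_covariates
from .data import LongitudinalDataset
from .parameters import DoseRegimen, PopulationParameters
from .structural import exposure, solve_fev1_grid, typical_values

__all__ = ["TrialDesign", "simulate_trial"]


@dataclass(frozen=True)
class Arm:
    label: str
    regimen: DoseRegimen
    fraction: float


@dataclass
class TrialDesign:
    """Arms, visit schedule and cohort size of one trial."""

    arms: list[Arm] = field(
        default_factory=lambda: [
            Arm("placebo", DoseRegimen(0.0), 0.5),
            Arm("salmeterol50", DoseRegimen(50.0, interval=12.0), 0.5),
        ]
    )
    duration: float = 24.0  # weeks
    visit_interval: float = 4.0  # weeks
    n_subjects: int = 2000
    seed: int = 20140918

    def __post_init__(self) -> None:
        if abs(sum(a.fraction for a in self.arms) - 1.0) > 1e-9:
            raise ValueError("arm allocation fractions must sum to 1")
        if not 2.0 <= self.visit_interval <= 4.0:
            raise ValueError("visit_interval must lie in [2, 4] weeks")
        if self.duration < self.visit_interval:
            raise ValueError("duration must be >= visit_interval")
        if self.n_subjects <= 0:
            raise ValueError("n_subjects must be > 0")

    @property
    def visit_times_days(self) -> np.ndarray:
        n_vis = int(np.floor(self.duration / self.visit_interval + 1e-9))
        return np.arange(n_vis + 1) * self.visit_interval * 7.0


def _residual_draws(ipred, pop: PopulationParameters, rng) -> np.ndarray:
    if pop.sigma_add > 0 and pop.sigma_prop > 0:
        eps = rng.standard_normal(ipred.shape + (2,))
        return ipred * (1 + pop.sigma_prop * eps[..., 0]) + pop.sigma_add * eps[..., 1]
    if pop.sigma_prop > 0:
        return ipred * (1 + pop.sigma_prop * rng.standard_normal(ipred.shape))
    if pop.sigma_add > 0:
        return ipred + pop.sigma_add * rng.standard_normal(ipred.shape)
    return ipred.copy()


def simulate_structural(
    pop: PopulationParameters,
    times_days: np.ndarray,
    cov: pd.DataFrame,
    dose_amount: np.ndarray,
    dose_interval_h: float,
    etas: np.ndarray,
) -> np.ndarray:
    """Noise-free IPRED matrix (n, m) for given covariates/doses/etas."""
    typ = typical_values(pop, cov)
    names = pop.iiv_parameters()
    indiv = {p: typ[p].copy() for p in typ}
    for k, p in enumerate(names):
        indiv[p] = indiv[p] * np.exp(etas[:, k])
    n, m = len(cov), len(times_days)
    eff = np.zeros((n, m))
    for amt in np.unique(dose_amount):
        if amt == 0:
            continue
        sel = dose_amount == amt
        reg = DoseRegimen(amt, interval=dose_interval_h)
        for kde in np.unique(indiv["kde"][sel]):
            sub = sel & (indiv["kde"] == kde)
            a = exposure(
                times_days, reg, kde, pop.exposure_parameterisation, predose=True
            )
            eff[sub] = indiv["emax"][sub, None] * a[None, :] / (
                indiv["edk50"][sub, None] + a[None, :]
            )
    return solve_fev1_grid(
        times_days,
        indiv["int_dis"],
        indiv["slope_dis"],
        indiv["kin"],
        eff,
        pop.drug_effect_mode,
    )


def _sample_dropout(
    pop: PopulationParameters,
    times_days: np.ndarray,
    ipred: np.ndarray,
    y: np.ndarray,
    rng,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised inverse-CDF dropout on the visit grid.

    Hazard is piecewise constant per interval, driven by the left-endpoint
    IPRED (and left-endpoint observed FEV1 when beta1 != 0).  Returns
    (dropped, event_idx) where event_idx is the grid index of the first
    missed visit.
    """
    spec = pop.hazard
    weeks = times_days / 7.0
    lin = spec.beta2 * ipred[:, :-1]
    if spec.beta1 != 0.0:
        lin = lin + spec.beta1 * y[:, :-1]
    if spec.form == "constant":
        base = np.full(len(weeks) - 1, spec.beta0) * np.diff(weeks)
    elif spec.form == "exponential":
        base = spec.beta0 / spec.shape * np.diff(np.exp(spec.shape * weeks))
    else:  # weibull
        base = spec.beta0 * np.diff(weeks**spec.shape)
    seg = base[None, :] * np.exp(lin)  # (n, m-1) interval cumulative hazards
    H = np.concatenate([np.zeros((len(ipred), 1)), np.cumsum(seg, axis=1)], axis=1)
    target = -np.log(rng.uniform(size=len(ipred)))
    dropped = target < H[:, -1]
    # first grid point whose cumulative hazard exceeds the target
    event_idx = np.argmax(H > target[:, None], axis=1)
    event_idx[~dropped] = -1
    # a "dropout" inside the first interval would erase the baseline visit;
    # the baseline observation always exists, so the earliest missed visit is 1
    event_idx[dropped] = np.maximum(event_idx[dropped], 1)
    return dropped, event_idx


def simulate_trial(
    pop: PopulationParameters,
    design: TrialDesign,
    dist: CovariateDistributions | None = None,
    seed: int | None = None,
    covariates: pd.DataFrame | None = None,
    arm_labels: np.ndarray | None = None,
) -> LongitudinalDataset:
    """Simulate one trial; reproducible under a fixed seed.

    ``covariates``/``arm_labels`` pin the cohort (used by VPC/NPDE
    re-simulation); otherwise covariates are drawn from ``dist`` and arms
    allocated by their fractions.
    """
    rng = np.random.default_rng(design.seed if seed is None else seed)
    n = design.n_subjects if covariates is None else len(covariates)
    if covariates is None:
        cov = sample_covariates(n, dist or CovariateDistributions(), rng)
    else:
        cov = covariates.reset_index(drop=True)

    labels = np.array([a.label for a in design.arms])
    regs = {a.label: a.regimen for a in design.arms}
    if arm_labels is None:
        fractions = np.array([a.fraction for a in design.arms])
        arm = rng.choice(labels, size=n, p=fractions)
    else:
        arm = np.asarray(arm_labels)
    dose_amount = np.array([regs[a].dose_amount for a in arm])
    interval_h = next(
        (r.interval for r in regs.values() if r.dose_amount > 0), 12.0
    )

    names = pop.iiv_parameters()
    q = len(names)
    omega = pop.omega_matrix()
    etas = (
        rng.multivariate_normal(np.zeros(q), omega, size=n, method="cholesky")
        if q
        else np.zeros((n, 0))
    )

    times = design.visit_times_days
    ipred = simulate_structural(pop, times, cov, dose_amount, interval_h, etas)
    y = _residual_draws(ipred, pop, rng)
    dropped, event_idx = _sample_dropout(pop, times, ipred, y, rng)

    regimens = [
        DoseRegimen(dose_amount[i], interval=interval_h, end_time=times[-1])
        if dose_amount[i] > 0
        else DoseRegimen(0.0)
        for i in range(n)
    ]
    ds = LongitudinalDataset.from_records(
        ids=np.arange(1, n + 1),
        times=times,
        y=y,
        regimens=regimens,
        arm=arm,
        covariates=cov,
        dropped=dropped,
        event_idx=event_idx,
    )
    return ds
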