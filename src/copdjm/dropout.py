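"""Time-to-event dropout model.

The dropout hazard (per week) is

    h(t) = base(t) * exp(beta1 * FEV1_obs + beta2 * IPRED)

with base(t) constant (beta0), Gompertz ("exponential", beta0*exp(shape*t))
or Weibull (beta0*shape*t**(shape-1)).  beta1 and beta2 capture at-random
and non-random (informative) missingness; beta1 = beta2 = 0 is completely
random dropout.  The individual-predicted FEV1 inside the hazard integral
is held piecewise constant between visits (the only times it is
materialised in a trial dataset), at the left visit endpoint.

All times here are weeks; the trajectory solver's day clock is converted by
the callers (7 days = 1 week).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import quad

from .parameters import HazardSpec

__all__ = [
    "DropoutRecord",
    "cumulative_hazard",
    "dropout_pdf",
    "hazard",
    "interval_dropout_probability",
    "piecewise_cumulative_hazard",
    "sample_dropout_time",
    "survivor",
]


@dataclass(frozen=True)
class DropoutRecord:
    subject_id: int
    last_observed_time: float  # weeks
    next_scheduled_time: float  # weeks; trial end for completers
    event: str  # "dropped" | "completed"

    def __post_init__(self) -> None:
        if self.event not in ("dropped", "completed"):
            raise ValueError(f"unknown event {self.event!r}")
        if self.event == "dropped" and not (
            self.next_scheduled_time > self.last_observed_time
        ):
            raise ValueError("dropped records need next > last observed time")


def _base_hazard(t, spec: HazardSpec):
    t = np.asarray(t, dtype=float)
    if spec.form == "constant":
        return np.broadcast_to(spec.beta0, t.shape).astype(float)
    if spec.form == "exponential":  # Gompertz
        return spec.beta0 * np.exp(spec.shape * t)
    # Weibull
    with np.errstate(divide="ignore"):
        return spec.beta0 * spec.shape * np.where(t > 0, t, np.nan) ** (spec.shape - 1)


def hazard(t, spec: HazardSpec, fev1_obs=None, ipred=0.0):
    """h(t) in 1/week.  ``fev1_obs`` is required only when beta1 != 0."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be >= 0")
    if spec.beta1 != 0.0 and fev1_obs is None:
        raise ValueError("fev1_obs required when beta1 != 0")
    ipred = np.asarray(ipred, dtype=float)
    if np.any(ipred < 0):
        raise ValueError("ipred must be >= 0")
    lin = spec.beta2 * ipred
    if spec.beta1 != 0.0:
        lin = lin + spec.beta1 * np.asarray(fev1_obs, dtype=float)
    out = _base_hazard(t, spec) * np.exp(lin)
    return out if out.ndim else float(out)


def cumulative_hazard(t0: float, t1: float, spec: HazardSpec, ipred_path) -> float:
    """Integral of the hazard on [t0, t1] weeks via adaptive quadrature.

    ``ipred_path`` maps t (weeks) to the individual-predicted FEV1 (L); pass
    a constant-returning callable for a flat trajectory.
    """
    if not 0 <= t0 <= t1:
        raise ValueError("need 0 <= t0 <= t1")
    if t0 == t1:
        return 0.0
    val, err = quad(
        lambda t: hazard(t, spec, fev1_obs=ipred_path(t), ipred=ipred_path(t)),
        t0,
        t1,
        limit=200,
    )
    if not np.isfinite(val) or err > 1e-6 * max(1.0, abs(val)):
        raise RuntimeError(f"hazard quadrature failed on [{t0}, {t1}]")
    return float(val)


def piecewise_cumulative_hazard(
    grid: np.ndarray, ipred: np.ndarray, spec: HazardSpec, fev1_obs=None
) -> np.ndarray:
    """Exact cumulative hazard at each grid point for an IPRED path held
    piecewise constant at the left endpoint of each interval.

    ``grid`` (weeks, increasing, grid[0] is the start) and ``ipred`` have
    equal length; returns H with H[0] = 0.  For the constant base hazard the
    per-interval integral is h*dt; Gompertz and Weibull bases are integrated
    in closed form on each interval.
    """
    grid = np.asarray(grid, dtype=float)
    ipred = np.asarray(ipred, dtype=float)
    lin = spec.beta2 * ipred[:-1]
    if spec.beta1 != 0.0:
        if fev1_obs is None:
            raise ValueError("fev1_obs required when beta1 != 0")
        lin = lin + spec.beta1 * np.asarray(fev1_obs, dtype=float)[:-1]
    mult = np.exp(lin)
    t0, t1 = grid[:-1], grid[1:]
    if spec.form == "constant":
        seg = spec.beta0 * (t1 - t0)
    elif spec.form == "exponential":
        seg = spec.beta0 / spec.shape * (np.exp(spec.shape * t1) - np.exp(spec.shape * t0))
    else:  # weibull
        seg = spec.beta0 * (t1**spec.shape - t0**spec.shape)
    return np.concatenate([[0.0], np.cumsum(seg * mult)])


def survivor(t: float, spec: HazardSpec, ipred_path) -> float:
    """P(still in trial at t weeks) = exp(-cumulative hazard)."""
    if t < 0:
        raise ValueError("t must be >= 0")
    return float(np.exp(-cumulative_hazard(0.0, t, spec, ipred_path)))


def dropout_pdf(t: float, spec: HazardSpec, ipred_path) -> float:
    """Density of the dropout time: S(t) * h(t)."""
    s = survivor(t, spec, ipred_path)
    h = hazard(t, spec, fev1_obs=ipred_path(t), ipred=ipred_path(t))
    return float(s * h)


def interval_dropout_probability(
    rec: DropoutRecord, spec: HazardSpec, ipred_path
) -> float:
    """Likelihood contribution of one subject's dropout status.

    Dropped: S(last observed) - S(next scheduled); completed: S(end).
    """
    s_last = survivor(rec.last_observed_time, spec, ipred_path)
    if rec.event == "completed":
        return s_last if rec.last_observed_time == rec.next_scheduled_time else survivor(
            rec.next_scheduled_time, spec, ipred_path
        )
    s_next = survivor(rec.next_scheduled_time, spec, ipred_path)
    if s_next > s_last + 1e-12:
        raise RuntimeError("survivor is not non-increasing (integration bug)")
    return float(s_last - s_next)


def sample_dropout_time(
    spec: HazardSpec,
    grid: np.ndarray,
    ipred: np.ndarray,
    horizon: float,
    rng: np.random.Generator,
):
    """Inverse-CDF dropout times on the piecewise-constant hazard grid.

    ``grid``/``ipred`` follow :func:`piecewise_cumulative_hazard`; ``ipred``
    may be 2-D (subjects x grid) to sample a cohort at once.  Returns an
    array of times (weeks) with ``np.inf`` for subjects retained beyond the
    horizon (or a scalar for 1-D input).
    """
    if horizon <= 0:
        raise ValueError("horizon must be > 0")
    grid = np.asarray(grid, dtype=float)
    ipred2 = np.atleast_2d(np.asarray(ipred, dtype=float))
    n, m = ipred2.shape
    mult = np.exp(spec.beta2 * ipred2[:, :-1])
    t0, t1 = grid[:-1], grid[1:]
    if spec.form == "constant":
        base = spec.beta0 * (t1 - t0)
    elif spec.form == "exponential":
        base = spec.beta0 / spec.shape * np.diff(np.exp(spec.shape * grid))
    else:
        base = spec.beta0 * np.diff(grid**spec.shape)
    seg = base[None, :] * mult
    H = np.concatenate([np.zeros((n, 1)), np.cumsum(seg, axis=1)], axis=1)
    lam = seg / np.diff(grid)[None, :]  # effective rate per interval
    target = -np.log(rng.uniform(size=n))
    inside = target < H[:, -1]
    # first grid point whose cumulative hazard exceeds the target
    k = np.argmax(H > target[:, None], axis=1) - 1
    k = np.clip(k, 0, m - 2)
    rows = np.arange(n)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = grid[k] + (target - H[rows, k]) / lam[rows, k]
    times = np.where(inside & (t <= horizon), t, np.inf)
    return times if np.asarray(ipred).ndim == 2 else float(times[0])
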