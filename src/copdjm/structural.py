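"""Structural disease-progression and drug-effect model.

FEV1 follows an indirect-response (turnover) model

    dFEV1/dt = Kin(t) - Kout(t) * FEV1,

where the disease status ``Dis(t) = Int_Dis + Slope_Dis * t`` (liters; a
negative slope is decline) ties the two rate constants together through
``Dis = Kin / Kout``: Kin is the structural parameter and
``Kout(t) = Kin / Dis(t)`` is derived.  Bronchodilator effect enters through
a KPD (kinetic-pharmacodynamic) exposure ``A(t)`` driven by dose with
first-order loss KDE, acting through an Emax function; in the final model it
multiplies Kin:  ``Kin(t) = Kin * (1 + Emax*A/(EDK50+A))``.

The trajectory solver provides both a closed-form piecewise solution (drug
effect held constant between visits, Dis linear in time) and an adaptive
numeric integrator; the two agree to well below the residual error and are
cross-checked in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .parameters import (
    CovariateEffect,
    CovariateVector,
    DoseRegimen,
    IndividualParameters,
    PopulationParameters,
)

__all__ = [
    "TrajectoryPoint",
    "apply_covariates",
    "apply_iiv",
    "disease_status",
    "drug_effect",
    "exposure",
    "residual_error",
    "solve_fev1",
    "trajectory_frame",
]

DRUG_EFFECT_MODES = (
    "additive_kin",
    "multiplicative_kin",
    "additive_kout",
    "multiplicative_kout",
)


@dataclass(frozen=True)
class TrajectoryPoint:
    time: float  # days
    dis: float  # L
    exposure: float  # micrograms
    kout: float  # 1/day
    ipred: float  # L, noise-free FEV1


def disease_status(t, int_dis: float, slope_dis: float):
    """Dis(t) = Int_Dis + Slope_Dis * t  (L); raises if it is not positive."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be >= 0")
    dis = int_dis + slope_dis * t
    if np.any(dis <= 0):
        raise ValueError("disease status must stay positive over the horizon")
    return dis if dis.ndim else float(dis)


def exposure(
    t,
    regimen: DoseRegimen,
    kde: float,
    parameterisation: str = "a",
    predose: bool = False,
) -> np.ndarray:
    """KPD exposure marker A(t) for a repeated-dose regimen.

    Parameterisations: (a) the superposed amount ``Dose*exp(-KDE*dt)`` over
    all administered doses; (b) the dose itself while dosing is active;
    (c) the input rate ``KDE * D(t)`` with D the superposed decaying dose.
    ``predose=True`` excludes a dose administered exactly at ``t`` (trough
    convention used for visits).
    """
    if kde <= 0:
        raise ValueError("kde must be > 0")
    if parameterisation not in ("a", "b", "c"):
        raise ValueError(f"unknown exposure parameterisation {parameterisation!r}")
    t = np.atleast_1d(np.asarray(t, dtype=float))
    if np.any(t < regimen.start_time):
        raise ValueError("t must be >= regimen.start_time")
    if regimen.is_placebo:
        return np.zeros_like(t)

    tau = regimen.interval_days
    rel = (t - regimen.start_time) / tau
    if parameterisation == "b":
        active = (rel > 0) if predose else (rel >= 0)
        active &= t <= regimen.end_time
        return np.where(active, regimen.dose_amount, 0.0)

    # number of administered doses contributing at t
    if predose:
        n = np.ceil(rel - 1e-9)
    else:
        n = np.floor(rel + 1e-9) + 1
    if np.isfinite(regimen.end_time):
        n_max = np.floor((regimen.end_time - regimen.start_time) / tau + 1e-9) + 1
        n = np.minimum(n, n_max)
    n = np.maximum(n, 0.0)
    t_last = regimen.start_time + (n - 1) * tau  # most recent dose
    with np.errstate(invalid="ignore"):
        amt = (
            regimen.dose_amount
            * np.exp(-kde * (t - t_last))
            * np.expm1(-kde * n * tau)
            / np.expm1(-kde * tau)
        )
    amt = np.where(n > 0, amt, 0.0)
    return amt * kde if parameterisation == "c" else amt


def drug_effect(a, emax: float, edk50: float):
    """Saturable Emax effect term ``Emax * A / (EDK50 + A)``."""
    a = np.asarray(a, dtype=float)
    if np.any(a < 0):
        raise ValueError("exposure must be >= 0")
    if edk50 <= 0:
        raise ValueError("edk50 must be > 0")
    out = emax * a / (edk50 + a)
    return out if out.ndim else float(out)


def exposure_grid(
    times: np.ndarray,
    dose_amount: np.ndarray,
    interval_h: float,
    kde: np.ndarray,
    parameterisation: str = "a",
) -> np.ndarray:
    """Pre-dose (trough) exposure at visit ``times`` for a cohort.

    Broadcast form of :func:`exposure` used by the likelihood engine:
    ``dose_amount`` and ``kde`` are per-subject (n,), ``times`` (m,) days;
    dosing starts at t=0 and continues through the horizon.  Returns (n, m).
    """
    times = np.asarray(times, dtype=float)
    dose_amount = np.asarray(dose_amount, dtype=float)[:, None]
    kde = np.asarray(kde, dtype=float)[:, None]
    tau = interval_h / 24.0
    if parameterisation == "b":
        return np.where((times[None, :] > 0), dose_amount, 0.0) * np.ones_like(kde)
    if parameterisation not in ("a", "c"):
        raise ValueError(f"unknown exposure parameterisation {parameterisation!r}")
    n_doses = np.maximum(np.ceil(times / tau - 1e-9), 0.0)[None, :]
    dt_last = times[None, :] - (n_doses - 1) * tau
    with np.errstate(invalid="ignore"):
        amt = (
            dose_amount
            * np.exp(-kde * dt_last)
            * np.expm1(-kde * n_doses * tau)
            / np.expm1(-kde * tau)
        )
    amt = np.where(n_doses > 0, amt, 0.0)
    return amt * kde if parameterisation == "c" else amt


# ---------------------------------------------------------------------------
# Covariate and IIV submodels
# ---------------------------------------------------------------------------

_BASE_PARAMS = ("kin", "int_dis", "slope_dis", "emax", "edk50", "kde")


def _base_typicals(pop: PopulationParameters) -> dict[str, float]:
    return {
        "kin": pop.tv_kin,
        "int_dis": pop.tv_int_dis,
        "slope_dis": pop.tv_slope_dis,
        "emax": pop.tv_emax,
        "edk50": pop.tv_edk50,
        "kde": pop.kde,
    }


def covariate_multipliers(
    effects: list[CovariateEffect], cov: pd.DataFrame
) -> dict[str, np.ndarray]:
    """Per-parameter multiplicative covariate factor for a numeric cohort
    table (categoricals encoded as 0/1 non-reference indicators)."""
    n = len(cov)
    mult: dict[str, np.ndarray] = {}
    for eff in effects:
        if eff.covariate_name not in cov.columns:
            raise KeyError(f"covariate {eff.covariate_name!r} missing from data")
        x = cov[eff.covariate_name].to_numpy(dtype=float)
        if eff.kind == "power":
            if np.any(x <= 0):
                raise ValueError(
                    f"non-positive {eff.covariate_name} with a power effect"
                )
            f = (x / eff.reference_value) ** eff.theta
        else:
            f = np.where(x > 0, eff.theta, 1.0)
        mult[eff.target_parameter] = mult.get(eff.target_parameter, np.ones(n)) * f
    return mult


def typical_values(
    pop: PopulationParameters, cov: pd.DataFrame
) -> dict[str, np.ndarray]:
    """Covariate-adjusted typical values for every subject (vectorised)."""
    n = len(cov)
    base = _base_typicals(pop)
    mult = covariate_multipliers(pop.covariate_effects, cov)
    return {p: np.full(n, base[p]) * mult.get(p, 1.0) for p in _BASE_PARAMS}


def apply_covariates(
    pop: PopulationParameters, cov: CovariateVector
) -> dict[str, float]:
    """Typical parameter values for one subject.

    Continuous covariates enter as ``(value/reference)**theta``; categorical
    covariates multiply by theta for the non-reference category; several
    effects on one parameter multiply.  EDK50's typical value is tied to the
    raw typical Emax through the estimated ratio and does not inherit Emax's
    covariate effects.
    """
    names = {e.covariate_name for e in pop.covariate_effects}
    row = pd.DataFrame({name: [cov.value(name)] for name in names}, index=[0])
    vals = typical_values(pop, row)
    return {p: float(v[0]) for p, v in vals.items()}


def apply_iiv(
    typical: dict[str, float],
    etas: dict[str, float],
    omega: dict[str, dict[str, float]] | None = None,
) -> IndividualParameters:
    """P_i = TVP * exp(eta) for parameters carrying IIV; others pass through.

    When ``omega`` is given, an eta supplied for a parameter without a
    positive variance is an error (flagged, not silently ignored).
    """
    if omega is not None:
        for name in etas:
            if omega.get(name, {}).get(name, 0.0) <= 0:
                raise ValueError(f"eta supplied for {name!r} which has no IIV")
    vals = dict(typical)
    for name, eta in etas.items():
        if name not in vals:
            raise KeyError(f"unknown parameter {name!r}")
        vals[name] = vals[name] * np.exp(eta)
    return IndividualParameters(
        kin_i=vals["kin"],
        int_dis_i=vals["int_dis"],
        slope_dis_i=vals["slope_dis"],
        emax_i=vals["emax"],
        edk50_i=vals["edk50"],
        kde_i=vals["kde"],
        etas=dict(etas),
    )


# ---------------------------------------------------------------------------
# Trajectory solver
# ---------------------------------------------------------------------------


def _segment_step(f0, t0, t1, a, b, inp, k):
    """Advance F' = inp - (k / (a + b t)) * F from t0 to t1 (all array-like).

    ``inp`` (the zero-order input, L/day) and ``k`` (the Kout numerator,
    L/day) are held constant on the segment; Dis = a + b t stays linear.
    """
    f0, a, b, inp, k = np.broadcast_arrays(
        *(np.asarray(x, dtype=float) for x in (f0, a, b, inp, k))
    )
    d0 = a + b * t0
    d1 = a + b * t1
    if np.any(d0 <= 0) or np.any(d1 <= 0):
        raise ValueError("disease status must stay positive on the segment")
    dt = t1 - t0
    out = np.empty_like(f0)

    flat = np.abs(b) * dt < 1e-12 * d0  # constant-coefficient limit
    if np.any(flat):
        kk = k[flat] / d0[flat]
        fss = inp[flat] / kk
        out[flat] = fss + (f0[flat] - fss) * np.exp(-kk * dt)
    gen = ~flat
    if np.any(gen):
        c = k[gen] / b[gen]
        r = d0[gen] / d1[gen]
        rc = np.exp(c * np.log(r))
        cp1 = c + 1.0
        main = np.abs(cp1) > 1e-8
        res = np.empty(c.shape)
        res[main] = f0[gen][main] * rc[main] + inp[gen][main] / (
            b[gen][main] * cp1[main]
        ) * (d1[gen][main] - d0[gen][main] * rc[main])
        if np.any(~main):  # k == -b: integrating factor is 1/Dis
            i = ~main
            res[i] = (d1[gen][i] / d0[gen][i]) * f0[gen][i] + d1[gen][i] * inp[gen][
                i
            ] / b[gen][i] * np.log(d1[gen][i] / d0[gen][i])
        out[gen] = res
    return out


def _input_and_kout_numerator(kin, effect, mode: str):
    """Map the drug-effect term onto (input, Kout numerator) per mode."""
    one = np.ones_like(np.asarray(kin, dtype=float) * np.asarray(effect, dtype=float))
    if mode == "multiplicative_kin":
        return kin * (1.0 + effect), kin * one
    if mode == "additive_kin":
        return kin + effect, kin * one
    if mode == "multiplicative_kout":
        return kin * one, kin * (1.0 + effect)
    raise ValueError(f"no closed form for drug-effect mode {mode!r}")


def solve_fev1_grid(
    times: np.ndarray,
    int_dis: np.ndarray,
    slope_dis: np.ndarray,
    kin: np.ndarray,
    effect: np.ndarray,
    mode: str = "multiplicative_kin",
) -> np.ndarray:
    """Vectorised closed-form FEV1 at grid ``times`` (days) for a cohort.

    ``effect[:, j]`` is the drug-effect term in force on the segment ending
    at ``times[j]`` (the trough convention: exposure evaluated at the right
    endpoint); FEV1(0) = Dis(0) (pre-treatment steady state).  Shapes:
    times (m,), parameters (n,), effect (n, m); returns (n, m).
    """
    times = np.asarray(times, dtype=float)
    n = len(int_dis)
    m = len(times)
    out = np.empty((n, m))
    if times[0] != 0.0:
        raise ValueError("grid must start at t=0")
    out[:, 0] = int_dis  # baseline steady state, Dis(0)
    f = out[:, 0].copy()
    for j in range(1, m):
        inp, k = _input_and_kout_numerator(kin, effect[:, j], mode)
        f = _segment_step(f, times[j - 1], times[j], int_dis, slope_dis, inp, k)
        out[:, j] = f
    return out


def _solve_numeric(times, int_dis, slope_dis, kin, effect, mode):
    """Adaptive-integrator fallback for one subject (same piecewise model)."""
    f = np.empty(len(times))
    f[0] = int_dis
    cur = float(int_dis)
    for j in range(1, len(times)):
        e = float(effect[j])

        def rhs(t, y):
            dis = int_dis + slope_dis * t
            kout = kin / dis
            if mode == "multiplicative_kin":
                return kin * (1.0 + e) - kout * y
            if mode == "additive_kin":
                return kin + e - kout * y
            if mode == "multiplicative_kout":
                return kin - kout * (1.0 + e) * y
            if mode == "additive_kout":
                return kin - (kout + e) * y
            raise ValueError(f"unknown drug-effect mode {mode!r}")

        sol = solve_ivp(
            rhs,
            (times[j - 1], times[j]),
            [cur],
            rtol=1e-10,
            atol=1e-12,
            method="LSODA",
        )
        if not sol.success:
            raise RuntimeError(f"integrator failed on segment {j}: {sol.message}")
        cur = float(sol.y[0, -1])
        f[j] = cur
    return f


def solve_fev1(
    indiv: IndividualParameters,
    regimen: DoseRegimen,
    times,
    mode: str = "multiplicative_kin",
    parameterisation: str = "a",
    method: str = "closed_form",
) -> list[TrajectoryPoint]:
    """FEV1 trajectory of one subject at visit ``times`` (days, sorted,
    starting at 0).  Visits are pre-dose: exposure is the trough of the
    regimen; the drug effect is held constant on each inter-visit segment.
    """
    times = np.asarray(times, dtype=float)
    if times.ndim != 1 or len(times) == 0:
        raise ValueError("times must be a non-empty 1-D array")
    if np.any(np.diff(times) <= 0) or times[0] < 0:
        raise ValueError("times must be strictly increasing and >= 0")
    if times[0] != 0.0:
        times = np.concatenate([[0.0], times])
        added = 1
    else:
        added = 0
    if mode not in DRUG_EFFECT_MODES:
        raise ValueError(f"unknown drug-effect mode {mode!r}")

    a = exposure(times, regimen, indiv.kde_i, parameterisation, predose=True)
    eff = drug_effect(a, indiv.emax_i, indiv.edk50_i)
    dis = disease_status(times, indiv.int_dis_i, indiv.slope_dis_i)

    if method == "closed_form" and mode != "additive_kout":
        f = solve_fev1_grid(
            times,
            np.array([indiv.int_dis_i]),
            np.array([indiv.slope_dis_i]),
            np.array([indiv.kin_i]),
            eff[None, :],
            mode,
        )[0]
    elif method in ("closed_form", "numeric"):
        f = _solve_numeric(
            times, indiv.int_dis_i, indiv.slope_dis_i, indiv.kin_i, eff, mode
        )
    else:
        raise ValueError(f"unknown method {method!r}")

    pts = [
        TrajectoryPoint(
            time=float(t),
            dis=float(d),
            exposure=float(av),
            kout=float(indiv.kin_i / d),
            ipred=float(fv),
        )
        for t, d, av, fv in zip(times, dis, a, f)
    ]
    return pts[added:]


def trajectory_frame(points: list[TrajectoryPoint], subject_id=1) -> pd.DataFrame:
    """Tidy trajectory export: ID, TIME, DIS, A, KOUT, IPRED."""
    return pd.DataFrame(
        {
            "ID": subject_id,
            "TIME": [p.time for p in points],
            "DIS": [p.dis for p in points],
            "A": [p.exposure for p in points],
            "KOUT": [p.kout for p in points],
            "IPRED": [p.ipred for p in points],
        }
    )


def residual_error(
    ipred,
    sigma_add: float,
    sigma_prop: float,
    eps,
    model: str = "additive",
):
    """Observed FEV1 from the noise-free prediction.

    additive:      Y = IPRED + sigma_add * eps
    proportional:  Y = IPRED * (1 + sigma_prop * eps)
    combined:      Y = IPRED * (1 + sigma_prop * eps[..., 0]) + sigma_add * eps[..., 1]
    """
    if sigma_add < 0 or sigma_prop < 0:
        raise ValueError("residual SDs must be >= 0")
    ipred = np.asarray(ipred, dtype=float)
    if np.any(ipred < 0):
        raise ValueError("ipred must be >= 0")
    eps = np.asarray(eps, dtype=float)
    if model == "additive":
        out = ipred + sigma_add * eps
    elif model == "proportional":
        out = ipred * (1.0 + sigma_prop * eps)
    elif model == "combined":
        if eps.shape[-1] != 2:
            raise ValueError("combined model needs eps with last dimension 2")
        out = ipred * (1.0 + sigma_prop * eps[..., 0]) + sigma_add * eps[..., 1]
    else:
        raise ValueError(f"unknown residual model {model!r}")
    return out if out.ndim else float(out)
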