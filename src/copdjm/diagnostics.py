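"""Model evaluation: dropout-aware VPC, Kaplan-Meier overlays, NPDE and
goodness-of-fit tables.

The VPC re-simulates full replicate trials — trajectories, residual error
AND dropout — for the observed cohort (same covariates, same arms), so the
percentile envelopes carry the same censoring process as the data.  NPDE
follows the simulation-based decorrelation construction: each subject's
observed vector is whitened with the mean and Cholesky factor of its
simulated replicates, ranked against the equally-whitened replicates and
mapped through the standard-normal quantile; under a correct model the
values are N(0, 1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import solve_triangular
from scipy.stats import kstest, norm

from .data import LongitudinalDataset
from .dropout import DropoutRecord
from .model import FitConfig, JointFEV1Model, JointFEV1Results
from .parameters import PopulationParameters
from .simulate import TrialDesign, simulate_trial

__all__ = ["NpdeResult", "VpcResult", "gof_tables", "kaplan_meier", "npde", "vpc"]

_STRATA_SOURCES = ("arm", "severity", "reversibility", "pics")


@dataclass
class VpcResult:
    """Observed percentiles and simulation envelopes per stratum and bin."""

    table: pd.DataFrame  # stratum, time, obs_p*, sim_p*_lo/md/hi, n_obs
    n_sim: int
    seed: int
    strata: tuple[str, ...]

    def to_frame(self) -> pd.DataFrame:
        return self.table.copy()

    def plot(self, ax=None):
        import matplotlib.pyplot as plt

        groups = list(self.table.groupby("stratum"))
        if ax is None:
            _, axes = plt.subplots(1, len(groups), figsize=(4 * len(groups), 3.2),
                                   squeeze=False)
            axes = axes[0]
        else:
            axes = [ax] * len(groups)
        for axis, (label, g) in zip(axes, groups):
            t = g["time"] / 7.0
            for p in (5, 50, 95):
                axis.fill_between(t, g[f"sim_p{p}_lo"], g[f"sim_p{p}_hi"],
                                  alpha=0.25, color="C0")
                axis.plot(t, g[f"obs_p{p}"], "k.-" if p == 50 else "k--", lw=1)
            axis.set_xlabel("time (weeks)")
            axis.set_ylabel("trough FEV1 (L)")
            axis.set_title(str(label))
        return axes


def _stratum_labels(packed, strata: tuple[str, ...]) -> np.ndarray:
    parts = []
    for s in strata:
        if s == "arm":
            parts.append(packed.arm.astype(str))
        elif s in _STRATA_SOURCES:
            flag = packed.covariates[s].to_numpy() > 0
            parts.append(np.where(flag, s, f"non-{s}"))
        else:
            raise ValueError(f"unknown stratification variable {s!r}")
    if not parts:
        return np.full(len(packed.ids), "all")
    out = parts[0]
    for p in parts[1:]:
        out = np.char.add(np.char.add(out.astype(str), "/"), p.astype(str))
    return out


def _bin_percentiles(y: np.ndarray, labels: np.ndarray, uniq) -> np.ndarray:
    """(stratum, time, percentile) percentile array with NaN for empty bins."""
    out = np.full((len(uniq), y.shape[1], 3), np.nan)
    for i, lab in enumerate(uniq):
        sub = y[labels == lab]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            out[i] = np.nanpercentile(sub, [5, 50, 95], axis=0).T
    return out


def vpc(
    data: LongitudinalDataset,
    pop: PopulationParameters,
    design: TrialDesign,
    n_sim: int = 200,
    strata: tuple[str, ...] = ("arm",),
    seed: int = 0,
) -> VpcResult:
    """Dropout-aware visual predictive check on the visit-time bins."""
    if n_sim < 100:
        raise ValueError("n_sim must be >= 100")
    packed = data.to_packed()
    labels = _stratum_labels(packed, strata)
    uniq = sorted(set(labels))
    obs = _bin_percentiles(packed.y, labels, uniq)
    empty = np.isnan(obs[:, :, 1])
    if empty.any():
        warnings.warn(
            f"{int(empty.sum())} stratum/time bins contain no observations",
            stacklevel=2,
        )
    rng = np.random.default_rng(seed)
    sims = np.empty((n_sim,) + obs.shape)
    for r in range(n_sim):
        rep = simulate_trial(
            pop, design, seed=int(rng.integers(2**31)),
            covariates=packed.covariates, arm_labels=packed.arm,
        ).to_packed()
        sims[r] = _bin_percentiles(rep.y, labels, uniq)
    lo = np.nanpercentile(sims, 2.5, axis=0)
    md = np.nanpercentile(sims, 50.0, axis=0)
    hi = np.nanpercentile(sims, 97.5, axis=0)

    rows = []
    for i, lab in enumerate(uniq):
        for j, t in enumerate(packed.times):
            row = {"stratum": lab, "time": t,
                   "n_obs": int(np.isfinite(packed.y[labels == lab, j]).sum())}
            for k, p in enumerate((5, 50, 95)):
                row[f"obs_p{p}"] = obs[i, j, k]
                row[f"sim_p{p}_lo"] = lo[i, j, k]
                row[f"sim_p{p}_md"] = md[i, j, k]
                row[f"sim_p{p}_hi"] = hi[i, j, k]
            rows.append(row)
    return VpcResult(pd.DataFrame(rows), n_sim, seed, strata)


def kaplan_meier(events, horizon: float | None = None) -> pd.DataFrame:
    """Product-limit dropout-survival table (time, at_risk, events,
    survival) from DropoutRecords or raw dropout times (weeks; ``inf`` or
    times beyond ``horizon`` are censored at the horizon)."""
    from lifelines import KaplanMeierFitter

    if len(events) == 0:
        raise ValueError("empty cohort")
    if isinstance(events[0], DropoutRecord):
        durations = np.array([r.next_scheduled_time for r in events])
        observed = np.array([r.event == "dropped" for r in events])
    else:
        t = np.asarray(events, dtype=float)
        if horizon is None:
            horizon = np.nanmax(t[np.isfinite(t)]) if np.isfinite(t).any() else 1.0
        observed = np.isfinite(t) & (t <= horizon)
        durations = np.where(observed, t, horizon)
    km = KaplanMeierFitter()
    km.fit(durations, event_observed=observed)
    table = km.event_table
    return pd.DataFrame(
        {
            "time": table.index.to_numpy(dtype=float),
            "at_risk": table["at_risk"].to_numpy(),
            "events": table["observed"].to_numpy(),
            "survival": km.survival_function_["KM_estimate"].to_numpy(),
        }
    )


@dataclass
class NpdeResult:
    values: pd.DataFrame  # ID, TIME, npde
    mean: float
    variance: float
    ks_stat: float
    ks_pvalue: float


def npde(
    data: LongitudinalDataset,
    pop: PopulationParameters,
    design: TrialDesign,
    n_rep: int = 1000,
    seed: int = 0,
) -> NpdeResult:
    """Normalised prediction distribution errors (simulation-based).

    ``n_rep`` replicate trials are simulated for the observed cohort
    (without dropout truncation — each subject is compared at its own
    observed times); ranks use the empirical replicate distribution with a
    1/(2K) continuity correction so the normal quantile stays finite.
    """
    if n_rep < 500:
        raise ValueError("n_rep must be >= 500")
    packed = data.to_packed()
    n, m = packed.y.shape
    rng = np.random.default_rng(seed)
    sims = np.empty((n_rep, n, m))
    from .simulate import simulate_structural, _residual_draws

    omega = pop.omega_matrix()
    q = omega.shape[0]
    for r in range(n_rep):
        etas = (
            rng.multivariate_normal(np.zeros(q), omega, size=n, method="cholesky")
            if q
            else np.zeros((n, 0))
        )
        ipred = simulate_structural(
            pop, packed.times, packed.covariates, packed.dose_amount,
            packed.dose_interval, etas,
        )
        sims[r] = _residual_draws(ipred, pop, rng)

    rows = []
    vals = []
    for i in range(n):
        obs_idx = np.where(np.isfinite(packed.y[i]))[0]
        d = len(obs_idx)
        yi = packed.y[i, obs_idx]
        si = sims[:, i, obs_idx]  # (K, d)
        mu = si.mean(axis=0)
        cov = np.cov(si, rowvar=False).reshape(d, d)
        try:
            L = np.linalg.cholesky(cov)
        except np.linalg.LinAlgError:
            warnings.warn(f"singular simulated covariance for subject "
                          f"{packed.ids[i]}; regularised", stacklevel=2)
            L = np.linalg.cholesky(cov + 1e-8 * np.eye(d))
        y_star = solve_triangular(L, yi - mu, lower=True)
        s_star = solve_triangular(L, (si - mu).T, lower=True)  # (d, K)
        pde = (s_star < y_star[:, None]).mean(axis=1)
        pde += 0.5 * (s_star == y_star[:, None]).mean(axis=1)
        pde = np.clip(pde, 1.0 / (2 * n_rep), 1.0 - 1.0 / (2 * n_rep))
        z = norm.ppf(pde)
        vals.append(z)
        for j, k in enumerate(obs_idx):
            rows.append((packed.ids[i], packed.times[k], z[j]))

    allv = np.concatenate(vals)
    ks = kstest(allv, "norm")
    return NpdeResult(
        values=pd.DataFrame(rows, columns=["ID", "TIME", "npde"]),
        mean=float(allv.mean()),
        variance=float(allv.var(ddof=1)),
        ks_stat=float(ks.statistic),
        ks_pvalue=float(ks.pvalue),
    )


def gof_tables(
    model_or_data,
    results: JointFEV1Results | None = None,
    pop: PopulationParameters | None = None,
) -> pd.DataFrame:
    """Per-observation goodness-of-fit table: PRED (eta-at-zero), IPRED
    (empirical-Bayes), RES = DV - PRED and IWRES = (DV - IPRED)/sigma."""
    if isinstance(model_or_data, JointFEV1Model):
        model = model_or_data
        pop = results.population if results is not None else (pop or model.population)
    else:
        model = JointFEV1Model(model_or_data, pop, FitConfig(free=()))
    q = len(model.eta_names)
    if results is not None and results.eta_hat.shape == (model.n, q):
        eta = results.eta_hat
    elif q:
        _, eta = model.marginal_loglik(pop)
    else:
        eta = np.zeros((model.n, 0))
    ipred = _ipred_matrix(model, pop, eta)
    pred = _ipred_matrix(model, pop, np.zeros_like(eta))
    sd = np.sqrt(pop.sigma_add**2 + (pop.sigma_prop * ipred) ** 2)
    rows = []
    for i in range(model.n):
        for j in np.where(model.mask[i])[0]:
            dv = model.y[i, j]
            rows.append(
                (
                    model.packed.ids[i],
                    model.times[j],
                    dv,
                    pred[i, j],
                    ipred[i, j],
                    dv - pred[i, j],
                    (dv - ipred[i, j]) / sd[i, j] if sd[i, j] > 0 else np.nan,
                )
            )
    return pd.DataFrame(
        rows, columns=["ID", "TIME", "DV", "PRED", "IPRED", "RES", "IWRES"]
    )


def _ipred_matrix(model: JointFEV1Model, pop, etas) -> np.ndarray:
    from .simulate import simulate_structural

    p = model.packed
    return simulate_structural(
        pop, p.times, p.covariates, p.dose_amount, p.dose_interval, etas
    )
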