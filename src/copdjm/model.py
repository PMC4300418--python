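"""Joint estimation of the FEV1 progression and dropout models.

`JointFEV1Model` holds one trial dataset plus a template
:class:`~copdjm.parameters.PopulationParameters` (initial values for free
parameters, fixed values for the rest) and a :class:`FitConfig` naming the
free parameters.  ``fit()`` minimises

    MOFV = -2 * sum_i log L_i(theta)  [+ prior penalty]

where each subject's marginal likelihood integrates the lognormal random
effects out by the Laplace approximation, and the subject likelihood joins
the Gaussian residual density of the observed FEV1 with the interval
probability of the subject's dropout/completion status.  Free parameters
are optimised on transformed scales (log for positive quantities), so the
fit is unconstrained and invariant to reasonable starting points.

The per-subject conditional likelihood is evaluated for the whole cohort at
once (closed-form trajectory solution), which keeps a 2000-subject joint
fit within minutes on one core.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .data import LongitudinalDataset, _Packed
from .laplace import batched_laplace
from .parameters import (
    CovariateEffect,
    PopulationParameters,
    PriorSpec,
)
from .priors import prior_penalty
from .structural import exposure_grid, solve_fev1_grid, typical_values

__all__ = [
    "FitConfig",
    "JointFEV1Model",
    "JointFEV1Results",
    "ScmResult",
    "bootstrap",
    "covariate_step",
    "get_param",
    "individual_joint_loglik",
    "laplace_marginal_loglik",
    "set_params",
]

_LOG2PI = float(np.log(2.0 * np.pi))
_HAZARD_FIELDS = ("beta0", "beta1", "beta2", "shape")
_LOG_PARAMS = {
    "tv_kin",
    "tv_int_dis",
    "tv_emax",
    "ratio_edk50_emax",
    "kde",
    "sigma_add",
    "sigma_prop",
    "beta0",
    "shape",
}
_ID_PARAMS = {"tv_slope_dis", "beta1", "beta2"}


# ---------------------------------------------------------------------------
# named-parameter access on PopulationParameters
# ---------------------------------------------------------------------------


def _find_effect(pop: PopulationParameters, cov_name: str, target: str) -> int:
    for i, e in enumerate(pop.covariate_effects):
        if e.covariate_name == cov_name and e.target_parameter == target:
            return i
    raise KeyError(f"no covariate effect cov:{cov_name}:{target}")


def get_param(pop: PopulationParameters, name: str) -> float:
    """Value of a named parameter (``tv_*``, ``sigma_*``, ``kde``,
    ``ratio_edk50_emax``, ``beta*``, ``shape``, ``omega_<p>`` variances,
    ``cov:<covariate>:<parameter>`` thetas)."""
    if name in _HAZARD_FIELDS:
        return getattr(pop.hazard, name)
    if name.startswith("omega_"):
        p = name[len("omega_"):]
        return pop.omega[p][p]
    if name.startswith("cov:"):
        _, cn, tp = name.split(":")
        return pop.covariate_effects[_find_effect(pop, cn, tp)].theta
    return getattr(pop, name)


def set_params(pop: PopulationParameters, updates: dict[str, float]) -> PopulationParameters:
    """New PopulationParameters with the named values replaced."""
    kwargs: dict = {}
    hz: dict = {}
    omega = None
    effects = None
    for name, v in updates.items():
        if name in _HAZARD_FIELDS:
            hz[name] = float(v)
        elif name.startswith("omega_"):
            if omega is None:
                omega = {p: dict(row) for p, row in (pop.omega or {}).items()}
            p = name[len("omega_"):]
            omega.setdefault(p, {})[p] = float(v)
        elif name.startswith("cov:"):
            if effects is None:
                effects = list(pop.covariate_effects)
            _, cn, tp = name.split(":")
            i = _find_effect(pop, cn, tp)
            effects[i] = dataclasses.replace(effects[i], theta=float(v))
        else:
            kwargs[name] = float(v)
    if hz:
        kwargs["hazard"] = dataclasses.replace(pop.hazard, **hz)
    if omega is not None:
        kwargs["omega"] = omega
    if effects is not None:
        kwargs["covariate_effects"] = effects
    return pop.replace(**kwargs)


def _is_log_scale(name: str, pop: PopulationParameters) -> bool:
    if name in _LOG_PARAMS or name.startswith("omega_"):
        return True
    if name in _ID_PARAMS:
        return False
    if name.startswith("cov:"):
        _, cn, tp = name.split(":")
        eff = pop.covariate_effects[_find_effect(pop, cn, tp)]
        return eff.kind == "multiplicative"  # power exponents are unconstrained
    raise KeyError(f"unknown parameter {name!r}")


# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FitConfig:
    """Which parameters are estimated and how the likelihood is assembled.

    The default frees the recovery set: baseline intercept, Emax, additive
    residual SD, the two dropout coefficients and the two dominant IIV
    variances, with kde and the EDK50/Emax ratio fixed (single active dose
    level leaves them unidentified without a prior).
    """

    free: tuple[str, ...] = (
        "tv_int_dis",
        "tv_emax",
        "sigma_add",
        "beta0",
        "beta2",
        "omega_int_dis",
        "omega_emax",
    )
    include_dropout: bool = True
    prior: PriorSpec | None = None


class JointFEV1Model:
    """Joint longitudinal + dropout model bound to one trial dataset."""

    def __init__(
        self,
        data: LongitudinalDataset | pd.DataFrame | _Packed,
        population: PopulationParameters,
        config: FitConfig | None = None,
    ):
        if isinstance(data, pd.DataFrame):
            data = LongitudinalDataset(data)
        if isinstance(data, LongitudinalDataset):
            self.data = data
            packed = data.to_packed()
        else:
            self.data = None
            packed = data
        self.packed = packed
        self.population = population
        self.config = config or FitConfig()
        for name in self.config.free:
            get_param(population, name)  # fail fast on unknown names

        self.eta_names = list(population.iiv_parameters())
        p = packed
        self.times = p.times
        self.weeks = p.times / 7.0
        self.y = p.y
        self.mask = np.isfinite(p.y)
        self.n, self.m = p.y.shape
        self.nobs = int(self.mask.sum())
        self._eta_cache = self._initial_etas(population)
        self.n_laplace_failures = 0

    def _initial_etas(self, pop: PopulationParameters) -> np.ndarray:
        """Warm start for the inner optimisation: the baseline observation
        pins eta on Int_Dis (FEV1(0) = Int_Dis_i), other etas start at 0."""
        eta = np.zeros((self.n, len(self.eta_names)))
        if "int_dis" in self.eta_names and self.m:
            typ = typical_values(pop, self.packed.covariates)["int_dis"]
            y0 = self.y[:, 0]
            with np.errstate(invalid="ignore", divide="ignore"):
                guess = np.log(np.where(y0 > 0.05, y0, typ) / typ)
            guess = np.clip(np.nan_to_num(guess), -3.0, 3.0)
            eta[:, self.eta_names.index("int_dis")] = guess
        return eta

    @classmethod
    def from_csv(
        cls, path, population: PopulationParameters, config: FitConfig | None = None
    ) -> "JointFEV1Model":
        return cls(LongitudinalDataset.read(path), population, config)

    # -- likelihood --------------------------------------------------------

    def _conditional_loglik_fn(self, pop: PopulationParameters):
        """Per-subject log p(y, dropout | eta) as a function of the (n, q)
        eta matrix; everything eta-independent is precomputed here."""
        if pop.drug_effect_mode not in ("multiplicative_kin", "additive_kin",
                                        "multiplicative_kout"):
            raise ValueError(
                f"estimation supports closed-form drug-effect modes only, "
                f"not {pop.drug_effect_mode!r}"
            )
        if pop.sigma_add <= 0 and pop.sigma_prop <= 0:
            raise ValueError("zero residual variance with nonzero residuals")
        p = self.packed
        typ = typical_values(pop, p.covariates)
        names = self.eta_names
        kde_eta = "kde" in names
        A0 = None
        if not kde_eta:
            A0 = exposure_grid(
                self.times, p.dose_amount, p.dose_interval, typ["kde"],
                pop.exposure_parameterisation,
            )
        spec = pop.hazard
        base_seg = self._base_hazard_segments(spec)
        sa, sp = pop.sigma_add, pop.sigma_prop
        y, mask = self.y, self.mask
        times = self.times
        mode = pop.drug_effect_mode
        end = times[-1]

        def loglik(etas: np.ndarray) -> np.ndarray:
            vals = {}
            for par in ("int_dis", "slope_dis", "kin", "emax", "edk50", "kde"):
                v = typ[par]
                if par in names:
                    v = v * np.exp(np.clip(etas[:, names.index(par)], -60.0, 60.0))
                vals[par] = v
            A = A0
            if kde_eta:
                A = exposure_grid(
                    times, p.dose_amount, p.dose_interval, vals["kde"],
                    pop.exposure_parameterisation,
                )
            eff = vals["emax"][:, None] * A / (vals["edk50"][:, None] + A)
            ok = (vals["int_dis"] > 0) & (vals["int_dis"] + vals["slope_dis"] * end > 0)
            idis = np.where(ok, vals["int_dis"], 1.0)
            slp = np.where(ok, vals["slope_dis"], 0.0)
            kin = np.where(ok & (vals["kin"] > 0), vals["kin"], 0.1)
            ipred = solve_fev1_grid(times, idis, slp, kin, eff, mode)
            sd = np.sqrt(sa**2 + (sp * ipred) ** 2)
            with np.errstate(invalid="ignore", divide="ignore"):
                z2 = ((y - ipred) / sd) ** 2 + 2.0 * np.log(sd) + _LOG2PI
            ll = -0.5 * np.where(mask, z2, 0.0).sum(axis=1)
            if self.config.include_dropout:
                ll = ll + self._dropout_loglik(spec, base_seg, ipred)
            return np.where(ok, ll, -1e10)

        return loglik

    def _base_hazard_segments(self, spec) -> np.ndarray:
        w0, w1 = self.weeks[:-1], self.weeks[1:]
        if spec.form == "constant":
            return spec.beta0 * (w1 - w0)
        if spec.form == "exponential":
            return spec.beta0 / spec.shape * (np.exp(spec.shape * w1) - np.exp(spec.shape * w0))
        return spec.beta0 * (w1**spec.shape - w0**spec.shape)

    def _dropout_loglik(self, spec, base_seg: np.ndarray, ipred: np.ndarray) -> np.ndarray:
        """log P(dropout interval | trajectory) per subject; IPRED (and
        observed FEV1 for beta1) held at the left endpoint of each
        inter-visit interval."""
        lin = spec.beta2 * ipred[:, :-1]
        if spec.beta1 != 0.0:
            lin = lin + spec.beta1 * self.y[:, :-1]
        with np.errstate(invalid="ignore", over="ignore"):
            seg = base_seg[None, :] * np.exp(np.minimum(lin, 50.0))
            H = np.concatenate(
                [np.zeros((self.n, 1)), np.cumsum(seg, axis=1)], axis=1
            )
        p = self.packed
        rows = np.arange(self.n)
        j = np.where(p.dropped, p.event_idx, 1)
        h_last = H[rows, j - 1]
        dh = np.maximum(H[rows, j] - h_last, 1e-300)
        with np.errstate(invalid="ignore"):
            ll_drop = -h_last + np.log(-np.expm1(-dh))
        return np.where(p.dropped, ll_drop, -H[:, -1])

    def marginal_loglik(self, pop: PopulationParameters | None = None):
        """(per-subject Laplace marginal log-likelihood, eta modes)."""
        pop = pop or self.population
        loglik = self._conditional_loglik_fn(pop)
        q = len(self.eta_names)
        if q == 0:
            return loglik(np.zeros((self.n, 0))), np.zeros((self.n, 0))
        omega = pop.omega_matrix()
        lm, eta, nfail = batched_laplace(loglik, omega, self._eta_cache.copy())
        self._eta_cache = eta
        self.n_laplace_failures = nfail
        return lm, eta

    def mofv(self, pop: PopulationParameters | None = None) -> float:
        """-2 log marginal likelihood (+ prior penalty when configured)."""
        pop = pop or self.population
        lm, _ = self.marginal_loglik(pop)
        out = -2.0 * float(lm.sum())
        if self.config.prior is not None:
            theta = {n: get_param(pop, n) for n in self.config.prior.theta_means
                     if _known(pop, n)}
            out += prior_penalty(theta, pop, self.config.prior)
        return out

    # -- parameter packing -------------------------------------------------

    def _pack(self, pop: PopulationParameters) -> np.ndarray:
        x = np.empty(len(self.config.free))
        for i, name in enumerate(self.config.free):
            v = get_param(pop, name)
            x[i] = np.log(v) if _is_log_scale(name, pop) else v
        return x

    def _unpack(self, x: np.ndarray) -> PopulationParameters:
        updates = {}
        for i, name in enumerate(self.config.free):
            updates[name] = (
                float(np.exp(np.clip(x[i], -700, 700)))
                if _is_log_scale(name, self.population)
                else float(x[i])
            )
        return set_params(self.population, updates)

    def _objective(self, x: np.ndarray) -> float:
        try:
            return self.mofv(self._unpack(x))
        except (ValueError, FloatingPointError):
            return 1e12

    # -- fitting -----------------------------------------------------------

    def fit(
        self,
        start: PopulationParameters | dict | None = None,
        maxiter: int = 500,
        polish: bool = True,
        polish_maxfev: int | None = None,
        compute_se: bool = False,
    ) -> "JointFEV1Results":
        """Minimise the MOFV over the free parameters.

        ``start`` overrides initial values (a dict of named values or a full
        parameter set); the model's template supplies the rest.  A quasi-
        Newton pass (L-BFGS-B on the transformed scale) is optionally
        polished by Nelder-Mead to tighten convergence.
        """
        if isinstance(start, dict):
            start_pop = set_params(self.population, start)
        else:
            start_pop = start or self.population
        x0 = self._pack(start_pop)
        if not np.isfinite(self._objective(x0)):
            raise ValueError("MOFV is not finite at the initial values")

        res = minimize(
            self._objective,
            x0,
            method="L-BFGS-B",
            options={"eps": 1e-5, "maxiter": maxiter, "ftol": 1e-13, "gtol": 1e-7},
        )
        nfev = res.nfev
        x_hat, f_hat = res.x, res.fun
        success = bool(res.success)
        if polish:
            res2 = minimize(
                self._objective,
                x_hat,
                method="Nelder-Mead",
                options={
                    "xatol": 1e-6,
                    "fatol": 1e-8,
                    "maxfev": polish_maxfev or 60 * len(x0),
                },
            )
            nfev += res2.nfev
            success = success or bool(res2.success)
            if res2.fun <= f_hat:
                x_hat, f_hat = res2.x, res2.fun
            # finish with full-Newton steps on the outer objective: the
            # FD-gradient noise floor is far below the quasi-Newton and
            # simplex stopping regions, so this pins the optimum to ~1e-5
            # on the transformed scale regardless of the starting point
            for _ in range(4):
                f0, grad, hess = self._fd_grad_hess(x_hat)
                nfev += 2 * len(x_hat) ** 2 + 2 * len(x_hat) + 1
                w, v = np.linalg.eigh(hess)
                w = np.maximum(np.abs(w), 1e-8 * np.abs(w).max() + 1e-12)
                step = -v @ ((v.T @ grad) / w)
                for s in (1.0, 0.5, 0.25, 0.1):
                    f_try = self._objective(x_hat + s * step)
                    nfev += 1
                    if f_try < f_hat:
                        x_hat = x_hat + s * step
                        f_hat = f_try
                        break
                else:
                    break
                if np.max(np.abs(step)) < 1e-7:
                    break
        pop_hat = self._unpack(x_hat)
        lm, eta_hat = self.marginal_loglik(pop_hat)

        bse = cov_nat = None
        if compute_se:
            bse, cov_nat = self._standard_errors(x_hat, pop_hat)

        shrink = {}
        if self.eta_names:
            om = pop_hat.omega_matrix()
            for k, nm in enumerate(self.eta_names):
                sd = float(np.std(eta_hat[:, k], ddof=1))
                shrink[nm] = 100.0 * (1.0 - sd / np.sqrt(om[k, k]))

        convergence = "converged" if success else "max_iter"
        if np.any(np.abs(x_hat) > 20):
            convergence = "boundary"
        return JointFEV1Results(
            model=self,
            population=pop_hat,
            params={n: get_param(pop_hat, n) for n in self.config.free},
            mofv=float(f_hat),
            bse=bse,
            cov_params=cov_nat,
            convergence=convergence,
            nfev=nfev,
            eta_hat=eta_hat,
            eta_names=tuple(self.eta_names),
            eta_shrinkage=shrink,
            n_laplace_failures=self.n_laplace_failures,
        )

    def _fd_grad_hess(self, x, h_scale: float = 2e-3):
        """Central-difference gradient and Hessian of the MOFV.

        The default step keeps the inner-solver noise of the objective
        (~1e-6) well below the quadratic signal h^2 * curvature in every
        Hessian entry; a 1e-4-style step would bury the cross terms."""
        k = len(x)
        h = h_scale * np.maximum(1.0, np.abs(x))
        H = np.empty((k, k))
        f0 = self._objective(x)
        fp = np.empty(k)
        fm = np.empty(k)
        for i in range(k):
            xp = x.copy(); xp[i] += h[i]
            xm = x.copy(); xm[i] -= h[i]
            fp[i], fm[i] = self._objective(xp), self._objective(xm)
            H[i, i] = (fp[i] + fm[i] - 2 * f0) / h[i] ** 2
        for i in range(k):
            for j in range(i + 1, k):
                xpp = x.copy(); xpp[[i, j]] += h[[i, j]]
                xmm = x.copy(); xmm[[i, j]] -= h[[i, j]]
                H[i, j] = H[j, i] = (
                    self._objective(xpp) + self._objective(xmm)
                    - fp[i] - fm[i] - fp[j] - fm[j] + 2 * f0
                ) / (2 * h[i] * h[j])
        return f0, (fp - fm) / (2 * h), H

    def _standard_errors(self, x_hat, pop_hat):
        """SEs from the inverse MOFV Hessian on the natural scale (delta
        method); (None, None) unless the Hessian is positive definite."""
        _, _, H = self._fd_grad_hess(x_hat)
        if np.any(np.linalg.eigvalsh(H) <= 0):
            return None, None
        cov_x = 2.0 * np.linalg.inv(H)
        grad = np.array(
            [
                get_param(pop_hat, n) if _is_log_scale(n, pop_hat) else 1.0
                for n in self.config.free
            ]
        )
        cov_nat = cov_x * np.outer(grad, grad)
        bse = {
            n: float(np.sqrt(cov_nat[i, i])) for i, n in enumerate(self.config.free)
        }
        return bse, cov_nat


def _known(pop, name) -> bool:
    try:
        get_param(pop, name)
        return True
    except (KeyError, AttributeError, TypeError):
        return False


@dataclass
class JointFEV1Results:
    """Estimates, uncertainties and diagnostics of one joint fit."""

    model: JointFEV1Model
    population: PopulationParameters
    params: dict[str, float]
    mofv: float
    bse: dict[str, float] | None
    cov_params: np.ndarray | None
    convergence: str
    nfev: int
    eta_hat: np.ndarray
    eta_names: tuple[str, ...]
    eta_shrinkage: dict[str, float]
    n_laplace_failures: int

    def iiv_cv_percent(self, parameter: str, exact: bool = False) -> float:
        """IIV reported as CV%%: 100*sqrt(omega^2) (first-order, the common
        pharmacometric convention) or the exact lognormal formula."""
        var = self.population.omega[parameter][parameter]
        if exact:
            return 100.0 * float(np.sqrt(np.expm1(var)))
        return 100.0 * float(np.sqrt(var))

    def summary(self) -> str:
        lines = [
            "Joint FEV1 disease-progression / dropout model (Laplace)",
            "=" * 60,
            f"subjects: {self.model.n}   observations: {self.model.nobs}"
            f"   MOFV: {self.mofv:.3f}",
            f"convergence: {self.convergence}   function evals: {self.nfev}",
            "-" * 60,
            f"{'parameter':<22}{'estimate':>12}{'SE':>12}{'RSE%':>8}",
        ]
        for name in self.params:
            est = self.params[name]
            if self.bse:
                se = self.bse[name]
                rse = 100 * se / abs(est) if est else np.inf
                lines.append(f"{name:<22}{est:>12.5g}{se:>12.3g}{rse:>8.1f}")
            else:
                lines.append(f"{name:<22}{est:>12.5g}{'--':>12}{'--':>8}")
        for nm, s in self.eta_shrinkage.items():
            lines.append(f"{'shrinkage ' + nm:<22}{s:>11.1f}%")
        for nm in self.eta_names:
            lines.append(
                f"{'IIV ' + nm + ' (CV%)':<22}{self.iiv_cv_percent(nm):>12.1f}"
            )
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "params": self.params,
            "bse": self.bse,
            "mofv": self.mofv,
            "convergence": self.convergence,
            "nfev": self.nfev,
            "eta_shrinkage": self.eta_shrinkage,
            "n_laplace_failures": self.n_laplace_failures,
            "free": list(self.model.config.free),
            "include_dropout": self.model.config.include_dropout,
            "n_subjects": self.model.n,
            "n_observations": self.model.nobs,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    # diagnostics / simulation hang off the results object
    def gof_table(self) -> pd.DataFrame:
        from .diagnostics import gof_tables

        return gof_tables(self.model, self)

    def simulate(self, design, dist=None, seed=None, covariates=None,
                 arm_labels=None):
        from .simulate import simulate_trial

        return simulate_trial(self.population, design, dist, seed=seed,
                              covariates=covariates, arm_labels=arm_labels)


# ---------------------------------------------------------------------------
# scalar conveniences (single-subject views of the same engine)
# ---------------------------------------------------------------------------


def _single_subject_model(ds, pop, include_dropout=True) -> JointFEV1Model:
    cfg = FitConfig(free=(), include_dropout=include_dropout)
    return JointFEV1Model(ds, pop, cfg)


def individual_joint_loglik(
    ds: LongitudinalDataset,
    pop: PopulationParameters,
    etas: dict[str, float] | None = None,
    include_dropout: bool = True,
) -> float:
    """Prior-free joint log-likelihood of one subject's data at fixed etas:
    Gaussian residual terms plus the log dropout/completion probability."""
    mdl = _single_subject_model(ds, pop, include_dropout)
    if mdl.n != 1:
        raise ValueError("expected a single-subject dataset")
    e = np.zeros((1, len(mdl.eta_names)))
    for k, nm in enumerate(mdl.eta_names):
        e[0, k] = (etas or {}).get(nm, 0.0)
    return float(mdl._conditional_loglik_fn(pop)(e)[0])


def laplace_marginal_loglik(
    ds: LongitudinalDataset,
    pop: PopulationParameters,
    include_dropout: bool = True,
) -> float:
    """Laplace marginal log-likelihood of a single subject under ``pop``."""
    mdl = _single_subject_model(ds, pop, include_dropout)
    lm, _ = mdl.marginal_loglik(pop)
    return float(lm.sum())


# ---------------------------------------------------------------------------
# stepwise covariate modelling
# ---------------------------------------------------------------------------


@dataclass
class ScmResult:
    selected: list[CovariateEffect]
    final: JointFEV1Results
    steps: pd.DataFrame


def _cand_name(e: CovariateEffect) -> str:
    return f"cov:{e.covariate_name}:{e.target_parameter}"


def covariate_step(
    data,
    population: PopulationParameters,
    config: FitConfig,
    candidates: list[CovariateEffect],
    forward_threshold: float = 3.84,
    backward_threshold: float = 11.0,
    **fit_kwargs,
) -> ScmResult:
    """Stepwise covariate modelling by likelihood-ratio thresholds.

    Forward: repeatedly add the candidate with the largest MOFV drop while
    that drop is >= ``forward_threshold`` (ties broken by the larger drop,
    then lexicographic (covariate, parameter) order).  Backward: drop any
    retained covariate whose removal raises the MOFV by <=
    ``backward_threshold``, weakest first.  Candidates whose refit fails are
    logged in the step table and skipped.
    """
    packed = data.to_packed() if isinstance(data, LongitudinalDataset) else data
    rows = []

    def fit_with(pop, extra_free):
        cfg = dataclasses.replace(config, free=tuple(config.free) + tuple(extra_free))
        mdl = JointFEV1Model(packed, pop, cfg)
        return mdl.fit(**fit_kwargs)

    current_pop = population
    current_free: list[str] = []
    base = fit_with(current_pop, current_free)
    rows.append(("forward", "<base>", base.mofv, np.nan, "start"))
    included: list[CovariateEffect] = []
    remaining = list(candidates)

    while remaining:
        trials = []
        for cand in remaining:
            pop_c = current_pop.replace(
                covariate_effects=list(current_pop.covariate_effects) + [cand]
            )
            try:
                res = fit_with(pop_c, current_free + [_cand_name(cand)])
            except Exception as exc:  # noqa: BLE001 - candidate skipped, logged
                rows.append(("forward", _cand_name(cand), np.nan, np.nan,
                             f"failed: {exc}"))
                continue
            delta = base.mofv - res.mofv
            trials.append((delta, cand, res))
            rows.append(("forward", _cand_name(cand), res.mofv, delta, "tested"))
        if not trials:
            break
        trials.sort(
            key=lambda t: (-t[0], t[1].covariate_name, t[1].target_parameter)
        )
        delta, cand, res = trials[0]
        if delta >= forward_threshold:  # boundary rule: exactly 3.84 is in
            included.append(cand)
            remaining = [c for c in remaining if c is not cand]
            current_pop = res.population
            current_free = current_free + [_cand_name(cand)]
            base = res
            rows.append(("forward", _cand_name(cand), res.mofv, delta, "included"))
        else:
            break

    # backward deletion
    while included:
        trials = []
        for cand in included:
            keep = [e for e in current_pop.covariate_effects if not (
                e.covariate_name == cand.covariate_name
                and e.target_parameter == cand.target_parameter
            )]
            pop_wo = current_pop.replace(covariate_effects=keep)
            free_wo = [f for f in current_free if f != _cand_name(cand)]
            try:
                res = fit_with(pop_wo, free_wo)
            except Exception as exc:  # noqa: BLE001
                rows.append(("backward", _cand_name(cand), np.nan, np.nan,
                             f"failed: {exc}"))
                continue
            delta = res.mofv - base.mofv  # increase caused by deletion
            trials.append((delta, cand, res, free_wo))
            rows.append(("backward", _cand_name(cand), res.mofv, delta, "tested"))
        if not trials:
            break
        trials.sort(key=lambda t: (t[0], t[1].covariate_name, t[1].target_parameter))
        delta, cand, res, free_wo = trials[0]
        if delta <= backward_threshold:
            included = [c for c in included if c is not cand]
            current_pop = res.population
            current_free = free_wo
            base = res
            rows.append(("backward", _cand_name(cand), res.mofv, delta, "removed"))
        else:
            break

    final_effects = [
        e for e in base.population.covariate_effects
        if any(
            e.covariate_name == c.covariate_name
            and e.target_parameter == c.target_parameter
            for c in included
        )
    ]
    steps = pd.DataFrame(rows, columns=["phase", "candidate", "mofv", "delta", "action"])
    return ScmResult(selected=final_effects, final=base, steps=steps)


# ---------------------------------------------------------------------------
# case-resampling bootstrap
# ---------------------------------------------------------------------------


def _resample_packed(p: _Packed, idx: np.ndarray) -> _Packed:
    return _Packed(
        ids=np.arange(1, len(idx) + 1),
        times=p.times,
        y=p.y[idx],
        dose_amount=p.dose_amount[idx],
        dose_interval=p.dose_interval,
        dropped=p.dropped[idx],
        event_idx=p.event_idx[idx],
        covariates=p.covariates.iloc[idx].reset_index(drop=True),
        arm=p.arm[idx],
    )


def bootstrap(
    data,
    population: PopulationParameters,
    config: FitConfig,
    n_boot: int = 100,
    seed: int = 0,
    start: PopulationParameters | None = None,
    ci_level: float = 0.90,
    **fit_kwargs,
) -> pd.DataFrame:
    """Percentile bootstrap CIs by case resampling of subjects.

    Each replicate refits the model (warm-started at the full-data
    estimates); non-converged replicates are counted and excluded.  Returns
    a per-parameter table with the estimate and the percentile interval.
    """
    if n_boot < 2:
        raise ValueError("n_boot must be >= 2")
    packed = data.to_packed() if isinstance(data, LongitudinalDataset) else data
    rng = np.random.default_rng(seed)
    full = JointFEV1Model(packed, population, config).fit(start=start, **fit_kwargs)
    draws: list[dict] = []
    n_failed = 0
    for _ in range(n_boot):
        idx = rng.integers(0, len(packed.ids), size=len(packed.ids))
        try:
            res = JointFEV1Model(_resample_packed(packed, idx), population, config).fit(
                start=full.population, **fit_kwargs
            )
            if res.convergence == "converged":
                draws.append(res.params)
            else:
                n_failed += 1
        except Exception:  # noqa: BLE001 - replicate counted as failed
            n_failed += 1
    if n_failed > n_boot // 2:
        raise RuntimeError(
            f"bootstrap aborted: {n_failed}/{n_boot} replicates failed"
        )
    frame = pd.DataFrame(draws)
    alpha = (1 - ci_level) / 2
    out = pd.DataFrame(index=frame.columns)
    out["estimate"] = [full.params[c] for c in frame.columns]
    out["ci_low"] = frame.quantile(alpha)
    out["ci_high"] = frame.quantile(1 - alpha)
    out.attrs["n_used"] = len(draws)
    out.attrs["n_failed"] = n_failed
    return out
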