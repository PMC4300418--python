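"""Domain types for the joint FEV1 / dropout model.

Parameter naming follows the pharmacometric convention used throughout the
package: ``tv_*`` are typical (population) values, ``omega`` is the
covariance matrix of the lognormal inter-individual random effects, and the
dropout hazard lives in :class:`HazardSpec` on a per-week clock.  The master
time unit everywhere else is days.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import yaml

__all__ = [
    "CovariateEffect",
    "CovariateVector",
    "DoseRegimen",
    "HazardSpec",
    "IndividualParameters",
    "PopulationParameters",
    "PriorSpec",
    "population_from_yaml",
    "population_to_yaml",
]

#: parameters that may carry lognormal IIV (order is the canonical eta order)
IIV_PARAMETERS = ("int_dis", "slope_dis", "kin", "emax", "edk50", "kde")


@dataclass(frozen=True)
class CovariateEffect:
    """One covariate–parameter relation.

    ``kind="power"``: the typical value is multiplied by
    ``(value / reference_value) ** theta`` (continuous covariates centred to
    their reference, typically the cohort median).
    ``kind="multiplicative"``: the typical value is multiplied by ``theta``
    when the subject is in the non-reference category (e.g. male, severe).
    """

    covariate_name: str
    target_parameter: str
    kind: str  # "power" | "multiplicative"
    theta: float
    reference_value: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("power", "multiplicative"):
            raise ValueError(f"unknown covariate-effect kind {self.kind!r}")
        if self.kind == "power":
            if self.reference_value is None or self.reference_value <= 0:
                raise ValueError("power effects need reference_value > 0")
        if not np.isfinite(self.theta):
            raise ValueError("theta must be finite")


@dataclass(frozen=True)
class CovariateVector:
    """Baseline characteristics of one subject."""

    age: float
    sex: str  # "female" | "male"
    height: float  # cm
    weight: float  # kg
    bmi: float  # kg/m^2
    severity: str  # "moderate" | "severe"
    reversibility: str  # "no" | "yes"
    pics: str  # "no" | "yes"  (previous inhaled corticosteroids)
    smoking: str = "no"

    _CATEGORICAL = {
        "sex": ("female", "male"),
        "severity": ("moderate", "severe"),
        "reversibility": ("no", "yes"),
        "pics": ("no", "yes"),
        "smoking": ("no", "yes"),
    }

    def __post_init__(self) -> None:
        if not 100.0 < self.height < 230.0:
            raise ValueError(f"height {self.height} cm out of range (100, 230)")
        if not 18.0 < self.age < 100.0:
            raise ValueError(f"age {self.age} out of range (18, 100)")
        for name, levels in self._CATEGORICAL.items():
            if getattr(self, name) not in levels:
                raise ValueError(f"{name}={getattr(self, name)!r} not in {levels}")

    def value(self, name: str) -> float:
        """Numeric view used by covariate models (categoricals -> 0/1)."""
        v = getattr(self, name)
        if name in self._CATEGORICAL:
            return float(v == self._CATEGORICAL[name][1])
        return float(v)


@dataclass(frozen=True)
class DoseRegimen:
    """Repeated dosing: ``dose_amount`` every ``interval`` hours on
    [start_time, end_time] days.  ``dose_amount = 0`` encodes placebo."""

    dose_amount: float  # micrograms
    interval: float = 12.0  # hours
    start_time: float = 0.0  # days
    end_time: float = np.inf  # days

    def __post_init__(self) -> None:
        if self.dose_amount < 0:
            raise ValueError("dose_amount must be >= 0")
        if self.interval <= 0:
            raise ValueError("interval must be > 0")
        if self.end_time < self.start_time:
            raise ValueError("end_time must be >= start_time")

    @property
    def interval_days(self) -> float:
        return self.interval / 24.0

    @property
    def is_placebo(self) -> bool:
        return self.dose_amount == 0.0


@dataclass(frozen=True)
class HazardSpec:
    """Dropout hazard h(t) = base(t) * exp(beta1*FEV1_obs + beta2*IPRED).

    ``beta0`` is on a per-week clock.  ``form``:

    * ``constant``   base(t) = beta0
    * ``exponential`` (Gompertz) base(t) = beta0 * exp(shape * t)
    * ``weibull``    base(t) = beta0 * shape * t**(shape-1)
    """

    form: str = "constant"
    beta0: float = 0.006
    beta1: float = 0.0
    beta2: float = 0.0
    shape: float = 1.0

    def __post_init__(self) -> None:
        if self.form not in ("constant", "exponential", "weibull"):
            raise ValueError(f"unknown hazard form {self.form!r}")
        if self.beta0 <= 0:
            raise ValueError("beta0 must be > 0")
        if self.form != "constant" and self.shape <= 0:
            raise ValueError("shape must be > 0 for non-constant forms")


@dataclass
class PopulationParameters:
    """Fixed effects, IIV covariance, residual SDs and dropout hazard."""

    tv_kin: float  # L/day, turnover input rate
    tv_int_dis: float  # L, disease baseline intercept
    tv_slope_dis: float  # L/day, negative = decline
    tv_emax: float  # max fractional drug effect
    ratio_edk50_emax: float  # EDK50 / Emax, micrograms
    kde: float  # 1/day, exposure elimination rate
    covariate_effects: list[CovariateEffect] = field(default_factory=list)
    omega: dict[str, dict[str, float]] | None = None  # nested {p: {p: var}}
    sigma_add: float = 0.0  # L
    sigma_prop: float = 0.0  # fraction
    hazard: HazardSpec = field(default_factory=HazardSpec)
    drug_effect_mode: str = "multiplicative_kin"
    exposure_parameterisation: str = "a"

    def __post_init__(self) -> None:
        if self.tv_int_dis <= 0:
            raise ValueError("tv_int_dis must be > 0")
        if self.tv_emax < 0:
            raise ValueError("tv_emax must be >= 0")
        if self.ratio_edk50_emax <= 0:
            raise ValueError("ratio_edk50_emax must be > 0")
        if self.kde <= 0:
            raise ValueError("kde must be > 0")
        if self.sigma_add < 0 or self.sigma_prop < 0:
            raise ValueError("residual SDs must be >= 0")
        self.omega_matrix()  # validates

    @property
    def tv_edk50(self) -> float:
        """EDK50 derived from the estimated ratio (micrograms)."""
        return self.ratio_edk50_emax * self.tv_emax

    def iiv_parameters(self) -> list[str]:
        if not self.omega:
            return []
        return [p for p in IIV_PARAMETERS if p in self.omega]

    def omega_matrix(self) -> np.ndarray:
        """Symmetric PSD covariance matrix in canonical eta order."""
        names = self.iiv_parameters()
        q = len(names)
        m = np.zeros((q, q))
        for i, a in enumerate(names):
            row = self.omega[a]
            for j, b in enumerate(names):
                m[i, j] = row.get(b, self.omega.get(b, {}).get(a, 0.0))
        if not np.allclose(m, m.T):
            raise ValueError("omega must be symmetric")
        if q and np.linalg.eigvalsh(m).min() < -1e-10:
            raise ValueError("omega must be positive semi-definite")
        return m

    def replace(self, **kwargs) -> "PopulationParameters":
        return dataclasses.replace(self, **kwargs)


@dataclass(frozen=True)
class IndividualParameters:
    """Covariate- and eta-adjusted parameters of one subject."""

    kin_i: float
    int_dis_i: float
    slope_dis_i: float
    emax_i: float
    edk50_i: float
    kde_i: float
    etas: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kin_i <= 0 or self.int_dis_i <= 0 or self.edk50_i <= 0:
            raise ValueError("kin_i, int_dis_i and edk50_i must be > 0")


@dataclass(frozen=True)
class PriorSpec:
    """Historical-fit penalty on the exposure–response parameters.

    Multivariate-normal prior on the fixed effects in ``theta_means`` and an
    inverse-Wishart prior (scale ``omega_scale``, ``df`` degrees of freedom)
    on the IIV block named by ``omega_parameters``.
    """

    theta_means: dict[str, float] = field(
        default_factory=lambda: {"tv_emax": 0.78, "ratio_edk50_emax": 4.0 / 0.78}
    )
    theta_cov: np.ndarray | None = None  # default: diag(omega_scale)
    omega_scale: np.ndarray = field(
        default_factory=lambda: np.array([[0.24, 0.1], [0.1, 0.14]])
    )
    omega_parameters: tuple[str, ...] = ("emax", "edk50")
    df: int = 24

    def __post_init__(self) -> None:
        scale = np.asarray(self.omega_scale, dtype=float)
        if self.df < scale.shape[0] + 1:
            raise ValueError("df must be >= dimension + 1")
        if np.linalg.eigvalsh(scale).min() <= 0:
            raise ValueError("omega_scale must be positive definite")

    def theta_covariance(self) -> np.ndarray:
        if self.theta_cov is not None:
            c = np.asarray(self.theta_cov, dtype=float)
        else:
            # documented approximation: diagonal from the printed IIV prior
            c = np.diag(np.diag(np.asarray(self.omega_scale, dtype=float)))
        if np.linalg.eigvalsh(c).min() <= 0:
            raise ValueError("theta covariance must be positive definite")
        return c


# ---------------------------------------------------------------------------
# YAML config I/O — parameter names in files are the stable API
# ---------------------------------------------------------------------------

_SCALAR_FIELDS = (
    "tv_kin",
    "tv_int_dis",
    "tv_slope_dis",
    "tv_emax",
    "ratio_edk50_emax",
    "kde",
    "sigma_add",
    "sigma_prop",
    "drug_effect_mode",
    "exposure_parameterisation",
)


def population_to_yaml(pop: PopulationParameters, path) -> None:
    doc: dict = {f: getattr(pop, f) for f in _SCALAR_FIELDS}
    doc["hazard"] = dataclasses.asdict(pop.hazard)
    doc["omega"] = pop.omega
    doc["covariate_effects"] = [dataclasses.asdict(e) for e in pop.covariate_effects]
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def population_from_dict(doc: dict) -> PopulationParameters:
    doc = dict(doc)
    try:
        effects = [CovariateEffect(**e) for e in doc.pop("covariate_effects", [])]
        hazard = HazardSpec(**doc.pop("hazard", {}))
        return PopulationParameters(covariate_effects=effects, hazard=hazard, **doc)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"invalid population config: {exc}") from exc


def population_from_yaml(path) -> PopulationParameters:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict):
        raise ValueError(f"{path}: population config must be a mapping")
    return population_from_dict(doc.get("population", doc))
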