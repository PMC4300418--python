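"""Prior penalty on exposure-response parameters (historical-fit borrowing).

With a single active dose level, Emax and EDK50 are only weakly identified;
the penalty adds the -2 log density of a multivariate-normal prior on the
covered fixed effects and of an inverse-Wishart prior (df from the size of
the historical study) on the covered IIV block to the objective function.
Density normalisation constants are kept (they are constant in the
parameters and cancel in objective-function comparisons).
"""

from __future__ import annotations

import numpy as np
from scipy.stats import invwishart, multivariate_normal

from .parameters import PopulationParameters, PriorSpec

__all__ = ["prior_penalty"]


def prior_penalty(
    theta: dict[str, float],
    pop: PopulationParameters,
    prior: PriorSpec,
) -> float:
    """-2 log prior density, added to the -2 log marginal likelihood.

    ``theta`` holds the current fixed-effect values by name; only the names
    present in ``prior.theta_means`` contribute.  The inverse-Wishart term
    applies to the sub-block of the model's omega whose parameters intersect
    ``prior.omega_parameters`` (the historical fit may cover IIV terms the
    final model dropped).
    """
    pen = 0.0
    names = [n for n in prior.theta_means if n in theta]
    if names:
        mu = np.array([prior.theta_means[n] for n in names])
        cov_full = prior.theta_covariance()
        order = list(prior.theta_means)
        sel = [order.index(n) for n in names]
        cov = cov_full[np.ix_(sel, sel)]
        x = np.array([theta[n] for n in names])
        pen += -2.0 * multivariate_normal.logpdf(x, mean=mu, cov=cov)

    model_iiv = pop.iiv_parameters()
    covered = [p for p in prior.omega_parameters if p in model_iiv]
    if covered:
        omega = pop.omega_matrix()
        midx = [model_iiv.index(p) for p in covered]
        pidx = [list(prior.omega_parameters).index(p) for p in covered]
        block = omega[np.ix_(midx, midx)]
        scale = np.asarray(prior.omega_scale, dtype=float)[np.ix_(pidx, pidx)]
        pen += -2.0 * invwishart.logpdf(block, df=prior.df, scale=scale)
    return float(pen)
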