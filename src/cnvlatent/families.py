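"""Response families for the latent-class association likelihood.

Each family provides the per-observation log density evaluated on an
n x C grid of linear predictors (one column per copy class) together with
its analytic derivatives with respect to the linear predictor and any
nuisance parameter.  Nuisance parameters are handled on an unconstrained
(log) scale so the optimiser works on an open parameter space:

* binomial  — logit link, no nuisance (dispersion fixed at 1);
* poisson   — log link, no nuisance;
* gaussian  — identity link, nuisance s = log(sigma);
* weibull   — proportional-hazards form with hazard
              h(t) = alpha t^(alpha-1) exp(eta), right censoring via the
              event indicator; nuisance a = log(alpha) (optionally fixed).
"""

from __future__ import annotations

import numpy as np
from scipy.special import expit, gammaln

_LOG2PI = np.log(2 * np.pi)


class Family:
    name: str = ""
    n_nuisance: int = 0
    requires_event: bool = False

    def check_response(self, y, event=None):
        y = np.asarray(y, dtype=float)
        if y.ndim != 1:
            raise ValueError("response must be one-dimensional")
        if not np.all(np.isfinite(y)):
            raise ValueError("response contains non-finite values")
        return y

    def loglik_matrix(self, y, eta, nuis, event=None):
        raise NotImplementedError

    def dlogf_deta(self, y, eta, nuis, event=None):
        raise NotImplementedError

    def dlogf_dnuis(self, y, eta, nuis, event=None):
        """n x C x n_nuisance array (empty last axis when no nuisance)."""
        return np.empty(y.shape + eta.shape[1:] + (0,))

    def init_nuisance(self, y, event=None):
        return np.empty(0)

    def nuisance_dict(self, nuis):
        return {}


class Binomial(Family):
    name = "binomial"

    def check_response(self, y, event=None):
        y = super().check_response(y)
        if not np.all(np.isin(y, (0.0, 1.0))):
            raise ValueError("binomial response must be coded 0/1")
        return y

    def loglik_matrix(self, y, eta, nuis, event=None):
        return y[:, None] * eta - np.logaddexp(0.0, eta)

    def dlogf_deta(self, y, eta, nuis, event=None):
        return y[:, None] - expit(eta)


class Poisson(Family):
    name = "poisson"

    def check_response(self, y, event=None):
        y = super().check_response(y)
        if np.any(y < 0) or np.any(y != np.round(y)):
            raise ValueError("poisson response must be non-negative integer counts")
        return y

    def loglik_matrix(self, y, eta, nuis, event=None):
        with np.errstate(over="ignore"):
            mu = np.exp(eta)
        return y[:, None] * eta - mu - gammaln(y + 1.0)[:, None]

    def dlogf_deta(self, y, eta, nuis, event=None):
        with np.errstate(over="ignore"):
            return y[:, None] - np.exp(eta)


class Gaussian(Family):
    name = "gaussian"
    n_nuisance = 1  # s = log(sigma)

    def loglik_matrix(self, y, eta, nuis, event=None):
        s = nuis[0]
        sigma2 = np.exp(2 * s)
        resid = y[:, None] - eta
        return -s - 0.5 * _LOG2PI - resid**2 / (2 * sigma2)

    def dlogf_deta(self, y, eta, nuis, event=None):
        return (y[:, None] - eta) / np.exp(2 * nuis[0])

    def dlogf_dnuis(self, y, eta, nuis, event=None):
        resid = y[:, None] - eta
        return (-1.0 + resid**2 / np.exp(2 * nuis[0]))[..., None]

    def init_nuisance(self, y, event=None):
        return np.array([0.5 * np.log(max(np.var(y), 1e-12))])

    def nuisance_dict(self, nuis):
        return {"sigma": float(np.exp(nuis[0]))}


class Weibull(Family):
    """Weibull proportional hazards with right censoring.

    log f = delta * (log alpha + (alpha - 1) log t + eta) - t^alpha exp(eta),
    with delta = 1 for an observed event and 0 for a censored time, so
    exp(beta) is a hazard ratio.  alpha = 1 recovers the exponential model.
    """

    name = "weibull"
    requires_event = True

    def __init__(self, fixed_shape: float | None = None):
        self.fixed_shape = fixed_shape
        self.n_nuisance = 0 if fixed_shape is not None else 1

    def check_response(self, y, event=None):
        y = super().check_response(y)
        if np.any(y <= 0):
            raise ValueError("weibull times must be positive")
        if event is None:
            raise ValueError("weibull family requires an event indicator")
        event = np.asarray(event, dtype=float)
        if not np.all(np.isin(event, (0.0, 1.0))):
            raise ValueError("event indicator must be coded 0/1")
        if event.shape != y.shape:
            raise ValueError("event indicator length must match the response")
        return y

    def _alpha(self, nuis):
        return self.fixed_shape if self.fixed_shape is not None else np.exp(nuis[0])

    def loglik_matrix(self, y, eta, nuis, event=None):
        alpha = self._alpha(nuis)
        logt = np.log(y)
        with np.errstate(over="ignore"):
            t_alpha_eeta = np.exp(alpha * logt[:, None] + eta)
        d = event[:, None]
        return d * (np.log(alpha) + (alpha - 1) * logt[:, None] + eta) - t_alpha_eeta

    def dlogf_deta(self, y, eta, nuis, event=None):
        alpha = self._alpha(nuis)
        with np.errstate(over="ignore"):
            t_alpha_eeta = np.exp(alpha * np.log(y)[:, None] + eta)
        return event[:, None] - t_alpha_eeta

    def dlogf_dnuis(self, y, eta, nuis, event=None):
        if self.fixed_shape is not None:
            return np.empty(eta.shape + (0,))
        alpha = self._alpha(nuis)
        logt = np.log(y)[:, None]
        with np.errstate(over="ignore"):
            t_alpha_eeta = np.exp(alpha * logt + eta)
        d = event[:, None]
        # derivative wrt a = log(alpha): alpha * d(logf)/d(alpha)
        return (d * (1.0 + alpha * logt) - alpha * logt * t_alpha_eeta)[..., None]

    def init_nuisance(self, y, event=None):
        return np.zeros(0 if self.fixed_shape is not None else 1)

    def nuisance_dict(self, nuis):
        if self.fixed_shape is not None:
            return {"shape": float(self.fixed_shape), "shape_fixed": True}
        return {"shape": float(np.exp(nuis[0]))}


_FAMILIES = {
    "binomial": Binomial,
    "poisson": Poisson,
    "gaussian": Gaussian,
    "weibull": Weibull,
}


def get_family(family, fixed_shape=None) -> Family:
    if isinstance(family, Family):
        return family
    try:
        cls = _FAMILIES[family]
    except KeyError:
        raise ValueError(
            f"unknown family {family!r}; choose from {sorted(_FAMILIES)}"
        ) from None
    if cls is Weibull:
        return Weibull(fixed_shape=fixed_shape)
    if fixed_shape is not None:
        raise ValueError("fixed_shape only applies to the weibull family")
    return cls()
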