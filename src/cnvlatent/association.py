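"""Latent-class association models between copy number and phenotype.

The copy number of individual *i* is not observed directly; the calling
step supplies posterior probabilities w_ic over copy classes c.  Rather
than conditioning on the best-guess class (which biases effect estimates
toward the null and understates uncertainty), the association model
maximises the observed-data likelihood

    l(theta) = sum_i log sum_c w_ic f(y_i | eta_ic, nu),

a finite mixture over the latent copy class, where eta_ic is the linear
predictor of class c for individual i and f is the response density
(binomial, Poisson, Gaussian, or right-censored Weibull proportional
hazards).  Two inheritance designs are supported:

* ``multiplicative`` (model-free): one intercept beta_c per copy class,
  effects reported as contrasts against the reference (lowest) class;
* ``additive``: a linear trend in copy number,
  eta_ic = beta_0 + beta_1 * copies_c.

Covariate effects x_i' gamma are shared across classes.  Estimation is by
Newton-Raphson on the observed log-likelihood (analytic score,
finite-difference Hessian, step-halving line search) with an EM fallback;
the coefficient covariance is the inverse observed information.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit, logsumexp
from scipy.stats import chi2, norm

from .calling import CNVGenotype, cnv_from_probabilities
from .families import Family, get_family

__all__ = [
    "CNVAssociationModel",
    "CNVAssociationResults",
    "TestResult",
    "latent_loglik",
    "fit_latent_model",
    "fit_null_model",
    "lrt",
    "wald_global",
    "wald_summary",
    "multi_assoc",
    "bh_adjust",
]

_Z975 = norm.ppf(0.975)

_EFFECT_LABEL = {"binomial": "OR", "poisson": "RR", "weibull": "HR", "gaussian": "diff"}


@dataclass
class TestResult:
    statistic: float
    df: int
    pvalue: float
    kind: str

    def __str__(self):
        return (
            f"----CNV {'Likelihood Ratio' if self.kind == 'LRT' else 'Wald'} Test----\n"
            f"Chi = {self.statistic:.6g} (df = {self.df}), pvalue = {self.pvalue:.6g}"
        )


def _norm_design(model: str) -> str:
    aliases = {
        "multiplicative": "multiplicative",
        "free": "multiplicative",
        "model-free": "multiplicative",
        "mul": "multiplicative",
        "additive": "additive",
        "add": "additive",
    }
    try:
        return aliases[model]
    except KeyError:
        raise ValueError(f"unknown inheritance model {model!r}") from None


class CNVAssociationModel:
    """Latent-class association model for one CNV.

    Parameters
    ----------
    y : array-like
        Response: 0/1 (binomial), counts (poisson), real values (gaussian)
        or positive times (weibull).
    cnv : CNVGenotype or array-like
        Posterior copy-class probability matrix (rows sum to 1); a plain
        matrix is wrapped with copy labels 0..C-1.
    covariates : array-like or DataFrame, optional
        n x p matrix of adjustment covariates (no intercept column).
    family : {"binomial", "poisson", "gaussian", "weibull"}
    model : {"multiplicative", "additive"}
        Inheritance design ("multiplicative" is the model-free design with
        one parameter per copy class).
    event : array-like, optional
        0/1 event indicator (1 = observed event), weibull family only.
    fixed_shape : float, optional
        Fix the Weibull shape instead of estimating it (shape 1 gives the
        exponential proportional-hazards model).
    """

    def __init__(
        self,
        y,
        cnv,
        covariates=None,
        family="binomial",
        model="multiplicative",
        event=None,
        fixed_shape=None,
        covariate_names=None,
        drop_class_tol=1e-6,
    ):
        self.family: Family = get_family(family, fixed_shape=fixed_shape)
        self.design = _norm_design(model)
        if not isinstance(cnv, CNVGenotype):
            cnv = cnv_from_probabilities(np.asarray(cnv, dtype=float))
        y = np.asarray(y, dtype=float)
        if event is not None:
            event = np.asarray(event, dtype=float)
        if covariates is not None:
            if isinstance(covariates, pd.DataFrame):
                covariate_names = covariate_names or list(covariates.columns)
                covariates = covariates.to_numpy(dtype=float)
            covariates = np.atleast_2d(np.asarray(covariates, dtype=float))
            if covariates.shape[0] != y.size and covariates.shape[1] == y.size:
                covariates = covariates.T
        if y.size != cnv.n:
            raise ValueError("response and CNV probability rows do not align")

        # listwise deletion of rows with missing response/covariates
        keep = np.isfinite(y)
        if covariates is not None:
            keep &= np.all(np.isfinite(covariates), axis=1)
        if event is not None:
            keep &= np.isfinite(event)
        if not np.all(keep):
            warnings.warn(f"dropping {int((~keep).sum())} rows with missing values")
        prob = cnv.prob[keep]
        y = y[keep]
        event = event[keep] if event is not None else None
        covariates = covariates[keep] if covariates is not None else None

        # drop copy classes carrying essentially no posterior mass
        mass = prob.sum(axis=0)
        cols = mass >= drop_class_tol
        if not np.all(cols):
            warnings.warn(
                f"dropping copy classes with no posterior mass: "
                f"{cnv.copies[~cols].tolist()}"
            )
            prob = prob[:, cols]
            prob = prob / prob.sum(axis=1, keepdims=True)
        self.copies = cnv.copies[cols].astype(float)
        self.w = prob
        self.y = self.family.check_response(y, event)
        self.event = event
        self.X = covariates
        self.n, self.n_classes = self.w.shape
        if self.n_classes < 1 or np.any(self.w.sum(axis=0) <= 0):
            raise ValueError("every retained copy class needs posterior mass")
        self.covariate_names = list(
            covariate_names
            if covariate_names is not None
            else (
                [f"x{j}" for j in range(self.X.shape[1])] if self.X is not None else []
            )
        )
        self.n_beta = self.n_classes if self.design == "multiplicative" else 2
        self.n_gamma = 0 if self.X is None else self.X.shape[1]
        self.n_nuis = self.family.n_nuisance
        self.n_params = self.n_beta + self.n_gamma + self.n_nuis
        self._logw = np.log(np.maximum(self.w, 1e-300))

    # -- parameter bookkeeping ---------------------------------------------

    @property
    def param_names(self):
        if self.design == "multiplicative":
            names = [f"CNV{int(c)}" for c in self.copies]
        else:
            names = ["intercept", "trend"]
        names += self.covariate_names
        if self.n_nuis:
            names.append(
                "log(sigma)" if self.family.name == "gaussian" else "log(shape)"
            )
        return names

    def _split(self, theta):
        nb, ng = self.n_beta, self.n_gamma
        return theta[:nb], theta[nb : nb + ng], theta[nb + ng :]

    def _eta(self, beta, gamma):
        if self.design == "multiplicative":
            eta = np.broadcast_to(beta[None, :], (self.n, self.n_classes)).copy()
        else:
            eta = beta[0] + beta[1] * self.copies[None, :]
            eta = np.broadcast_to(eta, (self.n, self.n_classes)).copy()
        if self.X is not None:
            eta += (self.X @ gamma)[:, None]
        return eta

    # -- likelihood machinery ----------------------------------------------

    def loglik(self, theta):
        """Observed-data latent-class log-likelihood at theta."""
        theta = np.asarray(theta, dtype=float)
        beta, gamma, nuis = self._split(theta)
        logf = self.family.loglik_matrix(self.y, self._eta(beta, gamma), nuis, self.event)
        with np.errstate(invalid="ignore"):
            ll = float(logsumexp(self._logw + logf, axis=1).sum())
        return ll if np.isfinite(ll) else -np.inf

    def responsibilities(self, theta):
        """Posterior class membership h_ic given the response (E-step weights)."""
        beta, gamma, nuis = self._split(np.asarray(theta, float))
        logf = self.family.loglik_matrix(self.y, self._eta(beta, gamma), nuis, self.event)
        lw = self._logw + logf
        return np.exp(lw - logsumexp(lw, axis=1)[:, None])

    def score(self, theta, resp=None):
        """Analytic gradient of the latent log-likelihood (or, with fixed
        responsibilities `resp`, of the EM minorant Q)."""
        theta = np.asarray(theta, dtype=float)
        beta, gamma, nuis = self._split(theta)
        eta = self._eta(beta, gamma)
        h = self.responsibilities(theta) if resp is None else resp
        u = self.family.dlogf_deta(self.y, eta, nuis, self.event)
        hu = h * u
        parts = []
        if self.design == "multiplicative":
            parts.append(hu.sum(axis=0))
        else:
            parts.append(np.array([hu.sum(), (hu * self.copies[None, :]).sum()]))
        if self.X is not None:
            parts.append(self.X.T @ hu.sum(axis=1))
        if self.n_nuis:
            v = self.family.dlogf_dnuis(self.y, eta, nuis, self.event)
            parts.append(np.einsum("ic,icq->q", h, v))
        return np.concatenate(parts)

    def hessian(self, theta, resp=None):
        """Central finite differences of the analytic score."""
        theta = np.asarray(theta, dtype=float)
        p = theta.size
        H = np.empty((p, p))
        for j in range(p):
            hstep = 1e-5 * (1.0 + abs(theta[j]))
            tp, tm = theta.copy(), theta.copy()
            tp[j] += hstep
            tm[j] -= hstep
            H[:, j] = (self.score(tp, resp) - self.score(tm, resp)) / (2 * hstep)
        return 0.5 * (H + H.T)

    # -- initial values ------------------------------------------------------

    def _init_params(self):
        cls = np.argmax(self.w, axis=1)
        eps = 0.5 / (self.n + 1)
        fam = self.family.name
        if self.design == "multiplicative":
            beta = np.empty(self.n_classes)
            for c in range(self.n_classes):
                sel = cls == c
                if fam == "binomial":
                    m = self.y[sel].mean() if sel.any() else self.y.mean()
                    beta[c] = np.log(np.clip(m, eps, 1 - eps) / (1 - np.clip(m, eps, 1 - eps)))
                elif fam == "poisson":
                    m = self.y[sel].mean() if sel.any() else self.y.mean()
                    beta[c] = np.log(max(m, eps))
                elif fam == "gaussian":
                    beta[c] = self.y[sel].mean() if sel.any() else self.y.mean()
                else:  # weibull: log crude hazard = events / person-time
                    ev = self.event[sel].sum() if sel.any() else self.event.sum()
                    pt = self.y[sel].sum() if sel.any() else self.y.sum()
                    beta[c] = np.log(max(ev, 0.5) / max(pt, eps))
        else:
            if fam == "binomial":
                m = np.clip(self.y.mean(), eps, 1 - eps)
                b0 = np.log(m / (1 - m))
            elif fam == "poisson":
                b0 = np.log(max(self.y.mean(), eps))
            elif fam == "gaussian":
                b0 = self.y.mean()
            else:
                b0 = np.log(max(self.event.sum(), 0.5) / self.y.sum())
            beta = np.array([b0, 0.0])
        gamma = np.zeros(self.n_gamma)
        nuis = self.family.init_nuisance(self.y, self.event)
        return np.concatenate([beta, gamma, nuis])

    # -- optimisation --------------------------------------------------------

    def _newton(self, theta, max_iter=100, tol=1e-10, grad_tol=1e-8):
        ll = self.loglik(theta)
        stalled = 0
        for it in range(1, max_iter + 1):
            g = self.score(theta)
            H = self.hessian(theta)
            try:
                step = np.linalg.solve(H, -g)
            except np.linalg.LinAlgError:
                step = g
            if g @ step <= 0:  # not an ascent direction; fall back to gradient
                scale = max(np.max(np.abs(np.diag(H))), 1.0)
                step = g / scale
            lam, new_ll, ok = 1.0, -np.inf, False
            for _ in range(40):
                cand = theta + lam * step
                new_ll = self.loglik(cand)
                if new_ll > ll - 1e-13 * (1 + abs(ll)):
                    ok = True
                    break
                lam *= 0.5
            if not ok:
                stalled += 1
                if stalled >= 5:
                    return theta, ll, it, False
                continue
            theta, improved = cand, new_ll - ll
            ll = new_ll
            if abs(improved) <= tol * (1 + abs(ll)) and np.max(np.abs(self.score(theta))) < grad_tol:
                return theta, ll, it, True
        return theta, ll, max_iter, np.max(np.abs(self.score(theta))) < grad_tol

    def _em(self, theta, max_iter=1000, tol=1e-10):
        ll = self.loglik(theta)
        for it in range(1, max_iter + 1):
            h = self.responsibilities(theta)
            # M-step: a few Newton steps on the minorant Q(theta | h)
            for _ in range(5):
                g = self.score(theta, resp=h)
                H = self.hessian(theta, resp=h)
                try:
                    step = np.linalg.solve(H, -g)
                except np.linalg.LinAlgError:
                    break
                if g @ step <= 0:
                    break
                lam = 1.0
                for _ in range(30):
                    cand = theta + lam * step
                    if self.loglik(cand) > -np.inf:
                        break
                    lam *= 0.5
                theta = cand
                if np.max(np.abs(g)) < 1e-9:
                    break
            new_ll = self.loglik(theta)
            if abs(new_ll - ll) <= tol * (1 + abs(new_ll)):
                return theta, new_ll, it, True
            ll = new_ll
        return theta, ll, max_iter, False

    def fit(self, start=None, max_iter=100, tol=1e-10) -> "CNVAssociationResults":
        """Maximise the latent-class likelihood.

        Newton-Raphson from a naive best-guess-class start; on failure an EM
        pass (E-step responsibilities, M-step Newton on the minorant) is run
        and Newton-Raphson is retried from its solution.
        """
        theta0 = np.asarray(start, float) if start is not None else self._init_params()
        theta, ll, n_iter, ok = self._newton(theta0, max_iter=max_iter, tol=tol)
        method = "newton-raphson"
        if not ok or not np.isfinite(ll):
            theta_em, ll_em, em_iter, em_ok = self._em(theta if np.isfinite(ll) else theta0)
            theta2, ll2, n2, ok2 = self._newton(theta_em, max_iter=max_iter, tol=tol)
            if ll2 >= ll or not np.isfinite(ll):
                theta, ll, ok = theta2, ll2, ok2
                n_iter += em_iter + n2
                method = "em-fallback"
        H = self.hessian(theta)
        cov = None
        try:
            cov = np.linalg.inv(-H)
            cov = 0.5 * (cov + cov.T)
            if not np.all(np.isfinite(cov)) or np.any(np.diag(cov) < 0):
                cov = None
        except np.linalg.LinAlgError:
            cov = None
        if cov is None:
            warnings.warn("observed information is singular; covariance unavailable")
            cov = np.full((self.n_params, self.n_params), np.nan)
            ok = False
        return CNVAssociationResults(
            model=self,
            params=theta,
            cov_params=cov,
            loglik=ll,
            converged=bool(ok and np.isfinite(ll)),
            n_iter=n_iter,
            method=method,
        )

    def fit_null(self, **kwargs) -> "CNVAssociationResults":
        """Fit the matching model without CNV terms (same data and covariates)."""
        return fit_null_model(
            self.y,
            covariates=self.X,
            family=self.family.name,
            event=self.event,
            fixed_shape=getattr(self.family, "fixed_shape", None),
            covariate_names=self.covariate_names,
            **kwargs,
        )


class CNVAssociationResults:
    """Fitted latent-class association model.

    Attributes
    ----------
    params : ndarray
        Maximum-likelihood estimates (class intercepts or intercept+trend,
        covariate effects, then any log-scale nuisance parameter).
    cov_params : ndarray
        Inverse observed information at the optimum.
    deviance : float
        -2 * log-likelihood.
    """

    def __init__(self, model, params, cov_params, loglik, converged, n_iter, method):
        self.model = model
        self.params = params
        self.cov_params = cov_params
        self.loglik = loglik
        self.converged = converged
        self.n_iter = n_iter
        self.method = method

    # -- basic accessors ----------------------------------------------------

    @property
    def deviance(self) -> float:
        return -2.0 * self.loglik

    @property
    def n_params(self) -> int:
        return self.model.n_params

    @property
    def nobs(self) -> int:
        return self.model.n

    @property
    def bse(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov_params))

    @property
    def beta(self) -> np.ndarray:
        return self.params[: self.model.n_beta]

    @property
    def gamma(self) -> np.ndarray:
        nb = self.model.n_beta
        return self.params[nb : nb + self.model.n_gamma]

    @property
    def nuisance(self) -> dict:
        return self.model.family.nuisance_dict(
            self.params[self.model.n_beta + self.model.n_gamma :]
        )

    def params_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"coef": self.params, "SE": self.bse}, index=self.model.param_names
        )

    # -- Wald coefficient table ---------------------------------------------

    def coef_table(self) -> pd.DataFrame:
        """Per-contrast effect table (Wald summary).

        For the model-free design each copy class is contrasted against the
        reference (lowest-copy) class; for the additive design a single
        per-copy trend row is shown.  Effects are exponentiated (OR/RR/HR)
        except for the gaussian family, which stays on the identity scale.
        """
        m = self.model
        fam = m.family.name
        label = _EFFECT_LABEL[fam]
        exp_scale = fam != "gaussian"
        rows, index = [], []
        V = self.cov_params

        def _row(est_log, se):
            stat = est_log / se
            p = 2 * norm.sf(abs(stat))
            lo, hi = est_log - _Z975 * se, est_log + _Z975 * se
            if exp_scale:
                return [np.exp(est_log), np.exp(lo), np.exp(hi), se, stat, p]
            return [est_log, lo, hi, se, stat, p]

        if m.design == "multiplicative":
            ref = 0  # lowest copy class
            index.append(f"CNV{int(m.copies[ref])}")
            rows.append([1.0 if exp_scale else 0.0] + [np.nan] * 5)
            for c in range(m.n_classes):
                if c == ref:
                    continue
                est = self.params[c] - self.params[ref]
                se = np.sqrt(V[c, c] + V[ref, ref] - 2 * V[c, ref])
                index.append(f"CNV{int(m.copies[c])}")
                rows.append(_row(est, se))
        else:
            index.append("trend")
            rows.append(_row(self.params[1], np.sqrt(V[1, 1])))
        for j, name in enumerate(m.covariate_names):
            k = m.n_beta + j
            index.append(name)
            rows.append(_row(self.params[k], np.sqrt(V[k, k])))
        cols = [label, "lower.lim", "upper.lim", "SE", "stat", "pvalue"]
        return pd.DataFrame(rows, columns=cols, index=index)

    # -- tests ---------------------------------------------------------------

    def lrt(self, null: "CNVAssociationResults | None" = None) -> TestResult:
        if null is None:
            null = self.model.fit_null()
        return lrt(self, null)

    def wald_global(self) -> TestResult:
        return wald_global(self)

    # -- display -------------------------------------------------------------

    def summary(self) -> str:
        m = self.model
        lines = [
            "Latent-class CNV association model "
            f"(family: {m.family.name}, design: {m.design})",
            f"Deviance: {self.deviance:.4f}",
            f"Number of parameters: {self.n_params}",
            f"Number of individuals: {self.nobs}",
            "",
            "Coefficients:",
            self.coef_table().to_string(float_format=lambda v: f"{v:.4f}"),
        ]
        for k, v in self.nuisance.items():
            if k.endswith("_fixed"):
                continue
            lines.append(f"\nEstimated {k}: {v:.4f}")
        if m.family.name == "binomial":
            lines.append("\n(Dispersion parameter for binomial family taken to be 1)")
        if m.design == "multiplicative":
            lines.append("\nCovariance between coefficients:")
            cov = pd.DataFrame(
                self.cov_params[: m.n_beta, : m.n_beta],
                index=m.param_names[: m.n_beta],
                columns=m.param_names[: m.n_beta],
            )
            lines.append(cov.to_string(float_format=lambda v: f"{v:.4f}"))
        if not self.converged:
            lines.append("\nWARNING: fit did not converge")
        return "\n".join(lines)

    def __repr__(self):
        return (
            f"<CNVAssociationResults family={self.model.family.name} "
            f"design={self.model.design} deviance={self.deviance:.3f} "
            f"converged={self.converged}>"
        )


# --------------------------------------------------------------------------
# functional interface
# --------------------------------------------------------------------------


def latent_loglik(
    y,
    cnv,
    beta,
    covariates=None,
    gamma=None,
    nuisance=None,
    family="binomial",
    model="multiplicative",
    event=None,
    fixed_shape=None,
):
    """Evaluate the latent-class log-likelihood at given parameter values.

    `nuisance` is on the natural scale (gaussian sigma or weibull shape).
    """
    m = CNVAssociationModel(
        y, cnv, covariates=covariates, family=family, model=model,
        event=event, fixed_shape=fixed_shape,
    )
    beta = np.atleast_1d(np.asarray(beta, dtype=float))
    gamma = np.atleast_1d(np.asarray(gamma, dtype=float)) if gamma is not None else np.empty(0)
    if m.n_nuis:
        if nuisance is None:
            raise ValueError(f"{m.family.name} family needs a nuisance parameter")
        nuis = np.array([np.log(float(nuisance))])
    else:
        nuis = np.empty(0)
    theta = np.concatenate([beta, gamma, nuis])
    if theta.size != m.n_params:
        raise ValueError(f"expected {m.n_params} parameters, got {theta.size}")
    return m.loglik(theta)


def fit_latent_model(
    y, cnv, covariates=None, family="binomial", model="multiplicative",
    event=None, fixed_shape=None, **fit_kwargs,
) -> CNVAssociationResults:
    """One-call fit of the latent-class association model."""
    return CNVAssociationModel(
        y, cnv, covariates=covariates, family=family, model=model,
        event=event, fixed_shape=fixed_shape,
    ).fit(**fit_kwargs)


def fit_null_model(
    y, covariates=None, family="binomial", event=None, fixed_shape=None,
    covariate_names=None, **fit_kwargs,
) -> CNVAssociationResults:
    """Fit the no-CNV model (single latent class): an ordinary GLM or
    parametric-survival fit with the same machinery."""
    y = np.asarray(y, dtype=float)
    null_cnv = CNVGenotype(prob=np.ones((y.size, 1)), copies=np.array([0]))
    return CNVAssociationModel(
        y, null_cnv, covariates=covariates, family=family, model="multiplicative",
        event=event, fixed_shape=fixed_shape, covariate_names=covariate_names,
    ).fit(**fit_kwargs)


def wald_summary(fit: CNVAssociationResults) -> pd.DataFrame:
    """Per-contrast Wald effect table; alias for ``fit.coef_table()``."""
    return fit.coef_table()


def lrt(fit: CNVAssociationResults, null: CNVAssociationResults) -> TestResult:
    """Likelihood-ratio test of the CNV terms: deviance(null) - deviance(fit)."""
    if fit.nobs != null.nobs:
        raise ValueError("LRT requires both models fitted to the same data")
    df = fit.n_params - null.n_params
    if df <= 0:
        raise ValueError("models are not nested (df <= 0)")
    stat = max(null.deviance - fit.deviance, 0.0)
    return TestResult(statistic=float(stat), df=int(df), pvalue=float(chi2.sf(stat, df)), kind="LRT")


def wald_global(fit: CNVAssociationResults) -> TestResult:
    """Global Wald test of the CNV block (quadratic form in the contrasts)."""
    m = fit.model
    V = fit.cov_params
    if m.design == "additive":
        est = np.array([fit.params[1]])
        Vc = np.array([[V[1, 1]]])
        df = 1
    else:
        C = m.n_classes
        if C < 2:
            raise ValueError("no CNV contrasts to test")
        L = np.zeros((C - 1, fit.params.size))
        for r in range(C - 1):
            L[r, 0] = -1.0
            L[r, r + 1] = 1.0
        est = L @ fit.params
        Vc = L @ V @ L.T
        df = C - 1
    stat = float(est @ np.linalg.solve(Vc, est))
    return TestResult(statistic=max(stat, 0.0), df=int(df), pvalue=float(chi2.sf(stat, df)), kind="Wald")


# --------------------------------------------------------------------------
# many CNVs
# --------------------------------------------------------------------------


def _one_cnv_pvalue(cnv, y, covariates, family, model, event, fixed_shape, test):
    try:
        res = fit_latent_model(
            y, cnv, covariates=covariates, family=family, model=model,
            event=event, fixed_shape=fixed_shape,
        )
        if not res.converged:
            return np.nan, "did not converge"
        t = res.wald_global() if test == "wald" else res.lrt()
        return t.pvalue, ""
    except Exception as exc:  # record, don't abort the batch
        return np.nan, f"{type(exc).__name__}: {exc}"


def multi_assoc(
    cnv_list,
    y,
    covariates=None,
    family="binomial",
    model="multiplicative",
    event=None,
    fixed_shape=None,
    test="lrt",
    workers=1,
    names=None,
    adjust=None,
) -> pd.DataFrame:
    """Association p-values for many CNVs sharing one phenotype.

    Results are independent per CNV, so the output is identical for any
    worker count.  Per-CNV failures are recorded as NaN with a reason.
    """
    if test not in ("lrt", "wald"):
        raise ValueError("test must be 'lrt' or 'wald'")
    names = list(names) if names is not None else list(range(len(cnv_list)))
    args = [
        (cnv, y, covariates, family, model, event, fixed_shape, test)
        for cnv in cnv_list
    ]
    if workers == 1:
        out = [_one_cnv_pvalue(*a) for a in args]
    else:
        from joblib import Parallel, delayed

        out = Parallel(n_jobs=workers)(delayed(_one_cnv_pvalue)(*a) for a in args)
    df = pd.DataFrame(
        {"cnv": names, "pvalue": [p for p, _ in out], "error": [e for _, e in out]}
    )
    if adjust == "bh":
        df["pvalue_bh"] = bh_adjust(df["pvalue"].to_numpy())
    elif adjust is not None:
        raise ValueError("adjust must be None or 'bh'")
    return df


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (NaN passed through)."""
    from statsmodels.stats.multitest import multipletests

    p = np.asarray(pvalues, dtype=float)
    out = np.full(p.shape, np.nan)
    ok = np.isfinite(p)
    if ok.any():
        out[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return out
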