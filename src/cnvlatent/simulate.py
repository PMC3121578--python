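"""Synthetic CNV data generators.

Each generator draws a true copy class per individual from the class
prevalences ``w``, a surrogate signal intensity from a Gaussian centred on
the class-specific mean (emulating an MLPA-like univariate probe signal),
and a phenotype from the family-specific model:

* binary cohort:       P(y=1 | c) = expit(logit(p0) + log(OR) * c)
* case-control:        the binary model, sampled retrospectively until the
                       requested case and control counts are reached
* poisson:             y ~ Poisson(lambda0 * RR^c)
* normal:              y ~ N(mean0 + delta * c, sd_resid)
* weibull (cohort):    event time T with hazard alpha t^(alpha-1) lambda_c,
                       right-censored at a fixed time.

``make_uncertainty_scenario`` builds case-control configurations whose
mixture-separation quality score Q is exactly a target value (unit-spaced
means, common sigma = 1/Q), the regime used to probe how calling
uncertainty degrades association estimates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SimData",
    "CaseControlScenario",
    "sim_binary",
    "sim_casecontrol",
    "sim_poisson",
    "sim_normal",
    "sim_weibull",
    "weibull_rates",
    "censoring_time",
    "make_uncertainty_scenario",
]


@dataclass
class SimData:
    """Simulated dataset: surrogate signal, true copy class, response."""

    surrog: np.ndarray
    copy: np.ndarray
    resp: np.ndarray
    cens: np.ndarray | None = None  # 1 = event observed, 0 = censored

    @property
    def n(self) -> int:
        return self.resp.size

    def to_frame(self):
        import pandas as pd

        data = {"surrog": self.surrog, "copy": self.copy, "resp": self.resp}
        if self.cens is not None:
            data["cens"] = self.cens
        return pd.DataFrame(data)


def _rng(seed):
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def _check_classes(w, mu_surrog, sd_surrog):
    w = np.asarray(w, dtype=float)
    mu = np.asarray(mu_surrog, dtype=float)
    sd = np.asarray(sd_surrog, dtype=float)
    if sd.size == 1:
        sd = np.full(w.size, float(sd))
    if not (w.size == mu.size == sd.size):
        raise ValueError("w, mu_surrog and sd_surrog must have equal length")
    if abs(w.sum() - 1.0) > 1e-8 or np.any(w <= 0):
        raise ValueError("class probabilities must be positive and sum to 1")
    if np.any(sd <= 0):
        raise ValueError("surrogate SDs must be positive")
    return w, mu, sd


def _draw_classes(rng, n, w):
    return rng.choice(w.size, size=n, p=w)


def _draw_signal(rng, copy, mu, sd):
    return rng.normal(mu[copy], sd[copy])


def sim_binary(n, w, mu_surrog, sd_surrog, p0, or_per_copy, seed=None) -> SimData:
    """Cohort with a binary response; log-odds linear in copy number."""
    rng = _rng(seed)
    w, mu, sd = _check_classes(w, mu_surrog, sd_surrog)
    if not 0 < p0 < 1:
        raise ValueError("baseline prevalence p0 must be in (0, 1)")
    copy = _draw_classes(rng, n, w)
    surrog = _draw_signal(rng, copy, mu, sd)
    logit_p = np.log(p0 / (1 - p0)) + np.log(or_per_copy) * copy
    y = (rng.random(n) < 1.0 / (1.0 + np.exp(-logit_p))).astype(int)
    return SimData(surrog=surrog, copy=copy, resp=y)


def sim_casecontrol(
    n_cases, n_controls, w, mu_surrog, sd_surrog, p0, or_per_copy,
    seed=None, max_draws=10_000_000,
) -> SimData:
    """Retrospective case-control design.

    Individuals are drawn from the binary cohort model and kept until the
    requested numbers of cases and controls are reached (rejection
    sampling, capped at `max_draws` candidate draws).  Cases come first in
    the returned arrays.
    """
    rng = _rng(seed)
    w, mu, sd = _check_classes(w, mu_surrog, sd_surrog)
    if not 0 < p0 < 1:
        raise ValueError("baseline prevalence p0 must be in (0, 1)")
    need = {1: int(n_cases), 0: int(n_controls)}
    got = {1: [], 0: []}
    drawn = 0
    batch = max(1024, 4 * (n_cases + n_controls))
    logit0 = np.log(p0 / (1 - p0))
    while (len(got[1]) < need[1] or len(got[0]) < need[0]):
        if drawn >= max_draws:
            raise RuntimeError(
                f"case-control sampling exhausted {max_draws} draws "
                f"(cases {len(got[1])}/{need[1]}, controls {len(got[0])}/{need[0]})"
            )
        m = min(batch, max_draws - drawn)
        drawn += m
        copy = _draw_classes(rng, m, w)
        p = 1.0 / (1.0 + np.exp(-(logit0 + np.log(or_per_copy) * copy)))
        y = (rng.random(m) < p).astype(int)
        for lab in (1, 0):
            short = need[lab] - len(got[lab])
            if short > 0:
                idx = np.flatnonzero(y == lab)[:short]
                got[lab].extend(copy[idx].tolist())
    copy = np.array(got[1] + got[0], dtype=int)
    y = np.concatenate([np.ones(need[1], int), np.zeros(need[0], int)])
    surrog = _draw_signal(rng, copy, mu, sd)
    return SimData(surrog=surrog, copy=copy, resp=y)


def sim_poisson(n, w, mu_surrog, sd_surrog, lambda0, rr_per_copy, seed=None) -> SimData:
    """Cohort with a count response; log-rate linear in copy number."""
    rng = _rng(seed)
    w, mu, sd = _check_classes(w, mu_surrog, sd_surrog)
    if lambda0 <= 0:
        raise ValueError("baseline rate must be positive")
    copy = _draw_classes(rng, n, w)
    surrog = _draw_signal(rng, copy, mu, sd)
    y = rng.poisson(lambda0 * rr_per_copy**copy)
    return SimData(surrog=surrog, copy=copy, resp=y)


def sim_normal(n, w, mu_surrog, sd_surrog, mean0, delta, sd_resid, seed=None) -> SimData:
    """Cohort with a quantitative response; mean shift `delta` per copy."""
    rng = _rng(seed)
    w, mu, sd = _check_classes(w, mu_surrog, sd_surrog)
    if sd_resid <= 0:
        raise ValueError("residual SD must be positive")
    copy = _draw_classes(rng, n, w)
    surrog = _draw_signal(rng, copy, mu, sd)
    y = rng.normal(mean0 + delta * copy, sd_resid)
    return SimData(surrog=surrog, copy=copy, resp=y)


def weibull_rates(incid0, hr_per_copy, n_classes=3) -> np.ndarray:
    """Per-class Weibull rate parameters lambda_c = incid0 * HR^c."""
    if incid0 <= 0 or hr_per_copy <= 0:
        raise ValueError("incidence and hazard ratio must be positive")
    return incid0 * hr_per_copy ** np.arange(n_classes)


def censoring_time(perc_obs, shape, lam, at="mean") -> float:
    """Fixed administrative censoring time giving roughly `perc_obs` events.

    The time is the `perc_obs` quantile of a Weibull with the given shape
    and scale lambda^(-1/shape); `at` selects which scale anchors the
    quantile: "mean" uses the mean of the per-class scales, "baseline" the
    zero-copy (first) class scale, under which the zero-copy event fraction
    is exactly `perc_obs`.
    """
    if not 0 < perc_obs < 1:
        raise ValueError("perc_obs must be in (0, 1)")
    lam = np.atleast_1d(np.asarray(lam, dtype=float))
    if np.any(lam <= 0) or shape <= 0:
        raise ValueError("rates and shape must be positive")
    scales = lam ** (-1.0 / shape)
    scale = float(scales.mean()) if at == "mean" else float(scales[0])
    return float(scale * (-np.log1p(-perc_obs)) ** (1.0 / shape))


def sim_weibull(n, w, mu_surrog, sd_surrog, lam, shape, time_cens, seed=None) -> SimData:
    """Cohort with a right-censored Weibull time-to-event response.

    The event time of class c has hazard shape * t^(shape-1) * lambda_c
    (Weibull with scale lambda_c^(-1/shape)); times are censored at the
    fixed time `time_cens`; `cens` is 1 for an observed event.
    """
    rng = _rng(seed)
    w, mu, sd = _check_classes(w, mu_surrog, sd_surrog)
    lam = np.asarray(lam, dtype=float)
    if lam.size != w.size:
        raise ValueError("one rate per copy class")
    if np.any(lam <= 0) or shape <= 0 or time_cens <= 0:
        raise ValueError("rates, shape and censoring time must be positive")
    copy = _draw_classes(rng, n, w)
    surrog = _draw_signal(rng, copy, mu, sd)
    u = rng.random(n)
    t = (-np.log(u) / lam[copy]) ** (1.0 / shape)
    cens = (t <= time_cens).astype(int)
    resp = np.minimum(t, time_cens)
    return SimData(surrog=surrog, copy=copy, resp=resp, cens=cens)


@dataclass
class CaseControlScenario:
    """A case-control simulation configuration with a target quality score.

    Signal means are unit-spaced and the common signal SD is 1/Q, so the
    adjacent-pair separation quality score of the generating mixture equals
    `q_target` exactly.
    """

    q_target: float
    n_cases: int
    n_controls: int
    w: np.ndarray
    p0: float
    or_per_copy: float
    mu_surrog: np.ndarray = field(init=False)
    sd_surrog: np.ndarray = field(init=False)

    def __post_init__(self):
        if self.q_target <= 0:
            raise ValueError("q_target must be positive")
        self.w = np.asarray(self.w, dtype=float)
        self.mu_surrog = np.arange(self.w.size, dtype=float)
        self.sd_surrog = np.full(self.w.size, 1.0 / self.q_target)

    def simulate(self, seed=None) -> SimData:
        return sim_casecontrol(
            self.n_cases, self.n_controls, self.w, self.mu_surrog,
            self.sd_surrog, self.p0, self.or_per_copy, seed=seed,
        )


def make_uncertainty_scenario(
    q_target, n_cases, n_controls, w=(0.25, 0.5, 0.25), p0=0.1, or_per_copy=1.5,
) -> CaseControlScenario:
    """Case-control scenario whose calling quality score equals `q_target`."""
    return CaseControlScenario(
        q_target=q_target, n_cases=n_cases, n_controls=n_controls,
        w=np.asarray(w, dtype=float), p0=p0, or_per_copy=or_per_copy,
    )
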