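"""Copy-number genotype calling from univariate probe-signal intensities.

Signal intensities (one value per individual, e.g. MLPA peak heights or
aCGH log-ratios summarised per region) are modelled as a finite mixture of
Gaussian components, one component per copy-number class.  Calling is
probabilistic: each individual receives a posterior probability for every
copy class, and the posterior matrix — not a hard call — is what the
association models consume.

Three features beyond a plain mixture fit:

* an optional *zero-copy threshold*: intensities strictly below it are
  assigned zero copies with certainty (a point mass at 0), and the EM runs
  only on the remaining signal;
* *batch handling*: component means and SDs are estimated separately per
  batch while the class prevalences are pooled across batches (prevalences
  are a population quantity and should not vary with the assay plate);
* model selection by BIC over the number of components.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import logsumexp
from scipy.stats import chi2, norm

__all__ = [
    "SignalData",
    "MixtureFit",
    "BatchedMixtureFit",
    "CNVGenotype",
    "GofResult",
    "QualityScore",
    "GaussianSignalMixture",
    "fit_gaussian_mixture",
    "fit_batched_mixture",
    "select_num_components",
    "pool_prevalences",
    "posterior_matrix",
    "call_from_cutpoints",
    "cnv_from_probabilities",
    "relabel_copies",
    "goodness_of_fit",
    "quality_score",
]


# --------------------------------------------------------------------------
# containers
# --------------------------------------------------------------------------


@dataclass
class SignalData:
    """Per-individual univariate signal with optional batch labels."""

    intensity: np.ndarray
    ids: np.ndarray | None = None
    batch: np.ndarray | None = None

    def __post_init__(self):
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.intensity.ndim != 1:
            raise ValueError("intensity must be one-dimensional")
        if not np.all(np.isfinite(self.intensity)):
            raise ValueError("intensities must be finite (drop missing values first)")
        n = self.intensity.size
        if self.ids is None:
            self.ids = np.arange(n)
        self.ids = np.asarray(self.ids)
        if self.ids.size != n:
            raise ValueError("ids and intensity lengths differ")
        if len(np.unique(self.ids)) != n:
            raise ValueError("duplicate ids in signal data")
        if self.batch is not None:
            self.batch = np.asarray(self.batch)
            if self.batch.size != n:
                raise ValueError("batch labels must cover all ids")

    @property
    def n(self) -> int:
        return self.intensity.size


def _as_signal(signal) -> SignalData:
    if isinstance(signal, SignalData):
        return signal
    return SignalData(np.asarray(signal, dtype=float))


@dataclass
class MixtureFit:
    """A fitted univariate Gaussian mixture over copy-number classes.

    When a zero-copy threshold was triggered the first component is a point
    mass at 0 (mean 0, sd 0) whose weight is the below-threshold sample
    fraction; ``loglik``/``bic``/``n_used`` refer to the EM fit on the
    above-threshold signal.
    """

    means: np.ndarray
    sds: np.ndarray
    weights: np.ndarray
    loglik: float
    bic: float
    n_used: int
    converged: bool
    has_zero_mass: bool = False
    threshold_zero: float | None = None
    n_iter: int = 0
    mix_method: str = "em_raw"
    bic_trace: dict | None = None

    def __post_init__(self):
        self.means = np.asarray(self.means, dtype=float)
        self.sds = np.asarray(self.sds, dtype=float)
        self.weights = np.asarray(self.weights, dtype=float)
        if abs(self.weights.sum() - 1.0) > 1e-10:
            raise ValueError("component weights must sum to 1")
        if np.any(np.diff(self.means) <= 0):
            raise ValueError("component means must be strictly increasing")

    @property
    def n_components(self) -> int:
        """Total number of copy classes, including a zero point mass if any."""
        return self.means.size

    def summary(self) -> str:
        lines = [
            "Gaussian mixture signal fit",
            f"  classes:     {self.n_components}"
            + (" (incl. zero-copy point mass)" if self.has_zero_mass else ""),
            f"  means:       {np.round(self.means, 4).tolist()}",
            f"  variances:   {np.round(self.sds ** 2, 4).tolist()}",
            f"  proportions: {np.round(self.weights, 4).tolist()}",
            f"  loglik: {self.loglik:.4f}   BIC: {self.bic:.4f}   n_used: {self.n_used}",
            f"  converged: {self.converged}",
        ]
        return "\n".join(lines)


@dataclass
class BatchedMixtureFit:
    """Per-batch mixture fits sharing one set of pooled class prevalences."""

    per_batch: dict
    batch_sizes: dict
    pooled_weights: np.ndarray
    n_total: int
    num_batches: int
    threshold_zero: float | None = None
    has_zero_mass: bool = False

    def __post_init__(self):
        sizes = np.array([self.batch_sizes[b] for b in self.per_batch], dtype=int)
        if sizes.sum() != self.n_total:
            raise ValueError("batch sizes do not sum to n_total")
        ks = {f.n_components for f in self.per_batch.values()}
        if len(ks) != 1:
            raise ValueError("all per-batch fits must share the component count")
        if abs(np.sum(self.pooled_weights) - 1.0) > 1e-10:
            raise ValueError("pooled weights must sum to 1")

    @property
    def n_components(self) -> int:
        return next(iter(self.per_batch.values())).n_components

    @property
    def converged(self) -> bool:
        return all(f.converged for f in self.per_batch.values())


@dataclass
class CNVGenotype:
    """Posterior copy-number probability matrix (n individuals x C classes).

    This is the central exchange object: produced by the mixture caller, by
    hard cut-point calling, or wrapped around an external probability matrix
    (e.g. genotype probabilities from SNP imputation), and consumed by the
    latent-class association models.
    """

    prob: np.ndarray
    copies: np.ndarray
    ids: np.ndarray | None = None
    source: str = "external"
    signal: SignalData | None = None
    fit: MixtureFit | BatchedMixtureFit | None = None

    def __post_init__(self):
        self.prob = np.asarray(self.prob, dtype=float)
        if self.prob.ndim != 2 or self.prob.shape[1] < 1:
            raise ValueError("prob must be an n x C matrix with C >= 1")
        if np.any(self.prob < -1e-12) or np.any(self.prob > 1 + 1e-12):
            raise ValueError("probabilities must lie in [0, 1]")
        rowsum = self.prob.sum(axis=1)
        if np.any(np.abs(rowsum - 1.0) > 1e-8):
            raise ValueError("posterior rows must sum to 1 (renormalise first)")
        self.copies = np.asarray(self.copies, dtype=int)
        if self.copies.size != self.prob.shape[1]:
            raise ValueError("one copy label per probability column")
        if self.copies.size > 1 and np.any(np.diff(self.copies) <= 0):
            raise ValueError("copy labels must be strictly increasing")
        if self.ids is None:
            self.ids = np.arange(self.prob.shape[0])
        self.ids = np.asarray(self.ids)
        if self.ids.size != self.prob.shape[0]:
            raise ValueError("ids must match the number of rows")

    @property
    def n(self) -> int:
        return self.prob.shape[0]

    @property
    def n_classes(self) -> int:
        return self.prob.shape[1]

    def best_guess(self) -> np.ndarray:
        """Hard calls: the copy label of the highest-posterior class per row."""
        return self.copies[np.argmax(self.prob, axis=1)]

    def relabel(self, copies) -> "CNVGenotype":
        return relabel_copies(self, copies)


@dataclass
class GofResult:
    statistic: float
    df: int
    pvalue: float
    n_bins: int


@dataclass
class QualityScore:
    value: float
    type: str


# --------------------------------------------------------------------------
# EM core
# --------------------------------------------------------------------------

_VAR_FLOOR_FRAC = 1e-6


def _quantile_init(x, counts, k):
    """Deterministic initial parameters: split the sorted signal into k
    equal-mass groups and use their moments."""
    order = np.argsort(x)
    xs, cs = x[order], counts[order]
    cum = np.cumsum(cs)
    total = cum[-1]
    edges = total * np.arange(1, k) / k
    idx = np.searchsorted(cum, edges, side="left")
    bounds = np.concatenate([[0], idx + 1, [xs.size]])
    overall_sd = np.sqrt(max(_weighted_var(x, counts), 1e-300))
    mu, sd, w = np.empty(k), np.empty(k), np.empty(k)
    for j in range(k):
        lo, hi = bounds[j], max(bounds[j + 1], bounds[j] + 1)
        seg_x, seg_c = xs[lo:hi], cs[lo:hi]
        w[j] = seg_c.sum() / total
        mu[j] = np.average(seg_x, weights=seg_c)
        sd[j] = np.sqrt(max(_weighted_var(seg_x, seg_c), 0.0))
        sd[j] = max(sd[j], 1e-3 * overall_sd, 1e-12)
    w = np.maximum(w, 1e-6)
    w /= w.sum()
    # nudge ties apart so components do not start identical
    for j in range(1, k):
        if mu[j] <= mu[j - 1]:
            mu[j] = mu[j - 1] + 1e-6 * (1 + overall_sd)
    return mu, sd, w


def _weighted_var(x, counts):
    m = np.average(x, weights=counts)
    return np.average((x - m) ** 2, weights=counts)


_LOG_SQRT_2PI = 0.5 * np.log(2 * np.pi)


def _log_mixture_components(x, mu, sd, w):
    """n x k matrix log(w_c) + log phi(x; mu_c, sd_c), computed directly."""
    z = (x[:, None] - mu[None, :]) / sd[None, :]
    return np.log(w)[None, :] - np.log(sd)[None, :] - _LOG_SQRT_2PI - 0.5 * z * z


def _em_once(x, counts, mu, sd, w, tol, max_iter, var_floor, debug=__debug__):
    """Run EM to convergence from the given start.  Returns params sorted by
    ascending mean plus (loglik, n_iter, converged, floor_hit)."""
    k = mu.size
    ll_prev = -np.inf
    ll_path = []
    converged = False
    n_iter = 0
    xc = x[:, None]
    unit_counts = np.all(counts == 1.0)
    for n_iter in range(1, max_iter + 1):
        z = (xc - mu) / sd
        log_comp = (np.log(w) - np.log(sd) - _LOG_SQRT_2PI) - 0.5 * (z * z)
        m = log_comp.max(axis=1)
        np.exp(log_comp - m[:, None], out=log_comp)  # now holds unnormalised resp
        tot = log_comp.sum(axis=1)
        ll_i = m + np.log(tot)
        ll = float(ll_i.sum()) if unit_counts else float(np.dot(counts, ll_i))
        ll_path.append(ll)
        if debug and len(ll_path) > 1:
            assert ll >= ll_path[-2] - 1e-8 * (1 + abs(ll)), "EM log-likelihood decreased"
        if abs(ll - ll_prev) <= tol * (1 + abs(ll)):
            converged = True
            break
        ll_prev = ll
        r = log_comp
        r /= tot[:, None]
        if not unit_counts:
            r *= counts[:, None]
        nk = np.maximum(r.sum(axis=0), 1e-300)
        w = nk / nk.sum()
        mu = (r * xc).sum(axis=0) / nk
        var = np.einsum("ik,ik->k", r, (xc - mu) ** 2) / nk
        var = np.maximum(var, var_floor)
        sd = np.sqrt(var)
    floor_hit = bool(np.any(sd**2 <= var_floor * (1 + 1e-9))) and k > 1
    order = np.argsort(mu)
    return mu[order], sd[order], w[order], ll_path[-1], n_iter, converged, floor_hit


def _fit_em(x, counts, k, tol, max_iter, seed, n_restarts=3):
    """Deterministic quantile-initialised EM with seeded multi-start fallback.

    Restarts fire only on genuine non-convergence of the log-likelihood;
    a variance-floor hit (component collapse, typical when k exceeds the
    number of real clusters) keeps converged=False but is not retried, as
    random restarts re-collapse and only burn iterations.
    """
    var_floor = _VAR_FLOOR_FRAC * max(_weighted_var(x, counts), 1e-300)
    mu0, sd0, w0 = _quantile_init(x, counts, k)
    best = _em_once(x, counts, mu0, sd0, w0, tol, max_iter, var_floor)
    if not best[5]:
        rng = np.random.default_rng(seed)
        lo, hi = x.min(), x.max()
        overall_sd = np.sqrt(_weighted_var(x, counts))
        for _ in range(n_restarts):
            mu = np.sort(rng.uniform(lo, hi, size=k))
            sd = np.full(k, max(overall_sd / k, 1e-6))
            w = np.full(k, 1.0 / k)
            cand = _em_once(x, counts, mu, sd, w, tol, max_iter, var_floor)
            if cand[5] and not cand[6] and cand[3] >= best[3]:
                best = cand
                break
            if cand[3] > best[3]:
                best = cand
    return best


# --------------------------------------------------------------------------
# fitting entry points
# --------------------------------------------------------------------------


def _split_zero(x, threshold_zero):
    if threshold_zero is None:
        return x, 0, False
    below = x < threshold_zero
    if not np.any(~below):
        raise ValueError("all intensities fall below threshold_zero")
    return x[~below], int(below.sum()), bool(below.any())


def _prepare(x, mix_method):
    """Return (values, counts) for the EM: raw values, or histogram-binned
    values (midpoints with counts) for the mixdist-like flavour."""
    if mix_method == "em_raw":
        return x, np.ones_like(x)
    if mix_method == "em_binned":
        n_bins = int(np.ceil(np.log2(x.size)) + 1)
        counts, edges = np.histogram(x, bins=n_bins)
        mids = 0.5 * (edges[:-1] + edges[1:])
        keep = counts > 0
        return mids[keep], counts[keep].astype(float)
    raise ValueError(f"unknown mix_method {mix_method!r}")


def _raw_loglik(x, mu, sd, w):
    log_comp = _log_mixture_components(x, mu, sd, w)
    return float(logsumexp(log_comp, axis=1).sum())


def _bic(loglik, k, n):
    return -2.0 * loglik + (3 * k - 1) * np.log(n)


def _fit_k(x_pos, k, mix_method, tol, max_iter, seed):
    xe, ce = _prepare(x_pos, mix_method)
    mu, sd, w, _, n_iter, converged, floor_hit = _fit_em(xe, ce, k, tol, max_iter, seed)
    ll = _raw_loglik(x_pos, mu, sd, w)  # report/select on the raw data
    return mu, sd, w, ll, n_iter, converged and not floor_hit


def fit_gaussian_mixture(
    signal,
    n_components="auto",
    threshold_zero: float | None = None,
    mix_method: str = "em_raw",
    max_components: int = 6,
    tol: float = 1e-8,
    max_iter: int = 500,
    seed: int = 0,
) -> MixtureFit:
    """Fit a univariate Gaussian mixture to signal intensities.

    Parameters
    ----------
    signal : SignalData or array-like
        Per-individual intensities.
    n_components : int or "auto"
        Number of Gaussian components for the EM (the zero-copy point mass,
        when triggered by `threshold_zero`, is an additional class).  "auto"
        selects by BIC over 1..max_components.
    threshold_zero : float, optional
        Intensities strictly below this value are called zero copies with
        certainty and excluded from the EM.
    mix_method : {"em_raw", "em_binned"}
        Fit the EM on raw values, or on histogram-binned values (counts at
        bin midpoints); reported log-likelihood and BIC always refer to the
        raw data.
    """
    sig = _as_signal(signal)
    x = sig.intensity
    if x.size < 10:
        raise ValueError("need at least 10 intensities to fit a mixture")
    if np.ptp(x) == 0:
        raise ValueError("degenerate fit: all intensities identical")
    x_pos, n_zero, has_zero = _split_zero(x, threshold_zero)
    if np.ptp(x_pos) == 0:
        raise ValueError("degenerate fit: all above-threshold intensities identical")
    n_used = x_pos.size

    bic_trace = None
    if n_components == "auto":
        bic_trace = {}
        best_k, best = None, None
        for kk in range(1, max_components + 1):
            if n_used < 2 * kk:
                break
            fit_kk = _fit_k(x_pos, kk, mix_method, tol, max_iter, seed)
            bic_trace[kk] = _bic(fit_kk[3], kk, n_used)
            # strict inequality: ties break toward the smaller model
            if best is None or bic_trace[kk] < bic_trace[best_k]:
                best_k, best = kk, fit_kk
        k = best_k
        mu, sd, w, ll, n_iter, converged = best
    else:
        k = int(n_components)
        if k < 1:
            raise ValueError("n_components must be >= 1")
        mu, sd, w, ll, n_iter, converged = _fit_k(x_pos, k, mix_method, tol, max_iter, seed)

    if has_zero:
        zero_frac = n_zero / x.size
        mu = np.concatenate([[0.0], mu])
        sd = np.concatenate([[0.0], sd])
        w = np.concatenate([[zero_frac], (1 - zero_frac) * w])
    return MixtureFit(
        means=mu,
        sds=sd,
        weights=w,
        loglik=ll,
        bic=_bic(ll, k, n_used),
        n_used=n_used,
        converged=bool(converged),
        has_zero_mass=has_zero,
        threshold_zero=threshold_zero,
        n_iter=n_iter,
        mix_method=mix_method,
        bic_trace=bic_trace,
    )


def select_num_components(
    signal,
    threshold_zero: float | None = None,
    mix_method: str = "em_raw",
    max_components: int = 6,
    tol: float = 1e-8,
    max_iter: int = 500,
    seed: int = 0,
) -> int:
    """Number of copy classes minimising BIC (= -2 loglik + (3k-1) log n).

    Returns the total class count, i.e. including the zero-copy point-mass
    class when `threshold_zero` is set and triggered.  Ties break toward the
    smaller model.
    """
    fit = fit_gaussian_mixture(
        signal,
        n_components="auto",
        threshold_zero=threshold_zero,
        mix_method=mix_method,
        max_components=max_components,
        tol=tol,
        max_iter=max_iter,
        seed=seed,
    )
    return fit.n_components


def pool_prevalences(per_batch_w, batch_sizes) -> np.ndarray:
    """Pool class prevalences across batches: w_c = sum_b n_b w_cb / n.

    Prevalences are assumed batch-invariant in the population, so the pooled
    estimate is the batch-size-weighted mean of the per-batch estimates.
    """
    ws = [np.asarray(w, dtype=float) for w in per_batch_w]
    sizes = np.asarray(batch_sizes, dtype=float)
    if len(ws) != sizes.size:
        raise ValueError("one batch size per weight vector")
    if np.any(sizes <= 0):
        raise ValueError("batch sizes must be positive")
    length = ws[0].size
    if any(w.size != length for w in ws):
        raise ValueError("weight vectors differ in length")
    stacked = np.vstack(ws)
    pooled = sizes @ stacked / sizes.sum()
    return pooled / pooled.sum()


def fit_batched_mixture(
    signal,
    n_components="auto",
    threshold_zero: float | None = None,
    mix_method: str = "em_raw",
    max_components: int = 6,
    tol: float = 1e-8,
    max_iter: int = 500,
    seed: int = 0,
) -> BatchedMixtureFit:
    """Fit batch-specific component means/SDs with pooled prevalences.

    The component count is chosen once on the pooled signal; each batch's EM
    is then initialised from the pooled fit so classes stay aligned across
    batches.  Pooled prevalences are the batch-size-weighted mean of the
    per-batch weights.
    """
    sig = _as_signal(signal)
    if sig.batch is None:
        raise ValueError("fit_batched_mixture requires batch labels")
    pooled_fit = fit_gaussian_mixture(
        sig.intensity,
        n_components=n_components,
        threshold_zero=threshold_zero,
        mix_method=mix_method,
        max_components=max_components,
        tol=tol,
        max_iter=max_iter,
        seed=seed,
    )
    k = pooled_fit.n_components - (1 if pooled_fit.has_zero_mass else 0)
    has_zero_any = pooled_fit.has_zero_mass
    init_mu = pooled_fit.means[1:] if has_zero_any else pooled_fit.means
    init_sd = pooled_fit.sds[1:] if has_zero_any else pooled_fit.sds
    init_w = pooled_fit.weights[1:] if has_zero_any else pooled_fit.weights
    init_w = init_w / init_w.sum()

    per_batch, batch_sizes = {}, {}
    labels = np.unique(sig.batch)
    for b in labels:
        xb = sig.intensity[sig.batch == b]
        batch_sizes[b] = xb.size
        xb_pos, n_zero, _ = _split_zero(xb, threshold_zero)
        if xb_pos.size < max(10, 2 * k):
            raise ValueError(
                f"batch {b!r} has only {xb_pos.size} usable intensities, "
                f"too few for a {k}-component fit"
            )
        xe, ce = _prepare(xb_pos, mix_method)
        var_floor = _VAR_FLOOR_FRAC * max(_weighted_var(xe, ce), 1e-300)
        mu, sd, w, _, n_iter, converged, floor_hit = _em_once(
            xe, ce, init_mu.copy(), init_sd.copy(), init_w.copy(), tol, max_iter, var_floor
        )
        ll = _raw_loglik(xb_pos, mu, sd, w)
        if has_zero_any:
            zf = n_zero / xb.size
            mu = np.concatenate([[0.0], mu])
            sd = np.concatenate([[0.0], sd])
            w = np.concatenate([[zf], (1 - zf) * w]) if zf < 1 else w
        per_batch[b] = MixtureFit(
            means=mu,
            sds=sd,
            weights=w,
            loglik=ll,
            bic=_bic(ll, k, xb_pos.size),
            n_used=xb_pos.size,
            converged=bool(converged and not floor_hit),
            has_zero_mass=has_zero_any,
            threshold_zero=threshold_zero,
            n_iter=n_iter,
            mix_method=mix_method,
        )
    pooled_w = pool_prevalences(
        [per_batch[b].weights for b in labels], [batch_sizes[b] for b in labels]
    )
    return BatchedMixtureFit(
        per_batch=per_batch,
        batch_sizes=batch_sizes,
        pooled_weights=pooled_w,
        n_total=sig.n,
        num_batches=labels.size,
        threshold_zero=threshold_zero,
        has_zero_mass=has_zero_any,
    )


# --------------------------------------------------------------------------
# posterior probabilities and alternative calling routes
# --------------------------------------------------------------------------


def _default_copies(n_classes: int, has_zero_mass: bool) -> np.ndarray:
    # 0..C-1 when a zero-copy class exists, else 1..C
    return np.arange(n_classes) if has_zero_mass else np.arange(1, n_classes + 1)


def _component_posterior(x, means, sds, weights, threshold_zero, has_zero_mass):
    n, C = x.size, means.size
    prob = np.zeros((n, C))
    if has_zero_mass:
        below = x < threshold_zero
        prob[below, 0] = 1.0
        gm, gs, gw = means[1:], sds[1:], weights[1:]
        idx = ~below
    else:
        below = np.zeros(n, dtype=bool)
        gm, gs, gw = means, sds, weights
        idx = np.ones(n, dtype=bool)
    if idx.any():
        logp = np.log(np.maximum(gw, 1e-300))[None, :] + norm.logpdf(
            x[idx, None], gm[None, :], gs[None, :]
        )
        logp -= logsumexp(logp, axis=1)[:, None]
        prob[np.ix_(idx, np.arange(C - gm.size, C))] = np.exp(logp)
    prob /= prob.sum(axis=1, keepdims=True)
    return prob


def posterior_matrix(fit, signal, copies=None) -> CNVGenotype:
    """Bayes posterior copy-class probabilities for each individual.

    w_ic = w_c phi(y_i; mu_c, sigma_c) / sum_k w_k phi(y_i; mu_k, sigma_k).
    For batched fits the densities use the individual's batch-specific
    means/SDs while the prior weights are the pooled prevalences.
    Below-threshold individuals get probability 1 on the zero-copy class.
    """
    sig = _as_signal(signal)
    if isinstance(fit, BatchedMixtureFit):
        if sig.batch is None:
            raise ValueError("batched fit requires batch labels on the signal")
        missing = set(np.unique(sig.batch)) - set(fit.per_batch)
        if missing:
            raise ValueError(f"signal contains batches absent from the fit: {missing}")
        C = fit.n_components
        prob = np.zeros((sig.n, C))
        for b, bfit in fit.per_batch.items():
            mask = sig.batch == b
            if not mask.any():
                continue
            prob[mask] = _component_posterior(
                sig.intensity[mask],
                bfit.means,
                bfit.sds,
                fit.pooled_weights,
                fit.threshold_zero,
                fit.has_zero_mass,
            )
        has_zero = fit.has_zero_mass
    else:
        if not fit.converged:
            warnings.warn("posterior_matrix called on a non-converged mixture fit")
        prob = _component_posterior(
            sig.intensity,
            fit.means,
            fit.sds,
            fit.weights,
            fit.threshold_zero,
            fit.has_zero_mass,
        )
        has_zero = fit.has_zero_mass
    if copies is None:
        copies = _default_copies(prob.shape[1], has_zero)
    return CNVGenotype(
        prob=prob, copies=copies, ids=sig.ids, source="mixture", signal=sig, fit=fit
    )


def call_from_cutpoints(signal, cutpoints, copies=None) -> CNVGenotype:
    """Hard copy-number calls from signal-intensity cut points.

    Intervals are left-closed/right-open: a value exactly at a cut point is
    assigned to the upper class.
    """
    sig = _as_signal(signal)
    cut = np.asarray(cutpoints, dtype=float)
    if cut.ndim != 1 or cut.size < 1:
        raise ValueError("need at least one cutpoint")
    if np.any(np.diff(cut) <= 0):
        raise ValueError("cutpoints must be strictly ascending")
    C = cut.size + 1
    if copies is None:
        copies = np.arange(C)
    copies = np.asarray(copies, dtype=int)
    if copies.size != C:
        raise ValueError("need len(cutpoints) + 1 copy labels")
    cls = np.searchsorted(cut, sig.intensity, side="right")
    prob = np.zeros((sig.n, C))
    prob[np.arange(sig.n), cls] = 1.0
    return CNVGenotype(prob=prob, copies=copies, ids=sig.ids, source="cutpoints", signal=sig)


def cnv_from_probabilities(prob, copies=None, ids=None) -> CNVGenotype:
    """Wrap an externally produced copy-number probability matrix.

    Rows are renormalised to sum to 1, so unnormalised non-negative scores
    are accepted.
    """
    prob = np.asarray(prob, dtype=float)
    if prob.ndim != 2:
        raise ValueError("prob must be a 2-d matrix")
    if np.any(prob < 0):
        raise ValueError("probabilities must be non-negative")
    rowsum = prob.sum(axis=1)
    if np.any(rowsum <= 0):
        bad = int(np.flatnonzero(rowsum <= 0)[0])
        raise ValueError(f"row {bad} has zero total probability")
    prob = prob / rowsum[:, None]
    if copies is None:
        copies = np.arange(prob.shape[1])
    return CNVGenotype(prob=prob, copies=copies, ids=ids, source="external")


def relabel_copies(cnv: CNVGenotype, copies) -> CNVGenotype:
    """Reassign copy labels to the probability columns (probabilities untouched)."""
    copies = np.asarray(copies, dtype=int)
    if copies.size != cnv.n_classes:
        raise ValueError("need one copy label per class")
    return replace(cnv, prob=cnv.prob.copy(), copies=copies)


# --------------------------------------------------------------------------
# diagnostics
# --------------------------------------------------------------------------


def goodness_of_fit(fit: MixtureFit, signal, params_estimated: bool = True) -> GofResult:
    """Pearson chi-square goodness of fit of the Gaussian part of the mixture.

    The above-threshold signal is histogrammed (Sturges' rule); expected
    counts come from the fitted mixture CDF with open-ended outer bins; bins
    with expected count < 5 are merged with their smaller neighbour.
    df = bins - 1 - (3k - 1) free parameters, or bins - 1 with
    ``params_estimated=False`` (mixture parameters fixed externally, not
    estimated from this signal).

    The df correction is exact when the parameters minimise the binned
    chi-square; for the EM flavours fitted here the statistic is
    stochastically somewhat larger, so small p-values are mildly
    anti-conservative and borderline results should not be over-read.
    """
    sig = _as_signal(signal)
    x = sig.intensity
    if fit.threshold_zero is not None:
        x = x[x >= fit.threshold_zero]
    if fit.has_zero_mass:
        gm, gs, gw = fit.means[1:], fit.sds[1:], fit.weights[1:]
        gw = gw / gw.sum()
    else:
        gm, gs, gw = fit.means, fit.sds, fit.weights
    k = gm.size
    n = x.size
    n_bins = int(np.ceil(np.log2(n)) + 1)
    edges = np.linspace(x.min(), x.max(), n_bins + 1)
    obs, _ = np.histogram(x, bins=edges)
    inner = edges[1:-1]
    cdf_at = np.array([np.dot(gw, norm.cdf(e, gm, gs)) for e in inner])
    cdf_full = np.concatenate([[0.0], cdf_at, [1.0]])
    exp = n * np.diff(cdf_full)

    obs, exp = list(obs.astype(float)), list(exp)
    i = 0
    while i < len(exp):
        if exp[i] < 5 and len(exp) > 1:
            j = i - 1 if (i > 0 and (i == len(exp) - 1 or exp[i - 1] <= exp[i + 1])) else i + 1
            lo, hi = min(i, j), max(i, j)
            obs[lo] += obs[hi]
            exp[lo] += exp[hi]
            del obs[hi], exp[hi]
            i = 0
        else:
            i += 1
    obs, exp = np.array(obs), np.array(exp)
    df = obs.size - 1 - ((3 * k - 1) if params_estimated else 0)
    if df <= 0:
        raise ValueError("too few histogram bins after merging (df <= 0)")
    stat = float(np.sum((obs - exp) ** 2 / exp))
    return GofResult(statistic=stat, df=int(df), pvalue=float(chi2.sf(stat, df)), n_bins=obs.size)


def quality_score(cnv: CNVGenotype, type: str = "class") -> QualityScore:
    """Scalar summary of calling certainty.

    type="class": expected proportion of correctly classified individuals,
    (1/n) sum_i max_c w_ic, in [1/C, 1].

    type="cnvtools": component-separation score — the standardised distance
    |mu_{c+1} - mu_c| / ((sigma_c + sigma_{c+1}) / 2) of each adjacent
    component pair, averaged with weights (w_c + w_{c+1}).  Values below ~3
    indicate moderate-to-high calling uncertainty; above ~4.5, uncertainty
    is negligible.  With unit-spaced means and a common sigma this reduces
    to 1/sigma.
    """
    if type == "class":
        return QualityScore(value=float(cnv.prob.max(axis=1).mean()), type="class")
    if type != "cnvtools":
        raise ValueError(f"unknown quality score type {type!r}")
    fit = cnv.fit
    if fit is None:
        raise ValueError("cnvtools score needs a mixture-backed cnv (component parameters)")
    if isinstance(fit, BatchedMixtureFit):
        parts = [
            _separation_score(f.means, f.sds, fit.pooled_weights)
            for f in fit.per_batch.values()
        ]
        sizes = np.array([fit.batch_sizes[b] for b in fit.per_batch], dtype=float)
        return QualityScore(value=float(np.dot(sizes, parts) / sizes.sum()), type="cnvtools")
    return QualityScore(
        value=_separation_score(fit.means, fit.sds, fit.weights), type="cnvtools"
    )


def _separation_score(mu, sd, w):
    if mu.size < 2:
        raise ValueError("cnvtools score needs at least two components")
    d = np.abs(np.diff(mu)) / ((sd[:-1] + sd[1:]) / 2.0)
    pw = w[:-1] + w[1:]
    return float(np.dot(pw, d) / pw.sum())


# --------------------------------------------------------------------------
# model-style front end
# --------------------------------------------------------------------------


class GaussianSignalMixture:
    """Model object for mixture-based copy-number calling.

    Parameters
    ----------
    intensity : array-like
        One signal value per individual.
    ids, batch : array-like, optional
        Identifiers and batch labels.

    ``fit()`` returns a :class:`MixtureResults` from which the posterior
    probability matrix, goodness of fit and quality scores are obtained.
    """

    def __init__(self, intensity, ids=None, batch=None):
        self.signal = SignalData(intensity=np.asarray(intensity, float), ids=ids, batch=batch)

    def fit(
        self,
        n_components="auto",
        threshold_zero=None,
        mix_method="em_raw",
        max_components=6,
        tol=1e-8,
        max_iter=500,
        seed=0,
        batch_effect=None,
    ) -> "MixtureResults":
        use_batch = self.signal.batch is not None if batch_effect is None else batch_effect
        kwargs = dict(
            n_components=n_components,
            threshold_zero=threshold_zero,
            mix_method=mix_method,
            max_components=max_components,
            tol=tol,
            max_iter=max_iter,
            seed=seed,
        )
        fit = (
            fit_batched_mixture(self.signal, **kwargs)
            if use_batch
            else fit_gaussian_mixture(self.signal, **kwargs)
        )
        return MixtureResults(self, fit)


class MixtureResults:
    """Results of a mixture-calling fit: parameters plus posterior access."""

    def __init__(self, model: GaussianSignalMixture, fit):
        self.model = model
        self.fit_ = fit

    @property
    def converged(self) -> bool:
        return self.fit_.converged

    def posterior(self, copies=None) -> CNVGenotype:
        return posterior_matrix(self.fit_, self.model.signal, copies=copies)

    def goodness_of_fit(self) -> GofResult:
        if isinstance(self.fit_, BatchedMixtureFit):
            raise ValueError("goodness of fit is per batch; use fit_.per_batch")
        return goodness_of_fit(self.fit_, self.model.signal)

    def quality_score(self, type: str = "class") -> QualityScore:
        return quality_score(self.posterior(), type=type)

    def summary(self) -> str:
        if isinstance(self.fit_, BatchedMixtureFit):
            parts = [
                f"Batched mixture fit ({self.fit_.num_batches} batches, "
                f"n={self.fit_.n_total})",
                f"  pooled proportions: {np.round(self.fit_.pooled_weights, 4).tolist()}",
            ]
            for b, f in self.fit_.per_batch.items():
                parts.append(f"-- batch {b} --\n{f.summary()}")
            return "\n".join(parts)
        lines = [self.fit_.summary()]
        try:
            gof = self.goodness_of_fit()
            lines.append(f"  goodness-of-fit p-value: {gof.pvalue:.6f}")
        except ValueError:
            pass
        return "\n".join(lines)
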