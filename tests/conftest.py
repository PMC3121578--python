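import json
import subprocess

import numpy as np
import pytest

from cnvlatent import CNVGenotype


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def one_hot_cnv(classes, n_classes=None, copies=None) -> CNVGenotype:
    """Certain-call posterior matrix from integer class indices."""
    classes = np.asarray(classes, dtype=int)
    C = n_classes or classes.max() + 1
    prob = np.eye(C)[classes]
    return CNVGenotype(prob=prob, copies=copies if copies is not None else np.arange(C))


def survreg_weibull_ph(time, event, X, colnames):
    """Independent Weibull proportional-hazards oracle via R survreg.

    survreg fits the AFT form log T = X b + scale * W; the PH coefficients
    are -b/scale with shape 1/scale, and the covariance transforms by the
    delta method from survreg's (b, log scale) covariance.
    Returns (params, bse) ordered (intercept, covariates..., log shape).
    """
    import pandas as pd
    import tempfile, os

    df = pd.DataFrame({"time": time, "event": event})
    for j, name in enumerate(colnames):
        df[name] = np.asarray(X)[:, j]
    with tempfile.TemporaryDirectory() as tmp:
        csv = os.path.join(tmp, "d.csv")
        df.to_csv(csv, index=False)
        rhs = " + ".join(colnames)
        rcode = f"""
        d <- read.csv("{csv}")
        f <- survival::survreg(survival::Surv(time, event) ~ {rhs}, data = d,
                dist = "weibull",
                control = survival::survreg.control(rel.tolerance = 1e-12, iter.max = 200))
        cat(jsonlite::toJSON(list(coef = as.numeric(coef(f)), scale = f$scale,
                                  vcov = as.numeric(vcov(f))), digits = 15))
        """
        res = subprocess.run(["Rscript", "-e", rcode], capture_output=True, text=True)
        if res.returncode != 0:
            raise RuntimeError(f"survreg oracle failed: {res.stderr[-500:]}")
        out = json.loads(res.stdout)
    b = np.asarray(out["coef"], dtype=float)
    scale = float(np.asarray(out["scale"]).ravel()[0])
    p = b.size + 1
    V = np.asarray(out["vcov"], dtype=float).reshape(p, p)  # (b..., log scale)
    theta = np.concatenate([-b / scale, [-np.log(scale)]])
    J = np.zeros((p, p))
    for j in range(b.size):
        J[j, j] = -1.0 / scale
        J[j, p - 1] = b[j] / scale
    J[p - 1, p - 1] = -1.0
    Vt = J @ V @ J.T
    return theta, np.sqrt(np.diag(Vt))
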