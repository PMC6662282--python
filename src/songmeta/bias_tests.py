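"""Classical random-effects meta-analysis and funnel-plot asymmetry tests.

These are the frequentist checks run alongside the Bayesian model: a
random-effects (meta-regression) fit with REML or DerSimonian–Laird
between-study variance, Egger's regression test (the effect size regressed
on its own standard error inside the random-effects model), and the
Begg–Mazumdar rank-correlation test of standardized effects against their
sampling variances.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .effect_size import AnalysisDataset

__all__ = [
    "REMAFit",
    "BiasTestResult",
    "random_effects_meta",
    "egger_test",
    "begg_rank_test",
    "funnel_table",
]


@dataclass
class REMAFit:
    """A fitted random-effects meta-analysis (optionally with moderators)."""

    beta: np.ndarray          # coefficients; beta[0] = intercept / pooled effect
    se_beta: np.ndarray
    tau2: float
    method: str
    k: int
    coef_names: list[str]

    @property
    def mu(self) -> float:
        return float(self.beta[0])

    @property
    def se_mu(self) -> float:
        return float(self.se_beta[0])

    def z_values(self) -> np.ndarray:
        return self.beta / self.se_beta

    def p_values(self) -> np.ndarray:
        return 2.0 * stats.norm.sf(np.abs(self.z_values()))


@dataclass
class BiasTestResult:
    """Outcome of a funnel-asymmetry test."""

    test: str
    statistic: float
    p: float
    k: int

    def to_dict(self) -> dict:
        return {"test": self.test, "statistic": self.statistic, "p": self.p, "k": self.k}


def _wls(y: np.ndarray, X: np.ndarray, w: np.ndarray):
    XtW = X.T * w
    cov = np.linalg.inv(XtW @ X)
    beta = cov @ (XtW @ y)
    return beta, cov


def _reml_tau2(y: np.ndarray, X: np.ndarray, v: np.ndarray,
               tol: float = 1e-8, max_iter: int = 1000) -> float:
    """REML estimate of the between-study variance by Fisher scoring.

    Iterates tau2 <- tau2 + delta from the REML score until the step is
    below ``tol``; negative iterates are truncated at zero.
    """
    tau2 = max(float(np.var(y, ddof=1) - v.mean()), 0.0)
    for _ in range(max_iter):
        w = 1.0 / (v + tau2)
        WX = X * w[:, None]
        M = np.linalg.inv(X.T @ WX)
        # REML projection P = W - W X (X'WX)^{-1} X'W
        P = np.diag(w) - WX @ M @ WX.T
        Py = P @ y
        score = -0.5 * np.trace(P) + 0.5 * float(Py @ Py)
        info = 0.5 * float(np.sum(P * P))
        if info <= 0:
            break
        delta = score / info
        new = max(tau2 + delta, 0.0)
        if abs(new - tau2) < tol:
            return new
        tau2 = new
    else:
        raise RuntimeError(f"REML did not converge; last tau2={tau2}")
    return tau2


def _dl_tau2(y: np.ndarray, X: np.ndarray, v: np.ndarray) -> float:
    """DerSimonian–Laird moment estimator (generalised to moderators)."""
    w = 1.0 / v
    beta, _ = _wls(y, X, w)
    resid = y - X @ beta
    Q = float(w @ resid**2)
    p = X.shape[1]
    XtW = X.T * w
    M = np.linalg.inv(XtW @ X)
    # E[Q] = (k - p) + tau2 * (sum w - tr(M X'W^2X))
    c = w.sum() - np.trace(M @ (X.T * w**2) @ X)
    return max((Q - (len(y) - p)) / c, 0.0) if c > 0 else 0.0


def random_effects_meta(
    z,
    se,
    X: np.ndarray | None = None,
    method: str = "REML",
) -> REMAFit:
    """Random-effects meta-analysis of effects ``z`` with standard errors ``se``.

    ``X`` adds moderator columns to the intercept (meta-regression). The
    between-study variance tau^2 is estimated by REML (default) or the
    DerSimonian–Laird moment estimator; coefficients follow by weighted
    least squares with weights 1/(se^2 + tau^2).
    """
    y = np.asarray(z, dtype=float)
    se = np.asarray(se, dtype=float)
    if y.shape != se.shape:
        raise ValueError("effect and SE vectors must have equal length")
    if y.size < 2:
        raise ValueError("need at least 2 studies")
    if np.any(se <= 0):
        raise ValueError("standard errors must be positive")
    v = se**2
    if X is None:
        design = np.ones((y.size, 1))
        names = ["mu"]
    else:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[0] != y.size:
            X = X.T
        design = np.column_stack([np.ones(y.size), X])
        names = ["mu"] + [f"mod{j}" for j in range(X.shape[1])]
    if method == "REML":
        tau2 = _reml_tau2(y, design, v)
    elif method == "DL":
        tau2 = _dl_tau2(y, design, v)
    else:
        raise ValueError(f"unknown tau^2 method: {method!r}")
    w = 1.0 / (v + tau2)
    beta, cov = _wls(y, design, w)
    return REMAFit(
        beta=beta,
        se_beta=np.sqrt(np.diag(cov)),
        tau2=tau2,
        method=method,
        k=y.size,
        coef_names=names,
    )


def egger_test(dataset: AnalysisDataset, method: str = "REML") -> BiasTestResult:
    """Egger's regression test for funnel-plot asymmetry.

    The Fisher's Z effects are meta-regressed on their own standard errors
    within a random-effects model (REML tau^2 by default); the reported z
    statistic is the se-moderator coefficient over its standard error, with
    a two-sided normal p-value. ``method='WLS'`` gives the classical
    fixed-weights Egger variant.
    """
    df = dataset.data
    z = df["z"].to_numpy(dtype=float)
    se = df["se"].to_numpy(dtype=float)
    if z.size < 3:
        raise ValueError("need at least 3 measurements")
    if np.allclose(se, se[0]):
        raise ValueError("all standard errors identical; Egger moderator is collinear")
    if method == "WLS":
        fit = REMAFit(  # classical: weights 1/v, i.e. tau2 forced to 0
            *_classical_egger(z, se), method="WLS", k=z.size, coef_names=["mu", "se"]
        )
    else:
        fit = random_effects_meta(z, se, X=se[:, None], method=method)
    stat = float(fit.z_values()[1])
    p = 2.0 * float(stats.norm.sf(abs(stat)))
    return BiasTestResult(test="egger", statistic=stat, p=p, k=z.size)


def _classical_egger(z, se):
    w = 1.0 / se**2
    design = np.column_stack([np.ones(z.size), se])
    beta, cov = _wls(z, design, w)
    return beta, np.sqrt(np.diag(cov)), 0.0


def begg_rank_test(dataset: AnalysisDataset) -> BiasTestResult:
    """Begg–Mazumdar rank correlation test for funnel-plot asymmetry.

    Each effect is standardized against the fixed-effect pooled mean,
    u_i = (z_i - z_hat) / sqrt(v_i - 1/sum(1/v_j)), and Kendall's tau
    (tie-corrected) is computed between the u_i and the sampling variances
    v_i. The p-value is exact (null enumeration) for k <= 10 without ties,
    otherwise the normal approximation with continuity correction.
    """
    df = dataset.data
    z = df["z"].to_numpy(dtype=float)
    v = df["se"].to_numpy(dtype=float) ** 2
    k = z.size
    if k < 3:
        raise ValueError("need at least 3 measurements")
    w = 1.0 / v
    z_hat = float((w * z).sum() / w.sum())
    var_adj = v - 1.0 / w.sum()
    if np.any(var_adj <= 0):
        raise ValueError("nonpositive adjusted variance; cannot standardize")
    u = (z - z_hat) / np.sqrt(var_adj)
    if np.ptp(u) == 0 or np.ptp(v) == 0:
        raise ValueError("zero variance in a ranking; rank test undefined")

    tau = kendall_tau_b(u, v)
    no_ties = len(set(u)) == k and len(set(v)) == k
    if k <= 10 and no_ties:
        res = stats.kendalltau(u, v, method="exact")
        p = float(res.pvalue)
    else:
        # tie-corrected normal approximation with continuity correction on
        # the concordance statistic S = C - D
        S = _concordance_s(u, v)
        var_s = _tau_b_variance(u, v)
        if var_s <= 0:
            raise ValueError("degenerate tie structure; variance of S is zero")
        z_stat = (abs(S) - 1.0) / math.sqrt(var_s) if abs(S) > 1 else 0.0
        p = 2.0 * float(stats.norm.sf(z_stat))
    return BiasTestResult(test="begg_rank", statistic=float(tau), p=min(p, 1.0), k=k)


def _concordance_s(x, y) -> float:
    S = 0.0
    n = len(x)
    for i in range(n):
        for j in range(i + 1, n):
            S += np.sign(x[j] - x[i]) * np.sign(y[j] - y[i])
    return S


def _tie_counts(x) -> np.ndarray:
    _, counts = np.unique(np.asarray(x), return_counts=True)
    return counts[counts > 1]


def _tau_b_variance(x, y) -> float:
    n = len(x)
    tx = _tie_counts(x)
    ty = _tie_counts(y)
    v0 = n * (n - 1) * (2 * n + 5)
    vt = sum(t * (t - 1) * (2 * t + 5) for t in tx)
    vu = sum(t * (t - 1) * (2 * t + 5) for t in ty)
    v1 = (sum(t * (t - 1) for t in tx) * sum(t * (t - 1) for t in ty)) / (
        2.0 * n * (n - 1)
    )
    v2 = (
        sum(t * (t - 1) * (t - 2) for t in tx)
        * sum(t * (t - 1) * (t - 2) for t in ty)
    ) / (9.0 * n * (n - 1) * (n - 2)) if n > 2 else 0.0
    return (v0 - vt - vu) / 18.0 + v1 + v2


def kendall_tau_b(x, y) -> float:
    """Tie-corrected Kendall rank correlation (tau-b)."""
    n = len(x)
    S = _concordance_s(x, y)
    n0 = n * (n - 1) / 2.0
    n1 = sum(t * (t - 1) / 2.0 for t in _tie_counts(x))
    n2 = sum(t * (t - 1) / 2.0 for t in _tie_counts(y))
    denom = math.sqrt((n0 - n1) * (n0 - n2))
    if denom == 0:
        raise ValueError("zero variance in a ranking")
    return S / denom


def funnel_table(dataset: AnalysisDataset, annotate: str = "none") -> pd.DataFrame:
    """Per-measurement funnel-plot data: Z, its SE, and the pooled mean line.

    ``annotate`` adds a column for the species' repertoire size
    (``'repertoire'``) or its song-stability class (``'stability'``);
    species with missing information are flagged ``'unknown'``.
    """
    df = dataset.data
    if len(df) == 0:
        raise ValueError("empty dataset")
    w = 1.0 / df["se"].to_numpy(dtype=float) ** 2
    pooled = float((w * df["z"].to_numpy(dtype=float)).sum() / w.sum())
    out = pd.DataFrame(
        {"z": df["z"].to_numpy(), "se": df["se"].to_numpy(), "pooled_mean": pooled}
    )
    if annotate == "repertoire":
        rep = np.exp(df["ln_syll_rep"].to_numpy(dtype=float))
        out["repertoire"] = [v if math.isfinite(v) else "unknown" for v in rep]
    elif annotate == "stability":
        out["stability"] = df["stability"].to_numpy()
    elif annotate != "none":
        raise ValueError(f"unknown annotation: {annotate!r}")
    return out
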