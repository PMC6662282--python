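"""Bayesian multilevel phylogenetic meta-analysis of Fisher's Z effect sizes.

The model for measurement i is

    Z_i = x_i' beta + sum_k u_{k, level_k(i)} + m_i + e_i

with the measurement-error term m_i ~ Normal(0, s_i^2) at the *known*
sampling variance s_i^2 = 1/(n_i - 3), the residual e_i ~ Normal(0,
sigma2_res), i.i.d. random effects u_k ~ Normal(0, sigma2_k I) for the
measurement-type (MType), Species and Study terms, and a phylogenetically
structured term u_Phylo ~ Normal(0, sigma2_Phylo * A) where A is the
Brownian-motion correlation matrix of the species tree.

Everything is conjugate, so the sampler is a blocked Gibbs scheme with
exact conditional updates: one joint multivariate-normal draw for
(beta, all u) given the variances, a normal draw for each latent m_i, and
scalar inverse-Wishart (equivalently inverse-gamma) draws for each
variance component. Fixed effects get a diffuse zero-mean normal prior;
variance components get IW(V, nu) priors with V derived from the observed
effect-size variance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve, solve_triangular

from .effect_size import AnalysisDataset
from .intervals import hdi
from .phylogeny import PhyloCorrelation

__all__ = [
    "RANDOM_TERMS",
    "ModelSpec",
    "PriorSpec",
    "ChainSettings",
    "PosteriorSample",
    "FitSummary",
    "default_priors",
    "fit_mcmc",
    "summarize",
    "heterogeneity",
    "dic",
    "gelman_rubin",
    "posterior_predictive",
    "typical_sampling_variance",
]

#: Random-effect terms the model knows about, in canonical order.
RANDOM_TERMS = ("MType", "Species", "Phylo", "Study")


@dataclass(frozen=True)
class ModelSpec:
    """Fixed-effect form plus the set of random-effect terms.

    ``fixed`` is one of:

    * ``"intercept"`` — population mean only (Z ~ 1);
    * ``"repertoire"`` — intercept + slope on ln species average syllable
      repertoire size;
    * ``"stability"`` — per-group means for song-stable and song-plastic
      species, fit without a global intercept so each group's posterior
      mean is directly interpretable.

    A custom design can be supplied via ``design``/``fixed_names``.
    """

    fixed: str = "intercept"
    random_terms: tuple[str, ...] = RANDOM_TERMS
    design: np.ndarray | None = None
    fixed_names: tuple[str, ...] | None = None

    def __post_init__(self):
        unknown = set(self.random_terms) - set(RANDOM_TERMS)
        if unknown:
            raise ValueError(f"unknown random terms: {sorted(unknown)}")


@dataclass(frozen=True)
class PriorSpec:
    """Variance-component prior IW(V, nu) and diffuse fixed-effect prior.

    The same (V, nu) applies to every estimated variance component,
    including the residual, unless ``residual_V`` overrides the scale or
    ``residual_fixed`` pins the residual variance to a constant.
    """

    V: float
    nu: float = 1.0
    fixed_effect_variance: float = 1e8
    residual_V: float | None = None
    residual_fixed: float | None = None

    def __post_init__(self):
        if self.V <= 0:
            raise ValueError(f"prior scale V must be > 0, got {self.V}")
        if self.nu <= 0:
            raise ValueError(f"prior degree of belief nu must be > 0, got {self.nu}")
        if self.fixed_effect_variance < 1e8:
            raise ValueError("fixed-effect prior variance must be at least 1e8")


@dataclass(frozen=True)
class ChainSettings:
    """MCMC run lengths; defaults follow the study's chain settings."""

    iterations: int = 200_000
    burn_in: int = 30_000
    thin: int = 10
    n_chains: int = 4
    seed: int = 0

    def __post_init__(self):
        if self.iterations <= self.burn_in:
            raise ValueError("iterations must exceed burn_in")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        if self.n_chains < 1:
            raise ValueError("need at least one chain")

    @property
    def n_draws(self) -> int:
        return (self.iterations - self.burn_in) // self.thin


@dataclass
class PosteriorSample:
    """Retained MCMC draws, organised per chain.

    ``beta`` has shape (n_chains, n_draws, p); each entry of ``u`` has shape
    (n_chains, n_draws, q_k); each variance component in ``sigma2`` —
    including ``"residual"`` — has shape (n_chains, n_draws); ``deviance``
    holds the per-draw conditional deviance used for DIC.
    """

    fixed_names: list[str]
    beta: np.ndarray
    u: dict[str, np.ndarray]
    sigma2: dict[str, np.ndarray]
    deviance: np.ndarray
    term_levels: dict[str, list[str]]
    X: np.ndarray
    Z: dict[str, np.ndarray]
    z_obs: np.ndarray
    s2: np.ndarray
    spec: ModelSpec | None = None

    @property
    def n_chains(self) -> int:
        return self.beta.shape[0]

    @property
    def n_draws(self) -> int:
        return self.beta.shape[0] * self.beta.shape[1]

    def fixed_draws(self, name: str) -> np.ndarray:
        """Pooled draws (all chains) of one fixed effect."""
        j = self.fixed_names.index(name)
        return self.beta[:, :, j].ravel()

    def variance_draws(self, component: str) -> np.ndarray:
        return self.sigma2[component].ravel()

    def location_draws(self) -> np.ndarray:
        """Per-draw linear predictor mu_i = x_i'beta + sum_k u (pooled chains)."""
        nc, nd, p = self.beta.shape
        beta_flat = self.beta.reshape(nc * nd, p)
        mu = beta_flat @ self.X.T
        for term, draws in self.u.items():
            q = draws.shape[2]
            mu += draws.reshape(nc * nd, q) @ self.Z[term].T
        return mu


@dataclass
class FitSummary:
    """Posterior summaries for the fixed effects plus model-level diagnostics."""

    fixed: pd.DataFrame  # columns: mean, hpd_low, hpd_high, p_mcmc
    dic: float
    rhat: dict[str, float]
    convention: str = "two_sided"

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"FitSummary(DIC={self.dic:.4g}, "
            f"max R-hat={max(self.rhat.values()) if self.rhat else float('nan'):.3f})\n"
            f"{self.fixed}"
        )


def default_priors(dataset: AnalysisDataset, random_terms) -> PriorSpec:
    """Prior scale V = Var(observed Z) / (#random terms + 1), nu = 1.

    The observed between-measurement variance of the Fisher's Z values is
    split evenly over the estimated variance components (the named random
    terms plus the residual), expressing no preference about which source
    dominates while keeping the total on the scale of the data.
    """
    z = dataset.data["z"].to_numpy(dtype=float)
    if z.size < 2:
        raise ValueError("need at least 2 measurements to set priors")
    var_z = float(np.var(z, ddof=1))
    if var_z <= 0:
        raise ValueError("observed effect sizes have zero variance")
    return PriorSpec(V=var_z / (len(tuple(random_terms)) + 1), nu=1.0)


def typical_sampling_variance(dataset: AnalysisDataset) -> float:
    """Typical (meta-analytic) sampling variance of the measurements.

    sigma2_m-bar = sum(w_i) (k - 1) / ((sum w_i)^2 - sum w_i^2) with
    w_i = 1/s_i^2 — the harmonic-style summary used when expressing
    heterogeneity as a proportion of total variance.
    """
    s2 = dataset.data["se"].to_numpy(dtype=float) ** 2
    k = s2.size
    if k < 2:
        raise ValueError("need at least 2 measurements")
    if np.any(s2 <= 0):
        raise ValueError("sampling variances must be positive")
    w = 1.0 / s2
    denom = w.sum() ** 2 - (w**2).sum()
    if denom <= 0:
        raise ValueError("degenerate weights: typical sampling variance undefined")
    return float(w.sum() * (k - 1) / denom)


def build_design(dataset: AnalysisDataset, spec: ModelSpec) -> tuple[np.ndarray, list[str]]:
    """Fixed-effect design matrix and column names for a dataset."""
    df = dataset.data
    n = len(df)
    if spec.design is not None:
        X = np.asarray(spec.design, dtype=float)
        if X.shape[0] != n:
            raise ValueError("custom design has wrong number of rows")
        names = list(spec.fixed_names or [f"x{j}" for j in range(X.shape[1])])
    elif spec.fixed == "intercept":
        X = np.ones((n, 1))
        names = ["intercept"]
    elif spec.fixed == "repertoire":
        ln_rep = df["ln_syll_rep"].to_numpy(dtype=float)
        if np.any(~np.isfinite(ln_rep)):
            raise ValueError(
                "repertoire model requires ln_syll_rep for every species; "
                "build the dataset with variant='repertoire'"
            )
        X = np.column_stack([np.ones(n), ln_rep])
        names = ["intercept", "ln_syll_rep"]
    elif spec.fixed == "stability":
        stab = df["stability"].to_numpy()
        if set(stab) - {"stable", "plastic"}:
            raise ValueError(
                "stability model requires known stability for every species; "
                "build the dataset with variant='stability'"
            )
        X = np.column_stack([(stab == "stable").astype(float),
                             (stab == "plastic").astype(float)])
        names = ["stable", "plastic"]
    else:
        raise ValueError(f"unknown fixed-effect form: {spec.fixed!r}")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("fixed-effect design matrix is rank deficient")
    return X, names


def _indicator(labels: np.ndarray, levels: list[str]) -> np.ndarray:
    Z = np.zeros((len(labels), len(levels)))
    index = {lv: j for j, lv in enumerate(levels)}
    for i, lab in enumerate(labels):
        Z[i, index[lab]] = 1.0
    return Z


def _random_structure(
    dataset: AnalysisDataset,
    spec: ModelSpec,
    phylo: PhyloCorrelation | None,
) -> tuple[dict[str, np.ndarray], dict[str, list[str]], dict[str, np.ndarray]]:
    """Indicator matrices Z_k, level labels, and prior-precision kernels K_k.

    K_k is the identity for i.i.d. terms and A^{-1} for the Phylo term, so
    that u_k ~ Normal(0, sigma2_k K_k^{-1}).
    """
    df = dataset.data
    Z: dict[str, np.ndarray] = {}
    levels: dict[str, list[str]] = {}
    K: dict[str, np.ndarray] = {}
    for term in spec.random_terms:
        if term == "MType":
            lv = sorted(df["mtype"].unique())
            lab = df["mtype"].to_numpy()
        elif term == "Species":
            lv = sorted(df["species"].unique())
            lab = df["species"].to_numpy()
        elif term == "Study":
            lv = sorted(df["study_id"].unique())
            lab = df["study_id"].to_numpy()
        else:  # Phylo
            if phylo is None:
                raise ValueError("Phylo random term requires a PhyloCorrelation")
            present = sorted(df["species"].unique())
            missing = set(present) - set(phylo.taxa)
            if missing:
                raise ValueError(f"species missing from phylogeny: {sorted(missing)}")
            sub = phylo.subset(present)
            eigmin = float(np.linalg.eigvalsh(sub.A).min())
            if eigmin < -1e-8:
                raise ValueError(f"phylogenetic correlation matrix not PSD (min eig {eigmin})")
            A = sub.A + 1e-10 * np.eye(len(present))
            lv = present
            lab = df["species"].to_numpy()
            K["Phylo"] = np.linalg.inv(A)
        Z[term] = _indicator(lab, lv)
        levels[term] = lv
        if term != "Phylo":
            K[term] = np.eye(len(lv))
    if phylo is not None and "Phylo" not in spec.random_terms:
        raise ValueError("phylo supplied but Phylo not in random_terms")
    return Z, levels, K


def fit_mcmc(
    dataset: AnalysisDataset,
    spec: ModelSpec,
    priors: PriorSpec,
    chains: ChainSettings,
    phylo: PhyloCorrelation | None = None,
) -> PosteriorSample:
    """Blocked Gibbs sampler for the multilevel phylogenetic meta-analysis.

    Per sweep: (1) a joint multivariate-normal draw of (beta, all u) from
    its full conditional given the variance components and the latent
    measurement errors m; (2) independent normal draws of each m_i given
    its fixed variance s_i^2; (3) inverse-gamma draws of each sigma2_k from
    the scalar inverse-Wishart full conditional, and of the residual
    variance unless it is pinned. Chains are run sequentially with seeds
    spawned from ``chains.seed``.
    """
    df = dataset.data
    z = df["z"].to_numpy(dtype=float)
    s2 = df["se"].to_numpy(dtype=float) ** 2
    if np.any(~np.isfinite(z)) or np.any(~np.isfinite(s2)) or np.any(s2 <= 0):
        raise ValueError("non-finite effect sizes or standard errors")
    n = z.size

    X, fixed_names = build_design(dataset, spec)
    Zr, levels, K = _random_structure(dataset, spec, phylo)
    terms = list(spec.random_terms)

    # Stacked design W = [X | Z_1 | ... ] with block slices per component.
    blocks = [X] + [Zr[t] for t in terms]
    W = np.hstack(blocks)
    p_fixed = X.shape[1]
    slices: dict[str, slice] = {}
    offset = p_fixed
    for t in terms:
        q = Zr[t].shape[1]
        slices[t] = slice(offset, offset + q)
        offset += q
    p_all = offset

    # Constant part of the prior precision (fixed effects only).
    P0 = np.zeros((p_all, p_all))
    P0[:p_fixed, :p_fixed] = np.eye(p_fixed) / priors.fixed_effect_variance

    nu = priors.nu
    V = priors.V
    V_res = priors.residual_V if priors.residual_V is not None else V
    res_fixed = priors.residual_fixed

    n_draws = chains.n_draws
    beta_out = np.empty((chains.n_chains, n_draws, p_fixed))
    u_out = {t: np.empty((chains.n_chains, n_draws, Zr[t].shape[1])) for t in terms}
    sig_out = {t: np.empty((chains.n_chains, n_draws)) for t in terms}
    sig_out["residual"] = np.empty((chains.n_chains, n_draws))
    dev_out = np.empty((chains.n_chains, n_draws))

    seed_seqs = np.random.SeedSequence(chains.seed).spawn(chains.n_chains)
    for c, ss in enumerate(seed_seqs):
        rng = np.random.default_rng(ss)
        theta = np.zeros(p_all)
        m = np.zeros(n)
        sigma2 = {t: V for t in terms}
        sigma2_res = res_fixed if res_fixed is not None else V_res

        kept = 0
        for it in range(chains.iterations):
            # --- (beta, u) | variances, with m integrated out ---
            # Marginally over m the noise is independent with variance
            # s_i^2 + sigma2_res, so this is an exact GLS block draw; it
            # mixes even when the residual variance is pinned near zero.
            w = 1.0 / (s2 + sigma2_res)
            Ww = W * w[:, None]
            Q = W.T @ Ww + P0
            for t in terms:
                sl = slices[t]
                Q[sl, sl] += K[t] / sigma2[t]
            b = Ww.T @ z
            cF, low = cho_factor(Q, lower=True)
            mean = cho_solve((cF, low), b)
            eps = rng.standard_normal(p_all)
            theta = mean + solve_triangular(cF.T, eps, lower=False)
            mu = W @ theta

            # --- m | theta, variances ---
            resid = z - mu
            v_m = 1.0 / (1.0 / s2 + 1.0 / sigma2_res)
            m = v_m * resid / sigma2_res + np.sqrt(v_m) * rng.standard_normal(n)

            # --- variance components | rest ---
            e = resid - m
            if res_fixed is None:
                shape = (nu + n) / 2.0
                scale = (nu * V_res + e @ e) / 2.0
                sigma2_res = scale / rng.gamma(shape)
            for t in terms:
                u_t = theta[slices[t]]
                S = float(u_t @ (K[t] @ u_t))
                q = u_t.size
                shape = (nu + q) / 2.0
                scale = (nu * V + S) / 2.0
                sigma2[t] = scale / rng.gamma(shape)

            if it >= chains.burn_in and (it - chains.burn_in) % chains.thin == 0:
                total_var = sigma2_res + s2
                dev = float(
                    np.sum(np.log(2.0 * np.pi * total_var) + (z - mu) ** 2 / total_var)
                )
                beta_out[c, kept] = theta[:p_fixed]
                for t in terms:
                    u_out[t][c, kept] = theta[slices[t]]
                    sig_out[t][c, kept] = sigma2[t]
                sig_out["residual"][c, kept] = sigma2_res
                dev_out[c, kept] = dev
                kept += 1
        assert kept == n_draws

    return PosteriorSample(
        fixed_names=fixed_names,
        beta=beta_out,
        u=u_out,
        sigma2=sig_out,
        deviance=dev_out,
        term_levels=levels,
        X=X,
        Z=Zr,
        z_obs=z,
        s2=s2,
        spec=spec,
    )


def _p_mcmc(draws: np.ndarray, convention: str) -> float:
    n = draws.size
    frac_pos = float(np.mean(draws > 0))
    if convention == "two_sided":
        p = 2.0 * min(frac_pos, 1.0 - frac_pos)
    elif convention == "frac_above_zero":
        p = 1.0 - frac_pos
    else:
        raise ValueError(f"unknown p_MCMC convention: {convention!r}")
    return max(p, 1.0 / n)


def summarize(post: PosteriorSample, convention: str = "two_sided") -> FitSummary:
    """Posterior mean, 95% HPD and p_MCMC per fixed effect, plus DIC and R-hat.

    ``p_MCMC`` is the posterior tail mass on the far side of zero:
    two-sided (default) doubles the smaller tail; ``frac_above_zero``
    reports 1 minus the fraction of draws above zero. Both are floored at
    one over the number of retained draws.
    """
    if post.n_draws < 100:
        raise ValueError("need at least 100 retained draws to summarise")
    rows = []
    for name in post.fixed_names:
        d = post.fixed_draws(name)
        lo, hi = hdi(d, 0.95)
        rows.append(
            {
                "effect": name,
                "mean": float(d.mean()),
                "hpd_low": lo,
                "hpd_high": hi,
                "p_mcmc": _p_mcmc(d, convention),
            }
        )
    fixed = pd.DataFrame(rows).set_index("effect")
    rhat = gelman_rubin(post) if post.n_chains >= 2 else {}
    return FitSummary(fixed=fixed, dic=dic(post), rhat=rhat, convention=convention)


def heterogeneity(post: PosteriorSample, dataset: AnalysisDataset) -> dict[str, float]:
    """Per-component I^2: share of total variance owned by each component.

    I2_k = 100 * mean(sigma2_k) / (sum_j mean(sigma2_j) + typical sampling
    variance), with the sum over every estimated component including the
    residual. Expressed in percent.
    """
    means = {name: float(draws.mean()) for name, draws in post.sigma2.items()}
    s2m = typical_sampling_variance(dataset)
    total = sum(means.values()) + s2m
    return {name: 100.0 * v / total for name, v in means.items()}


def dic(post: PosteriorSample) -> float:
    """Deviance information criterion from the conditional deviance.

    D(theta) is -2 log of the Gaussian likelihood of the observed Z given
    the location effects (beta, u) and variances, with the measurement
    error marginalised into the residual (variance sigma2_res + s_i^2).
    DIC = 2 mean(D) - D(posterior mean).
    """
    mu = post.location_draws()          # (ndraws_total, n)
    mu_bar = mu.mean(axis=0)
    res_bar = float(post.sigma2["residual"].mean())
    total_var = res_bar + post.s2
    d_at_mean = float(
        np.sum(np.log(2.0 * np.pi * total_var) + (post.z_obs - mu_bar) ** 2 / total_var)
    )
    return 2.0 * float(post.deviance.mean()) - d_at_mean


def _psrf(chains_matrix: np.ndarray) -> float:
    """Potential scale reduction factor for one parameter, chains in rows."""
    m, n = chains_matrix.shape
    means = chains_matrix.mean(axis=1)
    W = chains_matrix.var(axis=1, ddof=1).mean()
    B_over_n = means.var(ddof=1)
    if W <= 0:
        return 1.0
    var_plus = (n - 1) / n * W + B_over_n
    return float(np.sqrt(var_plus / W))


def gelman_rubin(chains) -> dict[str, float]:
    """Gelman–Rubin R-hat for every fixed effect and variance component.

    Accepts a multi-chain :class:`PosteriorSample` or a list of
    single-chain samples with identical parameters.
    """
    if isinstance(chains, PosteriorSample):
        post = chains
    else:
        chains = list(chains)
        if len(chains) < 2:
            raise ValueError("need at least 2 chains for R-hat")
        post = chains[0]
        post = PosteriorSample(
            fixed_names=post.fixed_names,
            beta=np.concatenate([c.beta for c in chains], axis=0),
            u={t: np.concatenate([c.u[t] for c in chains], axis=0) for t in post.u},
            sigma2={
                k: np.concatenate([c.sigma2[k] for c in chains], axis=0)
                for k in post.sigma2
            },
            deviance=np.concatenate([c.deviance for c in chains], axis=0),
            term_levels=post.term_levels,
            X=post.X,
            Z=post.Z,
            z_obs=post.z_obs,
            s2=post.s2,
            spec=post.spec,
        )
    if post.n_chains < 2:
        raise ValueError("need at least 2 chains for R-hat")
    out = {}
    for j, name in enumerate(post.fixed_names):
        out[name] = _psrf(post.beta[:, :, j])
    for name, draws in post.sigma2.items():
        out[f"sigma2_{name}"] = _psrf(draws)
    return out


def posterior_predictive(
    post: PosteriorSample, dataset: AnalysisDataset, seed: int = 0
) -> pd.DataFrame:
    """Predicted-versus-observed table for every measurement.

    For each retained draw, a replicate Z is simulated from Normal(mu_i,
    sigma2_res + s_i^2) with mu_i the draw's fixed-plus-random linear
    predictor; the table reports the predictive mean, central 95% interval,
    observed Z, and whether the observation falls inside its interval.
    """
    if len(dataset.data) != post.z_obs.size:
        raise ValueError("dataset does not match the fitted model")
    rng = np.random.default_rng(seed)
    mu = post.location_draws()
    sd = np.sqrt(post.sigma2["residual"].reshape(-1, 1) + post.s2[None, :])
    z_rep = mu + sd * rng.standard_normal(mu.shape)
    lo = np.quantile(z_rep, 0.025, axis=0)
    hi = np.quantile(z_rep, 0.975, axis=0)
    pred_mean = mu.mean(axis=0)
    return pd.DataFrame(
        {
            "study_id": dataset.data["study_id"].to_numpy(),
            "species": dataset.data["species"].to_numpy(),
            "observed_z": post.z_obs,
            "predicted_mean": pred_mean,
            "predictive_low": lo,
            "predictive_high": hi,
            "covered": (post.z_obs >= lo) & (post.z_obs <= hi),
        }
    )
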