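"""Gibbs sampler correctness, posterior summaries, heterogeneity, DIC, R-hat."""

import math

import numpy as np
import pandas as pd
import pytest

from songmeta.effect_size import AnalysisDataset
from songmeta.intervals import hdi
from songmeta.meta_model import (
    ChainSettings,
    ModelSpec,
    PriorSpec,
    PosteriorSample,
    default_priors,
    dic,
    fit_mcmc,
    gelman_rubin,
    heterogeneity,
    posterior_predictive,
    summarize,
    typical_sampling_variance,
)


def toy_dataset(z, se, species=None, studies=None, mtypes=None):
    n = len(z)
    df = pd.DataFrame(
        {
            "study_id": studies or [f"S{i}" for i in range(n)],
            "species": species or [f"sp{i}" for i in range(n)],
            "mtype": mtypes or ["clutch_size"] * n,
            "n": [int(1 / s**2 + 3) for s in se],
            "r": np.tanh(z),
            "z": np.asarray(z, float),
            "se": np.asarray(se, float),
            "ln_syll_rep": np.nan,
            "stability": "unknown",
        }
    )
    traits = df[["species"]].drop_duplicates().assign(ln_syll_rep=np.nan, stability="unknown")
    return AnalysisDataset(data=df, traits=traits)


class TestPriors:
    def test_scale_divides_observed_variance(self):
        rng = np.random.default_rng(0)
        z = rng.normal(0, 0.5, 40)
        ds = toy_dataset(z, np.full(40, 0.2))
        pri = default_priors(ds, ("MType", "Species", "Phylo", "Study"))
        assert pri.V == pytest.approx(np.var(z, ddof=1) / 5)
        assert pri.nu == 1.0
        pri1 = default_priors(ds, ("Study",))
        assert pri1.V == pytest.approx(np.var(z, ddof=1) / 2)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            default_priors(toy_dataset([0.1], [0.2]), ("Study",))
        with pytest.raises(ValueError):
            default_priors(toy_dataset([0.3, 0.3, 0.3], [0.2] * 3), ("Study",))


class TestTypicalSamplingVariance:
    def test_homogeneous_case(self):
        ds = toy_dataset([0.1, 0.2, 0.3], np.sqrt([0.04, 0.04, 0.04]))
        assert typical_sampling_variance(ds) == pytest.approx(0.04)

    def test_two_study_hand_formula(self):
        # w = (1, 3): sum w * (k-1) / ((sum w)^2 - sum w^2) = 4/(16-10)
        ds = toy_dataset([0.1, 0.2], np.sqrt([1.0, 1 / 3]))
        assert typical_sampling_variance(ds) == pytest.approx(2 / 3)

    def test_single_measurement_rejected(self):
        with pytest.raises(ValueError):
            typical_sampling_variance(toy_dataset([0.1], [0.5]))


class TestConjugateOracle:
    def test_posterior_matches_inverse_variance_weighting(self):
        """With no random effects and residual variance pinned near zero the
        intercept posterior is the closed-form precision-weighted normal."""
        rng = np.random.default_rng(10)
        se = rng.uniform(0.15, 0.5, 15)
        z = rng.normal(0.25, se)
        ds = toy_dataset(z, se)
        post = fit_mcmc(
            ds,
            ModelSpec(fixed="intercept", random_terms=()),
            PriorSpec(V=0.1, residual_fixed=1e-10),
            ChainSettings(iterations=3000, burn_in=500, thin=1, n_chains=1, seed=1),
        )
        d = post.fixed_draws("intercept")
        w = 1 / se**2
        mean_oracle = (w * z).sum() / w.sum()
        sd_oracle = 1 / math.sqrt(w.sum())
        mcse = d.std() / math.sqrt(d.size)
        assert abs(d.mean() - mean_oracle) < 3 * mcse
        assert d.std() == pytest.approx(sd_oracle, rel=0.1)

    def test_exchangeable_under_permutation(self):
        rng = np.random.default_rng(4)
        se = rng.uniform(0.2, 0.4, 12)
        z = rng.normal(0.2, se)
        ds = toy_dataset(z, se)
        perm = rng.permutation(12)
        ds_perm = toy_dataset(z[perm], se[perm])
        settings = ChainSettings(iterations=4000, burn_in=500, thin=1, n_chains=1, seed=2)
        spec = ModelSpec(fixed="intercept", random_terms=())
        pri = PriorSpec(V=0.1)
        m1 = fit_mcmc(ds, spec, pri, settings).fixed_draws("intercept").mean()
        m2 = fit_mcmc(ds_perm, spec, pri, settings).fixed_draws("intercept").mean()
        assert m1 == pytest.approx(m2, abs=0.02)

    def test_seed_reproducibility(self):
        ds = toy_dataset([0.1, 0.3, 0.2, 0.4], [0.2] * 4)
        spec = ModelSpec(fixed="intercept", random_terms=("Study",))
        pri = PriorSpec(V=0.05)
        cs = ChainSettings(iterations=1500, burn_in=300, thin=2, n_chains=2, seed=9)
        p1 = fit_mcmc(ds, spec, pri, cs)
        p2 = fit_mcmc(ds, spec, pri, cs)
        assert np.array_equal(p1.beta, p2.beta)
        assert np.array_equal(p1.sigma2["Study"], p2.sigma2["Study"])

    def test_identity_phylo_equivalent_to_iid_species_term(self, benchmark_dataset):
        """With A = I the phylogenetic term is exchangeable with an extra
        i.i.d. species term: the total species-level variance matches a
        single-component fit within MC error."""
        from songmeta.phylogeny import PhyloCorrelation

        ds = benchmark_dataset
        eye = PhyloCorrelation(taxa=ds.species, A=np.eye(len(ds.species)))
        pri = PriorSpec(V=0.02)
        cs = ChainSettings(iterations=6000, burn_in=1000, thin=5, n_chains=1, seed=3)
        both = fit_mcmc(ds, ModelSpec("intercept", ("Species", "Phylo")), pri, cs, phylo=eye)
        single = fit_mcmc(ds, ModelSpec("intercept", ("Species",)), pri, cs)
        total_both = (both.variance_draws("Species") + both.variance_draws("Phylo")).mean()
        total_single = single.variance_draws("Species").mean()
        assert total_both == pytest.approx(total_single, abs=0.02)


class TestErrors:
    def test_rank_deficient_design_rejected(self):
        ds = toy_dataset([0.1, 0.2, 0.3], [0.2] * 3)
        X = np.ones((3, 2))
        spec = ModelSpec(fixed="custom", random_terms=(), design=X)
        with pytest.raises(ValueError, match="rank"):
            fit_mcmc(ds, spec, PriorSpec(V=0.1), ChainSettings(1000, 100, 1, 1, 0))

    def test_phylo_without_matrix_rejected(self):
        ds = toy_dataset([0.1, 0.2, 0.3], [0.2] * 3)
        with pytest.raises(ValueError, match="Phylo"):
            fit_mcmc(ds, ModelSpec("intercept", ("Phylo",)), PriorSpec(V=0.1),
                     ChainSettings(1000, 100, 1, 1, 0))

    def test_non_finite_effects_rejected(self):
        ds = toy_dataset([0.1, np.nan, 0.3], [0.2] * 3)
        with pytest.raises(ValueError, match="non-finite"):
            fit_mcmc(ds, ModelSpec("intercept", ()), PriorSpec(V=0.1),
                     ChainSettings(1000, 100, 1, 1, 0))


class TestSummaries:
    def _post_from_draws(self, draws):
        draws = np.asarray(draws, float)[None, :, None]
        n = draws.shape[1]
        return PosteriorSample(
            fixed_names=["intercept"],
            beta=draws,
            u={},
            sigma2={"residual": np.full((1, draws.shape[1]), 0.1)},
            deviance=np.zeros((1, draws.shape[1])),
            term_levels={},
            X=np.ones((1, 1)),
            Z={},
            z_obs=np.array([0.0]),
            s2=np.array([0.04]),
        )

    def test_p_mcmc_conventions(self):
        n = 2000
        draws = np.concatenate([np.linspace(0.01, 1, int(n * 0.95)),
                                np.linspace(-1, -0.01, int(n * 0.05))])
        post = self._post_from_draws(draws)
        two = summarize(post, convention="two_sided")
        one = summarize(post, convention="frac_above_zero")
        assert two.fixed["p_mcmc"].iloc[0] == pytest.approx(0.10)
        assert one.fixed["p_mcmc"].iloc[0] == pytest.approx(0.05)

    def test_p_mcmc_floor_and_extremes(self):
        post = self._post_from_draws(np.linspace(0.1, 1, 500))
        s = summarize(post)
        assert s.fixed["p_mcmc"].iloc[0] == pytest.approx(1 / 500)
        sym = self._post_from_draws(np.concatenate([np.linspace(-1, -0.01, 250),
                                                    np.linspace(0.01, 1, 250)]))
        assert summarize(sym).fixed["p_mcmc"].iloc[0] == pytest.approx(1.0)

    def test_too_few_draws_rejected(self):
        with pytest.raises(ValueError):
            summarize(self._post_from_draws(np.ones(50)))


class TestHeterogeneity:
    def test_equal_partition(self):
        ds = toy_dataset([0.1, 0.2, 0.3], [1.0] * 3)  # typical sampling var = 1
        post = PosteriorSample(
            fixed_names=["intercept"],
            beta=np.zeros((1, 200, 1)),
            u={},
            sigma2={k: np.ones((1, 200)) for k in ("MType", "Species", "Phylo", "residual")},
            deviance=np.zeros((1, 200)),
            term_levels={},
            X=np.ones((3, 1)),
            Z={},
            z_obs=np.array([0.1, 0.2, 0.3]),
            s2=np.array([1.0] * 3),
        )
        i2 = heterogeneity(post, ds)
        for v in i2.values():
            assert v == pytest.approx(20.0)

    def test_single_component_share(self):
        ds = toy_dataset([0.1, 0.2, 0.3], [1.0] * 3)
        post = PosteriorSample(
            fixed_names=["intercept"],
            beta=np.zeros((1, 200, 1)),
            u={},
            sigma2={"Study": np.full((1, 200), 3.0)},
            deviance=np.zeros((1, 200)),
            term_levels={},
            X=np.ones((3, 1)),
            Z={},
            z_obs=np.array([0.1, 0.2, 0.3]),
            s2=np.array([1.0] * 3),
        )
        assert heterogeneity(post, ds)["Study"] == pytest.approx(75.0)


class TestDIC:
    def test_hand_computed_three_observation_deviance(self):
        z = np.array([0.1, -0.2, 0.4])
        s2 = np.array([0.04, 0.09, 0.05])
        mu = np.array([0.0, 0.0, 0.2])
        res = 0.02
        total = res + s2
        d_hand = float(np.sum(np.log(2 * np.pi * total) + (z - mu) ** 2 / total))
        # identical draws (design = I, beta rows = mu): the effective-parameter
        # penalty vanishes and DIC equals the hand-computed deviance
        post = PosteriorSample(
            fixed_names=["m1", "m2", "m3"],
            beta=np.tile(mu, (1, 150, 1)),
            u={},
            sigma2={"residual": np.full((1, 150), res)},
            deviance=np.full((1, 150), d_hand),
            term_levels={},
            X=np.eye(3),
            Z={},
            z_obs=z,
            s2=s2,
        )
        assert dic(post) == pytest.approx(d_hand, abs=1e-9)

    def test_informative_moderator_lowers_dic(self, benchmark_dataset):
        ds = benchmark_dataset
        pri = default_priors(ds, ("Study",))
        cs = ChainSettings(iterations=4000, burn_in=800, thin=4, n_chains=1, seed=6)
        d0 = dic(fit_mcmc(ds, ModelSpec("intercept", ("Study",)), pri, cs))
        d1 = dic(fit_mcmc(ds, ModelSpec("repertoire", ("Study",)), pri, cs))
        assert d1 < d0


class TestGelmanRubin:
    def _sample(self, chains_matrix):
        m, n = chains_matrix.shape
        return PosteriorSample(
            fixed_names=["x"],
            beta=chains_matrix[:, :, None],
            u={},
            sigma2={"residual": np.ones((m, n))},
            deviance=np.zeros((m, n)),
            term_levels={},
            X=np.ones((1, 1)),
            Z={},
            z_obs=np.zeros(1),
            s2=np.ones(1),
        )

    def test_identical_chains_near_one(self):
        rng = np.random.default_rng(0)
        c = rng.standard_normal(2000)
        r = gelman_rubin(self._sample(np.vstack([c, c])))
        # B = 0 leaves R-hat at sqrt((n-1)/n), marginally below 1
        assert r["x"] == pytest.approx(1.0, abs=1e-3)

    def test_separated_chains_flagged(self):
        rng = np.random.default_rng(1)
        a = rng.standard_normal(1000)
        b = rng.standard_normal(1000) + 10
        assert gelman_rubin(self._sample(np.vstack([a, b])))["x"] > 5

    def test_white_noise_chains_converged(self):
        rng = np.random.default_rng(2)
        mat = rng.standard_normal((4, 5000))
        assert gelman_rubin(self._sample(mat))["x"] < 1.05

    def test_single_chain_rejected(self):
        with pytest.raises(ValueError):
            gelman_rubin(self._sample(np.zeros((1, 100))))


class TestPosteriorPredictive:
    def test_one_row_per_measurement_and_calibration(self, benchmark_dataset, benchmark_phylo):
        ds = benchmark_dataset
        pri = default_priors(ds, ("MType", "Species", "Phylo", "Study"))
        cs = ChainSettings(iterations=4000, burn_in=1000, thin=3, n_chains=1, seed=8)
        post = fit_mcmc(ds, ModelSpec("repertoire"), pri, cs, phylo=benchmark_phylo)
        tbl = posterior_predictive(post, ds, seed=0)
        assert len(tbl) == ds.n_measurements
        # generated from the fitted model family: coverage near nominal
        assert tbl["covered"].mean() > 0.85

    def test_dataset_mismatch_rejected(self, benchmark_dataset):
        ds = benchmark_dataset
        pri = default_priors(ds, ("Study",))
        cs = ChainSettings(iterations=1200, burn_in=200, thin=2, n_chains=1, seed=8)
        post = fit_mcmc(ds, ModelSpec("intercept", ("Study",)), pri, cs)
        short = toy_dataset([0.1, 0.2, 0.3], [0.2] * 3)
        with pytest.raises(ValueError, match="match"):
            posterior_predictive(post, short)


class TestHPD:
    def test_uniform_grid_width(self):
        lo, hi = hdi(np.linspace(0, 1, 1001), 0.9)
        assert hi - lo == pytest.approx(0.9, abs=0.01)

    def test_normal_quantiles(self):
        rng = np.random.default_rng(5)
        lo, hi = hdi(rng.standard_normal(200_000), 0.95)
        assert lo == pytest.approx(-1.96, abs=0.03)
        assert hi == pytest.approx(1.96, abs=0.03)

    def test_point_mass(self):
        lo, hi = hdi(np.full(100, 2.5), 0.95)
        assert lo == hi == 2.5

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            hdi([], 0.95)
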