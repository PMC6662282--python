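"""Run configuration and end-to-end report assembly.

`run_pipeline` ties the stages together: load (or receive) the measurement
and trait tables and trees, build the requested dataset variant, run the
funnel-asymmetry tests, fit the Bayesian model, and export dataset
summaries, fit summaries, heterogeneity, forest- and funnel-plot tables.
Every artifact is stamped with the config hash and seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import bias_tests, effect_size, meta_model, phylogeny
from .effect_size import AnalysisDataset
from .meta_model import ChainSettings, ModelSpec, PriorSpec

logger = logging.getLogger("songmeta")

__all__ = ["RunConfig", "run_pipeline", "forest_table"]


@dataclass
class RunConfig:
    """Everything one pipeline run needs, loadable from YAML/JSON."""

    measurements: str
    traits: str
    trees: str | None = None
    variant: str = "full"
    territory_mode: str = "uncontrolled"
    repertoire_summary: str = "median"
    fixed: str = "intercept"
    random_terms: tuple[str, ...] = meta_model.RANDOM_TERMS
    priors: dict | None = None          # {"V":..., "nu":...}; None = auto
    iterations: int = 200_000
    burn_in: int = 30_000
    thin: int = 10
    n_chains: int = 4
    seed: int = 0
    out_dir: str = "results/run"
    log_level: str = "INFO"
    drop_outgroup: str | None = None

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text)
        if "random_terms" in data:
            data["random_terms"] = tuple(data["random_terms"])
        cfg = cls(**data)
        for p in (cfg.measurements, cfg.traits, cfg.trees):
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"configured input does not exist: {p}")
        return cfg

    def digest(self) -> str:
        payload = json.dumps(
            {k: (list(v) if isinstance(v, tuple) else v) for k, v in self.__dict__.items()},
            sort_keys=True,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def forest_table(dataset: AnalysisDataset, fit: meta_model.FitSummary | None = None) -> pd.DataFrame:
    """Forest-plot data: per-measurement Z with its 95% CI and the mean line.

    The confidence half-width is 1.96 / sqrt(n - 3); the population mean
    line is the fitted model's first coefficient when a fit is supplied,
    otherwise the inverse-variance pooled mean.
    """
    df = dataset.data
    if len(df) == 0:
        raise ValueError("empty dataset")
    half = 1.96 * df["se"].to_numpy(dtype=float)
    if fit is not None:
        mean_line = float(fit.fixed["mean"].iloc[0])
    else:
        w = 1.0 / df["se"].to_numpy(dtype=float) ** 2
        mean_line = float((w * df["z"].to_numpy(dtype=float)).sum() / w.sum())
    return pd.DataFrame(
        {
            "study_id": df["study_id"].to_numpy(),
            "species": df["species"].to_numpy(),
            "n": df["n"].to_numpy(),
            "z": df["z"].to_numpy(),
            "ci_low": df["z"].to_numpy() - half,
            "ci_high": df["z"].to_numpy() + half,
            "mean_line": mean_line,
        }
    )


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis described by ``config``; return the artifacts.

    Writes, under ``config.out_dir``: dataset_summary.json, funnel and
    forest CSVs, bias_tests.json, fit_summary.csv, heterogeneity.json and
    draws.csv. On a stage failure the partial outputs remain on disk and
    the exception propagates.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stamp = {"config_hash": config.digest(), "seed": config.seed}
    log_file = out / "run.log"
    fh = logging.FileHandler(log_file)
    logger.addHandler(fh)
    artifacts: dict = {"stamp": stamp}
    try:
        raw = effect_size.load_measurements(config.measurements)
        traits = effect_size.load_traits(config.traits)
        dataset = effect_size.build_dataset(
            raw,
            traits,
            variant=config.variant,
            territory_mode=config.territory_mode,
            repertoire_summary=config.repertoire_summary,
        )
        summary = {**dataset.counts(), **stamp}
        (out / "dataset_summary.json").write_text(json.dumps(summary, indent=2))
        logger.info("dataset: %s", dataset.counts())
        artifacts["dataset"] = dataset

        phylo = None
        if config.trees is not None and "Phylo" in config.random_terms:
            trees = phylogeny.read_trees(config.trees)
            tree = trees[0] if len(trees) == 1 else phylogeny.consensus_tree(trees)
            if config.drop_outgroup:
                tree = phylogeny.root_with_outgroup(
                    tree, config.drop_outgroup, drop_outgroup=True
                )
            phylo = phylogeny.phylo_correlation(tree, dataset.species)

        bias = {
            "egger": bias_tests.egger_test(dataset).to_dict(),
            "begg_rank": bias_tests.begg_rank_test(dataset).to_dict(),
            **stamp,
        }
        (out / "bias_tests.json").write_text(json.dumps(bias, indent=2))
        artifacts["bias"] = bias
        bias_tests.funnel_table(dataset).to_csv(out / "funnel.csv", index=False)

        spec = ModelSpec(fixed=config.fixed, random_terms=tuple(config.random_terms))
        if config.priors:
            priors = PriorSpec(**config.priors)
        else:
            priors = meta_model.default_priors(dataset, spec.random_terms)
        chains = ChainSettings(
            iterations=config.iterations,
            burn_in=config.burn_in,
            thin=config.thin,
            n_chains=config.n_chains,
            seed=config.seed,
        )
        post = meta_model.fit_mcmc(dataset, spec, priors, chains, phylo=phylo)
        fit = meta_model.summarize(post)
        fit.fixed.assign(**stamp).to_csv(out / "fit_summary.csv")
        het = {**meta_model.heterogeneity(post, dataset), "dic": fit.dic, **stamp}
        (out / "heterogeneity.json").write_text(json.dumps(het, indent=2))
        forest_table(dataset, fit).to_csv(out / "forest.csv", index=False)

        draws = {f"beta_{n}": post.fixed_draws(n) for n in post.fixed_names}
        draws.update({f"sigma2_{k}": v.ravel() for k, v in post.sigma2.items()})
        pd.DataFrame(draws).to_csv(out / "draws.csv", index=False)

        artifacts.update({"fit": fit, "heterogeneity": het, "posterior": post})
        logger.info("fit complete: DIC=%.3f", fit.dic)
        return artifacts
    finally:
        logger.removeHandler(fh)
        fh.close()
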