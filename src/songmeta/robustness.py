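"""Perturbation battery: refit the meta-analytic model under systematic
changes to the dataset and report how the focal coefficient moves.

Covers the species jackknife, exclusion of extreme-repertoire species,
min/median/max repertoire summaries, song-stability reclassification,
substitution of territory-controlled measurements, and refits across a
sample of candidate phylogenies.
"""

from __future__ import annotations

import math
from dataclasses import replace as dc_replace

import numpy as np
import pandas as pd

from .effect_size import AnalysisDataset, build_dataset
from .meta_model import (
    ChainSettings,
    ModelSpec,
    PriorSpec,
    default_priors,
    fit_mcmc,
    summarize,
)
from .phylogeny import PhyloCorrelation, phylo_correlation

__all__ = [
    "jackknife_species",
    "exclude_extremes",
    "flip_classification",
    "repertoire_variant",
    "territory_swap",
    "tree_uncertainty",
]


def _subset(dataset: AnalysisDataset, keep_species) -> AnalysisDataset:
    keep = set(keep_species)
    data = dataset.data.loc[dataset.data["species"].isin(keep)].reset_index(drop=True)
    traits = dataset.traits.loc[dataset.traits["species"].isin(keep)].reset_index(drop=True)
    return dc_replace(dataset, data=data, traits=traits)


def _fit_row(
    label: str,
    dataset: AnalysisDataset,
    spec: ModelSpec,
    priors: PriorSpec | None,
    chains: ChainSettings,
    phylo: PhyloCorrelation | None,
    focal: str,
) -> dict:
    pri = priors if priors is not None else default_priors(dataset, spec.random_terms)
    sub_phylo = phylo.subset(sorted(dataset.data["species"].unique())) if phylo else None
    post = fit_mcmc(dataset, spec, pri, chains, phylo=sub_phylo)
    two = summarize(post, convention="two_sided")
    one = summarize(post, convention="frac_above_zero")
    row = two.fixed.loc[focal]
    return {
        "label": label,
        "n_measurements": dataset.n_measurements,
        "n_species": dataset.n_species,
        "mean": float(row["mean"]),
        "hpd_low": float(row["hpd_low"]),
        "hpd_high": float(row["hpd_high"]),
        "p_mcmc_two_sided": float(row["p_mcmc"]),
        "p_mcmc_above_zero": float(one.fixed.loc[focal, "p_mcmc"]),
    }


def _focal_effect(spec: ModelSpec) -> str:
    if spec.fixed == "repertoire":
        return "ln_syll_rep"
    if spec.fixed == "stability":
        return "plastic"
    return "intercept"


def jackknife_species(
    dataset: AnalysisDataset,
    spec: ModelSpec,
    priors: PriorSpec | None = None,
    chains: ChainSettings | None = None,
    phylo: PhyloCorrelation | None = None,
    focal: str | None = None,
) -> pd.DataFrame:
    """Refit with each species removed in turn; first row is the baseline.

    Priors are recomputed from each reduced dataset by default (pass
    ``priors`` to freeze them at the baseline values).
    """
    chains = chains or ChainSettings()
    species = dataset.species
    if len(species) < 3:
        raise ValueError("jackknife needs at least 3 species")
    focal = focal or _focal_effect(spec)
    rows = [_fit_row("baseline", dataset, spec, priors, chains, phylo, focal)]
    for sp in species:
        sub = _subset(dataset, [s for s in species if s != sp])
        label = f"drop:{sp}"
        try:
            rows.append(_fit_row(label, sub, spec, priors, chains, phylo, focal))
        except ValueError as err:
            rows.append({"label": label, "n_measurements": sub.n_measurements,
                         "n_species": sub.n_species, "error": str(err)})
    return pd.DataFrame(rows)


def exclude_extremes(dataset: AnalysisDataset, end: str, k: int) -> AnalysisDataset:
    """Drop the k species at one extreme of ln repertoire size.

    Ties on repertoire size are broken lexicographically by species name
    for determinism.
    """
    if end not in ("largest", "smallest"):
        raise ValueError(f"end must be 'largest' or 'smallest', got {end!r}")
    species = dataset.traits.dropna(subset=["ln_syll_rep"]).copy()
    n_sp = dataset.n_species
    if k >= n_sp:
        raise ValueError(f"cannot drop k={k} of {n_sp} species")
    if k == 0:
        return dataset
    species = species.sort_values(
        ["ln_syll_rep", "species"], ascending=[end == "smallest", True]
    )
    drop = set(species["species"].head(k))
    keep = [s for s in dataset.species if s not in drop]
    return _subset(dataset, keep)


def flip_classification(dataset: AnalysisDataset, species: str) -> AnalysisDataset:
    """Flip one species between song-stable and song-plastic."""
    traits = dataset.traits
    match = traits.loc[traits["species"] == species]
    if len(match) == 0:
        raise ValueError(f"species {species!r} not in dataset")
    current = match["stability"].iloc[0]
    if current not in ("stable", "plastic"):
        raise ValueError(f"species {species!r} has unknown stability")
    flipped = "plastic" if current == "stable" else "stable"
    new_traits = traits.copy()
    new_traits.loc[new_traits["species"] == species, "stability"] = flipped
    new_data = dataset.data.copy()
    new_data.loc[new_data["species"] == species, "stability"] = flipped
    return dc_replace(dataset, data=new_data, traits=new_traits)


def repertoire_variant(dataset: AnalysisDataset, rule: str) -> AnalysisDataset:
    """Rebuild the dataset with the min/median/max repertoire summary."""
    if rule not in ("median", "min", "max"):
        raise ValueError(f"unknown repertoire summary rule: {rule!r}")
    if dataset.raw is None or dataset.raw_traits is None:
        raise ValueError("dataset does not carry its raw inputs; rebuild it with build_dataset")
    return build_dataset(
        dataset.raw,
        dataset.raw_traits,
        variant=dataset.variant,
        territory_mode=dataset.territory_mode,
        repertoire_summary=rule,
        bias_correct=dataset.bias_correct,
    )


def territory_swap(dataset: AnalysisDataset) -> AnalysisDataset:
    """Substitute territory-controlled values wherever a pair exists.

    Swapping twice returns the original dataset; records without a
    controlled counterpart are untouched (the resolution happens in
    ``build_dataset``'s pair-matching step).
    """
    if dataset.raw is None or dataset.raw_traits is None:
        raise ValueError("dataset does not carry its raw inputs; rebuild it with build_dataset")
    other = (
        "territory_controlled"
        if dataset.territory_mode == "uncontrolled"
        else "uncontrolled"
    )
    return build_dataset(
        dataset.raw,
        dataset.raw_traits,
        variant=dataset.variant,
        territory_mode=other,
        repertoire_summary=dataset.repertoire_summary,
        bias_correct=dataset.bias_correct,
    )


def tree_uncertainty(
    dataset: AnalysisDataset,
    spec: ModelSpec,
    priors: PriorSpec | None,
    chains: ChainSettings,
    trees,
    m: int,
    seed: int = 0,
    focal: str | None = None,
) -> pd.DataFrame:
    """Refit over ``m`` trees sampled without replacement from ``trees``.

    Reports the focal coefficient per tree plus a pooled summary row: the
    mean of the per-tree posterior means and the union range of the HPDs.
    No formal cross-tree posterior mixing is attempted.
    """
    trees = list(trees)
    if m > len(trees):
        raise ValueError(f"requested m={m} trees but only {len(trees)} supplied")
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(trees), size=m, replace=False)
    focal = focal or _focal_effect(spec)
    species = dataset.species
    rows = []
    for i in idx:
        corr = phylo_correlation(trees[int(i)], species)
        rows.append(
            _fit_row(f"tree:{int(i)}", dataset, spec, priors, chains, corr, focal)
        )
    report = pd.DataFrame(rows)
    pooled = {
        "label": "pooled",
        "n_measurements": dataset.n_measurements,
        "n_species": dataset.n_species,
        "mean": float(report["mean"].mean()),
        "hpd_low": float(report["hpd_low"].min()),
        "hpd_high": float(report["hpd_high"].max()),
        "p_mcmc_two_sided": float(report["p_mcmc_two_sided"].max()),
        "p_mcmc_above_zero": float(report["p_mcmc_above_zero"].max()),
    }
    return pd.concat([report, pd.DataFrame([pooled])], ignore_index=True)
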