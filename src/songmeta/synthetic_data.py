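"""Synthetic field-study generator for end-to-end testing of the pipeline.

Emulates the structure of the compiled field data: a pure-birth species
tree, species traits (literature-style syllable repertoire sizes and a
song-stability class), species-level true effects drawn from the
multilevel model's own variance structure (measurement-type, species,
phylogenetic and study components), and per-measurement sample
correlations with the correct sampling distribution of Pearson's r at the
stated sample size. True effects live on the Fisher's Z scale and are
mapped through tanh to a correlation before data are drawn, so the
fitted model is correctly specified for the generated data.

Default shape mirrors the repertoire analysis dataset: 25 species and on
the order of 86 measurements spread over studies, with per-measurement
sample sizes of 8-40 males and seven metrics of reproductive success.
"""

from __future__ import annotations

import json
import math
import random as _random
from dataclasses import dataclass, field, asdict
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd

from .effect_size import MTYPES, AnalysisDataset, build_dataset
from .phylogeny import phylo_correlation, write_tree

__all__ = [
    "SimulationConfig",
    "simulate_tree",
    "simulate_traits",
    "simulate_true_effects",
    "simulate_measurements",
    "generate_benchmark",
]


@dataclass
class SimulationConfig:
    """Generating parameters for one synthetic study compilation.

    The defaults are the benchmark conditions used throughout the test
    suite: a modest positive repertoire effect on the Fisher's Z scale
    over repertoires spanning roughly e^1 to e^7 syllables, with variance
    components small relative to the sampling noise — the regime the field
    data occupy.
    """

    n_species: int = 25
    mean_studies_per_species: float = 0.6   # studies = 1 + Poisson(this)
    mean_measurements_per_study: float = 1.15  # measurements = 1 + Poisson(this)
    n_min: int = 8
    n_max: int = 40
    beta0: float = -0.35
    beta1: float = 0.15
    sigma2_mtype: float = 0.02
    sigma2_species: float = 0.01
    sigma2_phylo: float = 0.01
    sigma2_study: float = 0.02
    sigma2_residual: float = 0.01
    ln_rep_mean: float = 3.5
    ln_rep_sd: float = 1.5
    ln_rep_range: tuple[float, float] = (1.0, 7.5)
    n_rep_reports_max: int = 3
    p_stable: float = 0.3
    p_plastic: float = 0.55   # remainder is unknown stability
    seed: int = 0

    def __post_init__(self):
        for name in ("sigma2_mtype", "sigma2_species", "sigma2_phylo",
                     "sigma2_study", "sigma2_residual"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_min < 4:
            raise ValueError("per-measurement sample sizes must be >= 4")
        if self.n_species < 2:
            raise ValueError("need at least 2 species")


def simulate_tree(n_species: int, seed: int = 0) -> dendropy.Tree:
    """Pure-birth (Yule) tree scaled to unit height, tips Species_001..."""
    if n_species < 2:
        raise ValueError("need at least 2 species")
    from dendropy.model import birthdeath

    tree = birthdeath.birth_death_tree(
        birth_rate=1.0,
        death_rate=0.0,
        num_extant_tips=n_species,
        rng=_random.Random(int(seed)),
    )
    for i, leaf in enumerate(tree.leaf_node_iter(), start=1):
        label = f"Species_{i:03d}"
        leaf.taxon.label = label
    tree.is_rooted = True
    depths = tree.calc_node_root_distances(return_leaf_distances_only=True)
    height = max(depths)
    if height == 0:
        # two-tip case: the process stops at the first split, leaving zero
        # elapsed time; give the cherry unit-length terminal edges directly
        for leaf in tree.leaf_node_iter():
            leaf.edge.length = 1.0
        return tree
    for edge in tree.preorder_edge_iter():
        if edge.length is not None:
            edge.length = edge.length / height
    return tree


def simulate_traits(config: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Species traits: repertoire reports (log-normal) and stability class."""
    rows = []
    lo, hi = config.ln_rep_range
    for i in range(1, config.n_species + 1):
        ln_rep = float(np.clip(rng.normal(config.ln_rep_mean, config.ln_rep_sd), lo, hi))
        n_reports = int(rng.integers(1, config.n_rep_reports_max + 1))
        # literature reports scatter around the species value
        reports = np.exp(ln_rep + 0.15 * rng.standard_normal(n_reports))
        u = rng.random()
        if u < config.p_stable:
            stability = "stable"
        elif u < config.p_stable + config.p_plastic:
            stability = "plastic"
        else:
            stability = "unknown"
        rows.append(
            {
                "species": f"Species_{i:03d}",
                "syll_rep_values": ";".join(f"{v:.4f}" for v in reports),
                "stability": stability,
                "increases_with_age": "yes" if stability == "plastic" and rng.random() < 0.7
                else ("no" if stability != "unknown" else "unknown"),
            }
        )
    return pd.DataFrame(rows)


def simulate_true_effects(
    tree: dendropy.Tree,
    config: SimulationConfig,
    rng: np.random.Generator,
    ln_rep: dict[str, float],
    layout: list[tuple[str, str, str]],
) -> np.ndarray:
    """True Fisher's Z mean for each planned measurement.

    ``layout`` lists (species, study_id, mtype) per measurement. Phylo
    effects are drawn from Normal(0, sigma2_phylo * A) via the Cholesky
    factor of the tree's correlation matrix; the other components are
    i.i.d. normal.
    """
    species = sorted({sp for sp, _, _ in layout})
    studies = sorted({st for _, st, _ in layout})
    corr = phylo_correlation(tree, species)
    eigmin = float(np.linalg.eigvalsh(corr.A).min())
    if eigmin < -1e-8:
        raise ValueError("phylogenetic correlation matrix is not PSD")
    L = np.linalg.cholesky(corr.A + 1e-10 * np.eye(len(species)))

    u_mtype = {m: rng.normal(0.0, math.sqrt(config.sigma2_mtype)) for m in MTYPES}
    u_species = {s: rng.normal(0.0, math.sqrt(config.sigma2_species)) for s in species}
    phylo_vec = math.sqrt(config.sigma2_phylo) * (L @ rng.standard_normal(len(species)))
    u_phylo = dict(zip(species, phylo_vec))
    u_study = {s: rng.normal(0.0, math.sqrt(config.sigma2_study)) for s in studies}

    z_true = np.empty(len(layout))
    for i, (sp, st, mt) in enumerate(layout):
        z = (
            config.beta0
            + config.beta1 * ln_rep[sp]
            + u_mtype[mt]
            + u_species[sp]
            + u_phylo[sp]
            + u_study[st]
            + rng.normal(0.0, math.sqrt(config.sigma2_residual))
        )
        z_true[i] = z
    return z_true


def sample_pearson_r(rho: float, n: int, rng: np.random.Generator) -> float:
    """Sample correlation of n bivariate-normal pairs with correlation rho."""
    x = rng.standard_normal(n)
    y = rho * x + math.sqrt(1.0 - rho**2) * rng.standard_normal(n)
    return float(np.corrcoef(x, y)[0, 1])


def simulate_measurements(
    true_z: np.ndarray,
    layout: list[tuple[str, str, str]],
    config: SimulationConfig,
    rng: np.random.Generator,
    as_t_statistics: bool = False,
) -> pd.DataFrame:
    """Draw a sample correlation per planned measurement and emit the raw table.

    Each measurement draws n_i individuals from a bivariate normal with
    correlation tanh(z*_i) and reports the sample Pearson r (or, with
    ``as_t_statistics``, the equivalent t = r sqrt((n-2)/(1-r^2)) with
    df = n - 2 to exercise the statistic conversions). Latency metrics are
    reported with the field sign convention (success correlations
    negated), which the harmonization step flips back.
    """
    rows = []
    for i, (sp, st, mt) in enumerate(layout):
        rho = math.tanh(true_z[i])
        if abs(rho) >= 1:
            raise ValueError(f"true correlation out of range for measurement {i}")
        n = int(rng.integers(config.n_min, config.n_max + 1))
        r = sample_pearson_r(rho, n, rng)
        r = float(np.clip(r, -0.999999, 0.999999))
        reported_r = -r if mt in ("pairing_latency", "laying_latency") else r
        if as_t_statistics:
            kind = "t"
            value = abs(reported_r) * math.sqrt((n - 2) / (1.0 - reported_r**2))
            df: float | str = n - 2
            direction = "positive" if reported_r >= 0 else "negative"
        else:
            kind = "pearson_r"
            value = reported_r
            df = ""
            direction = "positive"
        rows.append(
            {
                "study_id": st,
                "species": sp,
                "mtype": mt,
                "elaboration_metric": "syllable_repertoire",
                "statistic_kind": kind,
                "statistic_value": value,
                "n": n,
                "df": df,
                "effect_direction": direction,
                "territory_controlled": False,
                "excluded": False,
                "exclusion_reason": "",
            }
        )
    return pd.DataFrame(rows)


def _plan_layout(config: SimulationConfig, rng: np.random.Generator) -> list[tuple[str, str, str]]:
    layout = []
    study_counter = 0
    for i in range(1, config.n_species + 1):
        sp = f"Species_{i:03d}"
        n_studies = 1 + int(rng.poisson(config.mean_studies_per_species))
        for _ in range(n_studies):
            study_counter += 1
            st = f"Study_{study_counter:03d}"
            n_meas = 1 + int(rng.poisson(config.mean_measurements_per_study))
            mtypes = rng.choice(MTYPES, size=n_meas, replace=n_meas > len(MTYPES))
            for mt in np.atleast_1d(mtypes):
                layout.append((sp, st, str(mt)))
    return layout


def generate_benchmark(
    config: SimulationConfig | None = None,
    variant: str = "repertoire",
    as_t_statistics: bool = False,
    out_dir: str | Path | None = None,
):
    """End-to-end synthetic bundle: (AnalysisDataset, tree, truth record).

    The truth record carries every generating parameter plus the per-layout
    true effects for parameter-recovery tests. With ``out_dir`` the raw
    CSVs, the Newick tree and the truth JSON are also written to disk.
    """
    config = config or SimulationConfig()
    rng = np.random.default_rng(config.seed)
    tree = simulate_tree(config.n_species, seed=config.seed)
    traits_raw = simulate_traits(config, rng)

    from .effect_size import load_traits, repertoire_summary_value, _parse_rep_values

    traits = traits_raw.copy()
    traits["syll_rep_values"] = traits["syll_rep_values"].apply(_parse_rep_values)
    ln_rep = {
        row["species"]: math.log(repertoire_summary_value(row["syll_rep_values"], "median"))
        for _, row in traits.iterrows()
    }

    layout = _plan_layout(config, rng)
    true_z = simulate_true_effects(tree, config, rng, ln_rep, layout)
    raw = simulate_measurements(true_z, layout, config, rng,
                                as_t_statistics=as_t_statistics)
    dataset = build_dataset(raw, traits, variant=variant)

    truth = {
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in asdict(config).items()},
        "true_z_mean": [float(z) for z in true_z],
        "layout": [list(t) for t in layout],
        "ln_rep": ln_rep,
    }
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        raw.to_csv(out_dir / "measurements.csv", index=False)
        traits_raw.to_csv(out_dir / "traits.csv", index=False)
        write_tree(tree, out_dir / "tree.nwk")
        (out_dir / "truth.json").write_text(json.dumps(truth, indent=2))
    return dataset, tree, truth
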