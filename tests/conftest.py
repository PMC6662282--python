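import numpy as np
import pandas as pd
import pytest

from songmeta.phylogeny import phylo_correlation
from songmeta.synthetic_data import SimulationConfig, generate_benchmark


@pytest.fixture(scope="session")
def benchmark():
    """Default synthetic benchmark: dataset, tree, truth record."""
    return generate_benchmark(SimulationConfig(seed=42))


@pytest.fixture(scope="session")
def benchmark_dataset(benchmark):
    return benchmark[0]


@pytest.fixture(scope="session")
def benchmark_phylo(benchmark):
    ds, tree, _ = benchmark
    return phylo_correlation(tree, ds.species)


def make_measurement_rows(rows):
    """Fill in a raw measurement table from sparse row dicts."""
    defaults = {
        "study_id": "S1",
        "species": "Species_A",
        "mtype": "clutch_size",
        "elaboration_metric": "syllable_repertoire",
        "statistic_kind": "pearson_r",
        "statistic_value": 0.2,
        "n": 20,
        "df": np.nan,
        "effect_direction": "positive",
        "territory_controlled": False,
        "excluded": False,
        "exclusion_reason": "",
    }
    return pd.DataFrame([{**defaults, **r} for r in rows])


def make_traits(rows):
    defaults = {
        "species": "Species_A",
        "syll_rep_values": [10.0],
        "stability": "stable",
        "increases_with_age": "no",
    }
    return pd.DataFrame([{**defaults, **r} for r in rows])
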