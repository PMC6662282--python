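"""Perturbation battery: jackknife, extremes, reclassification, swaps, trees."""

import math

import numpy as np
import pandas as pd
import pytest

from songmeta.effect_size import build_dataset
from songmeta.meta_model import ChainSettings, ModelSpec
from songmeta.robustness import (
    exclude_extremes,
    flip_classification,
    jackknife_species,
    repertoire_variant,
    territory_swap,
    tree_uncertainty,
)
from songmeta.synthetic_data import SimulationConfig, generate_benchmark

from conftest import make_measurement_rows, make_traits

FAST = ChainSettings(iterations=1500, burn_in=300, thin=4, n_chains=1, seed=0)
NO_PHYLO = ("MType", "Species", "Study")


@pytest.fixture(scope="module")
def small_benchmark():
    cfg = SimulationConfig(n_species=8, seed=5)
    return generate_benchmark(cfg)


class TestJackknife:
    def test_one_row_per_species_plus_baseline(self, small_benchmark):
        ds, _, _ = small_benchmark
        spec = ModelSpec(fixed="repertoire", random_terms=NO_PHYLO)
        report = jackknife_species(ds, spec, chains=FAST)
        assert len(report) == ds.n_species + 1
        assert report["label"].iloc[0] == "baseline"
        assert (report["n_species"].iloc[1:] == ds.n_species - 1).all()

    def test_planted_outlier_species_drives_the_slope(self):
        """When one extreme-repertoire species carries the entire slope
        signal, removing it should lose significance."""
        rng = np.random.default_rng(12)
        rows, traits = [], []
        for i, (rep, z0) in enumerate([(5, 0.0), (6, 0.0), (7, 0.0), (8, 0.0),
                                       (10, 0.0), (1000, 0.9)]):
            sp = f"Sp{i}"
            traits.append({"species": sp, "syll_rep_values": [float(rep)],
                           "stability": "unknown"})
            for j in range(4):
                r = math.tanh(z0) + 0.05 * rng.standard_normal()
                rows.append({"study_id": f"St{i}_{j}", "species": sp,
                             "statistic_value": float(np.clip(r, -0.99, 0.99)),
                             "n": 40})
        ds = build_dataset(make_measurement_rows(rows), make_traits(traits),
                           variant="repertoire")
        spec = ModelSpec(fixed="repertoire", random_terms=("Species",))
        chains = ChainSettings(iterations=3000, burn_in=600, thin=2, n_chains=1, seed=1)
        report = jackknife_species(ds, spec, chains=chains)
        base = report.loc[report["label"] == "baseline"].iloc[0]
        dropped = report.loc[report["label"] == "drop:Sp5"].iloc[0]
        assert base["hpd_low"] > 0  # slope significant with the outlier in
        assert dropped["hpd_low"] <= 0  # and not significant without it

    def test_too_few_species_rejected(self):
        raw = make_measurement_rows([{"species": "A"}, {"species": "B", "study_id": "S2"}])
        traits = make_traits([{"species": "A"}, {"species": "B"}])
        ds = build_dataset(raw, traits)
        with pytest.raises(ValueError, match="at least 3"):
            jackknife_species(ds, ModelSpec("intercept", ("Study",)), chains=FAST)


class TestExcludeExtremes:
    def test_identity_and_counts(self, small_benchmark):
        ds, _, _ = small_benchmark
        assert exclude_extremes(ds, "largest", 0) is ds
        sub = exclude_extremes(ds, "largest", 3)
        assert sub.n_species == ds.n_species - 3
        dropped = set(ds.species) - set(sub.species)
        traits = ds.traits.set_index("species")["ln_syll_rep"]
        assert all(traits[d] >= traits[list(set(sub.species))].max() - 1e-12
                   for d in dropped)

    def test_smallest_end(self, small_benchmark):
        ds, _, _ = small_benchmark
        sub = exclude_extremes(ds, "smallest", 2)
        traits = ds.traits.set_index("species")["ln_syll_rep"]
        dropped = set(ds.species) - set(sub.species)
        assert all(traits[d] <= traits[list(set(sub.species))].min() + 1e-12
                   for d in dropped)

    def test_boundary_single_species_left(self, small_benchmark):
        ds, _, _ = small_benchmark
        sub = exclude_extremes(ds, "largest", ds.n_species - 1)
        assert sub.n_species == 1

    def test_k_too_large_rejected(self, small_benchmark):
        ds, _, _ = small_benchmark
        with pytest.raises(ValueError):
            exclude_extremes(ds, "largest", ds.n_species)


class TestFlipClassification:
    def _stab_dataset(self):
        raw = make_measurement_rows(
            [{"species": s, "study_id": f"S{s}"} for s in "ABC"]
        )
        traits = make_traits(
            [
                {"species": "A", "stability": "stable"},
                {"species": "B", "stability": "plastic"},
                {"species": "C", "stability": "unknown"},
            ]
        )
        return build_dataset(raw, traits, variant="full")

    def test_flip_is_an_involution(self):
        ds = self._stab_dataset()
        once = flip_classification(ds, "A")
        assert once.traits.set_index("species").loc["A", "stability"] == "plastic"
        twice = flip_classification(once, "A")
        pd.testing.assert_frame_equal(twice.traits, ds.traits)
        pd.testing.assert_frame_equal(twice.data, ds.data)

    def test_unknown_stability_rejected(self):
        with pytest.raises(ValueError, match="unknown stability"):
            flip_classification(self._stab_dataset(), "C")

    def test_absent_species_rejected(self):
        with pytest.raises(ValueError, match="not in dataset"):
            flip_classification(self._stab_dataset(), "Z")


class TestRepertoireVariant:
    def test_rules_order_elementwise(self, small_benchmark):
        ds, _, _ = small_benchmark
        mn = repertoire_variant(ds, "min").traits.set_index("species")["ln_syll_rep"]
        md = repertoire_variant(ds, "median").traits.set_index("species")["ln_syll_rep"]
        mx = repertoire_variant(ds, "max").traits.set_index("species")["ln_syll_rep"]
        assert (mn <= md + 1e-12).all()
        assert (md <= mx + 1e-12).all()

    def test_single_valued_species_invariant(self):
        raw = make_measurement_rows([{"species": "A"}])
        traits = make_traits([{"species": "A", "syll_rep_values": [12.0]}])
        ds = build_dataset(raw, traits, variant="repertoire")
        for rule in ("min", "median", "max"):
            v = repertoire_variant(ds, rule).traits["ln_syll_rep"].iloc[0]
            assert v == pytest.approx(math.log(12.0))


class TestTerritorySwap:
    def _paired(self):
        raw = make_measurement_rows(
            [
                {"study_id": "S1", "species": "A", "statistic_value": 0.4},
                {"study_id": "S1", "species": "A", "statistic_value": 0.1,
                 "territory_controlled": True},
                {"study_id": "S2", "species": "B", "statistic_value": 0.3},
            ]
        )
        traits = make_traits([{"species": "A"}, {"species": "B"}])
        return build_dataset(raw, traits)

    def test_exactly_one_value_changes(self):
        ds = self._paired()
        swapped = territory_swap(ds)
        merged = ds.data.merge(swapped.data, on=["study_id", "species", "mtype"],
                               suffixes=("_a", "_b"))
        changed = (merged["r_a"] != merged["r_b"]).sum()
        assert changed == 1
        assert swapped.data.query("species=='A'")["r"].iloc[0] == pytest.approx(0.1)

    def test_double_swap_is_identity(self):
        ds = self._paired()
        back = territory_swap(territory_swap(ds))
        pd.testing.assert_frame_equal(back.data, ds.data)

    def test_no_pairs_is_identity(self):
        raw = make_measurement_rows([{"species": "A"}, {"species": "B", "study_id": "S2"}])
        traits = make_traits([{"species": "A"}, {"species": "B"}])
        ds = build_dataset(raw, traits)
        swapped = territory_swap(ds)
        pd.testing.assert_frame_equal(
            swapped.data.sort_values("species").reset_index(drop=True),
            ds.data.sort_values("species").reset_index(drop=True),
        )


class TestTreeUncertainty:
    def test_perturbed_copies_agree(self, small_benchmark):
        import dendropy

        ds, tree, _ = small_benchmark
        rng = np.random.default_rng(3)
        newick = tree.as_string(schema="newick")
        tns = dendropy.TaxonNamespace()
        trees = []
        for _ in range(6):
            t = dendropy.Tree.get(data=newick, schema="newick", taxon_namespace=tns)
            for edge in t.preorder_edge_iter():
                if edge.length is not None:
                    edge.length = max(edge.length * rng.lognormal(0, 0.02), 1e-9)
            trees.append(t)
        spec = ModelSpec(fixed="repertoire", random_terms=("MType", "Species", "Phylo", "Study"))
        chains = ChainSettings(iterations=2500, burn_in=500, thin=4, n_chains=1, seed=2)
        report = tree_uncertainty(ds, spec, None, chains, trees, m=4, seed=0)
        assert len(report) == 5  # 4 per-tree rows + pooled
        per_tree = report.loc[report["label"] != "pooled", "mean"]
        assert per_tree.std() < 0.05
        pooled = report.loc[report["label"] == "pooled"].iloc[0]
        assert pooled["hpd_low"] <= per_tree.min()

    def test_m_exceeding_sample_rejected(self, small_benchmark):
        ds, tree, _ = small_benchmark
        spec = ModelSpec(fixed="repertoire", random_terms=NO_PHYLO)
        with pytest.raises(ValueError, match="m="):
            tree_uncertainty(ds, spec, None, FAST, [tree], m=2)
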