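#!/usr/bin/env python
"""BEST comparison of effect sizes between song-stable and song-plastic species.

Feeds the measurement-level Fisher's Z values of the two stability classes
to the Bayesian two-group model (Student-t likelihoods, broad priors) and
reports the posterior of the mean difference: its mean, 95% HDI, and the
percentage of posterior mass below zero. Groups are called different only
when that percentage leaves the 5-95% band.
"""

import json
from pathlib import Path

from songmeta.effect_size import build_dataset, load_measurements, load_traits
from songmeta.group_compare import best_fit, best_summary
from songmeta.meta_model import ChainSettings

DATA = Path("results/data")
OUT = Path("results")
SEED = 13


def main():
    raw = load_measurements(DATA / "measurements.csv")
    traits = load_traits(DATA / "traits.csv")
    ds = build_dataset(raw, traits, variant="stability")
    g_stable = ds.data.loc[ds.data["stability"] == "stable", "z"].to_numpy()
    g_plastic = ds.data.loc[ds.data["stability"] == "plastic", "z"].to_numpy()
    print(f"stable: {g_stable.size} measurements; plastic: {g_plastic.size}")

    post = best_fit(
        g_stable, g_plastic,
        ChainSettings(iterations=22_000, burn_in=2_000, thin=2, n_chains=1, seed=SEED),
    )
    summ = best_summary(post, n1=g_stable.size, n2=g_plastic.size)
    print(f"mean difference (stable - plastic) = {summ.mean_difference:.4f}")
    print(f"95% HDI = [{summ.hdi_low:.4f}, {summ.hdi_high:.4f}]")
    print(f"% of posterior mass below zero = {summ.percent_below_zero:.1f}%")
    print(f"verdict: {summ.verdict}")

    (OUT / "best_comparison.json").write_text(json.dumps(summ.to_dict(), indent=2))
    print(f"wrote {OUT}/best_comparison.json")


if __name__ == "__main__":
    main()
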