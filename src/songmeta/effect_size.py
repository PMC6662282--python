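"""Effect-size harmonization for field studies of birdsong and reproductive success.

Field studies report the association between an individual male's song
elaboration (song or syllable repertoire size) and a metric of his
reproductive success using a mix of test statistics. This module converts
every supported statistic to a signed Pearson correlation ``r``, applies
the latency sign convention (slower pairing/laying means *less* success,
so latency correlations are flipped), transforms to Fisher's Z with its
exact sampling standard error ``1/sqrt(n - 3)``, and assembles the
analysis datasets by applying the inclusion/exclusion rules.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MTYPES",
    "LATENCY_MTYPES",
    "STATISTIC_KINDS",
    "EffectSize",
    "AnalysisDataset",
    "r_from_statistic",
    "apply_direction",
    "fisher_z",
    "inverse_fisher",
    "load_measurements",
    "load_traits",
    "repertoire_summary_value",
    "build_dataset",
]

#: The seven recognised metrics of reproductive success.
MTYPES = (
    "n_females",
    "pairing_latency",
    "laying_latency",
    "extrapair_paternity",
    "clutch_size",
    "n_offspring",
    "n_recruits",
)

#: Latency metrics: a *negative* correlation with song elaboration indicates
#: higher success, so their r values are multiplied by -1.
LATENCY_MTYPES = ("pairing_latency", "laying_latency")

STATISTIC_KINDS = (
    "pearson_r",
    "spearman_rho",
    "t",
    "F_1df",
    "chi2_1df",
    "mannwhitney_z",
    "raw_r_reported",
)

MEASUREMENT_COLUMNS = [
    "study_id",
    "species",
    "mtype",
    "elaboration_metric",
    "statistic_kind",
    "statistic_value",
    "n",
    "df",
    "effect_direction",
    "territory_controlled",
    "excluded",
    "exclusion_reason",
]

TRAIT_COLUMNS = ["species", "syll_rep_values", "stability", "increases_with_age"]


@dataclass(frozen=True)
class EffectSize:
    """A signed correlation with its Fisher's Z transform and standard error."""

    r: float
    z: float
    se: float
    n: int


@dataclass
class AnalysisDataset:
    """An assembled analysis table plus species traits.

    ``data`` has one row per included measurement with columns
    ``study_id, species, mtype, n, r, z, se`` plus the trait columns
    ``ln_syll_rep`` and ``stability`` merged per species.
    """

    data: pd.DataFrame
    traits: pd.DataFrame
    variant: str = "full"
    territory_mode: str = "uncontrolled"
    repertoire_summary: str = "median"
    bias_correct: bool = True
    # Raw inputs retained so perturbation analyses can rebuild the dataset
    # under an alternative rule (territory swap, min/max repertoire summary).
    raw: pd.DataFrame | None = None
    raw_traits: pd.DataFrame | None = None

    @property
    def n_measurements(self) -> int:
        return len(self.data)

    @property
    def n_species(self) -> int:
        return self.data["species"].nunique()

    @property
    def n_studies(self) -> int:
        return self.data["study_id"].nunique()

    @property
    def species(self) -> list[str]:
        return sorted(self.data["species"].unique())

    def counts(self) -> dict[str, int]:
        return {
            "measurements": self.n_measurements,
            "species": self.n_species,
            "studies": self.n_studies,
        }


def r_from_statistic(
    kind: str,
    value: float,
    n: int,
    df: int | None = None,
    direction: str = "positive",
) -> float:
    """Convert a reported test statistic to a signed Pearson ``r``.

    Conversions follow the standard meta-analytic formulas:

    * ``t``:  r = sqrt(t^2 / (t^2 + df))
    * ``F_1df`` (1 numerator df):  r = sqrt(F / (F + df))
    * ``chi2_1df``:  r = sqrt(chi2 / n)
    * ``mannwhitney_z`` (normal deviate):  r = z / sqrt(n)
    * ``spearman_rho``:  r = 2 sin(pi * rho / 6)
    * ``pearson_r`` / ``raw_r_reported``: passthrough

    The sign is taken from ``direction`` (the statistic magnitudes above are
    nonnegative); latency sign flipping is a separate downstream step
    (:func:`apply_direction`).
    """
    if kind not in STATISTIC_KINDS:
        raise ValueError(f"unsupported statistic kind: {kind!r}")
    if not math.isfinite(value):
        raise ValueError(f"statistic value must be finite, got {value!r}")
    if n < 4:
        raise ValueError(f"n must be >= 4 (got n={n})")

    if kind in ("pearson_r", "raw_r_reported"):
        r = float(value)
    elif kind == "spearman_rho":
        if not -1.0 < value < 1.0:
            raise ValueError(f"spearman rho must lie in (-1, 1), got {value}")
        r = 2.0 * math.sin(math.pi * value / 6.0)
    elif kind == "t":
        if df is None:
            raise ValueError("df is required for a t statistic")
        r = math.sqrt(value**2 / (value**2 + df))
    elif kind == "F_1df":
        if df is None:
            raise ValueError("df (denominator) is required for an F statistic")
        if value < 0:
            raise ValueError(f"F statistic must be nonnegative, got {value}")
        r = math.sqrt(value / (value + df))
    elif kind == "chi2_1df":
        if value < 0:
            raise ValueError(f"chi-square statistic must be nonnegative, got {value}")
        r = math.sqrt(value / n)
    else:  # mannwhitney_z
        r = value / math.sqrt(n)

    if kind not in ("pearson_r", "raw_r_reported", "spearman_rho"):
        r = abs(r)
        if direction == "negative":
            r = -r
        elif direction != "positive":
            raise ValueError(f"unknown effect direction: {direction!r}")

    if not -1.0 < r < 1.0:
        raise ValueError(
            f"conversion of {kind}={value} (n={n}, df={df}) yields |r| >= 1 (r={r})"
        )
    return r


def apply_direction(r: float, mtype: str) -> float:
    """Flip the sign of latency correlations; identity for other metrics."""
    if mtype not in MTYPES:
        raise ValueError(f"unknown reproductive-success metric: {mtype!r}")
    return -r if mtype in LATENCY_MTYPES else r


def fisher_z(r: float, n: int, bias_correct: bool = True) -> EffectSize:
    """Fisher's r-to-Z transform with sampling SE ``1/sqrt(n-3)``.

    ``atanh(r)`` has a small positive bias at small n; with
    ``bias_correct=True`` Hotelling's correction

        z* = z - (3 z + r) / (4 (n - 1))

    is applied. The standard error is unchanged by the correction.
    """
    if not -1.0 < r < 1.0:
        raise ValueError(f"|r| must be < 1, got r={r}")
    if n < 4:
        raise ValueError(f"n must be >= 4 for a finite SE, got n={n}")
    z = math.atanh(r)
    if bias_correct:
        z = z - (3.0 * z + r) / (4.0 * (n - 1.0))
    se = 1.0 / math.sqrt(n - 3.0)
    return EffectSize(r=float(r), z=z, se=se, n=int(n))


def inverse_fisher(z: float) -> float:
    """Back-transform a Fisher's Z to the correlation scale, r = tanh(z)."""
    return math.tanh(z)


def load_measurements(path: str | Path) -> pd.DataFrame:
    """Read a measurement-level CSV and validate it.

    Records supplying only a p-value cannot be converted here (the standard
    conversions operate on test statistics) and are rejected with an
    explicit message.
    """
    df = pd.read_csv(path, dtype={"study_id": str, "species": str})
    missing = [c for c in MEASUREMENT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"measurement table is missing columns: {missing}")
    if (df["statistic_kind"] == "p_value").any():
        bad = df.loc[df["statistic_kind"] == "p_value", "study_id"].tolist()
        raise ValueError(
            "records reporting only a p-value cannot be converted; supply a "
            f"test statistic or a pre-converted r for studies {bad}"
        )
    unknown = set(df["statistic_kind"]) - set(STATISTIC_KINDS)
    if unknown:
        raise ValueError(f"unsupported statistic kinds in table: {sorted(unknown)}")
    unknown_m = set(df["mtype"]) - set(MTYPES)
    if unknown_m:
        raise ValueError(f"unknown reproductive-success metrics: {sorted(unknown_m)}")
    df["territory_controlled"] = df["territory_controlled"].astype(bool)
    df["excluded"] = df["excluded"].astype(bool)
    return df


def load_traits(path: str | Path) -> pd.DataFrame:
    """Read the species-trait CSV (repertoire values are ';'-separated)."""
    df = pd.read_csv(path, dtype={"species": str})
    missing = [c for c in TRAIT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"traits table is missing columns: {missing}")
    df = df.copy()
    df["syll_rep_values"] = df["syll_rep_values"].apply(_parse_rep_values)
    return df


def _parse_rep_values(cell) -> list[float]:
    if cell is None or (isinstance(cell, float) and math.isnan(cell)) or cell == "":
        return []
    if isinstance(cell, (list, tuple)):
        vals = [float(v) for v in cell]
    else:
        vals = [float(tok) for tok in str(cell).split(";") if tok.strip()]
    if any(v <= 0 for v in vals):
        raise ValueError(f"repertoire sizes must be positive, got {vals}")
    return vals


def repertoire_summary_value(values: Sequence[float], rule: str = "median") -> float:
    """Summarise a species' literature-reported repertoire sizes."""
    if len(values) == 0:
        raise ValueError("species has no repertoire values")
    if rule == "median":
        return float(np.median(values))
    if rule == "min":
        return float(min(values))
    if rule == "max":
        return float(max(values))
    raise ValueError(f"unknown repertoire summary rule: {rule!r}")


def _convert_row(row: pd.Series, bias_correct: bool) -> EffectSize:
    df_val = row.get("df")
    if df_val is None or df_val == "" or (isinstance(df_val, float) and math.isnan(df_val)):
        df_int = None
    else:
        df_int = int(df_val)
    try:
        r = r_from_statistic(
            row["statistic_kind"],
            float(row["statistic_value"]),
            int(row["n"]),
            df=df_int,
            direction=str(row["effect_direction"]),
        )
    except ValueError as err:
        raise ValueError(
            f"record (study={row['study_id']}, species={row['species']}, "
            f"mtype={row['mtype']}): {err}"
        ) from err
    r = apply_direction(r, row["mtype"])
    return fisher_z(r, int(row["n"]), bias_correct=bias_correct)


def build_dataset(
    raw: pd.DataFrame,
    traits: pd.DataFrame,
    variant: str = "full",
    territory_mode: str = "uncontrolled",
    repertoire_summary: str = "median",
    bias_correct: bool = True,
) -> AnalysisDataset:
    """Apply exclusion rules and assemble one analysis dataset.

    Steps, in order: drop rows flagged ``excluded``; among (study, species,
    mtype) groups that carry both a territory-controlled and an uncontrolled
    measurement keep the one matching ``territory_mode``; restrict to species
    with repertoire data (``variant='repertoire'``) or with known song
    stability (``variant='stability'``); convert each remaining statistic to
    signed r and Fisher's Z; compute ``ln_syll_rep`` from the selected
    repertoire summary.
    """
    if variant not in ("full", "repertoire", "stability"):
        raise ValueError(f"unknown dataset variant: {variant!r}")
    if territory_mode not in ("uncontrolled", "territory_controlled"):
        raise ValueError(f"unknown territory mode: {territory_mode!r}")

    df = raw.loc[~raw["excluded"].astype(bool)].copy()

    dup = df.duplicated(subset=["study_id", "species", "mtype", "territory_controlled"])
    if dup.any():
        rows = df.loc[dup, ["study_id", "species", "mtype"]].to_dict("records")
        raise ValueError(f"duplicate (study, species, mtype, territory) rows: {rows}")

    # Resolve territory-controlled / uncontrolled pairs.
    want_controlled = territory_mode == "territory_controlled"
    keep_idx = []
    for _, grp in df.groupby(["study_id", "species", "mtype"], sort=False):
        if grp["territory_controlled"].nunique() == 2:
            keep_idx.extend(grp.index[grp["territory_controlled"] == want_controlled])
        else:
            keep_idx.extend(grp.index)
    df = df.loc[keep_idx]

    traits = traits.set_index("species") if "species" in traits.columns else traits
    has_rep = {
        sp for sp, row in traits.iterrows() if len(row["syll_rep_values"]) > 0
    }
    has_stab = {
        sp
        for sp, row in traits.iterrows()
        if row.get("stability") in ("stable", "plastic")
    }

    if variant == "repertoire":
        df = df.loc[df["species"].isin(has_rep)]
    elif variant == "stability":
        df = df.loc[df["species"].isin(has_stab)]
    if len(df) == 0:
        raise ValueError(f"variant={variant!r} leaves no qualifying measurements")

    effects = [_convert_row(row, bias_correct) for _, row in df.iterrows()]
    out = pd.DataFrame(
        {
            "study_id": df["study_id"].to_numpy(),
            "species": df["species"].to_numpy(),
            "mtype": df["mtype"].to_numpy(),
            "n": df["n"].astype(int).to_numpy(),
            "r": [e.r for e in effects],
            "z": [e.z for e in effects],
            "se": [e.se for e in effects],
        }
    )

    trait_rows = []
    for sp in out["species"].unique():
        ln_rep = np.nan
        stability = "unknown"
        if sp in traits.index:
            trow = traits.loc[sp]
            if len(trow["syll_rep_values"]) > 0:
                ln_rep = math.log(
                    repertoire_summary_value(trow["syll_rep_values"], repertoire_summary)
                )
            stability = trow.get("stability", "unknown")
            if stability not in ("stable", "plastic"):
                stability = "unknown"
        trait_rows.append({"species": sp, "ln_syll_rep": ln_rep, "stability": stability})
    trait_df = pd.DataFrame(trait_rows)

    out = out.merge(trait_df, on="species", how="left")
    return AnalysisDataset(
        data=out.reset_index(drop=True),
        traits=trait_df,
        variant=variant,
        territory_mode=territory_mode,
        repertoire_summary=repertoire_summary,
        bias_correct=bias_correct,
        raw=raw.copy(),
        raw_traits=traits.reset_index().copy(),
    )
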