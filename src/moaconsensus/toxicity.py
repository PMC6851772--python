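"""Acute toxicity coverage and effect-distribution summaries by consensus MOA.

Study-level effect concentrations (LC50/EC50, mg/L) are joined to consensus
MOA assignments and summarized as quartiles of log10(effect).  Narcosis is
baseline toxicity, so specifically acting chemicals are expected to sit at
lower effect concentrations; these summaries are how that potency ordering
is checked against empirical data, per trophic level (algae, invertebrate,
fish).

Distributions are computed over all study entries, not per-chemical
aggregates (an option collapses to per-chemical medians first for
sensitivity analysis).  Quartiles use linear interpolation between order
statistics (numpy's default, the "type 7" convention).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

TROPHIC_LEVELS = ("algae", "invertebrate", "fish")


@dataclass(frozen=True)
class AcuteWindow:
    """Qualifying endpoint types and duration window (hours) for one
    trophic level."""

    endpoints: frozenset[str]
    min_hours: float
    max_hours: float


@dataclass(frozen=True)
class AcuteConfig:
    """Acute-filter definition per trophic level.

    The fish window (24–96-h LC50, inclusive) is the anchor definition;
    the invertebrate and algal windows are package defaults chosen to match
    standard acute test guidelines (48–96-h daphnid immobilization, 48–96-h
    algal growth inhibition), with EC50 accepted alongside LC50 for the
    lower trophic levels.
    """

    windows: dict[str, AcuteWindow] = field(
        default_factory=lambda: {
            "fish": AcuteWindow(frozenset({"LC50"}), 24.0, 96.0),
            "invertebrate": AcuteWindow(frozenset({"LC50", "EC50"}), 24.0, 96.0),
            "algae": AcuteWindow(frozenset({"LC50", "EC50"}), 48.0, 96.0),
        }
    )


def filter_acute(studies: pd.DataFrame, config: AcuteConfig | None = None) -> pd.DataFrame:
    """Retain study records matching their trophic level's acute window."""
    config = config or AcuteConfig()
    if studies.empty:
        return studies.copy()
    tl = studies["trophic_level"].str.lower()
    unknown = set(tl.unique()) - set(config.windows)
    if unknown:
        raise ValueError(f"unknown trophic level(s): {sorted(unknown)}")
    keep = pd.Series(False, index=studies.index)
    for level, win in config.windows.items():
        mask = (
            (tl == level)
            & studies["endpoint"].str.upper().isin(win.endpoints)
            & (studies["duration_h"] >= win.min_hours)
            & (studies["duration_h"] <= win.max_hours)
        )
        keep |= mask
    return studies[keep].copy()


def _join(studies: pd.DataFrame, results: pd.DataFrame) -> pd.DataFrame:
    joined = studies.merge(results[["id", "consensus_moa"]], on="id", how="inner")
    orphans = len(studies) - len(joined)
    if orphans:
        logger.warning("excluded %d study record(s) referencing unknown chemicals", orphans)
    return joined


def coverage_stats(results: pd.DataFrame, studies: pd.DataFrame) -> pd.DataFrame:
    """Fraction of chemicals and of studies in each consensus MOA bin.

    Chemical coverage counts each classified chemical once; study coverage
    counts every study record joined to a classified chemical.  Both
    fraction columns sum to 1.
    """
    joined = _join(studies, results)
    chem = results.groupby("consensus_moa")["id"].size().rename("n_chemicals")
    stud = joined.groupby("consensus_moa").size().rename("n_studies")
    out = pd.concat([chem, stud], axis=1).fillna(0).astype(int).reset_index()
    out["frac_chemicals"] = out["n_chemicals"] / out["n_chemicals"].sum()
    out["frac_studies"] = (
        out["n_studies"] / out["n_studies"].sum() if out["n_studies"].sum() else 0.0
    )
    return out


def distribution_by_moa(
    studies: pd.DataFrame,
    results: pd.DataFrame,
    *,
    by_trophic_level: bool = False,
    per_chemical_median: bool = False,
) -> pd.DataFrame:
    """Quartile summary of log10(effect mg/L) per consensus MOA.

    One row per consensus MOA (optionally × trophic level) with n_studies,
    n_chemicals and min/Q1/median/Q3/max of log10(effect).  Groups with no
    records are omitted.  With ``per_chemical_median`` each chemical is
    first collapsed to its median log10 effect within the group.
    """
    joined = _join(studies, results)
    if (joined["effect_mg_L"] <= 0).any():
        raise ValueError("effect concentrations must be positive")
    joined["log10_effect"] = np.log10(joined["effect_mg_L"].astype(float))
    keys = ["consensus_moa"] + (["trophic_level"] if by_trophic_level else [])
    rows = []
    for key, grp in joined.groupby(keys, sort=True):
        key = key if isinstance(key, tuple) else (key,)
        values = (
            grp.groupby("id")["log10_effect"].median()
            if per_chemical_median
            else grp["log10_effect"]
        ).to_numpy()
        q1, med, q3 = np.percentile(values, [25, 50, 75])
        rows.append(
            dict(
                zip(keys, key),
                n_studies=len(grp),
                n_chemicals=grp["id"].nunique(),
                min=values.min(),
                q1=q1,
                median=med,
                q3=q3,
                max=values.max(),
            )
        )
    return pd.DataFrame(rows)


def complete_acute_subset(studies: pd.DataFrame) -> list[str]:
    """Chemicals with at least one qualifying acute record in each of the
    three trophic levels (algae, invertebrate, fish).

    ``studies`` should already be acute-filtered.
    """
    if studies.empty:
        return []
    tl = studies.assign(trophic_level=studies["trophic_level"].str.lower())
    counts = tl.groupby("id")["trophic_level"].nunique()
    complete = counts[counts == len(TROPHIC_LEVELS)].index
    return sorted(complete)
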