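"""Germination indices and their drought/control relative forms.

Per trial unit:

* GR (germination rate, %)   = cumulative germinated by the final day / seeds × 100
* GE (germination energy, %) = cumulative germinated by the energy day / seeds × 100
* GI (germination index)     = Σ_t (seeds newly germinated on day t) / t

Per genotype×environment the relative indices are ratios of replicate MEANS,
drought over control: RGR = RD/RC, RGE = ED/EC, RGI = ID/IC.  A zero control
mean makes the ratio undefined; the row is set to missing with a warning and
excluded from downstream min–max scans.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .datatypes import GerminationTrial

__all__ = [
    "compute_gr",
    "compute_ge",
    "compute_gi",
    "trait_table",
    "relative_indices",
    "replicate_relative_indices",
    "TRAITS",
    "RELATIVE_TRAITS",
]

TRAITS = ("GR", "GE", "GI")
RELATIVE_TRAITS = ("RGR", "RGE", "RGI")


def compute_gr(trial: GerminationTrial) -> float:
    """Germination rate (%): all seeds germinated within the trial window."""
    if trial.total_seeds <= 0:
        raise ValueError("total_seeds must be positive")
    return trial.total_germinated / trial.total_seeds * 100.0


def compute_ge(trial: GerminationTrial, energy_day: int = 4) -> float:
    """Germination energy (%): cumulative germination through ``energy_day``."""
    if trial.total_seeds <= 0:
        raise ValueError("total_seeds must be positive")
    if energy_day > trial.n_days:
        raise ValueError("energy_day exceeds the number of recorded days")
    return float(trial.daily_counts[:energy_day].sum()) / trial.total_seeds * 100.0


def compute_gi(trial: GerminationTrial) -> float:
    """Germination index: Σ (newly germinated on day t)/t, weighting early days."""
    days = np.arange(1, trial.n_days + 1)
    return float((trial.daily_counts / days).sum())


def _day_columns(trials: pd.DataFrame) -> list[str]:
    cols = [c for c in trials.columns if c.startswith("day") and c[3:].isdigit()]
    return sorted(cols, key=lambda c: int(c[3:]))


def trait_table(trials: pd.DataFrame, energy_day: int = 4) -> pd.DataFrame:
    """Per-unit GR/GE/GI from a trial table (vectorised form of the above)."""
    day_cols = _day_columns(trials)
    if energy_day > len(day_cols):
        raise ValueError("energy_day exceeds the number of recorded days")
    counts = trials[day_cols].to_numpy(float)
    total = trials["total_seeds"].to_numpy(float)
    if (total <= 0).any():
        raise ValueError("total_seeds must be positive")
    if (counts.sum(axis=1) > total).any():
        raise ValueError("more germinated seeds than planted in some unit")
    out = trials[["genotype_id", "environment", "treatment", "replicate"]].copy()
    out["GR"] = counts.sum(axis=1) / total * 100.0
    out["GE"] = counts[:, :energy_day].sum(axis=1) / total * 100.0
    out["GI"] = (counts / np.arange(1, len(day_cols) + 1)).sum(axis=1)
    return out


def relative_indices(traits: pd.DataFrame) -> pd.DataFrame:
    """Genotype×environment relative indices from per-unit GR/GE/GI.

    Replicate means are taken per treatment arm first; each relative index is
    the drought mean divided by the control mean (ratio-of-means).  Returns
    one row per genotype×environment with the six arm means and RGR/RGE/RGI;
    ratios with a zero control mean are NaN (with a warning).
    """
    means = (
        traits.groupby(["genotype_id", "environment", "treatment"], sort=True)[
            list(TRAITS)
        ]
        .mean()
        .unstack("treatment")
    )
    if not {"control", "drought"} <= set(means.columns.get_level_values(1)):
        raise ValueError("both control and drought arms are required")
    out = pd.DataFrame(index=means.index)
    n_zero = 0
    for trait, rel in zip(TRAITS, RELATIVE_TRAITS):
        c = means[(trait, "control")]
        d = means[(trait, "drought")]
        out[f"{trait}_control"] = c
        out[f"{trait}_drought"] = d
        zero = c == 0
        n_zero += int(zero.sum())
        ratio = d / c.where(~zero)
        out[rel] = ratio
    if n_zero:
        warnings.warn(
            f"{n_zero} genotype×environment control means were zero; "
            "relative indices set to missing",
            stacklevel=2,
        )
    return out.reset_index()


def replicate_relative_indices(traits: pd.DataFrame) -> pd.DataFrame:
    """Replicate-level relative indices for the variance analysis.

    The screening-level relative index is a ratio of replicate means and has
    no within-cell replication; for the genotype×environment ANOVA each
    drought replicate is instead divided by its genotype×environment control
    mean, preserving r replicates per cell.  Zero control means give missing
    rows (warned).
    """
    ctrl = (
        traits[traits["treatment"] == "control"]
        .groupby(["genotype_id", "environment"])[list(TRAITS)]
        .mean()
        .rename(columns={t: f"{t}_cmean" for t in TRAITS})
    )
    d = traits[traits["treatment"] == "drought"].merge(
        ctrl, on=["genotype_id", "environment"], how="left"
    )
    n_zero = 0
    out = d[["genotype_id", "environment", "replicate"]].copy()
    for trait, rel in zip(TRAITS, RELATIVE_TRAITS):
        cm = d[f"{trait}_cmean"]
        zero = cm == 0
        n_zero += int(zero.sum())
        out[rel] = d[trait] / cm.where(~zero)
    if n_zero:
        warnings.warn(
            f"{n_zero} drought replicates had zero control means; set to missing",
            stacklevel=2,
        )
    return out
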