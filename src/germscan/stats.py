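"""Descriptive statistics, balanced two-way ANOVA, variance components,
broad-sense heritability and trait correlations.

The variance analysis follows the classical balanced genotype×environment
model with replication::

    y_ier = μ + g_i + e_e + (ge)_ie + ε_ier

Sums of squares decompose exactly; variance components come from the
expected mean squares (method of moments)::

    σ̂²   = MS_res
    σ̂ge² = (MS_GxE − MS_res) / r
    σ̂g²  = (MS_G − MS_GxE) / (n·r)

with negative estimates clipped to zero, and broad-sense heritability::

    h² = σg² / (σg² + σge²/n + σ²/(n·r))

for n environments and r replicates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "describe",
    "describe_table",
    "anova_two_way",
    "VarianceComponents",
    "variance_components",
    "heritability",
    "correlate",
]


def describe(values) -> pd.Series:
    """Max, min, range, mean, sample SD, CV (%), skewness and excess kurtosis.

    Skewness and kurtosis use the bias-adjusted sample formulas (the
    spreadsheet/SPSS convention). CV is missing when the mean is zero.
    """
    x = np.asarray(values, dtype=float)
    x = x[~np.isnan(x)]
    if x.size < 2:
        raise ValueError("describe needs at least 2 values")
    sd = float(np.std(x, ddof=1))
    mean = float(np.mean(x))
    cv = sd / mean * 100.0 if mean != 0 else np.nan
    if sd == 0:
        skew = kurt = 0.0
        cv = 0.0 if mean != 0 else np.nan
    else:
        skew = float(sps.skew(x, bias=False))
        kurt = float(sps.kurtosis(x, bias=False, fisher=True))
    return pd.Series(
        {
            "max": float(np.max(x)),
            "min": float(np.min(x)),
            "range": float(np.max(x) - np.min(x)),
            "mean": mean,
            "sd": sd,
            "cv": cv,
            "skewness": skew,
            "kurtosis": kurt,
            "n": int(x.size),
        }
    )


def describe_table(df: pd.DataFrame, value_cols, by) -> pd.DataFrame:
    """``describe`` per value column within each group of ``by`` columns."""
    rows = []
    for keys, sub in df.groupby(list(by), sort=True):
        keys = keys if isinstance(keys, tuple) else (keys,)
        for col in value_cols:
            s = describe(sub[col].dropna())
            rows.append(dict(zip(by, keys)) | {"trait": col} | s.to_dict())
    return pd.DataFrame(rows)


def anova_two_way(
    df: pd.DataFrame,
    value: str = "value",
    genotype: str = "genotype_id",
    environment: str = "environment",
) -> pd.DataFrame:
    """Balanced two-way ANOVA with replication (closed-form sums of squares).

    Returns a table with rows Genotype, Environment, GxE, Residual, Total and
    columns DF/SS/MS/F/P, with the design sizes in ``attrs`` (``n_env``,
    ``n_rep``).  Requires a complete balanced layout (equal replicates per
    cell) and at least two levels per factor and two replicates.
    """
    sub = df[[genotype, environment, value]].dropna()
    cells = sub.groupby([genotype, environment])[value].agg(["count", "mean"])
    counts = cells["count"].unique()
    n_g = sub[genotype].nunique()
    n_e = sub[environment].nunique()
    if n_g < 2 or n_e < 2:
        raise ValueError("need >= 2 genotypes and >= 2 environments")
    if len(counts) != 1 or len(cells) != n_g * n_e:
        raise ValueError("unbalanced design: equal replication per cell required")
    r = int(counts[0])
    if r < 2:
        raise ValueError("need >= 2 replicates per cell for a residual term")

    y = sub[value].to_numpy(float)
    grand = y.mean()
    gm = sub.groupby(genotype)[value].mean()
    em = sub.groupby(environment)[value].mean()
    cm = cells["mean"].unstack(environment)

    ss_g = n_e * r * float(((gm - grand) ** 2).sum())
    ss_e = n_g * r * float(((em - grand) ** 2).sum())
    interaction = cm.sub(gm, axis=0).sub(em, axis=1) + grand
    ss_ge = r * float((interaction**2).to_numpy().sum())
    ss_tot = float(((y - grand) ** 2).sum())
    ss_res = ss_tot - ss_g - ss_e - ss_ge

    df_g, df_e = n_g - 1, n_e - 1
    df_ge = df_g * df_e
    df_res = n_g * n_e * (r - 1)
    rows = []
    ms_res = ss_res / df_res
    for name, ss, dof in (
        ("Genotype", ss_g, df_g),
        ("Environment", ss_e, df_e),
        ("GxE", ss_ge, df_ge),
    ):
        ms = ss / dof
        f = ms / ms_res if ms_res > 0 else np.inf
        p = float(sps.f.sf(f, dof, df_res)) if np.isfinite(f) else 0.0
        rows.append({"source": name, "DF": dof, "SS": ss, "MS": ms, "F": f, "P": p})
    rows.append(
        {"source": "Residual", "DF": df_res, "SS": ss_res, "MS": ms_res,
         "F": np.nan, "P": np.nan}
    )
    rows.append(
        {"source": "Total", "DF": len(y) - 1, "SS": ss_tot, "MS": np.nan,
         "F": np.nan, "P": np.nan}
    )
    table = pd.DataFrame(rows).set_index("source")
    table.attrs["n_env"] = n_e
    table.attrs["n_rep"] = r
    table.attrs["n_genotypes"] = n_g
    return table


@dataclass
class VarianceComponents:
    sigma_g2: float
    sigma_ge2: float
    sigma_e2: float
    n_env: int
    n_rep: int
    clipped: tuple[str, ...] = ()

    @property
    def heritability(self) -> float:
        return heritability(
            self.sigma_g2, self.sigma_ge2, self.sigma_e2, self.n_env, self.n_rep
        )


def variance_components(anova: pd.DataFrame) -> VarianceComponents:
    """Expected-mean-squares (method-of-moments) components from a balanced ANOVA."""
    n = int(anova.attrs["n_env"])
    r = int(anova.attrs["n_rep"])
    ms_g = float(anova.loc["Genotype", "MS"])
    ms_ge = float(anova.loc["GxE", "MS"])
    ms_res = float(anova.loc["Residual", "MS"])
    sigma_e2 = ms_res
    sigma_ge2 = (ms_ge - ms_res) / r
    sigma_g2 = (ms_g - ms_ge) / (n * r)
    clipped = []
    if sigma_ge2 < 0:
        sigma_ge2 = 0.0
        clipped.append("sigma_ge2")
    if sigma_g2 < 0:
        sigma_g2 = 0.0
        clipped.append("sigma_g2")
    if clipped:
        warnings.warn(
            f"negative variance components clipped to 0: {', '.join(clipped)}",
            stacklevel=2,
        )
    return VarianceComponents(
        sigma_g2=sigma_g2,
        sigma_ge2=sigma_ge2,
        sigma_e2=sigma_e2,
        n_env=n,
        n_rep=r,
        clipped=tuple(clipped),
    )


def heritability(
    sigma_g2: float, sigma_ge2: float, sigma_e2: float, n_env: int, n_rep: int
) -> float:
    """Broad-sense heritability h² = σg²/(σg² + σge²/n + σ²/(n·r)), in [0, 1]."""
    if min(sigma_g2, sigma_ge2, sigma_e2) < 0:
        raise ValueError("variance components must be >= 0")
    if n_env < 1 or n_rep < 1:
        raise ValueError("n_env and n_rep must be >= 1")
    denom = sigma_g2 + sigma_ge2 / n_env + sigma_e2 / (n_env * n_rep)
    if denom == 0:
        return float("nan")
    return sigma_g2 / denom


def correlate(df: pd.DataFrame, cols) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise Pearson correlations with two-sided p-values.

    Pairs use their complete observations; fewer than 3 pairs or a
    zero-variance variable raises.
    """
    cols = list(cols)
    r = pd.DataFrame(np.eye(len(cols)), index=cols, columns=cols)
    p = pd.DataFrame(np.zeros((len(cols), len(cols))), index=cols, columns=cols)
    np.fill_diagonal(p.values, 0.0)
    for i, a in enumerate(cols):
        for j in range(i + 1, len(cols)):
            b = cols[j]
            sub = df[[a, b]].dropna()
            if len(sub) < 3:
                raise ValueError(f"fewer than 3 complete pairs for {a} vs {b}")
            if sub[a].std() == 0 or sub[b].std() == 0:
                raise ValueError(f"zero variance in {a} or {b}")
            res = sps.pearsonr(sub[a], sub[b])
            r.loc[a, b] = r.loc[b, a] = res.statistic
            p.loc[a, b] = p.loc[b, a] = res.pvalue
    return r, p
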