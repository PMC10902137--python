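"""Membership-function drought scoring and five-grade germplasm screening.

For each genotype i and trait j within an environment:

* drought-tolerance coefficient  DTC_ij = ȳ_ij(drought)/ȳ_ij(control) × 100
* subordinate (membership) value F_ij = (DTC_ij − min_i DTC_ij)/(max_i − min_i)
* ASFV_i = mean over the three traits of F_ij

The observed ASFV range is cut into five equal intervals, labelled (low to
high) HDS, DS, MDT, DT, HDT; a higher ASFV means stronger drought tolerance.
Min–max normalisation makes F invariant to positive affine transforms of the
trait, so feeding DTC (×100) or the raw relative index gives identical
scores.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .indices import RELATIVE_TRAITS

__all__ = [
    "GRADE_LABELS",
    "GradeScheme",
    "ScreeningResult",
    "compute_dtc",
    "compute_sfv",
    "compute_asfv",
    "build_grade_scheme",
    "assign_grades",
    "score_table",
    "screen_tolerant",
]

# low → high tolerance
GRADE_LABELS = ("HDS", "DS", "MDT", "DT", "HDT")


def compute_dtc(treatment_mean, control_mean):
    """Drought-tolerance coefficient: treatment/control mean × 100 (NaN for zero control)."""
    t = np.asarray(treatment_mean, dtype=float)
    c = np.asarray(control_mean, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(c == 0, np.nan, t / c * 100.0)
    if np.isnan(out).any() and not np.isnan(c[np.isnan(out)]).all():
        warnings.warn("zero control means produced missing DTC values", stacklevel=2)
    return out if out.ndim else float(out)


def compute_sfv(dtc: np.ndarray | pd.Series) -> np.ndarray:
    """Min–max membership value of a DTC column across genotypes.

    Missing values propagate. If every non-missing value is identical the
    trait carries no ranking information; all values are set to 0.5 with a
    warning. Fewer than two non-missing values is an error.
    """
    x = np.asarray(dtc, dtype=float)
    ok = ~np.isnan(x)
    if ok.sum() < 2:
        raise ValueError("need at least 2 non-missing values for min-max scaling")
    lo, hi = np.nanmin(x), np.nanmax(x)
    if hi == lo:
        warnings.warn(
            "all values identical; membership values set to 0.5", stacklevel=2
        )
        out = np.full_like(x, np.nan)
        out[ok] = 0.5
        return out
    return (x - lo) / (hi - lo)


def compute_asfv(sfv: pd.DataFrame | np.ndarray) -> np.ndarray:
    """Average membership value across the trait columns (NaN if any trait missing)."""
    arr = np.asarray(sfv, dtype=float)
    out = arr.mean(axis=1)
    n_missing = int(np.isnan(out).sum())
    if n_missing:
        warnings.warn(
            f"{n_missing} genotypes have a missing membership value; "
            "their ASFV is missing and they are excluded from grading",
            stacklevel=2,
        )
    return out


@dataclass
class GradeScheme:
    """Equal-interval grade boundaries over an observed ASFV range.

    Intervals are [min + (k−1)w, min + kw) with the top interval closed;
    boundary values therefore belong to the upper grade. ``boundaries`` holds
    the 4 interior cut points at full precision; display rounding is separate.
    """

    vmin: float
    vmax: float
    boundaries: tuple[float, ...]
    labels: tuple[str, ...] = GRADE_LABELS

    def rounded(self, ndigits: int = 2) -> list[float]:
        return [round(b, ndigits) for b in self.boundaries]

    def to_dict(self) -> dict:
        return {
            "min": self.vmin,
            "max": self.vmax,
            "boundaries": list(self.boundaries),
            "boundaries_rounded": self.rounded(),
            "labels": list(self.labels),
        }


def build_grade_scheme(asfv, n_classes: int = 5) -> GradeScheme:
    """Cut the observed ASFV range into ``n_classes`` equal intervals."""
    x = np.asarray(asfv, dtype=float)
    x = x[~np.isnan(x)]
    if x.size < 2 or np.nanmax(x) == np.nanmin(x):
        raise ValueError("grade scheme needs >= 2 distinct ASFV values")
    lo, hi = float(x.min()), float(x.max())
    w = (hi - lo) / n_classes
    boundaries = tuple(lo + k * w for k in range(1, n_classes))
    if n_classes != len(GRADE_LABELS):
        labels = tuple(f"C{k + 1}" for k in range(n_classes))
    else:
        labels = GRADE_LABELS
    return GradeScheme(vmin=lo, vmax=hi, boundaries=boundaries, labels=labels)


def assign_grades(asfv, scheme: GradeScheme) -> np.ndarray:
    """Map ASFV values to grade labels under ``scheme``.

    Values outside the scheme's range (possible when a scheme is applied to
    new material) are clamped to the extreme grades with a warning; missing
    values stay missing.
    """
    x = np.asarray(asfv, dtype=float)
    ok = ~np.isnan(x)
    if ((x[ok] < scheme.vmin) | (x[ok] > scheme.vmax)).any():
        warnings.warn("ASFV outside scheme range; clamped to extreme grades",
                      stacklevel=2)
    idx = np.searchsorted(np.asarray(scheme.boundaries), x[ok], side="right")
    out = np.full(x.shape, None, dtype=object)
    out[ok] = np.asarray(scheme.labels, dtype=object)[idx]
    return out


def score_table(
    rel: pd.DataFrame,
    traits: tuple[str, ...] = RELATIVE_TRAITS,
    n_classes: int = 5,
) -> tuple[pd.DataFrame, dict[str, GradeScheme]]:
    """Full scoring of a relative-index table, independently per environment.

    Returns the score table (genotype, environment, DTC/SFV per trait, ASFV,
    grade) and the per-environment grade schemes.
    """
    out_frames = []
    schemes: dict[str, GradeScheme] = {}
    for env, sub in rel.groupby("environment", sort=True):
        block = sub[["genotype_id"]].copy()
        block["environment"] = env
        sfv_cols = []
        for t in traits:
            base = t[1:] if t.startswith("R") else t  # RGR → GR arm means
            cm = sub.get(f"{base}_control")
            dm = sub.get(f"{base}_drought")
            if cm is not None and dm is not None:
                dtc = compute_dtc(dm.to_numpy(), cm.to_numpy())
            else:
                dtc = sub[t].to_numpy(float) * 100.0
            block[f"DTC_{t}"] = dtc
            block[f"SFV_{t}"] = compute_sfv(dtc)
            sfv_cols.append(f"SFV_{t}")
        block["ASFV"] = compute_asfv(block[sfv_cols])
        scheme = build_grade_scheme(block["ASFV"], n_classes=n_classes)
        block["grade"] = assign_grades(block["ASFV"], scheme)
        schemes[env] = scheme
        out_frames.append(block)
    return pd.concat(out_frames, ignore_index=True), schemes


@dataclass
class ScreeningResult:
    """Per-environment lists of genotypes at the target grade, with set summaries."""

    target_grade: str
    per_environment: dict[str, list[str]]
    union: list[str]
    intersection: list[str]
    population_size: int
    counts: dict[str, int] = field(init=False)
    percentages: dict[str, float] = field(init=False)

    def __post_init__(self) -> None:
        self.counts = {env: len(v) for env, v in self.per_environment.items()}
        self.counts["union"] = len(self.union)
        self.counts["intersection"] = len(self.intersection)
        self.percentages = {
            k: 100.0 * v / self.population_size for k, v in self.counts.items()
        }

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "target_grade": self.target_grade,
            "population_size": self.population_size,
            "per_environment": self.per_environment,
            "union": self.union,
            "intersection": self.intersection,
            "counts": self.counts,
            "percentages": self.percentages,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text


def screen_tolerant(scores: pd.DataFrame, target_grade: str = "HDT") -> ScreeningResult:
    """Select genotypes graded ``target_grade``, per environment and combined."""
    per_env: dict[str, list[str]] = {}
    for env, sub in scores.groupby("environment", sort=True):
        per_env[env] = sorted(sub.loc[sub["grade"] == target_grade, "genotype_id"])
    sets = [set(v) for v in per_env.values()]
    union = sorted(set().union(*sets)) if sets else []
    inter = sorted(set.intersection(*sets)) if sets else []
    return ScreeningResult(
        target_grade=target_grade,
        per_environment=per_env,
        union=union,
        intersection=inter,
        population_size=scores["genotype_id"].nunique(),
    )
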