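"""Core in-memory containers shared across the pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["GerminationTrial", "GenotypeMatrix", "TrialSet"]


@dataclass
class GerminationTrial:
    """Daily germination counts for one genotype×environment×treatment×replicate unit.

    ``daily_counts[t]`` is the number of seeds newly germinated on day ``t+1``.
    """

    genotype_id: str
    environment_id: str
    treatment: str  # "control" | "drought"
    replicate: int
    daily_counts: np.ndarray
    total_seeds: int

    def __post_init__(self) -> None:
        self.daily_counts = np.asarray(self.daily_counts, dtype=int)
        if (self.daily_counts < 0).any():
            raise ValueError("daily counts must be non-negative")
        if int(self.daily_counts.sum()) > self.total_seeds:
            raise ValueError("more germinated seeds than planted")
        if self.treatment not in ("control", "drought"):
            raise ValueError(f"unknown treatment {self.treatment!r}")

    @property
    def n_days(self) -> int:
        return len(self.daily_counts)

    @property
    def total_germinated(self) -> int:
        return int(self.daily_counts.sum())


@dataclass
class GenotypeMatrix:
    """Biallelic SNP dosages (alternate-allele counts in {0,1,2}) for a panel.

    Rows of ``dosage`` are genotypes, columns SNPs. Positions are 1-based and
    SNP ids follow the ``S{chrom:02d}_{position}`` convention.
    """

    genotype_ids: list[str]
    snp_ids: list[str]
    chrom: np.ndarray
    pos: np.ndarray
    ref: list[str]
    alt: list[str]
    dosage: np.ndarray

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage)
        n, m = self.dosage.shape
        if n != len(self.genotype_ids) or m != len(self.snp_ids):
            raise ValueError("dosage dimensions inconsistent with ids")
        if not np.isin(self.dosage, (0, 1, 2)).all():
            raise ValueError("dosages must be in {0,1,2}")

    @property
    def n_genotypes(self) -> int:
        return self.dosage.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosage.shape[1]

    def allele_freq(self) -> np.ndarray:
        """Alternate-allele frequency per SNP."""
        return self.dosage.mean(axis=0) / 2.0

    def maf(self) -> np.ndarray:
        p = self.allele_freq()
        return np.minimum(p, 1.0 - p)

    def filter_maf(self, min_maf: float = 0.05) -> "GenotypeMatrix":
        """Drop SNPs with minor-allele frequency below ``min_maf``."""
        keep = self.maf() >= min_maf
        return self.subset(np.flatnonzero(keep))

    def subset(self, snp_idx: np.ndarray) -> "GenotypeMatrix":
        snp_idx = np.asarray(snp_idx)
        return GenotypeMatrix(
            genotype_ids=list(self.genotype_ids),
            snp_ids=[self.snp_ids[j] for j in snp_idx],
            chrom=self.chrom[snp_idx],
            pos=self.pos[snp_idx],
            ref=[self.ref[j] for j in snp_idx],
            alt=[self.alt[j] for j in snp_idx],
            dosage=self.dosage[:, snp_idx],
        )

    def snp_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"snp_id": self.snp_ids, "chrom": self.chrom, "pos": self.pos,
             "ref": self.ref, "alt": self.alt, "maf": self.maf()}
        )


@dataclass
class TrialSet:
    """A full simulated experiment: trials plus the generating truth.

    ``trials`` has one row per unit with columns ``genotype_id, environment,
    treatment, replicate, total_seeds, day1..dayN``.  ``liability`` records
    the true per-genotype genetic value and per-genotype×environment
    liability used to generate the drought counts — available for power and
    enrichment checks, never consumed by the analysis stages.
    """

    trials: pd.DataFrame
    liability: pd.DataFrame
    config: "object" = field(repr=False, default=None)
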