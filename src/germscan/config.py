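"""Configuration objects for the synthetic germination-trial simulator.

The defaults describe the screening design this package targets: a natural
germplasm panel of 264 genotypes phenotyped in 2 environments under a
control and an osmotic-stress (15% PEG-6000) treatment, 3 replicates of 50
seeds each, with newly germinated seeds counted daily for 7 days and
germination energy read on day 4.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

__all__ = ["SimulationConfig"]


@dataclass
class SimulationConfig:
    """Parameters of the synthetic trial and genotype generator.

    Genetic signal is modelled on a latent drought-response liability:
    ``liability = polygenic + causal-SNP dosage effects + G×E + unit noise``.
    Liability shifts the drought-treatment germination probability through a
    logistic link and advances the germination-day distribution; control
    units germinate with ``control_germ_prob`` independent of liability.

    Parameters
    ----------
    n_genotypes, n_environments, n_replicates
        Panel size and trial design (defaults 264 × 2 × 3).
    seeds_per_replicate
        Seeds sown per replicate square (default 50).
    n_days
        Daily counts recorded per unit; day ``n_days`` closes the trial.
    energy_day
        Day on which germination energy is read (default 4).
    var_genotype, var_gxe, var_residual
        Variances of the polygenic, genotype×environment and per-unit
        components of the latent liability (unitless, liability scale).
    control_germ_prob
        Per-seed germination probability under control, in (0, 1].
    drought_germ_prob
        Baseline drought-treatment germination probability for a genotype of
        average (zero) liability; the logistic link moves around its logit.
    n_snps, maf_range, n_causal, causal_effect_sizes
        Genotype-panel shape: independent biallelic SNPs with allele
        frequencies uniform in ``maf_range``; ``n_causal`` of them carry an
        additive liability effect per alternate allele.
    day_mean_control, day_mean_drought, day_liability_slope
        Mean extra days to germination (beyond day 1) under control and for
        an average genotype under drought, and how much one liability unit
        advances drought germination (days per unit).
    rng_seed
        Mandatory seed; identical config + seed reproduces output exactly.
    strict
        If True, raise instead of warn when drought probabilities saturate.
    """

    n_genotypes: int = 264
    n_environments: int = 2
    n_replicates: int = 3
    seeds_per_replicate: int = 50
    n_days: int = 7
    energy_day: int = 4
    var_genotype: float = 0.4
    var_gxe: float = 0.3
    var_residual: float = 2.0
    control_germ_prob: float = 0.885
    drought_germ_prob: float = 0.5
    n_snps: int = 2000
    maf_range: tuple[float, float] = (0.05, 0.5)
    n_causal: int = 5
    causal_effect_sizes: float | tuple[float, ...] = 0.4
    day_mean_control: float = 1.0
    day_mean_drought: float = 2.0
    day_liability_slope: float = 0.6
    rng_seed: int = 0
    strict: bool = False

    def __post_init__(self) -> None:
        for name in ("n_genotypes", "n_environments", "n_replicates",
                     "seeds_per_replicate", "n_days", "energy_day"):
            if int(getattr(self, name)) < 1:
                raise ValueError(f"{name} must be >= 1")
        for name in ("var_genotype", "var_gxe", "var_residual"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 < self.control_germ_prob <= 1.0:
            raise ValueError("control_germ_prob must be in (0, 1]")
        if not 0.0 < self.drought_germ_prob < 1.0:
            raise ValueError("drought_germ_prob must be in (0, 1)")
        if self.energy_day > self.n_days:
            raise ValueError("energy_day must be <= n_days")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must satisfy 0 < low <= high <= 0.5")
        if self.n_causal > self.n_snps:
            raise ValueError("n_causal cannot exceed n_snps")
        if self.n_causal < 0 or self.n_snps < 0:
            raise ValueError("n_snps and n_causal must be >= 0")

    @property
    def causal_effects(self) -> list[float]:
        """Per-causal-SNP additive effects, broadcast from a scalar if needed."""
        eff = self.causal_effect_sizes
        if isinstance(eff, (int, float)):
            return [float(eff)] * self.n_causal
        eff = list(eff)
        if len(eff) != self.n_causal:
            raise ValueError("causal_effect_sizes length must equal n_causal")
        return [float(x) for x in eff]

    def to_dict(self) -> dict:
        d = asdict(self)
        d["maf_range"] = list(self.maf_range)
        if not isinstance(d["causal_effect_sizes"], (int, float)):
            d["causal_effect_sizes"] = list(d["causal_effect_sizes"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        if "maf_range" in d:
            d["maf_range"] = tuple(d["maf_range"])
        if "causal_effect_sizes" in d and isinstance(d["causal_effect_sizes"], list):
            d["causal_effect_sizes"] = tuple(d["causal_effect_sizes"])
        return cls(**d)

    @classmethod
    def from_file(cls, path: str | Path) -> "SimulationConfig":
        """Load a config from YAML or JSON; ``rng_seed`` must be present."""
        text = Path(path).read_text()
        data = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
        if "rng_seed" not in data:
            raise ValueError("config file must set rng_seed")
        return cls.from_dict(data)

    def save(self, path: str | Path) -> None:
        path = Path(path)
        if path.suffix == ".json":
            path.write_text(json.dumps(self.to_dict(), indent=2))
        else:
            path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))
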