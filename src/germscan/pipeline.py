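"""End-to-end orchestration: simulate → indices → scoring → stats → GWAS.

Every stage writes self-describing delimited text under the output
directory and can be re-run in isolation: a stage whose inputs are not in
memory reloads them from the files a previous run left behind.  Identical
config + seed reproduces byte-identical tabular outputs.
"""

from __future__ import annotations

import json
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .association import kinship, mlm_scan, significant_snps, manhattan_plot
from .config import SimulationConfig
from .datatypes import GenotypeMatrix
from .indices import (RELATIVE_TRAITS, relative_indices,
                      replicate_relative_indices, trait_table)
from .scoring import score_table, screen_tolerant
from .simulate import (read_dosage, read_trials, simulate_genotypes,
                       simulate_trials, write_dosage, write_trials, write_vcf)
from .stats import anova_two_way, correlate, describe_table, variance_components

__all__ = ["PipelineConfig", "RunReport", "run_pipeline", "ALL_STAGES"]

ALL_STAGES = ("simulate", "indices", "score", "stats", "gwas")


@dataclass
class PipelineConfig:
    """Configuration of a full screening run."""

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    outdir: str | Path = "germscan_out"
    stages: tuple[str, ...] = ALL_STAGES
    maf_min: float = 0.05
    significance_threshold: float = 5.0
    n_grades: int = 5
    gwas_traits: tuple[str, ...] = RELATIVE_TRAITS
    make_plots: bool = True

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text())
        sim = SimulationConfig.from_dict(data.pop("simulation", {}))
        for key in ("stages", "gwas_traits"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(simulation=sim, **data)

    @classmethod
    def demo(cls, outdir: str | Path = "germscan_demo", seed: int = 0) -> "PipelineConfig":
        """Small seeded profile (50 genotypes, 200 SNPs) for smoke runs."""
        sim = SimulationConfig(
            n_genotypes=50, n_snps=200, n_causal=2, rng_seed=seed
        )
        return cls(simulation=sim, outdir=outdir)


@dataclass
class RunReport:
    """Per-stage row counts, data-quality warnings and provenance of one run."""

    config: dict
    version: str = __version__
    stages: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)
    elapsed_seconds: float = 0.0

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=2, default=str))


def _sorted_trials(trials: pd.DataFrame) -> pd.DataFrame:
    return trials.sort_values(
        ["environment", "genotype_id", "treatment", "replicate"]
    ).reset_index(drop=True)


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Execute the requested stages in dependency order and write all outputs."""
    t0 = time.time()
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    report = RunReport(config={
        "simulation": config.simulation.to_dict(),
        "outdir": str(config.outdir),
        "stages": list(config.stages),
        "maf_min": config.maf_min,
        "significance_threshold": config.significance_threshold,
        "n_grades": config.n_grades,
        "gwas_traits": list(config.gwas_traits),
    })
    stages = [s for s in ALL_STAGES if s in config.stages]
    if not stages:
        raise ValueError("no recognised stages requested")

    trials = genotypes = traits = rel = None
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        for stage in stages:
            try:
                if stage == "simulate":
                    genotypes, registry = simulate_genotypes(config.simulation)
                    ts = simulate_trials(config.simulation, genotypes, registry)
                    trials = _sorted_trials(ts.trials)
                    write_trials(trials, out / "trials.tsv")
                    write_vcf(genotypes, out / "genotypes.vcf")
                    write_dosage(genotypes, out / "dosages.tsv")
                    ts.liability.to_csv(out / "liability.tsv", sep="\t", index=False)
                    registry.to_csv(out / "causal_snps.tsv", sep="\t", index=False)
                    report.stages["simulate"] = {
                        "trials": len(trials), "snps": genotypes.n_snps,
                        "causal": len(registry),
                    }
                elif stage == "indices":
                    if trials is None:
                        trials = read_trials(out / "trials.tsv")
                    traits = trait_table(trials, energy_day=config.simulation.energy_day)
                    rel = relative_indices(traits)
                    traits.to_csv(out / "traits_units.tsv", sep="\t", index=False)
                    rel.to_csv(out / "relative_indices.tsv", sep="\t", index=False)
                    report.stages["indices"] = {"units": len(traits), "rows": len(rel)}
                elif stage == "score":
                    if rel is None:
                        rel = pd.read_csv(out / "relative_indices.tsv", sep="\t")
                    scores, schemes = score_table(rel, n_classes=config.n_grades)
                    scores.to_csv(out / "scores.tsv", sep="\t", index=False)
                    screening = screen_tolerant(scores)
                    payload = json.loads(screening.to_json())
                    payload["grade_schemes"] = {
                        env: s.to_dict() for env, s in schemes.items()
                    }
                    (out / "screening.json").write_text(json.dumps(payload, indent=2))
                    report.stages["score"] = {
                        "genotypes": len(scores), "hdt_union": len(screening.union),
                    }
                elif stage == "stats":
                    if traits is None:
                        traits = pd.read_csv(out / "traits_units.tsv", sep="\t")
                    if rel is None:
                        rel = pd.read_csv(out / "relative_indices.tsv", sep="\t")
                    desc = describe_table(
                        traits, ["GR", "GE", "GI"], ["environment", "treatment"]
                    )
                    desc.to_csv(out / "descriptives.tsv", sep="\t", index=False)
                    rep_rel = replicate_relative_indices(traits)
                    herit_rows = []
                    for tr in RELATIVE_TRAITS:
                        sub = rep_rel.dropna(subset=[tr])
                        try:
                            an = anova_two_way(sub, value=tr)
                        except ValueError as err:
                            report.warnings.append(f"stats:{tr}: {err}")
                            continue
                        an.reset_index().to_csv(
                            out / f"anova_{tr}.tsv", sep="\t", index=False
                        )
                        vc = variance_components(an)
                        herit_rows.append({
                            "trait": tr, "sigma_g2": vc.sigma_g2,
                            "sigma_ge2": vc.sigma_ge2, "sigma_e2": vc.sigma_e2,
                            "n_env": vc.n_env, "n_rep": vc.n_rep,
                            "h2": vc.heritability,
                        })
                    pd.DataFrame(herit_rows).to_csv(
                        out / "heritability.tsv", sep="\t", index=False
                    )
                    r, p = correlate(rel.dropna(), RELATIVE_TRAITS)
                    r.to_csv(out / "correlations_r.tsv", sep="\t")
                    p.to_csv(out / "correlations_p.tsv", sep="\t")
                    report.stages["stats"] = {"traits": len(herit_rows)}
                elif stage == "gwas":
                    if rel is None:
                        rel = pd.read_csv(out / "relative_indices.tsv", sep="\t")
                    if genotypes is None:
                        dos = read_dosage(out / "dosages.tsv")
                        genotypes = _matrix_from_dosage(dos)
                    gm = genotypes.filter_maf(config.maf_min)
                    K = kinship(gm)
                    ids = list(gm.genotype_ids)
                    missing = sorted(set(rel["genotype_id"]) - set(ids))
                    if missing:
                        raise ValueError(
                            f"genotype id(s) absent from genotype data: {missing[:5]}"
                        )
                    n_hits = 0
                    for env, sub in rel.groupby("environment", sort=True):
                        sub = sub.set_index("genotype_id").reindex(ids)
                        for tr in config.gwas_traits:
                            y = sub[tr].to_numpy(float)
                            ok = ~np.isnan(y)
                            scan = mlm_scan(y[ok], gm.subset(np.arange(gm.n_snps))
                                            if ok.all() else _mask_rows(gm, ok),
                                            K=K[np.ix_(ok, ok)])
                            scan.to_csv(out / f"scan_{tr}_{env}.tsv",
                                        sep="\t", index=False)
                            hits = significant_snps(
                                scan, config.significance_threshold
                            )
                            hits.to_csv(out / f"significant_{tr}_{env}.tsv",
                                        sep="\t", index=False)
                            n_hits += len(hits)
                            if config.make_plots:
                                manhattan_plot(
                                    scan, str(out / f"manhattan_{tr}_{env}.png"),
                                    threshold=config.significance_threshold,
                                    title=f"{tr} {env}",
                                )
                    report.stages["gwas"] = {
                        "snps": gm.n_snps, "significant": n_hits,
                    }
            except Exception as err:
                raise RuntimeError(f"pipeline stage '{stage}' failed: {err}") from err
        seen = set()
        for w in caught:
            msg = str(w.message)
            if msg not in seen:
                seen.add(msg)
                report.warnings.append(msg)
    report.elapsed_seconds = round(time.time() - t0, 3)
    report.save(out / "run_report.json")
    return report


def _mask_rows(gm: GenotypeMatrix, mask: np.ndarray) -> GenotypeMatrix:
    return GenotypeMatrix(
        genotype_ids=[g for g, m in zip(gm.genotype_ids, mask) if m],
        snp_ids=gm.snp_ids, chrom=gm.chrom, pos=gm.pos,
        ref=gm.ref, alt=gm.alt, dosage=gm.dosage[mask],
    )


def _matrix_from_dosage(dos: pd.DataFrame) -> GenotypeMatrix:
    snp_ids = list(dos.columns)
    chrom, pos = [], []
    for s in snp_ids:
        try:
            c, q = s.lstrip("S").split("_")
            chrom.append(int(c))
            pos.append(int(q))
        except ValueError:
            chrom.append(0)
            pos.append(0)
    return GenotypeMatrix(
        genotype_ids=list(dos.index),
        snp_ids=snp_ids,
        chrom=np.array(chrom),
        pos=np.array(pos),
        ref=["A"] * len(snp_ids),
        alt=["T"] * len(snp_ids),
        dosage=dos.to_numpy(),
    )
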