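"""Synthetic germination trials and SNP panels.

The generator emulates a germplasm drought screen: each genotype carries a
latent drought-response liability (polygenic + causal-SNP + G×E + unit
noise).  Under osmotic stress the liability moves the per-seed germination
probability through a logistic link and advances the day on which seeds
germinate; control units are unaffected by liability.  All randomness flows
from ``SimulationConfig.rng_seed`` through independent named streams, so a
config reproduces its data bit-for-bit.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit, logit
from scipy.stats import poisson

from .config import SimulationConfig
from .datatypes import GenotypeMatrix, TrialSet

__all__ = [
    "simulate_genotypes",
    "simulate_trials",
    "simulate_trait_layout",
    "write_trials",
    "read_trials",
    "write_vcf",
    "read_vcf",
    "write_dosage",
    "read_dosage",
]

_PROB_EPS = 1e-9
N_CHROMOSOMES = 20


def _stream(config: SimulationConfig, key: int) -> np.random.Generator:
    # independent, reproducible sub-streams keyed off the one user seed
    return np.random.default_rng([int(config.rng_seed), key])


def simulate_genotypes(
    config: SimulationConfig,
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Draw an independent-SNP biallelic panel plus its causal-SNP registry.

    Per SNP an alternate-allele frequency is drawn uniformly from
    ``config.maf_range`` and dosages from Binomial(2, p); monomorphic columns
    are redrawn so every SNP stays polymorphic.  ``n_causal`` SNPs are chosen
    at random and assigned additive liability effects.

    Returns
    -------
    (GenotypeMatrix, DataFrame)
        The panel and a registry with columns ``snp_id, chrom, pos, effect``
        (empty when ``n_causal == 0``).
    """
    rng = _stream(config, 1)
    n, m = config.n_genotypes, config.n_snps
    lo, hi = config.maf_range
    p = rng.uniform(lo, hi, size=m)
    dosage = rng.binomial(2, p, size=(n, m)).astype(np.int8)
    # redraw any column that came out monomorphic
    for _ in range(100):
        mono = np.flatnonzero(dosage.min(axis=0) == dosage.max(axis=0))
        if mono.size == 0:
            break
        dosage[:, mono] = rng.binomial(2, p[mono], size=(n, mono.size)).astype(np.int8)
    else:  # pragma: no cover - would need pathological maf_range
        raise RuntimeError("could not generate polymorphic SNPs")

    chrom = 1 + (np.arange(m) * N_CHROMOSOMES) // max(m, 1)
    per_chrom_pos = np.zeros(m, dtype=np.int64)
    for c in np.unique(chrom):
        idx = np.flatnonzero(chrom == c)
        pos = np.sort(rng.choice(50_000_000, size=idx.size, replace=False)) + 1
        per_chrom_pos[idx] = pos
    bases = np.array(list("ACGT"))
    ref_idx = rng.integers(0, 4, size=m)
    alt_idx = (ref_idx + rng.integers(1, 4, size=m)) % 4
    snp_ids = [f"S{c:02d}_{q}" for c, q in zip(chrom, per_chrom_pos)]

    gm = GenotypeMatrix(
        genotype_ids=[f"G{i + 1:03d}" for i in range(n)],
        snp_ids=snp_ids,
        chrom=chrom.astype(int),
        pos=per_chrom_pos,
        ref=list(bases[ref_idx]),
        alt=list(bases[alt_idx]),
        dosage=dosage,
    )
    if config.n_causal:
        causal_idx = np.sort(rng.choice(m, size=config.n_causal, replace=False))
        registry = pd.DataFrame(
            {
                "snp_id": [snp_ids[j] for j in causal_idx],
                "chrom": chrom[causal_idx],
                "pos": per_chrom_pos[causal_idx],
                "effect": config.causal_effects,
            }
        )
    else:
        registry = pd.DataFrame(columns=["snp_id", "chrom", "pos", "effect"])
    return gm, registry


def _germination_day_probs(mean_extra_days: float, n_days: int) -> np.ndarray:
    """Discrete day-of-germination distribution: 1 + Poisson(mean), tail on last day."""
    d = np.arange(n_days - 1)
    probs = poisson.pmf(d, mean_extra_days)
    return np.append(probs, max(1.0 - probs.sum(), 0.0))


def simulate_trials(
    config: SimulationConfig,
    genotypes: GenotypeMatrix | None = None,
    causal_registry: pd.DataFrame | None = None,
) -> TrialSet:
    """Simulate one germination trial per genotype×environment×treatment×replicate.

    Drought units: per-seed germination probability is
    ``expit(logit(drought_germ_prob) + liability)`` and germinating seeds
    draw their day from ``1 + Poisson(max(day_mean_drought − slope·liability,
    0.05))`` truncated at ``n_days`` — tolerant genotypes germinate more and
    earlier.  Control units use ``control_germ_prob`` and
    ``day_mean_control`` independent of liability.

    When a genotype panel with causal SNPs is supplied (or ``n_causal > 0``,
    in which case one is simulated internally), centred causal dosages enter
    the genetic value additively.
    """
    if genotypes is None and config.n_causal > 0 and config.n_snps > 0:
        genotypes, causal_registry = simulate_genotypes(config)

    rng = _stream(config, 2)
    n, n_env, n_rep = config.n_genotypes, config.n_environments, config.n_replicates
    seeds, n_days = config.seeds_per_replicate, config.n_days

    g_poly = rng.normal(0.0, np.sqrt(config.var_genotype), size=n)
    g_causal = np.zeros(n)
    if genotypes is not None and causal_registry is not None and len(causal_registry):
        if genotypes.n_genotypes != n:
            raise ValueError("genotype panel size does not match n_genotypes")
        idx = [genotypes.snp_ids.index(s) for s in causal_registry["snp_id"]]
        dos = genotypes.dosage[:, idx].astype(float)
        dos -= dos.mean(axis=0)  # centre so liability stays zero-mean
        g_causal = dos @ causal_registry["effect"].to_numpy(float)
    g = g_poly + g_causal
    gxe = rng.normal(0.0, np.sqrt(config.var_gxe), size=(n, n_env))

    base_logit = logit(config.drought_germ_prob)
    rows: list[dict] = []
    liab_rows: list[dict] = []
    n_clipped = 0
    for e in range(n_env):
        env_id = f"E{e + 1}"
        for i in range(n):
            gid = f"G{i + 1:03d}"
            liab_rows.append(
                {"genotype_id": gid, "environment": env_id,
                 "genetic_value": g[i], "liability": g[i] + gxe[i, e]}
            )
            for rep in range(1, n_rep + 1):
                for treatment in ("control", "drought"):
                    if treatment == "control":
                        p = config.control_germ_prob
                        mu = config.day_mean_control
                    else:
                        liab = g[i] + gxe[i, e] + rng.normal(
                            0.0, np.sqrt(config.var_residual)
                        )
                        p = expit(base_logit + liab)
                        if p < _PROB_EPS or p > 1 - _PROB_EPS:
                            n_clipped += 1
                            p = float(np.clip(p, _PROB_EPS, 1 - _PROB_EPS))
                        mu = max(
                            config.day_mean_drought
                            - config.day_liability_slope * liab,
                            0.05,
                        )
                    k = int(rng.binomial(seeds, p))
                    counts = rng.multinomial(k, _germination_day_probs(mu, n_days))
                    row = {
                        "genotype_id": gid,
                        "environment": env_id,
                        "treatment": treatment,
                        "replicate": rep,
                        "total_seeds": seeds,
                    }
                    row.update({f"day{d + 1}": int(counts[d]) for d in range(n_days)})
                    rows.append(row)
    if n_clipped:
        msg = f"{n_clipped} drought units had saturated germination probabilities"
        if config.strict:
            raise ValueError(msg)
        warnings.warn(msg, stacklevel=2)
    return TrialSet(
        trials=pd.DataFrame(rows),
        liability=pd.DataFrame(liab_rows),
        config=config,
    )


def simulate_trait_layout(
    sigma_g2: float,
    sigma_ge2: float,
    sigma_e2: float,
    n_genotypes: int,
    n_environments: int,
    n_replicates: int,
    seed: int,
    grand_mean: float = 0.0,
) -> pd.DataFrame:
    """Balanced Gaussian genotype×environment layout with known components.

    Draws ``y = μ + g_i + (ge)_ie + ε`` with the stated variance components —
    the direct generative model behind the expected-mean-squares estimator,
    used for parameter-recovery checks of the ANOVA/heritability stage.
    """
    rng = np.random.default_rng(seed)
    gi = rng.normal(0, np.sqrt(sigma_g2), n_genotypes)
    ge = rng.normal(0, np.sqrt(sigma_ge2), (n_genotypes, n_environments))
    rows = []
    for i in range(n_genotypes):
        for e in range(n_environments):
            eps = rng.normal(0, np.sqrt(sigma_e2), n_replicates)
            for r in range(n_replicates):
                rows.append(
                    {
                        "genotype_id": f"G{i + 1:03d}",
                        "environment": f"E{e + 1}",
                        "replicate": r + 1,
                        "value": grand_mean + gi[i] + ge[i, e] + eps[r],
                    }
                )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# text I/O

def write_trials(trials: pd.DataFrame, path: str | Path) -> None:
    trials.to_csv(path, sep="\t", index=False)


def read_trials(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"genotype_id", "environment", "treatment", "replicate", "total_seeds"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"trial table missing columns: {sorted(missing)}")
    return df


def write_vcf(gm: GenotypeMatrix, path: str | Path) -> None:
    """Write the panel as a minimal uncompressed VCF (GT only)."""
    gt_codes = {0: "0/0", 1: "0/1", 2: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=germscan\n")
        for c in sorted(set(int(x) for x in gm.chrom)):
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(gm.genotype_ids)
            + "\n"
        )
        order = np.lexsort((gm.pos, gm.chrom))
        for j in order:
            gts = "\t".join(gt_codes[int(d)] for d in gm.dosage[:, j])
            fh.write(
                f"{int(gm.chrom[j])}\t{int(gm.pos[j])}\t{gm.snp_ids[j]}\t"
                f"{gm.ref[j]}\t{gm.alt[j]}\t.\tPASS\t.\tGT\t{gts}\n"
            )


def read_vcf(path: str | Path) -> GenotypeMatrix:
    """Load a biallelic VCF (GT field) into a GenotypeMatrix via cyvcf2."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    genotype_ids = list(vcf.samples)
    snp_ids, chrom, pos, ref, alt, cols = [], [], [], [], [], []
    for var in vcf:
        if len(var.ALT) != 1:
            raise ValueError(f"non-biallelic record at {var.CHROM}:{var.POS}")
        # gt_types: 0 hom-ref, 1 het, 2 unknown, 3 hom-alt
        gt = np.asarray(var.gt_types)
        if (gt == 2).any():
            raise ValueError(f"missing genotypes at {var.CHROM}:{var.POS}")
        cols.append(np.where(gt == 3, 2, gt).astype(np.int8))
        snp_ids.append(var.ID or f"S{int(var.CHROM):02d}_{var.POS}")
        chrom.append(int(var.CHROM))
        pos.append(var.POS)
        ref.append(var.REF)
        alt.append(var.ALT[0])
    return GenotypeMatrix(
        genotype_ids=genotype_ids,
        snp_ids=snp_ids,
        chrom=np.array(chrom),
        pos=np.array(pos),
        ref=ref,
        alt=alt,
        dosage=np.column_stack(cols),
    )


def write_dosage(gm: GenotypeMatrix, path: str | Path) -> None:
    """Plain genotype×SNP dosage matrix as TSV (rows genotypes)."""
    pd.DataFrame(gm.dosage, index=gm.genotype_ids, columns=gm.snp_ids).to_csv(
        path, sep="\t", index_label="genotype_id"
    )


def read_dosage(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="genotype_id")
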