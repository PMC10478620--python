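"""Synthetic genotype/phenotype generator emulating a pig SNP-chip cohort.

The generator mirrors the structure of a Landrace production cohort genotyped
on a ~60K porcine chip: biallelic SNPs spread over 18 autosomes at ~50 kb
spacing, Hardy-Weinberg genotypes at allele frequencies drawn from a MAF
band, additive polygenic traits with a target heritability of 0.3, and sex +
parity fixed effects with class counts proportional to the study demography
(1,667 males / 1,266 females; parity classes 698, 551, 534, 472, 368, 184,
85, 24, 17 — 2,933 animals in all). SNPs are independent by default: the
subset-selection machinery does not require linkage disequilibrium, and the
ground truth stays exactly interpretable.

Every draw flows from one integer seed, so datasets are bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .genotype_data import GenotypeDataset, SnpRecord, write_plink

__all__ = [
    "SimConfig",
    "SimTruth",
    "scale_counts",
    "simulate_genotypes",
    "simulate_phenotypes",
    "fixture_small",
    "write_dataset",
]

#: study demography: sex and parity class counts (sum to 2,933)
DEFAULT_SEX_COUNTS = (1667, 1266)
DEFAULT_PARITY_COUNTS = (698, 551, 534, 472, 368, 184, 85, 24, 17)


@dataclass(frozen=True)
class SimConfig:
    """Simulation parameters.

    Defaults match the emulated cohort: 2,933 individuals, 46,992 post-QC
    autosomal SNPs on 18 chromosomes, MAF in [0.05, 0.5], heritability 0.3,
    backfat-like trait anchors (mean 12.46 mm, SD 2.14 mm). ``n_qtl`` is the
    number of causal SNPs; effects are equal-variance normal draws scaled to
    hit ``h2_target``. ``sex_effect`` and ``parity_effects`` are additive
    fixed-effect shifts in phenotypic-SD units before rescaling.
    """

    n_individuals: int = 2933
    n_snps: int = 46992
    n_chromosomes: int = 18
    maf_range: tuple[float, float] = (0.05, 0.5)
    n_qtl: int = 100
    h2_target: float = 0.3
    effect_distribution: str = "normal"
    sex_effect: float = 0.5
    parity_effects: tuple[float, ...] = tuple(0.05 * i for i in range(9))
    sex_counts: tuple[int, ...] = DEFAULT_SEX_COUNTS
    parity_counts: tuple[int, ...] = DEFAULT_PARITY_COUNTS
    trait_mean: float | None = 12.46
    trait_sd: float | None = 2.14
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.h2_target <= 1.0:
            raise ValueError("h2_target must be in [0, 1]")
        if not 0 <= self.n_qtl <= self.n_snps:
            raise ValueError("need 0 <= n_qtl <= n_snps")
        lo, hi = self.maf_range
        if not 0.0 < lo <= hi <= 0.5:
            raise ValueError("maf_range must satisfy 0 < lo <= hi <= 0.5")
        if len(self.parity_effects) != len(self.parity_counts):
            raise ValueError("parity_effects and parity_counts lengths differ")
        if self.effect_distribution not in {"normal", "exponential", "equal"}:
            raise ValueError("effect_distribution must be normal, exponential or equal")


@dataclass
class SimTruth:
    """Ground truth of a simulated phenotype: causal SNPs, effects, realized h2."""

    causal_ids: list[str]
    effects: np.ndarray
    genetic_values: np.ndarray
    realized_h2: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"snp": self.causal_ids, "effect": self.effects})


def scale_counts(counts: tuple[int, ...], n: int) -> np.ndarray:
    """Rescale class counts to sum to ``n`` (largest-remainder apportionment)."""
    counts = np.asarray(counts, dtype=float)
    quota = counts * n / counts.sum()
    base = np.floor(quota).astype(int)
    short = n - base.sum()
    order = np.argsort(-(quota - base), kind="stable")
    base[order[:short]] += 1
    return base


def simulate_genotypes(config: SimConfig) -> GenotypeDataset:
    """Draw HWE genotypes at frequencies uniform on ``maf_range``.

    SNPs are split evenly over chromosomes with positions increasing at
    20-80 kb gaps (the chip's ~50 kb mean spacing). Dosages count the A1
    allele, whose frequency is the drawn value.
    """
    rng = np.random.default_rng([config.seed, 0])
    n, m = config.n_individuals, config.n_snps
    freqs = rng.uniform(*config.maf_range, size=m)
    dosage = rng.binomial(2, freqs, size=(n, m)).astype(float)
    if config.missing_rate > 0.0:
        mask = rng.random(size=(n, m)) < config.missing_rate
        dosage[mask] = np.nan

    bases = np.array(list("ACGT"))
    snps: list[SnpRecord] = []
    chrom_blocks = np.array_split(np.arange(m), config.n_chromosomes)
    for c, block in enumerate(chrom_blocks, start=1):
        pos = np.cumsum(rng.integers(20_000, 80_001, size=block.size))
        for j, bp in zip(block, pos):
            a1, a2 = rng.choice(4, size=2, replace=False)
            snps.append(SnpRecord(f"snp_{j + 1}", c, int(bp), str(bases[a1]), str(bases[a2])))
    individuals = [f"ind_{i + 1}" for i in range(n)]
    return GenotypeDataset(individuals, snps, dosage)


def simulate_phenotypes(
    geno: GenotypeDataset, config: SimConfig
) -> tuple[pd.DataFrame, SimTruth]:
    """Additive polygenic trait with sex/parity fixed effects and target h2.

    ``n_qtl`` causal SNPs get equal-variance normal effects; the residual
    variance is set so var(genetic) / var(genetic + residual) hits
    ``h2_target``. Sex and parity labels are assigned by seeded permutation
    with class counts proportional to the configured demography. When trait
    anchors are set the phenotype is affinely rescaled to them (the variance
    ratio is scale-free, so realized h2 is unchanged).
    """
    rng = np.random.default_rng([config.seed, 1])
    n = geno.n_individuals
    if config.n_qtl == 0 and config.h2_target > 0.0:
        raise ValueError("h2_target > 0 requires n_qtl >= 1")

    causal_idx = np.sort(
        rng.choice(geno.n_snps, size=config.n_qtl, replace=False)
    )
    if config.effect_distribution == "normal":
        effects = rng.normal(0.0, 1.0, size=config.n_qtl)
    elif config.effect_distribution == "exponential":
        effects = rng.exponential(1.0, size=config.n_qtl) * rng.choice(
            [-1.0, 1.0], size=config.n_qtl
        )
    else:  # "equal": every QTL equally strong, random sign
        effects = rng.choice([-1.0, 1.0], size=config.n_qtl)
    if config.h2_target == 0.0:
        effects = np.zeros(config.n_qtl)
    d = geno.dosage[:, causal_idx]
    if np.isnan(d).any():
        raise ValueError("causal SNPs contain missing calls; simulate without missingness")
    g = (d - d.mean(axis=0)) @ effects
    var_g = float(g.var())

    if config.h2_target in (0.0, 1.0) or var_g == 0.0:
        noise_sd = 1.0 if config.h2_target == 0.0 else 0.0
        if config.h2_target == 1.0:
            noise_sd = 0.0
    else:
        noise_sd = np.sqrt(var_g * (1.0 - config.h2_target) / config.h2_target)
    e = rng.normal(0.0, 1.0, size=n) * noise_sd if noise_sd > 0 else np.zeros(n)

    # demographic labels by seeded permutation, class counts apportioned to n
    sex_counts = scale_counts(config.sex_counts, n)
    parity_counts = scale_counts(config.parity_counts, n)
    sex = np.repeat(np.array(["male", "female"]), sex_counts)[rng.permutation(n)]
    parity = np.repeat(np.arange(1, len(parity_counts) + 1), parity_counts)[
        rng.permutation(n)
    ]
    base_sd = np.sqrt(var_g + e.var()) if (var_g + e.var()) > 0 else 1.0
    fixed = config.sex_effect * base_sd * (sex == "female").astype(float)
    fixed += base_sd * np.array(config.parity_effects)[parity - 1]

    y = fixed + g + e
    if config.trait_sd is not None and config.trait_mean is not None and y.std() > 0:
        scale = config.trait_sd / y.std()
        g = g * scale
        e = e * scale
        effects = effects * scale
        y = (y - y.mean()) * scale + config.trait_mean

    var_g, var_e = float(g.var()), float(e.var())
    realized_h2 = var_g / (var_g + var_e) if (var_g + var_e) > 0 else 0.0
    pheno = pd.DataFrame(
        {"iid": geno.individuals, "trait": y, "sex": sex, "parity": parity}
    )
    truth = SimTruth(
        causal_ids=[geno.snps[j].id for j in causal_idx],
        effects=effects,
        genetic_values=g,
        realized_h2=realized_h2,
    )
    return pheno, truth


FIXTURE_SEED = 20230902


def fixture_small() -> tuple[GenotypeDataset, pd.DataFrame, SimTruth]:
    """Fixed-seed desk-scale instance used across the test suite.

    300 individuals x 3,000 SNPs, 30 QTLs, h2 = 0.3 — small enough for
    second-scale refits, large enough that ranking and the PA trace behave
    like the full-scale design (use step = 500 for a 6-point trace).
    """
    config = SimConfig(
        n_individuals=300, n_snps=3000, n_qtl=30, h2_target=0.3, seed=FIXTURE_SEED
    )
    geno = simulate_genotypes(config)
    pheno, truth = simulate_phenotypes(geno, config)
    return geno, pheno, truth


def write_dataset(
    geno: GenotypeDataset,
    pheno: pd.DataFrame,
    truth: SimTruth | None,
    prefix: str | Path,
) -> None:
    """Write PLINK .bed/.bim/.fam plus ``<prefix>.pheno.tsv`` (and truth TSV)."""
    prefix = Path(prefix)
    write_plink(geno, prefix)
    pheno.to_csv(prefix.with_suffix(".pheno.tsv"), sep="\t", index=False)
    if truth is not None:
        truth.to_frame().to_csv(prefix.with_suffix(".truth.tsv"), sep="\t", index=False)
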