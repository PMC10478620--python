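"""Genotype containers, PLINK binary I/O, marker quality control, and imputation.

The central container is :class:`GenotypeDataset`: an individuals x SNPs matrix of
allele dosages (copies of the A1 allele, 0/1/2, ``nan`` = missing call) together
with the SNP map and individual ids. I/O follows the PLINK 1 binary layout
(.bed/.bim/.fam, SNP-major) so datasets interoperate with the standard GWAS
toolchain.

QC mirrors the conventional marker filters for SNP-chip data: minor allele
frequency, per-SNP call rate, and the exact conditional Hardy-Weinberg test
(Wigginton-style, as used by PLINK's ``--hwe``).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SnpRecord",
    "GenotypeDataset",
    "SnpQcStats",
    "PlinkFormatError",
    "DataConsistencyError",
    "read_plink",
    "write_plink",
    "read_phenotypes",
    "hwe_exact_p",
    "snp_qc_stats",
    "apply_qc",
    "impute_mean",
]

BED_MAGIC = bytes([0x6C, 0x1B, 0x01])

# 2-bit PLINK codes, least-significant pair = first individual in the byte:
# 0b00 hom A1 -> dosage 2, 0b01 missing, 0b10 het -> 1, 0b11 hom A2 -> 0
_CODE_TO_DOSAGE = np.array([2.0, np.nan, 1.0, 0.0])
_BYTE_TABLE = np.empty((256, 4))
for _b in range(256):
    for _k in range(4):
        _BYTE_TABLE[_b, _k] = _CODE_TO_DOSAGE[(_b >> (2 * _k)) & 0b11]


class PlinkFormatError(ValueError):
    """Malformed PLINK binary input (bad magic bytes / unsupported mode)."""


class DataConsistencyError(ValueError):
    """Dimensions of .bed payload disagree with .bim/.fam, or matched inputs conflict."""


@dataclass(frozen=True)
class SnpRecord:
    """One marker of the SNP map: id, chromosome, 1-based position, alleles."""

    id: str
    chromosome: int
    position: int
    allele_a1: str = "A"
    allele_a2: str = "B"

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError(f"SNP {self.id}: position must be >= 1 (1-based)")


@dataclass
class GenotypeDataset:
    """Individuals x SNPs dosage matrix plus marker map and sample ids.

    ``dosage[i, j]`` counts copies of ``snps[j].allele_a1`` carried by
    ``individuals[i]``; missing calls are ``nan``.
    """

    individuals: list[str]
    snps: list[SnpRecord]
    dosage: np.ndarray

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=float)
        if self.dosage.shape != (len(self.individuals), len(self.snps)):
            raise DataConsistencyError(
                f"dosage shape {self.dosage.shape} != "
                f"({len(self.individuals)} individuals, {len(self.snps)} SNPs)"
            )
        ids = [s.id for s in self.snps]
        if len(set(ids)) != len(ids):
            raise DataConsistencyError("duplicate SNP ids in dataset")

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    @property
    def snp_ids(self) -> list[str]:
        return [s.id for s in self.snps]

    def snp_index(self, snp_ids: Sequence[str]) -> np.ndarray:
        """Column indices of ``snp_ids`` (in the given order)."""
        lookup = {s.id: j for j, s in enumerate(self.snps)}
        try:
            return np.array([lookup[i] for i in snp_ids], dtype=int)
        except KeyError as exc:
            raise KeyError(f"unknown SNP id {exc.args[0]!r}") from None

    def subset(
        self,
        individuals: Sequence[str] | None = None,
        snp_ids: Sequence[str] | None = None,
    ) -> "GenotypeDataset":
        """New dataset restricted to the given individuals and/or SNPs (order as given)."""
        rows = np.arange(self.n_individuals)
        inds = self.individuals
        if individuals is not None:
            lookup = {iid: i for i, iid in enumerate(self.individuals)}
            rows = np.array([lookup[i] for i in individuals], dtype=int)
            inds = list(individuals)
        cols = np.arange(self.n_snps)
        snps = self.snps
        if snp_ids is not None:
            cols = self.snp_index(snp_ids)
            snps = [self.snps[j] for j in cols]
        return GenotypeDataset(list(inds), list(snps), self.dosage[np.ix_(rows, cols)])


@dataclass(frozen=True)
class SnpQcStats:
    """Per-SNP QC statistics from non-missing calls.

    ``maf`` is min(f, 1-f) for the A1 frequency f; ``hwe_p`` the exact
    conditional Hardy-Weinberg p-value. For an all-missing SNP every field is
    ``nan`` and ``defined`` is False (such a SNP always fails QC).
    """

    maf: float
    call_rate: float
    hwe_p: float
    defined: bool = True


# ---------------------------------------------------------------------------
# PLINK binary I/O


def read_plink(prefix: str | Path) -> GenotypeDataset:
    """Read a PLINK 1 binary fileset ``prefix``.bed/.bim/.fam.

    SNP order follows the .bim file, individual order the .fam file; missing
    genotypes stay missing (``nan``).
    """
    prefix = Path(prefix)
    bim = pd.read_csv(
        prefix.with_suffix(".bim"),
        sep=r"\s+",
        header=None,
        names=["chrom", "id", "cm", "pos", "a1", "a2"],
        dtype={"id": str, "a1": str, "a2": str},
    )
    fam = pd.read_csv(
        prefix.with_suffix(".fam"),
        sep=r"\s+",
        header=None,
        names=["fid", "iid", "father", "mother", "sex", "pheno"],
        dtype={"iid": str},
    )
    snps = [
        SnpRecord(r.id, int(r.chrom), int(r.pos), r.a1, r.a2)
        for r in bim.itertuples(index=False)
    ]
    individuals = fam["iid"].tolist()
    n, m = len(individuals), len(snps)

    raw = Path(prefix.with_suffix(".bed")).read_bytes()
    if raw[:3] != BED_MAGIC:
        raise PlinkFormatError(
            f"{prefix}.bed: bad magic bytes {raw[:3]!r} (expected SNP-major v1.00)"
        )
    bytes_per_snp = (n + 3) // 4
    payload = np.frombuffer(raw, dtype=np.uint8, offset=3)
    if payload.size != m * bytes_per_snp:
        raise DataConsistencyError(
            f"{prefix}.bed payload has {payload.size} bytes, expected "
            f"{m * bytes_per_snp} for {n} individuals x {m} SNPs"
        )
    # (m, bytes_per_snp) bytes -> (m, 4*bytes_per_snp) dosages -> trim padding
    dosage = _BYTE_TABLE[payload.reshape(m, bytes_per_snp)].reshape(m, -1)[:, :n]
    return GenotypeDataset(individuals, snps, np.ascontiguousarray(dosage.T))


def write_plink(geno: GenotypeDataset, prefix: str | Path) -> None:
    """Write ``geno`` as a PLINK 1 binary fileset (SNP-major .bed, text .bim/.fam)."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    n, m = geno.n_individuals, geno.n_snps

    codes = np.full((m, n), 0b01, dtype=np.uint8)  # missing
    d = geno.dosage.T
    codes[d == 2.0] = 0b00
    codes[d == 1.0] = 0b10
    codes[d == 0.0] = 0b11
    pad = (-n) % 4
    if pad:
        codes = np.concatenate(
            [codes, np.zeros((m, pad), dtype=np.uint8)], axis=1
        )
    shifts = 2 * np.arange(4, dtype=np.uint8)
    packed = (codes.reshape(m, -1, 4) << shifts).sum(axis=2).astype(np.uint8)
    prefix.with_suffix(".bed").write_bytes(BED_MAGIC + packed.tobytes())

    with prefix.with_suffix(".bim").open("w") as fh:
        for s in geno.snps:
            fh.write(f"{s.chromosome}\t{s.id}\t0\t{s.position}\t{s.allele_a1}\t{s.allele_a2}\n")
    with prefix.with_suffix(".fam").open("w") as fh:
        for iid in geno.individuals:
            fh.write(f"{iid}\t{iid}\t0\t0\t0\t-9\n")


def read_phenotypes(path: str | Path) -> pd.DataFrame:
    """Read a whitespace/tab-separated phenotype+covariate table with a header row.

    Requires an ``iid`` column; trait and covariate columns (e.g. sex, parity)
    are kept as-is. One row per individual.
    """
    pheno = pd.read_csv(path, sep=r"\s+", dtype={"iid": str})
    if "iid" not in pheno.columns:
        raise DataConsistencyError(f"{path}: phenotype table must have an 'iid' column")
    if pheno["iid"].duplicated().any():
        dup = pheno.loc[pheno["iid"].duplicated(), "iid"].iloc[0]
        raise DataConsistencyError(f"{path}: duplicate individual id {dup!r}")
    return pheno


# ---------------------------------------------------------------------------
# Quality control


def hwe_exact_p(n_het: int, n_hom1: int, n_hom2: int) -> float:
    """Exact conditional Hardy-Weinberg test p-value.

    Conditions on the observed allele counts and sums the probabilities of all
    heterozygote counts no more probable than the observed one (two-sided exact
    test; the PLINK ``--hwe`` statistic). Uses the stable ratio recurrence so
    large samples do not overflow.
    """
    if min(n_het, n_hom1, n_hom2) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_het + n_hom1 + n_hom2
    if n == 0:
        return float("nan")
    rare = 2 * min(n_hom1, n_hom2) + n_het
    # heterozygote counts compatible with `rare` rare-allele copies share its parity
    probs = np.zeros(rare + 1)
    mid = rare * (2 * n - rare) // (2 * n)
    if mid % 2 != rare % 2:
        mid += 1
    probs[mid] = 1.0
    # downward recurrence: het -> het - 2
    h, hom_r, hom_c = mid, (rare - mid) // 2, n - mid - (rare - mid) // 2
    while h >= 2:
        probs[h - 2] = probs[h] * h * (h - 1) / (4.0 * (hom_r + 1) * (hom_c + 1))
        h -= 2
        hom_r += 1
        hom_c += 1
    # upward recurrence: het -> het + 2
    h, hom_r, hom_c = mid, (rare - mid) // 2, n - mid - (rare - mid) // 2
    while h <= rare - 2:
        probs[h + 2] = probs[h] * 4.0 * hom_r * hom_c / ((h + 2.0) * (h + 1.0))
        h += 2
        hom_r -= 1
        hom_c -= 1
    probs /= probs.sum()
    p_obs = probs[n_het]
    return float(min(1.0, probs[probs <= p_obs * (1 + 1e-12)].sum()))


def snp_qc_stats(geno: GenotypeDataset) -> list[SnpQcStats]:
    """MAF, call rate, and exact HWE p-value for every SNP."""
    out: list[SnpQcStats] = []
    n = geno.n_individuals
    for j in range(geno.n_snps):
        col = geno.dosage[:, j]
        obs = col[~np.isnan(col)]
        if obs.size == 0:
            out.append(SnpQcStats(np.nan, 0.0, np.nan, defined=False))
            continue
        call_rate = obs.size / n
        f = obs.mean() / 2.0
        maf = min(f, 1.0 - f)
        hom1 = int((obs == 2.0).sum())
        het = int((obs == 1.0).sum())
        hom2 = int((obs == 0.0).sum())
        out.append(SnpQcStats(float(maf), float(call_rate), hwe_exact_p(het, hom1, hom2)))
    return out


def apply_qc(
    geno: GenotypeDataset,
    maf_min: float = 0.05,
    miss_max: float = 0.05,
    hwe_p_min: float = 1.0e-6,
) -> GenotypeDataset:
    """Retain SNPs with MAF >= ``maf_min``, missingness <= ``miss_max`` and
    HWE p >= ``hwe_p_min`` (all three computed jointly on the input).

    The individual set is unchanged and SNP order preserved; an empty result is
    allowed. All-missing SNPs always fail.
    """
    stats = snp_qc_stats(geno)
    keep = [
        s.id
        for s, st in zip(geno.snps, stats)
        if st.defined
        and st.maf >= maf_min
        and (1.0 - st.call_rate) <= miss_max
        and st.hwe_p >= hwe_p_min
    ]
    return geno.subset(snp_ids=keep)


def impute_mean(geno: GenotypeDataset) -> GenotypeDataset:
    """Replace each missing call by the SNP's mean dosage over observed calls.

    A deliberately simple stand-in for haplotype-based imputation; adequate for
    the low missingness left after QC.
    """
    d = geno.dosage.copy()
    missing = np.isnan(d)
    if missing.any():
        all_missing = missing.all(axis=0)
        if all_missing.any():
            bad = geno.snps[int(np.flatnonzero(all_missing)[0])].id
            raise ValueError(
                f"SNP {bad!r} has no observed calls; run apply_qc before impute_mean"
            )
        with np.errstate(invalid="ignore"):
            col_means = np.nanmean(d, axis=0)
        d[missing] = np.broadcast_to(col_means, d.shape)[missing]
    return replace(geno, dosage=d)
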