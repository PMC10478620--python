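"""Prediction-ability trace over nested SNP subsets and the cutoff decision.

The core procedure: rank SNPs by GWAS p-value, grow the marker set in fixed
steps (default 1,000 SNPs), refit G-BLUP on each nested subset, and record the
prediction ability

    PA = cor(phenotypic values, GEBVs)                      (in-sample)

and the correlation difference between consecutive subsets

    CD_i = PA[i * step] - PA[(i-1) * step].

The selected cutoff is the region immediately before the CD trace becomes
persistently negligible: the last trace point whose |CD| is at least the mean
|CD|, provided every later point stays below the mean. In-sample PA is
optimistically biased; the cross-validation module quantifies the out-of-sample
drop for the selected subset.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .annotation import GeneAnnotation, genes_covered
from .assoc import align_individuals, covariate_design
from .gblup import compute_grm, reml_fit
from .genotype_data import GenotypeDataset

__all__ = [
    "GarsConfig",
    "GarsDecision",
    "prediction_ability",
    "gars_trace",
    "select_cutoff",
    "pvalue_at_cutoff",
]


@dataclass(frozen=True)
class GarsConfig:
    """Trace parameters: subset increment and an optional ceiling on ranked SNPs.

    A step of 1,000 SNPs is the default; very small steps (~50) make the CD
    trace jumpy and can trigger a spuriously early cutoff.
    """

    step: int = 1000
    max_snps: int | None = None

    def __post_init__(self) -> None:
        if self.step < 1:
            raise ValueError("step must be >= 1")
        if self.max_snps is not None and self.max_snps < 1:
            raise ValueError("max_snps must be >= 1 when given")


@dataclass
class GarsDecision:
    """Selected cutoff and diagnostics.

    ``abruptness`` is |CD| at the first post-cutoff point divided by |CD| at
    the cutoff point — small values mean the trace collapses right after the
    cutoff. ``flags`` may contain ``no_plateau`` when no persistently
    sub-average tail exists and the cutoff falls back to all ranked SNPs.
    """

    cutoff_n_snps: int
    cutoff_p: float
    mean_abs_cd: float
    abruptness: float
    flags: list[str] = field(default_factory=list)


def prediction_ability(pheno_values: np.ndarray, gebv: np.ndarray) -> float:
    """Pearson correlation between phenotypes and breeding values."""
    y = np.asarray(pheno_values, dtype=float)
    u = np.asarray(gebv, dtype=float)
    if y.size != u.size:
        raise ValueError("phenotype and GEBV vectors differ in length")
    if y.size < 3:
        raise ValueError("need >= 3 observations for a meaningful correlation")
    if np.ptp(y) == 0.0 or np.ptp(u) == 0.0:
        raise ValueError("prediction ability undefined for a constant vector")
    return float(stats.pearsonr(y, u).statistic)


def _subset_sizes(n_ranked: int, step: int) -> list[int]:
    sizes = list(range(step, n_ranked + 1, step))
    if not sizes or sizes[-1] != n_ranked:
        sizes.append(n_ranked)  # final partial step
    return sizes


def gars_trace(
    geno: GenotypeDataset,
    pheno: pd.DataFrame,
    trait: str,
    ranked_ids: Sequence[str],
    config: GarsConfig = GarsConfig(),
    covariates: tuple[str, ...] | list[str] = ("sex", "parity"),
    annotation: GeneAnnotation | None = None,
) -> pd.DataFrame:
    """Compute the PA/CD trace over nested p-value-ranked subsets.

    Every subset gets a full refit: GRM on the subset's SNPs, REML variance
    components, fixed effects, and in-sample GEBVs. Returns a DataFrame with
    columns ``n_snps``, ``pa``, ``cd`` (NaN at the first point) and
    ``new_genes`` (NaN without annotation).
    """
    ranked = list(ranked_ids)
    if config.max_snps is not None:
        ranked = ranked[: config.max_snps]
    if not ranked:
        raise ValueError("empty SNP ranking")

    rows, matched = align_individuals(geno, pheno)
    sub_geno = geno.subset(individuals=[geno.individuals[i] for i in rows])
    y = matched[trait].to_numpy(dtype=float)
    X, _ = covariate_design(matched, covariates)

    sizes = _subset_sizes(len(ranked), config.step)
    pa_values: list[float] = []
    new_genes: list[float] = []
    seen_genes: set[str] = set()
    prev_end = 0
    for size in sizes:
        subset = ranked[:size]
        k = compute_grm(sub_geno, snp_ids=subset)
        fit = reml_fit(y, X, k)
        pa_values.append(prediction_ability(y, fit.gebv))
        if annotation is not None:
            cur = genes_covered(ranked[prev_end:size], geno.snps, annotation)
            new_genes.append(float(len(cur - seen_genes)))
            seen_genes |= cur
        else:
            new_genes.append(np.nan)
        prev_end = size

    pa_arr = np.array(pa_values)
    cd = np.full(len(sizes), np.nan)
    cd[1:] = pa_arr[1:] - pa_arr[:-1]
    trace = pd.DataFrame(
        {"n_snps": sizes, "pa": pa_arr, "cd": cd, "new_genes": new_genes}
    )
    trace.attrs["step"] = config.step
    return trace


def select_cutoff(trace: pd.DataFrame, assoc: pd.DataFrame | None = None) -> GarsDecision:
    """Apply the correlation-difference cutoff rule to a trace.

    With mu = mean |CD| over all CD points, the cutoff is the last point whose
    |CD| >= mu when all later points stay below mu (the persistently
    negligible tail). If the final point itself reaches mu there is no such
    tail: the decision is flagged ``no_plateau`` and the cutoff is the full
    ranked set. ``cutoff_p`` (the p-value of the last SNP inside the cutoff)
    is filled when an association table is supplied.
    """
    if len(trace) < 3:
        raise ValueError("cutoff selection needs >= 3 trace points (>= 2 CD values)")
    cd = trace["cd"].to_numpy(dtype=float)[1:]
    n_snps = trace["n_snps"].to_numpy(dtype=int)
    if np.isnan(cd).any():
        raise ValueError("trace CD values contain NaN beyond the first point")
    abs_cd = np.abs(cd)
    mu = float(abs_cd.mean())
    qualifying = np.flatnonzero(abs_cd >= mu)  # indices into cd (trace point i+1)
    flags: list[str] = []
    if qualifying.size == 0 or qualifying[-1] == cd.size - 1:
        # no persistently sub-average tail after the last qualifying point
        flags.append("no_plateau")
        cut_idx = len(trace) - 1
    else:
        cut_idx = int(qualifying[-1]) + 1  # trace-point index
    cutoff_n = int(n_snps[cut_idx])

    if cut_idx + 1 < len(trace):
        denom = abs(cd[cut_idx - 1]) if cut_idx >= 1 else np.nan
        numer = abs(cd[cut_idx])
        abruptness = float(numer / denom) if denom and np.isfinite(denom) else np.nan
    else:
        abruptness = np.nan

    cutoff_p = np.nan
    if assoc is not None:
        cutoff_p = pvalue_at_cutoff(assoc, cutoff_n)
    return GarsDecision(
        cutoff_n_snps=cutoff_n,
        cutoff_p=float(cutoff_p),
        mean_abs_cd=mu,
        abruptness=abruptness,
        flags=flags,
    )


def pvalue_at_cutoff(assoc: pd.DataFrame, cutoff_n_snps: int) -> float:
    """P-value of the ``cutoff_n_snps``-th SNP in ascending-p order.

    This is the per-test threshold equivalent to keeping the top
    ``cutoff_n_snps`` ranked SNPs, directly comparable to a Bonferroni cutoff.
    """
    p_sorted = np.sort(assoc.loc[assoc["testable"], "p"].to_numpy(dtype=float))
    if not 1 <= cutoff_n_snps <= p_sorted.size:
        raise ValueError(
            f"cutoff {cutoff_n_snps} outside the testable SNP count ({p_sorted.size})"
        )
    return float(p_sorted[cutoff_n_snps - 1])
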