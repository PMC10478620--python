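"""Monte-Carlo cross-validation of a selected SNP subset.

Each split holds out a seeded random test fraction (default 30%), refits the
variance components and fixed effects on the training rows with the
subset-SNP GRM, predicts test-set GEBVs out of sample, and records the Pearson
correlation between test phenotypes and predictions. Splits are independent
draws, so test sets may overlap across splits (the 10-splits-at-30% design is
Monte-Carlo CV, not disjoint 10-fold; a strict disjoint mode is available).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .assoc import align_individuals, covariate_design
from .gblup import compute_grm, predict_gebv_oos, reml_fit
from .trace import prediction_ability

__all__ = ["CvConfig", "CvResult", "cross_validate"]


@dataclass(frozen=True)
class CvConfig:
    """Cross-validation parameters.

    ``disjoint_kfold`` switches to classic disjoint folds (test fraction then
    1/n_splits); ``adjust_covariates`` correlates predictions against
    covariate-adjusted phenotypes (y - X b) instead of raw trait values.
    """

    n_splits: int = 10
    test_fraction: float = 0.3
    seed: int = 0
    disjoint_kfold: bool = False
    adjust_covariates: bool = False

    def __post_init__(self) -> None:
        if self.n_splits < 1:
            raise ValueError("n_splits must be >= 1")
        if not 0.0 < self.test_fraction < 1.0:
            raise ValueError("test_fraction must be in (0, 1)")


@dataclass
class CvResult:
    """Per-split prediction abilities and their aggregates.

    Splits whose test phenotype was constant get ``nan`` and are excluded from
    the mean/SD; ``n_failed`` counts them.
    """

    pa_per_split: list[float]
    mean_pa: float
    sd_pa: float
    n_train: int
    n_test: int
    n_failed: int = 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "split": np.arange(1, len(self.pa_per_split) + 1),
                "n_train": self.n_train,
                "n_test": self.n_test,
                "pa": self.pa_per_split,
            }
        )


def _split_indices(n: int, config: CvConfig) -> list[tuple[np.ndarray, np.ndarray]]:
    splits = []
    if config.disjoint_kfold:
        rng = np.random.default_rng(config.seed)
        perm = rng.permutation(n)
        for fold in np.array_split(perm, config.n_splits):
            test = np.sort(fold)
            train = np.setdiff1d(perm, fold)
            splits.append((train, test))
    else:
        n_test = math.ceil(config.test_fraction * n)
        for s in range(config.n_splits):
            # fold the split index into the seed so splits are independent draws
            rng = np.random.default_rng([config.seed, s])
            test = np.sort(rng.choice(n, size=n_test, replace=False))
            train = np.setdiff1d(np.arange(n), test)
            splits.append((train, test))
    return splits


def cross_validate(
    geno,
    pheno: pd.DataFrame,
    trait: str,
    snp_ids: Sequence[str],
    config: CvConfig = CvConfig(),
    covariates: tuple[str, ...] | list[str] = ("sex", "parity"),
) -> CvResult:
    """Out-of-sample prediction ability of the SNP subset over repeated splits."""
    if len(snp_ids) == 0:
        raise ValueError("SNP subset is empty")
    rows, matched = align_individuals(geno, pheno)
    sub_geno = geno.subset(individuals=[geno.individuals[i] for i in rows])
    y = matched[trait].to_numpy(dtype=float)
    X, _ = covariate_design(matched, covariates)
    n = y.size
    k_full = compute_grm(sub_geno, snp_ids=list(snp_ids))

    pa_list: list[float] = []
    n_failed = 0
    n_train = n_test = 0
    for train, test in _split_indices(n, config):
        n_train, n_test = train.size, test.size
        k_train = _sub_kinship(k_full, train)
        # a rare covariate class can vanish from the training rows; drop its
        # (then all-zero) dummy column so the fixed design stays full rank
        X_train = X[train]
        keep = [0] + [j for j in range(1, X.shape[1]) if np.ptp(X_train[:, j]) > 0]
        X_train = X_train[:, keep]
        fit = reml_fit(y[train], X_train, k_train)
        u_test = predict_gebv_oos(train, test, y[train], X_train, k_full, fit)
        y_test = y[test]
        if config.adjust_covariates:
            y_test = y_test - X[test][:, keep] @ fit.beta_fixed
        if np.ptp(y_test) == 0.0 or np.ptp(u_test) == 0.0:
            pa_list.append(np.nan)
            n_failed += 1
            continue
        pa_list.append(prediction_ability(y_test, u_test))

    valid = np.array([v for v in pa_list if not np.isnan(v)])
    mean_pa = float(valid.mean()) if valid.size else np.nan
    sd_pa = float(valid.std(ddof=1)) if valid.size > 1 else np.nan
    return CvResult(
        pa_per_split=pa_list,
        mean_pa=mean_pa,
        sd_pa=sd_pa,
        n_train=n_train,
        n_test=n_test,
        n_failed=n_failed,
    )


def _sub_kinship(k_full, idx: np.ndarray):
    from .gblup import KinshipMatrix

    return KinshipMatrix(
        k_full.submatrix(idx, idx), [k_full.individuals[i] for i in idx]
    )
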