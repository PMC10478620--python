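"""Single-marker association testing and p-value ranking.

Each SNP is tested by ordinary least squares of the trait on
``[intercept, covariates, dosage]``; the additive allele-substitution effect is
the dosage coefficient, with a two-sided t-test on ``n - rank(design)`` degrees
of freedom. Covariates are projected out once (Frisch-Waugh), so the per-SNP
work is a vectorised cross-product over all markers.

The association table is a pandas DataFrame with one row per SNP in genotype
order, carrying effect size, standard error, raw and adjusted p-values, and the
p-value rank used to form nested SNP subsets.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .genotype_data import DataConsistencyError, GenotypeDataset

__all__ = [
    "covariate_design",
    "align_individuals",
    "assoc_linear",
    "adjust_bonferroni",
    "bonferroni_threshold",
    "adjust_bh",
    "rank_snps",
]

#: columns of an association table
ASSOC_COLUMNS = ["snp", "chrom", "pos", "a1", "beta", "se", "p", "p_bh", "p_bonf", "testable"]

_P_FLOOR = np.finfo(float).tiny  # keep -log10(p) finite


def align_individuals(
    geno: GenotypeDataset, pheno: pd.DataFrame
) -> tuple[np.ndarray, pd.DataFrame]:
    """Match individuals between genotypes and phenotype table by id.

    Returns the genotype row indices of the intersection (genotype order) and
    the phenotype rows reindexed to match.
    """
    by_id = pheno.set_index("iid")
    rows = np.array([i for i, iid in enumerate(geno.individuals) if iid in by_id.index])
    if rows.size == 0:
        raise DataConsistencyError("no individuals shared between genotypes and phenotypes")
    matched = by_id.loc[[geno.individuals[i] for i in rows]].reset_index()
    return rows, matched


def covariate_design(
    pheno: pd.DataFrame,
    covariates: tuple[str, ...] | list[str] = (),
    categorical: set[str] | None = None,
) -> tuple[np.ndarray, list[str]]:
    """Build the fixed-effect design matrix [intercept | covariate columns].

    Columns named in ``categorical`` (default: ``sex`` and ``parity``) are
    dummy-coded with the first level as reference; other covariates enter as
    numeric. Parity classes are treated as groups, not a dose, unless removed
    from ``categorical``.
    """
    if categorical is None:
        categorical = {"sex", "parity"}
    cols = [np.ones(len(pheno))]
    names = ["intercept"]
    for cov in covariates:
        if cov not in pheno.columns:
            raise KeyError(f"covariate {cov!r} not in phenotype table")
        if cov in categorical:
            levels = pd.Categorical(pheno[cov])
            for lev in levels.categories[1:]:
                cols.append((levels == lev).astype(float))
                names.append(f"{cov}[{lev}]")
        else:
            cols.append(pheno[cov].to_numpy(dtype=float))
            names.append(cov)
    X = np.column_stack(cols)
    _check_full_rank(X, names)
    return X, names


def _check_full_rank(X: np.ndarray, names: list[str]) -> None:
    """Raise naming the offending columns if the design is rank-deficient."""
    if np.linalg.matrix_rank(X) == X.shape[1]:
        return
    # walk columns, flag those (nearly) in the span of the previous ones
    offenders = []
    basis = np.empty((X.shape[0], 0))
    for j in range(X.shape[1]):
        col = X[:, j]
        if basis.shape[1]:
            col = col - basis @ (basis.T @ col)
        norm = np.linalg.norm(col)
        if norm < 1e-8 * max(1.0, np.linalg.norm(X[:, j])):
            offenders.append(names[j])
        else:
            basis = np.column_stack([basis, col / norm])
    raise np.linalg.LinAlgError(
        f"collinear fixed-effect design; redundant columns: {offenders}"
    )


def assoc_linear(
    geno: GenotypeDataset,
    pheno: pd.DataFrame,
    trait: str,
    covariates: tuple[str, ...] | list[str] = ("sex", "parity"),
    categorical: set[str] | None = None,
) -> pd.DataFrame:
    """Per-SNP OLS association scan of ``trait`` with covariate adjustment.

    Genotypes must be imputed (no missing dosages). Individuals are matched by
    id; the intersection is used in genotype order. SNPs whose dosage is
    constant among matched individuals are flagged ``testable = False`` with
    missing statistics.
    """
    if np.isnan(geno.dosage).any():
        raise ValueError("missing dosages present; run impute_mean first")
    rows, matched = align_individuals(geno, pheno)
    y = matched[trait].to_numpy(dtype=float)
    if not np.all(np.isfinite(y)):
        raise ValueError(f"trait {trait!r} contains non-finite values")
    X, _ = covariate_design(matched, covariates, categorical)
    n, p = X.shape
    df = n - p - 1
    if df < 1:
        raise ValueError(f"too few individuals (n={n}) for design with {p} columns")

    G = geno.dosage[rows, :]
    Q, _ = np.linalg.qr(X)
    y_r = y - Q @ (Q.T @ y)
    G_r = G - Q @ (Q.T @ G)

    sxx = np.einsum("ij,ij->j", G_r, G_r)
    testable = sxx > n * np.finfo(float).eps * np.maximum(1.0, (G * G).sum(axis=0))
    sxy = G_r.T @ y_r
    syy = float(y_r @ y_r)

    with np.errstate(divide="ignore", invalid="ignore"):
        beta = sxy / sxx
        rss = np.maximum(syy - beta * sxy, 0.0)
        se = np.sqrt(rss / df / sxx)
        t = beta / se
    pvals = 2.0 * stats.t.sf(np.abs(t), df)
    pvals = np.clip(pvals, _P_FLOOR, 1.0)
    beta[~testable] = np.nan
    se[~testable] = np.nan
    pvals[~testable] = np.nan

    m = int(testable.sum())
    table = pd.DataFrame(
        {
            "snp": geno.snp_ids,
            "chrom": [s.chromosome for s in geno.snps],
            "pos": [s.position for s in geno.snps],
            "a1": [s.allele_a1 for s in geno.snps],
            "beta": beta,
            "se": se,
            "p": pvals,
            "testable": testable,
        }
    )
    table["p_bonf"] = np.nan
    table["p_bh"] = np.nan
    if m:
        mask = table["testable"].to_numpy()
        table.loc[mask, "p_bonf"] = adjust_bonferroni(table.loc[mask, "p"].to_numpy(), m)
        table.loc[mask, "p_bh"] = adjust_bh(table.loc[mask, "p"].to_numpy())
    table.attrs["n_tests"] = m
    table.attrs["n_individuals"] = n
    return table[ASSOC_COLUMNS]


def adjust_bonferroni(p: np.ndarray, m: int) -> np.ndarray:
    """Bonferroni family-wise adjustment: ``min(1, p * m)`` over ``m`` tests."""
    if m <= 0:
        raise ValueError("number of tests m must be positive")
    p = np.asarray(p, dtype=float)
    if m < p.size:
        raise ValueError(f"m = {m} smaller than the number of p-values ({p.size})")
    return np.minimum(1.0, p * m)


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Per-test p-value cutoff giving family-wise error rate ``alpha`` over ``m`` tests."""
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    if m < 1:
        raise ValueError("m must be >= 1")
    return alpha / m


def adjust_bh(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (input order preserved)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q = np.minimum(1.0, np.minimum.accumulate(ranked[::-1])[::-1])
    out = np.empty_like(q)
    out[order] = q
    return out


def rank_snps(assoc: pd.DataFrame) -> list[str]:
    """SNP ids sorted by ascending p-value.

    Ties break by (chromosome, position); non-testable SNPs are appended last
    in genome order. This ranking defines the nested subsets of the
    prediction-ability trace.
    """
    testable = assoc[assoc["testable"]]
    rest = assoc[~assoc["testable"]]
    ranked = testable.sort_values(["p", "chrom", "pos"], kind="stable")["snp"].tolist()
    ranked += rest.sort_values(["chrom", "pos"], kind="stable")["snp"].tolist()
    return ranked
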