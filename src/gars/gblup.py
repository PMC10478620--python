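"""Genomic relationship matrix, one-component REML, and GEBV prediction.

The model is the standard animal-model G-BLUP:

    y = X b + u + e,   u ~ N(0, Vu * K),   e ~ N(0, Ve * I)

with K the VanRaden (method 1) genomic relationship matrix built from
centred allele dosages. REML is maximised over the heritability
h2 = Vu / (Vu + Ve) by a bounded scalar search on the spectrum of K: after
rotating y and X by the eigenvectors of K the covariance is diagonal, the
variance scale has a closed form at every h2, and the restricted
log-likelihood is a cheap one-dimensional profile (the "mixed.solve" /
EMMA-style computation). Breeding values are the BLUPs
u = Vu K (Vu K + Ve I)^-1 (y - X b) — in-sample, or rectangular
K[test, train] for out-of-sample prediction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import minimize_scalar

from .genotype_data import GenotypeDataset

__all__ = [
    "KinshipMatrix",
    "MixedModelFit",
    "compute_grm",
    "reml_fit",
    "predict_gebv",
    "predict_gebv_oos",
]

_H2_LO, _H2_HI = 1e-6, 1.0 - 1e-6


@dataclass
class KinshipMatrix:
    """Symmetric n x n genomic relationship matrix with its individual id order."""

    matrix: np.ndarray
    individuals: list[str]

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = len(self.individuals)
        if self.matrix.shape != (n, n):
            raise ValueError(f"kinship matrix shape {self.matrix.shape} != ({n}, {n})")
        if not np.allclose(self.matrix, self.matrix.T, atol=1e-10):
            raise ValueError("kinship matrix is not symmetric")

    @property
    def n(self) -> int:
        return len(self.individuals)

    def submatrix(self, rows: Sequence[int], cols: Sequence[int]) -> np.ndarray:
        return self.matrix[np.ix_(np.asarray(rows), np.asarray(cols))]


@dataclass
class MixedModelFit:
    """REML estimates and BLUPs of the one-random-effect animal model.

    ``h2`` is Vu/(Vu+Ve); ``degenerate`` flags an optimum pinned at the
    heritability boundary (e.g. zero residual variance after fixed effects).
    """

    vu: float
    ve: float
    h2: float
    beta_fixed: np.ndarray
    gebv: np.ndarray
    reml_loglik: float
    h2_se: float | None = None
    degenerate: bool = False
    diagnostics: dict = field(default_factory=dict)


def compute_grm(geno: GenotypeDataset, snp_ids: Sequence[str] | None = None) -> KinshipMatrix:
    """VanRaden method-1 GRM from (optionally a subset of) the dataset's SNPs.

    Each dosage column is centred by twice its observed allele frequency and
    K = Z Z' / (2 * sum f_j (1 - f_j)). Rows and columns sum to zero by
    construction; the expected diagonal on unrelated individuals is ~1.
    """
    d = geno.dosage if snp_ids is None else geno.dosage[:, geno.snp_index(snp_ids)]
    if np.isnan(d).any():
        raise ValueError("missing dosages present; impute before computing the GRM")
    f = d.mean(axis=0) / 2.0
    denom = 2.0 * float(np.sum(f * (1.0 - f)))
    if denom <= 0.0:
        raise ValueError("all SNPs monomorphic: GRM denominator is zero")
    Z = d - 2.0 * f
    K = (Z @ Z.T) / denom
    K = 0.5 * (K + K.T)
    return KinshipMatrix(K, list(geno.individuals))


def _profile_restricted_loglik(
    h2: float,
    s: np.ndarray,
    yr: np.ndarray,
    Xr: np.ndarray,
    ld_xtx: float,
) -> tuple[float, float, np.ndarray]:
    """Restricted log-likelihood at h2 with the variance scale profiled out.

    Works in the eigenbasis of K: ``s`` are the (clipped) eigenvalues, ``yr``
    and ``Xr`` the rotated response and design. Returns (loglik, sigma2, beta)
    where Vu = sigma2*h2 and Ve = sigma2*(1-h2).
    """
    n, p = Xr.shape
    w = h2 * s + (1.0 - h2)
    Xw = Xr / w[:, None]
    xtwx = Xr.T @ Xw
    beta = np.linalg.solve(xtwx, Xw.T @ yr)
    r = yr - Xr @ beta
    quad = float(np.sum(r * r / w))
    if quad <= 0.0:
        return np.inf, 0.0, beta  # exact fixed-effect fit; caller flags degenerate
    sigma2 = quad / (n - p)
    sign, ld_xtwx = np.linalg.slogdet(xtwx)
    if sign <= 0:
        raise FloatingPointError(f"non-PD rotated design cross-product at h2={h2}")
    ll = -0.5 * (
        (n - p) * (np.log(2.0 * np.pi * sigma2) + 1.0)
        + float(np.log(w).sum())
        + ld_xtwx
        - ld_xtx
    )
    return ll, sigma2, beta


def reml_fit(
    y: np.ndarray,
    x_fixed: np.ndarray,
    k: KinshipMatrix,
    compute_se: bool = False,
) -> MixedModelFit:
    """Fit the animal model by spectral REML and return estimates plus in-sample GEBVs.

    Parameters
    ----------
    y : trait values, length n.
    x_fixed : fixed-effect design including the intercept, shape (n, p).
    k : genomic relationship matrix over the same n individuals.
    compute_se : also report an approximate standard error of h2 from the
        curvature of the restricted log-likelihood profile.
    """
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(x_fixed, dtype=float))
    n = y.size
    if k.n != n or X.shape[0] != n:
        raise ValueError("y, x_fixed and kinship dimensions disagree")
    p = X.shape[1]
    if n < p + 2:
        raise ValueError(f"need n >= rank(X) + 2 (n={n}, p={p})")
    if np.var(y) == 0.0:
        raise ValueError("phenotype has zero variance")
    if np.linalg.matrix_rank(X) < p:
        raise np.linalg.LinAlgError("fixed-effect design is rank-deficient")

    s, U = np.linalg.eigh(k.matrix)
    s = np.clip(s, 0.0, None)
    yr = U.T @ y
    Xr = U.T @ X
    _, ld_xtx = np.linalg.slogdet(X.T @ X)

    degenerate = False

    def neg_ll(h2: float) -> float:
        ll, _, _ = _profile_restricted_loglik(h2, s, yr, Xr, ld_xtx)
        return -ll if np.isfinite(ll) else -1e12  # exact fit: push toward boundary

    opt = minimize_scalar(
        neg_ll, bounds=(_H2_LO, _H2_HI), method="bounded",
        options={"xatol": 1e-8},
    )
    h2 = float(opt.x)
    ll, sigma2, beta = _profile_restricted_loglik(h2, s, yr, Xr, ld_xtx)
    if not np.isfinite(ll):
        # residual variance numerically zero: y in the span of X
        degenerate = True
        h2 = _H2_LO
        sigma2 = 0.0
        ll = np.inf
    if h2 <= _H2_LO * 1.01 or h2 >= 1.0 - 1e-5:
        degenerate = True
    if sigma2 <= 1e-12 * float(np.var(y)):
        degenerate = True  # residual variance numerically zero after fixed effects
    if not degenerate and not np.isfinite(ll):
        raise FloatingPointError(
            f"non-finite restricted likelihood at h2={h2} (sigma2={sigma2})"
        )

    vu = sigma2 * h2
    ve = sigma2 * (1.0 - h2)
    gebv = predict_gebv(y, X, k, vu, ve, beta)
    fit = MixedModelFit(
        vu=float(vu),
        ve=float(ve),
        h2=h2,
        beta_fixed=beta,
        gebv=gebv,
        reml_loglik=float(ll),
        degenerate=degenerate,
        diagnostics={"n": n, "p": p, "converged": bool(opt.success)},
    )
    if compute_se and not degenerate:
        fit.h2_se = _h2_se_from_curvature(h2, s, yr, Xr, ld_xtx)
    return fit


def _h2_se_from_curvature(
    h2: float, s: np.ndarray, yr: np.ndarray, Xr: np.ndarray, ld_xtx: float
) -> float | None:
    """SE of h2 from a central-difference second derivative of the REML profile."""
    eps = 1e-4
    lo = max(_H2_LO, h2 - eps)
    hi = min(_H2_HI, h2 + eps)
    step = min(h2 - lo, hi - h2)
    if step <= 0:
        return None
    f = lambda x: _profile_restricted_loglik(x, s, yr, Xr, ld_xtx)[0]
    d2 = (f(h2 - step) - 2.0 * f(h2) + f(h2 + step)) / step**2
    if d2 >= 0:
        return None
    return float(1.0 / np.sqrt(-d2))


def predict_gebv(
    y: np.ndarray,
    x_fixed: np.ndarray,
    k: KinshipMatrix,
    vu: float,
    ve: float,
    beta_fixed: np.ndarray,
) -> np.ndarray:
    """In-sample BLUP breeding values u = Vu K (Vu K + Ve I)^-1 (y - X b)."""
    if vu == 0.0:
        return np.zeros(len(y))
    r = np.asarray(y, dtype=float) - np.atleast_2d(x_fixed) @ np.asarray(beta_fixed)
    V = vu * k.matrix + ve * np.eye(k.n)
    try:
        sol = np.linalg.solve(V, r)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            f"phenotypic covariance singular (vu={vu:.3g}, ve={ve:.3g}): {exc}"
        ) from exc
    return vu * (k.matrix @ sol)


def predict_gebv_oos(
    train_idx: Sequence[int],
    test_idx: Sequence[int],
    y_train: np.ndarray,
    x_train: np.ndarray,
    k_full: KinshipMatrix,
    fit: MixedModelFit,
) -> np.ndarray:
    """Out-of-sample GEBVs for test individuals from a fit on the training rows.

    u_test = Vu K[test, train] (Vu K[train, train] + Ve I)^-1 (y_train - X_train b)
    """
    train_idx = np.asarray(train_idx)
    test_idx = np.asarray(test_idx)
    if np.intersect1d(train_idx, test_idx).size:
        raise ValueError("train and test sets overlap")
    if fit.vu == 0.0:
        return np.zeros(test_idx.size)
    r = np.asarray(y_train, dtype=float) - np.atleast_2d(x_train) @ fit.beta_fixed
    k_tt = k_full.submatrix(train_idx, train_idx)
    V = fit.vu * k_tt + fit.ve * np.eye(train_idx.size)
    sol = np.linalg.solve(V, r)
    return fit.vu * (k_full.submatrix(test_idx, train_idx) @ sol)
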