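"""Independent brute-force oracles the implementation is checked against.

Each oracle computes its quantity by a different route than the library:
exact enumeration for the Hardy-Weinberg test, normal equations for OLS,
a dense-matrix restricted-likelihood grid for REML, and Henderson's
mixed-model equations for BLUP breeding values.
"""

from fractions import Fraction
from math import factorial

import numpy as np
from scipy import stats


def hwe_enumeration_p(n_het: int, n_hom1: int, n_hom2: int) -> float:
    """Exact HWE p by full enumeration of the conditional distribution (exact rationals)."""
    n = n_het + n_hom1 + n_hom2
    rare = 2 * min(n_hom1, n_hom2) + n_het
    total = 2 * n

    def prob(h: int) -> Fraction:
        if (rare - h) % 2 or h < 0 or h > rare:
            return Fraction(0)
        hom_r = (rare - h) // 2
        hom_c = n - h - hom_r
        if hom_r < 0 or hom_c < 0:
            return Fraction(0)
        num = Fraction(factorial(n) * 2**h * factorial(rare) * factorial(total - rare))
        den = Fraction(
            factorial(hom_r) * factorial(h) * factorial(hom_c) * factorial(total)
        )
        return num / den

    probs = {h: prob(h) for h in range(rare + 1)}
    p_obs = probs[n_het]
    return float(sum(p for p in probs.values() if p <= p_obs))


def ols_normal_equations(y, covariate_design, dosage):
    """Per-SNP OLS via the normal equations: (beta, se, p) for the dosage column."""
    A = np.column_stack([covariate_design, dosage])
    n, k = A.shape
    coef = np.linalg.solve(A.T @ A, A.T @ y)
    resid = y - A @ coef
    df = n - k
    sigma2 = float(resid @ resid) / df
    cov = sigma2 * np.linalg.inv(A.T @ A)
    beta = float(coef[-1])
    se = float(np.sqrt(cov[-1, -1]))
    p = float(2 * stats.t.sf(abs(beta / se), df))
    return beta, se, p


def restricted_loglik_direct(h2: float, y, X, K) -> float:
    """REML log-likelihood at h2 with the variance scale profiled, dense-matrix route."""
    n, p = X.shape
    S = h2 * K + (1.0 - h2) * np.eye(n)
    Si = np.linalg.inv(S)
    beta = np.linalg.solve(X.T @ Si @ X, X.T @ Si @ y)
    r = y - X @ beta
    sigma2 = float(r @ Si @ r) / (n - p)
    Vi = Si / sigma2
    _, ld_v = np.linalg.slogdet(sigma2 * S)
    _, ld_xvx = np.linalg.slogdet(X.T @ Vi @ X)
    _, ld_xx = np.linalg.slogdet(X.T @ X)
    return -0.5 * ((n - p) * np.log(2 * np.pi) + ld_v + ld_xvx - ld_xx + (n - p))


def reml_grid_argmax(y, X, K, grid=None):
    """(h2*, loglik*) over a dense h2 grid using the direct-route likelihood."""
    if grid is None:
        grid = np.arange(0.001, 1.0, 0.001)
    lls = np.array([restricted_loglik_direct(h, y, X, K) for h in grid])
    i = int(np.argmax(lls))
    return float(grid[i]), float(lls[i])


def mme_blup(y, X, K, vu, ve):
    """Henderson's mixed-model equations with Z = I: returns (beta, u)."""
    n, p = X.shape
    lam = ve / vu
    Kinv = np.linalg.inv(K)
    lhs = np.block([[X.T @ X, X.T], [X, np.eye(n) + lam * Kinv]])
    rhs = np.concatenate([X.T @ y, y])
    sol = np.linalg.solve(lhs, rhs)
    return sol[:p], sol[p:]


def mme_blup_missing(y_train, X_train, train_idx, K_full, vu, ve):
    """MME with records only on training individuals; u spans all individuals."""
    n_full = K_full.shape[0]
    n_train, p = X_train.shape
    Z = np.zeros((n_train, n_full))
    Z[np.arange(n_train), np.asarray(train_idx)] = 1.0
    lam = ve / vu
    Kinv = np.linalg.inv(K_full)
    lhs = np.block([[X_train.T @ X_train, X_train.T @ Z], [Z.T @ X_train, Z.T @ Z + lam * Kinv]])
    rhs = np.concatenate([X_train.T @ y_train, Z.T @ y_train])
    sol = np.linalg.solve(lhs, rhs)
    return sol[:p], sol[p:]


def gls_beta(y, X, V):
    Vi = np.linalg.inv(V)
    return np.linalg.solve(X.T @ Vi @ X, X.T @ Vi @ y)
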