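"""Genomic relationship matrix, REML variance components, heritability.

Narrow-sense heritability of a line-mean phenotype y is estimated under the
mixed model

    y = mu + g + e,   Var(g) = G sigma2_G,   Var(e) = I sigma2_E,

where G is the marker-derived (VanRaden-type) relationship matrix built
from {-1, 0, +1} dosages: markers are mean-imputed, centered by twice the
allele frequency, and G = W W' / (2 sum_k p_k (1 - p_k)).  The variance
components are the restricted-maximum-likelihood solution obtained by a
spectral decomposition of G and a one-dimensional search over the variance
ratio, after which h2 = sigma2_G / (sigma2_G + sigma2_E).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from panicleqtl.io_formats import GenotypeMatrix

_LOG_RATIO_BOUNDS = (-10.0, 10.0)  # search range for log(sigma2_G / sigma2_E)


@dataclass
class KinshipMatrix:
    """Symmetric PSD (up to tolerance) lines x lines relationship matrix."""

    values: pd.DataFrame

    def __post_init__(self) -> None:
        G = self.values.to_numpy()
        if not np.allclose(G, G.T, atol=1e-10):
            raise ValueError("relationship matrix must be symmetric")

    @property
    def lines(self) -> list[str]:
        return list(self.values.index)

    def to_numpy(self) -> np.ndarray:
        return self.values.to_numpy()

    def subset(self, lines) -> "KinshipMatrix":
        return KinshipMatrix(self.values.loc[lines, lines])


def kinship_matrix(genotypes: GenotypeMatrix | pd.DataFrame) -> KinshipMatrix:
    """VanRaden relationship matrix from {-1, 0, +1} dosages.

    Missing dosages are imputed to the marker mean before centering;
    monomorphic markers contribute nothing to the numerator and are
    excluded from the denominator.  An all-monomorphic marker set carries
    no relationship information and raises.
    """
    if isinstance(genotypes, GenotypeMatrix):
        dosage = genotypes.dosage()
    else:
        dosage = pd.DataFrame(genotypes).astype(float)
    M = dosage.to_numpy(dtype=float)
    col_mean = np.nanmean(M, axis=0)
    nan_mask = np.isnan(M)
    M = np.where(nan_mask, np.broadcast_to(col_mean, M.shape), M)
    p = (col_mean + 1.0) / 2.0  # frequency of the +1 (donor) allele
    het = p * (1.0 - p)
    denom = 2.0 * het.sum()
    if denom <= 0:
        raise ValueError("all markers are monomorphic; relationship matrix undefined")
    W = M - col_mean
    G = (W @ W.T) / denom
    return KinshipMatrix(pd.DataFrame(G, index=dosage.index, columns=dosage.index))


@dataclass
class VarianceComponents:
    """REML estimates of genetic and residual variance for one trait."""

    sigma2_G: float
    sigma2_E: float
    loglik_restricted: float

    def __post_init__(self) -> None:
        if self.sigma2_G < 0 or self.sigma2_E < 0:
            raise ValueError("variance components must be nonnegative")


def reml_variance_components(y: np.ndarray, G: KinshipMatrix | np.ndarray) -> VarianceComponents:
    """Restricted ML variance components of y = mu + g + e with Var(g) = G s2G.

    The intercept is projected out, the projected kernel is
    eigendecomposed, and the restricted log-likelihood is profiled down to
    a one-dimensional function of the variance ratio, maximised by a
    bounded search over log(sigma2_G / sigma2_E) in [-10, 10] with
    endpoints checked so boundary solutions (h2 near 0 or 1) are kept.
    """
    y = np.asarray(y, dtype=float)
    if not np.all(np.isfinite(y)):
        raise ValueError("phenotype contains non-finite values")
    Gm = G.to_numpy() if isinstance(G, KinshipMatrix) else np.asarray(G, dtype=float)
    n = len(y)
    if Gm.shape != (n, n):
        raise ValueError(f"G shape {Gm.shape} does not match phenotype length {n}")
    if not np.allclose(Gm, Gm.T, atol=1e-8):
        raise ValueError("G must be symmetric")
    if np.var(y) == 0.0:
        warnings.warn("phenotype has zero variance; components set to 0", RuntimeWarning)
        return VarianceComponents(0.0, 0.0, np.nan)

    # Contrast basis orthogonal to the intercept (error contrasts), then
    # eigendecompose the kernel restricted to that subspace.
    Q, _ = np.linalg.qr(np.column_stack([np.ones(n), np.eye(n)[:, : n - 1]]))
    B = Q[:, 1:]  # n x (n-1), orthonormal, B' 1 = 0
    K = B.T @ Gm @ B
    K = 0.5 * (K + K.T)
    xi, U = np.linalg.eigh(K)
    xi = np.clip(xi, 0.0, None)
    eta = U.T @ (B.T @ y)
    m = n - 1  # residual degrees of freedom after the intercept

    def negloglik(log_ratio: float) -> float:
        # ratio = sigma2_G / sigma2_E; V proportional to (ratio * G + I)
        ratio = np.exp(log_ratio)
        d = ratio * xi + 1.0
        quad = float(np.sum(eta**2 / d))
        # profiled restricted LL up to constants
        return 0.5 * (m * np.log(quad / m) + float(np.sum(np.log(d))))

    lo, hi = _LOG_RATIO_BOUNDS
    grid = np.linspace(lo, hi, 81)
    vals = np.array([negloglik(g) for g in grid])
    i = int(np.argmin(vals))
    res = minimize_scalar(
        negloglik,
        bounds=(grid[max(i - 1, 0)], grid[min(i + 1, len(grid) - 1)]),
        method="bounded",
        options={"xatol": 1e-8},
    )
    best_log_ratio = res.x if res.fun <= vals[i] else grid[i]
    best_val = min(res.fun, vals[i])
    ratio = float(np.exp(best_log_ratio))
    d = ratio * xi + 1.0
    sigma2_E = float(np.sum(eta**2 / d) / m)
    sigma2_G = ratio * sigma2_E
    const = -0.5 * m * (np.log(2.0 * np.pi) + 1.0)
    loglik = const - best_val
    return VarianceComponents(sigma2_G=sigma2_G, sigma2_E=sigma2_E, loglik_restricted=float(loglik))


def heritability(vc: VarianceComponents) -> float:
    """Narrow-sense heritability h2 = s2G / (s2G + s2E); NaN if both are 0."""
    total = vc.sigma2_G + vc.sigma2_E
    if total <= 0:
        warnings.warn("both variance components are zero; h2 undefined", RuntimeWarning)
        return float("nan")
    return vc.sigma2_G / total


def heritability_table(
    phenotypes: pd.DataFrame, kinship: KinshipMatrix
) -> pd.DataFrame:
    """h2 per phenotype column; lines with missing values are dropped per trait."""
    rows = []
    for trait in phenotypes.columns:
        col = phenotypes[trait].dropna()
        lines = [ln for ln in col.index if ln in kinship.values.index]
        if len(lines) < 3:
            rows.append({"trait": trait, "h2": np.nan, "n_lines": len(lines)})
            continue
        vc = reml_variance_components(col.loc[lines].to_numpy(), kinship.subset(lines))
        rows.append({"trait": trait, "h2": heritability(vc), "n_lines": len(lines)})
    return pd.DataFrame(rows)
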