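"""PCA pattern features, PC-effect curves, and replicate confidence bands.

The unit-integral spline coefficients of each line form a small matrix
(lines x coefficients) per trait.  A covariance PCA of that matrix yields
interpretable pattern axes: in rice panicles the first component typically
separates distally from proximally laid organ mass, the second linear from
curvilinear profiles.  Because descriptors are linear in the coefficients,
moving the score on one component by +/- k standard deviations and mapping
back through the loadings reconstructs the corresponding curves exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from panicleqtl.spline_descriptor import SplineBasis, evaluate_curve

DEFAULT_GRID = np.linspace(0.0, 1.0, 201)


@dataclass
class PCAResult:
    """Covariance PCA of a descriptor matrix.

    ``loadings`` columns are orthonormal directions in coefficient space;
    ``scores`` are the centered data projected on them; ``sdev`` are the
    score standard deviations (ddof=1); ``var_proportions`` the per-PC
    fraction of total variance.  The sign of each loading is fixed so its
    largest-magnitude element is positive, making orientation reproducible.
    """

    center: np.ndarray
    loadings: np.ndarray  # (p, n_comp)
    scores: pd.DataFrame  # (n_lines, n_comp), columns PC1..
    sdev: np.ndarray
    var_proportions: np.ndarray

    @property
    def n_components(self) -> int:
        return self.loadings.shape[1]

    def reconstruct(self, line_scores: np.ndarray) -> np.ndarray:
        """Map PC scores back to a coefficient vector."""
        return self.center + self.loadings @ np.asarray(line_scores, dtype=float)


def pca_descriptors(matrix: pd.DataFrame) -> PCAResult:
    """Centered, unscaled PCA of a per-line descriptor coefficient matrix.

    One trait at a time; needs at least two lines.  All ``min(n-1, p)``
    components are kept so the reconstruction round-trip
    ``center + loadings @ scores`` is exact.
    """
    X = np.asarray(matrix, dtype=float)
    n, p = X.shape
    if n < 2:
        raise ValueError(f"PCA needs at least 2 lines, got {n}")
    center = X.mean(axis=0)
    Xc = X - center
    # economy SVD: all variance directions present in the data
    _, s, vt = np.linalg.svd(Xc, full_matrices=False)
    n_comp = min(n - 1, p)
    s = s[:n_comp]
    loadings = vt[:n_comp].T
    # deterministic orientation: largest-|.| element of each loading positive
    for j in range(n_comp):
        k = int(np.argmax(np.abs(loadings[:, j])))
        if loadings[k, j] < 0:
            loadings[:, j] *= -1
    scores = Xc @ loadings
    var = s**2 / (n - 1)
    total = var.sum()
    var_prop = var / total if total > 0 else np.zeros_like(var)
    idx = matrix.index if isinstance(matrix, pd.DataFrame) else pd.RangeIndex(n)
    score_df = pd.DataFrame(
        scores, index=idx, columns=[f"PC{j + 1}" for j in range(n_comp)]
    )
    return PCAResult(
        center=center,
        loadings=loadings,
        scores=score_df,
        sdev=scores.std(axis=0, ddof=1),
        var_proportions=var_prop,
    )


def reconstruct_pc_effect(
    pca: PCAResult,
    basis: SplineBasis,
    pc_index: int,
    k_sd: float = 2.0,
    grid: np.ndarray = DEFAULT_GRID,
) -> tuple[np.ndarray, np.ndarray, tuple[np.ndarray, np.ndarray]]:
    """Curves at score = mean +/- k_sd * SD on one PC, other scores at mean.

    Returns ``(curve_plus, curve_minus, (coeffs_plus, coeffs_minus))``
    evaluated on ``grid``.  ``k_sd=0`` returns the mean curve twice.  PCs
    with zero score variance carry no pattern information and raise.
    """
    if not 0 <= pc_index < pca.n_components:
        raise IndexError(f"pc_index {pc_index} out of range 0..{pca.n_components - 1}")
    if k_sd < 0:
        raise ValueError("k_sd must be >= 0")
    sd = float(pca.sdev[pc_index])
    if sd <= 1e-12 * float(np.max(pca.sdev)):
        raise ValueError(f"PC{pc_index + 1} has zero variance; no effect to reconstruct")
    delta = k_sd * sd * pca.loadings[:, pc_index]
    coeffs_plus = pca.center + delta
    coeffs_minus = pca.center - delta
    return (
        evaluate_curve(coeffs_plus, grid, basis),
        evaluate_curve(coeffs_minus, grid, basis),
        (coeffs_plus, coeffs_minus),
    )


@dataclass
class CurveBand:
    """Pointwise confidence band around a mean curve on a common grid."""

    grid: np.ndarray
    mean: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    level: float

    def __post_init__(self) -> None:
        if not (np.all(self.lower <= self.mean + 1e-12) and np.all(self.mean <= self.upper + 1e-12)):
            raise ValueError("band limits must bracket the mean pointwise")


def confidence_band(
    curves: np.ndarray, grid: np.ndarray, level: float = 0.95
) -> CurveBand:
    """Pointwise t confidence band from replicate curves (rows = replicates).

    mean(x) +/- t_{(1+level)/2, m-1} * sd(x)/sqrt(m), computed independently
    at each grid point; with identical replicates the band has zero width.
    """
    curves = np.asarray(curves, dtype=float)
    if curves.ndim != 2 or curves.shape[0] < 2:
        raise ValueError("need at least 2 replicate curves (rows)")
    if curves.shape[1] != len(grid):
        raise ValueError("curves and grid lengths disagree")
    m = curves.shape[0]
    mean = curves.mean(axis=0)
    se = curves.std(axis=0, ddof=1) / np.sqrt(m)
    tq = stats.t.ppf(0.5 * (1.0 + level), df=m - 1)
    return CurveBand(
        grid=np.asarray(grid, dtype=float),
        mean=mean,
        lower=mean - tq * se,
        upper=mean + tq * se,
        level=level,
    )


def bands_overlap_everywhere(
    band_a: CurveBand, band_b: CurveBand
) -> tuple[bool, tuple[float, float] | None]:
    """Do two bands intersect at every grid point?

    Two phenotypes are indistinguishable under this criterion when their
    confidence bands overlap along the whole axis.  Returns
    ``(True, None)`` if so, otherwise ``(False, (x_lo, x_hi))`` with the
    first contiguous x-range where the bands separate.
    """
    if len(band_a.grid) != len(band_b.grid) or not np.allclose(band_a.grid, band_b.grid):
        raise ValueError("bands must share a common grid")
    disjoint = np.maximum(band_a.lower, band_b.lower) > np.minimum(band_a.upper, band_b.upper)
    if not disjoint.any():
        return True, None
    idx = np.flatnonzero(disjoint)
    start = idx[0]
    end = start
    while end + 1 < len(disjoint) and disjoint[end + 1]:
        end += 1
    return False, (float(band_a.grid[start]), float(band_a.grid[end]))


def pca_report(results: dict[str, PCAResult], dfs: dict[str, int]) -> pd.DataFrame:
    """Per-trait variance-proportion table (percent), one row per trait."""
    rows = []
    max_pc = max(r.n_components for r in results.values())
    for trait, res in results.items():
        row: dict[str, object] = {"trait": trait, "df": dfs[trait]}
        for j in range(max_pc):
            row[f"PC{j + 1}"] = (
                round(100.0 * float(res.var_proportions[j]), 1)
                if j < res.n_components
                else np.nan
            )
        rows.append(row)
    return pd.DataFrame(rows)
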