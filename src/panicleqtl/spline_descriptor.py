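"""Unit-integral cubic-spline descriptors of organ distribution patterns.

A panicle with ``n`` primary branches is mapped onto the interval [0, 1]
(branch rank 1, at the distal end, sits at 0; the proximal branch at 1) and
each trait is modelled as

    y_i = alpha + sum_k beta_k b_k(x_i) + eps_i

where the ``b_k`` are ``K = df`` cubic B-spline basis functions with knots
evenly spaced on [0, 1] and *fixed across panicles*, so that coefficient
vectors from different panicles live in the same space and are directly
comparable.  The fitted curve is rescaled so its integral over [0, 1]
equals one; the rescaled coefficients (alpha', beta'_1..beta'_K) are the
*distribution descriptor* — a density-like summary of where along the
rachis the organ mass sits, independent of organ number or total size.

The model dimension ``df`` (number of non-intercept basis functions; the
intercept is always present) is chosen per trait from a small candidate set
by minimising the sum of per-panicle generalized cross-validation scores,
GCV = n * RSS / (n - edf)^2.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.interpolate import BSpline
from scipy.optimize import minimize_scalar

from panicleqtl.io_formats import PanicleDataset

logger = logging.getLogger(__name__)

_DEGREE = 3  # cubic


class DegeneratePanicleError(ValueError):
    """Panicle has too few branches to define a position axis or a fit."""


class NonPositiveMassError(ValueError):
    """Fitted curve has (near-)zero integral; cannot normalize to a density."""


def adjust_branch_positions(n_branches: int) -> np.ndarray:
    """Positions of branch ranks 1..n on [0, 1]: rank i sits at (i-1)/(n-1).

    Rank 1 is the distal-most primary branch (position 0) and rank n the
    proximal-most (position 1), so panicles with different branch numbers
    share a common axis.
    """
    if n_branches < 2:
        raise DegeneratePanicleError(
            f"need at least 2 primary branches to place positions, got {n_branches}"
        )
    return np.arange(n_branches) / (n_branches - 1)


@dataclass(frozen=True)
class SplineBasis:
    """Fixed cubic B-spline basis of model dimension ``df`` on [0, 1].

    ``df = K`` non-intercept basis functions; together with the intercept the
    design has K+1 columns.  ``integrals[k] = \\int_0^1 b_k(x) dx`` (exact,
    from the B-spline antiderivative) and ``penalty`` is the (K+1)x(K+1)
    Gram matrix of second derivatives of (1, b_1..b_K) used by the penalized
    fit mode.  The knots depend only on ``df``, never on the data, so every
    panicle fitted at the same ``df`` shares an identical basis.
    """

    df: int
    knots: np.ndarray
    integrals: np.ndarray  # length df
    penalty: np.ndarray  # (df+1, df+1)

    def evaluate(self, x: np.ndarray) -> np.ndarray:
        """Basis matrix [b_1(x) .. b_K(x)] without the intercept column."""
        x = np.asarray(x, dtype=float)
        full = BSpline.design_matrix(x, self.knots, _DEGREE).toarray()
        return full[:, 1:]  # drop the first B-spline; intercept supplies its role

    def design(self, x: np.ndarray) -> np.ndarray:
        """Full design matrix [1, b_1(x) .. b_K(x)]."""
        b = self.evaluate(x)
        return np.column_stack([np.ones(len(b)), b])


def _bspline_column(knots: np.ndarray, j: int) -> BSpline:
    n_basis = len(knots) - _DEGREE - 1
    coef = np.zeros(n_basis)
    coef[j] = 1.0
    return BSpline(knots, coef, _DEGREE)


def build_basis(df: int) -> SplineBasis:
    """Construct the shared basis for model dimension ``df`` (>= 3).

    A full cubic B-spline basis of size ``df + 1`` is built on evenly spaced
    knots spanning [0, 1] (``df - 3`` interior knots); its first member is
    dropped in favour of an explicit intercept.  Because B-splines sum to
    one, the constant function remains exactly in the span of
    (1, b_1..b_K).  The construction is fully deterministic.
    """
    if df < 3:
        raise ValueError(f"model dimension df must be >= 3 for a cubic basis, got {df}")
    n_interior = df - 3
    interior = np.linspace(0.0, 1.0, n_interior + 2)[1:-1]
    knots = np.concatenate([[0.0] * (_DEGREE + 1), interior, [1.0] * (_DEGREE + 1)])
    n_basis = df + 1
    integrals = np.empty(df)
    for k in range(1, n_basis):
        integrals[k - 1] = _bspline_column(knots, k).integrate(0.0, 1.0)
    penalty = _second_derivative_gram(knots, n_basis)
    return SplineBasis(df=df, knots=knots, integrals=integrals, penalty=penalty)


def _second_derivative_gram(knots: np.ndarray, n_basis: int) -> np.ndarray:
    """Gram matrix of second derivatives of (1, b_1..b_K) on [0, 1].

    Second derivatives of cubics are piecewise linear, so 3-point
    Gauss-Legendre per knot span integrates their products exactly.
    """
    spans = np.unique(knots)
    nodes, weights = np.polynomial.legendre.leggauss(3)
    d2 = []
    for j in range(1, n_basis):
        d2.append(_bspline_column(knots, j).derivative(2))
    gram = np.zeros((n_basis, n_basis))  # row/col 0 = intercept, stays zero
    for a, b in zip(spans[:-1], spans[1:]):
        xs = 0.5 * (b - a) * nodes + 0.5 * (a + b)
        ws = 0.5 * (b - a) * weights
        vals = np.array([f(xs) for f in d2])  # (K, 3)
        gram[1:, 1:] += (vals * ws) @ vals.T
    return gram


@dataclass
class SplineFit:
    """One panicle/trait spline fit: f(x) = alpha + sum_k betas[k] b_k(x)."""

    alpha: float
    betas: np.ndarray
    edf: float
    rss: float
    n_points: int
    lam: float
    basis: SplineBasis

    @property
    def coeffs(self) -> np.ndarray:
        return np.concatenate([[self.alpha], self.betas])

    def predict(self, x: np.ndarray) -> np.ndarray:
        return self.basis.design(np.asarray(x, dtype=float)) @ self.coeffs


def fit_smooth(
    x: np.ndarray,
    y: np.ndarray,
    basis: SplineBasis,
    mode: str = "regression",
) -> SplineFit:
    """Fit the spline model to one panicle's measurements.

    ``regression`` mode is ordinary least squares on (1, b_1..b_K) with
    ``edf = df + 1``; it requires at least df+1 points and a full-rank
    design.  ``penalized`` mode adds a second-derivative roughness penalty
    ``lam * c' P c`` with ``lam`` chosen by minimising this fit's GCV;
    ``edf`` is then the trace of the smoother matrix.  As ``lam`` grows the
    fit shrinks toward the least-squares straight line (the penalty's null
    space).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    n = len(x)
    if n < 2:
        raise DegeneratePanicleError(f"need at least 2 points to fit, got {n}")
    if np.any((x < 0) | (x > 1)):
        raise ValueError("positions must lie in [0, 1]")
    X = basis.design(x)
    p = X.shape[1]

    if mode == "regression":
        if n < p or np.linalg.matrix_rank(X) < p:
            raise np.linalg.LinAlgError(
                f"design is rank-deficient at df={basis.df} with n={n} points; "
                "use a smaller df"
            )
        coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ coef
        return SplineFit(
            alpha=float(coef[0]),
            betas=coef[1:],
            edf=float(p),
            rss=float(resid @ resid),
            n_points=n,
            lam=0.0,
            basis=basis,
        )
    if mode != "penalized":
        raise ValueError(f"unknown fit mode {mode!r}")

    XtX = X.T @ X
    Xty = X.T @ y
    P = basis.penalty

    def _solve(lam: float):
        A = XtX + lam * P
        coef = np.linalg.solve(A, Xty)
        # edf = tr(X A^-1 X') = tr(A^-1 X'X)
        edf = float(np.trace(np.linalg.solve(A, XtX)))
        resid = y - X @ coef
        rss = float(resid @ resid)
        return coef, edf, rss

    def _gcv(log_lam: float) -> float:
        _, edf, rss = _solve(np.exp(log_lam))
        denom = n - edf
        if denom <= 0:
            return np.inf
        return n * rss / denom**2

    grid = np.linspace(-10.0, 12.0, 45)
    scores = np.array([_gcv(g) for g in grid])
    i = int(np.argmin(scores))
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, len(grid) - 1)]
    res = minimize_scalar(_gcv, bounds=(lo, hi), method="bounded", options={"xatol": 1e-6})
    log_lam = res.x if res.fun <= scores[i] else grid[i]
    lam = float(np.exp(log_lam))
    coef, edf, rss = _solve(lam)
    return SplineFit(
        alpha=float(coef[0]),
        betas=coef[1:],
        edf=edf,
        rss=rss,
        n_points=n,
        lam=lam,
        basis=basis,
    )


def gcv_score(fit: SplineFit) -> float:
    """Generalized cross-validation score n*RSS/(n-edf)^2 of one fit.

    Saturated fits (n <= edf) have no information left for validation; they
    score ``inf`` and are excluded (with a warning) from per-trait sums.
    """
    denom = fit.n_points - fit.edf
    if denom <= 0:
        warnings.warn(
            f"GCV undefined for saturated fit (n={fit.n_points}, edf={fit.edf})",
            RuntimeWarning,
            stacklevel=2,
        )
        return np.inf
    return fit.n_points * fit.rss / denom**2


def select_df(
    dataset: PanicleDataset,
    trait: str,
    candidates: tuple[int, ...] = (3, 4, 5),
    mode: str = "regression",
    max_skip_fraction: float = 0.10,
) -> tuple[int, dict[int, float]]:
    """Choose the model dimension for one trait by summed GCV over panicles.

    Every plant's panicle is fitted at each candidate df; the candidate with
    the smallest total GCV wins, ties going to the smaller (more
    parsimonious) df.  Panicles whose GCV is non-finite at a candidate
    (saturated or rank-deficient fits) are dropped from that candidate's
    sum; a candidate missing more than ``max_skip_fraction`` of panicles is
    disqualified.  Returns ``(best_df, {df: gcv_sum})``.
    """
    if trait not in dataset.traits:
        raise KeyError(f"unknown trait {trait!r}")
    panicles = [
        (grp["rank"].to_numpy(), grp[trait].to_numpy(dtype=float))
        for _, grp in dataset.records.groupby(["line", "plant"], sort=True)
    ]
    n_panicles = len(panicles)
    sums: dict[int, float] = {}
    for df in sorted(candidates):
        basis = build_basis(df)
        total = 0.0
        n_skipped = 0
        for ranks, y in panicles:
            x = adjust_branch_positions(len(ranks))
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore", RuntimeWarning)
                    score = gcv_score(fit_smooth(x, y, basis, mode=mode))
            except (np.linalg.LinAlgError, DegeneratePanicleError):
                score = np.inf
            if np.isfinite(score):
                total += score
            else:
                n_skipped += 1
        if n_skipped:
            logger.info(
                "df=%d: %d/%d panicles excluded from GCV sum for %s",
                df, n_skipped, n_panicles, trait,
            )
        if n_skipped > max_skip_fraction * n_panicles:
            continue
        sums[df] = total
    if not sums:
        raise ValueError(
            f"no candidate df in {sorted(candidates)} is fittable for trait {trait!r}"
        )
    best = min(sums, key=lambda d: (sums[d], d))
    return best, sums


@dataclass
class DistributionDescriptor:
    """Unit-integral spline coefficients (alpha', beta'_1..beta'_K) for one trait.

    The descriptor is linear in the original fit coefficients (plain
    division by the curve's integral, no clipping), so principal-component
    reconstruction of descriptor vectors is exact.  Negative excursions of
    the normalized curve are retained.
    """

    trait: str
    coeffs: np.ndarray
    basis: SplineBasis

    @property
    def df(self) -> int:
        return self.basis.df

    def integral(self) -> float:
        return float(self.coeffs[0] + self.coeffs[1:] @ self.basis.integrals)


def curve_integral(coeffs: np.ndarray, basis: SplineBasis) -> float:
    """Exact integral over [0,1] of alpha + sum_k beta_k b_k."""
    coeffs = np.asarray(coeffs, dtype=float)
    return float(coeffs[0] + coeffs[1:] @ basis.integrals)


def normalize_to_density(
    fit: SplineFit, trait: str = "", eps: float = 1e-6, label: str = ""
) -> DistributionDescriptor:
    """Rescale a fitted curve so it integrates to one over [0, 1].

    Removes total-size information (organ number, summed length), leaving
    only the distribution pattern.  Curves whose integral is below ``eps``
    carry no usable mass and are rejected.
    """
    mass = curve_integral(fit.coeffs, fit.basis)
    if mass <= eps:
        raise NonPositiveMassError(
            f"fitted curve integral {mass:.3g} <= {eps:g}"
            + (f" for panicle {label}" if label else "")
        )
    return DistributionDescriptor(trait=trait, coeffs=fit.coeffs / mass, basis=fit.basis)


def describe_line(
    dataset: PanicleDataset,
    line_id: str,
    trait: str,
    df: int,
    mode: str = "regression",
    basis: SplineBasis | None = None,
) -> DistributionDescriptor:
    """Line-level descriptor: coefficient-wise mean of per-plant descriptors.

    Each replicate plant's panicle is fitted and normalized separately;
    averaging the normalized coefficients keeps the unit integral (the
    integral is linear in the coefficients).  Plants whose fit fails
    (too few branches for ``df``) are dropped with a warning.
    """
    if basis is None:
        basis = build_basis(df)
    coeff_rows = []
    for plant in dataset.plants(line_id):
        grp = dataset.panicle(line_id, plant)
        x = adjust_branch_positions(len(grp))
        y = grp[trait].to_numpy(dtype=float)
        try:
            fit = fit_smooth(x, y, basis, mode=mode)
            desc = normalize_to_density(fit, trait=trait, label=f"{line_id}/{plant}")
        except (np.linalg.LinAlgError, DegeneratePanicleError, NonPositiveMassError) as exc:
            logger.warning("line %s plant %s: %s (plant dropped)", line_id, plant, exc)
            continue
        coeff_rows.append(desc.coeffs)
    if not coeff_rows:
        raise ValueError(f"no fittable plant for line {line_id!r}, trait {trait!r}")
    mean_coeffs = np.mean(coeff_rows, axis=0)
    return DistributionDescriptor(trait=trait, coeffs=mean_coeffs, basis=basis)


def describe_dataset(
    dataset: PanicleDataset,
    trait: str,
    df: int | None = None,
    mode: str = "regression",
    candidates: tuple[int, ...] = (3, 4, 5),
) -> pd.DataFrame:
    """Descriptor matrix for all lines of one trait (rows = lines).

    When ``df`` is None it is first selected by summed GCV.  Columns are
    ``alpha`` and ``beta_1..beta_K``; this is the matrix handed to PCA.
    """
    if df is None:
        df, _ = select_df(dataset, trait, candidates=candidates, mode=mode)
    basis = build_basis(df)
    rows, index = [], []
    for line_id in dataset.lines:
        try:
            desc = describe_line(dataset, line_id, trait, df, mode=mode, basis=basis)
        except ValueError as exc:
            logger.warning("%s (line dropped for trait %s)", exc, trait)
            continue
        rows.append(desc.coeffs)
        index.append(line_id)
    cols = ["alpha"] + [f"beta_{k}" for k in range(1, df + 1)]
    out = pd.DataFrame(rows, index=pd.Index(index, name="line"), columns=cols)
    out.attrs["df"] = df
    out.attrs["trait"] = trait
    return out


def evaluate_curve(
    descriptor: DistributionDescriptor | np.ndarray,
    grid: np.ndarray,
    basis: SplineBasis | None = None,
) -> np.ndarray:
    """Evaluate alpha' + sum_k beta'_k b_k(x) on grid points in [0, 1].

    Accepts either a descriptor (carrying its basis) or a raw coefficient
    vector plus an explicit basis.  No extrapolation: points outside [0, 1]
    raise.
    """
    if isinstance(descriptor, DistributionDescriptor):
        coeffs, basis = descriptor.coeffs, descriptor.basis
    else:
        coeffs = np.asarray(descriptor, dtype=float)
        if basis is None:
            raise ValueError("a basis is required when passing raw coefficients")
    grid = np.asarray(grid, dtype=float)
    if np.any((grid < 0) | (grid > 1)):
        raise ValueError("grid points must lie in [0, 1]; no extrapolation")
    return basis.design(grid) @ coeffs


def write_descriptor_table(descriptors: pd.DataFrame, path) -> None:
    """Write a per-line descriptor matrix (one trait) with its df recorded."""
    out = descriptors.copy()
    out.insert(0, "trait", out.attrs.get("trait", ""))
    out["df"] = out.attrs.get("df", out.shape[1] - 2)
    out.to_csv(path)
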