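"""Single-QTL genome scan for backcross-derived inbred lines.

The population model is a BIL (backcross inbred line) panel: one backcross
of the F1 to the recurrent parent followed by repeated selfing, leaving
essentially homozygous lines with expected genotype frequencies 3/4
recurrent-parent homozygote and 1/4 donor homozygote at every locus.
Residual heterozygotes are rare (about (1/2)^7 per locus after six
selfings) and are treated as missing by default.

The scan pipeline is the classical interval-mapping stack:

* map distances from two-point recombination fractions via the Kosambi
  function d = 25 ln((1+2r)/(1-2r));
* a two-state hidden Markov model along each chromosome giving
  P(line genotype | marker data) on a cM grid (markers + pseudomarkers);
* at each grid position a two-component normal mixture (class means,
  common variance, mixture weights = the HMM probabilities) fitted by EM;
  LOD = log10 likelihood ratio against the single-normal null;
* genome-wide significance thresholds from permutations of the line
  phenotypes (labels permuted jointly across the genome, preserving
  marker correlation).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from panicleqtl.io_formats import P1_HOM, P2_HOM, GenotypeMatrix, LinkageMap

logger = logging.getLogger(__name__)

#: stationary genotype-class frequencies (recurrent hom, donor hom) after
#: one backcross and repeated selfing
BC1_PRIOR = np.array([0.75, 0.25])

_LN10 = np.log(10.0)


# ---------------------------------------------------------------------------
# map functions

def kosambi_distance(r) -> np.ndarray | float:
    """Kosambi map distance d = 25 ln((1+2r)/(1-2r)) in cM, for 0 <= r < 0.5."""
    r = np.asarray(r, dtype=float)
    if np.any((r < 0) | (r >= 0.5)):
        raise ValueError("recombination fraction must lie in [0, 0.5)")
    d = 25.0 * np.log((1.0 + 2.0 * r) / (1.0 - 2.0 * r))
    return float(d) if d.ndim == 0 else d


def kosambi_recfrac(d) -> np.ndarray | float:
    """Inverse Kosambi: r = tanh(2d/100)/2 for distances d >= 0 in cM."""
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise ValueError("map distance must be >= 0")
    r = 0.5 * np.tanh(2.0 * d / 100.0)
    return float(r) if r.ndim == 0 else r


# ---------------------------------------------------------------------------
# two-point map estimation

_R_MAX = 0.45  # cap for two-point estimates; beyond this linkage is essentially lost


def _r_from_discordance(D: float, expansion: str) -> float:
    """Invert the expected discordance between homozygous calls at linked loci.

    For lines fixed after a BC1 and repeated selfing the chance that two
    loci at recombination fraction r carry different parental alleles is
    D(r) = ((1-r) R + r) / 2 with the selfed-line expansion
    R = 2r/(1+2r) applied to the doubly heterozygous backcross progeny
    (``bc1_self``, the default for this population).  ``ril_self`` instead
    treats the observed discordance directly as R (plain selfed-RIL lines).
    """
    D = min(max(D, 0.0), 0.5)
    if expansion == "bc1_self":
        # D = 3r / (2 (1 + 2r))  =>  r = 2D / (3 - 4D)
        r = 2.0 * D / (3.0 - 4.0 * D)
    elif expansion == "ril_self":
        # R = 2r/(1+2r) with R = D  =>  r = D / (2 (1 - D))
        r = D / (2.0 * (1.0 - D)) if D < 1.0 else _R_MAX
    else:
        raise ValueError(f"unknown expansion model {expansion!r}")
    return min(r, _R_MAX)


def estimate_linkage_map(
    genotypes: GenotypeMatrix, expansion: str = "bc1_self"
) -> LinkageMap:
    """Linkage map from adjacent-marker discordance, Kosambi distances.

    Markers are taken in their stated within-chromosome order; for each
    adjacent pair the discordance fraction among lines with homozygous
    calls at both markers is inverted to a recombination fraction under the
    breeding-scheme expansion model, converted to cM via Kosambi and
    accumulated from 0.
    """
    calls = genotypes.calls.to_numpy()
    marker_ids = list(genotypes.calls.columns)
    col_of = {m: i for i, m in enumerate(marker_ids)}
    rows = []
    for chrom in genotypes.chromosomes:
        chrom_markers = genotypes.markers_on(chrom)
        pos = 0.0
        rows.append((chrom_markers[0], chrom, 0.0))
        for left, right in zip(chrom_markers[:-1], chrom_markers[1:]):
            a = calls[:, col_of[left]]
            b = calls[:, col_of[right]]
            ok = np.isin(a, (P1_HOM, P2_HOM)) & np.isin(b, (P1_HOM, P2_HOM))
            if not ok.any():
                raise ValueError(
                    f"markers {left!r} and {right!r} share no co-observed "
                    "homozygous lines; cannot estimate their distance"
                )
            D = float(np.mean(a[ok] != b[ok]))
            r = _r_from_discordance(D, expansion)
            pos += kosambi_distance(r)
            rows.append((right, chrom, pos))
    table = pd.DataFrame(rows, columns=["marker", "chromosome", "position_cm"])
    return LinkageMap(table.set_index("marker"))


# ---------------------------------------------------------------------------
# genotype probabilities (two-state HMM)

@dataclass
class GenoProbGrid:
    """Conditional genotype-class probabilities on a cM grid.

    ``positions`` has one row per grid position (chromosome, position_cm,
    nearest marker); ``probs`` is (n_lines, n_positions, 2) over the
    classes (recurrent hom, donor hom), each row summing to one.
    """

    positions: pd.DataFrame
    probs: np.ndarray
    lines: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        sums = self.probs.sum(axis=2)
        if not np.allclose(sums, 1.0, atol=1e-10):
            raise ValueError("genotype-class probabilities must sum to 1")

    @property
    def n_positions(self) -> int:
        return len(self.positions)

    def chromosome_slice(self, chrom) -> np.ndarray:
        return np.flatnonzero((self.positions["chromosome"] == chrom).to_numpy())


def _transition_matrices(dists_cm: np.ndarray) -> np.ndarray:
    """Per-interval 2x2 transitions between fixed-line genotypes.

    Derived from the two-locus joint distribution of the BC1-then-selfed
    scheme: with r the interval recombination fraction and R = 2r/(1+2r),
    the switch mass s = (1-r) R + r gives
    P(recurrent -> donor) = s/3 and P(donor -> recurrent) = s, which leaves
    the (3/4, 1/4) class frequencies stationary along the chromosome.
    """
    r = kosambi_recfrac(dists_cm)
    R = 2.0 * r / (1.0 + 2.0 * r)
    s = (1.0 - r) * R + r
    T = np.empty((len(np.atleast_1d(s)), 2, 2))
    s = np.atleast_1d(s)
    T[:, 0, 0] = 1.0 - s / 3.0
    T[:, 0, 1] = s / 3.0
    T[:, 1, 0] = s
    T[:, 1, 1] = 1.0 - s
    return T


def genotype_probabilities(
    genotypes: GenotypeMatrix,
    lmap: LinkageMap,
    step_cm: float = 1.0,
    error_rate: float = 1e-4,
) -> GenoProbGrid:
    """Forward-backward genotype-class probabilities at markers + pseudomarkers.

    Heterozygous calls are treated as missing (two-state model); missing
    calls are uninformative; observed calls are emitted with genotyping
    error rate ``error_rate``.  Pseudomarkers are placed every ``step_cm``
    from 0 to the end of each chromosome and merged with marker positions.
    """
    if step_cm <= 0:
        raise ValueError("step_cm must be > 0")
    unmapped = [m for m in genotypes.calls.columns if m not in lmap.table.index]
    if unmapped:
        raise ValueError(f"markers missing from the map: {unmapped[:5]}")
    calls_df = genotypes.calls
    n_lines = len(calls_df)
    pos_frames = []
    prob_blocks = []
    for chrom in genotypes.chromosomes:
        chrom_markers = genotypes.markers_on(chrom)
        marker_pos = lmap.table.loc[chrom_markers, "position_cm"].to_numpy(dtype=float)
        grid = np.arange(0.0, marker_pos[-1] + 1e-9, step_cm)
        all_pos = np.unique(np.round(np.concatenate([grid, marker_pos]), 9))
        # which grid index carries each marker
        marker_at = {}
        for mk, mp in zip(chrom_markers, marker_pos):
            marker_at.setdefault(int(np.argmin(np.abs(all_pos - mp))), []).append(mk)
        n_pos = len(all_pos)
        # emissions: (n_lines, n_pos, 2)
        emit = np.ones((n_lines, n_pos, 2))
        for idx, mks in marker_at.items():
            for mk in mks:
                obs = calls_df[mk].to_numpy()
                known = np.isin(obs, (P1_HOM, P2_HOM))
                is_p2 = obs == P2_HOM
                e = np.ones((n_lines, 2))
                e[known, 0] = np.where(is_p2[known], error_rate, 1.0 - error_rate)
                e[known, 1] = np.where(is_p2[known], 1.0 - error_rate, error_rate)
                emit[:, idx, :] *= e
        T = _transition_matrices(np.diff(all_pos))
        probs = _forward_backward(emit, T)
        nearest = []
        for i, p in enumerate(all_pos):
            j = int(np.argmin(np.abs(marker_pos - p)))
            nearest.append(chrom_markers[j])
        pos_frames.append(
            pd.DataFrame(
                {
                    "chromosome": chrom,
                    "position_cm": all_pos,
                    "nearest_marker": nearest,
                    "is_marker": [i in marker_at for i in range(n_pos)],
                }
            )
        )
        prob_blocks.append(probs)
    positions = pd.concat(pos_frames, ignore_index=True)
    return GenoProbGrid(
        positions=positions,
        probs=np.concatenate(prob_blocks, axis=1),
        lines=list(calls_df.index),
    )


def _forward_backward(emit: np.ndarray, T: np.ndarray) -> np.ndarray:
    """Scaled forward-backward over all lines at once.

    ``emit``: (n_lines, n_pos, 2); ``T``: (n_pos - 1, 2, 2).  Returns the
    smoothed posteriors, shape (n_lines, n_pos, 2).
    """
    n_lines, n_pos, _ = emit.shape
    alpha = np.empty_like(emit)
    a = BC1_PRIOR[None, :] * emit[:, 0, :]
    norm = a.sum(axis=1, keepdims=True)
    alpha[:, 0, :] = a / norm
    for t in range(1, n_pos):
        a = (alpha[:, t - 1, :] @ T[t - 1]) * emit[:, t, :]
        norm = a.sum(axis=1, keepdims=True)
        alpha[:, t, :] = a / norm
    beta = np.ones_like(emit)
    for t in range(n_pos - 2, -1, -1):
        b = (beta[:, t + 1, :] * emit[:, t + 1, :]) @ T[t].T
        beta[:, t, :] = b / b.sum(axis=1, keepdims=True)
    post = alpha * beta
    post /= post.sum(axis=2, keepdims=True)
    return post


# ---------------------------------------------------------------------------
# EM genome scan

@dataclass
class QTLScanResult:
    """LOD profile over the grid, with the threshold and peaks if computed."""

    table: pd.DataFrame  # chromosome, position_cm, nearest_marker, lod
    trait: str = ""
    threshold: float | None = None
    n_lines: int = 0

    @property
    def max_lod(self) -> float:
        return float(self.table["lod"].max())

    def chromosome(self, chrom) -> pd.DataFrame:
        return self.table[self.table["chromosome"] == chrom]


def _em_lods(
    y: np.ndarray, w: np.ndarray, max_iter: int = 100, tol: float = 1e-8
) -> np.ndarray:
    """Vectorised two-class normal-mixture EM at every grid position.

    ``y``: (n,) one phenotype, or (n, B) a batch of B phenotype vectors
    sharing the genotype probabilities (used for permutations);
    ``w``: (n, P, 2) per-line class weights per position.  The mixture at
    each position is y_i ~ sum_j w_ij N(mu_j, s2) with position-specific
    class means and a common variance.  Returns LOD per position, shape
    (P,) or (B, P), against the pooled single-normal null; EM starts from
    the prior weights and the result is floored at the null (LOD >= 0).
    """
    squeeze = y.ndim == 1
    Y = y[:, None] if squeeze else y  # (n, B)
    n, B = Y.shape
    mu0 = Y.mean(axis=0)
    s20 = np.mean((Y - mu0) ** 2, axis=0)  # (B,)
    if np.all(s20 <= 0):
        out = np.zeros((B, w.shape[1]))
        return out[0] if squeeze else out
    ll0 = -0.5 * n * (np.log(2.0 * np.pi * s20) + 1.0)  # (B,)
    P = w.shape[1]
    s2_floor = np.maximum(s20, 1e-300) * 1e-10
    ll_out = np.zeros((B, P))
    # EM over a shrinking active set of (batch column, position) pairs,
    # flattened so converged positions stop costing work
    yb = np.repeat(Y[:, :, None], P, axis=2).reshape(n, B * P)  # (n, B*P)
    wb = np.tile(w[:, None, :, :], (1, B, 1, 1)).reshape(n, B * P, 2)
    floor_b = np.repeat(s2_floor, P)
    active = np.arange(B * P)
    gamma = wb.copy()
    ll_flat = np.zeros(B * P)
    ll_prev = None
    for _ in range(max_iter):
        ya = yb[:, active]  # (n, A)
        wa = wb[:, active, :]  # (n, A, 2)
        gsum = np.maximum(gamma.sum(axis=0), 1e-300)  # (A, 2)
        mu = (gamma * ya[:, :, None]).sum(axis=0) / gsum
        resid2 = (ya[:, :, None] - mu[None]) ** 2  # (n, A, 2)
        s2 = np.maximum((gamma * resid2).sum(axis=(0, 2)) / n, floor_b[active])
        dens = np.exp(-0.5 * resid2 / s2[None, :, None]) / np.sqrt(2.0 * np.pi * s2)[None, :, None]
        mix = np.maximum((wa * dens).sum(axis=2), 1e-300)  # (n, A)
        ll = np.log(mix).sum(axis=0)  # (A,)
        gamma = wa * dens / mix[:, :, None]
        ll_flat[active] = ll
        if ll_prev is not None:
            still = np.abs(ll - ll_prev) >= tol
            if not still.any():
                break
            active = active[still]
            gamma = gamma[:, still, :]
            ll_prev = ll[still]
        else:
            ll_prev = ll
    lod = np.maximum((ll_flat.reshape(B, P) - ll0[:, None]) / _LN10, 0.0)
    return lod[0] if squeeze else lod


def scan_em(
    line_values: pd.Series | np.ndarray,
    probgrid: GenoProbGrid,
    max_iter: int = 100,
    tol: float = 1e-8,
    trait: str = "",
) -> QTLScanResult:
    """Single-QTL EM genome scan of one phenotype over the probability grid.

    ``line_values`` may be a Series indexed by line id (aligned to the
    grid's lines, missing lines dropped) or a bare array in grid order.
    At a fully informative position the EM solution coincides with
    single-marker regression, so LOD = (n/2) log10(RSS0/RSS1) there.
    """
    if isinstance(line_values, pd.Series):
        y = line_values.reindex(probgrid.lines).to_numpy(dtype=float)
    else:
        y = np.asarray(line_values, dtype=float)
        if len(y) != len(probgrid.lines):
            raise ValueError("phenotype length does not match grid lines")
    keep = np.isfinite(y)
    y = y[keep]
    if len(y) < 10:
        raise ValueError(f"need >= 10 phenotyped lines with genotypes, got {len(y)}")
    w = probgrid.probs[keep]  # (n, P, 2)
    if np.var(y) == 0.0:
        warnings.warn("phenotype has zero variance; LOD profile is all zero", RuntimeWarning)
        lod = np.zeros(probgrid.n_positions)
    else:
        lod = _em_lods(y, w, max_iter=max_iter, tol=tol)
    table = probgrid.positions[["chromosome", "position_cm", "nearest_marker"]].copy()
    table["lod"] = lod
    return QTLScanResult(table=table, trait=trait, n_lines=int(len(y)))


def permutation_threshold(
    line_values: pd.Series | np.ndarray,
    probgrid: GenoProbGrid,
    n_perm: int = 1000,
    alpha: float = 0.05,
    seed: int | np.random.Generator = 0,
    max_iter: int = 100,
    tol: float = 1e-8,
) -> tuple[float, np.ndarray]:
    """Genome-wide LOD threshold from phenotype permutations.

    Line labels are shuffled jointly across the whole genome, the scan is
    re-run, and the genome-wide maximum LOD recorded; the threshold is the
    empirical (1 - alpha) quantile (linear interpolation, R type 7) of
    those maxima.  Returns ``(threshold, max_lod_distribution)``.
    """
    if n_perm < 100:
        raise ValueError("use at least 100 permutations")
    if isinstance(line_values, pd.Series):
        y = line_values.reindex(probgrid.lines).to_numpy(dtype=float)
    else:
        y = np.asarray(line_values, dtype=float)
    keep = np.isfinite(y)
    y = y[keep]
    w = probgrid.probs[keep]
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    maxima = np.empty(n_perm)
    chunk = 32  # batch permutations through the vectorised EM
    for start in range(0, n_perm, chunk):
        b = min(chunk, n_perm - start)
        Yp = np.column_stack([rng.permutation(y) for _ in range(b)])
        lods = _em_lods(Yp, w, max_iter=max_iter, tol=tol)
        maxima[start : start + b] = lods.max(axis=1)
    threshold = float(np.quantile(maxima, 1.0 - alpha))
    return threshold, maxima


# ---------------------------------------------------------------------------
# peaks, intervals, effects

@dataclass
class QTLPeak:
    """One detected QTL: location, strength and allele effects."""

    trait: str
    chromosome: object
    position_cm: float
    nearest_marker: str
    lod: float
    pve: float
    support_interval: tuple[float, float]
    class_means: dict[str, tuple[float, float]]  # class -> (mean, se)


def lod_support_interval(
    scan: QTLScanResult, chromosome, peak_position: float, drop: float = 2.0
) -> tuple[float, float]:
    """Widest contiguous cM interval around the peak with LOD >= peak - drop.

    The interval is expanded to the nearest flanking grid positions where
    the profile falls below the cutoff (or to the chromosome ends).
    """
    sub = scan.chromosome(chromosome).reset_index(drop=True)
    pos = sub["position_cm"].to_numpy()
    lod = sub["lod"].to_numpy()
    i_peak = int(np.argmin(np.abs(pos - peak_position)))
    cutoff = lod[i_peak] - drop
    lo = i_peak
    while lo > 0 and lod[lo - 1] >= cutoff:
        lo -= 1
    hi = i_peak
    while hi < len(lod) - 1 and lod[hi + 1] >= cutoff:
        hi += 1
    # expand one step beyond the crossing, onto the flanking grid position
    lo = max(lo - 1, 0)
    hi = min(hi + 1, len(lod) - 1)
    return float(pos[lo]), float(pos[hi])


def allele_effects(
    line_values: pd.Series,
    genotypes: GenotypeMatrix,
    marker: str,
) -> dict[str, tuple[float, float]]:
    """Per-homozygous-class phenotype mean +/- SE at one marker.

    Heterozygous and missing lines are excluded; a class observed in fewer
    than two lines gets mean with SE = NaN (flagged by a warning).
    """
    calls = genotypes.calls[marker]
    out = {}
    for name, code in (("P1_HOM", P1_HOM), ("P2_HOM", P2_HOM)):
        lines = calls.index[calls == code]
        vals = line_values.reindex(lines).dropna()
        m = len(vals)
        if m == 0:
            out[name] = (float("nan"), float("nan"))
            continue
        mean = float(vals.mean())
        if m < 2:
            warnings.warn(f"class {name} at {marker} has {m} line(s); SE undefined", RuntimeWarning)
            out[name] = (mean, float("nan"))
        else:
            out[name] = (mean, float(vals.std(ddof=1) / np.sqrt(m)))
    return out


def pve_from_lod(lod: float, n_lines: int) -> float:
    """Proportion of phenotypic variance explained: 1 - 10^(-2 LOD / n)."""
    if lod < 0:
        raise ValueError("LOD must be >= 0")
    if n_lines < 2:
        raise ValueError("need at least 2 lines")
    return 1.0 - 10.0 ** (-2.0 * lod / n_lines)


def find_peaks(
    scan: QTLScanResult,
    threshold: float,
    line_values: pd.Series,
    genotypes: GenotypeMatrix,
    drop: float = 2.0,
) -> list[QTLPeak]:
    """One peak per chromosome above threshold, with PVE, support, effects."""
    peaks = []
    for chrom in dict.fromkeys(scan.table["chromosome"]):
        sub = scan.chromosome(chrom)
        i = sub["lod"].idxmax()
        row = sub.loc[i]
        if row["lod"] < threshold:
            continue
        interval = lod_support_interval(scan, chrom, row["position_cm"], drop=drop)
        effects = allele_effects(line_values, genotypes, row["nearest_marker"])
        peaks.append(
            QTLPeak(
                trait=scan.trait,
                chromosome=chrom,
                position_cm=float(row["position_cm"]),
                nearest_marker=str(row["nearest_marker"]),
                lod=float(row["lod"]),
                pve=pve_from_lod(float(row["lod"]), scan.n_lines),
                support_interval=interval,
                class_means=effects,
            )
        )
    return peaks


def peaks_table(peaks: list[QTLPeak]) -> pd.DataFrame:
    """Peaks as a flat report table (one row per QTL)."""
    rows = []
    for p in peaks:
        rows.append(
            {
                "trait": p.trait,
                "chromosome": p.chromosome,
                "nearest_marker": p.nearest_marker,
                "position_cm": round(p.position_cm, 1),
                "lod": round(p.lod, 3),
                "pve": round(p.pve, 3),
                "support_lo_cm": round(p.support_interval[0], 1),
                "support_hi_cm": round(p.support_interval[1], 1),
                "p1_mean": round(p.class_means["P1_HOM"][0], 3),
                "p1_se": round(p.class_means["P1_HOM"][1], 3),
                "p2_mean": round(p.class_means["P2_HOM"][0], 3),
                "p2_se": round(p.class_means["P2_HOM"][1], 3),
            }
        )
    return pd.DataFrame(rows)
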