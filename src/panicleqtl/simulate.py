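"""Synthetic BIL populations and panicles with planted number/pattern QTLs.

The generator mirrors the study design end to end so the whole pipeline is
testable without field data:

* **genomes** — 75 backcross inbred lines by default: an F1 between two
  inbred parents is backcrossed once to the recurrent parent and the
  progeny selfed for six generations (BC1F7).  Crossovers fall as a
  Poisson process on the centimorgan scale (no interference), realised at
  marker resolution via per-interval Haldane recombination fractions.
* **panicles** — each line carries a branch-position density d(x) on the
  distal(0)-proximal(1) axis and expected organ totals; a panicle with m
  primary branches puts expected value ``total * d(x_i)/sum_j d(x_j)`` on
  the branch at position x_i.  Branch lengths are gamma distributed with a
  configured coefficient of variation, counts negative binomial with a
  configured dispersion, spikelet counts floored at 1.
* **planted QTLs** — a *number* locus scales a line's expected totals by a
  genotype-dependent factor without touching the density; a *pattern*
  locus switches the density by genotype without touching the totals.
  This is the in-silico version of the organ-number / organ-pattern
  dissociation the pipeline is meant to detect.

All randomness flows from a single seed; identical configurations produce
identical datasets.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats

from panicleqtl.io_formats import (
    HET,
    P1_HOM,
    P2_HOM,
    GenotypeMatrix,
    LinkageMap,
    PanicleDataset,
)


# ---------------------------------------------------------------------------
# densities

@dataclass(frozen=True)
class BetaMixtureDensity:
    """Mixture of Beta densities on [0, 1]; integrates to one by construction."""

    alphas: tuple[float, ...]
    betas: tuple[float, ...]
    weights: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        w = self.weights or tuple([1.0 / len(self.alphas)] * len(self.alphas))
        object.__setattr__(self, "weights", tuple(np.asarray(w) / np.sum(w)))
        if len(self.alphas) != len(self.betas) or len(self.alphas) != len(self.weights):
            raise ValueError("alphas, betas and weights must have equal length")

    def pdf(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        out = np.zeros_like(x)
        for w, a, b in zip(self.weights, self.alphas, self.betas):
            out = out + w * stats.beta.pdf(x, a, b)
        return out


# Default density shapes, loosely following the two parental patterns seen
# in japonica x indica material: the recurrent parent lays organ mass
# proximally (rising toward x=1), the donor pattern is shifted distally.
# A uniform component keeps the density positive at both panicle ends —
# every primary branch carries at least some organ mass.
RECURRENT_DENSITY = BetaMixtureDensity(
    alphas=(2.0, 1.0), betas=(1.4, 1.0), weights=(0.85, 0.15)
)
DONOR_PATTERN_DENSITY = BetaMixtureDensity(
    alphas=(1.4, 1.0), betas=(2.0, 1.0), weights=(0.85, 0.15)
)

# Expected per-panicle organ totals for the recurrent-parent class, on the
# scale of a typical japonica panicle (lengths in cm, counts absolute).
DEFAULT_TOTALS = {
    "primary_branch_length": 92.0,
    "secondary_branch_number": 30.0,
    "spikelet_number": 162.0,
}


@dataclass
class QTLSpec:
    """One planted locus: ``kind`` is 'number' or 'pattern'.

    ``effect`` is the multiplicative ratio applied to all expected totals
    for donor homozygotes (number QTL) — heterozygotes get sqrt(effect) —
    or ignored for pattern QTLs, which switch the branch-position density
    to ``density`` for donor homozygotes.
    """

    chromosome: str
    position_cm: float
    kind: str
    effect: float = 1.45
    density: BetaMixtureDensity = DONOR_PATTERN_DENSITY

    def __post_init__(self) -> None:
        if self.kind not in ("number", "pattern"):
            raise ValueError(f"QTL kind must be 'number' or 'pattern', got {self.kind!r}")


@dataclass
class SimConfig:
    """Study-design parameters for one synthetic dataset.

    Defaults are the BIL panel design: 75 lines, 3 replicate plants, one
    backcross plus six selfing generations, markers every 5 cM.
    """

    seed: int = 0
    n_lines: int = 75
    n_plants: int = 3
    chromosomes: dict[str, float] = field(
        default_factory=lambda: {f"chr{i:02d}": 120.0 for i in range(1, 4)}
    )
    marker_spacing_cm: float = 5.0
    n_backcross: int = 1
    n_selfing: int = 6
    mean_branches: float = 11.0
    min_branches: int = 5
    totals: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_TOTALS))
    density: BetaMixtureDensity = RECURRENT_DENSITY
    length_cv: float = 0.20
    count_dispersion: float = 8.0
    qtls: list[QTLSpec] = field(default_factory=list)

    def __post_init__(self) -> None:
        if any(length <= 0 for length in self.chromosomes.values()):
            raise ValueError("chromosome lengths must be positive")
        if self.min_branches < 2:
            raise ValueError("panicles need at least 2 primary branches")


# ---------------------------------------------------------------------------
# genomes

def _haldane_recfrac(d_cm: np.ndarray) -> np.ndarray:
    return 0.5 * (1.0 - np.exp(-2.0 * d_cm / 100.0))


def _meiosis(hap_a: np.ndarray, hap_b: np.ndarray, r: np.ndarray, rng) -> np.ndarray:
    """Gametes from diploid parents, vectorised over individuals.

    ``hap_a, hap_b``: (n_ind, n_loci) parental haplotypes; ``r``: per-interval
    recombination fractions (n_loci - 1).  Crossovers are interference-free:
    the chosen strand switches independently between adjacent loci.
    """
    n_ind, n_loci = hap_a.shape
    start = rng.integers(0, 2, size=(n_ind, 1))
    switches = rng.random((n_ind, n_loci - 1)) < r[None, :]
    strand = (start + np.concatenate([np.zeros((n_ind, 1), dtype=int),
                                      np.cumsum(switches, axis=1)], axis=1)) % 2
    return np.where(strand == 0, hap_a, hap_b)


def simulate_genomes(
    config: SimConfig, rng: np.random.Generator | None = None
) -> tuple[GenotypeMatrix, LinkageMap]:
    """Simulate BC1-then-selfed line genomes and return calls + the true map."""
    rng = rng or np.random.default_rng(config.seed)
    marker_rows = []
    chrom_loci = {}
    for chrom, length in config.chromosomes.items():
        pos = np.arange(0.0, length + 1e-9, config.marker_spacing_cm)
        chrom_loci[chrom] = pos
        for j, p in enumerate(pos):
            marker_rows.append((f"{chrom}_m{j + 1:03d}", chrom, float(p), j))
    n = config.n_lines
    call_blocks = []
    for chrom, pos in chrom_loci.items():
        r = _haldane_recfrac(np.diff(pos))
        n_loci = len(pos)
        # F1: one haplotype from each parent (0 = recurrent allele, 1 = donor)
        f1_a = np.zeros((n, n_loci), dtype=int)
        f1_b = np.ones((n, n_loci), dtype=int)
        # backcross(es) to the recurrent parent
        hap_a, hap_b = f1_a, f1_b
        for _ in range(config.n_backcross):
            gamete = _meiosis(hap_a, hap_b, r, rng)
            hap_a, hap_b = gamete, np.zeros((n, n_loci), dtype=int)
        # selfing generations
        for _ in range(config.n_selfing):
            g1 = _meiosis(hap_a, hap_b, r, rng)
            g2 = _meiosis(hap_a, hap_b, r, rng)
            hap_a, hap_b = g1, g2
        total = hap_a + hap_b  # 0 recurrent hom, 1 het, 2 donor hom
        calls = np.where(total == 0, P1_HOM, np.where(total == 2, P2_HOM, HET))
        call_blocks.append(calls)
    markers = pd.DataFrame(
        marker_rows, columns=["marker", "chromosome", "position_cm", "order"]
    ).set_index("marker")
    lines = [f"BIL{i + 1:03d}" for i in range(n)]
    calls_df = pd.DataFrame(
        np.concatenate(call_blocks, axis=1), index=lines, columns=markers.index
    )
    geno = GenotypeMatrix(calls_df, markers[["chromosome", "order"]])
    lmap = LinkageMap(markers[["chromosome", "position_cm"]])
    return geno, lmap


# ---------------------------------------------------------------------------
# panicles

def simulate_panicle(
    density,
    n_branches: int,
    totals: dict[str, float],
    rng: np.random.Generator,
    length_cv: float = 0.20,
    count_dispersion: float | None = 8.0,
) -> pd.DataFrame:
    """One panicle's per-branch measurements from a branch-position density.

    Expected value on the branch at position x_i is
    ``total * d(x_i) / sum_j d(x_j)``.  ``length_cv=0`` and
    ``count_dispersion=None`` give the noise-free expectations (counts
    returned un-rounded), used for conservation checks.
    """
    if n_branches < 2:
        raise ValueError("a panicle needs at least 2 primary branches")
    x = np.arange(n_branches) / (n_branches - 1)
    d = density.pdf(x) if hasattr(density, "pdf") else np.asarray(density(x), dtype=float)
    if np.all(d <= 0):
        raise ValueError("density is non-positive at every branch position")
    d = np.clip(d, 0.0, None)
    wts = d / d.sum()
    rows = {"rank": np.arange(1, n_branches + 1)}
    mu_len = totals["primary_branch_length"] * wts
    if length_cv > 0:
        shape = 1.0 / length_cv**2
        lengths = rng.gamma(shape, mu_len / shape)
    else:
        lengths = mu_len
    rows["primary_branch_length"] = np.maximum(lengths, 1e-6)
    for trait, floor in (("secondary_branch_number", 0), ("spikelet_number", 1)):
        mu = totals[trait] * wts
        if count_dispersion is not None:
            theta = count_dispersion
            p = theta / (theta + np.maximum(mu, 1e-12))
            vals = rng.negative_binomial(theta, p).astype(float)
        else:
            vals = mu
        rows[trait] = np.maximum(vals, float(floor))
    return pd.DataFrame(rows)


def attach_qtl_effects(
    genotypes: GenotypeMatrix,
    lmap: LinkageMap,
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> tuple[PanicleDataset, dict]:
    """Simulate every line's panicles with genotype-dependent QTL effects.

    Each planted locus is snapped to its nearest marker; a line's totals
    and density are assembled from its genotypes at the planted loci, then
    each replicate plant's panicle is drawn independently.  Returns the
    dataset and a truth record (snapped positions, effects, seed).
    """
    rng = rng or np.random.default_rng(config.seed + 1)
    snapped = []
    for q in config.qtls:
        sub = lmap.table[lmap.table["chromosome"] == q.chromosome]
        if sub.empty:
            raise ValueError(f"QTL chromosome {q.chromosome!r} not on the map")
        if not (sub["position_cm"].min() - 1e-9 <= q.position_cm <= sub["position_cm"].max() + 1e-9):
            raise ValueError(
                f"QTL position {q.position_cm} cM outside chromosome {q.chromosome!r}"
            )
        marker = (sub["position_cm"] - q.position_cm).abs().idxmin()
        snapped.append((q, marker))
    records = []
    for line_id in genotypes.lines:
        totals = dict(config.totals)
        density = config.density
        for q, marker in snapped:
            call = genotypes.calls.at[line_id, marker]
            if q.kind == "number":
                if call == P2_HOM:
                    factor = q.effect
                elif call == HET:
                    factor = float(np.sqrt(q.effect))
                else:
                    factor = 1.0
                totals = {t: v * factor for t, v in totals.items()}
            else:  # pattern
                if call == P2_HOM:
                    density = q.density
        for plant in range(1, config.n_plants + 1):
            m = max(int(rng.poisson(config.mean_branches)), config.min_branches)
            pan = simulate_panicle(
                density,
                m,
                totals,
                rng,
                length_cv=config.length_cv,
                count_dispersion=config.count_dispersion,
            )
            pan.insert(0, "plant", f"p{plant}")
            pan.insert(0, "line", line_id)
            records.append(pan)
    dataset = PanicleDataset(pd.concat(records, ignore_index=True))
    truth = {
        "seed": config.seed,
        "n_lines": config.n_lines,
        "n_plants": config.n_plants,
        "qtls": [
            {
                "chromosome": q.chromosome,
                "position_cm": q.position_cm,
                "snapped_marker": marker,
                "kind": q.kind,
                "effect": q.effect,
                "density": None if q.kind == "number" else asdict(q.density),
            }
            for q, marker in snapped
        ],
        "base_density": asdict(config.density),
        "totals": config.totals,
    }
    return dataset, truth


def simulate_dataset(
    config: SimConfig,
) -> tuple[PanicleDataset, GenotypeMatrix, LinkageMap, dict]:
    """Full bundle: genomes, true map, phenotypes and the truth record."""
    rng = np.random.default_rng(config.seed)
    geno, lmap = simulate_genomes(config, rng)
    dataset, truth = attach_qtl_effects(geno, lmap, config, rng)
    return dataset, geno, lmap, truth


def write_truth(truth: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(truth, fh, indent=2, sort_keys=True)
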