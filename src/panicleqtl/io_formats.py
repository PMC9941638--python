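"""Tabular input/output and the validated data model.

Three tables drive the pipeline:

* a *panicle table* in long format — one row per primary branch, with the
  branch rank counted from the distal end of the rachis (rank 1 = tip) and
  the three per-branch measurements;
* a *genotype table* — rows are inbred lines, columns are biallelic markers,
  cells are symbols for the two parental homozygotes, heterozygotes and
  missing calls;
* a *map table* — marker, chromosome, genetic position in centimorgans.

All readers validate their input eagerly and raise :class:`FormatError` /
:class:`ValidationError` with the offending column, line or cell named, so
that malformed field data fails loudly before any model fitting starts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

# Canonical trait column names, in fixed order.
TRAITS = (
    "primary_branch_length",
    "secondary_branch_number",
    "spikelet_number",
)

#: Abbreviations used in figure labels and compact configs.
TRAIT_ABBREV = {
    "primary_branch_length": "PBL",
    "secondary_branch_number": "SBN",
    "spikelet_number": "SpN",
}

DEFAULT_COLUMNS = {
    "line": "line",
    "plant": "plant",
    "rank": "rank",
    "primary_branch_length": "pbl",
    "secondary_branch_number": "sbn",
    "spikelet_number": "spn",
}

# Genotype call codes (integer-encoded internally).
P1_HOM = 0  # recurrent-parent homozygote
HET = 1
P2_HOM = 2  # donor-parent homozygote
MISSING = -1

DEFAULT_CODE_MAP = {
    "A": "P1_HOM",
    "B": "P2_HOM",
    "H": "HET",
    "NA": "MISSING",
    "-": "MISSING",
    "": "MISSING",
}

_CODE_NAMES = {"P1_HOM": P1_HOM, "P2_HOM": P2_HOM, "HET": HET, "MISSING": MISSING}
_CODE_TO_NAME = {v: k for k, v in _CODE_NAMES.items()}
# dosage view: -1 recurrent hom, 0 het, +1 donor hom, NaN missing
_DOSAGE = {P1_HOM: -1.0, HET: 0.0, P2_HOM: 1.0, MISSING: np.nan}


class FormatError(ValueError):
    """A file does not have the expected layout (missing column, bad symbol)."""


class ValidationError(ValueError):
    """A file parses but violates a data-model invariant."""


@dataclass
class PanicleDataset:
    """Long-format per-branch measurements for a set of lines and plants.

    ``records`` holds one row per primary branch with canonical columns
    ``line, plant, rank`` plus the three trait columns; rank 1 is the branch
    at the distal end of the rachis.  Within each (line, plant) the ranks
    form a contiguous ``1..n`` sequence with ``n >= 2``.
    """

    records: pd.DataFrame
    traits: tuple[str, ...] = TRAITS

    def __post_init__(self) -> None:
        self.records = self.records.reset_index(drop=True)
        _validate_panicle_records(self.records, self.traits)
        self.records = self.records.sort_values(
            ["line", "plant", "rank"], kind="mergesort"
        ).reset_index(drop=True)

    @property
    def lines(self) -> list[str]:
        return sorted(self.records["line"].unique())

    def plants(self, line_id: str) -> list[str]:
        sub = self.records.loc[self.records["line"] == line_id, "plant"]
        if sub.empty:
            raise KeyError(f"no records for line {line_id!r}")
        return sorted(sub.unique())

    def panicle(self, line_id: str, plant_id: str) -> pd.DataFrame:
        mask = (self.records["line"] == line_id) & (self.records["plant"] == plant_id)
        sub = self.records.loc[mask]
        if sub.empty:
            raise KeyError(f"no records for line {line_id!r} plant {plant_id!r}")
        return sub.sort_values("rank")

    def __len__(self) -> int:
        return len(self.records)


def _validate_panicle_records(df: pd.DataFrame, traits: tuple[str, ...]) -> None:
    required = ["line", "plant", "rank", *traits]
    for col in required:
        if col not in df.columns:
            raise FormatError(f"panicle table is missing required column {col!r}")
    if df[["line", "plant", "rank"]].duplicated().any():
        dup = df[df[["line", "plant", "rank"]].duplicated()].iloc[0]
        raise ValidationError(
            f"duplicate branch record for line {dup['line']!r} plant "
            f"{dup['plant']!r} rank {dup['rank']}"
        )
    for (line, plant), grp in df.groupby(["line", "plant"], sort=False):
        ranks = np.sort(grp["rank"].to_numpy())
        n = len(ranks)
        if n < 2:
            raise ValidationError(
                f"line {line!r} plant {plant!r} has {n} branch record(s); "
                "a panicle needs at least 2 primary branches"
            )
        if not np.array_equal(ranks, np.arange(1, n + 1)):
            raise ValidationError(
                f"line {line!r} plant {plant!r} has non-contiguous branch ranks "
                f"{ranks.tolist()}; expected 1..{n}"
            )
    if (df["primary_branch_length"] <= 0).any():
        bad = df.loc[df["primary_branch_length"] <= 0].iloc[0]
        raise ValidationError(
            f"non-positive primary branch length for line {bad['line']!r} "
            f"plant {bad['plant']!r} rank {bad['rank']}"
        )
    if (df["secondary_branch_number"] < 0).any():
        raise ValidationError("negative secondary branch count")
    if (df["spikelet_number"] < 1).any():
        bad = df.loc[df["spikelet_number"] < 1].iloc[0]
        raise ValidationError(
            f"spikelet count below 1 for line {bad['line']!r} plant "
            f"{bad['plant']!r} rank {bad['rank']}"
        )


def read_panicle_table(
    path,
    columns: dict[str, str] | None = None,
    delimiter: str = ",",
) -> PanicleDataset:
    """Read a long-format per-branch CSV into a validated :class:`PanicleDataset`.

    ``columns`` maps canonical names (``line, plant, rank,
    primary_branch_length, secondary_branch_number, spikelet_number``) to the
    header names actually used in the file; unspecified entries fall back to
    the short defaults (``pbl, sbn, spn``).
    """
    colmap = dict(DEFAULT_COLUMNS)
    if columns:
        colmap.update(columns)
    df = pd.read_csv(path, sep=delimiter, dtype={colmap["line"]: str, colmap["plant"]: str})
    rename = {}
    for canonical, actual in colmap.items():
        if actual not in df.columns:
            raise FormatError(
                f"panicle table {path} is missing column {actual!r} "
                f"(expected for field {canonical!r})"
            )
        rename[actual] = canonical
    df = df.rename(columns=rename)[list(colmap)]
    df["rank"] = df["rank"].astype(int)
    return PanicleDataset(df)


def write_panicle_table(dataset: PanicleDataset, path, columns=None, delimiter=",") -> None:
    """Write a dataset back to CSV, inverse of :func:`read_panicle_table`."""
    colmap = dict(DEFAULT_COLUMNS)
    if columns:
        colmap.update(columns)
    out = dataset.records.rename(columns=colmap)
    out.to_csv(path, sep=delimiter, index=False)


@dataclass
class GenotypeMatrix:
    """Biallelic marker calls for inbred lines.

    ``calls`` is lines x markers with integer codes ``P1_HOM=0, HET=1,
    P2_HOM=2, MISSING=-1``; ``markers`` carries chromosome assignment and
    within-chromosome order.
    """

    calls: pd.DataFrame  # index: lines, columns: marker ids
    markers: pd.DataFrame  # index: marker ids; columns: chromosome, order

    def __post_init__(self) -> None:
        if list(self.calls.columns) != list(self.markers.index):
            raise ValidationError("genotype calls and marker table disagree on markers")
        for chrom, grp in self.markers.groupby("chromosome", sort=False):
            order = grp["order"].to_numpy()
            if not np.all(np.diff(order) > 0):
                raise ValidationError(
                    f"marker order not strictly increasing on chromosome {chrom}"
                )
        bad = ~self.calls.isin([P1_HOM, HET, P2_HOM, MISSING]).to_numpy()
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValidationError(
                f"invalid call code at line {self.calls.index[i]!r} marker "
                f"{self.calls.columns[j]!r}"
            )

    @property
    def lines(self) -> list[str]:
        return list(self.calls.index)

    @property
    def chromosomes(self) -> list:
        return list(dict.fromkeys(self.markers["chromosome"]))

    def markers_on(self, chromosome) -> list[str]:
        grp = self.markers[self.markers["chromosome"] == chromosome]
        return list(grp.sort_values("order").index)

    def dosage(self) -> pd.DataFrame:
        """Numeric view: -1 recurrent hom, 0 het, +1 donor hom, NaN missing."""
        return self.calls.replace(_DOSAGE).astype(float)


def read_genotype_table(
    path,
    code_map: dict[str, str] | None = None,
    strict: bool = True,
    marker_info: pd.DataFrame | None = None,
    delimiter: str = ",",
) -> GenotypeMatrix:
    """Read a lines x markers CSV of genotype symbols.

    The first column holds line identifiers.  ``code_map`` maps file symbols
    to the call names ``P1_HOM / P2_HOM / HET / MISSING`` (default letters
    A/B/H plus NA).  Unknown symbols raise a :class:`FormatError` naming the
    cell when ``strict``; otherwise they become missing with a warning.
    ``marker_info`` (marker-indexed, columns chromosome/order) may be given
    directly; if omitted, every marker goes on one pseudo-chromosome in file
    order and the map table supplies real assignments later.
    """
    cmap = dict(DEFAULT_CODE_MAP)
    if code_map:
        cmap.update(code_map)
    raw = pd.read_csv(path, sep=delimiter, index_col=0, dtype=str, keep_default_na=False)
    raw.index = raw.index.astype(str)
    calls = np.full(raw.shape, MISSING, dtype=int)
    arr = raw.to_numpy()
    known = {sym: _CODE_NAMES[name] for sym, name in cmap.items()}
    for sym, code in known.items():
        calls[arr == sym] = code
    unknown_mask = ~np.isin(arr, list(known))
    if unknown_mask.any():
        i, j = np.argwhere(unknown_mask)[0]
        msg = (
            f"unknown genotype symbol {arr[i, j]!r} at line {raw.index[i]!r} "
            f"marker {raw.columns[j]!r}"
        )
        if strict:
            raise FormatError(msg)
        logger.warning("%s; treated as missing", msg)
    calls_df = pd.DataFrame(calls, index=raw.index, columns=raw.columns)
    if marker_info is None:
        marker_info = pd.DataFrame(
            {"chromosome": ["un"] * raw.shape[1], "order": np.arange(raw.shape[1])},
            index=raw.columns,
        )
    return GenotypeMatrix(calls_df, marker_info.loc[raw.columns])


def write_genotype_table(
    geno: GenotypeMatrix, path, code_map: dict[str, str] | None = None, delimiter: str = ","
) -> None:
    """Write genotype calls as symbols, inverse of :func:`read_genotype_table`."""
    cmap = dict(DEFAULT_CODE_MAP)
    if code_map:
        cmap.update(code_map)
    # first symbol mapping to each call name wins
    sym_for: dict[int, str] = {}
    for sym, name in cmap.items():
        code = _CODE_NAMES[name]
        sym_for.setdefault(code, sym)
    out = geno.calls.replace({c: sym_for[c] for c in (P1_HOM, HET, P2_HOM, MISSING)})
    out.index.name = "line"
    out.to_csv(path, sep=delimiter)


@dataclass
class LinkageMap:
    """Genetic positions (cM) of the markers, grouped by chromosome."""

    table: pd.DataFrame  # index: marker ids; columns: chromosome, position_cm

    def __post_init__(self) -> None:
        for chrom, grp in self.table.groupby("chromosome", sort=False):
            pos = grp["position_cm"].to_numpy(dtype=float)
            if np.any(np.diff(pos) < 0):
                raise ValidationError(f"map positions decrease on chromosome {chrom}")
            if len(pos) and abs(pos[0]) > 1e-9:
                raise ValidationError(
                    f"first marker of chromosome {chrom} must sit at 0 cM, got {pos[0]}"
                )

    @property
    def chromosomes(self) -> list:
        return list(dict.fromkeys(self.table["chromosome"]))

    def positions(self, chromosome) -> pd.Series:
        grp = self.table[self.table["chromosome"] == chromosome]
        return grp["position_cm"]


def read_map_table(path, delimiter: str = ",") -> LinkageMap:
    df = pd.read_csv(path, sep=delimiter)
    for col in ("marker", "chromosome", "position_cm"):
        if col not in df.columns:
            raise FormatError(f"map table is missing required column {col!r}")
    df = df.set_index("marker")
    return LinkageMap(df[["chromosome", "position_cm"]])


def write_map_table(lmap: LinkageMap, path, delimiter: str = ",") -> None:
    out = lmap.table.copy()
    out.index.name = "marker"
    out.to_csv(path, sep=delimiter)


# Total ("organ number") traits derived from the per-branch table, in the
# order they are conventionally reported.
TOTAL_TRAITS = (
    "primary_branch_number",
    "total_primary_branch_length",
    "total_secondary_branch_number",
    "total_spikelet_number",
)


def compute_organ_totals(dataset: PanicleDataset, per_plant: bool = False) -> pd.DataFrame:
    """Per-line organ totals: branch number and summed lengths/counts.

    Each plant's panicle contributes its primary branch count, summed branch
    length, summed secondary branch count and summed spikelet count; the line
    value is the unweighted mean over that line's plants (replicate numbers
    may differ between lines).  With ``per_plant=True`` the plant-level table
    is returned instead.
    """
    grp = dataset.records.groupby(["line", "plant"])
    plant_totals = pd.DataFrame(
        {
            "primary_branch_number": grp.size().astype(float),
            "total_primary_branch_length": grp["primary_branch_length"].sum(),
            "total_secondary_branch_number": grp["secondary_branch_number"].sum().astype(float),
            "total_spikelet_number": grp["spikelet_number"].sum().astype(float),
        }
    )
    if per_plant:
        return plant_totals
    return plant_totals.groupby(level="line").mean().sort_index()
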