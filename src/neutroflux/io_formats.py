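"""Readers and writers for every on-disk artifact the pipeline touches.

All formats are plain tab-delimited text with headers. Spot tables may be
split one-file-per-array or concatenated into one long file with an
``array_id`` column; both are normalized to the long form on read.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from neutroflux.errors import FormatError, IntegrityError

logger = logging.getLogger(__name__)

GROUP_LABELS = ("SHAM", "LPS_PMN", "LPS_NOPMN")
SPOT_KINDS = ("regular", "positive_control", "negative_control")

SPOT_COLUMNS = [
    "array_id",
    "spot_id",
    "probe_id",
    "gene_symbol",
    "spot_kind",
    "sample_signal",
    "reference_signal",
]

#: Raw signals at or below zero (possible after upstream background
#: subtraction) are raised to this floor so the ln transform stays total.
SIGNAL_FLOOR = 1.0


# ---------------------------------------------------------------------------
# Domain containers
# ---------------------------------------------------------------------------


@dataclass
class SpotTable:
    """Per-spot two-channel fluorescence records for one or more arrays.

    ``data`` is a long-form frame with exactly the columns in
    :data:`SPOT_COLUMNS`; ``(array_id, spot_id)`` is unique and every array
    carries the identical spot set.
    """

    data: pd.DataFrame
    n_floored: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        missing = [c for c in SPOT_COLUMNS if c not in self.data.columns]
        if missing:
            raise FormatError(f"spot table missing column(s): {', '.join(missing)}")
        self.data = self.data[SPOT_COLUMNS].reset_index(drop=True)
        dup = self.data.duplicated(subset=["array_id", "spot_id"])
        if dup.any():
            pair = self.data.loc[dup.idxmax(), ["array_id", "spot_id"]]
            raise IntegrityError(
                f"duplicated (array_id, spot_id): ({pair['array_id']}, {pair['spot_id']})"
            )
        bad_kind = set(self.data["spot_kind"]) - set(SPOT_KINDS)
        if bad_kind:
            raise FormatError(
                f"unknown spot_kind {sorted(bad_kind)}; allowed: {list(SPOT_KINDS)}"
            )
        spot_sets = self.data.groupby("array_id", sort=False)["spot_id"].apply(
            lambda s: tuple(sorted(s))
        )
        if spot_sets.nunique() > 1:
            raise IntegrityError(
                "arrays carry different spot sets; every array must share "
                "the identical spot_ids"
            )
        for col in ("sample_signal", "reference_signal"):
            vals = self.data[col].to_numpy(dtype=float)
            if not np.isfinite(vals).all():
                raise FormatError(f"non-finite values in column {col}")
            if (vals <= 0).any():
                raise IntegrityError(
                    f"nonpositive {col} after floor policy; floor signals first"
                )

    @property
    def array_ids(self) -> list[str]:
        return list(dict.fromkeys(self.data["array_id"]))

    @property
    def spot_ids(self) -> list[str]:
        first = self.data["array_id"].iloc[0]
        return list(self.data.loc[self.data["array_id"] == first, "spot_id"])

    def regular(self) -> pd.DataFrame:
        """Rows for regular (non-control) spots."""
        return self.data[self.data["spot_kind"] == "regular"]

    def __len__(self) -> int:
        return len(self.data)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SpotTable):
            return NotImplemented
        a = self.data.sort_values(["array_id", "spot_id"]).reset_index(drop=True)
        b = other.data.sort_values(["array_id", "spot_id"]).reset_index(drop=True)
        if not a[SPOT_COLUMNS[:5]].equals(b[SPOT_COLUMNS[:5]]):
            return False
        return bool(
            np.allclose(a["sample_signal"], b["sample_signal"], rtol=0, atol=1e-9)
            and np.allclose(a["reference_signal"], b["reference_signal"], rtol=0, atol=1e-9)
        )


@dataclass
class StudyDesign:
    """Mapping of sample_id to experimental group."""

    groups: Mapping[str, str]  # sample_id -> group label

    def __post_init__(self) -> None:
        bad = set(self.groups.values()) - set(GROUP_LABELS)
        if bad:
            raise FormatError(
                f"unknown group label(s) {sorted(bad)}; allowed: {list(GROUP_LABELS)}"
            )
        for label in GROUP_LABELS:
            if label not in self.groups.values():
                raise IntegrityError(f"group {label} has no samples")
        self.groups = dict(self.groups)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.groups)

    def samples_in(self, group: str) -> list[str]:
        if group not in GROUP_LABELS:
            raise KeyError(f"unknown group {group!r}; allowed: {list(GROUP_LABELS)}")
        return [s for s, g in self.groups.items() if g == group]

    def __len__(self) -> int:
        return len(self.groups)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, StudyDesign):
            return NotImplemented
        return dict(self.groups) == dict(other.groups)


@dataclass
class GeneSetCollection:
    """Named gene sets with descriptions; members deduplicated, order kept."""

    sets: dict[str, tuple[str, list[str]]] = field(default_factory=dict)

    def add(self, name: str, description: str, members: Iterable[str]) -> None:
        deduped = list(dict.fromkeys(members))
        if not deduped:
            raise IntegrityError(f"gene set {name!r} is empty")
        self.sets[name] = (description, deduped)

    def members(self, name: str) -> list[str]:
        return self.sets[name][1]

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.items())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GeneSetCollection):
            return NotImplemented
        return self.sets == other.sets


@dataclass
class PhenotypeTable:
    """Per-animal phenotype markers.

    Columns: sample_id, mpo_balf_activity (mU/ml, NaN = below detection),
    mpo_lung_protein (ng MPO/mg protein), m1dg (adducts per 1e8 nt).
    """

    data: pd.DataFrame

    COLUMNS = ["sample_id", "mpo_balf_activity", "mpo_lung_protein", "m1dg"]

    def __post_init__(self) -> None:
        missing = [c for c in self.COLUMNS if c not in self.data.columns]
        if missing:
            raise FormatError(f"phenotype table missing column(s): {', '.join(missing)}")
        self.data = self.data[self.COLUMNS].reset_index(drop=True)
        if self.data["sample_id"].duplicated().any():
            raise IntegrityError("duplicate sample_id in phenotype table")
        m1dg = self.data["m1dg"].to_numpy(dtype=float)
        if not (np.isfinite(m1dg) & (m1dg > 0)).all():
            raise IntegrityError("m1dg must be finite and strictly positive")
        mpo = self.data[["mpo_balf_activity", "mpo_lung_protein"]].to_numpy(dtype=float)
        if (mpo[np.isfinite(mpo)] < 0).any():
            raise IntegrityError("MPO measurements must be >= 0")

    def marker(self, name: str, below_detection_value: float = 0.0) -> pd.Series:
        """Marker values indexed by sample_id; NaN (below detection) substituted."""
        if name not in self.COLUMNS[1:]:
            raise KeyError(f"unknown marker {name!r}; allowed: {self.COLUMNS[1:]}")
        series = self.data.set_index("sample_id")[name].astype(float)
        n_bd = int(series.isna().sum())
        if n_bd:
            logger.info(
                "marker %s: %d below-detection value(s) substituted with %g",
                name, n_bd, below_detection_value,
            )
        return series.fillna(below_detection_value)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PhenotypeTable):
            return NotImplemented
        a = self.data.sort_values("sample_id").reset_index(drop=True)
        b = other.data.sort_values("sample_id").reset_index(drop=True)
        if not a["sample_id"].equals(b["sample_id"]):
            return False
        x = a[self.COLUMNS[1:]].to_numpy(dtype=float)
        y = b[self.COLUMNS[1:]].to_numpy(dtype=float)
        both_nan = np.isnan(x) & np.isnan(y)
        return bool(np.all(both_nan | np.isclose(x, y, rtol=0, atol=1e-9, equal_nan=False)))


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------


def _floor_signals(df: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    n = 0
    for col in ("sample_signal", "reference_signal"):
        vals = df[col].to_numpy(dtype=float)
        low = vals <= 0
        n += int(low.sum())
        vals[low] = SIGNAL_FLOOR
        df[col] = vals
    return df, n


def read_spot_tables(paths: Sequence[str | Path] | str | Path) -> SpotTable:
    """Read one or more tab-delimited spot tables into a single :class:`SpotTable`.

    Accepts a single long file or one file per array; files missing the
    ``array_id`` column use the file stem as array_id. Signals at or below
    zero are floored to :data:`SIGNAL_FLOOR` with a logged count.
    """
    if isinstance(paths, (str, Path)):
        paths = [paths]
    frames = []
    for path in paths:
        path = Path(path)
        df = pd.read_csv(path, sep="\t", dtype={"gene_symbol": str}, keep_default_na=False)
        if "array_id" not in df.columns:
            df.insert(0, "array_id", path.stem)
        missing = [c for c in SPOT_COLUMNS if c not in df.columns]
        if missing:
            raise FormatError(f"{path}: missing column(s): {', '.join(missing)}")
        frames.append(df[SPOT_COLUMNS])
    merged = pd.concat(frames, ignore_index=True)
    merged["gene_symbol"] = merged["gene_symbol"].fillna("").astype(str)
    for col in ("sample_signal", "reference_signal"):
        merged[col] = pd.to_numeric(merged[col], errors="raise")
    merged, n_floored = _floor_signals(merged)
    if n_floored:
        logger.info("floored %d nonpositive signal(s) to %g", n_floored, SIGNAL_FLOOR)
    return SpotTable(merged, n_floored=n_floored)


def write_spot_table(table: SpotTable, path: str | Path) -> None:
    table.data.to_csv(path, sep="\t", index=False)


def read_design(path: str | Path) -> StudyDesign:
    """Read a two-column sample_id/group table."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("sample_id", "group"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing column {col}")
    if df["sample_id"].duplicated().any():
        raise IntegrityError(f"{path}: duplicate sample_id")
    return StudyDesign(dict(zip(df["sample_id"], df["group"])))


def write_design(design: StudyDesign, path: str | Path) -> None:
    pd.DataFrame(
        {"sample_id": design.sample_ids, "group": [design.groups[s] for s in design.sample_ids]}
    ).to_csv(path, sep="\t", index=False)


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a standard GMT file: name TAB description TAB member..."""
    collection = GeneSetCollection()
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}:{lineno}: GMT line has {len(fields)} field(s), "
                    "expected name, description and at least one member"
                )
            name, description, *members = fields
            members = [m for m in members if m]
            before = len(members)
            collection.add(name, description, members)
            after = len(collection.members(name))
            if after < before:
                logger.info("set %s: deduplicated %d member(s)", name, before - after)
    if len(collection) == 0:
        logger.warning("%s: empty gene-set collection", path)
    return collection


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as handle:
        for name, (description, members) in collection:
            handle.write("\t".join([name, description, *members]) + "\n")


def read_phenotypes(path: str | Path) -> PhenotypeTable:
    """Read a phenotype TSV; empty MPO fields mean below detection."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    return PhenotypeTable(df)


def write_phenotypes(table: PhenotypeTable, path: str | Path) -> None:
    table.data.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_annotation(path: str | Path) -> pd.DataFrame:
    """Read a probe_id -> gene_symbol annotation table."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in ("probe_id", "gene_symbol"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing column {col}")
    if df["probe_id"].duplicated().any():
        raise IntegrityError(f"{path}: duplicate probe_id")
    return df[["probe_id", "gene_symbol"]]


def write_annotation(annotation: pd.DataFrame, path: str | Path) -> None:
    annotation.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Expression matrices
# ---------------------------------------------------------------------------


def write_matrix(matrix: pd.DataFrame, path: str | Path) -> None:
    """Write a genes x samples matrix as TSV (gene symbols as row labels)."""
    if matrix.index.duplicated().any():
        dup = matrix.index[matrix.index.duplicated()][0]
        raise IntegrityError(f"duplicate gene symbol {dup!r}; collapse genes first")
    out = matrix.copy()
    out.index.name = "gene_symbol"
    out.to_csv(path, sep="\t", float_format="%.12g")


def read_matrix(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    if df.index.duplicated().any():
        raise IntegrityError(f"{path}: duplicate gene symbols")
    if not np.isfinite(df.to_numpy(dtype=float)).all():
        raise FormatError(f"{path}: non-finite expression values")
    return df
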