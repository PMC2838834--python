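"""Median-per-group fold-change differential expression.

Three fixed contrasts over the natural-log expression matrix:

* A = LPS_PMN - SHAM
* B = LPS_NOPMN - SHAM
* C = LPS_PMN - LPS_NOPMN

Genes are called differentially expressed by fold change alone (default:
strictly greater than 1.5-fold), and the three DE sets are partitioned into
the 7 disjoint Venn regions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from neutroflux.errors import ConfigError, IntegrityError
from neutroflux.io_formats import StudyDesign

#: contrast id -> (first group, second group); log-ratio = first - second
CONTRASTS: dict[str, tuple[str, str]] = {
    "A": ("LPS_PMN", "SHAM"),
    "B": ("LPS_NOPMN", "SHAM"),
    "C": ("LPS_PMN", "LPS_NOPMN"),
}

REGIONS = ("A_only", "B_only", "C_only", "AB", "AC", "BC", "ABC")


def group_medians(matrix: pd.DataFrame, design: StudyDesign) -> pd.DataFrame:
    """Per-gene median log expression for each experimental group."""
    missing = [s for s in matrix.columns if s not in design.groups]
    if missing:
        raise IntegrityError(f"samples absent from design: {missing}")
    cols = {}
    for group in dict.fromkeys(design.groups.values()):
        samples = [s for s in matrix.columns if design.groups[s] == group]
        if not samples:
            raise IntegrityError(f"group {group} has no samples in the matrix")
        cols[group] = matrix[samples].median(axis=1)
    return pd.DataFrame(cols, index=matrix.index)


def contrast_fold_changes(medians: pd.DataFrame, contrast: str) -> pd.DataFrame:
    """Log-ratio, linear fold change (>= 1) and direction for one contrast."""
    first, second = CONTRASTS[contrast]
    log_ratio = medians[first] - medians[second]
    fold = np.exp(log_ratio.abs())
    direction = pd.Series(
        np.where(log_ratio > 0, "up", np.where(log_ratio < 0, "down", "none")),
        index=medians.index,
    )
    return pd.DataFrame(
        {"log_ratio": log_ratio, "fold_change": fold, "direction": direction}
    )


def contrast_table(medians: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """All three contrasts keyed by contrast id."""
    return {c: contrast_fold_changes(medians, c) for c in CONTRASTS}


def call_de(
    table: dict[str, pd.DataFrame], threshold: float = 1.5, strict: bool = True
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Flag DE genes per contrast and tally counts by direction.

    ``strict`` (default) requires fold change strictly above the threshold;
    with ``strict=False`` the comparison is >=.
    """
    if threshold <= 1:
        raise ConfigError(f"fold-change threshold must be > 1, got {threshold}")
    flags = {}
    counts = []
    for contrast, frame in table.items():
        fc = frame["fold_change"]
        flag = fc > threshold if strict else fc >= threshold
        flags[contrast] = flag
        up = int((flag & (frame["direction"] == "up")).sum())
        down = int((flag & (frame["direction"] == "down")).sum())
        counts.append((contrast, int(flag.sum()), up, down))
    flag_frame = pd.DataFrame(flags)
    count_frame = pd.DataFrame(counts, columns=["contrast", "n_de", "n_up", "n_down"])
    return flag_frame, count_frame.set_index("contrast")


@dataclass
class VennPartition:
    """The 7 disjoint regions induced by the three DE sets, plus their union."""

    members: dict[str, list[str]]  # region -> sorted gene symbols

    @property
    def counts(self) -> dict[str, int]:
        return {region: len(genes) for region, genes in self.members.items()}

    @property
    def union_count(self) -> int:
        return sum(self.counts.values())

    @property
    def union(self) -> list[str]:
        return sorted(g for genes in self.members.values() for g in genes)

    def set_size(self, contrast: str) -> int:
        letter = contrast.upper()
        return sum(
            len(genes) for region, genes in self.members.items()
            if letter in region.replace("_only", "")
        )


def venn_partition(
    flags_a: pd.Series, flags_b: pd.Series, flags_c: pd.Series
) -> VennPartition:
    """Partition three boolean DE flag vectors over a common gene universe."""
    universe = set(flags_a.index)
    if set(flags_b.index) != universe or set(flags_c.index) != universe:
        raise IntegrityError("DE flag vectors are over different gene universes")
    a, b, c = (set(f.index[f.astype(bool)]) for f in (flags_a, flags_b, flags_c))
    members = {
        "A_only": a - b - c,
        "B_only": b - a - c,
        "C_only": c - a - b,
        "AB": (a & b) - c,
        "AC": (a & c) - b,
        "BC": (b & c) - a,
        "ABC": a & b & c,
    }
    return VennPartition({region: sorted(genes) for region, genes in members.items()})


def overlap_percentage(set_x: set[str], set_y: set[str]) -> int:
    """Percent of X that is also in Y, rounded half-up to the nearest integer."""
    set_x, set_y = set(set_x), set(set_y)
    if not set_x:
        raise ConfigError("overlap percentage of an empty set is undefined")
    return int(math.floor(100.0 * len(set_x & set_y) / len(set_x) + 0.5))


@dataclass
class ExtremePair:
    """Largest up- and down-regulated fold changes of one contrast."""

    up: tuple[str, float] | None
    down: tuple[str, float] | None


def extreme_changes(frame: pd.DataFrame) -> ExtremePair:
    """Most extreme genes of a contrast frame; ties break lexicographically."""
    if frame.empty:
        raise ConfigError("extreme_changes needs at least one gene")
    result = {}
    for direction in ("up", "down"):
        sub = frame[frame["direction"] == direction]
        if sub.empty:
            result[direction] = None
            continue
        ranked = sub.assign(gene=sub.index.astype(str)).sort_values(
            ["fold_change", "gene"], ascending=[False, True]
        )
        top = ranked.iloc[0]
        result[direction] = (str(top["gene"]), float(top["fold_change"]))
    return ExtremePair(up=result["up"], down=result["down"])


def cross_contrast_regression(
    table: dict[str, pd.DataFrame], genes: list[str], x: str = "A", y: str = "B"
) -> tuple[float, float]:
    """Pearson R and OLS slope of contrast-y log-ratios on contrast-x log-ratios."""
    if len(genes) < 3:
        raise ConfigError("regression needs at least 3 genes")
    xv = table[x].loc[genes, "log_ratio"].to_numpy(dtype=float)
    yv = table[y].loc[genes, "log_ratio"].to_numpy(dtype=float)
    xc = xv - xv.mean()
    yc = yv - yv.mean()
    sxx = float(xc @ xc)
    if sxx == 0:
        raise ConfigError("zero variance in predictor log-ratios")
    slope = float(xc @ yc) / sxx
    syy = float(yc @ yc)
    r = float(xc @ yc) / math.sqrt(sxx * syy) if syy > 0 else 0.0
    return r, slope
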