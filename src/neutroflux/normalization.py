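"""Four-step normalization: ln transform, quantile normalization across all
scans, reference-channel correction, gene-symbol collapse — plus PCA QC.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from neutroflux.errors import ConfigError, IntegrityError
from neutroflux.io_formats import SpotTable, StudyDesign

logger = logging.getLogger(__name__)


@dataclass
class ChannelMatrix:
    """Spots x channels table of natural-log intensities.

    ``values`` is indexed by spot_id with one column per channel
    (``<array_id>|sample`` and ``<array_id>|reference``); ``channels`` maps
    each column to its array and role; ``spots`` carries per-spot probe and
    gene annotation.
    """

    values: pd.DataFrame
    channels: pd.DataFrame  # channel_id, array_id, role
    spots: pd.DataFrame     # spot_id, probe_id, gene_symbol

    def __post_init__(self) -> None:
        roles = self.channels.groupby("array_id")["role"].apply(sorted)
        for array_id, role_list in roles.items():
            if role_list != ["reference", "sample"]:
                raise IntegrityError(
                    f"array {array_id} must contribute exactly one sample and "
                    f"one reference channel, got {role_list}"
                )
        if not np.isfinite(self.values.to_numpy()).all():
            raise IntegrityError("non-finite values in channel matrix")

    @property
    def array_ids(self) -> list[str]:
        return list(dict.fromkeys(self.channels["array_id"]))

    def columns_for(self, role: str) -> list[str]:
        return list(self.channels.loc[self.channels["role"] == role, "channel_id"])


@dataclass
class SampleMatrix:
    """Spots x arrays table of reference-corrected log intensities."""

    values: pd.DataFrame  # index spot_id, columns array_id
    spots: pd.DataFrame


@dataclass
class QCReport:
    scores: pd.DataFrame          # sample_id, group, PC1, PC2
    group_dispersion: pd.Series   # group -> mean distance to centroid (PC1/2)
    flagged_group: str
    constant_matrix: bool = False


def ln_transform(spots: SpotTable, include_controls: bool = False) -> ChannelMatrix:
    """Natural-log transform of both channels of every array.

    Control spots are used upstream for QC only and excluded here (with a
    logged count) unless ``include_controls`` is set.
    """
    data = spots.data
    if not include_controls:
        n_controls = int((data["spot_kind"] != "regular").sum())
        if n_controls:
            logger.info("excluding %d control spot record(s) from normalization", n_controls)
        data = data[data["spot_kind"] == "regular"]
    if (data[["sample_signal", "reference_signal"]].to_numpy() <= 0).any():
        raise IntegrityError("nonpositive signal reached ln_transform; floor upstream")
    arrays = list(dict.fromkeys(data["array_id"]))
    first = data[data["array_id"] == arrays[0]]
    spot_meta = first[["spot_id", "probe_id", "gene_symbol"]].reset_index(drop=True)
    cols, meta = {}, []
    for array_id in arrays:
        sub = data[data["array_id"] == array_id].set_index("spot_id")
        sub = sub.loc[spot_meta["spot_id"]]
        for role, signal in (("sample", "sample_signal"), ("reference", "reference_signal")):
            channel_id = f"{array_id}|{role}"
            cols[channel_id] = np.log(sub[signal].to_numpy(dtype=float))
            meta.append((channel_id, array_id, role))
    values = pd.DataFrame(cols, index=pd.Index(spot_meta["spot_id"], name="spot_id"))
    channels = pd.DataFrame(meta, columns=["channel_id", "array_id", "role"])
    return ChannelMatrix(values, channels, spot_meta)


def _qn_reference(block: np.ndarray) -> np.ndarray:
    return np.sort(block, axis=0).mean(axis=1)


def _qn_column(col: np.ndarray, ref: np.ndarray) -> np.ndarray:
    """Map one channel onto the reference distribution.

    Ties within the channel receive the mean of the reference values over
    the ranks they occupy.
    """
    order = np.argsort(col, kind="mergesort")
    sorted_vals = col[order]
    out = np.empty_like(col)
    # boundaries of runs of equal values in the sorted channel
    change = np.empty(len(col), dtype=bool)
    change[0] = True
    change[1:] = sorted_vals[1:] != sorted_vals[:-1]
    starts = np.flatnonzero(change)
    ends = np.append(starts[1:], len(col))
    for s, e in zip(starts, ends):
        out[order[s:e]] = ref[s:e].mean()
    return out


def quantile_normalize(channels: ChannelMatrix, pool: str = "all") -> ChannelMatrix:
    """Force channels onto the mean-of-sorted-values reference distribution.

    ``pool='all'`` (default) normalizes every scan — sample and reference
    channels of all arrays — together; ``pool='by-role'`` normalizes sample
    and reference channels separately.
    """
    if pool not in ("all", "by-role"):
        raise ConfigError(f"pool must be 'all' or 'by-role', got {pool!r}")
    values = channels.values
    if values.shape[1] < 2:
        raise IntegrityError("quantile normalization needs at least 2 channels")
    if values.isna().any().any():
        raise IntegrityError("channels have unequal spot counts")
    groups = (
        [list(values.columns)]
        if pool == "all"
        else [channels.columns_for("sample"), channels.columns_for("reference")]
    )
    out = values.copy()
    for cols in groups:
        block = values[cols].to_numpy(dtype=float)
        ref = _qn_reference(block)
        for j, col in enumerate(cols):
            out[col] = _qn_column(block[:, j], ref)
    return ChannelMatrix(out, channels.channels.copy(), channels.spots.copy())


def reference_correct(channels: ChannelMatrix, mode: str = "deviation") -> SampleMatrix:
    """Correct each sample channel for its array's reference-channel deviation.

    ``mode='deviation'`` (default): for spot g on array a,
    ``corrected = s_{g,a} - (r_{g,a} - mean_a' r_{g,a'})``, which removes
    between-array reference differences while preserving the intensity
    scale. ``mode='ratio'`` uses the plain log-ratio ``s - r``.
    """
    if mode not in ("deviation", "ratio"):
        raise ConfigError(f"mode must be 'deviation' or 'ratio', got {mode!r}")
    arrays = channels.array_ids
    sample_cols = [f"{a}|sample" for a in arrays]
    ref_cols = [f"{a}|reference" for a in arrays]
    for col in sample_cols + ref_cols:
        if col not in channels.values.columns:
            raise IntegrityError(f"array missing channel {col}")
    s = channels.values[sample_cols].to_numpy(dtype=float)
    r = channels.values[ref_cols].to_numpy(dtype=float)
    if mode == "deviation":
        corrected = s - (r - r.mean(axis=1, keepdims=True))
    else:
        corrected = s - r
    values = pd.DataFrame(corrected, index=channels.values.index, columns=arrays)
    return SampleMatrix(values, channels.spots.copy())


def collapse_genes(
    sample_matrix: SampleMatrix, annotation: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Average spots sharing a gene symbol into one row per gene.

    Symbols come from ``annotation`` (probe_id -> gene_symbol) when given,
    else from the spot table's own gene_symbol column. Spots without a
    symbol are dropped with a logged count.
    """
    spots = sample_matrix.spots
    if annotation is not None:
        mapping = dict(zip(annotation["probe_id"], annotation["gene_symbol"]))
        symbols = spots["probe_id"].map(mapping).fillna("")
    else:
        symbols = spots["gene_symbol"].fillna("")
    symbols = pd.Series(np.asarray(symbols, dtype=str), index=spots.index)
    annotated = symbols != ""
    n_dropped = int((~annotated).sum())
    if n_dropped:
        logger.info("dropping %d unannotated spot(s) at gene collapse", n_dropped)
    if not annotated.any():
        raise IntegrityError("no annotated spots; cannot collapse to genes")
    values = sample_matrix.values.reset_index(drop=True)
    kept = values[annotated.to_numpy()]
    matrix = kept.groupby(symbols[annotated].to_numpy()).mean()
    matrix.index.name = "gene_symbol"
    return matrix


def pca_qc(matrix: pd.DataFrame, design: StudyDesign) -> QCReport:
    """Covariance PCA of gene-centered expression; flags the most dispersed group.

    Dispersion is the mean Euclidean distance of a group's samples to their
    group centroid in the PC1/PC2 plane.
    """
    if matrix.shape[1] < 3:
        raise IntegrityError("PCA QC needs at least 3 samples")
    unknown = [s for s in matrix.columns if s not in design.groups]
    if unknown:
        raise IntegrityError(f"samples not in design: {unknown}")
    X = matrix.to_numpy(dtype=float)
    centered = X - X.mean(axis=1, keepdims=True)
    constant = bool(np.allclose(centered, 0.0))
    if constant:
        logger.warning("constant expression matrix; all PCA scores are zero")
        scores2 = np.zeros((matrix.shape[1], 2))
    else:
        # samples in rows for the decomposition
        u, s, vt = np.linalg.svd(centered.T, full_matrices=False)
        scores = u * s
        scores2 = np.zeros((matrix.shape[1], 2))
        scores2[:, : min(2, scores.shape[1])] = scores[:, :2]
    frame = pd.DataFrame(
        {
            "sample_id": list(matrix.columns),
            "group": [design.groups[s] for s in matrix.columns],
            "PC1": scores2[:, 0],
            "PC2": scores2[:, 1],
        }
    )
    dispersion = {}
    for group, sub in frame.groupby("group"):
        pts = sub[["PC1", "PC2"]].to_numpy()
        centroid = pts.mean(axis=0)
        dispersion[group] = float(np.linalg.norm(pts - centroid, axis=1).mean())
    group_dispersion = pd.Series(dispersion).sort_values(ascending=False)
    return QCReport(
        scores=frame,
        group_dispersion=group_dispersion,
        flagged_group=str(group_dispersion.index[0]),
        constant_matrix=constant,
    )


def normalize_pipeline(
    spots: SpotTable,
    annotation: pd.DataFrame | None = None,
    pool: str = "all",
    reference_mode: str = "deviation",
) -> pd.DataFrame:
    """ln transform -> quantile normalize -> reference correct -> collapse."""
    channels = ln_transform(spots)
    channels = quantile_normalize(channels, pool=pool)
    corrected = reference_correct(channels, mode=reference_mode)
    return collapse_genes(corrected, annotation)
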