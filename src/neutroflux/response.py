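"""Per-sample expression-response scores and phenotype correlations.

The response score of a sample is the root mean square of its deviations
from the sham-group median, over a chosen gene list — a scalar summary of
how far the sample's expression moved from the control state. Scores are
correlated against phenotype markers with Spearman (exact permutation p for
small n) or Pearson statistics.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from neutroflux.errors import ConfigError, IntegrityError
from neutroflux.io_formats import PhenotypeTable, StudyDesign

logger = logging.getLogger(__name__)

#: exact permutation p-values up to this sample size (9! = 362,880 draws)
EXACT_PERMUTATION_MAX_N = 9


@dataclass
class ResponseScores:
    """Per-sample RMS deviation from sham medians over ``genes``."""

    scores: pd.Series           # sample_id -> score (natural-log units, >= 0)
    genes: list[str]
    sham_medians: pd.Series     # gene -> median over SHAM samples


@dataclass
class CorrelationReport:
    marker: str
    method: str
    statistic: float
    p_value: float
    n: int


def response_score(
    matrix: pd.DataFrame, genes: Sequence[str], design: StudyDesign
) -> ResponseScores:
    """score_s = sqrt(mean_g (x_{g,s} - median_SHAM(x_g))^2) over the gene list."""
    genes = list(dict.fromkeys(genes))
    if not genes:
        raise ConfigError("response score needs a nonempty gene list")
    missing = [g for g in genes if g not in matrix.index]
    if missing:
        raise ConfigError(f"genes absent from matrix: {missing[:5]}")
    sham = [s for s in matrix.columns if design.groups.get(s) == "SHAM"]
    if not sham:
        raise IntegrityError("SHAM group has no samples in the matrix")
    sub = matrix.loc[genes]
    sham_medians = sub[sham].median(axis=1)
    deviations = sub.sub(sham_medians, axis=0)
    scores = np.sqrt((deviations**2).mean(axis=0))
    return ResponseScores(scores=scores, genes=genes, sham_medians=sham_medians)


def _check_pair(x: np.ndarray, y: np.ndarray) -> None:
    if x.shape != y.shape:
        raise ConfigError("paired vectors must have equal length")
    if len(x) < 3:
        raise ConfigError("correlation needs at least 3 paired observations")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ConfigError("correlation inputs must be finite")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ConfigError("correlation undefined for a constant vector")


def _rank_rho(rx: np.ndarray, ry: np.ndarray) -> float:
    rxc = rx - rx.mean()
    ryc = ry - ry.mean()
    return float((rxc @ ryc) / math.sqrt((rxc @ rxc) * (ryc @ ryc)))


def spearman_corr(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Spearman rho (average ranks for ties) with a two-sided p-value.

    For n <= 9 the p-value is exact, from the full permutation distribution
    of rho; for larger n the usual t approximation is used.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    _check_pair(x, y)
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rho = _rank_rho(rx, ry)
    n = len(x)
    if n <= EXACT_PERMUTATION_MAX_N:
        perms = np.array(list(itertools.permutations(rx)))
        rxc = perms - rx.mean()
        ryc = ry - ry.mean()
        denom = math.sqrt(float((rxc[0] @ rxc[0]) * (ryc @ ryc)))
        rhos = (rxc @ ryc) / denom
        p = float(np.mean(np.abs(rhos) >= abs(rho) - 1e-12))
    elif abs(rho) == 1.0:
        p = 0.0
    else:
        t = rho * math.sqrt((n - 2) / (1.0 - rho * rho))
        p = float(2.0 * stats.t.sf(abs(t), df=n - 2))
    return rho, p


def pearson_corr(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Product-moment correlation with a two-sided t-test p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    _check_pair(x, y)
    result = stats.pearsonr(x, y)
    return float(result.statistic), float(result.pvalue)


def correlate_response_with_phenotype(
    scores: ResponseScores,
    phenotypes: PhenotypeTable,
    marker: str = "m1dg",
    method: str = "spearman",
    below_detection: str = "zero",
) -> CorrelationReport:
    """Correlate response scores with a phenotype marker over shared animals.

    Below-detection marker values are substituted with 0 (default) or half
    the minimum detected value (``below_detection='halfmin'``), with a log
    note either way.
    """
    if method not in ("spearman", "pearson"):
        raise ConfigError(f"method must be 'spearman' or 'pearson', got {method!r}")
    if below_detection not in ("zero", "halfmin"):
        raise ConfigError("below_detection must be 'zero' or 'halfmin'")
    raw = phenotypes.data.set_index("sample_id")[marker] if marker in phenotypes.data else None
    if raw is None:
        raise ConfigError(f"unknown marker {marker!r}")
    fill = 0.0
    if below_detection == "halfmin" and raw.notna().any():
        fill = float(raw.min(skipna=True)) / 2.0
    values = phenotypes.marker(marker, below_detection_value=fill)
    shared = [s for s in scores.scores.index if s in values.index]
    if len(shared) < 3:
        raise ConfigError(
            f"only {len(shared)} animal(s) shared between scores and phenotypes"
        )
    xs = scores.scores.loc[shared].to_numpy(dtype=float)
    ys = values.loc[shared].to_numpy(dtype=float)
    corr = spearman_corr if method == "spearman" else pearson_corr
    statistic, p = corr(xs, ys)
    return CorrelationReport(
        marker=marker, method=method, statistic=statistic, p_value=p, n=len(shared)
    )
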