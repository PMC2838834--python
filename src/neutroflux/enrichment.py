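"""Over-representation analysis of gene lists against GMT gene sets.

One-sided hypergeometric tail test per set, with DAVID's conservative EASE
variant (overlap reduced by one) as an option, and Benjamini-Hochberg
adjustment across the reported rows.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from neutroflux.errors import ConfigError
from neutroflux.io_formats import GeneSetCollection


def hypergeom_p(k: int, n: int, K: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N population, K marked, n drawn)."""
    if not (0 <= K <= N and 0 <= n <= N):
        raise ConfigError(f"impossible counts: K={K}, n={n}, N={N}")
    if not 0 <= k <= min(n, K):
        raise ConfigError(f"overlap k={k} outside [0, min(n={n}, K={K})]")
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted values, capped at 1."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if ((p <= 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise ConfigError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    # enforce monotonicity from the largest p downwards
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


def enrich(
    query: Iterable[str],
    universe: Iterable[str],
    sets: GeneSetCollection,
    method: str = "fisher",
    min_set: int = 3,
) -> pd.DataFrame:
    """One enrichment row per gene set with at least ``min_set`` expressed members.

    Sets are intersected with the universe before counting. ``method='ease'``
    replaces the overlap k by max(k - 1, 0) in the tail test. Rows are
    sorted by p-value (ties by set name); q is BH across reported rows.
    """
    if method not in ("fisher", "ease"):
        raise ConfigError(f"method must be 'fisher' or 'ease', got {method!r}")
    query = list(dict.fromkeys(query))
    universe_set = set(universe)
    offenders = sorted(g for g in query if g not in universe_set)
    if offenders:
        raise ConfigError(f"query genes not in universe: {offenders}")
    query_set = set(query)
    N = len(universe_set)
    n = len(query_set)
    rows = []
    for name, (_description, members) in sets:
        expressed = sorted(set(members) & universe_set)
        K = len(expressed)
        if K < min_set:
            continue
        overlap = sorted(set(expressed) & query_set)
        k = len(overlap)
        k_test = max(k - 1, 0) if method == "ease" else k
        p = hypergeom_p(k_test, n, K, N)
        rows.append((name, K, k, n, N, p, overlap))
    frame = pd.DataFrame(
        rows, columns=["set_name", "K", "k", "n", "N", "p", "overlap"]
    ).sort_values(["p", "set_name"], kind="mergesort").reset_index(drop=True)
    frame["q"] = bh_adjust(frame["p"]) if len(frame) else []
    return frame[["set_name", "K", "k", "n", "N", "p", "q", "overlap"]]
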