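"""Count-level analytics for marker x core cell-count tables.

The conventions implemented here: counts are log2(x + 1) transformed
before analysis; each tumour is represented by the mean raw count of its
available (unflagged) cores, aggregated before the log transform;
agreement between count series is measured with Spearman rank
correlation; marker co-expression structure is explored with
complete-linkage hierarchical clustering on Euclidean distances cut into
two groups (immune-high / immune-low); and survival-ready group labels
come from a median split (ties to "low").  Survival estimation itself
(Kaplan-Meier, Cox) is deliberately left to standard tooling - this
module only produces the tidy inputs for it.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

__all__ = [
    "CountTable",
    "log2_transform",
    "aggregate_cores",
    "spearman",
    "coexpression_cluster",
    "median_split",
    "ordinal_agreement",
]

logger = logging.getLogger(__name__)


@dataclass
class CountTable:
    """Cell counts with rows = cores (or samples) and columns = markers.

    ``sample_of`` maps a core row label to its sample; ``is_log2``
    records the transform state so it cannot silently be applied twice.
    Missing values (NaN) mark flagged cores excluded from analysis.
    """

    data: pd.DataFrame
    sample_of: Mapping[str, str] | None = None
    is_log2: bool = False

    def __post_init__(self):
        if not self.is_log2:
            values = self.data.to_numpy(dtype=float)
            finite = values[np.isfinite(values)]
            if np.any(finite < 0):
                raise ValueError("raw counts must be non-negative")


def log2_transform(table: CountTable, pseudocount: float = 1.0) -> CountTable:
    """log2(count + pseudocount); a count of 0 maps to 0 with the default."""
    if table.is_log2:
        raise ValueError("table is already log2-transformed")
    return replace(table, data=np.log2(table.data + pseudocount), is_log2=True)


def aggregate_cores(table: CountTable, method: str = "mean") -> CountTable:
    """Collapse core rows to one row per sample (mean of available cores).

    Flagged cores (NaN) are skipped; samples whose cores are all flagged
    are dropped with a logged note.
    """
    if table.sample_of is None:
        raise ValueError("aggregate_cores needs a core -> sample mapping")
    if table.data.empty:
        raise ValueError("empty count table")
    if method != "mean":
        raise ValueError(f"unsupported aggregation method {method!r}")
    samples = table.data.index.map(lambda c: table.sample_of[c])
    grouped = table.data.groupby(samples).mean()  # NaN-skipping mean
    all_missing = grouped.isna().all(axis=1)
    for sample in grouped.index[all_missing]:
        logger.info("sample %s dropped: all cores flagged", sample)
    return CountTable(
        data=grouped.loc[~all_missing], sample_of=None, is_log2=table.is_log2
    )


def spearman(x, y) -> float:
    """Spearman rank correlation with average ranks for ties.

    Pairs with a missing value are removed first; a constant vector makes
    the correlation undefined and returns NaN with a warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have the same length")
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if x.size < 3:
        raise ValueError("need at least 3 complete pairs")
    if np.all(x == x[0]) or np.all(y == y[0]):
        warnings.warn("constant input: Spearman correlation undefined")
        return float("nan")
    rho, _ = sps.spearmanr(x, y)
    return float(rho)


def coexpression_cluster(table: pd.DataFrame | CountTable):
    """Complete-linkage clustering of samples cut into two groups.

    Rows are samples, columns markers (typically log2 mean counts).
    Returns ``(linkage_matrix, labels)`` with labels in {1, 2}; ties in
    merge distances resolve by scipy's deterministic row ordering.
    """
    data = table.data if isinstance(table, CountTable) else table
    if data.shape[0] < 2:
        raise ValueError("need at least 2 samples to cluster")
    values = data.to_numpy(dtype=float)
    if not np.all(np.isfinite(values)):
        raise ValueError("clustering requires a complete matrix; drop incomplete rows")
    linkage = hierarchy.linkage(pdist(values, metric="euclidean"), method="complete")
    labels = hierarchy.fcluster(linkage, t=2, criterion="maxclust")
    return linkage, labels


def median_split(values) -> pd.Series:
    """Dichotomise per-sample values: "high" iff value > median, else "low".

    Values exactly at the median go to "low"; an all-constant input makes
    every sample "low" and logs a warning.
    """
    series = pd.Series(values, dtype=float)
    if series.size < 2:
        raise ValueError("need at least 2 samples for a median split")
    med = float(series.median())
    if series.nunique() == 1:
        warnings.warn("all values equal: every sample labelled 'low'")
    return pd.Series(np.where(series > med, "high", "low"), index=series.index)


def ordinal_agreement(counts, scores):
    """Summarise counts per ordinal score level plus the rank correlation.

    ``scores`` is a small ordinal scale (e.g. pathology bins 0-3).
    Returns ``(summary, rho)``: per-level n / median / quartiles and the
    Spearman correlation of counts against the ordinal level (NaN when a
    single level is present).
    """
    df = pd.DataFrame({"count": np.asarray(counts, dtype=float), "score": list(scores)})
    df = df.dropna()
    grouped = df.groupby("score")["count"]
    summary = grouped.agg(
        n="size", median="median", q1=lambda s: s.quantile(0.25), q3=lambda s: s.quantile(0.75)
    ).reset_index()
    levels = {s: i for i, s in enumerate(sorted(df["score"].unique()))}
    if len(levels) < 2:
        return summary, float("nan")
    rho = spearman(df["count"], df["score"].map(levels))
    return summary, rho
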