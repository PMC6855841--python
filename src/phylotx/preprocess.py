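"""Expression preprocessing: filtering, replicate alignment, sample
clustering and profile normalization.

The low-expression filter removes genes whose arithmetic mean tpm over
all samples of both replicates is strictly below the threshold
(default 0.5 tpm); genes exactly at the threshold are retained.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from scipy.stats import spearmanr

from .io import ExpressionDataset

logger = logging.getLogger("phylotx")

__all__ = [
    "filter_low_expression",
    "align_replicates",
    "sample_correlation_clustering",
    "normalize",
    "NormalizedExpression",
    "SampleDendrogram",
]


def filter_low_expression(data: ExpressionDataset, threshold: float = 0.5) -> ExpressionDataset:
    """Drop genes with mean tpm (over all samples) strictly below threshold."""
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    keep = data.values.mean(axis=1) >= threshold
    if not keep.any():
        logger.warning("low-expression filter removed every gene")
    return ExpressionDataset(values=data.values.loc[keep].copy(), meta=data.meta.copy())


def align_replicates(data: ExpressionDataset, shift_hours: float, replicate=2) -> ExpressionDataset:
    """Shift the timepoint labels of one replicate (default replicate 2).

    A positive shift means the replicate ran late by ``shift_hours``:
    its nominal labels are moved back by that amount so that samples in
    equivalent biological states share a label. The shift must be an
    integer multiple of the sampling interval; samples whose corrected
    label falls outside the window shared by all replicates are dropped.
    """
    if shift_hours == 0:
        return ExpressionDataset(values=data.values.copy(), meta=data.meta.copy())
    tps = data.timepoints(replicate)
    intervals = np.diff(tps)
    step = intervals.min()
    if not np.isclose(shift_hours / step, round(shift_hours / step)):
        raise ValueError(
            f"shift {shift_hours} h is not an integer multiple of the "
            f"sampling interval {step} h"
        )
    meta = data.meta.copy()
    sel = meta["replicate"] == replicate
    meta.loc[sel, "timepoint"] = meta.loc[sel, "timepoint"] - shift_hours

    # keep only timepoints present in every replicate
    common = None
    for rep in sorted(meta["replicate"].unique()):
        tset = set(meta.loc[meta["replicate"] == rep, "timepoint"])
        common = tset if common is None else common & tset
    keep = meta["timepoint"].isin(common)
    dropped = meta.index[~keep].tolist()
    if dropped:
        logger.info("alignment dropped samples outside the common window: %s", dropped)
    meta = meta.loc[keep]
    return ExpressionDataset(values=data.values[meta.index].copy(), meta=meta)


@dataclass
class SampleDendrogram:
    """Agglomerative clustering of samples (scipy linkage encoding)."""

    linkage: np.ndarray
    labels: list

    def cut(self, n_groups: int) -> pd.Series:
        flat = hierarchy.fcluster(self.linkage, t=n_groups, criterion="maxclust")
        return pd.Series(flat, index=self.labels, name="group")

    def as_newick(self) -> str:
        tree = hierarchy.to_tree(self.linkage)

        def walk(node):
            if node.is_leaf():
                return self.labels[node.id]
            return (
                f"({walk(node.left)}:{node.dist - node.left.dist:.6g},"
                f"{walk(node.right)}:{node.dist - node.right.dist:.6g})"
            )

        return walk(tree) + ";"

    def merge_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.linkage, columns=["child_a", "child_b", "height", "size"]
        )


def sample_correlation_clustering(data: ExpressionDataset) -> SampleDendrogram:
    """Cluster samples by Euclidean distance between rows of the
    sample-sample Spearman correlation matrix (average linkage).

    A zero-variance sample has no defined rank correlation; its
    correlations are set to 0 with a warning.
    """
    X = data.values.to_numpy()
    if X.shape[1] < 2:
        raise ValueError("need at least 2 samples")
    const = X.std(axis=0) == 0
    if const.any():
        logger.warning(
            "constant sample(s) %s: Spearman correlation undefined, set to 0",
            [data.sample_ids[i] for i in np.flatnonzero(const)],
        )
    corr = spearmanr(X).statistic
    if np.isscalar(corr):  # two samples: spearmanr returns a scalar
        corr = np.array([[1.0, corr], [corr, 1.0]])
    corr = np.asarray(corr, dtype=float)
    corr[np.ix_(const, ~const)] = 0.0
    corr[np.ix_(~const, const)] = 0.0
    corr[np.ix_(const, const)] = 0.0
    np.fill_diagonal(corr, 1.0)
    dist = squareform(
        np.sqrt(np.maximum(((corr[:, None, :] - corr[None, :, :]) ** 2).sum(-1), 0.0)),
        checks=False,
    )
    Z = hierarchy.linkage(dist, method="average")
    return SampleDendrogram(linkage=Z, labels=list(data.sample_ids))


@dataclass
class NormalizedExpression:
    """Per-gene standardized temporal profiles.

    ``values``: genes x samples, log2(tpm + offset) then centered and
    scaled to unit standard deviation per gene. ``excluded`` lists
    zero-variance genes that cannot be standardized.
    """

    values: pd.DataFrame
    meta: pd.DataFrame
    excluded: list


def normalize(
    data: ExpressionDataset, offset: float = 1.0, per_replicate: bool = False
) -> NormalizedExpression:
    """log2(tpm + offset), then per-gene z-score.

    With ``per_replicate=True`` the centering/scaling is done within
    each replicate separately (the form used for co-expression
    clustering, where replicates are concatenated as extra profile
    dimensions). Zero-variance genes are excluded with a warning.
    """
    # all arithmetic on a C-contiguous array: the result is then a
    # bit-exact function of the values alone, independent of how the
    # incoming DataFrame happens to be laid out in memory
    logged = np.ascontiguousarray(np.log2(data.values.to_numpy() + offset))

    def zscore(block: np.ndarray) -> np.ndarray:
        mu = block.mean(axis=1, keepdims=True)
        sd = block.std(axis=1, ddof=0, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(sd == 0, np.nan, (block - mu) / sd)

    if per_replicate:
        out = np.empty_like(logged)
        rep_codes = data.meta["replicate"].to_numpy()
        for rep in data.replicates:
            idx = np.flatnonzero(rep_codes == rep)
            out[:, idx] = zscore(np.ascontiguousarray(logged[:, idx]))
    else:
        out = zscore(logged)
    z = pd.DataFrame(out, index=data.values.index, columns=data.values.columns)
    bad = z.index[z.isna().any(axis=1)].tolist()
    if bad:
        logger.warning("excluded %d zero-variance gene(s) from normalization", len(bad))
    z = z.drop(index=bad)
    return NormalizedExpression(values=z, meta=data.meta.copy(), excluded=bad)
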