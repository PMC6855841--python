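"""Consensus co-expression clustering with an unassigned remainder.

Tight temporally co-expressed clusters are extracted from normalized
profiles by a consensus over many k-means base partitions: k varies
over a grid and each (k, seed) run votes on which gene pairs belong
together. Genes whose co-assignment neighbourhood is not stable across
runs end up unassigned — the defining behaviour needed here, as only a
minority of genes follow a tight temporal program.

Procedure
---------
1. Base learners: k-means (k-means++ init, recorded seeds) for every k
   in ``k_grid`` x ``n_base_runs`` seeds, on the per-replicate
   normalized profiles with replicates concatenated as extra
   dimensions.
2. Consensus: the gene x gene co-assignment frequency matrix C.
3. Extraction: average-linkage hierarchical clustering on 1 - C cut at
   height 1 - tau gives candidate clusters; each candidate is then
   pruned by repeatedly removing the member whose mean co-assignment
   with the rest of the cluster is lowest, until every remaining
   member co-assigns with its cluster at frequency >= tau. Candidates
   that shrink below ``min_cluster_size`` dissolve; their genes are
   unassigned.

Raising tau both refines the cut (the partitions are nested) and
tightens the member-wise pruning, so the number of assigned genes does
not grow with tau.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from sklearn.cluster import KMeans
from sklearn.metrics import adjusted_rand_score

from .io import RunConfig, ExpressionDataset
from .preprocess import NormalizedExpression, normalize

logger = logging.getLogger("phylotx")

__all__ = [
    "consensus_cluster",
    "replicate_robustness",
    "mean_cluster_profiles",
    "coassignment_matrix",
]

UNASSIGNED = pd.NA


def _base_partitions(X: np.ndarray, k_grid, n_base_runs: int, rng_seed: int) -> np.ndarray:
    """Labels from every k-means base run; shape (n_runs, n_genes)."""
    n = X.shape[0]
    for k in k_grid:
        if k >= n:
            raise ValueError(f"k={k} in k_grid is not below the gene count {n}")
    # collapse exactly duplicated profiles so that k never exceeds the
    # number of distinct points (k-means would otherwise split ties
    # arbitrarily via empty-cluster relocation)
    uniq, inverse, counts = np.unique(
        X, axis=0, return_inverse=True, return_counts=True
    )
    seeds = np.random.SeedSequence(rng_seed).generate_state(len(list(k_grid)) * n_base_runs)
    labels = []
    i = 0
    for k in k_grid:
        for _ in range(n_base_runs):
            if k >= len(uniq):
                labels.append(inverse.copy())
            else:
                km = KMeans(n_clusters=k, init="k-means++", n_init=1,
                            random_state=int(seeds[i] % (2**31)))
                labels.append(km.fit_predict(uniq, sample_weight=counts)[inverse])
            i += 1
    return np.array(labels)


def coassignment_matrix(labels: np.ndarray) -> np.ndarray:
    """Fraction of base runs in which each gene pair shares a cluster."""
    n_runs, n = labels.shape
    C = np.zeros((n, n))
    for run in labels:
        onehot = np.eye(run.max() + 1, dtype=np.float32)[run]
        C += onehot @ onehot.T
    return C / n_runs


def _prune_loose_members(C: np.ndarray, members: np.ndarray, tau: float) -> np.ndarray:
    """Drop members until each co-assigns with the rest at >= tau.

    Greedy: repeatedly remove the member with the lowest mean
    co-assignment frequency to the other members (ties broken by
    index, so the result is deterministic).
    """
    members = np.array(members)
    while len(members) > 1:
        sub = C[np.ix_(members, members)]
        mean_to_rest = (sub.sum(axis=1) - 1.0) / (len(members) - 1)
        worst = int(np.argmin(mean_to_rest))
        if mean_to_rest[worst] >= tau:
            break
        members = np.delete(members, worst)
    return members


def consensus_cluster(norm: NormalizedExpression, config: RunConfig) -> pd.Series:
    """Consensus clustering; returns gene_id -> cluster id (Int64, NA =
    unassigned). Deterministic given ``config.rng_seed``.

    Clusters are numbered 1..K in decreasing size order.
    """
    X = norm.values.to_numpy()
    genes = norm.values.index
    if X.shape[0] < 2:
        raise ValueError("need at least 2 genes")
    if X.shape[1] < 3:
        raise ValueError("need at least 3 timepoints")
    labels = _base_partitions(X, config.k_grid, config.n_base_runs, config.rng_seed)
    C = coassignment_matrix(labels)
    np.fill_diagonal(C, 1.0)
    Z = hierarchy.linkage(squareform(1.0 - C, checks=False), method="average")
    flat = hierarchy.fcluster(Z, t=1.0 - config.consensus_tau, criterion="distance")

    members_of = {}
    for cand in np.unique(flat):
        members = np.flatnonzero(flat == cand)
        members = _prune_loose_members(C, members, config.consensus_tau)
        if len(members) >= config.min_cluster_size:
            members_of[cand] = members
    order = sorted(members_of, key=lambda c: (-len(members_of[c]), c))
    final = np.full(len(genes), -1)
    for new, cand in enumerate(order, start=1):
        final[members_of[cand]] = new
    out = pd.array(np.where(final < 0, pd.NA, final), dtype="Int64")
    assignment = pd.Series(out, index=genes, name="cluster")
    logger.info(
        "consensus clustering: %d clusters, %d/%d genes assigned",
        len(order), int(assignment.notna().sum()), len(genes),
    )
    return assignment


def replicate_robustness(data: ExpressionDataset, config: RunConfig) -> pd.DataFrame:
    """Agreement of cluster memberships across replicate choices.

    Clusters are computed on replicate 1 only, replicate 2 only, and
    the per-timepoint average of both; each pair is scored by the
    adjusted Rand index over genes assigned in both runs.
    """
    reps = data.replicates
    if len(reps) < 2:
        raise ValueError("need at least 2 replicates")
    runs = {}
    for rep in reps:
        cols = data.meta.index[data.meta["replicate"] == rep]
        sub = ExpressionDataset(data.values[cols].copy(), data.meta.loc[cols].copy())
        runs[f"rep{rep}"] = consensus_cluster(normalize(sub), config)
    mats = [data.replicate_matrix(rep).to_numpy() for rep in reps]
    avg_vals = pd.DataFrame(
        np.mean(mats, axis=0),
        index=data.gene_ids,
        columns=[f"t{t:g}_avg" for t in data.timepoints(reps[0])],
    )
    avg_meta = pd.DataFrame(
        {
            "timepoint": data.timepoints(reps[0]),
            "replicate": 1,
        },
        index=pd.Index(avg_vals.columns, name="sample_id"),
    )
    runs["average"] = consensus_cluster(
        normalize(ExpressionDataset(avg_vals, avg_meta)), config
    )

    rows = []
    names = list(runs)
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            a, b = runs[names[i]], runs[names[j]]
            both = a.notna() & b.notna()
            ari = (
                adjusted_rand_score(a[both].astype(int), b[both].astype(int))
                if both.sum() >= 2
                else np.nan
            )
            rows.append({"run_a": names[i], "run_b": names[j],
                         "n_shared": int(both.sum()), "ari": ari})
    return pd.DataFrame(rows)


def mean_cluster_profiles(
    norm: NormalizedExpression, assignment: pd.Series
) -> pd.DataFrame:
    """Per-cluster mean and standard deviation of member profiles,
    per timepoint and replicate (long format)."""
    rows = []
    for cl in sorted(assignment.dropna().unique()):
        members = assignment.index[assignment == cl]
        members = [g for g in members if g in norm.values.index]
        if not members:
            logger.warning("cluster %s has no members in the normalized set", cl)
            continue
        sub = norm.values.loc[members]
        for sample in sub.columns:
            rows.append(
                {
                    "cluster": int(cl),
                    "sample_id": sample,
                    "timepoint": norm.meta.loc[sample, "timepoint"],
                    "replicate": norm.meta.loc[sample, "replicate"],
                    "mean": float(sub[sample].mean()),
                    "sd": float(sub[sample].std(ddof=1)) if len(members) > 1 else 0.0,
                    "n_genes": len(members),
                }
            )
    return pd.DataFrame(rows)
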