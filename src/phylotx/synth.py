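"""Synthetic data with known ground truth.

Two generators feed every downstream stage:

* :func:`simulate_dollo_matrix` draws orthogroup presence/absence
  patterns under a single-gain / stochastic-loss (Dollo) model on a
  species tree, recording the true gain node of every orthogroup.
* :func:`simulate_expression` draws a replicated tpm time course with
  sharply-activated temporal cluster programs, a large low-expression
  gene fraction, multiplicative log-normal noise, an optional
  one-timepoint replicate offset, and a tunable age-by-phase interaction
  that plants an hourglass (or inverse-hourglass) transcriptome-age
  profile.

:func:`simulate_study` wires the two together into a complete labelled
dataset (tree, phyletic matrix, gene membership, expression, truth).

The defaults emulate the study conditions: a 10-stratum lineage with ~30
outgroup species, two replicates of a 10-timepoint course sampled every
6 h, at least half of all genes below the 0.5-tpm expression filter, and
five planted co-expression programs split into an early ("growth") and a
late ("cellularization") phase.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .io import ExpressionDataset
from .trees import SpeciesTree, species_tree_from_string

logger = logging.getLogger("phylotx")

__all__ = [
    "DolloSimParams",
    "ExprSimParams",
    "simulate_species_tree",
    "simulate_dollo_matrix",
    "simulate_expression",
    "simulate_study",
    "default_profiles",
    "StudyBundle",
]


# ---------------------------------------------------------------------------
# Species tree


def simulate_species_tree(
    n_strata: int = 10, n_outgroups: int = 30, focal: str = "FOCAL"
) -> SpeciesTree:
    """Ladder tree whose root-to-focal chain has ``n_strata`` ranks.

    Each of the ``n_strata - 1`` internal nodes on the chain carries a
    small outgroup clade; the outgroups are spread as evenly as
    possible. Deterministic (no randomness in the topology).
    """
    if n_strata < 2:
        raise ValueError("need at least 2 strata (root + focal)")
    if n_outgroups < n_strata - 1:
        raise ValueError("need at least one outgroup per internal stratum node")
    sizes = np.full(n_strata - 1, n_outgroups // (n_strata - 1))
    sizes[: n_outgroups % (n_strata - 1)] += 1
    names = iter(f"SP{i:02d}" for i in range(1, n_outgroups + 1))

    def clade(k: int) -> str:
        members = [next(names) for _ in range(k)]
        nwk = members[0]
        for m in members[1:]:
            nwk = f"({nwk},{m})"
        return nwk

    nwk = focal
    # deepest chain node first; root gets the largest clade
    for r in range(n_strata - 1, 0, -1):
        nwk = f"({nwk},{clade(int(sizes[r - 1]))})"
    return species_tree_from_string(nwk + ";", focal)


# ---------------------------------------------------------------------------
# Dollo presence/absence simulation


@dataclass
class DolloSimParams:
    """Parameters of the single-gain / stochastic-loss simulation.

    ``gain_weights`` is a probability vector over strata 1..S (1 =
    root); ``loss_prob`` is the per-branch Bernoulli loss probability
    applied independently to every branch strictly below the gain node,
    except branches on the gain-to-focal path (presence in the focal
    species is forced, matching orthogroups anchored on its proteome).
    """

    n_genes: int = 2000
    gain_weights: Optional[Sequence[float]] = None
    loss_prob: float = 0.2
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.loss_prob < 1:
            raise ValueError("loss_prob must be in [0, 1)")
        if self.gain_weights is not None:
            w = np.asarray(self.gain_weights, dtype=float)
            if (w < 0).any() or not np.isclose(w.sum(), 1.0):
                raise ValueError("gain_weights must be a probability vector")


def simulate_dollo_matrix(tree: SpeciesTree, params: DolloSimParams):
    """Draw orthogroup presence/absence patterns under the Dollo model.

    Returns
    -------
    (matrix, truth)
        ``matrix`` is an orthogroup x species 0/1 DataFrame;
        ``truth`` is a DataFrame indexed by orthogroup id with columns
        ``true_stratum`` (gain rank) and ``true_gain_label``.
    """
    rng = np.random.default_rng(params.rng_seed)
    S = tree.n_strata
    if params.gain_weights is None:
        weights = np.full(S, 1.0 / S)
    else:
        weights = np.asarray(params.gain_weights, dtype=float)
        if len(weights) != S:
            raise ValueError(f"gain_weights must have length S={S}")
    ranks = rng.choice(np.arange(1, S + 1), size=params.n_genes, p=weights)

    focal_path = [id(n) for n in tree.stratum_nodes]
    species = sorted(tree.leaf_names)
    col = {sp: j for j, sp in enumerate(species)}
    mat = np.zeros((params.n_genes, len(species)), dtype=int)

    for g, rank in enumerate(ranks):
        gain = tree.stratum_nodes[rank - 1]
        protected = set(focal_path[rank - 1 :])
        stack = [(gain, True)]
        while stack:
            node, alive = stack.pop()
            if node.is_leaf():
                if alive:
                    mat[g, col[node.taxon.label]] = 1
                continue
            for child in node.child_nodes():
                if id(child) in protected:
                    stack.append((child, alive))
                elif alive and rng.random() >= params.loss_prob:
                    stack.append((child, True))
                # lost (or parent already lost): subtree absent
    og_ids = [f"OG{g:05d}" for g in range(params.n_genes)]
    matrix = pd.DataFrame(mat, index=pd.Index(og_ids, name="orthogroup_id"), columns=species)
    truth = pd.DataFrame(
        {
            "true_stratum": ranks,
            "true_gain_label": [tree.stratum_label(int(r)) for r in ranks],
        },
        index=matrix.index,
    )
    return matrix, truth


# ---------------------------------------------------------------------------
# Expression simulation


def default_profiles(n_timepoints: int, n_profiles: int = 5) -> np.ndarray:
    """Sharply-activated unit-scale temporal programs.

    The programs emulate distinct transcriptional waves: "growth"
    programs that shut off sharply at staggered early times, a
    transient mid-course pulse, and "late" programs activated sharply
    at staggered late times. Switches complete within roughly one
    sampling interval, and the shapes stay distinct after per-gene
    standardization (pure time-shifted copies of one sigmoid would
    collapse to nearly collinear z-scored profiles). Values lie in
    (0, 1].
    """
    if n_profiles < 1:
        raise ValueError("need at least one profile")
    t = np.arange(n_timepoints, dtype=float)
    tmax = n_timepoints - 1
    sharp = max(0.35 * tmax / 9.0, 0.25)

    def down(frac):
        return 0.05 + 0.95 / (1.0 + np.exp((t - frac * tmax) / sharp))

    def up(frac):
        return 0.05 + 0.95 / (1.0 + np.exp(-(t - frac * tmax) / sharp))

    def pulse(frac, width=1.4):
        return 0.05 + 0.95 * np.exp(-((t - frac * tmax) ** 2) / (2 * (width * sharp * 3) ** 2))

    n_down = n_profiles // 2
    has_pulse = n_profiles >= 3 and n_profiles % 2 == 1
    n_up = n_profiles - n_down - int(has_pulse)
    shapes = [down(f) for f in np.linspace(0.25, 0.5, n_down)]
    if has_pulse:
        shapes.append(pulse(0.62))
    shapes += [up(f) for f in np.linspace(0.7, 0.9, n_up)]
    profiles = np.array([p / p.max() for p in shapes[:n_profiles]])
    return profiles


@dataclass
class ExprSimParams:
    """Parameters of the replicated time-course expression simulation.

    ``hourglass_delta`` couples gene age to mid-phase amplitude: the
    mean of gene *i* at a mid-phase timepoint is multiplied by
    ``1 + hourglass_delta * w(age_i)`` where ``w`` maps the oldest
    stratum to +1 and the youngest to -1 linearly. Positive values
    plant an hourglass (old genes up in mid-phase, so the
    transcriptome age index dips); negative values plant the inverse
    pattern; zero leaves the age-expression association null.
    ``background_sigma`` is the stationary log2 standard deviation of
    the mean-reverting random trajectories followed by unclustered
    expressed genes (0 makes them flat); their step-to-step
    autocorrelation is fixed at 0.3, so backgrounds vary smoothly in
    time yet stay mutually near-independent. ``replicate_shift``
    delays the biology of replicate 2 by that many
    timepoints while keeping its nominal labels, emulating a replicate
    that runs slow.
    """

    n_timepoints: int = 10
    n_replicates: int = 2
    cluster_profiles: Optional[np.ndarray] = None
    cluster_sizes: Sequence[int] = (100, 100, 100, 100, 100)
    frac_low_expression: float = 0.5
    noise_sigma: float = 0.2
    background_sigma: float = 0.6
    hourglass_delta: float = 0.0
    replicate_shift: int = 0
    phase_counts: Sequence[int] = (2, 4, 4)
    t_start: float = 6.0
    t_interval: float = 6.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sigma < 0 or self.background_sigma < 0:
            raise ValueError("noise_sigma and background_sigma must be >= 0")
        if not 0 <= self.frac_low_expression <= 1:
            raise ValueError("frac_low_expression must be in [0, 1]")
        if self.cluster_profiles is None:
            self.cluster_profiles = default_profiles(
                self.n_timepoints, len(self.cluster_sizes)
            )
        self.cluster_profiles = np.asarray(self.cluster_profiles, dtype=float)
        if self.cluster_profiles.shape != (len(self.cluster_sizes), self.n_timepoints):
            raise ValueError("cluster_profiles must be n_clusters x n_timepoints")
        if sum(self.phase_counts) != self.n_timepoints:
            raise ValueError("phase_counts must sum to n_timepoints")

    @property
    def mid_mask(self) -> np.ndarray:
        e, m, _ = self.phase_counts
        mask = np.zeros(self.n_timepoints, dtype=bool)
        mask[e : e + m] = True
        return mask


def simulate_expression(
    ages: pd.Series,
    params: ExprSimParams,
    true_clusters: Optional[pd.Series] = None,
):
    """Draw a replicated tpm time course for genes with known ages.

    Parameters
    ----------
    ages
        gene_id -> stratum (integers 1..S, 1 oldest). All genes of the
        dataset must appear.
    true_clusters
        Optional gene_id -> planted cluster id (1-based, NA for
        unclustered genes). When omitted, cluster members are drawn at
        random according to ``params.cluster_sizes`` and the
        low-expression subset is drawn from the remaining genes.

    Returns
    -------
    (data, truth)
        ``data`` is an :class:`ExpressionDataset`; ``truth`` is a
        DataFrame indexed by gene id with columns ``true_cluster``
        (nullable integer) and ``low_expression`` (bool), plus a
        ``pattern_kind`` attribute in ``truth.attrs``.
    """
    rng = np.random.default_rng(params.rng_seed)
    genes = ages.index
    n_genes = len(genes)
    n_clustered = int(sum(params.cluster_sizes))
    if n_clustered > n_genes:
        raise ValueError("sum(cluster_sizes) exceeds number of genes")

    if true_clusters is None:
        perm = rng.permutation(n_genes)
        cluster_of = np.zeros(n_genes, dtype=int)  # 0 = unclustered
        pos = 0
        for c, size in enumerate(params.cluster_sizes, start=1):
            cluster_of[perm[pos : pos + size]] = c
            pos += size
        free = perm[pos:]
    else:
        cluster_of = (
            true_clusters.reindex(genes).fillna(0).astype(int).to_numpy()
        )
        free = np.flatnonzero(cluster_of == 0)
        rng.shuffle(free)
    n_low = int(round(params.frac_low_expression * n_genes))
    if n_low > len(free):
        raise ValueError(
            "frac_low_expression too large: low-expression genes are drawn "
            "from the unclustered remainder"
        )
    low_mask = np.zeros(n_genes, dtype=bool)
    low_mask[free[:n_low]] = True

    T, R = params.n_timepoints, params.n_replicates
    # baseline abundance: expressed genes span ~5-200 tpm, the low
    # fraction is placed so its expected tpm mean stays below 0.5
    base = 10 ** rng.uniform(0.7, 2.3, size=n_genes)
    base[low_mask] = rng.uniform(0.01, 0.4, size=low_mask.sum()) / np.exp(
        params.noise_sigma**2 / 2.0
    )

    profiles = np.vstack([np.ones(T), params.cluster_profiles])  # row 0: flat
    prof_per_gene = profiles[cluster_of].copy()  # n_genes x T
    # unclustered expressed genes follow their own mean-reverting
    # random trajectory (stationary AR(1) on log2 scale, one
    # trajectory per gene shared by the replicates) instead of a
    # planted program; low-expression genes stay flat
    bg = (cluster_of == 0) & ~low_mask
    if bg.any() and params.background_sigma > 0:
        rho = 0.3
        eps = rng.normal(0.0, 1.0, size=(int(bg.sum()), T))
        x = np.empty_like(eps)
        x[:, 0] = eps[:, 0]
        for t in range(1, T):
            x[:, t] = rho * x[:, t - 1] + np.sqrt(1 - rho**2) * eps[:, t]
        walks = np.exp2(params.background_sigma * x)
        prof_per_gene[bg] = walks / walks.max(axis=1, keepdims=True)

    S = int(ages.max())
    a = ages.to_numpy(dtype=float)
    w = np.zeros(n_genes) if S <= 1 else 1.0 - 2.0 * (a - 1.0) / (S - 1.0)
    mid = params.mid_mask.astype(float)
    interaction = 1.0 + params.hourglass_delta * np.outer(w, mid)
    if (interaction < 0).any():
        logger.warning(
            "hourglass_delta produced negative means for %d gene-timepoint "
            "cells; clipped at 0", int((interaction < 0).sum()),
        )
        interaction = np.clip(interaction, 0.0, None)

    tps = params.t_start + params.t_interval * np.arange(T)
    cols, vals, meta_rows = [], [], []
    for rep in range(1, R + 1):
        idx = np.arange(T)
        if rep == 2 and params.replicate_shift:
            # replicate 2 lags: its sample at slot t shows the biology
            # of slot t - shift (edges clamp)
            idx = np.clip(idx - params.replicate_shift, 0, T - 1)
        mean = base[:, None] * prof_per_gene[:, idx] * interaction[:, idx]
        noise = rng.normal(0.0, params.noise_sigma, size=(n_genes, T))
        vals.append(mean * np.exp(noise))
        for t in range(T):
            cols.append(f"t{int(tps[t]):03d}_r{rep}")
            meta_rows.append((cols[-1], tps[t], rep))

    values = pd.DataFrame(
        np.hstack(vals), index=pd.Index(genes, name="gene_id"), columns=cols
    )
    meta = pd.DataFrame(
        meta_rows, columns=["sample_id", "timepoint", "replicate"]
    ).set_index("sample_id")
    data = ExpressionDataset(values=values, meta=meta)

    truth = pd.DataFrame(
        {
            "true_cluster": pd.array(
                np.where(cluster_of == 0, pd.NA, cluster_of), dtype="Int64"
            ),
            "low_expression": low_mask,
        },
        index=pd.Index(genes, name="gene_id"),
    )
    if params.hourglass_delta > 0:
        truth.attrs["pattern_kind"] = "hourglass"
    elif params.hourglass_delta < 0:
        truth.attrs["pattern_kind"] = "inverse"
    else:
        truth.attrs["pattern_kind"] = "flat"
    return data, truth


# ---------------------------------------------------------------------------
# Full labelled study


@dataclass
class StudyBundle:
    """A complete synthetic study with ground truth."""

    tree: SpeciesTree
    phyletic: pd.DataFrame
    membership: pd.Series
    expression: ExpressionDataset
    truth: pd.DataFrame  # per gene: true_stratum, true_cluster, low_expression
    og_truth: pd.DataFrame  # per orthogroup: true_stratum


def simulate_study(
    n_genes: int = 2000,
    n_strata: int = 10,
    n_outgroups: int = 30,
    loss_prob: float = 0.2,
    frac_no_orthogroup: float = 0.1,
    gain_weights: Optional[Sequence[float]] = None,
    expr_params: Optional[ExprSimParams] = None,
    age_bias_cluster: Optional[int] = None,
    rng_seed: int = 0,
) -> StudyBundle:
    """Simulate a full study: tree, phyletic matrix, membership, expression.

    Genes map one-to-one onto orthogroups except a ``frac_no_orthogroup``
    subset with no ortholog anywhere (true stratum S). When
    ``age_bias_cluster`` names a planted expression cluster, the genes
    of that cluster draw their true stratum from a young-skewed
    distribution (mass concentrated on the youngest three strata), so
    age and cluster membership are coupled — the configuration used to
    study enrichment of young strata in late clusters.
    """
    rng = np.random.default_rng(rng_seed)
    tree = simulate_species_tree(n_strata, n_outgroups)
    S = tree.n_strata
    if expr_params is None:
        expr_params = ExprSimParams(rng_seed=int(rng.integers(2**31)))
    genes = pd.Index([f"g{i:05d}" for i in range(n_genes)], name="gene_id")

    # planted cluster assignment (0 = unclustered)
    perm = rng.permutation(n_genes)
    cluster_of = np.zeros(n_genes, dtype=int)
    pos = 0
    for c, size in enumerate(expr_params.cluster_sizes, start=1):
        cluster_of[perm[pos : pos + size]] = c
        pos += size

    # true strata: baseline distribution, young-skewed for the biased cluster
    if gain_weights is None:
        weights = np.full(S, 1.0 / S)
    else:
        weights = np.asarray(gain_weights, dtype=float)
    strata = rng.choice(np.arange(1, S + 1), size=n_genes, p=weights / weights.sum())
    if age_bias_cluster is not None:
        young = np.zeros(S)
        young[-3:] = (0.2, 0.3, 0.5)
        sel = cluster_of == age_bias_cluster
        strata[sel] = rng.choice(np.arange(1, S + 1), size=sel.sum(), p=young)

    # orthogroup membership: a frac_no_orthogroup subset of unclustered
    # genes has no ortholog anywhere (stratum S by definition)
    no_og = np.zeros(n_genes, dtype=bool)
    free = np.flatnonzero(cluster_of == 0)
    rng.shuffle(free)
    n_no = int(round(frac_no_orthogroup * n_genes))
    no_og[free[:n_no]] = True
    strata[no_og] = S

    with_og = np.flatnonzero(~no_og)
    og_ids = [f"OG{i:05d}" for i in range(len(with_og))]
    membership = pd.Series(pd.NA, index=genes, dtype="object", name="orthogroup_id")
    membership.iloc[with_og] = og_ids

    # presence patterns: one orthogroup per gene-with-orthogroup, gain
    # node fixed at the gene's true stratum, Dollo losses below it
    species = sorted(tree.leaf_names)
    col = {sp: j for j, sp in enumerate(species)}
    focal_path = [id(n) for n in tree.stratum_nodes]
    mat = np.zeros((len(with_og), len(species)), dtype=int)
    for row, g in enumerate(with_og):
        rank = int(strata[g])
        gain = tree.stratum_nodes[rank - 1]
        protected = set(focal_path[rank - 1 :])
        stack = [(gain, True)]
        while stack:
            node, alive = stack.pop()
            if node.is_leaf():
                if alive:
                    mat[row, col[node.taxon.label]] = 1
                continue
            for child in node.child_nodes():
                if id(child) in protected:
                    stack.append((child, alive))
                elif alive and rng.random() >= loss_prob:
                    stack.append((child, True))
    phyletic = pd.DataFrame(
        mat, index=pd.Index(og_ids, name="orthogroup_id"), columns=species
    )
    og_truth = pd.DataFrame(
        {"true_stratum": strata[with_og]}, index=phyletic.index
    )

    ages = pd.Series(strata, index=genes, name="stratum")
    clusters = pd.Series(
        pd.array(np.where(cluster_of == 0, pd.NA, cluster_of), dtype="Int64"),
        index=genes,
    )
    expression, expr_truth = simulate_expression(ages, expr_params, true_clusters=clusters)

    truth = pd.DataFrame(
        {
            "true_stratum": strata,
            "true_cluster": expr_truth["true_cluster"],
            "low_expression": expr_truth["low_expression"],
            "has_orthogroup": ~no_og,
        },
        index=genes,
    )
    truth.attrs["pattern_kind"] = expr_truth.attrs["pattern_kind"]
    return StudyBundle(
        tree=tree,
        phyletic=phyletic,
        membership=membership,
        expression=expression,
        truth=truth,
        og_truth=og_truth,
    )
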