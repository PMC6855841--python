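import numpy as np
import pandas as pd
import pytest

import phylotx as px


@pytest.fixture(scope="session")
def toy_tree():
    """((((F,A),B),C),D) with focal F: 5 strata."""
    return px.species_tree_from_string("((((F,A),B),C),D);", "F")


@pytest.fixture(scope="session")
def six_leaf_tree():
    """(((((F,A),B),C),D),E) with focal F: 6 strata, 31 focal patterns."""
    return px.species_tree_from_string("(((((F,A),B),C),D),E);", "F")


@pytest.fixture(scope="session")
def study_tree():
    """The default 10-stratum, 31-species simulated tree."""
    return px.simulate_species_tree(10, 30)


@pytest.fixture(scope="session")
def uniform_ages():
    """2000 genes with strata drawn uniformly from 1..10 (seed 0)."""
    rng = np.random.default_rng(0)
    genes = pd.Index([f"g{i:05d}" for i in range(2000)], name="gene_id")
    return pd.Series(rng.integers(1, 11, 2000), index=genes, name="stratum")


@pytest.fixture(scope="session")
def planted_clusters_dataset():
    """Five planted profile clusters (100 genes each) + 500 unstructured
    genes, two replicates, noise 0.2 — the clustering benchmark."""
    rng = np.random.default_rng(0)
    genes = pd.Index([f"g{i:04d}" for i in range(1000)], name="gene_id")
    ages = pd.Series(rng.integers(1, 11, 1000), index=genes, name="stratum")
    params = px.ExprSimParams(
        cluster_sizes=(100,) * 5,
        frac_low_expression=0.0,
        noise_sigma=0.2,
        background_sigma=0.0,
        rng_seed=3,
    )
    data, truth = px.simulate_expression(ages, params)
    return data, truth


@pytest.fixture(scope="session")
def planted_assignment(planted_clusters_dataset):
    data, truth = planted_clusters_dataset
    norm = px.normalize(data, per_replicate=True)
    assignment = px.consensus_cluster(norm, px.RunConfig(rng_seed=5))
    return norm, assignment, truth


def dollo_min_losses(node, present):
    """Independent loss-counting oracle.

    Minimal number of loss events needed to explain ``present`` with a
    single gain at ``node``: every maximal subtree below the gain that
    contains no present leaf is one loss.
    """

    def walk(n):
        if n.is_leaf():
            return (n.taxon.label in present), 0
        losses = 0
        any_present = False
        for child in n.child_nodes():
            has, sub = walk(child)
            if has:
                any_present = True
                losses += sub
            else:
                losses += 1
        if not any_present:
            return False, 0
        return True, losses

    covered = {lf.taxon.label for lf in node.leaf_iter()}
    if not set(present) <= covered:
        return None  # single gain here cannot explain the pattern
    return walk(node)[1]
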