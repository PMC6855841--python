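"""End-to-end pipeline: ages -> filter -> align -> cluster -> TAI ->
hourglass -> per-stratum summaries -> enrichment.

:func:`run_all` takes the four validated inputs (tree, phyletic matrix,
membership, expression) plus a :class:`~phylotx.io.RunConfig` and
returns a :class:`RunResult`; :func:`write_results` dumps every result
table to an output directory (TSV + JSON).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, asdict, field
from pathlib import Path
from typing import Dict, Optional

import pandas as pd

from . import ages as ages_mod
from . import cluster as cluster_mod
from . import enrich as enrich_mod
from . import preprocess, tai
from .io import ExpressionDataset, RunConfig, FLOAT_FMT
from .trees import SpeciesTree

logger = logging.getLogger("phylotx")

__all__ = ["RunResult", "run_all", "write_results"]


@dataclass
class RunResult:
    ages: pd.DataFrame
    composition: pd.DataFrame
    filtered: ExpressionDataset
    sample_dendrogram: preprocess.SampleDendrogram
    assignment: pd.Series
    cluster_profiles: pd.DataFrame
    tai_profile: pd.DataFrame
    hourglass: Dict[int, tai.HourglassResult]
    cv_per_gene: pd.DataFrame
    cv_summary: pd.DataFrame
    mean_expr_summary: pd.DataFrame
    enrichment: pd.DataFrame
    config: RunConfig


def run_all(
    tree: SpeciesTree,
    phyletic: pd.DataFrame,
    membership: pd.Series,
    expression: ExpressionDataset,
    config: Optional[RunConfig] = None,
) -> RunResult:
    """Run every analysis stage on validated inputs."""
    config = config or RunConfig()
    logger.info("run config: seed=%d hash=%s", config.rng_seed, _config_hash(config))

    age_table = ages_mod.assign_ages(phyletic, membership, tree)
    composition = ages_mod.stratum_composition(age_table)

    filtered = preprocess.filter_low_expression(expression, config.filter_threshold)
    logger.info("filter: retained %d / %d genes", len(filtered.gene_ids), len(expression.gene_ids))
    if config.replicate_shift_hours:
        filtered = preprocess.align_replicates(filtered, config.replicate_shift_hours)

    dendro = preprocess.sample_correlation_clustering(filtered)

    norm = preprocess.normalize(filtered, per_replicate=True)
    assignment = cluster_mod.consensus_cluster(norm, config)
    profiles = cluster_mod.mean_cluster_profiles(norm, assignment)

    expressed_ages = age_table.loc[filtered.gene_ids]
    tai_profile = tai.compute_tai(filtered, expressed_ages)
    n_tp = min(len(filtered.timepoints(rep)) for rep in filtered.replicates)
    phases = tai.PhasePartition.from_counts(config.phase_counts, n_tp)
    hourglass = tai.reductive_hourglass_test(
        filtered, expressed_ages, phases,
        n_permutations=config.n_permutations, seed=config.rng_seed,
    )

    cv = tai.cv_by_stratum(filtered, expressed_ages)
    cv_summary = tai.stratum_summary(cv, "cv")
    me = tai.mean_expression_by_stratum(filtered, expressed_ages)
    me_summary = tai.stratum_summary(me, "mean_tpm")

    enrichment = enrich_mod.stratum_cluster_enrichment(expressed_ages, assignment)

    return RunResult(
        ages=age_table,
        composition=composition,
        filtered=filtered,
        sample_dendrogram=dendro,
        assignment=assignment,
        cluster_profiles=profiles,
        tai_profile=tai_profile,
        hourglass=hourglass,
        cv_per_gene=cv,
        cv_summary=cv_summary,
        mean_expr_summary=me_summary,
        enrichment=enrichment,
        config=config,
    )


def _config_hash(config: RunConfig) -> str:
    blob = json.dumps(asdict(config), sort_keys=True, default=list).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def write_results(result: RunResult, out_dir) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    result.ages.to_csv(out / "gene_ages.tsv", sep="\t", na_rep="")
    result.composition.to_csv(out / "stratum_composition.tsv", sep="\t",
                              float_format=FLOAT_FMT)
    result.assignment.to_csv(out / "cluster_assignment.tsv", sep="\t", na_rep="unassigned")
    result.cluster_profiles.to_csv(out / "cluster_profiles.tsv", sep="\t",
                                   index=False, float_format=FLOAT_FMT)
    result.tai_profile.to_csv(out / "tai_profile.tsv", sep="\t", index=False,
                              float_format=FLOAT_FMT)
    result.cv_summary.to_csv(out / "cv_by_stratum.tsv", sep="\t", float_format=FLOAT_FMT)
    result.mean_expr_summary.to_csv(out / "mean_expression_by_stratum.tsv", sep="\t",
                                    float_format=FLOAT_FMT)
    result.enrichment.to_csv(out / "stratum_cluster_enrichment.tsv", sep="\t",
                             index=False, float_format=FLOAT_FMT)
    (out / "sample_dendrogram.nwk").write_text(result.sample_dendrogram.as_newick() + "\n")
    result.sample_dendrogram.merge_table().to_csv(out / "sample_dendrogram_merges.tsv",
                                                  sep="\t", index=False)
    report = {
        "config": asdict(result.config),
        "config_hash": _config_hash(result.config),
        "hourglass": {str(rep): r.to_dict() for rep, r in result.hourglass.items()},
        "n_clusters": int(result.assignment.dropna().nunique()),
        "n_assigned": int(result.assignment.notna().sum()),
        "n_genes_filtered": int(len(result.filtered.gene_ids)),
    }
    (out / "report.json").write_text(json.dumps(report, indent=2, default=list) + "\n")
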