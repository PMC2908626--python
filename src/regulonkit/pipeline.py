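"""End-to-end orchestration: cluster, scan, propagate, profile, assign."""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from regulonkit.genome_io import GenomeSet
from regulonkit.motif_scanning import (
    MotifModel,
    OperonMap,
    build_motif_model,
    predict_operons_fallback,
    propagate_scores_df,
    scan_promoters,
    standardize_per_species,
)
from regulonkit.regulon_inference import (
    PhyloProfile,
    RegulonAssignment,
    assign_targets,
    build_regulator_profile,
    build_target_profile,
)
from regulonkit.similarity_graph import (
    SimilarityGraph,
    mcl,
    normalize_scores,
    rescale_by_species_pair,
)

logger = logging.getLogger(__name__)


@dataclass
class PipelineResult:
    """Artifacts of one full pipeline run."""

    clusters: dict[str, list[str]]          # ortholog partition (group id -> genes)
    model: MotifModel
    scores: pd.DataFrame                    # per-gene raw/z/propagated_z/significant
    regulator_groups: dict[str, list[str]]  # regulator name -> member genes
    regulator_profiles: dict[str, PhyloProfile]
    target_profiles: dict[str, PhyloProfile]
    assignments: list[RegulonAssignment]
    species_order: list[str]
    operon_map: OperonMap


def run_pipeline(
    genome_set: GenomeSet,
    similarity: pd.DataFrame,
    aligned_sites: Sequence[str],
    regulator_seeds: Mapping[str, Sequence[str]],
    operon_map: OperonMap | None = None,
    *,
    inflation: float = 3.0,
    percentile: float = 98.0,
    window: int = 300,
    z_threshold: float = 3.0,
    cutoff: float = 0.2,
    pseudocount: float = 0.5,
    background: Sequence[float] | None = None,
    species_order: Sequence[str] | None = None,
    mcl_kwargs: dict | None = None,
) -> PipelineResult:
    """Run the whole regulon-reconstruction pipeline.

    ``similarity`` is the filtered BLAST edge table (columns ``query,
    subject, bitscore``); ``regulator_seeds`` names each regulator of
    interest and lists one or more known member genes — the regulator
    sub-family is the union of the ortholog clusters containing those seeds.
    Without an ``operon_map`` the distance-based fallback predictor is used.
    """
    gene_species = genome_set.gene_species()

    norm = normalize_scores(similarity[["query", "subject", "bitscore"]])
    rescaled = rescale_by_species_pair(norm, gene_species, percentile=percentile)
    graph = SimilarityGraph.from_edges(rescaled, nodes=list(gene_species))
    raw_clusters = mcl(graph, inflation=inflation, **(mcl_kwargs or {}))
    clusters = {f"OG{i + 1:05d}": members for i, members in enumerate(raw_clusters)}
    gene_cluster = {g: cid for cid, members in clusters.items() for g in members}

    model = build_motif_model(aligned_sites, pseudocount=pseudocount,
                              background=background)
    promoters = genome_set.promoters(window=window)
    scores = scan_promoters(promoters, model)
    scores["species_id"] = scores["gene_id"].map(gene_species)
    scores = standardize_per_species(scores, z_threshold=z_threshold)
    if operon_map is None:
        logger.info("no operon table supplied; using the distance-based fallback")
        operon_map = predict_operons_fallback(genome_set.genes)
    scores = propagate_scores_df(scores, operon_map, z_threshold=z_threshold)

    order = list(species_order) if species_order is not None else list(genome_set.species)
    significant = dict(zip(scores["gene_id"], scores["significant"]))

    regulator_groups: dict[str, list[str]] = {}
    regulator_cluster_ids: set[str] = set()
    for reg, seeds in regulator_seeds.items():
        cids = {gene_cluster[s] for s in seeds if s in gene_cluster}
        if not cids:
            raise ValueError(f"no cluster contains any seed gene of regulator {reg!r}")
        members = sorted(g for cid in cids for g in clusters[cid])
        regulator_groups[reg] = members
        regulator_cluster_ids |= cids

    regulator_profiles = {
        reg: build_regulator_profile(members, gene_species, order)
        for reg, members in regulator_groups.items()
    }
    target_profiles = {
        cid: build_target_profile(members, significant, gene_species, order)
        for cid, members in clusters.items()
        if cid not in regulator_cluster_ids
    }
    assignments = assign_targets(target_profiles, regulator_profiles, cutoff=cutoff)

    return PipelineResult(
        clusters=clusters,
        model=model,
        scores=scores,
        regulator_groups=regulator_groups,
        regulator_profiles=regulator_profiles,
        target_profiles=target_profiles,
        assignments=assignments,
        species_order=order,
        operon_map=operon_map,
    )
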