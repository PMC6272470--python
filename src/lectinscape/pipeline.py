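"""End-to-end convenience wrapper: four inputs in, all survey tables out."""

from __future__ import annotations

from dataclasses import dataclass, field

from . import annotation_io as aio
from .expansion_attribution import attribute_mechanisms, family_mechanism_table
from .family_classifier import (
    FamilyDefinitionSet,
    assign_families,
    default_family_definitions,
)
from .genome_distribution import (
    chromosome_shares,
    family_counts,
    map_coordinates,
    summarize_families,
)
from .records import (
    CollinearPair,
    FamilyAssignment,
    GeneRecord,
    MechanismPartition,
    SegmentalAssignment,
    TandemCluster,
    TopologyAnnotation,
)
from .segmental_duplication import assign_segmental, segmental_summary
from .tandem_duplication import (
    detect_tandem_clusters,
    summarize_tandem,
    tandem_gene_ids,
)

__all__ = ["PipelineResult", "run_pipeline"]


@dataclass
class PipelineResult:
    genes: list[GeneRecord]
    assignments: dict[str, FamilyAssignment]
    clusters: list[TandemCluster]
    segmental: SegmentalAssignment
    partition: MechanismPartition
    family_summary: list = field(default_factory=list)
    tandem_summary: dict = field(default_factory=dict)
    segmental_summary: dict = field(default_factory=dict)
    family_mechanisms: dict = field(default_factory=dict)
    chromosome_shares: dict = field(default_factory=dict)
    map_rows: list = field(default_factory=list)


def run_pipeline(
    gff3,
    domain_tsv,
    topology_tsv,
    collinearity_txt,
    defs: FamilyDefinitionSet | None = None,
    *,
    max_intervening: int = 10,
    ks_max: float = 1.0,
) -> PipelineResult:
    """Classify, detect tandem clusters, assign segmental genes and
    attribute mechanisms in one pass over the four inputs."""
    defs = defs or default_family_definitions()

    genes = aio.read_gene_annotation(gff3)
    hits = aio.read_domain_table(domain_tsv)
    topology = aio.read_topology_table(topology_tsv)
    pairs: list[CollinearPair] = aio.read_collinearity(collinearity_txt)

    hits_by_gene: dict[str, list] = {}
    for h in hits:
        hits_by_gene.setdefault(h.protein_id, []).append(h)
    topology_by_gene: dict[str, TopologyAnnotation] = {
        t.protein_id: t for t in topology
    }

    assignments = assign_families(hits_by_gene, defs, topology_by_gene)
    clusters = detect_tandem_clusters(genes, assignments, max_intervening)
    tandem_ids = tandem_gene_ids(clusters)
    segmental = assign_segmental(pairs, assignments.keys(), ks_max)
    partition = attribute_mechanisms(
        tandem_ids, segmental.segmental_genes, assignments.keys()
    )

    occupancy: dict[str, set[str]] = {}
    gene_by_id = {g.gene_id: g for g in genes}
    for gid, a in assignments.items():
        g = gene_by_id.get(gid)
        if g is not None and g.is_placed:
            occupancy.setdefault(a.primary_family, set()).add(g.chromosome)

    return PipelineResult(
        genes=genes,
        assignments=assignments,
        clusters=clusters,
        segmental=segmental,
        partition=partition,
        family_summary=summarize_families(family_counts(assignments), occupancy),
        tandem_summary=summarize_tandem(clusters, assignments),
        segmental_summary=segmental_summary(segmental, assignments),
        family_mechanisms=family_mechanism_table(partition, assignments),
        chromosome_shares=chromosome_shares(assignments, genes),
        map_rows=map_coordinates(genes, assignments, tandem_ids),
    )
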