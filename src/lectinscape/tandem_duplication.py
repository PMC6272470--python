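"""Tandem-duplication cluster detection.

Two genes are tandem-linked when they (1) belong to the same lectin
family, (2) sit on the same chromosome and (3) are separated by no more
than ``max_intervening`` annotated genes of any family (rank difference
minus one).  Clusters are the maximal transitive chains under this
relation, so a cluster can span more than ``max_intervening`` genes end
to end.  Unplaced (scaffold) genes never join clusters.
"""

from __future__ import annotations

from typing import Iterable, Mapping

from .records import FamilyAssignment, GeneRecord, TandemCluster

__all__ = ["detect_tandem_clusters", "summarize_tandem", "tandem_gene_ids"]

DEFAULT_MAX_INTERVENING = 10


def detect_tandem_clusters(
    genes: Iterable[GeneRecord],
    assignments: Mapping[str, FamilyAssignment],
    max_intervening: int = DEFAULT_MAX_INTERVENING,
) -> list[TandemCluster]:
    """Find all maximal tandem clusters of lectin genes.

    ``genes`` must carry ranks over the FULL annotation (lectin and
    non-lectin genes alike): the intervening-gene count between ranks
    r1 < r2 is r2 - r1 - 1 over all annotated genes.  Each lectin gene
    participates under its primary family only.

    Returns clusters sorted by (family, chromosome, first-member rank)
    with ids ``TD_0001``....
    """
    if max_intervening < 0:
        raise ValueError("max_intervening must be >= 0")

    by_family_chrom: dict[tuple[str, str], list[GeneRecord]] = {}
    for g in genes:
        a = assignments.get(g.gene_id)
        if a is None or not g.is_placed:
            continue
        by_family_chrom.setdefault((a.primary_family, g.chromosome), []).append(g)

    clusters: list[TandemCluster] = []
    for (family, chrom) in sorted(by_family_chrom):
        members = sorted(by_family_chrom[(family, chrom)], key=lambda g: g.rank)
        chain: list[GeneRecord] = []
        for g in members:
            if chain and (g.rank - chain[-1].rank - 1) <= max_intervening:
                chain.append(g)
            else:
                if len(chain) >= 2:
                    clusters.append(_make_cluster(family, chrom, chain))
                chain = [g]
        if len(chain) >= 2:
            clusters.append(_make_cluster(family, chrom, chain))

    return [
        TandemCluster(
            cluster_id=f"TD_{i:04d}",
            family=c.family,
            chromosome=c.chromosome,
            members=c.members,
            gaps=c.gaps,
        )
        for i, c in enumerate(clusters, start=1)
    ]


def _make_cluster(family: str, chrom: str, chain: list[GeneRecord]) -> TandemCluster:
    gaps = tuple(b.rank - a.rank - 1 for a, b in zip(chain, chain[1:]))
    return TandemCluster(
        cluster_id="TD_tmp",
        family=family,
        chromosome=chrom,
        members=tuple(g.gene_id for g in chain),
        gaps=gaps,
    )


def tandem_gene_ids(clusters: Iterable[TandemCluster]) -> frozenset[str]:
    """Distinct genes involved in any tandem cluster."""
    return frozenset(gid for c in clusters for gid in c.members)


def summarize_tandem(
    clusters: Iterable[TandemCluster],
    assignments: Mapping[str, FamilyAssignment] | None = None,
) -> dict[str, tuple[int, int]]:
    """Per-family (n_clusters, n_distinct_genes_involved), plus 'total'.

    Families present in ``assignments`` but without clusters appear
    with zeros, so zero rows are visible in summaries.
    """
    per_family: dict[str, tuple[set, set]] = {}
    if assignments is not None:
        for a in assignments.values():
            per_family.setdefault(a.primary_family, (set(), set()))
    for c in clusters:
        clus, genes = per_family.setdefault(c.family, (set(), set()))
        clus.add(c.cluster_id)
        genes.update(c.members)

    out = {
        fam: (len(clus), len(genes))
        for fam, (clus, genes) in sorted(per_family.items())
    }
    out["total"] = (
        sum(v[0] for v in out.values()),
        sum(v[1] for v in out.values()),
    )
    return out
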