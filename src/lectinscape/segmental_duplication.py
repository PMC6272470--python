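"""Segmental-duplication assignment from Ks-filtered collinear blocks.

A lectin gene counts as segmentally duplicated when it appears on
either end of at least one retained collinear pair.  Pairs whose Ks
(synonymous substitution rate) exceeds ``ks_max`` are excluded because
synonymous sites saturate and the Ks estimate becomes unreliable; the
boundary is strict — Ks exactly equal to ks_max is retained.  Pairs
without a Ks value are excluded conservatively, with their count
reported.
"""

from __future__ import annotations

from typing import Iterable, Mapping

from .records import CollinearPair, FamilyAssignment, SegmentalAssignment

__all__ = ["filter_pairs_by_ks", "assign_segmental", "segmental_summary"]

DEFAULT_KS_MAX = 1.0


def filter_pairs_by_ks(
    pairs: Iterable[CollinearPair], ks_max: float = DEFAULT_KS_MAX
) -> tuple[list[CollinearPair], list[tuple[CollinearPair, str]]]:
    """Split pairs into (retained, excluded-with-reason) by the Ks cutoff.

    Retained iff ks is present and ks <= ks_max (strictly-higher values
    are excluded).  Excluded reasons are ``"ks>max"`` or ``"missing"``.
    """
    if ks_max <= 0:
        raise ValueError("ks_max must be > 0")
    retained: list[CollinearPair] = []
    excluded: list[tuple[CollinearPair, str]] = []
    for p in pairs:
        if p.ks is None:
            excluded.append((p, "missing"))
        elif p.ks > ks_max:
            excluded.append((p, "ks>max"))
        else:
            retained.append(p)
    return retained, excluded


def assign_segmental(
    pairs: Iterable[CollinearPair],
    lectin_gene_ids: Iterable[str],
    ks_max: float = DEFAULT_KS_MAX,
) -> SegmentalAssignment:
    """Ks-filter the pairs and collect segmentally duplicated lectin genes.

    ``excluded_gene_count`` counts the lectin genes that appear only in
    excluded pairs — duplicates dropped from the dataset by the
    saturation filter.
    """
    lectins = frozenset(lectin_gene_ids)
    retained, excluded = filter_pairs_by_ks(list(pairs), ks_max)

    segmental: set[str] = set()
    blocks: set[str] = set()
    for p in retained:
        hit = {p.gene_a, p.gene_b} & lectins
        if hit:
            segmental.update(hit)
            blocks.add(p.block_id)
    excluded_only = {
        g
        for p, _reason in excluded
        for g in (p.gene_a, p.gene_b)
        if g in lectins
    } - segmental

    return SegmentalAssignment(
        segmental_genes=frozenset(segmental),
        blocks_with_lectins=frozenset(blocks),
        excluded_pairs=excluded,
        excluded_gene_count=len(excluded_only),
        retained_pairs=retained,
    )


def segmental_summary(
    assignment: SegmentalAssignment,
    assignments: Mapping[str, FamilyAssignment],
) -> dict[str, int]:
    """Per-family count of segmentally duplicated genes, plus 'total'.

    'total' is the distinct-gene count, which equals the column sum
    because each gene has one primary family.
    """
    per_family: dict[str, int] = {}
    for a in assignments.values():
        per_family.setdefault(a.primary_family, 0)
    for gid in assignment.segmental_genes:
        a = assignments.get(gid)
        if a is None:
            continue
        per_family[a.primary_family] += 1
    out = dict(sorted(per_family.items()))
    out["total"] = sum(per_family.values())
    return out
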