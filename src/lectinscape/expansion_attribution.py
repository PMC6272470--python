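"""Four-way mechanism attribution for gene-family expansion.

Every lectin gene is labelled tandem_only, segmental_only, both, or
other (the residual — retrotransposition and mechanisms not detected
here are never inferred positively).  The denominator for overall
percentages is the full lectin-gene universe including unplaced genes:
those can sit in collinear blocks (segmental) even though they cannot
join tandem clusters.
"""

from __future__ import annotations

from typing import Iterable, Mapping

from .genome_distribution import round_half_up
from .records import MECHANISMS, FamilyAssignment, MechanismPartition

__all__ = ["attribute_mechanisms", "family_mechanism_table"]


def attribute_mechanisms(
    tandem_genes: Iterable[str],
    segmental_genes: Iterable[str],
    all_lectin_genes: Iterable[str],
) -> MechanismPartition:
    """Partition the lectin gene universe by duplication mechanism.

    both = tandem ∩ segmental; tandem_only and segmental_only are the
    set differences; other is the complement.  Percentages (one
    decimal, rounded half-up) are over the whole universe and the
    unrounded counts sum to it exactly.
    """
    universe = set(all_lectin_genes)
    tandem = set(tandem_genes)
    segmental = set(segmental_genes)
    stray = (tandem | segmental) - universe
    if stray:
        raise ValueError(
            "genes outside the lectin universe: " + ", ".join(sorted(stray))
        )

    labels: dict[str, str] = {}
    for g in universe:
        in_t, in_s = g in tandem, g in segmental
        if in_t and in_s:
            labels[g] = "both"
        elif in_t:
            labels[g] = "tandem_only"
        elif in_s:
            labels[g] = "segmental_only"
        else:
            labels[g] = "other"

    counts = {m: 0 for m in MECHANISMS}
    for m in labels.values():
        counts[m] += 1
    n = len(universe)
    percentages = {
        m: round_half_up(100.0 * c / n, 1) if n else 0.0 for m, c in counts.items()
    }
    return MechanismPartition(
        labels=labels, overall_counts=counts, overall_percentages=percentages
    )


def family_mechanism_table(
    partition: MechanismPartition,
    assignments: Mapping[str, FamilyAssignment],
) -> dict[str, dict[str, float]]:
    """Per-family stacked mechanism shares (percent, one decimal).

    One row per family present in the assignments; a zero-gene family
    passed in via assignments cannot occur (assignments imply >= 1
    gene), but zero shares appear whenever a family lacks a mechanism.
    """
    per_family: dict[str, dict[str, int]] = {}
    for gid, label in partition.labels.items():
        a = assignments.get(gid)
        if a is None:
            continue
        row = per_family.setdefault(a.primary_family, {m: 0 for m in MECHANISMS})
        row[label] += 1

    out: dict[str, dict[str, float]] = {}
    for fam in sorted(per_family):
        row = per_family[fam]
        n = sum(row.values())
        out[fam] = {
            m: round_half_up(100.0 * c / n, 1) if n else 0.0
            for m, c in row.items()
        }
    return out
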