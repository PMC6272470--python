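"""Per-family counts, chromosome distribution and map coordinates.

Reproduces the survey-style bookkeeping: a 12-row family summary with
percentages of all lectin genes, human-readable chromosome localization
strings ("all except chr 5" for near-complete occupancy), per-chromosome
shares, and a drawn-to-scale coordinates table for chromosome maps.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping

from .records import LECTIN_FAMILIES, FamilyAssignment, GeneRecord

__all__ = [
    "FamilySummaryRow",
    "round_half_up",
    "summarize_families",
    "family_counts",
    "localization_string",
    "chromosome_shares",
    "map_coordinates",
    "default_chromosome_universe",
]


@dataclass(frozen=True)
class FamilySummaryRow:
    family: str
    n_genes: int
    percentage: float
    chromosomes: str = "/"


def round_half_up(value: float, ndigits: int = 1) -> float:
    """Decimal round-half-up (0.85 -> 0.9), matching printed-table style.

    Python's builtin ``round`` is banker's rounding; survey tables
    round halves away from zero.
    """
    q = Decimal(10) ** -ndigits
    return float(Decimal(str(value)).quantize(q, rounding=ROUND_HALF_UP))


def default_chromosome_universe(n: int = 20, prefix: str = "chr") -> tuple[str, ...]:
    """chr1..chrN — the soybean genome has 20 chromosomes."""
    return tuple(f"{prefix}{i}" for i in range(1, n + 1))


def family_counts(assignments: Mapping[str, FamilyAssignment]) -> dict[str, int]:
    """Count genes per primary family, zeros included for all 12 families."""
    counts = {fam: 0 for fam in LECTIN_FAMILIES}
    for a in assignments.values():
        counts.setdefault(a.primary_family, 0)
        counts[a.primary_family] += 1
    return counts


def summarize_families(
    counts_or_assignments,
    occupancy: Mapping[str, Iterable[str]] | None = None,
    universe: tuple[str, ...] | None = None,
) -> list[FamilySummaryRow]:
    """Build the 12-row family summary with percentages of the total.

    Accepts either a mapping family -> gene count or a mapping
    gene_id -> FamilyAssignment.  ``percentage`` is
    round_half_up(100 * n_family / n_total, 1).  All twelve lectin
    families are reported, zero-count ones included.  With
    ``occupancy`` (family -> chromosomes occupied) the localization
    column is filled, else "/" for empty families and "" otherwise.
    """
    values = list(counts_or_assignments.values())
    if values and hasattr(values[0], "primary_family"):
        counts = family_counts(counts_or_assignments)
    else:
        counts = {fam: 0 for fam in LECTIN_FAMILIES}
        counts.update({k: int(v) for k, v in counts_or_assignments.items()})

    total = sum(counts.values())
    if total == 0:
        warnings.warn("no lectin genes: percentages reported as 0.0", stacklevel=2)
    universe = universe or default_chromosome_universe()

    rows = []
    for fam in sorted(counts, key=lambda f: LECTIN_FAMILIES.index(f) if f in LECTIN_FAMILIES else 99):
        n = counts[fam]
        pct = round_half_up(100.0 * n / total, 1) if total else 0.0
        if occupancy is not None:
            loc = localization_string(occupancy.get(fam, ()), universe)
        else:
            loc = "/" if n == 0 else ""
        rows.append(FamilySummaryRow(family=fam, n_genes=n, percentage=pct, chromosomes=loc))
    return rows


_CHROM_NUM_RE = re.compile(r"^(?:chr|chromosome|gm)\s*0*(\d+)$", re.IGNORECASE)


def _chrom_sort_label(chrom: str) -> tuple[int, object, str]:
    m = _CHROM_NUM_RE.match(chrom.strip())
    if m:
        return (0, int(m.group(1)), str(m.group(1)))
    return (1, chrom, chrom)


def localization_string(
    occupied: Iterable[str],
    universe: tuple[str, ...],
    *,
    all_except_threshold: float = 0.5,
) -> str:
    """Human-readable chromosome localization for one family.

    Empty occupancy -> "/".  Occupancy over more than
    ``all_except_threshold`` of the universe -> "all except chr 4 and
    chr 19" style (or plain "all" for full occupancy); otherwise the
    sorted list of chromosome numbers, e.g. "3, 5, 6, 7, 10".
    Non-numeric chromosome labels are listed verbatim.
    """
    occ = {c for c in occupied if c in universe}
    if not occ:
        return "/"
    if len(occ) == len(universe):
        return "all"
    if len(occ) / len(universe) > all_except_threshold:
        missing = sorted((c for c in universe if c not in occ), key=_chrom_sort_label)
        labels = []
        for c in missing:
            m = _CHROM_NUM_RE.match(c.strip())
            labels.append(f"chr {m.group(1)}" if m else c)
        return "all except " + " and ".join(labels)
    keys = sorted(occ, key=_chrom_sort_label)
    return ", ".join(_chrom_sort_label(c)[2] for c in keys)


def chromosome_shares(
    assignments: Mapping[str, FamilyAssignment],
    genes: Iterable[GeneRecord],
    universe: tuple[str, ...] | None = None,
) -> dict[str, tuple[int, float]]:
    """Per-chromosome lectin-gene count and percentage of placed genes.

    Only placed genes enter the denominator; percentages are rounded
    half-up to one decimal.
    """
    universe = universe or default_chromosome_universe()
    by_id = {g.gene_id: g for g in genes}
    counts = {c: 0 for c in universe}
    total = 0
    for gid in assignments:
        g = by_id.get(gid)
        if g is None or not g.is_placed:
            continue
        counts.setdefault(g.chromosome, 0)
        counts[g.chromosome] += 1
        total += 1
    return {
        c: (n, round_half_up(100.0 * n / total, 1) if total else 0.0)
        for c, n in counts.items()
    }


def map_coordinates(
    genes: Iterable[GeneRecord],
    assignments: Mapping[str, FamilyAssignment],
    tandem_gene_ids: frozenset[str] | set[str] = frozenset(),
    centromeres: Mapping[str, int] | None = None,
) -> list[dict]:
    """Plotting table for a drawn-to-scale chromosome map.

    One row per placed lectin gene: chromosome, position (gene start,
    bp), family, and a tandem flag for cluster members (the asterisk on
    a printed map).  Centromere rows, when positions are supplied, are
    appended with family "centromere".
    """
    rows = []
    for g in sorted(genes, key=lambda g: (_chrom_sort_label(g.chromosome), g.start)):
        a = assignments.get(g.gene_id)
        if a is None or not g.is_placed:
            continue
        rows.append(
            {
                "chromosome": g.chromosome,
                "position": g.start,
                "gene_id": g.gene_id,
                "family": a.primary_family,
                "tandem_flag": g.gene_id in tandem_gene_ids,
            }
        )
    for chrom, pos in (centromeres or {}).items():
        rows.append(
            {
                "chromosome": chrom,
                "position": pos,
                "gene_id": "",
                "family": "centromere",
                "tandem_flag": False,
            }
        )
    return rows
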