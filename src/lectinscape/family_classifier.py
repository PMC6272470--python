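"""Lectin family assignment and canonical domain-architecture strings.

A gene belongs to family F iff at least one of its protein's domain
hits carries an accession in F's definition.  Most plant lectins are
chimerolectins — one or more carbohydrate recognition domains combined
with unrelated domains (kinases, F-box, glycoside hydrolases, ...) —
so each gene also gets a canonical N-to-C architecture string built
from its hits, with SP (signal peptide) and TM (transmembrane segment)
tokens interleaved at their coordinate positions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources

import yaml

from .records import DomainHit, FamilyAssignment, TopologyAnnotation

__all__ = [
    "FamilyDefinition",
    "FamilyDefinitionSet",
    "load_family_definitions",
    "default_family_definitions",
    "assign_families",
    "build_architecture",
    "flag_truncated",
    "group_architectures",
    "parse_architecture",
]


class FamilyDefinitionError(ValueError):
    """Raised for inconsistent family definitions (shared accessions, ...)."""


@dataclass(frozen=True)
class FamilyDefinition:
    family: str
    member_domain_accessions: frozenset[str]
    reference_domain_length: int
    truncation_fraction: float = 0.75


@dataclass
class FamilyDefinitionSet:
    """All family definitions plus the non-lectin token vocabulary."""

    families: dict[str, FamilyDefinition]
    token_vocabulary: dict[str, str] = field(default_factory=dict)
    score_kind: str = "evalue"  # "evalue": lower is better; "bitscore": higher

    def __post_init__(self) -> None:
        claimed: dict[str, str] = {}
        for fam, d in self.families.items():
            for acc in d.member_domain_accessions:
                if acc in claimed:
                    raise FamilyDefinitionError(
                        f"accession {acc} claimed by both {claimed[acc]} and {fam}"
                    )
                claimed[acc] = fam
        self._accession_to_family = claimed

    def family_of(self, accession: str) -> str | None:
        return self._accession_to_family.get(accession)

    def token_of(self, accession: str) -> str:
        """Architecture token for an accession: family name for lectin
        CRDs, vocabulary name for known other domains, else the raw
        accession."""
        fam = self.family_of(accession)
        if fam is not None:
            return fam
        return self.token_vocabulary.get(accession, accession)

    def better_score(self, a: float, b: float) -> bool:
        """True if score a beats score b under this set's score kind."""
        return a < b if self.score_kind == "evalue" else a > b


def load_family_definitions(source) -> FamilyDefinitionSet:
    """Load a YAML family-definition / token-vocabulary config."""
    if hasattr(source, "read"):
        cfg = yaml.safe_load(source)
    else:
        with open(source, "rt") as fh:
            cfg = yaml.safe_load(fh)
    families = {
        name: FamilyDefinition(
            family=name,
            member_domain_accessions=frozenset(entry["member_domain_accessions"]),
            reference_domain_length=int(entry["reference_domain_length"]),
            truncation_fraction=float(entry.get("truncation_fraction", 0.75)),
        )
        for name, entry in cfg["families"].items()
    }
    return FamilyDefinitionSet(
        families=families,
        token_vocabulary=dict(cfg.get("token_vocabulary", {})),
        score_kind=cfg.get("score_kind", "evalue"),
    )


def default_family_definitions() -> FamilyDefinitionSet:
    """The packaged placeholder definitions (LEC_*/DOM_* accessions)."""
    ref = resources.files("lectinscape.data") / "family_definitions.yaml"
    with ref.open("rt") as fh:
        return load_family_definitions(fh)


def flag_truncated(hit: DomainHit, definition: FamilyDefinition) -> bool:
    """True iff the observed domain is shorter than the truncation cutoff.

    The cutoff is ``truncation_fraction * reference_domain_length``;
    the comparison is strict less-than, so a hit exactly at the cutoff
    is not flagged.
    """
    if definition.reference_domain_length <= 0:
        raise ValueError("reference_domain_length must be positive")
    return hit.length < definition.truncation_fraction * definition.reference_domain_length


def build_architecture(
    hits: list[DomainHit],
    topology: TopologyAnnotation | None,
    defs: FamilyDefinitionSet,
) -> tuple[str, ...]:
    """Canonical N-to-C token list for one protein.

    Overlapping hits of the same accession are merged into one token;
    overlapping hits of different accessions are both kept, ordered by
    start then accession.  TM tokens are interleaved at their aa
    positions; SP, when present, is always the first token.  A protein
    with no hits and no topology features yields an empty tuple.
    """
    merged: list[DomainHit] = []
    for hit in sorted(hits, key=lambda h: (h.d_start, h.d_end, h.domain_accession)):
        if (
            merged
            and merged[-1].domain_accession == hit.domain_accession
            and hit.d_start <= merged[-1].d_end
        ):
            prev = merged[-1]
            merged[-1] = DomainHit(
                protein_id=prev.protein_id,
                domain_accession=prev.domain_accession,
                description=prev.description,
                d_start=prev.d_start,
                d_end=max(prev.d_end, hit.d_end),
                score_or_evalue=prev.score_or_evalue,
            )
        else:
            merged.append(hit)

    events: list[tuple[int, int, str]] = [
        (h.d_start, 0, defs.token_of(h.domain_accession)) for h in merged
    ]
    if topology is not None:
        # A TM segment sorts after a domain starting at the same position.
        events.extend((s, 1, "TM") for s, _e in topology.tm_segments)
    events.sort(key=lambda t: (t[0], t[1], t[2]))
    tokens = [t[2] for t in events]
    if topology is not None and topology.has_signal_peptide:
        tokens.insert(0, "SP")
    return tuple(tokens)


def parse_architecture(architecture_string: str) -> tuple[str, ...]:
    """Inverse of joining tokens with '|' (empty string -> no tokens)."""
    if not architecture_string:
        return ()
    return tuple(architecture_string.split("|"))


def assign_families(
    hits_by_gene: dict[str, list[DomainHit]],
    defs: FamilyDefinitionSet,
    topology_by_gene: dict[str, TopologyAnnotation] | None = None,
    *,
    strict_multi_family: bool = False,
) -> dict[str, FamilyAssignment]:
    """Assign lectin families and architectures to every gene with hits.

    Genes with no lectin-domain hit are excluded from the result (and
    thus from all lectin tables).  A gene with hits from two lectin
    families is flagged ``multi_family``; its primary family is the
    family of its best-scoring lectin hit, so that per-family counts
    stay additive (each gene counted once).  With
    ``strict_multi_family=True`` downstream summaries may count it in
    every family it matches, breaking additivity.
    """
    topology_by_gene = topology_by_gene or {}
    out: dict[str, FamilyAssignment] = {}
    multi = 0
    for gene_id in sorted(hits_by_gene):
        hits = hits_by_gene[gene_id]
        lectin_hits = [
            (h, defs.family_of(h.domain_accession))
            for h in hits
            if defs.family_of(h.domain_accession) is not None
        ]
        if not lectin_hits:
            continue
        fams_in_order: list[str] = []
        for _h, fam in lectin_hits:
            if fam not in fams_in_order:
                fams_in_order.append(fam)
        best_hit, primary = lectin_hits[0]
        for h, fam in lectin_hits[1:]:
            if defs.better_score(h.score_or_evalue, best_hit.score_or_evalue):
                best_hit, primary = h, fam

        topology = topology_by_gene.get(gene_id)
        arch = build_architecture(hits, topology, defs)
        truncated: list[tuple[int, int]] = []
        offset = 1 if (topology is not None and topology.has_signal_peptide) else 0
        search_from = offset
        for h in sorted(hits, key=lambda h: (h.d_start, h.d_end, h.domain_accession)):
            fam = defs.family_of(h.domain_accession)
            if fam is None:
                continue
            d = defs.families[fam]
            if flag_truncated(h, d):
                tok = defs.token_of(h.domain_accession)
                try:
                    idx = arch.index(tok, search_from)
                    search_from = idx + 1
                except ValueError:
                    idx = -1
                truncated.append((idx, h.length))

        is_multi = len(fams_in_order) > 1
        if is_multi:
            multi += 1
        out[gene_id] = FamilyAssignment(
            gene_id=gene_id,
            families=tuple(fams_in_order) if (strict_multi_family or not is_multi) else (primary,) + tuple(f for f in fams_in_order if f != primary),
            primary_family=primary,
            architecture=arch,
            has_signal_peptide=bool(topology and topology.has_signal_peptide),
            has_tm=bool(topology and topology.tm_segments),
            truncated_domains=tuple(truncated),
            multi_family=is_multi,
        )
    if multi:
        warnings.warn(
            f"{multi} genes match more than one lectin family; counted once "
            "under their best-scoring family",
            stacklevel=2,
        )
    return out


def group_architectures(assignments: dict[str, FamilyAssignment]) -> dict[str, int]:
    """Group genes by exact architecture string.

    Returns a dict ordered by descending count, ties broken by string.
    """
    counts: dict[str, int] = {}
    for a in assignments.values():
        s = a.architecture_string
        counts[s] = counts.get(s, 0) + 1
    return dict(sorted(counts.items(), key=lambda kv: (-kv[1], kv[0])))
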