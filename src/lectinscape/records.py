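"""Core record types shared across the pipeline.

Coordinate conventions: genomic intervals are 1-based inclusive (GFF3);
protein-domain intervals are 1-based inclusive amino-acid positions;
gene ranks are 0-based positions in start-sorted order per chromosome.
"""

from __future__ import annotations

from dataclasses import dataclass, field


#: The twelve plant lectin families, defined by their carbohydrate
#: recognition domain (CRD), in alphabetical order.
LECTIN_FAMILIES = (
    "ABA",
    "amaranthin",
    "CRA",
    "cyanovirin",
    "EUL",
    "GNA",
    "hevein",
    "jacalin",
    "legume",
    "LysM",
    "Nictaba",
    "ricin B",
)

#: Mechanism-attribution categories for gene-family expansion.
MECHANISMS = ("tandem_only", "segmental_only", "both", "other")


@dataclass(frozen=True)
class GeneRecord:
    """One annotated gene and its position in chromosome gene order.

    ``rank`` is the 0-based index of the gene in start-sorted order within
    its chromosome; the number of intervening genes between two genes on
    the same chromosome with ranks r1 < r2 is r2 - r1 - 1, counted over
    all annotated genes regardless of family.
    """

    gene_id: str
    chromosome: str
    start: int
    end: int
    strand: str = "."
    rank: int = -1
    is_placed: bool = True


@dataclass(frozen=True)
class DomainHit:
    """A conserved-domain match on a protein (1-based aa coordinates)."""

    protein_id: str
    domain_accession: str
    description: str
    d_start: int
    d_end: int
    score_or_evalue: float

    @property
    def length(self) -> int:
        return self.d_end - self.d_start + 1


@dataclass(frozen=True)
class TopologyAnnotation:
    """Signal-peptide and transmembrane-segment calls for one protein.

    TM segments are non-overlapping, sorted (start, end) aa intervals.
    An N-terminal TM prediction overlapping a predicted signal peptide is
    a known false-positive mode of TM predictors and is suppressed at
    read time (see :func:`lectinscape.annotation_io.read_topology_table`).
    """

    protein_id: str
    has_signal_peptide: bool
    tm_segments: tuple[tuple[int, int], ...] = ()


@dataclass(frozen=True)
class CollinearPair:
    """A gene pair from a collinear block, with its Ks value.

    ``ks`` is the synonymous substitution rate between the duplicates;
    ``None`` means the source file carried no parseable Ks for the pair.
    Identity is block-scoped: the same unordered gene pair listed in two
    blocks yields two records.
    """

    block_id: str
    gene_a: str
    gene_b: str
    ks: float | None = None

    def unordered(self) -> frozenset[str]:
        return frozenset((self.gene_a, self.gene_b))


@dataclass
class FamilyAssignment:
    """Per-gene lectin family label(s) and canonical domain architecture."""

    gene_id: str
    families: tuple[str, ...]
    primary_family: str
    architecture: tuple[str, ...] = ()
    has_signal_peptide: bool = False
    has_tm: bool = False
    truncated_domains: tuple[tuple[int, int], ...] = ()
    multi_family: bool = False

    @property
    def architecture_string(self) -> str:
        return "|".join(self.architecture)


@dataclass
class TandemCluster:
    """A maximal chain of same-family genes on one chromosome.

    Consecutive members (by rank) are separated by at most
    ``max_intervening`` annotated genes; chaining is transitive, so a
    cluster may span more than ``max_intervening`` genes end to end.
    """

    cluster_id: str
    family: str
    chromosome: str
    members: tuple[str, ...]
    gaps: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.members) < 2:
            raise ValueError(
                f"tandem cluster {self.cluster_id} needs >= 2 members"
            )
        if len(self.gaps) != len(self.members) - 1:
            raise ValueError(
                f"tandem cluster {self.cluster_id}: gap list length "
                f"{len(self.gaps)} != {len(self.members) - 1}"
            )


@dataclass
class SegmentalAssignment:
    """Result of Ks filtering and collinear-block membership lookup."""

    segmental_genes: frozenset[str]
    blocks_with_lectins: frozenset[str]
    excluded_pairs: list[tuple[CollinearPair, str]] = field(default_factory=list)
    excluded_gene_count: int = 0
    retained_pairs: list[CollinearPair] = field(default_factory=list)


@dataclass
class MechanismPartition:
    """Four-way partition of the lectin gene set by expansion mechanism."""

    labels: dict[str, str]
    overall_counts: dict[str, int]
    overall_percentages: dict[str, float]
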