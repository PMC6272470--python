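"""Readers and writers for the four pipeline input formats.

Inputs are a gene-level GFF3 annotation, an InterProScan-style protein
domain table, a signal-peptide/transmembrane topology table, and an
MCScanX-style collinearity file carrying per-pair Ks values.  Everything
downstream relies on the gene-order model established here: genes are
ranked 0..n-1 per chromosome in start-sorted order, and "intervening
genes" between two genes is the difference of their ranks minus one.
"""

from __future__ import annotations

import io
import os
import re
import warnings
from dataclasses import dataclass

import gffutils
import pandas as pd

from .records import CollinearPair, DomainHit, GeneRecord, TopologyAnnotation

__all__ = [
    "AnnotationError",
    "CollinearityDialect",
    "read_gene_annotation",
    "read_domain_table",
    "read_topology_table",
    "read_collinearity",
    "write_table",
    "read_table",
]

#: Window (aa) at the N-terminus within which a TM prediction that
#: co-occurs with a predicted signal peptide is treated as the signal
#: peptide's hydrophobic core and suppressed.
SIGNAL_PEPTIDE_TM_WINDOW = 30

_PLACED_CHROM_RE = re.compile(r"^(chr|chromosome|gm)\s*0*\d+$", re.IGNORECASE)


class AnnotationError(ValueError):
    """Raised for malformed or inconsistent annotation inputs."""


def _as_text(source) -> str:
    """Accept a path, a text stream, or raw text and return the text."""
    if hasattr(source, "read"):
        return source.read()
    if isinstance(source, (str, os.PathLike)) and os.path.exists(str(source)):
        with open(source, "rt") as fh:
            return fh.read()
    return str(source)


def is_placed_chromosome(chromosome: str) -> bool:
    """True for a bona fide chromosome label, False for scaffolds.

    Labels like ``chr6``, ``Chromosome12`` or ``Gm08`` count as placed;
    anything else (``scaffold_123`` and friends) is unplaced and will be
    excluded from tandem detection and the chromosome map, though kept
    in family totals.
    """
    return bool(_PLACED_CHROM_RE.match(chromosome.strip()))


def read_gene_annotation(source, *, strand_aware_start: bool = False) -> list[GeneRecord]:
    """Read gene features from GFF3 and assign per-chromosome ranks.

    Parameters
    ----------
    source
        Path, text stream, or GFF3 text.  Only rows of feature type
        ``gene`` are used.
    strand_aware_start
        If True, genes are ordered by their strand-aware transcription
        start (``end`` for minus-strand genes) instead of the smaller
        coordinate.  Off by default.

    Returns
    -------
    list of GeneRecord sorted by (chromosome, start), with 0-based ranks
    assigned per chromosome in start order (ties broken by end, then
    gene id).  Genes on unmapped scaffolds get ``is_placed=False``.

    Raises
    ------
    AnnotationError
        For coordinates with start > end (all offenders listed) or
        duplicated gene ids.
    """
    text = _as_text(source)
    db = gffutils.create_db(
        text,
        dbfn=":memory:",
        from_string=True,
        merge_strategy="create_unique",
        keep_order=True,
    )

    raw: list[GeneRecord] = []
    bad_coords: list[str] = []
    seen: set[str] = set()
    duplicates: set[str] = set()
    for feat in db.features_of_type("gene"):
        gene_id = feat.attributes.get("ID", [feat.id])[0]
        if feat.start > feat.end:
            bad_coords.append(gene_id)
            continue
        if gene_id in seen:
            duplicates.add(gene_id)
            continue
        seen.add(gene_id)
        raw.append(
            GeneRecord(
                gene_id=gene_id,
                chromosome=feat.seqid,
                start=feat.start,
                end=feat.end,
                strand=feat.strand or ".",
                is_placed=is_placed_chromosome(feat.seqid),
            )
        )
    if bad_coords:
        raise AnnotationError(
            "genes with start > end: " + ", ".join(sorted(bad_coords))
        )
    if duplicates:
        raise AnnotationError(
            "duplicate gene ids: " + ", ".join(sorted(duplicates))
        )
    return _rank_genes(raw, strand_aware_start=strand_aware_start)


def _sort_key(g: GeneRecord, strand_aware_start: bool):
    start = g.end if (strand_aware_start and g.strand == "-") else g.start
    return (start, g.end, g.gene_id)


def _rank_genes(genes: list[GeneRecord], *, strand_aware_start: bool = False) -> list[GeneRecord]:
    """Assign 0-based per-chromosome ranks in gene-start order."""
    out: list[GeneRecord] = []
    by_chrom: dict[str, list[GeneRecord]] = {}
    for g in genes:
        by_chrom.setdefault(g.chromosome, []).append(g)
    for chrom in sorted(by_chrom):
        ordered = sorted(by_chrom[chrom], key=lambda g: _sort_key(g, strand_aware_start))
        for rank, g in enumerate(ordered):
            out.append(
                GeneRecord(
                    gene_id=g.gene_id,
                    chromosome=g.chromosome,
                    start=g.start,
                    end=g.end,
                    strand=g.strand,
                    rank=rank,
                    is_placed=g.is_placed,
                )
            )
    return out


_DOMAIN_COLUMNS = ["protein_id", "domain_accession", "description", "d_start", "d_end", "score_or_evalue"]


def read_domain_table(source) -> list[DomainHit]:
    """Read an InterProScan-style TSV of protein domain hits.

    The table must carry at least the columns ``protein_id``,
    ``domain_accession``, ``description``, ``d_start``, ``d_end`` and
    ``score_or_evalue`` (header names; extra columns are ignored).  Rows
    whose coordinates do not parse as positive integers with
    d_start <= d_end are dropped and counted in a single warning.
    Hits are returned sorted by (protein_id, d_start, d_end, accession).
    """
    text = _as_text(source)
    df = pd.read_csv(io.StringIO(text), sep="\t", dtype=str, comment="#")
    missing = [c for c in _DOMAIN_COLUMNS if c not in df.columns]
    if missing:
        raise AnnotationError(
            "domain table missing mandatory columns: " + ", ".join(missing)
        )

    hits: list[DomainHit] = []
    n_dropped = 0
    for row in df.itertuples(index=False):
        try:
            d_start = int(getattr(row, "d_start"))
            d_end = int(getattr(row, "d_end"))
            if d_start < 1 or d_start > d_end:
                raise ValueError
            score = float(getattr(row, "score_or_evalue"))
        except (TypeError, ValueError):
            n_dropped += 1
            continue
        hits.append(
            DomainHit(
                protein_id=str(getattr(row, "protein_id")),
                domain_accession=str(getattr(row, "domain_accession")),
                description=str(getattr(row, "description")),
                d_start=d_start,
                d_end=d_end,
                score_or_evalue=score,
            )
        )
    if n_dropped:
        warnings.warn(
            f"dropped {n_dropped} domain rows with unparseable coordinates",
            stacklevel=2,
        )
    hits.sort(key=lambda h: (h.protein_id, h.d_start, h.d_end, h.domain_accession))
    return hits


def read_topology_table(source, *, sp_tm_window: int = SIGNAL_PEPTIDE_TM_WINDOW) -> list[TopologyAnnotation]:
    """Read the per-protein signal-peptide / TM-segment table.

    Expected TSV columns: ``protein_id``, ``has_signal_peptide``
    (true/false/1/0), ``tm_segments`` (semicolon-separated ``start-end``
    aa intervals, empty for none).  A TM segment lying entirely within
    the first ``sp_tm_window`` aa of a protein that also has a signal
    peptide is discarded: N-terminal TM predictions over a signal
    peptide are a known false-positive mode of TM predictors.
    """
    text = _as_text(source)
    df = pd.read_csv(io.StringIO(text), sep="\t", dtype=str)
    for col in ("protein_id", "has_signal_peptide", "tm_segments"):
        if col not in df.columns:
            raise AnnotationError(f"topology table missing column: {col}")

    out: list[TopologyAnnotation] = []
    for row in df.itertuples(index=False):
        has_sp = str(getattr(row, "has_signal_peptide")).strip().lower() in ("1", "true", "yes")
        raw = getattr(row, "tm_segments")
        segments: list[tuple[int, int]] = []
        if isinstance(raw, str) and raw.strip() and raw.strip().upper() != "NA":
            for token in raw.split(";"):
                token = token.strip()
                if not token:
                    continue
                a, b = token.split("-")
                segments.append((int(a), int(b)))
        segments.sort()
        if has_sp:
            segments = [s for s in segments if s[1] > sp_tm_window]
        out.append(
            TopologyAnnotation(
                protein_id=str(getattr(row, "protein_id")),
                has_signal_peptide=has_sp,
                tm_segments=tuple(segments),
            )
        )
    return out


@dataclass(frozen=True)
class CollinearityDialect:
    """Parsing parameters for MCScanX-style collinearity text.

    ``block_header_prefix`` introduces a block; the block id is the
    first integer-looking token after the prefix.  Pair lines carry at
    least ``min_pair_fields`` whitespace/tab-separated fields once an
    optional leading ``N-M:`` index token is stripped; the two gene ids
    are the first two fields and Ks is the last numeric field after
    them (missing or non-numeric Ks is recorded as missing).
    """

    block_header_prefix: str = "## Alignment"
    comment_prefix: str = "#"
    min_pair_fields: int = 2


_PAIR_INDEX_RE = re.compile(r"^\s*\d+\s*-\s*\d+\s*:")


def read_collinearity(source, dialect: CollinearityDialect | None = None) -> list[CollinearPair]:
    """Parse an MCScanX-style collinearity file into gene pairs.

    Pairs duplicated within a block in either orientation are dropped,
    keeping the first occurrence; the same pair in two different blocks
    is two records (identity is block-scoped).
    """
    dialect = dialect or CollinearityDialect()
    text = _as_text(source)

    pairs: list[CollinearPair] = []
    seen: set[tuple[str, frozenset[str]]] = set()
    block_id = "block_0"
    for lineno, line in enumerate(text.splitlines(), start=1):
        stripped = line.strip()
        if not stripped:
            continue
        if stripped.startswith(dialect.block_header_prefix):
            m = re.search(re.escape(dialect.block_header_prefix) + r"\s*(\S+?):?(\s|$)", stripped)
            token = m.group(1) if m else stripped
            block_id = f"block_{token.rstrip(':')}"
            continue
        if stripped.startswith(dialect.comment_prefix):
            continue

        # MCScanX pair lines open with an "N-M:" within-block index.
        fields = _PAIR_INDEX_RE.sub("", stripped).split()
        if len(fields) < dialect.min_pair_fields:
            raise AnnotationError(
                f"collinearity line {lineno}: expected >= {dialect.min_pair_fields} "
                f"fields, got {len(fields)}"
            )
        gene_a, gene_b = fields[0], fields[1]
        if gene_a == gene_b:
            raise AnnotationError(
                f"collinearity line {lineno}: self-pair {gene_a}"
            )
        ks: float | None = None
        for token in reversed(fields[2:]):
            try:
                ks = float(token)
                break
            except ValueError:
                continue
        key = (block_id, frozenset((gene_a, gene_b)))
        if key in seen:
            continue
        seen.add(key)
        pairs.append(CollinearPair(block_id=block_id, gene_a=gene_a, gene_b=gene_b, ks=ks))
    return pairs


def write_table(rows, schema: list[str], path) -> None:
    """Write rows (mappings or dataclass-likes) as a TSV with header.

    Column order follows ``schema``; missing values are written as
    ``NA``.  The output round-trips through :func:`read_table`.
    """
    records = []
    for row in rows:
        if not isinstance(row, dict):
            row = {c: getattr(row, c) for c in schema}
        records.append({c: row.get(c) for c in schema})
    df = pd.DataFrame.from_records(records, columns=schema)
    df.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_table(source) -> pd.DataFrame:
    """Read back a TSV written by :func:`write_table` (``NA`` = missing)."""
    text = _as_text(source)
    return pd.read_csv(io.StringIO(text), sep="\t", na_values=["NA"], keep_default_na=False)
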