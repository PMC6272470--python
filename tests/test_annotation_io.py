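"""Readers, writers and the gene-order model."""

import io

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lectinscape import annotation_io as aio
from lectinscape.annotation_io import AnnotationError


def gff3(rows):
    lines = ["##gff-version 3"]
    for gid, chrom, start, end in rows:
        lines.append(f"{chrom}\t.\tgene\t{start}\t{end}\t.\t+\t.\tID={gid}")
    return "\n".join(lines) + "\n"


class TestGeneAnnotation:
    def test_two_gene_ordering(self):
        genes = aio.read_gene_annotation(gff3([("A", "chr1", 100, 200), ("B", "chr1", 500, 600)]))
        ranks = {g.gene_id: g.rank for g in genes}
        assert ranks == {"A": 0, "B": 1}

    def test_rank_from_coordinates_not_file_order(self):
        fwd = aio.read_gene_annotation(gff3([("A", "chr1", 100, 200), ("B", "chr1", 500, 600)]))
        rev = aio.read_gene_annotation(gff3([("B", "chr1", 500, 600), ("A", "chr1", 100, 200)]))
        assert [(g.gene_id, g.rank) for g in fwd] == [(g.gene_id, g.rank) for g in rev]

    def test_ranks_match_sort_oracle(self):
        rng = np.random.default_rng(42)
        rows = []
        for i in range(50):
            chrom = f"chr{rng.integers(1, 4)}"
            start = int(rng.integers(1, 10_000_000))
            rows.append((f"g{i}", chrom, start, start + int(rng.integers(100, 5000))))
        genes = aio.read_gene_annotation(gff3(rows))

        # independent oracle: per-chromosome sort-then-enumerate
        expected = {}
        for chrom in {r[1] for r in rows}:
            ordered = sorted(
                (r for r in rows if r[1] == chrom), key=lambda r: (r[2], r[3], r[0])
            )
            for rank, r in enumerate(ordered):
                expected[r[0]] = rank
        assert {g.gene_id: g.rank for g in genes} == expected

    def test_rank_bijection_per_chromosome(self):
        rng = np.random.default_rng(7)
        rows = [
            (f"g{i}", "chr2", int(rng.integers(1, 10**6)), int(rng.integers(1, 10**6)) + 10**6)
            for i in range(40)
        ]
        genes = aio.read_gene_annotation(gff3(rows))
        assert sorted(g.rank for g in genes) == list(range(40))

    def test_scaffold_genes_unplaced(self):
        genes = aio.read_gene_annotation(
            gff3([("A", "chr1", 1, 10), ("U", "scaffold_77", 5, 20)])
        )
        placed = {g.gene_id: g.is_placed for g in genes}
        assert placed == {"A": True, "U": False}

    def test_start_after_end_rejected_naming_offender(self):
        with pytest.raises(AnnotationError, match="BAD"):
            aio.read_gene_annotation(gff3([("BAD", "chr1", 500, 100)]))

    def test_duplicate_gene_id_rejected(self):
        with pytest.raises(AnnotationError, match="duplicate"):
            aio.read_gene_annotation(
                gff3([("A", "chr1", 1, 10), ("A", "chr1", 100, 200)])
            )


class TestDomainTable:
    HEADER = "protein_id\tdomain_accession\tdescription\td_start\td_end\tscore_or_evalue\n"

    def test_single_row(self):
        hits = aio.read_domain_table(self.HEADER + "P1\tDomX\tdesc\t10\t120\t1e-30\n")
        assert len(hits) == 1 and hits[0].d_start == 10 and hits[0].length == 111

    def test_sorted_by_start(self):
        text = self.HEADER + "P1\tB\tb\t200\t300\t1e-5\nP1\tA\ta\t10\t120\t1e-5\n"
        hits = aio.read_domain_table(text)
        assert [h.domain_accession for h in hits] == ["A", "B"]

    def test_corrupted_rows_dropped_and_warned(self):
        rng = np.random.default_rng(0)
        lines = [self.HEADER.rstrip("\n")]
        for i in range(200):
            if i % 20 == 0:  # exactly 10 corrupted rows
                lines.append(f"P{i}\tD\td\tnot_a_number\t50\t1e-9")
            else:
                s = int(rng.integers(1, 500))
                lines.append(f"P{i}\tD\td\t{s}\t{s + 99}\t1e-9")
        with pytest.warns(UserWarning, match="dropped 10"):
            hits = aio.read_domain_table("\n".join(lines))
        assert len(hits) == 190

    def test_missing_column_is_format_error(self):
        with pytest.raises(AnnotationError, match="d_end"):
            aio.read_domain_table("protein_id\tdomain_accession\tdescription\td_start\tscore_or_evalue\nP\tD\td\t1\t2\n")


class TestTopologyTable:
    def test_nterminal_tm_suppressed_with_signal_peptide(self):
        text = (
            "protein_id\thas_signal_peptide\ttm_segments\n"
            "P1\ttrue\t7-27;300-320\n"
            "P2\tfalse\t7-27\n"
        )
        topo = {t.protein_id: t for t in aio.read_topology_table(text)}
        assert topo["P1"].tm_segments == ((300, 320),)
        assert topo["P2"].tm_segments == ((7, 27),)


class TestCollinearity:
    def test_block_of_three_pairs(self):
        text = (
            "## Alignment 7: score=100 e_value=0 N=3 chr1&chr2 plus\n"
            "7-0:\tGa\tGb\t0.5\n7-1:\tGc\tGd\t0.7\n7-2:\tGe\tGf\t1.4\n"
        )
        pairs = aio.read_collinearity(text)
        assert len(pairs) == 3 and {p.block_id for p in pairs} == {"block_7"}
        assert [p.ks for p in pairs] == [0.5, 0.7, 1.4]

    def test_same_pair_in_two_blocks_kept_twice(self):
        text = (
            "## Alignment 0: a\n0-0:\tGa\tGb\t0.5\n"
            "## Alignment 1: b\n1-0:\tGa\tGb\t0.5\n"
        )
        assert len(aio.read_collinearity(text)) == 2

    def test_reversed_orientation_deduplicated(self):
        rng = np.random.default_rng(1)
        lines = ["## Alignment 0: x"]
        genes = [(f"A{i}", f"B{i}") for i in range(40)]
        for a, b in genes:
            lines.append(f"0-0:\t{a}\t{b}\t{rng.random():.3f}")
        for a, b in genes[:4]:
            lines.append(f"0-0:\t{b}\t{a}\t0.9")
        pairs = aio.read_collinearity("\n".join(lines))
        assert len(pairs) == 40
        assert len({frozenset((p.gene_a, p.gene_b)) for p in pairs}) == 40

    def test_missing_ks_recorded_as_missing(self):
        pairs = aio.read_collinearity("## Alignment 0: x\n0-0:\tGa\tGb\tNA\n")
        assert pairs[0].ks is None

    def test_short_pair_line_names_line_number(self):
        with pytest.raises(AnnotationError, match="line 2"):
            aio.read_collinearity("## Alignment 0: x\n0-0:\tGa\n")


class TestWriteTable:
    def test_empty_rows_header_only(self, tmp_path):
        path = tmp_path / "t.tsv"
        aio.write_table([], ["a", "b"], path)
        assert path.read_text().strip() == "a\tb"

    def test_twelve_family_rows_with_zeros(self, tmp_path):
        from lectinscape.genome_distribution import summarize_families
        from lectinscape.synthetic_genome import table1_fixture

        rows = [
            {"family": r.family, "n_genes": r.n_genes, "percentage": r.percentage}
            for r in summarize_families(table1_fixture())
        ]
        path = tmp_path / "summary.tsv"
        aio.write_table(rows, ["family", "n_genes", "percentage"], path)
        back = aio.read_table(path)
        assert len(back) == 12
        assert back.set_index("family").loc["ABA", "n_genes"] == 0

    @settings(deadline=None, max_examples=25)
    @given(
        rows=st.lists(
            st.tuples(
                st.text(alphabet="abcXYZ", min_size=1, max_size=8),
                st.integers(-1000, 1000),
                st.one_of(st.none(), st.floats(allow_nan=False, allow_infinity=False, width=32)),
            ),
            min_size=1,
            max_size=30,
        )
    )
    def test_round_trip_random_tables(self, rows, tmp_path_factory):
        path = tmp_path_factory.mktemp("rt") / "x.tsv"
        dicts = [{"name": a, "count": b, "score": c} for a, b, c in rows]
        aio.write_table(dicts, ["name", "count", "score"], path)
        back = aio.read_table(path)
        assert len(back) == len(rows)
        for (a, b, c), rec in zip(rows, back.to_dict("records")):
            assert rec["name"] == a and rec["count"] == b
            if c is None:
                assert rec["score"] != rec["score"]  # NaN
            else:
                assert rec["score"] == pytest.approx(c, rel=1e-6)
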