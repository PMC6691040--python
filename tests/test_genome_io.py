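import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst

from syntriad.genome_io import (
    AnchorPair,
    CollinearBlock,
    Gene,
    Genome,
    ParseError,
    read_blocks,
    read_gene_annotations,
    read_homolog_hits,
    read_ks_pairs,
    write_blocks,
    write_ks_pairs,
    KsPair,
)


class TestAnnotations:
    def test_bed_coordinates_convert_to_one_based_inclusive(self, tmp_path):
        p = tmp_path / "g.bed"
        p.write_text("chr1\t99\t200\tg1\t0\t+\n")
        genome = read_gene_annotations(p, "V", "bed")
        g = genome["g1"]
        assert (g.start, g.end, g.chromosome, g.strand) == (100, 200, "chr1", "+")

    def test_order_index_ranks_by_start(self, tmp_path):
        p = tmp_path / "g.bed"
        p.write_text(
            "chr1\t500\t600\tb\t0\t+\nchr1\t0\t100\ta\t0\t-\nchr1\t900\t950\tc\t0\t+\n"
        )
        genome = read_gene_annotations(p, "V", "bed")
        assert [g.gene_id for g in genome.chromosomes["chr1"]] == ["a", "b", "c"]
        assert [g.order_index for g in genome.chromosomes["chr1"]] == [0, 1, 2]

    def test_gff3_gene_rows_only_and_duplicate_id_rejected(self, tmp_path):
        p = tmp_path / "g.gff3"
        p.write_text(
            "##gff-version 3\n"
            "chr1\tsrc\tgene\t100\t200\t.\t+\t.\tID=g1\n"
            "chr1\tsrc\tmRNA\t100\t200\t.\t+\t.\tID=t1;Parent=g1\n"
            "chr2\tsrc\tgene\t10\t50\t.\t-\t.\tID=g2\n"
        )
        genome = read_gene_annotations(p, "V", "gff3")
        assert genome.n_genes == 2 and "t1" not in genome

        p.write_text(
            "chr1\tsrc\tgene\t100\t200\t.\t+\t.\tID=g1\n"
            "chr1\tsrc\tgene\t300\t400\t.\t+\t.\tID=g1\n"
        )
        with pytest.raises(ParseError, match="duplicate"):
            read_gene_annotations(p, "V", "gff3")

    def test_malformed_row_names_line_number(self, tmp_path):
        p = tmp_path / "g.bed"
        p.write_text("chr1\t0\t100\ta\nchr1\tnot_a_number\t200\tb\n")
        with pytest.raises(ParseError, match=":2"):
            read_gene_annotations(p, "V", "bed")

    @given(start0=hst.integers(min_value=0, max_value=10**8),
           length=hst.integers(min_value=1, max_value=10**6))
    @settings(max_examples=50, deadline=None)
    def test_bed_conversion_is_exact_inverse(self, start0, length):
        # internal (1-based incl) -> BED (0-based half-open) -> internal
        start1, end1 = start0 + 1, start0 + length
        assert (start1 - 1, end1) == (start0, start0 + length)
        assert (start0 + 1, end1) == (start1, end1)


class TestHomologHits:
    HITS = (
        "q1\ts1\t80.0\t100\t10\t0\t1\t100\t1\t100\t1e-06\t200\n"  # kept
        "q2\ts2\t70.0\t100\t10\t0\t1\t100\t1\t100\t1e-04\t150\n"  # above threshold
        "q3\tq3\t99.0\t100\t10\t0\t1\t100\t1\t100\t1e-50\t500\n"  # self-hit
        "q4\tq4\t99.0\t100\t10\t0\t1\t100\t1\t100\t1e-80\t600\n"  # self-hit
        "q5\ts5\t60.0\t100\t10\t0\t1\t100\t1\t100\t9e-06\t120\n"  # kept
    )

    def test_evalue_filter_and_self_hit_removal(self, tmp_path):
        p = tmp_path / "h.blast"
        p.write_text(self.HITS)
        hits = read_homolog_hits(p)
        assert [h.query_gene_id for h in hits] == ["q1", "q5"]
        assert all(h.e_value < 1e-5 for h in hits)

    def test_threshold_is_strict(self, tmp_path):
        p = tmp_path / "h.blast"
        p.write_text("q\ts\t80.0\t100\t10\t0\t1\t100\t1\t100\t1e-05\t200\n")
        assert read_homolog_hits(p) == []

    def test_non_numeric_evalue_is_a_parse_error(self, tmp_path):
        p = tmp_path / "h.blast"
        p.write_text("q\ts\t80.0\t100\t10\t0\t1\t100\t1\t100\tlow\t200\n")
        with pytest.raises(ParseError):
            read_homolog_hits(p)


def _random_blocks(rng_seed: int) -> list[CollinearBlock]:
    import random

    rnd = random.Random(rng_seed)
    blocks = []
    for bid in range(rnd.randint(1, 5)):
        n = rnd.randint(1, 8)
        anchors = [
            AnchorPair(f"a{bid}_{i}", f"b{bid}_{i}", i, i * 2, round(rnd.uniform(0, 3), 4))
            for i in range(n)
        ]
        blocks.append(
            CollinearBlock(
                block_id=bid, species_a="V", species_b="Cs",
                chromosome_a=f"c{bid}", chromosome_b="c9",
                orientation=rnd.choice(["same", "inverted"]),
                anchors=anchors,
                label=rnd.choice(CollinearBlock.LABELS),
                supernumerary=rnd.random() < 0.2,
            )
        )
    return blocks


class TestBlockFile:
    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_round_trip_identity(self, tmp_path, seed):
        blocks = _random_blocks(seed)
        p = tmp_path / "b.tsv"
        write_blocks(blocks, p)
        back = read_blocks(p)
        assert len(back) == len(blocks)
        for x, y in zip(blocks, back):
            assert (x.block_id, x.species_a, x.species_b, x.chromosome_a,
                    x.chromosome_b, x.orientation, x.label, x.supernumerary) == (
                    y.block_id, y.species_a, y.species_b, y.chromosome_a,
                    y.chromosome_b, y.orientation, y.label, y.supernumerary)
            assert x.anchors == y.anchors

    def test_empty_block_list_writes_format_comment(self, tmp_path):
        p = tmp_path / "b.tsv"
        write_blocks([], p)
        assert p.read_text().startswith("#syntriad-blocks")
        assert read_blocks(p) == []

    def test_truncated_anchor_section_rejected(self, tmp_path):
        blocks = _random_blocks(1)
        p = tmp_path / "b.tsv"
        write_blocks(blocks, p)
        lines = p.read_text().splitlines()
        p.write_text("\n".join(lines[:-1]) + "\n")
        with pytest.raises(ParseError, match="anchors"):
            read_blocks(p)


def test_ks_list_round_trip(tmp_path):
    pairs = [KsPair("a", "b", 0.52, 0.11), KsPair("c", "d", math.nan, math.nan)]
    p = tmp_path / "ks.tsv"
    write_ks_pairs(pairs, p)
    back = read_ks_pairs(p)
    assert back[0] == pairs[0]
    assert back[1].gene_id_a == "c" and math.isnan(back[1].ks)


def test_genome_rejects_duplicate_ids():
    genes = [Gene("g1", "V", "chr1", 1, 10, "+"), Gene("g1", "V", "chr2", 5, 20, "-")]
    with pytest.raises(ValueError, match="duplicate"):
        Genome.from_genes("V", genes)
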