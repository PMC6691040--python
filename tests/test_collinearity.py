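"""Collinear chaining: monotonicity, gap bounds, optimality vs brute force."""

import random

import numpy as np
import pytest

from syntriad.collinearity import best_monotone_chain, block_summary, chain_blocks
from syntriad.genome_io import AnchorPair, CollinearBlock, Gene, Genome, HomologHit


def toy_genomes(n_a=20, n_b=20, species=("A", "B")):
    ga = Genome.from_genes(
        species[0],
        [Gene(f"a{i}", species[0], "c1", 1 + i * 100, 50 + i * 100, "+") for i in range(n_a)],
    )
    gb = Genome.from_genes(
        species[1],
        [Gene(f"b{i}", species[1], "c1", 1 + i * 100, 50 + i * 100, "+") for i in range(n_b)],
    )
    return ga, gb


def hits_for(pairs):
    return [HomologHit(f"a{i}", f"b{j}", 80.0, 200.0, 1e-20) for i, j in pairs]


def oracle_best_chain_size(pairs, max_gap):
    """Exhaustive search over monotone gap-bounded chains (both orientations)."""

    best = 0

    def extend(chain_last, remaining, size, sign):
        nonlocal best
        best = max(best, size)
        la, lb = chain_last
        for idx, (oa, ob) in enumerate(remaining):
            if oa <= la or oa - la > max_gap + 1:
                continue
            d = (ob - lb) * sign
            if d <= 0 or d > max_gap + 1:
                continue
            extend((oa, ob), remaining[idx + 1 :], size + 1, sign)

    for sign in (1, -1):
        pts = sorted(pairs, key=lambda p: (p[0], -sign * p[1]))
        for i, p in enumerate(pts):
            extend(p, pts[i + 1 :], 1, sign)
    return best


class TestChaining:
    def test_perfect_diagonal_single_same_block(self):
        ga, gb = toy_genomes()
        blocks = chain_blocks(ga, gb, hits_for([(i, i) for i in range(5)]), min_block_size=4)
        assert len(blocks) == 1
        assert blocks[0].orientation == "same" and blocks[0].n_anchors == 5

    def test_perfect_antidiagonal_inverted_block(self):
        ga, gb = toy_genomes()
        blocks = chain_blocks(ga, gb, hits_for([(i, 10 - i) for i in range(4)]), min_block_size=4)
        assert len(blocks) == 1
        assert blocks[0].orientation == "inverted" and blocks[0].n_anchors == 4

    def test_short_chain_discarded_noise_ignored(self):
        # a 6-anchor diagonal, a 3-anchor diagonal, 10 scattered dots on a
        # 12x12 matrix; only the 6-anchor chain reaches min_block_size
        diag6 = [(i, i) for i in range(6)]
        diag3 = [(i + 8, i) for i in range(3)]
        rnd = random.Random(42)
        noise = []
        occupied = set(diag6) | set(diag3)
        while len(noise) < 10:
            p = (rnd.randrange(12), rnd.randrange(12))
            if p not in occupied and p not in noise:
                noise.append(p)
        all_pairs = diag6 + diag3 + noise
        assert oracle_best_chain_size(all_pairs, max_gap=2) == 6
        ga, gb = toy_genomes()
        blocks = chain_blocks(ga, gb, hits_for(all_pairs), min_block_size=4, max_gap=2)
        assert len(blocks) == 1
        assert {(a.order_a, a.order_b) for a in blocks[0].anchors} == set(diag6)

    def test_gap_bound_splits_chain(self):
        pairs = [(0, 0), (1, 1), (2, 2), (3, 3), (30, 30), (31, 31), (32, 32), (33, 33)]
        ga, gb = toy_genomes(40, 40)
        blocks = chain_blocks(ga, gb, hits_for(pairs), min_block_size=4, max_gap=10)
        assert len(blocks) == 2 and all(b.n_anchors == 4 for b in blocks)

    @pytest.mark.parametrize("seed", range(12))
    def test_matches_exhaustive_oracle_on_small_instances(self, seed):
        rnd = random.Random(seed)
        n = rnd.randint(5, 15)
        pairs = set()
        while len(pairs) < n:
            pairs.add((rnd.randrange(18), rnd.randrange(18)))
        pairs = sorted(pairs)
        max_gap = rnd.choice([2, 5, 25])
        chain, _ = best_monotone_chain(pairs, max_gap)
        assert len(chain) == oracle_best_chain_size(pairs, max_gap)

    def test_unknown_gene_ids_rejected(self):
        ga, gb = toy_genomes(5, 5)
        with pytest.raises(ValueError, match="zz9"):
            chain_blocks(ga, gb, [HomologHit("zz9", "zz10", 80, 200, 1e-20)])

    def test_determinism(self):
        ga, gb = toy_genomes()
        rnd = random.Random(5)
        pairs = sorted({(rnd.randrange(20), rnd.randrange(20)) for _ in range(30)})
        b1 = chain_blocks(ga, gb, hits_for(pairs))
        b2 = chain_blocks(ga, gb, hits_for(pairs))
        assert [(b.block_id, [(a.order_a, a.order_b) for a in b.anchors]) for b in b1] == [
            (b.block_id, [(a.order_a, a.order_b) for a in b.anchors]) for b in b2
        ]

    def test_intragenomic_mirror_chains_reported_once(self):
        genes = [Gene(f"g{i}", "A", "c1", 1 + i * 100, 50 + i * 100, "+") for i in range(8)] + [
            Gene(f"h{i}", "A", "c2", 1 + i * 100, 50 + i * 100, "+") for i in range(8)
        ]
        g = Genome.from_genes("A", genes)
        hits = [HomologHit(f"g{i}", f"h{i}", 80, 200, 1e-20) for i in range(5)]
        hits += [HomologHit(f"h{i}", f"g{i}", 80, 200, 1e-20) for i in range(5)]  # mirrors
        blocks = chain_blocks(g, g, hits)
        assert len(blocks) == 1
        assert (blocks[0].chromosome_a, blocks[0].chromosome_b) == ("c1", "c2")


class TestBlockProperties:
    def test_all_simulated_blocks_monotone_and_gap_bounded(self, small_sim):
        from syntriad.collinearity import chain_blocks

        cfg = small_sim.config
        ref = cfg.outgroup
        sp = cfg.ingroup_species[0]
        blocks = chain_blocks(
            small_sim.genomes[ref], small_sim.genomes[sp],
            small_sim.hits[(ref, sp)], max_gap=25,
        )
        assert blocks
        for b in blocks:
            oa = [a.order_a for a in b.anchors]
            ob = [a.order_b for a in b.anchors]
            assert oa == sorted(oa) and len(set(oa)) == len(oa)
            if b.orientation == "same":
                assert ob == sorted(ob) and len(set(ob)) == len(ob)
            else:
                assert ob == sorted(ob, reverse=True)
            for (x1, y1), (x2, y2) in zip(zip(oa, ob), zip(oa[1:], ob[1:])):
                assert x2 - x1 - 1 <= 25
                assert abs(y2 - y1) - 1 <= 25


class TestSummary:
    def test_hand_counted_summary(self):
        def mk(bid, anchors, chrom_a="c1"):
            return CollinearBlock(
                bid, "A", "B", chrom_a, "c9", "same",
                [AnchorPair(a, b, i, i) for i, (a, b) in enumerate(anchors)],
            )

        b1 = mk(0, [(f"x{i}", f"y{i}") for i in range(4)])
        # shares gene x0 with b1 on the A side
        b2 = mk(1, [("x0", "z0")] + [(f"u{i}", f"z{i}") for i in range(1, 4)], "c2")
        df = block_summary([b1, b2])
        row = df.iloc[0]
        assert row.n_blocks == 2 and row.n_gene_pairs == 8
        assert row.n_distinct_genes == 15  # 16 slots minus the shared x0
        assert row.longest_block == 4

    def test_empty_input_yields_zero_row(self):
        df = block_summary([])
        assert len(df) == 1 and df.iloc[0].n_blocks == 0
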