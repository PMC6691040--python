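"""Ortholog/outparalog resolution and scaffold-to-pseudochromosome ordering."""

import math

import pytest

from syntriad.genome_io import AnchorPair, CollinearBlock, Gene, Genome, HomologHit
from syntriad.homology_map import (
    classify_correspondence,
    ech_summary,
    label_ech_paralogs,
    order_scaffolds,
)
from syntriad.pipeline import run_on_simulation
from syntriad.simulate import SimulationConfig, simulate


def ref_genome(n=400, species="V", chrom="Vv6"):
    return Genome.from_genes(
        species,
        [Gene(f"v{i}", species, chrom, 1 + i * 100, 50 + i * 100, "+") for i in range(n)],
    )


def make_block(bid, chrom_b, n_anchors, ks, ref_start=0, species=("V", "Cs")):
    anchors = [
        AnchorPair(f"v{ref_start + i}", f"{chrom_b}_g{i}", ref_start + i, i, ks)
        for i in range(n_anchors)
    ]
    return CollinearBlock(bid, species[0], species[1], "Vv6", chrom_b, "same", anchors)


class TestClassify:
    def test_bigger_candidate_wins_smaller_becomes_outparalog(self):
        # the grape-chromosome-6 situation: 347 collinear genes at Ks 0.92
        # versus 90 at Ks 0.93 on the same reference span
        ref = ref_genome()
        big = make_block(0, "Cs8", 347, 0.92)
        small = make_block(1, "Cs6", 90, 0.93)
        decisions = classify_correspondence([big, small], ref)
        assert big.label == "ortholog" and small.label == "outparalog"
        assert decisions[0].ortholog_chromosome == "Cs8"

    def test_single_candidate_is_ortholog(self):
        ref = ref_genome()
        b = make_block(0, "Cs8", 12, 1.0)
        classify_correspondence([b], ref)
        assert b.label == "ortholog"

    def test_anchor_tie_broken_by_smaller_ks(self):
        ref = ref_genome()
        young = make_block(0, "Cs1", 40, 0.5)
        old = make_block(1, "Cs2", 40, 0.9)
        classify_correspondence([old, young], ref)
        assert young.label == "ortholog" and old.label == "outparalog"

    def test_tie_without_ks_is_an_error(self):
        ref = ref_genome()
        a = make_block(0, "Cs1", 40, math.nan)
        b = make_block(1, "Cs2", 40, math.nan)
        with pytest.raises(ValueError, match="Ks"):
            classify_correspondence([a, b], ref)

    def test_fragmented_ortholog_outvotes_intact_outparalog(self):
        # two fragments on the true orthologous chromosome sum to more
        # anchors than the single outparalogous block spanning the interval
        ref = ref_genome()
        frag1 = make_block(0, "Cs8", 60, 0.9, ref_start=0)
        frag2 = make_block(1, "Cs8", 55, 0.9, ref_start=65)
        outp = make_block(2, "Cs6", 90, 0.93, ref_start=0)
        classify_correspondence([frag1, frag2, outp], ref)
        assert frag1.label == frag2.label == "ortholog"
        assert outp.label == "outparalog"

    def test_non_overlapping_candidates_decided_separately(self):
        ref = ref_genome()
        left = make_block(0, "Cs8", 30, 0.9, ref_start=0)
        right = make_block(1, "Cs6", 30, 0.9, ref_start=200)
        classify_correspondence([left, right], ref)
        assert left.label == "ortholog" and right.label == "ortholog"

    def test_more_than_two_alternatives_flagged_supernumerary(self):
        ref = ref_genome()
        blocks = [make_block(i, f"Cs{i}", 50 - i, 0.9 + 0.01 * i) for i in range(4)]
        decisions = classify_correspondence(blocks, ref)
        labels = [b.label for b in blocks]
        assert labels == ["ortholog", "outparalog", "outparalog", "outparalog"]
        assert [b.supernumerary for b in blocks] == [False, False, False, True]
        assert decisions[0].supernumerary_blocks == [3]

    def test_relabelling_is_idempotent(self):
        ref = ref_genome()
        blocks = [make_block(0, "Cs8", 100, 0.9), make_block(1, "Cs6", 40, 0.93)]
        classify_correspondence(blocks, ref)
        first = [(b.label, b.supernumerary) for b in blocks]
        classify_correspondence(blocks, ref)
        assert [(b.label, b.supernumerary) for b in blocks] == first

    def test_ortholog_anchors_dominate_on_simulation(self, default_sim, default_run):
        out = default_run
        for sp, blocks in out.blocks_cross.items():
            orth = sum(b.n_anchors for b in blocks if b.label == "ortholog")
            outp = sum(b.n_anchors for b in blocks if b.label == "outparalog")
            assert orth > outp


class TestEchLabelling:
    def test_window_membership(self):
        inside = make_block(0, "Vv8", 10, 1.1, species=("V", "V"))
        recent = make_block(1, "Vv9", 10, 0.1, species=("V", "V"))
        labelled = label_ech_paralogs([inside, recent], (0.7, 1.8))
        assert inside.label == "ECH_paralog" and recent.label == "unassigned"
        assert labelled == [inside]
        df = ech_summary(labelled)
        assert df.iloc[0].n_gene_pairs == 10

    def test_empty_window_rejected(self):
        with pytest.raises(ValueError):
            label_ech_paralogs([], (1.0, 1.0))

    def test_pure_hexaploidy_simulation_all_blocks_are_ech(self):
        # a history with only the triplication: every intragenomic block of
        # >=4 anchors must fall in the ECH window
        from syntriad.collinearity import chain_blocks

        cfg = SimulationConfig(
            seed=3, genes_per_chromosome=60, n_proto_chromosomes=3,
            stem_retention=0.9, retention=0.9, n_inversions=0,
            n_translocations=0, noise_hit_rate=0.0,
            ingroup_species=("s1",), rho={"s1": 1.0},
        )
        res = simulate(cfg)
        sp = "s1"
        blocks = chain_blocks(
            res.genomes[sp], res.genomes[sp], res.hits[(sp, sp)],
            ks_lookup=res.ks_lookup,
        )
        assert blocks
        labelled = label_ech_paralogs(blocks, (0.5, 2.0))
        assert len(labelled) == len(blocks)


class TestScaffoldOrdering:
    def make_ref(self):
        genes = []
        for c in ("chr1", "chr2", "chr3"):
            genes += [
                Gene(f"{c}_r{i}", "R", c, 1 + i * 100, 50 + i * 100, "+")
                for i in range(150)
            ]
        return Genome.from_genes("R", genes)

    def test_plurality_and_median_placement(self):
        ref = self.make_ref()
        scaf_genes = [Gene(f"s{i}", "S", "scafA", 1 + i * 10, 5 + i * 10, "+") for i in range(5)]
        scaf = Genome.from_genes("S", scaf_genes, is_scaffold_level=True)
        # 3 best hits on chr1, 2 on chr3
        hits = [
            HomologHit("s0", "chr1_r10", 90, 300, 1e-30),
            HomologHit("s1", "chr1_r12", 90, 300, 1e-30),
            HomologHit("s2", "chr1_r14", 90, 300, 1e-30),
            HomologHit("s3", "chr3_r5", 90, 300, 1e-30),
            HomologHit("s4", "chr3_r6", 90, 300, 1e-30),
        ]
        pseudo, placement = order_scaffolds(scaf, ref, hits)
        row = placement.iloc[0]
        assert row.reference_chromosome == "chr1"
        assert row.median_ref_order == 12
        assert "pseudo_chr1" in pseudo.chromosomes

    def test_reversed_scaffold_is_flipped(self):
        ref = self.make_ref()
        scaf_genes = [Gene(f"s{i}", "S", "scafA", 1 + i * 10, 5 + i * 10, "+") for i in range(4)]
        scaf = Genome.from_genes("S", scaf_genes, is_scaffold_level=True)
        hits = [HomologHit(f"s{i}", f"chr2_r{20 - i}", 90, 300, 1e-30) for i in range(4)]
        pseudo, placement = order_scaffolds(scaf, ref, hits)
        assert bool(placement.iloc[0].flipped) is True
        assert [g.gene_id for g in pseudo.chromosomes["pseudo_chr2"]] == [
            "s3", "s2", "s1", "s0",
        ]

    def test_hitless_scaffold_goes_to_chrun(self):
        ref = self.make_ref()
        scaf = Genome.from_genes(
            "S", [Gene("x0", "S", "scafX", 1, 5, "+")], is_scaffold_level=True
        )
        pseudo, placement = order_scaffolds(scaf, ref, [])
        assert placement.iloc[0].pseudo_chromosome == "chrUn"
        assert "chrUn" in pseudo.chromosomes

    def test_simulator_fragmented_genome_mostly_recovered(self):
        # scaffolds from known chromosomes must return to their true homes
        cfg = SimulationConfig(
            seed=11, genes_per_chromosome=200, n_proto_chromosomes=4,
            ingroup_species=("s1", "s2"), rho={"s1": 1.0, "s2": 1.1},
            scaffold_species=("s2",), fragments_per_chromosome=4,
            n_inversions=0, n_translocations=0,
        )
        res = simulate(cfg)
        scaf_genome = res.genomes["s2"]
        ref_genome_ = res.genomes["s1"]
        hits = res.hits[("s1", "s2")]
        _, placement = order_scaffolds(scaf_genome, ref_genome_, hits)
        truth = dict(
            zip(res.truth.scaffold_map.scaffold, res.truth.scaffold_map.true_chromosome)
        )
        placed = placement[placement.reference_chromosome != "chrUn"]
        correct = sum(
            truth[row.scaffold] == row.reference_chromosome
            for row in placed.itertuples()
        )
        assert correct / len(placement) >= 0.95
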