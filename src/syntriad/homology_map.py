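"""Resolve block correspondences after a paleo-hexaploidy.

Under a shared genome triplication, a reference region is expected to match
one orthologous region and up to two outparalogous regions in each other
genome.  Orthologous correspondence shows more collinear genes and smaller
Ks than outparalogous correspondence, so candidate blocks overlapping the
same reference interval are ranked by anchor count with median Ks as the
tie-break.  Intragenomic blocks whose median Ks falls in the triplication
(ECH) Ks window are labelled ECH paralogs.

Scaffold-level assemblies are lifted to pseudo-chromosomes by placing each
scaffold on the reference chromosome that attracts the plurality of its
genes' best hits, ordering scaffolds by the median reference position of
those hits, and flipping scaffolds whose hit order runs against the
reference.
"""

from __future__ import annotations

import math
from collections import Counter, defaultdict
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd
from scipy.stats import kendalltau

from .genome_io import CollinearBlock, Gene, Genome, HomologHit

__all__ = [
    "classify_correspondence",
    "label_ech_paralogs",
    "ech_summary",
    "order_scaffolds",
    "CorrespondenceDecision",
]

#: two outparalogous copies are expected per reference region under a triplication
MAX_OUTPARALOGS = 2


@dataclass
class CorrespondenceDecision:
    """Outcome of ortholog/outparalog resolution on one reference interval.

    Candidates are aggregated per target chromosome: fragments of one
    correspondence (split by rearrangement or chaining gaps) vote together,
    so a fragmented orthologous region is not outscored by an intact
    outparalogous one.  ``ortholog_blocks`` lists every block of the winning
    target chromosome; the single best-supported block comes first.
    """

    chromosome: str
    interval: tuple[int, int]  # reference gene-order span covered by candidates
    ortholog_chromosome: str
    ortholog_blocks: list[int]
    outparalog_blocks: list[int]
    supernumerary_blocks: list[int]

    @property
    def ortholog_block(self) -> int:
        return self.ortholog_blocks[0]


def _overlap_groups(blocks: list[CollinearBlock], min_overlap: float) -> list[list[int]]:
    """Group candidate blocks whose reference spans overlap by >= min_overlap
    of the smaller span (single-linkage)."""
    n = len(blocks)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    spans = [b.span_a for b in blocks]
    for i in range(n):
        for j in range(i + 1, n):
            lo = max(spans[i][0], spans[j][0])
            hi = min(spans[i][1], spans[j][1])
            if hi < lo:
                continue
            shorter = min(spans[i][1] - spans[i][0], spans[j][1] - spans[j][0]) + 1
            if (hi - lo + 1) / shorter >= min_overlap:
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[rj] = ri
    groups: dict[int, list[int]] = defaultdict(list)
    for i in range(n):
        groups[find(i)].append(i)
    return list(groups.values())


def classify_correspondence(
    blocks: Sequence[CollinearBlock],
    reference_genome: Genome,
    min_overlap: float = 0.3,
) -> list[CorrespondenceDecision]:
    """Label blocks between the reference and one target genome in place.

    Within each group of reference-overlapping candidates the best-supported
    block (most anchors; smaller median Ks on ties) becomes the ortholog and
    the rest outparalogs; outparalogs beyond :data:`MAX_OUTPARALOGS` are
    flagged supernumerary.  Idempotent: labels are recomputed from scratch.
    """
    ref_sp = reference_genome.species
    for b in blocks:
        if b.species_a != ref_sp:
            raise ValueError(
                f"block {b.block_id}: species_a={b.species_a!r} is not the "
                f"reference {ref_sp!r}; chain with the reference as genome_a"
            )
        b.label = "unassigned"
        b.supernumerary = False

    by_chrom: dict[str, list[CollinearBlock]] = defaultdict(list)
    for b in blocks:
        by_chrom[b.chromosome_a].append(b)

    decisions: list[CorrespondenceDecision] = []
    for chrom in sorted(by_chrom):
        cands = by_chrom[chrom]
        for group in _overlap_groups(cands, min_overlap):
            members = [cands[i] for i in group]
            # aggregate candidate blocks per target chromosome: collinear
            # gene count first, pooled median Ks as the tie-break
            by_target: dict[str, list[CollinearBlock]] = defaultdict(list)
            for b in members:
                by_target[b.chromosome_b].append(b)
            scores: list[tuple[int, float, str]] = []
            top_anchors = max(sum(b.n_anchors for b in bl) for bl in by_target.values())
            for tchrom, bl in by_target.items():
                n = sum(b.n_anchors for b in bl)
                ks_vals = sorted(
                    a.ks for b in bl for a in b.anchors if not math.isnan(a.ks)
                )
                if ks_vals:
                    m = len(ks_vals)
                    med = ks_vals[m // 2] if m % 2 else 0.5 * (
                        ks_vals[m // 2 - 1] + ks_vals[m // 2]
                    )
                else:
                    med = math.nan
                scores.append((n, med, tchrom))
            tied_top = [s for s in scores if s[0] == top_anchors]
            if len(tied_top) > 1 and any(math.isnan(s[1]) for s in tied_top):
                raise ValueError(
                    "anchor-count tie needs median Ks to resolve; compute Ks for "
                    f"candidates on reference {chrom} (target chromosomes "
                    f"{[s[2] for s in tied_top]})"
                )
            scores.sort(key=lambda s: (-s[0],
                                       s[1] if not math.isnan(s[1]) else math.inf,
                                       s[2]))
            ortho_chrom = scores[0][2]
            ortho_blocks = sorted(
                by_target[ortho_chrom], key=lambda b: (-b.n_anchors, b.block_id)
            )
            for b in ortho_blocks:
                b.label = "ortholog"
            outp_ids: list[int] = []
            extra_ids: list[int] = []
            for rank, (_, _, tchrom) in enumerate(scores[1:]):
                for b in sorted(by_target[tchrom], key=lambda b: b.block_id):
                    b.label = "outparalog"
                    if rank < MAX_OUTPARALOGS:
                        outp_ids.append(b.block_id)
                    else:
                        b.supernumerary = True
                        extra_ids.append(b.block_id)
            lo = min(b.span_a[0] for b in members)
            hi = max(b.span_a[1] for b in members)
            decisions.append(
                CorrespondenceDecision(
                    chromosome=chrom,
                    interval=(lo, hi),
                    ortholog_chromosome=ortho_chrom,
                    ortholog_blocks=[b.block_id for b in ortho_blocks],
                    outparalog_blocks=outp_ids,
                    supernumerary_blocks=extra_ids,
                )
            )
    return decisions


def label_ech_paralogs(
    intragenomic_blocks: Sequence[CollinearBlock], ks_window: tuple[float, float]
) -> list[CollinearBlock]:
    """Label intragenomic blocks whose median Ks lies in the ECH window.

    Returns the blocks labelled ``ECH_paralog``; all others are reset to
    ``unassigned``.  The window is inclusive on both ends.
    """
    lo, hi = ks_window
    if not (lo < hi):
        raise ValueError(f"empty Ks window {ks_window}")
    out = []
    for b in intragenomic_blocks:
        mks = b.median_ks
        if not math.isnan(mks) and lo <= mks <= hi:
            b.label = "ECH_paralog"
            out.append(b)
        else:
            b.label = "unassigned"
    return out


def ech_summary(blocks: Sequence[CollinearBlock]) -> pd.DataFrame:
    """Per-species counts of ECH-labelled blocks, gene pairs and distinct genes."""
    per: dict[str, dict] = {}
    for b in blocks:
        if b.label != "ECH_paralog":
            continue
        d = per.setdefault(b.species_a, {"n_blocks": 0, "n_pairs": 0, "genes": set()})
        d["n_blocks"] += 1
        d["n_pairs"] += b.n_anchors
        for a in b.anchors:
            d["genes"].add(a.gene_a)
            d["genes"].add(a.gene_b)
    return pd.DataFrame(
        [
            {"species": sp, "n_blocks": d["n_blocks"], "n_gene_pairs": d["n_pairs"],
             "n_distinct_genes": len(d["genes"])}
            for sp, d in sorted(per.items())
        ]
    )


def order_scaffolds(
    scaffold_genome: Genome,
    reference_genome: Genome,
    hits: Iterable[HomologHit],
    gene_spacing: int = 1000,
) -> tuple[Genome, pd.DataFrame]:
    """Order scaffolds into pseudo-chromosomes by best hits to a reference.

    Each scaffold goes to the reference chromosome holding the plurality of
    its genes' best (highest-score) hits, ranked by the median reference
    order index of those hits; a scaffold is flipped when the Kendall
    concordance between scaffold gene order and reference hit order is
    negative.  Scaffolds without hits land on ``chrUn``.  Returns the
    pseudo-chromosome genome (coordinates re-spaced, order preserved) and a
    placement table.
    """
    best: dict[str, HomologHit] = {}
    for h in hits:
        if h.query_gene_id in scaffold_genome and h.subject_gene_id in reference_genome:
            q = h.query_gene_id
        elif h.subject_gene_id in scaffold_genome and h.query_gene_id in reference_genome:
            # orient scaffold-side as query
            h = HomologHit(h.subject_gene_id, h.query_gene_id, h.identity, h.score, h.e_value)
            q = h.query_gene_id
        else:
            continue
        if q not in best or h.score > best[q].score:
            best[q] = h

    placements = []
    for scaf in sorted(scaffold_genome.chromosomes):
        genes = scaffold_genome.chromosomes[scaf]
        pairs = [
            (g.order_index, reference_genome[best[g.gene_id].subject_gene_id])
            for g in genes
            if g.gene_id in best
        ]
        if not pairs:
            placements.append((scaf, "chrUn", math.inf, 0, False))
            continue
        chrom_votes = Counter(ref.chromosome for _, ref in pairs)
        top_count = max(chrom_votes.values())
        target = min(c for c, n in chrom_votes.items() if n == top_count)
        on_target = [(o, ref.order_index) for o, ref in pairs if ref.chromosome == target]
        ref_orders = sorted(o for _, o in on_target)
        median_order = ref_orders[len(ref_orders) // 2]
        flip = False
        if len(on_target) >= 2:
            tau = kendalltau([p[0] for p in on_target], [p[1] for p in on_target]).statistic
            flip = bool(tau is not None and not math.isnan(tau) and tau < 0)
        placements.append((scaf, target, median_order, len(on_target), flip))

    placements.sort(key=lambda p: (p[1], p[2], p[0]))
    new_genes: list[Gene] = []
    offsets: dict[str, int] = defaultdict(int)
    table_rows = []
    for rank, (scaf, target, median_order, n_hits, flip) in enumerate(placements):
        pseudo = "chrUn" if target == "chrUn" else f"pseudo_{target}"
        genes = list(scaffold_genome.chromosomes[scaf])
        if flip:
            genes = genes[::-1]
        for g in genes:
            pos = offsets[pseudo]
            offsets[pseudo] += gene_spacing
            new_genes.append(
                Gene(
                    g.gene_id, g.species, pseudo,
                    pos + 1, pos + gene_spacing // 2,
                    ("-" if g.strand == "+" else "+") if flip else g.strand,
                )
            )
        table_rows.append(
            {
                "scaffold": scaf,
                "pseudo_chromosome": pseudo,
                "reference_chromosome": target,
                "median_ref_order": (None if math.isinf(median_order) else median_order),
                "n_best_hits": n_hits,
                "flipped": flip,
            }
        )
    pseudo_genome = Genome.from_genes(scaffold_genome.species, new_genes)
    return pseudo_genome, pd.DataFrame(table_rows)
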