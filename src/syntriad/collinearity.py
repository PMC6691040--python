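"""Collinear block inference by sparse dynamic programming in gene-order space.

Homology hits between two genomes (or within one) are placed on a dot matrix
whose axes are gene-order indices.  Within each chromosome pair, maximal
unit-weighted monotone chains (strictly increasing on the first genome,
strictly increasing or strictly decreasing on the second, with at most
``max_gap`` intervening genes between consecutive anchors on either axis)
are extracted greedily by descending chain score; each hit joins at most one
block, and chains shorter than ``min_block_size`` are discarded.

Ties between equal-score chains are broken toward the chain whose first
anchor has the smaller order on the first genome, then on the second, making
the output deterministic for a fixed input.
"""

from __future__ import annotations

import math
from collections import defaultdict
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .genome_io import AnchorPair, CollinearBlock, Genome, HomologHit

__all__ = ["chain_blocks", "block_summary", "best_monotone_chain"]


def _resolve_hits(
    genome_a: Genome, genome_b: Genome, hits: Iterable[HomologHit]
) -> list[tuple]:
    """Orient hits as (gene_in_a, gene_in_b); dedupe; reject unknown IDs.

    For intragenomic input (genome_a is genome_b) pairs are canonicalized so
    the lexicographically smaller (chromosome, order) end comes first, which
    collapses a->b / b->a mirror hits into one dot.
    """
    intra = genome_a is genome_b or genome_a.species == genome_b.species
    unknown: set[str] = set()
    seen: set[tuple[str, str]] = set()
    out = []
    for h in hits:
        q, s = h.query_gene_id, h.subject_gene_id
        if q == s:
            continue
        if intra:
            if q not in genome_a or s not in genome_a:
                unknown.update(g for g in (q, s) if g not in genome_a)
                continue
            ga, gb = genome_a[q], genome_a[s]
            if (ga.chromosome, ga.order_index) > (gb.chromosome, gb.order_index):
                ga, gb = gb, ga
        else:
            if q in genome_a and s in genome_b:
                ga, gb = genome_a[q], genome_b[s]
            elif q in genome_b and s in genome_a:
                ga, gb = genome_a[s], genome_b[q]
            else:
                unknown.update(g for g in (q, s)
                               if g not in genome_a and g not in genome_b)
                continue
        key = (ga.gene_id, gb.gene_id)
        if key in seen:
            continue
        seen.add(key)
        out.append((ga, gb))
    if unknown:
        raise ValueError(
            "hits reference gene IDs absent from both genomes: "
            + ", ".join(sorted(unknown)[:20])
            + (" ..." if len(unknown) > 20 else "")
        )
    return out


def _chain_dp(
    oa: np.ndarray, ob: np.ndarray, max_gap: int
) -> tuple[list[int], tuple[int, int]]:
    """Best chain with oa, ob strictly increasing and gaps <= max_gap.

    Returns (indices of chain members in input order, first-anchor key).
    Score is chain length; ties prefer the smaller (first oa, first ob).
    """
    n = len(oa)
    order = np.lexsort((ob, oa))
    oa_s, ob_s = oa[order], ob[order]
    dp = np.zeros(n, dtype=np.int64)
    # first-anchor key of the best chain ending at j, encoded for lexicographic min
    span = int(max(oa_s.max(), ob_s.max())) + 2 if n else 1
    fkey = oa_s.astype(np.int64) * span + ob_s.astype(np.int64)
    parent = np.full(n, -1, dtype=np.int64)
    g = max_gap + 1
    for j in range(n):
        mask = (
            (oa_s[:j] < oa_s[j])
            & (ob_s[:j] < ob_s[j])
            & (oa_s[j] - oa_s[:j] <= g)
            & (ob_s[j] - ob_s[:j] <= g)
        )
        if mask.any():
            cand = np.flatnonzero(mask)
            dpc = dp[cand]
            best = dpc.max()
            if best >= 1:
                tied = cand[dpc == best]
                pick = tied[np.argmin(fkey[tied])]
                dp[j] = best + 1
                parent[j] = pick
                fkey[j] = fkey[pick]
                continue
        dp[j] = 1
    if n == 0:
        return [], (0, 0)
    top = dp.max()
    tied = np.flatnonzero(dp == top)
    end = tied[np.argmin(fkey[tied])]
    chain = []
    k = end
    while k >= 0:
        chain.append(int(order[k]))
        k = int(parent[k])
    chain.reverse()
    first = fkey[end]
    return chain, (int(first // span), int(first % span))


def best_monotone_chain(
    pairs: Sequence[tuple[int, int]], max_gap: int
) -> tuple[list[int], str]:
    """Best gap-bounded monotone chain over (order_a, order_b) dots.

    Tries both orientations; returns member indices (in input order along the
    chain) and the winning orientation.  Used directly by :func:`chain_blocks`
    and convenient for testing the chain optimality property.
    """
    oa = np.array([p[0] for p in pairs], dtype=np.int64)
    ob = np.array([p[1] for p in pairs], dtype=np.int64)
    fwd, fkey_f = _chain_dp(oa, ob, max_gap)
    hi = int(ob.max()) if len(ob) else 0
    rev, fkey_r = _chain_dp(oa, hi - ob, max_gap)
    if len(fwd) > len(rev):
        return fwd, "same"
    if len(rev) > len(fwd):
        return rev, "inverted"
    # equal scores: prefer the chain starting at the smaller true coordinates
    key_r = (fkey_r[0], hi - fkey_r[1])
    return (fwd, "same") if fkey_f <= key_r else (rev, "inverted")


def chain_blocks(
    genome_a: Genome,
    genome_b: Genome,
    hits: Iterable[HomologHit],
    min_block_size: int = 4,
    max_gap: int = 25,
    ks_lookup: dict[tuple[str, str], float] | None = None,
) -> list[CollinearBlock]:
    """Infer collinear blocks between two genomes (or within one).

    ``ks_lookup`` optionally maps unordered gene-ID pairs to Ks so anchors
    carry divergence estimates; missing pairs get ``nan``.
    """
    resolved = _resolve_hits(genome_a, genome_b, hits)
    by_chrom_pair: dict[tuple[str, str], list[tuple]] = defaultdict(list)
    for ga, gb in resolved:
        by_chrom_pair[(ga.chromosome, gb.chromosome)].append((ga, gb))

    def ks_of(a: str, b: str) -> float:
        if ks_lookup is None:
            return math.nan
        return ks_lookup.get((a, b), ks_lookup.get((b, a), math.nan))

    blocks: list[CollinearBlock] = []
    next_id = 0
    for chrom_pair in sorted(by_chrom_pair):
        dots = sorted(
            by_chrom_pair[chrom_pair],
            key=lambda p: (p[0].order_index, p[1].order_index, p[0].gene_id),
        )
        active = list(range(len(dots)))
        while len(active) >= min_block_size:
            pairs = [(dots[i][0].order_index, dots[i][1].order_index) for i in active]
            members, orientation = best_monotone_chain(pairs, max_gap)
            if len(members) < min_block_size:
                break
            chosen = [active[i] for i in members]
            anchors = [
                AnchorPair(
                    dots[i][0].gene_id,
                    dots[i][1].gene_id,
                    dots[i][0].order_index,
                    dots[i][1].order_index,
                    ks_of(dots[i][0].gene_id, dots[i][1].gene_id),
                )
                for i in chosen
            ]
            blocks.append(
                CollinearBlock(
                    block_id=next_id,
                    species_a=genome_a.species,
                    species_b=genome_b.species,
                    chromosome_a=chrom_pair[0],
                    chromosome_b=chrom_pair[1],
                    orientation=orientation,
                    anchors=anchors,
                )
            )
            next_id += 1
            used = set(chosen)
            active = [i for i in active if i not in used]
    # report blocks by descending size (greedy score order), then position
    blocks.sort(
        key=lambda b: (
            -b.n_anchors, b.chromosome_a, b.chromosome_b,
            b.anchors[0].order_a, b.anchors[0].order_b,
        )
    )
    for i, b in enumerate(blocks):
        b.block_id = i
    return blocks


def block_summary(blocks: Sequence[CollinearBlock]) -> pd.DataFrame:
    """Per-genome-pair block statistics.

    Columns: n_blocks, n_gene_pairs (anchors summed), n_distinct_genes
    (genes de-duplicated across blocks and both sides), longest_block.
    """
    per_pair: dict[tuple[str, str], dict] = {}
    for b in blocks:
        key = (b.species_a, b.species_b)
        d = per_pair.setdefault(
            key, {"n_blocks": 0, "n_gene_pairs": 0, "genes": set(), "longest_block": 0}
        )
        d["n_blocks"] += 1
        d["n_gene_pairs"] += b.n_anchors
        intra = b.species_a == b.species_b
        for a in b.anchors:
            d["genes"].add((b.species_a, a.gene_a) if not intra else ("", a.gene_a))
            d["genes"].add((b.species_b, a.gene_b) if not intra else ("", a.gene_b))
        d["longest_block"] = max(d["longest_block"], b.n_anchors)
    rows = [
        {
            "species_a": k[0],
            "species_b": k[1],
            "n_blocks": v["n_blocks"],
            "n_gene_pairs": v["n_gene_pairs"],
            "n_distinct_genes": len(v["genes"]),
            "longest_block": v["longest_block"],
        }
        for k, v in sorted(per_pair.items())
    ]
    if not rows:
        rows = [
            {
                "species_a": "", "species_b": "", "n_blocks": 0,
                "n_gene_pairs": 0, "n_distinct_genes": 0, "longest_block": 0,
            }
        ]
    return pd.DataFrame(rows)
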