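"""Gene-family copy-number census and polyploidy relatedness.

Starting from a seed list of family genes, homologs are collected per
species from protein-homology hits passing score and identity thresholds.
A family member counts as ECH-related when it forms an anchor of an
ECH-labelled intragenomic block whose partner gene is also in the family —
i.e. the pair is a retained duplicate created by the triplication.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .genome_io import CollinearBlock, Genome, HomologHit

__all__ = ["FamilyReport", "collect_family", "ech_relatedness"]


@dataclass
class FamilyReport:
    family: str
    table: pd.DataFrame  # species, n_homologs, n_ech_related, percent_ech_related


def collect_family(
    seed_gene_ids: Sequence[str],
    hits: Iterable[HomologHit],
    genomes: Mapping[str, Genome],
    score_min: float = 150.0,
    identity_min: float = 50.0,
) -> dict[str, set[str]]:
    """Per-species family homolog sets from hits against the seed proteins.

    A hit whose query or subject is a seed contributes its partner gene when
    ``score >= score_min`` and ``identity >= identity_min``.  Seed genes
    themselves are always members of their own species' set.
    """
    seeds = set(seed_gene_ids)
    if not seeds:
        raise ValueError("empty seed gene list")

    def species_of(gene_id: str) -> str | None:
        for sp, genome in genomes.items():
            if gene_id in genome:
                return sp
        return None

    members: dict[str, set[str]] = {sp: set() for sp in genomes}
    for gid in seeds:
        sp = species_of(gid)
        if sp is not None:
            members[sp].add(gid)
    for h in hits:
        if h.score < score_min or h.identity < identity_min:
            continue
        for seed, partner in ((h.query_gene_id, h.subject_gene_id),
                              (h.subject_gene_id, h.query_gene_id)):
            if seed in seeds:
                sp = species_of(partner)
                if sp is not None:
                    members[sp].add(partner)
    return members


def ech_relatedness(
    family_sets: Mapping[str, set[str]],
    ech_labelled_blocks: Iterable[CollinearBlock],
    family: str = "family",
) -> FamilyReport:
    """Count, per species, family homologs whose ECH duplicate is retained.

    Both anchor partners must be family members for either to count as
    ECH-related (the conservative, countable criterion).  Percentages are to
    2 decimals.  Stable under hit/block reordering.
    """
    ech_related: dict[str, set[str]] = {sp: set() for sp in family_sets}
    for b in ech_labelled_blocks:
        if b.label != "ECH_paralog":
            continue
        fam = family_sets.get(b.species_a, set())
        for a in b.anchors:
            if a.gene_a in fam and a.gene_b in fam:
                ech_related[b.species_a].update((a.gene_a, a.gene_b))
    rows = []
    for sp in sorted(family_sets):
        n = len(family_sets[sp])
        n_ech = len(ech_related.get(sp, set()))
        rows.append(
            {
                "species": sp,
                "n_homologs": n,
                "n_ech_related": n_ech,
                "percent_ech_related": round(100.0 * n_ech / n, 2) if n else 0.0,
            }
        )
    return FamilyReport(family=family, table=pd.DataFrame(rows))
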