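"""The reference-anchored, event-labelled multiple-genome homology table.

Rows are the reference genes in chromosomal order, chromosome by chromosome.
Columns come in three collinear groups reflecting the triplicated ancestry:
group 1 holds the reference gene and each target species' ortholog; groups 2
and 3 hold the reference gene's two retained ECH paralogs and, per species,
the genes collinear to those paralogous regions (outparalogs of the row
gene).  Empty cells are ".".
"""

from __future__ import annotations
from collections import defaultdict
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .genome_io import CollinearBlock, Gene, Genome, ParseError

__all__ = ["HomologyTable", "build_table", "table_stats", "write_table", "read_table"]

EMPTY = "."
GROUPS = (1, 2, 3)


class HomologyTable:
    """Reference-anchored homology matrix with per-cell backing block IDs.

    ``cells[(group, col)]`` and ``block_ids[(group, col)]`` are row-aligned
    lists; ``col`` is ``"ref"`` or a target species code.  Backing block IDs
    are ``-1`` for empty cells and for the group-1 reference column.
    """

    def __init__(self, reference: Genome, species: Sequence[str]):
        self.reference_species = reference.species
        self.species = list(species)
        self.ref_genes: list[Gene] = list(reference.genes())
        self.row_of: dict[str, int] = {g.gene_id: i for i, g in enumerate(self.ref_genes)}
        n = len(self.ref_genes)
        self.cells: dict[tuple[int, str], list[str]] = {}
        self.block_ids: dict[tuple[int, str], list[int]] = {}
        for grp in GROUPS:
            for col in ["ref", *self.species]:
                if grp == 1 and col == "ref":
                    self.cells[(grp, col)] = [g.gene_id for g in self.ref_genes]
                else:
                    self.cells[(grp, col)] = [EMPTY] * n
                self.block_ids[(grp, col)] = [-1] * n

    @property
    def n_rows(self) -> int:
        return len(self.ref_genes)

    @property
    def n_columns(self) -> int:
        return 3 * (1 + len(self.species))

    def column(self, group: int, col: str) -> list[str]:
        return self.cells[(group, col)]

    def filled(self, group: int, col: str) -> int:
        return sum(1 for v in self.cells[(group, col)] if v != EMPTY)

    def chromosome_rows(self) -> list[tuple[str, int, int]]:
        """(chromosome, first_row, last_row) spans, in row order."""
        spans = []
        start = 0
        for i in range(1, self.n_rows + 1):
            if i == self.n_rows or self.ref_genes[i].chromosome != self.ref_genes[start].chromosome:
                spans.append((self.ref_genes[start].chromosome, start, i - 1))
                start = i
        return spans


def _anchor_assignments(
    blocks: Sequence[CollinearBlock], label: str
) -> list[tuple[str, str, int, int, int]]:
    """(ref_gene, partner_gene, order_a, order_b, block_id) for anchors of
    blocks carrying ``label``, in block-then-anchor order."""
    out = []
    for b in blocks:
        if b.label != label:
            continue
        for a in b.anchors:
            out.append((a.gene_a, a.gene_b, a.order_a, a.order_b, b.block_id))
    return out


def build_table(
    reference_genome: Genome,
    labelled_blocks_per_species: Mapping[str, Sequence[CollinearBlock]],
    intragenomic_reference_blocks: Sequence[CollinearBlock] = (),
) -> HomologyTable:
    """Assemble the homology table from labelled blocks.

    Group 1 is filled from ortholog-labelled anchors.  A target gene
    anchored to several reference rows keeps the anchor with the closest
    gene-order rank (then the larger block); losing rows stay empty.  Groups
    2/3 take the row gene's ECH paralogs (from ``ECH_paralog``-labelled
    intragenomic blocks, group assignment by ascending block ID) in the
    reference columns, and each species' ortholog of those paralog genes in
    the species columns.
    """
    table = HomologyTable(reference_genome, list(labelled_blocks_per_species))

    # --- group 1: orthologs per species
    for sp, blocks in labelled_blocks_per_species.items():
        anchors = _anchor_assignments(blocks, "ortholog")
        # resolve target genes hit by several rows: closest order rank wins
        by_target: dict[str, list[tuple]] = defaultdict(list)
        for ref_g, tgt_g, oa, ob, bid in anchors:
            if ref_g not in table.row_of:
                raise ValueError(f"anchor gene {ref_g!r} is not a reference gene")
            by_target[tgt_g].append((abs(oa - ob), bid, ref_g, oa))
        col = table.cells[(1, sp)]
        bcol = table.block_ids[(1, sp)]
        for tgt_g, cands in by_target.items():
            cands.sort(key=lambda c: (c[0], c[1], c[3]))
            _, bid, ref_g, _ = cands[0]
            row = table.row_of[ref_g]
            if col[row] not in (EMPTY, tgt_g):
                # two ortholog blocks claiming one row: keep the earlier
                # (larger, since block IDs ascend by descending size) block
                if bid >= bcol[row]:
                    continue
            col[row] = tgt_g
            bcol[row] = bid

    # --- groups 2/3 reference columns: ECH paralogs of each row gene
    paralogs: dict[str, list[tuple[int, str]]] = defaultdict(list)
    for b in intragenomic_reference_blocks:
        if b.label != "ECH_paralog":
            continue
        for a in b.anchors:
            paralogs[a.gene_a].append((b.block_id, a.gene_b))
            paralogs[a.gene_b].append((b.block_id, a.gene_a))
    for gene_id, partners in paralogs.items():
        row = table.row_of.get(gene_id)
        if row is None:
            raise ValueError(f"ECH anchor gene {gene_id!r} is not a reference gene")
        partners.sort()
        for grp, (bid, partner) in zip((2, 3), partners[:2]):
            table.cells[(grp, "ref")][row] = partner
            table.block_ids[(grp, "ref")][row] = bid

    # --- groups 2/3 species columns: the species' ortholog of the paralog gene
    for grp in (2, 3):
        refcol = table.cells[(grp, "ref")]
        for sp in table.species:
            g1 = table.cells[(1, sp)]
            g1b = table.block_ids[(1, sp)]
            col = table.cells[(grp, sp)]
            bcol = table.block_ids[(grp, sp)]
            used: set[str] = set()
            for row in range(table.n_rows):
                para = refcol[row]
                if para == EMPTY:
                    continue
                prow = table.row_of[para]
                gene = g1[prow]
                if gene == EMPTY or gene in used:
                    continue
                col[row] = gene
                bcol[row] = g1b[prow]
                used.add(gene)

    _check_column_uniqueness(table)
    return table


def _check_column_uniqueness(table: HomologyTable) -> None:
    # target-species columns only: in the reference columns of groups 2/3 a
    # gene legitimately recurs as the mutual paralog of each of its partners
    for key, col in table.cells.items():
        if key[1] == "ref":
            continue
        seen: dict[str, int] = {}
        for row, v in enumerate(col):
            if v == EMPTY:
                continue
            if v in seen:
                raise ValueError(
                    f"gene {v!r} occupies two cells (rows {seen[v]} and {row}) "
                    f"in column group{key[0]}/{key[1]}"
                )
            seen[v] = row


def table_stats(table: HomologyTable) -> pd.DataFrame:
    """Per-species group-1 coverage: collinear fragments, genes, percent.

    A fragment is a maximal run of filled group-1 cells backed by the same
    block (internal gaps do not split a fragment; a block change or
    chromosome boundary does).  Percentages are of the reference gene count,
    to 2 decimals.
    """
    n_ref = table.n_rows
    rows = []
    for sp in table.species:
        filled = table.filled(1, sp)
        fragments = _count_fragments(table, sp)
        pct = round(100.0 * filled / n_ref, 2) if n_ref else 0.0
        rows.append(
            {"species": sp, "fragments": fragments, "collinear_genes": filled,
             "percent": pct, "reference_genes": n_ref}
        )
    return pd.DataFrame(rows)


def _count_fragments(
    table: HomologyTable, sp: str, rows: tuple[int, int] | None = None
) -> int:
    bcol = table.block_ids[(1, sp)]
    col = table.cells[(1, sp)]
    lo, hi = rows if rows else (0, table.n_rows - 1)
    fragments = 0
    prev_block = None
    prev_chrom = None
    for r in range(lo, hi + 1):
        if col[r] == EMPTY:
            continue
        chrom = table.ref_genes[r].chromosome
        if bcol[r] != prev_block or chrom != prev_chrom:
            fragments += 1
        prev_block, prev_chrom = bcol[r], chrom
    return fragments


# ---------------------------------------------------------------------------
# TSV round trip.  Non-reference filled cells are written as gene@block so the
# backing block IDs survive; the group-1 reference column is plain gene IDs.


def write_table(table: HomologyTable, path: str | Path) -> None:
    path = Path(path)
    cols = [(g, c) for g in GROUPS for c in ["ref", *table.species]]
    with path.open("w") as fh:
        fh.write(f"#syntriad-table\tref={table.reference_species}"
                 f"\tspecies={','.join(table.species)}\n")
        fh.write("#chrom\t" + "\t".join(f"g{g}.{c}" for g, c in cols) + "\n")
        for row in range(table.n_rows):
            out = [table.ref_genes[row].chromosome]
            for key in cols:
                v = table.cells[key][row]
                b = table.block_ids[key][row]
                out.append(v if (v == EMPTY or b < 0) else f"{v}@{b}")
            fh.write("\t".join(out) + "\n")


def read_table(path: str | Path, reference_genome: Genome) -> HomologyTable:
    """Read a table written by :func:`write_table`; the reference genome must
    match the one the table was built on (rows are validated against it)."""
    path = Path(path)
    with path.open() as fh:
        header = fh.readline().rstrip("\n")
        if not header.startswith("#syntriad-table"):
            raise ParseError(f"{path.name}: missing table header")
        fields = dict(p.split("=", 1) for p in header.split("\t")[1:])
        species = [s for s in fields.get("species", "").split(",") if s]
        table = HomologyTable(reference_genome, species)
        cols = [(g, c) for g in GROUPS for c in ["ref", *species]]
        fh.readline()  # column-name comment
        row = -1
        for lineno, raw in enumerate(fh, start=3):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            row += 1
            if row >= table.n_rows:
                raise ParseError(f"{path.name}: more rows than reference genes")
            parts = line.split("\t")
            if len(parts) != 1 + len(cols):
                raise ParseError(f"{path.name}:{lineno}: bad column count")
            for key, cell in zip(cols, parts[1:]):
                if key == (1, "ref"):
                    if cell != table.cells[key][row]:
                        raise ParseError(
                            f"{path.name}:{lineno}: reference gene {cell!r} does not "
                            f"match genome order ({table.cells[key][row]!r})"
                        )
                    continue
                if cell == EMPTY:
                    continue
                if "@" in cell:
                    gene, bid = cell.rsplit("@", 1)
                    table.cells[key][row] = gene
                    table.block_ids[key][row] = int(bid)
                else:
                    table.cells[key][row] = cell
    if row + 1 != table.n_rows:
        raise ParseError(f"{path.name}: {row + 1} rows, expected {table.n_rows}")
    return table
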