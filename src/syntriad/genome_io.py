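"""Domain types and file I/O for gene annotations, homology hits and synteny blocks.

All coordinates are stored 1-based inclusive (GFF3 convention); BED input is
converted on read.  Collinearity and gap computations elsewhere in the package
work in *gene-order* space: every gene carries an ``order_index``, its 0-based
rank along its chromosome by start position.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

__all__ = [
    "Gene",
    "Genome",
    "HomologHit",
    "KsPair",
    "AnchorPair",
    "CollinearBlock",
    "read_gene_annotations",
    "read_homolog_hits",
    "write_blocks",
    "read_blocks",
    "write_ks_pairs",
    "read_ks_pairs",
    "ParseError",
]

BLOCK_FORMAT_VERSION = "1"


class ParseError(ValueError):
    """Raised when an input file violates its declared format."""


@dataclass(frozen=True, slots=True)
class Gene:
    """One gene model: 1-based inclusive coordinates, order_index = rank by start."""

    gene_id: str
    species: str
    chromosome: str
    start: int
    end: int
    strand: str
    order_index: int = -1

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise ValueError(
                f"gene {self.gene_id}: invalid interval {self.start}..{self.end}"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be '+' or '-'")


@dataclass
class Genome:
    """Ordered gene models of one species, keyed by chromosome.

    ``chromosomes`` maps chromosome name to the list of genes sorted by start;
    order_index within each list is the bijection 0..n-1.
    """

    species: str
    chromosomes: dict[str, list[Gene]] = field(default_factory=dict)
    is_scaffold_level: bool = False

    def __post_init__(self) -> None:
        self._by_id: dict[str, Gene] = {}
        for chrom, genes in self.chromosomes.items():
            for g in genes:
                if g.gene_id in self._by_id:
                    raise ValueError(f"duplicate gene_id {g.gene_id!r} in {self.species}")
                self._by_id[g.gene_id] = g

    @classmethod
    def from_genes(
        cls, species: str, genes: Iterable[Gene], is_scaffold_level: bool = False
    ) -> "Genome":
        """Build a Genome, sorting genes and (re)assigning order_index per chromosome."""
        by_chrom: dict[str, list[Gene]] = {}
        for g in genes:
            by_chrom.setdefault(g.chromosome, []).append(g)
        out: dict[str, list[Gene]] = {}
        for chrom in sorted(by_chrom):
            ordered = sorted(by_chrom[chrom], key=lambda g: (g.start, g.end, g.gene_id))
            out[chrom] = [
                Gene(g.gene_id, g.species, g.chromosome, g.start, g.end, g.strand, i)
                for i, g in enumerate(ordered)
            ]
        return cls(species=species, chromosomes=out, is_scaffold_level=is_scaffold_level)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._by_id

    def __getitem__(self, gene_id: str) -> Gene:
        return self._by_id[gene_id]

    def get(self, gene_id: str) -> Gene | None:
        return self._by_id.get(gene_id)

    @property
    def n_genes(self) -> int:
        return len(self._by_id)

    def genes(self) -> Iterable[Gene]:
        """All genes, chromosome by chromosome (sorted names), in chromosomal order."""
        for chrom in sorted(self.chromosomes):
            yield from self.chromosomes[chrom]


@dataclass(frozen=True, slots=True)
class HomologHit:
    """One filtered protein-homology hit (BLAST tabular style)."""

    query_gene_id: str
    subject_gene_id: str
    identity: float
    score: float
    e_value: float


@dataclass(frozen=True, slots=True)
class KsPair:
    """Synonymous (and optionally nonsynonymous) divergence of one gene pair.

    ``ks`` is ``nan`` when the estimate is undefined: synonymous-site
    saturation (ps >= 3/4) or zero synonymous sites.
    """

    gene_id_a: str
    gene_id_b: str
    ks: float
    ka: float = math.nan


@dataclass(frozen=True, slots=True)
class AnchorPair:
    """A collinear gene pair inside a block, with gene-order coordinates."""

    gene_a: str
    gene_b: str
    order_a: int
    order_b: int
    ks: float = math.nan


@dataclass
class CollinearBlock:
    """A chained run of collinear gene pairs between two chromosomal regions.

    ``label`` is one of unassigned/ortholog/outparalog/ECH_paralog and is
    assigned by :mod:`syntriad.homology_map`.  ``supernumerary`` marks
    outparalog candidates beyond the two expected under a triplication.
    """

    block_id: int
    species_a: str
    species_b: str
    chromosome_a: str
    chromosome_b: str
    orientation: str  # "same" | "inverted"
    anchors: list[AnchorPair]
    label: str = "unassigned"
    supernumerary: bool = False

    LABELS = ("unassigned", "ortholog", "outparalog", "ECH_paralog")

    @property
    def n_anchors(self) -> int:
        return len(self.anchors)

    @property
    def median_ks(self) -> float:
        vals = sorted(a.ks for a in self.anchors if not math.isnan(a.ks))
        if not vals:
            return math.nan
        m = len(vals)
        mid = m // 2
        return vals[mid] if m % 2 else 0.5 * (vals[mid - 1] + vals[mid])

    @property
    def span_a(self) -> tuple[int, int]:
        orders = [a.order_a for a in self.anchors]
        return min(orders), max(orders)

    @property
    def span_b(self) -> tuple[int, int]:
        orders = [a.order_b for a in self.anchors]
        return min(orders), max(orders)


# ---------------------------------------------------------------------------
# Annotation readers


def read_gene_annotations(path: str | Path, species_code: str, format: str) -> Genome:
    """Read gene models from GFF3 (``gene`` rows) or BED (>=4 columns).

    BED input (0-based half-open) is converted to 1-based inclusive.
    Raises :class:`ParseError` naming the offending line on malformed rows,
    and ``ValueError`` on duplicate gene IDs.
    """
    path = Path(path)
    if format not in ("gff3", "bed"):
        raise ValueError(f"unknown annotation format {format!r}")
    genes: list[Gene] = []
    seen: set[str] = set()
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            try:
                if format == "gff3":
                    if len(fields) < 9:
                        raise ValueError("fewer than 9 columns")
                    if fields[2] != "gene":
                        continue
                    chrom = fields[0]
                    start, end = int(fields[3]), int(fields[4])
                    strand = fields[6]
                    gene_id = _gff3_id(fields[8])
                else:
                    if len(fields) < 4:
                        raise ValueError("fewer than 4 columns")
                    chrom = fields[0]
                    start = int(fields[1]) + 1  # 0-based half-open -> 1-based inclusive
                    end = int(fields[2])
                    gene_id = fields[3]
                    strand = fields[5] if len(fields) >= 6 else "+"
                if strand == ".":
                    strand = "+"
                gene = Gene(gene_id, species_code, chrom, start, end, strand)
            except (ValueError, IndexError) as exc:
                raise ParseError(f"{path.name}:{lineno}: malformed row ({exc})") from exc
            if gene_id in seen:
                raise ParseError(f"{path.name}:{lineno}: duplicate gene ID {gene_id!r}")
            seen.add(gene_id)
            genes.append(gene)
    return Genome.from_genes(species_code, genes)


def _gff3_id(attributes: str) -> str:
    for part in attributes.split(";"):
        part = part.strip()
        if part.startswith("ID="):
            return part[3:]
    raise ValueError(f"no ID attribute in {attributes!r}")


# ---------------------------------------------------------------------------
# Homology hits (BLAST outfmt 6)

_OUTFMT6_NCOL = 12


def read_homolog_hits(path: str | Path, max_evalue: float = 1e-5) -> list[HomologHit]:
    """Read a 12-column BLAST tabular file, keeping hits with E-value < ``max_evalue``.

    Self-hits (query == subject) are dropped.  A->B and B->A may both be
    present; no symmetry is assumed or imposed here.
    """
    path = Path(path)
    hits: list[HomologHit] = []
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < _OUTFMT6_NCOL:
                raise ParseError(
                    f"{path.name}:{lineno}: expected {_OUTFMT6_NCOL} columns, got {len(fields)}"
                )
            try:
                identity = float(fields[2])
                e_value = float(fields[10])
                score = float(fields[11])
            except ValueError as exc:
                raise ParseError(f"{path.name}:{lineno}: non-numeric field ({exc})") from exc
            if e_value < 0:
                raise ParseError(f"{path.name}:{lineno}: negative E-value")
            query, subject = fields[0], fields[1]
            if query == subject:
                continue
            if e_value >= max_evalue:
                continue
            hits.append(HomologHit(query, subject, identity, score, e_value))
    return hits


# ---------------------------------------------------------------------------
# Block file (TSV; one header line per block followed by its anchor rows)


def write_blocks(blocks: Sequence[CollinearBlock], path: str | Path) -> None:
    """Write blocks to the TSV block format (lossless; see :func:`read_blocks`)."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"#syntriad-blocks\tv{BLOCK_FORMAT_VERSION}\n")
        for b in blocks:
            fh.write(
                ">\t{}\t{}\t{}\t{}\t{}\t{}\t{}\t{:.6g}\t{}\t{}\n".format(
                    b.block_id,
                    b.species_a,
                    b.species_b,
                    b.chromosome_a,
                    b.chromosome_b,
                    b.orientation,
                    b.n_anchors,
                    b.median_ks,
                    b.label,
                    int(b.supernumerary),
                )
            )
            for a in b.anchors:
                fh.write(f"{a.gene_a}\t{a.gene_b}\t{a.order_a}\t{a.order_b}\t{a.ks:.6g}\n")


def read_blocks(path: str | Path) -> list[CollinearBlock]:
    """Read the TSV block format written by :func:`write_blocks`."""
    path = Path(path)
    blocks: list[CollinearBlock] = []
    current: CollinearBlock | None = None
    expected = 0
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if fields[0] == ">":
                if current is not None and current.n_anchors != expected:
                    raise ParseError(
                        f"{path.name}:{lineno}: block {current.block_id} has "
                        f"{current.n_anchors} anchors, header declared {expected}"
                    )
                try:
                    current = CollinearBlock(
                        block_id=int(fields[1]),
                        species_a=fields[2],
                        species_b=fields[3],
                        chromosome_a=fields[4],
                        chromosome_b=fields[5],
                        orientation=fields[6],
                        anchors=[],
                        label=fields[9],
                        supernumerary=bool(int(fields[10])),
                    )
                    expected = int(fields[7])
                except (ValueError, IndexError) as exc:
                    raise ParseError(f"{path.name}:{lineno}: bad block header") from exc
                blocks.append(current)
            else:
                if current is None:
                    raise ParseError(f"{path.name}:{lineno}: anchor row before any header")
                try:
                    current.anchors.append(
                        AnchorPair(
                            fields[0], fields[1], int(fields[2]), int(fields[3]),
                            float(fields[4]),
                        )
                    )
                except (ValueError, IndexError) as exc:
                    raise ParseError(f"{path.name}:{lineno}: bad anchor row") from exc
    if current is not None and current.n_anchors != expected:
        raise ParseError(
            f"{path.name}: truncated anchor section for block {current.block_id} "
            f"({current.n_anchors} of {expected} anchors)"
        )
    return blocks


# ---------------------------------------------------------------------------
# Ks list (TSV)


def write_ks_pairs(pairs: Sequence[KsPair], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write("#gene_a\tgene_b\tks\tka\n")
        for p in pairs:
            fh.write(f"{p.gene_id_a}\t{p.gene_id_b}\t{p.ks:.6g}\t{p.ka:.6g}\n")


def read_ks_pairs(path: str | Path) -> list[KsPair]:
    out: list[KsPair] = []
    with Path(path).open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{Path(path).name}:{lineno}: expected >=3 columns")
            ka = float(fields[3]) if len(fields) > 3 else math.nan
            out.append(KsPair(fields[0], fields[1], float(fields[2]), ka))
    return out
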