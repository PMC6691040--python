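"""Nei–Gojobori (1986) estimation of synonymous and nonsynonymous divergence.

The method counts, for each codon, the fraction of single-nucleotide changes
that are synonymous (the codon's synonymous "sites"), tallies observed
synonymous and nonsynonymous differences by averaging over all minimal
mutational pathways between differing codons, and applies the Jukes–Cantor
multiple-hit correction::

    Ks = -(3/4) * ln(1 - (4/3) * ps),   ps = Sd / S

Conventions (standard NG86 practice):

* standard genetic code only;
* changes to stop codons are counted as nonsynonymous at the site-counting
  stage; pathways that pass through a stop codon are dropped and the
  remaining pathways re-weighted (if every pathway hits a stop, all are kept);
* codons containing a gap or an ambiguous base in either sequence are removed
  pairwise before counting;
* Ks (or Ka) is undefined — returned as ``nan`` — when the corresponding
  proportion reaches saturation (p >= 3/4) or the site count is zero.
"""

from __future__ import annotations

import math
from functools import lru_cache
from itertools import permutations

from Bio.Data.CodonTable import standard_dna_table

from .genome_io import KsPair

__all__ = ["count_sites", "count_differences", "ng86", "CodonCounts"]

_BASES = "ACGT"
_STOPS = frozenset(standard_dna_table.stop_codons)
_CODE = dict(standard_dna_table.forward_table)  # codon -> amino acid, stops absent


def _translate(codon: str) -> str | None:
    """Amino acid for a codon, '*' for stop, None if ambiguous."""
    if codon in _STOPS:
        return "*"
    return _CODE.get(codon)


@lru_cache(maxsize=None)
def count_sites(codon: str) -> tuple[float, float]:
    """Fractional (synonymous, nonsynonymous) sites of one codon.

    At each of the 3 positions the 3 possible single-nucleotide changes are
    classified against the standard code; s is the synonymous fraction summed
    over positions and n = 3 - s.  Stop codons and codons with ambiguous
    bases are not countable and raise ``ValueError`` (callers skip them).
    """
    codon = codon.upper()
    aa = _translate(codon)
    if aa is None:
        raise ValueError(f"ambiguous codon {codon!r}")
    if aa == "*":
        raise ValueError(f"stop codon {codon!r} has no defined sites")
    s = 0.0
    for pos in range(3):
        syn = 0
        for base in _BASES:
            if base == codon[pos]:
                continue
            alt = codon[:pos] + base + codon[pos + 1 :]
            if _translate(alt) == aa:  # change to a stop counts as nonsynonymous
                syn += 1
        s += syn / 3.0
    return s, 3.0 - s


@lru_cache(maxsize=None)
def count_differences(codon_a: str, codon_b: str) -> tuple[float, float]:
    """Pathway-averaged (synonymous, nonsynonymous) differences between two codons.

    All orders of applying the differing positions one at a time are
    enumerated; each step is classified synonymous/nonsynonymous; pathways
    passing through a stop codon are discarded and the rest averaged with
    equal weight.  If no stop-free pathway exists the full set is used.
    """
    codon_a, codon_b = codon_a.upper(), codon_b.upper()
    diff_pos = [i for i in range(3) if codon_a[i] != codon_b[i]]
    if not diff_pos:
        return 0.0, 0.0
    valid: list[tuple[int, int]] = []
    through_stop: list[tuple[int, int]] = []
    for order in permutations(diff_pos):
        cur = codon_a
        sd = nd = 0
        hit_stop = False
        for pos in order:
            nxt = cur[:pos] + codon_b[pos] + cur[pos + 1 :]
            aa_cur, aa_nxt = _translate(cur), _translate(nxt)
            if aa_nxt == "*" or aa_cur == "*":
                hit_stop = True
            if aa_cur == aa_nxt:
                sd += 1
            else:
                nd += 1
            cur = nxt
        (through_stop if hit_stop else valid).append((sd, nd))
    chosen = valid if valid else through_stop
    sd = sum(x[0] for x in chosen) / len(chosen)
    nd = sum(x[1] for x in chosen) / len(chosen)
    return sd, nd


class CodonCounts:
    """NG86 site and difference tallies for one aligned sequence pair."""

    __slots__ = ("S", "N", "Sd", "Nd", "n_codons", "n_skipped")

    def __init__(self, S: float, N: float, Sd: float, Nd: float,
                 n_codons: int, n_skipped: int) -> None:
        self.S = S
        self.N = N
        self.Sd = Sd
        self.Nd = Nd
        self.n_codons = n_codons
        self.n_skipped = n_skipped

    @property
    def ps(self) -> float:
        return self.Sd / self.S if self.S > 0 else math.nan

    @property
    def pn(self) -> float:
        return self.Nd / self.N if self.N > 0 else math.nan


def _jc_correct(p: float) -> float:
    if math.isnan(p) or p >= 0.75:
        return math.nan
    return -0.75 * math.log(1.0 - (4.0 / 3.0) * p)


def _codon_ok(codon: str) -> bool:
    return all(b in _BASES for b in codon) and codon not in _STOPS


def count_pair(cds_a: str, cds_b: str) -> CodonCounts:
    """Tally NG86 sites and differences over an aligned CDS pair.

    Sites are averaged over the two sequences; codons with gaps, ambiguity
    codes or stops in either sequence are skipped pairwise.
    """
    if len(cds_a) != len(cds_b):
        raise ValueError(f"length mismatch: {len(cds_a)} vs {len(cds_b)}")
    if len(cds_a) % 3 != 0:
        raise ValueError(f"alignment length {len(cds_a)} not divisible by 3")
    cds_a, cds_b = cds_a.upper(), cds_b.upper()
    S = N = Sd = Nd = 0.0
    used = skipped = 0
    for i in range(0, len(cds_a), 3):
        ca, cb = cds_a[i : i + 3], cds_b[i : i + 3]
        if not (_codon_ok(ca) and _codon_ok(cb)):
            skipped += 1
            continue
        sa, na = count_sites(ca)
        sb, nb = count_sites(cb)
        S += 0.5 * (sa + sb)
        N += 0.5 * (na + nb)
        sd, nd = count_differences(ca, cb)
        Sd += sd
        Nd += nd
        used += 1
    return CodonCounts(S, N, Sd, Nd, used, skipped)


def ng86(cds_a: str, cds_b: str, gene_id_a: str = "a", gene_id_b: str = "b") -> KsPair:
    """Estimate Ks and Ka for an aligned coding-sequence pair (NG86 + Jukes–Cantor)."""
    counts = count_pair(cds_a, cds_b)
    return KsPair(gene_id_a, gene_id_b, _jc_correct(counts.ps), _jc_correct(counts.pn))
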