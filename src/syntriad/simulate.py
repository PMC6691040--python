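"""Synthetic genomes with hexaploid ancestry, for pipeline validation.

The generator embodies the evolutionary history the analysis assumes: a
7-proto-chromosome ancestor is tripled instantaneously (the ECH); the stem
lineage loses duplicated genes in geometric-length runs (losses shared by
every descendant); an outgroup then splits, followed by a star radiation of
ingroup lineages, each of which keeps fractionating independently, rearranges
(inversions, translocations, fusions) and may be emitted as fragmented
scaffolds.  Ks for every surviving homolog pair is drawn from
``Normal(mu, (cv*mu)^2)`` with ``mu = divergence depth x mean lineage rate``
in reference-rate Ks units, so ECH pairs inside species i peak at
``tau_ech * rho_i`` and cross-species pairs at the split depth times the
averaged rates.  Homology hits are emitted for every true pair plus uniform
random noise pairs.

All randomness flows from the config seed; a fixed seed reproduces every
output byte for byte.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .genome_io import Gene, Genome, HomologHit, KsPair

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "SimulationResult",
    "simulate",
    "mutate_cds",
    "write_simulation",
]

_SUBGENOME_TAGS = "ABC"


@dataclass
class SimulationConfig:
    """Parameters of the simulated history (defaults = study conditions).

    Retention is specified per branch segment: ``stem_retention`` is the
    fraction of post-ECH genes surviving the shared stem (before the
    outgroup split, hence common to all species), and ``retention`` the
    per-lineage fraction of stem survivors each terminal lineage keeps.  Both
    act per post-ECH chromosome copy; ``retention`` may be a single float or
    a per-species mapping.  Times are in Ks units at the reference
    (slowest-lineage) rate; rate multipliers ``rho`` are >= 1 with the
    outgroup fixed at 1.
    """

    seed: int
    n_proto_chromosomes: int = 7
    genes_per_chromosome: int = 400
    tau_ech: float = 1.053
    t_outgroup_split: float = 0.68
    t_radiation: float = 0.10
    outgroup: str = "out"
    ingroup_species: tuple[str, ...] = ("sp1", "sp2", "sp3")
    rho: Mapping[str, float] = field(
        default_factory=lambda: {"sp1": 1.0, "sp2": 1.19, "sp3": 1.24}
    )
    stem_retention: float = 0.45
    retention: float | Mapping[str, float] = 0.65
    p_loss: float = 0.53
    n_inversions: int = 2
    n_translocations: int = 1
    n_chromosome_fusions: int = 0
    inversion_size: tuple[int, int] = (5, 30)
    translocation_size: tuple[int, int] = (5, 20)
    ks_cv: float = 0.27
    noise_hit_rate: float = 0.05
    scaffold_species: tuple[str, ...] = ()
    fragments_per_chromosome: int = 8
    min_fragment_genes: int = 5

    @property
    def species(self) -> list[str]:
        return [self.outgroup, *self.ingroup_species]

    def retention_of(self, sp: str) -> float:
        if isinstance(self.retention, Mapping):
            return float(self.retention[sp])
        return float(self.retention)

    def rho_of(self, sp: str) -> float:
        if sp == self.outgroup:
            return 1.0
        return float(self.rho[sp])

    def validate(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        for name, v in (("p_loss", self.p_loss), ("stem_retention", self.stem_retention)):
            if not (0.0 < v <= 1.0):
                raise ValueError(f"{name} must be in (0, 1], got {v}")
        for sp in self.species:
            r = self.retention_of(sp)
            if not (0.0 < r <= 1.0):
                raise ValueError(f"retention for {sp!r} must be in (0, 1], got {r}")
            if self.rho_of(sp) < 1.0:
                raise ValueError(f"rate multiplier for {sp!r} must be >= 1")
        if not (0.0 < self.t_radiation <= self.t_outgroup_split < self.tau_ech):
            raise ValueError(
                "split times must satisfy 0 < t_radiation <= t_outgroup_split < tau_ech"
            )
        unknown = set(self.scaffold_species) - set(self.species)
        if unknown:
            raise ValueError(f"scaffold species not simulated: {sorted(unknown)}")


@dataclass
class GroundTruth:
    """Bookkeeping of the simulated history, for validating pipeline output."""

    genes: pd.DataFrame  # species, gene_id, ancestral_id, subgenome, chromosome
    losses: pd.DataFrame  # species, subgenome, n_ancestral, n_stem_lost, n_terminal_lost, n_retained
    pair_events: dict[frozenset, tuple[str, float]]  # {a, b} -> (event, expected Ks)
    scaffold_map: pd.DataFrame  # species, scaffold, true_chromosome

    def event_of(self, gene_a: str, gene_b: str) -> str | None:
        rec = self.pair_events.get(frozenset((gene_a, gene_b)))
        return rec[0] if rec else None


@dataclass
class SimulationResult:
    config: SimulationConfig
    genomes: dict[str, Genome]
    hits: dict[tuple[str, str], list[HomologHit]]
    ks_pairs: list[KsPair]
    ks_lookup: dict[tuple[str, str], float]
    truth: GroundTruth


def _geometric_run_mask(
    m: int, retention: float, p: float, rng: np.random.Generator
) -> tuple[np.ndarray, list[int]]:
    """Keep-mask over m ordered genes after geometric-run removal to ``retention``.

    Run lengths are i.i.d. geometric(p); runs are placed uniformly at random,
    never overlapping or abutting, by drawing a random composition of the
    retained genes into the gaps around them.  Raises when the target is
    unreachable (too many events to separate).
    """
    keep = np.ones(m, dtype=bool)
    n_remove = round(m * (1.0 - retention))
    if n_remove <= 0:
        return keep, []
    runs: list[int] = []
    total = 0
    while total < n_remove:
        k = int(rng.geometric(p))
        k = min(k, n_remove - total)
        runs.append(k)
        total += k
    E = len(runs)
    retained = m - n_remove
    if retained < E - 1:
        raise ValueError(
            f"retention target {retention} unreachable with p_loss={p} on {m} genes: "
            f"{E} removal events cannot be separated by {retained} survivors"
        )
    extra = retained - (E - 1)
    slots = rng.multinomial(extra, np.full(E + 1, 1.0 / (E + 1)))
    pos = int(slots[0])
    for i, k in enumerate(runs):
        keep[pos : pos + k] = False
        pos += k
        if i < E - 1:
            pos += 1 + int(slots[i + 1])
    return keep, runs


# ---------------------------------------------------------------------------
# rearrangements (operate on per-chromosome lists of gene records)

_Record = tuple[int, int]  # (ancestral index, subgenome)


def _apply_rearrangements(
    chroms: dict[str, list], strands: dict[str, list], cfg: SimulationConfig,
    rng: np.random.Generator,
) -> None:
    names = sorted(chroms)

    def pick_segment(size_range):
        name = names[rng.integers(len(names))]
        genes = chroms[name]
        if len(genes) < size_range[0] + 2:
            return None
        size = int(rng.integers(size_range[0], size_range[1] + 1))
        size = min(size, len(genes) - 1)
        start = int(rng.integers(0, len(genes) - size + 1))
        return name, start, size

    for _ in range(cfg.n_inversions):
        seg = pick_segment(cfg.inversion_size)
        if seg is None:
            continue
        name, start, size = seg
        chroms[name][start : start + size] = chroms[name][start : start + size][::-1]
        flipped = ["-" if s == "+" else "+" for s in strands[name][start : start + size][::-1]]
        strands[name][start : start + size] = flipped

    for _ in range(cfg.n_translocations):
        seg = pick_segment(cfg.translocation_size)
        if seg is None:
            continue
        name, start, size = seg
        moved = chroms[name][start : start + size]
        moved_s = strands[name][start : start + size]
        del chroms[name][start : start + size]
        del strands[name][start : start + size]
        dest = names[rng.integers(len(names))]
        at = int(rng.integers(0, len(chroms[dest]) + 1))
        chroms[dest][at:at] = moved
        strands[dest][at:at] = moved_s

    for _ in range(cfg.n_chromosome_fusions):
        if len([n for n in names if chroms[n]]) < 2:
            break
        a, b = rng.choice(len(names), size=2, replace=False)
        na, nb = names[int(a)], names[int(b)]
        chroms[na].extend(chroms[nb])
        strands[na].extend(strands[nb])
        chroms[nb] = []
        strands[nb] = []
        names = sorted(n for n in chroms if chroms[n])


def _fragment_genome(
    chroms: dict[str, list], strands: dict[str, list], n_fragments: int,
    min_genes: int, rng: np.random.Generator,
) -> tuple[dict[str, list], dict[str, list], list[tuple[str, str]]]:
    """Split each chromosome into scaffolds with shuffled order/orientation.

    Fragment sizes are a random composition with every piece >= ``min_genes``
    (assemblies anchor scaffolds only above a minimal gene content); the
    fragment count drops on chromosomes too short to honour that.
    """
    pieces = []
    for name in sorted(chroms):
        genes = chroms[name]
        if not genes:
            continue
        n = len(genes)
        k = max(1, min(n_fragments, n // max(min_genes, 1)))
        if k == 1:
            bounds = [0, n]
        else:
            sizes = np.full(k, min_genes) + rng.multinomial(
                n - k * min_genes, np.full(k, 1.0 / k)
            )
            bounds = [0, *np.cumsum(sizes).tolist()]
        for lo, hi in zip(bounds[:-1], bounds[1:]):
            pieces.append((name, genes[lo:hi], strands[name][lo:hi]))
    order = rng.permutation(len(pieces))
    new_chroms: dict[str, list] = {}
    new_strands: dict[str, list] = {}
    mapping = []
    for rank, idx in enumerate(order):
        true_chrom, genes, strds = pieces[int(idx)]
        scaf = f"scaf{rank:04d}"
        if rng.random() < 0.5:
            genes = genes[::-1]
            strds = ["-" if s == "+" else "+" for s in strds[::-1]]
        new_chroms[scaf] = genes
        new_strands[scaf] = strds
        mapping.append((scaf, true_chrom))
    return new_chroms, new_strands, mapping


# ---------------------------------------------------------------------------


def simulate(config: SimulationConfig) -> SimulationResult:
    """Run the generative history and return genomes, hits, Ks and ground truth."""
    config.validate()
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n_anc = cfg.n_proto_chromosomes * cfg.genes_per_chromosome

    def chrom_name(proto: int, sub: int) -> str:
        return f"chr{proto + 1}{_SUBGENOME_TAGS[sub]}"

    # shared stem fractionation, one pattern per post-ECH chromosome copy
    stem_keep: dict[tuple[int, int], np.ndarray] = {}
    for proto in range(cfg.n_proto_chromosomes):
        for sub in range(3):
            keep, _ = _geometric_run_mask(
                cfg.genes_per_chromosome, cfg.stem_retention, cfg.p_loss, rng
            )
            stem_keep[(proto, sub)] = keep

    genomes: dict[str, Genome] = {}
    gene_rows = []
    loss_rows = []
    scaffold_rows = []

    for sp in cfg.species:
        chroms: dict[str, list[_Record]] = {}
        strands: dict[str, list[str]] = {}
        per_sub_stats = {s: [0, 0, 0] for s in range(3)}  # stem_lost, term_lost, retained
        for proto in range(cfg.n_proto_chromosomes):
            for sub in range(3):
                base = proto * cfg.genes_per_chromosome
                keep = stem_keep[(proto, sub)]
                survivors = np.flatnonzero(keep)
                per_sub_stats[sub][0] += int(cfg.genes_per_chromosome - len(survivors))
                term_keep, _ = _geometric_run_mask(
                    len(survivors), cfg.retention_of(sp), cfg.p_loss, rng
                )
                final = survivors[term_keep]
                per_sub_stats[sub][1] += int(len(survivors) - len(final))
                per_sub_stats[sub][2] += int(len(final))
                name = chrom_name(proto, sub)
                chroms[name] = [(base + int(i), sub) for i in final]
                strands[name] = [
                    "+" if rng.random() < 0.5 else "-" for _ in range(len(final))
                ]
        _apply_rearrangements(chroms, strands, cfg, rng)

        if sp in cfg.scaffold_species:
            chroms, strands, mapping = _fragment_genome(
                chroms, strands, cfg.fragments_per_chromosome,
                cfg.min_fragment_genes, rng,
            )
            scaffold_rows.extend(
                {"species": sp, "scaffold": scaf, "true_chromosome": tc}
                for scaf, tc in mapping
            )

        # name genes in final chromosomal order and materialize Gene objects
        counter = 0
        genes: list[Gene] = []
        for name in sorted(chroms):
            for idx, ((anc, sub), strand) in enumerate(zip(chroms[name], strands[name])):
                gid = f"{sp}g{counter:05d}"
                counter += 1
                start = 1 + idx * 1000
                genes.append(Gene(gid, sp, name, start, start + 499, strand))
                gene_rows.append(
                    {
                        "species": sp, "gene_id": gid, "ancestral_id": f"anc{anc:05d}",
                        "subgenome": sub + 1, "chromosome": name,
                    }
                )
        genomes[sp] = Genome.from_genes(
            sp, genes, is_scaffold_level=sp in cfg.scaffold_species
        )
        for sub, (stem_l, term_l, ret) in per_sub_stats.items():
            loss_rows.append(
                {
                    "species": sp, "subgenome": sub + 1, "n_ancestral": n_anc,
                    "n_stem_lost": stem_l, "n_terminal_lost": term_l, "n_retained": ret,
                }
            )

    # --- homolog pairs: Ks draws, hits, truth events -----------------------
    species_rank = {sp: i for i, sp in enumerate(cfg.species)}
    hits: dict[tuple[str, str], list[HomologHit]] = {}
    ks_pairs: list[KsPair] = []
    ks_lookup: dict[tuple[str, str], float] = {}
    pair_events: dict[frozenset, tuple[str, float]] = {}

    def pair_key(sp_a: str, sp_b: str) -> tuple[str, str]:
        return tuple(sorted((sp_a, sp_b), key=species_rank.__getitem__))  # type: ignore[return-value]

    # multiple copies of one ancestral gene can survive in one species only
    # through the three subgenomes, so collect per species all copies
    all_copies: dict[int, list[tuple[str, str, int]]] = {a: [] for a in range(n_anc)}
    for row in gene_rows:
        anc = int(row["ancestral_id"][3:])
        all_copies[anc].append((row["species"], row["gene_id"], row["subgenome"] - 1))

    for anc in range(n_anc):
        members = all_copies[anc]
        for (sp_i, gid_i, sub_i), (sp_j, gid_j, sub_j) in itertools.combinations(members, 2):
            if sp_i == sp_j:
                event = "ech_paralog"
                depth = cfg.tau_ech
            elif sub_i == sub_j:
                event = "ortholog"
                depth = (
                    cfg.t_outgroup_split
                    if cfg.outgroup in (sp_i, sp_j)
                    else cfg.t_radiation
                )
            else:
                event = "outparalog"
                depth = cfg.tau_ech
            mu = depth * 0.5 * (cfg.rho_of(sp_i) + cfg.rho_of(sp_j))
            ks = max(0.005, float(rng.normal(mu, cfg.ks_cv * mu)))
            key = pair_key(sp_i, sp_j)
            qa, qb = (gid_i, gid_j) if key == (sp_i, sp_j) or sp_i == sp_j else (gid_j, gid_i)
            identity = float(np.clip(95.0 - 18.0 * ks + rng.normal(0, 2), 30.0, 99.9))
            score = float(max(60.0, 900.0 * math.exp(-ks / 2.0) + rng.normal(0, 15)))
            e_value = float(10.0 ** -min(180.0, max(8.0, 150.0 - 40.0 * ks)))
            hits.setdefault(key, []).append(HomologHit(qa, qb, identity, score, e_value))
            ks_pairs.append(KsPair(qa, qb, ks))
            ks_lookup[(qa, qb)] = ks
            pair_events[frozenset((qa, qb))] = (event, mu)

    # noise hits: uniform random gene pairs, stressing the chaining filter
    for key in sorted(hits):
        sp_a, sp_b = key
        ids_a = [g.gene_id for g in genomes[sp_a].genes()]
        ids_b = [g.gene_id for g in genomes[sp_b].genes()]
        n_noise = int(cfg.noise_hit_rate * len(hits[key]))
        for _ in range(n_noise):
            qa = ids_a[int(rng.integers(len(ids_a)))]
            qb = ids_b[int(rng.integers(len(ids_b)))]
            if qa == qb:
                continue
            hits[key].append(
                HomologHit(
                    qa, qb,
                    float(rng.uniform(30, 70)),
                    float(rng.uniform(60, 200)),
                    1e-8,
                )
            )

    truth = GroundTruth(
        genes=pd.DataFrame(gene_rows),
        losses=pd.DataFrame(loss_rows),
        pair_events=pair_events,
        scaffold_map=pd.DataFrame(
            scaffold_rows, columns=["species", "scaffold", "true_chromosome"]
        ),
    )
    return SimulationResult(
        config=cfg, genomes=genomes, hits=hits, ks_pairs=ks_pairs,
        ks_lookup=ks_lookup, truth=truth,
    )


# ---------------------------------------------------------------------------
# CDS pairs with synonymous-only divergence, for exercising the Ks estimator

_FOURFOLD_PREFIXES = ("GC", "GT", "AC", "CC", "GG", "TC")
_BASES = "ACGT"
MAX_MUTATE_KS = 3.0


def mutate_cds(
    n_pairs: int, codons: int, target_ks: float, seed: int
) -> list[tuple[str, str]]:
    """Generate CDS pairs whose expected NG86 Ks equals ``target_ks``.

    Sequences are built from codon families with exactly one synonymous site
    each (a fourfold-degenerate third position and fully nonsynonymous first
    and second positions), so synonymous divergence follows the Jukes-Cantor
    process exactly: each third position differs with probability
    ``3/4 (1 - exp(-4/3 Ks))``, the alternative base uniform.  Raises at
    ``target_ks`` beyond :data:`MAX_MUTATE_KS` (saturation guard).
    """
    if target_ks < 0:
        raise ValueError("target_ks must be >= 0")
    if target_ks > MAX_MUTATE_KS:
        raise ValueError(
            f"target_ks {target_ks} is beyond saturation (max {MAX_MUTATE_KS})"
        )
    rng = np.random.default_rng(seed)
    p_diff = 0.75 * (1.0 - math.exp(-4.0 / 3.0 * target_ks))
    pairs = []
    for _ in range(n_pairs):
        seq_a = []
        seq_b = []
        for _ in range(codons):
            prefix = _FOURFOLD_PREFIXES[int(rng.integers(len(_FOURFOLD_PREFIXES)))]
            third = _BASES[int(rng.integers(4))]
            seq_a.append(prefix + third)
            if rng.random() < p_diff:
                alt = _BASES[int(rng.integers(4))]
                while alt == third:
                    alt = _BASES[int(rng.integers(4))]
                seq_b.append(prefix + alt)
            else:
                seq_b.append(prefix + third)
        pairs.append(("".join(seq_a), "".join(seq_b)))
    return pairs


# ---------------------------------------------------------------------------


def write_simulation(result: SimulationResult, out_dir: str | Path) -> None:
    """Emit every pipeline input format plus the ground truth and config echo."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for sp, genome in result.genomes.items():
        with (out / f"{sp}.gff3").open("w") as fh:
            fh.write("##gff-version 3\n")
            for g in genome.genes():
                fh.write(
                    f"{g.chromosome}\tsyntriad-sim\tgene\t{g.start}\t{g.end}\t.\t"
                    f"{g.strand}\t.\tID={g.gene_id}\n"
                )
    for (sp_a, sp_b), hit_list in sorted(result.hits.items()):
        with (out / f"{sp_a}_{sp_b}.blast").open("w") as fh:
            for h in hit_list:
                fh.write(
                    f"{h.query_gene_id}\t{h.subject_gene_id}\t{h.identity:.1f}\t100\t"
                    f"10\t0\t1\t100\t1\t100\t{h.e_value:.2e}\t{h.score:.1f}\n"
                )
    with (out / "ks.tsv").open("w") as fh:
        fh.write("#gene_a\tgene_b\tks\tka\n")
        for p in result.ks_pairs:
            fh.write(f"{p.gene_id_a}\t{p.gene_id_b}\t{p.ks:.6g}\tnan\n")
    result.truth.genes.to_csv(out / "truth_genes.tsv", sep="\t", index=False)
    result.truth.losses.to_csv(out / "truth_losses.tsv", sep="\t", index=False)
    if len(result.truth.scaffold_map):
        result.truth.scaffold_map.to_csv(out / "truth_scaffolds.tsv", sep="\t", index=False)
    cfg = {
        k: (list(v) if isinstance(v, tuple) else dict(v) if isinstance(v, Mapping) else v)
        for k, v in vars(result.config).items()
    }
    with (out / "config.yaml").open("w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)
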