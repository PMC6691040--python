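"""End-to-end orchestration: chain -> classify -> table -> fractionation -> dating.

Two entry points: :func:`run_on_simulation` drives the full analysis on an
in-memory :class:`~syntriad.simulate.SimulationResult` (the form tests and
the acceptance study use), and :func:`run_pipeline` is the file-based driver
behind the command line, reading a YAML config, writing every artifact as
TSV plus a JSON manifest with input checksums and parameters.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

from . import alignment_table, collinearity, fractionation, genome_io, homology_map, ks_dating
from .genome_io import CollinearBlock, Genome, HomologHit
from .simulate import SimulationConfig, SimulationResult, simulate, write_simulation

__all__ = [
    "PipelineParams",
    "PipelineOutput",
    "run_on_simulation",
    "run_pipeline",
    "ortholog_label_accuracy",
]


@dataclass
class PipelineParams:
    min_block_size: int = 4
    max_gap: int = 25
    ks_bin_width: float = 0.05
    ks_range: tuple[float, float] = (0.005, 3.0)
    ech_window_sigmas: float = 2.0
    ech_calibration: tuple[float, float] = (115.0, 130.0)
    min_overlap: float = 0.3


@dataclass
class PipelineOutput:
    reference: str
    blocks_intra: dict[str, list[CollinearBlock]]
    blocks_cross: dict[str, list[CollinearBlock]]
    table: alignment_table.HomologyTable
    table_stats: pd.DataFrame
    retention: pd.DataFrame
    run_histograms: dict[str, fractionation.RunLengthHistogram]
    geometric_fits: dict[str, fractionation.GeometricFit]
    ech_peaks: dict[str, ks_dating.KsPeak]
    rates: ks_dating.RateCorrection
    ortholog_peaks: dict[str, ks_dating.KsPeak]
    dates: dict[str, ks_dating.DateEstimate]

    def report(self) -> str:
        """Human-readable summary of the main tables and dating results."""
        lines = [f"reference: {self.reference}", "", "group-1 coverage:"]
        lines.append(self.table_stats.to_string(index=False))
        lines.append("")
        lines.append("geometric fractionation fits:")
        for sp, fit in self.geometric_fits.items():
            h = self.run_histograms[sp]
            lines.append(
                f"  {sp}: events={h.total_events} removed={h.total_removed_genes} "
                f"p_reg={fit.p_regression:.4f} p_mle={fit.p_mle:.4f} "
                f"R2={fit.r_squared:.4f} F-p={fit.p_value:.4f}"
            )
        lines.append("")
        lines.append("ECH Ks peaks and rate correction:")
        for sp, pk in self.ech_peaks.items():
            lines.append(
                f"  {sp}: mu={pk.mu:.3f} sigma={pk.sigma:.3f} "
                f"r={self.rates.r[sp] * 100:.2f}% lambda={self.rates.lam[sp]:.4f}"
            )
        lines.append("")
        lines.append("dated splits (vs reference):")
        for sp, d in self.dates.items():
            lines.append(
                f"  {self.reference}-{sp}: corrected mu={d.corrected_mu:.3f} "
                f"-> {d.t_low:.2f}-{d.t_high:.2f} mya"
            )
        return "\n".join(lines)


def _anchor_ks(blocks: Sequence[CollinearBlock], label: str | None = None) -> list[float]:
    vals = []
    for b in blocks:
        if label is not None and b.label != label:
            continue
        vals.extend(a.ks for a in b.anchors if not math.isnan(a.ks))
    return vals


def run_on_simulation(
    result: SimulationResult, params: PipelineParams | None = None
) -> PipelineOutput:
    """Run the full analysis on simulator output, reference = outgroup."""
    return run_analysis(
        reference=result.config.outgroup,
        genomes=result.genomes,
        hits=result.hits,
        ks_lookup=result.ks_lookup,
        params=params,
    )


def run_analysis(
    reference: str,
    genomes: Mapping[str, Genome],
    hits: Mapping[tuple[str, str], Sequence[HomologHit]],
    ks_lookup: dict[tuple[str, str], float],
    params: PipelineParams | None = None,
) -> PipelineOutput:
    """Core pipeline on in-memory inputs.

    ``hits`` maps species pairs (reference first for cross pairs, ``(sp,
    sp)`` for intragenomic) to hit lists.  Stages: intragenomic chaining and
    ECH labelling per species; reference-vs-target chaining and
    ortholog/outparalog classification; homology table; retention and
    removal-run statistics with geometric fits; ECH peak fitting, rate
    correction and split dating.
    """
    p = params or PipelineParams()
    if reference not in genomes:
        raise ValueError(f"reference {reference!r} not among genomes {list(genomes)}")
    targets = [sp for sp in genomes if sp != reference]

    # --- intragenomic blocks and ECH labelling
    blocks_intra: dict[str, list[CollinearBlock]] = {}
    ech_peaks: dict[str, ks_dating.KsPeak] = {}
    for sp in genomes:
        key = (sp, sp)
        sp_hits = hits.get(key, [])
        blocks = collinearity.chain_blocks(
            genomes[sp], genomes[sp], sp_hits,
            min_block_size=p.min_block_size, max_gap=p.max_gap, ks_lookup=ks_lookup,
        )
        ks_vals = _anchor_ks(blocks)
        peak = ks_dating.fit_ks_peaks(
            ks_vals, n_components=1, ks_range=p.ks_range,
            bin_width=p.ks_bin_width, source=f"{sp} paralogs",
        )[0]
        ech_peaks[sp] = peak
        window = (
            max(p.ks_range[0], peak.mu - p.ech_window_sigmas * peak.sigma),
            peak.mu + p.ech_window_sigmas * peak.sigma,
        )
        homology_map.label_ech_paralogs(blocks, window)
        blocks_intra[sp] = blocks

    # --- cross-genome blocks and ortholog/outparalog resolution
    blocks_cross: dict[str, list[CollinearBlock]] = {}
    for sp in targets:
        key = (reference, sp) if (reference, sp) in hits else (sp, reference)
        blocks = collinearity.chain_blocks(
            genomes[reference], genomes[sp], hits.get(key, []),
            min_block_size=p.min_block_size, max_gap=p.max_gap, ks_lookup=ks_lookup,
        )
        homology_map.classify_correspondence(
            blocks, genomes[reference], min_overlap=p.min_overlap
        )
        blocks_cross[sp] = blocks

    # --- homology table and fractionation statistics
    table = alignment_table.build_table(
        genomes[reference], blocks_cross, blocks_intra[reference]
    )
    stats = alignment_table.table_stats(table)
    retention = fractionation.retention_by_chromosome(table)
    run_hists: dict[str, fractionation.RunLengthHistogram] = {}
    geo_fits: dict[str, fractionation.GeometricFit] = {}
    for sp in targets:
        h = fractionation.removal_runs(table, sp)
        run_hists[sp] = h
        if h.total_events:
            geo_fits[sp] = fractionation.fit_geometric(h)

    # --- rates and dating
    rates = ks_dating.rate_correction({sp: pk.mu for sp, pk in ech_peaks.items()})
    ortho_peaks: dict[str, ks_dating.KsPeak] = {}
    dates: dict[str, ks_dating.DateEstimate] = {}
    mu_ech_ref = ech_peaks[rates.reference].mu
    for sp in targets:
        vals = _anchor_ks(blocks_cross[sp], label="ortholog")
        if len(vals) < 10:
            continue
        peak = ks_dating.fit_ks_peaks(
            vals, n_components=1, ks_range=p.ks_range,
            bin_width=p.ks_bin_width, source=f"{reference}-{sp} orthologs",
        )[0]
        ortho_peaks[sp] = peak
        corrected = rates.lambda_pair(reference, sp) * peak.mu
        dates[sp] = ks_dating.date_event(
            corrected, mu_ech_ref, p.ech_calibration, event=f"{reference}-{sp} split"
        )

    return PipelineOutput(
        reference=reference,
        blocks_intra=blocks_intra,
        blocks_cross=blocks_cross,
        table=table,
        table_stats=stats,
        retention=retention,
        run_histograms=run_hists,
        geometric_fits=geo_fits,
        ech_peaks=ech_peaks,
        rates=rates,
        ortholog_peaks=ortho_peaks,
        dates=dates,
    )


def ortholog_label_accuracy(output: PipelineOutput, truth) -> float:
    """Fraction of anchors in ortholog-labelled blocks that are true orthologs."""
    good = total = 0
    for blocks in output.blocks_cross.values():
        for b in blocks:
            if b.label != "ortholog":
                continue
            for a in b.anchors:
                total += 1
                if truth.event_of(a.gene_a, a.gene_b) == "ortholog":
                    good += 1
    return good / total if total else float("nan")


# ---------------------------------------------------------------------------
# file-based driver


@dataclass
class PipelineConfig:
    """YAML-mappable configuration for the file-based pipeline."""

    out_dir: str
    seed: int = 0
    reference: str = ""
    simulate: dict | None = None  # SimulationConfig overrides; None = read files
    annotations: dict[str, str] = field(default_factory=dict)  # species -> gff3/bed path
    annotation_format: str = "gff3"
    hits: dict[str, str] = field(default_factory=dict)  # "spA:spB" -> blast path
    ks: str | None = None  # Ks TSV path
    params: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with Path(path).open() as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with path.open("rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> PipelineOutput:
    """File-based end-to-end run; writes artifacts and a manifest to out_dir."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    inputs: list[Path] = []

    if config.simulate is not None:
        sim_cfg = SimulationConfig(seed=config.seed, **{
            k: (tuple(v) if isinstance(v, list) else v)
            for k, v in config.simulate.items()
        })
        result = simulate(sim_cfg)
        write_simulation(result, out / "sim")
        reference = config.reference or sim_cfg.outgroup
        genomes, hit_map, ks_lookup = result.genomes, result.hits, result.ks_lookup
    else:
        if not config.reference:
            raise ValueError("reference species is required for file inputs")
        if config.reference not in config.annotations:
            raise ValueError(
                f"reference {config.reference!r} missing from annotations "
                f"({sorted(config.annotations)})"
            )
        reference = config.reference
        genomes = {}
        for sp, path in config.annotations.items():
            inputs.append(Path(path))
            genomes[sp] = genome_io.read_gene_annotations(path, sp, config.annotation_format)
        hit_map = {}
        for pair, path in config.hits.items():
            sp_a, sp_b = pair.split(":")
            inputs.append(Path(path))
            hit_map[(sp_a, sp_b)] = genome_io.read_homolog_hits(path)
        ks_lookup = {}
        if config.ks:
            inputs.append(Path(config.ks))
            for kp in genome_io.read_ks_pairs(config.ks):
                ks_lookup[(kp.gene_id_a, kp.gene_id_b)] = kp.ks

    params = PipelineParams(**{
        k: (tuple(v) if isinstance(v, list) else v) for k, v in config.params.items()
    })
    output = run_analysis(reference, genomes, hit_map, ks_lookup, params)

    # artifacts
    for sp, blocks in output.blocks_cross.items():
        genome_io.write_blocks(blocks, out / f"blocks_{reference}_{sp}.tsv")
    for sp, blocks in output.blocks_intra.items():
        genome_io.write_blocks(blocks, out / f"blocks_{sp}_{sp}.tsv")
    alignment_table.write_table(output.table, out / "homology_table.tsv")
    output.table_stats.to_csv(out / "table_stats.tsv", sep="\t", index=False)
    output.retention.to_csv(out / "retention.tsv", sep="\t", index=False)
    (out / "report.txt").write_text(output.report() + "\n")
    manifest = {
        "reference": reference,
        "seed": config.seed,
        "params": vars(params) | {
            k: list(v) for k, v in vars(params).items() if isinstance(v, tuple)
        },
        "inputs": {str(p): _sha256(p) for p in inputs if p.exists()},
        "artifacts": {
            p.name: _sha256(p) for p in sorted(out.glob("*.tsv")) if p.is_file()
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return output
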