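# syntriad

Polyploidy-aware multi-genome alignment for comparative plant genomics:
collinear-block chaining, ortholog/outparalog resolution under a shared
ancient hexaploidy, a reference-anchored homology table, genome-fractionation
statistics, and rate-corrected molecular dating — with a synthetic-genome
generator that provides ground truth for every stage.

## The problem

Core eudicots share an ancient whole-genome triplication (the
core-eudicot-common hexaploidy, ECH, the "gamma" event): every pre-event
gene gave rise to up to three copies. When several descendant genomes are
compared — say a family of related species against a slow-evolving outgroup
used as reference — each reference region therefore corresponds to one
*orthologous* region (same post-ECH copy, diverged at speciation) and up to
two *outparalogous* regions (different post-ECH copies, diverged at the
triplication) in every other genome. Confusing the two corrupts everything
downstream: gene-loss estimates, divergence dates, family histories.

`syntriad` resolves this hierarchy explicitly:

1. **Collinearity** (`syntriad.collinearity`) — homology hits (BLAST
   tabular, E < 1e-5) are chained in gene-order space by sparse dynamic
   programming into monotone, gap-bounded blocks of ≥ 4 collinear gene
   pairs.
2. **Correspondence** (`syntriad.homology_map`) — per reference interval,
   orthologous correspondence is recognised by *more collinear genes and
   smaller Ks* than outparalogous correspondence; intragenomic blocks whose
   median Ks falls in the triplication window are labelled ECH paralogs.
   Scaffold-level assemblies are lifted to pseudo-chromosomes by best-hit
   plurality against the reference.
3. **Homology table** (`syntriad.alignment_table`) — reference genes in
   chromosomal order × 3 collinear groups × (1 + N species) columns; a cell
   holds a collinear gene ID or "." for no inferred correspondence.
4. **Fractionation** (`syntriad.fractionation`) — runs of consecutively
   removed genes are read off the table and fitted to the geometric model
   `P(K = k) = p (1-p)^(k-1)`, by least squares on the event histogram and
   by the MLE `p = events / removed genes`, with regression F-test goodness.
5. **Ks and dating** (`syntriad.ng86`, `syntriad.ks_dating`) — synonymous
   divergence by Nei–Gojobori (1986) with Jukes–Cantor correction; Gaussian
   peaks fitted to binned Ks densities; per-lineage rates aligned to the
   slowest lineage via `r = (μᵢ − μ_G)/μ_G`, `λᵢ = 1/(1+r)`,
   `λᵢⱼ = (λᵢ+λⱼ)/2`; events dated by scaling the ECH calibration window
   `T = calibration × μ_event / μ_ECH`.
6. **Simulation** (`syntriad.simulate`) — a 7-proto-chromosome ancestor is
   tripled, fractionates in geometric runs along the shared stem and each
   terminal lineage, speciates (outgroup + star radiation) with
   lineage-specific rate multipliers, rearranges and optionally fragments
   into scaffolds; every pipeline input format is emitted alongside the
   ground truth.

## Worked example

```python
from syntriad.ks_dating import rate_correction, date_event

# ECH Ks peaks of two fast lineages against the slow outgroup standard
rc = rate_correction({"papeda": 1.252, "sweet_orange": 1.301, "grape": 1.053})
print(f"papeda evolves {100*rc.r['papeda']:.2f}% faster (lambda={rc.lam['papeda']:.4f})")
print(f"sweet orange   {100*rc.r['sweet_orange']:.2f}% faster")

# date the grape–Rutaceae split: ortholog Ks peak 0.744, ECH calibrated 115–130 mya
est = date_event(0.744, ech_mu=1.053, ech_calibration=(115, 130))
print(f"split: {est.t_low:.2f}–{est.t_high:.2f} mya")
```

prints

```
papeda evolves 18.90% faster (lambda=0.8411)
sweet orange   23.55% faster
split: 81.25–91.85 mya
```

i.e. the two lineages run 18.90% and 23.55% faster than the standard, and
linear scaling of the calibration window puts the outgroup split at roughly
81–92 million years ago.

A full synthetic analysis, end to end:

```bash
syntriad simulate --seed 1 --out-dir sim/
printf 'out_dir: run/\nseed: 1\nsimulate: {}\n' > config.yaml
syntriad run --config config.yaml     # chain → classify → table → fits → dates
```

`run/report.txt` then contains the per-species coverage table, geometric
fractionation fits and the dated splits; `run/homology_table.tsv` is the
3-group homology table.

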