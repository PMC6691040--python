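# Methods

This note documents the models behind each stage, the tunable parameters
and their defaults, the design choices made where the literature leaves the
procedure open, and the limits of what the synthetic benchmarks show.

## Collinear chaining

Hits are mapped to dots `(order_a, order_b)` in gene-order space (gene rank
along the chromosome, not base pairs: loss and insertion statistics are
counted in genes). Within each chromosome pair, the best chain is found by
sparse dynamic programming and chains are extracted greedily by descending
score until none reaches `min_block_size`; each hit joins at most one
block.

* A chain must be strictly monotone on both axes (increasing/increasing =
  `same`, increasing/decreasing = `inverted`) with at most `max_gap`
  intervening genes between consecutive anchors on either genome.
* **Score = anchor count** (unit weights). Ties prefer the chain whose
  first anchor has the smaller `order_a`, then `order_b`, so output is
  deterministic. We deliberately avoid similarity-weighted scores:
  reproducibility over sophistication, and the downstream statistics count
  genes, not bit-scores.
* `min_block_size = 4` (the conventional reporting floor for collinear
  blocks) and `max_gap = 25` genes. The gap bound is the one genuinely free
  parameter: too small fragments blocks in heavily fractionated regions
  (gaps are runs of lost genes plus unrelated insertions), too large chains
  across rearrangement breakpoints. 25 accommodates the long gap tail under
  geometric loss at p ≈ 0.5 (P(run > 25) ≈ 10⁻⁸) while staying far below
  typical block spacing. Both are exposed everywhere (`--min-block`,
  `--max-gap`).
* Intragenomic runs canonicalize each hit so the lexicographically smaller
  (chromosome, order) end comes first; mirror chains are thus reported
  once. Self-hits are dropped.

Optimality of the DP (score equality with exhaustive enumeration of
monotone gap-bounded chains) is asserted on random ≤15-hit instances; the
greedy multi-chain extraction is heuristic, as in all practical synteny
tools.

## Ortholog vs outparalog resolution

Under a shared triplication each reference interval is expected to match
one orthologous and up to two outparalogous regions per genome.
Orthologous correspondence retains more collinear genes and smaller Ks.
The classifier:

1. groups candidate blocks whose reference spans overlap by ≥ 30% of the
   smaller span (single linkage) into one decision;
2. within a decision, **aggregates blocks per target chromosome** — the
   fragments of one correspondence (split by rearrangement or chaining
   gaps) vote together — and ranks chromosomes by summed anchors, breaking
   ties by pooled median Ks (smaller wins; a tie without Ks is an error
   asking for Ks computation);
3. labels every block of the winning chromosome `ortholog`, the rest
   `outparalog`; alternatives beyond the two expected under a triplication
   are flagged `supernumerary` for inspection.

The 30% overlap threshold and the per-chromosome aggregation are design
choices: no numeric rule is standard, and block-level ranking (each
fragment judged alone) is unstable exactly where fractionation is strong.
When each candidate chromosome carries a single block the two rules
coincide. Relabelling is idempotent.

ECH paralogs are intragenomic blocks whose median anchor Ks falls inside
the triplication window; the pipeline derives the window per species as the
fitted ECH peak ± 2σ (configurable), so it adapts to each lineage's rate.

## Pseudo-chromosomes

A scaffold is assigned to the reference chromosome holding the plurality of
its genes' best hits (highest bit-score; lexicographic tie-break), ordered
by the median reference order index of those hits, and flipped when the
Kendall concordance between scaffold order and reference order is negative.
Hitless scaffolds are appended to `chrUn`. Single-gene scaffolds are
intrinsically ambiguous under triplicated ancestry (the best hit may be an
outparalog when the ortholog copy was lost); assemblies typically anchor
only scaffolds above a minimal gene content, and the generator's
`min_fragment_genes` mirrors that.

## The homology table

Rows are reference genes in chromosomal order; columns are 3 collinear
groups × (reference + one column per species); cells hold a gene ID or ".".
Group 1 carries each species' ortholog of the row gene. Groups 2/3 carry
the row gene's retained ECH paralogs in the reference columns (group
assignment by ascending paralog-block ID; a single retained paralog
occupies group 2) and, in the species columns, each species' ortholog of
that paralog gene — i.e. the outparalogs of the row gene, each cell backed
by a labelled-block anchor.

Conflict rules: a target gene anchored to several reference rows keeps the
anchor with the closest order rank (tandem ambiguity); a row claimed by two
ortholog blocks keeps the larger block's anchor; a gene recurring within a
target-species column is an error (in the group-2/3 *reference* columns a
gene legitimately recurs as the mutual paralog of each of its partners).

`table_stats` counts fragments as maximal same-block runs of filled group-1
cells — internal gaps do not split a fragment, a block change or chromosome
boundary does — and percentages of the reference gene count to 2 decimals.

## Fractionation and the geometric model

A removal run is a maximal stretch of "." group-1 cells strictly between
two filled cells of the same block: gaps abutting fragment boundaries
reflect rearrangement, not removal, and are excluded. If each gene in a
removal event independently terminates the event with probability p, run
lengths are geometric. Two estimators are reported:

* `p_mle = total events / total removed genes` (reciprocal mean run
  length, the closed-form MLE, bin-order invariant);
* `p_regression` from nonlinear least squares of
  `count(k) = E · p (1-p)^(k-1)` over the observed k (tail pooled at
  k = 50), with R², SSE, RMSE and the regression F statistic
  (regression MS / residual MS on df (1, K−2) over K distinct bins).

The reported "goodness p-value" is **P(F ≤ observed) under the
no-relation null** — a value near 1 *accepts* the geometric description.
This orientation (rather than the conventional survival function, which
tends to 0 for any good fit) is chosen so the statistic reads as a fitness
score on [0, 1]; it is the only interpretation under which published
acceptance-style values in the 0.88–0.94 range are attainable for strongly
geometric data.

When the reference genome itself has lost genes, observed runs are a
thinned version of the underlying events (rows vanish where the reference
lost the gene), biasing run lengths slightly downward; run-length
benchmarks therefore use a lossless reference, and real-data estimates
should be read as conditional on reference retention.

## Ks estimation (Nei–Gojobori 1986)

Per codon, the synonymous site count is the fraction of the 9
single-nucleotide neighbours that preserve the amino acid (standard code;
changes to stops count as nonsynonymous); sites are averaged over the two
sequences. Differences between codons are averaged over all orders of
applying the differing positions, dropping pathways that pass through a
stop and re-weighting the rest (if every pathway hits a stop the full set
is kept). Gapped or ambiguous codons are removed pairwise. The
Jukes–Cantor correction `Ks = −(3/4) ln(1 − (4/3) ps)` is undefined
(`nan`) at saturation (ps ≥ 3/4) or zero synonymous sites. The stop-pathway
and ambiguity conventions above are standard NG86 practice; the original
description leaves them open. The implementation is cross-checked in the
test suite against Biopython's independent NG86 route and against a
brute-force pathway enumeration over all sense-codon pairs.

## Ks peaks, rate correction, dating

Ks values in `(0.005, 3.0)` (saturation guard; both ends configurable) are
binned at width 0.05 and the density fitted by least squares to a sum of
Gaussians — the classical curve-fitting workflow on binned Ks
distributions, not a kernel density. Initial guesses come from quantile
slabs; peaks return sorted by μ with R², SSE, RMSE.

Lineage rates are corrected against the slowest lineage G (smallest ECH
peak): `r = (μᵢ − μ_G)/μ_G`, `λᵢ = 1/(1+r)`; after correction every
lineage's ECH peak equals μ_G exactly, by construction. Cross-species
distributions use the arithmetic mean `λᵢⱼ = (λᵢ + λⱼ)/2`, except that a
pair containing the standard itself uses the other member's λ alone.
Dates scale the ECH calibration window linearly:
`T = calibration × μ_event/μ_ECH`. With peaks quoted to 3 decimals,
reproduction of published date windows carries ~0.15% slack. No
uncertainty is propagated beyond the fit diagnostics; bootstrap intervals
are future work.

## The synthetic generator

The generator emulates the generative history the analysis assumes, and is
the source of ground truth for every recovery benchmark. Defaults are the
study conditions; sizes are chosen so the full benchmark runs in seconds on
one core while keeping counting noise well inside the stated tolerances.

| parameter | default | meaning |
|---|---|---|
| `n_proto_chromosomes` | 7 | ancestral chromosomes before tripling |
| `genes_per_chromosome` | 400 | ancestral genes per chromosome (2,800 total; 8,400 post-ECH) |
| `tau_ech` | 1.053 | triplication depth in reference-rate Ks units |
| `t_outgroup_split` | 0.68 | outgroup divergence depth |
| `t_radiation` | 0.10 | star radiation of the ingroup |
| `rho` | 1.0 / 1.19 / 1.24 | ingroup rate multipliers (outgroup = 1) |
| `stem_retention` | 0.45 | post-ECH survival on the shared stem |
| `retention` | 0.65 | per-lineage survival of stem survivors |
| `p_loss` | 0.53 | geometric run-length parameter of removal events |
| `ks_cv` | 0.27 | σ/μ of the Ks draw per pair |
| `noise_hit_rate` | 0.05 | random hits added per true hit |

Design points:

* **Two-stage loss.** Losses on the shared stem (before the outgroup
  split) are inherited by every species; per-lineage losses are
  independent. The shared stage is what makes orthologous correspondence
  denser than outparalogous (by a factor 1/stem_retention): with purely
  terminal loss the two densities are equal and the discrimination
  principle has no signal. Stem retention of 0.45 per subgenome copy makes
  both ECH copies of a gene jointly survive in ~9% of cases, the order
  observed in slowly-evolving triplicated genomes. Group-1 fill of the
  table recovers the *per-lineage* retention: shared losses are absent from
  the reference rows too.
* **Run placement.** Event lengths are i.i.d. geometric(p_loss); events
  are placed by a uniformly random composition of the survivors into the
  gaps around them, never overlapping or abutting, so observed table runs
  are exactly the simulated events. (Sequential random placement merges
  adjacent events and inflates observed run lengths.) An unreachable
  retention target — more events than survivors can separate — is an
  error.
* **Ks model.** Each surviving pair draws
  `Ks ~ Normal(μ, (ks_cv·μ)²)`, `μ = depth × (ρᵢ+ρⱼ)/2`: ECH pairs within
  species i peak at `tau_ech·ρᵢ`, orthologs at the split depth times the
  averaged rates. The triplication is instantaneous (no pre-merger
  subgenome divergence) and Ks noise is Gaussian by assertion — the model
  the peak-fitting stage assumes, deliberately.
* **`mutate_cds`** builds CDS pairs from codon families with exactly one
  fourfold-degenerate synonymous site (Ala/Gly/Val/Thr/Pro/TCx-Ser), so
  synonymous evolution is exactly Jukes–Cantor and expected NG86 Ks equals
  the target; arbitrary codons would mix in twofold-degenerate sites whose
  two-state process violates the JC correction and would bias calibration
  checks. Targets beyond Ks = 3 are refused (saturation).
* Same seed ⇒ byte-identical outputs, including emitted files.

**What passing the synthetic benchmarks does not show.** Real genomes have
tandem arrays, segmental duplications, gene-family hits between different
ancestral loci, assembly and annotation error, non-Gaussian and
non-independent Ks noise, and rate variation *within* lineages. The
generator emulates none of these; noise hits are uniform random pairs
only. Recovery results certify the internal consistency of the pipeline
under its own model assumptions — retention within ±2 points, lineage-rate
excess within ±0.02, ortholog labels ≥95% correct — not performance on any
real assembly.

## Numerical choices

* Gaussian and geometric fits use `scipy.optimize.curve_fit` with bounded
  parameters; a singular or non-convergent peak fit raises an error
  carrying the optimizer diagnostics rather than returning garbage.
* Degenerate inputs: zero-variance Ks input is an error; a single distinct
  run-length bin leaves the regression undefined (MLE still reported);
  fewer than 30 removal events or 100 Ks values warn but proceed.
* Median Ks of a block ignores `nan` anchors; an all-`nan` block has
  `nan` median and cannot take part in Ks tie-breaks (error).
* All orderings (chromosome names, species, block IDs) are sorted or
  fixed by input order and recorded in file headers; reruns on identical
  inputs are checksum-identical (asserted via the pipeline manifest).

## Problem sizes used by the benchmarks

Worked numbers run on their published inputs directly. Recovery benchmarks
use: 2,500 removal events per geometric parameter; 10,000 Ks draws for
peak recovery; 100 random ≤15-hit instances for chaining optimality; 200
CDS pairs × 300 codons for NG86 recovery; and the full default simulation
(2,800 ancestral genes, 4 genomes) for end-to-end recovery. These sizes
put binomial counting noise well inside each stated tolerance band.
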