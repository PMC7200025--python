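# Methods

## Differential expression and regulon calling

Inputs are already-normalized RPKM tables with paired replicates (wild type
and perturbed strain grown and sequenced side by side). For a contrast with
replicate pairs i = 1..n, per gene:

- per-pair log ratio `d_i = log2((mut_i + c) / (wt_i + c))` with
  pseudocount c = 1 by default (tolerates zeros; the statistic is then a
  log-scale difference matching the reported log2FC);
- `log2FC = mean(d_i)`;
- two-sided paired t-test on the `d_i` (df = n − 1). The study design has
  n = 2, so df = 1 is supported deliberately; nothing requires n ≥ 3.

Degenerate cases use the limit behaviour of the t statistic: all `d_i`
equal and nonzero → p = 0; all zero → p = 1. This keeps toy fixtures and
noiseless simulations well-defined.

A `ThresholdPolicy` turns statistics into membership. Two presets reflect
the two perturbation designs:

| parameter | depletion | deletion | note |
|---|---|---|---|
| min |log2FC| | 1.3 | 0.5 | inclusive (≥) |
| max p | 0.05 | 0.25 | inclusive (≤); read as "p at most" |
| min RPKM | 25 | 25 | strict (>), on the max across the contrast's samples |
| operon augmentation | on | off | co-operonic genes join with tag `operon` |

Using the maximum RPKM across all samples of the contrast means a gene
silenced only in the mutant is not discarded as low-abundance. Operon
augmentation is a closure (idempotent; the augmented set contains the
differential core). For the flow analysis, deletion-mode nodes additionally
drop the p filter ("flux regulons"): weak-effect knockouts transmit real
signal that a stringent p cutoff at df = 1 would discard, so flux regulons
are always supersets of the strict regulons.

## Binding sites and the direct regulon

Peaks are consumed as called (e.g. MACS2-style tables); retention requires
fold enrichment strictly > 2 and q ≤ 0.05. Assignment is by summit, not
interval, which avoids double counting wide peaks:

- summit inside a gene's 1-based closed [start, end] → `in_gene`;
- summit in an intergenic interval → `upstream` evidence for each flanking
  gene whose 5′ end faces the interval: the right neighbour if it is on
  '+', the left neighbour if it is on '−'. Divergent promoters therefore
  receive the peak on both sides; convergent gene pairs receive nothing.
  The upstream region is the whole intergenic interval by default; an
  optional `upstream_cap` bounds the summit-to-start distance, since no
  fixed window size is imposed;
- any gene with direct evidence shares `operon` evidence with its
  co-operonic partners (the partner carrying the direct evidence is named).

The direct regulon is the intersection of the sink's total regulon (the
union of the regulons of the sink-adjacent depletion nodes) with the bound
gene set; per-gene provenance records whether binding was direct or
operon-mediated. The reference set D used by the flow step is this direct
regulon, passed explicitly rather than hard-coded, so variants of the
intersection (with or without augmentation) can serve as the denominator.

The consensus scanner matches two exact half-sites separated by a
fixed-length free spacer (default `TTAA-N7-TTAAC`). `N` in the subject
sequence matches only the spacer, never a half-site base; minus-strand hits
are reported in forward coordinates; overlapping hits are all reported.

## Flow quantification

With D normalized to 100 %: `input(X) = 100·|R_X ∩ D|/|D|`,
`flux(X→Y) = 100·|R_X ∩ R_Y ∩ D|/|D|`,
`miss(Y) = 100·|(R_Y ∩ D) \ ⋃_pred R_X|/|D|` (undefined for sources).
Percentages count genes, so every value is a multiple of 100/|D| and the
gene lists behind each number are kept for audit. Because one gene can sit
in several predecessors' regulons, per-edge fluxes into a node may sum past
its input; equality holds exactly when predecessor regulons are disjoint on
D. Declared hidden intermediates (regulator known to exist, regulon not
measurable) get the set-algebra regulon
(⋃ predecessors' regulons) ∩ (⋃ successors' regulons), resolved in reverse
topological order. `infer_hidden_inputs` attaches a `missing_<node>` input
wherever miss exceeds a threshold (default 0), mirroring how unidentified
kinases are postulated from unexplained overlap.

The overlap report between two regulons defaults to the first (subject)
regulon as denominator — the natural reading of "A shows x % overlap with
B" — with `second` and `union` available.

## Synthetic cascade generator

The generator is the package's stand-in for the study's (undeposited) raw
data and defines the conditions under which the pipeline is validated.
Defaults: 3,500 genes, a 90-gene direct regulon, the
DivJ/PleC → DivK → DivL → CckA → ChpT → CtrA topology, two replicates,
weak-effect deletions upstream (effect scale 0.35) and strong-effect
depletions downstream (log2 effects ~N(2.5, 0.7), signed, direction fixed
per gene), log-normal baselines (log2 RPKM ~N(7, 1.5)), and a leak
structure representative of the study's finding (a dominant unexplained
input at DivL, a modest one at ChpT, a trace at DivK).

Membership is drawn **backward** from the sink. Every gene of D is at the
sink; at each node Y, a gene entered exogenously with probability
`node_exogenous_fraction[Y]`, otherwise it was carried across each
predecessor edge X→Y independently with probability
`edge_transmission[(X,Y)]`. A forward thinning model cannot express the
quantity the analysis estimates — genes lost before the sink are simply not
in D, so every single-predecessor edge would carry 100 % of the realized
sink set — whereas the backward draw makes the recovered flux on an edge a
binomial count over |D| with success probability equal to the planted
transmission, which is exactly what parameter-recovery tests need. Genes at
Y carried by no predecessor constitute Y's missing input, so the expected
miss(Y) is `e_Y + (1 − e_Y)·∏_edges(1 − t)`.

Each node's measured regulon additionally receives off-pathway targets
(2 × its sink-reaching set by default), sampled disjointly from D and from
every ChIP-bound gene so that the noiseless pipeline recovers planted sets
exactly. Expression is simulated at the gene level — the pipeline consumes
normalized tables, so read-level simulation would add no test power.
Replicate noise is log2-scale Gaussian, sd 0.1 by default: with two
replicates the paired t-test has one degree of freedom (critical |t| = 12.7
at p = 0.05), so the two-replicate design is only a workable significance
filter when replicate variance is small against ~2.5-log2 effects; 0.1 is
also a realistic spread for well-expressed genes.

The default genome is one contig of 900-bp genes with 300-bp gaps on
alternating strands. Every even/odd pair shares a divergent upstream gap,
so a planted peak also hits the divergent partner — deliberately producing
bound-but-unregulated genes, as real ChIP data contains. A passing peak is
planted upstream of every direct-regulon gene; decoy peaks (half failing
the filters, some genic) are added elsewhere. Operons are random runs of
2–4 adjacent genes covering ~35 % of the genome — a geometric
simplification (real operons are same-strand); they exercise augmentation
and operon-mediated binding, which is why exact-recovery checks run with
operons disabled. What the generator does **not** emulate: count-level
dispersion (negative binomial), batch effects, peak-width variation,
cross-contrast correlation of noise. Passing tests therefore demonstrate
correctness of the algebra and calling logic under the stated statistical
structure, not robustness to every artefact of real sequencing data.

## Protein stability

Translation-shutoff series are per-biomass signals (OD-normalized). Growth
after the shutoff dilutes a stable protein, so correction multiplies the
signal by the biomass ratio OD(t)/OD(0) — the unique multiplicative
correction under which a stable protein appears constant. The corrected
series is fitted to A·e^(−kt), by default as a linear regression of
ln(signal) on t (the standard procedure for blot quantification), with a
direct nonlinear mode for data near zero. A negative fitted k (signal
rising) is clamped to 0 with a warning; k below 1e−12 min⁻¹ reports an
infinite half-life. `percent_remaining` evaluates at measured timepoints
only unless interpolation is requested explicitly; the "decrease over 7 h"
readout is taken at the 7-h timepoint rather than averaged over late
points.

## Problem sizes and determinism

Tests and the acceptance script run the full pipeline at 600–5,000 genes
and |D| of 50–500, with 20-seed recovery loops — sizes at which every
quantity is stable (binomial three-sigma at |D| = 500 is ~6.7 points at
p = 0.5) and a complete run takes seconds. All randomness flows through
`numpy.random.default_rng(seed)` with integer-indexed gene identities, so
identical seeds reproduce byte-identical output files across platforms.
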