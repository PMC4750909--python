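# Methods

## Scope and data model

The package analyses specimen-controlled COI metabarcoding experiments on
aquatic oligochaete communities. Each mixed sample is characterized twice:
by per-specimen Sanger sequences (the reference composition) and by
paired-end amplicon sequencing of the pooled specimens, PCR-amplified in
duplicate. Because the ~658 bp barcode is longer than twice the 251 bp read
length, mates do not overlap and are analysed separately, yielding four
read datasets per sample: {LCO end, HCO end} x {PCR replicate 1, 2}. The
central in-memory object is the community table, a pandas DataFrame with
one row per (sample, OTU) holding specimen counts, the four read counts,
their arithmetic mean, optional corrected counts, and per-sample
percentages on each basis.

## Read filtering

A pair is retained when both mates have arithmetic mean Phred quality >= 30
and at most one base below Q30. "Average quality" is the mean of the Phred
scores themselves, not of error probabilities; both thresholds are
parameters of `FilterParams`. Orientation is then resolved by primer
content: the HCO2198 primer is searched in R1 and, if found, LCO1490 must
be found in R2; otherwise LCO1490 is searched in R1 and HCO2198 must be in
R2. Pairs with zero or one primer are discarded. Primer search allows a
bounded Levenshtein distance (default 1 edit, substitutions and indels,
via edlib) and is restricted to a prefix window of len(primer) + max_edits
bases — amplicon reads begin at a primer, and the window forestalls
spurious internal matches; a full-read scan and an IUPAC-aware mode are
available by flag. Reverse-complement primer search is off by default
(orientation is already handled by the R1/R2 pairing rule above) but can
be enabled for chemistries that deliver reads in mixed strand sense. The
primer and any bases preceding it are trimmed so primer mismatches cannot
inflate downstream distances.

Accounting is monotone by construction: total pairs >= quality-pass >=
shared >= primer-bearing. Quality passing is tallied at pair level (both
mates), which makes it coincide with the shared tally; per-mate tallies
are reported alongside for comparability with per-read summaries.

## Distances, trees, delineation

Distances use Kimura's two-parameter model, d = −½·ln((1−2P−Q)·√(1−2Q))
with P and Q the transition and transversion fractions over comparable
sites; sites with non-ACGT characters in either sequence are excluded
pairwise (the default of the common distance software; complete deletion
can be had by pre-masking). Saturated pairs (log argument <= 0) raise a
distinct error by default or return +inf on request; neighbor joining
refuses infinite inputs rather than silently distorting trees.

Neighbor joining is the classical Q-criterion algorithm with the standard
branch-length formulas; ties in the Q matrix break toward the lowest index
pair, making output deterministic in input order. On additive matrices the
returned tree reproduces the input distances exactly (verified in tests up
to 8 taxa, and against an exhaustive topology enumeration at 5 taxa).

OTU delineation at the species-level threshold of 10% COI divergence is
operationalized as: a query joins the nearest reference OTU when its K2P
distance is strictly < 0.10; queries matching no reference are clustered
among themselves by single linkage at the same threshold, each cluster
becoming a new OTU labeled "(1)", "(2)", ... in first-appearance order.
Boundary behavior (strict <) and the single-linkage choice are documented
constants: practitioners traditionally delineate by inspecting NJ trees,
and single linkage at the same cutoff is the reproducible analogue of that
manual procedure, not a claim about any particular historical analysis.
The LCO and HCO ends are assigned independently against end-specific
reference sub-sequences (forward prefix and reverse-complement prefix of
the barcode, respectively); an OTU counts as detected if found at either
end, and per-end assignments are reconciled by OTU label.

## Correction factors

Amplification efficiency varies by orders of magnitude among oligochaete
COI templates, and the resulting abundance skews are consistent in
direction and magnitude across samples. The package therefore fits one
multiplicative factor per OTU: for every candidate on the grid
{0.10, 0.15, …, 1.00} ∪ {1, 2, …, 200} (deduplicated at 1), the focal
OTU's mean read count is scaled in each sample — other OTUs left raw — the
proportion recomputed, and the mean absolute difference in percentage
points from the specimen-based proportion taken across samples; the
minimizing candidate is selected, ties broken toward 1 (no correction),
then toward the smaller value. The absolute-difference objective is the
default because reported minima are naturally read in percentage points; a
relative-error mode is available. Samples where the focal OTU is absent
from both bases carry no signal and are excluded; by default an OTU must
occur in at least four samples to be eligible (configurable).

For final reporting all selected factors are applied jointly and the
percentages renormalized together — deliberately different from the
one-at-a-time convention used during fitting; both tables are retained so
the discrepancy is visible. Two identifiability caveats: factors recover
*relative* bias only (proportions are invariant under a common rescaling
of all efficiencies), and a factor fitted on few samples absorbs sampling
noise; the per-OTU objective curve is exported for inspection.

## The IOBS index

IOBS = 10·S/T, with S the number of taxa present and T the percentage of
the dominant tubificid group (with vs without hair setae). Classes: >= 6
very good, [3, 6) good, [2, 3) medium, [1, 2) poor, < 1 bad (closed lower
bounds). On read-based bases, "present" means mean (or corrected) reads
> 0 with no minimum-read threshold, since legitimately detected OTUs can
sit at trace abundance; T is always computed on the same basis as S.
Samples without tubificids yield an explicit "undefined" verdict rather
than an infinite index. Display values are rounded half-up to two
decimals; the unrounded value is retained.

## Comparison layer

The detection matrix classifies each (sample, OTU) cell as detected on
both bases, one, or neither. Skew records report, per OTU and sample
where both percentages are positive, max(Sanger%/NGS%, NGS%/Sanger%); an
OTU is flagged when this ratio exceeds 2 in at least two samples, and its
direction is the sign of the mean log-ratio of NGS over Sanger
proportions. Cells detected on a single basis would have an infinite
ratio; they are listed separately and excluded from the flag rule.
Correlations are Pearson r with the two-sided p-value from the t
distribution on n−2 degrees of freedom plus the least-squares line
(scipy); pooled correlations concatenate every (sample, OTU) cell where
either percentage is positive, each table row used once. P-values are
descriptive; no multiple-testing correction is applied.

## Synthetic data generator

The generator emulates the statistical structure the analysis assumes.
Reference OTUs descend from a common random ancestor, each mutated at
~6-8% of sites (substitutions uniform over the three alternatives, giving
a 1:2 transition:transversion mix), and the draw is repeated with a raised
rate until every pairwise K2P distance exceeds the configured floor —
default 0.12, deliberately above the 0.10 delineation threshold so
clustering on synthetic data is unambiguous; intra-OTU specimen variation
is ~1% (ceiling 5%), keeping the intra/inter separation clean. Ecological
groups are drawn with tubificids in the majority, as in organically loaded
fine sediments. Default community sizes (43, 42, 28, 78, 32, 107
specimens over six samples) and the 658 bp barcode length mirror the
experimental design the package targets.

Read counts follow a multinomial per dataset with probabilities
proportional to specimen count x per-OTU amplification efficiency;
efficiencies are log10-uniform over ±2.2 decades by default, spanning the
skews observed empirically (correction factors from ~0.19 to ~149).
Efficiency is a single constant per OTU across samples — the model behind
fitting one factor per OTU — and replicate-level overdispersion is an
optional Dirichlet perturbation with one concentration knob. Biomass
variation among pooled fragments is not modeled separately: all bias is
attributed to amplification efficiency, consistent with pooling protocols
that equalize tissue quantity.

FASTQ emission works at fragment level: each sequenced fragment yields an
R1/R2 pair whose LCO/HCO orientation is random, so one pair contributes
one read to each end's dataset. Per-dataset counts drawn independently
(the table-level model above) cannot be realized exactly in paired FASTQ —
the two ends of a replicate share fragments — so the generator exposes
both: `simulate_read_counts` for table-level analyses and
`simulate_fragment_counts` + `emit_fastq` for FASTQ round trips, whose
per-end counts equal the fragment counts exactly when error is zero.
Substitution errors are i.i.d. per base; qualities are normal, rounded,
clipped to [2, 41]. Not modeled: indels, chimeras, quality-by-cycle decay,
length variation. Passing tests on these fixtures therefore demonstrate
correctness of the pipeline's logic under its own assumptions, not
robustness to artifacts real amplicon data can contain (chimeras,
pseudogenes, cross-contamination).

All randomness flows through explicit integer seeds; identical
configurations produce byte-identical fixtures.

## Problem sizes and numerical choices

The test suite runs the full pipeline on four-sample studies of 8-10 OTUs,
300-400 bp references and a few hundred read pairs per library — small
enough to verify exact round trips while exercising every stage — and
validates the correction-factor machinery on deep (10^5 reads/dataset)
dispersion-free simulations, where fitted factors land within one grid
step of the inverse simulated efficiency in >= 90% of seeded runs.
Floating-point comparisons in tree reconstruction use 1e-9 absolute
tolerance; oracle equivalence checks (edit distance, grid search, Pearson)
are exact or at 1e-12.

## Known limitations

- Equal-length, position-homologous sequences are assumed throughout; no
  alignment is performed, and real data must be pre-trimmed to a common
  end length.
- Delineation quality degrades when intra-OTU variation approaches the
  10% threshold; the single-linkage rule can chain in that regime.
- Correction factors are empirical, relative, and community-dependent;
  transferring them to other communities or primer sets requires
  revalidation.
- Bootstrap support, chimera detection and external database queries are
  out of scope.
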