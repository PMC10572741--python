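# Methods

This note documents the models, numerical choices and limitations behind
`indigoferm`. It describes what the code computes and why; every number
quoted here is produced by the package's own tests or example scripts.

## The analysis setting

The package targets time-series studies of indigo-reduction fermentation:
a taxon-by-sample 16S count table with per-sample metadata (fermentation
day, batch, pH, ORP in mV, dyeing intensity), predicted gene-family
("KEGG-ortholog-style") abundance tables in the PICRUSt2 legacy dialect,
taxon-stratified contribution tables, a function→subpathway hierarchy,
genome annotations as GFF3, and per-pixel CIE L\*a\*b\* colorimetry. The
biological question throughout is which community members and functions
track the vat's capacity to reduce indigo, as measured by dyeing
intensity under strongly negative ORP.

## Dyeing intensity

The phenotype is the mean over pixels of √(L\*² + a\*² + b\*²), scaled
×10. Two variants are exposed deliberately. The literal formula, the
default, produces magnitudes of hundreds for any visible cloth, whereas
the phenotype scale of such studies spans roughly 0.5–2.5; those two
facts are only compatible if the pixel measurements were first
normalized or differenced against a reference. How exactly the cloth
images were reduced to small L\*a\*b\* magnitudes (masking?
blank-cloth subtraction?) is not stated in the literature this package
follows, so a reference-difference variant
(|value − reference| × 10) is provided alongside the literal one rather
than guessing intent and silently "fixing" the formula. RGB→Lab
conversion and image segmentation are out of scope; input is Lab.

## Nernst pH adjustment and mediator feasibility

For a couple transferring *m* protons and *n* electrons,

E°′(pH₂) = E°′(pH₁) − 2.303·m·R·T/(n·F) · (pH₂ − pH₁),

with R = 8.315 J·K⁻¹·mol⁻¹, F = 96486 J·mol⁻¹·V⁻¹ and T defaulting to
298 K, giving a unit slope of ≈59.14 mV per pH unit. The relation is
linear in pH, strictly decreasing for m, n > 0, the identity for m = 0,
and composes (pH₁→pH₂→pH₃ equals pH₁→pH₃ to 1e−9 mV); all four
properties are asserted in the test suite. A mediator is classified
feasible for indigo reduction when its adjusted midpoint potential is at
or below −600 mV; the boundary counts as feasible, a documented and
configurable convention. Reference midpoint potentials for the usual
candidate couples (NADH, FMN, riboflavin, acetaldehyde, anthraquinone)
vary across compilations and are therefore shipped as an *empty*
editable template, not as data: the calculation is only as good as the
base potentials the user fills in. Activity- and concentration-dependent
corrections are out of scope; this is midpoint-potential arithmetic
only.

## Community processing

Relative abundance is per-sample closure; the display/analysis filter
keeps taxa reaching 2 % in at least one sample (inclusive boundary) and
folds the rest into an `Other` row so columns still sum to 1.
Rarefaction is a single seeded multivariate-hypergeometric draw per
sample — mirroring a single-depth diversity analysis — with a
repeat-and-average variant for stability checks; subsampling without
replacement guarantees rarefied totals equal the depth and can never
increase observed features. Shannon diversity uses log base 2 (bits),
the QIIME 2 convention; the base is a parameter. Beta diversity,
ordination and biomarker discovery are intentionally absent (standard
tools exist).

## Function screen

**Subpathway profiles.** Per sample, function abundance is summed within
each subpathway and expressed as a percentage of the sample total;
unmapped functions are binned as `Unclassified`, so columns sum to 100.

**Day-pair ratios.** Replicates of a day are averaged first (the
analyses this supports report day-level values; per-replicate ratios are
a switchable alternative). For each (numerator day, denominator day)
pair the ratio of subpathway percentages is formed; a subpathway is
selected when any pair's ratio is ≥ 1.05 and highlighted when the mean
ratio over pairs exceeds 1.4. Ratios with a zero denominator are
undefined: they are reported as NaN, excluded from selection, and
logged — never fabricated. Selection is monotone in the threshold by
construction.

**Stratified contributions.** A taxon's contribution to a function set
in a sample is the sum of `CountContributedByOTU` over its OTUs and the
set, normalized over taxa to percentages (summing to 100); rows produced
by this package satisfy `CountContributedByOTU = GeneCountPerGenome ×
OTUAbundanceInSample` exactly, while externally produced files violating
it beyond 1e−6 relative tolerance are kept with a warning, since other
pipelines round.

**CLR correlation screen.** Predicted abundance tables are
compositional, so correlation is computed on centered log-ratio values:
per sample, close to proportions, replace zeros, take natural logs,
subtract the sample mean log. Zero replacement is multiplicative, with
δ = 0.5 × the smallest nonzero proportion of that sample and the nonzero
parts shrunk so the composition still closes; the strategy is pluggable
because no single convention is canonical. The correlation of each
function's CLR series with the dyeing-intensity series is Pearson by
default (Spearman by flag); selection is one-sided at r ≥ 0.9 (fast-drop
design) or 0.77 (slow-drop design), thresholds being parameters, never
hard-coded. Zero-variance functions have undefined correlation and are
never selected. No multiple-testing correction is applied by default —
matching the screen this package operationalizes — and a
Benjamini–Hochberg option exists for users who want error control.

## Co-occurrence networks

Taxa are aggregated to genus (last `g__` rank of the lineage, else the
final token) and ordered by day; replicates are kept as separate ordered
points by default, which gives rank correlation more points, with a
day-averaging switch. Spearman's rs is Pearson on average ranks, which
remains correct under ties. Fermentation series are short (8–15 points)
and the t-approximation to the Spearman null is poor there, so for
n ≤ 8 the two-sided p-value is computed exactly by enumerating all n!
rank permutations (vectorized; 8! = 40 320 per pair is affordable),
conditioning on both observed tie patterns; beyond n = 8 the
t-approximation is used. Edges require |rs| > 0.6 **and** p < 0.05 —
note that at n = 4 even rs = 1 has exact p = 2/24 ≈ 0.083, so tiny
designs yield empty networks, a feature of honest exact inference, not a
bug. Edges are signed by rs; node weight is accumulated relative
abundance over the period. Early/late sub-communities are recovered as
connected components of the whole-period network, since no principled
period-splitting rule is available; this operationalization is a design
choice. No correction over the edge family by default (optional BH).

## EET gene scan

Matching uses an editable pattern catalog of the eleven canonical
flavin-EET labels in three role groups (FAD transport, electron
transfer, DMK synthesis). Name matches (case-insensitive regex on the
`gene` attribute) beat product matches; among equal kinds the longer
pattern wins; ties are logged and broken by catalog order. The ndh-2
patterns require type-II/ndh context precisely so that complex-I-style
"NADH dehydrogenase" annotations do not match. "Similar locations" are
defined by gene ordinals, not base pairs: single-linkage clusters of
matched features on one contig with ordinal gap ≤ 10 (configurable). A
role group is *clustered* when all its matched features share one
cluster, *dispersed* when every pairwise gap exceeds the bound, *split*
otherwise, *absent* when nothing matched. The pattern set is a
reconstruction — annotation pipelines vary — which is exactly why it is
data, not code. No homology search is performed; a genome annotated with
different vocabulary needs a locally adapted catalog.

## Synthetic data generator

The generator exists to give every downstream stage a ground-truth test
bed with the structure the two study designs imply. It is explicit about
what it emulates and what it does not.

**Latent dynamics.** Guilds of taxa follow logistic trajectories between
a baseline and an asymptote fraction (decliners decay, early/late risers
rise at different midpoints, stable guilds are constant); members split
the guild fraction equally, and the residual compositional mass is
spread over a configurable number of rare background taxa. Trajectories
are monotone by construction: the non-monotone tails real communities
show at very long times (a dominant riser receding after months) are
outside the generator's vocabulary, and the fast-drop dyeing intensity
consequently plateaus rather than collapsing at the final day.

**Sampling.** Replicates of a day share the latent state and differ only
by noise: a Dirichlet draw with concentration `noise_dispersion ×
composition` followed by a multinomial at fixed depth (default 20 000
reads, the order of merged reads per sample such studies report). The
dispersion default of 2000 makes within-day replicate CV ≈ 3 % at a 30 %
taxon — duplicate aliquots of one stirred vat, i.e. near-technical
replicates. True replicate variability of these ferments is not well
characterized; this default is a stated guess and a single knob.

**Scenarios.** `fast_drop` (big batch; default days 3, 10, 27, 212 × 2
replicates) holds ORP at or below −600 mV throughout, and its default
guilds encode a community already converged at first sampling: early and
late reducer guilds carry the visible mass, while aerobes and
Actinomycetota linger only below the 2 % prevalence threshold. That is
what makes the all-positive co-occurrence network reproducible: every
genus that survives the display filter co-rises. `slow_drop` (small
batch; default days 2, 5, 6, 7, 14, 29, 96, 200) starts above −400 mV,
crosses −598 mV around day 5, and its aerobic decliner guild is large
and visible, guaranteeing negative decliner×riser edges.

**Phenotype.** Dyeing intensity is a Hill function of the summed
reducer-guild fraction f — floor + I_max · f^h/(K^h + f^h) with defaults
I_max = 2.8, K = 0.55, h = 3, floor 0.45 — gated to the floor while ORP
is above −550 mV, plus Gaussian noise (sd 0.08). The defaults were
chosen so intensities span roughly 0.5–2.5 across both scenarios, the
range such phenotype series occupy. The law is an artifact choice: no
generative model for dyeing intensity exists in the literature, and
every parameter is config.

**Genome content and ground truth.** Signal functions get
`background + 5` copies in reducer-guild taxa; background functions are
either uniform-copy core functions (one or two copies everywhere) or
accessory functions enriched in five non-reducer taxa. This encodes the
dichotomy the screen is meant to detect — a "background" function
enriched specifically in reducer taxa would be indistinguishable from
signal by construction, so none are planted. Stratified tables are the
exact product of counts and genome copies; the function table is their
aggregation. The truth record lists planted functions, reducer taxa,
guild membership and latent compositions.

**What passing tests show.** On these defaults the screen recovers 100 %
of planted signal functions with 0 % background selections, and the
network signs separate the scenarios cleanly. Real data are harsher:
replicate noise is larger, trajectories are not monotone, genome content
is not block-structured, and predicted function tables carry PICRUSt2's
own error. Passing the recovery tests demonstrates the *pipeline's*
correctness and the detectability of a planted effect under the stated
conditions — not that real screens at r ≥ 0.9 enjoy these error rates.

**Determinism.** One global seed drives everything; per-stage generators
are spawned from it deterministically (`SeedSequence.spawn`), so an
identical config yields a bit-identical dataset, including the
stratified table.

## Numerical conventions

* GFF3 coordinates are 1-based inclusive everywhere; interval math never
  mixes conventions.
* Writers emit sorted rows/columns so outputs are diffable; readers name
  the first offending row, column or line.
* Tolerances: CLR columns sum to 0 within 1e−9; relative-abundance
  columns to 1 within 1e−9; contribution percentages to 100 within
  1e−6; stratified product invariant 1e−6 relative; Nernst composition
  1e−9 mV.
* Exact Spearman p-values compare |rs| with a 1e−12 slack to absorb
  floating-point ranks.
* All-zero samples, empty pixel lists, zero-variance series and zero
  denominators are errors or NaN-with-warning, never silently imputed.

## Problem sizes

The test suite and the acceptance script run the generator at its
default sizes (8 and 15–16 samples, ~90 taxa, 150 functions) and
enumerate permutations only for n ≤ 8; both complete in seconds on one
CPU. These sizes were chosen to mirror the study designs the generator
emulates, and suffice because every quantity tested is either exact
arithmetic or a large planted effect.

## Known limitations

* The dyeing-intensity scale discrepancy (literal formula vs phenotype
  range) is surfaced, not resolved; resolving it needs the original
  image-processing details.
* Mediator feasibility is only as good as user-supplied base potentials;
  printed mediator values in the literature cannot be reproduced from
  common pH-7 tabulations with integer m/n, so they are documented but
  not asserted.
* The EET catalog matches annotation vocabulary, not sequence; absence
  of a match is absence of an annotation, not of a gene.
* The generator does not simulate reads, chimeras, primer bias, or
  compositional artifacts of upstream denoising; it starts at the count
  table.
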