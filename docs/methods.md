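# Methods

## Scope and model

`asconsv` analyses strand-specific paired-end RNA-seq from two closely
related budding yeasts (labelled Sc and Sp) grown in three conditions —
mid-log (ML), early stationary phase (ES), and heat shock (HS) — to ask
how conserved antisense transcription is, and whether sense-antisense
pairs with inverse expression under stress are preserved between the
species. The unit of analysis is the *transcript unit* called from
per-base read depth on one strand, not the annotated gene model;
annotation enters only to classify units and to join homologs.

## Strand assignment and coverage

Fragments (properly paired templates, leftmost to rightmost aligned base)
carry the transcribed strand under a selectable dialect. The default
`dutp` dialect takes the strand of mate 2: dUTP second-strand marking
destroys the second cDNA strand, so mate 1 aligns antisense to the
transcript. `reverse` is an alias; `forward` takes mate 1's strand, since
aligner/protocol combinations differ in which mate is flagged first.
Uniqueness filtering keeps templates with alignment-multiplicity tag
(`NH`) equal to 1 when the tag is present, otherwise mapping quality ≥ 10;
the mechanism aligners use to mark multi-mappers varies, and this pair of
rules covers the common encodings. Depth is per *template*, not per mate:
two mates of one fragment are one RNA molecule, and counting them twice
would double-weight fragment interiors.

Coordinates are 0-based half-open everywhere in memory; GFF3 on disk is
1-based inclusive, bedGraph 0-based half-open. bedGraph round-trips are
bit-exact on depth; overlapping intervals within one bedGraph are refused
because their depth is ambiguous.

## Transcript calling

Per chromosome and strand: (i) seed at the unmasked maximum of depth,
requiring depth ≥ `min_seed_depth` (default 5); (ii) grow one base at a
time, alternating left/right (left attempted first), recomputing the mean
after each accepted step; a direction stops when the unit's mean depth is
≥ `edge_ratio` (default 4) times the depth of the next unmasked base
beyond that boundary; (iii) each stopped boundary is extended once to the
full span of every same-strand fragment containing the stop position;
(iv) the unit is masked and the cycle repeats.

Numerical/tie-break choices, fixed for determinism:

* equal maximal depths seed at the leftmost position; chromosomes are
  processed in lexicographic order, '+' before '−';
* out-of-bounds or masked neighbours count as depth 0, which always
  satisfies the stop rule;
* step (iii) is a single pass per end (no cascading re-extension) and is
  clipped so it never enters previously masked bases — without clipping
  the non-overlap guarantee for called units would not hold;
* masking is strand-specific: a '+' unit never blocks a '−' unit, because
  sense/antisense overlap is the object of study;
* units shorter than `min_length` (default 1, i.e. no minimum) are masked
  but not reported, so a spike cannot re-seed forever.

Raising `min_seed_depth` only truncates the greedy call sequence — the
trajectory does not otherwise depend on the threshold — so the called set
is monotone in it; the test suite asserts this, and checks the caller
against a deliberately naive, literal re-implementation on random tracks.

## Quantification, classification, pairing

BPKM = B / ((L/1000)·(T/10⁶)) with B the summed same-strand depth over
the unit, L its length, T the sample's total mapped bases. No further
normalisation is applied. Classification: same-orientation overlap
(≥ 1 base) with a verified or uncharacterized ORF → ORF-T (the
largest-overlap ORF id is recorded); same-orientation overlap only with
other/dubious ORFs → "other"; anything else → ncRNA. Opposite-strand
ORF-T/ncRNA duos overlapping ≥ 1 base become sense-antisense pairs; an
ncRNA spanning several ORF-Ts yields one pair each, the largest overlap
flagged primary. "Antisense arising from an intron" is operationalised as
the antisense unit's strand-aware 5′ start lying inside an intron of the
paired ORF.

The working set keeps pairs whose members have BPKM above a floor
(default 0, i.e. strictly positive — the floor is configurable because
"expressed" is not sharply defined) in all six samples, with the sense
ORF joined one-to-one across species by the homology map. Units are
called per species from coverage merged over the three conditions, then
quantified per condition, so a unit expressed only under stress still
exists before the expressed-in-all filter is applied.

## Metagene profile

Each profiled gene maps to 400 points: 100 upstream bases (per-base), 200
equal gene-body intervals (per-interval mean of per-base depth — the only
statistic consistent with a density), 100 downstream bases. Minus-strand
genes are flipped so index 0 is always 5′. Per-gene values are divided by
the mean of the gene's sense and antisense BPKM, making the profile
invariant to overall depth scaling; genes with a zero normaliser or a
body under 200 bases are excluded and counted. TSS/TTS are taken as the
called ORF-T unit boundaries. Flanks beyond chromosome ends are
zero-padded; overlapping neighbours are not masked.

## Comparative statistics

* Expression divergence: |log₂ e_Sc − log₂ e_Sp| on positive,
  pre-filtered values (base 2 chosen so one unit is one doubling).
* Correlation matrices: Pearson on log₁₀ BPKM (pseudocount configurable,
  default 0 — correlation is base-invariant) across the six samples, for
  sense and antisense members separately.
* Conservation score: S = min(C_Sc, C_Sp)/mean(C_Sc, C_Sp), C_i = O_i/L_i,
  S = 0 when both overlaps are absent. Symmetric in species, 1 iff the
  fractions agree and are positive.
* Inverse expression: direction requires the two fold changes on opposite
  sides of 1; significance applies the fold bound (default 1.5) to *both*
  members — the symmetric reading of "at least a 1.5-fold change" — with
  an `either`-member mode available. Counts at a higher threshold are
  provably a subset of counts at a lower one.
* Enrichment: rows stringent (S > 0.8) vs background (S < 0.5); columns,
  among pairs significantly inverse in the given condition in at least
  one species, inverse in both species ("conserved") vs in exactly one.
  Fisher's exact test, two-sided by default: in the reconstructed ES
  table the stringent set's conserved proportion is *below* background
  while in HS it is above, so no single one-sided alternative fits both;
  a one-sided option exists.
* Proportion test: classical two-sample z-test with pooled variance and
  continuity correction, one-sided (first proportion greater).
* Distribution shift: one-sided Wilcoxon rank-sum (condition > ML),
  exact for small tie-free samples; ranks are computed on raw positive
  values since the log transform preserves them.

## Synthetic data

The generator draws, per species, `n_genes` genes (lengths uniform on
600–2000 bp, alternating strands) separated by silent spacers of at least
twice the mean fragment length, so units are separable by construction.
A fraction (default 0.6) of genes receive an antisense unit anchored over
the sense 3′ terminus — matching where antisense initiation is observed —
extending 50–150 bp past the gene end. Overlap geometries split into a
conserved class (shared base fraction 0.35–0.6, jittered ±3% per species;
realised S > 0.9) and a divergent class (one species' fraction 10–30% of
the other's; realised S < 0.5), with the conserved share set by
`conserved_overlap_fraction` (default 0.6).

Log₂ expression is gene-wise Gaussian (sense mean 3.0, antisense 1.5,
SD 1.0 each) built from a latent term shared between species and scaled
to hit the configured cross-species correlations (sense 0.9 > antisense
0.4, reproducing the observed ordering that sense expression diverges
less). Condition effects are multiplicative: non-planted transcripts get
independent log₂ shifts of SD 0.25; planted inverse pairs (fractions
0.15 in ES, 0.25 in HS, drawn as exact-count subsets) get sense ×1/fold
and antisense ×fold exactly (fold default 2.0), in both species. Fragment
counts are Poisson with mean `depth_scale` × expression × length/1 kb
(depth_scale default 50 — deep enough that Poisson noise does not mask
the planted structure); lengths are truncated normal (250 ± 40, clipped
to [30, 2×mean] and to the transcript), positions uniform within the
transcript. Everything is reproducible byte-for-byte from the seed.

What the generator does **not** emulate: sequencing errors and base
content, splicing and introns, overlapping/nested genes, ncRNAs without a
sense partner, chromosome-scale heterogeneity, and non-lognormal
expression. Passing recovery tests therefore demonstrates the pipeline's
correctness on well-separated transcription units with the assumed
moment structure, not performance on real libraries with overlapping
transcription or degradation artefacts.

## Problem sizes and verification

The test suite and acceptance script use 40–200 gene simulations at
depth_scale 50 and 1,000 random depth tracks (length ≤ 200) for the
caller/oracle equivalence; at these sizes the whole suite runs in well
under a minute. Recovery checks assert: ORF-T boundaries within
fragment-length scale (mean + 2 SD) of truth; Spearman ≥ 0.9 between
BPKM and true expression; planted inverse fractions recovered within 3
binomial standard errors; cross-species sense correlation above
antisense; antisense metagene density higher in the 3′ body half than
the 5′ half.

## Known limitations

* The caller is greedy and depth-driven: abutting transcripts without a
  depth trough merge, and isoforms are not resolved.
* With bedGraph-only input there are no fragments for step (iii), and
  coverage ramps at transcript edges may split into small extra units;
  supply alignments (or a `min_length`) when this matters.
* Cross-species matching of ncRNA units uses the sense homolog as proxy
  (an antisense is "shared" when both species' homologous genes carry an
  overlapping antisense unit); no coordinate liftover is attempted.
* The enrichment test conditions on pairs inverse in ≥ 1 species; pairs
  inverse in neither contribute nothing, so small working sets can leave
  empty margins (reported as an informative error, not a p-value).
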