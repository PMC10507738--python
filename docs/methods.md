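# Methods

This note documents the statistical procedures implemented in
`mutotopo`, the defaults and units of every tunable that matters, what
the synthetic-data generator does and does not emulate, and the design
decisions taken where the procedure had genuinely open corners.

## Mutation classification

Mutations are typed from allele lengths: SBS (1↔1), DBS (2↔2, both
positions changed), ID (pure insertion/deletion, stored anchor-free:
a deletion carries the deleted sequence in `ref` with empty `alt`, an
insertion the inserted sequence in `alt`; `pos` is the first deleted
base, respectively the base the insertion precedes). Coordinates are
0-based half-open everywhere inside the package; VCF POS and wig starts
are converted at the read boundary, BED/bedGraph pass through.

* **SBS-96**: the mutated base plus immediate 5′/3′ flanks, reverse
  complemented when the reference base is a purine, giving labels
  `X[R>A]Y` with R ∈ {C,T} — 6 substitution classes × 16 flank pairs.
* **DBS-78**: the doublet and its reverse complement collapse to the
  canonical maximum-pyrimidine member of the 78-channel set.
* **ID-83**: event size (1–5+), base class for 1 bp events (C/T after
  pyrimidine collapse), the homopolymer/repeat unit count of the
  surrounding sequence, and — for deletions with no flanking repeat —
  the longest microhomology between the deleted sequence and its
  flanks. Label families: 24 one-bp, 48 repeat, 11 microhomology.
  The repeat index counts *additional* adjacent copies, capped at 5;
  e.g. deleting one T from a TTTT run is `1:Del:T:3`.

Mutations whose required context contains N or overruns a chromosome
end are excluded (never imputed) and counted per run. A reference
mismatch between catalog and genome is an input error, not an
exclusion. Attributable bases are A/C/G/T only; FASTA ambiguity codes
are stored as N.

Signature attribution is argmax over the per-mutation probability row,
accepted when the winning probability reaches the cutoff (default 0.5),
with ties broken by lexicographically smallest signature name for
determinism. The same ≥ 0.5 argmax rule serves wherever mutations must
be unambiguously attributed; per-signature analyses further require at
least `min_mutations` = 1,000 attributed mutations (the clustering
analysis applies only the probability filter).

## Background simulation

`simulate_catalog` draws, for each real mutation and each replicate, a
new position uniformly from same-chromosome loci whose reference
context reproduces the mutation's channel: the canonical trinucleotide
(32 contexts) for SBSs, the canonical reference doublet (10) for DBSs,
and the ID-83 class of the locus for indels (a vectorized run-length
index answers 1 bp indel classes; longer events use rejection sampling
with a cached exhaustive scan as fallback). The alternate allele is
copied, complemented when the target locus presents the opposite
strand. Consequences: per (sample, chromosome, channel) counts are
conserved *exactly* in every replicate, and the default run produces
100 replicates.

Randomness: one `numpy` Philox-family stream per (seed, replicate), so
replicates are independent, order-insensitive and byte-reproducible.
Sampling is with replacement within a replicate (two simulated
mutations may share a locus; `allow_collisions=False` forbids it);
real positions remain eligible targets. Whole-chromosome burden is the
only resolution implemented — no megabase-window or gene-level modes.

## Strand annotation

**Transcription.** Gene BED6 intervals are merged per strand. A
mutation outside genes is NONTRANSCRIBED; covered by genes on both
strands, EXCLUDED_BIDIRECTIONAL (dropped from strand tests); otherwise
TRANSCRIBED when the strand carrying the mutated pyrimidine is the
gene's template strand, UNTRANSCRIBED when it is the coding strand.
IDs, which lack a canonical pyrimidine, are oriented by the first base
of the inserted/deleted sequence — a package convention chosen for
uniform machinery.

**Replication.** Peak (initiation) and valley (termination) intervals
are reduced to midpoints and must alternate. Between adjacent anchors
the wavelet signal is piecewise monotone, so the slope is taken from
the anchor types rather than per-base differentiation: valley→peak is
+slope = leading on the + strand, peak→valley is −slope = lagging.
Stretches shorter than `min_stretch` = 10,000 bp are dropped;
`term_trim` = 25,000 bp adjacent to each valley midpoint is removed —
by default on both flanks (the last-replicated DNA of both converging
forks), with a `trim_mode` switch to trim only the approaching side,
since the printed procedure is ambiguous about the trim's sidedness.
A mutation's label combines region and pyrimidine strand (pyrimidine
on + in a leading-plus region → LEADING, etc.); outside the map it is
UNASSIGNED. Genic/intergenic strata reuse transcription labels: any
gene hit (including bidirectional exclusions) is genic.

## Asymmetry statistics

Counts per (signature, six-class channel) on two strata for real and
simulated catalogs form a 2×2 table; OR = (real_a/real_b)/(sim_a/sim_b)
with a two-sided Fisher exact p. The simulated cell is the
per-replicate mean rounded to the nearest integer — pooling replicate
sums would inflate the Fisher sample size tenfold-plus and manufacture
significance, so the mean is the default and the sum a config option.
BH correction runs once per analysis family (transcription;
replication; genic/intergenic) across all signatures × channels in the
run. Reported ⇔ q ≤ 0.05 and OR strictly above 1.10 in either
direction. For the asymmetry-corrected genic test, the genic count is
rebuilt as 2·max(transcribed, untranscribed) before testing, removing
strand asymmetry as a confounder of genic-vs-intergenic enrichment.

## Strand-coordinated mutagenesis

Within each sample, substitutions with an attributed signature at
probability ≥ 0.5 are sorted by position; maximal runs sharing the
six-class channel, the pyrimidine reference strand and the signature,
with every consecutive gap < 10,000 bp (strict), become groups;
singletons are discarded. "Same mutational context" is pinned to the
six-class level (config allows SBS-96 strictness). Mutations removed by
the probability filter do not carry distance: gaps are measured between
retained mutations only, which is this package's reading of the
run-merging adjustment. Observed counts per (signature, length) are
z-tested (sd with ddof = 1) against the replicate ensemble, BH-corrected
over all cells, reported at q ≤ 0.05. Zero-variance cells are flagged
degenerate: p = 1 when the observation equals the common simulated
value, else a zero-p sentinel with the flag set — a run length never
seen in any replicate is evidence, not an error, but the flag keeps it
distinguishable.

## Replication timing

Signal segments are sorted by value descending (ties by genomic order)
and filled into ten deciles, each targeting `remaining mass / remaining
deciles` so that every decile is non-empty and holds as close to 10% of
total signal as whole segments allow; segments are atomic. Densities
are counts per attributable base, normalized to the maximum (so
`max(x) = 1`); mutations outside signal coverage are excluded and
counted. The replicate ensemble supplies mean, sd (ddof = 1) and a
normal-approximation 95% CI (mean ± 1.96·sd/√n). Trend: OLS of x on
decile index 1..10; INCREASING/DECREASING require a two-sided slope
p ≤ 0.05 *and* monotone non-strict densities (plateaus allowed —
strict monotonicity would reject genuine saturation), else FLAT.
Cross-cohort summaries are unweighted means of normalized vectors.

## Occupancy and abundance

The window is 2,001 positions: 1,000 bp 5′, the mutation start, 1,000 bp
3′. Averaging is two-round: over mutations within each dataset
(K vectors), then unweighted over datasets and cohorts (M vectors) —
weighting by mutation count is exposed as config but not default, since
the reference procedure averages datasets equally. The same procedure
runs per simulation replicate and is averaged into K_sims/M_sims.
Similarity: Pearson r between K and M over the central ±500 bp
(1,001 points), p from the Fisher z-transform, similar ⇔ r ≥ 0.5 with
BH-adjusted p ≤ 0.05. Offsets within the window are autocorrelated and
are not decorrelated before the test; the r ≥ 0.5 floor guards against
significance from structure alone. Abundance: s = mean signal over
±50 bp (101 positions including offset 0); z-test of s_real against the
replicate ensemble, per-dataset p values combined by Fisher's method
(χ² with 2k df), fold changes averaged, BH across the run's
(signature, feature, cohort) cells, ENRICHED at fold ≥ 1.05 and
DEPLETED at ≤ 0.95 with q ≤ 0.05 — the 5% floor is applied uniformly
to all features. Uncovered track positions contribute the configured
missing value (0.0), matching sparse signal exports where absent signal
means zero; a coverage-gap counter records how often this fires.

## Cohort stratification

APOBEC3 ratio = ln(mutations attributed to SBS2 or SBS13) /
ln(all other attributed mutations), requiring ≥ 1 APOBEC and ≥ 2 other
mutations for a defined positive ratio. HIGH ⇔ ratio ≥ 0.90; MID ⇔
0.75 < ratio < 0.90, excluded from downstream group re-analyses; LOW ⇔
ratio ≤ 0.75. The boundary 0.75 is assigned LOW because the MID
interval is open at 0.75; the LOW rule is stated here as ≤ 0.75 because
any other reading contradicts the MID interval. Counts entering the
ratio are argmax-assigned, not probability-weighted. Group burden
comparisons use median fold and a two-sided Mann–Whitney U test; the
groups reuse the identical analysis machinery (no group-specific code
paths).

## Synthetic data generator

`mutotopo.synth` emulates, at desk scale, the input universe: random
uniform-composition chromosomes (default 3 × 2 Mb; generation retries
with doubled lengths if any trinucleotide context falls under 50
occurrences per chromosome, a simulator precondition), genes tiled on
alternating strands (20 kb every 50 kb, with periodic overlapping
opposite-strand genes as bidirectional regions), a sawtooth
replication-timing profile (period 200 kb, amplitude 100, 1 kb bins)
with printed peaks/valleys, and cosine (nucleosome-like, period
~200 bp), blocky and peaked (CTCF-like) feature tracks.

Catalogs are drawn per planted signature. Effects are realized by
**exact stratified allocation**: eligible loci are partitioned into
effect strata (e.g. transcribed / untranscribed / nontranscribed), each
stratum receives its exact expected share of the n mutations
(largest-remainder rounding), and loci are drawn uniformly without
replacement within strata. A planted odds ratio of 2.0 is therefore
realized at 2.0 up to stratum-composition noise rather than as a
binomial draw around it — the recovery tests then measure the analysis
machinery, not placement noise. Clustered runs are planted as
consecutive same-base loci (~100 bp spacing) on one strand. Probability
tables give the generating signature a sharp probability (default 0.9)
with the remainder spread evenly. Every planted truth is written to a
manifest consumed by the recovery tests.

What the fixtures do **not** emulate: real base composition and repeat
structure, realistic gene-length and expression distributions,
cell-type-specific chromatin, copy-number variation, sequencing
artifacts, or inter-sample heterogeneity. Passing recovery tests shows
the statistics recover planted topographical structure under matched
nulls at desk scale; it does not validate biological conclusions on
human data.

## Problem sizes and numerical choices

Tests and the acceptance script use scaled-down study conditions chosen
as the package's own trade-off between statistical resolution and a
laptop-friendly runtime: fixture genomes of 0.3–2 Mb, 3,000–5,000
mutations per planted signature, and 10 simulation replicates inside
multi-seed loops (the pipeline default remains 100; the replicate-count
and conservation checks run at the full default). Recovery thresholds
(OR within [1.8, 2.2] of a planted 2.0, ≥ 90–95% of seeds, null report
rates within binomial tolerance of 5%) are fixed properties of the
tests, not tuned quantities.

Other numerical details: OR uses the cross-product form a·d/(b·c) so
zero cells yield 0/∞ rather than exceptions; Fisher exact p comes from
`scipy.stats.fisher_exact` and is verified against full hypergeometric
enumeration in tests; BH uses `statsmodels` and is verified against the
step-up definition; the RNG is `numpy.random.default_rng` seeded with
(seed, stream) tuples; all output tables are deterministic in row
order for byte-stable reruns.

## Known limitations

* ID transcription-strand orientation is a convention (first event
  base), not a published rule; six-class run context and the 25 kb trim
  sidedness are likewise pinned choices exposed as config.
* bigWig is not parsed; tracks must be pre-converted to wig/bedGraph.
  Inputs must share one assembly (checked only by chromosome-name
  overlap); no liftOver.
* Clustered-mutation classes (omikli/kataegis) are consumed as optional
  labels, never called; signature extraction is upstream of this
  package and enters only as the probability table.
* The occupancy similarity test inherits the autocorrelation caveat
  above; its p values are anti-conservative for smooth signals.
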