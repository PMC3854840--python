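# Methods

This note records the models, conventions and numerical choices behind
`mitospectra`, in the spirit of a methods supplement: what each stage
assumes, which knobs matter, and what the synthetic data do and do not
establish about real libraries.

## Coordinates and the circular reference

All public coordinates are 1-based, fully closed, and modular on the
16,569 bp circle; the packaged reference is the rCRS (NC_012920.1) with the
standard gene annotation in `data/rcrs_regions.tsv`. Because the CRS origin
splits the control region (m.16024–16569 plus m.1–576), rearrangement
calling internally renumbers the circle so base 1 is the first base of
MT-TF (CRS m.577) — the "ALT" rotation — making the control region the
contiguous block 15,448–16,569 and the coding region exactly 1–15,447.
`CoordinateMap` is the bijection between the two numberings; everything
user-facing reports CRS.

## Direct repeats at junctions

A perfect repeat flanking a deletion makes the breakpoint assignment
ambiguous: the junction can slide anywhere within the repeat. The repeat
finder therefore reports, by default, the *total ambiguity*: the forward
longest common prefix of the sequences starting at the first deleted base
and at the resumption point, plus the backward common suffix of the
sequences ending at the junction flanks. This quantity is invariant to
where inside the repeat the junction was assigned and reproduces the
classic 13 bp repeat of the common deletion (m.8483_13459del4977) and the
9 bp repeat of the CRD prototype m.307_356del50 from either endpoint
convention. A pure-forward convention is available via
`convention="forward"`. N bases never match and truncate repeats.

## Alignment

The aligner is seed-and-extend over a doubled copy of the circle (windows
crossing the origin become ordinary slices; coordinates are reduced mod L).
Exact 12-mer seeds place each read; a fully vectorised first stage accepts
a full-length placement outright only when its mismatch count is small
enough that no end-trimming could change the verdict
(`nmm ≤ (1 − length_cutoff) · read_length`). Unresolved reads get an exact
per-diagonal search for the best-scoring ungapped window (match +1,
mismatch −2; ties broken toward more matches, making decisions consistent
with co-optimal alignments of a full local DP), and reads without usable
seeds can fall back to an exhaustive scan over every diagonal.

Two stringency levels define the pipeline contract: *low* (identity ≥ 0.80
over ≥ 0.50 of the read) collects mtDNA-like reads against the reference;
*high* (≥ 0.90 over ≥ 0.95) re-aligns them against the per-sample
consensus. Identity is matches over aligned columns; length is aligned
read bases over read length. The engine evaluates ungapped windows only:
reads whose best placement would require gaps fail high stringency and are
routed to split-read analysis, which is where reference-discordant reads
belong in this design. The test suite verifies that accept/reject
decisions equal those of an independent affine-gap local-DP oracle
(gap of length k costing 5 + 2k) for substitution-divergent reads, the
error model of these libraries.

The consensus is the per-position plurality base over the low-stringency
pass, ties and uncovered positions falling back to the reference; no
indels are emitted, so consensus coordinates remain CRS and cross-sample
phasing is the identity (the m.577 anchor is preserved by construction).
At very high coverage the consensus input is capped (250,000 reads by
default) because plurality at >1,000× is already saturated. A pair is
*broken* when either mate is unaligned, mates share a strand, or the
implied insert leaves the configured bounds (50–1,200 bp by default).

## Split-read breakpoint calling

Candidates are the reads accepted at low but rejected at high stringency.
Each read (both orientations) is decomposed into two same-sense segments on
distinct diagonals, found by word-15 seeds: segment ends are score-maximal
under the same +1/−2 scoring, the two segments must jointly cover the read,
neither may be internal to the other, each must reach the word length
(15 bp — a seed must exist), and the decomposition must explain ≥85% of
read bases as matches. Both segments extend independently and maximally, so
across a flanking repeat they overlap on the read: b5 is the rightmost
reference position consistent with the 5′ segment and b3 the leftmost
consistent with the 3′ segment. Under this convention the canonical common
deletion is called at CRS (8482, 13447), inside the printed count windows —
which is why those windows end 7–13 bp "short" of the textbook junction
coordinates. Repeat annotation first converts back to the non-overlapping
junction (shifting b3 right by the read overlap).

### Class windows and quantification

Counting windows (CRS): common deletion b5 ∈ 8477–8483 ∧ b3 ∈ 13262–13452;
major-arc deletions, both ends in 5576–15976, canonical orientation, span
> 320 bp, minus the common-deletion count and minus the reverse-orientation
count in the same window (the chimera estimate — library chimeras join
random loci in either orientation with equal probability, so the
non-canonical count estimates the canonical contamination); CRMs, both ends
in the origin-spanning window 16492–59 with modular junction span > 137 bp
(the window itself is 137 bp wide, so the span threshold excludes ordinary
small deletions inside the window while admitting tandem-duplication
read-through junctions of any unit length); CRDs, canonical junctions with
both ends in 244–494.

Frequency per mtDNA is count / average coverage. Because a junction is
callable only from read placements leaving ≥15 bases on both sides, the raw
estimator underestimates molecule fractions by the detection aperture
(read_length − 2·15 + 1)/read_length ≈ 0.71; `frequency_corrected` divides
this out and is, in simulation, an unbiased estimator of planted deletion
molecule fractions (flanking repeats widen the aperture by up to the repeat
length, a small positive residual bias ≤ r/71). For CRMs the same uniform
correction is applied and is a *lower bound* on the duplicated-unit burden:
reads interior to tandem arrays with units shorter than half a read never
pass the low-stringency gate at all (their best window is one unit long),
and units between ~50 and ~68 bp are callable only from a narrow placement
window. This detection limit is intrinsic to the two-pass design, not a
property of the simulator.

## SNV calling

Against the sample consensus, a read base is a valid observation iff its
quality exceeds Q33, the mean quality of the ±5 bp window (central base
included, clipped at read ends) exceeds Q30, and at most two *other*
mismatches fall within the window; no minimum count or coverage is
required. All reads in broken pairs are excluded, which in simulation
removes every chimeric fragment's contributions. Under the default quality
profile these filters discard 25–30% of raw aligned coverage. Per-position
four-allele counts give frequencies; alleles at or above 0.01 are treated
as inherited heteroplasmy/homoplasmy and removed from the somatic table
(strictly below 0.01 is kept — note this implies somatic analysis needs
effective depth comfortably above 100, else single-read observations
exceed the threshold).

Between-run normalisation is additive by default ("correcting linearly"):
one offset per run (global mean mode) or one per base change computed from
coding-region rows (per-base-change mode), chosen so matched means agree
across runs; corrected frequencies are floored at zero, and a
multiplicative variant is available behind a flag.

## Spectrum summaries and models

A sample's per-bp burden in a region is the sum of its sub-threshold
variant frequencies over the region divided by the region length; per-mtDNA
burden is the same sum, so per-mtDNA = per-bp × region length exactly.
Per-base-change means use the same region-length denominator (not the
source-base count) — a documented choice that keeps the strand-bias
statistic Δ[G>A]−[C>T] = mean(G>A) − mean(C>T) antisymmetric and simply
interpretable; a 25 bp rolling track is available for per-position bias.
The m.3243 hotspot report gives the top alternate allele per position of
m.3242–3244 and the A>B (all non-reference) frequency, which by
construction bounds A>G from above; zero-depth positions are reported
missing, not zero. Pathogenicity binning consumes an externally supplied
per-site score table (score > 0.667 or nonsense / 0.100–0.666 / synonymous
or < 0.100); the package ships only a synthetic stand-in generator for
testing, and bases where MT-ATP6 overlaps MT-ATP8 are listed once, under
MT-ATP8.

Accumulation is modelled by ordinary least squares of burden on age with a
t-based 95% CI on the slope and RMSE of residuals. Deletion loads are
evaluated on the fitted (unanchored) line; SNV loads are anchored,
baseline + slope × age, with the published infant forebrain baseline
0.37×10⁻⁵ bp⁻¹ — applied from age zero, the reading that reproduces the
printed 25- and 80-year loads. Fold changes are prediction ratios at 25 and
80 years, reported to three significant figures. Cohort tests are exact
two-tailed Mann–Whitney rank tests: the full assignment distribution is
enumerated (mid-ranks for ties) up to ~3×10⁵ combinations, beyond which
scipy's implementation is used; completely separated groups of five give
P = 2/252 ≈ 0.0079.

## Synthetic cohorts: what they emulate

The generator draws a population of full-length circular molecules, each
carrying at most one rearrangement: the canonical common deletion;
major-arc deletions placed between natural direct repeats of the reference
(80% of them, the rest at random window positions); CRMs as circular
tandem arrays (~2 kb) of one control-region unit of 44–87 bp; CRDs (90%
the m.307_356del50 prototype). Point mutations are Poisson per molecule at
the configured per-bp rate with a transition-dominated, reference-strand
biased change spectrum (weights G>A 0.40, T>C 0.22, C>T 0.18, A>G 0.10,
transversions 0.10 total), a ×5 control-region excess, and a separate
m.3243A>G carrier fraction. Fragments are sampled from molecules in
proportion to molecule length — so junction-spanning read counts scale with
molecule frequency exactly as the per-mtDNA estimator assumes — with
inserts N(300, 50) truncated to [150, 600] bp, 2×100 bp mates,
per-base qualities N(35, 2.5) clipped to [20, 41], optional quality-driven
miscalls, 8-oxoG-like G>T/C>A artifacts applied to fragments, and library
chimeras formed by joining two random same-sense fragments. Cohort loads
follow the configured linear age models (clamped at zero with a warning);
each sequencing run contains both young and aged specimens.

Defaults are the package's stated study conditions: class frequencies
follow the putamen accumulation coefficients (common deletion
3.35×10⁻⁵ yr⁻¹ through 0.16×10⁻³ at 25 y; major arc 22.36×10⁻⁵ yr⁻¹;
CRMs age-independent at 8×10⁻³; CRDs 1.2×10⁻⁴ yr⁻¹), SNV rates are
anchored at 0.37×10⁻⁵ + 4.02×10⁻⁷·age per bp, the chimera rate is a
conservative 10⁻³ per fragment and the oxo artifact rate 2×10⁻⁵ per base.
Where the source studies publish no library parameter (insert profile,
quality profile, chimera rate), the values above are stated choices, not
inferences — in particular, real libraries evidently carry a much larger
junction-read background than the 10⁻³ chimera default, so simulated total
breakpoint counts per alignment are intentionally lower than scaled
real-data totals.

What passing tests show: the pipeline recovers planted junction burdens,
SNV frequencies, strand bias and accumulation slopes from reads generated
under this model, and its estimators are unbiased up to the documented
detection geometry. What they do not show: robustness to PCR duplicates,
indel sequencing errors, nuclear mtDNA-like sequences (numts), mapping
bias, or batch structure beyond an additive between-run shift — none of
which the generator models.

## Problem sizes and numerical choices

The acceptance-style end-to-end checks run a six-sample cohort (ages
20–85) at 5,000× coverage over 20,000 molecules in the test suite, and at
3,000× in `scripts/acceptance.py`; slope-coverage replicates use twenty
six-sample cohorts at 200×. Recovery tolerances are three binomial
standard errors on expected junction-read counts (with the chimera
subtraction's variance added for the major arc), exact binomial
consistency for per-site SNV checks, and the fitted 95% CI for slope
coverage. All randomness flows from explicit integer seeds through
`numpy.random.default_rng`; identical seeds reproduce byte-identical
simulated libraries. Ties are deterministic everywhere (alignment window
selection by score, then matches, then diagonal and position; consensus
ties to the reference base; junction assignment rightmost-5′).
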