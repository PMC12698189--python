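# Methods

## Signal model

A double-stranded DNA deaminase converts accessible cytosines to uracil;
sequencing reads the conversion as C→T on the molecule's converted strand and
G→A on its complement.  For every reference cytosine on its own strand the
pileup records `n_total` (reads with a determinate base) and `n_conv` (reads
with the converted base); the rate `n_conv / n_total` is the accessibility
signal.  Coordinates are 0-based half-open throughout, and a genomic position
carries a cytosine on at most one strand, so strand-pooled queries stay
unambiguous.

Strand assignment is tag-first (a two-letter conversion-strand tag from the
aligner wins), falling back to the majority of C→T vs G→A mismatches; ties
and zero-information reads are discarded.  Read bases inconsistent with the
conversion model (e.g. C→A at a top-strand C) are sequencing error, not
protection, and are excluded from `n_total`.  Overlapping paired-end mates
contribute one observation per cytosine (higher base quality wins) so a
fragment is never double-counted.  Flagged duplicates are dropped by default;
a flag keeps them for amplification-free protocols.  The genome-wide
conversion rate is computed over cytosines with `n_total ≥ 3` (configurable)
to suppress shot noise; QC flags samples outside the optimal 25%–40% window,
above which occupancy scores degrade.

## Enzyme context bias

The enzyme's preference for flanking bases is fit on protein-free DNA as the
per-context expected conversion rate, with default context width k = 3
(`NCN`): the dominant preference is the 5′ neighbor (T over G), and k = 5 is
available where more resolution is warranted.  Correction is multiplicative —
`corrected = observed × genome_rate / expected_rate(context)`, clipped to
[0, 1] — because rates are probabilities and a ratio-to-genome-rate preserves
the scale; it is also exactly invertible in expectation, so per-context mean
corrected rates converge to the genome rate on naked DNA.  Contexts with
fewer than 200 supporting observations (configurable) fall back to the genome
rate rather than amplifying noise; contexts the control never converts are
uncorrectable and their records are dropped with a warning.  The fit pools
strands unless the strand-wise overall rates disagree by more than 10%
relative, in which case per-strand tables are kept.

## Occupancy scores

For a binding site, `FOS = mean corrected rate over the two 50 bp flanks −
mean corrected rate over the motif interval`, both strands pooled.  Sites
with fewer than 2 informative cytosines on either side (configurable) are
invalid — the guard matters for AT-rich motifs that carry too few cytosines
to score.  `TFOS` is the arithmetic mean of FOS over a factor's valid sites;
a positive-only variant (sites with FOS > 0) is exposed for correlating with
ChIP strength.  Aggregate profiles align sites on the motif center
`floor((start+end)/2)` and reverse-orient minus-strand sites.  Change ratios
between conditions are `(treated − control)/control` with a robustness floor
on the control (default TFOS ≥ 0.02 and ≥ 200 sites — an explicit stand-in
for an unpublished filtering rule, configurable).  Under the generative model
below, `E[FOS] = θ·(p_open − p_protected)`, which is the closed form the
calibration experiments test against.

Cross-sample comparisons first rescale each track by `reference_rate /
global_rate` (clipped to [0, 1]) so that samples converted at different
enzyme doses — or conditions whose global conversion shifted — overlay on one
scale.  In the dynamics experiments TFOS is computed on these normalized
tracks, while flanking chromatin accessibility deliberately uses the raw
corrected rates: the first asks whether the factor still occupies its sites
relative to its surroundings, the second how accessible the surroundings
are in absolute terms.  This is what lets a remodeler-inhibition regime
(accessibility halved, occupancy constant) show a strongly negative
flanking-accessibility change ratio with only a mild TFOS change.

## De novo footprint detection

Both strategies run inside user-supplied open-chromatin regions to avoid
calling nucleosomes, with a local background (mean corrected rate in a
±200 bp ring, excluding the interval) or a global one (region-set mean);
local is the default because accessibility is heterogeneous across regions.

**S1 (FootprintScan)** scores each PWM motif occurrence as `background −
motif mean rate`.  Motif models come from JASPAR PFM or MEME minimal files;
log-odds thresholds are calibrated to a background false-positive rate
(default 1e-4) from the exact score distribution.  Significance uses an
empirical null of length-matched random positions drawn within the same
search regions (default 1,000; abort under 100 valid draws), a rank-based
tail probability with add-one smoothing, and BH per motif.  The positional
null preserves the rate composition of the search space.

**S2 (FootprintRegion)** slides a 15 bp window (step 1) over the regions,
requires ≥ 3 informative cytosines per window, and tests the window's summed
counts one-sided against Binomial(n, p0) for depletion.  BH runs across all
windows; significant windows merge when within a 5 bp gap, and merged
intervals are trimmed to their individually depleted cytosines (one-sided
binomial p < 0.05 per cytosine), which places boundaries to within ~1
cytosine spacing at deep coverage.  Calls narrower than 6 bp are dropped.
The window width resolves the ~6–30 bp footprints typical of TFs; all
parameters are exposed.  Treating reads over cytosines as independent trials
ignores molecule-level correlation; this makes window p-values anti-
conservative in principle, but the empirical null-FDR check below shows the
discrete binomial's conservatism dominates at these depths.  Footprints are
annotated motif-matched when a motif occurrence overlaps ≥ 50% of the motif
length; density is reported per 200 bp of searched span (and per covered bp,
since the denominators answer different questions).

**Differential binding** compares cluster-level mean site scores between two
conditions scored over one candidate-site universe.  Scores are quantile-
normalized across conditions; each cluster's mean difference is judged
against a null of size-matched random site draws (default 10,000).  Because
quantile normalization forces the pooled distributions to agree, a genuine
shift in one cluster leaks a small opposite shift into the rest; cluster
differences are therefore re-centered on their median — robust while most
clusters are unchanged — before forming z.  The permutation z and its normal
p are an explicit stand-in for an unspecified test statistic and are labeled
as such.  Clusters under 50 sites are flagged underpowered.  A default motif
clustering by PWM column correlation (Pearson ≥ 0.8, best ungapped offset,
both orientations, single linkage) is provided; users can supply their own.

## Single molecules and single cells

Per-read calls use raw conversion states: bias correction is a rate-level
transform and cannot apply to a single binary base call, so the assessment
window (motif ± 2 bp) instead requires ≥ 2 informative cytosines to dilute
context effects.  A read is bound when ≤ 1/3 of its informative cytosines
converted, unbound at ≥ 2/3, ambiguous between — at the 2-cytosine minimum
this demands unanimity.  These thresholds are explicit defaults, not
published values, and are CLI-exposed.  The bound fraction is
`bound/(bound+unbound)` with a Wilson 95% interval; ambiguous reads are
excluded but counted.  Because determinacy differs between truly bound
(residual rate 0.05) and truly unbound (rate ≈ p_open) molecules, the
estimator carries a small upward bias that shrinks as the window's cytosine
count grows; the calibration below uses sites with 10 cytosines per strand,
where the bias stays within the ±0.05 tolerance.  Co-occupancy joins calls
on read id, keeps molecules determinate at both sites, and reports the 2×2
table with a Haldane-corrected odds ratio and a two-sided Fisher exact test;
pairs must lie within one fragment span.  Per-cell tracks aggregate calls by
barcode tag (non-whitelisted or missing barcodes go to `unassigned`); the
merged track is the exact sum of the per-cell counts.  Single-cell display
uses a centered 5-bp moving average over informative positions; positions
with no data anywhere in the window stay missing, never zero.

## The simulator

Each molecule samples a fragment, a strand, and (optionally) a cell barcode;
draws a bound/unbound state per overlapping TF site from Bernoulli(θ);
builds a protection mask from bound-TF footprints plus nucleosomes; then
converts each cytosine on its strand with probability `p_protected` if
masked, else `min(1, p_open · bias(context))`, and applies a uniform
substitution error.  Nucleosomes fill the complement of the open regions as
phased arrays (147 bp footprint, 190 bp repeat) anchored at each closed
span's edge with per-molecule Gaussian jitter (sd 10 bp) — phasing is a
qualitative feature of the data, and these defaults are documented choices,
not measured values.  `p_protected` defaults to 0.05, not 0, because real
footprints show residual conversion.  Reads are emitted as perfectly aligned
single-end SAM so pipeline tests are decoupled from an external aligner
(FASTQ-style use remains possible by realigning the emitted sequences); the
truth table stores per-molecule bound states, protection intervals, and
per-cytosine expected probabilities, and identical seed + config gives
byte-identical output.

What the simulator does not emulate: PCR duplication structure, indels,
transposase insertion bias, mappability, CpG methylation effects on
deamination, and realistic fragment-length mixtures.  Passing calibration
therefore demonstrates correctness of the statistical machinery under the
stated generative model, not performance on real libraries.

## Calibration experiments and problem sizes

`foottrack.evaluate` runs each experiment end-to-end (simulate → SAM/FASTA →
extract → correct/quantify), with all randomness derived from one seed:

* constructed-track FOS identities (exact);
* bias flatness: two independent naked samples of 20,000 molecules on
  100 kb with a 2× TC preference — fit on one, correct the other; reports
  the TC/GC fitted ratio and the corrected/uncorrected per-context CV;
* occupancy grid θ = 0.1…0.9 at 2,000 molecules/site, p_open = 0.6,
  p_protected = 0.05, 10 replicates per θ; the deviation of mean FOS from
  θ·(p_open − p_protected) is assessed jointly across the grid by chi-square
  on the per-θ z-scores (the per-θ replicate SE is itself a noisy estimate,
  so the joint 95% check has the intended coverage where nine separate 2-SE
  checks would not);
* single-molecule bound fractions on the same grid at p_open = 0.8 with a
  10-cytosine-per-strand site;
* S2 null FDR over 50 protein-free replicates (2 kb regions, 600 molecules)
  and planted 12 bp footprint recovery (θ = 0.9, 2,000 molecules, 10
  replicates);
* a 21-cluster spike-in (25 sites per cluster, ~50× coverage) for
  differential binding;
* the remodeler-inhibition dynamics regime (p_open 0.6 → 0.3, θ = 0.7
  constant, 40 sites);
* exact brute-force equivalences for pileup counting, BH, windowed
  smoothing, and interval assignment.

Sizes were chosen as the smallest at which the measured quantities are
stable; every one is a function parameter.

## Known limitations

* Bias correction assumes the naked-DNA control shares the genome build and
  context composition of the sample; models are keyed by build, not cell
  line.
* The S1 null and differential-binding z are pragmatic stand-ins where no
  canonical statistic exists; both are labeled in outputs.
* Deep-learning bias models and de novo discovery of motif-less footprints
  are out of scope.
* bigWig export is not provided; bedGraph and TSV are.
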