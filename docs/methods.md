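# Methods

## Scope and model

`breakscape` analyzes array-CGH copy-number profiles through the lens of
*breakpoints* — loci where the copy-number state changes — rather than the
amplified/deleted regions themselves. The pipeline is: probe-level log2
ratios → score-called aberrant segments → filtered breakpoints →
per-sample instability statistics (BPI, per-chromosome break density,
PGA) → operational chromothripsis calls → cohort aggregates. A
synthetic-data generator with known ground truth closes the loop so every
stage is testable without external downloads.

All coordinates are 0-based half-open. The default genome is hg19 with
chrY excluded (the reference DNA in two-color aCGH is sex-matched, so Y
is only interpretable when probes for it are present; it is a switch).
Scaled genomes (all chromosome lengths × a common factor) keep the
chromosome-number and length-proportion structure of the full genome
while making whole-genome simulation cheap.

## Segmentation

The statistic for a probe interval is its average log2 ratio's deviation
from zero in standard-deviation units,

    score(i, j) = mean(x[i:j]) · sqrt(j − i) / σ.

σ is estimated per sample from first differences of adjacent probes:
`MAD(diff)/ (√2 · 0.6745)`, which is robust to the sparse true segment
boundaries; it is floored at 0.05 so noise-free synthetic input cannot
produce infinite scores.

Detection is recursive and top-down: the maximal-|score| interval
(ties: longer, then leftmost — determinism) is refined by greedy
single-probe boundary moves while |score| increases, fixed, and the
search recurses left, right, and *within* the fixed interval relative to
its own mean, so nested amplicon steps are found. A second pass then
tests every tile for internal splits with the two-sample statistic
`|mean_L − mean_R| / (σ·sqrt(1/n_L + 1/n_R))` at the same threshold.
This pass exists because a region oscillating between two states can
outscore each of its constituent segments: the composite is fixed first,
and each segment's deviation from the composite mean is only half the
step amplitude. The split statistic tests the step itself. No extra
parameter is introduced; both passes use the same conservative threshold.

Called aberrations additionally require ≥ 5 probes and |mean log2| > 0.3
(defaults; `SegmentationParams`); rejected candidates are merged back
into the neutral state so each chromosome is tiled by alternating neutral
and aberrant segments. Defaults: score threshold 10 (a deliberately
conservative setting for a score whose exact normalization varies between
implementations; it is a free parameter), min probes 5, min |mean| 0.3.

Detection limits worth knowing: at σ = 0.2 and ~12.7 kb probe spacing, an
isolated single-copy gain (log2 ≈ 0.585) needs ~150 kb to reach score 10;
a four-copy gain (log2 = 1) reaches it at ~100 kb. An *oscillation* of
amplitude d is resolvable when (d/2)·sqrt(n)/σ ≥ 10 per segment, i.e.
amplitude-1 oscillations need ~16 probes (~200 kb) per segment.
Oscillations of amplitude 0.585 (two adjacent copy states, e.g. 2↔3) are
below the threshold at any realistic segment size for this platform —
this is an information limit of the conservative threshold, and the
synthetic chromothripsis generator consequently does not plant them (see
below).

## Breakpoints and instability statistics

A candidate breakpoint sits at every boundary between consecutive tiles
where at least one flank is a called aberration; neutral–neutral
boundaries and chromosome ends produce none. Candidates are kept when
|Δ mean log2| > 0.5 (strict). The breakpoint position is the midpoint of
the inter-probe gap, with the half-gap recorded as uncertainty (the
platform resolves ~10 kb breakpoint regions, not base-pair breakpoints).

- **BPI** (breakpoint instability index): total filtered breakpoints per
  genome.
- **Break density**: breaks per chromosome × 10⁸ / chromosome length
  (breaks per 100 Mb).
- **PGA**: summed length of called aberrant segments / genome length;
  overlaps are impossible by the tiling invariant.

Germline-CNV masking removes breakpoints within `slop_bp` (default
10 kb, the platform resolution) of user-supplied mask intervals;
`subtract_matched_normal` does the same against breakpoints called in a
matched non-aberrant (e.g. stromal 2N) fraction, which acts as a
negative control.

## Chromothripsis detector

The copy-number chromothripsis signature — many breakpoints confined to
one or two chromosomes, oscillating among two or three states — is
operationalized per chromosome over the minimal span containing its
aberrant segments:

1. segment means in the span are clustered 1-D (new state when the sorted
   gap exceeds 0.25, half the breakpoint filter);
2. `n_states` is the fewest *aberrant* states covering ≥ 80% of aberrant
   bases (states whose segments are all neutral are baseline, not
   oscillation states; the cover rule tolerates small outlier levels);
3. oscillations are adjacent returns — a segment revisiting the state two
   segments back — with returns into the neutral baseline ignored.
   Long-range revisits are deliberately not counted: scattered isolated
   aberrations revisit the baseline and can revisit amplitude levels by
   chance without ever alternating, which is the main false-positive mode
   of a looser definition.

A chromosome is called when breakpoints ≥ 10, n_states ≤ 3 and
oscillations ≥ 4 (all config-exposed; the pattern was historically
assessed visually and no published cutoffs exist, so these defaults are
this package's operationalization). A sample with calls on more than 2
chromosomes is flagged "global instability, review" and its calls are
withdrawn: confinement is part of the signature. LOH is not an input —
two-color aCGH cannot measure it — so the detector is copy-number-only.
Every call carries the parameter set and the evidence values behind it.

## Synthetic data generator

The generator emulates a 244K oligo-array study design:

- **Probe grid**: `round(length/spacing)` probes per chromosome (floor 2)
  on a regular grid with uniform ±0.4-spacing jitter (avoids aliasing
  between grid and planted boundaries). Default spacing 12.7 kb gives
  ~244,000 probes on hg19.
- **Rendering**: a probe over `c` tumor copies with stromal admixture `p`
  reads `log2((p·2 + (1−p)·c)/2) + N(0, σ_probe)`, clamped at −4 for
  homozygous losses in pure tumor. σ_probe defaults to 0.2 (typical aCGH
  probe noise); `p` defaults to 0 because the emulated design flow-sorts
  nuclei precisely to remove stromal admixture.
- **Stepwise CNAs**: non-overlapping events with integer copy states from
  {0,1,3,4,5} on the diploid baseline, log-uniform lengths in
  [100 kb, 2 Mb] (100 kb is the platform's stated confident detection
  floor), optional nested internal steps (gain-within-gain,
  loss-within-loss) producing intra-amplicon breakpoints.
- **Chromothripsis**: a sub-region tiled by `n_breaks + 1` oscillating
  segments (250–600 kb each) drawn from 2–3 copy states. State sets are
  restricted to pairwise expected-log2 separation ≥ 1.0 so that every
  transition is both above the 0.5 breakpoint filter and resolvable at
  the conservative score threshold (see detection limits above). The
  oscillation walk returns to the state two segments back with
  probability 0.75 — oscillation means returning; a memoryless walk over
  3 states frequently produces stretches with no adjacent returns, which
  is not the interdigitated pattern being modeled. When the neutral state
  belongs to the set, the walk starts and ends neutral where parity
  allows, keeping region edges silent; otherwise the two region edges add
  two further true breakpoints.
- **Cohorts**: per-subtype specs (event burden, chromothripsis
  probability, ploidy-class weights) default to a breast-cancer-like
  setting: chromothripsis probability 0.50 (ER+), 0.556 (HER2+), 0.25
  (TNBC); event burdens 10–50 per genome; aneuploid-dominated ploidy
  classes.

What the generator does *not* model: GC waves and other spatial noise
correlation, whole-genome-amplification artifacts, per-probe quality
weights, balanced translocations, subclonal (fractional) copy states,
and aneuploid baselines (an aneuploid genome is modeled by re-centering,
not fractional states). Passing recovery tests therefore demonstrates
correctness of the algorithms under idealized iid Gaussian noise, not
end-to-end performance on raw array data.

## Packaged cohort tables

Three small TSVs ship with the package: a 29-tumor roster (8 ER+, 9
HER2+, 12 TNBC with ploidy class, BPI, chromothripsis status), the
12-tumor × 8-chromosome chromothripsis tick matrix, and the disposition
of all 48 flow-sorted specimens (27 aneuploid / 21 diploid profiles; 29
included / 19 excluded). These drive exact integer-ratio computations:
overall chromothripsis prevalence 12/29 = 41.4%, HER2+ chr17 5/9 =
55.6%, HER2+ chr8 3/9 = 33.3%, ER+ 4/8 = 50%, TNBC 3/12 = 25%, and
flow-profile fractions 27/48 = 56.3% and 21/48 = 43.8%. Percentages are
reported to one decimal, round-half-up.

## Numerical choices

- Ties in the maximal-score interval: higher |score|, then longer, then
  leftmost; verified against exhaustive search.
- σ floor 0.05; log2 floor −4.
- Breakpoint delta filter is strictly greater-than 0.5.
- Percent rounding: decimal round-half-up to 1 digit.
- Empty chromosomes segment to empty lists; a fully aberrant chromosome
  has PGA contribution but no breakpoints (ends never count).

## Problem sizes

Simulation studies (tests and the acceptance script) run on hg19 scaled
×0.1 at 12 kb probe spacing (~25,800 probes/sample, preserving
chromosome count and proportions), 20 samples for breakpoint recovery
and 50 + 50 chromosomes for detector operating characteristics; these
sizes were chosen so the whole suite runs in well under a minute of
segmentation time while keeping per-chromosome probe counts in the
realistic range.

## Known limitations

- The segmenter is a functional equivalent of score-based aberration
  detection, not a bit-compatible clone of any vendor implementation;
  the score threshold's normalization is implementation-specific, so the
  threshold is a free parameter.
- Oscillations between adjacent copy states (amplitude ≈ 0.585) are not
  resolvable at threshold 10 on this platform's probe density; such
  patterns would need a lower threshold or a denser array.
- Centromere/terminal handling is minimal: chromosome-end boundaries are
  excluded, but no centromere model is built in (mask intervals can be
  supplied instead).
- BPI counts copy-number state changes; every such locus may hide
  multiple rearrangements, and balanced events are invisible, so BPI is
  a lower bound on true breakage.
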