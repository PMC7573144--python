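# Methods

## Scope and model

`microquant` quantifies nucleocytoplasmic translocation of an
immunostained protein at single-cell resolution in 4-channel 8-bit confocal
fields (DAPI = nuclei, ZsGreen1 = transfected cell bodies, AF568 = a second
marker, AF647 = the translocating protein). The pipeline assumes:

* one nucleus per cell, nuclei resolvable in DAPI above intensity 20;
* every analysable cell expresses the ZsGreen1 reporter, and the ZsGreen1
  detector offset is zero, so any value ≥ 1 is cell signal;
* intensities are linear in epitope abundance within 0–255 (no saturation
  handling), so summed intensity per compartment is a meaningful signal
  measure and area-normalised sums are mean intensities;
* background thresholds for "signal present" are measured, not assumed:
  they are the mean area-normalised AF647 values of cells in
  no-primary-antibody control fields.

## Segmentation constants

| parameter | default | meaning |
|---|---|---|
| `median_window`, `median_iterations` | 7 px, 10 | smoothing before thresholding |
| `dapi_threshold` | 20 | nuclei: strictly-above threshold |
| `zs_threshold` | 0 | bodies: value ≥ 1 is foreground |
| `nucleus_min_area` | 5,000 px (21.125 µm²) | strict "smaller than" removal |
| `body_min_area` | 3,000 px (12.675 µm²) | idem |
| `body_mean_intensity_min` | 6 | dim/untransfected-cell exclusion (strictly below) |
| `apoptosis_bright_k` | 2 | bright pixels = body mean + k·SD |
| `apoptosis_intensity_fraction` | 0.5 | blob must carry ≥ this fraction of body intensity |
| `pixel_edge` | 0.065 µm | fixed by the two printed px↔µm² equivalences |

The dim-cell filter operates on ZsGreen1: its purpose is removing
untransfected or barely transfected bodies, and ZsGreen1 is the
transfection reporter. The apoptosis rule makes a qualitative criterion
(a concentration of high intensity in an area smaller than the nucleus)
operational; both of its parameters are exposed in `FmisConfig`. A
zero-variance body has no bright pixels and is never flagged.

## Numerical conventions

* **Connectivity** is 8-neighbourhood throughout (components, holes,
  watershed basins); filter borders use reflect (symmetric) padding.
* **Threshold strictness** follows the literal reading: "above 20" is
  `> 20`; "smaller than 5,000" removes 4,999 px and keeps 5,000 px;
  "below 6" removes 5 and keeps 6.
* **Watershed markers** are the extended maxima of the Euclidean distance
  transform: regional maxima of the h-reconstruction with h = 2 distance
  units. (On a distance-to-background map cell centres are maxima;
  "minima" language refers to the negated map.) h = 2 absorbs the ≈1-unit
  discretisation dips a single mildly elliptical nucleus shows along its
  EDT crest — with h = 1 such nuclei can split, and the sub-5,000 px halves
  are then discarded, losing the cell — while remaining far below the
  ≳15-unit saddle depth of genuinely fused nuclei, which still split
  correctly. Plain regional-maxima marking without reconstruction does not
  merge twin peaks at all and over-segments.
* The 5,000 px nucleus filter is re-applied after the watershed split:
  a split piece below the minimum area is not a valid nucleus.
* **Ridge pixels** in the watershed are assigned by the deterministic
  flooding order of the priority-queue implementation; for symmetric
  inputs the two basins agree to within the one-pixel ridge line.
* **Holes** adjacent to two components go to the component with the longer
  shared boundary, ties to the lower label.
* **Nucleus ⊆ body** is enforced by clipping nucleus pixels to their body
  before quantification, so the cytoplasm area is never negative and
  `S_cell = S_nuc + S_cyt` holds exactly (integer arithmetic on 8-bit
  data).
* **Stage ties**: "above threshold" is strict, "at or below" inclusive,
  and `N_cyt = N_nuc` classifies as moderate (mild requires the
  cytoplasmic signal strictly below the nuclear one). Cells with empty
  cytoplasm have undefined `N_cyt` and are excluded from staging, counted
  as `unclassifiable` in the run log. Cells below both backgrounds are
  labelled "none", which deliberately conflates no-expression with
  nucleus-only expression.

## Background thresholds

Control cells come from no-primary-antibody fields segmented with the same
pipeline. In control fields the nuclear compartment is the DAPI-positive
area inside each retained body (the thresholded, smoothed DAPI mask, not
the watershed nucleus) and the cytoplasm is the ZsGreen1-positive,
DAPI-negative remainder. Thresholds default to the arithmetic mean of the
area-normalised values across all control cells, pooled over conditions; a
`mean+2sd` mode and per-condition computation are available where a more
conservative or plasmid-specific threshold is wanted.

## Statistics

* Two-group dispatch: Shapiro–Wilk on each sample at α = 0.05 (the study
  does not print its α; 0.05 is the convention and is configurable). Both
  normal → t-test, with Welch–Satterthwaite degrees of freedom when
  Levene's test rejects equal variances; otherwise Mann–Whitney U.
  Levene's test is mean-centred (the original form, as in SPSS) rather
  than median-centred.
* Mann–Whitney: exact enumeration when min(n₁, n₂) ≤ 8 without ties;
  otherwise the normal approximation with tie correction and **no**
  continuity correction, so two identical samples give U = n₁n₂/2 and
  p = 1 exactly.
* Fisher's exact test: hypergeometric two-sided for 2×2; Freeman–Halton
  for r×c, summing the null probabilities of all margin-compatible tables
  no more probable than the observed one (tolerance 1e-9 on log
  probabilities). Complete enumeration up to 200,000 tables (the count is
  obtained by dynamic programming first); beyond that, Patefield-sampled
  Monte Carlo with a fixed seed, add-one estimator and reported standard
  error. Zero-margin rows/columns are dropped.
* Kruskal–Wallis + Dunn: Dunn's z from pooled mid-ranks with tie
  correction; unadjusted and Bonferroni-adjusted (all pairs) p-values are
  both reported, the adjusted one being the headline number, since the
  study states multiplicity adjustment without naming the method.
* Normalisation: percent-of-control rescales by the control mean per
  batch; ΔΔCт relative expression is `2^−ΔΔCт · 100` with the per-batch
  rescale of the control mean to 100% done by the same percent-of-control
  step.

## Synthetic scenes

The generator emulates 512×512 fields of transfected BV-2-like cells as
rotated concentric ellipses: nucleus semi-radius 41–45 px (area always
above the 5,000 px filter), body semi-radius 72–80 px, up to 4 cells per
field at full separation, plus optional touching pairs (centre distance
0.85 of two body radii, to exercise the watershed), edge-clipped cells,
dim cells (ZsGreen1 mean 3), and apoptotic cells (a bright blob of half
the nucleus area at intensity 220 on a base of 15, carrying ≈70–80% of the
body intensity). The body radii floor is deliberate: with the mean+2SD
bright-pixel rule, a two-level body is only detectable when the blob
covers < 20% of the body area, and 0.5 × nucleus area stays below that
ceiling for all radius draws.

AF647 levels per programmed stage (nuclear/cytoplasmic): none 60/0,
mild 60/20, moderate 30/60, severe 0/60, against a diffuse background of 2
outside cells; no-primary-antibody control fields carry the background
process only, so the measured thresholds land near 3.1 at the default
noise and the programmed stages keep margins of several intensity units on
every inequality. Noise is additive Gaussian (σ = 5 by default), clipped
to [0, 255] and rounded, with true-zero pixels kept at zero to model the
zero detector offset that makes the ZsGreen1 threshold of 1 meaningful.
One integer seed drives a single generator stream (placement order), so
identical parameters give bit-identical scenes.

What the generator does **not** model: point-spread blur, shot noise,
intensity gradients, irregular cell shapes, overlapping nuclei, saturated
pixels, or chromatic misregistration. Passing the recovery benchmarks
therefore demonstrates that the pipeline implements its specification
faithfully on geometrically clean data, not that it would reach the same
accuracy on real micrographs.

## Benchmarks and problem sizes

The recovery benchmark used by the tests and by `scripts/acceptance.py`
runs 50 seeded default scenes (~190 cells, of which ~60 carry phenotype
flags) and scores scene-level count recovery, per-cell IoU, exclusion
sensitivity, false removal of clean cells, stage agreement on recovered
masks, and exact intensity conservation; a 12-scene noiseless batch scores
stage recovery on ground-truth masks, and 1,000 permutation-null
replicates (each a fresh lognormal pooled sample randomly split into two
groups of 30) estimate the empirical size of the dispatched two-group
test. Drawing fresh data per replicate makes the replicates independent,
so the rate estimates the unconditional test size with plain binomial
error (SE ≈ 0.7%); reusing one pooled sample would instead estimate a
size conditional on that draw. These sizes keep a full run in the minutes
range on one CPU while giving ≈ 3% resolution on scene-level rates.

## Known limitations

* The exclusion flags are evaluated after watershed matching; a cell both
  dim and on the border is counted once, under the first matching rule, in
  the run log's accounting.
* The Freeman–Halton enumeration is exponential in table size; large
  sparse tables fall back to Monte Carlo (seeded, with reported SE).
* The apoptosis rule is a surrogate for a qualitative morphological
  judgement; its two parameters were chosen from the generator's algebra,
  and real-data use would warrant re-tuning against annotated examples.
* Stage "none" cannot distinguish absent expression from strictly nuclear
  expression (see stage ties above).
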