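# Methods

This note documents the models, parameter choices, numerical conventions and
known limitations of each pipeline stage, and what the synthetic-data
generators do and do not emulate.

## Imaging and focus detection

**Model.** A diffraction-limited focus is fit as an isotropic 2D Gaussian
plus a constant local offset, `b + A·exp(−(Δr² + Δc²)/2σ²)`, by
Levenberg–Marquardt least squares with the centroid constrained to the
fitting window (default 7×7 px). An isotropic PSF is the minimal model for
wide-field imaging of sub-resolution spots; astigmatic or 3D PSFs are out of
scope. Non-convergent fits never raise: they return the initializing pixel
flagged `weak`.

**Quality flags.** `edge`: centroid within 1 px of the window border.
`weak`: fitted amplitude below `weak_snr` (default 3) noise standard
deviations; the noise scale is the MAD-based sd of mask pixels (or of fit
residuals when no mask estimate is supplied). There is no community-standard
intensity threshold for "having a focus", so the k·noise rule is exposed as
a parameter rather than fixed.

**Detection.** Candidates are local maxima inside each cell mask above
`background + 3·noise`. The background is the median of mask pixels, re-
estimated after excluding ~3 PSF sigmas (4 px) around candidates so bright
foci do not inflate it. Candidates closer than one fitted sd are merged,
keeping the higher amplitude — unresolved doublets should not double-count.
Detection is translation-equivariant by construction (integer-shift windows).

**Brightest pixel.** The argmax of intensity over mask pixels, ties broken
by lexicographic (row, col) order so the result is unique and deterministic.
It exists for every cell even before discrete foci are resolvable, which is
what makes it useful as a repletion metric and as a proxy focus for sparse
labels.

## Colocalization

Distances are Euclidean between sub-pixel centroids, scaled by the pixel
size (129 nm default, so the canonical 2-px threshold is 258 nm; the
comparison is inclusive). Denominators are conditional on cells having foci
in both channels; an unconditional mode exists for sensitivity analysis.
Cells missing a channel return a `None` sentinel, never a zero distance.

The random-pixel null draws, per analysed cell, `n_draws_per_cell` (default
10) pixel positions uniformly from the mask and records the distance from
the *nearest* reference-channel centroid to the drawn pixel centre, pooled
across cells. Ten draws per cell balances per-cell coverage against pooling
weight; the number is configurable because no canonical value exists. The
ECDF of distances is right-continuous, so its value at the threshold equals
the colocalization fraction on the same table.

## Repletion

Per timepoint, each replicate contributes its mean brightest-pixel intensity
and fraction of cells with ≥1 focus; the point estimate is the mean of
replicate means with SEM = sd(replicate means)/√R, which respects the
replicate (not the cell) as the independent unit.

The focus-fraction adjustment divides a series (intensities and fractions,
with their SEMs) by the strain's steady-state fraction of focus-forming
cells, expressing signal per focus-competent cell. The functional form of
such adjustments varies across labs; plain division is adopted here because
the population mean is, under the generator's model, exactly
`background + fraction · slope · t` — division recovers the per-cell rate —
and a no-adjust path is available for comparison.

Initial rates are OLS slopes over a per-series window (default 0–20 min;
slow strains are fitted over their longer sampled window, e.g. 0–90 min).
Fold differences are slope ratios and are scale-invariant; a non-positive
test slope raises rather than returning a signed fold.

## Cohesion time

**Replisome end** = time of the first frame of the terminal focus-free run.
Defining it via the *terminal* run makes the call robust to single-frame
blinking; a focus present in the last frame censors the cell.

**Segregation** = first frame of the first run of ≥ K consecutive separated
frames (K = 3 at 5-min spacing). "Separated" means ≥ 2 locus foci, and
additionally centroid distance ≥ 2 px when centroids are available. The run
*start* is reported: the locus was separated from that frame onward, the
later frames only certify persistence. Increasing K can only move calls
later (monotonicity), and runs shorter than K never affect the call.

**Cohesion time** = (segregation − replisome end) + 7 min. The offset
compensates for the terminus locus replicating ~2 min before termination
and the sliding clamp taking ~5 min to unload; it is a constant of the
experimental system, configurable. Negative measured intervals are legal —
with precocious segregation the locus separates ~2 min after its
replication, i.e. 5 min *before* the replisome focus disappears.

**Population summaries.** The step-curve t50 is the first time the
cumulative fraction of uncensored cells reaches 0.5, without interpolation;
censored cells are excluded from the denominator by default (optionally
counted as never-segregating). Because both event calls are quantized to the
frame grid, the measured interval for a true delay D behaves as
`Δt·floor((D + w)/Δt)` with `w ~ U(0, Δt)` — a dithered quantizer whose
*mean* is exactly D but whose median snaps to a frame multiple. Two
consequences: (i) t50 values are multiples of Δt plus the offset, and for
delays near a quantization boundary a finite cohort's t50 can flip to the
neighbouring frame, so recovery checks use the median t50 across several
cohorts; (ii) the mean cohesion time over cells is an unbiased summary and
is reported alongside t50. Interpolating the 50% crossing was considered and
rejected: it biases t50 downward whenever the first quantized value already
carries more than half the mass.

## ChIP enrichment

Coverage lives in 50-bp bins: sonication fragments span 200–1,000 bp, so
finer binning adds no information. Tracks are normalized to counts per
million of their library total (the standard depth correction; a zero-total
track is an error). The enrichment statistic is median-across-replicates
first, then ratio — the median damps single-replicate outliers before they
can distort the ratio — with a pseudocount ε = 0.5 CPM on both numerator and
denominator to stabilize low-coverage mock bins; ε is recorded in the track
metadata.

Smoothing is a centred 2-kb moving average that wraps across the origin of a
circular chromosome (mass-conserving in circular mode). Peak calling greedily
accepts local maxima of the smoothed track by descending score with 2-kb
exclusion zones, returning at most N = 26 peaks with no padding. Because a
site narrower than the smoothing window becomes a plateau whose argmax is
arbitrary within ~half a window, peak positions are optionally refined to
the raw-ratio maximum within ±1 kb of the smoothed maximum.

Motif scanning matches a degenerate IUPAC consensus on both strands with up
to `max_mismatch` (default 1) mismatches; non-ACGT genome characters never
match; palindromic double-hits collapse to one hit per position. The matS
consensus itself is injected via configuration (default
`GTGACRNYGTCAC`, 13 bp, palindromic) rather than hard-coded, since variant
consensus definitions exist. The scan is linear in coordinates; a hit
spanning the circular origin would be missed (a ~13-bp blind spot on a
4.6-Mb genome).

Anchored profiles extract ±2-kb windows around anchor positions, align by
anchor, and take the across-anchor median per offset (mean optional).
Profiles are computed on whichever enrichment track is supplied: the raw
ratio preserves planted peak heights (used for condition fold changes, i.e.
the ratio of profile maxima), while the smoothed track suits display and
flatness assessment (max/median ≈ 1 when nothing is enriched). Smoothing a
±2-bin site dilutes its height ~8-fold, so fold changes on smoothed profiles
would be compressed toward 1 — hence the raw-track convention for folds.

## Synthetic data: what it emulates, and what it does not

**Imaging.** Cells are identical spherocylinder projections placed on a
grid — adequate as a spatial universe for focus statistics and null draws,
but without the size variation, curvature, crowding or segmentation errors
of real fields. Foci are ideal Gaussians over a flat background with Poisson
(default) or additive Gaussian noise; no autofluorescence gradients, no
out-of-focus light, no drift. The colocalization jitter default (40 nm sd)
represents tight molecular association plus localization error. Channel-B
foci in non-colocalized cells are resampled until > 2 px from the A focus,
making truth labels exact rather than probabilistic.

**Time-lapse.** Replisome end times are uniform over the movie's middle
(20–60 min), delays default to +2 min, and transient separations/re-merges
are geometric runs capped strictly below K, placed so that at least one
cohesive frame precedes the persistent split and re-merges start only after
the first K separated frames. This placement guarantees unambiguous truth
labels; adversarially timed transients in real data could still shift a
call by a frame. Division, lineage and re-initiation are not modelled.

**ChIP.** Negative-binomial counts with dispersion 50 model moderate
replicate overdispersion (~14% cv at deep coverage) of technical replicates
from a clonal culture; library-size factors are lognormal (sd 0.1). Planted
sites raise the IP mean uniformly over ±2 bins — real ChIP peaks have
fragment-size-shaped profiles. HTR artifacts raise IP and mock alike and
cancel in the ratio, as formaldehyde-reactive loci do. Read sequences,
mapping, duplicates and GC bias are not simulated; coverage is generated
directly.

**Repletion.** Competent cells grow linearly in brightest-pixel intensity
from induction; focus onset times are uniform, so the fraction-with-foci
also rises linearly. Real induction has a lag and saturates; the optional
plateau models only the latter.

Passing tests on these generators demonstrate that the estimators recover
planted parameters under the stated noise models — not that they are robust
to segmentation artifacts, photobleaching, or mapping biases absent from the
simulations.

## Problem sizes and determinism

Recovery checks use 2,000-cell snapshots (colocalization), 100 spots
(localization error), 50-track cohorts (cohesion), 500–1,000 cells per
timepoint × 3 replicates (repletion), and full-genome (4.64-Mb) coverage at
1e6–1e7 reads per sample (ChIP) — sizes at which the statistics of interest
are stable while a full run stays interactive on a laptop. Every generator
is a pure function of its spec including the seed; all pipeline randomness
derives from the single configured seed, and identical config + seed gives
byte-identical outputs.
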