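# Methods

This note documents the models, parameter choices and numerical conventions
behind `myofuse`, and what validation on simulated data does and does not
establish.

## Fusion index and the ≥ 3-nuclei rule

The fusion index of a field of view is
`FI = 100 · fused_nuclei / total_nuclei`, where a nucleus counts as fused
when it lies inside a fiber region holding **at least three** nuclei.  The
threshold exists because a two-nucleus object is ambiguous in a live
culture — it may be an early fusion event or simply a dividing cell — so
two-nucleus regions contribute nothing.  The threshold is exposed
(`min_nuclei_per_fiber`) for sensitivity analysis but defaults to 3
everywhere, including in the simulator's ground truth.

An empty field (zero nuclei) has no fusion index; the pipeline raises
rather than reporting 0 %, so plate-level means cannot be silently diluted.
Fields are analysed independently; field-level values are averaged into one
replicate per well, and wells are the replicate unit for statistics.

## Nucleus detection

Nuclei appear in the nucleus channel as compact spots of roughly known
scale.  Detection filters the image with a negated, scale-normalised
Laplacian of Gaussian at `sigma_px` (default 3 px, matched to the rendered
nucleus radius), takes local maxima above `rel_threshold` (default 0.2) of
the filtered-image maximum, suppresses peaks closer than
`min_separation_px` (default 5 px) and refines each peak to a sub-pixel
centroid by center-of-mass of the positive response in a ±`sigma` window.
Detections within `2·sigma` of the border are dropped, because truncated
spots bias centroids.  The relative threshold makes the detection set
invariant to overall gain (and hence to bit depth); the filter makes it
translation-equivariant for interior spots.  Touching nuclei closer than
the separation limit are merged — there is no watershed splitting stage;
this is a known limitation at very high confluence.

## Fiber segmentation

The cytoplasm channel is processed as: subtract a Gaussian-smoothed
background estimate (`background_radius_px`, default 50 px — large relative
to the ~10 px fiber width, which also flattens scaffold autofluorescence);
threshold (Otsu by default; a fixed threshold on the background-subtracted
image is available); morphological closing (radius 2 px); hole filling;
8-connected components.  Candidates smaller than `min_area_px` (default
200 px², about twice the squared fiber width) or with best-fit-ellipse
elongation (major/minor axis ratio) below `min_elongation` (default 3) are
discarded.  Elongation is the automated stand-in for the human judgement
that myotubes are the "larger", elongated bodies: round mononucleated cells
have elongation ≈ 1 and are rejected regardless of brightness.  Because the
background estimate is subtracted before thresholding, adding a constant to
every pixel does not change the segmentation (shift covariance of the Otsu
path).  Touching fibers are not split; a merged region inherits all
contained nuclei.

## Object contrast

`Contrast_j = (S_j − bgd) / bgd` with `S_j` the arithmetic mean over the
object pixel set and `bgd` over the background set.  The sets must be
disjoint and non-empty, and `bgd = 0` is an explicit error.  The statistic
is invariant under multiplying the image by a positive constant and *not*
invariant under adding a constant — both properties are asserted in tests,
since they are what makes contrast comparable across exposure settings but
not across offsets.

## The scene simulator

The simulator is the validation instrument: it renders scenes for which the
true nucleus positions, fiber masks and fusion index are known exactly.

**Population model.**  Nuclei grow geometrically,
`n(t) = min(n0 · g^t, plateau)` with `n0 = 30`, `g = 1.4`/day and a plateau
of 90 nuclei per 384² field — cultures reach confluence around the switch
to differentiation media at day 3, and drugs do not affect growth (the
drug effects studied here inhibit fusion, not proliferation).  The fused
fraction follows a saturating first-order law
`df/dt = fusion_rate · effect(t) · (f_max − f)` from day 3, integrated as
exact exponential steps over unit days; `effect(t)` equals `drug_effect` on
scheduled drug days and 1 otherwise.  Defaults `fusion_rate = 0.5`/day and
`f_max = 0.6` give a course that rises over ~days 4–8 and levels off
around 60 % fusion by day 10, the qualitative shape of an untreated C2C12
differentiation.  No published absolute fusion-index numbers anchor these
values; they are calibrated to trends, and all dynamics claims validated
against them are ordinal (orderings, timing differences), not absolute.
A multiplicative drug effect on the rate is the simplest monotone model
consistent with observations that inhibitors freeze or slow fusion over
their exposure window and that activators reach maximal fusion earlier.

**Well-to-well variability.**  Each scene's nuclei count and fused fraction
are jittered multiplicatively with CV `biological_cv = 0.05`, a typical
replicate spread for plate cultures.  Without it, replicate wells would be
numerically identical and every between-condition ANOVA degenerate.

**Geometry.**  Fibers are capsules (rectangles with semicircular caps) of
half-width 5 px, randomly oriented, with their `k ≥ 3` member nuclei spaced
16 px along the axis (±1 px jitter), so fiber length grows with nuclei
count.  Mononucleated cells are 7 px-radius disks.  Placement is rejection
sampling with a 6 px clearance so that masks are disjoint and every
inter-nucleus distance exceeds ~3 detection sigmas; placement failure after
400 retries raises rather than silently dropping objects.  Fused-nucleus
budgets are partitioned into fibers of 3–8 nuclei; up to 2 leftover nuclei
return to the solitary pool, so the realized fused count is within ±2 of
`f · n`.  Two-nucleus capsules are generated at a low rate
(`binucleate_rate = 0.05` of the unfused pool) to exercise the ambiguous
case; they are labeled unfused in the ground truth, and their geometry
(elongation ≈ 2.5) falls below the segmentation elongation gate by design.

**Imaging model.**  The nucleus channel holds one Gaussian spot
(σ = 3 px) per nucleus; the cytoplasm channel holds flat-intensity fiber
and cell masks softened by a 1 px Gaussian blur.  Per-label-combination
amplitudes default to 120/320 counts (cytoplasm/nucleus) for the
cGFP+nmCherry combination and 60/160 for cmCherry+nGFP, over a uniform
autofluorescent background of 20 counts (×3 for the scaffold variant), so
the first combination images with roughly double the contrast — matching
the observed ordering of the two labeling schemes.  Noise is Poisson on
signal + background followed by additive Gaussian read noise (σ = 3),
clipped to the 16-bit range.  At these settings spot contrast is ≈ 16:1 and
fiber contrast ≈ 6:1.

**Determinism.**  Every scene draws from a stream seeded by
(master seed, condition-name hash, well, day, field), so runs are
bit-reproducible and adding wells or conditions never perturbs existing
scenes.

**What the simulator does not emulate.**  Uneven illumination, spatially
structured autofluorescence, overlapping or crossing fibers, multi-layer
growth, nucleus shape variation, cell motility and photobleaching.
Passing recovery tests on this synthetic data therefore demonstrates the
correctness and internal consistency of the pipeline, not its accuracy on
arbitrary real micrographs: real cultures at high density will show merged
nuclei and touching fibers, which this pipeline intentionally does not
split (matching the failure modes of manual marking).

## Statistics

Per day, conditions are compared by one-way ANOVA on well-level replicates;
zero total variance is reported as p = 1 rather than NaN.  Pairwise
comparisons are t-tests using the pooled within-group mean square from the
ANOVA (error degrees of freedom N − k), with raw p-values multiplied by the
number of pairs and capped at 1 — the conventional Bonferroni post-hoc as
computed by common statistics software.  Using the pooled error rather than
per-pair variances matters at n = 3: it raises the degrees of freedom from
4 to 8, which keeps the procedure usefully powered for large effects while
Bonferroni keeps the family-wise error below α.  Both properties are
verified by simulation in the acceptance suite (family-wise error ≈ 0.03
under the null; power ≈ 0.98 for a 5-SD separated pair).

Missing condition/day combinations are reported, never imputed; linear
interpolation is used only inside `time_to_fraction_max`, which returns the
earliest interpolated day at which the mean fusion index reaches a fraction
(default 0.9) of its course maximum.

## Problem sizes used in validation

The validation campaign (tests and `scripts/acceptance.py`) uses 384² px
scenes with up to 90 nuclei, 20 scenes for detection/segmentation recovery,
50 random geometry scenes (≤ 256², ≤ 200 nuclei, ≤ 10 fibers) for the
brute-force fusion-index oracle, a 4-condition × 3-well × 8-day plate (96
scenes, plus 24 for the rate-doubled course) for the dynamics scenario, and
1000 Monte-Carlo replicates for the statistical calibration.  These sizes
give stable estimates (binomial SE < 0.7 % at 1000 reps) at sub-minute
runtimes.

## I/O conventions

Coordinates are 0-based with x = column, y = row; masks are pixel-aligned.
Images are single-plane grayscale TIFF, 8- or 16-bit; unknown bit depths
are rejected rather than rescaled, because silent rescaling would corrupt
contrast values.  A scene bundle is a directory of two TIFFs plus a JSON
sidecar (and, for simulated scenes, a 16-bit label-image TIFF with the
ground-truth fiber masks), inspectable with standard viewers.  Camera bit
depth and physical pixel size are free configuration parameters.
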