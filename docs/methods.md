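# Methods

This note documents the models, conventions and numerical choices behind
`inclusiontools`, and what the synthetic-data tests do and do not establish
about real data.

## Pixel-set conventions

All image analyses operate on explicit pixel sets (`PixelROI`): 0-based
(row, col) coordinates, origin top-left, pixel-center semantics, no
sub-pixel contours. This makes the set algebra the pipeline depends on —
subtracting unbleached pixels from a whole inclusion, ring zones from scaled
boundaries — exact rather than approximate. Connected components use
8-connectivity; the boundary of an ROI is the subset of its pixels with at
least one 4-neighbour outside the ROI (pixels on the image edge count as
boundary). This standard pairing keeps boundaries closed.

**Automatic thresholding.** Otsu's method is the default; the method name
and threshold value are recorded in the ROI metadata and the method is a
configurable parameter (`otsu`, `li`, `yen`, `mean`, `triangle`,
`multiotsu_low`), because results in low-contrast regimes can be
method-sensitive and the upstream processing this reconstructs specifies
only "automatic thresholding". A constant image raises rather than
returning an arbitrary set. The first post-bleach frame of a FRAP series is
a special case: its fusion-protein channel is trimodal (background, dimmed
bleached half, bright unbleached half) and a two-class threshold merges the
dimmed half into background, so FRAP ROI assignment defaults the fusion
channel to the lower threshold of a three-class Otsu (`multiotsu_low`),
which separates background from all signal.

**ROI scaling.** "Scaling by 110%" is treated as a geometric statement
about the boundary: a pixel belongs to the scaled ROI iff its position,
inverse-mapped about the ROI centroid by the scale factor and rounded to the
nearest pixel, lies in the source ROI. Inverse nearest-neighbour mapping is
gap-free for any factor and any raster shape, unlike forward-mapping a
boundary polygon whose vertex ordering is ill-defined for arbitrary 4-boundaries.
Round-tripping (scale by f then 1/f) recovers disks of radius ≥ 10 px with
Jaccard ≥ 0.9 for 0.8 ≤ f ≤ 1.25; the residual is rasterization noise.

## Maturity classification

The FlAsH:Cerulean ratio inside an inclusion reports its conformational
age: high ratios mark disordered, recently formed aggregates (HBR), low
ratios mark amyloid-converted mature inclusions (PBR). Ratios are only
comparable within an experiment, so thresholds are calibrated per
experiment from the sample mean and SEM (sample SD with n−1 denominator
over √n) of the measured ratios. Classification uses strict inequalities:
HBR above mean + SEM, PBR below mean − SEM, and an explicit INTERMEDIATE
label inside the band (including exact ties and the degenerate SEM = 0
case). Labelling the band explicitly, rather than silently excluding it,
makes the exclusion auditable downstream; summaries report all three
counts. The classifier is monotone in the ratio and total over all
non-negative ratios.

## Zone enrichment

Each inclusion is partitioned into **core** and **middle** zones by the
normalised centroid-to-boundary distance, plus an **outer ring** between
the inclusion and its boundary scaled by 110% — the outer edge of the
fluorescent inclusion. The normalised distance of a pixel is its centroid
distance divided by the distance of the boundary pixel nearest in angle to
its ray (preferring pixels within ±10°); for convex inclusions this equals
the radial fraction, and it degrades gracefully for mildly non-circular
shapes. The default core fraction of 0.5 (core = inner half of the
normalised radius, i.e. a quarter of the area of a disk) is a symmetric
choice documented as configurable: the three-zone quantitation it
reconstructs never defined the inner split. Core and middle always
partition the inclusion exactly; the partition contract is asserted on
every construction. Inclusions under 9 px are rejected as too small to
partition.

RNA (EU/AF647) compartment intensities are background-subtracted means per
named compartment; the preferred background source is a matched no-EU
control level, with a user-supplied background ROI as fallback. Regressions
of compartment intensity on maturity ratio are ordinary least squares
(statsmodels) with the 95% confidence band for the mean response; the fit is
cross-checked in tests against the closed-form normal equations to 1e-9.

## FRAP

ROIs are fixed from the first post-bleach frame and reused for all frames —
inclusions are treated as stationary over the 21-minute window, matching
re-imaging of marked positions. The whole inclusion comes from the
fusion-protein channel, the unbleached half from the FlAsH channel (the
covalently bound dye does not recover, so its surviving signal marks
unbleached pixels), the bleached half by set subtraction, and background
from a 25 px circle placed by the user or automatically at the darkest
image corner. Relative recovery is the stated ratio

    r(t) = (bleached(t) − background(t)) / (unbleached(t) − background(t)),

which is invariant under affine gain/offset rescaling of the whole image —
asserted numerically in tests. No additional pre-bleach normalisation is
applied by default; the pre-bleach frame is retained for reporting, and the
flat curves of rigid inclusions are insensitive to this choice.

Mobility is summarised by Δr = r(t_end) − r(t0) and a single-exponential
fit r(t) − r(t0) = A·(1 − 2^(−t/h)) (base-2 halftime parameterisation, the
simplest model with a named, recoverable parameter). The mobile-fraction
estimate is A/(1 − r(t0)), since 1 − r(t0) estimates the bleach depth. On
simulated data with 5%-of-signal noise, mobile fractions 0.3/0.6/1.0 are
recovered within ±0.05 and halftimes 2/5/10 min within ±20% (means over 50
replicates); immobile simulations stay within |Δr| < 0.05, the no-recovery
phenotype. Fit failures degrade to a delta-only summary with a flag.

## Antibody penetration

Penetration is the mean centroid-to-external-boundary distance minus the
mean centroid-to-internal-boundary distance, in pixels, with distances
taken from the centroid of the 110%-scaled (outer) ROI. The internal
boundary comes from automatically thresholding the inverted anti-GFP
intensities within the inclusion's padded bounding region, restricted to
the inclusion — the reconstruction adopted here, since whether the original
analysis restricted the inverted threshold to the interior is unstated. Two
conventions close the degenerate cases: an antibody that stains the whole
inclusion leaves an empty unstained core, and penetration is then the
external mean distance (the limit of the formula as the core shrinks onto
the centroid); a completely unstained inclusion yields core = inclusion and
penetration ≈ the 10%-scaling offset. That offset is a geometric floor —
even a zero-depth surface coat measures ≈ 0.1 × radius — so the raw
internal and external distances are always reported alongside, letting
users subtract the floor. Measured penetration on noiseless raster disks
(r ∈ {15, 25, 40}, coat depths 0–10 px) agrees with an independent raster
oracle within 1.5 px and is monotone in true depth.

## Cytometry

**Gating.** Cells whose fluorescence is concentrated in an inclusion emit
narrower, taller pulses at a given pulse area. The gate is a supervised
linear discriminant (scikit-learn LDA) on area-normalised log pulse-shape
features, (log width − log area, log height − log area), calibrated on
explicit negative and positive control populations of ≥ 100 events each —
a deterministic, auditable reconstruction of pulse-shape gating whose
original gate geometry is not restated in this package's source material.
Identical calibration populations raise; barely separable ones (calibration
accuracy < 0.75) emit a machine-readable separability warning and the gate
degrades toward coin-flipping, as it should.

**Binning.** Expression (cerulean pulse area) is assigned to 20
logarithmic bins spanning the recorded positive range — consecutive edges
differ by a constant factor (10^0.2 for a four-decade range). The modifier
(TMR) axis has four ordered categories per construct: *none* below a
detection floor (default: the 1st percentile of a modifier-free calibration
population — "none" is otherwise undefined on a log scale), then
*low/medium/high* log-uniform from the floor to that construct's maximum.
Bins are half-open [lo, hi) with the last bin closed; zero or negative
intensities are excluded from log binning and counted in a QC sidecar.
Binning conserves gated events exactly and is invariant under permutation
of the event table; empty cells carry an undefined (NaN) fraction rather
than zero.

**Stall ratios.** Per-event mCherry:GFP with a GFP floor (excluded events
counted), summarised per construct by median and IQR. In the dual-reporter
cassette, a stall efficiency s yields an expected ratio 1 − s; medians
recover simulated s ∈ {0, 0.5, 0.9} within 2% at 50,000 events.

## The synthetic generator

The generator replaces the study-type raw data with seeded scenes of known
ground truth, emulating: one cell (radius 80 px) with one inclusion
(default radius 20 px) over a flat camera background (10 a.u.) with
additive Gaussian read noise clipped at zero (no Poisson term — shot noise
adds nothing to threshold-robustness testing); radial channel profiles
(uniform, boundary-straddling enriched shell, surface coat of given pixel
depth, excluded-from-inclusion); half-disk bleaching split by the vertical
diameter through the inclusion centre with single-exponential base-2
recovery; and cytometry populations of 50,000 events (the scale of a
typical acquisition) with log-normal expression (natural-log mean 7, SD 1),
logistic inclusion probability (intercept −9, expression coefficient 1 —
inclusion frequency rising with expression, ~16% prevalence overall), 30%
pulse-width narrowing and 30% extra height gain for inclusion-bearing
events, and log-normal mCherry:GFP noise (σ = 0.1).

Three generator choices deserve note. The *shell* profile places its
enriched band symmetrically about the inclusion boundary
(shell_fraction ≤ d/r ≤ 2 − shell_fraction): surface-recruited proteins
coat the outer edge of the fluorescent inclusion, which is exactly the
region the outer-ring zone samples; a shell strictly interior to the
thresholded disk would be invisible to an outer ring that lies outside it.
The *maturity* scene chooses the FlAsH level so the measured in-ROI mean
ratio — which sits on the background pedestal — equals the target exactly
in the noiseless limit. And pulse height is computed from the *narrowed*
width before the height shift is applied: pulse area is conserved when
fluorescence concentrates, so a narrower pulse is correspondingly taller;
modelling the height shift independently of the width change would
understate the separability that pulse-shape gating demonstrably achieves.

Determinism is strict: per-channel and per-frame RNG streams derive from
the seed plus a CRC of the channel name, so identical specs render
byte-identical images and changing one channel's profile leaves all other
channels' pixels untouched.

**What the synthetic tests do not show.** Scenes contain a single circular
inclusion per image — no crowded fields, touching inclusions, 3D structure,
bleed-through, photobleaching during acquisition, or non-stationary
inclusions. Passing tests establish that the measurements recover known
parameters under the stated noise model, not that segmentation or gating is
robust to every real-microscopy artefact; the threshold method and gate
calibration remain the user's responsibility on real data.

## Problem sizes

Test and acceptance computations use the sizes the assays themselves
suggest: 200×200 px scenes, 22-frame FRAP series, 20–100 seeded replicates
per Monte-Carlo check, and 50,000-event cytometry populations. The FRAP
replicate sweeps simulate ROI mean traces directly (per-pixel noise
attenuated by √ROI-area) rather than rendering every frame; the image
route is exercised end to end on single replicates and agrees with the
trace route.

## Out of scope

DNA construct design; wet-lab protocols; ANOVA/post-hoc machinery (the
package emits tidy tables for standard statistics tooling); FCS binary
parsing (CSV exports are the contract); compensation/spillover;
reaction–diffusion FRAP models; deconvolution and PSF modelling; watershed
separation of touching inclusions.
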