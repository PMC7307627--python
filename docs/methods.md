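# Methods

This note records the models implemented, the parameter choices that
matter, the numerical conventions, and what the synthetic fixtures do and
do not establish.

## Structure-tensor analysis

The local structure tensor of a grayscale image I is
J = w * (∇I ∇Iᵀ), the window-aggregated outer product of the gradient. The
gradient is computed by true convolution with sampled derivative-of-Gaussian
kernels (default size 11 px, σ = 3 px, reflect boundary); the x-kernel is
normalised to reproduce unit slope on a linear ramp, so derivative fields
have gradient units. Aggregation is **tiled** by default: one tensor per
non-overlapping 128 × 128-pixel window, partial border tiles dropped. This
matches downstream use (ROI summaries over tile grids) and makes the tensor
sum exactly reproducible by brute-force summation; a per-pixel **sliding**
box sum is available in `STConfig.aggregation` for map-like output.

Eigen-decomposition of the 2×2 tensor is closed-form. The anisotropy index
is AI = (λ₁ − λ₂)/(λ₁ + λ₂), with AI ≡ 0 for zero-gradient windows — the
standard coherence measure of 2D structure-tensor analysis, used here as
the single exposed formula. The reported orientation is the **texture**
(fiber) direction, i.e. the eigenvector of the *smaller* eigenvalue — the
direction of least intensity change — wrapped to [0, π). RGB input is
reduced to luminance (0.2125 R + 0.7154 G + 0.0721 B); AI is contrast-
polarity- and scale-invariant, so no inversion or normalisation is applied.

ROI summaries report two quantities: `ai_tensor`, the AI of the sum of the
covered windows' tensors (energy-weighted, orientation-aware: two equally
strong orthogonal windows cancel to 0), and `ai_mean`, the unweighted mean
of per-window AI values. Both are emitted because they answer different
questions (net directional coherence vs typical local coherence); the ROI
analyses in the statistics layer accept either.

## Automated cell counting

Stages and the defaults that drive them:

1. **Speed image** — Sobel gradient magnitude of the green channel,
   rescaled to [0, 1]. The green channel is used because Nissl membrane
   contrast is strongest there; grayscale input requires an explicit
   channel override.
2. **Chan–Vese** on the speed image, smoothing weight μ = 0.2, at most 300
   iterations. The level set is initialised with the fine sinusoidal
   checkerboard rather than a binary random mask: on a speed image the
   region data force vanishes over the flat background, so a ±1 random
   init can jam far from the optimum within the iteration budget, whereas
   the checkerboard's small level-set amplitude lets the region terms act
   on every pixel immediately and reaches the same optimum from any seed.
   `cv_init="random"` retains the literal seeded random-mask behaviour for
   comparison. The foreground phase is chosen as the one with higher mean
   speed; enclosed holes are filled; components are labelled with
   8-connectivity.
3. **Ellipse triage** by second-order image moments (equivalent-ellipse
   convention; "major axis" is the full axis length in pixels):
   major < S = 30 px → noise, discarded; major > B = 140 px →
   under-segmented; otherwise accepted. Components touching the image
   border are triaged normally.
4. **Markers** for under-segmented components: the HSV value channel is
   Gaussian-filtered (σ = 3 px), inverted so dark somata become maxima, and
   rescaled to [0, 1]. Regional maxima of the H-maxima transform
   (depth h = 0.1) inside the component are candidates; each must exceed
   intensity I = 0.5, and pairs closer than Dₛ = 70 px or with intensity
   difference below Dᵢ = 1 unit on an 8-bit-equivalent scale (1/255 after
   rescaling; `di_scale` configurable) are resolved by keeping the brighter
   marker. Suppression order is deterministic: descending intensity, then
   row, then column. h and the marker filter σ are not pinned down by the
   thresholds above; both live in `CellCountConfig`.
5. **Watershed** from the surviving markers on the inverted marker image,
   restricted to the component: one sub-label per marker, partitioning the
   component. A component with no surviving marker is kept as one cell and
   logged.

Cell density is ρ = N/A with N the number of final cells whose centroid
lies in the ROI and A the mask area in μm² (pixel area default
0.013 μm²/px). Counting by centroid inclusion makes N invariant to ROI
boundary effects on component shape.

## DTI scalar metrics and tensor fit

Scalars follow the standard eigenvalue definitions (see README). The
Westin shape indices use the λ₁-normalised convention, which partitions
unity exactly (CL + CP + CS = 1); the sum-normalised variant
(CL = (λ₁−λ₂)/Σλ, CP = 2(λ₂−λ₃)/Σλ, CS = 3λ₃/Σλ) is available via
`westin="sum"`. The all-zero tensor maps to FA = CL = CP = 0, CS = 1 with
a warning.

The tensor fit is ordinary least squares of log S against the six unique
tensor elements plus log S₀. Non-positive signals are excluded with a
warning; a design of rank < 7 (e.g. coplanar gradients) is an error.
Negative fitted eigenvalues are **kept**, flagged via
`TensorEigenvalues.from_fit`, and scalars are computed on the raw values —
clamping would bias noise studies. The default synthetic protocol is 4 b=0
volumes plus 60 directions at b = 2000 s/mm² on a Fibonacci sphere
lattice. The fit inverts the forward model exactly (machine precision) on
noiseless input; at b = 2000 the attenuated signals sit near the noise
floor even for moderate noise, so FA is biased upward — the tests bound
the median bias at SNR 50 rather than asserting unbiasedness.

ROI summaries of scalar volumes are plain masked means with NaN exclusion
(count reported); masks must share the volume grid and are never
resampled.

## ROI statistics

The measurement table is one row per (animal, hemisphere, bregma level,
region), with regions {cc, ec, S1} at +1.08 and −1.60 mm and
{cc, ec, S1, ic, VPL} at −3.60 mm. CD enters all statistics on the
×10⁻² cells/μm² scale and AD on ×10⁻³ mm²/s, keeping coefficients O(1).

*Group contrasts.* Unpaired two-sample t-tests per (level, region,
hemisphere, measure), pooled-variance Student's t by default (df =
n₁+n₂−2) with Welch's form behind a flag; degenerate zero-variance inputs
return t = 0 (equal means) or signed infinity. Benjamini–Hochberg step-up
q-values are computed per family; the default family layout pools all
t-tests of one measure across levels/regions/hemispheres (one AI family,
one CD family), with a single-family ("global") alternative — on the
default cohort parameterization the two layouts flag contrasts at rates
within a percentage point of each other. Significance is q < 0.05.

*Regressions.* OLS of FA or AD on (AI, CD) with intercept, per region
family — each single region plus the pooled sets cc+ec (all levels) and
cc+ec+ic, S1+VPL (lesion level). All records of a family enter: both
groups and both hemispheres, one observation per (animal, hemisphere,
region). All regression p-values (two coefficients + model F per fit) form
one BH family. The scatter projection is χ = β_AI·AI + β_CD·CD without the
intercept, so corr(response, χ) = √R² of the fit.

## Synthetic generators

All generators are bit-reproducible given (spec, seed) and return their
ground truth alongside the data.

*Fibers.* A coherent component (smooth 1D random profile swept along the
fiber direction) and an isotropic component (smoothed 2D noise) are each
normalised to unit variance and mixed with weights (c, 1−c); c is the
coherence. Amplitude 0.15 about a 0.5 background with additive noise
SD 0.01 keeps the texture well inside [0, 1]. Median tile AI rises
monotonically from ≈0.08 at c = 0 to ≈0.996 at c = 1.

*Nissl images.* Dark elliptical somata (paraboloid absorption profiles, so
every soma keeps a distinct intensity maximum even when fused) on a light
blue-violet background; the green channel absorbs most. Single-cell major
axes default to 45–90 px — inside the [S, B] = [30, 140] px acceptance
band. Touching pairs use 85–100 px cells at centre distance
max(78, 0.9·major): larger than Dₛ = 70 px so both markers survive, smaller
than the axis sum so the supports fuse, and the fused component's
moment-ellipse major axis (≈ distance + major) exceeds B. Per-cell
contrasts are drawn in [0.5, 0.7] with pair members at least 0.03 apart so
the Dᵢ rule never merges their markers. The default 30 cells in a 768²
frame at 0.013 μm²/px give ρ ≈ 0.39 ×10⁻² cells/μm², inside the 0.3–0.6
range the statistics layer assumes. The generator emulates soma geometry
and stain colour, not tissue context: no neuropil texture, no staining
gradients, no debris. Perfect counts here bound algorithmic error only;
they do not promise the same accuracy on real sections.

*DWI.* S = S₀·exp(−b gᵀDg) with optional Gaussian noise of SD S₀/SNR
(Rician magnitude noise behind a flag — the fixtures validate fitting
algebra, not scanner noise physics).

*Cohorts.* Independent Gaussian draws per record from per-cell (mean, SD)
parameters; sham n = 6, mTBI n = 8. The default AI and CD parameterization
places its real group effects in the ipsilateral hemisphere at −3.60 mm
(lowered external-capsule AI 0.76 → 0.60; raised CD in ec, S1 and ic) with
near-null cells rostrally. The per-cell FA and AD parameters are synthetic:
Table-style publications print only the histology summaries, so FA is
parameterized as 0.85·(AI mean) (SD 0.05) and AD as 0.9 + 0.5·(AI mean) in
×10⁻³ mm²/s (SD 0.08), which reproduces the white/gray-matter contrast
that makes pooled-family regressions informative. Draws are independent
across regions and measures — real data correlate within animal, so
regression effect sizes here are conservative relative to data with
animal-level covariance.

## Calibration behaviour and limitations

On 500 simulated cohorts, the lesion-level ipsilateral external-capsule AI
and CD contrasts are flagged (q < 0.05) in ≈82% and ≈90% of cohorts
respectively, while each individual rostral (+1.08 mm) contrast is flagged
in under 7% — the qualitative pattern the parameterization encodes. Note
that the probability that *no* rostral contrast is flagged anywhere in a
cohort is lower (≈71%): the rostral cells have small nonzero mean
differences and the lesion-level families contain several true effects, so
the BH step-up admits a borderline rostral p-value somewhere in roughly a
quarter of cohorts. That is a property of FDR control under these
conditions, not an implementation artefact.

Other limitations: the structure tensor is 2D (sections, not volumes);
no stain normalisation or colour deconvolution is attempted; cell counting
performs no stereological correction for 30 μm section thickness and no
cell-type classification; the statistics layer does not implement
voxel-wise permutation testing.
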