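# histotensor

Quantitative histology meets diffusion MRI: a Python library (plus a thin
CLI) for measuring tissue microstructure in stained brain sections and
relating it to diffusion-tensor imaging (DTI) metrics at the region level.
It is aimed at preclinical neuroimaging groups who validate in vivo DTI
findings — e.g. after experimental traumatic brain injury — against
myelin- and Nissl-stained sections of the same brains.

## What it computes

**Structure-tensor anisotropy (AI).** For a myelin-stained photomicrograph
the image gradient is estimated by convolution with the directional
derivatives of a 2D Gaussian (kernel 11 px, σ = 3 px); the pixelwise outer
products are summed over 128 × 128-pixel windows and eigen-decomposed
(λ₁ ≥ λ₂ ≥ 0). The anisotropy index

&nbsp;&nbsp;&nbsp;&nbsp;AI = (λ₁ − λ₂) / (λ₁ + λ₂) ∈ [0, 1]

is the 2D histological analogue of fractional anisotropy: 0 for isotropic
texture, 1 for perfectly coherent fibers.

**Automated cell counting and density (CD).** On Nissl-stained RGB images:
Chan–Vese active contours evolved on the green-channel gradient (the speed
image) give a preliminary segmentation; an ellipse is fitted to every
component by image moments and triaged by its major axis a — a < S = 30 px
is noise, a > B = 140 px is an under-segmented clump of touching cells,
otherwise a single soma. Under-segmented components are split by a
marker-based watershed whose markers are regional maxima of the H-maxima
transform of the (Gaussian-filtered, inverted) HSV value channel, subject
to three rules: marker intensity > I = 0.5, pairwise separation > Dₛ = 70 px
and pairwise intensity distance > Dᵢ = 1 (8-bit units). Cell density is
ρ = N/A in cells/μm².

**DTI scalar metrics.** From sorted tensor eigenvalues: MD = (λ₁+λ₂+λ₃)/3,
AD = λ₁, RD = (λ₂+λ₃)/2, FA = √(3/2)·‖λ − MD‖/‖λ‖, and the Westin shape
indices CL = (λ₁−λ₂)/λ₁, CP = (λ₂−λ₃)/λ₁, CS = λ₃/λ₁ (CL+CP+CS ≡ 1). A
log-linear least-squares tensor fit turns diffusion-weighted signals
(b-values/b-vectors in FSL layout) into eigenvalues; it is exact on
noiseless data.

**ROI statistics.** Tidy per-animal tables of AI, CD, FA and AD per
(hemisphere, bregma level, region) feed unpaired two-sample t-tests
(pooled-variance Student by default) with Benjamini–Hochberg FDR q-values,
and the multiple regression DTI ~ AI + CD over single or pooled region
families, reported with coefficient t statistics, adjusted R², model F and
the scatter projection χ = β_AI·AI + β_CD·CD.

**Synthetic data.** Every input has a seeded generator with machine-readable
ground truth: oriented fiber textures with controllable coherence,
Nissl-like images with planted (optionally touching) cells, DWI signals
from known tensors, and two-group ROI cohorts (sham n = 6, mTBI n = 8)
whose only real effects sit ipsilaterally at the lesion level.

## Worked example

`examples/cell_counting_demo.py` plants 30 cells (3 touching pairs) and
runs the full counting pipeline:

```
planted cells:            30 (3 touching pairs)
accepted single cells:    24
under-segmented (fused):  3
noise components dropped: 1
final count N:            30
ROI area A:               7668 um^2
cell density rho = N/A:   0.391 x1e-2 cells/um^2
```

The three fused pairs are recognised by their oversized fitted ellipses
(major axis > B) and each is split back into two cells by the watershed, so
the final count equals the planted truth; ρ lands in the 0.3–0.6 ×10⁻²
cells/μm² range typical of the regions this kind of study measures.

The other examples show the AI–coherence relationship
(`fiber_anisotropy.py`: median AI 0.081 → 0.996 as coherence goes 0 → 1,
orientation recovered to within a degree), the DTI closed forms
(`dti_scalars_demo.py`: λ = (1.7, 0.3, 0.3)×10⁻³ mm²/s → FA = 0.7990,
CL = 0.8235, and a noiseless fit exact to 4×10⁻¹⁶) and the cohort
statistics (`cohort_statistics_demo.py`).

A CLI mirrors the library: `histotensor {st-analyze, cell-count,
dti-scalars, dti-fit, roi-stats, simulate, run}`; `histotensor run --seed 5
--out OUT` executes the whole simulated pipeline and writes the report
tables.

## Documentation

`docs/methods.md` describes the models, parameter choices, numerical
conventions and known limitations.
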