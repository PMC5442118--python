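# Methods

`aarcmr` implements a multi-parametric cardiac-MR analysis for quantifying
myocardial infarct size (IS) and area-at-risk (AAR) after acute
ischemia-reperfusion injury, together with a digital short-axis phantom cohort
that provides ground truth for every stage.  This note documents the models,
the defaults and why they were chosen, and what passing tests do and do not
demonstrate about real data.

## Signal models and estimators

**T2 mapping.** Multi-echo spin-echo series follow S(TE) = S0·exp(−TE/T2),
sampled at the nine echo times TE = 3.5, 7, 10, 12, 15, 17, 20, 25, 30 ms.
Per pixel, (S0, T2) are estimated by bounded nonlinear least squares
(batched Levenberg–Marquardt with analytic Jacobians; all pixels of a map are
iterated in parallel, and the single-pixel API calls the same engine with a
batch of one).  Initialization is a signal-weighted log-linear regression.
Bounds: T2 ∈ [1, 300] ms, S0 ∈ (0, 10·max|signal|].

**Look-Locker T1 mapping.** Inversion-recovery series under a continuous
small-flip-angle readout follow the three-parameter model
s(t) = A − B·exp(−t/T1\*) with apparent rate
1/T1\* = 1/T1 + |ln cos α| / τ (α = 5°, τ = 3 ms excitation spacing),
A = S0·T1\*/T1 and B = A + S0 for ideal inversion.  The recovery curve is
sampled at 50 points; the acquisition protocol fixes the count and the 13.5 s
inversion repetition but not the spacing, so sampling is uniform on
[0.05, 10] s (> 4×T1 at 9.4 T, enough to determine the plateau A).
Magnitude data lose the sign of the inverted limb; polarity is restored by
negating all samples before a candidate zero-crossing index (candidates up to
the series minimum + 1) and keeping the restoration with the lower fit
residual.  The apparent time constant is corrected with the classical
three-parameter Look-Locker relation **T1 = T1\*·(B/A − 1)**.  Bounds:
T1\* ∈ [0.05, 5] s.

**Fit validity.** A pixel is invalid if the fit failed to converge, sits at a
bound, produced unphysical parameters (B ≤ A for IR), or has r² below
`min_r2 = 0.5`.  The screen is deliberately loose: r² is scale-dependent — at
fixed SNR a slower decay over the fixed TE range explains less variance — so
an aggressive cut (e.g. 0.8) rejects ~3% of T2 ≈ 38 ms (edematous) pixels
while rejecting none at 22 ms, i.e. it erodes exactly the tissue of interest.
Invalid pixels are excluded from both the numerator and denominator of every
area fraction and counted alongside it.  At the nominal SNR the Look-Locker
estimator is at the Cramér–Rao bound (empirical T1 SD 0.082 s vs CRLB
0.076 s), so map noise reflects the acquisition, not the fitter.

**FAIR-ASL perfusion (bpMBF).** Paired slice-selective ("control") and global
("tagged") inversions give two T1 maps; myocardial blood flow is

MBF = 60 · (λ / T1_blood) · (T1_global / T1_selective − 1)   [ml/g/min]

with λ = 0.95 ml/g the blood–tissue water partition coefficient and T1_blood
the median global-inversion T1 over the blood-pool ROI (configured default
2.4 s at 9.4 T when no ROI is available; the value actually used and its
provenance are recorded).  Negative pixels are retained — clipping would bias
the downstream SD-threshold statistics — and counted in QC.  The formula
lives in one function so an alternative quantification can be swapped in.

## Regional quantification

Normal-tissue statistics (mean, sample SD) are taken over the valid
myocardium of the **second-from-most-basal slice** (slices ordered
apex → base, index n−2), which is remote from the occluded territory in this
model.  Pixels strictly beyond mean ± k·SD are flagged:

| metric | map | rule |
|---|---|---|
| AAR/LV% | T2 | > mean + 1·SD |
| AAR/LV% | T1 (global) | > mean + 1·SD |
| AAR/LV% | perfusion | < mean − 1·SD |
| IS/LV%  | perfusion | < mean − 2·SD |
| IS/LV%  | LGE | > remote mean + 5·SD |

Area fractions are 100 × flagged / valid myocardial pixels over all slices.
The LGE rule is a transparent SD-based stand-in for the commercial automated
delineation used in practice (k_lge configurable).  Histology is label-image
planimetry: IS/LV%, AAR/LV%, IS/AAR% by pixel counting.

**Minimum feature size.** Flagged islands smaller than 25 px (1 mm² at
200 µm resolution) are discarded and enclosed unflagged holes smaller than
the same area filled, per slice.  This is load-bearing: a pure per-pixel
mean + 1·SD cut flags P(Z>1) ≈ 15.9% of perfectly normal tissue *at any
SNR* — the rule is scale-free in the noise — which would inflate AAR/LV% by
≈ 0.16 × remote fraction (~5 points here), contradicting the near-zero
biases the per-animal-calibrated method is designed to achieve.  Genuine
lesions are large contiguous regions; sub-millimetre islands are noise.
Both operations are monotone, so the 2 SD mask remains nested in the 1 SD
mask, and both are exact on noiseless phantoms.  Candidate rules
(3×3 opening, opening-by-reconstruction, island removal with/without hole
filling) were compared on noiseless fidelity and residual bias at nominal
SNR on a design cohort; opening erodes jagged sector edges (−0.2 to −3.5
points), while the chosen rule leaves |bias| ≲ 0.35 points on every
modality.  Set `min_feature_px = 0` for the raw per-pixel rule.

Residual boundary-layer systematics of ±0.1–0.35 points remain and are
irreducible without eroding the true lesion edge: flagged remote pixels
directly adjacent to the detected region occur at the 15.9% rate and attach
to it.  Because the phantom's only stochasticity is thermal noise, per-animal
estimator scatter is ~0.1 points, so a paired t test at n = 10 can flag these
sub-half-point biases as "significant" even though they are an order of
magnitude inside the ±3-point accuracy envelope.  Real cohorts, with
biological scatter of several points, would not resolve them.

## The phantom cohort

Each animal is an annular LV myocardium around a blood-pool disk on a
128×128 grid: 7 slices for the T2/LGE/histology context, 6 for ASL.
Apical/mid slices use a 10–20 px annulus; the two most basal slices a
smaller 8–14 px annulus (the short-axis plane near the base intersects the
outflow tract and carries less in-plane myocardium); both basal slices are
always outside the AAR span so the normal-ROI slice is genuinely remote.
The AAR is a contiguous transmural angular sector across the apical/mid
slices, realized by ranking span-slice myocardial pixels by angular distance
from a per-animal random sector centre and taking exactly the count that
matches the target AAR/LV fraction (quantization ≪ the 2/√N bound).  The
infarct and the edema mask are nested prefixes of the same ranking, so
infarct ⊆ edema ⊆ AAR by construction.

Tissue defaults (9.4 T mouse): remote T1/T2 1.55 s / 22 ms; edematous AAR
1.85 s / 35 ms; infarct 1.95 s / 38 ms with 3× LGE enhancement; blood T1
2.4 s.  Perfusion: remote 16.9 ml/g/min, salvaged AAR 8.0, infarct 3.0 — the
deficit spans the *full* AAR while elevated T2/T1 are confined to the edema
mask, which is the innermost `edema_extent_multiplier` fraction of the AAR
(1.0 everywhere except preconditioning-like groups, 0.85, the ratio of the
reported T2-derived to histology AAR under IPC).  The slice-selective
effective T1 is generated by inverting the bpMBF formula, which makes the
simulate → fit → quantify chain an exact closed loop on noiseless phantoms;
spin-transit and partial-volume physics are out of scope.

Noise is additive Gaussian with noise_sd = S0/20 (SNR 20) by default, with a
Rician magnitude mode available; IR series are stored as magnitude so the
polarity-restoration path is always exercised.  Cohort sampling per group:
AAR/LV ~ N(group mean, SD)/100 and IS/AAR ~ N(mean, SD)/100 truncated to
(0.05, 0.95) and clamped to 98% of the geometric sector capacity; normal
perfusion per animal ~ N(16.9, 0.8) (CsA 28.9 ± 11.1), truncated above the
deficit level.  All per-animal seeds derive from the cohort seed via
`numpy.random.SeedSequence`, making whole studies byte-reproducible.

The four default groups are control (n=6), IPC (n=10, edema extent 0.85),
vehicle (n=7) and CsA (n=9, elevated normal perfusion).

## What the phantom does and does not show

Passing tests demonstrate that the estimators are calibrated and the
thresholding logic reproduces the method's intended behaviour: unbiased AAR
and IS recovery in control-like conditions, underestimation by T2/T1 mapping
exactly proportional to the reduced edema extent, and insensitivity of the
perfusion-based AAR to both reduced edema and globally elevated normal
perfusion (the threshold is calibrated per animal).  The phantom has
region-constant tissue values, no intra-myocardial heterogeneity, no motion,
gating, coil-sensitivity or partial-volume effects, no transit-delay physics,
and histology is rendered as label images rather than stained photographs —
so agreement statistics on phantoms bound estimator error only, not
biological or registration variability.

Known structural behaviour: with zero noise the normal-ROI SD is zero, so
the 1 SD and 2 SD perfusion cuts coincide and the "2 SD infarct" equals the
full AAR; with a salvage deficit deeper than 2 SD of the normal ROI the 2 SD
rule overestimates IS under noise as well.  This mirrors the reported large
variability of the 2 SD threshold; the 1 SD AAR rule is the calibrated one.

## Numerical choices

Strict inequalities at thresholds (a pixel exactly at a cut is never
flagged).  Sample SD (ddof = 1) throughout.  Limits of agreement are the
classic bias ± 1.96·SD of paired differences; differences are method −
reference (CMR − histology).  Unpaired t tests pool variances by default
(Welch optional); Bonferroni multiplies pairwise p-values by the number of
pairwise comparisons, capped at 1.  Degenerate statistics resolve by limit:
all-zero paired differences give t = 0, p = 1; constant nonzero differences
give p = 0.  Simulated stacks are stored float32 so the on-disk and in-memory
paths are bit-identical.  Minimum normal-ROI size: 30 valid pixels.

## Problem sizes

Default studies run the full 128×128, 6–7-slice geometry (≈5,500 myocardial
pixels per animal) and the published group sizes (32 animals); a full
simulate → fit → quantify → compare study takes ~1.5 minutes on one CPU.
Unit tests use 64×64, 4-slice phantoms where geometry is not itself under
test.
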