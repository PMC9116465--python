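# Methods

## Descriptor model

The quality features rest on one perceptual premise: the human visual
system responds to *relative* intensity change (Weber's law, ΔI/I ≈
constant), and image degradation — blur, noise, contrast loss —
systematically reshapes the distribution of relative local change and
of local structure patterns.

**Differential excitation.** For every interior pixel of a 3×3
neighbourhood, `DE = arctan(Σ(x_i − x_c)/x_c)` with the sum over the 8
grid neighbours. The arctan bounds the unbounded contrast ratio in
[−π/2, π/2] and removes numerical blow-up near small centers. DE is
exactly invariant to multiplying the image by a positive constant — it
measures contrast, not brightness. Blur drains high-|DE| mass toward
zero; this is the monotone statistic the model keys on, and it is
asserted as a test.

**LBP^riu2.** The rotation-invariant uniform local binary pattern at
P = 8, R = 1 assigns each pixel the count of neighbours ≥ center when
the circular bit string has at most two transitions, and the overflow
code P+1 otherwise — 10 codes (0–9). The joint 10×10 relative-frequency
histogram of (LBP code, |DE| bin over [0, π/2]) gives 100 features per
scale tying structure patterns to variation strength.

**WB-LTP.** A local ternary pattern whose three-way test uses relative
contrast: neighbour i codes +1 if (g_i − g_c)/g_c > t, −1 if < −t, else
0 (the tie |Δ|/g_c = t codes 0). The +1 and −1 codes are binary-weighted
into 8-bit *up* and *low* channels and combined into a magnitude
channel √(up² + low²) (so magnitude ≥ max(up, low) pointwise). The
threshold adapts to the image: t = tan(mean |DE|)/256, i.e. regions
above the image's own average variation intensity count as "high
variation". Each channel yields a 15-bin histogram (up/low over
[0, 255], magnitude over [0, 255√2]) and a Shannon entropy over integer
levels (the magnitude is rounded to the nearest level first); entropies
are in [0, 8] bits and zero exactly for constant channels.

**Multi-scale assembly.** The inscribed square of the circular field of
view (side ⌊r√2⌋, centered on pixel centers so every crop pixel lies
inside the circle) is offset by +1 once — this single offset serves
both ratio-based descriptors — then processed at three scales: the
original crop and two 2×2-mean-pooled halvings. The Weber threshold is
computed once at the original scale and halved per scale (t_s = t/2^s),
matching the halving of spatial frequency content; DE and LBP maps are
recomputed on each level. Per-scale layout is frozen as
[100 DE-LBP | 15 up | 15 low | 15 mag | E_up | E_low | E_mag]
(148 entries), scales ordered fine-to-coarse (s = 0, 1, 2), 444 total.
Descriptors are computed only where the full neighbourhood exists (maps
shrink by R per side); padding would fabricate border texture.

## Parameters

| parameter | default | meaning |
|---|---|---|
| P, R | 8, 1 | LBP/LTP neighbourhood (8 grid neighbours; bilinear circle sampling for other (P, R)) |
| M, N | 10, 10 | joint-histogram bins; M = P + 2 riu2 codes |
| n_bins | 15 | WB-LTP channel histogram bins |
| n_scales | 3 | pyramid depth; feature length = n_scales · (M·N + 3·n_bins + 3) |
| C, γ grid | 2^−5…2^15, 2^−15…2^3 (log-2 steps of 2) | the canonical practical-guide RBF-SVR grid |
| ε | 0.1 | SVR tube half-width |
| inner CV | 5-fold, selection by mean validation SROCC | aligns model selection with the headline rank criterion |

Feature scaling is per-dimension min-max to [−1, 1], fitted on the
training partition only (RBF kernels need comparable scales; fitting on
test rows would leak, and a test asserts it does not happen).

## Evaluation protocol

SROCC uses midranks for ties. PLCC and RMSE are computed after fitting
the monotone 5-parameter logistic-plus-affine family
f(x) = β₁(1/2 − 1/(1+exp(β₂(x−β₃)))) + β₄x + β₅ by least squares;
initialization is β₁ = range(MOS)·sign(corr), β₂ = 1/std(pred),
β₃ = mean(pred), (β₄, β₅) from a linear pre-fit. Levenberg–Marquardt,
trust-region-reflective and dogbox solvers are tried in turn (each
capped at 2·10⁴ evaluations, tolerances 10⁻⁸) and the converged fit
with the smallest residual is kept; if none converges the identity
mapping is used and flagged. Identity and affine relations are inside
the family, so calibrated predictions fit with zero residual
(asserted).

Repeated evaluation draws train/test splits from a seeded generator:
train size = round(train_frac·n), remainder tested; medians and
sample STDs over repeats are reported, and the split sequence is
replayable by seed so competing feature sets can share identical
splits. The default repeat count is 1000; the test suite and the
acceptance script use 50, which stabilizes the median to well within
the reported STD at this sample size.

Method comparison uses the corrected resampled paired t-test:
t = mean(d)/√(var(d)·(1/K + n_test/n_train)) over K paired per-repeat
differences, two-sided with K−1 degrees of freedom at 95% confidence;
the n_test/n_train inflation compensates for overlapping resampled
training sets (the corrected statistic is never larger in magnitude
than the plain paired t, asserted). The pairwise significance matrix is
antisymmetric with entries {1, −1, 0}. By default the test is applied
to SROCC vectors; other criteria can be passed explicitly.

## Synthetic study

The generator emulates circular-field-of-view confocal frames: a field
of soft-edged elliptical blobs (quartic-falloff plateaus, ~1.2 blobs
per 1000 px², radii 3–12 px, 30% dark) over a low background, masked
to a centered circle (default 0.95 of the half-size) with a black
surround, quantized to 8 bits. Distortion ladders cover defocus blur
(Gaussian σ up to 4 px), motion blur (line kernel up to 15 px), additive
Gaussian noise (σ up to 25 gray levels), contrast compression toward
the FOV mean (gain down to 0.2), and a mixed cascade with fixed
component fractions blur(0.7s) → noise(0.5s) → contrast(0.6s). Fixed
fractions — rather than per-image random component weights — keep the
effective degradation monotone in nominal severity; random weights
would decouple the label from the realized distortion and make even a
perfect model mis-rank mixed ladders. Severity 0 is bit-exact identity.

Pseudo-MOS simulates eight raters: the mean of 8 draws from
N(5 − 4·severity, (0.25·√8)²) clipped to [1, 5], so the label noise SD
is 0.25 MOS units; an optional filter drops items whose simulated rater
STD exceeds 1.5, mirroring subjective-study screening.

What passing the end-to-end tests shows: the descriptor set orders
*these* parametric degradations of blob textures and supports SROCC
≈ 0.95 at n = 200. What it does not show: performance on real tissue
(fiber-bundle honeycomb structure, content variability between tissue
types, authentic mixed distortions, rater behaviour), where reported
correlations for descriptor-based NR-IQA are substantially lower. The
phantoms make no biological-realism claim; they exist to give the
descriptors non-trivial texture statistics.

## Numerical and design choices

- **|DE| convention:** the joint-histogram axis and the threshold mean
  both use absolute DE. This matches how DE maps are visualized,
  guarantees t ≥ 0, and prevents cancellation between bright- and
  dark-going variation.
- **Global +1 offset:** applied once to the crop before any ratio; a
  zero-valued center otherwise makes both DE and the ternary test
  unstable. Descriptor functions reject non-positive centers so the
  contract is explicit.
- **Grid neighbours at R = 1:** interpolating the diagonal samples onto
  the unit circle (the generic LBP convention) was rejected for the
  default configuration; the 8 grid neighbours are the natural 3×3
  neighbourhood shared with DE. General (P, R) uses bilinear sampling
  at angles 2πi/P.
- **Downsampling:** 2×2 mean pooling — parameter-free, exactly
  reproducible, and alias-suppressing for factor 2.
- **Histogram normalization:** all histograms are per-image relative
  frequencies (sum 1), making features independent of crop size.
- **FOV detection:** default is the largest circle inscribed in the
  bounding box of above-threshold pixels, falling back to the centered
  circle of radius min(H, W)/2; instrument-specific detection is out of
  scope.
- **Ties:** |ratio| exactly equal to t codes 0; neighbour equal to
  center codes 1 in LBP (the ≥ convention).
- **Model persistence:** a versioned joblib payload embedding the
  feature-layout fingerprint (hash of the ordered feature names);
  prediction refuses mismatched layouts or widths.

## Problem sizes

The packaged study uses 40 phantoms × 5 severities (200 images,
256² rasters, 171² crops) and 50 evaluation repeats with the full
11 × 10 hyperparameter grid — chosen as the smallest design at which
the median criteria are stable across seeds while the whole pipeline
remains a desk-scale computation.

## Known limitations

- Severity ladders share one phantom across severities; splits in
  `repeated_split_eval` are drawn per image, so training and test
  partitions can contain different distortions of the same phantom.
  The ladder-monotonicity check, which holds out whole phantoms, is the
  content-independent complement.
- The logistic fit can be ill-conditioned for small test partitions
  (< 10 points); PLCC/RMSE on such partitions should be read with care.
- `pattern_entropy` of the magnitude channel spans up to 362 levels, so
  its theoretical maximum slightly exceeds 8 bits; in practice observed
  values stay far below it.
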