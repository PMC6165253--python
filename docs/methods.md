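# Methods

## Polarimetric data model

A quad-pol pixel is summarised by the lexicographic covariance matrix
C₃ = ⟨k k†⟩ with k = (S_HH, √2·S_HV, S_VV), Hermitian positive semidefinite,
averaged over L looks. `C3Field` enforces Hermitian symmetry to 1e-9
relative, clips diagonal noise below 1e-12 to zero, and carries L and a
validity mask. Coherency (Pauli-basis) input is converted by the fixed
unitary in `t3_to_c3`; the trace (total power, Span) is preserved to 1e-10.

## Polarization-basis intensity transform

The nine real parameters of C₃ are mapped to nine backscatter intensities
DN_pq = ⟨|qᵀ S p|²⟩ for the state pairs (hh, vv, ++45, −−45, ll, rr, h+45,
hl, +45l), with Jones vectors h=(1,0), v=(0,1), ±45=(1,±1)/√2,
l=(1,i)/√2, r=(1,−i)/√2 in the backscatter alignment convention. Writing
the received amplitude as a linear form in k gives DN = u† C₃ u with
u = conj(q₁p₁, (q₁p₂+q₂p₁)/√2, q₂p₂); stacking the nine forms yields the
9×9 matrix **M**, constructed *analytically* at import time rather than
transcribed from a printed table (historic typesettings of this matrix are
ambiguous), and verified invertible with M·M⁻¹ = I to 1e-10. The physical
1/(4π) antenna prefactor is carried as a single documented `scale` constant
(default 1): it cancels in dB differences, min–max normalization, PCA and
both classifiers, so no downstream result depends on it. For any PSD input
all nine intensities are non-negative; values below −1e-9·Span raise a
warning counter and are clipped.

dB conversion σ = 10·log₁₀(P) uses a floor of −50 dB for non-positive
intensities so that feature normalization always sees finite values. The
floor is configurable; −50 dB sits far below any speckle realisation of the
scene scales used here.

## Yamaguchi four-component decomposition

Span = Ps + Pd + Pv + Pc is decomposed per pixel following the
four-component scheme with helix extension:

* helix: Pc = f_c = 2·|Im(⟨S_HH S_HV*⟩ + ⟨S_HV S_VV*⟩)|, capped at
  2⟨|S_HV|²⟩ so the remaining cross-pol power is non-negative;
* volume: the model covariance is chosen by the co-pol ratio
  10·log₁₀(⟨|S_VV|²⟩/⟨|S_HH|²⟩) with branches below −2 dB / within ±2 dB /
  above +2 dB, and f_v is sized so the volume term absorbs *all* remaining
  cross-pol power — this makes the surface/double system exactly
  2-dimensional and the power balance exact rather than approximate;
* surface/double: with remaining moments s₁₁, s₃₃, s₁₃, the sign of
  Re(s₁₃) selects α = −1 (surface-dominant) or β = +1 (double-dominant);
  the quadratic then gives f_d = (s₁₁s₃₃ − |s₁₃|²)/(s₁₁+s₃₃+2Re s₁₃) (or
  the mirrored form), and Ps + Pd = s₁₁ + s₃₃ identically;
* negative Ps or Pd is clipped to zero with the deficit reassigned to the
  partner term; Pv is capped at Span − Pc. After these steps
  Ps + Pd + Pv + Pc = Span holds to floating-point rounding on every pixel
  (tested at 1e-6 relative).

Non-PSD pixels (minimum eigenvalue below −1e-9·Span) are masked and
counted, not silently decomposed.

## Optical features

NDVI is (NIR−R)/(NIR+R) with zero-denominator pixels masked. The entropy
texture quantises a band into 32 equal-width bins over its global valid
min–max and computes −Σ pᵢ log₂ pᵢ of the bin proportions in a centred 7×7
window with reflection padding (implemented as box filters over bin
indicator rasters, so the histogram is exact). Window size, bin count and
the band (default R) are config-exposed; no published values exist for
them, so the defaults are ordinary texture-analysis choices and raster
values are not claimed to match any particular prior product. Band PCA
mean-centers but does not rescale the four reflectance bands (shared
units); a config flag enables standardization.

## PCA and feature integration

Both PCA reductions (σ⃗ channels, optical bands) keep the smallest leading
component set whose cumulative explained variance reaches the threshold —
0.98 for SAR, 0.99 for optical, matching the variance fractions the method
was designed around — with component signs fixed so each component's
largest-magnitude loading is positive (deterministic orientation). The
number of kept components is data-driven, with a floor of two inside the
pipeline because the integration modes name two PCA layers each. PCA on the
SAR side operates on the dB values (after the log transform), and
normalization follows PCA: dB → PCA → min–max. Min–max statistics computed
on a training scene can be reused on prediction scenes via
`minmax_normalize(stats=...)` to avoid leakage; a robust mode uses 1st/99th
percentiles with clipping.

The three integration modes are fixed layer lists:
`full` = (σ_pca1, σ_pca2, RVI, Ps, Pd, Ph, Pv) + (Opband_pca1, Opband_pca2,
NDVI, H); `sar7_opt2` keeps only NDVI and H on the optical side;
`sar5_opt4` drops the σ-PCA layers. `sar_only` / `optical_only` stacks are
provided for the comparison experiments. Masks are conservative: a pixel
invalid in any contributing layer is invalid in the stack.

## Classifiers

The complex-Wishart ML rule uses d_m(C) = ln det Σ_m + tr(Σ_m⁻¹ C) with
Σ_m the per-class arithmetic mean of training covariances (the Wishart
MLE); singular means receive ε = 1e-9·mean(Span) on the diagonal. Ties
break to the lowest class id; non-finite distances yield nodata and are
counted. The distance is invariant (up to a class-independent additive
constant) under a common scaling of C and all Σ_m, so classification does
not depend on radiometric scale — this is tested.

The SVM is scikit-learn's `SVC` with an RBF kernel; C ∈ {0.1, 1, 10, 100}
and γ ∈ {0.01, 0.1, 1, 10} are chosen by 5-fold cross-validated accuracy
(deterministic, unshuffled folds), and the chosen values are logged and
stored. Training is per-pixel; field/plot ids are kept on the training set
so grouped CV can be added later. Prediction aligns stack layers to
training layers *by name*, so layer order is irrelevant and genuine
mismatches raise with the differing names listed. Large training sets are
optionally subsampled per class (seeded) to bound fit cost; the pipeline
default is 600 pixels per class.

## Accuracy assessment

Confusion matrices use rows = classified, columns = reference (UA on rows,
PA on columns); conventions vary in the literature, so this is fixed and
documented here. OA = trace/total; κ = (P_o − P_e)/(1 − P_e) with
P_e = Σ row_i·col_i / total². One-vs-rest rates per class: TP = PA,
FN = 1 − PA, FP = (row − diag)/(total − col), TN = 1 − FP, so TP+FN = 1 and
TN+FP = 1 identically. Classes with an empty row or column get NaN UA/PA
and are listed in `undefined` instead of poisoning the report. Percentages
print to 2 decimals; internal values keep full precision.

The shipped reference table (`data/dongting_confusion.csv`) is the
published eight-class crop-survey confusion matrix over the Dongting Lake
basin; `metrics` reproduces its printed OA (85.2745 %), κ (0.8306) and all
UA/PA to the printed decimals. Two known internal inconsistencies of the
published numbers are preserved as printed rather than "repaired": the
Watermelon and Forest column sums fall 6 and 4 pixels short of the
published per-class testing-pixel counts (the other six classes match
exactly), and the prose claim of a >54 % misclassification rate for
two-season rice does not match 100 − UA = 51.02 % from the table.

## Scene simulator

`generate_scene` tiles the scene into a rectangular field mosaic (exact
area control, trivially correct ground truth), assigns classes to fields
in a balanced seeded shuffle, and draws each pixel's C₃ as (1/L)·Σ z_k z_k†
with z_k ~ CN(0, Σ_class) — i.e. exactly complex-Wishart multilook speckle,
so intensity CV = 1/√L — and optical reflectances as Gaussians truncated to
[0, 1]. SAR and optical draws are independent by default (the two sensors
are treated as complementary); training and testing pixels are disjoint *by
field*, not just by pixel.

The default preset has four classes at L = 9 on a 160×160 grid of 8×8
fields (four training fields per class): two rice stages share their
optical statistics and differ only in the sign of Im⟨S_HH S_VV*⟩ — a
difference invisible to RVI, Span and the Yamaguchi powers but visible in
the mixed-basis intensity channel (+45, l), hence to σ-PCA; lotus and grass
share one covariance and their R/NIR means (identical NDVI) and differ only
in G/B, visible only to optical band PCA. This makes multi-sensor
complementarity a *constructed property*: SAR-only and optical-only stacks
each top out near 63 % / 76 % OA while the full stack reaches ~88 %, and
the test suite asserts the ordering, not any fixed accuracy. What passing
these tests shows is that the pipeline extracts and combines exactly the
information each source carries; it does not certify accuracy on real
satellite scenes, whose texture, mixed pixels, registration error and
class overlap the simulator deliberately omits (no radiative-transfer
modelling, no spatial correlation of speckle, no SAR–optical correlation).

## Problem sizes and numerical choices

Simulated checks run at desk scale chosen as ordinary defaults for a
statistical emulator: 160×160 scenes for the integration experiments,
256×256 for the conservation sweep, n = 2000–20 000 draws for the moment
checks. Tolerances: basis-transform round trip 1e-10 relative; Yamaguchi
conservation 1e-6 relative; PCA orthonormality 1e-10; correlation of PCA
scores < 1e-8; Wishart covariance recovery < 5 % Frobenius at n = 2000,
L = 4 (a ~3σ CLT bound); speckle CV within 10 % of 1/√L at n = 10⁴.
Degenerate inputs are handled explicitly rather than propagated: zero-span
pixels are masked in RVI, constant bands give zero entropy with a warning,
zero-range layers normalize to zero, empty confusion overlap raises.

## Known limitations

* No polarimetric calibration, speckle filtering, co-registration or
  geocoding — inputs are assumed calibrated, filtered and on one grid.
* Raster I/O is plain TIFF + JSON sidecar; geographic metadata is carried
  as opaque sidecar fields only.
* The Wishart route ignores the optical data entirely, by design.
* The simulator's classes are internally homogeneous fields; no
  within-field gradients, boundaries or mixed pixels.
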