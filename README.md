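# polcropsar

Crop classification from integrated polarimetric SAR (PolSAR) and
multispectral optical imagery.

Quad-pol SAR and optical sensors see crops differently: the radar's 3×3
covariance matrix **C₃** encodes canopy structure, orientation and moisture
through multi-channel backscatter, while optical reflectances track leaf
pigment and water content. Combining them is awkward because a Hermitian
matrix per pixel does not stack with spectral bands. This package solves
that with the Hoekman polarization-basis transform: the nine real parameters
of C₃ are mapped, losslessly and linearly, to nine backscatter *intensities*
P⃗ on the linear (h, v), ±45° and left/right-circular polarization bases —
a nine-band image that integrates with optical bands like any other raster.

The pipeline, end to end:

1. **SAR features** — σ⃗ = 10·log₁₀ P⃗ (backscattering-coefficient form),
   PCA-reduced to σ_pca1, σ_pca2 (≥ 98 % of variance); the Yamaguchi
   four-component decomposition Span = Ps + Pd + Pv + Pc into surface,
   double-bounce, volume and helix power; and the radar vegetation index
   RVI = 8⟨|S_HV|²⟩ / Span ∈ [0, 4].
2. **Optical features** — band PCA (Opband_pca1, Opband_pca2, ≥ 99 % of
   variance), NDVI = (NIR − R)/(NIR + R), and a sliding-window Shannon
   entropy H as texture.
3. **Integration** — all features min–max normalized to [0, 1] and stacked
   in one of three modes: `full` (7 SAR + 4 optical layers), `sar7_opt2`
   (NDVI and H only on the optical side) or `sar5_opt4` (no σ-PCA layers).
4. **Classification** — an RBF-kernel SVM (hyperparameters by 5-fold CV over
   a log grid), or, directly on C₃, the complex-Wishart maximum-likelihood
   rule argmin_m [ln det Σ_m + tr(Σ_m⁻¹ C)].
5. **Assessment** — confusion matrix (rows = classified, columns =
   reference) with overall accuracy, kappa, per-class user's/producer's
   accuracy and one-vs-rest TP/FN/TN/FP rates.

A seeded simulator generates labeled scenes with the statistics the
pipeline assumes — complex-Wishart multilook speckle around class
covariances on a rectangular field mosaic, truncated-Gaussian reflectances —
so every stage is testable without satellite downloads.

## Worked example

```python
from polcropsar import load_reference_confusion, metrics, PipelineConfig, run_pipeline

# accuracy statistics of the shipped eight-class Dongting Lake reference table
rep = metrics(load_reference_confusion())
print(f"OA    = {100 * rep.overall_accuracy:.4f} %")
print(f"kappa = {rep.kappa:.4f}")
print(f"UA(Water) = {100 * rep.user_accuracy['Water']:.2f} %  "
      f"PA(Forest) = {100 * rep.producer_accuracy['Forest']:.2f} %")

# full pipeline on a simulated four-class scene
result = run_pipeline(PipelineConfig(mode="full", seed=42), output_dir="demo_out")
print(f"simulated scene, full 11-layer stack: "
      f"OA = {result.report.overall_accuracy:.4f}, kappa = {result.report.kappa:.4f}")
```

prints

```
OA    = 85.2745 %
kappa = 0.8306
UA(Water) = 99.28 %  PA(Forest) = 63.14 %
simulated scene, full 11-layer stack: OA = 0.8809, kappa = 0.8413
```

The first block recomputes every statistic of the reference crop-survey
confusion table from its raw pixel counts: 85.27 % of the 1.37 M test pixels
are classified correctly, with chance-corrected agreement κ = 0.83; water is
almost never over-mapped (UA 99.28 %) while forest is frequently omitted
(PA 63.14 %). The second block simulates a 160×160 four-class scene
(two rice stages separable only polarimetrically, lotus/grass only
spectrally), extracts and integrates all eleven layers, trains the SVM on
field-disjoint training pixels and scores the held-out fields: the
integrated stack reaches OA 0.88 where either sensor alone stays near 0.63
(SAR) / 0.76 (optical).

The same flows are scriptable from the shell:

```bash
polcropsar simulate --seed 42 --out scene/
polcropsar run --config config.yaml --out results/
```

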