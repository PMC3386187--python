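# ilpci

Simulation and texture analysis of in-line (propagation-based) X-ray
phase-contrast projection images of liver tumors.

## The problem

In-line phase-contrast imaging (ILPCI) records the intensity of a coherent
X-ray beam after free-space propagation: phase gradients acquired in the
sample turn into measurable edge enhancement at the detector, making soft
tissue — normal liver parenchyma, implanted tumors, necrotic cores, small
vessels — visible without contrast agents.  A practical analysis question is
whether the *texture* of such projections suffices to (a) tell tumor tissue
from normal parenchyma and (b) grade a tumor's age.  Because the original
animal images of this kind were never publicly deposited, this package
provides a fully synthetic, ground-truthed re-implementation of that whole
analysis chain, usable both as a simulation laboratory and as a reusable
texture-analysis toolkit for user-supplied grayscale TIFFs.

It is aimed at researchers in biomedical image analysis who want a
reproducible end-to-end pipeline: phantom → wave optics → detector →
ROIs → texture features → discriminant → classifier, with every stage
individually importable.

## The model

**Forward optics.** A monochromatic plane wave (default 15 keV) crosses a
thin object described by per-material projected thicknesses `t_m(x,y)`:

    phi(x,y) = -k Σ_m δ_m t_m(x,y),      I0(x,y) = exp(-2k Σ_m β_m t_m(x,y))

with `n = 1 - δ + iβ` the complex refractive index and `k = 2π/λ`.  The exit
wave `√I0 · e^{iφ}` is propagated a distance `z` (default 0.5 m) with the
paraxial Fresnel transfer function `H(u,v) = e^{ikz} e^{-iπλz(u²+v²)}`; for
weak objects the near-field intensity linearizes to the transport-of-intensity
form

    I ≈ I0 · (1 - (λz/2π) ∇²φ),

i.e. contrast proportional to the Laplacian of the phase — the edge
enhancement characteristic of ILPCI.  A detector model adds Gaussian PSF
blur, Poisson shot noise and 16-bit quantization (9 µm pixels by default).

**Phantoms.** Staged liver phantoms ("6d", "9d", "12d", "15d") emulate tumor
progression: diffuse fine-grained tumor texture at day 6; necrotic lumps of
growing number density and radius (with sharp, edge-enhancing boundaries) plus
adjacent curvilinear vessels at days 9–15.  Every scene carries ground-truth
region masks and a lump census, and is bit-reproducible from one seed.

**Texture.** From 60×60-pixel ROIs (20 per region, as in the emulated study
protocol) the package computes gray-level co-occurrence matrices `C_ij`
(per-ROI min–max quantization to 16 levels, distance-1 offsets averaged over
0°/45°/90°/135°) and nine Haralick-type features: angular second moment,
inertia, inverse difference moment, entropy, correlation, sum average,
difference average, sum entropy, difference entropy.  A 2-level dual-tree
complex wavelet transform (implemented in-package: CDF 9/7 level-1 pair,
lattice-designed 14-tap quarter-shift filters above, exactly invertible,
level-1 energy exactly 1-px-shift invariant) yields four subband images
(HF1, HF2, LF1, LF2) whose textures are re-extracted the same way.

**Statistics.** Per stage, the standardized 9-feature matrix is
eigendecomposed on its correlation matrix; components with cumulative
contribution rate `CR_i = λ_i/Σλ ≥ 80%` are retained, signs oriented so the
normal group's mean is positive, and the discriminant reads **F1 > 0 →
normal, F1 < 0 → tumor**.  Tumor LF1 textures pooled across stages feed a
stratified 5-fold cross-validated RBF SVM over a small (C, γ) grid for
staging, reported against a label-permutation chance baseline.

## Worked example

```bash
python examples/02_glcm_discriminant.py
```

prints (one simulated projection per stage, 20+20 ROIs each):

```
 stage        normal F1         tumor F1     CR1   agree
    6d +2.474 +- 0.992 -2.474 +- 0.742  78.1% 100.0%
    9d +1.943 +- 1.528 -1.943 +- 0.718  58.4%  97.5%
   12d +2.362 +- 1.317 -2.362 +- 0.565  74.7%  97.5%
   15d +2.133 +- 1.754 -2.133 +- 0.430  69.5% 100.0%
```

Normal-region F1 scores are positive and tumor-region scores negative at
every stage, so the sign of the first principal component alone recovers the
ground-truth region label for ≥ 97% of ROIs here.  `CR1` is the share of
standardized texture variance carried by F1; `agree` the fraction of ROIs
whose F1 sign matches the mask.  Likewise:

```bash
python examples/04_stage_trend.py
```

```
stage   6d: LF1 first-PC tumor mean -2.521
stage   9d: LF1 first-PC tumor mean -0.612
stage  12d: LF1 first-PC tumor mean +1.173
stage  15d: LF1 first-PC tumor mean +1.960
Spearman rho vs stage order: +1.00
```

— the low-frequency wavelet texture score rises strictly with tumor age, and
`examples/05_svm_staging.py` stages the same ROIs at 73.8% CV accuracy
against a 22.5% shuffled-label baseline.  The other examples cover the
wave-optics simulation (`01`) and the dual-tree decomposition itself (`03`).

A command-line interface wraps the same pipeline:

```bash
ilpci run --config pipeline.toml --out runs/exp1     # full pipeline
ilpci simulate --out dataset --seed 0                # images + masks + manifest
ilpci texture --rois rois.csv --ng 16 --out features.csv
```

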