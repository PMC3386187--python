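# Methods

This note documents the models, parameter choices and numerical decisions
behind `ilpci`, and what the synthetic experiments do and do not establish.

## Wave-optics forward model

Illumination is a monochromatic plane wave; partial coherence and source
size are not modeled explicitly but folded into the detector PSF.  The
object is thin (projection approximation): each material contributes phase
`-k δ_m t_m` and attenuation `2k β_m t_m` along the beam, with `t_m` the
projected thickness in meters.  Free-space propagation uses the paraxial
Fresnel transfer function `exp(ikz)·exp(-iπλz(u²+v²))` evaluated on the
periodic FFT grid.  Consequences of that choice:

* **Unitarity** — pure-phase objects conserve total intensity to machine
  precision (asserted in tests at 1e-9 relative).
* **Aliasing guard** — when the chirp phase at the Nyquist frequency
  exceeds π (i.e. `z > 1/(λ u_max²)`, about 3.9 m at 15 keV and 9 µm
  pixels), a warning reports the maximum alias-free distance.  The default
  z = 0.5 m is deep inside the safe region.
* **Periodic boundaries** — the linearized transport-of-intensity (TIE)
  operator uses a 5-point finite-difference Laplacian with *periodic*
  wrapping so its implicit boundary model matches the Fourier propagator's.

The TIE image `I0(1 - (λz/2π)∇²φ)` is first-order in the phase; it can go
negative at the strongest edges, where it is clipped at zero with a logged
count.  Tests verify the closed-form center contrast of a weak Gaussian
phase bump (`1 + (λz/π)φ0/σ²`) to 1% and that the Fresnel↔TIE RMS
discrepancy decreases monotonically as the phase amplitude halves — i.e.
the two routes agree exactly in the weak-object limit, which is the regime
the texture pipeline operates in.

Optical constants default to water-like soft tissue at 15 keV
(δ ≈ 1.0e-6 from `δ = r_e λ² n_e / 2π`; β ≈ 1.1e-9 from `β = µλ/4π` with
µ ≈ 1.7 cm⁻¹), with small density offsets for viable tumor (+5%), necrotic
material (+12%) and blood (+3%).  True rodent-liver constants at 15 keV
are not tabulated to this granularity anywhere authoritative; only the
*contrast ordering* matters for the texture analysis, and all values are
configurable.

## Synthetic phantoms: what they emulate

Each phantom is a 1024×1024 grid at 9 µm pixels (≈ 9.2 mm field), matching
the default detector.  An irregular ellipse (radius perturbed by a low-order
Fourier series) forms the liver; a second irregular ellipse (~25% of the
liver area) the tumor.  Texture model, per region:

* **Normal parenchyma** — elliptical-cap dome (2 mm peak thickness) plus a
  correlated Gaussian field: correlation length 4 px, amplitude 10 µm.
  At the default geometry this produces phase-contrast texture a few times
  above shot noise — visibly textured but smooth.
* **Tumor, day 6** — fine-grained correlated field (correlation length
  1.2 px, amplitude 12 µm) on a 200 µm base plate: diffuse, strongly
  contrasting micro-texture, no lumps.
* **Tumor, days 9/12/15** — the same fine grain plus necrotic lumps:
  spherical-cap thickness profiles placed uniformly inside the tumor with
  number density {0.8, 1.2, 1.6}·10⁻³ per px² and mean radius {4, 6, 9} px
  (sd 20%).  Necrotic coverage of the tumor thus rises from ~4% (day 9) to
  ~40% (day 15), and both the lump count and the mean radius are
  non-decreasing in stage for every seed (a tested invariant).  One or two
  random-walk vessels (Gaussian tube profile, 60 µm) start at the tumor
  boundary from day 9 on.

The detector applies a 0.6 px Gaussian PSF, Poisson noise at 5·10⁴ expected
photons/pixel (relative noise ~0.45%, a plausible synchrotron exposure) and
per-frame min–max 16-bit quantization.

**What this does not emulate:** anatomically realistic liver lobes or
vascular trees, beam-hardening/polychromaticity, partial coherence, detector
point-spread tails, scatter, or the matrix-stitching of large samples.
Passing tests therefore demonstrate that the *analysis chain* behaves as
designed under controlled, favorable contrast conditions; they do not
establish clinical-grade performance on real projections, where effect
sizes, artifacts and anatomy are less cooperative.

## ROI protocol and co-occurrence features

ROIs are 60×60 px, 20 per region per image, placed uniformly over all
origins whose square lies fully inside the region mask (integral-image
test).  Overlap is allowed by default, mirroring an operator clicking
freely; a disjoint mode (rejection sampling, 10 000-try cap, capacity error
reporting the feasible count) is available.

Quantization is per-ROI min–max to Ng = 16 levels
(`level = ⌊(v-min)/(max-min)·Ng⌋`, max ↦ Ng-1, constant ROI ↦ 0).  Per-ROI
scaling makes features invariant to local illumination; 16 levels keeps
60×60-pixel co-occurrence estimates well populated (≈ 14 pairs per matrix
cell on average).  The GLCM counts all ordered in-bounds pairs at one
offset, symmetrized by adding the transpose and normalized to sum 1.
Four distance-1 offsets (0°, 45°, 90°, 135°) are computed and the nine
features averaged across them — rotation-fair and standard practice when
no orientation protocol is prescribed.  Entropies use the natural log (the
base only rescales a feature and is absorbed by standardization).  The
correlation feature is defined as 0 when a marginal sd vanishes, so
degenerate ROIs cannot poison downstream PCA.

All nine features are verified against an independent double-loop
reference to 1e-12 on hundreds of random cases, against hand-computed
closed forms (constant patch, binary checkerboard), and the raw matrix
against `skimage.feature.graycomatrix`.

## Dual-tree complex wavelet transform

No suitable dual-tree implementation being available as a dependency, the
transform is implemented here on top of PyWavelets:

* **Level 1** — CDF 9/7 biorthogonal pair in both trees, tree B delayed by
  one sample (implemented as a circular roll, consistent with the
  periodized DWT).
* **Levels ≥ 2** — a 14-tap orthonormal *quarter-shift* lowpass for tree A
  and its time reverse for tree B.  The filter comes from an in-package
  paraunitary-lattice designer (`ilpci.dtcwt.design_qshift`): any lattice
  angle vector yields an exactly orthonormal pair, and the angles are
  optimized (deterministic multistart Nelder–Mead/Powell) for stopband
  energy and a passband group delay of 6.25 samples.  The frozen design has
  orthonormality at machine precision, H0(π) ~ 1e-15 (the angle-sum
  constraint forces the DC gain √2 exactly, hence an exact Nyquist zero),
  and group delay 6.25 ± 0.05 over the passband, so the two trees differ by
  half a sample at every scale.
* The four (row-tree × column-tree) real subbands per detail type combine
  unitarily into six oriented complex subbands per level.  Because the
  combination is unitary and each tree is individually perfect-
  reconstructing, the inverse is exact (< 1e-8 asserted; ~1e-12 typical),
  and total level-1 complex magnitude energy is *exactly* invariant to
  1-pixel circular shifts — a structural property of the delayed-tree
  construction that the tests exploit as a sharp bound, comparing against
  a critically-sampled DWT which has no such invariance.

A 2-level decomposition yields four derived images: LF1/LF2 (mean of the
four tree scaling images per level) and HF1/HF2 (root-mean-square of the
six oriented magnitudes — orientation-fair, non-negative, and the natural
way to collapse six bands to "one high-frequency image per level").
Subband texture uses the same quantize + orientation-average machinery as
the raw ROIs.  Odd-sized inputs are padded by symmetric reflection and the
padding stripped on inversion.

## PCA discriminant

Feature matrices are standardized column-wise with sample (n−1) sds;
constant columns are dropped with a warning naming the feature.  The
correlation matrix is eigendecomposed; eigenvalues are clipped at zero
(roundoff can produce −1e-16) and contribution rates are `λ_i/Σλ`.
Components are selected by the smallest leading set with cumulative CR
≥ 80% — when CR1 alone reaches 80% this is exactly {F1}.

Eigenvector signs are arbitrary, so the package orients them explicitly:

* **With region labels** — flip so the *normal* group's mean score is ≥ 0,
  making the discriminant "F1 > 0 → normal, F1 < 0 → tumor" well defined
  (F1 = 0 resolves to normal; any fixed rule works on a measure-zero tie).
* **Without labels** (pooled tumor stage analysis) — flip so the loading on
  the inverse difference moment is ≥ 0.  IDM is the local-homogeneity
  feature; as necrotic lumps grow, the low-frequency subband becomes
  dominated by large uniform blobs, so homogeneity is the axis along which
  tumor texture coarsens.  Anchoring that loading positive makes the
  first score a signed coarseness axis that rises with tumor age,
  independent of any stage labels.  (The plain max-|loading| SVD convention
  is also available.)

Stage monotonicity is summarized by the Spearman rank correlation between
stage order and per-stage mean scores; ρ = 1 iff strictly increasing, tied
means fall back to midranks.

Per-stage fits (one PCA per stage image) are the default, with pooled
analysis used where scores must be comparable across stages (trend, SVM);
this mirrors a per-image mean ± sd reporting protocol.

## SVM staging

Tumor-ROI LF1 texture across all stages is pooled, standardized, reduced by
the CR rule, and the retained PC scores rescaled to unit variance (the
kernel-width grid assumes standardized inputs).  An RBF SVM
(one-vs-one) is evaluated by stratified 5-fold cross-validation over
C ∈ {0.1, 1, 10, 100} × γ ∈ {0.01, 0.1, 1}; the report carries the maximum
mean CV accuracy over the grid (a "maximum accuracy" figure presumes such a
search), the per-fold accuracies and pooled confusion matrix at the best
grid point, and a chance baseline computed on the same machinery with
labels permuted by the run seed.  Folds depend only on (n, labels, seed),
so reruns are identical.

## Determinism and problem sizes

Every stochastic step draws from `numpy.random.default_rng` seeded by a
per-item seed derived via SHA-256 from (master seed, stage, index, role),
kept below 2³¹; adding images to a config never perturbs earlier ones, and
the whole pipeline is byte-reproducible (tested at the CSV level).  The
test suite and the acceptance script run the full default conditions
(1024² phantoms, four stages, 20+20 ROIs) over seed suites of 10 and 5
respectively — sizes chosen to give stable suite-level statistics while
keeping a complete run in tens of seconds on one CPU.

## Known limitations

* The stage model is morphological, not biological: lump density/radius
  schedules are stylized, and day-6 vs day-9 differ only through sparse
  small lumps, which is why staging accuracy (~70–78%) sits well below the
  region discriminant's (~98%).
* The quarter-shift filter favors an accurate fractional delay over deep
  stopband attenuation (max stopband ripple ≈ −7 dB); good enough for
  texture aggregation and exact reconstruction, but not for applications
  needing strong band isolation at levels ≥ 2.
* The TIE route is provided for analysis and cross-validation of the
  propagator; the pipeline's images always come from the full Fresnel
  propagator, so linearization error never enters the features.
* `read_image` accepts only single-channel 8/16-bit grayscale TIFFs by
  design; RGB inputs must be converted explicitly by the user.
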