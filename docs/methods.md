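# Methods

This note documents the models, parameter choices and numerical
conventions behind `csfmarkers`, and what the synthetic-data tests do and
do not establish about real imaging data.

## Enhanced perivascular contrast and Frangi segmentation

Perivascular spaces are CSF-filled and therefore hypointense on
T1-weighted and hyperintense on T2-weighted images; the EPC image
`T1w / max(T2w, floor)` compounds both, making PVS dark tubular
structures inside white matter. The denominator floor defaults to
1e-6 × the in-mask median of T2w, purely to keep the ratio finite where
T2w underflows; in-mask EPC values are otherwise unaffected.

Vesselness at scale σ is computed from the eigenvalues of the Gaussian
Hessian, taken in millimetres on the smoothed image and γ-normalized with
γ = 1 (second derivatives multiplied by σ²) so that responses are
comparable across scales. With |λ1| ≤ |λ2| ≤ |λ3|:

- R_A = |λ2|/|λ3| separates plates from lines,
- R_B = |λ1|/√(|λ2 λ3|) separates blobs from lines,
- S = √(λ1² + λ2² + λ3²) is the second-order structure strength,

and V = (1 − exp(−R_A²/2α²)) · exp(−R_B²/2β²) · (1 − exp(−S²/2c²)), set
to zero where the dark-tube sign condition λ2, λ3 > 0 fails. Defaults
are α = β = 0.5 with c equal to half the maximum Hessian Frobenius norm.
Two readings of the c rule are possible; `csfmarkers` computes c **per
scale** within the analysis mask, which keeps the S-term adaptive to each
scale's response range. The final map is the maximum over scales. The
filter is applied to EPC directly (dark polarity), not to an inverted or
renormalized copy; a bright-structure mode exists for other modalities.
Gaussian derivative kernels are truncated at 6σ so flat regions stay
numerically flat (residual curvature ≲ 1e-6 of the intensity scale).

Scale sets are resolution- and target-size-dependent: for 0.8 mm
isotropic clinical input targeting 1–3 voxel wide PVS the default is
{0.4, 0.6, 0.8} mm; the phantom tests use {1.0, 1.4, 2.0} mm, matched to
their 1 mm voxels and ~2 mm tube radii (the Frangi response of a cylinder
of radius r peaks near σ ≈ r/√2).

Thresholding keeps a voxel when strictly more than p% of the positive
in-mask vesselness values are ≤ its own value (an empirical-CDF rule).
This makes percentile 100 yield an empty mask, guarantees nesting of
masks across percentiles, and behaves sensibly under heavy ties. The
percentile is deliberately a **required, reported** parameter rather than
a hidden constant: on real data it is an externally validated choice
(98.0 is the package default), while the phantom-recovery tests use 30.0
because on a noise-free phantom the positive-vesselness support is
already confined to the immediate neighbourhood of the tubes, so the
volume-matching operating point sits much lower in the positive-value
distribution. Both values are recorded in the output metadata of every
run.

## PVS morphometry

Connected components (26-connectivity by default) are measured
individually. The second-moment matrix of a component's voxel centers
(in mm, plus the 1/12·voxel² diagonal term of a uniform cube so
single-voxel components have finite extent) is converted to
equivalent-ellipsoid principal-axis lengths 4√eigenvalue; the diameter of
a component is the mean of the two minor lengths, i.e. the
cross-sectional width of a tube, which recovers 2r exactly for a
continuum cylinder. Components are assigned to the region holding the
plurality of their voxels, provided at least half the voxels are inside
it (ties break to the lexicographically smallest region key; components
majority-outside all regions are dropped and logged). Mean diameter is
averaged over components, not voxels. Count fraction is count per mm³ of
regional WM; volume fraction is dimensionless.

The canonical analysis set is fixed at the 28 bilateral Desikan-Killiany
WM regions grouped as frontal 11 / parietal 5 / temporal 8 / occipital 4;
the feature table enforces all 56 hemisphere-qualified masks and emits
168 columns in deterministic (lobe, region, hemisphere, metric) order.
Extra regions in a subject's metrics are ignored with a warning; missing
regions are an error naming subject and region.

## DTI-ALPS

ROI membership is by voxel-center distance (no partial volumes) for a
5 mm diameter sphere, which on a 1 mm grid centered on a voxel gives
exactly 81 voxels. Per hemisphere the index is
mean(D̄xx_proj, D̄xx_assoc) / mean(D̄yy_proj, D̄zz_assoc) with each bar an
ROI mean; hemispheric indices are computed first and then averaged (not
pooled across the four ROIs). The index is invariant under global
positive scaling of the tensor and swaps hemispheres under an x-mirror.
Off-diagonal tensor elements are accepted and ignored.

## Volumetrics

Two table dialects are auto-detected: a flat multi-subject TSV/CSV
(subject, structure, hemi, volume_mm3, etiv_mm3) and the single-subject
FreeSurfer `aseg.stats` format (eTIV from the `# Measure
EstimatedTotalIntraCranialVol` line, volumes from the
Left/Right-Lateral-Ventricle and choroid-plexus rows). Normalized volume
is volume/eTIV; values ≥ 1 are flagged as implausible in logs but not
rejected.

## Permutation regression

Every marker is analysed with y ~ 1 + group + age_c + group:age_c, group
coded 0/1 and age centered at the full-sample mean (recentering is
idempotent). Inference per term uses the Freedman–Lane scheme: fit the
model without the term, permute its residuals with a seeded generator,
add them back to the reduced-model fit, refit the full model, and compare
|t*| against the observed |t|. The sampled-permutation p-value is the
add-one estimator (1 + #{|t*| ≥ |t|})/(1 + B), two-sided, bounded below
by 1/(B+1); an exhaustive mode enumerates all n! orderings (n ≤ 8) and
returns the exact tail proportion including the identity. Observed β,
SE and t are ordinary least squares. A perfect fit (zero residual
variance) yields infinite |t| and the minimum attainable p. Subjects
missing an outcome are dropped listwise for that model only. Permutation
refits are fully vectorized (one (B × n) matrix product per term), which
is what makes the 1000-cohort calibration run take seconds rather than
hours. In multi-outcome runs each outcome receives a child seed spawned
from the run seed, so results are independent of analysis order.

Bonferroni families follow the study design convention: per-lobe
bilateral mask counts (22/10/16/8) — not masks × metrics — plus 0.025
for each paired volume family and 0.05 for the single ALPS index.
Significance is called against the unrounded α/n; the 3-significant-
figure values (0.00227, 0.00500, 0.00313, 0.00625) are display-only,
rounded half-up. Demographics use the classical equal-variance
two-sample t for continuous variables and a Pearson chi-square without
continuity correction for sex — the latter reproduces published 2×2
tables exactly, while reported t statistics are generally not
recoverable from rounded summary rows, so the t flavour is a documented
convention. The Shapiro–Wilk screen is advisory: it flags non-normal
outcomes at p < 0.05 but permutation inference proceeds regardless.

Lobar summaries report, per term, the percentage of uncorrected-
significant (p_perm < 0.05) region rows per lobe, denominated by that
term's significant rows and rounded to one decimal, plus an L/R tally.

## Synthetic data: what it emulates and what it does not

The phantom generator places cylinders of random orientation wholly
inside disjoint box "regions", rasterizes them by center-to-axis
distance, and assigns tube voxels T1-like 0.5 / T2-like 2.0 against a
background of 1.0/1.0 — reproducing only the contrast polarity of
CSF-filled PVS (dark on the ratio image, EPC 0.25 vs 1.0). Defaults:
96×48×48 grid at 1 mm, 4 regions, 3 tubes per region, radii 1.8–2.2 mm,
lengths 12–18 mm, pairwise axis separation ≥ 6 mm so counts are
unambiguous. Radii were fixed at ~2 mm (not the 0.3–1.5 mm of typical
in-vivo PVS) because at 1 mm voxels the staircase error of thinner tubes
dominates their analytic volume; the rasterized volume of the default
tubes stays within ±20% of πr²L. Noise is additive Gaussian with
sd = background/SNR (the high-SNR approximation of Rician magnitude
noise); a true Rician mode is available. The generator does not emulate
bias fields, partial-volume effects, anatomy, lesions or motion — so
phantom recovery demonstrates the correctness of the filtering,
thresholding and morphometry chain, not segmentation accuracy on
clinical images.

The tensor-field generator writes prescribed Dxx/Dyy/Dzz means into the
four ROI spheres on a compact 1 mm grid covering them (background
0.8e-3 mm²/s, defaults in the healthy-white-matter range giving an
expected index of ≈1.77), with optional i.i.d. Gaussian noise. The
cohort generator draws 61 controls and 49 cases with ages uniform on
30–73 years — the target study design — and a linear outcome with
configurable group/age/interaction effects and Gaussian residuals. The
volumetric generator draws truncated-normal volumes (defaults:
ventricle 15 000 ± 6 000 mm³, choroid plexus 1 600 ± 400 mm³, eTIV
1.5 ± 0.15 × 10⁶ mm³, plausible adult magnitudes). All generators are
bit-reproducible under a fixed seed.

## Verification summary

The test suite checks, among others: Hessian eigenvalues against the
closed-form smoothed quadratic and under axis permutations; the Frangi
response against tube-vs-sphere construction and scikit-image's
implementation (correlation, not equality — boundary handling differs);
thresholding against a sort-and-count oracle; component counting against
an independent flood-fill; permutation p-values against brute-force
enumeration of all 720 orderings at n = 6 with statsmodels-based
refits; and the printed-table identities (thresholds, chi-square, lobar
percentages). `scripts/acceptance.py` re-derives the headline numbers
at run time: phantom recovery over 20 seeds (exact counts, volume within
±20%, diameter within ±25%) and type-I error of each term within
[0.03, 0.07] over 1000 null cohorts at B = 999 (problem sizes chosen to
keep the full run under a minute on one CPU).

## Known limitations

- The percentile threshold and scale set must be re-validated for any
  new resolution or contrast; phantom-calibrated values do not transfer
  to clinical data.
- Diameter is a second-moment (equivalent-ellipsoid) summary; it is
  biased for strongly curved or merging PVS and for components a single
  voxel wide.
- The ALPS implementation assumes tensor maps already registered to the
  1 mm template; no registration QC is modeled.
- Freedman–Lane exchangeability assumes i.i.d. reduced-model errors;
  heteroscedastic or clustered data would need a different permutation
  scheme (ter Braak and raw-Y variants are not currently exposed).
- The aseg.stats parser supports the volume fields this pipeline needs,
  not the full format.
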