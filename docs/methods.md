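# Methods

## Scope and model

`parascint` implements the quantitative chain of dual-phase ⁹⁹ᵐTc-MIBI
parathyroid imaging: planar uptake ratios, SPECT isocontour volumetry, the
PTH/Svol composite, and the downstream cohort statistics. The package starts
from *reconstructed* images: camera physics, OSEM reconstruction and CT
attenuation correction are outside its scope, and the phantom generator
emits post-reconstruction activity volumes directly. Visual localization of
the adenoma into anatomical regions is likewise treated as input metadata,
never computed.

## Planar quantification

The anterior view is the anterior-posterior ray sum of the volume, indexed
(row = z inferior→superior, column = x right→left) so the neck midline is a
pixel column. A manually drawn lesion ROI is mirrored across a user-supplied
midline column to produce the contralateral thyroid reference — guaranteeing
identical pixel count and congruent (mirrored) shape — and the background
reference is the mirrored ROI translated caudally, by default one ROI height,
so it clears the contralateral lobe. The same pixel masks are applied to the
early and delayed images.

"Mean counts" is the per-pixel arithmetic mean, which makes every ratio
independent of ROI area. The retention index is the fractional change of the
lesion/thyroid ratio, RI = (eLTR − dLTR)/eLTR: the alternative literal
parsing eLTR − (dLTR/eLTR) produces values far outside the plausible
bounded range of a fractional-change index, so the fractional form is used.
RI < 0 means the lesion accumulated tracer relative to thyroid at 90 min —
the classic scintigraphic appearance of an adenoma. No physical-decay
correction is applied between time points: ⁹⁹ᵐTc decay cancels inside each
single-time-point ratio.

## Isocontour volumetry

Svol operationalizes a semi-automated vendor VOI tool: the operator supplies
a seed near the focal uptake, the hottest voxel within a 15 mm search sphere
is taken as the local peak (ties broken by distance to the seed, then
lexicographic index, for determinism), and the VOI is the 26-connected
component of voxels ≥ 40% of that peak containing it. The percent-of-max
reference is deliberately the *local* peak, not the global maximum — normal
thyroid can out-shine a small adenoma. The threshold defaults to 40% and is
exposed as a parameter; volume is voxel count × voxel volume in cm³ (an
ellipsoid-fit volume is not used). An optional ellipsoid clip mask
reproduces vendor bounding-shell behavior and an optional background
subtraction mode exists; both are off by default. Components touching the
grid boundary are flagged rather than rejected.

Two practical caveats are inherent to percent-of-max segmentation and are
characterized (not corrected) here:

- **Partial-volume inflation.** PSF blur moves the 40% contour outward —
  the blurred edge crosses 40% of the interior level about 0.25 σ outside
  the true boundary, and peak depression for small objects pushes it
  further. On the default phantom (σ = 4 mm) a 1.41 cm³ adenoma reads
  ≈ 2.8 cm³; at σ = 2 mm it reads ≈ 1.41 cm³. Recovered Svol is a monotone
  function of σ.
- **Merging with adjacent hot structures.** When 40% of the adenoma peak
  falls below the thyroid concentration (e.g. 6:3:1 early contrast), the
  isocontour swallows the lobe. On the delayed volume the faster thyroid
  washout restores separation, which is why the pipeline segments the
  delayed acquisition — matching the clinical protocol, where SPECT follows
  the delayed planar view.

With light blur (σ = 1 mm at 2 mm voxels, high contrast) the recovered
volume of spheres with r = 6–16 mm stays within 15% of (4/3)πr³, dominated
by voxelization at the smallest radius; this band is asserted by the test
suite under exactly these phantom settings.

## Phantom generator

The neck phantom is three axis-aligned ellipsoids (two thyroid lobes
symmetric about the midline, one adenoma posterior to the right lobe) on a
uniform background, voxelized by center membership on an 80³ grid of 2 mm
voxels. Early activity concentrations default to adenoma 6, thyroid 3,
background 1 (arbitrary counts/voxel) — a detectable but not extreme lesion.
Washout is mono-exponential per compartment over the 80 min between scans;
default effective half-lives (adenoma 240, thyroid 60, background 90 min)
are placeholders chosen so the delayed image shows relative lesion retention
(thyroid clears ~2.5× over the interval, the adenoma ~20%), exposed as
configuration and not claimed to match measured MIBI kinetics. Imaging
degradation is a Gaussian PSF (default σ = 4 mm) followed by a voxelwise
Poisson draw at `count_scale` expected counts per unit concentration,
rescaled back to concentration units so replicate means converge to the
noise-free blurred volume; everything is reproducible from a single integer
seed. Attenuation, scatter, dead time and anthropomorphic anatomy are not
modeled.

What passing phantom tests show is that the *measurement chain* is correct
(ratios, contours, volumes match analytic and brute-force oracles under
known ground truth); they do not show robustness to patient motion,
reconstruction artifacts, attenuation gradients, or ROI placement error,
none of which the phantom emulates. The phantom's absolute planar ratios
also depend on its depth geometry and are not calibrated to published
patient values — the cohort simulator, not the phantom, carries those
distributions.

## Cohort simulator

Nine base variables (PTH, calcium, phosphorus, 25(OH)D, eLBR, dLBR, eLTR,
dLTR, Svol) are drawn from a Gaussian copula. Marginals are lognormal for
the skewed, strictly positive quantities (parameters from published
median/range summaries: e.g. PTH log-median 4.854, log-σ 0.70) and truncated
normals for near-symmetric ones (calcium, eLBR, eLTR). Rank correlation is
exact under the copula: each direct Spearman target ρ maps to a latent
Pearson correlation 2·sin(πρ/6), and monotone marginal transforms preserve
it.

Two columns are derived, never sampled: PTH/Svol = PTH ÷ Svol and
RI = (eLTR − dLTR)/eLTR. Because PTH and Svol are lognormal, their logs are
jointly Gaussian under the copula, so rank correlations of any variable with
PTH/Svol have closed forms on the latent scale. The default spec exploits
this to *calibrate* the generator: the Svol log-σ is solved so that
Spearman(PTH, PTH/Svol) attains its published 0.59 given the direct
Spearman(PTH, Svol) = 0.20, and the (unreported) marker–PTH latent
correlations are solved from the published marker–PTH/Svol targets (calcium
0.38, phosphorus −0.29, 25(OH)D −0.17). The calibration is exact in
expectation (verified at n = 2×10⁵); at the n = 5000 used in tests the
sampling SD of a recovered coefficient is ≈ 0.013. Pairs the study never
reports (e.g. eLTR–dLTR) are set once to conservative, physiologically
signed defaults. With both PTH–eLBR and Svol–eLBR pinned as direct targets,
the emergent eLBR–PTH/Svol correlation is ≈ −0.25 rather than the published
−0.07; the published matrix mixes two sample sizes (41 SPECT patients vs 70
overall) and cannot be reproduced jointly, so direct targets take
precedence. The assembled latent matrix is checked for positive
definiteness; a nearest-correlation repair is applied only if needed and
must not move any entry by more than 0.05.

The calcium marginal deserves a note: no normal truncated at the 10.5 mg/dL
eligibility bound can reach the published mean 11.02 / SD 0.71 (the required
SD exceeds the exponential-tail limit of the family, ≈ 0.52 at that mean —
the real data are more skewed than any truncated normal). The generator
therefore uses the published moments as the *parent* parameters, truncated
to [10.5, 15.0]; the realized mean is ≈ 11.3, SD ≈ 0.55, and the
mild : marked severity split ≈ 68 : 32 against the published 71 : 29.

Age (truncated normal 56.2 ± 13.1, range 24–84), sex (23% male) and the
adenoma location label (published site frequencies) are sampled
independently of the labs — the simulator does not attempt site-specific or
sex-specific effects.

## Statistics

- **Severity rule.** mild = [10.5, 11.5), marked = [11.5, ∞) mg/dL. The
  half-open boundary reconciles the two printed conventions ("10.50–11.49"
  vs "> 11.50") at two-decimal resolution; calcium below 10.5 raises as
  ineligible.
- **Descriptives.** Shapiro-Wilk at α = 0.05 gates mean ± SD vs
  median (min–max); constant samples count as non-normal.
- **Spearman.** Mid-ranks for ties, Pearson on ranks, p from the
  t-approximation with n − 2 df; zero rank variance raises.
- **Two-group tests.** Both groups normal (Shapiro-Wilk α = 0.05) →
  independent t test, pooling decided by Levene at α = 0.05; otherwise
  two-sided Mann-Whitney U (asymptotic, tie-corrected, continuity
  correction on). Groups need n ≥ 3.
- **ROC.** Empirical curve over realized marker values; a record is
  positive when marker ≥ cutoff ("greater" direction; mirrored for
  "lesser", auto-chosen so AUC ≥ 0.5). The trapezoidal AUC is identically
  the tie-corrected U/(n₁n₂). CI and the p-value against AUC = 0.5 come
  from DeLong's mid-rank structural-component variance — the deterministic
  standard where the publication method is unstated. Cutoffs are realized
  observations, not midpoints (reported as ">x"/"<x"); the Youden-optimal
  cutoff maximizes J with ties resolved at 1e-12 by higher sensitivity,
  then proximity to the marker median.
- **ICC.** ICC(2,1) — two-way random effects, absolute agreement, single
  rater — from the standard mean-square decomposition; complete matrices
  only, ≥ 5 subjects and ≥ 2 raters.
- **Multiplicity and display.** No multiple-testing correction is applied
  by default (an opt-in Benjamini-Hochberg annotation is possible without
  replacing raw p-values); p-values below 0.001 display as "<0.001" with
  exact values kept in machine output.

The report bundle assembles descriptives, the marker × imaging correlation
block (with per-cell n, since Svol-bearing columns may cover a subset),
the severity comparison, the ROC/cut-off table (calcium itself is excluded —
it defines the groups), and, when location labels are present, the
lower-right vs lower-left comparison.

## Numerical and design choices

- Voxel i sits at world coordinate i·spacing (mm); volumes are
  (x right→left, y anterior→posterior, z inferior→superior).
- Gaussian blur uses nearest-edge boundary handling so a flat background
  loses no mass at the grid edge.
- `locate_peak` and the Youden cutoff both carry explicit deterministic
  tie-breaks; all generators accept a single integer seed and are
  bit-reproducible.
- Problem sizes in the test-bench (80³ default phantom, 49³ recovery
  spheres, 200 ROC oracle instances, 200 noise replicates, n = 5000
  calibration cohorts) were chosen as the smallest sizes at which the
  targeted tolerances are statistically meaningful.

## Known limitations

Single-lesion only; no attenuation/scatter or absolute (SUV-style)
quantification; isocontour volumetry inherits the partial-volume and
merging behavior described above; the cohort simulator reproduces marginals
and rank correlations but not conditional structure (e.g. severity-specific
imaging distributions arise only through the modeled correlations); planar
ROI placement is assumed correct — there is no automatic lesion detection.
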