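# Methods

This note documents the models and numerical choices behind `nucquant`: what
each statistic computes, what the synthetic scenes emulate (and what they do
not), and where the design was genuinely open.

## Masked radially averaged autocorrelation

For a 2-D plane *I* and a boolean nucleus mask *m*, with μ and σ² the mean
and population variance of *I* over the mask:

    C(Δ) = Σₓ δI(x) δI(x+Δ) m(x) m(x+Δ) / (N(Δ) σ²),    δI = I − μ,

where N(Δ) is the number of voxel pairs at shift Δ with both ends in the
mask. Properties and choices:

- **Pearson-style normalisation.** Mean subtraction and division by σ² make
  the curve invariant under affine intensity transforms a·I + b (a > 0), so
  curves are comparable across staining intensities and detector gains.
  C(0) = 1 exactly.
- **Per-shift pair-count normalisation.** Dividing by N(Δ) rather than the
  total voxel count removes the artificial decay that the finite mask
  geometry would otherwise impose on the curve.
- **Boundedness.** |C(Δ)| ≤ 1 is guaranteed at Δ = 0 and holds in practice at
  well-sampled shifts, but it is not a theorem under this normalisation: at
  shifts with only a handful of overlapping pairs, the local second moment
  can exceed the global σ² (1-D counterexample: [10, 0, 0, 0, 10] at shift 4
  gives C = 1.5). This is why shifts with N(Δ) below `min_pair_count`
  (default 16 inside the per-nucleus pipeline) are dropped rather than
  reported.
- **Implementation.** FFT cross-correlation with zero padding to ≥ 2× the
  linear size, so the result is the exact non-periodic double sum up to
  floating-point error (~1e−15 normwise); the test suite checks this against
  a direct-sum oracle on hundreds of random masked instances.
- **2-D per z-plane, not 3-D.** Voxels are 4–5× coarser axially than
  laterally (e.g. 190 vs 42.5 nm), so correlation is computed per plane
  within each nucleus — by default the nucleus's largest-area plane
  (`plane_mode="central"`), optionally all planes above a size threshold.
  Per-nucleus curves are averaged weighted by pair counts.
- **Radial averaging.** Bin *b* collects shifts with
  (b−½)·w ≤ |Δ| < (b+½)·w (w = bin width, default one pixel); values are
  pair-count-weighted means, empty bins are dropped (never interpolated),
  and the reported radius of a bin is the weighted mean shift distance of
  its members rather than the nominal centre — on a lattice these differ,
  and the weighted mean is what the bin value actually estimates. Curves
  are reported to 1 µm by default; beyond that, single-nucleus pair counts
  are unreliable.
- **Correlation-length fit.** `fit_correlation_length` fits
  a·exp(−r²/(4ℓ²)), the ACF of white noise smoothed with a Gaussian kernel
  of width ℓ. The r = 0 bin is excluded: it is pinned at 1 by construction,
  while uncorrelated detection noise dilutes every other bin by a common
  factor that the amplitude a absorbs.

## Site detection and radial profiles

- **Detection** is a Laplacian-of-Gaussian filter at the expected spot scale
  (`log_sigma`, default 120 nm), with candidate local maxima thresholded at
  a multiple (default 8) of the robust (MAD-based) standard deviation of the
  in-nucleus background response. The threshold is deliberately strict
  because maxima are screened over millions of voxels, so the cutoff must
  clear the extreme-value tail of the background; genuine reporter spots
  respond tens of standard deviations above it. At most one site per
  nucleus is kept (the strongest response) — the reporter marks a single
  locus — and the centroid is refined to sub-voxel precision by an
  intensity-weighted centroid over a 3³ neighbourhood.
- **Profiles** are computed in 2-D in the site's nearest z-plane (same
  anisotropy argument as for the ACF): mean mark intensity over concentric
  annuli [r, r+w) of width w (default one lateral pixel; coarser widths
  trade radial resolution for per-bin noise), membership decided by
  voxel-centre distance to the sub-voxel centroid. Each per-site profile is
  divided by its maximum over the entire radial distribution — not by the
  value at r = 0 — so profiles with a central dip keep their shape with the
  peak pinned at 1. Sites closer than `max_radius` to the lateral border are
  excluded (with a logged reason), never partially integrated: partially
  covered outer annuli would bias the tails.
- **Aggregation** reports the per-bin mean and the population variance
  (n denominator) across sites — the variance, not the s.d., is the shaded
  band in the figure-style plots — with the sample variance carried
  alongside for standard errors.
- **Site mark level** (`site_mark_intensity`) is the mean mark in a lateral
  disc (default radius 300 nm) at the site: the single-number "level at the
  transcription site" used for zone comparisons. No principled default
  exists for the aperture; it is an explicit config parameter.

## Group statistics

Sites are classified *active*/*repressed* by which side of an axis-aligned
boundary plane their centroid falls on (ties → active, documented). Groups
are summarised as mean and sample s.d. (n−1), with ±1 and ±2 s.d. bounds.
Pairs are compared with the classical pooled-variance two-tailed Student's
t-test (df = n₁+n₂−2); Welch's form is available behind a flag. No
multiple-testing correction is applied by default, matching the reporting
convention the pipeline reproduces ("only pairs with P < 0.05 shown");
a Bonferroni flag exists and the number of comparisons is logged. Degenerate
inputs: identical constant samples give t = 0, p = 1 by convention; constant
samples with different means raise. Sites from all embryos/conditions in a
group are pooled; per-embryo averaging before testing is left to the caller.

## Synthetic scenes

The generator renders (nuclei, mark, spots) stacks with known ground truth:

- **Nuclei** are spheres (radius ~ N(mean, s.d.), in nm) placed by rejection
  sampling with a minimum gap; packing failure raises an error naming the
  placed/requested counts. Spheres may be clipped by thin stacks in z, as
  optical sections are.
- **Mark texture** inside nuclei: `uniform` (constant mean), `grf` (white
  noise convolved with a Gaussian kernel of width ℓ, giving the closed-form
  ACF exp(−r²/(4ℓ²)); generated over the full field with circular boundary
  handling so the statistics are stationary inside the masks, then
  standardised and scaled to mean `mark_mean` with relative contrast
  `grf_contrast`), or `blobs` (Poisson-distributed Gaussian blobs). The
  uniform mode stands in for the early, unstructured nucleus; grf/blobs for
  the partitioned late nucleus.
- **Sites**: each nucleus carries a reporter spot with probability
  `spot_fraction`, placed uniformly within 0.4 nucleus radii of the centre
  (so profile annuli stay inside the nucleus). Around each site the mark is
  multiplied by 1 + (A−1)·exp(−r²/(2σₑ²)): A > 1 plants enrichment, A < 1 a
  central dip. Spot intensities are Normal(mean, cv·mean) (floored at 5% of
  the mean; cv defaults to 0.2, i.e. noise s.d. = 20% of the mean), with the
  active-zone mean `zone_effect` times the repressed mean. The zone split is
  a single axis-aligned plane — a sharp expression-stripe edge; graded
  boundaries are out of scope.
- **Optics and noise**: axis-separable Gaussian PSF (a full optical model is
  out of scope), then Poisson shot noise at `photon_scale` expected photons
  per unit intensity and additive Gaussian read noise, clipped at 0.
- **Determinism**: one root seed is split (`SeedSequence.spawn`) into
  independent placement/texture/site/noise streams; identical parameters and
  seed reproduce bit-identical stacks.

What the scenes do **not** emulate: chromatin polymer structure, nuclear
envelope texture, spot shapes after antibody amplification (the Gaussian
spot is a modelling choice), curved embryo surfaces, z-dependent optical
degradation, or between-embryo staining variability. Passing tests therefore
demonstrate that the estimators recover known statistical structure under
realistic sampling and noise — not that any particular biological claim
holds in real images.

## Validation design and problem sizes

The test suite and `scripts/acceptance.py` validate against independent
references: a direct double-sum ACF oracle on random 8–16 px masked
instances (normwise relative error < 1e−10); the Gaussian closed form for
correlation-length recovery (ℓ ∈ {150, 300, 600} nm, 42.5 nm pixels, 512²
fields, fitted ℓ within 10%); uniform-vs-textured ordering of ACF(200 nm)
at 20 segmented nuclei per condition (≥ 3 s.e. separation); a hand-enumerable
3×3 radial average; planted-enrichment profile recovery at ~110 sites
(noisy aggregate within 3 s.e.m. per bin of the same scene rendered
noise-free — the planted signal sampled with identical geometry, which is
the correct reference because site z-positions fall between planes and the
per-bin voxel sets are site-specific); the planted central dip (profile
maximum at r > 0); the t-test worked example a={1,2,3}, b={2,3,4}
(t = −1.2247, df 4, p = 0.2879) and its type-I calibration (10,000 null
replicates, rate in [0.04, 0.06]); zone-effect power at the generator's
site-intensity model (ratio 1.5, n = 100/zone, ≥ 95/100 replicates
significant); the 20 µm depth rule on nuclei at 5/15/25 µm; and bit-level
determinism of full pipeline reruns. Scene sizes (≤ 7×768×768 voxels,
≤ 110 nuclei) were chosen so each check runs in seconds while keeping ≥ 100
sites or ≥ 20 nuclei where standard errors matter.

## Known limitations

- The ACF is 2-D per plane; a 3-D ACF for isotropic data is a natural
  extension but out of scope.
- Max-normalisation of noisy per-site profiles is slightly biased when the
  profile maximum is not well separated from other bins at the noise level;
  with the default binning and moderate shot noise the effect is second
  order (the normaliser's noise is zero-mean once the argmax is stable).
- Segmentation assumes a globally bimodal counterstain (one Otsu threshold
  per stack); dim or densely packed real-tissue counterstains may need a
  different segmenter — any label map can be supplied to the downstream
  steps.
- The t-test pools sites across embryos; embryo-level nesting (mixed
  models) is out of scope.
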