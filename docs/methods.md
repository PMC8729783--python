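# Methods

## Scientific problem

Super-resolved (SMLM / DNA-PAINT) images of the nuclear envelope show the
nuclear pore complexes (NPCs) of some tissues arranged in inter-linked chains
separated by pore-free areas, rather than spread evenly. Deciding whether an
observed arrangement is genuinely non-random is confounded by two nuisance
variables: the density of pores on the membrane (coverage) and the labelling
efficiency, both of which change the apparent spacing of segmented pore
clusters even for perfectly random placement. This package quantifies
clustering with a summary statistic that is cheap to measure on segmented
images, and calibrates it against simulations of the random null model under
matched coverage and labelling.

## The cluster-distance statistic

A binarized image of the envelope patch is Euclidean-distance-transformed on
its background (each background pixel carries the distance to the nearest
segmented NPC cluster). The background is thinned to a one-pixel skeleton:
the skeleton traces the ridges midway between neighbouring clusters, where
the transform value equals half the distance between them. The mean
transform value over skeleton pixels inside a circular analysis region,
multiplied by two (and by 10 nm/px), is the **mean NPC cluster distance**.
Skeleton pixels with zero transform value (thinning artifacts touching
foreground) are excluded. The statistic requires neither the location of
individual pores (which touching pores make unrecoverable) nor an edge
correction, but it is only interpretable at a known coverage.

Coverage is the corrected foreground fraction of the analysis disc.
Binarization systematically inflates cluster footprints; the inflation is
measured once per imaging condition by segmenting isolated single pores and
recording the effective equivalent-disc radius assigned to them
(`calibrate_effective_radius`). The excess delta over the nominal 5-px pore
radius is subtracted from each cluster's equivalent radius before its area
is summed (for the original line-scanning and TIRF data the published
corrections are 2.8 and 3.6 px; the simulated pipeline calibrates its own,
typically ~0.9 px at the default rendering settings).

## The null model and its envelope

The null hypothesis is complete spatial randomness constrained by steric
exclusion: pore centers uniform on the patch with pairwise distance >= one
pore diameter (100 nm). Classical nearest-neighbour tests are dominated by
the exclusion constraint itself — hard-disc fields at 30% coverage read as
strongly "regular" (Clark–Evans R ≈ 1.5) regardless of longer-range
structure — so the package instead simulates the null through the *identical*
measurement chain used for real images:

1. `place_pores` — hard-disc placement at target coverages 3–60%.
   Dart-throwing (rejection sampling, vectorised batches, max 10^6 attempts)
   is used wherever it can succeed; random sequential adsorption of discs
   jams near 55% area fraction, so denser targets fall back to a jittered
   triangular lattice whose spacing realises the target density, with
   per-axis jitter bounded by (s − 2r)/(2√2) so non-overlap is guaranteed by
   construction, thinned at random to the exact pore count.
2. `apply_labelling` — 32 binding sites per pore (the stoichiometry of an
   outer-ring nucleoporin with two copies per spoke in two rings) spaced
   equally on the 50-nm ring with a random phase, each retained with
   probability equal to the labelling efficiency (per-copy Bernoulli; an
   all-or-nothing per-pore mode exists behind a flag).
3. `draw_localization_coords` / `render_localizations` — Poisson blink
   counts per retained site (default mean 10) displaced by isotropic
   Gaussian localization noise (default 10 nm, the middle of the 8–14 nm
   regime of line-scanning DNA-PAINT), histogrammed at 10 nm/px with floor
   binning. A noise-free ideal-disc rendering (`render_ideal_image`) is
   available for isolating the morphological chain.
4. `binarize_npc` — the ring-nucleoporin recipe: Gaussian-weighted adaptive
   local threshold (11×11 window), isolated/spur pixel removal, minimum
   component area of half an NPC footprint, 2-px-square closing then
   opening, and removal of components dimmer than 10% of the image maximum.
5. `mean_cluster_distance` + `estimate_coverage` inside a circular analysis
   region (default radius 90% of the inscribed circle).

The grid runs 12 coverage levels × efficiencies {20, 40, 50, 60, 80, 100}% ×
10 repeats. The central **trend** is a power law a·x^b fitted (nonlinear
least squares on the linear scale, log-log fit as initializer) to the
50%-efficiency stratum against *measured* coverage — real nuclei can only be
placed on that axis, since their true coverage and labelling are unknown.
The cluster-distance/coverage relation is common to all efficiencies once
plotted against measured coverage, which is what makes the baseline usable
for tissues of unknown labelling; the **envelope** must therefore bound the
spread around that common trend. At each coverage level the grid row with
the highest (lowest) distance *relative to the trend at its own measured
coverage* is selected across all efficiencies and repeats, and the envelope
curves carry the trend's exponent with amplitude scaled to the extreme
ratio. (Selecting raw extremes instead picks the low-efficiency rows, which
are merely displaced along the trend — lower measured coverage, higher
distance — and the fitted bounds collapse onto and cross it.) With 10
repeats per cell a min/max envelope is an order-statistic band, not an exact
95% interval; the nominal level is left unquantified.

A nucleus is classified `within` / `above` / `below` by comparing its
cluster distance with the envelope evaluated at its measured coverage
(boundaries inclusive; coverage outside the fitted range warns and
extrapolates). Calibration and power are measured in the acceptance suite:
fresh random simulations at 30/50/80% labelling classify "within" (36/36 in
the shipped configuration), and synthetic clustered fields — pores confined
to randomly oriented ribbon strips occupying 30% of the patch, emulating the
chain phenotype — classify "above" (50/50 at matched 10% coverage).

## Effective labelling efficiency

With c tagged copies per pore and per-copy detection probability p, a pore
shows no signal with probability (1−p)^c. Homozygous tags give p = EL;
heterozygous tags give p = EL/2 (one allele untagged). Inverting the
observed empty fraction f yields EL = 1 − f^(1/c) (hom) or 2(1 − f^(1/c))
(het, clamped to [0,1] with a flag — sampling noise can push the inverse
past 1). The 95% CI propagates the Clopper–Pearson binomial interval on f
through the same inverse; EL is monotone decreasing in f so the endpoints
swap. The determination of which pores count as "empty" on real two-colour
images is left to the caller; the module consumes counts.

## Line-profile fitting

Feature widths are measured on raw localization coordinates, not rendered
pixels: points within ±300 nm of a user-drawn segment (restricted to the
segment's longitudinal span) are rotated into the segment frame and their
perpendicular offsets histogrammed (default 5 nm bins, one bin centered on
zero). A single Gaussian plus constant baseline gives the width as
FWHM = 2√(2 ln 2)·σ; a double Gaussian with shared σ gives the separation
|μ₂−μ₁| of two parallel features (the double membrane, or the
nucleoplasmic/cytoplasmic rings). Double-peak initialization takes the two
highest local maxima of the lightly smoothed profile. Fits whose separation
is below 2.5σ, or where one amplitude collapses below 10% of the other, are
flagged `ambiguous` rather than silently reported — below that overlap the
decomposition is not identifiable from the histogram.

## Parameters that matter

| parameter | default | units | rationale |
|---|---|---|---|
| pixel size | 10 | nm/px | the working resolution of the rendered images |
| pore radius | 5 | px (50 nm) | nominal NPC footprint radius |
| copies per pore | 32 | – | outer-ring nucleoporin stoichiometry |
| localization precision | 10 | nm | middle of the 8–14 nm experimental regime |
| mean blinks per site | 10 | – | DNA-PAINT produces many localizations per docking site; sets image SNR |
| render smoothing | 1 | px | matches the 10-nm precision; stabilises the adaptive threshold on count histograms |
| patch size | 512×512 | px (5.12 µm)² | a realistic flat envelope patch at the focal plane; sets simulation cost |
| adaptive-threshold window | 11×11, σ=11/6 | px | window spans ≈ ±3σ; reflect padding; zero offset (strict >) |
| analysis disc | 90% of inscribed radius | – | excludes edge/peripheral pixels |
| grid | 12 coverages 3–60%, 6 efficiencies, 10 repeats | – | the simulated study conditions |
| precision filter | [0.5, 30] | nm | fit-quality range, endpoints inclusive |
| PSF width filter | [50, 150] | nm | as above; log-likelihood cut off by default (engine-dependent scale) |

## What the generator does and does not emulate

Emulated: hard-core random placement, partial per-copy labelling, Poisson
blinking, Gaussian localization error, histogram rendering, ring geometry of
a single nucleoporin. Not emulated: 3D curvature of the nuclear surface
(patches are flat), docking-strand photodamage over the acquisition,
background/nonspecific localizations, drift residuals, multi-emitter fitting
artifacts, and the within-tissue variability of real nuclei. Passing tests
therefore demonstrate the *internal* consistency and calibration of the
measurement chain on its stated model, not that any particular tissue is
non-random.

## Numerical choices and degenerate inputs

- Exact Euclidean distance transform (`scipy.ndimage.distance_transform_edt`),
  not chamfer; background thinning via `skimage.morphology.skeletonize`.
- Empty and full masks raise distinct errors; a mask whose foreground fills
  the analysis disc has no ridge and is rejected.
- Coverage components are clipped to the analysis disc before labelling;
  8-connectivity throughout.
- Placement determinism: a single master seed; every stage derives an
  independent child stream via `numpy.random.SeedSequence` keyed by stage
  and grid indices, so identical seeds give bit-identical fields, sites and
  localization tables.
- Power-law fits require strictly positive data and ≥3 points; the
  constant-y case recovers b = 0 exactly.
- `el_from_empty_fraction` handles the boundary counts (0 and n) with the
  one-sided Clopper–Pearson limits.
- The 2×2 closing/opening pair uses mirrored-footprint adjunction (the
  skimage convention), verified in the tests against a hand-rolled
  structuring-element sweep.

## Known limitations

- The binarization recipe's final closing/opening can fragment thin
  components, so the half-footprint minimum area is guaranteed only at the
  size-filter stage, not in the final mask.
- The jittered-lattice fallback above the dart-throwing jamming density is
  slightly more regular than true equilibrium hard-disc configurations;
  affected coverages (≳55%) sit at the extreme end of the fitted range.
- The min/max envelope's nominal coverage probability depends on the number
  of grid repeats and is not an exact 95% band.
- Problem sizes in the shipped tests and acceptance script (512² px patches,
  256² px placement-oracle fields, 50-seed power runs) are the package's
  default study conditions; larger patches only tighten the statistics.
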