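# npcmorph

Morphometric analysis of nuclear pore complex (NPC) organization in
single-molecule localization microscopy (SMLM / DNA-PAINT) images.

In several *Drosophila* tissues, super-resolved images of the nuclear
envelope show NPCs arranged in inter-linked chains separated by pore-free
areas rather than spread evenly. Whether such an arrangement is genuinely
non-random cannot be judged by eye: the apparent spacing of pore clusters
depends on the pore density on the membrane (*coverage*) and on the
labelling efficiency. `npcmorph` implements the full measurement and
null-model chain needed to make that call, for microscopists and image
analysts working with localization tables or rendered super-resolved
images:

- **Simulation** of the random null model: non-overlapping pore placement
  (hard discs, radius 50 nm) on a membrane patch, per-copy Bernoulli
  labelling of the 32 ring sites, Poisson blinking and Gaussian
  localization noise, rendered at 10 nm/px. Ribbon-clustered fields
  emulate the chain phenotype for power checks.
- **Binarization** of super-resolved images with adaptive local
  thresholding and morphological clean-up, in a ring-nucleoporin variant
  (Nup160-style) and a central-channel variant (Gle1-style), plus
  calibration of the effective single-pore radius the segmentation assigns.
- **Cluster statistics**: the mean NPC cluster distance — twice the mean
  Euclidean-distance-transform value along the thinned background skeleton
  (the ridges between clusters) — and the corrected coverage, where each
  cluster's equivalent-disc radius is shrunk by the calibrated inflation
  delta. The Clark–Evans nearest-neighbour index is included for reference.
- **Null baseline**: a simulation grid over coverages 3–60% and labelling
  efficiencies 20–100% (10 repeats), a power-law trend *a·x^b* fitted to
  the 50%-efficiency stratum against measured coverage, and a min/max
  confidence envelope used to classify each nucleus as `within`, `above`
  (more clustered than random) or `below`.
- **Effective labelling efficiency** from the fraction of reference-marked
  pores lacking target signal, via (1−EL)^8 for homozygous tags and
  (1−EL/2)^8 for heterozygous tags, with Clopper–Pearson-propagated 95%
  intervals.
- **Line-profile fitting** on raw localizations: perpendicular-offset
  histograms around a line ROI, single-Gaussian width (FWHM = 2√(2 ln 2)·σ)
  and double-Gaussian separation with an ambiguity flag.
- **I/O and filtering**: headered CSV localization tables (nm coordinates),
  fit-quality filters (precision 0.5–30 nm, PSF width 50–150 nm), 16-bit
  TIFF images, and a CLI binding every stage.

See `docs/methods.md` for the model details, parameter defaults and known
limitations.

## Worked example

```python
import numpy as np
from npcmorph import (
    place_pores, apply_labelling, render_localizations, render_image,
    binarize_npc, default_disc, measure_nucleus,
)
from npcmorph import baseline as bl

# 1. simulate one random nucleus patch (5.12 um square, 20% NPC coverage,
#    50% labelling efficiency)
field = place_pores(512, 512, target_coverage=0.20, seed=7)
labelled = apply_labelling(field, efficiency=0.5, seed=7)
locs = render_localizations(labelled, mean_blinks_per_site=10,
                            precision_nm=10, seed=7)
image = render_image(locs, 512, 512, smooth_sigma_px=1.0)
print(f"{field.n_pores} pores, {len(locs)} localizations")

# 2. segment and measure
delta = bl.calibrate_delta(seed=7)
mask = binarize_npc(image)
m = measure_nucleus(mask, default_disc(mask.pixels.shape), delta_px=delta)
print(f"coverage correction delta = {delta:.2f} px")
print(f"mean NPC cluster distance = {m.mean_cluster_distance_nm:.1f} nm "
      f"at measured coverage {m.coverage_fraction:.3f}")

# 3. classify against a small random-placement baseline
grid = bl.build_null_grid(coverages=(0.05, 0.1, 0.2, 0.3, 0.45, 0.6),
                          repeats=4, seed=7, delta_px=delta)
base = bl.fit_baseline(grid)
a, b = base.trend
print(f"null trend: {a:.1f} * coverage^{b:.2f} nm")
print("classification:", bl.classify_nucleus(m, base))
```

prints

```
668 pores, 106421 localizations
coverage correction delta = 0.92 px
mean NPC cluster distance = 106.6 nm at measured coverage 0.137
null trend: 20.6 * coverage^-0.83 nm
classification: within
```

The simulated nucleus is random by construction, and the pipeline agrees:
its cluster distance falls inside the envelope at its measured coverage.
(Measured coverage, 13.7%, is below the 20% ground truth because only half
the pores' copies are labelled — exactly the confound the baseline
controls for.) A clustered field generated with
`place_pores_clustered(...)` instead classifies as `above`.

The same pipeline is available from the shell:

```sh
npcmorph simulate --coverage 0.2 --efficiency 0.5 --seed 7 \
    --out-image img.tif --out-locs locs.csv
npcmorph binarize img.tif mask.tif
npcmorph clusterstats mask.tif --delta-px 0.9
npcmorph el --n-empty 168 --n-total 1001 --zygosity hom
```

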