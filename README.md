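# csfmarkers

MRI markers of cerebrospinal-fluid (CSF) clearance for case-control
neuroimaging studies. The package implements, as a tested and reusable
Python library, the four marker families used to compare CSF-handling
between clinical groups across adulthood:

1. **White-matter perivascular spaces (PVS)** — segmentation on the
   enhanced perivascular contrast (EPC) image, the voxel-wise T1w/T2w
   ratio in which fluid-filled PVS are dark, using a multiscale Frangi
   vesselness filter followed by percentile thresholding; morphometry of
   the segmented PVS (count, total volume, mean diameter) per
   white-matter region, normalized by regional WM volume into count
   fraction (CF), volume fraction (VF) and mean diameter (DM), over the
   28 bilateral Desikan-Killiany regions grouped into four lobes
   (frontal 11, parietal 5, temporal 8, occipital 4) — 56 masks x 3
   metrics = 168 features per subject.
2. **DTI-ALPS** — diffusivity along the perivascular space, computed from
   diagonal tensor elements in 1 mm template space as
   `ALPS = mean(Dxx_proj, Dxx_assoc) / mean(Dyy_proj, Dzz_assoc)` using
   5 mm spherical ROIs at (±25, −20, 28) (projection fibers) and
   (±39, −20, 28) (association fibers), averaged over hemispheres.
3. **Volumetrics** — lateral-ventricle and choroid-plexus volumes parsed
   from segmentation-statistics tables and normalized by the estimated
   total intracranial volume (eTIV).
4. **Group statistics** — for every marker, the linear model
   `y ~ 1 + group + age_c + group:age_c` (age mean-centered) with
   Freedman–Lane permutation inference on each term (default B = 5000,
   two-sided on |t|, add-one estimator), Shapiro–Wilk normality
   screening, lobe-wise Bonferroni families (0.05/22 = 0.00227 frontal,
   0.05/10 = 0.00500 parietal, 0.05/16 = 0.00313 temporal,
   0.05/8 = 0.00625 occipital; 0.025 for the paired volumes, 0.05 for
   ALPS), demographics tests, and lobar effect summaries.

A first-class synthetic-data module generates PVS phantoms, tensor
fields, cohorts and volumetric tables with known ground truth, so the
whole pipeline is testable end to end without any imaging data.

## Worked example

```python
from csfmarkers import FrangiParams, generate_pvs_phantom
from csfmarkers.pipeline import segment_pvs

t1, t2, atlas, truth = generate_pvs_phantom(seed=1)   # dark tubes in WM boxes
pvs_mask, metrics, meta = segment_pvs(
    t1, t2, atlas,
    params=FrangiParams(sigmas=(1.0, 1.4, 2.0)),      # mm scales
    percentile=30.0,
)
for m in metrics:
    t = truth[m.region_key.split("-", 1)[1]]
    print(m.region_key, m.count, t.true_count, round(m.total_volume, 1))
```

prints (`python examples/01_segment_phantom_pvs.py` shows the full table):

```
L-phantom00 3 3 469.0
R-phantom01 3 3 467.0
L-phantom02 3 3 460.0
R-phantom03 3 3 482.0
```

Every region's recovered PVS count equals the ground-truth tube count and
the segmented volumes sit within the rasterization error of the true tube
volumes (~490 mm³ per region). The other scripts in `examples/` walk
through the ALPS index (a 2:1 prescribed anisotropy yields an index of
exactly 2.0), eTIV normalization (a 15 000 mm³ ventricle in a
1.5 × 10⁶ mm³ head gives 0.01), the permutation group analysis (an
injected group × age interaction is recovered in the right marker with
p_perm ≈ 0.001), and lobar effect summaries.

A thin CLI mirrors the library: `csfmarkers simulate|pvs|alps|volumes|stats`
(see `csfmarkers --help`); every stochastic run requires and logs its seed.

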