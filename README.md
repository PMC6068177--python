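# corneavasc

Quantification of corneal neovascularization (CoNV) from multimodal
angiography image series: optical coherence tomography angiography (OCTA),
indocyanine-green angiography (ICGA) and slit-lamp photography (SLP).

Corneal vessel ingrowth is the readout for anti-angiogenic therapy studies,
and the three imaging modalities disagree systematically: OCTA resolves
small-caliber and deep vessels that dye angiography and color photography
miss, while ICGA suffers dye leakage and bright iris-vessel background. This
package implements a reproducible measurement pipeline for comparing the
modalities and following vessel growth over weekly scans, aimed at
translational imaging groups who export en-face angiograms as ordinary
raster images:

1. **Pre-processing** — grayscale conversion; median + Gaussian (σ = 1)
   smoothing of OCTA speckle and motion lines; top-hat background
   suppression with a disk structuring element (dark-vessel SLP images are
   complemented first).
2. **Registration** — intensity-based global alignment (translation /
   similarity / affine; mutual information across modalities, normalized
   cross-correlation within one), defining the matched region of interest
   (ROI) for every comparison.
3. **Segmentation** — monogenic-signal local-phase ridge enhancement
   followed by an automated (Otsu-seeded hysteresis) threshold, removal of
   connected components of ≤ 2 px, and optional iris-background exclusion
   masks. White pixels are vessel (V = 1), black are background (V = 0).
4. **Quantification** — vessel density percentage over an ROI A,

   ```
   vessel density % = (∫ V dA / ∫ dA) × 100
   ```

   vessel growth density between consecutive follow-ups (the registered
   previous binary map subtracted from the new one, small change components
   filtered, surviving new-vessel pixels over the ROI area), the
   repeated-scan error floor from same-time-point scan pairs, and the
   percent → mm² conversion for a given scan field.
5. **Agreement statistics** — Kolmogorov–Smirnov (Lilliefors) normality
   check, paired t-test, Pearson correlation and Bland–Altman analysis with
   limits of agreement (mean ± 1.96 SD) and t-based 95% CIs.

No in-vivo images are bundled; a first-class synthetic generator
(`corneavasc.synthetic`) grows seeded capsule-segment vascular trees from
the limbus over 8 weekly time points and renders them per modality with
speckle, motion lines, leakage halos, iris bands and small-vessel contrast
attenuation, so that every stage is testable by parameter recovery against
exact ground truth.

## Worked example

```python
from corneavasc import (
    RegionOfInterest, ModalityRenderConfig, generate_tree, rasterize_truth,
    render_modality, segment_vessels, vessel_density, growth_density,
    density_to_area,
)

tree = generate_tree(seed=7)                      # 8-week vascular scene
roi = RegionOfInterest.full_frame((304, 304))     # 3 mm field, 304 px
cfg = ModalityRenderConfig.for_modality("OCTA")   # default OCTA degradations

maps = {}
for week in (5, 6):
    scan = render_modality(tree, week, cfg, noise_seed=week)
    maps[week] = segment_vessels(scan, roi)
    truth = vessel_density(rasterize_truth(tree, week), roi).density_percent
    meas = vessel_density(maps[week], roi).density_percent
    print(f"week {week}: measured density {meas:.2f}%  (ground truth {truth:.2f}%)")

growth = growth_density(maps[5], maps[6], None, roi)
print(f"vessel growth density week 5 -> 6: {growth.growth_percent:.2f}%")
print(f"new vessel area: {density_to_area(growth.growth_percent, 3.0):.3f} mm^2")
```

prints

```
week 5: measured density 22.64%  (ground truth 22.80%)
week 6: measured density 26.50%  (ground truth 26.90%)
vessel growth density week 5 -> 6: 4.37%
new vessel area: 0.393 mm^2
```

The measured densities come from the full render → preprocess → enhance →
binarize chain and land within a fraction of a percentage point of the
rasterized ground truth; the growth figure is the density of vessel pixels
newly present at week 6 inside the same ROI, and the final line converts it
to square millimeters of the 3 × 3 mm scan field.

The same operations are scriptable from the shell:

```sh
corneavasc simulate --seed 7 --weeks 1-8 --out study/
corneavasc segment study/octa_week6_rep1.png --modality octa --out mask6.png
corneavasc density mask6.png --out density.csv
corneavasc growth mask5.png mask6.png --out growth.csv
corneavasc agree --measurements densities.csv --pairs octa:icga --out report/
```

Pipeline stages are also exposed as scikit-learn-style transformers
(`MedianGaussianDenoiser`, `TopHatEnhancer`, `LocalPhaseEnhancer`,
`AutoBinarizer`, `IntensityRegistration`, `BlandAltmanAgreement`) that
compose with `sklearn.pipeline.Pipeline`.

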