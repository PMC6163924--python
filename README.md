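# earlyvigor

Tools for assessing **early plant vigor in winter wheat** from proximal
sensing, aimed at agronomists and phenotyping researchers who need to
estimate early-season dry weight (DW, kg ha⁻¹), nitrogen uptake
(Nup = DW · NC/100, kg ha⁻¹), nitrogen content (NC, %) and canopy cover
(CC) before and during tillering — the stages where spectral sensing is
notoriously degraded by soil background reflection.

The package implements, on a common data model, the five sensing/analysis
approaches such studies compare:

1. **RGB image segmentation** — vegetation pixels are separated from soil
   in HSV space (hue window plus saturation/value floors); CC is the green
   pixel fraction of the quadrat image.
2. **Narrow-band vegetation indices** from passive hyperspectral
   reflectance on a 3.3 nm grid (300–1140 nm): ATSAVI, EPVI, MCARI, MTCI,
   NDRE, NDVI, PRI, REIP and WBI, e.g.
   NDVI = (R₈₆₄ − R₆₇₁)/(R₈₆₄ + R₆₇₁) and
   REIP = 700 + 40 · ((R₆₆₈+R₇₇₈)/2 − R₆₉₈)/(R₇₃₈ − R₆₉₈).
3. **Active two-band NDVI** (Greenseeker-style): boxcar means over
   656 ± 12.5 nm and 774 ± 12.5 nm.
4. **Two-endmember linear spectral unmixing**: OLS of the mixed spectrum
   on bare-soil and dense-vegetation endmembers; fractional cover is
   b_veg/(b_veg + b_soil).
5. **Exhaustive normalized-difference screening ("contour maps")**: for
   every band pair b₁ > b₂ ≥ 400 nm, NDI = (R_b₁ − R_b₂)/(R_b₁ + R_b₂) is
   correlated with a trait per date; the symmetric R² matrices are averaged
   across dates, their coefficient of variation (sample SD / mean) measures
   temporal stability, and band pairs are classified into VIS (400–680 nm),
   red edge (680–740 nm) and NIR (740–1140 nm) groups.

An evaluation layer correlates every method with every trait per date
(R², two-sided p from the t transform, star notation) and assembles the
summary table with across-date means, CVs and the contour-map gain ratios.
Because the original field data are not public, the package ships the
published per-date R² cells (`earlyvigor.datasets`) for the arithmetic
checks, and a **synthetic trial generator** (`earlyvigor.synthetic`) that
emulates the study conditions end to end: linear spectral mixing with
date-1 NIR noise boost, exponential DW growth (≈73 → ≈1812 kg ha⁻¹),
near-constant-then-declining NC with a late DW–NC trade-off, sigmoidal
cover development (≈4.5% → ≈84%), and rendered quadrat images whose exact
green-pixel fraction is known.

## Worked example

```python
from earlyvigor import (
    TrialDesign, generate_trial, segment_green, fit_unmixing,
    default_endmembers, greenseeker_ndvi,
)
from earlyvigor.spectra import ESTABLISHED_INDICES, compute_index

plots = generate_trial(TrialDesign(seed=42), image_size=300)
p = next(q for q in plots if q.date == "D1")          # a seedling-stage plot
seg = segment_green(p.image)
lib = default_endmembers()
res = fit_unmixing(p.spectrum, lib.soil_spectrum(), lib.vegetation_spectrum())
print(f"plot {p.plot_id}, date {p.date}: true cover {p.true_cover:.3f}")
print(f"image segmentation cover   {seg.canopy_cover:.3f}")
print(f"spectral unmixing cover    {res.cover_estimate:.3f}")
```

prints

```
plot P001, date D1: true cover 0.039
image segmentation cover   0.039
spectral unmixing cover    0.040
NDVI 0.139  NDRE 0.054  Greenseeker NDVI 0.109
```

— at 3.9% ground cover both cover estimators recover the truth closely,
while the index values sit barely above their bare-soil baseline, which is
exactly why image-based CC dominates the method ranking at this stage.

Screening all two-band indices against dry weight across the four dates:

```python
from earlyvigor import NDIScreen, aggregate, trial_tables

traits, spectra = trial_tables(generate_trial(TrialDesign(seed=42), render_images=False))
mats = [
    NDIScreen([s for s in spectra if s.date == d],
              traits[traits.date == d]["dw_kg_ha"].to_numpy(),
              trait="dw", date=d).fit()
    for d in ("D1", "D2", "D3", "D4")
]
agg = aggregate(mats)
print(f"best mean-R2 pair: {agg.best_pair[0]:.0f} nm; {agg.best_pair[1]:.0f} nm")
print(f"mean R2 {agg.best_mean_r2:.2f}, CV of R2 {agg.cv_at_best:.2f}")
```

```
best mean-R2 pair: 907 nm; 673 nm
mean R2 0.74, CV of R2 0.11
```

A command-line interface mirrors the library:
`earlyvigor simulate | segment | indices | unmix | contour | summarize`
(see `earlyvigor --help`).

## Layout

- `earlyvigor.synthetic` — trial generator (spectra, images, traits)
- `earlyvigor.segmentation` — HSV segmentation, cropping, threshold calibration
- `earlyvigor.spectra` — spectral data model and vegetation indices
- `earlyvigor.unmixing` — `SpectralUnmixing` model / `UnmixingResult`
- `earlyvigor.contour` — `NDIScreen` model, aggregation, band groups
- `earlyvigor.evaluation` — correlations, `SummaryTable`, method ranking
- `earlyvigor.datasets` — published reference R² cells
- `docs/methods.md` — models, parameters and design choices in detail
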