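# ftirfp — ATR-FTIR metabolic fingerprinting of cultured cells

`ftirfp` implements a complete chemometric analysis chain for
attenuated-total-reflectance Fourier-transform infrared (ATR-FTIR)
absorbance spectra of cell samples, of the kind used to discriminate
myotonic dystrophy type 1 (DM1) patient-derived fibroblasts by CTG-repeat
length and age of onset. It is aimed at spectroscopists and biomedical
researchers who want the standard "fingerprinting" workflow — baseline
correction, area normalization, Savitzky–Golay second derivative,
region-restricted PCA, lipid band ratios, nonparametric statistics — as
tested, scriptable Python instead of point-and-click vendor software.

## The method

Each absorbance spectrum A(λ), λ in 4000–600 cm⁻¹, is processed as

1. **baseline correction** — rubberband (subtract the lower convex hull
   of the spectrum) or linear;
2. **area normalization** — scale so ∫|A| dλ = 1 over the full range;
3. **second derivative** — Savitzky–Golay local polynomial filter,
   d²A/dλ², which resolves overlapping bands (absorbance maxima become
   negative lobes);
4. **region PCA** — mean-centered PCA of the derivative spectra restricted
   to 3000–2800 (lipid C–H stretch), 1800–1500 (amide I/II + ester
   carbonyl) and 1200–900 cm⁻¹ (carbohydrate/phosphate). Group
   discrimination is read from the score signs per component ("PC sides"),
   quadrant membership on a two-component plane (Q1=(+,+), Q2=(−,+),
   Q3=(−,−), Q4=(+,−)), and the loading extrema, which are assigned to
   vibrational modes via a packaged literature band table;
5. **lipid intensity ratios** from second-derivative peak magnitudes
   I(λ) = |min d²A/dλ²| near the literature positions:

   * CH₂/CH₃ = I(~2922)/I(~2959) — mean acyl chain length,
   * Carbonyl/Total lipid = I(~1747)/(I(~2922)+I(~2851)) — lipid
     peroxidation,
   * Unsaturated/Saturated = I(~3013)/(I(~2922)+I(~2851));
6. **statistics** — D'Agostino K² normality screen, Kruskal–Wallis
   omnibus H (tie-corrected midranks, χ²ₖ₋₁ p), Dunn many-to-one rank
   comparisons vs a control with Bonferroni/Šidák adjustment,
   Mann–Whitney U (exact by enumeration for small tie-free samples) and
   Welch's t; significance at p ≤ 0.05.

A synthetic-cohort generator produces Gaussian-band spectra with known
group structure (band shifts and amplitude effects mimicking the DM1
fibroblast findings, per-sample lognormal amplitude variability shared
across technical replicates, per-replicate baseline drift and noise) and
the analytically implied true ratios, so the entire pipeline can be
validated without any instrument data.

## Worked example

```python
import ftirfp as f

cfg = f.default_profiles("coriell", seed=1)       # control / DM1_1000 / DM1_2000
cohort, truth = f.simulate_cohort(cfg)            # 36 spectra: 3 groups x 4 samples x 3 replicates
deriv = f.preprocess_pipeline(cohort)             # baseline -> area norm -> 2nd derivative

region = f.select_region(deriv, 2800, 3000)       # lipid C-H stretch window
res = f.pca(region, k=3)
print(f.pc_side_separation(res, 1))

ratios = f.compute_ratios(deriv)
for r in ratios[:3]:
    print(r.sample_id, round(r.carbonyl_total_lipid, 3))
```

prints

```
SideSeparation(pc_index=1, positive_fraction={'DM1_1000': 0.0, 'DM1_2000': 1.0,
  'control': 0.0}, clean_separation=True, positive_groups=('DM1_2000',),
  negative_groups=('DM1_1000', 'control'))
control_s1 0.338
control_s1 0.315
control_s1 0.286
```

— the long-repeat-like group (`DM1_2000`) sits alone on the positive side
of PC-1 of the lipid region (a clean separation), and the control
samples' carbonyl/total-lipid replicate ratios scatter around their
generator truth of ≈0.31. The same analysis runs end-to-end from the shell:

```sh
ftirfp run --scenario coriell --seed 1 --out-dir out/
# out/report.json, spectra.csv, ratios.csv, stats.csv, pca_region_*.csv
```

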