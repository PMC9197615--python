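# femora

Cortical-bone morphometry and diaphyseal curvature of the femur from CT
cross-sections.

`femora` implements, as a tested and reusable Python pipeline, a
CT-based morphological analysis of the femoral diaphysis of the kind used
to compare modern Japanese skeletal specimens with prehistoric Jomon
femurs: it segments cortical bone with a histogram-derived Hounsfield-unit
threshold, measures six cross-sectional parameters per diaphyseal level,
quantifies anterior and lateral shaft curvature through the central mass
distribution (CMD) of each section, classifies each femur's lateral
curvature into a four-way taxonomy, and runs the cohort statistics
(split-plot ANOVA with Scheffé post hoc, PCA, chi-squared independence).
It is aimed at biological anthropologists and skeletal biologists who want
reproducible, software-only morphometry of long-bone diaphyses.

## Method

For one femur scanned as an axial HU stack:

1. **Levels.** The span between the lower end of the lesser trochanter and
   the adductor tubercle is divided into nine equal segments; the ten
   bounding cross-sections are *level 1* (proximal) … *level 10* (distal).
2. **Threshold.** The HU values of all ten sections are pooled into one
   frequency table (10 HU bins). The air peak (≈ −1000 HU) and the bone
   peak are located and the cortical threshold is the midpoint of the two
   peak means.
3. **Segmentation.** Pixels ≥ threshold form the cortex (largest
   8-connected component; specks discarded); filling its interior gives
   the section region; the largest interior hole is the medullary cavity.
4. **Morphometry** per section: cross-sectional area CSA (pixel count ×
   pitch²), area of cortical bone ACB, cortical index CI = ACB/CSA,
   periosteal border length PBL (surface-point count × pitch), and the
   cortical bone thickness CBT at every periosteal point — the minimum
   Euclidean distance to the endosteal surface — summarized by its mean
   and maximum. Values are reported raw and divided by the femoral total
   or diaphyseal length.
5. **Curvature.** The CMD of a section is the intersection of the
   vertical and horizontal lines that each split the section area in
   half. Shifts dx (lateral +) and dy (anterior +) of the level 1–9 CMDs
   from the straight line through the level-1 and level-9 CMDs form the
   deviation profile; the sign pattern of dx over levels 2–8 classifies
   the femur as *primary lateral*, *primary medial*, *S lateral–medial*
   or *S medial–lateral*.
6. **Statistics.** Per-parameter split-plot ANOVA (cohort between-subject,
   level within-subject) with Scheffé contrasts; PCA of per-specimen
   parameter means on the correlation matrix; Pearson chi-squared on the
   cohort × pattern contingency table; period grouping of radiocarbon-dated
   specimens at the 6,000 cal BP boundary.

Because no CT volumes of the original specimens are deposited, the package
ships a synthetic phantom generator (`femora.phantom`) that renders bent
hollow cortical tubes in air with known analytic ground truth — thickness
profiles, linea-aspera ridge, anterior bow and all four lateral-curvature
modes — so every stage is validated against closed forms.

## Worked example

```python
import femora

# an analytic cortical annulus: outer radius 15 mm, cavity 10 mm, 0.2 mm px
section = femora.annulus_section(15.0, 10.0, spacing=0.2)
hist = femora.pool_histogram([section])
threshold = femora.derive_threshold(hist)     # -> 105.0 HU (peak midpoint)
mask = femora.segment_cortex(section, threshold)
record = femora.measure_section(mask)
print(f"CSA {record.csa:.1f} mm2  ACB {record.acb:.1f} mm2  "
      f"CI {record.ci:.3f}  mean CBT {record.mean_cbt:.2f} mm")
```

prints

```
CSA 706.6 mm2  ACB 393.1 mm2  CI 0.556  mean CBT 4.95 mm
```

against the closed forms π·15² = 706.9 mm², π(15²−10²) = 392.7 mm²,
CI = 0.556 and a true thickness of 5 mm — i.e. the rasterized measurement
is within 0.1 % on areas and a quarter pixel on thickness.

The same flow applies to real data: `femora.load_volume` reads a DICOM
series (RescaleSlope/Intercept honoured, left femurs mirrored so +x is
lateral) or a raw `volume.npy` + `meta.json` bundle, `plan_levels` /
`extract_sections` produce the ten sections, and the `femora` command line
chains everything:

```bash
femora simulate -c config.yaml   # render a phantom cohort
femora measure  -c config.yaml   # per-level morphometrics CSV
femora curvature -c config.yaml  # deviation profiles + pattern table
femora stats    -c config.yaml   # ANOVA/Scheffé + PCA reports
femora report   -c config.yaml   # summary figures
```

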