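# msiquant

Quantitative analysis of drug distribution in tissue sections imaged by
MALDI mass spectrometry imaging (MSI), built for pharmacology groups who
need more than a homogenate average: where in the tumor the drug
actually is, how much of the section it covers, and how many pmol/mm²
each region carries.

Raw MSI ion images are not quantitative. Ion suppression — local signal
loss caused by co-located tissue components — varies between organs and
within a single tumor section, so equal drug amounts can produce very
different raw intensities. `msiquant` implements the analysis chain
that corrects for this and turns ion images into absolute,
spatially-resolved amounts:

1. **Internal-standard normalization.** With a deuterated analogue of
   the drug sprayed uniformly over the section, both channels share the
   per-pixel suppression factor *s(p)*:

       drug(p) = g·d(p)·s(p)·ε₁(p) + b(p)
       istd(p) = I₀·s(p)·ε₂(p) + b(p)

   and the per-pixel ratio `drug/istd` cancels *s(p)*, leaving a
   quantity proportional to the local drug amount per area *d(p)*.
2. **Calibration.** Spots of known amount (0.2–15 pmol) fit an
   ordinary-least-squares line `y = β₁x + β₀` of mean normalized signal
   against amount per area, inverted to express any ROI in pmol/mm².
3. **Heterogeneity metrics.** A background threshold μ + 3σ estimated
   from untreated controls defines drug-positive pixels; the package
   reports percent-positive coverage and "particle" statistics (count,
   size, perimeter, circularity of connected positive clusters).
4. **Zonation.** Sections are binned into high / mid / low intensity
   bands (≥75%, 25–75%, <25% of the section maximum), circular ROIs
   are sampled inside each band, and per-zone amounts yield fold ratios
   such as high-vs-low.
5. **Statistics.** RSD% reproducibility, Welch t-tests between serial
   section series, one-way ANOVA + Tukey HSD across tumor models.

A phantom generator (`msiquant.synthetic`) produces tumor-section
phantoms with ground truth — compartment archetypes (homogeneous,
necrotic core, patchy vascular, fibrotic, scant), smooth suppression
fields, sprayed internal standard, calibration spots, untreated
controls, serial sections — so every stage is testable end-to-end
against known answers. Data I/O covers imzML 1.1 (+ ibd) and a plain
CSV grid dialect. See `docs/methods.md` for the full model description
and design choices.

## Worked example

```python
import msiquant as mq

# untreated controls -> background threshold (k = 3)
controls = [mq.normalize(*mq.make_control_section(seed=s)) for s in (101, 102)]
model = mq.estimate_threshold(controls, k=3.0)
print(f"background threshold: {model.threshold:.4f} "
      f"(mean {model.mean_bg:.4f} + 3 x sd {model.sd_bg:.4f})")

# spotted dilution series -> calibration curve
drug, istd, spots = mq.make_calibration_section(seed=7)
raw = mq.build_calibration(spots, drug)
curve = mq.build_calibration(spots, mq.normalize(drug, istd))
print(f"calibration R^2: raw {raw.r_squared:.3f} -> normalized {curve.r_squared:.5f}")

# a poorly perfused tumor phantom
section = mq.make_phantom(mq.PhantomConfig(archetype="patchy_vascular", seed=5))[0]
norm = mq.normalize(section.drug, section.istd)
pct = mq.percent_positive(norm, threshold=model.threshold)
print(f"percent positive: {pct:.2f}%  (ground truth {section.truth.positive_percent:.2f}%)")

# zonation of a designed-contrast phantom
zoned = mq.make_zoned_phantom(seed=5)
znorm = mq.normalize(zoned.drug, zoned.istd)
zones = mq.zone_map(znorm, model.threshold)
rois = mq.sample_zone_rois(zones, n_per_zone=3, roi_pixels=25, purity=1.0, seed=5)
report = mq.zone_quantify(znorm, rois, curve)
print(f"fold high vs low: {report.fold_high_vs_low:.2f}, "
      f"high vs mid: {report.fold_high_vs_mid:.2f}")
```

prints:

```
background threshold: 0.0159 (mean 0.0075 + 3 x sd 0.0028)
calibration R^2: raw 0.932 -> normalized 1.00000
percent positive: 62.90%  (ground truth 62.87%)
fold high vs low: 4.72, high vs mid: 2.08
```

Reading the numbers: per-spot suppression wrecks the raw calibration
line (R² 0.93) and normalization rescues it; the k = 3 threshold
recovers the phantom's true drug-positive coverage to a tenth of a
percentage point; and the per-zone amounts read back through the
calibration curve recover the phantom's designed 4.76× / 2.09×
high-to-low and high-to-mid contrast within a few percent.

## Command line

The same stages are available as subcommands of the `msiquant` CLI —
`simulate`, `extract` (imzML → CSV grid), `normalize`, `calibrate`,
`heterogeneity`, `zones`, `compare` and `run-all`:

```bash
msiquant run-all --seed 1 --outdir results/run
```

writes `sections.csv` (one row per section with coverage, particle and
zone metrics), `threshold.json`, `calibration.json`, `groups.json`
(ANOVA + Tukey across archetypes) and a `run_log.json` recording every
seed, threshold and boundary used. Re-running the same config is
byte-identical.

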