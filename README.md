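# rbcdeform

Red blood cells (RBCs) owe much of their physiological function to their
deformability: the capacity to elongate under flow-induced shear stress,
which lets them pass capillaries narrower than their own resting diameter.
A fraction of cytosolic hemoglobin (2–10%) is reversibly bound to the inner
membrane leaflet, and elevated membrane-bound hemoglobin (MBHb) is
associated with stiffer cells. `rbcdeform` packages the two measurement
stages used to study this association, driven entirely by calibrated
synthetic data so every stage is testable without access to donor material:

1. **Deformability morphometrics.** Adherent cells sheared in a narrow-gap
   flow chamber are imaged; each segmented cell is reduced to the
   equivalent ellipse of its binary mask using central second moments.
   With moment-matrix eigenvalues λ₁ ≥ λ₂, the full axes are a = 4√λ₁,
   b = 4√λ₂ and the elongation ratio is **ER = a/b ≥ 1** (ER = 1 is a
   round, non-deformed cell). The **average elongation ratio (AER)** pools
   per-cell ERs over ~8000–10,000 cells from 20–25 fields.
2. **MBHb correlation screen.** Label-free quantification (LFQ)
   intensities of the six membrane-bound globin chains — β (HBB),
   α (HBA1), δ (HBD), µ (HBM), γ (HBG2), θ (HBQ1) — are analysed on the
   natural-log scale: per-subunit abundance summaries, the 6×6
   inter-subunit Pearson matrix, the subunit-vs-AER screen
   (p two-sided from t = r√(n−2)/√(1−r²)), Welch contrasts between fresh
   donors and stored blood-bank units, Shapiro–Wilk normality checks, and
   the δ/α intensity ratio.

Both stages come with synthetic generators: a field renderer that places
non-overlapping elliptical cells with known geometry (so measured ER can be
validated against ground truth), and a cohort generator that draws
Ln(LFQ) + AER jointly from one multivariate Gaussian whose means, SDs and
correlation structure are calibrated to the published summary statistics.

## Worked example

```python
from rbcdeform import (MembraneHbDeformability, analyze_field,
                       generate_lfq_cohort, load_preset, render_field,
                       summarize)

# one synthetic flow-chamber field, segmented and pooled
spec = load_preset("fresh-donor").field_spec(seed=7)
image, truth = render_field(spec)
s = summarize(analyze_field(image))
print(f"{s.n_cells} cells, AER {s.aer:.3f} (SD {s.sd:.3f})")

# the default 15-sample cohort (9 fresh donors + 6 stored units)
preset = load_preset("study")
table, aer = generate_lfq_cohort(preset.cohort, seed=7)
print(MembraneHbDeformability(table, aer).fit().summary())
```

The first block prints

```
400 cells, AER 1.557 (SD 0.238)
```

— 400 cells measured in one field, whose pooled mean elongation sits near
the fresh-donor population target of 1.58. The model fit then prints the
abundance table (β most abundant at Ln(LFQ) ≈ 34.5, θ near the detection
limit at ≈ 23), the correlation matrix, and the deformability screen, e.g.

```
Deformability screen: subunit Ln(LFQ) vs AER
   beta r=-0.508  n=15  p=0.0533  [ns]
  alpha r=-0.847  n=15  p=0.0001  [**]
  delta r=-0.526  n=15  p=0.0439  [*]
  ...
gamma fresh  24.3+/-0.5 stored  26.5+/-0.6 (Welch t) p=0.000
```

Negative r means more membrane-bound subunit, stiffer cells. At the
study's own n = 15 a single draw has wide sampling error (here β narrowly
misses 0.05 while α and δ are flagged); the test suite checks the screen's
operating characteristics over many replicate cohorts. The γ contrast
shows the storage effect the generator builds in (elevated fetal globin in
stored units).

The same stages are scriptable from the shell:

```bash
rbcdeform run --preset study --fields 25 --seed 1 --out run/
rbcdeform simulate-lfq --preset fresh-donor --seed 2 --out cohort.csv
rbcdeform correlate --cohort cohort.csv --out tables/
```

`run` executes simulate → analyze → summarize → correlate → report and
writes a manifest with the config hash and seed; identical config + seed
reproduce byte-identical outputs.

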