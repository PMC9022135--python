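# focimetry

High-content imaging pipeline for quantitative, single-cell detection of
DNA damage in immune cells.

DNA double-strand breaks recruit repair factors that are visible by
immunofluorescence as nuclear foci. This package implements the image
analysis and statistics for a plate-based assay using the two standard
markers: **53BP1**, which relocalises into discrete foci (quantified as the
per-cell **sum of integrated focus intensities**), and **γ-H2AX**, which is
generated de novo by phosphorylation (quantified as **mean nuclear
intensity**). It is aimed at labs running 384-well etoposide-challenge or
baseline-damage screens who need per-cell feature tables and defensible
statistics out of per-channel TIFF fields.

The pipeline:

1. **Segment** nuclei from DAPI (Gaussian smooth → Otsu → hole fill →
   distance-transform watershed with h-maxima seeds → area gate → border
   exclusion).
2. **Detect** candidate foci inside nuclei with a multi-scale
   Laplacian-of-Gaussian detector at deliberately low stringency.
3. **Classify** focus vs background with a trainable Fisher Linear
   Discriminant, w = (S_W + εI)⁻¹(μ₁ − μ₀), threshold at the midpoint of
   the projected class means; stored sufficient statistics make fine-tuning
   to a new cell type exactly equivalent to retraining on pooled data.
4. **Quantify** per-cell marker features and call damage-positive cells
   against a negative-control **mean + 1 SD** threshold (strictly above).
5. **Test**: Mann–Whitney–Wilcoxon per marker, Yates-corrected χ² on
   positive/negative counts, inter-replicate one-way ANOVA, and 2D kernel
   densities of the dual-marker distribution.

A bundled synthetic-microscopy simulator (216 nm/px fields of elliptical
nuclei, Gaussian foci with log-normal amplitudes, Poisson + read noise,
full ground truth) makes every stage testable end to end; see
`docs/methods.md` for the model and its limits.

## Worked example

```python
from focimetry import (SimulationConfig, simulate_field, process_field,
                       train_spot_classifier, compare_conditions,
                       cell_records_to_frame)
from focimetry.io import SampleMeta

config = SimulationConfig(field_shape_px=(640, 640), n_cells=40, seed=0)
model = train_spot_classifier(config, n_fields=6, seed=100)

tables = {}
for condition in ("DMSO", "ETP"):
    records = []
    meta = SampleMeta("donor1", "JURKAT", condition,
                      30.0 if condition == "ETP" else 0.0)
    for k in range(5):
        images, truth = simulate_field(config, condition, seed=k)
        recs, labels, cands = process_field(images, model=model, meta=meta)
        records.extend(recs)
    tables[condition] = cell_records_to_frame(records)

report = compare_conditions(tables["ETP"], tables["DMSO"])
for marker, w in report.wilcoxon.items():
    print(marker.value, "Wilcoxon", w.p_display,
          "X2 = %.1f" % report.contingency[marker].statistic,
          "positive %.1f%% -> %.1f%%" % (
              100 * report.positive_fraction_control[marker],
              100 * report.positive_fraction_treated[marker]))
```

prints (exact numbers vary with the seed):

```
53BP1 Wilcoxon < 2.2e-16 X2 = 292.6 positive 13.5% -> 99.0%
gH2AX Wilcoxon < 2.2e-16 X2 = 306.6 positive 12.5% -> 100.0%
```

Both markers shift strongly under the etoposide-like condition: the
rank-sum p-value is at the display floor, and the fraction of
damage-positive cells (feature strictly above the vehicle control's
mean + 1 SD) rises for both the 53BP1 sum spot intensity and the γ-H2AX
mean nuclear intensity — the same dual-marker concerted response the 2D
kernel densities show as a diagonal shift.

Narrative scripts in `examples/` cover each capability (simulation,
segmentation + detection, classifier training and fine-tuning, positivity
calling, condition statistics, plate-scale batch processing); the `focimetry`
CLI exposes the same stages (`simulate`, `train-spots`, `quantify`,
`stats`) for shell use.

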