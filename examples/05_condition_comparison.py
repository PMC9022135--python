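"""Treated-vs-control statistics through the full image pipeline.

Simulates a few fields per condition, quantifies cells (segmentation + LoG
detection + FLD classification), and runs the standard comparison: Wilcoxon
rank-sum per marker, Yates chi-square on positive counts, and the signed
median differences that summarise the dual-marker "diagonal shift".
"""

from focimetry import (
    SimulationConfig,
    cell_records_to_frame,
    compare_conditions,
    process_field,
    simulate_field,
    train_spot_classifier,
)
from focimetry.io import SampleMeta

config = SimulationConfig(field_shape_px=(640, 640), n_cells=30, seed=0)
model = train_spot_classifier(config, n_fields=6, seed=100)

tables = {}
for condition in ("DMSO", "ETP"):
    meta = SampleMeta("donor1", "JURKAT", condition,
                      30.0 if condition == "ETP" else 0.0)
    records = []
    for k in range(4):
        images, _ = simulate_field(config, condition, seed=200 + k)
        recs, _, _ = process_field(images, model=model, meta=meta, field_index=k + 1)
        records.extend(recs)
    tables[condition] = cell_records_to_frame(records)

report = compare_conditions(tables["ETP"], tables["DMSO"],
                            treated_label="ETP", control_label="DMSO")
for marker, w in report.wilcoxon.items():
    x2 = report.contingency[marker]
    print(f"{marker.value:6s} Wilcoxon p {w.p_display:10s} X2 = {x2.statistic:7.1f}  "
          f"positive {report.positive_fraction_control[marker]:.1%} -> "
          f"{report.positive_fraction_treated[marker]:.1%}  "
          f"median shift {report.median_difference[marker]:+.3g} A.U.")
# Both median shifts are positive -- the concerted two-marker response that
# appears as a diagonal displacement in the 2D kernel-density contours.
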