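"""Segment nuclei and detect focus candidates on one simulated field.

Renders a treated field, segments the DAPI channel, measures per-nucleus
geometry, and runs the low-stringency LoG detector on the 53BP1 channel.
"""

from focimetry import (
    SimulationConfig,
    detect_candidates,
    measure_nuclei,
    segment_nuclei,
    simulate_field,
)
from focimetry.io import Channel

config = SimulationConfig(field_shape_px=(640, 640), n_cells=12, seed=3)
images, truth = simulate_field(config, "ETP", seed=3)

labels = segment_nuclei(images[Channel.DAPI])
shapes = measure_nuclei(labels, images[Channel.DAPI])
print(f"true nuclei: {len(truth)}   segmented: {labels.max()}")
print(f"mean nucleus area: {sum(s.area_px for s in shapes) / len(shapes):.0f} px "
      f"({shapes[0].mean_dapi:.0f} A.U. mean DAPI in nucleus 1)")

candidates = detect_candidates(images[Channel.M53BP1], labels)
true_foci = sum(c.focus_count[Channel.M53BP1] for c in truth.cells)
print(f"candidate foci: {len(candidates)}   true foci: {true_foci}")
# The detector is deliberately permissive: it returns more candidates than
# true foci and leaves the pruning to the trained classifier (example 03).
brightest = max(candidates, key=lambda c: c.integrated_intensity)
print(f"brightest candidate: nucleus {brightest.nucleus_label}, "
      f"integrated {brightest.integrated_intensity:.0f} A.U., "
      f"roundness {brightest.roundness:.2f}")
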