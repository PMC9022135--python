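"""Orchestration: simulate -> segment -> detect/classify -> quantify -> stats.

Each stage reads the previous stage's on-disk outputs, so stages can run
independently; a :class:`RunManifest` records configuration, seed, paths and
record counts for reproducibility.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .io import (
    Channel,
    PlateLayout,
    Treatment,
    cell_records_to_frame,
    parse_field_filename,
    read_channel_image,
)
from .foci import (
    DEFAULT_FEATURES,
    FldModel,
    SpotDetectionParams,
    detect_candidates,
    fld_classify,
    fld_train,
)
from .quantify import MARKER_FEATURE, compute_cell_features
from .segment import SegmentationParams, segment_nuclei
from .simulate import MARKERS, SimulationConfig, simulate_field
from .stats import anova_oneway, compare_conditions

logger = logging.getLogger("focimetry")

__all__ = [
    "RunManifest",
    "process_field",
    "quantify_plate",
    "label_candidates",
    "train_spot_classifier",
    "run_condition_stats",
]


@dataclass
class RunManifest:
    """Record of one pipeline run: config snapshot, seed, paths, counts."""

    stage: str
    seed: int | None = None
    version: str = __version__
    config: dict = dc_field(default_factory=dict)
    inputs: list[str] = dc_field(default_factory=list)
    outputs: list[str] = dc_field(default_factory=list)
    counts: dict = dc_field(default_factory=dict)
    started: float = dc_field(default_factory=time.time)
    finished: float | None = None

    def close(self) -> "RunManifest":
        self.finished = time.time()
        return self

    def write(self, path: str | Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        path.write_text(json.dumps(self.__dict__, indent=2, default=str))
        return path


def process_field(
    images: dict[Channel, "np.ndarray | object"],
    model: FldModel | None = None,
    seg_params: SegmentationParams | None = None,
    spot_params: SpotDetectionParams | None = None,
    well_id: str = "A01",
    field_index: int = 1,
    meta=None,
):
    """Segment one field and quantify its cells.

    Without a classifier model every candidate is accepted (pure
    low-stringency detection); with one, only accepted spots count.
    Returns (cell records, label map, candidates per marker).
    """
    labelmap = segment_nuclei(images[Channel.DAPI], seg_params)
    candidates: dict[Channel, list] = {}
    accepted: dict[Channel, list] = {}
    for marker in MARKERS:
        cands = detect_candidates(images[marker], labelmap, spot_params)
        if model is not None:
            cands = fld_classify(model, cands)
        else:
            for c in cands:
                c.accepted = True
        candidates[marker] = cands
        accepted[marker] = [c for c in cands if c.accepted]
    records = compute_cell_features(
        images, labelmap, accepted, well_id=well_id, field_index=field_index, meta=meta
    )
    return records, labelmap, candidates


def _discover_fields(images_dir: Path) -> dict[tuple[str, int], dict[Channel, Path]]:
    fields: dict[tuple[str, int], dict[Channel, Path]] = {}
    for path in sorted(images_dir.glob("*.tif")):
        well_id, field_index, channel = parse_field_filename(path.name)
        fields.setdefault((well_id, field_index), {})[channel] = path
    return fields


def quantify_plate(
    images_dir: str | Path,
    layout: PlateLayout,
    model: FldModel | None = None,
    seg_params: SegmentationParams | None = None,
    spot_params: SpotDetectionParams | None = None,
) -> pd.DataFrame:
    """Run segmentation + detection + quantification over an image directory.

    Wells present on disk but absent from the layout are skipped with a
    warning; fields missing a channel are a hard error.
    """
    images_dir = Path(images_dir)
    fields = _discover_fields(images_dir)
    if not fields:
        raise FileNotFoundError(f"no fields found in {images_dir}")

    all_records = []
    for (well_id, field_index), channels in sorted(fields.items()):
        if well_id not in layout:
            logger.warning("well %s on disk but not in layout; skipped", well_id)
            continue
        missing = [ch for ch in Channel if ch not in channels]
        if missing:
            raise FileNotFoundError(
                f"{well_id} field {field_index} missing channels: "
                f"{[m.value for m in missing]}"
            )
        images = {ch: read_channel_image(p) for ch, p in channels.items()}
        records, labelmap, _ = process_field(
            images, model=model, seg_params=seg_params, spot_params=spot_params,
            well_id=well_id, field_index=field_index, meta=layout[well_id],
        )
        logger.info("%s f%02d: %d nuclei, %d cells", well_id, field_index,
                    labelmap.max(), len(records))
        all_records.extend(records)
    return cell_records_to_frame(all_records)


def label_candidates(candidates, truth, match_radius_px: float = 3.0, marker=None):
    """Split detected candidates into true-focus / background by ground truth.

    A candidate matches a true focus if it lies within ``match_radius_px``
    of one; each true focus absorbs at most one candidate (nearest first).
    Returns (focus feature matrix, background feature matrix, match flags).
    """
    true_pts = []
    for cell in truth.cells:
        pts = cell.focus_centers[marker] if marker is not None else np.vstack(
            [cell.focus_centers[m] for m in MARKERS]
        )
        if len(pts):
            true_pts.append(pts)
    true_pts = np.vstack(true_pts) if true_pts else np.empty((0, 2))

    taken = np.zeros(len(true_pts), dtype=bool)
    order = sorted(range(len(candidates)), key=lambda i: -candidates[i].response)
    is_focus = np.zeros(len(candidates), dtype=bool)
    for i in order:
        r, c = candidates[i].centroid_px
        if len(true_pts) == 0:
            break
        d = np.hypot(true_pts[:, 0] - r, true_pts[:, 1] - c)
        d[taken] = np.inf
        j = int(np.argmin(d))
        if d[j] <= match_radius_px:
            taken[j] = True
            is_focus[i] = True
    X = np.array([c.feature_vector(DEFAULT_FEATURES) for c in candidates]).reshape(
        len(candidates), len(DEFAULT_FEATURES)
    )
    return X[is_focus], X[~is_focus], is_focus


def train_spot_classifier(
    config: SimulationConfig | None = None,
    n_fields: int = 6,
    seed: int = 0,
    conditions: tuple[Treatment, ...] = (Treatment.ETP, Treatment.UNTREATED),
    marker: Channel = Channel.M53BP1,
    spot_params: SpotDetectionParams | None = None,
    seg_params: SegmentationParams | None = None,
) -> FldModel:
    """Train an FLD spot classifier on simulated fields with known foci.

    Candidates are detected at low stringency on the marker channel and
    labelled against ground truth.  Training fields cycle through
    ``conditions``: treated fields supply plenty of true foci, control
    fields supply noise-only background candidates.  The model applies to
    either marker channel.
    """
    config = config or SimulationConfig()
    spot_params = spot_params or SpotDetectionParams()
    focus_rows, background_rows = [], []
    for k in range(n_fields):
        condition = conditions[k % len(conditions)]
        images, truth = simulate_field(config, condition=condition, seed=seed + k)
        labelmap = segment_nuclei(images[Channel.DAPI], seg_params)
        cands = detect_candidates(images[marker], labelmap, spot_params)
        if not cands:
            continue
        X_pos, X_neg, _ = label_candidates(cands, truth, marker=marker)
        focus_rows.append(X_pos)
        background_rows.append(X_neg)
    X_pos = np.vstack([x for x in focus_rows if len(x)])
    X_neg = np.vstack([x for x in background_rows if len(x)])
    logger.info("training FLD on %d focus / %d background candidates",
                len(X_pos), len(X_neg))
    return fld_train(X_pos, X_neg, feature_names=DEFAULT_FEATURES)


def run_condition_stats(
    cells: pd.DataFrame,
    control: str = "DMSO",
    treated: str = "ETP",
    replicate_anova: bool = True,
    with_kde: bool = True,
) -> dict:
    """Treatment-vs-control statistics from a per-cell table, as a JSON-able dict.

    Includes per-marker Wilcoxon, positivity thresholds and fractions,
    Yates chi-square on positive counts, median differences, and (optionally)
    a per-treatment-group one-way ANOVA with replicate as the factor.
    """
    if "treatment" not in cells.columns:
        raise KeyError("cell table has no 'treatment' column")
    available = set(cells["treatment"].unique())
    if control not in available:
        raise ValueError(f"control condition {control!r} not in table (has {sorted(available)})")
    if treated not in available:
        raise ValueError(f"treated condition {treated!r} not in table (has {sorted(available)})")
    tt = cells[cells["treatment"] == treated]
    cc = cells[cells["treatment"] == control]
    comparison = compare_conditions(tt, cc, with_kde=with_kde,
                                    treated_label=treated, control_label=control)

    report: dict = {
        "treated": treated,
        "control": control,
        "n_treated": int(len(tt)),
        "n_control": int(len(cc)),
        "markers": {},
    }
    for marker, feature in MARKER_FEATURE.items():
        w = comparison.wilcoxon[marker]
        x2 = comparison.contingency[marker]
        thr = comparison.thresholds[marker]
        report["markers"][marker.value] = {
            "feature": feature,
            "wilcoxon_U": w.statistic,
            "wilcoxon_p": w.p_value,
            "wilcoxon_p_display": w.p_display,
            "chi2": x2.statistic,
            "chi2_p": x2.p_value,
            "chi2_table": x2.table,
            "threshold": thr.value,
            "control_mean": thr.control_mean,
            "control_sd": thr.control_sd,
            "positive_fraction_treated": comparison.positive_fraction_treated[marker],
            "positive_fraction_control": comparison.positive_fraction_control[marker],
            "median_difference": comparison.median_difference[marker],
        }

    if replicate_anova and "replicate" in cells.columns:
        anova: dict = {}
        for condition, sub in cells.groupby("treatment"):
            groups = [g.to_numpy(dtype=np.float64)
                      for _, g in sub.groupby("replicate")["sum_spot_53bp1"]]
            if len(groups) >= 2 and all(len(g) >= 2 for g in groups):
                res = anova_oneway(groups)
                anova[str(condition)] = {
                    "F": res.statistic, "p": res.p_value,
                    "df": [res.df_between, res.df_within],
                    "group_sizes": list(res.group_sizes),
                }
        report["replicate_anova_53bp1"] = anova
    return report
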