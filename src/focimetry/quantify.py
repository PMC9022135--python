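"""Per-cell marker features and negative-control positivity calling.

The two downstream features mirror the distinct biology of the markers:
53BP1 pre-exists and relocalises into foci, so its readout is the per-cell
sum of integrated focus intensities; gamma-H2AX is generated de novo, so its
readout is mean nuclear intensity.  A cell is damage-positive for a marker
when its feature exceeds the negative-control mean plus one sample SD
(strict inequality; ties at the threshold are negative).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import Channel, ChannelImage, CellRecord, SampleMeta
from .foci import SpotCandidate

__all__ = [
    "PositivityThreshold",
    "WellSummary",
    "MARKER_FEATURE",
    "compute_cell_features",
    "compute_threshold",
    "classify_positive",
    "summarize_well",
]

#: paper-designated feature per marker (column names of the cell table)
MARKER_FEATURE = {
    Channel.M53BP1: "sum_spot_53bp1",
    Channel.GH2AX: "mean_gh2ax",
}


class InsufficientControlError(ValueError):
    """Fewer than two finite control values."""


@dataclass(frozen=True)
class PositivityThreshold:
    """mean + 1 sample SD of the negative control for one marker feature."""

    marker: Channel
    feature: str
    control_mean: float
    control_sd: float
    control_n: int

    @property
    def value(self) -> float:
        return self.control_mean + self.control_sd


@dataclass
class WellSummary:
    """Per-well aggregate of one marker feature plus positivity."""

    well_id: str
    meta: SampleMeta | None
    n_cells: int
    stats: dict[Channel, dict[str, float]]        # median/mean/sd/iqr per marker
    positive_fraction: dict[Channel, float]


def compute_cell_features(
    images: dict[Channel, ChannelImage | np.ndarray],
    labelmap: np.ndarray,
    accepted_spots: dict[Channel, list[SpotCandidate]],
    well_id: str = "A01",
    field_index: int = 1,
    meta: SampleMeta | None = None,
) -> list[CellRecord]:
    """One :class:`CellRecord` per nucleus label.

    Sum spot intensity and spot count use only *accepted* spots; mean nuclear
    intensity is the mean pixel value over the nucleus mask, computed for
    every provided channel.  Both feature families are stored for both
    markers; downstream analysis picks the designated one per marker.
    """
    labelmap = np.asarray(labelmap)
    labels = np.unique(labelmap)
    labels = labels[labels > 0]
    label_set = set(int(l) for l in labels)

    for marker, spots in accepted_spots.items():
        for spot in spots:
            if spot.nucleus_label not in label_set:
                raise ValueError(
                    f"{marker.value} spot references nucleus label "
                    f"{spot.nucleus_label}, not present in the label map"
                )

    mean_by_channel: dict[Channel, np.ndarray] = {}
    for channel, image in images.items():
        pixels = np.asarray(image.pixels if isinstance(image, ChannelImage) else image,
                            dtype=np.float64)
        if pixels.shape != labelmap.shape:
            raise ValueError(f"{channel.value} image shape mismatch with label map")
        sums = np.bincount(labelmap.ravel(), weights=pixels.ravel(),
                           minlength=labels.max() + 1 if len(labels) else 1)
        counts = np.bincount(labelmap.ravel(), minlength=labels.max() + 1 if len(labels) else 1)
        with np.errstate(invalid="ignore"):
            mean_by_channel[Channel(channel)] = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)

    counts_px = np.bincount(labelmap.ravel(), minlength=(labels.max() + 1 if len(labels) else 1))
    centroids = {}
    if len(labels):
        rr, cc = np.mgrid[: labelmap.shape[0], : labelmap.shape[1]]
        rsum = np.bincount(labelmap.ravel(), weights=rr.ravel(), minlength=labels.max() + 1)
        csum = np.bincount(labelmap.ravel(), weights=cc.ravel(), minlength=labels.max() + 1)
        for lab in labels:
            centroids[int(lab)] = (rsum[lab] / counts_px[lab], csum[lab] / counts_px[lab])

    records: list[CellRecord] = []
    for lab in labels:
        lab = int(lab)
        sum_spot: dict[Channel, float] = {}
        n_spot: dict[Channel, int] = {}
        for marker in (Channel.M53BP1, Channel.GH2AX):
            spots = [s for s in accepted_spots.get(marker, []) if s.nucleus_label == lab]
            sum_spot[marker] = float(sum(s.integrated_intensity for s in spots))
            n_spot[marker] = len(spots)
        records.append(
            CellRecord(
                cell_id=f"{well_id}_f{field_index:02d}_n{lab}",
                well_id=well_id,
                field_index=field_index,
                nucleus_label=lab,
                centroid_px=centroids[lab],
                nucleus_area_px=int(counts_px[lab]),
                mean_nuclear_intensity={
                    ch: float(means[lab]) for ch, means in mean_by_channel.items()
                },
                sum_spot_intensity=sum_spot,
                spot_count=n_spot,
                meta=meta,
            )
        )
    return records


def compute_threshold(
    control_values: np.ndarray,
    marker: Channel = Channel.GH2AX,
    feature: str | None = None,
) -> PositivityThreshold:
    """Negative-control threshold: mean + 1 sample SD (n-1 denominator)."""
    values = np.asarray(control_values, dtype=np.float64)
    values = values[np.isfinite(values)]
    if values.size < 2:
        raise InsufficientControlError(
            f"need >= 2 finite control values, got {values.size}"
        )
    mean = float(values.mean())
    sd = float(values.std(ddof=1))
    if sd == 0:
        warnings.warn(
            "control values are constant: SD = 0, threshold equals the mean",
            stacklevel=2,
        )
    return PositivityThreshold(
        marker=Channel(marker),
        feature=feature or MARKER_FEATURE[Channel(marker)],
        control_mean=mean,
        control_sd=sd,
        control_n=int(values.size),
    )


def classify_positive(
    values: np.ndarray | pd.Series,
    threshold: PositivityThreshold,
    marker: Channel | None = None,
) -> tuple[np.ndarray, float]:
    """Flags (value strictly > threshold) and the positive fraction."""
    if marker is not None and Channel(marker) is not threshold.marker:
        raise ValueError(
            f"threshold is for {threshold.marker.value}, requested {Channel(marker).value}"
        )
    values = np.asarray(values, dtype=np.float64)
    if values.size == 0:
        raise ValueError("cannot compute a positive fraction of zero cells")
    flags = values > threshold.value
    return flags, float(flags.mean())


def _feature_stats(values: np.ndarray) -> dict[str, float]:
    values = np.asarray(values, dtype=np.float64)
    q1, q3 = np.percentile(values, [25, 75])  # linear-interpolation quantiles
    return {
        "median": float(np.median(values)),
        "mean": float(values.mean()),
        "sd": float(values.std(ddof=1)) if values.size > 1 else float("nan"),
        "iqr": float(q3 - q1),
        "n": int(values.size),
    }


def summarize_well(
    cells: pd.DataFrame,
    thresholds: dict[Channel, PositivityThreshold] | None = None,
    meta: SampleMeta | None = None,
) -> WellSummary:
    """Aggregate one well's cells; empty wells yield n_cells = 0, no statistics."""
    wells = cells["well_id"].unique() if len(cells) else []
    if len(wells) > 1:
        raise ValueError(f"records span multiple wells: {sorted(wells)}")
    well_id = str(wells[0]) if len(wells) else ""
    if len(cells) == 0:
        return WellSummary(well_id=well_id, meta=meta, n_cells=0, stats={}, positive_fraction={})

    stats: dict[Channel, dict[str, float]] = {}
    positive: dict[Channel, float] = {}
    for marker, feature in MARKER_FEATURE.items():
        values = cells[feature].to_numpy(dtype=np.float64)
        stats[marker] = _feature_stats(values)
        if thresholds and marker in thresholds:
            _, positive[marker] = classify_positive(values, thresholds[marker])
    return WellSummary(
        well_id=well_id,
        meta=meta,
        n_cells=int(len(cells)),
        stats=stats,
        positive_fraction=positive,
    )
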