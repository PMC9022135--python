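"""Domain types and file I/O for plate-based fluorescence imaging.

The on-disk layout is one single-plane grayscale TIFF per well/field/channel,
named ``<WELL>_f<FIELD>_<CHANNEL>.tif`` (e.g. ``B03_f04_DAPI.tif``), plus a
per-cell CSV table and YAML plate layout / run configuration.  Intensities
are kept in native arbitrary units (A.U.); no normalisation or background
subtraction happens at I/O time.  Pixel coordinates are 0-based (row, col)
with row 0 the top image row.
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

__all__ = [
    "Channel",
    "Treatment",
    "ChannelImage",
    "SampleMeta",
    "PlateLayout",
    "CellRecord",
    "RunConfig",
    "FilenameError",
    "SchemaError",
    "parse_field_filename",
    "field_filename",
    "read_channel_image",
    "write_channel_image",
    "read_cell_table",
    "write_cell_table",
    "cell_records_to_frame",
    "read_plate_layout",
    "write_plate_layout",
]

#: physical pixel size of the emulated acquisition (60x lens, 2x2 binning)
DEFAULT_PIXEL_SIZE_UM = 0.216
#: default field shape in pixels (rows, cols): half of a 2560x2160 sCMOS chip
DEFAULT_FIELD_SHAPE = (1080, 1280)


class Channel(str, enum.Enum):
    """Fluorescence channel: DAPI (nuclei), 53BP1 and gamma-H2AX markers."""

    DAPI = "DAPI"
    M53BP1 = "53BP1"
    GH2AX = "gH2AX"


class Treatment(str, enum.Enum):
    UNTREATED = "UNTREATED"
    DMSO = "DMSO"
    ETP = "ETP"


_WELL_RE = re.compile(r"^([A-P])(0?[1-9]|1[0-9]|2[0-4])$")
_NAME_RE = re.compile(r"^(?P<well>[A-P]\d{2})_f(?P<field>\d+)_(?P<channel>DAPI|53BP1|gH2AX)\.tif{1,2}$")


class FilenameError(ValueError):
    """A field filename does not follow ``<WELL>_f<FIELD>_<CHANNEL>.tif``."""


class SchemaError(ValueError):
    """A table is missing mandatory columns."""


def validate_well_id(well_id: str) -> str:
    """Normalise a 384-well coordinate to zero-padded form (``B3`` -> ``B03``)."""
    m = _WELL_RE.match(well_id)
    if not m:
        raise ValueError(f"not a valid 384-well coordinate: {well_id!r}")
    return f"{m.group(1)}{int(m.group(2)):02d}"


@dataclass(frozen=True)
class ChannelImage:
    """One 2D fluorescence field for one well/field/channel.

    Parameters
    ----------
    pixels
        2D array of non-negative intensities in A.U.
    channel
        The acquisition channel.
    pixel_size_um
        Physical pixel size in micrometres (> 0).
    well_id
        384-well coordinate, e.g. ``"B03"``.
    field_index
        1-based field-of-view index within the well.
    """

    pixels: np.ndarray
    channel: Channel
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM
    well_id: str = "A01"
    field_index: int = 1

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2 or px.shape[0] < 1 or px.shape[1] < 1:
            raise ValueError(f"pixels must be a non-empty 2D array, got shape {px.shape}")
        if np.any(px < 0):
            raise ValueError("intensities must be >= 0")
        if not self.pixel_size_um > 0:
            raise ValueError("pixel_size_um must be > 0")
        if self.field_index < 1:
            raise ValueError("field_index must be >= 1")
        object.__setattr__(self, "pixels", px)
        object.__setattr__(self, "channel", Channel(self.channel))
        object.__setattr__(self, "well_id", validate_well_id(self.well_id))

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass(frozen=True)
class SampleMeta:
    """What was plated in one well."""

    donor_id: str
    cell_type: str
    treatment: Treatment
    treatment_dose_uM: float = 0.0
    replicate: int = 1

    def __post_init__(self) -> None:
        object.__setattr__(self, "treatment", Treatment(self.treatment))
        if self.treatment_dose_uM < 0:
            raise ValueError("treatment_dose_uM must be >= 0")
        if self.treatment is not Treatment.ETP and self.treatment_dose_uM != 0:
            raise ValueError("dose must be 0 unless treatment is ETP")
        if self.replicate < 1:
            raise ValueError("replicate must be >= 1")


@dataclass
class PlateLayout:
    """Map from 384-well coordinate to sample metadata."""

    wells: dict[str, SampleMeta] = field(default_factory=dict)

    def __post_init__(self) -> None:
        normalised: dict[str, SampleMeta] = {}
        for well_id, meta in self.wells.items():
            wid = validate_well_id(well_id)
            if wid in normalised:
                raise ValueError(f"duplicate well id {wid}")
            normalised[wid] = meta
        self.wells = normalised

    def __len__(self) -> int:
        return len(self.wells)

    def __getitem__(self, well_id: str) -> SampleMeta:
        return self.wells[validate_well_id(well_id)]

    def __contains__(self, well_id: str) -> bool:
        try:
            return validate_well_id(well_id) in self.wells
        except ValueError:
            return False


@dataclass
class CellRecord:
    """Per-cell marker features plus plate metadata.

    ``sum_spot_intensity`` holds the per-marker sum of integrated (background-
    subtracted) intensities of the accepted foci in the nucleus;
    ``mean_nuclear_intensity`` the per-channel mean pixel value over the
    nucleus mask.  Both are computed for both damage markers; downstream
    analysis uses sum spot intensity for 53BP1 and mean nuclear intensity for
    gamma-H2AX by default.
    """

    cell_id: str
    well_id: str
    field_index: int
    nucleus_label: int
    centroid_px: tuple[float, float]
    nucleus_area_px: int
    mean_nuclear_intensity: dict[Channel, float]
    sum_spot_intensity: dict[Channel, float]
    spot_count: dict[Channel, int]
    meta: SampleMeta | None = None

    def __post_init__(self) -> None:
        if self.nucleus_label < 1:
            raise ValueError("nucleus_label must be >= 1")
        if self.nucleus_area_px <= 0:
            raise ValueError("nucleus_area_px must be > 0")
        for marker, total in self.sum_spot_intensity.items():
            if total < 0:
                raise ValueError("sum_spot_intensity must be >= 0")
            if self.spot_count.get(marker, 0) == 0 and total != 0:
                raise ValueError(f"{marker}: zero spots but nonzero sum intensity")


@dataclass
class RunConfig:
    """Bundle of stage parameters plus seed and I/O paths for one pipeline run."""

    seed: int = 0
    images_dir: str | None = None
    layout_path: str | None = None
    output_path: str | None = None
    segmentation: dict = field(default_factory=dict)
    spot_detection: dict = field(default_factory=dict)
    classifier_path: str | None = None
    control_condition: str = "DMSO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.__dict__, fh, sort_keys=False)


# ---------------------------------------------------------------------------
# field filenames


def field_filename(well_id: str, field_index: int, channel: Channel | str) -> str:
    """Build the canonical field filename, inverse of :func:`parse_field_filename`."""
    if field_index < 1:
        raise ValueError("field_index must be >= 1")
    return f"{validate_well_id(well_id)}_f{field_index:02d}_{Channel(channel).value}.tif"


def parse_field_filename(name: str) -> tuple[str, int, Channel]:
    """Split ``<WELL>_f<FIELD>_<CHANNEL>.tif`` into (well_id, field_index, channel).

    Raises
    ------
    FilenameError
        If the name does not match the convention; the message names the
        offending token.
    """
    base = Path(name).name
    m = _NAME_RE.match(base)
    if not m:
        parts = base.rsplit(".", 1)[0].split("_")
        if len(parts) != 3:
            raise FilenameError(f"expected 3 '_'-separated tokens in {base!r}, got {len(parts)}")
        well, fld, chan = parts
        if not _WELL_RE.match(well):
            raise FilenameError(f"bad well token {well!r} in {base!r}")
        if not re.match(r"^f\d+$", fld):
            raise FilenameError(f"bad field token {fld!r} in {base!r} (expected fNN)")
        raise FilenameError(f"bad channel token {chan!r} in {base!r} (expected DAPI, 53BP1 or gH2AX)")
    return (m.group("well"), int(m.group("field")), Channel(m.group("channel")))


# ---------------------------------------------------------------------------
# TIFF images


def write_channel_image(image: ChannelImage, path: str | Path) -> Path:
    """Write one field as a single-plane grayscale TIFF; returns the path."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(
        path,
        image.pixels,
        resolution=(1e4 / image.pixel_size_um, 1e4 / image.pixel_size_um),
    )
    return path


def read_channel_image(path: str | Path, pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM) -> ChannelImage:
    """Read a single-plane grayscale TIFF whose name follows the convention.

    Multi-plane or RGB TIFFs are rejected with :class:`ValueError`.
    """
    path = Path(path)
    pixels = tifffile.imread(path)
    if pixels.ndim != 2:
        raise ValueError(
            f"{path.name}: unsupported format — expected single-plane grayscale, got shape {pixels.shape}"
        )
    well_id, field_index, channel = parse_field_filename(path.name)
    return ChannelImage(
        pixels=pixels,
        channel=channel,
        pixel_size_um=pixel_size_um,
        well_id=well_id,
        field_index=field_index,
    )


# ---------------------------------------------------------------------------
# per-cell CSV tables

#: stable column schema for per-cell tables (one row per cell)
CELL_TABLE_COLUMNS = [
    "cell_id",
    "well_id",
    "field_index",
    "nucleus_label",
    "centroid_row",
    "centroid_col",
    "nucleus_area_px",
    "mean_dapi",
    "mean_53bp1",
    "mean_gh2ax",
    "sum_spot_53bp1",
    "sum_spot_gh2ax",
    "spot_count_53bp1",
    "spot_count_gh2ax",
    "donor_id",
    "cell_type",
    "treatment",
    "treatment_dose_uM",
    "replicate",
]

_MANDATORY_COLUMNS = CELL_TABLE_COLUMNS[:14]


def cell_records_to_frame(records: list[CellRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        meta = r.meta
        rows.append(
            {
                "cell_id": r.cell_id,
                "well_id": r.well_id,
                "field_index": r.field_index,
                "nucleus_label": r.nucleus_label,
                "centroid_row": r.centroid_px[0],
                "centroid_col": r.centroid_px[1],
                "nucleus_area_px": r.nucleus_area_px,
                "mean_dapi": r.mean_nuclear_intensity.get(Channel.DAPI, np.nan),
                "mean_53bp1": r.mean_nuclear_intensity.get(Channel.M53BP1, np.nan),
                "mean_gh2ax": r.mean_nuclear_intensity.get(Channel.GH2AX, np.nan),
                "sum_spot_53bp1": r.sum_spot_intensity.get(Channel.M53BP1, 0.0),
                "sum_spot_gh2ax": r.sum_spot_intensity.get(Channel.GH2AX, 0.0),
                "spot_count_53bp1": r.spot_count.get(Channel.M53BP1, 0),
                "spot_count_gh2ax": r.spot_count.get(Channel.GH2AX, 0),
                "donor_id": meta.donor_id if meta else "",
                "cell_type": meta.cell_type if meta else "",
                "treatment": meta.treatment.value if meta else "",
                "treatment_dose_uM": meta.treatment_dose_uM if meta else 0.0,
                "replicate": meta.replicate if meta else 1,
            }
        )
    return pd.DataFrame(rows, columns=CELL_TABLE_COLUMNS)


def write_cell_table(records: list[CellRecord] | pd.DataFrame, path: str | Path) -> Path:
    """Write per-cell records as a comma-separated, UTF-8, headered CSV."""
    frame = records if isinstance(records, pd.DataFrame) else cell_records_to_frame(records)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(path, index=False)
    return path


def read_cell_table(path: str | Path) -> pd.DataFrame:
    """Read a per-cell CSV, validating the mandatory column schema."""
    frame = pd.read_csv(path)
    missing = [c for c in _MANDATORY_COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(f"cell table missing mandatory columns: {missing}")
    return frame


# ---------------------------------------------------------------------------
# plate layout YAML


def write_plate_layout(layout: PlateLayout, path: str | Path) -> Path:
    data = {
        wid: {
            "donor_id": m.donor_id,
            "cell_type": m.cell_type,
            "treatment": m.treatment.value,
            "treatment_dose_uM": m.treatment_dose_uM,
            "replicate": m.replicate,
        }
        for wid, m in layout.wells.items()
    }
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=True)
    return path


def read_plate_layout(path: str | Path) -> PlateLayout:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    wells = {wid: SampleMeta(**meta) for wid, meta in data.items()}
    return PlateLayout(wells=wells)
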