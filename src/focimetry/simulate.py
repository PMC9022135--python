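"""Synthetic fluorescence-microscopy fields with ground truth.

Emulates the three-channel acquisition of a DNA-damage assay: DAPI-stained
elliptical nuclei, a 53BP1 channel containing diffraction-limited Gaussian
foci, and a gamma-H2AX channel combining a pan-nuclear level with foci.
An etoposide-like "treated" condition raises both the per-cell focus rate
and the pan-nuclear gamma-H2AX level, so condition contrast propagates to
every downstream feature.

The signal model per channel, before noise, is

    DAPI    = background + nucleus_intensity * mask
    53BP1   = background + sum of foci
    gH2AX   = background + pan_nuclear(condition) * mask + sum of foci

with each focus an isotropic 2D Gaussian of width ``focus_sigma_um`` and a
log-normal amplitude.  Noise is Poisson on the noise-free signal followed by
additive Gaussian read noise (camera convention); images are clipped at 0.
Everything is reproducible from ``(config, seed)``.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .io import (
    Channel,
    ChannelImage,
    PlateLayout,
    Treatment,
    field_filename,
    write_channel_image,
)

__all__ = [
    "SimulationConfig",
    "CellTruth",
    "GroundTruth",
    "PlacementError",
    "simulate_field",
    "simulate_plate",
    "simulate_cell_features",
]

#: damage markers that carry foci
MARKERS = (Channel.M53BP1, Channel.GH2AX)


def _default_foci_rate() -> dict[tuple[Channel, Treatment], float]:
    # control -> treated contrast: 53BP1 lambda 1 -> 8; gH2AX lambda 1 -> 6
    return {
        (Channel.M53BP1, Treatment.UNTREATED): 1.0,
        (Channel.M53BP1, Treatment.DMSO): 1.0,
        (Channel.M53BP1, Treatment.ETP): 8.0,
        (Channel.GH2AX, Treatment.UNTREATED): 1.0,
        (Channel.GH2AX, Treatment.DMSO): 1.0,
        (Channel.GH2AX, Treatment.ETP): 6.0,
    }


def _default_pan_nuclear() -> dict[Treatment, float]:
    # 2.5x pan-nuclear gamma-H2AX induction under treatment
    return {Treatment.UNTREATED: 40.0, Treatment.DMSO: 40.0, Treatment.ETP: 100.0}


@dataclass
class SimulationConfig:
    """Parameters of the synthetic acquisition.

    Defaults emulate a 60x / 2x2-binned confocal field (216 nm/px) of
    immune-cell nuclei (radius 3.0-4.5 um) with a treated condition that
    raises the 53BP1 focus rate from 1 to 8 per cell and pan-nuclear
    gamma-H2AX 2.5-fold.
    """

    field_shape_px: tuple[int, int] = (1080, 1280)
    pixel_size_um: float = 0.216
    n_cells: int = 40
    nucleus_radius_um: tuple[float, float] = (3.0, 4.5)
    nucleus_intensity: float = 500.0
    foci_rate: dict[tuple[Channel, Treatment], float] = field(default_factory=_default_foci_rate)
    focus_sigma_um: float = 0.35
    focus_amplitude_median: float = 300.0
    focus_amplitude_gsd: float = 1.6
    pan_nuclear_gh2ax: dict[Treatment, float] = field(default_factory=_default_pan_nuclear)
    background: float = 10.0
    read_noise_sd: float = 2.0
    shot_noise: bool = True
    cell_brightness_gsd: float = 1.25
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be > 0")
        if self.n_cells < 0:
            raise ValueError("n_cells must be >= 0")
        rmin, rmax = self.nucleus_radius_um
        if not (0 < rmin <= rmax):
            raise ValueError("nucleus_radius_um must satisfy 0 < min <= max")
        if any(lam < 0 for lam in self.foci_rate.values()):
            raise ValueError("foci rates must be >= 0")
        for name in ("nucleus_intensity", "focus_sigma_um", "focus_amplitude_median",
                     "background", "read_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        h, w = self.field_shape_px
        if min(h, w) < 2 * rmax / self.pixel_size_um:
            raise ValueError("field too small to hold one nucleus")

    @property
    def focus_sigma_px(self) -> float:
        return self.focus_sigma_um / self.pixel_size_um


@dataclass
class CellTruth:
    """Ground truth for one simulated cell."""

    index: int
    condition: Treatment
    center_px: tuple[float, float]
    radii_px: tuple[float, float]
    theta: float
    brightness: float
    focus_centers: dict[Channel, np.ndarray]      # (k, 2) row/col
    focus_amplitudes: dict[Channel, np.ndarray]   # (k,)

    @property
    def focus_count(self) -> dict[Channel, int]:
        return {m: len(self.focus_centers[m]) for m in MARKERS}

    def mask(self, shape: tuple[int, int]) -> np.ndarray:
        return _ellipse_mask(shape, self.center_px, self.radii_px, self.theta)


@dataclass
class GroundTruth:
    """Per-field ground truth: one :class:`CellTruth` per placed cell."""

    cells: list[CellTruth]
    condition: Treatment
    field_shape_px: tuple[int, int]

    def __len__(self) -> int:
        return len(self.cells)

    def label_map(self) -> np.ndarray:
        """True segmentation: cells painted in placement order (non-overlapping)."""
        labels = np.zeros(self.field_shape_px, dtype=np.int32)
        for cell in self.cells:
            labels[cell.mask(self.field_shape_px)] = cell.index
        return labels


class PlacementError(RuntimeError):
    """Could not place the requested number of nuclei at the required spacing."""


def _ellipse_mask(shape, center, radii, theta) -> np.ndarray:
    rr, cc = np.mgrid[: shape[0], : shape[1]]
    dr, dc = rr - center[0], cc - center[1]
    ct, st = np.cos(theta), np.sin(theta)
    u = dr * ct + dc * st
    v = -dr * st + dc * ct
    return (u / radii[0]) ** 2 + (v / radii[1]) ** 2 <= 1.0


def _place_centers(rng, shape, n, min_dist, margin, retries_per_cell=200):
    centers: list[tuple[float, float]] = []
    attempts = 0
    budget = max(1, n) * retries_per_cell
    while len(centers) < n:
        if attempts >= budget:
            raise PlacementError(
                f"placed only {len(centers)}/{n} nuclei after {budget} attempts "
                f"(min spacing {min_dist:.1f} px)"
            )
        attempts += 1
        r = rng.uniform(margin, shape[0] - margin)
        c = rng.uniform(margin, shape[1] - margin)
        if all((r - r0) ** 2 + (c - c0) ** 2 >= min_dist**2 for r0, c0 in centers):
            centers.append((r, c))
    return centers


def _sample_point_in_ellipse(rng, center, radii, theta, shrink=0.85):
    """Uniform point inside the ellipse, pulled in from the rim."""
    t = rng.uniform(0, 2 * np.pi)
    rho = np.sqrt(rng.uniform()) * shrink
    u = rho * radii[0] * np.cos(t)
    v = rho * radii[1] * np.sin(t)
    ct, st = np.cos(theta), np.sin(theta)
    return (center[0] + u * ct - v * st, center[1] + u * st + v * ct)


def _render_foci(canvas: np.ndarray, centers: np.ndarray, amplitudes: np.ndarray, sigma: float) -> None:
    """Add isotropic Gaussians in place; window of 5 sigma keeps >99.99% of mass."""
    if len(centers) == 0:
        return
    h, w = canvas.shape
    half = int(np.ceil(5 * sigma))
    for (r0, c0), amp in zip(centers, amplitudes):
        rlo, rhi = max(0, int(r0) - half), min(h, int(r0) + half + 1)
        clo, chi = max(0, int(c0) - half), min(w, int(c0) + half + 1)
        rr, cc = np.mgrid[rlo:rhi, clo:chi]
        canvas[rlo:rhi, clo:chi] += amp * np.exp(
            -((rr - r0) ** 2 + (cc - c0) ** 2) / (2 * sigma**2)
        )


def _sample_amplitudes(rng, n, median, gsd):
    return median * np.exp(rng.normal(0.0, np.log(gsd), size=n))


def simulate_field(
    config: SimulationConfig,
    condition: Treatment | str = Treatment.UNTREATED,
    seed: int | None = None,
    well_id: str = "A01",
    field_index: int = 1,
) -> tuple[dict[Channel, ChannelImage], GroundTruth]:
    """Render one three-channel field plus its ground truth.

    Nuclei are ellipses whose centres are at least twice the maximum nucleus
    radius apart (non-overlapping by construction); focus centres lie inside
    their parent nucleus.
    """
    condition = Treatment(condition)
    rng = np.random.default_rng(config.seed if seed is None else seed)
    shape = tuple(config.field_shape_px)
    rmin_px = config.nucleus_radius_um[0] / config.pixel_size_um
    rmax_px = config.nucleus_radius_um[1] / config.pixel_size_um

    centers = _place_centers(
        rng, shape, config.n_cells, min_dist=2 * rmax_px, margin=rmax_px + 3
    )

    cells: list[CellTruth] = []
    for i, center in enumerate(centers, start=1):
        radii = tuple(np.sort(rng.uniform(rmin_px, rmax_px, size=2))[::-1])
        theta = rng.uniform(0, np.pi)
        brightness = float(np.exp(rng.normal(0.0, np.log(config.cell_brightness_gsd))))
        focus_centers: dict[Channel, np.ndarray] = {}
        focus_amplitudes: dict[Channel, np.ndarray] = {}
        for marker in MARKERS:
            lam = config.foci_rate.get((marker, condition), 0.0)
            k = int(rng.poisson(lam))
            pts = np.array(
                [_sample_point_in_ellipse(rng, center, radii, theta) for _ in range(k)]
            ).reshape(k, 2)
            focus_centers[marker] = pts
            focus_amplitudes[marker] = _sample_amplitudes(
                rng, k, config.focus_amplitude_median, config.focus_amplitude_gsd
            )
        cells.append(
            CellTruth(
                index=i,
                condition=condition,
                center_px=center,
                radii_px=radii,
                theta=theta,
                brightness=brightness,
                focus_centers=focus_centers,
                focus_amplitudes=focus_amplitudes,
            )
        )

    truth = GroundTruth(cells=cells, condition=condition, field_shape_px=shape)

    dapi = np.full(shape, config.background, dtype=np.float64)
    bp1 = np.full(shape, config.background, dtype=np.float64)
    gh2ax = np.full(shape, config.background, dtype=np.float64)
    pan = config.pan_nuclear_gh2ax.get(condition, 0.0)
    for cell in cells:
        mask = cell.mask(shape)
        dapi[mask] += config.nucleus_intensity * cell.brightness
        gh2ax[mask] += pan * cell.brightness
        _render_foci(bp1, cell.focus_centers[Channel.M53BP1],
                     cell.focus_amplitudes[Channel.M53BP1], config.focus_sigma_px)
        _render_foci(gh2ax, cell.focus_centers[Channel.GH2AX],
                     cell.focus_amplitudes[Channel.GH2AX], config.focus_sigma_px)

    images: dict[Channel, ChannelImage] = {}
    for channel, canvas in ((Channel.DAPI, dapi), (Channel.M53BP1, bp1), (Channel.GH2AX, gh2ax)):
        if config.shot_noise:
            canvas = rng.poisson(canvas).astype(np.float64)
        if config.read_noise_sd > 0:
            canvas = canvas + rng.normal(0.0, config.read_noise_sd, size=shape)
        images[channel] = ChannelImage(
            pixels=np.clip(canvas, 0, None).astype(np.float32),
            channel=channel,
            pixel_size_um=config.pixel_size_um,
            well_id=well_id,
            field_index=field_index,
        )
    return images, truth


def _well_field_seed(master_seed: int, well_id: str, field_index: int) -> int:
    """Deterministic per-well/field stream, independent of iteration order."""
    h = zlib.crc32(f"{well_id}/{field_index}".encode())
    return int(np.random.SeedSequence([master_seed, h]).generate_state(1)[0] % (2**31))


def truth_to_frames(
    truths: Iterable[tuple[str, int, GroundTruth]]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Flatten ground truth into a per-cell and a per-focus table."""
    cell_rows, focus_rows = [], []
    for well_id, field_index, truth in truths:
        for cell in truth.cells:
            cell_rows.append(
                {
                    "well_id": well_id,
                    "field_index": field_index,
                    "cell_index": cell.index,
                    "condition": cell.condition.value,
                    "center_row": cell.center_px[0],
                    "center_col": cell.center_px[1],
                    "radius_major_px": cell.radii_px[0],
                    "radius_minor_px": cell.radii_px[1],
                    "theta": cell.theta,
                    "brightness": cell.brightness,
                    "n_foci_53bp1": cell.focus_count[Channel.M53BP1],
                    "n_foci_gh2ax": cell.focus_count[Channel.GH2AX],
                }
            )
            for marker in MARKERS:
                for (r, c), amp in zip(cell.focus_centers[marker], cell.focus_amplitudes[marker]):
                    focus_rows.append(
                        {
                            "well_id": well_id,
                            "field_index": field_index,
                            "cell_index": cell.index,
                            "marker": marker.value,
                            "row": r,
                            "col": c,
                            "amplitude": amp,
                        }
                    )
    cell_cols = ["well_id", "field_index", "cell_index", "condition", "center_row",
                 "center_col", "radius_major_px", "radius_minor_px", "theta",
                 "brightness", "n_foci_53bp1", "n_foci_gh2ax"]
    focus_cols = ["well_id", "field_index", "cell_index", "marker", "row", "col", "amplitude"]
    return (
        pd.DataFrame(cell_rows, columns=cell_cols),
        pd.DataFrame(focus_rows, columns=focus_cols),
    )


def simulate_plate(
    layout: PlateLayout,
    config: SimulationConfig,
    out_dir: str | Path,
    fields_per_well: int = 9,
    seed: int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate every well of a layout to disk.

    Writes one TIFF per well/field/channel using the naming convention and
    returns (and writes) the per-cell / per-focus ground-truth tables.
    Per-well/field seeds are derived by hashing the master seed with the well
    id and field index, so adding wells never changes existing wells' data.
    """
    if len(layout) == 0:
        raise ValueError("layout is empty")
    master_seed = config.seed if seed is None else seed
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    truths: list[tuple[str, int, GroundTruth]] = []
    for well_id in sorted(layout.wells):
        meta = layout.wells[well_id]
        for field_index in range(1, fields_per_well + 1):
            fseed = _well_field_seed(master_seed, well_id, field_index)
            images, truth = simulate_field(
                config, condition=meta.treatment, seed=fseed,
                well_id=well_id, field_index=field_index,
            )
            for channel, image in images.items():
                write_channel_image(image, out_dir / field_filename(well_id, field_index, channel))
            truths.append((well_id, field_index, truth))

    cell_truth, focus_truth = truth_to_frames(truths)
    cell_truth.to_csv(out_dir / "ground_truth_cells.csv", index=False)
    focus_truth.to_csv(out_dir / "ground_truth_foci.csv", index=False)
    return cell_truth, focus_truth


def simulate_cell_features(
    config: SimulationConfig,
    condition: Treatment | str,
    n_cells: int,
    rng: np.random.Generator | int | None = None,
) -> pd.DataFrame:
    """Sample per-cell marker features from the generative model, skipping pixels.

    Draws each cell's true focus complement and nuclear brightness exactly as
    :func:`simulate_field` does and converts them to the two downstream
    features analytically: 53BP1 sum spot intensity is the sum of focus
    integrals ``amplitude * 2*pi*sigma_px**2``; gamma-H2AX mean nuclear
    intensity is background + pan-nuclear level + focus mass spread over the
    nucleus area, with read noise scaled down by the pixel count.  Useful for
    statistical calibrations that need many plates' worth of cells.
    """
    condition = Treatment(condition)
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(config.seed if rng is None else rng)
    focus_integral = 2 * np.pi * config.focus_sigma_px**2
    rmin_px = config.nucleus_radius_um[0] / config.pixel_size_um
    rmax_px = config.nucleus_radius_um[1] / config.pixel_size_um
    pan = config.pan_nuclear_gh2ax.get(condition, 0.0)

    radii = rng.uniform(rmin_px, rmax_px, size=(n_cells, 2))
    area = np.pi * radii[:, 0] * radii[:, 1]
    brightness = np.exp(rng.normal(0.0, np.log(config.cell_brightness_gsd), size=n_cells))

    def focus_mass(marker: Channel) -> tuple[np.ndarray, np.ndarray]:
        lam = config.foci_rate.get((marker, condition), 0.0)
        k = rng.poisson(lam, size=n_cells)
        amps = _sample_amplitudes(rng, int(k.sum()), config.focus_amplitude_median,
                                  config.focus_amplitude_gsd)
        sums = np.zeros(n_cells)
        np.add.at(sums, np.repeat(np.arange(n_cells), k), amps)
        return k, sums

    k_bp1, mass_bp1 = focus_mass(Channel.M53BP1)
    k_gh, mass_gh = focus_mass(Channel.GH2AX)
    mean_gh = (
        config.background
        + pan * brightness
        + mass_gh * focus_integral / area
        + rng.normal(0.0, 1.0, size=n_cells) * config.read_noise_sd / np.sqrt(area)
    )
    return pd.DataFrame(
        {
            "condition": condition.value,
            "sum_spot_53bp1": mass_bp1 * focus_integral,
            "mean_gh2ax": mean_gh,
            "spot_count_53bp1": k_bp1,
            "spot_count_gh2ax": k_gh,
        },
        columns=["condition", "sum_spot_53bp1", "mean_gh2ax",
                 "spot_count_53bp1", "spot_count_gh2ax"],
    )
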