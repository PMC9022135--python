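"""Simulator contracts: determinism, signal model, focus statistics."""

import numpy as np
import pytest

from focimetry.io import Channel, PlateLayout, SampleMeta, Treatment
from focimetry.simulate import (
    MARKERS,
    PlacementError,
    SimulationConfig,
    simulate_cell_features,
    simulate_field,
    simulate_plate,
)


class TestSimulateField:
    def test_empty_field_is_pure_background(self):
        config = SimulationConfig(field_shape_px=(256, 256), n_cells=0, seed=3)
        images, truth = simulate_field(config, "UNTREATED")
        assert len(truth) == 0
        for image in images.values():
            # mean of n iid pixels: background +/- 3 * noise_sd / sqrt(n)
            noise_sd = np.sqrt(config.background + config.read_noise_sd**2)
            tol = 3 * noise_sd / np.sqrt(image.pixels.size)
            # clipping at 0 biases the mean up slightly; allow 1% extra
            assert abs(image.pixels.mean() - config.background) < tol + 0.01 * config.background

    def test_zero_rates_give_zero_foci(self):
        config = SimulationConfig(
            field_shape_px=(512, 512),
            n_cells=6,
            foci_rate={(m, t): 0.0 for m in MARKERS for t in Treatment},
            seed=4,
        )
        _, truth = simulate_field(config, "ETP")
        assert all(c.focus_count[m] == 0 for c in truth.cells for m in MARKERS)

    def test_focus_count_matches_poisson_rate(self):
        # lambda = 4: sample mean over n cells within 3*sqrt(4/n) of 4
        config = SimulationConfig(
            field_shape_px=(1080, 1280),
            n_cells=120,
            foci_rate={(m, t): 4.0 for m in MARKERS for t in Treatment},
            shot_noise=False,
            read_noise_sd=0.0,
            seed=5,
        )
        counts = []
        for k in range(3):
            _, truth = simulate_field(config, "UNTREATED", seed=50 + k)
            counts.extend(c.focus_count[Channel.M53BP1] for c in truth.cells)
        counts = np.asarray(counts, dtype=float)
        assert abs(counts.mean() - 4.0) < 3 * np.sqrt(4.0 / counts.size)

    def test_determinism_and_seed_sensitivity(self, small_config):
        a1, t1 = simulate_field(small_config, "ETP", seed=7)
        a2, t2 = simulate_field(small_config, "ETP", seed=7)
        b, _ = simulate_field(small_config, "ETP", seed=8)
        for ch in a1:
            assert np.array_equal(a1[ch].pixels, a2[ch].pixels)
        assert any(not np.array_equal(a1[ch].pixels, b[ch].pixels) for ch in a1)
        assert len(t1) == len(t2)

    def test_focus_centers_inside_parent_nucleus(self, small_config):
        _, truth = simulate_field(small_config, "ETP", seed=9)
        shape = truth.field_shape_px
        for cell in truth.cells:
            mask = cell.mask(shape)
            for marker in MARKERS:
                for r, c in cell.focus_centers[marker]:
                    assert mask[int(round(r)), int(round(c))]

    def test_focus_integral_conservation_without_noise(self, noiseless_config):
        # integrated focus signal above background = amplitude * 2*pi*sigma^2
        images, truth = simulate_field(noiseless_config, "ETP", seed=11)
        sigma = noiseless_config.focus_sigma_px
        pixels = images[Channel.M53BP1].pixels.astype(np.float64)
        for cell in truth.cells:
            centers = cell.focus_centers[Channel.M53BP1]
            if len(centers) != 1:
                continue  # isolated foci only: overlapping integrals mix
            (r0, c0), amp = centers[0], cell.focus_amplitudes[Channel.M53BP1][0]
            half = int(np.ceil(5 * sigma))
            win = pixels[
                int(r0) - half : int(r0) + half + 1, int(c0) - half : int(c0) + half + 1
            ]
            integral = (win - noiseless_config.background).sum()
            assert integral == pytest.approx(amp * 2 * np.pi * sigma**2, rel=0.01)

    def test_treatment_raises_rates_and_pan_nuclear(self):
        config = SimulationConfig()
        lam = config.foci_rate
        assert lam[(Channel.M53BP1, Treatment.ETP)] > lam[(Channel.M53BP1, Treatment.UNTREATED)]
        assert (
            config.pan_nuclear_gh2ax[Treatment.ETP]
            > config.pan_nuclear_gh2ax[Treatment.UNTREATED]
        )
        # and it shows in the rendered images
        cfg = SimulationConfig(field_shape_px=(512, 512), n_cells=6)
        etp, truth_e = simulate_field(cfg, "ETP", seed=13)
        ctl, truth_c = simulate_field(cfg, "UNTREATED", seed=13)
        assert etp[Channel.GH2AX].pixels.mean() > ctl[Channel.GH2AX].pixels.mean()

    def test_overcrowded_field_raises_placement_error(self):
        config = SimulationConfig(field_shape_px=(256, 256), n_cells=80, seed=1)
        with pytest.raises(PlacementError):
            simulate_field(config, "UNTREATED")

    def test_invalid_rate_rejected(self):
        with pytest.raises(ValueError, match="rate"):
            SimulationConfig(foci_rate={(Channel.M53BP1, Treatment.ETP): -1.0})


class TestSimulatePlate:
    @pytest.fixture()
    def layout(self):
        return PlateLayout(
            {
                "B03": SampleMeta("D1", "JURKAT", Treatment.DMSO),
                "B04": SampleMeta("D1", "JURKAT", Treatment.ETP, 30.0),
            }
        )

    def test_file_count_and_determinism(self, layout, tmp_path):
        config = SimulationConfig(field_shape_px=(256, 256), n_cells=3, seed=0)
        simulate_plate(layout, config, tmp_path / "a", fields_per_well=9, seed=42)
        tiffs = sorted((tmp_path / "a").glob("*.tif"))
        assert len(tiffs) == 2 * 9 * 3  # wells x fields x channels
        simulate_plate(layout, config, tmp_path / "b", fields_per_well=9, seed=42)
        for p in tiffs:
            assert p.read_bytes() == (tmp_path / "b" / p.name).read_bytes()

    def test_distinct_wells_have_distinct_streams(self, layout, tmp_path):
        config = SimulationConfig(field_shape_px=(256, 256), n_cells=3, seed=0)
        # same condition in both wells so only the RNG stream differs
        same = PlateLayout(
            {
                "C01": SampleMeta("D1", "JURKAT", Treatment.DMSO),
                "C02": SampleMeta("D1", "JURKAT", Treatment.DMSO),
            }
        )
        simulate_plate(same, config, tmp_path / "p", fields_per_well=1, seed=7)
        a = (tmp_path / "p" / "C01_f01_DAPI.tif").read_bytes()
        b = (tmp_path / "p" / "C02_f01_DAPI.tif").read_bytes()
        assert a != b

    def test_empty_layout_rejected(self, tmp_path):
        with pytest.raises(ValueError, match="empty"):
            simulate_plate(PlateLayout({}), SimulationConfig(), tmp_path)


class TestCellFeatureSampler:
    def test_condition_contrast_matches_field_model(self):
        config = SimulationConfig(seed=0)
        rng = np.random.default_rng(21)
        ctl = simulate_cell_features(config, "UNTREATED", 400, rng)
        etp = simulate_cell_features(config, "ETP", 400, rng)
        assert etp["sum_spot_53bp1"].median() > ctl["sum_spot_53bp1"].median()
        assert etp["mean_gh2ax"].median() > ctl["mean_gh2ax"].median()
        lam = config.foci_rate[(Channel.M53BP1, Treatment.ETP)]
        assert etp["spot_count_53bp1"].mean() == pytest.approx(lam, abs=3 * np.sqrt(lam / 400))
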