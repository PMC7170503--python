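"""Voxel-wise fitting, S_Dw maps, file round-trips, and the CLI."""

import numpy as np
import pytest
from click.testing import CliRunner

import dwspect as dw
from dwspect import io
from dwspect.cli import main as cli_main


@pytest.fixture(scope="module")
def small_grid():
    return dw.make_d_grid(60, 1e-8, 1e-1)


@pytest.fixture(scope="module")
def phantom(small_grid):
    shape = (3, 2, 1)
    left = np.zeros(shape, bool)
    left[0] = True
    right = np.zeros(shape, bool)
    right[1:] = True
    slow_d = small_grid.values[25]
    fast_d = small_grid.values[45]
    spec = dw.PhantomSpec(
        shape=shape,
        regions={"slow": (left, (dw.CompartmentSpec(slow_d, 1.0),)),
                 "fast": (right, (dw.CompartmentSpec(fast_d, 1.0),))},
        schedule=dw.default_schedule(), snr=np.inf,
    )
    stack, truth, masks = dw.simulate_phantom(spec, small_grid)
    full = dw.RoiMask(left | right, label="tissue")
    return stack, truth, masks, full, (slow_d, fast_d)


class TestFitVoxelwise:
    def test_empty_mask_gives_empty_volume(self, schedule, small_grid, caplog):
        stack = np.ones((2, 2, 1, len(schedule)))
        mask = dw.RoiMask(np.zeros((2, 2, 1), bool), label="empty")
        with caplog.at_level("WARNING"):
            vol = dw.fit_voxelwise(stack, mask, schedule, small_grid,
                                   dw.FitConfig(alpha=0.0), denoise=False)
        assert vol.n_fitted == 0
        assert np.all(np.isnan(vol.weights))
        assert any("empty" in r.message for r in caplog.records)

    def test_homogeneous_phantom_has_one_dominant_d(self, schedule, small_grid, phantom):
        stack, _, masks, _, (slow_d, _) = phantom
        vol = dw.fit_voxelwise(stack, masks["slow"], schedule, small_grid,
                               dw.FitConfig(alpha=0.0), denoise=False)
        dominant = np.nanargmax(vol.weights[masks["slow"].data], axis=1)
        assert np.all(small_grid.values[dominant] == slow_d)

    def test_two_region_labels_recoverable_by_dominant_d(self, schedule, small_grid, phantom):
        stack, _, masks, full, (slow_d, fast_d) = phantom
        vol = dw.fit_voxelwise(stack, full, schedule, small_grid,
                               dw.FitConfig(alpha=0.0), denoise=False)
        threshold = np.sqrt(slow_d * fast_d)
        dominant = np.full(full.data.shape, np.nan)
        for idx in np.argwhere(full.data):
            dominant[tuple(idx)] = small_grid.values[int(np.argmax(vol.weights[tuple(idx)]))]
        assert np.all(dominant[masks["slow"].data] < threshold)
        assert np.all(dominant[masks["fast"].data] > threshold)

    def test_schedule_mismatch_raises(self, schedule, small_grid):
        stack = np.ones((2, 2, 1, 10))
        mask = dw.RoiMask(np.ones((2, 2, 1), bool))
        with pytest.raises(ValueError, match="schedule"):
            dw.fit_voxelwise(stack, mask, schedule, small_grid)

    def test_failed_voxels_flagged_not_dropped(self, schedule, small_grid):
        stack = np.ones((2, 1, 1, len(schedule)))
        stack[1, 0, 0] = 0.0  # unnormalizable voxel
        mask = dw.RoiMask(np.ones((2, 1, 1), bool))
        vol = dw.fit_voxelwise(stack, mask, schedule, small_grid,
                               dw.FitConfig(alpha=0.0), denoise=False)
        assert vol.failed[1, 0, 0]
        assert not vol.failed[0, 0, 0]


class TestSdwMap:
    def make_volume(self, grid, weights, mask):
        shape = mask.data.shape
        return dw.VoxelSpectraVolume(
            grid=grid, schedule=dw.default_schedule(), mask=mask,
            weights=weights, mu=np.zeros(shape), chi2_ratio=np.ones(shape),
            failed=np.zeros(shape, bool))

    def test_uniform_spectra_give_constant_map(self, small_grid):
        mask = dw.RoiMask(np.ones((2, 2, 1), bool))
        w = np.zeros((2, 2, 1, len(small_grid)))
        w[..., 10] = 0.7
        vol = self.make_volume(small_grid, w, mask)
        part = dw.SubintervalPartition(
            np.array([small_grid.d_min, small_grid.values[30], small_grid.d_max]),
            small_grid)
        sdw = dw.make_sdw_map(vol, part, 0)
        np.testing.assert_allclose(sdw.values[mask.data], 0.7)

    def test_whole_grid_subinterval_equals_total_weight(self, small_grid, rng):
        mask = dw.RoiMask(np.ones((2, 2, 1), bool))
        w = rng.random((2, 2, 1, len(small_grid)))
        vol = self.make_volume(small_grid, w, mask)
        part = dw.SubintervalPartition(
            np.array([small_grid.d_min, small_grid.d_max]), small_grid)
        sdw = dw.make_sdw_map(vol, part, 0)
        np.testing.assert_allclose(sdw.values, w.sum(axis=-1), rtol=1e-12)

    def test_matches_per_voxel_loop_oracle(self, small_grid, rng):
        mask_data = rng.random((3, 2, 1)) > 0.3
        mask_data[0, 0, 0] = True
        mask = dw.RoiMask(mask_data)
        w = rng.random((3, 2, 1, len(small_grid)))
        vol = self.make_volume(small_grid, w, mask)
        part = dw.SubintervalPartition(
            np.array([small_grid.d_min, small_grid.values[20],
                      small_grid.values[40], small_grid.d_max]), small_grid)
        for k in range(part.n_subintervals):
            sdw = dw.make_sdw_map(vol, part, k)
            for idx in np.argwhere(mask_data):
                expected = dw.sum_weights(w[tuple(idx)], part, k)
                assert sdw.values[tuple(idx)] == pytest.approx(expected, rel=1e-12)

    def test_finite_values_only_inside_mask(self, small_grid, rng):
        mask_data = np.zeros((3, 2, 1), bool)
        mask_data[0] = True
        mask = dw.RoiMask(mask_data)
        w = rng.random((3, 2, 1, len(small_grid)))
        vol = self.make_volume(small_grid, w, mask)
        part = dw.SubintervalPartition(
            np.array([small_grid.d_min, small_grid.d_max]), small_grid)
        sdw = dw.make_sdw_map(vol, part, 0)
        assert np.all(np.isfinite(sdw.values) == mask_data)

    def test_index_out_of_range(self, small_grid):
        mask = dw.RoiMask(np.ones((1, 1, 1), bool))
        vol = self.make_volume(small_grid, np.zeros((1, 1, 1, len(small_grid))), mask)
        part = dw.SubintervalPartition(
            np.array([small_grid.d_min, small_grid.d_max]), small_grid)
        with pytest.raises(IndexError):
            dw.make_sdw_map(vol, part, 1)


class TestRoundTrips:
    def test_map_nifti_round_trip(self, tmp_path, rng):
        values = rng.random((4, 3, 2)).astype(np.float32)
        values[0, 0, 0] = np.nan
        path = tmp_path / "map.nii.gz"
        io.write_map(path, values)
        back, _ = io.read_map(path)
        np.testing.assert_array_equal(back.astype(np.float32), values)

    def test_bvals_round_trip(self, tmp_path, schedule):
        path = tmp_path / "vals.bval"
        io.write_bvals(path, schedule)
        back = io.read_bvals(path)
        assert len(back) == 30
        assert back.values[0] == 0.0
        np.testing.assert_allclose(back.values, schedule.values, rtol=1e-5)

    def test_curve_csv_round_trip(self, tmp_path, schedule, two_compartment_mixture):
        curve = dw.simulate_decay(two_compartment_mixture, schedule, snr=30, seed=5)
        path = tmp_path / "curve.csv"
        io.write_curve_csv(path, curve)
        back = io.read_curve_csv(path)
        np.testing.assert_allclose(back.intensities, curve.intensities, rtol=1e-9)

    def test_curve_csv_non_numeric_row_names_line(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("b_s_per_mm2,intensity\n0,1.0\n100,oops\n")
        with pytest.raises(io.ParseError, match="line 3"):
            io.read_curve_csv(path)

    def test_spectrum_csv_round_trip_with_metadata(self, tmp_path, grid, rng):
        sp = dw.Spectrum(grid, rng.random(len(grid)), mu=0.123, chi2_ratio=1.09)
        path = tmp_path / "spectrum.csv"
        io.write_spectrum_csv(path, sp, sigma2=1e-4, alpha=0.09)
        back = io.read_spectrum_csv(path)
        np.testing.assert_allclose(back.weights, sp.weights, rtol=1e-9)
        assert back.mu == pytest.approx(0.123)
        assert back.chi2_ratio == pytest.approx(1.09)

    def test_partition_csv_round_trip(self, tmp_path, grid):
        part = dw.SubintervalPartition(
            np.array([grid.d_min, grid.values[6], grid.values[100], grid.d_max]),
            grid)
        path = tmp_path / "partition.csv"
        io.write_partition_csv(path, part)
        back = io.read_partition_csv(path, grid)
        np.testing.assert_array_equal(back.boundaries, part.boundaries)

    def test_summary_csv_deterministic(self, tmp_path, grid, rng):
        sa = [dw.Spectrum(grid, rng.random(len(grid))) for _ in range(3)]
        sb = [dw.Spectrum(grid, rng.random(len(grid))) for _ in range(3)]
        summary, _ = dw.summarize_groups(dw.average_spectra(sa), dw.average_spectra(sb))
        p1, p2 = tmp_path / "a.csv", tmp_path / "b.csv"
        io.write_summary_csv(p1, summary)
        io.write_summary_csv(p2, summary)
        assert p1.read_bytes() == p2.read_bytes()


class TestCli:
    def test_simulate_fit_partition_summarize(self, tmp_path):
        runner = CliRunner()
        prefix = tmp_path / "study"
        result = runner.invoke(cli_main, [
            "simulate", "--mode", "study", "--n-a", "3", "--n-b", "3",
            "--seed", "1", "--out-prefix", str(prefix)])
        assert result.exit_code == 0, result.output

        spectra = {}
        for label in ("A", "B"):
            spectra[label] = []
            for i in range(3):
                curve_csv = tmp_path / f"study_group{label}_{i:02d}.csv"
                out = tmp_path / f"spec_{label}_{i}.csv"
                result = runner.invoke(cli_main, [
                    "fit-roi", str(curve_csv), "--out", str(out),
                    "--n-grid", "100"])
                assert result.exit_code == 0, result.output
                spectra[label].append(str(out))

        part_csv = tmp_path / "partition.csv"
        args = ["partition", *spectra["A"]]
        for p in spectra["B"]:
            args += ["--group-b", p]
        args += ["--out", str(part_csv)]
        result = runner.invoke(cli_main, args)
        assert result.exit_code == 0, result.output
        assert part_csv.exists()

        args = ["summarize", *spectra["A"]]
        for p in spectra["B"]:
            args += ["--group-b", p]
        args += ["--out-prefix", str(tmp_path / "out")]
        result = runner.invoke(cli_main, args)
        assert result.exit_code == 0, result.output
        for suffix in ("_sadw.csv", "_sdw.csv", "_tests.csv"):
            assert (tmp_path / f"out{suffix}").exists()

    def test_fit_voxels_and_map(self, tmp_path):
        runner = CliRunner()
        shape = (2, 2, 1)
        region = np.ones(shape, bool)
        schedule = dw.default_schedule()
        spec = dw.PhantomSpec(shape=shape,
                              regions={"t": (region, dw.default_mixture())},
                              schedule=schedule, snr=30, seed=2)
        stack, _, _ = dw.simulate_phantom(spec)
        io.write_map(tmp_path / "stack.nii.gz", stack)
        io.write_map(tmp_path / "mask.nii.gz", region.astype(np.float32))
        io.write_bvals(tmp_path / "vals.bval", schedule)

        result = runner.invoke(cli_main, [
            "fit-voxels", str(tmp_path / "stack.nii.gz"),
            "--bvals", str(tmp_path / "vals.bval"),
            "--mask", str(tmp_path / "mask.nii.gz"),
            "--out", str(tmp_path / "weights.nii.gz"),
            "--n-grid", "100"])
        assert result.exit_code == 0, result.output
        assert "fitted 4 voxels" in result.output

        grid = dw.make_d_grid(100)
        part = dw.SubintervalPartition(
            np.array([grid.d_min, grid.values[50], grid.d_max]), grid)
        io.write_partition_csv(tmp_path / "part.csv", part)
        result = runner.invoke(cli_main, [
            "map", str(tmp_path / "weights.nii.gz"),
            "--mask", str(tmp_path / "mask.nii.gz"),
            "--partition", str(tmp_path / "part.csv"),
            "--out-prefix", str(tmp_path / "maps"), "--n-grid", "100"])
        assert result.exit_code == 0, result.output
        sdw, _ = io.read_map(str(tmp_path / "maps_sdw_01.nii.gz"))
        assert np.all(np.isfinite(sdw[region]))
        assert np.all(sdw[region] >= 0)
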