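"""Displacement tracking: schedule contract, NCC, subsample refinement,
median filtering, and full coarse-to-fine estimation on speckle fixtures."""

import numpy as np
import pytest

from plaquemech.errors import TrackingError
from plaquemech import tracking as tr
from plaquemech.ultrasound import RFFrame, simulate_rf
from plaquemech.phantom import make_scatterers
from plaquemech.ultrasound import displace_scatterers


class TestKernelSchedule:
    def test_printed_kernel_sizes(self):
        s = tr.default_schedule()
        assert s.stages[0].template_um == (3850.0, 715.0)
        assert s.stages[0].search_um == (7700.0, 935.0)
        assert s.stages[0].overlap == (0.50, 0.92)
        assert s.stages[1].template_um == s.stages[2].template_um == (60.0, 715.0)
        assert s.stages[1].search_um == (120.0, 935.0)
        assert s.stages[2].local_align and s.stages[2].subsample

    def test_final_axial_resolution_is_15_um(self):
        ax, lat = tr.default_schedule().final_grid_step_um()
        assert ax == 15.0

    def test_search_smaller_than_template_rejected(self):
        with pytest.raises(ValueError):
            tr.KernelStage((100.0, 100.0), (50.0, 100.0), (0.5, 0.5))


class TestNCCSurface:
    def test_embedded_template_peaks_at_true_lag(self):
        rng = np.random.default_rng(1)
        search = rng.standard_normal((40, 30))
        template = search[10:22, 5:15]
        surf = tr.ncc_surface(template, search)
        assert surf.max() == pytest.approx(1.0, abs=1e-9)
        assert np.unravel_index(np.argmax(surf), surf.shape) == (10, 5)

    def test_negated_template_gives_minus_one(self):
        rng = np.random.default_rng(2)
        search = rng.standard_normal((30, 30))
        surf = tr.ncc_surface(-search[5:15, 5:15], search)
        assert surf.min() == pytest.approx(-1.0, abs=1e-9)

    def test_independent_noise_has_subunit_peak(self):
        rng = np.random.default_rng(3)
        surf = tr.ncc_surface(rng.standard_normal((12, 12)),
                              rng.standard_normal((40, 40)))
        assert np.abs(surf).max() < 1.0

    def test_flat_template_rejected(self):
        with pytest.raises(TrackingError):
            tr.ncc_surface(np.ones((8, 8)), np.random.default_rng(0)
                           .standard_normal((16, 16)))

    def test_matches_direct_zero_mean_ncc(self):
        # FFT-based surface against a brute-force zero-mean NCC oracle
        rng = np.random.default_rng(7)
        search = rng.standard_normal((20, 16))
        template = rng.standard_normal((8, 6))
        surf = tr.ncc_surface(template, search)
        tm = template - template.mean()
        for i in range(surf.shape[0]):
            for j in range(surf.shape[1]):
                w = search[i:i + 8, j:j + 6]
                wm = w - w.mean()
                ref = np.sum(tm * wm) / np.sqrt(np.sum(tm ** 2) * np.sum(wm ** 2))
                assert surf[i, j] == pytest.approx(ref, abs=1e-9)


class TestParabolicSubsample:
    def test_symmetric_peak_is_centered(self):
        assert tr.parabolic_subsample(0.5, 1.0, 0.5) == 0.0

    def test_exact_for_parabola(self):
        y = lambda x: 1 - (x - 0.2) ** 2
        assert tr.parabolic_subsample(y(-1), y(0), y(1)) == pytest.approx(0.2)

    def test_flat_triple_warns_and_returns_zero(self):
        with pytest.warns(RuntimeWarning):
            assert tr.parabolic_subsample(1.0, 1.0, 1.0) == 0.0

    def test_offcenter_peak_rejected(self):
        with pytest.raises(ValueError):
            tr.parabolic_subsample(1.0, 0.5, 0.2)


class TestMedianFilter:
    def _map(self, arr):
        return tr.DisplacementMap(arr, np.zeros_like(arr), 15.0, 55.0, (0.0, 0.0))

    def test_constant_map_unchanged(self):
        out = tr.median_filter_displacements(self._map(np.full((8, 8), 3.0)))
        assert np.all(out.axial_um == 3.0)

    def test_spike_removed(self):
        arr = np.full((9, 9), 2.0)
        arr[4, 4] = 100.0
        out = tr.median_filter_displacements(self._map(arr))
        assert np.all(out.axial_um == 2.0)

    def test_output_within_input_order_statistics(self):
        rng = np.random.default_rng(5)
        arr = rng.standard_normal((12, 12))
        out = tr.median_filter_displacements(self._map(arr))
        assert out.axial_um.min() >= arr.min()
        assert out.axial_um.max() <= arr.max()

    def test_small_map_rejected(self):
        with pytest.raises(TrackingError):
            tr.median_filter_displacements(self._map(np.zeros((3, 3))))


@pytest.fixture(scope="module")
def frame_pair_integer_shift(small_rf):
    post = RFFrame(np.roll(small_rf.samples, 3, axis=0), small_rf.axial_step_um,
                   small_rf.line_pitch_um, small_rf.x0_mm, small_rf.transducer)
    return small_rf, post


class TestEstimateDisplacement:
    def test_identity_gives_zero_map(self, small_rf, tissue_roi):
        # zero up to the sub-sample interpolation floor (hundredths of a µm)
        dm = tr.estimate_displacement(small_rf, small_rf, roi_mm=tissue_roi)
        valid = np.isfinite(dm.axial_um)
        assert valid.any()
        assert np.nanmax(np.abs(dm.axial_um)) < 0.1
        assert np.nanmax(np.abs(dm.lateral_um)) < 0.5

    def test_integer_axial_shift_recovered(self, frame_pair_integer_shift,
                                           tissue_roi):
        pre, post = frame_pair_integer_shift
        dm = tr.estimate_displacement(pre, post, roi_mm=tissue_roi)
        expected = 3 * pre.axial_step_um
        err = np.abs(dm.axial_um - expected)
        assert np.nanmax(err) < 0.1

    def test_grid_steps_match_schedule(self, frame_pair_integer_shift,
                                       tissue_roi):
        pre, post = frame_pair_integer_shift
        dm = tr.estimate_displacement(pre, post, roi_mm=tissue_roi)
        assert dm.grid_axial_step_um == 15.0
        assert dm.grid_lateral_step_um == 55.0

    def test_forward_backward_antisymmetry(self, small_scatterers, small_fov,
                                           tissue_roi):
        disp = np.tile([0.0, 0.012], (len(small_scatterers), 1))
        moved = displace_scatterers(small_scatterers, disp)
        pre = simulate_rf(small_scatterers, None, small_fov,
                          noise_snr_db=30.0, seed=41)
        post = simulate_rf(moved, None, small_fov, noise_snr_db=30.0, seed=42)
        fwd = tr.estimate_displacement(pre, post, roi_mm=tissue_roi)
        bwd = tr.estimate_displacement(post, pre, roi_mm=tissue_roi)
        diff = fwd.axial_um + bwd.axial_um
        assert np.nanmedian(np.abs(diff)) < 1.0

    def test_subsample_shift_recovered(self, small_geometry, small_fov,
                                       tissue_roi):
        # 0.3-sample (1.5 µm) axial shift at 30 dB SNR, a few seeds
        step = 5.0
        errs = []
        for seed in range(3):
            scat = make_scatterers(small_geometry, 3000.0, seed=60 + seed)
            moved = displace_scatterers(
                scat, np.tile([0.0, 0.3 * step * 1e-3], (len(scat), 1)))
            pre = simulate_rf(scat, None, small_fov, noise_snr_db=30.0,
                              seed=80 + seed)
            post = simulate_rf(moved, None, small_fov, noise_snr_db=30.0,
                               seed=90 + seed)
            dm = tr.estimate_displacement(pre, post, roi_mm=tissue_roi)
            errs.append(np.nanmean(dm.axial_um) - 0.3 * step)
        rmse_samples = np.sqrt(np.mean(np.square(errs))) / step
        assert rmse_samples < 0.05

    def test_mismatched_frames_rejected(self, small_rf):
        other = RFFrame(small_rf.samples[:-10], small_rf.axial_step_um,
                        small_rf.line_pitch_um, small_rf.x0_mm,
                        small_rf.transducer)
        with pytest.raises(TrackingError):
            tr.estimate_displacement(small_rf, other)

    def test_all_zero_frames_rejected(self, small_rf):
        zero = RFFrame(np.zeros_like(small_rf.samples), small_rf.axial_step_um,
                       small_rf.line_pitch_um, small_rf.x0_mm,
                       small_rf.transducer)
        with pytest.raises(TrackingError):
            tr.estimate_displacement(zero, zero)


class TestAccumulate:
    def test_two_half_shifts_sum(self, small_scatterers, small_fov, tissue_roi):
        shift = 0.010  # mm per increment
        f0 = simulate_rf(small_scatterers, None, small_fov)
        s1 = displace_scatterers(small_scatterers,
                                 np.tile([0.0, shift], (len(small_scatterers), 1)))
        f1 = simulate_rf(s1, None, small_fov)
        s2 = displace_scatterers(s1,
                                 np.tile([0.0, shift], (len(s1), 1)))
        f2 = simulate_rf(s2, None, small_fov)
        maps = [tr.estimate_displacement(f0, f1, roi_mm=tissue_roi),
                tr.estimate_displacement(f1, f2, roi_mm=tissue_roi)]
        total = tr.accumulate_displacement(maps)
        assert np.nanmedian(np.abs(total.axial_um - 20.0)) < 0.5


def test_displacement_map_round_trip(tmp_path):
    rng = np.random.default_rng(9)
    dm = tr.DisplacementMap(rng.standard_normal((6, 5)),
                            rng.standard_normal((6, 5)), 15.0, 55.0, (-1.0, 2.0))
    tr.write_displacement_map(dm, tmp_path / "map")
    back = tr.read_displacement_map(tmp_path / "map")
    assert np.allclose(back.axial_um, dm.axial_um)
    assert back.origin_mm == dm.origin_mm
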