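"""Comet quantification: registration, peak position, ratios, erfc fits,
split-comet sums, sweep scoring, coverage."""

import numpy as np
import pytest
from scipy.special import erfc

from ebtip.analysis import (
    AnalysisError,
    LineScanProfile,
    coverage_fraction,
    detect_comets,
    growth_stats,
    line_scan,
    peak_eb1_position,
    profile_error,
    register_and_average,
    split_comet_fold_change,
    tip_lattice_ratio,
    tip_specificity,
    tip_standard_deviation,
)
from ebtip.imaging import Image

DX = 64.0


def synth_profile(end_nm=3000.0, peak_behind_nm=150.0, sigma_nm=191.0,
                  comet_amp=30.0, lattice_level=2.0, red_amp=200.0,
                  x_max=6000.0, shift_px=0):
    """Analytic two-channel profile: erfc red edge + Gaussian green comet on a
    lattice plateau that ends at the microtubule end."""
    x = np.arange(0.0, x_max, DX) + shift_px * DX
    red = red_amp * 0.5 * erfc((x - end_nm) / (sigma_nm * np.sqrt(2)))
    comet = comet_amp * np.exp(-0.5 * ((x - (end_nm - peak_behind_nm)) / 120.0) ** 2)
    green = comet + lattice_level * 0.5 * erfc((x - end_nm) / (sigma_nm * np.sqrt(2)))
    return LineScanProfile(positions=np.arange(0.0, x_max, DX), red=red, green=green)


class TestRegisterAndAverage:
    def test_identical_profiles_reproduced(self):
        profs = [synth_profile() for _ in range(5)]
        avg = register_and_average(profs)
        assert avg.n_averaged == 5
        assert not avg.flagged
        # pointwise equal to any single registered input over the overlap
        assert np.allclose(np.sort(avg.green)[-10:], np.sort(profs[0].green)[-10:])

    def test_shifted_copies_recovered_exactly(self):
        profs = [synth_profile(shift_px=s) for s in (0, 3, -2, 5, 1)]
        avg = register_and_average(profs)
        single = register_and_average([synth_profile()] * 5)
        # registration undoes the integer-pixel shifts exactly (noise off):
        # compare at matched relative positions over the common support
        common = np.intersect1d(
            np.round(avg.positions, 6), np.round(single.positions, 6)
        )
        assert common.size > 30
        a = np.interp(common, avg.positions, avg.green)
        b = np.interp(common, single.positions, single.green)
        assert np.allclose(a, b)

    def test_few_profiles_flagged(self):
        with pytest.warns(UserWarning):
            avg = register_and_average([synth_profile(), synth_profile()])
        assert avg.flagged

    def test_zero_position_at_red_half_max(self):
        avg = register_and_average([synth_profile() for _ in range(5)])
        k = int(np.argmin(np.abs(avg.positions)))
        half = 0.5 * (avg.red.max() + avg.red.min())
        assert abs(avg.red[k] - half) / half < 0.1


class TestPeakPosition:
    def test_synthetic_comet_position(self):
        avg = register_and_average([synth_profile(peak_behind_nm=150.0)] * 5)
        assert peak_eb1_position(avg) == pytest.approx(150.0, abs=15.0)

    def test_sign_convention_positive_toward_minus_end(self):
        avg = register_and_average([synth_profile(peak_behind_nm=300.0)] * 5)
        assert peak_eb1_position(avg) > 0

    def test_flat_green_rejected(self):
        avg = register_and_average([synth_profile() for _ in range(5)])
        avg.green[:] = 1.0
        with pytest.raises(AnalysisError):
            peak_eb1_position(avg)

    def test_scale_invariance(self):
        avg1 = register_and_average([synth_profile()] * 5)
        scaled = [synth_profile() for _ in range(5)]
        for p in scaled:
            p.green *= 37.0
            p.red *= 37.0
        avg2 = register_and_average(scaled)
        assert peak_eb1_position(avg1) == pytest.approx(peak_eb1_position(avg2))
        assert tip_lattice_ratio(avg1) == pytest.approx(tip_lattice_ratio(avg2))


class TestTipLatticeRatio:
    def test_uniform_green_is_one(self):
        avg = register_and_average([synth_profile()] * 5)
        avg.green[:] = 5.0
        assert tip_lattice_ratio(avg) == pytest.approx(1.0)

    def test_synthetic_threefold_comet(self):
        profs = [synth_profile(comet_amp=6.0, lattice_level=2.0) for _ in range(5)]
        avg = register_and_average(profs)
        # comet peak ~ lattice + comet amplitude = 8 over lattice 2
        assert tip_lattice_ratio(avg) == pytest.approx(4.0, rel=0.1)

    def test_short_profile_rejected(self):
        profs = [synth_profile(end_nm=500.0, x_max=1400.0) for _ in range(5)]
        avg = register_and_average(profs)
        with pytest.raises(AnalysisError):
            tip_lattice_ratio(avg)


class TestTipSpecificity:
    def image_with_boxes(self, tip=300.0, lattice=150.0, background=100.0):
        green = np.zeros((30, 80))
        green[8:12, 38:42] = tip / 16.0
        green[8:12, 18:22] = lattice / 16.0
        green[18:22, 38:42] = background / 16.0
        red = np.zeros_like(green)
        return Image(red=red, green=green, pixel_size_nm=64.0, origin_nm=0.0)

    def test_direct_arithmetic(self):
        img = self.image_with_boxes()
        m = tip_specificity(img, tip_point=(10, 40), lattice_point=(10, 20),
                            background_point=(20, 40))
        assert m.s == pytest.approx((300 - 100) / (150 - 100))

    def test_no_tip_tracking_is_one(self):
        img = self.image_with_boxes(tip=150.0)
        m = tip_specificity(img, tip_point=(10, 40), lattice_point=(10, 20),
                            background_point=(20, 40))
        assert m.s == pytest.approx(1.0)

    def test_affine_intensity_invariance(self):
        img = self.image_with_boxes()
        scaled = Image(red=img.red, green=3.5 * img.green + 2.0,
                       pixel_size_nm=64.0, origin_nm=0.0)
        args = dict(tip_point=(10, 40), lattice_point=(10, 20),
                    background_point=(20, 40))
        assert tip_specificity(scaled, **args).s == pytest.approx(
            tip_specificity(img, **args).s
        )

    def test_undefined_when_lattice_equals_background(self):
        img = self.image_with_boxes(lattice=100.0)
        with pytest.raises(AnalysisError):
            tip_specificity(img, tip_point=(10, 40), lattice_point=(10, 20),
                            background_point=(20, 40))

    def test_box_outside_image_rejected(self):
        img = self.image_with_boxes()
        with pytest.raises(AnalysisError):
            tip_specificity(img, tip_point=(1, 1), lattice_point=(10, 20),
                            background_point=(20, 40))


class TestTipStandardDeviation:
    @pytest.mark.parametrize("sigma", [80.0, 150.0, 250.0, 400.0])
    def test_parameter_recovery(self, sigma):
        x = np.arange(0.0, 6000.0, DX)
        red = 180.0 * 0.5 * erfc((x - 3000.0) / (sigma * np.sqrt(2))) + 5.0
        prof = LineScanProfile(positions=x, red=red, green=np.zeros_like(x))
        fit = tip_standard_deviation(prof, fit_halfwidth_nm=1800.0)
        assert fit.sigma_tip == pytest.approx(sigma, rel=0.05)
        assert fit.mu == pytest.approx(3000.0, abs=DX)

    def test_blunt_rendered_tip_recovers_psf(self, rng):
        from ebtip.imaging import RenderSettings, render_frame

        s = RenderSettings(noise_amplitude=0.0)
        img = render_frame(
            {"lengths": np.full(13, 200), "eb1_j": np.zeros(0), "time": 0.0}, s, rng
        )
        fit = tip_standard_deviation(img)
        assert fit.sigma_tip == pytest.approx(s.psf_sigma_nm, rel=0.15)

    def test_registered_profile_accepted(self):
        avg = register_and_average([synth_profile(sigma_nm=191.0)] * 5)
        fit = tip_standard_deviation(avg)
        assert fit.sigma_tip == pytest.approx(191.0, rel=0.08)

    def test_no_end_rejected(self):
        x = np.arange(0.0, 2000.0, DX)
        prof = LineScanProfile(positions=x, red=np.zeros_like(x),
                               green=np.zeros_like(x))
        with pytest.raises(AnalysisError):
            tip_standard_deviation(prof)


class TestSplitComet:
    def frame(self, blobs, height=20, width=120, level=0.0):
        green = np.full((height, width), level)
        x = np.arange(width)
        for center, amp in blobs:
            green += amp * np.exp(-0.5 * ((x - center) / 3.0) ** 2)[None, :] / height
        red = np.zeros_like(green)
        red[:, :100] = 1.0
        return Image(red=red, green=green, pixel_size_nm=64.0, origin_nm=0.0)

    def test_identical_frames_fold_one(self):
        single = self.frame([(60, 50.0)])
        bg = self.frame([], level=0.01)
        pair = split_comet_fold_change(single, single, bg, region=(30, 90))
        assert pair.fold_change == pytest.approx(1.0)

    def test_constructed_fold(self):
        single = self.frame([(60, 50.0)])
        split = self.frame([(50, 35.0), (70, 35.0)])
        bg = self.frame([], level=0.0)
        pair = split_comet_fold_change(single, split, bg, region=(20, 100))
        assert pair.fold_change == pytest.approx(70.0 / 50.0, rel=0.02)

    def test_clipped_region_rejected(self):
        single = self.frame([(60, 50.0)])
        bg = self.frame([])
        with pytest.raises(AnalysisError):
            split_comet_fold_change(single, single, bg, region=(100, 130))

    def test_detect_comets_counts_blobs(self):
        prof = line_scan(self.frame([(30, 40.0), (70, 40.0)]))
        assert len(detect_comets(prof, min_separation_nm=640.0)) == 2
        prof1 = line_scan(self.frame([(60, 40.0)]))
        assert len(detect_comets(prof1, min_separation_nm=640.0)) == 1


class TestGrowthStats:
    def make_traj(self, rate_nm_s=20.0, t_end=100.0, boost_at=None):
        from ebtip.engine import SimulationConfig, Trajectory

        times = np.arange(0.0, t_end, 1.0)
        dimers = 25 + times * rate_nm_s / 8.0
        lengths = np.tile(dimers[:, None], (1, 13)).astype(int)
        n = len(times)
        return Trajectory(
            config=SimulationConfig(),
            times=times,
            lengths=lengths,
            bound_counts=np.zeros((n, 4), dtype=int),
            tallies=np.zeros((n, 9), dtype=int),
            bound_i=np.zeros(0, dtype=int),
            bound_j=np.zeros(0, dtype=int),
            bound_origin=np.zeros(0, dtype=int),
            bound_offsets=np.zeros(n + 1, dtype=int),
            gtp_p=np.zeros(0, dtype=int),
            gtp_j=np.zeros(0, dtype=int),
            gtp_offsets=np.zeros(n + 1, dtype=int),
            boost_times=np.array([boost_at] if boost_at else []),
            boost_flags=np.array([1] if boost_at else []),
            status="max_time",
            end_time=t_end,
            final_state={},
        )

    def test_linear_growth_rate(self):
        out = growth_stats(self.make_traj(rate_nm_s=20.0))
        assert out["growth_rate_nm_s"] == pytest.approx(20.0, rel=0.02)
        assert out["censored"]

    def test_catastrophe_time_matches_boost_trip(self):
        out = growth_stats(self.make_traj(rate_nm_s=20.0, boost_at=80.0))
        assert out["time_to_catastrophe_s"] == pytest.approx(80.0)
        assert not out["censored"]

    def test_comet_length_from_profile(self):
        avg = register_and_average([synth_profile(comet_amp=30.0)] * 5)
        out = growth_stats(self.make_traj(), profile=avg)
        # 1/e decay of a 120 nm Gaussian sits ~170 nm past the peak
        assert 100.0 < out["comet_length_nm"] < 300.0


class TestProfileError:
    def test_identical_zero(self):
        p = synth_profile()
        assert profile_error(p, p) == 0.0

    def test_constant_offset(self):
        p = synth_profile()
        q = synth_profile()
        q.green = p.green + 2.5
        assert profile_error(p, q) == pytest.approx(2.5 * len(p.green))

    def test_disjoint_supports_rejected(self):
        p = synth_profile()
        q = synth_profile()
        q.positions = q.positions + 1e6
        with pytest.raises(AnalysisError):
            profile_error(p, q)


class TestCoverage:
    def test_known_fraction(self):
        red = np.zeros((40, 100))
        red[15:25, 10:90] = 10.0
        green = np.zeros_like(red)
        green[15:25, 10:34] = 5.0  # 24 of 80 columns -> 30%
        assert coverage_fraction(red, green, green_threshold=1.0) == pytest.approx(0.30)

    def test_full_and_empty(self):
        red = np.zeros((20, 50))
        red[5:15, 5:45] = 10.0
        green = np.full_like(red, 5.0)
        assert coverage_fraction(red, green, 1.0) == 1.0
        assert coverage_fraction(red, np.zeros_like(red), 1.0) == 0.0

    def test_empty_mask_rejected(self):
        red = np.zeros((20, 50))
        with pytest.raises(AnalysisError):
            coverage_fraction(red, red, 1.0)
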