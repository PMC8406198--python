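"""Massey-method analysis: peaks, fraction estimation, Nernst fit, replicates."""

import numpy as np
import pytest

from cycscreen import synthetic
from cycscreen.redox import (
    InsufficientDataError,
    NernstConfig,
    NoPeakError,
    RedoxFit,
    TitrationTrace,
    UnresolvedEndpointError,
    aggregate,
    analyze_trace,
    find_peak,
    fit_midpoint,
    fractions_from_trace,
    nernst_points,
)


class TestFindPeak:
    def test_oxidized_soret_at_410(self):
        wl, ab = synthetic.gen_spectrum("oxidized")
        assert find_peak(wl, ab, (380, 450)) == 410.0

    def test_reduced_soret_at_427_with_alpha_beta_bands(self):
        wl, ab = synthetic.gen_spectrum("reduced")
        assert find_peak(wl, ab, (380, 450)) == 427.0
        assert find_peak(wl, ab, (520, 545)) == 530.0
        assert find_peak(wl, ab, (545, 580)) == 560.0

    def test_oxidized_spectrum_has_no_alpha_beta_peaks(self):
        wl, ab = synthetic.gen_spectrum("oxidized")
        with pytest.raises(NoPeakError):
            find_peak(wl, ab, (500, 600))

    def test_flat_spectrum_errors(self):
        wl = np.arange(350.0, 800.0)
        with pytest.raises(NoPeakError):
            find_peak(wl, np.zeros_like(wl), (380, 450))

    def test_tie_goes_to_lowest_wavelength(self):
        wl = np.arange(400.0, 421.0)
        ab = np.zeros_like(wl)
        ab[5:8] = 1.0  # plateau: equal smoothed maxima
        ab[13:16] = 1.0
        assert find_peak(wl, ab, (400, 420)) == wl[5] + 1  # 3-pt smoothing shifts edges

    def test_zero_height_band_gives_flat_spectrum(self):
        cfg = synthetic.TitrationConfig(bands={"oxidized": ((410.0, 0.0, 16.0),)})
        wl, ab = synthetic.gen_spectrum("oxidized", cfg)
        with pytest.raises(NoPeakError):
            find_peak(wl, ab, (380, 450))


def _step_trace(f_heme_mid, f_dye_mid):
    """Trace with exact plateaus and specified mid-titration fractions."""
    n_mid = len(f_heme_mid)
    times = np.arange(0, (10 + n_mid) * 15.0, 15.0)
    f_h = np.concatenate([np.zeros(5), f_heme_mid, np.ones(5)])
    f_d = np.concatenate([np.zeros(5), f_dye_mid, np.ones(5)])
    a429 = 0.2 + 0.5 * f_h
    a610 = 0.9 - 0.8 * f_d
    return TitrationTrace(times, np.array([429.0, 610.0]), np.column_stack([a429, a610]))


class TestFractions:
    def test_fully_oxidized_start_is_excluded(self, noiseless_titration):
        trace, _ = noiseless_titration
        ratios = fractions_from_trace(trace)
        assert not ratios.included[0]
        assert np.isnan(ratios.r_heme[0]) or ratios.r_heme[0] < 0.065

    def test_midpoint_absorbance_gives_unit_ratio(self):
        trace = _step_trace(np.array([0.5]), np.array([0.5]))
        ratios = fractions_from_trace(trace)
        assert ratios.r_heme[5] == pytest.approx(1.0)
        assert ratios.r_dye[5] == pytest.approx(1.0)

    def test_noiseless_ratios_match_closed_form(self, noiseless_titration):
        trace, truth = noiseless_titration
        cfg = truth["config"]
        ratios = fractions_from_trace(trace)
        mask = ratios.included.astype(bool)
        expected = np.exp((cfg.E_m_heme - truth["E"][mask]) / 25.0)
        assert np.allclose(ratios.r_heme[mask], expected, rtol=1e-6)

    def test_exclusion_window_boundaries(self):
        # ratios of exactly 10 and 0.065 stay in (exclusion is strict:
        # "> 10" / "< 0.065"); just outside goes out; NaN is always out
        from cycscreen.redox import inclusion_mask

        ratios = np.array([10.0, 10.5, 0.065, 0.064, 1.0, np.nan])
        assert list(inclusion_mask(ratios)) == [True, False, True, False, True, False]

    def test_window_asymmetry_is_preserved(self):
        # the default window is not symmetric on the log scale: 1/10 = 0.1
        # is included while its mirror partner of 0.065's reciprocal is not
        from cycscreen.redox import inclusion_mask

        cfg = NernstConfig()
        assert cfg.ratio_lo != pytest.approx(1.0 / cfg.ratio_hi)
        assert inclusion_mask(np.array([0.1]), cfg)[0]
        assert not inclusion_mask(np.array([1.0 / 0.065]), cfg)[0]

    def test_mask_consistent_with_computed_ratios(self):
        target = np.array([10.0, 0.5, 0.01])
        f = target / (1.0 + target)
        ratios = fractions_from_trace(_step_trace(f, np.full(3, 0.5)))
        from cycscreen.redox import inclusion_mask

        mid = slice(5, 8)
        expected = inclusion_mask(ratios.r_heme[mid]) & inclusion_mask(ratios.r_dye[mid])
        assert list(ratios.included[mid]) == list(expected)

    def test_flat_heme_channel_is_an_unresolved_endpoint(self):
        times = np.arange(0, 20 * 15.0, 15.0)
        a429 = np.full(20, 0.5)
        a610 = np.concatenate([np.full(10, 0.9), np.full(10, 0.1)])
        trace = TitrationTrace(times, np.array([429.0, 610.0]), np.column_stack([a429, a610]))
        with pytest.raises(UnresolvedEndpointError):
            fractions_from_trace(trace)

    def test_rising_dye_signal_is_rejected(self):
        trace = _step_trace(np.array([0.5]), np.array([0.5]))
        flipped = TitrationTrace(
            trace.times, trace.wavelengths, trace.absorbance[:, [0, 0]]
        )  # "dye" channel now rises like the heme channel
        with pytest.raises(UnresolvedEndpointError):
            fractions_from_trace(flipped)


class TestNernstPoints:
    def test_unit_ratio_maps_to_zero_millivolts(self):
        mid = np.array([0.5, 0.5])
        ratios = fractions_from_trace(_step_trace(mid, mid))
        pts = nernst_points(ratios)
        assert pts.shape[0] == 2
        assert pts[0] == pytest.approx([0.0, 0.0])

    def test_fewer_than_two_included_points_error(self):
        ratios = fractions_from_trace(_step_trace(np.array([0.5, 0.5]), np.array([0.5, 0.5])))
        ratios.included[:] = False
        with pytest.raises(InsufficientDataError):
            nernst_points(ratios)


class TestFitMidpoint:
    def test_two_point_line_recovers_208(self):
        pts = np.array([[0.0, -9.0], [10.0, 1.0]])  # y = x - 9
        fit = fit_midpoint(pts, NernstConfig(E_dye=217.0))
        assert fit.intercept == pytest.approx(-9.0)
        assert fit.E_m == pytest.approx(208.0)
        assert fit.slope == pytest.approx(1.0)

    def test_noiseless_roundtrip_recovers_configured_midpoint(self):
        for em in (160.0, 208.0, 240.0):
            trace, _ = synthetic.gen_titration(
                synthetic.TitrationConfig(E_m_heme=em, noise_sd=0.0)
            )
            fit = analyze_trace(trace)
            assert fit.E_m == pytest.approx(em, abs=0.5)
            assert fit.slope == pytest.approx(1.0, abs=0.01)

    def test_identical_x_is_singular(self):
        with pytest.raises(ValueError):
            fit_midpoint(np.array([[1.0, 2.0], [1.0, 3.0]]))

    def test_intercept_sampling_noise_within_two_millivolts(self):
        # OLS on 50 points with 2 mV Gaussian noise on y: the intercept
        # standard error is ~0.3 mV, so a 2 mV error is rare
        truth = 208.0
        cfg = NernstConfig()
        hits = 0
        for seed in range(200):
            rng = np.random.default_rng(seed)
            x = rng.uniform(-25.0, 25.0, size=50)
            y = x + (truth - cfg.E_dye) + rng.normal(0.0, 2.0, size=50)
            fit = fit_midpoint(np.column_stack([x, y]), cfg)
            hits += abs(fit.E_m - truth) <= 2.0
        assert hits >= 190  # >= 95% of runs

    def test_midpoint_invariant_to_absorbance_gain_and_offset(self):
        trace, _ = synthetic.gen_titration(synthetic.TitrationConfig(noise_sd=0.0))
        rescaled = TitrationTrace(
            trace.times,
            trace.wavelengths,
            np.column_stack(
                [3.0 * trace.absorbance[:, 0] + 0.7, 0.5 * trace.absorbance[:, 1] - 0.1]
            ),
        )
        assert analyze_trace(rescaled).E_m == pytest.approx(analyze_trace(trace).E_m, abs=1e-9)


class TestAggregate:
    def test_mean_of_four_replicates(self):
        fits = [
            RedoxFit(points=np.zeros((2, 2)), slope=1.0, intercept=0.0, E_m=em, n_points_used=2)
            for em in (200.0, 210.0, 206.0, 216.0)
        ]
        s = aggregate(fits)
        assert s.mean == pytest.approx(208.0)
        assert s.sd == pytest.approx(np.std([200, 210, 206, 216], ddof=1))

    def test_identical_replicates_have_zero_sd(self):
        fits = [
            RedoxFit(points=np.zeros((2, 2)), slope=1.0, intercept=0.0, E_m=205.0, n_points_used=2)
        ] * 3
        assert aggregate(fits).sd == 0.0

    def test_single_replicate_rejected(self):
        fit = RedoxFit(points=np.zeros((2, 2)), slope=1.0, intercept=0.0, E_m=205.0, n_points_used=2)
        with pytest.raises(ValueError):
            aggregate([fit])


class TestTraceIO:
    def test_wide_csv_roundtrip(self, tmp_path, noiseless_titration):
        trace, _ = noiseless_titration
        p = tmp_path / "trace.csv"
        trace.to_csv(p)
        back = TitrationTrace.from_csv(p)
        assert np.allclose(back.times, trace.times)
        assert np.allclose(back.absorbance, trace.absorbance)

    def test_long_format_csv(self, tmp_path):
        import pandas as pd

        rows = []
        for t in (0.0, 15.0):
            for wl, ab in ((429.0, 0.3), (610.0, 0.8)):
                rows.append({"time_s": t, "wavelength_nm": wl, "absorbance": ab + t / 100})
        p = tmp_path / "long.csv"
        pd.DataFrame(rows).to_csv(p, index=False)
        trace = TitrationTrace.from_csv(p)
        assert trace.absorbance.shape == (2, 2)
        assert trace.at_wavelength(429.0)[0] == 0.3
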