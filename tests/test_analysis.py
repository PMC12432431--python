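import numpy as np
import pytest

from thermoidp.analysis import (
    ABSORBANCE_THRESHOLD,
    AnalysisError,
    BinodalDataset,
    DensityProfile,
    FloryConstants,
    NuSeries,
    block_stats,
    classify_transition,
    cloud_fit,
    cloud_point_from_absorbance,
    coexistence_densities,
    fit_binodal,
    model_rmsd,
    nu_from_rg,
    rg_from_nu,
    theta_temperature,
)
from thermoidp.synthetic import synthetic_binodal, synthetic_profiles


class TestFlory:
    def test_direct_substitution_at_theta(self):
        expected = 0.55 * 10.0 * np.sqrt(1.1615 * 2.1615 / (2 * 2.1615 * 3.1615))
        assert rg_from_nu(0.5, 100) == pytest.approx(expected, rel=1e-12)

    def test_monotone_in_nu(self):
        nus = np.linspace(0.1, 0.9, 50)
        s = np.array([rg_from_nu(v, 150) for v in nus])
        assert np.all(np.diff(s) > 0)

    def test_power_law_scaling(self):
        for nu in (0.3, 0.5, 0.7):
            ratio = rg_from_nu(nu, 200) / rg_from_nu(nu, 100)
            assert ratio == pytest.approx(2**nu, rel=1e-12)

    def test_round_trip(self):
        for nu in (0.3, 0.5, 0.7):
            s = rg_from_nu(nu, 150)
            assert nu_from_rg(s, 150) == pytest.approx(nu, abs=1e-8)

    def test_out_of_range_rg_reports_bounds(self):
        tiny = 0.5 * rg_from_nu(0.05, 150)
        with pytest.raises(AnalysisError, match="attainable range"):
            nu_from_rg(tiny, 150)

    def test_larger_rg_gives_larger_nu(self):
        s = [rg_from_nu(v, 120) for v in (0.3, 0.5, 0.7)]
        nus = [nu_from_rg(v, 120) for v in s]
        assert nus == sorted(nus)


class TestThetaTemperature:
    def test_linear_interpolation(self):
        series = NuSeries([310.0, 320.0], [0.55, 0.45])
        assert theta_temperature(series) == pytest.approx(315.0)

    def test_no_crossing_returns_none(self):
        series = NuSeries([300.0, 320.0, 340.0], [0.6, 0.58, 0.55])
        assert theta_temperature(series) is None

    def test_multiple_crossings_flagged_lowest_returned(self):
        series = NuSeries([300.0, 310.0, 320.0, 330.0], [0.55, 0.45, 0.55, 0.45])
        with pytest.warns(UserWarning, match="crosses"):
            assert theta_temperature(series) == pytest.approx(305.0)

    def test_classification_by_trend_sign(self):
        lcst = NuSeries([300.0, 320.0, 340.0], [0.6, 0.5, 0.4])
        ucst = NuSeries([300.0, 320.0, 340.0], [0.4, 0.5, 0.6])
        assert classify_transition(lcst) == "LCST"
        assert classify_transition(ucst) == "UCST"


class TestCloudFit:
    def test_recovers_constructed_onset(self):
        profiles = synthetic_profiles(
            np.arange(275.0, 371.0, 5.0), spike_onset_T=320.0, seed=11
        )
        assert cloud_fit(profiles) == pytest.approx(320.0)

    def test_all_flat_returns_none(self):
        profiles = synthetic_profiles(
            np.arange(275.0, 316.0, 5.0), spike_onset_T=1000.0, seed=11
        )
        assert cloud_fit(profiles) is None

    def test_no_spike_factor_one(self):
        profiles = synthetic_profiles(
            np.arange(275.0, 371.0, 5.0), spike_onset_T=300.0, spike_factor=1.0, seed=1
        )
        assert cloud_fit(profiles) is None

    def test_spike_at_lowest_temperature_warns(self):
        profiles = synthetic_profiles(
            np.arange(275.0, 301.0, 5.0), spike_onset_T=270.0, seed=2
        )
        with pytest.warns(UserWarning, match="lowest"):
            assert cloud_fit(profiles) == pytest.approx(275.0)

    def test_inconsistent_binning_rejected(self):
        p1 = synthetic_profiles([280.0], 1000.0, seed=1, n_bins=100)[0]
        p2 = synthetic_profiles([285.0], 1000.0, seed=1, n_bins=50)[0]
        with pytest.raises(AnalysisError, match="binning"):
            cloud_fit([p1, p2])


class TestCoexistenceDensities:
    def _profile(self, rho):
        nb = len(rho)
        return DensityProfile(300.0, (np.arange(nb) + 0.5) * 1.0, np.asarray(rho))

    def test_step_profile_exact(self):
        rho = np.full(100, 0.05)
        rho[40:60] = 0.60
        dil, den = coexistence_densities(self._profile(rho))
        assert dil == pytest.approx(0.05, abs=1e-6)
        assert den == pytest.approx(0.60, abs=1e-6)

    def test_uniform_profile_rejected(self):
        with pytest.raises(AnalysisError, match="single-phase"):
            coexistence_densities(self._profile(np.full(100, 0.3)))

    def test_tanh_interfaces_within_one_percent(self):
        z = np.arange(100) + 0.5
        w = 2.0
        rho = 0.05 + 0.55 * 0.5 * (np.tanh((z - 35) / w) - np.tanh((z - 65) / w))
        dil, den = coexistence_densities(self._profile(rho))
        assert den == pytest.approx(0.60, rel=0.01)
        assert dil == pytest.approx(0.05, rel=0.01)

    def test_dense_slab_split_across_boundary(self):
        rho = np.full(100, 0.05)
        rho[:10] = 0.60
        rho[90:] = 0.60  # periodic condensate across z boundary
        dil, den = coexistence_densities(self._profile(rho))
        assert den == pytest.approx(0.60, abs=1e-6)
        assert dil == pytest.approx(0.05, abs=1e-6)


class TestBinodalFit:
    def test_noiseless_recovery(self):
        data = synthetic_binodal(tc=300.0, rho_c=0.3, noise_sd=0.0)
        tc, rho_c, diag = fit_binodal(data)
        assert tc == pytest.approx(300.0, abs=0.1)
        assert rho_c == pytest.approx(0.3, abs=0.001)
        assert diag["rms_residual"] < 1e-8

    def test_ucst_branch(self):
        data = synthetic_binodal(tc=340.0, rho_c=0.25, mode="UCST", noise_sd=0.0)
        tc, rho_c, _ = fit_binodal(data)
        assert tc == pytest.approx(340.0, abs=0.1)
        assert np.all(data.temperatures < tc)

    def test_too_few_points_rejected(self):
        data = synthetic_binodal(t_offsets=(5.0, 10.0), noise_sd=0.0)
        with pytest.raises(AnalysisError, match="3 coexistence"):
            fit_binodal(data)

    def test_invariants_enforced(self):
        with pytest.raises(AnalysisError):
            BinodalDataset(
                temperatures=np.array([300.0, 310.0, 320.0]),
                rho_dilute=np.array([0.5, 0.5, 0.5]),
                rho_dense=np.array([0.4, 0.6, 0.6]),
            )


class TestBlockStats:
    def test_three_block_example(self):
        mean, se = block_stats([1, 1, 1, 2, 2, 2, 3, 3, 3])
        assert mean == pytest.approx(2.0)
        assert se == pytest.approx(1.0 / np.sqrt(3.0))

    def test_constant_series(self):
        mean, se = block_stats(np.full(30, 7.0))
        assert mean == 7.0
        assert se == 0.0

    def test_within_block_permutation_invariance(self):
        x = np.arange(12, dtype=float)
        m1, s1 = block_stats(x)
        y = x.copy()
        y[0:4] = y[0:4][::-1]  # permute inside block 1
        m2, s2 = block_stats(y)
        assert (m1, s1) == (m2, s2)

    def test_remainder_joins_last_block(self):
        x = np.array([1.0, 1.0, 2.0, 2.0, 3.0, 3.0, 3.0])
        mean, _ = block_stats(x, n_blocks=3)
        assert mean == pytest.approx((1.0 + 2.0 + 3.0) / 3.0)

    def test_short_series_rejected(self):
        with pytest.raises(AnalysisError):
            block_stats([1.0, 2.0], n_blocks=3)


class TestAbsorbanceCloudPoint:
    def test_threshold_is_half_transmittance(self):
        assert ABSORBANCE_THRESHOLD == pytest.approx(-np.log10(0.5), rel=1e-12)
        assert ABSORBANCE_THRESHOLD == pytest.approx(0.301, abs=5e-4)

    def test_linear_interpolation(self):
        cp = cloud_point_from_absorbance([(300.0, 0.0), (310.0, 0.602)])
        expected = 300.0 + 10.0 * ABSORBANCE_THRESHOLD / 0.602
        assert cp == pytest.approx(expected, abs=1e-9)

    def test_starts_above_threshold_warns(self):
        with pytest.warns(UserWarning, match="boundary"):
            cp = cloud_point_from_absorbance([(300.0, 0.5), (310.0, 0.9)])
        assert cp == 300.0

    def test_monotone_decreasing_never_crosses(self):
        with pytest.raises(AnalysisError, match="never crosses"):
            cloud_point_from_absorbance([(300.0, 0.2), (310.0, 0.1)])


class TestModelRmsd:
    def test_identical_lists(self):
        assert model_rmsd([300.0, 310.0], [300.0, 310.0]) == 0.0

    def test_single_offset(self):
        assert model_rmsd([300.0], [310.0]) == pytest.approx(10.0)

    def test_pairwise_reordering_invariance(self):
        a, b = [300.0, 320.0, 340.0], [302.0, 318.0, 343.0]
        assert model_rmsd(a, b) == pytest.approx(model_rmsd(a[::-1], b[::-1]))

    def test_length_mismatch(self):
        with pytest.raises(AnalysisError):
            model_rmsd([300.0], [300.0, 310.0])
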