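"""Generator correctness: exact fGn covariance, fBm duality, confounds,
4D fixtures and planted cohort structure."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.linalg import toeplitz

from fractalbold.synthetic_data import (CohortSpec, ConfoundSpec, FgnSpec,
                                        add_confounds, fgn_autocovariance,
                                        generate_cohort, generate_fbm,
                                        generate_fgn,
                                        generate_volume_with_roi)
from fractalbold.roi_extraction import extract_mean_timeseries, sphere_mask
from fractalbold.timeseries import TimeSeries


class TestFgnExactness:
    def test_sample_covariance_matches_analytic(self):
        """Full sample covariance at n=16 agrees entrywise with γ(k)."""
        n, reps, h = 16, 6000, 0.8
        draws = np.stack([generate_fgn(FgnSpec(h, n, seed=r)).values
                          for r in range(reps)])
        sample_cov = draws.T @ draws / reps
        gamma = toeplitz(fgn_autocovariance(h, np.arange(n)))
        # SE of a covariance-of-Gaussians estimate: sqrt((γii γjj + γij²)/R)
        se = np.sqrt((np.outer(np.diag(gamma), np.diag(gamma)) + gamma**2)
                     / reps)
        assert np.all(np.abs(sample_cov - gamma) < 4 * se)

    def test_cholesky_route_matches_analytic(self):
        n, reps, h = 12, 4000, 0.6
        draws = np.stack(
            [generate_fgn(FgnSpec(h, n, seed=r), method="cholesky").values
             for r in range(reps)])
        sample_cov = draws.T @ draws / reps
        gamma = toeplitz(fgn_autocovariance(h, np.arange(n)))
        se = np.sqrt((np.outer(np.diag(gamma), np.diag(gamma)) + gamma**2)
                     / reps)
        assert np.all(np.abs(sample_cov - gamma) < 4 * se)

    def test_lag1_autocorrelation_closed_form(self):
        """Mean lag-1 autocorrelation at H=0.7 hits 2^{2H-1} − 1 ≈ 0.3195."""
        target = 2 ** (2 * 0.7 - 1) - 1
        acs = []
        for r in range(200):
            x = generate_fgn(FgnSpec(0.7, 2**14, seed=r)).values
            acs.append(np.dot(x[:-1], x[1:]) / np.dot(x, x))
        acs = np.asarray(acs)
        se = acs.std(ddof=1) / np.sqrt(len(acs))
        assert abs(acs.mean() - target) < 3 * se

    def test_h_half_is_white(self):
        x = generate_fgn(FgnSpec(0.5, 2**16, seed=3)).values
        ac1 = np.dot(x[:-1], x[1:]) / np.dot(x, x)
        assert abs(ac1) < 0.02  # ~5 SE at this length

    def test_sigma_scales_marginal_sd(self):
        draws = np.stack([generate_fgn(FgnSpec(0.8, 64, sigma=3.0, seed=r)).values
                          for r in range(2000)])
        assert np.allclose(draws.var(axis=0).mean(), 9.0, rtol=0.1)

    @pytest.mark.parametrize("h", [0.0, 1.0, -0.2, 1.7])
    def test_rejects_hurst_outside_unit_interval(self, h):
        with pytest.raises(ValueError):
            FgnSpec(h, 100)

    def test_circulant_method_refuses_rather_than_approximates(self):
        # for fGn the embedding is valid; the explicit method must agree
        # with auto at any H rather than silently switching construction
        a = generate_fgn(FgnSpec(0.9, 256, seed=5), method="circulant")
        b = generate_fgn(FgnSpec(0.9, 256, seed=5), method="auto")
        np.testing.assert_array_equal(a.values, b.values)


class TestDeterminismAndDuality:
    def test_same_spec_same_series(self):
        spec = FgnSpec(0.8, 425, seed=11)
        np.testing.assert_array_equal(generate_fgn(spec).values,
                                      generate_fgn(spec).values)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(h=st.floats(0.05, 0.95), n=st.integers(2, 200),
           seed=st.integers(0, 2**31 - 1))
    def test_fbm_is_cumsum_of_fgn_bitforbit(self, h, n, seed):
        spec = FgnSpec(h, n, seed=seed)
        fgn = generate_fgn(spec).values
        fbm = generate_fbm(spec).values
        np.testing.assert_array_equal(fbm, np.cumsum(fgn))
        assert fbm[0] == fgn[0]

    def test_fbm_two_samples(self):
        spec = FgnSpec(0.7, 2, seed=1)
        x = generate_fgn(spec).values
        fbm = generate_fbm(spec).values
        np.testing.assert_allclose(fbm, [x[0], x[0] + x[1]])

    def test_fbm_random_walk_variance_growth(self):
        """H = 0.5 gives Var(B_t) = σ²·t."""
        reps, n = 4000, 64
        paths = np.stack([generate_fbm(FgnSpec(0.5, n, seed=r)).values
                          for r in range(reps)])
        for t in (8, 32, 64):
            var = paths[:, t - 1].var()
            tol = 4 * t * np.sqrt(2.0 / reps)  # 4 SE of a variance estimate
            assert abs(var - t) < tol


class TestConfounds:
    def test_zero_amplitudes_identity(self):
        ts = generate_fgn(FgnSpec(0.8, 128, seed=0))
        out = add_confounds(ts, ConfoundSpec(), seed=1)
        np.testing.assert_array_equal(out.values, ts.values)

    def test_cardiac_band_aliases_at_tr2(self):
        """At TR = 2 s the Nyquist is 0.25 Hz; a 0.6–1.2 Hz band must error."""
        ts = generate_fgn(FgnSpec(0.8, 128, seed=0), sampling_interval=2.0)
        spec = ConfoundSpec(amplitudes=(0.0, 1.0), sampling_interval=2.0)
        with pytest.raises(ValueError, match="[Nn]yquist"):
            add_confounds(ts, spec, seed=1)

    def test_respiratory_peak_lands_in_band(self):
        """A dominant respiratory sinusoid shows up as the periodogram
        argmax inside the requested band (fast sampling, TR = 0.5 s)."""
        from fractalbold.spectral import periodogram

        ts = generate_fgn(FgnSpec(0.5, 1024, seed=2), sampling_interval=0.5)
        spec = ConfoundSpec(amplitudes=(50.0, 0.0), sampling_interval=0.5)
        out = add_confounds(ts, spec, seed=3)
        psd = periodogram(out)
        peak = psd.frequencies[np.argmax(psd.power)]
        assert 0.1 <= peak <= 0.5

    def test_invalid_band_rejected(self):
        with pytest.raises(ValueError):
            ConfoundSpec(respiratory_band=(0.5, 0.1))


class TestVolumeFixture:
    def test_noiseless_extraction_recovers_signal(self):
        signal = generate_fgn(FgnSpec(0.8, 32, seed=4))
        img = generate_volume_with_roi((12, 12, 12), 2.0, (11, 11, 11), 5.0,
                                       signal, noise_sd=0.0, seed=0)
        mask = sphere_mask((11, 11, 11), 5.0, img.affine, img.shape)
        out = extract_mean_timeseries(img, mask)
        np.testing.assert_allclose(out.values, signal.values, atol=1e-10)

    def test_noise_averages_out_over_large_sphere(self):
        """ROI mean over ≥100 voxels keeps correlation > 0.9 at SNR 1."""
        signal = generate_fgn(FgnSpec(0.8, 64, seed=5))
        img = generate_volume_with_roi((16, 16, 16), 2.0, (15, 15, 15), 7.0,
                                       signal, noise_sd=1.0, seed=6)
        mask = sphere_mask((15, 15, 15), 7.0, img.affine, img.shape)
        assert mask.sum() >= 100
        out = extract_mean_timeseries(img, mask)
        assert np.corrcoef(out.values, signal.values)[0, 1] > 0.9

    def test_pure_noise_roi_mean_near_zero(self):
        signal = TimeSeries(np.zeros(50), 2.0)
        img = generate_volume_with_roi((12, 12, 12), 2.0, (11, 11, 11), 5.0,
                                       signal, noise_sd=1.0, seed=7)
        mask = sphere_mask((11, 11, 11), 5.0, img.affine, img.shape)
        out = extract_mean_timeseries(img, mask)
        se = 1.0 / np.sqrt(mask.sum() * 50)
        assert abs(out.values.mean()) < 4 * se

    def test_sphere_outside_fov_rejected(self):
        signal = generate_fgn(FgnSpec(0.8, 16, seed=0))
        with pytest.raises(ValueError, match="field of view"):
            generate_volume_with_roi((8, 8, 8), 2.0, (1, 1, 1), 6.0, signal)


class TestCohort:
    def test_row_count_and_groups(self):
        table = generate_cohort(CohortSpec(n_high=38, n_low=65, seed=1))
        assert len(table) == 103
        assert (table["group"] == "highIMP").sum() == 38
        assert (table["group"] == "lowIMP").sum() == 65
        # premature counts consistent with the >= 3 phenotype rule
        assert (table.loc[table.group == "highIMP", "premature_count"] >= 3).all()
        assert (table.loc[table.group == "lowIMP", "premature_count"] < 3).all()

    def test_zero_rho_gives_null_correlation(self):
        spec = CohortSpec(
            n_high=10_000, n_low=10_000,
            rho_by_group={"highIMP": {"c": 0.0}, "lowIMP": {"c": 0.0}},
            seed=2)
        table = generate_cohort(spec)
        for group in ("highIMP", "lowIMP"):
            sub = table[table.group == group]
            r = np.corrcoef(sub["deviation"], sub["c"])[0, 1]
            assert abs(r) < 0.03

    def test_planted_rho_recovery_at_study_sizes(self):
        """Mean per-group sample r recovers −0.03 / 0.36 at n = 65/38."""
        rs = {"highIMP": [], "lowIMP": []}
        for rep in range(300):
            table = generate_cohort(CohortSpec(seed=rep))
            for group in rs:
                sub = table[table.group == group]
                rs[group].append(
                    np.corrcoef(sub["deviation"], sub["ACC_to_l_HC"])[0, 1])
        for group, target in (("highIMP", 0.36), ("lowIMP", -0.03)):
            r = np.asarray(rs[group])
            se = r.std(ddof=1) / np.sqrt(len(r))
            assert abs(r.mean() - target) < 3 * se

    def test_deterministic_given_seed(self):
        a = generate_cohort(CohortSpec(seed=9))
        b = generate_cohort(CohortSpec(seed=9))
        assert a.equals(b)

    def test_rho_magnitude_validated(self):
        with pytest.raises(ValueError):
            CohortSpec(rho_by_group={"highIMP": {"c": 1.0},
                                     "lowIMP": {"c": 0.0}})
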