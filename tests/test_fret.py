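"""FRET estimators, Förster theory and the B-DNA helix geometry model."""

import numpy as np
import pytest

import ixflim
from ixflim.fret import ForsterContext
from ixflim.helix import HelixModel, fit_helix_model, helix_fret_curve


class TestRiseAndQuench:
    def test_rise_published_bead_values(self):
        """235 ps rise with a 0.75 ns donor gives E = 0.687, consistent
        with the printed 0.68 +/- 0.07; 0.18 ns with a 2.9 ns donor gives
        0.938, consistent with 0.93 +/- 0.03."""
        r = ixflim.efficiency_from_rise(0.235, 0.75)
        assert abs(r.efficiency - 0.687) < 1e-3
        assert abs(r.efficiency - 0.68) < 0.07
        r2 = ixflim.efficiency_from_rise(0.18, 2.9)
        assert abs(r2.efficiency - 0.938) < 1e-3
        assert abs(r2.efficiency - 0.93) < 0.03

    def test_rise_equal_lifetimes_zero(self):
        assert ixflim.efficiency_from_rise(0.75, 0.75).efficiency == 0.0

    def test_rise_exceeding_donor_warns_negative(self):
        with pytest.warns(RuntimeWarning, match="exceeds"):
            r = ixflim.efficiency_from_rise(1.0, 0.75)
        assert r.raw_efficiency < 0 and r.efficiency == 0.0

    def test_rise_error_propagation(self):
        """First-order propagation: reproduces the published 0.68 +/- 0.07
        from the printed rise and donor uncertainties."""
        r = ixflim.efficiency_from_rise(0.235, 0.75, 0.024, 0.08)
        expected = np.hypot(0.024 / 0.75, 0.235 * 0.08 / 0.75**2)
        assert abs(r.stderr - expected) < 1e-12
        assert 0.0 < r.stderr < 0.07  # within the published uncertainty

    def test_donor_quench(self):
        assert ixflim.efficiency_from_donor_quench(0.75, 0.75).efficiency == 0
        r = ixflim.efficiency_from_donor_quench(0.25, 0.75)
        assert abs(r.efficiency - 2.0 / 3.0) < 1e-12

    def test_quench_recovers_simulated_pair(self, t_axis, irf):
        """Donor-channel decay pair with ground-truth E = 0.66: the
        fitted-lifetime quench estimate recovers it within combined fit
        error."""
        from ixflim.globalfit import exp_gauss_kernel
        from ixflim.reconstruct import TransientMap

        e_true = 0.66
        kd = 1.0 / 0.75
        krise = kd / (1 - e_true)
        lam = np.linspace(540.0, 600.0, 7)
        taus = {}
        errs = {}
        for name, k in [("with", krise), ("alone", kd)]:
            values = np.ones(lam.size)[:, None] * \
                exp_gauss_kernel(k, irf, t_axis)[None, :]
            values *= 5e5 / values.sum()
            data = np.random.default_rng(13).poisson(values).astype(float)
            tmap = TransientMap(values=data, lambda_axis=lam, t_axis=t_axis,
                                valid_mask=np.ones(lam.size, bool),
                                roi={"raw_counts": True})
            fit = ixflim.fit_global(tmap, 1, irf, seed=0, n_starts=4)
            taus[name] = fit.lifetimes[0]
            errs[name] = fit.lifetime_stderr[0]
        r = ixflim.efficiency_from_donor_quench(taus["with"], taus["alone"],
                                                errs["with"], errs["alone"])
        assert abs(r.efficiency - e_true) < max(3 * r.stderr, 0.02)


class TestSpectralDecomposition:
    lam = np.linspace(480.0, 700.0, 111)

    def _bases(self):
        eps_d = ixflim.gaussian_band(self.lam, 550.0, 40.0)
        eps_a = ixflim.gaussian_band(self.lam, 650.0, 45.0)
        laser = ixflim.gaussian_band(self.lam, 590.0, 160.0)
        return eps_d, eps_a, laser

    def test_acceptor_only_spectrum_gives_zero(self):
        eps_d, eps_a, laser = self._bases()
        r = ixflim.efficiency_from_spectrum(eps_a * laser, eps_d, eps_a,
                                            laser)
        assert abs(r.efficiency) < 1e-10

    def test_equal_concentration_construction_recovered(self):
        """Spectrum built as eps_A + E eps_D (times the laser) returns E
        to 1e-6 for noiseless input."""
        eps_d, eps_a, laser = self._bases()
        e_true = 0.72
        y = (eps_a + e_true * eps_d) * laser
        r = ixflim.efficiency_from_spectrum(y, eps_d, eps_a, laser)
        assert abs(r.efficiency - e_true) < 1e-6

    @pytest.mark.parametrize("e_true,leak", [(0.4, 0.2), (0.9, 0.05),
                                             (0.68, 0.12)])
    def test_donor_leak_correction_algebra(self, e_true, leak):
        """A leak ratio r turns the donor weight into E + r (1 - E); the
        uncorrected estimate equals that, the corrected one equals E, and
        zero leak reduces to the plain form."""
        eps_d, eps_a, laser = self._bases()
        y = (eps_a + (e_true + leak * (1 - e_true)) * eps_d) * laser
        uncorr = ixflim.efficiency_from_spectrum(y, eps_d, eps_a, laser)
        assert abs(uncorr.efficiency - (e_true + leak * (1 - e_true))) < 1e-9
        corr = ixflim.efficiency_from_spectrum(y, eps_d, eps_a, laser,
                                               leak_ratio=leak)
        assert abs(corr.efficiency - e_true) < 1e-9

    def test_collinear_references_rejected(self):
        eps_d, _, laser = self._bases()
        with pytest.raises(ValueError, match="collinear"):
            ixflim.efficiency_from_spectrum(eps_d * laser, eps_d,
                                            eps_d * 2.0, laser)

    def test_time_integral_identity(self, irf):
        """The time integral of the sequential-kinetics map equals the
        stationary spectral form eps_A + E eps_D (the closed-form identity
        behind the spectral method), verified numerically to 1e-6."""
        from ixflim.globalfit import exp_gauss_kernel

        kd, ka = 1.0 / 0.75, 1.0 / 1.34
        e_true = 0.68
        kt = kd * e_true / (1 - e_true)
        krise = kd + kt
        t = np.arange(80000) * 5e-4  # 40 ns, fine bins
        irf0 = ixflim.Irf(fwhm=50.0, t0=2.0)
        acceptor_kin = ka * exp_gauss_kernel(ka, irf0, t)
        fed_kin = ka * kt / (krise - ka) * (
            exp_gauss_kernel(ka, irf0, t) - exp_gauss_kernel(krise, irf0, t))
        w_a = np.trapezoid(acceptor_kin, t)
        w_d = np.trapezoid(fed_kin, t)
        assert abs(w_a - 1.0) < 1e-6
        assert abs(w_d - e_true) < 1e-6


class TestEfficiencyMap:
    def _image(self, e_map, budget_per_px=None, seed=0):
        """Per-pixel time-integrated spectra eps_A + E eps_D, optionally
        Poisson-sampled at ``budget_per_px`` photons per pixel."""
        lam = np.linspace(480.0, 700.0, 56)
        eps_d = ixflim.gaussian_band(lam, 550.0, 40.0)
        eps_a = ixflim.gaussian_band(lam, 650.0, 45.0)
        ixfim = (eps_a[:, None, None]
                 + e_map[None, :, :] * eps_d[:, None, None])
        if budget_per_px is not None:
            ixfim = ixfim * budget_per_px / ixfim.sum(axis=0).mean()
            rng = np.random.default_rng(seed)
            ixfim = rng.poisson(np.maximum(ixfim, 0)).astype(float)
        return lam, eps_d, eps_a, ixfim

    def test_uniform_scene_constant_efficiency(self):
        e_map = np.full((8, 8), 0.7)
        lam, eps_d, eps_a, ixfim = self._image(e_map)
        img = ixflim.efficiency_map(ixfim, lam, (510.0, 590.0),
                                    (610.0, 690.0), eps_d, eps_a)
        np.testing.assert_allclose(img.values, 0.7, atol=1e-9)

    def test_two_population_mixture_resolved(self):
        """Mixed high/low-efficiency bead populations separate into pixel
        clusters near E = 1 and E = 0.7."""
        e_map = np.zeros((10, 10))
        e_map[:, :5] = 0.98
        e_map[:, 5:] = 0.70
        lam, eps_d, eps_a, ixfim = self._image(e_map, budget_per_px=5000,
                                               seed=2)
        img = ixflim.efficiency_map(ixfim, lam, (510.0, 590.0),
                                    (610.0, 690.0), eps_d, eps_a)
        left = np.nanmedian(img.values[:, :5])
        right = np.nanmedian(img.values[:, 5:])
        assert abs(left - 0.98) < 0.1
        assert abs(right - 0.70) < 0.1

    def test_dark_pixels_undefined(self):
        e_map = np.full((4, 4), 0.5)
        lam, eps_d, eps_a, ixfim = self._image(e_map)
        ixfim[:, 0, 0] = 0.0
        img = ixflim.efficiency_map(ixfim, lam, (510.0, 590.0),
                                    (610.0, 690.0), eps_d, eps_a,
                                    threshold=0.05)
        assert not img.mask[0, 0] and np.isnan(img.values[0, 0])

    def test_overlapping_bands_rejected(self):
        e_map = np.full((2, 2), 0.5)
        lam, eps_d, eps_a, ixfim = self._image(e_map)
        with pytest.raises(ValueError, match="disjoint"):
            ixflim.efficiency_map(ixfim, lam, (510.0, 620.0), (600.0, 690.0),
                                  eps_d, eps_a)


class TestKappaAndForsterRadius:
    def test_parallel_perpendicular_to_r(self):
        mu = np.array([0.0, 1.0, 0.0])
        r = np.array([1.0, 0.0, 0.0])
        assert abs(ixflim.kappa_bracket(mu, mu, r) - 1.0) < 1e-12

    def test_collinear_along_r(self):
        mu = np.array([1.0, 0.0, 0.0])
        assert abs(ixflim.kappa_bracket(mu, mu, mu) + 2.0) < 1e-12

    def test_isotropic_average_two_thirds(self):
        """Uniform-sphere Monte Carlo of kappa^2 averages to 2/3 within
        1% at 1e6 samples."""
        rng = np.random.default_rng(123)

        def sphere(n):
            v = rng.normal(size=(n, 3))
            return v / np.linalg.norm(v, axis=1, keepdims=True)

        n = 1_000_000
        br = ixflim.kappa_bracket(sphere(n), sphere(n), sphere(n))
        assert abs(np.mean(br**2) - 2.0 / 3.0) < 0.01 * 2.0 / 3.0

    def test_non_unit_inputs_normalized_with_warning(self):
        mu = np.array([0.0, 2.0, 0.0])
        r = np.array([1.0, 0.0, 0.0])
        with pytest.warns(RuntimeWarning, match="normaliz"):
            out = ixflim.kappa_bracket(mu, mu, r)
        assert abs(out - 1.0) < 1e-12

    def _ctx(self, **kw):
        lam = np.linspace(500.0, 700.0, 801)
        absn = 250_000.0 * np.exp(-0.5 * ((lam - 650.0) / 20.0) ** 2)
        emis = np.exp(-0.5 * ((lam - 600.0) / 18.0) ** 2)
        emis /= np.trapezoid(emis, lam)
        return ForsterContext(lam, absn, emis, refractive_index=1.33, **kw)

    def test_refractive_index_scaling(self):
        """n -> 2n divides R0 by 2^(2/3) (the n^-4 power)."""
        r1 = ixflim.forster_radius(self._ctx())
        ctx2 = self._ctx()
        ctx2.refractive_index *= 2.0
        r2 = ixflim.forster_radius(ctx2)
        assert abs(r2 - r1 / 2.0 ** (2.0 / 3.0)) < 1e-9

    def test_orientation_scaling(self):
        """Quadrupling kappa^2 multiplies R0 by 4^(1/6)."""
        iso = ixflim.forster_radius(self._ctx())
        mu = np.array([1.0, 0.0, 0.0])
        collinear = self._ctx(orientation=(mu, mu, mu))  # kappa^2 = 4
        r = ixflim.forster_radius(collinear)
        assert abs(r / iso - (4.0 / (2.0 / 3.0)) ** (1.0 / 6.0)) < 1e-9

    def test_overlap_quadrature_oracle(self):
        """R0 from the trapezoid overlap integral matches an independent
        fine-grid evaluation to < 1e-4 relative."""
        ctx = self._ctx()
        lam_fine = np.linspace(500.0, 700.0, 100001)
        absn = 250_000.0 * np.exp(-0.5 * ((lam_fine - 650.0) / 20.0) ** 2)
        emis = np.exp(-0.5 * ((lam_fine - 600.0) / 18.0) ** 2)
        emis /= np.trapezoid(emis, lam_fine)
        j = np.trapezoid(absn * emis * lam_fine**4, lam_fine)
        r0_ref = (8.79e-5 * (2.0 / 3.0) * 1.33**-4 * j) ** (1 / 6) / 10.0
        assert abs(ixflim.forster_radius(ctx) - r0_ref) / r0_ref < 1e-4

    def test_non_overlapping_spectra_zero_radius(self):
        lam = np.linspace(500.0, 700.0, 201)
        absn = np.where(lam > 680, 1e5, 0.0)
        emis = np.where(lam < 520, 1.0, 0.0)
        emis /= np.trapezoid(emis, lam)
        ctx = ForsterContext(lam, absn, emis)
        with pytest.warns(RuntimeWarning, match="overlap"):
            assert ixflim.forster_radius(ctx) == 0.0


class TestDistanceRelation:
    def test_half_efficiency_at_r0(self):
        assert abs(ixflim.efficiency_from_distance(5.5, 5.5) - 0.5) < 1e-12

    def test_published_npm_distance(self):
        """E = 0.938 (NPM rise/donor lifetimes) with R0 = 5.5 nm implies
        ~3.5 nm = 35 Å."""
        e = ixflim.efficiency_from_rise(0.18, 2.9).efficiency
        r = ixflim.distance_from_efficiency(e, 5.5)
        assert abs(10.0 * r - 35.0) < 1.0  # Å

    def test_direct_evaluation(self):
        assert abs(ixflim.efficiency_from_distance(6.8, 7.1) - 0.564) < 1e-3

    @pytest.mark.parametrize("e", [0.01, 0.25, 0.5, 0.68, 0.93, 0.999])
    def test_round_trip_identity(self, e):
        r = ixflim.distance_from_efficiency(e, 7.1)
        assert abs(ixflim.efficiency_from_distance(r, 7.1) - e) < 1e-12

    def test_inverse_undefined_at_bounds(self):
        with pytest.raises(ValueError):
            ixflim.distance_from_efficiency(1.0, 7.1)
        with pytest.raises(ValueError):
            ixflim.distance_from_efficiency(0.0, 7.1)

    def test_transfer_rate_consistency(self):
        k_d = 1.0 / 0.75
        k_t = ixflim.transfer_rate(k_d, 7.1, 6.8)
        assert abs(k_t / (k_t + k_d)
                   - ixflim.efficiency_from_distance(6.8, 7.1)) < 1e-12


class TestHelixModel:
    TABLE_BP = [4, 12, 13, 20]
    TABLE_RISE = [0.91, 0.81, 0.73, 0.68]
    TABLE_SIGMA = [0.07, 0.03, 0.05, 0.06]
    TABLE_THEORY = [1.0, 0.78, 0.69, 0.71]

    def test_zero_offset_zero_disorder_distance_is_axial(self):
        """With the dipole on the axis and no disorder the separation is
        exactly rise_per_bp x bp; with the isotropic orientation factor
        the curve equals the closed-form distance relation."""
        model = HelixModel(dipole_radial_offset=0.0, helical_angle_sigma=0.0,
                           rise_angle_sigma=0.0, mc_samples=1000)
        for bp in (6, 10, 20):
            e = helix_fret_curve(model, 7.1, [bp], isotropic_kappa=True)[0]
            assert abs(e - ixflim.efficiency_from_distance(bp * 0.34, 7.1)) \
                < 1e-12

    def test_isotropic_mode_tracks_distance_curve(self):
        """The kappa^2 = 2/3 reference mode reproduces the plain
        efficiency-distance curve up to the (small) distance spread from
        the radial offset."""
        model = HelixModel(dipole_radial_offset=0.5, mc_samples=50_000)
        bps = [8, 12, 16, 20]
        curve = helix_fret_curve(model, 7.1, bps, isotropic_kappa=True)
        ref = [ixflim.efficiency_from_distance(bp * 0.34, 7.1) for bp in bps]
        assert np.max(np.abs(curve - np.array(ref))) < 0.03

    def test_non_monotonic_with_paper_disorder(self):
        """At the published disorder (30 deg helical, ~0 rise) a rigid
        attachment geometry can invert the distance ordering: 20 bp is a
        whole number of turns, so E(13 bp) < E(20 bp)."""
        model = HelixModel(dipole_radial_offset=0.3, dipole_tilt=30.0,
                           helical_angle_sigma=30.0, rise_angle_sigma=0.0,
                           mc_samples=100_000)
        e13, e20 = helix_fret_curve(model, 7.1, [13, 20])
        assert e13 < e20

    def test_self_consistent_parameter_recovery(self):
        """Data generated by the model itself (4 separations, no noise) is
        refit with near-zero residual and recovered parameters."""
        true = HelixModel(dipole_radial_offset=0.8, dipole_tilt=25.0,
                          mc_samples=40_000)
        data = helix_fret_curve(true, 7.1, self.TABLE_BP)
        meas = [(bp, e, 0.01) for bp, e in zip(self.TABLE_BP, data)]
        start = HelixModel(dipole_radial_offset=1.2, dipole_tilt=10.0,
                           mc_samples=40_000)
        fitted, info = fit_helix_model(meas, start, 7.1)
        assert np.max(np.abs(info["residuals"])) < 0.01
        assert abs(fitted.dipole_radial_offset - 0.8) < 0.25
        assert abs(abs(fitted.dipole_tilt) - 25.0) < 5.0

    def test_fit_to_measured_reproduces_theory_column(self):
        """Fitting offset, tilt and helical disorder to the four measured
        signal-rise efficiencies reproduces the calculated per-separation
        efficiencies within +/-0.05."""
        meas = list(zip(self.TABLE_BP, self.TABLE_RISE, self.TABLE_SIGMA))
        start = HelixModel(mc_samples=20_000)
        fitted, info = fit_helix_model(
            meas, start, 7.1,
            free_parameters=("dipole_radial_offset", "dipole_tilt",
                             "helical_angle_sigma"))
        from dataclasses import replace
        curve = helix_fret_curve(replace(fitted, mc_samples=300_000), 7.1,
                                 self.TABLE_BP)
        assert np.max(np.abs(curve - np.array(self.TABLE_THEORY))) <= 0.05

    def test_deterministic_given_seed(self):
        m = HelixModel(mc_samples=5000, seed=7)
        c1 = helix_fret_curve(m, 7.1, [10, 15])
        c2 = helix_fret_curve(m, 7.1, [10, 15])
        np.testing.assert_array_equal(c1, c2)


class TestMethodConcordance:
    @pytest.mark.parametrize("e_true", [0.3, 0.68, 0.9])
    def test_rise_spectral_quench_agree(self, e_true, t_axis, irf):
        """Rise-time, spectral and donor-quench estimates from matched
        synthetic bead data agree with the ground truth within their
        propagated errors (floored at 0.02 for the near-noiseless fits)."""
        from ixflim.globalfit import exp_gauss_kernel
        from ixflim.reconstruct import TransientMap

        lam = np.linspace(480.0, 700.0, 45)
        eps_d = ixflim.gaussian_band(lam, 550.0, 40.0)
        eps_a = ixflim.gaussian_band(lam, 650.0, 45.0)
        kd, ka = 1.0 / 0.75, 1.0 / 1.34
        kt = kd * e_true / (1 - e_true)
        krise = kd + kt
        feed = kt / (krise - ka)
        values = (eps_a[:, None] * exp_gauss_kernel(ka, irf, t_axis)[None, :]
                  + eps_d[:, None] * feed
                  * (exp_gauss_kernel(ka, irf, t_axis)
                     - exp_gauss_kernel(krise, irf, t_axis))[None, :]) * ka
        values *= 2e6 / values.sum()
        data = np.random.default_rng(31).poisson(values).astype(float)
        tmap = TransientMap(values=data, lambda_axis=lam, t_axis=t_axis,
                            valid_mask=np.ones(lam.size, bool),
                            roi={"raw_counts": True})
        # rise route
        fit = ixflim.fit_global(tmap, 2, irf, seed=0, n_starts=4)
        rise = ixflim.efficiency_from_rise(
            1.0 / fit.rates[0], 0.75, fit.lifetime_stderr[0])
        # spectral route (flat laser: the map was built without one)
        spectrum = data.sum(axis=1)
        spectral = ixflim.efficiency_from_spectrum(
            spectrum, eps_d, eps_a, np.ones_like(lam))
        # donor-quench route from matched donor-channel decays
        quench_pair = {}
        for name, k in [("with", krise), ("alone", kd)]:
            v = np.ones(5)[:, None] * exp_gauss_kernel(k, irf, t_axis)
            v *= 5e5 / v.sum()
            d = np.random.default_rng(37).poisson(v).astype(float)
            tm = TransientMap(values=d, lambda_axis=np.linspace(540, 600, 5),
                              t_axis=t_axis,
                              valid_mask=np.ones(5, bool),
                              roi={"raw_counts": True})
            f1 = ixflim.fit_global(tm, 1, irf, seed=0, n_starts=4)
            quench_pair[name] = (f1.lifetimes[0], f1.lifetime_stderr[0])
        quench = ixflim.efficiency_from_donor_quench(
            quench_pair["with"][0], quench_pair["alone"][0],
            quench_pair["with"][1], quench_pair["alone"][1])
        for est in (rise, spectral, quench):
            tol = max(3 * est.stderr, 0.02)
            assert abs(est.efficiency - e_true) < tol, est
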