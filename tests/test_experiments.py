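"""Sweep workflows, extrapolation, L-curve, cross-validation, residual re-addition."""

import numpy as np
import pytest
from scipy.stats import spearmanr

from nuscs import (GreedyConfig, IrlsConfig, IstConfig, PeakList,
                   SweepSpec, cross_validate, extrapolate, fft_spectrum,
                   first_sufficient_level, irls, ist_d, l_curve, omp,
                   readd_residual, required_m, residual_curve, restrict,
                   synth_fid, uniform_schedule)


def omp_method(K):
    return lambda nus: omp(nus, GreedyConfig(epsilon=1e-10, max_iter=3 * K,
                                             mode="omp"))


THREE_PEAK_512 = PeakList([(60, 1.0, 0.0, 0.0), (200, 0.7, 0.5, 0.0),
                           (350, 0.4, 1.0, 0.0)])


class TestRequiredM:
    def test_printed_arithmetic(self):
        assert required_m(4, 512) == int(np.ceil(4 * np.log(128)))  # 20

    def test_half_grid_closed_form(self):
        n = 64
        assert required_m(n // 2, n) == int(np.ceil((n / 2) * np.log(2)))

    def test_monotone_in_k_and_n(self):
        assert required_m(4, 512) < required_m(8, 512)
        assert required_m(4, 512) < required_m(4, 2048)

    def test_k_bounds_enforced(self):
        with pytest.raises(ValueError):
            required_m(512, 512)


class TestResidualCurve:
    def test_full_sampling_level_is_exact(self):
        fid = synth_fid(THREE_PEAK_512, 512)
        spec = SweepSpec(truth=fid, levels=[512], method=omp_method(3),
                         n_schedules=2, seed=0)
        curve = residual_curve(spec)
        assert curve.mean_residual[0] <= 1e-8

    def test_reproducible_from_seed(self):
        fid = synth_fid(THREE_PEAK_512, 512)
        spec = SweepSpec(truth=fid, levels=[8, 16], method=omp_method(3),
                         n_schedules=3, seed=9)
        a = residual_curve(spec)
        b = residual_curve(spec)
        assert np.array_equal(a.mean_residual, b.mean_residual)

    def test_monotone_trend_and_k_dependence(self):
        """Mean residual trends down with m; the empirically required m is
        larger for 3 peaks than for 1, and grows only weakly with n."""
        levels = [2, 3, 4, 6, 8, 12, 16, 24, 32, 48]
        one_peak = PeakList([(60, 1.0, 0.0, 0.0)])
        three_1024 = PeakList([(120, 1.0, 0.0, 0.0), (400, 0.7, 0.5, 0.0),
                               (700, 0.4, 1.0, 0.0)])
        results = {}
        for key, model, n, K in (("K1n512", one_peak, 512, 1),
                                 ("K3n512", THREE_PEAK_512, 512, 3),
                                 ("K3n1024", three_1024, 1024, 3)):
            fid = synth_fid(model, n)
            curve = residual_curve(SweepSpec(
                truth=fid, levels=levels, method=omp_method(K),
                n_schedules=20, seed=42))
            ref = np.linalg.norm(fft_spectrum(fid).values)
            results[key] = (curve, first_sufficient_level(curve, ref))
        rho = spearmanr(levels, results["K3n512"][0].mean_residual).statistic
        assert rho <= -0.9
        m1, m3, m3b = (results["K1n512"][1], results["K3n512"][1],
                       results["K3n1024"][1])
        assert m1 is not None and m3 is not None and m3b is not None
        assert m3 > m1
        assert m3b < 1.5 * m3  # doubling n grows the requirement far less than 2x

    def test_ist_and_irls_monotone_trend(self):
        fid = synth_fid(THREE_PEAK_512, 512)
        levels = [8, 16, 32, 64, 128]

        def ist_method(nus):
            return ist_d(nus, IstConfig(threshold=0.9, epsilon=1e-8,
                                        n_iter=300, variant="D"))

        def irls_method(nus):
            return irls(nus, IrlsConfig(p=0.5, lam=1e-6, n_iter=20))

        for method in (ist_method, irls_method):
            curve = residual_curve(SweepSpec(truth=fid, levels=levels,
                                             method=method, n_schedules=10,
                                             seed=7))
            rho = spearmanr(levels, curve.mean_residual).statistic
            assert rho <= -0.9


class TestExtrapolate:
    MODEL = PeakList([(60.0, 1.0, 0.0, 0.03), (150.0, 0.2, 0.0, 0.03)])

    def test_keep_all_is_identity_pipeline(self):
        fid = synth_fid(self.MODEL, 256)
        r = extrapolate(fid, 256, IstConfig(threshold=0.9, epsilon=1e-10,
                                            n_iter=500, variant="D"))
        assert np.allclose(r.fid.samples, fid.samples, atol=1e-8)

    def test_twofold_extrapolation_recovers_small_peak(self):
        fid = synth_fid(self.MODEL, 256)
        truth = fft_spectrum(fid).values
        r = extrapolate(fid, 128, IstConfig(threshold=0.9, epsilon=1e-10,
                                            n_iter=3000, variant="D",
                                            use_ve=True))
        err = (abs(abs(r.spectrum.values[150]) - abs(truth[150]))
               / abs(truth[150]))
        assert err <= 0.2

    def test_oversparse_extreme_truncation_kills_decay(self):
        fid = synth_fid(self.MODEL, 256)
        r = extrapolate(fid, 8, IstConfig(threshold=0.999, epsilon=1e-10,
                                          n_iter=200, variant="D",
                                          use_ve=True))
        assert r.diagnostics["tail_decay"] < 0.2 * 0.03


class TestLCurve:
    """Corner selection for the sparsity weight of l_{1/2} IRLS.

    The sparsity penalty passed to the corner search matches the method's
    own term (sum of |x|^p): for noisy NUS data it is what separates a
    noise-fitting solution from a clean sparse one, because the restricted
    Fourier operator itself is well conditioned.
    """

    GRID = [10.0**e for e in np.arange(-5, 2.01, 0.5)]

    def _nus(self):
        model = PeakList([(10, 1.0, 0.0, 0.0), (40, 0.3, 0.0, 0.0)])
        fid = synth_fid(model, 64, noise_sigma=0.01, seed=1)
        return fft_spectrum(fid).values, restrict(
            fid, uniform_schedule(64, 24, 2))

    @staticmethod
    def _factory(lam):
        return lambda nus: irls(nus, IrlsConfig(p=0.5, lam=lam, n_iter=15))

    @staticmethod
    def _penalty(spec):
        return float(np.sum(np.abs(spec.values) ** 0.5))

    def test_misfit_monotone_in_lambda(self):
        _, nus = self._nus()
        _, table = l_curve(nus, self._factory, self.GRID,
                           penalty=self._penalty)
        assert np.all(np.diff(table[:, 1]) >= -1e-9)

    def test_selected_lambda_near_grid_optimum(self):
        truth, nus = self._nus()
        best, _ = l_curve(nus, self._factory, self.GRID,
                          penalty=self._penalty)

        def err(lam):
            r = self._factory(lam)(nus)
            return np.linalg.norm(r.spectrum.values - truth)

        grid_opt = min(self.GRID, key=err)
        assert err(best) <= 2 * err(grid_opt)

    def test_short_grid_rejected(self):
        _, nus = self._nus()
        with pytest.raises(ValueError):
            l_curve(nus, self._factory, [0.1, 1.0])


class TestCrossValidate:
    def test_train_split_size(self):
        model = PeakList([(10, 1.0, 0.0, 0.0)])
        fid = synth_fid(model, 64)
        nus = restrict(fid, uniform_schedule(64, 32, 0))
        sizes = []

        def factory(lam):
            def run(d):
                sizes.append(d.m)
                return irls(d, IrlsConfig(p=1.0, lam=lam, n_iter=3))
            return run

        cross_validate(nus, factory, [{"lam": 0.1}], holdout_frac=0.25,
                       seed=0)
        assert sizes == [round(0.75 * 32)]

    def test_duplicate_grid_entries_same_selection(self):
        model = PeakList([(10, 1.0, 0.0, 0.0), (40, 0.3, 0.0, 0.0)])
        fid = synth_fid(model, 64, noise_sigma=0.02, seed=4)
        nus = restrict(fid, uniform_schedule(64, 32, 5))

        def factory(lam):
            return lambda d: irls(d, IrlsConfig(p=1.0, lam=lam, n_iter=8))

        grid = [{"lam": 1e-3}, {"lam": 1.0}, {"lam": 100.0}]
        best_a, _ = cross_validate(nus, factory, grid, seed=6)
        best_b, _ = cross_validate(nus, factory, grid + grid, seed=6)
        assert best_a == best_b

    def test_cv_close_to_oracle_choice(self):
        """CV-selected lambda performs within 2x of the grid-oracle error
        (median over seeded trials)."""
        model = PeakList([(10, 1.0, 0.0, 0.0), (40, 0.3, 0.0, 0.0)])
        grid = [{"lam": 1e-4}, {"lam": 1e-2}, {"lam": 1.0}, {"lam": 100.0}]

        def factory(lam):
            return lambda d: irls(d, IrlsConfig(p=1.0, lam=lam, n_iter=8))

        ratios = []
        for seed in range(10):
            fid = synth_fid(model, 64, noise_sigma=0.02, seed=seed + 50)
            truth = fft_spectrum(fid).values
            nus = restrict(fid, uniform_schedule(64, 32, seed))

            def err(lam):
                r = factory(lam)(nus)
                return np.linalg.norm(r.spectrum.values - truth)

            best, _ = cross_validate(nus, factory, grid, seed=seed)
            oracle_err = min(err(g["lam"]) for g in grid)
            ratios.append(err(best["lam"]) / oracle_err)
        assert np.median(ratios) <= 2.0


class TestReaddResidual:
    def test_identity_on_exact_recovery(self):
        model = PeakList([(10, 1.0, 0.0, 0.0)])
        fid = synth_fid(model, 64)
        nus = restrict(fid, uniform_schedule(64, 32, 0))
        r = omp(nus, GreedyConfig(epsilon=1e-12, max_iter=4, mode="omp"))
        out = readd_residual(r, nus)
        assert np.allclose(out.values, r.spectrum.values, atol=1e-10)

    def test_recovers_peak_missed_by_early_stop(self):
        model = PeakList([(10, 1.0, 0.0, 0.0), (40, 0.5, 0.0, 0.0)])
        fid = synth_fid(model, 64)
        nus = restrict(fid, uniform_schedule(64, 32, 1))
        r = omp(nus, GreedyConfig(epsilon=1e-12, max_iter=1, mode="omp"))
        out = readd_residual(r, nus)
        mags = np.abs(out.values)
        floor = np.max(np.delete(mags, [10, 40]))
        assert mags[40] > 3 * floor

    def test_data_domain_consistency(self, lorentzian_model):
        fid = synth_fid(lorentzian_model, 128)
        nus = restrict(fid, uniform_schedule(128, 48, 2))
        r = omp(nus, GreedyConfig(epsilon=1e-12, max_iter=5, mode="omp"))
        out = readd_residual(r, nus)
        back = np.fft.ifft(out.values, norm="ortho")
        assert np.max(np.abs(back[nus.schedule.indices] - nus.measured)) <= 1e-12
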