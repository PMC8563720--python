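import dataclasses

import numpy as np
import pytest

from flimfret.fitting import (
    BiFitImage,
    FitConfig,
    LifetimeMap,
    _Forward,
    estimate_tau0_donor_only,
    fit_bi,
    fit_image,
    fit_mono,
)
from flimfret.io import TcspcCube
from flimfret.models import (
    BiDecayParams,
    MonoDecayParams,
    convolve_with_irf,
)
from flimfret.phantom import generate_phantom, simulate_cube


def _mono_expected(tau, n_photons, irf, acq):
    """Expected counts for a mono decay scaled to a photon budget."""
    shape = convolve_with_irf(MonoDecayParams(amplitude=1.0, tau=tau), irf, acq)
    return shape / shape.sum() * n_photons


def _bi_expected(tau_f, tau0, a1_frac, n_photons, irf, acq):
    p = BiDecayParams(a1=a1_frac, a2=1 - a1_frac, tau_fret=tau_f, tau0=tau0)
    shape = convolve_with_irf(p, irf, acq)
    return shape / shape.sum() * n_photons


def _uniform_cube(tau, n_photons, shape2d, irf, acq, seed):
    expected = _mono_expected(tau, n_photons, irf, acq)
    lam = np.broadcast_to(expected[:, None, None], (acq.n_bins, *shape2d))
    counts = np.random.default_rng(seed).poisson(lam).astype(np.uint32)
    return TcspcCube(counts=counts, acq=acq)


class TestFitMono:
    def test_noiseless_recovery(self, delta_irf, acq):
        decay = _mono_expected(2.46, 5000, delta_irf, acq)
        fit = fit_mono(decay, delta_irf, acq, FitConfig())
        assert fit.converged
        assert fit.tau == pytest.approx(2.46, rel=1e-4)

    def test_noiseless_recovery_gaussian_irf(self, gauss_irf, acq):
        decay = _mono_expected(1.8, 5000, gauss_irf, acq)
        fit = fit_mono(decay, gauss_irf, acq, FitConfig())
        assert fit.tau == pytest.approx(1.8, rel=1e-4)

    def test_poisson_recovery_and_chi2(self, gauss_irf, acq):
        expected = _mono_expected(2.46, 5000, gauss_irf, acq)
        decay = np.random.default_rng(42).poisson(expected)
        fit = fit_mono(decay, gauss_irf, acq, FitConfig())
        assert fit.tau == pytest.approx(2.46, rel=0.02)
        assert 0.8 < fit.chi2_reduced < 1.2

    def test_below_threshold_masked(self, gauss_irf, acq):
        decay = np.zeros(acq.n_bins)
        decay[:10] = 1  # 10 total counts, threshold 30
        fit = fit_mono(decay, gauss_irf, acq, FitConfig(threshold_counts=30))
        assert not fit.fitted and not fit.converged
        assert np.isnan(fit.tau)

    def test_all_zero_masked(self, gauss_irf, acq):
        fit = fit_mono(np.zeros(acq.n_bins), gauss_irf, acq, FitConfig())
        assert not fit.fitted

    def test_wrong_length_rejected(self, gauss_irf, acq):
        with pytest.raises(ValueError):
            fit_mono(np.zeros(acq.n_bins + 1), gauss_irf, acq, FitConfig())

    def test_grid_search_oracle_equivalence(self, gauss_irf, acq):
        # brute-force grid over tau must agree with the optimizer
        step = 0.005
        grid = np.arange(1.0, 4.0, step)
        for tau_true in (1.8, 2.46, 3.1):
            decay = _mono_expected(tau_true, 8000, gauss_irf, acq)
            nll = []
            for tau in grid:
                mu = _mono_expected(tau, decay.sum(), gauss_irf, acq)
                nll.append(np.sum(mu) - np.sum(decay * np.log(mu)))
            tau_grid = grid[int(np.argmin(nll))]
            fit = fit_mono(decay, gauss_irf, acq, FitConfig())
            assert abs(fit.tau - tau_grid) <= step

    def test_estimator_consistency_sd_scaling(self, gauss_irf, acq):
        # SD of tau-hat shrinks like 1/sqrt(N); bias vanishes with N
        rng = np.random.default_rng(3)
        sds, biases = [], []
        for n_photons in (100, 1000, 10000):
            expected = _mono_expected(2.46, n_photons, gauss_irf, acq)
            taus = [
                fit_mono(rng.poisson(expected), gauss_irf, acq,
                         FitConfig(threshold_counts=0)).tau
                for _ in range(30)
            ]
            sds.append(np.std(taus))
            biases.append(abs(np.mean(taus) - 2.46))
        assert sds[0] > sds[1] > sds[2]
        # each decade of photons should shrink SD by ~sqrt(10)
        for hi, lo in zip(sds, sds[1:]):
            assert 1.5 < hi / lo < 7.0
        assert biases[2] < 0.02

    @pytest.mark.parametrize("seed", [11, 12, 13, 14, 15])
    def test_objectives_agree_at_high_counts(self, gauss_irf, acq, seed):
        expected = _mono_expected(2.3, 5000, gauss_irf, acq)
        decay = np.random.default_rng(seed).poisson(expected)
        mle = fit_mono(decay, gauss_irf, acq, FitConfig(objective="poisson_mle"))
        wls = fit_mono(decay, gauss_irf, acq,
                       FitConfig(objective="weighted_least_squares"))
        assert mle.tau == pytest.approx(wls.tau, rel=0.01)


class TestFitBi:
    def test_noiseless_recovery_free_tau0(self, delta_irf, acq):
        decay = _bi_expected(1.0, 2.47, 0.5, 20000, delta_irf, acq)
        fit = fit_bi(decay, delta_irf, acq, FitConfig(model="bi"))
        p = fit.params
        assert p.tau_fret == pytest.approx(1.0, rel=1e-3)
        assert p.tau0 == pytest.approx(2.47, rel=1e-3)
        assert p.a1_fraction == pytest.approx(0.5, abs=1e-3)
        assert not fit.collapsed

    def test_pure_mono_input_degenerates(self, gauss_irf, acq):
        decay = _mono_expected(2.47, 20000, gauss_irf, acq)
        fit = fit_bi(decay, gauss_irf, acq, FitConfig(model="bi"))
        assert fit.collapsed or fit.params.a1_fraction < 0.05 \
            or fit.delta_nll < 1.0

    def test_poisson_recovery_fixed_tau0(self, gauss_irf, acq):
        expected = _bi_expected(1.2, 2.47, 0.5, 10000, gauss_irf, acq)
        decay = np.random.default_rng(21).poisson(expected)
        fit = fit_bi(decay, gauss_irf, acq,
                     FitConfig(model="bi", fix_tau0=2.47))
        assert fit.params.tau0 == 2.47
        assert fit.params.tau_fret == pytest.approx(1.2, rel=0.05)

    def test_below_threshold_masked(self, gauss_irf, acq):
        decay = np.zeros(acq.n_bins)
        fit = fit_bi(decay, gauss_irf, acq, FitConfig(model="bi"))
        assert not fit.fitted

    def test_delta_nll_separates_models(self, gauss_irf, acq):
        mono = _mono_expected(2.47, 20000, gauss_irf, acq)
        bi = _bi_expected(0.9, 2.47, 0.5, 20000, gauss_irf, acq)
        f_mono = fit_bi(mono, gauss_irf, acq, FitConfig(model="bi", fix_tau0=2.47))
        f_bi = fit_bi(bi, gauss_irf, acq, FitConfig(model="bi", fix_tau0=2.47))
        assert f_bi.delta_nll > 100 * max(f_mono.delta_nll, 1e-6)


class TestFitImage:
    def test_threshold_contract(self, small_cfg, gauss_irf, acq):
        ph = generate_phantom("early", small_cfg, seed=1)
        cube = simulate_cube(ph, gauss_irf, acq, seed=2)
        cfg = FitConfig(threshold_counts=30, binning_factor=1)
        lmap = fit_image(cube, gauss_irf, cfg)
        from flimfret.fitting import _binned_counts

        binned_totals = _binned_counts(cube.counts, 1).sum(axis=0)
        expected_mask = binned_totals >= 30
        # mask is the threshold criterion minus any convergence failures
        assert np.all(expected_mask[lmap.mask])
        assert (expected_mask & ~lmap.mask).sum() <= 0.01 * expected_mask.sum()

    def test_threshold_monotonicity(self, small_cfg, gauss_irf, acq):
        ph = generate_phantom("late", small_cfg, seed=3)
        cube = simulate_cube(ph, gauss_irf, acq, seed=4)
        low = fit_image(cube, gauss_irf, FitConfig(threshold_counts=30))
        high = fit_image(cube, gauss_irf, FitConfig(threshold_counts=300))
        assert np.all(low.mask[high.mask])  # raising threshold never adds pixels

    def test_recovery_against_truth(self, small_cfg, gauss_irf, acq):
        ph = generate_phantom("early", small_cfg, seed=1)
        cube = simulate_cube(ph, gauss_irf, acq, seed=2)
        lmap = fit_image(cube, gauss_irf, FitConfig())
        sel = lmap.mask & ph.focus_mask
        w = lmap.intensity_map[sel]
        mean = np.average(lmap.tau_map[sel], weights=w)
        assert mean == pytest.approx(ph.truth_mean_tau(), abs=0.05)

    def test_chi2_calibration(self, gauss_irf, acq):
        cube = _uniform_cube(2.4, 1000, (24, 24), gauss_irf, acq, seed=5)
        lmap = fit_image(cube, gauss_irf, FitConfig(binning_factor=0))
        chi2 = lmap.chi2_map[lmap.mask]
        assert chi2.size >= 500
        assert 0.9 < chi2.mean() < 1.1

    def test_binning_reduces_variance(self, gauss_irf, acq):
        cube = _uniform_cube(2.4, 300, (20, 20), gauss_irf, acq, seed=6)
        v = {}
        for b in (0, 1):
            lmap = fit_image(cube, gauss_irf, FitConfig(binning_factor=b))
            inner = np.zeros((20, 20), dtype=bool)
            inner[2:-2, 2:-2] = True
            v[b] = np.var(lmap.tau_map[lmap.mask & inner])
        assert v[1] < v[0]

    def test_all_zero_cube_all_masked(self, gauss_irf, acq):
        counts = np.zeros((acq.n_bins, 8, 8), dtype=np.uint16)
        cube = TcspcCube(counts=counts, acq=acq)
        lmap = fit_image(cube, gauss_irf, FitConfig())
        assert not lmap.mask.any()
        assert np.all(np.isnan(lmap.tau_map))

    def test_bi_image_maps(self, small_cfg, gauss_irf, acq):
        from flimfret.phantom import generate_fret_phantom

        cfg = dataclasses.replace(small_cfg,
                                  n_foci={"early": 10, "mid": 5, "late": 5})
        ph = generate_fret_phantom("early", "late", cfg, seed=8,
                                   mode="simultaneous")
        cube = simulate_cube(ph, gauss_irf, acq, seed=9, photons_per_pixel=5000)
        bi = fit_image(cube, gauss_irf, FitConfig(model="bi", fix_tau0=2.47))
        assert isinstance(bi, BiFitImage)
        sel = bi.mask
        assert sel.any()
        # tau maps defined exactly on the mask
        assert np.array_equal(np.isfinite(bi.tau_fret_map), sel)
        assert np.all(bi.tau_fret_map[sel] <= bi.tau0_map[sel] + 1e-9)


class TestEstimateTau0:
    def _map(self, tau, intensity):
        tau = np.asarray(tau, dtype=float)
        mask = np.isfinite(tau)
        return LifetimeMap(
            tau_map=tau,
            mask=mask,
            chi2_map=np.full(tau.shape, np.nan),
            intensity_map=np.asarray(intensity, dtype=float),
        )

    def test_singleton(self):
        lmap = self._map([[2.47]], [[100.0]])
        assert estimate_tau0_donor_only(lmap) == 2.47

    def test_weighted_mean(self):
        # oracle: (2.0*100 + 3.0*300) / 400 = 2.75
        lmap = self._map([[2.0, 3.0]], [[100.0, 300.0]])
        assert estimate_tau0_donor_only(lmap) == pytest.approx(2.75)

    def test_empty_mask_raises(self):
        lmap = self._map([[np.nan]], [[0.0]])
        with pytest.raises(ValueError):
            estimate_tau0_donor_only(lmap)


class TestInvariants:
    def test_lifetime_map_definedness_contract(self):
        tau = np.array([[2.0, np.nan]])
        with pytest.raises(ValueError):
            LifetimeMap(
                tau_map=tau,
                mask=np.array([[True, True]]),
                chi2_map=np.full((1, 2), np.nan),
                intensity_map=np.ones((1, 2)),
            )

    def test_fit_config_validation(self):
        with pytest.raises(ValueError):
            FitConfig(model="tri")
        with pytest.raises(ValueError):
            FitConfig(threshold_counts=-1)
        with pytest.raises(ValueError):
            FitConfig(binning_factor=-1)
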