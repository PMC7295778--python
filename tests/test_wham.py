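"""WHAM solver tests: Boltzmann-inversion limit, oracle equivalence,
bootstrap behavior, 2D reweighting and barrier measurement."""

import numpy as np
import pytest
from scipy import stats

import porepmf as pp
from porepmf.constants import KB, kbt
from porepmf.wham import (ConvergenceError, DisconnectedSupportError,
                          UmbrellaWindow, _wham_iterate)

KT = kbt(303.15)


def _gauss_windows(rng, centers, k=30.0, n=400, temperature=303.15):
    """Windows sampled from the exact biased stationary Gaussian of a flat
    landscape (independent of the Brownian engine)."""
    sigma = np.sqrt(KB * temperature / k)
    return [UmbrellaWindow(center=c, force_constant=k,
                           samples_z=rng.normal(c, sigma, n),
                           temperature=temperature)
            for c in centers]


def naive_wham(windows, edges, n_iter=60_000):
    """Brute-force fixed-point WHAM: direct formulas, no log-space tricks.

    Independent oracle implementation for small inputs.
    """
    centers = 0.5 * (edges[:-1] + edges[1:])
    kt = KB * windows[0].temperature
    h = np.stack([np.histogram(w.samples_z, bins=edges)[0].astype(float)
                  for w in windows])
    n_i = h.sum(axis=1)
    w_ib = np.stack([0.5 * w.force_constant * (centers - w.center) ** 2
                     for w in windows])
    f = np.zeros(len(windows))
    for _ in range(n_iter):
        denom = np.sum(n_i[:, None] * np.exp((f[:, None] - w_ib) / kt), axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            rho = np.where(denom > 0, h.sum(axis=0) / denom, 0.0)
        f_new = -kt * np.log(np.sum(rho[None, :] * np.exp(-w_ib / kt), axis=1))
        f_new -= f_new[0]
        if np.max(np.abs(f_new - f)) < 1e-13:
            f = f_new
            break
        f = f_new
    with np.errstate(divide="ignore"):
        free = -kt * np.log(rho)
    return centers, free - np.nanmin(free[np.isfinite(free)]), f


class TestSolveWham:
    def test_unbiased_window_reduces_to_boltzmann_inversion(self):
        rng = np.random.default_rng(0)
        samples = rng.normal(22.0, 1.0, 5000)
        w = UmbrellaWindow(center=0.0, force_constant=0.0, samples_z=samples)
        edges = np.linspace(18, 26, 41)
        prof = pp.solve_wham([w], edges)
        counts, _ = np.histogram(samples, bins=edges)
        with np.errstate(divide="ignore"):
            expect = -KT * np.log(counts.astype(float))
        expect -= np.nanmin(expect[np.isfinite(expect)])
        sel = counts > 0
        assert np.allclose(prof.free_energy[sel], expect[sel], atol=1e-9)

    def test_duplicated_windows_leave_profile_unchanged(self):
        rng = np.random.default_rng(1)
        wins = _gauss_windows(rng, [20.0, 20.5, 21.0])
        edges = pp.default_grid(wins, 40)
        p1 = pp.solve_wham(wins, edges, tolerance=1e-10)
        p2 = pp.solve_wham(wins + wins, edges, tolerance=1e-10)
        sel = np.isfinite(p1.free_energy) & np.isfinite(p2.free_energy)
        assert np.allclose(p1.free_energy[sel], p2.free_energy[sel],
                           atol=1e-6)

    def test_matches_naive_fixed_point_oracle(self):
        rng = np.random.default_rng(2)
        wins = _gauss_windows(rng, [20.0, 20.6, 21.2], n=50)
        edges = np.linspace(18.5, 22.7, 22)
        prof = pp.solve_wham(wins, edges, tolerance=1e-12)
        centers, free_oracle, f_oracle = naive_wham(wins, edges)
        sel = np.isfinite(prof.free_energy) & np.isfinite(free_oracle)
        assert np.allclose(prof.free_energy[sel], free_oracle[sel], atol=1e-8)
        assert np.allclose(prof.window_free_energies, f_oracle, atol=1e-8)

    def test_bias_offset_invariance(self):
        # adding a constant energy to every window's bias must not move F(z)
        class OffsetWindow(UmbrellaWindow):
            def bias(self, z):
                return super().bias(z) + 7.3

        rng = np.random.default_rng(3)
        wins = _gauss_windows(rng, [20.0, 20.5, 21.0])
        off = [OffsetWindow(center=w.center, force_constant=w.force_constant,
                            samples_z=w.samples_z) for w in wins]
        edges = pp.default_grid(wins, 30)
        p1 = pp.solve_wham(wins, edges, tolerance=1e-10)
        p2 = pp.solve_wham(off, edges, tolerance=1e-10)
        sel = np.isfinite(p1.free_energy)
        assert np.allclose(p1.free_energy[sel], p2.free_energy[sel],
                           atol=1e-6)

    def test_disconnected_support_raises_named_gap(self):
        rng = np.random.default_rng(4)
        wins = _gauss_windows(rng, [18.0, 30.0])
        edges = np.linspace(16, 32, 81)
        with pytest.raises(DisconnectedSupportError, match="gap"):
            pp.solve_wham(wins, edges)

    def test_adjacent_windows_without_shared_bins_warn(self):
        rng = np.random.default_rng(5)
        wins = _gauss_windows(rng, [18.0, 20.0])
        edges = np.linspace(17.0, 21.0, 21)
        with pytest.warns(UserWarning, match="share no occupied bin"):
            try:
                pp.solve_wham(wins, edges)
            except DisconnectedSupportError:
                pass

    def test_nonconvergence_carries_residual(self):
        rng = np.random.default_rng(6)
        wins = _gauss_windows(rng, [20.0, 20.5])
        edges = pp.default_grid(wins, 20)
        with pytest.raises(ConvergenceError) as err:
            pp.solve_wham(wins, edges, max_iter=0)
        assert err.value.residual == np.inf or err.value.residual > 0


class TestBootstrap:
    def test_identical_windows_have_zero_sem(self):
        rng = np.random.default_rng(7)
        base = _gauss_windows(rng, [20.5], n=2000)[0]
        wins = [UmbrellaWindow(center=20.5, force_constant=30.0,
                               samples_z=base.samples_z) for _ in range(5)]
        edges = pp.default_grid(wins, 20)
        sem = pp.bootstrap_pmf(wins, edges, B=20, seed=1)
        assert np.nanmax(sem[np.isfinite(sem)]) < 1e-10

    def test_fixed_seed_reproducible(self):
        rng = np.random.default_rng(8)
        wins = _gauss_windows(rng, [20.0, 20.5, 21.0])
        edges = pp.default_grid(wins, 25)
        s1 = pp.bootstrap_pmf(wins, edges, B=30, seed=5)
        s2 = pp.bootstrap_pmf(wins, edges, B=30, seed=5)
        assert np.array_equal(s1, s2)

    def test_too_few_replicates_rejected(self):
        rng = np.random.default_rng(9)
        wins = _gauss_windows(rng, [20.0])
        with pytest.raises(ValueError):
            pp.bootstrap_pmf(wins, pp.default_grid(wins, 10), B=1, seed=0)

    def test_sem_ranks_agree_with_jackknife_oracle(self, default_run):
        """Bootstrap per-bin SEM orders bins like leave-one-window-out
        jackknife, and edge bins (fewest covering windows) are noisier than
        plateau bins."""
        windows = default_run["windows"]
        grid = default_run["grid"]
        prof = default_run["profile"]
        kt = KT
        full = prof.free_energy
        n = len(windows)
        reps = []
        for i in range(0, n, 4):  # thinned jackknife, still 26 replicates
            sub = windows[:i] + windows[i + 1:]
            p = pp.solve_wham(sub, grid, tolerance=1e-8,
                              f_init=np.delete(prof.window_free_energies, i))
            reps.append(p.free_energy)
        reps = np.array(reps)
        jack = np.nanstd(reps, axis=0, ddof=1)
        sel = np.isfinite(jack) & np.isfinite(prof.sem)
        rho = stats.spearmanr(jack[sel], prof.sem[sel]).statistic
        assert rho > 0.5
        interior = prof.sem[10:90]
        edges_sem = np.concatenate([prof.sem[:3], prof.sem[-3:]])
        assert np.median(edges_sem) > np.median(interior)

    def test_more_samples_shrink_per_sample_bootstrap_sem(self):
        rng = np.random.default_rng(10)
        small = _gauss_windows(rng, [20.0, 20.5, 21.0], n=200)
        big = [UmbrellaWindow(center=w.center, force_constant=w.force_constant,
                              samples_z=np.concatenate(
                                  [w.samples_z,
                                   rng.normal(w.center,
                                              np.sqrt(KT / 30.0), 600)]))
               for w in small]
        edges = np.linspace(19.2, 21.8, 21)
        s_small = pp.bootstrap_pmf(small, edges, B=60, seed=2,
                                   resample="samples")
        s_big = pp.bootstrap_pmf(big, edges, B=60, seed=2,
                                 resample="samples")
        sel = np.isfinite(s_small) & np.isfinite(s_big)
        assert np.median(s_big[sel]) < np.median(s_small[sel])


class TestReweight2D:
    def test_constant_aux_collapses_to_single_bin(self):
        rng = np.random.default_rng(11)
        wins = _gauss_windows(rng, [20.0, 20.5, 21.0], n=500)
        for w in wins:
            w.samples_aux = np.full(w.n_samples, 6.0)
        edges = pp.default_grid(wins, 25)
        prof = pp.solve_wham(wins, edges, tolerance=1e-10)
        n_grid = np.arange(0, 10.5, 1.0)
        pmf2 = pp.reweight_2d(wins, prof.window_free_energies, edges, n_grid)
        occupied_cols = np.flatnonzero(pmf2.visited.any(axis=0))
        assert occupied_cols.tolist() == [6]  # the bin holding n = 6
        col = pmf2.free_energy[:, 6]
        sel = np.isfinite(col) & np.isfinite(prof.free_energy)
        assert np.allclose(col[sel], prof.free_energy[sel], atol=1e-6)

    def test_missing_aux_rejected(self):
        rng = np.random.default_rng(12)
        wins = _gauss_windows(rng, [20.0, 20.5])
        edges = pp.default_grid(wins, 10)
        prof = pp.solve_wham(wins, edges)
        with pytest.raises(ValueError, match="aux"):
            pp.reweight_2d(wins, prof.window_free_energies, edges,
                           np.arange(0, 10, 1.0))

    def test_valley_tracks_programmed_coordination_dip(self, default_run):
        prof = default_run["profile"]
        pmf2 = pp.reweight_2d(default_run["windows"],
                              prof.window_free_energies,
                              default_run["grid"],
                              np.arange(0.0, 10.0 + 1e-9, 0.25))
        spec = default_run["spec"]

        def valley_n(z):
            iz = np.argmin(np.abs(pmf2.z_centers - z))
            return pmf2.n_centers[np.argmin(pmf2.free_energy[iz])]

        assert valley_n(spec.barrier_center_z) < valley_n(17.5) - 1.5


class TestBarrierHeight:
    def _profile(self, f):
        z = np.linspace(16.5, 36.5, 201)  # includes z = 22.0 exactly
        return pp.PMFProfile(bin_centers=z, free_energy=f(z))

    def test_flat_profile_zero_barrier(self):
        prof = self._profile(lambda z: np.zeros_like(z))
        h, _ = pp.barrier_height(prof, (19, 25), (16.5, 18.5))
        assert h == pytest.approx(0.0)

    def test_analytic_gaussian_barrier_recovered_exactly(self):
        prof = self._profile(
            lambda z: 6.0 * np.exp(-((z - 22.0) ** 2) / (2 * 1.5 ** 2)))
        h, _ = pp.barrier_height(prof, (19, 25), (33, 36.5))
        assert h == pytest.approx(6.0, abs=1e-6)

    def test_range_outside_support_rejected(self):
        prof = self._profile(lambda z: np.zeros_like(z))
        with pytest.raises(ValueError):
            pp.barrier_height(prof, (50, 60), (16.5, 18.5))
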