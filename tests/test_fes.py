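"""Free-energy reconstruction: grids, estimators, barriers, uncertainty."""

import numpy as np
import pytest

from sookit import fes, surfaces
from sookit.constants import KBT_310
from sookit.fes import (
    FreeEnergyLandscape,
    WindowSet,
    block_uncertainty,
    make_umbrella_grid,
    mbar_fes,
    path_barrier,
    variational_profile,
    wham2d,
)
from sookit.surfaces import (
    BiasedTrajectory,
    GaussianComponent,
    ModelSurface,
    RestraintWindow,
    make_surface,
    sample_window,
    sample_windows,
)


def flat_surface():
    return ModelSurface(components=(), confinement_k=0.0, label="flat")


class TestUmbrellaGrid:
    def test_13_per_axis_gives_169_windows(self):
        wins = make_umbrella_grid(((-1, 1), (-1, 1)), 13)
        assert len(wins) == 169
        assert wins[0].force_constants == (200.0, 200.0)

    def test_corners_of_unit_square(self):
        wins = make_umbrella_grid(((0, 1), (0, 1)), 2)
        centers = sorted(w.center for w in wins)
        assert centers == [(0, 0), (0, 1), (1, 0), (1, 1)]

    def test_three_per_axis_lattice(self):
        wins = make_umbrella_grid(((0, 1), (0, 1)), 3)
        xs = sorted({w.center[0] for w in wins})
        assert xs == [0.0, 0.5, 1.0]

    def test_degenerate_bounds_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            make_umbrella_grid(((0, 0), (0, 1)), 3)
        with pytest.raises(ValueError):
            make_umbrella_grid(((0, 1), (0, 1)), 1)


class TestWham:
    def test_single_window_recovers_harmonic_curvature(self):
        from scipy import ndimage

        k_s = 100.0
        surf = make_surface("harmonic-well", k=k_s)
        w = RestraintWindow(center=(0.0, 0.0), force_constants=(100.0, 100.0))
        traj = sample_window(surf, w, 50_000, seed=14)
        land = wham2d([traj], bins=25)
        gx, gy = np.meshgrid(land.x_centers, land.y_centers, indexing="ij")
        # drop the occupancy boundary: bins that barely pass the count
        # threshold are upward count fluctuations with downward-biased F
        interior = ndimage.binary_erosion(land.occupied, iterations=2)
        r2 = (gx**2 + gy**2)[interior]
        f = land.values[interior]
        slope = np.polyfit(r2 / 2.0, f, 1)[0]
        assert slope == pytest.approx(k_s, rel=0.05)

    def test_two_overlapping_windows_on_flat_surface(self):
        surf = flat_surface()
        sigma = np.sqrt(KBT_310 / 200.0)
        wins = [RestraintWindow(center=(c, 0.0),
                                force_constants=(200.0, 200.0))
                for c in (-sigma / 2, sigma / 2)]
        trajs = sample_windows(surf, wins, 30_000, seed=3)
        land = wham2d(trajs, bins=15)
        unc = block_uncertainty(trajs, "wham", n_boot=15, bins=15, seed=0)
        vals = land.values[land.occupied]
        # deviation from the mean level (min-referencing biases the raw
        # values upward); flat within ~2 SE for the bulk of bins, with
        # multiple-comparison headroom on the max
        spread = np.abs(vals - vals.mean())
        err = unc.uncertainty[land.occupied]
        assert np.mean(spread <= 2.0 * err + 0.02) > 0.8
        assert np.all(spread <= 4.0 * err + 0.05)

    def test_disconnected_windows_error_names_components(self):
        surf = flat_surface()
        wins = [RestraintWindow(center=(c, 0.0),
                                force_constants=(200.0, 200.0))
                for c in (-5.0, 5.0)]
        trajs = sample_windows(surf, wins, 500, seed=1)
        with pytest.raises(ValueError, match="disconnected.*\\[0\\].*\\[1\\]"):
            wham2d(trajs)

    def test_reference_bin_is_zero_and_unoccupied_flagged(self, pcet_landscapes):
        for land in pcet_landscapes.values():
            occ_vals = land.values[land.occupied]
            assert occ_vals.min() == pytest.approx(0.0, abs=1e-12)
            assert np.isnan(land.values[~land.occupied]).all()


class TestMbar:
    def test_window_order_permutation_invariance(self):
        surf = make_surface("harmonic-well", k=20.0)
        wins = [RestraintWindow(center=(c, 0.0),
                                force_constants=(100.0, 100.0))
                for c in (-0.1, 0.0, 0.1)]
        trajs = sample_windows(surf, wins, 3000, seed=5)
        edges = fes._auto_edges(trajs, 30)
        a = mbar_fes(trajs, edges=edges)
        b = mbar_fes(trajs[::-1], edges=edges)
        assert np.allclose(a.values, b.values, atol=1e-6, equal_nan=True)

    def test_single_window_equals_reweighted_histogram(self):
        surf = make_surface("harmonic-well", k=50.0)
        w = RestraintWindow(center=(0.1, -0.1), force_constants=(80.0, 80.0))
        traj = sample_window(surf, w, 20_000, seed=17)
        edges = fes._auto_edges([traj], 25)
        land = mbar_fes([traj], edges=edges)
        # independent reweighting: F_b = -kBT ln sum_in-bin exp(+bias/kBT)
        ix = np.searchsorted(edges[0], traj.samples[:, 0], side="right") - 1
        iy = np.searchsorted(edges[1], traj.samples[:, 1], side="right") - 1
        logw = w.bias_energy(traj.samples) / KBT_310
        ref = np.full((25, 25), np.nan)
        for b in range(25 * 25):
            sel = (ix == b // 25) & (iy == b % 25)
            if sel.sum() >= fes.DEFAULT_MIN_COUNT:
                m = logw[sel].max()
                ref[b // 25, b % 25] = -KBT_310 * (
                    m + np.log(np.exp(logw[sel] - m).sum()))
        ref -= np.nanmin(ref)
        both = land.occupied & ~np.isnan(ref)
        assert np.allclose(land.values[both], ref[both], atol=1e-9)

    def test_compressed_solver_matches_exact(self):
        surf = make_surface("harmonic-well", k=30.0)
        wins = [RestraintWindow(center=(c, 0.0),
                                force_constants=(120.0, 120.0))
                for c in (-0.15, 0.0, 0.15)]
        trajs = sample_windows(surf, wins, 4000, seed=23)
        edges = fes._auto_edges(trajs, 40)
        exact = mbar_fes(trajs, edges=edges, compress_threshold=1e12)
        compressed = mbar_fes(trajs, edges=edges, compress_threshold=1)
        both = exact.occupied & compressed.occupied
        assert np.abs(exact.values[both] - compressed.values[both]).max() < 0.05


class TestVariational:
    def test_under_determined_basis_rejected(self):
        surf = make_surface("harmonic-well", k=50.0)
        w = RestraintWindow(center=(0.0, 0.0), force_constants=(100.0, 100.0))
        traj = sample_window(surf, w, 2000, seed=2)
        with pytest.raises(ValueError, match="under-determined"):
            variational_profile([traj], bins=20, basis=(40, 40))

    def test_coarse_basis_smooths_but_tracks_wham(self):
        surf = make_surface("harmonic-well", k=50.0)
        wins = [RestraintWindow(center=(c, 0.0),
                                force_constants=(100.0, 100.0))
                for c in (-0.1, 0.1)]
        trajs = sample_windows(surf, wins, 10_000, seed=31)
        edges = fes._auto_edges(trajs, 30)
        smooth = variational_profile(trajs, edges=edges, basis=(12, 12))
        ref = wham2d(trajs, edges=edges)
        both = smooth.occupied & ref.occupied
        assert np.abs(smooth.values[both] - ref.values[both]).max() < 0.5


class TestConstantOffsetInvariance:
    def test_adding_constant_to_surface_leaves_landscape_unchanged(self):
        base = make_surface("harmonic-well", k=60.0)
        shifted = ModelSurface(
            components=base.components + (GaussianComponent(
                amplitude=123.4, center=(0.0, 0.0),
                quad=((0.0, 0.0), (0.0, 0.0))),),
            confinement_k=base.confinement_k, label="shifted")
        w = RestraintWindow(center=(0.0, 0.0), force_constants=(100.0, 100.0))
        a = sample_window(base, w, 5000, seed=7)
        b = sample_window(shifted, w, 5000, seed=7)
        assert np.array_equal(a.samples, b.samples)
        ea = fes._auto_edges([a], 30)
        assert np.allclose(wham2d([a], edges=ea).values,
                           wham2d([b], edges=ea).values, equal_nan=True)


class TestPathBarrier:
    def make_flat_landscape(self, value=0.0):
        edges = np.linspace(-1, 1, 21)
        vals = np.full((20, 20), value)
        return FreeEnergyLandscape(x_edges=edges, y_edges=edges, values=vals,
                                   occupied=np.ones((20, 20), bool),
                                   estimator="test")

    def test_flat_landscape_zero_barrier(self):
        land = self.make_flat_landscape()
        path = np.stack([np.linspace(-0.8, 0.8, 50)] * 2, axis=1)
        assert path_barrier(land, path) == (0.0, 0.0)

    def test_monotone_ramp_barrier_equals_delta_g(self):
        edges = np.linspace(-1, 1, 41)
        centers = 0.5 * (edges[:-1] + edges[1:])
        vals = np.tile(5.0 * (centers - centers[0])[:, None], (1, 40))
        land = FreeEnergyLandscape(x_edges=edges, y_edges=edges, values=vals,
                                   occupied=np.ones((40, 40), bool),
                                   estimator="test")
        # path runs between bin centers; a tight basin radius makes the
        # endpoint bins themselves the basins
        path = np.stack([np.linspace(-0.925, 0.925, 100),
                         np.zeros(100)], axis=1)
        barrier, dg = path_barrier(land, path, basin_radius=0.04)
        assert barrier == pytest.approx(dg, rel=1e-6)
        assert dg > 0

    def test_path_through_unoccupied_bins_rejected(self):
        land = self.make_flat_landscape()
        land.values[10, :] = np.nan
        land.occupied[10, :] = False
        path = np.stack([np.linspace(-0.8, 0.8, 50)] * 2, axis=1)
        with pytest.raises(ValueError, match="unoccupied"):
            path_barrier(land, path)


class TestBlockUncertainty:
    def test_zero_variance_samples_give_zero_uncertainty(self):
        w = RestraintWindow(center=(0.0, 0.0), force_constants=(100.0, 100.0))
        samples = np.zeros((100, 2))
        traj = BiasedTrajectory(window=w, samples=samples, seed=0,
                                step_size=1e-3)
        unc = block_uncertainty([traj], "wham", n_boot=8, bins=10, seed=1)
        assert np.nanmax(unc.uncertainty) == pytest.approx(0.0, abs=1e-12)

    def test_uncertainty_shrinks_with_sample_size(self):
        surf = make_surface("harmonic-well", k=50.0)
        w = RestraintWindow(center=(0.0, 0.0), force_constants=(100.0, 100.0))
        small = sample_window(surf, w, 4000, seed=3)
        big = sample_window(surf, w, 64_000, seed=4)
        edges = fes._auto_edges([big], 20)
        u_small = block_uncertainty([small], "wham", n_boot=25, seed=2,
                                    edges=edges)
        u_big = block_uncertainty([big], "wham", n_boot=25, seed=2,
                                  edges=edges)
        both = u_small.occupied & u_big.occupied
        ratio = (np.nanmedian(u_small.uncertainty[both])
                 / np.nanmedian(u_big.uncertainty[both]))
        # 16x the data: errors should shrink ~4x
        assert 2.0 < ratio < 8.0

    def test_seeded_bootstrap_reproducible(self):
        surf = make_surface("harmonic-well", k=50.0)
        w = RestraintWindow(center=(0.0, 0.0), force_constants=(100.0, 100.0))
        traj = sample_window(surf, w, 3000, seed=3)
        a = block_uncertainty([traj], "wham", n_boot=10, bins=15, seed=9)
        b = block_uncertainty([traj], "wham", n_boot=10, bins=15, seed=9)
        assert np.allclose(a.uncertainty, b.uncertainty, equal_nan=True)


class TestWindowSet:
    def test_mixed_temperatures_rejected(self):
        w1 = RestraintWindow(center=(0, 0), temperature=310.0)
        w2 = RestraintWindow(center=(0, 0), temperature=300.0)
        t1 = BiasedTrajectory(w1, np.zeros((10, 2)), 0, 1e-3)
        t2 = BiasedTrajectory(w2, np.zeros((10, 2)), 0, 1e-3)
        with pytest.raises(ValueError, match="temperature"):
            WindowSet([t1, t2])

    def test_overlap_matrix_diagonal_is_one(self, pcet_window_trajs):
        ws = WindowSet(pcet_window_trajs[:5])
        m = ws.overlap_matrix(bins=40)
        assert np.allclose(np.diag(m), 1.0)
        assert m[0, 1] > 0  # neighbours along the string overlap
        assert m[0, 4] < m[0, 1]
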