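"""String construction, reparameterization, drift and convergence."""

import numpy as np
import pytest
from scipy.integrate import quad

from sookit import string_method as sm, surfaces, topology
from sookit.string_method import (
    ConvergenceRecord,
    StringPath,
    check_convergence,
    estimate_drift,
    init_path,
    refit_path,
    reparameterize,
    run_string,
)
from sookit.surfaces import RestraintWindow, make_surface


class TestInitPath:
    def test_straight_segment_is_linear_interpolation(self):
        path = init_path((0, 0), (1, 1), 5)
        expected = np.stack([np.linspace(0, 1, 5)] * 2, axis=1)
        assert np.allclose(path.nodes, expected)

    def test_polyline_via_corner_has_equal_spacing(self):
        path = init_path((0, 0), (1, 1), 19, via=(1, 0))
        seg = np.linalg.norm(np.diff(path.nodes, axis=0), axis=1)
        assert np.allclose(seg, 2.0 / 18.0, atol=1e-12)
        assert np.allclose(path.nodes[0], (0, 0))
        assert np.allclose(path.nodes[-1], (1, 1))

    def test_diagonal_total_length(self):
        path = init_path((-0.8, -0.8), (0.8, 0.8), 12)
        assert path.total_length() == pytest.approx(2 * np.sqrt(2) * 0.8)

    def test_invalid_endpoints_rejected(self):
        with pytest.raises(ValueError, match="distinct"):
            init_path((0.5, 0.5), (0.5, 0.5), 8)
        with pytest.raises(ValueError):
            init_path((0, 0), (1, 1), 3)


class TestReparameterize:
    def test_straight_segment_uniform_spacing(self):
        curve = lambda t: np.stack([np.atleast_1d(t) * 3.0,
                                    np.atleast_1d(t) * 4.0], axis=1)
        nodes = reparameterize(curve, 6)
        seg = np.linalg.norm(np.diff(nodes, axis=0), axis=1)
        assert np.allclose(seg, 1.0, atol=1e-6)

    def test_parabola_arclengths_match_closed_form(self):
        # y = x^2 on [0, 1]; arclength element sqrt(1 + 4x^2)
        curve = lambda t: np.stack([np.atleast_1d(t),
                                    np.atleast_1d(t) ** 2], axis=1)
        n = 11
        nodes = reparameterize(curve, n)
        total = quad(lambda x: np.sqrt(1 + 4 * x * x), 0, 1)[0]
        for i, node in enumerate(nodes):
            partial = quad(lambda x: np.sqrt(1 + 4 * x * x), 0, node[0])[0]
            assert partial == pytest.approx(total * i / (n - 1), abs=1e-4)

    def test_endpoints_preserved_exactly(self):
        curve = lambda t: np.stack([np.cos(np.atleast_1d(t)),
                                    np.sin(np.atleast_1d(t)) ** 3], axis=1)
        nodes = reparameterize(curve, 9)
        assert np.array_equal(nodes[0], curve(0.0)[0])
        assert np.array_equal(nodes[-1], curve(1.0)[0])

    def test_nonfinite_curve_rejected(self):
        bad = lambda t: np.full((np.atleast_1d(t).size, 2), np.nan)
        with pytest.raises(ValueError, match="non-finite"):
            reparameterize(bad, 5)


class TestRefit:
    def test_zero_drift_straight_path_is_fixed_point(self):
        path = init_path((0, 0), (1, 1), 9)
        new, resid = refit_path(path, np.zeros((9, 2)))
        assert np.abs(new.nodes - path.nodes).max() < 1e-9
        assert resid == 0.0

    def test_quarter_circle_nodes_at_equal_angles(self):
        theta = np.linspace(0, np.pi / 2, 13)
        nodes = np.stack([np.cos(theta), np.sin(theta)], axis=1)
        path = StringPath(nodes=nodes, fit_mode="spline")
        new, _ = refit_path(path, np.zeros_like(nodes))
        angles = np.arctan2(new.nodes[:, 1], new.nodes[:, 0])
        assert np.allclose(np.diff(angles), np.pi / 2 / 12, atol=1e-3)

    def test_polynomial_and_spline_modes_agree(self):
        # gentle arc: both interpolation schemes give similar strings
        t = np.linspace(0, 1, 12)
        nodes = np.stack([t, 0.2 * np.sin(np.pi * t)], axis=1)
        drifts = np.zeros_like(nodes)
        spline, _ = refit_path(StringPath(nodes, fit_mode="spline"), drifts)
        poly, _ = refit_path(StringPath(nodes, fit_mode="poly4"), drifts)
        assert np.abs(spline.nodes - poly.nodes).max() < 0.05

    def test_quartic_needs_five_nodes(self):
        nodes = np.stack([np.linspace(0, 1, 4)] * 2, axis=1)
        with pytest.raises(ValueError, match="at least 5"):
            refit_path(StringPath(nodes, fit_mode="poly4"),
                       np.zeros_like(nodes))


class TestDrift:
    def test_node_at_minimum_has_negligible_drift(self, pcet_surface,
                                                  pcet_oracle,
                                                  window_template):
        nodes = np.tile(pcet_oracle["reactant"].point, (4, 1))
        nodes += np.linspace(0, 1e-4, 4)[:, None]  # nearly degenerate
        path = StringPath(nodes)
        drift = estimate_drift(path, pcet_surface, window_template, seed=3,
                               pin_endpoints=False)
        assert np.linalg.norm(drift, axis=1).max() < 0.02

    def test_harmonic_wall_drift_closed_form(self):
        # node 0.2 A up a harmonic wall: drift = -ks*x/(ks+kr)
        k_s, k_r = 100.0, 200.0
        surf = make_surface("harmonic-well", k=k_s)
        nodes = np.array([[0.2, 0.0]] * 4) + np.linspace(0, 1e-6, 4)[:, None]
        tmpl = RestraintWindow(center=(0, 0), force_constants=(k_r, k_r),
                               n_steps=150)
        path = StringPath(nodes)
        expected = -k_s * 0.2 / (k_s + k_r)
        quad_drift = estimate_drift(path, surf, tmpl, seed=0,
                                    mode="quadrature", pin_endpoints=False)
        assert quad_drift[:, 0] == pytest.approx(expected, abs=1e-4)
        sampled = estimate_drift(path, surf, tmpl, seed=8, mode="sample",
                                 pin_endpoints=False)
        assert sampled[:, 0].mean() == pytest.approx(expected, abs=0.01)

    def test_saddle_node_tangential_drift_vanishes(self, pcet_surface,
                                                   pcet_oracle,
                                                   window_template):
        saddle = pcet_oracle["saddle"].point
        nodes = np.array([saddle - 0.3, saddle, saddle + 0.3])
        nodes = np.vstack([nodes, saddle + 0.45])
        drift = estimate_drift(StringPath(nodes), pcet_surface,
                               window_template, seed=0, mode="quadrature",
                               pin_endpoints=False)
        tangent = np.array([1.0, 1.0]) / np.sqrt(2)
        assert abs(drift[1] @ tangent) < 5e-3

    def test_out_of_range_force_constant_warns(self, pcet_surface):
        path = init_path((-0.5, -0.5), (0.5, 0.5), 5)
        tmpl = RestraintWindow(center=(0, 0), force_constants=(500.0, 500.0),
                               n_steps=50)
        with pytest.warns(UserWarning, match="50-200"):
            estimate_drift(path, pcet_surface, tmpl, seed=0)


class TestConvergenceRule:
    def make_record(self, ssq, max_dev=None):
        rec = ConvergenceRecord()
        for s, m in zip(ssq, max_dev or ssq):
            rec.append(s, m)
        return rec

    def test_three_small_changes_converge(self):
        assert check_convergence(self.make_record([0.001, 0.001, 0.001]))

    def test_spike_in_last_three_blocks_convergence(self):
        assert not check_convergence(
            self.make_record([0.001, 0.009, 0.001]))

    def test_zero_tail_converges(self):
        assert check_convergence(self.make_record([0.5, 0.0, 0.0, 0.0]))

    def test_max_deviation_threshold_applies_separately(self):
        rec = self.make_record([0.001] * 3, max_dev=[0.06, 0.001, 0.001])
        assert not check_convergence(rec)
        rec2 = self.make_record([0.001] * 3, max_dev=[0.04] * 3)
        assert check_convergence(rec2)

    def test_too_short_history(self):
        assert not check_convergence(self.make_record([0.0, 0.0]))
        with pytest.raises(ValueError):
            check_convergence(ConvergenceRecord())

    def test_negative_metrics_rejected(self):
        rec = ConvergenceRecord()
        with pytest.raises(ValueError):
            rec.append(-0.1, 0.0)


class TestRunString:
    def test_degenerate_path_at_minimum_converges_quickly(self):
        surf = make_surface("harmonic-well", k=50.0)
        nodes = np.zeros((6, 2))
        tmpl = RestraintWindow(center=(0, 0), force_constants=(200.0, 200.0),
                               n_steps=150)
        path, rec = run_string(surf, StringPath(nodes), tmpl, seed=4)
        assert rec.converged and rec.n_iterations <= 3
        # within sampling noise of a single point at the minimum
        assert np.abs(path.nodes).max() < 0.1
        exact, rec_q = run_string(surf, StringPath(nodes), tmpl, seed=4,
                                  drift_mode="quadrature")
        assert rec_q.converged and np.abs(exact.nodes).max() < 1e-6

    def test_endpoints_and_node_count_preserved(self, pcet_surface,
                                                pcet_string, pcet_oracle):
        assert pcet_string.n_nodes == 19
        assert np.allclose(pcet_string.nodes[0],
                           pcet_oracle["reactant"].point, atol=1e-9)
        assert np.allclose(pcet_string.nodes[-1],
                           pcet_oracle["product"].point, atol=1e-9)

    def test_mep_is_fixed_point_of_noiseless_iteration(self, pcet_surface,
                                                       pcet_oracle):
        """A steepest-descent MEP is invariant under one quadrature
        iteration once the restraint dominates the surface curvature."""
        mep = topology.steepest_descent_path(pcet_surface,
                                             pcet_oracle["saddle"].point)
        idx = np.linspace(0, len(mep) - 1, 600).astype(int)
        curve_pts = mep[idx]
        seg = np.linalg.norm(np.diff(curve_pts, axis=0), axis=1)
        cum = np.concatenate([[0], np.cumsum(seg)])
        targets = np.linspace(0, cum[-1], 15)
        nodes = np.stack([np.interp(targets, cum, curve_pts[:, 0]),
                          np.interp(targets, cum, curve_pts[:, 1])], axis=1)
        path = StringPath(nodes)
        tmpl = RestraintWindow(center=(0, 0),
                               force_constants=(5000.0, 5000.0), n_steps=1)
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            drift = estimate_drift(path, pcet_surface, tmpl, seed=0,
                                   mode="quadrature")
        new_path, _ = refit_path(path, drift)
        assert np.abs(new_path.nodes - path.nodes).max() < 1e-3

    def test_distinct_initial_paths_yield_distinct_strings(self, pcet_surface,
                                                           pcet_oracle,
                                                           window_template):
        start = pcet_oracle["reactant"].point
        end = pcet_oracle["product"].point
        paths = {}
        for label, via in (("upper", (-0.8, 0.8)), ("lower", (0.8, -0.8))):
            p0 = init_path(start, end, 19, via=via)
            path, rec = run_string(pcet_surface, p0, window_template,
                                   seed=6, drift_mode="quadrature")
            assert rec.converged
            paths[label] = path
        gap = np.linalg.norm(paths["upper"].nodes - paths["lower"].nodes,
                             axis=1).max()
        assert gap > 1.0  # locally converged, genuinely different channels

    def test_ssq_change_trend_is_nonincreasing(self, mb_surface, mb_oracle):
        p0 = init_path(mb_oracle["minima"]["A"], mb_oracle["minima"]["C"], 25,
                       via=mb_oracle["minima"]["B"])
        tmpl = RestraintWindow(center=(0, 0),
                               force_constants=(1000.0, 1000.0), n_steps=150)
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            _, rec = run_string(mb_surface, p0, tmpl, seed=0,
                                drift_mode="quadrature")
        ssq = np.array(rec.ssq_change)
        assert np.all(np.diff(ssq[2:]) <= ssq[2:-1] * 0.05 + 1e-12)

    def test_nonconvergence_reported_not_raised(self, pcet_surface,
                                                window_template):
        p0 = init_path((-0.78, -0.78), (0.77, 0.77), 12)
        path, rec = run_string(pcet_surface, p0, window_template,
                               max_iterations=1, seed=0)
        assert not rec.converged
        assert rec.n_iterations == 1
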