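"""Unbiased 2D free-energy landscapes from umbrella-window samples.

Three estimators reconstruct F(RC1, RC2) in kcal/mol from harmonically
biased samples:

``wham2d``
    Self-consistent weighted-histogram analysis on a shared 2D grid.
    The per-window bias Boltzmann factor is averaged analytically over
    each bin (Gaussian mass via erf), which removes most of the
    bin-discretization bias relative to sample-based estimators.
``mbar_fes``
    Multistate Bennett acceptance ratio on per-sample bias energies,
    followed by weighted histogramming of the unbiased sample weights.
``variational_profile``
    Maximum-likelihood free-energy field given all biased samples, with
    the field parameterized on a (possibly coarser) control grid and
    bilinearly interpolated to the histogram grid.

All estimators reference the minimum occupied bin to zero and flag
unoccupied bins (NaN) rather than silently zeroing them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Optional, Sequence, Union

import numpy as np
from scipy.optimize import minimize
from scipy.special import log_ndtr, logsumexp

from .constants import kbt
from .surfaces import BiasedTrajectory, RestraintWindow
from .string_method import StringPath, dense_curve

DEFAULT_BINS = 100
DEFAULT_MIN_COUNT = 10
DEFAULT_FORCE_CONSTANT = 200.0
BASIN_RADIUS = 0.3  # Å, basin search radius around path endpoints


@dataclass
class WindowSet:
    """A collection of biased trajectories sharing one temperature."""

    windows: list  # list[BiasedTrajectory]

    def __post_init__(self) -> None:
        if not self.windows:
            raise ValueError("empty window set")
        temps = {w.window.temperature for w in self.windows}
        if len(temps) > 1:
            raise ValueError(f"windows must share temperature, got {sorted(temps)}")

    def __iter__(self):
        return iter(self.windows)

    def __len__(self) -> int:
        return len(self.windows)

    @property
    def temperature(self) -> float:
        return self.windows[0].window.temperature

    def overlap_matrix(self, bins: int = DEFAULT_BINS) -> np.ndarray:
        """Fraction of occupied bins shared between window pairs."""
        edges = _auto_edges(self.windows, bins)
        occ = [_histogram(w.samples, edges) > 0 for w in self.windows]
        n = len(occ)
        out = np.zeros((n, n))
        for i in range(n):
            for j in range(n):
                union = np.logical_or(occ[i], occ[j]).sum()
                inter = np.logical_and(occ[i], occ[j]).sum()
                out[i, j] = inter / union if union else 0.0
        return out


def _as_windows(windows: Union[WindowSet, Sequence[BiasedTrajectory]]) -> WindowSet:
    return windows if isinstance(windows, WindowSet) else WindowSet(list(windows))


@dataclass
class FreeEnergyLandscape:
    """Gridded 2D free energy (kcal/mol); unoccupied bins are NaN."""

    x_edges: np.ndarray
    y_edges: np.ndarray
    values: np.ndarray          # (nx, ny), min occupied bin = 0
    occupied: np.ndarray        # (nx, ny) bool
    estimator: str
    uncertainty: Optional[np.ndarray] = None

    @property
    def x_centers(self) -> np.ndarray:
        return 0.5 * (self.x_edges[:-1] + self.x_edges[1:])

    @property
    def y_centers(self) -> np.ndarray:
        return 0.5 * (self.y_edges[:-1] + self.y_edges[1:])

    def interpolate(self, points: np.ndarray) -> np.ndarray:
        """Bilinear interpolation between occupied bin centers."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        xc, yc = self.x_centers, self.y_centers
        ix = np.clip(np.searchsorted(xc, pts[:, 0]) - 1, 0, len(xc) - 2)
        iy = np.clip(np.searchsorted(yc, pts[:, 1]) - 1, 0, len(yc) - 2)
        tx = np.clip((pts[:, 0] - xc[ix]) / (xc[ix + 1] - xc[ix]), 0.0, 1.0)
        ty = np.clip((pts[:, 1] - yc[iy]) / (yc[iy + 1] - yc[iy]), 0.0, 1.0)
        v = self.values
        out = ((1 - tx) * (1 - ty) * v[ix, iy] + tx * (1 - ty) * v[ix + 1, iy]
               + (1 - tx) * ty * v[ix, iy + 1] + tx * ty * v[ix + 1, iy + 1])
        return out

    def to_matrix_text(self) -> str:
        """Plain-text matrix export (rows = RC1 bins, columns = RC2 bins)."""
        header = ("# free energy (kcal/mol), estimator=" + self.estimator + "\n"
                  "# x_edges: " + " ".join(f"{v:.6g}" for v in self.x_edges) + "\n"
                  "# y_edges: " + " ".join(f"{v:.6g}" for v in self.y_edges) + "\n")
        body = "\n".join(" ".join(f"{v:.6f}" for v in row) for row in self.values)
        return header + body + "\n"


# ---------------------------------------------------------------------------
# grids and histograms
# ---------------------------------------------------------------------------

def make_umbrella_grid(bounds, n_per_axis: int,
                       force_constant: float = DEFAULT_FORCE_CONSTANT,
                       n_steps: int = 1000,
                       temperature: Optional[float] = None) -> list:
    """Regular n×n lattice of restraint windows inclusive of ``bounds``.

    ``bounds`` is ((x_min, x_max), (y_min, y_max)); 13 per axis gives the
    169-window protocol.
    """
    (x0, x1), (y0, y1) = bounds
    if n_per_axis < 2:
        raise ValueError("need at least 2 windows per axis")
    if x1 <= x0 or y1 <= y0:
        raise ValueError(f"degenerate bounds {bounds}")
    xs = np.linspace(x0, x1, n_per_axis)
    ys = np.linspace(y0, y1, n_per_axis)
    kwargs = {} if temperature is None else {"temperature": temperature}
    return [RestraintWindow(center=(float(x), float(y)),
                            force_constants=(force_constant, force_constant),
                            n_steps=n_steps, **kwargs)
            for x in xs for y in ys]


def _auto_edges(windows, bins: int, pad: float = 0.05):
    samples = np.concatenate([w.samples for w in windows])
    lo = samples.min(axis=0)
    hi = samples.max(axis=0)
    span = np.where(hi > lo, hi - lo, 1.0)
    lo = lo - pad * span
    hi = hi + pad * span
    return (np.linspace(lo[0], hi[0], bins + 1), np.linspace(lo[1], hi[1], bins + 1))


def _resolve_edges(windows, bins, edges):
    return edges if edges is not None else _auto_edges(windows, bins)


def _histogram(samples: np.ndarray, edges) -> np.ndarray:
    h, _, _ = np.histogram2d(samples[:, 0], samples[:, 1], bins=edges)
    return h


def _log_gauss_mass(z0: np.ndarray, z1: np.ndarray) -> np.ndarray:
    """log(Φ(z1) − Φ(z0)) for z1 > z0, stable in both tails."""
    z0, z1 = np.broadcast_arrays(z0, z1)
    out = np.empty(z0.shape)
    both_neg = z1 <= 0
    flip = z0 >= 0
    mid = ~(both_neg | flip)
    # left tail: work with Φ directly
    a, b = z0[both_neg], z1[both_neg]
    out[both_neg] = log_ndtr(b) + np.log1p(-np.exp(
        np.minimum(log_ndtr(a) - log_ndtr(b), -1e-12)))
    # right tail: mirror
    a, b = z0[flip], z1[flip]
    out[flip] = log_ndtr(-a) + np.log1p(-np.exp(
        np.minimum(log_ndtr(-b) - log_ndtr(-a), -1e-12)))
    # straddling zero
    a, b = z0[mid], z1[mid]
    out[mid] = np.log(np.maximum(
        np.exp(log_ndtr(b)) - np.exp(log_ndtr(a)), 1e-300))
    return out


def _log_bias_factors(windows: WindowSet, edges) -> np.ndarray:
    """log⟨exp(−b_i/kBT)⟩ averaged analytically over every bin: (K, nx, ny)."""
    kbt_ = kbt(windows.temperature)
    x_edges, y_edges = edges
    logc = []
    for w in windows:
        parts = []
        for axis, e in ((0, x_edges), (1, y_edges)):
            k = w.window.force_constants[axis]
            c = w.window.center[axis]
            sigma = math.sqrt(kbt_ / k)
            z = (e - c) / sigma
            width = np.diff(e)
            log_mass = _log_gauss_mass(z[:-1], z[1:])
            parts.append(log_mass + 0.5 * math.log(2 * math.pi) +
                         math.log(sigma) - np.log(width))
        logc.append(parts[0][:, None] + parts[1][None, :])
    return np.stack(logc)


def _connected_components(per_window_hist: list) -> list:
    occ = [h > 0 for h in per_window_hist]
    n = len(occ)
    seen = [False] * n
    comps = []
    for i in range(n):
        if seen[i]:
            continue
        stack, comp = [i], []
        seen[i] = True
        while stack:
            a = stack.pop()
            comp.append(a)
            for b in range(n):
                if not seen[b] and np.logical_and(occ[a], occ[b]).any():
                    seen[b] = True
                    stack.append(b)
        comps.append(sorted(comp))
    return comps


def _require_connected(ws: WindowSet, coarse_bins: int = 32) -> None:
    """Reject window sets whose sampled regions split into disjoint
    patches; co-occupancy is judged on a coarse grid so the check does
    not depend on the output bin resolution."""
    edges = _auto_edges(ws.windows, coarse_bins)
    hists = [_histogram(w.samples, edges) for w in ws]
    comps = _connected_components(hists)
    if len(comps) > 1:
        raise ValueError(
            "window graph is disconnected; components (by window index): "
            + "; ".join(str(c) for c in comps))


def _finalize(edges, log_p: np.ndarray, counts: np.ndarray, kbt_: float,
              estimator: str, min_count: int) -> FreeEnergyLandscape:
    occupied = counts >= min_count
    if not occupied.any():
        raise ValueError("no occupied bins at the requested threshold")
    values = np.full(log_p.shape, np.nan)
    values[occupied] = -kbt_ * log_p[occupied]
    values -= np.nanmin(values[occupied])
    return FreeEnergyLandscape(x_edges=edges[0], y_edges=edges[1],
                               values=values, occupied=occupied,
                               estimator=estimator)


def _aggregate(ws: WindowSet, land_fine: FreeEnergyLandscape, edges,
               refine: int, min_count: int, estimator: str
               ) -> FreeEnergyLandscape:
    """Sum fine-grid Boltzmann weights into the coarser output bins."""
    kbt_ = kbt(ws.temperature)
    nx, ny = len(edges[0]) - 1, len(edges[1]) - 1
    logw = np.where(land_fine.occupied, -land_fine.values / kbt_, -np.inf)
    log_p = np.full((nx, ny), -np.inf)
    for dx in range(refine):
        for dy in range(refine):
            block = logw[dx::refine, dy::refine]
            log_p = np.logaddexp(log_p, block)
    counts = np.sum([_histogram(w.samples, edges) for w in ws], axis=0)
    return _finalize(edges, log_p, counts, kbt_, estimator, min_count)


# ---------------------------------------------------------------------------
# WHAM
# ---------------------------------------------------------------------------

def wham2d(windows, bins: int = DEFAULT_BINS, tolerance: float = 1e-7,
           max_iterations: int = 20_000, edges=None,
           min_count: int = DEFAULT_MIN_COUNT,
           refine: int = 2) -> FreeEnergyLandscape:
    """2D weighted-histogram estimate of the unbiased free energy.

    The window free energies are first obtained by minimizing the convex
    WHAM likelihood, then polished by direct self-consistent iteration
    until the largest change is below ``tolerance`` (kcal/mol).

    With ``refine`` > 1 the self-consistent problem is solved on a grid
    that many times finer than the output bins and the resulting
    Boltzmann weights are aggregated back; this keeps the within-bin
    variation of the bias factors small on steep landscapes and makes
    the histogram estimate consistent with the per-sample (MBAR) one.
    """
    ws = _as_windows(windows)
    edges = _resolve_edges(ws, bins, edges)
    if refine > 1:
        fine = (_refine_edges(edges[0], refine), _refine_edges(edges[1], refine))
        land_fine = wham2d(ws, tolerance=tolerance,
                           max_iterations=max_iterations, edges=fine,
                           min_count=1, refine=1)
        return _aggregate(ws, land_fine, edges, refine, min_count, "wham")
    hists = [_histogram(w.samples, edges) for w in ws]
    if len(ws) >= 2:
        _require_connected(ws)
    counts = np.sum(hists, axis=0)
    kbt_ = kbt(ws.temperature)
    n_i = np.array([w.n_samples for w in ws], dtype=float)
    logc = _log_bias_factors(ws, edges)          # (K, nx, ny)
    k = len(ws)
    logc_flat = logc.reshape(k, -1)
    n_b = counts.ravel()
    occ = n_b > 0
    logn_b = np.where(occ, np.log(np.maximum(n_b, 1)), 0.0)
    log_ni = np.log(n_i)

    def log_denominator(g):
        return logsumexp(log_ni[:, None] + g[:, None] + logc_flat[:, occ], axis=0)

    def objective(g):
        log_d = log_denominator(g)
        val = -np.dot(n_i, g) + np.dot(n_b[occ], log_d)
        w = np.exp(log_ni[:, None] + g[:, None] + logc_flat[:, occ] - log_d)
        grad = -n_i + w @ n_b[occ]
        return val, grad

    g = np.zeros(k)
    if k > 1:
        res = minimize(objective, g, jac=True, method="L-BFGS-B",
                       options={"maxiter": 2000, "ftol": 1e-15, "gtol": 1e-10})
        g = res.x - res.x[0]
    # self-consistent polish to the stated tolerance
    for _ in range(max_iterations):
        log_d = log_denominator(g)
        log_p = logn_b[occ] - log_d
        log_p -= logsumexp(log_p)
        g_new = -logsumexp(log_p[None, :] + logc_flat[:, occ], axis=1)
        g_new -= g_new[0]
        delta = kbt_ * np.abs(g_new - g).max()
        g = g_new
        if delta < tolerance:
            break
    else:
        raise RuntimeError("WHAM iteration did not reach tolerance")
    log_p_full = np.full(n_b.shape, -np.inf)
    log_p_full[occ] = logn_b[occ] - log_denominator(g)
    return _finalize(edges, log_p_full.reshape(counts.shape), counts, kbt_,
                     "wham", min_count)


# ---------------------------------------------------------------------------
# MBAR
# ---------------------------------------------------------------------------

def _bias_energy_matrix(windows: WindowSet, samples: np.ndarray) -> np.ndarray:
    """Reduced (dimensionless) bias energies u_kn for a sample chunk."""
    kbt_ = kbt(windows.temperature)
    centers = np.array([w.window.center for w in windows])
    ks = np.array([w.window.force_constants for w in windows])
    d = samples[None, :, :] - centers[:, None, :]
    return 0.5 * np.einsum("knj,kj->kn", d**2, ks) / kbt_


def _solve_mbar(u: np.ndarray, log_mult: np.ndarray, log_ni: np.ndarray,
                n_i: np.ndarray, f: np.ndarray, tolerance: float,
                max_iterations: int) -> np.ndarray:
    """Solve the MBAR equations for dimensionless window free energies.

    Damped Newton iterations on the (convex) MBAR objective with the
    exact Hessian, falling back to a self-consistent update whenever a
    Newton step does not decrease the fixed-point residual.  ``u`` holds
    reduced bias energies for (possibly multiplicity-weighted) sample
    positions.
    """
    k = len(n_i)

    def sc_update(fv):
        log_d = logsumexp(log_ni[:, None] + fv[:, None] - u, axis=0)
        fn = -logsumexp(-u + log_mult - log_d, axis=1)
        return fn - fn[0]

    f = f - f[0]
    for _ in range(max_iterations):
        a = log_ni[:, None] + f[:, None] - u
        log_d = logsumexp(a, axis=0)
        w = np.exp(a - log_d)                        # (K, M), Σ_k w_km = 1
        wm = w * np.exp(log_mult)
        s = wm.sum(axis=1)
        grad = s - n_i
        hess = np.diag(s) - wm @ w.T
        try:
            step = np.linalg.solve(hess[1:, 1:], -grad[1:])
            f_newton = f.copy()
            f_newton[1:] += step
        except np.linalg.LinAlgError:
            f_newton = None
        f_sc = sc_update(f)
        res_sc = np.abs(f_sc - f).max()
        if f_newton is not None and np.all(np.isfinite(f_newton)):
            res_newton = np.abs(sc_update(f_newton) - f_newton).max()
            if res_newton < res_sc:
                f, res = f_newton, res_newton
            else:
                f, res = f_sc, res_sc
        else:
            f, res = f_sc, res_sc
        if res < tolerance:
            break
    return f


def _refine_edges(edges_1d: np.ndarray, factor: int) -> np.ndarray:
    fine = [np.linspace(edges_1d[i], edges_1d[i + 1], factor + 1)[:-1]
            for i in range(len(edges_1d) - 1)]
    return np.append(np.concatenate(fine), edges_1d[-1])


def mbar_fes(windows, bins: int = DEFAULT_BINS, tolerance: float = 1e-8,
             edges=None, min_count: int = DEFAULT_MIN_COUNT,
             f_init: Optional[np.ndarray] = None,
             max_sc_iterations: int = 200,
             compress_threshold: float = 5e6,
             quantization: int = 5) -> FreeEnergyLandscape:
    """Free-energy landscape from the multistate Bennett acceptance ratio.

    Solves the MBAR self-consistent equations for the dimensionless
    window free energies f_k (gradient-based minimization of the convex
    MBAR objective, then self-consistent polish), computes per-sample
    unbiased weights, and histograms them on the shared grid.

    When the bias-energy matrix would exceed ``compress_threshold``
    entries, sample positions are quantized onto a grid ``quantization``
    times finer than the output bins and carried with multiplicities;
    this leaves the MBAR equations unchanged while bounding memory and
    time for dense umbrella-grid protocols.
    """
    ws = _as_windows(windows)
    edges = _resolve_edges(ws, bins, edges)
    hists = [_histogram(w.samples, edges) for w in ws]
    if len(ws) >= 2:
        _require_connected(ws)
    counts = np.sum(hists, axis=0)
    kbt_ = kbt(ws.temperature)
    samples = np.concatenate([w.samples for w in ws])
    n_i = np.array([w.n_samples for w in ws], dtype=float)
    n_total = samples.shape[0]
    log_ni = np.log(n_i)
    nx, ny = counts.shape

    if len(ws) * n_total > compress_threshold:
        fx = _refine_edges(edges[0], quantization)
        fy = _refine_edges(edges[1], quantization)
        jx = np.clip(np.searchsorted(fx, samples[:, 0], side="right") - 1,
                     0, len(fx) - 2)
        jy = np.clip(np.searchsorted(fy, samples[:, 1], side="right") - 1,
                     0, len(fy) - 2)
        flat_fine = jx * (len(fy) - 1) + jy
        uniq, inverse, mult = np.unique(flat_fine, return_inverse=True,
                                        return_counts=True)
        fxc = 0.5 * (fx[:-1] + fx[1:])
        fyc = 0.5 * (fy[:-1] + fy[1:])
        positions = np.stack([fxc[uniq // (len(fy) - 1)],
                              fyc[uniq % (len(fy) - 1)]], axis=1)
        mult = mult.astype(float)
        coarse_bin = ((uniq // (len(fy) - 1)) // quantization) * ny \
            + ((uniq % (len(fy) - 1)) // quantization)
    else:
        positions = samples
        mult = np.ones(n_total)
        ix = np.clip(np.searchsorted(edges[0], samples[:, 0], side="right") - 1,
                     0, nx - 1)
        iy = np.clip(np.searchsorted(edges[1], samples[:, 1], side="right") - 1,
                     0, ny - 1)
        coarse_bin = ix * ny + iy

    u = _bias_energy_matrix(ws, positions)        # (K, M)
    log_mult = np.log(mult)

    f = np.zeros(len(ws)) if f_init is None else np.array(f_init, dtype=float)
    if len(ws) > 1:
        f = _solve_mbar(u, log_mult, log_ni, n_i, f, tolerance,
                        max_sc_iterations)
    log_d = logsumexp(log_ni[:, None] + f[:, None] - u, axis=0)
    log_w = log_mult - log_d   # unbiased log-weights (unnormalized)

    log_p = np.full(nx * ny, -np.inf)
    order = np.argsort(coarse_bin, kind="stable")
    bin_sorted = coarse_bin[order]
    logw_sorted = log_w[order]
    starts = np.searchsorted(bin_sorted, np.arange(nx * ny))
    ends = np.searchsorted(bin_sorted, np.arange(nx * ny), side="right")
    for b in np.nonzero(ends > starts)[0]:
        log_p[b] = logsumexp(logw_sorted[starts[b]:ends[b]])
    return _finalize(edges, log_p.reshape(nx, ny), counts, kbt_, "mbar", min_count)


# ---------------------------------------------------------------------------
# variational maximum-likelihood profile
# ---------------------------------------------------------------------------

def _bilinear_basis(x_centers, y_centers, basis: tuple) -> tuple:
    """Sparse-ish bilinear map from a coarse control grid to bin centers."""
    bx, by = basis
    cx = np.linspace(x_centers[0], x_centers[-1], bx)
    cy = np.linspace(y_centers[0], y_centers[-1], by)

    def weights_1d(centers, controls):
        idx = np.clip(np.searchsorted(controls, centers) - 1, 0, len(controls) - 2)
        t = (centers - controls[idx]) / (controls[idx + 1] - controls[idx])
        return idx, np.clip(t, 0.0, 1.0)

    ixc, tx = weights_1d(x_centers, cx)
    iyc, ty = weights_1d(y_centers, cy)
    nxb, nyb = len(x_centers), len(y_centers)
    rows, cols, vals = [], [], []
    for bin_i in range(nxb):
        for bin_j in range(nyb):
            r = bin_i * nyb + bin_j
            for dx, wx in ((0, 1 - tx[bin_i]), (1, tx[bin_i])):
                for dy, wy in ((0, 1 - ty[bin_j]), (1, ty[bin_j])):
                    rows.append(r)
                    cols.append((ixc[bin_i] + dx) * by + (iyc[bin_j] + dy))
                    vals.append(wx * wy)
    from scipy.sparse import csr_matrix
    return csr_matrix((vals, (rows, cols)), shape=(nxb * nyb, bx * by)), (bx, by)


def variational_profile(windows, bins: int = DEFAULT_BINS,
                        basis: Optional[tuple] = None, edges=None,
                        min_count: int = DEFAULT_MIN_COUNT,
                        refine: int = 2) -> FreeEnergyLandscape:
    """Maximum-likelihood free-energy field given all biased samples.

    Maximizes the product over windows of the probability of the binned
    samples under p_i(bin) ∝ exp(−(F + b_i)/kBT), with F parameterized on
    a control grid of resolution ``basis`` (default: one control point
    per occupied bin, i.e. the unsmoothed maximum-likelihood field).
    As in :func:`wham2d`, the default ``refine`` solves the likelihood on
    an internally finer grid and aggregates the weights to the output
    bins.
    """
    ws = _as_windows(windows)
    edges = _resolve_edges(ws, bins, edges)
    if refine > 1 and basis is None:
        fine = (_refine_edges(edges[0], refine), _refine_edges(edges[1], refine))
        land_fine = variational_profile(ws, basis=None, edges=fine,
                                        min_count=1, refine=1)
        return _aggregate(ws, land_fine, edges, refine, min_count, "vfep")
    hists = np.stack([_histogram(w.samples, edges) for w in ws])  # (K, nx, ny)
    if len(ws) >= 2:
        _require_connected(ws)
    counts = hists.sum(axis=0)
    kbt_ = kbt(ws.temperature)
    logc = _log_bias_factors(ws, edges)
    nx, ny = counts.shape
    n_i = hists.reshape(len(ws), -1).sum(axis=1)
    occ_flat = (counts > 0).ravel()
    m_b = counts.ravel()[occ_flat]
    logc_occ = logc.reshape(len(ws), -1)[:, occ_flat]

    if basis is None:
        design = None
        n_params = int(occ_flat.sum())
    else:
        x_centers = 0.5 * (edges[0][:-1] + edges[0][1:])
        y_centers = 0.5 * (edges[1][:-1] + edges[1][1:])
        design_full, (bx, by) = _bilinear_basis(x_centers, y_centers, basis)
        design = design_full[occ_flat]
        n_params = bx * by
        if n_params > int(occ_flat.sum()):
            raise ValueError(
                f"under-determined basis: {n_params} parameters for "
                f"{int(occ_flat.sum())} occupied bins")

    def unpack(theta):
        return theta if design is None else design @ theta

    def objective(theta):
        f_occ = unpack(theta) / kbt_   # dimensionless free energy per occupied bin
        a = logc_occ - f_occ[None, :]
        log_z = logsumexp(a, axis=1)
        val = np.dot(n_i, log_z) + np.dot(m_b, f_occ)
        p = np.exp(a - log_z[:, None])
        grad_f = (m_b - n_i @ p) / kbt_
        grad = grad_f if design is None else design.T @ grad_f
        return val, grad

    theta0 = np.zeros(n_params)
    res = minimize(objective, theta0, jac=True, method="L-BFGS-B",
                   options={"maxiter": 5000, "ftol": 1e-15, "gtol": 1e-9})
    f_occ = unpack(res.x)
    log_p = np.full(nx * ny, -np.inf)
    log_p[occ_flat] = -f_occ / kbt_
    return _finalize(edges, log_p.reshape(nx, ny), counts, kbt_,
                     "vfep", min_count)


ESTIMATORS: dict[str, Callable] = {
    "wham": wham2d,
    "mbar": mbar_fes,
    "vfep": variational_profile,
}


# ---------------------------------------------------------------------------
# barriers and uncertainties
# ---------------------------------------------------------------------------

def _basin_value(landscape: FreeEnergyLandscape, point: np.ndarray,
                 radius: float) -> float:
    gx, gy = np.meshgrid(landscape.x_centers, landscape.y_centers, indexing="ij")
    mask = ((gx - point[0]) ** 2 + (gy - point[1]) ** 2 <= radius**2) \
        & landscape.occupied
    if not mask.any():
        raise ValueError(f"no occupied bins within {radius} Å of {point}")
    return float(np.nanmin(landscape.values[mask]))


def path_barrier(landscape: FreeEnergyLandscape,
                 path: Union[StringPath, np.ndarray],
                 basin_radius: float = BASIN_RADIUS) -> tuple[float, float]:
    """(barrier, ΔG_reaction) in kcal/mol along a path across a landscape.

    The barrier is the maximum interpolated free energy along the densely
    sampled path minus the reactant-basin minimum (lowest occupied bin
    within ``basin_radius`` of the first path point); ΔG is product basin
    minus reactant basin.  Paths crossing unoccupied bins raise.
    """
    pts = dense_curve(path) if isinstance(path, StringPath) else np.atleast_2d(path)
    values = landscape.interpolate(pts)
    if np.isnan(values).any():
        bad = int(np.nonzero(np.isnan(values))[0][0])
        raise ValueError(f"path crosses unoccupied bins near {pts[bad]}")
    f_react = _basin_value(landscape, pts[0], basin_radius)
    f_prod = _basin_value(landscape, pts[-1], basin_radius)
    return float(values.max() - f_react), float(f_prod - f_react)


def _block_resample(ws: WindowSet, n_blocks: int,
                    rng: np.random.Generator) -> WindowSet:
    new = []
    for w in ws:
        blocks = np.array_split(np.arange(w.n_samples), n_blocks)
        pick = rng.integers(0, n_blocks, size=n_blocks)
        idx = np.concatenate([blocks[p] for p in pick])
        new.append(replace(w, samples=w.samples[idx]))
    return WindowSet(new)


def block_uncertainty(windows, estimator: str = "wham", n_boot: int = 20,
                      n_blocks: int = 10, seed: int = 0, bins: int = DEFAULT_BINS,
                      edges=None, **kwargs) -> FreeEnergyLandscape:
    """Per-bin block-bootstrap standard error of a landscape estimate.

    Contiguous sample blocks are resampled with replacement within every
    window; the estimator is re-run on each replicate and the bin-wise
    standard deviation is attached to the point-estimate landscape.
    """
    ws = _as_windows(windows)
    edges = _resolve_edges(ws, bins, edges)
    est = ESTIMATORS[estimator]
    base = est(ws, edges=edges, **kwargs)
    rng = np.random.Generator(np.random.PCG64(seed))
    stack = []
    for _ in range(n_boot):
        rep = est(_block_resample(ws, n_blocks, rng), edges=edges, **kwargs)
        stack.append(rep.values)
    with np.errstate(invalid="ignore"):
        sd = np.nanstd(np.stack(stack), axis=0, ddof=1)
    return replace(base, uncertainty=sd)


def bootstrap_barrier(windows, path, estimator: str = "wham", n_boot: int = 20,
                      n_blocks: int = 10, seed: int = 0, bins: int = DEFAULT_BINS,
                      edges=None, ci: float = 0.95,
                      **kwargs) -> tuple[float, np.ndarray, tuple]:
    """Point estimate, bootstrap replicates and CI of a path barrier."""
    ws = _as_windows(windows)
    edges = _resolve_edges(ws, bins, edges)
    est = ESTIMATORS[estimator]
    point, _ = path_barrier(est(ws, edges=edges, **kwargs), path)
    rng = np.random.Generator(np.random.PCG64(seed))
    reps = []
    for _ in range(n_boot):
        land = est(_block_resample(ws, n_blocks, rng), edges=edges, **kwargs)
        try:
            b, _ = path_barrier(land, path)
            reps.append(b)
        except ValueError:
            continue
    reps = np.array(reps)
    alpha = 0.5 * (1.0 - ci)
    lo, hi = np.quantile(reps, [alpha, 1.0 - alpha])
    return point, reps, (float(lo), float(hi))
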