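"""Analytic 2D surrogate energy surfaces and biased sampling.

These surfaces stand in for proton-coupled electron transfer energetics
over two proton-transfer coordinates (RC1, RC2, in Å): Gaussian-mixture
topographies with known minima, saddles and minimum-energy-path barriers,
plus an optional harmonic confinement.  Restrained sampling emulates the
short umbrella-restrained trajectories a string iteration consumes: an
overdamped-Langevin (Euler–Maruyama) proposal with a Metropolis
correction, so the stationary distribution is exactly
exp(−(U + bias)/kBT) at the window temperature.

Presets
-------
``harmonic-well``
    Single isotropic harmonic well at the origin (k in kcal mol⁻¹ Å⁻²).
``mueller-brown``
    The standard Müller–Brown benchmark (three minima, two saddles).
``pcet-double-well``
    Two anisotropic wells at (−0.8, −0.8) and (+0.8, +0.8) Å whose overlap
    forms a single saddle on the diagonal.  Well depths and the diagonal
    width are calibrated numerically at construction so that the
    minimum-energy-path barrier, the reaction free energy, and the barrier
    of the alternative (off-diagonal) route hit the requested values
    (defaults 12, 7.5 and 15 kcal/mol — the computed energetics of the
    favored stepwise pathway versus its higher-lying alternatives).
"""

from __future__ import annotations

import functools
import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .constants import T_DEFAULT, kbt


class SamplerDivergence(RuntimeError):
    """Raised when the biased sampler cannot recover by halving its step."""

    def __init__(self, message: str, step_index: int):
        super().__init__(message)
        self.step_index = step_index


@dataclass(frozen=True)
class GaussianComponent:
    """One exponential-quadratic term  A · exp(dᵀ M d),  d = r − center.

    ``quad`` is the symmetric matrix M (units Å⁻²); wells have negative
    amplitude with negative-definite M, or equivalently are built from a
    width matrix via :meth:`from_widths`.
    """

    amplitude: float
    center: tuple
    quad: tuple  # ((mxx, mxy), (mxy, myy))

    @staticmethod
    def from_widths(amplitude: float, center: Sequence[float],
                    sigma_par: float, sigma_perp: float,
                    direction: Sequence[float]) -> "GaussianComponent":
        """Anisotropic Gaussian with principal widths along ``direction``."""
        if sigma_par <= 0 or sigma_perp <= 0:
            raise ValueError("widths must be positive")
        u = np.asarray(direction, dtype=float)
        u = u / np.linalg.norm(u)
        v = np.array([-u[1], u[0]])
        m = -(np.outer(u, u) / (2 * sigma_par**2) + np.outer(v, v) / (2 * sigma_perp**2))
        return GaussianComponent(amplitude=float(amplitude),
                                 center=(float(center[0]), float(center[1])),
                                 quad=((m[0, 0], m[0, 1]), (m[1, 0], m[1, 1])))

    @staticmethod
    def isotropic(amplitude: float, center: Sequence[float], sigma: float) -> "GaussianComponent":
        return GaussianComponent.from_widths(amplitude, center, sigma, sigma, (1.0, 0.0))


@dataclass(frozen=True)
class ModelSurface:
    """Analytic 2D energy surface (kcal/mol over Å coordinates)."""

    components: tuple
    confinement_k: float = 0.0
    confinement_center: tuple = (0.0, 0.0)
    label: str = "custom"
    domain: tuple = ((-2.0, 2.0), (-2.0, 2.0))

    def _terms(self, points: np.ndarray):
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        for comp in self.components:
            d = pts - np.asarray(comp.center)
            m = np.asarray(comp.quad)
            md = d @ m
            expo = np.einsum("...i,...i->...", d, md)
            # clip keeps far-field evaluations finite (repulsive MB term)
            yield comp, d, md, comp.amplitude * np.exp(np.minimum(expo, 700.0))

    def energy(self, points) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        e = np.zeros(pts.shape[:-1])
        for _, _, _, term in self._terms(pts):
            e += term
        if self.confinement_k:
            dc = pts - np.asarray(self.confinement_center)
            e += 0.5 * self.confinement_k * np.einsum("...i,...i->...", dc, dc)
        return e if np.asarray(points).ndim > 1 else e[0]

    def gradient(self, points) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        g = np.zeros_like(pts)
        for _, _, md, term in self._terms(pts):
            g += 2.0 * term[..., None] * md
        if self.confinement_k:
            g += self.confinement_k * (pts - np.asarray(self.confinement_center))
        return g if np.asarray(points).ndim > 1 else g[0]

    def hessian(self, point) -> np.ndarray:
        p = np.asarray(point, dtype=float)
        h = np.zeros((2, 2))
        for comp, d, md, term in self._terms(p[None, :]):
            m = np.asarray(comp.quad)
            h += term[0] * (2.0 * m + 4.0 * np.outer(md[0], md[0]))
        if self.confinement_k:
            h += self.confinement_k * np.eye(2)
        return h


@dataclass(frozen=True)
class RestraintWindow:
    """Harmonic umbrella restraint  ½ kx (RC1−cx)² + ½ ky (RC2−cy)²."""

    center: tuple
    force_constants: tuple = (200.0, 200.0)
    n_steps: int = 150
    temperature: float = T_DEFAULT

    def __post_init__(self) -> None:
        if min(self.force_constants) <= 0:
            raise ValueError("force constants must be positive")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")

    def bias_energy(self, points) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        d = pts - np.asarray(self.center)
        k = np.asarray(self.force_constants)
        b = 0.5 * np.einsum("...i,i,...i->...", d, k, d)
        return b if np.asarray(points).ndim > 1 else b[0]

    def bias_gradient(self, points) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        g = np.asarray(self.force_constants) * (pts - np.asarray(self.center))
        return g if np.asarray(points).ndim > 1 else g[0]


@dataclass(frozen=True)
class BiasedTrajectory:
    """Seeded biased samples from one restraint window."""

    window: RestraintWindow
    samples: np.ndarray  # (n, 2)
    seed: int
    step_size: float

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]


# ---------------------------------------------------------------------------
# presets
# ---------------------------------------------------------------------------

_MB_PARAMS = [  # (A, a, b, c, x0, y0): the standard Müller–Brown terms
    (-200.0, -1.0, 0.0, -10.0, 1.0, 0.0),
    (-100.0, -1.0, 0.0, -10.0, 0.0, 0.5),
    (-170.0, -6.5, 11.0, -6.5, -0.5, 1.5),
    (15.0, 0.7, 0.6, 0.7, -1.0, 1.0),
]


def _mueller_brown() -> ModelSurface:
    comps = tuple(
        GaussianComponent(amplitude=A, center=(x0, y0),
                          quad=((a, b / 2.0), (b / 2.0, c)))
        for A, a, b, c, x0, y0 in _MB_PARAMS)
    return ModelSurface(components=comps, label="mueller-brown",
                        domain=((-1.7, 1.3), (-0.5, 2.2)))


_PCET_WELLS = ((-0.8, -0.8), (0.8, 0.8))
_PCET_SIGMA_PERP = 0.30
_PCET_CONF_K = 1.0


def _pcet_surface(depth_r: float, depth_p: float, sigma_par: float) -> ModelSurface:
    diag = (1.0, 1.0)
    comps = (
        GaussianComponent.from_widths(-depth_r, _PCET_WELLS[0], sigma_par,
                                      _PCET_SIGMA_PERP, diag),
        GaussianComponent.from_widths(-depth_p, _PCET_WELLS[1], sigma_par,
                                      _PCET_SIGMA_PERP, diag),
    )
    return ModelSurface(components=comps, confinement_k=_PCET_CONF_K,
                        label="pcet-double-well",
                        domain=((-1.8, 1.8), (-1.8, 1.8)))


@functools.lru_cache(maxsize=16)
def _calibrated_pcet(barrier: float, delta_g: float, alt_barrier: float) -> ModelSurface:
    """Solve for well depths and diagonal width that plant the requested
    direct barrier, reaction ΔG and alternative-route barrier.

    The alternative-route barrier is anchored at the off-diagonal corner
    (+0.8, −0.8): a string forced around the direct saddle crosses the
    confined plateau there, so the corner energy relative to the
    reactant minimum is the planted height of the alternative pathway.
    """
    from scipy.optimize import least_squares, minimize_scalar

    from . import topology

    def measure(params):
        d_r, d_p, s_par = params
        surf = _pcet_surface(d_r, d_p, s_par)
        e_r = topology.refine_minimum(surf, _PCET_WELLS[0])
        e_p = topology.refine_minimum(surf, _PCET_WELLS[1])
        # by construction the saddle lies on the diagonal between the wells
        u = np.array([1.0, 1.0]) / math.sqrt(2.0)
        res = minimize_scalar(lambda s: -surf.energy(s * u),
                              bounds=(-0.8, 0.8), method="bounded",
                              options={"xatol": 1e-12})
        saddle = res.x * u
        direct = surf.energy(saddle) - e_r.energy
        alt = surf.energy(np.array([0.8, -0.8])) - e_r.energy
        return surf, e_r, e_p, direct, alt

    def residuals(params):
        surf, e_r, e_p, direct, alt = measure(params)
        return [direct - barrier,
                (e_p.energy - e_r.energy) - delta_g,
                alt - alt_barrier]

    x0 = np.array([alt_barrier, alt_barrier - delta_g, 0.55])
    sol = least_squares(residuals, x0, xtol=1e-10, ftol=1e-12,
                        bounds=([1.0, 1.0, 0.3], [60.0, 60.0, 0.9]))
    res = np.abs(sol.fun)
    if res.max() > 0.05:
        raise RuntimeError(
            f"pcet-double-well calibration failed: residuals {sol.fun}")
    d_r, d_p, s_par = sol.x
    return _pcet_surface(d_r, d_p, s_par)


def make_surface(preset: str, **overrides) -> ModelSurface:
    """Build a preset surface; keyword overrides tune the preset.

    ``harmonic-well``: k (default 1.0).
    ``mueller-brown``: no parameters.
    ``pcet-double-well``: barrier (12), delta_g (7.5), alt_barrier (15),
    all kcal/mol.
    """
    if preset == "harmonic-well":
        k = float(overrides.pop("k", 1.0))
        if k <= 0:
            raise ValueError("harmonic-well requires k > 0")
        surf = ModelSurface(components=(), confinement_k=k, label="harmonic-well")
    elif preset == "mueller-brown":
        surf = _mueller_brown()
    elif preset == "pcet-double-well":
        barrier = float(overrides.pop("barrier", 12.0))
        delta_g = float(overrides.pop("delta_g", 7.5))
        alt_barrier = float(overrides.pop("alt_barrier", 15.0))
        if barrier <= 0 or alt_barrier <= barrier:
            raise ValueError("need 0 < barrier < alt_barrier")
        surf = _calibrated_pcet(barrier, delta_g, alt_barrier)
    else:
        raise ValueError(f"unknown surface preset {preset!r}")
    if overrides:
        raise TypeError(f"unknown overrides for {preset!r}: {sorted(overrides)}")
    return surf


def surface_from_config(config: dict) -> ModelSurface:
    """Plain-dict (JSON-compatible) surface declaration: {"preset": ..., ...}."""
    cfg = dict(config)
    preset = cfg.pop("preset")
    return make_surface(preset, **cfg)


# ---------------------------------------------------------------------------
# biased sampling
# ---------------------------------------------------------------------------

_MAX_ENERGY = 1e12
_OVERFLOW_LIMIT = 25


def sample_windows(surface: ModelSurface, windows: Sequence[RestraintWindow],
                   n: int, seed: int, step_size: float = 1e-3,
                   burn_in: int = 100) -> list[BiasedTrajectory]:
    """Draw ``n`` biased samples in every window simultaneously.

    Metropolis-adjusted overdamped Langevin: proposals
    x' = x − ∇V Δt + √(2 kBT Δt) ξ with the exact acceptance correction,
    so the stationary density is exp(−V/kBT) with V = U + bias.  Chains
    start at the window centers; ``burn_in`` steps are discarded.  The
    step (Å²·(kcal/mol)⁻¹) is halved automatically for a window after
    repeated energy overflows; irrecoverable divergence raises
    :class:`SamplerDivergence` with the offending step index.
    """
    if n < 1:
        raise ValueError("need n >= 1 samples")
    if step_size <= 0:
        raise ValueError("step size must be positive")
    windows = list(windows)
    n_w = len(windows)
    rng = np.random.Generator(np.random.PCG64(seed))
    centers = np.array([w.center for w in windows], dtype=float)
    force_k = np.array([w.force_constants for w in windows], dtype=float)
    kbts = np.array([kbt(w.temperature) for w in windows])
    steps = np.full(n_w, float(step_size))
    overflow_run = np.zeros(n_w, dtype=int)

    def potential(x):
        d = x - centers
        return surface.energy(x) + 0.5 * np.einsum("ij,ij,ij->i", force_k, d, d)

    def grad(x):
        return surface.gradient(x) + force_k * (x - centers)

    x = centers.copy()
    ex = potential(x)
    if not np.all(np.isfinite(ex)):
        bad = int(np.nonzero(~np.isfinite(ex))[0][0])
        raise SamplerDivergence(
            f"non-finite energy at window {bad} start", step_index=0)
    gx = grad(x)
    out = np.empty((n, n_w, 2))
    total = burn_in + n
    for it in range(total):
        noise = rng.standard_normal((n_w, 2))
        mean_fwd = x - steps[:, None] * gx
        prop = mean_fwd + np.sqrt(2.0 * kbts * steps)[:, None] * noise
        ep = potential(prop)
        finite = np.isfinite(ep) & (np.abs(ep) < _MAX_ENERGY)
        ep_safe = np.where(finite, ep, 0.0)
        gp = grad(np.where(finite[:, None], prop, x))
        mean_rev = prop - steps[:, None] * gp
        log_q_fwd = -np.sum((prop - mean_fwd) ** 2, axis=1) / (4 * kbts * steps)
        log_q_rev = -np.sum((x - mean_rev) ** 2, axis=1) / (4 * kbts * steps)
        log_alpha = -(ep_safe - ex) / kbts + log_q_rev - log_q_fwd
        accept = finite & (np.log(rng.random(n_w)) < log_alpha)
        x[accept] = prop[accept]
        ex[accept] = ep[accept]
        gx[accept] = gp[accept]
        overflow_run = np.where(finite, 0, overflow_run + 1)
        if np.any(overflow_run >= _OVERFLOW_LIMIT):
            idx = overflow_run >= _OVERFLOW_LIMIT
            steps[idx] *= 0.5
            overflow_run[idx] = 0
            if np.any(steps < 1e-12):
                bad = int(np.nonzero(steps < 1e-12)[0][0])
                raise SamplerDivergence(
                    f"window {bad} diverged (step size underflow)", step_index=it)
        if it >= burn_in:
            out[it - burn_in] = x
    return [
        BiasedTrajectory(window=windows[i], samples=out[:, i, :].copy(),
                         seed=seed, step_size=float(steps[i]))
        for i in range(n_w)
    ]


def sample_window(surface: ModelSurface, window: RestraintWindow, n: int,
                  seed: int, step_size: float = 1e-3,
                  burn_in: int = 100) -> BiasedTrajectory:
    """Biased samples from a single restraint window (see :func:`sample_windows`)."""
    return sample_windows(surface, [window], n, seed, step_size, burn_in)[0]


# ---------------------------------------------------------------------------
# quadrature reference for the biased density
# ---------------------------------------------------------------------------

def biased_density_grid(surface: ModelSurface, window: RestraintWindow,
                        n_grid: int = 161, n_sigma: float = 6.0,
                        margin: float = 0.1):
    """Dense grid and normalized biased Boltzmann weights for one window.

    The grid is re-centered iteratively on the running mean so that
    windows whose biased minimum is displaced from the restraint center
    are still fully covered.
    """
    k = np.asarray(window.force_constants)
    sig = np.sqrt(kbt(window.temperature) / k)
    half = n_sigma * sig + margin
    center = np.asarray(window.center, dtype=float)
    for _ in range(3):
        xs = np.linspace(center[0] - half[0], center[0] + half[0], n_grid)
        ys = np.linspace(center[1] - half[1], center[1] + half[1], n_grid)
        gx, gy = np.meshgrid(xs, ys, indexing="ij")
        pts = np.stack([gx.ravel(), gy.ravel()], axis=1)
        v = surface.energy(pts) + window.bias_energy(pts)
        v = v.reshape(n_grid, n_grid)
        w = np.exp(-(v - v.min()) / kbt(window.temperature))
        w /= w.sum()
        center = np.array([np.sum(w * gx), np.sum(w * gy)])
    return xs, ys, w


def biased_mean_quadrature(surface: ModelSurface, window: RestraintWindow,
                           n_grid: int = 161) -> np.ndarray:
    """Mean of the biased density by direct quadrature (noise-free drift)."""
    xs, ys, w = biased_density_grid(surface, window, n_grid=n_grid)
    gx, gy = np.meshgrid(xs, ys, indexing="ij")
    return np.array([np.sum(w * gx), np.sum(w * gy)])


def recenter_windows(surface: ModelSurface, targets,
                     force_constants=(200.0, 200.0),
                     temperature: float = T_DEFAULT, n_iter: int = 3,
                     n_steps: int = 1000) -> list:
    """Restraint windows whose *sampled* means sit on the target points.

    On steep surfaces the biased density is displaced from the restraint
    center by roughly ∇U/k; each fixed-point iteration moves the center
    by the (quadrature) residual so the sampled distribution covers the
    intended point.  Standard umbrella design for stiff landscapes.
    """
    k = np.asarray(force_constants, dtype=float)
    windows = []
    for target in np.atleast_2d(np.asarray(targets, dtype=float)):
        # first order: the biased mean sits ~∇U/k below the center, so
        # start from the explicitly corrected center, then polish with
        # damped fixed-point steps (a plain iteration diverges wherever
        # the surface curvature exceeds the restraint stiffness)
        center = target + surface.gradient(target) / k
        for _ in range(n_iter):
            w = RestraintWindow(center=tuple(center),
                                force_constants=tuple(force_constants),
                                temperature=temperature, n_steps=n_steps)
            center += 0.5 * (target - biased_mean_quadrature(surface, w))
        windows.append(RestraintWindow(center=tuple(center),
                                       force_constants=tuple(force_constants),
                                       temperature=temperature,
                                       n_steps=n_steps))
    return windows


def biased_marginal_quadrature(surface: ModelSurface, window: RestraintWindow,
                               axis: int, edges: np.ndarray,
                               n_grid: int = 641) -> np.ndarray:
    """Probability mass of the biased density in 1D bins along ``axis``.

    The 1D marginal CDF is built by fine quadrature and interpolated at
    the bin edges, so bin masses are accurate independently of how the
    quadrature grid aligns with the bins.
    """
    xs, ys, w = biased_density_grid(surface, window, n_grid=n_grid)
    coord = xs if axis == 0 else ys
    marg = w.sum(axis=1 - axis)
    cdf = np.concatenate([[0.0], np.cumsum(marg)])
    # cumulative mass up to the right edge of every quadrature cell
    half = 0.5 * (coord[1] - coord[0])
    cdf_x = np.concatenate([[coord[0] - half], coord + half])
    at_edges = np.interp(edges, cdf_x, cdf / cdf[-1])
    return np.diff(at_edges)
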