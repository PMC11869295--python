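"""Dense-grid topography analysis of analytic surfaces.

Stationary-point location (Newton refinement of grid candidates with the
analytic Hessian), minimax ("mountain-pass") barriers between basins by
threshold flooding, and steepest-descent minimum-energy-path tracing.
These serve as ground-truth oracles for the string method and the
free-energy estimators.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage
from scipy.optimize import minimize, root


@dataclass(frozen=True)
class StationaryPoint:
    point: np.ndarray
    energy: float
    kind: str  # "minimum" | "saddle" | "maximum"


def _grid(surface, n_grid: int):
    (x0, x1), (y0, y1) = surface.domain
    xs = np.linspace(x0, x1, n_grid)
    ys = np.linspace(y0, y1, n_grid)
    gx, gy = np.meshgrid(xs, ys, indexing="ij")
    pts = np.stack([gx.ravel(), gy.ravel()], axis=1)
    e = surface.energy(pts).reshape(n_grid, n_grid)
    return xs, ys, e


def refine_minimum(surface, guess: Sequence[float]) -> StationaryPoint:
    res = minimize(lambda p: surface.energy(p), np.asarray(guess, float),
                   jac=lambda p: surface.gradient(p), method="BFGS",
                   options={"gtol": 1e-10})
    return StationaryPoint(point=res.x, energy=float(surface.energy(res.x)),
                           kind="minimum")


def refine_saddle(surface, guess: Sequence[float]) -> np.ndarray:
    """Newton-refine a stationary point from ``guess`` (returns the point)."""
    res = root(lambda p: surface.gradient(p), np.asarray(guess, float),
               jac=lambda p: surface.hessian(p), tol=1e-12)
    if not res.success:
        raise RuntimeError(f"saddle refinement failed from {guess}: {res.message}")
    return res.x


def find_stationary_points(surface, n_grid: int = 201,
                           grad_quantile: float = 0.05) -> list[StationaryPoint]:
    """Locate and classify all stationary points on the declared domain.

    Grid cells where |∇U| is a local minimum seed Newton iterations on the
    gradient; converged points inside the domain are classified by the
    eigenvalues of the analytic Hessian and deduplicated.
    """
    xs, ys, _ = _grid(surface, n_grid)
    gx, gy = np.meshgrid(xs, ys, indexing="ij")
    pts = np.stack([gx.ravel(), gy.ravel()], axis=1)
    gnorm = np.linalg.norm(surface.gradient(pts), axis=1).reshape(n_grid, n_grid)
    local_min = (gnorm == ndimage.minimum_filter(gnorm, size=5))
    cutoff = np.quantile(gnorm, grad_quantile)
    seeds = np.argwhere(local_min & (gnorm <= max(cutoff, 1e-6) * 50))

    (x0, x1), (y0, y1) = surface.domain
    found: list[StationaryPoint] = []
    for i, j in seeds:
        guess = np.array([xs[i], ys[j]])
        res = root(lambda p: surface.gradient(p), guess,
                   jac=lambda p: surface.hessian(p), tol=1e-12)
        if not res.success:
            continue
        p = res.x
        if np.linalg.norm(surface.gradient(p)) > 1e-6:
            continue
        if not (x0 - 1e-9 <= p[0] <= x1 + 1e-9 and y0 - 1e-9 <= p[1] <= y1 + 1e-9):
            continue
        if any(np.linalg.norm(p - q.point) < 1e-3 for q in found):
            continue
        eig = np.linalg.eigvalsh(surface.hessian(p))
        if np.all(eig > 0):
            kind = "minimum"
        elif np.all(eig < 0):
            kind = "maximum"
        else:
            kind = "saddle"
        found.append(StationaryPoint(point=p, energy=float(surface.energy(p)),
                                     kind=kind))
    return sorted(found, key=lambda s: s.energy)


def minimax_barrier(surface, start: Sequence[float], end: Sequence[float],
                    n_grid: int = 301,
                    mask_disks: Optional[list] = None) -> float:
    """Lowest maximum energy (relative to the start basin) over all grid
    paths connecting ``start`` and ``end``, by bisection on the flooding
    threshold with 8-connected component labeling.

    ``mask_disks`` — list of ((x, y), radius) regions removed from the grid,
    used to block a known channel and measure an alternative route.
    """
    xs, ys, e = _grid(surface, n_grid)
    gx, gy = np.meshgrid(xs, ys, indexing="ij")
    allowed = np.ones_like(e, dtype=bool)
    for center, radius in (mask_disks or []):
        allowed &= (gx - center[0]) ** 2 + (gy - center[1]) ** 2 > radius**2

    def cell(p):
        return (int(np.argmin(np.abs(xs - p[0]))), int(np.argmin(np.abs(ys - p[1]))))

    ca, cb = cell(start), cell(end)
    if not (allowed[ca] and allowed[cb]):
        raise ValueError("start or end point lies inside a masked disk")
    structure = np.ones((3, 3), dtype=bool)

    def connected(level: float) -> bool:
        labels, _ = ndimage.label((e <= level) & allowed, structure=structure)
        return labels[ca] != 0 and labels[ca] == labels[cb]

    lo = float(max(e[ca], e[cb]))
    hi = float(e[allowed].max())
    if not connected(hi):
        raise RuntimeError("basins are not connected on the allowed grid")
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if connected(mid):
            hi = mid
        else:
            lo = mid
    e_start = float(surface.energy(np.asarray(start, float)))
    return hi - e_start


def steepest_descent_path(surface, saddle: Sequence[float], step: float = 1e-3,
                          max_steps: int = 200_000, offset: float = 1e-4,
                          gtol: float = 1e-8) -> np.ndarray:
    """Trace the minimum-energy path through a saddle by steepest descent
    along ± the unstable Hessian eigenvector; returns an ordered polyline
    from one minimum through the saddle to the other."""
    s = np.asarray(saddle, dtype=float)
    eigval, eigvec = np.linalg.eigh(surface.hessian(s))
    direction = eigvec[:, int(np.argmin(eigval))]

    def descend(sign: float) -> list:
        x = s + sign * offset * direction
        path = [x.copy()]
        for _ in range(max_steps):
            g = surface.gradient(x)
            gn = np.linalg.norm(g)
            if gn < gtol:
                break
            x = x - step * g / max(gn, 1.0)
            path.append(x.copy())
        return path

    left = descend(-1.0)
    right = descend(+1.0)
    return np.array(left[::-1] + [s] + right)
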