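"""Finite-temperature string method on 2D reaction-coordinate surfaces.

A string is an ordered set of nodes in (RC1, RC2) space.  Each iteration
(i) estimates the drift of every node from short restrained sampling (or
noise-free quadrature over the biased density), (ii) refits a smooth
curve — quartic polynomial per coordinate or cubic spline — through the
drift-updated nodes, and (iii) redistributes the nodes to equal arclength
along the fitted curve.  Iterations stop once both the sum-of-squares
change and the maximum squared node deviation between consecutive strings
stay below 0.008 and 0.05 Å² for at least three consecutive iterations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Callable, Optional

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline

from .surfaces import (
    ModelSurface,
    RestraintWindow,
    biased_mean_quadrature,
    sample_windows,
)

SSQ_TOL = 0.008   # Å², sum-of-squares change threshold
MAXDEV_TOL = 0.05  # Å², maximum squared node-deviation threshold
N_CONSECUTIVE = 3


@dataclass(frozen=True)
class StringPath:
    """Ordered string nodes with their fit mode and iteration index."""

    nodes: np.ndarray            # (n, 2)
    iteration: int = 0
    fit_mode: str = "spline"     # "spline" | "poly4"

    def __post_init__(self) -> None:
        object.__setattr__(self, "nodes", np.asarray(self.nodes, dtype=float))
        if self.nodes.ndim != 2 or self.nodes.shape[1] != 2:
            raise ValueError("nodes must be an (n, 2) array")
        if self.fit_mode not in ("spline", "poly4"):
            raise ValueError(f"unknown fit mode {self.fit_mode!r}")

    @property
    def n_nodes(self) -> int:
        return self.nodes.shape[0]

    def arclengths(self) -> np.ndarray:
        """Cumulative chord arclength of the node polyline (Å)."""
        seg = np.linalg.norm(np.diff(self.nodes, axis=0), axis=1)
        return np.concatenate([[0.0], np.cumsum(seg)])

    def total_length(self) -> float:
        return float(self.arclengths()[-1])


@dataclass
class ConvergenceRecord:
    """Per-iteration string-change metrics (both in Å²)."""

    ssq_change: list = field(default_factory=list)
    max_deviation: list = field(default_factory=list)
    converged: bool = False

    def append(self, ssq: float, max_dev: float) -> None:
        if ssq < 0 or max_dev < 0:
            raise ValueError("convergence metrics must be non-negative")
        self.ssq_change.append(float(ssq))
        self.max_deviation.append(float(max_dev))

    @property
    def n_iterations(self) -> int:
        return len(self.ssq_change)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "iteration": np.arange(self.n_iterations),
            "ssq_change_A2": self.ssq_change,
            "max_deviation_A2": self.max_deviation,
        })


def init_path(start, end, n_nodes: int, via=None,
              fit_mode: str = "spline") -> StringPath:
    """Equally spaced initial string from ``start`` to ``end``.

    With ``via`` the nodes are spread at equal arclength along the
    two-segment polyline start→via→end; endpoints are kept exactly.
    """
    start = np.asarray(start, dtype=float)
    end = np.asarray(end, dtype=float)
    if n_nodes < 4:
        raise ValueError("need at least 4 nodes")
    if np.allclose(start, end):
        raise ValueError("endpoints must be distinct")
    if via is None:
        frac = np.linspace(0.0, 1.0, n_nodes)[:, None]
        nodes = start + frac * (end - start)
    else:
        via = np.asarray(via, dtype=float)
        l1 = np.linalg.norm(via - start)
        l2 = np.linalg.norm(end - via)
        s = np.linspace(0.0, l1 + l2, n_nodes)
        nodes = np.empty((n_nodes, 2))
        first = s <= l1
        nodes[first] = start + (s[first, None] / l1) * (via - start)
        nodes[~first] = via + ((s[~first, None] - l1) / l2) * (end - via)
        nodes[0], nodes[-1] = start, end
    return StringPath(nodes=nodes, fit_mode=fit_mode)


# ---------------------------------------------------------------------------
# drift estimation
# ---------------------------------------------------------------------------

def estimate_drift(path: StringPath, surface: ModelSurface,
                   window_template: RestraintWindow, seed: int,
                   mode: str = "sample",
                   pin_endpoints: bool = True) -> np.ndarray:
    """Per-node mean displacement of the biased density from the node.

    ``mode="sample"`` draws ``window_template.n_steps`` restrained samples
    per node (one seeded run covering all nodes); ``mode="quadrature"``
    integrates the biased density directly (noise-free drift).  Endpoint
    drifts are zeroed when ``pin_endpoints`` is set.
    """
    k = window_template.force_constants
    if not (50.0 <= min(k) and max(k) <= 200.0):
        warnings.warn(
            f"restraint force constants {k} lie outside the usual "
            "50-200 kcal/mol/A^2 range", stacklevel=2)
    windows = [replace(window_template, center=(float(x), float(y)))
               for x, y in path.nodes]
    if mode == "sample":
        trajs = sample_windows(surface, windows, n=window_template.n_steps,
                               seed=seed)
        means = np.array([t.samples.mean(axis=0) for t in trajs])
    elif mode == "quadrature":
        means = np.array([biased_mean_quadrature(surface, w) for w in windows])
    else:
        raise ValueError(f"unknown drift mode {mode!r}")
    drift = means - path.nodes
    if pin_endpoints:
        drift[0] = 0.0
        drift[-1] = 0.0
    return drift


# ---------------------------------------------------------------------------
# curve fitting and reparameterization
# ---------------------------------------------------------------------------

def _fit_curve(nodes: np.ndarray, fit_mode: str):
    """Fit x(t), y(t) against normalized chord arclength t ∈ [0, 1].

    Returns (curve(t) -> (m, 2), residual): quartic least-squares
    polynomial per coordinate, or an interpolating cubic spline.
    """
    seg = np.linalg.norm(np.diff(nodes, axis=0), axis=1)
    t = np.concatenate([[0.0], np.cumsum(seg)])
    if t[-1] == 0:
        return (lambda s: np.repeat(nodes[:1], np.atleast_1d(s).size, axis=0)), 0.0
    t = t / t[-1]
    if fit_mode == "poly4":
        if nodes.shape[0] < 5:
            raise ValueError("quartic fit needs at least 5 nodes")
        # guard against coincident parameter values (rank deficiency)
        if np.any(np.diff(t) <= 1e-12):
            raise np.linalg.LinAlgError("degenerate node spacing for quartic fit")
        cx = np.polynomial.polynomial.polyfit(t, nodes[:, 0], 4)
        cy = np.polynomial.polynomial.polyfit(t, nodes[:, 1], 4)

        def curve(s):
            s = np.atleast_1d(np.asarray(s, dtype=float))
            return np.stack([np.polynomial.polynomial.polyval(s, cx),
                             np.polynomial.polynomial.polyval(s, cy)], axis=1)

        resid = float(np.sqrt(np.mean(np.sum((curve(t) - nodes) ** 2, axis=1))))
    else:
        # collapse near-coincident nodes; spline needs strictly increasing t
        keep = np.concatenate([[True], np.diff(t) > 1e-12])
        if keep.sum() < 2:
            return (lambda s: np.repeat(nodes[:1], np.atleast_1d(s).size,
                                        axis=0)), 0.0
        spl = CubicSpline(t[keep], nodes[keep], axis=0)

        def curve(s):
            s = np.atleast_1d(np.asarray(s, dtype=float))
            return spl(s)

        resid = 0.0  # interpolating
    return curve, resid


def reparameterize(curve: Callable, n_nodes: int, n_dense: int = 2001,
                   rel_tol: float = 1e-6) -> np.ndarray:
    """Place ``n_nodes`` points at equal arclength along ``curve``.

    ``curve`` maps t ∈ [0, 1] to points (m, 2).  Cumulative arclength is
    accumulated on a dense parameter grid; each target fraction i/(n−1)
    is then bracketed and located by bisection to ``rel_tol`` relative
    arclength.  Curve endpoints are kept exactly.
    """
    ts = np.linspace(0.0, 1.0, n_dense)
    pts = curve(ts)
    if not np.all(np.isfinite(pts)):
        raise ValueError("curve evaluates to non-finite values")
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    total = cum[-1]
    if total == 0:
        return pts[np.zeros(n_nodes, dtype=int)]

    def arclen(t: float) -> float:
        # piecewise-linear interpolation of the cumulative arclength table
        return float(np.interp(t, ts, cum))

    out = np.empty((n_nodes, 2))
    out[0] = curve(0.0)[0]
    out[-1] = curve(1.0)[0]
    for i in range(1, n_nodes - 1):
        target = total * i / (n_nodes - 1)
        lo, hi = 0.0, 1.0
        # bisect well past rel_tol; the extra iterations are negligible
        while (hi - lo) > 1e-14:
            mid = 0.5 * (lo + hi)
            if arclen(mid) < target:
                lo = mid
            else:
                hi = mid
        assert abs(arclen(0.5 * (lo + hi)) - target) <= rel_tol * total
        out[i] = curve(0.5 * (lo + hi))[0]
    return out


def refit_path(path: StringPath, drifts: np.ndarray,
               fit_mode: Optional[str] = None) -> tuple[StringPath, float]:
    """Apply drifts, refit the smooth curve, and re-space the nodes.

    Returns the updated string (same node count, endpoints preserved when
    drifts there are zero) and the RMS fitting residual (0 for the
    interpolating spline).
    """
    mode = fit_mode or path.fit_mode
    updated = path.nodes + np.asarray(drifts, dtype=float)
    curve, resid = _fit_curve(updated, mode)
    nodes = reparameterize(curve, path.n_nodes)
    return StringPath(nodes=nodes, iteration=path.iteration + 1,
                      fit_mode=mode), resid


# ---------------------------------------------------------------------------
# convergence and driver
# ---------------------------------------------------------------------------

def check_convergence(record: ConvergenceRecord, ssq_tol: float = SSQ_TOL,
                      max_tol: float = MAXDEV_TOL,
                      n_consecutive: int = N_CONSECUTIVE) -> bool:
    """True iff both metrics are below threshold for the latest
    ``n_consecutive`` iterations (requires at least that many)."""
    if record.n_iterations < 1:
        raise ValueError("need at least one recorded iteration")
    if record.n_iterations < n_consecutive:
        return False
    tail_ssq = record.ssq_change[-n_consecutive:]
    tail_max = record.max_deviation[-n_consecutive:]
    return all(s < ssq_tol for s in tail_ssq) and all(m < max_tol for m in tail_max)


def run_string(surface: ModelSurface, path: StringPath,
               window_template: RestraintWindow, max_iterations: int = 60,
               seed: int = 0, drift_mode: str = "sample",
               pin_endpoints: bool = True,
               log: Optional[Callable[[str], None]] = None
               ) -> tuple[StringPath, ConvergenceRecord]:
    """Iterate drift estimation → refit → reparameterize to convergence.

    Non-convergence within ``max_iterations`` is reported through the
    record (``converged=False``), not raised.  Per-iteration sampling uses
    an independent child seed derived from ``seed``.
    """
    record = ConvergenceRecord()
    seeds = np.random.SeedSequence(seed).generate_state(max_iterations)
    for it in range(max_iterations):
        drifts = estimate_drift(path, surface, window_template,
                                seed=int(seeds[it] % (2**31)), mode=drift_mode,
                                pin_endpoints=pin_endpoints)
        new_path, _ = refit_path(path, drifts)
        delta = np.sum((new_path.nodes - path.nodes) ** 2, axis=1)
        record.append(float(delta.sum()), float(delta.max()))
        if log is not None:
            log(f"iteration {it}: ssq_change={delta.sum():.3e} A^2, "
                f"max_dev={delta.max():.3e} A^2")
        path = new_path
        if check_convergence(record):
            record.converged = True
            break
    return path, record


def dense_curve(path: StringPath, n_dense: int = 500) -> np.ndarray:
    """Densely sampled fitted curve through the string nodes."""
    curve, _ = _fit_curve(path.nodes, path.fit_mode)
    return curve(np.linspace(0.0, 1.0, n_dense))
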