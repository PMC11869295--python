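"""Trajectory-ensemble statistics for membrane/substrate partitioning.

Operates on :class:`ParticleTrajectory` — frames of labeled 3D positions
in an orthorhombic periodic box, with the membrane normal along z and the
membrane center at z = 0.  Provides the distribution analyses used to
characterize substrate harvesting: axial density profiles with a
core/bulk partition ratio, radial distribution functions about a
reference atom (e.g. heme atom C2D), binding-site occupancies within
distance cutoffs, center-of-mass distance time series with bound/unbound
segmentation, and concentration-dependent redox-potential profiles along
the membrane axis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .rates import RedoxCouple, nernst_shift


@dataclass
class ParticleTrajectory:
    """Frames of labeled particle positions in a periodic box.

    ``positions`` has shape (n_frames, n_particles, 3) in Å; ``species``
    labels each particle; ``box`` holds orthorhombic box lengths.  The
    membrane normal is ``axis`` (default z) with the membrane geometric
    center at coordinate 0.
    """

    positions: np.ndarray
    species: np.ndarray
    box: np.ndarray
    axis: int = 2
    masses: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.species = np.asarray(self.species)
        self.box = np.asarray(self.box, dtype=float)
        if self.positions.ndim != 3 or self.positions.shape[2] != 3:
            raise ValueError("positions must have shape (frames, particles, 3)")
        if self.species.shape[0] != self.positions.shape[1]:
            raise ValueError("one species label per particle required")
        if np.any(self.box <= 0):
            raise ValueError("box lengths must be positive")

    @property
    def n_frames(self) -> int:
        return self.positions.shape[0]

    @property
    def n_particles(self) -> int:
        return self.positions.shape[1]

    def select(self, species: Union[str, Sequence[str]]) -> np.ndarray:
        wanted = [species] if isinstance(species, str) else list(species)
        mask = np.isin(self.species, wanted)
        if not mask.any():
            raise ValueError(f"no particles with species {wanted}")
        return mask


def minimum_image(delta: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Minimum-image displacement vectors in an orthorhombic box."""
    return delta - box * np.round(delta / box)


# ---------------------------------------------------------------------------
# axial density and partitioning
# ---------------------------------------------------------------------------

@dataclass
class AxialDensityProfile:
    z_edges: np.ndarray
    density: np.ndarray        # mean particle count per Å per frame
    partition_ratio: float
    core_half_width: float

    @property
    def z_centers(self) -> np.ndarray:
        return 0.5 * (self.z_edges[:-1] + self.z_edges[1:])


def axial_density(traj: ParticleTrajectory, species: Union[str, Sequence[str]],
                  bin_width: float = 1.0,
                  core_half_width: float = 10.0) -> AxialDensityProfile:
    """Per-frame-normalized density of ``species`` along the membrane normal.

    The partition ratio is the mean density inside the membrane core
    (|z| < ``core_half_width``) over the mean density in the remaining
    bulk region; ≈ 1 for a uniformly distributed species.
    """
    mask = traj.select(species)
    half = traj.box[traj.axis] / 2.0
    z = minimum_image(traj.positions[:, mask, traj.axis], traj.box[traj.axis])
    edges = np.arange(-half, half + bin_width, bin_width)
    hist, _ = np.histogram(z.ravel(), bins=edges)
    density = hist / (traj.n_frames * bin_width)
    centers = 0.5 * (edges[:-1] + edges[1:])
    core = np.abs(centers) < core_half_width
    if not core.any() or core.all():
        raise ValueError("core region must be a strict subset of the box")
    bulk_mean = density[~core].mean()
    ratio = float(density[core].mean() / bulk_mean) if bulk_mean > 0 else np.inf
    return AxialDensityProfile(z_edges=edges, density=density,
                               partition_ratio=ratio,
                               core_half_width=core_half_width)


# ---------------------------------------------------------------------------
# radial distribution
# ---------------------------------------------------------------------------

@dataclass
class RadialDistribution:
    r_edges: np.ndarray
    g: np.ndarray
    reference: np.ndarray
    n_species: int
    box: np.ndarray

    @property
    def r_centers(self) -> np.ndarray:
        return 0.5 * (self.r_edges[:-1] + self.r_edges[1:])

    def peak_position(self) -> float:
        return float(self.r_centers[int(np.argmax(self.g))])

    def coordination_number(self, r_max: Optional[float] = None) -> float:
        """∫ ρ g(r) 4πr² dr up to ``r_max`` (default: full histogram range)."""
        rho = self.n_species / float(np.prod(self.box))
        centers, widths = self.r_centers, np.diff(self.r_edges)
        keep = centers <= (r_max if r_max is not None else self.r_edges[-1])
        shell = 4.0 * np.pi * centers[keep] ** 2 * widths[keep]
        return float(np.sum(rho * self.g[keep] * shell))


def radial_distribution(traj: ParticleTrajectory,
                        species: Union[str, Sequence[str]],
                        reference, bin_width: float = 0.25,
                        r_max: Optional[float] = None) -> RadialDistribution:
    """Shell-volume-normalized g(r) of ``species`` about a reference point.

    ``reference`` is either a fixed 3-vector or a species label whose
    (single) particle provides a per-frame center.  For an ideal gas the
    profile is ≈ 1 at all radii.
    """
    mask = traj.select(species)
    if isinstance(reference, str):
        ref_mask = traj.select(reference)
        ref = traj.positions[:, ref_mask, :].mean(axis=1)
    else:
        ref = np.broadcast_to(np.asarray(reference, dtype=float),
                              (traj.n_frames, 3))
    if r_max is None:
        r_max = float(traj.box.min()) / 2.0
    delta = minimum_image(traj.positions[:, mask, :] - ref[:, None, :], traj.box)
    r = np.linalg.norm(delta, axis=2).ravel()
    edges = np.arange(0.0, r_max + bin_width, bin_width)
    hist, _ = np.histogram(r, bins=edges)
    shell_vol = 4.0 / 3.0 * np.pi * (edges[1:] ** 3 - edges[:-1] ** 3)
    n_sp = int(mask.sum())
    rho = n_sp / float(np.prod(traj.box))
    g = hist / (traj.n_frames * shell_vol * rho)
    return RadialDistribution(r_edges=edges, g=g, reference=ref[0],
                              n_species=n_sp, box=traj.box)


# ---------------------------------------------------------------------------
# site occupancy
# ---------------------------------------------------------------------------

@dataclass
class OccupancyReport:
    """Binding-site occupancies under two conventions.

    ``frame_fraction`` — fraction of frames with at least one species
    particle within the cutoff; ``species_fraction`` — mean fraction of
    all species particles found within the cutoff per frame.
    """

    table: pd.DataFrame  # columns: site, cutoff, frame_fraction, species_fraction

    def __post_init__(self) -> None:
        for col in ("frame_fraction", "species_fraction"):
            vals = self.table[col].to_numpy()
            if np.any((vals < 0) | (vals > 1)):
                raise ValueError(f"{col} outside [0, 1]")


def site_occupancy(traj: ParticleTrajectory, species: Union[str, Sequence[str]],
                   sites: dict, cutoffs: Union[float, dict]) -> OccupancyReport:
    """Occupancy of named binding sites within distance cutoffs (Å).

    ``sites`` maps site name → fixed 3-vector position (a decoy/control
    site far from any genuine cluster gives the random-diffusion
    baseline).  ``cutoffs`` is a single cutoff or a per-site mapping.
    """
    mask = traj.select(species)
    pos = traj.positions[:, mask, :]
    rows = []
    for name, center in sites.items():
        cut = cutoffs[name] if isinstance(cutoffs, dict) else float(cutoffs)
        delta = minimum_image(pos - np.asarray(center, dtype=float), traj.box)
        within = np.linalg.norm(delta, axis=2) <= cut
        rows.append({
            "site": name, "cutoff": cut,
            "frame_fraction": float(within.any(axis=1).mean()),
            "species_fraction": float(within.mean()),
        })
    return OccupancyReport(table=pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# center-of-mass distances
# ---------------------------------------------------------------------------

@dataclass
class DistanceSeries:
    distances: np.ndarray
    bound: Optional[np.ndarray] = None
    segments: Optional[list] = None  # list of (start, stop_exclusive, is_bound)


def com_distance_series(traj: ParticleTrajectory, group_a, group_b,
                        bound_threshold: Optional[float] = None) -> DistanceSeries:
    """Minimum-image distance between mass-weighted group centers per frame.

    With ``bound_threshold`` (Å) frames are segmented into contiguous
    bound (< threshold) / unbound runs.
    """

    def com(group):
        mask = traj.select(group)
        p = traj.positions[:, mask, :]
        if traj.masses is not None:
            m = traj.masses[mask]
            return (p * m[None, :, None]).sum(axis=1) / m.sum()
        return p.mean(axis=1)

    delta = minimum_image(com(group_a) - com(group_b), traj.box)
    d = np.linalg.norm(delta, axis=1)
    if bound_threshold is None:
        return DistanceSeries(distances=d)
    bound = d < bound_threshold
    segments = []
    start = 0
    for i in range(1, len(bound) + 1):
        if i == len(bound) or bound[i] != bound[start]:
            segments.append((start, i, bool(bound[start])))
            start = i
    return DistanceSeries(distances=d, bound=bound, segments=segments)


# ---------------------------------------------------------------------------
# concentration-shifted potential profile
# ---------------------------------------------------------------------------

@dataclass
class PotentialProfile:
    z_centers: np.ndarray
    potential_mv: np.ndarray   # NaN where either species is absent
    valid: np.ndarray


def potential_shift_profile(reduced: AxialDensityProfile,
                            oxidized: AxialDensityProfile,
                            em_mv: float) -> PotentialProfile:
    """Nernst-shifted redox potential along the membrane axis.

    Applies the concentration correction bin-wise to the local
    reduced/oxidized density ratio; bins lacking either species are
    flagged invalid rather than extrapolated.
    """
    if not np.array_equal(reduced.z_edges, oxidized.z_edges):
        raise ValueError("density profiles must share their z grid")
    valid = (reduced.density > 0) & (oxidized.density > 0)
    pot = np.full(reduced.density.shape, np.nan)
    for i in np.nonzero(valid)[0]:
        couple = RedoxCouple("profile", em_mv,
                             conc_red=float(reduced.density[i]),
                             conc_ox=float(oxidized.density[i]))
        pot[i] = nernst_shift(couple)
    return PotentialProfile(z_centers=reduced.z_centers, potential_mv=pot,
                            valid=valid)
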