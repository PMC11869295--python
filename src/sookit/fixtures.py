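"""Seeded synthetic trajectories with planted ensemble statistics.

Every generator returns a :class:`~sookit.ensemble.ParticleTrajectory`
whose target statistic (membrane partition ratio, RDF peak position,
site dwell fraction, telegraph binding switch points) is known by
construction, so the corresponding estimator can be validated against
exact ground truth.  These fixtures emulate the distributional features
of membrane MD — partitioning, clustering around a reference atom,
transient site binding — not its dynamics or interactions.
"""

from __future__ import annotations

import numpy as np

from .ensemble import ParticleTrajectory


def _rng(seed: int) -> np.random.Generator:
    return np.random.Generator(np.random.PCG64(seed))


def partition_fixture(n_particles: int = 10_000, n_frames: int = 1,
                      box=(100.0, 100.0, 100.0), core_half_width: float = 10.0,
                      ratio: float = 12.0, species: str = "O2",
                      seed: int = 0) -> ParticleTrajectory:
    """Particles partitioned between membrane core and bulk.

    z is drawn from a piecewise-uniform density that is ``ratio`` times
    higher inside |z| < ``core_half_width`` than outside, emulating a
    hydrophobic species enriched in the membrane core.
    """
    rng = _rng(seed)
    box = np.asarray(box, dtype=float)
    half = box[2] / 2.0
    core_len = 2.0 * core_half_width
    bulk_len = box[2] - core_len
    p_core = ratio * core_len / (ratio * core_len + bulk_len)
    pos = rng.uniform(-box / 2.0, box / 2.0, size=(n_frames, n_particles, 3))
    in_core = rng.random((n_frames, n_particles)) < p_core
    z_core = rng.uniform(-core_half_width, core_half_width,
                         size=(n_frames, n_particles))
    z_bulk_mag = rng.uniform(core_half_width, half, size=(n_frames, n_particles))
    z_bulk = np.where(rng.random((n_frames, n_particles)) < 0.5,
                      z_bulk_mag, -z_bulk_mag)
    pos[..., 2] = np.where(in_core, z_core, z_bulk)
    return ParticleTrajectory(positions=pos,
                              species=np.array([species] * n_particles),
                              box=box)


def rdf_shell_fixture(n_gas: int = 2000, n_shell: int = 2000,
                      peak_r: float = 9.0, shell_width: float = 0.5,
                      box=(60.0, 60.0, 60.0), n_frames: int = 5,
                      species: str = "SUP", seed: int = 0) -> ParticleTrajectory:
    """Uniform gas plus a Gaussian radial shell of particles at ``peak_r``
    around the box center, planting an RDF peak at a known radius."""
    rng = _rng(seed)
    box = np.asarray(box, dtype=float)
    gas = rng.uniform(-box / 2.0, box / 2.0, size=(n_frames, n_gas, 3))
    direction = rng.standard_normal((n_frames, n_shell, 3))
    direction /= np.linalg.norm(direction, axis=2, keepdims=True)
    radius = rng.normal(peak_r, shell_width, size=(n_frames, n_shell, 1))
    shell = direction * np.abs(radius)
    pos = np.concatenate([gas, shell], axis=1)
    return ParticleTrajectory(positions=pos,
                              species=np.array([species] * (n_gas + n_shell)),
                              box=box)


def dwell_fixture(site=(10.0, 0.0, 0.0), cutoff: float = 5.0,
                  dwell_fraction: float = 0.4, n_frames: int = 5000,
                  box=(80.0, 80.0, 80.0), species: str = "SUP",
                  seed: int = 0) -> ParticleTrajectory:
    """Single particle dwelling at a binding site a known fraction of frames.

    Each frame independently places the particle uniformly inside the
    cutoff sphere with probability ``dwell_fraction``, else uniformly in
    the box outside the sphere (emulating the ~40% occupancy of the
    superoxide-collecting site).
    """
    rng = _rng(seed)
    box = np.asarray(box, dtype=float)
    site = np.asarray(site, dtype=float)
    inside = rng.random(n_frames) < dwell_fraction
    # uniform in sphere
    u = rng.standard_normal((n_frames, 3))
    u /= np.linalg.norm(u, axis=1, keepdims=True)
    r = cutoff * 0.99 * rng.random(n_frames) ** (1.0 / 3.0)
    sphere = site + u * r[:, None]
    outside = np.empty((n_frames, 3))
    need = np.ones(n_frames, dtype=bool)
    while need.any():
        cand = rng.uniform(-box / 2.0, box / 2.0, size=(int(need.sum()), 3))
        ok = np.linalg.norm(cand - site, axis=1) > cutoff
        idx = np.nonzero(need)[0][ok]
        outside[idx] = cand[ok]
        need[idx] = False
    pos = np.where(inside[:, None], sphere, outside)[:, None, :]
    return ParticleTrajectory(positions=pos, species=np.array([species]),
                              box=box)


def telegraph_fixture(d_bound: float = 8.0, d_unbound: float = 20.0,
                      segment_length: int = 50, n_frames: int = 500,
                      box=(80.0, 80.0, 80.0)) -> ParticleTrajectory:
    """Two single-particle groups alternating between two exact separations.

    The center-of-mass distance flips between ``d_bound`` and
    ``d_unbound`` every ``segment_length`` frames (a telegraph signal),
    so bound/unbound segmentation has exact known switch points.
    """
    box = np.asarray(box, dtype=float)
    a = np.zeros((n_frames, 1, 3))
    b = np.zeros((n_frames, 1, 3))
    blocks = (np.arange(n_frames) // segment_length) % 2
    b[:, 0, 0] = np.where(blocks == 0, d_bound, d_unbound)
    pos = np.concatenate([a, b], axis=1)
    return ParticleTrajectory(positions=pos, species=np.array(["Q", "HEM1"]),
                              box=box)
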