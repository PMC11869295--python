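"""File input/output: biased-trajectory CSV/HDF5, landscape export, and
structure/trajectory readers for standard formats (PDB/XYZ/DCD via
MDAnalysis)."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Sequence, Union

import h5py
import numpy as np
import pandas as pd

from .ensemble import ParticleTrajectory
from .fes import FreeEnergyLandscape
from .surfaces import BiasedTrajectory, RestraintWindow


# ---------------------------------------------------------------------------
# biased window trajectories
# ---------------------------------------------------------------------------

def write_trajectory_csv(traj: BiasedTrajectory, path) -> None:
    df = pd.DataFrame({
        "step": np.arange(traj.n_samples),
        "RC1": traj.samples[:, 0],
        "RC2": traj.samples[:, 1],
    })
    df.to_csv(path, index=False)


def read_trajectory_csv(path, window: Optional[RestraintWindow] = None,
                        seed: int = -1) -> BiasedTrajectory:
    df = pd.read_csv(path)
    samples = df[["RC1", "RC2"]].to_numpy()
    if window is None:
        window = RestraintWindow(center=tuple(samples.mean(axis=0)))
    return BiasedTrajectory(window=window, samples=samples, seed=seed,
                            step_size=float("nan"))


def write_windows_h5(trajectories: Sequence[BiasedTrajectory], path) -> None:
    """All windows of one sampling stage into a single HDF5 file."""
    with h5py.File(path, "w") as f:
        for i, t in enumerate(trajectories):
            g = f.create_group(f"window_{i:04d}")
            g.create_dataset("samples", data=t.samples)
            g.attrs["center"] = t.window.center
            g.attrs["force_constants"] = t.window.force_constants
            g.attrs["temperature"] = t.window.temperature
            g.attrs["seed"] = t.seed
            g.attrs["step_size"] = t.step_size


def read_windows_h5(path) -> list:
    out = []
    with h5py.File(path, "r") as f:
        for name in sorted(f.keys()):
            g = f[name]
            window = RestraintWindow(
                center=tuple(g.attrs["center"]),
                force_constants=tuple(g.attrs["force_constants"]),
                temperature=float(g.attrs["temperature"]))
            out.append(BiasedTrajectory(
                window=window, samples=g["samples"][...],
                seed=int(g.attrs["seed"]), step_size=float(g.attrs["step_size"])))
    return out


# ---------------------------------------------------------------------------
# landscapes
# ---------------------------------------------------------------------------

def write_landscape_text(landscape: FreeEnergyLandscape, path) -> None:
    Path(path).write_text(landscape.to_matrix_text())


def write_landscape_h5(landscape: FreeEnergyLandscape, path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("x_edges", data=landscape.x_edges)
        f.create_dataset("y_edges", data=landscape.y_edges)
        f.create_dataset("values", data=landscape.values)
        f.create_dataset("occupied", data=landscape.occupied)
        if landscape.uncertainty is not None:
            f.create_dataset("uncertainty", data=landscape.uncertainty)
        f.attrs["estimator"] = landscape.estimator


def read_landscape_h5(path) -> FreeEnergyLandscape:
    with h5py.File(path, "r") as f:
        return FreeEnergyLandscape(
            x_edges=f["x_edges"][...], y_edges=f["y_edges"][...],
            values=f["values"][...], occupied=f["occupied"][...],
            estimator=str(f.attrs["estimator"]),
            uncertainty=f["uncertainty"][...] if "uncertainty" in f else None)


# ---------------------------------------------------------------------------
# particle trajectories (standard structure formats)
# ---------------------------------------------------------------------------

def load_particle_trajectory(topology, trajectory=None, axis: int = 2,
                             species_attr: str = "names") -> ParticleTrajectory:
    """Read a trajectory through MDAnalysis (PDB/XYZ/DCD and friends).

    ``species_attr`` selects which atom attribute labels the species
    ("names" or "resnames").  The box is taken from the first frame; a
    missing box falls back to the coordinate bounding extent.
    """
    import MDAnalysis as mda

    u = mda.Universe(str(topology)) if trajectory is None else \
        mda.Universe(str(topology), str(trajectory))
    frames = np.array([u.atoms.positions.copy() for _ in u.trajectory],
                      dtype=float)
    labels = np.asarray(getattr(u.atoms, species_attr))
    dims = u.dimensions
    if dims is not None and np.all(dims[:3] > 0):
        box = np.asarray(dims[:3], dtype=float)
    else:
        box = np.ptp(frames.reshape(-1, 3), axis=0) + 1.0
    masses = None
    try:
        masses = np.asarray(u.atoms.masses, dtype=float)
        if not np.all(masses > 0):
            masses = None
    except Exception:
        masses = None
    return ParticleTrajectory(positions=frames, species=labels, box=box,
                              axis=axis, masses=masses)


def write_particle_trajectory_xyz(traj: ParticleTrajectory, path) -> None:
    """Plain multi-frame XYZ export (element column = species label)."""
    with open(path, "w") as fh:
        for f in range(traj.n_frames):
            fh.write(f"{traj.n_particles}\nframe {f}\n")
            for sp, (x, y, z) in zip(traj.species, traj.positions[f]):
                fh.write(f"{sp} {x:.4f} {y:.4f} {z:.4f}\n")


# ---------------------------------------------------------------------------
# misc
# ---------------------------------------------------------------------------

def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
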