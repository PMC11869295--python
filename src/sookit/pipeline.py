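"""End-to-end orchestration: surrogate surface → string → free-energy
landscape → barrier → TST rate → charge-transfer network → turnover.

A :class:`RunConfig` (JSON, schema-validated, unknown keys rejected)
drives the pipeline deterministically: the global seed is split into one
child seed per stage, every stage writes its outputs under the run
directory, and the run manifest records inputs, seeds, per-stage results
and SHA-256 checksums of every written file.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Literal, Optional

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, ValidationError

from . import __version__
from . import io as sio
from .fes import ESTIMATORS, WindowSet, path_barrier
from .kinetics import build_soo_network, turnover
from .rates import default_soo_steps, rate_table, tst_rate
from .string_method import StringPath, init_path, run_string
from .surfaces import RestraintWindow, make_surface, sample_windows


class _Section(BaseModel):
    model_config = ConfigDict(extra="forbid")


class SurfaceConfig(_Section):
    preset: str = "pcet-double-well"
    barrier: float = 12.0
    delta_g: float = 7.5
    alt_barrier: float = 15.0
    k: float = 1.0  # harmonic-well only


class StringConfig(_Section):
    n_nodes: int = 19
    start: tuple[float, float] = (-0.8, -0.8)
    end: tuple[float, float] = (0.8, 0.8)
    via: Optional[tuple[float, float]] = None
    fit_mode: Literal["spline", "poly4"] = "spline"
    force_constant: float = Field(200.0, gt=0)
    n_steps: int = Field(150, ge=1)
    max_iterations: int = 60
    drift_mode: Literal["sample", "quadrature"] = "sample"


class FesConfig(_Section):
    estimators: list[Literal["wham", "mbar", "vfep"]] = ["wham", "mbar", "vfep"]
    samples_per_window: int = Field(1000, ge=10)
    force_constant: float = Field(200.0, gt=0)
    bins: int = Field(100, ge=10)


class KineticsConfig(_Section):
    delivery_rate: float = Field(1e8, gt=0)
    barrier_estimator: Literal["wham", "mbar", "vfep"] = "wham"


class RunConfig(_Section):
    seed: int = 1
    surface: SurfaceConfig = SurfaceConfig()
    string: StringConfig = StringConfig()
    fes: FesConfig = FesConfig()
    kinetics: KineticsConfig = KineticsConfig()

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        try:
            return cls.model_validate_json(Path(path).read_text())
        except ValidationError as err:
            lines = [f"{'.'.join(str(p) for p in e['loc'])}: {e['msg']}"
                     for e in err.errors()]
            raise ValueError("invalid run config:\n  " + "\n  ".join(lines)) from err

    def to_json(self) -> str:
        return self.model_dump_json(indent=2)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _surface_kwargs(cfg: SurfaceConfig) -> dict:
    if cfg.preset == "pcet-double-well":
        return {"barrier": cfg.barrier, "delta_g": cfg.delta_g,
                "alt_barrier": cfg.alt_barrier}
    if cfg.preset == "harmonic-well":
        return {"k": cfg.k}
    return {}


def run_pipeline(config: RunConfig, out_dir) -> dict:
    """Execute all stages; returns (and writes) the run manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage_seeds = [int(s) for s in
                   np.random.SeedSequence(config.seed).generate_state(4) % (2**31)]
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "stage_seeds": {"string": stage_seeds[0], "fes": stage_seeds[1]},
        "config": json.loads(config.to_json()),
        "stages": {},
        "files": {},
    }
    files: list[Path] = []

    def record(stage: str, **results) -> None:
        manifest["stages"][stage] = results

    try:
        # 1 — surface
        surface = make_surface(config.surface.preset,
                               **_surface_kwargs(config.surface))
        record("surface", preset=surface.label)

        # 2 — string optimization
        s = config.string
        path0 = init_path(s.start, s.end, s.n_nodes, via=s.via,
                          fit_mode=s.fit_mode)
        template = RestraintWindow(center=(0.0, 0.0),
                                   force_constants=(s.force_constant,) * 2,
                                   n_steps=s.n_steps)
        path, rec = run_string(surface, path0, template,
                               max_iterations=s.max_iterations,
                               seed=stage_seeds[0], drift_mode=s.drift_mode)
        conv_csv = out / "string_convergence.csv"
        rec.to_frame().to_csv(conv_csv, index=False)
        nodes_csv = out / "string_nodes.csv"
        np.savetxt(nodes_csv, path.nodes, delimiter=",", header="RC1,RC2",
                   comments="")
        files += [conv_csv, nodes_csv]
        record("string", converged=rec.converged, iterations=rec.n_iterations,
               final_ssq=rec.ssq_change[-1], n_nodes=path.n_nodes)

        # 3 — biased sampling along the converged string
        fcfg = config.fes
        windows = [RestraintWindow(center=(float(x), float(y)),
                                   force_constants=(fcfg.force_constant,) * 2)
                   for x, y in path.nodes]
        trajs = sample_windows(surface, windows, fcfg.samples_per_window,
                               seed=stage_seeds[1])
        win_h5 = out / "windows.h5"
        sio.write_windows_h5(trajs, win_h5)
        files.append(win_h5)
        record("sampling", n_windows=len(trajs),
               samples_per_window=fcfg.samples_per_window)

        # 4 — free-energy landscapes and barriers
        ws = WindowSet(trajs)
        barriers = {}
        for name in fcfg.estimators:
            land = ESTIMATORS[name](ws, bins=fcfg.bins)
            text_path = out / f"landscape_{name}.txt"
            sio.write_landscape_text(land, text_path)
            files.append(text_path)
            b, dg = path_barrier(land, path)
            barriers[name] = {"barrier_kcal": b, "delta_g_kcal": dg}
        record("fes", **barriers)

        # 5 — rates and kinetic network
        kcfg = config.kinetics
        est = barriers[kcfg.barrier_estimator]
        pcet = tst_rate(est["barrier_kcal"])
        table = rate_table(default_soo_steps())
        rates_csv = out / "rate_table.csv"
        table.to_csv(rates_csv, index=False)
        files.append(rates_csv)
        network = build_soo_network(table, pcet_rate=pcet,
                                    delivery_rate=kcfg.delivery_rate)
        result = turnover(network)
        flux_csv = out / "flux.csv"
        result.flux.to_csv(flux_csv, index=False)
        files.append(flux_csv)
        record("kinetics", pcet_rate_per_s=pcet, t_half_s=result.t_half,
               turnover_per_s=result.turnover)
    except Exception as err:  # halt with partial manifest
        manifest["error"] = f"{type(err).__name__}: {err}"
        manifest["files"] = {str(p.name): _sha256(p) for p in files}
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        raise

    manifest["files"] = {str(p.name): _sha256(p) for p in files}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
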