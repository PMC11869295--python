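"""Shared fixtures: calibrated surfaces, oracle topographies, and the
(expensive) converged-string window samples reused across test modules."""

import numpy as np
import pytest

from sookit import fes, string_method as sm, surfaces, topology


@pytest.fixture(scope="session")
def pcet_surface():
    return surfaces.make_surface("pcet-double-well")


@pytest.fixture(scope="session")
def pcet_oracle(pcet_surface):
    """Ground-truth topography of the calibrated double well, from the
    dense-grid/Newton stationary-point search (independent of sampling)."""
    points = topology.find_stationary_points(pcet_surface)
    minima = [p for p in points if p.kind == "minimum"]
    saddles = [p for p in points if p.kind == "saddle"]
    reactant = min(minima, key=lambda p: p.energy)
    product = max(minima, key=lambda p: p.energy)
    saddle = saddles[0]
    return {
        "reactant": reactant,
        "product": product,
        "saddle": saddle,
        "barrier": saddle.energy - reactant.energy,
        "delta_g": product.energy - reactant.energy,
        "alt_barrier": float(
            pcet_surface.energy(np.array([0.8, -0.8])) - reactant.energy),
    }


@pytest.fixture(scope="session")
def mb_surface():
    return surfaces.make_surface("mueller-brown")


@pytest.fixture(scope="session")
def mb_oracle(mb_surface):
    points = topology.find_stationary_points(mb_surface)
    minima = [p.point for p in points if p.kind == "minimum"]
    saddles = [p.point for p in points if p.kind == "saddle"]
    a = max(minima, key=lambda p: p[1])
    c = min(minima, key=lambda p: p[1])
    b = [p for p in minima
         if not (np.allclose(p, a) or np.allclose(p, c))][0]
    return {"minima": {"A": a, "B": b, "C": c}, "saddles": saddles}


@pytest.fixture(scope="session")
def window_template():
    return surfaces.RestraintWindow(center=(0.0, 0.0),
                                    force_constants=(200.0, 200.0),
                                    n_steps=150)


@pytest.fixture(scope="session")
def pcet_string(pcet_surface, pcet_oracle, window_template):
    """Converged 19-node string on the double well, stochastic drift."""
    path0 = sm.init_path(pcet_oracle["reactant"].point,
                         pcet_oracle["product"].point, 19)
    path, record = sm.run_string(pcet_surface, path0, window_template,
                                 seed=1, drift_mode="sample")
    assert record.converged
    return path


@pytest.fixture(scope="session")
def pcet_window_trajs(pcet_surface, pcet_string):
    """5000 biased samples in each of the 19 windows along the string."""
    windows = [surfaces.RestraintWindow(center=(float(x), float(y)),
                                        force_constants=(200.0, 200.0))
               for x, y in pcet_string.nodes]
    return surfaces.sample_windows(pcet_surface, windows, 5000, seed=7)


@pytest.fixture(scope="session")
def pcet_edges(pcet_window_trajs):
    return fes._auto_edges(pcet_window_trajs, fes.DEFAULT_BINS)


@pytest.fixture(scope="session")
def pcet_landscapes(pcet_window_trajs, pcet_edges):
    ws = fes.WindowSet(pcet_window_trajs)
    return {
        "wham": fes.wham2d(ws, edges=pcet_edges),
        "mbar": fes.mbar_fes(ws, edges=pcet_edges),
        "vfep": fes.variational_profile(ws, edges=pcet_edges),
    }
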