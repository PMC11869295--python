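"""Electron-transfer rates and redox thermodynamics.

Implements the empirical Moser–Dutton tunneling ruler for cofactor-to-
cofactor electron transfer, transition-state-theory conversion between
free-energy barriers and rate constants, and Nernst arithmetic for
concentration-shifted redox potentials and driving forces.

The ruler used here is the standard exergonic form

    log10 k = 13 − (1.2 − 0.8 ρ) (R − 3.6) − 3.1 (ΔG + λ)² / λ

with the edge-to-edge distance R in Å, the driving force ΔG and
reorganization energy λ in eV, and the protein packing density ρ
dimensionless.  The same quadratic Marcus term is applied on the
endergonic branch.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple, Optional

import numpy as np
import pandas as pd

from .constants import (
    EV_TO_KCAL,
    FARADAY_KCAL_PER_V,
    NERNST_MV_PER_DECADE,
    T_DEFAULT,
    TST_PREFACTOR,
    kbt,
)

#: van der Waals contact distance (Å) at which the tunneling penalty vanishes.
CONTACT_DISTANCE = 3.6


@dataclass(frozen=True)
class ETStep:
    """A single electron-tunneling step between two cofactors.

    Parameters
    ----------
    donor, acceptor:
        Labels of the redox centers.
    r_edge:
        Edge-to-edge distance in Å (heavy atoms, ≥ 3.6 Å).
    lam:
        Marcus reorganization energy λ in eV (> 0).
    rho:
        Packing density of the intervening protein medium, in [0, 1].
    delta_g:
        Driving force ΔG in eV; negative values are exergonic.
    """

    donor: str
    acceptor: str
    r_edge: float
    lam: float = 0.7
    rho: float = 0.76
    delta_g: float = 0.0

    def __post_init__(self) -> None:
        if self.r_edge < CONTACT_DISTANCE:
            raise ValueError(
                f"edge-to-edge distance must be >= {CONTACT_DISTANCE} Å, got {self.r_edge}"
            )
        if self.lam <= 0:
            raise ValueError(f"reorganization energy must be positive, got {self.lam}")
        if not 0.0 <= self.rho <= 1.0:
            raise ValueError(f"packing density must lie in [0, 1], got {self.rho}")


@dataclass(frozen=True)
class RedoxCouple:
    """A redox couple with midpoint potential and optional concentrations.

    ``em_mv`` is the midpoint potential in mV vs NHE.  ``conc_red`` and
    ``conc_ox`` (mol/L) are only needed for Nernst concentration shifts.
    """

    name: str
    em_mv: float
    conc_red: Optional[float] = None
    conc_ox: Optional[float] = None

    def __post_init__(self) -> None:
        for label, c in (("conc_red", self.conc_red), ("conc_ox", self.conc_ox)):
            if c is not None and c <= 0:
                raise ValueError(f"{label} must be positive when set, got {c}")


class DrivingForce(NamedTuple):
    kcal: float
    ev: float


def moser_dutton_log10(step: ETStep) -> float:
    """log10 of the tunneling rate (k in s⁻¹) for one ET step."""
    distance_term = (1.2 - 0.8 * step.rho) * (step.r_edge - CONTACT_DISTANCE)
    marcus_term = 3.1 * (step.delta_g + step.lam) ** 2 / step.lam
    return 13.0 - distance_term - marcus_term


def moser_dutton_rate(step: ETStep) -> float:
    """Electron tunneling rate (s⁻¹) from the Moser–Dutton ruler."""
    return 10.0 ** moser_dutton_log10(step)


def tst_rate(barrier: float, temperature: float = T_DEFAULT,
             prefactor: float = TST_PREFACTOR) -> float:
    """Rate constant k = k₀ exp(−ΔG‡ / kBT) for a free-energy barrier.

    ``barrier`` is ΔG‡ in kcal/mol (≥ 0); ``prefactor`` defaults to
    kBT/h = 6 ps⁻¹.  Barrier-recrossing corrections are neglected.
    """
    if barrier < 0:
        raise ValueError(f"barrier must be non-negative, got {barrier}")
    return prefactor * math.exp(-barrier / kbt(temperature))


def tst_barrier(rate: float, temperature: float = T_DEFAULT,
                prefactor: float = TST_PREFACTOR) -> float:
    """Invert :func:`tst_rate`: ΔG‡ (kcal/mol) that reproduces ``rate``."""
    if not 0 < rate <= prefactor:
        raise ValueError(
            f"rate must satisfy 0 < rate <= prefactor ({prefactor:g} s^-1), got {rate}"
        )
    return kbt(temperature) * math.log(prefactor / rate)


def nernst_shift(couple: RedoxCouple,
                 mv_per_decade: float = NERNST_MV_PER_DECADE) -> float:
    """Concentration-corrected effective potential (mV) of a couple.

        E = E_m − (59 mV) · log10([reduced] / [oxidized])

    Depleting the reduced species therefore raises the effective
    potential (e.g. scarce superoxide upshifts the O₂/O₂•⁻ couple).
    """
    if couple.conc_red is None or couple.conc_ox is None:
        raise ValueError(
            f"couple {couple.name!r} needs both concentrations for a Nernst shift"
        )
    return couple.em_mv - mv_per_decade * math.log10(couple.conc_red / couple.conc_ox)


def driving_force(donor: RedoxCouple, acceptor: RedoxCouple,
                  n_electrons: int = 1, effective: bool = False) -> DrivingForce:
    """Thermodynamic driving force ΔG = −n·F·(E_acceptor − E_donor).

    Returns ΔG both in kcal/mol and eV; negative values are downhill.
    With ``effective=True`` concentration-shifted potentials are used for
    any couple that carries concentrations.
    """

    def potential(c: RedoxCouple) -> float:
        if effective and c.conc_red is not None and c.conc_ox is not None:
            return nernst_shift(c)
        return c.em_mv

    delta_e_v = (potential(acceptor) - potential(donor)) / 1000.0
    dg_ev = -n_electrons * delta_e_v
    return DrivingForce(kcal=dg_ev * FARADAY_KCAL_PER_V, ev=dg_ev)


# ---------------------------------------------------------------------------
# tabular interface (CSV in, CSV out) used by the CLI and the kinetic model
# ---------------------------------------------------------------------------

def load_steps_csv(path) -> list[ETStep]:
    """Read ET steps from CSV columns donor, acceptor, R, lambda, rho, dG_eV."""
    df = pd.read_csv(path)
    return [
        ETStep(donor=row["donor"], acceptor=row["acceptor"], r_edge=row["R"],
               lam=row["lambda"], rho=row["rho"], delta_g=row["dG_eV"])
        for _, row in df.iterrows()
    ]


def load_couples_csv(path) -> list[RedoxCouple]:
    """Read redox couples from CSV columns name, Em_mV, conc_red, conc_ox."""
    df = pd.read_csv(path)
    couples = []
    for _, row in df.iterrows():
        conc_red = row.get("conc_red")
        conc_ox = row.get("conc_ox")
        couples.append(RedoxCouple(
            name=row["name"], em_mv=row["Em_mV"],
            conc_red=None if pd.isna(conc_red) else float(conc_red),
            conc_ox=None if pd.isna(conc_ox) else float(conc_ox)))
    return couples


def rate_table(steps: list[ETStep]) -> pd.DataFrame:
    """Moser–Dutton rates for a list of steps, as a tidy DataFrame."""
    rows = [{
        "donor": s.donor, "acceptor": s.acceptor, "R": s.r_edge,
        "lambda": s.lam, "rho": s.rho, "dG_eV": s.delta_g,
        "log10_k": moser_dutton_log10(s), "k_per_s": moser_dutton_rate(s),
    } for s in steps]
    return pd.DataFrame(rows)


def default_soo_steps() -> list[ETStep]:
    """The three ET steps of the superoxide oxidase cycle with the
    measured/estimated midpoint potentials (superoxide 0 mV, hemes −8/+100 mV,
    quinone +90 mV) and the standard λ = 0.7 eV, ρ = 0.76."""
    sup = RedoxCouple("superoxide", 0.0)
    heme2 = RedoxCouple("heme2", -8.0)
    heme1 = RedoxCouple("heme1", 100.0)
    q = RedoxCouple("Q", 90.0)
    return [
        ETStep("superoxide", "heme2", r_edge=9.0,
               delta_g=driving_force(sup, heme2).ev),
        ETStep("heme2", "heme1", r_edge=11.0,
               delta_g=driving_force(heme2, heme1).ev),
        ETStep("heme1", "Q", r_edge=6.0,
               delta_g=driving_force(heme1, q).ev),
    ]
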