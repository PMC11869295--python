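"""Master-equation kinetics of the superoxide→quinol charge-transfer cycle.

The network couples the two heme redox states with the quinone species
(Q, semiquinone Q•⁻, quinol QH₂).  Each elementary transition carries a
forward rate (s⁻¹); reversible transitions get their reverse rate from
detailed balance against the supplied ΔG, while the final proton-coupled
electron transfer that forms QH₂ is irreversible (the quinol unbinds and
dissociates to the membrane pool).  State probabilities evolve by

    dP_i/dt = Σ_j (k_ji P_j − k_ij P_i)

and the overall turnover is k = ln 2 / t_1/2 of QH₂ formation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .constants import T_DEFAULT, EV_TO_KCAL, kbt
from .rates import ETStep, moser_dutton_rate


@dataclass
class KineticNetwork:
    """Labeled continuous-time Markov network of the catalytic cycle.

    ``rates[i, j]`` is the first-order rate constant (s⁻¹) for the
    transition ``states[i] → states[j]``.  ``irreversible`` lists (i, j)
    pairs whose reverse rate is structurally zero.  ``delta_g`` optionally
    records the reaction free energy (kcal/mol) of reversible pairs for
    detailed-balance auditing.
    """

    states: list[str]
    rates: np.ndarray
    irreversible: set = field(default_factory=set)
    p0: Optional[np.ndarray] = None
    delta_g: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.rates = np.asarray(self.rates, dtype=float)
        n = len(self.states)
        if self.rates.shape != (n, n):
            raise ValueError(f"rate matrix must be {n}x{n}, got {self.rates.shape}")
        if np.any(self.rates < 0):
            raise ValueError("all rates must be non-negative")
        if self.p0 is None:
            self.p0 = np.zeros(n)
            self.p0[0] = 1.0
        self.p0 = np.asarray(self.p0, dtype=float)
        if abs(self.p0.sum() - 1.0) > 1e-12 or np.any(self.p0 < 0):
            raise ValueError("initial probabilities must be non-negative and sum to 1")

    @property
    def n_states(self) -> int:
        return len(self.states)

    def generator(self) -> np.ndarray:
        """Generator matrix M with dP/dt = M P (columns sum to zero)."""
        m = self.rates.T.copy()
        np.fill_diagonal(m, 0.0)
        m -= np.diag(self.rates.sum(axis=1))
        return m

    def audit_detailed_balance(self, temperature: float = T_DEFAULT,
                               rtol: float = 1e-6) -> None:
        """Check k_fwd/k_rev = exp(−ΔG/kBT) for every recorded reversible pair."""
        for (i, j), dg in self.delta_g.items():
            k_f, k_r = self.rates[i, j], self.rates[j, i]
            if k_r == 0:
                raise ValueError(f"pair {self.states[i]}->{self.states[j]} has no reverse rate")
            expected = math.exp(-dg / kbt(temperature))
            if abs(k_f / k_r - expected) > rtol * expected:
                raise ValueError(
                    f"detailed balance violated for {self.states[i]}<->{self.states[j]}: "
                    f"ratio {k_f / k_r:g}, expected {expected:g}")


@dataclass
class TimeCourse:
    times: np.ndarray
    probabilities: np.ndarray  # (n_times, n_states)
    states: list[str]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.probabilities, columns=self.states)
        df.insert(0, "time_s", self.times)
        return df

    def state_probability(self, labels: Sequence[str]) -> np.ndarray:
        idx = [self.states.index(s) for s in labels]
        return self.probabilities[:, idx].sum(axis=1)


@dataclass(frozen=True)
class TurnoverResult:
    t_half: float
    turnover: float
    flux: pd.DataFrame

    def __post_init__(self) -> None:
        if self.turnover <= 0:
            raise ValueError("turnover must be positive when the product is reached")


# ---------------------------------------------------------------------------
# network construction
# ---------------------------------------------------------------------------

Q_SPECIES = ("Q", "SQ", "QH2")


def _state_label(h2_red: int, h1_red: int, q: str) -> str:
    return f"h2{'r' if h2_red else 'o'}.h1{'r' if h1_red else 'o'}.{q}"


def _reverse_rate(k_fwd: float, dg_kcal: float, temperature: float) -> float:
    return k_fwd * math.exp(dg_kcal / kbt(temperature))


def build_soo_network(rate_table: Optional[pd.DataFrame] = None,
                      pcet_rate: float = 2.0e4,
                      delivery_rate: float = 1.0e8,
                      temperature: float = T_DEFAULT) -> KineticNetwork:
    """Assemble the two-electron superoxide→quinol cycle.

    Parameters
    ----------
    rate_table:
        Output of :func:`sookit.rates.rate_table` covering the
        superoxide→heme2, heme2→heme1 and heme1→Q steps (with their
        ΔG in eV).  Defaults to the printed distances/potentials
        (R = 9/11/6 Å, λ = 0.7 eV, ρ = 0.76; 0/−8/+100/+90 mV).
    pcet_rate:
        Irreversible rate (s⁻¹) of the final proton-coupled electron
        transfer forming QH₂, typically a TST conversion of the
        computed 12 kcal/mol barrier (~2×10⁴ s⁻¹).
    delivery_rate:
        Pseudo-first-order rate (s⁻¹) at which a fresh superoxide is
        delivered to the electron-entry site.  Acts in series with the
        9 Å tunneling step; the model's main free knob since the value
        used upstream is not printed.
    """
    if rate_table is None:
        from .rates import default_soo_steps, rate_table as _rt
        rate_table = _rt(default_soo_steps())
    if pcet_rate < 0 or delivery_rate <= 0:
        raise ValueError("rates must be positive")

    def lookup(donor: str, acceptor: str):
        row = rate_table[(rate_table.donor == donor) & (rate_table.acceptor == acceptor)]
        if row.empty:
            raise ValueError(f"rate table is missing the {donor}->{acceptor} transition")
        r = row.iloc[0]
        if r.k_per_s < 0:
            raise ValueError(f"negative rate for {donor}->{acceptor}")
        return float(r.k_per_s), float(r.dG_eV) * EV_TO_KCAL

    k_sup, dg_sup = lookup("superoxide", "heme2")
    k_hh, dg_hh = lookup("heme2", "heme1")
    k_hq, dg_hq = lookup("heme1", "Q")
    # delivery and tunneling act in series (steady-state two-step approximation)
    k_sup_eff = 1.0 / (1.0 / delivery_rate + 1.0 / k_sup)

    states = [_state_label(h2, h1, q) for h2 in (0, 1) for h1 in (0, 1) for q in Q_SPECIES]
    index = {s: i for i, s in enumerate(states)}
    n = len(states)
    rates = np.zeros((n, n))
    irreversible = set()
    delta_g = {}

    def add_reversible(i: int, j: int, k_fwd: float, dg: float) -> None:
        rates[i, j] = k_fwd
        rates[j, i] = _reverse_rate(k_fwd, dg, temperature)
        delta_g[(i, j)] = dg

    for q in Q_SPECIES:
        for h1 in (0, 1):
            i = index[_state_label(0, h1, q)]
            j = index[_state_label(1, h1, q)]
            add_reversible(i, j, k_sup_eff, dg_sup)          # superoxide -> heme 2
        i = index[_state_label(1, 0, q)]
        j = index[_state_label(0, 1, q)]
        add_reversible(i, j, k_hh, dg_hh)                    # heme 2 -> heme 1
    for h2 in (0, 1):
        i = index[_state_label(h2, 1, "Q")]
        j = index[_state_label(h2, 0, "SQ")]
        add_reversible(i, j, k_hq, dg_hq)                    # heme 1 -> Q (first e-)
        i = index[_state_label(h2, 1, "SQ")]
        j = index[_state_label(h2, 0, "QH2")]
        rates[i, j] = pcet_rate                              # final PCET, irreversible
        irreversible.add((i, j))

    p0 = np.zeros(n)
    p0[index[_state_label(0, 0, "Q")]] = 1.0
    return KineticNetwork(states=states, rates=rates, irreversible=irreversible,
                          p0=p0, delta_g=delta_g)


def product_states(network: KineticNetwork, species: str = "QH2") -> list[str]:
    return [s for s in network.states if s.endswith("." + species) or s == species]


# ---------------------------------------------------------------------------
# integration and turnover
# ---------------------------------------------------------------------------

def integrate(network: KineticNetwork, t_end: float,
              t_grid: Optional[np.ndarray] = None,
              n_points: int = 10_000,
              conservation_tol: float = 1e-8) -> TimeCourse:
    """Numerically integrate the master equation to ``t_end`` seconds.

    Uses a stiff-capable BDF integrator with the exact (constant) Jacobian.
    The output grid defaults to ``n_points`` log-spaced times.  Probability
    conservation is enforced to ``conservation_tol`` at every output.
    """
    if t_end <= 0:
        raise ValueError("t_end must be positive")
    m = network.generator()
    if t_grid is None:
        positive = network.rates[network.rates > 0]
        t0 = 1e-6 / positive.max() if positive.size else t_end * 1e-9
        t_grid = np.geomspace(min(t0, t_end / 10), t_end, n_points)
    t_grid = np.asarray(t_grid, dtype=float)

    sol = solve_ivp(lambda t, p: m @ p, (0.0, float(t_grid[-1])), network.p0,
                    t_eval=t_grid, method="BDF", jac=lambda t, p: m,
                    rtol=1e-10, atol=1e-13)
    if not sol.success:
        raise RuntimeError(f"master-equation integration failed: {sol.message}")
    probs = sol.y.T
    drift = np.abs(probs.sum(axis=1) - 1.0).max()
    if drift > conservation_tol:
        raise RuntimeError(f"probability conservation violated: max drift {drift:g}")
    if probs.min() < -conservation_tol:
        raise RuntimeError(f"negative probability encountered: {probs.min():g}")
    return TimeCourse(times=t_grid, probabilities=probs, states=list(network.states))


def _transition_flux(network: KineticNetwork, course: TimeCourse) -> pd.DataFrame:
    rows = []
    for i in range(network.n_states):
        for j in range(network.n_states):
            k = network.rates[i, j]
            if k > 0:
                flux = np.trapezoid(k * course.probabilities[:, i], course.times)
                rows.append({"from": network.states[i], "to": network.states[j],
                             "rate_per_s": k, "integrated_flux": flux})
    return pd.DataFrame(rows)


def turnover(network: KineticNetwork, product: Optional[Sequence[str]] = None,
             t_end: Optional[float] = None, n_points: int = 10_000) -> TurnoverResult:
    """Half-time of product formation and overall turnover k = ln2 / t½.

    ``product`` lists the state labels counted as product (default: every
    state carrying QH₂).  t½ is located by linear interpolation on the
    dense log-spaced output grid.
    """
    if product is None:
        product = product_states(network)
        if not product:
            raise ValueError("network has no QH2-carrying states; pass `product`")
    if t_end is None:
        slowest = network.rates[network.rates > 0].min()
        t_end = 200.0 / slowest
    course = integrate(network, t_end, n_points=n_points)
    p_prod = course.state_probability(product)
    above = np.nonzero(p_prod >= 0.5)[0]
    if above.size == 0:
        raise RuntimeError(
            f"product probability never reached 0.5 within t_end = {t_end:g} s "
            f"(final value {p_prod[-1]:.4f})")
    hi = above[0]
    if hi == 0:
        t_half = course.times[0]
    else:
        t0, t1 = course.times[hi - 1], course.times[hi]
        y0, y1 = p_prod[hi - 1], p_prod[hi]
        t_half = t0 + (0.5 - y0) * (t1 - t0) / (y1 - y0)
    return TurnoverResult(t_half=float(t_half), turnover=math.log(2) / float(t_half),
                          flux=_transition_flux(network, course))
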