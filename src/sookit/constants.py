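"""Physical constants shared across the package.

All free energies are carried in kcal/mol, distances in Å, redox
potentials in mV vs NHE, and rates in s⁻¹.  The simulation temperature is
310 K throughout; the corresponding thermal energy is centralized here so
that every module agrees on beta.
"""

#: Boltzmann constant, kcal mol⁻¹ K⁻¹.
KB_KCAL = 1.987204259e-3

#: Default simulation temperature (K).
T_DEFAULT = 310.0

#: Thermal energy at 310 K, kcal/mol.  Single shared constant.
KBT_310 = 0.6160

#: Faraday constant, kcal mol⁻¹ V⁻¹.
FARADAY_KCAL_PER_V = 23.061

#: Conversion: 1 eV in kcal/mol.
EV_TO_KCAL = 23.061

#: Nernst slope used for concentration corrections, mV per decade.
#: The conventional room-temperature value is used verbatim (not RT·ln10/F
#: at 310 K = 61.5 mV); configurable at the call sites.
NERNST_MV_PER_DECADE = 59.0

#: Transition-state-theory pre-exponential factor kBT/h, s⁻¹ (6 ps⁻¹).
TST_PREFACTOR = 6.0e12


def kbt(temperature: float = T_DEFAULT) -> float:
    """Thermal energy kB·T in kcal/mol at ``temperature`` (K).

    At the default 310 K this returns the shared :data:`KBT_310` constant
    exactly, so beta is identical everywhere in the package.
    """
    if temperature <= 0:
        raise ValueError(f"temperature must be positive, got {temperature}")
    if temperature == T_DEFAULT:
        return KBT_310
    return KB_KCAL * temperature
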