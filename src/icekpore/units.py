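"""Internal unit system and physical constants.

Every quantity inside the package is carried in the "molecular" unit system
commonly used for nanopore MD observables:

========= =======================
length    ångström (Å)
time      nanosecond (ns)
charge    elementary charge (e)
potential volt (V)
mass      dalton (Da)
temperature kelvin (K)
========= =======================

Derived units follow: energy e·V (= eV), velocity Å/ns (= 0.1 m/s), current
e/ns (≈ 160.2 pA), capacitance e/V, viscosity eV·ns/Å³, number density Å⁻³.

The CODATA-2018 exact constants are stored once, already converted, and the
helpers below translate the handful of quantities that users naturally supply
in lab units (mol/L, mPa·s, mC/m², nm, m/s).
"""

from __future__ import annotations

# --- exact SI defining constants --------------------------------------------
ELEMENTARY_CHARGE_C = 1.602176634e-19  # C
BOLTZMANN_SI = 1.380649e-23            # J/K
AVOGADRO = 6.02214076e23               # 1/mol
VACUUM_PERMITTIVITY_SI = 8.8541878128e-12  # F/m

# --- constants in internal units --------------------------------------------
#: vacuum permittivity, e/(V·Å)
EPS0 = VACUUM_PERMITTIVITY_SI / ELEMENTARY_CHARGE_C / 1e10  # 5.526349e-3
#: Boltzmann constant, eV/K
KB = BOLTZMANN_SI / ELEMENTARY_CHARGE_C  # 8.617333e-5

# --- conversion factors ------------------------------------------------------
#: multiply mol/L by this to get particles per Å³
MOLAR_TO_PER_A3 = AVOGADRO / 1e27  # 6.02214076e-4
#: multiply mPa·s by this to get eV·ns/Å³
MPAS_TO_INTERNAL = 1e-3 / ELEMENTARY_CHARGE_C * 1e9 / 1e30  # 6.2415091e-6
#: multiply mC/m² by this to get e/Å²
MC_PER_M2_TO_E_PER_A2 = 1e-3 / ELEMENTARY_CHARGE_C / 1e20  # 6.2415091e-5
#: multiply Å/ns by this to get m/s
A_PER_NS_TO_M_PER_S = 0.1
#: multiply e/ns by this to get pA
E_PER_NS_TO_PA = ELEMENTARY_CHARGE_C / 1e-9 / 1e-12  # 160.2176634
NM_TO_A = 10.0


def molar_to_per_A3(c_mol_per_l: float) -> float:
    """Concentration mol/L → number density Å⁻³."""
    return c_mol_per_l * MOLAR_TO_PER_A3


def viscosity_to_internal(eta_mpas: float) -> float:
    """Dynamic viscosity mPa·s → eV·ns/Å³."""
    return eta_mpas * MPAS_TO_INTERNAL


def surface_charge_to_internal(sigma_mc_per_m2: float) -> float:
    """Surface charge density mC/m² → e/Å²."""
    return sigma_mc_per_m2 * MC_PER_M2_TO_E_PER_A2


def velocity_to_si(v_A_per_ns: float) -> float:
    """Velocity Å/ns → m/s."""
    return v_A_per_ns * A_PER_NS_TO_M_PER_S


def velocity_from_si(v_m_per_s: float) -> float:
    """Velocity m/s → Å/ns."""
    return v_m_per_s / A_PER_NS_TO_M_PER_S


def current_to_pA(i_e_per_ns: float) -> float:
    """Current e/ns → pA."""
    return i_e_per_ns * E_PER_NS_TO_PA
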