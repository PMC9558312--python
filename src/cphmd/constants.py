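"""Physical constants in the MD unit system (kJ/mol, nm, ps, amu, e, K)."""

import math

#: Boltzmann constant, kJ/(mol K)
KB = 0.0083144621

#: Coulomb prefactor f = 1/(4 pi eps0), kJ mol^-1 nm e^-2
COULOMB = 138.935458

#: ln 10, used throughout the pH/pKa free-energy conversions
LN10 = math.log(10.0)


def kT(temperature: float) -> float:
    """Thermal energy k_B*T in kJ/mol."""
    return KB * temperature
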