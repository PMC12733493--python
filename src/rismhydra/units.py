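"""Physical constants and unit conventions.

Internal units throughout the package: lengths in Angstrom, energies in
kcal/mol, charges in elementary charge units, temperatures in Kelvin.
Potentials handed to the closures are always reduced by kT (dimensionless).
"""

#: Boltzmann constant, kcal/(mol K)
K_BOLTZMANN = 1.987204259e-3

#: Coulomb conversion factor: q1*q2*COULOMB/r gives kcal/mol for charges in e
#: and r in Angstrom (= e^2/(4 pi eps0) in these units).
COULOMB = 332.06371

#: Bohr radius in Angstrom (Gaussian CUBE files are written in Bohr).
BOHR = 0.529177210903

#: Angstrom per nanometre.
ANGSTROM_PER_NM = 10.0


def kT(temperature: float) -> float:
    """Thermal energy in kcal/mol at the given temperature (K)."""
    return K_BOLTZMANN * temperature
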